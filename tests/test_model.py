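"""Intensity, background families, and the exact log-likelihood."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from crashhawkes import (EventCatalog, HawkesModel, PiecewiseBackground,
                         SinusoidalBackground, StationaryBackground,
                         TriggeringParams, background_rate, compensator,
                         intensity_at, log_likelihood)
from crashhawkes.model import ModelError, decay_sums, decay_sums_direct
from crashhawkes.simulate import DEFAULT_ORIGIN, simulate_branching

TWO_PI = 2.0 * math.pi


def _cat(times, T, origin=DEFAULT_ORIGIN):
    return EventCatalog(np.asarray(times, dtype=float), origin, T)


class TestBackgroundRate:
    def test_stationary_constant(self):
        bg = StationaryBackground(0.495)
        for t in (0.0, 3.7, 1000.0):
            assert background_rate(bg, t, DEFAULT_ORIGIN) == 0.495

    def test_flat_sinusoid_reduces_to_constant(self):
        bg = SinusoidalBackground(0.3, 0.0, TWO_PI / 7, 0.0, 1.0)
        t = np.linspace(0, 21, 50)
        assert background_rate(bg, t, DEFAULT_ORIGIN) == pytest.approx([0.3] * 50)

    def test_weekly_piecewise_friday_to_sunday_ratio(self):
        mu_sun = 0.25
        rates = [0.3, 0.3, 0.3, 0.3, 1.36 * mu_sun, 0.3, mu_sun]
        bg = PiecewiseBackground.weekly(rates)
        # DEFAULT_ORIGIN is a Monday: Friday is day 4, Sunday day 6
        friday = background_rate(bg, 4.5, DEFAULT_ORIGIN)
        sunday = background_rate(bg, 6.5, DEFAULT_ORIGIN)
        assert friday / sunday == pytest.approx(1.36)

    def test_weekly_phase_anchored_to_origin_weekday(self):
        rates = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7]
        bg = PiecewiseBackground.weekly(rates)
        # origin weekday index 3 (Thursday) shifts the pattern
        assert bg.rate(0.5, weekday0=3) == 0.4
        assert bg.rate(4.5, weekday0=3) == 0.1  # wraps to Monday

    def test_rush_hour_bins(self):
        bg = PiecewiseBackground.daily_rush(0.2, 0.8, 1.1)
        assert bg.rate(7.5 / 24) == 0.8    # morning rush 06-09
        assert bg.rate(17.0 / 24) == 1.1   # evening rush 16-19
        assert bg.rate(12.0 / 24) == 0.2   # midday
        assert bg.rate(2.0 / 24) == 0.2    # night shares the non-rush rate

    def test_positivity_constraint_on_sinusoid(self):
        with pytest.raises(ModelError):
            SinusoidalBackground(0.3, 1.2, TWO_PI / 7, 0.0, 1.0)


class TestIntensity:
    def test_no_history_gives_background(self):
        m = HawkesModel(StationaryBackground(0.5), TriggeringParams(0.3, 10.0))
        assert intensity_at(m, _cat([], 10.0), 3.0) == 0.5

    def test_jump_just_after_an_event(self):
        m = HawkesModel(StationaryBackground(0.495),
                        TriggeringParams(0.114, 10.459))
        cat = _cat([1.0], 10.0)
        lam = intensity_at(m, cat, 1.0 + 1e-10)
        assert lam == pytest.approx(0.495 + 0.114 * 10.459, rel=1e-6)
        assert lam == pytest.approx(1.68733, abs=5e-6)

    def test_single_event_decay_closed_form(self):
        alpha = 8.0
        with pytest.warns(UserWarning, match="supercritical"):
            trig = TriggeringParams(1.0, alpha)
        m = HawkesModel(StationaryBackground(1e-9), trig)
        cat = _cat([0.0], 10.0)
        lam = intensity_at(m, cat, 1.0 / alpha)
        assert lam == pytest.approx(alpha * math.exp(-1.0), rel=1e-6)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(A=st.floats(0.01, 0.95), alpha=st.floats(0.5, 50.0))
    def test_kernel_integrates_to_branching_ratio(self, A, alpha):
        trig = TriggeringParams(A, alpha)
        total, _ = quad(lambda s: trig.kernel(s), 0, np.inf)
        assert total == pytest.approx(A, abs=1e-8)


def _segmented_quad(bg, t_end, weekday0):
    """Background integral by piecewise quadrature (independent oracle)."""
    per = bg.period_days
    offset = weekday0 if getattr(bg, "period", getattr(bg, "phase", None)) == "weekly" else 0.0
    # break at every period boundary of the phase variable
    ks = np.arange(math.ceil(offset / per), math.floor((t_end + offset) / per) + 1)
    breaks = np.unique(np.clip(ks * per - offset, 0.0, t_end))
    breaks = np.concatenate([[0.0], breaks, [t_end]])
    breaks = np.unique(breaks)
    total = 0.0
    for a, b in zip(breaks[:-1], breaks[1:]):
        total += quad(lambda s: float(np.atleast_1d(bg.rate(s, weekday0))[0]),
                      a, b, limit=400)[0]
    return total


class TestCompensator:
    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(mu0=st.floats(0.1, 2.0), P=st.floats(0.0, 0.8),
           Q=st.floats(0.4, 3.0), R=st.floats(0, TWO_PI),
           t_end=st.floats(0.5, 25.0),
           waveform=st.sampled_from(["sin", "cos"]),
           phase=st.sampled_from(["weekly", "daily"]),
           weekday0=st.integers(0, 6))
    def test_sinusoidal_integral_matches_quadrature(self, mu0, P, Q, R, t_end,
                                                    waveform, phase, weekday0):
        bg = SinusoidalBackground(mu0, P, Q, R, P + 1.0, phase, waveform)
        exact = bg.integral(t_end, weekday0)
        num = _segmented_quad(bg, t_end, weekday0)
        assert exact == pytest.approx(num, rel=1e-8, abs=1e-10)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(t_end=st.floats(0.5, 30.0), weekday0=st.integers(0, 6))
    def test_piecewise_integral_matches_quadrature(self, t_end, weekday0):
        rates = [0.2, 0.3, 0.4, 0.5, 0.6, 0.45, 0.25]
        bg = PiecewiseBackground.weekly(rates)
        exact = bg.integral(t_end, weekday0)
        # independent oracle: rate is constant over each whole day, so sum
        # day-rate times the day's overlap with [0, t_end]
        total = 0.0
        for d in range(int(math.ceil(t_end))):
            overlap = min(d + 1.0, t_end) - d
            total += rates[(d + weekday0) % 7] * overlap
        assert exact == pytest.approx(total, rel=1e-12)

    def test_rush_hour_integral_exact_over_whole_days(self):
        bg = PiecewiseBackground.daily_rush(0.2, 0.8, 1.1)
        per_day = 0.2 * (18 / 24) + 0.8 * (3 / 24) + 1.1 * (3 / 24)
        assert bg.integral(5.0) == pytest.approx(5 * per_day, rel=1e-12)

    def test_compensator_nondecreasing(self, stationary_truth, sim_small):
        cat = sim_small.catalog
        ts = np.linspace(0, cat.window_end, 80)
        vals = [compensator(stationary_truth, cat, t) for t in ts]
        assert np.all(np.diff(vals) >= -1e-12)


class TestLogLikelihood:
    def test_empty_catalog_is_minus_compensator(self):
        m = HawkesModel(StationaryBackground(0.7), TriggeringParams(0.2, 5.0))
        assert log_likelihood(m, _cat([], 12.0)) == pytest.approx(-0.7 * 12.0)

    def test_single_event_closed_form(self):
        mu, A, alpha, t1, T = 0.4, 0.3, 9.0, 2.5, 10.0
        m = HawkesModel(StationaryBackground(mu), TriggeringParams(A, alpha))
        expected = math.log(mu) - mu * T - A * (1 - math.exp(-alpha * (T - t1)))
        assert log_likelihood(m, _cat([t1], T)) == pytest.approx(expected, rel=1e-12)

    def test_recursion_equals_direct_sum(self, stationary_truth):
        syn = simulate_branching(stationary_truth, 200.0, seed=11)
        cat = syn.catalog
        assert cat.n >= 50
        ll_r = log_likelihood(stationary_truth, cat, method="recursion")
        ll_d = log_likelihood(stationary_truth, cat, method="direct")
        assert ll_r == pytest.approx(ll_d, rel=1e-9)

    def test_decay_sums_recursion_vs_direct(self):
        rng = np.random.default_rng(3)
        t = np.sort(rng.uniform(0, 50, size=120))
        assert decay_sums(t, 7.5) == pytest.approx(decay_sums_direct(t, 7.5),
                                                   rel=1e-9, abs=1e-12)

    def test_zero_excitation_reduces_to_poisson(self):
        bg = SinusoidalBackground(0.6, 0.3, TWO_PI / 7, 0.4, 1.0)
        m = HawkesModel(bg, TriggeringParams(0.0, 5.0))
        cat = _cat([0.5, 2.0, 3.3, 6.1, 9.9], 14.0)
        w0 = cat.origin_weekday
        poisson = (float(np.sum(np.log(bg.rate(cat.times, w0))))
                   - bg.integral(cat.window_end, w0))
        assert log_likelihood(m, cat) == pytest.approx(poisson, rel=1e-12)


class TestSerialization:
    @pytest.mark.parametrize("bg", [
        StationaryBackground(0.495),
        PiecewiseBackground.weekly([0.2, 0.3, 0.4, 0.5, 0.6, 0.45, 0.25]),
        PiecewiseBackground.daily_rush(0.2, 0.8, 1.1),
        SinusoidalBackground(0.5, 0.3, TWO_PI / 7, 1.0, 1.0, "weekly", "sin"),
        SinusoidalBackground(0.5, 0.3, TWO_PI, 1.0, 1.0, "daily", "cos"),
    ])
    def test_model_json_round_trip(self, bg):
        m = HawkesModel(bg, TriggeringParams(0.114, 10.459))
        m2 = HawkesModel.from_json(m.to_json())
        t = np.linspace(0, 14, 29)
        assert np.allclose(m2.background.rate(t, 2), m.background.rate(t, 2))
        assert m2.trigger == m.trigger

    def test_supercritical_warns(self):
        with pytest.warns(UserWarning, match="supercritical"):
            TriggeringParams(1.2, 5.0)
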