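"""Model fitting: MLE of the Hawkes parameters, least-squares fitting of
periodic background shapes from crash-count histograms, and AIC comparison.

Fitting is two-stage for the sinusoidal family, mirroring how periodic
traffic structure is usually extracted from crash data: the shape
parameters (P, Q, R, S) are fitted to the weekday or hour-of-day histogram
first and then held fixed, leaving (mu0, A, alpha) free in the likelihood.
All positive parameters are optimized as logarithms with a quasi-Newton
method (L-BFGS-B), with seeded random restarts against local optima.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize

from .catalog import EventCatalog
from .model import (DEFAULT_RUSH_HOURS, TWO_PI, WEEKDAY_NAMES, Background,
                    HawkesModel, PiecewiseBackground, SinusoidalBackground,
                    StationaryBackground, TriggeringParams, log_likelihood)

FAMILIES = ("stationary", "piecewise-weekly", "piecewise-daily",
            "sinusoidal-weekly", "sinusoidal-daily")


class FitError(RuntimeError):
    """Estimation failed in a way the caller must handle."""


@dataclass
class FitResult:
    """Outcome of a maximum-likelihood fit.

    ``aic = 2 * n_params - 2 * loglik``; ``n_params`` counts only the
    parameters that were free in the likelihood (fixed sinusoidal shape
    parameters are excluded).
    """

    model: HawkesModel
    family: str
    loglik: float
    n_params: int
    converged: bool
    n_iter: int
    gradient_norm: float

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.loglik

    def to_dict(self) -> dict:
        return {"family": self.family, "model": self.model.to_dict(),
                "loglik": self.loglik, "n_params": self.n_params,
                "aic": self.aic, "converged": self.converged,
                "n_iter": self.n_iter, "gradient_norm": self.gradient_norm}


@dataclass
class HistogramData:
    """Event counts over period bins (7 weekdays or 24 hours)."""

    bin_labels: list[str]
    counts: np.ndarray
    period: str  # 'weekly' or 'daily'

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.size != len(self.bin_labels):
            raise ValueError("counts and bin_labels length mismatch")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if self.period not in ("weekly", "daily"):
            raise ValueError(f"period must be 'weekly' or 'daily', got {self.period!r}")

    @property
    def period_days(self) -> float:
        return 7.0 if self.period == "weekly" else 1.0


@dataclass(frozen=True)
class ShapeParams:
    """Fitted periodic shape mu(u)/mu0 = P * wave(Q u + R) + S."""

    P: float
    Q: float
    R: float
    S: float
    waveform: str
    period: str
    flat: bool = False


def histogram_from_catalog(catalog: EventCatalog, period: str = "weekly") -> HistogramData:
    """Weekday (Monday-first) or hour-of-day histogram of the event times."""
    t = catalog.times
    if period == "weekly":
        idx = (np.floor(t).astype(int) + catalog.origin_weekday) % 7
        counts = np.bincount(idx, minlength=7)[:7]
        return HistogramData(list(WEEKDAY_NAMES), counts, "weekly")
    if period == "daily":
        idx = np.floor((t % 1.0) * 24.0).astype(int) % 24
        counts = np.bincount(idx, minlength=24)[:24]
        return HistogramData([f"{h:02d}:00" for h in range(24)], counts, "daily")
    raise ValueError(f"period must be 'weekly' or 'daily', got {period!r}")


def fit_background_shape(hist: HistogramData, waveform: str = "sin") -> ShapeParams:
    """Least-squares fit of ``P * wave(Q x + R) + S`` to normalized counts.

    Counts are normalized to unit mean so the overall level is absorbed into
    ``mu0`` during the likelihood stage.  A constant histogram yields the
    degenerate flat shape (P = 0, S = 1) with ``flat=True``.  The positivity
    constraint ``S > |P|`` is enforced on the result.
    """
    if waveform not in ("sin", "cos"):
        raise ValueError(f"waveform must be 'sin' or 'cos', got {waveform!r}")
    counts = hist.counts
    n = counts.size
    if n < 4:
        raise ValueError("need at least 4 bins to fit 4 shape parameters")
    if counts.sum() <= 0:
        raise ValueError("histogram is empty")
    per = hist.period_days
    x = (np.arange(n) + 0.5) * per / n  # bin centers on the day axis
    y = counts / counts.mean()

    q0 = TWO_PI / per
    if np.ptp(y) < 1e-10 * max(1.0, np.abs(y).max()):
        return ShapeParams(0.0, q0, 0.0, 1.0, waveform, hist.period, flat=True)

    # linear init at the fundamental frequency: y - 1 ~ a cos(q0 x) + b sin(q0 x)
    G = np.column_stack([np.cos(q0 * x), np.sin(q0 * x)])
    a, b = np.linalg.lstsq(G, y - 1.0, rcond=None)[0]
    amp = math.hypot(a, b)
    if waveform == "cos":
        # P cos(Qx+R) = P cosR cos - P sinR sin
        r0 = math.atan2(-b, a)
    else:
        # P sin(Qx+R) = P sinR cos + P cosR sin
        r0 = math.atan2(a, b)
    p0 = max(amp, 1e-6)

    wave = np.sin if waveform == "sin" else np.cos

    def resid(theta):
        P, Q, R, S = theta
        return P * wave(Q * x + R) + S - y

    sol = least_squares(resid, x0=[p0, q0, r0, 1.0], xtol=1e-14, ftol=1e-14, gtol=1e-14)
    P, Q, R, S = sol.x
    if Q < 0:  # wave(-Qx+R) = +/- wave(Qx-R): fold the frequency positive
        Q = -Q
        R = -R if waveform == "cos" else math.pi - R
    if P < 0:
        P, R = -P, R + math.pi
    R = math.remainder(R, TWO_PI)
    if S <= abs(P):
        S = abs(P) + max(1e-9, 1e-9 * abs(P))
    return ShapeParams(float(P), float(Q), float(R), float(S),
                       waveform, hist.period, flat=False)


def _family_period(family: str) -> tuple[str, str | None]:
    if family == "stationary":
        return "stationary", None
    try:
        base, period = family.split("-")
    except ValueError:
        raise FitError(f"unknown family {family!r}; expected one of {FAMILIES}") from None
    if (base not in ("piecewise", "sinusoidal")) or (period not in ("weekly", "daily")):
        raise FitError(f"unknown family {family!r}; expected one of {FAMILIES}")
    return base, period


def _builder(family: str, catalog: EventCatalog, shape: ShapeParams | None,
             waveform: str | None, rush_hours) -> tuple:
    """Return (build(theta) -> HawkesModel, x0, n_params, shape_used)."""
    base, period = _family_period(family)
    N, T = max(catalog.n, 1), catalog.window_end
    mu_init = 0.5 * N / T
    a_init, alpha_init = 0.5, 10.0

    if base == "stationary":
        def build(th):
            return HawkesModel(StationaryBackground(th[0]), TriggeringParams(th[1], th[2]))
        return build, np.array([mu_init, a_init, alpha_init]), 3, None

    if base == "piecewise":
        k = 7 if period == "weekly" else 3

        def build(th, _k=k, _period=period):
            if _period == "weekly":
                bg = PiecewiseBackground.weekly(th[:_k])
            else:
                bg = PiecewiseBackground.daily_rush(th[0], th[1], th[2], rush_hours)
            return HawkesModel(bg, TriggeringParams(th[_k], th[_k + 1]))
        x0 = np.concatenate([np.full(k, mu_init), [a_init, alpha_init]])
        return build, x0, k + 2, None

    # sinusoidal: shape fixed, (mu0, A, alpha) free
    if shape is None:
        wf = waveform or ("sin" if period == "weekly" else "cos")
        hist = histogram_from_catalog(catalog, period)
        shape = fit_background_shape(hist, wf)

    def build(th, _s=shape, _period=period):
        bg = SinusoidalBackground(th[0], _s.P, _s.Q, _s.R, _s.S,
                                  phase=_period, waveform=_s.waveform)
        return HawkesModel(bg, TriggeringParams(th[1], th[2]))
    return build, np.array([mu_init, a_init, alpha_init]), 3, shape


def fit_mle(catalog: EventCatalog, family: str = "stationary", *,
            shape: ShapeParams | None = None, waveform: str | None = None,
            rush_hours=DEFAULT_RUSH_HOURS, n_restarts: int = 3, seed: int = 0,
            gtol: float = 1e-6, maxiter: int = 500, min_events: int = 10,
            param_space: str = "log",
            extra_starts: list[np.ndarray] | None = None) -> FitResult:
    """Maximum-likelihood fit of a Hawkes model to an event catalog.

    Parameters are kept in the positive orthant either by optimizing their
    logarithms (default) or by box bounds in natural space
    (``param_space='natural'``); both reach the same optimum.  ``seed``
    controls the random restarts.  Non-convergence returns the best point
    found with ``converged=False`` rather than raising.
    """
    if catalog.n < min_events:
        raise FitError(f"catalog has {catalog.n} events; need at least {min_events}")
    if param_space not in ("log", "natural"):
        raise ValueError(f"param_space must be 'log' or 'natural', got {param_space!r}")

    build, x0_nat, n_params, _ = _builder(family, catalog, shape, waveform, rush_hours)

    with np.errstate(over="ignore"):
        def nll(z):
            theta = np.exp(np.clip(z, -40.0, 40.0)) if param_space == "log" else z
            try:
                import warnings as _w
                with _w.catch_warnings():
                    _w.simplefilter("ignore")
                    model = build(theta)
            except Exception:
                return 1e12
            ll = log_likelihood(model, catalog)
            return -ll if math.isfinite(ll) else 1e12

        rng = np.random.default_rng(seed)
        starts = [np.log(x0_nat)]
        for _ in range(n_restarts):
            starts.append(np.log(x0_nat) + rng.normal(0.0, 0.7, size=x0_nat.size))
        if extra_starts:
            starts.extend(np.log(np.asarray(s, dtype=float)) for s in extra_starts)
        if param_space == "natural":
            starts = [np.exp(s) for s in starts]

        best = None
        n_iter = 0
        kwargs = {"method": "L-BFGS-B",
                  "options": {"maxiter": maxiter, "gtol": gtol, "ftol": 1e-12}}
        if param_space == "natural":
            kwargs["bounds"] = [(1e-10, None)] * x0_nat.size
        for s in starts:
            res = minimize(nll, s, **kwargs)
            n_iter += res.nit
            if best is None or res.fun < best.fun:
                best = res

    theta = np.exp(best.x) if param_space == "log" else np.asarray(best.x)
    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore")
        model = build(theta)
    grad_norm = float(np.max(np.abs(best.jac))) if best.jac is not None else math.nan
    return FitResult(model=model, family=family, loglik=-float(best.fun),
                     n_params=n_params, converged=bool(best.success),
                     n_iter=int(n_iter), gradient_norm=grad_norm)


def compare_models(catalog: EventCatalog,
                   families=("stationary", "piecewise-weekly", "sinusoidal-weekly"),
                   seed: int = 0, **fit_kwargs) -> list[FitResult]:
    """Fit several background families and rank them by AIC (ascending).

    Ties are broken by fewer parameters (parsimony).  A family whose fit
    raises is skipped with a warning; the rest are still ranked.  To make
    nesting exact, non-stationary families receive the fitted stationary
    solution as an additional optimizer start when it is available.
    """
    if len(families) < 2:
        raise FitError("need at least 2 families to compare")
    results: list[FitResult] = []
    stationary_start = None
    order = sorted(families, key=lambda f: f != "stationary")  # stationary first
    for fam in order:
        kw = dict(fit_kwargs)
        if fam != "stationary" and stationary_start is not None:
            mu, A, alpha = stationary_start
            base, period = _family_period(fam)
            k = (7 if period == "weekly" else 3) if base == "piecewise" else 1
            start = np.concatenate([np.full(k, mu), [A, alpha]])
            kw.setdefault("extra_starts", []).append(start)
        try:
            fit = fit_mle(catalog, fam, seed=seed, **kw)
        except FitError:
            import warnings
            warnings.warn(f"family {fam!r} failed to fit; skipping", stacklevel=2)
            continue
        if fam == "stationary":
            stationary_start = (fit.model.background.mu, fit.model.trigger.A,
                                fit.model.trigger.alpha)
        results.append(fit)
    return sorted(results, key=lambda r: (r.aic, r.n_params))


def aic_table(results: list[FitResult]) -> pd.DataFrame:
    """AIC comparison table: family, k, loglik, AIC (sorted ascending)."""
    return pd.DataFrame([{"family": r.family, "k": r.n_params,
                          "loglik": r.loglik, "aic": r.aic} for r in results])
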