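"""Hawkes (self-exciting) model: background families, intensity, likelihood.

The conditional intensity is

    lambda(t) = mu(t) + A * sum_{t_i < t} alpha * exp(-alpha * (t - t_i))

where ``mu(t)`` is the background (primary-event) rate and each prior event
contributes a decaying excitation.  ``A`` is the branching ratio — the
expected number of triggered (secondary) events per event — and ``1/alpha``
is the mean trigger delay in days.  Three background families are provided:
stationary, piecewise-constant over calendar bins (day-of-week or
rush-hour), and sinusoidal with a weekly or daily phase.

The log-likelihood over an observation window [0, T] is

    l = sum_i log lambda(t_i) - integral_0^T lambda(t) dt,

with the compensator integral in closed form for every background family
and the event sum evaluated by the standard O(N) exponential-kernel
recursion (a direct O(N^2) evaluation is kept as a cross-check).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from datetime import datetime

import numpy as np

from .catalog import EventCatalog

TWO_PI = 2.0 * math.pi
#: Default rush-hour bin edges in hours: 06-09 morning, 16-19 evening.
DEFAULT_RUSH_HOURS = (6.0, 9.0, 16.0, 19.0)
WEEKDAY_NAMES = ("Monday", "Tuesday", "Wednesday", "Thursday",
                 "Friday", "Saturday", "Sunday")


class ModelError(ValueError):
    """Invalid model specification."""


@dataclass(frozen=True)
class TriggeringParams:
    """Exponential triggering kernel g(s) = A * alpha * exp(-alpha * s).

    ``A`` (dimensionless) is the expected offspring count per event and
    ``alpha`` (1/day) the decay rate; the kernel integrates to ``A``.
    """

    A: float
    alpha: float

    def __post_init__(self):
        if self.A < 0:
            raise ModelError(f"A must be >= 0, got {self.A}")
        if self.alpha <= 0:
            raise ModelError(f"alpha must be > 0, got {self.alpha}")
        if self.A >= 1:
            warnings.warn(f"A = {self.A} >= 1: the process is supercritical "
                          "(expected cluster size diverges)", stacklevel=2)

    def kernel(self, s):
        """Triggering density A*alpha*exp(-alpha*s) for lags s >= 0."""
        s = np.asarray(s, dtype=float)
        return np.where(s >= 0, self.A * self.alpha * np.exp(-self.alpha * np.minimum(s, 700 / self.alpha)), 0.0)


class Background:
    """Interface for background-rate families.

    ``weekday0`` is the weekday of the catalog origin (Monday = 0); weekly
    families use it to anchor t = 0 at the right position in the week.
    """

    period_days: float | None = None

    def rate(self, t, weekday0: int = 0):
        raise NotImplementedError

    def integral(self, t: float, weekday0: int = 0) -> float:
        """Cumulative integral of the rate over [0, t]."""
        raise NotImplementedError

    def max_rate(self) -> float:
        raise NotImplementedError

    def to_dict(self) -> dict:
        raise NotImplementedError


@dataclass(frozen=True)
class StationaryBackground(Background):
    """Constant background rate mu (events/day)."""

    mu: float

    def __post_init__(self):
        if self.mu <= 0:
            raise ModelError(f"mu must be > 0, got {self.mu}")

    def rate(self, t, weekday0: int = 0):
        return np.broadcast_to(self.mu, np.shape(t)).copy() if np.ndim(t) else self.mu

    def integral(self, t: float, weekday0: int = 0) -> float:
        return self.mu * t

    def max_rate(self) -> float:
        return self.mu

    def to_dict(self) -> dict:
        return {"type": "stationary", "mu": self.mu}


class PiecewiseBackground(Background):
    """Step-function background over calendar bins tiling a period.

    Parameters
    ----------
    rates
        The K free rate parameters (events/day).
    edges
        Bin edges in days within the period, from 0 to the period length.
    period
        ``'weekly'`` (period 7 days, phase anchored to the weekday of the
        origin) or ``'daily'`` (period 1 day, anchored to midnight).
    rate_index
        Maps each inter-edge interval to one of the K rates, so disjoint
        intervals (e.g. all non-rush hours) can share a parameter.
    """

    def __init__(self, rates, edges, period: str = "weekly",
                 rate_index=None, labels=None):
        self.rates = np.asarray(rates, dtype=float)
        self.edges = np.asarray(edges, dtype=float)
        if period not in ("weekly", "daily"):
            raise ModelError(f"period must be 'weekly' or 'daily', got {period!r}")
        self.period = period
        self.period_days = 7.0 if period == "weekly" else 1.0
        if self.edges[0] != 0.0 or abs(self.edges[-1] - self.period_days) > 1e-12:
            raise ModelError("edges must tile the period exactly")
        if np.any(np.diff(self.edges) <= 0):
            raise ModelError("edges must be strictly increasing")
        n_int = self.edges.size - 1
        self.rate_index = (np.arange(n_int) if rate_index is None
                           else np.asarray(rate_index, dtype=int))
        if self.rate_index.size != n_int:
            raise ModelError("rate_index must have one entry per interval")
        if np.any(self.rates <= 0):
            raise ModelError("all rates must be > 0")
        self.labels = list(labels) if labels is not None else None
        # cumulative integral at the bin edges, one period
        widths = np.diff(self.edges)
        self._cum = np.concatenate([[0.0], np.cumsum(self.rates[self.rate_index] * widths)])

    @classmethod
    def weekly(cls, rates) -> "PiecewiseBackground":
        """Seven day-of-week rates, Monday first."""
        rates = np.asarray(rates, dtype=float)
        if rates.size != 7:
            raise ModelError("weekly background needs 7 rates")
        return cls(rates, np.arange(8.0), period="weekly", labels=list(WEEKDAY_NAMES))

    @classmethod
    def daily_rush(cls, non_rush: float, morning: float, evening: float,
                   rush_hours=DEFAULT_RUSH_HOURS) -> "PiecewiseBackground":
        """Three time-of-day rates: non-rush, morning rush, evening rush."""
        h = np.asarray(rush_hours, dtype=float) / 24.0
        edges = np.concatenate([[0.0], h, [1.0]])
        return cls([non_rush, morning, evening], edges, period="daily",
                   rate_index=[0, 1, 0, 2, 0],
                   labels=["non-rush", "morning-rush", "evening-rush"])

    def _phase(self, t, weekday0: int):
        offset = weekday0 if self.period == "weekly" else 0.0
        return np.mod(np.asarray(t, dtype=float) + offset, self.period_days)

    def bin_of(self, t, weekday0: int = 0):
        """Index of the interval (not the rate parameter) containing t."""
        u = self._phase(t, weekday0)
        idx = np.searchsorted(self.edges, u, side="right") - 1
        return np.clip(idx, 0, self.edges.size - 2)

    def rate(self, t, weekday0: int = 0):
        out = self.rates[self.rate_index[self.bin_of(t, weekday0)]]
        return float(out) if np.ndim(t) == 0 else out

    def _antiderivative(self, u: float) -> float:
        """Integral of one period's pattern from phase 0 to phase u."""
        k = min(int(np.searchsorted(self.edges, u, side="right")) - 1,
                self.edges.size - 2)
        k = max(k, 0)
        return self._cum[k] + self.rates[self.rate_index[k]] * (u - self.edges[k])

    def integral(self, t: float, weekday0: int = 0) -> float:
        offset = weekday0 if self.period == "weekly" else 0.0

        def F(x):
            n_full, rem = divmod(x, self.period_days)
            return n_full * self._cum[-1] + self._antiderivative(rem)

        return F(t + offset) - F(offset)

    def max_rate(self) -> float:
        return float(np.max(self.rates))

    def to_dict(self) -> dict:
        return {"type": "piecewise", "period": self.period,
                "rates": self.rates.tolist(), "edges": self.edges.tolist(),
                "rate_index": self.rate_index.tolist(), "labels": self.labels}

    @classmethod
    def from_dict(cls, d: dict) -> "PiecewiseBackground":
        return cls(d["rates"], d["edges"], d.get("period", "weekly"),
                   d.get("rate_index"), d.get("labels"))


@dataclass(frozen=True)
class SinusoidalBackground(Background):
    """Sinusoidal background mu0 * {P * wave(Q * u + R) + S}.

    ``u`` is the periodic phase variable: days since the start of the week
    (Monday) for ``phase='weekly'``, or days since midnight for
    ``phase='daily'``.  ``Q`` is in radians/day (2*pi/period for one cycle
    per period), ``R`` in radians, ``P`` and ``S`` dimensionless with
    ``S > |P|`` so the rate stays positive.  ``waveform`` selects sin
    (weekly convention) or cos (daily convention).
    """

    mu0: float
    P: float
    Q: float
    R: float
    S: float
    phase: str = "weekly"
    waveform: str = "sin"

    def __post_init__(self):
        if self.mu0 <= 0:
            raise ModelError(f"mu0 must be > 0, got {self.mu0}")
        if self.S <= abs(self.P):
            raise ModelError(f"need S > |P| for positivity (S={self.S}, P={self.P})")
        if self.phase not in ("weekly", "daily"):
            raise ModelError(f"phase must be 'weekly' or 'daily', got {self.phase!r}")
        if self.waveform not in ("sin", "cos"):
            raise ModelError(f"waveform must be 'sin' or 'cos', got {self.waveform!r}")
        if self.Q <= 0:
            raise ModelError(f"Q must be > 0, got {self.Q}")

    @property
    def period_days(self) -> float:  # type: ignore[override]
        return 7.0 if self.phase == "weekly" else 1.0

    def _wave(self, x):
        return np.sin(x) if self.waveform == "sin" else np.cos(x)

    def rate(self, t, weekday0: int = 0):
        offset = weekday0 if self.phase == "weekly" else 0.0
        u = np.mod(np.asarray(t, dtype=float) + offset, self.period_days)
        out = self.mu0 * (self.P * self._wave(self.Q * u + self.R) + self.S)
        return float(out) if np.ndim(t) == 0 else out

    def _antiderivative(self, u: float) -> float:
        # integral of P*wave(Q v + R) + S over v in [0, u]
        if self.waveform == "sin":
            trig = -(self.P / self.Q) * (math.cos(self.Q * u + self.R) - math.cos(self.R))
        else:
            trig = (self.P / self.Q) * (math.sin(self.Q * u + self.R) - math.sin(self.R))
        return trig + self.S * u

    def integral(self, t: float, weekday0: int = 0) -> float:
        offset = weekday0 if self.phase == "weekly" else 0.0
        per = self.period_days
        per_int = self._antiderivative(per)

        def F(x):
            n_full, rem = divmod(x, per)
            return n_full * per_int + self._antiderivative(rem)

        return self.mu0 * (F(t + offset) - F(offset))

    def max_rate(self) -> float:
        return self.mu0 * (abs(self.P) + self.S)

    def to_dict(self) -> dict:
        return {"type": "sinusoidal", "mu0": self.mu0, "P": self.P, "Q": self.Q,
                "R": self.R, "S": self.S, "phase": self.phase,
                "waveform": self.waveform}


def background_from_dict(d: dict) -> Background:
    kind = d.get("type")
    if kind == "stationary":
        return StationaryBackground(d["mu"])
    if kind == "piecewise":
        return PiecewiseBackground.from_dict(d)
    if kind == "sinusoidal":
        return SinusoidalBackground(d["mu0"], d["P"], d["Q"], d["R"], d["S"],
                                    d.get("phase", "weekly"), d.get("waveform", "sin"))
    raise ModelError(f"unknown background type {kind!r}")


@dataclass(frozen=True)
class HawkesModel:
    """A background specification plus triggering parameters."""

    background: Background
    trigger: TriggeringParams

    def to_dict(self) -> dict:
        return {"background": self.background.to_dict(),
                "trigger": {"A": self.trigger.A, "alpha": self.trigger.alpha}}

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "HawkesModel":
        trig = d["trigger"]
        return cls(background_from_dict(d["background"]),
                   TriggeringParams(trig["A"], trig["alpha"]))

    @classmethod
    def from_json(cls, text: str) -> "HawkesModel":
        return cls.from_dict(json.loads(text))


def background_rate(spec: Background, t, origin: datetime | int = 0):
    """Background rate at time ``t`` days after ``origin``.

    ``origin`` may be a calendar date-time or directly the weekday index of
    t = 0 (Monday = 0).
    """
    weekday0 = origin.weekday() if isinstance(origin, datetime) else int(origin)
    return spec.rate(t, weekday0)


def decay_sums(times: np.ndarray, alpha: float) -> np.ndarray:
    """S_i = sum_{j < i} exp(-alpha (t_i - t_j)) via the O(N) recursion."""
    n = times.size
    out = np.empty(n)
    if n == 0:
        return out
    out[0] = 0.0
    s = 0.0
    t = times
    for i in range(1, n):
        s = (s + 1.0) * math.exp(-alpha * (t[i] - t[i - 1]))
        out[i] = s
    return out


def decay_sums_direct(times: np.ndarray, alpha: float) -> np.ndarray:
    """O(N^2) direct evaluation of the decay sums (oracle for the recursion)."""
    t = np.asarray(times, dtype=float)
    diff = t[:, None] - t[None, :]
    mask = np.tril(np.ones((t.size, t.size), dtype=bool), k=-1)
    contrib = np.where(mask, np.exp(-alpha * np.where(mask, diff, 0.0)), 0.0)
    return contrib.sum(axis=1)


def intensity_at(model: HawkesModel, catalog: EventCatalog, t: float) -> float:
    """Conditional intensity lambda(t) given the catalog history before t."""
    A, alpha = model.trigger.A, model.trigger.alpha
    prior = catalog.times[catalog.times < t]
    excite = A * alpha * float(np.sum(np.exp(-alpha * (t - prior)))) if prior.size else 0.0
    return float(model.background.rate(t, catalog.origin_weekday)) + excite


def event_intensities(model: HawkesModel, catalog: EventCatalog,
                      method: str = "recursion") -> np.ndarray:
    """lambda(t_i) at every event time, history-exclusive."""
    A, alpha = model.trigger.A, model.trigger.alpha
    sums = (decay_sums if method == "recursion" else decay_sums_direct)(catalog.times, alpha)
    mu = np.atleast_1d(model.background.rate(catalog.times, catalog.origin_weekday))
    return mu + A * alpha * sums


def compensator(model: HawkesModel, catalog: EventCatalog, t: float | None = None) -> float:
    """Integrated intensity over [0, t] (t defaults to the window end)."""
    if t is None:
        t = catalog.window_end
    A, alpha = model.trigger.A, model.trigger.alpha
    prior = catalog.times[catalog.times < t]
    bg = model.background.integral(t, catalog.origin_weekday)
    trig = A * float(np.sum(1.0 - np.exp(-alpha * (t - prior)))) if prior.size else 0.0
    return bg + trig


def log_likelihood(model: HawkesModel, catalog: EventCatalog,
                   method: str = "recursion") -> float:
    """Exact log-likelihood of the catalog under the model.

    ``method='direct'`` uses the O(N^2) event sum as an independent check of
    the O(N) recursion.  Returns ``-inf`` when any event intensity is
    non-positive (a rejected point in optimization).
    """
    if method not in ("recursion", "direct"):
        raise ValueError(f"unknown method {method!r}")
    T = catalog.window_end
    if catalog.n == 0:
        return -model.background.integral(T, catalog.origin_weekday)
    lam = event_intensities(model, catalog, method)
    if np.any(lam <= 0) or not np.all(np.isfinite(lam)):
        return -math.inf
    return float(np.sum(np.log(lam)) - compensator(model, catalog, T))
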