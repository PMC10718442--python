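"""Stochastic declustering: triggering probabilities, primary/secondary
classification, and queue-time extraction.

Given a fitted model, every ordered pair of events (i before j) receives
the probability that i triggered j,

    p_ij = A * alpha * exp(-alpha (t_j - t_i)) / lambda(t_j),

so p_j = sum_{i<j} p_ij is the probability that j is a secondary (triggered)
event and 1 - p_j = mu(t_j) / lambda(t_j) that it is primary.  These terms
partition the intensity, so p_j + mu/lambda = 1 holds to machine precision.

The classification rule mirrors common post-processing practice: event j is
labeled secondary when the gap to the immediately preceding event is below
the queue time (1/alpha, in minutes) AND p_j clears a probability
threshold.  Both ingredients are exposed separately so alternative rules
can be applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .catalog import EventCatalog
from .estimate import FitError, FitResult, fit_mle
from .model import HawkesModel, TriggeringParams, decay_sums

MINUTES_PER_DAY = 1440.0


@dataclass
class ClassificationConfig:
    """Temporal threshold (minutes) and probability threshold for labeling."""

    queue_time_min: float
    prob_threshold: float = 0.5

    def __post_init__(self):
        if self.queue_time_min <= 0:
            raise ValueError("queue_time_min must be positive")
        if not 0.0 <= self.prob_threshold <= 1.0:
            raise ValueError("prob_threshold must be in [0, 1]")


@dataclass
class DeclusterResult:
    """Triggering-probability structure for one catalog.

    ``p_pairs`` maps (i, j) with i < j to p_ij, pruned below a floor for
    sparsity (``prune=0`` keeps every pair).  ``p_secondary`` is the exact
    per-event p_j computed by the O(N) recursion, not the pruned sum.
    """

    p_pairs: dict[tuple[int, int], float]
    p_secondary: np.ndarray
    p_primary: np.ndarray
    labels: np.ndarray | None = None

    @property
    def n(self) -> int:
        return int(self.p_secondary.size)

    def pair_matrix(self) -> np.ndarray:
        """Dense (n, n) matrix of p_ij from the stored pairs."""
        m = np.zeros((self.n, self.n))
        for (i, j), p in self.p_pairs.items():
            m[i, j] = p
        return m


@dataclass
class QueueTimeReport:
    """Per-period queue times (minutes) and their count-weighted average."""

    per_period: dict[str, float]
    weights: dict[str, int]
    weighted_average: float


def triggering_probabilities(model: HawkesModel, catalog: EventCatalog, *,
                             prune: float = 1e-12, dense: bool = False) -> DeclusterResult:
    """Compute p_ij, p_j and the primary probabilities for every event.

    ``dense=True`` evaluates every pair directly (O(N^2); exact mode used
    for cross-checks); otherwise pairs with p_ij < ``prune`` are dropped
    from ``p_pairs`` while ``p_secondary`` stays exact.
    """
    t = catalog.times
    n = t.size
    A, alpha = model.trigger.A, model.trigger.alpha
    w0 = catalog.origin_weekday
    mu = np.atleast_1d(model.background.rate(t, w0)).astype(float)
    S = decay_sums(t, alpha)
    lam = mu + A * alpha * S
    p_sec = np.where(lam > 0, A * alpha * S / lam, 0.0)
    p_prim = np.where(lam > 0, mu / lam, 1.0)

    pairs: dict[tuple[int, int], float] = {}
    if A > 0:
        if dense:
            for j in range(1, n):
                pij = A * alpha * np.exp(-alpha * (t[j] - t[:j])) / lam[j]
                for i in range(j):
                    pairs[(i, j)] = float(pij[i])
        else:
            # walk backwards from j; contributions decay monotonically in lag
            for j in range(1, n):
                scale = A * alpha / lam[j]
                i = j - 1
                while i >= 0:
                    p = scale * math.exp(-alpha * (t[j] - t[i]))
                    if p < prune:
                        break
                    pairs[(i, j)] = p
                    i -= 1
    return DeclusterResult(pairs, p_sec, p_prim)


def queue_time(fit) -> float:
    """Average secondary-crash time window, 1/alpha, in minutes.

    Accepts a :class:`FitResult`, :class:`HawkesModel`,
    :class:`TriggeringParams`, or a bare decay rate alpha (1/day).
    """
    if isinstance(fit, FitResult):
        alpha = fit.model.trigger.alpha
    elif isinstance(fit, HawkesModel):
        alpha = fit.trigger.alpha
    elif isinstance(fit, TriggeringParams):
        alpha = fit.alpha
    else:
        alpha = float(fit)
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    return MINUTES_PER_DAY / alpha


def _period_segments(catalog: EventCatalog, period: str):
    """(label, [(start, end), ...]) covering [0, T] for each period bin."""
    from .model import WEEKDAY_NAMES, DEFAULT_RUSH_HOURS
    T = catalog.window_end
    w0 = catalog.origin_weekday
    if period == "weekly":
        segs = {name: [] for name in WEEKDAY_NAMES}
        d = 0
        while d < T:
            name = WEEKDAY_NAMES[(w0 + d) % 7]
            segs[name].append((float(d), min(float(d + 1), T)))
            d += 1
        return segs
    if period == "daily":
        h = np.array(DEFAULT_RUSH_HOURS) / 24.0
        bins = {"non-rush": [(0.0, h[0]), (h[1], h[2]), (h[3], 1.0)],
                "morning-rush": [(h[0], h[1])], "evening-rush": [(h[2], h[3])]}
        segs = {name: [] for name in bins}
        d = 0
        while d < T:
            for name, parts in bins.items():
                for a, b in parts:
                    lo, hi = d + a, min(d + b, T)
                    if hi > lo:
                        segs[name].append((lo, hi))
            d += 1
        return segs
    raise ValueError(f"period must be 'weekly' or 'daily', got {period!r}")


def _collapse(catalog: EventCatalog, segments) -> EventCatalog:
    """Concatenate time segments onto a contiguous axis, keeping their events."""
    new_times = []
    offset = 0.0
    for lo, hi in segments:
        mask = (catalog.times >= lo) & (catalog.times < hi)
        new_times.append(catalog.times[mask] - lo + offset)
        offset += hi - lo
    times = np.concatenate(new_times) if new_times else np.empty(0)
    return EventCatalog(np.sort(times), catalog.origin, offset, None)


def per_period_queue_times(catalog: EventCatalog, period: str = "weekly",
                           seed: int = 0, min_events: int = 10,
                           **fit_kwargs) -> QueueTimeReport:
    """Queue time per calendar period via per-period stationary refits.

    For each period bin (weekday, or rush/non-rush block) the catalog is
    restricted to that bin's time segments, the segments are concatenated
    onto a contiguous axis, and a stationary Hawkes model is refitted; the
    bin's queue time is 1440/alpha_hat.  Bins with fewer than ``min_events``
    events are omitted.  The weighted average uses per-bin event counts.
    """
    segs = _period_segments(catalog, period)
    per: dict[str, float] = {}
    weights: dict[str, int] = {}
    for name, seglist in segs.items():
        sub = _collapse(catalog, seglist)
        if sub.n < min_events:
            continue
        try:
            fit = fit_mle(sub, "stationary", seed=seed, min_events=min_events,
                          **fit_kwargs)
        except FitError:
            continue
        per[name] = queue_time(fit)
        weights[name] = sub.n
    if not per:
        raise FitError("no period bin had enough events to fit")
    total_w = sum(weights.values())
    wavg = sum(weights[k] * per[k] for k in per) / total_w
    return QueueTimeReport(per_period=per, weights=weights, weighted_average=wavg)


def summarize_labels(labels: np.ndarray, p_secondary: np.ndarray | None = None) -> dict:
    """Count/percentage summary of a primary/secondary label vector."""
    labels = np.asarray(labels)
    n = int(labels.size)
    sec = labels == "secondary"
    count = int(np.sum(sec))
    pct = 100.0 * count / n if n else math.nan
    mean_p = math.nan
    if p_secondary is not None and count:
        mean_p = float(np.mean(np.asarray(p_secondary)[sec]))
    return {"n": n, "secondary_count": count, "percent_secondary": pct,
            "mean_p_secondary": mean_p}


def classify_secondary(catalog: EventCatalog, decluster: DeclusterResult,
                       config: ClassificationConfig) -> tuple[np.ndarray, dict]:
    """Label each event primary/secondary and summarize.

    Event j is secondary iff the gap to the immediately preceding event is
    below ``config.queue_time_min`` minutes AND p_j >=
    ``config.prob_threshold``.  The first event is always primary.
    """
    t = catalog.times
    if t.size != decluster.n:
        raise ValueError("decluster result does not match catalog length")
    if t.size == 0:
        return np.empty(0, dtype=object), summarize_labels(np.empty(0))
    gaps_min = np.empty(t.size)
    gaps_min[0] = math.inf
    gaps_min[1:] = np.diff(t) * MINUTES_PER_DAY
    sec = (gaps_min < config.queue_time_min) & \
          (decluster.p_secondary >= config.prob_threshold)
    labels = np.where(sec, "secondary", "primary").astype(object)
    decluster.labels = labels
    summary = summarize_labels(labels, decluster.p_secondary)
    summary["queue_time_min"] = config.queue_time_min
    summary["prob_threshold"] = config.prob_threshold
    return labels, summary


def match_against_reference(labels: np.ndarray, reference_labels: np.ndarray) -> dict:
    """Agreement of our secondary set with an external method's, as a
    percentage of the reference set, plus one-sided counts."""
    labels = np.asarray(labels)
    reference_labels = np.asarray(reference_labels)
    if labels.size != reference_labels.size:
        raise ValueError(f"label sets differ in length: {labels.size} vs "
                         f"{reference_labels.size}")
    ours = labels == "secondary"
    ref = reference_labels == "secondary"
    matched = int(np.sum(ours & ref))
    n_ref = int(np.sum(ref))
    pct = 100.0 * matched / n_ref if n_ref else math.nan
    return {"matched": matched, "reference_count": n_ref,
            "percent_of_reference": pct,
            "ours_only": int(np.sum(ours & ~ref)),
            "reference_only": int(np.sum(ref & ~ours))}
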