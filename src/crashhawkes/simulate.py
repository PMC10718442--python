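"""Synthetic crash catalogs: exact simulation of the self-exciting model.

Two independent exact samplers are provided and cross-checked against each
other in the test suite:

* :func:`simulate_thinning` — Ogata's thinning: propose from a local upper
  bound on the intensity (background maximum plus the current excitation,
  which is nonincreasing between events) and accept with ratio
  lambda/bound, attributing a parent by sampling a component of lambda.
* :func:`simulate_branching` — the cluster representation: background
  events form an (in)homogeneous Poisson process, each event spawns
  Poisson(A) children at Exp(alpha) delays.

Both record ground-truth parent links (-1 for background events), which is
what makes simulated catalogs usable as declustering oracles.  A writer
emulating a DOT-style CSV export (date, time, longitude, latitude columns,
coordinates placed along a highway corridor) closes the loop with
:func:`crashhawkes.catalog.load_catalog`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import datetime, timedelta

import numpy as np
import pandas as pd

from .catalog import EventCatalog, EventRecord, point_along, polyline_length_miles
from .model import HawkesModel

#: Default calendar origin for simulated catalogs (a Monday, midnight).
DEFAULT_ORIGIN = datetime(2015, 1, 5)


@dataclass
class SyntheticCatalog:
    """A simulated catalog with ground-truth parent attribution.

    ``parent[i]`` is the index of the event that triggered event i, or -1
    for background (primary) events; ``generation[i]`` is the cluster depth
    (0 for background).
    """

    catalog: EventCatalog
    parent: np.ndarray
    generation: np.ndarray
    seed: int

    def __post_init__(self):
        self.parent = np.asarray(self.parent, dtype=int)
        self.generation = np.asarray(self.generation, dtype=int)
        n = self.catalog.n
        if self.parent.size != n or self.generation.size != n:
            raise ValueError("parent/generation length mismatch")
        idx = np.arange(n)
        if np.any(self.parent >= idx):
            raise ValueError("parents must precede their children")

    @property
    def is_background(self) -> np.ndarray:
        return self.parent < 0

    @property
    def true_labels(self) -> np.ndarray:
        """Ground-truth 'primary'/'secondary' labels."""
        return np.where(self.is_background, "primary", "secondary").astype(object)


def _check_supercritical(model: HawkesModel, allow: bool):
    if model.trigger.A >= 1 and not allow:
        raise ValueError(f"A = {model.trigger.A} >= 1 is supercritical; pass "
                         "allow_supercritical=True to simulate anyway")


def simulate_thinning(model: HawkesModel, T: float, seed: int,
                      origin: datetime = DEFAULT_ORIGIN,
                      allow_supercritical: bool = False,
                      max_events: int = 5_000_000) -> SyntheticCatalog:
    """Exact Ogata-thinning sample of the model on [0, T].

    The proposal bound at time t is ``max_t mu + A alpha S(t+)`` where S is
    the excitation sum just after the last accepted event; both pieces
    dominate the true intensity until the next event, so acceptance with
    ratio lambda/bound is exact.  Reproducible given ``seed``.
    """
    if T <= 0:
        raise ValueError("T must be positive")
    _check_supercritical(model, allow_supercritical)
    rng = np.random.default_rng(seed)
    A, alpha = model.trigger.A, model.trigger.alpha
    w0 = origin.weekday()
    bg = model.background
    mu_max = bg.max_rate()

    times: list[float] = []
    parents: list[int] = []
    gens: list[int] = []
    t = 0.0
    S = 0.0  # sum of exp(-alpha (t - t_i)) over accepted events
    while True:
        bound = mu_max + A * alpha * S
        t_new = t + rng.exponential(1.0 / bound)
        if t_new >= T:
            break
        S *= math.exp(-alpha * (t_new - t))
        t = t_new
        mu_t = float(bg.rate(t, w0))
        lam = mu_t + A * alpha * S
        if rng.uniform() * bound <= lam:
            u = rng.uniform() * lam
            if u < mu_t or not times:
                parents.append(-1)
                gens.append(0)
            else:
                # pick a parent proportional to its kernel contribution;
                # restrict to lags where the contribution is non-negligible
                ts = np.asarray(times)
                lo = int(np.searchsorted(ts, t - 60.0 / alpha))
                if lo >= len(times):
                    lo = len(times) - 1
                w = np.exp(-alpha * (t - ts[lo:]))
                c = np.cumsum(w)
                pick = lo + int(np.searchsorted(c, rng.uniform() * c[-1]))
                pick = min(pick, len(times) - 1)
                parents.append(pick)
                gens.append(gens[pick] + 1)
            times.append(t)
            S += 1.0
            if len(times) > max_events:
                raise RuntimeError("simulation exceeded max_events; "
                                   "check the branching ratio")
    cat = EventCatalog(np.asarray(times), origin, float(T), None)
    return SyntheticCatalog(cat, np.asarray(parents, dtype=int),
                            np.asarray(gens, dtype=int), seed)


def simulate_branching(model: HawkesModel, T: float, seed: int,
                       origin: datetime = DEFAULT_ORIGIN,
                       allow_supercritical: bool = False,
                       max_events: int = 5_000_000) -> SyntheticCatalog:
    """Cluster-representation sample, equivalent in law to thinning.

    Background events are drawn as a Poisson process with rate mu(t)
    (thinned against its maximum); every event then spawns
    Poisson(A) offspring at Exp(alpha) delays, recursively, truncated at T.
    """
    if T <= 0:
        raise ValueError("T must be positive")
    _check_supercritical(model, allow_supercritical)
    rng = np.random.default_rng(seed)
    A, alpha = model.trigger.A, model.trigger.alpha
    w0 = origin.weekday()
    bg = model.background
    mu_max = bg.max_rate()

    n_cand = rng.poisson(mu_max * T)
    cand = np.sort(rng.uniform(0.0, T, size=n_cand))
    accept = rng.uniform(size=n_cand) * mu_max <= np.atleast_1d(bg.rate(cand, w0))
    bg_times = cand[accept]

    times = list(bg_times)
    parents = [-1] * len(times)
    gens = [0] * len(times)
    queue = list(range(len(times)))
    while queue:
        idx = queue.pop()
        k = rng.poisson(A)
        if k == 0:
            continue
        delays = rng.exponential(1.0 / alpha, size=k)
        for d in delays:
            ct = times[idx] + d
            if ct >= T:
                continue
            times.append(ct)
            parents.append(idx)
            gens.append(gens[idx] + 1)
            queue.append(len(times) - 1)
            if len(times) > max_events:
                raise RuntimeError("simulation exceeded max_events; "
                                   "check the branching ratio")

    order = np.argsort(np.asarray(times), kind="stable")
    times_s = np.asarray(times)[order]
    rank = np.empty(order.size, dtype=int)
    rank[order] = np.arange(order.size)
    parents_arr = np.asarray(parents)
    parents_s = np.where(parents_arr[order] < 0, -1, rank[parents_arr[order]])
    gens_s = np.asarray(gens)[order]
    cat = EventCatalog(times_s, origin, float(T), None)
    return SyntheticCatalog(cat, parents_s, gens_s, seed)


#: A straight ~25-mile corridor (roughly I-4 heading, decorative only).
DEFAULT_CORRIDOR = [(-81.55, 28.45), (-81.15, 28.62)]


def write_fdot_like_csv(syn: SyntheticCatalog, path, corridor=DEFAULT_CORRIDOR,
                        seed: int = 0, max_child_offset_miles: float = 1.9) -> pd.DataFrame:
    """Write a DOT-export-shaped CSV (date, time, lon, lat) for a simulation.

    Background events are placed uniformly along the corridor polyline;
    triggered events are placed within ``max_child_offset_miles`` of their
    parent along the corridor, so a 2-mile corridor filter around any
    parent retains its children.  Timestamps are written to the minute.
    Returns the frame that was written.
    """
    rng = np.random.default_rng(seed)
    L = polyline_length_miles(corridor)
    n = syn.catalog.n
    offsets = np.empty(n)
    for i in range(n):
        p = syn.parent[i]
        if p < 0:
            offsets[i] = rng.uniform(0.0, L)
        else:
            lo = max(0.0, offsets[p] - max_child_offset_miles)
            hi = min(L, offsets[p] + max_child_offset_miles)
            offsets[i] = rng.uniform(lo, hi)
    lonlat = [point_along(corridor, o) for o in offsets]
    origin = syn.catalog.origin
    stamps = [origin + timedelta(minutes=math.floor(t * 1440.0))
              for t in syn.catalog.times]
    df = pd.DataFrame({
        "crash_date": [s.strftime("%m/%d/%Y") for s in stamps],
        "crash_time": [s.strftime("%H:%M") for s in stamps],
        "longitude": [ll[0] for ll in lonlat],
        "latitude": [ll[1] for ll in lonlat],
        "weather": "clear",
    })
    df.to_csv(path, index=False)
    return df


def write_truth_csv(syn: SyntheticCatalog, path) -> pd.DataFrame:
    """Ground-truth companion CSV: index, t_days, parent, generation."""
    df = pd.DataFrame({
        "index": np.arange(syn.catalog.n),
        "t_days": syn.catalog.times,
        "parent": syn.parent,
        "generation": syn.generation,
    })
    df.to_csv(path, index=False)
    return df


def attach_records(syn: SyntheticCatalog) -> SyntheticCatalog:
    """Fill the underlying catalog's records from the simulated times."""
    recs = [EventRecord(ts) for ts in syn.catalog.timestamps()]
    syn.catalog.records = recs
    return syn
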