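# Methods

## The model

`crashhawkes` models a crash catalog as a temporal self-exciting point
process. Events arrive with conditional intensity

    λ(t | H_t) = μ(t) + A Σ_{t_i < t} α e^{−α (t − t_i)},

the superposition of a background stream of *primary* crashes at rate
`μ(t)` and, for every past event, an exponentially fading excitation that
generates *secondary* crashes. The kernel `g(s) = A α e^{−α s}` integrates
to `A`, so `A` is the branching ratio (expected direct offspring per
event) and `α e^{−α s}` is the normalized delay density with mean delay
`1/α`. The process is subcritical for `A < 1`; constructing
`TriggeringParams` with `A ≥ 1` warns, and the simulators refuse it unless
explicitly overridden.

This is a purely temporal model. Geography enters only as a
pre-processing step: catalogs are windowed to a corridor (haversine
distance on a sphere of radius 3958.8 mi) before fitting, the standard
practice for secondary-crash studies where a ~2-mile spatial threshold
around a site is assumed rather than estimated. No spatial triggering
kernel or mark distribution is used.

## Background families

* **Stationary** — `μ(t) = μ`. One parameter.
* **Piecewise** — a step function over calendar bins that tile a period:
  seven day-of-week rates (Monday-first), or three time-of-day rates with
  morning rush 06:00–09:00, evening rush 16:00–19:00 and the remaining
  hours sharing one non-rush rate. The rush-hour edges are configurable;
  the defaults reflect the usual twin weekday peaks in crash counts.
* **Sinusoidal** — `μ(t) = μ0 {P · wave(Q u + R) + S}` where the phase
  variable `u` is days since the start of the week (weekly form,
  `wave = sin` by convention) or days since midnight (daily form,
  `wave = cos`). `Q` defaults to `2π/period` so one cycle spans the
  period; positivity requires `S > |P|`, which is enforced.

All rates are per day; the time axis is fractional days since the catalog
origin (midnight of the first event's date unless given). Anchoring the
origin at midnight makes weekday and time-of-day exact calendar functions
of `t`. Tied timestamps (crash data is minute-resolved) are nudged apart
by +1 s in input order so event times are strictly increasing.

## Likelihood and fitting

The exact log-likelihood over `[0, T]` is
`Σ_i log λ(t_i) − ∫_0^T λ(t) dt`. The compensator is closed-form for all
three background families (the periodic families integrate per period
plus a partial term, so an arbitrary fitted `Q` remains exact under the
mod-period phase), and the excitation term uses the O(N) recursion
`S_i = e^{−α Δt_i}(1 + S_{i−1})`; an O(N²) direct evaluation is retained
and tested to agree to 1e−9 relative. The likelihood conditions on an
empty pre-history (standard for ETAS-type fits), which biases `Â` slightly
downward on short windows.

MLE maximizes over the positive orthant by optimizing log-parameters with
L-BFGS-B (numerical gradients, gradient tolerance 1e−6, max 500
iterations); a natural-space bounded path exists and reaches the same
optimum (property-tested). Initialization is `μ⁽⁰⁾ = 0.5 N/T`,
`A⁽⁰⁾ = 0.5`, `α⁽⁰⁾ = 10/day`, plus three seeded random restarts.
Free parameters: stationary (μ, A, α); piecewise (μ_1..μ_K, A, α);
sinusoidal (μ0, A, α).

The sinusoidal shape (P, Q, R, S) is fitted **first**, by least squares to
the weekday (7-bin) or hour-of-day (24-bin) histogram normalized to unit
mean, and held fixed during MLE. This two-stage design reflects how the
periodic structure is read off the raw crash histograms rather than
jointly estimated; a consequence is that the sinusoidal family's AIC
counts k = 3 free parameters only, which slightly favors it in
comparisons — a deliberate, documented trade-off. The shape fit is
initialized from the fundamental-frequency linear regression, recovers
noiseless inputs to 1e−6, and returns the canonical branch (P ≥ 0,
R ∈ (−π, π], S > |P|). A constant histogram yields the flat shape
(P = 0, S = 1) with a `flat` flag.

`compare_models` ranks families by AIC = 2k − 2 ln L, ties broken by fewer
parameters. Non-stationary fits additionally start from the fitted
stationary solution, so a richer nested family can never report a worse
likelihood than its nested special case.

## Declustering and classification

Triggering probabilities `p_ij = A α e^{−α(t_j−t_i)} / λ(t_j)` and
`p_j = Σ_{i<j} p_ij` partition each event's intensity, so
`p_j + μ(t_j)/λ(t_j) = 1` holds to machine precision by construction;
`p_secondary` is computed from the exact recursion while the pair map is
pruned below 1e−12 for sparsity (exact dense mode available).

Classification follows the successive-gap rule used in post-processing
practice: event j is secondary iff the gap to the *immediately preceding*
event is under the queue time (1440/α minutes) **and** `p_j ≥ 0.5`. The
0.5 default says "triggered is more likely than not"; both the gaps and
the probabilities are exposed for alternative rules. The rule is monotone
in both thresholds (property-tested).

Per-period queue times (per weekday, or per rush block) are produced by
refitting a stationary model to each period's events after concatenating
that period's calendar segments onto a contiguous axis, and averaging
1440/α̂ weighted by per-period event counts. Excitation leaking across
segment boundaries makes this an approximation; it is the mechanism
implied by per-period queue-time tables in the secondary-crash literature,
not an exact likelihood decomposition.

## Simulators

`simulate_thinning` is Ogata's algorithm with proposal bound
`max_t μ + A α S(t⁺)`: the background maximum is known analytically for
every family and the excitation term is nonincreasing between events, so
the bound is valid and the sample exact. Parents are attributed by
sampling a component of λ (candidates restricted to lags within 60/α,
where the kernel weight is below 1e−26 — exact at double precision).
`simulate_branching` draws background events as a thinned Poisson process
and recursively spawns Poisson(A) offspring with Exp(α) delays. The two
are independent implementations, cross-checked by a two-sample KS test on
inter-event times and by the branching identities E[N] = μT/(1−A) and
background fraction ≈ 1−A.

`write_fdot_like_csv` emulates a DOT crash export: `MM/DD/YYYY` dates,
`HH:MM` times (minute-truncated), and coordinates placed along a corridor
polyline with triggered events within 2 miles of their parents. What the
synthetic catalogs do **not** emulate: reporting errors and missing
records, severity/weather covariates that correlate with triggering,
spatial clustering beyond the decorative corridor placement, and
long-range nonstationarity (construction seasons, demand trends). Passing
the recovery and classification tests therefore demonstrates correctness
of the method under its own assumptions, not robustness to every
real-data artifact.

## Study sizes and numerical choices

The test suite and acceptance script use simulation studies sized for
sharp yet fast checks, generated by the package's own simulators:

* parameter recovery: stationary truth μ = 0.4/day, A = 0.25, α = 12/day
  (queue time 2 h), T = 5000 days, 20 seeds — median relative errors are
  a few percent, well under the 10 % acceptance band;
* model selection: weekly sinusoidal truth μ0 = 0.5, P = 0.4, Q = 2π/7,
  Friday peak (max/min rate ratio ≈ 2.3, i.e. pronounced weekly
  structure), A = 0.25, α = 12, T = 365 days, 50 replicates; the
  sinusoidal family should attain the lowest AIC in ≥ 90 % of replicates;
* simulator calibration: T = 10000 days, 20 seeds, tolerances of ±3
  standard errors; distributional agreement at KS p > 0.01.

Degenerate inputs: empty catalogs are valid for likelihood evaluation
(compensator only) and classification (empty labels); catalogs under 10
events refuse to fit; constant histograms return the flat shape; any
non-positive event intensity makes the log-likelihood −∞, which the
optimizer treats as a rejected point. Published queue-time values are
printed to one decimal (truncated), so worked-example comparisons use a
0.1-minute band.

## Known limitations

* Temporal-only: simultaneous crashes in opposite directions are related
  only through time, and the corridor pre-filter cannot separate
  co-located but causally unrelated events.
* `Â` is biased slightly low on short windows (empty pre-history).
* The two-stage sinusoidal fit understates that family's effective
  parameter count in AIC comparisons.
* Per-period queue times ignore excitation across period boundaries.
* The classification rule uses the gap to the immediately preceding event
  even though `p_j` aggregates all predecessors; in very dense clusters
  the two ingredients can disagree, and users wanting a pure
  probability rule should threshold `p_j` directly.
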