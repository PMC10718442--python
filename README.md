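# crashhawkes

Temporal self-exciting point-process (Hawkes/ETAS-style) declustering of
highway crash catalogs into **primary** crashes and the **secondary**
crashes that occur in their congestion wake.

Secondary crashes — collisions triggered by the queueing, shockwaves and
rubbernecking that follow an earlier crash — are among the most dangerous
highway incidents, yet crash databases do not label them. `crashhawkes`
fits a temporal Hawkes process to a catalog of crash times and uses
stochastic declustering to assign every crash a probability of having been
triggered by each earlier crash. It is written for traffic-safety
researchers and practitioners working with DOT-style crash exports
(date, time, longitude, latitude per record).

## Model

Given crash times `t_1 < … < t_N` on `[0, T]`, the conditional intensity is

    λ(t) = μ(t) + A Σ_{t_i < t} α · exp(−α (t − t_i))

* `μ(t)` — background rate generating independent primary crashes:
  stationary (`μ`), piecewise-constant over calendar bins (7 weekdays, or
  morning-rush / evening-rush / non-rush), or sinusoidal
  `μ0 · {P · wave(Q·u + R) + S}` with a weekly or daily phase `u`;
* `A` — branching ratio, the expected number of secondary crashes per crash;
* `1/α` — mean triggering delay; `1440/α` is the **queue time** in minutes,
  the window after a primary crash within which secondary crashes occur.

Parameters are estimated by exact maximum likelihood
(`Σ log λ(t_i) − ∫ λ`, closed-form compensator, O(N) kernel recursion,
quasi-Newton optimization in log-parameter space). Background families are
ranked by AIC = 2k − 2 ln L. Declustering probabilities

    p_ij = A α e^{−α(t_j − t_i)} / λ(t_j),   p_j = Σ_{i<j} p_ij,
    1 − p_j = μ(t_j)/λ(t_j)

partition each event's intensity; events are labeled secondary when the
gap to the preceding event is below the queue time and `p_j` clears a
probability threshold (default 0.5). Two exact simulators (Ogata thinning
and the cluster/branching construction) generate synthetic catalogs with
ground-truth parent links for validation.

## Worked example

Simulate three years of a corridor with background rate 0.4 crashes/day,
branching ratio 0.25 and a 2-hour mean trigger delay, then recover the
parameters and classify the catalog — all from the shell:

```sh
crashhawkes simulate --model-json model.json -T 1000 --seed 42 \
    --out-catalog catalog.csv --out-truth truth.csv
# simulated 469 events over 1000.0 days (seed 42)

crashhawkes fit -i catalog.csv --family stationary --seed 0 -o fit.json
# fitted stationary to N=469 events over T=990.0 d: loglik=-719.715 aic=1445.43

crashhawkes classify -i catalog.csv --out-csv labels.csv --out-summary summary.json
# 97 of 469 events (20.68%) classified secondary; queue time 152.7 min

crashhawkes compare -i catalog.csv -o aic.csv
#            family  k      loglik         aic
# sinusoidal-weekly  3 -716.650995 1439.301990
#        stationary  3 -719.715217 1445.430435
#  piecewise-weekly  9 -714.530442 1447.060884
```

The fitted parameters (μ̂ = 0.355/day, Â = 0.251, α̂ = 9.43/day) sit within
sampling error of the generating values; the queue time 1440/α̂ = 152.7 min
says a crash arriving within ~2.5 h (and flagged by its triggering
probability) of its predecessor is attributed to it. 20.7 % of the
simulated events are classified secondary, consistent with the generating
branching ratio of 0.25 (some triggered events arrive after long delays
and are correctly left primary).

The same workflow applies to a real DOT export: point `-i` at the CSV
(configurable date/time/coordinate column names), optionally pre-filter to
a 2-mile corridor around a city center with
`crashhawkes.filter_corridor` / `sliding_windows`, and choose the
background family by AIC.

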