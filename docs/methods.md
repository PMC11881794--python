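# Methods

## The design

A seamless diagnostic accuracy study evaluates one index test against a
reference standard in a single two-stage study. Stage I recruits
`n1 = round(s·N)` participants population-based (`N` the intended final
sample size, `s` the stopping time as a fraction of `N`). Because the
prevalence `p` is below 0.5, cases are scarce at the interim; external
(e.g. retrospective) cases are added until the case arm equals the control
arm, so the interim analysis resembles a case–control comparison with
representative controls. The interim applies a pure futility rule on the
point estimates: continue only if `se_hat > f_se` **and** `sp_hat > f_sp`,
both strictly. Stage II completes the population sample to `N`; the final
analysis removes the added cases, keeps every stage-I population subject
unchanged, and tests the co-primary minimum values `(se0, sp0)` by the
intersection–union rule on Wilson lower limits. Because only futility (not
efficacy) can stop the study, no multiplicity adjustment of the final level
is needed; the price is a conditional selection bias in the final
estimates, which the simulation engine quantifies.

Prevalence above 0.5 is the mirror image (controls would be added); the
composition functions raise a `SymmetricModeRequiredError` rather than
silently swapping roles.

## Estimation and testing

- Point estimates are the subgroup proportions `TP/(TP+FN)` and
  `TN/(TN+FP)`.
- Confidence intervals are plain two-sided Wilson score intervals (no
  continuity correction), the recommended default for binomial proportions
  in this setting. The closed form is implemented directly (vectorized over
  count arrays for the simulation engine) and is cross-checked against
  statsmodels in the test suite.
- The intersection–union test rejects an endpoint when the Wilson lower
  limit is **strictly** above the minimum value; the global null requires
  both. With two-sided 95% intervals the endpoint tests are one-sided at
  2.5% and the nominal global level is `0.025² = 0.000625`. The realized
  level is additionally deflated by the discreteness of the binomial
  counts and by early stopping.

## Tie rule

The continue/stop and reject/accept comparisons are strict throughout: an
interim estimate equal to its futility boundary stops, and a Wilson lower
limit equal to the minimum value does not reject. The "above" wording of
the decision rules leaves ties formally open; strictness resolves them
conservatively for rejection and is fixed (not configurable) so that every
analysis of the same numbers gives the same verdict. The exact enumeration
oracle applies the identical floating-point comparison (`k/m > f`) as the
simulation, so the two routes agree even when `f·m` is an integer.

## Rounding and composition

`n1 = round(s·N)` and `pop_cases = round(p·n1)` use round-half-up;
controls (`n1 − pop_cases`) and added cases (`controls − pop_cases`) follow
by subtraction, which keeps the balance `pop_cases + added = controls`
exact after rounding and reproduces the planning table for all 18
combinations of p ∈ {0.1, 0.2, 0.3}, N ∈ {1000, 500, 250, 333, 167},
s ∈ {0.1, 0.2, 0.3}. The alternative parameterization fixing the interim
analysis population at `T` participants split 1:1 rounds
`n1 = round(controls/(1−p))` first and again derives the integer fields by
subtraction; rounding any other field first can violate the balance
invariant by one case.

## Simulation model

Each replicate draws four (fixed margins) or six (binomial margins)
binomial counts:

- positives among population cases ~ `Bin(pop_cases, se_true)`;
- positives among added cases ~ `Bin(added, min(se_true + δ_add, 1))` —
  the clamp is the only probability-valid treatment of the
  `se_true = 0.95, δ_add = 0.1` corner;
- negatives among controls ~ `Bin(controls, sp_true)`;
- stage-II case/control results analogously.

`margin_mode="fixed"` (default) freezes the case/control margins at their
planning-table values and the final case count at `round(p·N)`; this
matches the deterministic compositions of the planning table and keeps the
final analysis at exactly the intended number of cases. `"binomial"` draws
the stage-I case count from `Bin(n1, p)` and recomputes the enrichment
from the realized split (clamped at zero if cases outnumber controls), and
draws stage-II cases from `Bin(N − n1, p)`.

Stage-II counts are drawn for every replicate, including stopped ones.
This costs nothing at these sizes and makes the no-stopping (cohort-only)
analysis of the same draws an exactly paired comparator: the seamless
power can never exceed the cohort power replicate-by-replicate, and with
boundaries at zero the two analyses coincide bit-for-bit.

## Exact stopping probability

Under fixed margins the interim case-pool positive count and the control
negative count are independent, so P(stop) = 1 − P(se side continues)·
P(sp side continues), computed from exact binomial pmfs (a convolution of
the population and added-case binomials when δ_add ≠ 0). The
implementation sums the stop-side tails, which keeps near-zero
probabilities exact instead of leaving 1e−15 cancellation residue. Pools
above a configurable cap raise `OracleUnavailableError`. The oracle backs
the Monte Carlo engine in the test suite: simulated stopping frequencies
must agree within three Monte Carlo standard errors.

## Performance measures

Per scenario, over `R` replicates:

- **Stopping frequency** — stopped replicates / `R`.
- **Conditional relative bias** — `mean(est − true)/(1 − true)·100` over
  non-stopped replicates; relating the bias to `1 − true` reflects that
  the same absolute bias is more harmful near 1.
- **Conditional / unconditional coverage** — covering replicates divided
  by non-stopped replicates, or by `R` with stopped replicates counted as
  covering; the identity
  `uncond = stop_freq + (1 − stop_freq)·cond` holds exactly by
  construction and is asserted in the tests.
- **Power** — global rejections / `R` for each of the 25 minimum-value
  pairs on {0.55, 0.65, 0.75, 0.85, 0.95}²; stopped replicates count as
  not rejecting.
- **Type I error** — the power entry at `(se_true, sp_true)` when the
  truth lies on that grid.

The scenario grid is the full factorial of N ∈ {333, 500, 1000} (chosen to
put about 100 or 50 cases in the final analysis), s ∈ {0.1, 0.2, 0.3},
p ∈ {0.1, 0.2, 0.3}, true values in {0.65, 0.75, 0.85, 0.95}², a common
boundary distance Δ = f − true in {−0.3, …, +0.1} step 0.05, and
δ_add ∈ {0, 0.1}: 7776 scenarios in deterministic lexicographic order.
Boundaries above 1 (se_true = 0.95, Δ = +0.1) are legal and make stopping
certain.

## Reproducibility

Every scenario gets an independent `SeedSequence([seed, grid_index])`
substream, so results are independent of run order and bit-reproducible
for a given seed. Result CSVs carry a JSON sidecar recording seed,
replicate counts, version, tie rule and margin mode.

## Reporting filters and summaries

Cross-design summaries (e.g. the 90th percentile of conditional relative
bias grouped by stopping time) omit designs whose conditional measures
rest on too few final analyses: fewer than 40 non-stopped runs for bias
and 200 for conditional coverage at 40000 replicates, rescaled
proportionally at reduced replicate counts. Percentiles use linear
interpolation between order statistics. Sensitivity and specificity biases
are pooled within each group before taking percentiles; the pooling choice
is recorded in the results metadata sidecar.

## Problem sizes

Full fidelity is 7776 scenarios × 40000 replicates. The bundled checks use
reduced sizes chosen for desk-scale runs: stopping-frequency medians over
the 432 Δ = 0 (and 432 Δ = +0.05), δ_add = 0 designs at 2000 replicates
(medians across hundreds of designs are robust to per-design Monte Carlo
noise), and the bias percentile over the 288 Δ = 0, s = 0.1 designs at
10000 replicates (percentiles of per-design means are inflated by
replicate noise, so this quantity gets the larger budget). The vectorized
engine runs all of this in a few seconds.

## What the generator does and does not emulate

The binomial model captures the stochastic structure of the design —
selection at the interim, data reuse, enrichment and its removal — exactly
as specified. It does not model covariates, spectrum effects beyond the
single δ_add shift, verification bias, imperfect reference standards,
delayed reference results, or enrichment-pool shortfalls (the latter can
be flagged at planning time via `validate_design`'s `enrichment_pool`
argument but is not simulated). Passing tests therefore validate the
design's statistical operating characteristics under the stated model, not
robustness to those real-data complications.

## Known limitations

- Wilson-interval coverage oscillates with `n` and `p`; at some margins the
  exact no-stopping coverage dips slightly below 0.95 (e.g. 0.933 at
  n = 100, p = 0.85). This is a property of the interval, not of the
  seamless design; the validity property tests use margins where the
  interval is conservative.
- The exact oracle covers fixed margins only; binomial-margin stopping
  probabilities are estimated by simulation.
- Only the single-test design is implemented: no comparative two-test
  variants, ROC/AUC endpoints, weighted composite futility criteria, or
  post-interim sample-size reassessment.
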