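# seamlessdx

Planning, analysis and simulation of **seamless diagnostic accuracy study
designs**: a two-stage design that embeds a case-enriched interim analysis
with futility stopping into an ongoing population-based cohort study of a
single diagnostic test.

## The problem

Diagnostic accuracy is traditionally established in two separate studies: an
efficient but potentially biased case–control study first, then — if the test
looks promising — an unbiased population-based cohort study. The seamless
design merges them. Population-based recruitment starts immediately; once a
fraction *s* of the intended final sample size *N* has been recruited,
external cases are added until cases and controls are balanced
(*n*<sub>add</sub> = controls − cases), and an interim analysis compares the
point estimates of sensitivity and specificity against futility boundaries
*f*<sub>se</sub>, *f*<sub>sp</sub>. The study continues only if both
estimates lie strictly above their boundaries. At the final analysis the
added cases are removed, every stage-I population subject is kept (data
reuse), and the co-primary hypotheses

H₀: se ≤ se₀ ∪ sp ≤ sp₀  vs.  H₁: se > se₀ ∩ sp > sp₀

are tested by the intersection–union principle: reject when the lower limits
of the two-sided 95% Wilson score intervals satisfy CI<sub>se,l</sub> > se₀
**and** CI<sub>sp,l</sub> > sp₀. With independent endpoints this gives a
nominal global level of 0.025² = 0.000625.

The package provides the composition arithmetic, the interim/final analysis
of observed 2×2 count tables, an exact enumeration oracle for the stopping
probability, and a vectorized Monte Carlo engine reproducing the design's
operating characteristics (stopping frequency, conditional relative bias,
coverage, power, type I error) over a 7776-scenario grid.

## Worked example

A test developer expects 20% prevalence and wants se₀ = 0.90, sp₀ = 0.85
with N = 500 (≈100 cases, giving a sensitivity standard error of 0.03) and
an interim after s = 0.2 of recruitment, boundaries ten points below the
minimum values:

```sh
$ seamlessdx plan --prevalence 0.2 --final-n 500 --stopping-time 0.2
n1,pop_cases,added_cases,controls
100,20,60,80
```

Stage I holds 100 participants — 20 expected cases and 80 controls — so 60
external cases are added for a balanced 80-vs-80 interim analysis. Suppose
the interim observes 71/80 true positives and 61/80 true negatives:

```sh
$ seamlessdx interim --final-n 500 --prevalence 0.2 --fse 0.80 --fsp 0.75 \
    --se0 0.90 --sp0 0.85 --tp 71 --fn 9 --tn 61 --fp 19
{"se_hat": 0.8875, "sp_hat": 0.7625, "f_se": 0.8, "f_sp": 0.75,
 "verdict": "continue", "added_cases_needed": 0}
```

Both estimates lie strictly above the boundaries, so the study proceeds.
After stage II the final population-based table (added cases removed) gives
82/100 and 308/400:

```sh
$ seamlessdx final --final-n 500 --prevalence 0.2 --se0 0.90 --sp0 0.85 \
    --tp 82 --fn 18 --tn 308 --fp 92
{"se_hat": 0.82, "sp_hat": 0.77,
 "ci_se": [0.7333, 0.8830], "ci_sp": [0.7263, 0.8086],
 "reject_se": false, "reject_sp": false, "reject_global": false}
```

Neither Wilson lower limit clears its minimum value: the global null is not
rejected. Simulating this design's operating characteristics with the truth
sitting exactly on the futility boundaries (Δ = 0):

```sh
$ seamlessdx simulate --final-n 500 --stopping-time 0.2 --prevalence 0.2 \
    --se 0.85 --sp 0.85 --delta 0.0 --reps 20000 --seed 1
{"stop_freq": 0.79515, "n_final": 4097,
 "cond_rel_bias_se": 3.56, "cond_rel_bias_sp": 4.47,
 "cond_cov_se": 0.9363, "cond_cov_sp": 0.9463,
 "uncond_cov_se": 0.98695, "uncond_cov_sp": 0.989, "type1": 0.0004}
```

About 80% of such trials stop early (the exact enumeration gives 0.79552);
among continued trials the data reuse inflates the estimates by a few
percent of the distance to 1, unconditional coverage is conservative, and
the type I error stays below the 0.000625 nominal level.

The `grid` and `summarize` commands sweep the full factorial scenario grid
(N ∈ {333, 500, 1000}, s ∈ {0.1, 0.2, 0.3}, p ∈ {0.1, 0.2, 0.3}, true
values in {0.65, …, 0.95}, boundary distance Δ ∈ {−0.3, …, 0.1}, added-case
sensitivity shift δ ∈ {0, 0.1}) and compute grouped percentile summaries
with the reporting filters described in `docs/methods.md`.

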