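"""Single-trial engine for the seamless diagnostic accuracy design.

A trial runs in two stages.  Stage I recruits ``n1 = round(s * N)``
participants from the population stream and adds external cases until cases
and controls are balanced; the interim analysis compares the point
estimates of sensitivity and specificity against the futility boundaries
and continues only if both lie strictly above them (equality stops).
Stage II completes the population sample to ``N``; the final analysis keeps
every stage-I *population* subject (data reuse), removes the added cases,
and applies Wilson intervals and the intersection-union test.

The engine exposes a scalar path (``run_trial``) for analysing or
simulating one trial, a vectorized path (``simulate_trials``) used by the
scenario study, and an exact enumeration oracle for the stopping
probability (``exact_stopping_probability``).  The vectorized path draws
stage II unconditionally so that a no-stopping (cohort-only) analysis of
the same draws is exactly paired with the seamless analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import binom

from .accuracy import (
    AccuracyEstimate,
    ConfidenceInterval,
    Counts2x2,
    HypothesisPair,
    IUTestResult,
    estimate_accuracy,
    iu_test,
    wilson_bounds,
    wilson_ci,
)
from .design import (
    DesignSpec,
    InterimComposition,
    interim_composition,
    observed_added_cases,
)

__all__ = [
    "TrialTruth",
    "Stage1Counts",
    "TrialOutcome",
    "TrialBatch",
    "InterimReport",
    "OracleUnavailableError",
    "interim_decision",
    "simulate_stage1",
    "run_trial",
    "simulate_trials",
    "exact_stopping_probability",
    "analyze_interim",
    "analyze_final",
]


class OracleUnavailableError(RuntimeError):
    """Raised when the enumeration oracle cannot be applied (pool too large)."""


@dataclass(frozen=True)
class TrialTruth:
    """True accuracy parameters generating a simulated trial.

    ``delta_add`` shifts the sensitivity of the *added* cases only,
    emulating enriched cases that are easier to detect than population
    cases; the shifted probability is clamped at 1.
    """

    se_true: float
    sp_true: float
    prevalence: float
    delta_add: float = 0.0

    def __post_init__(self) -> None:
        for name in ("se_true", "sp_true"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError(f"prevalence must be in (0, 1), got {self.prevalence}")

    @property
    def se_added(self) -> float:
        """Sensitivity of the added cases, clamped to 1."""
        return min(self.se_true + self.delta_add, 1.0)


@dataclass(frozen=True)
class Stage1Counts:
    """Realized stage-I results, before the interim decision."""

    pop_cases: int
    added_cases: int
    controls: int
    pop_case_pos: int
    added_case_pos: int
    control_neg: int

    @property
    def interim_se_hat(self) -> float:
        pool = self.pop_cases + self.added_cases
        return (self.pop_case_pos + self.added_case_pos) / pool

    @property
    def interim_sp_hat(self) -> float:
        return self.control_neg / self.controls


@dataclass(frozen=True)
class TrialOutcome:
    """One seamless trial: interim estimates, stop flag, final analysis.

    Final fields are ``None`` when the trial stopped for futility.  The
    final counts exclude all added cases and include every stage-I
    population subject unchanged.
    """

    stopped: bool
    interim_se_hat: float
    interim_sp_hat: float
    final_counts: Counts2x2 | None = None
    final_estimates: AccuracyEstimate | None = None
    ci_se: ConfidenceInterval | None = None
    ci_sp: ConfidenceInterval | None = None
    rejections: dict[HypothesisPair, bool] | None = None


def interim_decision(
    est: AccuracyEstimate, f_se: float, f_sp: float
) -> bool:
    """Interim futility decision; returns True when the trial stops.

    The study continues only if both point estimates lie strictly above
    their futility boundaries; an estimate equal to its boundary stops.
    """
    return not (est.se_hat > f_se and est.sp_hat > f_sp)


def _stage1_margins(
    spec: DesignSpec, rng: np.random.Generator
) -> tuple[int, int, int]:
    """Realized (pop_cases, added_cases, controls) for one trial."""
    if spec.margin_mode == "fixed":
        comp = interim_composition(spec.prevalence, spec.final_n, spec.stopping_time)
        return comp.pop_cases, comp.added_cases, comp.controls
    n1 = spec.n1
    pop_cases = int(rng.binomial(n1, spec.prevalence))
    controls = n1 - pop_cases
    added = max(controls - pop_cases, 0)
    return pop_cases, added, controls


def simulate_stage1(
    spec: DesignSpec, truth: TrialTruth, rng: np.random.Generator
) -> Stage1Counts:
    """Draw the stage-I recruitment, enrichment and test results.

    Positives among population cases are Binomial(pop_cases, se_true),
    among added cases Binomial(added, min(se_true + delta_add, 1)), and
    negatives among controls Binomial(controls, sp_true).
    """
    pop_cases, added, controls = _stage1_margins(spec, rng)
    return Stage1Counts(
        pop_cases=pop_cases,
        added_cases=added,
        controls=controls,
        pop_case_pos=int(rng.binomial(pop_cases, truth.se_true)),
        added_case_pos=int(rng.binomial(added, truth.se_added)),
        control_neg=int(rng.binomial(controls, truth.sp_true)),
    )


def run_trial(
    spec: DesignSpec,
    truth: TrialTruth,
    rng: np.random.Generator,
    hypotheses: tuple[HypothesisPair, ...] | None = None,
) -> TrialOutcome:
    """Simulate one complete seamless trial.

    Stage-I draws precede the stage-II draws in the random stream.  If the
    trial continues, stage II recruits the remaining population subjects;
    stage-I population results are carried into the final counts unchanged
    and added-case results are discarded.
    """
    if hypotheses is None:
        hypotheses = (spec.hyp,)
    s1 = simulate_stage1(spec, truth, rng)
    est1 = AccuracyEstimate(s1.interim_se_hat, s1.interim_sp_hat)
    if interim_decision(est1, spec.f_se, spec.f_sp):
        return TrialOutcome(
            stopped=True,
            interim_se_hat=est1.se_hat,
            interim_sp_hat=est1.sp_hat,
        )
    if spec.margin_mode == "fixed":
        stage2_cases = spec.final_cases - s1.pop_cases
        if stage2_cases < 0:
            stage2_cases = 0
        stage2_controls = spec.final_controls - s1.controls
    else:
        n2 = spec.final_n - spec.n1
        stage2_cases = int(rng.binomial(n2, spec.prevalence))
        stage2_controls = n2 - stage2_cases
    tp = s1.pop_case_pos + int(rng.binomial(stage2_cases, truth.se_true))
    tn = s1.control_neg + int(rng.binomial(stage2_controls, truth.sp_true))
    n_cases = s1.pop_cases + stage2_cases
    n_controls = s1.controls + stage2_controls
    counts = Counts2x2(n_tp=tp, n_fp=n_controls - tn, n_tn=tn, n_fn=n_cases - tp)
    est = estimate_accuracy(counts)
    ci_se = wilson_ci(tp, n_cases, spec.ci_level)
    ci_sp = wilson_ci(tn, n_controls, spec.ci_level)
    rejections = {
        hyp: (ci_se.lower > hyp.se0 and ci_sp.lower > hyp.sp0) for hyp in hypotheses
    }
    return TrialOutcome(
        stopped=False,
        interim_se_hat=est1.se_hat,
        interim_sp_hat=est1.sp_hat,
        final_counts=counts,
        final_estimates=est,
        ci_se=ci_se,
        ci_sp=ci_sp,
        rejections=rejections,
    )


@dataclass
class TrialBatch:
    """Vectorized results of ``reps`` independent seamless trials.

    Stage II is drawn for every replicate, including stopped ones, so the
    arrays describe both the seamless trial (apply ``stopped``) and the
    exactly paired cohort-only trial of the same size (ignore ``stopped``).
    Final estimate entries are NaN in the (practically impossible) event of
    an empty final margin under binomial margins.
    """

    spec: DesignSpec
    truth: TrialTruth
    reps: int
    stopped: np.ndarray
    interim_se: np.ndarray
    interim_sp: np.ndarray
    final_cases: np.ndarray
    final_controls: np.ndarray
    final_tp: np.ndarray
    final_tn: np.ndarray
    se_hat: np.ndarray
    sp_hat: np.ndarray
    lower_se: np.ndarray
    lower_sp: np.ndarray
    upper_se: np.ndarray
    upper_sp: np.ndarray

    @property
    def n_final(self) -> int:
        """Number of replicates that reached the final analysis."""
        return int(np.count_nonzero(~self.stopped))


def simulate_trials(
    spec: DesignSpec, truth: TrialTruth, reps: int, rng: np.random.Generator
) -> TrialBatch:
    """Simulate ``reps`` seamless trials with vectorized binomial draws."""
    if reps < 1:
        raise ValueError(f"reps must be >= 1, got {reps}")
    if spec.margin_mode == "fixed":
        comp = interim_composition(spec.prevalence, spec.final_n, spec.stopping_time)
        pop_cases = np.full(reps, comp.pop_cases)
        added = np.full(reps, comp.added_cases)
        controls = np.full(reps, comp.controls)
        final_cases = np.full(reps, spec.final_cases)
        stage2_cases = final_cases - pop_cases
        stage2_controls = np.full(reps, spec.final_controls) - controls
    else:
        n1 = spec.n1
        pop_cases = rng.binomial(n1, spec.prevalence, reps)
        controls = n1 - pop_cases
        added = np.maximum(controls - pop_cases, 0)
        n2 = spec.final_n - n1
        stage2_cases = rng.binomial(n2, spec.prevalence, reps)
        stage2_controls = n2 - stage2_cases
        final_cases = pop_cases + stage2_cases
    final_controls = spec.final_n - final_cases

    x_pop = rng.binomial(pop_cases, truth.se_true)
    x_add = rng.binomial(added, truth.se_added)
    y1 = rng.binomial(controls, truth.sp_true)
    with np.errstate(invalid="ignore", divide="ignore"):
        interim_se = (x_pop + x_add) / (pop_cases + added)
        interim_sp = y1 / controls
    stopped = ~((interim_se > spec.f_se) & (interim_sp > spec.f_sp))

    x2 = rng.binomial(stage2_cases, truth.se_true)
    y2 = rng.binomial(stage2_controls, truth.sp_true)
    tp = x_pop + x2
    tn = y1 + y2
    with np.errstate(invalid="ignore", divide="ignore"):
        se_hat = tp / final_cases
        sp_hat = tn / final_controls
    ok_cases = final_cases > 0
    ok_controls = final_controls > 0
    lower_se = np.full(reps, np.nan)
    upper_se = np.full(reps, np.nan)
    lower_sp = np.full(reps, np.nan)
    upper_sp = np.full(reps, np.nan)
    if np.all(ok_cases):
        lower_se, upper_se = wilson_bounds(tp, final_cases, spec.ci_level)
    elif np.any(ok_cases):
        lower_se[ok_cases], upper_se[ok_cases] = wilson_bounds(
            tp[ok_cases], final_cases[ok_cases], spec.ci_level
        )
    if np.all(ok_controls):
        lower_sp, upper_sp = wilson_bounds(tn, final_controls, spec.ci_level)
    elif np.any(ok_controls):
        lower_sp[ok_controls], upper_sp[ok_controls] = wilson_bounds(
            tn[ok_controls], final_controls[ok_controls], spec.ci_level
        )
    return TrialBatch(
        spec=spec,
        truth=truth,
        reps=reps,
        stopped=stopped,
        interim_se=interim_se,
        interim_sp=interim_sp,
        final_cases=final_cases,
        final_controls=final_controls,
        final_tp=tp,
        final_tn=tn,
        se_hat=se_hat,
        sp_hat=sp_hat,
        lower_se=lower_se,
        lower_sp=lower_sp,
        upper_se=upper_se,
        upper_sp=upper_sp,
    )


def _case_pool_pmf(
    pop_cases: int, added: int, truth: TrialTruth
) -> np.ndarray:
    """PMF of the interim case-pool positive count.

    Population and added positives are independent binomials; when the
    added-case sensitivity differs the mixture pmf is their convolution.
    """
    if added == 0 or truth.se_added == truth.se_true:
        m = pop_cases + added
        return binom.pmf(np.arange(m + 1), m, truth.se_true)
    pmf_pop = binom.pmf(np.arange(pop_cases + 1), pop_cases, truth.se_true)
    pmf_add = binom.pmf(np.arange(added + 1), added, truth.se_added)
    return np.convolve(pmf_pop, pmf_add)


def exact_stopping_probability(
    spec: DesignSpec, truth: TrialTruth, max_pool: int = 100_000
) -> float:
    """Exact P(stop) by enumerating the two independent interim counts.

    Requires fixed margins.  The case-pool and control counts are
    independent, so P(continue) factorizes into the two one-sided tail
    probabilities of the strict boundary comparisons.
    """
    if spec.margin_mode != "fixed":
        raise OracleUnavailableError(
            "exact enumeration requires margin_mode='fixed'"
        )
    comp = interim_composition(spec.prevalence, spec.final_n, spec.stopping_time)
    m_case = comp.pop_cases + comp.added_cases
    m_ctrl = comp.controls
    if m_case > max_pool or m_ctrl > max_pool:
        raise OracleUnavailableError(
            f"pool sizes ({m_case}, {m_ctrl}) exceed enumeration cap {max_pool}"
        )
    pmf_case = _case_pool_pmf(comp.pop_cases, comp.added_cases, truth)
    k = np.arange(m_case + 1)
    p_stop_se = float(pmf_case[~((k / m_case) > spec.f_se)].sum())
    j = np.arange(m_ctrl + 1)
    pmf_ctrl = binom.pmf(j, m_ctrl, truth.sp_true)
    p_stop_sp = float(pmf_ctrl[~((j / m_ctrl) > spec.f_sp)].sum())
    # stop if either endpoint fails; summing the stop-side tails keeps the
    # value exact when one tail is empty
    return min(p_stop_se + p_stop_sp - p_stop_se * p_stop_sp, 1.0)


@dataclass(frozen=True)
class InterimReport:
    """Interim analysis of observed counts: estimates, boundaries, verdict."""

    estimate: AccuracyEstimate
    f_se: float
    f_sp: float
    stop: bool
    added_cases_needed: int


def analyze_interim(observed: Counts2x2, spec: DesignSpec) -> InterimReport:
    """Apply the futility rule to observed interim counts.

    ``added_cases_needed`` reports how many external cases would balance
    the table as observed (zero when it is already balanced or
    case-heavy); pass the unenriched stage-I counts to obtain the realized
    enrichment requirement.
    """
    est = estimate_accuracy(observed)
    if observed.n_controls >= observed.n_cases:
        needed = observed_added_cases(observed.n_cases, observed.n_controls)
    else:
        needed = 0
    return InterimReport(
        estimate=est,
        f_se=spec.f_se,
        f_sp=spec.f_sp,
        stop=interim_decision(est, spec.f_se, spec.f_sp),
        added_cases_needed=needed,
    )


def analyze_final(
    observed: Counts2x2, spec: DesignSpec
) -> IUTestResult:
    """Final confirmatory analysis: Wilson CIs and the intersection-union test."""
    return iu_test(observed, spec.hyp, spec.ci_level)
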