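"""Scenario grid and operating-characteristic study for the seamless design.

The full factorial grid crosses final sample size N in {333, 500, 1000}
(chosen so that the final analysis holds roughly 100 or 50 cases at the
prevalences considered), stopping time s in {0.1, 0.2, 0.3}, prevalence in
{0.1, 0.2, 0.3}, true sensitivity and specificity in {0.65, 0.75, 0.85,
0.95}, a common boundary distance Delta = futility boundary minus true
value in {-0.30, ..., +0.10} (step 0.05), and an added-case sensitivity
shift delta_add in {0.0, 0.1} — 7776 scenarios in total.

Per scenario the replicated trials yield: the stopping frequency;
conditional relative bias (mean error over non-stopped runs, scaled by one
minus the true value, in percent); conditional and unconditional coverage
(a stopped run counts as covering by convention); power over a grid of 25
minimum-value pairs (a stopped run counts as not rejecting); and the type I
error (the power entry at the true values, when those lie on the
hypothesis grid).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import DesignSpec
from .accuracy import HypothesisPair
from .trial import TrialBatch, TrialTruth, simulate_trials

__all__ = [
    "FINAL_NS",
    "STOPPING_TIMES",
    "PREVALENCES",
    "TRUE_VALUES",
    "DELTAS",
    "DELTA_ADDS",
    "HYPOTHESIS_VALUES",
    "Scenario",
    "PerformanceSummary",
    "build_grid",
    "run_scenario",
    "run_grid",
    "summarize_batch",
    "stopping_probability",
    "conditional_relative_bias",
    "coverage",
    "power_grid",
    "type1_error",
    "cohort_only_power",
    "results_to_dataframe",
    "summarize_across_designs",
]

logger = logging.getLogger(__name__)

FINAL_NS: tuple[int, ...] = (333, 500, 1000)
STOPPING_TIMES: tuple[float, ...] = (0.1, 0.2, 0.3)
PREVALENCES: tuple[float, ...] = (0.1, 0.2, 0.3)
TRUE_VALUES: tuple[float, ...] = (0.65, 0.75, 0.85, 0.95)
DELTAS: tuple[float, ...] = (-0.3, -0.25, -0.2, -0.15, -0.1, -0.05, 0.0, 0.05, 0.1)
DELTA_ADDS: tuple[float, ...] = (0.0, 0.1)
#: Minimum-value grid for the power map: all 25 (se0, sp0) combinations.
HYPOTHESIS_VALUES: tuple[float, ...] = (0.55, 0.65, 0.75, 0.85, 0.95)

#: Replicate count of a full-fidelity run; reporting filters expressed at
#: this scale are rescaled proportionally for reduced-replicate runs.
FULL_FIDELITY_REPS: int = 40_000
#: Minimum non-stopped runs (at full fidelity) for bias summaries and for
#: conditional-coverage summaries, respectively.
MIN_FINAL_RUNS_BIAS: int = 40
MIN_FINAL_RUNS_COVERAGE: int = 200


@dataclass(frozen=True)
class Scenario:
    """One cell of the simulation grid."""

    final_n: int
    s: float
    prevalence: float
    se_true: float
    sp_true: float
    delta: float
    delta_add: float

    @property
    def f_se(self) -> float:
        """Futility boundary for sensitivity: true value plus Delta."""
        return self.se_true + self.delta

    @property
    def f_sp(self) -> float:
        return self.sp_true + self.delta

    def design(self, margin_mode: str = "fixed") -> DesignSpec:
        return DesignSpec(
            final_n=self.final_n,
            stopping_time=self.s,
            prevalence=self.prevalence,
            f_se=self.f_se,
            f_sp=self.f_sp,
            margin_mode=margin_mode,
        )

    def truth(self) -> TrialTruth:
        return TrialTruth(
            se_true=self.se_true,
            sp_true=self.sp_true,
            prevalence=self.prevalence,
            delta_add=self.delta_add,
        )


def build_grid() -> list[Scenario]:
    """The full 7776-scenario grid in deterministic lexicographic order.

    Order of variation (slowest to fastest): final_n, s, prevalence,
    se_true, sp_true, delta, delta_add.
    """
    return [
        Scenario(*combo)
        for combo in itertools.product(
            FINAL_NS,
            STOPPING_TIMES,
            PREVALENCES,
            TRUE_VALUES,
            TRUE_VALUES,
            DELTAS,
            DELTA_ADDS,
        )
    ]


@dataclass
class PerformanceSummary:
    """Operating characteristics of one scenario.

    Conditional fields are ``None`` when no replicate reached the final
    analysis; ``power`` and ``type1`` are ``None`` when the power map was
    not requested.
    """

    scenario: Scenario
    reps: int
    stop_freq: float
    n_final: int
    cond_rel_bias_se: float | None
    cond_rel_bias_sp: float | None
    cond_cov_se: float | None
    cond_cov_sp: float | None
    uncond_cov_se: float
    uncond_cov_sp: float
    power: dict[tuple[float, float], float] | None = None
    type1: float | None = None

    @property
    def conditional_unreliable(self) -> bool:
        """True when too few final analyses back the conditional measures."""
        threshold = MIN_FINAL_RUNS_BIAS * self.reps / FULL_FIDELITY_REPS
        return self.n_final < threshold


def stopping_probability(batch: TrialBatch) -> float:
    """Relative frequency of stopping at the interim."""
    return float(np.mean(batch.stopped))


def conditional_relative_bias(batch: TrialBatch) -> tuple[float | None, float | None]:
    """Mean error over non-stopped runs, scaled by (1 - truth), in percent.

    Returns ``(bias_se, bias_sp)``; ``None`` when every run stopped or the
    scaling is degenerate (true value of 1).
    """
    cont = ~batch.stopped
    if not np.any(cont):
        return None, None
    truth = batch.truth

    def _one(est: np.ndarray, true: float) -> float | None:
        if true >= 1.0:
            return None
        return float(np.nanmean(est[cont] - true) / (1.0 - true) * 100.0)

    return _one(batch.se_hat, truth.se_true), _one(batch.sp_hat, truth.sp_true)


def coverage(
    batch: TrialBatch, conditional: bool
) -> tuple[float | None, float | None]:
    """CI coverage of the true values, per endpoint.

    Conditional: covering runs divided by non-stopped runs.  Unconditional:
    a stopped run counts as covering, so the denominator is all runs.
    """
    cont = ~batch.stopped
    truth = batch.truth
    cov_se = (batch.lower_se <= truth.se_true) & (truth.se_true <= batch.upper_se)
    cov_sp = (batch.lower_sp <= truth.sp_true) & (truth.sp_true <= batch.upper_sp)
    if conditional:
        n_final = int(np.count_nonzero(cont))
        if n_final == 0:
            return None, None
        return (
            float(np.count_nonzero(cov_se & cont) / n_final),
            float(np.count_nonzero(cov_sp & cont) / n_final),
        )
    n = batch.reps
    n_stopped = n - int(np.count_nonzero(cont))
    return (
        float((np.count_nonzero(cov_se & cont) + n_stopped) / n),
        float((np.count_nonzero(cov_sp & cont) + n_stopped) / n),
    )


def power_grid(
    batch: TrialBatch,
    values: tuple[float, ...] = HYPOTHESIS_VALUES,
    ignore_stopping: bool = False,
) -> dict[tuple[float, float], float]:
    """Global rejection rate for every (se0, sp0) pair on the value grid.

    A stopped run counts as not rejecting unless ``ignore_stopping`` is set
    (the cohort-only analysis of the same draws).
    """
    cont = np.ones(batch.reps, dtype=bool) if ignore_stopping else ~batch.stopped
    out: dict[tuple[float, float], float] = {}
    for se0 in values:
        rej_se = batch.lower_se > se0
        for sp0 in values:
            rej = cont & rej_se & (batch.lower_sp > sp0)
            out[(se0, sp0)] = float(np.count_nonzero(rej) / batch.reps)
    return out


def type1_error(
    power: dict[tuple[float, float], float], truth: TrialTruth
) -> float | None:
    """Power entry at the true values; absent when truth is off the grid."""
    key = (truth.se_true, truth.sp_true)
    return power.get(key)


_GRID_INDEX: dict[Scenario, int] | None = None


def _scenario_index(scn: Scenario) -> int:
    """Position of the scenario in the canonical grid (hash fallback off-grid)."""
    global _GRID_INDEX
    if _GRID_INDEX is None:
        _GRID_INDEX = {s: i for i, s in enumerate(build_grid())}
    return _GRID_INDEX.get(scn, hash(scn) % (2**31))


def _scenario_rng(scn: Scenario, seed: int) -> np.random.Generator:
    """Independent substream per scenario, reproducible across run order."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), _scenario_index(scn)])
    )


def run_scenario(
    scn: Scenario,
    reps: int,
    seed: int,
    compute_power: bool = True,
    margin_mode: str = "fixed",
    rng: np.random.Generator | None = None,
) -> PerformanceSummary:
    """Replicate the scenario's trial and compute all performance measures.

    The random substream is derived from ``(seed, scenario grid index)``,
    so results do not depend on the order in which scenarios are run.
    """
    if rng is None:
        rng = _scenario_rng(scn, seed)
    batch = simulate_trials(scn.design(margin_mode), scn.truth(), reps, rng)
    return summarize_batch(batch, scn, compute_power=compute_power)


def summarize_batch(
    batch: TrialBatch, scn: Scenario, compute_power: bool = True
) -> PerformanceSummary:
    """Performance measures of an already-simulated batch."""
    bias_se, bias_sp = conditional_relative_bias(batch)
    cond_se, cond_sp = coverage(batch, conditional=True)
    uncond_se, uncond_sp = coverage(batch, conditional=False)
    power = power_grid(batch) if compute_power else None
    t1 = type1_error(power, batch.truth) if power is not None else None
    return PerformanceSummary(
        scenario=scn,
        reps=batch.reps,
        stop_freq=stopping_probability(batch),
        n_final=batch.n_final,
        cond_rel_bias_se=bias_se,
        cond_rel_bias_sp=bias_sp,
        cond_cov_se=cond_se,
        cond_cov_sp=cond_sp,
        uncond_cov_se=uncond_se,
        uncond_cov_sp=uncond_sp,
        power=power,
        type1=t1,
    )


def cohort_only_power(
    scn: Scenario,
    reps: int,
    seed: int,
    values: tuple[float, ...] = HYPOTHESIS_VALUES,
    margin_mode: str = "fixed",
) -> dict[tuple[float, float], float]:
    """Power of a population-based study of the same final sample size.

    Runs the same engine with the same seed and ignores the stopping flag,
    so every draw is shared with the seamless run: the comparison is
    exactly paired and the seamless power can never exceed this one.
    """
    rng = _scenario_rng(scn, seed)
    batch = simulate_trials(scn.design(margin_mode), scn.truth(), reps, rng)
    return power_grid(batch, values, ignore_stopping=True)


def run_grid(
    scenarios: list[Scenario],
    reps: int,
    seed: int,
    compute_power: bool = True,
    margin_mode: str = "fixed",
    log_every: int = 500,
) -> list[PerformanceSummary]:
    """Run many scenarios with per-scenario substreams spawned from ``seed``."""
    out = []
    for i, scn in enumerate(scenarios):
        out.append(
            run_scenario(scn, reps, seed, compute_power=compute_power,
                         margin_mode=margin_mode)
        )
        if log_every and (i + 1) % log_every == 0:
            logger.info("ran %d / %d scenarios", i + 1, len(scenarios))
    return out


def results_to_dataframe(summaries: list[PerformanceSummary]) -> pd.DataFrame:
    """Flatten summaries to one row per scenario.

    Power columns are named ``power_{se0}_{sp0}``; missing conditional
    measures become NaN.
    """
    rows = []
    for s in summaries:
        row: dict[str, object] = {
            "final_n": s.scenario.final_n,
            "s": s.scenario.s,
            "prevalence": s.scenario.prevalence,
            "se_true": s.scenario.se_true,
            "sp_true": s.scenario.sp_true,
            "delta": s.scenario.delta,
            "delta_add": s.scenario.delta_add,
            "reps": s.reps,
            "stop_freq": s.stop_freq,
            "n_final": s.n_final,
            "cond_rel_bias_se": s.cond_rel_bias_se,
            "cond_rel_bias_sp": s.cond_rel_bias_sp,
            "cond_cov_se": s.cond_cov_se,
            "cond_cov_sp": s.cond_cov_sp,
            "uncond_cov_se": s.uncond_cov_se,
            "uncond_cov_sp": s.uncond_cov_sp,
            "type1": s.type1,
        }
        if s.power is not None:
            for (se0, sp0), value in s.power.items():
                row[f"power_{se0}_{sp0}"] = value
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_across_designs(
    results: pd.DataFrame,
    group_by: list[str] | tuple[str, ...] = ("s",),
    percentile: float = 90.0,
    min_final_runs: int = MIN_FINAL_RUNS_BIAS,
    value_columns: tuple[str, ...] = ("cond_rel_bias_se", "cond_rel_bias_sp"),
) -> pd.DataFrame:
    """Grouped percentiles of per-design measures with reporting filters.

    Designs with fewer non-stopped runs than ``min_final_runs`` (expressed
    at the 40000-replicate scale and rescaled proportionally to the actual
    replicate count) are omitted, mirroring the exclusion of designs whose
    conditional measures rest on too few final analyses.  The value columns
    are pooled within each group (by default sensitivity and specificity
    biases together) and summarized by their median and the requested
    percentile (linear interpolation between order statistics).
    """
    if results.empty:
        raise ValueError("results must be nonempty")
    df = results.copy()
    threshold = min_final_runs * df["reps"] / FULL_FIDELITY_REPS
    df = df[df["n_final"] >= threshold]
    records = []
    group_by = list(group_by)
    for key, grp in df.groupby(group_by):
        pooled = pd.concat([grp[c] for c in value_columns]).dropna().to_numpy()
        if len(pooled) == 0:
            continue
        rec = dict(zip(group_by, key if isinstance(key, tuple) else (key,)))
        rec.update(
            n_designs=len(grp),
            n_values=len(pooled),
            median=float(np.median(pooled)),
            percentile=percentile,
            percentile_value=float(np.percentile(pooled, percentile)),
        )
        records.append(rec)
    return pd.DataFrame(records)
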