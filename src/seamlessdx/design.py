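"""Planning a seamless diagnostic accuracy design.

A seamless design embeds a case-enriched interim analysis with futility
stopping into an ongoing population-based cohort study.  Stage I recruits a
fraction ``s`` of the intended final sample size ``N`` from the population
stream; cases from an external source are then added until cases and
controls are balanced, the interim analysis is run, and — if the study
continues — stage II completes the population sample while the added cases
are removed again before the final analysis.

This module encodes the design parameters and the interim composition
arithmetic: how prevalence, final sample size and stopping time determine
the number of population cases, added cases and controls analysed at the
interim.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .accuracy import HypothesisPair

__all__ = [
    "DesignSpec",
    "InterimComposition",
    "SymmetricModeRequiredError",
    "round_half_up",
    "interim_composition",
    "composition_for_target_interim_total",
    "observed_added_cases",
    "validate_design",
]


class SymmetricModeRequiredError(ValueError):
    """Raised when balancing would require adding controls (prevalence >= 0.5).

    The canonical composition adds cases; a prevalence at or above 50% must
    be handled by the symmetric role swap (adding controls instead).
    """


def round_half_up(x: float) -> int:
    """Round to the nearest integer with halves rounded up (0.5 -> 1)."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class InterimComposition:
    """Breakdown of the stage-I analysis population.

    ``pop_cases + controls = n1`` (the recruited stage-I population) and,
    for prevalence below 0.5, ``pop_cases + added_cases = controls`` (the
    interim case pool is enriched up to the number of controls).
    """

    n1: int
    pop_cases: int
    added_cases: int
    controls: int

    @property
    def interim_cases(self) -> int:
        """Total cases analysed at the interim (population plus added)."""
        return self.pop_cases + self.added_cases

    @property
    def interim_total(self) -> int:
        return self.interim_cases + self.controls


@dataclass(frozen=True)
class DesignSpec:
    """All planning parameters of a seamless design.

    Parameters
    ----------
    final_n : intended sample size N of the final (population-based) analysis.
    stopping_time : fraction s in (0, 1) of N recruited before the interim.
    prevalence : expected prevalence p of the target condition, in (0, 1).
    f_se, f_sp : futility boundaries; the study continues only if both
        interim point estimates lie strictly above them.  Values >= 1 are
        allowed and make stopping certain.
    hyp : minimum sensitivity/specificity (se0, sp0) tested at the final
        analysis.
    ci_level : two-sided confidence level of the Wilson intervals.
    margin_mode : "fixed" freezes the case/control margins at their expected
        values; "binomial" draws the stage-I and stage-II case counts
        binomially from the prevalence.
    """

    final_n: int
    stopping_time: float
    prevalence: float
    f_se: float
    f_sp: float
    hyp: HypothesisPair = field(default_factory=lambda: HypothesisPair(0.8, 0.8))
    ci_level: float = 0.95
    margin_mode: str = "fixed"

    def __post_init__(self) -> None:
        if self.final_n < 1:
            raise ValueError(f"final_n must be >= 1, got {self.final_n}")
        if not 0.0 < self.stopping_time < 1.0:
            raise ValueError(
                f"stopping_time must be in (0, 1), got {self.stopping_time}"
            )
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError(f"prevalence must be in (0, 1), got {self.prevalence}")
        if self.f_se < 0 or self.f_sp < 0:
            raise ValueError("futility boundaries must be non-negative")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError(f"ci_level must be in (0, 1), got {self.ci_level}")
        if self.margin_mode not in ("fixed", "binomial"):
            raise ValueError(
                f"margin_mode must be 'fixed' or 'binomial', got {self.margin_mode!r}"
            )

    @property
    def n1(self) -> int:
        """Planned stage-I population size round_half_up(s * N)."""
        return round_half_up(self.stopping_time * self.final_n)

    @property
    def final_cases(self) -> int:
        """Expected case count in the final analysis, round_half_up(p * N)."""
        return round_half_up(self.prevalence * self.final_n)

    @property
    def final_controls(self) -> int:
        return self.final_n - self.final_cases


def interim_composition(p: float, final_n: int, s: float) -> InterimComposition:
    """Stage-I composition from prevalence, final sample size and stopping time.

    ``n1 = round(s * N)`` and ``pop_cases = round(p * n1)`` use round-half-up;
    controls and added cases follow by subtraction, so the balance
    ``pop_cases + added_cases = controls`` holds exactly after rounding.
    """
    if not 0.0 < s < 1.0:
        raise ValueError(f"stopping time must be in (0, 1), got {s}")
    if not 0.0 < p < 1.0:
        raise ValueError(f"prevalence must be in (0, 1), got {p}")
    n1 = round_half_up(s * final_n)
    pop_cases = round_half_up(p * n1)
    controls = n1 - pop_cases
    added_cases = controls - pop_cases
    if added_cases < 0:
        raise SymmetricModeRequiredError(
            f"prevalence {p} yields more cases ({pop_cases}) than controls "
            f"({controls}) in stage I; balancing requires adding controls"
        )
    return InterimComposition(
        n1=n1, pop_cases=pop_cases, added_cases=added_cases, controls=controls
    )


def composition_for_target_interim_total(
    p: float, interim_total: int
) -> InterimComposition:
    """Composition when the interim analysis population is fixed in advance.

    The interim population of ``interim_total`` participants is split 1:1
    into cases and controls; the population stream is recruited until it
    yields ``interim_total / 2`` controls, and enough cases are added to
    reach balance.  ``n1 = round(controls / (1 - p))`` uses round-half-up;
    the remaining fields follow by subtraction.
    """
    if interim_total < 2:
        raise ValueError(f"interim_total must be >= 2, got {interim_total}")
    if not 0.0 < p <= 0.5:
        raise SymmetricModeRequiredError(
            f"prevalence must be in (0, 0.5] for case enrichment, got {p}"
        )
    controls = interim_total // 2
    n1 = round_half_up(controls / (1.0 - p))
    pop_cases = n1 - controls
    added_cases = controls - pop_cases
    if added_cases < 0:
        raise SymmetricModeRequiredError(
            f"prevalence {p} over-fills the case arm of a {interim_total}-participant "
            "interim population; balancing requires adding controls"
        )
    return InterimComposition(
        n1=n1, pop_cases=pop_cases, added_cases=added_cases, controls=controls
    )


def observed_added_cases(observed_cases: int, observed_controls: int) -> int:
    """Cases to add for balance, from *realized* stage-I recruitment.

    At the interim the enrichment requirement is recomputed from the cases
    and controls actually recruited, not from the planned prevalence.
    """
    if observed_cases < 0 or observed_controls < 0:
        raise ValueError("observed counts must be non-negative")
    n_add = observed_controls - observed_cases
    if n_add < 0:
        raise SymmetricModeRequiredError(
            f"observed cases ({observed_cases}) exceed controls "
            f"({observed_controls}); balancing requires adding controls"
        )
    return n_add


def validate_design(
    spec: DesignSpec, enrichment_pool: int | None = None
) -> list[str]:
    """Sanity-check a design and return a list of human-readable warnings.

    Warns when a futility boundary is not below the corresponding minimum
    value, when the stopping time lies outside the customary [0.1, 0.3]
    range, when a boundary can never be exceeded, and when the planned
    enrichment exceeds a declared pool of available external cases.
    Structural invalidity (handled in ``DesignSpec``) raises instead.
    """
    warnings: list[str] = []
    if spec.f_se >= spec.hyp.se0:
        warnings.append(
            f"futility boundary f_se={spec.f_se} is not below the minimum "
            f"sensitivity se0={spec.hyp.se0}; boundaries should sit below the "
            "minimally acceptable values"
        )
    if spec.f_sp >= spec.hyp.sp0:
        warnings.append(
            f"futility boundary f_sp={spec.f_sp} is not below the minimum "
            f"specificity sp0={spec.hyp.sp0}"
        )
    if spec.f_se >= 1.0 or spec.f_sp >= 1.0:
        warnings.append(
            "a futility boundary >= 1 can never be exceeded: the study "
            "always stops at the interim"
        )
    if not 0.1 <= spec.stopping_time <= 0.3:
        warnings.append(
            f"stopping time s={spec.stopping_time} lies outside the customary "
            "range [0.1, 0.3]"
        )
    if enrichment_pool is not None:
        comp = interim_composition(spec.prevalence, spec.final_n, spec.stopping_time)
        if comp.added_cases > enrichment_pool:
            warnings.append(
                f"planned enrichment needs {comp.added_cases} added cases but "
                f"only {enrichment_pool} are available; the interim analysis "
                "would proceed unbalanced"
            )
    return warnings
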