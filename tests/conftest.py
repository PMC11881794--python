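import pytest

from seamlessdx import DesignSpec, HypothesisPair, TrialTruth

#: (prevalence, final N, stopping time s) -> (pop cases, added cases, controls)
#: for every composition printed in the planning table.
COMPOSITION_TABLE = [
    (0.1, 1000, 0.1, 10, 80, 90),
    (0.1, 1000, 0.2, 20, 160, 180),
    (0.1, 1000, 0.3, 30, 240, 270),
    (0.1, 500, 0.1, 5, 40, 45),
    (0.1, 500, 0.2, 10, 80, 90),
    (0.1, 500, 0.3, 15, 120, 135),
    (0.2, 500, 0.1, 10, 30, 40),
    (0.2, 500, 0.2, 20, 60, 80),
    (0.2, 500, 0.3, 30, 90, 120),
    (0.2, 250, 0.1, 5, 15, 20),
    (0.2, 250, 0.2, 10, 30, 40),
    (0.2, 250, 0.3, 15, 45, 60),
    (0.3, 333, 0.1, 10, 13, 23),
    (0.3, 333, 0.2, 20, 27, 47),
    (0.3, 333, 0.3, 30, 40, 70),
    (0.3, 167, 0.1, 5, 7, 12),
    (0.3, 167, 0.2, 10, 13, 23),
    (0.3, 167, 0.3, 15, 20, 35),
]


@pytest.fixture
def worked_design() -> DesignSpec:
    """The two-study worked example: se0=0.90, sp0=0.85, boundaries ten
    points below, 20% expected prevalence, N=500, interim after 100."""
    return DesignSpec(
        final_n=500,
        stopping_time=0.2,
        prevalence=0.2,
        f_se=0.80,
        f_sp=0.75,
        hyp=HypothesisPair(0.90, 0.85),
    )


@pytest.fixture
def boundary_truth() -> TrialTruth:
    """Truth sitting exactly on futility boundaries f_se = f_sp = 0.85."""
    return TrialTruth(se_true=0.85, sp_true=0.85, prevalence=0.2)
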