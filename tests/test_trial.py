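"""Single-trial engine: interim decision, data reuse, enumeration oracle."""

import math

import numpy as np
import pytest

from seamlessdx import (
    AccuracyEstimate,
    Counts2x2,
    DesignSpec,
    HypothesisPair,
    TrialTruth,
    analyze_final,
    analyze_interim,
    exact_stopping_probability,
    interim_decision,
    run_trial,
    simulate_stage1,
    simulate_trials,
)
from seamlessdx.trial import OracleUnavailableError

# Frozen from an independent brute-force enumeration (double/triple sum over
# all interim outcomes with exact binomial pmfs) for the worked-example
# composition (20 population + 60 added cases, 80 controls), truth
# se = sp = 0.85, boundaries 0.85.
STOP_PROB_DELTA0 = 0.7955237571019407
STOP_PROB_DELTA_ADD = 0.5544286913447796


class TestInterimDecision:
    @pytest.mark.parametrize(
        "se_hat, sp_hat, stop",
        [
            (0.73, 0.81, True),   # sensitivity below its boundary
            (0.89, 0.76, False),  # both strictly above
            (0.80, 0.90, True),   # tie on sensitivity boundary stops
            (0.90, 0.75, True),   # tie on specificity boundary stops
        ],
    )
    def test_strictly_above_rule(self, se_hat, sp_hat, stop):
        est = AccuracyEstimate(se_hat, sp_hat)
        assert interim_decision(est, 0.80, 0.75) is stop


class TestStage1:
    def test_fixed_margins_match_planned_composition(self, worked_design):
        truth = TrialTruth(0.85, 0.80, 0.2)
        rng = np.random.default_rng(1)
        s1 = simulate_stage1(worked_design, truth, rng)
        assert (s1.pop_cases, s1.added_cases, s1.controls) == (20, 60, 80)

    def test_perfect_test_yields_perfect_interim_estimates(self, worked_design):
        truth = TrialTruth(1.0, 1.0, 0.2)
        s1 = simulate_stage1(worked_design, truth, np.random.default_rng(0))
        assert s1.interim_se_hat == 1.0
        assert s1.interim_sp_hat == 1.0

    def test_added_case_sensitivity_clamped_at_one(self, worked_design):
        truth = TrialTruth(0.95, 0.85, 0.2, delta_add=0.1)
        assert truth.se_added == 1.0
        s1 = simulate_stage1(worked_design, truth, np.random.default_rng(0))
        assert s1.added_case_pos == s1.added_cases


class TestRunTrial:
    def test_stopped_trial_has_no_final_fields(self, worked_design):
        truth = TrialTruth(0.2, 0.2, 0.2)  # far below boundaries: stops
        outcome = run_trial(worked_design, truth, np.random.default_rng(3))
        assert outcome.stopped
        assert outcome.final_counts is None
        assert outcome.ci_se is None

    def test_final_counts_reuse_population_and_drop_added_cases(self, worked_design):
        truth = TrialTruth(1.0, 1.0, 0.2)
        outcome = run_trial(worked_design, truth, np.random.default_rng(0))
        assert not outcome.stopped
        counts = outcome.final_counts
        # 100 cases = 20 stage-I population + 80 stage-II; added 60 removed.
        assert counts.n_cases == 100
        assert counts.n_controls == 400
        assert counts.n_tp == 100 and counts.n_tn == 400
        assert outcome.rejections[worked_design.hyp]

    def test_no_stopping_reduces_to_plain_cohort(self):
        spec = DesignSpec(
            final_n=500, stopping_time=0.2, prevalence=0.2,
            f_se=0.0, f_sp=0.0, hyp=HypothesisPair(0.8, 0.8),
        )
        truth = TrialTruth(0.85, 0.85, 0.2)
        rng = np.random.default_rng(7)
        outcomes = [run_trial(spec, truth, rng) for _ in range(400)]
        assert not any(o.stopped for o in outcomes)
        mean_se = np.mean([o.final_estimates.se_hat for o in outcomes])
        # binomial mean with MC error 3 * sqrt(se(1-se)/100)/sqrt(400)
        assert mean_se == pytest.approx(0.85, abs=3 * 0.0357 / 20)

    def test_binomial_margins_draw_final_case_count(self):
        spec = DesignSpec(
            final_n=500, stopping_time=0.2, prevalence=0.2,
            f_se=0.0, f_sp=0.0, margin_mode="binomial",
        )
        truth = TrialTruth(0.9, 0.9, 0.2)
        rng = np.random.default_rng(11)
        cases = [run_trial(spec, truth, rng).final_counts.n_cases for _ in range(300)]
        assert np.std(cases) > 0
        assert np.mean(cases) == pytest.approx(100, abs=3 * math.sqrt(500 * 0.16) / math.sqrt(300))


class TestExactStoppingProbability:
    def test_zero_boundaries_never_stop(self, worked_design, boundary_truth):
        spec = DesignSpec(
            final_n=500, stopping_time=0.2, prevalence=0.2, f_se=0.0, f_sp=0.0
        )
        # under the strict "above" rule an all-negative interim would stop
        # even at boundary zero, but that event has probability ~1e-66
        assert exact_stopping_probability(spec, boundary_truth) == pytest.approx(
            0.0, abs=1e-30
        )

    def test_boundaries_above_one_always_stop(self, boundary_truth):
        spec = DesignSpec(
            final_n=500, stopping_time=0.2, prevalence=0.2, f_se=1.01, f_sp=1.01
        )
        assert exact_stopping_probability(spec, boundary_truth) == 1.0

    def test_matches_frozen_enumeration_oracle(self, boundary_truth):
        spec = DesignSpec(
            final_n=500, stopping_time=0.2, prevalence=0.2, f_se=0.85, f_sp=0.85
        )
        assert exact_stopping_probability(spec, boundary_truth) == pytest.approx(
            STOP_PROB_DELTA0, abs=1e-10
        )
        shifted = TrialTruth(0.85, 0.85, 0.2, delta_add=0.1)
        assert exact_stopping_probability(spec, shifted) == pytest.approx(
            STOP_PROB_DELTA_ADD, abs=1e-10
        )

    def test_monte_carlo_agrees_within_three_standard_errors(self, boundary_truth):
        spec = DesignSpec(
            final_n=500, stopping_time=0.2, prevalence=0.2, f_se=0.85, f_sp=0.85
        )
        reps = 20000
        batch = simulate_trials(spec, boundary_truth, reps, np.random.default_rng(5))
        mc = float(np.mean(batch.stopped))
        se = math.sqrt(STOP_PROB_DELTA0 * (1 - STOP_PROB_DELTA0) / reps)
        assert abs(mc - STOP_PROB_DELTA0) <= 3 * se

    def test_binomial_margins_unsupported(self, boundary_truth):
        spec = DesignSpec(
            final_n=500, stopping_time=0.2, prevalence=0.2,
            f_se=0.85, f_sp=0.85, margin_mode="binomial",
        )
        with pytest.raises(OracleUnavailableError):
            exact_stopping_probability(spec, boundary_truth)

    def test_pool_cap_enforced(self, boundary_truth):
        spec = DesignSpec(
            final_n=500, stopping_time=0.2, prevalence=0.2, f_se=0.85, f_sp=0.85
        )
        with pytest.raises(OracleUnavailableError):
            exact_stopping_probability(spec, boundary_truth, max_pool=10)


class TestBatchAccounting:
    def test_final_margins_exclude_added_and_include_stage1(self, worked_design):
        truth = TrialTruth(0.85, 0.80, 0.2)
        batch = simulate_trials(worked_design, truth, 500, np.random.default_rng(2))
        assert np.all(batch.final_cases == 100)
        assert np.all(batch.final_controls == 400)
        # final positives can never exceed margins
        assert np.all(batch.final_tp <= batch.final_cases)
        assert np.all(batch.final_tn <= batch.final_controls)

    def test_selection_effect_direction(self, worked_design):
        # conditional-on-continue final estimates are stochastically larger
        truth = TrialTruth(0.82, 0.77, 0.2)
        batch = simulate_trials(worked_design, truth, 20000, np.random.default_rng(9))
        cont = ~batch.stopped
        assert 0 < cont.sum() < batch.reps
        assert batch.se_hat[cont].mean() >= batch.se_hat.mean()
        assert batch.sp_hat[cont].mean() >= batch.sp_hat.mean()


class TestObservedAnalyses:
    def test_interim_stop_verdict_low_sensitivity(self, worked_design):
        # 58/80 = 0.725 sensitivity below the 0.80 boundary: stop
        counts = Counts2x2(n_tp=58, n_fn=22, n_tn=65, n_fp=15)
        report = analyze_interim(counts, worked_design)
        assert report.stop
        assert report.estimate.se_hat < worked_design.f_se

    def test_interim_continue_verdict(self, worked_design):
        # 71/80 = 0.8875 and 61/80 = 0.7625: both strictly above boundaries
        counts = Counts2x2(n_tp=71, n_fn=9, n_tn=61, n_fp=19)
        report = analyze_interim(counts, worked_design)
        assert not report.stop

    def test_interim_reports_realized_enrichment_need(self, worked_design):
        # unenriched stage-I data: 10 cases, 90 controls -> 80 cases to add
        counts = Counts2x2(n_tp=9, n_fn=1, n_tn=72, n_fp=18)
        report = analyze_interim(counts, worked_design)
        assert report.added_cases_needed == 80

    def test_final_no_rejection_below_minimums(self, worked_design):
        # estimates 0.82 and 0.77 against minimums 0.90 / 0.85
        counts = Counts2x2(n_tp=82, n_fn=18, n_tn=308, n_fp=92)
        res = analyze_final(counts, worked_design)
        assert res.estimate.se_hat == pytest.approx(0.82)
        assert res.estimate.sp_hat == pytest.approx(0.77)
        assert not res.reject_global

    def test_final_rejection_with_overwhelming_counts(self):
        spec = DesignSpec(
            final_n=2000, stopping_time=0.2, prevalence=0.5,
            f_se=0.0, f_sp=0.0, hyp=HypothesisPair(0.5, 0.5),
        )
        counts = Counts2x2(n_tp=1000, n_fn=0, n_tn=1000, n_fp=0)
        assert analyze_final(counts, spec).reject_global
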