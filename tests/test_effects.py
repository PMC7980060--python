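"""Outcome standardization, weighted estimators and question orchestration."""

import numpy as np
import pandas as pd
import pytest

from ipwmed import (
    CausalSpec,
    ModelOptions,
    ate_weights,
    cde_weights,
    estimate_ate,
    estimate_total_effect,
    estimates_to_frame,
    fit_msm_cde,
    population_table,
    run_question,
    standardize_outcomes,
    total_effect_weights,
    true_estimands,
)
from ipwmed.effects import EstimationError


class TestStandardization:
    def test_weighted_sd_becomes_one(self, small_cohort, spec):
        out = standardize_outcomes(small_cohort, spec, "design_weight")
        w = out.df.design_weight.to_numpy()
        for y in spec.outcomes:
            v = out.df[y].to_numpy()
            mean = np.average(v, weights=w)
            sd = np.sqrt(np.average((v - mean) ** 2, weights=w))
            assert sd == pytest.approx(1.0, abs=1e-10)
            assert mean == pytest.approx(0.0, abs=1e-10)

    def test_scale_invariance_of_input(self, small_cohort, spec):
        rescaled = small_cohort.copy()
        rescaled.df["y_ext"] = rescaled.df["y_ext"] * 10.0
        a = standardize_outcomes(small_cohort, spec, "design_weight")
        b = standardize_outcomes(rescaled, spec, "design_weight")
        np.testing.assert_allclose(a.df.y_ext, b.df.y_ext, atol=1e-10)

    def test_scale_factor_multiplies_output(self, small_cohort, spec):
        a = standardize_outcomes(small_cohort, spec, "design_weight")
        b = standardize_outcomes(small_cohort, spec, "design_weight", scale_factor=100)
        np.testing.assert_allclose(b.df.y_ext, 100 * a.df.y_ext, atol=1e-8)

    def test_zero_sd_outcome_rejected(self, small_cohort, spec):
        degenerate = small_cohort.copy()
        degenerate.df["y_ext"] = 3.14
        with pytest.raises(EstimationError, match="zero weighted SD"):
            standardize_outcomes(degenerate, spec, "design_weight")


class TestPopulationOracle:
    """Saturated weighted analyses of the exact population table must equal
    enumeration g-formula values."""

    def test_all_estimands_match_enumeration(self, discrete_config):
        spec = CausalSpec(
            "x", "m", ("c1", "c2"), ("l1",), ("y_ext", "y_voc")
        )
        pop = population_table(discrete_config)
        truth = true_estimands(discrete_config)
        opts = ModelOptions(saturated=True)

        aw = ate_weights(pop, spec, "design_weight", opts)
        for e in estimate_ate(pop, aw, spec):
            lev = e.contrast.split(" ")[0]
            assert e.point == pytest.approx(truth.ate[e.outcome][lev], abs=1e-10)

        tw = total_effect_weights(pop, spec, "design_weight", opts)
        for e in estimate_total_effect(pop, tw, spec):
            assert e.point == pytest.approx(truth.total_effect[e.outcome], abs=1e-10)

        cw = cde_weights(pop, spec, "design_weight", opts)
        ests = fit_msm_cde(
            pop, cw, spec, scenarios=("parental", "non_centre", "centre")
        )
        for e in ests:
            assert e.point == pytest.approx(truth.cde[e.outcome][e.scenario], abs=1e-10)

    def test_no_interaction_outcome_has_equal_cdes(self, discrete_config):
        spec = CausalSpec("x", "m", ("c1", "c2"), ("l1",), ("y_voc",))
        pop = population_table(discrete_config)
        cw = cde_weights(pop, spec, "design_weight", ModelOptions(saturated=True))
        ests = fit_msm_cde(pop, cw, spec, scenarios=("parental", "centre"))
        by_scenario = {e.scenario: e.point for e in ests}
        assert by_scenario["parental"] == pytest.approx(by_scenario["centre"], abs=1e-10)


class TestEstimators:
    def test_weight_estimand_labels_enforced(self, small_cohort, spec):
        tw = total_effect_weights(small_cohort, spec, "design_weight")
        with pytest.raises(EstimationError, match="ate_mediator"):
            estimate_ate(small_cohort, tw, spec)
        with pytest.raises(EstimationError, match="cde"):
            fit_msm_cde(small_cohort, tw, spec)

    def test_randomized_exposure_equals_weighted_mean_difference(self, small_cohort):
        """With an empty adjustment set the stabilized weights reduce to the
        design weights and the estimate is the design-weighted mean difference."""
        spec = CausalSpec("x", "m", (), (), ("y_ext",))
        ws = total_effect_weights(small_cohort, spec, "design_weight")
        est = estimate_total_effect(small_cohort, ws, spec)[0]
        df, w = small_cohort.df, small_cohort.df.design_weight
        diff = np.average(df.y_ext[df.x == 1], weights=w[df.x == 1]) - np.average(
            df.y_ext[df.x == 0], weights=w[df.x == 0]
        )
        assert est.point == pytest.approx(diff, abs=1e-10)

    def test_empty_exposure_mediator_cell_named(self, small_cohort, spec):
        broken = small_cohort.copy()
        drop = (broken.df.x == 1) & (broken.df.m == "centre")
        broken.df = broken.df.loc[~drop].reset_index(drop=True)
        ws = cde_weights(broken, spec, "design_weight")
        with pytest.raises(EstimationError, match="x=1.*centre"):
            fit_msm_cde(broken, ws, spec)

    def test_ci_uses_196_se(self, small_cohort, spec, design):
        ws = total_effect_weights(small_cohort, spec, design.weight_col)
        est = estimate_total_effect(small_cohort, ws, spec, design)[0]
        assert est.ci_low == pytest.approx(est.point - 1.96 * est.se)
        assert est.ci_high == pytest.approx(est.point + 1.96 * est.se)
        assert est.ci_low <= est.point <= est.ci_high


class TestRunQuestion:
    def test_questions_2_and_3_share_total_effects(self, small_cohort, spec, design):
        q2 = estimates_to_frame(run_question(small_cohort, spec, 2, design))
        q3 = estimates_to_frame(run_question(small_cohort, spec, 3, design))
        te2 = q2[q2.estimand == "total_effect"].reset_index(drop=True)
        te3 = q3[q3.estimand == "total_effect"].reset_index(drop=True)
        pd.testing.assert_frame_equal(te2, te3)
        assert set(q2[q2.estimand == "cde"].scenario) == {"centre"}
        assert set(q3[q3.estimand == "cde"].scenario) == {"parental"}

    def test_one_estimate_per_declared_outcome(self, small_cohort, spec, design):
        q1 = estimates_to_frame(run_question(small_cohort, spec, 1, design))
        counts = q1.groupby("outcome").size()
        assert (counts == 2).all()  # two non-reference mediator contrasts
        assert set(counts.index) == set(spec.outcomes)

    def test_orchestration_equals_manual_stages(self, small_cohort, spec, design):
        auto = run_question(small_cohort, spec, 1, design)
        ws = ate_weights(small_cohort, spec, design.weight_col)
        manual = estimate_ate(small_cohort, ws, spec, design)
        for a, m in zip(auto, manual):
            assert a.point == pytest.approx(m.point, abs=1e-12)
            assert a.se == pytest.approx(m.se, abs=1e-12)

    def test_unknown_question_rejected(self, small_cohort, spec):
        with pytest.raises(ValueError):
            run_question(small_cohort, spec, 4)
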