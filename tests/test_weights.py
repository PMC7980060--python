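"""Propensity models, stabilized weights, truncation and balance diagnostics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ipwmed import (
    CausalSpec,
    CohortTable,
    ColumnDef,
    ModelOptions,
    WeightSet,
    ate_weights,
    balance_report,
    cde_weights,
    fit_exposure_model,
    fit_mediator_model,
    total_effect_weights,
    truncate_weights,
)
from ipwmed.weights import WeightEstimationError


def toy_cohort(rows: dict) -> CohortTable:
    df = pd.DataFrame(rows)
    dictionary = {
        "x": ColumnDef("exposure", "binary"),
        "m": ColumnDef(
            "mediator", "categorical",
            levels=("parental", "non_centre", "centre"), reference="parental",
        ),
        "c1": ColumnDef("confounder_pre", "binary"),
        "l1": ColumnDef("confounder_post", "binary"),
    }
    for col in df.columns:
        if col.startswith("y"):
            dictionary[col] = ColumnDef("outcome", "continuous")
    return CohortTable(df, {k: v for k, v in dictionary.items() if k in df.columns})


MLEVELS = ["parental", "non_centre", "centre"]


class TestExposureModel:
    def test_intercept_only_returns_prevalence(self):
        coh = toy_cohort({"x": [1, 1, 0, 0, 0]})
        spec = CausalSpec("x", "m", (), (), ())
        model = fit_exposure_model(coh, spec)
        assert np.allclose(model.prob1, 0.4)

    def test_saturated_cells_match_toy_counts(self):
        # C=1: 8 of 10 exposed; C=0: 2 of 10 exposed
        coh = toy_cohort({"x": [1] * 8 + [0] * 2 + [1] * 2 + [0] * 8,
                          "c1": [1] * 10 + [0] * 10})
        spec = CausalSpec("x", "m", ("c1",), (), ())
        for opts in (ModelOptions(saturated=True), ModelOptions()):
            model = fit_exposure_model(coh, spec, options=opts)
            assert model.prob1[0] == pytest.approx(0.8, abs=1e-6)
            assert model.prob1[-1] == pytest.approx(0.2, abs=1e-6)

    def test_probabilities_strictly_inside_unit_interval(self, small_cohort, spec):
        model = fit_exposure_model(small_cohort, spec, "design_weight")
        assert np.all(model.prob1 > 0) and np.all(model.prob1 < 1)

    def test_separation_raises_with_remedy_hint(self):
        coh = toy_cohort({"x": [1] * 10 + [0] * 10, "c1": [1] * 10 + [0] * 10})
        spec = CausalSpec("x", "m", ("c1",), (), ())
        with pytest.raises(WeightEstimationError, match="ridge|clip"):
            fit_exposure_model(coh, spec)
        model = fit_exposure_model(coh, spec, options=ModelOptions(ridge=1.0))
        assert np.all((model.prob1 > 0) & (model.prob1 < 1))

    def test_missing_confounder_values_rejected(self):
        coh = toy_cohort({"x": [1, 0, 1, 0], "c1": [1.0, np.nan, 0.0, 1.0]})
        spec = CausalSpec("x", "m", ("c1",), (), ())
        with pytest.raises(WeightEstimationError, match="impute"):
            fit_exposure_model(coh, spec)


class TestMediatorModel:
    def test_marginal_equals_observed_shares(self):
        coh = toy_cohort({"m": MLEVELS * 4 + ["parental"] * 2, "x": [0, 1] * 7})
        spec = CausalSpec("x", "m", (), (), ())
        model = fit_mediator_model(coh, spec, "marginal")
        assert model.probs.iloc[0].to_dict() == pytest.approx(
            {"parental": 6 / 14, "non_centre": 4 / 14, "centre": 4 / 14}
        )

    def test_probabilities_sum_to_one(self, small_cohort, spec):
        model = fit_mediator_model(small_cohort, spec, "full", "design_weight")
        assert np.allclose(model.probs.sum(axis=1), 1.0, atol=1e-12)

    def test_saturated_fit_reproduces_cell_frequencies(self):
        rng = np.random.default_rng(5)
        n = 600
        x = rng.integers(0, 2, n)
        m = np.where(rng.random(n) < 0.3 + 0.2 * x, "centre",
                     np.where(rng.random(n) < 0.5, "parental", "non_centre"))
        coh = toy_cohort({"x": x, "m": m})
        spec = CausalSpec("x", "m", (), (), ())
        model = fit_mediator_model(
            coh, spec, "marginal_given_x", options=ModelOptions(saturated=True)
        )
        tab = pd.crosstab(coh.df.x, coh.df.m, normalize="index")
        for xv in (0, 1):
            row = model.probs[coh.df.x.to_numpy() == xv].iloc[0]
            for lev in MLEVELS:
                assert row[lev] == pytest.approx(tab.loc[xv, lev], abs=1e-12)

    def test_absent_level_error_names_level(self):
        coh = toy_cohort({"m": ["parental", "non_centre"] * 3, "x": [0, 1] * 3})
        spec = CausalSpec("x", "m", (), (), ())
        with pytest.raises(WeightEstimationError, match="centre"):
            fit_mediator_model(coh, spec, "marginal")


class TestWeightConstruction:
    def test_no_confounding_gives_unit_weights(self, small_cohort):
        """With empty adjustment sets the stabilization numerator equals the
        denominator and every analysis weight is exactly its design weight."""
        spec = CausalSpec("x", "m", (), (), ("y_ext",))
        dw = small_cohort.df.design_weight.to_numpy()
        for builder in (total_effect_weights, cde_weights):
            ws = builder(small_cohort, spec, "design_weight")
            np.testing.assert_allclose(ws.weights, dw, rtol=1e-9)
        # ATE weights cancel exactly when stabilized by the X-conditional margin
        ws = ate_weights(
            small_cohort, spec, "design_weight", stabilizer="marginal_given_x"
        )
        np.testing.assert_allclose(ws.weights, dw, rtol=1e-9)
        # with the marginal stabilizer they still average to the design weights
        ws_m = ate_weights(small_cohort, spec, "design_weight")
        assert ws_m.weights.mean() == pytest.approx(dw.mean(), abs=0.02)

    def test_product_contract(self, small_cohort, spec):
        ws = cde_weights(small_cohort, spec, "design_weight")
        prod = np.ones(small_cohort.n)
        for comp in ws.components.values():
            prod = prod * comp
        np.testing.assert_allclose(ws.weights, prod, rtol=1e-12)
        assert set(ws.components) == {"exposure_ipw", "mediator_ipw", "design"}

    def test_total_effect_weights_ignore_post_confounders(self, small_cohort, spec):
        """Permuting an L column leaves total-effect weights unchanged."""
        shuffled = small_cohort.copy()
        rng = np.random.default_rng(0)
        shuffled.df["l1"] = rng.permutation(shuffled.df["l1"].to_numpy())
        w0 = total_effect_weights(small_cohort, spec, "design_weight").weights
        w1 = total_effect_weights(shuffled, spec, "design_weight").weights
        np.testing.assert_allclose(w0, w1, rtol=1e-12)

    def test_stabilized_mean_near_one_within_groups(self, small_cohort, spec):
        ws = ate_weights(small_cohort, spec, "design_weight")
        m = small_cohort.df.m
        for lev in MLEVELS:
            assert ws.weights[(m == lev).to_numpy()].mean() == pytest.approx(
                1.0, abs=0.05
            )

    def test_outcome_columns_never_consulted(self, small_cohort, spec):
        """Weight construction must not read Y: corrupting outcomes changes nothing."""
        corrupted = small_cohort.copy()
        corrupted.df["y_ext"] = 1e6
        corrupted.df["y_voc"] = -1e6
        for builder in (ate_weights, total_effect_weights, cde_weights):
            w0 = builder(small_cohort, spec, "design_weight").weights
            w1 = builder(corrupted, spec, "design_weight").weights
            np.testing.assert_allclose(w0, w1, rtol=1e-12)

    def test_nonpositive_weights_rejected(self):
        with pytest.raises(WeightEstimationError):
            WeightSet("cde", np.array([1.0, 0.0]), {})
        with pytest.raises(WeightEstimationError):
            WeightSet("cde", np.array([1.0, np.inf]), {})


class TestTruncation:
    def test_full_range_is_identity(self):
        ws = WeightSet("cde", np.array([0.5, 1.0, 4.0]), {})
        out = truncate_weights(ws, 0, 100)
        np.testing.assert_allclose(out.weights, ws.weights)
        assert out.truncation is not None

    def test_constant_weights_unchanged_at_any_bounds(self):
        ws = WeightSet("cde", np.ones(10) * 2.0, {})
        out = truncate_weights(ws, 5, 95)
        np.testing.assert_allclose(out.weights, 2.0)

    def test_winsorizes_at_stated_percentile(self):
        ws = WeightSet("cde", np.array([1.0, 1, 1, 1, 100.0]), {})
        out = truncate_weights(ws, 0, 80)
        expected_cap = np.percentile(ws.weights, 80)
        assert out.weights.max() == pytest.approx(expected_cap)
        assert out.truncation[1] == pytest.approx(expected_cap)

    def test_crossed_percentiles_rejected(self):
        ws = WeightSet("cde", np.ones(3), {})
        with pytest.raises(ValueError):
            truncate_weights(ws, 60, 95)
        with pytest.raises(ValueError):
            truncate_weights(ws, 0, 40)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        st.lists(st.floats(0.01, 100.0), min_size=3, max_size=40),
        st.floats(0, 20),
        st.floats(80, 100),
    )
    def test_truncation_bounds_and_order_preserved(self, w, lo, hi):
        ws = WeightSet("cde", np.asarray(w), {})
        out = truncate_weights(ws, lo, hi)
        assert out.weights.min() >= ws.weights.min() - 1e-12
        assert out.weights.max() <= ws.weights.max() + 1e-12
        # winsorizing preserves the ordering of untied weights
        assert np.all(np.diff(out.weights[np.argsort(ws.weights)]) >= -1e-12)


class TestBalance:
    def test_uniform_weights_leave_smd_unchanged(self, small_cohort, spec):
        dw = small_cohort.df.design_weight.to_numpy()
        ws = WeightSet("total_effect", dw.copy(), {"design": dw})
        rep = balance_report(small_cohort, ws, spec)
        t = rep.table
        merged = t[t.stage == "weighted"].merge(
            t[t.stage == "unweighted"],
            on=["confounder", "contrast", "stratum"],
            suffixes=("_w", "_u"),
        )
        np.testing.assert_allclose(merged.smd_w, merged.smd_u, atol=1e-12)

    def test_constant_confounder_reports_zero_smd_with_flag(self, small_cohort):
        coh = small_cohort.copy()
        coh.df["c1"] = 1.0
        spec = CausalSpec("x", "m", ("c1", "c2"), ("l1",), ("y_ext",))
        ws = total_effect_weights(coh, spec, "design_weight")
        rep = balance_report(coh, ws, spec)
        c1_rows = rep.table[rep.table.confounder == "c1"]
        assert (c1_rows.smd == 0).all()
        assert c1_rows.zero_sd.all()

    def test_weighting_improves_balance_on_confounded_cohort(self, small_cohort, spec):
        ws = total_effect_weights(small_cohort, spec, "design_weight")
        rep = balance_report(small_cohort, ws, spec)
        t = rep.table[(t_strat := rep.table.stratum == "overall")]
        before = t[t.stage == "unweighted"].smd.abs().max()
        after = t[t.stage == "weighted"].smd.abs().max()
        assert after < before

    def test_mediator_balance_reported_within_exposure_strata(self, small_cohort, spec):
        ws = ate_weights(small_cohort, spec, "design_weight")
        rep = balance_report(small_cohort, ws, spec)
        assert {"overall", "x=0", "x=1"} <= set(rep.table.stratum.unique())
        assert set(rep.weight_summary["groups"]) == set(MLEVELS)
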