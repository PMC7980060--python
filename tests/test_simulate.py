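"""Synthetic cohort generator: determinism, calibration, design, MAR, truths."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit

from ipwmed import (
    apply_missingness,
    assign_design,
    default_config,
    generate_cohort,
    true_estimands,
)
from ipwmed.simulate import ConfigError, GeneratorConfig


class TestConfigValidation:
    @pytest.mark.parametrize(
        "overrides,fieldname",
        [
            ({"n": 0}, "n"),
            ({"missing_rate": 1.0}, "missing_rate"),
            ({"n_strata": 0}, "n_strata"),
            ({"oversample_ratio": 0.0}, "oversample_ratio"),
            ({"p_c1": 1.5}, "p_c1"),
            ({"exposure_prevalence": 0.0}, "exposure_prevalence"),
        ],
    )
    def test_invalid_config_names_field(self, overrides, fieldname):
        with pytest.raises(ConfigError, match=fieldname):
            default_config(**overrides).validate()

    def test_mediator_marginals_must_sum_to_one(self):
        with pytest.raises(ConfigError, match="sum to 1"):
            default_config(mediator_marginals=(0.5, 0.3, 0.3)).validate()


class TestDeterminism:
    def test_identical_seed_identical_cohort(self):
        cfg = default_config(n=100, seed=9)
        a = generate_cohort(cfg)
        b = generate_cohort(cfg)
        pd.testing.assert_frame_equal(a.df, b.df)

    def test_full_chain_deterministic(self):
        cfg = default_config(n=500, seed=9, missing_rate=0.1)
        runs = []
        for _ in range(2):
            coh = apply_missingness(assign_design(generate_cohort(cfg), cfg), cfg)
            runs.append(coh.df)
        pd.testing.assert_frame_equal(runs[0], runs[1])

    def test_different_seed_differs(self):
        a = generate_cohort(default_config(n=200, seed=1))
        b = generate_cohort(default_config(n=200, seed=2))
        assert not a.df.equals(b.df)


def test_null_model_makes_exposure_independent_of_confounders():
    cfg = default_config(
        n=30_000,
        seed=4,
        exposure_prevalence=0.5,
        coef_c_on_x=(("intercept", 0.0),),
    )
    coh = generate_cohort(cfg)
    assert coh.df.x.mean() == pytest.approx(0.5, abs=0.02)
    assert abs(np.corrcoef(coh.df.x, coh.df.c1)[0, 1]) < 0.02


def test_exposure_prevalence_calibrated_with_confounding():
    cfg = default_config(n=50_000, seed=4, attrition_model=None)
    coh = assign_design(generate_cohort(cfg), cfg)
    wprev = np.average(coh.df.x, weights=coh.df.design_weight)
    assert wprev == pytest.approx(0.54, abs=0.01)


class TestDesign:
    def test_design_weight_mean_one(self, small_cohort):
        assert small_cohort.df.design_weight.mean() == pytest.approx(1.0, abs=1e-6)

    def test_weighted_stratum_shares_recover_population(self):
        """2:1 oversampling of the disadvantaged stratum is undone by weighting."""
        cfg = default_config(n=40_000, seed=6, attrition_model=None)
        coh = assign_design(generate_cohort(cfg), cfg)
        df, w = coh.df, coh.df.design_weight
        raw_share = (df.stratum == 1).mean()
        w_share = np.average((df.stratum == 1), weights=w)
        assert raw_share == pytest.approx(2 / 3, abs=0.02)  # oversampled
        assert w_share == pytest.approx(0.5, abs=0.02)  # population
        # weighted disadvantage prevalence recovers the population value
        assert np.average(df.c2, weights=w) == pytest.approx(
            cfg.p_c2_population, abs=0.01
        )

    def test_degenerate_design_is_simple_random_sample(self):
        cfg = default_config(
            n=5_000, seed=6, n_strata=1, clusters_per_stratum=1,
            attrition_model=None, cluster_sd=0.0,
        )
        coh = assign_design(generate_cohort(cfg), cfg)
        assert (coh.df.design_weight == 1.0).all()
        assert np.average(coh.df.y_ext, weights=coh.df.design_weight) == pytest.approx(
            coh.df.y_ext.mean()
        )

    def test_clusters_nest_within_strata(self, small_cohort):
        assert small_cohort.validate() == []

    def test_attrition_drops_rows_and_reweights(self):
        cfg = default_config(n=20_000, seed=8)
        coh = assign_design(generate_cohort(cfg), cfg)
        assert coh.n < cfg.n  # nonrespondents removed
        assert coh.df.design_weight.mean() == pytest.approx(1.0, abs=1e-9)
        # attrition depends on exposure, so respondents are selected; weighting
        # still recovers the population exposure prevalence
        assert np.average(coh.df.x, weights=coh.df.design_weight) == pytest.approx(
            0.54, abs=0.015
        )


class TestMissingness:
    def test_zero_rate_is_identity(self, small_cohort, small_config):
        cfg = dataclasses.replace(small_config, missing_rate=0.0)
        out = apply_missingness(small_cohort, cfg)
        pd.testing.assert_frame_equal(out.df, small_cohort.df)

    def test_masked_fraction_matches_rate(self):
        cfg = default_config(n=14_376, seed=3, missing_rate=0.05)
        coh = assign_design(generate_cohort(cfg), cfg)
        out = apply_missingness(coh, cfg)
        se = np.sqrt(0.05 * 0.95 / out.n)
        for col in ("m", "l1", "y_ext", "c3"):
            assert out.df[col].isna().mean() == pytest.approx(0.05, abs=2 * se)

    def test_exposure_and_design_columns_never_masked(self):
        cfg = default_config(n=5_000, seed=3, missing_rate=0.3)
        out = apply_missingness(assign_design(generate_cohort(cfg), cfg), cfg)
        for col in ("x", "stratum", "cluster", "design_weight"):
            assert out.df[col].notna().all()

    def test_mar_contract_missingness_independent_of_value(self):
        """Given the always-observed predictors, masking ignores the true value:
        the true value's coefficient in a missingness model is ~0."""
        cfg = default_config(n=40_000, seed=13, missing_rate=0.10)
        coh = assign_design(generate_cohort(cfg), cfg)
        out = apply_missingness(coh, cfg)
        miss = out.df.y_ext.isna().astype(float)
        X = sm.add_constant(
            pd.DataFrame(
                {
                    "true_value": coh.df.y_ext,
                    "x": coh.df.x,
                    "disadv": (coh.df.stratum == 1).astype(float),
                }
            )
        )
        res = sm.GLM(miss, X, family=sm.families.Binomial()).fit()
        z = res.params["true_value"] / res.bse["true_value"]
        assert abs(z) < 3.0


class TestTrueEstimands:
    def test_no_interaction_gives_equal_cdes(self):
        te = true_estimands(default_config())
        cdes = te.cde["y_voc"]  # y_voc has no exposure-mediator interaction
        assert cdes["parental"] == pytest.approx(cdes["centre"], abs=1e-12)
        assert cdes["parental"] == pytest.approx(cdes["non_centre"], abs=1e-12)

    def test_closed_form_without_x_to_l_path(self):
        """With no X->L path the CDE is exactly coef_x + interaction."""
        cfg = default_config(
            coef_on_l1=(("intercept", -1.0), ("c1", 0.3), ("c2", 0.4)),
            coef_on_l2=(("intercept", 0.0), ("c1", 0.1), ("sd", 1.0)),
        )
        te = true_estimands(cfg, n_mc=10_000)
        assert te.cde["y_ext"]["parental"] == pytest.approx(0.15, abs=1e-10)
        assert te.cde["y_ext"]["centre"] == pytest.approx(0.02, abs=1e-10)

    def test_default_cde_targets_hit_exactly(self):
        te = true_estimands(default_config())
        assert te.cde["y_ext"]["parental"] == pytest.approx(0.15, abs=1e-4)
        assert te.cde["y_ext"]["centre"] == pytest.approx(0.02, abs=1e-4)

    def test_enumeration_matches_independent_brute_force(self, discrete_config):
        """CDE with an active X->L->Y path equals a hand-rolled expectation
        over the discrete confounder support: coef_x + gamma_l1 * E_C[dP(L1)]."""
        cfg = discrete_config
        te = true_estimands(cfg)  # enumeration path
        l1b = dict(cfg.coef_on_l1)
        spec_ext = dict(cfg.outcomes)["y_ext"]
        gamma_l1 = dict(spec_ext.coef_l)["l1"]
        d = 0.0
        p_pop = cfg.p_c2_population
        for c1 in (0, 1):
            for c2 in (0, 1):
                pc = (cfg.p_c1 if c1 else 1 - cfg.p_c1) * (p_pop if c2 else 1 - p_pop)
                eta = l1b["intercept"] + l1b["c1"] * c1 + l1b["c2"] * c2
                d += pc * (expit(eta + l1b["x"]) - expit(eta))
        assert gamma_l1 * d != pytest.approx(0.0, abs=1e-4)  # path really open
        expected_parental = spec_ext.coef_x + gamma_l1 * d
        expected_centre = expected_parental + dict(spec_ext.interaction)["centre"]
        assert te.cde["y_ext"]["parental"] == pytest.approx(expected_parental, abs=1e-12)
        assert te.cde["y_ext"]["centre"] == pytest.approx(expected_centre, abs=1e-12)

    def test_enumeration_and_monte_carlo_agree(self, discrete_config):
        enum = true_estimands(discrete_config, method="enumeration")
        mc = true_estimands(discrete_config, method="monte_carlo", n_mc=400_000)
        for y in ("y_ext", "y_voc"):
            assert mc.total_effect[y] == pytest.approx(enum.total_effect[y], abs=2e-3)
            for lev, v in enum.cde[y].items():
                assert mc.cde[y][lev] == pytest.approx(v, abs=2e-3)
            for lev, v in enum.ate[y].items():
                assert mc.ate[y][lev] == pytest.approx(v, abs=2e-3)

    def test_enumeration_refused_for_continuous_config(self):
        with pytest.raises(ConfigError):
            true_estimands(default_config(), method="enumeration")


def test_mediator_levels_are_the_three_declared(small_cohort):
    assert set(small_cohort.df.m.unique()) <= {"parental", "non_centre", "centre"}


def test_serialization_roundtrip(tmp_path, small_cohort):
    small_cohort.to_files(tmp_path / "c.csv", tmp_path / "d.yaml")
    from ipwmed import CohortTable

    back = CohortTable.from_files(tmp_path / "c.csv", tmp_path / "d.yaml")
    assert back.n == small_cohort.n
    assert back.validate() == []
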