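"""Simulation studies validating the estimation pipeline end to end.

These routines run the package against its own synthetic-data generator under
the study conditions (cohort sizes, replicate counts, missingness rates) and
summarize how well each estimand is recovered:

* :func:`oracle_study` — exact-agreement check of every weighted estimator
  against enumeration g-formula values on a fully discrete population table;
* :func:`recovery_study` — replicate bias / coverage / attenuation for the
  ATE, total-effect and CDE estimators at the default study size;
* :func:`balance_study` — post-weighting confounder balance and stabilized
  weight means on a large confounded cohort;
* :func:`mi_study` — Rubin pooling worked example plus the end-to-end
  imputation-vs-complete-data comparison;
* :func:`variance_study` — linearized sandwich vs HC0 and vs the stratified
  cluster bootstrap;
* :func:`calibration_study` — design-weighted mediator marginals and exposure
  prevalence of the default generator.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import patsy
import statsmodels.api as sm

from .cohort import CausalSpec
from .design import DesignSpec, cluster_bootstrap_cov, robust_variance
from .effects import (
    estimate_ate,
    estimate_total_effect,
    fit_msm_cde,
)
from .mice import EffectEstimate, ImputationConfig, impute, pool
from .simulate import (
    GeneratorConfig,
    OutcomeSpec,
    apply_missingness,
    assign_design,
    default_causal_spec,
    default_config,
    generate_cohort,
    population_table,
    true_estimands,
)
from .weights import (
    ModelOptions,
    ate_weights,
    balance_report,
    cde_weights,
    total_effect_weights,
)

_Z = 1.96


def discrete_oracle_config() -> GeneratorConfig:
    """Fully discrete generator (binary C, binary L) with explicit coefficients."""
    return default_config(
        include_c3=False,
        include_l2=False,
        exposure_prevalence=0.5,
        mediator_marginals=None,
        coef_c_on_x=(("intercept", 0.0), ("c1", 0.7), ("c2", -0.5)),
        coef_on_l1=(("intercept", -1.0), ("x", 0.6), ("c1", 0.3), ("c2", 0.4)),
        coef_on_m_non_centre=(
            ("intercept", 0.2), ("x", -0.4), ("c1", -0.3), ("c2", 0.2), ("l1", -0.3),
        ),
        coef_on_m_centre=(
            ("intercept", -0.1), ("x", -0.6), ("c1", -0.5), ("c2", 0.3), ("l1", -0.4),
        ),
        outcomes=(
            (
                "y_ext",
                OutcomeSpec(
                    coef_x=0.12,
                    coef_m=(("non_centre", -0.03), ("centre", -0.08)),
                    interaction=(("centre", -0.10),),
                    coef_c=(("c1", 0.10), ("c2", 0.25)),
                    coef_l=(("l1", 0.25),),
                ),
            ),
            (
                "y_voc",
                OutcomeSpec(
                    coef_x=-0.25,
                    coef_m=(("non_centre", 0.10), ("centre", 0.03)),
                    coef_c=(("c1", -0.10), ("c2", -0.20)),
                    coef_l=(("l1", -0.10),),
                ),
            ),
        ),
    )


def _all_estimates(cohort, spec, design, scenarios=("parental", "centre")):
    """ATE + total-effect + CDE estimates keyed by (estimand, outcome, detail)."""
    wcol = design.weight_col if design is not None else None
    out: dict[tuple, EffectEstimate] = {}
    aw = ate_weights(cohort, spec, wcol)
    for e in estimate_ate(cohort, aw, spec, design):
        out[("ate", e.outcome, e.contrast.split(" ")[0])] = e
    tw = total_effect_weights(cohort, spec, wcol)
    for e in estimate_total_effect(cohort, tw, spec, design):
        out[("te", e.outcome, "")] = e
    cw = cde_weights(cohort, spec, wcol)
    for e in fit_msm_cde(cohort, cw, spec, design, scenarios=scenarios):
        out[("cde", e.outcome, e.scenario)] = e
    return out


# --------------------------------------------------------------------------


def oracle_study(config: GeneratorConfig | None = None) -> dict:
    """Saturated IPW analyses of the exact population table vs enumeration."""
    config = config or discrete_oracle_config()
    spec = default_causal_spec(config)
    pop = population_table(config)
    truth = true_estimands(config)
    opts = ModelOptions(saturated=True)
    errs = []

    aw = ate_weights(pop, spec, "design_weight", opts)
    for e in estimate_ate(pop, aw, spec):
        errs.append(abs(e.point - truth.ate[e.outcome][e.contrast.split(" ")[0]]))
    tw = total_effect_weights(pop, spec, "design_weight", opts)
    for e in estimate_total_effect(pop, tw, spec):
        errs.append(abs(e.point - truth.total_effect[e.outcome]))
    cw = cde_weights(pop, spec, "design_weight", opts)
    for e in fit_msm_cde(pop, cw, spec, scenarios=("parental", "non_centre", "centre")):
        errs.append(abs(e.point - truth.cde[e.outcome][e.scenario]))
    return {"max_abs_error": float(max(errs)), "n_checks": len(errs)}


def recovery_study(
    n_reps: int = 200, n: int = 20_000, seed: int = 0
) -> dict:
    """Replicate bias, CI coverage and the scenario-attenuation pattern."""
    base = default_config(n=n, missing_rate=0.0)
    spec = default_causal_spec(base)
    design = DesignSpec()
    truth = true_estimands(base)

    keys: list[tuple] = []
    tvals: list[float] = []
    for y in base.outcome_names:
        for lev in ("non_centre", "centre"):
            keys.append(("ate", y, lev))
            tvals.append(truth.ate[y][lev])
        keys.append(("te", y, ""))
        tvals.append(truth.total_effect[y])
        for lev in ("parental", "centre"):
            keys.append(("cde", y, lev))
            tvals.append(truth.cde[y][lev])
    tarr = np.asarray(tvals)

    points = np.empty((n_reps, len(keys)))
    ses = np.empty_like(points)
    for r in range(n_reps):
        cfg = dataclasses.replace(base, seed=seed + 7919 * (r + 1))
        cohort = assign_design(generate_cohort(cfg), cfg)
        ests = _all_estimates(cohort, spec, design)
        for j, k in enumerate(keys):
            points[r, j] = ests[k].point
            ses[r, j] = ests[k].se

    bias = points.mean(axis=0) - tarr
    covered = (points - _Z * ses <= tarr) & (tarr <= points + _Z * ses)
    i_par = keys.index(("cde", "y_ext", "parental"))
    i_cen = keys.index(("cde", "y_ext", "centre"))
    return {
        "keys": ["/".join(map(str, k)).rstrip("/") for k in keys],
        "bias": bias.tolist(),
        "max_abs_bias": float(np.abs(bias).max()),
        "coverage_by_estimand": covered.mean(axis=0).tolist(),
        "coverage_pooled": float(covered.mean()),
        "attenuation_fraction": float(
            (points[:, i_cen] < points[:, i_par]).mean()
        ),
        "replicate_sd": points.std(axis=0).tolist(),
        "n": n,
        "n_reps": n_reps,
    }


def balance_study(n: int = 50_000, seed: int = 0) -> dict:
    """Post-weighting balance and stabilized-weight means on the default cohort."""
    cfg = default_config(n=n, seed=seed + 104_729, missing_rate=0.0)
    spec = default_causal_spec(cfg)
    cohort = assign_design(generate_cohort(cfg), cfg)
    wcol = "design_weight"

    out = {"n": int(cohort.n)}
    max_smd = 0.0
    max_mean_dev = 0.0
    for builder, label in ((ate_weights, "ate"), (total_effect_weights, "total_effect")):
        ws = builder(cohort, spec, wcol)
        rep = balance_report(cohort, ws, spec, wcol)
        t = rep.table
        overall = t[(t.stratum == "overall") & (t.stage == "weighted")]
        before = t[(t.stratum == "overall") & (t.stage == "unweighted")]
        out[f"{label}_max_abs_smd_weighted"] = float(overall.smd.abs().max())
        out[f"{label}_max_abs_smd_unweighted"] = float(before.smd.abs().max())
        for g, s in rep.weight_summary["groups"].items():
            # stabilized mean: IPW component only (design weights average 1)
            treat = (
                cohort.df[spec.mediator].astype(str)
                if ws.estimand == "ate_mediator"
                else cohort.df[spec.exposure].astype(int).astype(str)
            )
            comp = [v for k, v in ws.components.items() if k.endswith("_ipw")][0]
            dev = abs(float(comp[(treat == g).to_numpy()].mean()) - 1.0)
            max_mean_dev = max(max_mean_dev, dev)
        max_smd = max(max_smd, out[f"{label}_max_abs_smd_weighted"])
    out["max_abs_smd_weighted"] = max_smd
    out["stabilized_mean_max_abs_dev"] = max_mean_dev
    return out


def mi_study(n: int = 20_000, m: int = 25, seed: int = 0) -> dict:
    """Rubin worked example and pooled-vs-complete-data comparison under MAR."""
    # hand-checkable worked example: points 1,2,3 with unit within-variance
    runs = [
        [EffectEstimate("cde", "x=1 vs x=0", "centre", "y", p, 1.0, df=np.inf)]
        for p in (1.0, 2.0, 3.0)
    ]
    worked = pool(runs)[0]

    cfg = default_config(n=n, seed=seed + 15_485_863, missing_rate=0.05)
    spec = default_causal_spec(cfg)
    design = DesignSpec()
    complete = assign_design(generate_cohort(cfg), cfg)
    masked = apply_missingness(complete, cfg)
    comp = _all_estimates(complete, spec, design)
    datasets = impute(masked, ImputationConfig(m=m, iterations=10, seed=seed + 11))
    per_imp = [list(_all_estimates(ds, spec, design).values()) for ds in datasets]
    pooled = pool(per_imp)
    comp_list = list(comp.values())
    shifts = [abs(p.point - c.point) for p, c in zip(pooled, comp_list)]
    return {
        "worked_example": {
            "point": worked.point,
            "within_var": worked.within_var,
            "between_var": worked.between_var,
            "total_var": worked.total_var,
        },
        "max_abs_shift": float(max(shifts)),
        "n": n,
        "m": m,
    }


def variance_study(n: int = 20_000, n_boot: int = 500, seed: int = 0) -> dict:
    """Linearized sandwich vs HC0 (iid case) and vs the cluster bootstrap."""
    # iid case: one-person clusters, flat weights
    rng = np.random.default_rng(seed + 33)
    n_iid = 2_000
    X = np.column_stack([np.ones(n_iid), rng.standard_normal(n_iid)])
    y = X @ [0.2, 0.5] + rng.standard_normal(n_iid) * (1 + 0.4 * np.abs(X[:, 1]))
    res = sm.OLS(y, X).fit(cov_type="HC0")
    cov, _ = robust_variance(
        X, y - X @ res.params, np.ones(n_iid), np.zeros(n_iid, int), np.arange(n_iid)
    )
    hc0 = np.asarray(res.cov_params())
    rel = np.abs(np.sqrt(np.diag(cov)) - np.sqrt(np.diag(hc0))) / np.sqrt(np.diag(hc0))

    # default two-stage design: bootstrap the MSM CDE(parental) standard error
    cfg = default_config(n=n, seed=seed + 86_028_121, missing_rate=0.0)
    spec = default_causal_spec(cfg)
    design = DesignSpec()
    cohort = assign_design(generate_cohort(cfg), cfg)
    ws = cde_weights(cohort, spec, design.weight_col)
    est = [
        e
        for e in fit_msm_cde(cohort, ws, spec, design, scenarios=("parental",))
        if e.outcome == "y_ext"
    ][0]
    df = cohort.df.copy()
    df["_w"] = ws.weights
    formula = f"y_ext ~ {spec.exposure} * C({spec.mediator}, Treatment('parental'))"

    def fit_params(d):
        yv, Xv = patsy.dmatrices(formula, d, return_type="dataframe")
        Xm = Xv.to_numpy()
        w = d["_w"].to_numpy()
        xtw = Xm.T * w
        beta = np.linalg.solve(xtw @ Xm, xtw @ yv.to_numpy().ravel())
        return beta[Xv.design_info.column_names.index(spec.exposure)]

    boot = cluster_bootstrap_cov(fit_params, df, design, n_boot=n_boot, seed=seed + 5)
    boot_se = float(np.sqrt(np.atleast_2d(boot)[0, 0]))
    return {
        "iid_max_rel_se_diff": float(rel.max()),
        "linearized_se": est.se,
        "bootstrap_se": boot_se,
        "bootstrap_over_linearized": boot_se / est.se,
        "n": n,
        "n_boot": n_boot,
    }


def calibration_study(n: int = 14_376, seed: int = 0) -> dict:
    """Design-weighted mediator marginals and exposure prevalence at study size."""
    cfg = default_config(n=n, seed=seed + 49_979_687)
    cohort = assign_design(generate_cohort(cfg), cfg)
    df, w = cohort.df, cohort.df.design_weight.to_numpy()
    shares = {
        lev: float(np.average((df.m == lev).to_numpy(float), weights=w))
        for lev in ("parental", "non_centre", "centre")
    }
    return {
        "mediator_marginals_pct": {k: 100 * v for k, v in shares.items()},
        "exposure_prevalence_pct": float(100 * np.average(df.x, weights=w)),
        "n": n,
    }
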