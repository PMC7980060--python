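"""Weighted outcome models and the three causal estimands.

All estimands are read off weighted least-squares fits with cluster-robust
(stratified sandwich) variances:

* ATE of the 3-level childcare mediator: Y ~ mediator dummies, under
  stabilized mediator weights — centre-vs-parental and non-centre-vs-parental
  contrasts per outcome;
* total effect of the exposure: Y ~ X under stabilized exposure weights
  adjusting pre-exposure confounders only;
* controlled direct effects: the marginal structural model
  Y ~ X + mediator + X:mediator under product weights, with
  CDE(m) = beta_X + beta_{X:m} evaluated at each scenario level (scenario 1 =
  universal centre-based care, scenario 2 = parental care only).

Effects are reported in the outcome's analysis scale; outcomes may first be
standardized to design-weighted unit SD so estimates read as SD differences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy

from .cohort import CausalSpec, CohortTable
from .design import DesignSpec, robust_variance
from .weights import ModelOptions, WeightSet, ate_weights, cde_weights, total_effect_weights

logger = logging.getLogger("ipwmed")

Z95 = 1.96


class EstimationError(RuntimeError):
    pass


@dataclass(frozen=True)
class EffectEstimate:
    """One causal contrast for one outcome."""

    estimand: str  # ate_mediator | total_effect | cde
    contrast: str  # e.g. "centre vs parental", "x=1 vs x=0"
    scenario: str  # mediator scenario level, or "n/a"
    outcome: str
    point: float
    se: float
    ci_low: float = field(default=np.nan)
    ci_high: float = field(default=np.nan)
    scale_factor: float = 1.0
    n_effective: float = np.nan
    df: float = np.nan

    def __post_init__(self):
        if np.isnan(self.ci_low):
            object.__setattr__(self, "ci_low", self.point - Z95 * self.se)
        if np.isnan(self.ci_high):
            object.__setattr__(self, "ci_high", self.point + Z95 * self.se)


def estimates_to_frame(estimates: list[EffectEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "estimand": e.estimand,
                "contrast": e.contrast,
                "scenario": e.scenario,
                "outcome": e.outcome,
                "point": e.point,
                "se": e.se,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "scale_factor": e.scale_factor,
                "n_effective": e.n_effective,
            }
            for e in estimates
        ]
    )


# --------------------------------------------------------------------------
# outcome standardization
# --------------------------------------------------------------------------


def standardize_outcomes(
    cohort: CohortTable,
    spec: CausalSpec,
    weight_col: str | None = None,
    center: bool = True,
    scale_factor: float = 1.0,
) -> CohortTable:
    """Rescale each outcome to design-weighted unit SD (optionally centered).

    ``scale_factor`` further multiplies the standardized outcome (x100
    mimics percent-of-SD reporting magnitudes).
    """
    out = cohort.copy()
    cols = out.columns_with_role("design_weight")
    wname = weight_col or (cols[0] if cols else None)
    w = (
        out.df[wname].to_numpy(float)
        if wname and wname in out.df.columns
        else np.ones(out.n)
    )
    for y in spec.outcomes:
        v = out.df[y].to_numpy(float)
        ok = ~np.isnan(v)
        mean = np.average(v[ok], weights=w[ok])
        sd = np.sqrt(np.average((v[ok] - mean) ** 2, weights=w[ok]))
        if sd == 0 or not np.isfinite(sd):
            raise EstimationError(f"outcome {y!r} has zero weighted SD")
        out.df[y] = (v - (mean if center else 0.0)) / sd * scale_factor
    return out


# --------------------------------------------------------------------------
# weighted least squares with survey variance
# --------------------------------------------------------------------------


def _wls(
    df: pd.DataFrame,
    formula: str,
    w: np.ndarray,
    design: DesignSpec | None,
):
    y, X = patsy.dmatrices(formula, df, return_type="dataframe")
    yv = y.to_numpy(float).ravel()
    Xv = X.to_numpy(float)
    xtw = Xv.T * w
    beta = np.linalg.solve(xtw @ Xv, xtw @ yv)
    resid = yv - Xv @ beta
    if design is not None:
        stratum = df[design.stratum_col].to_numpy()
        cluster = df[design.cluster_col].to_numpy()
    else:
        stratum = np.zeros(len(df), dtype=int)
        cluster = np.arange(len(df))
    cov, dof = robust_variance(Xv, resid, w, stratum, cluster)
    names = list(X.design_info.column_names)
    n_eff = float(w.sum() ** 2 / (w**2).sum())
    return beta, cov, names, dof, n_eff


def _contrast(beta, cov, names, terms: dict[str, float]):
    L = np.zeros(len(names))
    for t, c in terms.items():
        if t not in names:
            raise EstimationError(f"model term {t!r} not found among {names}")
        L[names.index(t)] = c
    point = float(L @ beta)
    se = float(np.sqrt(L @ cov @ L))
    return point, se


def _mediator_term(spec: CausalSpec) -> str:
    return f"C({spec.mediator}, Treatment('{spec.mediator_reference}'))"


# --------------------------------------------------------------------------
# estimators
# --------------------------------------------------------------------------


def estimate_ate(
    cohort: CohortTable,
    ws: WeightSet,
    spec: CausalSpec,
    design: DesignSpec | None = None,
    scale_factor: float = 1.0,
) -> list[EffectEstimate]:
    """ATE of each non-reference mediator level vs parental care, per outcome."""
    if ws.estimand != "ate_mediator":
        raise EstimationError(f"expected ate_mediator weights, got {ws.estimand}")
    df = cohort.df
    m = df[spec.mediator].astype(str)
    for lev in spec.mediator_levels:
        if ws.weights[(m == lev).to_numpy()].sum() <= 0:
            raise EstimationError(f"mediator level {lev!r} empty after weighting")
    mt = _mediator_term(spec)
    out = []
    for y in spec.outcomes:
        beta, cov, names, dof, n_eff = _wls(df, f"{y} ~ {mt}", ws.weights, design)
        for lev in spec.nonreference_levels:
            point, se = _contrast(beta, cov, names, {f"{mt}[T.{lev}]": 1.0})
            out.append(
                EffectEstimate(
                    "ate_mediator",
                    f"{lev} vs {spec.mediator_reference}",
                    "n/a",
                    y,
                    point,
                    se,
                    scale_factor=scale_factor,
                    n_effective=n_eff,
                    df=dof,
                )
            )
    return out


def estimate_total_effect(
    cohort: CohortTable,
    ws: WeightSet,
    spec: CausalSpec,
    design: DesignSpec | None = None,
    scale_factor: float = 1.0,
) -> list[EffectEstimate]:
    """Total effect of the exposure (all pathways open), per outcome."""
    if ws.estimand != "total_effect":
        raise EstimationError(f"expected total_effect weights, got {ws.estimand}")
    df = cohort.df
    out = []
    for y in spec.outcomes:
        beta, cov, names, dof, n_eff = _wls(
            df, f"{y} ~ {spec.exposure}", ws.weights, design
        )
        point, se = _contrast(beta, cov, names, {spec.exposure: 1.0})
        out.append(
            EffectEstimate(
                "total_effect",
                f"{spec.exposure}=1 vs {spec.exposure}=0",
                "n/a",
                y,
                point,
                se,
                scale_factor=scale_factor,
                n_effective=n_eff,
                df=dof,
            )
        )
    return out


def fit_msm_cde(
    cohort: CohortTable,
    ws: WeightSet,
    spec: CausalSpec,
    design: DesignSpec | None = None,
    scale_factor: float = 1.0,
    scenarios: tuple[str, ...] | None = None,
) -> list[EffectEstimate]:
    """Controlled direct effects from the exposure-by-mediator MSM.

    CDE(m) = beta_X + beta_{X:m}, with beta_{X:reference} = 0 by coding; the
    variance uses the full cluster-robust coefficient covariance.
    """
    if ws.estimand != "cde":
        raise EstimationError(f"expected cde weights, got {ws.estimand}")
    df = cohort.df
    scenarios = tuple(scenarios or spec.scenario_levels)
    cells = pd.crosstab(df[spec.exposure], df[spec.mediator].astype(str))
    for xv in (0, 1):
        for lev in spec.mediator_levels:
            if xv not in cells.index or lev not in cells.columns or cells.loc[xv, lev] == 0:
                raise EstimationError(
                    f"empty exposure-mediator cell ({spec.exposure}={xv}, "
                    f"{spec.mediator}={lev!r})"
                )
    mt = _mediator_term(spec)
    out = []
    for y in spec.outcomes:
        beta, cov, names, dof, n_eff = _wls(
            df, f"{y} ~ {spec.exposure} * {mt}", ws.weights, design
        )
        for lev in scenarios:
            terms = {spec.exposure: 1.0}
            if lev != spec.mediator_reference:
                terms[f"{spec.exposure}:{mt}[T.{lev}]"] = 1.0
            point, se = _contrast(beta, cov, names, terms)
            out.append(
                EffectEstimate(
                    "cde",
                    f"{spec.exposure}=1 vs {spec.exposure}=0",
                    lev,
                    y,
                    point,
                    se,
                    scale_factor=scale_factor,
                    n_effective=n_eff,
                    df=dof,
                )
            )
    return out


# --------------------------------------------------------------------------
# question-level orchestration
# --------------------------------------------------------------------------


def run_question(
    cohort: CohortTable,
    spec: CausalSpec,
    question: int,
    design: DesignSpec | None = None,
    options: ModelOptions = ModelOptions(),
    scale_factor: float = 1.0,
    stabilizer: str = "marginal",
) -> list[EffectEstimate]:
    """Run one research question's estimation stage.

    Question 1: ATEs of childcare.  Question 2: total effects plus CDEs under
    universal centre-based care.  Question 3: total effects plus CDEs under
    parental care only.
    """
    wcol = design.weight_col if design is not None else None
    if question == 1:
        ws = ate_weights(cohort, spec, wcol, options, stabilizer=stabilizer)
        logger.info("question 1 weights: %s", ws.summary())
        return estimate_ate(cohort, ws, spec, design, scale_factor)
    if question in (2, 3):
        scenario = "centre" if question == 2 else "parental"
        ws_te = total_effect_weights(cohort, spec, wcol, options)
        ws_cde = cde_weights(cohort, spec, wcol, options)
        logger.info("question %d weights: %s / %s", question, ws_te.summary(), ws_cde.summary())
        ests = estimate_total_effect(cohort, ws_te, spec, design, scale_factor)
        ests += fit_msm_cde(
            cohort, ws_cde, spec, design, scale_factor, scenarios=(scenario,)
        )
        return ests
    raise ValueError("question must be 1, 2 or 3")
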