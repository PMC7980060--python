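"""Stabilized inverse-probability weights and covariate balance diagnostics.

Three weight families are built here, one per estimand:

* ``ate_weights`` — stabilized mediator weights P(M=m) / P(M=m | X, C, L) for
  average treatment effects of the 3-level childcare mediator;
* ``total_effect_weights`` — stabilized exposure weights P(X=x) / P(X=x | C),
  adjusting pre-exposure confounders only (post-exposure pathways are part of
  the total effect and must stay open);
* ``cde_weights`` — the product of an exposure factor P(X=x)/P(X=x|C) and a
  mediator factor P(M=m|X)/P(M=m|X,C,L), feeding the marginal structural
  model from which controlled direct effects are read off.

Design/attrition weights multiply into every analysis weight and are used as
fitting weights for all propensity models.  Balance is assessed with
standardized mean differences before and after weighting, overall and within
exposure strata.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm

from .cohort import CausalSpec, CohortTable

_PROB_FLOOR = 1e-10


class WeightEstimationError(RuntimeError):
    pass


@dataclass(frozen=True)
class ModelOptions:
    """Options for one propensity model.

    ``formula`` overrides the default main-effects right-hand side;
    ``saturated`` estimates conditional probabilities by weighted cell
    proportions (exact for fully discrete predictors); ``ridge`` > 0 enables
    an L2 penalty for separated fits; ``clip`` bounds fitted probabilities
    away from 0/1.  Penalization and clipping are off unless configured.
    """

    formula: str | None = None
    saturated: bool = False
    ridge: float = 0.0
    clip: float | None = None


@dataclass
class WeightSet:
    """Per-person analysis weights with their named component factors."""

    estimand: str  # ate_mediator | total_effect | cde
    weights: np.ndarray
    components: dict[str, np.ndarray]
    truncation: tuple[float, float] | None = None

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if not np.all(np.isfinite(w)) or np.any(w <= 0):
            raise WeightEstimationError(
                f"{self.estimand} weights must be strictly positive and finite"
            )
        self.weights = w

    def summary(self, groups: pd.Series | None = None) -> dict:
        def stats(w):
            return {
                "mean": float(np.mean(w)),
                "max": float(np.max(w)),
                "p99": float(np.percentile(w, 99)),
            }

        out = {"overall": stats(self.weights), "estimand": self.estimand}
        if groups is not None:
            g = pd.Series(np.asarray(groups))
            for name, idx in g.groupby(g).groups.items():
                out[str(name)] = stats(self.weights[np.asarray(idx)])
        return out


def truncate_weights(ws: WeightSet, lower_pct: float, upper_pct: float) -> WeightSet:
    """Winsorize analysis weights at the given percentiles (default pipeline
    behaviour is no truncation)."""
    if not (0 <= lower_pct < 50):
        raise ValueError("lower_pct must be in [0, 50)")
    if not (50 < upper_pct <= 100):
        raise ValueError("upper_pct must be in (50, 100]")
    lo, hi = np.percentile(ws.weights, [lower_pct, upper_pct])
    return WeightSet(
        estimand=ws.estimand,
        weights=np.clip(ws.weights, lo, hi),
        components=ws.components,
        truncation=(float(lo), float(hi)),
    )


# --------------------------------------------------------------------------
# model fitting
# --------------------------------------------------------------------------


def _base_weights(cohort: CohortTable, weight_col: str | None) -> np.ndarray:
    if weight_col is None:
        cols = cohort.columns_with_role("design_weight")
        weight_col = cols[0] if cols else None
    if weight_col is None or weight_col not in cohort.df.columns:
        return np.ones(cohort.n)
    w = cohort.df[weight_col].to_numpy(float)
    if np.any(~np.isfinite(w)) or np.any(w <= 0):
        raise WeightEstimationError(f"design weight column {weight_col!r} not positive")
    return w


def _rhs_terms(cohort: CohortTable, cols: tuple[str, ...]) -> list[str]:
    terms = []
    for c in cols:
        d = cohort.dictionary.get(c)
        if d is not None and d.vtype == "categorical":
            terms.append(f"C({c})")
        else:
            terms.append(c)
    return terms


def _predictor_matrix(
    cohort: CohortTable, cols: tuple[str, ...], options: ModelOptions
) -> pd.DataFrame:
    rhs = options.formula or " + ".join(_rhs_terms(cohort, cols)) or "1"
    mat = patsy.dmatrix(rhs, cohort.df, return_type="dataframe")
    return mat.drop(columns=[c for c in mat.columns if c == "Intercept"])


def _check_complete(cohort: CohortTable, cols) -> None:
    bad = [c for c in cols if cohort.df[c].isna().any()]
    if bad:
        raise WeightEstimationError(
            f"columns {bad} contain missing values; impute before weighting"
        )


def _finalize_probs(p: np.ndarray, options: ModelOptions, what: str) -> np.ndarray:
    if options.clip is not None:
        p = np.clip(p, options.clip, 1 - options.clip)
    if np.any(p <= _PROB_FLOOR) or np.any(p >= 1 - _PROB_FLOOR):
        raise WeightEstimationError(
            f"{what}: fitted probabilities at 0/1 suggest separation; "
            "enable ridge penalization or probability clipping via ModelOptions"
        )
    return p


@dataclass
class ExposureModel:
    """Fitted P(X=1 | predictors) with its stabilization marginal."""

    prob1: np.ndarray
    marginal_p1: float

    def prob_of(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return np.where(x == 1.0, self.prob1, 1.0 - self.prob1)

    def marginal_of(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return np.where(x == 1.0, self.marginal_p1, 1.0 - self.marginal_p1)


def fit_exposure_model(
    cohort: CohortTable,
    spec: CausalSpec,
    weight_col: str | None = None,
    options: ModelOptions = ModelOptions(),
) -> ExposureModel:
    """Main-effects logistic model for the binary exposure given C."""
    bw = _base_weights(cohort, weight_col)
    x = cohort.df[spec.exposure].to_numpy(float)
    if set(np.unique(x)) - {0.0, 1.0}:
        raise WeightEstimationError(f"exposure {spec.exposure!r} is not binary 0/1")
    cols = spec.confounders_pre
    _check_complete(cohort, (spec.exposure, *cols))
    marginal = float(np.average(x, weights=bw))

    if not cols:
        p1 = np.full(cohort.n, marginal)
        return ExposureModel(_finalize_probs(p1, options, "exposure model"), marginal)

    if options.saturated:
        df = cohort.df
        key = list(cols)
        num = pd.Series(bw * x).groupby([df[c] for c in key]).sum()
        den = pd.Series(bw).groupby([df[c] for c in key]).sum()
        cell_p = (num / den).rename("p1").reset_index()
        cell_p.columns = key + ["p1"]
        p1 = df[key].merge(cell_p, on=key, how="left")["p1"].to_numpy()
    elif options.ridge > 0:
        from sklearn.linear_model import LogisticRegression

        X = _predictor_matrix(cohort, cols, options)
        clf = LogisticRegression(
            C=1.0 / options.ridge, solver="lbfgs", max_iter=5000, tol=1e-10
        )
        clf.fit(X.to_numpy(), x, sample_weight=bw)
        p1 = clf.predict_proba(X.to_numpy())[:, 1]
    else:
        X = sm.add_constant(_predictor_matrix(cohort, cols, options), has_constant="add")
        try:
            res = sm.GLM(x, X, family=sm.families.Binomial(), freq_weights=bw).fit()
        except Exception as exc:  # perfect separation and friends
            raise WeightEstimationError(
                "exposure model failed to converge; consider ModelOptions(ridge=...)"
            ) from exc
        p1 = np.asarray(res.predict(X))
    return ExposureModel(_finalize_probs(p1, options, "exposure model"), marginal)


@dataclass
class MediatorModel:
    """Fitted multinomial P(M | predictors): one probability column per level."""

    probs: pd.DataFrame  # columns = mediator levels, rows aligned with cohort
    conditioning: str

    def prob_of(self, m: pd.Series) -> np.ndarray:
        lut = self.probs.to_numpy()
        levels = list(self.probs.columns)
        idx = m.astype(str).map({l: i for i, l in enumerate(levels)}).to_numpy()
        return lut[np.arange(len(m)), idx]


def fit_mediator_model(
    cohort: CohortTable,
    spec: CausalSpec,
    conditioning: str = "full",
    weight_col: str | None = None,
    options: ModelOptions = ModelOptions(),
) -> MediatorModel:
    """Multinomial logistic model for the 3-level mediator.

    ``conditioning`` selects the adjustment set: ``full`` = {X} ∪ C ∪ L (the
    weight denominator), ``marginal_given_x`` = {X} (CDE stabilization
    numerator), ``marginal`` = intercept only (ATE stabilization numerator).
    """
    bw = _base_weights(cohort, weight_col)
    m = cohort.df[spec.mediator].astype(str)
    levels = list(spec.mediator_levels)
    missing_levels = [l for l in levels if l not in set(m.unique())]
    if missing_levels:
        raise WeightEstimationError(
            f"mediator level(s) {missing_levels} absent from the data"
        )
    if conditioning == "full":
        cols = (spec.exposure, *spec.confounders_pre, *spec.confounders_post)
    elif conditioning == "marginal_given_x":
        cols = (spec.exposure,)
    elif conditioning == "marginal":
        cols = ()
    else:
        raise ValueError(f"unknown conditioning {conditioning!r}")
    _check_complete(cohort, (spec.mediator, *cols))

    if not cols:
        shares = np.array(
            [np.average((m == l).to_numpy(float), weights=bw) for l in levels]
        )
        probs = pd.DataFrame(
            np.tile(shares, (cohort.n, 1)), columns=levels, index=cohort.df.index
        )
    elif options.saturated:
        df = cohort.df
        key = list(cols)
        den = pd.Series(bw, index=df.index).groupby([df[c] for c in key]).sum()
        cell = {}
        for l in levels:
            num = (
                pd.Series(bw * (m == l).to_numpy(float), index=df.index)
                .groupby([df[c] for c in key])
                .sum()
            )
            cell[l] = num / den
        cell_df = pd.DataFrame(cell).reset_index()
        cell_df.columns = key + levels
        probs = df[key].merge(cell_df, on=key, how="left")[levels]
        probs.index = df.index
    else:
        from sklearn.linear_model import LogisticRegression

        X = _predictor_matrix(cohort, cols, options)
        clf = LogisticRegression(
            C=np.inf if options.ridge == 0 else 1.0 / options.ridge,
            solver="lbfgs",
            max_iter=5000,
            tol=1e-10,
        )
        clf.fit(X.to_numpy(), m.to_numpy(), sample_weight=bw)
        raw = clf.predict_proba(X.to_numpy())
        order = [list(clf.classes_).index(l) for l in levels]
        probs = pd.DataFrame(raw[:, order], columns=levels, index=cohort.df.index)

    p = probs.to_numpy()
    if np.any(~np.isfinite(p)):
        raise WeightEstimationError("mediator model produced non-finite probabilities")
    return MediatorModel(probs=probs, conditioning=conditioning)


# --------------------------------------------------------------------------
# weight constructors
# --------------------------------------------------------------------------


def _ratio(num: np.ndarray, den: np.ndarray, what: str) -> np.ndarray:
    if np.any(den <= 0):
        raise WeightEstimationError(f"{what}: nonpositive denominator probability")
    return num / den


def ate_weights(
    cohort: CohortTable,
    spec: CausalSpec,
    weight_col: str | None = None,
    options: ModelOptions = ModelOptions(),
    stabilizer: str = "marginal",
) -> WeightSet:
    """Stabilized IPW for the ATE of the mediator on each outcome."""
    bw = _base_weights(cohort, weight_col)
    m = cohort.df[spec.mediator].astype(str)
    den = fit_mediator_model(cohort, spec, "full", weight_col, options)
    num = fit_mediator_model(cohort, spec, stabilizer, weight_col, options)
    w = _ratio(num.prob_of(m), den.prob_of(m), "ate mediator weight")
    return WeightSet(
        estimand="ate_mediator",
        weights=w * bw,
        components={"mediator_ipw": w, "design": bw},
    )


def total_effect_weights(
    cohort: CohortTable,
    spec: CausalSpec,
    weight_col: str | None = None,
    options: ModelOptions = ModelOptions(),
) -> WeightSet:
    """Stabilized exposure IPW adjusting pre-exposure confounders only."""
    bw = _base_weights(cohort, weight_col)
    x = cohort.df[spec.exposure].to_numpy(float)
    model = fit_exposure_model(cohort, spec, weight_col, options)
    w = _ratio(model.marginal_of(x), model.prob_of(x), "total-effect weight")
    return WeightSet(
        estimand="total_effect",
        weights=w * bw,
        components={"exposure_ipw": w, "design": bw},
    )


def cde_weights(
    cohort: CohortTable,
    spec: CausalSpec,
    weight_col: str | None = None,
    options: ModelOptions = ModelOptions(),
) -> WeightSet:
    """Product weights for the controlled-direct-effect MSM."""
    bw = _base_weights(cohort, weight_col)
    x = cohort.df[spec.exposure].to_numpy(float)
    m = cohort.df[spec.mediator].astype(str)
    xmodel = fit_exposure_model(cohort, spec, weight_col, options)
    w_x = _ratio(xmodel.marginal_of(x), xmodel.prob_of(x), "cde exposure factor")
    den = fit_mediator_model(cohort, spec, "full", weight_col, options)
    num = fit_mediator_model(cohort, spec, "marginal_given_x", weight_col, options)
    w_m = _ratio(num.prob_of(m), den.prob_of(m), "cde mediator factor")
    return WeightSet(
        estimand="cde",
        weights=w_x * w_m * bw,
        components={"exposure_ipw": w_x, "mediator_ipw": w_m, "design": bw},
    )


# --------------------------------------------------------------------------
# balance diagnostics
# --------------------------------------------------------------------------


@dataclass
class BalanceReport:
    """Standardized mean differences before/after weighting plus weight summaries."""

    table: pd.DataFrame  # confounder, contrast, stratum, stage, smd, zero_sd
    weight_summary: dict

    def max_abs_smd(self, stage: str = "weighted") -> float:
        t = self.table[(self.table.stage == stage) & (self.table.stratum == "overall")]
        return float(t.smd.abs().max())

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _covariate_columns(cohort: CohortTable, cols: tuple[str, ...]) -> pd.DataFrame:
    """Numeric covariate frame; categorical columns expand to level indicators."""
    out = {}
    for c in cols:
        d = cohort.dictionary.get(c)
        if d is not None and d.vtype == "categorical":
            s = cohort.df[c].astype(str)
            for lev in sorted(s.unique()):
                out[f"{c}[{lev}]"] = (s == lev).astype(float)
        else:
            out[c] = cohort.df[c].to_numpy(float)
    return pd.DataFrame(out, index=cohort.df.index)


def _smd(v: np.ndarray, g1: np.ndarray, g0: np.ndarray, w: np.ndarray):
    sd = np.sqrt(
        (np.var(v[g1], ddof=1) + np.var(v[g0], ddof=1)) / 2.0
    )  # pooled *unweighted* SD keeps before/after comparable
    if sd == 0 or not np.isfinite(sd):
        return 0.0, True
    diff = np.average(v[g1], weights=w[g1]) - np.average(v[g0], weights=w[g0])
    return float(diff / sd), False


def balance_report(
    cohort: CohortTable,
    ws: WeightSet,
    spec: CausalSpec,
    weight_col: str | None = None,
) -> BalanceReport:
    """SMD of each confounder across treatment contrasts, before and after
    weighting; mediator contrasts are also reported within exposure strata."""
    if not np.all(np.isfinite(ws.weights)):
        raise WeightEstimationError("weights must be finite for balance reporting")
    bw = ws.components.get("design", _base_weights(cohort, weight_col))
    stages = {"unweighted": bw, "weighted": ws.weights}
    rows = []

    def add_contrasts(treat: pd.Series, covs: pd.DataFrame, strata: dict):
        vals = sorted(treat.dropna().astype(str).unique())
        for i, a in enumerate(vals):
            for b in vals[:i]:
                for sname, smask in strata.items():
                    g1 = ((treat == a) & smask).to_numpy()
                    g0 = ((treat == b) & smask).to_numpy()
                    if g1.sum() < 2 or g0.sum() < 2:
                        continue
                    for stage, w in stages.items():
                        for cov in covs.columns:
                            smd, flag = _smd(covs[cov].to_numpy(), g1, g0, w)
                            rows.append(
                                {
                                    "confounder": cov,
                                    "contrast": f"{a} vs {b}",
                                    "stratum": sname,
                                    "stage": stage,
                                    "smd": smd,
                                    "zero_sd": flag,
                                }
                            )

    everywhere = {"overall": pd.Series(True, index=cohort.df.index)}
    if ws.estimand in ("total_effect", "cde"):
        covs = _covariate_columns(cohort, spec.confounders_pre)
        add_contrasts(cohort.df[spec.exposure].astype(int).astype(str), covs, everywhere)
    if ws.estimand in ("ate_mediator", "cde"):
        covs = _covariate_columns(
            cohort, spec.confounders_pre + spec.confounders_post
        )
        x = cohort.df[spec.exposure]
        strata = dict(everywhere)
        for xv in sorted(x.dropna().unique()):
            strata[f"{spec.exposure}={int(xv)}"] = x == xv
        add_contrasts(cohort.df[spec.mediator].astype(str), covs, strata)

    treat = (
        cohort.df[spec.mediator].astype(str)
        if ws.estimand == "ate_mediator"
        else cohort.df[spec.exposure].astype(int).astype(str)
    )
    summary = {"estimand": ws.estimand, "groups": {}}
    for g in sorted(treat.unique()):
        wg = ws.weights[(treat == g).to_numpy()]
        summary["groups"][g] = {
            "mean": float(wg.mean()),
            "max": float(wg.max()),
            "p99": float(np.percentile(wg, 99)),
        }
    return BalanceReport(table=pd.DataFrame(rows), weight_summary=summary)
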