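"""Multiple imputation by chained equations and Rubin's-rules pooling.

Each of the ``m`` completed datasets is produced by an independent chain:
missing cells are initialized by random draws from the observed margin, then
each incomplete analysis variable is re-imputed in a fixed visitation order
for a configured number of cycles.  Conditional models follow variable type —
Bayesian logistic draws for binary columns, a multinomial logistic draw for
categorical columns, and predictive mean matching (type-1, k donors) or a
Bayesian normal draw for continuous columns.  Every conditional model uses
all other analysis variables (exposure, mediator, confounders, outcomes) plus
the design weight as predictors; observed cells are never altered.

Pooling follows Rubin's rules with the Barnard-Rubin small-sample degrees of
freedom: T = W + (1 + 1/m) B, with the pooled CI from the t quantile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .cohort import CohortTable
from .effects import EffectEstimate

_ANALYSIS_ROLES = {
    "exposure",
    "mediator",
    "confounder_pre",
    "confounder_post",
    "outcome",
}


class ImputationError(RuntimeError):
    pass


@dataclass(frozen=True)
class ImputationConfig:
    m: int = 25
    iterations: int = 10
    seed: int = 0
    pmm_donors: int = 5
    method_by_type: tuple[tuple[str, str], ...] = (
        ("binary", "logistic"),
        ("categorical", "multinomial"),
        ("continuous", "pmm"),
    )
    #: include the exposure-by-mediator product among predictors, keeping the
    #: conditional models congenial with the interaction MSM analysed downstream
    xm_interaction: bool = True

    def validate(self):
        if self.m < 2:
            raise ImputationError("m must be >= 2 for pooling")
        if self.iterations < 1:
            raise ImputationError("iterations must be >= 1")
        if self.pmm_donors < 1:
            raise ImputationError("pmm_donors must be >= 1")

    def method_for(self, vtype: str) -> str:
        return dict(self.method_by_type).get(vtype, "pmm")


# --------------------------------------------------------------------------
# conditional draws
# --------------------------------------------------------------------------


def _design_frame(
    df: pd.DataFrame,
    cols: list[str],
    dictionary,
    interaction: tuple[str, str] | None = None,
) -> np.ndarray:
    parts = [np.ones((len(df), 1))]
    for c in cols:
        d = dictionary.get(c)
        if d is not None and d.vtype == "categorical":
            s = df[c].astype(str)
            levels = sorted(s.unique())[1:]
            for lev in levels:
                parts.append((s == lev).to_numpy(float)[:, None])
        else:
            parts.append(df[c].to_numpy(float)[:, None])
    if interaction is not None:
        a, b = interaction  # numeric x categorical product terms
        if a in cols and b in cols:
            av = df[a].to_numpy(float)
            s = df[b].astype(str)
            for lev in sorted(s.unique())[1:]:
                parts.append((av * (s == lev).to_numpy(float))[:, None])
    return np.hstack(parts)


def _bayes_ols_draw(X, y, rng):
    n, k = X.shape
    xtx = X.T @ X
    xtx_inv = np.linalg.pinv(xtx)
    beta_hat = xtx_inv @ (X.T @ y)
    resid = y - X @ beta_hat
    dof = max(n - k, 1)
    sigma2_hat = float(resid @ resid) / dof
    sigma2 = sigma2_hat * dof / rng.chisquare(dof)
    beta = rng.multivariate_normal(beta_hat, sigma2 * xtx_inv, method="cholesky")
    return beta_hat, beta, np.sqrt(sigma2)


def _impute_continuous(X_obs, y_obs, X_mis, rng, method, donors):
    beta_hat, beta_draw, sigma = _bayes_ols_draw(X_obs, y_obs, rng)
    if method == "linear":
        return X_mis @ beta_draw + sigma * rng.standard_normal(len(X_mis))
    # predictive mean matching: donors nearest in predicted value
    pred_obs = X_obs @ beta_hat
    pred_mis = X_mis @ beta_draw
    order = np.argsort(pred_obs)
    sorted_pred = pred_obs[order]
    sorted_y = y_obs[order]
    pos = np.searchsorted(sorted_pred, pred_mis)
    out = np.empty(len(pred_mis))
    n_obs = len(sorted_pred)
    for i, (p, v) in enumerate(zip(pos, pred_mis)):
        lo = max(0, p - donors)
        hi = min(n_obs, p + donors)
        cand = np.arange(lo, hi)
        nearest = cand[np.argsort(np.abs(sorted_pred[cand] - v))[:donors]]
        out[i] = sorted_y[rng.choice(nearest)]
    return out


def _impute_binary(X_obs, y_obs, X_mis, rng, col, it):
    import statsmodels.api as sm

    try:
        res = sm.GLM(y_obs, X_obs, family=sm.families.Binomial()).fit()
        cov = np.asarray(res.cov_params())
        beta = rng.multivariate_normal(np.asarray(res.params), cov, method="svd")
    except Exception as exc:
        raise ImputationError(
            f"conditional logistic model for {col!r} failed at iteration {it}"
        ) from exc
    p = expit(X_mis @ beta)
    return (rng.random(len(X_mis)) < p).astype(float)


def _impute_categorical(X_obs, y_obs, X_mis, rng, col, it):
    from sklearn.linear_model import LogisticRegression

    try:
        clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=2000, tol=1e-8)
        clf.fit(X_obs[:, 1:], y_obs)  # sklearn supplies its own intercept
        probs = clf.predict_proba(X_mis[:, 1:])
    except Exception as exc:
        raise ImputationError(
            f"conditional multinomial model for {col!r} failed at iteration {it}"
        ) from exc
    u = rng.random(len(X_mis))
    idx = (u[:, None] > probs.cumsum(axis=1)).sum(axis=1)
    idx = np.minimum(idx, probs.shape[1] - 1)
    return np.asarray(clf.classes_, dtype=object)[idx]


# --------------------------------------------------------------------------
# chained equations
# --------------------------------------------------------------------------


def impute(cohort: CohortTable, cfg: ImputationConfig) -> list[CohortTable]:
    """Return ``cfg.m`` completed copies of the cohort (observed cells untouched)."""
    cfg.validate()
    analysis_cols = [
        c for c, d in cohort.dictionary.items()
        if d.role in _ANALYSIS_ROLES and c in cohort.df.columns
    ]
    weight_cols = cohort.columns_with_role("design_weight")
    predictors_extra = [c for c in weight_cols if c in cohort.df.columns]

    miss = {c: cohort.df[c].isna() for c in analysis_cols}
    incomplete = [c for c in analysis_cols if miss[c].any()]
    for c in incomplete:
        frac = miss[c].mean()
        if frac > 0.95:
            raise ImputationError(f"column {c!r} is {frac:.0%} missing")

    if not incomplete:
        return [cohort.copy() for _ in range(cfg.m)]

    exposure_cols = [c for c, d in cohort.dictionary.items() if d.role == "exposure"]
    mediator_cols = [c for c, d in cohort.dictionary.items() if d.role == "mediator"]
    xm_pair = (
        (exposure_cols[0], mediator_cols[0])
        if cfg.xm_interaction and exposure_cols and mediator_cols
        else None
    )

    root = np.random.default_rng(cfg.seed)
    chain_seeds = root.integers(0, 2**31 - 1, size=cfg.m)
    completed = []
    for chain_seed in chain_seeds:
        rng = np.random.default_rng(int(chain_seed))
        df = cohort.df.copy()
        # initialize from observed margins
        for c in incomplete:
            obs_vals = df.loc[~miss[c], c].to_numpy()
            df.loc[miss[c], c] = rng.choice(obs_vals, size=int(miss[c].sum()))
        for it in range(1, cfg.iterations + 1):
            for c in incomplete:
                others = [o for o in analysis_cols if o != c] + predictors_extra
                X = _design_frame(df, others, cohort.dictionary, interaction=xm_pair)
                obs = (~miss[c]).to_numpy()
                mis = miss[c].to_numpy()
                vtype = cohort.dictionary[c].vtype
                method = cfg.method_for(vtype)
                if vtype == "categorical" or method == "multinomial":
                    vals = _impute_categorical(
                        X[obs], df.loc[obs, c].astype(str).to_numpy(), X[mis], rng, c, it
                    )
                elif vtype == "binary" or method == "logistic":
                    vals = _impute_binary(
                        X[obs], df.loc[obs, c].to_numpy(float), X[mis], rng, c, it
                    )
                else:
                    vals = _impute_continuous(
                        X[obs],
                        df.loc[obs, c].to_numpy(float),
                        X[mis],
                        rng,
                        method,
                        cfg.pmm_donors,
                    )
                df.loc[mis, c] = vals
        completed.append(CohortTable(df, dict(cohort.dictionary)))
    return completed


# --------------------------------------------------------------------------
# Rubin's rules
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PooledEstimate:
    estimand: str
    contrast: str
    scenario: str
    outcome: str
    point: float
    within_var: float
    between_var: float
    total_var: float
    se: float
    df: float
    ci_low: float
    ci_high: float
    fmi: float
    m: int


def pool(estimate_lists: list[list[EffectEstimate]]) -> list[PooledEstimate]:
    """Rubin's-rules combination of per-imputation estimate lists."""
    m = len(estimate_lists)
    if m < 2:
        raise ImputationError("pooling requires at least 2 imputed analyses")

    def key(e: EffectEstimate):
        return (e.estimand, e.contrast, e.scenario, e.outcome)

    grids = [tuple(key(e) for e in lst) for lst in estimate_lists]
    if len(set(grids)) != 1:
        raise ImputationError("per-imputation estimate grids do not match")

    pooled = []
    for j, k in enumerate(grids[0]):
        ests = [lst[j] for lst in estimate_lists]
        points = np.array([e.point for e in ests])
        ses = np.array([e.se for e in ests])
        qbar = float(points.mean())
        W = float((ses**2).mean())
        B = float(points.var(ddof=1))
        T = W + (1 + 1 / m) * B
        nu_com = float(np.nanmean([e.df for e in ests]))
        if not np.isfinite(nu_com) or nu_com <= 0:
            nu_com = np.inf
        if B <= 0 or T <= 0:
            nu = nu_com
            lam = 0.0
        else:
            lam = (1 + 1 / m) * B / T
            nu_old = (m - 1) / lam**2
            if np.isfinite(nu_com):
                nu_obs = (nu_com + 1) / (nu_com + 3) * nu_com * (1 - lam)
                nu = 1.0 / (1.0 / nu_old + 1.0 / nu_obs)
            else:
                nu = nu_old
        se = float(np.sqrt(T))
        tq = stats.t.ppf(0.975, nu) if np.isfinite(nu) else stats.norm.ppf(0.975)
        pooled.append(
            PooledEstimate(
                estimand=k[0],
                contrast=k[1],
                scenario=k[2],
                outcome=k[3],
                point=qbar,
                within_var=W,
                between_var=B,
                total_var=T,
                se=se,
                df=float(nu),
                ci_low=qbar - tq * se,
                ci_high=qbar + tq * se,
                fmi=float(lam),
                m=m,
            )
        )
    return pooled


def pooled_to_frame(pooled: list[PooledEstimate]) -> pd.DataFrame:
    return pd.DataFrame([p.__dict__ for p in pooled])
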