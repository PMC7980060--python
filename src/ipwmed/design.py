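"""Survey design handling: weight combination and cluster-robust variance.

The variance estimator is the linearized (Taylor) stratified cluster sandwich:
per-observation score contributions are summed within primary sampling units,
centered within stratum, and accumulated into the meat of a sandwich around
the weighted-least-squares bread.  No small-sample factor is applied by
default, so with one-person clusters and a single stratum the estimator
reduces exactly to the heteroskedasticity-robust (HC0) covariance; a
Stata-style n_h/(n_h - 1) correction is available via ``ddof="cluster"``.
A stratified cluster bootstrap is provided as a cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .weights import WeightSet


class DesignError(ValueError):
    pass


@dataclass(frozen=True)
class DesignSpec:
    """Names of the survey-design columns and the variance method."""

    stratum_col: str = "stratum"
    cluster_col: str = "cluster"
    weight_col: str = "design_weight"
    variance_method: str = "linearized"  # or "cluster_bootstrap"

    def check_against(self, cohort: CohortTable) -> None:
        for col in (self.stratum_col, self.cluster_col, self.weight_col):
            if col not in cohort.df.columns:
                raise DesignError(f"design column {col!r} missing from cohort")
        nest = cohort.df.groupby(self.cluster_col, observed=True)[
            self.stratum_col
        ].nunique()
        if (nest > 1).any():
            raise DesignError("clusters must nest within strata")
        if (cohort.df[self.weight_col] <= 0).any():
            raise DesignError("design weights must be strictly positive")


def combine_weights(
    ws: WeightSet, design: DesignSpec, cohort: CohortTable
) -> WeightSet:
    """Fold design weights into an analysis WeightSet that lacks them."""
    design.check_against(cohort)
    if "design" in ws.components:
        raise DesignError("WeightSet already carries a design component")
    dw = cohort.df[design.weight_col].to_numpy(float)
    return WeightSet(
        estimand=ws.estimand,
        weights=ws.weights * dw,
        components={**ws.components, "design": dw},
        truncation=ws.truncation,
    )


def robust_variance(
    exog: np.ndarray,
    resid: np.ndarray,
    weights: np.ndarray,
    stratum: np.ndarray,
    cluster: np.ndarray,
    ddof: str = "none",
) -> tuple[np.ndarray, int]:
    """Stratified cluster-sandwich covariance for a WLS fit.

    Parameters are the model design matrix, residuals, fitting weights and the
    stratum/cluster labels.  Returns (covariance, design degrees of freedom =
    clusters - strata).  ``ddof="cluster"`` applies the n_h/(n_h - 1) factor.
    """
    exog = np.asarray(exog, float)
    resid = np.asarray(resid, float)
    weights = np.asarray(weights, float)
    scores = exog * (weights * resid)[:, None]

    key = pd.DataFrame({"s": np.asarray(stratum), "c": np.asarray(cluster)})
    cl = key.groupby(["s", "c"], observed=True, sort=True).indices
    strata_ids = sorted({s for s, _ in cl})
    per_stratum: dict = {s: [] for s in strata_ids}
    for (s, c), idx in cl.items():
        per_stratum[s].append(scores[idx].sum(axis=0))

    k = exog.shape[1]
    meat = np.zeros((k, k))
    n_clusters = 0
    for s, glist in per_stratum.items():
        g = np.vstack(glist)
        n_h = g.shape[0]
        if n_h < 2:
            raise DesignError(f"stratum {s!r} has fewer than 2 clusters")
        centered = g - g.mean(axis=0)
        contrib = centered.T @ centered
        if ddof == "cluster":
            contrib *= n_h / (n_h - 1)
        meat += contrib
        n_clusters += n_h

    bread = np.linalg.pinv(exog.T @ (weights[:, None] * exog))
    cov = bread @ meat @ bread
    df = n_clusters - len(strata_ids)
    return cov, df


def cluster_bootstrap_cov(
    fit_params,
    df: pd.DataFrame,
    design: DesignSpec,
    n_boot: int = 500,
    seed: int = 0,
) -> np.ndarray:
    """Covariance of ``fit_params(resampled_df)`` under a stratified cluster
    bootstrap (clusters resampled with replacement within stratum)."""
    rng = np.random.default_rng(seed)
    work = df.reset_index(drop=True)
    pos: dict[object, list[np.ndarray]] = {}
    for (s, _), idx in work.groupby(
        [design.stratum_col, design.cluster_col], observed=True
    ).indices.items():
        pos.setdefault(s, []).append(np.asarray(idx))
    reps = []
    for _ in range(n_boot):
        take = []
        for s, clusters in pos.items():
            n_h = len(clusters)
            picks = rng.integers(0, n_h, size=n_h)
            take.extend(clusters[p] for p in picks)
        idx = np.concatenate(take)
        reps.append(fit_params(work.iloc[idx]))
    reps = np.asarray(reps)
    return np.cov(reps, rowvar=False, ddof=1)
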