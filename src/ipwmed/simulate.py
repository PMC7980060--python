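"""Synthetic cohort generator with known true causal estimands.

Emulates the causal structure of the childcare-inequalities design: binary
exposure X (low parental education), 3-category childcare mediator M
(parental / non-centre / centre-based), pre-exposure confounders C influencing
X, M and Y, post-exposure confounders L influenced by X and influencing M and
Y, and continuous child outcomes with exposure-by-mediator interaction.  On
top of the structural model it layers a stratified-clustered survey design
with oversampling of disadvantaged areas, follow-up attrition with
inverse-probability response weights, and missing-at-random masking.

Outcomes are built with total standard deviation close to one, so structural
coefficients are directly interpretable as SD-unit effects.  Intercepts of the
exposure and mediator models are calibrated at run time (on a fixed-seed
calibration population) so that the population exposure prevalence and
mediator marginals hit their configured targets; the default targets are an
exposure prevalence of 0.54 and childcare shares of 39.6 / 33.0 / 27.4%.

``true_estimands`` returns the generator-side ground truth for the three
estimands recovered downstream: ATEs of the mediator, total effects of the
exposure, and controlled direct effects CDE(m) at each childcare level.  For
discrete-only configurations the truth is an exact enumeration over the full
covariate support; otherwise a large-population Monte Carlo evaluation with a
fixed internal seed is used.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit

from .cohort import MEDIATOR_LEVELS, CohortTable, ColumnDef

_CAL_SEED = 202_103  # calibration population; independent of cohort seeds
_TRUTH_SEED = 864_123  # Monte Carlo truth evaluation
_CAL_N = 400_000


class ConfigError(ValueError):
    """Invalid generator configuration; message names the offending field."""


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class OutcomeSpec:
    """Structural outcome equation Y = a + bX·X + bM[m] + X·int[m] + C,L terms + noise.

    If ``cde_parental`` / ``cde_centre`` targets are given, ``coef_x`` and the
    centre interaction are solved so the true controlled direct effects equal
    those targets exactly (accounting for the open X→L→Y path).
    """

    intercept: float = 0.0
    coef_x: float | None = None
    cde_parental: float | None = None
    cde_centre: float | None = None
    coef_m: tuple[tuple[str, float], ...] = ()
    interaction: tuple[tuple[str, float], ...] = ()
    coef_c: tuple[tuple[str, float], ...] = ()
    coef_l: tuple[tuple[str, float], ...] = ()
    noise_sd: float = 0.9

    def m_effect(self, level: str) -> float:
        return dict(self.coef_m).get(level, 0.0)


def _block(**kw) -> tuple[tuple[str, float], ...]:
    return tuple(kw.items())


@dataclass(frozen=True)
class GeneratorConfig:
    """All structural, design and missingness parameters of the generator."""

    n: int = 14_376
    seed: int = 20_210_312
    # pre-exposure confounders
    p_c1: float = 0.15  # binary, e.g. minority-ethnicity analogue
    p_c2_advantaged: float = 0.18  # binary disadvantage, by area stratum
    p_c2_disadvantaged: float = 0.42
    include_c3: bool = True  # continuous confounder, N(0, 1)
    # exposure model X | C (logistic); intercept calibrated if prevalence given
    exposure_prevalence: float | None = 0.54
    coef_c_on_x: tuple[tuple[str, float], ...] = _block(
        intercept=0.0, c1=0.5, c2=0.8, c3=0.35
    )
    # post-exposure confounders L | X, C
    coef_on_l1: tuple[tuple[str, float], ...] = _block(
        intercept=-1.6, x=0.5, c1=0.2, c2=0.5, c3=0.25
    )
    include_l2: bool = True
    coef_on_l2: tuple[tuple[str, float], ...] = _block(
        intercept=0.0, x=0.3, c1=0.1, c2=0.25, c3=0.2, sd=1.0
    )
    # mediator M | X, C, L (multinomial logistic, reference "parental");
    # intercepts calibrated to mediator_marginals when given
    mediator_marginals: tuple[float, float, float] | None = (0.396, 0.330, 0.274)
    coef_on_m_non_centre: tuple[tuple[str, float], ...] = _block(
        intercept=0.0, x=-0.3, c1=-0.4, c2=-0.2, c3=-0.1, l1=-0.3, l2=-0.1
    )
    coef_on_m_centre: tuple[tuple[str, float], ...] = _block(
        intercept=0.0, x=-0.6, c1=-0.5, c2=-0.4, c3=-0.15, l1=-0.4, l2=-0.15
    )
    # outcomes
    outcomes: tuple[tuple[str, OutcomeSpec], ...] = (
        (
            "y_ext",  # externalising-symptom analogue; CDE targets 0.15 / 0.02
            OutcomeSpec(
                cde_parental=0.15,
                cde_centre=0.02,
                coef_m=_block(non_centre=-0.03, centre=-0.08),
                interaction=_block(non_centre=-0.05),
                coef_c=_block(c1=0.10, c2=0.25, c3=0.15),
                coef_l=_block(l1=0.25, l2=0.15),
                noise_sd=0.9,
            ),
        ),
        (
            "y_voc",  # vocabulary analogue; non-centre care benefit, no interaction
            OutcomeSpec(
                coef_x=-0.25,
                coef_m=_block(non_centre=0.10, centre=0.03),
                coef_c=_block(c1=-0.10, c2=-0.20, c3=-0.10),
                coef_l=_block(l1=-0.10, l2=-0.10),
                noise_sd=0.9,
            ),
        ),
    )
    # survey design
    n_strata: int = 2
    clusters_per_stratum: int = 50
    oversample_ratio: float = 2.0  # disadvantaged strata sampling rate
    cluster_sd: float = 0.05  # cluster-level outcome intercept SD
    # attrition (response) model on always-observed X and disadvantage;
    # None disables attrition entirely
    attrition_model: tuple[tuple[str, float], ...] | None = _block(
        intercept=2.4, x=-0.35, c2=-0.3
    )
    # missingness
    missing_rate: float = 0.05

    # ---- validation ----------------------------------------------------
    def validate(self) -> None:
        if self.n < 1:
            raise ConfigError("n must be >= 1")
        for name in ("p_c1", "p_c2_advantaged", "p_c2_disadvantaged"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be a probability in [0, 1]")
        if self.exposure_prevalence is not None and not (
            0.0 < self.exposure_prevalence < 1.0
        ):
            raise ConfigError("exposure_prevalence must be in (0, 1)")
        if self.mediator_marginals is not None:
            mm = self.mediator_marginals
            if len(mm) != 3 or any(not 0 < p < 1 for p in mm):
                raise ConfigError("mediator_marginals must be 3 probabilities in (0,1)")
            if abs(sum(mm) - 1.0) > 1e-8:
                raise ConfigError("mediator_marginals must sum to 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigError("missing_rate must be in [0, 1)")
        if self.n_strata < 1:
            raise ConfigError("n_strata must be >= 1")
        if self.clusters_per_stratum < 1:
            raise ConfigError("clusters_per_stratum must be >= 1")
        if self.oversample_ratio <= 0:
            raise ConfigError("oversample_ratio must be > 0")
        if self.cluster_sd < 0:
            raise ConfigError("cluster_sd must be >= 0")
        for name, spec in self.outcomes:
            if spec.noise_sd <= 0:
                raise ConfigError(f"outcomes[{name}].noise_sd must be > 0")
            if spec.coef_x is None and spec.cde_parental is None:
                raise ConfigError(
                    f"outcomes[{name}] needs either coef_x or a cde_parental target"
                )

    # ---- design helpers ------------------------------------------------
    @property
    def stratum_rates(self) -> np.ndarray:
        """Relative sampling rate per stratum (second half oversampled)."""
        s = self.n_strata
        if s == 1:
            return np.array([1.0])
        r = np.ones(s)
        r[s // 2 :] = self.oversample_ratio
        return r

    @property
    def stratum_c2_prev(self) -> np.ndarray:
        s = self.n_strata
        if s == 1:
            return np.array([(self.p_c2_advantaged + self.p_c2_disadvantaged) / 2])
        p = np.full(s, self.p_c2_advantaged)
        p[s // 2 :] = self.p_c2_disadvantaged
        return p

    @property
    def p_c2_population(self) -> float:
        # population stratum shares are uniform
        return float(np.mean(self.stratum_c2_prev))

    @property
    def p_c2_sample(self) -> float:
        q = self.stratum_rates / self.stratum_rates.sum()
        return float(q @ self.stratum_c2_prev)

    @property
    def outcome_names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.outcomes)

    @property
    def is_discrete(self) -> bool:
        """True when every structural variable has finite discrete support."""
        return not self.include_c3 and not self.include_l2

    def _cal_key(self):
        return (
            self.p_c1,
            self.p_c2_advantaged,
            self.p_c2_disadvantaged,
            self.include_c3,
            self.exposure_prevalence,
            self.coef_c_on_x,
            self.coef_on_l1,
            self.include_l2,
            self.coef_on_l2,
            self.mediator_marginals,
            self.coef_on_m_non_centre,
            self.coef_on_m_centre,
            self.outcomes,
            self.n_strata,
            self.oversample_ratio,
        )


def default_config(**overrides) -> GeneratorConfig:
    return dataclasses.replace(GeneratorConfig(), **overrides)


def default_causal_spec(config: GeneratorConfig | None = None):
    from .cohort import CausalSpec

    config = config or GeneratorConfig()
    pre = ["c1", "c2"] + (["c3"] if config.include_c3 else [])
    post = ["l1"] + (["l2"] if config.include_l2 else [])
    return CausalSpec(
        exposure="x",
        mediator="m",
        confounders_pre=tuple(pre),
        confounders_post=tuple(post),
        outcomes=config.outcome_names,
    )


# --------------------------------------------------------------------------
# structural pieces
# --------------------------------------------------------------------------


def _lin(coefs: dict[str, float], cols: dict[str, np.ndarray]) -> np.ndarray:
    """Linear predictor from a coefficient block over available columns."""
    out = np.full_like(next(iter(cols.values())), coefs.get("intercept", 0.0), dtype=float)
    for name, arr in cols.items():
        if name in coefs:
            out = out + coefs[name] * arr
    return out


def _mediator_probs(
    config: GeneratorConfig,
    intercepts: dict[str, float],
    cols: dict[str, np.ndarray],
) -> np.ndarray:
    """n x 3 probabilities ordered as MEDIATOR_LEVELS (reference first)."""
    eta = []
    for level, block in (
        ("non_centre", dict(config.coef_on_m_non_centre)),
        ("centre", dict(config.coef_on_m_centre)),
    ):
        block = dict(block)
        block["intercept"] = intercepts[level]
        eta.append(_lin(block, cols))
    eta = np.column_stack([np.zeros_like(eta[0]), *eta])
    eta -= eta.max(axis=1, keepdims=True)
    p = np.exp(eta)
    p /= p.sum(axis=1, keepdims=True)
    return p


def _draw_population_c(config: GeneratorConfig, n: int, rng: np.random.Generator):
    """Pre-exposure confounders under the *population* distribution."""
    cols = {
        "c1": (rng.random(n) < config.p_c1).astype(float),
        "c2": (rng.random(n) < config.p_c2_population).astype(float),
    }
    if config.include_c3:
        cols["c3"] = rng.standard_normal(n)
    return cols


# --------------------------------------------------------------------------
# calibration (intercepts and CDE-targeted exposure coefficients)
# --------------------------------------------------------------------------

_CAL_CACHE: dict[tuple, dict] = {}


def _calibration(config: GeneratorConfig) -> dict:
    key = config._cal_key()
    if key in _CAL_CACHE:
        return _CAL_CACHE[key]
    rng = np.random.default_rng(_CAL_SEED)
    c = _draw_population_c(config, _CAL_N, rng)

    xb = dict(config.coef_c_on_x)
    lin_x = _lin({**xb, "intercept": 0.0}, c)
    if config.exposure_prevalence is None:
        x_icpt = xb.get("intercept", 0.0)
    else:
        x_icpt = optimize.brentq(
            lambda a: float(np.mean(expit(a + lin_x))) - config.exposure_prevalence,
            -15.0,
            15.0,
            xtol=1e-12,
        )
    p_x = expit(x_icpt + lin_x)
    x = (rng.random(_CAL_N) < p_x).astype(float)

    cols = dict(c)
    cols["x"] = x
    cols["l1"] = (rng.random(_CAL_N) < expit(_lin(dict(config.coef_on_l1), cols))).astype(
        float
    )
    if config.include_l2:
        l2b = dict(config.coef_on_l2)
        cols["l2"] = _lin(l2b, cols) + l2b.get("sd", 1.0) * rng.standard_normal(_CAL_N)

    if config.mediator_marginals is None:
        m_icpt = {
            "non_centre": dict(config.coef_on_m_non_centre).get("intercept", 0.0),
            "centre": dict(config.coef_on_m_centre).get("intercept", 0.0),
        }
    else:
        targets = np.asarray(config.mediator_marginals[1:])  # non_centre, centre

        def gap(a):
            p = _mediator_probs(
                config, {"non_centre": a[0], "centre": a[1]}, cols
            ).mean(axis=0)
            return p[1:] - targets

        sol = optimize.root(gap, x0=np.zeros(2), tol=1e-12)
        if not sol.success:  # pragma: no cover - well-behaved softmax
            raise ConfigError("mediator_marginals: intercept calibration failed")
        m_icpt = {"non_centre": float(sol.x[0]), "centre": float(sol.x[1])}

    # X -> L -> Y open-path contribution to the CDE, per outcome
    l1b = dict(config.coef_on_l1)
    eta_l1_x0 = _lin({**l1b, "x": 0.0}, {**c, "x": np.zeros(1)})
    d_l1 = float(np.mean(expit(eta_l1_x0 + l1b.get("x", 0.0)) - expit(eta_l1_x0)))
    d_l2 = dict(config.coef_on_l2).get("x", 0.0) if config.include_l2 else 0.0

    outcome_cal = {}
    for name, spec in config.outcomes:
        cl = dict(spec.coef_l)
        l_path = cl.get("l1", 0.0) * d_l1 + cl.get("l2", 0.0) * d_l2
        if spec.cde_parental is not None:
            coef_x = spec.cde_parental - l_path
        else:
            coef_x = spec.coef_x
        inter = dict(spec.interaction)
        if spec.cde_centre is not None and spec.cde_parental is not None:
            inter["centre"] = spec.cde_centre - spec.cde_parental
        outcome_cal[name] = {"coef_x": coef_x, "interaction": inter, "l_path": l_path}

    cal = {
        "x_intercept": float(x_icpt),
        "m_intercepts": m_icpt,
        "outcomes": outcome_cal,
        "p_x_population": float(np.mean(p_x)),
    }
    _CAL_CACHE[key] = cal
    return cal


# --------------------------------------------------------------------------
# cohort generation
# --------------------------------------------------------------------------


def _outcome_mean(
    config: GeneratorConfig, cal: dict, name: str, spec: OutcomeSpec, cols: dict
) -> np.ndarray:
    """Structural conditional mean E[Y | X, C, L, M-dummies in cols]."""
    ocal = cal["outcomes"][name]
    mu = spec.intercept + ocal["coef_x"] * cols["x"]
    mu = mu + _lin({**dict(spec.coef_c), "intercept": 0.0}, cols)
    mu = mu + _lin({**dict(spec.coef_l), "intercept": 0.0}, cols)
    for level in ("non_centre", "centre"):
        ind = cols[f"m_{level}"]
        mu = mu + spec.m_effect(level) * ind
        mu = mu + ocal["interaction"].get(level, 0.0) * cols["x"] * ind
    return mu


def generate_cohort(config: GeneratorConfig) -> CohortTable:
    """Draw a complete (no-missingness, pre-design) cohort from the structural model.

    The binary disadvantage confounder is drawn at its *sample* prevalence,
    reflecting the oversampling of disadvantaged areas; ``assign_design``
    later assigns strata consistently with that two-stage scheme.
    """
    config.validate()
    cal = _calibration(config)
    rng = np.random.default_rng(config.seed)
    n = config.n

    cols = {
        "c1": (rng.random(n) < config.p_c1).astype(float),
        "c2": (rng.random(n) < config.p_c2_sample).astype(float),
    }
    if config.include_c3:
        cols["c3"] = rng.standard_normal(n)

    xb = {**dict(config.coef_c_on_x), "intercept": cal["x_intercept"]}
    cols["x"] = (rng.random(n) < expit(_lin(xb, cols))).astype(float)

    cols["l1"] = (rng.random(n) < expit(_lin(dict(config.coef_on_l1), cols))).astype(float)
    if config.include_l2:
        l2b = dict(config.coef_on_l2)
        cols["l2"] = _lin(l2b, cols) + l2b.get("sd", 1.0) * rng.standard_normal(n)

    pm = _mediator_probs(config, cal["m_intercepts"], cols)
    u = rng.random(n)
    m_idx = (u[:, None] > pm.cumsum(axis=1)).sum(axis=1)
    m = np.asarray(MEDIATOR_LEVELS, dtype=object)[m_idx]
    cols["m_non_centre"] = (m == "non_centre").astype(float)
    cols["m_centre"] = (m == "centre").astype(float)

    data = {k: v for k, v in cols.items() if not k.startswith("m_")}
    data["m"] = m
    for name, spec in config.outcomes:
        mu = _outcome_mean(config, cal, name, spec, cols)
        data[name] = mu + spec.noise_sd * rng.standard_normal(n)

    df = pd.DataFrame(data)
    dictionary = {
        "c1": ColumnDef("confounder_pre", "binary"),
        "c2": ColumnDef("confounder_pre", "binary"),
        "x": ColumnDef("exposure", "binary"),
        "l1": ColumnDef("confounder_post", "binary"),
        "m": ColumnDef(
            "mediator", "categorical", levels=MEDIATOR_LEVELS, reference="parental"
        ),
    }
    if config.include_c3:
        dictionary["c3"] = ColumnDef("confounder_pre", "continuous")
    if config.include_l2:
        dictionary["l2"] = ColumnDef("confounder_post", "continuous")
    for name in config.outcome_names:
        dictionary[name] = ColumnDef("outcome", "continuous")
    order = [c for c in dictionary if c in df.columns]
    return CohortTable(df[order], dictionary)


def assign_design(cohort: CohortTable, config: GeneratorConfig) -> CohortTable:
    """Attach stratum, cluster and design/attrition weights; apply attrition.

    Strata are assigned conditionally on the disadvantage confounder by
    Bayes' rule under the two-stage oversampling scheme, clusters uniformly
    within stratum.  A cluster-level random intercept (SD ``cluster_sd``) is
    added to every outcome.  When an attrition model is configured,
    nonrespondents are dropped and the true inverse response probability is
    folded into the design weight; weights are rescaled to mean 1.
    """
    config.validate()
    if config.n_strata < 1:
        raise ConfigError("n_strata must be >= 1")
    rng = np.random.default_rng(config.seed + 1_000_003)
    df = cohort.df.copy()
    n = len(df)
    rates = config.stratum_rates
    prev = config.stratum_c2_prev
    q = rates / rates.sum()  # sample stratum shares

    # P(stratum | c2) under the two-stage scheme
    c2 = df["c2"].to_numpy(float)
    post = np.where(c2[:, None] == 1.0, q * prev, q * (1.0 - prev))
    post /= post.sum(axis=1, keepdims=True)
    u = rng.random(n)
    stratum = (u[:, None] > post.cumsum(axis=1)).sum(axis=1)
    df["stratum"] = stratum

    cluster_in_stratum = rng.integers(0, config.clusters_per_stratum, size=n)
    df["cluster"] = stratum * config.clusters_per_stratum + cluster_in_stratum

    # cluster random intercepts on outcomes
    if config.cluster_sd > 0:
        n_clusters = config.n_strata * config.clusters_per_stratum
        for name in config.outcome_names:
            effects = rng.normal(0.0, config.cluster_sd, size=n_clusters)
            df[name] = df[name].to_numpy(float) + effects[df["cluster"].to_numpy()]

    w = 1.0 / rates[stratum]

    if config.attrition_model is not None:
        am = dict(config.attrition_model)
        p_resp = expit(
            _lin(am, {"x": df["x"].to_numpy(float), "c2": c2})
        )
        responded = rng.random(n) < p_resp
        df = df.loc[responded].reset_index(drop=True)
        w = w[responded] / p_resp[responded]

    df["design_weight"] = w / w.mean()

    dictionary = dict(cohort.dictionary)
    dictionary["stratum"] = ColumnDef("stratum", "id")
    dictionary["cluster"] = ColumnDef("cluster", "id")
    dictionary["design_weight"] = ColumnDef("design_weight", "continuous")
    return CohortTable(df, dictionary)


def apply_missingness(
    cohort: CohortTable, config: GeneratorConfig, seed: int | None = None
) -> CohortTable:
    """Mask analysis values missing-at-random.

    The missingness propensity of every maskable column depends only on the
    always-observed exposure and (when present) the sampling stratum; the
    intercept is solved so the expected masked fraction equals
    ``missing_rate`` exactly.  Exposure and design columns are never masked.
    """
    if not 0.0 <= config.missing_rate < 1.0:
        raise ConfigError("missing_rate must be in [0, 1)")
    out = cohort.copy()
    if config.missing_rate == 0.0:
        return out
    rng = np.random.default_rng(
        config.seed + 2_000_003 if seed is None else seed
    )
    df = out.df
    x = df["x"].to_numpy(float)
    eta = 0.5 * x
    if "stratum" in df.columns:
        disadvantaged = (
            df["stratum"].to_numpy(int) >= config.n_strata // 2
            if config.n_strata > 1
            else np.zeros(len(df))
        )
        eta = eta + 0.3 * disadvantaged
    g0 = optimize.brentq(
        lambda a: float(np.mean(expit(a + eta))) - config.missing_rate, -20.0, 20.0
    )
    p_miss = expit(g0 + eta)

    never = {"exposure", "stratum", "cluster", "design_weight"}
    maskable = [
        c
        for c, d in out.dictionary.items()
        if d.role not in never and c in df.columns
    ]
    for col in maskable:
        mask = rng.random(len(df)) < p_miss
        if out.dictionary[col].vtype in ("categorical",):
            df[col] = df[col].where(~mask, other=None)
        else:
            df[col] = df[col].mask(mask)
    return out


# --------------------------------------------------------------------------
# true estimands
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class TrueEstimands:
    """Ground-truth ATE / total-effect / CDE values implied by a config."""

    ate: dict[str, dict[str, float]]  # outcome -> non-reference level -> effect
    total_effect: dict[str, float]  # outcome -> effect of X=1 vs 0
    cde: dict[str, dict[str, float]]  # outcome -> mediator level -> effect
    method: str  # "enumeration" or "monte_carlo"

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "ate_mediator": self.ate,
                    "total_effect_x": self.total_effect,
                    "cde": self.cde,
                    "method": self.method,
                },
                indent=2,
            )
        )


def _expected_y_given_xm(
    spec: OutcomeSpec, ocal: dict, x: float, level: str
) -> float:
    """E[Y | do(X=x, M=level)] minus confounder terms (added by caller)."""
    return (
        spec.intercept
        + ocal["coef_x"] * x
        + spec.m_effect(level)
        + x * ocal["interaction"].get(level, 0.0)
    )


def true_estimands(
    config: GeneratorConfig, method: str = "auto", n_mc: int = 1_000_000
) -> TrueEstimands:
    """Ground-truth estimands, by exhaustive enumeration when the structural
    support is fully discrete, otherwise by coupled Monte Carlo at ``n_mc``."""
    config.validate()
    if method == "auto":
        method = "enumeration" if config.is_discrete else "monte_carlo"
    if method == "enumeration":
        if not config.is_discrete:
            raise ConfigError(
                "include_c3/include_l2: enumeration requires a discrete-only config"
            )
        return _estimands_enumeration(config)
    return _estimands_mc(config, n_mc)


def _estimands_mc(config: GeneratorConfig, n_mc: int) -> TrueEstimands:
    cal = _calibration(config)
    rng = np.random.default_rng(_TRUTH_SEED)
    c = _draw_population_c(config, n_mc, rng)
    lin_x = _lin({**dict(config.coef_c_on_x), "intercept": cal["x_intercept"]}, c)
    p_x = expit(lin_x)

    l1b = dict(config.coef_on_l1)
    l2b = dict(config.coef_on_l2)
    u_l1 = rng.random(n_mc)
    eps_l2 = rng.standard_normal(n_mc)

    def l_given(x: float):
        cx = {**c, "x": np.full(n_mc, x)}
        p_l1 = expit(_lin(l1b, cx))
        l1 = (u_l1 < p_l1).astype(float)
        out = {"l1": l1, "p_l1": p_l1}
        if config.include_l2:
            out["l2"] = _lin(l2b, cx) + l2b.get("sd", 1.0) * eps_l2
        return out

    L = {x: l_given(x) for x in (0.0, 1.0)}
    mean_px = float(np.mean(p_x))

    ate: dict[str, dict[str, float]] = {}
    te: dict[str, float] = {}
    cde: dict[str, dict[str, float]] = {}
    for name, spec in config.outcomes:
        ocal = cal["outcomes"][name]
        cl = dict(spec.coef_l)

        # ATE of mediator: only M main effects + interaction at natural X
        ate[name] = {
            lev: spec.m_effect(lev) + mean_px * ocal["interaction"].get(lev, 0.0)
            for lev in MEDIATOR_LEVELS
            if lev != "parental"
        }

        # CDE(m): X main effect + open X->L->Y path + interaction, using the
        # analytic l1 expectation (no extra Monte Carlo noise from l1 draws)
        d_l = cl.get("l1", 0.0) * float(np.mean(L[1.0]["p_l1"] - L[0.0]["p_l1"]))
        if config.include_l2:
            d_l += cl.get("l2", 0.0) * l2b.get("x", 0.0)
        base = ocal["coef_x"] + d_l
        cde[name] = {
            lev: base + ocal["interaction"].get(lev, 0.0) for lev in MEDIATOR_LEVELS
        }

        # total effect: average structural contrast with coupled draws
        def ey(x: float) -> np.ndarray:
            cols = {**c, "x": np.full(n_mc, x), "l1": L[x]["l1"]}
            if config.include_l2:
                cols["l2"] = L[x]["l2"]
            pm = _mediator_probs(config, cal["m_intercepts"], cols)
            mu = ocal["coef_x"] * x
            mu = mu + cl.get("l1", 0.0) * cols["l1"]
            if config.include_l2:
                mu = mu + cl.get("l2", 0.0) * cols["l2"]
            for j, lev in enumerate(MEDIATOR_LEVELS):
                mu = mu + pm[:, j] * (
                    spec.m_effect(lev) + x * ocal["interaction"].get(lev, 0.0)
                )
            return mu

        te[name] = float(np.mean(ey(1.0) - ey(0.0)))
    return TrueEstimands(ate=ate, total_effect=te, cde=cde, method="monte_carlo")


def _discrete_cells(config: GeneratorConfig):
    """Iterate (c1, c2, prob) over the discrete pre-exposure support."""
    p_pop = config.p_c2_population
    for c1 in (0.0, 1.0):
        for c2 in (0.0, 1.0):
            p = (config.p_c1 if c1 else 1 - config.p_c1) * (
                p_pop if c2 else 1 - p_pop
            )
            yield c1, c2, p


def _estimands_enumeration(config: GeneratorConfig) -> TrueEstimands:
    cal = _calibration(config)
    xb = {**dict(config.coef_c_on_x), "intercept": cal["x_intercept"]}
    l1b = dict(config.coef_on_l1)

    def one(arrs):
        return {k: np.asarray([v]) for k, v in arrs.items()}

    ate: dict[str, dict[str, float]] = {n: {} for n in config.outcome_names}
    te: dict[str, float] = {}
    cde: dict[str, dict[str, float]] = {n: {} for n in config.outcome_names}

    mean_px = 0.0
    d_l1 = 0.0
    for c1, c2, pc in _discrete_cells(config):
        cc = one({"c1": c1, "c2": c2})
        mean_px += pc * float(expit(_lin(xb, cc))[0])
        p1 = float(expit(_lin(l1b, {**cc, "x": np.asarray([1.0])}))[0])
        p0 = float(expit(_lin(l1b, {**cc, "x": np.asarray([0.0])}))[0])
        d_l1 += pc * (p1 - p0)

    for name, spec in config.outcomes:
        ocal = cal["outcomes"][name]
        cl = dict(spec.coef_l)
        for lev in MEDIATOR_LEVELS:
            if lev != "parental":
                ate[name][lev] = spec.m_effect(lev) + mean_px * ocal[
                    "interaction"
                ].get(lev, 0.0)
            cde[name][lev] = (
                ocal["coef_x"]
                + cl.get("l1", 0.0) * d_l1
                + ocal["interaction"].get(lev, 0.0)
            )

        total = 0.0
        for c1, c2, pc in _discrete_cells(config):
            cc = {"c1": c1, "c2": c2}
            contrast = 0.0
            for x in (1.0, 0.0):
                sgn = 1.0 if x == 1.0 else -1.0
                p_l1 = float(
                    expit(_lin(l1b, one({**cc, "x": x})))[0]
                )
                for l1, pl in ((1.0, p_l1), (0.0, 1 - p_l1)):
                    cols = one({**cc, "x": x, "l1": l1})
                    pm = _mediator_probs(config, cal["m_intercepts"], cols)[0]
                    ey = ocal["coef_x"] * x + cl.get("l1", 0.0) * l1
                    for j, lev in enumerate(MEDIATOR_LEVELS):
                        ey += pm[j] * (
                            spec.m_effect(lev)
                            + x * ocal["interaction"].get(lev, 0.0)
                        )
                    contrast += sgn * pl * ey
            total += pc * contrast
        te[name] = total
    return TrueEstimands(ate=ate, total_effect=te, cde=cde, method="enumeration")


# --------------------------------------------------------------------------
# exhaustive population table (for saturated-model oracle analyses)
# --------------------------------------------------------------------------


def population_table(config: GeneratorConfig) -> CohortTable:
    """The full discrete population as one row per covariate cell.

    Requires a discrete-only config.  Each row carries the exact cell
    probability as its design weight and the structural conditional outcome
    mean as its outcome value, so saturated weighted analyses of this table
    are population (not sample) computations.
    """
    if not config.is_discrete:
        raise ConfigError("include_c3/include_l2: population_table needs a discrete config")
    config.validate()
    cal = _calibration(config)
    xb = {**dict(config.coef_c_on_x), "intercept": cal["x_intercept"]}
    l1b = dict(config.coef_on_l1)

    rows = []
    for c1, c2, pc in _discrete_cells(config):
        cc = {"c1": np.asarray([c1]), "c2": np.asarray([c2])}
        px1 = float(expit(_lin(xb, cc))[0])
        for x, px in ((1.0, px1), (0.0, 1 - px1)):
            pl1 = float(expit(_lin(l1b, {**cc, "x": np.asarray([x])}))[0])
            for l1, pl in ((1.0, pl1), (0.0, 1 - pl1)):
                cols1 = {k: np.asarray([v]) for k, v in
                         (("c1", c1), ("c2", c2), ("x", x), ("l1", l1))}
                pm = _mediator_probs(config, cal["m_intercepts"], cols1)[0]
                for j, lev in enumerate(MEDIATOR_LEVELS):
                    cell_cols = {
                        **{k: np.asarray([v]) for k, v in
                           (("c1", c1), ("c2", c2), ("x", x), ("l1", l1))},
                        "m_non_centre": np.asarray([float(lev == "non_centre")]),
                        "m_centre": np.asarray([float(lev == "centre")]),
                    }
                    row = {
                        "c1": c1,
                        "c2": c2,
                        "x": x,
                        "l1": l1,
                        "m": lev,
                        "prob": pc * px * pl * pm[j],
                    }
                    for name, spec in config.outcomes:
                        row[name] = float(
                            _outcome_mean(config, cal, name, spec, cell_cols)[0]
                        )
                    rows.append(row)
    df = pd.DataFrame(rows)
    df["design_weight"] = df.pop("prob")
    df["design_weight"] /= df["design_weight"].mean()
    df["stratum"] = 0
    df["cluster"] = np.arange(len(df))
    dictionary = {
        "c1": ColumnDef("confounder_pre", "binary"),
        "c2": ColumnDef("confounder_pre", "binary"),
        "x": ColumnDef("exposure", "binary"),
        "l1": ColumnDef("confounder_post", "binary"),
        "m": ColumnDef("mediator", "categorical", levels=MEDIATOR_LEVELS,
                       reference="parental"),
        **{n: ColumnDef("outcome", "continuous") for n in config.outcome_names},
        "stratum": ColumnDef("stratum", "id"),
        "cluster": ColumnDef("cluster", "id"),
        "design_weight": ColumnDef("design_weight", "continuous"),
    }
    return CohortTable(df, dictionary)
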