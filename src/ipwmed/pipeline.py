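"""Configuration-driven end-to-end analysis pipeline.

One :class:`RunConfig` drives the full analysis plan: generate (or load and
validate) a cohort, standardize outcomes, multiply impute missing values, fit
stabilized weights, estimate ATEs / total effects / controlled direct effects
for the requested research questions, pool across imputations by Rubin's
rules, and write tidy result tables, balance diagnostics and a reproducibility
manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import CausalSpec, CohortTable, SchemaError
from .design import DesignSpec
from .effects import (
    EffectEstimate,
    estimates_to_frame,
    run_question,
    standardize_outcomes,
)
from .mice import ImputationConfig, impute, pool, pooled_to_frame
from .simulate import (
    GeneratorConfig,
    apply_missingness,
    assign_design,
    default_causal_spec,
    generate_cohort,
    true_estimands,
)
from .weights import ModelOptions, ate_weights, balance_report, cde_weights

logger = logging.getLogger("ipwmed")


@dataclass(frozen=True)
class SensitivityVariant:
    """A labelled re-run with a modified adjustment set or mediator column."""

    name: str
    confounders_post: tuple[str, ...] | None = None  # reduced L set (kept columns)
    mediator: str | None = None  # alternative exposure-window mediator column


@dataclass(frozen=True)
class RunConfig:
    input: str = "synthetic"  # "synthetic" or a CSV path
    dictionary: str | None = None  # YAML data dictionary for CSV input
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    causal: CausalSpec | None = None
    imputation: ImputationConfig = field(default_factory=ImputationConfig)
    design: DesignSpec | None = field(default_factory=DesignSpec)
    questions: tuple[int, ...] = (1, 2, 3)
    scenarios: tuple[str, ...] = ("centre", "parental")
    output_dir: str = "results"
    seed: int = 20_210_312
    scale_factor: float = 1.0
    standardize: bool = True
    model_options: ModelOptions = field(default_factory=ModelOptions)
    sensitivity: tuple[SensitivityVariant, ...] = ()

    def __post_init__(self):
        if not self.questions:
            raise ValueError("questions must be nonempty")
        if set(self.questions) - {1, 2, 3}:
            raise ValueError("questions must be a subset of {1, 2, 3}")


def runconfig_from_yaml(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kw: dict = {}
    for simple in (
        "input",
        "dictionary",
        "output_dir",
        "seed",
        "scale_factor",
        "standardize",
    ):
        if simple in raw:
            kw[simple] = raw[simple]
    if "questions" in raw:
        kw["questions"] = tuple(int(q) for q in raw["questions"])
    if "scenarios" in raw:
        kw["scenarios"] = tuple(raw["scenarios"])
    if "generator" in raw:
        kw["generator"] = dataclasses.replace(GeneratorConfig(), **raw["generator"])
    if "imputation" in raw:
        kw["imputation"] = dataclasses.replace(ImputationConfig(), **raw["imputation"])
    if "design" in raw:
        d = raw["design"]
        kw["design"] = DesignSpec(
            stratum_col=d.get("stratum", "stratum"),
            cluster_col=d.get("cluster", "cluster"),
            weight_col=d.get("weight", "design_weight"),
            variance_method=d.get("variance_method", "linearized"),
        )
    if "causal" in raw:
        c = raw["causal"]
        kw["causal"] = CausalSpec(
            exposure=c["exposure"],
            mediator=c["mediator"],
            confounders_pre=tuple(c.get("confounders_pre", ())),
            confounders_post=tuple(c.get("confounders_post", ())),
            outcomes=tuple(c.get("outcomes", ())),
            mediator_levels=tuple(c.get("mediator_levels", ("parental", "non_centre", "centre"))),
            mediator_reference=c.get("mediator_reference", "parental"),
            scenario_levels=tuple(c.get("scenario_levels", ("centre", "parental"))),
        )
    if "model_options" in raw:
        kw["model_options"] = ModelOptions(**raw["model_options"])
    if "sensitivity" in raw:
        kw["sensitivity"] = tuple(
            SensitivityVariant(
                name=v["name"],
                confounders_post=tuple(v["confounders_post"])
                if "confounders_post" in v
                else None,
                mediator=v.get("mediator"),
            )
            for v in raw["sensitivity"]
        )
    return RunConfig(**kw)


# --------------------------------------------------------------------------
# input validation
# --------------------------------------------------------------------------


def validate_input(path: str | Path, dictionary: str | Path) -> CohortTable:
    """Load a CSV + data dictionary, reporting every schema violation at once."""
    cohort = CohortTable.from_files(path, dictionary)
    problems = cohort.validate()
    if problems:
        raise SchemaError(problems)
    logger.info("missingness summary:\n%s", cohort.missingness_summary())
    return cohort


# --------------------------------------------------------------------------
# orchestration
# --------------------------------------------------------------------------


def _config_hash(config: RunConfig) -> str:
    blob = repr(config).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _prepare_cohort(config: RunConfig) -> tuple[CohortTable, CausalSpec, DesignSpec | None]:
    if config.input == "synthetic":
        gen = dataclasses.replace(config.generator, seed=config.seed)
        cohort = generate_cohort(gen)
        cohort = assign_design(cohort, gen)
        if gen.missing_rate > 0:
            cohort = apply_missingness(cohort, gen)
        spec = config.causal or default_causal_spec(gen)
        design = config.design
    else:
        if config.dictionary is None:
            raise ValueError("CSV input requires a data dictionary path")
        cohort = validate_input(config.input, config.dictionary)
        if config.causal is None:
            raise ValueError("CSV input requires an explicit causal spec")
        spec = config.causal
        design = config.design
        if design is not None and design.weight_col not in cohort.df.columns:
            design = None
    problems = spec.check_against(cohort)
    if problems:
        raise SchemaError(problems)
    if design is not None:
        design.check_against(cohort)
    return cohort, spec, design


def _analyze(
    cohort: CohortTable,
    spec: CausalSpec,
    design: DesignSpec | None,
    config: RunConfig,
) -> dict[int, pd.DataFrame]:
    """Impute (if needed), estimate per question per imputation, pool."""
    analysis_cols = list(spec.all_columns())
    any_missing = cohort.df[analysis_cols].isna().any().any()
    if any_missing:
        imp_cfg = dataclasses.replace(config.imputation, seed=config.seed + 1)
        datasets = impute(cohort, imp_cfg)
    else:
        datasets = [cohort]

    per_question: dict[int, list[list[EffectEstimate]]] = {q: [] for q in config.questions}
    for ds in datasets:
        prepared = (
            standardize_outcomes(
                ds, spec, weight_col=design.weight_col if design else None,
                scale_factor=config.scale_factor,
            )
            if config.standardize
            else ds
        )
        for q in config.questions:
            ests = run_question(
                prepared,
                spec,
                q,
                design=design,
                options=config.model_options,
                scale_factor=config.scale_factor,
            )
            per_question[q].append(ests)

    results = {}
    for q in config.questions:
        runs = per_question[q]
        if len(runs) > 1:
            results[q] = pooled_to_frame(pool(runs))
        else:
            results[q] = estimates_to_frame(runs[0])
    return results


def run(config: RunConfig) -> dict:
    """Execute the full pipeline; returns a results bundle (also written to disk)."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stage = "prepare"
    try:
        cohort, spec, design = _prepare_cohort(config)
        stage = "estimate"
        results = _analyze(cohort, spec, design, config)

        # balance diagnostics on a complete version of the cohort
        stage = "balance"
        analysis_cols = list(spec.all_columns())
        if cohort.df[analysis_cols].isna().any().any():
            bal_cohort = impute(
                cohort, dataclasses.replace(config.imputation, m=2, seed=config.seed + 2)
            )[0]
        else:
            bal_cohort = cohort
        wcol = design.weight_col if design else None
        reports = {
            "ate_mediator": balance_report(
                bal_cohort, ate_weights(bal_cohort, spec, wcol, config.model_options),
                spec, wcol,
            ),
            "cde": balance_report(
                bal_cohort, cde_weights(bal_cohort, spec, wcol, config.model_options),
                spec, wcol,
            ),
        }

        stage = "write"
        bundle: dict = {"results": results, "balance": reports}
        for q, frame in results.items():
            frame.to_csv(out_dir / f"effects_question{q}.csv", index=False)
        bal_rows = []
        for name, rep in reports.items():
            t = rep.table.copy()
            t.insert(0, "weighting", name)
            bal_rows.append(t)
        pd.concat(bal_rows).to_csv(out_dir / "balance.csv", index=False)
        (out_dir / "weight_summary.json").write_text(
            json.dumps({k: r.weight_summary for k, r in reports.items()}, indent=2)
        )
        warnings = []
        for name, rep in reports.items():
            t = rep.table
            resid = t[(t.stage == "weighted") & (t.smd.abs() > 0.1)]
            for _, r in resid.iterrows():
                warnings.append(
                    f"{name}: residual imbalance |SMD|={abs(r.smd):.3f} for "
                    f"{r.confounder} ({r.contrast}, {r.stratum})"
                )

        if config.input == "synthetic":
            gen = dataclasses.replace(config.generator, seed=config.seed)
            true_estimands(gen).to_json(out_dir / "true_estimands.json")

        # sensitivity variants: re-run the questions under modified specs
        variants = {}
        for variant in config.sensitivity:
            stage = f"sensitivity:{variant.name}"
            vspec = spec
            if variant.confounders_post is not None:
                vspec = vspec.with_reduced_post_set(variant.confounders_post)
            if variant.mediator is not None:
                vspec = dataclasses.replace(vspec, mediator=variant.mediator)
            vres = _analyze(cohort, vspec, design, config)
            for q, frame in vres.items():
                frame.to_csv(
                    out_dir / f"effects_question{q}_{variant.name}.csv", index=False
                )
            variants[variant.name] = {
                "confounders_post": list(vspec.confounders_post),
                "mediator": vspec.mediator,
            }
        bundle["variants"] = variants

        manifest = {
            "package_version": __version__,
            "seed": config.seed,
            "config_hash": _config_hash(config),
            "n_rows": int(cohort.n),
            "questions": list(config.questions),
            "scenarios": list(config.scenarios),
            "adjustment_sets": {
                "confounders_pre": list(spec.confounders_pre),
                "confounders_post": list(spec.confounders_post),
            },
            "variants": variants,
            "standardize": config.standardize,
            "scale_factor": config.scale_factor,
            "warnings": warnings,
            "versions": {
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        bundle["manifest"] = manifest
        return bundle
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
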