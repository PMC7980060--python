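"""Cohort data model: typed person-level tables and the causal variable roles.

A :class:`CohortTable` couples a rectangular pandas DataFrame (one row per
child) with a data dictionary assigning every analysis column a *role* —
exposure, mediator, pre-exposure confounder (C), post-exposure confounder (L),
outcome, or a survey-design column — and a *type* (binary, categorical,
continuous).  A :class:`CausalSpec` names the column sets entering a causal
analysis: which column is the exposure X, which the 3-level childcare mediator
M, which columns are C vs L, and which outcomes Y are modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

ROLES = frozenset(
    {
        "exposure",
        "mediator",
        "confounder_pre",
        "confounder_post",
        "outcome",
        "stratum",
        "cluster",
        "design_weight",
        "auxiliary",
    }
)
VTYPES = frozenset({"binary", "categorical", "continuous", "id"})

#: canonical childcare mediator levels
MEDIATOR_LEVELS = ("parental", "non_centre", "centre")


class SchemaError(ValueError):
    """A cohort table violates its declared data dictionary."""

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__("; ".join(self.problems))


@dataclass(frozen=True)
class ColumnDef:
    """Role and type declaration for one column."""

    role: str
    vtype: str
    levels: tuple[str, ...] | None = None
    reference: str | None = None

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        if self.vtype not in VTYPES:
            raise ValueError(f"unknown vtype {self.vtype!r}")


@dataclass
class CohortTable:
    """Person-level analysis dataset plus its role/type dictionary."""

    df: pd.DataFrame
    dictionary: dict[str, ColumnDef]

    # -- convenience role accessors -------------------------------------
    def columns_with_role(self, role: str) -> list[str]:
        return [c for c, d in self.dictionary.items() if d.role == role]

    @property
    def n(self) -> int:
        return len(self.df)

    def copy(self) -> "CohortTable":
        return CohortTable(self.df.copy(), dict(self.dictionary))

    # -- validation -----------------------------------------------------
    def validate(self) -> list[str]:
        """Collect (do not raise) every schema violation."""
        problems: list[str] = []
        for col, cdef in self.dictionary.items():
            if col not in self.df.columns:
                problems.append(f"column {col!r} declared but absent from data")
                continue
            s = self.df[col]
            nonmiss = s.dropna()
            if cdef.vtype == "binary":
                bad = set(pd.unique(nonmiss)) - {0, 1, 0.0, 1.0, True, False}
                if bad:
                    problems.append(
                        f"binary column {col!r} has non 0/1 values {sorted(map(str, bad))}"
                    )
            elif cdef.vtype == "categorical":
                if cdef.levels is not None:
                    extra = set(nonmiss.astype(str).unique()) - set(cdef.levels)
                    if extra:
                        problems.append(
                            f"categorical column {col!r} has undeclared level(s) "
                            f"{sorted(extra)}"
                        )
            elif cdef.vtype == "continuous":
                if not pd.api.types.is_numeric_dtype(nonmiss):
                    problems.append(f"continuous column {col!r} is not numeric")
            if cdef.role == "design_weight":
                if nonmiss.isna().any() or (nonmiss <= 0).any() or s.isna().any():
                    problems.append(f"design weight {col!r} must be positive and complete")
        # cluster nesting
        strata = self.columns_with_role("stratum")
        clusters = self.columns_with_role("cluster")
        if strata and clusters and not self.df.empty:
            sc = self.df.groupby(clusters[0], observed=True)[strata[0]].nunique()
            bad = sc[sc > 1]
            if len(bad):
                problems.append(
                    f"cluster(s) {list(bad.index)[:5]} span more than one stratum"
                )
        return problems

    def require_valid(self) -> "CohortTable":
        problems = self.validate()
        if problems:
            raise SchemaError(problems)
        return self

    # -- missingness bookkeeping ----------------------------------------
    def missingness_summary(self) -> pd.DataFrame:
        """Per-column missing fraction, the analogue of a descriptive
        'proportion missing' table."""
        rows = []
        for col in self.dictionary:
            if col in self.df.columns:
                rows.append(
                    {
                        "column": col,
                        "role": self.dictionary[col].role,
                        "n_missing": int(self.df[col].isna().sum()),
                        "prop_missing": float(self.df[col].isna().mean()),
                    }
                )
        return pd.DataFrame(rows)

    # -- serialization --------------------------------------------------
    def to_files(self, csv_path: str | Path, dict_path: str | Path) -> None:
        self.df.to_csv(csv_path, index=False)
        payload = {
            col: {
                "role": d.role,
                "type": d.vtype,
                **({"levels": list(d.levels)} if d.levels else {}),
                **({"reference": d.reference} if d.reference else {}),
            }
            for col, d in self.dictionary.items()
        }
        Path(dict_path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_files(cls, csv_path: str | Path, dict_path: str | Path) -> "CohortTable":
        raw = yaml.safe_load(Path(dict_path).read_text())
        dictionary = {
            col: ColumnDef(
                role=meta["role"],
                vtype=meta["type"],
                levels=tuple(meta["levels"]) if "levels" in meta else None,
                reference=meta.get("reference"),
            )
            for col, meta in raw.items()
        }
        df = pd.read_csv(csv_path)
        # restore declared categorical columns as strings
        for col, d in dictionary.items():
            if d.vtype == "categorical" and col in df.columns:
                df[col] = df[col].astype("object")
        return cls(df, dictionary)


@dataclass(frozen=True)
class CausalSpec:
    """Names the X / M / C / L / Y column sets of one analysis.

    ``scenario_levels`` are the mediator levels at which controlled direct
    effects are evaluated (universal centre-based care; parental care only).
    """

    exposure: str
    mediator: str
    confounders_pre: tuple[str, ...]
    confounders_post: tuple[str, ...]
    outcomes: tuple[str, ...]
    mediator_levels: tuple[str, ...] = MEDIATOR_LEVELS
    mediator_reference: str = "parental"
    exposure_reference: int = 0
    scenario_levels: tuple[str, ...] = ("centre", "parental")

    def __post_init__(self):
        pre, post = set(self.confounders_pre), set(self.confounders_post)
        if pre & post:
            raise ValueError(f"confounder sets overlap: {sorted(pre & post)}")
        special = {self.exposure, self.mediator} | set(self.outcomes)
        if special & (pre | post):
            raise ValueError(
                "exposure/mediator/outcome columns cannot also be confounders: "
                f"{sorted(special & (pre | post))}"
            )
        if self.mediator_reference not in self.mediator_levels:
            raise ValueError(
                f"reference level {self.mediator_reference!r} not among mediator levels"
            )
        if not set(self.scenario_levels) <= set(self.mediator_levels):
            raise ValueError(
                "scenario levels must be declared mediator levels, got "
                f"{sorted(set(self.scenario_levels) - set(self.mediator_levels))}"
            )

    @property
    def nonreference_levels(self) -> tuple[str, ...]:
        return tuple(l for l in self.mediator_levels if l != self.mediator_reference)

    def all_columns(self) -> tuple[str, ...]:
        return (
            (self.exposure, self.mediator)
            + self.confounders_pre
            + self.confounders_post
            + self.outcomes
        )

    def check_against(self, cohort: CohortTable) -> list[str]:
        problems = []
        for col in self.all_columns():
            if col not in cohort.df.columns:
                problems.append(f"spec column {col!r} missing from cohort")
        if self.mediator in cohort.df.columns:
            observed = set(cohort.df[self.mediator].dropna().astype(str).unique())
            extra = observed - set(self.mediator_levels)
            if extra:
                problems.append(
                    f"mediator column {self.mediator!r} has undeclared level(s) {sorted(extra)}"
                )
        return problems

    def with_reduced_post_set(self, keep: Iterable[str]) -> "CausalSpec":
        """Sensitivity variant: restrict the post-exposure adjustment set."""
        keep = tuple(c for c in self.confounders_post if c in set(keep))
        return replace(self, confounders_post=keep)
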