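"""Dataset schema, input validation, outcome derivation and exclusion rules.

The analysis operates on person-level survey records: a continuous BMI (or a
precomputed binary outcome), a positive sampling weight, a two-level group
label (e.g. urban/rural residence) and a set of categorical covariates.
Records from pregnant respondents and records with missing BMI/outcome are
excluded before any estimation, with the exclusion counts retained for audit.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

OVERWEIGHT_BMI_THRESHOLD = 25.0


class DataError(ValueError):
    """Malformed or inconsistent input data."""


class EmptyAnalysisSetError(DataError):
    """No records survive the exclusion rules."""


class DegenerateGroupingError(DataError):
    """The group variable does not take exactly two values after exclusions."""


class ConflictingOutcomeError(DataError):
    """A supplied binary outcome disagrees with the outcome derived from BMI."""


@dataclass(frozen=True)
class Covariate:
    """A categorical covariate: ordered levels and a reference level."""

    name: str
    levels: tuple[str, ...]
    reference: str

    def __post_init__(self) -> None:
        if len(set(self.levels)) != len(self.levels):
            raise DataError(f"covariate {self.name!r}: duplicate levels")
        if self.reference not in self.levels:
            raise DataError(
                f"covariate {self.name!r}: reference {self.reference!r} "
                f"is not one of its levels {self.levels}"
            )

    @property
    def nonreference_levels(self) -> tuple[str, ...]:
        return tuple(l for l in self.levels if l != self.reference)


@dataclass(frozen=True)
class CovariateSchema:
    """Ordered covariate definitions plus the group/outcome/weight contract.

    ``group_levels`` is ordered: the first label is "group 1" (the urban
    analogue, the group whose mean outcome is the minuend of the gap) and the
    second is "group 2" (the rural analogue).
    """

    covariates: tuple[Covariate, ...]
    group_variable: str
    group_levels: tuple[str, str]
    outcome_name: str = "outcome"
    weight_column: str = "weight"
    bmi_column: str = "bmi"
    pregnancy_column: str = "pregnant"

    def __post_init__(self) -> None:
        names = [c.name for c in self.covariates]
        if len(set(names)) != len(names):
            raise DataError("covariate names must be unique")
        if len(self.group_levels) != 2 or self.group_levels[0] == self.group_levels[1]:
            raise DataError("group_levels must be two distinct labels")
        if self.group_variable in names:
            raise DataError("group variable must not repeat a covariate name")

    @property
    def covariate_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.covariates)

    def covariate(self, name: str) -> Covariate:
        for c in self.covariates:
            if c.name == name:
                return c
        raise KeyError(f"unknown covariate {name!r}")

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "covariates": [
                {"name": c.name, "levels": list(c.levels), "reference": c.reference}
                for c in self.covariates
            ],
            "group_variable": self.group_variable,
            "group_levels": list(self.group_levels),
            "outcome_name": self.outcome_name,
            "weight_column": self.weight_column,
            "bmi_column": self.bmi_column,
            "pregnancy_column": self.pregnancy_column,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CovariateSchema":
        return cls(
            covariates=tuple(
                Covariate(c["name"], tuple(c["levels"]), c["reference"])
                for c in d["covariates"]
            ),
            group_variable=d["group_variable"],
            group_levels=tuple(d["group_levels"]),
            outcome_name=d.get("outcome_name", "outcome"),
            weight_column=d.get("weight_column", "weight"),
            bmi_column=d.get("bmi_column", "bmi"),
            pregnancy_column=d.get("pregnancy_column", "pregnant"),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "CovariateSchema":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


@dataclass
class AnalysisDataset:
    """Cleaned person-level records plus the schema and exclusion audit trail.

    ``data`` holds one row per retained record with columns: the group
    variable, every schema covariate (string labels), the binary outcome and
    the sampling weight. Row order of the raw input is preserved.
    """

    data: pd.DataFrame
    schema: CovariateSchema
    n_excluded_pregnant: int = 0
    n_excluded_missing: int = 0
    n_excluded_missing_covariate: int = 0

    def __post_init__(self) -> None:
        s = self.schema
        if len(self.data) == 0:
            raise EmptyAnalysisSetError("no records survive the exclusion rules")
        groups = self.data[s.group_variable].unique()
        if not set(groups) <= set(s.group_levels) or len(groups) != 2:
            raise DegenerateGroupingError(
                f"group variable {s.group_variable!r} must take exactly the two "
                f"levels {s.group_levels}; found {sorted(map(str, groups))}"
            )
        w = self.data[s.weight_column].to_numpy(float)
        if not np.all(np.isfinite(w) & (w > 0)):
            raise DataError("every retained record must have a finite positive weight")
        y = self.data[s.outcome_name].to_numpy()
        if not np.isin(y, [0, 1]).all():
            raise DataError("outcome must be binary 0/1 for every retained record")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def outcome(self) -> np.ndarray:
        return self.data[self.schema.outcome_name].to_numpy(float)

    @property
    def weights(self) -> np.ndarray:
        return self.data[self.schema.weight_column].to_numpy(float)

    def group_mask(self, group: str) -> np.ndarray:
        if group not in self.schema.group_levels:
            raise KeyError(f"unknown group {group!r}")
        return (self.data[self.schema.group_variable] == group).to_numpy()

    def subset(self, mask: np.ndarray) -> "AnalysisDataset":
        """A new dataset restricted to ``mask`` rows (audit counts reset)."""
        return AnalysisDataset(self.data.loc[mask].reset_index(drop=True), self.schema)

    def write_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Outcome derivation
# ---------------------------------------------------------------------------

def derive_outcome(bmi):
    """Binary overweight/obesity indicator: 1 iff BMI >= 25 kg/m^2.

    Accepts a scalar or an array. A missing or non-finite BMI signals a
    missing outcome (``DataError`` for scalars); array inputs must be finite —
    missing values are routed to exclusion upstream, never silently coded.
    """
    arr = np.asarray(bmi, dtype=float)
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        raise DataError("missing outcome: BMI is missing, non-finite or non-positive")
    out = (arr >= OVERWEIGHT_BMI_THRESHOLD).astype(int)
    return int(out) if np.isscalar(bmi) or arr.ndim == 0 else out


def _resolve_outcome(df: pd.DataFrame, schema: CovariateSchema) -> pd.Series:
    """Outcome column from ``outcome`` and/or ``bmi``; NaN marks missing.

    A record carrying both a precomputed outcome and a BMI that derives to a
    different value is a hard error, never a silent preference.
    """
    has_outcome = schema.outcome_name in df.columns
    has_bmi = schema.bmi_column in df.columns
    if not has_outcome and not has_bmi:
        raise DataError(
            f"need an {schema.outcome_name!r} or {schema.bmi_column!r} column"
        )
    derived = None
    if has_bmi:
        bmi = pd.to_numeric(df[schema.bmi_column], errors="coerce")
        ok = np.isfinite(bmi) & (bmi > 0)
        derived = pd.Series(np.where(ok, (bmi >= OVERWEIGHT_BMI_THRESHOLD), np.nan),
                            index=df.index, dtype=float)
    if has_outcome:
        supplied = pd.to_numeric(df[schema.outcome_name], errors="coerce")
        bad = supplied.dropna()[~supplied.dropna().isin([0, 1])]
        if len(bad):
            raise DataError("supplied outcome values must be 0 or 1")
        if derived is not None:
            both = supplied.notna() & derived.notna()
            if (supplied[both] != derived[both]).any():
                n_bad = int((supplied[both] != derived[both]).sum())
                raise ConflictingOutcomeError(
                    f"{n_bad} record(s) have a supplied outcome conflicting "
                    f"with the outcome derived from BMI"
                )
            return supplied.where(supplied.notna(), derived)
        return supplied
    return derived


# ---------------------------------------------------------------------------
# Exclusion rules
# ---------------------------------------------------------------------------

def apply_exclusions(df: pd.DataFrame, schema: CovariateSchema) -> AnalysisDataset:
    """Drop pregnant respondents and records with a missing outcome/BMI.

    Covariate missingness (empty or NaN label) triggers listwise deletion with
    its own logged count, so all model fits share one sample. Returns the
    cleaned :class:`AnalysisDataset`; raw row order is preserved.
    """
    df = df.copy()
    # trim label whitespace; match case-sensitively thereafter
    for col in (*schema.covariate_names, schema.group_variable):
        if col not in df.columns:
            raise DataError(f"missing required column {col!r}")
        df[col] = df[col].astype("string").str.strip()

    outcome = _resolve_outcome(df, schema)

    n_raw = len(df)
    if schema.pregnancy_column in df.columns:
        preg = pd.to_numeric(df[schema.pregnancy_column], errors="coerce").fillna(0)
        pregnant = (preg == 1).to_numpy()
    else:  # synthetic data may omit the flag: no pregnancy exclusions
        pregnant = np.zeros(n_raw, bool)
    missing_outcome = outcome.isna().to_numpy() & ~pregnant

    keep = ~pregnant & ~missing_outcome
    cov_missing = np.zeros(n_raw, bool)
    for c in schema.covariates:
        col = df[c.name]
        bad_level = col.notna() & ~col.isin(c.levels)
        if (bad_level & keep).any():
            example = col[bad_level & keep].iloc[0]
            raise DataError(
                f"covariate {c.name!r}: value {example!r} is not a declared level"
            )
        cov_missing |= (col.isna() | (col == "")).to_numpy()
    grp = df[schema.group_variable]
    bad_grp = grp.notna() & ~grp.isin(schema.group_levels)
    if (bad_grp & keep).any():
        raise DataError(
            f"group variable {schema.group_variable!r}: value "
            f"{grp[bad_grp & keep].iloc[0]!r} is not one of {schema.group_levels}"
        )
    cov_missing |= grp.isna().to_numpy()
    cov_missing &= keep
    keep &= ~cov_missing

    if not keep.any():
        raise EmptyAnalysisSetError("no records survive the exclusion rules")

    out = df.loc[keep].copy()
    out[schema.outcome_name] = outcome[keep].astype(int)
    out[schema.weight_column] = pd.to_numeric(
        out[schema.weight_column], errors="coerce"
    )
    cols = [schema.group_variable, *schema.covariate_names,
            schema.outcome_name, schema.weight_column]
    if "id" in out.columns:
        cols = ["id"] + cols
    return AnalysisDataset(
        out[cols].reset_index(drop=True),
        schema,
        n_excluded_pregnant=int(pregnant.sum()),
        n_excluded_missing=int(missing_outcome.sum()),
        n_excluded_missing_covariate=int(cov_missing.sum()),
    )


def read_dataset(path: str | Path, schema: CovariateSchema) -> AnalysisDataset:
    """Read a comma-delimited file with a header row and apply exclusions."""
    df = pd.read_csv(path)
    if schema.weight_column not in df.columns:
        raise DataError(f"missing weight column {schema.weight_column!r}")
    return apply_exclusions(df, schema)


# ---------------------------------------------------------------------------
# Design-matrix encoding
# ---------------------------------------------------------------------------

def encode_design_matrix(
    data: pd.DataFrame | AnalysisDataset,
    schema: CovariateSchema | None = None,
    covariates: Sequence[str] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Intercept + reference-coded (k-1) indicator columns per covariate.

    Column labels are ``"covariate=level"`` (the intercept is ``"constant"``);
    row order matches record order. A level absent from the data leaves an
    all-zero column, which is retained (cross-group counterfactual predictions
    need both groups encoded on one layout) with a warning.
    """
    if isinstance(data, AnalysisDataset):
        schema = schema or data.schema
        df = data.data
    else:
        if schema is None:
            raise TypeError("schema is required when passing a bare DataFrame")
        df = data
    names = list(covariates) if covariates is not None else list(schema.covariate_names)
    cols: list[np.ndarray] = [np.ones(len(df))]
    labels = ["constant"]
    for name in names:
        cov = schema.covariate(name)
        values = df[name].to_numpy()
        for level in cov.nonreference_levels:
            ind = (values == level).astype(float)
            if ind.sum() == 0:
                warnings.warn(
                    f"level {name}={level!r} absent from the data; "
                    f"all-zero column retained", stacklevel=2,
                )
            cols.append(ind)
            labels.append(f"{name}={level}")
    return np.column_stack(cols), labels


def decode_design_row(
    row: np.ndarray, labels: Sequence[str], schema: CovariateSchema
) -> dict[str, str]:
    """Invert one encoded row back to its category labels (round-trip check)."""
    out: dict[str, str] = {}
    seen: dict[str, str] = {}
    for value, label in zip(row, labels):
        if label == "constant":
            continue
        name, level = label.split("=", 1)
        if value == 1.0:
            if name in seen:
                raise DataError(f"row sets two levels for covariate {name!r}")
            seen[name] = level
    for label in labels:
        if label == "constant":
            continue
        name = label.split("=", 1)[0]
        out[name] = seen.get(name, schema.covariate(name).reference)
    return out
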