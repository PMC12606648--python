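"""Reading, writing and validating the flat assay table.

The on-disk representation is a plain UTF-8 CSV with a header row.  Missing
categorical cells are mapped to the reserved level ``"NA"`` at load time and
written back as the literal token ``NA`` — the level round-trips.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .schema import CONDITION_FIELDS, NA_LEVEL, DatasetSchema, SchemaError


class ParseError(ValueError):
    """A cell could not be parsed under its column's role."""


@dataclass
class ConditionVector:
    """The 11 categorical boundary conditions of one assay record."""

    values: dict[str, str]

    def as_tuple(self, fields=CONDITION_FIELDS) -> tuple[str, ...]:
        return tuple(self.values[f] for f in fields)


@dataclass
class AssayRecord:
    """One compound × assay observation."""

    compound_id: str
    target_id: str
    activity_value: float
    conditions: ConditionVector
    drug: dict[str, float]
    protein: dict[str, float]
    variables: dict[str, float]
    label: int | None = None


@dataclass
class Dataset:
    """An ordered collection of assay records, pandas-backed.

    ``df`` holds one row per record; ``schema`` maps columns to roles.
    """

    df: pd.DataFrame
    schema: DatasetSchema

    def __post_init__(self) -> None:
        missing = [c for c in self.schema.required_columns if c not in self.df.columns]
        if missing:
            raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
        if (self.df[self.schema.compound_column].astype(str).str.len() == 0).any():
            raise SchemaError("empty compound_id")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_compounds(self) -> int:
        return self.df[self.schema.compound_column].nunique()

    @property
    def conditions(self) -> pd.DataFrame:
        """The c0..c10 block, columns renamed to canonical field names."""
        cmap = self.schema.condition_map
        return self.df[list(cmap.values())].rename(
            columns={v: k for k, v in cmap.items()}
        )

    @property
    def descriptors(self) -> pd.DataFrame:
        return self.df[self.schema.descriptor_columns]

    @property
    def activity(self) -> pd.Series:
        return self.df[self.schema.activity_column]

    @property
    def labels(self) -> pd.Series | None:
        if self.schema.label_column in self.df.columns:
            return self.df[self.schema.label_column]
        return None

    def with_labels(self, labels: pd.Series) -> "Dataset":
        df = self.df.copy()
        df[self.schema.label_column] = labels.to_numpy()
        return Dataset(df, self.schema)

    def records(self):
        """Iterate rows as :class:`AssayRecord` objects (convenience view)."""
        s = self.schema
        cmap = s.condition_map
        labels = self.labels
        for i, row in self.df.iterrows():
            yield AssayRecord(
                compound_id=str(row[s.compound_column]),
                target_id=str(row[s.target_column]),
                activity_value=float(row[s.activity_column]),
                conditions=ConditionVector(
                    {f: str(row[col]) for f, col in cmap.items()}
                ),
                drug={c: float(row[c]) for c in s.drug_descriptor_columns},
                protein={c: float(row[c]) for c in s.protein_descriptor_columns},
                variables={c: float(row[c]) for c in s.variable_columns},
                label=None if labels is None else int(labels.loc[i]),
            )


@dataclass
class ValidationReport:
    n_records: int
    n_compounds: int
    missingness: dict[str, float]
    condition_cardinality: dict[str, int]
    descriptor_ranges: dict[str, tuple[float, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_records": self.n_records,
            "n_compounds": self.n_compounds,
            "missingness": self.missingness,
            "condition_cardinality": self.condition_cardinality,
            "descriptor_ranges": {
                k: list(v) for k, v in self.descriptor_ranges.items()
            },
        }


def _coerce_numeric(df: pd.DataFrame, columns, allow_missing=(), label="") -> None:
    """In-place numeric coercion with row-indexed error reporting."""
    for col in columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        raw_missing = df[col].isna() | (df[col].astype(str).str.strip() == "")
        bad = converted.isna() & ~raw_missing
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"non-numeric value {df[col].iloc[row]!r} in column {col!r} "
                f"at row {row}"
            )
        if col not in allow_missing and converted.isna().any():
            row = int(np.flatnonzero(converted.isna().to_numpy())[0])
            raise ParseError(f"missing {label or 'numeric'} value in column "
                             f"{col!r} at row {row}")
        df[col] = converted.astype(float)


def load_dataset(path, schema: DatasetSchema) -> Dataset:
    """Read the flat CSV into a validated :class:`Dataset`.

    Missing categorical cells become the reserved ``"NA"`` level.  Descriptor
    cells must be finite; assay variables may be missing.  Raises
    :class:`SchemaError` for a missing mandatory column and
    :class:`ParseError` (with the row index) for a non-numeric descriptor.
    """
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False,
                         na_values=[""], skipinitialspace=False)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"empty file: {path}") from exc
    missing = [c for c in schema.required_columns if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")

    for col in schema.condition_columns:
        df[col] = df[col].fillna(NA_LEVEL).replace("", NA_LEVEL).astype(str)
    df[schema.compound_column] = df[schema.compound_column].astype(str)

    _coerce_numeric(df, [schema.activity_column], label="activity")
    _coerce_numeric(
        df,
        schema.drug_descriptor_columns + schema.protein_descriptor_columns,
        label="descriptor",
    )
    _coerce_numeric(df, schema.variable_columns,
                    allow_missing=schema.variable_columns)
    for col in schema.variable_columns:
        if (df[col].dropna() < 0).any():
            raise ParseError(f"negative concentration in column {col!r}")

    desc = schema.drug_descriptor_columns + schema.protein_descriptor_columns
    if desc and not np.isfinite(df[desc].to_numpy(float)).all():
        raise ParseError("non-finite descriptor value")

    if schema.label_column in df.columns:
        _coerce_numeric(df, [schema.label_column],
                        allow_missing=[schema.label_column])
        vals = df[schema.label_column].dropna().unique()
        if not set(vals) <= {0.0, 1.0}:
            raise ParseError("label column must be in {0, 1}")

    return Dataset(df, schema)


def write_dataset(ds: Dataset, path) -> None:
    """Write the dataset as CSV, column order from the registry."""
    cols = list(ds.schema.required_columns)
    if ds.schema.label_column in ds.df.columns:
        cols.append(ds.schema.label_column)
    ds.df[cols].to_csv(path, index=False)


def validate_dataset(ds: Dataset) -> ValidationReport:
    """Report-only profile: missingness, condition cardinalities, ranges."""
    s = ds.schema
    missingness = {}
    for col in s.required_columns:
        if col in s.condition_columns:
            frac = float((ds.df[col] == NA_LEVEL).mean()) if len(ds.df) else 0.0
        else:
            frac = float(ds.df[col].isna().mean()) if len(ds.df) else 0.0
        missingness[col] = frac
    cardinality = {
        f: int(ds.df[col].nunique()) for f, col in s.condition_map.items()
    }
    ranges = {}
    for col in s.descriptor_columns:
        vals = ds.df[col].dropna()
        if len(vals):
            ranges[col] = (float(vals.min()), float(vals.max()))
    return ValidationReport(
        n_records=len(ds),
        n_compounds=ds.n_compounds,
        missingness=missingness,
        condition_cardinality=cardinality,
        descriptor_ranges=ranges,
    )
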