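"""Column registry for the flat assay table.

An assay table has one row per (compound, assay) observation.  Besides the
compound identifier and the raw activity value, every column belongs to one
of four roles:

* 11 categorical *boundary conditions* ``c0``–``c10`` (activity-measure
  class, target name, cell type, tissue, organisms, target type,
  subcellular fraction, buffer, standard relation, assay type),
* continuous *drug descriptors* (molecular weight, rule-of-five count,
  AlogP and the Markovian electronegativity / van der Waals / AlogP
  atomic-contribution blocks),
* continuous *protein-domain descriptors* (electronegativity of three
  domains at five propagation levels),
* *assay variables* (substrate and inhibitor concentration, μM).

The registry is externalised so that both the deposited table's headers and
synthetic headers can be mapped onto these roles without code changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

#: reserved level representing a missing categorical value; it is a real
#: grouping level, not an NA sentinel to be dropped.
NA_LEVEL = "NA"

#: canonical names of the 11 boundary-condition fields, in order.
CONDITION_FIELDS = tuple(f"c{i}" for i in range(11))

#: legal levels of the standard-relation field c9.
C9_LEVELS = ("=", ">", "<")

#: legal levels of the assay-type field c10 (binding, functional, ADMET,
#: physicochemical).
C10_LEVELS = ("B", "F", "A", "P")

#: condition fields entering the assay-condition grouping (c_assay).
ASSAY_GROUP = ("c1", "c2", "c3", "c4", "c5")

#: condition fields entering the data-condition grouping (c_dat).
DAT_GROUP = ("c6", "c7", "c8", "c9", "c10")


class SchemaError(ValueError):
    """A column required by the registry is missing or malformed."""


@dataclass
class DatasetSchema:
    """Maps physical CSV columns onto their pipeline roles.

    ``condition_columns`` must list exactly 11 columns, in c0..c10 order.
    """

    compound_column: str = "compound_id"
    activity_column: str = "activity_value"
    condition_columns: list[str] = field(
        default_factory=lambda: list(CONDITION_FIELDS)
    )
    drug_descriptor_columns: list[str] = field(default_factory=list)
    protein_descriptor_columns: list[str] = field(default_factory=list)
    variable_columns: list[str] = field(default_factory=list)
    label_column: str = "f_obj"

    def __post_init__(self) -> None:
        if len(self.condition_columns) != len(CONDITION_FIELDS):
            raise SchemaError(
                f"condition_columns must have {len(CONDITION_FIELDS)} entries "
                f"(c0..c10), got {len(self.condition_columns)}"
            )

    # -- derived views ----------------------------------------------------
    @property
    def condition_map(self) -> dict[str, str]:
        """Canonical field name (c0..c10) -> physical column name."""
        return dict(zip(CONDITION_FIELDS, self.condition_columns))

    @property
    def target_column(self) -> str:
        """The target is identified by c1 (target name)."""
        return self.condition_columns[1]

    @property
    def descriptor_columns(self) -> list[str]:
        """All continuous columns entering the perturbation features."""
        return (
            list(self.drug_descriptor_columns)
            + list(self.protein_descriptor_columns)
            + list(self.variable_columns)
        )

    @property
    def required_columns(self) -> list[str]:
        return (
            [self.compound_column, self.activity_column]
            + list(self.condition_columns)
            + self.descriptor_columns
        )

    def role_of(self, column: str) -> str:
        if column == self.compound_column:
            return "identifier"
        if column == self.activity_column:
            return "activity"
        if column == self.label_column:
            return "label"
        if column in self.condition_columns:
            return "condition"
        if column in self.drug_descriptor_columns:
            return "drug"
        if column in self.protein_descriptor_columns:
            return "protein"
        if column in self.variable_columns:
            return "variable"
        raise SchemaError(f"column {column!r} not covered by the registry")

    # -- (de)serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "compound_column": self.compound_column,
            "activity_column": self.activity_column,
            "condition_columns": list(self.condition_columns),
            "drug_descriptor_columns": list(self.drug_descriptor_columns),
            "protein_descriptor_columns": list(self.protein_descriptor_columns),
            "variable_columns": list(self.variable_columns),
            "label_column": self.label_column,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DatasetSchema":
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "DatasetSchema":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))
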