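"""Readers and writers for every external representation the pipeline touches.

All format dialects are isolated here: raw microarray spot tables (TSV),
GMT gene-set files, interaction lists for pathway sign-consistency checks,
and generic results tables. Gene identity is the symbol string,
case-preserved; matching against gene sets is case-insensitive.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "SpotTable",
    "GeneSet",
    "InteractionList",
    "ROLES",
    "read_spot_table",
    "read_spot_tables",
    "write_spot_table",
    "read_gene_sets",
    "read_interaction_list",
    "write_results_table",
    "read_results_table",
    "parse_sample_label",
]


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


SPOT_COLUMNS = ["spot_id", "gene", "sample", "fg", "bg", "flag"]
FLAG_VALUES = {"ok", "corrupted"}

#: partner roles in an interaction list; + roles expect synergistic
#: expression with the center block, − roles antagonistic.
ROLES = (
    "upstream_activator",
    "upstream_inhibitor",
    "downstream_activated",
    "downstream_inhibited",
)

# Column aliases for tables exported from Agilent-style feature extraction.
_AGILENT_ALIASES = {
    "ProbeName": "spot_id",
    "GeneName": "gene",
    "Sample": "sample",
    "gMedianSignal": "fg",
    "gBGMedianSignal": "bg",
    "gIsFeatNonUnifOL": "flag",
}


def parse_sample_label(label: str) -> tuple[str, int]:
    """Split a "<phenotype>.<replica>" sample label.

    The replica index is 1-based. Raises :class:`ValidationError` if the
    label does not parse.
    """
    head, sep, tail = str(label).rpartition(".")
    if not sep or not tail.isdigit() or int(tail) < 1 or not head:
        raise ValidationError(
            f"sample label {label!r} does not parse as <phenotype>.<replica>"
        )
    return head, int(tail)


@dataclass
class SpotTable:
    """Raw per-array spot measurements.

    ``data`` holds one row per (spot, sample) with the mandatory columns
    ``spot_id, gene, sample, fg, bg, flag``; unknown input columns are
    preserved as opaque metadata. Control spots carry an empty gene symbol
    and are excluded from all downstream statistics.
    """

    array_id: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        df = self.data
        for col in SPOT_COLUMNS:
            if col not in df.columns:
                raise FormatError(f"missing mandatory column {col!r}")
        for col in ("fg", "bg"):
            vals = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
            bad = ~np.isfinite(vals) | (vals < 0)
            if bad.any():
                row = int(np.argmax(bad)) + 1
                raise ValidationError(
                    f"array {self.array_id}: non-finite or negative {col} at row {row}"
                )
        badflag = ~df["flag"].isin(FLAG_VALUES)
        if badflag.any():
            raise ValidationError(
                f"array {self.array_id}: flag must be one of {sorted(FLAG_VALUES)}"
            )
        dup = df.duplicated(subset=["spot_id", "sample"])
        if dup.any():
            sid = df.loc[dup, "spot_id"].iloc[0]
            raise ValidationError(
                f"array {self.array_id}: duplicate spot_id {sid!r} within a sample"
            )
        for label in df["sample"].unique():
            parse_sample_label(label)

    @property
    def samples(self) -> list[str]:
        return list(dict.fromkeys(self.data["sample"]))

    @property
    def spot_ids(self) -> list[str]:
        return list(dict.fromkeys(self.data["spot_id"]))


@dataclass
class GeneSet:
    """A named pathway membership list (e.g. CHS, AKT, GLU, GAB...)."""

    name: str
    genes: list[str]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"gene set {self.name!r} is empty")
        seen: dict[str, None] = {}
        for g in self.genes:
            seen.setdefault(g, None)
        self.genes = list(seen)

    def symbols_ci(self) -> set[str]:
        """Case-folded symbols, for case-insensitive membership tests."""
        return {g.casefold() for g in self.genes}


@dataclass
class InteractionList:
    """A center gene block plus annotated upstream/downstream partners."""

    center_block: list[str]
    partners: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        df = self.partners
        if not {"gene", "role"}.issubset(df.columns):
            raise FormatError("interaction list needs columns gene, role")
        bad = ~df["role"].isin(ROLES)
        if bad.any():
            raise ValidationError(
                f"unknown role {df.loc[bad, 'role'].iloc[0]!r}; expected one of {ROLES}"
            )
        conflicts = df.groupby(df["gene"].str.casefold())["role"].nunique()
        if (conflicts > 1).any():
            g = conflicts[conflicts > 1].index[0]
            raise ValidationError(f"partner {g!r} listed with conflicting roles")
        self.partners = df.drop_duplicates(subset=["gene", "role"]).reset_index(
            drop=True
        )


def read_spot_table(path: str | os.PathLike, dialect: str = "simple_tsv") -> SpotTable:
    """Read one raw spot table (one array, possibly several samples)."""
    if dialect not in ("simple_tsv", "agilent_like"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"spot_id": str},
        keep_default_na=False,
        float_precision="round_trip",  # fg/bg must re-parse losslessly
    )
    if dialect == "agilent_like":
        df = df.rename(columns=_AGILENT_ALIASES)
        if "flag" in df.columns and df["flag"].dtype != object:
            df["flag"] = df["flag"].map({0: "ok", 1: "corrupted"})
    for col in SPOT_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    df["spot_id"] = df["spot_id"].astype(str)
    df["gene"] = df["gene"].astype(str)
    df["fg"] = pd.to_numeric(df["fg"])
    df["bg"] = pd.to_numeric(df["bg"])
    array_id = os.path.splitext(os.path.basename(os.fspath(path)))[0]
    return SpotTable(array_id=array_id, data=df)


def read_spot_tables(directory: str | os.PathLike, dialect: str = "simple_tsv") -> list[SpotTable]:
    """Read every ``*.tsv`` spot table in a directory, sorted by name."""
    paths = sorted(
        os.path.join(directory, f)
        for f in os.listdir(directory)
        if f.endswith(".tsv")
    )
    if not paths:
        raise FormatError(f"no .tsv spot tables found in {directory}")
    return [read_spot_table(p, dialect=dialect) for p in paths]


def write_spot_table(table: SpotTable, path: str | os.PathLike) -> None:
    table.data.to_csv(path, sep="\t", index=False)


def read_gene_sets(path: str | os.PathLike) -> list[GeneSet]:
    """Parse a GMT file: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3"
                )
            name, desc, *genes = fields
            genes = [g for g in genes if g.strip()]
            if not genes:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} has no genes")
            sets.append(GeneSet(name=name, genes=genes, description=desc))
    return sets


def read_interaction_list(
    path: str | os.PathLike, center_block: list[str]
) -> InteractionList:
    """Read a partner TSV (columns gene, role) for a given center block."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return InteractionList(center_block=list(center_block), partners=df)


def write_results_table(records, path: str | os.PathLike) -> None:
    """Write any tabular result as TSV, floats at 6 significant digits.

    ``records`` may be a DataFrame or a non-empty homogeneous sequence of
    dicts/dataclass instances. Writing an empty table is an error.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        rows = list(records)
        if not rows:
            raise ValidationError("refusing to write an empty results table")
        if hasattr(rows[0], "__dataclass_fields__"):
            rows = [vars(r) for r in rows]
        df = pd.DataFrame(rows)
    if df.empty:
        raise ValidationError("refusing to write an empty results table")
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_results_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
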