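"""Data model and tabular I/O for multi-parallel qRT-PCR experiments.

The experiment layout is a full factorial of genotype x time point (days of
in vitro culture) x biological replicate.  Each sample was measured in a PCR
run (plate) that also carried technical replicate wells of a reference gene
(ubiquitin, AT1G55060, by default); relative quantification normalizes every
gene's Ct against the median of those wells.

Canonical file formats (TSV, UTF-8):

* Ct file      -- columns ``gene_id genotype time_point replicate run_id ct``;
  rows whose ``gene_id`` equals the reference gene are routed to the per-run
  reference wells rather than the gene records.
* Annotation   -- columns ``gene_id family categories hormone_class``;
  ``categories`` is ``;``-separated, later columns optional.
* Phenotype    -- columns ``line replicate efficiency productivity``.
"""

from __future__ import annotations

import dataclasses
import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    CtRangeError,
    DuplicateRecordError,
    FormatError,
    MissingReferenceError,
)

DEFAULT_REFERENCE_GENE = "AT1G55060"
DEFAULT_CEILING = 40.0

CT_COLUMNS = ("gene_id", "genotype", "time_point", "replicate", "run_id", "ct")
PHENOTYPE_COLUMNS = ("line", "replicate", "efficiency", "productivity")


@dataclass(frozen=True, order=True)
class SampleDesign:
    """One biological sample: genotype x time point (days) x replicate.

    ``run_id`` names the PCR run/plate on which the sample was measured,
    linking it to that run's reference-gene wells.
    """

    genotype: str
    time_point: int
    replicate: int
    run_id: str

    @property
    def condition(self) -> tuple[str, int]:
        return (self.genotype, self.time_point)


@dataclass
class CtTable:
    """Per-(gene, sample) Ct measurements plus per-run reference wells.

    ``records`` has the columns of :data:`CT_COLUMNS`.  A Ct equal to
    ``ceiling`` (40 cycles by default) encodes an undetected transcript.
    """

    records: pd.DataFrame
    reference_wells: dict[str, list[float]]
    reference_gene_id: str = DEFAULT_REFERENCE_GENE
    ceiling: float = DEFAULT_CEILING

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        df = self.records
        missing = [c for c in CT_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"Ct records missing column(s): {', '.join(missing)}")
        ct = df["ct"].to_numpy(dtype=float)
        bad = np.flatnonzero(~((ct > 0) & (ct <= self.ceiling)))
        if bad.size:
            i = int(bad[0])
            raise CtRangeError(
                f"ct value {ct[i]} outside (0, {self.ceiling}] at record {i}"
            )
        dup = df.duplicated(subset=["gene_id", "genotype", "time_point", "replicate"])
        if dup.any():
            row = df[dup].iloc[0]
            raise DuplicateRecordError(
                "duplicate record for gene "
                f"{row['gene_id']} / ({row['genotype']}, {row['time_point']} d, "
                f"rep {row['replicate']})"
            )
        for run in df["run_id"].unique():
            if not self.reference_wells.get(run):
                raise MissingReferenceError(
                    f"run {run!r} has no reference-gene wells"
                )

    # -- convenience accessors -------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return sorted(self.records["gene_id"].unique())

    @property
    def genotypes(self) -> list[str]:
        return sorted(self.records["genotype"].unique())

    @property
    def time_points(self) -> list[int]:
        return sorted(int(t) for t in self.records["time_point"].unique())

    def n_replicates(self, genotype: str, time_point: int) -> int:
        df = self.records
        mask = (df["genotype"] == genotype) & (df["time_point"] == time_point)
        return int(df.loc[mask, "replicate"].nunique())


@dataclass
class AnnotationTable:
    """User-supplied flat gene annotation.

    ``categories`` maps a gene to a (possibly empty) set of functional
    categories: a gene with an empty set is "not annotated"; a gene may carry
    several categories and is counted once per category in tallies.
    """

    family: dict[str, str] = field(default_factory=dict)
    categories: dict[str, set[str]] = field(default_factory=dict)
    hormone_class: dict[str, str | None] = field(default_factory=dict)


@dataclass(frozen=True)
class PhenotypeAssay:
    """Per-replicate somatic-embryogenesis capacity of one line.

    ``efficiency`` is the percentage of explants forming somatic embryos;
    ``productivity`` is the mean number of embryos per responding explant.
    """

    line: str
    replicate: int
    efficiency: float
    productivity: float

    def __post_init__(self) -> None:
        if not 0 <= self.efficiency <= 100:
            raise FormatError(
                f"efficiency {self.efficiency} outside [0, 100] for {self.line}"
            )
        if self.productivity < 0:
            raise FormatError(
                f"productivity {self.productivity} < 0 for {self.line}"
            )


# ---------------------------------------------------------------------------
# readers


def _read_frame(path: str | Path, dialect: str) -> pd.DataFrame:
    if dialect not in ("tsv", "csv"):
        raise FormatError(f"unknown dialect {dialect!r}; use 'tsv' or 'csv'")
    sep = "\t" if dialect == "tsv" else ","
    return pd.read_csv(path, sep=sep)


def read_ct_table(
    path: str | Path,
    dialect: str = "tsv",
    reference_gene_id: str = DEFAULT_REFERENCE_GENE,
    ceiling: float = DEFAULT_CEILING,
) -> CtTable:
    """Read a Ct file; reference-gene rows become per-run reference wells.

    Raises :class:`FormatError` for missing columns, :class:`CtRangeError`
    (naming the offending file row) for Ct values outside (0, ceiling], and
    :class:`DuplicateRecordError` for repeated (gene, sample) records.
    """
    df = _read_frame(path, dialect)
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    ct = pd.to_numeric(df["ct"], errors="coerce")
    bad = np.flatnonzero(~((ct > 0) & (ct <= ceiling)))
    if bad.size:
        i = int(bad[0])
        # +2: one for the header line, one for 1-based numbering
        raise CtRangeError(
            f"{path}: line {i + 2}: ct value {df['ct'].iloc[i]!r} "
            f"outside (0, {ceiling}]"
        )
    is_ref = df["gene_id"] == reference_gene_id
    wells: dict[str, list[float]] = {}
    for run, grp in df[is_ref].groupby("run_id"):
        wells[str(run)] = [float(v) for v in grp["ct"]]
    records = df[~is_ref].reset_index(drop=True)
    records = records.astype({"time_point": int, "replicate": int, "ct": float})
    records["run_id"] = records["run_id"].astype(str)
    return CtTable(
        records=records[list(CT_COLUMNS)],
        reference_wells=wells,
        reference_gene_id=reference_gene_id,
        ceiling=ceiling,
    )


def read_annotation_table(path: str | Path, dialect: str = "tsv") -> AnnotationTable:
    """Read a gene annotation file (family / categories / hormone class).

    Only ``gene_id`` is mandatory; an annotation may cover genes that are
    absent from the Ct table.  An empty categories cell means "not annotated".
    """
    df = _read_frame(path, dialect)
    if "gene_id" not in df.columns:
        raise FormatError(f"{path}: missing required column: gene_id")
    table = AnnotationTable()
    for i, row in df.iterrows():
        gene = str(row["gene_id"])
        if "family" in df.columns and not _is_blank(row.get("family")):
            table.family[gene] = str(row["family"]).strip()
        if "categories" in df.columns:
            table.categories[gene] = _parse_categories(
                row.get("categories"), path, int(i) + 2
            )
        if "hormone_class" in df.columns:
            val = row.get("hormone_class")
            table.hormone_class[gene] = None if _is_blank(val) else str(val).strip()
    return table


def _is_blank(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return isinstance(value, str) and not value.strip()


def _parse_categories(cell, path, line: int) -> set[str]:
    if _is_blank(cell):
        return set()
    parts = [p.strip() for p in str(cell).split(";")]
    if any(not p for p in parts):
        raise FormatError(
            f"{path}: line {line}: malformed multi-value categories cell {cell!r}"
        )
    return set(parts)


def read_phenotype_table(path: str | Path, dialect: str = "tsv") -> list[PhenotypeAssay]:
    """Read per-replicate SE efficiency/productivity assays."""
    df = _read_frame(path, dialect)
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    return [
        PhenotypeAssay(
            line=str(r["line"]),
            replicate=int(r["replicate"]),
            efficiency=float(r["efficiency"]),
            productivity=float(r["productivity"]),
        )
        for _, r in df.iterrows()
    ]


# ---------------------------------------------------------------------------
# writer

#: column-name fragments rendered in scientific notation (p-values and FDRs)
_SCIENTIFIC_HINTS = ("_p", "p_value", "pvalue", "fdr")


def _is_pvalue_column(name: str) -> bool:
    low = name.lower()
    return (
        low.endswith("_p")
        or low.startswith("p_")
        or any(h in low for h in _SCIENTIFIC_HINTS[1:])
    )


def _format_cell(value, column: str) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return "NA"
    if isinstance(value, (bool, np.bool_)):
        return "true" if value else "false"
    if isinstance(value, (int, np.integer)):
        return str(int(value))
    if isinstance(value, (float, np.floating)):
        if _is_pvalue_column(column):
            return f"{float(value):.3e}"
        return f"{float(value):.4f}"
    return str(value)


def write_table(rows, path: str | Path) -> None:
    """Write a result table as a byte-stable TSV.

    Fixed contract: column order as given, floats to 4 decimals, p-value-like
    columns (``*_p``, ``*fdr*``) in scientific notation, missing values as
    ``NA``, ``\\n`` line endings.  ``rows`` may be a DataFrame or a sequence
    of dataclass instances; an empty sequence of dataclasses is not writable
    (pass a DataFrame with the desired columns for a header-only file).
    """
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        rows = list(rows)
        if rows and dataclasses.is_dataclass(rows[0]):
            df = pd.DataFrame([dataclasses.asdict(r) for r in rows])
        else:
            df = pd.DataFrame(rows)
    columns = [str(c) for c in df.columns]
    lines = ["\t".join(columns)]
    for _, row in df.iterrows():
        lines.append("\t".join(_format_cell(row[c], c) for c in df.columns))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
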