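"""Tabular I/O with strict validation.

Canonical on-disk dialect is tab-separated UTF-8 with ``NA`` as the missing
marker; comma-separated files are accepted on read via delimiter sniffing.
Missing intensities are carried in memory as ``NaN`` and are distinct from an
observed zero (which downstream log-ratio code rejects loudly rather than
silently dropping).

A quantification file holds one protein per row: the accession key, the four
metadata columns (``gene_name``, ``n_unique_peptides``, ``quality_score``,
``coverage_pct``), then one intensity column per sample. The design table maps
each sample column to (animal, condition CT/LPS, time point T0/T50/T90,
technical replicate); annotations travel in GMT format.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DesignError, FormatError

PROTEIN_KEY = "protein_id"
METADATA_COLUMNS = ["gene_name", "n_unique_peptides", "quality_score", "coverage_pct"]
DESIGN_COLUMNS = ["sample_id", "animal_id", "condition", "timepoint", "tech_rep", "group"]
MISSING_MARKER = "NA"
_NA_VALUES = ["NA", "nan", "NaN", ""]

CONDITIONS = ("CT", "LPS")
TIMEPOINTS = ("T0", "T50", "T90")
ENDPOINTS = ("T50", "T90")


@dataclass
class QuantMatrix:
    """Protein x sample intensity table plus per-protein metadata.

    ``intensities`` is indexed by accession with float values (NaN = missing);
    ``metadata`` shares the index and carries gene name, unique-peptide count,
    quality score and % sequence coverage.
    """

    intensities: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.intensities.index.name = PROTEIN_KEY
        self.metadata.index.name = PROTEIN_KEY
        if self.intensities.index.has_duplicates:
            dupes = self.intensities.index[self.intensities.index.duplicated()].unique()
            raise FormatError(f"duplicate protein accessions: {list(dupes)[:5]}")
        if not self.intensities.index.equals(self.metadata.index):
            raise FormatError("intensity and metadata tables index different proteins")
        missing_meta = [c for c in METADATA_COLUMNS if c not in self.metadata.columns]
        if missing_meta:
            raise FormatError(f"metadata columns absent: {missing_meta}")
        values = self.intensities.to_numpy(dtype=float)
        observed = values[~np.isnan(values)]
        if observed.size and observed.min() < 0:
            raise FormatError("negative intensity encountered")
        cov = self.metadata["coverage_pct"].to_numpy(dtype=float)
        if ((cov < 0) | (cov > 100)).any():
            raise FormatError("coverage_pct outside [0, 100]")

    @property
    def protein_ids(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensities.columns)

    def subset(self, proteins=None, samples=None) -> "QuantMatrix":
        """Pure selection of rows and/or columns; values are never altered."""
        intens = self.intensities
        meta = self.metadata
        if proteins is not None:
            proteins = [p for p in intens.index if p in set(proteins)]
            intens = intens.loc[proteins]
            meta = meta.loc[proteins]
        if samples is not None:
            samples = [s for s in intens.columns if s in set(samples)]
            intens = intens[samples]
        return QuantMatrix(intens.copy(), meta.copy())


@dataclass
class SampleDesign:
    """Maps sample columns to (animal, condition, time point, technical rep)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in DESIGN_COLUMNS if c not in self.table.columns]
        if missing:
            raise DesignError(f"design columns absent: {missing}")
        t = self.table
        if t["sample_id"].duplicated().any():
            raise DesignError("duplicate sample_id in design")
        if t.duplicated(subset=["animal_id", "timepoint", "tech_rep"]).any():
            raise DesignError("(animal_id, timepoint, tech_rep) not unique")
        bad_cond = set(t["condition"]) - set(CONDITIONS)
        if bad_cond:
            raise DesignError(f"unknown condition labels: {bad_cond}")
        bad_tp = set(t["timepoint"]) - set(TIMEPOINTS)
        if bad_tp:
            raise DesignError(f"unknown time points: {bad_tp}")
        for animal, sub in t.groupby("animal_id"):
            tps = sorted(set(sub["timepoint"]))
            if len(tps) != 2 or "T0" not in tps:
                raise DesignError(
                    f"animal {animal!r} must appear at exactly T0 and one endpoint, got {tps}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def groups(self) -> list[str]:
        return sorted(self.table["group"].unique())

    def endpoint_of_group(self, group: str) -> str:
        sub = self.table[self.table["group"] == group]
        eps = sorted(set(sub["timepoint"]) - {"T0"})
        if len(eps) != 1:
            raise DesignError(f"group {group!r} has no unique endpoint: {eps}")
        return eps[0]

    def samples_for(self, group: str | None = None, timepoint: str | None = None) -> list[str]:
        t = self.table
        if group is not None:
            t = t[t["group"] == group]
        if timepoint is not None:
            t = t[t["timepoint"] == timepoint]
        return list(t["sample_id"])

    def subset_groups(self, groups) -> "SampleDesign":
        keep = self.table[self.table["group"].isin(list(groups))].reset_index(drop=True)
        return SampleDesign(keep.copy())


@dataclass
class AnnotationSet:
    """Flat term -> member-accession mapping (GMT semantics)."""

    terms: dict[str, frozenset] = field(default_factory=dict)
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, members in self.terms.items():
            if not members:
                raise FormatError(f"annotation term {term!r} has no members")

    def __len__(self) -> int:
        return len(self.terms)


def _read_table(path) -> pd.DataFrame:
    """Read a delimited text table, sniffing tab vs comma."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    return pd.read_csv(path, sep=sep, na_values=_NA_VALUES, keep_default_na=False, dtype={0: str})


def read_quant_matrix(path, design: SampleDesign | None = None) -> QuantMatrix:
    """Parse a protein quantification table; optionally cross-validate columns.

    ``NA``, ``nan`` and empty cells all parse as missing. With a design given,
    every design sample must be present as a column.
    """
    raw = _read_table(path)
    if raw.columns[0] != PROTEIN_KEY:
        raise FormatError(f"first column must be {PROTEIN_KEY!r}, got {raw.columns[0]!r}")
    raw = raw.set_index(PROTEIN_KEY)
    meta_cols = [c for c in METADATA_COLUMNS if c in raw.columns]
    if len(meta_cols) != len(METADATA_COLUMNS):
        raise FormatError(f"metadata columns absent: {sorted(set(METADATA_COLUMNS) - set(meta_cols))}")
    sample_cols = [c for c in raw.columns if c not in METADATA_COLUMNS]
    intens = raw[sample_cols].astype(float)
    meta = raw[METADATA_COLUMNS].copy()
    meta["n_unique_peptides"] = meta["n_unique_peptides"].astype(int)
    q = QuantMatrix(intens, meta)
    if design is not None:
        absent = [s for s in design.sample_ids if s not in set(q.sample_ids)]
        if absent:
            raise DesignError(f"design samples absent from quant matrix: {absent[:5]}")
        extra = [s for s in q.sample_ids if s not in set(design.sample_ids)]
        if extra:
            raise DesignError(f"quant columns absent from design: {extra[:5]}")
    return q


def write_quant_matrix(q: QuantMatrix, path) -> None:
    out = pd.concat([q.metadata, q.intensities], axis=1)
    out.index.name = PROTEIN_KEY
    out.to_csv(path, sep="\t", na_rep=MISSING_MARKER)


def read_design(path) -> SampleDesign:
    t = _read_table(path)
    t["tech_rep"] = t["tech_rep"].astype(int)
    for col in ("sample_id", "animal_id", "condition", "timepoint", "group"):
        if col in t.columns:
            t[col] = t[col].astype(str)
    return SampleDesign(t[DESIGN_COLUMNS].reset_index(drop=True))


def write_design(d: SampleDesign, path) -> None:
    d.table.to_csv(path, sep="\t", index=False)


def read_gmt(path) -> AnnotationSet:
    """Parse a GMT file: one term per line, ``term<TAB>description<TAB>ids...``."""
    terms: dict[str, frozenset] = {}
    names: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"GMT line {lineno}: term has no members")
            term, desc, members = parts[0], parts[1], [m for m in parts[2:] if m]
            if not members:
                raise FormatError(f"GMT line {lineno}: term {term!r} is empty")
            if term in terms:
                raise FormatError(f"GMT: duplicate term {term!r}")
            if len(set(members)) != len(members):
                raise FormatError(f"GMT line {lineno}: duplicate members in {term!r}")
            terms[term] = frozenset(members)
            names[term] = desc
    return AnnotationSet(terms, names)


def write_gmt(annotations: AnnotationSet, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for term in annotations.terms:
            members = sorted(annotations.terms[term])
            desc = annotations.names.get(term, term)
            fh.write("\t".join([term, desc, *members]) + "\n")


def write_results(tables: dict[str, pd.DataFrame], out_dir) -> list[Path]:
    """Write each result table as ``<name>.tsv`` under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, table in tables.items():
        dest = out_dir / f"{name}.tsv"
        table.to_csv(dest, sep="\t", index=False, na_rep=MISSING_MARKER)
        written.append(dest)
    return written


def assert_finite_fraction(x: float) -> float:
    """Validate a proportion argument in [0, 1]."""
    if not (isinstance(x, (int, float)) and math.isfinite(x) and 0 <= x <= 1):
        raise FormatError(f"expected a proportion in [0, 1], got {x!r}")
    return float(x)
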