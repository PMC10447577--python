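"""Tabular input/output for the B-cell proteome/transcriptome pipeline.

Reads and writes the MaxQuant-dialect ``proteinGroups`` table, the gene-level
TPM table, sample-design sheets, gene-set lists and UniProt-to-Ensembl
mappings, validating invariants on the way in. All tables are thin wrappers
around :class:`pandas.DataFrame` with the canonical (internal) column names;
the MaxQuant column dialect is translated at the file boundary.

Conventions
-----------
* Molecular weight is stored in daltons internally and written as
  ``Mol. weight [kDa]`` on disk.
* A zero intensity means "not quantified" (missing), never a measured zero.
* Boolean artifact flags use the MaxQuant ``'+'``/``''`` encoding on disk.
* Numeric parsing assumes a decimal point, no thousands separators, UTF-8.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, FormatError, ParseError

logger = logging.getLogger(__name__)

SUBSETS = ("T1", "T2", "MZ", "FoB")

# MaxQuant proteinGroups dialect <-> internal names
_MQ_COLUMNS = {
    "Protein IDs": "group_id",
    "Gene names": "gene_symbol",
    "Mol. weight [kDa]": "mol_weight_kda",
    "Peptides": "peptides_total",
    "Unique peptides": "peptides_unique",
    "Razor + unique peptides": "peptides_unique_razor",
    "Potential contaminant": "flag_contaminant",
    "Reverse": "flag_reverse",
    "Only identified by site": "flag_only_by_site",
}
_FLAG_COLUMNS = ("flag_contaminant", "flag_reverse", "flag_only_by_site")


# ---------------------------------------------------------------------------
# sample design
# ---------------------------------------------------------------------------

@dataclass
class SampleDesign:
    """Mapping of intensity columns to cell subset and biological replicate."""

    table: pd.DataFrame  # columns: sample_id, subset, replicate

    def __post_init__(self) -> None:
        required = {"sample_id", "subset", "replicate"}
        missing = required - set(self.table.columns)
        if missing:
            raise FormatError(f"design table missing columns: {sorted(missing)}")
        if self.table["sample_id"].duplicated().any():
            raise FormatError("design table has duplicated sample_id entries")
        counts = self.table.groupby("subset").size()
        if (counts < 2).any():
            bad = counts[counts < 2].index.tolist()
            raise FormatError(f"each subset needs >=2 replicates; offending: {bad}")

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    @property
    def subsets(self) -> list[str]:
        # stable order of first appearance
        return list(dict.fromkeys(self.table["subset"]))

    def samples_for(self, subset: str) -> list[str]:
        sel = self.table.loc[self.table["subset"] == subset, "sample_id"]
        return sel.tolist()

    def n_replicates(self, subset: str) -> int:
        return len(self.samples_for(subset))

    @classmethod
    def read_tsv(cls, path: str | Path) -> "SampleDesign":
        return cls(pd.read_csv(path, sep="\t", dtype={"sample_id": str, "subset": str}))

    def write_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# protein groups
# ---------------------------------------------------------------------------

@dataclass
class ProteinGroupTable:
    """Validated protein-group evidence: intensities, MW, peptide counts, flags.

    ``table`` holds one row per protein group with the canonical metadata
    columns plus one intensity column per ``design`` sample.  ``rejected``
    records rows dropped during validation as ``(row_index, reason)`` pairs.
    """

    table: pd.DataFrame
    design: SampleDesign
    rejected: list[tuple[int, str]] = field(default_factory=list)

    META_COLUMNS = (
        "group_id",
        "lead_protein_id",
        "gene_symbol",
        "mol_weight_da",
        "peptides_total",
        "peptides_unique",
        "peptides_unique_razor",
        "flag_contaminant",
        "flag_reverse",
        "flag_only_by_site",
    )

    @property
    def intensities(self) -> pd.DataFrame:
        """Per-sample MS intensity, columns ordered as in the design."""
        return self.table[self.design.sample_ids]

    def __len__(self) -> int:
        return len(self.table)

    def equals(self, other: "ProteinGroupTable", rtol: float = 1e-9) -> bool:
        a, b = self.table, other.table
        if len(a) != len(b) or list(a.columns) != list(b.columns):
            return False
        for col in a.columns:
            if a[col].dtype.kind in "fc":
                if not np.allclose(a[col], b[col], rtol=rtol, equal_nan=True):
                    return False
            elif not a[col].reset_index(drop=True).equals(b[col].reset_index(drop=True)):
                return False
        return True


def _validate_protein_rows(df: pd.DataFrame, sample_ids: Sequence[str]) -> tuple[pd.DataFrame, list[tuple[int, str]]]:
    rejected: list[tuple[int, str]] = []
    keep = np.ones(len(df), dtype=bool)
    mw = df["mol_weight_da"].to_numpy(float)
    pu = df["peptides_unique"].to_numpy(float)
    pr = df["peptides_unique_razor"].to_numpy(float)
    pt = df["peptides_total"].to_numpy(float)
    inten = df[list(sample_ids)].to_numpy(float)
    reasons = {
        "mol_weight_da must be > 0": ~(mw > 0),
        "peptide counts must satisfy unique <= unique_razor <= total": (pu > pr) | (pr > pt),
        "intensities must be >= 0": (inten < 0).any(axis=1),
    }
    for reason, bad in reasons.items():
        for idx in np.nonzero(bad & keep)[0]:
            rejected.append((int(df.index[idx]), reason))
        keep &= ~bad
    dup = df["group_id"].duplicated(keep="first").to_numpy()
    for idx in np.nonzero(dup & keep)[0]:
        rejected.append((int(df.index[idx]), "duplicate group_id"))
    keep &= ~dup
    if rejected:
        logger.warning("rejected %d protein-group rows failing invariants", len(rejected))
    return df.loc[keep].reset_index(drop=True), rejected


def read_protein_groups(path: str | Path, design: SampleDesign) -> ProteinGroupTable:
    """Read a MaxQuant-dialect proteinGroups TSV against a sample design.

    Rows violating table invariants (non-positive MW, inconsistent peptide
    counts, negative intensities, duplicate group ids) are dropped and listed
    in ``.rejected`` with row-indexed diagnostics.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, encoding="utf-8")
    missing = [c for c in _MQ_COLUMNS if c not in raw.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    intensity_cols = {s: f"Intensity {s}" for s in design.sample_ids}
    absent = [c for c in intensity_cols.values() if c not in raw.columns]
    if absent:
        raise FormatError(f"{path}: missing intensity columns {absent}")

    df = pd.DataFrame()
    df["group_id"] = raw["Protein IDs"]
    df["lead_protein_id"] = raw["Protein IDs"].str.split(";").str[0]
    df["gene_symbol"] = raw["Gene names"]
    for mq_col, name in [
        ("Mol. weight [kDa]", "mol_weight_kda"),
        ("Peptides", "peptides_total"),
        ("Unique peptides", "peptides_unique"),
        ("Razor + unique peptides", "peptides_unique_razor"),
    ]:
        try:
            df[name] = pd.to_numeric(raw[mq_col], errors="raise")
        except (ValueError, TypeError):
            bad = pd.to_numeric(raw[mq_col], errors="coerce").isna() & (raw[mq_col] != "")
            row = int(bad.idxmax())
            raise ParseError(f"{path}: non-numeric value {raw[mq_col][row]!r} in column {mq_col!r}, row {row}")
    df["mol_weight_da"] = df.pop("mol_weight_kda") * 1000.0
    for col in ("peptides_total", "peptides_unique", "peptides_unique_razor"):
        df[col] = df[col].astype(int)
    for mq_col, name in [
        ("Potential contaminant", "flag_contaminant"),
        ("Reverse", "flag_reverse"),
        ("Only identified by site", "flag_only_by_site"),
    ]:
        df[name] = raw[mq_col].str.strip() == "+"
    for sample_id, col in intensity_cols.items():
        try:
            df[sample_id] = pd.to_numeric(raw[col], errors="raise").astype(float)
        except (ValueError, TypeError):
            bad = pd.to_numeric(raw[col], errors="coerce").isna()
            row = int(bad.idxmax())
            raise ParseError(f"{path}: non-numeric intensity {raw[col][row]!r} in column {col!r}, row {row}")

    df = df[list(ProteinGroupTable.META_COLUMNS) + design.sample_ids]
    clean, rejected = _validate_protein_rows(df, design.sample_ids)
    return ProteinGroupTable(clean, design, rejected)


def write_protein_groups(t: ProteinGroupTable, path: str | Path) -> None:
    """Write back to the MaxQuant dialect. ``%.12g`` keeps floats round-trip safe."""
    out = pd.DataFrame()
    out["Protein IDs"] = t.table["group_id"]
    out["Gene names"] = t.table["gene_symbol"]
    out["Mol. weight [kDa]"] = t.table["mol_weight_da"] / 1000.0
    out["Peptides"] = t.table["peptides_total"]
    out["Unique peptides"] = t.table["peptides_unique"]
    out["Razor + unique peptides"] = t.table["peptides_unique_razor"]
    out["Potential contaminant"] = np.where(t.table["flag_contaminant"], "+", "")
    out["Reverse"] = np.where(t.table["flag_reverse"], "+", "")
    out["Only identified by site"] = np.where(t.table["flag_only_by_site"], "+", "")
    for s in t.design.sample_ids:
        out[f"Intensity {s}"] = t.table[s]
    out.to_csv(path, sep="\t", index=False, float_format="%.12g")


def filter_artifacts(t: ProteinGroupTable) -> ProteinGroupTable:
    """Remove contaminant, reverse-database and only-identified-by-site rows.

    Per-flag removal counts are logged (a row carrying several flags counts
    towards each). Retained rows are passed through unmodified.
    """
    flags = t.table[list(_FLAG_COLUMNS)]
    counts = {c: int(flags[c].sum()) for c in _FLAG_COLUMNS}
    drop = flags.any(axis=1)
    logger.info(
        "artifact filter removed %d rows (contaminant=%d, reverse=%d, only_by_site=%d)",
        int(drop.sum()), counts["flag_contaminant"], counts["flag_reverse"], counts["flag_only_by_site"],
    )
    kept = t.table.loc[~drop].reset_index(drop=True)
    return ProteinGroupTable(kept, t.design, list(t.rejected))


def filter_replicate_presence(cn, min_reps: int = 3, min_unique: int = 1):
    """Keep protein groups quantified in >=``min_reps`` replicates of at least
    one subset and identified by >=``min_unique`` unique peptides.

    Operates on a :class:`~poised_omics.ruler.CopyNumberMatrix`; presence is a
    nonzero copy number. Idempotent by construction.
    """
    design = cn.design
    for s in design.subsets:
        if min_reps > design.n_replicates(s):
            raise ConfigurationError(
                f"min_reps={min_reps} exceeds replicate count of subset {s}"
            )
    copies = cn.copies
    present_any = np.zeros(len(copies), dtype=bool)
    for s in design.subsets:
        cols = design.samples_for(s)
        present_any |= (copies[cols].to_numpy() > 0).sum(axis=1) >= min_reps
    keep = present_any & (cn.meta["peptides_unique"].to_numpy() >= min_unique)
    logger.info("replicate-presence filter retained %d / %d protein groups", int(keep.sum()), len(copies))
    return cn.subset_rows(keep)


# ---------------------------------------------------------------------------
# transcripts
# ---------------------------------------------------------------------------

@dataclass
class TranscriptTable:
    """Gene-level TPM per sample with biotype and per-subset full-length flags."""

    table: pd.DataFrame
    design: SampleDesign

    def __post_init__(self) -> None:
        for col in ("gene_id", "gene_symbol", "biotype"):
            if col not in self.table.columns:
                raise FormatError(f"transcript table missing column {col!r}")
        if self.table["gene_id"].duplicated().any():
            raise FormatError("transcript table has duplicated gene_id entries")
        tpm = self.table[self.design.sample_ids].to_numpy(float)
        if (tpm < 0).any():
            raise FormatError("TPM values must be >= 0")

    def subset_mean_tpm(self) -> pd.DataFrame:
        """Mean TPM per subset, indexed by gene_id."""
        out = {}
        for s in self.design.subsets:
            out[s] = self.table[self.design.samples_for(s)].mean(axis=1)
        df = pd.DataFrame(out)
        df.index = pd.Index(self.table["gene_id"], name="gene_id")
        return df

    def full_length(self, subset: str) -> pd.Series:
        col = f"full_length_{subset}"
        if col not in self.table.columns:
            raise FormatError(f"transcript table missing column {col!r}")
        return pd.Series(self.table[col].to_numpy(bool), index=self.table["gene_id"], name=col)

    @classmethod
    def read_tsv(cls, path: str | Path, design: SampleDesign) -> "TranscriptTable":
        df = pd.read_csv(path, sep="\t", encoding="utf-8")
        for col in df.columns:
            if col.startswith("full_length_"):
                df[col] = df[col].astype(bool)
        missing = [s for s in design.sample_ids if s not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing TPM columns {missing}")
        return cls(df, design)

    def write_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# gene sets and id mapping
# ---------------------------------------------------------------------------

@dataclass
class GeneSetDefinition:
    name: str
    members: list[str]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise FormatError(f"gene set {self.name!r} is empty")
        if len(set(self.members)) != len(self.members):
            raise FormatError(f"gene set {self.name!r} has duplicate members")


def read_gene_set(path: str | Path, name: str | None = None) -> GeneSetDefinition:
    """One gene_id per line; ``#`` starts a comment."""
    path = Path(path)
    members: list[str] = []
    for line in path.read_text(encoding="utf-8").splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            members.append(line)
    default = path.stem.removeprefix("geneset_")
    return GeneSetDefinition(name or default, members, provenance=str(path))


def write_gene_set(gs: GeneSetDefinition, path: str | Path) -> None:
    Path(path).write_text("\n".join(gs.members) + "\n", encoding="utf-8")


@dataclass
class IdMapping:
    """Protein accession -> gene_id map (many accessions to one gene allowed)."""

    table: pd.DataFrame  # columns: accession, gene_id

    def __post_init__(self) -> None:
        dup = self.table[self.table["accession"].duplicated(keep=False)]
        conflict = dup.groupby("accession")["gene_id"].nunique()
        if (conflict > 1).any():
            bad = conflict[conflict > 1].index.tolist()[:5]
            raise FormatError(f"accessions mapping to multiple genes: {bad}")
        self._map = dict(zip(self.table["accession"], self.table["gene_id"]))

    def get(self, accession: str) -> str | None:
        return self._map.get(accession)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "IdMapping":
        return cls(pd.read_csv(path, sep="\t", dtype=str))

    def write_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class GeneMappedProteins:
    """Gene-keyed view of a protein table, via the first (lead) accession."""

    table: pd.DataFrame          # protein table columns + gene_id
    unmapped: list[str]          # lead accessions without a mapping
    ambiguous_genes: list[str]   # genes claimed by more than one group


def map_groups_to_genes(t: ProteinGroupTable, m: IdMapping) -> GeneMappedProteins:
    """Key each protein group by the gene of its first (lead) accession.

    The lead accession corresponds to the most represented isoform of the
    group. Groups with an unmapped lead are reported, not silently dropped;
    genes claimed by two or more groups are kept and flagged ambiguous.
    """
    genes = t.table["lead_protein_id"].map(m.get)
    unmapped = t.table.loc[genes.isna(), "lead_protein_id"].tolist()
    out = t.table.copy()
    out["gene_id"] = genes
    mapped = out.loc[genes.notna()].reset_index(drop=True)
    dup = mapped["gene_id"].duplicated(keep=False)
    ambiguous = sorted(mapped.loc[dup, "gene_id"].unique())
    if unmapped:
        logger.info("%d protein groups have unmapped lead accessions", len(unmapped))
    if ambiguous:
        logger.info("%d genes are claimed by more than one protein group", len(ambiguous))
    return GeneMappedProteins(mapped, unmapped, ambiguous)


def read_xlsx_sheet_as_table(path: str | Path, sheet: str | int = 0) -> pd.DataFrame:
    """Thin adapter: load a supplementary workbook sheet as a DataFrame with
    the same dtypes `read_csv` would produce, for conversion to canonical TSV."""
    return pd.read_excel(path, sheet_name=sheet)
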