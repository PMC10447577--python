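"""Histone proteomic-ruler copy-number estimation.

The ruler converts label-free MS intensities to protein copies per cell by
using the summed histone signal as an internal standard: histone mass per
cell tracks DNA mass, which is fixed by genome size and ploidy. For protein
*i* in sample *j*::

    copies_ij = (I_ij / sum_histones I_hj) * m_DNA * N_A / M_i

where ``m_DNA`` is the DNA mass per cell, ``N_A`` Avogadro's number and
``M_i`` the molecular weight of the protein group in daltons. The estimate is
self-normalizing: rescaling all intensities of a sample leaves copies
unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, EmptyCategoryError, RulerError
from .io_tables import ProteinGroupTable, SampleDesign

logger = logging.getLogger(__name__)

AVOGADRO = 6.02214076e23  # 1/mol

# Mouse core/linker histone accessions used as the internal standard.
# Configurable; matching is against any accession in a protein group.
DEFAULT_HISTONE_IDS = (
    "P10922",  # H1f0
    "P15864",  # H1.2
    "P43277",  # H1.3
    "P43274",  # H1.4
    "P43276",  # H1.5
    "P22752",  # H2A type 1
    "Q64475",  # H2B type 1-B
    "P68433",  # H3.1
    "P84228",  # H3.2
    "P62806",  # H4
)

DALTON_GRAMS = 1.0 / AVOGADRO  # grams per dalton


@dataclass
class RulerConfig:
    """Parameters of the proteomic ruler.

    ``genome_size_bp`` defaults to the mouse genome (2.73e9 bp); the average
    mass of a base pair (615.9 Da) includes the sodium counterions convention
    used by the original plugin.
    """

    genome_size_bp: float = 2.73e9
    ploidy: float = 2.0
    avg_bp_mass_da: float = 615.9
    avogadro: float = AVOGADRO
    histone_ids: tuple[str, ...] = DEFAULT_HISTONE_IDS
    min_histones: int = 3
    min_reps_detected: int = 3

    def __post_init__(self) -> None:
        for name in ("genome_size_bp", "ploidy", "avg_bp_mass_da", "avogadro"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if not self.histone_ids:
            raise ConfigurationError("histone_ids must be nonempty")


def dna_mass_per_cell(cfg: RulerConfig) -> float:
    """DNA mass per cell in picograms: genome_size * ploidy * bp_mass / N_A."""
    grams = cfg.genome_size_bp * cfg.ploidy * cfg.avg_bp_mass_da / cfg.avogadro
    return grams * 1e12


@dataclass
class CopyNumberMatrix:
    """Protein copies per cell per sample, with detection flags and totals.

    ``meta`` carries the protein-group metadata (ids, MW, peptide counts);
    ``copies`` the per-sample copy numbers aligned row-for-row with ``meta``.
    A protein is *detected* in a subset when it has a nonzero copy number in
    at least ``min_reps`` of that subset's replicates.
    """

    meta: pd.DataFrame
    copies: pd.DataFrame
    design: SampleDesign
    total_protein_mass_pg: pd.Series = field(default=None)
    min_reps: int = 3

    def subset_rows(self, keep: np.ndarray) -> "CopyNumberMatrix":
        return CopyNumberMatrix(
            self.meta.loc[keep].reset_index(drop=True),
            self.copies.loc[keep].reset_index(drop=True),
            self.design,
            self.total_protein_mass_pg,
            self.min_reps,
        )

    def __len__(self) -> int:
        return len(self.meta)

    def detected(self) -> pd.DataFrame:
        """Boolean protein x subset detection flags (>= min_reps nonzero)."""
        out = {}
        for s in self.design.subsets:
            cols = self.design.samples_for(s)
            out[s] = (self.copies[cols].to_numpy() > 0).sum(axis=1) >= self.min_reps
        return pd.DataFrame(out)

    def subset_means(self) -> pd.DataFrame:
        """Mean copies per subset over quantified (nonzero) replicates only.

        NaN where a protein has no nonzero replicate in the subset.
        """
        out = {}
        for s in self.design.subsets:
            vals = self.copies[self.design.samples_for(s)].to_numpy(float)
            nz = vals > 0
            cnt = nz.sum(axis=1)
            tot = np.where(nz, vals, 0.0).sum(axis=1)
            out[s] = np.where(cnt > 0, tot / np.maximum(cnt, 1), np.nan)
        return pd.DataFrame(out)

    def write_tsv(self, path) -> None:
        pd.concat([self.meta[["group_id", "lead_protein_id", "gene_symbol"]], self.copies], axis=1).to_csv(
            path, sep="\t", index=False, float_format="%.12g"
        )


def _histone_mask(t_meta: pd.DataFrame, histone_ids) -> np.ndarray:
    hist = set(histone_ids)
    return np.array([
        any(acc in hist for acc in gid.split(";")) for gid in t_meta["group_id"]
    ])


def estimate_copy_numbers(t: ProteinGroupTable, cfg: RulerConfig | None = None) -> CopyNumberMatrix:
    """Apply the histone ruler to a (filtered) protein-group table.

    Requires the histone internal standard to have nonzero summed intensity
    in every sample. Rows with missing molecular weight are excluded with a
    warning. Zero intensity yields zero copies, i.e. "not quantified".
    """
    cfg = cfg or RulerConfig()
    meta_cols = [c for c in t.table.columns if c not in t.design.sample_ids]
    meta = t.table[meta_cols].reset_index(drop=True)
    inten = t.table[t.design.sample_ids].to_numpy(float)
    mw = meta["mol_weight_da"].to_numpy(float)

    good_mw = np.isfinite(mw) & (mw > 0)
    if not good_mw.all():
        logger.warning("excluding %d rows with missing molecular weight", int((~good_mw).sum()))
        meta = meta.loc[good_mw].reset_index(drop=True)
        inten = inten[good_mw]
        mw = mw[good_mw]

    hist = _histone_mask(meta, cfg.histone_ids)
    n_hist = int(hist.sum())
    if n_hist < len(cfg.histone_ids):
        logger.info("found %d of %d configured histone groups", n_hist, len(cfg.histone_ids))
    if n_hist < cfg.min_histones:
        raise RulerError(
            f"only {n_hist} histone groups present; ruler needs >= {cfg.min_histones}"
        )
    hist_sum = inten[hist].sum(axis=0)
    zero = hist_sum == 0
    if zero.any():
        bad = [t.design.sample_ids[i] for i in np.nonzero(zero)[0]]
        raise RulerError(f"zero histone signal in samples: {bad}")

    m_dna_g = dna_mass_per_cell(cfg) * 1e-12
    copies = (inten / hist_sum[None, :]) * (m_dna_g * cfg.avogadro) / mw[:, None]
    copies_df = pd.DataFrame(copies, columns=t.design.sample_ids)

    total_mass_pg = pd.Series(
        (copies * mw[:, None]).sum(axis=0) / cfg.avogadro * 1e12,
        index=t.design.sample_ids,
        name="total_protein_mass_pg",
    )
    return CopyNumberMatrix(meta, copies_df, t.design, total_mass_pg, cfg.min_reps_detected)


def total_mass_fraction(cn: CopyNumberMatrix, category: set[str] | list[str], subset: str) -> float:
    """Mass fraction of a protein category: sum(CN*MW)/N_A over the category
    divided by the same sum over all proteins, on per-subset mean copies.

    Category members are matched against gene symbols and accessions.
    """
    cat = set(category)
    mask = (
        cn.meta["gene_symbol"].isin(cat)
        | cn.meta["lead_protein_id"].isin(cat)
        | cn.meta["group_id"].map(lambda g: any(a in cat for a in g.split(";")))
    ).to_numpy()
    if not mask.any():
        raise EmptyCategoryError("category has no members in the copy-number table")
    means = cn.subset_means()[subset].to_numpy(float)
    means = np.nan_to_num(means, nan=0.0)
    mass = means * cn.meta["mol_weight_da"].to_numpy(float)
    total = mass.sum()
    if total <= 0:
        raise EmptyCategoryError(f"no protein mass in subset {subset}")
    return float(mass[mask].sum() / total)


def classify_quant_confidence(t: ProteinGroupTable) -> pd.Series:
    """Quantitation-confidence class per protein group.

    high:   > 8 unique peptides and (razor+unique)/total >= 0.75
    medium: >= 3 unique peptides and (razor+unique)/total >= 0.5
    low:    otherwise (including zero total peptides, with a warning)
    """
    total = t.table["peptides_total"].to_numpy(float)
    unique = t.table["peptides_unique"].to_numpy(float)
    razor = t.table["peptides_unique_razor"].to_numpy(float)
    zero_total = total == 0
    if zero_total.any():
        logger.warning("%d protein groups have zero total peptides; classed low", int(zero_total.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(total > 0, razor / np.where(total > 0, total, 1), 0.0)
    cls = np.full(len(t.table), "low", dtype=object)
    cls[(unique >= 3) & (ratio >= 0.5)] = "medium"
    cls[(unique > 8) & (ratio >= 0.75)] = "high"
    cls[zero_total] = "low"
    return pd.Series(cls, name="confidence")
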