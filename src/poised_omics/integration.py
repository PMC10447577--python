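"""Gene-level integration of proteome and transcriptome.

Joins mean protein copy numbers with mean TPM per subset on gene identifiers
(protein groups keyed by the gene of their first accession), and provides the
cross-modal summaries: Pearson/Spearman correlations on log10 scales, dynamic
ranges, and the density-contour trend line describing the overall
mRNA-to-protein relationship of each subset.

Averaging order follows the upstream convention: replicate means per subset
first, then the log10 transform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skimage import measure

from .exceptions import IntegrationError, PoisedOmicsError
from .io_tables import IdMapping, TranscriptTable, map_groups_to_genes
from .ruler import CopyNumberMatrix

logger = logging.getLogger(__name__)


@dataclass
class IntegratedGeneTable:
    """Gene-keyed join of per-subset mean TPM, mean copies and detection flags.

    Restricted to genes identified by both modalities in at least one subset.
    ``coverage`` reports the fraction of protein-detected genes and of
    transcribed genes that made it into the join.
    """

    table: pd.DataFrame  # index gene_id; columns tpm_<s>, copies_<s>, detected_<s>, biotype, full_length_<s>
    subsets: list[str]
    coverage: dict[str, float]

    def __len__(self) -> int:
        return len(self.table)

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", float_format="%.12g")


def merge_omics(
    cn: CopyNumberMatrix,
    transcripts: TranscriptTable,
    mapping: IdMapping,
) -> IntegratedGeneTable:
    """Inner-join proteome and transcriptome at gene level.

    Protein groups are keyed by the gene of their lead accession; when two
    groups claim one gene the group with more total peptides (then higher
    overall mean copies) represents it. Genes enter the join when the protein
    is detected in >= 1 subset and the transcript has TPM > 0 in >= 1 subset.
    """
    subsets = cn.design.subsets
    gm = map_groups_to_genes(
        # reconstruct a minimal protein-table facade from the CN matrix
        _cn_as_protein_view(cn),
        mapping,
    )
    prot = gm.table.copy()
    det = cn.detected()
    means = cn.subset_means()
    prot_rows = prot["__row__"].to_numpy(int)
    prot_det = det.to_numpy()[prot_rows]
    prot_means = means.to_numpy()[prot_rows]

    detected_any = prot_det.any(axis=1)
    prot = prot.loc[detected_any].reset_index(drop=True)
    prot_det = prot_det[detected_any]
    prot_means = prot_means[detected_any]

    # resolve multi-group genes: most peptides, then largest mean copies
    score = prot["peptides_total"].to_numpy(float) + np.nan_to_num(prot_means, nan=0.0).mean(axis=1) * 1e-12
    prot = prot.assign(__score__=score)
    order = prot.sort_values(["gene_id", "__score__"], ascending=[True, False], kind="mergesort").index
    first = ~prot.loc[order, "gene_id"].duplicated().to_numpy()
    keep_idx = order.to_numpy()[first]
    prot_keep = prot.loc[keep_idx].reset_index(drop=True)
    det_keep = prot_det[keep_idx]
    means_keep = prot_means[keep_idx]

    tpm = transcripts.subset_mean_tpm()
    transcribed = tpm.index[(tpm.to_numpy() > 0).any(axis=1)]

    prot_genes = pd.Index(prot_keep["gene_id"])
    joined = prot_genes.intersection(transcribed)
    # denominator for protein coverage: every protein group detected somewhere,
    # including ones whose lead accession has no gene mapping
    n_prot_detected = int(det.to_numpy().any(axis=1).sum())
    n_transcribed = len(transcribed)
    coverage = {
        "proteins_covered": len(joined) / n_prot_detected if n_prot_detected else 0.0,
        "transcripts_covered": len(joined) / n_transcribed if n_transcribed else 0.0,
        "n_joined": float(len(joined)),
    }
    if len(joined) == 0:
        raise IntegrationError(f"empty proteome/transcriptome join; coverage: {coverage}")

    pos = {g: i for i, g in enumerate(prot_keep["gene_id"])}
    rows = [pos[g] for g in joined]
    data = {}
    tt = transcripts.table.set_index("gene_id")
    for j, s in enumerate(subsets):
        data[f"tpm_{s}"] = tpm.loc[joined, s].to_numpy()
        data[f"copies_{s}"] = np.nan_to_num(means_keep[rows, j], nan=0.0)
        data[f"detected_{s}"] = det_keep[rows, j]
        fl_col = f"full_length_{s}"
        if fl_col in tt.columns:
            data[fl_col] = tt.loc[joined, fl_col].to_numpy(bool)
    data["biotype"] = tt.loc[joined, "biotype"].to_numpy()
    table = pd.DataFrame(data, index=pd.Index(joined, name="gene_id"))
    logger.info(
        "joined %d genes (%.1f%% of detected proteins, %.1f%% of transcripts)",
        len(joined), 100 * coverage["proteins_covered"], 100 * coverage["transcripts_covered"],
    )
    return IntegratedGeneTable(table, list(subsets), coverage)


def _cn_as_protein_view(cn: CopyNumberMatrix):
    """Adapter giving map_groups_to_genes what it needs from a CN matrix."""
    from .io_tables import ProteinGroupTable

    df = cn.meta.copy()
    df["__row__"] = np.arange(len(df))
    for s in cn.design.sample_ids:
        df[s] = cn.copies[s].to_numpy()
    view = ProteinGroupTable.__new__(ProteinGroupTable)
    view.table = df
    view.design = cn.design
    view.rejected = []
    return view


def correlations(t: IntegratedGeneTable, subset: str) -> dict[str, float]:
    """Pearson r and Spearman rho of log10 TPM vs log10 copies for a subset.

    Genes with a zero in either modality are excluded (log undefined); the
    number used and excluded is reported.
    """
    tpm = t.table[f"tpm_{subset}"].to_numpy(float)
    copies = t.table[f"copies_{subset}"].to_numpy(float)
    ok = (tpm > 0) & (copies > 0)
    if ok.sum() < 3:
        raise PoisedOmicsError(f"need >= 3 genes with positive values in {subset}, got {int(ok.sum())}")
    x = np.log10(tpm[ok])
    y = np.log10(copies[ok])
    r = stats.pearsonr(x, y).statistic
    rho = stats.spearmanr(x, y).statistic
    return {"pearson_r": float(r), "spearman_rho": float(rho), "n": int(ok.sum()), "n_excluded": int((~ok).sum())}


def dynamic_range(
    t: IntegratedGeneTable,
    subset: str,
    modality: str,
    trim_percentiles: tuple[float, float] = (0.0, 100.0),
) -> float:
    """Orders of magnitude spanned by positive values of one modality:
    log10(max) - log10(min), optionally percentile-trimmed."""
    col = {"mrna": f"tpm_{subset}", "protein": f"copies_{subset}"}.get(modality)
    if col is None:
        raise PoisedOmicsError(f"modality must be 'mrna' or 'protein', got {modality!r}")
    vals = t.table[col].to_numpy(float)
    vals = vals[vals > 0]
    if vals.size == 0:
        raise PoisedOmicsError(f"no positive {modality} values in {subset}")
    lo, hi = np.percentile(vals, trim_percentiles)
    return float(np.log10(hi) - np.log10(lo))


@dataclass
class TrendLine:
    """OLS line through the extreme-sum vertices of 2D density contours."""

    subset: str
    slope: float
    intercept: float
    r_squared: float
    support_points: np.ndarray  # (m, 2) contour vertices used for the fit
    fallback: bool = False      # True when density was degenerate -> raw OLS


def fit_trend_line(
    t: IntegratedGeneTable,
    subset: str,
    n_levels: int = 10,
    grid_size: int = 100,
) -> TrendLine:
    """Trend line of log10 copies vs log10 TPM via density-contour extremes.

    A 2D Gaussian kernel density (normal-reference bandwidth) is evaluated on
    a grid; contour polylines are extracted at ``n_levels`` levels evenly
    spaced between 10% and 90% of the peak density. Per level, the vertices
    maximizing and minimizing x+y (assuming a positive mRNA/protein
    relationship) are collected and an ordinary least-squares line is fitted
    through them.
    """
    tpm = t.table[f"tpm_{subset}"].to_numpy(float)
    copies = t.table[f"copies_{subset}"].to_numpy(float)
    ok = (tpm > 0) & (copies > 0)
    if ok.sum() < 50:
        raise PoisedOmicsError(f"need >= 50 genes with positive values in {subset}")
    x = np.log10(tpm[ok])
    y = np.log10(copies[ok])

    try:
        kde = stats.gaussian_kde(np.vstack([x, y]), bw_method="silverman")
        pad_x = 0.05 * (x.max() - x.min() + 1e-9)
        pad_y = 0.05 * (y.max() - y.min() + 1e-9)
        gx = np.linspace(x.min() - pad_x, x.max() + pad_x, grid_size)
        gy = np.linspace(y.min() - pad_y, y.max() + pad_y, grid_size)
        mx, my = np.meshgrid(gx, gy, indexing="ij")
        dens = kde(np.vstack([mx.ravel(), my.ravel()])).reshape(grid_size, grid_size)
    except np.linalg.LinAlgError:
        dens = None

    points = []
    if dens is not None and np.ptp(dens) > 0:
        levels = np.linspace(0.1, 0.9, n_levels) * dens.max()
        for level in levels:
            best_hi, best_lo = None, None
            for contour in measure.find_contours(dens, level):
                cx = np.interp(contour[:, 0], np.arange(grid_size), gx)
                cy = np.interp(contour[:, 1], np.arange(grid_size), gy)
                ssum = cx + cy
                i_hi, i_lo = int(ssum.argmax()), int(ssum.argmin())
                if best_hi is None or ssum[i_hi] > best_hi[0]:
                    best_hi = (ssum[i_hi], cx[i_hi], cy[i_hi])
                if best_lo is None or ssum[i_lo] < best_lo[0]:
                    best_lo = (ssum[i_lo], cx[i_lo], cy[i_lo])
            for best in (best_hi, best_lo):
                if best is not None:
                    points.append((best[1], best[2]))

    if len(points) >= 4 and np.ptp([p[0] for p in points]) > 0:
        pts = np.array(points)
        res = stats.linregress(pts[:, 0], pts[:, 1])
        return TrendLine(subset, float(res.slope), float(res.intercept), float(res.rvalue**2), pts)

    logger.warning("degenerate density for %s; falling back to OLS on raw points", subset)
    res = stats.linregress(x, y)
    return TrendLine(subset, float(res.slope), float(res.intercept), float(res.rvalue**2),
                     np.column_stack([x, y]), fallback=True)
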