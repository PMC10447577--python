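"""Poised-mRNA identification: detection calibration, candidate filtering,
expression-matched resampling null, and classification.

A "poised" mRNA is a full-length protein-coding transcript expressed above an
abundance threshold (TPM > 10 by default, where MS detection probability
reaches 50%) whose encoded protein is not detected. Because RNA-seq is more
sensitive than MS, low-abundance transcripts would otherwise be
misclassified; the calibration step quantifies that detection probability as
a function of mRNA abundance and justifies the threshold.

Whether a gene *set* is depleted of detected proteins is judged against an
expression-matched null: for each member, the 100 protein-coding genes
closest in log2 TPM form its candidate pool; one is drawn per member per
iteration, 100 iterations give the control distribution of detected-protein
counts, and the observed count is compared with its median and 5th/95th
percentiles (linear-interpolation percentiles).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import PoisedOmicsError
from .integration import IntegratedGeneTable
from .io_tables import GeneSetDefinition, TranscriptTable

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# detection-probability calibration
# ---------------------------------------------------------------------------

@dataclass
class DetectionCalibration:
    """Binned protein-detection probability vs log2 mean TPM for one subset."""

    subset: str
    bins: pd.DataFrame        # bin_lo, bin_hi (log2 TPM), n, fraction
    tpm50: float | None       # TPM at interpolated 50% detection; None if out of range
    tpm50_status: str         # "ok" | "below_range" | "above_range"

    def fraction_at(self, tpm: float) -> float:
        """Detection fraction of the bin whose range contains ``tpm``."""
        x = np.log2(tpm)
        sel = (self.bins["bin_lo"] <= x) & (x < self.bins["bin_hi"])
        if not sel.any():
            raise PoisedOmicsError(f"{tpm} TPM outside calibrated range")
        return float(self.bins.loc[sel, "fraction"].iloc[0])


def _candidate_frame(
    integrated: IntegratedGeneTable,
    transcripts: TranscriptTable,
    subset: str,
) -> pd.DataFrame:
    """All protein-coding genes with TPM > 0 in the subset, with their
    detection status (genes absent from the proteome are undetected)."""
    tpm = transcripts.subset_mean_tpm()[subset]
    tt = transcripts.table.set_index("gene_id")
    coding = tt["biotype"] == "protein_coding"
    genes = tpm.index[coding.to_numpy() & (tpm.to_numpy() > 0)]
    detected = pd.Series(False, index=genes)
    in_join = genes.intersection(integrated.table.index)
    detected.loc[in_join] = integrated.table.loc[in_join, f"detected_{subset}"].to_numpy(bool)
    return pd.DataFrame({"tpm": tpm.loc[genes], "detected": detected})


def detection_calibration(
    integrated: IntegratedGeneTable,
    transcripts: TranscriptTable,
    subset: str,
    bin_width_log2: float = 1.0,
) -> DetectionCalibration:
    """Bin protein-coding genes by log2 mean TPM and compute the per-bin
    fraction with detected protein; interpolate the 50% crossing.

    Bin edges are aligned to multiples of ``bin_width_log2``. Empty bins are
    reported with n = 0 and excluded from the interpolation. When every
    populated bin is above (below) 0.5 the 50% point is reported as below
    (above) the calibrated range.
    """
    cand = _candidate_frame(integrated, transcripts, subset)
    x = np.log2(cand["tpm"].to_numpy(float))
    det = cand["detected"].to_numpy(bool)
    lo = np.floor(x.min() / bin_width_log2) * bin_width_log2
    hi = np.ceil(x.max() / bin_width_log2) * bin_width_log2
    edges = np.arange(lo, hi + bin_width_log2 / 2, bin_width_log2)
    idx = np.clip(np.digitize(x, edges) - 1, 0, len(edges) - 2)
    rows = []
    for b in range(len(edges) - 1):
        sel = idx == b
        n = int(sel.sum())
        frac = float(det[sel].mean()) if n else np.nan
        rows.append({"bin_lo": edges[b], "bin_hi": edges[b + 1], "n": n, "fraction": frac})
    bins = pd.DataFrame(rows)

    filled = bins.dropna(subset=["fraction"])
    mids = ((filled["bin_lo"] + filled["bin_hi"]) / 2).to_numpy()
    fracs = filled["fraction"].to_numpy()
    tpm50, status = None, "ok"
    crossing = np.nonzero((fracs[:-1] < 0.5) & (fracs[1:] >= 0.5))[0]
    if crossing.size:
        i = int(crossing[0])
        x50 = mids[i] + (0.5 - fracs[i]) / (fracs[i + 1] - fracs[i]) * (mids[i + 1] - mids[i])
        tpm50 = float(2**x50)
    elif (fracs >= 0.5).all():
        status = "below_range"
    elif (fracs < 0.5).all():
        status = "above_range"
    else:  # first populated bin already >= 0.5 but later dips: report range edge
        status = "below_range"
    return DetectionCalibration(subset, bins, tpm50, status)


# ---------------------------------------------------------------------------
# candidate filtering
# ---------------------------------------------------------------------------

@dataclass
class FilteredGeneSet:
    name: str
    subset: str
    genes: list[str]
    stage_counts: dict[str, int]
    unresolved: list[str] = field(default_factory=list)


def filter_candidates(
    gs: GeneSetDefinition,
    transcripts: TranscriptTable,
    subset: str,
    tpm_min: float = 10.0,
    require_full_length: bool = True,
) -> FilteredGeneSet:
    """Restrict a gene set to members with mean TPM strictly above
    ``tpm_min`` (and full-length transcripts, if required) in the subset."""
    tpm = transcripts.subset_mean_tpm()[subset]
    members = pd.Index(gs.members)
    resolved = members.intersection(tpm.index)
    unresolved = members.difference(tpm.index).tolist()
    if unresolved:
        logger.warning("gene set %s: %d members not in transcript table", gs.name, len(unresolved))
    passing = resolved[tpm.loc[resolved].to_numpy() > tpm_min]
    counts = {"members": len(members), "resolved": len(resolved), "tpm_pass": len(passing)}
    if require_full_length:
        fl = transcripts.full_length(subset)
        passing = passing[fl.loc[passing].to_numpy()]
        counts["full_length_pass"] = len(passing)
    # preserve the gene set's original member order
    order = {g: i for i, g in enumerate(gs.members)}
    genes = sorted(passing.tolist(), key=order.get)
    return FilteredGeneSet(gs.name, subset, genes, counts, unresolved)


# ---------------------------------------------------------------------------
# expression-matched resampling null
# ---------------------------------------------------------------------------

@dataclass
class ControlSetSummary:
    """Observed detected-protein count vs the expression-matched null envelope."""

    set_name: str
    subset: str
    set_size: int
    observed_detected: int
    control_median: float
    control_p5: float
    control_p95: float
    n_iterations: int
    verdict: str              # depleted | within-envelope | enriched
    effect_size: float        # observed / median - 1


def build_control_sets(
    filtered: FilteredGeneSet,
    integrated: IntegratedGeneTable,
    transcripts: TranscriptTable,
    n_nearest: int = 100,
    n_iterations: int = 100,
    seed: int = 0,
) -> ControlSetSummary:
    """Expression-matched resampling null for one gene set in one subset.

    For each member, the ``n_nearest`` protein-coding genes closest in log2
    TPM (excluding the member itself, other members permitted) form its
    candidate pool; each iteration draws one pool gene per member uniformly
    at random. The detected-protein counts of the ``n_iterations`` control
    sets give the median and 5th/95th percentile envelope; the observed
    count below the 5th percentile is called depleted, above the 95th
    enriched.
    """
    subset = filtered.subset
    cand = _candidate_frame(integrated, transcripts, subset)
    pool_genes = cand.index.to_numpy()
    pool_tpm = cand["tpm"].to_numpy(float)
    pool_detected = cand["detected"].to_numpy(bool)
    gene_pos = {g: i for i, g in enumerate(pool_genes)}

    members = [g for g in filtered.genes if g in gene_pos]
    if len(members) < len(filtered.genes):
        logger.warning(
            "%d/%d filtered genes missing from candidate pool",
            len(filtered.genes) - len(members), len(filtered.genes),
        )
    if not members:
        raise PoisedOmicsError(f"no members of {filtered.name} in candidate pool for {subset}")

    focal_idx = np.array([gene_pos[g] for g in members])
    observed = int(pool_detected[focal_idx].sum())

    log_pool = np.log2(pool_tpm)
    order = np.argsort(log_pool, kind="stable")
    sorted_log = log_pool[order]
    pools = []
    short = 0
    for fi in focal_idx:
        target = log_pool[fi]
        pos = np.searchsorted(sorted_log, target)
        lo = max(0, pos - n_nearest - 2)
        hi = min(len(sorted_log), pos + n_nearest + 2)
        window = order[lo:hi]
        window = window[window != fi]
        d = np.abs(log_pool[window] - target)
        take = min(n_nearest, window.size)
        if take < n_nearest:
            short += 1
        sel = np.argsort(d, kind="stable")[:take]
        pools.append(np.sort(window[sel]))
    if short:
        logger.warning("%d members had pools smaller than %d", short, n_nearest)

    rng = np.random.default_rng(seed)
    counts = np.empty(n_iterations, dtype=int)
    pool_det = [pool_detected[p] for p in pools]
    sizes = np.array([p.size for p in pools])
    picks = rng.random((n_iterations, len(pools)))
    pick_idx = (picks * sizes[None, :]).astype(int)
    det_matrix = np.zeros((len(pools), max(sizes)), dtype=bool)
    for g, dvec in enumerate(pool_det):
        det_matrix[g, : dvec.size] = dvec
    counts = det_matrix[np.arange(len(pools))[None, :], pick_idx].sum(axis=1)

    p5, med, p95 = np.percentile(counts, [5, 50, 95])
    if observed < p5:
        verdict = "depleted"
    elif observed > p95:
        verdict = "enriched"
    else:
        verdict = "within-envelope"
    return ControlSetSummary(
        filtered.name, subset, len(members), observed,
        float(med), float(p5), float(p95), n_iterations, verdict,
        float(observed / med - 1) if med > 0 else np.nan,
    )


# ---------------------------------------------------------------------------
# per-gene expectation and classification
# ---------------------------------------------------------------------------

def expected_protein_box(
    gene: str,
    integrated: IntegratedGeneTable,
    transcripts: TranscriptTable,
    subset: str,
    n_nearest: int = 100,
) -> dict[str, float]:
    """Box statistics of protein copies for the ``n_nearest`` protein-coding
    genes closest in RNA expression to ``gene`` (deterministic, no random
    selection; undetected neighbors contribute 0 copies).

    Whiskers extend to min/max, or to quartile +/- 1.5 * IQR when outliers
    exist beyond that range. Percentiles use linear interpolation.
    """
    cand = _candidate_frame(integrated, transcripts, subset)
    if gene not in cand.index:
        raise PoisedOmicsError(f"gene {gene!r} absent from transcript candidates in {subset}")
    log_tpm = np.log2(cand["tpm"].to_numpy(float))
    genes = cand.index.to_numpy()
    focal = int(np.nonzero(genes == gene)[0][0])
    d = np.abs(log_tpm - log_tpm[focal])
    d[focal] = np.inf
    take = min(n_nearest, len(genes) - 1)
    nearest = np.argsort(d, kind="stable")[:take]
    copies = np.zeros(take)
    neighbor_genes = genes[nearest]
    in_join = pd.Index(neighbor_genes).intersection(integrated.table.index)
    cop = integrated.table.loc[in_join, f"copies_{subset}"]
    det = integrated.table.loc[in_join, f"detected_{subset}"]
    lookup = (cop.where(det, 0.0)).to_dict()
    copies = np.array([lookup.get(g, 0.0) for g in neighbor_genes])

    q25, med, q75 = np.percentile(copies, [25, 50, 75])
    iqr = q75 - q25
    lo_fence, hi_fence = q25 - 1.5 * iqr, q75 + 1.5 * iqr
    lo = copies.min() if copies.min() >= lo_fence else max(copies[copies >= lo_fence].min(), lo_fence)
    hi = copies.max() if copies.max() <= hi_fence else min(copies[copies <= hi_fence].max(), hi_fence)
    return {
        "median": float(med), "q25": float(q25), "q75": float(q75),
        "whisker_lo": float(lo), "whisker_hi": float(hi), "n_neighbors": float(take),
    }


def classify_poised(
    filtered: FilteredGeneSet,
    integrated: IntegratedGeneTable,
    transcripts: TranscriptTable,
    n_nearest: int = 100,
    with_boxes: bool = True,
) -> pd.DataFrame:
    """Classify each filtered gene as poised (no detected protein) or not.

    Returns one row per gene with its mean TPM, full-length and detection
    flags, the poised call, and (optionally) the expected-protein box
    statistics from the 100 nearest-expression genes.
    """
    subset = filtered.subset
    tpm = transcripts.subset_mean_tpm()[subset]
    fl = transcripts.full_length(subset)
    rows = []
    for g in filtered.genes:
        det = bool(
            g in integrated.table.index and integrated.table.loc[g, f"detected_{subset}"]
        )
        row = {
            "gene_id": g,
            "subset": subset,
            "mean_tpm": float(tpm.loc[g]),
            "full_length": bool(fl.loc[g]),
            "protein_detected": det,
            "poised": not det,
        }
        if with_boxes:
            row.update({f"expected_{k}": v for k, v in
                        expected_protein_box(g, integrated, transcripts, subset, n_nearest).items()})
        rows.append(row)
    return pd.DataFrame(rows)
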