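"""Differential proteome statistics across B-cell subsets.

Implements the label-free differential workflow: sum-normalization of copy
numbers, per-protein one-way ANOVA with Benjamini-Hochberg FDR control,
log2 deviation-from-mean profiles, hierarchical six-cluster partitioning of
the differential proteins, subset presence (Venn) counts, a two-group Welch
comparison, and protein-complex stoichiometry ratios.

Missing-value policy: copy numbers of zero are missing, tests run on the
available values, and a protein needs at least two subsets with at least two
quantified replicates each to be tested at all. No imputation.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import AgglomerativeClustering
from statsmodels.stats.multitest import multipletests

from .exceptions import ConfigurationError, PoisedOmicsError
from .io_tables import SampleDesign
from .ruler import CopyNumberMatrix

logger = logging.getLogger(__name__)


@dataclass
class NormalizedMatrix:
    """Sum-normalized copy numbers: linear scale and log2, missing as NaN."""

    linear: pd.DataFrame
    log2: pd.DataFrame
    design: SampleDesign
    meta: pd.DataFrame


def normalize_and_log(cn: CopyNumberMatrix) -> NormalizedMatrix:
    """Scale each sample so its total copy number equals the across-sample
    mean total, then log2-transform. Zeros become NaN (not quantified)."""
    copies = cn.copies.to_numpy(float)
    totals = copies.sum(axis=0)
    if (totals <= 0).any():
        bad = [cn.design.sample_ids[i] for i in np.nonzero(totals <= 0)[0]]
        raise PoisedOmicsError(f"samples with zero total copy number: {bad}")
    target = totals.mean()
    linear = copies * (target / totals)[None, :]
    linear[linear == 0] = np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        log2 = np.log2(linear)
    cols = cn.design.sample_ids
    return NormalizedMatrix(
        pd.DataFrame(linear, columns=cols),
        pd.DataFrame(log2, columns=cols),
        cn.design,
        cn.meta,
    )


def _anova_oneway_nan(values: np.ndarray, groups: list[np.ndarray], min_per_group: int = 2):
    """Vectorized one-way fixed-effects ANOVA per row with missing values.

    ``groups`` is a list of column-index arrays. A group enters a row's test
    only with >= ``min_per_group`` finite values; a row is tested when >= 2
    groups qualify. Returns (F, p, tested).
    """
    n_rows = values.shape[0]
    counts, sums, sqsums = [], [], []
    for cols in groups:
        block = values[:, cols]
        finite = np.isfinite(block)
        counts.append(finite.sum(axis=1))
        sums.append(np.where(finite, block, 0.0).sum(axis=1))
        sqsums.append(np.where(finite, block**2, 0.0).sum(axis=1))
    counts = np.array(counts)          # (k, n_rows)
    sums = np.array(sums)
    sqsums = np.array(sqsums)

    usable = counts >= min_per_group
    k_eff = usable.sum(axis=0)
    tested = k_eff >= 2

    counts = np.where(usable, counts, 0)
    sums = np.where(usable, sums, 0.0)
    sqsums = np.where(usable, sqsums, 0.0)

    n_tot = counts.sum(axis=0)
    grand = np.divide(sums.sum(axis=0), n_tot, out=np.zeros(n_rows), where=n_tot > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        group_means = sums / counts
    ss_between = (counts * (group_means - grand[None, :]) ** 2)
    ss_between = np.where(usable, ss_between, 0.0).sum(axis=0)
    ss_within = sqsums - counts * group_means**2
    ss_within = np.where(usable, ss_within, 0.0).sum(axis=0)

    df_b = (k_eff - 1).astype(float)
    df_w = (n_tot - k_eff).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat = (ss_between / df_b) / (ss_within / df_w)
    degenerate = ~np.isfinite(f_stat) | (df_w <= 0)
    tested = tested & ~degenerate
    f_stat = np.where(tested, f_stat, np.nan)
    p = np.full(n_rows, np.nan)
    p[tested] = stats.f.sf(f_stat[tested], df_b[tested], df_w[tested])
    return f_stat, p, tested


def anova_bh(norm: NormalizedMatrix, alpha: float = 0.05) -> pd.DataFrame:
    """Per-protein one-way ANOVA across subsets with BH correction.

    Returns a frame with F, p, q, ``tested`` and ``significant`` (q < alpha).
    Proteins with identical values everywhere (zero variance) or with fewer
    than two quantified replicates in two subsets are marked untested.
    """
    groups = [
        np.array([norm.design.sample_ids.index(s) for s in norm.design.samples_for(sub)])
        for sub in norm.design.subsets
    ]
    values = norm.log2.to_numpy(float)
    f_stat, p, tested = _anova_oneway_nan(values, groups)
    q = np.full(len(p), np.nan)
    if tested.any():
        q[tested] = multipletests(p[tested], method="fdr_bh")[1]
    significant = tested & (q < alpha)
    out = pd.DataFrame(
        {
            "F": f_stat,
            "p": p,
            "q": q,
            "tested": tested,
            "significant": significant,
        }
    )
    logger.info(
        "ANOVA: %d tested, %d significant at FDR < %g",
        int(tested.sum()), int(significant.sum()), alpha,
    )
    return out


def log2_deviation_from_mean(norm: NormalizedMatrix) -> pd.DataFrame:
    """Per-protein log2 deviation of each subset mean from the across-subset
    mean, computed on normalized linear copies.

    Rows sum to zero over the subsets in which the protein was detected;
    undetected subsets are NaN (and flagged by the ``n_subsets`` column of
    the caller if needed).
    """
    means = {}
    for s in norm.design.subsets:
        vals = norm.linear[norm.design.samples_for(s)].to_numpy(float)
        finite = np.isfinite(vals)
        cnt = finite.sum(axis=1)
        tot = np.where(finite, vals, 0.0).sum(axis=1)
        means[s] = np.where(cnt > 0, tot / np.maximum(cnt, 1), np.nan)
    m = pd.DataFrame(means)
    with np.errstate(divide="ignore", invalid="ignore"):
        logm = np.log2(m.to_numpy(float))
    dev = logm - np.nanmean(logm, axis=1, keepdims=True)
    return pd.DataFrame(dev, columns=norm.design.subsets)


def cluster_de_proteins(dev: pd.DataFrame, k: int = 6) -> pd.Series:
    """Partition differential proteins into k clusters by their deviation
    profile (agglomerative, Euclidean distance, complete linkage).

    Cluster ids 1..k are ordered by the subset at which the cluster's mean
    profile peaks (column order), ties broken by descending peak height, so
    labels are reproducible run to run.
    """
    complete = dev.dropna()
    if len(complete) < k:
        raise ConfigurationError(f"need >= {k} complete profiles, got {len(complete)}")
    if k == 1:
        raw = np.zeros(len(complete), dtype=int)
    else:
        model = AgglomerativeClustering(n_clusters=k, metric="euclidean", linkage="complete")
        raw = model.fit_predict(complete.to_numpy())
    order = []
    for lbl in range(k):
        profile = complete.to_numpy()[raw == lbl].mean(axis=0)
        order.append((int(profile.argmax()), -float(profile.max()), lbl))
    relabel = {lbl: i + 1 for i, (_, _, lbl) in enumerate(sorted(order))}
    out = pd.Series(np.nan, index=dev.index, name="cluster_id")
    out.loc[complete.index] = [relabel[v] for v in raw]
    return out


def presence_venn(cn: CopyNumberMatrix) -> dict[tuple[str, ...], int]:
    """Counts for every nonempty subset combination of the presence Venn.

    A protein is expressed in a subset when detected in >= min_reps of its
    replicates; each protein contributes to exactly one region (its full
    combination of expressing subsets). Region counts sum to the number of
    proteins expressed somewhere.
    """
    det = cn.detected()
    subsets = list(det.columns)
    regions: dict[tuple[str, ...], int] = {}
    for r in range(1, len(subsets) + 1):
        for combo in itertools.combinations(subsets, r):
            mask = np.ones(len(det), dtype=bool)
            for s in subsets:
                want = s in combo
                mask &= det[s].to_numpy() == want
            regions[combo] = int(mask.sum())
    return regions


def welch_volcano(
    wt_log2: pd.DataFrame,
    ko_log2: pd.DataFrame,
    fc_line: float = 0.5,
    p_line: float = 0.05,
) -> pd.DataFrame:
    """Per-protein Welch two-sample two-tailed t-test (KO vs WT).

    Inputs are log2 matrices aligned row-for-row; the fold change is the
    difference of group means in log2 units. Rows with fewer than two finite
    values in either group are untested.
    """
    wt = wt_log2.to_numpy(float)
    ko = ko_log2.to_numpy(float)
    n_wt = np.isfinite(wt).sum(axis=1)
    n_ko = np.isfinite(ko).sum(axis=1)
    tested = (n_wt >= 2) & (n_ko >= 2)
    with np.errstate(invalid="ignore"):
        fc = np.nanmean(ko, axis=1) - np.nanmean(wt, axis=1)
    t = np.full(len(wt), np.nan)
    p = np.full(len(wt), np.nan)
    if tested.any():
        with warnings.catch_warnings():
            # near-identical groups trigger a precision warning inside the
            # t-test; the degenerate case is handled explicitly below
            warnings.simplefilter("ignore", RuntimeWarning)
            res = stats.ttest_ind(ko[tested], wt[tested], axis=1, equal_var=False, nan_policy="omit")
        t[tested] = res.statistic
        p[tested] = res.pvalue
    # identical groups: t == 0 exactly, p == 1 (incl. the zero-variance case
    # where the Welch statistic is 0/0)
    degenerate = tested & ~np.isfinite(t) & (fc == 0)
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate | (tested & (t == 0)), 1.0, p)
    return pd.DataFrame(
        {
            "log2_fc": fc,
            "t": t,
            "p": p,
            "tested": tested,
            "passes_fc": np.abs(fc) > fc_line,
            "passes_p": p < p_line,
            "hit": tested & (np.abs(fc) > fc_line) & (p < p_line),
        }
    )


def stoichiometry_ratio(cn: CopyNumberMatrix, numerator: str, denominator: str) -> pd.DataFrame:
    """Per-subset copy-number ratio of two proteins (e.g. eIF4A1 : PDCD4).

    Genes are matched by gene symbol or accession. The ratio is NaN where the
    denominator is not quantified; no exception is raised for that case.
    """
    def locate(name: str) -> int:
        hits = np.nonzero(
            (cn.meta["gene_symbol"] == name) | (cn.meta["lead_protein_id"] == name)
        )[0]
        if hits.size == 0:
            raise PoisedOmicsError(f"protein {name!r} not found in copy-number table")
        return int(hits[0])

    i_num, i_den = locate(numerator), locate(denominator)
    means = cn.subset_means()
    rows = []
    for s in cn.design.subsets:
        num = means[s].iloc[i_num]
        den = means[s].iloc[i_den]
        ratio = num / den if np.isfinite(den) and den > 0 and np.isfinite(num) else np.nan
        rows.append({"subset": s, "numerator_copies": num, "denominator_copies": den, "ratio": ratio})
    return pd.DataFrame(rows)
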