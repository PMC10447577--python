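"""Paired proteome/transcriptome simulator with ground truth.

Generates a MaxQuant-style protein-group table and a gene-level TPM table for
four splenic B-cell subsets (T1, T2, MZ, FoB) x four replicates, with the
statistical structure the downstream analysis assumes:

* gene-level log10 TPM ~ N(mean, sd) spanning ~5 orders of magnitude;
* log10 copies per cell = intercept + slope * log10 TPM + noise, spanning
  ~7+ orders and giving Pearson r ~ 0.45 with log TPM among detected genes
  (MS detection preferentially censors low-abundance proteins, so the slope
  and noise are calibrated for the *post-detection* correlation);
* a logistic protein-detection model in log2 TPM with 50% detection at
  10 TPM and a 0.95 asymptote;
* histone anchor rows whose summed mass equals the DNA mass per cell, so the
  proteomic ruler is exactly invertible at zero noise;
* six planted differential-expression archetypes (transitional-high,
  T2-leaning, up-from-T2-maintained, T1+MZ, MZ-only, mature MZ+FoB);
* a named "early_activation" gene set containing planted poised genes
  (abundant full-length mRNA, protein never detected) and a "pb_related"
  set with no planted effect.

Intensities are constructed by inverting the ruler,
``I = copies * MW * scale_sample * 10^eps``, so estimated copy numbers
recover the planted truth. All draws come from one seeded stream in a fixed
order: the same seed reproduces bit-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigurationError
from .io_tables import (
    GeneSetDefinition,
    IdMapping,
    ProteinGroupTable,
    SampleDesign,
    TranscriptTable,
    write_gene_set,
    write_protein_groups,
)
from .ruler import AVOGADRO, DEFAULT_HISTONE_IDS, RulerConfig, dna_mass_per_cell

# (accession, gene symbol, MW in Da) of the histone anchors
HISTONE_ANCHORS = [
    ("P10922", "H1f0", 20861.0),
    ("P15864", "H1c", 21267.0),
    ("P43277", "H1d", 22100.0),
    ("P43274", "H1e", 21977.0),
    ("P43276", "H1b", 22576.0),
    ("P22752", "Hist1h2ab", 14135.0),
    ("Q64475", "Hist1h2bb", 13952.0),
    ("P68433", "Hist1h3a", 15404.0),
    ("P84228", "Hist2h3b", 15388.0),
    ("P62806", "Hist1h4a", 11367.0),
]

# Six archetype deviation patterns over (T1, T2, MZ, FoB), centered and
# scaled by de_log2_effect when applied. Shapes mirror maturation-stage
# clusters: 1-2 transitional, 3 up-from-T2 maintained, 4 T1+MZ shared,
# 5 MZ-only, 6 mature (MZ+FoB).
DE_ARCHETYPES = np.array(
    [
        [1.0, 0.5, 0.0, 0.0],
        [0.5, 1.0, 0.0, 0.0],
        [0.0, 1.0, 1.0, 1.0],
        [1.0, 0.0, 1.0, 0.0],
        [0.0, 0.0, 1.0, 0.0],
        [0.0, 0.0, 1.0, 1.0],
    ]
)


@dataclass
class SyntheticConfig:
    """Study-condition parameters of the simulator (defaults = the profiled design)."""

    n_genes: int = 8000
    subsets: tuple[str, ...] = ("T1", "T2", "MZ", "FoB")
    n_replicates: int = 4
    frac_noncoding: float = 0.10
    log10_tpm_mean: float = 0.8
    log10_tpm_sd: float = 0.7          # ~5 orders of magnitude across 8000 genes
    tpm_replicate_sd: float = 0.05     # log10 units
    protein_intercept: float = 3.2     # log10 copies at 1 TPM
    protein_slope: float = 0.9
    protein_noise_sd: float = 0.95     # calibrated for r ~ 0.45 among detected genes
    target_pearson_r: float = 0.45
    intensity_noise_sd: float = 0.06   # log10 units, multiplicative MS noise
    detect_tpm50: float = 10.0         # TPM at 50% detection probability
    detect_slope: float = 1.0          # logistic steepness per log2 TPM
    detect_asymptote: float = 0.95
    n_histones: int = 10
    frac_de: float = 0.27
    de_log2_effect: float = 1.5
    full_length_prob: float = 0.8
    gene_set_size: int = 150
    poised_set_size: int = 50
    frac_unmapped: float = 0.034       # lead accessions absent from the id mapping
    n_contaminant: int = 40
    n_reverse: int = 30
    n_only_by_site: int = 20
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_genes < self.n_histones:
            raise ConfigurationError("n_genes must be >= n_histones")
        for name in ("log10_tpm_sd", "detect_tpm50", "detect_slope"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if not (0 < self.detect_asymptote <= 1):
            raise ConfigurationError("detect_asymptote must be in (0, 1]")
        if not (0 <= self.frac_de <= 1):
            raise ConfigurationError("frac_de must be in [0, 1]")
        if self.n_histones > len(HISTONE_ANCHORS):
            raise ConfigurationError(f"at most {len(HISTONE_ANCHORS)} histone anchors available")
        if self.poised_set_size > self.gene_set_size:
            raise ConfigurationError("poised_set_size must be <= gene_set_size")


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside the tables, for test oracles.

    ``genes`` is indexed by gene_id; ``copies_true`` / ``detected`` are
    gene x subset (true mean copies per cell; subset-level detection).
    ``total_mass_pg`` is the true mass of all quantified proteins per sample.
    """

    genes: pd.DataFrame
    copies_true: pd.DataFrame
    detected: pd.DataFrame
    total_mass_pg: pd.Series
    poised_genes: list[str]

    @property
    def cluster_labels(self) -> pd.Series:
        return self.genes["cluster"]


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    design: SampleDesign
    protein_groups: ProteinGroupTable
    transcripts: TranscriptTable
    mapping: IdMapping
    gene_sets: dict[str, GeneSetDefinition]
    truth: SyntheticTruth

    def ruler_config(self) -> RulerConfig:
        """Ruler configuration matching the generator's histone anchors."""
        ids = tuple(a for a, _, _ in HISTONE_ANCHORS[: self.config.n_histones])
        return RulerConfig(histone_ids=ids)


def detection_probability(tpm: np.ndarray, cfg: SyntheticConfig) -> np.ndarray:
    """Logistic detection model in log2 TPM (the generator's ground truth)."""
    x = np.log2(np.maximum(tpm, 1e-12))
    x50 = np.log2(cfg.detect_tpm50)
    return cfg.detect_asymptote / (1.0 + np.exp(-cfg.detect_slope * (x - x50)))


def generate_dataset(cfg: SyntheticConfig | None = None) -> SyntheticDataset:
    """Generate one paired proteome/transcriptome bundle with ground truth."""
    cfg = cfg or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_genes
    subsets = list(cfg.subsets)
    n_sub = len(subsets)

    # --- design ---------------------------------------------------------
    design = SampleDesign(
        pd.DataFrame(
            {
                "sample_id": [f"{s}_{r}" for s in subsets for r in range(1, cfg.n_replicates + 1)],
                "subset": [s for s in subsets for _ in range(cfg.n_replicates)],
                "replicate": [r for _ in subsets for r in range(1, cfg.n_replicates + 1)],
            }
        )
    )
    sample_ids = design.sample_ids

    # --- gene universe ---------------------------------------------------
    n_coding = int(round(n * (1 - cfg.frac_noncoding)))
    gene_ids = np.array([f"ENSMUSG{i:011d}" for i in range(1, n + 1)])
    symbols = np.array([f"Gene{i}" for i in range(1, n + 1)], dtype=object)
    biotype = np.where(np.arange(n) < n_coding, "protein_coding", "lncRNA")
    is_histone = np.zeros(n, dtype=bool)
    is_histone[: cfg.n_histones] = True

    accession = np.array([f"P{i:05d}" for i in range(1, n + 1)], dtype=object)
    mw = 10 ** rng.normal(4.65, 0.25, n)
    mw = np.clip(mw, 8e3, 5e5)
    for k, (acc, sym, hmw) in enumerate(HISTONE_ANCHORS[: cfg.n_histones]):
        accession[k], symbols[k], mw[k] = acc, sym, hmw

    # --- mRNA abundance ---------------------------------------------------
    log10_tpm = rng.normal(cfg.log10_tpm_mean, cfg.log10_tpm_sd, n)
    log10_tpm[is_histone] = rng.normal(2.7, 0.3, cfg.n_histones)

    # --- planted gene sets (members get abundant mRNA) -------------------
    eligible = np.nonzero((biotype == "protein_coding") & ~is_histone)[0]
    picked = rng.choice(eligible, size=2 * cfg.gene_set_size, replace=False)
    early_idx = picked[: cfg.gene_set_size]
    pb_idx = picked[cfg.gene_set_size:]
    poised_idx = early_idx[: cfg.poised_set_size]
    log10_tpm[picked] = rng.uniform(1.3, 2.5, picked.size)

    poised = np.zeros(n, dtype=bool)
    poised[poised_idx] = True

    # --- DE archetypes ----------------------------------------------------
    cluster = np.zeros(n, dtype=int)
    de_eligible = np.setdiff1d(eligible, poised_idx)
    n_de = int(round(cfg.frac_de * n_coding))
    de_idx = rng.choice(de_eligible, size=min(n_de, de_eligible.size), replace=False)
    cluster[de_idx] = rng.integers(1, 7, de_idx.size)

    # --- true protein copies ---------------------------------------------
    eps = rng.normal(0.0, cfg.protein_noise_sd, n)
    base_log10_copies = cfg.protein_intercept + cfg.protein_slope * log10_tpm + eps
    centered = DE_ARCHETYPES - DE_ARCHETYPES.mean(axis=1, keepdims=True)
    offsets = np.zeros((n, n_sub))
    has_de = cluster > 0
    offsets[has_de] = centered[cluster[has_de] - 1] * cfg.de_log2_effect * np.log10(2.0)
    log10_copies_subset = base_log10_copies[:, None] + offsets
    copies_true = 10 ** log10_copies_subset
    # histone copies anchor the ruler: equal mass share of the DNA mass
    m_dna_da = dna_mass_per_cell(RulerConfig()) * 1e-12 / (1.0 / AVOGADRO)  # daltons
    hist_copies = m_dna_da / (cfg.n_histones * mw[: cfg.n_histones])
    copies_true[: cfg.n_histones, :] = hist_copies[:, None]
    copies_true[biotype != "protein_coding", :] = np.nan

    # --- detection (subset level) and replicate presence ------------------
    p_det = detection_probability(10 ** log10_tpm, cfg)
    det = rng.random((n, n_sub)) < p_det[:, None]
    det[is_histone] = True
    det[poised] = False
    det[biotype != "protein_coding"] = False

    # replicate presence: detected -> 3 or 4 reps; undetected -> mostly 0,
    # occasionally 1-2 sporadic replicates (still failing the >=3 rule)
    reps = np.zeros((n, n_sub, cfg.n_replicates), dtype=bool)
    n_full = rng.random((n, n_sub)) < 0.8
    missing_rep = rng.integers(0, cfg.n_replicates, (n, n_sub))
    sporadic = rng.random((n, n_sub)) < 0.1
    sporadic_count = rng.integers(1, 3, (n, n_sub))
    sporadic_rep = rng.integers(0, cfg.n_replicates, (n, n_sub, 2))
    for j in range(n_sub):
        dj = det[:, j]
        reps[dj, j, :] = True
        drop = dj & ~n_full[:, j]
        reps[drop, j, missing_rep[drop, j]] = False
        sp = ~dj & sporadic[:, j] & (biotype == "protein_coding") & ~poised
        idx_sp = np.nonzero(sp)[0]
        for i in idx_sp:
            for r in sporadic_rep[i, j, : sporadic_count[i, j]]:
                reps[i, j, r] = True
    reps[is_histone] = True

    # --- observed TPM per sample ------------------------------------------
    tpm_noise = rng.normal(0.0, cfg.tpm_replicate_sd, (n, n_sub * cfg.n_replicates))
    tpm_obs = 10 ** (log10_tpm[:, None] + tpm_noise)

    # --- intensities by ruler inversion -----------------------------------
    sample_scale = 10 ** (-2.0 + rng.uniform(-0.3, 0.3, n_sub * cfg.n_replicates))
    inten_noise = 10 ** rng.normal(0.0, cfg.intensity_noise_sd, (n, n_sub * cfg.n_replicates))
    copies_per_sample = np.repeat(copies_true, cfg.n_replicates, axis=1)
    present = reps.reshape(n, n_sub * cfg.n_replicates)
    with np.errstate(invalid="ignore"):
        inten = copies_per_sample * mw[:, None] * sample_scale[None, :] * inten_noise
    inten = np.where(present & np.isfinite(inten), inten, 0.0)

    # --- peptide counts ----------------------------------------------------
    finite = np.isfinite(copies_true) & (copies_true > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        logc = np.where(finite, np.log10(np.where(finite, copies_true, 1.0)), 0.0)
    cnt = finite.sum(axis=1)
    mean_logc = np.where(cnt > 0, logc.sum(axis=1) / np.maximum(cnt, 1), 1.0)
    lam = np.clip(2.0 * (mean_logc - 1.0), 0.2, 30.0)
    peptides_total = 1 + rng.poisson(lam)
    peptides_razor = rng.binomial(peptides_total, 0.85)
    peptides_unique = rng.binomial(peptides_razor, 0.9)
    peptides_total[: cfg.n_histones] = np.maximum(peptides_total[: cfg.n_histones], 12)
    peptides_razor[: cfg.n_histones] = peptides_total[: cfg.n_histones] - 1
    peptides_unique[: cfg.n_histones] = peptides_razor[: cfg.n_histones] - 1

    # --- protein rows: quantified coding genes + artifact rows -------------
    has_row = (biotype == "protein_coding") & ~poised & present.any(axis=1)
    row_idx = np.nonzero(has_row)[0]

    second_acc = rng.random(row_idx.size) < 0.15
    group_ids = []
    for k, i in enumerate(row_idx):
        gid = accession[i]
        if second_acc[k] and not is_histone[i]:
            gid = f"{gid};Q{i + 1:05d}"
        group_ids.append(gid)

    prot = pd.DataFrame(
        {
            "group_id": group_ids,
            "lead_protein_id": accession[row_idx],
            "gene_symbol": symbols[row_idx],
            "mol_weight_da": mw[row_idx],
            "peptides_total": peptides_total[row_idx],
            "peptides_unique": peptides_unique[row_idx],
            "peptides_unique_razor": peptides_razor[row_idx],
            "flag_contaminant": False,
            "flag_reverse": False,
            "flag_only_by_site": False,
        }
    )
    for j, sid in enumerate(sample_ids):
        prot[sid] = inten[row_idx, j]

    junk_rows = []
    junk_spec = [
        ("CON__", cfg.n_contaminant, "flag_contaminant"),
        ("REV__", cfg.n_reverse, "flag_reverse"),
        ("SITE__", cfg.n_only_by_site, "flag_only_by_site"),
    ]
    for prefix, count, flag in junk_spec:
        for k in range(count):
            row = {
                "group_id": f"{prefix}X{k:04d}",
                "lead_protein_id": f"{prefix}X{k:04d}",
                "gene_symbol": "",
                "mol_weight_da": float(10 ** rng.normal(4.65, 0.25)),
                "peptides_total": int(1 + rng.poisson(3)),
                "peptides_unique": 0,
                "peptides_unique_razor": 0,
                "flag_contaminant": flag == "flag_contaminant",
                "flag_reverse": flag == "flag_reverse",
                "flag_only_by_site": flag == "flag_only_by_site",
            }
            row["peptides_unique_razor"] = min(row["peptides_total"], 1)
            row["peptides_unique"] = row["peptides_unique_razor"]
            vals = 10 ** rng.normal(6.0, 1.0, len(sample_ids))
            for sid, v in zip(sample_ids, vals):
                row[sid] = float(v)
            junk_rows.append(row)
    if junk_rows:
        prot = pd.concat([prot, pd.DataFrame(junk_rows)], ignore_index=True)

    protein_groups = ProteinGroupTable(prot, design)

    # --- transcripts --------------------------------------------------------
    fl = rng.random((n, n_sub)) < cfg.full_length_prob
    fl[biotype != "protein_coding"] = False
    fl[picked] = True  # gene-set members (incl. all poised genes) full length
    trans = pd.DataFrame({"gene_id": gene_ids, "gene_symbol": symbols, "biotype": biotype})
    for j, sid in enumerate(sample_ids):
        trans[sid] = tpm_obs[:, j]
    for j, s in enumerate(subsets):
        trans[f"full_length_{s}"] = fl[:, j]
    transcripts = TranscriptTable(trans, design)

    # --- id mapping ----------------------------------------------------------
    unmappable = rng.random(n) < cfg.frac_unmapped
    unmappable[is_histone] = False
    mapped = (biotype == "protein_coding") & ~unmappable
    mapping = IdMapping(
        pd.DataFrame({"accession": accession[mapped], "gene_id": gene_ids[mapped]})
    )

    # --- gene sets -------------------------------------------------------------
    gene_sets = {
        "early_activation": GeneSetDefinition(
            "early_activation", list(gene_ids[np.sort(early_idx)]), "planted: poised + matched members"
        ),
        "pb_related": GeneSetDefinition(
            "pb_related", list(gene_ids[np.sort(pb_idx)]), "planted: no detection deficit"
        ),
    }

    # --- truth -------------------------------------------------------------------
    genes = pd.DataFrame(
        {
            "gene_symbol": symbols,
            "biotype": biotype,
            "is_histone": is_histone,
            "accession": accession,
            "mapped": mapped,
            "log10_tpm_true": log10_tpm,
            "cluster": cluster,
            "poised": poised,
            "in_early_set": np.isin(np.arange(n), early_idx),
            "in_pb_set": np.isin(np.arange(n), pb_idx),
            "has_protein_row": has_row,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    copies_true_df = pd.DataFrame(copies_true, index=genes.index, columns=subsets)
    detected_df = pd.DataFrame(det, index=genes.index, columns=subsets)
    quantified = np.where(present, np.nan_to_num(copies_per_sample, nan=0.0), 0.0)
    total_mass = pd.Series(
        (quantified * mw[:, None]).sum(axis=0) / AVOGADRO * 1e12,
        index=sample_ids,
        name="total_mass_pg",
    )
    truth = SyntheticTruth(genes, copies_true_df, detected_df, total_mass, list(gene_ids[np.sort(poised_idx)]))

    return SyntheticDataset(cfg, design, protein_groups, transcripts, mapping, gene_sets, truth)


def generate_two_group(
    n_proteins: int = 3000,
    n_planted: int = 24,
    log2_fc: float = 5.0,
    n_replicates: int = 3,
    noise_sd_log2: float = 0.3,
    seed: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Two-group (WT vs KO) log2 abundance matrices for the Welch comparison.

    Returns (wt, ko, planted_index); the first ``n_planted`` proteins carry a
    +``log2_fc`` shift in KO. Matrices are log2-normalized-copy scale.
    """
    rng = np.random.default_rng(seed)
    base = rng.normal(12.0, 2.0, n_proteins)
    wt = base[:, None] + rng.normal(0.0, noise_sd_log2, (n_proteins, n_replicates))
    ko = base[:, None] + rng.normal(0.0, noise_sd_log2, (n_proteins, n_replicates))
    planted = np.arange(n_planted)
    ko[planted] += log2_fc
    wt_df = pd.DataFrame(wt, columns=[f"WT_{i+1}" for i in range(n_replicates)])
    ko_df = pd.DataFrame(ko, columns=[f"KO_{i+1}" for i in range(n_replicates)])
    return wt_df, ko_df, planted


def write_fixture_bundle(ds: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write all external-interface files plus a YAML manifest of config+seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "protein_groups": outdir / "protein_groups.tsv",
        "transcripts": outdir / "transcripts.tsv",
        "design": outdir / "design.tsv",
        "mapping": outdir / "id_mapping.tsv",
        "manifest": outdir / "manifest.yaml",
    }
    write_protein_groups(ds.protein_groups, paths["protein_groups"])
    ds.transcripts.write_tsv(paths["transcripts"])
    ds.design.write_tsv(paths["design"])
    ds.mapping.write_tsv(paths["mapping"])
    for name, gs in ds.gene_sets.items():
        p = outdir / f"geneset_{name}.txt"
        write_gene_set(gs, p)
        paths[f"geneset_{name}"] = p
    cfg = asdict(ds.config)
    cfg["subsets"] = list(cfg["subsets"])
    manifest = {"format_version": 1, "seed": ds.config.seed, "config": cfg}
    paths["manifest"].write_text(yaml.safe_dump(manifest, sort_keys=True), encoding="utf-8")
    return paths
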