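"""End-to-end orchestration: configuration, stages, and the run report.

Stages are plain functions over files so that CLI subcommands compose:
running ``simulate``, ``ruler``, ``de``, ``integrate``, ``calibrate`` and
``poised`` in sequence produces byte-identical outputs to ``run-all``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import differential, integration, poised, ruler, synthetic_data
from .exceptions import ConfigurationError, PoisedOmicsError
from .io_tables import (
    IdMapping,
    SampleDesign,
    TranscriptTable,
    filter_artifacts,
    filter_replicate_presence,
    read_gene_set,
    read_protein_groups,
)

logger = logging.getLogger(__name__)

CONFIG_VERSION = 1


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (YAML-backed, CLI-overridable)."""

    protein_groups: str
    design: str
    transcripts: str
    mapping: str
    gene_sets: list[str] = field(default_factory=list)
    outdir: str = "results/pipeline"
    seed: int = 0
    ruler: ruler.RulerConfig = field(default_factory=ruler.RulerConfig)
    fdr: float = 0.05
    tpm_min: float = 10.0
    fc_line: float = 0.5
    p_line: float = 0.05
    min_reps: int = 3
    min_unique: int = 1
    n_clusters: int = 6
    n_nearest: int = 100
    n_iterations: int = 100
    bin_width_log2: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.fdr < 1):
            raise ConfigurationError("fdr must be in (0, 1)")
        if self.tpm_min < 0 or self.n_nearest < 1 or self.n_iterations < 1:
            raise ConfigurationError("thresholds out of documented range")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        if raw.get("version", CONFIG_VERSION) != CONFIG_VERSION:
            raise ConfigurationError(f"unsupported config version {raw.get('version')}")
        inputs = raw.get("inputs", {})
        kwargs = {
            "protein_groups": inputs.get("protein_groups"),
            "design": inputs.get("design"),
            "transcripts": inputs.get("transcripts"),
            "mapping": inputs.get("mapping"),
            "gene_sets": inputs.get("gene_sets", []),
            "outdir": raw.get("outdir", "results/pipeline"),
            "seed": raw.get("seed", 0),
        }
        rcfg = raw.get("ruler", {})
        if "histone_ids" in rcfg:
            rcfg["histone_ids"] = tuple(rcfg["histone_ids"])
        kwargs["ruler"] = ruler.RulerConfig(**rcfg)
        kwargs.update(raw.get("thresholds", {}))
        kwargs.update(raw.get("resampling", {}))
        kwargs.update({k: v for k, v in overrides.items() if v is not None})
        missing = [k for k in ("protein_groups", "design", "transcripts", "mapping") if not kwargs.get(k)]
        if missing:
            raise ConfigurationError(f"config missing inputs: {missing}")
        return cls(**kwargs)


def _load_inputs(cfg: PipelineConfig):
    for key in ("protein_groups", "design", "transcripts", "mapping"):
        if not Path(getattr(cfg, key)).exists():
            raise PoisedOmicsError(f"input file for {key!r} not found: {getattr(cfg, key)}")
    design = SampleDesign.read_tsv(cfg.design)
    prot = read_protein_groups(cfg.protein_groups, design)
    transcripts = TranscriptTable.read_tsv(cfg.transcripts, design)
    mapping = IdMapping.read_tsv(cfg.mapping)
    gene_sets = [read_gene_set(p) for p in cfg.gene_sets]
    return design, prot, transcripts, mapping, gene_sets


def stage_ruler(cfg: PipelineConfig, outdir: Path) -> dict:
    """Artifact filtering, ruler copy numbers, presence filter, confidence."""
    design, prot, _, _, _ = _load_inputs(cfg)
    n_raw = len(prot)
    prot = filter_artifacts(prot)
    cn = ruler.estimate_copy_numbers(prot, cfg.ruler)
    cn = filter_replicate_presence(cn, cfg.min_reps, cfg.min_unique)
    conf = ruler.classify_quant_confidence(_as_table_view(cn, design))
    cn.write_tsv(outdir / "copy_numbers.tsv")
    means = cn.subset_means()
    means.insert(0, "group_id", cn.meta["group_id"].to_numpy())
    means.to_csv(outdir / "copy_number_subset_means.tsv", sep="\t", index=False, float_format="%.12g")
    cn.total_protein_mass_pg.to_csv(outdir / "total_protein_mass_pg.tsv", sep="\t", float_format="%.12g")
    pd.DataFrame({"group_id": cn.meta["group_id"], "confidence": conf}).to_csv(
        outdir / "quant_confidence.tsv", sep="\t", index=False
    )
    return {
        "n_groups_raw": n_raw,
        "n_groups_after_artifact_filter": len(prot),
        "n_groups_after_presence_filter": len(cn),
        "confidence_counts": conf.value_counts().to_dict(),
    }


def _as_table_view(cn: ruler.CopyNumberMatrix, design: SampleDesign):
    from .io_tables import ProteinGroupTable

    view = ProteinGroupTable.__new__(ProteinGroupTable)
    df = cn.meta.copy()
    for s in design.sample_ids:
        df[s] = cn.copies[s].to_numpy()
    view.table = df
    view.design = design
    view.rejected = []
    return view


def _rebuild_cn(cfg: PipelineConfig) -> ruler.CopyNumberMatrix:
    design, prot, _, _, _ = _load_inputs(cfg)
    prot = filter_artifacts(prot)
    cn = ruler.estimate_copy_numbers(prot, cfg.ruler)
    return filter_replicate_presence(cn, cfg.min_reps, cfg.min_unique)


def stage_de(cfg: PipelineConfig, outdir: Path) -> dict:
    """Normalization, ANOVA+BH, deviation clustering, presence Venn."""
    cn = _rebuild_cn(cfg)
    norm = differential.normalize_and_log(cn)
    de = differential.anova_bh(norm, alpha=cfg.fdr)
    dev = differential.log2_deviation_from_mean(norm)
    sig = de["significant"].to_numpy(bool)
    clusters = pd.Series(np.nan, index=de.index)
    if sig.sum() >= cfg.n_clusters:
        clusters.loc[sig] = differential.cluster_de_proteins(dev.loc[sig], cfg.n_clusters)
    out = pd.concat(
        [cn.meta[["group_id", "gene_symbol"]], de, clusters.rename("cluster_id"), dev.add_prefix("dev_")],
        axis=1,
    )
    out.to_csv(outdir / "differential_proteome.tsv", sep="\t", index=False, float_format="%.12g")
    venn = differential.presence_venn(cn)
    pd.DataFrame(
        [{"region": "&".join(k), "count": v} for k, v in sorted(venn.items(), key=lambda kv: (len(kv[0]), kv[0]))]
    ).to_csv(outdir / "presence_venn.tsv", sep="\t", index=False)
    return {
        "n_tested": int(de["tested"].sum()),
        "n_significant": int(sig.sum()),
        "n_unchanged": int(de["tested"].sum() - sig.sum()),
        "venn_total": int(sum(venn.values())),
    }


def stage_integrate(cfg: PipelineConfig, outdir: Path) -> dict:
    cn = _rebuild_cn(cfg)
    design, _, transcripts, mapping, _ = _load_inputs(cfg)
    integ = integration.merge_omics(cn, transcripts, mapping)
    integ.write_tsv(outdir / "integrated_genes.tsv")
    stats_rows, trend_rows = [], []
    for s in design.subsets:
        corr = integration.correlations(integ, s)
        corr["subset"] = s
        corr["mrna_orders"] = integration.dynamic_range(integ, s, "mrna")
        corr["protein_orders"] = integration.dynamic_range(integ, s, "protein")
        stats_rows.append(corr)
        tl = integration.fit_trend_line(integ, s)
        trend_rows.append(
            {"subset": s, "slope": tl.slope, "intercept": tl.intercept, "r_squared": tl.r_squared,
             "n_support": len(tl.support_points), "fallback": tl.fallback}
        )
    pd.DataFrame(stats_rows).to_csv(outdir / "correlations.tsv", sep="\t", index=False, float_format="%.6g")
    pd.DataFrame(trend_rows).to_csv(outdir / "trend_lines.tsv", sep="\t", index=False, float_format="%.6g")
    return {"n_joined_genes": len(integ), **{k: round(v, 4) for k, v in integ.coverage.items()}}


def stage_calibrate(cfg: PipelineConfig, outdir: Path) -> dict:
    cn = _rebuild_cn(cfg)
    design, _, transcripts, mapping, _ = _load_inputs(cfg)
    integ = integration.merge_omics(cn, transcripts, mapping)
    frames, info = [], {}
    for s in design.subsets:
        cal = poised.detection_calibration(integ, transcripts, s, cfg.bin_width_log2)
        b = cal.bins.copy()
        b.insert(0, "subset", s)
        frames.append(b)
        info[s] = {"tpm50": cal.tpm50, "status": cal.tpm50_status}
    pd.concat(frames).to_csv(outdir / "detection_calibration.tsv", sep="\t", index=False, float_format="%.6g")
    return {"tpm50": info}


def stage_poised(cfg: PipelineConfig, outdir: Path) -> dict:
    cn = _rebuild_cn(cfg)
    design, _, transcripts, mapping, gene_sets = _load_inputs(cfg)
    integ = integration.merge_omics(cn, transcripts, mapping)
    summaries, records = [], []
    for gs in gene_sets:
        for s in design.subsets:
            filt = poised.filter_candidates(gs, transcripts, s, cfg.tpm_min, True)
            if not filt.genes:
                continue
            # one stream per (gene set, subset) so sets don't perturb each other
            sub_seed = zlib.crc32(f"{gs.name}|{s}|{cfg.seed}".encode()) % (2**31)
            summary = poised.build_control_sets(
                filt, integ, transcripts, cfg.n_nearest, cfg.n_iterations, sub_seed
            )
            summaries.append(dataclasses.asdict(summary))
            records.append(poised.classify_poised(filt, integ, transcripts, cfg.n_nearest))
    if summaries:
        pd.DataFrame(summaries).to_csv(outdir / "control_set_summary.tsv", sep="\t", index=False, float_format="%.6g")
    if records:
        pd.concat(records, ignore_index=True).to_csv(
            outdir / "poised_signature.tsv", sep="\t", index=False, float_format="%.12g"
        )
    n_poised = int(sum(r["poised"].sum() for r in records)) if records else 0
    return {"n_gene_set_subset_pairs": len(summaries), "n_poised_calls": n_poised}


STAGES = {
    "ruler": stage_ruler,
    "de": stage_de,
    "integrate": stage_integrate,
    "calibrate": stage_calibrate,
    "poised": stage_poised,
}


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages in order and write a machine-readable run report."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": cfg.seed, "stages": {}}
    for name, fn in STAGES.items():
        try:
            report["stages"][name] = fn(cfg, outdir)
        except PoisedOmicsError as exc:
            report["stages"][name] = {"error": str(exc)}
            (outdir / "run_report.json").write_text(json.dumps(report, indent=2, default=str))
            raise PoisedOmicsError(f"stage {name!r} failed: {exc}") from exc
    (outdir / "run_report.json").write_text(json.dumps(report, indent=2, default=str))
    return report


def simulate_to_dir(outdir: str | Path, seed: int = 1, **config_overrides) -> synthetic_data.SyntheticDataset:
    """Generate a synthetic bundle and write it under ``outdir``."""
    cfg = synthetic_data.SyntheticConfig(seed=seed, **config_overrides)
    ds = synthetic_data.generate_dataset(cfg)
    synthetic_data.write_fixture_bundle(ds, outdir)
    return ds


def config_for_bundle(bundle_dir: str | Path, outdir: str | Path, seed: int = 0, **kw) -> PipelineConfig:
    """PipelineConfig pointing at a written fixture bundle."""
    b = Path(bundle_dir)
    gene_sets = sorted(str(p) for p in b.glob("geneset_*.txt"))
    return PipelineConfig(
        protein_groups=str(b / "protein_groups.tsv"),
        design=str(b / "design.tsv"),
        transcripts=str(b / "transcripts.tsv"),
        mapping=str(b / "id_mapping.tsv"),
        gene_sets=gene_sets,
        outdir=str(outdir),
        seed=seed,
        **kw,
    )
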