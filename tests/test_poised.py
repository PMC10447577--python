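"""Detection calibration, candidate filtering, resampling null, poised calls."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from poised_omics import poised
from poised_omics.exceptions import PoisedOmicsError
from poised_omics.integration import IntegratedGeneTable
from poised_omics.io_tables import GeneSetDefinition, SampleDesign, TranscriptTable


def make_world(tpm, detected, full_length=None, subset="T1", biotype=None):
    """Build a minimal (integrated table, transcripts) pair for one subset."""
    n = len(tpm)
    genes = [f"g{i}" for i in range(n)]
    full_length = np.ones(n, dtype=bool) if full_length is None else np.asarray(full_length)
    biotype = np.array(["protein_coding"] * n) if biotype is None else np.asarray(biotype)
    design = SampleDesign(pd.DataFrame({
        "sample_id": [f"{subset}_1", f"{subset}_2"],
        "subset": [subset, subset],
        "replicate": [1, 2],
    }))
    tt = pd.DataFrame({
        "gene_id": genes, "gene_symbol": genes, "biotype": biotype,
        f"{subset}_1": tpm, f"{subset}_2": tpm,
        f"full_length_{subset}": full_length,
    })
    transcripts = TranscriptTable(tt, design)
    detected = np.asarray(detected, dtype=bool)
    it = pd.DataFrame(
        {
            f"tpm_{subset}": tpm,
            f"copies_{subset}": np.where(detected, 1000.0, 0.0),
            f"detected_{subset}": detected,
            "biotype": biotype,
        },
        index=pd.Index(genes, name="gene_id"),
    )
    integrated = IntegratedGeneTable(it, [subset], {})
    return integrated, transcripts


class TestDetectionCalibration:
    def test_saturated_case_all_detected(self):
        tpm = np.logspace(0, 3, 200)
        it, tt = make_world(tpm, np.ones(200, dtype=bool))
        cal = poised.detection_calibration(it, tt, "T1")
        filled = cal.bins.dropna(subset=["fraction"])
        assert (filled["fraction"] == 1.0).all()
        assert cal.tpm50 is None and cal.tpm50_status == "below_range"

    def test_synthetic_bin_at_ten_tpm_near_half(self, default_ds, default_integrated):
        cal = poised.detection_calibration(default_integrated, default_ds.transcripts, "T1")
        assert cal.fraction_at(10.0) == pytest.approx(0.5, abs=0.05)
        assert cal.tpm50 == pytest.approx(10.0, rel=0.5)

    def test_fractions_nondecreasing_with_tpm(self, default_ds, default_integrated):
        # monotone detection model -> monotone fractions up to MC noise; allow
        # single-bin violations in sparse bins
        for s in default_ds.design.subsets:
            cal = poised.detection_calibration(default_integrated, default_ds.transcripts, s)
            filled = cal.bins[cal.bins["n"] >= 100]
            frac = filled["fraction"].to_numpy()
            violations = (np.diff(frac) < -0.05).sum()
            assert violations <= 1

    def test_empty_bins_reported_not_interpolated(self):
        tpm = np.concatenate([np.full(50, 1.0), np.full(50, 64.0)])
        det = np.concatenate([np.zeros(50, bool), np.ones(50, bool)])
        it, tt = make_world(tpm, det)
        cal = poised.detection_calibration(it, tt, "T1")
        empty = cal.bins[cal.bins["n"] == 0]
        assert len(empty) >= 1 and empty["fraction"].isna().all()
        assert cal.tpm50 is not None and 1.0 < cal.tpm50 < 64.0


class TestFilterCandidates:
    def test_strict_tpm_boundary_and_full_length(self):
        tpm = np.array([10.0, 10.5, 100.0, 5.0])
        fl = np.array([True, True, False, True])
        it, tt = make_world(tpm, np.zeros(4, bool), full_length=fl)
        gs = GeneSetDefinition("s", ["g0", "g1", "g2", "g3"])
        out = poised.filter_candidates(gs, tt, "T1")
        assert out.genes == ["g1"]  # g0 exactly 10 excluded; g2 not full length; g3 low
        assert out.stage_counts["tpm_pass"] == 2

    def test_unresolvable_members_reported_not_fatal(self):
        it, tt = make_world(np.array([50.0, 20.0, 30.0]), np.zeros(3, bool))
        gs = GeneSetDefinition("s", ["g0", "missing1", "g2"])
        out = poised.filter_candidates(gs, tt, "T1")
        assert out.unresolved == ["missing1"]
        assert set(out.genes) == {"g0", "g2"}

    def test_planted_set_fully_retained(self, default_ds):
        gs = default_ds.gene_sets["early_activation"]
        out = poised.filter_candidates(gs, default_ds.transcripts, "MZ")
        assert len(out.genes) == len(gs.members)


class TestControlSets:
    def _world(self, n=2000, det_rate=0.7, seed=0):
        rng = np.random.default_rng(seed)
        tpm = 10 ** rng.uniform(0.5, 3.0, n)
        det = rng.random(n) < det_rate
        return make_world(tpm, det), det, tpm

    def test_reproducible_given_seed(self, default_ds, default_integrated):
        gs = default_ds.gene_sets["pb_related"]
        filt = poised.filter_candidates(gs, default_ds.transcripts, "T1")
        a = poised.build_control_sets(filt, default_integrated, default_ds.transcripts, seed=42)
        b = poised.build_control_sets(filt, default_integrated, default_ds.transcripts, seed=42)
        assert (a.control_median, a.control_p5, a.control_p95) == (b.control_median, b.control_p5, b.control_p95)

    def test_saturated_case(self):
        (it, tt), _, _ = self._world(det_rate=1.0)
        gs = GeneSetDefinition("s", [f"g{i}" for i in range(0, 300, 10)])
        filt = poised.filter_candidates(gs, tt, "T1", require_full_length=False)
        out = poised.build_control_sets(filt, it, tt, seed=0)
        assert out.observed_detected == out.set_size
        assert out.control_median == out.set_size
        assert out.verdict == "within-envelope"

    def test_envelope_estimate_noisier_with_fewer_iterations(self, default_ds, default_integrated):
        # the 5th-95th band is an empirical-percentile estimate: at 10
        # iterations it fluctuates far more from seed to seed than at 100
        gs = default_ds.gene_sets["pb_related"]
        filt = poised.filter_candidates(gs, default_ds.transcripts, "T1")
        widths = {10: [], 100: []}
        for n_iter in widths:
            for seed in range(20):
                out = poised.build_control_sets(
                    filt, default_integrated, default_ds.transcripts, n_iterations=n_iter, seed=seed
                )
                widths[n_iter].append(out.control_p95 - out.control_p5)
        assert np.std(widths[10]) > np.std(widths[100])

    def test_planted_deficit_called_depleted(self, default_ds, default_integrated):
        gs = default_ds.gene_sets["early_activation"]
        filt = poised.filter_candidates(gs, default_ds.transcripts, "T1")
        out = poised.build_control_sets(filt, default_integrated, default_ds.transcripts, seed=7)
        assert out.verdict == "depleted"
        assert out.effect_size < -0.2

    def test_null_envelope_coverage_property(self):
        (it, tt), det, tpm = self._world()
        rng = np.random.default_rng(11)
        inside = 0
        n_sets = 200
        for k in range(n_sets):
            members = [f"g{i}" for i in rng.choice(len(tpm), 60, replace=False)]
            gs = GeneSetDefinition("r", members)
            filt = poised.filter_candidates(gs, tt, "T1", tpm_min=0.0, require_full_length=False)
            out = poised.build_control_sets(filt, it, tt, n_nearest=50, n_iterations=100, seed=k)
            if out.verdict == "within-envelope":
                inside += 1
        assert inside / n_sets >= 0.85


class TestExpectedBoxAndClassification:
    def test_constant_neighbors(self):
        tpm = np.full(150, 100.0)
        it, tt = make_world(tpm, np.ones(150, bool))
        box = poised.expected_protein_box("g0", it, tt, "T1")
        assert box["median"] == 1000.0 and box["q75"] - box["q25"] == 0.0

    def test_quartiles_match_percentile_oracle(self):
        # neighbors carry copies 0..99 (the 101st value is the focal gene)
        n = 101
        tpm = np.full(n, 50.0) + np.arange(n) * 1e-9  # distinct, focal nearest to all
        it, tt = make_world(tpm, np.ones(n, bool))
        copies = np.arange(n, dtype=float)
        it.table["copies_T1"] = copies
        box = poised.expected_protein_box("g100", it, tt, "T1")
        expected = np.percentile(np.arange(100, dtype=float), [25, 50, 75])
        assert [box["q25"], box["median"], box["q75"]] == pytest.approx(list(expected))

    def test_missing_gene_errors(self):
        it, tt = make_world(np.full(10, 10.0), np.ones(10, bool))
        with pytest.raises(PoisedOmicsError):
            poised.expected_protein_box("nope", it, tt, "T1")

    def test_poised_subset_of_candidates_and_planted_recovered(self, default_ds, default_integrated):
        gs = default_ds.gene_sets["early_activation"]
        for s in ("T1", "MZ"):
            filt = poised.filter_candidates(gs, default_ds.transcripts, s)
            rec = poised.classify_poised(filt, default_integrated, default_ds.transcripts, with_boxes=False)
            assert set(rec["gene_id"]) <= set(filt.genes)
            assert not rec.loc[rec["poised"], "protein_detected"].any()
            called = set(rec.loc[rec["poised"], "gene_id"])
            assert set(default_ds.truth.poised_genes) <= called

    def test_planted_nonpoised_mostly_not_called(self, default_ds, default_integrated):
        gs = default_ds.gene_sets["early_activation"]
        filt = poised.filter_candidates(gs, default_ds.transcripts, "T1")
        rec = poised.classify_poised(filt, default_integrated, default_ds.transcripts, with_boxes=False)
        non_planted = rec.loc[~rec["gene_id"].isin(default_ds.truth.poised_genes)]
        # non-planted members follow the detection model (~15% naturally missing)
        assert non_planted["poised"].mean() < 0.4
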