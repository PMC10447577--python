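"""Normalization, ANOVA+BH, clustering, presence Venn, Welch, stoichiometry."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from sklearn.metrics import adjusted_rand_score
from statsmodels.stats.multitest import multipletests

from poised_omics import differential as diff
from poised_omics.exceptions import ConfigurationError, PoisedOmicsError
from poised_omics.io_tables import SampleDesign
from poised_omics.ruler import CopyNumberMatrix

from conftest import truth_rows


def bh_stepup_bruteforce(p: np.ndarray) -> np.ndarray:
    """Independent step-up oracle: q_i = min_{j: p_j >= p_i} (m * p_(j) / j)."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        q[i] = min(running, 1.0)
    return q


def _design():
    subsets = ["T1", "T2", "MZ", "FoB"]
    return SampleDesign(pd.DataFrame({
        "sample_id": [f"{s}_{r}" for s in subsets for r in (1, 2, 3, 4)],
        "subset": [s for s in subsets for _ in range(4)],
        "replicate": [r for _ in subsets for r in (1, 2, 3, 4)],
    }))


def _cn_from_matrix(mat: np.ndarray) -> CopyNumberMatrix:
    design = _design()
    n = mat.shape[0]
    meta = pd.DataFrame({
        "group_id": [f"P{i}" for i in range(n)],
        "lead_protein_id": [f"P{i}" for i in range(n)],
        "gene_symbol": [f"g{i}" for i in range(n)],
        "mol_weight_da": np.full(n, 5e4),
        "peptides_total": np.full(n, 10), "peptides_unique": np.full(n, 5),
        "peptides_unique_razor": np.full(n, 6),
    })
    return CopyNumberMatrix(meta, pd.DataFrame(mat, columns=design.sample_ids), design)


class TestNormalize:
    def test_equal_totals_unchanged(self):
        mat = np.tile(np.array([[100.0], [300.0]]), (1, 16))
        norm = diff.normalize_and_log(_cn_from_matrix(mat))
        np.testing.assert_allclose(norm.linear.to_numpy(), mat)

    def test_scaled_sample_restored(self):
        rng = np.random.default_rng(0)
        mat = rng.lognormal(5, 1, (50, 16))
        cn = _cn_from_matrix(mat)
        base = diff.normalize_and_log(cn).linear.to_numpy()
        mat2 = mat.copy()
        mat2[:, 3] *= 2.0
        scaled = diff.normalize_and_log(_cn_from_matrix(mat2)).linear.to_numpy()
        # the doubled sample normalizes back; other samples shift only via the
        # (slightly changed) target mean, uniformly
        np.testing.assert_allclose(scaled[:, 3] / base[:, 3], scaled[:, 0] / base[:, 0], rtol=1e-12)
        np.testing.assert_allclose(scaled[:, 3] * base[:, 0], base[:, 3] * scaled[:, 0], rtol=1e-12)

    def test_sums_equal_after_normalization(self, default_norm):
        lin = default_norm.linear.to_numpy()
        sums = np.nansum(lin, axis=0)
        np.testing.assert_allclose(sums, sums.mean(), rtol=1e-9)

    def test_zero_total_sample_errors(self):
        mat = np.ones((3, 16))
        mat[:, 5] = 0
        with pytest.raises(PoisedOmicsError):
            diff.normalize_and_log(_cn_from_matrix(mat))


class TestAnovaBH:
    def test_constant_protein_untested(self):
        groups = [np.arange(4), np.arange(4, 8), np.arange(8, 12), np.arange(12, 16)]
        f, p, tested = diff._anova_oneway_nan(np.vstack([np.full(16, 7.0)]), groups)
        assert not tested[0] and np.isnan(f[0])

    def test_f_matches_scipy_oracle(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(10, 2, (200, 16))
        groups = [np.arange(4), np.arange(4, 8), np.arange(8, 12), np.arange(12, 16)]
        f, p, tested = diff._anova_oneway_nan(vals, groups)
        for i in range(200):
            ref = stats.f_oneway(*[vals[i, g] for g in groups])
            assert f[i] == pytest.approx(ref.statistic, abs=1e-10, rel=1e-10)
            assert p[i] == pytest.approx(ref.pvalue, abs=1e-10, rel=1e-10)

    def test_missing_value_policy(self):
        groups = [np.arange(4), np.arange(4, 8), np.arange(8, 12), np.arange(12, 16)]
        row = np.full(16, np.nan)
        row[:4] = [1, 2, 3, 4]
        row[4] = 9.0  # only one value in T2 -> group dropped
        vals = np.vstack([row])
        f, p, tested = diff._anova_oneway_nan(vals, groups)
        assert not tested[0]  # only one usable group remains
        row2 = row.copy()
        row2[5] = 11.0  # two values in T2 -> two usable groups
        f2, p2, tested2 = diff._anova_oneway_nan(np.vstack([row2]), groups)
        assert tested2[0]
        ref = stats.f_oneway(np.array([1, 2, 3, 4.0]), np.array([9.0, 11.0]))
        assert f2[0] == pytest.approx(ref.statistic, rel=1e-10)

    def test_bh_worked_example(self):
        q = bh_stepup_bruteforce(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])
        q2 = multipletests(np.array([0.01, 0.02, 0.03, 0.04]), method="fdr_bh")[1]
        np.testing.assert_allclose(q2, q)

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=60))
    def test_bh_matches_bruteforce(self, pvals):
        p = np.array(pvals)
        q_lib = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(q_lib, bh_stepup_bruteforce(p), atol=1e-12)

    def test_q_at_least_p_and_significance(self, default_norm):
        de = diff.anova_bh(default_norm)
        t = de[de.tested]
        assert (t.q >= t.p - 1e-15).all()
        assert (de.loc[de.significant, "q"] < 0.05).all()


class TestDeviation:
    @staticmethod
    def _norm(mat: np.ndarray) -> diff.NormalizedMatrix:
        design = _design()
        lin = pd.DataFrame(mat, columns=design.sample_ids)
        with np.errstate(divide="ignore"):
            lg = np.log2(mat)
        return diff.NormalizedMatrix(lin, pd.DataFrame(lg, columns=design.sample_ids), design, pd.DataFrame())

    def test_equal_means_all_zero(self):
        dev = diff.log2_deviation_from_mean(self._norm(np.full((2, 16), 100.0)))
        np.testing.assert_allclose(dev.to_numpy(), 0.0, atol=1e-12)

    def test_two_fold_pattern(self):
        row = np.concatenate([np.full(4, 200.0), np.full(12, 100.0)])
        dev = diff.log2_deviation_from_mean(self._norm(np.vstack([row])))
        np.testing.assert_allclose(dev.to_numpy()[0], [0.75, -0.25, -0.25, -0.25], atol=1e-12)

    def test_rows_sum_to_zero(self, default_norm):
        dev = diff.log2_deviation_from_mean(default_norm)
        sums = np.nansum(dev.to_numpy(), axis=1)
        np.testing.assert_allclose(sums, 0.0, atol=1e-9)


class TestClustering:
    def test_noiseless_archetypes_fully_recovered(self):
        from poised_omics.synthetic_data import DE_ARCHETYPES

        centered = DE_ARCHETYPES - DE_ARCHETYPES.mean(axis=1, keepdims=True)
        dev = pd.DataFrame(np.repeat(centered, 50, axis=0), columns=["T1", "T2", "MZ", "FoB"])
        labels = diff.cluster_de_proteins(dev, k=6)
        truth = np.repeat(np.arange(6), 50)
        assert adjusted_rand_score(truth, labels.to_numpy()) == 1.0

    def test_k_one_single_cluster(self):
        dev = pd.DataFrame(np.random.default_rng(0).normal(size=(10, 4)), columns=["T1", "T2", "MZ", "FoB"])
        labels = diff.cluster_de_proteins(dev, k=1)
        assert set(labels) == {1}

    def test_fewer_rows_than_k_errors(self):
        dev = pd.DataFrame(np.zeros((3, 4)), columns=["T1", "T2", "MZ", "FoB"])
        with pytest.raises(ConfigurationError):
            diff.cluster_de_proteins(dev, k=6)

    def test_default_bundle_recovers_planted_clusters(self, default_ds, default_cn, default_norm):
        de = diff.anova_bh(default_norm)
        dev = diff.log2_deviation_from_mean(default_norm)
        sig_idx = de.index[de.significant]
        labels = diff.cluster_de_proteins(dev.loc[sig_idx]).dropna()
        genes = truth_rows(default_ds, default_cn)
        true_cl = default_ds.truth.genes.loc[genes, "cluster"].to_numpy()
        tc = true_cl[labels.index.to_numpy()]
        m = tc > 0
        assert adjusted_rand_score(tc[m], labels.to_numpy()[m]) >= 0.8


class TestPresenceVenn:
    def _cn(self, patterns):
        mat = np.zeros((len(patterns), 16))
        for i, pat in enumerate(patterns):
            for j, n in enumerate(pat):
                mat[i, 4 * j: 4 * j + n] = 1000.0
        return _cn_from_matrix(mat)

    def test_unique_and_full_intersection(self):
        cn = self._cn([(0, 0, 4, 0), (3, 3, 3, 3), (2, 2, 2, 2)])
        venn = diff.presence_venn(cn)
        assert venn[("MZ",)] == 1
        assert venn[("T1", "T2", "MZ", "FoB")] == 1
        assert sum(venn.values()) == 2  # the 2/4-everywhere protein is absent

    def test_invariant_to_column_order(self, small_cn):
        base = diff.presence_venn(small_cn)
        design = small_cn.design
        perm = np.random.default_rng(3).permutation(16)
        new_design = SampleDesign(design.table.iloc[perm].reset_index(drop=True))
        shuffled = CopyNumberMatrix(small_cn.meta, small_cn.copies, new_design)
        result = diff.presence_venn(shuffled)
        assert {frozenset(k): v for k, v in result.items()} == {
            frozenset(k): v for k, v in base.items()
        }

    def test_regions_sum_to_expressed_proteins(self, default_cn):
        venn = diff.presence_venn(default_cn)
        expressed = default_cn.detected().any(axis=1).sum()
        assert sum(venn.values()) == expressed


class TestWelch:
    def test_identical_groups_null(self):
        a = pd.DataFrame([[5.0, 5.0, 5.0]])
        res = diff.welch_volcano(a, a)
        assert res.t[0] == 0.0 and res.p[0] == 1.0

    def test_closed_form_oracle(self):
        wt = pd.DataFrame([[1.0, 2.0, 3.0]])
        ko = pd.DataFrame([[4.0, 5.0, 6.0]])
        res = diff.welch_volcano(wt, ko)
        va = vb = 1.0
        t = (5.0 - 2.0) / np.sqrt(va / 3 + vb / 3)
        df = (va / 3 + vb / 3) ** 2 / ((va / 3) ** 2 / 2 + (vb / 3) ** 2 / 2)
        p = 2 * stats.t.sf(abs(t), df)
        assert res.t[0] == pytest.approx(t, rel=1e-12)
        assert res.p[0] == pytest.approx(p, rel=1e-12)

    def test_planted_fold_changes_all_hit(self):
        from poised_omics.synthetic_data import generate_two_group

        wt, ko, planted = generate_two_group(n_proteins=2000, n_planted=24, log2_fc=5.0, seed=5)
        res = diff.welch_volcano(wt, ko)
        assert res.hit.to_numpy()[planted].all()

    def test_insufficient_replicates_untested(self):
        wt = pd.DataFrame([[1.0, np.nan, np.nan]])
        ko = pd.DataFrame([[2.0, 3.0, 4.0]])
        res = diff.welch_volcano(wt, ko)
        assert not res.tested[0]


class TestStoichiometry:
    def test_equal_copies_ratio_one(self):
        mat = np.full((2, 16), 5000.0)
        rep = diff.stoichiometry_ratio(_cn_from_matrix(mat), "g0", "g1")
        assert (rep["ratio"] == 1.0).all()

    def test_zero_denominator_undefined_not_raising(self):
        mat = np.vstack([np.full(16, 5000.0), np.zeros(16)])
        rep = diff.stoichiometry_ratio(_cn_from_matrix(mat), "g0", "g1")
        assert rep["ratio"].isna().all()

    def test_known_ratio(self):
        mat = np.vstack([np.full(16, 26000.0), np.full(16, 10000.0)])
        rep = diff.stoichiometry_ratio(_cn_from_matrix(mat), "g0", "g1")
        assert rep["ratio"].to_numpy() == pytest.approx(2.6)
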