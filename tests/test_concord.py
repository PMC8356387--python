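"""Concordance statistics against independent brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy import stats

import snconcord as s

from conftest import make_matrix


class TestDetectedGeneSet:
    def test_three_droplet_threshold(self):
        counts = np.zeros((2, 5), dtype=int)
        counts[0, :3] = 1
        counts[1, :2] = 9
        mat = make_matrix(counts)
        assert s.detected_gene_set(mat, min_cells=3) == {"g0000"}

    def test_degenerate_threshold(self):
        counts = np.array([[0, 0, 7], [0, 0, 0]])
        mat = make_matrix(counts)
        assert s.detected_gene_set(mat, min_cells=1) == {"g0000"}

    def test_all_zero_matrix(self):
        mat = make_matrix(np.zeros((3, 4), dtype=int))
        assert s.detected_gene_set(mat) == set()


class TestGeneSetOverlap:
    def test_identity(self):
        st = s.gene_set_overlap({"a", "b"}, {"a", "b"})
        assert st["jaccard"] == 1.0
        assert st["percent_of_smaller"] == 100.0

    def test_disjoint(self):
        st = s.gene_set_overlap({"a"}, {"b"})
        assert st["jaccard"] == 0.0
        assert st["percent_of_smaller"] == 0.0

    def test_worked_example(self):
        st = s.gene_set_overlap({"g1", "g2", "g3", "g4"}, {"g3", "g4", "g5", "g6"})
        assert st["n_intersection"] == 2
        assert st["jaccard"] == pytest.approx(1 / 3)
        assert st["percent_of_smaller"] == pytest.approx(50.0)

    def test_symmetric(self):
        a, b = {"x", "y", "z"}, {"y", "q"}
        sa = s.gene_set_overlap(a, b)
        sb = s.gene_set_overlap(b, a)
        assert sa["jaccard"] == sb["jaccard"]
        assert sa["n_intersection"] == sb["n_intersection"]


class TestMeanProfiles:
    def test_single_droplet_mean_is_its_vector(self):
        ln = sp.csr_matrix(np.array([[1.0], [0.5]]))
        means, _ = s.celltype_mean_profiles(ln, ["beta"], ["g1", "g2"])
        assert means["beta"].tolist() == [1.0, 0.5]

    def test_mean_arithmetic(self):
        ln = sp.csr_matrix(np.array([[0.0, 2.0]]))
        means, small = s.celltype_mean_profiles(ln, ["t", "t"], ["g1"])
        assert means.loc["g1", "t"] == 1.0
        assert small["t"] is True  # fewer than 10 droplets

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        ln = rng.random((6, 20))
        types = np.array(["a"] * 12 + ["b"] * 8)
        m1, _ = s.celltype_mean_profiles(sp.csr_matrix(ln), types, [f"g{i}" for i in range(6)])
        perm = rng.permutation(20)
        m2, _ = s.celltype_mean_profiles(
            sp.csr_matrix(ln[:, perm]), types[perm], [f"g{i}" for i in range(6)]
        )
        assert np.allclose(m1[sorted(m1.columns)], m2[sorted(m2.columns)])


class TestProfileCorrelation:
    def _means(self, data):
        return pd.DataFrame(data, index=[f"g{i}" for i in range(len(next(iter(data.values()))))])

    def test_identity_r2(self):
        x = np.arange(12.0)
        out = s.profile_correlation(self._means({"t": x}), self._means({"t": x}))
        assert out["r2"].item() == pytest.approx(1.0)

    def test_affine_r2(self):
        x = np.arange(12.0)
        out = s.profile_correlation(self._means({"t": x}), self._means({"t": 3 - 2 * x}))
        assert out["r2"].item() == pytest.approx(1.0)

    def test_worked_four_point_example(self):
        x = np.array([0.0, 1, 2, 3] * 3)
        y = np.array([0.0, 1, 1, 2] * 3)
        out = s.profile_correlation(self._means({"t": x}), self._means({"t": y}))
        assert out["r"].item() == pytest.approx(3 / np.sqrt(10))
        assert out["r2"].item() == pytest.approx(0.9)

    def test_too_few_shared_genes(self):
        with pytest.raises(ValueError, match="shared genes"):
            s.profile_correlation(
                self._means({"t": np.arange(4.0)}), self._means({"t": np.arange(4.0)})
            )

    def test_matches_scipy_on_random_profiles(self):
        rng = np.random.default_rng(5)
        a = self._means({"u": rng.random(40), "v": rng.random(40)})
        b = self._means({"w": rng.random(40)})
        out = s.profile_correlation(a, b)
        for _, row in out.iterrows():
            r, p = stats.pearsonr(a[row.type_a], b[row.type_b])
            assert row.r == pytest.approx(r)
            assert row.p == pytest.approx(p)


class TestTopGeneOverlap:
    def _means(self, values, genes):
        return pd.DataFrame({"t": values}, index=genes)

    def test_identity_full_overlap(self):
        rng = np.random.default_rng(1)
        m = self._means(rng.random(1200), [f"g{i:05d}" for i in range(1200)])
        out = s.top_gene_overlap(m, m)
        assert (out["overlap"] == 1.0).all()
        assert sorted(out["n"]) == [100, 200, 500, 1000]

    def test_worked_small_example(self):
        genes = ["g1", "g2", "g3", "g4", "g5"]
        a = self._means([5.0, 4.0, 3.0, 1.0, 0.5], genes)
        b = self._means([0.5, 5.0, 4.0, 3.0, 1.0], genes)
        out = s.top_gene_overlap(a, b, n_list=[3])
        # topA = {g1,g2,g3}, topB = {g2,g3,g4} -> 2/3
        assert out["overlap"].item() == pytest.approx(2 / 3)

    def test_disjoint_supports(self):
        genes = [f"g{i}" for i in range(6)]
        a = self._means([3.0, 2.0, 1.0, 0, 0, 0], genes)
        b = self._means([0, 0, 0, 3.0, 2.0, 1.0], genes)
        out = s.top_gene_overlap(a, b, n_list=[3])
        assert out["overlap"].item() == 0.0

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(300)]
        a = self._means(rng.random(300), genes)
        b = self._means(rng.random(300), genes)
        oab = s.top_gene_overlap(a, b, n_list=[100])["overlap"].item()
        oba = s.top_gene_overlap(b, a, n_list=[100])["overlap"].item()
        assert oab == oba

    def test_infeasible_n_skipped_with_warning(self):
        genes = [f"g{i}" for i in range(50)]
        m = self._means(np.arange(50.0), genes)
        with pytest.warns(UserWarning, match="smaller than max N"):
            out = s.top_gene_overlap(m, m)
        assert out.empty


class TestDetectionRates:
    def test_rate_arithmetic(self):
        counts = np.zeros((3, 10), dtype=int)
        counts[0, :7] = 2
        counts[2, :] = 1
        mat = make_matrix(counts)
        rates = s.detection_rates(mat)
        assert rates.loc["g0000", "pct_detected"] == pytest.approx(70.0)
        assert rates.loc["g0001", "pct_detected"] == 0.0
        assert rates.loc["g0002", "pct_detected"] == 100.0

    def test_zero_droplets_rejected(self):
        mat = make_matrix(np.zeros((3, 1), dtype=int)).subset_droplets(np.array([], dtype=int))
        with pytest.raises(ValueError, match="zero droplets"):
            s.detection_rates(mat)


class TestDetectionEnrichment:
    def _rates(self, detected, n):
        genes = [f"g{i}" for i in range(len(detected))]
        return pd.DataFrame(
            {
                "n_detected": detected,
                "pct_detected": 100.0 * np.asarray(detected) / n,
            },
            index=pd.Index(genes, name="gene_id"),
        )

    def _anno(self, n, biotypes=None):
        return pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(n)],
                "biotype": biotypes or ["protein_coding"] * n,
            }
        )

    def test_equal_rates_not_enriched(self):
        sn = self._rates([30, 300], 1000)
        sc = self._rates([30, 300], 1000)
        table, _ = s.detection_enrichment(sn, sc, 1000, 1000, self._anno(2))
        assert (table["fold_change"] == 1.0).all()
        assert not table["enriched"].any()

    def test_fold_change_values(self):
        sn = self._rates([700, 155], 1000)
        sc = self._rates([355, 10], 1000)
        table, _ = s.detection_enrichment(sn, sc, 1000, 1000, self._anno(2))
        t = table.set_index("gene_id")
        assert t.loc["g0", "fold_change"] == pytest.approx(700 / 355)
        assert t.loc["g1", "fold_change"] == pytest.approx(15.5)
        assert t.loc["g0", "enriched"]

    def test_zero_denominator_flagged_infinite(self):
        sn = self._rates([50, 10], 1000)
        sc = self._rates([0, 10], 1000)
        table, _ = s.detection_enrichment(sn, sc, 1000, 1000, self._anno(2))
        t = table.set_index("gene_id")
        assert np.isinf(t.loc["g0", "fold_change"])
        assert t.loc["g0", "fold_undefined"]
        assert t.loc["g0", "enriched"]  # 5% vs 0% in 1000 droplets is significant

    def test_pvalues_match_statsmodels(self):
        """Vectorised two-proportion z-test agrees with the reference
        implementation in statsmodels on every gene."""
        from statsmodels.stats.proportion import proportions_ztest

        rng = np.random.default_rng(3)
        k_sn = rng.integers(1, 900, 25)
        k_sc = rng.integers(1, 900, 25)
        sn, sc = self._rates(k_sn, 1000), self._rates(k_sc, 900)
        table, _ = s.detection_enrichment(sn, sc, 1000, 900, self._anno(25), alpha=0.05)
        t = table.set_index("gene_id")
        for i in range(25):
            _, p_ref = proportions_ztest(
                [k_sn[i], k_sc[i]], [1000, 900], alternative="two-sided"
            )
            assert t.loc[f"g{i}", "p"] == pytest.approx(p_ref, rel=1e-9)

    def test_biotype_proportions_sum_to_one(self):
        sn = self._rates([800, 700, 20], 1000)
        sc = self._rates([100, 90, 20], 1000)
        table, props = s.detection_enrichment(
            sn, sc, 1000, 1000, self._anno(3, ["lncRNA", "protein_coding", "lncRNA"])
        )
        assert props.sum() == pytest.approx(1.0)
        assert set(props.index) <= {"lncRNA", "protein_coding"}

    def test_mismatched_gene_spaces_rejected(self):
        sn = self._rates([10, 10], 100)
        sc = self._rates([10, 10, 10], 100)
        with pytest.raises(ValueError, match="gene spaces"):
            s.detection_enrichment(sn, sc, 100, 100, self._anno(3))


class TestOracleEquivalence:
    def test_statistics_match_brute_force_on_random_matrix(self):
        """Every concordance statistic equals a direct recomputation from
        first principles on a small random matrix."""
        rng = np.random.default_rng(11)
        counts_a = rng.poisson(0.8, size=(120, 90))
        counts_b = rng.poisson(0.6, size=(120, 70))
        mat_a = make_matrix(counts_a)
        mat_b = make_matrix(counts_b)

        # detected sets
        set_a = s.detected_gene_set(mat_a)
        brute_a = {
            f"g{i:04d}" for i in range(120) if (counts_a[i] > 0).sum() >= 3
        }
        assert set_a == brute_a

        # detection rates
        rates = s.detection_rates(mat_b)
        for i in (0, 17, 119):
            assert rates.iloc[i]["pct_detected"] == pytest.approx(
                100.0 * (counts_b[i] > 0).mean()
            )

        # per-type means and pearson
        types_a = np.where(np.arange(90) % 2 == 0, "x", "y")
        ln_a = s.normalize_ln(mat_a)
        means, _ = s.celltype_mean_profiles(ln_a, types_a, mat_a.genes["gene_id"])
        brute_mean = np.log1p(counts_a[:, types_a == "x"]).mean(axis=1)
        assert np.allclose(means["x"].to_numpy(), brute_mean)
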