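"""CPM/TMM/dispersion/threshold-test unit and recovery tests."""

import numpy as np
import pandas as pd
import pytest

from qsig import dge, simdata


def _meta(groups, cell_lines=None):
    n = len(groups)
    return pd.DataFrame(
        {"group": groups,
         "cell_line": cell_lines or ["CL1"] * n,
         "replicate": range(n)},
        index=[f"s{i}" for i in range(n)])


class TestCpm:
    def test_single_sample_hand_values(self):
        counts = pd.DataFrame({"s0": [1, 1]}, index=["a", "b"])
        cpm = dge.compute_cpm(counts)
        assert np.allclose(cpm["s0"], [5e5, 5e5])

    def test_scale_invariance(self):
        counts = pd.DataFrame({"s0": [3, 7, 10], "s1": [1, 2, 3]},
                              index=list("abc"))
        doubled = counts.copy()
        doubled["s0"] *= 2
        pd.testing.assert_series_equal(dge.compute_cpm(counts)["s0"],
                                       dge.compute_cpm(doubled)["s0"])

    def test_norm_factor_hand_oracle(self):
        counts = pd.DataFrame({"s0": [2, 3, 5], "s1": [1, 1, 2]},
                              index=list("abc"))
        factors = pd.Series([1.0, 2.0], index=["s0", "s1"])
        cpm = dge.compute_cpm(counts, factors)
        # library sizes 10 and 4; effective 10 and 8
        expected = pd.DataFrame({"s0": [2e5, 3e5, 5e5],
                                 "s1": [1.25e5, 1.25e5, 2.5e5]},
                                index=list("abc"))
        pd.testing.assert_frame_equal(cpm, expected)

    def test_zero_library_named_in_error(self):
        counts = pd.DataFrame({"good": [1, 2], "empty": [0, 0]},
                              index=list("ab"))
        with pytest.raises(ValueError, match="empty"):
            dge.compute_cpm(counts)


class TestFilterLowExpression:
    def test_all_zero_gene_removed(self):
        counts = pd.DataFrame({"s0": [0, 5], "s1": [0, 8]}, index=["z", "g"])
        out = dge.filter_low_expression(counts, k_cpm=1.0, n_samples=1)
        assert list(out.index) == ["g"]

    def test_zero_threshold_keeps_any_expressed_gene(self):
        counts = pd.DataFrame({"s0": [1, 0], "s1": [2, 0]}, index=["g", "z"])
        out = dge.filter_low_expression(counts, k_cpm=0.0, n_samples=1)
        assert "g" in out.index and "z" not in out.index

    def test_matches_brute_force_rule(self, rng):
        counts = pd.DataFrame(rng.poisson(5, size=(5, 4)),
                              index=[f"g{i}" for i in range(5)],
                              columns=[f"s{i}" for i in range(4)])
        counts.iloc[0] = 0
        k, n = 1.0, 2
        out = dge.filter_low_expression(counts, k_cpm=k, n_samples=n)
        cpm = counts / counts.sum(axis=0) * 1e6
        expected = [g for g in counts.index if (cpm.loc[g] > k).sum() >= n]
        assert list(out.index) == expected

    def test_row_order_preserved(self, small_counts):
        counts, _ = small_counts
        out = dge.filter_low_expression(counts, k_cpm=1.0, n_samples=3)
        assert list(out.index) == [g for g in counts.index if g in out.index]

    def test_n_samples_out_of_range(self):
        counts = pd.DataFrame({"s0": [1], "s1": [1]}, index=["g"])
        with pytest.raises(ValueError):
            dge.filter_low_expression(counts, k_cpm=1, n_samples=3)


class TestTmm:
    def test_identical_columns_unit_factors(self):
        col = [10, 20, 30, 5]
        counts = pd.DataFrame({"s0": col, "s1": col, "s2": col},
                              index=list("abcd"))
        factors = dge.tmm_norm_factors(counts)
        assert np.allclose(factors, 1.0)

    def test_pure_library_size_difference(self):
        rng = np.random.default_rng(0)
        base = rng.poisson(100, size=300)
        counts = pd.DataFrame({"s0": base, "s1": base * 2},
                              index=[f"g{i}" for i in range(300)])
        factors = dge.tmm_norm_factors(counts)
        assert np.allclose(factors, 1.0, atol=1e-6)

    def test_geometric_mean_one(self, small_counts):
        counts, _ = small_counts
        factors = dge.tmm_norm_factors(counts)
        assert abs(np.exp(np.mean(np.log(factors))) - 1.0) < 1e-8

    def test_untrimmed_matches_independent_oracle(self):
        """With trims at 0, the factor is a plain precision-weighted mean of
        M-values, recomputed here from scratch."""
        rng = np.random.default_rng(1)
        base = rng.poisson(200, size=200).astype(float) + 1
        up = base.copy()
        up[:20] *= 8  # 20 genes 8-fold up in sample 2
        counts = pd.DataFrame({"s0": base, "s1": up},
                              index=[f"g{i}" for i in range(200)])
        factors = dge.tmm_norm_factors(counts, trim_M=0.0, trim_A=0.0)

        n0, n1 = counts.sum(axis=0)
        p0, p1 = base / n0, up / n1
        M = np.log2(p1 / p0)
        w = (n1 - up) / (n1 * up) + (n0 - base) / (n0 * base)
        f1 = 2.0 ** (np.sum(M / w) / np.sum(1.0 / w))
        expected = np.array([1 / np.sqrt(f1), np.sqrt(f1)])  # geomean-rescaled
        assert np.allclose(factors.to_numpy(), expected, atol=0.02)

    def test_all_zero_sample_rejected(self):
        counts = pd.DataFrame({"s0": [1, 2], "s1": [0, 0]}, index=list("ab"))
        with pytest.raises(ValueError):
            dge.tmm_norm_factors(counts)


class TestDispersions:
    def _cells(self, truth):
        m = truth.sample_meta
        return m["cell_line"].astype(str) + ":" + m["group"].astype(str)

    def test_poisson_counts_near_zero_dispersion(self):
        counts, truth = simdata.simulate_counts(
            n_genes=2000, de_fraction=0, dispersion=0.0, seed=21)
        est = dge.estimate_dispersions(counts, self._cells(truth))
        assert est.common <= 0.05

    def test_nb_dispersion_recovered(self):
        counts, truth = simdata.simulate_counts(
            n_genes=2000, de_fraction=0, dispersion=0.4, seed=22)
        est = dge.estimate_dispersions(counts, self._cells(truth))
        assert abs(est.common - 0.4) < 0.1

    def test_infinite_prior_gives_trended(self):
        counts, truth = simdata.simulate_counts(
            n_genes=300, de_fraction=0, dispersion=0.2, seed=23)
        est = dge.estimate_dispersions(counts, self._cells(truth),
                                       prior_weight=1e12)
        assert np.allclose(est.tagwise, est.trended, rtol=1e-4)

    def test_no_replication_rejected(self):
        counts = pd.DataFrame({"s0": [5, 8], "s1": [4, 9]}, index=list("ab"))
        groups = pd.Series(["a", "b"], index=["s0", "s1"])
        with pytest.raises(ValueError):
            dge.estimate_dispersions(counts, groups)


class TestThresholdTest:
    def test_inside_threshold_never_called(self):
        """A gene whose estimated |log2FC| < theta cannot be significant."""
        rng = np.random.default_rng(3)
        n = 12
        meta = _meta(["DiD-"] * 6 + ["DiD+"] * 6)
        base = rng.poisson(1000, size=(40, n)).astype(np.int64)
        counts = pd.DataFrame(base, index=[f"g{i}" for i in range(40)],
                              columns=meta.index)
        # plant a tight 1.4-fold gene: inside theta=1.5 by construction
        counts.iloc[0, 6:] = (counts.iloc[0, 6:] * 2 ** 1.4).astype(np.int64)
        res = dge.test_de_threshold(counts, meta, theta=1.5)
        g0 = res.loc["g0"]
        if abs(g0["log2FC"]) < 1.5:
            assert g0["PValue"] > 0.25
            assert g0["direction"] == "ns"

    def test_sensitivity_on_planted_signal(self):
        counts, truth = simdata.simulate_counts(
            n_genes=1000, de_fraction=0.05, lfc_magnitude=3.0, dispersion=0.1,
            seed=31)
        res = dge.test_de_threshold(counts, truth.sample_meta)
        called = set(res.index[res["direction"] != "ns"])
        de_true = set(truth.de_genes)
        assert len(called & de_true) / len(de_true) >= 0.8

    def test_direction_sign_matches_planted_sign(self):
        counts, truth = simdata.simulate_counts(
            n_genes=800, de_fraction=0.05, lfc_magnitude=3.0, dispersion=0.1,
            seed=32, up_fraction=0.5)
        res = dge.test_de_threshold(counts, truth.sample_meta)
        for g in truth.de_genes:
            if res.loc[g, "direction"] != "ns":
                planted_up = truth.log2_fc[g] > 0
                assert (res.loc[g, "direction"] == "up") == planted_up

    def test_threshold_dominance(self, small_counts):
        """Calls at theta=1.5 are a subset of calls at theta=0."""
        counts, truth = small_counts
        meta = truth.sample_meta
        factors = dge.tmm_norm_factors(counts)
        cells = meta["cell_line"].astype(str) + ":" + meta["group"].astype(str)
        disp = dge.estimate_dispersions(counts, cells, factors)
        strict = dge.test_de_threshold(counts, meta, dispersions=disp,
                                       theta=1.5, norm_factors=factors)
        loose = dge.test_de_threshold(counts, meta, dispersions=disp,
                                      theta=0.0, norm_factors=factors)
        called_strict = set(strict.index[strict["direction"] != "ns"])
        called_loose = set(loose.index[loose["direction"] != "ns"])
        assert called_strict <= called_loose

    def test_bh_monotone(self, small_counts):
        counts, truth = small_counts
        res = dge.test_de_threshold(counts, truth.sample_meta)
        ordered = res.sort_values("PValue", kind="stable")
        assert (np.diff(ordered["FDR"].to_numpy()) >= -1e-12).all()

    def test_singular_design_rejected(self):
        meta = _meta(["DiD-", "DiD-", "DiD+", "DiD+"],
                     ["CL1", "CL1", "CL2", "CL2"])  # group == cell line
        counts = pd.DataFrame(
            np.random.default_rng(0).poisson(50, size=(10, 4)),
            index=[f"g{i}" for i in range(10)], columns=meta.index)
        with pytest.raises(ValueError, match="singular"):
            dge.test_de_threshold(counts, meta)


class TestClusterSamples:
    def test_duplicated_sample_merges_first_at_zero(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(30, 4))
        x[:, 1] = x[:, 0]
        df = pd.DataFrame(x, columns=list("abcd"))
        res = dge.cluster_samples(df)
        assert res.linkage_matrix[0, 2] == pytest.approx(0.0)
        assert set(res.linkage_matrix[0, :2].astype(int)) == {0, 1}

    def test_groups_separate_in_first_bipartition(self):
        counts, truth = simdata.simulate_counts(
            n_genes=400, de_fraction=0.3, lfc_magnitude=4.0, dispersion=0.05,
            n_celllines=1, n_reps=5, seed=6)
        logcpm = dge.compute_cpm(counts, log2=True)
        res = dge.cluster_samples(logcpm)
        from scipy.cluster.hierarchy import fcluster
        labels = fcluster(res.linkage_matrix, t=2, criterion="maxclust")
        groups = truth.sample_meta["group"].to_numpy()
        # the two-cluster cut must coincide with DiD-/DiD+
        tab = pd.crosstab(labels, groups)
        assert (tab.to_numpy() == 0).sum() == 2

    def test_full_pca_preserves_distances(self, rng):
        df = pd.DataFrame(rng.normal(size=(20, 6)))
        res = dge.cluster_samples(df)
        from scipy.spatial.distance import pdist
        orig = pdist(df.to_numpy().T)
        proj = pdist(res.pca_scores.to_numpy())
        assert np.allclose(orig, proj, atol=1e-8)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            dge.cluster_samples(pd.DataFrame({"s0": [1.0, 2.0]}))
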