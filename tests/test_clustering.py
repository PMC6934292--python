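import numpy as np
import pandas as pd
import pytest
from sklearn.datasets import make_blobs
from sklearn.metrics import adjusted_rand_score

import spathet as sp
from spathet.clustering import retained_markers
from spathet.synthetic import DEFAULT_HALLMARKS, GroupSpec, SyntheticConfig, make_phenotype_means


@pytest.fixture(scope="module")
def blobs4():
    X, y = make_blobs(n_samples=1500, centers=4, cluster_std=0.5, random_state=0)
    return X, y


@pytest.fixture(scope="module")
def seven_phenotype_sample(markers):
    phens = tuple(f"p{i + 1}" for i in range(7))
    means = make_phenotype_means(phens, markers, separation=2.0, marker_log_sd=1.0, seed=0)
    cfg = SyntheticConfig(
        groups={"g": GroupSpec(phens, 1.0)},
        phenotype_marker_means=means,
        cells_per_sample=4000,
        n_subjects_per_group=1,
        rng_seed=0,
    )
    t = sp.generate_sample(cfg, "g", "s1", 0)
    lg = sp.log2_transform(t)
    pre = sp.fit_preprocess(lg.df[list(markers)])
    X, _ = sp.apply_preprocess(pre, lg.df[list(markers)])
    return t, lg, X, means


class TestPreprocess:
    def test_standardized_mean_zero_sd_one(self):
        rng = np.random.default_rng(0)
        V = rng.normal(5, 2, size=(2000, 3))
        pre = sp.fit_preprocess(V)
        X, _ = sp.apply_preprocess(pre, V)
        np.testing.assert_allclose(X.mean(axis=0), 0, atol=1e-9)
        np.testing.assert_allclose(X.std(axis=0), 1, atol=0.05)

    def test_extreme_value_clipped_to_trim_bound(self):
        rng = np.random.default_rng(1)
        v = rng.normal(0, 1, 4000)
        pre = sp.fit_preprocess(v[:, None])
        p99 = np.quantile(v, 0.99)
        clipped = np.clip(p99, pre.lower[0], pre.upper[0])
        assert clipped == pytest.approx(pre.upper[0])  # 99th pct maps to 97.5th bound

    def test_constant_marker_flagged_and_excluded(self):
        rng = np.random.default_rng(2)
        V = np.column_stack([rng.normal(size=500), np.full(500, 3.0)])
        pre = sp.fit_preprocess(V, markers=("a", "const"))
        assert pre.dropped == ("const",)
        X, _ = sp.apply_preprocess(pre, V)
        assert X.shape[1] == 1
        assert retained_markers(pre) == ("a",)

    def test_trim_cells_mode_removes_rows(self):
        rng = np.random.default_rng(3)
        V = rng.normal(size=(1000, 2))
        pre = sp.fit_preprocess(V, mode="trim_cells")
        X, keep = sp.apply_preprocess(pre, V)
        assert keep.sum() < 1000
        assert len(X) == keep.sum()


class TestKMeansScan:
    def test_silhouette_maximal_at_two_blobs(self):
        X, _ = make_blobs(n_samples=800, centers=2, cluster_std=0.4, random_state=1)
        models = sp.kmeans_scan(X, range(2, 7), seed=0)
        best = max(models, key=lambda m: m.silhouette)
        assert best.k == 2

    def test_sse_non_increasing_in_k(self, blobs4):
        X, _ = blobs4
        models = sp.kmeans_scan(X, range(2, 10), seed=0)
        sses = [m.sse for m in models]
        assert all(b <= a * (1 + 1e-9) for a, b in zip(sses, sses[1:]))

    def test_deterministic_given_seed(self, blobs4):
        X, _ = blobs4
        m1 = sp.kmeans_scan(X, [3], seed=7)[0]
        m2 = sp.kmeans_scan(X, [3], seed=7)[0]
        np.testing.assert_array_equal(m1.labels, m2.labels)

    def test_labels_one_based_nonempty(self, blobs4):
        X, _ = blobs4
        m = sp.kmeans_scan(X, [5], seed=0)[0]
        assert set(m.labels) == {1, 2, 3, 4, 5}

    def test_k_exceeding_cells_errors(self):
        with pytest.raises(ValueError, match="exceeds"):
            sp.kmeans_scan(np.zeros((3, 2)), [5], seed=0)


class TestConsensus:
    def test_separated_blobs_give_binary_consensus(self):
        X, y = make_blobs(n_samples=300, centers=3, cluster_std=0.1, random_state=2)
        res = sp.consensus_cluster(X, [3], n_iterations=25, seed=0, n_starts=5)[0]
        v = res.values().astype(np.float64)
        assert np.all((v < 1e-9) | (v > 1 - 1e-9))
        # within-blob 1, between-blob 0
        same = y[:, None] == y[None, :]
        iu = np.triu_indices(len(X), k=1)
        finite = np.isfinite(res.consensus[iu])
        np.testing.assert_allclose(res.consensus[iu][finite], same[iu][finite])

    def test_matrix_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(120, 3))
        res = sp.consensus_cluster(X, [4], n_iterations=15, seed=1)[0]
        C = res.consensus
        np.testing.assert_allclose(C, C.T, equal_nan=True)
        d = np.diag(C)
        np.testing.assert_allclose(d[np.isfinite(d)], 1.0)

    def test_stable_across_seeds_for_separated_data(self):
        X, _ = make_blobs(n_samples=500, centers=3, cluster_std=0.1, random_state=3)
        r1 = sp.consensus_cluster(X, [3], n_iterations=50, seed=10)[0]
        r2 = sp.consensus_cluster(X, [3], n_iterations=50, seed=20)[0]
        m = np.isfinite(r1.consensus) & np.isfinite(r2.consensus)
        np.testing.assert_allclose(r1.consensus[m], r2.consensus[m], atol=1e-9)

    def test_resample_fraction_validated(self):
        with pytest.raises(ValueError, match="resample_fraction"):
            sp.consensus_cluster(np.zeros((10, 2)), [2], resample_fraction=1.5)


class TestChooseK:
    def test_clean_mixture_all_criteria_agree(self, blobs4):
        X, _ = blobs4
        models = sp.kmeans_scan(X, range(2, 8), seed=0)
        cons = sp.consensus_cluster(X, range(2, 8), subsample_cells=600,
                                    n_iterations=25, seed=0)
        sel = sp.choose_k(models, cons)
        assert sel.recommended_k == 4
        assert "criteria_disagree" not in sel.flags
        assert max(models, key=lambda m: m.silhouette).k == 4

    def test_single_blob_flagged_unreliable(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(800, 6))
        models = sp.kmeans_scan(X, range(2, 7), seed=0)
        cons = sp.consensus_cluster(X, range(2, 7), subsample_cells=500,
                                    n_iterations=20, seed=0)
        sel = sp.choose_k(models, cons)
        assert "unreliable" in sel.flags

    def test_report_table_contains_all_metrics(self, blobs4):
        X, _ = blobs4
        models = sp.kmeans_scan(X, range(2, 5), seed=0)
        cons = sp.consensus_cluster(X, range(2, 5), subsample_cells=400,
                                    n_iterations=15, seed=0)
        sel = sp.choose_k(models, cons)
        for col in ("sse", "silhouette", "calinski", "consensus_cdf_area",
                    "consensus_sharpness"):
            assert col in sel.table.columns


class TestProfilesAndComposition:
    def test_k1_profile_is_zero_with_full_percentage(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(200, 3))
        model = sp.ClusterModel(
            k=1, centroids=X.mean(axis=0, keepdims=True),
            labels=np.ones(200, dtype=int), sse=0.0, silhouette=0.0,
            calinski=0.0, n_starts=1, seed=None,
        )
        prof = sp.cluster_profiles(model, X)
        np.testing.assert_allclose(prof.deviations.to_numpy(), 0, atol=1e-12)
        assert prof.percentages.sum() == pytest.approx(100.0)

    def test_size_weighted_deviations_conserved(self, blobs4):
        X, _ = blobs4
        m = sp.kmeans_scan(X, [4], seed=0)[0]
        prof = sp.cluster_profiles(m, X)
        weighted = (
            prof.deviations.mul(prof.percentages / 100.0, axis=0).sum(axis=0)
        )
        np.testing.assert_allclose(weighted, 0, atol=1e-9)
        assert prof.percentages.sum() == pytest.approx(100.0)

    def test_recovers_generator_shifts(self, seven_phenotype_sample, markers):
        t, lg, X, means = seven_phenotype_sample
        m7 = sp.kmeans_scan(X, [7], seed=0)[0]
        # profiles in raw log2 space against the generator's known means
        L = lg.df[list(markers)].to_numpy()
        prof = sp.cluster_profiles(m7, L, markers)
        truth = t.df["true_phenotype"].to_numpy()
        pop_mean = L.mean(axis=0)
        for c in range(1, 8):
            mask = m7.labels == c
            phen = pd.Series(truth[mask]).mode()[0]
            expected = np.array([means[phen][m] for m in markers]) - pop_mean
            np.testing.assert_allclose(
                prof.deviations.loc[c].to_numpy(), expected, atol=0.35
            )

    def test_composition_rows_sum_to_one_and_indicator_case(self):
        labels = np.array([2, 2, 2, 1, 3])
        model = sp.ClusterModel(k=3, centroids=np.zeros((3, 2)), labels=labels,
                                sse=0, silhouette=0, calinski=0, n_starts=1, seed=None)
        comp = sp.sample_composition(model, ["a", "a", "a", "b", "b"])
        np.testing.assert_allclose(comp.sum(axis=1), 1.0)
        assert comp.loc["a"].tolist() == [0.0, 1.0, 0.0]

    def test_missing_phenotype_gives_near_zero_fraction(self, markers):
        # group A has phenotypes 1-2, group B has 1-3; the cluster matched to
        # phenotype 3 should be (near) absent from A's samples
        phens = ("p1", "p2", "p3")
        means = make_phenotype_means(phens, markers, 3.0, 1.0, seed=1)
        cfg = SyntheticConfig(
            groups={"A": GroupSpec(phens[:2], 1.0), "B": GroupSpec(phens, 1.0)},
            phenotype_marker_means=means, cells_per_sample=600,
            n_subjects_per_group=2, rng_seed=1,
        )
        tables, meta = sp.generate_cohort(cfg)
        df = pd.concat([t.df for t in tables.values()], ignore_index=True)
        lg = sp.log2_transform(sp.CellTable(df=df, markers=tuple(markers)))
        pre = sp.fit_preprocess(lg.df[list(markers)])
        X, _ = sp.apply_preprocess(pre, lg.df[list(markers)])
        m3 = sp.kmeans_scan(X, [3], seed=0)[0]
        comp = sp.sample_composition(m3, lg.df["sample_id"].to_numpy())
        truth = lg.df["true_phenotype"].to_numpy()
        cluster_of_p3 = pd.Series(m3.labels[truth == "p3"]).mode()[0]
        a_samples = meta.loc[meta["group"] == "A", "sample_id"]
        assert comp.loc[a_samples, cluster_of_p3].mean() < 0.05

    def test_cell_order_invariance_end_to_end(self, markers):
        rng = np.random.default_rng(6)
        V = rng.normal(size=(400, len(markers)))
        perm = rng.permutation(400)
        pre1 = sp.fit_preprocess(V, markers)
        pre2 = sp.fit_preprocess(V[perm], markers)
        np.testing.assert_allclose(pre1.mean, pre2.mean)
        X1, _ = sp.apply_preprocess(pre1, V)
        X2, _ = sp.apply_preprocess(pre2, V[perm])
        np.testing.assert_allclose(X1[perm], X2, atol=1e-12)
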