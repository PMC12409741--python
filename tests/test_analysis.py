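"""Latent-analysis battery against hand-computed and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist
from sklearn.metrics import silhouette_samples

import fclatent as fl
from fclatent.analysis import DegenerateInputError, default_lambda_grid


def brute_force_silhouette(points, labels, metric):
    """Double-loop textbook silhouette per sample."""
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    if metric == "euclidean":
        d = cdist(points, points)
    else:
        d = 1.0 - np.corrcoef(points)
        np.fill_diagonal(d, 0.0)
    out = np.full(len(points), np.nan)
    for i in range(len(points)):
        own = [j for j in range(len(points)) if labels[j] == labels[i] and j != i]
        if not own:
            continue
        a = sum(d[i, j] for j in own) / len(own)
        b = min(
            np.mean([d[i, j] for j in range(len(points)) if labels[j] == u])
            for u in set(labels) if u != labels[i]
        )
        out[i] = (b - a) / max(a, b)
    return out


class TestSilhouette:
    def test_perfectly_separated_clusters_reach_nearly_one(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(20, 2)) * 0.01
        b = rng.normal(size=(20, 2)) * 0.01 + 1000.0
        res = fl.silhouette(np.vstack([a, b]), [0] * 20 + [1] * 20)
        assert res.overall_mean > 0.999

    def test_hand_computed_one_dimensional_example(self):
        # points {0, 0.1} vs {10, 10.1}: a(0)=0.1, b(0)=10.05
        pts = np.array([[0.0], [0.1], [10.0], [10.1]])
        res = fl.silhouette(pts, ["x", "x", "y", "y"])
        expected = (10.05 - 0.1) / 10.05
        assert res.si[0] == pytest.approx(expected, abs=1e-12)
        assert res.a[0] == pytest.approx(0.1)
        assert res.b[0] == pytest.approx(10.05)

    @pytest.mark.parametrize("metric", ["euclidean", "correlation"])
    def test_matches_brute_force(self, metric):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(30, 5))
        labels = rng.integers(0, 3, size=30)
        res = fl.silhouette(pts, labels, metric=metric)
        expected = brute_force_silhouette(pts, labels, metric)
        np.testing.assert_allclose(res.si, expected, atol=1e-10)

    def test_matches_sklearn_euclidean(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(40, 3))
        labels = rng.integers(0, 4, size=40)
        res = fl.silhouette(pts, labels)
        np.testing.assert_allclose(
            res.si, silhouette_samples(pts, labels), atol=1e-10)

    def test_singleton_network_is_nan_but_not_fatal(self):
        pts = np.array([[0.0, 0], [0.1, 0], [5.0, 0]])
        res = fl.silhouette(pts, [0, 0, 1])
        assert np.isnan(res.si[2])
        assert np.isnan(res.network_mean[1])
        assert np.isfinite(res.overall_mean)

    def test_single_network_rejected(self):
        with pytest.raises(ValueError):
            fl.silhouette(np.zeros((4, 2)), [0, 0, 0, 0])

    def test_values_bounded_in_unit_interval(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(50, 4))
        labels = rng.integers(0, 5, size=50)
        si = fl.silhouette(pts, labels).si
        finite = si[np.isfinite(si)]
        assert (finite >= -1 - 1e-12).all() and (finite <= 1 + 1e-12).all()


class TestBootstrapCI:
    def test_degenerate_cohort_gives_point_interval(self):
        # every subject identical: all bootstrap draws produce one value
        base = np.array([[0.0, 0], [0.1, 0], [10, 0], [10.1, 0.0]])
        emb = np.tile(base, (5, 1, 1))
        labels = ["x", "x", "y", "y"]
        ci = fl.bootstrap_network_si(emb, labels, n_boot=50, seed=0)
        fixed = fl.silhouette(base, labels).network_mean
        for u in ("x", "y"):
            assert ci[u][0] == pytest.approx(fixed[u], abs=1e-12)
            assert ci[u][1] == pytest.approx(fixed[u], abs=1e-12)

    def test_interval_is_ordered_and_reproducible(self):
        rng = np.random.default_rng(4)
        emb = rng.normal(size=(8, 12, 2)) + np.array([0.0] * 6 + [4.0] * 6)[:, None]
        labels = [0] * 6 + [1] * 6
        c1 = fl.bootstrap_network_si(emb, labels, n_boot=100, seed=1)
        c2 = fl.bootstrap_network_si(emb, labels, n_boot=100, seed=1)
        assert c1 == c2
        for lo, hi in c1.values():
            assert lo <= hi

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            fl.bootstrap_network_si(np.zeros((1, 4, 2)), [0, 0, 1, 1])


class TestDispersion:
    def test_hand_computed_example(self):
        # points (0,0),(2,0): centroid (1,0), squared distances 1,1
        assert fl.dispersion([[0, 0], [2, 0]]) == pytest.approx(1.0)

    def test_coincident_points_have_zero_dispersion(self):
        assert fl.dispersion(np.ones((5, 3))) == 0.0

    def test_equals_trace_of_biased_covariance(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(40, 6))
        expected = np.trace(np.cov(pts.T, bias=True))
        assert fl.dispersion(pts) == pytest.approx(expected, rel=1e-12)

    def test_snr_ratio_and_zero_intra_rejected(self):
        assert fl.dispersion_snr(6.0, 2.0) == pytest.approx(3.0)
        with pytest.raises(ZeroDivisionError):
            fl.dispersion_snr(1.0, 0.0)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            fl.dispersion(np.zeros((0, 2)))


class TestBarcodes:
    def test_connectome_barcode_length_and_order(self):
        c = np.array([[1.0, 0.2, 0.3],
                      [0.2, 1.0, 0.4],
                      [0.3, 0.4, 1.0]])
        bc = fl.connectome_barcode(c)
        np.testing.assert_array_equal(bc, [0.2, 0.3, 0.4])

    def test_asymmetric_connectome_rejected(self):
        c = np.array([[1.0, 0.5], [0.1, 1.0]])
        with pytest.raises(ValueError):
            fl.connectome_barcode(c)

    def test_full_scale_barcode_length(self):
        n = 326
        c = np.eye(n)
        assert fl.connectome_barcode(c).size == n * (n - 1) // 2

    def test_latent_barcode_concatenates_parcels(self):
        emb = np.arange(8.0).reshape(4, 2)
        np.testing.assert_array_equal(fl.latent_barcode(emb), np.arange(8.0))
        assert fl.latent_barcode(np.zeros((326, 2))).size == 652


class TestFingerprint:
    def test_identical_sessions_identify_everyone(self):
        rng = np.random.default_rng(6)
        b = rng.normal(size=(10, 50))
        res = fl.fingerprint(b, b)
        assert res.accuracy == 1.0
        assert res.hits_1 == res.hits_2 == 10
        assert res.ties == 0

    def test_derangement_identifies_no_one(self):
        rng = np.random.default_rng(7)
        b = rng.normal(size=(5, 50))
        res = fl.fingerprint(b, np.roll(b, 1, axis=0))
        assert res.accuracy == 0.0

    def test_similarity_matches_brute_force_pearson(self):
        rng = np.random.default_rng(8)
        b1 = rng.normal(size=(4, 30))
        b2 = rng.normal(size=(4, 30))
        res = fl.fingerprint(b1, b2)
        for i in range(4):
            for j in range(4):
                assert res.similarity[i, j] == pytest.approx(
                    np.corrcoef(b1[i], b2[j])[0, 1], abs=1e-12)

    def test_affine_rescaling_of_a_session_is_irrelevant(self):
        rng = np.random.default_rng(9)
        b1 = rng.normal(size=(6, 40))
        b2 = b1 + rng.normal(size=(6, 40)) * 0.1
        base = fl.fingerprint(b1, b2)
        scaled = fl.fingerprint(b1 * 3.0 - 2.0, b2)
        np.testing.assert_allclose(scaled.similarity, base.similarity, atol=1e-12)
        assert scaled.accuracy == base.accuracy

    def test_constant_barcode_rejected(self):
        b = np.random.default_rng(10).normal(size=(3, 20))
        bad = b.copy()
        bad[1] = 5.0
        with pytest.raises(DegenerateInputError):
            fl.fingerprint(bad, b)

    def test_tie_counting_on_duplicate_barcodes(self):
        b1 = np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        b2 = np.array([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]])
        res = fl.fingerprint(b1, b2)
        # rows have unique maxima, but both columns' maxima are duplicated
        assert res.ties == 2
        res2 = fl.fingerprint(b1, b1)
        assert res2.ties == 4  # every row and column max is duplicated


class TestSubcluster:
    def test_recovers_two_well_separated_blobs(self):
        rng = np.random.default_rng(11)
        a = rng.normal(size=(30, 2)) * 0.1
        b = rng.normal(size=(30, 2)) * 0.1 + 10.0
        labels, centroids, _ = fl.subcluster(np.vstack([a, b]), k=2, seed=0)
        assert len(set(labels[:30])) == 1 and len(set(labels[30:])) == 1
        assert labels[0] != labels[30]
        got = np.sort(centroids[:, 0])
        assert got[0] == pytest.approx(0.0, abs=0.2)
        assert got[1] == pytest.approx(10.0, abs=0.2)

    def test_k_one_puts_everything_together(self):
        x = np.random.default_rng(12).normal(size=(10, 2))
        labels, centroids, _ = fl.subcluster(x, k=1, seed=0)
        assert set(labels) == {0}
        np.testing.assert_allclose(centroids[0], x.mean(axis=0), atol=1e-10)

    def test_inertia_beats_random_labelings(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=(40, 2))
        labels, centroids, _ = fl.subcluster(x, k=2, n_restarts=10, seed=0)
        inertia = sum(((x[labels == c] - centroids[c]) ** 2).sum() for c in (0, 1))
        for _ in range(100):
            rl = rng.integers(0, 2, size=40)
            if len(set(rl)) < 2:
                continue
            ri = sum(((x[rl == c] - x[rl == c].mean(axis=0)) ** 2).sum()
                     for c in (0, 1))
            assert inertia <= ri + 1e-9

    def test_probability_table_sums_to_one_per_parcel(self):
        rng = np.random.default_rng(14)
        x = rng.normal(size=(24, 2))
        parcels = np.repeat(np.arange(4), 6)
        _, _, table = fl.subcluster(x, k=2, seed=0, parcel_ids=parcels)
        np.testing.assert_allclose(table.sum(axis=1), 1.0, atol=1e-12)
        assert list(table.index) == [0, 1, 2, 3]


def bh_step_up(pvals, q):
    """Reference Benjamini-Hochberg: reject the largest k with p_(k) <= kq/m."""
    p = np.asarray(pvals)
    m = p.size
    order = np.argsort(p)
    thresh = q * (np.arange(1, m + 1)) / m
    below = np.flatnonzero(p[order] <= thresh)
    reject = np.zeros(m, dtype=bool)
    if below.size:
        reject[order[: below[-1] + 1]] = True
    return reject


class TestTraitCorrelation:
    def _make(self, rng, n_subj=20, n_parcel=6, n_dim=2):
        return rng.normal(size=(n_subj, n_parcel, n_dim))

    def test_exact_linear_trait_has_r_one(self):
        rng = np.random.default_rng(15)
        emb = self._make(rng)
        trait = emb[:, 3, 1] * 2.0 + 5.0
        df = fl.trait_correlation(emb, {"t": trait}, q=0.05)
        row = df[(df.dim == 1) & (df.parcel == 3)].iloc[0]
        assert row.r == pytest.approx(1.0, abs=1e-12)
        assert row.significant

    def test_rejections_match_reference_step_up(self):
        rng = np.random.default_rng(16)
        emb = self._make(rng, n_subj=25, n_parcel=12)
        trait = rng.normal(size=25) + emb[:, 0, 0]
        df = fl.trait_correlation(emb, {"t": trait}, q=0.1)
        for dim in (0, 1):
            fam = df[df.dim == dim].sort_values("parcel")
            expected = bh_step_up(fam.p.to_numpy(), 0.1)
            np.testing.assert_array_equal(fam.significant.to_numpy(), expected)

    def test_equal_pvalues_all_or_none(self):
        # m identical p-values: BH rejects all iff p <= q
        flags = bh_step_up(np.full(8, 0.04), 0.05)
        assert flags.all()
        flags = bh_step_up(np.full(8, 0.06), 0.05)
        assert not flags.any()

    def test_adjusted_p_is_monotone_and_at_least_raw(self):
        rng = np.random.default_rng(17)
        emb = self._make(rng, n_parcel=10)
        df = fl.trait_correlation(emb, {"t": rng.normal(size=20)}, q=0.05)
        for dim in (0, 1):
            fam = df[df.dim == dim]
            assert (fam.p_adj >= fam.p - 1e-12).all()
            s = fam.sort_values("p")
            assert (np.diff(s.p_adj.to_numpy()) >= -1e-12).all()

    def test_missing_scores_dropped_pairwise(self):
        rng = np.random.default_rng(18)
        emb = self._make(rng, n_subj=15, n_parcel=3)
        trait = emb[:, 0, 0].copy()
        trait[0] = np.nan
        df = fl.trait_correlation(emb, {"t": trait}, q=0.05)
        row = df[(df.dim == 0) & (df.parcel == 0)].iloc[0]
        assert row.r == pytest.approx(1.0, abs=1e-12)

    def test_constant_trait_rejected(self):
        emb = self._make(np.random.default_rng(19))
        with pytest.raises(DegenerateInputError):
            fl.trait_correlation(emb, {"t": np.ones(20)}, q=0.05)

    def test_family_structure(self):
        rng = np.random.default_rng(20)
        emb = self._make(rng, n_subj=12, n_parcel=5, n_dim=3)
        df = fl.trait_correlation(
            emb, {"a": rng.normal(size=12), "b": rng.normal(size=12)}, q=0.05)
        assert len(df) == 2 * 3 * 5
        assert set(df.groupby(["trait", "dim"]).size()) == {5}


class TestPredictCovariate:
    def test_grid_is_fifteen_log_even_values(self):
        grid = default_lambda_grid()
        assert grid.size == 15
        assert grid[0] == pytest.approx(1e-8)
        assert grid[-1] == pytest.approx(1e3)
        ratios = grid[1:] / grid[:-1]
        np.testing.assert_allclose(ratios, ratios[0], rtol=1e-10)

    def test_exact_linear_relation_recovered(self):
        rng = np.random.default_rng(21)
        x = rng.normal(size=(60, 4))
        y = x @ np.array([1.0, -2.0, 0.5, 3.0]) + 7.0
        out = fl.predict_covariate(x, y, n_repeats=10, seed=0)
        assert out["mean"] == pytest.approx(1.0, abs=1e-6)

    def test_null_features_score_near_zero(self):
        rng = np.random.default_rng(22)
        x = rng.normal(size=(80, 4))
        y = rng.normal(size=80)
        out = fl.predict_covariate(x, y, n_repeats=40, seed=1)
        assert abs(out["mean"]) < 3 * out["sd"] / np.sqrt(len(out["values"])) + 0.15

    def test_reproducible_and_ci_ordered(self):
        rng = np.random.default_rng(23)
        x = rng.normal(size=(40, 3))
        y = x[:, 0] + rng.normal(size=40)
        a = fl.predict_covariate(x, y, n_repeats=8, seed=5)
        b = fl.predict_covariate(x, y, n_repeats=8, seed=5)
        np.testing.assert_array_equal(a["values"], b["values"])
        assert a["ci"][0] <= a["mean"] <= a["ci"][1]

    def test_svr_option_runs(self):
        rng = np.random.default_rng(24)
        x = rng.normal(size=(30, 2))
        y = x[:, 0] * 2.0
        out = fl.predict_covariate(x, y, n_repeats=3, seed=0, model="svr")
        assert out["mean"] > 0.9

    def test_too_few_sessions_rejected(self):
        with pytest.raises(ValueError):
            fl.predict_covariate(np.zeros((5, 2)), np.zeros(5))


class TestDensityMaps:
    def test_single_cluster_mass_lands_in_one_bin(self):
        pts = np.full((50, 2), 0.55)
        d = fl.density_map(pts, (0, 1, 0, 1, 10), bandwidth=0.0)
        assert d.sum() == pytest.approx(1.0)
        assert d[5, 5] == pytest.approx(1.0)

    def test_smoothing_preserves_total_mass(self):
        rng = np.random.default_rng(25)
        pts = rng.uniform(-1, 1, size=(200, 2))
        d = fl.density_map(pts, (-2, 2, -2, 2, 16), bandwidth=1.5)
        assert d.sum() == pytest.approx(1.0)

    def test_identical_cohorts_difference_is_zero(self):
        rng = np.random.default_rng(26)
        pts = rng.normal(size=(100, 2))
        spec = (-4, 4, -4, 4, 20)
        d1 = fl.density_map(pts, spec, bandwidth=1.0)
        diff = fl.density_difference(d1, fl.density_map(pts, spec, bandwidth=1.0))
        np.testing.assert_array_equal(diff, 0.0)

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError):
            fl.density_difference(np.zeros((4, 4)), np.zeros((5, 5)))

    def test_non_planar_embeddings_rejected(self):
        with pytest.raises(ValueError):
            fl.density_map(np.zeros((10, 3)), (0, 1, 0, 1, 4))
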