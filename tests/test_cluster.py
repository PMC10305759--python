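"""Clustering core: GFP, peaks, modified K-means (with exhaustive oracle),
silhouette selection, two-level clustering and map labeling."""

import itertools

import numpy as np
import pytest

from microstates import (MapSet, Recording, gfp, gfp_peaks, label_maps,
                         make_layout, modified_kmeans, silhouette_k,
                         spatial_correlation, two_level_cluster)
from microstates.cluster import GFPSeries, ModifiedKMeans, correlation_distances


def _norm(v):
    v = np.asarray(v, dtype=float)
    v = v - v.mean()
    return v / np.linalg.norm(v)


class TestGFP:
    def test_two_channel_arithmetic(self):
        layout = make_layout()
        data = np.zeros((19, 1))
        # spread [1, -1, 0 ...] has population SD sqrt(2/19); use an
        # explicitly computed value
        data[0, 0], data[1, 0] = 1.0, -1.0
        data -= data.mean(axis=0)
        rec = Recording(data=data, rate=256.0, layout=layout, reference="average")
        expected = data[:, 0].std(ddof=0)
        assert gfp(rec).values[0] == pytest.approx(expected, abs=1e-12)

    def test_zero_sample(self):
        layout = make_layout()
        rec = Recording(data=np.zeros((19, 3)), rate=256.0, layout=layout,
                        reference="average")
        assert np.allclose(gfp(rec).values, 0.0)

    def test_homogeneity(self, rendered_subject):
        rec, _ = rendered_subject
        scaled = rec.copy(data=3.0 * rec.data)
        assert np.allclose(gfp(scaled).values, 3.0 * gfp(rec).values)

    def test_requires_average_reference(self, layout):
        rec = Recording(data=np.ones((19, 5)), rate=256.0, layout=layout)
        with pytest.raises(ValueError):
            gfp(rec)


class TestGFPPeaks:
    def test_enumerated_maxima(self):
        s = GFPSeries(values=np.array([0, 1, 0, 2, 0.0]), rate=10.0,
                      segments=[(0, 5)])
        assert gfp_peaks(s).tolist() == [1, 3]

    def test_monotone_has_no_peaks(self):
        s = GFPSeries(values=np.arange(10.0), rate=10.0, segments=[(0, 10)])
        assert gfp_peaks(s).size == 0

    def test_never_across_segment_splice(self):
        v = np.array([0, 1, 0, 0, 1, 0.0])
        merged = GFPSeries(values=v, rate=10.0, segments=[(0, 6)])
        split = GFPSeries(values=v, rate=10.0, segments=[(0, 3), (3, 6)])
        assert gfp_peaks(merged).tolist() == [1, 4]
        assert gfp_peaks(split).tolist() == [1, 4]
        # a spurious boundary maximum is not created
        v2 = np.array([0, 1, 2, 2, 1, 0.0])
        s2 = GFPSeries(values=v2, rate=10.0, segments=[(0, 3), (3, 6)])
        assert gfp_peaks(s2).size == 0

    def test_alpha_rate_on_rendering(self, noiseless_subject):
        rec, _ = noiseless_subject
        peaks = gfp_peaks(gfp(rec))
        per_second = peaks.size / rec.duration
        # two GFP maxima per 10 Hz alpha cycle
        assert 16.0 <= per_second <= 24.0


def exhaustive_gev(peak_maps, peak_gfp, n_clusters):
    """Independent oracle: enumerate every assignment, use the closed-form
    per-cluster optimal map, return the best GEV."""
    X = np.array([_norm(m) for m in peak_maps])
    w = np.asarray(peak_gfp, dtype=float) ** 2
    n = X.shape[0]
    best = -1.0
    for assign in itertools.product(range(n_clusters), repeat=n):
        assign = np.asarray(assign)
        if len(set(assign.tolist())) < n_clusters:
            continue
        gev = 0.0
        for k in range(n_clusters):
            members = X[assign == k]
            wk = w[assign == k]
            cov = (members * wk[:, None]).T @ members
            vals, vecs = np.linalg.eigh(cov)
            m = vecs[:, -1]
            gev += float(wk @ (members @ m) ** 2)
        best = max(best, gev / w.sum())
    return best


class TestModifiedKMeans:
    def test_recovers_orthogonal_generators(self):
        rng = np.random.default_rng(0)
        a = _norm(rng.standard_normal(19))
        b = _norm(rng.standard_normal(19))
        b = _norm(b - (a @ b) * a)                      # orthogonalize
        signs = rng.choice([-1.0, 1.0], size=40)
        peaks = np.concatenate([np.outer(signs[:20], a), np.outer(signs[20:], b)])
        fit = modified_kmeans(peaks, 2, seed=0)
        recovered = fit.mapset.maps
        match = max(spatial_correlation(recovered[0], a),
                    spatial_correlation(recovered[0], b))
        assert match == pytest.approx(1.0, abs=1e-6)
        assert fit.gev == pytest.approx(1.0, abs=1e-9)

    def test_polarity_invariance(self):
        rng = np.random.default_rng(1)
        peaks = rng.standard_normal((30, 19))
        flip = rng.choice([-1.0, 1.0], size=30)
        a = modified_kmeans(peaks, 3, seed=7)
        b = modified_kmeans(peaks * flip[:, None], 3, seed=7)
        for ma, mb in zip(a.mapset.maps, b.mapset.maps):
            assert spatial_correlation(ma, mb) == pytest.approx(1.0, abs=1e-9)
        assert a.gev == pytest.approx(b.gev, abs=1e-12)

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(2)
        peaks = rng.standard_normal((8, 19)) * rng.uniform(0.5, 2.0, (8, 1))
        pg = peaks.std(axis=1, ddof=0)
        fit = modified_kmeans(peaks, 2, n_init=20, seed=0)
        oracle = exhaustive_gev(peaks, pg, 2)
        assert fit.gev == pytest.approx(oracle, abs=1e-9)

    def test_gev_trace_monotone(self, rendered_subject):
        rec, _ = rendered_subject
        series = gfp(rec)
        peaks = gfp_peaks(series)
        fit = modified_kmeans(rec.data[:, peaks].T, 4, seed=0,
                              peak_gfp=series.values[peaks])
        assert all(b >= a - 1e-12 for a, b in zip(fit.gev_trace, fit.gev_trace[1:]))
        assert 0.0 <= fit.gev <= 1.0

    def test_k_larger_than_peaks_rejected(self):
        with pytest.raises(ValueError):
            modified_kmeans(np.random.default_rng(0).standard_normal((3, 19)), 5)

    def test_summary_mentions_gev(self, rendered_subject):
        rec, _ = rendered_subject
        series = gfp(rec)
        peaks = gfp_peaks(series)[:50]
        fit = ModifiedKMeans(rec.data[:, peaks].T, 4).fit(seed=0)
        assert "GEV" in fit.summary()


def silhouette_oracle(dist, labels):
    """Direct silhouette formula on a precomputed distance matrix."""
    n = dist.shape[0]
    scores = []
    for i in range(n):
        own = labels == i * 0 + labels[i]
        own_idx = np.flatnonzero(own)
        if own_idx.size == 1:
            scores.append(0.0)
            continue
        a = dist[i, own_idx[own_idx != i]].mean()
        b = min(dist[i, labels == k].mean() for k in set(labels) if k != labels[i])
        scores.append((b - a) / max(a, b))
    return float(np.mean(scores))


class TestSilhouette:
    @pytest.fixture(scope="class")
    def separated_peaks(self, templates):
        rng = np.random.default_rng(3)
        reps = []
        for m in templates.maps:
            pts = m[None, :] + 0.05 * rng.standard_normal((25, 19))
            pts *= rng.choice([-1.0, 1.0], size=(25, 1))
            reps.append(pts)
        return np.concatenate(reps)

    def test_selects_four_for_four_generators(self, separated_peaks):
        best, scores = silhouette_k(separated_peaks, range(2, 8), seed=0)
        assert best == 4

    def test_score_matches_direct_formula(self, separated_peaks):
        best, scores = silhouette_k(separated_peaks, [4], seed=0)
        fit = modified_kmeans(separated_peaks, 4, seed=np.random.default_rng(0)
                              .integers(2 ** 31))
        dist = correlation_distances(separated_peaks)
        assert scores[4] == pytest.approx(silhouette_oracle(dist, fit.assignments),
                                          abs=1e-6)

    def test_perfect_separation_score(self):
        # a point at zero distance to its cluster, distance 1 to the other
        dist = np.array([[0, 0, 1, 1], [0, 0, 1, 1],
                         [1, 1, 0, 0], [1, 1, 0, 0]], dtype=float)
        labels = np.array([0, 0, 1, 1])
        assert silhouette_oracle(dist, labels) == pytest.approx(1.0)

    def test_true_k_scores_at_least_k_plus_one(self, separated_peaks):
        _, scores = silhouette_k(separated_peaks, [4, 5], seed=1)
        assert scores[4] >= scores[5]

    def test_invalid_range(self):
        with pytest.raises(ValueError):
            silhouette_k(np.eye(5), [1, 2])


class TestTwoLevel:
    def test_single_subject_identity(self, rendered_subject):
        rec, _ = rendered_subject
        series = gfp(rec)
        peaks = gfp_peaks(series)
        solo = modified_kmeans(rec.data[:, peaks].T, 4, seed=1,
                               peak_gfp=series.values[peaks])
        group = two_level_cluster([rec], 4, seed=1)
        matched = sorted(max(spatial_correlation(g, s) for s in solo.mapset.maps)
                         for g in group.maps)
        assert np.allclose(matched, 1.0, atol=1e-6)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            two_level_cluster([], 4)

    def test_scale_invariance(self, rendered_subject):
        rec, _ = rendered_subject
        a = two_level_cluster([rec], 4, seed=2)
        b = two_level_cluster([rec.copy(data=5.0 * rec.data)], 4, seed=2)
        for ma, mb in zip(a.maps, b.maps):
            assert spatial_correlation(ma, mb) == pytest.approx(1.0, abs=1e-9)


class TestSpatialCorrelationAndLabeling:
    def test_identity_and_polarity(self, templates):
        m = templates.maps[0]
        assert spatial_correlation(m, m) == pytest.approx(1.0)
        assert spatial_correlation(m, -m) == pytest.approx(1.0)

    def test_orthogonal_maps(self):
        a = _norm([1, -1] + [0] * 17)
        b = _norm([0, 0, 1, -1] + [0] * 15)
        assert spatial_correlation(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            spatial_correlation(np.ones(19), np.arange(19.0))

    def test_self_labeling_is_identity(self, templates):
        lab, corr = label_maps(templates, templates)
        assert lab.class_labels == templates.class_labels
        assert np.allclose(np.diag(corr), 1.0)

    def test_permutation_recovered(self, templates):
        perm = [2, 0, 3, 1]
        shuffled = MapSet(maps=templates.maps[perm].copy())
        lab, corr = label_maps(shuffled, templates)
        assert np.allclose(lab.maps, templates.maps)

    def test_matches_permutation_bruteforce(self, templates):
        rng = np.random.default_rng(4)
        noisy = templates.maps + 0.2 * rng.standard_normal((4, 19))
        noisy -= noisy.mean(axis=1, keepdims=True)
        noisy /= np.linalg.norm(noisy, axis=1, keepdims=True)
        noisy = noisy[[3, 1, 0, 2]]
        lab, corr = label_maps(MapSet(maps=noisy), templates)
        # oracle: exhaustive search over all 24 permutations
        best_perm, best_total = None, -1.0
        for perm in itertools.permutations(range(4)):
            total = sum(spatial_correlation(templates.maps[i], noisy[perm[i]])
                        for i in range(4))
            if total > best_total:
                best_total, best_perm = total, perm
        assert np.allclose(lab.maps, noisy[list(best_perm)])

    def test_k_mismatch_rejected(self, templates):
        with pytest.raises(ValueError):
            label_maps(MapSet(maps=templates.maps[:2].copy()), templates)
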