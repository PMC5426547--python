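import numpy as np
import pytest

from veinmap import extract, metrics, synth
from veinmap.types import DegenerateInputError


class TestProfileCurvature:
    def test_linear_profile_has_zero_curvature_everywhere(self):
        p = 3.0 * np.arange(40) + 7.0
        kappa = extract.profile_curvature(p, sigma=2.0)
        assert np.abs(kappa).max() < 1e-12

    def test_parabola_vertex_curvature_is_two(self):
        z = np.arange(-50, 51, dtype=float)
        kappa = extract.profile_curvature(z**2, sigma=0.5)
        assert abs(kappa[50] - 2.0) < 1e-3

    def test_gaussian_valley_matches_finite_difference_oracle(self):
        """Independent oracle: explicit sampled-Gaussian convolution plus a
        per-sample central-difference loop."""
        z = np.arange(-200, 201, dtype=float)
        p = 1.0 - 0.5 * np.exp(-(z**2) / (2 * 40.0**2))
        sigma = 2.0
        kappa = extract.profile_curvature(p, sigma)

        pad = int(np.ceil(4 * sigma)) + 1
        k = np.arange(1, pad + 1)
        ext = np.concatenate(
            [p[0] - (p[1] - p[0]) * k[::-1], p, p[-1] + (p[-1] - p[-2]) * k]
        )
        r = int(4 * sigma + 0.5)
        x = np.arange(-r, r + 1)
        g = np.exp(-(x**2) / (2 * sigma**2))
        g /= g.sum()
        ps = np.convolve(ext, g[::-1], mode="same")
        oracle = np.empty(p.size)
        for j in range(p.size):
            jj = j + pad
            d1 = (ps[jj + 1] - ps[jj - 1]) / 2
            d2 = ps[jj + 1] - 2 * ps[jj] + ps[jj - 1]
            oracle[j] = d2 / (1 + d1**2) ** 1.5
        assert np.abs(kappa[10:-10] - oracle[10:-10]).max() < 1e-6

    def test_dent_sign_convention(self):
        """An intensity valley (vein) must have positive curvature."""
        z = np.arange(-30, 31, dtype=float)
        valley = 100.0 - 50.0 * np.exp(-(z**2) / 18.0)
        kappa = extract.profile_curvature(valley, sigma=1.5)
        assert kappa[30] > 0

    def test_short_profile_rejected(self):
        with pytest.raises(DegenerateInputError):
            extract.profile_curvature(np.ones(4), sigma=1.0)


def dent_scan_oracle(kappa):
    """Brute-force scan over maximal positive runs."""
    out = []
    i = 0
    n = len(kappa)
    while i < n:
        if kappa[i] > 0:
            j = i
            while j < n and kappa[j] > 0:
                j += 1
            run = kappa[i:j]
            peak = i + int(np.argmax(run))
            out.append((peak, run.max() * (j - i)))
            i = j
        else:
            i += 1
    return out


class TestScoreDents:
    def test_no_positive_curvature_yields_empty(self):
        centers, scores = extract.score_dents(-np.ones(10))
        assert centers.size == 0 and scores.size == 0

    def test_single_run_score_is_peak_times_width(self):
        kappa = np.array([-1, 0.1, 0.2, 0.4, 0.2, 0.1, -1.0])
        centers, scores = extract.score_dents(kappa)
        assert list(centers) == [3]
        assert scores[0] == pytest.approx(0.4 * 5)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_run_scan_oracle(self, seed, rng):
        kappa = np.random.default_rng(seed).normal(0, 1, size=200)
        centers, scores = extract.score_dents(kappa)
        expect = dent_scan_oracle(kappa)
        assert list(centers) == [c for c, _ in expect]
        assert np.allclose(scores, [s for _, s in expect])


class TestAccumulatePlane:
    def test_constant_image_scores_zero(self):
        V = extract.accumulate_plane(np.full((20, 20), 5.0), np.ones((20, 20), bool))
        assert (V == 0).all()

    def test_zero_outside_roi(self, rng):
        img = rng.random((30, 30))
        roi = np.zeros((30, 30), bool)
        roi[5:25, 5:25] = True
        V = extract.accumulate_plane(img, roi, sigma=1.5)
        assert (V[~roi] == 0).all()

    def test_planted_dark_line_centers_on_intensity_minimum(self):
        """Vertical-profile dents of a dark horizontal line must land within
        1 px of the per-column intensity argmin (the planted row)."""
        img = np.full((40, 60), 100.0)
        img[19, :] = 40.0
        img[18, :] = img[20, :] = 70.0
        roi = np.ones((40, 60), bool)
        V = extract.accumulate_plane(img, roi, sigma=2.0)
        for c in range(5, 55):
            detected = np.argmax(V[:, c])
            assert abs(detected - np.argmin(img[:, c])) <= 1

    def test_quarter_turn_equivariance(self, rng):
        """The 4-direction set is closed under 90° rotation."""
        img = rng.random((24, 24))
        roi = np.ones((24, 24), bool)
        roi[:3] = False
        V = extract.accumulate_plane(img, roi, sigma=1.5)
        V_rot = extract.accumulate_plane(np.rot90(img), np.rot90(roi), sigma=1.5)
        assert np.allclose(np.rot90(V), V_rot, atol=1e-10)


def connect_oracle(V, rule_median=True):
    """Per-pixel evaluation of the directional min/max template + threshold."""
    H, W = V.shape

    def at(r, c):
        return V[r, c] if 0 <= r < H and 0 <= c < W else 0.0

    G = np.zeros_like(V)
    for r in range(H):
        for c in range(W):
            best = 0.0
            for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
                fwd = max(at(r + dr, c + dc), at(r + 2 * dr, c + 2 * dc))
                bwd = max(at(r - dr, c - dc), at(r - 2 * dr, c - 2 * dc))
                best = max(best, min(fwd, bwd))
            G[r, c] = best
    pos = G[G > 0]
    if pos.size == 0:
        return np.zeros_like(V, dtype=bool)
    return G > np.median(pos)


class TestConnectAndBinarize:
    def test_zero_plane_gives_empty_mask(self):
        assert not extract.connect_and_binarize(np.zeros((10, 10))).any()

    def test_isolated_positive_pixel_suppressed(self):
        V = np.zeros((11, 11))
        V[5, 5] = 3.0
        assert not extract.connect_and_binarize(V, rule="median").any()

    def test_continuous_ridge_retained(self):
        V = np.zeros((9, 30))
        V[4, 2:28] = 1.0
        mask = extract.connect_and_binarize(V, threshold=0.5)
        assert mask[4, 5:25].all()
        assert not mask[[0, 8], :].any()

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_per_pixel_oracle(self, seed):
        rng = np.random.default_rng(seed)
        V = np.where(rng.random((32, 32)) < 0.3, rng.random((32, 32)), 0.0)
        got = extract.connect_and_binarize(V, rule="median")
        assert np.array_equal(got, connect_oracle(V))


class TestKMeans:
    def test_three_distinct_values_perfectly_partitioned(self):
        img = np.tile(np.array([10.0, 120.0, 230.0]), (6, 5))
        roi = np.ones(img.shape, bool)
        model = extract.kmeans_segment(img, roi, k=3, seed=0)
        assert model.inertia == pytest.approx(0.0, abs=1e-9)
        assert sorted(model.centroids) == [10.0, 120.0, 230.0]

    def test_separated_groups_recovered_with_exact_centroids(self):
        data = np.concatenate(
            [np.arange(10), np.arange(100, 110), np.arange(200, 210)]
        ).astype(float)
        img = data.reshape(3, 10)
        model = extract.kmeans_segment(img, np.ones((3, 10), bool), k=3, seed=1)
        assert np.allclose(sorted(model.centroids), [4.5, 104.5, 204.5])
        lab = model.label_raster()
        for row in range(3):  # each intensity group is one cluster
            assert np.unique(lab[row]).size == 1

    def test_duplicating_pixels_doubles_objective(self, rng):
        img = rng.random((12, 12))
        m1 = extract.kmeans_segment(img, np.ones((12, 12), bool), seed=0)
        dbl = np.concatenate([img, img], axis=0)
        m2 = extract.kmeans_segment(dbl, np.ones((24, 12), bool), seed=0)
        assert np.allclose(np.sort(m1.centroids), np.sort(m2.centroids))
        assert m2.inertia == pytest.approx(2 * m1.inertia, rel=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_objective_non_increasing_each_iteration(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.normal(0, 1, (30, 30)) + rng.choice([0, 5, 9], (30, 30))
        model = extract.kmeans_segment(img, np.ones((30, 30), bool), seed=seed)
        hist = np.array(model.history)
        assert (np.diff(hist) <= 1e-9).all()

    def test_matches_sklearn_objective(self, rng):
        """Independent oracle: sklearn's k-means on the same 1-D data."""
        from sklearn.cluster import KMeans

        img = rng.normal(0, 1, (40, 40)) + rng.choice([0, 6, 12], (40, 40))
        roi = np.ones((40, 40), bool)
        model = extract.kmeans_segment(img, roi, k=3, seed=0)
        sk = KMeans(n_clusters=3, n_init=10, random_state=0).fit(
            img[roi].reshape(-1, 1)
        )
        assert model.inertia == pytest.approx(sk.inertia_, rel=1e-6)
        assert np.allclose(
            np.sort(model.centroids), np.sort(sk.cluster_centers_.ravel()), atol=1e-6
        )

    def test_pixel_order_invariance(self, rng):
        img = rng.random((20, 20))
        roi = np.ones((20, 20), bool)
        m1 = extract.kmeans_segment(img, roi, seed=3)
        perm = np.random.default_rng(9).permutation(400)
        img2 = img.reshape(-1)[perm].reshape(20, 20)
        m2 = extract.kmeans_segment(img2, roi, seed=3)
        assert np.array_equal(m1.centroids, m2.centroids)
        assert np.array_equal(m1.label_raster().reshape(-1)[perm], m2.label_raster().reshape(-1))

    def test_too_few_distinct_values_rejected(self):
        img = np.tile(np.array([1.0, 2.0]), (4, 4))
        with pytest.raises(DegenerateInputError):
            extract.kmeans_segment(img, np.ones(img.shape, bool), k=3)


class TestVeinClusterSelection:
    def test_lowest_centroid_selected(self):
        model = extract.KMeansModel(
            n_clusters=3,
            centroids=np.array([120.0, 10.0, 230.0]),
            labels=np.array([0, 1, 2, 1]),
            mask=np.array([[True, True], [True, True]]),
            inertia=0.0,
        )
        sel = extract.select_vein_cluster(model)
        assert np.array_equal(sel, np.array([[False, True], [False, True]]))

    def test_tie_breaks_to_lowest_index_with_warning(self):
        model = extract.KMeansModel(
            n_clusters=3,
            centroids=np.array([5.0, 5.0, 5.0]),
            labels=np.array([0, 1, 2]),
            mask=np.ones((1, 3), bool),
            inertia=0.0,
        )
        with pytest.warns(UserWarning):
            sel = extract.select_vein_cluster(model)
        assert np.array_equal(sel, np.array([[True, False, False]]))

    def test_flat_dent_veins_covered(self, rng):
        """Veins uniformly 30% darker than tissue: the darkest cluster must
        cover at least 90% of the planted vein pixels."""
        img = np.full((80, 80), 10000.0) + rng.normal(0, 120, (80, 80))
        truth = np.zeros((80, 80), bool)
        truth[20:26, :] = True
        truth[50:56, :] = True
        img[truth] *= 0.7
        roi = np.ones((80, 80), bool)
        model = extract.kmeans_segment(img, roi, k=3, seed=0)
        sel = extract.select_vein_cluster(model)
        assert (sel & truth).sum() / truth.sum() >= 0.90


class TestDetectVeins:
    def test_combined_mask_is_subset_of_both_passes(self, small_spec):
        swir, truth, fg = synth.generate_phantom(small_spec)
        det = extract.detect_veins(swir, method="kmeans")
        a, b = det.per_mask
        assert not (det.mask & ~a).any()
        assert not (det.mask & ~b).any()
        assert not (det.mask & ~det.roi.evaluation_roi).any()

    def test_deterministic_bit_exact(self, small_spec):
        swir, _, _ = synth.generate_phantom(small_spec)
        d1 = extract.detect_veins(swir, method="kmeans", seed=5)
        d2 = extract.detect_veins(swir, method="kmeans", seed=5)
        assert np.array_equal(d1.mask, d2.mask)

    def test_vein_free_phantom_low_false_positives(self):
        spec = synth.PhantomSpec(
            swir_shape=(256, 320), tof_shape=(72, 88), vein_count=0, seed=21
        )
        swir, truth, _ = synth.generate_phantom(spec)
        det = extract.detect_veins(swir, method="max_curvature")
        roi = det.roi.evaluation_roi
        assert det.mask[roi].sum() / roi.sum() < 0.01

    def test_single_vein_noise_free_kmeans_accuracy(self):
        spec = synth.PhantomSpec(
            swir_shape=(256, 320), tof_shape=(72, 88),
            vein_count=1, vein_width=6.0, noise_sigma=0.0, seed=8,
        )
        swir, truth, _ = synth.generate_phantom(spec)
        det = extract.detect_veins(swir, method="kmeans")
        c = metrics.confusion(det.mask, truth, det.roi.evaluation_roi)
        assert metrics.accuracy(c) >= 95.0

    def test_unknown_method_rejected(self, small_spec):
        swir, _, _ = synth.generate_phantom(small_spec)
        with pytest.raises(ValueError):
            extract.detect_veins(swir, method="watershed")
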