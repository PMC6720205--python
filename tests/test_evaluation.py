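"""Histogram metrics, GLCM/Haralick statistics, t-tests, PCA, tally, filter."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_h

from embryogan import evaluation as ev
from embryogan.imageset import LabeledImageSet


def _set(arrays):
    return LabeledImageSet(images=list(arrays), labels=[0] * len(arrays))


# ---------------------------------------------------------------------------
# histograms
# ---------------------------------------------------------------------------

class TestAverageHistogram:
    def test_uniform_image_gives_one_hot(self):
        h = ev.average_histogram(_set([np.full((8, 8), 42, dtype=np.uint8)]))
        assert h[42] == 1.0 and h.sum() == 1.0

    def test_mean_of_per_image_histograms(self):
        a = np.full((4, 4), 10, dtype=np.uint8)
        b = np.full((4, 4), 20, dtype=np.uint8)
        h = ev.average_histogram(_set([a, b]))
        assert h[10] == 0.5 and h[20] == 0.5

    def test_sums_to_one(self, rng):
        imgs = [rng.integers(0, 256, (16, 16)).astype(np.uint8) for _ in range(5)]
        assert ev.average_histogram(_set(imgs)).sum() == pytest.approx(1.0, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ev.average_histogram(_set([]))


class TestHistogramMetrics:
    def test_identity_cases_simultaneously(self, rng):
        h = rng.uniform(0, 1, 64)
        h /= h.sum()
        assert ev.hist_correlation(h, h) == pytest.approx(1.0)
        assert ev.hist_chi_square(h, h) == 0.0
        assert ev.hist_intersection(h, h) == pytest.approx(1.0)
        assert ev.hist_bhattacharyya(h, h) == pytest.approx(0.0, abs=1e-7)

    def test_correlation_examples(self):
        assert ev.hist_correlation([.5, .5, 0, 0], [0, 0, .5, .5]) == pytest.approx(-1.0)

    def test_correlation_affine_invariance(self, rng):
        h = rng.uniform(0, 1, 32)
        assert ev.hist_correlation(h, 3.0 * h + 0.2) == pytest.approx(1.0)

    def test_correlation_zero_variance_reported(self):
        with pytest.raises(ValueError, match="zero variance"):
            ev.hist_correlation(np.full(8, 0.125), np.arange(8.0))

    def test_chi_square_direct_evaluation(self):
        assert ev.hist_chi_square([.5, .5], [.25, .75]) == pytest.approx(0.25)

    def test_chi_square_skips_empty_reference_bins(self):
        assert ev.hist_chi_square([0.0, 1.0], [0.5, 0.5]) == pytest.approx(0.25)

    def test_intersection_examples(self):
        assert ev.hist_intersection([.5, .5], [.25, .75]) == pytest.approx(0.75)
        assert ev.hist_intersection([1, 0], [0, 1]) == 0.0

    def test_bhattacharyya_direct_evaluation(self):
        coeff = math.sqrt(.5 * .25) + math.sqrt(.5 * .75)
        assert ev.hist_bhattacharyya([.5, .5], [.25, .75]) == pytest.approx(
            math.sqrt(1 - coeff), abs=1e-12)

    def test_bhattacharyya_disjoint_supports(self):
        assert ev.hist_bhattacharyya([1, 0], [0, 1]) == pytest.approx(1.0)

    def test_bhattacharyya_bounds_and_zero_rejection(self, rng):
        h1 = rng.uniform(0, 1, 16); h1 /= h1.sum()
        h2 = rng.uniform(0, 1, 16); h2 /= h2.sum()
        assert 0.0 <= ev.hist_bhattacharyya(h1, h2) <= 1.0
        with pytest.raises(ValueError):
            ev.hist_bhattacharyya(np.zeros(4), h1[:4])

    def test_bin_count_mismatch_rejected(self):
        with pytest.raises(ValueError, match="bin"):
            ev.hist_correlation([.5, .5], [.2, .3, .5])

    @settings(max_examples=30, deadline=None)
    @given(st_h.integers(min_value=0, max_value=2 ** 31))
    def test_metrics_invariant_to_appended_empty_bins(self, seed):
        rng = np.random.default_rng(seed)
        h1 = rng.uniform(0.01, 1, 16); h1 /= h1.sum()
        h2 = rng.uniform(0.01, 1, 16); h2 /= h2.sum()
        pad = np.zeros(8)
        p1, p2 = np.concatenate([h1, pad]), np.concatenate([h2, pad])
        assert ev.hist_intersection(p1, p2) == pytest.approx(ev.hist_intersection(h1, h2))
        assert ev.hist_chi_square(p1, p2) == pytest.approx(ev.hist_chi_square(h1, h2))
        assert ev.hist_bhattacharyya(p1, p2) == pytest.approx(
            ev.hist_bhattacharyya(h1, h2), abs=1e-9)

    def test_rescale_pair_compatibility_mode(self):
        h1 = np.array([.5, .5])
        h2 = np.array([.25, .75])
        r1, r2 = ev.rescale_pair(h1, h2, total=2.0)
        assert r1.sum() + r2.sum() == pytest.approx(2.0)
        assert ev.hist_intersection(r1, r2) == pytest.approx(0.75)


# ---------------------------------------------------------------------------
# GLCM / Haralick
# ---------------------------------------------------------------------------

def brute_force_glcm(img, levels, dy, dx):
    """Enumerate every symmetric pixel pair at offset (dy, dx)."""
    q = (img.astype(np.int64) * levels) // 256
    h, w = q.shape
    mat = np.zeros((levels, levels))
    for i in range(h):
        for j in range(w):
            i2, j2 = i + dy, j + dx
            if 0 <= i2 < h and 0 <= j2 < w:
                mat[q[i, j], q[i2, j2]] += 1
                mat[q[i2, j2], q[i, j]] += 1
    return mat / mat.sum()


class TestGLCM:
    def test_constant_image_single_diagonal_cell(self):
        m = ev.glcm(np.full((8, 8), 200, dtype=np.uint8), levels=4)
        q = (200 * 4) // 256
        assert m[q, q] == pytest.approx(1.0)
        assert m.sum() == pytest.approx(1.0)

    def test_two_by_two_hand_enumeration(self):
        img = np.array([[0, 255], [0, 255]], dtype=np.uint8)
        m = ev.glcm(img, levels=2, distance=1, angles=(0,))
        # horizontal neighbors: (0,1) twice, counted symmetrically
        assert np.allclose(m, [[0, .5], [.5, 0]])

    @pytest.mark.parametrize("angle,offset", [(0, (0, 1)), (90, (-1, 0))])
    def test_matches_bruteforce_pair_enumeration(self, rng, angle, offset):
        img = rng.integers(0, 256, (4, 4)).astype(np.uint8)
        ours = ev.glcm(img, levels=4, distance=1, angles=(angle,))
        oracle = brute_force_glcm(img, 4, *offset)
        assert np.allclose(ours, oracle)

    def test_normalized_sum_one(self, rng):
        img = rng.integers(0, 256, (16, 16)).astype(np.uint8)
        assert ev.glcm(img, levels=8).sum() == pytest.approx(1.0)

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError):
            ev.glcm(np.zeros((4, 4), dtype=np.uint8), levels=1)


class TestHaralick:
    def test_constant_image_degenerate_features(self):
        m = ev.glcm(np.full((8, 8), 100, dtype=np.uint8), levels=8)
        f = ev.haralick_features(m)
        assert f["energy"] == pytest.approx(1.0)
        assert f["contrast"] == 0.0
        assert f["entropy"] == 0.0
        assert math.isnan(f["correlation"])  # undefined, reported as NaN

    def test_checkerboard_contrast(self):
        """At distance 1 horizontally every pair spans the full level range,
        so contrast = (levels - 1)^2 under 2-level quantization."""
        board = np.indices((8, 8)).sum(axis=0) % 2 * 255
        m = ev.glcm(board.astype(np.uint8), levels=2, distance=1, angles=(0,))
        f = ev.haralick_features(m)
        assert f["contrast"] == pytest.approx(1.0)
        assert f["homogeneity"] == pytest.approx(0.5)

    def test_against_reference_library_props(self, rng):
        """Energy, contrast, homogeneity and correlation agree with the
        scikit-image graycoprops reference on a toy 4-level image to 1e-6."""
        from skimage.feature import graycomatrix, graycoprops

        img = (rng.integers(0, 4, (16, 16)) * 64).astype(np.uint8)
        m = ev.glcm(img, levels=4, distance=1, angles=(0,))
        f = ev.haralick_features(m)

        q = ((img.astype(np.int64) * 4) // 256).astype(np.uint8)
        ref = graycomatrix(q, [1], [0], levels=4, symmetric=True, normed=True)
        assert f["energy"] == pytest.approx(float(graycoprops(ref, "ASM")[0, 0]), abs=1e-6)
        assert f["contrast"] == pytest.approx(
            float(graycoprops(ref, "contrast")[0, 0]), abs=1e-6)
        assert f["homogeneity"] == pytest.approx(
            float(graycoprops(ref, "homogeneity")[0, 0]), abs=1e-6)
        assert f["correlation"] == pytest.approx(
            float(graycoprops(ref, "correlation")[0, 0]), abs=1e-6)

    def test_all_fourteen_features_present_and_finite(self, rng):
        img = rng.integers(0, 256, (32, 32)).astype(np.uint8)
        f = ev.haralick_features(ev.glcm(img, levels=8))
        assert tuple(f) == ev.HARALICK_NAMES
        assert all(np.isfinite(v) for v in f.values())
        assert 0 < f["energy"] <= 1
        assert f["entropy"] >= 0 and f["sum_entropy"] >= 0

    def test_unnormalized_glcm_rejected(self):
        with pytest.raises(ValueError, match="normalized"):
            ev.haralick_features(np.ones((4, 4)))

    def test_matrix_over_set(self, small_phantom_set):
        df = ev.haralick_matrix(small_phantom_set, levels=16)
        assert df.shape == (len(small_phantom_set), 14)
        assert not df.isna().any().any()


# ---------------------------------------------------------------------------
# feature-set comparison
# ---------------------------------------------------------------------------

class TestCompareFeatureSets:
    def test_identical_groups_not_significant(self, small_phantom_set):
        df = ev.haralick_matrix(small_phantom_set, levels=16)
        out = ev.compare_feature_sets(df, df.copy())
        assert (out["t"] == 0.0).all()
        assert (out["p"] == 1.0).all()
        assert not out["significant"].any()

    def test_shifted_distribution_power_matches_analytic(self, rng):
        """Welch t-test rejection rate for a mean shift at n=100/group,
        alpha=0.01, matches the normal-approximation power within
        Monte-Carlo error."""
        from scipy import stats as sps

        n, delta, alpha, reps = 100, 0.5, 0.01, 400
        rejections = 0
        for _ in range(reps):
            a = rng.normal(0, 1, n)
            b = rng.normal(delta, 1, n)
            _, p = sps.ttest_ind(a, b, equal_var=False)
            rejections += p < alpha
        observed = rejections / reps
        ncp = delta / math.sqrt(2 / n)
        z = sps.norm.ppf(1 - alpha / 2)
        power = 1 - sps.norm.cdf(z - ncp) + sps.norm.cdf(-z - ncp)
        mc_err = 3 * math.sqrt(power * (1 - power) / reps)
        assert abs(observed - power) < mc_err + 0.02

    def test_alpha_threshold_honored(self, rng):
        real = pd.DataFrame({"f": rng.normal(0, 1, 30)})
        fake = pd.DataFrame({"f": rng.normal(0.8, 1, 30)})
        for alpha in (0.001, 0.01, 0.5):
            out = ev.compare_feature_sets(real, fake, alpha=alpha)
            assert bool(out.loc[0, "significant"]) == (out.loc[0, "p"] < alpha)

    def test_constant_features(self):
        same = pd.DataFrame({"f": [1.0, 1.0, 1.0]})
        other = pd.DataFrame({"f": [2.0, 2.0, 2.0]})
        eq = ev.compare_feature_sets(same, same.copy())
        assert eq.loc[0, "p"] == 1.0 and eq.loc[0, "t"] == 0.0
        ne = ev.compare_feature_sets(same, other)
        assert ne.loc[0, "p"] == 0.0 and ne.loc[0, "significant"]

    def test_small_groups_rejected(self):
        one = pd.DataFrame({"f": [1.0]})
        with pytest.raises(ValueError):
            ev.compare_feature_sets(one, one)


class TestPCACompare:
    def test_identical_matrices_unit_correlation(self, rng):
        x = rng.normal(size=(20, 14))
        out = ev.pca_pc1_compare(x, x.copy())
        assert out.pc1_correlation == pytest.approx(1.0)
        assert out.explained_var_real == out.explained_var_fake

    def test_rank_one_matrix_explains_everything(self, rng):
        scores = rng.normal(size=(20, 1))
        loading = rng.normal(size=(1, 14))
        x = scores @ loading
        out = ev.pca_pc1_compare(x, x)
        assert out.explained_var_real == pytest.approx(1.0)

    def test_loadings_match_eigendecomposition_oracle(self, rng):
        """PC1 loading equals the top eigenvector of the covariance matrix
        (independent eigen-decomposition), up to sign."""
        x = rng.normal(size=(50, 6)) @ np.diag([5, 3, 1, 1, 0.5, 0.2])
        y = rng.normal(size=(50, 6))
        out = ev.pca_pc1_compare(x, y)
        cov = np.cov(x, rowvar=False)
        w, v = np.linalg.eigh(cov)
        top = v[:, np.argmax(w)]
        from sklearn.decomposition import PCA

        pc1 = PCA(n_components=1).fit(x).components_[0]
        assert min(np.abs(pc1 - top).max(), np.abs(pc1 + top).max()) < 1e-8
        assert 0.0 <= out.pc1_correlation <= 1.0

    def test_degenerate_input_reported(self):
        flat = np.ones((5, 3))
        with pytest.raises(ValueError, match="zero variance"):
            ev.pca_pc1_compare(flat, flat)


# ---------------------------------------------------------------------------
# expert tally
# ---------------------------------------------------------------------------

class TestExpertScore:
    def test_single_class_rate(self):
        score = ev.expert_score(ev.ExpertTally({1: (500, 481)}))
        assert ev.round_half_up(score.trr_percent[1], 1) == 96.2

    def test_all_accepted_zero_misclassification(self):
        score = ev.expert_score(ev.ExpertTally({1: (10, 10), 2: (5, 5)}))
        assert score.misclassification_percent == 0.0

    def test_zero_generated_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            ev.expert_score(ev.ExpertTally({1: (0, 0)}))

    def test_accepted_exceeding_generated_rejected(self):
        with pytest.raises(ValueError):
            ev.ExpertTally({1: (5, 6)})

    def test_majority_vote_tally_from_judgments(self):
        rows = []
        for img, votes in [("a", [1, 1, 0]), ("b", [0, 0, 1]), ("c", [1, 1, 1])]:
            for judge, v in enumerate(votes):
                rows.append({"image": img, "class": 1, "judge": judge, "accepted": v})
        tally = ev.tally_from_judgments(pd.DataFrame(rows))
        assert tally.counts[1] == (3, 2)  # a and c accepted by majority


# ---------------------------------------------------------------------------
# median filter
# ---------------------------------------------------------------------------

class TestMedianFilter:
    def test_constant_unchanged(self):
        img = np.full((10, 10), 50, dtype=np.uint8)
        assert np.array_equal(ev.median_filter(img), img)

    def test_salt_pixel_restored(self):
        img = np.full((10, 10), 50, dtype=np.uint8)
        img[4, 4] = 255
        assert np.all(ev.median_filter(img) == 50)

    def test_matches_bruteforce_sorted_window_oracle(self, rng):
        img = rng.integers(0, 256, (9, 9)).astype(np.uint8)
        out = ev.median_filter(img, window=3)
        padded = np.pad(img, 1, mode="symmetric")  # edge-duplicating reflection
        for i in range(9):
            for j in range(9):
                window = np.sort(padded[i:i + 3, j:j + 3].ravel())
                assert out[i, j] == window[4], (i, j)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            ev.median_filter(np.zeros((4, 4), dtype=np.uint8), window=4)


def test_phantom_vs_noise_discrimination(small_phantom_set, rng):
    """Sanity ordering: a structured phantom set matches itself far better
    than pure noise — histogram correlation is materially lower against
    noise, and at least one Haralick feature separates the sets."""
    noise = _set([rng.integers(0, 256, (32, 32)).astype(np.uint8)
                  for _ in range(len(small_phantom_set))])
    h_real = ev.average_histogram(small_phantom_set)
    h_noise = ev.average_histogram(noise)
    self_corr = ev.hist_correlation(h_real, h_real)
    cross_corr = ev.hist_correlation(h_real, h_noise)
    assert cross_corr < self_corr - 0.5
    feats_real = ev.haralick_matrix(small_phantom_set, levels=16)
    feats_noise = ev.haralick_matrix(noise, levels=16)
    out = ev.compare_feature_sets(feats_real, feats_noise, alpha=0.01)
    assert out["significant"].sum() >= 1
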