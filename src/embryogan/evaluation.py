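"""Quality evaluation of generated image sets.

Three complementary comparisons between a real (training) set and a
generated set:

* first-order: the probability-normalized average histograms H1, H2 are
  compared with correlation, Chi-square, intersection and Bhattacharyya
  distance;
* second-order: 14 Haralick statistics of the gray-level co-occurrence
  matrix (GLCM) per image, compared feature-wise with two-sample t-tests
  and globally through the first principal component of each feature
  matrix;
* human: tally arithmetic for expert (visual Turing test) judgments —
  per-class true recognition rate and the overall misclassification
  rate.

A median filter is provided for salt-and-pepper cleanup of generated
frames before presentation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage.feature import graycomatrix

from .imageset import LabeledImageSet

__all__ = [
    "average_histogram", "hist_correlation", "hist_chi_square",
    "hist_intersection", "hist_bhattacharyya", "rescale_pair",
    "glcm", "haralick_features", "haralick_matrix", "HARALICK_NAMES",
    "compare_feature_sets", "pca_pc1_compare", "PCAComparison",
    "ExpertTally", "ExpertScore", "expert_score", "median_filter",
    "round_half_up",
]


# ---------------------------------------------------------------------------
# histograms
# ---------------------------------------------------------------------------

def average_histogram(imgset: LabeledImageSet | Sequence[np.ndarray],
                      bins: int = 256) -> np.ndarray:
    """Mean of per-image probability histograms; sums to 1.

    Each 8-bit image contributes its own normalized histogram, so every
    frame has equal weight regardless of size.
    """
    images = imgset.images if isinstance(imgset, LabeledImageSet) else list(imgset)
    if not images:
        raise ValueError("empty image set")
    acc = np.zeros(bins, dtype=np.float64)
    for img in images:
        arr = np.asarray(img)
        idx = (arr.astype(np.int64) * bins) // 256 if bins != 256 else arr.astype(np.int64)
        h = np.bincount(idx.ravel(), minlength=bins).astype(np.float64)
        acc += h / h.sum()
    return acc / len(images)


def _check_pair(h1, h2):
    h1 = np.asarray(h1, dtype=np.float64).ravel()
    h2 = np.asarray(h2, dtype=np.float64).ravel()
    if h1.shape != h2.shape:
        raise ValueError(f"histograms must have equal bin counts: {h1.size} vs {h2.size}")
    return h1, h2


def hist_correlation(h1, h2) -> float:
    """Pearson correlation over bins; 1 for identical histograms.

    Undefined (raises) when either histogram has zero variance across bins.
    """
    h1, h2 = _check_pair(h1, h2)
    d1 = h1 - h1.mean()
    d2 = h2 - h2.mean()
    denom = math.sqrt(float((d1 * d1).sum() * (d2 * d2).sum()))
    if denom == 0.0:
        raise ValueError("correlation undefined: a histogram has zero variance over bins")
    return float((d1 * d2).sum() / denom)


def hist_chi_square(h1, h2) -> float:
    """Chi-square statistic sum (H1-H2)^2 / H1 over bins with H1 > 0.

    Bins where the reference H1 is empty are skipped (the convention of
    the statistic's common implementation); the result is >= 0 and 0 iff
    the histograms agree on H1's support.
    """
    h1, h2 = _check_pair(h1, h2)
    nz = h1 > 0
    diff = h1[nz] - h2[nz]
    return float((diff * diff / h1[nz]).sum())


def hist_intersection(h1, h2) -> float:
    """Histogram intersection sum min(H1, H2); equals 1 for identical
    probability histograms and 0 for disjoint supports."""
    h1, h2 = _check_pair(h1, h2)
    return float(np.minimum(h1, h2).sum())


def hist_bhattacharyya(h1, h2) -> float:
    """Bhattacharyya distance in [0, 1]; 0 for identical histograms.

    B = sqrt(1 - sum(sqrt(H1 H2)) / sqrt(mean(H1) mean(H2) N^2)); for
    probability-normalized histograms the denominator equals 1 and the
    expression reduces to sqrt(1 - Bhattacharyya coefficient).
    """
    h1, h2 = _check_pair(h1, h2)
    if np.any(h1 < 0) or np.any(h2 < 0):
        raise ValueError("histograms must be non-negative")
    s1, s2 = h1.sum(), h2.sum()
    if s1 == 0 or s2 == 0:
        raise ValueError("all-zero histogram")
    n = h1.size
    coeff = float(np.sqrt(h1 * h2).sum()) / math.sqrt((s1 / n) * (s2 / n) * n * n)
    return math.sqrt(max(0.0, 1.0 - coeff))


def rescale_pair(h1, h2, total: float = 2.0) -> tuple[np.ndarray, np.ndarray]:
    """Rescale two histograms jointly so their masses sum to ``total``.

    Compatibility helper for intersection values quoted on a sum=2-over-
    the-pair normalization instead of the per-histogram probability one.
    """
    h1, h2 = _check_pair(h1, h2)
    s = h1.sum() + h2.sum()
    if s == 0:
        raise ValueError("all-zero histogram pair")
    f = total / s
    return h1 * f, h2 * f


# ---------------------------------------------------------------------------
# GLCM and Haralick statistics
# ---------------------------------------------------------------------------

def glcm(img: np.ndarray, levels: int = 64, distance: int = 1,
         angles: Sequence[float] = (0, 45, 90, 135),
         average: bool = True) -> np.ndarray:
    """Symmetric, normalized gray-level co-occurrence matrix.

    The 8-bit image is quantized to ``levels`` gray levels, pair counts are
    accumulated at the given pixel ``distance`` for each angle (degrees),
    counted symmetrically, and normalized to sum to 1 per angle.  With
    ``average=True`` (Haralick's rotation-invariant protocol) the per-angle
    matrices are averaged into one (levels, levels) matrix; otherwise the
    matrices are returned stacked as (levels, levels, n_angles).
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    arr = np.asarray(img)
    if arr.dtype != np.uint8:
        arr = np.clip(np.round(arr), 0, 255).astype(np.uint8)
    q = ((arr.astype(np.int64) * levels) // 256).astype(np.uint8)
    rad = [math.radians(a) for a in angles]
    mats = graycomatrix(q, distances=[distance], angles=rad, levels=levels,
                        symmetric=True, normed=True)
    mats = mats[:, :, 0, :]  # drop the distance axis
    if average:
        return mats.mean(axis=2)
    return mats


HARALICK_NAMES = (
    "energy", "contrast", "correlation", "variance", "homogeneity",
    "sum_average", "sum_variance", "sum_entropy", "entropy",
    "difference_variance", "difference_entropy",
    "info_measure_corr_1", "info_measure_corr_2", "max_correlation_coeff",
)


def _entropy(p: np.ndarray) -> float:
    nz = p > 0
    return float(-(p[nz] * np.log(p[nz])).sum())


def haralick_features(p: np.ndarray) -> dict[str, float]:
    """The 14 Haralick texture statistics of a normalized GLCM.

    Natural logarithms throughout with the 0 log 0 = 0 convention.  The
    sum-variance moment is taken about the sum average (the standard
    correction of the original formula's misprint).  For a degenerate
    matrix with a single nonzero cell the entropies are 0 and the
    correlation-type features are undefined (returned as NaN).
    """
    p = np.asarray(p, dtype=np.float64)
    if p.ndim != 2 or p.shape[0] != p.shape[1]:
        raise ValueError("GLCM must be square")
    total = p.sum()
    if not math.isclose(total, 1.0, rel_tol=1e-6):
        raise ValueError(f"GLCM must be normalized (sums to {total})")
    ng = p.shape[0]
    i = np.arange(ng, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float((i * px).sum())
    mu_y = float((i * py).sum())
    sigma_x = math.sqrt(float(((i - mu_x) ** 2 * px).sum()))
    sigma_y = math.sqrt(float(((i - mu_y) ** 2 * py).sum()))

    # distributions of i+j and |i-j|
    p_sum = np.zeros(2 * ng - 1)
    np.add.at(p_sum, (ii + jj).astype(int).ravel(), p.ravel())
    p_diff = np.zeros(ng)
    np.add.at(p_diff, np.abs(ii - jj).astype(int).ravel(), p.ravel())
    k_sum = np.arange(2 * ng - 1, dtype=np.float64)
    k_diff = np.arange(ng, dtype=np.float64)

    feats: dict[str, float] = {}
    feats["energy"] = float((p * p).sum())  # angular second moment
    feats["contrast"] = float(((ii - jj) ** 2 * p).sum())
    if sigma_x > 0 and sigma_y > 0:
        feats["correlation"] = float(((ii * jj * p).sum() - mu_x * mu_y)
                                     / (sigma_x * sigma_y))
    else:
        feats["correlation"] = float("nan")
    feats["variance"] = float(((ii - mu_x) ** 2 * p).sum())
    feats["homogeneity"] = float((p / (1.0 + (ii - jj) ** 2)).sum())
    sa = float((k_sum * p_sum).sum())
    feats["sum_average"] = sa
    feats["sum_variance"] = float(((k_sum - sa) ** 2 * p_sum).sum())
    feats["sum_entropy"] = _entropy(p_sum)
    hxy = _entropy(p.ravel())
    feats["entropy"] = hxy
    mu_d = float((k_diff * p_diff).sum())
    feats["difference_variance"] = float(((k_diff - mu_d) ** 2 * p_diff).sum())
    feats["difference_entropy"] = _entropy(p_diff)

    # information measures of correlation
    hx, hy = _entropy(px), _entropy(py)
    pxpy = np.outer(px, py)
    nz = (p > 0) & (pxpy > 0)
    hxy1 = float(-(p[nz] * np.log(pxpy[nz])).sum())
    nz2 = pxpy > 0
    hxy2 = float(-(pxpy[nz2] * np.log(pxpy[nz2])).sum())
    denom = max(hx, hy)
    feats["info_measure_corr_1"] = (hxy - hxy1) / denom if denom > 0 else float("nan")
    feats["info_measure_corr_2"] = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy))))

    # maximal correlation coefficient: sqrt of the second-largest eigenvalue
    # of Q(i,j) = sum_k p(i,k) p(j,k) / (px(i) py(k))
    pos = (px > 0) & (py > 0)
    if pos.sum() >= 2:
        psub = p[np.ix_(pos, pos)]
        q = (psub / px[pos, None]) @ (psub / py[pos][None, :]).T
        eigvals = np.sort(np.linalg.eigvals(q).real)
        feats["max_correlation_coeff"] = math.sqrt(max(0.0, float(eigvals[-2])))
    else:
        feats["max_correlation_coeff"] = float("nan")
    return feats


def haralick_matrix(imgset: LabeledImageSet | Sequence[np.ndarray],
                    levels: int = 64, distance: int = 1,
                    angles: Sequence[float] = (0, 45, 90, 135)) -> pd.DataFrame:
    """Per-image Haralick vectors as an (N, 14) DataFrame."""
    images = imgset.images if isinstance(imgset, LabeledImageSet) else list(imgset)
    rows = [haralick_features(glcm(img, levels=levels, distance=distance, angles=angles))
            for img in images]
    return pd.DataFrame(rows, columns=list(HARALICK_NAMES))


# ---------------------------------------------------------------------------
# feature-set comparison
# ---------------------------------------------------------------------------

def compare_feature_sets(real: pd.DataFrame | np.ndarray,
                         fake: pd.DataFrame | np.ndarray,
                         alpha: float = 0.01,
                         equal_var: bool = False) -> pd.DataFrame:
    """Two-sample t-test per Haralick feature (Welch by default).

    Returns a DataFrame (feature, t, p, significant) flagging features with
    p < alpha.  Features that are the same constant in both groups are
    reported as t = 0, p = 1; a feature constant at different values in the
    two groups is maximally significant (p = 0).  Features undefined (NaN)
    in either group are reported with NaN statistics and not flagged.
    """
    real_df = pd.DataFrame(real)
    fake_df = pd.DataFrame(fake)
    if isinstance(real, np.ndarray) and real_df.shape[1] == len(HARALICK_NAMES):
        real_df.columns = fake_df.columns = list(HARALICK_NAMES)
    if list(real_df.columns) != list(fake_df.columns):
        raise ValueError("feature sets must share columns")
    if len(real_df) < 2 or len(fake_df) < 2:
        raise ValueError("need at least 2 samples per group")

    rows = []
    for col in real_df.columns:
        a = real_df[col].to_numpy(dtype=np.float64)
        b = fake_df[col].to_numpy(dtype=np.float64)
        if np.isnan(a).any() or np.isnan(b).any():
            t_stat, p_val = float("nan"), float("nan")
        elif a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
            same = math.isclose(a.mean(), b.mean(), rel_tol=1e-12, abs_tol=1e-12)
            t_stat, p_val = (0.0, 1.0) if same else (float("inf"), 0.0)
        else:
            t_stat, p_val = stats.ttest_ind(a, b, equal_var=equal_var)
        rows.append({
            "feature": col, "t": float(t_stat), "p": float(p_val),
            "significant": bool(p_val < alpha) if not math.isnan(p_val) else False,
        })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PCAComparison:
    """PC1 explained-variance ratios of both sets and the absolute Pearson
    correlation between their PC1 loading vectors."""

    explained_var_real: float
    explained_var_fake: float
    pc1_correlation: float


def pca_pc1_compare(real: pd.DataFrame | np.ndarray,
                    fake: pd.DataFrame | np.ndarray) -> PCAComparison:
    """Compare the dominant variance direction of two feature matrices.

    PCA is fit separately on each matrix; the explained-variance ratio of
    the first component and the correlation between the two loading
    vectors are returned.  The correlation is reported as an absolute
    value because principal-axis signs are arbitrary.
    """
    from sklearn.decomposition import PCA

    out = []
    for mat in (real, fake):
        x = np.asarray(pd.DataFrame(mat), dtype=np.float64)
        if x.shape[0] < 2:
            raise ValueError("need at least 2 samples for PCA")
        if np.isnan(x).any():
            raise ValueError("feature matrix contains NaN; drop undefined features first")
        if np.allclose(x.var(axis=0), 0.0):
            raise ValueError("feature matrix has zero variance; PCA undefined")
        pca = PCA(n_components=1)
        pca.fit(x)
        out.append((float(pca.explained_variance_ratio_[0]), pca.components_[0]))
    (ev_r, load_r), (ev_f, load_f) = out
    corr = float(np.corrcoef(load_r, load_f)[0, 1])
    return PCAComparison(explained_var_real=ev_r, explained_var_fake=ev_f,
                         pc1_correlation=abs(corr))


# ---------------------------------------------------------------------------
# expert tally (visual Turing test arithmetic)
# ---------------------------------------------------------------------------

def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal rounding with ties away from zero, as in reported percentages."""
    factor = 10 ** ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class ExpertTally:
    """Per-class counts of generated images and expert-accepted ones."""

    counts: Mapping[int, tuple[int, int]]  # class -> (generated, accepted)

    def __post_init__(self) -> None:
        for cls, (gen, acc) in self.counts.items():
            if not 0 <= acc <= gen:
                raise ValueError(f"class {cls}: need 0 <= accepted <= generated, "
                                 f"got ({gen}, {acc})")


@dataclass(frozen=True)
class ExpertScore:
    trr_percent: Mapping[int, float]       # per-class true recognition rate, %
    misclassification_percent: float       # overall, %


def expert_score(tally: ExpertTally) -> ExpertScore:
    """Per-class true recognition rate and overall misclassification rate.

    TRR_c = 100 * accepted_c / generated_c; the overall misclassification
    rate pools all classes: 100 * sum(generated - accepted) / sum(generated).
    A class with zero generated images is undefined and rejected.
    """
    trr = {}
    total_gen = total_acc = 0
    for cls, (gen, acc) in tally.counts.items():
        if gen == 0:
            raise ValueError(f"class {cls}: TRR undefined for zero generated images")
        trr[cls] = 100.0 * acc / gen
        total_gen += gen
        total_acc += acc
    mis = 100.0 * (total_gen - total_acc) / total_gen
    return ExpertScore(trr_percent=trr, misclassification_percent=mis)


def tally_from_judgments(df: pd.DataFrame) -> ExpertTally:
    """Build a tally from a long-format judgments table.

    Expects columns ``image``, ``class``, ``judge``, ``accepted`` (0/1).
    An image counts as accepted when the majority of its judges accepted
    it (ties round down).
    """
    required = {"image", "class", "judge", "accepted"}
    if not required.issubset(df.columns):
        raise ValueError(f"judgments CSV needs columns {sorted(required)}")
    per_image = df.groupby(["class", "image"])["accepted"].agg(["sum", "count"])
    accepted = per_image["sum"] * 2 > per_image["count"]
    counts = {}
    for cls, sub in accepted.groupby(level="class"):
        counts[int(cls)] = (int(sub.size), int(sub.sum()))
    return ExpertTally(counts=counts)


def median_filter(img: np.ndarray, window: int = 3) -> np.ndarray:
    """Square-window median filter (salt-and-pepper cleanup).

    The window must be odd; edges use edge-duplicating reflected padding
    (the pixel at the border is repeated before mirroring).
    """
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be odd and positive")
    arr = np.asarray(img)
    return ndimage.median_filter(arr, size=window, mode="reflect")
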