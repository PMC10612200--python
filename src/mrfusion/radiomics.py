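"""From-scratch 2D radiomic feature extraction.

Per MRI sequence the extractor produces exactly 372 features: a 93-feature
block (18 first-order statistics + 75 texture features) on the original
image and the same block on three Laplacian-of-Gaussian filtered images
(sigma = 1, 2, 3 mm at the enforced 1 mm pixel spacing).  The texture
features come from five matrices computed on an ROI discretized to a fixed
number of gray levels:

=======  ==  ==============================================
GLCM     24  gray-level co-occurrence (distance 1, 4 directions)
GLRLM    16  gray-level run length (4 directions)
GLSZM    16  gray-level size zone (8-connected zones)
GLDM     14  gray-level dependence (distance 1, alpha = 0)
NGTDM     5  neighbouring gray-tone difference
=======  ==  ==============================================

Feature definitions follow the IBSI reference formulations; GLCM and GLRLM
features are computed per direction and averaged feature-wise.  Degenerate
ROIs (single gray level) use fixed finite conventions so every vector entry
stays finite: skewness/kurtosis -> 0, GLCM correlation/MCC -> 1, NGTDM
coarseness capped at 1e6.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io_formats import AnnotatedSlice, SchemaError

EPS = np.spacing(1.0)
COARSENESS_CAP = 1e6

DEFAULT_N_BINS = 32
DEFAULT_LOG_SIGMAS_MM = (1.0, 2.0, 3.0)

# distance-1 direction offsets: 0, 45, 90, 135 degrees (row, col)
DIRECTIONS_2D = ((0, 1), (-1, 1), (-1, 0), (-1, -1))

FIRSTORDER_NAMES = (
    "Energy", "TotalEnergy", "Entropy", "Minimum", "10Percentile", "90Percentile",
    "Maximum", "Mean", "Median", "InterquartileRange", "Range",
    "MeanAbsoluteDeviation", "RobustMeanAbsoluteDeviation", "RootMeanSquared",
    "Skewness", "Kurtosis", "Variance", "Uniformity",
)
GLCM_NAMES = (
    "Autocorrelation", "JointAverage", "ClusterProminence", "ClusterShade",
    "ClusterTendency", "Contrast", "Correlation", "DifferenceAverage",
    "DifferenceEntropy", "DifferenceVariance", "Id", "Idm", "Idmn", "Idn",
    "Imc1", "Imc2", "InverseVariance", "JointEnergy", "JointEntropy",
    "MaximumProbability", "MCC", "SumAverage", "SumEntropy", "SumSquares",
)
GLRLM_NAMES = (
    "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "GrayLevelVariance",
    "RunVariance", "RunEntropy", "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis", "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
)
GLSZM_NAMES = (
    "SmallAreaEmphasis", "LargeAreaEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "ZonePercentage", "GrayLevelVariance",
    "ZoneVariance", "ZoneEntropy", "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
)
GLDM_NAMES = (
    "SmallDependenceEmphasis", "LargeDependenceEmphasis",
    "GrayLevelNonUniformity", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "GrayLevelVariance",
    "DependenceVariance", "DependenceEntropy", "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis", "SmallDependenceLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis", "LargeDependenceLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
)
NGTDM_NAMES = ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength")

CLASS_NAMES = {
    "firstorder": FIRSTORDER_NAMES,
    "glcm": GLCM_NAMES,
    "glrlm": GLRLM_NAMES,
    "glszm": GLSZM_NAMES,
    "gldm": GLDM_NAMES,
    "ngtdm": NGTDM_NAMES,
}
FILTER_IDS = ("original", "log-sigma-1", "log-sigma-2", "log-sigma-3")


def canonical_feature_names(
    filters: tuple[str, ...] = FILTER_IDS,
) -> list[str]:
    """The frozen 372-entry feature-name registry: <filter>_<class>_<feature>."""
    return [
        f"{filt}_{cls}_{feat}"
        for filt in filters
        for cls in ("firstorder", "glcm", "glrlm", "glszm", "gldm", "ngtdm")
        for feat in CLASS_NAMES[cls]
    ]


FEATURE_NAMES = tuple(canonical_feature_names())
N_FEATURES = len(FEATURE_NAMES)  # 372


@dataclass
class DiscretizedROI:
    """ROI gray levels quantized to 1..Ng over the in-mask intensity range."""

    levels: np.ndarray  # int grid, 0 outside mask
    n_levels: int
    mask: np.ndarray

    @property
    def roi_levels(self) -> np.ndarray:
        return self.levels[self.mask]


@dataclass
class FeatureVector:
    values: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.names),):
            raise SchemaError("feature values/names length mismatch")
        if not np.all(np.isfinite(self.values)):
            bad = [n for n, v in zip(self.names, self.values) if not np.isfinite(v)]
            raise ValueError(f"non-finite feature value(s): {bad[:5]}")


@dataclass
class FeatureMatrix:
    """3 x n feature matrix in channel order (T2w, T1c, ADC)."""

    values: np.ndarray
    names: tuple[str, ...]
    patient_id: str = ""
    label: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[0] != 3:
            raise SchemaError(f"feature matrix must be 3 x n, got {self.values.shape}")
        if self.values.shape[1] != len(self.names):
            raise SchemaError("feature matrix width does not match name registry")


# ---------------------------------------------------------------------------
# filtering and discretization


def log_filter(sl: AnnotatedSlice, sigma_mm: float) -> AnnotatedSlice:
    """Laplacian-of-Gaussian response image at scale ``sigma_mm``.

    At the enforced 1 mm spacing the sigma is in pixels.  Sign convention
    follows the plain Laplacian of the Gaussian-smoothed image: a bright
    blob on a dark background has a negative response at its center.  The
    mask passes through unchanged.
    """
    if sigma_mm <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma_mm}")
    if sl.spacing != (1.0, 1.0):
        raise ValueError("log_filter requires unit spacing; resample first")
    response = ndimage.convolve(sl.pixels, _log_kernel(sigma_mm), mode="nearest")
    return AnnotatedSlice(response, sl.mask, sl.spacing, sl.sequence_id)


_LOG_KERNELS: dict[float, np.ndarray] = {}


def _log_kernel(sigma: float) -> np.ndarray:
    """Discrete LoG kernel, zero-mean corrected so constants map exactly to 0.

    The kernel is the impulse response of the sampled Gaussian Laplacian;
    subtracting its (tiny) mean removes the DC leakage of truncation while
    the even symmetry keeps linear ramps annihilated too.
    """
    if sigma not in _LOG_KERNELS:
        half = int(np.ceil(4.0 * sigma))
        impulse = np.zeros((2 * half + 1, 2 * half + 1))
        impulse[half, half] = 1.0
        k = ndimage.gaussian_laplace(impulse, sigma=sigma, mode="constant")
        k -= k.mean()
        _LOG_KERNELS[sigma] = k
    return _LOG_KERNELS[sigma]


def discretize(sl: AnnotatedSlice, n_bins: int = DEFAULT_N_BINS) -> DiscretizedROI:
    """Fixed-bin-count discretization of in-mask intensities into 1..n_bins.

    The in-mask minimum maps to level 1 and the maximum to level
    ``n_bins``; a constant ROI collapses to a single level (Ng = 1).
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    vals = sl.roi_values
    lo, hi = vals.min(), vals.max()
    levels = np.zeros(sl.pixels.shape, dtype=np.int64)
    if hi == lo:
        levels[sl.mask] = 1
        return DiscretizedROI(levels, 1, sl.mask)
    binned = np.floor((sl.pixels[sl.mask] - lo) / (hi - lo) * n_bins).astype(np.int64) + 1
    binned = np.clip(binned, 1, n_bins)
    levels[sl.mask] = binned
    return DiscretizedROI(levels, n_bins, sl.mask)


# ---------------------------------------------------------------------------
# first-order statistics


def first_order_features(
    sl: AnnotatedSlice, n_bins: int = DEFAULT_N_BINS
) -> dict[str, float]:
    """The 18 first-order intensity statistics over in-mask pixels.

    Entropy and Uniformity use the fixed-bin-count histogram (same binning
    as the texture matrices); all moments are population moments.  At unit
    pixel spacing TotalEnergy coincides with Energy.
    """
    x = sl.roi_values
    n = x.size
    mean = x.mean()
    var = x.var()
    p10, p25, med, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]

    hist = np.bincount(discretize(sl, n_bins).roi_levels)[1:].astype(np.float64)
    p = hist[hist > 0] / n

    if var > 0:
        m2 = var
        skew = np.mean((x - mean) ** 3) / m2**1.5
        kurt = np.mean((x - mean) ** 4) / m2**2
    else:
        skew, kurt = 0.0, 0.0  # constant-ROI convention

    pixel_area = 1.0  # mm^2 at enforced unit spacing
    energy = float(np.sum(x**2))
    return {
        "Energy": energy,
        "TotalEnergy": pixel_area * energy,
        "Entropy": float(-np.sum(p * np.log2(p))),
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": float(mean),
        "Median": float(med),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": float(np.abs(robust - robust.mean()).mean()),
        "RootMeanSquared": float(np.sqrt(np.mean(x**2))),
        "Skewness": float(skew),
        "Kurtosis": float(kurt),
        "Variance": float(var),
        "Uniformity": float(np.sum(p**2)),
    }


# ---------------------------------------------------------------------------
# GLCM


def glcm_matrix(d: DiscretizedROI, direction: tuple[int, int]) -> np.ndarray:
    """Symmetric normalized co-occurrence matrix for one distance-1 offset."""
    ng = d.n_levels
    dr, dc = direction
    lv, mk = d.levels, d.mask
    h, w = lv.shape
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    a = lv[r0:r1, c0:c1]
    b = lv[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    valid = mk[r0:r1, c0:c1] & mk[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    counts = np.zeros((ng, ng), dtype=np.float64)
    np.add.at(counts, (a[valid] - 1, b[valid] - 1), 1.0)
    counts = counts + counts.T  # symmetrize
    total = counts.sum()
    return counts / total if total > 0 else counts


def _glcm_features_single(P: np.ndarray, ng: int) -> dict[str, float]:
    if P.sum() == 0 or ng == 0:
        # no valid pixel pair in this direction: neutral degenerate output
        P = np.zeros((max(ng, 1), max(ng, 1)))
        P[0, 0] = 1.0
        ng = max(ng, 1)
    i = np.arange(1, ng + 1, dtype=np.float64)
    I, J = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    mu = float((i * px).sum())  # symmetric: mu_x == mu_y
    sigma2 = float(((i - mu) ** 2 * px).sum())
    sigma = np.sqrt(sigma2)

    # p_{x+y} over k = 2..2Ng, p_{x-y} over k = 0..Ng-1
    ksum = np.arange(2, 2 * ng + 1, dtype=np.float64)
    p_sum = np.zeros(2 * ng - 1)
    np.add.at(p_sum, (I + J).astype(int).ravel() - 2, P.ravel())
    kdiff = np.arange(0, ng, dtype=np.float64)
    p_diff = np.zeros(ng)
    np.add.at(p_diff, np.abs(I - J).astype(int).ravel(), P.ravel())

    diff_avg = float((kdiff * p_diff).sum())
    nz = P > 0
    joint_entropy = float(-np.sum(P[nz] * np.log2(P[nz])))
    hx = float(-np.sum(px[px > 0] * np.log2(px[px > 0])))
    # HXY1 / HXY2 for the information measures of correlation
    pxpy = np.outer(px, px)
    m = nz & (pxpy > 0)
    hxy1 = float(-np.sum(P[m] * np.log2(pxpy[m])))
    m2 = pxpy > 0
    hxy2 = float(-np.sum(pxpy[m2] * np.log2(pxpy[m2])))
    imc1 = (joint_entropy - hxy1) / hx if hx > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - joint_entropy)))))

    if sigma2 > 0:
        correlation = float((np.sum(I * J * P) - mu * mu) / (sigma * sigma))
    else:
        correlation = 1.0  # single-level convention

    # MCC: second largest eigenvalue of Q(i,j) = sum_k P(i,k)P(j,k)/(px_i px_k)
    active = px > 0
    if active.sum() < 2:
        mcc = 1.0
    else:
        Pa = P[np.ix_(active, active)]
        pxa = px[active]
        Q = (Pa / pxa[:, None]) @ (Pa / pxa[None, :]).T
        ev = np.sort(np.real(np.linalg.eigvals(Q)))
        mcc = float(np.sqrt(max(0.0, min(1.0, ev[-2]))))

    inv_var_mask = I != J
    dsq = (I - J) ** 2
    return {
        "Autocorrelation": float(np.sum(I * J * P)),
        "JointAverage": mu,
        "ClusterProminence": float(np.sum((I + J - 2 * mu) ** 4 * P)),
        "ClusterShade": float(np.sum((I + J - 2 * mu) ** 3 * P)),
        "ClusterTendency": float(np.sum((I + J - 2 * mu) ** 2 * P)),
        "Contrast": float(np.sum(dsq * P)),
        "Correlation": correlation,
        "DifferenceAverage": diff_avg,
        "DifferenceEntropy": float(-np.sum(p_diff[p_diff > 0] * np.log2(p_diff[p_diff > 0]))),
        "DifferenceVariance": float(((kdiff - diff_avg) ** 2 * p_diff).sum()),
        "Id": float(np.sum(P / (1.0 + np.abs(I - J)))),
        "Idm": float(np.sum(P / (1.0 + dsq))),
        "Idmn": float(np.sum(P / (1.0 + dsq / ng**2))),
        "Idn": float(np.sum(P / (1.0 + np.abs(I - J) / ng))),
        "Imc1": imc1,
        "Imc2": imc2,
        "InverseVariance": float(np.sum(P[inv_var_mask] / dsq[inv_var_mask])),
        "JointEnergy": float(np.sum(P**2)),
        "JointEntropy": joint_entropy,
        "MaximumProbability": float(P.max()),
        "MCC": mcc,
        "SumAverage": float((ksum * p_sum).sum()),
        "SumEntropy": float(-np.sum(p_sum[p_sum > 0] * np.log2(p_sum[p_sum > 0]))),
        "SumSquares": sigma2,
    }


def glcm_features(
    d: DiscretizedROI, directions: tuple[tuple[int, int], ...] = DIRECTIONS_2D
) -> dict[str, float]:
    """24 co-occurrence features, averaged feature-wise over directions."""
    per_dir = [_glcm_features_single(glcm_matrix(d, off), d.n_levels) for off in directions]
    return {k: float(np.mean([f[k] for f in per_dir])) for k in GLCM_NAMES}


# ---------------------------------------------------------------------------
# GLRLM


def glrlm_matrix(d: DiscretizedROI, direction: tuple[int, int]) -> np.ndarray:
    """Run-length matrix R[level-1, length-1] for one direction.

    A run is a maximal in-mask streak of equal gray level along the
    direction; out-of-mask pixels break runs.
    """
    ng = d.n_levels
    lv = np.where(d.mask, d.levels, 0)
    h, w = lv.shape
    max_len = max(h, w)
    R = np.zeros((ng, max_len), dtype=np.float64)

    dr, dc = direction
    # enumerate lines along the direction by walking from seed pixels
    seeds = []
    if (dr, dc) == (0, 1):
        seeds = [(r, 0) for r in range(h)]
    elif (dr, dc) == (-1, 0):
        seeds = [(h - 1, c) for c in range(w)]
    elif (dr, dc) == (-1, 1):
        seeds = [(h - 1, c) for c in range(w)] + [(r, 0) for r in range(h - 1)]
    elif (dr, dc) == (-1, -1):
        seeds = [(h - 1, c) for c in range(w)] + [(r, w - 1) for r in range(h - 1)]
    else:
        raise ValueError(f"unsupported direction {direction}")

    for r, c in seeds:
        cur, length = 0, 0
        rr, cc = r, c
        while 0 <= rr < h and 0 <= cc < w:
            v = lv[rr, cc]
            if v == cur and v != 0:
                length += 1
            else:
                if cur != 0:
                    R[cur - 1, length - 1] += 1
                cur, length = v, (1 if v != 0 else 0)
            rr += dr
            cc += dc
        if cur != 0:
            R[cur - 1, length - 1] += 1
    return R


def _rlm_style_features(P: np.ndarray, n_pixels: int, names: tuple[str, ...]) -> dict[str, float]:
    """Shared feature formulas for run-length / size-zone / dependence matrices.

    ``P[i-1, s-1]`` counts entities (runs, zones, dependencies) of gray
    level i and size s.  ``names`` selects + labels the output block.
    """
    ns = P.sum()
    if ns == 0:  # degenerate guard; unreachable for a non-empty mask
        return {k: 0.0 for k in names}
    ng, smax = P.shape
    i = np.arange(1, ng + 1, dtype=np.float64)
    s = np.arange(1, smax + 1, dtype=np.float64)
    I, S = np.meshgrid(i, s, indexing="ij")
    p = P / ns
    pg = P.sum(axis=1)  # per gray level
    psz = P.sum(axis=0)  # per size
    mu_i = float(np.sum(I * p))
    mu_s = float(np.sum(S * p))
    nz = p > 0

    core = {
        "Small": float(np.sum(P / S**2) / ns),
        "Large": float(np.sum(P * S**2) / ns),
        "GLN": float(np.sum(pg**2) / ns),
        "GLNN": float(np.sum(pg**2) / ns**2),
        "SN": float(np.sum(psz**2) / ns),
        "SNN": float(np.sum(psz**2) / ns**2),
        "Pct": float(ns / n_pixels),
        "GLV": float(np.sum(p * (I - mu_i) ** 2)),
        "SV": float(np.sum(p * (S - mu_s) ** 2)),
        "Entropy": float(-np.sum(p[nz] * np.log2(p[nz]))),
        "LGL": float(np.sum(P / I**2) / ns),
        "HGL": float(np.sum(P * I**2) / ns),
        "SmallLGL": float(np.sum(P / (I**2 * S**2)) / ns),
        "SmallHGL": float(np.sum(P * I**2 / S**2) / ns),
        "LargeLGL": float(np.sum(P * S**2 / I**2) / ns),
        "LargeHGL": float(np.sum(P * I**2 * S**2) / ns),
    }
    order = [
        "Small", "Large", "GLN", "GLNN", "SN", "SNN", "Pct", "GLV", "SV",
        "Entropy", "LGL", "HGL", "SmallLGL", "SmallHGL", "LargeLGL", "LargeHGL",
    ]
    if len(names) == 16:
        keys = order
    else:  # GLDM: 14 features, no SNN/Pct, different ordering
        keys = [
            "Small", "Large", "GLN", "SN", "SNN", "GLV", "SV", "Entropy",
            "LGL", "HGL", "SmallLGL", "SmallHGL", "LargeLGL", "LargeHGL",
        ]
    return {name: core[key] for name, key in zip(names, keys)}


def glrlm_features(
    d: DiscretizedROI, directions: tuple[tuple[int, int], ...] = DIRECTIONS_2D
) -> dict[str, float]:
    """16 run-length features, averaged feature-wise over the 4 directions."""
    n_pix = int(d.mask.sum())
    per_dir = [
        _rlm_style_features(glrlm_matrix(d, off), n_pix, GLRLM_NAMES) for off in directions
    ]
    return {k: float(np.mean([f[k] for f in per_dir])) for k in GLRLM_NAMES}


# ---------------------------------------------------------------------------
# GLSZM


def glszm_matrix(d: DiscretizedROI) -> np.ndarray:
    """Size-zone matrix Z[level-1, size-1] using 8-connected zones."""
    ng = d.n_levels
    n_pix = int(d.mask.sum())
    Z = np.zeros((ng, max(n_pix, 1)), dtype=np.float64)
    structure = np.ones((3, 3), dtype=bool)  # 8-connectivity
    for g in range(1, ng + 1):
        binary = (d.levels == g) & d.mask
        if not binary.any():
            continue
        labeled, n_zones = ndimage.label(binary, structure=structure)
        sizes = np.bincount(labeled.ravel())[1:]
        for sz in sizes:
            Z[g - 1, sz - 1] += 1
    return Z


def glszm_features(d: DiscretizedROI) -> dict[str, float]:
    """16 size-zone features (zones are 8-connected components per level)."""
    return _rlm_style_features(glszm_matrix(d), int(d.mask.sum()), GLSZM_NAMES)


# ---------------------------------------------------------------------------
# GLDM


def gldm_matrix(d: DiscretizedROI, alpha: float = 0.0) -> np.ndarray:
    """Dependence matrix D[level-1, k-1].

    For each in-mask pixel, its dependence k is 1 + the number of in-mask
    8-neighbours whose gray-level difference is <= alpha.
    """
    ng = d.n_levels
    lv, mk = d.levels, d.mask
    h, w = lv.shape
    dep = np.zeros((h, w), dtype=np.int64)
    offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    for dr, dc in offsets:
        r0, r1 = max(0, -dr), min(h, h - dr)
        c0, c1 = max(0, -dc), min(w, w - dc)
        nb_ok = (
            mk[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
            & (np.abs(lv[r0:r1, c0:c1] - lv[r0 + dr : r1 + dr, c0 + dc : c1 + dc]) <= alpha)
        )
        dep[r0:r1, c0:c1] += nb_ok
    k = dep[mk] + 1  # count the pixel itself
    g = lv[mk]
    D = np.zeros((ng, 9), dtype=np.float64)
    np.add.at(D, (g - 1, k - 1), 1.0)
    return D


def gldm_features(d: DiscretizedROI, alpha: float = 0.0) -> dict[str, float]:
    """14 dependence features (distance-1 neighbourhood, threshold alpha)."""
    return _rlm_style_features(gldm_matrix(d, alpha), int(d.mask.sum()), GLDM_NAMES)


# ---------------------------------------------------------------------------
# NGTDM


def ngtdm_table(d: DiscretizedROI) -> tuple[np.ndarray, np.ndarray]:
    """Per-level counts n_i and summed absolute differences s_i.

    s_i sums |i - mean(valid 8-neighbours)| over in-mask pixels of level i;
    pixels without any in-mask neighbour contribute zero difference.
    """
    ng = d.n_levels
    lv, mk = d.levels, d.mask
    h, w = lv.shape
    nb_sum = np.zeros((h, w), dtype=np.float64)
    nb_cnt = np.zeros((h, w), dtype=np.int64)
    offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    for dr, dc in offsets:
        r0, r1 = max(0, -dr), min(h, h - dr)
        c0, c1 = max(0, -dc), min(w, w - dc)
        nb_m = mk[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        nb_sum[r0:r1, c0:c1] += np.where(nb_m, lv[r0 + dr : r1 + dr, c0 + dc : c1 + dc], 0)
        nb_cnt[r0:r1, c0:c1] += nb_m
    g = lv[mk].astype(np.float64)
    cnt = nb_cnt[mk]
    diff = np.zeros_like(g)
    has = cnt > 0
    diff[has] = np.abs(g[has] - nb_sum[mk][has] / cnt[has])
    n_i = np.zeros(ng)
    s_i = np.zeros(ng)
    np.add.at(n_i, lv[mk] - 1, 1.0)
    np.add.at(s_i, lv[mk] - 1, diff)
    return n_i, s_i


def ngtdm_features(d: DiscretizedROI) -> dict[str, float]:
    """The 5 neighbouring-gray-tone-difference features."""
    n_i, s_i = ngtdm_table(d)
    nvp = n_i.sum()
    p_i = n_i / nvp
    present = p_i > 0
    ngp = int(present.sum())
    i = np.arange(1, d.n_levels + 1, dtype=np.float64)

    denom_coarse = float(np.sum(p_i * s_i))
    coarseness = min(COARSENESS_CAP, 1.0 / denom_coarse) if denom_coarse > 0 else COARSENESS_CAP

    if ngp > 1:
        pi, pj = np.meshgrid(p_i[present], p_i[present], indexing="ij")
        ii, jj = np.meshgrid(i[present], i[present], indexing="ij")
        contrast = float(
            np.sum(pi * pj * (ii - jj) ** 2) / (ngp * (ngp - 1)) * (np.sum(s_i) / nvp)
        )
        busy_den = float(np.sum(np.abs(ii * pi - jj * pj)))
        busyness = denom_coarse / busy_den if busy_den > 0 else 0.0
        si, sj = np.meshgrid(s_i[present], s_i[present], indexing="ij")
        complexity = float(np.sum(np.abs(ii - jj) * (pi * si + pj * sj) / (pi + pj)) / nvp)
        s_tot = float(np.sum(s_i))
        strength = float(np.sum((pi + pj) * (ii - jj) ** 2)) / s_tot if s_tot > 0 else 0.0
    else:
        contrast = busyness = complexity = strength = 0.0

    return {
        "Coarseness": float(coarseness),
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }


# ---------------------------------------------------------------------------
# assembly


@dataclass
class RadiomicsConfig:
    """Extraction settings (LoG scales in mm, gray-level bin count)."""

    log_sigmas_mm: tuple[float, ...] = DEFAULT_LOG_SIGMAS_MM
    n_bins: int = DEFAULT_N_BINS
    gldm_alpha: float = 0.0


def _feature_block(sl: AnnotatedSlice, cfg: RadiomicsConfig) -> list[float]:
    d = discretize(sl, cfg.n_bins)
    block: list[float] = []
    block += first_order_features(sl, cfg.n_bins).values()
    block += glcm_features(d).values()
    block += glrlm_features(d).values()
    block += glszm_features(d).values()
    block += gldm_features(d, cfg.gldm_alpha).values()
    block += ngtdm_features(d).values()
    return block


def extract_sequence_features(
    sl: AnnotatedSlice, config: RadiomicsConfig | None = None
) -> FeatureVector:
    """All 372 features for one sequence: 93 original + 3 x 93 LoG-filtered."""
    cfg = config or RadiomicsConfig()
    if sl.spacing != (1.0, 1.0):
        raise ValueError("extraction requires unit spacing; resample first")
    values = _feature_block(sl, cfg)
    for sigma in cfg.log_sigmas_mm:
        values += _feature_block(log_filter(sl, sigma), cfg)
    names = canonical_feature_names(
        ("original",) + tuple(f"log-sigma-{int(s) if float(s).is_integer() else s}"
                              for s in cfg.log_sigmas_mm)
    )
    return FeatureVector(np.asarray(values), tuple(names))


class FeatureStandardizer:
    """Per-feature z-scoring with one scaler shared by all three channels.

    Fitting pools the 3 channel rows of every training patient so the
    learned channel-attention weights stay comparable across channels.
    """

    def __init__(self) -> None:
        self.mean_: np.ndarray | None = None
        self.scale_: np.ndarray | None = None

    def fit(self, matrices: list[FeatureMatrix]) -> "FeatureStandardizer":
        pooled = np.vstack([m.values for m in matrices])
        self.mean_ = pooled.mean(axis=0)
        scale = pooled.std(axis=0)
        scale[scale == 0] = 1.0
        self.scale_ = scale
        return self

    def transform(self, values: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise RuntimeError("standardizer not fitted")
        return (values - self.mean_) / self.scale_


def build_feature_matrix(
    vectors: dict[str, FeatureVector],
    standardizer: FeatureStandardizer | None = None,
    patient_id: str = "",
    label: int | None = None,
) -> FeatureMatrix:
    """Stack per-sequence vectors into a 3 x n matrix in channel order.

    ``vectors`` maps sequence id -> FeatureVector; a name-order mismatch
    between sequences raises :class:`SchemaError`.  The optional
    standardizer (fitted on the training cohort) is applied to every row.
    """
    from .io_formats import SEQUENCES

    missing = [s for s in SEQUENCES if s not in vectors]
    if missing:
        raise SchemaError(f"missing sequence vector(s): {missing}")
    names = vectors[SEQUENCES[0]].names
    for s in SEQUENCES[1:]:
        if vectors[s].names != names:
            raise SchemaError(f"feature name order differs between sequences ({s})")
    rows = np.stack([vectors[s].values for s in SEQUENCES])
    if standardizer is not None:
        rows = standardizer.transform(rows)
    return FeatureMatrix(rows, names, patient_id=patient_id, label=label)
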