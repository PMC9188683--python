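"""Moving-window radiomic texture parametric maps.

Spatial enhancement characteristics at the wash-in, peak and wash-out
frames are described by 43 texture features per window: 3 first-order
(histogram) statistics plus matrix-based families capturing second- and
higher-order spatial gray-level statistics — co-occurrence (GLCM, 9),
run-length (GLRLM, 13), size-zone (GLSZM, 13) and neighborhood gray-tone
difference (NGTDM, 5).

Instead of one value per ROI, the analysis window (21 x 21 px, stride 3)
is slid across the ROI so each feature becomes a parametric map that
preserves local structure.  Before feature extraction each window's own
intensity range is uniformly quantized to 64 gray levels, which makes
all matrix-based features invariant to affine intensity rescaling.

Conventions for the 2-D matrix constructions: GLCM and GLRLM pool counts
over the four in-plane directions (0, 45, 90, 135 degrees) before
normalization; GLSZM zones are 8-connected constant-level components;
NGTDM uses the 8-neighbor mean over interior pixels.  The exact
definition of every statistic is fixed by the brute-force reference
implementations in the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import convolve
from skimage.feature import graycomatrix
from skimage.measure import label as cc_label

N_GRAY_LEVELS = 64
EPS_NGTDM = 1e-6          # guard in Coarseness/Strength denominators

GLOBAL_NAMES = ("Variance", "Skewness", "Kurtosis")
GLCM_NAMES = (
    "Energy", "Contrast", "Correlation", "Homogeneity", "Variance",
    "SumAverage", "Entropy", "Dissimilarity", "AutoCorrelation",
)
GLRLM_NAMES = (
    "SRE", "LRE", "GLN", "RLN", "RP", "LGRE", "HGRE",
    "SRLGE", "SRHGE", "LRLGE", "LRHGE", "GLV", "RLV",
)
GLSZM_NAMES = (
    "SZE", "LZE", "GLN", "ZSN", "ZP", "LGZE", "HGZE",
    "SZLGE", "SZHGE", "LZLGE", "LZHGE", "GLV", "ZSV",
)
NGTDM_NAMES = ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength")

TEXTURE_FEATURE_NAMES = tuple(
    [f"Global_{n}" for n in GLOBAL_NAMES]
    + [f"GLCM_{n}" for n in GLCM_NAMES]
    + [f"GLRLM_{n}" for n in GLRLM_NAMES]
    + [f"GLSZM_{n}" for n in GLSZM_NAMES]
    + [f"NGTDM_{n}" for n in NGTDM_NAMES]
)
assert len(TEXTURE_FEATURE_NAMES) == 43

FIDUCIAL_PREFIXES = {"wash_in": "WiIm", "peak": "PkIm", "wash_out": "WoIm"}


def quantize(window: np.ndarray, n_levels: int = N_GRAY_LEVELS) -> np.ndarray:
    """Uniformly quantize a window's own min-max range into 1..n_levels.

    A constant window maps to all ones.  Because quantization uses the
    local range, the output is invariant to affine rescaling of the raw
    intensities.
    """
    x = np.asarray(window, dtype=np.float64)
    if x.size == 0:
        raise ValueError("empty window")
    lo = x.min()
    rng = x.max() - lo
    if rng == 0:
        return np.ones(x.shape, dtype=np.int64)
    q = np.floor(n_levels * (x - lo) / rng).astype(np.int64) + 1
    return np.minimum(q, n_levels)


def global_features(window: np.ndarray) -> dict[str, float]:
    """First-order histogram statistics of the raw window intensities.

    Kurtosis is non-excess (normal distribution -> 3).  A constant window
    yields (0, 0, 0) by convention.
    """
    x = np.asarray(window, dtype=np.float64).ravel()
    mu = x.mean()
    m2 = np.mean((x - mu) ** 2)
    if np.ptp(x) == 0 or m2 == 0:
        return {"Variance": 0.0, "Skewness": 0.0, "Kurtosis": 0.0}
    m3 = np.mean((x - mu) ** 3)
    m4 = np.mean((x - mu) ** 4)
    return {
        "Variance": float(m2),
        "Skewness": float(m3 / m2**1.5),
        "Kurtosis": float(m4 / m2**2),
    }


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

_GLCM_ANGLES = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)
_grid_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _level_grids(n_levels: int) -> tuple[np.ndarray, np.ndarray]:
    if n_levels not in _grid_cache:
        lv = np.arange(1, n_levels + 1, dtype=np.float64)
        _grid_cache[n_levels] = (lv[:, None], lv[None, :])
    return _grid_cache[n_levels]


def glcm_matrix(qwin: np.ndarray, n_levels: int) -> np.ndarray:
    """Normalized symmetric co-occurrence matrix, distance 1, pooled over
    the four in-plane directions."""
    counts = graycomatrix(
        (qwin - 1).astype(np.uint8), distances=[1], angles=_GLCM_ANGLES,
        levels=n_levels, symmetric=True, normed=False,
    )[:, :, 0, :].sum(axis=2).astype(np.float64)
    total = counts.sum()
    return counts / total if total > 0 else counts


def glcm_features(qwin: np.ndarray, n_levels: int = N_GRAY_LEVELS) -> dict[str, float]:
    """Nine Haralick-family statistics of the pooled co-occurrence matrix.

    Level indices are the 1-based quantized gray levels.  Correlation of a
    zero-variance matrix (constant window) is defined as 0.
    """
    p = glcm_matrix(qwin, n_levels)
    i, j = _level_grids(n_levels)
    px = p.sum(axis=1)
    lv = np.arange(1, n_levels + 1, dtype=np.float64)
    mu = float((lv * px).sum())
    var = float(((lv - mu) ** 2 * px).sum())
    autocorr = float((i * j * p).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = float(-(p[p > 0] * np.log2(p[p > 0])).sum())
    return {
        "Energy": float((p**2).sum()),
        "Contrast": float(((i - j) ** 2 * p).sum()),
        "Correlation": float((autocorr - mu**2) / var) if var > 0 else 0.0,
        "Homogeneity": float((p / (1.0 + np.abs(i - j))).sum()),
        "Variance": var,
        "SumAverage": float(((i + j) * p).sum()),
        "Entropy": ent,
        "Dissimilarity": float((np.abs(i - j) * p).sum()),
        "AutoCorrelation": autocorr,
    }


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

def _runs_of_lines(lines: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Run levels and lengths over a list of 1-D level sequences."""
    parts = []
    for ln in lines:
        parts.append(ln)
        parts.append(np.zeros(1, dtype=ln.dtype))   # separator (levels are >= 1)
    cat = np.concatenate(parts)
    starts = np.flatnonzero(np.r_[True, cat[1:] != cat[:-1]])
    lengths = np.diff(np.r_[starts, cat.size])
    levels = cat[starts]
    keep = levels > 0
    return levels[keep], lengths[keep]


def glrlm_matrix(qwin: np.ndarray, n_levels: int) -> np.ndarray:
    """Run-length count matrix (levels x run length) pooled over the four
    in-plane directions."""
    h, w = qwin.shape
    max_len = max(h, w)
    lines: list[np.ndarray] = []
    lines += [qwin[r] for r in range(h)]                      # 0 deg
    lines += [qwin[:, c] for c in range(w)]                   # 90 deg
    lines += [qwin.diagonal(k) for k in range(-(h - 1), w)]   # 45 deg
    fl = np.fliplr(qwin)
    lines += [fl.diagonal(k) for k in range(-(h - 1), w)]     # 135 deg
    levels, lengths = _runs_of_lines(lines)
    mat = np.zeros((n_levels, max_len), dtype=np.float64)
    np.add.at(mat, (levels - 1, lengths - 1), 1.0)
    return mat


def _rlm_style_features(
    mat: np.ndarray, names: tuple[str, ...], n_sites: float
) -> dict[str, float]:
    """Shared statistics for run-length and size-zone matrices.

    ``mat`` is a (levels x size) count matrix; ``n_sites`` normalizes the
    percentage feature (runs per possible run site / zones per pixel).
    """
    n = mat.sum()
    i = np.arange(1, mat.shape[0] + 1, dtype=np.float64)[:, None]
    s = np.arange(1, mat.shape[1] + 1, dtype=np.float64)[None, :]
    p = mat / n
    pg = p.sum(axis=1)          # marginal over sizes -> per-level
    ps = p.sum(axis=0)          # marginal over levels -> per-size
    mu_i = float((i.ravel() * pg).sum())
    mu_s = float((s.ravel() * ps).sum())
    vals = (
        float((p / s**2).sum()),                       # short emphasis
        float((p * s**2).sum()),                       # long emphasis
        float((mat.sum(axis=1) ** 2).sum() / n),       # gray-level non-unif.
        float((mat.sum(axis=0) ** 2).sum() / n),       # size non-uniformity
        float(n / n_sites),                            # percentage
        float((p / i**2).sum()),                       # low gray-level
        float((p * i**2).sum()),                       # high gray-level
        float((p / (i**2 * s**2)).sum()),
        float((p * i**2 / s**2).sum()),
        float((p * s**2 / i**2).sum()),
        float((p * i**2 * s**2).sum()),
        float((p * (i - mu_i) ** 2).sum()),            # gray-level variance
        float((p * (s - mu_s) ** 2).sum()),            # size variance
    )
    return dict(zip(names, vals))


def glrlm_features(qwin: np.ndarray, n_levels: int = N_GRAY_LEVELS) -> dict[str, float]:
    """Thirteen run-length statistics; run percentage is normalized by
    pixels x directions so it lies in (0, 1]."""
    mat = glrlm_matrix(qwin, n_levels)
    return _rlm_style_features(mat, GLRLM_NAMES, 4.0 * qwin.size)


# ---------------------------------------------------------------------------
# GLSZM
# ---------------------------------------------------------------------------

def glszm_matrix(qwin: np.ndarray, n_levels: int) -> np.ndarray:
    """Size-zone count matrix from 8-connected constant-level components."""
    labels = cc_label(qwin, connectivity=2)
    n_zones = labels.max()
    sizes = np.bincount(labels.ravel())[1:]
    flat_labels = labels.ravel()
    flat_levels = qwin.ravel()
    zone_level = np.zeros(n_zones + 1, dtype=np.int64)
    zone_level[flat_labels] = flat_levels
    mat = np.zeros((n_levels, int(sizes.max())), dtype=np.float64)
    np.add.at(mat, (zone_level[1:] - 1, sizes - 1), 1.0)
    return mat


def glszm_features(qwin: np.ndarray, n_levels: int = N_GRAY_LEVELS) -> dict[str, float]:
    """Thirteen size-zone statistics; zone percentage = zones / pixels."""
    mat = glszm_matrix(qwin, n_levels)
    return _rlm_style_features(mat, GLSZM_NAMES, float(qwin.size))


# ---------------------------------------------------------------------------
# NGTDM
# ---------------------------------------------------------------------------

_NEIGHBOR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=np.float64)


def ngtdm_table(qwin: np.ndarray, n_levels: int) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-level occurrence counts n_i and gray-tone difference sums s_i,
    computed over interior pixels (full 8-neighborhood available)."""
    x = qwin.astype(np.float64)
    nb_mean = convolve(x, _NEIGHBOR_KERNEL, mode="constant")[1:-1, 1:-1] / 8.0
    interior = qwin[1:-1, 1:-1]
    diffs = np.abs(interior - nb_mean)
    n_i = np.bincount(interior.ravel() - 1, minlength=n_levels).astype(float)
    s_i = np.bincount(interior.ravel() - 1, weights=diffs.ravel(),
                      minlength=n_levels)
    return n_i, s_i, interior.size


def ngtdm_features(qwin: np.ndarray, n_levels: int = N_GRAY_LEVELS) -> dict[str, float]:
    """Five neighborhood gray-tone difference statistics (Amadasun-style),
    with a small epsilon guarding the Coarseness and Strength denominators."""
    n_i, s_i, n_tot = ngtdm_table(qwin, n_levels)
    p_i = n_i / n_tot
    present = np.flatnonzero(p_i > 0)
    lv = present + 1.0
    pg = p_i[present]
    sg = s_i[present]
    ng = present.size

    coarseness = 1.0 / (EPS_NGTDM + float((pg * sg).sum()))
    if ng > 1:
        dl = lv[:, None] - lv[None, :]
        pp = pg[:, None] * pg[None, :]
        contrast = (float((pp * dl**2).sum()) / (ng * (ng - 1))) \
            * (float(sg.sum()) / n_tot)
        busy_den = float(np.abs(lv[:, None] * pg[:, None]
                                - lv[None, :] * pg[None, :]).sum())
        busyness = float((pg * sg).sum()) / busy_den if busy_den > 0 else 0.0
        psum = pg[:, None] + pg[None, :]
        ps_term = (pg * sg)[:, None] + (pg * sg)[None, :]
        complexity = float((np.abs(dl) * ps_term / (n_tot * psum)).sum())
        strength = float((psum * dl**2).sum()) / (EPS_NGTDM + float(sg.sum()))
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "Coarseness": coarseness,
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }


# ---------------------------------------------------------------------------
# Full vector and moving-window maps
# ---------------------------------------------------------------------------

def texture_vector(
    window: np.ndarray, n_levels: int = N_GRAY_LEVELS
) -> dict[str, float]:
    """All 43 named texture features of one raw-intensity window."""
    qwin = quantize(window, n_levels)
    out: dict[str, float] = {}
    for name, v in global_features(window).items():
        out[f"Global_{name}"] = v
    for name, v in glcm_features(qwin, n_levels).items():
        out[f"GLCM_{name}"] = v
    for name, v in glrlm_features(qwin, n_levels).items():
        out[f"GLRLM_{name}"] = v
    for name, v in glszm_features(qwin, n_levels).items():
        out[f"GLSZM_{name}"] = v
    for name, v in ngtdm_features(qwin, n_levels).items():
        out[f"NGTDM_{name}"] = v
    return out


def _nn_upsample_index(side: int, window: int, stride: int, n_grid: int) -> np.ndarray:
    """Map each ROI pixel to the nearest moving-window grid cell."""
    centers_off = window // 2
    idx = np.round((np.arange(side) - centers_off) / stride).astype(int)
    return np.clip(idx, 0, n_grid - 1)


def texture_map(
    frame: np.ndarray,
    roi,
    window: int = 21,
    stride: int = 3,
    n_levels: int = N_GRAY_LEVELS,
    upsample: bool = True,
) -> dict[str, np.ndarray]:
    """Slide the texture window over the ROI and return 43 parametric maps.

    The stride grid has ``floor((S - window) / stride) + 1`` positions per
    axis for ROI side S.  With ``upsample=True`` (default) each map is
    nearest-neighbor upsampled back to the ROI pixel grid so all
    parametric maps share one support for the summary statistics.
    """
    if window % 2 == 0:
        raise ValueError("window size must be odd")
    box = getattr(roi, "box", roi)
    r0, r1, c0, c1 = box
    crop = np.asarray(frame, dtype=np.float64)[r0:r1, c0:c1]
    h, w = crop.shape
    if h < window or w < window:
        raise ValueError(f"ROI {h}x{w} smaller than the {window}x{window} window")
    nr = (h - window) // stride + 1
    nc = (w - window) // stride + 1
    grids = {name: np.empty((nr, nc)) for name in TEXTURE_FEATURE_NAMES}
    for gi in range(nr):
        for gj in range(nc):
            win = crop[gi * stride:gi * stride + window,
                       gj * stride:gj * stride + window]
            for name, v in texture_vector(win, n_levels).items():
                grids[name][gi, gj] = v
    if not upsample:
        return grids
    ri = _nn_upsample_index(h, window, stride, nr)
    ci = _nn_upsample_index(w, window, stride, nc)
    return {name: g[np.ix_(ri, ci)] for name, g in grids.items()}


def texture_at_fiducials(
    ceus: np.ndarray,
    roi,
    fiducials,
    window: int = 21,
    stride: int = 3,
    n_levels: int = N_GRAY_LEVELS,
) -> dict[str, np.ndarray]:
    """Texture maps at the wash-in, peak and wash-out frames (3 x 43 = 129
    maps), named ``WiIm_/PkIm_/WoIm_<Family>_<Feature>``."""
    out: dict[str, np.ndarray] = {}
    cache: dict[int, dict[str, np.ndarray]] = {}
    for stage, prefix in FIDUCIAL_PREFIXES.items():
        frame_idx = int(getattr(fiducials, stage))
        if frame_idx not in cache:
            cache[frame_idx] = texture_map(
                ceus[frame_idx], roi, window, stride, n_levels
            )
        for name, m in cache[frame_idx].items():
            out[f"{prefix}_{name}"] = m
    return out
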