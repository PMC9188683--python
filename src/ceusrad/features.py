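"""Condensing parametric maps into a lesion feature table and filtering it.

Each lesion contributes 137 parametric maps (8 spatiotemporal + 3 x 43
texture).  Because the map-value distributions over the ROI are generally
not normal, each map is condensed into median, interquartile range and
skewness — 411 scalar features per lesion, named
``<MapName>_<median|iqr|skew>``.

Two filtering stages reduce redundancy before modeling:

1. correlation pruning: of every feature pair with |Pearson r| > 0.9 the
   member with the weaker (point-biserial) correlation with the
   benign/malignant label is dropped;
2. adaptive univariate selection: within each feature set
   (spatiotemporal, WiIm, PkIm, WoIm) the number of features to keep is
   set to the number of principal components explaining 95% of the set's
   variance, and the top features by mutual information with the label
   are retained.

Filtering can be applied once on the full table (paper mode, the
published workflow) or refit inside every training fold (leak-free
mode); paper mode is the default and logs a caveat.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.feature_selection import mutual_info_classif

from .perfusion import PERFUSION_MAP_NAMES
from .similarity import SIMILARITY_MAP_NAMES
from .texture import FIDUCIAL_PREFIXES, TEXTURE_FEATURE_NAMES

logger = logging.getLogger(__name__)

SUMMARY_SUFFIXES = ("median", "iqr", "skew")
SPATIOTEMPORAL_MAP_NAMES = tuple(PERFUSION_MAP_NAMES) + tuple(SIMILARITY_MAP_NAMES)
ALL_MAP_NAMES = tuple(SPATIOTEMPORAL_MAP_NAMES) + tuple(
    f"{prefix}_{name}"
    for prefix in FIDUCIAL_PREFIXES.values()
    for name in TEXTURE_FEATURE_NAMES
)
ALL_FEATURE_NAMES = tuple(
    f"{m}_{s}" for m in ALL_MAP_NAMES for s in SUMMARY_SUFFIXES
)
assert len(ALL_MAP_NAMES) == 137 and len(ALL_FEATURE_NAMES) == 411


def feature_set_of(column: str) -> str:
    """Feature-set provenance of a column: spatiotemporal, WiIm, PkIm or WoIm."""
    prefix = column.split("_", 1)[0]
    return prefix if prefix in FIDUCIAL_PREFIXES.values() else "spatiotemporal"


def summarize_map(
    map2d: np.ndarray, mask: np.ndarray | None = None, min_valid: int = 8
) -> tuple[float, float, float]:
    """(median, IQR, skewness) of a map's non-missing values.

    IQR uses linear-interpolation quantiles; skewness is the moment
    estimator with skew(constant) = 0.  Fewer than ``min_valid`` valid
    pixels yields all-NaN (the feature goes missing for that lesion).
    """
    v = np.asarray(map2d, dtype=np.float64)
    if mask is not None:
        v = v[np.asarray(mask, bool)]
    v = v[np.isfinite(v)]
    if v.size < min_valid:
        return float("nan"), float("nan"), float("nan")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    mu = v.mean()
    m2 = np.mean((v - mu) ** 2)
    skew = float(np.mean((v - mu) ** 3) / m2**1.5) if m2 > 0 else 0.0
    return float(med), float(q3 - q1), skew


def build_feature_table(
    map_stacks: list[dict[str, np.ndarray]],
    labels: list[str] | None = None,
    min_valid: int = 8,
) -> pd.DataFrame:
    """Summarize per-lesion map stacks into the 411-column feature table.

    Every stack must contain the full set of 137 named maps; column order
    is deterministic (spatiotemporal, then WiIm/PkIm/WoIm texture, each
    map contributing median/iqr/skew).  When *labels* is given a
    ``label`` column is appended.
    """
    rows = []
    for i, stack in enumerate(map_stacks):
        missing = set(ALL_MAP_NAMES) - set(stack)
        extra = set(stack) - set(ALL_MAP_NAMES)
        if missing or extra:
            raise ValueError(
                f"lesion {i}: inconsistent map names "
                f"(missing {sorted(missing)[:3]}..., extra {sorted(extra)[:3]}...)"
            )
        row = {}
        for m in ALL_MAP_NAMES:
            med, iqr, skew = summarize_map(stack[m], min_valid=min_valid)
            row[f"{m}_median"] = med
            row[f"{m}_iqr"] = iqr
            row[f"{m}_skew"] = skew
        rows.append(row)
    table = pd.DataFrame(rows, columns=list(ALL_FEATURE_NAMES))
    if labels is not None:
        if len(labels) != len(map_stacks):
            raise ValueError("one label per lesion required")
        table["label"] = list(labels)
    return table


def split_features_labels(table: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Split a table with a ``label`` column into (X, y) with y = 1 for
    malignant (the positive class)."""
    if "label" not in table.columns:
        raise ValueError("table has no 'label' column")
    X = table.drop(columns="label")
    y = (table["label"].to_numpy() == "malignant").astype(int)
    return X, y


def impute_median(X: pd.DataFrame, reference: pd.DataFrame | None = None) -> pd.DataFrame:
    """Fill missing values with per-column medians (of *reference* when
    given, e.g. training-fold medians applied to a test fold)."""
    med = (reference if reference is not None else X).median()
    return X.fillna(med).fillna(0.0)


def correlation_prune(
    X: pd.DataFrame, y: np.ndarray, threshold: float = 0.9
) -> pd.DataFrame:
    """Drop the weaker member of every highly correlated feature pair.

    Pairs with |Pearson r| > threshold are visited in descending |r|; for
    each pair still fully present, the member with the lower absolute
    point-biserial correlation with the label is dropped (ties drop the
    later column, so the result is deterministic in column order).
    """
    cols = list(X.columns)
    vals = X.to_numpy(dtype=float)
    n = len(cols)
    if n < 2:
        return X.copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(vals, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    yc = np.asarray(y, dtype=float)
    yc = yc - yc.mean()
    dev = vals - vals.mean(axis=0)
    denom = np.linalg.norm(dev, axis=0) * np.linalg.norm(yc)
    with np.errstate(invalid="ignore", divide="ignore"):
        label_corr = np.abs(dev.T @ yc) / denom
    label_corr = np.nan_to_num(label_corr, nan=0.0)

    iu, ju = np.triu_indices(n, k=1)
    strong = np.abs(corr[iu, ju]) > threshold
    order = np.argsort(-np.abs(corr[iu, ju][strong]), kind="stable")
    pairs = list(zip(iu[strong][order], ju[strong][order]))

    alive = np.ones(n, dtype=bool)
    for i, j in pairs:
        if alive[i] and alive[j]:
            drop = j if label_corr[i] >= label_corr[j] else i
            alive[drop] = False
    kept = [c for c, a in zip(cols, alive) if a]
    return X[kept]


def adaptive_select(
    X: pd.DataFrame, y: np.ndarray, seed: int = 0, variance_target: float = 0.95
) -> pd.DataFrame:
    """Per-set univariate selection with a PCA-chosen feature budget.

    For each feature set: standardize, find the smallest number N of
    principal components whose cumulative explained variance reaches the
    target, and keep the N features with the highest mutual information
    with the label (fixed-seed nearest-neighbor estimator).
    """
    kept: list[str] = []
    sets: dict[str, list[str]] = {}
    for c in X.columns:
        sets.setdefault(feature_set_of(c), []).append(c)
    for set_name in ("spatiotemporal", "WiIm", "PkIm", "WoIm"):
        cols = sets.get(set_name, [])
        if not cols:
            logger.warning("feature set %s is empty after pruning", set_name)
            continue
        sub = X[cols].to_numpy(dtype=float)
        sd = sub.std(axis=0)
        std = (sub - sub.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
        n_comp = min(len(cols), len(X) - 1) if len(X) > 1 else 1
        if n_comp < 1 or len(cols) == 1:
            n_keep = 1
        else:
            pca = PCA(n_components=n_comp)
            pca.fit(std)
            cum = np.cumsum(pca.explained_variance_ratio_)
            n_keep = int(np.searchsorted(cum, variance_target) + 1)
            n_keep = min(n_keep, len(cols))
        mi = mutual_info_classif(sub, y, random_state=seed)
        top = np.argsort(-mi, kind="stable")[:n_keep]
        kept.extend(cols[i] for i in sorted(top))
    return X[kept]


def filter_features(
    X: pd.DataFrame,
    y: np.ndarray,
    threshold: float = 0.9,
    seed: int = 0,
    variance_target: float = 0.95,
) -> pd.DataFrame:
    """Full filtering pipeline: median imputation, correlation pruning,
    then adaptive per-set univariate selection."""
    Xi = impute_median(X)
    Xp = correlation_prune(Xi, y, threshold)
    return adaptive_select(Xp, y, seed=seed, variance_target=variance_target)
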