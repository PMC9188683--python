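"""Classifier bench: repeated nested cross-validation with imbalance
resampling, backward feature selection, soft voting, permutation
importance and a variance-corrected resampled t-test.

The evaluation protocol targets small, imbalanced lesion cohorts:

* stratified 4-fold outer CV, repeated over 5 random splits, giving 20
  train/test evaluations per model;
* on each training fold the benign (minority) class is SMOTE-oversampled
  to half the malignant count and the malignant class is randomly
  undersampled to 0.7 of its original size — test folds are never
  resampled, so no metric is ever computed on synthetic rows;
* hyperparameters are grid-searched (inner 4-fold CV on balanced
  accuracy) per fold, the most frequent winners across all folds are
  fixed, and the whole procedure is re-run with them to produce the
  reported metrics;
* backward sequential feature selection optionally reduces the feature
  count per model inside each training fold;
* model comparison uses the resampled t-test on the 20 per-fold
  balanced-accuracy differences, with the Nadeau-Bengio variance
  correction (test/train size ratio) accounting for the overlap of
  training sets across repetitions.

Balanced accuracy (bACC) is the headline metric throughout, with a
malignant lesion regarded as positive.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import SequentialFeatureSelector
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier, NearestNeighbors
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

METRIC_NAMES = ("ACC", "bACC", "SENS", "SPEC", "AUC")


class ResamplingError(ValueError):
    """Training-fold resampling cannot be performed."""


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def balanced_accuracy(tp: int, fn: int, tn: int, fp: int) -> float:
    """0.5 * (sensitivity + specificity); malignant is the positive class."""
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("balanced accuracy undefined with an empty class")
    return 0.5 * (tp / (tp + fn) + tn / (tn + fp))


def classification_metrics(
    y_true: np.ndarray, y_pred: np.ndarray, y_prob: np.ndarray | None = None
) -> dict[str, float]:
    """ACC, bACC, SENS, SPEC and AUC (from the malignant-class probability)."""
    y_true = np.asarray(y_true, int)
    y_pred = np.asarray(y_pred, int)
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    auc = float("nan")
    if y_prob is not None and len(np.unique(y_true)) == 2:
        auc = float(roc_auc_score(y_true, y_prob))
    return {
        "ACC": (tp + tn) / y_true.size,
        "bACC": 0.5 * (sens + spec),
        "SENS": sens,
        "SPEC": spec,
        "AUC": auc,
    }


# ---------------------------------------------------------------------------
# Resampling (SMOTE + random undersampling)
# ---------------------------------------------------------------------------

def smote_oversample(
    X_min: np.ndarray, n_new: int, k_neighbors: int, rng: np.random.Generator
) -> np.ndarray:
    """Synthetic minority samples by interpolation toward k-NN neighbors."""
    n_min = len(X_min)
    if n_min < k_neighbors + 1:
        raise ResamplingError(
            f"SMOTE needs at least {k_neighbors + 1} minority samples, "
            f"got {n_min}"
        )
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(X_min)
    _, idx = nn.kneighbors(X_min)
    idx = idx[:, 1:]                              # drop self
    base = rng.integers(0, n_min, size=n_new)
    nb = idx[base, rng.integers(0, k_neighbors, size=n_new)]
    gap = rng.random((n_new, 1))
    return X_min[base] + gap * (X_min[nb] - X_min[base])


def resample_training(
    X: np.ndarray,
    y: np.ndarray,
    smote_ratio: float = 0.5,
    undersample_ratio: float = 0.7,
    seed: int = 0,
    k_neighbors: int = 5,
) -> tuple[np.ndarray, np.ndarray]:
    """Rebalance a training fold: SMOTE the minority class up to
    ``smote_ratio`` of the majority count, then randomly undersample the
    majority class to ``undersample_ratio`` of its original size.

    Deterministic under *seed*; never applied to test data.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, int)
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ResamplingError("both classes must be present")
    if counts[0] == counts[1]:
        minority, majority = classes[0], classes[1]   # tie: benign is minority
    else:
        minority = classes[np.argmin(counts)]
        majority = classes[np.argmax(counts)]
    n_maj = int((y == majority).sum())
    n_min = int((y == minority).sum())

    X_min = X[y == minority]
    X_maj = X[y == majority]
    target_min = int(np.floor(smote_ratio * n_maj))
    if n_min < target_min:
        X_syn = smote_oversample(X_min, target_min - n_min, k_neighbors, rng)
        X_min = np.vstack([X_min, X_syn])
    target_maj = int(np.floor(undersample_ratio * n_maj))
    if target_maj < n_maj:
        keep = rng.choice(n_maj, size=target_maj, replace=False)
        X_maj = X_maj[keep]
    X_out = np.vstack([X_min, X_maj])
    y_out = np.concatenate([
        np.full(len(X_min), minority), np.full(len(X_maj), majority)
    ])
    perm = rng.permutation(len(y_out))
    return X_out[perm], y_out[perm]


# ---------------------------------------------------------------------------
# Models
# ---------------------------------------------------------------------------

def default_models(seed: int = 0) -> dict[str, tuple[Pipeline, dict]]:
    """The four base classifiers with their hyperparameter grids.

    Each grid contains the optimum reported for liver-lesion cohorts
    (LR C = 0.5; SVM rbf, C = 50, gamma = 1e-3; RF min-leaf 1,
    max-features 0.2; kNN k = 5).  Margin-based SVM probabilities come
    from Platt scaling.  All features are standardized inside the
    pipeline so scale-sensitive models behave.
    """
    def pipe(clf):
        return Pipeline([("scale", StandardScaler()), ("clf", clf)])

    return {
        "LR": (
            pipe(LogisticRegression(max_iter=5000, random_state=seed)),
            {"clf__C": [0.1, 0.5, 1.0, 5.0, 10.0]},
        ),
        "SVM": (
            pipe(CalibratedClassifierCV(
                SVC(random_state=seed), method="sigmoid", cv=3, ensemble=False,
            )),
            {
                "clf__estimator__kernel": ["rbf", "linear"],
                "clf__estimator__C": [1.0, 10.0, 50.0, 100.0],
                "clf__estimator__gamma": [1e-4, 1e-3, 1e-2],
            },
        ),
        "RF": (
            pipe(RandomForestClassifier(n_estimators=100, random_state=seed)),
            {
                "clf__min_samples_leaf": [1, 2, 5],
                "clf__max_features": [0.2, 0.5, "sqrt"],
            },
        ),
        "kNN": (
            pipe(KNeighborsClassifier()),
            {"clf__n_neighbors": [3, 5, 7, 9]},
        ),
    }


class SoftVotingClassifier:
    """Equal-weight soft voting over fitted base models.

    Each base model may use its own feature subset (column indices).
    Prediction is the argmax of the averaged malignant-class probability;
    exact ties go to malignant.
    """

    def __init__(self, fitted: Sequence[tuple[object, np.ndarray]]):
        for model, _ in fitted:
            if not hasattr(model, "predict_proba"):
                raise ValueError(
                    "soft voting requires probability outputs; calibrate "
                    "margin-based models first"
                )
        self.fitted = list(fitted)
        self.classes_ = np.array([0, 1])

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, float)
        probs = [m.predict_proba(X[:, cols]) for m, cols in self.fitted]
        return np.mean(probs, axis=0)

    def predict(self, X: np.ndarray) -> np.ndarray:
        p = self.predict_proba(X)[:, 1]
        return (p >= 0.5).astype(int)          # ties -> malignant


# ---------------------------------------------------------------------------
# Backward sequential feature selection
# ---------------------------------------------------------------------------

def backward_sfs(
    model,
    X: np.ndarray,
    y: np.ndarray,
    n_target: int,
    cv: int = 4,
    seed: int = 0,
) -> np.ndarray:
    """Greedy backward elimination to ``n_target`` features, scored by
    cross-validated balanced accuracy on the training data.

    Returns sorted column indices.  ``n_target >= n_features`` is the
    identity.  Ties during elimination drop the lowest-index candidate
    column (scikit-learn's deterministic behavior with a seeded CV).
    """
    n_feat = X.shape[1]
    if n_target > n_feat:
        raise ValueError("n_target exceeds the number of features")
    if n_target == n_feat:
        return np.arange(n_feat)
    splitter = StratifiedKFold(cv, shuffle=True, random_state=seed)
    sfs = SequentialFeatureSelector(
        clone(model), n_features_to_select=n_target, direction="backward",
        scoring="balanced_accuracy", cv=splitter, n_jobs=1,
    )
    sfs.fit(X, y)
    return np.flatnonzero(sfs.get_support())


# ---------------------------------------------------------------------------
# Permutation feature importance
# ---------------------------------------------------------------------------

def permutation_importance(
    model,
    X_test: np.ndarray,
    y_test: np.ndarray,
    n_perm: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """Mean balanced-accuracy drop over ``n_perm`` shuffles per feature."""
    rng = np.random.default_rng(seed)
    X_test = np.asarray(X_test, float)
    base = classification_metrics(y_test, model.predict(X_test))["bACC"]
    drops = np.zeros(X_test.shape[1])
    for jf in range(X_test.shape[1]):
        for _ in range(n_perm):
            Xp = X_test.copy()
            Xp[:, jf] = rng.permutation(Xp[:, jf])
            perm = classification_metrics(y_test, model.predict(Xp))["bACC"]
            drops[jf] += base - perm
    return drops / n_perm


# ---------------------------------------------------------------------------
# Corrected resampled t-test
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class TTestResult:
    t: float
    df: int
    p_value: float
    reject: bool
    degenerate: bool = False


def corrected_t_test(
    p_a: np.ndarray,
    p_b: np.ndarray,
    n_train: int,
    n_test: int,
    alpha: float = 0.05,
    correction_ratio: float | None = None,
) -> TTestResult:
    """Resampled t-test on per-repetition metric differences with the
    Nadeau-Bengio variance correction.

    t = mean(p) / sqrt(s^2 * (1/n + rho)) with s^2 the sample variance of
    the differences and rho = n_test / n_train by default (the standard
    test/train overlap correction; pass ``correction_ratio`` to override,
    e.g. 0 to recover the uncorrected resampled t-test).  The null is
    rejected at level alpha when |t| exceeds the two-sided Student
    quantile with n - 1 degrees of freedom.  Zero variance with a nonzero
    mean difference is flagged degenerate (t = +/-inf).
    """
    p = np.asarray(p_a, float) - np.asarray(p_b, float)
    n = p.size
    if n < 2:
        raise ValueError("need at least 2 repetitions")
    rho = n_test / n_train if correction_ratio is None else correction_ratio
    mean = float(p.mean())
    s2 = float(p.var(ddof=1))
    df = n - 1
    if np.ptp(p) == 0 or s2 == 0:       # constant differences: no spread
        if mean == 0:
            return TTestResult(0.0, df, 1.0, False)
        return TTestResult(float(np.sign(mean)) * float("inf"), df, 0.0,
                           True, degenerate=True)
    t = mean / np.sqrt(s2 * (1.0 / n + rho))
    p_value = 2.0 * float(stats.t.sf(abs(t), df))
    crit = float(stats.t.ppf(1.0 - alpha / 2.0, df))
    return TTestResult(float(t), df, p_value, abs(t) > crit)


# ---------------------------------------------------------------------------
# Nested cross-validation
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class CVConfig:
    """Protocol knobs for the repeated nested CV bench."""

    outer_folds: int = 4
    repeats: int = 5
    inner_folds: int = 4
    smote_ratio: float = 0.5
    undersample_ratio: float = 0.7
    smote_neighbors: int = 5
    sfs_n_features: int | None = None      # None = keep all features
    sfs_cv: int = 3
    n_perm: int = 10
    seed: int = 0

    @property
    def n_evaluations(self) -> int:
        return self.outer_folds * self.repeats


@dataclasses.dataclass
class CVReport:
    """Aggregated bench output over repeats x outer folds evaluations."""

    metrics: pd.DataFrame            # (model, metric) -> mean
    metrics_sd: pd.DataFrame
    per_fold: pd.DataFrame           # long format: repeat, fold, model, metrics
    best_params: dict[str, dict]
    selection_frequency: pd.DataFrame   # model x feature -> fraction of folds
    pfi: pd.DataFrame                # model x feature -> normalized mean PFI
    ttests: pd.DataFrame             # pairwise corrected t on bACC
    feature_names: list[str]


def _outer_splits(y: np.ndarray, config: CVConfig):
    for rep in range(config.repeats):
        skf = StratifiedKFold(config.outer_folds, shuffle=True,
                              random_state=config.seed + rep)
        for fold, (tr, te) in enumerate(skf.split(np.zeros_like(y), y)):
            yield rep, fold, tr, te


def _mode_params(param_list: list[dict]) -> dict:
    """Most frequent parameter dict (ties broken by first occurrence)."""
    keys = [tuple(sorted(p.items())) for p in param_list]
    winner = Counter(keys).most_common(1)[0][0]
    return dict(winner)


def nested_cv(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    config: CVConfig | None = None,
    models: dict[str, tuple[Pipeline, dict]] | None = None,
) -> CVReport:
    """Run the full repeated nested CV bench.

    Stage 1 grid-searches each model's hyperparameters per outer training
    fold (inner stratified k-fold on balanced accuracy, after
    resampling); the most frequent winners are fixed.  Stage 2 re-runs
    every fold with fixed hyperparameters: resample the training fold,
    optionally reduce features by backward SFS, fit, and evaluate on the
    untouched test fold.  A soft-voting ensemble of all base models and a
    naive all-malignant baseline are reported alongside.
    """
    if config is None:
        config = CVConfig()
    if models is None:
        models = default_models(config.seed)
    feature_names = (list(X.columns) if isinstance(X, pd.DataFrame)
                     else [f"f{i}" for i in range(np.asarray(X).shape[1])])
    Xv = np.asarray(X, dtype=float)
    y = np.asarray(y, int)

    # ---- stage 1: per-fold grid search, then majority vote on params ----
    fold_params: dict[str, list[dict]] = {m: [] for m in models}
    for rep, fold, tr, te in _outer_splits(y, config):
        fold_seed = config.seed + 1000 * rep + fold
        Xr, yr = resample_training(
            Xv[tr], y[tr], config.smote_ratio, config.undersample_ratio,
            seed=fold_seed, k_neighbors=config.smote_neighbors,
        )
        inner = StratifiedKFold(config.inner_folds, shuffle=True,
                                random_state=fold_seed)
        for name, (model, grid) in models.items():
            gs = GridSearchCV(clone(model), grid, cv=inner,
                              scoring="balanced_accuracy", n_jobs=1)
            gs.fit(Xr, yr)
            fold_params[name].append(gs.best_params_)
    best_params = {m: _mode_params(ps) for m, ps in fold_params.items()}

    # ---- stage 2: fixed hyperparameters, SFS, final evaluation ----------
    rows = []
    n_feat = Xv.shape[1]
    sel_counts = {m: np.zeros(n_feat) for m in models}
    pfi_sums = {m: np.zeros(n_feat) for m in list(models) + ["sVC"]}
    sel_counts["sVC"] = np.zeros(n_feat)
    n_folds_total = 0
    for rep, fold, tr, te in _outer_splits(y, config):
        fold_seed = config.seed + 1000 * rep + fold
        X_test_before = Xv[te].copy()
        Xr, yr = resample_training(
            Xv[tr], y[tr], config.smote_ratio, config.undersample_ratio,
            seed=fold_seed, k_neighbors=config.smote_neighbors,
        )
        fitted = []
        for name, (model, _) in models.items():
            est = clone(model).set_params(**best_params[name])
            if config.sfs_n_features and config.sfs_n_features < n_feat:
                cols = backward_sfs(est, Xr, yr, config.sfs_n_features,
                                    cv=config.sfs_cv, seed=fold_seed)
            else:
                cols = np.arange(n_feat)
            est.fit(Xr[:, cols], yr)
            fitted.append((name, est, cols))
            sel_counts[name][cols] += 1
            prob = est.predict_proba(Xv[te][:, cols])[:, 1]
            pred = est.predict(Xv[te][:, cols])
            m = classification_metrics(y[te], pred, prob)
            rows.append({"repeat": rep, "fold": fold, "model": name, **m})
            pfi = permutation_importance(est, Xv[te][:, cols], y[te],
                                         config.n_perm, seed=fold_seed)
            pfi_sums[name][cols] += pfi

        svc = SoftVotingClassifier([(est, cols) for _, est, cols in fitted])
        prob = svc.predict_proba(Xv[te])[:, 1]
        pred = svc.predict(Xv[te])
        m = classification_metrics(y[te], pred, prob)
        rows.append({"repeat": rep, "fold": fold, "model": "sVC", **m})
        used = np.unique(np.concatenate([cols for _, _, cols in fitted]))
        sel_counts["sVC"][used] += 1
        pfi = permutation_importance(svc, Xv[te], y[te], config.n_perm,
                                     seed=fold_seed)
        pfi_sums["sVC"] += pfi

        naive = classification_metrics(
            y[te], np.ones_like(y[te]), np.full(len(te), 0.5)
        )
        naive["AUC"] = float("nan")
        rows.append({"repeat": rep, "fold": fold, "model": "Naive", **naive})

        # leakage guard: test rows must be untouched by resampling
        assert np.array_equal(X_test_before, Xv[te])
        n_folds_total += 1

    per_fold = pd.DataFrame(rows)
    model_order = list(models) + ["sVC", "Naive"]
    metrics = (per_fold.groupby("model")[list(METRIC_NAMES)].mean()
               .reindex(model_order))
    metrics_sd = (per_fold.groupby("model")[list(METRIC_NAMES)].std(ddof=1)
                  .reindex(model_order))

    sel_freq = pd.DataFrame(
        {m: sel_counts[m] / n_folds_total for m in sel_counts},
        index=feature_names,
    ).T
    pfi_mean = {m: pfi_sums[m] / n_folds_total for m in pfi_sums}
    pfi_norm = {}
    for m, v in pfi_mean.items():
        top = np.abs(v).max()
        pfi_norm[m] = v / top if top > 0 else v
    pfi_df = pd.DataFrame(pfi_norm, index=feature_names).T

    # pairwise corrected t-tests on bACC
    n_test = len(y) // config.outer_folds
    n_train = len(y) - n_test
    compared = list(models) + ["sVC"]
    tt_rows = []
    series = {
        m: per_fold[per_fold["model"] == m].sort_values(["repeat", "fold"])
        ["bACC"].to_numpy()
        for m in compared
    }
    for i, a in enumerate(compared):
        for b in compared[i + 1:]:
            res = corrected_t_test(series[a], series[b], n_train, n_test)
            tt_rows.append({
                "model_a": a, "model_b": b, "t": res.t, "df": res.df,
                "p_value": res.p_value, "reject": res.reject,
                "degenerate": res.degenerate,
            })
    ttests = pd.DataFrame(tt_rows)

    return CVReport(
        metrics=metrics, metrics_sd=metrics_sd, per_fold=per_fold,
        best_params=best_params, selection_frequency=sel_freq,
        pfi=pfi_df, ttests=ttests, feature_names=feature_names,
    )


def feature_count_sweep(
    X: pd.DataFrame,
    y: np.ndarray,
    n_values: Sequence[int],
    config: CVConfig | None = None,
    models: dict[str, tuple[Pipeline, dict]] | None = None,
) -> pd.DataFrame:
    """Re-run the bench for several SFS feature counts; returns the mean
    and sd of bACC per model per count (the feature-count optimization
    curve)."""
    if config is None:
        config = CVConfig()
    out = []
    for n in n_values:
        cfg = dataclasses.replace(config, sfs_n_features=int(n))
        report = nested_cv(X, y, cfg, models)
        for model in report.metrics.index:
            if model == "Naive":
                continue
            out.append({
                "n_features": int(n), "model": model,
                "bACC_mean": report.metrics.loc[model, "bACC"],
                "bACC_sd": report.metrics_sd.loc[model, "bACC"],
            })
    return pd.DataFrame(out)
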