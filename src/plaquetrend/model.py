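"""ΔPAV regression with repeated stratified group cross-validation.

The protocol: folds are formed at the pullback level (every ROI of a
pullback lands on one side only) with stratification on the sign of the
pullback-level ΔPAV; 5 folds × 20 repeats give 100 train/test partitions.
Per model: one-hot expansion of the artery label, mean/std standardization
fitted on the training side, optional k-best mutual-information feature
selection against the binary progression/regression label, then an XGBoost
regressor (256 trees, depth 12, squared-error loss).  Classification is
obtained by thresholding the regression output at 0.

Reported per model: MAE, MSE, Pearson r on the raw regression; ACC, MCC and
per-class/average F1 on the thresholded classes.  Post hoc, each ROI's
correct-classification rate (CCR) over its 20 test appearances and each
pullback's length-weighted correctly-classified fraction (CCL) are
computed, and SHAP attributions are summarized per feature as the selection
ratio times the summed mean |SHAP| over the models that selected it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.exceptions import UndefinedMetricWarning
from sklearn.feature_selection import mutual_info_classif
from sklearn.metrics import accuracy_score, f1_score, matthews_corrcoef
from sklearn.model_selection import StratifiedKFold

from .errors import ConfigError, DataError
from .treeshap import TreeEnsemble, shap_values

__all__ = [
    "ExperimentConfig",
    "FoldAssignment",
    "ExperimentResult",
    "make_folds",
    "one_hot",
    "standardize",
    "select_k_best",
    "train_regressor",
    "evaluate",
    "run_experiment",
    "shap_report",
    "posthoc_indices",
    "metrics_table",
]

METRIC_NAMES = ("ACC", "MCC", "F1a", "F1neg", "F1pos", "MAE", "MSE", "r")


@dataclass(frozen=True)
class ExperimentConfig:
    """Fixed protocol configuration for one experiment."""

    seed: int = 0
    n_folds: int = 5
    n_repeats: int = 20
    feature_set: str = "Sd"
    k_select: int | None = None  # None, 8 or 32
    n_estimators: int = 256
    max_depth: int = 12
    group_by: str = "pullback"  # or "patient"
    compute_shap: bool = True

    def __post_init__(self) -> None:
        if self.n_folds < 2 or self.n_repeats < 1 or self.n_estimators < 1:
            raise ConfigError("n_folds, n_repeats and n_estimators must be positive")
        if self.k_select is not None and self.k_select <= 0:
            raise ConfigError("k_select must be positive when given")
        if self.group_by not in ("pullback", "patient"):
            raise ConfigError("group_by must be 'pullback' or 'patient'")


@dataclass(frozen=True)
class FoldAssignment:
    repeat_id: int
    fold_id: int
    train_groups: tuple
    test_groups: tuple


@dataclass
class ModelRecord:
    """Everything retained from one fitted fold model."""

    repeat_id: int
    fold_id: int
    test_index: np.ndarray  # ROI row positions in the dataset
    y_true: np.ndarray
    y_pred: np.ndarray
    metrics: dict
    selected: np.ndarray  # selected column names
    mean_abs_shap: dict | None  # per selected feature
    shap_base: float | None = None


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    feature_columns: list
    models: list = field(default_factory=list)

    @property
    def n_models(self) -> int:
        return len(self.models)


def make_folds(groups, signs, config: ExperimentConfig) -> list:
    """Pullback-level repeated stratified k-fold assignments.

    ``groups`` are the pullback (or patient) identifiers and ``signs`` their
    progression/regression class (sign of the pullback-level ΔPAV).
    Deterministic given the config seed.
    """
    groups = np.asarray(groups)
    signs = np.asarray(signs)
    if groups.size != signs.size or groups.size == 0:
        raise DataError("groups and signs must be equal-length and non-empty")
    if np.unique(groups).size != groups.size:
        raise DataError("group labels must be unique at the fold level")
    if groups.size < config.n_folds:
        raise ConfigError(
            f"{groups.size} groups cannot be split into {config.n_folds} folds"
        )
    repeat_seeds = np.random.SeedSequence(config.seed).generate_state(config.n_repeats)
    folds = []
    for r in range(config.n_repeats):
        skf = StratifiedKFold(
            n_splits=config.n_folds,
            shuffle=True,
            random_state=int(repeat_seeds[r] % (2**31)),
        )
        for f, (train_idx, test_idx) in enumerate(skf.split(groups, signs)):
            folds.append(
                FoldAssignment(r, f, tuple(groups[train_idx]), tuple(groups[test_idx]))
            )
    return folds


def one_hot(features: pd.DataFrame) -> pd.DataFrame:
    """Expand categorical columns (the artery label) to 0/1 indicators."""
    cat_cols = [c for c in features.columns if features[c].dtype == object]
    return pd.get_dummies(features, columns=cat_cols, dtype=float)


def standardize(train: np.ndarray, apply: np.ndarray, passthrough=None):
    """Mean/std standardization with training-set parameters.

    ``passthrough`` marks columns (e.g. one-hot indicators) left untouched.
    Zero-variance columns map to zero.  Returns the transformed matrices and
    the (mean, std) parameters.
    """
    train = np.asarray(train, dtype=float)
    apply = np.asarray(apply, dtype=float)
    mean = train.mean(axis=0)
    std = train.std(axis=0)  # population std
    if passthrough is not None:
        passthrough = np.asarray(passthrough, dtype=bool)
        mean = np.where(passthrough, 0.0, mean)
        std = np.where(passthrough, 1.0, std)
    safe = np.where(std > 0.0, std, 1.0)
    t = (train - mean) / safe
    a = (apply - mean) / safe
    dead = std == 0.0
    if passthrough is not None:
        dead = dead & ~passthrough
    t[:, dead] = 0.0
    a[:, dead] = 0.0
    return t, a, (mean, std)


def select_k_best(train: np.ndarray, labels: np.ndarray, k: int, seed: int = 0) -> np.ndarray:
    """Indices of the k features with highest estimated mutual information
    with the binary class label; ties broken by column order."""
    if k <= 0:
        raise ConfigError("k must be positive")
    if k > train.shape[1]:
        raise ConfigError(f"k={k} exceeds {train.shape[1]} features")
    mi = mutual_info_classif(train, labels, random_state=seed)
    order = np.argsort(-mi, kind="stable")
    return np.sort(order[:k])


def train_regressor(train: np.ndarray, y: np.ndarray, config: ExperimentConfig, seed: int):
    """Gradient-boosted tree ensemble with the fixed protocol hyperparameters."""
    if train.shape[0] == 0:
        raise DataError("empty training set")
    model = xgb.XGBRegressor(
        n_estimators=config.n_estimators,
        max_depth=config.max_depth,
        objective="reg:squarederror",
        tree_method="hist",
        n_jobs=1,
        random_state=int(seed % (2**31)),
    )
    model.fit(train, y)
    return model


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) < 1e-15 or np.std(b) < 1e-15:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def evaluate(y_pred, y_true) -> dict:
    """Regression metrics on raw values, classification metrics after
    thresholding both at 0 (ΔPAV ≤ 0 is the regression class).

    Degenerate denominators (single-class truth or predictions) yield
    MCC = r = 0 and per-class F1 = 0.
    """
    y_pred = np.asarray(y_pred, dtype=float)
    y_true = np.asarray(y_true, dtype=float)
    if y_pred.size == 0 or y_pred.size != y_true.size:
        raise DataError("predictions and targets must be non-empty and equal-length")
    cls_pred = (y_pred > 0).astype(int)
    cls_true = (y_true > 0).astype(int)
    err = y_pred - y_true
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UndefinedMetricWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        f1_neg = f1_score(cls_true, cls_pred, pos_label=0, zero_division=0.0)
        f1_pos = f1_score(cls_true, cls_pred, pos_label=1, zero_division=0.0)
        mcc = matthews_corrcoef(cls_true, cls_pred)
    return {
        "MAE": float(np.mean(np.abs(err))),
        "MSE": float(np.mean(err**2)),
        "r": _pearson(y_pred, y_true),
        "ACC": float(accuracy_score(cls_true, cls_pred)),
        "MCC": float(mcc),
        "F1neg": float(f1_neg),
        "F1pos": float(f1_pos),
        "F1a": float(0.5 * (f1_neg + f1_pos)),
    }


def run_experiment(
    features: pd.DataFrame,
    meta: pd.DataFrame,
    config: ExperimentConfig,
) -> ExperimentResult:
    """Full repeated stratified group cross-validation experiment.

    ``features`` holds one row per ROI (categorical artery column allowed);
    ``meta`` must carry per ROI: ``pullback_id``, ``patient_id``, ``dpav``
    (the target), ``length_mm`` and ``pullback_dpav`` (the pullback-level
    target used for stratification).
    """
    if len(features) != len(meta):
        raise DataError("features and meta must align row-wise")
    X_df = one_hot(features)
    columns = list(X_df.columns)
    passthrough = np.array(
        [c not in features.columns for c in columns], dtype=bool
    )  # one-hot expansions are exempt from standardization
    X = X_df.to_numpy(dtype=float)
    y = meta["dpav"].to_numpy(dtype=float)
    group_col = "pullback_id" if config.group_by == "pullback" else "patient_id"
    roi_groups = meta[group_col].to_numpy()

    pb = meta.drop_duplicates(group_col)
    folds = make_folds(
        pb[group_col].to_numpy(),
        (pb["pullback_dpav"].to_numpy() > 0).astype(int),
        config,
    )

    model_seeds = np.random.SeedSequence([config.seed, 1]).generate_state(len(folds))
    result = ExperimentResult(config=config, feature_columns=columns)
    for assignment, mseed in zip(folds, model_seeds):
        train_mask = np.isin(roi_groups, assignment.train_groups)
        test_mask = np.isin(roi_groups, assignment.test_groups)
        if not (np.any(train_mask) and np.any(test_mask)):
            raise DataError("a fold has an empty train or test side")
        if np.any(train_mask & test_mask):
            raise DataError("group integrity violated: ROI on both fold sides")
        Xtr, Xte, _ = standardize(X[train_mask], X[test_mask], passthrough)
        ytr, yte = y[train_mask], y[test_mask]
        if config.k_select is not None:
            sel = select_k_best(Xtr, (ytr > 0).astype(int), config.k_select, seed=int(mseed % (2**31)))
        else:
            sel = np.arange(X.shape[1])
        model = train_regressor(Xtr[:, sel], ytr, config, int(mseed))
        y_pred = model.predict(Xte[:, sel]).astype(float)
        record = ModelRecord(
            repeat_id=assignment.repeat_id,
            fold_id=assignment.fold_id,
            test_index=np.flatnonzero(test_mask),
            y_true=yte,
            y_pred=y_pred,
            metrics=evaluate(y_pred, yte),
            selected=np.array([columns[j] for j in sel]),
            mean_abs_shap=None,
        )
        if config.compute_shap:
            ens = TreeEnsemble(model.get_booster())
            phi, base = shap_values(ens, Xte[:, sel])
            record.mean_abs_shap = {
                columns[j]: float(np.mean(np.abs(phi[:, i]))) for i, j in enumerate(sel)
            }
            record.shap_base = base
        result.models.append(record)
    return result


def shap_report(result: ExperimentResult) -> pd.DataFrame:
    """Per-feature selection counts and SR-weighted mean |SHAP| totals.

    ``weighted_shap`` = selection ratio × Σ over selecting models of the
    model's mean absolute SHAP value for the feature; exactly 0 for features
    never selected.
    """
    if any(m.mean_abs_shap is None for m in result.models):
        raise DataError("experiment was run without SHAP attribution")
    n_models = result.n_models
    rows = []
    for feat in result.feature_columns:
        count = sum(1 for m in result.models if feat in m.selected)
        total = sum(m.mean_abs_shap.get(feat, 0.0) for m in result.models)
        ratio = count / n_models
        rows.append(
            {
                "feature": feat,
                "selection_count": count,
                "selection_ratio": ratio,
                "mean_abs_shap_sum": total,
                "weighted_shap": ratio * total,
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values(["weighted_shap", "feature"], ascending=[False, True])
        .reset_index(drop=True)
    )


def posthoc_indices(result: ExperimentResult, meta: pd.DataFrame):
    """Per-ROI CCR and per-pullback CCL over each unit's test appearances.

    CCR is the fraction of a ROI's test-set models (one per repeat) that
    classified it correctly; CCL is, per pullback and model, the summed
    length of correctly classified ROIs over the summed length of all its
    ROIs, then averaged over the pullback's test models.  Both are
    dichotomized at 0.5.
    """
    n_rois = len(meta)
    correct_sum = np.zeros(n_rois)
    pred_sum = np.zeros(n_rois)
    abs_err_sum = np.zeros(n_rois)
    appearances = np.zeros(n_rois, dtype=int)
    lengths = meta["length_mm"].to_numpy(dtype=float)
    pullbacks = meta["pullback_id"].to_numpy()
    ccl_per_pullback: dict = {}
    for m in result.models:
        correct = (m.y_pred > 0) == (m.y_true > 0)
        idx = m.test_index
        correct_sum[idx] += correct
        pred_sum[idx] += m.y_pred
        abs_err_sum[idx] += np.abs(m.y_pred - m.y_true)
        appearances[idx] += 1
        for pb_id in np.unique(pullbacks[idx]):
            in_pb = pullbacks[idx] == pb_id
            ccl = float(np.sum(lengths[idx][in_pb] * correct[in_pb]) / np.sum(lengths[idx][in_pb]))
            ccl_per_pullback.setdefault(pb_id, []).append(ccl)
    if np.any(appearances != result.config.n_repeats):
        raise DataError("bookkeeping error: ROI test appearances != n_repeats")
    roi_df = pd.DataFrame(
        {
            "pullback_id": pullbacks,
            "ccr": correct_sum / appearances,
            "mean_pred": pred_sum / appearances,
            "mean_abs_err": abs_err_sum / appearances,
        }
    )
    roi_df["ccr_gt_half"] = roi_df["ccr"] > 0.5
    pb_df = pd.DataFrame(
        {
            "pullback_id": list(ccl_per_pullback),
            "ccl_mean": [float(np.mean(v)) for v in ccl_per_pullback.values()],
            "ccl_std": [float(np.std(v)) for v in ccl_per_pullback.values()],
            "n_test_models": [len(v) for v in ccl_per_pullback.values()],
        }
    )
    pb_df["ccl_gt_half"] = pb_df["ccl_mean"] > 0.5
    return roi_df, pb_df


def metrics_table(result: ExperimentResult) -> pd.DataFrame:
    """mean (std) [min, max] aggregate of every metric over the fold models."""
    rows = []
    for name in METRIC_NAMES:
        vals = np.array([m.metrics[name] for m in result.models])
        rows.append(
            {
                "metric": name,
                "mean": float(vals.mean()),
                "std": float(vals.std()),
                "min": float(vals.min()),
                "max": float(vals.max()),
            }
        )
    return pd.DataFrame(rows)
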