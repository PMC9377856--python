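"""Linear-SVM classification, penalty grid search, and cross-validated
evaluation of the full feature pipeline.

The classifier is a hard linear-kernel SVM, k(x_i, x_j) = x_i . x_j; the
only hyperparameter is the error penalty C, chosen by grid search over
decades and validated with stratified 10-fold cross-validation.  The
orchestrating :func:`cross_validate_pipeline` keeps every fitted quantity
— CSP filters, fusion standardization, selector, C — strictly inside the
training fold, so the held-out accuracy is leakage-free.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .csp import csp_features, csp_fit
from .epochs import EpochSet
from .features import (
    ARConfig,
    FeatureMatrix,
    WaveletSpec,
    ar_features,
    dwt_features,
    fuse_features,
)
from .selection import (
    ETConfig,
    SelectionModel,
    apply_selection,
    et_fit,
    pca_fit,
    relieff_weights,
    rfe_fit,
)

__all__ = [
    "SVMConfig",
    "FeaturePipelineConfig",
    "FoldResult",
    "CVReport",
    "svm_train",
    "grid_search_C",
    "cross_validate_pipeline",
    "paired_ttest",
]

DEFAULT_C_GRID = tuple(10.0**k for k in range(-3, 4))

# libsvm's solver can need millions of iterations for large C on
# non-separable data; such settings lose the grid search anyway, so the
# iteration count is capped and the convergence warning silenced.
_MAX_ITER = 100_000


def _fit_svc(values: np.ndarray, y: np.ndarray, C: float) -> SVC:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=ConvergenceWarning)
        return SVC(kernel="linear", C=C, max_iter=_MAX_ITER).fit(values, y)


@dataclass(frozen=True)
class SVMConfig:
    """Linear SVM with a grid-searched penalty and stratified k-fold CV."""

    C_grid: tuple[float, ...] = DEFAULT_C_GRID
    cv_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not all(c > 0 for c in self.C_grid):
            raise ValueError("all C values must be positive")
        if self.cv_folds < 2:
            raise ValueError(f"cv_folds must be >= 2, got {self.cv_folds}")


def svm_train(X: FeatureMatrix | np.ndarray, y: np.ndarray, C: float = 1.0) -> SVC:
    """Train a linear-kernel SVM (kernel values are plain dot products)."""
    if C <= 0:
        raise ValueError(f"C must be positive, got {C}")
    values = X.values if isinstance(X, FeatureMatrix) else np.asarray(X)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    return _fit_svc(values, y, C)


def grid_search_C(
    X: FeatureMatrix | np.ndarray, y: np.ndarray, cfg: SVMConfig = SVMConfig()
) -> tuple[float, pd.DataFrame]:
    """Pick the C maximizing mean stratified-CV accuracy (ties -> smallest C).

    Returns the winning C and the full (C, fold, accuracy) table.
    """
    values = X.values if isinstance(X, FeatureMatrix) else np.asarray(X)
    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    if cfg.cv_folds > counts.min():
        raise ValueError(
            f"cv_folds={cfg.cv_folds} exceeds the smallest class count {counts.min()}"
        )
    skf = StratifiedKFold(n_splits=cfg.cv_folds, shuffle=True, random_state=cfg.seed)
    splits = list(skf.split(values, y))
    rows = []
    for C in sorted(cfg.C_grid):
        for fold, (tr, te) in enumerate(splits):
            model = _fit_svc(values[tr], y[tr], C)
            acc = float(np.mean(model.predict(values[te]) == y[te]))
            rows.append({"C": C, "fold": fold, "accuracy": acc})
    table = pd.DataFrame(rows)
    means = table.groupby("C")["accuracy"].mean()
    best_C = float(means.index[np.argmax(means.values)])  # grid ascending: tie -> min C
    return best_C, table


@dataclass(frozen=True)
class FeaturePipelineConfig:
    """Which extractors feed the classifier, and the per-fold selector.

    ``extractors`` is an ordered subset of ("ar", "csp", "dwt");
    ``selector`` is one of None/"rfe"/"pca"/"et"/"relieff".  All fitting —
    CSP, standardization, selection — happens inside each training fold
    unless ``fit_selector_on_all`` requests the (leaky) whole-dataset fit
    for comparison.
    """

    extractors: tuple[str, ...] = ("ar", "csp", "dwt")
    ar: ARConfig = ARConfig()
    wavelet: WaveletSpec = WaveletSpec()
    csp_log_variance: bool = False
    standardize: bool = True
    selector: str | None = None
    n_keep: int = 20
    et: ETConfig = ETConfig()
    relieff_k_neighbors: int = 10
    fit_selector_on_all: bool = False

    def __post_init__(self) -> None:
        valid = ("ar", "csp", "dwt")
        if not self.extractors or any(e not in valid for e in self.extractors):
            raise ValueError(
                f"extractors must be a non-empty subset of {valid}, "
                f"got {self.extractors}"
            )
        if self.selector not in (None, "none", "rfe", "pca", "et", "relieff"):
            raise ValueError(f"unknown selector {self.selector!r}")

    @property
    def selector_name(self) -> str:
        return "none" if self.selector in (None, "none") else self.selector


@dataclass(frozen=True)
class FoldResult:
    fold: int
    test_indices: tuple[int, ...]
    chosen_C: float
    accuracy: float
    n_features_used: int


@dataclass(frozen=True)
class CVReport:
    """Per-fold and aggregate accuracy for one pipeline configuration."""

    feature_set: str
    selector: str
    folds: tuple[FoldResult, ...]
    seed: int
    cv_folds: int

    @property
    def fold_accuracies(self) -> np.ndarray:
        return np.array([f.accuracy for f in self.folds])

    @property
    def mean_accuracy(self) -> float:
        return float(self.fold_accuracies.mean())

    def to_dict(self) -> dict:
        return {
            "feature_set": self.feature_set,
            "selector": self.selector,
            "seed": self.seed,
            "cv_folds": self.cv_folds,
            "mean_accuracy": self.mean_accuracy,
            "folds": [
                {
                    "fold": f.fold,
                    "test_indices": list(f.test_indices),
                    "chosen_C": f.chosen_C,
                    "accuracy": f.accuracy,
                    "n_features_used": f.n_features_used,
                }
                for f in self.folds
            ],
        }


def _fit_selector(
    cfg: FeaturePipelineConfig, X: FeatureMatrix, y: np.ndarray, seed: int
) -> SelectionModel | None:
    name = cfg.selector_name
    if name == "none":
        return None
    if name == "rfe":
        return rfe_fit(X, y, n_keep=cfg.n_keep)
    if name == "pca":
        return pca_fit(X, n_components=cfg.n_keep)
    if name == "et":
        return et_fit(X, y, replace(cfg.et, k_keep=cfg.n_keep, seed=seed))
    if name == "relieff":
        k = min(cfg.relieff_k_neighbors, int(np.bincount(_as01(y)).min()) - 1)
        return relieff_weights(X, y, k_neighbors=k, k_keep=cfg.n_keep, seed=seed)
    raise AssertionError(name)


def _as01(y: np.ndarray) -> np.ndarray:
    classes = np.unique(y)
    return (y == classes[-1]).astype(int)


def _trialwise_parts(
    epochs: EpochSet, cfg: FeaturePipelineConfig
) -> dict[str, FeatureMatrix]:
    """Label-free extractors (AR, DWT) computed once on all trials."""
    parts = {}
    if "ar" in cfg.extractors:
        parts["ar"] = ar_features(epochs, cfg.ar)
    if "dwt" in cfg.extractors:
        parts["dwt"] = dwt_features(epochs, cfg.wavelet)
    return parts


def _fold_features(
    epochs: EpochSet,
    cfg: FeaturePipelineConfig,
    cached: dict[str, FeatureMatrix],
    train_idx: np.ndarray,
) -> FeatureMatrix:
    """Assemble the fused matrix for all trials, fitting CSP and the
    standardization on the training rows only."""
    parts = []
    for name in cfg.extractors:
        if name == "csp":
            filt = csp_fit(epochs.subset(train_idx))
            parts.append(
                csp_features(epochs, filt, log_variance=cfg.csp_log_variance)
            )
        else:
            parts.append(cached[name])
    return fuse_features(parts, standardize=cfg.standardize, train_rows=train_idx)


def cross_validate_pipeline(
    epochs: EpochSet,
    pipeline_cfg: FeaturePipelineConfig = FeaturePipelineConfig(),
    svm_cfg: SVMConfig = SVMConfig(),
) -> CVReport:
    """Stratified k-fold evaluation of extraction + fusion + selection + SVM.

    Within each fold, the CSP filters, the fusion standardization, the
    selector and the grid-searched C are fitted on the training rows only;
    accuracy is measured on the held-out fold.  Identical seeds give an
    identical report.
    """
    y = epochs.labels
    _, counts = np.unique(y, return_counts=True)
    if svm_cfg.cv_folds > counts.min():
        raise ValueError(
            f"cv_folds={svm_cfg.cv_folds} exceeds the smallest class count "
            f"{counts.min()}"
        )
    cached = _trialwise_parts(epochs, pipeline_cfg)
    skf = StratifiedKFold(
        n_splits=svm_cfg.cv_folds, shuffle=True, random_state=svm_cfg.seed
    )
    fold_results = []
    for fold, (train_idx, test_idx) in enumerate(skf.split(epochs.data[:, 0, 0:1], y)):
        try:
            fused = _fold_features(epochs, pipeline_cfg, cached, train_idx)
            X_train = FeatureMatrix(
                values=fused.values[train_idx],
                provenance=fused.provenance,
            )
            fold_seed = int(
                np.random.SeedSequence(
                    entropy=svm_cfg.seed, spawn_key=(fold,)
                ).generate_state(1)[0]
                % 2**31
            )
            model = _fit_selector(pipeline_cfg, X_train, y[train_idx], fold_seed)
            if model is not None:
                sel_all = apply_selection(model, fused)
            else:
                sel_all = fused
            inner_folds = min(svm_cfg.cv_folds, int(np.bincount(_as01(y[train_idx])).min()))
            inner_cfg = SVMConfig(
                C_grid=svm_cfg.C_grid, cv_folds=inner_folds, seed=fold_seed
            )
            best_C, _ = grid_search_C(sel_all.values[train_idx], y[train_idx], inner_cfg)
            clf = svm_train(sel_all.values[train_idx], y[train_idx], C=best_C)
            pred = clf.predict(sel_all.values[test_idx])
            acc = float(np.mean(pred == y[test_idx]))
        except Exception as exc:  # annotate stage errors with the fold
            raise RuntimeError(f"fold {fold}: {exc}") from exc
        fold_results.append(
            FoldResult(
                fold=fold,
                test_indices=tuple(int(i) for i in test_idx),
                chosen_C=best_C,
                accuracy=acc,
                n_features_used=sel_all.n_features,
            )
        )
    return CVReport(
        feature_set="+".join(e.upper() for e in pipeline_cfg.extractors),
        selector=pipeline_cfg.selector_name,
        folds=tuple(fold_results),
        seed=svm_cfg.seed,
        cv_folds=svm_cfg.cv_folds,
    )


def paired_ttest(acc_a: np.ndarray | list, acc_b: np.ndarray | list) -> tuple[float, float]:
    """Classical paired two-tailed t-test on accuracy differences.

    If every difference is zero the statistic is undefined; by convention
    (nan, 1.0) is returned rather than raising.
    """
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size < 2:
        raise ValueError("need at least 2 paired observations")
    d = a - b
    if np.allclose(d, 0.0):
        return float("nan"), 1.0
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)
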