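"""Feature selection: extremely randomized trees, RFE, PCA and ReliefF.

The centerpiece is the extremely-randomized-trees (ET) selector.  Unlike a
random forest, every tree is grown on the *full* training sample (no
bootstrap); at each node one uniformly random cut-point is drawn per
candidate feature between that feature's minimum and maximum over the node
samples, and the best cut is kept by the normalized information gain

    Score = 2 I(split; class) / (H_split + H_class)

with entropies in bits and the 0*log0 = 0 convention.  The score is 1 for
a perfect balanced split and 0 when split and class are independent.
Per-feature importance is the split score weighted by the node's sample
fraction, summed over nodes, averaged over trees, and normalized to sum
to one.

The other selectors are the standard baselines they are compared against:
recursive feature elimination under a linear support-vector regressor with
the squared-weight criterion, centered PCA, and ReliefF near-hit/near-miss
feature weighting.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from sklearn.decomposition import PCA
from sklearn.svm import SVR

from .features import FeatureMatrix, Provenance

__all__ = [
    "SplitCounts",
    "split_score",
    "ETConfig",
    "SelectionModel",
    "et_fit",
    "rfe_fit",
    "pca_fit",
    "relieff_weights",
    "apply_selection",
    "save_selection_model",
    "load_selection_model",
]


# ---------------------------------------------------------------------------
# Normalized information-gain split score
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SplitCounts:
    """Per-class sample counts on the two sides of a candidate split."""

    left: Mapping[str, int]
    right: Mapping[str, int]

    def table(self) -> np.ndarray:
        """2 x n_classes count table (rows: left/right side)."""
        classes = sorted(set(self.left) | set(self.right))
        return np.array(
            [
                [self.left.get(c, 0) for c in classes],
                [self.right.get(c, 0) for c in classes],
            ],
            dtype=float,
        )


def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def _score_from_table(table: np.ndarray) -> float:
    total = table.sum()
    if total < 1:
        raise ValueError("empty node")
    p_side = table.sum(axis=1) / total
    p_class = table.sum(axis=0) / total
    h_side = _entropy_bits(p_side)
    h_class = _entropy_bits(p_class)
    p_joint = (table / total).ravel()
    h_joint = _entropy_bits(p_joint)
    mutual = h_side + h_class - h_joint
    denom = h_side + h_class
    if denom <= 0.0:
        return 0.0
    # clip tiny negative rounding of the mutual information
    return max(0.0, 2.0 * mutual / denom)


def split_score(counts: SplitCounts) -> float:
    """Normalized information gain of a split, in [0, 1].

    0 when the split outcome is independent of the class, 1 for a perfect
    balanced split (each side pure, one class per side, equal sizes).
    """
    table = counts.table()
    if table.sum() < 2:
        raise ValueError("split_score needs at least 2 samples")
    if (table.sum(axis=0) > 0).sum() < 1:
        raise ValueError("no class present")
    return _score_from_table(table)


# ---------------------------------------------------------------------------
# Selection model container
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SelectionModel:
    """A fitted selector: kept-feature mask (rfe/et/relieff) or projection (pca).

    ``scores`` holds the per-feature importance/weight (or per-component
    explained variance for PCA); ``n_features_in`` pins the dimension the
    model was fitted on.
    """

    kind: str  # rfe | pca | et | relieff
    n_features_in: int
    mask: np.ndarray | None = None  # sorted kept indices
    components: np.ndarray | None = None  # (k, n_features_in), orthonormal rows
    center: np.ndarray | None = None
    scores: np.ndarray | None = None
    seed: int | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("rfe", "pca", "et", "relieff"):
            raise ValueError(f"unknown selector kind {self.kind!r}")
        if self.kind == "pca":
            if self.components is None:
                raise ValueError("pca model requires components")
        elif self.mask is None:
            raise ValueError(f"{self.kind} model requires a feature mask")
        if self.mask is not None:
            mask = np.asarray(self.mask, dtype=int)
            object.__setattr__(self, "mask", mask)
            if len(np.unique(mask)) != len(mask) or mask.min(initial=0) < 0 or (
                mask.size and mask.max() >= self.n_features_in
            ):
                raise ValueError("mask indices must be unique and within range")


def apply_selection(model: SelectionModel, X: FeatureMatrix) -> FeatureMatrix:
    """Apply a fitted selector to a feature matrix (labels never consulted)."""
    if X.n_features != model.n_features_in:
        raise ValueError(
            f"feature-count mismatch: matrix has {X.n_features}, model was "
            f"fitted on {model.n_features_in}"
        )
    if model.kind == "pca":
        center = model.center if model.center is not None else 0.0
        proj = (X.values - center) @ model.components.T
        prov = tuple(
            Provenance("PCA", f"PC{k + 1}", k + 1)
            for k in range(model.components.shape[0])
        )
        return FeatureMatrix(values=proj, provenance=prov)
    return FeatureMatrix(
        values=X.values[:, model.mask],
        provenance=tuple(X.provenance[i] for i in model.mask),
    )


def _validate_binary(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"binary labels required, got classes {list(classes)}")
    return (y == classes[1]).astype(int)


def _top_k_mask(scores: np.ndarray, k: int) -> np.ndarray:
    # descending score, ties broken toward the lower column index
    order = np.lexsort((np.arange(scores.size), -scores))
    return np.sort(order[:k])


# ---------------------------------------------------------------------------
# Extremely randomized trees
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ETConfig:
    """Extremely-randomized-trees parameters.

    ``features_per_node`` (m) defaults to all features (m = M);
    ``min_split`` (n_min) is the smallest node that may still be split;
    ``n_trees`` (R) is the ensemble size; ``k_keep`` the number of features
    retained by the selector.
    """

    n_trees: int = 10
    features_per_node: int | None = None  # None -> m = M
    min_split: int = 2
    k_keep: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError(f"n_trees must be >= 1, got {self.n_trees}")
        if self.min_split < 2:
            raise ValueError(f"min_split must be >= 2, got {self.min_split}")
        if self.k_keep < 1:
            raise ValueError(f"k_keep must be >= 1, got {self.k_keep}")
        if self.features_per_node is not None and self.features_per_node < 1:
            raise ValueError(
                f"features_per_node must be >= 1, got {self.features_per_node}"
            )


@dataclass
class _Node:
    n: int
    feature: int | None = None
    cut: float | None = None
    score: float = 0.0
    left: "_Node | None" = None
    right: "_Node | None" = None

    def count_nodes(self) -> int:
        if self.feature is None:
            return 1
        return 1 + self.left.count_nodes() + self.right.count_nodes()


def _binary_split_score(y_left: np.ndarray, y_right: np.ndarray) -> float:
    table = np.array(
        [
            [np.sum(y_left == 0), np.sum(y_left == 1)],
            [np.sum(y_right == 0), np.sum(y_right == 1)],
        ],
        dtype=float,
    )
    return _score_from_table(table)


def _grow_tree(
    X: np.ndarray,
    y: np.ndarray,
    idx: np.ndarray,
    m: int,
    n_min: int,
    rng: np.random.Generator,
    importance: np.ndarray,
    n_total: int,
) -> _Node:
    node = _Node(n=idx.size)
    y_node = y[idx]
    if idx.size < n_min or np.all(y_node == y_node[0]):
        return node
    n_feat = X.shape[1]
    if m >= n_feat:
        candidates = np.arange(n_feat)
    else:
        candidates = np.sort(rng.choice(n_feat, size=m, replace=False))
    best_score = -1.0
    best = None
    for f in candidates:  # ascending feature order fixes the draw sequence
        col = X[idx, f]
        lo, hi = col.min(), col.max()
        if hi <= lo:
            continue  # constant feature at this node: no valid cut
        cut = rng.uniform(lo, hi)
        go_left = col <= cut
        score = _binary_split_score(y_node[go_left], y_node[~go_left])
        if score > best_score:
            best_score = score
            best = (f, cut, go_left)
    if best is None:
        return node
    f, cut, go_left = best
    node.feature = int(f)
    node.cut = float(cut)
    node.score = best_score
    importance[f] += best_score * (idx.size / n_total)
    node.left = _grow_tree(X, y, idx[go_left], m, n_min, rng, importance, n_total)
    node.right = _grow_tree(X, y, idx[~go_left], m, n_min, rng, importance, n_total)
    return node


def et_fit(X: FeatureMatrix, y: np.ndarray, cfg: ETConfig = ETConfig()) -> SelectionModel:
    """Fit the extremely-randomized-trees selector.

    Every tree sees the full training sample; importances aggregate the
    normalized information gain of each split weighted by the node's sample
    fraction, averaged over trees and normalized to sum to one.  The top
    ``k_keep`` features by importance form the mask.
    """
    y01 = _validate_binary(y)
    vals = X.values
    n, n_feat = vals.shape
    if n < cfg.min_split:
        raise ValueError(f"need at least min_split={cfg.min_split} samples, got {n}")
    m = cfg.features_per_node if cfg.features_per_node is not None else n_feat
    m = min(m, n_feat)
    importance = np.zeros(n_feat)
    trees = []
    for r in range(cfg.n_trees):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=cfg.seed, spawn_key=(r,))
        )
        tree_importance = np.zeros(n_feat)
        root = _grow_tree(
            vals, y01, np.arange(n), m, cfg.min_split, rng, tree_importance, n
        )
        importance += tree_importance
        trees.append(root)
    importance /= cfg.n_trees
    total = importance.sum()
    if total > 0:
        importance = importance / total
    k = min(cfg.k_keep, n_feat)
    if cfg.k_keep > n_feat:
        warnings.warn(
            f"k_keep={cfg.k_keep} exceeds the {n_feat} available features; keeping all",
            stacklevel=2,
        )
    mask = _top_k_mask(importance, k)
    return SelectionModel(
        kind="et",
        n_features_in=n_feat,
        mask=mask,
        scores=importance,
        seed=cfg.seed,
        extra={
            "trees": trees,
            "n_trees": cfg.n_trees,
            "features_per_node": m,
            "min_split": cfg.min_split,
        },
    )


# ---------------------------------------------------------------------------
# Recursive feature elimination (linear SVR, squared-weight criterion)
# ---------------------------------------------------------------------------


def rfe_fit(
    X: FeatureMatrix, y: np.ndarray, n_keep: int = 20, C: float = 1.0
) -> SelectionModel:
    """Backward elimination under a linear support-vector regressor.

    At each round a linear SVR is fitted on the surviving columns with the
    labels coded as -1/+1, features are ranked by the squared weight w_f^2,
    and the single lowest-ranked feature is dropped (ties: lowest column
    index) until ``n_keep`` remain.
    """
    if n_keep < 1:
        raise ValueError(f"n_keep must be >= 1, got {n_keep}")
    y01 = _validate_binary(y)
    target = 2.0 * y01 - 1.0
    n_feat = X.n_features
    if n_keep >= n_feat:
        if n_keep > n_feat:
            warnings.warn(
                f"n_keep={n_keep} exceeds the {n_feat} available features; keeping all",
                stacklevel=2,
            )
        w = SVR(kernel="linear", C=C).fit(X.values, target).coef_.ravel()
        return SelectionModel(
            kind="rfe",
            n_features_in=n_feat,
            mask=np.arange(n_feat),
            scores=w**2,
            extra={"n_rounds": 0},
        )
    surviving = list(range(n_feat))
    rounds = 0
    while len(surviving) > n_keep:
        w = SVR(kernel="linear", C=C).fit(X.values[:, surviving], target).coef_.ravel()
        drop_pos = int(np.argmin(w**2))  # argmin is first-of-ties: lowest index
        surviving.pop(drop_pos)
        rounds += 1
    w = SVR(kernel="linear", C=C).fit(X.values[:, surviving], target).coef_.ravel()
    scores = np.zeros(n_feat)
    scores[surviving] = w**2
    return SelectionModel(
        kind="rfe",
        n_features_in=n_feat,
        mask=np.asarray(surviving),
        scores=scores,
        extra={"n_rounds": rounds},
    )


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


def pca_fit(X: FeatureMatrix, n_components: int = 20) -> SelectionModel:
    """Centered (not re-scaled) PCA projection onto the leading components."""
    if n_components < 1:
        raise ValueError(f"n_components must be >= 1, got {n_components}")
    cap = min(X.n_trials - 1 if X.n_trials > 1 else 1, X.n_features)
    if n_components > cap:
        warnings.warn(
            f"n_components={n_components} capped at {cap} "
            f"(trials={X.n_trials}, features={X.n_features})",
            stacklevel=2,
        )
        n_components = cap
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(X.values)
    return SelectionModel(
        kind="pca",
        n_features_in=X.n_features,
        components=pca.components_,
        center=pca.mean_,
        scores=pca.explained_variance_,
    )


# ---------------------------------------------------------------------------
# ReliefF
# ---------------------------------------------------------------------------


def relieff_weights(
    X: FeatureMatrix,
    y: np.ndarray,
    k_neighbors: int = 10,
    n_sampled: int | None = None,
    k_keep: int = 20,
    seed: int = 0,
) -> SelectionModel:
    """ReliefF feature weights for binary classes.

    For each sampled instance the k nearest same-class neighbors (near
    hits) pull the weight of agreeing features down and the k nearest
    other-class neighbors (near misses) push disagreeing features up.
    Distances are Manhattan on per-feature standardized values, feature
    differences are normalized by the feature range, and neighbor ties are
    broken by row index.  Weights lie in [-1, 1].
    """
    y01 = _validate_binary(y)
    vals = X.values
    n, n_feat = vals.shape
    counts = np.bincount(y01, minlength=2)
    if k_neighbors >= counts.min():
        raise ValueError(
            f"k_neighbors={k_neighbors} must be below the smallest class "
            f"count {counts.min()}"
        )
    sd = vals.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    Z = (vals - vals.mean(axis=0)) / sd
    rng_feat = Z.max(axis=0) - Z.min(axis=0)
    rng_feat = np.where(rng_feat > 0, rng_feat, 1.0)
    if n_sampled is None:
        sampled = np.arange(n)
    else:
        sampled = np.random.default_rng(seed).choice(
            n, size=min(n_sampled, n), replace=False
        )
    w = np.zeros(n_feat)
    for i in sampled:
        dist = np.abs(Z - Z[i]).sum(axis=1)
        dist[i] = np.inf
        order = np.argsort(dist, kind="stable")  # stable sort = index tie-break
        hits, misses = [], []
        for j in order:
            if len(hits) >= k_neighbors and len(misses) >= k_neighbors:
                break
            if y01[j] == y01[i]:
                if len(hits) < k_neighbors:
                    hits.append(j)
            elif len(misses) < k_neighbors:
                misses.append(j)
        diff_hit = np.abs(Z[hits] - Z[i]) / rng_feat
        diff_miss = np.abs(Z[misses] - Z[i]) / rng_feat
        w += diff_miss.mean(axis=0) - diff_hit.mean(axis=0)
    w /= sampled.size
    k = min(k_keep, n_feat)
    return SelectionModel(
        kind="relieff",
        n_features_in=n_feat,
        mask=_top_k_mask(w, k),
        scores=w,
        seed=seed,
        extra={"k_neighbors": k_neighbors},
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def save_selection_model(model: SelectionModel, path: str | Path) -> None:
    """Write a SelectionModel to JSON (trees summarized by node counts)."""
    payload: dict = {
        "kind": model.kind,
        "n_features_in": model.n_features_in,
        "seed": model.seed,
    }
    if model.mask is not None:
        payload["mask"] = model.mask.tolist()
    if model.components is not None:
        payload["components"] = model.components.tolist()
        payload["center"] = model.center.tolist()
    if model.scores is not None:
        payload["scores"] = model.scores.tolist()
    extra = {k: v for k, v in model.extra.items() if k != "trees"}
    if "trees" in model.extra:
        extra["tree_node_counts"] = [t.count_nodes() for t in model.extra["trees"]]
    payload["extra"] = extra
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def load_selection_model(path: str | Path) -> SelectionModel:
    payload = json.loads(Path(path).read_text())
    return SelectionModel(
        kind=payload["kind"],
        n_features_in=payload["n_features_in"],
        mask=np.asarray(payload["mask"]) if "mask" in payload else None,
        components=(
            np.asarray(payload["components"]) if "components" in payload else None
        ),
        center=np.asarray(payload["center"]) if "center" in payload else None,
        scores=np.asarray(payload["scores"]) if "scores" in payload else None,
        seed=payload.get("seed"),
        extra=payload.get("extra", {}),
    )
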