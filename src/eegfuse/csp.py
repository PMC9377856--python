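"""Common spatial patterns (CSP) for two-class motor imagery.

CSP finds a projection W of the multichannel signal such that the variance
of the projected components is maximally discriminative between the two
classes.  The construction: average the trace-normalized per-trial
covariances within each class (R1bar, R2bar), whiten their sum
R_m = R1bar + R2bar with P = lambda^{-1/2} U^T (so that P R_m P^T = I),
jointly diagonalize the whitened class covariances S1 = P R1bar P^T and
S2 = P R2bar P^T (they share eigenvectors B, and their eigenvalues sum to
one per component), and set W = B^T P.  Filters are sorted by descending
class-1 eigenvalue, so the first row maximizes class-1 variance share and
the last row maximizes class-2's.

The per-trial CSP feature is the variance of each spatially filtered
component (optionally the log of the trial-normalized variance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .epochs import EpochSet
from .features import FeatureMatrix, Provenance

__all__ = ["SpatialFilter", "csp_fit", "csp_features"]


@dataclass(frozen=True)
class SpatialFilter:
    """Fitted CSP projection with its eigenvalue diagnostics.

    ``W`` has one spatial filter per row; ``eigenvalues_class1[k]`` +
    ``eigenvalues_class2[k]`` = 1 for every filter k.  ``P`` is the
    whitening matrix of the mixed covariance.
    """

    W: np.ndarray
    eigenvalues_class1: np.ndarray
    eigenvalues_class2: np.ndarray
    P: np.ndarray
    channel_names: tuple[str, ...]
    classes: tuple[str, str]

    @property
    def n_filters(self) -> int:
        return self.W.shape[0]


def _class_mean_covariance(data: np.ndarray) -> np.ndarray:
    """Arithmetic mean of trace-normalized per-trial covariances X X^T / tr."""
    covs = []
    for X in data:
        C = X @ X.T
        tr = np.trace(C)
        if tr <= 0:
            raise ValueError("trial with zero power; cannot normalize covariance")
        covs.append(C / tr)
    return np.mean(covs, axis=0)


def csp_fit(epochs_train: EpochSet) -> SpatialFilter:
    """Fit CSP filters on labelled training epochs (exactly two classes)."""
    classes = epochs_train.classes
    if len(classes) != 2:
        raise ValueError(
            f"CSP requires exactly two classes, got {list(map(str, classes))}"
        )
    by_class = epochs_train.class_indices()
    for label, idx in by_class.items():
        if idx.size < 2:
            raise ValueError(f"class {label!r} has fewer than 2 trials")
    c1, c2 = (str(c) for c in classes)
    R1 = _class_mean_covariance(epochs_train.data[by_class[c1]])
    R2 = _class_mean_covariance(epochs_train.data[by_class[c2]])
    Rm = R1 + R2
    lam, U = np.linalg.eigh(Rm)
    if lam.min() <= 1e-12 * lam.max():
        raise ValueError(
            "mixed covariance R_m is rank-deficient; add a small diagonal "
            "ridge to the data or drop redundant channels (regularization hint)"
        )
    P = np.diag(lam**-0.5) @ U.T  # whitener: P Rm P^T = I
    S1 = P @ R1 @ P.T
    mu, B = np.linalg.eigh(S1)  # S1 and S2 = I - S1 share eigenvectors
    order = np.argsort(mu)[::-1]
    mu = mu[order]
    B = B[:, order]
    W = B.T @ P
    # deterministic sign: largest-magnitude weight of each filter positive
    for k in range(W.shape[0]):
        j = np.argmax(np.abs(W[k]))
        if W[k, j] < 0:
            W[k] *= -1.0
    lam2 = np.diag(B.T @ (P @ R2 @ P.T) @ B)
    return SpatialFilter(
        W=W,
        eigenvalues_class1=mu,
        eigenvalues_class2=lam2,
        P=P,
        channel_names=epochs_train.channel_names,
        classes=(c1, c2),
    )


def csp_features(
    epochs: EpochSet,
    filt: SpatialFilter,
    log_variance: bool = False,
    eps: float = 1e-12,
) -> FeatureMatrix:
    """Variance of each CSP component per trial.

    With ``log_variance`` the feature is ``log(var_k / sum_j var_j)`` with an
    ``eps`` floor; the default is the raw variance.
    """
    if epochs.channel_names != filt.channel_names:
        raise ValueError(
            f"channel mismatch: epochs have {list(epochs.channel_names)}, "
            f"filter was fitted on {list(filt.channel_names)}"
        )
    n_filt = filt.n_filters
    out = np.empty((epochs.n_trials, n_filt))
    for t in range(epochs.n_trials):
        Z = filt.W @ epochs.data[t]
        var = Z.var(axis=1)
        if log_variance:
            total = var.sum()
            if total <= 0:
                var = np.full(n_filt, eps)
                total = var.sum()
            out[t] = np.log(np.maximum(var / total, eps))
        else:
            out[t] = var
    prov = tuple(Provenance("CSP", f"CSP{k + 1}", k + 1) for k in range(n_filt))
    return FeatureMatrix(values=out, provenance=prov)
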