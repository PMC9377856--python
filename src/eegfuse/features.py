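"""Time-domain (AR) and time-frequency-domain (DWT) features, and fusion.

Every extractor returns a :class:`FeatureMatrix` — a trials x features
table carrying per-feature provenance (which extractor, which channel or
spatial filter, which coefficient) so that fused feature sets remain
auditable and can be split back into their parts.

AR features are the coefficients of the autoregressive recursion
``y(t) = -sum_{i=1..p} a_i y(t-i) + e(t)`` estimated per channel; note the
sign convention — the reported a_i are the *negated* regression
coefficients.  DWT features are the mean squared detail coefficients of a
chosen decomposition level (db4, 3 levels by default); at a 128 Hz
sampling rate the level-3 detail subband spans 8-16 Hz, i.e. the mu band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pywt
from statsmodels.regression.linear_model import burg, yule_walker

from .epochs import EpochSet

__all__ = [
    "Provenance",
    "FeatureMatrix",
    "ARConfig",
    "ar_features",
    "WaveletSpec",
    "dwt_features",
    "fuse_features",
]


@dataclass(frozen=True)
class Provenance:
    """Origin of a single feature column."""

    extractor: str  # "AR" | "CSP" | "DWT" | "PCA"
    source: str  # channel name or filter/component label
    index: int  # coefficient / level / component index


@dataclass(frozen=True)
class FeatureMatrix:
    """Trials x features table with provenance and optional standardization."""

    values: np.ndarray
    provenance: tuple[Provenance, ...]
    mean_: np.ndarray | None = field(default=None)
    scale_: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "provenance", tuple(self.provenance))
        if values.ndim != 2:
            raise ValueError(f"values must be 2-D, got shape {values.shape}")
        if len(self.provenance) != values.shape[1]:
            raise ValueError(
                f"{len(self.provenance)} provenance records for "
                f"{values.shape[1]} features"
            )
        if not np.isfinite(values).all():
            raise ValueError("feature values contain non-finite entries")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def standardized(self) -> bool:
        return self.mean_ is not None

    def column_names(self) -> list[str]:
        return [f"{p.extractor}:{p.source}:{p.index}" for p in self.provenance]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.column_names())

    def part(self, extractor: str) -> "FeatureMatrix":
        """Columns produced by one extractor (de-fusion by provenance)."""
        keep = [i for i, p in enumerate(self.provenance) if p.extractor == extractor]
        return FeatureMatrix(
            values=self.values[:, keep],
            provenance=tuple(self.provenance[i] for i in keep),
        )


# ---------------------------------------------------------------------------
# AR features
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ARConfig:
    """Autoregressive model order and estimator."""

    order: int = 6
    estimation_method: str = "burg"  # burg | yule_walker | least_squares

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError(f"order must be >= 1, got {self.order}")
        if self.estimation_method not in ("burg", "yule_walker", "least_squares"):
            raise ValueError(
                f"unknown estimation_method {self.estimation_method!r}"
            )


def _ar_fit(y: np.ndarray, p: int, method: str) -> np.ndarray:
    """Regression coefficients rho of y(t) = sum rho_i y(t-i) + e(t)."""
    if method == "burg":
        rho, _ = burg(y, order=p, demean=True)
        return np.asarray(rho)
    if method == "yule_walker":
        rho, _ = yule_walker(y, order=p, method="mle")
        return np.asarray(rho)
    # least squares: regress y(t) on its p lags
    yc = y - y.mean()
    n = yc.size
    design = np.column_stack([yc[p - i - 1 : n - i - 1] for i in range(p)])
    target = yc[p:]
    rho, *_ = np.linalg.lstsq(design, target, rcond=None)
    return rho


def ar_features(epochs: EpochSet, cfg: ARConfig = ARConfig()) -> FeatureMatrix:
    """Per-channel AR coefficients under the negated-sum sign convention.

    Returns ``p * n_channels`` features per trial, channel-major: the first
    ``p`` columns are channel 0's a_1..a_p, and so on.
    """
    p = cfg.order
    if epochs.n_samples < 2 * p:
        raise ValueError(
            f"trials of {epochs.n_samples} samples are too short for AR order {p} "
            f"(need >= {2 * p})"
        )
    out = np.empty((epochs.n_trials, p * epochs.n_channels))
    for t in range(epochs.n_trials):
        for c in range(epochs.n_channels):
            rho = _ar_fit(epochs.data[t, c], p, cfg.estimation_method)
            out[t, c * p : (c + 1) * p] = -rho  # a_i = -rho_i
    prov = tuple(
        Provenance("AR", name, i + 1)
        for name in epochs.channel_names
        for i in range(p)
    )
    return FeatureMatrix(values=out, provenance=prov)


# ---------------------------------------------------------------------------
# DWT features
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WaveletSpec:
    """Discrete wavelet decomposition settings.

    ``feature_level`` selects which decomposition level supplies the
    feature (mean of squared coefficients); ``coefficient_set`` chooses the
    detail or approximation coefficients at that level.
    """

    family: str = "db4"
    levels: int = 3
    boundary_mode: str = "symmetric"
    feature_level: int = 3
    coefficient_set: str = "detail"  # detail | approximation

    def __post_init__(self) -> None:
        if not 1 <= self.feature_level <= self.levels:
            raise ValueError(
                f"need 1 <= feature_level <= levels, got "
                f"({self.feature_level}, {self.levels})"
            )
        if self.coefficient_set not in ("detail", "approximation"):
            raise ValueError(f"unknown coefficient_set {self.coefficient_set!r}")
        pywt.Wavelet(self.family)  # raises for unknown families

    def min_samples(self) -> int:
        return pywt.Wavelet(self.family).dec_len * 2**self.levels


def dwt_decompose(x: np.ndarray, spec: WaveletSpec) -> list[np.ndarray]:
    """Full multilevel decomposition ``[cA_L, cD_L, ..., cD_1]`` of a 1-D signal."""
    return pywt.wavedec(x, spec.family, mode=spec.boundary_mode, level=spec.levels)


def dwt_features(epochs: EpochSet, spec: WaveletSpec = WaveletSpec()) -> FeatureMatrix:
    """Mean squared wavelet coefficients at ``spec.feature_level``, per channel."""
    if epochs.n_samples < spec.min_samples():
        raise ValueError(
            f"trials of {epochs.n_samples} samples are too short for a "
            f"{spec.levels}-level {spec.family} decomposition "
            f"(need >= {spec.min_samples()})"
        )
    out = np.empty((epochs.n_trials, epochs.n_channels))
    for t in range(epochs.n_trials):
        for c in range(epochs.n_channels):
            coeffs = dwt_decompose(epochs.data[t, c], spec)
            if spec.coefficient_set == "approximation":
                if spec.feature_level != spec.levels:
                    raise ValueError(
                        "approximation coefficients only exist at the deepest level"
                    )
                band = coeffs[0]
            else:
                band = coeffs[spec.levels - spec.feature_level + 1]
            out[t, c] = np.mean(band**2)
    prov = tuple(
        Provenance("DWT", name, spec.feature_level) for name in epochs.channel_names
    )
    return FeatureMatrix(values=out, provenance=prov)


# ---------------------------------------------------------------------------
# Fusion
# ---------------------------------------------------------------------------


def fuse_features(
    parts: list[FeatureMatrix] | tuple[FeatureMatrix, ...],
    standardize: bool = False,
    train_rows: np.ndarray | None = None,
) -> FeatureMatrix:
    """Column-wise concatenation of feature matrices, optionally z-scored.

    Standardization parameters (per-feature mean and standard deviation)
    are fitted on ``train_rows`` only (all rows if ``None``) and applied to
    every row, so held-out rows never leak into the scaling.  Constant
    columns get unit scale.
    """
    if not parts:
        raise ValueError("no feature matrices to fuse")
    n = parts[0].n_trials
    for p in parts[1:]:
        if p.n_trials != n:
            raise ValueError(
                f"trial-count mismatch between fused parts: {n} vs {p.n_trials}"
            )
    values = np.hstack([p.values for p in parts])
    prov = tuple(q for p in parts for q in p.provenance)
    if not standardize:
        return FeatureMatrix(values=values, provenance=prov)
    rows = np.arange(n) if train_rows is None else np.asarray(train_rows)
    mean = values[rows].mean(axis=0)
    scale = values[rows].std(axis=0, ddof=0)
    scale = np.where(scale > 0, scale, 1.0)
    return FeatureMatrix(
        values=(values - mean) / scale, provenance=prov, mean_=mean, scale_=scale
    )
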