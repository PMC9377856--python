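"""Shared fixtures: synthetic epochs reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

import eegfuse as ef


@pytest.fixture(scope="session")
def planted_epochs() -> ef.EpochSet:
    """Two-class epochs with a strong planted ERD (mu attenuation 0.4)."""
    cfg = ef.SyntheticConfig(
        n_trials_per_class=50, fs=128.0, erd_ratio=0.4, snr=2.0, seed=11
    )
    return ef.generate_mi_epochs(cfg)


@pytest.fixture(scope="session")
def filtered_epochs(planted_epochs: ef.EpochSet) -> ef.EpochSet:
    spec = ef.design_bandpass(8, 30, 4, planted_epochs.fs)
    return ef.apply_filter(planted_epochs, spec)


@pytest.fixture(scope="session")
def fused_features(filtered_epochs: ef.EpochSet) -> ef.FeatureMatrix:
    """Standard 24-column fused matrix: AR(18) + CSP(3) + DWT(3)."""
    ar = ef.ar_features(filtered_epochs, ef.ARConfig(order=6))
    filt = ef.csp_fit(filtered_epochs)
    csp = ef.csp_features(filtered_epochs, filt)
    dwt = ef.dwt_features(filtered_epochs, ef.WaveletSpec())
    return ef.fuse_features([ar, csp, dwt], standardize=True)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
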