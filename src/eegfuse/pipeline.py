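"""Full-pipeline orchestration: config, the comparison grid, and reports.

``run_pipeline`` ties the stages together: load (or synthesize) epochs,
band-pass filter, pick the analysis channels, then evaluate every
requested (feature-set x selector) configuration with cross-validation on
*identical folds*, so selector comparisons are paired and the t-tests on
their per-fold accuracies are valid.  The report is written as JSON plus a
flat CSV (one row per fold x configuration), and every random draw traces
back to the single seed recorded in the report.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classify import (
    CVReport,
    FeaturePipelineConfig,
    SVMConfig,
    cross_validate_pipeline,
    paired_ttest,
)
from .epochs import EpochSet
from .io import read_epochs
from .preprocess import apply_filter, design_bandpass, select_channels
from .synthetic import SyntheticConfig, generate_mi_epochs

__all__ = [
    "PipelineConfig",
    "load_config",
    "save_config",
    "run_pipeline",
    "FEATURE_SETS",
    "SELECTORS",
]

FEATURE_SETS: dict[str, tuple[str, ...]] = {
    "AR": ("ar",),
    "CSP": ("csp",),
    "DWT": ("dwt",),
    "AR+CSP+DWT": ("ar", "csp", "dwt"),
}
SELECTORS = ("none", "rfe", "pca", "et", "relieff")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one run needs, YAML-serializable and round-trippable."""

    # preprocessing
    low_hz: float = 8.0
    high_hz: float = 30.0
    filter_order: int = 4
    channels: tuple[str, ...] = ("C3", "Cz", "C4")
    # features
    ar_order: int = 6
    ar_method: str = "burg"
    wavelet_family: str = "db4"
    wavelet_levels: int = 3
    wavelet_feature_level: int = 3
    csp_log_variance: bool = False
    standardize: bool = True
    # selection
    selection: str = "all"  # one of SELECTORS or "all"
    n_keep: int = 20
    et_trees: int = 10
    et_min_split: int = 2
    relieff_k_neighbors: int = 10
    # feature sets to evaluate
    feature_sets: tuple[str, ...] = tuple(FEATURE_SETS)
    # classifier
    C_grid: tuple[float, ...] = tuple(10.0**k for k in range(-3, 4))
    cv_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.selection not in SELECTORS + ("all",):
            raise ValueError(
                f"selection must be one of {SELECTORS + ('all',)}, "
                f"got {self.selection!r}"
            )
        unknown = [f for f in self.feature_sets if f not in FEATURE_SETS]
        if unknown:
            raise ValueError(
                f"unknown feature set(s) {unknown}; choose from {list(FEATURE_SETS)}"
            )

    def selectors(self) -> tuple[str, ...]:
        return SELECTORS if self.selection == "all" else (self.selection,)

    def feature_pipeline(self, feature_set: str, selector: str) -> FeaturePipelineConfig:
        from .features import ARConfig, WaveletSpec
        from .selection import ETConfig

        return FeaturePipelineConfig(
            extractors=FEATURE_SETS[feature_set],
            ar=ARConfig(order=self.ar_order, estimation_method=self.ar_method),
            wavelet=WaveletSpec(
                family=self.wavelet_family,
                levels=self.wavelet_levels,
                feature_level=self.wavelet_feature_level,
            ),
            csp_log_variance=self.csp_log_variance,
            standardize=self.standardize,
            selector=None if selector == "none" else selector,
            n_keep=self.n_keep,
            et=ETConfig(
                n_trees=self.et_trees, min_split=self.et_min_split, seed=self.seed
            ),
            relieff_k_neighbors=self.relieff_k_neighbors,
        )

    def svm(self) -> SVMConfig:
        return SVMConfig(C_grid=self.C_grid, cv_folds=self.cv_folds, seed=self.seed)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    payload = asdict(config)
    # tuples -> lists for YAML; restored on load
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def load_config(path: str | Path) -> PipelineConfig:
    payload = yaml.safe_load(Path(path).read_text())
    for key in ("channels", "feature_sets", "C_grid"):
        if key in payload and payload[key] is not None:
            payload[key] = tuple(payload[key])
    return PipelineConfig(**payload)


@dataclass
class _RunLogger:
    lines: list[dict] = field(default_factory=list)

    def event(self, stage: str, **info) -> None:
        self.lines.append({"t": time.time(), "stage": stage, **info})

    def write(self, path: Path) -> None:
        path.write_text(
            "\n".join(json.dumps(line) for line in self.lines) + "\n"
            if self.lines
            else ""
        )


def _prepare_epochs(epochs: EpochSet, config: PipelineConfig) -> EpochSet:
    epochs = select_channels(epochs, config.channels)
    spec = design_bandpass(
        config.low_hz, config.high_hz, config.filter_order, epochs.fs
    )
    return apply_filter(epochs, spec)


def run_pipeline(
    config: PipelineConfig,
    epochs: EpochSet | None = None,
    epochs_path: str | Path | None = None,
    synthetic: SyntheticConfig | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Run the preprocess -> extract -> fuse -> select -> classify grid.

    Exactly one epoch source must be given: an in-memory ``epochs``, a
    native-format ``epochs_path``, or a ``synthetic`` generator config.
    Returns the report dict; if ``out_dir`` is given, also writes
    ``report.json``, ``report.csv`` (one row per fold x configuration) and
    ``run_log.jsonl`` there.
    """
    sources = [s is not None for s in (epochs, epochs_path, synthetic)]
    if sum(sources) != 1:
        raise ValueError("provide exactly one of epochs, epochs_path, synthetic")
    log = _RunLogger()
    if synthetic is not None:
        epochs = generate_mi_epochs(synthetic)
        log.event("simulate", seed=synthetic.seed, n_trials=epochs.n_trials)
    elif epochs_path is not None:
        epochs = read_epochs(epochs_path)
        log.event("load", path=str(epochs_path), n_trials=epochs.n_trials)

    t0 = time.time()
    prepared = _prepare_epochs(epochs, config)
    log.event("preprocess", seconds=time.time() - t0, channels=list(config.channels))

    reports: list[CVReport] = []
    for feature_set in config.feature_sets:
        for selector in config.selectors():
            t0 = time.time()
            try:
                rep = cross_validate_pipeline(
                    prepared,
                    config.feature_pipeline(feature_set, selector),
                    config.svm(),
                )
            except Exception as exc:
                raise RuntimeError(
                    f"configuration ({feature_set}, {selector}): {exc}"
                ) from exc
            reports.append(rep)
            log.event(
                "evaluate",
                feature_set=feature_set,
                selector=selector,
                mean_accuracy=rep.mean_accuracy,
                seconds=time.time() - t0,
            )

    comparisons = []
    # selectors share folds within a feature set -> paired tests are valid
    by_fs: dict[str, list[CVReport]] = {}
    for rep in reports:
        by_fs.setdefault(rep.feature_set, []).append(rep)
    for feature_set, reps in by_fs.items():
        for ra, rb in combinations(reps, 2):
            t, p = paired_ttest(ra.fold_accuracies, rb.fold_accuracies)
            comparisons.append(
                {
                    "feature_set": feature_set,
                    "selector_a": ra.selector,
                    "selector_b": rb.selector,
                    "mean_diff": ra.mean_accuracy - rb.mean_accuracy,
                    "t": None if np.isnan(t) else t,
                    "p": p,
                }
            )

    report = {
        "schema_version": 1,
        "seed": config.seed,
        "config": asdict(config),
        "results": [rep.to_dict() for rep in reports],
        "comparisons": comparisons,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n"
        )
        rows = [
            {
                "feature_set": rep.feature_set,
                "selector": rep.selector,
                "fold": f.fold,
                "accuracy": f.accuracy,
                "chosen_C": f.chosen_C,
                "n_features_used": f.n_features_used,
            }
            for rep in reports
            for f in rep.folds
        ]
        pd.DataFrame(rows).to_csv(out_dir / "report.csv", index=False)
        log.write(out_dir / "run_log.jsonl")
    return report
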