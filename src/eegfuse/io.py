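"""Reading and writing epochs in the pipeline's native on-disk format.

The native format is deliberately plain: a long-format CSV
(``trial_id,channel,sample_index,value``) next to a JSON sidecar holding
the sampling rate, the channel order, the per-trial labels and a schema
version.  Floats are written with shortest round-trip ``repr``, so a
write/read cycle is bit-identical and the byte output is stable for a
given EpochSet.

EDF/GDF recordings (e.g. the Graz BCI-competition files) can be adapted
through the optional mne-backed reader; epoching windows and event codes
come from the caller since competition files differ.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .epochs import EpochSet

__all__ = ["read_epochs", "write_epochs", "read_raw_epochs_mne", "SCHEMA_VERSION"]

SCHEMA_VERSION = 1
_DATA_NAME = "epochs.csv"
_META_NAME = "epochs.json"


def write_epochs(epochs: EpochSet, path: str | Path) -> tuple[Path, Path]:
    """Write an EpochSet to ``path`` (a directory) as CSV + JSON sidecar.

    Row order is deterministic: trial-major, then channel, then sample.
    Returns the (data, sidecar) paths.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    data_path = path / _DATA_NAME
    meta_path = path / _META_NAME
    lines = ["trial_id,channel,sample_index,value"]
    for t in range(epochs.n_trials):
        for c, name in enumerate(epochs.channel_names):
            for s in range(epochs.n_samples):
                lines.append(f"{t},{name},{s},{float(epochs.data[t, c, s])!r}")
    data_path.write_text("\n".join(lines) + "\n")
    meta = {
        "schema_version": SCHEMA_VERSION,
        "fs": epochs.fs,
        "channel_names": list(epochs.channel_names),
        "labels": {str(t): str(epochs.labels[t]) for t in range(epochs.n_trials)},
    }
    meta_path.write_text(json.dumps(meta, indent=2) + "\n")
    return data_path, meta_path


def _read_native(path: Path) -> EpochSet:
    data_path = path / _DATA_NAME
    meta_path = path / _META_NAME
    for p in (data_path, meta_path):
        if not p.exists():
            raise FileNotFoundError(f"missing native epoch file {p}")
    meta = json.loads(meta_path.read_text())
    if "schema_version" not in meta:
        raise ValueError(f"{meta_path}: sidecar lacks schema_version")
    fs = float(meta["fs"])
    channel_names = tuple(meta["channel_names"])
    df = pd.read_csv(data_path, float_precision="round_trip")
    required = {"trial_id", "channel", "sample_index", "value"}
    if set(df.columns) != required:
        raise ValueError(
            f"{data_path}: expected columns {sorted(required)}, got {list(df.columns)}"
        )
    trial_ids = np.sort(df["trial_id"].unique())
    labels_map = meta["labels"]
    missing = [str(t) for t in trial_ids if str(t) not in labels_map]
    if missing:
        raise ValueError(f"{meta_path}: sidecar lacks labels for trial_id(s) {missing}")
    counts = df.groupby(["trial_id", "channel"]).size()
    if counts.nunique() != 1:
        bad = counts[counts != counts.iloc[0]].index.tolist()[:5]
        raise ValueError(
            f"{data_path}: unequal sample counts per (trial, channel), e.g. {bad}"
        )
    n_samples = int(counts.iloc[0])
    n_trials = trial_ids.size
    data = np.empty((n_trials, len(channel_names), n_samples))
    df = df.sort_values(["trial_id", "channel", "sample_index"], kind="stable")
    grouped = {k: g for k, g in df.groupby(["trial_id", "channel"])}
    for ti, t in enumerate(trial_ids):
        for c, name in enumerate(channel_names):
            key = (t, name)
            if key not in grouped:
                raise ValueError(f"{data_path}: no rows for trial {t}, channel {name}")
            data[ti, c] = grouped[key]["value"].to_numpy()
    labels = np.array([labels_map[str(t)] for t in trial_ids])
    return EpochSet(data=data, labels=labels, fs=fs, channel_names=channel_names)


def read_raw_epochs_mne(
    path: str | Path,
    fmt: str,
    event_id: dict[str, int],
    tmin: float,
    tmax: float,
) -> EpochSet:
    """Epoch an EDF/GDF recording around its annotated cues (requires mne).

    ``event_id`` maps class labels to annotation codes; the analysis window
    is ``[tmin, tmax]`` seconds relative to each cue onset.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - mne is an optional extra
        raise ImportError(
            "reading EDF/GDF requires the optional 'mne' dependency "
            "(pip install eegfuse[edf])"
        ) from exc
    reader = {"edf": mne.io.read_raw_edf, "gdf": mne.io.read_raw_gdf}[fmt]
    raw = reader(str(path), preload=True, verbose="error")
    events, mapping = mne.events_from_annotations(raw, verbose="error")
    wanted = {label: mapping[str(code)] for label, code in event_id.items()
              if str(code) in mapping}
    if not wanted:
        wanted = {label: code for label, code in event_id.items()}
    ep = mne.Epochs(
        raw, events, event_id=wanted, tmin=tmin, tmax=tmax,
        baseline=None, preload=True, verbose="error",
    )
    inv = {v: k for k, v in wanted.items()}
    labels = np.array([inv[e] for e in ep.events[:, 2]])
    return EpochSet(
        data=ep.get_data(copy=True),
        labels=labels,
        fs=float(ep.info["sfreq"]),
        channel_names=tuple(ep.ch_names),
    )


def read_epochs(
    path: str | Path,
    fmt: str = "native_csv",
    event_id: dict[str, int] | None = None,
    tmin: float = 0.5,
    tmax: float = 3.5,
) -> EpochSet:
    """Load epochs from the native CSV/JSON format or an EDF/GDF recording."""
    path = Path(path)
    if fmt == "native_csv":
        return _read_native(path)
    if fmt in ("edf", "gdf"):
        if event_id is None:
            raise ValueError("edf/gdf reading requires an event_id mapping")
        return read_raw_epochs_mne(path, fmt, event_id, tmin, tmax)
    raise ValueError(f"unknown format {fmt!r}; expected native_csv, edf or gdf")
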