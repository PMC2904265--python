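"""Serialization: recordings and epochs to HDF5, tables to TSV, models to JSON.

Recordings are stored as an HDF5 container (data in microvolts, sampling
rate and channel labels as attributes) with a tab-separated event sidecar
(``<stem>.events.tsv``) so the marker stream stays human-readable.
"""

from __future__ import annotations

import io as _stdlib_io
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .classification import FeatureSpec, LDAModel
from .paradigm import TrialSchedule
from .preprocessing import EpochSet
from .synth import Recording

_EVENT_COLUMNS = ["sample", "index", "level", "phase", "element_id",
                  "is_target"]


def _sidecar(path: Path) -> Path:
    return path.with_suffix("").with_suffix(".events.tsv")


def write_recording(recording: Recording, path: str | Path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        d = f.create_dataset("samples", data=recording.samples,
                             compression="gzip", compression_opts=1)
        d.attrs["units"] = "uV"
        f.attrs["fs_hz"] = recording.fs_hz
        f.attrs["channel_labels"] = list(recording.channel_labels)
    ev = recording.events[_EVENT_COLUMNS].copy()
    ev["is_target"] = ev["is_target"].astype(int)
    ev.to_csv(_sidecar(path), sep="\t", index=False)
    return path


def read_recording(path: str | Path) -> Recording:
    path = Path(path)
    sidecar = _sidecar(path)
    if not sidecar.exists():
        raise FileNotFoundError(
            f"event sidecar {sidecar} missing for recording {path}"
        )
    with h5py.File(path, "r") as f:
        samples = f["samples"][()]
        fs = float(f.attrs["fs_hz"])
        labels = tuple(str(x) for x in f.attrs["channel_labels"])
    events = pd.read_csv(sidecar, sep="\t")
    missing = set(_EVENT_COLUMNS) - set(events.columns)
    if missing:
        raise ValueError(f"event sidecar lacks columns: {sorted(missing)}")
    if len(events) == 0:
        raise ValueError("event sidecar is empty; nothing to epoch")
    events["is_target"] = events["is_target"].astype(bool)
    # Recording.__post_init__ re-validates sample ranges against the data.
    return Recording(channel_labels=labels, fs_hz=fs, samples=samples,
                     events=events)


def schedule_to_tsv(schedule: TrialSchedule, path: str | Path) -> Path:
    path = Path(path)
    frame = schedule.to_frame().copy()
    frame["is_target"] = frame["is_target"].astype(int)
    frame.to_csv(path, sep="\t", index=False)
    return path


def read_schedule_frame(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    frame["is_target"] = frame["is_target"].astype(bool)
    return frame


def write_epochs(epochs: EpochSet, path: str | Path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data, compression="gzip",
                         compression_opts=1)
        f.create_dataset("times_ms", data=epochs.times_ms)
        f.create_dataset("labels", data=epochs.labels.astype(np.int8))
        f.create_dataset("kept", data=epochs.kept.astype(np.int8))
        f.create_dataset(
            "reasons",
            data=np.array([r.encode() for r in epochs.reasons]),
        )
        f.attrs["fs_hz"] = epochs.fs_hz
        f.attrs["channels"] = list(epochs.channels)
        f.attrs["meta_json"] = epochs.meta.to_json(orient="split")
    return path


def read_epochs(path: str | Path) -> EpochSet:
    with h5py.File(path, "r") as f:
        meta = pd.read_json(
            _stdlib_io.StringIO(str(f.attrs["meta_json"])), orient="split"
        )
        return EpochSet(
            data=f["data"][()],
            times_ms=f["times_ms"][()],
            channels=tuple(str(c) for c in f.attrs["channels"]),
            labels=f["labels"][()].astype(bool),
            kept=f["kept"][()].astype(bool),
            reasons=np.array([r.decode() for r in f["reasons"][()]],
                             dtype=object),
            meta=meta,
            fs_hz=float(f.attrs["fs_hz"]),
        )


def model_to_json(model: LDAModel, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "weights": model.weights.tolist(),
        "bias": model.bias,
        "gamma": model.gamma,
        "feature_spec": None,
    }
    if model.feature_spec is not None:
        payload["feature_spec"] = {
            "channels": list(model.feature_spec.channels),
            "windows": [list(w) for w in model.feature_spec.windows],
        }
    path.write_text(json.dumps(payload, indent=1))
    return path


def model_from_json(path: str | Path) -> LDAModel:
    payload = json.loads(Path(path).read_text())
    spec = None
    if payload["feature_spec"] is not None:
        spec = FeatureSpec(
            channels=tuple(payload["feature_spec"]["channels"]),
            windows=tuple(tuple(w) for w in payload["feature_spec"]["windows"]),
        )
    return LDAModel(
        weights=np.asarray(payload["weights"], dtype=float),
        bias=float(payload["bias"]),
        gamma=float(payload["gamma"]),
        feature_spec=spec,
    )


def load_config_file(path: str | Path) -> dict:
    """Read a JSON or YAML experiment configuration into a plain dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)
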