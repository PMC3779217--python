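"""Epoch container I/O: raw float32 binary plus a JSON sidecar.

One directory per subject holds ``epochs.bin`` (little-endian 32-bit
floats, trial-major, dimensions declared in the sidecar) and
``epochs.json`` (sampling rate, epoch offset, channel names, per-trial
labels, subject id and provenance).  A long-format CSV alternative
(subject, trial, label, channel, sample_index, value) is accepted for
tiny fixtures.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ConfigurationError
from .simulate import EpochSet

__all__ = ["write_epochs", "read_epochs", "write_epochs_csv",
           "read_epochs_csv", "write_array", "read_array"]


def write_epochs(epochs: EpochSet, directory, provenance: dict | None = None) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    data = np.ascontiguousarray(epochs.data, dtype="<f4")
    (directory / "epochs.bin").write_bytes(data.tobytes())
    sidecar = {
        "shape": list(epochs.data.shape),
        "dtype": "<f4",
        "order": "trial-major",
        "fs_hz": epochs.fs_hz,
        "t0_offset_ms": epochs.t0_offset_ms,
        "channel_names": list(epochs.channel_names),
        "labels": list(epochs.labels),
        "subject_id": epochs.subject_id,
        "provenance": provenance or {},
    }
    (directory / "epochs.json").write_text(json.dumps(sidecar, indent=1))
    return directory


def read_epochs(directory) -> EpochSet:
    directory = Path(directory)
    sidecar = json.loads((directory / "epochs.json").read_text())
    shape = tuple(sidecar["shape"])
    raw = np.frombuffer((directory / "epochs.bin").read_bytes(),
                        dtype=sidecar.get("dtype", "<f4"))
    if raw.size != int(np.prod(shape)):
        raise ConfigurationError(
            f"{directory}: binary holds {raw.size} values, sidecar declares "
            f"shape {shape}"
        )
    return EpochSet(
        data=raw.reshape(shape).astype(float),
        fs_hz=float(sidecar["fs_hz"]),
        t0_offset_ms=float(sidecar["t0_offset_ms"]),
        channel_names=tuple(sidecar["channel_names"]),
        labels=tuple(sidecar["labels"]),
        subject_id=sidecar.get("subject_id", "S00"),
    )


def write_epochs_csv(epochs: EpochSet, path) -> Path:
    """Long-format CSV for tiny fixtures (one row per sample)."""
    n_tr, n_ch, n_s = epochs.data.shape
    tr, ch, sm = np.meshgrid(np.arange(n_tr), np.arange(n_ch),
                             np.arange(n_s), indexing="ij")
    df = pd.DataFrame({
        "subject": epochs.subject_id,
        "trial": tr.ravel(),
        "label": np.asarray(epochs.labels)[tr.ravel()],
        "channel": np.asarray(epochs.channel_names)[ch.ravel()],
        "sample_index": sm.ravel(),
        "value": epochs.data.ravel(),
    })
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def read_epochs_csv(path, fs_hz: float, t0_offset_ms: float) -> EpochSet:
    df = pd.read_csv(path)
    trials = np.sort(df["trial"].unique())
    channels = tuple(df[df["trial"] == trials[0]]["channel"].unique())
    n_s = int(df["sample_index"].max()) + 1
    data = np.zeros((len(trials), len(channels), n_s))
    labels = []
    ch_index = {c: i for i, c in enumerate(channels)}
    for t_i, trial in enumerate(trials):
        sub = df[df["trial"] == trial]
        labels.append(sub["label"].iloc[0])
        for ch, grp in sub.groupby("channel"):
            data[t_i, ch_index[ch], grp["sample_index"].to_numpy()] = \
                grp["value"].to_numpy()
    return EpochSet(data=data, fs_hz=fs_hz, t0_offset_ms=t0_offset_ms,
                    channel_names=channels, labels=tuple(labels),
                    subject_id=str(df["subject"].iloc[0]))


def write_array(array: np.ndarray, directory, name: str,
                meta: dict | None = None) -> Path:
    """Generic binary+JSON pair for masks, count maps and spectrograms."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    arr = np.ascontiguousarray(array, dtype="<f4")
    (directory / f"{name}.bin").write_bytes(arr.tobytes())
    sidecar = {"shape": list(array.shape), "dtype": "<f4"}
    sidecar.update(meta or {})
    (directory / f"{name}.json").write_text(json.dumps(sidecar, indent=1))
    return directory / f"{name}.bin"


def read_array(directory, name: str):
    directory = Path(directory)
    sidecar = json.loads((directory / f"{name}.json").read_text())
    raw = np.frombuffer((directory / f"{name}.bin").read_bytes(),
                        dtype=sidecar.get("dtype", "<f4"))
    return raw.reshape(tuple(sidecar["shape"])).astype(float), sidecar
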