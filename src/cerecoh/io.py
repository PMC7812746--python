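"""File formats: HDF5 recording container, TSV tables, YAML configs.

Recording container layout (HDF5)::

    /signal                  float dataset, (n_samples, n_channels)
    /meta                    group
        @sampling_rate       Hz (scalar attribute, required)
        /channel_depth_um    float dataset, one value per channel
        /area                string dataset, one label per channel

Event tables are sidecar TSV files with columns ``onset_s`` (float,
seconds) and ``condition`` (string).  Behavior traces use TSV with
columns ``trial``, ``time_s``, ``angle_deg``.  All writes round-trip
bit-identically.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .containers import EventTable, MultichannelRecording

__all__ = [
    "read_recording",
    "write_recording",
    "read_events",
    "write_events",
    "read_behavior_traces",
    "write_behavior_traces",
    "load_config",
    "config_hash",
]


def write_recording(rec: MultichannelRecording, path) -> None:
    """Write a recording to the documented HDF5 layout."""
    with h5py.File(path, "w") as fh:
        fh.create_dataset("signal", data=rec.data)
        meta = fh.create_group("meta")
        meta.attrs["sampling_rate"] = float(rec.sampling_rate)
        meta.create_dataset("channel_depth_um", data=rec.channel_depth_um)
        meta.create_dataset("area", data=np.asarray(rec.area, dtype=object),
                            dtype=h5py.string_dtype("utf-8"))


def read_recording(path) -> MultichannelRecording:
    """Read a recording; missing metadata fails hard, naming the field."""
    with h5py.File(path, "r") as fh:
        if "signal" not in fh:
            raise KeyError(f"{path}: missing dataset 'signal'")
        if "meta" not in fh:
            raise KeyError(f"{path}: missing group 'meta'")
        meta = fh["meta"]
        if "sampling_rate" not in meta.attrs:
            raise KeyError(f"{path}: missing metadata field 'sampling_rate'")
        for name in ("channel_depth_um", "area"):
            if name not in meta:
                raise KeyError(f"{path}: missing metadata field '{name}'")
        return MultichannelRecording(
            data=fh["signal"][()],
            sampling_rate=float(meta.attrs["sampling_rate"]),
            channel_depth_um=meta["channel_depth_um"][()],
            area=[a.decode() if isinstance(a, bytes) else str(a) for a in meta["area"][()]],
        )


def write_events(events: EventTable, path) -> None:
    events.frame.to_csv(path, sep="\t", index=False)


def read_events(path) -> EventTable:
    """Read a TSV event table; malformed rows abort with line numbers."""
    frame = pd.read_csv(path, sep="\t", dtype={"condition": str})
    missing = [c for c in EventTable.REQUIRED if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    onsets = pd.to_numeric(frame["onset_s"], errors="coerce")
    bad = frame.index[onsets.isna() | frame["condition"].isna()]
    if len(bad):
        lines = ", ".join(str(i + 2) for i in bad[:10])  # +2: header + 1-based
        raise ValueError(f"{path}: malformed rows at lines {lines}; load aborted")
    frame["onset_s"] = onsets
    return EventTable(frame)


def write_behavior_traces(traces: np.ndarray, sampling_rate: float, pre: float, path) -> None:
    """Write per-trial whisker-angle traces as long-format TSV."""
    n_trials, n_samples = traces.shape
    t = np.arange(n_samples) / sampling_rate - pre
    frame = pd.DataFrame(
        {
            "trial": np.repeat(np.arange(n_trials), n_samples),
            "time_s": np.tile(t, n_trials),
            "angle_deg": traces.ravel(),
        }
    )
    frame.to_csv(path, sep="\t", index=False)


def read_behavior_traces(path) -> tuple[np.ndarray, np.ndarray]:
    """Read whisker traces; returns (traces (n_trials, n_samples), times)."""
    frame = pd.read_csv(path, sep="\t")
    for col in ("trial", "time_s", "angle_deg"):
        if col not in frame.columns:
            raise ValueError(f"{path}: missing column '{col}'")
    trials = sorted(frame["trial"].unique())
    times = frame.loc[frame["trial"] == trials[0], "time_s"].to_numpy()
    traces = np.stack(
        [frame.loc[frame["trial"] == k, "angle_deg"].to_numpy() for k in trials]
    )
    return traces, times


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return cfg


def config_hash(cfg: dict) -> str:
    """Stable short hash of a config mapping, recorded in every output."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
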