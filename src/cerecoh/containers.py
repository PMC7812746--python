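"""Core in-memory containers shared across the analysis pipeline.

The package revolves around three light-weight containers:

``MultichannelRecording``
    A continuous multichannel signal (laminar LFP or a model-derived
    proxy) with its sampling rate and per-channel depth/area metadata.

``EventTable``
    Stimulus onsets with condition labels.  Internally a thin wrapper
    around a :class:`pandas.DataFrame` with columns ``onset_s`` and
    ``condition``.

``TrialTensor``
    Event-aligned trial segments, shaped ``(n_trials, n_channels,
    n_samples)``, carrying the segmentation window and condition labels.

All times are seconds, frequencies Hz, depths micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["MultichannelRecording", "EventTable", "TrialTensor"]


@dataclass
class MultichannelRecording:
    """Continuous multichannel signal with channel metadata.

    Parameters
    ----------
    data:
        Array of shape ``(n_samples, n_channels)``.
    sampling_rate:
        Sampling rate in Hz.
    channel_depth_um:
        Depth of each channel below the pial surface, in micrometres.
    area:
        Area label per channel (e.g. ``"S1"`` / ``"M1"``).
    """

    data: np.ndarray
    sampling_rate: float
    channel_depth_um: np.ndarray
    area: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (n_samples, n_channels)")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        self.channel_depth_um = np.asarray(self.channel_depth_um, dtype=float)
        self.area = list(self.area)
        n_ch = self.data.shape[1]
        if len(self.channel_depth_um) != n_ch or len(self.area) != n_ch:
            raise ValueError("channel metadata length must match n_channels")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate

    def channels_in_area(self, area: str) -> np.ndarray:
        """Indices of channels belonging to ``area``."""
        return np.flatnonzero(np.asarray(self.area) == area)


class EventTable:
    """Stimulus onset table with condition labels.

    Wraps a :class:`pandas.DataFrame` with columns ``onset_s`` (float,
    seconds) and ``condition`` (str).
    """

    REQUIRED = ("onset_s", "condition")

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in frame.columns]
        if missing:
            raise ValueError(f"event table missing columns: {missing}")
        self.frame = frame.reset_index(drop=True)

    @classmethod
    def from_onsets(cls, onsets, conditions) -> "EventTable":
        onsets = np.asarray(onsets, dtype=float)
        conditions = np.asarray(conditions, dtype=object)
        if conditions.shape == ():  # a single label for all events
            conditions = np.repeat(conditions, len(onsets))
        if len(onsets) != len(conditions):
            raise ValueError("onsets and conditions must have equal length")
        return cls(pd.DataFrame({"onset_s": onsets, "condition": conditions}))

    @property
    def onsets(self) -> np.ndarray:
        return self.frame["onset_s"].to_numpy(dtype=float)

    @property
    def conditions(self) -> np.ndarray:
        return self.frame["condition"].to_numpy(dtype=object)

    def __len__(self) -> int:
        return len(self.frame)

    def select(self, condition: str) -> "EventTable":
        return EventTable(self.frame[self.frame["condition"] == condition])


@dataclass
class TrialTensor:
    """Event-aligned trial segments.

    ``data`` has shape ``(n_trials, n_channels, n_samples)``; samples run
    over the half-open window ``[-pre, post)`` around each event onset.
    """

    data: np.ndarray
    sampling_rate: float
    window: tuple[float, float]  # (pre, post), both positive, seconds
    conditions: np.ndarray = field(default=None)
    channel_depth_um: np.ndarray | None = None
    area: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be 3-D (n_trials, n_channels, n_samples)")
        pre, post = self.window
        if pre < 0 or post <= 0:
            raise ValueError("window must satisfy pre >= 0 and post > 0")
        if self.conditions is None:
            self.conditions = np.asarray(["trial"] * self.data.shape[0], dtype=object)
        else:
            self.conditions = np.asarray(self.conditions, dtype=object)
        if len(self.conditions) != self.data.shape[0]:
            raise ValueError("conditions length must match n_trials")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Time axis relative to event onset (onset at t = 0)."""
        pre, _ = self.window
        return np.arange(self.n_samples) / self.sampling_rate - pre

    @property
    def onset_index(self) -> int:
        """Sample index of the event onset."""
        return int(round(self.window[0] * self.sampling_rate))

    def select(self, condition: str) -> "TrialTensor":
        mask = self.conditions == condition
        return TrialTensor(
            self.data[mask],
            self.sampling_rate,
            self.window,
            self.conditions[mask],
            self.channel_depth_um,
            self.area,
        )

    def channel(self, index: int) -> "TrialTensor":
        """Single-channel view as a new tensor."""
        return TrialTensor(
            self.data[:, [index], :],
            self.sampling_rate,
            self.window,
            self.conditions,
            None if self.channel_depth_um is None else self.channel_depth_um[[index]],
            None if self.area is None else [self.area[index]],
        )
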