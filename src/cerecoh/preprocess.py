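"""Trial segmentation, event-related averaging, peak metrics and CSD.

Conventions (documented, not taken from any single standard):

* Baseline window defaults to -1.0 .. -0.1 s before onset, avoiding
  stimulus bleed into the baseline statistics.
* Peak search window defaults to 0 .. 200 ms after onset, the span of
  the transient evoked deflection.
* Probe channels are numbered 1..n; channel 3 serves as the
  supragranular and channel 10 as the subgranular reference on a
  14-channel probe.
* CSD sign convention: sinks negative, ``csd_i = -(phi_{i-1} - 2 phi_i
  + phi_{i+1}) / h**2`` on interior channels of a uniformly spaced
  probe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .containers import EventTable, MultichannelRecording, TrialTensor

__all__ = [
    "ErpResult",
    "PeakMetrics",
    "CsdProfile",
    "segment_trials",
    "event_related_average",
    "peak_metrics",
    "csd_profile",
]

logger = logging.getLogger(__name__)

DEFAULT_BASELINE = (-1.0, -0.1)
DEFAULT_PEAK_WINDOW = (0.0, 0.2)
SUPRAGRANULAR_CHANNEL = 3
SUBGRANULAR_CHANNEL = 10


@dataclass
class ErpResult:
    """Event-related average with per-channel Z-scored traces."""

    mean: np.ndarray  # (n_channels, n_samples)
    zscored: np.ndarray  # same shape; NaN rows where Z-scoring was refused
    times: np.ndarray  # s, onset at 0
    n_trials: int
    baseline_window: tuple[float, float]
    sampling_rate: float
    channel_depth_um: np.ndarray | None = None

    @property
    def n_channels(self) -> int:
        return self.mean.shape[0]


@dataclass
class PeakMetrics:
    """First negative / first positive peak of an evoked trace.

    Amplitudes are relative to the baseline mean; an absent peak is
    reported as ``None``, never as zero.
    """

    neg_amplitude: float | None
    neg_latency_s: float | None
    pos_amplitude: float | None
    pos_latency_s: float | None
    search_window: tuple[float, float]


@dataclass
class CsdProfile:
    """Second-spatial-derivative profile; sinks are negative."""

    csd: np.ndarray  # (n_channels - 2, n_samples)
    channels: np.ndarray  # 1-based interior channel numbers
    spacing_um: float
    times: np.ndarray


def segment_trials(
    rec: MultichannelRecording,
    events: EventTable,
    window: tuple[float, float],
) -> TrialTensor:
    """Slice ``rec`` into trials over the half-open window [-pre, post).

    Events whose window does not fit inside the recording are dropped
    with a log message rather than silently truncated.
    """
    pre, post = window
    if pre < 0 or post <= 0:
        raise ValueError("window must satisfy pre >= 0 and post > 0")
    fs = rec.sampling_rate
    n_pre = int(round(pre * fs))
    n_post = int(round(post * fs))
    slices, kept = [], []
    for i, onset in enumerate(events.onsets):
        onset_idx = int(round(onset * fs))
        start, stop = onset_idx - n_pre, onset_idx + n_post
        if start < 0 or stop > rec.n_samples:
            logger.warning(
                "dropping event %d at t=%.3f s: window [%.3f, %.3f) s outside recording",
                i, onset, onset - pre, onset + post,
            )
            continue
        slices.append(rec.data[start:stop].T)  # (n_channels, n_samples)
        kept.append(i)
    if not slices:
        raise ValueError("no event fits inside the recording with this window")
    data = np.stack(slices, axis=0)
    return TrialTensor(
        data,
        fs,
        window,
        events.conditions[kept],
        channel_depth_um=rec.channel_depth_um,
        area=rec.area,
    )


def event_related_average(
    trials: TrialTensor,
    baseline_window: tuple[float, float] = DEFAULT_BASELINE,
) -> ErpResult:
    """Average trials and Z-score each channel on its baseline statistics.

    The Z-score uses the mean and standard deviation of the *averaged*
    trace within ``baseline_window`` (seconds relative to onset, both
    negative for a pre-stimulus baseline).  Channels with zero baseline
    variance get NaN Z-scores and a diagnostic, never a silent division.
    """
    if trials.n_trials < 2:
        raise ValueError("event-related averaging requires >= 2 trials")
    t = trials.times
    b_lo, b_hi = baseline_window
    mask = (t >= b_lo) & (t < b_hi)
    if not mask.any():
        raise ValueError(f"baseline window {baseline_window} outside trial window")
    mean = trials.data.mean(axis=0)  # (n_channels, n_samples)
    base_mean = mean[:, mask].mean(axis=1, keepdims=True)
    base_sd = mean[:, mask].std(axis=1, ddof=1, keepdims=True)
    z = np.full_like(mean, np.nan)
    ok = base_sd[:, 0] > 0
    if not ok.all():
        for ch in np.flatnonzero(~ok):
            logger.warning("channel %d: zero baseline variance, Z-scoring refused", ch + 1)
    z[ok] = (mean[ok] - base_mean[ok]) / base_sd[ok]
    return ErpResult(
        mean=mean,
        zscored=z,
        times=t,
        n_trials=trials.n_trials,
        baseline_window=baseline_window,
        sampling_rate=trials.sampling_rate,
        channel_depth_um=trials.channel_depth_um,
    )


def _first_extremum(
    trace: np.ndarray, comparator, threshold: float
) -> int | None:
    """Index of the first local extremum passing ``comparator`` vs threshold."""
    for i in range(1, len(trace) - 1):
        if comparator(trace[i], trace[i - 1]) and comparator(trace[i], trace[i + 1]):
            if comparator(trace[i], threshold):
                return i
    return None


def peak_metrics(
    erp: ErpResult,
    channel: int,
    search_window: tuple[float, float] = DEFAULT_PEAK_WINDOW,
    use_zscored: bool = False,
) -> PeakMetrics:
    """First negative then first positive evoked peak on one channel.

    ``channel`` is 1-based (probe numbering).  The first local minimum
    below the baseline mean is the negative peak; the first subsequent
    local maximum above baseline is the positive peak.  Amplitudes are
    baseline-subtracted, so they are invariant to constant offsets.
    """
    traces = erp.zscored if use_zscored else erp.mean
    if not 1 <= channel <= erp.n_channels:
        raise ValueError(f"channel must lie in [1, {erp.n_channels}]")
    trace = traces[channel - 1]
    t = erp.times
    lo, hi = search_window
    if lo < t[0] or hi > t[-1] + 1.0 / erp.sampling_rate:
        raise ValueError("search window outside the trial window")
    b_lo, b_hi = erp.baseline_window
    base = trace[(t >= b_lo) & (t < b_hi)].mean()
    sel = np.flatnonzero((t >= lo) & (t < hi))
    seg = trace[sel] - base
    seg_t = t[sel]

    neg_i = _first_extremum(seg, np.less, 0.0)
    neg_amp = neg_lat = pos_amp = pos_lat = None
    if neg_i is not None:
        neg_amp, neg_lat = float(seg[neg_i]), float(seg_t[neg_i])
        rest = seg[neg_i:]
        pos_i = _first_extremum(rest, np.greater, 0.0)
        if pos_i is not None:
            pos_amp = float(rest[pos_i])
            pos_lat = float(seg_t[neg_i + pos_i])
    else:
        pos_i = _first_extremum(seg, np.greater, 0.0)
        if pos_i is not None:
            pos_amp, pos_lat = float(seg[pos_i]), float(seg_t[pos_i])
    return PeakMetrics(neg_amp, neg_lat, pos_amp, pos_lat, search_window)


def csd_profile(
    erp: ErpResult,
    spacing_um: float | None = None,
    smooth: bool = False,
) -> CsdProfile:
    """Current source density of a laminar ERP (sinks negative).

    Standard second spatial difference on a uniformly spaced probe.  If
    per-channel depths are available they must be uniformly spaced;
    otherwise ``spacing_um`` must be given.  Optional three-point
    spatial smoothing before differencing.
    """
    if erp.n_channels < 3:
        raise ValueError("CSD requires at least 3 channels")
    if erp.channel_depth_um is not None and len(set(np.round(np.diff(erp.channel_depth_um), 6))) > 1:
        raise ValueError("CSD requires uniform electrode spacing")
    if spacing_um is None:
        if erp.channel_depth_um is None:
            raise ValueError("spacing_um required when depths are unknown")
        spacing_um = float(np.diff(erp.channel_depth_um)[0])
    phi = erp.mean
    if smooth:
        phi = np.vstack(
            [phi[0], *(0.25 * phi[i - 1] + 0.5 * phi[i] + 0.25 * phi[i + 1] for i in range(1, len(phi) - 1)), phi[-1]]
        )
    h2 = spacing_um**2
    csd = -(phi[:-2] - 2 * phi[1:-1] + phi[2:]) / h2
    channels = np.arange(2, erp.n_channels)
    return CsdProfile(csd=csd, channels=channels, spacing_um=spacing_um, times=erp.times)
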