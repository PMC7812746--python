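"""Surrogate laminar LFP and behavior generators with known ground truth.

Every analysis stage in this package (event-related averaging, CSD,
coherence, Granger causality, the behavior-linked predictor) is exercised
on surrogate data whose spectral and causal structure is known by
construction:

* Two simulated "areas" of laminar channels share a stochastic
  narrowband component.  The shared component is a noise-driven damped
  harmonic oscillator (an AR(2) process), whose analytic spectrum makes
  the requested coherence level exactly computable: mixing
  ``sqrt(c)*shared + sqrt(1-c)*private`` with equal-spectrum components
  yields inter-area coherence ``c`` at every frequency of the band.
* A directed inter-area lag is a pure sample delay of the shared
  component into the second area, giving a linear phase slope and a
  known Granger direction.
* 50 Hz line contamination is a fixed-amplitude sinusoid with a random
  phase per trial.
* Evoked responses are biphasic (negative-then-positive) transients with
  a smooth laminar amplitude profile.
* Trial-varying whisker protraction amplitudes can be linked to the
  inter-area coupling strength, emulating behavior-dependent coherence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .containers import EventTable, MultichannelRecording, TrialTensor

__all__ = [
    "EvokedTemplate",
    "SurrogateSpec",
    "BehaviorLinkSpec",
    "ar2_coefficients",
    "narrowband_process",
    "gen_coupled_lfp",
    "gen_laminar_volley",
    "gen_behavior_dataset",
]


# ---------------------------------------------------------------------------
# narrowband AR(2) building block


def ar2_coefficients(f0: float, bandwidth: float, fs: float) -> tuple[float, float]:
    """AR(2) coefficients of a stochastic oscillator at ``f0`` Hz.

    Poles at radius ``r = exp(-pi * bandwidth / fs)`` and angle
    ``2*pi*f0/fs``, giving a spectral peak at ``f0`` with an
    approximately ``bandwidth``-wide resonance.
    """
    if not (0 < f0 < fs / 2):
        raise ValueError(f"f0={f0} must lie in (0, Nyquist={fs / 2})")
    r = np.exp(-np.pi * bandwidth / fs)
    a1 = 2.0 * r * np.cos(2.0 * np.pi * f0 / fs)
    a2 = -(r**2)
    return a1, a2


def _ar2_stationary_std(a1: float, a2: float) -> float:
    # variance of x_t = a1 x_{t-1} + a2 x_{t-2} + e_t with unit-variance drive
    var = (1 - a2) / ((1 + a2) * ((1 - a2) ** 2 - a1**2))
    return float(np.sqrt(var))


def narrowband_process(
    n: int, f0: float, bandwidth: float, fs: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance AR(2) narrowband noise of length ``n`` samples."""
    a1, a2 = ar2_coefficients(f0, bandwidth, fs)
    # burn-in of several decay times so the slice is stationary
    burn = max(512, int(5 * fs / max(bandwidth, 1.0)))
    e = rng.standard_normal(n + burn)
    x = sps.lfilter([1.0], [1.0, -a1, -a2], e)[burn:]
    return x / _ar2_stationary_std(a1, a2)


def ar2_power_spectrum(f: np.ndarray, f0: float, bandwidth: float, fs: float) -> np.ndarray:
    """Analytic one-sided PSD of the unit-variance AR(2) oscillator."""
    a1, a2 = ar2_coefficients(f0, bandwidth, fs)
    z = np.exp(-2j * np.pi * np.asarray(f) / fs)
    h = 1.0 / np.abs(1.0 - a1 * z - a2 * z**2) ** 2
    # scale drive so that the integrated (two-sided) spectrum is 1
    sigma2 = 1.0 / _ar2_stationary_std(a1, a2) ** 2
    return 2.0 * sigma2 * h / fs


# ---------------------------------------------------------------------------
# specs


@dataclass
class EvokedTemplate:
    """Biphasic (negative-then-positive) stimulus-evoked transient."""

    amplitude: float = 1.0
    neg_latency_s: float = 0.02
    pos_latency_s: float = 0.06
    width_s: float = 0.015

    def waveform(self, t: np.ndarray) -> np.ndarray:
        """Evaluate the template on times ``t`` (s, onset at 0)."""
        neg = np.exp(-((t - self.neg_latency_s) ** 2) / (2 * self.width_s**2))
        pos = np.exp(-((t - self.pos_latency_s) ** 2) / (2 * (1.5 * self.width_s) ** 2))
        w = self.amplitude * (-neg + 0.7 * pos)
        w[t < 0] = 0.0
        return w


@dataclass
class SurrogateSpec:
    """Parameters of the coupled two-area surrogate recording.

    ``shared_fraction`` is the fraction of narrowband variance common to
    the two areas; it equals the analytic inter-area coherence inside
    ``shared_band``.  ``directed_lag`` delays the shared component in the
    second area (positive: area 1 leads).
    """

    n_channels_per_area: int = 14
    sampling_rate: float = 1000.0
    n_trials: int = 100
    trial_length: float = 3.0
    shared_band: tuple[float, float] = (30.0, 50.0)
    shared_fraction: float = 0.5
    directed_lag: float = 0.0
    line_noise_amp: float = 0.0
    evoked_template: EvokedTemplate | None = None
    seed: int = 0
    # plumbing defaults (not part of the scientific contract)
    onset_offset: float = 1.0  # onset position within each trial segment, s
    background_noise_amp: float = 0.3  # broadband noise std per channel
    background_color: str = "pink"  # "pink" (1/f) or "white"
    channel_spacing_um: float = 100.0

    def __post_init__(self) -> None:
        f_lo, f_hi = self.shared_band
        nyq = self.sampling_rate / 2.0
        if not (0 < f_lo < f_hi):
            raise ValueError("shared_band must satisfy 0 < f_lo < f_hi")
        if f_hi >= nyq:
            raise ValueError(
                f"shared_band upper edge {f_hi} Hz >= Nyquist {nyq} Hz "
                f"(sampling_rate={self.sampling_rate} Hz)"
            )
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise ValueError("shared_fraction must lie in [0, 1]")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.trial_length <= self.onset_offset:
            raise ValueError("trial_length must exceed onset_offset")
        if self.background_color not in ("pink", "white"):
            raise ValueError("background_color must be 'pink' or 'white'")

    @property
    def band_center(self) -> float:
        return 0.5 * (self.shared_band[0] + self.shared_band[1])

    @property
    def band_width(self) -> float:
        return 0.5 * (self.shared_band[1] - self.shared_band[0])


@dataclass
class BehaviorLinkSpec:
    """Trial-varying protraction amplitudes linked to inter-area coupling.

    Protraction amplitudes are drawn from ``N(amplitude_mean,
    amplitude_sd**2)`` (degrees).  The narrowband coupling of each trial
    within ``link_band`` is ``base + link_slope * (A - amplitude_mean)``,
    clipped to [0.02, 0.98].
    """

    amplitude_mean: float = 10.0
    amplitude_sd: float = 2.0
    link_band: tuple[float, float] = (30.0, 50.0)
    link_slope: float = 0.1  # coherence units per degree
    noise_sd: float = 0.0  # angular measurement noise, degrees

    def __post_init__(self) -> None:
        if self.amplitude_sd < 0:
            raise ValueError("amplitude_sd must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


# ---------------------------------------------------------------------------
# generators


def _background(n: int, n_ch: int, spec: SurrogateSpec, rng: np.random.Generator) -> np.ndarray:
    """Broadband per-channel noise, white or 1/f-coloured, std = amp."""
    w = rng.standard_normal((n, n_ch))
    if spec.background_color == "white" or spec.background_noise_amp == 0:
        return spec.background_noise_amp * w
    # shape white noise to 1/f magnitude in the Fourier domain
    spec_w = np.fft.rfft(w, axis=0)
    f = np.fft.rfftfreq(n, 1.0 / spec.sampling_rate)
    gain = np.ones_like(f)
    nonzero = f > 0
    gain[nonzero] = 1.0 / np.sqrt(np.maximum(f[nonzero], 1.0))
    colored = np.fft.irfft(spec_w * gain[:, None], n=n, axis=0)
    sd = colored.std(axis=0, keepdims=True)
    sd[sd == 0] = 1.0
    return spec.background_noise_amp * colored / sd


def _laminar_profile(n_ch: int) -> np.ndarray:
    """Smooth depth profile for evoked amplitudes, peaking mid-probe."""
    z = np.arange(n_ch)
    return np.exp(-((z - (n_ch - 1) / 2.0) ** 2) / (2 * (n_ch / 4.0) ** 2))


def _trial_band_signals(
    n: int,
    spec: SurrogateSpec,
    coupling: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One trial of the two-area narrowband mixture (area1, area2)."""
    f0, bw = spec.band_center, max(spec.band_width, 1.0)
    fs = spec.sampling_rate
    lag = int(round(spec.directed_lag * fs))
    shared = narrowband_process(n + lag, f0, bw, fs, rng)
    priv1 = narrowband_process(n, f0, bw, fs, rng)
    priv2 = narrowband_process(n, f0, bw, fs, rng)
    a, b = np.sqrt(coupling), np.sqrt(1.0 - coupling)
    x1 = a * shared[lag:] + b * priv1  # area 1 leads for positive lag
    x2 = a * shared[: n] + b * priv2
    return x1, x2


def gen_coupled_lfp(spec: SurrogateSpec) -> tuple[MultichannelRecording, EventTable]:
    """Generate a two-area laminar surrogate recording plus event table.

    The recording concatenates ``n_trials`` independent segments of
    ``trial_length`` seconds.  Within each segment both areas carry the
    shared/private narrowband mixture (constant over the segment),
    per-channel broadband background noise, optional 50 Hz line noise
    with random per-trial phase, and an optional evoked transient at the
    event onset (``onset_offset`` seconds into the segment).
    """
    rng = np.random.default_rng(spec.seed)
    fs = spec.sampling_rate
    n_seg = int(round(spec.trial_length * fs))
    n_ch = spec.n_channels_per_area
    n_total = n_seg * spec.n_trials
    data = np.empty((n_total, 2 * n_ch))
    onsets = np.empty(spec.n_trials)

    profile = _laminar_profile(n_ch)
    t_seg = np.arange(n_seg) / fs

    for k in range(spec.n_trials):
        x1, x2 = _trial_band_signals(n_seg, spec, spec.shared_fraction, rng)
        seg = np.empty((n_seg, 2 * n_ch))
        seg[:, :n_ch] = x1[:, None] + _background(n_seg, n_ch, spec, rng)
        seg[:, n_ch:] = x2[:, None] + _background(n_seg, n_ch, spec, rng)
        if spec.line_noise_amp:
            phase = rng.uniform(0, 2 * np.pi)
            seg += spec.line_noise_amp * np.sin(2 * np.pi * 50.0 * t_seg + phase)[:, None]
        if spec.evoked_template is not None:
            wave = spec.evoked_template.waveform(t_seg - spec.onset_offset)
            seg += wave[:, None] * np.concatenate([profile, profile])[None, :]
        data[k * n_seg : (k + 1) * n_seg] = seg
        onsets[k] = k * spec.trial_length + spec.onset_offset

    depths = np.tile(np.arange(1, n_ch + 1) * spec.channel_spacing_um, 2)
    areas = ["area1"] * n_ch + ["area2"] * n_ch
    rec = MultichannelRecording(data, fs, depths, areas)
    events = EventTable.from_onsets(onsets, "stim")
    return rec, events


def gen_laminar_volley(
    n_channels: int,
    sink_channel: int,
    spacing_um: float,
    spec: SurrogateSpec | None = None,
) -> MultichannelRecording:
    """Laminar potential with a current sink of known depth.

    A negative-going potential well, Gaussian across depth and centred
    on ``sink_channel`` (1-based, matching the probe numbering), is
    modulated by a transient time course.  Its second spatial derivative
    therefore has a sink (negative CSD) extremum exactly at
    ``sink_channel``.
    """
    if n_channels < 3:
        raise ValueError("CSD requires at least 3 channels")
    if not 1 <= sink_channel <= n_channels:
        raise ValueError(f"sink_channel must lie in [1, {n_channels}]")
    spec = spec or SurrogateSpec(n_channels_per_area=n_channels, n_trials=1)
    fs = spec.sampling_rate
    n = int(round(spec.trial_length * fs))
    t = np.arange(n) / fs
    wave = np.exp(-((t - spec.onset_offset - 0.03) ** 2) / (2 * 0.01**2))
    z = np.arange(1, n_channels + 1, dtype=float)
    depth_profile = np.exp(-((z - sink_channel) ** 2) / (2 * 2.0**2))
    data = -wave[:, None] * depth_profile[None, :]
    depths = z * spacing_um
    return MultichannelRecording(data, fs, depths, ["S1"] * n_channels)


def _protraction_pulse(t: np.ndarray) -> np.ndarray:
    """Unit-peak reflexive protraction time course (onset at t = 0)."""
    tau_rise, tau_fall = 0.02, 0.08
    w = (1 - np.exp(-np.maximum(t, 0) / tau_rise)) * np.exp(-np.maximum(t, 0) / tau_fall)
    w[t < 0] = 0.0
    peak = w.max()
    return w / peak if peak > 0 else w


def gen_behavior_dataset(
    spec: SurrogateSpec, link: BehaviorLinkSpec
) -> tuple[TrialTensor, list]:
    """Trials whose inter-area coupling follows whisker protraction size.

    Returns a two-channel :class:`TrialTensor` (one channel per area)
    and a list of :class:`~cerecoh.behavior.BehaviorTrial` objects whose
    ``amplitude_deg`` fields are the generative ground truth.
    """
    from .behavior import BehaviorTrial  # local import: behavior does not import us

    rng = np.random.default_rng(spec.seed)
    fs = spec.sampling_rate
    n_seg = int(round(spec.trial_length * fs))
    pre = spec.onset_offset
    post = spec.trial_length - pre
    t = np.arange(n_seg) / fs - pre

    band_spec = SurrogateSpec(
        n_channels_per_area=1,
        sampling_rate=fs,
        n_trials=1,
        trial_length=spec.trial_length,
        shared_band=link.link_band,
        shared_fraction=spec.shared_fraction,
        directed_lag=spec.directed_lag,
        onset_offset=spec.onset_offset,
        background_noise_amp=spec.background_noise_amp,
        background_color=spec.background_color,
    )

    amplitudes = rng.normal(link.amplitude_mean, link.amplitude_sd, size=spec.n_trials)
    couplings = np.clip(
        spec.shared_fraction + link.link_slope * (amplitudes - link.amplitude_mean),
        0.02,
        0.98,
    )

    data = np.empty((spec.n_trials, 2, n_seg))
    trials = []
    pulse = _protraction_pulse(t)
    for k in range(spec.n_trials):
        x1, x2 = _trial_band_signals(n_seg, band_spec, couplings[k], rng)
        noise = band_spec.background_noise_amp
        data[k, 0] = x1 + noise * rng.standard_normal(n_seg)
        data[k, 1] = x2 + noise * rng.standard_normal(n_seg)
        angle = amplitudes[k] * pulse
        if link.noise_sd > 0:
            angle = angle + link.noise_sd * rng.standard_normal(n_seg)
        response = angle[t >= 0]
        trials.append(
            BehaviorTrial(
                angle_deg=angle,
                sampling_rate=fs,
                amplitude_deg=float(amplitudes[k]),
                movement_power=float(np.mean(response**2)),
                condition="stim",
                coupling_truth=float(couplings[k]),
            )
        )

    tensor = TrialTensor(
        data,
        fs,
        (pre, post),
        np.asarray(["stim"] * spec.n_trials, dtype=object),
        channel_depth_um=np.array([0.0, 0.0]),
        area=["area1", "area2"],
    )
    return tensor, trials
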