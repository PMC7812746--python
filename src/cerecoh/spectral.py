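"""Time-frequency decomposition, coherence and phase-difference spectra.

Estimator layout
----------------

* Morlet wavelet decomposition with a fixed cycle count (default 7)
  yields complex coefficients ``X_k(f, t)`` per trial ``k``.
* Trial coherence is the inter-trial cross-spectral consistency

  ``C(f, t) = |sum_k X_k Y_k*| / sqrt(sum_k |X_k|^2 sum_k |Y_k|^2)``

  and is then averaged, per frequency, over a frequency-dependent
  post-onset window spanning two oscillation cycles (``[onset,
  onset + 2/f]``).  The two-cycle rule applies to the averaging window;
  the wavelet cycle count is an independent parameter.
* 50 Hz line noise is removed by power-spectrum normalization: power in
  a narrow band around the line frequency is rescaled to the level
  interpolated from the flanking bands, leaving phases untouched.

Band partition used throughout: delta 1-4, theta 4-8, alpha 8-12,
beta 12-30, gamma 30-100 Hz (low gamma 30-55, high gamma 65-100 to
skirt the 50 Hz line).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .containers import TrialTensor

__all__ = [
    "BANDS",
    "TfDecomposition",
    "CoherenceResult",
    "PhaseDiffResult",
    "default_freq_grid",
    "wavelet_transform",
    "power_spectrum",
    "event_coherence",
    "trial_coherence",
    "remove_line_noise",
    "phase_difference",
    "band_average",
]

BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
    "gamma": (30.0, 100.0),
    "gamma_low": (30.0, 55.0),
    "gamma_high": (65.0, 100.0),
}


def default_freq_grid(f_lo: float = 2.0, f_hi: float = 100.0, n: int = 40) -> np.ndarray:
    """Logarithmic frequency grid (Hz), 2-100 Hz in 40 steps by default."""
    return np.geomspace(f_lo, f_hi, n)


@dataclass
class TfDecomposition:
    """Complex Morlet coefficients, shape (n_trials, n_channels, n_freqs, n_times)."""

    coeffs: np.ndarray
    freqs: np.ndarray
    times: np.ndarray  # s relative to event onset
    cycles: float
    sampling_rate: float

    @property
    def n_trials(self) -> int:
        return self.coeffs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.coeffs.shape[1]

    def channel(self, index: int) -> "TfDecomposition":
        return TfDecomposition(
            self.coeffs[:, [index]], self.freqs, self.times, self.cycles, self.sampling_rate
        )


@dataclass
class CoherenceResult:
    """Trial-coherence spectrum with the metadata the DoC test needs."""

    coherence: np.ndarray  # C(f) in [0, 1]
    freqs: np.ndarray
    n_trials: int
    pair: tuple[str, str] = ("x", "y")
    condition: str = ""
    mode: str = "poststim"
    coherence_tf: np.ndarray | None = None  # optional C(f, t)
    times: np.ndarray | None = None
    cross_phase: np.ndarray | None = None  # arg of windowed cross-spectrum


@dataclass
class PhaseDiffResult:
    """Phase-lag spectrum; positive values mean x leads y."""

    dphi: np.ndarray  # radians, wrapped to (-pi, pi]
    freqs: np.ndarray
    unreliable: np.ndarray  # True where the cross-spectrum is too weak
    band_means: dict = field(default_factory=dict)  # circular mean per band


# ---------------------------------------------------------------------------
# wavelet transform


def _morlet_kernel(f: float, cycles: float, fs: float) -> np.ndarray:
    """Complex Morlet kernel; |X| of a unit-amplitude sinusoid is ~1."""
    sigma_t = cycles / (2.0 * np.pi * f)
    half = int(np.ceil(4 * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    env = np.exp(-(t**2) / (2 * sigma_t**2))
    kernel = env * np.exp(2j * np.pi * f * t)
    return 2.0 * kernel / env.sum()


def wavelet_transform(
    trials: TrialTensor,
    freqs: np.ndarray | None = None,
    cycles: float = 7.0,
    dtype=np.complex64,
) -> TfDecomposition:
    """Morlet decomposition of every trial and channel.

    Coefficients are scaled so a unit-amplitude sinusoid at a grid
    frequency has magnitude ~1.  Edge samples within the kernel support
    carry tapering artefacts; analysis windows should avoid them.
    """
    freqs = default_freq_grid() if freqs is None else np.asarray(freqs, dtype=float)
    fs = trials.sampling_rate
    nyq = fs / 2.0
    if np.any(np.diff(freqs) <= 0):
        raise ValueError("frequency grid must be strictly increasing")
    if freqs[-1] >= nyq:
        raise ValueError(f"max frequency {freqs[-1]} Hz >= Nyquist {nyq} Hz")
    if cycles < 2:
        raise ValueError("cycles must be >= 2")
    n_tr, n_ch, n_t = trials.data.shape
    out = np.empty((n_tr, n_ch, len(freqs), n_t), dtype=dtype)
    flat = trials.data.reshape(n_tr * n_ch, n_t)
    for i, f in enumerate(freqs):
        kernel = _morlet_kernel(f, cycles, fs)
        conv = sps.fftconvolve(flat, kernel[None, :], mode="same", axes=1)
        out[:, :, i, :] = conv.reshape(n_tr, n_ch, n_t)
    return TfDecomposition(out, freqs, trials.times, cycles, fs)


# ---------------------------------------------------------------------------
# power spectra


def power_spectrum(
    x: np.ndarray,
    sampling_rate: float,
    segment_length: int | None = None,
    overlap: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Welch-averaged one-sided power spectral density.

    ``segment_length`` is in samples (default: n//8, at least 256 when
    possible); ``overlap`` is the fractional segment overlap.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    if segment_length is None:
        segment_length = min(n, max(256, n // 8))
    if segment_length > n:
        raise ValueError("segment longer than signal")
    if not 0 <= overlap < 1:
        raise ValueError("overlap must lie in [0, 1)")
    f, p = sps.welch(
        x,
        fs=sampling_rate,
        nperseg=segment_length,
        noverlap=int(overlap * segment_length),
        detrend="constant",
    )
    return f, p


# ---------------------------------------------------------------------------
# coherence


def _window_mask(times: np.ndarray, f: float, onset: float, mode: str) -> np.ndarray:
    """Frequency-dependent two-cycle averaging window."""
    width = 2.0 / f
    if mode == "poststim":
        lo, hi = onset, onset + width
    elif mode == "baseline":
        lo, hi = onset - width, onset
    elif mode == "full":
        lo, hi = times[0], times[-1] + np.inf
    else:
        raise ValueError(f"unknown mode {mode!r}")
    mask = (times >= lo) & (times <= hi)
    if not mask.any():
        raise ValueError(f"averaging window [{lo:.3f}, {hi:.3f}] s outside trial times")
    return mask


def _coherence_from_sums(sxy: np.ndarray, sxx: np.ndarray, syy: np.ndarray) -> np.ndarray:
    denom = np.sqrt(sxx * syy)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.abs(sxy) / denom
    return np.nan_to_num(np.minimum(c, 1.0))


def event_coherence(
    tf_x: TfDecomposition,
    tf_y: TfDecomposition,
    onset: float = 0.0,
    mode: str = "poststim",
    pair: tuple[str, str] = ("x", "y"),
    condition: str = "",
) -> CoherenceResult:
    """Inter-trial coherence between two single-channel decompositions.

    Coherence across trials is computed per (f, t) and then averaged
    over the two-cycle window selected by ``mode`` ("poststim",
    "baseline" or "full").
    """
    if tf_x.n_channels != 1 or tf_y.n_channels != 1:
        raise ValueError("event_coherence expects single-channel decompositions")
    if tf_x.n_trials != tf_y.n_trials:
        raise ValueError("trial counts differ between x and y")
    if tf_x.n_trials < 2:
        raise ValueError("coherence across trials requires >= 2 trials")
    if not np.allclose(tf_x.freqs, tf_y.freqs):
        raise ValueError("frequency grids differ between x and y")
    x = tf_x.coeffs[:, 0]  # (K, F, T)
    y = tf_y.coeffs[:, 0]
    sxy = np.einsum("kft,kft->ft", x, np.conj(y))
    sxx = np.einsum("kft,kft->ft", x, np.conj(x)).real
    syy = np.einsum("kft,kft->ft", y, np.conj(y)).real
    c_tf = _coherence_from_sums(sxy, sxx, syy)
    times = tf_x.times
    coh = np.empty(len(tf_x.freqs))
    phase = np.empty(len(tf_x.freqs))
    for i, f in enumerate(tf_x.freqs):
        mask = _window_mask(times, f, onset, mode)
        coh[i] = c_tf[i, mask].mean()
        phase[i] = np.angle(sxy[i, mask].sum())
    return CoherenceResult(
        coherence=coh,
        freqs=tf_x.freqs.copy(),
        n_trials=tf_x.n_trials,
        pair=pair,
        condition=condition,
        mode=mode,
        coherence_tf=c_tf,
        times=times,
        cross_phase=phase,
    )


def trial_coherence(
    trials: TrialTensor,
    ch_x: int,
    ch_y: int,
    freqs: np.ndarray | None = None,
    cycles: float = 7.0,
    onset: float = 0.0,
    mode: str = "poststim",
    batch: int = 50,
    condition: str = "",
) -> CoherenceResult:
    """Memory-bounded coherence between two channels of a trial tensor.

    Equivalent to ``event_coherence(wavelet_transform(...), ...)`` but
    accumulates the cross/auto spectra over batches of trials, so the
    full coefficient array is never materialized.
    """
    freqs = default_freq_grid() if freqs is None else np.asarray(freqs, dtype=float)
    if trials.n_trials < 2:
        raise ValueError("coherence across trials requires >= 2 trials")
    n_f, n_t = len(freqs), trials.n_samples
    sxy = np.zeros((n_f, n_t), dtype=complex)
    sxx = np.zeros((n_f, n_t))
    syy = np.zeros((n_f, n_t))
    for start in range(0, trials.n_trials, batch):
        sub = TrialTensor(
            trials.data[start : start + batch][:, [ch_x, ch_y], :],
            trials.sampling_rate,
            trials.window,
            trials.conditions[start : start + batch],
        )
        tf = wavelet_transform(sub, freqs, cycles)
        x, y = tf.coeffs[:, 0], tf.coeffs[:, 1]
        sxy += np.einsum("kft,kft->ft", x, np.conj(y))
        sxx += np.einsum("kft,kft->ft", x, np.conj(x)).real
        syy += np.einsum("kft,kft->ft", y, np.conj(y)).real
    c_tf = _coherence_from_sums(sxy, sxx, syy)
    times = trials.times
    coh = np.empty(n_f)
    phase = np.empty(n_f)
    for i, f in enumerate(freqs):
        mask = _window_mask(times, f, onset, mode)
        coh[i] = c_tf[i, mask].mean()
        phase[i] = np.angle(sxy[i, mask].sum())
    return CoherenceResult(
        coherence=coh,
        freqs=freqs,
        n_trials=trials.n_trials,
        pair=(f"ch{ch_x}", f"ch{ch_y}"),
        condition=condition,
        mode=mode,
        coherence_tf=c_tf,
        times=times,
        cross_phase=phase,
    )


# ---------------------------------------------------------------------------
# line-noise normalization


def remove_line_noise(
    obj,
    line_freq: float = 50.0,
    half_width: float = 1.0,
    flank_width: float = 4.0,
):
    """Rescale power near ``line_freq`` to the flanking-band level.

    Accepts either a ``(f, P)`` spectrum tuple or a
    :class:`TfDecomposition`.  Power within ``line_freq +- half_width``
    is rescaled (never amplified above its original level) to the
    linear interpolation of the mean power in the two flanking bands;
    phases are untouched.  Idempotent within tolerance.
    """
    if isinstance(obj, TfDecomposition):
        freqs = obj.freqs
        power = np.mean(np.abs(obj.coeffs) ** 2, axis=(0, 1, 3))  # (F,)
        gain = _line_gain(freqs, power, line_freq, half_width, flank_width)
        coeffs = obj.coeffs * np.sqrt(gain)[None, None, :, None].astype(obj.coeffs.dtype)
        return TfDecomposition(coeffs, freqs, obj.times, obj.cycles, obj.sampling_rate)
    f, p = obj
    f = np.asarray(f, dtype=float)
    p = np.asarray(p, dtype=float)
    gain = _line_gain(f, p, line_freq, half_width, flank_width)
    return f, p * gain


def _line_gain(
    f: np.ndarray, p: np.ndarray, line_freq: float, half_width: float, flank_width: float
) -> np.ndarray:
    in_band = np.abs(f - line_freq) <= half_width
    lo_flank = (f >= line_freq - half_width - flank_width) & (f < line_freq - half_width)
    hi_flank = (f > line_freq + half_width) & (f <= line_freq + half_width + flank_width)
    if not in_band.any():
        raise ValueError(f"line frequency {line_freq} Hz not covered by the grid")
    if (
        not lo_flank.any()
        or not hi_flank.any()
        or f.max() < line_freq + half_width + 0.5 * flank_width
        or f.min() > line_freq - half_width - 0.5 * flank_width
    ):
        raise ValueError("line frequency too close to the grid edge for flanking bands")
    target = 0.5 * (p[lo_flank].mean() + p[hi_flank].mean())
    # only bins clearly above the interpolated level are rescaled; a dead
    # zone of 2x keeps the operation a no-op on uncontaminated spectra
    # and makes repeated application idempotent
    gain = np.ones_like(p, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(p[in_band] > 2.0 * target, target / p[in_band], 1.0)
    gain[in_band] = np.nan_to_num(g, nan=1.0)
    return gain


# ---------------------------------------------------------------------------
# phase differences


def phase_difference(
    tf_x: TfDecomposition,
    tf_y: TfDecomposition,
    onset: float = 0.0,
    mode: str = "poststim",
    reliability_floor: float = 0.1,
) -> PhaseDiffResult:
    """Cross-spectral phase lag per frequency; positive = x leads y.

    Computed as ``arg(sum_k sum_t X_k Y_k*)`` over the two-cycle window.
    Frequencies whose inter-trial coherence falls below
    ``reliability_floor`` are flagged unreliable.
    """
    coh = event_coherence(tf_x, tf_y, onset=onset, mode=mode)
    dphi = coh.cross_phase.copy()
    unreliable = coh.coherence < reliability_floor
    band_means = {}
    for name, (lo, hi) in BANDS.items():
        sel = (coh.freqs >= lo) & (coh.freqs < hi) & ~unreliable
        if sel.any():
            band_means[name] = float(np.angle(np.exp(1j * dphi[sel]).mean()))
    return PhaseDiffResult(dphi=dphi, freqs=coh.freqs, unreliable=unreliable, band_means=band_means)


def band_average(result: CoherenceResult, band: str | tuple[float, float]) -> float:
    """Mean coherence over a named or explicit frequency band."""
    lo, hi = BANDS[band] if isinstance(band, str) else band
    sel = (result.freqs >= lo) & (result.freqs < hi)
    if not sel.any():
        raise ValueError(f"band {band} not covered by the frequency grid")
    return float(result.coherence[sel].mean())
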