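"""Whisker-protraction quantification and coherence-based amplitude prediction.

Air-puff stimulation evokes a reflexive whisker protraction whose
amplitude varies from trial to trial (approximately normally).  This
module quantifies that amplitude, stratifies trials by it (median split
or eight overlapping quantile groups), estimates coherence between LFP
and the whisker-movement power signal, and fits a linear predictor that
maps per-trial coherence features across frequencies to the protraction
amplitude, including cross-condition transfer of a fitted predictor.

Per-trial "coherence" needs a convention, because coherence proper is
defined across trials.  Two feature modes are provided:

``"loo"`` (default)
    Leave-one-out delta: (number of trials) times the change in the
    inter-trial coherence when the trial is removed — the trial's
    marginal contribution to the ensemble phase alignment.

``"within_trial"``
    Time-averaged coherency magnitude of the trial's wavelet
    coefficients over the analysis window — a consistent per-trial
    coupling estimate when the window spans many cycles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from sklearn.linear_model import LinearRegression, Ridge
from sklearn.metrics import r2_score
from sklearn.model_selection import KFold, LeaveOneOut

from .containers import TrialTensor
from .spectral import (
    CoherenceResult,
    _coherence_from_sums,
    _window_mask,
    default_freq_grid,
    wavelet_transform,
)

__all__ = [
    "BehaviorTrial",
    "PredictorModel",
    "protraction_amplitude",
    "split_trials",
    "movement_power_signal",
    "lfp_behavior_coherence",
    "trial_coherence_features",
    "fit_coherence_predictor",
    "apply_predictor",
]


@dataclass
class BehaviorTrial:
    """Whisker-angle trace of one trial with its protraction summary."""

    angle_deg: np.ndarray
    sampling_rate: float
    amplitude_deg: float
    movement_power: float  # mean squared baseline-subtracted angle, deg^2
    condition: str = ""
    coupling_truth: float | None = None  # generator ground truth, if any


def protraction_amplitude(
    trace: np.ndarray,
    sampling_rate: float,
    pre: float,
    baseline_window: tuple[float, float] = (-0.5, -0.05),
    response_window: tuple[float, float] = (0.0, 0.3),
) -> tuple[float, float]:
    """Protraction amplitude and movement power of a whisker-angle trace.

    ``trace`` covers ``[-pre, len/fs - pre)`` seconds around onset.
    Amplitude is the maximum angle in the response window minus the
    baseline mean; movement power is the mean squared baseline-
    subtracted angle over the response window.
    """
    trace = np.asarray(trace, dtype=float)
    t = np.arange(len(trace)) / sampling_rate - pre
    b = (t >= baseline_window[0]) & (t < baseline_window[1])
    r = (t >= response_window[0]) & (t < response_window[1])
    if not b.any() or not r.any():
        raise ValueError("baseline/response windows do not overlap the trace")
    base = trace[b].mean()
    amp = float(trace[r].max() - base)
    power = float(np.mean((trace[r] - base) ** 2))
    return amp, power


def split_trials(amplitudes, mode: str = "median") -> list[np.ndarray]:
    """Stratify trials by protraction amplitude.

    ``"median"``: two equal-size groups (small, large); with an odd
    count the middle trial joins the small group; ties are broken by
    trial order (stable sort).
    ``"overlapping8"``: eight overlapping groups from a sliding
    quantile window of width 25% stepped by 75/7 ~ 10.7%, so the group
    centers span the amplitude range and neighbouring groups share
    trials.
    """
    amps = np.asarray(amplitudes, dtype=float)
    n = len(amps)
    order = np.argsort(amps, kind="stable")
    if mode == "median":
        if n < 2:
            raise ValueError("median split requires >= 2 trials")
        half = n // 2
        return [np.sort(order[: n - half]), np.sort(order[n - half :])]
    if mode == "overlapping8":
        if n < 8:
            raise ValueError("overlapping8 split requires >= 8 trials")
        width, step = 25.0, 75.0 / 7.0
        pct = np.empty(n)
        pct[order] = np.arange(n) / (n - 1) * 100.0 if n > 1 else 0.0
        groups = []
        for k in range(8):
            lo = k * step
            hi = lo + width
            # half-open (lo, hi] except the first group, which keeps 0%
            above = pct >= lo - 1e-9 if k == 0 else pct > lo + 1e-9
            groups.append(np.flatnonzero(above & (pct <= hi + 1e-9)))
        return groups
    raise ValueError(f"unknown split mode {mode!r}")


def movement_power_signal(
    behavior: list[BehaviorTrial],
    n_samples: int,
    sampling_rate: float,
    pre: float,
    smooth_s: float = 0.05,
) -> np.ndarray:
    """Per-trial instantaneous movement-power traces at the LFP rate.

    Squared baseline-subtracted whisker angle, smoothed with a moving
    average of ``smooth_s`` seconds, resampled to ``n_samples`` at
    ``sampling_rate``.  Returns shape (n_trials, n_samples).
    """
    out = np.empty((len(behavior), n_samples))
    for k, tr in enumerate(behavior):
        angle = np.asarray(tr.angle_deg, dtype=float)
        t = np.arange(len(angle)) / tr.sampling_rate - pre
        base = angle[t < 0].mean() if (t < 0).any() else angle.mean()
        power = (angle - base) ** 2
        w = max(1, int(round(smooth_s * tr.sampling_rate)))
        power = np.convolve(power, np.ones(w) / w, mode="same")
        if len(power) != n_samples:
            power = sps.resample(power, n_samples)
        out[k] = power
    return out


def lfp_behavior_coherence(
    trials: TrialTensor,
    behavior: list[BehaviorTrial],
    lfp_channel: int = 0,
    freqs: np.ndarray | None = None,
    cycles: float = 7.0,
    onset: float = 0.0,
    mode: str = "poststim",
) -> CoherenceResult:
    """Inter-trial coherence between an LFP channel and movement power.

    The whisker-movement power signal of each trial is resampled to the
    LFP sampling rate and treated as the second channel of the standard
    trial-coherence estimator.
    """
    if len(behavior) != trials.n_trials:
        raise ValueError("behavior trial count must match the LFP tensor")
    power = movement_power_signal(
        behavior, trials.n_samples, trials.sampling_rate, trials.window[0]
    )
    paired = TrialTensor(
        np.stack([trials.data[:, lfp_channel, :], power], axis=1),
        trials.sampling_rate,
        trials.window,
        trials.conditions,
    )
    from .spectral import trial_coherence

    res = trial_coherence(paired, 0, 1, freqs=freqs, cycles=cycles, onset=onset, mode=mode)
    res.pair = (f"lfp_ch{lfp_channel}", "movement_power")
    return res


def trial_coherence_features(
    trials: TrialTensor,
    ch_x: int,
    ch_y: int,
    freqs: np.ndarray | None = None,
    cycles: float = 7.0,
    onset: float = 0.0,
    mode: str = "full",
    feature: str = "loo",
) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial coupling features over the frequency grid.

    Returns ``(features, freqs)`` with features shaped (n_trials,
    n_freqs).  See the module docstring for the two feature modes.
    """
    freqs = default_freq_grid() if freqs is None else np.asarray(freqs, dtype=float)
    tf = wavelet_transform(
        TrialTensor(
            trials.data[:, [ch_x, ch_y], :], trials.sampling_rate, trials.window, trials.conditions
        ),
        freqs,
        cycles,
    )
    x, y = tf.coeffs[:, 0], tf.coeffs[:, 1]  # (K, F, T)
    masks = [_window_mask(tf.times, f, onset, mode) for f in freqs]
    k_tr, n_f = x.shape[0], len(freqs)
    feats = np.empty((k_tr, n_f))
    if feature == "within_trial":
        for i in range(n_f):
            m = masks[i]
            sxy = np.sum(x[:, i, m] * np.conj(y[:, i, m]), axis=1)
            sxx = np.sum(np.abs(x[:, i, m]) ** 2, axis=1)
            syy = np.sum(np.abs(y[:, i, m]) ** 2, axis=1)
            feats[:, i] = _coherence_from_sums(sxy, sxx, syy)
        return feats, freqs
    if feature == "loo":
        if k_tr < 3:
            raise ValueError("leave-one-out features require >= 3 trials")
        for i in range(n_f):
            m = masks[i]
            xv, yv = x[:, i, m], y[:, i, m]
            pxy = xv * np.conj(yv)
            pxx = np.abs(xv) ** 2
            pyy = np.abs(yv) ** 2
            txy, txx, tyy = pxy.sum(axis=0), pxx.sum(axis=0), pyy.sum(axis=0)
            c_all = _coherence_from_sums(txy, txx, tyy).mean()
            c_loo = _coherence_from_sums(txy - pxy, txx - pxx, tyy - pyy).mean(axis=1)
            feats[:, i] = k_tr * (c_all - c_loo)
        return feats, freqs
    raise ValueError(f"unknown feature mode {feature!r}")


@dataclass
class PredictorModel:
    """Linear map from coherence features over frequencies to amplitude."""

    freqs: np.ndarray
    weights: np.ndarray  # degrees per coherence unit, per frequency
    intercept: float
    r2: float  # held-out (cross-validated) R^2
    r2_train: float
    scheme: str
    condition: str = ""
    ridge_alpha: float | None = None

    def predict(self, features: np.ndarray) -> np.ndarray:
        features = np.atleast_2d(np.asarray(features, dtype=float))
        if features.shape[1] != len(self.weights):
            raise ValueError("feature dimension does not match the fitted grid")
        return features @ self.weights + self.intercept

    def to_json(self, path) -> None:
        payload = {
            "freqs": self.freqs.tolist(),
            "weights": self.weights.tolist(),
            "intercept": self.intercept,
            "r2": self.r2,
            "r2_train": self.r2_train,
            "scheme": self.scheme,
            "condition": self.condition,
            "ridge_alpha": self.ridge_alpha,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "PredictorModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            freqs=np.asarray(d["freqs"]),
            weights=np.asarray(d["weights"]),
            intercept=float(d["intercept"]),
            r2=float(d["r2"]),
            r2_train=float(d["r2_train"]),
            scheme=d["scheme"],
            condition=d.get("condition", ""),
            ridge_alpha=d.get("ridge_alpha"),
        )


def fit_coherence_predictor(
    features: np.ndarray,
    amplitudes: np.ndarray,
    scheme: str = "kfold",
    n_folds: int = 10,
    ridge_alpha: float | None = None,
    freqs: np.ndarray | None = None,
    condition: str = "",
) -> PredictorModel:
    """Least-squares frequency-weight predictor of protraction amplitude.

    ``features`` is (n_trials, n_freqs); held-out R^2 comes from
    cross-validated predictions (``scheme`` = "kfold" or "loo").
    Without regularization the trial count must be at least twice the
    feature count; otherwise enable ridge.
    """
    X = np.asarray(features, dtype=float)
    yv = np.asarray(amplitudes, dtype=float)
    if X.ndim != 2 or X.shape[0] != len(yv):
        raise ValueError("features must be (n_trials, n_freqs) matching amplitudes")
    k_tr, n_f = X.shape
    if ridge_alpha is None and k_tr < 2 * n_f:
        raise ValueError(
            f"only {k_tr} trials for {n_f} frequency features; "
            "enable ridge regularization (ridge_alpha=...) or reduce the grid"
        )
    freqs = np.arange(n_f, dtype=float) if freqs is None else np.asarray(freqs, dtype=float)

    def make_model():
        return LinearRegression() if ridge_alpha is None else Ridge(alpha=ridge_alpha)

    if scheme == "loo":
        splitter = LeaveOneOut()
    elif scheme == "kfold":
        splitter = KFold(n_splits=min(n_folds, k_tr), shuffle=False)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    y_hat = np.empty_like(yv)
    for train, test in splitter.split(X):
        m = make_model().fit(X[train], yv[train])
        y_hat[test] = m.predict(X[test])
    r2_cv = r2_score(yv, y_hat)

    final = make_model().fit(X, yv)
    r2_train = r2_score(yv, final.predict(X))
    return PredictorModel(
        freqs=freqs,
        weights=np.asarray(final.coef_, dtype=float),
        intercept=float(final.intercept_),
        r2=float(r2_cv),
        r2_train=float(r2_train),
        scheme=scheme,
        condition=condition,
        ridge_alpha=ridge_alpha,
    )


def apply_predictor(
    model: PredictorModel, features: np.ndarray, amplitudes: np.ndarray
) -> float:
    """Cross-condition transfer: R^2 of a fitted predictor on new trials."""
    pred = model.predict(features)
    return float(r2_score(np.asarray(amplitudes, dtype=float), pred))
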