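"""Config-driven pipeline: generate or simulate, then analyze per condition.

Two front ends feed the same analysis stack:

* ``mode: surrogate`` — the synthetic generator produces one recording
  per condition (air puff, Purkinje stimulation, combinations) with
  configurable band-limited coupling;
* ``mode: model`` — the laminar network is simulated per condition
  (trigeminal and/or Purkinje drive, steady state in noise), and the
  excitatory-population rates of chosen laminar modules serve as LFP
  proxies.

Per condition pair, the pipeline writes coherence spectra, DoC tables
(frequency, delta, chi2, p, BH-adjusted p, significance) and a
machine-readable JSON summary with band-averaged coherence differences.
Outputs carry the config hash and seed; identical config + seed
reproduce identical files.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from . import model as lm
from .containers import TrialTensor
from .inference import bh_correct, doc_test
from .io import config_hash, ensure_dir
from .preprocess import segment_trials
from .spectral import BANDS, band_average, trial_coherence
from .synthetic import EvokedTemplate, SurrogateSpec, gen_coupled_lfp

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "simulate_condition_trials", "DEFAULT_COMPARISONS"]

# condition pairs reported by default: (numerator/test, reference)
DEFAULT_COMPARISONS = [
    ("air_puff_pc", "air_puff"),
    ("air_puff_pc_delay", "air_puff"),
    ("air_puff", "baseline"),
    ("pc", "baseline"),
]


def _freq_grid(analysis: dict) -> np.ndarray:
    g = analysis.get("freqs", {})
    return np.geomspace(g.get("lo", 2.0), g.get("hi", 100.0), g.get("n", 30))


def simulate_condition_trials(
    network: lm.NetworkSpec,
    tn_drive: float,
    pc_drive: float,
    n_trials: int,
    epoch: float,
    seed: int,
    burn: float = 0.5,
    decimate: int = 10,
    pair=(("S1", "inf"), ("M1", "sup")),
) -> TrialTensor:
    """Simulate independent noisy epochs and return two LFP proxies.

    Each trial is an independent noise realization of the steady-state
    stimulated network; the first ``burn`` seconds are discarded and the
    proxies are FIR-decimated by ``decimate``.
    """
    protocol = lm.StimulusProtocol(air_puff_amp=tn_drive, pc_amp=pc_drive, mode="steady_state")
    net = lm.NetworkSpec(
        network.populations, network.W, network.dt, burn + epoch, seed, network.noise_tau
    )
    sim = lm.simulate(net, protocol, n_trials=n_trials, seed=seed)
    (area_x, layer_x), (area_y, layer_y) = pair
    x = lm.lfp_proxy(sim, area_x, layer_x)
    y = lm.lfp_proxy(sim, area_y, layer_y)
    if decimate > 1:
        x = sps.decimate(x, decimate, ftype="fir", axis=1)
        y = sps.decimate(y, decimate, ftype="fir", axis=1)
    fs = 1.0 / (sim.dt * decimate)
    keep = slice(int(round(burn * fs)), None)
    data = np.stack([x[:, keep], y[:, keep]], axis=1)
    data -= data.mean(axis=2, keepdims=True)
    return TrialTensor(data, fs, (0.0, data.shape[2] / fs),
                       area=[f"{area_x}_{layer_x}", f"{area_y}_{layer_y}"],
                       channel_depth_um=np.zeros(2))


def _surrogate_condition_tensors(cfg: dict, seed: int) -> dict[str, TrialTensor]:
    sur = cfg.get("surrogate", {})
    base_kwargs = dict(
        n_channels_per_area=sur.get("n_channels_per_area", 2),
        sampling_rate=sur.get("sampling_rate", 500.0),
        n_trials=sur.get("n_trials", 100),
        trial_length=sur.get("trial_length", 2.5),
        onset_offset=sur.get("onset_offset", 0.5),
        line_noise_amp=sur.get("line_noise_amp", 0.0),
    )
    conditions = sur.get("conditions") or {
        "baseline": {"shared_fraction": 0.05, "shared_band": [30, 50]},
        "air_puff": {"shared_fraction": 0.6, "shared_band": [30, 50], "evoked": True},
        "air_puff_pc": {"shared_fraction": 0.6, "shared_band": [4, 8], "evoked": True},
        "air_puff_pc_delay": {"shared_fraction": 0.55, "shared_band": [30, 50], "evoked": True},
        "pc": {"shared_fraction": 0.5, "shared_band": [4, 8]},
    }
    window = (base_kwargs["onset_offset"],
              base_kwargs["trial_length"] - base_kwargs["onset_offset"])
    tensors = {}
    for i, (name, overrides) in enumerate(sorted(conditions.items())):
        kw = dict(base_kwargs)
        ov = dict(overrides)
        evoked = ov.pop("evoked", False)
        kw.update(ov)
        if "shared_band" in kw:
            kw["shared_band"] = tuple(kw["shared_band"])
        spec = SurrogateSpec(
            **kw, evoked_template=EvokedTemplate() if evoked else None, seed=seed + 101 * i
        )
        rec, events = gen_coupled_lfp(spec)
        tensors[name] = segment_trials(rec, events, window)
        logger.info("surrogate condition %s: %d trials", name, tensors[name].n_trials)
    return tensors


def _model_condition_tensors(cfg: dict, seed: int) -> dict[str, TrialTensor]:
    mod = cfg.get("model", {})
    network = lm.build_network(mod.get("config"))
    drives = mod.get("conditions") or {
        "baseline": {"tn": 0.0, "pc": 0.0},
        "air_puff": {"tn": mod.get("tn_drive", 6.0), "pc": 0.0},
        "pc": {"tn": 0.0, "pc": mod.get("pc_drive", 6.0)},
        "air_puff_pc": {"tn": mod.get("tn_drive", 6.0), "pc": mod.get("pc_drive", 6.0)},
    }
    pair = mod.get("pair", [["S1", "inf"], ["M1", "sup"]])
    tensors = {}
    for i, (name, drive) in enumerate(sorted(drives.items())):
        tensors[name] = simulate_condition_trials(
            network,
            tn_drive=drive.get("tn", 0.0),
            pc_drive=drive.get("pc", 0.0),
            n_trials=mod.get("n_trials", 100),
            epoch=mod.get("epoch", 2.0),
            seed=seed + 211 * i,
            burn=mod.get("burn", 0.5),
            decimate=mod.get("decimate", 10),
            pair=(tuple(pair[0]), tuple(pair[1])),
        )
        logger.info("model condition %s simulated", name)
    return tensors


def run_pipeline(cfg: dict, outdir) -> dict:
    """Run generate/simulate -> coherence -> DoC and write the result bundle."""
    out = ensure_dir(outdir)
    seed = int(cfg.get("seed", 0))
    mode = cfg.get("mode", "surrogate")
    analysis = cfg.get("analysis", {})
    freqs = _freq_grid(analysis)
    cycles = analysis.get("cycles", 7.0)
    alpha = analysis.get("alpha", 0.05)
    window_mode = analysis.get("window_mode", "full")
    chash = config_hash(cfg)
    stamp = {"config_hash": chash, "seed": seed}

    try:
        if mode == "surrogate":
            tensors = _surrogate_condition_tensors(cfg, seed)
            ch_x, ch_y = cfg.get("surrogate", {}).get("pair", [0, 1])
        elif mode == "model":
            tensors = _model_condition_tensors(cfg, seed)
            ch_x, ch_y = 0, 1
        else:
            raise ValueError(f"unknown mode {mode!r}")
    except Exception:
        logger.exception("stage 'generate' failed")
        raise

    coherences = {}
    for name, tensor in tensors.items():
        try:
            coherences[name] = trial_coherence(
                tensor, ch_x, ch_y, freqs=freqs, cycles=cycles,
                onset=0.0, mode=window_mode, condition=name,
            )
        except Exception:
            logger.exception("stage 'coherence' failed for condition %s", name)
            raise
        pd.DataFrame({"f_hz": freqs, "coherence": coherences[name].coherence}).to_csv(
            out / f"coherence_{name}.tsv", sep="\t", index=False
        )

    comparisons = [
        tuple(c) for c in cfg.get("comparisons", DEFAULT_COMPARISONS)
        if c[0] in coherences and c[1] in coherences
    ]
    summary = {**stamp, "mode": mode, "bands": {}, "comparisons": {}}
    for cond_a, cond_b in comparisons:
        try:
            res = doc_test(coherences[cond_a], coherences[cond_b], alpha=alpha)
        except Exception:
            logger.exception("stage 'doc' failed for %s vs %s", cond_a, cond_b)
            raise
        rejected, p_adj = bh_correct(res.p, q=alpha)
        table = pd.DataFrame(
            {
                "f_hz": res.freqs,
                "delta_coherence": res.delta,
                "chi2": res.chi2,
                "p": res.p,
                "p_adj": p_adj,
                "significant": res.significant,
                "significant_bh": rejected,
            }
        )
        key = f"{cond_a}_vs_{cond_b}"
        table.to_csv(out / f"doc_{key}.tsv", sep="\t", index=False)
        band_delta = {}
        for band in ("theta", "gamma"):
            lo, hi = BANDS[band]
            sel = (res.freqs >= lo) & (res.freqs < hi)
            band_delta[band] = {
                "delta_coherence": float(res.delta[sel].mean()),
                "max_chi2": float(res.chi2[sel].max()),
                "any_significant": bool(res.significant[sel].any()),
            }
        summary["comparisons"][key] = band_delta

    for name, coh in coherences.items():
        summary["bands"][name] = {
            band: band_average(coh, band) for band in ("theta", "alpha", "beta", "gamma")
        }

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    with open(out / "run_config.json", "w") as fh:
        json.dump({**stamp, "config": cfg}, fh, indent=1, sort_keys=True, default=str)
    logger.info("pipeline complete: %s", out / "summary.json")
    return summary
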