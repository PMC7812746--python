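"""Laminar cortico-thalamo-cerebellar firing-rate model.

The network couples laminar S1 and M1 — each with supragranular and
infragranular excitatory/inhibitory pairs — through the trigeminal
nuclei (TN), thalamic relays (VPM, Pom, VL), the zona incerta (ZI) and
the cerebellum (Purkinje cells PC inhibiting the cerebellar nuclei CN).

Population dynamics follow a standard noise-driven rate equation

    tau * dr/dt = -r + phi(W r + I_ext + b - g_a * a + eta),
    tau_a * da/dt = r - a            (adaptation, CN only),

with transfer function ``phi(x) = x / (1 - exp(-x))`` (smooth, positive,
near-linear for large x).  Supragranular modules use fast time
constants (tau_E = 6 ms, tau_I = 8 ms) and resonate in the gamma band;
infragranular modules are slow (tau_E = 30 ms, tau_I = 75 ms) and
resonate at low frequencies — the laminar division of labour the
cortical base model provides.  CN rebound firing after release from
Purkinje inhibition arises mechanistically from rate-tracking
adaptation rather than scripted injection.

The input noise ``eta`` is an Ornstein-Uhlenbeck process with a short
correlation time (2 ms default) and stationary standard deviation
``sigma``; this keeps the effective noise drive independent of the
integration step.

Anatomical sign constraints are enforced: Purkinje cells, the zona
incerta and cortical interneurons may only have non-positive outgoing
weights, all other populations non-negative ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "PopulationSpec",
    "NetworkSpec",
    "StimulusProtocol",
    "SimResult",
    "phi",
    "build_network",
    "simulate",
    "steady_state_rates",
    "lfp_proxy",
    "POPULATIONS",
    "DEFAULT_WEIGHTS",
]


def phi(x: np.ndarray) -> np.ndarray:
    """Transfer function ``x / (1 - exp(-x))``; phi(0) = 1, positive."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = np.abs(x) < 1e-9
    out[small] = 1.0 + x[small] / 2.0
    with np.errstate(over="ignore"):
        xs = x[~small]
        out[~small] = np.where(xs > 30, xs, xs / (1.0 - np.exp(-np.clip(xs, -700, 30))))
    return out


INHIBITORY = {"PC", "ZI", "S1_supI", "S1_infI", "M1_supI", "M1_infI"}

# population order is fixed; W[target, source]
POPULATIONS = [
    "TN", "VPM", "Pom", "VL", "ZI", "PC", "CN",
    "S1_supE", "S1_supI", "S1_infE", "S1_infI",
    "M1_supE", "M1_supI", "M1_infE", "M1_infI",
]


@dataclass
class PopulationSpec:
    """Single-population parameters (times in seconds, rates unitless)."""

    name: str
    tau: float
    sigma: float = 0.0
    baseline_drive: float = 0.0
    g_a: float = 0.0  # adaptation strength (CN rebound mechanism)
    tau_a: float = 0.08

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError(f"{self.name}: tau must be positive")
        if self.sigma < 0:
            raise ValueError(f"{self.name}: sigma must be >= 0")
        if self.g_a != 0 and self.tau_a <= 0:
            raise ValueError(f"{self.name}: tau_a must be positive when g_a != 0")


def _default_populations(sigma_ctx: float = 0.35, sigma_sub: float = 0.12) -> list[PopulationSpec]:
    # Pom is slower and noisier than the other relays: it acts as the
    # incerta-gated hub broadcasting low-frequency drive to both areas.
    taus = {"supE": 0.006, "supI": 0.008, "infE": 0.030, "infI": 0.075}
    pops = [
        PopulationSpec("TN", 0.010, sigma_sub, baseline_drive=0.3),
        PopulationSpec("VPM", 0.010, sigma_sub, baseline_drive=0.2),
        PopulationSpec("Pom", 0.025, 1.0, baseline_drive=5.0),
        PopulationSpec("VL", 0.010, sigma_sub, baseline_drive=0.2),
        PopulationSpec("ZI", 0.010, sigma_sub, baseline_drive=0.2),
        PopulationSpec("PC", 0.010, sigma_sub, baseline_drive=0.5),
        PopulationSpec("CN", 0.010, sigma_sub, baseline_drive=4.0, g_a=0.5, tau_a=0.08),
    ]
    for area in ("S1", "M1"):
        for layer in ("sup", "inf"):
            pops.append(
                PopulationSpec(f"{area}_{layer}E", taus[layer + "E"], sigma_ctx, baseline_drive=2.0)
            )
            pops.append(
                PopulationSpec(f"{area}_{layer}I", taus[layer + "I"], sigma_ctx, baseline_drive=1.0)
            )
    order = {n: i for i, n in enumerate(POPULATIONS)}
    return sorted(pops, key=lambda p: order[p.name])


def _local_weights(area: str) -> dict[tuple[str, str], float]:
    """Laminar E-I modules plus the intra-areal interlaminar couplings."""
    w = {}
    for layer in ("sup", "inf"):
        e, i = f"{area}_{layer}E", f"{area}_{layer}I"
        w[(e, e)] = 1.5
        w[(e, i)] = 3.5
        w[(i, e)] = -3.25
        w[(i, i)] = -2.5
    w[(f"{area}_supE", f"{area}_infE")] = 1.0  # superficial drive of deep layers
    w[(f"{area}_infE", f"{area}_supI")] = 1.0  # deep feedback damping the gamma module
    return w


# (source, target): weight.  Tuned default set; every entry overridable.
# The Pom projections realise the incerta-gated broadcast: at rest the
# zona incerta keeps Pom silent; Purkinje stimulation silences CN, the
# incerta drops, and Pom wakes up — exciting the deep S1 / superficial
# M1 theta route while recruiting supragranular S1 interneurons, which
# damps the sensory-driven gamma module.
DEFAULT_WEIGHTS: dict[tuple[str, str], float] = {
    # ascending sensory pathway
    ("TN", "VPM"): 2.0,
    ("TN", "Pom"): 0.3,
    ("TN", "PC"): 0.5,  # mossy/climbing sensory drive of cerebellar cortex
    ("TN", "CN"): 0.5,  # mossy fiber collaterals to the nuclei
    # cerebellar loop
    ("PC", "CN"): -1.5,
    ("CN", "VL"): 1.5,
    ("CN", "ZI"): 1.5,
    ("CN", "Pom"): 0.2,
    ("ZI", "Pom"): -2.5,
    # thalamocortical projections
    ("VPM", "S1_supE"): 1.5,
    ("VPM", "S1_supI"): 0.6,
    ("Pom", "S1_supI"): 3.0,  # layer-I terminals recruiting superficial interneurons
    ("Pom", "S1_infE"): 1.5,
    ("Pom", "M1_supE"): 1.0,
    ("Pom", "M1_supI"): 0.5,
    ("VL", "M1_supE"): 1.2,
    ("VL", "M1_infE"): 0.8,
    # cortico-cortical (deep <-> superficial, the strongest anatomical route)
    ("S1_infE", "M1_supE"): 0.5,
    ("M1_infE", "S1_supE"): 0.5,
    # reciprocal superficial loop (ablatable variant)
    ("S1_supE", "M1_supE"): 0.75,
    ("M1_supE", "S1_supE"): 0.75,
    **_local_weights("S1"),
    **_local_weights("M1"),
}

VARIANTS = {
    "no_s1_m1_superficial": {("S1_supE", "M1_supE"): 0.0, ("M1_supE", "S1_supE"): 0.0},
    "m1_to_zi": {("M1_infE", "ZI"): 0.5},
    # thalamic-hub variants: which relays carry the cerebellar signal
    "cn_vl_only": {("CN", "Pom"): 0.0},
    "cn_vpm": {("CN", "VPM"): 0.8},
    "cn_pom_strong": {("CN", "Pom"): 1.5},
}


@dataclass
class NetworkSpec:
    """Populations plus the signed connection matrix W[target, source]."""

    populations: list[PopulationSpec]
    W: np.ndarray
    dt: float = 2e-4
    duration: float = 2.0
    seed: int = 0
    noise_tau: float = 0.002  # OU correlation time of the input noise

    def __post_init__(self) -> None:
        n = len(self.populations)
        self.W = np.asarray(self.W, dtype=float)
        if self.W.shape != (n, n):
            raise ValueError("W must be (n_populations, n_populations)")
        names = [p.name for p in self.populations]
        for j, src in enumerate(names):
            col = self.W[:, j]
            if src in INHIBITORY and np.any(col > 0):
                bad = names[int(np.argmax(col > 0))]
                raise ValueError(f"inhibitory source {src} has positive weight onto {bad}")
            if src not in INHIBITORY and np.any(col < 0):
                bad = names[int(np.argmax(col < 0))]
                raise ValueError(f"excitatory source {src} has negative weight onto {bad}")

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.populations]

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError as err:
            raise KeyError(f"unknown population {name!r}") from err

    def weight(self, source: str, target: str) -> float:
        return float(self.W[self.index(target), self.index(source)])


def build_network(config: dict | None = None) -> NetworkSpec:
    """Assemble the default cerebello-thalamo-cortical network.

    ``config`` may contain:

    ``weights``: {(source, target) or "source->target": value} overrides
    ``variants``: list of named variants (see ``VARIANTS``)
    ``populations``: {name: {tau/sigma/baseline_drive/g_a/tau_a}} overrides
    ``dt``, ``duration``, ``seed``, ``noise_tau``, ``sigma_ctx``, ``sigma_sub``
    """
    config = dict(config or {})
    sigma_ctx = config.get("sigma_ctx", 0.35)
    sigma_sub = config.get("sigma_sub", 0.12)
    pops = _default_populations(sigma_ctx, sigma_sub)
    by_name = {p.name: p for p in pops}
    for name, overrides in (config.get("populations") or {}).items():
        if name not in by_name:
            raise KeyError(f"unknown population {name!r}")
        idx = pops.index(by_name[name])
        pops[idx] = replace(by_name[name], **overrides)

    weights = dict(DEFAULT_WEIGHTS)
    for variant in config.get("variants") or []:
        if variant not in VARIANTS:
            raise KeyError(f"unknown variant {variant!r}; options: {sorted(VARIANTS)}")
        weights.update(VARIANTS[variant])
    for key, value in (config.get("weights") or {}).items():
        if isinstance(key, str):
            src, dst = (s.strip() for s in key.split("->"))
        else:
            src, dst = key
        if src not in POPULATIONS or dst not in POPULATIONS:
            raise KeyError(f"unknown edge {src}->{dst}")
        weights[(src, dst)] = float(value)

    n = len(POPULATIONS)
    order = {name: i for i, name in enumerate(POPULATIONS)}
    W = np.zeros((n, n))
    for (src, dst), value in weights.items():
        W[order[dst], order[src]] = value
    return NetworkSpec(
        populations=pops,
        W=W,
        dt=config.get("dt", 2e-4),
        duration=config.get("duration", 2.0),
        seed=config.get("seed", 0),
        noise_tau=config.get("noise_tau", 0.002),
    )


@dataclass
class StimulusProtocol:
    """Air-puff (TN drive) and/or Purkinje-cell drive, pulsed or sustained.

    ``delay`` shifts the PC stimulus onset relative to the air puff
    (0 or 0.02 s in the experimental protocols).  In ``steady_state``
    mode both drives are constant over the whole simulation.
    """

    air_puff_amp: float = 0.0
    air_puff_onset: float = 0.5
    air_puff_duration: float = 0.01
    pc_amp: float = 0.0
    pc_duration: float = 0.1
    delay: float = 0.0
    mode: str = "pulse"  # "pulse" | "steady_state"

    def __post_init__(self) -> None:
        if self.air_puff_duration <= 0 or self.pc_duration <= 0:
            raise ValueError("stimulus durations must be positive")
        if self.delay < 0:
            raise ValueError("delay must be >= 0")
        if self.mode not in ("pulse", "steady_state"):
            raise ValueError("mode must be 'pulse' or 'steady_state'")

    def drives(self, times: np.ndarray) -> dict[str, np.ndarray]:
        """External drive time courses for TN and PC."""
        if self.mode == "steady_state":
            return {
                "TN": np.full_like(times, self.air_puff_amp),
                "PC": np.full_like(times, self.pc_amp),
            }
        tn = np.where(
            (times >= self.air_puff_onset) & (times < self.air_puff_onset + self.air_puff_duration),
            self.air_puff_amp,
            0.0,
        )
        pc_on = self.air_puff_onset + self.delay
        pc = np.where((times >= pc_on) & (times < pc_on + self.pc_duration), self.pc_amp, 0.0)
        return {"TN": tn, "PC": pc}


@dataclass
class SimResult:
    """Simulated rate trajectories, shape (n_trials, n_populations, n_steps)."""

    rates: np.ndarray
    times: np.ndarray
    names: list[str]
    protocol: StimulusProtocol
    seed: int
    dt: float

    def rate(self, name: str, trial: int = 0) -> np.ndarray:
        return self.rates[trial, self.names.index(name)]

    @property
    def n_trials(self) -> int:
        return self.rates.shape[0]


def simulate(
    network: NetworkSpec,
    protocol: StimulusProtocol,
    n_trials: int = 1,
    seed: int | None = None,
    record_every: int = 1,
) -> SimResult:
    """Euler-Maruyama integration of the rate network.

    All trials share the network and protocol but receive independent
    noise; they are integrated as one batched state update per step.
    ``record_every`` subsamples the stored trajectories.
    """
    dt = network.dt
    taus = np.array([p.tau for p in network.populations])
    if dt >= taus.min() / 5:
        raise ValueError(f"dt={dt} too coarse; must be < min(tau)/5 = {taus.min() / 5:.2e}")
    n_steps = int(round(network.duration / dt))
    times = np.arange(n_steps) * dt
    n_pop = len(network.populations)
    sigma = np.array([p.sigma for p in network.populations])[:, None]
    base = np.array([p.baseline_drive for p in network.populations])[:, None]
    g_a = np.array([p.g_a for p in network.populations])[:, None]
    tau_a = np.array([p.tau_a for p in network.populations])[:, None]
    tau = taus[:, None]
    W = network.W

    drives = protocol.drives(times)
    ext = np.zeros((n_pop, n_steps))
    for name, tc in drives.items():
        if name in network.names:
            ext[network.index(name)] = tc
        elif np.any(tc):
            raise KeyError(f"stimulus targets unknown population {name!r}")

    rng = np.random.default_rng(network.seed if seed is None else seed)
    r = np.ones((n_pop, n_trials))
    a = r.copy()
    eta = np.zeros_like(r)
    # OU noise update coefficients (exact discretization)
    rho = np.exp(-dt / network.noise_tau)
    noise_scale = sigma * np.sqrt(1.0 - rho**2)

    n_rec = (n_steps + record_every - 1) // record_every
    out = np.empty((n_trials, n_pop, n_rec))
    rec_i = 0
    for step in range(n_steps):
        eta = rho * eta + noise_scale * rng.standard_normal((n_pop, n_trials))
        x = W @ r + base + ext[:, step : step + 1] - g_a * a + eta
        r = r + dt / tau * (-r + phi(x))
        np.maximum(r, 0.0, out=r)
        a = a + dt / tau_a * (r - a)
        if not np.all(np.isfinite(r)):
            bad = int(np.argmax(~np.isfinite(r).all(axis=1)))
            raise FloatingPointError(
                f"divergence at t={step * dt:.4f} s, first diverging population "
                f"{network.names[bad]}"
            )
        if step % record_every == 0:
            out[:, :, rec_i] = r.T
            rec_i += 1
    return SimResult(
        rates=out[:, :, :rec_i],
        times=times[::record_every][:rec_i],
        names=network.names,
        protocol=protocol,
        seed=network.seed if seed is None else seed,
        dt=dt * record_every,
    )


def steady_state_rates(
    network: NetworkSpec,
    constant_inputs: dict[str, float] | None = None,
    eta: float = 0.1,
    tol: float = 1e-12,
    max_iter: int = 200_000,
) -> np.ndarray:
    """Noise-free fixed point by damped iteration.

    ``constant_inputs`` maps population names to sustained external
    drives.  At the fixed point the adaptation variable equals the rate,
    so the effective recurrent input is ``W r + b + I - g_a r``.
    Non-convergence raises with a diagnostic.
    """
    n = len(network.populations)
    base = np.array([p.baseline_drive for p in network.populations])
    g_a = np.array([p.g_a for p in network.populations])
    ext = np.zeros(n)
    for name, value in (constant_inputs or {}).items():
        ext[network.index(name)] = value
    r = np.ones(n)
    for _ in range(max_iter):
        target = phi(network.W @ r + base + ext - g_a * r)
        r_new = np.maximum((1 - eta) * r + eta * target, 0.0)
        if np.max(np.abs(r_new - r)) < tol:
            return r_new
        r = r_new
    raise RuntimeError(
        f"steady state not reached within {max_iter} iterations "
        f"(residual {np.max(np.abs(target - r)):.2e})"
    )


def lfp_proxy(sim: SimResult, area: str, layer: str, trial: int | None = None) -> np.ndarray:
    """Mean-subtracted excitatory rate of a laminar module.

    ``layer`` is ``"sup"``/``"supra"`` or ``"inf"``/``"infra"``.  With
    ``trial=None`` all trials are returned, shape (n_trials, n_steps).
    """
    layer_key = {"sup": "sup", "supra": "sup", "inf": "inf", "infra": "inf"}.get(layer)
    name = f"{area}_{layer_key}E" if layer_key else None
    if name not in sim.names:
        raise KeyError(f"unknown area/layer {area!r}/{layer!r}")
    idx = sim.names.index(name)
    traces = sim.rates[:, idx, :] if trial is None else sim.rates[[trial], idx, :]
    out = traces - traces.mean(axis=1, keepdims=True)
    return out if trial is None else out[0]
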