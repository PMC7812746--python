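# Methods

`cerecoh` couples a firing-rate model of the cerebello-thalamo-cortical
loop to a trial-based LFP coherence pipeline. This note documents the
model, the estimators, the synthetic-data generators and the numerical
choices, in enough detail to reproduce or modify any of them.

## 1. The laminar network model

### Populations and dynamics

Fifteen populations: trigeminal nuclei (TN), three thalamic relays
(VPM, Pom, VL), zona incerta (ZI), cerebellar Purkinje cells (PC) and
cerebellar nuclei (CN), and — for each cortical area S1 and M1 — a
supragranular and an infragranular excitatory/inhibitory pair. Each
population follows

    tau * dr/dt   = -r + phi(W r + b + I_ext(t) - g_a * a + eta(t))
    tau_a * da/dt = r - a                       (adaptation; CN only)

with transfer function `phi(x) = x / (1 - exp(-x))`: smooth, strictly
positive (`phi(0)=1`), near-linear for large x, with slope rising from
0 (deep inhibition) through 0.5 (x=0) toward 1. That slope profile
matters: a population's ability to transmit fluctuations grows with its
operating point, which is the mechanism behind several of the
condition contrasts below.

`eta(t)` is an Ornstein–Uhlenbeck process with correlation time 2 ms
and stationary standard deviation `sigma`. Band-limited noise makes
the discretized dynamics independent of the integration step; the
exact OU update is used at each Euler step. `sigma` defaults to 0.35
for cortical populations and 0.12 for subcortical relays; Pom is the
exception (below).

Time constants (seconds): supragranular tau_E=0.006, tau_I=0.008;
infragranular tau_E=0.030, tau_I=0.075; subcortical relays 0.010. The
local E–I weights are (E→E 1.5, E→I 3.5, I→E −3.25, I→I −2.5). With
these values an isolated supragranular pair resonates near 47 Hz
(gamma) and an isolated infragranular pair near 5 Hz — the laminar
division of rhythms the cortical model builds on. Note that the
resonance is visible in the noise-driven spectrum only when the module
receives a tonic drive comparable to what the full network provides
(total input ≈ 6 on the E population); at a near-zero operating point
the low-frequency shoulder of the input noise dominates.

### Connectivity

`W[target, source]`, signed; sign constraints are enforced at
construction (PC, ZI and cortical interneurons may only inhibit,
everything else may only excite). The default weights (all
overridable through `build_network(config)`):

* Ascending sensory: TN→VPM 2.0, TN→Pom 0.3, TN→PC 0.5, TN→CN 0.5
  (mossy-fiber collaterals); VPM→S1_supE 1.5, VPM→S1_supI 0.6.
* Cerebellar loop: PC⊣CN 1.5; CN→VL 1.5, CN→ZI 1.5, CN→Pom 0.2;
  ZI⊣Pom 2.5.
* Pom broadcast: Pom→S1_infE 1.5, Pom→S1_supI 3.0 (layer-I terminals
  recruiting superficial interneurons), Pom→M1_supE 1.0, Pom→M1_supI
  0.5.
* VL→M1_supE 1.2, VL→M1_infE 0.8.
* Cortico-cortical: S1_infE→M1_supE 0.5, M1_infE→S1_supE 0.5, plus a
  reciprocal superficial loop S1_supE↔M1_supE 0.75 (removable via the
  `no_s1_m1_superficial` variant).
* Intra-areal interlaminar: supE→infE 1.0 and infE→supI 1.0. The
  second link lets deep-layer activity damp the superficial gamma
  module; it is part of the base laminar framework and is essential
  for the gamma-suppression effect.

Named variants also cover M1→ZI feedback and the thalamic-hub
alternatives (`cn_vl_only`, `cn_vpm`, `cn_pom_strong`), since which
relays carry the cerebellar signal is a question the model is meant to
explore, not a settled fact.

### The incerta-gated Pom hub

Baseline drives put the circuit in a specific resting state: CN is
tonically active (baseline 4.0, moderated by tonic PC inhibition), so
ZI is active, and ZI's strong inhibition keeps Pom almost silent
despite its large intrinsic drive (5.0). Pom is deliberately slower
(tau=25 ms) and noisier (sigma=1.0) than the other relays, so when it
is active it broadcasts a low-frequency (delta–theta) stochastic
signal to both cortical areas.

The stimulation conditions then play out as follows:

* **Trigeminal drive** (air puff): TN→VPM→S1 raises the supragranular
  operating point, amplifying the local gamma resonance; the gamma
  signal reaches M1 through the superficial reciprocal loop and the
  deep-S1→superficial-M1 projection, raising gamma-band S1–M1
  coherence. Pom stays gated off.
* **Purkinje drive**: PC silences CN, CN's drive to ZI collapses, Pom
  is disinhibited and wakes up. Its shared low-frequency output
  reaches deep S1 (excitatory) and superficial M1, producing
  theta-band coherence between the areas.
* **Combined drive**: Pom is active while S1 is sensory-driven; the
  strong Pom→S1_supI projection pushes the superficial interneurons,
  lowering the gamma module's operating point and cancelling the
  sensory gamma-coherence increase, while theta coherence persists.
* **CN rebound**: CN carries rate-tracking adaptation (g_a=0.5,
  tau_a=80 ms). During a 100-ms PC pulse the adaptation variable decays
  toward the suppressed rate; at stimulus offset the lowered adaptation
  lets CN overshoot its pre-stimulus rate — rebound firing without any
  scripted injection.

Weight magnitudes were tuned by the package authors to make these four
signatures robust at the simulation sizes used in the test suite; they
are stated defaults, not measurements.

### Integration and model-side "trials"

Euler–Maruyama with dt=0.2 ms (validated: halving dt changes
steady-state rates by <1e-3 relative; noise-free simulations match the
damped-iteration fixed point to ~1e-12). A model "trial" is an
independent noise realization of a fixed-duration stimulated epoch:
trials are integrated as one batched state update, 0.5 s of burn-in is
discarded, and the LFP proxy of a laminar module (its mean-subtracted
excitatory rate) is FIR-decimated from 5 kHz to 500 Hz before spectral
analysis. The condition runs used by the acceptance script are 100
trials x 2 s per condition, which one CPU completes in seconds.

The coherence pair reported for the model is deep S1 against
superficial M1, the most strongly connected inter-areal channel pair
and the one the laminar probe convention singles out (channels 10 and
3 of a 14-channel probe).

## 2. Spectral estimators

* **Time–frequency decomposition**: Morlet wavelets, 7 cycles, on a
  logarithmic 2–100 Hz grid (40 points by default). Coefficients are
  scaled so a unit sinusoid has magnitude ~1. The cycle count of the
  kernel and the length of the post-onset averaging window are
  independent parameters.
* **Trial coherence**: `C(f,t) = |sum_k X_k Y_k*| / sqrt(sum_k |X_k|^2
  sum_k |Y_k|^2)` across trials k, then averaged per frequency over a
  window of two oscillation cycles after stimulus onset (`[onset,
  onset+2/f]`); baseline (pre-onset) and whole-epoch windows are
  selectable. For stationary epochs the whole-epoch window is used.
  A batched accumulation path (`trial_coherence`) computes the same
  quantity without materializing all coefficients.
* **Line-noise normalization**: power within ±1 Hz of 50 Hz is rescaled
  to the level interpolated from 4-Hz flanking bands; phases are never
  touched. Only bins exceeding twice the interpolated level are
  rescaled — the dead zone makes the operation a no-op on clean
  spectra and idempotent. This flanking-band rule is a documented
  stand-in for the original toolbox's normalization, whose exact form
  is not public.
* **Phase differences**: `arg` of the window-summed cross-spectrum;
  positive means the first signal leads. Frequencies whose coherence
  falls below a reliability floor (default 0.1) are flagged.
* **Band partition**: delta 1–4, theta 4–8, alpha 8–12, beta 12–30,
  gamma 30–100 Hz (low gamma 30–55 and high gamma 65–100 skirt the
  line frequency). Theta/alpha/gamma edges follow the convention of
  the experimental literature; delta and beta edges are package
  conventions.

## 3. Inference

* **Difference of coherence (DoC)**: per frequency,
  `z = [atanh C_A - atanh C_B] / sqrt(1/(2K_A-2) + 1/(2K_B-2))`,
  referred two-tailed to chi-squared(1) via `z^2`; the 0.05 boundary is
  3.84. Monte-Carlo calibration at the conditions used here (true
  coherence 0.5, K=100) gives a type-I rate of ~0.05; at true
  coherence 0 the Fisher-z approximation is conservative (~0.003)
  because the estimator's bias floor compresses its variance. A
  label-permutation test is provided as an assumption-free check.
* **Benjamini–Hochberg**: standard step-up, delegated to statsmodels;
  the test suite holds it to the brute-force step-up definition on
  random inputs.
* **Granger causality**: parametric backend fits a multi-trial VAR by
  stacked least squares (BIC order selection, capped at 20, with
  companion-matrix stability check) and evaluates the Geweke
  frequency-domain decomposition; the same closed form applied to the
  true coefficients serves as the oracle in tests. The nonparametric
  backend estimates the trial-averaged cross-spectral density (Welch,
  two-sided scaling, DC bin extrapolated because detrending notches
  it) and factorizes it with Wilson's algorithm. The two backends
  agree within 0.1 (absolute, natural-log units) on VAR-generated
  data; the nonparametric route is biased at frequencies where the
  true causality is small, a known property of CSD-based
  factorization at finite data.
* Trial-shuffle nulls (re-pairing x and y trials) provide significance
  floors for both backends.

## 4. Synthetic data

The generators provide every analysis stage with inputs whose ground
truth is known analytically:

* **Coupled two-area recordings**: each trial mixes a shared and two
  private narrowband components, all unit-variance AR(2) oscillators
  with identical spectra, as `sqrt(c)*S + sqrt(1-c)*N_area`. Because
  the spectra are equal, the inter-area coherence is exactly `c` at
  every frequency of the band — the calibration target. The directed
  lag is a pure sample delay of the shared component (area 1 leads),
  giving a linear phase slope `2*pi*f*tau` and a known Granger
  direction. Per-channel 1/f background noise (sd 0.3 by default;
  white selectable), 50 Hz line contamination with random per-trial
  phase, and a biphasic evoked transient with a smooth laminar profile
  complete the recording. Trials are independent segments
  concatenated into one continuous recording with a sidecar event
  table.
* **Laminar volley**: a negative potential well, Gaussian across
  depth and centred on a chosen channel, modulated by a transient —
  its second spatial derivative localizes the sink at that channel
  exactly.
* **Behavior-linked trials**: protraction amplitudes `A_k ~ N(10, 2^2)`
  degrees; each trial's coupling is `0.5 + slope*(A_k - 10)`, clipped
  to [0.02, 0.98]; whisker-angle traces are a unit-peak
  rise-and-decay pulse scaled by `A_k` plus optional angular noise.
  The "strong link" conditions used for predictor recovery are 200
  trials of 5 s with slope 0.12 — chosen so the amplitude spread spans
  the coupling range without saturating the clip (at steeper slopes
  the clipped trials put a hard ceiling on attainable R^2).

What the surrogates do **not** emulate: volume conduction between
channels, non-stationary coupling within a trial, spike-field
structure, artifacts, or 1/f^2 components. Passing tests on these
surrogates validates the estimators and the pipeline plumbing, not the
biological interpretation of any real recording.

## 5. Behavior module conventions

* Protraction amplitude = max angle in the response window (0–0.3 s)
  minus the pre-stimulus baseline mean; movement power = mean squared
  baseline-subtracted angle over the response window (a convention).
* Trial stratification: median split (stable-sorted, small group takes
  the middle trial at odd counts) and eight overlapping quantile
  groups of width 25% stepped by 75/7 ≈ 10.7%, membership half-open
  `(lo, hi]` with the first group closed at 0% so group means are
  strictly ordered on distinct amplitudes.
* Per-trial coherence features (coherence proper is undefined for a
  single trial): default is the leave-one-out delta — K times the
  change in inter-trial coherence when the trial is removed; a
  within-trial time-averaged coherency magnitude is the alternative.
  Both recover the generative link (R^2 >= 0.9) under the strong-link
  conditions.
* The amplitude predictor is ordinary least squares (ridge optional,
  required when trials < 2x features) over the frequency grid, with
  held-out R^2 from K-fold (default) or leave-one-out prediction, and
  support for applying a fitted predictor to another condition's
  trials.

## 6. Pipeline and formats

Recordings travel as HDF5 (`/signal` time x channel; `/meta` with
`sampling_rate`, `channel_depth_um`, `area`), events and result tables
as TSV, predictor models as JSON, run configuration as YAML. Every
pipeline output directory carries `run_config.json` with the config
hash and seed; identical config + seed reproduce identical files.
Malformed event rows abort the load with their line numbers; trials
whose window leaves the recording are dropped and logged, never
silently truncated.

## 7. Known limitations

* The rate model has no spiking, no conductances, no plasticity, and
  its weights are tuned defaults, not fitted parameters; only the
  qualitative condition contrasts are claims.
* The DoC chi-squared reference is approximate at very low coherence
  (conservative) and assumes trial counts, not mouse counts, as the
  effective sample size.
* The nonparametric Granger backend inherits Welch bias; treat its
  small values as order-of-magnitude.
* The line-noise rule is a stand-in (see above).
* `phi`'s gain saturation means condition contrasts depend on
  operating points; configurations far from the defaults may need
  re-tuning to reproduce the documented effects.
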