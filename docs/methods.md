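# Methods

This note documents the models, algorithms, numerical choices and
limitations of `empop`, in the order a user meets them.

## Compartmental model and simulator

Each membrane compartment follows the standard conductance-based form

    c_m du/dt = −Σ_k I_k(u, x) + I_axial + I(t),

with ionic currents `I_k = ḡ_k · o_k(x) · (u − E_k)` and first-order gating
variables `dx/dt = (x_∞(u) − x)/τ_x(u)`.  The built-in channel set is
minimal but sufficient for the pipeline's dynamics:

| mechanism | gates | reversal | role |
|---|---|---|---|
| `pas` | — | e_pas = −90 mV | leak; sets rest and input resistance |
| `NaT` | m³h (act. ≈ −38 mV, inact. ≈ −66 mV) | +50 mV | spike upstroke |
| `KdR` | n⁴ (act. ≈ −35 mV, τ 0.5–4.5 ms) | −85 mV | repolarization, repetitive firing |
| `Ih`  | q (half-act. −82 mV, τ 40 ms) | −45 mV | sag, resting depolarization |

Rates are at a nominal fixed temperature (no q10).  Parameters are
addressed as `region.mechanism.field` strings (`somatic.NaT.gbar`,
`all.pas.g`, ...) with region groups `all` and `alldend`.

**Discretization.** Sections are split into segments of at most
60 μm (≈ λ/10 at the default leak; configurable), with frustum lateral
areas and exact tapered-frustum axial resistances (Ra = 100 Ω·cm,
c_m = 1 μF/cm²).  The soma is a single compartment whose area counts
lateral plus end caps.  Myelin compartments have capacitance *and*
conductance densities reduced ×50 (the sheath insulates both).  Region
size scales: `soma_scale` multiplies the soma cylinder's radius and length
jointly (area ∝ scale²); `ais_scale` multiplies AIS diameters only
(length fixed at 60 μm).

**Integration.** Implicit Euler (default dt = 0.025 ms): gating states are
relaxed exactly (exponential integration with x_∞ and exp(−dt/τ) tabulated
on a 0.1 mV grid), then the voltage step — linear once gates are frozen —
is solved by Hines elimination on the compartment tree.  The scheme is
unconditionally stable; halving dt changes steady-state voltages by far
less than the tolerances used anywhere downstream.  Sub-threshold steady
states (holding search, input resistances) are computed by a damped
fixed-point iteration (gates at x_∞(v), linear tree solve; fallback to
relaxation by time integration if it fails to converge), which agrees with
long-probe simulation to numerical precision on passive and resting cells.

## Protocols and features

The characterization suite: (1) holding current to keep the soma at
−83 mV, bisection on the steady-state voltage to 10⁻³ nA; (2) rheobase =
smallest step above holding eliciting ≥ 1 spike, bisection between holding
and the current that would reach −30 mV (from the input resistance) — a
cell not spiking there is NON_SPIKING and later protocols are skipped;
(3) square steps at 150% and 200% of rheobase on top of holding (100 ms
pre-window, 400 ms step in the fixture suite, 1000 ms by default).
Spike/no-spike probes run at dt = 0.05 ms and end as soon as their outcome
is decided: at the first upward threshold crossing (spike), or once the
recorded voltage has been flat (change below 10⁻⁷ mV over a 100 ms
checkpoint window) and more than 2 mV below the spike threshold during the
stimulus — a settled sub-threshold autonomous cell cannot spike later.  An
optional bracket hint from a previous nearby evaluation narrows the
bisection, and the result is invariant to the starting bracket within
tolerance (tested).

Feature definitions are frozen in `protocols.py` (voltage_base, spikecount,
mean_frequency, AP_amplitude from the −20 mV crossing, AHP_depth relative
to voltage_base, ISI_mean, time_to_first_spike and its inverse, plus the
holding and threshold currents).  Undefined features are *missing*, never
zero.  The "reduced" feature set drops the redundant derived features
(ISI_mean, inv_time_to_first_spike) and is used for everything downstream
of sampling, mirroring the practice of discarding dendrite-shape-sensitive
features when generalizing across morphologies.

## Cost

`C(p) = max_i |z_i|` with `z_i = |f_i − mean_i| / sd_i`.  Missing features
score the sentinel `max_cost = 250 sd` (so a model that never produces a
feature is never rewarded), non-spiking models score the sentinel on every
feature, and grid-search/visualization clip at 8 sd.  Validity thresholds:
C* = 5 sd, strict 3 sd for sub-sampling.  A sum-of-scores aggregate exists
behind a flag for comparison only.

## MCMC

Parameters are affinely normalized to [−1, 1] per coordinate so bound sizes
and units cannot bias the isotropic Gaussian proposal `N(p̂, ε)`.
Proposals outside the hypercube are re-sampled until inside (as specified —
note this truncates the proposal without the corresponding
Metropolis–Hastings correction, so detailed balance is mildly violated in
an ε-wide boundary layer; at T → ∞ the outermost layer is measurably
depleted, which the tests document by checking uniformity on the interior).
Acceptance: draw a ~ U(0,1), accept iff `exp((C_i − C_j)/T) ≥ a`.
Two-phase schedule: burn-in chains from uniform starts (T = 5, ε = 0.2),
then main chains re-seeded from the k lowest-cost burn-in records (k = main
chain count, ties by record order) at T = 0.5, ε = 0.02.  One RNG per
chain, spawned from the master seed: runs are bitwise reproducible.
Burn-in records are excluded from analysis by default.  Diagnostics:
per-chain acceptance rate, chain-averaged normalized cost autocorrelation
(with the first lag below 0.1), per-feature cost-saturation fractions, and
the C < C* filter.

## ρ factors, calibration and adaptation

Component resistances are measured with active conductances at rest using a
−0.02 nA probe: isolated soma; isolated AIS probed at its proximal end; all
neurites (AIS + myelin + dendrites) joined at a near-zero-area junction node
and probed there ("no-soma"); soma + dendrites without AIS probed at the
soma ("no-AIS").  ρ = R_soma/R_nosoma, ρ_AIS = R_AIS/R_noAIS.

**Calibration.** A 10 × 10 grid of AIS/soma scales over [0.5, 1.5]
(endpoints inclusive) is evaluated with the reduced feature set, clipped at
8 sd, smoothed with a Gaussian kernel of sd 0.1 scale units (reflective
boundaries), and the argmin grid point (ties → lowest AIS scale, then
lowest soma scale) is converted to ρ targets via the component resistances
at those scales.  Calibration fails only if every grid point is non-spiking.

**Resistance surrogates.** Isolated-component input resistance vs scale is
fitted by a cubic in log₁₀–log₁₀ over scales 0.1–10 (13 points); fits with
log-RMS > 0.05 flag the e-model as non-adaptable.  For an isolated soma all
membrane conductances scale with area, so the curve is an exact power law
of slope −2; the AIS deviates through axial resistance, which is what the
cubic captures.

**Adaptation.** Two rounds of: measure R_noAIS → required R_AIS =
ρ_AIS,target · R_noAIS → AIS scale by surrogate inversion; measure R_nosoma
with the new AIS → required R_soma = ρ_target · R_nosoma → soma scale.
Inversion picks the in-range root nearest scale 1.0 and clamps (with a
flag) when the target is outside the fitted range.  Because the surrogate
is fitted on the exemplar while the adapted cell's component has a
different absolute size, the cubic is **anchored per cell**: each round
measures the cell's own isolated component once and shifts the curve by the
log-resistance offset before inverting.  With that anchoring the achieved ρ
factors land well inside the few-percent contract (typically < 0.5%).

## Evaluation matrix, selection, statistics, ML surrogates

Every (e-model, morphology) pair is adapted (optionally) and evaluated with
the reduced set; statuses VALID (C < 5 sd), FEATURE_FAIL, NON_SPIKING, or
FAILED (adaptation/simulation error) partition the matrix.  Selection
greedily drops the row or column with the most non-valid cells (ties prefer
dropping an e-model) until the remaining submatrix's valid fraction reaches
the target (0.95 default) — deterministic, possibly empty.

Statistics: Levene's test centered with the mean is the one-way ANOVA on
|x − group mean| (identical deviations everywhere → W = 0, p = 1);
Pearson r/p per parameter–feature pair (constant columns → missing);
feature–feature dependence by mutual information with 16 equal-frequency
bins (rank order breaks ties; optional median ± 5·MAD outlier removal, off
by default), in nats.

ML surrogates use a pluggable gradient-boosted-tree learner (XGBoost when
installed, sklearn's GradientBoosting otherwise; learning rate 0.1, 10-fold
validation reported).  Inputs are normalized parameters filtered by
|Pearson r| > 0.4 (ρ targets) or > 0.7 (resistance-model coefficients); if
nothing passes, the predictor is the training mean.  Predictions are
refused for inputs whose selected parameters leave the training 10th–90th
percentile box.

## Synthetic study conditions

The fixture generator emulates the conditions the pipeline targets:

- **Morphologies**: soma (radius 8 μm at scale 1), 60 μm axon stub, 1–3
  basal trees (count drawn once per population) with fixed total cable
  split across trees, an apical trunk with a tuft bifurcation; a per-cell
  global scale on lengths and diameters drawn log-uniformly so the total
  surface area spans a configurable fold-range (default 4, matching the
  3-to-5-fold spread of real pyramidal-cell morphometrics).  At spread 1
  cells are identical up to rotation.
- **Targets**: 10 virtual cells simulated at a known ground-truth parameter
  vector with Gaussian jitter of sd 0.05 in normalized coordinates;
  per-feature target mean/sd are the empirical moments, the sd floored at
  5% of |mean| (10⁻³ absolute for near-zero features) so z-scores stay
  finite as jitter → 0.  Non-spiking virtual cells halve the jitter and
  retry (3 attempts).
- **Ground truth** (6 sampled parameters): somatic/axonal NaT, somatic/basal
  KdR, global leak and Ih densities, with fixed axonal KdR (0.5 S/cm²) and
  e_pas = −90 mV.  The fixture protocol suite uses 400 ms steps at
  dt = 0.05 ms.

Problem sizes are chosen for desk scale: the recovery experiment runs
4 burn-in chains × 100 steps and 4 main chains × 300 steps, calibrates and
adapts 5 sampled e-models over 12 morphologies; the acceptance script runs
the full printed schedule (8 × 200 burn-in, 8 × 1000 main).  Everything is
deterministic per master seed.

What passing these tests shows — and does not.  The synthetic population
exercises every algorithmic path (degenerate parameter directions, size
extremes, non-spiking regions), and closed-loop recovery proves the
pipeline can find and generalize models when a consistent ground truth
exists.  It does not show that the 4-channel model class spans real L5PC
electrophysiology: real recordings have richer channel repertoires,
dendritic nonlinearities (calcium spikes, backpropagation) and measurement
noise that the generator deliberately omits.

## Known limitations

- The proposal truncation (re-sampling into the hypercube) slightly
  depletes an ε-wide boundary layer of the stationary distribution; the
  sampler is defined with exactly this boundary rule, and the effect is
  irrelevant when the posterior mass sits away from the bounds (the usual
  case after burn-in).
- Holding-current correlations have model-determined signs: positive with
  the leak conductance (e_pas = −90 mV below the −83 mV target) and
  negative with Ih (reversal −45 mV above it).  Any fixed pair of
  reversals on opposite sides of the target forces opposite signs.
- AHP depth is measured relative to voltage_base; eFEL-style alternatives
  (relative to spike threshold) would shift its scale but not the
  pipeline's behavior.
- The exemplar's soma-contour handling reduces every soma to an
  equivalent-area cylinder; reconstructed contours with strong asphericity
  lose shape information (area is preserved).
- Adaptation rescales only AIS and soma; dendritic load differences remain,
  so cells far from the exemplar in proximal dendritic surface area can
  stay invalid — that residual is exactly what the selection step and the
  proximal-surface-area predictor are for.
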