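# empop

Populations of detailed conductance-based neuron models with **controlled
morpho-electrical variability**: Metropolis–Hastings sampling of channel
conductance densities against feature-based electrophysiological targets,
and generalization of the sampled models across a morphology population by
ρ-factor-driven adaptation of axon-initial-segment (AIS) and soma sizes.

## Who this is for

Computational neuroscientists who need *many* valid biophysical models of a
cell type — not one optimized model — so that the variability of
experimental recordings (firing rates, spike amplitudes, holding and
rheobase currents, ...) is represented in the model population, and who
then need those models to remain valid across the morphological variability
of real reconstructions.

## The method

**Sampling.** An electrical model is a parameter vector `p` of maximal
conductance densities assigned to morphological regions (somatic/axonal
NaT, somatic/basal KdR, global leak and Ih in the built-in set).  Model
quality against experimental feature targets is the maximum absolute
z-score over features,

    C(p) = max_i |f_i(p) − f̄_exp,i| / σ(f_exp,i),

and models are sampled from

    P(p) ∝ exp(−C(p) / T)

with Metropolis–Hastings on the normalized hypercube `p̂ ∈ [−1, 1]^n`
(burn-in at T = 5 with proposal sd 0.2, main phase re-seeded from the best
burn-in records at T = 0.5 with proposal sd 0.02).  Features come from
simulated current-clamp protocols: holding current to −83 mV, rheobase by
bisection, and percent-rheobase square steps, all on a built-in
multi-compartment Hodgkin–Huxley simulator (implicit Euler, Hines tree
solve) — no external simulation engine.

**Generalization.** The excitability coupling between compartments is
summarized by the ρ factors

    ρ = R_in,soma / R_in,nosoma        ρ_AIS = R_in,AIS / R_in,noAIS,

ratios of isolated-component input resistances.  Target ρ factors per
(e-model, morphology-type) are calibrated by a smoothed grid search of the
model cost over AIS/soma scales on an exemplar morphology; each cell of the
population is then adapted — AIS and soma surface areas rescaled through
inverted log–log resistance models — so its ρ factors match the targets.
A model × morphology evaluation matrix (valid / feature-failure /
non-spiking) feeds a greedy selection of a generalizable sub-population,
and variability is analysed with mean-centered Levene tests, Pearson
correlations and binned mutual information.  Gradient-boosted-tree
surrogates can replace the expensive calibration for new models.

## Worked example

`examples/` contains one short script per capability.  For instance:

```bash
python examples/adapt_across_morphologies.py
```

prints (abbreviated):

```
calibrated targets: rho=6.53 rho_AIS=30.71 at grid point (AIS, soma) = (1.06, 0.94)
cell scale 0.81: soma x1.00, AIS x0.58, achieved rho 6.53, cost 10.16 ->  7.33 sd
cell scale 1.12: soma x0.93, AIS x0.95, achieved rho 6.53, cost  2.15 ->  1.66 sd
cell scale 1.20: soma x0.92, AIS x1.06, achieved rho 6.52, cost  0.38 ->  0.44 sd
cell scale 1.39: soma x0.91, AIS x1.33, achieved rho 6.52, cost  5.57 ->  4.91 sd
```

Each line is one cell of the synthetic population: its global size scale,
the AIS/soma rescaling the adaptation chose, the achieved ρ (vs. the 6.53
target), and the model cost in experimental standard deviations before and
after adaptation — a cost below 5 sd means every feature of the model on
that morphology lies within 5 experimental sd, i.e. the pair is valid.
Large cells are rescued by adaptation; cells far smaller than the exemplar
remain the hard cases.

Other examples: `simulate_and_characterize.py` (protocols and feature
extraction), `sample_electrical_models.py` (two-phase MCMC with
diagnostics), `diametrize_and_exemplar.py` (diameter models and exemplar
construction).  A thin CLI mirrors the main steps: `empop fixtures`,
`empop exemplar`, `empop diametrize`, `empop sample`, `empop calibrate-rho`,
`empop recover`.

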