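# socdev — self-organized criticality in developing neuronal networks

`socdev` simulates how a dissociated neuronal culture grows itself into
a critical network, and provides the complete avalanche-statistics
toolchain needed to classify any spike raster — simulated or recorded
on a multi-electrode array (MEA) — as subcritical, critical, or
supercritical.

## The science

**Growth model.** Each of *n* neurons on a planar grid carries a
membrane potential *v* (spike probability per step, hard-bounded to 1),
a calcium concentration *Ca* (a slow running estimate of its firing
rate), and two neurite fields: an axonal radius *a* and a dendritic
radius *d*. The synaptic density between two neurons is the overlap
area of the presynaptic axonal disk and the postsynaptic dendritic
disk, Ω_ij. Growth is homeostatic: with G = tanh((Ca − Ca_T)/Ca_T),

    Δd = −ρ_d · G,   Δa = +ρ_a · G,

so dendrites grow while the cell is too quiet (Ca < Ca_T) and are
pruned when it is too active; axons do the opposite. This closed loop
(activity → calcium → neurite fields → connectivity → activity) drives
the network through three developmental phases: slow dendritic
outgrowth (I), an explosive activity/connectivity overshoot during
which 20% of the neurons switch to inhibitory coupling (II, the GABA
switch), and morphological homeostasis (III), where the mean firing
rate settles at the calcium-balance value R\* = Ca_T/(τ_Ca β)
regardless of the inhibition level — only the *connectivity* (and the
criticality of the fluctuations) depends on inhibition.

**Avalanche analysis.** An avalanche is a maximal run of pooled spikes
with no silent gap of at least one time bin; the bin is adaptive (the
mean pooled inter-spike interval, after discarding intervals beyond
the 99%-area lag of the mean cross-correlogram). The size distribution
P(s) is fit by OLS on the log–log plot over its left linear region;
the deviation measure Δ — the mean log₁₀ residual of all observed
sizes from that line — classifies the state: Δ > 0.1 supercritical
(excess of system-spanning avalanches), Δ < −0.1 subcritical (tail
deficit), otherwise critical. Four further tests probe genuine
scale-freeness: spatial subsampling, time-bin robustness,
inter-avalanche scaling-function collapse, and the Fano factor
F(T) = Var(N_T)/E(N_T).

**Mean-field theory.** Averaging the dynamics gives closed-form limits
for the mean potential and calcium at fixed connectivity (bounded
below the critical gain, saturating/divergent above it), the
homeostatic rate R\*, the S-shaped (hysteresis) nullcline of potential
versus connectivity under a sigmoid firing surrogate, and the
fixed-point connectivity Ω̄\* with its equal-density hyperbola in
(a, d) space.

## Worked example

```python
from socdev import simulate, detect_phase
from socdev.experiments import default_development_params

params = default_development_params(seed=0)   # 100 neurons, 10x10 grid
raster, traj, state = simulate(params, 30_000)
phases = detect_phase(traj, params)
print("spikes:", raster.n_spikes)
print("phases reached:", sorted(set(str(x) for x in phases)))
print("switch time:", traj.switch_time)
print("late mean rate:", round(float(traj.rate[-10_000:].mean()), 4),
      " prediction:", params.ca_target / (params.tau_ca * params.beta_ca))
print("late mean calcium:", round(float(traj.ca_mean[-10_000:].mean()), 2),
      " target:", params.ca_target)
```

prints

```
spikes: 189465
phases reached: ['I', 'II', 'III']
switch time: 440
late mean rate: 0.0611  prediction: 0.06
late mean calcium: 30.65  target: 30.0
```

The development traverses all three phases: the GABA switch fires at
the Phase II calcium crossing (step 440), and in Phase III the mean
calcium sits at the homeostatic target with the firing rate within 2%
of the calcium-balance prediction R\* = 0.06 spikes/neuron/step. The
full developmental criticality sequence
(initial → supercritical → subcritical → critical) is produced by
`socdev.experiments.run_phase_experiment`, which analyzes avalanche
windows in each state over quasi-stationary (growth-slowed) epochs.

A critical branching-process raster recovers the hallmark −1.5
exponent through the adaptive avalanche pipeline:

```python
from socdev import analyze_raster
from socdev.fixtures import branching_raster
raster = branching_raster(59, sigma=1.0, drive_rate=0.002,
                          duration=2e6, seed=7)
_, fit = analyze_raster(raster)
print(round(fit.exponent, 2))   # -1.47
```

## Command line

```bash
socdev simulate --config cfg.yaml --steps 30000 --seed 1 \
       --out raster.tsv --traj traj.tsv
socdev analyze --raster raster.tsv          # bin, fit, Delta, label
socdev tests --raster raster.tsv            # criticality battery
socdev meanfield --config cfg.yaml --omega 0 --omega 5
socdev fixtures --kind branching --sigma 1.0 --out branching.tsv
socdev experiment --seed 1 --out-dir experiment_out
```

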