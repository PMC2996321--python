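# Methods

This note documents the model, the analysis pipeline, the synthetic
oracles, and the numerical and design choices behind them. Everything
quantitative stated here is computed by the test suite or by
`scripts/acceptance.py`; nothing is quoted from elsewhere.

## The growth-network model

The simulator implements an activity-dependent neurite-outgrowth
network of the classic homeostatic-growth family, with separate axonal
and dendritic fields per neuron. `n` neurons sit on an open (non-periodic)
rectangular grid. Each neuron `i` carries four state variables:

* membrane potential `v_i ∈ [0, 1]`,
* intracellular calcium `ca_i ≥ 0`,
* axonal field radius `a_i ≥ 0` ("axonal supply"),
* dendritic field radius `d_i ≥ 0` ("dendritic acceptance").

One Euler step (`dt = 1` simulated time step) advances:

1. **Spiking.** A non-refractory neuron spikes iff `v_j ≥ ξ_j` with a
   fresh uniform threshold `ξ_j ~ U[0, 1)`; so the instantaneous spike
   probability per step equals the membrane potential. A spike starts a
   refractory period of `refractory_steps` (default 4) silent steps, so
   the rate ceiling is `1/(refractory_steps+1) = 0.2` spikes/step.
2. **Potential.** `v_i ← v_i + (v_rest − v_i)/τ_v + Σ_j ε_j Ω_ij S_j`,
   where `S_j` is the spike indicator, `ε_j = +w_exc` for excitatory
   and `−w_inh` for inhibitory presynaptic neurons, and the result is
   clipped to `[v_floor, 1]` (hard bound at 1; floor 0 by default).
3. **Calcium.** `ca_i ← ca_i − ca_i/τ_ca + β S_i`: a slow, per-neuron
   running estimate of the firing rate (`ca* = τ_ca β R`).
4. **Growth.** With the saturating drive
   `G_i = tanh((ca_i − Ca_T)/Ca_T)`:
   `d_i ← max(0, d_i − ρ_d G_i)`, `a_i ← max(0, a_i + ρ_a G_i)`.
   Dendrites grow when calcium is below the homeostatic target `Ca_T`
   and shrink above it; axons do the opposite at a slower rate.
5. **Connectivity.** `Ω_ij` = area of intersection of the dendritic
   disk of `i` and the axonal disk of `j` (closed-form circular-lens
   formula), `Ω_ii = 0`; recomputed from `(a, d)` every step. A
   Gaussian-product kernel is available as a configuration alternative
   (`overlap_kernel="gaussian"`).

Throughout the package the scalar "mean connectivity" `Ω̄` is the mean
over neurons of the **total incoming** synaptic density (row sum of
`Ω`).

### Why the growth drive saturates

A linear drive `ρ (ca − Ca_T)` is ill-posed here: during Phase I the
calcium deficit is of order `Ca_T`, so the axonal field shrinks at
`~ρ_a Ca_T` per step and reaches zero radius — hence zero overlap with
every dendrite, permanently — before the first activity overshoot can
raise calcium, for plausible targets. The `tanh` of the *relative*
deviation is linear near the target (gain `ρ/Ca_T`) and bounded by `ρ`
far from it, which keeps early development well-posed and makes the
near-equilibrium dynamics gentle. This is also the standard choice in
the outgrowth-model family this simulator extends.

### Parameters and defaults

Time constants and rates are per simulated step: `τ_v = 5`,
`τ_ca = 1000`, `v_rest = 0.0005`, `β = 0.5`, `ρ_d = 0.05`,
`ρ_a = 0.01`, `w_exc = 0.02`, 100 neurons on a 10×10 grid, 20%
inhibitory conversion, refractory period 4. These follow the standard
parameter set of this model family; the homeostatic calcium target
`Ca_T` has no canonical published value and must be chosen per use
(`ModelParams.ca_target` is a required argument).

Two packaged configurations cover the two regimes of interest:

* **Development configuration** (`default_development_params`):
  `Ca_T = 30`, grid spacing 4, initial fields `(a, d) = (3.9, 0)`.
  The large target lengthens the calcium lag behind the activity
  explosion, so the dendritic overshoot spans most of the grid and the
  Phase II potential plateau saturates at the hard bound — the regime
  in which a dissociated culture's overshoot drives essentially every
  cell. Homeostatic rate `R* = Ca_T/(τ_ca β) = 0.06` spikes/neuron/step.
* **Analysis configuration** (`default_experiment_params`):
  `Ca_T = 2.5`, grid spacing 10, initial fields `(5, 0)`. The
  homeostatic pooled rate (0.5 spikes/step for 100 neurons) keeps the
  adaptive avalanche time bin above the simulation step, so avalanches
  are resolved rather than chopped at step boundaries, and the wider
  grid keeps connectivity local so avalanches are spatially graded
  rather than all-or-none.

The initial fields are chosen so that no overlaps exist at `t = 0`
("no connections") while the axonal field survives its Phase I
shrinkage until dendritic growth creates the first contacts.

### Developmental phases

`detect_phase` labels a recorded trajectory: Phase I while mean calcium
is below target, Phase II from the first crossing (the overshoot),
Phase III once the sliding-window mean of the relative calcium
deviation stays within `ca_tol` (default 0.1 over 500 steps) for the
rest of the recording. The defaults reflect the intrinsic fluctuation
scale of a 100-neuron network: per-neuron calcium is a shot-noise
estimate of the rate, so small populations cannot hold the population
mean much tighter than a few percent.

The GABA switch (conversion of a uniformly random 20% subset to
`ε = −w_inh`) fires by default at the Phase II calcium crossing, the
point of massive synapse formation; a fixed-step trigger is available.

## Avalanche analysis

Avalanches are maximal runs of pooled (all-unit) spikes with no silent
gap of at least one time bin. The bin is the mean pooled inter-spike
interval after discarding intervals longer than a cutoff: the lag
below which 99% of the mean pairwise cross-correlogram area lies. The
correlogram is computed at the native resolution (1 step or 1 ms) up
to a default maximum lag of 1000, as the pooled pair histogram (FFT)
minus the same-unit pair histograms (sparse per unit); its
normalization cancels in the cutoff.

The size distribution `P(s)` over observed sizes is compared with an
ordinary least-squares line through `(log10 s, log10 P)` anchored at
the small-size end: starting from the three smallest observed sizes,
the window expands to the largest size at which the regression R²
stays ≥ 0.98 ("the end of the linear behaviour"); both ends can be
overridden. The deviation measure Δ is the mean log10 residual of
*all* observed sizes from that line; classification uses heuristic
thresholds ±0.1 (configurable): Δ > 0.1 supercritical, Δ < −0.1
subcritical, otherwise critical.

Two properties of Δ are worth knowing. First, it is intentionally
left-anchored, so tail excess (a bump of large avalanches) gives
Δ > 0 and tail deficit gives Δ < 0; on exact power laws it is 0 to
numerical precision. Second, on finite samples the sparse tail sits at
the resolution floor `1/n_avalanches`, which biases Δ upward for
heavy-tailed data: on Galton-Watson cascade oracles the measured Δ
crosses zero near branching parameter σ ≈ 0.9 and is ≈ +0.5 at σ = 1.
Δ is therefore used as an ordinal criticality index (it is strictly
monotone in σ across 0.8–1.2 on the oracles), not as an unbiased
distance to the σ = 1 process.

## Criticality test battery

* **Spatial subsampling** re-runs the full pipeline on random unit
  subsets; a scale-free raster keeps its exponent and Δ.
* **Time-bin robustness** repeats the analysis at rescaled bins.
  Multipliers below the cascade propagation delay resolve individual
  generations and chop cascades; the robustness claim applies to bins
  at or above that delay (on the branching oracle, exponent and Δ move
  by < 0.01 across multipliers 1–4).
* **Scaling-function collapse**: inter-onset intervals of avalanches
  with size ≥ s, rescaled by the rate λ_s = (n−1)/span (exact unit
  mean), compared across s by the maximum pairwise Kolmogorov
  sup-distance between empirical distribution functions (tolerance
  0.1). On bursts with iid sizes riding Poisson onsets every rescaled
  curve is the unit exponential (verified against `Exp(1)` by KS).
  Note a structural caveat: for *dense* rasters the silent-gap
  definition imposes a refractory-like floor ≈ one bin on inter-onset
  intervals, which distorts the smallest-s curves; heavy thinning
  removes it.
* **Fano factor** `F(T)` over disjoint windows from `t = 0`. For a
  Poisson raster `F ≡ 1`; for binary trains `F(T→0) → 1 − p`. On
  clustered scale-free rasters F follows a power law across the
  avalanche-relevant range of T and plateaus beyond the cascade
  timescale, where cascades decorrelate (both regimes are asserted on
  the oracle).

## Mean-field companion

Averaging over neurons with the uniform-threshold rate `R(V) = V`
makes the averaged potential equation linear with effective gain
`g = τ_v W f(Ω̄)` (density function `f` = identity by default):
`g = 0` relaxes to `v_rest`; `0 < g < 1` to bounded limits
`V∞ = v_rest/(1−g)`, `Ca∞ = τ_ca β V∞` (closed forms verified against
an independent ODE integration to 1e-6); `g ≥ 1` is the transition
regime — the potential saturates at the hard bound and calcium is
flagged divergent (never a floating overflow).

The homeostatic rate follows from calcium stationarity at the target:
`R* = Ca_T/(τ_ca β)`, infeasible above the refractory ceiling. The
fixed point maps `R*` through the actual firing rule with refractory
correction (`R = V (1 − refractory_steps·R)`) to `V*`, then through
the stationary potential balance to `Ω̄*`. The equal-density relation
in `(a, d)` space — many field combinations, one connectivity — is
exposed as the `on_hyperbola` predicate.

The nullcline analysis replaces the Heaviside firing rule with a
sigmoid `σ_k(V − v_θ)` (defaults `k = 20`, `v_θ = 0.5`; the steepness
has no canonical value and is exposed in the configuration): for steep
sigmoids the stationary potential equation has an S-shaped solution
set (one or three stationary points per density, hysteresis), found by
bracketed root-finding (tolerance 1e-10) on a 2001-point scan of
`[0, 1]` plus the saturated branch `V = 1` where the drive at the
bound is positive.

## Synthetic oracles

* `poisson_raster`: independent homogeneous Poisson trains — the null
  model (F ≡ 1, strongly sub-power-law avalanche distribution,
  Δ ≈ −1.8 at the packaged rate/duration).
* `branching_raster`: Galton-Watson cascades with Poisson(σ) offspring
  per spike, ancestors arriving as a Poisson process (default rate
  0.002/step, sparse enough that the adaptive bin separates cascades;
  merging probability ~1%). Generations are one step apart with spikes
  jittered uniformly within the step, as in a continuous-time
  recording. Cascades stop after 100 generations (critical cascades
  have infinite mean size; a time cap leaves no pileup at any single
  size) with a hard safety cap of 5000 spikes. At σ = 1 the size
  distribution is Borel: the left-anchored OLS slope over the linear
  region is ≈ −1.45 to −1.5 (the small-s Borel curvature flattens the
  pure −3/2 asymptote slightly); for σ < 1 the mean total progeny is
  `1/(1−σ)` (asserted against the generator's own sizes).

What these fixtures emulate: the event statistics (sizes, timing,
clustering) of culture recordings. What they do not: spatial electrode
geometry, per-electrode rate heterogeneity, bursts with internal
temporal structure, or any nonstationarity across a recording. Tests
passing on them validate the analysis pipeline, not the biology of any
particular culture.

## The developmental-state experiment

`run_phase_experiment` reproduces the four-state developmental
sequence with one parameter set (the analysis configuration) and a
protocol with two deliberate timescale devices:

1. **Initial state, frozen growth.** The run is paused just below the
   activity explosion (recurrent gain 0.6) and a cloned state runs
   20,000 steps with growth frozen. In a real culture neurite growth
   is orders of magnitude slower than spiking, so an activity window
   sees a fixed network; the simulator's growth is fast by
   construction, and freezing restores that separation for the one
   state that exists only transiently. This window shows the
   Poisson-to-power-law transitional distribution (Δ well below the
   subcritical threshold).
2. **Supercritical overshoot.** A window centred on the GABA switch
   captures the overshoot: connectivity far above the balance level
   produces a heavy bump of system-spanning avalanches (Δ ≫ 0.1) even
   though the inhibition onset is strong.
3. **Subcritical, strong inhibition.** The development runs to
   equilibrium under the strong onset, then the growth rate is reduced
   100-fold and a 30,000-step quasi-stationary window is analyzed. The
   over-inhibited network lacks large avalanches (Δ below the
   subcritical threshold; the saturation is shallow, ≈ −0.1 to −0.2,
   and single-window estimates fluctuate by ≈ ±0.06 across seeds).
4. **Critical, pruned inhibition.** Still within the quasi-stationary
   epoch the inhibitory strength is reduced to the network's balance
   point — connectivity barely moves, as for a culture whose
   inhibitory synapses weaken on the slow developmental timescale —
   and a second window is analyzed (|Δ| ≤ 0.1 across seeds).

Two ratios parametrize the protocol: the onset strength (default
`w_inh = 8 w_exc`) and the final, balance strength (default
`4 w_exc`). In this reconstruction the balance point sits above unity
because sub-threshold inhibitory input is partially shunted at the
potential floor (`v` cannot fall below 0, and between avalanches it
sits near 0), so a unit inhibitory weight dissipates less than a unit
excitatory weight amplifies; the overlap-kernel normalization also
shifts where the balance lies. The homeostatic *rate* is independent
of these ratios; only the criticality of the fluctuations around it
changes. Scanning `w_inh/w_exc` over 0–8 in from-scratch equilibria
gives Δ falling monotonically from ≈ +0.3 (purely excitatory:
slightly supercritical) through ≈ 0 near ratio 3–4 to the shallow
subcritical saturation at ratio 8 — further increases change little,
consistent with inhibition acting only on the shrinking set of
moments when potentials are elevated.

One further caveat belongs here: at the full growth rate the Phase III
connectivity is not stationary — the slow outward drift of the axonal
fields (see Limitations) inflates the total overlap over tens of
thousands of steps, carrying the fluctuation statistics gradually
toward supercriticality at any inhibition level. State classification
is therefore only meaningful on growth-slowed epochs, and the
rebalancing step is performed inside one.

The sudden-inhibition-change experiment (`run_inhibition_jump`)
equilibrates under the strong onset, jumps `w_inh`, and shows the
model's signature dissociation: Δ changes immediately (weakened
inhibition → supercritical transient), the firing rate relaxes back
to `R*` once growth responds, and the total connectivity settles at a
lastingly different level.

## Numerical choices and conventions

* Refractory bookkeeping: a neuron spiking at step t is eligible again
  at t+5 (4 fully silent steps).
* `Ω` diagonal forced to zero (no autapses): self-excitation would
  distort avalanche statistics.
* Disk-overlap formula guards `acos` arguments and the triangle term
  against round-off at tangency; overlap is exactly 0 for zero radii.
* Avalanche detection splits at gaps `≥ bin` (silence of at least one
  bin ends an avalanche); inter-avalanche intervals (end-to-start) are
  therefore `≥ bin` by construction.
* Cross-correlogram pair counts use both orders at every lag,
  including lag 0, so the curve is comparable across lags.
* Electrode selection excludes units with counts strictly greater than
  mean + 2 SD, in a single pass (mean/SD are not recomputed after
  exclusion); "active" means ≥ 1 spike; acceptance requires ≥ 50
  active units. With zero SD (identical counts) nothing is excluded.
* All randomness flows from explicit seeds through
  `numpy.random.Generator`; identical seed and parameters give
  bit-identical rasters.

## Problem sizes

Packaged protocols use 100-neuron networks and runs of 25,000–130,000
steps (development plus analysis epochs), 59-unit fixture rasters of
2×10^5–6×10^6 time units, and ≥ 10^4 cascades for exponent recovery.
These sizes hold Monte-Carlo errors on the reported quantities to the
few-percent level while keeping any single protocol in the
one-to-few-minute range on one CPU core.

## Known limitations

* The network topology is abstract (overlap areas, not synapses); no
  axon guidance, no spatial heterogeneity of real cultures.
* The GABA switch is a sign flip, not a chloride-reversal model.
* Δ is a biased estimator of distance-to-criticality on finite
  samples (see above); comparisons should stay within a fixed raster
  size and pipeline configuration.
* Growth and activity share one clock; quasi-stationary analysis
  requires the explicit slowdown devices described above.
* Small networks (tens of neurons) cannot hold tight calcium
  homeostasis; population-level claims are asserted at n = 100.
* The mean-field density function `f` and the sigmoid steepness are
  modeling choices exposed in configuration, not fitted quantities.
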