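"""In-silico developmental experiments.

Scenario drivers that reproduce the characteristic protocols on the
growth network:

* :func:`run_phase_experiment` — a full development with per-state
  avalanche analysis: a frozen-growth snapshot of the late-Phase-I
  network (initial state, trending from Poisson toward a power law),
  the Phase II overshoot window at the GABA switch (supercritical),
  the equilibrated Phase III under the strong inhibition onset
  (subcritical), and Phase III after the inhibitory strength has been
  pruned back to the network's balance point (critical).
* :func:`run_inhibition_jump` — disturb an equilibrated network by a
  sudden change of inhibition and follow the transient.
* measurement helpers (:func:`phase2_plateau`, :func:`inhibitory_share`).

Two deliberate timescale devices, both documented in the methods note:

* The initial-state window is analyzed with growth frozen at a
  late-Phase-I connectivity. In a developing culture, neurite growth is
  orders of magnitude slower than spiking, so any activity window sees
  an essentially fixed network; the simulator's growth step is fast by
  construction, and freezing restores the separation for the one state
  that exists only transiently.
* The equilibrated Phase III windows run with growth slowed by
  ``analysis_slowdown``: avalanche statistics require a quasi-stationary
  network, and the homeostatic state is independent of the growth rate,
  which only sets the tempo.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, replace

import numpy as np

from .avalanches import DEFAULT_THRESHOLDS, analyze_raster, DistributionFit
from .model import (
    ModelParams,
    Trajectory,
    apply_gaba_switch,
    apply_inhibition_jump,
    detect_phase,
    init_network,
    simulate,
    step_dynamics,
    update_growth,
)

__all__ = [
    "PhaseExperimentConfig",
    "PhaseExperimentReport",
    "run_phase_experiment",
    "run_inhibition_jump",
    "InhibitionJumpReport",
    "phase2_plateau",
    "inhibitory_share",
    "default_experiment_params",
    "default_development_params",
]


def default_development_params(seed: int = 0, **overrides) -> ModelParams:
    """Standard development configuration (overshoot physics).

    A compact grid with a large calcium target: the dendritic overshoot
    then spans most of the population, so the Phase II potential
    plateau saturates at the hard bound, as in the full-size system.
    """
    kw = dict(ca_target=30.0, grid_spacing=4.0, init_a=3.9, seed=seed)
    kw.update(overrides)
    return ModelParams(**kw)


def default_experiment_params(seed: int = 0, **overrides) -> ModelParams:
    """Configuration for avalanche-statistics experiments.

    The lower calcium target keeps the homeostatic pooled rate well
    below one spike per step, so the adaptive time bin exceeds the
    simulation step and avalanches are resolved rather than chopped at
    step boundaries.
    """
    kw = dict(ca_target=2.5, grid_spacing=10.0, init_a=5.0, seed=seed)
    kw.update(overrides)
    return ModelParams(**kw)


@dataclass(kw_only=True)
class PhaseExperimentConfig:
    """Protocol of the development-and-rebalancing experiment.

    Inhibition arrives strong (``strong_ratio`` times the excitatory
    weight) at the Phase II transition and is later pruned to
    ``final_ratio``; the network's own balance point sits above one
    because sub-threshold inhibitory input is partially shunted at the
    potential floor. Analysis epochs run with growth slowed by
    ``analysis_slowdown`` (quasi-stationary network).
    """

    params: ModelParams
    strong_ratio: float = 8.0
    final_ratio: float = 4.0
    n_develop: int = 25_000
    n_initial: int = 20_000
    n_analysis: int = 40_000
    analysis_window: int = 30_000
    overshoot_window: int = 3_000
    analysis_slowdown: float = 100.0
    freeze_gain: float = 0.6
    thresholds: tuple = DEFAULT_THRESHOLDS


@dataclass
class PhaseExperimentReport:
    """Windows, fits and classifications of the phase experiment.

    ``windows`` maps window name -> (raster, DistributionFit or None).
    A ``None`` fit marks a window whose avalanche analysis was
    degenerate (e.g. one endless avalanche), reported via ``notes``.
    """

    config: PhaseExperimentConfig
    windows: dict
    trajectory: Trajectory
    phase_labels: np.ndarray
    switch_time: int | None
    notes: list

    def labels(self) -> dict:
        return {
            name: (fit.label if fit is not None else None)
            for name, (_, fit) in self.windows.items()
        }

    def deltas(self) -> dict:
        return {
            name: (fit.delta if fit is not None else None)
            for name, (_, fit) in self.windows.items()
        }


def _analyze(raster, thresholds, notes, name):
    try:
        _, fit = analyze_raster(raster, thresholds=thresholds)
    except ValueError as err:
        notes.append(f"window {name!r}: degenerate analysis ({err})")
        fit = None
    return (raster, fit)


def _cat_trajs(trajs, switch_time, ca_target):
    return Trajectory(
        t=np.concatenate([t.t for t in trajs]),
        v_mean=np.concatenate([t.v_mean for t in trajs]),
        ca_mean=np.concatenate([t.ca_mean for t in trajs]),
        a_mean=np.concatenate([t.a_mean for t in trajs]),
        d_mean=np.concatenate([t.d_mean for t in trajs]),
        omega_mean=np.concatenate([t.omega_mean for t in trajs]),
        rate=np.concatenate([t.rate for t in trajs]),
        switch_time=switch_time,
        ca_target=ca_target,
    )


def run_phase_experiment(config: PhaseExperimentConfig) -> PhaseExperimentReport:
    """Full development with per-state avalanche analysis.

    Stages:

    1. develop with the strong inhibition onset until the network is
       near (but below) the activity explosion; clone the state, freeze
       growth, and record the ``initial`` window at fixed connectivity;
    2. continue the development through the overshoot; the
       ``supercritical`` window starts at the GABA switch;
    3. slow the growth and record the equilibrated strong-inhibition
       ``subcritical`` window;
    4. still within the growth-slowed epoch, prune the inhibitory
       strength to the balance point and record the ``critical``
       window.
    """
    notes: list[str] = []
    p = config.params
    w_exc = p.w_exc
    p_dev = replace(p, w_inh=config.strong_ratio * w_exc)
    p_slow = replace(
        p_dev,
        rho_d=p.rho_d / config.analysis_slowdown,
        rho_a=p.rho_a / config.analysis_slowdown,
    )
    trajs = []

    # stage 1: grow to the pre-critical point, snapshot, freeze
    state = init_network(p_dev)
    gain_threshold = config.freeze_gain / (p.tau_v * w_exc)
    while state.mean_omega() < gain_threshold:
        step_dynamics(state, p_dev)
        update_growth(state, p_dev)
        if state.t >= config.n_develop:
            notes.append("pre-critical gain threshold never reached")
            break
    frozen = copy.deepcopy(state)
    p_frozen = replace(p_dev, rho_d=1e-300, rho_a=1e-300)
    raster_init, _, _ = simulate(p_frozen, config.n_initial, state=frozen,
                                 switch_policy="never")
    windows = {
        "initial": _analyze(
            raster_init.crop(raster_init.duration - config.n_initial,
                             raster_init.duration),
            config.thresholds, notes, "initial",
        )
    }

    # stage 2: development through the overshoot and on to equilibrium
    # under the strong inhibition onset
    t_start = state.t
    raster_dev, traj_dev, state = simulate(
        p_dev, config.n_develop - state.t, state=state
    )
    trajs.append(traj_dev)
    switch_time = traj_dev.switch_time
    if switch_time is None:
        notes.append("GABA switch never triggered during development")
    t_over = switch_time if switch_time is not None else t_start
    # the overshoot spans the transition: window centred on the switch
    half = config.overshoot_window // 2
    windows["supercritical"] = _analyze(
        raster_dev.crop(max(t_start, t_over - half), t_over + half),
        config.thresholds, notes, "supercritical",
    )

    # stage 3: quasi-stationary strong-inhibition epoch (equilibrated,
    # still over-inhibited relative to the balance point)
    raster_a, traj_a, state = simulate(p_slow, config.n_analysis, state=state)
    trajs.append(traj_a)
    windows["subcritical"] = _analyze(
        raster_a.crop(state.t - config.analysis_window, state.t),
        config.thresholds, notes, "subcritical",
    )

    # stage 4: prune the inhibitory strength to the balance point
    # within the quasi-stationary epoch (connectivity barely moves, as
    # for a culture whose inhibitory synapses weaken on the slow
    # developmental timescale)
    w_final = config.final_ratio * w_exc
    p_final_slow = replace(p_slow, w_inh=w_final)
    if state.gaba_switched:
        apply_inhibition_jump(state, w_final)
    raster_b, traj_b, state = simulate(p_final_slow, config.n_analysis,
                                       state=state)
    trajs.append(traj_b)
    windows["critical"] = _analyze(
        raster_b.crop(state.t - config.analysis_window, state.t),
        config.thresholds, notes, "critical",
    )

    traj = _cat_trajs(trajs, switch_time, p.ca_target)
    phase_labels = detect_phase(traj, p, ca_tol=0.1, window=500)
    return PhaseExperimentReport(
        config=config, windows=windows, trajectory=traj,
        phase_labels=phase_labels, switch_time=switch_time, notes=notes,
    )


@dataclass
class InhibitionJumpReport:
    """Response of an equilibrated network to an inhibition jump.

    ``fit_before``/``fit_after`` bracket the jump (both measured on
    quasi-stationary epochs); ``fit_late`` is measured after the growth
    process has responded at the developmental rate. The model's
    signature: criticality changes immediately and remains changed,
    the firing rate relaxes back to its homeostatic value, and the
    total connectivity settles at a lastingly different level.
    """

    fit_before: DistributionFit | None
    fit_after: DistributionFit | None
    fit_late: DistributionFit | None
    rate_before: float
    rate_after: float
    rate_late: float
    omega_before: float
    omega_late: float
    trajectory: Trajectory


def run_inhibition_jump(
    params: ModelParams,
    new_w_inh: float,
    strong_ratio: float = 8.0,
    n_equilibrate: int = 25_000,
    n_analysis: int = 40_000,
    analysis_window: int = 30_000,
    n_regrow: int = 25_000,
    analysis_slowdown: float = 100.0,
    thresholds=DEFAULT_THRESHOLDS,
) -> InhibitionJumpReport:
    """Equilibrate, jump the inhibitory strength, follow the response.

    Staging mirrors :func:`run_phase_experiment`: every avalanche
    window sits on a growth-slowed (quasi-stationary) epoch. After the
    ``before`` epoch the inhibitory strength jumps to ``new_w_inh``
    with connectivity quasi-frozen (``after`` epoch, the immediate
    criticality change); then growth responds at the developmental
    rate for ``n_regrow`` steps and a final slowed epoch (``late``)
    shows the rate restored by homeostasis while connectivity and
    criticality remain changed.
    """
    notes: list[str] = []
    p_dev = replace(params, w_inh=strong_ratio * params.w_exc)
    p_slow = replace(p_dev, rho_d=params.rho_d / analysis_slowdown,
                     rho_a=params.rho_a / analysis_slowdown)
    _, traj0, state = simulate(p_dev, n_equilibrate)
    raster1, traj1, state = simulate(p_slow, n_analysis, state=state)
    fit_before = _analyze(
        raster1.crop(state.t - analysis_window, state.t), thresholds,
        notes, "before",
    )[1]
    omega_before = float(traj1.omega_mean[-10_000:].mean())
    rate_before = float(traj1.rate[-10_000:].mean())

    apply_inhibition_jump(state, new_w_inh)
    p_post_slow = replace(p_slow, w_inh=new_w_inh)
    raster2, traj2, state = simulate(p_post_slow, n_analysis, state=state)
    fit_after = _analyze(
        raster2.crop(state.t - analysis_window, state.t), thresholds,
        notes, "after",
    )[1]
    rate_after = float(traj2.rate[-10_000:].mean())

    # growth responds at the developmental rate, then a final slowed
    # epoch for like-for-like measurement
    p_post = replace(p_dev, w_inh=new_w_inh)
    _, traj3, state = simulate(p_post, n_regrow, state=state)
    raster4, traj4, state = simulate(p_post_slow, n_analysis, state=state)
    fit_late = _analyze(
        raster4.crop(state.t - analysis_window, state.t), thresholds,
        notes, "late",
    )[1]
    rate_late = float(traj4.rate[-10_000:].mean())
    omega_late = float(traj4.omega_mean[-10_000:].mean())

    traj = _cat_trajs([traj0, traj1, traj2, traj3, traj4],
                      traj0.switch_time, params.ca_target)
    return InhibitionJumpReport(
        fit_before=fit_before, fit_after=fit_after, fit_late=fit_late,
        rate_before=rate_before, rate_after=rate_after, rate_late=rate_late,
        omega_before=omega_before, omega_late=omega_late,
        trajectory=traj,
    )


def phase2_plateau(
    params: ModelParams, n_steps: int = 6_000, smooth: int = 20
) -> float:
    """Plateau of the mean membrane potential through the Phase II
    overshoot (no inhibitory conversion): the maximum of the
    ``smooth``-step running mean of the population-mean potential."""
    p = replace(params, inhib_fraction=0.0)
    _, traj, _ = simulate(p, n_steps, switch_policy="never")
    kernel = np.ones(smooth) / smooth
    running = np.convolve(traj.v_mean, kernel, mode="valid")
    return float(running.max())


def inhibitory_share(
    params: ModelParams,
    n_steps: int = 130_000,
    average_last: int = 20_000,
    sample_every: int = 100,
) -> float:
    """Fraction of total synaptic density with inhibitory presynapse
    after Phase III equilibration (a number in [0, 1]).

    The development runs to homeostasis with the GABA switch at the
    Phase II transition; over the last ``average_last`` steps the ratio
    ``sum_(j inhibitory) sum_i Omega_ij / sum_ij Omega_ij`` is sampled
    every ``sample_every`` steps and averaged.
    """
    state = init_network(params)
    shares: list[float] = []
    for i in range(n_steps):
        if (not state.gaba_switched and params.inhib_fraction > 0
                and state.ca.mean() >= params.ca_target):
            apply_gaba_switch(state, params)
        step_dynamics(state, params)
        update_growth(state, params)
        if i >= n_steps - average_last and i % sample_every == 0:
            total = state.omega.sum()
            if total > 0:
                shares.append(
                    float(state.omega[:, state.inhibitory].sum() / total)
                )
    if not shares:
        raise RuntimeError("no connectivity during the averaging window")
    return float(np.mean(shares))
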