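"""Activity-dependent neurite-outgrowth network model.

A two-dimensional recurrent network of stochastic threshold units whose
connectivity is not fixed but grows: each neuron carries an axonal field
(its "supply" of presynaptic contact area) and a dendritic field (its
"acceptance" of inputs), both modelled as disks on a planar grid. The
pairwise overlap of dendritic and axonal disks defines the synaptic
density Omega_ij between postsynaptic neuron i and presynaptic neuron j.

Per-neuron dynamics (Euler-integrated, one simulated time step):

* membrane potential ``v`` decays exponentially toward the resting
  potential with time constant ``tau_v`` and jumps by
  ``sum_j eps_j * Omega_ij`` over the presynaptic neurons j that spiked;
  ``v`` is hard-bounded to 1 (and floored at 0).
* a non-refractory neuron spikes when ``v >= xi`` for a fresh uniform
  threshold ``xi ~ U[0, 1)``; spiking triggers a refractory period.
* calcium ``ca`` decays with time constant ``tau_ca`` and receives an
  influx ``beta_ca`` on each spike, so calcium is a running measure of
  the firing rate.
* growth drives calcium toward a homeostatic target ``ca_target``: the
  dendritic field grows when calcium is below target and shrinks above
  it; the axonal field does the opposite, with its own (slower) rate.

The negative feedback loop activity -> calcium -> neurite fields ->
connectivity -> activity carries the network through three
developmental phases: dendritic outgrowth at low activity (Phase I), an
activity/connectivity overshoot with a one-time conversion of a neuron
subset to inhibitory coupling (Phase II, the GABA switch), and
morphological homeostasis (Phase III) in which mean calcium sits at the
target and the mean firing rate is parameter-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .raster import SpikeRaster

__all__ = [
    "ModelParams",
    "NetworkState",
    "Trajectory",
    "init_network",
    "step_dynamics",
    "update_growth",
    "compute_connectivity",
    "disk_overlap",
    "apply_gaba_switch",
    "apply_inhibition_jump",
    "simulate",
    "detect_phase",
]


@dataclass(kw_only=True)
class ModelParams:
    """Model configuration.

    ``ca_target`` has no universal default in the literature this model
    descends from and must be supplied explicitly; the packaged
    configurations in :mod:`socdev.experiments` use 30 (development /
    overshoot studies) and 2.5 (avalanche statistics). All rates and
    time constants are per simulated time step (dt = 1). The implied
    homeostatic rate ``ca_target / (tau_ca * beta_ca)`` must stay below
    the refractory ceiling ``1 / (refractory_steps + 1)``.
    """

    ca_target: float
    n_neurons: int = 100
    grid_rows: int = 10
    grid_cols: int = 10
    grid_spacing: float = 10.0
    tau_v: float = 5.0
    tau_ca: float = 1000.0
    v_rest: float = 0.0005
    beta_ca: float = 0.5
    rho_d: float = 0.05
    rho_a: float = 0.01
    w_exc: float = 0.02
    w_inh: float = 0.02
    inhib_fraction: float = 0.2
    refractory_steps: int = 4
    init_a: float = 5.0
    init_d: float = 0.0
    overlap_kernel: str = "disk"  # "disk" | "gaussian"
    v_floor: float | None = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_neurons < 1:
            raise ValueError("n_neurons must be positive")
        if self.grid_rows * self.grid_cols < self.n_neurons:
            raise ValueError(
                f"grid capacity {self.grid_rows * self.grid_cols} "
                f"< n_neurons {self.n_neurons}"
            )
        for name in ("grid_spacing", "tau_v", "tau_ca", "beta_ca",
                     "ca_target", "rho_d", "rho_a", "w_exc"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0.0 <= self.v_rest < 1.0:
            raise ValueError("v_rest must lie in [0, 1)")
        if self.w_inh < 0:
            raise ValueError("w_inh must be nonnegative")
        if not 0.0 <= self.inhib_fraction <= 1.0:
            raise ValueError("inhib_fraction must lie in [0, 1]")
        if self.refractory_steps < 0:
            raise ValueError("refractory_steps must be nonnegative")
        if self.overlap_kernel not in ("disk", "gaussian"):
            raise ValueError("overlap_kernel must be 'disk' or 'gaussian'")


@dataclass
class NetworkState:
    """Full dynamical state of the network at one time step.

    Per-neuron arrays: membrane potential ``v``, calcium ``ca``, axonal
    supply ``a``, dendritic acceptance ``d``, signed coupling prefactor
    ``eps`` (+w_exc excitatory, -w_inh inhibitory), refractory counters.
    ``omega[i, j]`` is the synaptic density from presynaptic neuron j
    onto postsynaptic neuron i; it is recomputed deterministically from
    (a, d, positions) at every growth update. ``positions`` are fixed
    grid coordinates, ``rng`` carries all stochasticity.
    """

    v: np.ndarray
    ca: np.ndarray
    a: np.ndarray
    d: np.ndarray
    eps: np.ndarray
    refrac_count: np.ndarray
    omega: np.ndarray
    positions: np.ndarray
    t: int
    gaba_switched: bool
    inhibitory: np.ndarray  # boolean mask, all-False before the switch
    rng: np.random.Generator
    _dist: np.ndarray = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return self.v.size

    def distances(self) -> np.ndarray:
        if self._dist is None:
            diff = self.positions[:, None, :] - self.positions[None, :, :]
            self._dist = np.hypot(diff[..., 0], diff[..., 1])
        return self._dist

    def mean_omega(self) -> float:
        """Mean per-neuron total incoming synaptic density (row sum)."""
        return float(self.omega.sum(axis=1).mean())


@dataclass
class Trajectory:
    """Per-step population means recorded by :func:`simulate`.

    ``rate`` is the fraction of neurons spiking per step. ``omega_mean``
    follows the row-sum convention of :meth:`NetworkState.mean_omega`.
    """

    t: np.ndarray
    v_mean: np.ndarray
    ca_mean: np.ndarray
    a_mean: np.ndarray
    d_mean: np.ndarray
    omega_mean: np.ndarray
    rate: np.ndarray
    switch_time: int | None = None
    ca_target: float | None = None

    def __len__(self) -> int:
        return int(self.t.size)


def disk_overlap(r1, r2, dist):
    """Intersection area of two disks of radii ``r1``, ``r2`` whose
    centres are ``dist`` apart (vectorized, standard lens formula)."""
    r1 = np.asarray(r1, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    dist = np.asarray(dist, dtype=float)
    r1, r2, dist = np.broadcast_arrays(r1, r2, dist)

    # this runs every simulation step; the partial-overlap shell is
    # thin, so handle contained/disjoint branchlessly and evaluate the
    # lens formula only where the circles actually intersect
    overlap = dist < r1 + r2
    area = np.where(overlap, np.pi * np.minimum(r1, r2) ** 2, 0.0)
    partial = overlap & (dist > np.abs(r1 - r2)) & (r1 > 0) & (r2 > 0)
    if np.any(partial):
        d = dist[partial]
        a = r1[partial]
        b = r2[partial]
        # clip guards the acos against round-off at tangency
        cos1 = np.clip((d * d + a * a - b * b) / (2 * d * a), -1.0, 1.0)
        cos2 = np.clip((d * d + b * b - a * a) / (2 * d * b), -1.0, 1.0)
        tri = (-d + a + b) * (d + a - b) * (d - a + b) * (d + a + b)
        area[partial] = (
            a * a * np.arccos(cos1)
            + b * b * np.arccos(cos2)
            - 0.5 * np.sqrt(np.maximum(tri, 0.0))
        )
    return area


def _gaussian_overlap(r1, r2, dist):
    """Alternative kernel: product of two isotropic Gaussian 'probability
    zones' with s.d. r1, r2, integrated over the plane."""
    r1 = np.asarray(r1, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    dist = np.asarray(dist, dtype=float)
    s2 = r1**2 + r2**2
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(
            s2 > 0,
            2 * np.pi * r1**2 * r2**2 / np.where(s2 > 0, s2, 1.0)
            * np.exp(-(dist**2) / (2 * np.where(s2 > 0, s2, 1.0))),
            0.0,
        )
    return out


def compute_connectivity(a, d, positions=None, dist=None, kernel="disk"):
    """Connectivity matrix Omega from neurite fields.

    ``Omega[i, j]`` is the overlap of the dendritic zone of neuron i
    (radius ``d[i]``, centred at its position) with the axonal zone of
    neuron j (radius ``a[j]``): an abstract synapse-formation
    probability. The diagonal is zero (no autapses). The matrix is
    symmetric only when ``a == d`` elementwise.
    """
    a = np.asarray(a, dtype=float)
    d = np.asarray(d, dtype=float)
    if dist is None:
        positions = np.asarray(positions, dtype=float)
        diff = positions[:, None, :] - positions[None, :, :]
        dist = np.hypot(diff[..., 0], diff[..., 1])
    fn = disk_overlap if kernel == "disk" else _gaussian_overlap
    omega = fn(d[:, None], a[None, :], dist)
    np.fill_diagonal(omega, 0.0)
    return omega


def _grid_positions(params: ModelParams) -> np.ndarray:
    rows, cols = np.divmod(np.arange(params.n_neurons), params.grid_cols)
    return np.column_stack((cols, rows)).astype(float) * params.grid_spacing


def init_network(params: ModelParams) -> NetworkState:
    """Fresh network: all neurons excitatory, no connections.

    Potentials start at rest; calcium starts at the steady state implied
    by spontaneous firing at rate ``v_rest``
    (``ca0 = tau_ca * beta_ca * v_rest``). Neurons fill the grid
    row-major with spacing ``grid_spacing``; initial neurite fields are
    (``init_a``, ``init_d``), chosen so that no disks overlap.
    """
    n = params.n_neurons
    a = np.full(n, params.init_a, dtype=float)
    d = np.full(n, params.init_d, dtype=float)
    positions = _grid_positions(params)
    state = NetworkState(
        v=np.full(n, params.v_rest, dtype=float),
        ca=np.full(n, params.tau_ca * params.beta_ca * params.v_rest),
        a=a,
        d=d,
        eps=np.full(n, params.w_exc, dtype=float),
        refrac_count=np.zeros(n, dtype=np.int64),
        omega=np.zeros((n, n), dtype=float),
        positions=positions,
        t=0,
        gaba_switched=False,
        inhibitory=np.zeros(n, dtype=bool),
        rng=np.random.default_rng(params.seed),
    )
    state.omega = compute_connectivity(
        a, d, dist=state.distances(), kernel=params.overlap_kernel
    )
    if state.omega.max() > 0:
        raise ValueError(
            "initial neurite fields produce nonzero connectivity; "
            "decrease init_a/init_d or increase grid_spacing"
        )
    return state


def step_dynamics(state: NetworkState, params: ModelParams) -> np.ndarray:
    """Advance membrane/calcium/spiking by one step, in place.

    Returns the boolean spike vector for this step. A neuron that spikes
    at step t is eligible again at step t + refractory_steps + 1.
    """
    eligible = state.refrac_count == 0
    xi = state.rng.random(state.n)
    spikes = eligible & (state.v >= xi)

    state.refrac_count[~eligible] -= 1
    state.refrac_count[spikes] = params.refractory_steps

    drive = state.omega @ (state.eps * spikes)
    state.v += (params.v_rest - state.v) / params.tau_v + drive
    np.clip(state.v, params.v_floor, 1.0, out=state.v)

    state.ca += -state.ca / params.tau_ca + params.beta_ca * spikes
    state.t += 1
    return spikes


def update_growth(state: NetworkState, params: ModelParams) -> None:
    """One Euler step of the neurite growth rules, in place.

    Dendritic acceptance moves opposite to the calcium deviation
    (grows below target), axonal supply moves with it (grows above
    target); both are clipped at zero and the connectivity matrix is
    recomputed from the new fields.

    The drive is a saturating function of the relative calcium
    deviation, ``G = tanh((ca - ca_target) / ca_target)``: linear for
    small deviations, bounded by the growth-rate constants for large
    ones. The bound keeps the outgrowth well-posed (an unbounded linear
    drive lets the axonal field shrink to zero radius during the
    low-calcium Phase I faster than activity can ever rescue it,
    silencing the network permanently) and is the standard choice in
    the activity-dependent outgrowth model family this simulator
    extends.
    """
    dev = np.tanh((state.ca - params.ca_target) / params.ca_target)
    state.d -= params.rho_d * dev
    state.a += params.rho_a * dev
    np.clip(state.d, 0.0, None, out=state.d)
    np.clip(state.a, 0.0, None, out=state.a)
    state.omega = compute_connectivity(
        state.a, state.d, dist=state.distances(),
        kernel=params.overlap_kernel,
    )


def apply_gaba_switch(state: NetworkState, params: ModelParams) -> np.ndarray:
    """One-time conversion of a random neuron subset to inhibitory.

    ``floor(inhib_fraction * n)`` neurons, drawn uniformly without
    replacement from the state's RNG, get ``eps = -w_inh``. Returns the
    converted ids. Calling twice is an error.
    """
    if state.gaba_switched:
        raise RuntimeError("GABA switch already applied")
    n_inh = int(np.floor(params.inhib_fraction * state.n))
    chosen = (
        state.rng.choice(state.n, size=n_inh, replace=False)
        if n_inh > 0
        else np.empty(0, dtype=np.int64)
    )
    state.eps[chosen] = -params.w_inh
    state.inhibitory[:] = False
    state.inhibitory[chosen] = True
    state.gaba_switched = True
    return np.sort(chosen)


def apply_inhibition_jump(state: NetworkState, new_w_inh: float) -> None:
    """Instantaneously set the magnitude of all inhibitory couplings."""
    if not state.gaba_switched:
        raise RuntimeError("inhibition jump requires a switched network")
    if new_w_inh < 0:
        raise ValueError("new_w_inh must be nonnegative")
    state.eps[state.inhibitory] = -new_w_inh


def simulate(
    params: ModelParams,
    n_steps: int,
    switch_policy: str | tuple = "ca-crossing",
    record_every: int = 1,
    state: NetworkState | None = None,
):
    """Run the developmental simulation.

    Each step applies :func:`step_dynamics` then :func:`update_growth`.
    The GABA switch fires once according to ``switch_policy``:

    * ``"ca-crossing"`` (default): at the first step where the mean
      calcium reaches ``ca_target`` (the activity-overshoot transition);
    * ``("step", t)``: at a fixed step;
    * ``"never"``: no conversion.

    Returns ``(raster, trajectory)``; fully reproducible from
    ``params.seed``. Pass an existing ``state`` to continue a run (e.g.
    after an inhibition jump); recorded times then continue from
    ``state.t``.
    """
    if state is None:
        state = init_network(params)
    n_rec = n_steps // record_every
    rec = {
        k: np.empty(n_rec)
        for k in ("t", "v", "ca", "a", "d", "omega", "rate")
    }
    spike_t: list[np.ndarray] = []
    spike_u: list[np.ndarray] = []
    switch_time = None
    fixed_step = None
    if isinstance(switch_policy, tuple):
        if switch_policy[0] != "step":
            raise ValueError(f"unknown switch policy {switch_policy!r}")
        fixed_step = int(switch_policy[1])
    elif switch_policy not in ("ca-crossing", "never"):
        raise ValueError(f"unknown switch policy {switch_policy!r}")

    i_rec = 0
    for i in range(n_steps):
        if not state.gaba_switched and params.inhib_fraction > 0:
            if (switch_policy == "ca-crossing"
                    and state.ca.mean() >= params.ca_target) or (
                    fixed_step is not None and state.t >= fixed_step):
                apply_gaba_switch(state, params)
                switch_time = state.t
        spikes = step_dynamics(state, params)
        update_growth(state, params)
        if np.any(spikes):
            ids = np.flatnonzero(spikes)
            spike_t.append(np.full(ids.size, state.t - 1, dtype=float))
            spike_u.append(ids)
        if (i + 1) % record_every == 0 and i_rec < n_rec:
            rec["t"][i_rec] = state.t
            rec["v"][i_rec] = state.v.mean()
            rec["ca"][i_rec] = state.ca.mean()
            rec["a"][i_rec] = state.a.mean()
            rec["d"][i_rec] = state.d.mean()
            rec["omega"][i_rec] = state.omega.sum(axis=1).mean()
            rec["rate"][i_rec] = spikes.mean()
            i_rec += 1

    raster = SpikeRaster(
        times=np.concatenate(spike_t) if spike_t else np.empty(0),
        units=np.concatenate(spike_u) if spike_u else np.empty(0, dtype=int),
        n_units=params.n_neurons,
        duration=float(state.t),
        time_unit="steps",
    )
    traj = Trajectory(
        t=rec["t"], v_mean=rec["v"], ca_mean=rec["ca"], a_mean=rec["a"],
        d_mean=rec["d"], omega_mean=rec["omega"], rate=rec["rate"],
        switch_time=switch_time, ca_target=params.ca_target,
    )
    return raster, traj, state


def detect_phase(
    traj: Trajectory,
    params: ModelParams,
    ca_tol: float = 0.1,
    window: int = 500,
) -> np.ndarray:
    """Label each recorded point with its developmental phase.

    Phase I runs while mean calcium is still below target; Phase II
    starts at the first crossing ``ca_mean >= ca_target`` (the activity
    overshoot); Phase III starts once the sliding-window mean of the
    relative calcium deviation stays within ``ca_tol`` of the target for
    the remainder of the recording. Labels are contiguous and ordered
    I -> II -> III; phases not reached are simply absent.
    """
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    target = params.ca_target
    labels = np.array(["I"] * len(traj), dtype="<U3")
    crossing = np.flatnonzero(traj.ca_mean >= target)
    if crossing.size == 0:
        return labels
    t2 = int(crossing[0])
    labels[t2:] = "II"

    dev = np.abs(traj.ca_mean / target - 1.0)
    w = min(window, len(traj))
    # sliding-window mean of the deviation (partial windows at the start)
    csum = np.concatenate(([0.0], np.cumsum(dev)))
    idx = np.arange(len(traj))
    lo = np.maximum(idx - w + 1, 0)
    smooth = (csum[idx + 1] - csum[lo]) / (idx + 1 - lo)
    ok = smooth <= ca_tol
    # Phase III = first index >= t2 from which the condition never fails
    ok_from = np.logical_and.accumulate(ok[::-1])[::-1]
    candidates = np.flatnonzero(ok_from[t2:])
    if candidates.size:
        labels[t2 + int(candidates[0]):] = "III"
    return labels
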