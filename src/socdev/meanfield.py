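"""Mean-field companion to the growth-network simulator.

Averaging the membrane/calcium dynamics over neurons and replacing the
recurrent spike input by its expectation turns the network into two
scalar ODEs for the mean potential V(t) and mean calcium Ca(t):

    dV/dt  = (v_rest - V)/tau_v + W * f(Omega) * R(V)
    dCa/dt = -Ca/tau_ca + beta_ca * R(V)

where Omega is the mean per-neuron total incoming synaptic density
(row sum of the connectivity matrix), W the mean coupling prefactor,
f the density function (identity by default) and R(V) the firing
probability per step. With the model's uniform random threshold,
R(V) = V, which makes the averaged potential equation linear: defining
the effective gain g = tau_v * W * f(Omega),

* g = 0:      V -> v_rest, Ca -> tau_ca * beta_ca * v_rest;
* 0 < g < 1:  bounded limits V -> v_rest / (1 - g), Ca proportional;
* g >= 1:     no bounded solution; the potential saturates at the hard
              bound 1 and calcium grows without limit (the Phase II
              activity overshoot) — reported as a divergence flag.

For the nullcline analysis the Heaviside firing rule is smoothed by a
sigmoid R(V) = 1 / (1 + exp(-k (V - v_theta))), which makes the
stationary potential equation nonlinear and produces the S-shaped
(hysteresis) relation between Omega and V underlying the Phase II
transition.

Homeostasis fixes the steady-state rate independently of connectivity:
stationary calcium at the target gives R* = ca_target/(tau_ca*beta_ca).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .model import ModelParams, compute_connectivity

__all__ = [
    "MeanFieldParams",
    "MeanFieldResult",
    "FixedPoint",
    "mean_field_solution",
    "steady_state_rate",
    "nullcline",
    "fixed_point",
]


@dataclass(kw_only=True)
class MeanFieldParams:
    """Constants of the averaged dynamics.

    ``W`` is the effective (purely excitatory) coupling prefactor and
    ``k`` the steepness of the sigmoid surrogate for the Heaviside
    firing rule (``v_theta`` its midpoint). ``f_scale`` scales the
    density function ``f(Omega) = f_scale * Omega``.
    """

    ca_target: float
    tau_v: float = 5.0
    tau_ca: float = 1000.0
    v_rest: float = 0.0005
    beta_ca: float = 0.5
    W: float = 0.02
    k: float = 20.0
    v_theta: float = 0.5
    f_scale: float = 1.0
    refractory_steps: int = 4

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("k must be positive")
        if self.W < 0:
            raise ValueError("W must be nonnegative for the excitatory analysis")

    @classmethod
    def from_model(cls, params: ModelParams, **overrides) -> "MeanFieldParams":
        kw = dict(
            ca_target=params.ca_target, tau_v=params.tau_v,
            tau_ca=params.tau_ca, v_rest=params.v_rest,
            beta_ca=params.beta_ca, W=params.w_exc,
            refractory_steps=params.refractory_steps,
        )
        kw.update(overrides)
        return cls(**kw)

    def f(self, omega_bar: float) -> float:
        return self.f_scale * omega_bar


@dataclass
class MeanFieldResult:
    """Closed-form limits and trajectories of the averaged dynamics."""

    regime: str  # "zero" | "sub-unity" | "transition"
    V_limit: float
    Ca_limit: float  # inf in the transition regime
    ca_divergent: bool
    gain: float
    V_of_t: callable
    Ca_of_t: callable
    R_star: float


def mean_field_solution(
    params: MeanFieldParams, omega_bar: float
) -> MeanFieldResult:
    """Closed-form solution of the averaged dynamics at fixed density.

    The regime follows the effective gain
    ``g = tau_v * W * f(omega_bar)``: zero density relaxes to the
    resting potential, sub-unity gain to a bounded limit increasing in
    the density, and gain >= 1 saturates the potential at 1 with
    divergent calcium (divergence is reported as a flag, never as an
    overflow).
    """
    if omega_bar < 0:
        raise ValueError("omega_bar must be nonnegative")
    g = params.tau_v * params.W * params.f(omega_bar)
    v0, ca0 = params.v_rest, 0.0

    if g >= 1.0:
        regime = "transition"
        V_inf = 1.0
        ca_div = True
        Ca_inf = float("inf")
        # effective growth rate of the potential before the hard bound
        lam = (g - 1.0) / params.tau_v

        def V_of_t(t):
            t = np.asarray(t, dtype=float)
            if lam > 0:
                # overflow is benign: the bound clips it to 1
                with np.errstate(over="ignore"):
                    v = v0 * np.exp(lam * t)
            else:  # g == 1: linear drift v_rest/tau_v
                v = v0 + (v0 / params.tau_v) * t
            return np.minimum(v, 1.0)

        def Ca_of_t(t):
            # numerically integrate calcium driven by the clipped V
            t = np.atleast_1d(np.asarray(t, dtype=float))
            out = np.empty(t.shape)
            for i, ti in enumerate(t):
                sol = solve_ivp(
                    lambda s, ca: -ca / params.tau_ca
                    + params.beta_ca * float(V_of_t(s)),
                    (0.0, max(ti, 1e-12)), [ca0], rtol=1e-8, atol=1e-12,
                )
                out[i] = sol.y[0, -1]
            return out if out.size > 1 else float(out[0])

    else:
        regime = "zero" if g == 0.0 else "sub-unity"
        tau_eff = params.tau_v / (1.0 - g)
        V_inf = params.v_rest / (1.0 - g)
        Ca_inf = params.tau_ca * params.beta_ca * V_inf
        ca_div = False

        def V_of_t(t):
            t = np.asarray(t, dtype=float)
            return V_inf + (v0 - V_inf) * np.exp(-t / tau_eff)

        def Ca_of_t(t):
            # linear ODE driven by an exponential: closed form
            t = np.asarray(t, dtype=float)
            tc = params.tau_ca
            hom = (ca0 - _ca_particular(0.0, V_inf, v0, tau_eff, params)
                   ) * np.exp(-t / tc)
            return hom + _ca_particular(t, V_inf, v0, tau_eff, params)

    return MeanFieldResult(
        regime=regime, V_limit=float(min(V_inf, 1.0)),
        Ca_limit=Ca_inf, ca_divergent=ca_div, gain=float(g),
        V_of_t=V_of_t, Ca_of_t=Ca_of_t,
        R_star=steady_state_rate(params, check_feasible=False),
    )


def _ca_particular(t, V_inf, v0, tau_eff, params: MeanFieldParams):
    """Particular solution of dCa/dt = -Ca/tau_ca + beta*V(t) with
    V(t) = V_inf + (v0 - V_inf) exp(-t/tau_eff)."""
    t = np.asarray(t, dtype=float)
    tc, b = params.tau_ca, params.beta_ca
    steady = b * tc * V_inf
    if abs(1.0 / tau_eff - 1.0 / tc) < 1e-15:
        trans = b * (v0 - V_inf) * t * np.exp(-t / tc)
    else:
        trans = (
            b * (v0 - V_inf) / (1.0 / tc - 1.0 / tau_eff)
            * (np.exp(-t / tc) - np.exp(-t / tau_eff))
            * -1.0
        )
    return steady + trans


def steady_state_rate(
    params: MeanFieldParams, check_feasible: bool = True
) -> float:
    """Homeostatic firing rate R* (spikes per neuron per step).

    From stationary calcium at the target with spikes uniformly
    distributed in time: ``ca_target / tau_ca = beta_ca * R*``, hence
    ``R* = ca_target / (tau_ca * beta_ca)``. Raises if R* exceeds the
    refractory ceiling ``1 / (refractory_steps + 1)``.
    """
    r = params.ca_target / (params.tau_ca * params.beta_ca)
    ceiling = 1.0 / (params.refractory_steps + 1)
    if check_feasible and r > ceiling:
        raise ValueError(
            f"homeostatic rate {r:.4g} exceeds the refractory ceiling "
            f"{ceiling:.4g}; no steady state exists"
        )
    return float(r)


def _sigmoid(x: np.ndarray, k: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-k * x))


def nullcline(params: MeanFieldParams, omega_grid) -> list:
    """Stationary mean potential(s) for each density on the grid.

    Solves ``0 = (v_rest - V)/tau_v + W f(Omega) sigma_k(V - v_theta)``
    for V in [0, 1] at each Omega. For steep sigmoids the solution set
    is S-shaped: up to three coexisting roots (lower, middle, upper
    branch) over an intermediate density interval — the hysteresis that
    underlies the Phase II transition. Returns a list of root arrays,
    one per grid point (non-converged points yield an empty array, they
    are flagged, not fabricated).
    """
    omega_grid = np.asarray(omega_grid, dtype=float)
    if np.any(omega_grid < 0):
        raise ValueError("omega_grid must be nonnegative")

    def stationary(v, om):
        return (params.v_rest - v) / params.tau_v + params.W * params.f(
            om
        ) * _sigmoid(v - params.v_theta, params.k)

    out: list[np.ndarray] = []
    v_scan = np.linspace(0.0, 1.0, 2001)
    for om in omega_grid:
        f_scan = stationary(v_scan, om)
        roots: list[float] = []
        sign_change = np.flatnonzero(np.diff(np.sign(f_scan)) != 0)
        for i in sign_change:
            try:
                roots.append(
                    brentq(stationary, v_scan[i], v_scan[i + 1],
                           args=(om,), xtol=1e-10)
                )
            except RuntimeError:  # pragma: no cover - flagged, not faked
                continue
        # exact zeros on the scan grid
        for i in np.flatnonzero(f_scan == 0.0):
            roots.append(float(v_scan[i]))
        # saturated branch: positive drive at the hard bound pins V = 1
        if f_scan[-1] > 0:
            roots.append(1.0)
        out.append(np.unique(np.round(np.asarray(roots), 12)))
    return out


@dataclass
class FixedPoint:
    """Homeostatic equilibrium of the averaged system.

    ``v_star`` is the stationary mean potential consistent with the
    homeostatic rate under the model's actual uniform-threshold firing
    rule (refractory-corrected, ``R = V (1 - refractory_steps R)``);
    ``omega_star`` is the density at which the stationary potential
    equation balances at that rate. ``feasible`` is False when the
    homeostatic rate exceeds the refractory ceiling.
    """

    feasible: bool
    v_star: float | None
    omega_star: float | None
    r_star: float | None
    params: MeanFieldParams

    def on_hyperbola(
        self,
        a_bar: float,
        d_bar: float,
        positions: np.ndarray,
        tol: float = 0.1,
        omega_ref: float | None = None,
    ) -> bool:
        """Does a uniform network with mean fields (a_bar, d_bar) yield
        connectivity within relative ``tol`` of the fixed-point density?

        The set of (a, d) pairs with equal overlap forms a hyperbola-like
        curve in field space: different initial conditions end at
        different (a, d) but the same total density. ``omega_ref``
        overrides the analytic ``omega_star`` as reference (e.g. to
        compare two simulated endpoints with each other).
        """
        ref = self.omega_star if omega_ref is None else omega_ref
        if not self.feasible or ref is None:
            return False
        n = positions.shape[0]
        omega = compute_connectivity(
            np.full(n, a_bar), np.full(n, d_bar), positions=positions
        )
        value = float(omega.sum(axis=1).mean())
        return abs(value - ref) <= tol * abs(ref)


def fixed_point(params: MeanFieldParams) -> FixedPoint:
    """Intersect the stationary potential equation with homeostasis.

    The homeostatic rate R* fixes the stationary potential through the
    firing rule, and the density follows from the stationary potential
    balance ``(v_star - v_rest)/tau_v = W f(omega_star) R*``. Returns a
    clean infeasibility report when R* exceeds the refractory ceiling.
    """
    r = params.ca_target / (params.tau_ca * params.beta_ca)
    if r > 1.0 / (params.refractory_steps + 1):
        return FixedPoint(
            feasible=False, v_star=None, omega_star=None, r_star=None,
            params=params,
        )
    # R = V * P(eligible) with P(eligible) = 1 - refractory_steps * R
    v_star = r / (1.0 - params.refractory_steps * r)
    f_omega = (v_star - params.v_rest) / (params.tau_v * params.W * r)
    omega_star = f_omega / params.f_scale
    return FixedPoint(
        feasible=True, v_star=float(v_star), omega_star=float(omega_star),
        r_star=float(r), params=params,
    )
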