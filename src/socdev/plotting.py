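"""Plotting helpers (matplotlib)."""

from __future__ import annotations

import numpy as np

from .avalanches import DistributionFit
from .model import Trajectory
from .raster import SpikeRaster

__all__ = ["plot_raster", "plot_trajectory", "plot_size_distribution"]


def plot_raster(raster: SpikeRaster, ax=None, **kwargs):
    """Dot raster: time on x, unit id on y."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    kwargs.setdefault("s", 2)
    kwargs.setdefault("color", "k")
    ax.scatter(raster.times, raster.units, marker="|", **kwargs)
    ax.set_xlabel(f"time [{raster.time_unit}]")
    ax.set_ylabel("unit")
    return ax


def plot_trajectory(traj: Trajectory, axes=None):
    """Mean potential/calcium (top) and neurite fields (bottom)."""
    import matplotlib.pyplot as plt

    if axes is None:
        _, axes = plt.subplots(2, 1, sharex=True)
    ax0, ax1 = axes
    ax0.plot(traj.t, traj.v_mean, label="mean potential")
    ax0b = ax0.twinx()
    ax0b.plot(traj.t, traj.ca_mean, color="C1", label="mean calcium")
    if traj.ca_target is not None:
        ax0b.axhline(traj.ca_target, ls=":", color="C1")
    ax0.set_ylabel("V")
    ax0b.set_ylabel("Ca")
    ax1.plot(traj.t, traj.a_mean, label="axonal supply")
    ax1.plot(traj.t, traj.d_mean, label="dendritic acceptance")
    ax1.plot(traj.t, traj.omega_mean, label="connectivity")
    if traj.switch_time is not None:
        for ax in (ax0, ax1):
            ax.axvline(traj.switch_time, ls="--", color="gray")
    ax1.set_xlabel("time [steps]")
    ax1.legend(fontsize="small")
    return (ax0, ax1)


def plot_size_distribution(fit: DistributionFit, ax=None):
    """Log-log size distribution with its regression line and Delta."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.loglog(fit.sizes_axis, fit.prob, "o", ms=3, label="P(s)")
    s = np.array(fit.fit_range)
    ax.loglog(s, 10 ** fit.predict_log10(s), "--",
              label=f"slope {fit.exponent:.2f}")
    title = ""
    if fit.delta is not None:
        title = f"Delta = {fit.delta:+.3f}"
        if fit.label:
            title += f" ({fit.label})"
    ax.set_title(title)
    ax.set_xlabel("avalanche size s")
    ax.set_ylabel("P(s)")
    ax.legend(fontsize="small")
    return ax
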