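"""Spike raster container.

A raster is a timestamped event list over a fixed set of units
(model neurons or MEA electrodes). It is the common currency of the
simulator output and of recording-style input files: every analysis
operation in this package consumes a :class:`SpikeRaster`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SpikeRaster"]


@dataclass
class SpikeRaster:
    """Timestamped spike events over ``n_units`` units.

    Parameters
    ----------
    times : array-like of float
        Event times, in ``time_unit`` units. Stored sorted; ties keep a
        stable (time, unit) order so rasters are deterministic.
    units : array-like of int
        0-based unit id per event, each in ``[0, n_units)``.
    n_units : int
        Number of declared units (silent units count).
    duration : float
        Total observation length. Defaults to the last spike time if
        not given.
    time_unit : str
        Label for the time axis, ``"steps"`` (simulation) or ``"ms"``.
    """

    times: np.ndarray
    units: np.ndarray
    n_units: int
    duration: float | None = None
    time_unit: str = "steps"
    _unit_times: dict | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        units = np.asarray(self.units, dtype=np.int64)
        if times.shape != units.shape:
            raise ValueError("times and units must have equal length")
        if times.size and (units.min() < 0 or units.max() >= self.n_units):
            raise ValueError("unit ids must lie in [0, n_units)")
        order = np.lexsort((units, times))
        self.times = times[order]
        self.units = units[order]
        if self.duration is None:
            self.duration = float(self.times[-1]) if self.times.size else 0.0
        self.duration = float(self.duration)

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def n_spikes(self) -> int:
        return len(self)

    def spike_counts(self) -> np.ndarray:
        """Per-unit spike counts (length ``n_units``)."""
        return np.bincount(self.units, minlength=self.n_units)

    def active_units(self) -> np.ndarray:
        """Ids of units with at least one spike."""
        return np.flatnonzero(self.spike_counts() > 0)

    def unit_train(self, unit: int) -> np.ndarray:
        """Sorted spike times of one unit."""
        return self.times[self.units == unit]

    def subset(self, keep_units) -> "SpikeRaster":
        """Raster restricted to ``keep_units``; unit ids are re-indexed
        to ``0..len(keep_units)-1`` in the given order."""
        keep_units = np.asarray(keep_units, dtype=np.int64)
        remap = -np.ones(self.n_units, dtype=np.int64)
        remap[keep_units] = np.arange(keep_units.size)
        mask = remap[self.units] >= 0
        return SpikeRaster(
            times=self.times[mask],
            units=remap[self.units[mask]],
            n_units=int(keep_units.size),
            duration=self.duration,
            time_unit=self.time_unit,
        )

    def crop(self, t_start: float, t_stop: float) -> "SpikeRaster":
        """Raster restricted to ``[t_start, t_stop)``, times re-zeroed."""
        mask = (self.times >= t_start) & (self.times < t_stop)
        return SpikeRaster(
            times=self.times[mask] - t_start,
            units=self.units[mask],
            n_units=self.n_units,
            duration=float(t_stop - t_start),
            time_unit=self.time_unit,
        )

    def pooled(self) -> np.ndarray:
        """All spike times pooled across units, sorted."""
        return self.times
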