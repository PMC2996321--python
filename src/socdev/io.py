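"""Raster/trajectory readers and writers, electrode selection.

Rasters travel as tab-delimited event tables (``time<TAB>unit_id``,
header line); trajectories as tab-delimited per-step means. The
electrode-selection filter reproduces the culture-data criteria:
electrodes far more active than the population (clustering artifacts)
are excluded, and a recording is accepted only if enough active
electrodes remain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import ModelParams, Trajectory
from .raster import SpikeRaster

__all__ = [
    "SelectionReport",
    "read_raster",
    "write_raster",
    "write_trajectory",
    "read_trajectory",
    "electrode_selection",
    "load_params",
    "save_params",
]


@dataclass
class SelectionReport:
    """Outcome of the electrode-selection filter."""

    spike_counts: np.ndarray
    excluded_units: list  # (unit id, reason)
    n_active: int
    accepted: bool
    mean_count: float
    sd_count: float


def read_raster(
    path,
    time_unit: str = "steps",
    unit_base: int = 0,
    n_units: int | None = None,
    duration: float | None = None,
) -> SpikeRaster:
    """Read a tab-delimited event table into a raster.

    The dialect arguments normalize external conventions: ``time_unit``
    labels the time axis (``steps`` or ``ms``), ``unit_base`` handles
    0- vs 1-based unit ids (ids are stored 0-based). Events are sorted
    on load. A header-only file yields an empty raster with a warning;
    malformed lines raise with their line number.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            warnings.warn(f"{path}: empty file, empty raster returned",
                          stacklevel=2)
        times: list[float] = []
        units: list[int] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.split("\t")
            try:
                t = float(parts[0])
                u = int(parts[1])
            except (IndexError, ValueError) as err:
                raise ValueError(
                    f"{path}:{lineno}: malformed raster line "
                    f"{line.strip()!r}"
                ) from err
            times.append(t)
            units.append(u - unit_base)
    if not times and header.strip():
        warnings.warn(f"{path}: no events (header only)", stacklevel=2)
    units_arr = np.asarray(units, dtype=np.int64)
    if n_units is None:
        n_units = int(units_arr.max()) + 1 if units_arr.size else 1
    return SpikeRaster(
        times=np.asarray(times, dtype=float),
        units=units_arr,
        n_units=n_units,
        duration=duration,
        time_unit=time_unit,
    )


def write_raster(raster: SpikeRaster, path) -> None:
    """Write a raster as ``time<TAB>unit_id`` with a header line.

    Events are written in the raster's canonical (time, unit) order, so
    writing is deterministic and round-trip safe.
    """
    df = pd.DataFrame({"time": raster.times, "unit_id": raster.units})
    df.to_csv(path, sep="\t", index=False)


def write_trajectory(traj: Trajectory, path) -> None:
    """Write recorded per-step means as a tab-delimited table."""
    df = pd.DataFrame(
        {
            "t": traj.t,
            "v_mean": traj.v_mean,
            "ca_mean": traj.ca_mean,
            "a_mean": traj.a_mean,
            "d_mean": traj.d_mean,
            "omega_mean": traj.omega_mean,
            "rate": traj.rate,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_trajectory(path) -> Trajectory:
    df = pd.read_csv(path, sep="\t")
    return Trajectory(
        t=df["t"].to_numpy(),
        v_mean=df["v_mean"].to_numpy(),
        ca_mean=df["ca_mean"].to_numpy(),
        a_mean=df["a_mean"].to_numpy(),
        d_mean=df["d_mean"].to_numpy(),
        omega_mean=df["omega_mean"].to_numpy(),
        rate=df["rate"].to_numpy(),
    )


def electrode_selection(
    raster: SpikeRaster,
    min_active: int = 50,
    sd_mult: float = 2.0,
):
    """Exclude over-active units and check the active-unit floor.

    Units whose spike count is strictly greater than
    ``mean + sd_mult * SD`` (mean/SD over all declared units, computed
    once — no recursive re-exclusion) are removed: on MEA recordings
    such electrodes indicate neuron clustering, which distorts the
    avalanche statistics. The recording is ``accepted`` only if at
    least ``min_active`` retained units have >= 1 spike. Rejection is a
    report state, never an exception.

    Returns ``(filtered_raster, SelectionReport)``.
    """
    if raster.n_spikes == 0:
        raise ValueError("electrode selection requires a nonempty raster")
    counts = raster.spike_counts()
    mean = counts.mean()
    sd = counts.std()
    threshold = mean + sd_mult * sd
    excluded = np.flatnonzero(counts > threshold)
    keep = np.setdiff1d(np.arange(raster.n_units), excluded)
    filtered = raster.subset(keep)
    n_active = int(np.count_nonzero(counts[keep] > 0))
    report = SelectionReport(
        spike_counts=counts,
        excluded_units=[
            (int(u), f"count {counts[u]} > mean+{sd_mult:g}*SD "
                     f"({threshold:.2f})")
            for u in excluded
        ],
        n_active=n_active,
        accepted=n_active >= min_active,
        mean_count=float(mean),
        sd_count=float(sd),
    )
    return filtered, report


def load_params(path) -> ModelParams:
    """Load a flat key->value YAML config into :class:`ModelParams`."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a flat mapping")
    return ModelParams(**cfg)


def save_params(params: ModelParams, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(params), fh, sort_keys=False)
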