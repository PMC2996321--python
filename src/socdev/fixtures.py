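"""Synthetic raster generators.

These act as statistical oracles for the analysis stack, standing in
for cell-culture recordings that are not deposited:

* :func:`poisson_raster` — independent homogeneous Poisson trains, the
  null model with no correlation structure (Fano factor 1, strongly
  sub-power-law avalanche distribution);
* :func:`branching_raster` — a critical/sub/supercritical
  Galton-Watson cascade process. At branching parameter sigma = 1 the
  avalanche (cascade) size distribution follows the Borel distribution
  with the classic power-law tail of exponent -3/2; for sigma < 1 the
  mean cascade size is 1 / (1 - sigma).
"""

from __future__ import annotations

import numpy as np

from .raster import SpikeRaster

__all__ = ["poisson_raster", "branching_raster"]


def poisson_raster(
    n_units: int,
    rate_per_unit: float,
    duration: float,
    seed: int | np.random.Generator = 0,
) -> SpikeRaster:
    """Independent homogeneous Poisson spike trains.

    ``rate_per_unit`` is in spikes per time unit; expected total spike
    count is ``n_units * rate_per_unit * duration``.
    """
    if rate_per_unit <= 0 or duration <= 0:
        raise ValueError("rate and duration must be positive")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    counts = rng.poisson(rate_per_unit * duration, size=n_units)
    total = int(counts.sum())
    times = rng.random(total) * duration
    units = np.repeat(np.arange(n_units), counts)
    return SpikeRaster(
        times=times, units=units, n_units=n_units, duration=duration
    )


def branching_raster(
    n_units: int,
    sigma: float,
    drive_rate: float,
    duration: float,
    seed: int | np.random.Generator = 0,
    max_generations: int = 100,
    max_size: int = 5_000,
    generation_step: float = 1.0,
    jitter: bool = True,
    return_sizes: bool = False,
):
    """Galton-Watson cascades on a population of units.

    Exogenous ancestor spikes arrive as a homogeneous Poisson process
    with rate ``drive_rate``; each spike spawns ``Poisson(sigma)``
    child spikes one generation later, on uniformly random units, with
    each generation's spikes spread uniformly over its
    ``generation_step`` (``jitter``), as in a continuous-time recording.
    A cascade stops after ``max_generations`` generations (critical
    cascades have infinite mean size, so some cap is required; capping
    in time rather than size leaves no pileup at a single size and only
    trims the far tail). ``max_size`` is a hard safety bound for
    supercritical cascades. Keep ``drive_rate`` small enough that
    cascades rarely overlap and the adaptive time bin cleanly separates
    them.

    With ``return_sizes=True`` also returns the per-cascade true sizes
    (before any temporal merging), for use as an independent oracle.
    """
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    if drive_rate <= 0 or duration <= 0:
        raise ValueError("drive_rate and duration must be positive")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n_anc = rng.poisson(drive_rate * duration)
    anc_times = np.sort(rng.random(n_anc) * duration)
    all_t: list[np.ndarray] = []
    all_u: list[np.ndarray] = []
    sizes = np.empty(n_anc, dtype=np.int64)
    for c, t0 in enumerate(anc_times):
        gen_n = 1
        size = 1
        all_t.append(np.array([t0]))
        all_u.append(rng.integers(0, n_units, 1))
        for g in range(1, max_generations + 1):
            children = int(rng.poisson(sigma * gen_n))
            children = min(children, max_size - size)
            if children == 0:
                break
            t = t0 + g * generation_step
            if jitter:
                t = t + rng.random(children) * generation_step
            all_t.append(np.broadcast_to(t, (children,)).astype(float))
            all_u.append(rng.integers(0, n_units, children))
            size += children
            gen_n = children
            if size >= max_size:
                break
        sizes[c] = size
    times = np.concatenate(all_t) if all_t else np.empty(0)
    units = np.concatenate(all_u) if all_u else np.empty(0, dtype=int)
    raster = SpikeRaster(
        times=times,
        units=units,
        n_units=n_units,
        duration=max(duration, float(times.max()) + 1 if times.size else 0),
    )
    if return_sizes:
        return raster, sizes
    return raster
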