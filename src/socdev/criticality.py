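"""Additional tests for genuine scale-free (critical) behavior.

A power-law avalanche size distribution alone does not prove
criticality (e.g. sums of exponentials can mimic one). This module
implements a four-test battery on a spike raster:

1. spatial subsampling — the power law must survive analysis on random
   unit subsets (spatially scale-free);
2. time-bin robustness — the distribution must change only weakly when
   the avalanche time bin is rescaled (temporally scale-free);
3. scaling-function collapse — the distributions of inter-avalanche
   intervals for different minimum avalanche sizes s, rescaled by the
   rate lambda_s of avalanches >= s, must collapse onto a single curve;
4. Fano factor — the variance-to-mean ratio F(T) of pooled spike counts
   in windows of length T must follow a power law in T over the
   avalanche-relevant range (F = 1 identifies a Poisson process).
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

from .raster import SpikeRaster
from . import avalanches as av_mod
from .avalanches import (
    DistributionFit,
    analyze_raster,
    compute_time_bin,
    detect_avalanches,
)

__all__ = [
    "ScalingCollapse",
    "FanoResult",
    "spatial_subsample_test",
    "bin_robustness_test",
    "scaling_function_collapse",
    "fano_factor",
]


@dataclass
class ScalingCollapse:
    """Rescaled inter-avalanche-interval distributions.

    For each minimum size s, intervals between consecutive onsets of
    avalanches of size >= s are multiplied by the rate ``lambda_s``
    (avalanches >= s per unit time), which maps every curve to unit
    mean. ``collapse_score`` is the maximum pairwise sup-distance
    (Kolmogorov-style) between the rescaled empirical distribution
    functions; near zero means the curves form a single scaling
    function.
    """

    s_list: np.ndarray
    lambda_s: np.ndarray
    rescaled_intervals: list
    collapse_score: float


@dataclass
class FanoResult:
    """Fano factor curve F(T) and its log-log power-law slope."""

    T_list: np.ndarray
    F: np.ndarray
    exponent_alpha: float
    fit_range: tuple


def spatial_subsample_test(
    raster: SpikeRaster,
    fractions,
    seed: int | np.random.Generator = 0,
    thresholds=av_mod.DEFAULT_THRESHOLDS,
) -> dict:
    """Avalanche analysis on random unit subsets.

    For each fraction in ``fractions`` a uniform random subset of units
    is retained and the full adaptive pipeline (time bin, avalanches,
    fit, Delta) is re-run. Fraction 1 reproduces the full analysis.
    Returns ``{fraction: DistributionFit}``.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    results: dict[float, DistributionFit] = {}
    for frac in fractions:
        if not 0 < frac <= 1:
            raise ValueError("fractions must lie in (0, 1]")
        n_keep = int(round(frac * raster.n_units))
        if n_keep < 2:
            raise ValueError(
                f"fraction {frac} keeps {n_keep} unit(s); need >= 2"
            )
        if n_keep == raster.n_units:
            sub = raster
        else:
            keep = np.sort(rng.choice(raster.n_units, n_keep, replace=False))
            sub = raster.subset(keep)
        _, fit = analyze_raster(sub, thresholds=thresholds)
        results[float(frac)] = fit
    return results


def bin_robustness_test(
    raster: SpikeRaster,
    bin_multipliers,
    thresholds=av_mod.DEFAULT_THRESHOLDS,
) -> dict:
    """Avalanche analysis at rescaled time bins.

    The adaptive bin is computed once and multiplied by each factor.
    Degenerate outcomes (too few distinct sizes to fit) are reported as
    ``None`` rather than raised. Returns ``{multiplier: fit_or_None}``.
    """
    base_bin = compute_time_bin(raster)
    results: dict[float, DistributionFit | None] = {}
    for mult in bin_multipliers:
        if mult <= 0:
            raise ValueError("bin multipliers must be positive")
        try:
            _, fit = analyze_raster(
                raster, time_bin=base_bin * mult, thresholds=thresholds
            )
        except ValueError as err:
            warnings.warn(
                f"bin multiplier {mult}: degenerate analysis ({err})",
                stacklevel=2,
            )
            fit = None
        results[float(mult)] = fit
    return results


def _ecdf_sup_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sample Kolmogorov sup-distance between empirical CDFs."""
    grid = np.sort(np.concatenate((x, y)))
    fx = np.searchsorted(np.sort(x), grid, side="right") / x.size
    fy = np.searchsorted(np.sort(y), grid, side="right") / y.size
    return float(np.max(np.abs(fx - fy)))


def scaling_function_collapse(
    raster: SpikeRaster,
    s_list,
    time_bin: float | None = None,
    min_count: int = 50,
) -> ScalingCollapse:
    """Inter-avalanche-interval scaling-function collapse.

    Intervals are onset-to-onset between consecutive avalanches of size
    >= s; the rate ``lambda_s = (n-1) / (last onset - first onset)``
    rescales every interval set to unit mean. For a scale-free raster
    the rescaled distributions coincide for all s.
    """
    if time_bin is None:
        time_bin = compute_time_bin(raster)
    av = detect_avalanches(raster, time_bin)
    s_arr = np.asarray(sorted(s_list), dtype=np.int64)
    lambdas = np.empty(s_arr.size)
    rescaled: list[np.ndarray] = []
    for k, s in enumerate(s_arr):
        onsets = av.start_times[av.sizes >= s]
        if onsets.size < max(min_count, 2):
            raise ValueError(
                f"minimum size {s}: only {onsets.size} qualifying "
                f"avalanches (< {min_count})"
            )
        span = onsets[-1] - onsets[0]
        lam = (onsets.size - 1) / span
        lambdas[k] = lam
        rescaled.append(np.diff(onsets) * lam)
    score = 0.0
    for i in range(s_arr.size):
        for j in range(i + 1, s_arr.size):
            score = max(score, _ecdf_sup_distance(rescaled[i], rescaled[j]))
    return ScalingCollapse(
        s_list=s_arr,
        lambda_s=lambdas,
        rescaled_intervals=rescaled,
        collapse_score=score,
    )


def fano_factor(
    raster: SpikeRaster,
    T_list,
    fit_range: tuple | None = None,
    native_resolution: float = 1.0,
) -> FanoResult:
    """Fano factor F(T) = Var(N_T) / E(N_T) of pooled spike counts.

    Time is partitioned into disjoint windows of length T starting at
    t = 0. Windows with zero mean count are dropped with a warning. The
    slope ``exponent_alpha`` is the OLS log-log regression of F against
    T over ``fit_range`` (default: T between 10x the native resolution
    and duration / 20).
    """
    T_arr = np.asarray(sorted(T_list), dtype=float)
    if np.any(T_arr > raster.duration / 10):
        raise ValueError("window lengths must not exceed duration / 10")
    t = raster.pooled()
    F = np.full(T_arr.size, np.nan)
    for k, T in enumerate(T_arr):
        n_win = int(np.floor(raster.duration / T))
        counts = np.bincount(
            np.clip((t / T).astype(np.int64), 0, n_win - 1),
            minlength=n_win,
        )[:n_win]
        mean = counts.mean()
        if mean == 0:
            warnings.warn(f"window T={T}: zero mean count, dropped",
                          stacklevel=2)
            continue
        F[k] = counts.var() / mean
    keep = np.isfinite(F)
    T_arr, F = T_arr[keep], F[keep]

    if fit_range is None:
        fit_range = (10 * native_resolution, raster.duration / 20)
    lo, hi = fit_range
    mask = (T_arr >= lo) & (T_arr <= hi) & (F > 0)
    if mask.sum() >= 2:
        slope, _ = np.polyfit(np.log10(T_arr[mask]), np.log10(F[mask]), 1)
        alpha = float(slope)
    else:
        alpha = float("nan")
    return FanoResult(
        T_list=T_arr, F=F, exponent_alpha=alpha, fit_range=(lo, hi)
    )
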