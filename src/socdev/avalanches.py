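"""Neuronal-avalanche statistics.

An avalanche is a maximal run of spikes in the pooled (all-unit) spike
train with no silent gap of at least one *time bin*; its size is its
spike count. The time bin is adaptive: the mean inter-spike interval of
the pooled train, after discarding intervals longer than a cutoff
derived from the mean pairwise cross-correlogram (the lag below which
99% of the correlogram area lies), so that pauses between bursts on
long timescales do not distort the bin.

The avalanche size distribution P(s) is compared with an ideal power
law obtained by ordinary least squares on (log10 s, log10 P(s)) over
the left linear region of the distribution. The deviation measure
Delta is the mean log10 residual of *all* observed sizes from that
regression line: excess probability mass at large sizes (a
"bump" of long avalanches) gives Delta > 0 (supercritical), a
truncated tail gives Delta < 0 (subcritical), and Delta near zero
marks the critical state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .raster import SpikeRaster

__all__ = [
    "AvalancheSet",
    "DistributionFit",
    "CorrelationCurve",
    "mean_cross_correlation",
    "cc_cutoff",
    "compute_time_bin",
    "detect_avalanches",
    "size_distribution",
    "fit_power_law",
    "delta_measure",
    "classify_state",
    "analyze_raster",
    "DEFAULT_THRESHOLDS",
]

#: Heuristic Delta thresholds (log10 units): below the first ->
#: subcritical, above the second -> supercritical.
DEFAULT_THRESHOLDS = (-0.1, 0.1)


@dataclass
class CorrelationCurve:
    """Mean cross-correlogram over ordered unit pairs, lags >= 0."""

    lags: np.ndarray
    values: np.ndarray

    def total_area(self) -> float:
        return float(self.values.sum())


@dataclass
class AvalancheSet:
    """Avalanches extracted from a raster at a fixed time bin.

    Invariant: sizes sum to the raster's total spike count (every spike
    belongs to exactly one avalanche); inter-avalanche intervals (end of
    one avalanche to start of the next) are all >= time_bin.
    """

    sizes: np.ndarray
    durations: np.ndarray
    start_times: np.ndarray
    inter_avalanche_intervals: np.ndarray
    time_bin: float

    @property
    def n(self) -> int:
        return int(self.sizes.size)

    def __len__(self) -> int:
        return self.n


@dataclass
class DistributionFit:
    """Power-law regression of an avalanche size distribution.

    ``exponent`` is the log-log OLS slope over ``fit_range``;
    ``delta`` the mean log10 residual of all observed sizes;
    ``label`` the resulting state classification.
    """

    sizes_axis: np.ndarray
    prob: np.ndarray
    fit_range: tuple
    exponent: float
    intercept: float
    delta: float | None = None
    label: str | None = None

    def predict_log10(self, sizes) -> np.ndarray:
        return self.intercept + self.exponent * np.log10(sizes)


def _binned_counts(times, lag_resolution, n_bins):
    b = np.floor(times / lag_resolution).astype(np.int64)
    return np.bincount(b, minlength=n_bins)


def mean_cross_correlation(
    raster: SpikeRaster,
    max_lag: float = 1000.0,
    lag_resolution: float = 1.0,
) -> CorrelationCurve:
    """Average spike-train cross-correlogram over all ordered unit pairs.

    Trains are binned at ``lag_resolution``; the value at lag k is the
    number of spike pairs on *different* units whose bin distance is k,
    for k in [0, max_lag], averaged over ordered pairs. Computed as the
    pooled-train pair histogram (one FFT correlation) minus the same-unit
    pair histograms (sparse, per unit).
    """
    active = raster.active_units()
    if active.size < 2:
        raise ValueError("mean cross-correlation requires >= 2 active units")
    L = int(round(max_lag / lag_resolution))
    n_bins = int(np.floor(raster.duration / lag_resolution)) + 1
    c = _binned_counts(raster.times, lag_resolution, n_bins)

    # pooled pair histogram via FFT: H_all[k] = sum_t c[t] c[t+k]
    nfft = 1
    while nfft < 2 * n_bins:
        nfft *= 2
    C = np.fft.rfft(c, nfft)
    full = np.fft.irfft(C * np.conj(C), nfft)
    h_all = full[: L + 1].copy()
    h_all[0] -= c.sum()  # remove self-pairs at lag 0 (both orders kept)

    # same-unit pair histogram, sparse per unit
    h_same = np.zeros(L + 1)
    for u in active:
        b = np.floor(raster.unit_train(u) / lag_resolution).astype(np.int64)
        p, q = np.unique(b, return_counts=True)
        hi = np.searchsorted(p, p + L, side="right")
        lengths = hi - np.arange(p.size)
        ii = np.repeat(np.arange(p.size), lengths)
        jj = np.arange(lengths.sum()) - np.repeat(
            np.cumsum(lengths) - lengths, lengths
        ) + ii
        np.add.at(h_same, p[jj] - p[ii], q[ii] * q[jj])
        # at lag 0 the loop added q_i^2; same-unit distinct ordered
        # pairs (both orders, matching h_all) are q_i * (q_i - 1)
        h_same[0] -= np.sum(q**2) - np.sum(q * (q - 1))

    n_pairs = active.size * (active.size - 1)
    values = np.maximum(h_all - h_same, 0.0) / n_pairs
    lags = np.arange(L + 1) * lag_resolution
    return CorrelationCurve(lags=lags, values=values)


def cc_cutoff(curve: CorrelationCurve, area_fraction: float = 0.99) -> float:
    """Smallest lag below which ``area_fraction`` of the correlogram
    area lies."""
    total = curve.total_area()
    if total <= 0:
        raise ValueError("cross-correlation curve has zero area")
    cum = np.cumsum(curve.values)
    idx = int(np.searchsorted(cum, area_fraction * total))
    return float(curve.lags[min(idx, curve.lags.size - 1)])


def compute_time_bin(
    raster: SpikeRaster,
    cutoff: float | None = None,
    max_lag: float = 1000.0,
    lag_resolution: float = 1.0,
) -> float:
    """Adaptive avalanche time bin.

    Mean of consecutive pooled inter-spike intervals, excluding
    intervals longer than ``cutoff`` (by default the 99%-area lag of
    the mean cross-correlogram), so that long silent pauses between
    bursts do not inflate the bin.
    """
    if raster.n_spikes < 2:
        raise ValueError("time bin requires at least 2 spikes")
    if cutoff is None:
        cutoff = cc_cutoff(
            mean_cross_correlation(raster, max_lag, lag_resolution)
        )
    isis = np.diff(raster.pooled())
    kept = isis[isis <= cutoff]
    if kept.size == 0:
        raise ValueError(
            f"no inter-spike interval survives the cutoff {cutoff:g} "
            f"(min interval {isis.min():g}); the raster may be too sparse"
        )
    return float(kept.mean())


def detect_avalanches(raster: SpikeRaster, time_bin: float) -> AvalancheSet:
    """Partition the pooled spike train into avalanches.

    An avalanche ends whenever the system is silent for at least
    ``time_bin``; the next spike starts a new one. Every spike belongs
    to exactly one avalanche.
    """
    if time_bin <= 0:
        raise ValueError("time_bin must be positive")
    t = raster.pooled()
    if t.size == 0:
        empty = np.empty(0)
        return AvalancheSet(
            sizes=np.empty(0, dtype=np.int64), durations=empty,
            start_times=empty, inter_avalanche_intervals=empty,
            time_bin=float(time_bin),
        )
    gaps = np.diff(t)
    breaks = np.flatnonzero(gaps >= time_bin)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [t.size - 1]))
    sizes = ends - starts + 1
    return AvalancheSet(
        sizes=sizes.astype(np.int64),
        durations=t[ends] - t[starts],
        start_times=t[starts],
        inter_avalanche_intervals=t[starts[1:]] - t[ends[:-1]],
        time_bin=float(time_bin),
    )


def size_distribution(av: AvalancheSet):
    """Empirical probability of each observed avalanche size."""
    if av.n == 0:
        raise ValueError("empty avalanche set")
    sizes_axis, counts = np.unique(av.sizes, return_counts=True)
    return sizes_axis, counts / counts.sum()


def fit_power_law(
    sizes_axis,
    prob,
    fit_range: tuple | None = None,
    r2_min: float = 0.98,
) -> DistributionFit:
    """OLS power-law regression of the left linear region.

    The regression line is anchored on the small-size end of the
    distribution: starting from the three smallest observed sizes, the
    window is expanded to the largest size for which the regression R^2
    stays at or above ``r2_min`` ("to the end of the linear behaviour").
    An explicit ``fit_range=(s_lo, s_hi)`` overrides the policy.
    """
    sizes_axis = np.asarray(sizes_axis, dtype=float)
    prob = np.asarray(prob, dtype=float)
    order = np.argsort(sizes_axis)
    sizes_axis = sizes_axis[order]
    prob = prob[order]
    if np.any(prob <= 0):
        raise ValueError("probabilities must be positive (observed sizes only)")
    logs = np.log10(sizes_axis)
    logp = np.log10(prob)

    if fit_range is not None:
        s_lo, s_hi = fit_range
        mask = (sizes_axis >= s_lo) & (sizes_axis <= s_hi)
        if mask.sum() < 3:
            raise ValueError("fewer than 3 distinct sizes in fit range")
        k_lo, k_hi = np.flatnonzero(mask)[[0, -1]]
    else:
        if sizes_axis.size < 3:
            raise ValueError("fewer than 3 distinct sizes")
        k_lo = 0
        k_hi = 2
        for k in range(2, sizes_axis.size):
            x = logs[: k + 1]
            y = logp[: k + 1]
            slope, icpt = np.polyfit(x, y, 1)
            resid = y - (icpt + slope * x)
            ss_tot = np.sum((y - y.mean()) ** 2)
            r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 1.0
            if r2 >= r2_min:
                k_hi = k
            elif k > 2:
                break

    x = logs[k_lo: k_hi + 1]
    y = logp[k_lo: k_hi + 1]
    slope, icpt = np.polyfit(x, y, 1)
    return DistributionFit(
        sizes_axis=sizes_axis,
        prob=prob,
        fit_range=(float(sizes_axis[k_lo]), float(sizes_axis[k_hi])),
        exponent=float(slope),
        intercept=float(icpt),
    )


def delta_measure(sizes_axis, prob, fit: DistributionFit) -> float:
    """Mean log10 residual of the full distribution from the fit line.

    Positive when the distribution carries excess mass at large sizes
    relative to the left-anchored power law, negative when the tail is
    depleted.
    """
    sizes_axis = np.asarray(sizes_axis, dtype=float)
    prob = np.asarray(prob, dtype=float)
    resid = np.log10(prob) - fit.predict_log10(sizes_axis)
    return float(resid.mean())


def classify_state(delta: float, thresholds=DEFAULT_THRESHOLDS) -> str:
    """Map Delta to a state label.

    ``Delta > hi`` -> supercritical, ``Delta < lo`` -> subcritical,
    otherwise critical. Thresholds are heuristic and configurable.
    """
    lo, hi = thresholds
    if not lo < 0 < hi:
        raise ValueError("thresholds must satisfy lo < 0 < hi")
    if delta > hi:
        return "supercritical"
    if delta < lo:
        return "subcritical"
    return "critical"


def analyze_raster(
    raster: SpikeRaster,
    time_bin: float | None = None,
    thresholds=DEFAULT_THRESHOLDS,
    fit_range: tuple | None = None,
    max_lag: float = 1000.0,
    lag_resolution: float = 1.0,
):
    """Full avalanche pipeline: adaptive bin -> avalanches -> power-law
    fit -> Delta -> state label.

    Returns ``(AvalancheSet, DistributionFit)`` with ``delta`` and
    ``label`` filled in on the fit.
    """
    if time_bin is None:
        time_bin = compute_time_bin(
            raster, max_lag=max_lag, lag_resolution=lag_resolution
        )
    av = detect_avalanches(raster, time_bin)
    sizes_axis, prob = size_distribution(av)
    fit = fit_power_law(sizes_axis, prob, fit_range=fit_range)
    fit.delta = delta_measure(sizes_axis, prob, fit)
    fit.label = classify_state(fit.delta, thresholds)
    return av, fit
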