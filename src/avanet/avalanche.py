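"""Avalanche segmentation and size-distribution scaling statistics.

An avalanche is a maximal run of consecutive raster bins with at least one
event, bracketed by empty bins; its size S is the total event count and its
lifetime L the number of bins. Size distributions are fitted with a discrete,
window-truncated power-law MLE and compared against exponential and
log-normal alternatives with a Vuong-style normalized log-likelihood ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _stats
from ._stats import OLSTrend, ols_trend
from .preprocess import EventRaster, InsufficientDataError, ParameterError

__all__ = [
    "Avalanche",
    "PowerLawFit",
    "StabilitySeries",
    "segment_avalanches",
    "coarsen_raster",
    "raster_mean_iei",
    "fit_size_distribution",
    "exponent_stability",
]


@dataclass(frozen=True)
class Avalanche:
    """One segmented spatiotemporal cluster.

    per_bin_sizes[t] is the number of events in the t-th bin of the
    avalanche (all >= 1 by construction); size = sum, lifetime = length.
    """

    start_bin: int
    per_bin_sizes: tuple

    @property
    def lifetime_bins(self) -> int:
        return len(self.per_bin_sizes)

    @property
    def size(self) -> int:
        return int(sum(self.per_bin_sizes))


@dataclass(frozen=True)
class PowerLawFit:
    """Discrete power-law MLE on a fixed size window with model comparison.

    llr_* > 0 with small p_* means the power law is favored over that
    alternative (exponential / log-normal, fitted on the same window).
    """

    alpha: float
    fit_range: tuple
    llr_exp: float
    p_exp: float
    llr_logn: float
    p_logn: float
    n_obs: int


@dataclass(frozen=True)
class StabilitySeries:
    """Per-session statistic with its linear day-trend and 95% CI."""

    day: np.ndarray
    value: np.ndarray
    trend: OLSTrend


def segment_avalanches(raster: EventRaster) -> list:
    """Maximal runs of consecutive nonzero population bins.

    The population vector sums counts over electrodes; every run of
    consecutive bins with population > 0 becomes one avalanche. Sizes count
    all events, including multiple events per electrode per bin.
    """
    pop = raster.population()
    occupied = pop > 0
    d = np.diff(np.r_[False, occupied, False].astype(np.int8))
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return [Avalanche(start_bin=int(a), per_bin_sizes=tuple(int(v) for v in pop[a:b]))
            for a, b in zip(starts, stops)]


def coarsen_raster(raster: EventRaster, factor: int) -> EventRaster:
    """Re-bin a raster at factor x coarser resolution (counts summed).

    The trailing partial bin, if any, is kept (summed over the remaining
    columns), so events are conserved exactly.
    """
    if factor < 1 or int(factor) != factor:
        raise ParameterError("factor must be a positive integer")
    factor = int(factor)
    if factor == 1:
        return raster
    n_new = -(-raster.n_bins // factor)
    pad = n_new * factor - raster.n_bins
    counts = raster.counts
    if pad:
        counts = np.pad(counts, ((0, 0), (0, pad)))
    counts = counts.reshape(raster.n_electrodes, n_new, factor).sum(axis=2)
    return EventRaster(counts=counts, dt_ms=raster.dt_ms * factor,
                       t0_ms=raster.t0_ms, electrode_ids=list(raster.electrode_ids))


def raster_mean_iei(raster: EventRaster) -> float:
    """Mean inter-event interval (ms) of pooled raster events.

    Event times are taken at bin resolution (bin index x dt); several events
    in one bin contribute zero gaps, consistent with pooling all electrodes.
    """
    pop = raster.population()
    if pop.sum() < 2:
        raise InsufficientDataError("need at least 2 events for <IEI>")
    t = np.repeat(np.arange(raster.n_bins), pop)
    return float(np.diff(t).mean() * raster.dt_ms)


def fit_size_distribution(sizes, s_min: int = 1, s_max: int = 40,
                          min_obs: int = 100) -> PowerLawFit:
    """Fit p(S) ∝ S^-alpha on [s_min, s_max] and compare against alternatives.

    Only sizes inside the window enter the likelihood; the power law,
    discrete exponential, and discrete log-normal are all normalized over the
    same window, and the normalized LLR (two-sided p) decides which model the
    data favor. Positive LLR with p < 0.05 means the power law wins.
    """
    s = np.asarray(sizes, dtype=np.int64)
    s = s[(s >= s_min) & (s <= s_max)]
    if s.size < min_obs:
        raise InsufficientDataError(
            f"only {s.size} sizes in [{s_min}, {s_max}]; need >= {min_obs}")
    alpha = _stats.fit_discrete_powerlaw(s, s_min, s_max)
    logp_pl = _stats.discrete_powerlaw_logpmf(s, alpha, s_min, s_max)
    lam = _stats.fit_discrete_exponential(s, s_min, s_max)
    logp_exp = _stats._discrete_exponential_logpmf(s, lam, s_min, s_max)
    mu, sigma = _stats.fit_discrete_lognormal(s, s_min, s_max)
    logp_logn = _stats._discrete_lognormal_logpmf(s, mu, sigma, s_min, s_max)
    llr_exp, p_exp = _stats.vuong_llr(logp_pl, logp_exp)
    llr_logn, p_logn = _stats.vuong_llr(logp_pl, logp_logn)
    return PowerLawFit(alpha=alpha, fit_range=(s_min, s_max),
                       llr_exp=llr_exp, p_exp=p_exp,
                       llr_logn=llr_logn, p_logn=p_logn, n_obs=int(s.size))


def exponent_stability(fits_per_day) -> StabilitySeries:
    """OLS trend of the fitted exponent across recording days.

    fits_per_day: iterable of (day, PowerLawFit) or (day, float).
    """
    pairs = list(fits_per_day)
    if len(pairs) < 2:
        raise InsufficientDataError("need >= 2 sessions for a stability slope")
    days = np.array([d for d, _ in pairs], dtype=float)
    vals = np.array([f.alpha if isinstance(f, PowerLawFit) else float(f)
                     for _, f in pairs])
    return StabilitySeries(day=days, value=vals, trend=ols_trend(days, vals))
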