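"""Avalanche temporal-profile shape collapse and profile-model comparison.

Mean per-lifetime profiles <S>(t, L) are rescaled by L^-(chi-1) and mapped
onto a common relative-time grid; the scaling exponent chi is the value that
minimizes the collapse error Delta_F, the mean squared deviation of the
rescaled profiles from their pointwise average, normalized by the squared
range of that average motif. A critical branching process collapses at
chi = 2 with an inverted-parabola motif; uncorrelated (shuffled) data
collapse near chi = 1 with a flattened motif.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .preprocess import InsufficientDataError, ParameterError

logger = logging.getLogger("avanet")

__all__ = [
    "ProfileSet",
    "CollapseResult",
    "ProfileFitComparison",
    "DegenerateCollapseError",
    "mean_profiles",
    "collapse_profiles",
    "fit_profile_models",
]


class DegenerateCollapseError(ValueError):
    """Collapse needs profiles from at least two distinct lifetimes."""


@dataclass
class ProfileSet:
    """Lifetime-grouped mean temporal profiles.

    profiles[L] is the arithmetic mean of per-bin sizes over all avalanches
    of exactly L bins; counts[L] is how many were averaged.
    """

    dt_ms: float
    profiles: dict
    counts: dict


@dataclass
class CollapseResult:
    chi: float
    delta_f: float
    grid: np.ndarray          # common relative-time grid t/L
    motif: np.ndarray         # pointwise average of rescaled profiles at chi
    scanned_chis: np.ndarray
    delta_f_curve: np.ndarray
    failed: bool              # Delta_F > 1 at the optimum


@dataclass
class ProfileFitComparison:
    """Parabolic vs semicircle least-squares fits of each profile.

    delta_parab / delta_semi are per-profile RMSEs; the paired t test and
    one-way ANOVA compare the two RMSE populations across profiles.
    """

    delta_parab: np.ndarray
    delta_semi: np.ndarray
    paired_t_p: float
    anova_f: float
    n_failed: int = 0


def mean_profiles(avalanches, L_set=(3, 4, 5), min_count: int = 1) -> ProfileSet:
    """Mean temporal profile per lifetime L in L_set.

    Lifetimes with fewer than min_count avalanches are omitted with a
    warning. The default L_set {3, 4, 5} brackets L_min = 4 bins, short
    enough to be well sampled yet long enough to resolve profile shape.
    """
    groups = {L: [] for L in L_set}
    for av in avalanches:
        if av.lifetime_bins in groups:
            groups[av.lifetime_bins].append(av.per_bin_sizes)
    profiles, counts = {}, {}
    for L in sorted(L_set):
        if len(groups[L]) < min_count:
            warnings.warn(f"no (or too few) avalanches of lifetime {L}; omitted")
            continue
        arr = np.asarray(groups[L], dtype=float)
        profiles[L] = arr.mean(axis=0)
        counts[L] = arr.shape[0]
    dt = getattr(avalanches, "dt_ms", np.nan)
    return ProfileSet(dt_ms=dt, profiles=profiles, counts=counts)


def _relative_times(L: int) -> np.ndarray:
    # bin centers: symmetric treatment of the first and last bins
    return (np.arange(1, L + 1) - 0.5) / L


def _interp_profile(grid, x, y):
    """Map a short profile onto the common grid.

    Profiles have only a handful of points; exact polynomial interpolation
    (degree L-1) reproduces smooth profile families without the systematic
    flattening of a piecewise-linear rendering, which would bias the scan.
    Longer profiles fall back to a cubic spline to avoid Runge oscillation.
    """
    if y.size <= 7:
        from scipy.interpolate import BarycentricInterpolator
        return BarycentricInterpolator(x, y)(grid)
    from scipy.interpolate import CubicSpline
    return CubicSpline(x, y)(grid)


def collapse_profiles(pset: ProfileSet, chi_min: float = 0.5,
                      chi_max: float = 3.0, step: float = 0.001,
                      n_grid: int = 25) -> CollapseResult:
    """Scan chi to find the best shape collapse.

    For each chi the profiles are rescaled by L^-(chi-1), interpolated
    (exact polynomial through the profile points; cubic spline for long
    profiles) onto a common t/L grid spanning the overlap of their bin
    centers, and the collapse error Delta_F is the mean squared deviation
    from the pointwise average, normalized by the squared range of that
    average (scale-free: multiplying all profiles by a constant leaves chi
    unchanged). Delta_F > 1 at the optimum flags a failed collapse.
    """
    Ls = sorted(pset.profiles)
    if len(Ls) < 2:
        raise DegenerateCollapseError("collapse needs >= 2 distinct lifetimes")
    lo = max(_relative_times(L)[0] for L in Ls)
    hi = min(_relative_times(L)[-1] for L in Ls)
    grid = np.linspace(lo, hi, n_grid)
    base = np.array([_interp_profile(grid, _relative_times(L), pset.profiles[L])
                     for L in Ls])                        # (n_L, n_grid)
    Larr = np.asarray(Ls, dtype=float)
    chis = np.arange(chi_min, chi_max + step / 2, step)
    scales = Larr[None, :] ** -(chis[:, None] - 1.0)      # (n_chi, n_L)
    rescaled = scales[:, :, None] * base[None, :, :]      # (n_chi, n_L, n_grid)
    motifs = rescaled.mean(axis=1)                        # (n_chi, n_grid)
    span2 = np.ptp(motifs, axis=1) ** 2
    span2 = np.where(span2 > 0, span2, np.nan)
    dev = ((rescaled - motifs[:, None, :]) ** 2).mean(axis=(1, 2))
    delta = dev / span2
    k = int(np.nanargmin(delta))
    return CollapseResult(chi=float(chis[k]), delta_f=float(delta[k]),
                          grid=grid, motif=motifs[k], scanned_chis=chis,
                          delta_f_curve=delta, failed=bool(delta[k] > 1.0))


# ----------------------------------------------------------- profile models

def _parabola(x, A, m):
    return A * np.clip(x * (1.0 - x), 0.0, None) ** m


def _semicircle_amplitude(x, y):
    b = np.sqrt(np.clip(1.0 - (2.0 * x - 1.0) ** 2, 0.0, None))
    denom = float(b @ b)
    return (float(y @ b) / denom) if denom > 0 else 0.0


def fit_profile_models(profiles) -> ProfileFitComparison:
    """Compare parabolic and semicircle fits of avalanche profiles.

    Parabola: y = A [ (t/T)(1 - t/T) ]^m with amplitude A and shape exponent
    m free (m = 1 is the exact inverted parabola). Semicircle: an
    amplitude-scaled arc y = A sqrt(1 - (2t/T - 1)^2) over the normalized
    lifetime. Each profile is evaluated at its bin centers; the per-profile
    RMSEs feed a paired t test and a one-way ANOVA.
    """
    if isinstance(profiles, ProfileSet):
        items = [profiles.profiles[L] for L in sorted(profiles.profiles)]
    elif isinstance(profiles, dict):
        items = [profiles[L] for L in sorted(profiles)]
    else:
        items = [np.asarray(p, dtype=float) for p in profiles]
    d_par, d_semi = [], []
    n_failed = 0
    for y in items:
        y = np.asarray(y, dtype=float)
        if y.size < 3:
            raise ParameterError("profile needs >= 3 points")
        x = _relative_times(y.size)
        try:
            popt, _ = optimize.curve_fit(
                _parabola, x, y, p0=[max(y.max(), 1e-6) * 4.0, 1.0],
                bounds=([1e-9, 0.05], [np.inf, 10.0]), maxfev=20000)
            rmse_p = float(np.sqrt(np.mean((y - _parabola(x, *popt)) ** 2)))
        except RuntimeError:
            logger.warning("parabolic fit failed to converge; profile excluded")
            n_failed += 1
            continue
        A = _semicircle_amplitude(x, y)
        b = A * np.sqrt(np.clip(1.0 - (2.0 * x - 1.0) ** 2, 0.0, None))
        rmse_s = float(np.sqrt(np.mean((y - b) ** 2)))
        d_par.append(rmse_p)
        d_semi.append(rmse_s)
    d_par = np.asarray(d_par)
    d_semi = np.asarray(d_semi)
    if d_par.size >= 2:
        t_p = float(stats.ttest_rel(d_par, d_semi).pvalue)
        f = float(stats.f_oneway(d_par, d_semi).statistic)
    else:
        t_p, f = np.nan, np.nan
    return ProfileFitComparison(delta_parab=d_par, delta_semi=d_semi,
                                paired_t_p=t_p, anova_f=f, n_failed=n_failed)
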