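"""Shared statistical primitives.

Discrete, window-truncated maximum-likelihood fits (power law, exponential,
log-normal) with Vuong-style normalized log-likelihood-ratio model comparison,
plus a small OLS trend helper used by every stability analysis.

All discrete fits normalize the model over the integer window [s_min, s_max]
rather than conditioning on the tail, matching an analysis that fits a fixed
range below the distribution cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "fit_discrete_powerlaw",
    "discrete_powerlaw_logpmf",
    "fit_discrete_exponential",
    "fit_discrete_lognormal",
    "vuong_llr",
    "sample_discrete_powerlaw",
    "OLSTrend",
    "ols_trend",
]


# ---------------------------------------------------------------- discrete fits

def discrete_powerlaw_logpmf(s: np.ndarray, alpha: float, s_min: int, s_max: int) -> np.ndarray:
    """log pmf of p(s) ∝ s^-alpha on integer support [s_min, s_max]."""
    support = np.arange(s_min, s_max + 1, dtype=float)
    log_z = np.log(np.sum(support ** -alpha))
    return -alpha * np.log(s) - log_z


def fit_discrete_powerlaw(
    sizes: np.ndarray, s_min: int = 1, s_max: int = 40,
    alpha_bounds: tuple[float, float] = (0.01, 8.0),
) -> float:
    """MLE exponent alpha for p(s) ∝ s^-alpha on [s_min, s_max].

    The likelihood depends on the data only through mean(log s), so the
    optimization is a 1-d bounded minimization.
    """
    s = np.asarray(sizes, dtype=float)
    mean_log = np.mean(np.log(s))
    support = np.arange(s_min, s_max + 1, dtype=float)
    log_support = np.log(support)

    def negll(alpha: float) -> float:
        log_z = np.log(np.sum(np.exp(-alpha * log_support)))
        return alpha * mean_log + log_z

    res = optimize.minimize_scalar(negll, bounds=alpha_bounds, method="bounded")
    return float(res.x)


def _discrete_exponential_logpmf(s, lam, s_min, s_max):
    support = np.arange(s_min, s_max + 1, dtype=float)
    log_z = np.log(np.sum(np.exp(-lam * support)))
    return -lam * np.asarray(s, dtype=float) - log_z


def fit_discrete_exponential(sizes, s_min=1, s_max=40):
    """MLE rate lambda for p(s) ∝ exp(-lambda s) on [s_min, s_max]."""
    s = np.asarray(sizes, dtype=float)
    mean_s = s.mean()
    support = np.arange(s_min, s_max + 1, dtype=float)

    def negll(lam):
        log_z = np.log(np.sum(np.exp(-lam * support)))
        return lam * mean_s + log_z

    res = optimize.minimize_scalar(negll, bounds=(1e-6, 20.0), method="bounded")
    return float(res.x)


def _discrete_lognormal_logpmf(s, mu, sigma, s_min, s_max):
    support = np.arange(s_min, s_max + 1, dtype=float)
    log_w = -np.log(support) - (np.log(support) - mu) ** 2 / (2.0 * sigma**2)
    log_z = _logsumexp(log_w)
    sf = np.asarray(s, dtype=float)
    return -np.log(sf) - (np.log(sf) - mu) ** 2 / (2.0 * sigma**2) - log_z


def _logsumexp(x):
    m = np.max(x)
    return m + np.log(np.sum(np.exp(x - m)))


def fit_discrete_lognormal(sizes, s_min=1, s_max=40):
    """MLE (mu, sigma) for p(s) ∝ (1/s)·exp(-(ln s - mu)^2 / 2 sigma^2) on the window."""
    s = np.asarray(sizes, dtype=float)
    logs = np.log(s)
    x0 = np.array([logs.mean(), max(logs.std(), 0.1)])

    def negll(theta):
        mu, sigma = theta
        if sigma <= 1e-4:
            return np.inf
        return -np.sum(_discrete_lognormal_logpmf(s, mu, sigma, s_min, s_max))

    res = optimize.minimize(negll, x0, method="Nelder-Mead",
                            options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000})
    mu, sigma = res.x
    return float(mu), float(abs(sigma))


def vuong_llr(logp_a: np.ndarray, logp_b: np.ndarray) -> tuple[float, float]:
    """Normalized log-likelihood-ratio test between two fitted models.

    Returns (llr, p). llr = sum(logp_a - logp_b); positive means model A gives
    the data higher likelihood. p is the two-sided significance of the
    normalized ratio llr / (sqrt(n)·sd(pointwise differences)); a large llr
    with small p means the sign of llr is trustworthy.
    """
    d = np.asarray(logp_a, dtype=float) - np.asarray(logp_b, dtype=float)
    n = d.size
    llr = float(d.sum())
    sd = float(d.std())
    if sd < 1e-12 or n < 2:
        return llr, 1.0  # models indistinguishable on these data
    z = llr / (sd * np.sqrt(n))
    p = float(2.0 * stats.norm.sf(abs(z)))
    return llr, p


def sample_discrete_powerlaw(n: int, alpha: float, s_min: int, s_max: int, rng) -> np.ndarray:
    """Draw n samples from p(s) ∝ s^-alpha on integers [s_min, s_max]."""
    support = np.arange(s_min, s_max + 1)
    w = support.astype(float) ** -alpha
    return rng.choice(support, size=n, p=w / w.sum())


# ------------------------------------------------------------------- OLS trend

@dataclass(frozen=True)
class OLSTrend:
    """Slope of an ordinary least-squares line with 95% confidence limits."""

    slope: float
    intercept: float
    ci_low: float
    ci_high: float
    n: int

    def ci_contains(self, value: float) -> bool:
        return self.ci_low <= value <= self.ci_high


def ols_trend(x, y) -> OLSTrend:
    """OLS regression of y on x; slope with 95% confidence limits.

    With exactly two points the slope is exact and the confidence interval
    degenerate (zero residual degrees of freedom -> infinite limits).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 points for a trend")
    if np.ptp(x) == 0:
        raise ValueError("x values are all identical")
    res = stats.linregress(x, y)
    n = x.size
    if n > 2 and np.isfinite(res.stderr) and res.stderr > 0:
        half = stats.t.ppf(0.975, n - 2) * res.stderr
    elif n > 2:
        half = 0.0
    else:
        half = np.inf
    return OLSTrend(float(res.slope), float(res.intercept),
                    float(res.slope - half), float(res.slope + half), int(n))
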