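"""Entropy-of-mixing analysis of link-weight stability across sessions.

Links of a reference (day-1) network half — the strongest or weakest 50% —
are labeled by weight quintile (N_c = 5 categories). On each later day the
same links are re-sorted by their current weights and partitioned into
N_g = k·N_c rank groups (k = 3, N_g = 15 by default); each group's Shannon
entropy over the day-1 labels measures how much the original categories have
mixed. H_M averages the non-edge groups g = 2..N_g-1 (n = N_g - 2 = 13). It
is 0 when ranks are unchanged and approaches log N_c under complete
reshuffling. A Monte-Carlo test decides whether H_M rises over days faster
than its measurement noise allows.

Natural logarithms throughout; the theoretical maximum log N_c is reported
alongside so the base is self-documenting.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from ._stats import ols_trend
from .netrecon import WeightedDigraph
from .preprocess import InsufficientDataError, ParameterError

logger = logging.getLogger("avanet")

__all__ = [
    "MixingConfig",
    "LinkLabels",
    "MixingTrajectory",
    "assign_day1_labels",
    "mixing_entropy",
    "randomized_baseline",
    "trend_test",
    "mixing_trajectory",
]


@dataclass(frozen=True)
class MixingConfig:
    n_categories: int = 5       # N_c weight quintiles on day 1
    group_multiplier: int = 3   # k; N_g = k * N_c rank groups on later days
    half: str = "top"           # analyze strongest ("top") or weakest ("bottom") 50%

    def __post_init__(self):
        if self.n_categories < 2:
            raise ParameterError("need N_c >= 2 categories")
        if self.group_multiplier < 1 or int(self.group_multiplier) != self.group_multiplier:
            raise ParameterError("group multiplier k must be a positive integer")
        if self.half not in ("top", "bottom"):
            raise ParameterError("half must be 'top' or 'bottom'")

    @property
    def n_groups(self) -> int:
        return self.n_categories * self.group_multiplier


@dataclass
class LinkLabels:
    """Day-1 category labels for a fixed set of links.

    pairs is in ascending day-1 weight order; labels[r] in 1..N_c is the
    category of the r-th weakest link of the selected half.
    """

    pairs: list                 # [(i, j), ...] ordered by day-1 weight
    labels: np.ndarray          # parallel array of categories 1..N_c
    half: str


@dataclass
class MixingTrajectory:
    day: np.ndarray
    h_m: np.ndarray
    sem: np.ndarray
    h_m_randomized: np.ndarray
    h_m_max: float
    trend_slope: float = np.nan
    trend_p: float = np.nan


def _sorted_pairs(graph: WeightedDigraph):
    """Nonzero links sorted ascending by (weight, then node pair lexically)."""
    i, j, w = graph.link_arrays()
    order = np.lexsort((j, i, w))
    return [(int(a), int(b)) for a, b in zip(i[order], j[order])], w[order]


def _rank_partition(n: int, n_parts: int) -> np.ndarray:
    """Rank-proportional part index: equal counts to within one.

    part(r) = floor(r·n_parts / n). For integer k, the N_g = k·N_c partition
    exactly refines the N_c partition for any n, which is what makes the
    day-1 self-comparison identically zero.
    """
    return (np.arange(n) * n_parts) // n


def assign_day1_labels(graph_day1: WeightedDigraph, cfg: MixingConfig) -> LinkLabels:
    """Select the configured half of the day-1 links and label them by quintile.

    Category c = 1 marks the weakest fifth of the selected half's links,
    c = N_c the strongest fifth. Ties are broken by node-pair lexical order
    (stable and deterministic).
    """
    pairs, _ = _sorted_pairs(graph_day1)
    m = len(pairs)
    half_m = m // 2
    if cfg.half == "top":
        sel = pairs[m - half_m:]
    else:
        sel = pairs[:half_m]
    if len(sel) < cfg.n_groups:
        raise InsufficientDataError(
            f"selected half has {len(sel)} links; need >= N_g = {cfg.n_groups}")
    labels = _rank_partition(len(sel), cfg.n_categories) + 1
    return LinkLabels(pairs=sel, labels=labels, half=cfg.half)


def _group_entropies(labels_in_day_k_order: np.ndarray, cfg: MixingConfig) -> np.ndarray:
    n = labels_in_day_k_order.size
    groups = _rank_partition(n, cfg.n_groups)
    h = np.empty(cfg.n_groups)
    for g in range(cfg.n_groups):
        lab = labels_in_day_k_order[groups == g]
        counts = np.bincount(lab, minlength=cfg.n_categories + 1)[1:]
        f = counts[counts > 0] / lab.size
        h[g] = float(-(f * np.log(f)).sum())
    return h


def mixing_entropy(graph_day_k: WeightedDigraph, labels: LinkLabels,
                   cfg: MixingConfig):
    """Entropy of mixing of day-k weights against day-1 labels.

    The labeled links are re-sorted by their day-k weights (links absent on
    day k rank at the bottom with weight 0, logged) and partitioned into N_g
    equal-count rank groups; per group g the label fractions f_c give
    H_g = -sum f_c log f_c. Returns (H_M, sem, H_g) where H_M and the
    standard error are taken over the non-edge groups g = 2..N_g-1.
    """
    w_k = np.array([graph_day_k.weights[p] for p in labels.pairs])
    n_absent = int((w_k == 0).sum())
    if n_absent:
        logger.info("%d labeled links absent on the later day; ranked bottom",
                    n_absent)
    pair_arr = np.asarray(labels.pairs)
    order = np.lexsort((pair_arr[:, 1], pair_arr[:, 0], w_k))
    h_g = _group_entropies(labels.labels[order], cfg)
    inner = h_g[1:-1]
    h_m = float(inner.mean())
    sem = float(inner.std(ddof=1) / np.sqrt(inner.size))
    return h_m, sem, h_g


def randomized_baseline(labels: LinkLabels, cfg: MixingConfig,
                        n_reps: int = 20, seed: int = 0) -> float:
    """Mean H_M when the day-1 labels are fully randomized.

    The label array is permuted uniformly; with random labels the day-k
    weight ordering is irrelevant, so groups are formed directly on the
    permuted sequence. Approaches log N_c for large link counts.
    """
    rng = np.random.default_rng(seed)
    vals = []
    for _ in range(n_reps):
        perm = rng.permutation(labels.labels)
        h_g = _group_entropies(perm, cfg)
        vals.append(h_g[1:-1].mean())
    return float(np.mean(vals))


def trend_test(days, h_m, sems, n_mc: int = 1_000_000, seed: int = 0,
               chunk: int = 100_000):
    """Monte-Carlo test for a progressive increase of H_M across days.

    The observed slope is the OLS slope of the mean H_M values on day. Under
    the null, each point is replaced by pure noise N(0, sigma_G) with the
    per-point standard errors; the one-sided p counts null slopes exceeding
    the observed one: p = (N_pos + 1) / (N_MC + 1).
    """
    days = np.asarray(days, dtype=float)
    h_m = np.asarray(h_m, dtype=float)
    sems = np.asarray(sems, dtype=float)
    if days.size < 3:
        raise InsufficientDataError("trend test needs >= 3 sessions after day 1")
    if (sems <= 0).any():
        warnings.warn("zero sigma_G at some point; applying a jitter floor")
        floor = max(1e-9, 1e-6 * max(np.abs(h_m).max(), 1.0))
        sems = np.maximum(sems, floor)
    slope = ols_trend(days, h_m).slope
    dc = days - days.mean()
    w = dc / (dc @ dc)
    rng = np.random.default_rng(seed)
    n_pos = 0
    left = n_mc
    while left > 0:
        k = min(chunk, left)
        noise = rng.standard_normal((k, days.size)) * sems
        n_pos += int((noise @ w > slope).sum())
        left -= k
    p = (n_pos + 1) / (n_mc + 1)
    return float(slope), float(p)


def mixing_trajectory(graphs, days, cfg: MixingConfig = MixingConfig(),
                      n_baseline_reps: int = 20, n_mc: int = 1_000_000,
                      seed: int = 0) -> MixingTrajectory:
    """Full per-session H_M trajectory with baselines and trend test.

    graphs[0] (day 1) defines the labels; the day-1 H_M is identically 0 by
    construction and excluded from the trend, which is evaluated on the
    remaining sessions.
    """
    graphs = list(graphs)
    days = np.asarray(days, dtype=float)
    if len(graphs) != days.size or len(graphs) < 2:
        raise ParameterError("need >= 2 sessions with matching day indices")
    labels = assign_day1_labels(graphs[0], cfg)
    h_m, sems, base = [], [], []
    ss = np.random.SeedSequence(seed)
    for g, child in zip(graphs, ss.spawn(len(graphs))):
        h, s, _ = mixing_entropy(g, labels, cfg)
        h_m.append(h)
        sems.append(s)
        base.append(randomized_baseline(labels, cfg, n_baseline_reps,
                                        seed=int(child.generate_state(1)[0])))
    traj = MixingTrajectory(day=days, h_m=np.asarray(h_m), sem=np.asarray(sems),
                            h_m_randomized=np.asarray(base),
                            h_m_max=float(np.log(cfg.n_categories)))
    if days.size >= 4:
        slope, p = trend_test(days[1:], traj.h_m[1:], traj.sem[1:],
                              n_mc=n_mc, seed=int(ss.generate_state(1)[0]))
        traj.trend_slope, traj.trend_p = slope, p
    return traj
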