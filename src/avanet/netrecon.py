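"""Functional-network reconstruction from event rasters.

The normalized-count (NC) estimator assigns, for every activation of a node,
equal causal credit 1/|A| to each node active in the preceding frame (the
candidate-cause set A), then normalizes each target's accumulated credit by
its total activation count so weights are comparable across nodes. A
correlation-threshold network from the continuous signal is provided for
comparison, thresholded upward in 0.01 steps until a target link density is
reached.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._stats import vuong_llr
from .preprocess import (EventRaster, InsufficientDataError, ParameterError,
                         SignalRecording)

logger = logging.getLogger("avanet")

__all__ = [
    "WeightedDigraph",
    "WeightDistributionReport",
    "nc_reconstruct",
    "weight_distribution_report",
    "correlation_network",
    "threshold_graph",
]


@dataclass
class WeightedDigraph:
    """Directed weighted functional network: weights[i, j] is the link i -> j.

    Zero diagonal, nonnegative finite weights. Undirected (correlation)
    networks are stored symmetrically in the same container.
    """

    weights: np.ndarray
    node_ids: list = None
    dt_ms: float = np.nan
    n_transitions: int = 0

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        n = self.weights.shape[0]
        if self.weights.shape != (n, n):
            raise ParameterError("weights must be square")
        if not np.isfinite(self.weights).all():
            raise ParameterError("weights must be finite")
        if (self.weights < 0).any():
            raise ParameterError("weights must be nonnegative")
        if np.diagonal(self.weights).any():
            raise ParameterError("diagonal must be zero (no self-links)")
        if self.node_ids is None:
            self.node_ids = list(range(n))

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_links(self) -> int:
        return int(np.count_nonzero(self.weights))

    def link_arrays(self):
        """(sources, targets, weights) of nonzero links, row-major order."""
        i, j = np.nonzero(self.weights)
        return i, j, self.weights[i, j]


@dataclass
class WeightDistributionReport:
    """Normalized weight histograms per session and exponential-vs-log-normal LLR.

    llr_exp_vs_logn > 0 favors the exponential model (sign convention:
    first-named model on top).
    """

    histograms: list            # (bin_edges, density) per session
    llr_exp_vs_logn: np.ndarray
    p: np.ndarray
    span_decades: np.ndarray    # log10(max/min) of nonzero weights


def nc_reconstruct(raster: EventRaster, window_ms: float = None) -> WeightedDigraph:
    """Normalized-count reconstruction of a directed weighted network.

    For every activation of node j in frame b, each node i active anywhere in
    the preceding window (default: the single previous frame), i != j,
    accrues credit 1/|A| toward w_ij; frames with an empty candidate set
    contribute nothing (the activation is attributed to external drive).
    w_ij is the accumulated credit divided by j's total activation count.
    Deterministic.
    """
    if window_ms is None:
        win = 1
    else:
        if window_ms <= 0:
            raise ParameterError("window must be positive")
        # sub-bin windows clamp to one bin: the raster cannot be subdivided
        win = max(1, int(round(window_ms / raster.dt_ms)))
    n = raster.n_electrodes
    counts = raster.counts
    active = counts > 0
    pop = raster.population()
    credit = np.zeros((n, n))
    total_act = counts.sum(axis=1).astype(float)
    n_transitions = 0
    for b in range(1, raster.n_bins):
        if pop[b] == 0:
            continue
        lo = max(0, b - win)
        prev = np.flatnonzero(active[:, lo:b].any(axis=1))
        if prev.size == 0:
            continue
        n_transitions += 1
        prev_set = set(prev.tolist())
        for j in np.flatnonzero(active[:, b]):
            if j in prev_set:
                causes = prev[prev != j]
            else:
                causes = prev
            if causes.size == 0:
                continue
            credit[causes, j] += counts[j, b] / causes.size
    if n_transitions == 0:
        warnings.warn("no consecutive-frame activity; returning an empty graph")
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(total_act[None, :] > 0, credit / total_act[None, :], 0.0)
    np.fill_diagonal(w, 0.0)
    return WeightedDigraph(weights=w, node_ids=list(raster.electrode_ids),
                           dt_ms=raster.dt_ms * win, n_transitions=n_transitions)


def weight_distribution_report(graphs, n_hist_bins: int = 30,
                               min_links: int = 50) -> WeightDistributionReport:
    """Distribution of nonzero link weights per session, with model comparison.

    Histograms are density-normalized on logarithmic bins. The LLR compares
    a maximum-likelihood exponential against a log-normal on the nonzero
    weights (positive = exponential favored), with a Vuong-normalized
    two-sided p.
    """
    graphs = list(graphs)
    if not graphs:
        raise ParameterError("need at least one graph")
    hists, llrs, ps, spans = [], [], [], []
    for g in graphs:
        w = g.weights[g.weights > 0]
        if w.size < min_links:
            raise InsufficientDataError(
                f"graph has {w.size} nonzero weights; need >= {min_links}")
        edges = np.geomspace(w.min(), w.max(), n_hist_bins + 1)
        dens, edges = np.histogram(w, bins=edges, density=True)
        hists.append((edges, dens))
        spans.append(float(np.log10(w.max() / w.min())))
        logp_exp = stats.expon.logpdf(w, scale=w.mean())
        lw = np.log(w)
        sigma = max(lw.std(), 1e-9)
        logp_logn = stats.lognorm.logpdf(w, s=sigma, scale=np.exp(lw.mean()))
        llr, p = vuong_llr(logp_exp, logp_logn)
        llrs.append(llr)
        ps.append(p)
    return WeightDistributionReport(histograms=hists,
                                    llr_exp_vs_logn=np.asarray(llrs),
                                    p=np.asarray(ps),
                                    span_decades=np.asarray(spans))


def threshold_graph(graph: WeightedDigraph, density: float = 0.40) -> WeightedDigraph:
    """Keep only the strongest links up to the requested link density.

    Reconstruction spreads faint spurious credit over most node pairs;
    graph-theoretical analyses operate on a sparsified network in which weak
    links below the density cutoff are removed. Density is the retained
    fraction of ordered node pairs. Ties at the cutoff break by node-pair
    lexical order (deterministic).
    """
    if not 0 < density <= 1:
        raise ParameterError("density must be in (0, 1]")
    i, j, w = graph.link_arrays()
    n = graph.n_nodes
    keep_n = min(w.size, int(round(density * n * (n - 1))))
    order = np.lexsort((j, i, w))[::-1][:keep_n]
    out = np.zeros_like(graph.weights)
    out[i[order], j[order]] = w[order]
    return WeightedDigraph(weights=out, node_ids=list(graph.node_ids),
                           dt_ms=graph.dt_ms, n_transitions=graph.n_transitions)


def correlation_network(sig: SignalRecording, target_density: float = 0.40,
                        step: float = 0.01) -> WeightedDigraph:
    """Correlation-threshold network at a predefined sparsity.

    Pairwise Pearson R on non-excised samples; the threshold rises in `step`
    increments from below the weakest correlation, discarding links below
    it, and stops at the first step where the surviving undirected link
    density is <= target_density. The result is symmetric, with surviving
    R values as weights.
    """
    if sig.n_channels < 3:
        raise ParameterError("correlation network needs >= 3 channels")
    kept = sig.kept()
    r = np.corrcoef(sig.data[:, kept])
    n = sig.n_channels
    iu = np.triu_indices(n, k=1)
    vals = r[iu]
    n_possible = vals.size
    if np.ptp(vals) == 0:
        raise ParameterError(
            "all pairwise correlations identical; thresholding cannot reach "
            f"the target density (R = {vals[0]:.3f} everywhere)")
    thr = np.floor(vals.min() / step) * step
    while True:
        keep = vals >= thr
        density = keep.mean()
        if density <= target_density:
            break
        thr += step
    w = np.zeros((n, n))
    ki, kj = iu[0][keep], iu[1][keep]
    w[ki, kj] = vals[keep]
    w[kj, ki] = vals[keep]
    if (vals[keep] < 0).any():
        # negative correlations surviving a low threshold would violate the
        # nonnegative-weight contract; they can only survive when the target
        # density exceeds the positive-link fraction
        w = np.abs(w)
        logger.info("negative correlations retained; stored as magnitudes")
    g = WeightedDigraph(weights=w, node_ids=list(sig.channel_ids),
                        n_transitions=int(kept.sum()))
    g.threshold = float(thr)
    g.density = float(density)
    return g
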