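"""Synthetic data with known ground truth.

Every input the analysis consumes can be generated here: event rasters from a
critical branching process on an electrode grid, cascades on an arbitrary
known weighted directed network, continuous signals with planted negative
deflections, multi-day session sequences with controlled drift of the
ground-truth network, and time-shuffled controls.

All generators are pure functions of (inputs, seed): the same arguments give
byte-identical output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .preprocess import EventRaster, ParameterError, SignalRecording

logger = logging.getLogger("avanet")

__all__ = [
    "SimConfig",
    "GroundTruthNetwork",
    "DriftModel",
    "simulate_branching_raster",
    "simulate_cascades_on_network",
    "make_synthetic_signal",
    "generate_session_sequence",
    "shuffle_raster_times",
    "make_small_world_network",
    "make_integrative_network",
]


# ------------------------------------------------------------------ configs

@dataclass(frozen=True)
class SimConfig:
    """Branching-process simulation parameters.

    branching_ratio is sigma, the expected number of next-generation
    descendants per active node; drive_rate is the spontaneous (Poisson)
    activation rate per node per bin. The default drive of 2e-4 puts a 10x10
    grid at criticality in the regime where the pooled mean inter-event
    interval is ~1-2 bins, so that binning at <IEI> balances premature
    termination against concatenation of avalanches — the operating point of
    the avalanche definition.
    """

    n_rows: int = 10
    n_cols: int = 10
    branching_ratio: float = 1.0
    drive_rate: float = 2e-4
    n_bins: int = 500_000
    dt_ms: float = 1.0
    seed: int = 0
    neighborhood_radius: int = None  # Chebyshev radius; None = whole array
    generations_per_bin: int = 2     # branching micro-steps aggregated per bin

    def __post_init__(self):
        if self.n_rows * self.n_cols < 2:
            raise ParameterError("grid must have at least 2 nodes")
        if self.branching_ratio < 0:
            raise ParameterError("branching_ratio must be >= 0")
        if not 0 <= self.drive_rate < 1:
            raise ParameterError("drive_rate must be in [0, 1)")
        if self.n_bins < 1:
            raise ParameterError("n_bins must be >= 1")
        if self.dt_ms <= 0:
            raise ParameterError("dt_ms must be positive")
        if self.generations_per_bin < 1:
            raise ParameterError("generations_per_bin must be >= 1")


@dataclass
class GroundTruthNetwork:
    """Generative weighted digraph: weights[i, j] = P(activity at i activates j)."""

    weights: np.ndarray
    labels: list = None

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        n = self.weights.shape[0]
        if self.weights.shape != (n, n):
            raise ParameterError("weights must be square")
        if (self.weights < 0).any() or (self.weights > 1).any():
            raise ParameterError("weights must lie in [0, 1]")
        if np.diagonal(self.weights).any():
            raise ParameterError("weights must have a zero diagonal")
        if self.labels is None:
            self.labels = list(range(n))

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclass(frozen=True)
class DriftModel:
    """Session-to-session drift of the ground-truth network.

    Each session, a fraction of links has its weight redrawn from the day-1
    weight pool, and every link receives multiplicative log-normal jitter.
    """

    resample_fraction_per_day: float = 0.0
    jitter_sd: float = 0.0

    def __post_init__(self):
        if not 0 <= self.resample_fraction_per_day <= 1:
            raise ParameterError("resample fraction must be in [0, 1]")
        if self.jitter_sd < 0:
            raise ParameterError("jitter_sd must be >= 0")


# ------------------------------------------------------- branching simulator

def _grid_neighbors(n_rows: int, n_cols: int, radius: int = None):
    """Offspring targets per node on a rows x cols grid, no wrap-around.

    radius is a Chebyshev (chessboard) distance; None means every other node
    on the array is a potential target, the mean-field offspring pool of a
    classic critical branching network, which yields the size exponent 3/2
    and collapse exponent 2. Small radii instead give nearest-neighbor
    (directed-percolation-like) spread with flatter distributions.
    """
    n = n_rows * n_cols
    neigh = []
    for r in range(n_rows):
        for c in range(n_cols):
            me = r * n_cols + c
            if radius is None:
                ids = np.delete(np.arange(n), me)
            else:
                rr, cc = np.meshgrid(
                    np.arange(max(0, r - radius), min(n_rows, r + radius + 1)),
                    np.arange(max(0, c - radius), min(n_cols, c + radius + 1)),
                    indexing="ij")
                ids = (rr * n_cols + cc).ravel()
                ids = ids[ids != me]
            neigh.append(np.asarray(ids, dtype=np.intp))
    return neigh


def simulate_branching_raster(config: SimConfig) -> EventRaster:
    """Simulate a branching process on an electrode grid.

    Cascades propagate in micro-steps (branching generations): each node
    active at a micro-step independently activates each node j of its
    offspring pool at the next micro-step with probability sigma/deg(node),
    so the expected offspring per active node equals the branching ratio
    everywhere. Node states are binary per micro-step: simultaneous
    activations of the same target saturate, supplying the finite-size
    cutoff of a physical array -- without it a critical cascade's population
    grows without bound. The default offspring pool is the whole array
    (mean-field critical branching).

    generations_per_bin micro-steps are aggregated into each raster bin,
    reflecting that event binning is coarser than cascade propagation; a
    node firing in several micro-steps of one bin contributes several
    events, so multiple events per node per bin occur naturally inside
    avalanches. A homogeneous Poisson drive (drive_rate per node per BIN,
    spread uniformly over micro-steps) seeds cascades.
    """
    n = config.n_rows * config.n_cols
    neigh = _grid_neighbors(config.n_rows, config.n_cols,
                            config.neighborhood_radius)
    deg = np.array([len(v) for v in neigh], dtype=float)
    if config.branching_ratio > deg.min():
        raise ParameterError(
            "branching_ratio exceeds the minimum offspring-pool size; "
            "per-target probability sigma/deg would leave [0, 1]")
    p = config.branching_ratio / deg
    g = config.generations_per_bin
    n_micro = config.n_bins * g

    rng = np.random.default_rng(config.seed)
    counts = np.zeros((n, config.n_bins), dtype=np.int32)
    n_drive = int(rng.poisson(config.drive_rate * n * config.n_bins))
    d_nodes = rng.integers(0, n, n_drive)
    d_micro = rng.integers(0, n_micro, n_drive)
    order = np.argsort(d_micro, kind="stable")
    d_micro, d_nodes = d_micro[order], d_nodes[order]

    cur = np.zeros(n, dtype=np.int32)
    prev_active = np.empty(0, dtype=np.intp)
    ptr = 0
    m = int(d_micro[0]) if n_drive else n_micro
    while m < n_micro:
        cur[:] = 0
        while ptr < n_drive and d_micro[ptr] == m:
            cur[d_nodes[ptr]] += 1
            ptr += 1
        if config.branching_ratio > 0 and prev_active.size:
            hit = np.zeros(n, dtype=bool)
            for i in prev_active:
                trials = rng.random(neigh[i].size) < p[i]
                if trials.any():
                    hit[neigh[i][trials]] = True
            cur[hit] += 1
        prev_active = np.flatnonzero(cur)
        if prev_active.size:
            counts[prev_active, m // g] += cur[prev_active]
            m += 1
        elif ptr < n_drive:
            m = int(d_micro[ptr])  # jump over the idle stretch
        else:
            break
    return EventRaster(counts=counts, dt_ms=config.dt_ms)


def simulate_cascades_on_network(net: GroundTruthNetwork, drive_rate: float,
                                 n_bins: int, seed: int,
                                 drive_nodes=None) -> EventRaster:
    """Stochastic cascades on a known weighted digraph.

    Each activation of node i at bin t activates node j at t+1 with
    probability weights[i, j], independently per activation and per link;
    a Poisson drive (optionally restricted to drive_nodes) seeds activity.
    """
    if not 0 <= drive_rate < 1:
        raise ParameterError("drive_rate must be in [0, 1)")
    n = net.n_nodes
    rng = np.random.default_rng(seed)
    out_targets = [np.flatnonzero(net.weights[i]) for i in range(n)]
    out_p = [net.weights[i, t] for i, t in enumerate(out_targets)]

    if drive_nodes is None:
        drive_nodes = np.arange(n)
    else:
        drive_nodes = np.asarray(drive_nodes, dtype=np.intp)
    n_drive = rng.poisson(drive_rate * drive_nodes.size * n_bins)
    d_nodes = drive_nodes[rng.integers(0, drive_nodes.size, n_drive)]
    d_bins = rng.integers(0, n_bins, n_drive)

    counts = np.zeros((n, n_bins), dtype=np.int32)
    np.add.at(counts, (d_nodes, d_bins), 1)
    pop = np.zeros(n_bins, dtype=np.int64)
    np.add.at(pop, d_bins, 1)

    for t in range(n_bins - 1):
        if pop[t] == 0:
            continue
        if pop[t] > 100 * n:
            raise ParameterError(
                "cascade population is running away (supercritical network); "
                "scale the weights so row sums stay below ~1")
        col = counts[:, t]
        nxt = counts[:, t + 1]
        added = 0
        for i in np.flatnonzero(col):
            if out_targets[i].size == 0:
                continue
            off = rng.binomial(int(col[i]), out_p[i])
            s = int(off.sum())
            if s:
                nxt[out_targets[i]] += off.astype(np.int32)
                added += s
        if added:
            pop[t + 1] += added
    return EventRaster(counts=counts, dt_ms=1.0)


# --------------------------------------------------------- continuous signal

def _negative_biphasic_kernel(fs_hz: float, width_ms: float = 20.0) -> np.ndarray:
    """Brief negative-peaked kernel (inverted Ricker), unit peak depth.

    20 ms wide so its spectral content sits inside a 1-100 Hz passband.
    """
    half = int(round(width_ms / 2000.0 * fs_hz))
    t = np.arange(-half, half + 1, dtype=float)
    s = half / 2.5
    u = t / max(s, 1.0)
    k = -(1.0 - u**2) * np.exp(-(u**2) / 2.0)
    return k / np.abs(k).max()


def make_synthetic_signal(raster: EventRaster, kernel_depth_sd: float = 5.0,
                          noise_sd: float = 1.0, fs_hz: float = 2000.0,
                          seed: int = 0) -> SignalRecording:
    """Continuous per-channel signal with one negative deflection per event.

    White Gaussian noise of SD noise_sd plus, for every raster event, a
    negative biphasic kernel whose trough (kernel_depth_sd noise-SDs deep) is
    aligned with the center of the event's bin. kernel_depth_sd must exceed 2
    so that planted events clear the -2 SD detection threshold.
    """
    if kernel_depth_sd <= 2:
        raise ParameterError("kernel_depth_sd must exceed 2 (detection threshold)")
    spb = raster.dt_ms / 1000.0 * fs_hz
    if abs(spb - round(spb)) > 1e-9 or round(spb) < 1:
        raise ParameterError(
            f"fs {fs_hz} Hz incompatible with bin width {raster.dt_ms} ms")
    spb = int(round(spb))
    n_samples = raster.n_bins * spb
    rng = np.random.default_rng(seed)
    scale = noise_sd if noise_sd > 0 else 1.0
    if noise_sd > 0:
        data = rng.normal(0.0, noise_sd, size=(raster.n_electrodes, n_samples))
    else:
        data = np.zeros((raster.n_electrodes, n_samples))
    kernel = _negative_biphasic_kernel(fs_hz) * kernel_depth_sd * scale
    half = kernel.size // 2
    chans, bins = np.nonzero(raster.counts)
    for ch, b in zip(chans, bins):
        c = int(raster.counts[ch, b])
        center = b * spb + spb // 2
        lo, hi = center - half, center + half + 1
        klo, khi = max(0, -lo), kernel.size - max(0, hi - n_samples)
        data[ch, max(0, lo):min(n_samples, hi)] += c * kernel[klo:khi]
    return SignalRecording(data=data, fs_hz=fs_hz,
                           channel_ids=list(raster.electrode_ids))


# --------------------------------------------------------- session sequences

def _drift_network(net: GroundTruthNetwork, drift: DriftModel,
                   weight_pool: np.ndarray, rng) -> GroundTruthNetwork:
    w = net.weights.copy()
    links = np.argwhere(w > 0)
    m = len(links)
    k = int(round(drift.resample_fraction_per_day * m))
    if k > 0:
        pick = rng.choice(m, size=k, replace=False)
        w[links[pick, 0], links[pick, 1]] = rng.choice(weight_pool, size=k)
    if drift.jitter_sd > 0:
        i, j = np.nonzero(w)
        w[i, j] = np.clip(w[i, j] * np.exp(rng.normal(0, drift.jitter_sd, i.size)),
                          0.0, 1.0)
    return GroundTruthNetwork(weights=w, labels=list(net.labels))


def generate_session_sequence(net0: GroundTruthNetwork, drift: DriftModel,
                              n_days: int, per_day_bins: int, seed: int,
                              drive_rate: float = 5e-3):
    """Multi-day study: day k's network drifts from day k-1's, raster per day.

    Returns a list of (GroundTruthNetwork, EventRaster), one entry per day.
    The resampling pool is the day-1 nonzero weight set, so the marginal
    weight distribution is preserved while link identities mix.
    """
    if n_days < 2:
        raise ParameterError("need n_days >= 2")
    rng = np.random.default_rng(seed)
    pool = net0.weights[net0.weights > 0].copy()
    out = []
    net = net0
    for day in range(n_days):
        if day > 0:
            net = _drift_network(net, drift, pool, rng)
        raster = simulate_cascades_on_network(
            net, drive_rate=drive_rate, n_bins=per_day_bins,
            seed=int(rng.integers(0, 2**31 - 1)))
        out.append((net, raster))
    return out


# ------------------------------------------------------------------ controls

def shuffle_raster_times(raster: EventRaster, seed: int = 0) -> EventRaster:
    """Reassign every event an independent uniform random bin.

    Per-electrode event counts are preserved exactly; all spatial and
    temporal correlations are destroyed.
    """
    if raster.total_events == 0:
        raise ParameterError("cannot shuffle an empty raster")
    rng = np.random.default_rng(seed)
    counts = np.zeros_like(raster.counts)
    totals = raster.counts.sum(axis=1)
    for e in range(raster.n_electrodes):
        if totals[e] == 0:
            continue
        b = rng.integers(0, raster.n_bins, int(totals[e]))
        np.add.at(counts[e], b, 1)
    return EventRaster(counts=counts, dt_ms=raster.dt_ms, t0_ms=raster.t0_ms,
                       electrode_ids=list(raster.electrode_ids))


# -------------------------------------------------- ground-truth topologies

def make_small_world_network(n_nodes: int = 20, k: int = 4,
                             rewire_p: float = 0.1, weight_scale: float = 0.15,
                             weight_sd: float = 0.7, seed: int = 0) -> GroundTruthNetwork:
    """Watts-Strogatz-style weighted digraph for cascade simulations.

    Each undirected lattice/rewired edge yields two directed links with
    independent log-normal weights of median weight_scale, clipped to [0, 1].
    """
    rng = np.random.default_rng(seed)
    g = nx.watts_strogatz_graph(n_nodes, k, rewire_p, seed=int(rng.integers(2**31)))
    w = np.zeros((n_nodes, n_nodes))
    for a, b in g.edges():
        w[a, b] = weight_scale * np.exp(rng.normal(0, weight_sd))
        w[b, a] = weight_scale * np.exp(rng.normal(0, weight_sd))
    np.clip(w, 0.0, 1.0, out=w)
    np.fill_diagonal(w, 0.0)
    return GroundTruthNetwork(weights=w)


def make_integrative_network(n_cliques: int = 6, clique_size: int = 5,
                             strong_range=(0.4, 0.9), weak_range=(0.005, 0.05),
                             inter_density: float = 0.05,
                             seed: int = 0) -> GroundTruthNetwork:
    """Planted integrative topology: strong links inside cliques, weak between.

    Strong links sit inside fully connected modules (their end nodes share
    many neighbors), while sparse weak links bridge modules; link weight is
    therefore positively coupled to link clustering by construction.
    """
    rng = np.random.default_rng(seed)
    n = n_cliques * clique_size
    w = np.zeros((n, n))
    for c in range(n_cliques):
        nodes = np.arange(c * clique_size, (c + 1) * clique_size)
        for a in nodes:
            for b in nodes:
                if a != b:
                    w[a, b] = rng.uniform(*strong_range)
    for a in range(n):
        for b in range(n):
            if a // clique_size != b // clique_size and rng.random() < inter_density:
                w[a, b] = rng.uniform(*weak_range)
    np.fill_diagonal(w, 0.0)
    return GroundTruthNetwork(weights=w)
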