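"""Continuous-signal preprocessing for avalanche analysis.

Takes multichannel local-field-potential-like recordings from raw trace to
event raster: band-pass + notch filtering, artifact excision, per-channel
z-scoring, detection of negative threshold-crossing events (nLFPs), the mean
inter-event interval that sets the avalanche bin width, binning into rasters,
and pairwise-correlation stability summaries across sessions.

Core containers (`SignalRecording`, `EventList`, `EventRaster`) live here and
are shared by the synthesis and analysis modules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from ._stats import OLSTrend, ols_trend

logger = logging.getLogger("avanet")

__all__ = [
    "ParameterError",
    "InsufficientDataError",
    "SignalsEmptyError",
    "ContractError",
    "SignalRecording",
    "EventList",
    "EventRaster",
    "CorrelationSummary",
    "bandpass_and_notch",
    "excise_artifacts",
    "ztransform",
    "detect_nlfps",
    "mean_iei",
    "bin_events",
    "pairwise_correlation_summary",
]


class ParameterError(ValueError):
    """An argument violates an operation's preconditions."""


class InsufficientDataError(ValueError):
    """Too few observations to compute the requested statistic."""


class SignalsEmptyError(ValueError):
    """No usable samples remain after artifact excision."""


class ContractError(ValueError):
    """Input does not satisfy a documented contract (e.g. not z-scored)."""


# ------------------------------------------------------------------ containers

@dataclass
class SignalRecording:
    """Continuous multichannel recording.

    data : channels x samples, in microvolts (or SD units after z-scoring).
    excluded_mask : per-sample boolean, True where artifacts were excised;
        masked samples are ignored by every downstream statistic.
    """

    data: np.ndarray
    fs_hz: float
    channel_ids: list = None
    excluded_mask: np.ndarray = None

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs_hz <= 0:
            raise ParameterError("fs_hz must be positive")
        if self.channel_ids is None:
            self.channel_ids = list(range(self.data.shape[0]))
        if len(self.channel_ids) != self.data.shape[0]:
            raise ParameterError("channel_ids length does not match data rows")
        if self.excluded_mask is None:
            self.excluded_mask = np.zeros(self.data.shape[1], dtype=bool)
        else:
            self.excluded_mask = np.asarray(self.excluded_mask, dtype=bool)
            if self.excluded_mask.shape != (self.data.shape[1],):
                raise ParameterError("excluded_mask must be per-sample")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_ms(self) -> float:
        return self.n_samples / self.fs_hz * 1000.0

    def kept(self) -> np.ndarray:
        """Boolean mask of retained (non-excised) samples."""
        return ~self.excluded_mask


@dataclass
class EventList:
    """Detected events: one row per event (channel_id, time_ms, amplitude_sd)."""

    events: pd.DataFrame
    duration_ms: float = np.nan

    def __post_init__(self):
        required = {"channel_id", "time_ms", "amplitude_sd"}
        if not required.issubset(self.events.columns):
            raise ParameterError(f"event table needs columns {sorted(required)}")

    def __len__(self) -> int:
        return len(self.events)

    @property
    def times_ms(self) -> np.ndarray:
        return self.events["time_ms"].to_numpy(dtype=float)


@dataclass
class EventRaster:
    """Electrode x time-bin count matrix at resolution dt_ms.

    Counts are integers >= 0; multiple events per electrode per bin are
    allowed and all participate in avalanche sizes.
    """

    counts: np.ndarray
    dt_ms: float
    t0_ms: float = 0.0
    electrode_ids: list = None

    def __post_init__(self):
        self.counts = np.atleast_2d(np.asarray(self.counts))
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ParameterError("raster counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if self.dt_ms <= 0:
            raise ParameterError("dt_ms must be positive")
        if (self.counts < 0).any():
            raise ParameterError("raster counts must be nonnegative")
        if self.electrode_ids is None:
            self.electrode_ids = list(range(self.counts.shape[0]))

    @property
    def n_electrodes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]

    @property
    def total_events(self) -> int:
        return int(self.counts.sum())

    def population(self) -> np.ndarray:
        """Per-bin event count summed over electrodes (the population vector)."""
        return self.counts.sum(axis=0)


@dataclass
class CorrelationSummary:
    """Per-session pairwise Pearson correlations and their cross-session trend."""

    r_matrices: list
    r_values: list            # off-diagonal coefficients per session
    mean_r: np.ndarray        # <R> per session
    days: np.ndarray
    trend: OLSTrend = None    # slope of <R> vs day; None for a single session


# ------------------------------------------------------------------ operations

def bandpass_and_notch(raw: SignalRecording, low_hz: float = 1.0,
                       high_hz: float = 100.0, notch_hz: float = 60.0,
                       notch_q: float = 30.0) -> SignalRecording:
    """Sixth-order Butterworth band-pass plus a narrow notch, zero phase.

    Zero-phase (forward-backward) filtering is used so event peak times are
    not lag-shifted; those times define avalanche timing downstream.
    """
    if raw.fs_hz < 2.0 * high_hz:
        raise ParameterError(
            f"sampling rate {raw.fs_hz} Hz too low for band edge {high_hz} Hz")
    sos = sps.butter(3, [low_hz, high_hz], btype="bandpass", fs=raw.fs_hz,
                     output="sos")
    out = sps.sosfiltfilt(sos, raw.data, axis=1)
    if notch_hz is not None and notch_hz < raw.fs_hz / 2:
        b, a = sps.iirnotch(notch_hz, notch_q, fs=raw.fs_hz)
        out = sps.filtfilt(b, a, out, axis=1)
    return replace(raw, data=out, excluded_mask=raw.excluded_mask.copy())


def excise_artifacts(sig: SignalRecording, sd_threshold: float = 7.0,
                     pad_s: float = 0.25) -> SignalRecording:
    """Mask samples exceeding sd_threshold per-channel SDs, padded by pad_s.

    A sample is flagged when any channel exceeds the threshold (in units of
    that channel's SD over currently retained samples); the mask is the union
    across channels plus +/- pad_s seconds around every flagged sample.
    """
    kept = sig.kept()
    if not kept.any():
        raise SignalsEmptyError("recording is already fully excised")
    sd = sig.data[:, kept].std(axis=1, ddof=0)
    mean = sig.data[:, kept].mean(axis=1)
    sd = np.where(sd > 0, sd, 1.0)
    z = np.abs(sig.data - mean[:, None]) / sd[:, None]
    bad = (z > sd_threshold).any(axis=0)
    pad = int(round(pad_s * sig.fs_hz))
    if bad.any() and pad > 0:
        from scipy.ndimage import binary_dilation
        bad = binary_dilation(bad, structure=np.ones(2 * pad + 1, dtype=bool))
    mask = sig.excluded_mask | bad
    if mask.all():
        raise SignalsEmptyError("artifact excision removed the whole recording")
    frac = bad.mean()
    if frac > 0:
        logger.info("excised %.2f%% of samples as artifacts", 100 * frac)
    return replace(sig, data=sig.data.copy(), excluded_mask=mask)


def ztransform(sig: SignalRecording) -> SignalRecording:
    """Per-channel z-score over non-excised samples.

    Channels with zero variance on the retained samples are dropped (and
    logged), mirroring the exclusion of dead electrodes.
    """
    kept = sig.kept()
    if not kept.any():
        raise SignalsEmptyError("no retained samples to estimate z-scale")
    mean = sig.data[:, kept].mean(axis=1)
    sd = sig.data[:, kept].std(axis=1, ddof=0)
    good = sd > 0
    if not good.all():
        dropped = [cid for cid, g in zip(sig.channel_ids, good) if not g]
        logger.warning("dropping zero-variance channels: %s", dropped)
    if not good.any():
        raise SignalsEmptyError("all channels have zero variance")
    data = (sig.data[good] - mean[good, None]) / sd[good, None]
    ids = [cid for cid, g in zip(sig.channel_ids, good) if g]
    return SignalRecording(data=data, fs_hz=sig.fs_hz, channel_ids=ids,
                           excluded_mask=sig.excluded_mask.copy())


def _check_zscored(sig: SignalRecording, tol: float = 0.25) -> None:
    kept = sig.kept()
    mean = sig.data[:, kept].mean(axis=1)
    sd = sig.data[:, kept].std(axis=1, ddof=0)
    # silent channels (sd ~ 0, mean ~ 0) are trivially fine: no excursions
    active = sd > tol
    if np.abs(mean).max() > tol or (active & (np.abs(sd - 1.0) > tol)).any():
        raise ContractError("detect_nlfps requires a z-scored recording "
                            "(per-channel mean ~0, SD ~1 on retained samples)")


def detect_nlfps(sig: SignalRecording, threshold_sd: float = -2.0,
                 resolution_ms: float = 0.5) -> EventList:
    """Detect negative threshold-crossing events (nLFPs).

    One event per contiguous sub-threshold excursion, placed at the
    excursion's most negative sample; peak times are quantized to
    resolution_ms. Events whose peak falls inside the excluded mask are
    discarded. Requires a z-scored input.
    """
    _check_zscored(sig)
    rows = []
    mask = sig.excluded_mask
    for cid, trace in zip(sig.channel_ids, sig.data):
        below = trace <= threshold_sd
        if not below.any():
            continue
        d = np.diff(np.r_[False, below, False].astype(np.int8))
        starts, stops = np.flatnonzero(d == 1), np.flatnonzero(d == -1)
        for a, b in zip(starts, stops):
            peak = a + int(np.argmin(trace[a:b]))
            if mask[peak]:
                continue
            t_ms = peak / sig.fs_hz * 1000.0
            t_ms = round(t_ms / resolution_ms) * resolution_ms
            rows.append((cid, t_ms, float(trace[peak])))
    df = pd.DataFrame(rows, columns=["channel_id", "time_ms", "amplitude_sd"])
    df = df.sort_values(["time_ms", "channel_id"], kind="stable",
                        ignore_index=True)
    return EventList(events=df, duration_ms=sig.duration_ms)


def mean_iei(events: EventList) -> float:
    """Mean inter-event interval (ms) of events pooled over all channels."""
    t = np.sort(events.times_ms)
    if t.size < 2:
        raise InsufficientDataError("need at least 2 events for <IEI>")
    return float(np.diff(t).mean())


def bin_events(events: EventList, dt_ms: float, t0_ms: float = 0.0,
               n_bins: int = None, electrode_ids: list = None) -> EventRaster:
    """Bin event peak times into an electrode x bin count raster.

    Half-open convention: an event at time t lands in bin floor((t-t0)/dt);
    a peak exactly on a boundary is assigned to the later bin. Total counts
    are conserved.
    """
    if dt_ms <= 0:
        raise ParameterError("dt_ms must be positive")
    df = events.events
    if electrode_ids is None:
        electrode_ids = sorted(df["channel_id"].unique()) if len(df) else []
    row_of = {cid: i for i, cid in enumerate(electrode_ids)}
    if len(df):
        bins = np.floor((df["time_ms"].to_numpy() - t0_ms) / dt_ms).astype(int)
        if (bins < 0).any():
            raise ParameterError("events before t0_ms")
        if n_bins is None:
            n_bins = int(bins.max()) + 1
        elif (bins >= n_bins).any():
            raise ParameterError("events beyond the requested raster span")
        rows = df["channel_id"].map(row_of).to_numpy()
    else:
        n_bins = n_bins or 1
        rows = bins = np.array([], dtype=int)
    counts = np.zeros((len(electrode_ids), n_bins), dtype=np.int64)
    np.add.at(counts, (rows, bins), 1)
    return EventRaster(counts=counts, dt_ms=dt_ms, t0_ms=t0_ms,
                       electrode_ids=list(electrode_ids))


def pairwise_correlation_summary(sessions: list, days=None) -> CorrelationSummary:
    """Pairwise Pearson R per session and the cross-session trend of <R>.

    R is computed on non-excised samples only. With >= 2 sessions, <R> is
    regressed on recording day (OLS, 95% confidence limits on the slope).
    """
    if len(sessions) < 1:
        raise ParameterError("need at least one session")
    if days is None:
        days = np.arange(1, len(sessions) + 1)
    days = np.asarray(days, dtype=float)
    mats, vals, means = [], [], []
    for sig in sessions:
        if sig.n_channels < 2:
            raise ParameterError("pairwise correlation needs >= 2 channels")
        kept = sig.kept()
        if kept.sum() < 3:
            raise InsufficientDataError("too few retained samples")
        r = np.corrcoef(sig.data[:, kept])
        iu = np.triu_indices(sig.n_channels, k=1)
        mats.append(r)
        vals.append(r[iu])
        means.append(float(r[iu].mean()))
    trend = ols_trend(days, means) if len(sessions) >= 2 else None
    return CorrelationSummary(r_matrices=mats, r_values=vals,
                              mean_r=np.asarray(means), days=days, trend=trend)
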