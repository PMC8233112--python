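"""Study orchestration and standard-format I/O.

Runs the full multi-session analysis — preprocess, avalanche scaling, shape
collapse, network reconstruction, integrative metrics, entropy of mixing —
over a list of sessions, producing a JSON-serializable study report with
per-session estimates and cross-session stability regressions.

File formats: signals and rasters in HDF5, rasters and event lists also as
tabular text, networks as weighted edge-list text, reports as JSON.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from . import avalanche as av
from . import collapse as col
from . import integrative as intg
from . import mixing as mix
from . import netrecon as nr
from . import preprocess as pp
from .preprocess import (EventList, EventRaster, ParameterError,
                         SignalRecording)

logger = logging.getLogger("avanet")

__all__ = [
    "StudyConfig",
    "run_study",
    "validate_report",
    "write_raster_text", "read_raster_text",
    "write_raster_h5", "read_raster_h5",
    "write_signal_h5", "read_signal_h5",
    "write_events_text", "read_events_text",
    "write_edgelist", "read_edgelist",
    "write_report_json", "read_report_json",
]


# ------------------------------------------------------------------------ I/O

def write_raster_text(raster: EventRaster, path) -> None:
    """Tabular text raster: electrode_id, bin_index, count (nonzero only)."""
    i, b = np.nonzero(raster.counts)
    df = pd.DataFrame({
        "electrode_id": [raster.electrode_ids[k] for k in i],
        "bin_index": b,
        "count": raster.counts[i, b],
    })
    with open(path, "w") as fh:
        fh.write(f"# dt_ms={raster.dt_ms} t0_ms={raster.t0_ms} "
                 f"n_electrodes={raster.n_electrodes} n_bins={raster.n_bins}\n")
        df.to_csv(fh, index=False)


def read_raster_text(path) -> EventRaster:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ParameterError(f"{path}: missing raster header line")
        meta = dict(tok.split("=") for tok in header[1:].split())
        df = pd.read_csv(fh)
    n_e, n_b = int(meta["n_electrodes"]), int(meta["n_bins"])
    counts = np.zeros((n_e, n_b), dtype=np.int64)
    ids = sorted(df["electrode_id"].unique()) if len(df) else list(range(n_e))
    if len(ids) < n_e:  # electrodes with no events still occupy rows
        ids = list(range(n_e))
    row = {cid: k for k, cid in enumerate(ids)}
    for cid, b, c in df.itertuples(index=False):
        counts[row[cid], int(b)] = int(c)
    return EventRaster(counts=counts, dt_ms=float(meta["dt_ms"]),
                       t0_ms=float(meta["t0_ms"]), electrode_ids=ids)


def write_raster_h5(raster: EventRaster, path) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("counts", data=raster.counts, compression="gzip")
        d.attrs["dt_ms"] = raster.dt_ms
        d.attrs["t0_ms"] = raster.t0_ms
        f.create_dataset("electrodes",
                         data=np.asarray([str(e) for e in raster.electrode_ids],
                                         dtype="S"))


def read_raster_h5(path) -> EventRaster:
    with h5py.File(path, "r") as f:
        counts = f["counts"][...]
        dt = float(f["counts"].attrs["dt_ms"])
        t0 = float(f["counts"].attrs["t0_ms"])
        ids = [e.decode() for e in f["electrodes"][...]]
    try:
        ids = [int(e) for e in ids]
    except ValueError:
        pass
    return EventRaster(counts=counts, dt_ms=dt, t0_ms=t0, electrode_ids=ids)


def write_signal_h5(sig: SignalRecording, path) -> None:
    """HDF5 signal container: /data, /fs, /channels, /mask."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=sig.data, compression="gzip")
        f.create_dataset("fs", data=sig.fs_hz)
        f.create_dataset("channels",
                         data=np.asarray([str(c) for c in sig.channel_ids],
                                         dtype="S"))
        f.create_dataset("mask", data=sig.excluded_mask)


def read_signal_h5(path) -> SignalRecording:
    with h5py.File(path, "r") as f:
        data = f["data"][...]
        fs = float(f["fs"][()])
        ids = [c.decode() for c in f["channels"][...]]
        mask = f["mask"][...].astype(bool)
    try:
        ids = [int(c) for c in ids]
    except ValueError:
        pass
    return SignalRecording(data=data, fs_hz=fs, channel_ids=ids,
                           excluded_mask=mask)


def write_events_text(events: EventList, path) -> None:
    events.events.to_csv(path, index=False)


def read_events_text(path) -> EventList:
    return EventList(events=pd.read_csv(path))


def write_edgelist(graph: nr.WeightedDigraph, path) -> None:
    """Weighted edge list text: src dst weight, one nonzero link per line."""
    i, j, w = graph.link_arrays()
    with open(path, "w") as fh:
        fh.write("src\tdst\tweight\n")
        for a, b, x in zip(i, j, w):
            fh.write(f"{graph.node_ids[a]}\t{graph.node_ids[b]}\t{x:.10g}\n")


def read_edgelist(path) -> nr.WeightedDigraph:
    df = pd.read_csv(path, sep="\t")
    if len(df) == 0:
        raise ParameterError(f"{path}: empty edge list")
    nodes = sorted(set(df["src"]) | set(df["dst"]))
    idx = {v: k for k, v in enumerate(nodes)}
    w = np.zeros((len(nodes), len(nodes)))
    for rec in df.itertuples(index=False):
        if rec.src == rec.dst:
            raise ParameterError(
                f"{path}: self-loop on record ({rec.src} -> {rec.dst})")
        w[idx[rec.src], idx[rec.dst]] = rec.weight
    return nr.WeightedDigraph(weights=w, node_ids=nodes)


REPORT_SCHEMA = {
    "sessions": list,
    "stability": dict,
    "mixing": dict,
    "config": dict,
}

_SESSION_KEYS = {"day", "status"}


def validate_report(report: dict) -> None:
    """Check a study report against the shipped key/type schema."""
    for key, typ in REPORT_SCHEMA.items():
        if key not in report:
            raise ParameterError(f"report missing required key '{key}'")
        if not isinstance(report[key], typ):
            raise ParameterError(f"report key '{key}' must be {typ.__name__}")
    for s in report["sessions"]:
        missing = _SESSION_KEYS - set(s)
        if missing:
            raise ParameterError(f"session record missing {sorted(missing)}")


def write_report_json(report: dict, path) -> None:
    validate_report(report)
    with open(path, "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_report_json(path) -> dict:
    with open(path) as fh:
        report = json.load(fh)
    validate_report(report)
    return report


# ---------------------------------------------------------------- the study

@dataclass
class StudyConfig:
    """Configuration of a full multi-session study.

    sessions: list of (day_index, session) where session is a
    SignalRecording, an EventRaster, or a path to a signal/raster file
    (.h5 signals via read_signal_h5, .txt/.csv rasters via read_raster_text).
    dt_policy: "iei" (bin width = <IEI> rounded to the nearest 0.5 ms) or a
    fixed bin width in ms.
    """

    sessions: list
    dt_policy: object = "iei"
    nlfp_threshold_sd: float = -2.0
    artifact_sd: float = 7.0
    artifact_pad_s: float = 0.25
    collapse_l_set: tuple = (3, 4, 5)
    recon_window_ms: float = None
    graph_density: float = 0.40
    mixing: mix.MixingConfig = field(default_factory=mix.MixingConfig)
    n_rand: int = 10
    n_mc: int = 100_000
    seed: int = 0

    def __post_init__(self):
        days = [d for d, _ in self.sessions]
        if len(days) == 0:
            raise ParameterError("empty study")
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ParameterError("session days must be strictly increasing")


def _load_session(obj):
    if isinstance(obj, (SignalRecording, EventRaster)):
        return obj
    s = str(obj)
    if s.endswith((".h5", ".hdf5")):
        try:
            return read_signal_h5(s)
        except KeyError:
            return read_raster_h5(s)
    return read_raster_text(s)


def _session_raster(obj, cfg: StudyConfig):
    """Preprocess a signal session down to an event raster; rasters pass through."""
    obj = _load_session(obj)
    if isinstance(obj, EventRaster):
        iei = av.raster_mean_iei(obj)
        return obj, None, iei
    sig = pp.bandpass_and_notch(obj)
    sig = pp.excise_artifacts(sig, sd_threshold=cfg.artifact_sd,
                              pad_s=cfg.artifact_pad_s)
    sig = pp.ztransform(sig)
    events = pp.detect_nlfps(sig, threshold_sd=cfg.nlfp_threshold_sd)
    iei = pp.mean_iei(events)
    if cfg.dt_policy == "iei":
        dt = max(0.5, round(iei / 0.5) * 0.5)  # nearest 0.5 ms multiple
    else:
        dt = float(cfg.dt_policy)
    n_bins = int(np.ceil(sig.duration_ms / dt))
    raster = pp.bin_events(events, dt_ms=dt, n_bins=n_bins,
                           electrode_ids=sig.channel_ids)
    return raster, sig, iei


def run_study(cfg: StudyConfig) -> dict:
    """Execute every analysis stage per session plus cross-session statistics.

    Per-session failures are quarantined (recorded with their error message)
    and the study-level run continues. Fully reproducible from
    (sessions, config, seed).
    """
    ss = np.random.SeedSequence(cfg.seed)
    session_seeds = ss.spawn(len(cfg.sessions))
    records, signals, signal_days, graphs, graph_days = [], [], [], [], []
    for (day, obj), child in zip(cfg.sessions, session_seeds):
        rec = {"day": day, "status": "ok"}
        try:
            raster, sig, iei = _session_raster(obj, cfg)
            rec["iei_ms"] = iei
            if sig is not None:
                signals.append(sig)
                signal_days.append(day)
            avs = av.segment_avalanches(raster)
            fit = av.fit_size_distribution([a.size for a in avs])
            rec.update(alpha=fit.alpha, llr_exp=fit.llr_exp, p_exp=fit.p_exp,
                       llr_logn=fit.llr_logn, p_logn=fit.p_logn,
                       n_avalanches=len(avs))
            pset = col.mean_profiles(avs, L_set=cfg.collapse_l_set)
            cres = col.collapse_profiles(pset)
            rec.update(chi=cres.chi, delta_f=cres.delta_f,
                       collapse_failed=cres.failed)
            g = nr.nc_reconstruct(raster, window_ms=cfg.recon_window_ms)
            # graph metrics run on the sparsified network; mixing keeps the
            # full weighted reconstruction
            g_sparse = nr.threshold_graph(g, density=cfg.graph_density)
            prof = intg.excess_clustering_profile(
                g_sparse, n_rand=cfg.n_rand,
                seed=int(child.generate_state(1)[0]))
            rec["r_cl"] = prof.r_cl
            graphs.append(g)
            graph_days.append(day)
        except Exception as exc:  # quarantine the session, keep the study
            logger.warning("session day %s failed: %s", day, exc)
            rec["status"] = "failed"
            rec["error"] = f"{type(exc).__name__}: {exc}"
        records.append(rec)

    stability = {}
    ok = [r for r in records if r["status"] == "ok"]
    for key in ("alpha", "chi", "r_cl"):
        vals = [(r["day"], r[key]) for r in ok if np.isfinite(r.get(key, np.nan))]
        if len(vals) >= 2:
            days_, v = zip(*vals)
            t = av.ols_trend(days_, v)
            stability[key] = {"slope": t.slope, "ci95": [t.ci_low, t.ci_high]}
    if len(signals) >= 2:
        summ = pp.pairwise_correlation_summary(signals, days=signal_days)
        stability["mean_r"] = {"slope": summ.trend.slope,
                               "ci95": [summ.trend.ci_low, summ.trend.ci_high]}
        for rec2, m in zip([r for r in records if r["status"] == "ok"], summ.mean_r):
            rec2["mean_r"] = float(m)

    mixing_out = {}
    pruning_out = {}
    if len(graphs) >= 2:
        try:
            traj = mix.mixing_trajectory(graphs, graph_days, cfg.mixing,
                                         n_mc=cfg.n_mc,
                                         seed=int(ss.generate_state(1)[0]))
            mixing_out = {
                "day": list(map(float, traj.day)),
                "H_M": traj.h_m.tolist(),
                "sem": traj.sem.tolist(),
                "baseline": traj.h_m_randomized.tolist(),
                "max": traj.h_m_max,
                "slope": traj.trend_slope,
                "p": traj.trend_p,
            }
        except Exception as exc:
            logger.warning("mixing stage skipped: %s", exc)
            mixing_out = {"skipped": f"{type(exc).__name__}: {exc}"}
        try:
            curve = intg.pruning_analysis(
                nr.threshold_graph(graphs[0], density=cfg.graph_density),
                n_rand=cfg.n_rand, seed=cfg.seed)
            pruning_out = {
                "fraction_removed": curve.fraction_removed.tolist(),
                "delta_c_bottom": curve.delta_c_bottom.tolist(),
                "delta_c_top": curve.delta_c_top.tolist(),
                "truncated": curve.truncated,
            }
        except Exception as exc:
            logger.warning("pruning stage skipped: %s", exc)
            pruning_out = {"skipped": f"{type(exc).__name__}: {exc}"}

    report = {
        "sessions": _jsonable(records),
        "stability": _jsonable(stability),
        "mixing": _jsonable(mixing_out),
        "pruning": _jsonable(pruning_out),
        "config": {
            "dt_policy": str(cfg.dt_policy),
            "nlfp_threshold_sd": cfg.nlfp_threshold_sd,
            "collapse_l_set": list(cfg.collapse_l_set),
            "mixing_half": cfg.mixing.half,
            "seed": cfg.seed,
        },
    }
    validate_report(report)
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    if isinstance(obj, (np.floating, float)):
        # 12 significant digits: reports stay byte-identical across reruns
        # (summation order of vectorized reductions can wobble the last ulp)
        x = float(obj)
        return float(f"{x:.12g}") if np.isfinite(x) else x
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    return obj
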