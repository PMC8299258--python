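"""End-to-end pipeline stages: simulate -> analyze -> classify -> dfs -> report.

Each stage is a plain function over files or in-memory objects; the CLI is
a thin wrapper.  Every run writes a resolved-configuration snapshot
(version, config hash, master seed) next to its outputs, and reruns with
the same seeds are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .curve_analysis import SelectionCriteria, analyze_curve
from .dfs_kinetics import bin_by_loading_rate, dfs_from_bins
from .mechanics import SegmentTable, WlcParameters
from .pathway_inference import build_default_pathways, classify_event, tabulate
from .synthetic import CONSTRUCTS, build_construct, simulate_dataset

log = logging.getLogger("mtforce")

__all__ = [
    "resolve_config",
    "stage_simulate",
    "stage_analyze",
    "stage_classify",
    "stage_dfs",
    "stage_report",
    "run_pipeline",
]

DEFAULT_CONFIG = {
    "construct": "Zn-aMT",
    "n_curves": 50,
    "seed": 1,
    "simulation": {},  # overrides for SimulationConfig fields
    "criteria": {},  # overrides for SelectionCriteria fields
    "wlc": {},  # overrides for WlcParameters fields
    "classify": {
        "one_step_window": [10.0, 13.0],
        "pair_tolerance": 0.7,
        "direction_resolution": 0.5,
        "pathway_source": "measured",
    },
    "dfs": {
        "n_bins": 5,
        "rate_range": [1e3, 3e5],
        # pulling speeds (nm/s) of the dedicated dynamic-force-spectroscopy
        # sweep in run_pipeline; loading rate only spans decades when the
        # speed does
        "speeds": [300.0, 1000.0, 3000.0, 10000.0, 30000.0],
        "n_curves_per_speed": 40,
    },
}


def resolve_config(overrides: dict | None = None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, value in (overrides or {}).items():
        if isinstance(value, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(value)
        else:
            cfg[key] = value
    if cfg["construct"] not in CONSTRUCTS:
        raise ValueError(
            f"unknown construct {cfg['construct']!r}; choose from {CONSTRUCTS}"
        )
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()
    ).hexdigest()[:12]


def _write_snapshot(cfg: dict, out_dir: Path) -> None:
    from . import __version__

    snapshot = {
        "version": __version__,
        "config_hash": config_hash(cfg),
        "config": cfg,
    }
    (out_dir / "resolved_config.json").write_text(
        json.dumps(snapshot, indent=1, sort_keys=True) + "\n"
    )


def _criteria(cfg: dict) -> SelectionCriteria:
    kw = dict(cfg.get("criteria", {}))
    if "marker_dlc_window" in kw:
        kw["marker_dlc_window"] = tuple(kw["marker_dlc_window"])
    return SelectionCriteria(**kw)


def _wlc(cfg: dict) -> WlcParameters:
    return WlcParameters(**cfg.get("wlc", {}))


def stage_simulate(cfg: dict, out_dir) -> dict:
    """Simulate a dataset of the configured construct into ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sim_kwargs = dict(cfg.get("simulation", {}))
    if cfg.get("wlc"):
        sim_kwargs["wlc"] = _wlc(cfg)
    config = build_construct(cfg["construct"], sim_kwargs)
    manifest = simulate_dataset(config, cfg["n_curves"], cfg["seed"], out_dir)
    _write_snapshot(cfg, out_dir)
    log.info("simulated %d curves of %s", cfg["n_curves"], cfg["construct"])
    return manifest


def stage_analyze(cfg: dict, data_dir, out_dir) -> pd.DataFrame:
    """Analyze every curve of a dataset; write the events table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    criteria = _criteria(cfg)
    wlc = _wlc(cfg)
    results = [
        analyze_curve(curve, criteria, wlc) for curve in mio.read_dataset(data_dir)
    ]
    df = mio.events_dataframe(results)
    n_acc = sum(r.accepted for r in results)
    log.info(
        "curves read: %d; accepted: %d; events: %d",
        len(results), n_acc, len(df),
    )
    mio.write_events_tsv(df, out_dir / "events.tsv")
    _write_snapshot(cfg, out_dir)
    return df


def classify_events(cfg: dict, events: pd.DataFrame):
    """Group target events per accepted curve and classify each molecule."""
    ccfg = cfg["classify"]
    pathways = build_default_pathways(
        SegmentTable.default(), source=ccfg.get("pathway_source", "measured")
    )
    assignments = []
    accepted = events[events["accepted"]]
    for _cid, grp in accepted.groupby("curve_id", sort=True):
        target = grp[grp["attribution"] == "target"].sort_values("peak_index")
        dlcs = [d for d in target["dlc_nm"].tolist() if np.isfinite(d)]
        if not dlcs:
            continue
        assignments.append(
            classify_event(
                dlcs,
                pathways,
                one_step_window=tuple(ccfg["one_step_window"]),
                pair_tolerance=ccfg["pair_tolerance"],
                direction_resolution=ccfg["direction_resolution"],
            )
        )
    return assignments, pathways


def stage_classify(cfg: dict, events_path, out_dir) -> dict:
    """Classify accepted molecules; write the pathway-statistics tables."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    events = mio.read_events_tsv(events_path)
    assignments, pathways = classify_events(cfg, events)
    if not assignments:
        raise ValueError("no accepted target events to classify")
    stats = tabulate(assignments)
    stats.to_table(pathways).to_csv(out_dir / "pathway_stats.tsv", sep="\t",
                                    index=False)
    for name, hist in (
        ("two_step_dlc_hist.tsv", stats.two_step_hist),
        ("one_step_dlc_hist.tsv", stats.one_step_hist),
    ):
        if hist is not None:
            pd.DataFrame({"bin_left_nm": hist[0], "count": hist[1]}).to_csv(
                out_dir / name, sep="\t", index=False
            )
    summary = {
        "n_molecules": stats.n_total,
        "n_assigned": stats.n_assigned,
        "one_step_fraction": stats.frequencies.get("one-step"),
        "c_terminal_fraction": stats.c_terminal_fraction,
        "counts": stats.counts,
    }
    (out_dir / "classification.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True) + "\n"
    )
    _write_snapshot(cfg, out_dir)
    log.info("classified %d molecules (%d assigned)", stats.n_total,
             stats.n_assigned)
    return summary


def stage_dfs(cfg: dict, events_path, out_dir) -> dict:
    """Bell-Evans fit over the target events' (force, loading rate) pairs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    events = mio.read_events_tsv(events_path)
    if {"attribution", "accepted"}.issubset(events.columns):
        sel = events[(events["attribution"] == "target") & events["accepted"]]
    else:  # bare force/rate table
        sel = events
    sel = sel.dropna(subset=["rupture_force_pN", "loading_rate_pN_s"])
    dcfg = cfg["dfs"]
    bins, n_excluded = bin_by_loading_rate(
        sel["rupture_force_pN"], sel["loading_rate_pN_s"],
        n_bins=dcfg["n_bins"], rate_range=tuple(dcfg["rate_range"]),
    )
    result: dict = {"n_events": int(len(sel)), "n_excluded": n_excluded}
    try:
        fit = dfs_from_bins(bins)
        result.update(
            {k: getattr(fit, k) for k in
             ("k_off", "delta_x", "k_off_geom_se", "delta_x_se", "slope",
              "intercept", "n_bins")}
        )
    except ValueError as exc:
        result["error"] = str(exc)
        log.warning("DFS fit not possible: %s", exc)
    (out_dir / "dfs_fit.json").write_text(
        json.dumps(result, indent=1, sort_keys=True) + "\n"
    )
    _write_snapshot(cfg, out_dir)
    return result


def build_dfs_dataset(cfg: dict, out_path=None) -> pd.DataFrame:
    """Simulate a multi-speed sweep and collect one-step rupture events.

    Cluster-rupture kinetics are read off the force vs loading-rate trend,
    which requires pulling at several speeds; one-step events are used, as
    two-step intermediates rupture from a different starting state.
    Returns (and optionally writes) a (rupture_force_pN, loading_rate_pN_s)
    table ready for :func:`stage_dfs`.
    """
    dcfg = cfg["dfs"]
    criteria = _criteria(cfg)
    wlc = _wlc(cfg)
    lo, hi = cfg["classify"]["one_step_window"]
    rows = []
    for i, speed in enumerate(dcfg["speeds"]):
        sim_kwargs = dict(cfg.get("simulation", {}))
        sim_kwargs["pulling_speed"] = float(speed)
        if cfg.get("wlc"):
            sim_kwargs["wlc"] = wlc
        config = build_construct(cfg["construct"], sim_kwargs)
        results = simulate_dataset(
            config, dcfg["n_curves_per_speed"], cfg["seed"] + 7919 * (i + 1)
        )
        for curve, _truth in results:
            res = analyze_curve(curve, criteria, wlc)
            if not res.accepted or res.target_event is None:
                continue
            ev = res.target_event
            if len(ev.dlc_list) != 1 or not lo <= ev.dlc_list[0] <= hi:
                continue
            rate = ev.loading_rates[0]
            if rate is None or rate <= 0:
                continue
            rows.append(
                {
                    "rupture_force_pN": round(ev.forces[0], 3),
                    "loading_rate_pN_s": round(rate, 2),
                    "pulling_speed_nm_s": speed,
                }
            )
    df = pd.DataFrame(rows)
    if out_path is not None:
        df.to_csv(out_path, sep="\t", index=False)
    return df


def stage_report(cfg: dict, run_dir) -> dict:
    """Aggregate the per-stage outputs of a run directory into report.json."""
    run_dir = Path(run_dir)
    report: dict = {"config_hash": config_hash(cfg), "seed": cfg["seed"]}
    from . import __version__

    report["version"] = __version__
    for name in ("classification", "dfs_fit"):
        p = run_dir / f"{name}.json"
        if p.exists():
            report[name] = json.loads(p.read_text())
    events_path = run_dir / "events.tsv"
    if events_path.exists():
        events = mio.read_events_tsv(events_path)
        report["n_events"] = int(len(events))
        report["n_curves"] = int(events["curve_id"].nunique())
        report["n_accepted_curves"] = int(
            events[events["accepted"]]["curve_id"].nunique()
        )
    (run_dir / "report.json").write_text(
        json.dumps(report, indent=1, sort_keys=True) + "\n"
    )
    return report


def run_pipeline(cfg: dict, out_dir) -> dict:
    """Convenience chain: simulate, analyze, classify, dfs, report.

    The classification dataset is simulated at the default speed; the
    Bell-Evans fit uses a dedicated multi-speed sweep (single-speed data
    spans too narrow a loading-rate range to constrain the line).
    """
    out_dir = Path(out_dir)
    data_dir = out_dir / "data"
    stage_simulate(cfg, data_dir)
    stage_analyze(cfg, data_dir, out_dir)
    stage_classify(cfg, out_dir / "events.tsv", out_dir)
    if cfg["dfs"].get("speeds"):
        build_dfs_dataset(cfg, out_dir / "dfs_events.tsv")
        stage_dfs(cfg, out_dir / "dfs_events.tsv", out_dir)
    else:
        stage_dfs(cfg, out_dir / "events.tsv", out_dir)
    return stage_report(cfg, out_dir)
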