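"""Orchestration: simulation -> tracking -> kinetics -> statistics.

Each stage reads and writes plain files (multi-page TIFF movies with a JSON
schedule sidecar, CSV traces/truth/events, JSON summaries) plus a manifest
recording the full config, seed and package versions, so any run can be
reproduced byte-for-byte from its manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .kinetics import (EventRecord, apply_leaky_rule, classify_outcome,
                       colocalize, detect_docking, detect_efflux_onset,
                       estimate_diameter, estimate_flow_rate, events_table)
from .popstats import (fit_exponential_lag, fit_gaussian_rates,
                       insertion_probability_by_size, mechanosensitivity_split)
from .simulate import (AcquisitionSchedule, Movie, NoiseParams, PORE_CHANNEL,
                       acquisition_schedule, default_scenarios,
                       events_to_frame, render_movie,
                       sample_event_stream, sample_vesicle_population,
                       synthesize_traces)
from .tracking import (correct_drift, detect_spots, estimate_drift,
                       extract_trace, link_tracks)
from .transport import (DEFAULT_PLUGGED_PORE, DEFAULT_PORE, DFITC_40K,
                        DFITC_500K, SRB, classify_translocation)

log = logging.getLogger("poretrace")

__all__ = ["run_simulate", "run_analyze", "run_report", "run_end_to_end"]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(out_dir: Path, config: RunConfig, stage: str,
                    outputs: Dict[str, Path]) -> Path:
    cfg_json = json.dumps(config.to_dict(), sort_keys=True, default=str)
    manifest = {
        "stage": stage,
        "seed": config.seed,
        "poretrace_version": __version__,
        "numpy_version": np.__version__,
        "config": json.loads(cfg_json),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "outputs": {k: {"path": str(p.name), "sha256": _sha256(p)}
                    for k, p in outputs.items()},
    }
    path = out_dir / f"manifest_{stage}.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return path


def _schedule_from_config(cfg: RunConfig) -> AcquisitionSchedule:
    s = cfg.simulate.schedule
    return acquisition_schedule(s.n_fov, s.n_channels, s.exposure_s,
                                s.change_time_s, s.n_cycles,
                                tuple(s.channel_labels))


def run_simulate(config: RunConfig, out_dir) -> Dict[str, Path]:
    """Generate a synthetic experiment: traces + truth CSVs, optional movie.

    Deterministic: rerunning with the same config and seed reproduces the
    output files bit for bit (checked via manifest checksums).
    """
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sim = config.simulate
    schedule = _schedule_from_config(config)
    pop = sim.population
    vesicles = sample_vesicle_population(
        pop.n_vesicles, pop.lognormal_mu, pop.lognormal_sigma,
        pop.extent_px, seed=config.seed,
        min_separation=pop.min_separation_px)
    scenarios = default_scenarios()
    if sim.scenario not in scenarios:
        raise ValueError(f"unknown scenario {sim.scenario!r}; "
                         f"choose from {sorted(scenarios)}")
    scenario = scenarios[sim.scenario]
    if sim.scenario_overrides:
        scenario = dataclasses.replace(scenario, **dict(sim.scenario_overrides))
    t_max = schedule.n_cycles * schedule.cycle_period
    events = sample_event_stream(vesicles, scenario, t_max=t_max,
                                 seed=config.seed + 1)
    noise = NoiseParams(enabled=sim.noise.enabled,
                        read_sigma=sim.noise.read_sigma,
                        background=sim.noise.background,
                        poisson=sim.noise.poisson)
    traces = synthesize_traces(vesicles, events, schedule, noise=noise,
                               seed=config.seed + 2)
    truth = events_to_frame(vesicles, events)

    outputs: Dict[str, Path] = {}
    traces_path = out_dir / "traces.csv"
    traces.to_csv(traces_path, index=False)
    outputs["traces"] = traces_path
    truth_path = out_dir / "truth.csv"
    truth.to_csv(truth_path, index=False)
    outputs["truth"] = truth_path

    if sim.render:
        drift = np.tile(np.asarray(sim.drift_px_per_frame, dtype=float),
                        (schedule.n_frames, 1))
        movie, render_truth = render_movie(
            vesicles, traces, schedule, psf_sigma=sim.psf_sigma_px,
            drift=drift, noise=noise, seed=config.seed + 3,
            canvas=int(pop.extent_px))
        movie_path = out_dir / "movie.tif"
        sidecar_path = out_dir / "schedule.json"
        movie.write(movie_path, sidecar_path)
        render_truth_path = out_dir / "render_truth.csv"
        render_truth.to_csv(render_truth_path, index=False)
        outputs.update(movie=movie_path, schedule=sidecar_path,
                       render_truth=render_truth_path)

    outputs["manifest"] = _write_manifest(out_dir, config, "simulate",
                                          outputs)
    log.info("simulate: %d vesicles, %d perforated, %d frames",
             len(vesicles),
             sum(e.outcome == "docked_perforated" for e in events),
             schedule.n_frames)
    return outputs


# --------------------------------------------------------------------------
# Analysis
# --------------------------------------------------------------------------

def _analyze_movie(movie: Movie, config: RunConfig
                   ) -> Tuple[pd.DataFrame, AcquisitionSchedule]:
    """Imaging stack: detect -> link -> drift -> correct -> extract traces.

    Returns a tidy trace table in the same schema the simulator writes
    (vesicle_id anchored on detected vesicle positions).
    """
    ana = config.analyze
    schedule = movie.schedule
    if movie.frames.shape[0] != schedule.n_frames:
        raise ValueError("schedule/movie frame-count mismatch")
    labels = schedule.channel_labels or tuple(
        f"ch{i}" for i in range(schedule.n_channels))
    dye_channels = [c for c in labels if c != PORE_CHANNEL]
    if not dye_channels:
        raise ValueError("schedule lists no dye channel")
    anchor_channel = dye_channels[0]
    fov = 0

    # per-channel detection + linking on the raw series
    locs_by_channel: Dict[str, List[List]] = {}
    for ci, ch in enumerate(labels):
        frames_idx = schedule.frames_for(fov, ci)
        locs = [detect_spots(movie.frames[f], ana.detect_sigma_px,
                             k_mad=ana.detect_k_mad, frame_index=j,
                             channel=ch)
                for j, f in enumerate(frames_idx)]
        locs_by_channel[ch] = locs
    vesicle_tracks = link_tracks(locs_by_channel[anchor_channel],
                                 ana.max_disp_px, ana.max_gap_frames)
    # drop short noise-born tracks before drift estimation (vesicles whose
    # dye effluxes mid-movie still contribute their pre-efflux span)
    min_len = max(5, schedule.n_cycles // 10)
    drift_tracks = [t for t in vesicle_tracks
                    if len(t.localizations) >= min_len]
    log.info("analyze: %d detections -> %d vesicle tracks (%d for drift)",
             sum(len(l) for l in locs_by_channel[anchor_channel]),
             len(vesicle_tracks), len(drift_tracks))

    drift = estimate_drift(drift_tracks, n_frames=schedule.n_cycles)
    cum = drift.cumulative

    # pore tracks for colocalization stage counts
    pore_tracks = []
    if PORE_CHANNEL in labels:
        pore_tracks = link_tracks(locs_by_channel[PORE_CHANNEL],
                                  ana.max_disp_px, ana.max_gap_frames)

    margin = int(math.ceil(max(1.0, np.abs(cum).max() + 1)))
    corrected = {}
    for ci, ch in enumerate(labels):
        frames_idx = schedule.frames_for(fov, ci)
        corrected[ch] = correct_drift(movie.frames[frames_idx], drift,
                                      margin=margin)

    # anchors: every vesicle is tethered from frame 0, so localize on the
    # raw first frame (cumulative drift there is zero by construction) and
    # shift into the corrected, margin-padded canvas
    first = schedule.frames_for(fov, labels.index(anchor_channel))[0]
    anchor_locs = detect_spots(movie.frames[first], ana.detect_sigma_px,
                               k_mad=ana.detect_k_mad)
    anchors = [(l.x + margin, l.y + margin) for l in anchor_locs]

    records = []
    for vid, (ax, ay) in enumerate(anchors):
        for ci, ch in enumerate(labels):
            trace = extract_trace(corrected[ch], ax, ay,
                                  ana.aperture_radius_px,
                                  tuple(ana.annulus_px))
            times = schedule.times_for(fov, ci)
            records.append(pd.DataFrame({
                "vesicle_id": vid, "cycle": np.arange(schedule.n_cycles),
                "frame": schedule.frames_for(fov, ci), "time_s": times,
                "channel": ch, "intensity": trace,
            }))
    traces = pd.concat(records, ignore_index=True)

    # attach colocalization info for the events stage
    pairs, _, lone_pores = colocalize(vesicle_tracks, pore_tracks,
                                      ana.coloc_radius_px) \
        if pore_tracks else ([], vesicle_tracks, [])
    paired_ids = {id(v): pid for pid, (v, p) in enumerate(pairs)}
    traces.attrs["n_pore_tracks"] = len(pore_tracks)
    traces.attrs["n_pairs"] = len(pairs)
    log.info("analyze: %d pore tracks, %d colocalized pairs, %d lone pores",
             len(pore_tracks), len(pairs),
             len(lone_pores) if pore_tracks else 0)
    return traces, schedule


def _events_from_traces(traces: pd.DataFrame, config: RunConfig
                        ) -> Tuple[pd.DataFrame, List[EventRecord], float]:
    """Kinetics stage: per-vesicle tau1 / onset / kf / diameter / outcome."""
    ana = config.analyze
    dye_channels = [c for c in traces["channel"].unique()
                    if c != PORE_CHANNEL]
    if not dye_channels:
        raise ValueError("trace table lists no dye channel")
    dye = dye_channels[0]
    t_end = float(traces["time_s"].max())

    records: List[EventRecord] = []
    initial_intensities = {}
    per_vesicle = dict(tuple(traces.groupby("vesicle_id")))
    for vid, grp in per_vesicle.items():
        dye_grp = grp[grp["channel"] == dye].sort_values("time_s")
        initial_intensities[vid] = float(
            dye_grp["intensity"].head(max(3, ana.baseline_window)).mean())

    i_med = float(np.median(list(initial_intensities.values())))
    for vid, grp in per_vesicle.items():
        dye_grp = grp[grp["channel"] == dye].sort_values("time_s")
        pore_grp = grp[grp["channel"] == PORE_CHANNEL].sort_values("time_s")
        rec = EventRecord(vesicle_track_id=int(vid))
        if len(pore_grp):
            rec.tau1 = detect_docking(
                pore_grp["intensity"].to_numpy(),
                pore_grp["time_s"].to_numpy(),
                baseline_window=ana.baseline_window,
                k_sigma=ana.docking_k_sigma,
                min_persist=ana.docking_min_persist)
        onset = None
        if rec.tau1 is not None:
            onset = detect_efflux_onset(
                dye_grp["intensity"].to_numpy(),
                dye_grp["time_s"].to_numpy(), rec.tau1,
                min_drop=ana.min_drop)
        rec.outcome = classify_outcome(rec.tau1, onset)
        if onset is not None:
            rec.efflux_onset = onset.onset
            rec.tau2 = max(0.0, onset.onset - rec.tau1)
            rec.decay_tau = onset.decay_tau
            kf = estimate_flow_rate(dye_grp["intensity"].to_numpy(),
                                    dye_grp["time_s"].to_numpy(),
                                    onset.onset, plateau=onset.plateau)
            rec.kf = {dye: kf}
        if initial_intensities[vid] > 0:
            rec.d_m_est = estimate_diameter(
                initial_intensities[vid], (i_med, ana.nominal_diameter_nm))
        records.append(rec)

    apply_leaky_rule(records, factor=ana.leaky_factor)
    events = events_table(records)
    kf_col = f"kf_{dye}_counts_per_s"
    if kf_col in events.columns:
        events = events.rename(columns={kf_col: "kf"})
    return events, records, t_end


def summarize_events(events: pd.DataFrame, t_end: float,
                     config: RunConfig) -> dict:
    """Population statistics block of the summary JSON."""
    ana = config.analyze
    n = len(events)
    docked = events[events["outcome"] != "undocked"]
    perforated = events[events["outcome"] == "docked_perforated"]
    summary: dict = {
        "n_vesicles": int(n),
        "n_docked": int(len(docked)),
        "n_perforated": int(len(perforated)),
        "n_excluded_leaky": int((events["outcome"] == "excluded_leaky").sum()),
        "docked_percent": 100.0 * len(docked) / n if n else float("nan"),
        "perforated_percent": (100.0 * len(perforated) / n if n
                               else float("nan")),
    }
    tau1 = docked["tau1_s"].dropna().to_numpy()
    n_undocked = n - len(docked)
    if tau1.size:
        lag = fit_exponential_lag(tau1, np.full(n_undocked, t_end))
        summary["docking_lag"] = dataclasses.asdict(lag)
    kf = perforated["kf"].dropna().to_numpy() if "kf" in perforated else \
        np.array([])
    if kf.size >= 2:
        summary["flow_rate"] = dataclasses.asdict(fit_gaussian_rates(kf))
        split = mechanosensitivity_split(perforated, ana.size_cutoff_nm)
        summary["mechanosensitivity"] = {
            "cutoff_nm": split.cutoff,
            "sufficient": split.sufficient,
            "small": dataclasses.asdict(split.small) if split.small else None,
            "large": dataclasses.asdict(split.large) if split.large else None,
            "ks": dataclasses.asdict(split.ks) if split.ks else None,
        }
    if len(docked):
        prob = insertion_probability_by_size(events,
                                             ana.size_bin_edges_nm)
        summary["insertion_probability_by_size"] = prob.to_dict("records")
    return summary


def run_analyze(config: RunConfig, out_dir,
                movie_path=None, sidecar_path=None,
                traces_path=None) -> Dict[str, Path]:
    """Analysis: (movie ->) traces -> events CSV + summary JSON.

    Accepts either a rendered movie (with its schedule sidecar) or a
    pre-extracted trace table; both produce the identical downstream schema.
    """
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if movie_path is not None:
        if sidecar_path is None:
            raise ValueError("movie analysis requires the schedule sidecar")
        movie = Movie.read(movie_path, sidecar_path)
        traces, _ = _analyze_movie(movie, config)
    elif traces_path is not None:
        traces = pd.read_csv(traces_path)
    else:
        raise ValueError("provide a movie or a trace table")

    events, records, t_end = _events_from_traces(traces, config)
    summary = summarize_events(events, t_end, config)
    outputs: Dict[str, Path] = {}
    events_path = out_dir / "events.csv"
    events.to_csv(events_path, index=False)
    outputs["events"] = events_path
    summary_path = out_dir / "summary.json"
    with open(summary_path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
    outputs["summary"] = summary_path
    if movie_path is not None:
        traces_out = out_dir / "extracted_traces.csv"
        traces.to_csv(traces_out, index=False)
        outputs["traces"] = traces_out
    outputs["manifest"] = _write_manifest(out_dir, config, "analyze", outputs)
    log.info("analyze: %d events (%d perforated)", len(events),
             summary["n_perforated"])
    return outputs


def gating_truth_table() -> pd.DataFrame:
    """Size-selectivity table for the canonical pores and cargoes."""
    rows = []
    for pore_name, pore in (("open", DEFAULT_PORE),
                            ("plugged", DEFAULT_PLUGGED_PORE)):
        for cargo in (SRB, DFITC_40K, DFITC_500K):
            rows.append({"pore": pore_name, "cargo": cargo.name,
                         "verdict": classify_translocation(pore, cargo)})
    return pd.DataFrame(rows)


def run_report(events_path, summary_path, out_dir) -> Dict[str, Path]:
    """Human-readable report + machine-readable metrics JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    events = pd.read_csv(events_path)
    with open(summary_path) as fh:
        summary = json.load(fh)
    gating = gating_truth_table()

    lines = ["# poretrace run report", ""]
    if len(events) == 0:
        lines += ["No events.", ""]
    else:
        lines += [f"Vesicles analyzed: {summary.get('n_vesicles', 0)}",
                  f"Docked: {summary.get('n_docked', 0)} "
                  f"({summary.get('docked_percent', float('nan')):.1f}%)",
                  f"Perforated: {summary.get('n_perforated', 0)} "
                  f"({summary.get('perforated_percent', float('nan')):.1f}%)",
                  f"Excluded (leaky): {summary.get('n_excluded_leaky', 0)}",
                  ""]
        if "docking_lag" in summary:
            d = summary["docking_lag"]
            lines.append(
                f"Docking lag (censored-exponential MLE): {d['mean']:.0f} s "
                f"[{d['ci_low']:.0f}, {d['ci_high']:.0f}] "
                f"(n={d['n_events']}, censored={d['n_censored']})")
        if "flow_rate" in summary:
            fr = summary["flow_rate"]
            lines.append(
                f"Flow rate (Gaussian fit): {fr['mean']:.4g} +/- {fr['sd']:.3g} "
                f"counts/s, 95% CI [{fr['ci_low']:.4g}, {fr['ci_high']:.4g}] "
                f"(n={fr['n']})")
        if "mechanosensitivity" in summary and \
                summary["mechanosensitivity"].get("ks"):
            m = summary["mechanosensitivity"]
            lines.append(
                f"Size split at {m['cutoff_nm']:.0f} nm: "
                f"KS D={m['ks']['statistic']:.3f}, p={m['ks']['pvalue']:.3g}")
        lines.append("")
    lines += ["## Size-selective gating (translocation verdicts)", ""]
    for _, row in gating.iterrows():
        lines.append(f"  {row['pore']:8s} pore x {row['cargo']:12s} -> "
                     f"{row['verdict']}")
    lines.append("")

    report_path = out_dir / "report.txt"
    report_path.write_text("\n".join(lines))
    metrics = {"summary": summary,
               "gating_truth_table": gating.to_dict("records")}
    metrics_path = out_dir / "metrics.json"
    with open(metrics_path, "w") as fh:
        json.dump(metrics, fh, indent=2, sort_keys=True, default=float)
    return {"report": report_path, "metrics": metrics_path}


def run_end_to_end(config: RunConfig, out_dir) -> Dict[str, Path]:
    """simulate -> analyze -> report in one call (movie path when rendered)."""
    out_dir = Path(out_dir)
    sim_out = run_simulate(config, out_dir / "sim")
    if config.simulate.render:
        ana_out = run_analyze(config, out_dir / "analysis",
                              movie_path=sim_out["movie"],
                              sidecar_path=sim_out["schedule"])
    else:
        ana_out = run_analyze(config, out_dir / "analysis",
                              traces_path=sim_out["traces"])
    rep_out = run_report(ana_out["events"], ana_out["summary"],
                         out_dir / "report")
    return {**sim_out, **ana_out, **rep_out}
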