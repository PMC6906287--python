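"""Self-contained parameter-recovery experiments.

Each function builds a synthetic study with the generator, runs the relevant
part of the analysis stack, and returns the measured quantity together with
the problem size.  These are the package's own validation experiments: the
test suite asserts tolerances on them and the acceptance script reports
their raw numbers.
"""

from __future__ import annotations

import itertools
import math
from typing import Dict, Tuple

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .kinetics import detect_efflux_onset, estimate_flow_rate
from .popstats import (fit_exponential_lag, fit_gaussian_rates,
                       mechanosensitivity_split)
from .simulate import (NoiseParams, ScenarioParams, acquisition_schedule,
                       default_scenarios, render_movie,
                       sample_event_stream, sample_vesicle_population)
from .tracking import (_assign_pair, correct_drift, detect_spots,
                       estimate_drift, link_tracks)
from .transport import (DEFAULT_PLUGGED_PORE, DEFAULT_PORE, DFITC_40K,
                        DFITC_500K, SRB, Vesicle, classify_translocation,
                        dye_count_timecourse, transport_rate_constant)

__all__ = [
    "schedule_cycle_period", "gating_accuracy", "docking_lag_recovery",
    "flow_rate_recovery", "flow_rate_ci_coverage", "mechano_power",
    "mechano_type1_rate", "detection_performance",
    "linking_oracle_agreement", "drift_removal_fraction",
    "scenario_contract", "timecourse_oracle_agreement",
]


def schedule_cycle_period() -> float:
    """Cycle period of the canonical 4-position two-color schedule (s)."""
    return acquisition_schedule(4, 2, 0.1, 0.5).cycle_period


#: observed size-selectivity of the assay: (pore, cargo) -> verdict
GATING_EXPECTED = {
    ("open", "SRB"): "pass",
    ("open", "dFITC-40k"): "hindered",
    ("open", "dFITC-500k"): "blocked",
    ("plugged", "SRB"): "pass",
    ("plugged", "dFITC-40k"): "blocked",
}


def gating_accuracy() -> Tuple[int, int]:
    """(correct, total) of the default-parameter translocation verdicts."""
    pores = {"open": DEFAULT_PORE, "plugged": DEFAULT_PLUGGED_PORE}
    cargoes = {c.name: c for c in (SRB, DFITC_40K, DFITC_500K)}
    correct = sum(
        classify_translocation(pores[p], cargoes[c]) == verdict
        for (p, c), verdict in GATING_EXPECTED.items())
    return correct, len(GATING_EXPECTED)


def docking_lag_recovery(seed: int, n_vesicles: int = 500,
                         true_mean: float = 1450.0,
                         censor_frac: float = 0.2) -> Dict[str, float]:
    """Censored-exponential MLE of the docking lag on a simulated cohort.

    t_max is set so the configured right-censoring fraction holds in
    expectation (t_max = -mean * ln(censor_frac))."""
    t_max = -true_mean * math.log(censor_frac)
    ves = sample_vesicle_population(n_vesicles, positions_extent=4000.0,
                                    seed=seed, min_separation=1.0)
    scen = ScenarioParams("L+", docking_rate=1.0 / true_mean)
    events = sample_event_stream(ves, scen, t_max=t_max, seed=seed + 1)
    obs = [e.dock_time for e in events if e.dock_time is not None]
    cens = [t_max] * sum(e.dock_time is None for e in events)
    fit = fit_exponential_lag(obs, cens)
    return {"estimate_s": fit.mean, "true_s": true_mean,
            "n_events": fit.n_events, "n_censored": fit.n_censored}


def _flow_rate_traces(rng: np.random.Generator, n_traces: int, mean: float,
                      sd: float, onset_frame: int = 30, n_frames: int = 120,
                      dt: float = 1.0, noise_sd: float = 0.005
                      ) -> Tuple[np.ndarray, np.ndarray]:
    """Normalized efflux traces with per-trace initial derivative drawn from
    Normal(mean, sd**2); returns (times, traces[n, t])."""
    times = np.arange(n_frames) * dt
    k = rng.normal(mean, sd, size=n_traces)  # I0 = 1 so kf = k
    traces = np.where(times[None, :] < onset_frame * dt, 1.0,
                      np.exp(-k[:, None]
                             * np.clip(times - onset_frame * dt, 0, None)))
    traces = traces + rng.normal(0, noise_sd, size=traces.shape)
    return times, traces


def flow_rate_recovery(seed: int, n_traces: int = 200, mean: float = 0.098,
                       sd: float = 0.02) -> Dict[str, float]:
    """Gaussian-fit mean flow rate recovered from a synthetic trace set,
    onset located by changepoint detection per trace."""
    rng = np.random.default_rng(seed)
    times, traces = _flow_rate_traces(rng, n_traces, mean, sd)
    kfs = []
    for tr in traces:
        fit = detect_efflux_onset(tr, times, tau1=0.0, min_drop=0.3)
        if fit is None:
            continue
        kfs.append(estimate_flow_rate(tr, times, fit.onset,
                                      plateau=fit.plateau))
    g = fit_gaussian_rates(kfs)
    return {"mean_estimate": g.mean, "true_mean": mean, "sd": g.sd,
            "n_events": g.n}


def flow_rate_ci_coverage(seed: int, n_rep: int = 200, n_traces: int = 200,
                          mean: float = 0.098, sd: float = 0.02
                          ) -> Dict[str, float]:
    """Coverage of the 95% t-interval for the mean flow rate over replicate
    trace sets (onset known; the estimator still runs on every trace)."""
    rng = np.random.default_rng(seed)
    onset_frame, dt = 30, 1.0
    hits = 0
    for _ in range(n_rep):
        times, traces = _flow_rate_traces(rng, n_traces, mean, sd)
        kfs = [estimate_flow_rate(tr, times, onset_frame * dt, plateau=1.0)
               for tr in traces]
        g = fit_gaussian_rates(kfs)
        hits += g.ci_low <= mean <= g.ci_high
    return {"coverage": hits / n_rep, "nominal": 0.95, "n_rep": n_rep}


def _alpha_hl_events(seed: int, n_vesicles: int,
                     mechano_beta: float) -> pd.DataFrame:
    """Perforation events of a protein-pore-control run, as an events table
    with true diameters and intensity flow rates kf = k * I0."""
    base = default_scenarios()["alpha_hemolysin"]
    scen = ScenarioParams(
        "alpha_hemolysin", docking_rate=base.docking_rate,
        insertion_prob_max=base.insertion_prob_max,
        insertion_d50=base.insertion_d50,
        mechano_beta=mechano_beta, d_ref=base.d_ref,
        empirical_hindrance=base.empirical_hindrance)
    # ~1 mM dye load (6e-4 molecules/nm^3): the small-vesicle population
    # still encapsulates >~100 molecules, so count discreteness is negligible
    ves = sample_vesicle_population(
        n_vesicles, lognormal_mu=math.log(70.0), lognormal_sigma=0.35,
        positions_extent=4000.0, seed=seed, min_separation=1.0,
        dye_conc={"ATTO655": 6.0e-4})
    events = sample_event_stream(ves, scen, t_max=28800.0, seed=seed + 1)
    by_id = {v.id: v for v in ves}
    rows = []
    for e in events:
        if e.outcome != "docked_perforated":
            continue
        v = by_id[e.vesicle_id]
        kf = e.k_per_species["ATTO655"] * v.content["ATTO655"] * 10.0
        rows.append({"d_m_est_nm": v.diameter, "kf": kf,
                     "outcome": e.outcome})
    return pd.DataFrame(rows)


def mechano_power(seed: int, n_vesicles: int = 400) -> Dict[str, float]:
    """Mechanosensitive run (side flow-rate means configured in the observed
    ~3.8x ratio): KS discrimination across the 70 nm split."""
    beta = default_scenarios()["alpha_hemolysin"].mechano_beta
    ev = _alpha_hl_events(seed, n_vesicles, beta)
    split = mechanosensitivity_split(ev, cutoff_nm=70.0)
    return {"ks_pvalue": split.ks.pvalue, "ks_statistic": split.ks.statistic,
            "rate_ratio": split.large.mean / split.small.mean,
            "n_small": split.small.n, "n_large": split.large.n}


def mechano_type1_rate(seed: int, n_rep: int = 200,
                       n_vesicles: int = 300,
                       alpha: float = 0.05) -> Dict[str, float]:
    """False-rejection rate of the size-split KS test on mechano-insensitive
    runs (mechano_beta = 0)."""
    rejections = 0
    used = 0
    for r in range(n_rep):
        ev = _alpha_hl_events(seed + 1000 * (r + 1), n_vesicles, 0.0)
        split = mechanosensitivity_split(ev, cutoff_nm=70.0)
        if not split.sufficient:
            continue
        used += 1
        rejections += split.ks.pvalue < alpha
    return {"rejection_rate": rejections / used, "alpha": alpha,
            "n_rep": used}


def _spot_field(seed: int, n_spots: int = 40, canvas: int = 128,
                flux: float = 3000.0, n_frames: int = 1, drift=None):
    rng = np.random.default_rng(seed)
    pos = []
    while len(pos) < n_spots:
        cand = rng.uniform(10, canvas - 10, size=2)
        if all(math.hypot(cand[0] - p[0], cand[1] - p[1]) > 8 for p in pos):
            pos.append((float(cand[0]), float(cand[1])))
    schedule = acquisition_schedule(1, 1, 0.1, 0.0, n_cycles=n_frames,
                                    channel_labels=("ch",))
    ves = [Vesicle(id=i, diameter=200.0, content={}, position=p)
           for i, p in enumerate(pos)]
    traces = pd.DataFrame(
        [{"vesicle_id": i, "frame": f, "clean_intensity": flux}
         for f in range(n_frames) for i in range(n_spots)])
    movie, truth = render_movie(
        ves, traces, schedule, psf_sigma=1.2, drift=drift,
        noise=NoiseParams(read_sigma=3.0, background=100.0),
        canvas=canvas, seed=seed + 7)
    return movie.frames.astype(float), pos


def detection_performance(seed: int, n_spots: int = 40) -> Dict[str, float]:
    """Detection rate and localization RMSE on a rendered noisy field."""
    frames, pos = _spot_field(seed, n_spots)
    locs = detect_spots(frames[0], sigma=1.2, k_mad=5.0)
    errs = []
    for x, y in pos:
        d = [math.hypot(l.x - x, l.y - y) for l in locs]
        if d and min(d) < 2.0:
            errs.append(min(d))
    rmse = math.sqrt(np.mean(np.square(errs))) if errs else math.inf
    return {"rmse_px": rmse, "found_fraction": len(errs) / n_spots,
            "n_spots": n_spots}


def _pairwise_bruteforce_cost(src, tgt, max_disp):
    alt = max_disp ** 2
    ns, nt = len(src), len(tgt)
    best = None
    for k in range(min(ns, nt) + 1):
        for s_idx in itertools.combinations(range(ns), k):
            for t_perm in itertools.permutations(range(nt), k):
                cost = alt * (ns - k) + alt * (nt - k)
                ok = True
                for si, ti in zip(s_idx, t_perm):
                    d2 = float(((src[si] - tgt[ti]) ** 2).sum())
                    if d2 > alt:
                        ok = False
                        break
                    cost += d2
                if ok and (best is None or cost < best):
                    best = cost
    return best


def linking_oracle_agreement(seed: int, n_trials: int = 40
                             ) -> Dict[str, float]:
    """Fraction of random <= 4-particle frame pairs where the LAP solution
    cost equals exhaustive enumeration."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_trials):
        ns, nt = int(rng.integers(1, 5)), int(rng.integers(1, 5))
        src = rng.uniform(0, 10, size=(ns, 2))
        tgt = rng.uniform(0, 10, size=(nt, 2))
        max_disp = float(rng.uniform(1.5, 6.0))
        links = _assign_pair(src, tgt, max_disp)
        alt = max_disp ** 2
        cost = alt * (ns - len(links)) + alt * (nt - len(links)) + sum(
            float(((src[s] - tgt[t]) ** 2).sum()) for s, t in links)
        oracle = _pairwise_bruteforce_cost(src, tgt, max_disp)
        agree += abs(cost - oracle) < 1e-9
    return {"agreement": agree / n_trials, "n_trials": n_trials}


def drift_removal_fraction(seed: int, n_frames: int = 60,
                           drift_vec: Tuple[float, float] = (0.15, -0.1)
                           ) -> Dict[str, float]:
    """Fraction of the apparent start-to-end track displacement removed by
    drift correction on a linear-drift rendered movie."""
    drift = np.tile(drift_vec, (n_frames, 1))
    frames, _ = _spot_field(seed, n_spots=25, canvas=128, n_frames=n_frames,
                            drift=drift)

    def mean_displacement(stack):
        per_frame = [detect_spots(stack[f], 1.2, k_mad=5.0, frame_index=f)
                     for f in range(n_frames)]
        tracks = link_tracks(per_frame, max_disp=3.0, max_gap=1)
        disp = [math.hypot(t.localizations[-1].x - t.localizations[0].x,
                           t.localizations[-1].y - t.localizations[0].y)
                for t in tracks if len(t.localizations) >= n_frames // 2]
        return float(np.mean(disp)), tracks

    before, tracks = mean_displacement(frames)
    est = estimate_drift(tracks, n_frames=n_frames)
    margin = int(np.ceil(np.abs(est.cumulative).max() + 1))
    corrected = correct_drift(frames, est, margin=margin)
    # crop to the interior covered by every shifted frame, so the moving
    # embedding border cannot masquerade as trackable structure
    m2 = 2 * margin
    corrected = corrected[:, m2:frames.shape[1], m2:frames.shape[2]]
    after, _ = mean_displacement(corrected)
    return {"removed_fraction": 1.0 - after / before,
            "before_px": before, "after_px": after}


def scenario_contract(seed: int, n_vesicles_per_rep: int = 175,
                      n_rep: int = 4) -> Dict[str, float]:
    """Scenario ordering: no docking without lipidation/keys, and the
    configured L+/L- perforation fold change over replicate flow runs."""
    scen = default_scenarios()
    ves = sample_vesicle_population(200, positions_extent=2000.0, seed=seed,
                                    min_separation=1.0)
    nl = sample_event_stream(ves, scen["NL-"], t_max=28800.0, seed=seed)
    n_docked_nl = sum(e.outcome != "undocked" for e in nl)

    fracs = {"L+": [], "L-": []}
    for r in range(n_rep):
        for label in ("L+", "L-"):
            v = sample_vesicle_population(
                n_vesicles_per_rep, positions_extent=2000.0,
                seed=seed + 10 * r + (0 if label == "L+" else 5),
                min_separation=1.0)
            ev = sample_event_stream(v, scen[label], t_max=28800.0,
                                     seed=seed + 100 * r
                                     + (0 if label == "L+" else 50))
            frac = np.mean([e.outcome == "docked_perforated" for e in ev])
            fracs[label].append(frac)
    fold = float(np.mean(fracs["L+"]) / np.mean(fracs["L-"]))
    return {"nl_minus_docked": n_docked_nl, "fold_change": fold,
            "configured_fold": 2.2,
            "n_total": 2 * n_rep * n_vesicles_per_rep}


def timecourse_oracle_agreement(seed: int, n_draws: int = 100
                                ) -> Dict[str, float]:
    """Closed-form efflux vs numerical ODE integration; initial-slope and
    unplugging identities."""
    rng = np.random.default_rng(seed)
    ves = Vesicle(id=0, diameter=200.0, content={"dye": 1000.0})
    worst = 0.0
    t = np.linspace(0.0, 600.0, 121)
    for _ in range(n_draws):
        k = float(rng.uniform(1e-4, 0.05))
        t_ins = float(rng.uniform(0, 300))
        closed = dye_count_timecourse(ves, k, t_ins, t)
        mask = t >= t_ins
        sol = solve_ivp(lambda tt, y: [-k * y[0]], (t_ins, t[-1]),
                        [1000.0], t_eval=t[mask], rtol=1e-10, atol=1e-13)
        ref = sol.y[0]
        sig = ref >= 1e-6 * 1000.0  # counts below 1e-6 of N0 are zero
        rel = np.max(np.abs(closed[mask][sig] - ref[sig]) / ref[sig])
        worst = max(worst, float(rel))

    # initial efflux slope == k * I0 (quenching disabled, brightness 1)
    k, t_ins, dt = 0.02, 100.0, 1e-8 / 0.02
    n = dye_count_timecourse(ves, k, t_ins,
                             np.array([t_ins, t_ins + dt]))
    slope = (n[0] - n[1]) / dt
    slope_rel_err = abs(slope - k * n[0]) / (k * n[0])

    k_plugged = transport_rate_constant(DEFAULT_PLUGGED_PORE, SRB, ves)
    k_open = transport_rate_constant(DEFAULT_PORE, SRB, ves)
    k_unplugged = transport_rate_constant(DEFAULT_PLUGGED_PORE.unplugged(),
                                          SRB, ves)
    return {"max_rel_error": worst, "n_draws": n_draws,
            "slope_rel_error": float(slope_rel_err),
            "unplug_restores_open_rate": float(k_unplugged == k_open),
            "plugged_rate_reduced": float(0 < k_plugged < k_open)}
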