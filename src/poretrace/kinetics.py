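"""Per-event kinetic descriptors from colocalized pore/vesicle traces.

From each pore-vesicle trace pair this module extracts the docking lag tau1
(step onset in the pore channel), the efflux onset and reorientation time
tau2 = onset - tau1 (changepoint in the dye channel), the flow rate k_f
(initial time derivative of the dye intensity after onset), a vesicle
diameter estimate from the pre-onset intensity (volume-encapsulated dye,
cube-root law), and an outcome label.  Events whose decay is far slower than
typical are re-flagged as leaky bilayer influx and excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .tracking import Track

__all__ = [
    "EventRecord",
    "OnsetFit",
    "colocalize",
    "detect_docking",
    "detect_efflux_onset",
    "estimate_flow_rate",
    "estimate_diameter",
    "classify_outcome",
    "apply_leaky_rule",
    "events_table",
]

OUTCOMES = ("undocked", "docked_only", "docked_perforated", "excluded_leaky")


@dataclass
class EventRecord:
    """Kinetic descriptors of one tracked vesicle."""

    vesicle_track_id: int
    pore_track_id: Optional[int] = None
    tau1: Optional[float] = None
    tau2: Optional[float] = None
    efflux_onset: Optional[float] = None
    kf: Optional[Dict[str, float]] = None  # counts/s per channel
    d_m_est: Optional[float] = None
    outcome: str = "undocked"
    decay_tau: Optional[float] = None  # s, fitted decay time constant
    reject_reason: str = ""

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        for val in (self.tau1, self.tau2):
            if val is not None and val < 0:
                raise ValueError("lag times must be non-negative")
        if self.outcome == "docked_perforated":
            if self.tau1 is None or self.efflux_onset is None:
                raise ValueError("perforated events need tau1 and onset")
            if self.efflux_onset < self.tau1:
                raise ValueError("onset must be >= tau1")


@dataclass(frozen=True)
class OnsetFit:
    """Result of the two-phase changepoint fit on a dye trace."""

    onset: float  # s
    model: str  # "exponential" | "linear"
    decay_tau: float  # s
    plateau: float  # counts
    frac_drop: float


def colocalize(vesicle_tracks: Sequence[Track], pore_tracks: Sequence[Track],
               radius: float) -> Tuple[List[Tuple[Track, Track]],
                                       List[Track], List[Track]]:
    """Pair pore tracks with vesicle tracks by time-averaged distance.

    Greedy one-to-one matching in order of increasing distance between track
    mean positions; pairs farther than ``radius`` stay unpaired.  Returns
    (pairs as (vesicle, pore), unpaired vesicles, unpaired pores).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    cands = []
    for pi, p in enumerate(pore_tracks):
        px, py = p.mean_position
        for vi, v in enumerate(vesicle_tracks):
            vx, vy = v.mean_position
            d = math.hypot(px - vx, py - vy)
            if d <= radius:
                cands.append((d, vi, pi))
    cands.sort()
    used_v: set = set()
    used_p: set = set()
    pairs = []
    for d, vi, pi in cands:
        if vi in used_v or pi in used_p:
            continue
        pairs.append((vesicle_tracks[vi], pore_tracks[pi]))
        used_v.add(vi)
        used_p.add(pi)
    lone_v = [v for i, v in enumerate(vesicle_tracks) if i not in used_v]
    lone_p = [p for i, p in enumerate(pore_tracks) if i not in used_p]
    return pairs, lone_v, lone_p


def detect_docking(pore_trace: np.ndarray, times: np.ndarray,
                   baseline_window: int = 10, k_sigma: float = 5.0,
                   min_persist: int = 3) -> Optional[float]:
    """Docking lag tau1: first sustained step of the pore-channel trace.

    Threshold = baseline mean + k_sigma * baseline SD over the first
    ``baseline_window`` frames; tau1 is the timestamp of the first frame
    strictly above threshold for >= ``min_persist`` consecutive frames.
    Returns None when never satisfied (including flat traces).
    """
    trace = np.asarray(pore_trace, dtype=float)
    times = np.asarray(times, dtype=float)
    if trace.size <= baseline_window + min_persist:
        raise ValueError("trace shorter than baseline_window + min_persist")
    base = trace[:baseline_window]
    thr = base.mean() + k_sigma * base.std()
    above = trace > thr
    run = 0
    for i, a in enumerate(above):
        run = run + 1 if a else 0
        if run >= min_persist:
            return float(times[i - min_persist + 1])
    return None


def _linear_fit(t: np.ndarray, y: np.ndarray) -> Tuple[float, float, float]:
    """LS line y = a + b t; returns (a, b, rss)."""
    A = np.vstack([np.ones_like(t), t]).T
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    return float(coef[0]), float(coef[1]), float(resid @ resid)


def _exp_fit(t: np.ndarray, y: np.ndarray,
             baseline: float = 0.0) -> Tuple[float, float, float]:
    """Fit y = A exp(-k (t - t0)) + baseline via y^2-weighted log-linear LS.

    The weights make the log-space fit equivalent to least squares under
    additive intensity noise, so near-zero tail samples cannot dominate.
    Returns (A_at_first_point, k, rss in the original intensity space).
    """
    y0 = y - baseline
    floor = max(1e-9, 1e-6 * max(abs(y0).max(), 1.0))
    yc = np.maximum(y0, floor)
    ylog = np.log(yc)
    w = np.sqrt(yc * yc)  # sigma_log ~ sigma_lin / y
    tt = t - t[0]
    A = np.vstack([np.ones_like(tt), tt]).T * w[:, None]
    coef, *_ = np.linalg.lstsq(A, ylog * w, rcond=None)
    k = -float(coef[1])
    amp = math.exp(float(coef[0]))
    pred = amp * np.exp(-k * tt) + baseline
    rss = float(((y - pred) ** 2).sum())
    return amp, k, rss


def detect_efflux_onset(dye_trace: np.ndarray, times: np.ndarray,
                        tau1: float, min_drop: float = 0.3,
                        min_tail: int = 4, baseline: float = 0.0,
                        max_decay_tau: Optional[float] = None
                        ) -> Optional[OnsetFit]:
    """Efflux onset by exhaustive two-phase changepoint fitting after tau1.

    Every candidate changepoint after tau1 is scored as a constant plateau
    followed by a decay (exponential toward ``baseline`` or linear, whichever
    fits better); the onset minimises the total residual sum of squares
    (ties to the earliest frame).  Rejected (None) when the total fractional
    drop is below ``min_drop`` or, if ``max_decay_tau`` is given, when the
    fitted decay constant exceeds it (leaky-influx rule).
    """
    if tau1 is None:
        raise ValueError("tau1 must be set before onset detection")
    trace = np.asarray(dye_trace, dtype=float)
    times = np.asarray(times, dtype=float)
    i1 = int(np.searchsorted(times, tau1))
    n = trace.size
    if n - i1 < min_tail + 2:
        return None

    plateau_all = trace[i1:max(i1 + 1, n - min_tail)].max()
    tail_level = trace[-min(min_tail, n):].mean()
    best: Optional[Tuple[float, int, str, float, float]] = None
    for c in range(i1 + 1, n - min_tail + 1):
        seg_p = trace[i1:c]
        plateau = seg_p.mean()
        rss_p = float(((seg_p - plateau) ** 2).sum())
        t_d = times[c:]
        y_d = trace[c:]
        a_lin, b_lin, rss_lin = _linear_fit(t_d, y_d)
        amp, k_exp, rss_exp = _exp_fit(t_d, y_d, baseline)
        if rss_exp <= rss_lin:
            model, rss_d = "exponential", rss_exp
            tau_d = math.inf if k_exp <= 0 else 1.0 / k_exp
        else:
            model, rss_d = "linear", rss_lin
            tau_d = math.inf if b_lin >= 0 else plateau / (-b_lin)
        total = rss_p + rss_d
        if best is None or total < best[0] - 1e-12:
            best = (total, c, model, tau_d, plateau)
    if best is None:
        return None
    _, c, model, tau_d, plateau = best
    if plateau <= 0:
        return None
    frac_drop = (plateau - tail_level) / plateau
    if frac_drop < min_drop:
        return None
    if max_decay_tau is not None and tau_d > max_decay_tau:
        return None
    return OnsetFit(onset=float(times[c]), model=model, decay_tau=float(tau_d),
                    plateau=float(plateau), frac_drop=float(frac_drop))


def estimate_flow_rate(dye_trace: np.ndarray, times: np.ndarray,
                       onset: float, plateau: Optional[float] = None,
                       method: str = "auto", baseline: float = 0.0,
                       max_window: Optional[int] = None) -> float:
    """Flow rate k_f: the initial time derivative of the dye intensity.

    The fit window runs from the onset until the intensity first falls below
    50% of the pre-onset plateau (at least 3 points).  ``method='auto'``
    fits both a line and an exponential and reports the initial derivative
    of the better-fitting model (|slope| for the line, ``k * I(onset)`` for
    the exponential, its derivative at the onset); ``method='line'`` forces
    the raw LS-line slope.
    """
    trace = np.asarray(dye_trace, dtype=float)
    times = np.asarray(times, dtype=float)
    i0 = int(np.searchsorted(times, onset))
    if plateau is None:
        plateau = trace[max(0, i0 - 5):max(1, i0)].mean() if i0 > 0 \
            else trace[0]
    below = np.nonzero(trace[i0:] - baseline < 0.5 * (plateau - baseline))[0]
    i_end = i0 + (int(below[0]) if below.size else trace.size - i0)
    i_end = max(i_end, i0 + 3)
    if max_window is not None:
        i_end = min(i_end, i0 + max_window)
    i_end = min(i_end, trace.size)
    if i_end - i0 < 3:
        raise ValueError("fewer than 3 points in the flow-rate window")
    t = times[i0:i_end]
    y = trace[i0:i_end]
    a_lin, b_lin, rss_lin = _linear_fit(t, y)
    if method == "line":
        return abs(b_lin)
    amp, k_exp, rss_exp = _exp_fit(t, y, baseline)
    if method == "auto" and rss_exp < rss_lin:
        return abs(k_exp * amp)
    return abs(b_lin)


def estimate_diameter(pre_onset_intensity: float,
                      calibration: Tuple[float, float]) -> float:
    """Vesicle diameter from encapsulated-dye intensity, cube-root law.

    With volume-encapsulated dye, I ~ d^3, so
    ``d = d_ref * (I / I_ref)**(1/3)`` for a calibration pair (I_ref, d_ref).
    """
    i_ref, d_ref = calibration
    if pre_onset_intensity <= 0:
        raise ValueError("intensity must be positive")
    if i_ref <= 0 or d_ref <= 0:
        raise ValueError("calibration must be positive")
    return d_ref * (pre_onset_intensity / i_ref) ** (1.0 / 3.0)


def classify_outcome(tau1: Optional[float], onset: Optional[OnsetFit],
                     leaky: bool = False) -> str:
    """Mutually exclusive outcome label for one event record."""
    if tau1 is None:
        if onset is not None:
            raise ValueError("onset without docking is contradictory")
        return "undocked"
    if onset is None:
        return "docked_only"
    if leaky:
        return "excluded_leaky"
    return "docked_perforated"


def apply_leaky_rule(records: List[EventRecord],
                     factor: float = 10.0) -> List[EventRecord]:
    """Re-flag accepted events whose decay constant exceeds ``factor`` times
    the median decay over all accepted events (slow multi-frame filling is
    interpreted as leaky bilayer influx and omitted)."""
    taus = [r.decay_tau for r in records
            if r.outcome == "docked_perforated" and r.decay_tau is not None
            and math.isfinite(r.decay_tau)]
    if not taus:
        return records
    cutoff = factor * float(np.median(taus))
    for r in records:
        if (r.outcome == "docked_perforated" and r.decay_tau is not None
                and r.decay_tau > cutoff):
            r.outcome = "excluded_leaky"
            r.reject_reason = "decay slower than leaky-influx cutoff"
    return records


def events_table(records: Sequence[EventRecord]) -> pd.DataFrame:
    """Tidy events table (one row per vesicle track)."""
    rows = []
    for r in records:
        row = {
            "vesicle_id": r.vesicle_track_id,
            "pore_id": r.pore_track_id,
            "tau1_s": np.nan if r.tau1 is None else r.tau1,
            "tau2_s": np.nan if r.tau2 is None else r.tau2,
            "onset_s": np.nan if r.efflux_onset is None else r.efflux_onset,
            "d_m_est_nm": np.nan if r.d_m_est is None else r.d_m_est,
            "outcome": r.outcome,
            "reject_reason": r.reject_reason,
        }
        if r.kf:
            for ch, v in r.kf.items():
                row[f"kf_{ch}_counts_per_s"] = v
        rows.append(row)
    return pd.DataFrame(rows)
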