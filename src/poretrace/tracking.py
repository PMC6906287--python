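"""Spot detection, LAP particle linking, drift estimation/correction and
background-corrected trace extraction.

Coordinates are pixel-center, 0-based; y increases downward (image
convention).  Detection uses a scale-normalized Laplacian-of-Gaussian
response with a robust (MAD-based) threshold and intensity-weighted centroid
refinement.  Linking solves per-frame-pair linear assignment problems with a
birth/death cost of ``max_disp**2``, followed by a gap-closing assignment
between track ends and starts.  Drift is the mean per-frame-pair
displacement of all linked particles; correction embeds each frame in a
larger canvas and shifts it by the rounded negative cumulative drift
(integer shifts preserve photometry).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import gaussian_laplace, maximum_filter
from scipy.optimize import linear_sum_assignment

__all__ = [
    "Localization",
    "Track",
    "DriftSeries",
    "detect_spots",
    "link_tracks",
    "estimate_drift",
    "correct_drift",
    "extract_trace",
]

_BIG = 1e12


@dataclass(frozen=True)
class Localization:
    frame: int
    x: float
    y: float
    intensity: float
    channel: str = ""


@dataclass
class Track:
    id: int
    localizations: List[Localization] = field(default_factory=list)

    @property
    def frames(self) -> np.ndarray:
        return np.array([l.frame for l in self.localizations])

    @property
    def positions(self) -> np.ndarray:
        return np.array([[l.x, l.y] for l in self.localizations])

    def position_at(self, frame: int) -> Optional[Tuple[float, float]]:
        for l in self.localizations:
            if l.frame == frame:
                return (l.x, l.y)
        return None

    @property
    def mean_position(self) -> Tuple[float, float]:
        p = self.positions
        return (float(p[:, 0].mean()), float(p[:, 1].mean()))


@dataclass
class DriftSeries:
    """Per-frame-pair mean displacement and its running sum.

    ``pairwise[i]`` is the mean displacement from frame i to i+1;
    ``cumulative[f]`` is the summed displacement of frame f relative to
    frame 0 (``cumulative[0] = (0, 0)``).
    """

    pairwise: np.ndarray  # (n_frames-1, 2)
    filled: np.ndarray  # bool per pair: True where no track spanned the pair

    @property
    def cumulative(self) -> np.ndarray:
        n = self.pairwise.shape[0] + 1
        cum = np.zeros((n, 2))
        cum[1:] = np.cumsum(self.pairwise, axis=0)
        return cum


def detect_spots(frame: np.ndarray, sigma: float,
                 threshold: Optional[float] = None, k_mad: float = 5.0,
                 frame_index: int = 0, channel: str = "") -> List[Localization]:
    """Detect diffraction-limited spots in one frame.

    Local maxima of the (sign-flipped, scale-normalized) LoG response above
    a threshold — by default ``median + k_mad * 1.4826 * MAD`` of the
    response — refined to subpixel by an intensity-weighted centroid in a
    ``(2*ceil(2*sigma)+1)**2`` window.  No two detections closer than
    ``2*sigma`` (the brighter wins).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    img = np.asarray(frame, dtype=float)
    if min(img.shape) <= 2 * sigma:
        raise ValueError("sigma too large for the frame")
    response = -sigma ** 2 * gaussian_laplace(img, sigma)
    if threshold is None:
        med = np.median(response)
        mad = np.median(np.abs(response - med))
        threshold = med + k_mad * 1.4826 * mad
    min_dist = 2.0 * sigma
    foot = int(max(1, math.floor(min_dist)))
    local_max = (response == maximum_filter(response, size=2 * foot + 1))
    cand = np.argwhere(local_max & (response > threshold))
    if cand.size == 0:
        return []
    # brightest-wins suppression of close pairs
    order = np.argsort(-response[cand[:, 0], cand[:, 1]])
    cand = cand[order]
    kept: List[Tuple[int, int]] = []
    for r, c in cand:
        if all((r - r2) ** 2 + (c - c2) ** 2 >= min_dist ** 2
               for r2, c2 in kept):
            kept.append((int(r), int(c)))

    half = int(math.ceil(2 * sigma))
    locs = []
    h, w = img.shape
    for r, c in kept:
        r_lo, r_hi = max(0, r - half), min(h, r + half + 1)
        c_lo, c_hi = max(0, c - half), min(w, c + half + 1)
        window = img[r_lo:r_hi, c_lo:c_hi]
        weights = window - window.min()
        total = weights.sum()
        if total <= 0:
            y, x = float(r), float(c)
        else:
            rr, cc = np.mgrid[r_lo:r_hi, c_lo:c_hi]
            y = float((weights * rr).sum() / total)
            x = float((weights * cc).sum() / total)
        locs.append(Localization(frame=frame_index, x=x, y=y,
                                 intensity=float(img[r, c]),
                                 channel=channel))
    return locs


def _assign_pair(sources: np.ndarray, targets: np.ndarray,
                 max_disp: float) -> List[Tuple[int, int]]:
    """LAP between two point sets with birth/death cost max_disp**2.

    Returns (source_idx, target_idx) links of the optimal augmented
    assignment; unmatched points pay the birth/death cost.
    """
    ns, nt = len(sources), len(targets)
    if ns == 0 or nt == 0:
        return []
    alt = max_disp ** 2
    d2 = ((sources[:, None, :] - targets[None, :, :]) ** 2).sum(axis=2)
    cost = np.full((ns + nt, nt + ns), alt, dtype=float)
    top_left = np.where(d2 <= max_disp ** 2, d2, _BIG)
    cost[:ns, :nt] = top_left
    cost[:ns, nt:] = _BIG
    cost[ns:, :nt] = _BIG
    np.fill_diagonal(cost[:ns, nt:], alt)  # deaths
    np.fill_diagonal(cost[ns:, :nt], alt)  # births
    cost[ns:, nt:] = 0.0  # completion block (absorbs leftover rows/cols)
    rows, cols = linear_sum_assignment(cost)
    return [(int(r), int(c)) for r, c in zip(rows, cols)
            if r < ns and c < nt and d2[r, c] <= max_disp ** 2]


def link_tracks(localizations: Sequence[Sequence[Localization]],
                max_disp: float, max_gap: int = 0) -> List[Track]:
    """Link per-frame localizations into tracks (frame-to-frame LAP +
    gap closing).

    ``localizations[f]`` holds the detections of frame f.  Frame-to-frame
    links minimise total squared displacement with birth/death cost
    ``max_disp**2``; then track ends are linked to later track starts within
    ``max_gap`` skipped frames and ``max_disp`` distance by a second
    assignment.  Every localization belongs to at most one track.
    """
    if max_disp <= 0:
        raise ValueError("max_disp must be positive")
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    tracks: List[Track] = []
    active: List[Track] = []  # tracks whose last localization is at frame f-1
    next_id = 0
    n_frames = len(localizations)
    for f in range(n_frames):
        locs = list(localizations[f])
        if f == 0 or not active:
            linked_targets: Dict[int, Track] = {}
        else:
            src_pos = np.array([[t.localizations[-1].x,
                                 t.localizations[-1].y] for t in active])
            tgt_pos = np.array([[l.x, l.y] for l in locs]) if locs else \
                np.empty((0, 2))
            links = _assign_pair(src_pos, tgt_pos, max_disp)
            linked_targets = {c: active[r] for r, c in links}
        new_active = []
        for j, loc in enumerate(locs):
            if j in linked_targets:
                tr = linked_targets[j]
                tr.localizations.append(loc)
            else:
                tr = Track(id=next_id, localizations=[loc])
                next_id += 1
                tracks.append(tr)
            new_active.append(tr)
        active = new_active

    if max_gap > 0 and len(tracks) > 1:
        tracks = _close_gaps(tracks, max_disp, max_gap)
    return tracks


def _close_gaps(tracks: List[Track], max_disp: float,
                max_gap: int) -> List[Track]:
    """Merge track ends to later track starts (one assignment pass)."""
    ends = [(i, t.localizations[-1]) for i, t in enumerate(tracks)]
    starts = [(i, t.localizations[0]) for i, t in enumerate(tracks)]
    ne, ns = len(ends), len(starts)
    alt = max_disp ** 2
    cost = np.full((ne + ns, ns + ne), alt)
    d2 = np.full((ne, ns), _BIG)
    for a, (i, le) in enumerate(ends):
        for b, (j, ls) in enumerate(starts):
            if i == j:
                continue
            gap = ls.frame - le.frame - 1
            if not 1 <= gap <= max_gap:
                continue
            dist2 = (le.x - ls.x) ** 2 + (le.y - ls.y) ** 2
            if dist2 <= max_disp ** 2:
                d2[a, b] = dist2
    cost[:ne, :ns] = d2
    cost[:ne, ns:] = _BIG
    np.fill_diagonal(cost[:ne, ns:], alt)
    cost[ne:, :ns] = _BIG
    np.fill_diagonal(cost[ne:, :ns], alt)
    cost[ne:, ns:] = 0.0  # completion block
    rows, cols = linear_sum_assignment(cost)
    merge_into: Dict[int, int] = {}  # start-track index -> end-track index
    for r, c in zip(rows, cols):
        if r < ne and c < ns and d2[r, c] < _BIG:
            merge_into[starts[c][0]] = ends[r][0]

    # resolve chains end->start->end... by following each merge to its
    # surviving head track
    head = {i: i for i in range(len(tracks))}
    for j in sorted(merge_into,
                    key=lambda j: tracks[j].localizations[0].frame):
        i = merge_into[j]
        while head[i] != i:
            i = head[i]
        tracks[i].localizations.extend(tracks[j].localizations)
        tracks[j].localizations = []
        head[j] = i
    merged = [t for t in tracks if t.localizations]
    for new_id, t in enumerate(merged):
        t.id = new_id
    return merged


def estimate_drift(tracks: Sequence[Track],
                   n_frames: Optional[int] = None) -> DriftSeries:
    """Mean per-frame-pair displacement over all tracks present in both frames.

    Pairs spanned by no track inherit the previous pair's displacement and
    are flagged in ``filled``.
    """
    if not tracks:
        raise ValueError("no tracks to estimate drift from")
    if n_frames is None:
        n_frames = max(int(t.frames.max()) for t in tracks) + 1
    sums = np.zeros((n_frames - 1, 2))
    counts = np.zeros(n_frames - 1, dtype=int)
    for t in tracks:
        locs = t.localizations
        for a, b in zip(locs[:-1], locs[1:]):
            if b.frame == a.frame + 1:
                sums[a.frame] += (b.x - a.x, b.y - a.y)
                counts[a.frame] += 1
    pairwise = np.zeros_like(sums)
    filled = counts == 0
    prev = np.zeros(2)
    for i in range(n_frames - 1):
        if counts[i] > 0:
            prev = sums[i] / counts[i]
        pairwise[i] = prev
    return DriftSeries(pairwise=pairwise, filled=filled)


def correct_drift(frames: np.ndarray, drift: DriftSeries,
                  margin: int = 25) -> np.ndarray:
    """Embed each frame centered in a canvas ``margin`` px larger per side and
    shift it by the rounded negative cumulative drift (512 -> 562 at the
    default margin).  Integer shifts; vacated regions are zero-filled.
    """
    frames = np.asarray(frames)
    n, h, w = frames.shape
    cum = drift.cumulative
    if cum.shape[0] < n:
        raise ValueError("drift does not cover all frames")
    if np.max(np.abs(cum[:n])) > margin:
        raise ValueError("cumulative drift exceeds the margin; enlarge the "
                         "canvas margin")
    out = np.zeros((n, h + 2 * margin, w + 2 * margin), dtype=frames.dtype)
    for f in range(n):
        sx = margin - int(round(cum[f, 0]))
        sy = margin - int(round(cum[f, 1]))
        out[f, sy:sy + h, sx:sx + w] = frames[f]
    return out


def extract_trace(frames: np.ndarray, x: float, y: float,
                  aperture_radius: float = 3.0,
                  bg_annulus: Tuple[float, float] = (5.0, 8.0)) -> np.ndarray:
    """Background-corrected integrated intensity of a fixed spot per frame.

    Per frame: sum over the aperture disk minus the annulus median times the
    aperture pixel count.  Pixel-center convention: pixel (i, j) is at
    distance hypot(j - x, i - y).
    """
    r_in, r_out = bg_annulus
    if not r_out > r_in >= aperture_radius:
        raise ValueError("need r_out > r_in >= aperture_radius")
    frames = np.asarray(frames, dtype=float)
    n, h, w = frames.shape
    if not (0 <= x < w and 0 <= y < h):
        raise ValueError("anchor outside canvas")
    yy, xx = np.mgrid[0:h, 0:w]
    dist = np.hypot(xx - x, yy - y)
    aperture = dist <= aperture_radius
    annulus = (dist > r_in) & (dist <= r_out)
    n_ap = aperture.sum()
    if annulus.sum() == 0:
        raise ValueError("annulus contains no pixels")
    flat = frames.reshape(n, -1)
    ap_sum = flat[:, aperture.ravel()].sum(axis=1)
    bg_med = np.median(flat[:, annulus.ravel()], axis=1)
    return ap_sum - bg_med * n_ap
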