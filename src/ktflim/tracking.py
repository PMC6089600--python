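"""Kinetochore detection, tracking, pairing and classification.

Spots are detected as local maxima refined by intensity-weighted centroids
(sub-pixel, 0-based coordinates with pixel centers at integers), linked
frame-to-frame by gated greedy nearest-neighbor assignment with one-frame gap
bridging, and drift-corrected from frame-to-frame image cross-correlation.
Sister pairs are identified by separation and velocity-correlation gates;
per-frame labels (leading/trailing, centered/off-centered/mid,
poleward/anti-poleward) follow the conventions used for metaphase and
monopolar-spindle analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import maximum_filter
from skimage.registration import phase_cross_correlation

__all__ = [
    "Detection",
    "Track",
    "SisterPair",
    "KinetochoreGroup",
    "detect_spots",
    "link_tracks",
    "correct_drift",
    "pair_sisters",
    "five_point_velocity",
    "classify_pair",
    "group_stats",
]


@dataclass(frozen=True)
class Detection:
    frame: int
    x: float
    y: float
    intensity: float


@dataclass
class Track:
    """Positions per frame in micrometers; NaN rows mark gaps."""

    id: int
    frames: np.ndarray
    xy_um: np.ndarray  # (n, 2)

    def positions_at(self, frames: np.ndarray) -> np.ndarray:
        out = np.full((len(frames), 2), np.nan)
        idx = {f: i for i, f in enumerate(self.frames)}
        for k, f in enumerate(frames):
            if f in idx:
                out[k] = self.xy_um[idx[f]]
        return out

    @property
    def n_frames(self) -> int:
        return len(self.frames)


@dataclass
class SisterPair:
    track_a: Track
    track_b: Track
    frames: np.ndarray
    kk_um: np.ndarray
    labels: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if np.any(self.kk_um <= 0):
            raise ValueError("K-K distances must be positive")


@dataclass
class KinetochoreGroup:
    members: list
    variable: str
    mean: float
    sem: float
    iqr: tuple[float, float]
    values: np.ndarray = field(repr=False, default=None)


# ---------------------------------------------------------------------------


def detect_spots(image: np.ndarray, threshold: float, window: int = 3) -> list[Detection]:
    """Local maxima above ``threshold`` with intensity-weighted sub-pixel
    centroids computed in a ``(2*window+1)``-pixel box."""
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a single 2-D frame")
    local_max = (img == maximum_filter(img, size=3)) & (img > threshold)
    ys, xs = np.nonzero(local_max)
    detections = []
    ny, nx = img.shape
    for y0, x0 in zip(ys, xs):
        y_lo, y_hi = max(y0 - window, 0), min(y0 + window + 1, ny)
        x_lo, x_hi = max(x0 - window, 0), min(x0 + window + 1, nx)
        patch = img[y_lo:y_hi, x_lo:x_hi]
        patch = np.clip(patch - np.median(img), 0.0, None)
        total = patch.sum()
        if total <= 0:
            continue
        yy, xx = np.mgrid[y_lo:y_hi, x_lo:x_hi]
        detections.append(
            Detection(
                frame=0,
                x=float((patch * xx).sum() / total),
                y=float((patch * yy).sum() / total),
                intensity=float(img[y0, x0]),
            )
        )
    return detections


def link_tracks(
    detections_per_frame: Sequence[Sequence[Detection]],
    max_disp_um: float,
    pixel_size_um: float = 0.107,
    max_gap: int = 1,
) -> list[Track]:
    """Gated greedy nearest-neighbor linking with one-frame gap bridging.

    Assignments are made in order of increasing displacement (one-to-one);
    detections left unmatched start new tracks.  A track missing for up to
    ``max_gap`` frames may be resumed; the gap is linearly interpolated.
    """
    if len(detections_per_frame) < 2:
        raise ValueError("need at least 2 frames")
    active: list[dict] = []
    done: list[dict] = []
    next_id = 0
    for fi, dets in enumerate(detections_per_frame):
        pts = np.array([[d.x, d.y] for d in dets], dtype=float) * pixel_size_um
        cand = [tr for tr in active if fi - tr["frames"][-1] <= max_gap + 1]
        for tr in active:
            if tr not in cand:
                done.append(tr)
        active = cand
        assigned_tr: set[int] = set()
        assigned_pt: set[int] = set()
        if active and len(pts):
            costs = []
            for ti, tr in enumerate(active):
                last = tr["xy"][-1]
                gap = fi - tr["frames"][-1]
                for pi, p in enumerate(pts):
                    d = np.linalg.norm(p - last)
                    if d <= max_disp_um * gap:
                        costs.append((d, ti, pi))
            for d, ti, pi in sorted(costs):
                if ti in assigned_tr or pi in assigned_pt:
                    continue
                tr = active[ti]
                gap = fi - tr["frames"][-1]
                if gap > 1:  # bridge: interpolate the missing frame(s)
                    last = tr["xy"][-1]
                    for g in range(1, gap):
                        tr["frames"].append(tr["frames"][-1] + 1)
                        tr["xy"].append(last + (pts[pi] - last) * g / gap)
                tr["frames"].append(fi)
                tr["xy"].append(pts[pi])
                assigned_tr.add(ti)
                assigned_pt.add(pi)
        for pi, p in enumerate(pts):
            if pi not in assigned_pt:
                active.append({"id": next_id, "frames": [fi], "xy": [p]})
                next_id += 1
    done.extend(active)
    return [
        Track(id=tr["id"], frames=np.array(tr["frames"]), xy_um=np.array(tr["xy"]))
        for tr in sorted(done, key=lambda t: t["id"])
    ]


def correct_drift(
    frames: np.ndarray, upsample: int = 20, min_confidence: float = 0.2
) -> np.ndarray:
    """Cumulative per-frame (dx, dy) drift in pixels from consecutive-frame
    cross-correlation (sub-pixel by upsampled correlation).

    A frame pair whose normalized correlation peak falls below
    ``min_confidence`` contributes zero offset with a warning.
    """
    stack = np.asarray(frames, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError("need a (n_frames, ny, nx) stack with >= 2 frames")
    offsets = np.zeros((stack.shape[0], 2))
    for i in range(1, stack.shape[0]):
        a = stack[i - 1] - stack[i - 1].mean()
        b = stack[i] - stack[i].mean()
        denom = np.sqrt((a**2).sum() * (b**2).sum())
        if denom <= 0:
            conf = 0.0
        else:
            corr = np.fft.irfft2(np.fft.rfft2(a) * np.conj(np.fft.rfft2(b)))
            conf = corr.max() / denom
        if conf < min_confidence:
            warnings.warn(f"low correlation between frames {i-1} and {i}; "
                          "zero offset assumed", RuntimeWarning)
            shift = np.zeros(2)
        else:
            shift, _, _ = phase_cross_correlation(a, b, upsample_factor=upsample)
            shift = -shift[::-1]  # (dy, dx) of b relative to a -> (dx, dy) drift
        offsets[i] = offsets[i - 1] + shift
    return offsets


def five_point_velocity(track: Track | np.ndarray, dt: float) -> np.ndarray:
    """Central five-point derivative of position,
    v(t) = [-x(t+2dt) + 8 x(t+dt) - 8 x(t-dt) + x(t-2dt)] / (12 dt);
    exact for polynomials up to degree 4.  Endpoints (2-frame margins) are NaN.
    """
    x = track.xy_um if isinstance(track, Track) else np.asarray(track, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n = x.shape[0]
    if n < 5:
        raise ValueError("need at least 5 consecutive frames")
    v = np.full_like(x, np.nan, dtype=float)
    v[2:-2] = (-x[4:] + 8 * x[3:-1] - 8 * x[1:-3] + x[:-4]) / (12.0 * dt)
    return v


def _velocity_correlation(pa: np.ndarray, pb: np.ndarray, dt: float) -> float:
    """Correlation of the two sisters' frame-to-frame displacement vectors."""
    va = np.diff(pa, axis=0)
    vb = np.diff(pb, axis=0)
    ok = ~np.isnan(va).any(axis=1) & ~np.isnan(vb).any(axis=1)
    va, vb = va[ok], vb[ok]
    if len(va) < 3:
        return -np.inf
    num = np.sum(va * vb)
    den = np.sqrt(np.sum(va**2) * np.sum(vb**2))
    return float(num / den) if den > 0 else -np.inf


def pair_sisters(
    tracks: Sequence[Track],
    dist_range_um: tuple[float, float] = (0.5, 2.5),
    min_vel_corr: float = 0.5,
    min_covisible: int = 5,
    dt: float = 1.0,
) -> tuple[list[SisterPair], list[Track]]:
    """Pair tracks whose mean separation and velocity correlation pass gates.

    Candidate pairs are scored by velocity correlation; conflicts are resolved
    by maximum-weight matching on the candidate graph, so each track joins at
    most one pair and the total correlation is maximal.  Returns
    (pairs, unpaired).
    """
    import networkx as nx

    candidates = {}
    for i in range(len(tracks)):
        for j in range(i + 1, len(tracks)):
            common = np.intersect1d(tracks[i].frames, tracks[j].frames)
            if len(common) < min_covisible:
                continue
            pa = tracks[i].positions_at(common)
            pb = tracks[j].positions_at(common)
            sep = np.linalg.norm(pa - pb, axis=1)
            if not (dist_range_um[0] <= np.nanmean(sep) <= dist_range_um[1]):
                continue
            corr = _velocity_correlation(pa, pb, dt)
            if corr >= min_vel_corr:
                candidates[(i, j)] = (corr, common, sep)
    graph = nx.Graph()
    for (i, j), (corr, _, _) in candidates.items():
        graph.add_edge(i, j, weight=corr - min_vel_corr + 1e-6)
    used: set[int] = set()
    pairs = []
    for i, j in sorted(tuple(sorted(e)) for e in nx.max_weight_matching(graph)):
        corr, common, sep = candidates[(i, j)]
        used.update((i, j))
        pairs.append(SisterPair(track_a=tracks[i], track_b=tracks[j],
                                frames=common, kk_um=sep))
    unpaired = [t for k, t in enumerate(tracks) if k not in used]
    return pairs, unpaired


def classify_pair(
    pair: SisterPair,
    plate: tuple[np.ndarray, np.ndarray] | None = None,
    pole: np.ndarray | None = None,
    dt: float = 1.0,
    centered_um: float = 1.0,
    off_centered_um: float = 2.5,
) -> SisterPair:
    """Attach per-frame labels to a sister pair.

    leading/trailing: the sister in front of the pair-center motion projected
    on the pair axis leads.  centered/off_centered/mid: distance from the
    metaphase plate (supplied as a point and unit normal) below
    ``centered_um`` / above ``off_centered_um`` / between.  poleward /
    anti_poleward: the sister nearer ``pole`` (monopolar spindles).
    """
    if plate is None and pole is None:
        raise ValueError("supply plate geometry and/or a pole position")
    pa = pair.track_a.positions_at(pair.frames)
    pb = pair.track_b.positions_at(pair.frames)
    center = (pa + pb) / 2
    axis = pa - pb
    norm = np.linalg.norm(axis, axis=1, keepdims=True)
    axis = axis / np.where(norm > 0, norm, 1.0)
    vel = np.gradient(center, dt, axis=0)
    v_axial = np.sum(vel * axis, axis=1)
    rows: dict[str, list] = {"frame": list(pair.frames)}
    # sister a is ahead of the center motion when v_axial > 0
    rows["leading"] = ["a" if v > 0 else "b" if v < 0 else "tie" for v in v_axial]
    if plate is not None:
        point, normal = (np.asarray(p, dtype=float) for p in plate)
        normal = normal / np.linalg.norm(normal)
        for name, p in (("a", pa), ("b", pb)):
            d = np.abs((p - point) @ normal)
            rows[f"plate_{name}"] = [
                "centered" if di < centered_um
                else "off_centered" if di > off_centered_um
                else "mid"
                for di in d
            ]
    if pole is not None:
        pole = np.asarray(pole, dtype=float)
        da = np.linalg.norm(pa - pole, axis=1)
        db = np.linalg.norm(pb - pole, axis=1)
        rows["poleward"] = ["a" if x < y else "b" for x, y in zip(da, db)]
    pair.labels = pd.DataFrame(rows)
    return pair


def group_stats(
    items: Sequence,
    values: Sequence[float],
    variable: str,
    n_groups: int,
) -> list[KinetochoreGroup]:
    """Equal-count quantile grouping with per-group mean, SEM and IQR.

    ``values`` is the grouping variable evaluated per item.  Identical values
    collapse into a single effective group.
    """
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    values = np.asarray(values, dtype=float)
    if len(values) < n_groups:
        raise ValueError("fewer items than groups")
    edges = np.unique(np.quantile(values, np.linspace(0, 1, n_groups + 1)))
    if len(edges) == 1:  # all values identical: one effective group
        edges = np.array([edges[0], edges[0]])
    bins = np.clip(np.searchsorted(edges, values, side="right") - 1, 0, len(edges) - 2)
    groups = []
    for b in range(len(edges) - 1):
        mask = bins == b
        if not mask.any():
            continue
        v = values[mask]
        groups.append(
            KinetochoreGroup(
                members=[it for it, m in zip(items, mask) if m],
                variable=variable,
                mean=float(v.mean()),
                sem=float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0,
                iqr=(float(np.percentile(v, 25)), float(np.percentile(v, 75))),
                values=v,
            )
        )
    return groups
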