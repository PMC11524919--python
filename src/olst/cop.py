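"""Center-of-pressure trajectory estimation and sway features.

The COP of each pressure frame is the pressure-weighted centroid of the
active cells.  Per trial, the plantar contact region is summarized by
its pressure-weighted second-moment ellipse and the trajectory is
rotated into a foot-aligned frame: the ellipse major axis becomes the Y
(anteroposterior) axis and the minor axis the X (mediolateral) axis.

Sway features follow the standard posturography definitions: total
sway-path length, mean sway speed, approximate entropy (Pincus ApEn,
m=2, r=0.2*SD per axis, averaged over axes), convex-hull sway area, and
the mediolateral distance between the keypoint-derived center of mass
and the COP.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .errors import InsufficientDataError
from .records import KeypointSeries, PressureFrameSeries, TrialRecording

logger = logging.getLogger(__name__)

#: Dempster segment mass fractions used for the 2-D center of mass.
#: Segments are straight lines between landmarks; each contributes its
#: midpoint weighted by the fraction.  Fractions sum to 1.
SEGMENT_MASS_FRACTIONS: tuple[tuple[str, str, float], ...] = (
    ("nose", "neck", 0.081),            # head + neck
    ("neck", "mid_hip", 0.497),         # trunk
    ("right_shoulder", "right_elbow", 0.028),
    ("left_shoulder", "left_elbow", 0.028),
    ("right_elbow", "right_wrist", 0.022),   # forearm + hand
    ("left_elbow", "left_wrist", 0.022),
    ("right_hip", "right_knee", 0.100),
    ("left_hip", "left_knee", 0.100),
    ("right_knee", "right_ankle", 0.061),    # shank + foot
    ("left_knee", "left_ankle", 0.061),
)


@dataclass
class FootEllipse:
    center: tuple[float, float]     # cm, mat frame
    major: float                    # semi-axis, cm
    minor: float
    angle: float                    # rad, major axis vs mat +y axis


@dataclass
class CopTrajectory:
    """COP path in the foot-aligned frame (y along the foot major axis)."""

    timestamps: np.ndarray
    points: np.ndarray              # (n, 2) cm
    valid: np.ndarray               # (n,) bool
    ellipse: FootEllipse

    @property
    def x(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.points[:, 1]

    def in_window(self, window: tuple[float, float]) -> "CopTrajectory":
        m = (self.timestamps >= window[0]) & (self.timestamps < window[1])
        return CopTrajectory(self.timestamps[m], self.points[m],
                             self.valid[m], self.ellipse)


def compute_cop_trajectory(series: PressureFrameSeries,
                           active_frac: float = 0.05,
                           total_frac: float = 0.10,
                           min_active: int = 3) -> CopTrajectory:
    """Estimate the COP path and foot-aligned frame from pressure frames.

    A cell is active when its pressure exceeds ``active_frac`` of its
    frame's maximum; a frame is valid when its total pressure exceeds
    ``total_frac`` of the trial's median frame total and it has at least
    ``min_active`` active cells.
    """
    n = series.n_frames
    x_all, y_all = series.cell_xy()
    v = series.values
    fi = series.frame_index

    frame_max = np.zeros(n)
    np.maximum.at(frame_max, fi, v)
    active = v > active_frac * frame_max[fi]

    w = np.where(active, v, 0.0)
    tot = np.bincount(fi, weights=w, minlength=n)
    n_active = np.bincount(fi, weights=active.astype(float), minlength=n)
    sx = np.bincount(fi, weights=w * x_all, minlength=n)
    sy = np.bincount(fi, weights=w * y_all, minlength=n)

    median_tot = np.median(tot)
    valid = (tot > total_frac * median_tot) & (n_active >= min_active) & (tot > 0)
    if not valid.any():
        raise InsufficientDataError("all pressure frames invalid")

    cop = np.full((n, 2), np.nan)
    nz = tot > 0
    cop[nz, 0] = sx[nz] / tot[nz]
    cop[nz, 1] = sy[nz] / tot[nz]

    # pooled pressure-weighted second-moment ellipse over valid frames
    pool = active & valid[fi]
    wp = v[pool]
    xp, yp = x_all[pool], y_all[pool]
    W = wp.sum()
    cx, cy = (wp * xp).sum() / W, (wp * yp).sum() / W
    dx, dy = xp - cx, yp - cy
    cxx = (wp * dx * dx).sum() / W
    cyy = (wp * dy * dy).sum() / W
    cxy = (wp * dx * dy).sum() / W
    cov = np.array([[cxx, cxy], [cxy, cyy]])
    evals, evecs = np.linalg.eigh(cov)           # ascending
    major_vec = evecs[:, 1]
    if major_vec[1] < 0:                         # orient toward +y
        major_vec = -major_vec
    angle = float(np.arctan2(major_vec[0], major_vec[1]))  # vs +y axis
    ellipse = FootEllipse(center=(float(cx), float(cy)),
                          major=float(2.0 * np.sqrt(max(evals[1], 0.0))),
                          minor=float(2.0 * np.sqrt(max(evals[0], 0.0))),
                          angle=angle)

    # rotate so the major axis is the Y axis of the trajectory frame
    minor_vec = np.array([major_vec[1], -major_vec[0]])
    R = np.stack([minor_vec, major_vec])          # rows: new x, new y
    pts = (cop - np.array([cx, cy])) @ R.T
    pts[~valid] = np.nan
    return CopTrajectory(series.timestamps.copy(), pts, valid, ellipse)


def sway_path_metrics(traj: CopTrajectory,
                      window: tuple[float, float] | None = None
                      ) -> tuple[float, float]:
    """(total sway-path length cm, mean sway speed cm/s) over the window."""
    t = traj.in_window(window) if window is not None else traj
    pts = t.points[t.valid]
    ts = t.timestamps[t.valid]
    if len(pts) < 2:
        raise InsufficientDataError("need >= 2 valid COP points")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    length = float(seg.sum())
    elapsed = float(ts[-1] - ts[0])
    return length, length / elapsed


def approximate_entropy(x: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """Pincus approximate entropy ApEn(m, r) of a 1-D series.

    Chebyshev distance, self-matches included.  ``r`` is an absolute
    tolerance; if the series is (near-)constant so that r <= 0, returns
    0 by convention.
    """
    x = np.asarray(x, dtype=float)
    N = x.size
    if N < m + 2:
        raise InsufficientDataError(f"ApEn needs length >= {m + 2}, got {N}")
    if r is None:
        r = 0.2 * float(np.std(x))
    if r <= 0:
        logger.info("ApEn: zero tolerance (constant series); returning 0")
        return 0.0

    def phi(mm: int) -> float:
        k = N - mm + 1
        emb = np.lib.stride_tricks.sliding_window_view(x, mm)   # (k, mm)
        d = np.abs(emb[:, None, :] - emb[None, :, :]).max(axis=2)
        c = (d <= r).mean(axis=1)
        return float(np.log(c).mean())

    return phi(m) - phi(m + 1)


def cop_entropy(traj: CopTrajectory, window: tuple[float, float] | None = None,
                m: int = 2, r_factor: float = 0.2) -> float:
    """ApEn of COP sway: per-axis ApEn(m, r_factor*SD) averaged over X and Y."""
    t = traj.in_window(window) if window is not None else traj
    vals = []
    for axis in (0, 1):
        s = t.points[t.valid, axis]
        vals.append(approximate_entropy(s, m=m, r=r_factor * float(np.std(s))))
    return float(np.mean(vals))


def convex_hull_area(points: np.ndarray) -> float:
    """Area (cm^2) of the convex hull of 2-D points; degenerate sets -> 0."""
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if pts.shape[0] == 0:
        raise InsufficientDataError("convex hull of empty point set")
    uniq = np.unique(pts, axis=0)
    if uniq.shape[0] < 3:
        return 0.0
    try:
        return float(ConvexHull(uniq).volume)    # "volume" is area in 2-D
    except QhullError:
        return 0.0                               # collinear


def cop_hull_area(traj: CopTrajectory,
                  window: tuple[float, float] | None = None) -> float:
    t = traj.in_window(window) if window is not None else traj
    pts = t.points[t.valid]
    if len(pts) == 0:
        raise InsufficientDataError("no valid COP points in window")
    return convex_hull_area(pts)


def com_series(kp: KeypointSeries, conf_threshold: float = 0.1
               ) -> tuple[np.ndarray, np.ndarray]:
    """Mediolateral center-of-mass series (cm) and per-frame validity.

    COM is the mass-fraction-weighted mean of segment midpoints in image
    x, converted to cm.  A frame is valid when every required landmark
    has confidence >= ``conf_threshold``.
    """
    from .records import LANDMARK_INDEX
    names = sorted({n for a, b, _ in SEGMENT_MASS_FRACTIONS for n in (a, b)})
    idx = [LANDMARK_INDEX[n] for n in names]
    conf_ok = (kp.data[:, idx, 2] >= conf_threshold).all(axis=1)
    com_x = np.zeros(kp.n_frames)
    for a, b, frac in SEGMENT_MASS_FRACTIONS:
        xa = kp.data[:, LANDMARK_INDEX[a], 0]
        xb = kp.data[:, LANDMARK_INDEX[b], 0]
        com_x += frac * 0.5 * (xa + xb)
    return com_x / kp.px_per_cm, conf_ok


def com_cop_distance(kp: KeypointSeries, traj: CopTrajectory,
                     window: tuple[float, float] | None = None,
                     conf_threshold: float = 0.1,
                     min_valid_frac: float = 0.5) -> float:
    """Mean |COM_x - COP_x| (cm) after mean-offset alignment.

    The frontal camera provides no depth, so only the mediolateral axis
    is compared; the unknown image<->mat origin offset is removed by
    matching means over the valid frames of the window.
    """
    com_x, com_ok = com_series(kp, conf_threshold)
    if window is not None:
        m = (traj.timestamps >= window[0]) & (traj.timestamps < window[1])
    else:
        m = np.ones(traj.timestamps.size, dtype=bool)
    ok = m & com_ok & traj.valid
    if ok.sum() < max(2, min_valid_frac * m.sum()):
        raise InsufficientDataError(
            f"only {int(ok.sum())}/{int(m.sum())} frames have valid COM and COP")
    c = com_x[ok]
    p = traj.points[ok, 0]
    c = c - c.mean() + p.mean()
    return float(np.mean(np.abs(c - p)))


def max_trial_duration(trials: list[TrialRecording]) -> float:
    """Longest stand (s) across the participant's trials."""
    if not trials:
        raise InsufficientDataError("no trials")
    return float(max(t.duration for t in trials))
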