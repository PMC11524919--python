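"""Joint-angle series from 2-D keypoints and COP-angle coupling features.

Ten angles are computed per frame.  Two are inclinations against the
image horizontal (neck, shoulder line), in (-90, 90] degrees; the other
eight are interior joint angles in [0, 180] degrees (elbows, trunk
left/right, hips, knees).  Image y is flipped to point upward before
any angle math.

The coupling features are Pearson correlations between the first
difference of the mediolateral COP coordinate and the first difference
of each angle series ("change in COP" vs "change in angle").
"""
from __future__ import annotations

import logging

import numpy as np

from .cop import CopTrajectory
from .errors import FormatError, InsufficientDataError
from .records import LANDMARK_INDEX, KeypointSeries

logger = logging.getLogger(__name__)

ANGLE_NAMES: tuple[str, ...] = (
    "neck", "shoulder",
    "right_elbow", "left_elbow",
    "right_trunk", "left_trunk",
    "right_hip", "left_hip",
    "right_knee", "left_knee",
)

#: landmarks needed per angle (for confidence gating)
_ANGLE_LANDMARKS: dict[str, tuple[str, ...]] = {
    "neck": ("neck", "nose"),
    "shoulder": ("right_shoulder", "left_shoulder"),
    "right_elbow": ("right_shoulder", "right_elbow", "right_wrist"),
    "left_elbow": ("left_shoulder", "left_elbow", "left_wrist"),
    "right_trunk": ("mid_hip", "neck", "right_hip"),
    "left_trunk": ("mid_hip", "neck", "left_hip"),
    "right_hip": ("right_hip", "right_shoulder", "right_knee"),
    "left_hip": ("left_hip", "left_shoulder", "left_knee"),
    "right_knee": ("right_knee", "right_hip", "right_ankle"),
    "left_knee": ("left_knee", "left_hip", "left_ankle"),
}


class AngleSeries:
    """Per-frame values (degrees) and validity flags for the 10 angles."""

    def __init__(self, timestamps: np.ndarray, angles: dict[str, np.ndarray],
                 valid: dict[str, np.ndarray]):
        if set(angles) != set(ANGLE_NAMES):
            raise FormatError("AngleSeries requires exactly the 10 named angles")
        self.timestamps = np.asarray(timestamps, dtype=float)
        self.angles = angles
        self.valid = valid

    def __getitem__(self, name: str) -> np.ndarray:
        return self.angles[name]


def _xy_up(kp: KeypointSeries, name: str) -> np.ndarray:
    """(n, 2) landmark positions with y pointing up (image px)."""
    d = kp.data[:, LANDMARK_INDEX[name], :2].copy()
    d[:, 1] = kp.image_size[1] - d[:, 1]
    return d


def _conf(kp: KeypointSeries, name: str) -> np.ndarray:
    return kp.data[:, LANDMARK_INDEX[name], 2]


def _inclination(p_from: np.ndarray, p_to: np.ndarray) -> np.ndarray:
    """Signed inclination (deg) of the segment vs horizontal, in (-90, 90]."""
    d = p_to - p_from
    ang = np.degrees(np.arctan2(d[:, 1], d[:, 0]))
    ang = np.mod(ang + 90.0, 180.0) - 90.0
    return np.where(ang == -90.0, 90.0, ang)


def _interior(vertex: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Interior angle (deg, [0, 180]) at ``vertex`` between rays to a and b."""
    u = a - vertex
    v = b - vertex
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.einsum("ij,ij->i", u, v) / (nu * nv)
    return np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))


def compute_joint_angles(kp: KeypointSeries,
                         conf_threshold: float = 0.1) -> AngleSeries:
    """Compute the 10 joint-angle series from a keypoint series."""
    P = {n: _xy_up(kp, n) for n in
         {ln for lms in _ANGLE_LANDMARKS.values() for ln in lms}}
    angles: dict[str, np.ndarray] = {}
    angles["neck"] = _inclination(P["neck"], P["nose"])
    angles["shoulder"] = _inclination(P["right_shoulder"], P["left_shoulder"])
    for side in ("right", "left"):
        angles[f"{side}_elbow"] = _interior(
            P[f"{side}_elbow"], P[f"{side}_shoulder"], P[f"{side}_wrist"])
        angles[f"{side}_trunk"] = _interior(
            P["mid_hip"], P["neck"], P[f"{side}_hip"])
        angles[f"{side}_hip"] = _interior(
            P[f"{side}_hip"], P[f"{side}_shoulder"], P[f"{side}_knee"])
        angles[f"{side}_knee"] = _interior(
            P[f"{side}_knee"], P[f"{side}_hip"], P[f"{side}_ankle"])

    valid = {}
    for name in ANGLE_NAMES:
        ok = np.ones(kp.n_frames, dtype=bool)
        for lm in _ANGLE_LANDMARKS[name]:
            ok &= _conf(kp, lm) >= conf_threshold
        ok &= np.isfinite(angles[name])
        valid[name] = ok
    return AngleSeries(kp.timestamps.copy(), angles, valid)


def diff_correlation(a: np.ndarray, b: np.ndarray,
                     valid_a: np.ndarray | None = None,
                     valid_b: np.ndarray | None = None
                     ) -> tuple[float, int]:
    """Pearson correlation between the first differences of two series.

    A difference pair is used when both endpoints of both series are
    valid.  Returns ``(r, n_pairs)``; a zero-variance difference series
    gives ``(nan, n_pairs)`` (undefined correlation, logged).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise FormatError("series lengths differ")
    ok = np.isfinite(a) & np.isfinite(b)
    if valid_a is not None:
        ok &= np.asarray(valid_a, dtype=bool)
    if valid_b is not None:
        ok &= np.asarray(valid_b, dtype=bool)
    pair = ok[1:] & ok[:-1]
    da = (a[1:] - a[:-1])[pair]
    db = (b[1:] - b[:-1])[pair]
    n = int(pair.sum())
    if n < 3:
        raise InsufficientDataError(f"need >= 3 difference pairs, got {n}")
    sa, sb = da.std(), db.std()
    if sa == 0 or sb == 0:
        logger.info("diff_correlation: zero variance, correlation undefined")
        return float("nan"), n
    r = float(np.mean((da - da.mean()) * (db - db.mean())) / (sa * sb))
    return max(-1.0, min(1.0, r)), n


def cop_joint_correlations(angles: AngleSeries, traj: CopTrajectory,
                           window: tuple[float, float] | None = None,
                           cop_change: str = "x",
                           min_valid_frac: float = 0.5
                           ) -> dict[str, float]:
    """The 10 ``corr_*`` coupling features over the analysis window.

    ``cop_change`` selects the COP scalarization: mediolateral ``"x"``
    (default), anteroposterior ``"y"``, or resultant ``"magnitude"``.
    Features whose data are insufficient or degenerate come back NaN.
    """
    if window is not None:
        m = (traj.timestamps >= window[0]) & (traj.timestamps < window[1])
    else:
        m = np.ones(traj.timestamps.size, dtype=bool)
    if cop_change == "x":
        cop = traj.points[:, 0]
    elif cop_change == "y":
        cop = traj.points[:, 1]
    elif cop_change == "magnitude":
        cop = np.linalg.norm(traj.points, axis=1)
    else:
        raise FormatError(f"unknown cop_change {cop_change!r}")

    out: dict[str, float] = {}
    n_win = int(m.sum())
    for name in ANGLE_NAMES:
        ok = m & traj.valid & angles.valid[name]
        if ok.sum() < max(3, min_valid_frac * n_win):
            logger.info("corr_%s: insufficient valid frames", name)
            out[f"corr_{name}"] = float("nan")
            continue
        a = np.where(m, cop, np.nan)
        b = np.where(m, angles[name], np.nan)
        try:
            r, _ = diff_correlation(a, b, valid_a=traj.valid,
                                    valid_b=angles.valid[name])
        except InsufficientDataError:
            r = float("nan")
        out[f"corr_{name}"] = r
    return out
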