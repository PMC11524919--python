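"""Synthetic OLST cohort generator.

Real recordings of this protocol are not publicly available, so this
module generates cohorts with the statistical structure the screening
analysis assumes: children with a higher latent trait severity show

* smaller and more regular (lower-entropy) COP sway,
* shorter one-legged stands (higher fall hazard),
* stronger coupling between joint angles and COP motion,
* a severity-dependent COM-COP mismatch.

Mechanism: per trial, the COP path follows a discretized
Ornstein-Uhlenbeck process per axis, blended with a periodic component
whose weight grows with severity; pressure frames render an elliptical
plantar footprint whose pressure-weighted centroid is matched to the
simulated COP; trial duration is an exponential fall time right-censored
at the protocol cap; keypoints come from a template skeleton driven by
angle series of the form ``baseline + gain * beta(severity) * COP_x +
noise``.  Severity itself is the participant's SRS-2 percentile within
the cohort, mapped to [0, 1].

All randomness flows through a single seeded generator per cohort plus
one derived generator per participant, so identical ``(config, seed)``
produce identical cohorts.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
from scipy import stats

from .errors import ConfigError, OlstError
from .records import (LANDMARK_NAMES, KeypointSeries, ParticipantRecord,
                      PressureFrameSeries, TrialRecording)

# --------------------------------------------------------------- config


@dataclass
class SeverityEffect:
    """How the latent severity in [0, 1] shapes the balance dynamics.

    All per-severity slopes are applied to the shaped severity
    ``g = severity ** shaping``; the quadratic default concentrates the
    behavioural contrast in the high-trait tail, where the screening
    cutoff sits.
    """

    sway_sigma: float = -0.85        # cm per unit severity (negative: less sway)
    regularity_gain: float = 1.2     # periodic-component weight per unit severity
    coupling_beta: float = 14.0      # deg/cm of extra joint-COP coupling
    fall_hazard: float = 0.12        # 1/s fall hazard per unit severity
    ou_theta: float = 1.2            # 1/s mean reversion of the OU sway
    footprint_axes: tuple[float, float] = (3.5, 8.0)   # semi-axes, cm (ML, AP)
    # baselines and nuisance scales
    base_sway_sigma: float = 1.2     # cm, mediolateral stationary SD at severity 0
    ap_ratio: float = 1.4            # anteroposterior/mediolateral sway ratio
    base_coupling: float = 1.0       # deg/cm baseline joint-COP coupling
    angle_noise: float = 0.8         # deg, white noise on each angle series
    noise_damping: float = 0.6       # fractional angle-noise drop at severity 1
                                     # (more stereotyped movement)
    com_gain: float = 1.8            # COM_x excursion per cm of COP_x
    com_noise: float = 0.25          # cm, COM-only sway noise
    shaping: float = 2.0             # severity response exponent
    min_sigma: float = 0.15          # cm, floor on the sway SD
    transition_coupling: float = 1.0   # joint response share of the
                                       # weight-shift excursion

    def response(self, severity: float) -> float:
        return float(severity) ** self.shaping


def null_effect() -> SeverityEffect:
    """A severity-blind effect: every severity-dependent term is zero."""
    return SeverityEffect(sway_sigma=0.0, regularity_gain=0.0,
                          coupling_beta=0.0, fall_hazard=0.0)


@dataclass
class CohortConfig:
    """Cohort composition, protocol constants and generator dynamics."""

    n_boys: int = 64
    n_girls: int = 62
    high_frac_by_sex: dict[str, float] = field(
        default_factory=lambda: {"male": 9 / 64, "female": 10 / 62})
    srs_mean_high: float = 69.79
    srs_sd_high: float = 23.66
    srs_mean_low: float = 31.24
    srs_sd_low: float = 11.48
    cutoff_male: float = 53.5
    cutoff_female: float = 52.5
    sample_rate: float = 20.0        # Hz
    trial_cap: float = 20.0          # s
    n_trials: int = 4
    grid_cells: tuple[int, int] = (48, 48)
    sensor_size: float = 48.0        # cm
    transition_ramp: float = 0.5     # s, two-foot -> one-foot weight shift
    stance_offset: float = 4.0       # cm, standing-foot center from mat middle
    px_per_cm: float = 3.0
    image_size: tuple[int, int] = (640, 480)
    effect: SeverityEffect = field(default_factory=SeverityEffect)
    seed: int = 0

    @property
    def cell_pitch(self) -> float:
        return self.sensor_size / self.grid_cells[0]

    def validate(self) -> None:
        if self.n_boys <= 0 or self.n_girls <= 0 or self.n_trials <= 0:
            raise ConfigError("counts must be positive")
        if self.sample_rate <= 0 or self.trial_cap <= 0:
            raise ConfigError("sample_rate and trial_cap must be positive")
        for sex, frac in self.high_frac_by_sex.items():
            if not 0 <= frac <= 1:
                raise ConfigError(f"high_frac_by_sex[{sex!r}] outside [0, 1]")
        if self.grid_cells[0] < 8 or self.grid_cells[1] < 8:
            raise ConfigError("grid must be at least 8x8")
        if self.effect.fall_hazard < 0:
            raise ConfigError("fall_hazard must be >= 0")
        if self.effect.ou_theta <= 0:
            raise ConfigError("ou_theta must be positive")
        a, b = self.effect.footprint_axes
        if a <= 0 or b <= 0 or \
                2 * max(a, b) + self.stance_offset > self.sensor_size / 2:
            raise ConfigError("footprint does not fit within the sensor")


def default_config() -> CohortConfig:
    """Configuration matching the study protocol: 64 boys + 62 girls,
    SRS-2 group parameters 69.79 (23.66) high / 31.24 (11.48) low,
    cutoffs 53.5 (boys) / 52.5 (girls), 20 Hz, four trials capped at
    20 s on a 48-cm mat, with the documented strong severity effects."""
    return CohortConfig()


def null_config() -> CohortConfig:
    """Default protocol but with all severity effects zeroed (for
    calibration checks: features carry no group signal)."""
    return replace(default_config(), effect=null_effect())


# ------------------------------------------------------ pressure render

def _ellipse_cells(cfg: CohortConfig, center: tuple[float, float],
                   axes: tuple[float, float], phi: float
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Grid cells inside an ellipse; returns (rows, cols, x_cm, y_cm)."""
    nr, nc = cfg.grid_cells
    pitch = cfg.cell_pitch
    rows, cols = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    rows, cols = rows.ravel(), cols.ravel()
    x = (cols + 0.5) * pitch - nc * pitch / 2.0
    y = nr * pitch / 2.0 - (rows + 0.5) * pitch
    dx, dy = x - center[0], y - center[1]
    c, s = math.cos(phi), math.sin(phi)
    u = c * dx + s * dy          # mediolateral in foot frame
    v = -s * dx + c * dy         # anteroposterior
    inside = (u / axes[0]) ** 2 + (v / axes[1]) ** 2 <= 1.0
    return rows[inside], cols[inside], x[inside], y[inside]


def _match_centroids(xc: np.ndarray, yc: np.ndarray, base: np.ndarray,
                     tx: np.ndarray, ty: np.ndarray, tol: float,
                     max_iter: int = 12) -> np.ndarray:
    """Reweight per-frame cell pressures so each frame's weighted
    centroid lands on its target, keeping pressures non-negative.

    Each iteration applies the multiplicative linear tilt whose first
    order effect moves the centroid exactly onto the target.
    """
    p = base.copy()
    if p.shape[0] == 0:
        return p
    for _ in range(max_iter):
        W = p.sum(axis=1)
        xb = (p * xc).sum(axis=1) / W
        yb = (p * yc).sum(axis=1) / W
        ex, ey = tx - xb, ty - yb
        if max(np.abs(ex).max(), np.abs(ey).max()) < tol:
            break
        dx = xc[None, :] - xb[:, None]
        dy = yc[None, :] - yb[:, None]
        sxx = (p * dx * dx).sum(axis=1)
        syy = (p * dy * dy).sum(axis=1)
        sxy = (p * dx * dy).sum(axis=1)
        det = np.maximum(sxx * syy - sxy ** 2, 1e-12)
        a = W * (ex * syy - ey * sxy) / det
        b = W * (ey * sxx - ex * sxy) / det
        p = p * np.clip(1.0 + a[:, None] * dx + b[:, None] * dy, 0.02, None)
    return p


# ------------------------------------------------------------- skeleton

_BASE_ANGLES = {
    "neck": 30.0, "shoulder": 0.0,
    "right_elbow": 150.0, "left_elbow": 145.0,
    "right_trunk": 105.0, "left_trunk": 105.0,
    "right_hip": 160.0, "left_hip": 158.0,
    "right_knee": 168.0, "left_knee": 168.0,
}

#: deg of angle change per deg/cm coupling unit per cm of COP_x
_COUPLING_GAINS = {
    "neck": 0.5, "shoulder": 1.0,
    "right_elbow": 0.4, "left_elbow": -0.4,
    "right_trunk": 0.8, "left_trunk": -0.8,
    "right_hip": 0.7, "left_hip": -0.6,
    "right_knee": 0.6, "left_knee": -0.5,
}

_SEG = dict(trunk=33.0, head=15.0, half_shoulder=11.0, hip_off=8.0,
            upper_arm=15.0, forearm=14.0, thigh=24.0, shank=23.0,
            hip_height=55.0)


def _rot(theta_deg: np.ndarray, vx: np.ndarray, vy: np.ndarray
         ) -> tuple[np.ndarray, np.ndarray]:
    t = np.radians(theta_deg)
    c, s = np.cos(t), np.sin(t)
    return c * vx - s * vy, s * vx + c * vy


def skeleton_from_angles(angles: dict[str, np.ndarray], body_x_cm: np.ndarray,
                         cfg: CohortConfig, lifted: str,
                         arm_abduction: float = 12.0,
                         trunk_tilt: np.ndarray | float = 0.0) -> np.ndarray:
    """Forward-kinematics template realizing the 10 target angle series.

    Returns keypoint positions (n, 15, 2) in image pixels (y down).  By
    construction :func:`olst.kinematics.compute_joint_angles` recovers
    the input angles (inclinations exactly, interior angles up to the
    arccos sign ambiguity, which the construction keeps on one branch).
    """
    n = body_x_cm.size
    pts = {}
    tilt = np.broadcast_to(np.asarray(trunk_tilt, dtype=float), (n,)).copy()

    mh_x = body_x_cm
    mh_y = np.full(n, _SEG["hip_height"])
    pts["mid_hip"] = (mh_x, mh_y)
    ux, uy = _rot(tilt, np.zeros(n), np.ones(n))            # trunk midline
    nk_x, nk_y = mh_x + _SEG["trunk"] * ux, mh_y + _SEG["trunk"] * uy
    pts["neck"] = (nk_x, nk_y)

    eta = np.radians(angles["neck"])
    pts["nose"] = (nk_x + _SEG["head"] * np.cos(eta),
                   nk_y + _SEG["head"] * np.sin(eta))

    sig = np.radians(angles["shoulder"])
    hw = _SEG["half_shoulder"]
    pts["right_shoulder"] = (nk_x - hw * np.cos(sig), nk_y - hw * np.sin(sig))
    pts["left_shoulder"] = (nk_x + hw * np.cos(sig), nk_y + hw * np.sin(sig))

    hx_r, hy_r = _rot(angles["right_trunk"], ux, uy)        # CCW -> -x side
    hx_l, hy_l = _rot(-angles["left_trunk"], ux, uy)
    pts["right_hip"] = (mh_x + _SEG["hip_off"] * hx_r, mh_y + _SEG["hip_off"] * hy_r)
    pts["left_hip"] = (mh_x + _SEG["hip_off"] * hx_l, mh_y + _SEG["hip_off"] * hy_l)

    for side, s in (("right", 1.0), ("left", -1.0)):
        sx, sy = pts[f"{side}_shoulder"]
        dx, dy = _rot(np.full(n, -s * arm_abduction), np.zeros(n), -np.ones(n))
        ex, ey = sx + _SEG["upper_arm"] * dx, sy + _SEG["upper_arm"] * dy
        pts[f"{side}_elbow"] = (ex, ey)
        ux_es, uy_es = (sx - ex) / _SEG["upper_arm"], (sy - ey) / _SEG["upper_arm"]
        wx, wy = _rot(s * angles[f"{side}_elbow"], ux_es, uy_es)
        pts[f"{side}_wrist"] = (ex + _SEG["forearm"] * wx, ey + _SEG["forearm"] * wy)

        hx, hy = pts[f"{side}_hip"]
        dhs_x, dhs_y = sx - hx, sy - hy
        nrm = np.hypot(dhs_x, dhs_y)
        kx, ky = _rot(s * angles[f"{side}_hip"], dhs_x / nrm, dhs_y / nrm)
        knx, kny = hx + _SEG["thigh"] * kx, hy + _SEG["thigh"] * ky
        pts[f"{side}_knee"] = (knx, kny)
        ukh_x, ukh_y = (hx - knx) / _SEG["thigh"], (hy - kny) / _SEG["thigh"]
        ax, ay = _rot(s * angles[f"{side}_knee"], ukh_x, ukh_y)
        pts[f"{side}_ankle"] = (knx + _SEG["shank"] * ax, kny + _SEG["shank"] * ay)

    w_px, h_px = cfg.image_size
    data = np.empty((n, len(LANDMARK_NAMES), 2))
    for j, name in enumerate(LANDMARK_NAMES):
        x_cm, y_cm = pts[name]
        data[:, j, 0] = cfg.px_per_cm * x_cm + w_px / 2.0
        data[:, j, 1] = h_px - cfg.px_per_cm * y_cm
    return data


# ---------------------------------------------------------------- trial

def _ou_path(n: int, dt: float, theta: float, sigma: float,
             rng: np.random.Generator) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck sample path (exact discretization)."""
    a = math.exp(-theta * dt)
    s = sigma * math.sqrt(1.0 - a * a)
    x = np.empty(n)
    x[0] = sigma * rng.standard_normal()
    eps = rng.standard_normal(n - 1) if n > 1 else np.empty(0)
    for i in range(1, n):
        x[i] = a * x[i - 1] + s * eps[i - 1]
    return x


def simulate_trial(severity: float, leg: str, cfg: CohortConfig,
                   rng: np.random.Generator,
                   return_info: bool = False):
    """Simulate one one-legged standing trial at the given severity.

    Returns a :class:`TrialRecording`; with ``return_info`` also a dict
    holding the simulated COP target (mat frame), the foot-frame
    mediolateral COP used for coupling, and the driving angle series.
    """
    if not 0.0 <= severity <= 1.0:
        raise OlstError(f"severity must be in [0, 1], got {severity}")
    cfg.validate()
    eff = cfg.effect
    g = eff.response(severity)
    fs, dt = cfg.sample_rate, 1.0 / cfg.sample_rate

    hazard = eff.fall_hazard * g
    if hazard > 0:
        duration = min(float(rng.exponential(1.0 / hazard)), cfg.trial_cap)
    else:
        duration = cfg.trial_cap
    n = max(int(round(duration * fs)), 10)
    duration = n / fs
    ts = np.arange(n) * dt

    # --- COP path in the foot frame -----------------------------------
    sigma_x = max(eff.base_sway_sigma + eff.sway_sigma * g, eff.min_sigma)
    sigma_y = sigma_x * eff.ap_ratio
    rho = min(max(eff.regularity_gain * g, 0.0), 0.95)
    freq = rng.uniform(0.6, 1.0)
    sway = np.empty((n, 2))
    for axis, sig in ((0, sigma_x), (1, sigma_y)):
        ou = _ou_path(n, dt, eff.ou_theta, sig, rng)
        phase = rng.uniform(0, 2 * np.pi)
        per = sig * math.sqrt(2.0) * np.sin(2 * np.pi * freq * ts + phase)
        sway[:, axis] = (1.0 - rho) * ou + rho * per
    ax_len, ay_len = eff.footprint_axes
    np.clip(sway[:, 0], -0.62 * ax_len, 0.62 * ax_len, out=sway[:, 0])
    np.clip(sway[:, 1], -0.62 * ay_len, 0.62 * ay_len, out=sway[:, 1])

    # --- foot placement and mat-frame target --------------------------
    x0 = cfg.stance_offset if leg == "right" else -cfg.stance_offset
    phi = math.radians(rng.normal(0.0, 5.0))        # foot long-axis vs mat +y
    c, s = math.cos(phi), math.sin(phi)
    # foot frame u (ML) along rotated x, v (AP) along rotated y
    target = np.empty((n, 2))
    target[:, 0] = x0 + c * sway[:, 0] - s * sway[:, 1]
    target[:, 1] = s * sway[:, 0] + c * sway[:, 1]

    ramp_n = min(int(round(cfg.transition_ramp * fs)), n)
    lam = np.zeros(n)
    if ramp_n > 0:
        lam[:ramp_n] = 0.5 * (1.0 - ts[:ramp_n] / cfg.transition_ramp)
        target[:ramp_n, 0] += lam[:ramp_n] * 2.0 * (-x0)   # toward two-foot midpoint
    # mediolateral weight-shift excursion in the foot frame (drives the
    # posture response during the two-to-one-foot transfer)
    shift_u = c * lam * 2.0 * (-x0)

    # --- render pressure frames ---------------------------------------
    st_rows, st_cols, st_x, st_y = _ellipse_cells(
        cfg, (x0, 0.0), (ax_len, ay_len), phi)
    tol = 0.45 * cfg.cell_pitch

    def gaussian_base(xc, yc, tx, ty):
        dx = xc[None, :] - tx[:, None]
        dy = yc[None, :] - ty[:, None]
        u = c * dx + s * dy
        v = -s * dx + c * dy
        return np.exp(-(u ** 2 / (2 * 2.0 ** 2) + v ** 2 / (2 * 4.5 ** 2)))

    main = slice(ramp_n, n)
    base_main = gaussian_base(st_x, st_y, target[main, 0], target[main, 1])
    base_main /= base_main.sum(axis=1, keepdims=True)   # constant body weight
    p_main = _match_centroids(st_x, st_y, base_main,
                              target[main, 0], target[main, 1], tol)

    if ramp_n > 0:
        lf_rows, lf_cols, lf_x, lf_y = _ellipse_cells(
            cfg, (-x0, 0.0), (ax_len, ay_len), -phi)
        u_rows = np.concatenate([st_rows, lf_rows])
        u_cols = np.concatenate([st_cols, lf_cols])
        u_x = np.concatenate([st_x, lf_x])
        u_y = np.concatenate([st_y, lf_y])
        base_st = gaussian_base(st_x, st_y, target[:ramp_n, 0], target[:ramp_n, 1])
        dxl = lf_x[None, :] + x0
        dyl = lf_y[None, :]
        base_lf = np.exp(-(dxl ** 2 / (2 * 2.0 ** 2) + dyl ** 2 / (2 * 4.5 ** 2)))
        base_lf = np.broadcast_to(base_lf, (ramp_n, lf_x.size)).copy()
        wst = base_st.sum(axis=1, keepdims=True)
        wlf = base_lf.sum(axis=1, keepdims=True)
        base = np.concatenate(
            [(1 - lam[:ramp_n, None]) * base_st / wst,
             lam[:ramp_n, None] * base_lf / wlf], axis=1)
        p_ramp = _match_centroids(u_x, u_y, base,
                                  target[:ramp_n, 0], target[:ramp_n, 1], tol)
    else:
        u_rows, u_cols = st_rows, st_cols
        p_ramp = np.empty((0, st_x.size))

    scale = 50.0 * (1.0 + 0.03 * rng.standard_normal(n))[:, None]

    def sparsify(pmat, rows_, cols_, frame0):
        pmat = pmat * scale[frame0:frame0 + pmat.shape[0]]
        keep = pmat > 1e-3 * pmat.max(axis=1, keepdims=True)
        fidx, cidx = np.nonzero(keep)
        return (fidx + frame0, rows_[cidx], cols_[cidx], pmat[keep])

    f1, r1, c1, v1 = sparsify(p_ramp, u_rows, u_cols, 0)
    f2, r2, c2, v2 = sparsify(p_main, st_rows, st_cols, ramp_n)
    order = np.argsort(np.concatenate([f1, f2]), kind="stable")
    pressure = PressureFrameSeries(
        timestamps=ts,
        frame_index=np.concatenate([f1, f2])[order],
        rows=np.concatenate([r1, r2])[order],
        cols=np.concatenate([c1, c2])[order],
        values=np.concatenate([v1, v2])[order],
        grid_shape=cfg.grid_cells, cell_pitch=cfg.cell_pitch)

    # --- keypoints ----------------------------------------------------
    beta = eff.base_coupling + eff.coupling_beta * g
    cop_x_foot = sway[:, 0].copy()
    # joints respond to the sway plus the weight-shift excursion: the
    # feed-forward transfer moves COP and posture together
    drive = cop_x_foot + eff.transition_coupling * shift_u
    lifted = "left" if leg == "right" else "right"
    angles = {}
    for name, base_deg in _BASE_ANGLES.items():
        jitter = rng.normal(0.0, 2.0)
        noise = eff.angle_noise * (1.0 - eff.noise_damping * g) \
            * rng.standard_normal(n)
        angles[name] = base_deg + jitter + \
            _COUPLING_GAINS[name] * beta * drive + noise
    angles[f"{lifted}_knee"] = angles[f"{lifted}_knee"] - 46.0   # flexed lifted leg
    angles[f"{lifted}_hip"] = angles[f"{lifted}_hip"] - 10.0
    for name in angles:                      # keep interior angles off the
        if name not in ("neck", "shoulder"):  # arccos folds at 0/180 deg
            np.clip(angles[name], 2.0, 178.0, out=angles[name])

    body_x = eff.com_gain * cop_x_foot + shift_u \
        + eff.com_noise * rng.standard_normal(n)
    trunk_tilt = 0.3 * cop_x_foot
    data_xy = skeleton_from_angles(angles, body_x + x0, cfg, lifted,
                                   trunk_tilt=trunk_tilt)
    conf = 1.0 - np.minimum(rng.exponential(0.03, size=data_xy.shape[:2]), 1.0)
    drop = rng.random(size=conf.shape) < 0.002
    conf[drop] *= 0.05
    kp_data = np.concatenate([data_xy, conf[:, :, None]], axis=2)
    keypoints = KeypointSeries(timestamps=ts, data=kp_data,
                               image_size=cfg.image_size,
                               px_per_cm=cfg.px_per_cm)

    trial = TrialRecording(leg=leg, duration=duration,
                           pressure=pressure, keypoints=keypoints)
    if return_info:
        return trial, {"target_cop": target, "cop_x_foot": cop_x_foot,
                       "angles": angles, "foot_angle": phi}
    return trial


# --------------------------------------------------------------- cohort

def _draw_demographics(cfg: CohortConfig, seed: int):
    rng = np.random.default_rng(seed)
    sexes = ["male"] * cfg.n_boys + ["female"] * cfg.n_girls
    cutoffs = {"male": cfg.cutoff_male, "female": cfg.cutoff_female}
    srs = np.empty(len(sexes))
    highs = np.empty(len(sexes), dtype=bool)
    for i, sex in enumerate(sexes):
        high = rng.random() < cfg.high_frac_by_sex[sex]
        cut = cutoffs[sex]
        if high:
            mu, sd = cfg.srs_mean_high, cfg.srs_sd_high
            a, b = (cut - mu) / sd, np.inf
        else:
            mu, sd = cfg.srs_mean_low, cfg.srs_sd_low
            a, b = max((0.0 - mu) / sd, -np.inf), (cut - mu) / sd
        srs[i] = stats.truncnorm.rvs(a, b, loc=mu, scale=sd, random_state=rng)
        highs[i] = high
    ages = 5.0 + rng.uniform(0.0, 0.33, size=len(sexes))
    # severity = SRS percentile within the cohort, mapped to [0, 1]
    order = np.argsort(np.argsort(srs))
    severity = order / max(len(sexes) - 1, 1)
    return sexes, srs, ages, severity


def iter_cohort(cfg: CohortConfig, seed: int) -> Iterator[ParticipantRecord]:
    """Yield participants one at a time (memory-friendly for large runs)."""
    cfg.validate()
    sexes, srs, ages, severity = _draw_demographics(cfg, seed)
    legs = ["right", "left"] * ((cfg.n_trials + 1) // 2)
    for i, sex in enumerate(sexes):
        trial_rng = np.random.default_rng([seed, i])
        trials = [simulate_trial(severity[i], legs[k], cfg, trial_rng)
                  for k in range(cfg.n_trials)]
        yield ParticipantRecord(
            id=f"P{i + 1:03d}", sex=sex, age=float(ages[i]),
            srs_total=float(srs[i]), trials=trials,
            severity=float(severity[i]))


def generate_cohort(cfg: CohortConfig, seed: int) -> list[ParticipantRecord]:
    """Generate a full synthetic cohort (deterministic in (cfg, seed))."""
    return list(iter_cohort(cfg, seed))
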