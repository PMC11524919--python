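"""Assembly of the 16-variable feature table and group assignment.

Variables fall into three categories used for model building:

* ``conventional`` — the 4 COP-sway variables (path length, mean speed,
  approximate entropy, convex-hull area) plus the 2 overall-balance
  variables (longest stand, COM-COP distance);
* ``proposed`` — the 10 COP-joint-angle coupling correlations;
* ``combined`` — all 16.

Every variable except the longest stand is computed on the first two
seconds of the participant's first trial: the two-to-one-leg weight
transfer is a feed-forward balance action whose quality separates the
groups.  High/Low autistic-trait labels come from sex-specific SRS-2
screening cutoffs (boys 53.5, girls 52.5, strict ``>``).
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import cop as _cop
from . import kinematics as _kin
from .errors import InsufficientDataError, OlstError
from .records import ParticipantRecord

logger = logging.getLogger(__name__)

SWAY_COLUMNS = ["len_total_path", "m_cop_speed", "cop_entropy", "cop_convex_hull"]
BALANCE_COLUMNS = ["len_max_trial", "com_cop_dist"]
CONVENTIONAL_COLUMNS = SWAY_COLUMNS + BALANCE_COLUMNS
PROPOSED_COLUMNS = [f"corr_{n}" for n in _kin.ANGLE_NAMES]
ALL_FEATURE_COLUMNS = CONVENTIONAL_COLUMNS + PROPOSED_COLUMNS

FEATURE_CSV_COLUMNS = ["participant_id", "sex", "srs_total", "group"] + \
    ALL_FEATURE_COLUMNS

DEFAULT_CUTOFFS = {"male": 53.5, "female": 52.5}

CATEGORIES = ("conventional", "proposed", "combined")


def category_columns(category: str) -> list[str]:
    """Feature column names belonging to a variable category."""
    if category == "conventional":
        return list(CONVENTIONAL_COLUMNS)
    if category == "proposed":
        return list(PROPOSED_COLUMNS)
    if category == "combined":
        return list(ALL_FEATURE_COLUMNS)
    raise OlstError(f"unknown category {category!r}; expected one of {CATEGORIES}")


def assign_group(sex: str, srs_total: float,
                 cutoffs: dict[str, float] = DEFAULT_CUTOFFS) -> str:
    """High/Low autistic-trait label from the sex-specific SRS-2 cutoff.

    High iff the total strictly exceeds the cutoff; the half-point
    cutoffs make ties impossible for integer-scored instruments.
    """
    if srs_total < 0:
        raise OlstError("srs_total must be non-negative")
    try:
        cut = cutoffs[sex]
    except KeyError:
        raise OlstError(f"unknown sex {sex!r}") from None
    return "High" if srs_total > cut else "Low"


def extract_features(participant: ParticipantRecord,
                     window: float = 2.0,
                     min_valid_frames: int = 10,
                     apen_m: int = 2, apen_r_factor: float = 0.2,
                     cop_change: str = "x") -> dict[str, float]:
    """The 16 explanatory variables for one participant.

    All window features come from the first ``window`` seconds of the
    first trial; ``len_max_trial`` is the longest stand over all trials.
    Unobtainable components are NaN (missing), never imputed.
    """
    feats: dict[str, float] = {c: float("nan") for c in ALL_FEATURE_COLUMNS}
    feats["len_max_trial"] = _cop.max_trial_duration(participant.trials)

    trial1 = participant.trials[0]
    win = (0.0, window)
    try:
        traj = _cop.compute_cop_trajectory(trial1.pressure)
    except InsufficientDataError:
        logger.warning("participant %s: first trial unusable", participant.id)
        return feats
    wmask = (traj.timestamps >= win[0]) & (traj.timestamps < win[1])
    if (wmask & traj.valid).sum() < min_valid_frames:
        logger.warning("participant %s: <%d valid frames in window",
                       participant.id, min_valid_frames)
        return feats

    try:
        length, speed = _cop.sway_path_metrics(traj, win)
        feats["len_total_path"] = length
        feats["m_cop_speed"] = speed
    except InsufficientDataError:
        pass
    try:
        feats["cop_entropy"] = _cop.cop_entropy(traj, win, m=apen_m,
                                                r_factor=apen_r_factor)
    except InsufficientDataError:
        pass
    try:
        feats["cop_convex_hull"] = _cop.cop_hull_area(traj, win)
    except InsufficientDataError:
        pass
    try:
        feats["com_cop_dist"] = _cop.com_cop_distance(trial1.keypoints, traj, win)
    except InsufficientDataError:
        pass

    angles = _kin.compute_joint_angles(trial1.keypoints)
    feats.update(_kin.cop_joint_correlations(angles, traj, win,
                                             cop_change=cop_change))
    return feats


def build_feature_table(cohort, window: float = 2.0,
                        cutoffs: dict[str, float] = DEFAULT_CUTOFFS,
                        **extract_kwargs) -> pd.DataFrame:
    """One row per participant: id, sex, SRS total, group label and the
    16 features.  ``cohort`` may be any iterable of participants."""
    rows = []
    for p in cohort:
        row: dict[str, object] = {
            "participant_id": p.id, "sex": p.sex, "srs_total": p.srs_total,
            "group": assign_group(p.sex, p.srs_total, cutoffs),
        }
        row.update(extract_features(p, window=window, **extract_kwargs))
        rows.append(row)
    if not rows:
        raise OlstError("empty cohort")
    return pd.DataFrame(rows, columns=FEATURE_CSV_COLUMNS)


def complete_rows(table: pd.DataFrame, category: str) -> pd.DataFrame:
    """Rows with no missing value in the category's columns (listwise
    exclusion; the dropped count is logged)."""
    cols = category_columns(category)
    keep = table[cols].notna().all(axis=1)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("category %s: excluding %d incomplete rows", category, dropped)
    return table.loc[keep].reset_index(drop=True)
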