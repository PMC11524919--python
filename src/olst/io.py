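"""On-disk formats for OLST recordings, manifests, feature tables and
model reports.

Formats
-------
Pressure CSV
    Header ``t,row,col,value`` (one row per active cell per frame,
    indices 0-based, UTF-8).  An optional leading comment line
    ``# grid=ROWSxCOLS pitch_cm=P`` carries the grid geometry; absent,
    the 48x48 / 1 cm default applies.
Keypoint JSON
    An object ``{"image_size": [w, h], "px_per_cm": s, "frames": [...]}``
    where each frame is ``{"t": seconds, "people": [{"keypoints":
    {name: [x, y, confidence]}}]}``.  A bare array of frames is also
    accepted on read, as is a directory of per-frame OpenPose BODY_25
    JSON files (read-only; only the first 15 landmarks are used).
Manifest CSV
    Header ``participant_id,sex,age,srs_total,trial1_pressure,
    trial1_keypoints,trial1_leg,...,trial4_leg``; trial paths are
    relative to the manifest location.
Feature CSV
    One row per participant with the fixed 16-variable column order
    (see :mod:`olst.features`).
"""
from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, OlstError
from .records import (LANDMARK_NAMES, KeypointSeries, ParticipantRecord,
                      PressureFrameSeries, TrialRecording)

N_TRIALS = 4

MANIFEST_COLUMNS = ["participant_id", "sex", "age", "srs_total"] + [
    f"trial{k}_{part}" for k in range(1, N_TRIALS + 1)
    for part in ("pressure", "keypoints", "leg")
]

_SEX_ALIASES = {
    "male": "male", "m": "male", "boy": "male",
    "female": "female", "f": "female", "girl": "female",
}


# ---------------------------------------------------------------- trials

def write_trial(trial: TrialRecording, directory: str | Path,
                stem: str) -> tuple[Path, Path]:
    """Write one trial as ``<stem>_pressure.csv`` + ``<stem>_keypoints.json``.

    Returns the two paths; :func:`load_trial` inverts this exactly
    (timestamps to better than 1e-9 s).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    p = trial.pressure
    if p.n_frames == 0:
        raise FormatError("refusing to write an empty trial")
    ppath = directory / f"{stem}_pressure.csv"
    kpath = directory / f"{stem}_keypoints.json"

    nr, nc = p.grid_shape
    with open(ppath, "w", encoding="utf-8") as fh:
        fh.write(f"# grid={nr}x{nc} pitch_cm={p.cell_pitch!r} "
                 f"leg={trial.leg} duration={trial.duration!r}\n")
        fh.write("t,row,col,value\n")
        t = p.timestamps[p.frame_index]
        for ti, r, c, v in zip(t.tolist(), p.rows.tolist(),
                               p.cols.tolist(), p.values.tolist()):
            fh.write(f"{ti!r},{r},{c},{v!r}\n")

    kp = trial.keypoints
    frames = []
    for i in range(kp.n_frames):
        kd = {name: [float(v) for v in kp.data[i, j]]
              for j, name in enumerate(LANDMARK_NAMES)}
        frames.append({"t": float(kp.timestamps[i]),
                       "people": [{"keypoints": kd}]})
    payload = {"image_size": list(kp.image_size),
               "px_per_cm": kp.px_per_cm,
               "frames": frames}
    with open(kpath, "w", encoding="utf-8") as fh:
        json.dump(payload, fh)
    return ppath, kpath


def _parse_pressure_csv(path: Path) -> tuple[PressureFrameSeries, str | None, float | None]:
    grid_shape, pitch = (48, 48), 1.0
    leg: str | None = None
    duration: float | None = None
    t_list, r_list, c_list, v_list = [], [], [], []
    with open(path, encoding="utf-8") as fh:
        lines = fh.readlines()
    start = 0
    if lines and lines[0].startswith("#"):
        m = re.search(r"grid=(\d+)x(\d+)", lines[0])
        if m:
            grid_shape = (int(m.group(1)), int(m.group(2)))
        m = re.search(r"pitch_cm=([0-9.eE+-]+)", lines[0])
        if m:
            pitch = float(m.group(1))
        m = re.search(r"leg=(\w+)", lines[0])
        if m:
            leg = m.group(1)
        m = re.search(r"duration=([0-9.eE+-]+)", lines[0])
        if m:
            duration = float(m.group(1))
        start = 1
    if start >= len(lines) or lines[start].strip() != "t,row,col,value":
        raise FormatError(f"{path}: expected header 't,row,col,value'")
    for ln, line in enumerate(lines[start + 1:], start=start + 2):
        line = line.strip()
        if not line:
            continue
        parts = line.split(",")
        if len(parts) != 4:
            raise FormatError(f"{path}: line {ln}: expected 4 fields")
        try:
            t, r, c, v = float(parts[0]), int(parts[1]), int(parts[2]), float(parts[3])
        except ValueError as exc:
            raise FormatError(f"{path}: line {ln}: {exc}") from None
        if v < 0:
            raise FormatError(f"{path}: line {ln}: negative pressure {v}")
        t_list.append(t); r_list.append(r); c_list.append(c); v_list.append(v)
    if not t_list:
        raise FormatError(f"{path}: no pressure data rows")
    t_arr = np.asarray(t_list)
    ts, inverse = np.unique(t_arr, return_inverse=True)
    series = PressureFrameSeries(
        timestamps=ts, frame_index=inverse,
        rows=np.asarray(r_list), cols=np.asarray(c_list),
        values=np.asarray(v_list), grid_shape=grid_shape, cell_pitch=pitch)
    return series, leg, duration


def _load_keypoint_json(path: Path) -> KeypointSeries:
    if path.is_dir():
        return _load_openpose_dir(path)
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    if isinstance(payload, list):
        frames, image_size, px_per_cm = payload, (640, 480), 3.0
    else:
        frames = payload["frames"]
        image_size = tuple(payload.get("image_size", (640, 480)))
        px_per_cm = float(payload.get("px_per_cm", 3.0))
    n = len(frames)
    ts = np.empty(n)
    data = np.zeros((n, len(LANDMARK_NAMES), 3))
    for i, fr in enumerate(frames):
        ts[i] = float(fr["t"])
        people = fr.get("people", [])
        if people:
            kps = people[0]["keypoints"]
            for name, xyc in kps.items():
                if name not in LANDMARK_NAMES:
                    raise FormatError(f"{path}: unknown landmark {name!r}")
                data[i, LANDMARK_NAMES.index(name)] = xyc
    return KeypointSeries(timestamps=ts, data=data,
                          image_size=image_size, px_per_cm=px_per_cm)


def _load_openpose_dir(path: Path) -> KeypointSeries:
    """Read a directory of per-frame OpenPose BODY_25 JSON files.

    Files are ordered by name; timestamps are assigned at 20 Hz from 0.
    Only BODY_25 indices 0-14 (our 15-landmark vocabulary) are kept.
    """
    files = sorted(path.glob("*.json"))
    if not files:
        raise FormatError(f"{path}: no per-frame JSON files")
    n = len(files)
    ts = np.arange(n) / 20.0
    data = np.zeros((n, len(LANDMARK_NAMES), 3))
    for i, f in enumerate(files):
        with open(f, encoding="utf-8") as fh:
            payload = json.load(fh)
        people = payload.get("people", [])
        if people:
            flat = people[0]["pose_keypoints_2d"]
            arr = np.asarray(flat, dtype=float).reshape(-1, 3)
            data[i] = arr[:len(LANDMARK_NAMES)]
    return KeypointSeries(timestamps=ts, data=data)


def load_trial(pressure_path: str | Path,
               keypoints_path: str | Path) -> tuple[PressureFrameSeries, KeypointSeries]:
    """Load and cross-validate one trial's two streams."""
    pressure_path, keypoints_path = Path(pressure_path), Path(keypoints_path)
    for p in (pressure_path, keypoints_path):
        if not p.exists():
            raise OlstError(f"missing file: {p}")
    series, _, _ = _parse_pressure_csv(pressure_path)
    kp = _load_keypoint_json(keypoints_path)
    if kp.n_frames != series.n_frames:
        raise FormatError(
            f"stream length mismatch: {pressure_path} has {series.n_frames} "
            f"frames but {keypoints_path} has {kp.n_frames}")
    if not np.allclose(kp.timestamps, series.timestamps, atol=1e-6):
        raise FormatError(
            f"timestamp mismatch between {pressure_path} and {keypoints_path}")
    return series, kp


def load_trial_recording(pressure_path: str | Path,
                         keypoints_path: str | Path) -> TrialRecording:
    """Load a trial together with its leg/duration metadata."""
    series, kp = load_trial(pressure_path, keypoints_path)
    _, leg, duration = _parse_pressure_csv(Path(pressure_path))
    if duration is None:
        dt = np.median(np.diff(series.timestamps)) if series.n_frames > 1 else 0.05
        duration = float(series.timestamps[-1] + dt)
    return TrialRecording(leg=leg or "right", duration=duration,
                          pressure=series, keypoints=kp)


# -------------------------------------------------------------- manifest

@dataclass
class CohortManifest:
    """Validated cohort manifest; trial paths resolved against base_dir."""

    table: pd.DataFrame
    base_dir: Path

    def __len__(self) -> int:
        return len(self.table)


def load_manifest(path: str | Path, check_files: bool = True) -> CohortManifest:
    path = Path(path)
    if not path.exists():
        raise OlstError(f"missing manifest: {path}")
    df = pd.read_csv(path, dtype={"participant_id": str})
    missing_cols = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing_cols:
        raise FormatError(f"{path}: missing columns {missing_cols}")
    if df["participant_id"].duplicated().any():
        dup = df.loc[df["participant_id"].duplicated(), "participant_id"].iloc[0]
        raise FormatError(f"{path}: duplicate participant id {dup!r}")
    df = df.copy()
    if len(df):
        try:
            df["sex"] = df["sex"].str.lower().map(_SEX_ALIASES)
        except AttributeError:
            raise FormatError(f"{path}: sex column must be text") from None
        if df["sex"].isna().any():
            raise FormatError(f"{path}: sex outside vocabulary male/female")
    base = path.parent
    if check_files:
        for k in range(1, N_TRIALS + 1):
            for part in ("pressure", "keypoints"):
                col = f"trial{k}_{part}"
                if df[col].isna().any():
                    raise FormatError(f"{path}: empty {col} entry")
                for rel in df[col]:
                    if not (base / rel).exists():
                        raise OlstError(f"{path}: referenced file missing: {base / rel}")
    return CohortManifest(table=df, base_dir=base)


def load_participants(manifest: CohortManifest) -> list[ParticipantRecord]:
    """Materialize every participant's four trials from a manifest."""
    out = []
    for _, row in manifest.table.iterrows():
        trials = []
        for k in range(1, N_TRIALS + 1):
            tr = load_trial_recording(
                manifest.base_dir / row[f"trial{k}_pressure"],
                manifest.base_dir / row[f"trial{k}_keypoints"])
            tr.leg = row[f"trial{k}_leg"]
            trials.append(tr)
        out.append(ParticipantRecord(
            id=row["participant_id"], sex=row["sex"], age=float(row["age"]),
            srs_total=float(row["srs_total"]), trials=trials))
    return out


def write_cohort(cohort: list[ParticipantRecord], directory: str | Path) -> Path:
    """Write every trial of every participant plus ``manifest.csv``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for p in cohort:
        row: dict[str, object] = {
            "participant_id": p.id, "sex": p.sex,
            "age": p.age, "srs_total": p.srs_total,
        }
        for k, trial in enumerate(p.trials, start=1):
            ppath, kpath = write_trial(trial, directory / p.id,
                                       stem=f"trial{k}")
            row[f"trial{k}_pressure"] = str(ppath.relative_to(directory))
            row[f"trial{k}_keypoints"] = str(kpath.relative_to(directory))
            row[f"trial{k}_leg"] = trial.leg
        rows.append(row)
    mpath = directory / "manifest.csv"
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(mpath, index=False)
    return mpath


# -------------------------------------------------- feature table / report

def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    from .features import FEATURE_CSV_COLUMNS
    missing = [c for c in FEATURE_CSV_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"feature table missing columns {missing}")
    table[FEATURE_CSV_COLUMNS].to_csv(path, index=False)


def load_feature_table(path: str | Path) -> pd.DataFrame:
    from .features import FEATURE_CSV_COLUMNS
    path = Path(path)
    if not path.exists():
        raise OlstError(f"missing feature table: {path}")
    df = pd.read_csv(path, dtype={"participant_id": str})
    missing = [c for c in FEATURE_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return df


def write_model_report(report: dict, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, default=_json_default)


def load_model_report(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
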