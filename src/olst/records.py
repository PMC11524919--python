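"""Core in-memory containers for OLST recordings.

A trial pairs two synchronous 20 Hz streams: a sparse plantar-pressure
grid from the mat sensor and 2-D skeletal keypoints from a frontal
camera.  Both containers validate their invariants on construction.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import FormatError

#: Fixed vocabulary of the 15 skeletal landmarks used throughout the
#: package, in canonical column order.  The first 15 entries of the
#: OpenPose BODY_25 layout map onto these one-to-one.
LANDMARK_NAMES: tuple[str, ...] = (
    "nose",
    "neck",
    "right_shoulder",
    "right_elbow",
    "right_wrist",
    "left_shoulder",
    "left_elbow",
    "left_wrist",
    "mid_hip",
    "right_hip",
    "right_knee",
    "right_ankle",
    "left_hip",
    "left_knee",
    "left_ankle",
)

LANDMARK_INDEX: dict[str, int] = {n: i for i, n in enumerate(LANDMARK_NAMES)}


@dataclass
class PressureFrameSeries:
    """Sparse time series of plantar pressure frames.

    Active cells of all frames are stored flat; ``frame_index[k]`` gives
    the frame each entry belongs to.  ``grid_shape`` is (rows, cols) and
    ``cell_pitch`` the cell edge length in cm.
    """

    timestamps: np.ndarray          # (n_frames,) seconds from trial start
    frame_index: np.ndarray         # (n_cells,) int, frame of each entry
    rows: np.ndarray                # (n_cells,) int
    cols: np.ndarray                # (n_cells,) int
    values: np.ndarray              # (n_cells,) float, pressure >= 0
    grid_shape: tuple[int, int] = (48, 48)
    cell_pitch: float = 1.0

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.frame_index = np.asarray(self.frame_index, dtype=np.int64)
        self.rows = np.asarray(self.rows, dtype=np.int64)
        self.cols = np.asarray(self.cols, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        if self.timestamps.ndim != 1 or self.timestamps.size == 0:
            raise FormatError("pressure series needs at least one frame")
        if np.any(np.diff(self.timestamps) <= 0):
            raise FormatError("pressure timestamps must be strictly increasing")
        if np.any(self.values < 0):
            k = int(np.argmax(self.values < 0))
            raise FormatError(f"negative pressure value at entry {k}")
        nr, nc = self.grid_shape
        if np.any(self.rows < 0) or np.any(self.rows >= nr) or \
                np.any(self.cols < 0) or np.any(self.cols >= nc):
            raise FormatError("cell index outside grid_shape")
        if self.frame_index.size and (
                self.frame_index.min() < 0
                or self.frame_index.max() >= self.timestamps.size):
            raise FormatError("frame_index outside timestamp range")

    @property
    def n_frames(self) -> int:
        return int(self.timestamps.size)

    def frame(self, i: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (rows, cols, values) of frame ``i``."""
        m = self.frame_index == i
        return self.rows[m], self.cols[m], self.values[m]

    def cell_xy(self) -> tuple[np.ndarray, np.ndarray]:
        """Mat-frame coordinates (cm) of every stored cell center.

        Origin at mat center, x mediolateral (columns, rightward), y
        anteroposterior (rows, increasing row index = toward the camera,
        mapped to negative y so that y points away).
        """
        nr, nc = self.grid_shape
        x = (self.cols + 0.5) * self.cell_pitch - nc * self.cell_pitch / 2.0
        y = nr * self.cell_pitch / 2.0 - (self.rows + 0.5) * self.cell_pitch
        return x, y


@dataclass
class KeypointSeries:
    """Named 2-D landmarks with confidences over time.

    ``data`` has shape (n_frames, 15, 3) holding (x_px, y_px, confidence)
    in image coordinates (origin top-left, y downward), columns ordered
    as :data:`LANDMARK_NAMES`.
    """

    timestamps: np.ndarray
    data: np.ndarray
    image_size: tuple[int, int] = (640, 480)   # (width, height) px
    px_per_cm: float = 3.0

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[1:] != (len(LANDMARK_NAMES), 3):
            raise FormatError(
                f"keypoint data must be (n, {len(LANDMARK_NAMES)}, 3), "
                f"got {self.data.shape}")
        if self.data.shape[0] != self.timestamps.size:
            raise FormatError("keypoint frames do not match timestamps")
        conf = self.data[:, :, 2]
        if np.any(conf < 0) or np.any(conf > 1):
            raise FormatError("keypoint confidences must lie in [0, 1]")

    @property
    def n_frames(self) -> int:
        return int(self.timestamps.size)

    def landmark(self, name: str) -> np.ndarray:
        """(n_frames, 3) slice for one landmark name."""
        try:
            return self.data[:, LANDMARK_INDEX[name], :]
        except KeyError:
            raise FormatError(f"unknown landmark {name!r}") from None


@dataclass
class TrialRecording:
    """One one-legged standing trial: which leg stood, how long the
    stand lasted (s, right-censored at the protocol cap), and the two
    synchronous streams."""

    leg: str                        # "left" | "right" (the standing leg)
    duration: float
    pressure: PressureFrameSeries
    keypoints: KeypointSeries

    def __post_init__(self) -> None:
        if self.leg not in ("left", "right"):
            raise FormatError(f"leg must be 'left' or 'right', got {self.leg!r}")
        if self.duration <= 0:
            raise FormatError("trial duration must be positive")
        if self.pressure.n_frames != self.keypoints.n_frames:
            raise FormatError(
                f"pressure ({self.pressure.n_frames} frames) and keypoints "
                f"({self.keypoints.n_frames} frames) are not synchronous")


@dataclass
class ParticipantRecord:
    """One child: identity, demographics, SRS-2 total and the ordered
    list of OLST trials (legs alternate, starting with the right)."""

    id: str
    sex: str                        # "male" | "female"
    age: float
    srs_total: float
    trials: list[TrialRecording] = field(default_factory=list)
    severity: float | None = None   # latent [0,1]; synthetic cohorts only

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise FormatError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.srs_total < 0:
            raise FormatError("srs_total must be non-negative")
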