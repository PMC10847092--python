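"""Readers and writers for keypoint trajectories and clinical tables.

Internal coordinate convention: x = direction of progression (positive),
y = up. OpenPose image coordinates are y-down, so the OpenPose reader negates
y; both readers flip x when the net hip displacement is negative so that the
walker always progresses in +x. Limb angle and limb length are unit-free, so
pixel coordinates need no calibration; gait speed needs an optional
meters-per-pixel factor supplied elsewhere.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("limbkin")

SCHEMA_HEADER = "# limbkin keypoints v1"

#: BODY_25 keypoint indices for (hip, knee, ankle) per body side.
BODY25_SIDE_INDICES = {"right": (9, 10, 11), "left": (12, 13, 14)}

#: Clinical scale validity ranges. MAS is the converted 0-5 point scale
#: (0 = no increase in muscle tone, 5 = rigid); SF-BBS is the 7-item
#: short form (0-28); FAC is the Functional Ambulation Category (0-5).
CLINICAL_SCALES = {
    "fms": (0, 22),
    "fma_sensory": (0, 12),
    "mas": (0, 5),
    "sf_bbs": (0, 28),
    "fac": (0, 5),
}

KEYPOINT_COLUMNS = [
    "frame", "time_s",
    "hip_x", "hip_y", "knee_x", "knee_y", "ankle_x", "ankle_y",
]


@dataclass
class KeypointSeries:
    """Time-indexed sagittal-plane joint-center coordinates for one walk.

    Attributes
    ----------
    time : (n,) seconds, uniformly sampled.
    hip, knee, ankle : (n, 2) x/y coordinates in the internal convention.
    sampling_rate : Hz.
    side : paretic side label ("left"/"right") or "unknown".
    confidence : optional (n, 3) per-frame per-joint detector confidence.
    """

    time: np.ndarray
    hip: np.ndarray
    knee: np.ndarray
    ankle: np.ndarray
    sampling_rate: float
    side: str = "unknown"
    confidence: np.ndarray | None = None

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        for name in ("hip", "knee", "ankle"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 2:
                raise ValueError(f"{name} must be an (n, 2) array")
            setattr(self, name, arr)
        n = len(self.time)
        if not (len(self.hip) == len(self.knee) == len(self.ankle) == n):
            raise ValueError("hip/knee/ankle/time must have equal length")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    def __len__(self) -> int:
        return len(self.time)


def normalize_orientation(series: KeypointSeries) -> KeypointSeries:
    """Flip x so the net hip displacement (direction of progression) is +x."""
    if series.hip[-1, 0] - series.hip[0, 0] < 0:
        for arr in (series.hip, series.knee, series.ankle):
            arr[:, 0] *= -1.0
    return series


# ---------------------------------------------------------------------------
# CSV keypoints


def write_keypoint_csv(series: KeypointSeries, path: str | Path) -> None:
    """Write a KeypointSeries as CSV with a schema-version header comment."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "frame": np.arange(len(series)),
            "time_s": series.time,
            "hip_x": series.hip[:, 0], "hip_y": series.hip[:, 1],
            "knee_x": series.knee[:, 0], "knee_y": series.knee[:, 1],
            "ankle_x": series.ankle[:, 0], "ankle_y": series.ankle[:, 1],
        }
    )
    with open(path, "w") as fh:
        fh.write(SCHEMA_HEADER + f" side={series.side}"
                 f" sampling_rate={series.sampling_rate:g}\n")
        df.to_csv(fh, index=False, float_format="%.6f")


def read_keypoint_csv(path: str | Path, rel_tol: float = 1e-3) -> KeypointSeries:
    """Read a keypoint CSV written by :func:`write_keypoint_csv`.

    Raises on missing columns (naming the column) and on time stamps that
    deviate from uniform sampling by more than ``rel_tol`` of the frame
    interval. Extra columns are ignored with a logged warning.
    """
    path = Path(path)
    side, rate = "unknown", None
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        for tok in first.split():
            if tok.startswith("side="):
                side = tok.split("=", 1)[1]
            elif tok.startswith("sampling_rate="):
                rate = float(tok.split("=", 1)[1])
    df = pd.read_csv(path, comment="#")
    missing = [c for c in KEYPOINT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"keypoint CSV {path} is missing column(s): {missing}")
    extra = [c for c in df.columns if c not in KEYPOINT_COLUMNS]
    if extra:
        logger.warning("keypoint CSV %s: ignoring extra column(s) %s", path, extra)
    t = df["time_s"].to_numpy(float)
    if len(t) < 2:
        raise ValueError(f"keypoint CSV {path} has fewer than 2 frames")
    dt = np.diff(t)
    dt_med = float(np.median(dt))
    if dt_med <= 0 or np.any(np.abs(dt - dt_med) > rel_tol * dt_med):
        raise ValueError(f"keypoint CSV {path}: non-uniform time stamps")
    if rate is None:
        rate = 1.0 / dt_med
    series = KeypointSeries(
        time=t,
        hip=df[["hip_x", "hip_y"]].to_numpy(float),
        knee=df[["knee_x", "knee_y"]].to_numpy(float),
        ankle=df[["ankle_x", "ankle_y"]].to_numpy(float),
        sampling_rate=rate,
        side=side,
    )
    return normalize_orientation(series)


# ---------------------------------------------------------------------------
# OpenPose per-frame JSON


def _select_person(people: list[dict]) -> np.ndarray:
    """Pick the person with the largest keypoint bounding-box area.

    The walker is filmed closest to the camera, so spurious background
    detections have smaller boxes.
    """
    best, best_area = None, -1.0
    for person in people:
        kp = np.asarray(person["pose_keypoints_2d"], dtype=float).reshape(-1, 3)
        vis = kp[kp[:, 2] > 0]
        if len(vis) == 0:
            continue
        area = float(np.ptp(vis[:, 0]) * np.ptp(vis[:, 1]))
        if area > best_area:
            best, best_area = kp, area
    if best is None:
        raise ValueError("frame contains people entries with no visible keypoints")
    return best


def _interpolate_gaps(values: np.ndarray, valid: np.ndarray, max_gap: int) -> np.ndarray:
    """Linearly interpolate runs of invalid frames no longer than ``max_gap``."""
    out = values.copy()
    n = len(values)
    idx = np.flatnonzero(valid)
    if len(idx) == 0:
        raise ValueError("no frames above the confidence floor")
    runs = []
    i = 0
    while i < n:
        if not valid[i]:
            j = i
            while j < n and not valid[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    for i, j in runs:
        if j - i > max_gap:
            raise ValueError(
                f"gap of {j - i} low-confidence frames exceeds the "
                f"interpolation limit of {max_gap}")
        out[i:j] = np.interp(np.arange(i, j), idx, values[idx])
    return out


def read_openpose_dir(
    path: str | Path,
    side: str,
    confidence_floor: float = 0.3,
    sampling_rate: float = 120.0,
    max_gap: int = 5,
    max_missing_frac: float = 0.10,
) -> KeypointSeries:
    """Read a directory of OpenPose BODY_25 per-frame JSON files.

    Files are processed in sorted name order, one frame each. The requested
    side's hip/knee/ankle are extracted, image y (down-positive) is negated
    to the internal up-positive convention, joints below ``confidence_floor``
    are marked missing and linearly interpolated (gaps of at most ``max_gap``
    consecutive frames), and the walking direction is normalized to +x.
    """
    path = Path(path)
    if side not in BODY25_SIDE_INDICES:
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    files = sorted(path.glob("*.json"))
    if not files:
        raise ValueError(f"no OpenPose JSON files found in {path}")
    joints = BODY25_SIDE_INDICES[side]
    coords = np.full((len(files), 3, 2), np.nan)
    conf = np.zeros((len(files), 3))
    n_empty = 0
    for i, f in enumerate(files):
        with open(f) as fh:
            data = json.load(fh)
        people = data.get("people", [])
        if not people:
            n_empty += 1
            continue
        kp = _select_person(people)
        if kp.shape[0] != 25:
            raise ValueError(
                f"{f} has {kp.shape[0]} keypoints; expected BODY_25 layout")
        for j, joint_idx in enumerate(joints):
            coords[i, j] = kp[joint_idx, :2]
            conf[i, j] = kp[joint_idx, 2]
    if n_empty > max_missing_frac * len(files):
        raise ValueError(
            f"{n_empty}/{len(files)} frames contain no people "
            f"(> {max_missing_frac:.0%} allowed)")
    valid = conf >= confidence_floor
    for j in range(3):
        for axis in range(2):
            coords[:, j, axis] = _interpolate_gaps(
                coords[:, j, axis], valid[:, j] & np.isfinite(coords[:, j, axis]),
                max_gap)
    coords[:, :, 1] *= -1.0  # image y-down -> internal y-up
    t = np.arange(len(files)) / sampling_rate
    series = KeypointSeries(
        time=t, hip=coords[:, 0], knee=coords[:, 1], ankle=coords[:, 2],
        sampling_rate=sampling_rate, side=side, confidence=conf)
    return normalize_orientation(series)


def write_openpose_dir(series: KeypointSeries, path: str | Path) -> None:
    """Write a KeypointSeries as OpenPose-style BODY_25 per-frame JSON.

    Only the requested side's hip/knee/ankle slots are populated (confidence
    1.0); the other 22 keypoints are zero. Internal y-up is converted back to
    image y-down.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    side = series.side if series.side in BODY25_SIDE_INDICES else "right"
    joints = BODY25_SIDE_INDICES[side]
    for i in range(len(series)):
        kp = np.zeros((25, 3))
        for j, (arr) in enumerate((series.hip, series.knee, series.ankle)):
            kp[joints[j], 0] = arr[i, 0]
            kp[joints[j], 1] = -arr[i, 1]
            kp[joints[j], 2] = 1.0
        payload = {"people": [{"pose_keypoints_2d": kp.ravel().tolist()}]}
        with open(path / f"frame_{i:06d}_keypoints.json", "w") as fh:
            json.dump(payload, fh)


# ---------------------------------------------------------------------------
# Clinical tables


def read_clinical_csv(path: str | Path, id_column: str = "participant") -> pd.DataFrame:
    """Read and validate a per-participant clinical table.

    Known scale columns (see :data:`CLINICAL_SCALES`) are validated against
    their valid ranges; violations raise an error citing the participant and
    variable. Duplicate participant ids raise.
    """
    df = pd.read_csv(path, comment="#")
    if id_column not in df.columns:
        raise ValueError(f"clinical CSV {path} is missing id column {id_column!r}")
    dup = df[id_column][df[id_column].duplicated()]
    if len(dup):
        raise ValueError(
            f"clinical CSV {path}: duplicate participant id(s) {sorted(set(dup))}")
    for var, (lo, hi) in CLINICAL_SCALES.items():
        if var not in df.columns:
            continue
        vals = df[var]
        bad = df[(vals.notna()) & ((vals < lo) | (vals > hi))]
        if len(bad):
            pid = bad[id_column].iloc[0]
            raise ValueError(
                f"clinical CSV {path}: {var}={bad[var].iloc[0]} for participant "
                f"{pid!r} outside valid range [{lo}, {hi}]")
    return df
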