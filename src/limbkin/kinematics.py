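"""Limb-kinematics signal processing: filtering, limb angle and effective limb
length, gait-event detection from shank angular velocity, 201-point cycle
normalization, and per-participant feature extraction.

Definitions
-----------
limb angle
    Signed angle between the downward vertical axis and the hip->ankle vector
    in the sagittal plane; flexion (ankle anterior to the hip) positive,
    extension negative. Its cycle minimum is the peak limb extension angle.
effective limb length
    Hip-ankle distance divided by the sum of hip-knee and knee-ankle
    distances; 1 when the knee is fully extended. Its swing-phase minimum
    quantifies limb shortening.
shank angle
    Signed angle of the knee->ankle vector from the downward vertical, same
    sign convention as the limb angle. Its time derivative carries the stride
    signature used for event detection: a dominant positive peak at swing,
    with heel contact at the local minimum immediately after the peak and toe
    off at the local minimum immediately before it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import butter, filtfilt, find_peaks

from .io import KeypointSeries

logger = logging.getLogger("limbkin")

N_CYCLE_POINTS = 201  # samples per normalized gait cycle (0..100% in 0.5% steps)


# ---------------------------------------------------------------------------
# Elementary operations


def lowpass_filter(series: np.ndarray, sampling_rate: float,
                   cutoff_hz: float = 6.0, order: int = 4) -> np.ndarray:
    """Zero-lag Butterworth low-pass filter (forward-backward pass).

    The filter is designed at ``order`` and applied in both directions, which
    cancels phase lag and doubles the effective order; the stated order is
    per pass.
    """
    series = np.asarray(series, dtype=float)
    if cutoff_hz >= sampling_rate / 2:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz must be below the Nyquist frequency "
            f"{sampling_rate / 2} Hz")
    b, a = butter(order, cutoff_hz / (sampling_rate / 2))
    padlen = 3 * (max(len(a), len(b)) - 1)
    if series.shape[0] <= padlen:
        raise ValueError(
            f"series of length {series.shape[0]} is shorter than the filter "
            f"warm-up length {padlen + 1}")
    return filtfilt(b, a, series, axis=0)


def limb_angle(hip_xy: np.ndarray, ankle_xy: np.ndarray) -> np.ndarray:
    """Signed limb angle in degrees (flexion positive) of the hip->ankle vector.

    Measured from the downward vertical; positive when the ankle is anterior
    (+x) to the hip. Accepts single points or (n, 2) arrays.
    """
    hip_xy = np.asarray(hip_xy, dtype=float)
    ankle_xy = np.asarray(ankle_xy, dtype=float)
    v = ankle_xy - hip_xy
    if np.any(np.all(np.isclose(v, 0.0), axis=-1)):
        raise ValueError("hip and ankle coincide; limb angle undefined")
    return np.degrees(np.arctan2(v[..., 0], -v[..., 1]))


def limb_length(hip_xy: np.ndarray, knee_xy: np.ndarray,
                ankle_xy: np.ndarray) -> np.ndarray:
    """Effective limb length: |hip-ankle| / (|hip-knee| + |knee-ankle|).

    Dimensionless, in (0, 1]; equals 1 iff the knee lies on the hip-ankle
    segment (fully extended limb). Invariant to translation, rotation and
    uniform scaling of the three joints.
    """
    hip_xy = np.asarray(hip_xy, dtype=float)
    knee_xy = np.asarray(knee_xy, dtype=float)
    ankle_xy = np.asarray(ankle_xy, dtype=float)
    d_ha = np.linalg.norm(ankle_xy - hip_xy, axis=-1)
    denom = (np.linalg.norm(knee_xy - hip_xy, axis=-1)
             + np.linalg.norm(ankle_xy - knee_xy, axis=-1))
    if np.any(denom == 0):
        raise ValueError("degenerate joint configuration: zero segment lengths")
    return d_ha / denom


def shank_angle(knee_xy: np.ndarray, ankle_xy: np.ndarray) -> np.ndarray:
    """Signed shank angle in degrees of the knee->ankle vector from vertical."""
    knee_xy = np.asarray(knee_xy, dtype=float)
    ankle_xy = np.asarray(ankle_xy, dtype=float)
    v = ankle_xy - knee_xy
    if np.any(np.all(np.isclose(v, 0.0), axis=-1)):
        raise ValueError("knee and ankle coincide; shank angle undefined")
    return np.degrees(np.arctan2(v[..., 0], -v[..., 1]))


def differentiate(series: np.ndarray, sampling_rate: float) -> np.ndarray:
    """First time derivative: central differences interior, one-sided ends."""
    series = np.asarray(series, dtype=float)
    if series.shape[0] < 3:
        raise ValueError("need at least 3 samples to differentiate")
    return np.gradient(series, 1.0 / sampling_rate, axis=0)


# ---------------------------------------------------------------------------
# Gait events


def _dominant_period(signal: np.ndarray, sampling_rate: float,
                     min_s: float = 0.4, max_s: float = 3.0) -> int:
    """Stride period in frames from the autocorrelation peak."""
    x = signal - signal.mean()
    ac = np.correlate(x, x, mode="full")[len(x) - 1:]
    lo = int(min_s * sampling_rate)
    hi = min(int(max_s * sampling_rate), len(ac) - 1)
    if hi <= lo:
        raise ValueError("signal too short to estimate a stride period")
    return lo + int(np.argmax(ac[lo:hi]))


def detect_gait_events(
    shank_angular_velocity: np.ndarray,
    sampling_rate: float,
    prominence_frac: float = 0.2,
    min_prominence_frac: float = 0.02,
) -> tuple[np.ndarray, np.ndarray]:
    """Detect heel contacts and toe offs from shank angular velocity.

    Per stride the swing phase appears as a dominant positive peak of the
    (filtered) shank angular velocity. Heel contact is the local minimum
    immediately following that peak and toe off the local minimum immediately
    preceding it — the standard shank-gyroscope rule. Swing peaks must exceed
    ``prominence_frac`` of the maximum peak prominence and are separated by at
    least 60% of the autocorrelation stride period; minima below
    ``min_prominence_frac`` of the signal range are treated as ripple.

    Returns (heel_contacts, toe_offs) as strictly increasing frame indices.
    """
    om = np.asarray(shank_angular_velocity, dtype=float)
    peaks, props = find_peaks(om, prominence=0)
    if len(peaks) == 0:
        raise ValueError("no strides detected: shank angular velocity has no peaks")
    threshold = prominence_frac * props["prominences"].max()
    period = _dominant_period(om, sampling_rate)
    peaks, _ = find_peaks(om, prominence=threshold,
                          distance=max(1, int(0.6 * period)))
    if len(peaks) < 2:
        raise ValueError("no strides detected: fewer than 2 swing peaks")
    minima, _ = find_peaks(-om, prominence=min_prominence_frac * np.ptp(om))
    heel_contacts, toe_offs = [], []
    for p in peaks:
        after = minima[minima > p]
        before = minima[minima < p]
        if len(after):
            heel_contacts.append(int(after[0]))
        if len(before):
            toe_offs.append(int(before[-1]))
    heel_contacts = np.unique(heel_contacts)
    toe_offs = np.unique(toe_offs)
    if len(heel_contacts) == 0:
        raise ValueError("no heel contacts detected")
    return heel_contacts, toe_offs


# ---------------------------------------------------------------------------
# Containers


@dataclass
class LimbKinematicsSeries:
    """Per-frame limb kinematics derived from a KeypointSeries."""

    limb_angle: np.ndarray              # deg, flexion positive
    limb_length: np.ndarray             # dimensionless, (0, 1]
    shank_angle: np.ndarray             # deg
    shank_angular_velocity: np.ndarray  # deg/s
    sampling_rate: float


@dataclass
class StrideSet:
    """Stride segmentation plus 201-sample normalized per-stride curves."""

    heel_contacts: np.ndarray
    toe_offs: np.ndarray
    angle_cycles: np.ndarray   # (n_strides, 201)
    length_cycles: np.ndarray  # (n_strides, 201)
    sampling_rate: float

    @property
    def n_strides(self) -> int:
        return self.angle_cycles.shape[0]


@dataclass
class ParticipantFeatures:
    """Stride-averaged per-participant gait features."""

    limb_angle_ext_peak: float          # deg, negative (extension)
    limb_length_min_swing: float        # dimensionless
    cadence: float                      # steps/min
    gait_speed: float | None = None     # m/s (needs meters-per-pixel)
    gait_stability_ratio: float | None = None  # steps/m
    n_strides_used: int = 0


# ---------------------------------------------------------------------------
# Cycle normalization and feature extraction


def compute_kinematics(series: KeypointSeries, cutoff_hz: float = 6.0,
                       order: int = 4,
                       filter_coordinates: bool = False) -> LimbKinematicsSeries:
    """Angle/length series from keypoints, low-pass filtered.

    By default the derived angle and length series are filtered (the angle
    data are what the filter specification refers to); set
    ``filter_coordinates`` to filter the raw coordinates instead, as a
    sensitivity analysis.
    """
    fs = series.sampling_rate
    hip, knee, ankle = series.hip, series.knee, series.ankle
    if filter_coordinates:
        hip = lowpass_filter(hip, fs, cutoff_hz, order)
        knee = lowpass_filter(knee, fs, cutoff_hz, order)
        ankle = lowpass_filter(ankle, fs, cutoff_hz, order)
        la = limb_angle(hip, ankle)
        ll = limb_length(hip, knee, ankle)
        sa = shank_angle(knee, ankle)
    else:
        la = lowpass_filter(limb_angle(hip, ankle), fs, cutoff_hz, order)
        ll = lowpass_filter(limb_length(hip, knee, ankle), fs, cutoff_hz, order)
        sa = lowpass_filter(shank_angle(knee, ankle), fs, cutoff_hz, order)
    om = differentiate(sa, fs)
    return LimbKinematicsSeries(la, ll, sa, om, fs)


def normalize_cycles(series: np.ndarray, heel_contacts: np.ndarray,
                     n_points: int = N_CYCLE_POINTS) -> np.ndarray:
    """Resample each heel-contact-to-heel-contact stride onto ``n_points``
    equally spaced samples with a cubic spline (endpoints preserved exactly).

    Strides shorter than 4 frames are dropped with a warning. Returns an
    (n_strides, n_points) array.
    """
    series = np.asarray(series, dtype=float)
    heel_contacts = np.asarray(heel_contacts, dtype=int)
    if len(heel_contacts) < 2:
        raise ValueError("need at least two heel contacts to form a stride")
    out = []
    for a, b in zip(heel_contacts[:-1], heel_contacts[1:]):
        if b - a < 3:  # fewer than 4 frames including both endpoints
            logger.warning("dropping stride of %d frames (< 4)", b - a + 1)
            continue
        frames = np.arange(a, b + 1)
        spline = CubicSpline(frames, series[a:b + 1])
        out.append(spline(np.linspace(a, b, n_points)))
    if not out:
        raise ValueError("no stride long enough to normalize")
    return np.vstack(out)


def segment_strides(kin: LimbKinematicsSeries) -> StrideSet:
    """Detect events and build normalized per-stride angle/length curves."""
    hc, to = detect_gait_events(kin.shank_angular_velocity, kin.sampling_rate)
    angle_cycles = normalize_cycles(kin.limb_angle, hc)
    length_cycles = normalize_cycles(kin.limb_length, hc)
    return StrideSet(hc, to, angle_cycles, length_cycles, kin.sampling_rate)


def _swing_window(stride_start: int, stride_end: int,
                  toe_offs: np.ndarray) -> tuple[int, int]:
    """Swing phase of one stride: detected toe off -> next heel contact."""
    tos = toe_offs[(toe_offs > stride_start) & (toe_offs < stride_end)]
    if len(tos) == 0:
        return stride_start, stride_end  # fall back to the full stride
    return int(tos[0]), stride_end


def extract_features(
    stride_set: StrideSet,
    kin: LimbKinematicsSeries,
    trim: int = 3,
    n_keep: int = 10,
    meters_per_pixel: float | None = None,
    hip_x: np.ndarray | None = None,
) -> ParticipantFeatures:
    """Stride-averaged limb kinematics features.

    The first and last ``trim`` strides are removed (acceleration and
    deceleration transients) and up to ``n_keep`` of the remaining strides are
    retained; if fewer remain, all are used with a logged warning. Per stride,
    the peak limb extension angle is the minimum of the limb-angle cycle
    (earliest frame on ties) and the effective limb length is the minimum of
    the limb-length series restricted to the swing phase (detected toe off to
    the stride-ending heel contact). Cadence comes from heel-contact
    intervals (2 steps per stride); gait speed needs ``meters_per_pixel`` and
    the hip trajectory; the gait stability ratio is cadence / (speed * 60) in
    steps per meter.
    """
    hc = stride_set.heel_contacts
    n_available = stride_set.n_strides
    if n_available < 2 * trim + 1:
        raise ValueError(
            f"only {n_available} strides available; need at least "
            f"{2 * trim + 1} to trim {trim} from each end")
    lo, hi = trim, n_available - trim
    kept = list(range(lo, hi))[:n_keep]
    if len(kept) < n_keep:
        logger.warning("only %d strides after trimming; using all of them "
                       "(requested %d)", len(kept), n_keep)

    angle_peaks, length_mins = [], []
    for i in kept:
        a, b = int(hc[i]), int(hc[i + 1])
        angle_peaks.append(float(stride_set.angle_cycles[i].min()))
        sw_a, sw_b = _swing_window(a, b, stride_set.toe_offs)
        length_mins.append(float(kin.limb_length[sw_a:sw_b + 1].min()))

    first, last = int(hc[kept[0]]), int(hc[kept[-1] + 1])
    duration_s = (last - first) / stride_set.sampling_rate
    cadence = 2.0 * len(kept) * 60.0 / duration_s  # steps/min

    speed = gsr = None
    if meters_per_pixel is not None and hip_x is not None:
        dist_m = abs(hip_x[last] - hip_x[first]) * meters_per_pixel
        speed = dist_m / duration_s
        if speed > 0:
            gsr = cadence / (speed * 60.0)

    return ParticipantFeatures(
        limb_angle_ext_peak=float(np.mean(angle_peaks)),
        limb_length_min_swing=float(np.mean(length_mins)),
        cadence=cadence,
        gait_speed=speed,
        gait_stability_ratio=gsr,
        n_strides_used=len(kept),
    )


def process_walk(series: KeypointSeries, cutoff_hz: float = 6.0,
                 order: int = 4, trim: int = 3, n_keep: int = 10,
                 meters_per_pixel: float | None = None,
                 filter_coordinates: bool = False) -> ParticipantFeatures:
    """Full single-walk pipeline: keypoints -> filtered kinematics -> events ->
    normalized strides -> stride-averaged features."""
    kin = compute_kinematics(series, cutoff_hz, order, filter_coordinates)
    strides = segment_strides(kin)
    return extract_features(strides, kin, trim=trim, n_keep=n_keep,
                            meters_per_pixel=meters_per_pixel,
                            hip_x=series.hip[:, 0])
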