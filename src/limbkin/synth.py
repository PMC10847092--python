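"""Synthetic gait generator with planted Gaussian-mixture cluster structure.

Three layers, matching the real pipeline's inputs:

1. ``sample_features`` draws per-participant (limb extension angle, limb
   length) pairs from a configurable K-component Gaussian mixture.
2. ``synthesize_walk`` solves the inverse problem: it constructs a smooth
   periodic hip/knee/ankle trajectory whose *extracted* features equal the
   planted pair. The hip translates forward at constant mean height; the limb
   angle follows a three-harmonic Fourier waveform scaled so its cycle
   minimum equals the planted extension angle (extension peak at ~55% cycle,
   flexion peak at ~94%, plus a terminal-swing shank-retraction dip that
   gives the shank-angular-velocity heel-contact rule a local minimum at the
   cycle boundary); knee flexion during swing is a raised-cosine bump whose
   depth is set so the minimum swing-phase effective limb length equals the
   planted value. Gaussian keypoint jitter is added on top, and ground-truth
   heel-contact/toe-off frames are stored.
3. ``sample_clinical`` draws bounded ordinal clinical scores and gait
   parameters from cluster-shifted distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import CLINICAL_SCALES, KeypointSeries

TWO_PI = 2.0 * np.pi

# Limb-angle waveform: unit three-harmonic Fourier series
#   s(phi) = cos(2*pi*phi - B1) + A2*cos(4*pi*phi - B2) + A3*cos(6*pi*phi - B3)
# designed so that (after min-max rescaling to the planted angle range) the
# extension peak sits at ~55% cycle, the flexion peak in terminal swing, and
# the angular-velocity retraction dip at the heel contact. Frozen constants.
_B1, _A2, _B2, _A3, _B3 = 6.550812, -0.14151, 0.550439, 0.126835, 3.926398

PHI_TOE_OFF = 0.60    # toe-off phase (fraction of gait cycle)
PHI_SWING_END = 0.98  # knee fully re-extended before the next heel contact
FLEXION_PEAK_DEG = 25.0  # limb-angle flexion maximum

#: Ordinal clinical scales generated as shifted binomial scores:
#: name -> baseline success probability (of scale maximum).
CLINICAL_BASELINES = {
    "fms": 0.75,
    "fma_sensory": 0.85,
    "mas": 0.25,
    "sf_bbs": 0.80,
    "fac": 0.85,
}

#: Continuous gait parameters: name -> (baseline mean, sd).
GAIT_BASELINES = {
    "gait_speed": (0.7, 0.12),   # m/s, comfortable post-stroke pace
    "cadence": (100.0, 8.0),     # steps/min
}


def _s_base(phi: np.ndarray) -> np.ndarray:
    u = TWO_PI * np.asarray(phi)
    return (np.cos(u - _B1) + _A2 * np.cos(2 * u - _B2)
            + _A3 * np.cos(3 * u - _B3))


_PHI_GRID = np.linspace(0.0, 1.0, 8001, endpoint=False)
_S_GRID = _s_base(_PHI_GRID)
_S_MIN, _S_MAX = float(_S_GRID.min()), float(_S_GRID.max())


# ---------------------------------------------------------------------------
# Scenario specification


@dataclass
class ClusterSpec:
    """One mixture component in (limb extension angle deg, limb length)."""

    label: int
    mean: tuple[float, float]
    covariance: np.ndarray
    weight: float
    clinical_effects: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        self.covariance = np.asarray(self.covariance, dtype=float)
        if self.covariance.shape != (2, 2):
            raise ValueError("covariance must be 2x2")
        if not np.allclose(self.covariance, self.covariance.T):
            raise ValueError(f"cluster {self.label}: covariance not symmetric")
        eigvals = np.linalg.eigvalsh(self.covariance)
        if np.any(eigvals < -1e-10):
            raise ValueError(
                f"cluster {self.label}: covariance not positive semidefinite "
                f"(eigenvalues {eigvals})")
        if not 0.0 <= self.weight <= 1.0:
            raise ValueError(f"cluster {self.label}: weight outside [0, 1]")
        if not 0.0 < self.mean[1] <= 1.0:
            raise ValueError(
                f"cluster {self.label}: limb-length mean {self.mean[1]} "
                f"outside (0, 1]")


@dataclass
class Scenario:
    """Full synthetic-cohort specification."""

    clusters: list[ClusterSpec]
    n_participants: int = 67
    sampling_rate: float = 120.0
    n_strides: int = 19
    stride_period_s: float = 1.2
    stride_period_sd: float = 0.04
    noise_sd_px: float = 1.0
    seed: int = 0
    leg_segment_px: float = 500.0     # thigh = shank length, pixels
    hip_speed_px_s: float = 700.0
    meters_per_pixel: float = 0.001

    def __post_init__(self):
        if not self.clusters:
            raise ValueError("scenario needs at least one cluster")
        w = sum(c.weight for c in self.clusters)
        if abs(w - 1.0) > 1e-6:
            raise ValueError(f"cluster weights sum to {w}, expected 1")
        if self.n_participants < len(self.clusters):
            raise ValueError("n_participants must be >= number of clusters")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.stride_period_s <= 0:
            raise ValueError("stride_period_s must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Scenario":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "seed" not in raw:
            raise ValueError("scenario YAML must specify a seed")
        clusters = [
            ClusterSpec(
                label=int(c.get("label", i + 1)),
                mean=tuple(c["mean"]),
                covariance=np.asarray(c["covariance"], dtype=float),
                weight=float(c["weight"]),
                clinical_effects=dict(c.get("clinical_effects", {})),
            )
            for i, c in enumerate(raw.pop("clusters"))
        ]
        return cls(clusters=clusters, **raw)


def default_scenario(n_participants: int = 67, seed: int = 0,
                     noise_sd_px: float = 1.0,
                     cov_scale: float = 1.0) -> Scenario:
    """Five-component scenario emulating the study cohort's feature layout.

    Component means span high/mid/low limb extension angle crossed with
    high/low limb length (angle in degrees, extension negative); weights
    follow the observed cluster sizes 10/17/11/10/19 of 67. The first
    component has the largest angle variance, the others a relatively larger
    length variance, and — like the observed scatter — adjacent components
    partially overlap. Cluster-conditional clinical effects shift the ordinal
    scores the way the clusters differed clinically (e.g. low motor-synergy
    score with high spasticity in cluster 1, mild impairment with fast gait
    in clusters 4-5).

    ``cov_scale`` multiplies every component covariance; values well below 1
    give a well-separated variant of the same layout (see
    :func:`well_separated_scenario`).
    """

    def cov(sd_a, sd_l, rho=0.0):
        c = rho * sd_a * sd_l
        return cov_scale * np.array([[sd_a ** 2, c], [c, sd_l ** 2]])

    clusters = [
        ClusterSpec(1, (-22.0, 0.96), cov(3.0, 0.012), 10 / 67,
                    {"fms": -0.25, "mas": +0.35, "sf_bbs": +0.05}),
        ClusterSpec(2, (-14.0, 0.96), cov(1.5, 0.018), 17 / 67,
                    {"mas": +0.30, "sf_bbs": -0.20, "gait_speed": -0.15,
                     "cadence": -10.0}),
        ClusterSpec(3, (-6.0, 0.96), cov(1.5, 0.018), 11 / 67,
                    {"fms": -0.35, "mas": +0.30, "sf_bbs": -0.30}),
        ClusterSpec(4, (-22.0, 0.87), cov(1.5, 0.020), 10 / 67,
                    {"gait_speed": +0.25, "cadence": -5.0}),
        ClusterSpec(5, (-14.0, 0.87), cov(1.5, 0.020), 19 / 67,
                    {"gait_speed": +0.25, "cadence": +12.0}),
    ]
    return Scenario(clusters=clusters, n_participants=n_participants,
                    seed=seed, noise_sd_px=noise_sd_px)


def well_separated_scenario(n_participants: int = 300, seed: int = 0,
                            noise_sd_px: float = 1.0) -> Scenario:
    """The default five-component layout with covariances shrunk (x 0.25)
    so components barely overlap — the regime where mixture-order recovery
    by BIC is expected to succeed."""
    return default_scenario(n_participants=n_participants, seed=seed,
                            noise_sd_px=noise_sd_px, cov_scale=0.25)


# ---------------------------------------------------------------------------
# Feature sampling


def sample_features(scenario: Scenario,
                    rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw per-participant feature pairs from the scenario's mixture.

    Returns a DataFrame with columns ``participant``, ``limb_angle_ext``,
    ``limb_length`` and ``cluster_truth``; deterministic given the scenario
    seed.
    """
    rng = rng or np.random.default_rng(scenario.seed)
    weights = np.array([c.weight for c in scenario.clusters])
    assignment = rng.choice(len(scenario.clusters), size=scenario.n_participants,
                            p=weights)
    rows = []
    for i, k in enumerate(assignment):
        c = scenario.clusters[k]
        # redraw Gaussian tails that leave the physically feasible domain
        # (effective limb length cannot exceed 1; extension angle is negative)
        for _ in range(1000):
            x = rng.multivariate_normal(c.mean, c.covariance)
            if -60.0 < x[0] < 0.0 and 0.5 < x[1] <= 0.9995:
                break
        else:
            raise ValueError(
                f"cluster {c.label}: could not draw a feasible feature pair; "
                f"its mean/covariance put almost all mass outside the "
                f"physical domain")
        rows.append((f"P{i + 1:03d}", x[0], x[1], c.label))
    return pd.DataFrame(rows, columns=["participant", "limb_angle_ext",
                                       "limb_length", "cluster_truth"])


# ---------------------------------------------------------------------------
# Walk synthesis (inverse kinematics problem)


def _limb_angle_waveform(phi: np.ndarray, ext_angle_deg: float) -> np.ndarray:
    """Planted-limb-angle profile: waveform rescaled so min = planted angle
    and max = FLEXION_PEAK_DEG."""
    s = _s_base(phi)
    return ext_angle_deg + (FLEXION_PEAK_DEG - ext_angle_deg) * (
        (s - _S_MIN) / (_S_MAX - _S_MIN))


def _knee_flexion_waveform(phi: np.ndarray, limb_length_min: float) -> np.ndarray:
    """Swing-phase knee flexion (radians); raised-cosine bump whose depth
    makes min effective limb length equal the planted value."""
    kappa_max = 2.0 * np.arccos(limb_length_min)
    phi = np.asarray(phi) % 1.0
    kappa = np.zeros_like(phi, dtype=float)
    m = (phi >= PHI_TOE_OFF) & (phi < PHI_SWING_END)
    kappa[m] = kappa_max * np.sin(
        np.pi * (phi[m] - PHI_TOE_OFF) / (PHI_SWING_END - PHI_TOE_OFF)) ** 2
    return kappa


def synthesize_walk(features_row, scenario: Scenario,
                    rng: np.random.Generator | None = None,
                    noise_sd_px: float | None = None) -> tuple[KeypointSeries, dict]:
    """Construct a keypoint trajectory whose extracted features equal the
    planted (limb extension angle, limb length) pair.

    ``features_row`` is a mapping with ``limb_angle_ext`` (degrees, in
    (-60, 0)) and ``limb_length`` (in (0.5, 1]); optional ``cadence``
    (steps/min) and ``gait_speed`` (m/s) override the scenario's mean stride
    period and hip speed so that cluster-conditional gait parameters are
    realized in the trajectory itself. Returns the KeypointSeries plus a
    ground-truth dict with heel-contact/toe-off frame indices, the
    per-stride periods and the planted features.
    """
    ext = float(features_row["limb_angle_ext"])
    llen = float(features_row["limb_length"])
    if not -60.0 < ext < 0.0:
        raise ValueError(f"planted limb extension angle {ext} outside (-60, 0)")
    if not 0.5 < llen <= 1.0:
        raise ValueError(f"planted limb length {llen} outside (0.5, 1]")

    rng = rng or np.random.default_rng(scenario.seed)
    fs = scenario.sampling_rate
    noise = scenario.noise_sd_px if noise_sd_px is None else noise_sd_px

    mean_period = scenario.stride_period_s
    try:
        if "cadence" in features_row and np.isfinite(features_row["cadence"]):
            mean_period = 120.0 / float(features_row["cadence"])
    except TypeError:
        pass
    hip_speed = scenario.hip_speed_px_s
    try:
        if "gait_speed" in features_row and np.isfinite(features_row["gait_speed"]):
            hip_speed = float(features_row["gait_speed"]) / scenario.meters_per_pixel
    except TypeError:
        pass

    # per-stride periods with mild stride-to-stride variability
    periods = mean_period + scenario.stride_period_sd * rng.standard_normal(
        scenario.n_strides)
    periods = np.clip(periods, 0.5 * mean_period, 1.5 * mean_period)
    cycle_starts_s = np.concatenate([[0.0], np.cumsum(periods)])
    n = int(np.floor(cycle_starts_s[-1] * fs))
    t = np.arange(n) / fs
    stride_idx = np.searchsorted(cycle_starts_s, t, side="right") - 1
    stride_idx = np.clip(stride_idx, 0, scenario.n_strides - 1)
    phi = (t - cycle_starts_s[stride_idx]) / periods[stride_idx]
    phi = np.clip(phi, 0.0, 1.0 - 1e-12)

    theta = np.deg2rad(_limb_angle_waveform(phi, ext))
    kappa = _knee_flexion_waveform(phi, llen)

    d = scenario.leg_segment_px
    hip = np.column_stack([
        hip_speed * t + 8.0 * np.sin(2 * TWO_PI * (t / mean_period)),
        np.full(n, 2.0 * d),
    ])

    def unit(a):
        return np.column_stack([np.sin(a), -np.cos(a)])

    knee = hip + d * unit(theta + kappa / 2.0)
    ankle = knee + d * unit(theta - kappa / 2.0)

    if noise > 0:
        hip = hip + rng.normal(0.0, noise, hip.shape)
        knee = knee + rng.normal(0.0, noise, knee.shape)
        ankle = ankle + rng.normal(0.0, noise, ankle.shape)

    series = KeypointSeries(time=t, hip=hip, knee=knee, ankle=ankle,
                            sampling_rate=fs, side="right")
    heel_contacts = np.round(cycle_starts_s[1:-1] * fs).astype(int)
    toe_offs = np.round(
        (cycle_starts_s[:-1] + PHI_TOE_OFF * periods) * fs).astype(int)
    truth = {
        "heel_contacts": heel_contacts,
        "toe_offs": toe_offs[toe_offs < n],
        "stride_periods_s": periods,
        "limb_angle_ext": ext,
        "limb_length": llen,
    }
    return series, truth


# ---------------------------------------------------------------------------
# Clinical tables


def sample_clinical(features_table: pd.DataFrame, scenario: Scenario,
                    rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Cluster-conditional clinical and gait variables.

    Ordinal scales are shifted binomial-discretized scores bounded to each
    scale's range; ``gait_speed`` and ``cadence`` are truncated normals with
    cluster location shifts, and the gait stability ratio is their quotient.
    Requires a ``cluster_truth`` column.
    """
    if "cluster_truth" not in features_table.columns:
        raise ValueError("features table must carry a cluster_truth column")
    rng = rng or np.random.default_rng(scenario.seed + 1)
    by_label = {c.label: c for c in scenario.clusters}
    unknown = set()
    for c in scenario.clusters:
        unknown |= set(c.clinical_effects) - set(CLINICAL_BASELINES) - set(GAIT_BASELINES)
    if unknown:
        raise ValueError(f"unknown clinical variable(s) in cluster effects: "
                         f"{sorted(unknown)}")

    out = {"participant": features_table["participant"].to_numpy(),
           "cluster_truth": features_table["cluster_truth"].to_numpy()}
    labels = features_table["cluster_truth"].to_numpy()

    for var, p0 in CLINICAL_BASELINES.items():
        lo, hi = CLINICAL_SCALES[var]
        vals = np.empty(len(labels), dtype=int)
        for i, lab in enumerate(labels):
            shift = by_label[lab].clinical_effects.get(var, 0.0)
            p = float(np.clip(p0 + shift, 0.02, 0.98))
            vals[i] = lo + rng.binomial(hi - lo, p)
        out[var] = np.clip(vals, lo, hi)

    for var, (mu0, sd) in GAIT_BASELINES.items():
        vals = np.empty(len(labels))
        for i, lab in enumerate(labels):
            shift = by_label[lab].clinical_effects.get(var, 0.0)
            vals[i] = rng.normal(mu0 + shift, sd)
        out[var] = np.maximum(vals, 0.05)

    df = pd.DataFrame(out)
    df["gait_stability_ratio"] = df["cadence"] / (df["gait_speed"] * 60.0)
    return df
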