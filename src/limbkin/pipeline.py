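"""End-to-end orchestration: simulate -> extract -> cluster -> compare.

Every stage exchanges plain CSV so any stage can be rerun standalone on
external data. All randomness flows from a single root seed that is split
per stage with ``numpy.random.SeedSequence``; two runs with the same config
and seed produce byte-identical CSV outputs (timestamps only appear in the
run log).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import gmm, kinematics, stats, synth
from .io import write_keypoint_csv

logger = logging.getLogger("limbkin")

CONTINUOUS_VARS = ["fms", "fma_sensory", "mas", "sf_bbs", "fac",
                   "gait_speed", "cadence", "gait_stability_ratio"]


@dataclass
class RunConfig:
    """Resolved pipeline configuration with study defaults.

    Defaults: 120 Hz sampling, 6 Hz 4th-order zero-lag low-pass, 201-point
    cycle normalization, 3 strides trimmed per end with 10 retained, mixture
    search over K = 4..7.
    """

    seed: int = 0
    out_dir: str = "run"
    scenario_yaml: str | None = None      # None -> bundled default scenario
    n_participants: int = 67
    noise_sd_px: float = 1.0
    sampling_rate: float = 120.0
    cutoff_hz: float = 6.0
    filter_order: int = 4
    filter_coordinates: bool = False
    trim: int = 3
    n_keep: int = 10
    k_min: int = 4
    k_max: int = 7
    n_restarts: int = 10
    meters_per_pixel: float | None = 0.001
    write_walks: bool = False
    significance_levels: tuple = (0.05, 0.01, 0.001)

    def validate(self) -> None:
        if self.cutoff_hz >= self.sampling_rate / 2:
            raise ValueError(
                f"filter cutoff {self.cutoff_hz} Hz must be below the "
                f"Nyquist frequency {self.sampling_rate / 2} Hz")
        if self.k_min > self.k_max:
            raise ValueError("k_min must not exceed k_max")
        if self.trim < 0 or self.n_keep < 1:
            raise ValueError("trim must be >= 0 and n_keep >= 1")
        if self.filter_order < 1:
            raise ValueError("filter_order must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.validate()
        return cfg


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.6f")


def simulate_stage(cfg: RunConfig, out: Path, seed_seq: np.random.SeedSequence):
    """Sample planted features and clinical scores; synthesize walks."""
    if cfg.scenario_yaml:
        scenario = synth.Scenario.from_yaml(cfg.scenario_yaml)
    else:
        scenario = synth.default_scenario(
            n_participants=cfg.n_participants, noise_sd_px=cfg.noise_sd_px)
    rngs = [np.random.default_rng(s) for s in seed_seq.spawn(3)]
    feats = synth.sample_features(scenario, rng=rngs[0])
    clinical = synth.sample_clinical(feats, scenario, rng=rngs[1])
    # realize the cluster-conditional gait parameters in the trajectories
    planted = feats.merge(
        clinical[["participant", "gait_speed", "cadence"]], on="participant")
    walks = {}
    for _, row in planted.iterrows():
        series, truth = synth.synthesize_walk(row, scenario, rng=rngs[2])
        walks[row["participant"]] = (series, truth)
        if cfg.write_walks:
            wdir = out / "walks"
            wdir.mkdir(exist_ok=True)
            write_keypoint_csv(series, wdir / f"{row['participant']}.csv")
    _write_csv(feats, out / "planted_features.csv")
    _write_csv(clinical, out / "clinical.csv")
    logger.info("simulate: %d participants, %d clusters, noise %.2g px",
                scenario.n_participants, len(scenario.clusters),
                scenario.noise_sd_px)
    return feats, clinical, walks


def extract_stage(cfg: RunConfig, out: Path, walks: dict) -> pd.DataFrame:
    """Per-participant stride-averaged features from keypoint trajectories."""
    rows = []
    for pid, (series, _truth) in walks.items():
        f = kinematics.process_walk(
            series, cutoff_hz=cfg.cutoff_hz, order=cfg.filter_order,
            trim=cfg.trim, n_keep=cfg.n_keep,
            meters_per_pixel=cfg.meters_per_pixel,
            filter_coordinates=cfg.filter_coordinates)
        rows.append((pid, f.limb_angle_ext_peak, f.limb_length_min_swing,
                     f.cadence, f.gait_speed, f.gait_stability_ratio,
                     f.n_strides_used))
    feats = pd.DataFrame(rows, columns=[
        "participant", "limb_angle_ext_peak", "limb_length_min_swing",
        "cadence", "gait_speed", "gait_stability_ratio", "n_strides_used"])
    _write_csv(feats, out / "features.csv")
    logger.info("extract: features for %d participants", len(feats))
    return feats


def cluster_stage(cfg: RunConfig, out: Path, features: pd.DataFrame,
                  seed_seq: np.random.SeedSequence):
    """Mixture-model clustering of the 2-D feature table with K selection."""
    X = features[["limb_angle_ext_peak", "limb_length_min_swing"]].to_numpy()
    seed = int(seed_seq.generate_state(1)[0] % (2 ** 31))
    model, table = gmm.select_model(X, K_range=range(cfg.k_min, cfg.k_max + 1),
                                    seed=seed, n_restarts=cfg.n_restarts)
    _write_csv(table, out / "selection_table.csv")
    labels = pd.DataFrame({"participant": features["participant"],
                           "cluster": model.hard_labels + 1})
    _write_csv(labels, out / "clusters.csv")
    _write_csv(gmm.ellipse_table(model), out / "ellipses.csv")
    logger.info("cluster: selected K=%d (BIC %.1f)", model.K,
                gmm.bic(model, len(X)))
    return model, labels


def compare_stage(cfg: RunConfig, out: Path, features: pd.DataFrame,
                  clinical: pd.DataFrame, labels: pd.DataFrame) -> dict:
    """Correlation of the two features plus cluster-wise group comparisons."""
    corr = stats.spearman_ci(features["limb_angle_ext_peak"],
                             features["limb_length_min_swing"])
    _write_csv(pd.DataFrame([{
        "rho": corr.rho, "ci_low": corr.ci_low, "ci_high": corr.ci_high,
        "p": corr.p, "n": corr.n}]), out / "correlation.csv")

    # measured gait parameters (from the trajectories) take precedence over
    # any synthetic draws carried in the clinical table
    dup = [c for c in clinical.columns
           if c != "participant" and c in features.columns]
    merged = features.merge(clinical.drop(columns=dup), on="participant")
    merged = merged.merge(labels, on="participant")
    variables = [v for v in CONTINUOUS_VARS if v in merged.columns]
    report = stats.compare_clusters(merged, merged["cluster"],
                                    continuous=variables)
    _write_csv(report["kw"], out / "kw_results.csv")
    _write_csv(report["pairwise"], out / "pairwise_posthoc.csv")
    for var, mat in report["posthoc"].items():
        mat.to_frame().to_csv(out / f"steel_dwass_{var}.csv",
                              float_format="%.6f")
    logger.info("compare: %d variables, %d pairwise tests",
                len(report["kw"]), len(report["pairwise"]))
    return report


def run_all(cfg: RunConfig, dry_run: bool = False) -> Path:
    """Run simulate -> extract -> cluster -> compare into ``cfg.out_dir``.

    On a stage failure, partial outputs are retained next to a FAILED marker
    naming the stage. Returns the run directory.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    if dry_run:
        print("resolved config:")
        for k, v in asdict(cfg).items():
            print(f"  {k}: {v}")
        print("stage plan: simulate -> extract -> cluster -> compare")
        return out
    out.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    root = np.random.SeedSequence(cfg.seed)
    stage_seeds = root.spawn(4)
    logger.info("run_all: seed=%d out=%s", cfg.seed, out)
    for key, value in asdict(cfg).items():
        logger.info("config %s = %r", key, value)

    stage = "simulate"
    try:
        feats_true, clinical, walks = simulate_stage(cfg, out, stage_seeds[0])
        stage = "extract"
        features = extract_stage(cfg, out, walks)
        stage = "cluster"
        model, labels = cluster_stage(cfg, out, features, stage_seeds[2])
        stage = "compare"
        compare_stage(cfg, out, features, clinical, labels)
    except Exception as exc:
        (out / "FAILED").write_text(f"stage {stage}: {exc}\n")
        logger.error("stage %s failed: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()
    return out
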