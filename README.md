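# limbkin

Post-stroke gait analysis from sagittal-plane limb kinematics: a Python
library plus a scripted analysis that goes from 2-D hip/knee/ankle
joint-center trajectories (markerless video capture at 120 Hz) to
per-participant gait features, Gaussian-mixture subgrouping, and
nonparametric clinical comparison of the subgroups. It is aimed at movement
scientists and rehabilitation researchers who want a reproducible,
scriptable version of this analysis — and, since clinical gait recordings
are rarely shareable, it ships a synthetic-cohort generator with planted
ground truth so every stage can be exercised and validated end to end.

## What it computes

Two whole-limb descriptors of the paretic side, per gait cycle:

- **peak limb extension angle** — the minimum of the signed angle θ between
  the downward vertical and the hip→ankle vector (flexion positive, so the
  extension peak is negative): how far the limb trails the body in late
  stance;
- **minimum swing-phase effective limb length** — the minimum of
  ℓ = |hip−ankle| / (|hip−knee| + |knee−ankle|) ∈ (0, 1] during swing: how
  much the limb functionally shortens for foot clearance.

Gait cycles are segmented from the shank angular velocity (heel contact at
the local minimum after the dominant swing peak, toe off at the one before
it), each cycle is spline-resampled onto 201 points, the first/last 3
strides are trimmed, and features are averaged over 10 retained strides.

Participants are then clustered in the (angle × length) plane with a
full-covariance Gaussian mixture fitted by EM; the number of clusters
K ∈ [4, 7] is selected by BIC, with ICL reported alongside
(BIC = −2 log L + p ln n, ICL = BIC + 2·assignment entropy; lower is
better). Clinical and gait variables are compared across clusters with
Kruskal–Wallis (effect size ε² = H/(n−1)) and the Steel–Dwass all-pairs
post-hoc test on the studentized-range scale; demographics use χ² tests.

See `docs/methods.md` for the full model, parameter defaults and
limitations.

## Worked example

The numbered scripts under `analysis/` run the whole study on a synthetic
67-participant cohort (seed 7) and write their tables under `results/run/`:

```bash
python analysis/01_simulate.py          # cohort with 5 planted clusters
python analysis/02_extract_features.py  # trajectories -> features
python analysis/03_cluster.py           # GMM + BIC/ICL selection
python analysis/04_compare_clusters.py  # nonparametric comparison
```

`02_extract_features.py` reports how well the measurement chain recovers
the planted ground truth through 1 px keypoint jitter:

```
extracted features for 67 participants
planted-vs-extracted angle error: mean -0.001 deg, max |.| 0.019 deg
planted-vs-extracted length error: mean +0.0010, max |.| 0.0065
```

`03_cluster.py` prints the model-selection table (lower is better) and the
chosen K:

```
 K        BIC        ICL  log_likelihood
 4 212.511262 214.328215      -57.901666
 5 237.840584 252.946155      -57.952249
 6 237.587663 244.997379      -45.211711
 7 240.405192 242.737812      -34.006397
selected K = 4
```

At n = 67 with overlapping planted components, BIC prefers a 4-component
merge of the two most-overlapping planted clusters — a realistic outcome
at this cohort size (on well-separated components the selection recovers
the planted K = 5; see the acceptance results below).

`04_compare_clusters.py` correlates the two features and compares the
clusters:

```
limb extension angle vs length: rho = 0.285, 95% CI [0.048, 0.492], p = 0.019

            variable      H  df  epsilon_sq     p stars
                 fms 23.521   3       0.356 0.000   ***
                 mas 11.925   3       0.181 0.008    **
              sf_bbs 48.517   3       0.735 0.000   ***
          gait_speed 40.888   3       0.620 0.000   ***
```

i.e. extension angle and limb length are weakly positively associated
overall, and the fitted clusters differ strongly in motor synergy (fms),
spasticity (mas), balance (sf_bbs) and gait speed — the planted
cluster-conditional effects — while sensory score (planted null) does not
separate. The same pipeline is available as a CLI
(`limbkin simulate|extract|cluster|compare|run-all`) and accepts real data
as OpenPose BODY_25 per-frame JSON or keypoint CSV plus a clinical CSV.

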