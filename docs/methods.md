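# Methods

## The measurement model

The pipeline quantifies post-stroke gait on the paretic side with two
whole-limb descriptors computed from sagittal-plane hip, knee and ankle
joint-center trajectories (markerless capture, 120 Hz):

- **Limb angle** θ: the signed angle between the downward vertical and the
  hip→ankle vector; flexion (ankle anterior to the hip) is positive. The
  per-cycle minimum of θ — a negative number reached in late stance — is the
  *peak limb extension angle*. It summarizes how far the limb trails behind
  the body at push-off.
- **Effective limb length** ℓ: the hip–ankle distance divided by the sum of
  the hip–knee and knee–ankle distances, so ℓ ∈ (0, 1] with ℓ = 1 for a
  fully extended knee. Its minimum during swing measures how much the limb
  functionally shortens to clear the ground.

Both quantities are unit-free (angles) or scale-free (a length ratio), so
pixel coordinates need no calibration. Gait speed alone requires an optional
meters-per-pixel factor.

Processing per walk:

1. Angle and length time series are computed from the raw coordinates and
   low-pass filtered at 6 Hz with a 4th-order Butterworth applied
   forward–backward (zero phase lag; the bidirectional pass doubles the
   effective order — we treat the stated order as per pass and document it,
   because biomechanics usage is ambiguous on this point). A config switch
   moves the filter to the coordinate level for sensitivity analysis.
2. The shank angle (knee→ankle from vertical, same sign convention) is
   differentiated (central differences) to angular velocity. Per stride,
   swing appears as a dominant positive peak; **heel contact** is the local
   minimum immediately following that peak and **toe off** the local minimum
   immediately preceding it — the standard shank-gyroscope event rule. Swing
   peaks must exceed 20 % of the maximum peak prominence and are separated
   by at least 60 % of the autocorrelation-estimated stride period; minima
   with prominence below 2 % of the signal range are treated as ripple.
   Both thresholds are exposed in the API.
3. Each heel-contact-to-heel-contact cycle is resampled onto 201 equally
   spaced points with a cubic spline (endpoints preserved exactly).
4. The first and last 3 strides are discarded (gait initiation/termination
   transients) and up to 10 of the remaining strides are retained; if fewer
   remain, all are used with a logged warning. Features are per-stride
   minima — the limb-angle minimum over the whole cycle, the limb-length
   minimum over the detected swing window (toe off → next heel contact) —
   averaged across retained strides; ties at the minimum resolve to the
   earliest frame. Cadence comes from heel-contact intervals (2 steps per
   stride), speed from net hip displacement, and the gait stability ratio
   is cadence / (speed × 60) in steps per meter.

Open choices we fixed (the source protocol does not pin them down): the
swing window for the length minimum uses the *detected* toe off rather than
a fixed %-cycle window; the filter acts on derived angle/length series
rather than raw coordinates; the shank segment is knee→ankle measured from
vertical.

## Clustering

Participants are points in the 2-D feature plane (peak extension angle ×
minimum swing limb length). A Gaussian mixture with full, unequal
per-component covariances is fitted by EM (k-means++-style seeding, 10
restarts, relative log-likelihood tolerance 1e-8, at most 500 iterations).
Covariances receive a 1e-6 trace-scaled ridge only when nearly singular, so
healthy fits are exact maximum likelihood; a run that still collapses a
component is retried with a stronger ridge and the fit fails only if every
restart collapses.

Model order is searched over K = 4…7 and selected by criteria in the
lower-is-better convention:

    BIC = −2 log L + p ln n,        p = 6K − 1 in 2-D
    ICL = BIC + 2·EN,               EN = −Σᵢₖ ẑᵢₖ ln ẑᵢₖ

ICL ≥ BIC, with equality for a perfectly hard partition. The tool selects
the lowest BIC and logs any BIC/ICL disagreement: deciding whether a
clustering is *substantively* valid is an analyst judgment that cannot be
mechanized. Per-component 95 % confidence ellipses use semi-axes
√(χ²₂(0.95)·eigenvalues) (χ²₂(0.95) = 5.9915) and the leading-eigenvector
orientation.

## Statistics

- **Spearman ρ** between the two features, two-sided p from
  t = ρ√((n−2)/(1−ρ²)) on n−2 df, and a 95 % CI from the Fisher
  z-transform with SE 1/√(n−3). These reproduce the published triple
  (ρ = 0.246, n = 67 → p = 0.045, CI [0.006, 0.459]) to printed precision,
  which is how the CI method was identified.
- **Kruskal–Wallis** (tie-corrected) per variable across clusters with the
  effect size ε² = H/(n−1); this definition reproduces both published
  values (0.829 from H = 54.691 and 0.726 from H = 47.947 at n = 67).
- **Steel–Dwass** all-pairs post hoc: per pair, rank the pooled pair with
  average ranks, form the tie-corrected standardized rank-sum statistic z,
  and refer q = |z|√2 to the studentized range distribution with k groups
  and ∞ df. No further multiplicity adjustment is applied (the procedure
  controls the family-wise error itself). An exhaustive-permutation exact
  version (`steel_dwass_exact`) serves as a small-sample reference; on
  integer fixtures with three groups of four the asymptotic p-values agree
  with it within about 0.013.
- **Pearson χ²** (no continuity correction) for categorical demographics,
  with a logged warning when expected counts fall below 5.

## Synthetic cohort generator

No real cohort is distributed, so every pipeline stage is exercised against
a generator with planted structure:

- **Features**: a configurable K-component Gaussian mixture over
  (extension angle, limb length). The default five-component layout crosses
  high/mid/low extension angle (−22°, −14°, −6°) with high/low limb length
  (0.96, 0.87), weights 10/17/11/10/19 ÷ 67, the first component with the
  largest angle variance — qualitatively the published cluster geometry,
  including partial overlap of adjacent ellipses. Draws falling outside the
  physical domain (ℓ ≤ 1) are redrawn, i.e. components are truncated
  Gaussians at the feasibility boundary. `well_separated_scenario()` is the
  same layout with covariances × 0.25, used for mixture-order-recovery
  studies where separation is the stated premise.
- **Walks**: the inverse problem. The limb angle follows a fixed
  three-harmonic Fourier waveform rescaled so its minimum equals the
  planted extension angle and its maximum a +25° flexion peak; the
  extension peak sits at ~55 % cycle and the flexion peak in terminal
  swing. The third harmonic sculpts a terminal-swing retraction dip so the
  shank-angular-velocity heel-contact rule lands within 2 frames of the
  true cycle boundary even after 6 Hz filtering — with fewer harmonics the
  dip location cannot be controlled independently of the two peaks. Knee
  flexion is a raised-cosine swing bump (toe off at 60 %, re-extension by
  98 %) whose depth 2·arccos(ℓ_min) plants the length minimum exactly;
  hip height is constant at twice the 500 px segment length, forward
  progression is linear plus a small 2-per-cycle sway, stride periods are
  N(1.2 s, 0.04 s) truncated to ±50 % (a comfortable post-stroke cadence of
  ~100 steps/min), and isotropic Gaussian keypoint jitter (default 1 px on
  a 1000 px leg) emulates markerless-capture noise. Per-participant cadence
  and speed, when supplied, override the stride period and hip speed so
  cluster-conditional gait differences are realized in the trajectories.
- **Clinical scores**: shifted binomial-discretized ordinals clipped to
  each scale's range (motor synergy 0–22, sensory 0–12, spasticity 0–5,
  short-form balance 0–28, ambulation category 0–5) — bounded, ordinal and
  nonparametric-friendly — plus truncated-normal gait speed and cadence.
  These are structural stand-ins: no published distributional description
  of the cohort exists beyond summary tables, so they are not calibrated
  to it.

What passing tests therefore do and do not show: the round-trip and
recovery results demonstrate that the *measurement and inference chain* is
correct on data whose ground truth is known and whose waveform family the
generator controls; they do not certify accuracy on real video-derived
keypoints, which have occlusions, identity switches, soft-tissue and
perspective artifacts the generator does not emulate (dropout handling in
the OpenPose reader — linear interpolation up to 5 consecutive
low-confidence frames, error beyond — is a documented policy, not a
validated model of such artifacts).

## Numerical choices and problem sizes

- Round-trip accuracy is quoted on the physiological core domain
  (extension angle −40°…−4°, length 0.80…0.98, 10×10 grid): noise-free
  errors ≤ 0.004° and ≤ 0.002, well inside the 0.5° / 0.005 contracts. The
  generator accepts the wider domain (−60°, 0°) × (0.5, 1]; very deep
  shortening (ℓ < 0.7) pushes knee-bump harmonics toward the 6 Hz cutoff
  and degrades length recovery to ~0.006.
- Mixture-order recovery: 20 cohorts of n = 300 from the well-separated
  layout, K searched over 4…7 with 10 restarts (~1 min on one CPU).
- Null calibration: 10⁴ replicate 67-participant cohorts with zero planted
  clinical effects; the Kruskal–Wallis rejection rate at α = 0.05, pooled
  over two ordinal and two continuous variables, is ~0.045 (mild
  conservatism from discreteness of the ordinal scales).
- EM determinism: all randomness flows from integer seeds through
  `numpy.random.Generator`; identical seeds give identical models, and the
  whole pipeline splits one root seed per stage via `SeedSequence`.

## Known limitations

- 2-D sagittal kinematics only; no joint-angle decomposition, no frontal or
  transverse planes, no kinetics or EMG.
- The event rule is tuned to signals with a single dominant swing peak per
  stride; pathological gait with double-peaked shank velocity may need the
  exposed prominence/period thresholds adjusted.
- ICL is implemented in its standard entropy-penalized form; published
  values computed under other conventions are not comparable in magnitude.
- The exact Steel–Dwass reference enumerates all partitions and is feasible
  only for pooled samples of ≤ 14 observations.
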