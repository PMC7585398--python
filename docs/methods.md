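# Methods

`cprnfl` studies the behaviour of the *global circumpapillary RNFL
thickness change* metric — ΔG, the follow-up-minus-baseline difference of
the 360° average cpRNFL thickness G from an optic-disc circle scan — as an
event criterion for glaucomatous progression. The package simulates
paired-visit thickness profiles with known ground truth, applies the
progression criteria clinicians use, grades the measurement artifacts that
corrupt ΔG, and quantifies the resulting false-positive and
false-negative behaviour.

## The measurement model

A visit is a thickness profile T(θ), θ ∈ [0°, 360°), sampled on a uniform
grid of 768 points (a typical A-scan count for a 3.5-mm circle scan).
Angle 0° is the temporal meridian, increasing through superior, in
right-eye canonical orientation; display conventions (TSNIT,
temporal-centered) are left to the caller. G is the plain arithmetic mean
of the grid samples; ΔG = G_followup − G_baseline, so negative values mean
thinning.

Two numerical conventions matter:

* **Exact quadrature.** G and all region contributions use correctly
  rounded summation (`math.fsum`), so G is invariant under any permutation
  of the samples — a pure rotation (alignment) artifact changes ΔG by
  *exactly* zero — and contributions over any partition of the circle sum
  to ΔG exactly.
* **Grid-snapped regions.** Angular regions (lesions, artifact arcs,
  sectors) are realized by rounding their start and end independently to
  the nearest grid step. An arc and its complement therefore tile the
  circle exactly, at the cost of realized widths differing from requested
  ones by up to half a step (0.23°).

The validity mask distinguishes measured-but-corrupt samples from clean
ones. The default `include_measured` policy averages measured values
regardless of validity — mirroring devices, where clipped A-scans corrupt
the reported G — while `exclude` drops them; both are exposed because
device behaviour for clipped samples is not documented.

## The synthetic cohort generator

The generator defines the study conditions and is first-class, tested
code. Each eye is built as:

* **Healthy shape**: base level 70 µm plus wrapped-Gaussian superior and
  inferior humps (centers 90°/270°, amplitudes 60/65 µm, SD 40°) and four
  narrow raised-cosine vessel bumps (15 µm × 6°, shadow width 3°),
  giving a healthy G ≈ 105 µm, within the normal range for this scan
  circle. Between-eye anatomy varies by an additive offset with SD 8 µm.
* **Test-retest noise**, split structurally into (a) a per-visit G-level
  offset drawn from N(0, g_retest_sd/√2) with g_retest_sd = 2.4 µm, so ΔG
  under no change has SD exactly 2.4 µm and 95% limits 1.96 × 2.4 ≈
  4.7 µm — slightly below 5 µm, the empirical basis of the clinical
  "rule of 5"; and (b) a pointwise field (SD 1 µm, moving-average
  smoothed over ~5°, circular-mean removed) that perturbs profile *shape*
  without touching G. Only the G-level SD is contractual; the split
  allocates most pointwise retest variance (total ≈ 2 µm per sample) to
  the common mode, and keeps detector thresholds (below) separated from
  shape noise by ≥ 5σ.
* **Lesions**: boxcar (uniform, exact arithmetic) or raised-cosine
  (tapered, default) thinning. `depth_um` is the *mean* thinning over the
  support, so any lesion removes width·depth/360 µm from G up to grid
  realization; a local defect is < 45° wide, widespread thinning ≥ 90°.
* **Artifacts**, applied per visit in a fixed canonical order
  (segmentation → schisis → scaling → rotation → clipping): signed
  regional offsets (segmentation/schisis, graded only when > 5° wide),
  whole-profile scaling by 1+s with |s| ≤ 5% (the "apparent change in
  retinal thickness"), rotation by whole grid steps (shifting vessel
  markers identically), and clipping, which collapses a region to a floor
  value (default 10 µm) and invalidates it. Noise is added *before*
  artifacts so clipping deterministically produces its floor value.

Cohort defaults emulate the observed factor mix: segmentation errors in
44% of eyes, clipping in 1.2%, scaling in 5%, rotation in ~7%;
segmentation magnitudes (5–20 µm over 6–40°) are configuration, not
claims — published examples quantify only single cases (e.g. a −2 µm
contribution from one region).

What the generator does **not** emulate: B-scan image content (graders'
primary evidence), spatial correlation of disease with anatomy, floor
effects in advanced damage, left-eye mirroring, media opacity, or
longitudinal series beyond two visits. Passing tests therefore demonstrate
the *arithmetic and statistical* mechanisms of ΔG failure, not clinical
performance on real scans.

## ΔG decomposition

For synthetic eyes the measured ΔG is decomposed by replaying the
lesion/artifact chain on the latent noise-free profiles and assigning each
step the increment of G it produces (baseline-visit artifacts enter with
opposite sign — the grid analogue of measuring the area between the
baseline and follow-up curves over each region). The residual is tagged
`noise`, so tagged contributions sum to ΔG exactly (telescoping); the
lesion-only term equals the ΔG that perfect segmentation would have
yielded. Factor ranking (primary/secondary cause per eye) orders causes by
absolute contribution, ignoring causes below 0.1 µm.

## Progression criteria

* **Fixed cutoff**: flag iff ΔG ≤ −c, c ∈ {3,…,8} µm; c = 5 is the rule
  of 5. The boundary is inclusive (no published eye sits exactly on one).
* **Quantile-regression cutoff**: an affine conditional quantile of
  follow-up G on baseline G fitted on short-interval test-retest pairs at
  τ = 0.05 (the 95th percentile of loss — reported cutoffs are negative,
  i.e. the lower tail of follow-up given baseline), via
  `statsmodels` QuantReg (IRLS minimization of the check loss,
  deterministic for fixed input order). The cutoff function is
  cutoff(G_b) = (intercept + slope·G_b) − G_b; under heteroscedastic
  retest noise growing with baseline thickness it spans ≈ −1.4 µm at
  G_b = 60 to ≈ −4 µm at G_b = 110. Both criteria are scikit-learn-style
  estimators (`fit`/`predict`/`get_params`) and compose with sklearn
  tooling.

Note a subtlety the calibration tests respect: when the regressor is the
*measured* (noisy) baseline G, the conditional spread of follow-up given
baseline widens and the fitted cutoff is correspondingly deeper than
−1.645·σ of a single visit. Calibration uses the standard construction —
follow-up = baseline + N(0, σ) — where the closed form −1.645σ applies.

## Artifact grading rules

Operational versions of the visual grading rules, with defaults chosen so
every detector false-alarms on ≤ 2% of clean eyes (measured by Monte
Carlo, n = 1000):

* **Defects** (`detect_defects`): runs where follow-up < baseline −
  depth_min (5 µm) *and* below the normative 5th-percentile band; runs
  separated by < 5° merge; merged runs narrower than 6° (the noise
  correlation scale) are not graded. Local < 45°; widespread when the
  containing below-band run ≥ 90°; the [45°, 90°) gap is labelled
  `intermediate` rather than forced into either class. Width is measured
  on the follow-up-minus-baseline run. Normative bands are empirical
  per-sample 5th/1st percentiles over simulated healthy eyes (device
  normative databases are proprietary).
* **Segmentation** (`grade_segmentation`): defined for synthetic eyes
  (requires latent truth — graders use b-scan images, which are not
  modelled). The global median of measured−true is subtracted first
  (a uniform offset is retest noise, not mis-segmentation); runs with
  |departure| > tol (5 µm, 5× the shape-noise SD) wider than 5° are
  reported with signed mean error per visit. Clipped samples are never
  charged to segmentation.
* **Alignment** (`check_alignment`): vessel-shadow markers matched in
  order; misaligned when the median absolute shift exceeds the median
  shadow width (~3°).
* **Scaling** (`estimate_scaling`): least-squares fit of
  T_f = a + (1+s)·T_b on samples valid in both visits and outside known
  defect/segmentation arcs. The intercept absorbs additive G-level retest
  offsets, which an intercept-free ratio estimator would misread as
  scaling; for angularly flat profiles (intercept unidentifiable) the
  exact ratio estimator is used. Flag at |s| ≥ 0.02, below the 5%
  physical ceiling.
* **Clipping** (`detect_clipping`): runs of invalid or ≤ floor samples at
  least 10° wide.

## Evaluation

Confusion tables count flags against reference labels P / NP; `uncertain`
eyes are excluded from accuracy (their count is still reported).
Sensitivity = 1 − FN rate is emitted alongside FN. Display rounding
follows the published convention: percentages to one decimal, accuracy to
the nearest integer percent with .5 rounding away from zero; raw
fractions are retained in machine output. `reproduce_published_tables`
recomputes every sweep-table accuracy cell from its own FP/FN counts
(30 P / 61 NP), cross-checks the listed FP eyes' ΔG against the FP
column, and verifies the 16 listed FN eyes are unflagged at the 4 µm
criterion; two internal inconsistencies of the printed tables (one
ambiguous rounding cell; an FN count at cutoff 3 inconsistent with the
rounded per-eye ΔG list) are *reported* as discrepancies, never silently
reconciled.

The mechanism experiment runs paired cohorts differing in one factor:
local 30° × 12 µm lesions (true ΔG −1 µm) versus widespread 270° × 8 µm
thinning (true ΔG −6 µm) for sensitivity of the 4 µm criterion, and NP
arms with/without a 40° × −20 µm follow-up segmentation error (≈ −2.2 µm
bias) for the FP rate. Because ΔG under the noise model is exactly
N(truth, 2.4 µm), each arm has a closed-form normal-tail oracle
(≈ 10.6% vs ≈ 79.8% sensitivity; ≈ 4.8% vs ≈ 22.8% FP), and the Monte
Carlo arms (default n = 800–2000 eyes, chosen to resolve these contrasts
at ≥ 3σ while keeping runs in seconds) reproduce them.

## Determinism and problem sizes

All randomness flows from one seed through named substreams
(`numpy.random.default_rng([seed, k])`); identical configurations yield
bit-identical artifact directories, including CSV bytes (floats are
written with shortest-roundtrip precision and parsed with
`float_precision="round_trip"`). Default test and acceptance problem
sizes — 2000 pairs for QR calibration, 20 000 pairs for retest limits,
800–2000 eyes per mechanism arm, 1000-eye decomposition sweeps — complete
in a few seconds each on one core.

## Known limitations

* Segmentation grading and ΔG decomposition require latent ground truth
  and are therefore synthetic-only; no measured-only segmentation
  detector is provided.
* The heteroscedastic retest model behind the baseline-dependent QR
  cutoff is a stylized linear-SD emulation, not an estimate from real
  repeatability data.
* Grid snapping makes requested region widths exact only when they are
  multiples of the 0.46875° step.
* The reference cohort's published FP/FN counts arise from expert grading
  of real scans and are not recomputable from synthetic data; the package
  reproduces their internal arithmetic and the mechanisms behind them,
  not the counts themselves.
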