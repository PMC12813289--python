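# Methods

`nirflow` quantifies near-infrared fluorescence (NIRF) lymphangiography of
the mouse flank: indocyanine green (ICG) is carried by a conducting
lymphatic vessel between the inguinal and axillary lymph nodes, and the
vessel's phasic contractions modulate the fluorescence seen by the camera.
This note records the models, the parameters that matter, and the design
choices made where the imaging procedure left them open.

## Pumping rate

The measurement is trough counting. A circular ROI is placed over the
conducting vessel, the mean ROI intensity of each frame gives a trace, and
the rate is

    rate [pumps/min] = T_r / (F / (fps · 60))

with `T_r` counted troughs, `F` frames in the session, and `fps` the frame
rate (5 frames/s throughout). The implementation computes the
algebraically identical `T_r · fps · 60 / F` so that integer-valued worked
examples round-trip exactly in floating point.

**Trough detection** (`pumping.detect_troughs`) returns interior local
minima whose topographic prominence is at least `prominence_fraction`
(default 0.15) of the trace's max−min range — absolute NIRF intensity is
arbitrary, so the threshold must be relative. Candidates closer together
than `min_separation_s` (default 2 s, i.e. a physiological ceiling near 30
pumps/min) are thinned, keeping the deeper (lower-valued) minimum and, on
ties, the earlier one. Endpoints are never troughs because their
prominence is undefined.

Whether any smoothing precedes counting was an open choice; we apply a
Gaussian pre-smoothing with sigma `smooth_s` = 1.0 s by default. A human
counter reading a plotted trace implicitly low-passes it; without
smoothing, shot noise produces spurious prominence-passing minima and the
estimated rate is biased high by roughly one false trough per 3-minute
session. The smoothing kernel is symmetric, so the minima of noiseless
periodic traces do not move and all exact-count checks are unaffected.
Detrending (running-median subtraction, `detrend_window_s`) exists for
drifting traces but is **off** by default, matching the raw-trace reading
procedure.

**Baseline averaging** (`pumping.baseline_rate`): the left and right
collecting vessels imaged on two different days give four measurements per
animal; the baseline is their unweighted mean. Sessions shorter than 180 s
trigger a warning, not an error.

## Synthetic NIRF data

The generators state the world the tests live in; every one is a pure
function of its parameters and an integer seed (bit-identical reruns), and
timing and camera noise draw from separate child streams so that toggling
noise never changes the contraction times.

* **Traces** (`simulate_trace`): raised-cosine dips below an ICG baseline.
  Dip depth is `amplitude_fraction · background` (default 0.3 — a clearly
  visible but not saturating pulse), dip width is half the nominal period.
  Inter-pulse intervals are gamma distributed with mean `60/true_rate` s
  and CV `rate_jitter_cv` (default 0.1; gamma keeps intervals positive).
  The first trough sits half an interval in, so a jitter-free 3-minute
  trace at 6 pumps/min holds exactly 18 evenly spaced troughs. Truth
  trough times are the interior local minima of the noiseless pulsation
  component — under jitter two dips can overlap, and the merged minimum is
  the observable ground truth.
* **Camera** (`CameraParams`): 5 frames/s, optional Poisson shot noise on
  the clean signal followed by additive Gaussian read noise (default SD
  2), clipped to the bit depth (default 16-bit). The default background of
  100 counts puts shot noise at SD ≈ 10 against a 30-count pulse — a
  moderately noisy but countable trace.
* **Stacks** (`simulate_stack`): a tube of half-width `radius_px` around a
  centerline polyline, 150 counts above background, modulated by the same
  contraction model, with a mild 0.8-px optical blur. The truth mask stays
  the crisp distance-to-centerline threshold.
* **Cohorts** (`simulate_cohort`): per-animal true rates are Normal(mean,
  SD) per genotype preset, truncated at 0.5 pumps/min by resampling (the
  GHA preset's SD of 1.5 makes negative draws possible otherwise). The
  shipped presets are bGH 8.6 ± 0.7, WT 6.8 ± 1.0, GHA 6.4 ± 1.5, GHRKO
  4.7 ± 1.1 pumps/min; the "±" values are read as between-animal SD (they
  are unlabeled at source; SEM or CI readings would shrink the spread but
  not move the means the recovery tests target).
* **Wound series** (`simulate_wound_series`): before the truth
  reconnection day the main vessel mask has a 12-px gap at the polyline
  midpoint; from that day on it is continuous. Collateral detours, when
  requested, attach only on the node-A side and never bridge the gap, so
  truth connectivity is exactly the day threshold.
* **IHC phantoms** (`make_ihc_phantom`): a Gaussian-smoothed random field
  thresholded at the matching quantile gives a truth mask whose area
  fraction equals the requested positive fraction almost exactly; positive
  pixels are drawn ~80 counts brighter than background.

What the generators do **not** model: dye pharmacokinetics, optical
scattering and depth-dependent PSF, breathing/motion artifacts, vessel
diameter changes, or registration error across imaging days. A green test
therefore establishes that the algorithms recover the stated contraction
and geometry model under camera noise — not that they are robust to every
artifact of in-vivo imaging.

## Vascular density and reconnection

LVD follows the imaging workflow: average projection over the session's
frames, multiscale Hessian "tubeness" enhancement, pixel-classifier
segmentation, and normalization.

* **Tubeness** (`vasculature.tubeness`): per scale σ the image is smoothed
  at σ and the Hessian eigenvalues ordered |λ1| ≤ |λ2|; the bright-tube
  response is σ²·max(0, −λ2), maximized over scales (a Sato-style filter,
  mirroring the common plugin behavior). Boundaries are reflective so
  constant images give exactly zero. For a ridge of Gaussian cross-section
  width w, the σ²-normalized centerline response peaks at σ = √2·w — the
  scale-selection tests assert this closed form. Choose `scales` near the
  expected vessel half-width; defaults are (1, 2, 3) px for the bundled
  phantoms. Oversized scales produce a broad halo that can bridge true
  gaps, which matters for reconnection calls.
* **Segmentation** (`train_segmenter`/`segment`): a 100-tree random
  forest over a Weka-like feature stack (per scale: Gaussian smoothing,
  gradient magnitude, both Hessian eigenvalues, difference of Gaussians,
  plus raw intensity), deterministic for a fixed seed. Untrained, a
  deterministic fallback Otsu-thresholds the tubeness map; because Otsu
  always splits something, the fallback returns an empty mask unless the
  putative foreground is at least 2 background-SDs brighter than the rest
  of the image.
* **LVD** (`compute_lvd`): foreground area divided by the normalization
  ROI. The genotype ROI is realized as a square whose side is the mean of
  the ear-to-tail and back-to-belly lengths (the source describes the
  average length only; a square is the simplest consistent area). With a
  pixel size the ratio is mm²/mm²; uncalibrated, both terms are px².
  Genotype body lengths are configuration inputs, not constants.
* **Reconnection** (`reconnection_day`): a day is connected when, after
  one pass of 3×3 morphological closing (tolerating 1-px segmentation
  gaps without bridging distinct vessels), a single 8-connected foreground
  component intersects both node ROIs. The reconnection day is the
  earliest connected day; later re-occlusion is allowed and reported in
  the per-day flags.

## IHC area fraction

`area_fraction` is foreground count over region size; on the two-phase
phantoms the bright (stained) phase is segmented by Otsu thresholding of
the intensity image, the single-image analogue of a trained two-class
pixel classifier.

## Adaptive statistics

All decisions use α = 0.05. For two groups, Shapiro-Wilk runs per group
and the data are "normal" only when **both** pass; variance homogeneity is
then tested with the F-test (normal data) or the Brown-Forsythe
median-centered Levene test (non-normal data). The selection table:

| normal | equal variance | test |
|---|---|---|
| yes | yes | unpaired two-tailed t |
| yes | no | Welch's t |
| no | yes | Mann-Whitney U |
| no | no | Kolmogorov-Smirnov |

Mann-Whitney uses exact enumeration for groups of ≤ 8 without ties and
the tie-corrected normal approximation otherwise. Degenerate input (all
values identical in both groups) short-circuits to p = 1.

For ≥ 3 groups: one-way ANOVA with the Tukey-Kramer post hoc (harmonic
handling of unequal n via statsmodels) and a capital letter display when
every group is normal with homogeneous variance; otherwise Kruskal-Wallis
(tie-corrected H) with Dunn's rank z-tests, Bonferroni-adjusted over all
pairs (the adjustment was unspecified at source; Bonferroni is the
conservative default), and a lower-case display. The normal-but-
heteroscedastic multi-group case was undefined in the source procedure;
it routes to the nonparametric branch as the safer choice. Post hoc
matrices are computed **only** when the omnibus p < α.

**Compact letter display** (`compact_letter_display`): the
insert-and-absorb algorithm — start with one column holding all groups;
for each significant pair, split every column containing both members
into two copies (each missing one member) and absorb columns that are
subsets of others; letters are assigned to the surviving columns in group
order. Groups share a letter iff their adjusted p ≥ α; tests verify both
this equivalence and minimality of the letter count against an exhaustive
clique-cover search for up to five groups.

Under a Normal null the full adaptive two-group procedure's empirical
type-I error is 0.05 within ±0.01 (10,000-replicate simulation in the
test suite).

## Numerical and interface choices

* fps is mandatory stack metadata (TOML sidecar or explicit flag): a wrong
  frame rate rescales every rate silently, so absence is an error, never a
  default.
* Coordinates are 0-based (row, col); ROI circles are `row,col,radius`.
* JSON/CSV outputs format floats at 6 significant digits so identical
  runs diff byte-for-byte.
* Every stochastic stage takes an explicit integer seed; generators use
  split child streams so sub-stage draws are independent of each other.

## Known limitations

* The trough detector's defaults are tuned for rates of roughly 2–30
  pumps/min at 5 frames/s; far faster rhythms need a smaller
  `min_separation_s` and `smooth_s`.
* The Otsu fallback segmentation assumes bright vessels on a darker,
  roughly uniform background; heterogeneous backgrounds need the trained
  classifier.
* Reconnection is judged on segmented masks, not flow; a geometrically
  continuous but non-conducting vessel would still count as connected.
* The statistics module implements the two-group and one-way comparisons
  only; repeated-measures (mixed-effects two-way) designs are out of
  scope.
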