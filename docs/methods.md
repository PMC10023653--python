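# Methods

This note documents the models, conventions and design choices behind
`tdpquant`: what the synthetic scenes emulate, how the classifier and
pool-partitioning are defined, how the FRAP metrics are computed, and what
the tests do and do not establish about real microscopy data.

## Synthetic scenes

### Geometry

A scene is a single 2-D field (default 1024×1024 px at 0.19 µm/px,
16-bit saturation 65535), standing in for a maximum-projected confocal
field. Cells are ellipses: nuclei with semi-major axis 5.0–6.5 µm
(HEK-like, ~10–13 µm across), aspect 0.75–0.95, random orientation; the
cytoplasm is the surrounding ellipse scaled 1.6×. Cells are placed by
rejection sampling so that their bounding circles are disjoint; a scene
that cannot accommodate the requested cell count within a bounded number
of attempts is rejected with an error. Each nucleus carries 1–3 dark
nucleolar voids (0.6–1.2 µm semi-axes), from which both channels are
excluded.

### Channels and expression

Every cell expresses tagged endogenous TDP-43: a per-cell diffuse nuclear
concentration drawn lognormally around 12% of saturation (σ_log = 0.08,
modelling clone-to-clone and cell-to-cell expression variability). A
configurable fraction of cells (default 0.7) is transfected with the
exogenous GFP-tagged variant at a lognormal level (median 5% of
saturation, σ_log = 0.5) — the cell-to-cell variability that the
concentration-dependence regressions rely on. Nuclear variants (WT, 4FL,
2KQ) distribute the exogenous protein in the nucleoplasm; ∆NLS variants in
the cytoplasm; the GFP-only control fills the whole cell and forms no
assemblies.

### Assemblies

Per transfected cell, each class count is Poisson with the configured
rate. True diameters: puncta 0.5–2.5 µm (homogeneous disks), anisosomes
1–4 µm (rings with inner radius 0.5× the outer radius; core intensity
fixed at 0.15× the rim, safely under the 0.3 class-consistency bound),
inclusions 4.6–7 µm (disks perturbed by low-order radial harmonics,
re-drawn if the equivalent diameter falls below 4.05 µm). Rim/disk
amplitudes are 32–55% of saturation for puncta and anisosome shells and
75–95% for inclusions, so puncta/anisosomes clear the 25% detection
threshold but not the 60% inclusion criterion.

Placement samples centres inside the nucleus (anisosomes and nuclear-
variant assemblies) or the cytoplasmic annulus, largest object first —
this ordering makes dense draws packable far more often than insertion
order. Two policies govern what happens when an object cannot be placed
without touching another after 150 attempts:

* `overlap` (default): the object is placed anyway. This is the realistic
  projected-3-D behaviour and the only way to render the crowded regime of
  ~20 anisosomes per nucleus formed by nuclear 4FL/2KQ; overlapping pixels
  belong to the first-placed object, and fully occluded draws keep a
  ground-truth row with zero rendered pixels.
* `drop`: the draw is omitted from the scene *and* the ground truth. This
  is the resolvable-object regime used for oracle-recovery testing, where
  per-object identity must be well defined.

Cytoplasmic inclusions deserve a note: a 4.6–7 µm object cannot fit
between the nucleus and a disjoint cell boundary at these cell sizes, so
their nucleus-exclusion margin is capped (they press against the nucleus,
as real perinuclear aggregates do) and they effectively exist only under
the `overlap` policy. Oracle-recovery scenes therefore carry inclusions in
the nuclear condition, where a single inclusion does fit.

### Sequestration and conservation

Each cell owns a fixed endogenous budget `T = c0 · area(nucleus \ voids)`.
Assemblies are enriched in endogenous signal by a partition coefficient
`K_cell = K · L / E[L]`, where `K` is the configured
`sequestration_coefficient` and `L` the cell's exogenous level — a
mass-action-like recruitment that makes sequestration concentration-
dependent without changing object counts or geometry. The diffuse
concentration solves

    c = T / (A_diffuse + K_cell · A_shell),

and the channel is painted with `c` on the diffuse nuclear area, `K_cell·c`
on assembly pixels (shell pixels for anisosomes; their cores are TDP-43
voids), and 0 elsewhere. The image is then quantized to whole grey levels
and the ground-truth pools are integrated from the quantized noiseless
image over the true masks, so

    diffuse + sequestered(nuclear) + sequestered(cytoplasmic) = total

holds exactly in integer arithmetic, cell by cell. Gaussian read noise
(default σ = 300 grey levels ≈ 0.5% of range) is added last and clipped;
ground truth is always emitted before noise. Per-variant defaults encode
the phenotypes the analysis contrasts: anisosome rate 20 for nuclear
4FL/2KQ, puncta-dominated rates for WT and the ∆NLS variants, and
coefficients ordered 2KQ/4FL > ∆NLS-combinations > WT > ∆NLS > GFP-only.

What the generator does **not** model: optics (no PSF; a blur option was
deliberately omitted because it would redistribute signal across mask
boundaries and break exact conservation), Poisson/photon statistics,
camera gain, 3-D structure beyond what overlapping projections imply,
stress-granule biology, or autofluorescence. Passing tests therefore
certify the *measurement pipeline* — thresholds, masks, bookkeeping,
estimators — not robustness to real-microscope noise or debris.

## Segmentation and classification

Nuclei are segmented on the endogenous channel with an automatic global
threshold (Li minimum cross-entropy by default — robust to the skewed
histograms that bright inclusions create; Otsu available), hole filling
(nucleolar and anisosome-core voids belong to the nucleus), removal of
objects below 5 µm diameter, and distance-transform watershed to split
touching nuclei. Cells grow from nuclei by bounded expansion (8 µm)
restricted to the foreground of the summed channels.

Assemblies are connected components of exogenous pixels at or above 25% of
saturation. Each candidate is hole-filled (a dark anisosome core leaves a
hole at the detection threshold) and classified on measured properties:

1. **inclusion** — equivalent diameter ≥ 4 µm *and* maximum intensity
   ≥ 60% of saturation. The intensity criterion uses the object maximum
   because inclusions are described as saturated structures; this makes
   the 25% detection and 60% inclusion thresholds composable on one
   candidate set.
2. otherwise, with equivalent diameter in [0.5, 4) µm: **anisosome** when
   the mean intensity of the core zone (pixels within 40% of the
   equivalent radius of the centroid) is at most 0.5× the rim mean
   (boundary inclusive), else **punctum**.
3. everything else is discarded and tallied in a QC report — including
   ≥ 4 µm objects that fail the 60% criterion, a decision-table cell with
   no printed definition.

Diameter is the area-equivalent diameter (`2·sqrt(area/π)`), matching the
generator's circular objects and CellProfiler's typical-diameter
semantics, not a Feret diameter. Coordinates are 0-based row-major;
compartment is nuclear when at least 50% of the object's pixels lie in the
parent nucleus (an exact tie is nuclear); objects touching the image
border are flagged and excluded from size statistics.

## Pool partitioning and references

Per cell, the nuclear total is the endogenous pixel sum over the nucleus;
the *diffuse* pool excludes detected-assembly pixels; the *sequestered*
pool is the endogenous sum over assembly pixels, split nuclear vs
cytoplasmic. Because detected assemblies are disjoint components, diffuse
+ nuclear-sequestered = nuclear-total holds exactly as a pixel-sum
identity. Whole-cell sequestered proportions include cytoplasmic assembly
signal. Fold changes use mean intensities normalized to the control mean
nuclear endogenous intensity; proportions use integrated sums.

Control references come from GFP-only scenes: the lower quartile (linear
interpolation between order statistics; the quantile method is
configurable because the upstream convention is not specified) of per-cell
diffuse nuclear means defines the sequestering threshold (strictly
exceeded ⇒ sequestering). The transfection gate is the 99th percentile of
exogenous intensity in the GFP-*negative* subpopulation of control cells,
identified by an Otsu split of control exogenous levels — a plain 99th
percentile over all control cells would sit above genuine transfectants
because controls include GFP-positive cells. Concentration dependence is
ordinary least squares (statsmodels) of a per-cell response (diffuse or
sequestered signal) on exogenous level, restricted to gated cells;
group-level inference (ANOVA/Tukey, t-tests) is delegated to standard
statistics libraries and is out of scope.

## FRAP

Traces carry three series (bleached ROI, unbleached reference, background)
with 3 pre-bleach frames, bleach at t = 0, 1-s frame interval (the
acquisition interval is not otherwise constrained; 1 s reproduces ~120
frames over the 120-s recording window) and 120 s of recovery. The
simulator composes a single-exponential recovery
`I0 + (plateau − I0)(1 − 2^(−t/t½))` — the base-2 kernel makes
`half_time_s` the literal half-time — with a shared multiplicative decay
`exp(−λt)` on ROI and reference, so double normalization cancels it
*exactly*, an analytically checkable property. Defaults mirror the diffuse
nuclear endogenous regime (I0 = 0.53, plateau = 0.74, t½ = 8.7 s). Noise
is additive Gaussian on all three series.

Metrics: the recovery is fit by least squares to `I0 + A(1 − e^(−kt))`
(initialized from the first post-bleach point, the last point, and the
first midpoint crossing); when the fit fails or A ≤ 0 the plateau falls
back to the mean of the last five frames. Mobile fraction is
`100·(I_max − I0)/(1 − I0)` on the double-normalized scale — this
convention reproduces co-reported maximal recoveries of ~0.74 with mobile
fractions of ~45%. It is undefined (NaN) when I0 ≥ 1. AUC is the
trapezoidal integral of the normalized curve over [0, 120 s]
(configurable; a curve pinned at 1 integrates to 120, and plateaus of
0.7–0.8 give values in the reported 68–83 a.u. range). t½ is reported both
by linear interpolation of the first half-recovery crossing and as ln2/k;
the two agree within one frame interval on clean exponentials. A
full-scale rescaling (I0 → 0) is available but off by default, since
maximal recoveries are reported below 1 on the double-normalized scale.

## Densitometry

Editing ratios divide each band by the lane's total-protein signal, then
form tagged/(tagged+untagged). Bands labelled `other` (e.g. a
lower-molecular-weight tag-positive degradation band) are excluded from
numerator and denominator by default; a flag admits them to the
denominator, since their treatment upstream is not stated. The ratio is
scale-invariant by construction and NaN for lanes without TDP-43 signal.

## Numerical conventions and degenerate inputs

* All randomness flows through one `numpy.random.Generator` per
  configuration; identical seeds give bit-identical scenes, truths and
  traces.
* Blank images segment to zero labels (not an error); empty cell lists
  produce empty summaries; metrics with undefined denominators (no
  transfected cells, no bleach depth) are NaN, never silently 0.
* Quantile and OLS conventions are the library defaults (numpy `linear`
  interpolation, statsmodels OLS); an r² that is numerically undefined
  (constant response) is reported as 0.
* Regression requires ≥ 3 cells and a non-constant predictor; the control
  reference requires ≥ 4 cells; recovery fitting requires ≥ 5 post-bleach
  frames.

## Test problem sizes

Unit and property tests run on 320–768 px scenes with 4–14 cells. The
oracle-recovery acceptance test uses 8 seeded images of 30 cells at
1024² px per condition, in the resolvable (`drop`) regime: a nuclear
condition carrying anisosomes, puncta and inclusions, and a cytoplasmic
condition carrying puncta. The concentration-dependence check uses two
4-image batches differing only in partition coefficient. FRAP recovery
statistics use 50 noisy traces. The analysis drivers render 4 images × 20
cells per condition at the per-variant default (crowded) rates.

## Known limitations

* In the crowded anisosome regime (~20 per nucleus), touching rings merge
  in projection; merged components larger than 4 µm that fail the 60%
  criterion are discarded by the decision table, so detected counts and
  measured sequestration underestimate the truth there. The analysis
  drivers print ground-truth comparisons alongside the measured values.
* The classifier's per-object identity is only meaningful for resolvable
  objects; no declumping of merged assemblies is attempted.
* Additive Gaussian noise and the absence of a PSF mean detection
  thresholds behave more sharply than on real images.
* Time series are processed frame-independently; there is no tracking,
  3-D segmentation, or learned segmentation.
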