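# Methods

`radvasc` implements a vessel-segmentation workflow for non-contrast lung CT
that stays specific inside radiographically damaged (post-radiotherapy)
lung, and the downstream analysis that quantifies dose-dependent vascular
change and correlates it with perfusion change. Because no public
ground-truth dataset exists for vessel segmentation in damaged lung, every
quantitative claim in this package is exercised on fully-labelled synthetic
thorax phantoms; this note records the models, the generator, the numerical
choices, and what the phantom experiments do and do not establish.

## 1. The segmentation workflow

Four independent maps are computed from one CT volume and then combined:

1. **Vessel probability map.** Multiscale patch feature learning: 5x5x5
   patches at native and 2x block-mean resolution are whitened per
   dimension and clustered into K=32 unit-norm atoms by spherical k-means
   (cosine assignment, mean-and-renormalize update, 10 iterations). A voxel
   is encoded by the soft-threshold "triangle" activation
   `max(0, a_k . x_hat - mean_k(a_k . x_hat))` of its whitened patch
   against the atoms, concatenated over scales; a logistic model (200
   epochs of full-batch gradient descent, step 0.1, L2 1e-4, internally
   standardized features) maps the encoding to a vessel probability.
   Patches with standard deviation below 1e-6 encode to the zero vector, so
   constant regions get probability `sigmoid(bias)`. A multiscale Hessian
   tubularity filter (Frangi-style bright-tube response, maximized over
   scales and rescaled to [0,1]) is available as a training-free backend.
2. **Texture map.** Block-wise seven-class tissue classification
   (section 2).
3. **Filled lung mask.** Voxels below -500 HU inside the hole-filled body,
   two largest components, morphological closing with a radius-5 ball
   (fills vessels, smooths the mediastinal boundary). An externally
   supplied lung mask may replace this stage.
4. **Aerated mask and large vessels.** Ridler-Calvard iterative optimal
   thresholding of in-lung HU (start at the median, `t <- mean of class
   means`, stop at |dt| < 0.5 HU) keeps well-aerated voxels; opening and
   closing with a radius-1 ball and filling holes under 30 voxels smooth
   it. The convergence is treated as degenerate when the class means end
   closer than 50 HU — with a unimodal histogram the iteration happily
   "converges" at the mode's median, so a minimum-separation check is the
   only reliable collapse detector; the whole lung is then returned as
   aerated, with a warning. The large-vessel mask is lung minus aerated
   with connected components under 20 voxels removed.

The combination is: threshold the probability map at strictly p > 0.4;
delete thresholded voxels whose texture class is ground-glass reticular or
bronchovascular (radiation-change textures; `consolidated` can be added by
config); clip to the lung; union with the large-vessel mask. The texture
veto also deletes blocks dominated by large vessels — their texture is
genuinely streak-like — and the union step restores them.

For the union step the large-vessel mask is dilated by one voxel (clipped
to the lung; config key `large_shell_voxels`): the aerated-mask morphology
eats the one-voxel partial-volume shell of each large vessel, and without
the shell the veto/re-addition round trip costs several percentage points
of sensitivity on large-vessel boundaries. The workflow result stores the
aerated mask minus that shell so the stored aerated and large-vessel masks
stay disjoint. The `large_vessel_mask` function itself defaults to no
dilation (the pure difference operation).

Prediction runs the patch encoder at every voxel (stride 1). Encoding at
stride 2 with nearest-neighbour upsampling — attractive because it is 8x
cheaper — paints whole 2x2x2 cells around every thin vessel and alone
costs about 5 percentage points of specificity at the p > 0.4 operating
point, which is why stride 1 is the default for prediction while training
samples features at stride 2.

## 2. Texture classification

Lung voxels are classified into normal, ground glass, ground glass
reticular, honeycombing, bronchovascular, emphysema, consolidated.
Non-overlapping 16^3 blocks with at least half their voxels in the lung
are processed as follows.

**Edgementation.** Adjacent (6-connected) voxels whose grey-level
difference is at most 2 quantization bins (76.5 HU) merge into regions;
each region is replaced by its mean. This suppresses acquisition noise
while preserving strong boundaries.

**Features (17).** First order: mean, variance, skewness, kurtosis
(population moments), grey-level entropy over the quantized histogram.
Run-length (pooled over the 13 unique 3D directions at unit distance):
short- and long-run emphasis, grey-level and run-length non-uniformity,
run percentage (runs divided by pooled voxel samples, so all-unit runs
give exactly 1). Co-occurrence (same 13 offsets, symmetric, normalized):
angular second moment, entropy, inertia (sum (i-j)^2 p), contrast
(sum |i-j| p — kept distinct from inertia), correlation (0 for
zero-variance matrices), inverse difference moment. Fractal: box-counting
dimension of the edge map (gradient magnitude above its in-block median)
over box edges {1, 2, 4, 8}. Grey levels are quantized into 32 bins over
the fixed window [-1024, 200] HU so that co-occurrence and run-length
features are comparable across blocks and scans.

**Selection.** Features are ranked by the summed pairwise-class 1-D
Gaussian divergence
`J = (s1^2/s2^2 + s2^2/s1^2 - 2)/2 + (m1-m2)^2 (1/s1^2 + 1/s2^2)/2`
and kept greedily (at most 16), skipping any feature with |Pearson r| >
0.95 against an already-kept one.

**Classifier.** Gaussian class-conditionals with diagonal covariance and
uniform priors on the selected features; argmax posterior, ties broken in
enum order. Features are normalized by the training-set mean/sd — a fixed
affine map applied identically at train and classify time. (Per-lung
re-normalization was considered and rejected: it makes a block's features
depend on the lesion burden of the lung around it, shifting test features
off the class-balanced training distribution.) Class variances are shrunk
halfway toward the pooled within-class variance: homogeneous training
classes otherwise get near-degenerate variances and veto any block that
deviates microscopically in one feature even when every discriminative
feature matches.

**Training data.** The classifier trains on generator-labelled patches
(section 3), not radiologist labels. Two aspects matter: the normal class
mixes crops of undamaged phantom lung (which contain real tapering,
bifurcating vessels) with synthetic parenchyma patches, so that both
vessel-rich and featureless normal blocks are inside the class; and the
ground-glass-reticular class is augmented with partial-coverage patches
(texture over a random half-space of normal parenchyma), because in-lung
analysis blocks straddle lesion borders and a majority-damaged block must
still be recognized. The streak-like classes get no partial augmentation —
a sparse bronchovascular presentation is indistinguishable from normal
parenchyma containing small vessels, which a vessel workflow must never
veto.

## 3. The phantom generator

Each case is a paired pre/post-RT study on a 96^3 grid at 1 mm isotropic
(large enough for four vessel-tree generations, small enough to generate in
seconds): a soft-tissue body (+40 HU), two ellipsoidal lungs (-850 HU),
and **two disjoint bifurcating tube trees per lung** (root radius 2.5 mm,
radius decay 0.7 per generation, tapering conical-frustum segments, depth
4). Two disjoint trees per lung is deliberate: "lung territory fed by
vasculature branching from the irradiated vessel" is then identifiable both
by branch descent (used for the stored truth) and by skeleton connectivity
(used by the analysis), and the two definitions coincide by construction.

**Dose.** A Gaussian falloff (sigma 9 mm) peaking at 60 Gy on the root
segment of the right anterior tree. The contralateral lung stays below
5 Gy everywhere (asserted per case). Dose bins: no (<5), low (5-20),
medium (20-40), high (>=40 Gy).

**Atrophy.** Per-bin fractional radius reductions; the defaults encode
volume changes of -5 / -10 / -25 / -40 % through
`f_radius = 1 - sqrt(1 + pct/100)`. The post-RT tree is rasterized with
each centreline point's radius scaled by its dose bin's factor, so atrophy
only removes voxels. At 1 mm resolution the medium bin holds only ~100
vessel voxels per case; per-bin recovery within the +-5-point budget is
therefore a property of cohort means (3-5 cases), not of single cases.

**Damage.** The region above 20 Gy (dilated, kept 4 voxels clear of the
lung boundary) is painted with ground-glass-reticular texture: a hazy base
at -700 HU (smoothly varying, +-40 HU) carrying sparse intense reticular
filaments (-150 HU, 25 % of voxels, band-pass structure ~1-2 voxels
thick). This bimodal form is load-bearing three times over: the bright
filaments are what intensity-driven vessel detectors falsely fire on; the
empty mid-HU range (-650..-450) keeps the Ridler-Calvard iteration away
from a spurious intermediate fixed point that otherwise appears for damage
means between -600 and -500 and silently reroutes half the damage into the
large-vessel mask; and the filaments are thin enough that the aerated
mask's closing absorbs them, so damage is not re-added as "large vessel".
The damage is painted in the post frame (after the deformation is applied)
so its texture statistics match the training patches exactly; linear
resampling would otherwise blur the filaments off-distribution.

**Deformation.** The synthetic inter-scan deformation is a sum of three
Gaussian bumps (sigma 15 mm, magnitude <= 2 mm). The post image samples
the pre-frame scene through the analytic bump field; the stored true
field (pre -> post positions) is its fixed-point inverse (10 iterations,
evaluated analytically). Warping the post-RT truth back with the stored
field recovers the pre-frame scene to nearest-neighbour accuracy; mask
containment after the round trip is therefore tested at >= 98 %, not
bit-exactly.

**Perfusion truth.** Each of the seven analysis regions (fed / not-fed x
no/low/medium dose, plus contralateral) gets a programmed perfusion change
`-0.9 %/Gy x mean dose - 35 % x [fed] - 4 %`, emulating the observed
pattern that fed regions lose far more perfusion than their local dose
explains.

**Determinism.** One `numpy` Generator seeded from `PhantomParams.seed`
drives every random draw; identical parameters give bit-identical cases.

## 4. Change analysis

The post-RT vessel mask is warped into the pre-RT frame with
nearest-neighbour sampling along the true (or externally estimated)
displacement field; volumes are voxel counts times voxel volume, and the
percent change is `100 (V_post - V_pre)/V_pre` (evaluated as
`100 V_post/V_pre - 100`, which is exact for decimally-round ratios).
Per-bin records with no pre-RT vessel are flagged and excluded from
cohort summaries. The fed partition skeletonizes the pre-RT vessels, seeds
fed skeleton voxels at >= 40 Gy (the high-dose bin floor), grows along
26-connected skeleton paths, and assigns each ipsilateral lung voxel the
label of its Euclidean-nearest skeleton voxel; the lung component with
maximum dose below 5 Gy is the contralateral control. Paired two-tailed
t-tests run on volumes (mL); zero-variance difference vectors are flagged
(all-zero gives t = 0, p = 1). Ordinary least squares provides the
dose-response fit (mean change vs bin centers 2.5/12.5/30/50 Gy) and the
vessel-vs-perfusion correlation with `r^2 = Sxy^2/(Sxx Syy)`.

The package bundles the seven region-mean (vessel change, perfusion
change) pairs of the published five-subject swine SBRT cohort as the
reference input for the correlation; `fit_line_r2` on those pairs is the
worked example in the README.

## 5. What the phantom experiments establish — and what they do not

The phantoms establish that the pipeline's machinery is correct and that
its central qualitative claim — the texture veto raises specificity inside
damaged lung while the large-vessel re-addition preserves sensitivity
elsewhere — holds under controlled conditions where ground truth is known
exactly. The specificity experiment supplies the true lung mask to the
workflow so that lung-segmentation error does not confound the comparison
of the raw and refined segmentations.

They do not establish performance on real CT: the phantom's noise is
white (no scanner noise spectrum or reconstruction kernel), its vessels
are circular tubes without airway counterparts, its damage is a single
texture with statistics chosen to be separable by the classifier the same
generator trains, and its deformation is smooth and small. Accuracy
numbers on phantoms are internal-consistency checks, not clinical claims.

## 6. Default problem sizes

Cohort analyses use 5 phantom subjects; the specificity experiment uses 10
damaged phantoms; texture training uses 100 patches per class; vessel
training samples 3000 voxels per class from one phantom. These sizes keep
a full pipeline run in minutes on one CPU while leaving the acceptance
margins comfortable.

## 7. Known limitations

- The probability map is a logistic score, not a calibrated posterior; the
  p > 0.4 operating point is honoured as a strict threshold without any
  claim of calibration equivalence.
- The fed/not-fed partition depends on skeleton connectivity; on real data
  a single connected arterial tree would mark the entire ipsilateral lung
  fed, and a finer operationalization (e.g. flow direction or generation
  counting) would be needed.
- B-spline registration itself is out of scope: displacement fields are
  inputs (the phantom supplies its true field), and masses are not
  Jacobian-corrected — volumes are compared in the pre-RT frame by
  nearest-neighbour warping.
- Perfusion computation from contrast CT is out of scope; perfusion
  changes are consumed as a table.
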