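# Methods

This note documents the models behind `wmhdrift`, the parameters that
matter, the numerical conventions, and what the synthetic validation does
and does not establish about real data.

## 1. The phantom generator

### Geometry and tissues

Each subject is an ellipsoidal head on a 128 × 128 × 20 grid of
0.94 × 0.94 × 6.5 mm voxels (5-mm slices plus a 1.5-mm gap — the thick-slice
geometry of clinical stroke imaging).  Inside the intracranial volume (ICV):
two lateral-ventricle ellipsoids and a two-voxel peripheral CSF rim (a
stand-in for sulcal CSF), with everything else lumped as parenchyma
(normal-appearing white and grey matter together, "NAWM" below).  Per-subject
jitter (±4%) moves centres and semi-axes.

Lesions are planted as the set of nearest free parenchyma voxels around a
seed (distance weighted 3× in the slice direction, so lesions are in-plane
discs spanning one to three slices, matching thick-slice appearance), which
makes the realised volume match the planned volume to the voxel.
Periventricular lesions seed on the ventricle wall, deep lesions in the
interior.  Intense lesions may carry a one-voxel subtle halo.  One stroke
lesion (cortical, 3–10 ml, or lacunar, 0.1–0.5 ml) is placed per subject by
default.

Between time points each lesion follows its plan: *grow* (adds the planned
extra volume around the footprint), *disappear* (replaced by NAWM — true
regression — or by CSF — ex-vacuo tissue loss — with probability ½ each, so
the known conflation of the two in subtraction pipelines is exercised),
*intensify* (subtle → intense on the identical footprint), *new*, *static*.
The ventricles dilate by `atrophy_rate` (default 1) in-plane voxels.

### Rendering conventions

Tissue classes map to constant per-modality means.  On FLAIR the defaults
are CSF 20, NAWM 100, subtle WMH 140, intense WMH 180, stroke 180 (arbitrary
units).  Subtle WMH is deliberately placed halfway between NAWM and intense
WMH so that subtle lesions straddle the parenchyma/WMH quantisation boundary
— the regime where correction-induced drift does its damage.

Two discrete-grid conventions matter downstream and are deliberate:

* **Partial volume** is a one-voxel shell at tissue boundaries whose value
  is the mean of the tissue means present in the in-plane 3 × 3
  neighbourhood.  The blend is rendered on the *higher-tissue-class* side of
  each boundary, so every structure's ground-truth mask contains its own
  blurred edge.  (With blends on both sides, the inner and outer edge rings
  of a lesion share one intensity and no intensity-based method can recover
  the mask-defined volume — sub-voxel truth would be needed.)
* **Ependymal gap**: lesions keep one voxel clear of CSF (including the
  planned atrophic dilation), so lesion edges blend with NAWM, never with
  CSF.  Real periventricular caps do touch the ventricle wall; this is the
  price of exact voxel-level bookkeeping.

Bias fields are `1 + a·g(x)` with `g` a mean-centred (over the ICV) sum of
2–4 broad random-sign 3-D Gaussians plus an optional through-slice quadratic
(`bias_slice_hat`, default 0.3) emulating the top/bottom-hat slice artefact;
`a = bias_amplitude` (default 0.2) is the maximum deviation attained inside
the ICV.  Noise is Rician, `sqrt((I+n1)² + n2²)`, with
`sd = noise_sigma × NAWM mean` and `noise_sigma = 0.02` by default.

Cohort lesion loads are log-normal with median ≈ 10 ml total baseline WMH
(`wmh_load_sigma_log = 0.6`) — a plausible small-vessel-disease range chosen
once, not fitted to any dataset.

### What the phantoms do not emulate

No real anatomy (no gyri, no grey/white contrast), no registration error
(time points are generated aligned), no motion/ghosting, no k-space effects,
and lesion/tissue intensities are homogeneous up to the partial-volume
shell.  Passing the validation studies therefore shows the *pipeline logic*
is correct and calibrated under its own assumptions; it does not bound
errors on clinical data, where tissue heterogeneity and misregistration
dominate.

## 2. Minimum-variance quantisation

`minimum_variance_quantise` minimises the within-level sum of squared
deviations of the masked intensities over K contiguous levels.  The masked
histogram (distinct values when ≤ 2048, else 1024 equal-width bins) is
solved *exactly* by the standard O(K·B²) dynamic program over prefix sums;
Lloyd-Max centroid/boundary iteration then polishes on the raw unbinned
values (stopping at relative SSE change < 1e-10, keeping the best iterate).
Labels follow the midpoint boundaries between adjacent centroids; a value
exactly on a boundary goes to the lower level.  Quantisation is performed on
the full 3-D volume (global boundaries), not slice-wise.  Labelling is
monotone in intensity and invariant under positive affine intensity maps.

## 3. HUM bias-field correction

In the log domain the multiplicative field is additive and low-frequency:

    log I = log b + log J,   b smooth  →  b ≈ exp(L[log I])

`L` is a zero-phase 3-D Butterworth low-pass `1/(1+(f/f_c)^{2n})` applied in
the frequency domain with zero-padding (half the grid per axis — without
padding the FFT's periodic wrap mixes the top and bottom slices, crushing
the through-slice component of the field).  Frequencies are in cycles/mm
(isotropic in physical space); the cut-off is quoted in cycles per in-plane
voxel.  Filtering is masked-ratio: `L[m·log I]/L[m]` evaluated wherever the
filtered mask has support, which both removes edge bleed from background
zeros and interpolates the field smoothly across masked-out structures.
The log offset is 1% of the mask median; the field is normalised to mean 1
over the mask and is 1 far from any support.

**Estimation support.**  The field is estimated on a normal-tissue intensity
band (0.75–1.3 × the parenchyma quantisation centroid), not the full ICV:
CSF is ~5× darker than parenchyma, and with full-ICV support the ventricle
anatomy leaks into the low-frequency estimate (recovery correlation drops
from ≳0.95 to ~0.7 on phantoms).  The band is wide enough to retain tissue
under a ±25% field, so the support itself is nearly field-independent.

**Cut-off choice.**  The default is 0.02 cycles/voxel (0.021 cycles/mm),
order 2: coil-scale inhomogeneity on this geometry lives below ~0.016
cycles/mm while the smallest anatomy (ventricle width) starts around 0.025
cycles/mm.  Much lower settings (≤ 0.005) pass essentially only the DC term:
the estimated field keeps the right shape but ~10⁻⁴ amplitude and corrects
nothing.  An entropy-driven mode (`estimate_bias_hum_entropy`) picks the
cut-off from {0.001, 0.005, 0.01, 0.02} by minimising the corrected
histogram's entropy.  The through-slice hat component is *not* recoverable
at 20 slices and the validation does not pretend otherwise: the recovery
study uses pure Gaussian-bump fields, and the hat survives correction — as
residual slice artefacts survive every practical corrector.

Correction divides by the field inside the ICV and rescales to preserve the
ICV mean; stroke lesions are excluded from the estimation support (a bright
mass drags the local field estimate — measurably: the estimated field with
vs without stroke masking differs whenever a stroke lesion is present).

## 4. The two change methods

**Independent multispectral ("MCMxxxVI-style").**  Per time point: quantise
FLAIR in the ICV to 5 levels; the WMH threshold is
`min(level-3/4 boundary, 1.2 × parenchyma centroid)` — the quantiser's own
boundary, guarded by a 20% hyperintensity-contrast criterion.  The guard
matters: minimum-variance quantisation happily splits the dominant
parenchyma peak when lesions are scarce, and a literal "levels {4, 5}" rule
then counts half the white matter as lesion.  A T2\*W veto removes
candidates that are bright on T2\*W but only moderately bright on FLAIR
(CSF-flow artefact signature).  Stroke voxels are removed (the stroke mask
is always delineated on the *uncorrected* images, since correctors attenuate
large lesions).  Rule-based cleanup stands in for manual editing: components
under 5 voxels and components centred in a 2-voxel edge belt of the ICV are
dropped; finally a boundary-completion pass grows detected components into
adjacent voxels brighter than the midpoint between parenchyma and the
threshold, capturing the partial-volume lesion edge.  Change is the
voxelwise decomposition increased/disappeared/unchanged of the two masks.

**Gamma-corrected FLAIR subtraction.**  Both FLAIR volumes are linearly
mapped so the 2nd ICV percentile (CSF anchor) → 0.1 and the parenchyma
histogram mode → 0.5, clipped to [0, 1.2].  Both landmarks sit in tissue
whose volume is stable between scans; anchoring on a bright percentile
couples the scale to the lesion load — the very thing that changes — and on
phantoms produced tens of ml of spurious "change".  The mode estimate uses a
200-bin histogram over the 25th–99th percentile window, which makes the
whole map affine-equivariant and hence idempotent.  Gamma is solved per
volume from `mode^γ = 0.5` (γ = 1 after this normalisation, by
construction; the power law is exercised when volumes arrive on other
scales).  The difference D = follow-up − baseline inside ICV∖stroke is
thresholded at ±2 SD of D over normal tissue; components under 5 voxels are
dropped.  The method *reports* the increase volume as its change estimate;
the decrease volume is kept separate because it mixes atrophic tissue loss
with true WMH regression.

## 5. Statistics

* Bland-Altman: mean difference, sample SD (n−1), limits md ± 1.96·sd.
* Wilcoxon signed-rank: zeros discarded (Wilcoxon's rule — Pratt's would
  change p), mid-ranks for ties; for n ≤ 25 the null of the positive-rank
  sum is enumerated exactly by dynamic programming over doubled ranks,
  beyond that a tie- and continuity-corrected normal approximation.
* Correlations: Spearman/Pearson with percentile-bootstrap 95% CIs
  (B = 1000 default); the "after outlier removal" variant drops points more
  than 2.24 robust (MAD) units from the median in either coordinate.
  Skewed volume inputs are signed-log transformed before Pearson.
* Henze-Zirkler multivariate normality is delegated to
  `pingouin.multivariate_normality` (standard β(n,d) smoothing, log-normal
  null); the wrapper validates n > d and covariance rank, and the test suite
  checks size (type-I ∈ [0.02, 0.09] at α = 0.05) and power against
  log-normal data.
* Simulated ratings are deterministic rules on ground truth.  Fazekas:
  periventricular score from the maximum in-plane cap thickness (thresholds
  3 and 6 voxels), deep score from the largest component's in-plane
  equivalent diameter (4 and 8 voxels) and component count.  Prins-style
  change: per region, +1/−1 when the regional WMH volume changes by at
  least τ = 0.25 ml, summed.  Regions on phantoms are *geometric sectors*
  (periventricular shell, infratentorial slab, anterior/middle/posterior
  thirds), not anatomy, and are labelled as such in outputs.

## 6. Validation studies and problem sizes

The studies in `wmhdrift.evaluation` (run by `tests/test_acceptance.py` and
`scripts/acceptance.py`) use: 200 random small histograms for quantiser
exactness against exhaustive enumeration; 10 full-geometry phantoms with
amplitude-0.2 Gaussian-bump fields for bias recovery and ΔVMR calibration;
and three 20-subject cohorts — planned net changes spanning −1…+6 ml
(bias-free) for recovery, an intensification-dominated cohort for the
method comparison, and a 10%-bias cohort for BFC neutrality.  These sizes
give each check a comfortable noise margin while a full run stays in the
minutes range on one CPU.

## 7. Known limitations

* The HUM stand-in is a classical homomorphic filter with fixed or
  entropy-selected cut-off; it does not reproduce any specific published
  corrector's internals (N4 and FSL-FAST are adapter-only).
* "Changed vs unchanged" quantised-level volumes across time points are
  defined as symmetric difference/intersection of the level-{4,5} masks —
  one reasonable reading of an operationally underspecified quantity.
* The subtraction threshold is SD-based (z = 2); absolute-threshold variants
  would need their own calibration.
* Ratings, regions and the age covariate in cohort reports are synthetic
  stand-ins wired to ground truth; they exercise report plumbing and
  correlation machinery, not clinical rating behaviour.
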