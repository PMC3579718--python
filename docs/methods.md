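# Methods

## The analysis model

`memrimap` implements a voxel-wise Z-score pipeline for manganese-enhanced
MRI (MEMRI) of the mouse brain.  Mn²⁺ entering active neurons (largely via
voltage-gated Ca²⁺ channels) shortens T₁ and raises T₁-weighted signal, so
regional signal intensity acts as a proxy for basal neural activity.  The
raw signal is not comparable across scans — coil loading, dose delivery and
gain vary — so each masked brain volume is standardized internally:

    Zᵢ = (xᵢ − x̄) / σ

with x̄ and σ the mean and standard deviation of intensity over the
in-mask brain voxels of that scan.  σ is the **population (1/N) standard
deviation**; with ~10⁵ brain voxels the sample/population distinction is
far below float tolerance, but one convention must be fixed for exact
tests.  A voxel at Z ≥ 1 sits one whole-brain SD above the mean and is
counted as "active"; sub-threshold voxels are zeroed for the ROI readouts.
Thresholding produces a *new* map — the un-thresholded map is retained
because the histogram census and suprathreshold-fraction statistics use
the full distribution.  Negative-tail analysis is out of scope.

The per-subject chain is: brain mask (externally supplied, or the Otsu +
largest-component + closing fallback for phantoms) → non-linear denoise →
12-parameter affine atlas registration → nearest-neighbour label
propagation into subject space → Z-score map → Z ≥ 1 threshold → per-ROI
metrics.  Group inference is a homoscedastic unpaired two-tailed Student
t-test per ROI per metric (df = n₁+n₂−2), raw p values with no
multiplicity correction (a Holm option exists but is off by default, since
the study design reports per-ROI raw p), significance inclusive at
p ≤ α = 0.05.

Two distinct ROI readouts coexist, deliberately kept apart:

* thresholded Z-scale: mean suprathreshold Z ("mean signal") and active
  volume in mm³ (suprathreshold voxel count × voxel volume);
* raw relative-intensity scale: ROI mean ÷ whole-brain mean, used for the
  hippocampal CA1/DG subfield contrast and their ratio (in the ratio the
  brain mean cancels).

An ROI with no suprathreshold voxel records mean suprathreshold Z as a
missing value (NaN), never 0 — imputing 0 would drag group means toward
the threshold — and is dropped pairwise from group tests with the count
reported.  Active volume is legitimately 0 in that case.

Hippocampal thickness is measured on the label volume: at the coronal
slice nearest a stereotaxic anterior–posterior coordinate (default
bregma −2 mm; the phantom declares its bregma origin in the NIfTI affine),
in the column ±1.5 mm lateral of the midsagittal plane, the contiguous
dorsoventral run of hippocampal labels containing the dorsal-most hit is
counted and multiplied by the z pitch; hemispheres are measured separately
and averaged, and a column that misses the hippocampus is a missing value,
not zero.  "1.5 mm from center" is interpreted as lateral world distance
from the midsagittal plane.

## Registration

`register_affine` wraps SimpleITK's registration framework: Mattes mutual
information (32 bins; MI is robust to the systematic intensity differences
between a plain template and Mn²⁺-enhanced scans), random 50% metric
sampling with a fixed seed, 3-level multi-resolution pyramid
(shrink 4/2/1, smoothing 2/1/0 mm), regular-step gradient descent with
physical-shift parameter scaling, initialized by centred geometry.
Because the MI surface on small rodent volumes has genuine side basins,
the search uses seeded restarts: further attempts perturb the initial pose
by a random rotation up to ±10° per axis and ±1 mm translation; the best
final metric wins, and an attempt reaching the `accept_metric` level
(−0.85, which cleanly separates converged alignments at ≈ −1.0 from
trapped ones at ≈ −0.4 on brain-masked phantom scans) is accepted without
spending the remaining restarts.  The estimated transform is stored in
world millimetres with direction `atlas->subject`, matching the
construction of subject-specific atlas copies; label maps are always
resampled nearest-neighbour so no label identities are invented.

The unnamed "non-linear filter" of the original workflow is realized as a
3-D median (radius 1 voxel, the default) with Perona–Malik anisotropic
diffusion as an alternative; this is a declared substitute, not a claim of
equivalence to any particular tool.  Denoising never changes the grid, and
a supplied mask is re-applied after filtering so the skull-strip survives.

## The phantom cohort generator

No scans are distributed with the package, so the study conditions are
emulated by a digital phantom with known ground truth.  The atlas is a
deterministic nested-ellipsoid brain carrying 17 labels: the 12 standard
analysis ROIs, CA1 and DG subfields (disjoint subsets of a hippocampal
slab, CA1 as a dorsal sheet so a dorsoventral thickness is measurable),
lateral ventricles, a habenular pair, and generic deep tissue.  Geometry
is defined in brain-normalized coordinates, so any grid ≥ 32 voxels per
axis works; the default grid is 128×128×64 at 0.2×0.156×0.3 mm, echoing
small-animal acquisition geometry, while tests and the acceptance battery
run reduced grids (48×48×32 or 64×64×48) for desk-scale runtime.

Template intensities are piecewise-constant per label (CSF dark, mild
grey/white contrast) multiplied by a **within-region "hot core" texture**:
intensity rises from each region's rim toward its interior by 70%, with a
concave profile ((depth/max)^0.4).  This emulates the subregional
heterogeneity of Mn²⁺ uptake (central amygdala, olfactory-bulb layers,
hippocampal laminae, colliculi) and is what gives *every* ROI a
suprathreshold tail, as the real per-ROI battery requires; with flat
regions, unenhanced ROIs would have no voxels above Z = 1 at all.

A simulated subject applies, in order:

1. **Atrophy** — per-ROI retained-volume fraction; outermost voxels
   (smallest distance-to-boundary, ties broken by index) are reassigned to
   a donor label until the target count is met exactly.  Hippocampal loss
   donates to the ventricles (ventricular widening); cortical loss to
   background CSF.
2. **Regional uptake factors** — multiplicative per-label gains.  Both
   groups share strong enhancement in the canonical Mn²⁺-avid regions and
   moderate enhancement in basal ganglia, thalamus, midbrain and
   brainstem.  The mutant (tauopathy-like) spec lowers hippocampus
   (1.35 → 1.00), DG (1.60 → 1.05) and amygdala (1.45 → 1.10), raises CA1
   (1.50 → 1.70) and striatum (1.10 → 1.40) — the directions the disease
   model shows — and atrophies hippocampus to 0.70 and neocortex to 0.92.
3. **Uptake jitter** — each region's gain is multiplied by a per-subject
   lognormal factor (sd 0.06): animal-to-animal variability in dose,
   metabolism and behavioural state.  Without it a simulated 5+5 cohort
   has unrealistically small within-group variance, and the arithmetic
   coupling of z-normalization (a deficit in one region shifts x̄ and σ,
   hence every other region's Z) would flag all ROIs.
4. **Bias field** — multiplicative 1 + a·P(x) with P a random quadratic
   normalized to unit peak, amplitude 5%: coil shading that perturbs
   regional means without dominating the z maps.
5. **Misalignment** — a random world affine about the brain centre:
   translations uniform ±1 mm and rotations uniform ±10° (head pose);
   per-axis scale and shear truncated-normal with 3% SD clipped at ±10%
   (anatomical size/shape variability; mouse brain volume varies ~5% CV,
   which a uniform ±10% per-axis scale would triple).  Intensity is
   resampled linearly, truth labels nearest-neighbour.
6. **Noise** — Rician by default (magnitude MR data; Gaussian noise on two
   quadrature channels), σ = 5 intensity units ≈ 5% of mean tissue
   signal; plain Gaussian available for analytically clean tests.

Identical (spec, seed) pairs are bit-identical; cohort seeds derive from a
single master seed, and written NIfTI files are byte-stable across reruns.

### Choice of the effect sizes

The disease model's quantitative regional uptake values are unknown, so
the default effect sizes were fixed once by a small calibration study
(kept under `scratch/`, not part of the library): the mutant deficit must
be reliably detectable by a 5+5 t-test battery (joint rate of
"hippocampus and amygdala flagged, cerebellum not" ≈ 0.94, which is close
to the design ceiling of 0.95 × power since a calibrated test flags
cerebellum 5% of the time by chance), while null cohorts keep per-ROI
type-I error at the nominal 5% (measured 0.04–0.06 over 2000 replicates).
The mutant striatal increase and CA1 increase — both real features of the
modelled phenotype — double as moment balancers: they keep the mutant
whole-brain mean and SD close to control so z-score coupling does not
masquerade as activity changes in unaffected regions.  These defaults are
frozen; they are modelling choices, not fitted quantities.

### What the phantom does not model

* MR physics (TR/TE/flip-angle, k-space, partial volume beyond linear
  resampling) and pharmacokinetics of Mn²⁺ transport.
* The shape of real intensity histograms: real scans put < 5–10% of brain
  voxels above Z = 1 (heavy central mass), whereas the phantom's
  suprathreshold fraction is ≈ 15–19%, and the direction of the
  between-group difference in that whole-brain fraction is not
  constrained.  Conclusions from passing tests therefore concern the
  *pipeline's* correctness and sensitivity, not in-vivo effect sizes.
* Anatomical realism of the label geometry; ROIs are ellipsoidal stand-ins
  with correct topology (subfields inside hippocampus, ventricles interior
  to the brain), not atlas-accurate shapes.

## Numerical conventions

* Volumes are float32 on disk and in containers; statistics accumulate in
  float64.  Labels are int16.  Canonical orientation is RAS, voxel centres
  at world coordinates, 0-based indices.
* Z-maps: normalization is affine-invariant to float tolerance (1e-6);
  the census clips values into the outermost bins (default 0.25-Z bins
  over [−5, 8]) so per-subject counts sum to the mask size.
* Atrophy erosion hits the target voxel count exactly (±1 discretization);
  the reported recovery band for a 0.70 cohort ratio (65–75%) absorbs the
  misalignment scale variability of the groups.
* Degenerate t-tests: zero pooled variance with unequal means reports the
  limiting p → 0 with a `degenerate` flag; both groups constant and equal
  raises in the single-test API, and batch comparisons record the entry as
  not computable (NaN statistics, not significant) instead of aborting.
* Registration is seeded end-to-end (metric sampling, restarts); the
  single pipeline master seed fixes every stochastic choice, so a rerun is
  bit-stable.

## Problem sizes used by tests and the acceptance script

Unit and acceptance tests use 48×48×32 phantoms (≈ 28k brain voxels) for
cohort simulation, 64×64×48 for registration recovery (20 misaligned
phantoms), 10⁶-voxel standard-normal fields for Gaussian calibration, 100
random 16³ instances for brute-force oracle equivalence, 200 replicate
cohorts for effect detection and 2000 for null calibration.  These sizes
were chosen to make the full battery a coffee-break run on one CPU while
keeping every statistical check adequately powered.
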