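# Methods

`vesseltrace` is a validation pipeline for whole-brain vasculature imaging:
it generates synthetic cleared-tissue vessel stacks with exact ground truth,
segments them with an unsupervised Markov-random-field model, quantifies the
segmentation depth-by-depth the way vascular-staining studies report it, and
traces the result into a centerline graph for length/density/diameter
morphometry. This note records the models, the parameter choices that
matter, and the limits of what the synthetic validation shows.

## Synthetic vascular phantoms

### Geometry

Vessel networks are grown by seeded random-walk elongation inside an
axis-aligned box. Each active tip advances in 2 µm steps; the direction
receives an isotropic Gaussian perturbation of sd 0.15 per step, giving a
directional persistence length of about 90 µm — capillary-scale tortuosity
of roughly 1.05–1.1, in line with measured cortical microvasculature.
Branches appear as a Bernoulli event per unit grown length (default
0.02 µm⁻¹, i.e. a branch every ~50 µm on average); each segment carries one
radius drawn uniformly from the capillary range 2–5 µm. Seed vessels are
stratified along the depth axis so no slab of the stack is avascular, as in
real cortical tissue.

Distinct vessels exclude one another: a step is rejected (and retried in a
widening cone, the tip terminating if fully walled in) whenever it would
bring two centerlines closer than the sum of their radii plus a 2 µm
clearance. Real capillaries never interpenetrate, and without this
constraint the fused tube unions produce medial-surface webs that no
thinning-based tracer can resolve — an artifact of the generator, not of
the microscopy being emulated. Parent and child are exempt from mutual
exclusion only within a couple of diameters of the attachment point, where
a real bifurcation genuinely shares lumen space.

Growth stops when total centerline length reaches `density × volume`; the
default target density of 450 mm/mm³ sits inside the histologically
reported range for mouse hippocampus (387–777 mm/mm³). If tips and reseeded
roots cannot reach the target (domain too small for the radius range, or no
collision-free room left), generation fails loudly rather than silently
under-filling.

### Rasterization

The ground-truth mask marks a voxel as vessel iff its center lies within
the local radius of the (densely resampled) centerline — the filled lumen —
or, in wall mode, within a band of thickness *t* (default 1 µm) centered on
the vessel surface. Distances are computed exactly with a k-d tree over
centerline samples spaced at half the finest voxel pitch. The default grid
is the light-sheet acquisition geometry: 0.65 µm in-plane, 2 µm z-step
(anisotropy 3.08), voxel centers at `(i + 0.5)·pitch`.

### Image formation

The noise-free image is `bg + (fg − bg)·M(v)·exp(−z/λ)`: a single
exponential depth attenuation along z only, the minimal model reproducing a
monotone SNR decline with imaging depth. It is followed by an isotropic
Gaussian PSF (default sd 1 µm), then Poisson shot noise (optional, before
read noise, as in a real detector chain), then additive Gaussian read noise
(default sd 10), then clipping to the intensity range.

The two staining regimes the package contrasts are:

* **lumen** (gel-albumin-style): the filled vessel interior at
  foreground 200 over background 20, attenuation length λ = 1500 µm —
  bright, well-cleared tissue in which contrast survives the full stack;
* **wall** (lectin-style): only a 1 µm surface band is labelled. The thin
  shell loses roughly two thirds of its amplitude to PSF dilution, so its
  effective contrast starts far lower than the lumen's; the wall
  comparisons in the tests additionally use short attenuation lengths
  (λ = 60–100 µm) so that the remaining contrast sinks into the read
  noise within ~250 µm of depth — the regime in which wall staining is
  reported to fail. Depth-resolved recall for these comparisons is
  computed voxelwise rather than on projected masks: the maximum
  projection of a 3-D label mask over a 40 µm slab saturates recall by
  construction (any detection anywhere in a 20-slice column covers the
  reference pixel), hiding exactly the degradation being measured.

## MRF segmentation

The segmentation model is a two-class hidden Markov random field: Gaussian
emissions N(μ₀, σ₀²) / N(μ₁, σ₁²) for background/vessel, a homogeneous
Potts prior over the 6-connected neighborhood, and the posterior energy

    E(l) = Σ_v [ (I_v − μ_{l_v})²/(2σ²_{l_v}) + ½ ln(2π σ²_{l_v}) ]
         + β · #{6-neighbor pairs with unequal labels}.

Inference is ICM interleaved with maximum-likelihood parameter
re-estimation (HMRF-EM). Both half-steps are exact coordinate descent, so
the outer energy trace is non-increasing — asserted throughout the test
suite. An ICM sweep updates the two checkerboard parity classes in turn;
voxels of one parity share no 6-neighbor pairs, so the parallel update
equals sequential coordinate descent while remaining fully vectorized.
Ties are broken toward background (conservative vessel calls,
deterministic).

Numerical choices:

* intensities are z-scored internally, so β is stated on a unit-variance
  scale and transfers across bit depths; the labeling is consequently
  invariant to affine intensity shifts;
* β defaults to 1.0, equal for in-plane and axial neighbor pairs; a
  per-axis β triple is accepted for anisotropy-aware smoothing but is not
  the default (no evidence the axial coupling should differ);
* class variances are floored at 10⁻⁶ (z-scored units) so noise-free
  inputs remain well-posed;
* convergence: relative energy change < 10⁻⁴ or 20 outer iterations with
  up to 2 sweeps each;
* initialization: Otsu's threshold (a 1-D two-means split is available);
  constant volumes are rejected as having no threshold.

Known limitation: with a foreground fraction of ~1% **and** weak contrast,
the unsupervised two-Gaussian fit can collapse onto a split of the
background noise (both fitted means inside the noise mode and ~40% of the
volume labelled foreground). This is a genuine failure mode of unsupervised
intensity segmentation at extreme class imbalance, not an implementation
defect; the shipped study conditions keep enough bright structure for the
fit to anchor. Classical global thresholds (Otsu, isodata, mean) are
provided as baselines; on depth-attenuated stacks they lose dim deep
structure that the spatial prior still recovers, which is the package's
reproduction of the reported MRF-versus-thresholding comparison.

`segment_blockwise` processes arbitrarily large stacks: class parameters
are fitted once on a strided subsample (≤ 2·10⁶ voxels) and frozen, blocks
are labelled independently with fixed-parameter ICM over a halo overlap
(discarded on write-back), keeping labels consistent across block seams.

## Evaluation

* **SNR** is the ratio of mean grey values, signal ROI over background ROI
  — deliberately not (S−B)/σ, matching how light-sheet staining studies
  report it. Profiles sample every 20 µm down to 500 µm by default.
* **Overlap metrics** count TP/FP/FN pixels between the automatic and a
  reference mask, by default on 40 µm maximum-intensity-projected slabs
  (manual reference segmentations in the emulated studies are drawn on
  such MIPs). Percentage-rate denominators are an explicit recorded
  convention: TP and FN over reference-positive pixels (so
  tp + fn = 100% by construction) and FP over auto-positive pixels;
  an all-over-reference alternative is selectable. Undefined rates (empty
  denominator) are reported as missing, never as zero. Precision
  TP/(TP+FP) and recall TP/(TP+FN) come from the raw counts.
* **Perfusion completeness**: a vessel branch is non-perfused iff strictly
  more than half its length is unstained; the boundary case (exactly half)
  counts as perfused.

## Centerline tracing and morphometry

The mask is resampled to an isotropic grid at the finest voxel pitch by
linear interpolation of the indicator (cut at 0.5) — nearest-neighbor
upsampling embosses the coarse z-steps as ledges that thinning turns into
spurious branches — then thinned with Lee's 3D topological algorithm.
Skeleton voxels whose 26-neighborhood degree differs from 2 are clustered
(26-connected components) into nodes; edges are traced through degree-2
chains; isolated cycles receive one artificial node.

Cleaning, in order:

1. **spur pruning** — terminal edges shorter than max(5 µm, local vessel
   diameter at the junction) are removed iteratively; thinning a tube of
   radius *r* sheds surface spurs up to about *r* long, so the threshold
   tracks local caliber rather than a single global constant;
2. **centerline smoothing** — one window-3 moving-average pass over each
   polyline (endpoints fixed). A voxel-traced path zig-zags around the
   true axis and overestimates arc length by ~10% at this resolution; one
   light pass removes the aliasing without flattening real capillary-scale
   curvature;
3. **tip repair** — endpoints march along their terminal tangent while the
   local caliber (distance-transform value) stays above 80% of its value
   at the endpoint. This recovers genuinely retracted tips but stops at
   the rounded end cap, avoiding the ~one-radius overshoot that
   unconditional extension to the mask boundary produces.

Lengths are 3-D arc lengths in µm (anisotropy already applied); edge length
includes both node endpoints, making total length additive. Vascular
density is total length (mm) over analyzed volume (mm³). Diameters are
2× the Euclidean distance transform sampled along the centerline, i.e.
distance to the nearest background voxel center — a one-voxel-wide line at
1 µm pitch therefore reports 2 µm. Paired segment-length comparisons use
Pearson's R.

On phantom masks at the default acquisition geometry this chain recovers
the generator's total centerline length to within ±8% across seeds
(typically ±3%), with the residual dominated by junction geometry and the
smoothing/staircase balance.

## Pipeline and I/O

Stacks are multi-page grayscale TIFFs (8/16-bit) with voxel size carried in
a JSON sidecar — TIFF resolution tags are dialect-prone, and a missing
voxel size is an error, never a silent assumption. Graphs round-trip
through a JSON text format; metric tables are TSV. All physical quantities
are µm internally; mm and mm/mm³ appear only at report boundaries. Depth is
`z-index × z-pitch`, slice 0 shallowest. The `pipeline` driver
(phantom-or-stack → segment → evaluate → trace) echoes its full
configuration next to every report, draws all randomness from one seed, and
produces byte-identical tables on re-runs; it is also the report generator
(no separate `report` command). The CLI (`vesseltrace phantom|segment|
evaluate|snr|trace|pipeline`) is a thin wrapper over the library.

## Problem sizes in the shipped tests

Unit tests run on volumes of 16³–96³ voxels; the headline accuracy checks
use four 256×256×128-voxel lumen phantoms (the full stated acquisition
geometry) and smaller 128×128×64 phantoms for morphometric parameter
recovery across seeds. These sizes were chosen so the whole suite completes
in minutes on a single CPU while still exercising every stage at realistic
anisotropy and contrast.

## What the phantoms do and do not show

The generator reproduces the features that drive segmentation and tracing
difficulty — capillary caliber and density, anisotropic sampling, depth
attenuation, PSF blur, mixed noise, lumen-versus-wall contrast — but not
arterial/venous hierarchy, diameter tapering, anastomotic loops,
hemodynamics, spatially varying background (autofluorescence, striping), or
optical aberrations. Passing the phantom suite therefore demonstrates the
correctness and internal consistency of the algorithms under controlled
degradation, not their performance on any particular real acquisition; the
phantom-derived numbers should not be read as biology.
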