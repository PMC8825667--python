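# Methods

This note records the models implemented in `hepatoseg`, the defaults and
why they were chosen, what the synthetic phantoms do and do not emulate,
and the numerical choices a maintainer would want to know.

## Synthetic phantoms

The generator rasterizes a declarative spec onto a voxel grid with physical
spacing: an ellipsoidal organ, piecewise-linear tubes (distance-to-segment
≤ radius) for contrast-enhanced vessels, and ellipsoidal hypodense lesions,
plus additive Gaussian noise clipped to [0, 255].  Default intensities on
the 0–255 windowed scale are background 20, organ 120, vessel 200, lesion
70 — the hypodense-lesion / enhanced-vessel ordering every downstream
energy assumes.  These absolute values are conventions for the windowed
scale, not measurements.  The standard study phantom (`default_phantom`)
places one vessel tube and 5 mm spherical lesions sized so lesion voxels
are 1–2 % of organ voxels — the class-imbalance regime that motivates the
class-balanced loss.  Truth masks are computed from the same analytic
geometry and are therefore independent of the noise level; identical spec
and seed give bit-identical volumes.

What the phantoms do **not** emulate: CT physics (beam hardening, partial
volume, reconstruction kernels), anatomical texture, deformable organ
shape, registration or breathing artifacts.  Passing tests demonstrate
correctness of the algorithms under their stated assumptions, not clinical
performance.

Rasterized spheres centred on a voxel center match the analytic volume to
≈2 % at radius 5 voxels; off-center placement can reach ≈5 %.

## Shape function and surface correspondence

S(p, r) is computed by quadrature over the seed ball: midpoint-offset
lattice samples (step = max(min-spacing/4, r/20)) of the trilinearly
interpolated occupancy.  The half-step lattice offset decorrelates the
quadrature from the voxel grid and removes the dominant aliasing bias;
agreement with a 10⁶-sample Monte-Carlo integration of the same
interpolated object is within ~10⁻³.  Note a resolution limit: a curved
boundary is indistinguishable from flat when the sag r²/2R is below one
voxel, so S on gently curved surfaces reads ≈0.5 unless r is several
voxels.

Default seed radius is 10 % of the smallest principal extent, configurable.
PCA alignment fixes axis signs by non-negative skewness (largest-component
positive for symmetric bodies) and forces a right-handed frame.  Candidate
plane normals are the canonical axes (tried first — this is the tie rule)
followed by a 32-vertex pentakis-dodecahedron sampling (12 icosahedron +
20 dodecahedron vertices), folded to 16 hemisphere directions.  A
direction's score is the mean number of cross-section curves per slice,
counting interior holes as extra curves (so an annular torus section
scores 2, not 1); the minimizer wins.  Slice curves are extracted by
subvoxel contouring at the 0.5 level, traversed counterclockwise from the
point of maximal first-in-plane coordinate — a deterministic anchor that
makes the (plane, division) index correspond across shapes.  Comparison
averages S at both ends of the correspondence and min-max normalizes;
the ≥ 0.5 threshold on the normalized map is inclusive.

## Hessian enhancement

Second derivatives are Gaussian-derivative filters at physical scales with
γ = 2 normalization (multiplication by σ²); the volume is centred first, so
truncated-kernel DC leakage cancels and responses are exactly invariant to
additive offsets.  Scales are expressed as **structure radii**: a
γ = 2-normalized response for a solid tube of radius R peaks at σ = R/√2,
so the applied Gaussian is σ = scale/√2 and the reported best scale matches
the radius of the structure that produced it.  Default scale list:
{1, 2, 3, 4, 6, 8} mm radii.

Vesselness (bright tubes): v = |λ2|·exp(−λ1²/(2(α|λ2|)²)) for λ2 < 0, else
0, with α = 0.5; blobness (dark, roughly isotropic masses):
w = exp(1 − λ1/λ3) for λ3 > 0, else 0, which lies in (0, 1] and is maximal
exactly at isotropy λ1 = λ3.  Energies are −ln of the min-max rescaled
response mapped into (ε, 1] with ε = 10⁻⁶, keeping them finite (≤ ~13.8)
where the raw response is zero.

## Graph-cut segmentation

Per-class intensity likelihoods default to one Gaussian per class (a
64-bin floored histogram is available); densities are floored at 10⁻⁶ so
costs stay finite.  The unary costs are negative log posterior odds.  The
blob energy is added to the object (tumor) unary and the vessel energy to
the background unary: dark isotropic structures become cheap to label
tumor, enhanced tubes cheap to keep out.  The pairwise term is
1/(1 + (Ip−Iq)²/2σ²) on 6-connected neighbours (26 optional), divided by
the inter-voxel distance so anisotropic grids are treated consistently;
σ defaults to 10 intensity units (the scale of plausible noise on the
0–255 window).

The energy coefficients print as (enhance, shape, boundary) = (1, 1, 1) in
the library API.  The assembled enhancement energies span ~[0, 13.8] while
the data term is decisive only within a few units, so the classical
pipeline config uses enhance = shape = 0.25 to keep the intensity evidence
dominant and the Hessian terms as shape priors; this was set from the
energy-scale argument above and is exposed in `PipelineConfig`.

Min-cut: capacities are scaled by 10⁵ and rounded to integers for
`scipy.sparse.csgraph.maximum_flow`; the partition is the set of nodes
reachable from the source in the positive residual graph.  On random toy
fields (≤ 12 voxels) the result matches exhaustive enumeration of all 2ⁿ
labelings exactly; the rounding resolution (10⁻⁵) is far below any energy
difference arising in practice.  Vessel removal runs both as a pre-cut
eligibility mask (default) and a post-cut relabeling to the vessel class;
the threshold applies to the min-max normalized vesselness, and removal
uses ≥, so threshold 0 removes everything and +∞ nothing.

## Contour refinement

The speed image is 1/(1 + exp((g − β)/α)) on the (optionally
Gaussian-smoothed) gradient magnitude — near 1 in flat tissue, near 0 at
edges.  In the pipeline β is set to half the 99.5th percentile of gradients
in the eroded liver interior (excluding the organ capsule), with
α = β/5, so the front stops at lesion boundaries rather than only at the
capsule.  Fast marching (first-order upwind, SimpleITK) supports ball
seeding: trial points within a radius are initialized with their exact
distances, and seed values are scaled by 8 before integer rounding, which
cuts the near-source diagonal error to ≈1.5 % mean on a 64³ uniform-speed
grid.  GAC defaults: propagation 5, curvature 2.5, advection 1; the outer
loop stops when the relative volume change drops below 0.5 % (tolerance
configurable); evolution is clamped to a ±10-voxel band around the initial
surface to prevent leakage across weak edges, and a vanished contour is an
error, not a silent empty mask.

## Feature battery (157)

Counts by block: size/shape 4 (volume ml, maximal 3D diameter mm, tumor
size ratio = candidate/liver volume, binary elongation = candidate volume /
bounding-box volume, π/6 for a sphere); intensity statistics 12 × 2 regions
(tumor and a 2-voxel peri-tumoral rim inside the liver) = 24; enhancement 3
(edge-tumor contrast, mean and max blobness); co-occurrence texture 7
statistics × 2 regions × 3 gray-level quantizations (8/16/32, equal-width
over the region range) × 3 offset distances (1/2/3 voxels) = 126.  Total
4 + 24 + 3 + 126 = 157.  Co-occurrence matrices are 3D, symmetric,
direction-averaged over the 13 unique offsets; for a uniform region energy
is 1 and entropy/inertia are 0, and correlation is defined as 0 when a
marginal variance vanishes.  Candidates under 8 voxels get imputed (zero)
texture values and are flagged.  The manifest (name, descriptor category,
parameters) is generated programmatically and is the single source of
column order.

mRMR uses equal-frequency 8-bin discretization and `mutual_info_score`;
ties break by manifest order; constant columns are excluded with a
warning.  The default classifier is a standardized linear SVM; the
classifier object is pluggable.

## Cascaded FCN

Both stages are miniature 3-level U-Nets (two 3×3 conv+ReLU blocks per
level, max-pool down, nearest-neighbour up, skip concatenations, 1×1
head — 11 convolutions, ~19 layers counting activations and resampling),
implemented in numpy with im2col convolutions, hand-derived backprop
(max-pool gradients split ties evenly, so finite-difference checks pass
exactly) and Adam (lr 2·10⁻³ in the trainer default, halved every 40 % of
the epoch budget — the decay stabilizes the late phase in which the
recall-biased class weighting prunes its false positives).  Channel widths are
×8 below a clinical-scale network; the architecture class, not capacity,
is the point.  Inputs are intensity/255 in [0, 1]; an optional 2.5D mode
stacks the upper/lower adjacent slices as channels.

Stage 2 trains on liver-masked slices cropped to the in-plane liver
bounding box (+2 voxels) and resampled to 48×48; the crop transform is
recorded and inverted to map probabilities back.  Prediction thresholds
stage-1 probabilities at 0.5, keeps the largest 3D liver component, and
constrains the lesion mask to the predicted liver — the cascade contract.
Class weights are inverse pixel frequency normalized to mean 1 (ratio 99
at 1 % lesion pixels).

Desk-scale training conditions used by the tests and the acceptance
script: four phantoms of 64×64×32 voxels with noise σ = 4, 20 epochs,
batch 8 — about 3 min on one CPU, reaching liver Dice ≈ 0.99 and held-out
lesion Dice 0.75–0.92 across seeds.  These sizes were chosen as the
smallest configuration at which the cascade's behaviour (near-perfect
organ, good lesion recovery) is stable across seeds; with fewer phantoms
or epochs stage 2 can remain in its recall-heavy phase and over-segment.

## Metrics

VOE = 100(1 − |A∩B|/|A∪B|), RVD = 100(|A|−|B|)/|B|, Dice =
200|A∩B|/(|A|+|B|); surface voxels are the 6-connectivity erosion
difference and ASD/MSD are the mean/max of symmetric surface distances
computed with the exact Euclidean distance transform under anisotropic
spacing (hence millimetres).  An empty reference or prediction is an error
for the surface metrics.  Tumor burden is tumor volume / liver volume in
percent; the burden error is the absolute difference to a reference
burden.  The robustness probe re-runs a user-supplied pipeline under
Gaussian noise and axial (in-plane) rotation, one row per (σ, θ, seed),
recording failures instead of aborting.

## Known limitations

* No initial whole-abdomen liver localization: the pipeline takes a liver
  mask (from the cascade, a file, or elsewhere) as input.
* The shape-function resolution limit above: concavity measurements need
  r of several voxels and features larger than the voxel sag.
* First-order fast marching keeps a ~2 % diagonal error even with ball
  seeding; adequate for seeding, not for distance-accurate geodesics.
* The numpy networks are CPU-bound and desk-scale by design; no GPU path,
  no augmentation beyond optional in-plane flips, no transfer learning.
* Phantom realism limits: see above — clinical performance claims are out
  of scope.
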