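# Methods

This note records the models implemented in `limbtrack`, the parameter
choices that matter, and the places where the design was genuinely open.

## Geometry and pose parameterization

The acquisition frame is right-handed with the origin at the isocenter:
`x` horizontal along detector rows, `y` vertical, `z` the
source→detector axis.  The source sits at `(0,0,−sod)` and the detector
plane at `z = sdd − sod`; a point at depth `z` projects with scale
`sdd/(sod+z)`, so the isocenter magnification is `sdd/sod`.  Detector
coordinates are continuous, origin at the detector center, expressed in
*binned* pixels (`det_pitch · binning` voxel units per pixel).

A rigid pose is `R = R_y(φ)·R_z(θ)·R_x(η)` plus a translation.  The
axis attachment — φ about the vertical axis (the projection/gantry
angle), θ about the projection axis, η about the horizontal axis — is a
documented package convention: the physical setup fixes only that φ is
the projection angle and η a pitch about a horizontal axis.  The
whole-object pitch η duplicates the parent joint's articulation, so it
is excluded from the registration vector and carried as a fixed,
externally supplied value; the free vector is
τ = {x°, y°, z°, θ°, φ°, η_j1..η_jN}, 5+N parameters.  Degrees at every
public interface, radians internally.

## Volumes, segmentation, bone frames, interpolation

World coordinates are `index − (shape−1)/2`, putting the volume center
at the isocenter.  Bone segmentation: Otsu threshold (256 uniform bins
over [min,max], ties toward the lower cut), removal of 6-connected
components below `min_voxels`, morphological closing with a cubic
structuring element, 6-connected relabeling sorted by size.  The
closing window is configurable because its physical size must scale
with resolution; the phantom default is 9³, and at that scale the
phantom's joint gap (24 voxels) is what keeps the two bones from being
bridged — closing dilates each surface by half the window.

Bone frames are PCA of unweighted voxel coordinates (population
covariance).  The largest-variance eigenvector is the longitudinal axis
`e_ŷ`, the smallest the transverse `e_ẑ`, and `e_x̂ = e_ŷ × e_ẑ`; signs
are fixed deterministically (largest-magnitude component positive).
The joint origin slides the center of mass along `e_ŷ` by
`2·√σ_max` — the "axis length" is read as two standard deviations,
roughly the semi-axis of an equivalent uniform rod — with the direction
chosen by an explicit `end_hint` argument in place of the visual check
a human would perform on real anatomy.  An isotropic voxel cloud
(σ_max within 1% of σ_mid) raises an ambiguous-frame error.

Interpolation is local separable tricubic Lagrange over the 4×4×4
neighborhood: it reproduces cubic polynomials exactly in the interior
and passes through the samples on the lattice.  Neighbor indices clamp
at the grid edge (so boundary lattice points stay exact); points
strictly outside the grid return 0.  A global spline was rejected
because the operation must be streamable over arbitrary query points.

## The limb phantom

The phantom stands in for a dissected-limb CT scan: two capsule bones
("femur" 28 voxels long, radius 6.5; "tibia" 26 long, radius 5) with
two condyle-like spherical bulges at the knee-facing ends, meeting at a
24-voxel joint gap, inside a soft-tissue ellipsoid, in a 96³ grid.
Attenuation is background 0 < soft tissue 0.25 (± mild seeded texture
noise, clipped so the ordering stays strict) < bone 1.0.  The default
bend between the bone axes is 25°, and the limb plane is tilted 25°
about the vertical axis so the bone transverse axes are *oblique* to
the projection axis, as they are in real limbs.  That obliqueness
matters: with both transverse axes parallel to the projection axis, the
in-plane rotation θ° can nearly reproduce the joint pitches and the
pose becomes ill-conditioned under detection noise.  Bulges are placed
so PCA axes have a well-defined sign structure and scale-space
keypoints exist; pure cylinders would leave the frame sign ambiguous.

What the phantom does *not* emulate: anatomical bone shape, muscle,
beam hardening, scatter, detector response.  Passing tests therefore
demonstrate the correctness and conditioning of the geometry, the
motion model, the selection/voting machinery and the optimizer — not
detection accuracy on real radiographs.

## Landmark selection

Both candidate pools (bone voxels; DoG scale-space extrema over 26
spatial neighbors × adjacent scales, restricted to within 2 voxels of
the bone, with a contrast floor of 0.1× the scale-space maximum to
suppress blob side lobes) feed the same greedy scheme.  The distance
floor compares `d ≥ λ·√σ_min`: the eigenvalue is a variance (voxel²)
while the distance is in voxels, so the standard deviation is the
dimensionally consistent reading, and it makes the working λ range
(≈1.5–4) span sensible fractions of a bone's minor radius.  A config
switch (`sigma_scale="variance"`) provides the literal eigenvalue
comparison.  Ties in CoM distance break toward the lowest lexicographic
coordinate.  The implementation is a single pass over candidates sorted
by descending CoM distance, which is equivalent to the re-scanning
greedy definition because disqualification is monotone; the test suite
checks it against a full-rescan brute-force oracle.

## Polyaffine articulation

Rotation angle `α = arccos((tr R − 1)/2)`; matrix log
`log R = α/(2 sin α)(R − Rᵀ)` for α ∈ (0,π), zero at α=0, an error at
α≈π (outside the principal branch).  Each bone's speed is stored as a
homogeneous affine (rotation log plus the translation induced by
centering at the joint origin), so the sub-step `e^{A/S}` is evaluated
*exactly* as the rotation by η/S about the origin — composition of S
sub-steps therefore reproduces the rigid rotation to machine precision
in the single-bone uniform-weight limit, which the tests assert at
1e-9.

Fusion weights convolve each binary segment with a truncated Gaussian
(sd σ_f, support k_f per axis) and normalize voxelwise where the summed
raw weight exceeds 1e-8; elsewhere the transformation is the identity.
Composition re-samples weights at every intermediate position by
tricubic lookup (a freeze option evaluates them once at the start).
The inverse model negates the angles — exact deep inside a bone,
approximate where weights blend; the forward–inverse round trip on all
phantom bone voxels stays below 0.1 voxel.

One scale caveat found during development: the weight support must
cover the articulation displacements.  A kernel truncated at ~1σ
leaves a band only a few voxels wide around each bone; bone ends that
sweep farther than the band exit the support mid-composition and stop
moving, which breaks invertibility.  The phantom default σ_f=5, k_f=29
gives a 14-voxel band, covering pitches up to ≈±35° at phantom bone
lengths.  The full-scale configuration (σ_f=13, k_f=23, S=18) is kept
as the `FusionConfig` default for compatibility with the original
acquisition scale.

Volume warping maps each target voxel through the inverse model over S
steps and samples the source tricubically; voxels outside the weight
support never move and are copied, which confines the cost to the
articulated region.

## Radiograph simulation

One ray per binned detector pixel, from the source through the pixel
center, trilinear volume sampling at 0.5-voxel steps scaled by step
length, restricted to the bounding sphere of the posed volume.  The
projector is linear and monotone in the volume by construction.  Bone
masks mark pixels whose ray meets any bone material.  Noise follows
the training-data recipe literally: the noiseless projection is scaled
so its maximum equals `I0` and every pixel becomes a Poisson draw with
that mean (means clamped at 0 against interpolation undershoot).  A
transmission-mode (Beer–Lambert) variant was considered and left out:
the stated recipe acts on the line-integral image directly.

The acquisition-plan enumerator reproduces the two campaigns: training
(6×5 joint-angle grid → 30 articulated volumes; 40 projection-angle
intervals of ±1.5° across [−30°,30°] ∪ [150°,210°]; 13 projections per
interval → 15,600 radiographs; SOD 6550±180, SDD 10000±540, offsets
±180/±120/±180 voxels, tilts ±15°, binning 6, I0 2000±350; split
0.75/0.20/0.05 by seeded shuffle) and study (3×3 grid → 9 volumes,
8 ±7.5° intervals, SOD 6450±180, SDD 10200±540).

## Voting detection

Field encoding and decoding follow the keypoint-voting convention:
unit vectors on mask pixels; pixel-pair ray intersections as
hypotheses (both ray parameters must be nonnegative — the vectors
point *at* the landmark); hypothesis score = angular inlier count at
cos ≥ 0.99; `μ̂` = score-weighted hypothesis mean, `σ` = score-weighted
mean squared distance to `μ̂` (a scalar, as defined), `ω = 1/(σ+1e-6)`.
Two defaults are the package's own: 256 hypotheses, and a consensus
*quorum* — hypotheses scoring below 0.9× the best get zero weight.
The quorum exists because any hypothesis near the mask collects a
baseline of accidental inliers (≈70% of the best score on small
masks), and without it the weighted mean is dragged pixels away once a
fifth of the vectors are corrupted.  With it, decoding is exact on
clean fields and stays within ~0.02 px at 40% corruption.

## BoneNet

Encoder: stride-2 stem convolution, then four residual stages with
basic blocks (two 3×3 convs + batch norm + ReLU, projection shortcuts
on shape change) at depths [3,3,4,3] — one, one, two and one blocks
more than the [2,2,2,2] baseline voting network.  Stages 2 and 3
stride; stage 4 keeps 1/8 resolution with dilation 2 instead of
striding further.  Decoder: three (concatenate-skip → 3×3 conv →
2× nearest-neighbor upsample) steps whose first skip is sourced from
stage 3, then a 1×1 head emitting 2K vector-field channels plus 2
segmentation logits at input resolution.  Implemented in numpy with
explicit backprop (im2col convolution, batch norm, Adam); desk-scale
widths (8,16,32,64) default.

Loss: masked smooth-L1 (Huber, δ=1 — the transition point is not
otherwise specified) between predicted and target fields, averaged
over masked field entries, **plus** the segmentation cross entropy.
The printed formula subtracts the cross-entropy term, which would
reward bad segmentation; the subtraction is retained behind
`ce_sign=-1` but the sum is the default, treated as the corrected
sign.  Training uses Adam at base rate 1e-5 with the multistep
schedule 0.5^e over the first five epochs; 30 epochs is the desk
default (the full protocol runs to 600).  The single-sample overfit
check uses 3e-3 instead: it is a capacity check of the architecture,
and 200 steps at 1e-5 cannot move a fresh network materially.

## Registration

The articulated forward model transforms reference landmarks with the
same polyaffine motion that generated the data, with fusion weights
frozen at the reference positions — each landmark's motion is then an
exact affine map iterated S times, smooth in the joint pitches, and
the forward model at the generating pose reproduces the dataset's 2D
ground truth to 1e-6.  The hierarchy question (does the parent pitch
move the child bone's landmarks?) is resolved the way the generator
works: each bone rotates independently about its own transverse axis,
blended by the weights; a `rigid_chain` mode implements the
parent-moves-child alternative.

The solver runs the staged schedule — φ°, y°, {x°,y°,z°},
{η_j1,η_j2}, {θ°,φ°} — with two additions the package takes
responsibility for:

* the first φ° stage is a coarse global sweep (5° grid over the
  allowed gantry range, each candidate scored after a quick
  translation fit).  The gantry angle lives in two disjoint windows
  around 0° and 180°, and a purely local solve from zero cannot cross
  between them, nor can the sweep rank candidates meaningfully while
  ±180-voxel offsets are still unknown;
* each cycle ends with a full-parameter trust-region polish
  (`joint_refine=True`).  Pure block-coordinate cycling converges only
  linearly here (strong x↔φ and z↔magnification coupling) and was
  still drifting after 150 cycles; with the polish, noiseless
  recovery from zero initialization is exact in every trial.

Both are configurable off.  Each stage is a bounded trust-region
least-squares solve (forward-difference Jacobian) over that stage's
parameters only; bounds are twice the simulation ranges; the outer
cycle stops when the largest parameter update or the cost change falls
below 1e-8.  With fewer than 3 landmarks on any joint the rotation
stages are refused and a translation-only partial estimate is
returned.  Error tables report median, quartiles, 1.5·IQR whiskers and
outliers per parameter — the statistics behind standard boxplots.

## Study conditions and problem sizes

The phantom studies use the full-scale source/detector distances
(SOD 6550±180, SDD 10000±540) and pose ranges (±180/±120/±180 voxel
offsets, ±15° tilts, both gantry windows, joint pitches in the
training articulation ranges), with an unbinned 512² detector so the
96³ phantom subtends a pixel extent comparable to the original
850³-scale images — a binned detector at this miniature scale would
make one pixel a third of a bone radius and measure pixel-quantization
rather than method behavior.  The recovery and noise studies run 50
trials; the training smoke uses 20 toy 64×64 samples for 30 epochs and
a single-sample 200-epoch overfit.  These sizes keep the full suite
and the acceptance script each within minutes on one CPU while leaving
every qualitative conclusion intact.

## Known limitations

Single-view depth (`z°`) is weakly observable — noise studies show
voxel-scale in-plane errors but tens of voxels in depth, consistent
with the geometry's ~2% magnification sensitivity.  The polyaffine
inverse-by-negation is approximate in blend regions.  The phantom's
geometric simplicity means network results here say nothing about
detection accuracy on real anatomy.  Biplanar acquisition, temporal
smoothing, muscle/soft-tissue realism and GPU-scale training are out
of scope.
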