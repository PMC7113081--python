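# Methods

This note documents the models, estimators, numerical choices and
deliberate simplifications in dmrikit, in the order the pipeline runs.

## Coordinate and gradient conventions

All geometry lives in RAS world millimeters. Voxel indexing is 0-based
and voxel *centers* map through the 4×4 affine. NRRD inputs declared in
LPS have x and y negated on the space directions, origin and gradient
vectors at read time. FSL-style bvecs are interpreted in the image
frame and rotated into world coordinates by the orthonormalized
(polar-decomposed) rotation of the affine, then re-normalized; NRRD
gradients follow the DWMRI convention in which per-gradient b-values
scale as the squared gradient norm. Zero-norm directions are legal only
for b = 0.

## Tensor estimation

The default estimator is log-linear least squares over the 7 unknowns
(6 unique tensor components and ln S0); `wls` adds a second pass with
weights equal to the squared predicted signals, the usual
variance-stabilizing choice for log-transformed magnitude data. Choices
that matter:

- Multiple baselines are averaged into one S0 image before fitting.
- Signals at or below `1e-6·S0` are floored before the log; voxels
  where more than 25% of measurements hit the floor are dropped from
  the mask, as are all-zero voxels.
- Negative eigenvalues are clamped to zero and the tensor rebuilt from
  its eigendecomposition, so every in-mask tensor is symmetric PSD. No
  constrained or robust (RESTORE-style) fitting is attempted — adequate
  at the SNRs and sizes this package targets.
- Eigenvalues are reported descending; eigenvector signs follow a
  first-nonzero-component-positive convention so runs are bit-identical.

FA of a zero (degenerate or out-of-mask) tensor is defined as 0.

## Single-tensor tractography

Fixed-step Euler integration on the principal-eigenvector field,
bidirectional from each seed, with the two half-tracks joined sharing
the seed point once. The *tensor* is interpolated component-wise
(trilinear) and decomposed at the interpolated point; interpolating
eigenvectors directly would hit sign-discontinuity artifacts. The new
direction is sign-aligned with the previous one (line fields have no
orientation). Stopping: interpolated FA below `fa_stop`, turning angle
above `angle_stop_deg`, leaving the tracking mask or grid, or length.
Each half-track is capped at `max_length_mm/2` so the joined streamline
respects the bound; results shorter than `min_length_mm` are discarded
and seeds outside the mask are skipped and counted.

Defaults (conventional clinical-research values, not tuned to any
dataset): step 0.5 mm, fa_stop 0.15, angle 45°, lengths 10–250 mm.
The integrator is deliberately first-order; on the quarter-circle
phantom its endpoint error scales linearly with step size, which the
tests use as a convergence check. Tracking is restricted to whatever
mask the tensor volume carries; quantitative geometry checks run inside
the bundle mask, the analogue of tracking within a white-matter mask.

## Two-tensor + free-water UKF tractography

State (11 components): two unit directions, per-compartment axial and
radial diffusivities (axially symmetric tensors), and the free-water
volume fraction. The measurement model mixes the two tensor
compartments with equal ½ weights and an isotropic compartment with
fixed diffusivity `d_iso = 3.0e-3 mm²/s` (body-temperature water); the
signal is divided by interpolated S0 before filtering so the
measurement noise `R` is scale-free.

Numerical choices:

- Diffusivities are filtered in log-space, so Kalman updates cannot
  produce negative eigenvalues; after every update directions are
  re-normalized, fw clipped to [0, 1], and eigenvalues clipped to
  [1e-6, 2.0e-3] mm²/s.
- The 2.0e-3 upper bound encodes that *tissue* diffusivity stays well
  below free water. Without it, a single-shell acquisition cannot
  separate an inflated tissue tensor from a free-water admixture (the
  likelihood is flat along that trade-off), and the filter drifts along
  the ridge under noise.
- Scaled sigma points with α = 0.001, β = 2, κ = 0; covariance is
  symmetrized and eigenvalue-floored after every update, and a
  non-finite state or covariance raises a divergence error that ends
  the streamline.
- Process noise: 1e-8 on direction and log-diffusivity components,
  1e-6 on fw; measurement noise R = 0.02 on the normalized signal. All
  exposed in `UKFParams`.

**Initialization.** A plain log-linear fit at the seed absorbs any
free water into inflated eigenvalues, which would start the filter on
the wrong side of the degeneracy. The initializer therefore
grid-searches fw ∈ [0, 0.95] under the standard single-shell
constraint that the tissue compartment's mean diffusivity equals a
typical parenchymal value (0.75e-3 mm²/s): for each candidate the
isotropic compartment is subtracted from the normalized attenuations, a
tensor is refit on the corrected attenuations and rescaled to the fixed
tissue MD, and the candidate minimizing the composite-model residual
wins, with the configured `init_fw` (default 0.1) acting as a floor.
The seed signal is averaged over a small 7-point ball to keep the init
off a single voxel's noise. Compartment 1 starts on the principal
eigenvector; compartment 2 on the second eigenvector with the second
and third eigenvalues, so in single-fiber voxels its FA is ≈ 0 and the
second branch is not spawned, while in crossing voxels the oblate fit
starts both compartments anisotropic.

Initial covariance: 0.01 on directions, 1e-4 on log-diffusivities, 0.1
on fw. The asymmetry is deliberate: diffusivities are treated as known
after the constrained init (the single shell cannot re-estimate them
reliably), while directions and fw remain data-driven. With these
settings the filter behaves as recursive least squares for fw along
the track, which is what makes free-water recovery work at SNR 30.

**Branching and stopping.** Exactly two streamlines per seed (one per
compartment, each tracked bidirectionally) rather than recursive
branching — output size is bounded and deterministic. A branch stops on
the followed compartment's FA, the turning angle, grid/mask exit, or
filter divergence. Per-point scalars `fw` and `fa_compartment` are
attached to every streamline. Sigma points are deterministic, so
identical inputs give bit-identical tractograms; randomness exists only
in seed placement.

**Known limitation.** fw and the diffusivities are jointly identifiable
only through the constraints above; on multi-shell data the constraint
could be dropped, but multi-shell acquisitions are out of scope. The
convergence unit test accordingly holds fw near truth and verifies
recovery of directions (to 1e-4) and diffusivities (to 1e-6 mm²/s).

## Tract quantification

Statistics pool over fiber *points*; averaging per-streamline means
first is available behind a flag. Points that fall outside the scalar
grid get the edge-clamped value but are flagged invalid and excluded
from pooled statistics. Tract volume marks every voxel containing at
least one fiber point after densifying each streamline to at most half
the smallest voxel edge between samples — an error bounded by the
densification pitch and idempotent under streamline duplication, which
is the behavior the tests pin down (a 20 mm axis-aligned line through
2 mm voxels gives exactly 80 mm³). Length histograms span
[min, max] with fixed-width bins, final bin closed, so counts are
conserved.

## Fiber clustering and identification

Streamlines are resampled to k = 15 arc-length-uniform points.
Distances: MDF (min of direct and flipped mean corresponding-point
distance; orientation invariant) as default, symmetric mean closest
point as alternative. Spectral embedding: affinity
`A = exp(−M²/σ²)` with σ = 30 mm, top 10 eigenvectors of the
symmetrically normalized affinity, rows unit-normalized; eigenvector
signs are fixed (largest-magnitude entry positive) for bit-identical
repeats. Partitioning is k-means (scikit-learn) with a fixed seed.
Atlas identification resamples each fiber to the atlas's k, assigns the
nearest centroid by MDF, and rejects beyond a configurable radius. The
atlas format is a JSON header plus a centroid TRK; no anatomical atlas
is bundled — synthetic atlases are built from labeled tractograms.
Dense pairwise distances are adequate at the intended scale (a few
thousand fibers); Nyström-style approximations are out of scope.

## Phantoms

Bundles are tubes swept along straight, circular-arc, or helical
centerlines, rasterized with 3× supersampling per axis; tube end caps
are flat (points projecting beyond the centerline ends are excluded) so
arc lengths match their analytic values. Voxel signals mix bundle
compartments (weights from occupancy fractions; overlapping full
bundles share a voxel equally), an isotropic background
(0.7e-3 mm²/s), and a free-water compartment inside an optional edema
region. Bundle eigenvalues default to textbook white-matter values
(λ∥ = 1.7e-3, λ⊥ = 0.3e-3 mm²/s). The acquisition defaults mirror a
clinical 3T protocol: b = 1000 s/mm², six baselines, 30 directions
from a deterministic generalized-spiral scheme (midpoint latitudes, no
poles), 2 mm isotropic voxels, S0 = 1000. Noise is Rician,
σ = S0/SNR, reproducible from a seed.

What the phantoms do *not* emulate: head geometry and partial-volume
anatomy beyond tube boundaries, eddy-current/motion artifacts,
multi-shell acquisitions, spatially varying S0 or coil profiles, and
tensor distortion inside edema (the collar changes only the free-water
fraction, isolating the variable the UKF estimates). Passing tests
therefore demonstrate correctness of the estimators and trackers under
their own model assumptions, not robustness to real-scanner artifacts.

Preset problem sizes are small on purpose: 20×12×12 (straight, edema),
20×20×8 (arc), 16×16×16 (crossing), all at 2 mm. The full test suite
runs in well under a minute and the acceptance script in seconds on one
CPU.

## Pipeline runner

`dmri run` executes stages in dependency order from a single YAML
config (unknown keys rejected), writes uncompressed NIfTI/TRK outputs
so re-runs are bit-identical, and emits a JSON manifest with per-output
SHA-256 hashes and input hashes for provenance.
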