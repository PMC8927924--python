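# Methods

`trabstiff` predicts the apparent stiffness tensor of trabecular bone cubes
from spherical summaries of their microarchitecture. This note records the
models implemented, the numerical choices behind them, and what the
synthetic benchmark does and does not establish.

## Problem and pipeline

A segmented micro-CT cube of trabecular bone behaves, at the continuum
scale, like a homogeneous elastic solid described by a fourth-order
apparent stiffness tensor `C` (sigma_ij = C_ijkl eps_kl), carried here as a
6x6 Voigt matrix in MPa, order (11, 22, 33, 23, 13, 12), engineering shear
convention. The reference ("observed") `C` comes from voxel micro-finite
element homogenization; the predictor is a spherical convolutional neural
network (SphCNN) whose input summarizes the volume as functions on the unit
sphere:

1. preprocessing: 3-D Gaussian filter (sigma 1.2 voxels, kernel radius 2),
   single-level threshold, largest 26-connected component;
2. local morphometry: trabecular thickness Tb.Th(p) and spacing Tb.Sp(p) as
   the diameter of the largest inscribed sphere covering p in bone
   (resp. marrow), in mm;
3. extended Gaussian image (EGI): each voxel deposits |grad x| (optionally
   weighted) into the spherical bin of its outward normal direction
   -grad x/|grad x|;
4. the network regresses the 36 entries of `C` from one of three input
   variants: `egi` (1 channel), `scaling` (EGI plus EGIs weighted by Tb.Th
   and Tb.Sp), `channels` (EGI plus EGIs of the gradients of the Tb.Th and
   Tb.Sp maps).

A fabric-tensor baseline (GST / MIL moments of the EGI driving an
orthotropic power law) provides the classical morphology-elasticity
comparison.

## Micro-FE homogenizer (gold standard)

Every foreground voxel is an eight-node hexahedral element (2x2x2 Gauss
quadrature) of linear isotropic tissue, E = 12000 MPa, nu = 0.3; marrow is
void. Kinematic uniform boundary conditions impose u = eps_bar . x on all
nodes of the cube faces; six canonical unit strains (magnitude 1e-3, three
normal, three engineering shear — the magnitude divides out of the linear
problem) are solved and column k of `C` is the stress average over the
*total* cube volume. For a fully solid cube the affine field satisfies the
discrete equations exactly, so the homogenized matrix equals the isotropic
closed form (C11 = 16153.85, C12 = 6923.08, C44 = 4615.38 MPa) to solver
precision — the strongest available end-to-end check. KUBC averaging gives
an upper bound on the apparent stiffness, so removing elements can never
raise a diagonal entry; the suite verifies this monotonicity on random
structures.

Solver: the global system is assembled as a sparse matrix and the free
block solved with Jacobi-preconditioned conjugate gradients to relative
residual 1e-8 (a direct factorization is used below ~3000 unknowns and
available as an option). On 12k-DOF trabecular systems Jacobi-CG converged
in ~220 iterations (~0.2 s), roughly 20x faster than sparse LU at this
scale. Raw output asymmetry is ~1e-14 relative and is symmetrized away.

Structures not connected to the cube boundary make the system singular;
generation enforces a single connected component upstream.

## Local thickness and spacing

Hildebrand–Rüegsegger style: the Euclidean distance transform gives the
largest inscribed-sphere radius at every candidate center; spheres are
painted in decreasing radius order so every voxel keeps the diameter of the
largest covering sphere. Membership uses voxel centers with *integer*
squared distances (strict inequality), which removes float leakage at
sphere surfaces; radii are converted to mm at the end. Background maps to
zero (Tb.Th) and foreground to zero (Tb.Sp). No edge correction is applied:
the distance transform only sees real background voxels, so structures
touching the volume border are measured as if they continued outward. A
brute-force O(n^2) inscribed-sphere oracle (independent code path over
pairwise integer distances) agrees with the implementation exactly on
random volumes up to 24^3; digital balls, slabs and cylinders reproduce
their analytic diameters within 1 voxel.

## Spherical grid, EGI, and transforms

The grid is equiangular with 2b x 2b samples: azimuth alpha_i = pi i / b,
elevation beta_j = pi (2j+1) / (4b). The half-step elevation offset places
the nodes at Chebyshev abscissae and avoids pole samples; Fejér first-rule
weights make the quadrature exact for band-limited integrands and sum to
4 pi. The default bandwidth is b = 32 (64x64 maps).

EGI binning is nearest-bin (mass per bin, not density); the discretized
surface integral is explicit, and total mass is conserved exactly. Two
degeneracies are handled deterministically: gradients numerically parallel
to the polar axis (undefined azimuth, tolerance 1e-9 relative) spread their
mass uniformly over the azimuth row, and mass landing exactly on an
interior elevation-bin edge (e.g. equator normals of axis-aligned slabs) is
split half-half between the adjacent rows. These two rules make a 90-degree
rotation about the polar axis shift the EGI by exactly b/2 azimuth bins and
make complementing the volume exchange bins antipodally, with no float
caveats. The gradient uses spacing-aware central differences after a small
Gaussian pre-smoothing (default 0.5 voxels) since the indicator's gradient
is otherwise degenerate; epsilon = 1e-12 guards the direction
normalization. The gradient-direction convention is the outward surface
normal of bone (bone -> marrow), with no antipodal symmetrization.

Spherical-harmonic analysis/synthesis use orthonormal complex harmonics
(Condon–Shortley phase) as explicit quadrature matrices; round trips on
band-limited maps are exact to ~1e-13 and Parseval holds to the same
level. Zonal convolution is diagonal in degree, yhat_lm =
2 pi sqrt(4 pi/(2l+1)) fhat_lm hhat_l. Rotations act through Wigner-D
blocks (ZYZ Euler angles; little-d by the stable log-factorial sum), and
zonal convolution commutes with them to ~1e-10 at b = 8. A real
orthonormal-harmonics fast path backs the network so all training tensors
stay real.

Pooling halves the bandwidth by area-weighted 2x2 block means; the pooled
grid carries the block-summed weights so repeated pooling and the global
weighted average telescope exactly. Block pooling is a smoothing operator
(it attenuates high azimuthal orders and carries a half-sample azimuth
offset); the spectral alternative `pool_half_truncate` (coefficient
truncation, exact resampling of the truncated function) is provided and
used as the reference in tests.

## Network

Three spherical convolution layers (widths 64/128/256) with full
cross-channel zonal kernels, each followed by affine batch normalization,
per-channel PReLU (slope init 0.25), and pooling (b: 32 -> 16 -> 8 -> 4);
area-weighted global average pooling to 256 features; dense 256 -> 64
(batchnorm + PReLU) -> 36; identity output activation; prediction not
symmetrized. Kernel coefficient counts default to (32, 16, 8): a kernel at
a pooled layer cannot hold degrees beyond that layer's bandwidth, and this
truncation gives 420,132 trainable parameters for 3-channel input (416,036
for 1-channel), i.e. about 0.4 M. The counts are configurable.

Training: ADAM (beta 0.9/0.999), batch 16, loss = mean per-sample relative
Frobenius error ||C_o - C_p||_F / ||C_o||_F on the plain Voigt matrices
(this 6x6 norm is deliberately not the rotation-invariant Mandel norm: the
output is modeled as a 36-vector). Default schedule 600 epochs at
0.01/0.001/0.001 per 200-epoch third, reshuffled every epoch,
deterministic in the seed. Two numerical choices matter on top of this:

- **Head units.** The head regresses `C` in multiples of the tissue
  modulus (output_scale = 12000 MPa, a fixed unit conversion, not a
  data-dependent normalization). ADAM steps are O(lr) per parameter, so
  with raw-MPa targets (entries of order 10^3) the head could not reach
  the required magnitudes under the stated schedule; in tissue-modulus
  units all parameters stay O(1). The loss is scale-free, so the reported
  errors are unaffected.
- **Zero-initialized head.** The last dense layer starts at zero, so an
  untrained network predicts the zero matrix (error exactly 1) and the
  first learning phase fits the dataset mean.
- **Batchnorm recalibration.** Mini-batch running averages estimate the
  inference statistics poorly on datasets of this size; after training,
  one full pass pins the running statistics to the training-set moments.

All gradients are closed-form per layer and are checked against central
finite differences (relative agreement better than 1e-4) on a small
configuration.

Cross-validation is k-fold (default 5) stratified by site with a rolling
offset so fold sizes stay balanced; every sample is validated exactly
once. Optional data augmentation rotates inputs by whole grid steps in
azimuth (the only rotation exact on the grid); off by default.

## Fabric baseline

GST: the second (or fourth) directional moment of the EGI mass, trace-
normalized to 3. MIL-style tensors: the EGI density is filtered with a
zonal kernel — |cos theta| for the classic mean-intercept construction, a
symmetrized concentrated bump exp(kappa |cos theta|) - 1 as a GMIL-style
stand-in (it is labeled synthetic: the published generalized-MIL kernels
are not reproduced here) — the filtered distribution is inverted, and an
order-2 tensor fitted by area-weighted least squares over directions. For
extreme synthetic inputs (e.g. a two-point slab EGI) the least-squares fit
can produce a negative smallest eigenvalue; realistic EGIs yield positive
tensors.

The stiffness baseline is an orthotropic Zysset–Curnier-type power law in
the fabric eigenframe: C_iiii = c_a rho^k m_i^{2q}, C_iijj = c_b rho^k
(m_i m_j)^q, C_ijij = c_c rho^k (m_i m_j)^q, with rho = BV/TV and m_i the
trace-3 fabric eigenvalues. The five constants are fitted by linear least
squares in log space on training folds only (deterministic); data generated
exactly from the family are recovered to machine precision. This family
stands in for published fourth-order fabric models whose exact constants
are not reproduced here; its role is the protocol (closed-form
morphology-based baseline, tuned per fold) rather than any specific
published coefficient set.

## Synthetic microstructures

Real micro-CT specimens are not distributable, so the benchmark generates
binary microstructures by thresholding stationary anisotropic Gaussian
random fields: prolate correlation (elongated along a principal axis) for
rod-like, oblate for plate-like, a blend for mixed, with base correlation
length 3 voxels. All classes mix in a 35%-weight isotropic component —
without it, strongly anisotropic realizations percolate abruptly and
intermediate volume fractions become unreachable after connected-component
cleanup. The threshold is found by a damped fixed-point iteration on the
post-cleanup volume fraction (contract: within 0.03 of the target, typically
0.02), resampling the field up to twice — deterministically from the same
seeded stream — if a percolation jump straddles the target. The anisotropy
parameter monotonically controls the GST eigenvalue ratio (measured ~1.0,
~2.8, ~5.3 at settings 0/1/2.5 for rods).

In dataset generation the structural principal axis scatters about the
specimen z axis (Gaussian transverse components, scale 0.35, about 19
degrees mean tilt) rather than being uniform on the sphere. This mirrors
how micro-CT cubes are cut along anatomical directions, with the main
trabecular orientation correlated to them. It also matters for what the
benchmark can show: after global average pooling the network is nearly
rotation-invariant (pointwise nonlinearities on the grid break this only
through discretization), so a specimen set with uniformly random
orientations would ask the architecture for exactly the equivariance it is
known not to have, and the oriented part of the stiffness would be
unlearnable by construction. With anatomically plausible orientation
scatter the task matches the method's operating regime.

What the generator emulates: connected plate/rod networks with realistic
volume fractions (0.05–0.4), controllable fabric orientation and strength,
and the strong coupling of density and stiffness. What it does not emulate:
scanner noise and partial-volume effects, cortical remnants, marrow-space
heterogeneity, the morphometric scale of real trabeculae relative to the
18 um voxel size, and site-specific architecture differences — the
"sites" of the benchmark are structure classes (rods/plates/mixed), not
skeletal sites. Passing the benchmark therefore demonstrates that the
pipeline machinery (features -> network -> evaluation protocol) works and
that spherical summaries carry stiffness information; it does not certify
accuracy on clinical micro-CT data.

## Benchmark problem sizes

The end-to-end benchmark in the acceptance suite uses 100 specimens at
24^3 voxels (18 um spacing), spherical bandwidth 16, a reduced network
(widths 16/32/64, kernel coefficient counts 8/4/2, batch size 8, 300
epochs at 0.01/0.001/0.0001 per third), and 5-fold cross-validation per
input mode — sizes chosen so the full suite runs on a single desktop core
in minutes while keeping the protocol identical to the full-scale
configuration. At this data scale the full-width kernel parameterization
overfits (training error well below validation with no validation gain),
so the benchmark kernels carry fewer coefficients per layer; the network
family and everything else is unchanged. Stiffness ground truth for all
specimens comes from the in-package micro-FE homogenizer.

## Known limitations

- The spherical CNN runs on NumPy with hand-written backpropagation; it is
  sized for method validation, not GPU-scale training.
- Spatial block pooling attenuates high azimuthal orders (see above); the
  paper-shaped architecture inherits this property.
- Arbitrary-angle volume rotation uses trilinear resampling with edge
  cropping and a 0.5 re-threshold for binary volumes; only lattice (90
  degree) rotations are exact, and the rotation experiment treats them as
  the reference points.
- The micro-FE model is linear elastic with a single tissue modulus; no
  damage, no tissue heterogeneity, no periodic boundary conditions (KUBC
  only, hence stiffness upper bounds).
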