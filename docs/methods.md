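# Methods

This note documents the models, numerical schemes and design choices behind
`chondrosim`, in the order of the pipeline: synthetic data → segmentation →
geometry → electro-quasistatic solver → dielectric extraction → uncertainty
quantification. It also states what the synthetic generator does and does
not emulate, and therefore what passing tests do and do not demonstrate
about real microscopy data.

## Synthetic tissue generator

Chondrocytes are modelled as solid ellipsoids. Cell volumes are drawn from
a truncated normal distribution with mean 2,157 µm³ and s.d. 957 µm³
(truncated at zero), the population statistics reported for healthy
articular cartilage; both parameters are exposed. Shape is controlled by
two axis ratios drawn uniformly: a/c ∈ [1, 2] and b/c ∈ [1, a/c], giving
blob-like ellipsoids consistent with the ellipsoidal-cell assumption the
whole pipeline rests on. Orientations are uniform random rotations
(normalized random quaternions). Placement is uniform in the box; with
`allow_touching=False` a conservative bounding-sphere criterion guarantees
disjoint cells fully inside the box, at the cost of slightly looser
packings than strictly necessary.

Axis order is (z, y, x) everywhere, voxel centers at (i + 0.5)·voxel. The
default voxel size is the confocal acquisition geometry being emulated:
0.1099 × 0.1099 µm in-plane, 1 µm between slices.

Rendering assigns each cell a jittered foreground intensity over a uniform
background, multiplies a linear illumination ramp per axis, optionally adds
bright spherical artifacts (Poisson-distributed count), Poisson shot noise
and additive Gaussian noise, then quantizes to 8/16 bits. Ground-truth
labels come from the analytic quadratic-form membership test at voxel
centers, so the reference segmentation is exact by construction (later
labels win on the rare overlap voxels).

**Not emulated:** optical point-spread blurring, z-attenuation,
multi-channel dyes, pericellular matrix, non-ellipsoidal cell shapes.
Passing segmentation tests therefore show that the chain recovers
ellipsoidal cells under intensity noise, shading and artifacts — not that
it handles PSF-distorted or irregular real cells.

## Classical segmentation chain

`resample_isotropic` brings anisotropic stacks to cubic voxels equal to the
smallest voxel dimension (configurable interpolation order, linear by
default); physical extent is preserved within one voxel per axis.

`preprocess` = Gaussian denoising (0.5 µm) → illumination flattening →
percentile contrast stretch, each stage toggleable. Background flattening
fits a total-degree-2 polynomial surface to voxels at or below the 60th
intensity percentile and subtracts it. A rolling-ball / grayscale-opening
estimator was considered and rejected: on desk-scale test stacks the
structuring element (which must exceed a ~20 µm cell) is comparable to the
whole stack, so boundary effects dominate; the polynomial surface is exact
for the linear and bilinear shading fields the generator produces and has
no boundary pathology.

`auto_threshold` is Otsu by default (li, yen, triangle, isodata, mean are
selectable); a polarity flag handles inverted contrast; constant images
raise.

`filter_artifacts` removes per-slice 2D components above 300 µm²
(8-connectivity) and then 3D components below 200 µm³ (26-connectivity).
Both thresholds are physical units converted through the voxel size, so the
filters behave identically across resolutions. The operation is
idempotent.

`split_cells` fills holes, computes the Euclidean distance transform with
physical sampling, and waters heds the inverted map from h-maxima seeds.
The seeds are the regional maxima of the h-reconstruction of the distance
map (not the residue-based peak markers): on a discrete grid a single cell
often carries several equal-height distance maxima separated by shallow
saddles, and the reconstruction plateau connects them into one seed while
peaks separated by deeper saddles (genuinely touching cells) stay distinct.
The default depth h = 1 µm is well below the saddle depth of two touching
8 µm spheres at 12 µm center distance (≈ 2.7 µm), so those split correctly.

`fit_ellipsoids` uses solid-body moments: center = voxel centroid, axes
from the eigen-decomposition of the voxel covariance with the per-voxel
uniform term h²/12 added back, semi-axis ᵢ = √(5 λᵢ), then a uniform
rescaling that makes each fitted ellipsoid's volume equal its labeled voxel
volume exactly (the volume identity Σ fitted = Σ labeled holds by
construction and is asserted in tests).

## Instance metrics

Matching is optimal one-to-one assignment maximizing total IoU
(Hungarian algorithm on the sparse overlap table); zero-overlap pairs never
match, pairs below τ (default 0.5) are discarded. accuracy = TP/(TP+FN+FP),
precision/recall/F1 as usual, with both-empty defined as accuracy 1. A
brute-force enumeration over all one-to-one assignments serves as the test
oracle on small grids.

## Geometry assembly

The intersection graph performs all n(n−1)/2 pair tests (the count is part
of the contract); each test is a bounding-sphere reject followed by
deterministic 1,000-point Fibonacci surface sampling with an algebraic
containment check, tolerance 0.01 µm. Void repair walks the fundamental
cycle basis of each component: cycle cells are voxelized locally, pairwise
common volumes fused, and two void types handled — enclosed cavities
(background unreachable by outside flood fill; filler at the cavity
centroid, radius 1.1× its bounding radius) and open pockets (fused common
volumes disconnected, e.g. the open "donut hole" of a three-cell ring;
filler at the pocket's Chebyshev center with radius 1.1× the max distance
to the cycle cells, so it bridges all of them). Cavities larger than half
the cycle union are flagged for manual review instead of auto-filled.

Surface meshes are per-label marching cubes in physical coordinates with a
one-voxel Gaussian pre-smoothing of the binary indicator by default: raw
binary marching cubes produces 45°-faceted staircase surfaces that
overestimate a sphere's area by roughly 9%, while the smoothed indicator
brings both area and volume errors to the percent level. Smoothing can be
disabled. Taubin smoothing (λ = 0.5, μ = −0.53, 10 iterations — the
classic pass-band choice) uses the uniform umbrella Laplacian; quadric edge
collapse decimation is a Garland–Heckbert implementation with area-weighted
quadrics, link-condition and normal-flip guards, stopping early with a
warning when no legal collapse remains.

The solver geometry is a direct voxelization: cytoplasm = union of cell
memberships at voxel centers (intersecting cells fuse — interior walls
carry no membrane), everything else buffer, plates on the two box faces
normal to the electrode axis. Cells crossing the box are clipped with a
warning, mirroring cells cut by the imaging boundary. The STL
surface-mesh chain above is retained for export and fidelity accounting; no
CAD or tetrahedral meshing step exists.

## Electro-quasistatic solver

The potential obeys ∇·((σ + jωε₀ε_r)∇φ) = 0 between plates at fixed
potentials (1 V drop by default). Discretization is a node-centered
finite-volume admittance network: one node per voxel; the branch between
neighbours is the series combination of the two half-voxel admittances
κ·A/(d/2); boundary voxels attach to their plate through a half-voxel
branch so the electrode separation equals the box length exactly. The
scheme is exactly conservative and reproduces piecewise-constant 1D fields
to solver tolerance, which the closed-form parallel-plate tests exploit.

The 7 nm membrane is a thin-layer series element on every buffer/cytoplasm
face — never a resolved shell. Each face element is weighted by the axis
component |n_a| of the local interface normal: a voxelized curved surface
presents staircase faces whose total area exceeds the true area (×3/2 for
a sphere), and the unweighted thin-layer elements would overestimate the
total membrane capacitance by the same factor (empirically a ~40% error in
the low-frequency permittivity of a dilute suspension). With the
projection weight the summed membrane admittance of a patch equals that of
the true surface (Σ A_face·n_a² = S), and the per-face transmembrane
potential becomes orientation-independent. Normals are estimated from the
gradient of a Gaussian-smoothed cytoplasm indicator whose width is fixed in
physical units at construction (1.5× the coarsest voxel) so that grid
refinement of a fixed geometry converges.

Default material parameters: σ_m = 8.7×10⁻⁶ S/m, σ_cyt = 0.48 S/m,
σ_buf = 1 S/m, ε_rm = 5.8, ε_rcyt = 60, ε_rbuf = 80, d_m = 7 nm.

The complex-symmetric system is solved by COCG (conjugate orthogonal
conjugate gradient) with Jacobi preconditioning, zero initial guess, fixed
ordering, relative residual 10⁻¹⁰ — deterministic per platform. A sparse
direct solve is available for small grids. Z = V/I with I summed over the
driven-plate branches; conservation makes any cross-section equivalent,
which the plate-balance test asserts to 10⁻⁶. The frequency grid is
10^linspace over the decades including both endpoints (1 kHz → 1 THz at 10
points per decade = 91 frequencies). The transmembrane potential per face
is the membrane share of the node-to-node potential drop (series-impedance
division), signed cytoplasm minus buffer.

**Discretization accuracy.** On a fixed voxelized shelled sphere the
functional quantities converge at roughly O(h^1.4), limited by the corner
singularities of the blocky interface; on a 40 µm box the 64³→96³
difference is ≈ 0.04% in σ_eff and ≈ 0.4% in the low-frequency ε_r_eff.
Reaching 0.05% consistency in ε_r_eff would need grids well beyond desk
scale (or higher-order interface-fitted elements, which are out of scope);
this is measured honestly by the refinement fixture rather than tuned.
The refinement protocol deliberately refines the solver grid by integer
subdivision of a fixed voxelized geometry, so the measured differences are
pure discretization error, not geometry re-sampling jitter.

## Dielectric extraction and the single-shell oracle

With cell constant k = separation/area, σ_eff = Re(1/Z)·k and
ε_r_eff = Im(1/Z)·k/(ωε₀); ω = 0 rows report NaN permittivity. The
analytic reference for dilute suspensions is the single-shell model: the
membrane-covered sphere is replaced by an equivalent homogeneous particle

    ε*_p = ε*_m · [2(1−v)ε*_m + (1+2v)ε*_cyt] / [(2+v)ε*_m + (1−v)ε*_cyt],
    v = (1 − d_m/R)³,

mixed with the medium by the first-order Maxwell–Wagner formula

    ε*_eff = ε*_buf · [2(1−φ)ε*_buf + (1+2φ)ε*_p] / [(2+φ)ε*_buf + (1−φ)ε*_p],

with ε* = ε_r − jσ/(ωε₀). For the default parameters this produces the
β-dispersion step near 1 MHz. A single sphere in a box with insulating
side walls corresponds to a cubic lattice of spheres, which the dilute
formula approximates to O(φ²); at 2% volume fraction the solver and the
oracle agree within ~3% across 10 kHz–100 MHz.

## Uncertainty quantification

Uniform parameters are expanded in a total-degree orthonormal shifted
Legendre basis of order p = 4; M = C(d+p, p) terms. Coefficients come from
point collocation: least squares on 2M + 2 seeded pseudo-random nodes (the
2M + 2 rule reproduces the canonical evaluation counts 254 for d = 5 and
662 for d = 7). Mean and variance are read off the orthonormal
coefficients; first-order Sobol indices sum the squared coefficients of
terms depending on one parameter alone; 5th/95th percentiles are empirical
over 10⁴ surrogate samples. Collapsed (zero-width) parameter ranges are
held constant and excluded from the expansion; an all-constant study
evaluates the model once and reports zero variance.

Case 1 (geometric uncertainty): a movable ellipsoid (nominal volume
2,157 µm³, axis ratios 1.5 : 1.2 : 1) at the center of a 54 µm box with a
fixed copy toward the top-right corner. Uncertain parameters: x, y, z
position (half-width 5.20 µm per axis), volume (±25%), and one rotation
angle about a transverse axis ([0°, 90°]). The position ranges are
constructed so the nominal surface-to-surface distance between the cells
spans exactly [4.5, 22.5] µm along the box diagonal; draws that would
intersect the fixed copy are rejected and redrawn. The box size keeps the
fixed copy inside the domain and the volume ratio (~2.7%) within the range
observed for cartilage samples (2–5%).

Case 2 (dielectric uncertainty): fixed geometry; seven uniform parameters
(d_m and all σ/ε_r values) at ±25% around nominal by default, or the five
cellular ones with the extracellular medium fixed. Ranges are fully
configurable since the reference intervals are not printed in the main
literature.

Outputs tracked through UQ are σ_eff and ε_r_eff per frequency. The
scaled-down acceptance study uses a 32³ grid and a 6-point frequency grid
(10 kHz–1 GHz); at that scale the expected ordering — volume dominant for
ε_r below 1 MHz, positions below 0.05 — is reproduced with wide margin
(volume ≈ 0.9, positions ≤ 0.04).

## Problem sizes and tolerances

Defaults used by the test suite and the acceptance script: segmentation
fixtures 160³ voxels at 0.5 µm; suspension oracle 64³; TMP fixture 48³;
refinement fixture 64³/96³; UQ 32³ with 254 solves × 6 frequencies.
Solver tolerance 10⁻¹⁰ (10⁻⁸ inside UQ where surrogate noise dominates).
These sizes were chosen so each stage completes in minutes on one CPU
while leaving every qualitative conclusion unchanged at finer settings.

## Known limitations

- First-order voxel discretization: percent-level absolute accuracy at the
  tested grids and ~O(h^1.4) convergence near blocky interfaces.
- The membrane normal-projection weight assumes a locally smooth interface;
  deliberately blocky solids are treated as smooth at the ~1.5-voxel
  smoothing scale.
- No electrode polarization, no eddy currents, no PSF optics in the
  generator; z-elongation of confocal stacks is not corrected.
- The single-shell oracle is first-order in volume fraction; above ~10% it
  is only indicative (a warning is emitted).
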