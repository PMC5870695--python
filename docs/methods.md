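# Methods

This note documents the models, algorithms, defaults and design choices in
hexfem, and what the synthetic phantoms do and do not establish about real
head models.

## Volume conductor and discretization

The electric potential in the head is modeled quasi-statically:
`∇·(σ∇u) = ∇·jᵖ` in the head volume `Ω` with homogeneous Neumann boundary
conditions (no current crosses the scalp). `σ` is piecewise constant per
tissue; the default isotropic values follow the standard isotropic
literature values used across FEM head-modeling toolchains:

| tissue       | σ (S/m) |
|--------------|---------|
| skin         | 0.43    |
| skull        | 0.01    |
| CSF          | 1.79    |
| gray matter  | 0.33    |
| white matter | 0.14    |

These are defaults only; every entry point takes an explicit label→σ table.

**Meshing.** One 8-node hexahedral element per nonzero voxel, nodes at voxel
corners, deduplicated; background (label 0) is never meshed. Local corner
ordering is the right-handed unit-cube order documented in
`hexfem._element`. Coordinates are world mm; voxel indices are 0-based with
nodes at voxel corners.

**Geometry adaptation (node shift).** For every node whose eight incident
voxels (the 2×2×2 neighborhood; out-of-volume voxels count as background)
carry at least two distinct labels, the strict minority label is found and
the node moves by `node_shift` times the vector from the node to the
centroid of the minority-label voxel centers. Ties in the minority count
leave the node in place, so flat interfaces are not biased sideways; the
displacement is bounded by `node_shift·(√3/2)·h` and is halved iteratively
on any element whose isoparametric Jacobian would become non-positive.
Default `node_shift = 0.3`, mid-range of the admissible `[0, 0.49)` band
from the geometry-adapted meshing literature. The neighborhood definition
(corner-incident voxels) is our choice; the smoothing is monotone in the
sense that the outer surface area of a voxelized sphere does not increase
with `node_shift` (tested 0 → 0.3).

**Skull-thickness enforcement.** Thin voxelized skull layers let current
leak through edge-connected voxels, so the segmentation stage can enforce a
minimum skull thickness (3 mm by convention). Implementation: the skull-
enclosed compartments are identified by flood fill (any non-skull region
not 6-connected to the volume border), and every outside voxel (skin or
background) within Euclidean distance `min_mm + √3·h` of the enclosed region
is relabeled skull. The `√3·h` margin accounts for the distance transform
measuring voxel centers while a ray can enter and leave voxel cells half a
cell diagonal from their centers; it guarantees a contiguous radial skull
run of at least `min_mm` along arbitrary ray directions (verified over 1000
random rays), at the cost of slightly over-thickening — in particular a
shell already exactly at `min_mm` still gains up to `√3·h`. Interior labels
are never modified; the geometry is assumed star-shaped from the volume
centroid at skull level, which holds for heads and for all phantoms here.

**Electrode alignment.** Each electrode maps to the closest mesh surface
node (faces belonging to exactly one element); ties break to the lowest
node index, making projection deterministic and idempotent.

## FEM solution

**Assembly.** Trilinear isoparametric elements with 2×2×2 Gauss quadrature,
which integrates the stiffness integrand exactly on parallelepiped
(axis-aligned voxel) elements; on shift-adapted boundary elements it is the
standard isoparametric approximation. The test suite checks the element
matrices against an independent 4×4×4-point quadrature and the assembled
matrix against the summed element energy form. The assembled matrix is
symmetrized against roundoff; row sums vanish (pure-Neumann null space
`span{1}` for connected meshes; disconnected meshes raise a warning).

**St. Venant loads.** The dipole `(x₀, m)` becomes monopole loads `q` on the
patch consisting of the node nearest `x₀` plus all nodes sharing an element
with it. `q` minimizes the squared second-order moments of the patch (plus a
relative Tikhonov term `1e-6` on `‖q‖²`) subject to *exact* equality
constraints `Σq = 0` and `Σ q (x − x₀) = m`, solved via the KKT system on
offsets scaled by the voxel size. Exact constraint satisfaction (machine
precision for the monopole sum, ≤1e-8 relative for the moment) is the
property the rest of the pipeline relies on; the quadratic penalty fixes the
remaining null space smoothly. Sources are admissible when their containing
element carries an admissible (gray-matter) label.

**Reference and solver.** Uniqueness comes from eliminating one node
(Dirichlet `u = 0`) by row/column removal, preserving symmetry and making
the reduced matrix SPD; by default the node of the last (or named) reference
electrode. Systems are solved with conjugate gradients preconditioned by
incomplete Cholesky with zero fill-in (IC(0), implemented in numba), default
relative residual `1e-8`, at most 5000 iterations; if the factorization
hits a non-positive pivot it retries with a diagonal shift of `1e-3` times
the mean diagonal, escalating tenfold. Solves are deterministic.

**Transfer matrix and leadfield.** Row `s` of `T^eeg` solves
`A tₛ = e_{node(s)} − e_{node(ref)}` (self-adjoint, so the adjoint solve is
the direct solve); the reference row is zero, and `T·b` reproduces direct-
solve electrode differences to solver tolerance for arbitrary loads.
Leadfield columns are `T · venant_rhs(x_k, e_axis)` for unit moments along
x, y, z, optionally (default) re-referenced to the average reference, in
which every column sums to zero. Potentials are in consistent arbitrary
units (moment units × S⁻¹ × mm⁻¹); no SI rescaling is attempted, and RDM is
unit-free while lnMAG comparisons always use the same unit system on both
sides.

## Analytic sphere reference

For a dipole inside the innermost shell of concentric spherical shells the
surface potential is a Legendre series; the per-degree response `g_n` of the
layered conductor comes from a small linear system per degree expressing
continuity of `u` and `σ ∂u/∂r` at the interfaces and the insulating outer
boundary, with per-shell scaled radial coefficients for conditioning. The
homogeneous case reduces to the closed form `g_n = (2n+1)/n`, which is an
oracle in the tests along with rotational equivariance and mirror
antisymmetry. The series truncates adaptively (default start 100 terms,
doubling until the tail contributes < 1e-12 of the running norm, cap 1600);
coefficients decay geometrically for eccentricity < 1. Default 4-shell
model: radii 80/86/92/100 mm, conductivities 0.33/1.79/0.01/0.43 S/m.

## Error metrics and the dipole scan

RDM (range [0, 2], scale-invariant topography error) and lnMAG (log
magnitude ratio) are computed in the average-reference gauge by default — a
common-mode offset is a reference choice, not an error — with a flag to
disable. The goal-function scan fits, per admissible grid position, the
least-squares moment of the (average-referenced) data against the 3-column
gain block and maximizes `GoF = 1 − relative residual variance`; ties break
to the lowest position index, rank-deficient gains yield the minimum-norm
moment with a flag. Grid admissibility follows the gray-matter node rule
(every element touching the nearest mesh node is gray) plus the requirement
that the position itself lies in a gray element. The normal constraint on
voxelized anatomy uses the normalized gradient of the distance transform to
the white-matter compartment; sphere phantoms fall back to radially outward
orientations.

## Phantoms, problem sizes, and what the tests show

The concentric-sphere phantom stands in for a segmented MRI: labels by
radial thresholding at voxel centers, a golden-angle spiral electrode cap on
the outer sphere (seeded azimuthal phase; otherwise deterministic). It
reproduces the layered, star-shaped topology of a head segmentation but none
of its anatomy: no cortical folding, no skull openings, no anisotropy, no
segmentation noise. Passing the sphere suite therefore demonstrates the
correctness and convergence of the numerics (meshing, assembly, Venant
loads, solver, transfer algebra, scan), not the anatomical accuracy of any
particular head model.

Validation problem sizes were chosen to keep the full suite in the
minutes range on a single CPU while preserving the resolution ratios that
drive the numerics (voxels per shell thickness, voxels per brain radius):

- **FEM vs analytic (4-shell):** radii 40/44/48/54 mm at 2 mm voxels
  (every shell ≥ 2 voxels thick, brain radius 20 voxels), node shift 0.3,
  33-electrode cap to 150°, eccentricities 0.2/0.5/0.8, radial and
  tangential dipoles along an oblique axis (avoids lattice-aligned
  symmetry). Observed: RDM < 0.05 and |lnMAG| < 0.1 throughout.
- **Resolution sweep:** collapsed-conductivity single-shell sphere
  (r = 30 mm) at 4/2/1 mm; mean RDM decreases monotonically.
- **Transfer equivalence:** homogeneous 20 mm sphere at 2 mm voxels, 100
  random dipoles, transfer rows at tolerance 1e-10 against exact sparse-LU
  direct solves; max absolute deviation ≤ 1e-6.
- **Scan recovery:** 4-shell 20/22/24/27 mm phantom at 2 mm voxels, 4 mm
  gray-matter grid, 32 electrodes: 200/200 noiseless on-grid recoveries with
  GoF 1; off-grid sources localize within one grid spacing.

## Numerical choices and degenerate inputs

- Quadrature 2×2×2 for assembly, 4×4×4 reserved for test oracles.
- Downsampling uses block majority vote; ties resolve to the smallest label.
- Zero-norm vectors make RDM/lnMAG undefined and raise; zero dipole moments
  yield identically zero loads/potentials.
- Empty volumes, unknown labels, out-of-range node shifts, sources outside
  the mesh or in non-admissible compartments, invalid reference nodes and
  non-converged solves all raise typed errors carrying context (the solver
  error carries its final residual).
- HDF5 containers are written without timestamps, so identical inputs give
  byte-identical artifacts; the pipeline records config hash, package
  version and seed in every container.

## Known limitations

- Isotropic conductivities only (no white-matter anisotropy tensors).
- The St. Venant variant here (exact zeroth/first-moment constraints,
  penalized second moments) is fully specified and tested, but not claimed
  binary-identical to other implementations of the same family.
- Electrode model is a point electrode collapsed to the nearest surface
  node (no complete-electrode model).
- Skull enforcement assumes a closed skull shell star-shaped about the
  volume centroid; a punctured shell is rejected rather than repaired.
- The dipole scan is the linear goal-function scan on a fixed grid; no
  nonlinear position refinement.
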