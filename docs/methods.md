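# Methods

## Physical models

**Standard problem.** Near-infrared light transport in highly scattering
tissue is modeled by the frequency-domain diffusion approximation

    -div(kappa(r) grad Phi(r,w)) + mua(r) Phi(r,w) + i w/c(r) Phi(r,w) = q(r,w)

with fluence rate `Phi`, absorption `mua` (mm^-1), diffusion coefficient
`kappa = 1/(3(mua + musp'))` (mm), reduced scattering `musp'` (mm^-1), and
modulation angular frequency `w` (`w = 0` is the continuous-wave case).
The speed of light in the medium is `c = c0/n` with
`c0 = 2.99792458e11 mm/s`; all lengths are mm and times seconds (the CLI
accepts ns/ps where that is the natural unit).  At the tissue-air surface
the Robin (partial-current) condition `Phi + 2 beta kappa dPhi/dnu = 0`
models internal reflection; `beta` encodes the refractive-index mismatch.

**Fluorescence.** Excitation (`x`) and re-emission (`m`) fields satisfy a
pair of one-way-coupled diffusion equations; the re-emission source is
`gamma * Phi_x / (1 + i w tau)` with the lumped yield `gamma = eta * muaf`
(mm^-1) and lifetime `tau` (s).  The model is linear in the excitation
field and therefore valid for weakly fluorescent media (no saturation or
re-absorption cascade).

**DCS.** Brownian-motion diffuse correlation spectroscopy obeys the same
elliptic operator with a delay-dependent extra absorption
`2 alphaDb musp' k0^2 tau`, where `k0 = 2 pi / lambda` (lambda in mm) and
`alphaDb` (mm^2/s) is the lumped flow index.  `g1(tau)` is the boundary
`G1` normalized per channel by its `tau = 0` (CW) value.

## Discretization

Linear (P1) simplex elements in 2D (triangles) and 3D (tetrahedra), with
one-based connectivity throughout for compatibility with the classic
ASCII mesh format.  The system matrix is

    A = K(kappa) + M(mua) + M_boundary / (2 beta),    B = M(1/c)

where weighted element integrals use the *element mean* of the nodal
coefficient (the standard lowest-order choice, consistent with P1
accuracy), and the boundary term uses exact closed-form facet mass
matrices (edge: length/6 * [2 1; 1 2]; triangle: area/12 * (2 on the
diagonal, 1 off)).  The basis-overlap matrix `U` (unweighted mass matrix)
converts nodal source densities (fluorescence re-emission, Mellin source
recursions) into FEM load vectors.

One global `beta` is computed from the *modal* refractive index of the
boundary nodes (boundaries are assumed homogeneous); the default method
is Groenhuis's empirical polynomial, with exact and approximate Fresnel
integrations available.  Note that the exact-Fresnel and empirical values
differ by about 10% over the tissue range (both conventions circulate in
the literature); all validation comparisons use the same method on both
the FEM and the analytical side.

Point sources are projected onto the surface and moved one scattering
length `1/musp'` (`1/muspx'` for fluorescence) along the inward surface
normal -- the area-weighted average of adjacent boundary-face normals,
which is robust at edges and vertices.  Detectors are projected but not
moved; boundary data are barycentric interpolations of the nodal field at
the projected detector point.  If the displaced source would exit a thin
mesh, it falls back to the deepest interior point along the normal with a
warning.

## Solvers

All systems are solved by FSAI-preconditioned Krylov iterations: a sparse
lower-triangular `G` with `M^-1 = G^T G ~ A^-1`, applied as two sparse
matrix-vector products.  Row `i` of `G` solves the dense local system
`A[P_i, P_i] y = e_last` over the pattern `P_i` and is scaled by
`1/sqrt(y_last)`; construction is fully vectorized (rows grouped by
pattern size, batched `linalg.solve`).  Patterns:

* `bicgstab3` -- three largest-magnitude entries of the lower triangle per
  row (diagonal always forced in),
* `pcg_diag4` -- diagonal plus four largest strictly-lower entries,
* `full_lower` -- every lower-triangular position; this reproduces the
  exact inverse Cholesky factor and is used for verification.

"Largest" means largest absolute value (FEM off-diagonals are negative);
ties break deterministically toward the smaller column index.  Singular
local systems fall back to diagonal-only rows with a warning.

Real SPD problems (CW, moments, time steps, DCS) use preconditioned CG
with relative-residual tolerance 1e-12 (default) and a 1000-iteration
cap; the complex symmetric FD system `A + i w B` uses BiCGStab
preconditioned by the FSAI of the real part only -- at 100 MHz the
imaginary part is a small mass-matrix perturbation, and a real `G` keeps
the two-product application.  Columns (sources) are solved independently
in a loop; the DCS sweep warm-starts each delay from the previous
solution.  Reported residuals are recomputed as true residuals
`||Ax - q||/||q||`.

## Time-resolved data

**TPSF stepping.** `B dPhi/dt + A Phi = 0` is advanced by a theta scheme
(Crank-Nicolson, `theta = 1/2`, by default; `theta` configurable) with
the impulse launched as the mass-consistent state `B Phi0 = Q`, which
makes the trapezoid time integral of the TPSF equal the CW solution up to
truncation.  The first step is replaced by two backward-Euler half steps
(Rannacher startup) to damp ringing from the impulsive start.  One
factorized operator (sparse LU below 20k nodes, otherwise a reused FSAI)
serves all steps.  On coarse meshes the spatially oscillatory impulse
produces small pre-peak undershoots at the detectors; this is a
discretization artifact that shrinks with mesh refinement, and only
genuine energy growth (possible when `theta < 1/2`) raises an error.
The fluorescence re-emission source is the running exponential
convolution `w_{k+1} = w_k e^(-dt/tau) + gamma Phi^x_{k+1} (1 - e^(-dt/tau))`
(instantaneous re-emission where `tau = 0`) applied through `U`.

**Direct moments.** The Mellin transform `m_n = int t^n f(t) dt` obeys
`m_0 = A^-1 Q` and `m_n = n A^-1 B m_{n-1}`: one linear solve per order
instead of one per time step.  The fluorescence chain additionally tracks
`s_n = gamma .* m_n^x + n tau .* s_{n-1}` and
`m_n^m = (A^m)^-1 (n B^m m_{n-1}^m + U s_n)`.  Normalized moments are
`<t^n> = m_n / m_0` per channel; order 0 is bitwise the CW solve.

## Analytical oracles (semi-infinite medium)

Closed-form Green's functions with zero (ZBC), extrapolated (EBC,
`zb = 2 beta kappa`), and partial-current (PCB) boundaries, for CW/FD
fluence, time-resolved fluence and reflectance, and DCS via the
absorption substitution.  Numerical choices:

* The FD wavenumber is `k = sqrt((mua c - i w)/(c kappa))`, which reduces
  to the CW effective attenuation `sqrt(mua/kappa)`.
* The PCB reflectance factor `T(t) = (1 - sqrt(pi/(a b)) erfcx((1+a)/sqrt(ab)))/a`
  is evaluated with the scaled complementary error function to avoid
  overflow of `exp((1+a)^2/(ab))`.
* PCB line-image integrals use adaptive quadrature truncated at `40 zb`
  (tail below `e^-40`).
* The DCS substitution replaces `mua` only where it acts as absorption
  (inside the wavenumber); `kappa`, the source depth `z0 = 1/(mua+musp')`
  and `zb` keep their static values, matching the correlation-diffusion
  operator the FEM assembles.

A numerically integrated Hankel-transform solution of the exact Robin
half-space problem is kept in the test suite as an independent
transcription oracle; it confirms that the PCB formula *is* the exact
Robin solution, and that the converged FEM surface fluence sits ~6% below
the EBC surface fluence while the *normalized* moments of the EBC
reflectance match the Robin solution to better than 0.1%.  Validation of
slab moments therefore compares normalized moments (orders 1-3) against
the EBC time-resolved reflectance.

## Voxel space and Jacobians

A `VoxelGrid` samples uniform voxel centers, locates each in the mesh
(KD-tree over element centroids with barycentric verification), and
stores the sparse interpolation operator; inside rows sum to one and the
mapping is exact for affine fields.  Grids may cover only a region of
interest; outside voxels are masked.

Jacobians are adjoint products in voxel space: with direct fields `Phi`
(sources) and adjoint fields `Psi` (detectors injected like sources but
not moved inside), the absorption block is `-Phi .* Psi * V_voxel`, the
scattering block applies the chain rule `dkappa/dmusp' = -3 kappa^2` to
the stiffness sensitivity `grad Phi . grad Psi` (P1 per-element constant
gradients, sampled at the voxel's containing element), the fluorescence
yield block is `Phi^x .* Psi^m * V / (1 + i w tau)` (the lifetime block
`-i w gamma Phi^x Psi^m V/(1+i w tau)^2` vanishes at CW, so the CW
Jacobian is the single real gamma block), and the DCS block scales the
absorption product by `2 musp' k0^2 tau` (zero matrix at `tau = 0`).
Frequency-domain matrices interleave real and imaginary rows.  Defaults:
log-intensity data for standard/DCS, Born-ratio (re-emission divided by
excitation) for fluorescence.

Tikhonov reconstruction uses the underdetermined form
`x = J^T (J J^T + lam * max(diag(J J^T)) I)^-1 y`; scaling the
regularizer by the largest diagonal makes `lam` (default 10) unit-free
across grid resolutions.

## Synthetic data and validation scale

The generators produce the idealized geometries the validation pipeline
needs: Delaunay disks from concentric staggered rings (node count within
about 20% of target) and structured Kuhn-subdivided tetrahedral slabs
with exact volume, optionally graded.  They emulate homogeneous phantoms
with perfect point optodes; they contain no measurement noise, no optode
coupling or calibration factors, no heterogeneous anatomy, and no
refractive-index discontinuities inside the domain -- so passing
validation demonstrates correctness of the numerics, not robustness to
real-data artifacts.

Reference experiment sizes (chosen once as the package's production
validation scale):

* moment-validation disks: 43 mm radius, ~2000 nodes, 1 source + 15
  circumferential detectors; TPSF spans 10 ns (standard) and 15 ns
  (fluorescence) at 10 ps resolution;
* reference slab: 120 x 120 x 60 mm, graded 0.9 mm corridor / 5 mm bulk
  (~141k nodes), source at the bottom-face center, detector at 20 mm;
  the grading keeps FEM dispersion in the corridor below ~0.5% where a
  uniform mesh of the same node count would leave several percent;
* DCS sweep: 0 plus 50 log-spaced delays over [1e-8, 1e-3] s, alphaDb in
  {1e-7, 1e-6, 1e-5} mm^2/s at 750 nm;
* anomaly reconstruction: 5% absorption increase in a 10 mm-radius
  region 20 mm off-center, 16-optode all-pairs array, 5% Gaussian noise
  on the log-intensity differences, lam = 10, grids of 2/3/5 mm.

## Known limitations

* Diffusion approximation only: inaccurate for early photons, low
  scattering, or strong source anisotropy.
* Lowest-order elements; no internal refractive-index mismatches; one
  global boundary `beta`.
* CPU only; sources are solved in a loop (no batched multi-RHS kernels).
* The disk mesher is Delaunay-based and can produce stretched boundary
  triangles at very low node counts.
* TPSFs on coarse meshes show small pre-peak undershoots (see above).
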