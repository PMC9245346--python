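# Methods

## Physical model

TTFields operate near 200 kHz, where tissue conduction dominates over
capacitive effects; the field is modeled quasi-statically as ohmic
conduction. The electric potential satisfies ∇·(σ∇φ) = 0 in the conductive
head volume, with zero-flux (insulating) boundaries on the head surface
except at the transducer faces. Conductivities are isotropic and purely
real; no frequency dependence, permittivity, or DTI-derived anisotropy is
modeled. Field intensity |E| = ‖−∇φ‖ (V/m) is the sole dose metric; exposure
time, frequency and field orientation are held fixed by design since the
skull intervention only modifies intensity.

## Discretization and solver

The conduction equation is discretized with a cell-centered finite-volume
7-point stencil on the voxel lattice. Face conductance between adjacent
voxels uses the harmonic mean of the two voxel conductivities times the face
area over the centre distance, so insulating (background) neighbours drop
out naturally and the scheme is conservative by construction — interior
matrix rows sum to zero, and the assembled system is symmetric positive
definite. Voxels may be anisotropic in size (face areas and distances follow
the affine); all phantoms use isotropic lattices.

Electrodes: each 20 mm disc claims the outermost scalp voxels under its
footprint (surface scalp voxels within the disc radius of the disc axis).
Those voxels receive a high cap conductivity (500 S/m, configurable — the
nominal 1 mm cap height is below one voxel at working resolutions, so the
cap occupies the outermost scalp voxel layer) and all nine caps of an array
are constrained to one ideal terminal potential (a Dirichlet super-node).
Caps of *different* terminals are electrically insulated from each other at
assembly (face conductance zeroed): transducer discs are insulated ceramic,
so two arrays pushed into contact must not form a metal-to-metal short.
Without this guard, extreme vertex-translation layouts whose caps become
face-adjacent voxels collapse non-physically to near-zero brain field.

The pair is solved at ±0.5 V terminal potentials with conjugate gradients
(Jacobi preconditioner by default, incomplete-LU optional) to a relative
residual of 1e-8, deterministically; the solution is then rescaled so the
net terminal current equals the requested drive (default 0.9 A
baseline-to-peak), which is exact by linearity. Net source and sink currents
agree to better than 1e-6 relative. E is recovered by central differences
inside the domain and one-sided differences at domain boundaries. A
disconnected conductive domain (terminals in different components) is
rejected; isolated conductive islands are excluded from the solve.

## Phantom

The head is a nest of axis-aligned ellipsoids: outer semi-axes 85 × 105 ×
95 mm (≈ adult head), shells scalp 6 mm, skull 7 mm, CSF 3 mm, GM 4 mm,
remainder WM. All solids (shells, cavity and tumor spheres, funnel and
burr-hole cylinders) are defined analytically in world RAS mm and rasterised
by voxel-centre inclusion, making every label volume a deterministic
function of geometry and voxel size. Construction is rejected when the voxel
size exceeds the thinnest shell (the compartment would vanish); below two
voxels per shell the layer is resolved but stair-stepped, which is the main
source of discretization noise at 3 mm. Muscle, blood and eyeballs are
omitted: they lie far from the current path in all studied layouts, a known
fidelity limitation.

The pathology is a 25 mm spherical resection cavity, an 8 mm cylindrical
funnel track from the cavity to the inner skull table (the surgical
corridor, CSF-filled), and a 25 mm residual tumor sphere tangent to the
cavity, strictly deeper along the funnel axis. The default lesion sits on
the radial ray through the scalp point at azimuth 60°, 50 mm above the
central horizontal plane, so the over-tumor burr-hole template and the
60°-circumferential array overlap — the clinically optimal case.

Skull-remodeling surgery drills five 15 mm burr holes — one central, four at
the corners of a 45 mm square (the quincunx) — along local skull-surface
normals; only skull voxels are relabelled, each hole must pierce the full
skull thickness, and hole material maps to CSF conductivity. Placement
variants: `over_tumor` (radially above the cavity/tumor centroid), `sup3` /
`post3` / `sup3post3` (30 mm geodesic displacements along the skull surface,
matching surgical marking practice), `far` (ipsilateral occipito-parietal,
≥ 80 mm surface distance) and `none` (control).

## Tissue conductivities

Defaults (S/m): scalp 0.25, skull 0.010 (merged compact+spongy bone; the
two-layer values 0.008/0.025 are exposed for users who rasterise the layers
separately), CSF 1.654, GM 0.276, WM 0.126, residual tumor 0.24, necrotic
resection cavity 1.0, funnel and burr holes 1.654 (CSF-filled, both
configurable — which compartment the funnel scar belongs to is genuinely
uncertain). Skull conductivity is the sensitive parameter: the more
resistive the skull, the larger the burr-hole benefit.

## Array layouts

Arrays are rigid 3×3 grids (45 mm pitch along the long axis, 22 mm along the
short axis) laid out by geodesic walks on the analytic scalp ellipsoid, so
pitch is preserved as surface distance (< 1 mm chord/geodesic difference at
head curvature); disc normals are local surface normals. Three families:

* **circumferential** — the opposed pair rotates in 15° steps (0–165°,
  exploiting the pair's 180° symmetry) around the craniocaudal axis on the
  ring 50 mm above the central horizontal plane. Azimuth 0° is the
  anterior–posterior axis (the no-overlap reference).
* **normal_rotation** — from the 60° pair, the ipsilateral array spins about
  the surface normal at its fixed centre; the contralateral array is
  bitwise identical across angles.
* **vertex_translation** — from 30 mm inferior to the 60° pair, both arrays
  slide up their meridians in 10 mm steps (20–150 mm). Travel saturates at
  the last full 10 mm step before the vertex, so all saturated travels share
  one geometry in which the two footprints abut at the vertex — the
  maximally shunted configuration. (A continuous clamp leaves sub-voxel
  geometry wiggles between near-identical saturated layouts; quantizing the
  stop to the family's own step removes them.)

## Dose statistics

Per-region statistics are unweighted voxelwise quantities (the lattice is
regular, so voxels are equal-volume — unlike element-volume weighting on a
tetrahedral mesh): median, "peak" = 99th percentile with numpy's linear
interpolation between order statistics, and cumulative exposure curves
(fraction of region above x, sampled 0–400 V/m in 2 V/m steps). Regions:
whole WM, whole GM, residual tumor, and a peritumoral shell — brain voxels
within a configurable 10 mm margin (Euclidean distance transform) of the
cavity-or-tumor solid, excluding cavity, funnel and tumor. The margin is a
stand-in for a region the source literature uses but never defines.

Enhancement is voxelwise ΔE = |E|holes − |E|control and %Δ = 100·ΔE/|E|control,
always against a control solved with the identical array geometry. Voxels
with control |E| < 1 V/m are flagged undefined in %Δ maps (never silently
infinite). Region summaries use the difference-of-medians form
(median_holes − median_control, and that difference over median_control),
which needs no floor; medians-of-differences is available from the voxelwise
maps. The "under the holes" region of interest is brain within 20 mm
laterally of the *nearest* hole axis: with the 45 mm template the corner
holes sit ~32 mm off the template centre, so a single centre-axis cylinder
would exclude the tissue under four of the five holes (the single-cylinder
variant is exposed as `mode="template_axis"`).

## Uncertainty quantification

The burr-hole filling conductivity is uncertain (scar, fluid, regrown bone);
it is modeled as uniform on [0.465, 1.654] S/m — between skin and CSF — with
all other conductivities fixed. Plain seeded Monte Carlo (default 64 draws)
re-solves the forward problem per draw and accumulates voxelwise mean and
(n−1)-denominator SD of |E|; one uncertain scalar makes MC adequate and
trivially verifiable against the closed-form uniform moments, and each draw
warm-starts from the previous solution so a UQ run costs far less than n
independent solves. A polynomial-chaos surrogate would be a natural
extension point but is not implemented.

## Problem sizes and numerical choices

The package's working resolution is 3 mm (≈ 130k unknowns, ~1.5 s per solve
on one CPU core); 2 mm (≈ 450k unknowns) is the refinement profile used for
grid-robustness checks, and 1 mm remains within the supported [1, 4] mm
range. The test suite and the acceptance script run the full experiment
matrices at 3 mm. Solver tolerance 1e-8 relative; CG iteration caps abort
with diagnostics rather than returning unconverged fields; all sweeps are
pure functions of their configuration (order-independent, bit-reproducible),
and every artifact embeds a hash of its canonicalised configuration.

## What the phantom does and does not show

The ellipsoidal phantom reproduces the geometry-generic mechanisms: skull
shielding, focal enhancement under burr holes, the overlap requirement
between array and holes, scalp shunting between closely spaced arrays, and
insensitivity to rotation about the array normal. Passing tests demonstrate
these mechanisms and the solver's correctness against closed forms — they do
not certify absolute dose values for any real head: cortical folding,
ventricles, edema, skull thickness variation and tumor shape all
substantially shift absolute intensities. Quantities on the phantom are
systematically higher (brain medians ≈ 150–190 V/m at 0.9 A) than on
MRI-derived models (≈ 70–100 V/m), mainly because the smooth ellipsoid lacks
CSF-filled folds and has a thinner effective conductive cross-section;
bounded quantities (whole-brain enhancement limits, relative UQ spread) are
the meaningful scaled-down comparisons. Two further caveats: layouts whose
true dose difference is below the rasterization noise (mirror-symmetric
angles about the optimum differ by ~0.01% at 3 mm) cannot be stably ranked
across resolutions; and the burr-hole UQ spread on the phantom (relative SD
≈ 0.6% under the holes) is smaller than on anatomical models, where the
holes carry a larger share of the current path.
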