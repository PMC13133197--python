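# Methods

This note documents the models implemented in `spinecage`, the assumptions
behind them, the parameters that matter, and what the synthetic phantoms do
and do not establish about real data.

## Coordinate and notation conventions

World coordinates are `index * spacing + origin` with 0-based indices and
array axis order (x, y, z). In the fusion scenes, x is left–right, +y is
anterior, z is superior. All 6×6 stiffness matrices use Voigt order
(11, 22, 33, 23, 13, 12) with engineering shear strains; fourth-order tensor
algebra (rotations, Eshelby operators) runs internally in the orthonormal
Mandel basis, where conjugation by an orthogonal operator preserves symmetry
and definiteness exactly. Units are mm, N, MPa in the FE chain; the
micromechanical models work in GPa and are converted at the mapping step.

## Synthetic vertebra phantoms

A vertebral body is an elliptical cylinder with flat superellipsoid caps
(`(x/a)² + (y/b)² + (z/c)⁸ ≤ 1`), half-axes (18, 14, 12.5) mm by default.
A cortical shell is the set of interior voxels within `cortical_thickness`
(default 1 mm; it thins to about one voxel where the surface is oblique) of
the boundary, assigned HU in 700–1400 with a depth ramp; the trabecular core
gets `HU = mode + spread·t + 0.6·spread·max(t,0)²`, where `t` is a
unit-variance oriented Gaussian texture, producing a unimodal histogram at
the mode (default 220 HU, spread 70 HU) with a high-HU tail, plus 5 HU white
measurement noise. Defaults mirror a clinical lumbar CT at
0.326×0.326×0.6 mm.

The texture is white noise filtered by an anisotropic Gaussian whose
correlation length is `sigma_perp` (0.35 mm, about one in-plane voxel,
comparable to trabecular separation at clinical resolution) transverse to
`texture_direction` and `sigma_par = sigma_perp/√(1−DA)` along it. For a
Gaussian random field the gradient-covariance eigenvalue along an axis
scales as 1/σ² of that axis, so the *target* degree of anisotropy DA enters
analytically; the generator is deterministic per seed. The two-vertebra
scene crops the axial air margins so the surface-to-surface disc gap equals
the requested value (9 mm default) and reports the gap planes and elliptical
footprint for cage fitting.

What the phantom does not emulate: scanner physics (PSF, beam hardening),
posterior elements beyond what the pipeline needs, real trabecular
plate/rod microarchitecture (the texture has Gaussian, not bimodal-phase,
statistics), and HU calibration drift.

## HU → porosity

Porosity uses two linear laws per tissue, anchored on the scan's own HU
statistics: the trabecular law passes through (HU_mode, 0.85) and
(HU_min, 0.92); the cortical law is zero at the dense-bone threshold and 0.5
at the lowest cortical HU, both clamped to their physical ranges. The
dense-bone threshold is the 0.98 quantile of a distribution fitted to the
full vertebral-body histogram (skew-normal by default; normal and gamma
available). Fit adequacy is judged by the Kolmogorov–Smirnov *statistic*
(cutoff 0.1) rather than its p-value, which rejects any parametric family at
CT sample sizes; an inadequate or non-convergent fit falls back to the
empirical quantile, flagged in the diagnostics. Calibration minima are taken
inside the labels after isotropic resampling, matching the pipeline order
(resample, then segment, then calibrate).

## Gradient structure tensor

Per voxel, the GST is the 7×7×7 boxcar average of the outer product of the
central-difference intensity gradient with itself, restricted to in-label
voxels and normalized by its trace; eigenvalues ascend, and the
minimum-gradient eigenvector e1 is taken as the stiffest material axis
(intensity varies least along trabeculae). Voxels whose window is more than
25% outside the current tissue, or whose tensor trace vanishes, are flagged
isotropic and carry no directions. DA = 1 − λ1/λ3; the Kelvin aspect ratio
is R = λ3/λ1 ≥ 1, capped at 10 (the λ1 → 0 degeneracy would otherwise send
tan θ → ∞). Reading R as λ3/λ1 rather than its reciprocal keeps R ≥ 1,
consistent with vertically elongated trabecular cells.

Two estimator properties matter for interpretation:

- **Per-voxel sampling bias.** A 7×7×7 window holds only ~30–150
  statistically independent texture samples, so per-voxel eigenvalues
  scatter strongly: even for a perfectly isotropic field the median
  per-voxel DA reads 0.2–0.5, and the per-voxel axis error at true DA = 0.3
  is tens of degrees. This is irreducible estimator noise, not a bug; the
  per-voxel axis becomes accurate (≤10° median) only for strongly oriented
  textures (DA ≈ 0.9). Region-level anisotropy therefore uses
  `pooled_fabric`: the tensor average over all unflagged label voxels, an
  unbiased estimator of the expected GST. Its noise floor scales with
  1/√(number of independent windows); a full-size body at 0.326 mm gives a
  pooled-DA floor of ~0.03–0.07 and recovers the texture axis to a few
  degrees at DA ≥ 0.3.
- **Anisotropic-acquisition artifact.** Resampling the 0.326×0.326×0.6 mm
  grid to isotropic voxels with cubic B-splines adds ~10% excess z-gradient
  power, which reads as a spurious pooled DA of up to ~0.1 with the z axis
  as λ3. Estimator-property checks therefore run on phantoms generated
  directly at the isotropic working resolution; the anisotropic path is
  exercised end-to-end in the fusion pipeline, where material assignment is
  robust to it.

## Cortical micromechanics

Cortical tissue is a Mori–Tanaka composite: an isotropic mineralized matrix
(E = 20 GPa, ν = 0.3 — 20 GPa is also the isotropic fallback stiffness
scale) containing aligned water-filled inclusions (bulk modulus 2.3 GPa,
zero shear). Oriented voxels use the interior Eshelby tensor of an infinite
circular cylinder (Haversian canals), giving transverse isotropy about the
canal axis, which is rotated onto the voxel's stiff axis; flagged voxels use
spherical inclusions, giving isotropy. Porosity above the calibrated
cortical maximum (0.5) is clamped. At φ = 0.05–0.15 the axial modulus falls
in the 15–19 GPa band with the transverse modulus below it. The scheme is
validated against the closed-form dilute limit, the scalar Mori–Tanaka
bulk/shear formulas for spheres, and the Voigt bound.

## Trabecular Kelvin-cell model

Trabecular bone is an open-cell foam of stretched Kelvin cells
(tetrakaidecahedra). Geometry: stretching the regular Kelvin network along
the rise axis by R makes the aspect ratio H/D = tan θ = R with oblique strut
length L and horizontal strut length b = √2 L cos θ — a one-parameter cell
shape that recovers the regular cell at θ = 45°. Struts have circular
sections (A = πr², I = πr⁴/4, J = πr⁴/2). The thin-strut relative density is

    1 − φ = π (r/L)² (√2 cos θ + 2) / (8 cos²θ sin θ),

reducing to the classic 3πr²/(2√2 L²) at R = 1; r/L is solved from the voxel
porosity and errors out above r/L = 0.5, where slender-beam theory stops
applying.

Elastic constants come from closed forms obtained by exact symbolic energy
minimization of the periodic 24-strut Euler-beam frame (rigid joints, one
Hermite element per strut — exact for end-loaded Euler beams). The
symmetry-reduced periodic corrections (≤5 scalars per strain case) were
solved with a computer-algebra system and the resulting expressions frozen
into `_kelvin_forms.py`; `scripts/derive_kelvin_forms.py` regenerates and
re-verifies them. The rise-direction modulus has the compact guided-strut
form given in the `kelvin` module docstring and reproduces the classic
Kelvin-foam result at θ = 45° exactly. The cell is tetragonal; the material
model exports the five transversely isotropic engineering constants
(E_axial, E_trans, ν_axial, ν_trans, G_axial), replacing the tetragonal C66
by the transverse-isotropy relation. An independent numerical beam-frame
homogenization (`beamframe`) cross-validates the closed forms to machine
precision across R ∈ [1, 3], φ ∈ [0.7, 0.92]; the modulus–density log–log
slope is 1.89, the bending-dominated ρ² regime.

The solid (tissue-level) strut modulus E₀ is not a measurable of the CT
pipeline; the default 13 GPa is a typical tissue-level value and puts the
axial modulus at R = 1.7, φ = 0.85 at ~305 MPa — inside the 400 ± 90 MPa
band reported for vertebral trabecular bone. The model's transverse modulus
(~70 MPa there, axial/transverse ≈ 4.4) is softer than patient-average
reports (~160 MPa, ratio ≈ 2.5): an idealized strut lattice lacks the
transverse plates and cross-struts of real trabecular architecture, so its
transverse anisotropy is stronger. Flagged-isotropic trabecular voxels use
the equiaxed cell (R = 1) — an extension of the cortical-only fallback rule,
applied for symmetry.

## Scaffold generation and homogenization

Devices are voxelized implicitly (solid where a voxel centre lies within the
strut radius of the strut skeleton) on a 0.15 mm grid and clipped to the
elliptical footprint. FCC cells use corner-to-face-centre struts; Kelvin
cells use the tetrakaidecahedron network; Voronoi struts are the ridge edges
of a seeded tessellation. The strut radius for a porosity target is solved
by bisection on the unit cell and refined by bisection on the measured
device porosity (rim-clipped cells shift it); the lattice carries a fixed
generic phase offset relative to the device so lattice planes do not align
degenerately with voxel-centre planes, which would quantize the porosity.
The graded Voronoi device grades the seed density radially with a power-law
profile (exponent 2.5) between endpoint densities calibrated by fixed-point
iteration on the innermost/outermost radial porosity bins; the
λ^(2/3) scaling of Poisson–Voronoi edge length density drives the update. A
steep profile is needed because ridges of the denser rim invade a sparse
core. Incomplete cells at the rim are not corrected (their effect is what
the device-porosity refinement absorbs). The Ti ring comparator is the
footprint minus an offset ellipse (3.8 mm wall).

Unit-cell homogenization is first-order periodic voxel FE: partial-volume
(4× supersampled) densities, 8-node hexahedra with Wilson incompatible
bending modes statically condensed (plain trilinear hexes lock and
overstiffen strut lattices — verified on a voxel cantilever: 99.4% vs 87.6%
of the Euler deflection), node indices wrapped modulo the grid, six unit
macroscopic strains, mutual-energy assembly. The solver is sparse Cholesky
via SuperLU below 60k DOF and Jacobi-preconditioned CG above. The
implementation is exact on a solid/void laminate and a full-solid cell.
Default grid 64³; the result still drifts down by a few percent per
refinement octave at 75% porosity (strut diameter ≈ 12 voxels).

**Published device moduli.** At φ = 0.75, E₀ = 100 GPa the voxel FE gives
E ≈ 7.6 GPa (Kelvin) and 6.2 GPa (FCC); Euler beam-frame homogenization of
the same lattices gives 3.06 and 3.19 GPa. Values reported in the literature
for these cage designs (4.88 and 5.10 GPa, FCC > Kelvin) sit between the
two, are each ≈1.6× the beam values, and match the beam FCC/Kelvin *ratio*
(1.041 vs 1.045) — consistent with a beam-type homogenizer with a uniform
junction-stiffening correction rather than solid FE of the meshed geometry.
Solid FE exceeds beam theory here because at r/L ≈ 0.27 the short Kelvin
struts are junction-dominated (the excess persists, ×1.55, even at φ = 0.95
where struts are slender). Both routes are reported; neither is tuned toward
the published numbers.

The macroscopic strength of the porous ceramic is σ = 1.21 (1−φ)³ σ₀ with
σ₀ = 100 MPa (tension) and 350 MPa (compression) for dense HAp, giving
1.89 / 6.62 MPa at 75% porosity.

## Meshing, FE solver and load cases

Meshing is structured: labelled voxels (optionally resampled to a target
edge length) split into six Freudenthal tetrahedra with globally consistent
orientation, so meshes are conforming and parts built on one grid are tied
by shared nodes — the usual bonded-contact idealization. Element
volumes equal voxel volumes exactly; a shape-quality summary is reported.

The solver assembles constant-strain tetrahedra into a sparse symmetric
system; supports are full clamps, and loads enter through a rigid kinematic
coupling: the coupled node set moves with a 6-DOF reference point carrying
force and moment, implemented by a sparse reduction transform. Direct
factorization is used below 150k DOF, CG above; singular factorizations
(unconstrained modes) are detected by residual check. Benchmarks: exact
single-element patch test, tip-loaded cantilever within 10% of
Euler–Bernoulli at 8 elements per thickness, equilibrium residual < 1e-9,
and dense-assembly equivalence on small meshes.

Load cases: standing = 500 N axial; flexion = 1175 N axial + 7.5 N·m about
the left–right axis (anterior-down). Some published protocols print this
moment as 7.5 N·mm, which is mechanically negligible and inconsistent with
the usual lumbar loading standards; N·m is the default and the N·mm variant
is one argument away (`moment_Nm=0.0075`).

The fusion scene places the cage by filling each (x, y) column of the disc
gap between the actual endplate surfaces (snug fit), inserts four 5 mm
pedicle screws and two posterior 5 mm rods (Ti6Al4V, E = 113.8 GPa,
ν = 0.342, σ_Y = 795 MPa), pads the grid posteriorly so the rods fit, fixes
the inferior slab, and couples the superior slab to the reference point.
Bone elements get their material by nearest-voxel mapping (centroid
distance, ties to the lowest linear voxel index) with the micromechanical
stiffness computed on a quantized (porosity, R) grid and rotated into each
voxel's fabric frame.

Damage metrics are volume-weighted: failed scaffold volume compares maximum
(minimum) principal stresses to the tensile (compressive) thresholds —
dense-HAp values for strut-resolved devices, the strength-law values for
homogenized ones, union reported alongside the single modes; damaged
trabecular volume counts |min principal strain| > 0.84%; fixation metrics
report σ_Y over the peak von Mises stress in the central half of each rod,
axial microstrains, and the load share as the axial force through a mid-rod
planar band divided by the applied force; system stiffness and rotation come
from the reference-point response.

## Problem sizes and determinism

Default problem sizes: phantom bodies 20–36 mm across at 0.326 mm; GST
property checks on a (16, 12, 11) mm half-axis body (~236k trabecular
voxels); unit-cell homogenization at 64³; device generation at 0.15 mm over
the 27×32×9 mm footprint (~1.8M envelope voxels); fusion scenes meshed at
1.8 mm (~22k elements), with the scaffold homogenized at 24³–32³. Every
stochastic component (phantom noise and texture, Voronoi seeds) is driven by
an explicit integer seed and is bit-reproducible.

## Known limitations

- Linear kinematics and elasticity only; no contact (tied interfaces only),
  no screw threads, no fatigue or post-failure redistribution.
- The trabecular model is a strut-only foam: transverse moduli are
  underestimated relative to plate-rich real architecture.
- Constant-strain tetrahedra are stiff in bending; comparative metrics are
  mesh-consistent, absolute stiffnesses carry discretization bias at the
  coarse scene resolution.
- Voxel homogenization converges from above; reported unit-cell moduli at
  64³ retain a few percent of discretization overstiffness.
- Phantom realism bounds what green tests prove: they establish the
  pipeline's correctness and parameter recovery on fields with known ground
  truth, not fidelity to any particular patient's anatomy.
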