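# Methods

## Overview

`ctistim` models the brain's response to transcranial direct current
stimulation when the conductivity of brain tissue is described by a
per-voxel tensor reconstructed from conductivity-tensor-imaging (CTI)
inputs, and compares it against the conventional isotropic
literature-value model. The pipeline has four stages: synthetic phantom
generation, conductivity tensor reconstruction, finite-element forward
solution, and response quantification.

## Conductivity tensor reconstruction

The cross-property relation

    C = (1 − v_int) σ_H / (v_int β λ + (1 − v_int) λ̄_ext) · D_eʷ = η D_eʷ

assumes that below ~10 kHz cell membranes block current, so conduction is
confined to the extracellular space and shares the directional structure of
extracellular water diffusion (D_eʷ), while the high-frequency conductivity
σ_H (at the Larmor frequency) senses both spaces. η rescales the diffusion
tensor into conductivity units.

Unit convention: diffusivities in mm²/s, conductivities in S/m. η is
stored as the plain quotient of the maps in these units, so η·D_eʷ is in
S/m with no further factor. The worked example σ_H = 0.5 S/m, v_int = 0.4,
β = 0.41, λ = 2.0e-3, λ̄_ext = 1.5e-3 mm²/s gives η = 0.3/1.228e-3 =
244.2997, and with D_eʷ eigenvalues (2.7, 0.9, 0.9)e-3 mm²/s the
conductivity eigenvalues (0.660, 0.220, 0.220) S/m.

Interpretation choices, made once and fixed:

- **β** is treated as a global scalar with default 0.41 (a typical
  intracellular/extracellular ion-concentration ratio); it is exposed in
  the configuration because the reconstruction is linearly sensitive to it.
- **λ** is interpreted as the intracellular (stick) diffusivity of the
  two-compartment signal model.
- **λ̄_ext** is defined as tr(D_eʷ)/3.

### Two-compartment DWI fit

Per voxel the signal model is stick-plus-tensor:

    S(b, g)/S0 = v_int exp(−b λ (g·f)²) + (1 − v_int) exp(−b gᵀ D_eʷ g)

with f the fiber direction. The estimator is deliberately simple and fully
vectorized:

1. orientation f from a log-linear tensor fit of the inner shell
   (b = 800 s/mm²);
2. (v_int, λ) from the per-shell spherical means, using the spherical mean
   of the stick (√(π/4x)·erf(√x)) and a tortuosity closure for the
   extracellular compartment — a damped Newton iteration on the 2×2
   system, clipped to v ∈ [0, 1) and diffusivities ∈ (1e-5, 4e-3) mm²/s;
3. extracellular axial/radial diffusivities (l, t) from a log-linear fit of
   the stick-corrected signals;
4. a joint Gauss–Newton refinement of (v_int, λ, l, t) with fixed
   orientation (20 iterations, Levenberg damping 1e-10, box projection).

Degenerate inputs: all-zero voxels are masked out rather than raising;
voxels whose final RMS misfit exceeds 0.2 (far above the ~0.05 expected
from Rician noise at SNR 20) are flagged non-convergent in the validity
mask and fall back to literature values in the hybrid conductivity
assignment. In isotropic voxels (CSF) the orientation is arbitrary, which
is harmless because l ≈ t there.

On noiseless phantom data the fit recovers v_int within 5e-5, the fiber
direction within 0.03°, and the conductivity tensor within 0.05% Frobenius
error (the acceptance thresholds of 0.05 / 5° / 5% leave wide margins).

## Synthetic phantom

The generator emulates a segmented head as concentric spherical shells
(scalp 6, skull 6, CSF 3, GM 4 mm around a WM core; default outer radius
80 mm, 2 mm isotropic voxels, ≈271k head voxels). Tissue microstructure is
piecewise constant:

| tissue | σ_H (S/m) | v_int | λ (mm²/s) | λ̄_ext (mm²/s) | aniso ratio |
|--------|----------|-------|-----------|----------------|-------------|
| WM     | 0.35     | 0.60  | 2.0e-3    | 0.9e-3         | 3           |
| GM     | 0.60     | 0.55  | 2.0e-3    | 1.0e-3         | 1           |
| CSF    | 2.00     | 0.00  | 3.0e-3    | 3.0e-3         | 1           |

These are plausible in-vivo magnitudes chosen so the *mean* low-frequency
conductivities land near the literature values used by the isotropic
comparator (WM ≈ 0.15 vs 0.14, GM ≈ 0.30 vs 0.27, CSF 2.0 vs 1.79 S/m):
the two models are then comparable but not identical. The WM anisotropy
ratio 3 corresponds to moderate coherent-fiber anisotropy (FA ≈ 0.6); it is
a declared phantom parameter, not an estimate of any particular brain.
Fiber fields are coherent (`radial`, mimicking corona-radiata-like
radiation; `tangential`, azimuthal circles mimicking commissural fibers; or
`uniform-x`). A midline WM block (|x| ≤ 6 mm, |y| ≤ 25 mm, 0 ≤ z ≤ 25 mm)
is tagged as a corpus-callosum-analog ROI.

DWI is simulated with the same stick-plus-tensor model on a two-shell
scheme (b = 800 s/mm² × 30 directions, b = 2,200 s/mm² × 64 directions,
one b = 0; deterministic spherical-Fibonacci directions). Optional Rician
noise uses two seeded Gaussian channels (magnitude-MRI convention); the
default study is noiseless so that reconstruction error isolates estimator
bias from noise.

What the phantom does *not* emulate: cortical folding, tissue
heterogeneity and partial-volume mixing, crossing fibers, susceptibility or
eddy artifacts, and a realistic skull shape. Passing tests therefore show
the pipeline's internal consistency (round trips, conservation laws,
montage physics on a sphere), not in-vivo accuracy; in particular the
relative differences between models (~6–26% by ROI) are smaller than on
real heads, where anatomy and microstructure vary within tissue.

Electrodes: square sponge pads (50 × 50 mm, 3 mm saline sponge at 1.0 S/m,
2 mm conductor plate) are centered on 10-20 positions and projected onto
the scalp sphere. The encoded angle table (inclination from vertex,
azimuth from anterior, degrees): C3/C4 (36, ∓90), Fz/Pz (36, 0/180),
F3/F4 (50, ∓40), FP1/FP2 (72, ∓18), T7/T8 (72, ∓90), O1/O2 (72, ∓162) —
standard 10-20 arc fractions on a sphere. The pad footprint (radially
projected staircase envelope) reproduces the nominal 2,500 mm² within 10%
at 2 mm voxels, so 2 mA yields the nominal average pad current density of
0.8 A/m².

## Finite-element solver

Every non-air voxel is split into six tetrahedra by the same Kuhn
decomposition (conforming across voxels, all volumes positive). Because
the grid is regular, the per-voxel 8×8 stiffness block is a fixed linear
combination of six precomputed matrices contracted with the voxel's
conductivity tensor; assembly is one einsum plus a COO→CSR conversion.
This is algebraically identical to element-by-element P1 assembly (tested
against a hand-assembled reference).

Boundary conditions: uniform Neumann influx I/area over the anode's
exposed faces; the cathode is the voltage reference. A pure-Neumann mode
(influx/efflux on both electrodes, zero-mean solution) exists for
reciprocity checks.

**Electrode model.** The metal plate (literature value 5.99e7 S/m) is
treated as a perfect conductor: each patch's nodes are condensed into one
equipotential super-node and its elements leave the stiffness. The plate's
internal resistance is ~1e-10 of the head's, so this is physically
indistinguishable from meshing the metal, while removing a ~6e9
conductivity contrast from the system — with the metal meshed as ordinary
elements, the attainable true-residual floor of conjugate gradients in
double precision is ~2e-5, above the solver's 1e-6 target; with
condensation the target is met in ~500 iterations on the default phantom.
The ordinary-element formulation remains available
(`condense_electrodes=False`) and agrees with the condensed model to
<0.5% in brain current density at its attainable tolerance. The sponge
remains an ordinary element at 1.00 S/m; no contact impedance is modelled.

The solve is Jacobi-preconditioned CG with restarts until the *recomputed*
residual ‖f − Ku‖/‖f‖ meets the tolerance (default 1e-6), because the
recursive CG residual drifts on high-contrast systems. Identical inputs
give bit-identical solutions. E = −∇u and J = −C∇u are P1-exact per
tetrahedron and stored as the volume average over each voxel's six tets
(conductivity is voxel-constant, so J = C·E holds exactly per voxel).

## Response quantification

- ROI statistics: arithmetic mean ± **population** standard deviation
  (ddof = 0; a documented convention) of |E| and |J| over GM, WM, entire
  brain (GM ∪ WM by default; flag to include CSF) and the CC-analog block.
- Relative difference rD uses the absolute difference of per-voxel
  *magnitudes* in the numerator (the reading consistent with defining
  J_CTI, J_ISO as magnitudes); the vector-difference variant is available
  via `vector_difference=` for sensitivity analysis.
- Slice analyses: S1 is the coronal plane through the anode center; S2/S3
  are axial planes 25/75 mm below the inner skull of a reference adult
  head (intracranial radius 75 mm), scaled by the phantom's intracranial
  radius — S3 therefore always samples the deep center and S2 an
  upper-cortex plane, for any phantom size.
- Streamlines: fixed-step RK4 on the normalized, trilinearly interpolated
  J field; termination on leaving the head, on |J| < 1e-6 A/m², or after
  the step cap. Out-of-grid interpolation evaluates to zero so lines
  cannot slide along the volume border.

On the default phantom the trans-hemispheric C3-FP2 montage delivers ~1.5×
the deep-slice current density of the frontal F4-F3 pair, whose current
stays superficial (deep mean < shallow mean), and the CC-analog carries
~1.5× more current under the tensor model than under the isotropic model —
the qualitative montage and anisotropy effects the pipeline is built to
expose.

## Problem sizes

The default study (80 mm / 2 mm phantom, ≈271k head voxels, ≈287k nodes,
1.6M tetrahedra; 95-volume DWI) runs in about two minutes end to end. The
test suite uses a 40 mm / 2.5 mm phantom for unit-level round trips and the
default scale for the acceptance battery; the oracle boxes are 10–24
voxels per edge. These sizes were chosen so the whole verification cycle
stays interactive on a laptop while keeping every mesh fine enough for the
1–2% oracle tolerances.

## Known limitations

- Voxel (staircase) meshes: no surface smoothing; field values in the
  1–2 voxel layer at tissue interfaces carry staircase error, and electrode
  patch areas are only accurate to ~10% at 2 mm voxels.
- The two-compartment fit assumes a single coherent fiber per voxel; in
  crossing-fiber geometry the orientation estimate degrades (not exercised
  by the phantom).
- The boundary condition under the pad is a uniform influx; real electrode
  current profiles peak at pad edges.
- rD magnitudes on the phantom are not comparable to in-vivo reports,
  since piecewise-constant microstructure understates intra-tissue
  variability.
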