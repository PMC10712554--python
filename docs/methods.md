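# Methods

This note records the models behind `rotaxle`, the parameter choices that
matter, what the built-in toy systems do and do not emulate, and the
numerical conventions. Nothing here states a result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Geometry: parametric components

Backbones are CA-only. A helical fragment follows the Crick coiled-coil
curve: a minor helix of radius R₁ (default 2.26 Å) and twist ω₁ (default
100°/residue, the 18/5 α-helix) wound on a major helix of radius R₀, twist
ω₀ and rise d per residue (default 1.51 Å), with the minor-helix plane
tilted by the supercoil pitch angle α = atan2(R₀ω₀, d). Phases Δφ₀ and Δφ₁
are reduced modulo 360° before use, so adding a full turn reproduces
bitwise-identical coordinates. With R₀ = ω₀ = 0 the curve degenerates to an
ideal straight α-helix on the z axis, for which the consecutive CA–CA
distance has the closed form √(d² + (2R₁ sin(ω₁/2))²) ≈ 3.78 Å.

Two facts about chord lengths are worth keeping apart. The generator itself
is a faithful coiled coil: for a canonical left-handed supercoil
(R₀ = 4.9 Å, ω₀ = −3.6°/res, ω₁ = 102.857°/res) the CA–CA distance is
constant to 0.014 Å, as it should be. The *straight-helix closed form*,
however, is only the ω₀ = 0 limit: the exact chord departs from it linearly
in the supercoil motion per residue, reaching ~0.1–0.15 Å at
|ω₀| = 5°/res for R₀ ≈ 5 Å, for either supercoil handedness. The test
suite therefore asserts the 0.05 Å envelope on its measured validity region
(|ω₀| ≤ 2°/res at R₀ = 5 Å) and asserts chord *constancy*, a stronger
property, for the canonical coiled coil.

`invert_z` builds the antiparallel partner of a fragment as a proper 180°
rotation about the x axis ((x, y, z) → (x, −y, −z)). This is the same
convention as the dihedral flip (below), genuinely inverts the chain
direction, and preserves helix handedness; a reflection-based construction
would not.

## Symmetry

Cn is realized as rotations about z by 360k/n; Dn adds each of those
composed with a 180° rotation about x (the 2-fold axis is fixed along x — a
pure convention). Operators are proper rotations, numerically orthogonal to
1e−12, and closed under composition (verified for all n ≤ 12). Symmetric
expansion assigns chain identifiers deterministically: fragment order, then
operator order, ids A–Z a–z 0–9; expansions needing more than 62 chains are
rejected (PDB chain-id space). Components whose chains approach below 2 Å
CA–CA raise a clash error naming the worst pair.

The landscape periodicity rule: any pairwise-additive interface energy
between an axle of rotational order n and a rotor of order m about the same
axis is periodic in their relative rotation with period 360°/lcm(n, m).
For a Dn axle the effective rotational order about z is n — the flipped
copies are geometry, not additional rotational symmetry. A component may
carry an `internal_order` metadata label (e.g. a rotor built from a
higher-symmetry repeat protein), but it is reporting-only and never enters
the periodicity rule.

Rigid poses use a fixed convention: extrinsic rotations about the fixed
axes applied z, then y, then x (R = Rx·Ry·Rz), followed by the translation.

## Interface energy model

The score is a stand-in with transparent physics, not a calibrated force
field; its energies are kcal/mol *of this model*:

E(r) = min(cap, 4ε((σ/r)¹² − (σ/r)⁶)) + C q₁q₂ e^(−r/λ_D) / (ε_r r)

per CA pair, truncated at `cutoff` and shifted per term so E(cutoff) = 0
(landscapes on a grid stay continuous; the derivative still jumps at the
cutoff, which matters for fixture design, below). Defaults, all
config-overridable: ε = 0.2 kcal/mol, σ = 5.0 Å (effective CA diameter),
cap = 50 kcal/mol per pair (keeps clashed poses finite so scans are total
on their grid), C = 332.06 kcal·Å/(mol·e²), ε_r = 80, λ_D = 10 Å (~100 mM
ionic strength), cutoff 12 Å, contact cutoff 8 Å, clash cutoff 3.5 Å.
Distances below 0.5 Å are clamped to 0.5 Å for evaluation — a numerical
floor that only pathological poses reach.

Charges sit on CA positions. Asp/Glu are −1 e and Lys/Arg +1 e independent
of pH (their pKas sit far outside the 5–8 working range); only histidine
titrates, with the Henderson–Hasselbalch fraction +1/(1+10^(pH−pKa)),
default pKa 6.0. Complementary-surface assignment mirrors the design rule
for electrostatically driven axle–rotor interfaces: interface residues
(those in the closest `interface_fraction` — default 0.30 — of a
component's radial range, outward-facing for the axle, inward-facing for
the rotor) become Glu on the axle and Lys on the rotor, so the axle never
carries positive and the rotor never carries negative charge. The selection
mask is computed once per fragment and replicated across symmetry copies,
making the assignment exactly symmetric.

Interface energy sums pairs across components (axle×rotor, rotor×rotor for
multi-rotor machines); a KD-tree neighbor-list path is available and agrees
with the all-pairs sum to 1e−9 kcal/mol.

## Landscapes and features

1D scans rotate one rotor about the machine axis on a uniform grid
(0.25° for headline counts, 1° otherwise); 2D scans add translation along z
(±10 Å, 0.5 Å steps by default). Local minima are detected circularly:
grid points chained within `merge_tol` (1e−9 kcal/mol) form plateau runs; a
run is a minimum iff strictly below both neighboring runs, and is reported
at its centroid. A flat landscape has zero minima by convention. Principal
minima lie within `principal_fraction` (0.10) of the dynamic range above
the global minimum. The Fourier spectrum is the DFT of the mean-subtracted
energy; the dominant mode is the largest-amplitude integer harmonic k ≥ 1,
ties broken toward smaller k.

DOF classification scans each of the six rigid-body DOFs separately
(rotations over the full turn in 5° steps, pivoting at the rotor centroid
for x/y tilts; translations over ±10 Å in 0.5 Å steps) and calls a DOF
accessible iff the energy stays within `access_factor`·kT (3 × 0.593
kcal/mol) of that scan's minimum over at least half the rotational range or
a fifth of the translational range.

## Brownian dynamics

Rotor motion on a scanned landscape is overdamped Langevin by
Euler–Maruyama: θ' = θ − (D/kT)E′(θ)dt + √(2D dt)ξ, with E′ from a
periodic cubic spline of the landscape, tabulated on a 4× refined grid and
linearly interpolated inside the integration loop. Time is in reduced
units (all-atom timescales are not transferable to a 1-DOF model); defaults
D = 100 deg²/unit, dt = 1e−3, kT = 0.593 kcal/mol. A stability guard
rejects parameter sets whose deterministic drift exceeds 5° per step.
Trajectories are bit-reproducible from (seed, params, landscape); the
recorded series is unwrapped, with wrapping on demand. Multi-DOF motion is
modelled as independent 1-DOF simulations per accessible DOF; DOF coupling
is out of scope.

Equilibrium statistics computed on trajectories: time-and-ensemble averaged
MSD (linear with slope 2D for free diffusion); well occupancy (samples
within half the minimum well spacing of the nearest minimum, first 10%
discarded as burn-in); and comparison against the discrete Boltzmann
distribution on the landscape grid. Two statistical points: (i) successive
trajectory samples are strongly correlated, so occupancy equality of
degenerate wells is judged against a σ built from the number of *core*
well-to-well transitions (hysteresis labelling — a sample changes wells
only inside a ±45° core — so boundary recrossings do not inflate the
count); (ii) the ideal two-state ratio exp(−ΔE/kT) ignores basin-shape
prefactors, which shift the true basin ratio by ~10% even for
curvature-matched wells, so the sampler is validated against the exact
discrete Boltzmann basin ratio (direct summation of e^(−E/kT) over each
basin's grid points).

`boltzmann_ensemble` draws i.i.d. grid samples by inverse CDF on the
discrete weights, stable down to the kT → 0 limit.

## Projections

Simulated 2D views project CAs orthographically along x, y or z and splat a
unit-integral Gaussian (width `blur_sigma` ≥ pixel size, truncated at 4σ,
losing < 0.04% of mass) per atom, averaging over an ensemble of poses or
rot_z samples. Each per-pose image integrates to the atom count, and so
does the average. Averaging over a Boltzmann ensemble on a flat landscape
is the package's analogue of conformational variability in experimental
class averages: it suppresses azimuthal structure (the rotor-arm
signature) by more than an order of magnitude in ring variance while
leaving radial structure intact.

## The toy systems

The fixtures module defines the study systems; their geometry was chosen
once, from the energy model's length scales, and is part of the package's
experimental design.

**Point-feature rings** (axle ring of −1 e features, rotor ring of +1 e):
ring gap 7 Å keeps every populated separation beyond the LJ minimum at
2^(1/6)σ ≈ 5.6 Å, so each aligned feature pair is a single monotone
attractive well; ring radii 140/147 Å make that well angularly narrow (the
12 Å cutoff subtends ±3.9°), so wells of neighbouring symmetry sectors
never overlap — without this, the derivative kink at the shifted cutoff
can imprint a secondary ripple per sector when wells overlap. Under these
conditions a Cn×Cm scan carries exactly one well per lcm(n, m) sector:
15 for C5×C3, 8 spaced 45° for D8–C4 (two C4 rotors on the two D8 ring
planes, 30 Å apart — beyond the cutoff, so each rotor sees a clean 8-fold
interface), 3 for C3×C3. These model the *symmetry content* of an
interface and nothing else: no backbone, no sequence, no packing.

**Helical toys**: a D3 axle of two 36-residue straight fragments per
asymmetric unit (twelve columns 30° apart at R₀ = 14 Å — azimuthally
smooth on the Debye scale, so the charged surface does not corrugate the
rotational landscape), with complementary charges from the assignment rule.
The tight partner is a C3 ring with a 41 Å bore (~4 Å radial clearance):
lateral translation and tilt are sterically blocked while rotation and
sliding along z stay thermally open. The loose partner is a C5 ring with a
66 Å bore (the wall sits beyond the interaction cutoff at the centred
pose) and a sparse charge set (interface fraction 0.05), paired with a
weak-dispersion model (ε = 0.02 kcal/mol, core unchanged) because a
loose-packing, electrostatics-dominated interface should not have sticky
CA-grain contacts; all six DOFs then stay within a few kT of the minimum
over wide ranges. These toys emulate the *regimes* — tight symmetric
cogwheel versus loose electrostatic sleeve — not any particular designed
sequence or its Rosetta energetics.

What passing tests on these toys shows: that the symmetry-forced landscape
structure (well counts, spacings, Fourier content, accessibility classes)
follows from component symmetry plus a generic smooth interaction, and that
the dynamics layer samples such landscapes correctly. What it does not
show: anything about real sequence-level energetics, barrier heights,
absolute timescales, or the design-specific "lesser" wells that sculpted
side chains add on top of the symmetry-forced pattern.

## Problem sizes

Headline scans use a 0.25° grid (1440 poses) on point models of ≤ 24
features — well under a second each. Brownian validation runs use 10⁶
steps (single trajectory) or 200 replicas × 2×10⁴ steps; the full test
suite completes in well under a minute on one CPU.

## Known limitations

- CA-only geometry: no rotamers, no loop closure, no full-atom clashes.
- The energy model is not Rosetta and makes no claim of REU equivalence;
  dynamic ranges are not comparable to published design energies.
- Landscape scans are single deterministic evaluations of a rigid model;
  there is no per-pose relaxation, so well depths are upper bounds on
  ruggedness only in the rigid limit.
- Brownian time is in reduced units; rates and barrier-crossing times are
  not physical predictions.
- The 2-fold axis convention (x) and pose-composition order are fixed
  conventions; structures from other tools may need re-orientation.
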