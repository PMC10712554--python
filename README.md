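# rotaxle

Desk-scale modelling of designed **axle–rotor protein machines**: two-component
assemblies in which a ring-shaped rotor is threaded onto a high-aspect-ratio
symmetric axle and diffuses along designed rigid-body degrees of freedom.

The package is for protein designers and modellers who want to reason about
the *symmetry-forced structure* of such machines without running an all-atom
design pipeline: how the rotational interface energy landscape is shaped by
the components' cyclic (Cn) or dihedral (Dn) symmetries, which rigid-body
DOFs remain thermally accessible, and what equilibrium (Brownian) motion on
that landscape looks like.

## What it computes

- **Parametric components.** CA-level helical backbones from the Crick
  coiled-coil parameterization (supercoil radius R₀, twist ω₀, phase Δφ₀;
  minor-helix radius R₁, twist ω₁, phase Δφ₁; rise d; z-offset), expanded by
  Cn/Dn point groups into axles, rotor rings, and analytic point-feature
  models.
- **Interface score.** A capped 12-6 steric term plus Debye-screened
  electrostatics on CA centers,

  E(r) = min(cap, 4ε((σ/r)¹² − (σ/r)⁶)) + C·q₁q₂·e^(−r/λ_D)/(ε_r·r),

  truncated and shifted at a cutoff, with the design charge rule (no Lys/Arg
  on the axle, no Asp/Glu on the rotor) and Henderson–Hasselbalch histidine
  titration for pH-controlled assembly.
- **Landscapes.** 1D rotational and 2D rotation×translation scans; circular
  local-minima detection with plateau merging; dynamic range; discrete
  Fourier periodicity.  For an axle of rotational order n and a rotor of
  order m the landscape is periodic with 360°/lcm(n, m) — a quasisymmetric
  interface (e.g. C5–C3) therefore carries lcm(5, 3) = 15 wells per turn,
  a D8–C4 interface 8 wells spaced 45°, a matched C3–C3 interface 3.
- **Dynamics.** Overdamped Langevin (Euler–Maruyama) diffusion of the rotor
  coordinate on a scanned landscape, MSD analysis, well occupancy versus
  Boltzmann expectation, i.i.d. Boltzmann ensembles, and ensemble-averaged
  2D projections (simulated class averages with conformational variability).

## Worked example

```
$ rotaxle demo c5c3 --out demo_out --step 0.25
c5c3: 15 minima, 15 principal, spacing 24.00 deg, dominant mode 15
```

The demo builds a C5 point-feature axle (ring of −1 charges) and a C3 rotor
(+1 charges), scans the interface energy over a full rotation at 0.25°, and
reports: **15 minima** — one well per 360°/lcm(5, 3) = 24° symmetry sector —
all within 10% of the dynamic range of the global minimum (principal), with
the Fourier spectrum dominated by harmonic 15.  The landscape itself is
written to `demo_out/c5c3.landscape.tsv` and the features to
`demo_out/c5c3.features.json`.

The helical demos additionally classify the accessible DOFs:

```
$ rotaxle demo d3c5 --out demo_out --step 1.0
d3c5: 0 minima, 0 principal, spacing nan deg, dominant mode 1, accessible \
DOFs: ['rot_x', 'rot_y', 'rot_z', 'trans_x', 'trans_y', 'trans_z']
```

The loose-fitting D3–C5 toy (wide bore, sparse charges) leaves all six
rigid-body DOFs thermally open and its rotational landscape flat (zero wells
by convention); the tight D3–C3 toy (`rotaxle demo d3c3`) is restricted to
rotation and translation along the machine axis.

Other subcommands: `generate` (TOML → CA-only PDB), `assemble`, `scan`,
`analyze`, `simulate` (Brownian trajectory + occupancy), `render`
(ensemble-averaged projection as PGM).

## Layout

```
src/rotaxle/
  components.py   Crick backbones, toy axles/rotors, point-feature models
  symmetry.py     Cn/Dn operators, symmetric expansion, poses, assemblies
  energetics.py   charge rules, pair potential, interface scoring
  landscape.py    1D/2D scans, minima, spectra, DOF classification
  dynamics.py     Brownian simulation, MSD, occupancy, projections
  fixtures.py     the toy systems used in tests, demos and acceptance runs
  io.py           PDB / TSV / PGM / TOML, run configuration
  cli.py          the `rotaxle` command
docs/methods.md   model assumptions, parameter choices, limitations
```
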