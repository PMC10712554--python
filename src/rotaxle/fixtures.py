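"""Toy axle-rotor systems used by the test suite, demos and acceptance runs.

Two families:

* **Point-feature models** — analytic stands-in for interface "features":
  rings of unit charges about z.  Their geometry is chosen once from the
  energy model's length scales: a ring gap of 7 A keeps every populated
  separation beyond the LJ minimum at 2^(1/6) sigma = 5.6 A, so the pair
  potential is monotone in distance and each aligned feature pair is a
  single attractive well; ring radii of 140/147 A make that well angularly
  narrow (the 12 A interaction cutoff subtends +/- 3.9 deg), so the wells of
  neighbouring symmetry sectors never overlap.  Under these conditions the
  rotational landscape of a Cn axle x Cm rotor carries exactly one energy
  well per lcm(n, m) sector, which is the structure the scans probe.

* **Helical toys** — Crick-generated Cn/Dn components: a D3 axle of six
  interdigitated 36-residue helices, and C3 (tight) / C5 (loose) rotor
  rings, with complementary charges on the facing surfaces.  These emulate
  the loose electrostatic (D3-C3 / D3-C5) design regime.
"""
from __future__ import annotations

import numpy as np

from ._geometry import Chain, Residue
from .components import CrickParams, build_point_feature_model, build_toy_axle, build_toy_rotor
from .energetics import EnergyModel, assign_complementary_charges
from .symmetry import (AxleRotorAssembly, Component, RigidPose, SymmetryGroup,
                       apply_symmetry, compose_assembly)

__all__ = [
    "AXLE_RING_RADIUS",
    "ROTOR_RING_RADIUS",
    "point_pair_assembly",
    "c5c3_assembly",
    "c3c3_assembly",
    "d8_point_axle",
    "d8c4_assembly",
    "d3_axle",
    "c3_rotor",
    "c5_rotor",
    "d3c3_assembly",
    "d3c5_assembly",
    "demo_assembly",
    "demo_model",
]

#: default ring radii (A) for point-feature scans; gap = 7 A (see module doc)
AXLE_RING_RADIUS = 140.0
ROTOR_RING_RADIUS = 147.0

#: half-height (A) of the D8 point axle rings; 2h = 30 A keeps the two
#: rotors and the two axle rings mutually beyond the 12 A cutoff
D8_RING_HALF_HEIGHT = 15.0


def point_pair_assembly(axle_order: int, rotor_order: int,
                        axle_radius: float = AXLE_RING_RADIUS,
                        rotor_radius: float = ROTOR_RING_RADIUS,
                        label: str = "") -> AxleRotorAssembly:
    """Cn point axle (charge -1) threaded by a Cm point rotor (charge +1)."""
    axle = build_point_feature_model(axle_order, axle_radius, charge=-1.0, role="axle")
    rotor = build_point_feature_model(rotor_order, rotor_radius, charge=+1.0, role="rotor")
    return compose_assembly(axle, [(rotor, RigidPose())],
                            label=label or f"C{axle_order}-C{rotor_order}")


def c5c3_assembly() -> AxleRotorAssembly:
    """Quasisymmetric C5 axle x C3 rotor: 15 wells per revolution."""
    return point_pair_assembly(5, 3, label="c5c3")


def c3c3_assembly() -> AxleRotorAssembly:
    """Symmetry-matched C3 axle x C3 rotor: 3 principal wells."""
    return point_pair_assembly(3, 3, label="c3c3")


def d8_point_axle(radius: float = AXLE_RING_RADIUS,
                  half_height: float = D8_RING_HALF_HEIGHT) -> Component:
    """D8 point axle: 16 chains in two 8-fold rings at z = +/- half_height."""
    unit = Chain("A", [Residue(1, "X", np.array([radius, 0.0, half_height]), -1.0)])
    comp = apply_symmetry(unit, SymmetryGroup("D", 8), role="axle", check_clash=False)
    comp.metadata["kind"] = "point_feature_model"
    return comp


def d8c4_assembly() -> AxleRotorAssembly:
    """D8 axle with two C4 rotors, one per ring plane (the D8-C4 machine).

    Each rotor sees an 8-fold ring in its own plane; the rotors sit 30 A
    apart along z, beyond the interaction cutoff, so each rotor's landscape
    is the pure quasisymmetric lcm(8, 4) = 8-well pattern spaced 45 deg.
    """
    axle = d8_point_axle()
    rotor = build_point_feature_model(4, ROTOR_RING_RADIUS, charge=+1.0, role="rotor")
    top = RigidPose(trans_z=+D8_RING_HALF_HEIGHT)
    bottom = RigidPose(trans_z=-D8_RING_HALF_HEIGHT)
    return compose_assembly(axle, [(rotor, top), (rotor, bottom)], label="d8c4")


# --- helical toys -----------------------------------------------------------

#: two straight 36-residue fragments per asymmetric unit; D3 expansion gives
#: twelve interdigitated columns 30 deg apart at supercoil radius 14 A, so
#: the axle's charged surface is azimuthally smooth on the Debye scale
D3_AXLE_FRAGMENTS = [
    CrickParams(supercoil_radius_r0=14.0, supercoil_phase_dphi0=15.0,
                n_res=36, z_offset=-(36 - 1) * 1.51 / 2.0),
    CrickParams(supercoil_radius_r0=14.0, supercoil_phase_dphi0=45.0,
                n_res=36, z_offset=-(36 - 1) * 1.51 / 2.0),
]

ROTOR_FRAGMENT = CrickParams(n_res=12)


def d3_axle() -> Component:
    """D3 axle of 36-residue single helices (12 interdigitated columns)."""
    return build_toy_axle("D3", D3_AXLE_FRAGMENTS)


def c3_rotor(inner_diameter: float = 28.0) -> Component:
    """C3 rotor ring calibrated to the requested inner diameter (A)."""
    ring_radius = inner_diameter / 2.0 + ROTOR_FRAGMENT.minor_radius_r1
    return build_toy_rotor("C3", ring_radius, ROTOR_FRAGMENT)


def c5_rotor(inner_diameter: float = 44.0) -> Component:
    """C5 rotor ring, larger bore: the loose-fitting partner for the D3 axle."""
    ring_radius = inner_diameter / 2.0 + ROTOR_FRAGMENT.minor_radius_r1
    return build_toy_rotor("C5", ring_radius, ROTOR_FRAGMENT)


def _charged_pair(axle: Component, rotor: Component, label: str,
                  interface_fraction: float = 0.30) -> AxleRotorAssembly:
    axle, rotor = assign_complementary_charges(axle, rotor, interface_fraction)
    return compose_assembly(axle, [(rotor, RigidPose())], label=label)


def d3c3_assembly() -> AxleRotorAssembly:
    """Tight helical toy: D3 axle + C3 rotor (rotation/translation in z only).

    Axle outer CA radius 16.3 A; rotor inner CA radius 20.5 A: the ~4 A
    radial clearance (under one effective CA diameter) blocks lateral
    translation and off-axis tilt while leaving rot_z and trans_z open.
    """
    return _charged_pair(d3_axle(), c3_rotor(41.0), "d3c3")


def d3c5_assembly() -> AxleRotorAssembly:
    """Loose helical toy: D3 axle + C5 rotor (all six DOFs partially open).

    The bore is wide enough that the rotor rattles freely (the bore wall
    sits beyond the interaction cutoff at the centred pose) and the charged
    set is sparse (interface fraction 0.05): any wall or tilt contact stays
    within a few kT of the minimum, emulating the low-specificity,
    few-contact electrostatic regime.  Pair with the weak-dispersion model
    from :func:`demo_model`.
    """
    return _charged_pair(d3_axle(), c5_rotor(66.0), "d3c5",
                         interface_fraction=0.05)


_DEMOS = {
    "c5c3": c5c3_assembly,
    "c3c3": c3c3_assembly,
    "d8c4": d8c4_assembly,
    "d3c3": d3c3_assembly,
    "d3c5": d3c5_assembly,
}


def demo_assembly(name: str) -> AxleRotorAssembly:
    """Named demo system: one of c5c3, c3c3, d8c4, d3c3, d3c5."""
    try:
        return _DEMOS[name]()
    except KeyError:
        raise KeyError(f"unknown demo {name!r}; choose from {sorted(_DEMOS)}") from None


def demo_model(name: str) -> EnergyModel:
    """Energy model paired with each demo.

    The loose electrostatic pair (d3c5) uses a weak dispersion well
    (lj_epsilon = 0.02 kcal/mol): its interface is designed to avoid close
    packing, so CA-level contacts should not be sticky.  The repulsive core
    (sigma and the r^-12 wall) is unchanged.  All other demos use defaults.
    """
    if name not in _DEMOS:
        raise KeyError(f"unknown demo {name!r}; choose from {sorted(_DEMOS)}")
    if name == "d3c5":
        return EnergyModel(lj_epsilon=0.02)
    return EnergyModel()
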