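"""Parametric CA-level helical backbones and toy machine components.

The generator follows the Crick coiled-coil parameterization: a minor helix
of radius R1 and twist w1 wound on a major (supercoil) helix of radius R0,
twist w0 and rise d per residue, the minor-helix plane tilted by the
supercoil pitch angle alpha = atan2(R0*w0, d).  With R0 = 0 and w0 = 0 the
curve degenerates to an ideal straight alpha-helix on the z axis.

Defaults for the constants the parameterization needs but designers rarely
vary: w1 = 100°/res (the 18/5 alpha-helix), R1 = 2.26 A, d = 1.51 A.
"""
from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np

from ._geometry import Chain, ParameterError, Residue, rot_x
from .symmetry import Component, SymmetryGroup, apply_symmetry

__all__ = [
    "CrickParams",
    "Residue",
    "Chain",
    "generate_crick_helix",
    "build_toy_axle",
    "build_toy_rotor",
    "build_point_feature_model",
]


@dataclass(frozen=True)
class CrickParams:
    """Parameters of one helical fragment (lengths in A, angles in deg)."""

    supercoil_radius_r0: float = 0.0   # R0, major-helix radius
    supercoil_twist_w0: float = 0.0    # w0, deg per residue about the supercoil axis
    supercoil_phase_dphi0: float = 0.0
    minor_radius_r1: float = 2.26      # R1, alpha-helix radius
    helix_twist_w1: float = 100.0      # w1, deg per residue about the minor axis
    helical_phase_dphi1: float = 0.0
    z_offset: float = 0.0
    rise_per_res_d: float = 1.51
    n_res: int = 28
    invert_z: bool = False

    def validate(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name == "invert_z":
                continue
            if not np.isfinite(v):
                raise ParameterError(f"{f.name} is not finite: {v!r}")
        if self.supercoil_radius_r0 < 0:
            raise ParameterError(f"supercoil_radius_r0 must be >= 0, got {self.supercoil_radius_r0}")
        if self.minor_radius_r1 <= 0:
            raise ParameterError(f"minor_radius_r1 must be > 0, got {self.minor_radius_r1}")
        if self.rise_per_res_d <= 0:
            raise ParameterError(f"rise_per_res_d must be > 0, got {self.rise_per_res_d}")
        if int(self.n_res) != self.n_res or self.n_res < 2:
            raise ParameterError(f"n_res must be an integer >= 2, got {self.n_res}")


def generate_crick_helix(params: CrickParams, chain_id: str = "A",
                         sequence: str | None = None) -> Chain:
    """CA trace of one fragment on the minor-helix-on-major-helix curve.

    Phases are reduced modulo 360° before use, so adding a full turn to
    either phase yields bitwise-identical coordinates.  ``invert_z`` rotates
    the finished fragment 180° about x, producing the antiparallel partner
    (the same convention as the dihedral flip axis).
    """
    params.validate()
    n = int(params.n_res)
    t = np.arange(n, dtype=float)
    r0 = params.supercoil_radius_r0
    r1 = params.minor_radius_r1
    d = params.rise_per_res_d
    w0 = np.radians(params.supercoil_twist_w0)
    w1 = np.radians(params.helix_twist_w1)
    p0 = np.radians(params.supercoil_phase_dphi0 % 360.0)
    p1 = np.radians(params.helical_phase_dphi1 % 360.0)

    alpha = np.arctan2(r0 * w0, d)  # supercoil pitch angle
    a = w0 * t + p0
    b = w1 * t + p1
    x = r0 * np.cos(a) + r1 * np.cos(a) * np.cos(b) - r1 * np.cos(alpha) * np.sin(a) * np.sin(b)
    y = r0 * np.sin(a) + r1 * np.sin(a) * np.cos(b) + r1 * np.cos(alpha) * np.cos(a) * np.sin(b)
    z = d * t - r1 * np.sin(alpha) * np.sin(b) + params.z_offset
    xyz = np.column_stack([x, y, z])
    if params.invert_z:
        xyz = xyz @ rot_x(180.0).T

    seq = sequence if sequence is not None else "A" * n
    if len(seq) != n:
        raise ParameterError(f"sequence length {len(seq)} != n_res {n}")
    residues = [Residue(i + 1, seq[i], xyz[i]) for i in range(n)]
    return Chain(chain_id, residues)


def _as_param_list(fragment_params) -> list[CrickParams]:
    if isinstance(fragment_params, CrickParams):
        return [fragment_params]
    out = list(fragment_params)
    if not out:
        raise ParameterError("at least one fragment is required")
    return out


def build_toy_axle(symmetry: str | SymmetryGroup, fragment_params) -> Component:
    """Symmetric axle from one or more Crick fragments; COM recentred on z=0."""
    group = SymmetryGroup.from_label(symmetry)
    frags = [generate_crick_helix(p) for p in _as_param_list(fragment_params)]
    comp = apply_symmetry(frags, group, role="axle")
    z_com = comp.coords[:, 2].mean()
    # shifting along z only, so the Cn/Dn axis placement is preserved
    comp = comp.transformed(translation=np.array([0.0, 0.0, -z_com]))
    comp.metadata["kind"] = "toy_axle"
    return comp


def build_toy_rotor(symmetry: str | SymmetryGroup, ring_radius: float,
                    fragment_params) -> Component:
    """Ring of fragments about z; reports the inner diameter in metadata.

    Each fragment is generated in its own frame, recentred along z, pushed
    out to ``ring_radius`` along +x, and expanded by the cyclic group.  The
    inner diameter is 2x the minimum CA radial distance of the finished ring.
    """
    group = SymmetryGroup.from_label(symmetry)
    if group.kind != "C":
        raise ParameterError(f"rotors are cyclic; got {group.label}")
    if ring_radius <= 0:
        raise ParameterError(f"ring_radius must be > 0, got {ring_radius}")
    frags = []
    for p in _as_param_list(fragment_params):
        chain = generate_crick_helix(p)
        xyz = chain.coords
        shift = np.array([ring_radius, 0.0, -xyz[:, 2].mean()])
        frags.append(chain.transformed(translation=shift))
    comp = apply_symmetry(frags, group, role="rotor")
    radial = np.hypot(comp.coords[:, 0], comp.coords[:, 1])
    comp.metadata["kind"] = "toy_rotor"
    comp.metadata["ring_radius"] = float(ring_radius)
    comp.metadata["inner_diameter"] = float(2.0 * radial.min())
    return comp


def build_point_feature_model(n_fold: int, radius: float, z: float = 0.0,
                              charge: float = 0.0, role: str | None = None) -> Component:
    """Analytic stand-in component: n_fold point features on a circle.

    One single-residue chain per feature, at angles 360k/n_fold on a circle
    of the given radius and height, each carrying the given charge.  Used to
    verify the symmetry-forced landscape structure independently of any
    backbone detail.
    """
    if int(n_fold) != n_fold or n_fold < 1:
        raise ParameterError(f"n_fold must be an integer >= 1, got {n_fold}")
    unit = Chain("A", [Residue(1, "X", np.array([radius, 0.0, z]), charge)])
    comp = apply_symmetry(unit, SymmetryGroup("C", int(n_fold)), role=role,
                          check_clash=False)
    comp.metadata["kind"] = "point_feature_model"
    return comp
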