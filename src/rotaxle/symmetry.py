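"""Cyclic and dihedral point groups, symmetric expansion, and assemblies.

A component (axle or rotor) is an asymmetric unit of one or more chains
expanded by a Cn or Dn group about the z axis.  The dihedral 2-fold axis is
fixed along x.  The quasisymmetric composition rule — the interface energy of
an axle of rotational order n and a rotor of order m is periodic with
360°/lcm(n, m) — lives here as :func:`landscape_period`.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from ._geometry import CHAIN_IDS, Chain, ParameterError, rot_x, rot_y, rot_z

__all__ = [
    "SymmetryGroup",
    "Component",
    "RigidPose",
    "AxleRotorAssembly",
    "ClashError",
    "AssemblyError",
    "symmetry_operators",
    "apply_symmetry",
    "landscape_period",
    "compose_assembly",
    "pose_transform",
]

#: minimum allowed CA-CA distance between distinct chains of one component
CLASH_DISTANCE = 2.0


class ClashError(ValueError):
    """Two chains of a single component approach below the clash distance."""


class AssemblyError(ValueError):
    """Component roles are inconsistent with the requested assembly."""


@dataclass(frozen=True)
class SymmetryGroup:
    """A cyclic (Cn) or dihedral (Dn) point group about the z axis."""

    kind: str  # 'C' or 'D'
    order_n: int

    def __post_init__(self) -> None:
        if self.kind not in ("C", "D"):
            raise ParameterError(f"symmetry kind must be 'C' or 'D', got {self.kind!r}")
        if not isinstance(self.order_n, int) or self.order_n < 1:
            raise ParameterError(f"order_n must be an integer >= 1, got {self.order_n!r}")

    @classmethod
    def from_label(cls, label: "str | SymmetryGroup") -> "SymmetryGroup":
        if isinstance(label, SymmetryGroup):
            return label
        label = str(label).strip()
        if len(label) < 2 or label[0] not in "CD":
            raise ParameterError(f"cannot parse symmetry label {label!r}")
        try:
            n = int(label[1:])
        except ValueError as exc:
            raise ParameterError(f"cannot parse symmetry label {label!r}") from exc
        return cls(label[0], n)

    @property
    def label(self) -> str:
        return f"{self.kind}{self.order_n}"

    @property
    def n_operators(self) -> int:
        return self.order_n if self.kind == "C" else 2 * self.order_n

    @property
    def rotational_order(self) -> int:
        """Effective rotational order about z.

        For a Dn group the flipped copies are geometry, not extra rotational
        symmetry, so the landscape-relevant order is n.
        """
        return self.order_n


def symmetry_operators(group: SymmetryGroup | str) -> list[np.ndarray]:
    """Proper-rotation operators of the group, in deterministic order.

    Cn: rotations about z by 360k/n, k ascending.  Dn: the same set followed
    by each composed with a 180° rotation about x (the flipped copies).
    """
    group = SymmetryGroup.from_label(group)
    ops = [rot_z(360.0 * k / group.order_n) for k in range(group.order_n)]
    if group.kind == "D":
        flip = rot_x(180.0)
        ops += [op @ flip for op in list(ops)]
    return ops


def landscape_period(axle_order: int, rotor_order: int) -> float:
    """Period (deg) of the axle-rotor interface energy along rot_z.

    Any pairwise-additive interface energy between components with rotational
    orders n and m about the same axis is periodic with 360/lcm(n, m): this
    is the symmetry-forced quasisymmetric landscape rule.
    """
    if axle_order < 1 or rotor_order < 1:
        raise ParameterError("rotational orders must be >= 1")
    return 360.0 / math.lcm(int(axle_order), int(rotor_order))


@dataclass
class Component:
    """A symmetric rigid body: chains of CA residues plus symmetry annotation.

    ``symmetry`` may be None for structures read from a PDB file before any
    symmetry is assigned; symmetric invariants then do not apply.
    """

    chains: list[Chain]
    symmetry: SymmetryGroup | None = None
    role: str | None = None  # 'axle' | 'rotor' | None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.role not in (None, "axle", "rotor"):
            raise ParameterError(f"role must be 'axle', 'rotor' or None, got {self.role!r}")
        if self.symmetry is not None and len(self.chains) % self.symmetry.n_operators:
            raise ParameterError(
                f"{len(self.chains)} chains are not a multiple of the "
                f"{self.symmetry.label} operator count {self.symmetry.n_operators}"
            )

    @property
    def n_chains(self) -> int:
        return len(self.chains)

    @property
    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains)

    @property
    def coords(self) -> np.ndarray:
        """All CA coordinates, chain-major order, shape (n_residues, 3)."""
        if self.n_residues == 0:
            return np.zeros((0, 3))
        return np.vstack([c.coords for c in self.chains])

    @property
    def charges(self) -> np.ndarray:
        if self.n_residues == 0:
            return np.zeros(0)
        return np.concatenate([c.charges for c in self.chains])

    @property
    def rotational_order(self) -> int:
        return 1 if self.symmetry is None else self.symmetry.rotational_order

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "Component":
        chains = [c.transformed(rotation, translation) for c in self.chains]
        return Component(chains, self.symmetry, self.role, dict(self.metadata))

    def with_role(self, role: str) -> "Component":
        return Component(self.chains, self.symmetry, role, dict(self.metadata))


def _check_interchain_clashes(chains: list[Chain]) -> None:
    worst = (np.inf, None, None)
    for i in range(len(chains)):
        for j in range(i + 1, len(chains)):
            d = cdist(chains[i].coords, chains[j].coords)
            dmin = float(d.min())
            if dmin < worst[0]:
                worst = (dmin, chains[i].chain_id, chains[j].chain_id)
    if worst[0] < CLASH_DISTANCE:
        raise ClashError(
            f"inter-chain CA-CA distance {worst[0]:.3f} A between chains "
            f"{worst[1]!r} and {worst[2]!r} is below {CLASH_DISTANCE} A"
        )


def apply_symmetry(asym_unit: Chain | list[Chain], group: SymmetryGroup | str,
                   role: str | None = None, check_clash: bool = True,
                   metadata: dict | None = None) -> Component:
    """Expand an asymmetric unit into a full symmetric component.

    Chain order is deterministic: fragment order first, then symmetry
    operator order, with ids assigned A, B, C, ... in that order.
    """
    group = SymmetryGroup.from_label(group)
    fragments = [asym_unit] if isinstance(asym_unit, Chain) else list(asym_unit)
    if not fragments or any(len(f) == 0 for f in fragments):
        raise ParameterError("asymmetric unit must contain at least one non-empty chain")
    ops = symmetry_operators(group)
    if len(ops) * len(fragments) > len(CHAIN_IDS):
        raise ParameterError(
            f"{len(ops) * len(fragments)} chains exceed the {len(CHAIN_IDS)}-chain id space"
        )
    chains = []
    for frag in fragments:
        for op in ops:
            chains.append(frag.transformed(op, chain_id=CHAIN_IDS[len(chains)]))
    if check_clash:
        _check_interchain_clashes(chains)
    return Component(chains, group, role, metadata or {})


@dataclass(frozen=True)
class RigidPose:
    """Six-DOF transform of a rotor relative to the axle frame.

    Convention (fixed): rotations are extrinsic about the fixed axes, applied
    in the order z, then y, then x (R = Rx · Ry · Rz), followed by the
    translation.  The machine's main axis is z.
    """

    rot_z: float = 0.0
    rot_x: float = 0.0
    rot_y: float = 0.0
    trans_x: float = 0.0
    trans_y: float = 0.0
    trans_z: float = 0.0

    def as_tuple(self) -> tuple[float, ...]:
        return (self.rot_z, self.rot_x, self.rot_y,
                self.trans_x, self.trans_y, self.trans_z)


def pose_transform(pose: RigidPose) -> tuple[np.ndarray, np.ndarray]:
    """Rotation matrix and translation vector realizing a pose."""
    R = rot_x(pose.rot_x) @ rot_y(pose.rot_y) @ rot_z(pose.rot_z)
    t = np.array([pose.trans_x, pose.trans_y, pose.trans_z])
    return R, t


@dataclass
class AxleRotorAssembly:
    """An axle plus one or more posed rotors (the two-component machine)."""

    axle: Component
    rotors: list[tuple[Component, RigidPose]]
    label: str = ""

    @property
    def n_rotors(self) -> int:
        return len(self.rotors)

    def posed_rotor(self, i: int = 0) -> Component:
        """Rotor ``i`` with its pose applied (a transformed copy)."""
        comp, pose = self.rotors[i]
        R, t = pose_transform(pose)
        return comp.transformed(R, t)

    def posed_rotor_coords(self, i: int = 0) -> np.ndarray:
        comp, pose = self.rotors[i]
        R, t = pose_transform(pose)
        return comp.coords @ R.T + t

    def with_pose(self, i: int, pose: RigidPose) -> "AxleRotorAssembly":
        rotors = list(self.rotors)
        rotors[i] = (rotors[i][0], pose)
        return AxleRotorAssembly(self.axle, rotors, self.label)

    @property
    def all_coords(self) -> np.ndarray:
        return np.vstack([self.axle.coords]
                         + [self.posed_rotor_coords(i) for i in range(self.n_rotors)])


def compose_assembly(axle: Component, rotors: list[tuple[Component, RigidPose]],
                     label: str = "") -> AxleRotorAssembly:
    """Assemble one axle and >= 1 posed rotors; inputs are not modified."""
    if axle.role != "axle":
        raise AssemblyError(f"axle component has role {axle.role!r}, expected 'axle'")
    if not rotors:
        raise AssemblyError("an assembly needs at least one rotor")
    for comp, pose in rotors:
        if comp.role != "rotor":
            raise AssemblyError(f"rotor component has role {comp.role!r}, expected 'rotor'")
        if not isinstance(pose, RigidPose):
            raise AssemblyError("each rotor must be paired with a RigidPose")
    return AxleRotorAssembly(axle, [(c, p) for c, p in rotors], label)
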