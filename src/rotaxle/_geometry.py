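"""Low-level geometric primitives shared by the component and symmetry layers.

Angles are degrees at every public boundary; radians appear only inside
trigonometric calls.  All coordinates are Cartesian, in Angstrom, with the
machine's main symmetry axis along z.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")

#: chain identifier space, in deterministic assignment order (PDB-compatible)
CHAIN_IDS = (
    "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    "abcdefghijklmnopqrstuvwxyz"
    "0123456789"
)


class ParameterError(ValueError):
    """A parameter is non-finite or outside its documented range."""


@dataclass
class Residue:
    """One CA-level residue: position, identity and point charge (in e)."""

    index: int
    aa: str
    ca: np.ndarray
    charge: float = 0.0

    def __post_init__(self) -> None:
        self.ca = np.asarray(self.ca, dtype=float)
        if self.ca.shape != (3,):
            raise ParameterError(f"ca must be a 3-vector, got shape {self.ca.shape}")
        if not np.all(np.isfinite(self.ca)):
            raise ParameterError(f"residue {self.index}: non-finite coordinate")
        if self.aa not in AA_ALPHABET:
            raise ParameterError(f"residue {self.index}: unknown amino acid {self.aa!r}")


@dataclass
class Chain:
    """An ordered list of residues sharing one chain identifier."""

    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __post_init__(self) -> None:
        idx = [r.index for r in self.residues]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ParameterError(f"chain {self.chain_id}: residue indices not strictly increasing")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def coords(self) -> np.ndarray:
        return np.array([r.ca for r in self.residues], dtype=float).reshape(len(self), 3)

    @property
    def charges(self) -> np.ndarray:
        return np.array([r.charge for r in self.residues], dtype=float)

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None,
                    chain_id: str | None = None) -> "Chain":
        """Return a rigidly transformed copy (rotate about the origin, then translate)."""
        R = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
        t = np.zeros(3) if translation is None else np.asarray(translation, dtype=float)
        new_id = self.chain_id if chain_id is None else chain_id
        residues = [Residue(r.index, r.aa, R @ r.ca + t, r.charge) for r in self.residues]
        return Chain(new_id, residues)


def rot_x(deg: float) -> np.ndarray:
    a = np.radians(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def rot_y(deg: float) -> np.ndarray:
    a = np.radians(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def rot_z(deg: float) -> np.ndarray:
    a = np.radians(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
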