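"""Interface scoring: soft sterics plus Debye-screened electrostatics.

The designed axle-rotor interfaces lean on electrostatic complementarity —
charges are longer range and far less dependent on shape matching than
hydrophobic packing — so the score is a capped Lennard-Jones steric term on
CA centers plus a screened Coulomb term:

    E(r) = min(cap, 4 eps ((sigma/r)^12 - (sigma/r)^6))
         + C q1 q2 exp(-r / lambda_D) / (dielectric * r)

truncated at ``cutoff`` and shifted per term so E(cutoff) = 0 (continuous
landscapes on a grid).  Energies are kcal/mol of this model; no equivalence
with any all-atom force field is claimed.

The charge-assignment rule mirrors the design convention: no positive
charges (Lys/Arg) on the axle, no negative charges (Asp/Glu) on the rotor.
Asp/Glu/Lys/Arg carry fixed unit charges; only histidine titrates, with a
Henderson-Hasselbalch protonation fraction.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from ._geometry import ParameterError
from .symmetry import AxleRotorAssembly, Component

__all__ = [
    "EnergyModel",
    "EnergyValue",
    "DEFAULT_PKA",
    "assign_complementary_charges",
    "protonation_charge",
    "lennard_jones_energy",
    "electrostatic_energy",
    "pair_energy",
    "interface_energy",
    "clash_count",
]

DEFAULT_PKA = {"H": 6.0}


@dataclass(frozen=True)
class EnergyModel:
    """Constants of the interface score (kcal/mol, Angstrom, e)."""

    lj_epsilon: float = 0.2
    lj_sigma: float = 5.0        # effective CA diameter
    lj_cap: float = 50.0         # per-pair steric cap; keeps clashes finite
    elec_constant: float = 332.06
    dielectric: float = 80.0
    debye_length: float = 10.0
    cutoff: float = 12.0
    contact_cutoff: float = 8.0
    clash_cutoff: float = 3.5
    pH: float = 7.4
    pka_table: dict = field(default_factory=lambda: dict(DEFAULT_PKA))

    def __post_init__(self) -> None:
        if self.cutoff < self.lj_sigma:
            raise ParameterError("cutoff must be >= lj_sigma")
        if self.debye_length <= 0:
            raise ParameterError("debye_length must be > 0")
        if self.dielectric <= 0:
            raise ParameterError("dielectric must be > 0")


@dataclass(frozen=True)
class EnergyValue:
    """Decomposed interface energy; total = steric + electrostatic."""

    total: float
    steric: float
    electrostatic: float
    n_contacts: int
    n_clashes: int


def protonation_charge(aa: str, pH: float | None = None,
                       pka_table: dict | None = None,
                       model: EnergyModel | None = None) -> float:
    """Mean charge (e) of a residue type at the given pH.

    His follows Henderson-Hasselbalch: +1 / (1 + 10^(pH - pKa)).  Asp/Glu are
    -1 and Lys/Arg +1 independent of pH (their pKas sit far outside the
    working range); every other residue type is neutral.
    """
    m = model or EnergyModel()
    pH = m.pH if pH is None else pH
    pka = dict(m.pka_table)
    if pka_table:
        pka.update(pka_table)
    if aa in ("D", "E"):
        return -1.0
    if aa in ("K", "R"):
        return 1.0
    if aa == "H":
        return 1.0 / (1.0 + 10.0 ** (pH - pka.get("H", 6.0)))
    return 0.0


def _radial_interface_mask(comp: Component, interface_fraction: float,
                           facing: str) -> np.ndarray:
    """Per-ASU-residue mask of interface positions, by radial band.

    Interface residues are those whose CA radial distance lies within the
    closest ``interface_fraction`` of the component's radial range on the
    side facing its partner ('outer' for the axle, 'inner' for the rotor).
    Computed on the first chain of each fragment group and replicated, so the
    assignment is exactly identical on every symmetry copy.
    """
    r = np.hypot(comp.coords[:, 0], comp.coords[:, 1])
    lo, hi = float(r.min()), float(r.max())
    band = interface_fraction * (hi - lo)
    if facing == "outer":
        mask = r >= hi - band
    else:
        mask = r <= lo + band
    # replicate the first symmetry copy's mask onto all copies, per fragment
    n_ops = comp.symmetry.n_operators if comp.symmetry else 1
    per_chain = [len(c) for c in comp.chains]
    out = np.zeros(comp.n_residues, dtype=bool)
    start = 0
    starts = np.cumsum([0] + per_chain)
    for ci in range(comp.n_chains):
        ref = (ci // n_ops) * n_ops  # first chain of this fragment group
        out[starts[ci]:starts[ci + 1]] = mask[starts[ref]:starts[ref] + per_chain[ci]]
        start += per_chain[ci]
    return out


def _with_charges(comp: Component, mask: np.ndarray, aa: str, q: float) -> Component:
    new_chains = []
    i = 0
    for chain in comp.chains:
        residues = []
        for res in chain.residues:
            if mask[i]:
                residues.append(type(res)(res.index, aa, res.ca.copy(), q))
            else:
                residues.append(type(res)(res.index, res.aa, res.ca.copy(), res.charge))
            i += 1
        new_chains.append(type(chain)(chain.chain_id, residues))
    return Component(new_chains, comp.symmetry, comp.role, dict(comp.metadata))


def assign_complementary_charges(axle: Component, rotor: Component,
                                 interface_fraction: float = 0.30,
                                 ) -> tuple[Component, Component]:
    """Charge the facing surfaces: Glu (-1) on the axle, Lys (+1) on the rotor.

    Returns charged copies; the inputs are unmodified.  A component whose
    radial band selects no residues is returned unchanged with a warning.
    """
    axle_mask = _radial_interface_mask(axle, interface_fraction, facing="outer")
    rotor_mask = _radial_interface_mask(rotor, interface_fraction, facing="inner")
    if not axle_mask.any():
        warnings.warn("axle has no interface residues at this fraction; left uncharged")
    if not rotor_mask.any():
        warnings.warn("rotor has no interface residues at this fraction; left uncharged")
    new_axle = _with_charges(axle, axle_mask, "E", -1.0) if axle_mask.any() else axle
    new_rotor = _with_charges(rotor, rotor_mask, "K", 1.0) if rotor_mask.any() else rotor
    return new_axle, new_rotor


def lennard_jones_energy(r, model: EnergyModel | None = None):
    """Capped 12-6 steric term, unshifted (vectorized over r)."""
    m = model or EnergyModel()
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ParameterError("pair distance must be > 0")
    sr6 = (m.lj_sigma / r) ** 6
    return np.minimum(m.lj_cap, 4.0 * m.lj_epsilon * (sr6 * sr6 - sr6))


def electrostatic_energy(r, q1, q2, model: EnergyModel | None = None):
    """Debye-screened Coulomb term, unshifted (vectorized over r)."""
    m = model or EnergyModel()
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ParameterError("pair distance must be > 0")
    return m.elec_constant * np.asarray(q1) * np.asarray(q2) * np.exp(-r / m.debye_length) / (m.dielectric * r)


def _pair_terms(r: np.ndarray, qq: np.ndarray, m: EnergyModel
                ) -> tuple[np.ndarray, np.ndarray]:
    """Shifted, truncated (steric, electrostatic) terms for distance array r.

    qq is the product q1*q2, broadcastable against r.  Each term is shifted
    by its own value at the cutoff so the total is continuous there.
    """
    r = np.asarray(r, dtype=float)
    inside = r < m.cutoff
    # 0.5 A numerical floor: keeps deeply clashed poses finite (the steric
    # term is capped anyway) without affecting any physical separation
    rs = np.where(inside, np.maximum(r, 0.5), m.cutoff)
    sr6 = (m.lj_sigma / rs) ** 6
    steric = np.minimum(m.lj_cap, 4.0 * m.lj_epsilon * (sr6 * sr6 - sr6))
    src6 = (m.lj_sigma / m.cutoff) ** 6
    steric = steric - 4.0 * m.lj_epsilon * (src6 * src6 - src6)
    screen = m.elec_constant / m.dielectric
    elec = screen * qq * np.exp(-rs / m.debye_length) / rs
    elec = elec - screen * qq * np.exp(-m.cutoff / m.debye_length) / m.cutoff
    return np.where(inside, steric, 0.0), np.where(inside, elec, 0.0)


def pair_energy(r: float, q1: float, q2: float,
                model: EnergyModel | None = None) -> float:
    """Total shifted pair energy between two interaction centers."""
    m = model or EnergyModel()
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr <= 0):
        raise ParameterError("pair distance must be > 0")
    steric, elec = _pair_terms(r_arr, np.asarray(q1, dtype=float) * np.asarray(q2, dtype=float), m)
    out = steric + elec
    return float(out) if out.ndim == 0 else out


def _block_pairs(assembly: AxleRotorAssembly) -> list[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]]:
    """Coordinate/charge blocks whose cross pairs constitute the interface."""
    blocks = [(assembly.axle.coords, assembly.axle.charges)]
    for i in range(assembly.n_rotors):
        blocks.append((assembly.posed_rotor_coords(i), assembly.rotors[i][0].charges))
    pairs = []
    # axle x each rotor, plus rotor x rotor across distinct rotors
    for i in range(len(blocks)):
        for j in range(i + 1, len(blocks)):
            pairs.append((blocks[i][0], blocks[i][1], blocks[j][0], blocks[j][1]))
    return pairs


def interface_energy(assembly: AxleRotorAssembly, model: EnergyModel | None = None,
                     method: str = "bruteforce") -> EnergyValue:
    """Sum of pair energies over all inter-component pairs within the cutoff.

    ``method='bruteforce'`` evaluates the full distance matrix per block;
    ``method='neighbor'`` uses a KD-tree neighbor list (identical result,
    faster for large components).
    """
    m = model or EnergyModel()
    if assembly.axle.n_residues == 0 or any(c.n_residues == 0 for c, _ in assembly.rotors):
        raise ParameterError("assembly has an empty component")
    steric_sum = 0.0
    elec_sum = 0.0
    n_contacts = 0
    n_clashes = 0
    for xa, qa, xb, qb in _block_pairs(assembly):
        if method == "bruteforce":
            r = cdist(xa, xb)
            qq = np.outer(qa, qb)
        elif method == "neighbor":
            ta, tb = cKDTree(xa), cKDTree(xb)
            pairs = ta.query_ball_tree(tb, m.cutoff)
            ii = [i for i, js in enumerate(pairs) for _ in js]
            jj = [j for js in pairs for j in js]
            if not ii:
                continue
            ii = np.asarray(ii, dtype=int)
            jj = np.asarray(jj, dtype=int)
            r = np.linalg.norm(xa[ii] - xb[jj], axis=1)
            qq = qa[ii] * qb[jj]
        else:
            raise ParameterError(f"unknown method {method!r}")
        steric, elec = _pair_terms(r, qq, m)
        steric_sum += float(steric.sum())
        elec_sum += float(elec.sum())
        n_contacts += int(np.count_nonzero(r < m.contact_cutoff))
        n_clashes += int(np.count_nonzero(r < m.clash_cutoff))
    return EnergyValue(steric_sum + elec_sum, steric_sum, elec_sum, n_contacts, n_clashes)


def clash_count(assembly: AxleRotorAssembly, clash_cutoff: float | None = None,
                model: EnergyModel | None = None) -> int:
    """Number of inter-component CA pairs closer than the clash cutoff."""
    m = model or EnergyModel()
    cut = m.clash_cutoff if clash_cutoff is None else clash_cutoff
    n = 0
    for xa, _, xb, _ in _block_pairs(assembly):
        n += int(np.count_nonzero(cdist(xa, xb) < cut))
    return n
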