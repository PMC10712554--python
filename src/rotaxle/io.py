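"""File formats: CA-only PDB, TSV landscapes/trajectories, PGM images, TOML.

The PDB dialect is deliberately narrow: fixed-column v3.3 ATOM records, CA
atoms only, one chain id per symmetry copy, TER after each chain, END last.
Chain ids are preserved verbatim (case-sensitive); insertion codes and
duplicate (chain, resseq) pairs are format errors.  All numeric output is
locale-independent and newline-normalized.
"""
from __future__ import annotations

import json
import logging
import tomllib
from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import numpy as np

from ._geometry import AA_ALPHABET, Chain, Residue
from .components import CrickParams, build_point_feature_model, build_toy_axle, build_toy_rotor
from .energetics import EnergyModel
from .landscape import Landscape1D, Landscape2D
from .symmetry import AxleRotorAssembly, Component, RigidPose, compose_assembly

__all__ = [
    "FormatError",
    "RunConfig",
    "write_pdb",
    "read_pdb",
    "write_landscape_tsv",
    "read_landscape_tsv",
    "write_landscape2d_tsv",
    "write_trajectory_tsv",
    "write_pgm",
    "write_features_json",
    "load_component_toml",
    "load_assembly_toml",
    "load_energy_model",
    "load_run_config",
    "save_run_config",
    "dumps_toml",
]

log = logging.getLogger("rotaxle")

_AA3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR", "X": "UNK",
}
_AA1 = {v: k for k, v in _AA3.items()}


class FormatError(ValueError):
    """A file does not conform to the supported dialect."""


# --- PDB --------------------------------------------------------------------

def write_pdb(obj: Component | AxleRotorAssembly, path) -> None:
    """CA-only PDB v3.3; coordinates to 3 decimals; error if out of columns."""
    if isinstance(obj, AxleRotorAssembly):
        comps = [obj.axle] + [obj.posed_rotor(i) for i in range(obj.n_rotors)]
        chains: list[Chain] = [c for comp in comps for c in comp.chains]
    else:
        chains = list(obj.chains)
    if not chains or all(len(c) == 0 for c in chains):
        raise FormatError("cannot write an empty component")
    if len(chains) > 62:
        raise FormatError(f"{len(chains)} chains exceed the 62-chain PDB id space")
    lines = []
    serial = 0
    for chain in chains:
        for res in chain.residues:
            serial += 1
            x, y, z = res.ca
            if not (-999.999 <= x <= 9999.999 and -999.999 <= y <= 9999.999
                    and -999.999 <= z <= 9999.999):
                raise FormatError(
                    f"atom {serial} (chain {chain.chain_id}, residue {res.index}): "
                    f"coordinate out of PDB fixed-column range"
                )
            lines.append(
                f"ATOM  {serial:5d}  CA  {_AA3.get(res.aa, 'UNK'):>3s} "
                f"{chain.chain_id:1s}{res.index:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                f"          {'C':>2s}"
            )
        lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_pdb(path) -> Component:
    """Parse CA records into a Component with symmetry unassigned.

    Non-CA atoms are ignored (count logged); missing CA atoms, insertion
    codes, and duplicate (chain, resseq) pairs are format errors.
    """
    chains: dict[str, list[Residue]] = {}
    seen: set[tuple[str, int]] = set()
    n_skipped = 0
    for line in Path(path).read_text().splitlines():
        rec = line[:6]
        if rec not in ("ATOM  ", "HETATM"):
            continue
        name = line[12:16].strip()
        if name != "CA":
            n_skipped += 1
            continue
        if line[26].strip():
            raise FormatError(f"insertion codes are not supported: {line.rstrip()!r}")
        chain_id = line[21]
        resseq = int(line[22:26])
        key = (chain_id, resseq)
        if key in seen:
            raise FormatError(f"duplicate residue: chain {chain_id!r} resseq {resseq}")
        seen.add(key)
        aa = _AA1.get(line[17:20].strip(), "X")
        if aa not in AA_ALPHABET:
            aa = "X"
        xyz = np.array([float(line[30:38]), float(line[38:46]), float(line[46:54])])
        chains.setdefault(chain_id, []).append(Residue(resseq, aa, xyz))
    if n_skipped:
        log.info("read_pdb: ignored %d non-CA atoms", n_skipped)
    if not chains:
        raise FormatError(f"no CA atoms found in {path}")
    return Component([Chain(cid, residues) for cid, residues in chains.items()],
                     symmetry=None)


# --- TSV / JSON / PGM -------------------------------------------------------

def _meta_header(meta: dict) -> list[str]:
    return [f"# {k} = {json.dumps(v, sort_keys=True)}" for k, v in sorted(meta.items())
            if not isinstance(v, dict)]


def write_landscape_tsv(landscape: Landscape1D, path) -> None:
    lines = _meta_header({"dof": landscape.dof, "periodic": landscape.periodic,
                          **{k: v for k, v in landscape.model_meta.items()
                             if not isinstance(v, dict)}})
    lines.append("dof_value\tenergy_kcal")
    for g, e in zip(landscape.grid, landscape.energy):
        lines.append(f"{g:.6f}\t{e:.9f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_landscape_tsv(path) -> Landscape1D:
    dof, periodic = "rot_z", True
    grid, energy = [], []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            if "=" in line:
                key, _, val = line[1:].partition("=")
                key = key.strip()
                if key == "dof":
                    dof = json.loads(val.strip())
                elif key == "periodic":
                    periodic = json.loads(val.strip())
            continue
        if line.startswith("dof_value") or not line.strip():
            continue
        a, b = line.split("\t")
        grid.append(float(a))
        energy.append(float(b))
    if not grid:
        raise FormatError(f"no landscape rows in {path}")
    return Landscape1D(dof, np.array(grid), np.array(energy), periodic=periodic)


def write_landscape2d_tsv(landscape: Landscape2D, path) -> None:
    lines = _meta_header({"rot_label": landscape.rot_label,
                          "trans_label": landscape.trans_label})
    lines.append("rot_deg\ttrans_A\tenergy_kcal")
    for i, g in enumerate(landscape.rot_grid):
        for j, t in enumerate(landscape.trans_grid):
            lines.append(f"{g:.6f}\t{t:.6f}\t{landscape.energy[i, j]:.9f}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_trajectory_tsv(traj, path) -> None:
    lines = _meta_header({"dof": traj.dof, **asdict(traj.params)})
    lines.append("step\tvalue_deg\tvalue_unwrapped_deg")
    wrapped = traj.values_wrapped
    for i, (w, u) in enumerate(zip(wrapped, traj.values_unwrapped)):
        lines.append(f"{i}\t{w:.6f}\t{u:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_features_json(features, path) -> None:
    """LandscapeFeatures as JSON with fixed key order (diff-stable)."""
    d = features.to_dict()
    ordered = {k: d[k] for k in sorted(d)}
    Path(path).write_text(json.dumps(ordered, indent=2, sort_keys=True) + "\n")


def write_pgm(image: np.ndarray, path, maxval: int = 65535) -> None:
    """16-bit plain (P2) PGM, row-major, intensity scaled to [0, maxval]."""
    img = np.asarray(image, dtype=float)
    lo, hi = float(img.min()), float(img.max())
    scale = (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)
    pix = np.round(scale * maxval).astype(int)
    lines = ["P2", f"{img.shape[1]} {img.shape[0]}", str(maxval)]
    lines += [" ".join(str(v) for v in row) for row in pix]
    Path(path).write_text("\n".join(lines) + "\n")


# --- TOML -------------------------------------------------------------------

def _toml_scalar(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return json.dumps(v)
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_scalar(x) for x in v) + "]"
    raise FormatError(f"cannot serialize {type(v).__name__} to TOML")


def dumps_toml(data: dict) -> str:
    """Minimal TOML emitter: scalars, lists, tables and arrays of tables."""
    top, tables, arrays = [], [], []
    for k, v in data.items():
        if isinstance(v, dict):
            tables.append((k, v))
        elif isinstance(v, list) and v and all(isinstance(x, dict) for x in v):
            arrays.append((k, v))
        else:
            top.append(f"{k} = {_toml_scalar(v)}")
    out = list(top)
    for name, tab in tables:
        out.append(f"\n[{name}]")
        for k, v in tab.items():
            if isinstance(v, dict):  # one nesting level, e.g. [fragment.1]
                out.append(f"\n[{name}.{k}]")
                out += [f"{k2} = {_toml_scalar(v2)}" for k2, v2 in v.items()]
            else:
                out.append(f"{k} = {_toml_scalar(v)}")
    for name, items in arrays:
        for tab in items:
            out.append(f"\n[[{name}]]")
            out += [f"{k} = {_toml_scalar(v)}" for k, v in tab.items()]
    return "\n".join(out).lstrip("\n") + "\n"


_CRICK_FIELDS = {f.name for f in fields(CrickParams)}


def load_component_toml(path) -> Component:
    """Build a component from a TOML description.

    ``[component]`` holds ``symmetry`` ("C3", "D8", ...), ``role`` and, for
    rotors, ``ring_radius``; ``kind = "point"`` instead builds a point
    feature model from n_fold/radius/z/charge.  ``[fragment.N]`` tables
    mirror the CrickParams field names exactly.
    """
    data = tomllib.loads(Path(path).read_text())
    comp_tab = data.get("component", {})
    kind = comp_tab.get("kind", "helical")
    if kind == "point":
        return build_point_feature_model(
            int(comp_tab["n_fold"]), float(comp_tab["radius"]),
            z=float(comp_tab.get("z", 0.0)), charge=float(comp_tab.get("charge", 0.0)),
            role=comp_tab.get("role"))
    frags_tab = data.get("fragment", {})
    if not frags_tab:
        raise FormatError(f"{path}: no [fragment.N] tables")
    params = []
    for key in sorted(frags_tab, key=str):
        tab = frags_tab[key]
        unknown = set(tab) - _CRICK_FIELDS
        if unknown:
            raise FormatError(f"{path}: unknown CrickParams fields {sorted(unknown)}")
        params.append(CrickParams(**tab))
    symmetry = comp_tab.get("symmetry", "C1")
    role = comp_tab.get("role", "axle")
    if role == "rotor":
        return build_toy_rotor(symmetry, float(comp_tab["ring_radius"]), params)
    return build_toy_axle(symmetry, params)


def load_energy_model(data: dict) -> EnergyModel:
    """EnergyModel from an ``[energy]`` table (missing keys -> defaults)."""
    allowed = {f.name for f in fields(EnergyModel)}
    unknown = set(data) - allowed
    if unknown:
        raise FormatError(f"unknown energy-model fields {sorted(unknown)}")
    return EnergyModel(**data)


def load_assembly_toml(path) -> tuple[AxleRotorAssembly, EnergyModel]:
    """Assembly from TOML: [axle] and [[rotor]] tables naming component files.

    Each table has ``file`` (path relative to the assembly file) and rotors
    a ``pose`` of six numbers (rot_z, rot_x, rot_y, trans_x, trans_y,
    trans_z).  An optional [energy] table overrides model constants.
    """
    base = Path(path).parent
    data = tomllib.loads(Path(path).read_text())
    if "axle" not in data or "rotor" not in data:
        raise FormatError(f"{path}: needs an [axle] table and >= 1 [[rotor]] table")
    axle = load_component_toml(base / data["axle"]["file"]).with_role("axle")
    rotors = []
    for tab in data["rotor"]:
        comp = load_component_toml(base / tab["file"]).with_role("rotor")
        pose_vals = tab.get("pose", [0.0] * 6)
        if len(pose_vals) != 6:
            raise FormatError(f"{path}: pose must have six numbers")
        rotors.append((comp, RigidPose(*[float(v) for v in pose_vals])))
    model = load_energy_model(data.get("energy", {}))
    return compose_assembly(axle, rotors, label=data.get("label", "")), model


# --- run configuration ------------------------------------------------------

@dataclass
class RunConfig:
    """Everything needed to reproduce a run: (config, seed) is sufficient."""

    assembly_file: str = ""
    out_dir: str = "out"
    seed: int = 0
    log_level: str = "INFO"
    rot_step: float = 1.0
    trans_range: float = 8.0
    trans_step: float = 0.5
    kT: float = 0.593
    diffusion: float = 100.0
    dt: float = 1e-3
    n_steps: int = 100000
    energy: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return asdict(self)


def load_run_config(path) -> RunConfig:
    data = tomllib.loads(Path(path).read_text())
    allowed = {f.name for f in fields(RunConfig)}
    unknown = set(data) - allowed
    if unknown:
        raise FormatError(f"unknown run-config fields {sorted(unknown)}")
    return RunConfig(**data)


def save_run_config(config: RunConfig, path) -> None:
    Path(path).write_text(dumps_toml(config.as_dict()))
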