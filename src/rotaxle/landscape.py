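"""Energy landscapes along rigid-body DOFs and their feature analysis.

Scans rotate (and translate) one rotor relative to the axle on a uniform
grid and tabulate the interface energy.  Feature extraction — circular local
minima with plateau merging, principal-minima selection, dynamic range, and
discrete Fourier periodicity — quantifies the symmetry-forced structure of
the landscape: an axle of rotational order n against a rotor of order m
gives lcm(n, m) equivalent sectors per revolution.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from ._geometry import ParameterError, rot_x, rot_y, rot_z
from .energetics import EnergyModel, _pair_terms
from .symmetry import AxleRotorAssembly

__all__ = [
    "Landscape1D",
    "Landscape2D",
    "LandscapeFeatures",
    "scan_rotation",
    "scan_rotation_translation",
    "find_local_minima",
    "dynamic_range",
    "frequency_spectrum",
    "classify_dofs",
]

KT_ROOM = 0.593  # kcal/mol at 298 K


@dataclass
class Landscape1D:
    """Energies on a uniform 1D grid over one DOF (periodic for rotations)."""

    dof: str
    grid: np.ndarray        # deg (rotations) or A (translations)
    energy: np.ndarray      # kcal/mol
    periodic: bool = True
    model_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.energy = np.asarray(self.energy, dtype=float)
        if self.grid.shape != self.energy.shape or self.grid.ndim != 1:
            raise ParameterError("grid and energy must be 1D arrays of equal length")
        if len(self.grid) >= 2:
            steps = np.diff(self.grid)
            if np.any(steps <= 0) or not np.allclose(steps, steps[0], atol=1e-9):
                raise ParameterError("grid must be strictly increasing and uniform")
        if not np.all(np.isfinite(self.energy)):
            raise ParameterError("landscape energies must be finite")

    @property
    def step(self) -> float:
        return float(self.grid[1] - self.grid[0])

    @classmethod
    def from_function(cls, f, step_deg: float = 1.0, dof: str = "rot_z") -> "Landscape1D":
        """Tabulate an analytic energy function of angle (deg) on [0, 360)."""
        grid = _rotation_grid(step_deg)
        return cls(dof, grid, np.asarray([f(g) for g in grid], dtype=float))


@dataclass
class Landscape2D:
    """Energy matrix over a rotation x translation grid (rot periodic)."""

    rot_grid: np.ndarray    # deg
    trans_grid: np.ndarray  # A, along z
    energy: np.ndarray      # shape (len(rot_grid), len(trans_grid))
    rot_label: str = "rot_z"
    trans_label: str = "trans_z"
    model_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.rot_grid = np.asarray(self.rot_grid, dtype=float)
        self.trans_grid = np.asarray(self.trans_grid, dtype=float)
        self.energy = np.asarray(self.energy, dtype=float)
        if self.energy.shape != (len(self.rot_grid), len(self.trans_grid)):
            raise ParameterError("energy matrix shape must be (n_rot, n_trans)")
        if not np.all(np.isfinite(self.energy)):
            raise ParameterError("landscape energies must be finite")

    def rotation_slice(self, trans_value: float) -> Landscape1D:
        j = int(np.argmin(np.abs(self.trans_grid - trans_value)))
        return Landscape1D(self.rot_label, self.rot_grid, self.energy[:, j],
                           periodic=True, model_meta=dict(self.model_meta))


@dataclass
class LandscapeFeatures:
    """Summary features of a periodic 1D rotational landscape."""

    minima_positions: np.ndarray      # deg, sorted
    minima_count: int
    principal_minima_count: int
    principal_positions: np.ndarray   # deg, sorted
    mean_spacing: float               # deg
    dynamic_range: float              # kcal/mol
    dominant_mode: int                # integer harmonic of largest amplitude
    mode_amplitudes: np.ndarray       # |c_k| for k = 0 .. N//2

    def to_dict(self) -> dict:
        d = asdict(self)
        d["minima_positions"] = [float(x) for x in self.minima_positions]
        d["principal_positions"] = [float(x) for x in self.principal_positions]
        d["mode_amplitudes"] = [float(x) for x in self.mode_amplitudes]
        return d


def _rotation_grid(step_deg: float) -> np.ndarray:
    if step_deg <= 0:
        raise ParameterError(f"step must be > 0, got {step_deg}")
    n = 360.0 / step_deg
    if abs(n - round(n)) > 1e-9:
        raise ParameterError(f"360 must be divisible by the step, got {step_deg}")
    return np.arange(round(n)) * step_deg


def _scan_blocks(assembly: AxleRotorAssembly, rotor_index: int):
    """Static (coords, charges) vs moving rotor (coords, charges) split."""
    static_xyz = [assembly.axle.coords]
    static_q = [assembly.axle.charges]
    for i in range(assembly.n_rotors):
        if i == rotor_index:
            continue
        static_xyz.append(assembly.posed_rotor_coords(i))
        static_q.append(assembly.rotors[i][0].charges)
    moving_xyz = assembly.posed_rotor_coords(rotor_index)
    moving_q = assembly.rotors[rotor_index][0].charges
    return (np.vstack(static_xyz), np.concatenate(static_q), moving_xyz, moving_q)


def _grid_energy(static_xyz, static_q, moving_xyz, moving_q, model,
                 rot_deg: float, dz: float = 0.0) -> float:
    xyz = moving_xyz @ rot_z(rot_deg).T
    if dz:
        xyz = xyz + np.array([0.0, 0.0, dz])
    diff = static_xyz[:, None, :] - xyz[None, :, :]
    r = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    steric, elec = _pair_terms(r, np.outer(static_q, moving_q), model)
    return float(steric.sum() + elec.sum())


def scan_rotation(assembly: AxleRotorAssembly, step_deg: float = 1.0,
                  model: EnergyModel | None = None, rotor_index: int = 0,
                  trans_z: float = 0.0) -> Landscape1D:
    """Interface energy versus rotation of one rotor about z.

    The grid rotation is applied on top of the rotor's pose (about the global
    z axis), with all other DOFs fixed.  Clashing poses are kept — their
    steric term is capped per pair — so the landscape is total on the grid.
    """
    m = model or EnergyModel()
    grid = _rotation_grid(step_deg)
    blocks = _scan_blocks(assembly, rotor_index)
    energy = np.array([_grid_energy(*blocks, m, g, trans_z) for g in grid])
    meta = {"model": asdict(m), "rotor_index": rotor_index, "trans_z": trans_z,
            "label": assembly.label}
    return Landscape1D("rot_z", grid, energy, periodic=True, model_meta=meta)


def scan_rotation_translation(assembly: AxleRotorAssembly, rot_step: float = 1.0,
                              trans_range: float = 10.0, trans_step: float = 0.5,
                              model: EnergyModel | None = None,
                              rotor_index: int = 0) -> Landscape2D:
    """Energy over the product grid: rotation about z x translation along z."""
    m = model or EnergyModel()
    rot_grid = _rotation_grid(rot_step)
    n_half = int(round(trans_range / trans_step))
    trans_grid = np.arange(-n_half, n_half + 1) * trans_step
    blocks = _scan_blocks(assembly, rotor_index)
    energy = np.empty((len(rot_grid), len(trans_grid)))
    for i, g in enumerate(rot_grid):
        for j, dz in enumerate(trans_grid):
            energy[i, j] = _grid_energy(*blocks, m, g, dz)
    meta = {"model": asdict(m), "rotor_index": rotor_index, "label": assembly.label}
    return Landscape2D(rot_grid, trans_grid, energy, model_meta=meta)


def dynamic_range(landscape: Landscape1D | Landscape2D) -> float:
    """max - min of the tabulated energy (kcal/mol)."""
    if landscape.energy.size == 0:
        raise ParameterError("empty landscape")
    return float(landscape.energy.max() - landscape.energy.min())


def _circular_runs(energy: np.ndarray, merge_tol: float) -> list[np.ndarray]:
    """Split the circular grid into plateau runs chained within merge_tol."""
    n = len(energy)
    breaks = np.nonzero(np.abs(np.diff(energy, append=energy[0])) > merge_tol)[0]
    if len(breaks) == 0:
        return [np.arange(n)]
    runs = []
    # runs start just after each break; wrap the final run onto the first
    starts = (breaks + 1) % n
    for k in range(len(starts)):
        a = starts[k]
        b = starts[(k + 1) % len(starts)]
        runs.append(np.arange(a, b if b > a else b + n) % n)
    return runs


def find_local_minima(landscape: Landscape1D, merge_tol: float = 1e-9,
                      principal_fraction: float = 0.10) -> LandscapeFeatures:
    """Strict circular local minima, plateaus merged to their centroid.

    A plateau run (grid points equal within ``merge_tol``, chained) is a
    minimum iff its level is strictly below both circular neighbor runs.
    Principal minima lie within ``principal_fraction`` of the dynamic range
    above the global minimum.  A flat landscape has zero minima by
    convention.
    """
    if not landscape.periodic:
        raise ParameterError("minima detection assumes a periodic landscape")
    e = landscape.energy
    grid = landscape.grid
    n = len(e)
    runs = _circular_runs(e, merge_tol)
    positions, levels = [], []
    if len(runs) > 1:
        run_levels = [float(e[r].mean()) for r in runs]
        for k, r in enumerate(runs):
            prev = run_levels[(k - 1) % len(runs)]
            nxt = run_levels[(k + 1) % len(runs)]
            if run_levels[k] < prev and run_levels[k] < nxt:
                # circular centroid of the run (runs were built unwrapped)
                first = r[0]
                span = np.arange(first, first + len(r))
                pos = (grid[0] + landscape.step * span.mean()) % 360.0
                positions.append(pos)
                levels.append(run_levels[k])
    order = np.argsort(positions)
    positions = np.asarray(positions, dtype=float)[order]
    levels = np.asarray(levels, dtype=float)[order]
    count = len(positions)
    drange = float(e.max() - e.min())
    if count:
        thresh = e.min() + principal_fraction * drange
        principal = levels <= thresh + 1e-12
    else:
        principal = np.zeros(0, dtype=bool)
    amplitudes, dominant = frequency_spectrum(landscape)
    return LandscapeFeatures(
        minima_positions=positions,
        minima_count=count,
        principal_minima_count=int(principal.sum()),
        principal_positions=positions[principal],
        mean_spacing=float(360.0 / count) if count else float("nan"),
        dynamic_range=drange,
        dominant_mode=dominant,
        mode_amplitudes=amplitudes,
    )


def frequency_spectrum(landscape: Landscape1D) -> tuple[np.ndarray, int]:
    """One-sided DFT amplitudes |c_k| of the mean-subtracted energy.

    Returns amplitudes for k = 0 .. N//2 (normalized so that the full
    two-sided sum of |c_k|^2 equals the grid variance) and the dominant
    integer harmonic (argmax over k >= 1; ties break to the smallest k).
    """
    if not landscape.periodic:
        raise ParameterError("spectrum assumes a periodic uniform grid")
    e = landscape.energy - landscape.energy.mean()
    n = len(e)
    c = np.fft.rfft(e) / n
    amps = np.abs(c)
    if n // 2 >= 1:
        dominant = int(np.argmax(amps[1:n // 2 + 1])) + 1
    else:
        dominant = 0
    return amps, dominant


_ROT_AXES = {"rot_x": rot_x, "rot_y": rot_y, "rot_z": rot_z}
_TRANS_AXES = {"trans_x": 0, "trans_y": 1, "trans_z": 2}


def classify_dofs(assembly: AxleRotorAssembly, model: EnergyModel | None = None,
                  kT: float = KT_ROOM, rotor_index: int = 0,
                  rot_step: float = 5.0, trans_range: float = 10.0,
                  trans_step: float = 0.5, access_factor: float = 3.0,
                  min_span_rot: float = 0.5, min_span_trans: float = 0.2,
                  ) -> set[str]:
    """Which rigid-body DOFs the rotor can explore thermally.

    A DOF is accessible iff the scanned energy stays within
    ``access_factor * kT`` of its minimum over at least the minimum span of
    the scan range (50% for rotations over the full turn, 20% for
    translations over +/- ``trans_range``).  Rotations about x and y pivot
    at the rotor centroid; rot_z uses the machine axis.
    """
    m = model or EnergyModel()
    static_xyz, static_q, moving_xyz, moving_q = _scan_blocks(assembly, rotor_index)
    centroid = moving_xyz.mean(axis=0)
    accessible = set()

    def band_fraction(energies: np.ndarray) -> float:
        return float(np.mean(energies <= energies.min() + access_factor * kT))

    for dof, rot_fn in _ROT_AXES.items():
        grid = _rotation_grid(rot_step)
        energies = np.empty(len(grid))
        for i, g in enumerate(grid):
            if dof == "rot_z":
                xyz = moving_xyz @ rot_fn(g).T
            else:
                xyz = (moving_xyz - centroid) @ rot_fn(g).T + centroid
            diff = static_xyz[:, None, :] - xyz[None, :, :]
            r = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
            s, el = _pair_terms(r, np.outer(static_q, moving_q), m)
            energies[i] = s.sum() + el.sum()
        if band_fraction(energies) >= min_span_rot:
            accessible.add(dof)

    n_half = int(round(trans_range / trans_step))
    offsets = np.arange(-n_half, n_half + 1) * trans_step
    for dof, axis in _TRANS_AXES.items():
        energies = np.empty(len(offsets))
        for i, off in enumerate(offsets):
            shift = np.zeros(3)
            shift[axis] = off
            xyz = moving_xyz + shift
            diff = static_xyz[:, None, :] - xyz[None, :, :]
            r = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
            s, el = _pair_terms(r, np.outer(static_q, moving_q), m)
            energies[i] = s.sum() + el.sum()
        if band_fraction(energies) >= min_span_trans:
            accessible.add(dof)
    return accessible
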