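"""Brownian (overdamped Langevin) rotor dynamics on a computed landscape.

The rotor coordinate (rot_z by default) diffuses on the periodic interface
energy landscape by Euler-Maruyama:

    theta_{t+1} = theta_t - (D / kT) E'(theta_t) dt + sqrt(2 D dt) xi_t

with E' taken from a periodic cubic-spline interpolation of the scanned
landscape.  Time is in reduced units; D is a rotational diffusion constant
in deg^2 per time unit.  This is an explicit, simplified stand-in for
all-atom molecular dynamics: it preserves the Boltzmann measure on the
landscape and nothing else.

Also here: MSD analysis, well occupancancy versus Boltzmann expectation,
i.i.d. Boltzmann ensembles, and simulated 2D projection averages over
conformational ensembles (the computational analogue of class averages).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from ._geometry import ParameterError, rot_z
from .landscape import KT_ROOM, Landscape1D
from .symmetry import AxleRotorAssembly, Component, RigidPose, pose_transform

__all__ = [
    "BrownianParams",
    "BrownianTrajectory",
    "simulate_brownian",
    "simulate_brownian_ensemble",
    "msd",
    "well_occupancy",
    "boltzmann_ensemble",
    "render_projection",
]

#: Euler-Maruyama stability guard: max drift per step, deg
MAX_DRIFT_PER_STEP = 5.0


class StabilityError(ValueError):
    """The drift per step exceeds the stability guard; reduce dt."""


@dataclass(frozen=True)
class BrownianParams:
    """Integration parameters (reduced time units; angles in deg)."""

    diffusion: float = 100.0   # deg^2 per time unit (or A^2 for translations)
    kT: float = KT_ROOM        # kcal/mol
    dt: float = 1e-3
    n_steps: int = 10000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.diffusion < 0 or self.dt <= 0 or self.kT <= 0:
            raise ParameterError("diffusion >= 0, dt > 0 and kT > 0 required")
        if self.n_steps < 1:
            raise ParameterError("n_steps must be >= 1")


@dataclass
class BrownianTrajectory:
    """Time series of one DOF; bit-reproducible from (seed, params, landscape)."""

    dof: str
    values_unwrapped: np.ndarray   # length n_steps + 1
    params: BrownianParams
    meta: dict = field(default_factory=dict)

    @property
    def values_wrapped(self) -> np.ndarray:
        return np.mod(self.values_unwrapped, 360.0)

    def __len__(self) -> int:
        return len(self.values_unwrapped)


def _force_table(landscape: Landscape1D, refine: int = 4
                 ) -> tuple[np.ndarray, float]:
    """-dE/dtheta on a refined uniform grid from a periodic cubic spline."""
    if not landscape.periodic:
        raise ParameterError("Brownian simulation expects a periodic landscape")
    grid = np.append(landscape.grid, landscape.grid[0] + 360.0)
    energy = np.append(landscape.energy, landscape.energy[0])
    spline = CubicSpline(grid, energy, bc_type="periodic")
    h = landscape.step / refine
    fine = np.arange(0.0, 360.0 + h / 2, h)
    force = -spline.derivative()(fine)
    force[-1] = force[0]
    return force, h


def _drift_guard(force: np.ndarray, params: BrownianParams) -> None:
    max_drift = params.diffusion * params.dt / params.kT * np.max(np.abs(force))
    if max_drift >= MAX_DRIFT_PER_STEP:
        raise StabilityError(
            f"drift per step {max_drift:.2f} deg exceeds {MAX_DRIFT_PER_STEP} deg; "
            "use a smaller dt"
        )


def simulate_brownian(landscape: Landscape1D, params: BrownianParams,
                      theta0: float = 0.0) -> BrownianTrajectory:
    """Single Euler-Maruyama trajectory on the landscape (unwrapped record)."""
    force, h = _force_table(landscape)
    _drift_guard(force, params)
    rng = np.random.default_rng(params.seed)
    noise = rng.standard_normal(params.n_steps) * np.sqrt(2.0 * params.diffusion * params.dt)
    c = params.diffusion * params.dt / params.kT
    ntab = len(force) - 1
    out = np.empty(params.n_steps + 1)
    out[0] = x = float(theta0)
    for i in range(params.n_steps):
        u = (x % 360.0) / h
        j = int(u)
        if j >= ntab:
            j = ntab - 1
        f = force[j] + (force[j + 1] - force[j]) * (u - j)
        x += c * f + noise[i]
        out[i + 1] = x
    return BrownianTrajectory(landscape.dof, out, params,
                              meta={"theta0": theta0})


def simulate_brownian_ensemble(landscape: Landscape1D, params: BrownianParams,
                               theta0: np.ndarray) -> np.ndarray:
    """Vectorized replica ensemble; returns (n_steps+1, n_replicas) unwrapped.

    Replica r uses the common seed stream (one Gaussian block per step), so
    the ensemble is reproducible as a whole.
    """
    force, h = _force_table(landscape)
    _drift_guard(force, params)
    theta0 = np.asarray(theta0, dtype=float)
    rng = np.random.default_rng(params.seed)
    amp = np.sqrt(2.0 * params.diffusion * params.dt)
    c = params.diffusion * params.dt / params.kT
    ntab = len(force) - 1
    out = np.empty((params.n_steps + 1, len(theta0)))
    out[0] = x = theta0.copy()
    for i in range(params.n_steps):
        u = np.mod(x, 360.0) / h
        j = np.minimum(u.astype(int), ntab - 1)
        f = force[j] + (force[j + 1] - force[j]) * (u - j)
        x = x + c * f + amp * rng.standard_normal(len(x))
        out[i + 1] = x
    return out


def msd(trajectories, lag: int) -> float:
    """Time-and-ensemble averaged squared displacement at an integer lag.

    Accepts a BrownianTrajectory, an unwrapped 1D array, a list of either,
    or a 2D (time, replica) array.  Uses unwrapped values.
    """
    if isinstance(trajectories, BrownianTrajectory):
        arrays = [trajectories.values_unwrapped]
    elif isinstance(trajectories, np.ndarray) and trajectories.ndim == 2:
        arrays = [trajectories[:, k] for k in range(trajectories.shape[1])]
    elif isinstance(trajectories, np.ndarray):
        arrays = [trajectories]
    else:
        arrays = [t.values_unwrapped if isinstance(t, BrownianTrajectory)
                  else np.asarray(t, dtype=float) for t in trajectories]
    if lag < 0 or any(lag >= len(a) for a in arrays):
        raise ParameterError("lag must satisfy 0 <= lag < trajectory length")
    if lag == 0:
        return 0.0
    total, count = 0.0, 0
    for a in arrays:
        d = a[lag:] - a[:-lag]
        total += float(np.sum(d * d))
        count += len(d)
    return total / count


def well_occupancy(samples, minima_positions, assignment_width: float | None = None,
                   burn_in_fraction: float = 0.1) -> tuple[np.ndarray, float]:
    """Fraction of samples assigned to each well, plus unassigned mass.

    ``samples`` is a trajectory or an array of rot_z values (deg); the first
    ``burn_in_fraction`` is discarded for trajectories.  A sample belongs to
    the nearest minimum if its circular distance is within the assignment
    width (default: half the minimum spacing between wells).
    """
    if isinstance(samples, BrownianTrajectory):
        values = samples.values_wrapped
        values = values[int(burn_in_fraction * len(values)):]
    else:
        values = np.mod(np.asarray(samples, dtype=float), 360.0)
    minima = np.mod(np.asarray(minima_positions, dtype=float), 360.0)
    if minima.size == 0:
        raise ParameterError("at least one well position is required")
    if assignment_width is None:
        if len(minima) > 1:
            s = np.sort(minima)
            gaps = np.diff(np.append(s, s[0] + 360.0))
            assignment_width = float(gaps.min()) / 2.0
        else:
            assignment_width = 180.0
    d = np.abs(values[:, None] - minima[None, :])
    d = np.minimum(d, 360.0 - d)
    nearest = np.argmin(d, axis=1)
    within = d[np.arange(len(values)), nearest] <= assignment_width
    probs = np.array([np.mean(within & (nearest == k)) for k in range(len(minima))])
    return probs, float(1.0 - probs.sum())


def boltzmann_ensemble(landscape: Landscape1D, kT: float = KT_ROOM,
                       n_samples: int = 1, seed: int = 0) -> np.ndarray:
    """i.i.d. grid samples with probability proportional to exp(-E/kT)."""
    if n_samples < 1:
        raise ParameterError("n_samples must be >= 1")
    e = landscape.energy - landscape.energy.min()
    w = np.exp(-e / kT)
    cdf = np.cumsum(w)
    cdf /= cdf[-1]
    rng = np.random.default_rng(seed)
    idx = np.searchsorted(cdf, rng.random(n_samples), side="right")
    return landscape.grid[np.minimum(idx, len(cdf) - 1)]


_PROJECTIONS = {"z": (0, 1), "x": (1, 2), "y": (0, 2)}


def render_projection(obj: Component | AxleRotorAssembly, view_axis: str = "z",
                      poses=None, pixel_size: float = 2.0, blur_sigma: float = 3.0,
                      shape: tuple[int, int] | None = None) -> np.ndarray:
    """Orthographic Gaussian-splat projection averaged over poses.

    ``poses`` is a list of RigidPose or an array of rot_z angles (deg); None
    means the identity pose.  Each atom contributes a unit-integral Gaussian
    of width ``blur_sigma`` (A), so each per-pose image integrates to the
    atom count and so does the average.  Averaging over an ensemble of rot_z
    samples is the computational analogue of conformational variability in
    2D class averages.
    """
    if blur_sigma < pixel_size:
        raise ParameterError("blur_sigma must be >= pixel_size for faithful splatting")
    if view_axis not in _PROJECTIONS:
        raise ParameterError(f"view_axis must be one of {sorted(_PROJECTIONS)}")
    base = obj.all_coords if isinstance(obj, AxleRotorAssembly) else obj.coords
    if base.shape[0] == 0:
        raise ParameterError("nothing to project")
    if poses is None:
        pose_list = [np.eye(3)]
        shifts = [np.zeros(3)]
    elif isinstance(poses, (list, tuple)) and poses and isinstance(poses[0], RigidPose):
        pose_list, shifts = zip(*(pose_transform(p) for p in poses))
    else:
        angles = np.atleast_1d(np.asarray(poses, dtype=float))
        if angles.size == 0:
            raise ParameterError("poses must be non-empty")
        pose_list = [rot_z(a) for a in angles]
        shifts = [np.zeros(3)] * len(pose_list)

    ax = _PROJECTIONS[view_axis]
    pts = [(base @ R.T + t)[:, ax] for R, t in zip(pose_list, shifts)]
    allpts = np.vstack(pts)
    margin = 4.0 * blur_sigma
    lo = allpts.min(axis=0) - margin
    hi = allpts.max(axis=0) + margin
    need = tuple(int(np.ceil((hi[k] - lo[k]) / pixel_size)) + 1 for k in (1, 0))
    if shape is None:
        shape = need
    elif shape[0] < need[0] or shape[1] < need[1]:
        raise ParameterError(f"pixel grid {shape} too small; requires at least {need}")
    center = (lo + hi) / 2.0
    ny, nx = shape
    x0 = center[0] - (nx - 1) / 2.0 * pixel_size
    y0 = center[1] - (ny - 1) / 2.0 * pixel_size

    img = np.zeros((ny, nx))
    halfwin = int(np.ceil(4.0 * blur_sigma / pixel_size))
    amp = pixel_size ** 2 / (2.0 * np.pi * blur_sigma ** 2)
    inv2s2 = 1.0 / (2.0 * blur_sigma ** 2)
    for pt_block in pts:
        for px, py in pt_block:
            cx = int(round((px - x0) / pixel_size))
            cy = int(round((py - y0) / pixel_size))
            xs = np.arange(max(0, cx - halfwin), min(nx, cx + halfwin + 1))
            ys = np.arange(max(0, cy - halfwin), min(ny, cy + halfwin + 1))
            gx = x0 + xs * pixel_size - px
            gy = y0 + ys * pixel_size - py
            img[np.ix_(ys, xs)] += amp * np.exp(-(gy[:, None] ** 2 + gx[None, :] ** 2) * inv2s2)
    return img / len(pts)
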