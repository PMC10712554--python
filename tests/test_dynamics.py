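"""Brownian dynamics, equilibrium statistics and projection rendering."""
import numpy as np
import pytest
from scipy import stats

from rotaxle import ParameterError
from rotaxle.dynamics import (BrownianParams, StabilityError,
                              boltzmann_ensemble, msd, render_projection,
                              simulate_brownian, simulate_brownian_ensemble,
                              well_occupancy)
from rotaxle.fixtures import c3_rotor
from rotaxle.landscape import Landscape1D, find_local_minima

KT = 0.593


def vonmises_two_well(b1=2.0, k1=4.5, b2=3.0, k2=3.0):
    """Curvature-matched asymmetric double well (wells at 90 and 270 deg)."""
    def energy(th):
        t = np.radians(th)
        return (-b1 * np.exp(k1 * (np.cos(t - np.pi / 2) - 1))
                - b2 * np.exp(k2 * (np.cos(t - 3 * np.pi / 2) - 1)))
    return Landscape1D.from_function(energy, 1.0)


class TestSimulateBrownian:
    def test_zero_diffusion_on_flat_landscape_is_constant(self, flat_landscape):
        p = BrownianParams(diffusion=0.0, n_steps=100, seed=1)
        traj = simulate_brownian(flat_landscape, p, theta0=42.0)
        assert np.all(traj.values_unwrapped == 42.0)

    def test_same_seed_reproduces_bit_exactly(self, two_well_landscape):
        p = BrownianParams(diffusion=50.0, dt=0.01, n_steps=2000, seed=99)
        t1 = simulate_brownian(two_well_landscape, p, theta0=10.0)
        t2 = simulate_brownian(two_well_landscape, p, theta0=10.0)
        assert np.array_equal(t1.values_unwrapped, t2.values_unwrapped)

    def test_stability_guard_rejects_large_dt(self):
        steep = Landscape1D.from_function(
            lambda t: 30.0 * np.cos(np.radians(8 * t)), 1.0)
        with pytest.raises(StabilityError, match="dt"):
            simulate_brownian(steep, BrownianParams(diffusion=100.0, dt=1.0,
                                                    n_steps=10, seed=0))

    def test_free_diffusion_msd_matches_2dt(self, flat_landscape):
        """Ensemble MSD at lag t within 5% of 2 D t (200 replicas)."""
        D = 100.0
        p = BrownianParams(diffusion=D, dt=1e-3, n_steps=20000, seed=42)
        ens = simulate_brownian_ensemble(flat_landscape, p, np.zeros(200))
        lag = 1000
        expected = 2.0 * D * lag * p.dt
        assert msd(ens, lag) == pytest.approx(expected, rel=0.05)

    def test_free_diffusion_msd_slope(self, flat_landscape):
        """Fitted MSD slope within 5% of 2D over 200 replicas."""
        D = 100.0
        p = BrownianParams(diffusion=D, dt=1e-3, n_steps=20000, seed=7)
        ens = simulate_brownian_ensemble(flat_landscape, p, np.zeros(200))
        lags = np.array([100, 200, 300, 400, 500])
        msds = [msd(ens, int(k)) for k in lags]
        slope = np.polyfit(lags * p.dt, msds, 1)[0]
        assert slope == pytest.approx(2.0 * D, rel=0.05)


class TestMSD:
    def test_lag_zero_and_constant_trajectory(self, flat_landscape):
        p = BrownianParams(diffusion=0.0, n_steps=50, seed=3)
        traj = simulate_brownian(flat_landscape, p, theta0=5.0)
        assert msd(traj, 0) == 0.0
        assert msd(traj, 25) == 0.0

    def test_monotone_in_lag_for_free_diffusion(self, flat_landscape):
        p = BrownianParams(diffusion=100.0, dt=1e-3, n_steps=5000, seed=21)
        ens = simulate_brownian_ensemble(flat_landscape, p, np.zeros(100))
        msds = [msd(ens, k) for k in (100, 400, 900, 1600, 2500)]
        assert np.all(np.diff(msds) > 0)

    def test_lag_out_of_range(self, flat_landscape):
        p = BrownianParams(diffusion=1.0, n_steps=10, seed=0)
        traj = simulate_brownian(flat_landscape, p)
        with pytest.raises(ParameterError):
            msd(traj, 11)


class TestEquilibrium:
    def test_detailed_balance_total_variation(self, two_well_landscape):
        """Long-run wrapped histogram matches exp(-E/kT): TV < 0.05."""
        p = BrownianParams(diffusion=100.0, dt=0.1, n_steps=1_000_000, seed=7)
        traj = simulate_brownian(two_well_landscape, p, theta0=90.0)
        wrapped = traj.values_wrapped[100_000:]
        bins = np.arange(0.0, 361.0, 10.0)
        hist, _ = np.histogram(wrapped, bins=bins)
        emp = hist / hist.sum()
        centers = (bins[:-1] + bins[1:]) / 2.0
        # bin-averaged Boltzmann weights on the same 10-deg bins
        w = np.exp(-two_well_landscape.energy / KT).reshape(36, 10).mean(axis=1)
        assert len(centers) == len(w)
        w = w / w.sum()
        tv = 0.5 * np.abs(emp - w).sum()
        assert tv < 0.05

    def test_degenerate_wells_equally_occupied(self, two_well_landscape):
        """Two symmetric wells are equiprobable: the two-state degenerate limit.

        The binomial sigma uses the number of observed well transitions —
        the effective number of independent well assignments in a correlated
        trajectory.
        """
        p = BrownianParams(diffusion=100.0, dt=0.1, n_steps=1_000_000, seed=13)
        traj = simulate_brownian(two_well_landscape, p, theta0=90.0)
        f = find_local_minima(two_well_landscape)
        assert f.minima_count == 2
        probs, unassigned = well_occupancy(traj, f.minima_positions)
        assert unassigned == pytest.approx(0.0, abs=1e-12)
        wrapped = traj.values_wrapped[100_000:]
        # hysteresis labelling (flips only in well cores) so rapid boundary
        # recrossings do not inflate the effective sample count
        core0 = np.minimum(np.abs(wrapped - 90.0), 360 - np.abs(wrapped - 90.0)) < 45
        core1 = np.minimum(np.abs(wrapped - 270.0), 360 - np.abs(wrapped - 270.0)) < 45
        raw = np.where(core0, 0, np.where(core1, 1, -1))
        idx = np.where(raw >= 0, np.arange(len(raw)), 0)
        np.maximum.accumulate(idx, out=idx)
        labels = raw[idx]
        n_eff = max(int(np.count_nonzero(np.diff(labels[labels >= 0]))), 1)
        # renewal-process sigma for the occupancy difference: 1/sqrt(n_eff)
        assert abs(probs[0] - probs[1]) < 3.0 / np.sqrt(n_eff)

    def test_two_well_boltzmann_ratio(self):
        """Occupancy ratio matches the discrete Boltzmann basin oracle.

        Oracle: direct summation of exp(-E/kT) over each basin's grid
        points, independent of the sampler.  The ideal two-state formula
        exp(-dE/kT) ignores basin-shape prefactors, so it is asserted only
        as a scale check.
        """
        ls = vonmises_two_well()  # depths 2 and 3 kcal/mol -> dE = 1
        p = BrownianParams(diffusion=100.0, dt=0.05, n_steps=1_000_000, seed=11)
        traj = simulate_brownian(ls, p, theta0=270.0)
        f = find_local_minima(ls)
        probs, _ = well_occupancy(traj, f.minima_positions)
        ratio = probs[0] / probs[1]  # upper (shallow) over lower (deep)
        w = np.exp(-(ls.energy - ls.energy.min()) / KT)
        upper = (ls.grid > 0) & (ls.grid < 180)
        oracle = w[upper].sum() / w[~upper].sum()
        assert ratio == pytest.approx(oracle, rel=0.10)
        assert ratio == pytest.approx(np.exp(-1.0 / KT), rel=0.25)


class TestBoltzmannEnsemble:
    def test_flat_landscape_is_uniform(self, flat_landscape):
        samples = boltzmann_ensemble(flat_landscape, n_samples=100_000, seed=5)
        hist, _ = np.histogram(samples, bins=np.arange(0.0, 361.0, 10.0))
        assert stats.chisquare(hist).pvalue > 0.01

    def test_zero_temperature_collapses_to_global_minimum(self, two_well_landscape):
        e = two_well_landscape.energy.copy()
        e[200] = e.min() - 0.5  # unique global minimum at 200 deg
        ls = Landscape1D("rot_z", two_well_landscape.grid, e)
        samples = boltzmann_ensemble(ls, kT=1e-9, n_samples=1000, seed=2)
        assert np.all(samples == ls.grid[200])

    def test_degenerate_wells_split_half_half(self, two_well_landscape):
        n = 1_000_000
        samples = boltzmann_ensemble(two_well_landscape, n_samples=n, seed=17)
        f = find_local_minima(two_well_landscape)
        # width just under the half-spacing excludes the two grid points
        # exactly equidistant from both wells (their tie-break is arbitrary)
        probs, _ = well_occupancy(samples, f.minima_positions,
                                  assignment_width=89.5)
        sigma = np.sqrt(0.25 / n)
        assert abs(probs[0] - probs[1]) < 2 * 3 * sigma


class TestRenderProjection:
    def test_single_atom_peaks_at_image_centre(self):
        from rotaxle.components import build_point_feature_model
        comp = build_point_feature_model(1, 0.0)
        img = render_projection(comp, pixel_size=1.0, blur_sigma=2.0)
        peak = np.unravel_index(np.argmax(img), img.shape)
        assert peak == ((img.shape[0] - 1) // 2, (img.shape[1] - 1) // 2)

    def test_intensity_conserved_under_pose_averaging(self):
        rotor = c3_rotor(28.0)
        rng = np.random.default_rng(0)
        img = render_projection(rotor, view_axis="z",
                                poses=rng.uniform(0, 360, 50),
                                pixel_size=1.0, blur_sigma=1.5)
        assert img.sum() == pytest.approx(rotor.n_residues, rel=1e-3)

    def test_rotational_averaging_blurs_azimuthal_structure(self):
        """Boltzmann averaging on a flat landscape erases the arm signature."""
        rotor = c3_rotor(28.0)
        flat = Landscape1D("rot_z", np.arange(0.0, 360.0, 1.0), np.zeros(360))
        samples = boltzmann_ensemble(flat, n_samples=200, seed=4)
        single = render_projection(rotor, view_axis="z", pixel_size=1.0,
                                   blur_sigma=1.5)
        averaged = render_projection(rotor, view_axis="z", poses=samples,
                                     pixel_size=1.0, blur_sigma=1.5)

        def ring_variance(img):
            ny, nx = img.shape
            cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
            ang = np.linspace(0, 2 * np.pi, 360, endpoint=False)
            r = rotor.metadata["ring_radius"]
            ys, xs = cy + r * np.sin(ang), cx + r * np.cos(ang)
            i0, j0 = np.floor(ys).astype(int), np.floor(xs).astype(int)
            fy, fx = ys - i0, xs - j0
            v = (img[i0, j0] * (1 - fy) * (1 - fx) + img[i0 + 1, j0] * fy * (1 - fx)
                 + img[i0, j0 + 1] * (1 - fy) * fx + img[i0 + 1, j0 + 1] * fy * fx)
            return v.var()

        assert ring_variance(single) >= 10.0 * ring_variance(averaged)

    def test_undersized_pixel_grid_rejected(self):
        rotor = c3_rotor(28.0)
        with pytest.raises(ParameterError, match="requires at least"):
            render_projection(rotor, pixel_size=1.0, blur_sigma=1.5,
                              shape=(4, 4))
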