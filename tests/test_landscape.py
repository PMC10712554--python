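"""Landscape scans, minima detection, spectra and DOF classification."""
import math

import numpy as np
import pytest

from rotaxle import ParameterError
from rotaxle.fixtures import demo_model, point_pair_assembly
from rotaxle.landscape import (Landscape1D, classify_dofs, dynamic_range,
                               find_local_minima, frequency_spectrum,
                               scan_rotation, scan_rotation_translation)
from rotaxle.symmetry import landscape_period


def _empirical_period(landscape, tol=1e-9):
    """Oracle: smallest grid shift under which the scan maps onto itself."""
    e = landscape.energy
    n = len(e)
    for k in range(1, n + 1):
        if n % k:
            continue
        if np.max(np.abs(np.roll(e, k) - e)) < tol:
            return k * landscape.step
    return 360.0


class TestScanRotation:
    def test_c3_point_models_have_120deg_period(self):
        asm = point_pair_assembly(3, 3)
        ls = scan_rotation(asm, step_deg=1.0)
        assert np.max(np.abs(np.roll(ls.energy, 120) - ls.energy)) < 1e-6

    def test_noninteracting_components_give_flat_landscape(self):
        asm = point_pair_assembly(3, 5, axle_radius=10.0, rotor_radius=100.0)
        ls = scan_rotation(asm, step_deg=2.0)
        assert dynamic_range(ls) < 1e-9

    def test_grid_refinement_preserves_existing_points(self, c5c3):
        coarse = scan_rotation(c5c3, step_deg=2.0)
        fine = scan_rotation(c5c3, step_deg=1.0)
        assert np.allclose(fine.energy[::2], coarse.energy, atol=1e-12)

    def test_invalid_step_rejected(self, c5c3):
        with pytest.raises(ParameterError):
            scan_rotation(c5c3, step_deg=-1.0)
        with pytest.raises(ParameterError):
            scan_rotation(c5c3, step_deg=7.0)  # does not divide 360


class TestScanRotationTranslation:
    def test_row_matches_1d_scan(self, d8c4):
        ls2 = scan_rotation_translation(d8c4, rot_step=5.0, trans_range=2.0,
                                        trans_step=1.0)
        j = list(ls2.trans_grid).index(1.0)
        ls1 = scan_rotation(d8c4, step_deg=5.0, trans_z=1.0)
        assert np.allclose(ls2.energy[:, j], ls1.energy, atol=1e-12)

    def test_loose_rotor_has_large_low_energy_area(self, d3c5):
        """Most of the rotation-translation grid is thermally accessible."""
        ls2 = scan_rotation_translation(d3c5, rot_step=10.0, trans_range=8.0,
                                        trans_step=1.0, model=demo_model("d3c5"))
        frac = np.mean(ls2.energy <= ls2.energy.min() + 0.593)
        assert frac > 0.5

    def test_tight_cogwheel_low_energy_band_is_narrow(self):
        """A rotor ring nested between two axle rings sits in a narrow z band."""
        from rotaxle.components import build_point_feature_model
        from rotaxle.fixtures import d8_point_axle
        from rotaxle.symmetry import RigidPose, compose_assembly
        axle = d8_point_axle(half_height=6.0)
        rotor = build_point_feature_model(4, 140.0, charge=1.0, role="rotor")
        asm = compose_assembly(axle, [(rotor, RigidPose())], label="cogwheel")
        ls2 = scan_rotation_translation(asm, rot_step=5.0, trans_range=8.0,
                                        trans_step=1.0)
        low = ls2.energy <= ls2.energy.min() + 0.593
        rows = np.nonzero(low.any(axis=0))[0]
        assert (rows.max() - rows.min()) <= 2  # <= 2 trans steps wide


class TestFindLocalMinima:
    def test_cos3_minima_positions(self):
        ls = Landscape1D.from_function(lambda t: np.cos(np.radians(3 * t)), 1.0)
        f = find_local_minima(ls)
        assert f.minima_count == 3
        assert np.allclose(f.minima_positions, [60.0, 180.0, 300.0], atol=1e-9)
        assert f.mean_spacing == pytest.approx(120.0)

    def test_flat_landscape_has_zero_minima(self, flat_landscape):
        f = find_local_minima(flat_landscape)
        assert f.minima_count == 0
        assert f.principal_minima_count == 0

    def test_plateau_merges_to_single_minimum(self):
        e = np.ones(360)
        e[100:110] = 0.0  # flat-bottomed well
        ls = Landscape1D("rot_z", np.arange(360.0), e)
        f = find_local_minima(ls)
        assert f.minima_count == 1
        assert f.minima_positions[0] == pytest.approx(104.5)

    def test_invariant_under_grid_origin_shift(self, c5c3):
        ls = scan_rotation(c5c3, step_deg=0.5)
        f0 = find_local_minima(ls)
        k = 100  # relabel theta = 0 at 50 deg
        shifted = Landscape1D("rot_z", ls.grid, np.roll(ls.energy, -k))
        f1 = find_local_minima(shifted)
        assert f1.minima_count == f0.minima_count
        expected = np.sort(np.mod(f0.minima_positions - k * ls.step, 360.0))
        assert np.allclose(f1.minima_positions, expected, atol=1e-6)

    @pytest.mark.parametrize("n, m", [(n, m) for n in range(1, 9)
                                      for m in range(n, 9) if n * m <= 40])
    def test_minima_count_equals_lcm_oracle(self, n, m):
        """Generic Cn x Cm scans carry lcm(n, m) wells; period matches too.

        The shift-matching period oracle needs a grid commensurate with the
        period, so the ~0.25 deg step is rounded to an exact divisor of
        360/lcm.
        """
        asm = point_pair_assembly(n, m)
        lcm = math.lcm(n, m)
        step = 360.0 / (lcm * max(1, round(1440 / lcm)))
        ls = scan_rotation(asm, step_deg=step)
        f = find_local_minima(ls)
        assert f.minima_count == lcm
        assert _empirical_period(ls, tol=1e-9) == pytest.approx(
            landscape_period(n, m), abs=ls.step)


class TestDynamicRangeAndSpectrum:
    def test_dynamic_range_examples(self):
        ls = Landscape1D("rot_z", np.arange(3.0), np.array([0.0, 1.0, 3.0]),
                         periodic=False)
        assert dynamic_range(ls) == 3.0
        shifted = Landscape1D("rot_z", np.arange(3.0), np.array([5.0, 6.0, 8.0]),
                              periodic=False)
        assert dynamic_range(shifted) == 3.0

    def test_cos8_dominant_mode(self):
        ls = Landscape1D.from_function(lambda t: np.cos(np.radians(8 * t)), 1.0)
        _, mode = frequency_spectrum(ls)
        assert mode == 8

    def test_c8_interface_dominant_mode_is_8(self):
        ls = scan_rotation(point_pair_assembly(8, 8), step_deg=0.5)
        _, mode = frequency_spectrum(ls)
        assert mode == 8

    @pytest.mark.parametrize("n", [2, 3, 5])
    def test_matched_scan_mode_is_multiple_of_n(self, n):
        ls = scan_rotation(point_pair_assembly(n, n), step_deg=0.5)
        _, mode = frequency_spectrum(ls)
        assert mode % n == 0

    def test_parseval_identity(self, c5c3):
        ls = scan_rotation(c5c3, step_deg=1.0)
        amps, _ = frequency_spectrum(ls)
        n = len(ls.energy)
        # two-sided power: interior harmonics count twice, Nyquist once
        power = amps[0]**2 + 2 * np.sum(amps[1:-1]**2)
        power += amps[-1]**2 if n % 2 == 0 else 2 * amps[-1]**2
        var = np.var(ls.energy)
        assert power == pytest.approx(var, rel=1e-9)

    def test_nonuniform_grid_rejected(self):
        with pytest.raises(ParameterError):
            Landscape1D("rot_z", np.array([0.0, 1.0, 3.0]), np.zeros(3))


class TestClassifyDofs:
    def test_tight_toy_rotates_and_slides_on_z_only(self, d3c3):
        accessible = classify_dofs(d3c3, model=demo_model("d3c3"))
        assert {"rot_z", "trans_z"} <= accessible
        assert not accessible & {"trans_x", "trans_y"}

    def test_loose_toy_opens_lateral_and_tilt_dofs(self, d3c5):
        accessible = classify_dofs(d3c5, model=demo_model("d3c5"))
        assert {"rot_z", "trans_z", "trans_x", "trans_y",
                "rot_x", "rot_y"} <= accessible

    def test_welded_rotor_has_no_accessible_dofs(self):
        """Deep wells everywhere freeze every DOF at small kT."""
        asm = point_pair_assembly(3, 3)
        accessible = classify_dofs(asm, kT=1e-4)
        assert accessible == set()
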