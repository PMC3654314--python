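"""Geometry: channel/angle transforms, scattering vectors, wavelength
selection and cell arithmetic."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from curvedpsd.geometry import (AngularPosition, Cell, DegenerateCellError,
                                DetectorGeometry, OutOfFaceError, ScanConfig,
                                angles_from_lab_vector, angles_to_channels,
                                cell_from_ub, cell_volume, channels_to_angles,
                                crystal_to_lab, d_spacing, ewald_crossings,
                                lab_to_crystal, monochromator_wavelength,
                                scattering_vector_lab,
                                total_scattering_angle)


class TestChannelAngleConversion:
    def test_origin_maps_to_arm_angle_on_equator(self, geom):
        ang = channels_to_angles(geom.x0, geom.y0, geom)
        assert ang.two_theta_b == pytest.approx(geom.arm_angle, abs=1e-12)
        assert ang.chi_d == pytest.approx(0.0, abs=1e-12)

    def test_hundred_channels_off_origin(self, printed_geom):
        # 100 channels to the right of the origin: 40 + 100*0.2614 deg
        ang = channels_to_angles(281.50, printed_geom.y0, printed_geom)
        assert ang.two_theta_b == pytest.approx(66.14, abs=1e-9)

    def test_elevation_tangent_relation(self, geom):
        # at the origin column the shear term vanishes:
        # chi_d = arctan(c_y * 100) = arctan(0.3917)
        ang = channels_to_angles(geom.x0, geom.y0 + 100.0, geom)
        assert ang.chi_d == pytest.approx(math.degrees(math.atan(0.3917)),
                                          abs=1e-9)
        assert ang.chi_d == pytest.approx(21.390, abs=1e-3)

    def test_equator_line_is_tilted_by_the_channel_slope(self, geom):
        # constant chi_d = 0 in raw channels: Y = y0 + slope*(X - x0)
        x = geom.x0 + 150.0
        y = geom.y0 + geom.xy_slope * 150.0
        assert channels_to_angles(x, y, geom).chi_d == pytest.approx(
            0.0, abs=1e-12)

    def test_inverse_of_origin_case(self, geom):
        x, y = angles_to_channels(AngularPosition(geom.arm_angle, 0.0), geom)
        assert x == pytest.approx(geom.x0, abs=1e-9)
        assert y == pytest.approx(geom.y0, abs=1e-9)

    def test_inverse_of_shifted_case(self, printed_geom):
        x, y = angles_to_channels(AngularPosition(66.14, 0.0), printed_geom)
        assert x == pytest.approx(281.50, abs=1e-9)
        # the equator at X = x0+100 sits slope*100 channels above y0
        assert y == pytest.approx(94.135 + 0.0041 * 100.0, abs=1e-9)

    @settings(max_examples=200, deadline=None)
    @given(x=st.floats(60.0, 460.0), y=st.floats(100.0, 360.0))
    def test_round_trip_is_identity(self, geom, x, y):
        ang = channels_to_angles(x, y, geom)
        x2, y2 = angles_to_channels(ang, geom)
        assert abs(x2 - x) < 1e-9 and abs(y2 - y) < 1e-9

    def test_round_trip_many_points_vectorized(self, geom):
        rng = np.random.default_rng(1)
        x = rng.uniform(60, 460, 1000)
        y = rng.uniform(100, 360, 1000)
        ang = channels_to_angles(x, y, geom)
        x2, y2 = angles_to_channels(ang, geom)
        assert np.max(np.abs(x2 - x)) < 1e-9
        assert np.max(np.abs(y2 - y)) < 1e-9

    def test_linear_small_angle_mode(self, geom):
        lin = replace(geom, chi_mode="linear")
        ang = channels_to_angles(geom.x0, geom.y0 + 50.0, lin)
        assert ang.chi_d == pytest.approx(math.degrees(0.003917 * 50), rel=1e-12)

    def test_non_finite_input_rejected(self, geom):
        with pytest.raises(ValueError):
            channels_to_angles(float("nan"), 100.0, geom)

    def test_off_face_angle_raises_with_coordinates(self, geom):
        with pytest.raises(OutOfFaceError) as err:
            angles_to_channels(AngularPosition(179.0, 0.0), geom)
        assert err.value.x is not None

    def test_out_of_window_points_convert_but_flag(self, geom):
        assert not geom.contains(10.0, 10.0)
        ang = channels_to_angles(10.0, 10.0, geom)
        assert math.isfinite(ang.two_theta_b)


class TestScatteringVectors:
    def test_forward_beam_is_null(self):
        q = scattering_vector_lab(AngularPosition(0.0, 0.0), 1.0)
        assert np.allclose(q, 0.0)

    def test_equatorial_closed_form(self):
        q = scattering_vector_lab(AngularPosition(60.0, 0.0), 1.0)
        assert np.linalg.norm(q) == pytest.approx(1.0, abs=1e-12)

    def test_inclined_spot_magnitude(self):
        # cos 2theta = cos30 cos60 -> 2theta = 64.3411, |Q| = 2 sin(theta)
        q = scattering_vector_lab(AngularPosition(60.0, 30.0), 1.0)
        ang2t = total_scattering_angle(AngularPosition(60.0, 30.0))
        assert ang2t == pytest.approx(64.3411, abs=1e-4)
        assert np.linalg.norm(q) == pytest.approx(1.0648824, abs=1e-6)

    @pytest.mark.parametrize("tt,chi", [(25.0, 5.0), (80.0, -30.0),
                                        (140.0, 40.0), (60.0, 0.0)])
    def test_total_angle_identity(self, tt, chi):
        # |Q| = 2 sin(theta)/lambda with cos 2theta = cos chi cos 2theta_B
        lam = 1.153
        q = scattering_vector_lab(AngularPosition(tt, chi), lam)
        two_theta = total_scattering_angle(AngularPosition(tt, chi))
        assert np.linalg.norm(q) == pytest.approx(
            2.0 * math.sin(math.radians(two_theta / 2)) / lam, abs=1e-12)

    def test_angles_round_trip(self):
        ang = AngularPosition(73.2, -17.5)
        q = scattering_vector_lab(ang, 1.3)
        back = angles_from_lab_vector(q, 1.3)
        assert back.two_theta_b == pytest.approx(73.2, abs=1e-10)
        assert back.chi_d == pytest.approx(-17.5, abs=1e-10)


class TestCrystalFrameRotation:
    def test_zero_rotation_is_identity(self):
        v = np.array([0.3, -0.2, 0.5])
        assert np.allclose(lab_to_crystal(v, 0.0), v)

    def test_full_turn_is_identity(self):
        v = np.array([0.3, -0.2, 0.5])
        assert np.allclose(lab_to_crystal(v, 360.0), v, atol=1e-12)

    def test_quarter_turn(self):
        assert np.allclose(lab_to_crystal([1.0, 0.0, 0.0], 90.0),
                           [0.0, -1.0, 0.0], atol=1e-12)

    def test_norm_preserved_and_composition(self):
        rng = np.random.default_rng(3)
        v = rng.normal(size=3)
        a, b = 37.3, 121.9
        v1 = lab_to_crystal(lab_to_crystal(v, a), b)
        v2 = lab_to_crystal(v, a + b)
        assert np.allclose(v1, v2, atol=1e-12)
        assert np.linalg.norm(v1) == pytest.approx(np.linalg.norm(v),
                                                   abs=1e-12)

    def test_inverse_pair(self):
        v = np.array([0.1, 0.7, -0.3])
        assert np.allclose(crystal_to_lab(lab_to_crystal(v, 55.0), 55.0), v,
                           atol=1e-13)


class TestEwaldCrossings:
    def test_outside_sphere_no_solution(self):
        assert ewald_crossings(np.array([2.1, 0, 0]), 1.0) == []

    def test_rotation_axis_blind(self):
        assert ewald_crossings(np.array([0.0, 0.0, 0.5]), 1.0) == []

    def test_crossings_satisfy_diffraction_condition(self):
        lam = 1.153
        q = np.array([0.4, 0.2, 0.3])
        sols = ewald_crossings(q, lam)
        assert len(sols) == 2
        for phi, branch in sols:
            q_lab = crystal_to_lab(q, phi)
            assert q_lab[0] == pytest.approx(-lam * (q @ q) / 2, abs=1e-12)
            assert branch in ("entry", "exit")


class TestMonochromator:
    @pytest.mark.parametrize("plane,lam", [((3, 1, 1), 1.153),
                                           ((5, 1, 1), 0.7358),
                                           ((4, 2, 2), 0.7804)])
    def test_published_wavelengths(self, plane, lam):
        assert monochromator_wavelength(plane) == pytest.approx(
            lam, rel=5e-4)

    def test_ge111_bragg_value(self):
        # the computed Bragg value; the instrument's nominal 2.204 A is
        # 0.17% away for any standard Ge lattice constant
        assert monochromator_wavelength((1, 1, 1)) == pytest.approx(
            2.2075, abs=5e-4)

    def test_out_of_zone_plane_warns(self):
        with pytest.warns(UserWarning):
            monochromator_wavelength((1, 2, 0))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            monochromator_wavelength((0, 0, 0))
        with pytest.raises(ValueError):
            monochromator_wavelength((3, 1, 1), a_ge=-1.0)


class TestCellArithmetic:
    def test_cubic_volume(self):
        assert cell_volume(Cell(2, 2, 2)) == pytest.approx(8.0)

    @pytest.mark.parametrize("cell,vol,tol", [
        (Cell(5.296, 11.680, 7.947, 90.01, 94.16, 89.97), 490.3, 0.6),
        (Cell(5.2813, 11.6416, 7.9203, 90.001, 94.093, 89.997), 485.72, 0.03),
        (Cell(8.89, 23.04, 58.72, 90.04, 89.94, 90.00), 12025.0, 31.0),
    ])
    def test_published_cell_volumes(self, cell, vol, tol):
        assert cell_volume(cell) == pytest.approx(vol, abs=tol)

    def test_volume_equals_basis_determinant(self):
        # oracle: V = 1/det(B) for the reciprocal-basis matrix
        rng = np.random.default_rng(11)
        for _ in range(50):
            cell = _random_cell(rng)
            assert cell.volume == pytest.approx(
                1.0 / abs(np.linalg.det(cell.b_matrix())), rel=1e-10)

    def test_nacl_220_spacing(self, nacl):
        assert d_spacing(nacl, (2, 2, 0)) == pytest.approx(
            5.6402 / math.sqrt(8), rel=1e-12)

    def test_unit_cube_100(self):
        assert d_spacing(Cell(1, 1, 1), (1, 0, 0)) == pytest.approx(1.0)

    def test_d_spacing_against_gemmi(self):
        gemmi = pytest.importorskip("gemmi")
        rng = np.random.default_rng(7)
        for _ in range(50):
            cell = _random_cell(rng)
            hkl = tuple(int(v) for v in rng.integers(-6, 7, size=3))
            if hkl == (0, 0, 0):
                hkl = (1, 1, 1)
            ref = gemmi.UnitCell(*cell.parameters).calculate_d(hkl)
            assert d_spacing(cell, hkl) == pytest.approx(ref, rel=1e-10)
            assert cell.volume == pytest.approx(
                gemmi.UnitCell(*cell.parameters).volume, rel=1e-10)

    def test_b_matrix_gives_reciprocal_lengths(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            cell = _random_cell(rng)
            hkl = rng.integers(-5, 6, size=3)
            if not hkl.any():
                continue
            assert np.linalg.norm(cell.b_matrix() @ hkl) == pytest.approx(
                1.0 / d_spacing(cell, hkl), rel=1e-10)

    def test_cell_from_ub_round_trip(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            cell = _random_cell(rng)
            back = cell_from_ub(cell.b_matrix())
            assert np.allclose(back.parameters, cell.parameters, atol=1e-8)

    def test_zero_hkl_rejected(self, nacl):
        with pytest.raises(ValueError):
            d_spacing(nacl, (0, 0, 0))

    def test_degenerate_cell_rejected(self):
        with pytest.raises(DegenerateCellError):
            Cell(5, 5, 5, 170, 170, 170)
        with pytest.raises(DegenerateCellError):
            Cell(-1, 5, 5)


class TestValidation:
    def test_detector_geometry_invariants(self):
        with pytest.raises(ValueError):
            DetectorGeometry(c_x=-0.1)
        with pytest.raises(ValueError):
            DetectorGeometry(active_window=((500.0, 10.0), (400.0, 300.0)))

    def test_scan_config_invariants(self):
        with pytest.raises(ValueError):
            ScanConfig(wavelength=-1.0)
        with pytest.raises(ValueError):
            ScanConfig(wavelength=1.0, delta_phi=0.2, n_frames=2000)

    def test_angular_position_bounds(self):
        with pytest.raises(ValueError):
            AngularPosition(40.0, 95.0)


def _random_cell(rng):
    while True:
        a, b, c = rng.uniform(3, 15, size=3)
        al, be, ga = rng.uniform(70, 110, size=3)
        try:
            return Cell(a, b, c, al, be, ga)
        except DegenerateCellError:
            continue
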