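"""UB determination: the four construction routes, refinement, Bravais
search and prediction — all checked against generator ground truth."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from curvedpsd.geometry import (Cell, ScanConfig, cell_from_ub, d_spacing)
from curvedpsd.indexing import (IndexingError, UBMatrix, bravais_search,
                                canonical_lengths, index_points,
                                observations_to_q, predict_observations,
                                refine_ub_lsq, ub_from_three_reflections,
                                ub_from_two_reflections, ub_montecarlo,
                                vector_minimum)
from curvedpsd.peaksearch import Peak3D
from curvedpsd.simulate import hkl_sphere, predict_spots

WAVELENGTH = 1.153
ORTHO = Cell(5.0, 7.0, 9.0)


def _random_ub(cell, seed):
    u = Rotation.random(random_state=np.random.default_rng(seed)).as_matrix()
    return u @ cell.b_matrix()


def _sample_qs(ub, n, seed, lam=WAVELENGTH):
    rng = np.random.default_rng(seed)
    hkls = hkl_sphere(ub, lam)
    sel = hkls[rng.choice(len(hkls), size=n, replace=False)]
    return sel @ ub.T, sel


class TestObservationsToQ:
    def test_closed_form_at_origin(self, geom):
        scan = ScanConfig(wavelength=WAVELENGTH, delta_phi=1.0, n_frames=360)
        pk = Peak3D(members=[], first_frame=0, last_frame=0, x=geom.x0,
                    y=geom.y0, phi=0.0, intensity=1.0, sigma=1.0)
        q = observations_to_q([pk], geom, scan)[0]
        tc = math.radians(geom.arm_angle)
        want = np.array([(math.cos(tc) - 1), math.sin(tc), 0.0]) / WAVELENGTH
        assert np.allclose(q, want, atol=1e-12)

    def test_pipeline_identity_on_predictions(self, geom):
        """q(observation(prediction(hkl))) indexes back to hkl exactly."""
        scan = ScanConfig(wavelength=WAVELENGTH, delta_phi=0.5, n_frames=720)
        ub = _random_ub(ORTHO, 21)
        preds = [p for p in predict_spots(ub, geom, scan) if p.on_face][:50]
        pks = [Peak3D(members=[], first_frame=0, last_frame=0, x=p.x, y=p.y,
                      phi=p.phi_hit, intensity=1.0, sigma=1.0)
               for p in preds]
        qs = observations_to_q(pks, geom, scan)
        obs = index_points(ub, qs, tol=1e-6)
        for o, p in zip(obs, preds):
            assert o.hkl == p.hkl
            assert o.residual < 1e-8

    def test_recovered_q_matches_generator_truth(self, geom, ortho_chain):
        """Noise-free chain: for every cleanly-measurable (interior,
        isolated) ground-truth spot, the nearest recovered q lies within
        1e-3 1/A."""
        from conftest import interior_mask, isolated_mask
        truth = ortho_chain["truth"]
        truth_q = truth[["h", "k", "l"]].to_numpy() @ \
            ortho_chain["ub_truth"].T
        keep = interior_mask(truth["x"], truth["y"], geom) & \
            isolated_mask(truth["x"].to_numpy(), truth["y"].to_numpy(),
                          truth["phi"].to_numpy())
        qs = ortho_chain["qs"]
        d = np.linalg.norm(truth_q[keep][:, None, :] - qs[None, :, :],
                           axis=2).min(axis=1)
        assert keep.sum() > 500
        assert np.max(d) < 1e-3
        assert np.median(d) < 2e-4


class TestVectorMinimum:
    def test_recovers_orthorhombic_cell(self):
        ub = _random_ub(ORTHO, 7)
        qs, _ = _sample_qs(ub, 40, 7)
        got = vector_minimum(qs)
        lengths = canonical_lengths(got.cell)
        assert np.allclose(lengths, (5.0, 7.0, 9.0), rtol=1e-4)
        angles = sorted(got.cell.parameters[3:])
        assert np.allclose(angles, 90.0, atol=0.01)

    def test_rank_deficient_inputs_rejected(self):
        qs = np.array([[0.1, 0.0, 0.0], [0.2, 0.0, 0.0], [0.3, 0.0, 0.0],
                       [0.1, 0.1, 0.0], [0.2, 0.3, 0.0]])
        with pytest.raises(IndexingError, match="coplanar"):
            vector_minimum(qs)
        with pytest.raises(IndexingError):
            vector_minimum(qs[:2])

    def test_tolerates_spurious_points(self):
        ub = _random_ub(ORTHO, 13)
        qs, _ = _sample_qs(ub, 40, 13)
        rng = np.random.default_rng(99)
        fake = rng.uniform(-1.0, 1.0, size=(2, 3))
        allq = np.vstack([qs, fake])
        got = vector_minimum(allq)
        obs = index_points(got, qs)
        assert np.mean([o.indexed for o in obs]) >= 0.95

    def test_all_indexed_on_clean_data(self):
        ub = _random_ub(ORTHO, 29)
        qs, _ = _sample_qs(ub, 60, 29)
        got = vector_minimum(qs)
        assert all(o.indexed and o.residual < 0.02
                   for o in index_points(got, qs))


class TestTwoReflections:
    def test_exact_recovery(self):
        ub = _random_ub(ORTHO, 5)
        h1, h2 = (1, 2, 0), (0, 1, 3)
        got = ub_from_two_reflections(ub @ h1, ub @ h2, ORTHO, h1, h2)
        assert np.allclose(got.matrix, ub, atol=1e-8)

    def test_collinear_rejected(self):
        ub = _random_ub(ORTHO, 5)
        h1, h2 = (1, 0, 0), (2, 0, 0)
        with pytest.raises(ValueError, match="collinear"):
            ub_from_two_reflections(ub @ h1, ub @ h2, ORTHO, h1, h2)

    def test_metric_mismatch_rejected(self):
        ub = _random_ub(ORTHO, 5)
        h1, h2 = (1, 2, 0), (0, 1, 3)
        with pytest.raises(ValueError, match="metric"):
            ub_from_two_reflections(1.05 * (ub @ h1), ub @ h2, ORTHO, h1, h2)

    def test_u_is_proper_orthogonal(self):
        ub = _random_ub(ORTHO, 17)
        h1, h2 = (2, 1, 1), (-1, 0, 2)
        got = ub_from_two_reflections(ub @ h1, ub @ h2, ORTHO, h1, h2)
        u = got.matrix @ np.linalg.inv(ORTHO.b_matrix())
        assert np.allclose(u @ u.T, np.eye(3), atol=1e-10)
        assert np.linalg.det(u) == pytest.approx(1.0, abs=1e-10)


class TestThreeReflections:
    def test_exact_recovery(self):
        ub = _random_ub(ORTHO, 23)
        hs = [(1, 0, 0), (0, 2, 1), (1, 1, 3)]
        got = ub_from_three_reflections(*(ub @ np.array(h) for h in hs), *hs)
        assert np.allclose(got.matrix, ub, atol=1e-10)

    def test_coplanar_triple_rejected(self):
        ub = _random_ub(ORTHO, 23)
        hs = [(1, 0, 0), (0, 1, 0), (1, 1, 0)]
        with pytest.raises(ValueError):
            ub_from_three_reflections(*(ub @ np.array(h) for h in hs), *hs)

    def test_cell_agrees_with_vector_minimum(self):
        ub = _random_ub(ORTHO, 31)
        qs, hkls = _sample_qs(ub, 40, 31)
        vm_cell = vector_minimum(qs).cell
        tr_cell = ub_from_three_reflections(
            qs[0], qs[1], qs[2], hkls[0], hkls[1], hkls[2]).cell
        assert np.allclose(sorted(canonical_lengths(vm_cell)),
                           sorted(canonical_lengths(tr_cell)), rtol=5e-4)


class TestMonteCarlo:
    def test_indexes_everything_with_correct_cell(self):
        ub = _random_ub(ORTHO, 7)
        qs, _ = _sample_qs(ub, 40, 7)
        got = ub_montecarlo(qs, ORTHO, seed=3, n_trials=20000)
        assert all(o.indexed for o in index_points(got, qs))

    def test_wrong_cell_fails_honestly(self):
        ub = _random_ub(ORTHO, 7)
        qs, _ = _sample_qs(ub, 40, 7)
        with pytest.raises(IndexingError):
            ub_montecarlo(qs, Cell(5.5, 7.7, 9.9), seed=3, n_trials=2000)

    def test_seed_makes_it_bit_reproducible(self):
        ub = _random_ub(ORTHO, 7)
        qs, _ = _sample_qs(ub, 30, 7)
        a = ub_montecarlo(qs, ORTHO, seed=11, n_trials=5000)
        b = ub_montecarlo(qs, ORTHO, seed=11, n_trials=5000)
        assert np.array_equal(a.matrix, b.matrix)

    def test_seed_required(self):
        with pytest.raises(ValueError):
            ub_montecarlo(np.eye(3), ORTHO, seed=None)


class TestBravais:
    def test_face_centred_cubic_recognised(self):
        a = 5.6402
        prim = np.array([[0, .5, .5], [.5, 0, .5], [.5, .5, 0]]) * a
        ub, symbol = bravais_search(np.linalg.inv(prim))
        assert symbol == "cF"
        assert np.allclose(ub.cell.parameters, (a, a, a, 90, 90, 90),
                           atol=1e-6)

    def test_body_centred_cubic_recognised(self):
        prim = np.array([[-.5, .5, .5], [.5, -.5, .5], [.5, .5, -.5]]) * 4.0
        _, symbol = bravais_search(np.linalg.inv(prim))
        assert symbol == "cI"

    def test_generic_cell_stays_triclinic_unchanged(self):
        tric = Cell(6.1, 7.3, 8.9, 83.2, 101.5, 96.7)
        ub, symbol = bravais_search(tric.b_matrix())
        assert symbol == "aP"
        assert np.array_equal(ub.matrix, tric.b_matrix())

    def test_monoclinic_conventional_setting(self):
        mono = Cell(5.296, 11.680, 7.947, 90.0, 94.16, 90.0)
        ubm = _random_ub(mono, 1)
        ub, symbol = bravais_search(ubm)
        assert symbol == "mP"
        assert np.allclose(ub.cell.parameters, mono.parameters, atol=1e-4)

    def test_hexagonal_recognised(self):
        hexc = Cell(4.0, 4.0, 6.5, 90, 90, 120)
        _, symbol = bravais_search(_random_ub(hexc, 2))
        assert symbol == "hP"


class TestRefinement:
    def test_exact_data_reproduces_start(self):
        ub = _random_ub(ORTHO, 41)
        qs, hkls = _sample_qs(ub, 30, 41)
        got = refine_ub_lsq(UBMatrix(ub), hkls, qs)
        assert np.allclose(got.matrix, ub, atol=1e-10)
        assert max(got.cell_su) < 1e-8

    def test_noisy_parameter_recovery_within_su(self):
        ub = _random_ub(ORTHO, 43)
        qs, hkls = _sample_qs(ub, 200, 43)
        rng = np.random.default_rng(43)
        noisy = qs + rng.normal(scale=1e-3, size=qs.shape)
        got = refine_ub_lsq(UBMatrix(ub), hkls, noisy)
        for value, truth, su in zip(got.cell.parameters, ORTHO.parameters,
                                    got.cell_su):
            assert abs(value - truth) < 3 * su + 1e-9

    def test_refinement_never_increases_residual(self):
        ub = _random_ub(ORTHO, 47)
        qs, hkls = _sample_qs(ub, 50, 47)
        rng = np.random.default_rng(47)
        noisy = qs + rng.normal(scale=5e-4, size=qs.shape)
        for trial in range(50):
            pert = ub * (1 + rng.normal(scale=1e-3, size=(3, 3)))
            before = np.linalg.norm(noisy - np.array(hkls) @ pert.T)
            got = refine_ub_lsq(UBMatrix(pert), hkls, noisy)
            after = np.linalg.norm(noisy - np.array(hkls) @ got.matrix.T)
            assert after <= before + 1e-12

    def test_deficient_design_rejected(self):
        hkls = [(1, 0, 0), (2, 0, 0), (3, 0, 0), (4, 0, 0)]
        qs = np.array(hkls, float) * 0.1
        with pytest.raises(IndexingError):
            refine_ub_lsq(None, hkls, qs)


class TestUBInvariants:
    def test_ub_maps_hkl_to_reciprocal_lengths(self):
        rng = np.random.default_rng(53)
        for seed in range(5):
            ub = _random_ub(ORTHO, seed)
            cell = cell_from_ub(ub)
            for _ in range(20):
                hkl = rng.integers(-6, 7, size=3)
                if not hkl.any():
                    continue
                assert np.linalg.norm(ub @ hkl) == pytest.approx(
                    1.0 / d_spacing(cell, hkl), rel=1e-8)

    def test_all_methods_agree_on_the_cell(self):
        ub = _random_ub(ORTHO, 59)
        qs, hkls = _sample_qs(ub, 40, 59)
        cells = [
            vector_minimum(qs).cell,
            ub_from_two_reflections(qs[0], qs[1], ORTHO,
                                    hkls[0], hkls[1]).cell,
            ub_from_three_reflections(qs[0], qs[1], qs[2],
                                      hkls[0], hkls[1], hkls[2]).cell,
            ub_montecarlo(qs, ORTHO, seed=2, n_trials=10000).cell,
        ]
        ref = sorted(canonical_lengths(cells[0]))
        for c in cells[1:]:
            assert np.allclose(sorted(canonical_lengths(c)), ref, rtol=5e-4)


class TestPredictObservations:
    def test_self_consistency_with_simulator_truth(self, geom, ortho_chain):
        ub = ortho_chain["ub_truth"]
        scan = ortho_chain["stack"].scan
        preds = predict_observations(ub, geom, scan)
        truth = ortho_chain["truth"]
        on = preds[preds["on_face"]]
        key = lambda df: set(zip(df["h"], df["k"], df["l"], df["branch"]))
        assert key(on) == key(truth)
        merged = on.merge(truth, on=["h", "k", "l", "branch"],
                          suffixes=("", "_t"))
        assert np.max(np.abs(merged["x"] - merged["x_t"])) < 1e-9
        assert np.max(np.abs(merged["frame"] - merged["frame_t"])) == 0

    def test_zero_hkl_never_predicted(self, geom):
        scan = ScanConfig(wavelength=WAVELENGTH, delta_phi=2.0, n_frames=180)
        preds = predict_observations(_random_ub(ORTHO, 3), geom, scan)
        assert not ((preds.h == 0) & (preds.k == 0) & (preds.l == 0)).any()

    def test_coverage_is_orientation_independent(self, geom):
        scan = ScanConfig(wavelength=WAVELENGTH, delta_phi=2.0, n_frames=180)
        counts = []
        for seed in range(5):
            ub = _random_ub(ORTHO, seed)
            preds = predict_observations(ub, geom, scan)
            counts.append(int(preds["on_face"].sum()))
        counts = np.array(counts)
        assert counts.std() / counts.mean() < 0.02


class TestOrientationIndependence:
    def test_cell_recovery_for_twenty_random_orientations(self):
        """Auto-indexing succeeds whatever the initial crystal setting."""
        for seed in range(20):
            ub = _random_ub(ORTHO, 100 + seed)
            qs, _ = _sample_qs(ub, 40, 100 + seed)
            got = vector_minimum(qs)
            assert np.allclose(canonical_lengths(got.cell), (5.0, 7.0, 9.0),
                               rtol=1e-4)
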