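"""Shared fixtures: instrument profiles, reference cells and one rendered
synthetic rotation scan reused across the peak-search / indexing /
reduction tests (rendering a full stack is the expensive step, so it is
session-scoped)."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from curvedpsd.geometry import Cell, DetectorGeometry, ScanConfig
from curvedpsd.indexing import observations_to_q
from curvedpsd.peaksearch import find_peaks_stack, merge_frames
from curvedpsd.profiles import builtin_profile
from curvedpsd.simulate import simulate_full_rotation

NACL = Cell(5.6402, 5.6402, 5.6402)
ORTHO = Cell(5.0, 7.0, 9.0)
WAVELENGTH = 1.153


@pytest.fixture(scope="session")
def geom():
    return builtin_profile("hanaro")[0]


@pytest.fixture(scope="session")
def printed_geom():
    return builtin_profile("hanaro-printed")[0]


@pytest.fixture(scope="session")
def nacl():
    return NACL


@pytest.fixture(scope="session")
def ortho_cell():
    return ORTHO


@pytest.fixture(scope="session")
def small_geom():
    """A miniature detector for cheap rendering/I-O tests."""
    return DetectorGeometry(radius=200.0, n_x=96, n_y=96, c_x=0.25,
                            c_y=0.004, x0=48.0, y0=48.0, xy_slope=0.003,
                            arm_angle=40.0,
                            active_window=((8.0, 8.0), (88.0, 88.0)))


@pytest.fixture(scope="session")
def ortho_chain(geom):
    """One noise-free orthorhombic rotation scan pushed through the chain.

    Returns a dict with the stack, ground truth, 2D/3D peaks and the
    recovered q vectors; orientation fixed by seed 42.
    """
    orientation = Rotation.random(
        random_state=np.random.default_rng(42)).as_matrix()
    stack, truth = simulate_full_rotation(
        geom, ORTHO, WAVELENGTH, orientation=orientation, delta_phi=1.0,
        intensity=20000.0)
    peaks2d = find_peaks_stack(stack, threshold=5.0, box=11)
    peaks3d = merge_frames(peaks2d, stack.scan)
    qs = observations_to_q(peaks3d, geom, stack.scan)
    return {
        "stack": stack,
        "truth": truth,
        "ub_truth": stack.ub_truth,
        "orientation": orientation,
        "peaks2d": peaks2d,
        "peaks3d": peaks3d,
        "qs": qs,
    }


def interior_mask(xs, ys, geom, margin=6.0):
    """Spots whose integration box cannot touch the active-window edge."""
    (xmin, ymin), (xmax, ymax) = geom.active_window
    xs = np.asarray(xs)
    ys = np.asarray(ys)
    return ((xs > xmin + margin) & (xs < xmax - margin) &
            (ys > ymin + margin) & (ys < ymax - margin))


def isolated_mask(xs, ys, phis=None, min_dist=12.0, phi_window=8.0):
    """Spots with no neighbour inside min_dist channels (and, when phi
    centroids are given, only counting neighbours within phi_window deg,
    since spots on disjoint frame ranges cannot overlap)."""
    xs = np.asarray(xs)
    ys = np.asarray(ys)
    d2 = (xs[:, None] - xs[None, :]) ** 2 + (ys[:, None] - ys[None, :]) ** 2
    np.fill_diagonal(d2, np.inf)
    close = d2 < min_dist ** 2
    if phis is not None:
        dphi = np.abs(np.asarray(phis)[:, None] - np.asarray(phis)[None, :])
        dphi = np.minimum(dphi, 360.0 - dphi)
        close &= dphi < phi_window
    return ~close.any(axis=1)
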