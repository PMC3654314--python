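"""Synthetic rotation-scan data: spot prediction, frame rendering, calibration
scans and the point-counting throughput model.

The simulator is the test bed for every downstream stage.  Given a known
orientation matrix, detector geometry and scan, it solves the
rotation-method diffraction condition for every reachable reflection,
deposits each spot as a separable Gaussian in (X, Y) with a Gaussian
partition of its total intensity across consecutive frames in phi (an
idealised mosaic-spread profile), adds a flat background and optionally
Poisson counting noise.

Default spot widths sigma_x = 1.34 and sigma_y = 1.13 channels correspond
to the instrument's point-spread FWHM of 3.16 and 2.66 channels
(FWHM / 2.355).  Intensities are user-assigned: there is no
structure-factor physics here, by design.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .frame_io import FrameStack, ImageFrame
from .geometry import (AngularPosition, Cell, DetectorGeometry, ScanConfig,
                       angles_from_lab_vector, angles_to_channels,
                       crystal_to_lab, ewald_crossings)

__all__ = ["SpotPrediction", "SpotShape", "predict_spots", "render_frames",
           "simulate_calibration_sets", "simulate_arm_scan",
           "simulate_full_rotation", "throughput_model",
           "predictions_to_frame", "hkl_sphere"]


@dataclass(frozen=True)
class SpotPrediction:
    """One Ewald-sphere crossing of one reflection."""

    hkl: tuple
    q: tuple                  # crystal-frame reciprocal vector (1/A)
    phi_hit: float            # rotation angle of the crossing (deg)
    x: float
    y: float
    two_theta_b: float
    chi_d: float
    branch: str               # "entry" | "exit"
    on_face: bool             # inside the active detector window


@dataclass(frozen=True)
class SpotShape:
    """Gaussian spot profile: total counts and widths in X, Y and phi."""

    intensity_total: float
    sigma_x: float = 1.34
    sigma_y: float = 1.13
    sigma_phi: float = 0.3    # degrees; mosaic spread across frames

    def __post_init__(self):
        if min(self.intensity_total, self.sigma_x, self.sigma_y,
               self.sigma_phi) <= 0:
            raise ValueError("all spot-shape parameters must be positive")


def hkl_sphere(ub, wavelength: float):
    """All nonzero integer hkl with |UB.hkl| <= 2/lambda (the Ewald limit)."""
    ub = np.asarray(ub, dtype=float)
    qmax = 2.0 / wavelength
    inv = np.linalg.inv(ub)
    bounds = [int(math.floor(qmax * np.linalg.norm(inv[i]))) for i in range(3)]
    axes = [np.arange(-b, b + 1) for b in bounds]
    h, k, l = np.meshgrid(*axes, indexing="ij")
    hkl = np.stack([h.ravel(), k.ravel(), l.ravel()], axis=1)
    hkl = hkl[np.any(hkl != 0, axis=1)]
    q = hkl @ ub.T
    keep = np.linalg.norm(q, axis=1) <= qmax
    return hkl[keep]


def predict_spots(ub, geom: DetectorGeometry, scan: ScanConfig,
                  hkl_range=None):
    """Predict every spot of a rotation scan for orientation matrix ``ub``.

    For each reflection ``q = UB.hkl`` inside the Ewald limit, solves
    ``(R_z(phi) q).x_hat = -lambda |q|^2 / 2`` for the crossing angles
    (up to two: entry and exit branches), converts each crossing to
    ``(2theta_B, chi_d)`` and channels, and flags off-face hits.
    Blind-region reflections (no real solution) are excluded.  Only
    crossings inside the scanned phi range are returned.

    ``hkl_range`` restricts the index search: an iterable of hkl triples,
    or None to enumerate the full Ewald sphere.
    """
    ub = np.asarray(ub, dtype=float)
    if abs(np.linalg.det(ub)) < 1e-12:
        raise ValueError("singular UB matrix")
    lam = scan.wavelength
    if hkl_range is None:
        hkls = hkl_sphere(ub, lam)
    else:
        hkls = np.atleast_2d(np.asarray(hkl_range, dtype=int))
    out = []
    phi_end = scan.phi_start + scan.phi_span
    for hkl in hkls:
        q = ub @ hkl
        for phi, branch in ewald_crossings(q, lam):
            # map phi into the scanned interval (phi is 360-periodic)
            ph = scan.phi_start + (phi - scan.phi_start) % 360.0
            if ph >= phi_end:
                continue
            q_lab = crystal_to_lab(q, ph)
            ang = angles_from_lab_vector(q_lab, lam)
            x, y = angles_to_channels(ang, geom, strict=False)
            out.append(SpotPrediction(
                hkl=tuple(int(v) for v in hkl), q=tuple(q), phi_hit=ph,
                x=float(x), y=float(y), two_theta_b=float(ang.two_theta_b),
                chi_d=float(ang.chi_d), branch=branch,
                on_face=bool(geom.contains(x, y))))
    return out


def predictions_to_frame(preds, scan: ScanConfig | None = None):
    """Tabulate predictions as a DataFrame (ground-truth table)."""
    rows = [{
        "h": p.hkl[0], "k": p.hkl[1], "l": p.hkl[2], "branch": p.branch,
        "phi": p.phi_hit, "x": p.x, "y": p.y,
        "two_theta_b": p.two_theta_b, "chi_d": p.chi_d,
        "on_face": p.on_face,
    } for p in preds]
    df = pd.DataFrame(rows)
    if scan is not None and len(df):
        df["frame"] = scan.frame_of(df["phi"].to_numpy())
    return df


# ---------------------------------------------------------------------------
# frame rendering
# ---------------------------------------------------------------------------


def _pixel_mass_1d(center, sigma, lo, hi):
    """Integrated unit-Gaussian mass per pixel for pixels lo..hi-1.

    Pixel i spans [i-0.5, i+0.5]; COG coordinates are pixel centers.
    """
    edges = np.arange(lo, hi + 1) - 0.5
    cdf = ndtr((edges - center) / sigma)
    return np.diff(cdf)


def render_frames(preds, shapes, scan: ScanConfig, geom: DetectorGeometry,
                  background: float = 0.0, noise: str = "none",
                  seed=None) -> FrameStack:
    """Deposit predicted spots into a synthetic frame stack.

    ``shapes`` is a single :class:`SpotShape` applied to every spot, or a
    sequence parallel to ``preds``.  Each spot's total intensity is
    partitioned over frames by the Gaussian phi profile (truncated at
    +/- 4 sigma_phi) and over pixels by the pixel-integrated separable
    Gaussian, so noiseless deposited counts conserve the requested mass up
    to truncation.  Spots entirely off the detector face are skipped.

    ``noise="poisson"`` draws every pixel from a Poisson law with the
    noiseless expectation; a seed is then required and makes the stack
    bit-reproducible.
    """
    if noise not in ("none", "poisson"):
        raise ValueError("noise must be 'none' or 'poisson'")
    if noise == "poisson" and seed is None:
        raise ValueError("poisson noise requires a seed")
    if isinstance(shapes, SpotShape):
        shapes = [shapes] * len(preds)
    if len(shapes) != len(preds):
        raise ValueError("one SpotShape per prediction required")

    expected = np.full((scan.n_frames, geom.n_x, geom.n_y), float(background))
    skipped = []
    phi_end = scan.phi_start + scan.phi_span
    for pred, shape in zip(preds, shapes):
        xw = 4.0 * shape.sigma_x
        yw = 4.0 * shape.sigma_y
        x_lo = max(0, int(math.floor(pred.x - xw)))
        x_hi = min(geom.n_x, int(math.ceil(pred.x + xw)) + 1)
        y_lo = max(0, int(math.floor(pred.y - yw)))
        y_hi = min(geom.n_y, int(math.ceil(pred.y + yw)) + 1)
        if x_lo >= x_hi or y_lo >= y_hi:
            skipped.append(pred)
            continue
        mx = _pixel_mass_1d(pred.x, shape.sigma_x, x_lo, x_hi)
        my = _pixel_mass_1d(pred.y, shape.sigma_y, y_lo, y_hi)
        patch = np.outer(mx, my)

        pw = 4.0 * shape.sigma_phi
        f_lo = int(scan.frame_of(pred.phi_hit - pw))
        f_hi = int(scan.frame_of(pred.phi_hit + pw))
        if not scan.full_circle:
            f_lo = max(0, f_lo)
            f_hi = min(scan.n_frames - 1, f_hi)
            if f_hi < f_lo:
                continue
        edges = scan.phi_start + np.arange(f_lo, f_hi + 2) * scan.delta_phi
        frac = np.diff(ndtr((edges - pred.phi_hit) / shape.sigma_phi))
        for j, f in enumerate(range(f_lo, f_hi + 1)):
            if frac[j] <= 0:
                continue
            # phi is periodic: on a full-circle scan the tail of a spot
            # near the 0/360 seam lands in the frames on the other side
            target = f % scan.n_frames if scan.full_circle else f
            expected[target, x_lo:x_hi, y_lo:y_hi] += \
                shape.intensity_total * frac[j] * patch

    if noise == "poisson":
        rng = np.random.default_rng(seed)
        counts = rng.poisson(expected).astype(np.uint32)
    else:
        counts = np.rint(expected).astype(np.uint32)
    frames = [ImageFrame(counts[i], i, float(scan.phi_mid(i)))
              for i in range(scan.n_frames)]
    stack = FrameStack(frames, scan, geom)
    stack.skipped_spots = skipped
    return stack


# ---------------------------------------------------------------------------
# calibration protocols
# ---------------------------------------------------------------------------


def _bragg_two_theta(cell: Cell, hkl, wavelength: float):
    d = cell.d_spacing(hkl)
    s = wavelength / (2.0 * d)
    if s > 1.0:
        raise ValueError(f"reflection {hkl} unreachable at {wavelength} A")
    return 2.0 * math.degrees(math.asin(s))


def simulate_arm_scan(geom: DetectorGeometry, cell: Cell, wavelength: float,
                      hkl=(2, 2, 0), n_steps: int = 8, step: float = 5.0,
                      intensity: float = 20000.0, shape: SpotShape = None,
                      noise: str = "none", seed=None):
    """Detector-arm stepping protocol for the X conversion factor.

    One equatorial reflection is held in the diffraction condition while
    the detector arm moves in ``step``-degree increments, so the spot
    walks across the face at channel ``X = x0 + (2theta_Bragg - arm)/c_x``.
    Returns ``(arm_angles, frames)`` where each frame is an
    :class:`ImageFrame` rendered with the arm at that angle (single-frame
    exposures; phi is irrelevant here).
    """
    tt = _bragg_two_theta(cell, hkl, wavelength)
    arm_angles = tt + step * (np.arange(n_steps) - (n_steps - 1) / 2.0)
    if shape is None:
        shape = SpotShape(intensity_total=intensity, sigma_phi=1.0)
    scan1 = ScanConfig(wavelength=wavelength, delta_phi=8.0 * shape.sigma_phi,
                       n_frames=1, phi_start=-4.0 * shape.sigma_phi)
    frames = []
    for i, arm in enumerate(arm_angles):
        g = geom.with_arm(arm)
        x, y = angles_to_channels(AngularPosition(tt, 0.0), g, strict=False)
        pred = SpotPrediction(hkl=tuple(hkl), q=(0, 0, 0), phi_hit=0.0,
                              x=x, y=y, two_theta_b=tt, chi_d=0.0,
                              branch="entry", on_face=bool(g.contains(x, y)))
        stk = render_frames([pred], shape, scan1, g, noise=noise,
                            seed=None if seed is None else seed + i)
        fr = stk.frames[0]
        frames.append(ImageFrame(fr.counts, i, float(arm)))
    return np.asarray(arm_angles), frames


def simulate_full_rotation(geom: DetectorGeometry, cell: Cell,
                           wavelength: float, orientation=None,
                           delta_phi: float = 1.0, intensity: float = 20000.0,
                           shape: SpotShape = None, background: float = 0.0,
                           noise: str = "none", seed=None, hkl_range=None):
    """Complete 360-degree rotation scan of a crystal with known cell.

    ``orientation`` is a 3x3 rotation matrix U (default: identity, i.e.
    the reciprocal basis axis-aligned at phi = 0).  Returns
    ``(stack, truth)`` where ``truth`` is the ground-truth prediction
    table including per-spot deposited intensity.
    """
    u = np.eye(3) if orientation is None else np.asarray(orientation, float)
    ub = u @ cell.b_matrix()
    n_frames = int(round(360.0 / delta_phi))
    scan = ScanConfig(wavelength=wavelength, delta_phi=delta_phi,
                      n_frames=n_frames)
    preds = predict_spots(ub, geom, scan, hkl_range=hkl_range)
    if shape is None:
        shape = SpotShape(intensity_total=intensity,
                          sigma_phi=0.8 * delta_phi)
    on_face = [p for p in preds if p.on_face]
    stack = render_frames(on_face, shape, scan, geom, background=background,
                          noise=noise, seed=seed)
    truth = predictions_to_frame(on_face, scan)
    if len(truth):
        truth["intensity"] = shape.intensity_total
    stack.ub_truth = ub
    return stack, truth


def simulate_calibration_sets(kind: str, geom: DetectorGeometry, cell: Cell,
                              wavelength: float, **kwargs):
    """Dispatch to the named calibration protocol.

    ``kind="arm_scan"`` -> :func:`simulate_arm_scan`;
    ``kind="full_rotation"`` -> :func:`simulate_full_rotation`.
    """
    if kind == "arm_scan":
        return simulate_arm_scan(geom, cell, wavelength, **kwargs)
    if kind == "full_rotation":
        return simulate_full_rotation(geom, cell, wavelength, **kwargs)
    raise ValueError(f"unknown calibration protocol {kind!r}")


# ---------------------------------------------------------------------------
# throughput model
# ---------------------------------------------------------------------------


def _count_reachable(cell: Cell, wavelength: float, two_theta_max: float):
    """Unique nonzero lattice points with 2theta <= 2theta_max (full sphere)."""
    d_min = wavelength / (2.0 * math.sin(math.radians(two_theta_max / 2.0)))
    qmax = 1.0 / d_min
    b = cell.b_matrix()
    inv = np.linalg.inv(b)
    bounds = [int(math.floor(qmax * np.linalg.norm(inv[i]))) for i in range(3)]
    axes = [np.arange(-bb, bb + 1) for bb in bounds]
    h, k, l = np.meshgrid(*axes, indexing="ij")
    hkl = np.stack([h.ravel(), k.ravel(), l.ravel()], axis=1)
    hkl = hkl[np.any(hkl != 0, axis=1)]
    q = hkl @ b.T
    return int(np.sum(np.linalg.norm(q, axis=1) <= qmax))


def throughput_model(cell: Cell, mode: str, minutes_per_point: float = 10.0,
                     wavelength: float = 1.24, two_theta_max: float = 150.0,
                     scan_speed: float = 0.2, scan_range: float = 180.0,
                     n_settings: int = 1):
    """Total measurement time in minutes for one data collection.

    ``mode="fcd"``: a four-circle point-detector instrument spends a fixed
    time on each unique reciprocal lattice point inside the 2theta limit,
    so the time grows with cell volume.  ``mode="area"``: an area-detector
    rotation scan takes ``scan_range / scan_speed`` minutes per detector
    arm setting regardless of the cell.
    """
    if mode == "area":
        return scan_range / scan_speed * n_settings
    if mode == "fcd":
        return minutes_per_point * _count_reachable(cell, wavelength,
                                                    two_theta_max)
    raise ValueError(f"unknown mode {mode!r}")
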