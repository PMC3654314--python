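"""Machine-parameter calibration from a reference crystal (NaCl protocol).

Three fits, run in a fixed order because later ones consume earlier
results:

1. :func:`fit_x_conversion` — the X conversion factor ``c_x`` (degrees per
   channel) from one equatorial reflection imaged at stepped detector-arm
   angles.  The spot position is linear in the arm angle with slope
   ``-1/c_x``: stepping the arm forward moves a fixed reflection to lower
   X channels.
2. :func:`fit_layer_lines` — the equator origin ``Y0``, the X-Y channel
   slope and the vertical conversion factor ``c_y`` from the layer-line
   structure of a full-rotation peak set.  Reflections cluster into
   horizontal bands of constant l; the l = 0 band is a straight line
   ``Y = Y0 + s (X - X0)`` whose intercept and slope are the first two
   parameters, and the band-to-band heights give ``c_y`` through
   ``tan(chi_l) = c_y * dY_l`` with ``sin(chi_l) = l lambda / c``.
3. :func:`fit_wavelength` — the neutron wavelength from equatorial hk0
   reflections of a crystal with known lattice parameter, via the Bragg
   equation applied to each spot's observed 2theta.

All fits are exact on noise-free input and report standard uncertainties
from the fit covariance (or scatter) so that coverage can be checked on
seeded replicates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import (Cell, DetectorGeometry, channels_to_angles)

__all__ = ["CalibrationResult", "fit_x_conversion", "fit_layer_lines",
           "fit_wavelength"]


@dataclass
class CalibrationResult:
    """Fitted parameters with uncertainties and per-point residuals."""

    protocol: str
    params: dict            # name -> (value, standard uncertainty or nan)
    residuals: np.ndarray
    notes: tuple = ()

    def value(self, name):
        return self.params[name][0]

    def su(self, name):
        return self.params[name][1]


def _weighted_line(x, y, w=None):
    """Weighted straight-line fit y = a + b x; returns a, b, cov(2x2), resid.

    The covariance is scaled by the residual variance (chi^2/dof), so the
    reported uncertainties reflect the observed scatter.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if w is None:
        w = np.ones_like(x)
    w = np.asarray(w, float)
    design = np.column_stack([np.ones_like(x), x])
    wd = design * w[:, None]
    gram = design.T @ wd
    if abs(np.linalg.det(gram)) < 1e-12 * max(1.0, float(np.trace(gram)) ** 2):
        raise ValueError("degenerate design: need at least two distinct "
                         "abscissae")
    gram_inv = np.linalg.inv(gram)
    coef = gram_inv @ wd.T @ y
    resid = y - design @ coef
    dof = max(len(x) - 2, 1)
    s2 = float(w @ resid ** 2) / dof
    return coef[0], coef[1], s2 * gram_inv, resid


def fit_x_conversion(arm_angles, xs, weights=None, reference_arm=None,
                     expected_two_theta=None) -> CalibrationResult:
    """Recover c_x (deg/channel) from a detector-arm stepping scan.

    ``arm_angles`` and ``xs`` are matched arrays of arm angle (degrees)
    and observed spot X (channels).  If ``expected_two_theta`` (the known
    Bragg angle of the stepped reflection) and ``reference_arm`` are
    given, the origin channel ``x0`` at that arm setting is reported too.
    """
    arm = np.asarray(arm_angles, float)
    xs = np.asarray(xs, float)
    if len(arm) < 2:
        raise ValueError("need at least two arm positions")
    if np.ptp(arm) == 0:
        raise ValueError("arm angles are all identical (rank error)")
    a, b, cov, resid = _weighted_line(arm, xs, weights)
    if b >= 0:
        raise ValueError("spot X does not decrease with arm angle; check "
                         "the scan direction convention")
    c_x = -1.0 / b
    su_cx = math.sqrt(cov[1, 1]) / b ** 2
    params = {"c_x": (c_x, su_cx)}
    if expected_two_theta is not None and reference_arm is not None:
        # X(arm) = x0 + (2theta_B - arm)/c_x with b = -1/c_x, so
        # x0 = X(ref) + b*(2theta_B - ref): linear in (a, b)
        lever = reference_arm + (expected_two_theta - reference_arm)
        x0 = a + b * lever
        var_x0 = cov[0, 0] + lever ** 2 * cov[1, 1] + 2 * lever * cov[0, 1]
        params["x0"] = (x0, math.sqrt(max(var_x0, 0.0)))
    return CalibrationResult("arm_scan", params, resid)


def _split_layers(values, min_gap):
    """1D valley clustering: split sorted values at gaps wider than min_gap."""
    order = np.argsort(values)
    sorted_v = np.asarray(values)[order]
    breaks = np.where(np.diff(sorted_v) > min_gap)[0]
    labels = np.zeros(len(values), dtype=int)
    lab = 0
    prev = 0
    for brk in breaks:
        labels[order[prev:brk + 1]] = lab
        lab += 1
        prev = brk + 1
    labels[order[prev:]] = lab
    return labels


def fit_layer_lines(xs, ys, cell: Cell, wavelength: float,
                    geom: DetectorGeometry, min_gap: float = 10.0,
                    clip_sigma: float = 4.0, weights=None
                    ) -> CalibrationResult:
    """Recover Y0, the X-Y slope and c_y from a full-rotation peak set.

    ``xs, ys`` are the channel positions of all found peaks; ``cell`` and
    ``wavelength`` provide the known layer heights (rotation axis along
    the cell's c axis: ``sin(chi_l) = l * lambda / c``).  ``geom``
    supplies the X origin used to anchor the slope and the trial ``c_y``
    for layer identification.  With only the equatorial layer present,
    ``Y0`` and the slope are still fitted but ``c_y`` is flagged unfitted.

    The per-layer line fits share a common slope and are made robust by
    iterated sigma-clipping of outliers.
    """
    xs = np.asarray(xs, float)
    ys = np.asarray(ys, float)
    if len(xs) < 2:
        raise ValueError("need at least two peaks")
    labels = _split_layers(ys - geom.xy_slope * (xs - geom.x0), min_gap)
    # spurious bands (powder rings, stray spots) form sparse clusters;
    # keep only bands with at least a quarter of the largest membership
    sizes = np.bincount(labels)
    good_bands = np.where(sizes >= max(2, sizes.max() // 4))[0]
    keep_pts = np.isin(labels, good_bands)
    xs, ys = xs[keep_pts], ys[keep_pts]
    labels = np.searchsorted(good_bands, labels[keep_pts])
    n_layers = labels.max() + 1

    # joint fit: y = intercept[layer] + slope * (x - x0), sigma-clipped
    keep = np.ones(len(xs), dtype=bool)
    for _ in range(3):
        design = np.zeros((int(keep.sum()), n_layers + 1))
        xk = xs[keep]
        yk = ys[keep]
        lk = labels[keep]
        design[np.arange(len(xk)), lk] = 1.0
        design[:, -1] = xk - geom.x0
        coef, *_ = np.linalg.lstsq(design, yk, rcond=None)
        resid_k = yk - design @ coef
        s = float(np.std(resid_k)) if len(resid_k) > n_layers + 1 else 0.0
        if s <= 1e-12:
            break
        new_keep = keep.copy()
        new_keep[keep] = np.abs(resid_k) < clip_sigma * s
        if new_keep.sum() == keep.sum() or new_keep.sum() < n_layers + 2:
            break
        keep = new_keep

    xk, yk, lk = xs[keep], ys[keep], labels[keep]
    design = np.zeros((len(xk), n_layers + 1))
    design[np.arange(len(xk)), lk] = 1.0
    design[:, -1] = xk - geom.x0
    coef, res_ss, *_ = np.linalg.lstsq(design, yk, rcond=None)
    resid = yk - design @ coef
    dof = max(len(xk) - (n_layers + 1), 1)
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.inv(design.T @ design)
    intercepts = coef[:n_layers]
    slope = float(coef[-1])
    su_slope = math.sqrt(cov[-1, -1])

    # identify layer indices by matching intercept offsets to the known
    # tan(chi_l) ladder; choose the offset assignment with least misfit
    chi = lambda l: math.asin(min(1.0, max(-1.0, l * wavelength / cell.c)))
    order = np.argsort(intercepts)
    b_sorted = intercepts[order]
    best = None
    for l0 in range(-6, 7):
        ls = np.arange(len(b_sorted)) + l0
        if np.any(np.abs(ls * wavelength / cell.c) >= 1.0):
            continue
        t = np.array([math.tan(chi(int(l))) for l in ls])
        # b = y0 + t / c_y : linear in (y0, 1/c_y)
        dm = np.column_stack([np.ones_like(t), t])
        sol, *_ = np.linalg.lstsq(dm, b_sorted, rcond=None)
        mis = float(np.sum((b_sorted - dm @ sol) ** 2))
        if sol[1] <= 0 and len(b_sorted) > 1:
            continue
        if best is None or mis < best[0]:
            best = (mis, ls, sol)
    _, layer_ls, sol = best
    i_zero = int(np.argwhere(layer_ls == 0)[0][0]) if 0 in layer_ls else None
    if i_zero is None:
        raise ValueError("no equatorial (l = 0) layer identified")
    y0 = float(b_sorted[i_zero])
    su_y0 = math.sqrt(cov[order[i_zero], order[i_zero]])

    params = {"y0": (y0, su_y0), "xy_slope": (slope, su_slope)}
    notes = []
    if n_layers >= 2:
        t = np.array([math.tan(chi(int(l))) for l in layer_ls])
        nz = t != 0
        inv_cy = (b_sorted[nz] - y0) / t[nz]
        c_y = 1.0 / float(np.mean(inv_cy))
        # propagate intercept uncertainties through the mean of 1/c_y
        su_b = np.sqrt(np.diag(cov))[order][nz]
        su_inv = np.sqrt(su_b ** 2 + su_y0 ** 2) / np.abs(t[nz])
        su_invcy = math.sqrt(float(np.sum(su_inv ** 2))) / max(nz.sum(), 1)
        params["c_y"] = (c_y, su_invcy * c_y ** 2)
    else:
        params["c_y"] = (float("nan"), float("nan"))
        notes.append("single layer only: c_y not fitted")
    return CalibrationResult("layer_lines", params, resid,
                             notes=tuple(notes))


def fit_wavelength(hkls, xs, cell: Cell, geom: DetectorGeometry,
                   ys=None) -> CalibrationResult:
    """Recover lambda from indexed equatorial reflections by the Bragg law.

    Each reflection's observed ``2theta`` comes from the calibrated
    channel-to-angle conversion at its X channel (Y defaults to the
    equator); the per-reflection wavelength is ``2 d(hkl) sin(theta)`` and
    the reported value is their least-squares (mean) combination, with the
    uncertainty from the scatter.
    """
    hkls = np.atleast_2d(np.asarray(hkls, int))
    xs = np.atleast_1d(np.asarray(xs, float))
    if len(hkls) != len(xs) or len(xs) < 1:
        raise ValueError("need matched hkl and X lists, at least one entry")
    if np.any(np.all(hkls == 0, axis=1)):
        raise ValueError("unindexed (0,0,0) input")
    if ys is None:
        ys = geom.y0 + geom.xy_slope * (xs - geom.x0)   # equator line
    lams = np.empty(len(xs))
    for i, (hkl, x, y) in enumerate(zip(hkls, xs, np.atleast_1d(ys))):
        ang = channels_to_angles(x, y, geom)
        d = cell.d_spacing(hkl)
        lams[i] = 2.0 * d * math.sin(math.radians(ang.two_theta_b / 2.0))
    lam = float(np.mean(lams))
    if len(lams) > 1:
        su = float(np.std(lams, ddof=1) / math.sqrt(len(lams)))
    else:
        su = float("nan")
    return CalibrationResult("wavelength", {"wavelength": (lam, su)},
                             lams - lam)
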