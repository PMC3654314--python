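"""2D Bragg-spot search and cross-frame 3D integration.

The 2D search follows the classic relocating center-of-gravity scheme:
candidate seeds are local maxima above a user threshold, processed from
strongest to weakest; for each seed a square box is iteratively re-centred
on the background-subtracted centre of gravity until the centre pixel is
stable.  The local background is estimated from the box's one-pixel border
rim, the net intensity is the inner-pixel sum minus the scaled background,
and the variance follows Poisson propagation of both sums.  Pixels claimed
by a converged peak are masked so that no pixel contributes to two peaks
in one frame; overlapping reflections are therefore resolved greedily and
the integration assumes each reflection is essentially isolated within the
box.

The 3D stage merges 2D peaks that coincide in (X, Y) on consecutive frames
into a single integrated reflection; the integrated intensity is the exact
sum of the member net intensities, sigma adds in quadrature, and the phi
centroid is intensity-weighted.  A merged peak touching the stack or
active-window boundary is flagged partial (its integral is incomplete).
For full 360-degree scans the first and last frames are treated as
adjacent, since phi is periodic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .frame_io import FrameStack, ImageFrame
from .geometry import DetectorGeometry, ScanConfig

__all__ = ["Peak2D", "Peak3D", "find_peaks_2d", "find_peaks_stack",
           "merge_frames"]


@dataclass
class Peak2D:
    """One spot footprint in a single frame (COG position, net counts)."""

    frame_index: int
    x: float
    y: float
    net_intensity: float
    background_per_pixel: float
    sigma: float
    box_size: int
    converged: bool = True
    touches_edge: bool = False


@dataclass
class Peak3D:
    """A reflection integrated over consecutive frames."""

    members: list
    first_frame: int
    last_frame: int
    x: float
    y: float
    phi: float
    intensity: float
    sigma: float
    partial: bool = False


def _box_bounds(cx, cy, half, nx, ny):
    return (max(0, cx - half), min(nx, cx + half + 1),
            max(0, cy - half), min(ny, cy + half + 1))


def find_peaks_2d(frame, threshold: float, box: int = 11,
                  geom: DetectorGeometry | None = None,
                  rim_width: int = 1, max_iter: int = 20):
    """Locate and integrate 2D peaks in one frame.

    Parameters
    ----------
    frame : ImageFrame or 2D array
        Counts indexed ``[X, Y]``.
    threshold : float
        Minimum height (counts) for a local-maximum seed.  Must be > 0.
    box : int
        Odd box width in channels, >= 3.
    geom : DetectorGeometry, optional
        Restricts the search to the active window and flags peaks whose
        box touches its boundary.
    """
    if box < 3 or box % 2 == 0:
        raise ValueError("box must be odd and >= 3")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if isinstance(frame, ImageFrame):
        counts = frame.counts
        frame_index = frame.frame_index
    else:
        counts = np.asarray(frame)
        frame_index = 0
    data = counts.astype(float)
    nx, ny = data.shape
    half = box // 2
    rw = rim_width

    search_mask = np.ones_like(data, dtype=bool)
    if geom is not None:
        (xmin, ymin), (xmax, ymax) = geom.active_window
        search_mask[:] = False
        search_mask[int(math.ceil(xmin)):int(math.floor(xmax)) + 1,
                    int(math.ceil(ymin)):int(math.floor(ymax)) + 1] = True

    local_max = (data == ndimage.maximum_filter(data, size=3)) & \
                (data > threshold) & search_mask
    seeds = np.argwhere(local_max)
    if len(seeds) == 0:
        return []
    order = np.argsort(-data[seeds[:, 0], seeds[:, 1]], kind="stable")
    seeds = seeds[order]

    claimed = np.zeros_like(data, dtype=bool)
    peaks = []
    for sx, sy in seeds:
        if claimed[sx, sy]:
            continue
        cx, cy = int(sx), int(sy)
        converged = False
        visited = {(cx, cy)}
        for _ in range(max_iter):
            x0, x1, y0, y1 = _box_bounds(cx, cy, half, nx, ny)
            sub = data[x0:x1, y0:y1]
            rim = np.ones(sub.shape, dtype=bool)
            rim[rw:-rw or None, rw:-rw or None] = False
            bg = sub[rim].mean() if rim.any() else 0.0
            inner = ~rim
            net_pix = np.clip(sub - bg, 0.0, None) * inner
            tot = net_pix.sum()
            if tot <= 0:
                break
            gx = (net_pix.sum(axis=1) @ np.arange(x0, x1)) / tot
            gy = (net_pix.sum(axis=0) @ np.arange(y0, y1)) / tot
            # tie-break toward smaller channel on exact .5 boundaries
            nxt = (int(math.floor(gx + 0.5 - 1e-12)),
                   int(math.floor(gy + 0.5 - 1e-12)))
            if nxt == (cx, cy):
                converged = True
                break
            if nxt in visited:  # oscillation: report at the last centre
                break
            visited.add(nxt)
            cx, cy = nxt
        x0, x1, y0, y1 = _box_bounds(cx, cy, half, nx, ny)
        sub = data[x0:x1, y0:y1]
        rim = np.ones(sub.shape, dtype=bool)
        rim[rw:-rw or None, rw:-rw or None] = False
        inner = ~rim
        if claimed[x0:x1, y0:y1][inner].any():
            continue  # fully or partly claimed by a stronger peak
        n_inner = int(inner.sum())
        n_rim = int(rim.sum())
        bg = sub[rim].sum() / n_rim if n_rim else 0.0
        net = float(sub[inner].sum() - n_inner * bg)
        var = float(sub[inner].sum() + (n_inner / n_rim) ** 2 * sub[rim].sum()
                    if n_rim else sub[inner].sum())
        net_pix = np.clip(sub - bg, 0.0, None) * inner
        tot = net_pix.sum()
        if tot <= 0 or net <= 0:
            continue
        gx = (net_pix.sum(axis=1) @ np.arange(x0, x1)) / tot
        gy = (net_pix.sum(axis=0) @ np.arange(y0, y1)) / tot
        touches = (x0 == 0 or x1 == nx or y0 == 0 or y1 == ny)
        if geom is not None:
            (wxmin, wymin), (wxmax, wymax) = geom.active_window
            touches = touches or (x0 <= wxmin or x1 - 1 >= wxmax or
                                  y0 <= wymin or y1 - 1 >= wymax)
        claimed[x0:x1, y0:y1] |= inner
        peaks.append(Peak2D(frame_index=frame_index, x=float(gx), y=float(gy),
                            net_intensity=net, background_per_pixel=float(bg),
                            sigma=math.sqrt(max(var, 0.0)), box_size=box,
                            converged=converged, touches_edge=bool(touches)))
    peaks.sort(key=lambda p: -p.net_intensity)
    return peaks


def find_peaks_stack(stack: FrameStack, threshold: float, box: int = 11,
                     **kwargs):
    """Run :func:`find_peaks_2d` over every frame of a stack."""
    out = []
    for fr in stack.frames:
        out.extend(find_peaks_2d(fr, threshold, box, geom=stack.geom,
                                 **kwargs))
    return out


def _circular_weighted_mean(phis, weights, period=360.0):
    ang = np.asarray(phis) * (2 * np.pi / period)
    w = np.asarray(weights, dtype=float)
    s = np.sum(w * np.sin(ang))
    c = np.sum(w * np.cos(ang))
    return (math.atan2(s, c) * period / (2 * np.pi)) % period


def merge_frames(peaks, scan: ScanConfig, xy_tol: float = 1.5,
                 gap_tol: int = 0, geom: DetectorGeometry | None = None):
    """Group 2D peaks across consecutive frames into integrated 3D peaks.

    Single-linkage grouping: two 2D peaks connect when their (X, Y)
    distance is at most ``xy_tol`` channels and their frame indices differ
    by at least 1 and at most ``gap_tol + 1``.  For full-circle scans the
    frame index is periodic, so a spot straddling the 0/360 boundary is
    merged into one reflection rather than split.  The result is
    independent of the input order.
    """
    if xy_tol <= 0 or gap_tol < 0:
        raise ValueError("xy_tol must be > 0 and gap_tol >= 0")
    peaks = sorted(peaks, key=lambda p: (p.frame_index, p.x, p.y))
    n = len(peaks)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    nf = scan.n_frames
    wrap = scan.full_circle and nf > 1
    max_gap = gap_tol + 1
    for i in range(n):
        for j in range(i + 1, n):
            df = abs(peaks[j].frame_index - peaks[i].frame_index)
            if wrap:
                df = min(df, nf - df)
            if df < 1 or df > max_gap:
                continue
            if math.hypot(peaks[i].x - peaks[j].x,
                          peaks[i].y - peaks[j].y) <= xy_tol:
                union(i, j)

    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(peaks[i])

    out = []
    for members in groups.values():
        members.sort(key=lambda p: p.frame_index)
        w = np.array([max(p.net_intensity, 1e-30) for p in members])
        intensity = float(sum(p.net_intensity for p in members))
        sigma = math.sqrt(sum(p.sigma ** 2 for p in members))
        x = float(np.sum(w * [p.x for p in members]) / w.sum())
        y = float(np.sum(w * [p.y for p in members]) / w.sum())
        phis = [scan.phi_mid(p.frame_index) for p in members]
        if wrap:
            phi = _circular_weighted_mean(phis, w)
        else:
            phi = float(np.sum(w * np.asarray(phis)) / w.sum())
        first = members[0].frame_index
        last = members[-1].frame_index
        at_stack_edge = (not wrap) and (first == 0 or last == nf - 1)
        partial = at_stack_edge or any(p.touches_edge for p in members)
        out.append(Peak3D(members=members, first_frame=first, last_frame=last,
                          x=x, y=y, phi=float(phi), intensity=intensity,
                          sigma=sigma, partial=partial))
    out.sort(key=lambda p: -p.intensity)
    return out
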