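"""Final reflection-intensity list: prediction/observation matching, quality
classification, Lorentz correction and export.

Every predicted reflection receives exactly one quality label:

``good_peak``
    matched to an observation within the indexing tolerance (0.1 in
    fractional hkl units by default);
``partial``
    a good match whose underlying integrated peak touches a frame-stack
    or detector-window boundary, so its integral is incomplete;
``no_good_peak``
    an observation exists nearby (within 3x the tolerance) but misses the
    predicted position by more than the tolerance;
``no_peak``
    the prediction is observable (on-face, in the scanned phi range) but
    no observation lies anywhere near it;
``out_of_expected_region``
    the predicted crossing is on the detector face but outside the
    scanned phi range;
``out_of_experimental_area``
    the predicted position falls outside the active detector window.

Intensities of good and partial peaks are corrected by the normal-beam
rotation-geometry Lorentz factor ``L = 1/(cos chi_d sin 2theta_B)``
(``F^2 = I/L``); the factor diverges in the blind region near the
rotation axis, where the correction is refused rather than applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import AngularPosition, DetectorGeometry, ScanConfig
from .indexing import UBMatrix

__all__ = ["Reflection", "QUALITY_LABELS", "BlindRegionError",
           "lorentz_factor", "classify", "build_reflection_list",
           "export_reflections"]

QUALITY_LABELS = ("good_peak", "no_peak", "no_good_peak",
                  "out_of_expected_region", "out_of_experimental_area",
                  "partial")


class BlindRegionError(ValueError):
    """Lorentz correction undefined too close to the rotation axis."""


@dataclass
class Reflection:
    """One predicted reflection with its quality label and, when measured,
    its Lorentz-corrected intensity."""

    hkl: tuple
    quality: str
    f2: float = float("nan")
    sigma_f2: float = float("nan")
    peak: object = None            # matched Peak3D, or None
    residual: float = float("nan")  # fractional-hkl match distance
    branch: str = ""
    phi: float = float("nan")
    two_theta_b: float = float("nan")
    chi_d: float = float("nan")

    def __post_init__(self):
        if self.quality not in QUALITY_LABELS:
            raise ValueError(f"unknown quality {self.quality!r}")


def lorentz_factor(ang: AngularPosition, eps: float = 1e-3) -> float:
    """Normal-beam rotation-geometry Lorentz factor 1/(cos chi_d sin 2theta_B).

    Equatorial spots reduce to the classic 1/sin(2theta).  Raises
    :class:`BlindRegionError` when ``cos chi_d * sin 2theta_B <= eps``
    (reflections near the rotation axis cross the Ewald sphere
    tangentially and cannot be corrected).
    """
    denom = (math.cos(math.radians(ang.chi_d)) *
             math.sin(math.radians(ang.two_theta_b)))
    if denom <= eps:
        raise BlindRegionError(
            f"Lorentz factor undefined at 2theta_B={ang.two_theta_b:.3f}, "
            f"chi_d={ang.chi_d:.3f} (blind region)")
    return 1.0 / denom


def classify(predictions: pd.DataFrame, observations, ub,
             geom: DetectorGeometry, scan: ScanConfig,
             tol_recip: float = 0.1, near_factor: float = 3.0,
             qs=None):
    """Label every prediction with exactly one quality category.

    ``predictions`` is the table from
    :func:`~curvedpsd.indexing.predict_observations` (one row per Ewald
    crossing).  ``observations`` is the list of integrated
    :class:`~curvedpsd.peaksearch.Peak3D`; their reciprocal vectors are
    computed via ``qs`` (pass precomputed vectors to skip the conversion).
    Matching is greedy nearest-first in fractional-hkl distance under the
    UB metric, each observation assigned to at most one prediction.
    """
    from .indexing import observations_to_q

    ubm = ub.matrix if isinstance(ub, UBMatrix) else np.asarray(ub, float)
    inv = np.linalg.inv(ubm)
    if qs is None:
        qs = observations_to_q(observations, geom, scan)
    qs = np.atleast_2d(np.asarray(qs, float)) if len(observations) else \
        np.zeros((0, 3))
    obs_hr = qs @ inv.T

    preds = predictions.reset_index(drop=True)
    pred_hkl = preds[["h", "k", "l"]].to_numpy(dtype=float)

    phi_end = scan.phi_start + scan.phi_span
    observable = np.ones(len(preds), dtype=bool)
    labels = np.array(["no_peak"] * len(preds), dtype=object)
    for i, row in preds.iterrows():
        if not geom.contains(row["x"], row["y"]):
            labels[i] = "out_of_experimental_area"
            observable[i] = False
        elif not (scan.phi_start <= row["phi"] < phi_end):
            labels[i] = "out_of_expected_region"
            observable[i] = False

    # pairwise fractional-hkl distances, greedy nearest-first assignment
    matches = {}
    if len(obs_hr) and observable.any():
        cand_p = np.where(observable)[0]
        dist = np.linalg.norm(
            pred_hkl[cand_p][:, None, :] - obs_hr[None, :, :], axis=2)
        order = np.argsort(dist, axis=None)
        used_p, used_o = set(), set()
        limit = near_factor * tol_recip
        for flat in order:
            pi, oi = np.unravel_index(flat, dist.shape)
            d = dist[pi, oi]
            if d > limit:
                break
            p = int(cand_p[pi])
            if p in used_p or oi in used_o:
                continue
            used_p.add(p)
            used_o.add(int(oi))
            matches[p] = (int(oi), float(d))

    out = []
    for i, row in preds.iterrows():
        hkl = (int(row["h"]), int(row["k"]), int(row["l"]))
        common = dict(branch=str(row.get("branch", "")), phi=float(row["phi"]),
                      two_theta_b=float(row["two_theta_b"]),
                      chi_d=float(row["chi_d"]))
        if not observable[i]:
            out.append(Reflection(hkl, labels[i], **common))
            continue
        if i in matches:
            oi, d = matches[i]
            obs = observations[oi]
            if d < tol_recip:
                quality = "partial" if obs.partial else "good_peak"
            else:
                quality = "no_good_peak"
            out.append(Reflection(hkl, quality, peak=obs, residual=d,
                                  **common))
        else:
            out.append(Reflection(hkl, "no_peak", **common))
    return out


def build_reflection_list(classified, scale: float = 1.0,
                          include_partial: bool = True,
                          lorentz_eps: float = 1e-3):
    """Assemble the final [h k l F^2 sigma(F^2)] table and a rejects table.

    Good (and by default partial) peaks are Lorentz-corrected and scaled;
    duplicate observations of one hkl — e.g. the entry and exit Ewald
    crossings — are combined by inverse-variance weighting, with the
    internal agreement reported as a chi value.  Everything else lands in
    the rejects table with its reason.
    """
    keep_quality = {"good_peak"} | ({"partial"} if include_partial else set())
    measured = {}
    rejects = []
    for refl in classified:
        if refl.quality in keep_quality and refl.peak is not None:
            ang = AngularPosition(refl.two_theta_b, refl.chi_d)
            try:
                lf = lorentz_factor(ang, eps=lorentz_eps)
            except BlindRegionError as exc:
                rejects.append((refl, f"blind_region: {exc}"))
                continue
            f2 = refl.peak.intensity / lf * scale
            sig = refl.peak.sigma / lf * scale
            measured.setdefault(refl.hkl, []).append((f2, sig, refl))
        else:
            rejects.append((refl, refl.quality))

    rows = []
    for hkl, entries in measured.items():
        f2s = np.array([e[0] for e in entries])
        sigs = np.array([e[1] for e in entries])
        flag = "partial" if any(e[2].quality == "partial"
                                for e in entries) else "good"
        if len(entries) == 1:
            f2, sig, agreement = float(f2s[0]), float(sigs[0]), 0.0
        else:
            w = 1.0 / sigs ** 2
            f2 = float(np.sum(w * f2s) / np.sum(w))
            sig = float(1.0 / math.sqrt(np.sum(w)))
            agreement = float(math.sqrt(np.sum(w * (f2s - f2) ** 2)
                                        / max(len(entries) - 1, 1)))
        rows.append({"h": hkl[0], "k": hkl[1], "l": hkl[2],
                     "f2": f2, "sigma_f2": sig, "flag": flag,
                     "n_obs": len(entries), "agreement": agreement})
    table = pd.DataFrame(
        rows, columns=["h", "k", "l", "f2", "sigma_f2", "flag",
                       "n_obs", "agreement"])
    if len(table):
        table = table.sort_values(["h", "k", "l"]).reset_index(drop=True)
    reject_table = pd.DataFrame(
        [{"h": r.hkl[0], "k": r.hkl[1], "l": r.hkl[2], "reason": why,
          "branch": r.branch} for r, why in rejects],
        columns=["h", "k", "l", "reason", "branch"])
    return table, reject_table


def export_reflections(table: pd.DataFrame, path, fmt: str = "plain"):
    """Write a reflection table as a plain hkl table or SHELX HKLF-4 file.

    The SHELX dialect uses fixed-width records: three I4 index fields and
    two F8.2 value fields.  Values that do not fit their field raise an
    overflow error naming the reflection.
    """
    path = Path(path)
    if fmt == "plain":
        from .frame_io import write_table
        df = table[["h", "k", "l", "f2", "sigma_f2", "flag"]]
        return write_table("hkl", df, path)
    if fmt != "shelx_hkl":
        raise ValueError(f"unknown export format {fmt!r}")
    lines = []
    for _, row in table.iterrows():
        h, k, l = int(row["h"]), int(row["k"]), int(row["l"])
        f2, sig = float(row["f2"]), float(row["sigma_f2"])
        for v in (h, k, l):
            if not -999 <= v <= 9999:
                raise OverflowError(
                    f"index {v} of reflection ({h},{k},{l}) overflows the "
                    "4-column SHELX field")
        for v in (f2, sig):
            if not -99999.99 <= v <= 999999.99 or len(f"{v:8.2f}") > 8:
                raise OverflowError(
                    f"value {v} of reflection ({h},{k},{l}) overflows the "
                    "8-column SHELX field")
        lines.append(f"{h:4d}{k:4d}{l:4d}{f2:8.2f}{sig:8.2f}")
    lines.append(f"{0:4d}{0:4d}{0:4d}{0.0:8.2f}{0.0:8.2f}")  # terminator
    path.write_text("\n".join(lines) + "\n")
    return path
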