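"""Instrument configuration profiles and their on-disk representation.

A profile is a human-editable YAML document with two sections, ``geometry``
and ``scan``, whose keys mirror the fields of
:class:`~curvedpsd.geometry.DetectorGeometry` and
:class:`~curvedpsd.geometry.ScanConfig`.  Two built-in profiles ship with
the package:

``hanaro``
    The default HANARO-like curved-PSD geometry.  All constants are the
    published machine parameters except the equator origin ``y0``, which is
    set to 194.135 so that the elevation range implied by the active
    Y-window (100-360 channels) matches the instrument's stated chi_d range
    of roughly -18.4 to +34.5 degrees.  The published parameter table
    prints ``y0 = 94.135`` together with that same window, which would put
    the whole face *above* the equator and is inconsistent with the layer
    ranges the instrument demonstrably records; the 100-channel shift
    reconciles the two.

``hanaro-printed``
    The machine-parameter table exactly as printed (``y0 = 94.135``),
    retained for reference and cross-checking.
"""

from __future__ import annotations

import dataclasses
import io

import yaml

from .geometry import DetectorGeometry, ScanConfig

__all__ = ["builtin_profile", "load_profile", "save_profile",
           "geometry_from_dict", "scan_from_dict", "profile_to_dict"]

_GEOM_FIELDS = {f.name for f in dataclasses.fields(DetectorGeometry)}
_SCAN_FIELDS = {f.name for f in dataclasses.fields(ScanConfig)}

_BUILTIN = {
    "hanaro": {
        "geometry": dict(radius=530.0, n_x=512, n_y=512,
                         c_x=0.2614, c_y=0.003917,
                         x0=181.50, y0=194.135, xy_slope=0.0041,
                         arm_angle=40.0,
                         active_window=[[60.0, 100.0], [460.0, 360.0]],
                         chi_mode="tan"),
        "scan": dict(wavelength=1.153, delta_phi=0.2, n_frames=1800,
                     phi_start=0.0, omega_offset=0.0),
    },
    "hanaro-printed": {
        "geometry": dict(radius=530.0, n_x=512, n_y=512,
                         c_x=0.2614, c_y=0.003917,
                         x0=181.50, y0=94.135, xy_slope=0.0041,
                         arm_angle=40.0,
                         active_window=[[60.0, 100.0], [460.0, 360.0]],
                         chi_mode="tan"),
        "scan": dict(wavelength=1.153, delta_phi=0.2, n_frames=1800,
                     phi_start=0.0, omega_offset=0.0),
    },
}


def geometry_from_dict(d) -> DetectorGeometry:
    unknown = set(d) - _GEOM_FIELDS
    if unknown:
        raise ValueError(f"unknown geometry keys: {sorted(unknown)}")
    d = dict(d)
    if "active_window" in d:
        (xmin, ymin), (xmax, ymax) = d["active_window"]
        d["active_window"] = ((float(xmin), float(ymin)),
                              (float(xmax), float(ymax)))
    return DetectorGeometry(**d)


def scan_from_dict(d) -> ScanConfig:
    unknown = set(d) - _SCAN_FIELDS
    if unknown:
        raise ValueError(f"unknown scan keys: {sorted(unknown)}")
    return ScanConfig(**d)


def builtin_profile(name: str = "hanaro"):
    """Return (DetectorGeometry, ScanConfig) for a named built-in profile."""
    try:
        raw = _BUILTIN[name]
    except KeyError:
        raise KeyError(f"no built-in profile {name!r}; available: "
                       f"{sorted(_BUILTIN)}") from None
    return geometry_from_dict(raw["geometry"]), scan_from_dict(raw["scan"])


def profile_to_dict(geom: DetectorGeometry, scan: ScanConfig | None = None):
    out = {"geometry": dataclasses.asdict(geom)}
    out["geometry"]["active_window"] = [list(p) for p in geom.active_window]
    if scan is not None:
        out["scan"] = dataclasses.asdict(scan)
    return out


def load_profile(path):
    """Read a profile file; returns (DetectorGeometry, ScanConfig or None)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "geometry" not in raw:
        raise ValueError(f"{path}: not a profile file (missing 'geometry')")
    geom = geometry_from_dict(raw["geometry"])
    scan = scan_from_dict(raw["scan"]) if "scan" in raw else None
    return geom, scan


def save_profile(geom: DetectorGeometry, scan, path):
    """Write a profile file (scan may be None)."""
    with open(path, "w") as fh:
        yaml.safe_dump(profile_to_dict(geom, scan), fh,
                       default_flow_style=None, sort_keys=False)
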