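"""Instrument and crystal geometry for a curved-PSD rotation diffractometer.

Coordinate conventions used throughout the package
--------------------------------------------------

Laboratory frame (right-handed):

* the incident monochromatic beam travels along ``+x``;
* the sample rotation axis (the phi axis) is vertical, along ``+z``;
* the in-plane diffraction angle ``2theta_B`` opens from ``+x`` toward
  ``+y``, so the detector sits on the ``+y`` side of the beam.

A Bragg spot on the detector is described either by fractional channel
coordinates ``(X, Y)`` (0-based, center-of-gravity positions allowed) or by
the equivalent angular pair ``(2theta_B, chi_d)``: ``2theta_B`` is the
diffraction angle measured in the horizontal (equatorial) plane and
``chi_d`` is the angle of elevation above that plane.  The detector is a
cylinder section, curved horizontally around the sample at radius ``L`` and
flat vertically, so ``2theta_B`` is linear in the X channel while ``chi_d``
follows a tangent relation in Y.

Channel-to-angle model::

    2theta_B = 2theta_c + c_x * (X - X0)
    chi_d    = arctan( c_y * ((Y - Y0) - s * (X - X0)) )

where ``2theta_c`` is the detector-arm angle, ``(X0, Y0)`` the origin
channel of the arm axis and the equator, ``c_x`` the degrees-per-channel
conversion factor, ``c_y`` the tangent-units-per-channel vertical factor
(vertical channel pitch divided by the radius ``L``) and ``s`` a small
dimensionless X-Y channel coupling (shear) of the delay-line readout.  The
shear is carried by the elevation relation: a line of constant ``chi_d``
(a layer line, in particular the equator) appears tilted by slope ``s`` in
raw ``(X, Y)`` channels, which is exactly the feature the layer-line
calibration fits.  A linear small-angle variant ``chi_d = c_y*(...)`` (in
radians) is available through ``DetectorGeometry.chi_mode`` for
cross-checking.

Angles are degrees at every interface and radians internally.  Scattering
vectors carry no 2*pi: ``|q| = 2 sin(theta) / lambda = 1/d``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "DetectorGeometry",
    "AngularPosition",
    "ScanConfig",
    "Cell",
    "MonochromatorSetting",
    "GE_LATTICE_CONSTANT",
    "MONOCHROMATOR_TABLE",
    "DegenerateCellError",
    "OutOfFaceError",
    "channels_to_angles",
    "angles_to_channels",
    "scattering_vector_lab",
    "angles_from_lab_vector",
    "lab_to_crystal",
    "crystal_to_lab",
    "ewald_crossings",
    "total_scattering_angle",
    "monochromator_wavelength",
    "cell_volume",
    "d_spacing",
    "cell_from_ub",
]


class DegenerateCellError(ValueError):
    """Raised when lattice parameters do not define a positive cell volume."""


class OutOfFaceError(ValueError):
    """Raised when an angular position falls outside the full detector face."""

    def __init__(self, message, x=None, y=None):
        super().__init__(message)
        self.x = x
        self.y = y


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DetectorGeometry:
    """Machine constants mapping detector channels to diffraction angles.

    Parameters
    ----------
    radius : float
        Sample-to-detector distance L in mm (cylinder radius).
    n_x, n_y : int
        Channel counts of the digitized image (readout resolution).
    c_x : float
        X conversion factor, degrees of ``2theta_B`` per channel.
    c_y : float
        Y conversion factor in tangent units per channel
        (vertical pitch / L).
    x0, y0 : float
        Origin channel: ``x0`` is where ``2theta_B`` equals the arm angle,
        ``y0`` the equator line at ``X = x0``.
    xy_slope : float
        Dimensionless X-Y channel coupling ``s`` (see module docstring).
    arm_angle : float
        Nominal detector arm angle ``2theta_c`` in degrees.
    active_window : ((float, float), (float, float))
        ``((X_min, Y_min), (X_max, Y_max))``, inclusive channel bounds of
        the usable detector area.
    chi_mode : str
        ``"tan"`` (default, curved-horizontal / flat-vertical detector) or
        ``"linear"`` small-angle variant.
    """

    radius: float = 530.0
    n_x: int = 512
    n_y: int = 512
    c_x: float = 0.2614
    c_y: float = 0.003917
    x0: float = 181.50
    y0: float = 194.135
    xy_slope: float = 0.0041
    arm_angle: float = 40.0
    active_window: tuple = ((60.0, 100.0), (460.0, 360.0))
    chi_mode: str = "tan"

    def __post_init__(self):
        if not (self.radius > 0 and self.c_x > 0 and self.c_y > 0):
            raise ValueError("radius, c_x and c_y must be positive")
        (xmin, ymin), (xmax, ymax) = self.active_window
        if not (0 <= xmin < xmax < self.n_x and 0 <= ymin < ymax < self.n_y):
            raise ValueError("active_window must lie inside [0,n_x)x[0,n_y) "
                             "with min < max")
        if self.chi_mode not in ("tan", "linear"):
            raise ValueError(f"unknown chi_mode {self.chi_mode!r}")

    # -- convenience -------------------------------------------------------
    @property
    def x_bounds(self):
        return self.active_window[0][0], self.active_window[1][0]

    @property
    def y_bounds(self):
        return self.active_window[0][1], self.active_window[1][1]

    def contains(self, x, y):
        """True where (x, y) lies inside the active window (inclusive)."""
        (xmin, ymin), (xmax, ymax) = self.active_window
        return (np.asarray(x) >= xmin) & (np.asarray(x) <= xmax) & \
               (np.asarray(y) >= ymin) & (np.asarray(y) <= ymax)

    def with_arm(self, arm_angle):
        """Copy of this geometry at a different detector-arm angle."""
        return replace(self, arm_angle=float(arm_angle))


@dataclass(frozen=True)
class AngularPosition:
    """A Bragg-spot direction: in-plane angle and elevation, degrees."""

    two_theta_b: float
    chi_d: float

    def __post_init__(self):
        tt = np.asarray(self.two_theta_b, dtype=float)
        ch = np.asarray(self.chi_d, dtype=float)
        if not (np.all(np.isfinite(tt)) and np.all(np.isfinite(ch))):
            raise ValueError("non-finite angular position")
        if np.any(np.abs(ch) >= 90.0):
            raise ValueError("chi_d must satisfy -90 < chi_d < 90 degrees")


@dataclass(frozen=True)
class ScanConfig:
    """A continuous phi-rotation scan: fixed chi = 0, omega fixed.

    ``phi`` is a right-handed rotation of the crystal about the vertical
    (+z) axis; frame ``i`` integrates over
    ``[phi_start + i*delta_phi, phi_start + (i+1)*delta_phi)``.
    """

    wavelength: float
    delta_phi: float = 0.2
    n_frames: int = 1800
    phi_start: float = 0.0
    omega_offset: float = 0.0

    def __post_init__(self):
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")
        if self.delta_phi <= 0 or self.n_frames < 0:
            raise ValueError("delta_phi must be > 0 and n_frames >= 0")
        if self.n_frames * self.delta_phi > 360.0 + 1e-6:
            raise ValueError("scan exceeds a full rotation")

    @property
    def phi_span(self):
        return self.n_frames * self.delta_phi

    @property
    def full_circle(self):
        return abs(self.phi_span - 360.0) < 1e-9

    def phi_mid(self, frame_index):
        return self.phi_start + (np.asarray(frame_index) + 0.5) * self.delta_phi

    def frame_of(self, phi):
        """Frame index containing rotation angle phi (may be out of range)."""
        return np.floor((np.asarray(phi) - self.phi_start) / self.delta_phi).astype(int)


@dataclass(frozen=True)
class Cell:
    """Unit-cell lattice parameters: lengths in Angstrom, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self):
        if min(self.a, self.b, self.c) <= 0:
            raise DegenerateCellError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise DegenerateCellError("cell angles must lie in (0, 180)")
        if self._discriminant() <= 0:
            raise DegenerateCellError("cell angles do not close a 3D cell")

    def _discriminant(self):
        ca, cb, cg = (math.cos(math.radians(x))
                      for x in (self.alpha, self.beta, self.gamma))
        return 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg

    @property
    def volume(self):
        """Cell volume in cubic Angstrom (triclinic closed form)."""
        return self.a * self.b * self.c * math.sqrt(self._discriminant())

    @property
    def parameters(self):
        return (self.a, self.b, self.c, self.alpha, self.beta, self.gamma)

    def reciprocal_parameters(self):
        """(a*, b*, c*, alpha*, beta*, gamma*) without a 2*pi factor."""
        v = self.volume
        sa, sb, sg = (math.sin(math.radians(x))
                      for x in (self.alpha, self.beta, self.gamma))
        ca, cb, cg = (math.cos(math.radians(x))
                      for x in (self.alpha, self.beta, self.gamma))
        astar = self.b * self.c * sa / v
        bstar = self.a * self.c * sb / v
        cstar = self.a * self.b * sg / v
        cos_as = (cb * cg - ca) / (sb * sg)
        cos_bs = (ca * cg - cb) / (sa * sg)
        cos_gs = (ca * cb - cg) / (sa * sb)
        return (astar, bstar, cstar,
                math.degrees(math.acos(max(-1.0, min(1.0, cos_as)))),
                math.degrees(math.acos(max(-1.0, min(1.0, cos_bs)))),
                math.degrees(math.acos(max(-1.0, min(1.0, cos_gs)))))

    def b_matrix(self):
        """Reciprocal-basis matrix B (Busing-Levy), columns a*, b*, c*.

        ``B @ hkl`` is the reciprocal vector of ``hkl`` in a crystal-fixed
        orthonormal frame; ``|B @ hkl| = 1/d(hkl)``.
        """
        astar, bstar, cstar, al_s, be_s, ga_s = self.reciprocal_parameters()
        ca = math.cos(math.radians(self.alpha))
        cbs, sbs = math.cos(math.radians(be_s)), math.sin(math.radians(be_s))
        cgs, sgs = math.cos(math.radians(ga_s)), math.sin(math.radians(ga_s))
        return np.array([
            [astar, bstar * cgs, cstar * cbs],
            [0.0, bstar * sgs, -cstar * sbs * ca],
            [0.0, 0.0, 1.0 / self.c],
        ])

    def d_spacing(self, hkl):
        """Interplanar spacing d(hkl) in Angstrom (triclinic metric)."""
        return d_spacing(self, hkl)


#: reference germanium lattice constant (Angstrom) for the monochromator
GE_LATTICE_CONSTANT = 5.6575


@dataclass(frozen=True)
class MonochromatorSetting:
    """One slab position of the rotatable Ge(311) monochromator."""

    plane: tuple
    rotation_angle: float
    wavelength: float
    takeoff_angle: float = 39.5

    def __post_init__(self):
        lam = monochromator_wavelength(self.plane, takeoff=self.takeoff_angle)
        if abs(lam - self.wavelength) > 0.005 * self.wavelength:
            raise ValueError(
                f"stored wavelength {self.wavelength} inconsistent with "
                f"Bragg value {lam:.4f} for Ge{self.plane}")


def _mono_table():
    # Ge(111) is listed at its computed Bragg value 2.2076 A; the nominal
    # instrument value 2.204 A differs by 0.17% for any standard Ge constant.
    return (
        MonochromatorSetting((5, 1, 1), -9.46, 0.7358),
        MonochromatorSetting((3, 1, 1), 0.0, 1.153),
        MonochromatorSetting((4, 2, 2), 10.09, 0.7804),
        MonochromatorSetting((1, 1, 1), 29.57, 2.2076),
    )


# ---------------------------------------------------------------------------
# channel <-> angle transforms
# ---------------------------------------------------------------------------


def _validate_finite(*arrays):
    for a in arrays:
        if not np.all(np.isfinite(a)):
            raise ValueError("non-finite input")


def channels_to_angles(x, y, geom: DetectorGeometry) -> AngularPosition:
    """Convert fractional channel coordinates to (2theta_B, chi_d) degrees.

    Points outside the active window are converted normally; use
    ``geom.contains`` to flag them.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _validate_finite(x, y)
    two_theta = geom.arm_angle + geom.c_x * (x - geom.x0)
    v = geom.c_y * ((y - geom.y0) - geom.xy_slope * (x - geom.x0))
    if geom.chi_mode == "tan":
        chi = np.degrees(np.arctan(v))
    else:
        chi = np.degrees(v)
    if two_theta.ndim == 0:
        return AngularPosition(float(two_theta), float(chi))
    return AngularPosition(two_theta, chi)


def angles_to_channels(ang: AngularPosition, geom: DetectorGeometry,
                       strict: bool = True):
    """Exact algebraic inverse of :func:`channels_to_angles`.

    With ``strict`` the result must land on the full detector face
    ``[0, n_x) x [0, n_y)``; otherwise an :class:`OutOfFaceError` carrying
    the offending coordinates is raised.
    """
    tt = np.asarray(ang.two_theta_b, dtype=float)
    chi = np.asarray(ang.chi_d, dtype=float)
    _validate_finite(tt, chi)
    x = geom.x0 + (tt - geom.arm_angle) / geom.c_x
    if geom.chi_mode == "tan":
        v = np.tan(np.radians(chi))
    else:
        v = np.radians(chi)
    y = geom.y0 + geom.xy_slope * (x - geom.x0) + v / geom.c_y
    if strict:
        bad = (x < 0) | (x >= geom.n_x) | (y < 0) | (y >= geom.n_y)
        if np.any(bad):
            xb = np.atleast_1d(x)[np.atleast_1d(bad)][0]
            yb = np.atleast_1d(y)[np.atleast_1d(bad)][0]
            raise OutOfFaceError(
                f"angular position maps outside the detector face at "
                f"X={xb:.2f}, Y={yb:.2f}", x=xb, y=yb)
    if x.ndim == 0:
        return float(x), float(y)
    return x, y


# ---------------------------------------------------------------------------
# scattering vectors
# ---------------------------------------------------------------------------


def scattering_vector_lab(ang: AngularPosition, wavelength: float):
    """Laboratory-frame scattering vector Q (1/Angstrom) of a spot.

    With the incident unit vector along +x and the diffracted unit vector

        s = (cos chi_d cos 2theta_B, cos chi_d sin 2theta_B, sin chi_d),

    ``Q = (s - x_hat)/lambda``; then ``|Q| = 2 sin(theta)/lambda`` where the
    total scattering angle obeys ``cos 2theta = cos chi_d cos 2theta_B``.
    """
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    tt = np.radians(np.asarray(ang.two_theta_b, dtype=float))
    chi = np.radians(np.asarray(ang.chi_d, dtype=float))
    s = np.stack([np.cos(chi) * np.cos(tt),
                  np.cos(chi) * np.sin(tt),
                  np.sin(chi)], axis=-1)
    s[..., 0] -= 1.0
    return s / wavelength


def angles_from_lab_vector(q_lab, wavelength: float) -> AngularPosition:
    """Inverse of :func:`scattering_vector_lab` (diffracted-beam direction)."""
    q = np.asarray(q_lab, dtype=float)
    s = wavelength * q.copy()
    s[..., 0] += 1.0
    norm = np.linalg.norm(s, axis=-1)
    if not np.allclose(norm, 1.0, atol=1e-6):
        raise ValueError("vector does not satisfy the elastic condition")
    chi = np.degrees(np.arcsin(np.clip(s[..., 2], -1.0, 1.0)))
    tt = np.degrees(np.arctan2(s[..., 1], s[..., 0]))
    if q.ndim == 1:
        return AngularPosition(float(tt), float(chi))
    return AngularPosition(tt, chi)


def total_scattering_angle(ang: AngularPosition):
    """Full scattering angle 2theta (degrees): cos 2theta = cos chi cos 2theta_B."""
    c = (np.cos(np.radians(np.asarray(ang.chi_d, dtype=float))) *
         np.cos(np.radians(np.asarray(ang.two_theta_b, dtype=float))))
    return np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))


def _rotz(phi_deg):
    p = math.radians(phi_deg)
    c, s = math.cos(p), math.sin(p)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def lab_to_crystal(q_lab, phi_deg: float):
    """Rotate a laboratory Q into the crystal frame at phi = 0.

    ``q = R_z(-phi) Q_lab``; the crystal was rotated by +phi when the spot
    was recorded, so undoing that rotation expresses the vector in the
    crystal-fixed frame.
    """
    return np.asarray(q_lab, dtype=float) @ _rotz(-phi_deg).T


def crystal_to_lab(q, phi_deg: float):
    """Inverse of :func:`lab_to_crystal`: Q_lab = R_z(phi) q."""
    return np.asarray(q, dtype=float) @ _rotz(phi_deg).T


def ewald_crossings(q, wavelength: float):
    """Rotation angles at which a crystal-frame vector crosses the Ewald sphere.

    Solves ``(R_z(phi) q) . x_hat = -lambda |q|^2 / 2`` for phi in
    [0, 360).  Returns a list of ``(phi_deg, branch)`` with branch
    ``"entry"`` where the reciprocal point is moving into the sphere
    (diffracted beam toward +y, the detector side) and ``"exit"`` on the
    opposite side.  Empty for blind-region vectors (no real solution),
    including any vector parallel to the rotation axis.
    """
    q = np.asarray(q, dtype=float)
    qx, qy, qz = q
    rho = math.hypot(qx, qy)
    c = -wavelength * float(q @ q) / 2.0
    if rho < 1e-12 or abs(c) > rho:
        return []
    delta = math.atan2(qy, qx)
    base = math.acos(max(-1.0, min(1.0, c / rho)))
    out = []
    for sgn in (+1.0, -1.0):
        phi = math.degrees(sgn * base - delta) % 360.0
        # at the crossing Q_y determines the diffraction side: Q_y > 0 means
        # the diffracted beam points toward the detector (+y) and the point
        # is entering the sphere (d|Q + x/lambda|/dphi = -Q_y / |...| < 0).
        q_lab = crystal_to_lab(q, phi)
        branch = "entry" if q_lab[1] > 0 else "exit"
        out.append((phi, branch))
    if abs(c) == rho:  # tangential: the two solutions coincide
        out = out[:1]
    return out


# ---------------------------------------------------------------------------
# wavelength selection and cell arithmetic
# ---------------------------------------------------------------------------

MONOCHROMATOR_TABLE = None  # populated below (needs monochromator_wavelength)


def monochromator_wavelength(plane, a_ge: float = GE_LATTICE_CONSTANT,
                             takeoff: float = 39.5) -> float:
    """Wavelength selected by a Ge monochromator plane at a take-off angle.

    ``lambda = 2 d(hkl) sin(takeoff/2)`` with ``d = a_Ge/sqrt(h^2+k^2+l^2)``.
    Planes outside the [0,-1,1] zone of the Ge(311) slab (i.e. with k != l)
    cannot be reached by rotating the slab about its vertical axis; a
    warning is issued for them.
    """
    h, k, l = plane
    if a_ge <= 0:
        raise ValueError("a_ge must be positive")
    if h == 0 and k == 0 and l == 0:
        raise ValueError("null reflection plane")
    if k != l:
        warnings.warn(f"plane {plane} is outside the [0,-1,1] zone of the "
                      "Ge(311) slab", stacklevel=2)
    d = a_ge / math.sqrt(h * h + k * k + l * l)
    lam = 2.0 * d * math.sin(math.radians(takeoff / 2.0))
    if lam <= 0:
        raise ValueError("implausible (non-positive) wavelength")
    return lam


MONOCHROMATOR_TABLE = _mono_table()


def cell_volume(cell: Cell) -> float:
    """Unit-cell volume in cubic Angstrom."""
    return cell.volume


def d_spacing(cell: Cell, hkl) -> float:
    """d(hkl) in Angstrom from the general triclinic reciprocal metric."""
    hkl = np.asarray(hkl, dtype=float)
    if not np.any(hkl):
        raise ValueError("d-spacing undefined for hkl = (0,0,0)")
    return 1.0 / float(np.linalg.norm(cell.b_matrix() @ hkl))


def cell_from_ub(ub) -> Cell:
    """Lattice parameters of the direct cell implied by a UB matrix."""
    ub = np.asarray(ub, dtype=float)
    gstar = ub.T @ ub
    g = np.linalg.inv(gstar)
    a, b, c = np.sqrt(np.diag(g))
    al = math.degrees(math.acos(g[1, 2] / (b * c)))
    be = math.degrees(math.acos(g[0, 2] / (a * c)))
    ga = math.degrees(math.acos(g[0, 1] / (a * b)))
    return Cell(a, b, c, al, be, ga)
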