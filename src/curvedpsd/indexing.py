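"""UB-matrix determination, refinement, Bravais-lattice search and spot
prediction from observed reciprocal-space vectors.

The UB matrix maps integer Miller indices to crystal-frame reciprocal
vectors at phi = 0: ``q = UB @ hkl`` (units 1/Angstrom, no 2*pi).  Four
construction routes are provided:

* :func:`vector_minimum` - auto-indexing without prior knowledge, from the
  three shortest linearly independent candidate vectors (observations and
  their pairwise differences) that integer-index the data set;
* :func:`ub_from_two_reflections` - known cell plus two indexed
  reflections (orthonormal-triad orientation construction);
* :func:`ub_from_three_reflections` - three indexed reflections, no cell
  assumed (exact linear solve);
* :func:`ub_montecarlo` - known cell, random orientation search scored by
  how many observations index.

Indexing residuals are measured in fractional hkl units,
``|UB^-1 q - nearest integers|``; the acceptance criterion for a "good"
index is a residual below 0.1 in that metric (configurable).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .geometry import (Cell, DetectorGeometry, ScanConfig, cell_from_ub,
                       channels_to_angles, lab_to_crystal,
                       scattering_vector_lab)
from .simulate import predict_spots, predictions_to_frame

__all__ = ["UBMatrix", "IndexedObservation", "IndexingError",
           "observations_to_q", "index_points", "vector_minimum",
           "ub_from_two_reflections", "ub_from_three_reflections",
           "ub_montecarlo", "bravais_search", "refine_ub_lsq",
           "predict_observations", "canonical_lengths"]

INDEX_TOL_DEFAULT = 0.1   # fractional-hkl acceptance radius for one index


class IndexingError(RuntimeError):
    pass


@dataclass(frozen=True)
class UBMatrix:
    """Orientation matrix with optional refined-cell uncertainties."""

    matrix: np.ndarray
    cell_su: tuple | None = None
    lattice: str | None = None     # Bravais symbol like "cF", "mP", "aP"

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3) or abs(np.linalg.det(m)) < 1e-15:
            raise ValueError("UB must be a non-singular 3x3 matrix")
        object.__setattr__(self, "matrix", m)

    @property
    def cell(self) -> Cell:
        return cell_from_ub(self.matrix)

    def hkl_real(self, q):
        """Real-valued Miller indices of reciprocal vectors q (n,3)."""
        return np.atleast_2d(np.asarray(q, float)) @ \
            np.linalg.inv(self.matrix).T


@dataclass
class IndexedObservation:
    """One observation with its (nearest-integer) index assignment."""

    peak: object                  # Peak3D or None
    q: np.ndarray
    hkl_real: np.ndarray
    hkl: tuple
    residual: float
    indexed: bool


def observations_to_q(peaks, geom: DetectorGeometry, scan: ScanConfig):
    """Convert integrated 3D peaks to crystal-frame reciprocal vectors.

    Composition of channel->angle conversion, laboratory scattering-vector
    construction and the phi back-rotation, evaluated at each peak's phi
    centroid.  Peaks outside the active window are converted all the same
    (callers may flag them via ``geom.contains``).
    """
    qs = np.empty((len(peaks), 3))
    for i, p in enumerate(peaks):
        ang = channels_to_angles(p.x, p.y, geom)
        q_lab = scattering_vector_lab(ang, scan.wavelength)
        qs[i] = lab_to_crystal(q_lab, p.phi)
    return qs


def index_points(ub, qs, tol: float = INDEX_TOL_DEFAULT, peaks=None):
    """Assign nearest-integer indices; returns a list of IndexedObservation."""
    ub = ub.matrix if isinstance(ub, UBMatrix) else np.asarray(ub, float)
    qs = np.atleast_2d(np.asarray(qs, float))
    hr = qs @ np.linalg.inv(ub).T
    hi = np.rint(hr)
    res = np.linalg.norm(hr - hi, axis=1)
    out = []
    for i in range(len(qs)):
        out.append(IndexedObservation(
            peak=None if peaks is None else peaks[i], q=qs[i],
            hkl_real=hr[i], hkl=tuple(int(v) for v in hi[i]),
            residual=float(res[i]), indexed=bool(res[i] < tol)))
    return out


def _reduce_basis(basis):
    """Pairwise (Minkowski-style) size reduction of a 3-vector basis.

    Repeatedly replaces a column by its shortest translate under integer
    combinations of the others; unimodular, so the lattice is unchanged
    while the basis becomes the compact, near-orthogonal representative.
    """
    b = np.array(basis, dtype=float)
    for _ in range(100):
        changed = False
        for i in range(3):
            for j in range(3):
                if i == j:
                    continue
                m = round(float(b[:, i] @ b[:, j]) /
                          float(b[:, j] @ b[:, j]))
                if m != 0:
                    trial = b[:, i] - m * b[:, j]
                    if np.linalg.norm(trial) < np.linalg.norm(b[:, i]) - 1e-12:
                        b[:, i] = trial
                        changed = True
        if not changed:
            break
    order = np.argsort(np.linalg.norm(b, axis=0))
    b = b[:, order]
    if np.linalg.det(b) < 0:
        b[:, 2] = -b[:, 2]
    return b


def _indexed_fraction(basis, qs, tol):
    try:
        inv = np.linalg.inv(basis)
    except np.linalg.LinAlgError:
        return 0.0
    hr = qs @ inv.T
    return float(np.mean(np.linalg.norm(hr - np.rint(hr), axis=1) < tol))


def vector_minimum(qs, index_tol: float = INDEX_TOL_DEFAULT,
                   min_fraction: float = 0.8, det_floor: float = 1e-6,
                   max_candidates: int = 60,
                   dedupe_tol: float = 5e-3) -> UBMatrix:
    """Auto-index by the difference-vector (vector-minimum) search.

    Builds the candidate set from the observations and all their pairwise
    differences, collapsed onto a ``dedupe_tol`` grid (1/A) — coarse
    enough to merge noisy repeats of one lattice vector, fine against any
    plausible reciprocal basis length — then scans triples of short
    linearly independent candidates (|det| above ``det_floor``, in
    1/A^3) for the first basis whose inverse integer-indexes at least
    ``min_fraction`` of the observations within ``index_tol``.  The
    accepted primitive basis is least-squares refined on the points it
    indexes and returned with a right-handed sign convention.
    """
    qs = np.atleast_2d(np.asarray(qs, float))
    if len(qs) < 3:
        raise IndexingError("need at least 3 observations")
    if np.linalg.matrix_rank(qs, tol=1e-8) < 3:
        raise IndexingError("observations are coplanar (rank-deficient)")

    diffs = (qs[:, None, :] - qs[None, :, :]).reshape(-1, 3)
    cands = np.vstack([qs, diffs])
    norms = np.linalg.norm(cands, axis=1)
    cands = cands[norms > 2 * dedupe_tol]
    # canonical sign, then average each dedupe-grid cluster
    sign = np.where(cands[:, 0] != 0, np.sign(cands[:, 0]),
                    np.where(cands[:, 1] != 0, np.sign(cands[:, 1]),
                             np.sign(cands[:, 2])))
    cands = cands * sign[:, None]
    key = np.round(cands / dedupe_tol).astype(np.int64)
    _, inverse = np.unique(key, axis=0, return_inverse=True)
    sums = np.zeros((inverse.max() + 1, 3))
    np.add.at(sums, inverse, cands)
    counts = np.bincount(inverse)
    cands = sums / counts[:, None]
    cands = cands[np.argsort(np.linalg.norm(cands, axis=1))]
    cands = cands[:max_candidates]

    best_frac = 0.0
    m = len(cands)
    # scan triples ordered by the largest member index, i.e. shortest first
    for k in range(2, m):
        for i, j in itertools.combinations(range(k), 2):
            basis = np.column_stack([cands[i], cands[j], cands[k]])
            if abs(np.linalg.det(basis)) < det_floor:
                continue
            frac = _indexed_fraction(basis, qs, index_tol)
            best_frac = max(best_frac, frac)
            if frac >= min_fraction:
                basis = _reduce_basis(basis)
                obs = index_points(basis, qs, index_tol)
                idx = [o for o in obs if o.indexed]
                refined = refine_ub_lsq(
                    UBMatrix(basis),
                    hkls=[o.hkl for o in idx], qs=[o.q for o in idx])
                mat = refined.matrix
                if np.linalg.det(mat) < 0:
                    mat = mat @ np.diag([1, 1, -1])
                return UBMatrix(mat, cell_su=refined.cell_su)
    raise IndexingError(
        f"no candidate basis indexes >= {min_fraction:.0%} of the points "
        f"(best fraction {best_frac:.0%})")


def ub_from_two_reflections(q1, q2, cell: Cell, hkl1, hkl2,
                            length_tol: float = 0.02) -> UBMatrix:
    """Orientation from a known cell and two indexed reflections.

    Builds B from the cell, then the proper-orthogonal U that aligns the
    orthonormal triad spanned by (B hkl1, B hkl2) with the one spanned by
    (q1, q2).
    """
    b = cell.b_matrix()
    q1 = np.asarray(q1, float)
    q2 = np.asarray(q2, float)
    h1 = b @ np.asarray(hkl1, float)
    h2 = b @ np.asarray(hkl2, float)
    for qi, hi, lab in ((q1, h1, "1"), (q2, h2, "2")):
        expected = np.linalg.norm(hi)
        if abs(np.linalg.norm(qi) - expected) > length_tol * expected:
            raise ValueError(
                f"|q{lab}| = {np.linalg.norm(qi):.5f} inconsistent with "
                f"1/d = {expected:.5f} for the given cell (metric mismatch)")

    def triad(u, v):
        t1 = u / np.linalg.norm(u)
        t3 = np.cross(u, v)
        n3 = np.linalg.norm(t3)
        if n3 < 1e-10 * np.linalg.norm(u) * np.linalg.norm(v):
            raise ValueError("collinear reflections cannot fix the orientation")
        t3 = t3 / n3
        return np.column_stack([t1, np.cross(t3, t1), t3])

    tc = triad(h1, h2)
    tq = triad(q1, q2)
    u = tq @ tc.T
    # re-orthogonalize against rounding
    w, _, vt = np.linalg.svd(u)
    u = w @ vt
    return UBMatrix(u @ b)


def ub_from_three_reflections(q1, q2, q3, hkl1, hkl2, hkl3) -> UBMatrix:
    """UB = [q1 q2 q3] [hkl1 hkl2 hkl3]^-1 (no cell assumed; exact)."""
    qmat = np.column_stack([q1, q2, q3]).astype(float)
    hmat = np.column_stack([hkl1, hkl2, hkl3]).astype(float)
    if abs(np.linalg.det(hmat)) < 1e-12:
        raise ValueError("hkl triple is linearly dependent")
    return UBMatrix(qmat @ np.linalg.inv(hmat))


def ub_montecarlo(qs, cell: Cell, seed, n_trials: int = 20000,
                  index_tol: float = INDEX_TOL_DEFAULT,
                  min_fraction: float = 0.5) -> UBMatrix:
    """Orientation search with a known cell: uniformly random rotations.

    Each trial draws a random pair of observations and a random index
    assignment compatible with the known cell (matching |q| against the
    1/d ladder, then the inter-vector angle), builds the candidate
    orientation by the two-reflection triad construction and scores it by
    how many observations index within ``index_tol`` under U B.  The
    winning orientation is polished by an index-and-refine bootstrap:
    observations are indexed under a loose tolerance, the UB is
    least-squares refined on them, and the tolerance is shrunk stepwise
    to ``index_tol``.  Deterministic for a given seed.  Fails (reporting
    the best fraction) if the refined orientation still indexes fewer
    than ``min_fraction`` of the points.
    """
    if seed is None:
        raise ValueError("a seed is required")
    qs = np.atleast_2d(np.asarray(qs, float))
    if len(qs) < 2:
        raise IndexingError("need at least 2 observations")
    b = cell.b_matrix()
    rng = np.random.default_rng(seed)
    binv = np.linalg.inv(b)

    # candidate indices per observation: every hkl whose 1/d matches |q|
    from .simulate import hkl_sphere
    qnorm = np.linalg.norm(qs, axis=1)
    all_hkl = hkl_sphere(b, 2.0 / (qnorm.max() * 1.05))
    all_len = np.linalg.norm(all_hkl @ b.T, axis=1)
    length_tol = 0.02
    cand = [np.where(np.abs(all_len - qn) < length_tol * qn)[0]
            for qn in qnorm]
    usable = [i for i, c in enumerate(cand) if len(c)]
    if len(usable) < 2:
        raise IndexingError("no observation matches the cell's d-spacing "
                            "ladder; wrong cell?")
    # draw pairs preferentially from the shortest observed vectors: their
    # d-spacing shells hold few candidate indices, so a random assignment
    # is far more likely to be the true one
    usable.sort(key=lambda i: qnorm[i])
    pool = usable[:max(6, (len(usable) + 2) // 3)]

    def score(u):
        hr = qs @ (binv @ u.T).T
        res = np.linalg.norm(hr - np.rint(hr), axis=1)
        return (-int(np.sum(res < index_tol)),
                float(np.mean(np.minimum(res, 0.5))))

    best_key, best_u = None, None
    n_all = len(qs)
    for _ in range(n_trials):
        i, j = rng.choice(pool, size=2, replace=False)
        hi = all_hkl[rng.choice(cand[i])]
        hj = all_hkl[rng.choice(cand[j])]
        vi, vj = b @ hi, b @ hj
        cos_obs = qs[i] @ qs[j] / (qnorm[i] * qnorm[j])
        denom = np.linalg.norm(vi) * np.linalg.norm(vj)
        if abs(vi @ vj / denom - cos_obs) > 0.05 or \
           1 - abs(cos_obs) < 1e-4:
            continue   # incompatible or collinear assignment
        try:
            u_cand = ub_from_two_reflections(
                qs[i], qs[j], cell, hi, hj).matrix @ binv
        except ValueError:
            continue
        key = score(u_cand)
        if best_key is None or key < best_key:
            best_key, best_u = key, u_cand
        if best_key[0] == -n_all:
            break
    if best_u is None:
        raise IndexingError("no orientation trial was compatible with the "
                            "given cell")

    ub = UBMatrix(best_u @ b)
    # bootstrap: low-|q| points index first; each pass tightens the net
    order = np.argsort(np.linalg.norm(qs, axis=1))
    for tol, subset in ((4 * index_tol, order[:max(10, len(qs) // 3)]),
                        (3 * index_tol, order),
                        (2 * index_tol, order),
                        (index_tol, order), (index_tol, order)):
        sel = qs[subset]
        obs = [o for o in index_points(ub, sel, tol) if o.indexed]
        if len(obs) < 3:
            continue
        try:
            ub = refine_ub_lsq(ub, hkls=[o.hkl for o in obs],
                               qs=[o.q for o in obs])
        except IndexingError:
            continue
    n_final = sum(o.indexed for o in index_points(ub, qs, index_tol))
    if n_final / len(qs) < min_fraction:
        raise IndexingError(
            f"Monte-Carlo search failed: best orientation indexes only "
            f"{n_final}/{len(qs)} points ({n_final / len(qs):.0%})")
    return ub


# ---------------------------------------------------------------------------
# least-squares refinement
# ---------------------------------------------------------------------------


def refine_ub_lsq(ub0, hkls, qs) -> UBMatrix:
    """Linear least squares of the nine UB elements against (hkl -> q) pairs.

    Each observation contributes three equations ``q = UB hkl``; the three
    rows of UB decouple into independent fits sharing one design matrix.
    Cell standard uncertainties are propagated from the element covariance
    (block-diagonal across rows) through the UB -> cell map by forward
    differences.  Needs at least 3 observations spanning 3D; the refined
    mean residual can never exceed that of any feasible start, ``ub0``
    included (``ub0`` may be None; it is only a reference).
    """
    h = np.atleast_2d(np.asarray(hkls, float))
    q = np.atleast_2d(np.asarray(qs, float))
    if len(h) != len(q) or len(h) < 3:
        raise ValueError("need >= 3 (hkl, q) pairs")
    if np.linalg.matrix_rank(h, tol=1e-10) < 3:
        raise IndexingError("design matrix is rank-deficient "
                            "(indices do not span 3D)")
    n = len(h)
    gram = h.T @ h
    gram_inv = np.linalg.inv(gram)
    ub = (gram_inv @ h.T @ q).T          # rows of UB
    resid = q - h @ ub.T
    dof = max(n - 3, 1)
    row_var = (resid ** 2).sum(axis=0) / dof
    cov = np.zeros((9, 9))
    for r in range(3):
        cov[3 * r:3 * r + 3, 3 * r:3 * r + 3] = row_var[r] * gram_inv

    cell0 = np.array(cell_from_ub(ub).parameters)
    jac = np.zeros((6, 9))
    step = 1e-7 * max(1.0, float(np.abs(ub).max()))
    for p in range(9):
        d = np.zeros(9)
        d[p] = step
        cell_p = np.array(cell_from_ub(ub + d.reshape(3, 3)).parameters)
        jac[:, p] = (cell_p - cell0) / step
    cell_cov = jac @ cov @ jac.T
    su = tuple(float(s) for s in np.sqrt(np.clip(np.diag(cell_cov), 0, None)))
    return UBMatrix(ub, cell_su=su)


# ---------------------------------------------------------------------------
# Bravais-lattice search
# ---------------------------------------------------------------------------

_SYMMETRY_RANK = {"cubic": 6, "hexagonal": 5, "tetragonal": 4,
                  "orthorhombic": 3, "monoclinic": 2, "triclinic": 1}
_SYMBOL = {"cubic": "c", "hexagonal": "h", "tetragonal": "t",
           "orthorhombic": "o", "monoclinic": "m", "triclinic": "a"}


def _transform_catalog():
    """Integer transformation matrices with entries in {-1,0,1}, det 1..4.

    ``M`` maps primitive direct-basis vectors to conventional ones
    (a'_i = sum_j M_ij a_j); its determinant is the centering multiplicity.
    """
    vals = np.array(list(itertools.product((-1, 0, 1), repeat=9)))
    mats = vals.reshape(-1, 3, 3).astype(float)
    dets = np.linalg.det(mats)
    keep = (dets > 0.5) & (dets < 4.5) & \
           (np.abs(dets - np.rint(dets)) < 1e-9)
    return mats[keep].astype(int), np.rint(dets[keep]).astype(int)


_CATALOG = None


def _centering_symbol(m, det):
    """Centering letter from the primitive translations mod 1."""
    if det == 1:
        return "P"
    rows = np.linalg.inv(m)   # row j = conventional coords of primitive a_j
    pts = set()
    rng = range(-2, 3)
    for i, j, k in itertools.product(rng, rng, rng):
        t = i * rows[0] + j * rows[1] + k * rows[2]
        t = np.round(np.mod(np.round(t, 9), 1.0), 6)
        pts.add(tuple(t))
    pts.discard((0.0, 0.0, 0.0))
    half = {(0.5, 0.5, 0.5): "I", (0.5, 0.5, 0.0): "C",
            (0.0, 0.5, 0.5): "A", (0.5, 0.0, 0.5): "B"}
    if det == 4 and len(pts) == 3:
        return "F"
    if det == 2 and len(pts) == 1:
        return half.get(next(iter(pts)), "?")
    if det == 3 and len(pts) == 2:
        return "R"
    return "?"


def _classify(params, length_tol, angle_tol):
    """(system, badness) for a conventional cell candidate.

    badness = worst constraint violation in units of its tolerance;
    a candidate fits the system when badness <= 1.
    """
    a, b, c, al, be, ga = params
    mean_len = (a + b + c) / 3.0

    def leq(x, y):
        return abs(x - y) / mean_len / length_tol

    def aeq(x, y):
        return abs(x - y) / angle_tol

    checks = {
        "cubic": [leq(a, b), leq(b, c), aeq(al, 90), aeq(be, 90), aeq(ga, 90)],
        "tetragonal": [leq(a, b), aeq(al, 90), aeq(be, 90), aeq(ga, 90)],
        "hexagonal": [leq(a, b), aeq(al, 90), aeq(be, 90), aeq(ga, 120)],
        "orthorhombic": [aeq(al, 90), aeq(be, 90), aeq(ga, 90)],
        "monoclinic": [aeq(al, 90), aeq(ga, 90)],
        "triclinic": [0.0],
    }
    return {sys: max(v) for sys, v in checks.items()}


def bravais_search(ub, length_tol: float = 0.002, angle_tol: float = 0.2):
    """Find the highest-symmetry Bravais description of a primitive UB.

    Scans a catalog of small integer transformations from the primitive
    cell to candidate conventional cells (determinants 1-4, covering P, A,
    B, C, I, F and R centerings), classifies each candidate's metric
    against the lattice systems within ``length_tol`` (relative, on
    lengths) and ``angle_tol`` (degrees), and returns
    ``(UBMatrix, symbol)`` for the best fit — highest symmetry first, then
    smallest centering multiplicity, then smallest metric deviation.
    Triclinic P (the unchanged input) is always available.
    """
    global _CATALOG
    ubm = ub.matrix if isinstance(ub, UBMatrix) else np.asarray(ub, float)
    if _CATALOG is None:
        _CATALOG = _transform_catalog()
    mats, dets = _CATALOG

    invs = np.linalg.inv(mats)                       # (n,3,3)
    cand_ub = np.einsum("ij,njk->nik", ubm, invs)    # UB' = UB M^-1
    gstar = np.einsum("nji,njk->nik", cand_ub, cand_ub)
    g = np.linalg.inv(gstar)
    aa = np.sqrt(g[:, 0, 0])
    bb = np.sqrt(g[:, 1, 1])
    cc = np.sqrt(g[:, 2, 2])
    al = np.degrees(np.arccos(np.clip(g[:, 1, 2] / (bb * cc), -1, 1)))
    be = np.degrees(np.arccos(np.clip(g[:, 0, 2] / (aa * cc), -1, 1)))
    ga = np.degrees(np.arccos(np.clip(g[:, 0, 1] / (aa * bb), -1, 1)))

    best = None   # key = (neg rank, det, badness, perimeter, beta>=90, idx)
    for i in range(len(mats)):
        params = (aa[i], bb[i], cc[i], al[i], be[i], ga[i])
        badness = _classify(params, length_tol, angle_tol)
        for system, bad in badness.items():
            if system == "triclinic" or bad > 1.0:
                continue
            key = (-_SYMMETRY_RANK[system], dets[i], round(bad, 6),
                   round(aa[i] + bb[i] + cc[i], 6), be[i] < 90.0, i)
            if best is None or key < best[0]:
                best = (key, i, system)
    if best is None:
        # no metric specialization: triclinic P, input basis kept as is
        return UBMatrix(ubm, lattice="aP"), "aP"
    _, idx, system = best
    letter = _centering_symbol(mats[idx], dets[idx])
    new_ub = UBMatrix(cand_ub[idx], lattice=_SYMBOL[system] + letter)
    return new_ub, _SYMBOL[system] + letter


def canonical_lengths(cell: Cell):
    """Sorted (a, b, c) for permutation-insensitive cell comparison."""
    return tuple(sorted((cell.a, cell.b, cell.c)))


# ---------------------------------------------------------------------------
# prediction of observable spots
# ---------------------------------------------------------------------------


def predict_observations(ub, geom: DetectorGeometry, scan: ScanConfig):
    """Enumerate all reachable reflections with their (frame, X, Y).

    All hkl inside the Ewald limit are run through the rotation-method
    crossing solution and the geometry inversion; the table reports every
    crossing inside the scanned phi range, with ``on_face`` marking hits
    inside the active window and ``frame`` the acquisition frame index.
    """
    ubm = ub.matrix if isinstance(ub, UBMatrix) else np.asarray(ub, float)
    preds = predict_spots(ubm, geom, scan)
    return predictions_to_frame(preds, scan)
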