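"""Swim-bladder ellipse fitting and 3D ellipsoid reconstruction.

The swim bladder is modeled as an ellipsoid.  Each view observes one
silhouette, fitted as a 2D ellipse with quadratic form
``u^T Q^T A Q u = 1`` where ``A = diag(1/j^2, 1/k^2)`` and ``Q`` is the
in-plane rotation by ``phi``.  The ellipsoid has form
``v^T R^T B R v = 1`` with ``B = diag(1/a^2, 1/b^2, 1/c^2)`` and
``R = Rx(phi) Rz(psi) Ry(theta)`` (this matrix order is the product
actually used by the reconstruction; the conventional ``Rx Ry Rz`` order
is available behind a flag).

The silhouette of an ellipsoid along a coordinate axis is itself an
ellipse whose 2x2 form is the Schur complement of the dropped axis in the
3x3 form.  Reconstruction minimizes the element-wise L1 error between the
two predicted silhouette forms and the two fitted ellipse forms over the
six shape parameters (a, b, c, phi, psi, theta).  The objective is
non-smooth, so a derivative-free Nelder-Mead simplex with multi-start is
used; the multi-start spread doubles as an identifiability diagnostic,
since two orthogonal silhouettes need not pin down the ellipsoid uniquely
in degenerate configurations.

Because the fitted pixel sizes assume the nominal object distance, a
height-based magnification factor (cubed for volume) corrects the final
volume for the larva's actual height in the well.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import least_squares, minimize
from skimage import measure

from .errors import FitError, GeometryError
from .geometry import (
    ViewGeometry,
    WellGeometry,
    WorldPoint,
    fuse_point,
    thin_lens_magnification,
)

__all__ = [
    "Ellipse2D",
    "Ellipsoid3D",
    "BladderRecord",
    "EllipsoidFitResult",
    "fit_ellipse",
    "fit_ellipse_world",
    "ellipse_form",
    "ellipsoid_form",
    "rotation_matrix",
    "project_form",
    "fit_ellipsoid",
    "bladder_volume",
    "dice",
]


@dataclass(frozen=True)
class Ellipse2D:
    """Ellipse with semi-axes ``j >= k`` (mm) rotated by ``phi`` in [0, pi)."""

    center: tuple[float, float]
    j: float
    k: float
    phi: float

    def __post_init__(self) -> None:
        if not (self.j >= self.k > 0):
            raise FitError(f"semi-axes must satisfy j >= k > 0, got {self.j}, {self.k}")
        object.__setattr__(self, "phi", float(self.phi) % math.pi)

    @property
    def area(self) -> float:
        return math.pi * self.j * self.k

    def x_half_extent(self) -> float:
        """Half extent of the ellipse along the shared (first) axis."""
        M = ellipse_form(self)
        return float(np.sqrt(np.linalg.inv(M)[0, 0]))


@dataclass(frozen=True)
class Ellipsoid3D:
    """Ellipsoid with semi-axes a, b, c (mm) and rotation angles (radians)."""

    center: WorldPoint
    a: float
    b: float
    c: float
    phi: float = 0.0
    psi: float = 0.0
    theta: float = 0.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise FitError("semi-axes must be positive")

    @property
    def volume(self) -> float:
        """Geometric volume (4/3) pi a b c in mm^3, before any rescaling."""
        return 4.0 / 3.0 * math.pi * self.a * self.b * self.c


@dataclass(frozen=True)
class BladderRecord:
    """Per-frame reconstruction result written to the results CSV."""

    frame_index: int
    ellipse_top: Ellipse2D
    ellipse_side: Ellipse2D
    ellipsoid: Ellipsoid3D
    objective_value: float
    volume: float
    magnification_scale: float
    qc_pass: bool


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels = measure.label(mask > 0, connectivity=2)
    if labels.max() == 0:
        raise FitError("empty mask")
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == np.argmax(counts)


def fit_ellipse(mask: np.ndarray, pixel_size: float = 1.0) -> Ellipse2D:
    """Least-squares ellipse fit to the outer contour of a binary mask.

    The largest 8-connected foreground component is kept, its outer
    contour extracted by sub-pixel border following, and an ellipse fitted
    by direct least squares.  Center and semi-axes are scaled to mm by
    ``pixel_size``; the center is in (x=column, y=row) pixel-grid order.
    """
    mask = np.asarray(mask)
    if int(np.count_nonzero(mask)) < 5:
        raise FitError("mask has fewer than 5 foreground pixels")
    comp = _largest_component(mask)
    padded = np.pad(comp.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        raise FitError("no contour found")
    contour = max(contours, key=len) - 1.0  # undo padding offset
    # contour is (row, col); fit in (x=col, y=row)
    pts = contour[:, ::-1]
    model = measure.EllipseModel.from_estimate(pts)
    if not model:
        raise FitError("degenerate contour: ellipse fit failed")
    (xc, yc), (ax1, ax2), theta = model.center, model.axis_lengths, model.theta
    if not np.all(np.isfinite([xc, yc, ax1, ax2, theta])) or min(ax1, ax2) <= 0:
        raise FitError("degenerate ellipse parameters")
    if ax1 >= ax2:
        j, k, phi = ax1, ax2, theta
    else:
        j, k, phi = ax2, ax1, theta + math.pi / 2
    return Ellipse2D(
        center=(xc * pixel_size, yc * pixel_size),
        j=j * pixel_size,
        k=k * pixel_size,
        phi=phi,
    )


def fit_ellipse_world(
    mask: np.ndarray,
    view: str,
    geom: ViewGeometry,
    downsample: int = 1,
    object_distance: float | None = None,
) -> Ellipse2D:
    """Fit a mask ellipse and express it in the view's world frame (mm).

    The mask may be ``downsample`` times coarser than the sensor grid.
    Pixels are converted at the nominal (focal-plane) object distance
    unless ``object_distance`` is given; the per-larva height correction
    is applied later, to the volume, via :func:`bladder_volume`.  The
    image row axis points down while y/z point up, so the fitted
    orientation angle flips sign.
    """
    from .geometry import pixel_to_world

    e_px = fit_ellipse(mask, pixel_size=1.0)
    d = (
        object_distance
        if object_distance is not None
        else geom.object_distance(view, z=geom.focal_plane_z, y=geom.focal_plane_y)
    )
    # coarse pixel centre -> fine sensor coordinates
    u = e_px.center[0] * downsample + (downsample - 1) / 2.0
    v = e_px.center[1] * downsample + (downsample - 1) / 2.0
    center = pixel_to_world(view, (u, v), d, geom)
    m = thin_lens_magnification(geom.focal_length, d)
    px_mm = geom.pixel_pitch / m * downsample
    return Ellipse2D(
        center=center, j=e_px.j * px_mm, k=e_px.k * px_mm, phi=-e_px.phi
    )


def ellipse_form(e: Ellipse2D) -> np.ndarray:
    """2x2 SPD matrix ``Q^T A Q`` with eigenvalues 1/j^2 and 1/k^2."""
    c, s = math.cos(e.phi), math.sin(e.phi)
    Q = np.array([[c, -s], [s, c]])
    A = np.diag([1.0 / e.j**2, 1.0 / e.k**2])
    return Q.T @ A @ Q


def rotation_matrix(
    phi: float, psi: float, theta: float, order: str = "xzy"
) -> np.ndarray:
    """Rotation used in the ellipsoid form.

    ``order='xzy'`` (default) is the product Rx(phi) Rz(psi) Ry(theta)
    actually used by the reconstruction; ``order='xyz'`` gives the
    conventional Rx(phi) Ry(psi) Rz(theta).
    """
    cphi, sphi = math.cos(phi), math.sin(phi)
    cpsi, spsi = math.cos(psi), math.sin(psi)
    cth, sth = math.cos(theta), math.sin(theta)
    Rx = np.array([[1, 0, 0], [0, cphi, -sphi], [0, sphi, cphi]])
    Rz = np.array([[cpsi, -spsi, 0], [spsi, cpsi, 0], [0, 0, 1]])
    Ry = np.array([[cth, 0, sth], [0, 1, 0], [-sth, 0, cth]])
    if order == "xzy":
        return Rx @ Rz @ Ry
    if order == "xyz":
        Ry_psi = np.array([[cpsi, 0, spsi], [0, 1, 0], [-spsi, 0, cpsi]])
        Rz_th = np.array([[cth, -sth, 0], [sth, cth, 0], [0, 0, 1]])
        return Rx @ Ry_psi @ Rz_th
    raise ValueError(f"unknown rotation order {order!r}")


def ellipsoid_form(E: Ellipsoid3D, order: str = "xzy") -> np.ndarray:
    """3x3 SPD matrix ``R^T B R`` with eigenvalues 1/a^2, 1/b^2, 1/c^2."""
    R = rotation_matrix(E.phi, E.psi, E.theta, order=order)
    B = np.diag([1.0 / E.a**2, 1.0 / E.b**2, 1.0 / E.c**2])
    return R.T @ B @ R


_AXIS = {"x": 0, "y": 1, "z": 2}


def project_form(M: np.ndarray, drop_axis: str) -> np.ndarray:
    """Silhouette ellipse form of an ellipsoid viewed along ``drop_axis``.

    Eliminating coordinate k from ``v^T M v = 1`` by minimizing over it
    yields the Schur complement ``M_rr - M_rk M_kk^-1 M_kr`` over the
    remaining axes, which is the quadratic form of the shadow boundary.
    The top view drops z (image plane x-y); the side view drops y (x-z).
    """
    M = np.asarray(M, dtype=float)
    if M.shape != (3, 3) or not np.allclose(M, M.T, atol=1e-10):
        raise GeometryError("project_form expects a symmetric 3x3 matrix")
    if np.any(np.linalg.eigvalsh(M) <= 0):
        raise GeometryError("project_form expects a positive-definite matrix")
    k = _AXIS[drop_axis]
    r = [i for i in range(3) if i != k]
    Mrr = M[np.ix_(r, r)]
    Mrk = M[np.ix_(r, [k])]
    return Mrr - (Mrk @ Mrk.T) / M[k, k]


def _ellipse_from_form(M: np.ndarray, center: tuple[float, float]) -> Ellipse2D:
    vals, vecs = np.linalg.eigh(M)
    axes = 1.0 / np.sqrt(vals)  # ascending vals -> descending axes
    j, k = axes[0], axes[1]
    vec_j = vecs[:, 0]
    # the major-axis direction of form Q^T A Q is (cos phi, -sin phi)
    phi = math.atan2(-vec_j[1], vec_j[0])
    return Ellipse2D(center=center, j=float(max(j, k)), k=float(min(j, k)), phi=phi)


def _euler_xzy_from_rotation(R: np.ndarray) -> tuple[float, float, float]:
    """Invert R = Rx(phi) Rz(psi) Ry(theta); gimbal-safe fallback at |R01|=1."""
    psi = math.asin(np.clip(-R[0, 1], -1.0, 1.0))
    if abs(math.cos(psi)) > 1e-9:
        phi = math.atan2(R[2, 1], R[1, 1])
        theta = math.atan2(R[0, 2], R[0, 0])
    else:  # cos(psi)=0: phi and theta degenerate; fold into phi
        phi = math.atan2(-R[1, 2], R[2, 2])
        theta = 0.0
    return phi, psi, theta


def canonicalize(E: Ellipsoid3D) -> Ellipsoid3D:
    """Sort semi-axes a >= b >= c and re-derive rotation angles.

    The ellipsoid's symmetry group (axis permutations and sign flips of
    its principal directions) makes the raw parameter vector non-unique.
    The canonical form sorts the axes, fixes each principal direction's
    sign deterministically (sign flips leave the quadratic form
    unchanged), and re-extracts the Euler angles, making round trips
    comparable; ``ellipsoid_form`` of the result equals that of the input.
    """
    M = ellipsoid_form(E)
    vals, vecs = np.linalg.eigh(M)  # ascending eigenvalues -> a >= b >= c
    axes = 1.0 / np.sqrt(vals)
    R = vecs.T  # rows are principal directions: M = R^T diag(vals) R
    for i in range(2):  # sign convention: dominant component positive
        if R[i, np.argmax(np.abs(R[i]))] < 0:
            R[i] = -R[i]
    if np.linalg.det(R) < 0:
        R[2] = -R[2]
    phi, psi, theta = _euler_xzy_from_rotation(R)
    return Ellipsoid3D(
        center=E.center,
        a=float(axes[0]),
        b=float(axes[1]),
        c=float(axes[2]),
        phi=phi,
        psi=psi,
        theta=theta,
    )


@dataclass(frozen=True)
class EllipsoidFitResult:
    ellipsoid: Ellipsoid3D
    objective: float
    start_objectives: tuple[float, ...]
    start_volumes: tuple[float, ...]
    warnings: tuple[str, ...] = ()

    @property
    def multistart_volume_spread(self) -> float:
        """Relative spread of converged volumes among successful starts."""
        vols = [
            v
            for v, o in zip(self.start_volumes, self.start_objectives)
            if np.isfinite(o)
        ]
        if len(vols) < 2:
            return 0.0
        return (max(vols) - min(vols)) / min(vols)


def _schur_pair(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Top (drop z) and side (drop y) silhouette forms, inlined for speed."""
    top = M[:2, :2] - np.outer(M[:2, 2], M[:2, 2]) / M[2, 2]
    side = M[np.ix_([0, 2], [0, 2])] - np.outer(M[[0, 2], 1], M[[0, 2], 1]) / M[1, 1]
    return top, side


def _projection_error(params: np.ndarray, Mt: np.ndarray, Ms: np.ndarray) -> float:
    a, b, c, phi, psi, theta = params
    a, b, c = abs(a), abs(b), abs(c)
    if min(a, b, c) < 1e-6:
        return 1e12
    R = rotation_matrix(phi, psi, theta)
    B = np.diag([1.0 / a**2, 1.0 / b**2, 1.0 / c**2])
    top, side = _schur_pair(R.T @ B @ R)
    return float(np.abs(top - Mt).sum() + np.abs(side - Ms).sum())


def _chol_to_form(L6: np.ndarray) -> np.ndarray:
    """Lower-triangular 6-vector -> SPD matrix L L^T."""
    L = np.zeros((3, 3))
    L[0, 0], L[1, 0], L[1, 1], L[2, 0], L[2, 1], L[2, 2] = L6
    return L @ L.T


def _warm_start(Mt: np.ndarray, Ms: np.ndarray, L0: np.ndarray) -> np.ndarray | None:
    """Smooth pre-solve of the projection-matching problem.

    Parametrizes the candidate 3x3 form by its Cholesky factor (which
    keeps it positive definite) and solves the six silhouette-matching
    residuals by least squares; the result seeds the simplex polish of
    the non-smooth L1 objective.
    """

    def residuals(L6: np.ndarray) -> np.ndarray:
        M = _chol_to_form(L6)
        if M[2, 2] <= 0 or M[1, 1] <= 0:
            return np.full(6, 1e6)
        top, side = _schur_pair(M)
        return np.concatenate([(top - Mt).ravel()[[0, 1, 3]], (side - Ms).ravel()[[0, 1, 3]]])

    try:
        sol = least_squares(residuals, L0, method="lm", xtol=1e-15, ftol=1e-15, max_nfev=2000)
    except Exception:
        return None
    M = _chol_to_form(sol.x)
    if np.any(np.linalg.eigvalsh(M) <= 0):
        return None
    return M


def _params_from_form(M: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(M)
    axes = 1.0 / np.sqrt(vals)
    R = vecs.T
    if np.linalg.det(R) < 0:
        R[2] = -R[2]
    phi, psi, theta = _euler_xzy_from_rotation(R)
    return np.array([axes[0], axes[1], axes[2], phi, psi, theta])


def _canonical_form(Mt: np.ndarray, Ms: np.ndarray) -> np.ndarray | None:
    """Closed-form canonical ellipsoid consistent with both silhouettes.

    The inverse of a silhouette form is a principal submatrix of the
    ellipsoid's inverse form W = M^-1, so the two silhouettes determine
    every entry of W except W_yz — the coupling between the two axes
    never seen together in one view.  Among the one-parameter family the
    maximum-volume member has W_yz = W_xy W_xz / W_xx (the vertex of the
    concave parabola det W(W_yz)); it is always feasible, coincides with
    the truth whenever the bladder has no tilt in the unobserved plane,
    and is the least-eccentric extrapolation of the missing coupling.
    Returns None when the silhouettes are too inconsistent to combine.
    """
    try:
        Wt = np.linalg.inv(Mt)
        Ws = np.linalg.inv(Ms)
    except np.linalg.LinAlgError:
        return None
    wxx = 0.5 * (Wt[0, 0] + Ws[0, 0])  # shared-axis extent: average views
    W = np.array(
        [
            [wxx, Wt[0, 1], Ws[0, 1]],
            [Wt[0, 1], Wt[1, 1], 0.0],
            [Ws[0, 1], 0.0, Ws[1, 1]],
        ]
    )
    W[1, 2] = W[2, 1] = W[0, 1] * W[0, 2] / W[0, 0]
    if np.any(np.linalg.eigvalsh(W) <= 0):
        return None
    return np.linalg.inv(W)


def fit_ellipsoid(
    top: Ellipse2D,
    side: Ellipse2D,
    n_starts: int = 8,
    seed: int = 0,
    xatol: float = 1e-10,
    early_stop: float = 1e-10,
    extent_tolerance: float = 0.1,
    fuse_tolerance: float = 0.05,
) -> EllipsoidFitResult:
    """Reconstruct a 3D ellipsoid whose silhouettes match two ellipses.

    Minimizes the element-wise L1 difference between the Schur-complement
    projections of the candidate ellipsoid form and the two fitted ellipse
    forms over (a, b, c, phi, psi, theta) with Nelder-Mead multi-start;
    stops early once the objective falls below ``early_stop``.  The
    ellipsoid center fuses the two ellipse centers (top gives x, y; side
    gives x, z).

    Identifiability: two orthogonal silhouettes constrain the ellipsoid's
    inverse form except for its y-z coupling, so a one-parameter family of
    ellipsoids matches any consistent silhouette pair exactly (see
    :func:`_canonical_form`).  The deterministic first start is the
    closed-form canonical (maximum-volume) member, which the simplex
    polish then refines against the L1 objective; perturbed restarts and
    the reported per-start volumes act as identifiability diagnostics
    (``multistart_volume_spread``, and an ``identifiability`` warning when
    converged volumes disagree by more than 2%).

    Both ellipses observe the same shared-axis (x) extent of the bladder;
    a relative mismatch above ``extent_tolerance`` indicates inconsistent
    segmentations and is reported as a ``shared_extent_mismatch`` warning
    while the fit is still returned.
    """
    Mt, Ms = ellipse_form(top), ellipse_form(side)
    warnings: list[str] = []
    ext_top, ext_side = top.x_half_extent(), side.x_half_extent()
    if abs(ext_top - ext_side) > extent_tolerance * max(ext_top, ext_side):
        warnings.append(
            f"shared_extent_mismatch: top x-extent {2 * ext_top:.4g} mm vs "
            f"side {2 * ext_side:.4g} mm"
        )
    x0 = np.array([top.j, top.k, side.k, 0.0, 0.0, 0.0])
    M_canon = _canonical_form(Mt, Ms)
    # Cholesky seed for the smooth pre-solve used by the restarts
    M0 = M_canon
    if M0 is None:
        M0 = np.array(
            [
                [(Mt[0, 0] + Ms[0, 0]) / 2, Mt[0, 1], Ms[0, 1]],
                [Mt[0, 1], Mt[1, 1], 0.0],
                [Ms[0, 1], 0.0, Ms[1, 1]],
            ]
        )
    try:
        L0 = np.linalg.cholesky(M0)
    except np.linalg.LinAlgError:
        L0 = np.diag(1.0 / np.abs(x0[:3]))
    L0_6 = np.array([L0[0, 0], L0[1, 0], L0[1, 1], L0[2, 0], L0[2, 1], L0[2, 2]])
    rng = np.random.default_rng(seed)
    best = None
    objs: list[float] = []
    vols: list[float] = []
    for start in range(n_starts):
        if start == 0 and M_canon is not None:
            p0 = _params_from_form(M_canon)
        else:
            M_warm = _warm_start(
                Mt, Ms, L0_6 if start == 0 else L0_6 * rng.lognormal(0.0, 0.2, size=6)
            )
            if M_warm is not None:
                p0 = _params_from_form(M_warm)
            else:
                p0 = x0.copy()
                if start > 0:
                    p0[:3] *= rng.lognormal(0.0, 0.15, size=3)
                    p0[3:] = rng.uniform(-0.5, 0.5, size=3)
        res = minimize(
            _projection_error,
            p0,
            args=(Mt, Ms),
            method="Nelder-Mead",
            options={
                "xatol": xatol,
                "fatol": xatol,
                "maxiter": 4000,
                "maxfev": 6000,
            },
        )
        objs.append(float(res.fun))
        a, b, c = np.abs(res.x[:3])
        vols.append(4.0 / 3.0 * math.pi * a * b * c)
        if best is None or res.fun < best.fun:
            best = res
        if start == 0:
            first = res
        if best.fun < early_stop:
            break
    if best is None or not np.isfinite(best.fun):
        raise FitError(f"ellipsoid fit failed on all starts (best {best})")
    # near-ties resolve to the deterministic canonical start, so noise in
    # the silhouettes cannot swap in a different member of the solution
    # family between frames
    if np.isfinite(first.fun) and first.fun - best.fun <= 1e-3 * max(first.fun, 1e-9):
        best = first
    a, b, c = np.abs(best.x[:3])
    center, mismatch = fuse_point(top.center, side.center, fuse_tolerance)
    if mismatch:
        warnings.append("shared_axis_mismatch: ellipse centers disagree in x")
    raw = Ellipsoid3D(
        center=center,
        a=float(a),
        b=float(b),
        c=float(c),
        phi=float(best.x[3]),
        psi=float(best.x[4]),
        theta=float(best.x[5]),
    )
    result = EllipsoidFitResult(
        ellipsoid=canonicalize(raw),
        objective=float(best.fun),
        start_objectives=tuple(objs),
        start_volumes=tuple(vols),
        warnings=tuple(warnings),
    )
    if result.multistart_volume_spread > 0.02:
        result = replace(
            result,
            warnings=result.warnings
            + (
                f"identifiability: multi-start volumes spread by "
                f"{100 * result.multistart_volume_spread:.1f}%",
            ),
        )
    return result


def bladder_volume(
    E: Ellipsoid3D,
    fish_height_z: float,
    geom: ViewGeometry,
    well: WellGeometry,
) -> tuple[float, float]:
    """Final bladder volume (mm^3) with height-based magnification factor.

    Ellipse fits assume the nominal pixel size, i.e. the magnification of
    the top-view reference (focal-plane) height.  A larva at height z is
    imaged at object distance d(z), so true lengths are the measured ones
    times ``scale = m(d_ref) / m(d(z))`` and the volume scales by the cube.
    Returns ``(volume, scale)``.
    """
    if not 0.0 <= fish_height_z <= well.depth:
        raise GeometryError(
            f"fish height {fish_height_z} mm outside well depth [0, {well.depth}]"
        )
    m_ref = geom.magnification("top", z=geom.focal_plane_z)
    m_z = geom.magnification("top", z=fish_height_z)
    scale = m_ref / m_z
    return E.volume * scale**3, scale


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A| + |B|); two empty masks score 1.0."""
    a = np.asarray(mask_a) > 0
    b = np.asarray(mask_b) > 0
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)
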