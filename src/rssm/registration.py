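"""Rigid point-set registration and cohort alignment.

Registration follows the coherent point drift (CPD) formulation: the source
cloud is treated as the centroids of an isotropic Gaussian mixture fit to
the target by expectation-maximisation, with the rigid (rotation +
translation, no scaling) update obtained from an SVD of the weighted
cross-covariance.  Scaling is deliberately excluded everywhere in this
package so that overall bone size survives into the first principal
component of the shape model.

Cohort alignment is generalized Procrustes analysis (GPA): each corresponded
mesh is rigidly aligned to the running consensus mean until the mean
stabilises.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .mesh import TriangleMesh

__all__ = [
    "RigidTransform", "CorrespondedSet", "DegenerateInputError",
    "cpd_rigid", "select_template", "establish_correspondence",
    "generalized_procrustes", "closest_points_on_surface",
]


class DegenerateInputError(ValueError):
    """Raised when a point set is too degenerate to register."""


@dataclass
class RigidTransform:
    """A proper rigid motion ``x -> R x + t`` (rotation in SO(3), t in mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=np.float64).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=np.float64).reshape(3)
        if not np.allclose(self.rotation.T @ self.rotation, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthonormal to 1e-9")
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-9:
            raise ValueError("rotation determinant is not +1 to 1e-9")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_axis_angle(cls, axis: np.ndarray, angle_deg: float,
                        translation=(0.0, 0.0, 0.0)) -> "RigidTransform":
        axis = np.asarray(axis, float)
        axis = axis / np.linalg.norm(axis)
        a = np.deg2rad(angle_deg)
        K = np.array([[0, -axis[2], axis[1]],
                      [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        R = np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * (K @ K)
        return cls(R, np.asarray(translation, float))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation, in degrees."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.rad2deg(np.arccos(np.clip(c, -1.0, 1.0))))

    def to_matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix."""
        M = np.eye(4)
        M[:3, :3] = self.rotation
        M[:3, 3] = self.translation
        return M

    @classmethod
    def from_matrix(cls, M: np.ndarray) -> "RigidTransform":
        M = np.asarray(M, float)
        return cls(M[:3, :3], M[:3, 3])


@dataclass
class CorrespondedSet:
    """A cohort of meshes sharing one connectivity, with the template marked."""

    meshes: list
    template_index: int
    rms_to_template: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        faces0 = self.meshes[0].faces
        n0 = self.meshes[0].vertex_count
        for i, m in enumerate(self.meshes):
            if m.vertex_count != n0 or not np.array_equal(m.faces, faces0):
                raise ValueError(f"mesh {i} does not share the set's connectivity")
        if self.rms_to_template is None:
            self.rms_to_template = np.full(len(self.meshes), np.nan)
        self.rms_to_template = np.asarray(self.rms_to_template, float)

    def __len__(self) -> int:
        return len(self.meshes)


def _check_nondegenerate(points: np.ndarray, label: str) -> None:
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 3:
        raise DegenerateInputError(f"{label} must be an (N>=3, 3) point set")
    # collinearity: rank of centred cloud < 2
    c = pts - pts.mean(axis=0)
    s = np.linalg.svd(c, compute_uv=False)
    if s[1] <= 1e-12 * max(s[0], 1.0):
        raise DegenerateInputError(f"{label} points are collinear or coincident")


def _procrustes_rigid(source: np.ndarray, target: np.ndarray,
                      weights: np.ndarray | None = None) -> RigidTransform:
    """Closed-form weighted rigid fit of corresponded clouds (Kabsch)."""
    if weights is None:
        mu_s = source.mean(axis=0)
        mu_t = target.mean(axis=0)
        A = (target - mu_t).T @ (source - mu_s)
    else:
        w = weights / weights.sum()
        mu_s = w @ source
        mu_t = w @ target
        A = (target - mu_t).T @ ((source - mu_s) * w[:, None])
    U, _, Vt = np.linalg.svd(A)
    C = np.diag([1.0, 1.0, np.sign(np.linalg.det(U @ Vt))])
    R = U @ C @ Vt
    return RigidTransform(R, mu_t - R @ mu_s)


def cpd_rigid(source: np.ndarray, target: np.ndarray, max_iter: int = 100,
              tol: float = 1e-6, outlier_weight: float = 0.0):
    """Rigid coherent point drift of ``source`` onto ``target``.

    Parameters
    ----------
    source, target : (M, 3), (N, 3) arrays
        Point clouds in mm.  ``source`` plays the GMM-centroid role.
    max_iter : int
        EM iteration cap.  Non-convergence at the cap returns the current
        estimate with ``converged=False`` in the info dict (a warning, not
        an error).
    tol : float
        Relative change of the EM objective below which iteration stops.
    outlier_weight : float
        CPD's uniform-component weight ``w`` in [0, 1); 0 assumes no
        outliers.

    Notes
    -----
    For large products N*M the coarse annealing phase of the EM (sigma
    still larger than the point spacing) runs on a deterministic strided
    subsample of both clouds; the pose is then refined on the full clouds,
    so the converged transform is a full-resolution CPD fixed point.

    Returns
    -------
    (RigidTransform, info) where ``info`` has keys ``objective``,
    ``iterations``, ``converged``, ``sigma2``.
    """
    X = np.ascontiguousarray(target, dtype=np.float64)
    Y = np.ascontiguousarray(source, dtype=np.float64)
    _check_nondegenerate(Y, "source")
    _check_nondegenerate(X, "target")
    init = None
    if len(X) * len(Y) > 120_000:
        step = int(np.ceil(np.sqrt(len(X) * len(Y) / 120_000)))
        coarse, _ = _cpd_em(Y[::step], X[::step], max_iter, tol, outlier_weight)
        init = coarse
    return _cpd_em(Y, X, max_iter, tol, outlier_weight, init=init)


def _cpd_em(Y: np.ndarray, X: np.ndarray, max_iter: int, tol: float,
            outlier_weight: float, init: RigidTransform | None = None):
    """One EM run of rigid CPD (source Y onto target X)."""
    N, M, D = len(X), len(Y), 3
    if init is None:
        R = np.eye(3)
        t = np.zeros(3)
    else:
        R = init.rotation.copy()
        t = init.translation.copy()
    TY = Y @ R.T + t
    if init is None:
        sigma2 = _mean_sq_dist(X, TY) / D
    else:
        # warm start: spread set by the current nearest-point residuals
        tree0 = cKDTree(X)
        d0 = tree0.query(TY, k=1)[0]
        sigma2 = max(float((d0 ** 2).mean()), 1e-10)
    sigma2_floor = max(1e-12, 1e-10 * _mean_sq_dist(X, Y) / D)
    # once sigma drops below half the target's own point spacing the
    # responsibilities are local; a k-NN truncated E-step is then exact to
    # float precision and much cheaper than the dense N x M one
    knn_k = min(M, 48)
    use_knn_below = None
    if N * M > 120_000:
        tree_x = cKDTree(X)
        nn = tree_x.query(X, k=2)[0][:, 1]
        use_knn_below = (0.5 * float(np.median(nn))) ** 2
    prev_obj = np.inf
    converged = False
    it = 0
    scale = float(np.abs(X).max()) + float(np.abs(Y).max()) + 1.0
    prev_R, prev_t = R.copy(), t.copy()
    for it in range(1, max_iter + 1):
        if outlier_weight > 0.0:
            c = ((2 * np.pi * sigma2) ** (D / 2.0)
                 * outlier_weight / (1.0 - outlier_weight) * M / N)
        else:
            c = 1e-30  # guard against empty rows only
        if use_knn_below is not None and sigma2 < use_knn_below:
            # sparse E-step: k nearest mixture centroids per target point
            tree = cKDTree(TY)
            dist, idx = tree.query(X, k=knn_k)
            Pk = np.exp(-dist ** 2 / (2.0 * sigma2))
            Pk /= (Pk.sum(axis=1) + c)[:, None]
            Pt1 = Pk.sum(axis=1)
            P1 = np.zeros(M)
            np.add.at(P1, idx, Pk)
            Np = Pt1.sum()
            mu_x = (Pt1 @ X) / Np
            mu_y = (P1 @ Y) / Np
            Xc = X - mu_x
            Yc = Y - mu_y
            PY = np.einsum("nk,nkj->nj", Pk, Yc[idx])
            A = Xc.T @ PY
        else:
            # dense E-step in float32: the N*M-entry exp dominates the cost
            # and the responsibilities only need ~1e-7 relative accuracy;
            # all M-step reductions are float64.
            D2 = cdist(X, TY, "sqeuclidean").astype(np.float32)
            D2 *= np.float32(-1.0 / (2.0 * sigma2))
            P = np.exp(D2, out=D2)
            denom = P.sum(axis=1, dtype=np.float64)
            P /= (denom + c)[:, None].astype(np.float32)
            Pt1 = P.sum(axis=1, dtype=np.float64)   # per-target mass
            P1 = P.sum(axis=0, dtype=np.float64)    # per-source mass
            Np = Pt1.sum()
            mu_x = (Pt1 @ X) / Np
            mu_y = (P1 @ Y) / Np
            Xc = X - mu_x
            Yc = Y - mu_y
            A = Xc.T @ (P @ Yc.astype(np.float32)).astype(np.float64)
        U, s, Vt = np.linalg.svd(A)
        C = np.diag([1.0, 1.0, np.sign(np.linalg.det(U @ Vt))])
        R = U @ C @ Vt
        t = mu_x - R @ mu_y
        trAR = np.trace(A.T @ R)
        xPx = (Pt1 * (Xc ** 2).sum(axis=1)).sum()
        yPy = (P1 * (Yc ** 2).sum(axis=1)).sum()
        sigma2_new = (xPx - 2.0 * trAR + yPy) / (Np * D)
        sigma2 = max(sigma2_new, sigma2_floor)
        TY = Y @ R.T + t

        # negative log-likelihood proxy used for the stopping rule
        obj = (xPx - 2.0 * trAR + yPy) / (2.0 * sigma2) + Np * D / 2.0 * np.log(sigma2)
        step = max(np.abs(R - prev_R).max(), np.abs(t - prev_t).max() / scale)
        prev_R, prev_t = R.copy(), t.copy()
        if np.isfinite(prev_obj):
            denom_obj = abs(prev_obj) if prev_obj != 0 else 1.0
            # converged when the likelihood plateaus or the transform itself
            # has stopped moving (the latter kicks in for clean data, where
            # sigma^2 keeps shrinking long after the pose is fixed)
            if abs(prev_obj - obj) / denom_obj < tol or step < 1e-9:
                converged = True
                prev_obj = obj
                break
        prev_obj = obj
    if not converged:
        warnings.warn(f"cpd_rigid: not converged after {max_iter} iterations",
                      RuntimeWarning, stacklevel=2)
    transform = RigidTransform(R, t)
    info = {"objective": float(prev_obj), "iterations": it,
            "converged": converged, "sigma2": float(sigma2)}
    return transform, info


def _mean_sq_dist(X: np.ndarray, Y: np.ndarray) -> float:
    # E||x - y||^2 over the product, without forming the N x M x 3 tensor
    mx, my = X.mean(axis=0), Y.mean(axis=0)
    vx = ((X - mx) ** 2).sum() / len(X)
    vy = ((Y - my) ** 2).sum() / len(Y)
    return float(vx + vy + ((mx - my) ** 2).sum())


def _nearest_point_rms(a: np.ndarray, b: np.ndarray) -> float:
    """RMS of nearest-neighbour distances from cloud a to cloud b."""
    d = cdist(a, b).min(axis=1)
    return float(np.sqrt((d ** 2).mean()))


def select_template(meshes: list, max_iter: int = 150, tol: float = 1e-7):
    """Pick the template subject: the mesh with the lowest mean post-registration
    RMS nearest-point distance to every other mesh.

    Every ordered pair is rigidly registered with :func:`cpd_rigid` and the
    RMS nearest-point distance of the registered source to the target is
    tabulated.  Ties in the mean break to the lowest index.

    Returns
    -------
    (template_index, rms_table) with ``rms_table[i, j]`` the RMS (mm) of
    mesh ``i`` registered onto mesh ``j``; the diagonal is zero.
    """
    n = len(meshes)
    if n < 2:
        raise ValueError("select_template needs at least 2 meshes")
    rms = np.zeros((n, n))
    with warnings.catch_warnings():
        # the RMS ranking is stable long before the EM objective meets its
        # tolerance; a slow annealing tail is not worth a warning here
        warnings.simplefilter("ignore", RuntimeWarning)
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                T, _ = cpd_rigid(meshes[i].vertices, meshes[j].vertices,
                                 max_iter=max_iter, tol=tol)
                rms[i, j] = _nearest_point_rms(T.apply(meshes[i].vertices),
                                               meshes[j].vertices)
    mean_rms = rms.sum(axis=1) / (n - 1)
    template_index = int(np.argmin(mean_rms))  # argmin takes the first minimum
    return template_index, rms


def closest_points_on_surface(points: np.ndarray, mesh: TriangleMesh,
                              chunk: int = 256) -> np.ndarray:
    """Project each query point to its closest point on the mesh surface.

    Exhaustive vectorised point-to-triangle projection (no spatial index),
    adequate for the mesh sizes this package works at.
    """
    tri = mesh.vertices[mesh.faces]           # (F, 3, 3)
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab = b - a
    ac = c - a
    pts = np.asarray(points, float)
    out = np.empty_like(pts)
    for lo in range(0, len(pts), chunk):
        p = pts[lo:lo + chunk]                 # (Q, 3)
        # barycentric projection of each point onto each triangle's plane,
        # clamped to the triangle (Ericson, Real-Time Collision Detection)
        ap = p[:, None, :] - a[None, :, :]     # (Q, F, 3)
        d1 = np.einsum("fk,qfk->qf", ab, ap)
        d2 = np.einsum("fk,qfk->qf", ac, ap)
        bp = p[:, None, :] - b[None, :, :]
        d3 = np.einsum("fk,qfk->qf", ab, bp)
        d4 = np.einsum("fk,qfk->qf", ac, bp)
        cp = p[:, None, :] - c[None, :, :]
        d5 = np.einsum("fk,qfk->qf", ab, cp)
        d6 = np.einsum("fk,qfk->qf", ac, cp)

        va = d3 * d6 - d5 * d4
        vb = d5 * d2 - d1 * d6
        vc = d1 * d4 - d3 * d2
        denom_face = va + vb + vc
        with np.errstate(divide="ignore", invalid="ignore"):
            v = np.where(denom_face != 0, vb / denom_face, 0.0)
            w = np.where(denom_face != 0, vc / denom_face, 0.0)
            # edge AB
            v_ab = np.clip(np.where(d1 - d3 != 0, d1 / (d1 - d3 + (d1 - d3 == 0)), 0.0), 0, 1)
            # edge AC
            w_ac = np.clip(np.where(d2 - d6 != 0, d2 / (d2 - d6 + (d2 - d6 == 0)), 0.0), 0, 1)
            # edge BC
            num_bc = d4 - d3
            den_bc = (d4 - d3) + (d5 - d6)
            w_bc = np.clip(np.where(den_bc != 0, num_bc / (den_bc + (den_bc == 0)), 0.0), 0, 1)

        cand_int = a[None] + v[..., None] * ab[None] + w[..., None] * ac[None]
        cand_ab = a[None] + v_ab[..., None] * ab[None]
        cand_ac = a[None] + w_ac[..., None] * ac[None]
        cand_bc = b[None] + w_bc[..., None] * (c - b)[None]
        interior = (v >= 0) & (w >= 0) & (v + w <= 1)
        best = np.where(interior[..., None], cand_int, cand_ab)
        d_best = ((p[:, None, :] - best) ** 2).sum(axis=2)
        for cand in (cand_ac, cand_bc):
            d_c = ((p[:, None, :] - cand) ** 2).sum(axis=2)
            closer = d_c < d_best
            best = np.where(closer[..., None], cand, best)
            d_best = np.where(closer, d_c, d_best)
        f_idx = np.argmin(d_best, axis=1)
        out[lo:lo + chunk] = best[np.arange(len(p)), f_idx]
    return out


def establish_correspondence(template: TriangleMesh, target: TriangleMesh,
                             max_iter: int = 100, tol: float = 1e-6) -> TriangleMesh:
    """Dense correspondence: rigid CPD of the template onto the target,
    then projection of every transformed template vertex to the closest
    point on the target surface.

    The result carries the template's connectivity; its vertex ``i`` marks
    the target-surface location corresponding to template vertex ``i``, in
    the target's coordinate frame.
    """
    tri_areas = _face_areas(target)
    if not (tri_areas > 0).any():
        raise DegenerateInputError("target has no faces with positive area")
    T, _ = cpd_rigid(template.vertices, target.vertices, max_iter=max_iter, tol=tol)
    moved = T.apply(template.vertices)
    projected = closest_points_on_surface(moved, target)
    return TriangleMesh(projected, template.faces.copy(),
                        name=f"{target.name or 'target'}~corr")


def _face_areas(mesh: TriangleMesh) -> np.ndarray:
    tri = mesh.vertices[mesh.faces]
    return 0.5 * np.linalg.norm(np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1)


def generalized_procrustes(meshes: list, max_iter: int = 100, tol: float = 1e-8):
    """Rigid-only generalized Procrustes alignment of a corresponded cohort.

    Iteratively aligns every mesh to the running consensus mean (closed-form
    rigid Procrustes; no scaling) and recomputes the mean, until the mean
    moves by less than ``tol`` mm RMS.  The consensus is kept centred at the
    origin.  The sum of squared deviations from the mean is non-increasing.

    Returns ``(aligned_meshes, mean_shape)`` where ``mean_shape`` is a
    TriangleMesh with the shared connectivity.
    """
    if len(meshes) < 2:
        raise ValueError("generalized_procrustes needs at least 2 meshes")
    faces0 = meshes[0].faces
    V = [m.vertices.copy() for m in meshes]
    for i, m in enumerate(meshes):
        if m.vertex_count != len(V[0]) or not np.array_equal(m.faces, faces0):
            raise ValueError(f"mesh {i} is not corresponded with mesh 0")
    mean = V[0] - V[0].mean(axis=0)
    for _ in range(max_iter):
        for i in range(len(V)):
            T = _procrustes_rigid(V[i], mean)
            V[i] = T.apply(V[i])
        new_mean = np.mean(V, axis=0)
        new_mean = new_mean - new_mean.mean(axis=0)
        shift = float(np.sqrt(((new_mean - mean) ** 2).sum(axis=1).mean()))
        mean = new_mean
        if shift < tol:
            break
    aligned = [m.with_vertices(v) for m, v in zip(meshes, V)]
    return aligned, TriangleMesh(mean, faces0.copy(), name="consensus-mean")
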