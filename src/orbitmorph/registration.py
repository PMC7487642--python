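"""Rigid surface-based registration (ICP), T1 fixed / T2 moving.

The clinical workflow aligns the follow-up (T2) orbit model onto the
baseline (T1) model with a rigid "global registration" before any
comparison.  Here that is iterative closest point: area-uniform sample
points on the moving surface, exact closest points on the fixed surface,
and the least-squares rigid update from the SVD (Kabsch) solution.

Because the T2 surface carries genuine anatomical change (the deformed
wall regions), correspondences falling on deformed areas must not drag
the rigid fit.  Each iteration therefore rejects a configurable worst
fraction of correspondences *and* any correspondence whose distance
exceeds a multiple of the current median distance; early iterations
(when everything is far) keep all points, late iterations automatically
exclude the deformation sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from .errors import DegenerateGeometry
from .meshes import NearestSurface, make_mesh, surface_samples

__all__ = ["RigidTransform", "IcpConfig", "RegistrationReport", "icp_register", "apply_transform"]


@dataclass
class RigidTransform:
    """Proper rigid transform x -> R x + t (no scaling or shear)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        err = np.abs(self.rotation @ self.rotation.T - np.eye(3)).max()
        if err > 1e-6:
            raise ValueError(f"rotation is not orthonormal (deviation {err:.2e})")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation must be proper (det = +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_euler_deg(cls, angles_deg, translation) -> "RigidTransform":
        """Rz @ Ry @ Rx from per-axis angles in degrees."""
        ax, ay, az = np.radians(np.asarray(angles_deg, dtype=float))
        cx, sx = np.cos(ax), np.sin(ax)
        cy, sy = np.cos(ay), np.sin(ay)
        cz, sz = np.cos(az), np.sin(az)
        rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        return cls(rz @ ry @ rx, translation)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return self o other (apply ``other`` first)."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    @property
    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def to_json_dict(self) -> dict:
        return {"matrix_4x4_row_major": self.matrix.ravel().tolist()}

    @classmethod
    def from_json_dict(cls, d: dict) -> "RigidTransform":
        m = np.asarray(d["matrix_4x4_row_major"], dtype=float).reshape(4, 4)
        return cls(m[:3, :3], m[:3, 3])


@dataclass
class IcpConfig:
    n_samples: int = 6000
    coarse_samples: int = 2500  # subset used during point-to-point iterations
    max_iterations: int = 60
    tolerance_mm: float = 1e-5  # stop when RMS improves by less than this
    trim_fraction: float = 0.1  # always drop at least this worst fraction
    reject_rms_mult: float = 2.5  # annealed cutoff: mult * previous kept RMS
    reject_floor_mm: float = 0.20  # cutoff never shrinks below this
    min_keep_fraction: float = 0.35  # never reject more than this leaves
    # point-to-plane refinement: residuals along the fixed-surface normal
    # average out surface-extraction ripple, pinning the pose far more
    # precisely than point-to-point correspondences can
    refine_iterations: int = 10
    refine_floor_mm: float = 0.10
    # final stage: exclude coherent deviation patches (true anatomical
    # change) detected as neighbourhood-averaged signed residuals, so the
    # rigid pose does not "accommodate" one-sided deformation at all
    patch_exclude_mm: float = 0.025
    patch_neighbors: int = 40
    patch_iterations: int = 3
    seed: int = 0


@dataclass
class RegistrationReport:
    transform: RigidTransform
    rms_residual: float
    iterations: int
    converged: bool
    history: list = field(default_factory=list)  # kept RMS per iteration, all stages
    point_to_point_iterations: int = 0  # history[:this] is the classic ICP stage


def _kabsch(src: np.ndarray, dst: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform mapping src onto dst (SVD solution)."""
    mu_s = src.mean(axis=0)
    mu_d = dst.mean(axis=0)
    h = (src - mu_s).T @ (dst - mu_d)
    u, s, vt = np.linalg.svd(h)
    if s[1] < 1e-9 * max(s[0], 1e-30):
        raise DegenerateGeometry("correspondence set is rank-deficient (collinear points)")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = mu_d - r @ mu_s
    return RigidTransform(r, t)


def _point_to_plane_step(
    query: NearestSurface, pts: np.ndarray, current: RigidTransform, floor_mm: float
) -> tuple[RigidTransform, float, float]:
    """One linearised point-to-plane update (small-angle Gauss-Newton).

    Returns (new transform, kept RMS, max point motion of the update).
    """
    dist, closest, face, _ = query.query(pts)
    keep = dist <= max(floor_mm, 2.0 * float(np.median(dist)))
    if keep.sum() < 12:
        keep = dist <= np.partition(dist, 11)[11]
    p = pts[keep]
    q = closest[keep]
    n = query._face_normals[face[keep]]
    r = np.einsum("ij,ij->i", p - q, n)
    jac = np.hstack([np.cross(p, n), n])  # rows: [p x n, n]
    a = jac.T @ jac
    b = jac.T @ r
    try:
        x = np.linalg.solve(a, -b)
    except np.linalg.LinAlgError as exc:
        raise DegenerateGeometry("point-to-plane system is singular") from exc
    omega, t = x[:3], x[3:]
    angle = np.linalg.norm(omega)
    if angle > 1e-12:
        k = omega / angle
        kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
        rot = np.eye(3) + np.sin(angle) * kx + (1 - np.cos(angle)) * (kx @ kx)
    else:
        rot = np.eye(3)
    step = RigidTransform(rot, t)
    new = step.compose(current)
    moved = float(np.abs(step.apply(p) - p).max())
    rms = float(np.sqrt(np.mean(np.einsum("ij,ij->i", step.apply(p) - q, n) ** 2)))
    return new, rms, moved


def apply_transform(mesh: trimesh.Trimesh, t: RigidTransform) -> trimesh.Trimesh:
    """Map every vertex by R v + t; topology unchanged."""
    return make_mesh(t.apply(mesh.vertices.view(np.ndarray)), mesh.faces.copy())


def icp_register(
    moving: trimesh.Trimesh, fixed: trimesh.Trimesh, config: IcpConfig | None = None
) -> RegistrationReport:
    """Rigidly align ``moving`` onto ``fixed``; returns the moving->fixed transform.

    Initialisation is centroid alignment (T1/T2 scans share a scanner
    frame, so the misalignment is small).  Non-convergence is reported in
    the flag, not raised.
    """
    config = config or IcpConfig()
    for mesh, name in ((moving, "moving"), (fixed, "fixed")):
        if len(mesh.vertices) < 100:
            raise DegenerateGeometry(f"{name} mesh has fewer than 100 vertices")
    pts0 = surface_samples(moving, config.n_samples, seed=config.seed)
    ext = np.ptp(pts0, axis=0)
    if np.min(ext) < 1e-9 * np.max(ext):
        raise DegenerateGeometry("moving surface samples are coplanar")
    query = NearestSurface(fixed, k=8, signed=False)
    pts0_coarse = pts0[: min(config.coarse_samples, len(pts0))]

    # centroid initialisation
    t0 = fixed.vertices.view(np.ndarray).mean(axis=0) - moving.vertices.view(np.ndarray).mean(axis=0)
    current = RigidTransform(np.eye(3), t0)

    history: list[float] = []
    prev_rms = np.inf
    converged = False
    iterations = 0
    for iterations in range(1, config.max_iterations + 1):
        pts = current.apply(pts0_coarse)
        dist, closest, _, _ = query.query(pts)
        cutoff = np.quantile(dist, 1.0 - config.trim_fraction)
        if np.isfinite(prev_rms):
            # anneal: as the far-field residual shrinks, correspondences on
            # genuinely deformed regions fall outside the shrinking cutoff
            cutoff = min(cutoff, max(config.reject_rms_mult * prev_rms,
                                     config.reject_floor_mm))
        keep = dist <= cutoff
        min_keep = max(3, int(config.min_keep_fraction * len(dist)))
        if keep.sum() < min_keep:
            keep = dist <= np.partition(dist, min_keep - 1)[min_keep - 1]
        step = _kabsch(pts[keep], closest[keep])
        current = step.compose(current)
        rms = float(np.sqrt(np.mean((step.apply(pts[keep]) - closest[keep]) ** 2)))
        history.append(rms)
        if abs(prev_rms - rms) < config.tolerance_mm:
            converged = True
            break
        prev_rms = rms
    p2p_iterations = len(history)

    for _ in range(config.refine_iterations):
        current, rms, moved = _point_to_plane_step(
            query, current.apply(pts0), current, config.refine_floor_mm
        )
        history.append(rms)
        if moved < 1e-6:
            converged = True
            break

    if config.patch_iterations > 0:
        from scipy.spatial import cKDTree

        for _ in range(config.patch_iterations):
            pts = current.apply(pts0)
            dist, closest, face, _ = query.query(pts)
            n = query._face_normals[face]
            r = np.einsum("ij,ij->i", pts - closest, n)
            # neighbourhood mean of the signed residual: coherent anatomical
            # change survives the averaging, zero-mean extraction ripple does not
            _, nb = cKDTree(pts).query(pts, k=min(config.patch_neighbors, len(pts)))
            r_smooth = r[nb].mean(axis=1)
            keep = np.abs(r_smooth) <= config.patch_exclude_mm
            if keep.sum() < max(200, 0.05 * len(pts)):
                break  # nothing reliably undeformed: keep the previous pose
            current, rms, moved = _point_to_plane_step(
                query, pts[keep], current, config.refine_floor_mm
            )
            history.append(rms)
            if moved < 1e-7:
                break

    return RegistrationReport(
        transform=current,
        rms_residual=history[-1] if history else float("nan"),
        iterations=iterations,
        converged=converged,
        history=history,
        point_to_point_iterations=p2p_iterations,
    )
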