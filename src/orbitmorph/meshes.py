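"""Triangle-mesh utilities shared by registration, cropping and deviation.

Meshes are :class:`trimesh.Trimesh` objects with vertices in world mm.
The exact point-to-surface query (closest point on the nearest triangle,
signed with angle-weighted pseudo-normals) is implemented here because
it is the numerical core of both ICP correspondence search and the
deviation analysis, and must be exact point-to-triangle rather than
point-to-vertex.
"""

from __future__ import annotations

import numpy as np
import trimesh
from scipy.spatial import cKDTree

from .errors import DegenerateMesh, OpenMeshError

__all__ = [
    "make_mesh",
    "ensure_outward",
    "require_closed",
    "surface_samples",
    "NearestSurface",
]


def make_mesh(vertices: np.ndarray, faces: np.ndarray) -> trimesh.Trimesh:
    """Build a mesh without any automatic processing/reordering."""
    return trimesh.Trimesh(vertices=vertices, faces=faces, process=False)


def ensure_outward(mesh: trimesh.Trimesh) -> trimesh.Trimesh:
    """Flip winding if the signed (divergence-theorem) volume is negative."""
    if mesh.volume < 0:
        mesh = make_mesh(mesh.vertices.copy(), mesh.faces[:, ::-1].copy())
    return mesh


def require_closed(mesh: trimesh.Trimesh, what: str = "mesh") -> None:
    if len(mesh.faces) == 0:
        raise DegenerateMesh(f"{what} has no faces")
    if not mesh.is_watertight:
        raise OpenMeshError(f"{what} is not closed (watertight)")


def surface_samples(
    mesh: trimesh.Trimesh, n: int, seed: int | np.random.Generator | None = 0
) -> np.ndarray:
    """Draw ``n`` area-uniform points on the surface (seeded, reproducible)."""
    if isinstance(seed, np.random.Generator):
        seed = int(seed.integers(0, 2**31 - 1))
    pts, _ = trimesh.sample.sample_surface(mesh, n, seed=seed)
    return np.asarray(pts, dtype=float)


def _closest_point_triangles(p: np.ndarray, a, b, c):
    """Exact closest point on each triangle (a,b,c) for each point p.

    Vectorised Voronoi-region classification (Ericson, Real-Time
    Collision Detection).  Returns (closest_points, region) where region
    is 0 face, 1/2/3 vertex a/b/c, 4/5/6 edge ab/ac/bc.
    """
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    out = np.empty_like(p)
    region = np.zeros(len(p), dtype=np.int8)
    done = np.zeros(len(p), dtype=bool)

    m = (d1 <= 0) & (d2 <= 0)  # vertex a
    out[m] = a[m]
    region[m] = 1
    done |= m

    m = ~done & (d3 >= 0) & (d4 <= d3)  # vertex b
    out[m] = b[m]
    region[m] = 2
    done |= m

    m = ~done & (d6 >= 0) & (d5 <= d6)  # vertex c
    out[m] = c[m]
    region[m] = 3
    done |= m

    vc = d1 * d4 - d3 * d2
    m = ~done & (vc <= 0) & (d1 >= 0) & (d3 <= 0)  # edge ab
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(d1 - d3 != 0, d1 / np.where(d1 - d3 == 0, 1.0, d1 - d3), 0.0)
    out[m] = a[m] + t[m, None] * ab[m]
    region[m] = 4
    done |= m

    vb = d5 * d2 - d1 * d6
    m = ~done & (vb <= 0) & (d2 >= 0) & (d6 <= 0)  # edge ac
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(d2 - d6 != 0, d2 / np.where(d2 - d6 == 0, 1.0, d2 - d6), 0.0)
    out[m] = a[m] + t[m, None] * ac[m]
    region[m] = 5
    done |= m

    va = d3 * d6 - d5 * d4
    m = ~done & (va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0)  # edge bc
    denom = (d4 - d3) + (d5 - d6)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(denom != 0, (d4 - d3) / np.where(denom == 0, 1.0, denom), 0.0)
    out[m] = b[m] + t[m, None] * (c[m] - b[m])
    region[m] = 6
    done |= m

    m = ~done  # face interior
    denom = va + vb + vc
    denom = np.where(denom == 0, 1.0, denom)
    v = vb / denom
    w = vc / denom
    out[m] = a[m] + v[m, None] * ab[m] + w[m, None] * ac[m]
    return out, region


class NearestSurface:
    """Closest-point and signed-distance queries against a fixed mesh.

    Candidate triangles come from a KD-tree over triangle centroids
    (k nearest); the exact minimum over candidates is then computed with
    the vectorised point-triangle routine.  Signs use the angle-weighted
    pseudo-normal of the face/edge/vertex the closest point falls on,
    which is the standard robust signing for closed meshes.
    """

    def __init__(self, mesh: trimesh.Trimesh, k: int = 16, signed: bool = True):
        """``signed=False`` skips the pseudo-normal tables (cheaper build)
        for callers that only need unsigned distances."""
        if len(mesh.faces) == 0:
            raise DegenerateMesh("reference mesh has no faces")
        self.mesh = mesh
        self.signed = bool(signed)
        self.k = int(min(k, len(mesh.faces)))
        self._tri = mesh.triangles.view(np.ndarray)  # (F, 3, 3)
        # candidate lookup tree: one centroid per typical triangle, plus a
        # barycentric lattice of extra samples on oversized triangles (planar
        # cap fans), whose surface can be close while their centroid is not
        edge_max = np.linalg.norm(
            self._tri - np.roll(self._tri, 1, axis=1), axis=2
        ).max(axis=1)
        step = 2.0 * float(np.median(edge_max))
        pts = [self._tri.mean(axis=1)]
        owner = [np.arange(len(self._tri))]
        for fi in np.nonzero(edge_max > step)[0]:
            n = int(np.ceil(edge_max[fi] / step))
            ii, jj = np.meshgrid(np.arange(n + 1), np.arange(n + 1), indexing="ij")
            keep = ii + jj <= n
            u = ii[keep] / n
            v = jj[keep] / n
            a, b, c = self._tri[fi]
            pts.append(a + np.outer(u, b - a) + np.outer(v, c - a))
            owner.append(np.full(keep.sum(), fi))
        self._tree = cKDTree(np.concatenate(pts, axis=0))
        self._owner = np.concatenate(owner)
        self._face_normals = mesh.face_normals.view(np.ndarray)
        self._vertex_normals = None
        self._edge_normal = {}
        if self.signed:
            self._vertex_normals = mesh.vertex_normals.view(np.ndarray)
            # edge pseudo-normals: sum of the two adjacent face normals
            edges = mesh.face_adjacency_edges
            pairs = mesh.face_adjacency
            en = self._face_normals[pairs[:, 0]] + self._face_normals[pairs[:, 1]]
            for (v0, v1), n in zip(map(tuple, np.sort(edges, axis=1)), en):
                self._edge_normal[(int(v0), int(v1))] = n

    def query(self, points: np.ndarray):
        """Return (distance, closest_point, face_index, sign) per point.

        ``sign`` is +1 when the point lies on the outward side of the
        surface (outside a closed, outward-oriented mesh).
        """
        points = np.atleast_2d(np.asarray(points, dtype=float))
        npts = len(points)
        _, idx = self._tree.query(points, k=self.k)
        idx = self._owner[np.atleast_2d(idx)]
        k = idx.shape[1]
        flat = idx.ravel()
        tri = self._tri[flat]
        prep = np.repeat(points, k, axis=0)
        cp, region = _closest_point_triangles(prep, tri[:, 0], tri[:, 1], tri[:, 2])
        d2 = np.einsum("ij,ij->i", prep - cp, prep - cp).reshape(npts, k)
        best = np.argmin(d2, axis=1)
        rows = np.arange(npts)
        face = idx[rows, best]
        cp_best = cp.reshape(npts, k, 3)[rows, best]
        region_best = region.reshape(npts, k)[rows, best]
        dist = np.sqrt(d2[rows, best])

        if not self.signed:
            return dist, cp_best, face, np.ones(npts)
        normals = self._face_normals[face].copy()
        faces = self.mesh.faces.view(np.ndarray)
        vert_mask = (region_best >= 1) & (region_best <= 3)
        if vert_mask.any():
            vidx = faces[face[vert_mask], region_best[vert_mask] - 1]
            normals[vert_mask] = self._vertex_normals[vidx]
        edge_mask = region_best >= 4
        if edge_mask.any():
            local = {4: (0, 1), 5: (0, 2), 6: (1, 2)}
            for i in np.nonzero(edge_mask)[0]:
                i0, i1 = local[int(region_best[i])]
                key = tuple(sorted((int(faces[face[i], i0]), int(faces[face[i], i1]))))
                normals[i] = self._edge_normal.get(key, normals[i])
        side = np.einsum("ij,ij->i", points - cp_best, normals)
        sign = np.where(side >= 0, 1.0, -1.0)
        return dist, cp_best, face, sign

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        """Signed distance, positive outside the closed reference mesh."""
        dist, _, _, sign = self.query(points)
        return dist * sign
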