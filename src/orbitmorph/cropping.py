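"""Orbital boundary definition: landmark cut planes and watertight clipping.

Anterior boundary: plane through the frontozygomatic suture (FZS),
supraorbital foramen (SF) and anterior lacrimal crest (ALC).  Posterior
boundary: plane through the optic-canal landmarks OC1/OC2/OC3.  Meshes
are clipped to the slab between the planes with the intersection loops
re-capped by ear-clipping, so every intermediate model stays closed and
admits a divergence-theorem volume.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import trimesh
from trimesh.intersections import slice_mesh_plane

from .errors import (
    AmbiguousSide,
    DegenerateCrop,
    DegeneratePlane,
    EmptyClip,
    MissingLandmark,
    OpenMeshError,
)
from .meshes import ensure_outward, make_mesh, require_closed

__all__ = [
    "Landmark",
    "CutPlane",
    "make_plane",
    "clip_mesh",
    "crop_orbit",
    "read_landmarks",
    "write_landmarks",
]

LANDMARK_VOCABULARY = {"FZS", "SF", "ALC", "OC1", "OC2", "OC3"}
ANTERIOR_NAMES = ("FZS", "SF", "ALC")
POSTERIOR_NAMES = ("OC1", "OC2", "OC3")


@dataclass
class Landmark:
    name: str
    position: np.ndarray

    def __post_init__(self) -> None:
        if self.name not in LANDMARK_VOCABULARY:
            raise MissingLandmark(f"unknown landmark name {self.name!r}")
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.position)):
            raise ValueError("landmark coordinates must be finite")


@dataclass
class CutPlane:
    """Oriented plane; the kept side is the one containing ``interior``.

    ``normal`` is unit length and points *away* from the interior, so
    points with positive signed distance are removed by a clip.
    """

    point: np.ndarray
    normal: np.ndarray
    interior: np.ndarray

    def signed_distance(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return (pts - self.point) @ self.normal


def make_plane(p1, p2, p3, interior) -> CutPlane:
    """Plane through three points, oriented away from the interior reference."""
    p1, p2, p3, interior = (np.asarray(p, dtype=float).reshape(3) for p in (p1, p2, p3, interior))
    n = np.cross(p2 - p1, p3 - p1)
    area2 = np.linalg.norm(n)
    if area2 / 2.0 <= 1e-6:
        raise DegeneratePlane("the three points are (near-)collinear")
    n = n / area2
    s = float((interior - p1) @ n)
    if abs(s) < 1e-9:
        raise AmbiguousSide("interior reference point lies on the plane")
    if s > 0:
        n = -n
    return CutPlane(point=p1.copy(), normal=n, interior=interior.copy())


# ---------------------------------------------------------------------------
# cap triangulation

def _merge_cut_vertices(
    vertices: np.ndarray, faces: np.ndarray, decimals: int = 7
) -> trimesh.Trimesh:
    """Merge coincident vertices after slicing without pruning the mesh.

    Only faces that collapse (repeated vertex index) are dropped — such a
    face contributes a cancelling edge pair, so dropping it preserves
    edge pairing.  Automatic processing is avoided because its sliver
    removal can open holes elsewhere.
    """
    rounded = np.round(vertices, decimals)
    uniq, inverse = np.unique(rounded, axis=0, return_inverse=True)
    faces = inverse[faces]
    ok = (
        (faces[:, 0] != faces[:, 1])
        & (faces[:, 1] != faces[:, 2])
        & (faces[:, 0] != faces[:, 2])
    )
    return make_mesh(uniq, faces[ok])


def _boundary_loops(mesh: trimesh.Trimesh) -> list[np.ndarray]:
    """Directed boundary loops (vertex index cycles) of an open mesh.

    Walks the directed boundary edges consuming each exactly once, so
    pinched boundaries (a vertex shared by two loops) still decompose
    into closed cycles.  Raises if any chain cannot be closed.
    """
    edges = mesh.edges  # directed, per-face winding
    keys = np.sort(edges, axis=1)
    _, inv, counts = np.unique(keys, axis=0, return_inverse=True, return_counts=True)
    boundary = edges[counts[inv] == 1]
    out_edges: dict[int, list[int]] = {}
    for a, b in boundary:
        out_edges.setdefault(int(a), []).append(int(b))
    loops = []
    for start in sorted(out_edges):
        while out_edges.get(start):
            loop = [start]
            cur = out_edges[start].pop()
            while cur != start:
                loop.append(cur)
                nxts = out_edges.get(cur)
                if not nxts:
                    raise ValueError("open boundary chain cannot be closed")
                cur = nxts.pop()
            if len(loop) >= 3:
                loops.append(np.asarray(loop, dtype=np.int64))
    return loops


def _ear_clip(poly2d: np.ndarray) -> list[tuple[int, int, int]]:
    """Ear-clipping triangulation of a simple polygon (local indices)."""
    n = len(poly2d)
    idx = list(range(n))
    # polygon orientation
    x, y = poly2d[:, 0], poly2d[:, 1]
    orient = np.sign(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))
    if orient == 0:
        orient = 1.0
    tris: list[tuple[int, int, int]] = []
    guard = 0
    while len(idx) > 3 and guard < 4 * n * n:
        n_cur = len(idx)
        clipped = False
        for ii in range(n_cur):
            guard += 1
            i0, i1, i2 = idx[ii - 1], idx[ii], idx[(ii + 1) % n_cur]
            a, b, c = poly2d[i0], poly2d[i1], poly2d[i2]
            cross = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
            if cross * orient < -1e-12:
                continue  # reflex vertex
            # no other polygon vertex strictly inside the candidate ear
            others = [j for j in idx if j not in (i0, i1, i2)]
            if others and abs(cross) > 1e-12:
                pts = poly2d[others]
                d0 = (b[0] - a[0]) * (pts[:, 1] - a[1]) - (b[1] - a[1]) * (pts[:, 0] - a[0])
                d1 = (c[0] - b[0]) * (pts[:, 1] - b[1]) - (c[1] - b[1]) * (pts[:, 0] - b[0])
                d2 = (a[0] - c[0]) * (pts[:, 1] - c[1]) - (a[1] - c[1]) * (pts[:, 0] - c[0])
                inside = (d0 * orient > 1e-12) & (d1 * orient > 1e-12) & (d2 * orient > 1e-12)
                if inside.any():
                    continue
            tris.append((i0, i1, i2))
            del idx[ii]
            clipped = True
            break
        if not clipped:
            raise ValueError("ear clipping stalled")
    tris.append((idx[0], idx[1], idx[2]))
    return tris


def _cap_loops(
    mesh: trimesh.Trimesh, inward: np.ndarray, style: str = "ear"
) -> trimesh.Trimesh:
    """Triangulate the boundary loops of a sliced mesh into planar caps.

    ``inward`` is the normal direction pointing into the kept half-space;
    cap faces are wound so their outward normal is ``-inward``.
    ``style`` "ear" uses ear clipping (no added vertices), "fan" a
    centroid fan (one added vertex per loop, robust for any simple loop).
    """
    loops = _boundary_loops(mesh)
    if not loops:
        return mesh
    # in-plane basis
    u = np.cross(inward, [1.0, 0.0, 0.0])
    if np.linalg.norm(u) < 1e-6:
        u = np.cross(inward, [0.0, 1.0, 0.0])
    u /= np.linalg.norm(u)
    v = np.cross(inward, u)
    verts = mesh.vertices.view(np.ndarray)
    new_faces = []
    extra_vertices = []
    n_orig = len(verts)
    for loop in loops:
        # hole filling traverses the boundary opposite to the face winding
        loop = loop[::-1]
        pts = verts[loop]
        if style == "ear":
            poly2d = np.column_stack([pts @ u, pts @ v])
            tris = _ear_clip(poly2d)
            new_faces.extend([(loop[a], loop[b], loop[c]) for a, b, c in tris])
        else:
            ci = n_orig + len(extra_vertices)
            extra_vertices.append(pts.mean(axis=0))
            m = len(loop)
            new_faces.extend([(loop[i], loop[(i + 1) % m], ci) for i in range(m)])
    all_verts = verts if not extra_vertices else np.vstack([verts, np.asarray(extra_vertices)])
    faces = np.vstack([mesh.faces.view(np.ndarray), np.asarray(new_faces, dtype=np.int64)])
    return make_mesh(all_verts, faces)


def clip_mesh(mesh: trimesh.Trimesh, plane: CutPlane) -> trimesh.Trimesh:
    """Closed kept-side portion of ``mesh`` with a planar cap."""
    require_closed(mesh, "clip input")
    d = plane.signed_distance(mesh.vertices.view(np.ndarray))
    if d.max() <= 0:
        return make_mesh(mesh.vertices.copy(), mesh.faces.copy())  # fully kept
    if d.min() >= 0:
        raise EmptyClip("kept side excludes the mesh entirely")
    inward = -plane.normal  # points into the kept half-space
    sliced = slice_mesh_plane(mesh, plane_normal=inward, plane_origin=plane.point, cap=False)
    if sliced is None or len(sliced.faces) == 0:
        raise EmptyClip("plane clip removed the entire mesh")
    sliced = _merge_cut_vertices(
        sliced.vertices.view(np.ndarray), sliced.faces.view(np.ndarray)
    )
    capped = None
    for style in ("ear", "fan"):
        try:
            candidate = ensure_outward(_cap_loops(sliced, inward, style=style))
        except ValueError:
            continue
        if candidate.is_watertight:
            capped = candidate
            break
    if capped is None:
        raise OpenMeshError("capping failed to produce a watertight result")
    return capped


def crop_orbit(
    mesh: trimesh.Trimesh, landmarks: dict[str, np.ndarray] | list[Landmark], interior
) -> trimesh.Trimesh:
    """Clip to the slab between the anterior and posterior landmark planes."""
    if isinstance(landmarks, list):
        landmarks = {lm.name: lm.position for lm in landmarks}
    missing = (set(ANTERIOR_NAMES) | set(POSTERIOR_NAMES)) - set(landmarks)
    if missing:
        raise MissingLandmark(f"missing landmarks: {sorted(missing)}")
    interior = np.asarray(interior, dtype=float).reshape(3)
    anterior = make_plane(*(landmarks[n] for n in ANTERIOR_NAMES), interior)
    posterior = make_plane(*(landmarks[n] for n in POSTERIOR_NAMES), interior)
    try:
        out = clip_mesh(mesh, anterior)
        out = clip_mesh(out, posterior)
    except EmptyClip as exc:
        raise DegenerateCrop(f"landmark planes leave no slab: {exc}") from exc
    return out


# ---------------------------------------------------------------------------

def read_landmarks(path: str | Path) -> dict[str, np.ndarray]:
    records = json.loads(Path(path).read_text())
    return {r["name"]: np.array([r["x"], r["y"], r["z"]], dtype=float) for r in records}


def write_landmarks(landmarks: dict[str, np.ndarray], path: str | Path) -> None:
    records = [
        {"name": n, "x": float(p[0]), "y": float(p[1]), "z": float(p[2])}
        for n, p in landmarks.items()
    ]
    Path(path).write_text(json.dumps(records, indent=2))
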