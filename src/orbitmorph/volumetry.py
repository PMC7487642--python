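"""Closed-mesh volumetry (the primary outcome) and the palatal width measure.

Volumes use the divergence theorem on the triangle mesh,
``V = |sum_f v1 . (v2 x v3)| / 6``, reported in cm^3 (mm^3 / 1000) to
two decimals in all tabular output.  The maxillary palatal width is the
Euclidean distance between the left and right hard-palate / lingual
alveolar junction points picked on one coronal section.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh

from .errors import DegenerateMesh, OpenMeshError, SectionMismatch

__all__ = ["VolumeRecord", "ExpansionRecord", "mesh_volume", "palatal_width"]

MM3_PER_CM3 = 1000.0


@dataclass
class VolumeRecord:
    subject_id: str
    side: str  # left | right
    group: str  # TB | BB
    timepoint: str  # T1 | T2
    volume: float  # cm^3

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ValueError("volume must be positive")


@dataclass
class ExpansionRecord:
    subject_id: str
    group: str
    palatal_width_t1: float  # mm
    palatal_width_t2: float  # mm

    @property
    def expansion(self) -> float:
        return self.palatal_width_t2 - self.palatal_width_t1


def mesh_volume(mesh: trimesh.Trimesh) -> float:
    """Enclosed volume of a closed, consistently oriented mesh, in cm^3."""
    if len(mesh.faces) == 0 or mesh.area < 1e-12:
        raise DegenerateMesh("mesh has (near-)zero surface area")
    if not mesh.is_watertight:
        raise OpenMeshError("volume of an open mesh is undefined")
    tri = mesh.triangles.view(np.ndarray)
    v = np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])).sum() / 6.0
    return float(abs(v)) / MM3_PER_CM3


def palatal_width(p_left, p_right, anteroposterior_axis: int = 1, tol_mm: float = 0.5) -> float:
    """Distance (mm) between the palatal junction points of one coronal cut."""
    p_left = np.asarray(p_left, dtype=float).reshape(3)
    p_right = np.asarray(p_right, dtype=float).reshape(3)
    if abs(p_left[anteroposterior_axis] - p_right[anteroposterior_axis]) > tol_mm:
        raise SectionMismatch("junction points lie on different coronal sections")
    return float(np.linalg.norm(p_right - p_left))
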