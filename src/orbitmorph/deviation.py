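"""Surface deviation analysis between registered T1/T2 orbital models.

Signed point-to-surface distances are sampled area-uniformly on the
follow-up (T2, "test") model against the baseline (T1, "reference")
model, classified at the two clinical tolerances (0.20 mm and 0.40 mm),
and summarised as the matching percentage — the share of samples whose
absolute deviation stays within tolerance.  Positive distances lie on
the outward side of the reference surface (local expansion), negative
inside (local reduction): the red/blue convention of the colour maps.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

from .errors import EmptyDeviation, OpenMeshError
from .meshes import NearestSurface, surface_samples

__all__ = [
    "TOLERANCE_A",
    "TOLERANCE_B",
    "DeviationResult",
    "signed_surface_distance",
    "matching_percentage",
    "classify_colormap",
    "export_distances_csv",
    "export_colored_ply",
]

TOLERANCE_A = 0.20  # mm
TOLERANCE_B = 0.40  # mm


@dataclass
class DeviationResult:
    sample_points: np.ndarray  # (n, 3) points on the test (T2) surface
    signed_distance: np.ndarray  # (n,) mm, positive outside the reference
    tolerance_a: float = TOLERANCE_A
    tolerance_b: float = TOLERANCE_B
    matching_percent: dict[float, float] = field(default_factory=dict)
    class_labels: dict[float, np.ndarray] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.signed_distance)


def signed_surface_distance(
    test: trimesh.Trimesh,
    reference: trimesh.Trimesh,
    n_samples: int = 50_000,
    seed: int = 0,
) -> DeviationResult:
    """Sample the test surface and measure signed distance to the reference.

    Distances are exact point-to-triangle; the sign comes from the
    pseudo-normal side test against the closed reference surface.
    """
    if n_samples < 1000:
        raise ValueError("n_samples must be >= 1000 for a stable percentage")
    if not reference.is_watertight:
        raise OpenMeshError("reference must be closed for the sign to be defined")
    if not test.is_watertight:
        raise OpenMeshError("test mesh must be closed")
    pts = surface_samples(test, n_samples, seed=seed)
    d = NearestSurface(reference).signed_distance(pts)
    res = DeviationResult(sample_points=pts, signed_distance=d)
    for tol in (res.tolerance_a, res.tolerance_b):
        res.matching_percent[tol] = matching_percentage(res, tol)
        res.class_labels[tol] = classify_colormap(res, tol)
    return res


def matching_percentage(d: DeviationResult, tol: float) -> float:
    """100 x fraction of samples with |distance| <= tol (boundary inclusive)."""
    if tol <= 0:
        raise ValueError("tolerance must be > 0")
    if d.n == 0:
        raise EmptyDeviation("no distance samples")
    return float(100.0 * np.count_nonzero(np.abs(d.signed_distance) <= tol) / d.n)


def classify_colormap(d: DeviationResult, tol: float) -> np.ndarray:
    """Per-sample labels: 'positive' (red), 'within' (green), 'negative' (blue)."""
    labels = np.full(d.n, "within", dtype="<U8")
    labels[d.signed_distance > tol] = "positive"
    labels[d.signed_distance < -tol] = "negative"
    return labels


def export_distances_csv(d: DeviationResult, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["x", "y", "z", "signed_distance_mm"])
        for p, dist in zip(d.sample_points, d.signed_distance):
            writer.writerow([f"{p[0]:.4f}", f"{p[1]:.4f}", f"{p[2]:.4f}", f"{dist:.5f}"])


def export_colored_ply(d: DeviationResult, tol: float, path: str | Path) -> None:
    """Sample cloud as PLY with the red/green/blue tolerance classes."""
    labels = classify_colormap(d, tol)
    colors = {"positive": (255, 60, 40), "within": (60, 200, 80), "negative": (50, 90, 255)}
    cloud = trimesh.PointCloud(
        d.sample_points, colors=np.array([colors[l] for l in labels], dtype=np.uint8)
    )
    cloud.export(str(path))
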