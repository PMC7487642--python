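"""Rigid transforms and ICP surface registration."""

import numpy as np
import pytest
import trimesh

from orbitmorph.errors import DegenerateGeometry
from orbitmorph.meshes import make_mesh
from orbitmorph.registration import (
    IcpConfig,
    RigidTransform,
    apply_transform,
    icp_register,
)
from orbitmorph.volumetry import mesh_volume


def lumpy_mesh() -> trimesh.Trimesh:
    """Asymmetric closed test surface: a sphere with fixed bumps.

    A plain sphere or box has continuous or discrete symmetries that make
    a recovered pose ambiguous; the bumps remove all of them.
    """
    m = trimesh.creation.icosphere(subdivisions=4, radius=12.0)
    v = m.vertices.view(np.ndarray).copy()
    centers = np.array([[12, 0, 0], [0, 12, 0], [0, 0, 12], [-8, -8, 2], [5, -7, -8.0]])
    amps = [1.5, -1.2, 0.9, 1.1, -0.8]
    r = np.linalg.norm(v, axis=1)
    for c, a in zip(centers, amps):
        d2 = ((v - c) ** 2).sum(axis=1)
        v += (v / r[:, None]) * (a * np.exp(-d2 / (2 * 3.0**2)))[:, None]
    return make_mesh(v, m.faces.copy())


class TestRigidTransform:
    def test_orthonormality_enforced(self):
        with pytest.raises(ValueError):
            RigidTransform(np.eye(3) * 1.5, np.zeros(3))

    def test_improper_rotation_rejected(self):
        with pytest.raises(ValueError):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))

    def test_compose_inverse_identity(self, rng):
        t = RigidTransform.from_euler_deg(rng.uniform(-30, 30, 3), rng.uniform(-5, 5, 3))
        ident = t.compose(t.inverse())
        assert np.allclose(ident.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(ident.translation, 0.0, atol=1e-12)

    def test_json_roundtrip(self):
        t = RigidTransform.from_euler_deg((5.0, -3.0, 8.0), (1.0, 2.0, 3.0))
        back = RigidTransform.from_json_dict(t.to_json_dict())
        assert np.allclose(back.matrix, t.matrix)


class TestApplyTransform:
    def test_identity(self, icosphere):
        out = apply_transform(icosphere, RigidTransform.identity())
        assert np.allclose(out.vertices, icosphere.vertices)

    def test_pure_translation_moves_centroid(self, icosphere):
        t = RigidTransform(np.eye(3), [1.0, 0.0, 0.0])
        out = apply_transform(icosphere, t)
        shift = out.vertices.mean(axis=0) - icosphere.vertices.view(np.ndarray).mean(axis=0)
        assert np.allclose(shift, [1.0, 0.0, 0.0], atol=1e-12)

    def test_volume_preserved_random_rigid(self, rng):
        mesh = lumpy_mesh()
        t = RigidTransform.from_euler_deg(rng.uniform(-90, 90, 3), rng.uniform(-20, 20, 3))
        assert mesh_volume(apply_transform(mesh, t)) == pytest.approx(
            mesh_volume(mesh), rel=1e-9
        )


class TestIcp:
    def test_self_registration_is_identity(self):
        mesh = lumpy_mesh()
        report = icp_register(mesh, mesh, IcpConfig(n_samples=2000))
        assert report.rms_residual < 1e-6
        assert np.allclose(report.transform.rotation, np.eye(3), atol=1e-6)
        assert np.allclose(report.transform.translation, 0.0, atol=1e-5)

    def test_known_transform_recovery(self):
        """5 deg about z + (1, 2, 3) mm recovered to < 0.05 mm vertex error."""
        fixed = lumpy_mesh()
        applied = RigidTransform.from_euler_deg((0.0, 0.0, 5.0), (1.0, 2.0, 3.0))
        moving = apply_transform(fixed, applied)
        report = icp_register(moving, fixed, IcpConfig())
        assert report.converged
        v = moving.vertices.view(np.ndarray)
        err = np.linalg.norm(report.transform.apply(v) - fixed.vertices, axis=1)
        assert err.max() < 0.05

    def test_partial_overlap_recovery(self):
        """Anterior 60% crop under the same motion recovers within 0.2 mm RMS."""
        from orbitmorph.cropping import clip_mesh, make_plane

        fixed = lumpy_mesh()
        zmin, zmax = fixed.vertices[:, 2].min(), fixed.vertices[:, 2].max()
        zcut = zmin + 0.4 * (zmax - zmin)  # keep upper 60%
        plane = make_plane([0, 0, zcut], [1, 0, zcut], [0, 1, zcut], [0, 0, zmax])
        part = clip_mesh(fixed, plane)
        applied = RigidTransform.from_euler_deg((0.0, 0.0, 5.0), (1.0, 2.0, 3.0))
        moving = apply_transform(part, applied)
        report = icp_register(moving, fixed, IcpConfig())
        v = moving.vertices.view(np.ndarray)
        err = np.linalg.norm(report.transform.apply(v) - part.vertices, axis=1)
        assert np.sqrt((err**2).mean()) < 0.2

    def test_perturbation_recovery_within_spec(self):
        """Any initial offset <= 10 deg / 5 mm comes back within 0.1 mm RMS."""
        fixed = lumpy_mesh()
        applied = RigidTransform.from_euler_deg((6.0, -8.0, 9.0), (4.0, -3.0, 2.0))
        moving = apply_transform(fixed, applied)
        report = icp_register(moving, fixed, IcpConfig())
        v = moving.vertices.view(np.ndarray)
        err = np.linalg.norm(report.transform.apply(v) - fixed.vertices, axis=1)
        assert np.sqrt((err**2).mean()) < 0.1

    def test_residual_history_non_increasing(self):
        """The classic point-to-point stage must not let the residual grow
        (later refinement stages change the residual metric)."""
        fixed = lumpy_mesh()
        applied = RigidTransform.from_euler_deg((3.0, 2.0, -4.0), (1.0, -1.0, 2.0))
        moving = apply_transform(fixed, applied)
        report = icp_register(moving, fixed, IcpConfig())
        h = np.asarray(report.history[: report.point_to_point_iterations])
        assert len(h) >= 2
        assert np.all(np.diff(h) <= 1e-6)

    def test_coplanar_rejected(self):
        grid = trimesh.creation.box(extents=(10.0, 10.0, 1e-9))
        with pytest.raises(DegenerateGeometry):
            icp_register(grid, grid, IcpConfig())

    def test_too_few_vertices_rejected(self):
        tetra = trimesh.creation.box()
        with pytest.raises(DegenerateGeometry):
            icp_register(tetra, tetra, IcpConfig())
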