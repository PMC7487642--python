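"""Phantom generator: determinism, ground truth, calibration."""

import dataclasses

import numpy as np
import pytest

from orbitmorph.errors import DegeneratePhantom, GridTooSmall
from orbitmorph.synthetic import (
    LANDMARK_NAMES,
    PhantomParams,
    calibrate_bumps,
    generate_phantom_pair,
    oracle_cropped_volume,
    save_phantom_pair,
)
from tests.conftest import small_params


class TestIdentityCase:
    def test_no_deformation_no_offset_no_noise_is_voxel_identical(self, quiet_pair):
        _, (vol1, vol2, truth) = quiet_pair
        assert np.array_equal(vol1.voxels, vol2.voxels)
        assert truth.true_increment == 0.0
        assert truth.true_match_fraction[0.20] == 1.0
        assert truth.true_match_fraction[0.40] == 1.0


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        params = small_params(bump_amplitudes=(0.5, 0.4), seed=11)
        a = generate_phantom_pair(params)
        b = generate_phantom_pair(params)
        assert np.array_equal(a[0].voxels, b[0].voxels)
        assert np.array_equal(a[1].voxels, b[1].voxels)
        assert a[2].true_increment == b[2].true_increment

    def test_different_seeds_differ(self):
        a = generate_phantom_pair(small_params(seed=1))
        b = generate_phantom_pair(small_params(seed=2))
        assert not np.array_equal(a[0].voxels, b[0].voxels)


class TestTruth:
    def test_landmark_names_exact(self, small_pair):
        _, (_, _, truth) = small_pair
        assert set(truth.landmarks_t1) == set(LANDMARK_NAMES)
        assert set(truth.landmarks_t2) == set(LANDMARK_NAMES)

    def test_increment_identity(self, small_pair):
        _, (_, _, truth) = small_pair
        assert truth.true_increment == pytest.approx(
            truth.true_volume_t2 - truth.true_volume_t1
        )

    def test_match_fraction_monotone(self, small_pair):
        _, (_, _, truth) = small_pair
        assert truth.true_match_fraction[0.40] >= truth.true_match_fraction[0.20]

    def test_t2_landmarks_are_rigidly_moved_t1_landmarks(self, small_pair):
        _, (_, _, truth) = small_pair
        for name in LANDMARK_NAMES:
            moved = truth.applied_rigid.apply(truth.landmarks_t1[name])
            assert np.allclose(moved, truth.landmarks_t2[name], atol=1e-12)

    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
    def test_truth_volumes_match_oversampled_oracle(self, seed):
        """Radial-quadrature truth vs 4x marching-cubes oracle within 1%."""
        params = small_params(bump_amplitudes=(0.7, 0.5), seed=seed)
        _, _, truth = generate_phantom_pair(params)
        geom = truth.geometry
        for timepoint, expected in (("T1", truth.true_volume_t1),
                                    ("T2", truth.true_volume_t2)):
            oracle = oracle_cropped_volume(geom, timepoint, params.voxel_spacing,
                                           oversample=4) / 1000.0
            assert expected == pytest.approx(oracle, rel=0.01)

    def test_single_bump_increment_matches_mesh_oracle(self):
        """A lone outward bump: generator truth vs the mesh-difference oracle.

        Uses a smooth relief-free cavity so the only T1/T2 difference is
        the single Gaussian bump (amplitude 1 mm, sigma 3 mm).
        """
        params = small_params(seed=0, texture_amplitude=0.0,
                              cavity_volume_cv=0.0, noise_sd=0.0)
        probe = generate_phantom_pair(params)[2].geometry
        center = probe.rim_point(probe.ya0 + 0.55 * probe.length, 1.0)
        params = dataclasses.replace(
            params, bump_centers=np.array([center]), bump_amplitudes=(1.0,),
        )
        _, _, truth = generate_phantom_pair(params)
        g = truth.geometry
        o1 = oracle_cropped_volume(g, "T1", params.voxel_spacing, oversample=4)
        o2 = oracle_cropped_volume(g, "T2", params.voxel_spacing, oversample=4)
        assert truth.true_increment == pytest.approx((o2 - o1) / 1000.0, rel=0.01)
        assert truth.true_increment > 0


class TestValidation:
    def test_bump_exceeding_shell_rejected(self):
        with pytest.raises(DegeneratePhantom):
            small_params(bump_amplitudes=(5.0, 0.0)).validate()

    def test_grid_too_small(self):
        params = small_params(grid_shape=(16, 16, 16))
        with pytest.raises(GridTooSmall):
            generate_phantom_pair(params)

    def test_noise_separation_invariant(self):
        with pytest.raises(ValueError):
            small_params(noise_sd=200.0).validate()


class TestCalibration:
    def test_zero_target_zero_amplitudes(self):
        out = calibrate_bumps(0.0, None, small_params())
        assert all(a == 0.0 for a in out.bump_amplitudes)

    def test_increment_calibration_hits_target(self):
        """Desk-scale run of the printed BB-group increment target."""
        params = PhantomParams(
            cavity_mean_volume=3.2, grid_shape=(112, 112, 112),
            bump_amplitudes=(1.0, 0.85), texture_amplitude=0.0,
        )
        out = calibrate_bumps(0.77, None, params)
        _, _, truth = generate_phantom_pair(
            dataclasses.replace(out, cavity_volume_cv=0.0, seed=0)
        )
        assert 0.755 <= truth.true_increment <= 0.785

    def test_match_fraction_calibration_hits_target(self):
        params = PhantomParams(
            cavity_mean_volume=3.2, grid_shape=(112, 112, 112),
            bump_amplitudes=(1.0, 0.85), texture_amplitude=0.0,
        )
        out = calibrate_bumps(None, {0.20: 0.8384}, params)
        _, _, truth = generate_phantom_pair(
            dataclasses.replace(out, cavity_volume_cv=0.0, seed=0)
        )
        assert truth.true_match_fraction[0.20] == pytest.approx(0.8384, abs=0.01)


def test_save_phantom_pair_roundtrip(tmp_path, quiet_pair):
    import json

    from orbitmorph.image import read_volume

    params, (vol1, vol2, truth) = quiet_pair
    outdir = save_phantom_pair(tmp_path / "run", vol1, vol2, truth, params)
    back = read_volume(outdir / "t1.nrrd")
    assert np.allclose(back.voxels, vol1.voxels, atol=1e-4)
    assert np.allclose(back.spacing, vol1.spacing)
    assert np.allclose(back.origin, vol1.origin)
    manifest = json.loads((outdir / "manifest.json").read_text())
    assert set(manifest["files"]) == {
        "t1.nrrd", "t2.nrrd", "truth.json", "landmarks_t1.json", "landmarks_t2.json",
    }
    tr = json.loads((outdir / "truth.json").read_text())
    assert {r["name"] for r in tr["landmarks_t1"]} == set(LANDMARK_NAMES)
    from orbitmorph.cropping import read_landmarks

    lms = read_landmarks(outdir / "landmarks_t1.json")
    assert set(lms) == set(LANDMARK_NAMES)
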