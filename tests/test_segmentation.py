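"""Fast-marching segmentation, mask smoothing, surface extraction."""

import numpy as np
import pytest
from scipy import ndimage

from orbitmorph.errors import EmptySegmentation, SeedOutsideWindow
from orbitmorph.image import SegmentationMask, VolumeImage
from orbitmorph.segmentation import (
    FastMarchParams,
    extract_surface,
    fast_march_segment,
    smooth_mask,
)


def flood_fill_oracle(vol: np.ndarray, seed, window) -> np.ndarray:
    """Brute-force 6-connected flood fill restricted to the window."""
    lo, hi = window
    admissible = (vol >= lo) & (vol <= hi)
    structure = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    labels, _ = ndimage.label(admissible, structure=structure)
    return labels == labels[tuple(seed)]


def make_volume(arr, spacing=0.5):
    return VolumeImage(np.asarray(arr, dtype=np.float32), np.full(3, spacing), np.zeros(3))


class TestFastMarch:
    def test_homogeneous_volume_fills_entirely(self):
        vol = make_volume(np.full((16, 16, 16), 500.0))
        p = FastMarchParams(seeds=[(8, 8, 8)], intensity_window=(400, 600),
                            beta=0.0, arrival_cap=np.inf)
        mask = fast_march_segment(vol, p)
        assert mask.voxels.all()

    def test_seed_in_bone_rejected(self):
        arr = np.full((16, 16, 16), 500.0)
        arr[2, 2, 2] = 1600.0
        vol = make_volume(arr)
        p = FastMarchParams(seeds=[(2, 2, 2)], intensity_window=(400, 600))
        with pytest.raises(SeedOutsideWindow):
            fast_march_segment(vol, p)

    def test_wall_blocks_propagation(self):
        """Two chambers separated by a bone wall: only the seeded one fills."""
        arr = np.full((20, 20, 20), 500.0)
        arr[:, 10, :] = 1600.0
        vol = make_volume(arr)
        p = FastMarchParams(seeds=[(5, 5, 5)], intensity_window=(400, 600),
                            beta=0.0, arrival_cap=np.inf)
        mask = fast_march_segment(vol, p)
        assert mask.voxels[:, :10, :].all()
        assert not mask.voxels[:, 10:, :].any()

    @pytest.mark.parametrize("seed_int", range(4))
    def test_flood_fill_oracle_equivalence(self, seed_int):
        """beta = 0, tau = inf equals the brute-force windowed flood fill."""
        rng = np.random.default_rng(seed_int)
        smooth = ndimage.gaussian_filter(rng.standard_normal((40, 40, 40)), 4.0)
        arr = np.where(smooth > 0, 500.0, 1500.0)
        inside = np.argwhere(arr == 500.0)
        seed = tuple(inside[rng.integers(len(inside))])
        vol = make_volume(arr)
        p = FastMarchParams(seeds=[seed], intensity_window=(400, 600),
                            beta=0.0, arrival_cap=np.inf)
        mask = fast_march_segment(vol, p)
        oracle = flood_fill_oracle(arr, seed, (400, 600))
        assert np.array_equal(mask.voxels, oracle)

    def test_monotone_in_tau(self):
        rng = np.random.default_rng(0)
        arr = 500.0 + 30.0 * rng.standard_normal((24, 24, 24))
        vol = make_volume(arr)
        masks = []
        for tau in (2.0, 5.0):
            p = FastMarchParams(seeds=[(12, 12, 12)], intensity_window=(300, 700),
                                beta=0.01, arrival_cap=tau)
            masks.append(fast_march_segment(vol, p).voxels)
        assert np.all(masks[1][masks[0]])  # tau1 <= tau2 -> mask1 subset mask2


def voxel_ball(radius_mm: float, spacing: float) -> SegmentationMask:
    n = int(2 * radius_mm / spacing) + 9
    idx = np.arange(n) * spacing
    c = idx[n // 2]
    x, y, z = np.meshgrid(idx, idx, idx, indexing="ij")
    ball = (x - c) ** 2 + (y - c) ** 2 + (z - c) ** 2 <= radius_mm**2
    return SegmentationMask(ball, np.full(3, spacing), np.zeros(3))


class TestSmoothMask:
    def test_radius_zero_identity(self):
        mask = voxel_ball(3.0, 0.5)
        out = smooth_mask(mask, 0.0)
        assert np.array_equal(out.voxels, mask.voxels)

    def test_ball_volume_nearly_preserved(self):
        mask = voxel_ball(6.0, 0.3)
        out = smooth_mask(mask, 0.6)
        assert abs(out.count - mask.count) / mask.count < 0.02

    def test_isolated_voxel_removed(self):
        mask = voxel_ball(3.0, 0.5)
        vox = mask.voxels.copy()
        vox[1, 1, 1] = True  # speck far from the ball
        speckled = SegmentationMask(vox, mask.spacing, mask.origin)
        out = smooth_mask(speckled, 0.6)
        assert not out.voxels[1, 1, 1]

    def test_empty_rejected(self):
        empty = SegmentationMask(np.zeros((9, 9, 9), bool), np.full(3, 0.5), np.zeros(3))
        with pytest.raises(EmptySegmentation):
            smooth_mask(empty, 0.5)


class TestExtractSurface:
    def test_ball_volume_closed_form(self):
        mask = voxel_ball(17.9, 0.3)
        mesh = extract_surface(mask)
        assert mesh.is_watertight
        expected = 4.0 / 3.0 * np.pi * 17.9**3
        assert abs(mesh.volume) == pytest.approx(expected, rel=0.02)

    def test_euler_characteristic_genus_zero(self):
        mesh = extract_surface(voxel_ball(4.0, 0.5))
        v = len(mesh.vertices)
        e = len(mesh.edges_unique)
        f = len(mesh.faces)
        assert v - e + f == 2

    def test_volume_converges_with_spacing(self):
        expected = 4.0 / 3.0 * np.pi * 6.0**3
        errs = []
        for spacing in (0.6, 0.3):
            mesh = extract_surface(voxel_ball(6.0, spacing))
            errs.append(abs(abs(mesh.volume) - expected) / expected)
        assert errs[1] < errs[0]

    def test_empty_mask_rejected(self):
        empty = SegmentationMask(np.zeros((9, 9, 9), bool), np.full(3, 0.5), np.zeros(3))
        with pytest.raises(EmptySegmentation):
            extract_surface(empty)

    def test_outward_orientation(self):
        mesh = extract_surface(voxel_ball(4.0, 0.5))
        assert mesh.volume > 0
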