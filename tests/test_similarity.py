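import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sliceatlas.similarity import (
    GlobalTransform,
    HOGConfig,
    apply_global_transform,
    global_align,
    hog_features,
    hog_l2,
    rough_mask,
    smooth_contour,
)


def _disk(shape, center, radius):
    yy, xx = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


class TestSmoothContour:
    def test_circle_is_a_single_harmonic(self):
        mask = _disk((64, 64), (32, 32), 20)
        contour = smooth_contour(mask, keep_harmonics=1)
        radii = np.linalg.norm(contour - [32, 32], axis=1)
        assert np.ptp(radii) / radii.mean() < 0.02
        assert radii.mean() == pytest.approx(20, rel=0.02)

    def test_square_reconstruction_with_many_harmonics(self):
        mask = np.zeros((64, 64), bool)
        mask[16:48, 16:48] = True
        contour = smooth_contour(mask, keep_harmonics=32)
        # every reconstructed vertex lies within 1 px of the square outline
        d_left = np.abs(contour[:, 1] - 15.5)
        d_right = np.abs(contour[:, 1] - 47.5)
        d_top = np.abs(contour[:, 0] - 15.5)
        d_bot = np.abs(contour[:, 0] - 47.5)
        dist = np.minimum.reduce([d_left, d_right, d_top, d_bot])
        assert dist.max() < 1.0

    def test_empty_mask_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            smooth_contour(np.zeros((16, 16), bool))


class TestHOGFeatures:
    def test_constant_image_has_zero_features(self):
        cfg = HOGConfig(cell_size_px=4)
        feats = hog_features(np.full((32, 32), 0.5), cfg)
        assert np.allclose(feats, 0.0)

    def test_vertical_step_edge_votes_horizontal_gradient_bin(self):
        cfg = HOGConfig(cell_size_px=8, n_orientations=9)
        img = np.zeros((32, 32))
        img[:, 16:] = 1.0
        feats = hog_features(img, cfg)
        energy = feats.reshape(feats.shape[0], feats.shape[1], 4, 9).sum(
            axis=(0, 1, 2)
        )
        # gradient of a vertical edge points along +x: orientation bin 0
        assert int(np.argmax(energy)) == 0

    def test_everything_below_threshold_gives_zero(self):
        cfg = HOGConfig(cell_size_px=4, intensity_threshold=0.5)
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 0.4, (24, 24))
        assert np.allclose(hog_features(img, cfg), 0.0)

    def test_image_smaller_than_block_is_an_error(self):
        with pytest.raises(ValueError):
            hog_features(np.ones((5, 5)), HOGConfig(cell_size_px=4))


class TestHOGL2:
    def test_self_distance_zero_and_shape_mismatch(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(size=(32, 32))
        assert hog_l2(x, x, HOGConfig(cell_size_px=4)) == 0.0
        with pytest.raises(ValueError):
            hog_l2(x, x[:16], HOGConfig(cell_size_px=4))

    @settings(max_examples=10, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_symmetric_and_nonnegative(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(size=(24, 24))
        b = rng.uniform(size=(24, 24))
        cfg = HOGConfig(cell_size_px=4)
        ab = hog_l2(a, b, cfg)
        assert ab >= 0.0
        assert ab == pytest.approx(hog_l2(b, a, cfg))

    def test_brightness_invariance_from_block_normalization(self, mid_plane):
        plane, _, _ = mid_plane
        cfg = HOGConfig(cell_size_px=8)
        other = np.roll(plane, 5, axis=0)
        base = hog_l2(plane, other, cfg)
        for factor in (0.5, 2.0):
            scaled = hog_l2(np.clip(plane * factor, 0, None), other, cfg)
            assert abs(scaled - base) / base < 0.10

    def test_locally_flat_under_small_shifts(self, native_reslice):
        """A 3 px shift perturbs the score less than moving to the next
        phantom plane (the distortion-tolerance property)."""
        atlas, _ = native_reslice
        j = len(atlas) // 2
        a = atlas.slices[j] / atlas.slices[j].max()
        neighbor = atlas.slices[j + 4] / atlas.slices[j + 4].max()
        cfg = HOGConfig(cell_size_px=15)
        shifted = np.roll(a, 3, axis=1)
        assert hog_l2(a, shifted, cfg) < hog_l2(a, neighbor, cfg)


class TestGlobalAlign:
    def test_identity_pair(self, mid_plane):
        plane, _, _ = mid_plane
        mask = rough_mask(plane)
        gt = global_align(plane, mask, plane, mask, HOGConfig(cell_size_px=8),
                          refine_anisotropic=False)
        assert abs(gt.rotation_rad) < np.deg2rad(1.0)
        assert gt.scale == pytest.approx(1.0, abs=0.02)
        assert np.abs(gt.translation).max() < 2.0

    @staticmethod
    def _asymmetric_slice():
        """Textured slice with an asymmetric outline: a rotation of a
        near-symmetric (elliptical) outline is unidentifiable from the
        contour, so rotation recovery needs a shape like this one."""
        yy, xx = np.meshgrid(np.arange(128), np.arange(128), indexing="ij")
        body = (yy - 70) ** 2 + (xx - 56) ** 2 <= 36**2
        lobe = (yy - 36) ** 2 + (xx - 86) ** 2 <= 18**2
        mask = body | lobe
        rng = np.random.default_rng(0)
        from scipy import ndimage

        tex = ndimage.gaussian_filter(rng.uniform(size=(128, 128)), 2)
        return (0.3 + 0.7 * tex) * mask

    def test_known_rotation_and_scale_recovered(self):
        from scipy import ndimage

        plane = self._asymmetric_slice()
        theta, scale = np.deg2rad(10.0), 1.15
        c = (np.asarray(plane.shape) - 1) / 2
        # backward matrix scale*R: the moving image shows the plane
        # shrunk by 1/scale (stays inside the frame) and rotated
        m = scale * np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        moving = ndimage.affine_transform(plane, m, offset=c - m @ c, order=1)
        gt = global_align(
            moving, rough_mask(moving), plane, rough_mask(plane),
            HOGConfig(cell_size_px=8), refine_anisotropic=False,
        )
        assert abs(abs(gt.rotation_rad) - theta) < np.deg2rad(1.0)
        assert gt.scale == pytest.approx(scale, rel=0.02)

    def test_anisotropic_stretch_recovered_within_grid_step(self, mid_plane):
        from scipy import ndimage

        plane, _, _ = mid_plane
        sx = 1.1  # moving is the plane stretched horizontally by sx
        c = (np.asarray(plane.shape) - 1) / 2
        m = np.diag([1.0, 1.0 / sx])
        moving = ndimage.affine_transform(plane, m, offset=c - m @ c, order=1)
        gt = global_align(
            moving, rough_mask(moving), plane, rough_mask(plane),
            HOGConfig(cell_size_px=8), refine_anisotropic=True,
        )
        # mapping moving -> fixed must undo the stretch: 1/sx, within
        # one 0.05 grid step
        total_sx = gt.sx * gt.scale
        assert abs(total_sx - 1.0 / sx) <= 0.051

    def test_empty_mask_is_an_error(self, mid_plane):
        plane, _, _ = mid_plane
        with pytest.raises(ValueError, match="empty"):
            global_align(plane, np.zeros_like(plane, dtype=bool), plane,
                         rough_mask(plane))


def test_apply_global_transform_identity(mid_plane):
    plane, _, _ = mid_plane
    out = apply_global_transform(plane, GlobalTransform.identity())
    np.testing.assert_allclose(out, plane, atol=1e-12)
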