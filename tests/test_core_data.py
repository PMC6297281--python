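import numpy as np
import pytest

from sliceatlas.core_data import (
    AnnotationVolume,
    Rotation,
    SliceStack,
    Volume,
    half_masks,
    load_slice_stack,
    load_volume,
    rotate_and_reslice,
    save_slice_stack,
    save_volume,
)


def _smooth_blob_volume(shape=(32, 40, 36)):
    """Band-limited compactly supported test volume."""
    zz, yy, xx = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    c = [(s - 1) / 2 for s in shape]
    r2 = (
        ((zz - c[0]) / 10) ** 2
        + ((yy - c[1]) / 13) ** 2
        + ((xx - c[2]) / 11) ** 2
    )
    data = np.exp(-2.0 * r2)
    data[r2 > 2.0] = 0.0
    return Volume(data=data, voxel_size_um=25.0)


class TestVolumeIO:
    @pytest.mark.parametrize("suffix", [".nrrd", ".nii.gz"])
    def test_roundtrip_bit_exact_for_integer_volume(self, tmp_path, suffix):
        labels = np.arange(2 * 3 * 4, dtype=np.int32).reshape(2, 3, 4)
        ann = AnnotationVolume(
            labels=labels, free_label_set=frozenset({0}), voxel_size_um=25.0
        )
        path = tmp_path / f"ann{suffix}"
        save_volume(path, ann)
        back = load_volume(path, "annotation")
        np.testing.assert_array_equal(back.labels, labels)
        assert back.voxel_size_um == pytest.approx(25.0)

    def test_header_spacing_is_read(self, tmp_path):
        vol = Volume(data=np.ones((3, 4, 5)), voxel_size_um=25.0)
        path = tmp_path / "v.nrrd"
        save_volume(path, vol)
        assert load_volume(path).voxel_size_um == pytest.approx(25.0)

    def test_anisotropic_voxels_rejected(self, tmp_path):
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(np.ones((3, 4, 5)))
        img.SetSpacing((25.0, 25.0, 50.0))
        sitk.WriteImage(img, str(tmp_path / "aniso.nrrd"))
        with pytest.raises(ValueError, match="anisotropic"):
            load_volume(tmp_path / "aniso.nrrd")

    def test_annotation_shape_mismatch_is_an_error(self):
        vol = Volume(data=np.ones((3, 4, 5)), voxel_size_um=25.0)
        ann = AnnotationVolume(
            labels=np.zeros((3, 4, 6), dtype=np.int32),
            free_label_set=frozenset({0}),
            voxel_size_um=25.0,
        )
        with pytest.raises(ValueError, match="does not match"):
            ann.check_congruent(vol)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_volume(tmp_path / "nope.nrrd")


class TestSliceStackIO:
    def test_roundtrip(self, tmp_path):
        stack = SliceStack(
            images=[np.random.default_rng(0).uniform(size=(8, 9)) for _ in range(4)],
            spacing_um=50.0,
            pixel_size_um=25.0,
            selected=[0, 2, 3],
        )
        save_slice_stack(tmp_path / "stack", stack)
        back = load_slice_stack(tmp_path / "stack")
        assert back.selected == [0, 2, 3]
        assert back.spacing_um == 50.0
        for a, b in zip(stack.images, back.images):
            np.testing.assert_allclose(a, b, atol=1e-6)

    def test_missing_sidecar_is_an_error(self, tmp_path):
        (tmp_path / "empty").mkdir()
        with pytest.raises(FileNotFoundError, match="sidecar"):
            load_slice_stack(tmp_path / "empty")


class TestReslice:
    def test_identity_rotation_returns_native_planes_exactly(self):
        vol = _smooth_blob_volume()
        res = rotate_and_reslice(vol, Rotation(0.0, 0.0))
        assert len(res) == vol.shape[0]
        for z in range(vol.shape[0]):
            np.testing.assert_array_equal(res.slices[z], vol.data[z])

    def test_compose_and_invert_recovers_planes(self):
        vol = _smooth_blob_volume()
        beta = 6.0
        fwd = rotate_and_reslice(vol, Rotation(0.0, beta))
        vol_fwd = Volume(
            data=np.clip(np.stack(fwd.slices), 0, None), voxel_size_um=25.0
        )
        back = rotate_and_reslice(vol_fwd, Rotation(0.0, -beta))
        # compare central planes (ends are clipped by the two rotations)
        offset = back.kept_indices[0] + fwd.kept_indices[0]
        scale = float(vol.data.max())
        errs = []
        for k, z in enumerate(back.kept_indices):
            z_orig = z + fwd.kept_indices[0]
            if not 8 <= z_orig < vol.shape[0] - 8:
                continue
            diff = back.slices[k] - vol.data[z_orig]
            errs.append(np.sqrt(np.mean(diff**2)) / scale)
        assert errs and max(errs) < 0.02

    def test_point_source_plane_shift_follows_geometry(self):
        shape = (40, 48, 44)
        data = np.zeros(shape)
        z0, y0, x0 = 20, 10, 22
        data[z0, y0, x0] = 1.0
        vol = Volume(data=data, voxel_size_um=25.0)
        beta = 6.0
        res = rotate_and_reslice(vol, Rotation(0.0, beta), min_support=0.0)
        bright = np.array([s.max() for s in res.slices])
        z_found = res.kept_indices[int(np.argmax(bright))]
        cy = (shape[1] - 1) / 2
        cz = (shape[0] - 1) / 2
        expected = cz + np.cos(np.radians(beta)) * (z0 - cz) - np.sin(
            np.radians(beta)
        ) * (y0 - cy)
        assert abs(z_found - expected) <= 1.0

    def test_total_intensity_preserved_under_small_rotations(self):
        vol = _smooth_blob_volume()
        total = vol.data.sum()
        for alpha, beta in [(10.0, 0.0), (0.0, -10.0), (7.0, 7.0)]:
            res = rotate_and_reslice(vol, Rotation(alpha, beta))
            assert np.sum(np.stack(res.slices)) == pytest.approx(total, rel=0.01)

    def test_rotation_out_of_range(self):
        vol = _smooth_blob_volume()
        with pytest.raises(ValueError):
            rotate_and_reslice(vol, Rotation(50.0, 0.0))


class TestHalfMasks:
    @pytest.mark.parametrize("shape", [(10, 8), (11, 8), (9, 13)])
    @pytest.mark.parametrize("axis", ["vertical", "horizontal"])
    def test_complementary_and_disjoint(self, shape, axis):
        a, b = half_masks(shape, axis)
        assert ((a | b) == np.ones(shape, bool)).all()
        assert not (a & b).any()

    def test_floor_split_convention(self):
        upper, lower = half_masks((11, 8), "vertical")
        assert upper[:5].all() and not upper[5:].any()
        assert lower[5:].all() and not lower[:5].any()

    def test_bad_axis(self):
        with pytest.raises(ValueError):
            half_masks((4, 4), "diagonal")
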