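"""Domain containers, volume/slice I/O and geometric reslicing.

Axis convention (fixed at load time and used everywhere downstream):

* array axis 0 = ``z``: anterior -> posterior, the slicing axis; a coronal
  plane is a fixed-``z`` section,
* array axis 1 = ``y``: superior -> inferior,
* array axis 2 = ``x``: left -> right.

Sectioning-angle rotations are parameterized by ``alpha`` (about the
superior-inferior ``y`` axis) and ``beta`` (about the left-right ``x``
axis), composed alpha-first, about the geometric center of the volume.
Both angles are small in practice (single digits of degrees), so the
composition order is second-order, but the same order is used for both
angle estimation and final reslicing.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage

__all__ = [
    "Volume",
    "AnnotationVolume",
    "SliceStack",
    "Rotation",
    "ReslicedAtlas",
    "load_volume",
    "save_volume",
    "load_slice_stack",
    "save_slice_stack",
    "rotation_matrix",
    "rotate_and_reslice",
    "half_masks",
]

#: planes whose in-bounds support fraction falls below this are dropped
MIN_PLANE_SUPPORT = 0.01


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Volume:
    """Isotropic 3D grayscale reference volume in ``(z, y, x)`` order."""

    data: np.ndarray
    voxel_size_um: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.data.shape}")
        if not self.voxel_size_um > 0:
            raise ValueError("voxel_size_um must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        if self.data.min() < 0:
            raise ValueError("volume intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class AnnotationVolume:
    """Integer region-label volume congruent with its paired :class:`Volume`.

    ``free_label_set`` lists the region IDs treated as hollow space
    (ventricular system) plus the background label 0.
    """

    labels: np.ndarray
    free_label_set: frozenset[int]
    voxel_size_um: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("annotation labels must be integer-typed")
        if self.labels.ndim != 3:
            raise ValueError("annotation must be 3D")
        self.free_label_set = frozenset(int(v) for v in self.free_label_set)
        if not self.free_label_set:
            raise ValueError("free_label_set must be non-empty")
        if not self.voxel_size_um > 0:
            raise ValueError("voxel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def check_congruent(self, volume: Volume) -> None:
        if self.labels.shape != volume.data.shape:
            raise ValueError(
                f"annotation shape {self.labels.shape} does not match "
                f"volume shape {volume.data.shape}"
            )

    def free_mask(self) -> np.ndarray:
        """Boolean mask of hollow/background voxels."""
        return np.isin(self.labels, sorted(self.free_label_set))


@dataclass
class SliceStack:
    """Ordered experimental slice sequence with physical metadata.

    ``selected`` is the 0-based, strictly increasing subset ``A`` of slice
    indices used for angle estimation and sparse plane matching.
    """

    images: list[np.ndarray]
    spacing_um: float
    pixel_size_um: float
    selected: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.images = [np.asarray(im, dtype=np.float64) for im in self.images]
        if not self.images:
            raise ValueError("slice stack is empty")
        if any(im.ndim != 2 for im in self.images):
            raise ValueError("slices must be 2D grayscale images")
        if not self.spacing_um > 0:
            raise ValueError("spacing_um must be positive")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        sel = list(self.selected)
        if sel:
            if any(b <= a for a, b in zip(sel, sel[1:])):
                raise ValueError("selected must be strictly increasing")
            if sel[0] < 0 or sel[-1] >= len(self.images):
                raise ValueError("selected indices out of range")
        self.selected = sel

    def __len__(self) -> int:
        return len(self.images)


@dataclass(frozen=True)
class Rotation:
    """Sectioning-angle pair: ``alpha`` about y, ``beta`` about x (degrees)."""

    alpha_deg: float
    beta_deg: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.alpha_deg) and math.isfinite(self.beta_deg)):
            raise ValueError("rotation angles must be finite")


@dataclass
class ReslicedAtlas:
    """Coronal planes of a rotated volume, re-indexed anterior->posterior.

    ``kept_indices`` records which rotated-grid plane indices survived the
    support filter; ``support`` is the in-bounds area fraction per kept
    plane.
    """

    slices: list[np.ndarray]
    rotation: Rotation
    spacing_um: float
    kept_indices: list[int] = field(default_factory=list)
    support: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.slices) < 1:
            raise ValueError("resliced atlas has no planes")

    def __len__(self) -> int:
        return len(self.slices)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def _read_nrrd(path: Path) -> tuple[np.ndarray, float]:
    import SimpleITK as sitk

    img = sitk.ReadImage(str(path))
    data = sitk.GetArrayFromImage(img)  # (z, y, x)
    spacing = img.GetSpacing()[::-1]
    return data, _isotropic_spacing(spacing, path)


def _read_nifti(path: Path) -> tuple[np.ndarray, float]:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    spacing = img.header.get_zooms()[:3]
    return data, _isotropic_spacing(spacing, path)


def _isotropic_spacing(spacing, path: Path) -> float:
    s = np.asarray(spacing, dtype=float)
    if np.ptp(s) > 1e-3 * s.mean():
        raise ValueError(f"{path}: anisotropic voxels {tuple(s)} are not supported")
    return float(s.mean())


def load_volume(path, kind: str = "grayscale"):
    """Read a 3D NRRD or NIfTI volume into the canonical axis convention.

    Parameters
    ----------
    path : str or Path
    kind : {"grayscale", "annotation"}
        Grayscale volumes become :class:`Volume`; annotation volumes become
        :class:`AnnotationVolume` with the background label 0 in the free
        set (extend ``free_label_set`` afterwards for ventricle IDs).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith(".nrrd"):
        data, voxel = _read_nrrd(path)
    elif suffixes.endswith((".nii", ".nii.gz")):
        data, voxel = _read_nifti(path)
    else:
        raise ValueError(f"unsupported volume format: {path.name}")
    if data.ndim != 3:
        raise ValueError(f"{path}: expected 3D data, got shape {data.shape}")
    if kind == "grayscale":
        return Volume(data=np.asarray(data, dtype=np.float64), voxel_size_um=voxel)
    if kind == "annotation":
        if not np.issubdtype(np.asarray(data).dtype, np.integer):
            data = np.rint(np.asarray(data)).astype(np.int32)
        return AnnotationVolume(
            labels=data, free_label_set=frozenset({0}), voxel_size_um=voxel
        )
    raise ValueError(f"unknown kind {kind!r}")


def save_volume(path, volume) -> None:
    """Write a :class:`Volume` or :class:`AnnotationVolume` to NRRD/NIfTI."""
    path = Path(path)
    if isinstance(volume, AnnotationVolume):
        data, voxel = volume.labels, volume.voxel_size_um
    else:
        data, voxel = volume.data, volume.voxel_size_um
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith(".nrrd"):
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(data)
        img.SetSpacing((voxel,) * 3)
        sitk.WriteImage(img, str(path))
    elif suffixes.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        affine = np.diag([voxel, voxel, voxel, 1.0])
        nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))
    else:
        raise ValueError(f"unsupported volume format: {path.name}")


def save_slice_stack(directory, stack: SliceStack) -> None:
    """Write a stack as zero-padded float32 TIFFs plus a JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, image in enumerate(stack.images):
        tifffile.imwrite(
            directory / f"slice_{i:04d}.tif", image.astype(np.float32)
        )
    meta = {
        "spacing_um": stack.spacing_um,
        "pixel_size_um": stack.pixel_size_um,
        "selected_0based": list(stack.selected),
    }
    (directory / "stack.json").write_text(json.dumps(meta, indent=2))


def load_slice_stack(directory) -> SliceStack:
    """Read a stack written by :func:`save_slice_stack` (TIFF or PNG)."""
    directory = Path(directory)
    sidecar = directory / "stack.json"
    if not sidecar.exists():
        raise FileNotFoundError(f"missing stack sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    paths = sorted(
        p for p in directory.iterdir() if p.suffix.lower() in {".tif", ".tiff", ".png"}
    )
    if not paths:
        raise FileNotFoundError(f"no slice images in {directory}")
    images = []
    for p in paths:
        if p.suffix.lower() == ".png":
            from imageio.v3 import imread

            images.append(np.asarray(imread(p), dtype=np.float64))
        else:
            images.append(np.asarray(tifffile.imread(p), dtype=np.float64))
    return SliceStack(
        images=images,
        spacing_um=float(meta["spacing_um"]),
        pixel_size_um=float(meta["pixel_size_um"]),
        selected=[int(i) for i in meta.get("selected_0based", [])],
    )


# ---------------------------------------------------------------------------
# reslicing geometry
# ---------------------------------------------------------------------------

def rotation_matrix(rotation: Rotation) -> np.ndarray:
    """3x3 matrix acting on ``(z, y, x)`` vectors: alpha about y, then beta
    about x, right-hand sense."""
    a = math.radians(rotation.alpha_deg)
    b = math.radians(rotation.beta_deg)
    ca, sa = math.cos(a), math.sin(a)
    cb, sb = math.cos(b), math.sin(b)
    # alpha rotates the (z, x) components, beta the (z, y) components
    r_alpha = np.array([[ca, 0.0, -sa], [0.0, 1.0, 0.0], [sa, 0.0, ca]])
    r_beta = np.array([[cb, -sb, 0.0], [sb, cb, 0.0], [0.0, 0.0, 1.0]])
    return r_beta @ r_alpha


def _plane_support(shape, rot: np.ndarray, center: np.ndarray) -> np.ndarray:
    """In-bounds area fraction of each rotated coronal plane.

    Computed analytically from the inverse mapping on a coordinate grid;
    identical for grayscale and annotation reslices of the same geometry.
    """
    nz, ny, nx = shape
    rinv = rot.T
    ys, xs = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    frac = np.empty(nz)
    for z in range(nz):
        out = np.stack(
            [np.full(ys.shape, float(z)), ys.astype(float), xs.astype(float)], axis=0
        )
        rel = out.reshape(3, -1) - center[:, None]
        src = rinv @ rel + center[:, None]
        inside = (
            (src[0] >= 0) & (src[0] <= nz - 1)
            & (src[1] >= 0) & (src[1] <= ny - 1)
            & (src[2] >= 0) & (src[2] <= nx - 1)
        )
        frac[z] = inside.mean()
    return frac


def rotate_and_reslice(
    volume,
    rotation: Rotation,
    *,
    min_support: float = MIN_PLANE_SUPPORT,
) -> ReslicedAtlas:
    """Rotate a volume about its geometric center and cut coronal planes.

    Grayscale volumes are resampled trilinearly, annotation volumes with
    nearest neighbors (labels must not blend). Planes whose in-bounds
    support falls below ``min_support`` are dropped; at identity rotation
    no interpolation is applied and the native z-planes are returned.
    """
    if abs(rotation.alpha_deg) > 45 or abs(rotation.beta_deg) > 45:
        raise ValueError("rotation angles must satisfy |alpha|, |beta| <= 45 deg")

    if isinstance(volume, AnnotationVolume):
        data, voxel, order = volume.labels, volume.voxel_size_um, 0
    else:
        data, voxel, order = volume.data, volume.voxel_size_um, 1

    if rotation.alpha_deg == 0 and rotation.beta_deg == 0:
        slices = [data[z].copy() for z in range(data.shape[0])]
        return ReslicedAtlas(
            slices=slices,
            rotation=rotation,
            spacing_um=voxel,
            kept_indices=list(range(data.shape[0])),
            support=[1.0] * data.shape[0],
        )

    rot = rotation_matrix(rotation)
    center = (np.asarray(data.shape, dtype=float) - 1.0) / 2.0
    rinv = rot.T
    offset = center - rinv @ center
    rotated = ndimage.affine_transform(
        data.astype(np.float64 if order else data.dtype),
        rinv,
        offset=offset,
        order=order,
        mode="constant",
        cval=0.0,
        prefilter=False,
    )
    support = _plane_support(data.shape, rot, center)
    kept = [z for z in range(data.shape[0]) if support[z] >= min_support]
    if not kept:
        raise ValueError("rotation leaves no plane with sufficient support")
    slices = [rotated[z] for z in kept]
    return ReslicedAtlas(
        slices=slices,
        rotation=rotation,
        spacing_um=voxel,
        kept_indices=kept,
        support=[float(support[z]) for z in kept],
    )


def half_masks(shape, split_axis: str) -> tuple[np.ndarray, np.ndarray]:
    """Complementary binary masks splitting an image at its midline.

    ``split_axis='vertical'`` stacks an upper and a lower half (split
    across rows; the upper mask gets ``floor(h/2)`` rows),
    ``split_axis='horizontal'`` a left and a right half.
    """
    h, w = int(shape[0]), int(shape[1])
    if h <= 0 or w <= 0:
        raise ValueError("mask shape must be positive")
    first = np.zeros((h, w), dtype=bool)
    second = np.zeros((h, w), dtype=bool)
    if split_axis == "vertical":
        first[: h // 2, :] = True
        second[h // 2 :, :] = True
    elif split_axis == "horizontal":
        first[:, : w // 2] = True
        second[:, w // 2 :] = True
    else:
        raise ValueError("split_axis must be 'vertical' or 'horizontal'")
    return first, second
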