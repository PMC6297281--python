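"""Global pre-alignment and the HOG-L2 similarity metric.

The difference score between two slices is the summed squared difference
of block-normalized histogram-of-oriented-gradients features computed at
the same block coordinates. A large cell (15 px at atlas resolution)
makes the score tolerant to small uncorrected distortions, which is what
lets plane matching work before any nonrigid registration; a small cell
(4 px) is used later when the point is to correct those distortions.

Before the score is computed the moving slice is brought into the fixed
plane's coordinates with a similarity transform (closed-form Umeyama fit
on Shape Context contour correspondences over Fourier-smoothed tissue
outlines), optionally refined by a small grid search over anisotropic
horizontal/vertical rescaling to absorb sectioning compression.

All 2D geometry here is carried in homogeneous ``(row, col)`` coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import linear_sum_assignment
from skimage import measure
from skimage.transform import SimilarityTransform

__all__ = [
    "HOGConfig",
    "GlobalTransform",
    "ContourFeatures",
    "smooth_contour",
    "resample_contour",
    "shape_context",
    "contour_features",
    "global_align",
    "apply_global_transform",
    "rough_mask",
    "hog_features",
    "hog_l2",
    "block_mask",
]

ANISO_GRID = (0.90, 0.95, 1.00, 1.05, 1.10)


@dataclass(frozen=True)
class HOGConfig:
    """Parameters of the oriented-gradient descriptor.

    ``intensity_threshold`` is relative to a [0, 1] intensity scale:
    pixels darker than it contribute no gradient mass, which suppresses
    the faint non-tissue halo around atlas slices.
    """

    cell_size_px: int = 15
    n_orientations: int = 9
    intensity_threshold: float = 0.02
    block_norm_eps: float = 1e-4

    def __post_init__(self) -> None:
        if self.cell_size_px < 2:
            raise ValueError("cell_size_px must be >= 2")
        if self.n_orientations < 4:
            raise ValueError("n_orientations must be >= 4")
        if not 0.0 <= self.intensity_threshold <= 1.0:
            raise ValueError("intensity_threshold must lie in [0, 1]")


@dataclass
class GlobalTransform:
    """Similarity + anisotropic rescale, mapping moving -> fixed coords."""

    rotation_rad: float
    scale: float
    translation: np.ndarray  # (d_row, d_col)
    sx: float = 1.0
    sy: float = 1.0
    matrix: np.ndarray = field(default=None)  # 3x3 homogeneous (row, col)

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise ValueError("scale must be positive")
        if not (self.sx > 0 and self.sy > 0):
            raise ValueError("anisotropic scales must be positive")
        if self.matrix is None:
            c, s = np.cos(self.rotation_rad), np.sin(self.rotation_rad)
            m = np.eye(3)
            m[:2, :2] = self.scale * np.array([[c, -s], [s, c]])
            m[:2, 2] = np.asarray(self.translation, dtype=float)
            self.matrix = m

    @classmethod
    def identity(cls) -> "GlobalTransform":
        return cls(rotation_rad=0.0, scale=1.0, translation=np.zeros(2))


@dataclass
class ContourFeatures:
    """Resampled smooth contour points plus their Shape Context descriptors."""

    points: np.ndarray  # (n, 2) as (row, col)
    descriptors: np.ndarray  # (n, n_radial * n_angular)


# ---------------------------------------------------------------------------
# contours
# ---------------------------------------------------------------------------

def smooth_contour(mask: np.ndarray, keep_harmonics: int = 16) -> np.ndarray:
    """Low-pass the boundary of a binary mask via Fourier descriptors.

    The largest closed boundary curve is expressed as a complex signal and
    reconstructed from its ``keep_harmonics`` lowest positive and negative
    frequencies (plus DC). Returns an open polyline of ``(row, col)``
    vertices tracing the closed curve once.
    """
    mask = np.asarray(mask).astype(float)
    if mask.max() <= 0:
        raise ValueError("empty mask has no contour")
    contours = measure.find_contours(mask, 0.5)
    if not contours:
        raise ValueError("no contour found in mask")
    if len(contours) > 1:
        warnings.warn(
            f"mask has {len(contours)} boundary components; using the largest",
            stacklevel=2,
        )
    contour = max(contours, key=len)
    if np.allclose(contour[0], contour[-1]):
        contour = contour[:-1]
    z = contour[:, 0] + 1j * contour[:, 1]
    spec = np.fft.fft(z)
    freqs = np.fft.fftfreq(len(z), d=1.0 / len(z))
    spec[np.abs(freqs) > keep_harmonics] = 0.0
    smooth = np.fft.ifft(spec)
    return np.column_stack([smooth.real, smooth.imag])


def resample_contour(points: np.ndarray, n: int) -> np.ndarray:
    """Uniform arc-length resampling of a closed polyline to ``n`` points."""
    closed = np.vstack([points, points[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        raise ValueError("degenerate contour with zero length")
    targets = np.linspace(0.0, total, n, endpoint=False)
    rows = np.interp(targets, s, closed[:, 0])
    cols = np.interp(targets, s, closed[:, 1])
    return np.column_stack([rows, cols])


def shape_context(
    points: np.ndarray, n_radial: int = 5, n_angular: int = 12
) -> np.ndarray:
    """Log-polar relative-position histograms for each contour point.

    Two histogram sets are concatenated per point: one binned in the
    absolute image frame and one relative to the local contour tangent.
    The absolute half anchors the orientation on near-symmetric
    outlines (where tangent-relative views repeat along the curve); the
    tangent half is rotation-invariant and lets the correspondence
    follow a genuinely rotated shape instead of biasing the recovered
    rotation toward zero.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    if n < 8:
        raise ValueError("degenerate contour: need at least 8 points")
    diff = points[None, :, :] - points[:, None, :]
    dist = np.linalg.norm(diff, axis=2)
    mean_dist = dist[dist > 0].mean()
    r = dist / mean_dist
    # log-spaced radial edges over [1/8, 2] mean distances
    edges = np.logspace(np.log10(0.125), np.log10(2.0), n_radial + 1)
    r_bin = np.searchsorted(edges, r, side="right") - 1
    valid = (r_bin >= 0) & (r_bin < n_radial) & (dist > 0)
    abs_ang = np.arctan2(diff[..., 0], diff[..., 1]) % (2 * np.pi)
    tangent = np.roll(points, -1, axis=0) - np.roll(points, 1, axis=0)
    t_ang = np.arctan2(tangent[:, 0], tangent[:, 1])
    rel_ang = (abs_ang - t_ang[:, None]) % (2 * np.pi)

    halves = []
    for ang in (abs_ang, rel_ang):
        a_bin = np.minimum(
            (ang / (2 * np.pi) * n_angular).astype(int), n_angular - 1
        )
        hist = np.zeros((n, n_radial * n_angular))
        flat = r_bin * n_angular + a_bin
        for i in range(n):
            np.add.at(hist[i], flat[i][valid[i]], 1.0)
        hist /= np.maximum(hist.sum(axis=1, keepdims=True), 1e-12)
        halves.append(hist)
    return np.concatenate(halves, axis=1)


def contour_features(
    mask: np.ndarray, n_points: int = 100, keep_harmonics: int = 16
) -> ContourFeatures:
    """Smooth, resample and describe a mask's outline in one step."""
    pts = resample_contour(smooth_contour(mask, keep_harmonics), n_points)
    return ContourFeatures(points=pts, descriptors=shape_context(pts))


def rough_mask(image: np.ndarray, threshold: float = 0.02) -> np.ndarray:
    """Quick tissue mask: threshold, keep largest component, fill holes."""
    mask = np.asarray(image) > threshold * max(float(np.max(image)), 1e-12)
    if not mask.any():
        return mask
    labels, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    return ndimage.binary_fill_holes(mask)


# ---------------------------------------------------------------------------
# global alignment
# ---------------------------------------------------------------------------

def _fit_similarity(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Closed-form least-squares similarity fit (3x3 homogeneous)."""
    if hasattr(SimilarityTransform, "from_estimate"):
        tform = SimilarityTransform.from_estimate(src, dst)
        if not tform:
            raise ValueError("similarity fit failed (degenerate correspondences)")
    else:  # older scikit-image
        tform = SimilarityTransform()
        if not tform.estimate(src, dst):
            raise ValueError("similarity fit failed (degenerate correspondences)")
    return np.asarray(tform.params)


def _chi2_cost(h1: np.ndarray, h2: np.ndarray) -> np.ndarray:
    num = (h1[:, None, :] - h2[None, :, :]) ** 2
    den = h1[:, None, :] + h2[None, :, :] + 1e-12
    return 0.5 * np.sum(num / den, axis=2)


def _aniso_matrix(sx: float, sy: float, center: np.ndarray) -> np.ndarray:
    m = np.eye(3)
    m[0, 0] = sy
    m[1, 1] = sx
    m[:2, 2] = center - np.array([sy * center[0], sx * center[1]])
    return m


def apply_global_transform(
    image: np.ndarray, transform: GlobalTransform, output_shape=None
) -> np.ndarray:
    """Resample ``image`` (moving) into the fixed frame of ``transform``."""
    if output_shape is None:
        output_shape = image.shape
    minv = np.linalg.inv(transform.matrix)
    return ndimage.affine_transform(
        image,
        minv[:2, :2],
        offset=minv[:2, 2],
        output_shape=tuple(output_shape),
        order=1,
        mode="constant",
        cval=0.0,
    )


def global_align(
    moving: np.ndarray,
    moving_mask: np.ndarray,
    fixed: np.ndarray,
    fixed_mask: np.ndarray,
    config: HOGConfig | None = None,
    *,
    n_contour: int = 100,
    keep_harmonics: int = 16,
    refine_anisotropic: bool = True,
    refine_iters: int = 3,
    aniso_grid=ANISO_GRID,
    moving_features: ContourFeatures | None = None,
    fixed_features: ContourFeatures | None = None,
) -> GlobalTransform:
    """Estimate the similarity (+ anisotropic rescale) aligning two slices.

    Shape Context descriptors of the two smoothed outlines are matched with
    the Hungarian algorithm; the correspondences feed a closed-form
    least-squares similarity fit. When ``refine_anisotropic`` is set, a
    small grid over horizontal/vertical scale factors picks the pair that
    minimizes the HOG-L2 score of the warped moving image against the
    fixed one. Precomputed :class:`ContourFeatures` can be supplied to
    amortize contour work across many pairings.
    """
    config = config or HOGConfig()
    if moving_features is None:
        if not np.asarray(moving_mask).any():
            raise ValueError("moving mask is empty")
        moving_features = contour_features(moving_mask, n_contour, keep_harmonics)
    if fixed_features is None:
        if not np.asarray(fixed_mask).any():
            raise ValueError("fixed mask is empty")
        fixed_features = contour_features(fixed_mask, n_contour, keep_harmonics)

    cost = _chi2_cost(moving_features.descriptors, fixed_features.descriptors)
    ri, ci = linear_sum_assignment(cost)
    src = moving_features.points[ri]
    dst = fixed_features.points[ci]

    sim = _fit_similarity(src, dst)
    # refine the correspondence on the transformed contour: the absolute
    # half of the descriptor biases the first match toward zero apparent
    # rotation, and re-matching after each fit removes the residual
    # geometrically
    for _ in range(refine_iters):
        hom = np.column_stack(
            [moving_features.points, np.ones(len(moving_features.points))]
        )
        warped_pts = (sim @ hom.T).T[:, :2]
        warped_desc = shape_context(warped_pts)
        cost = _chi2_cost(warped_desc, fixed_features.descriptors)
        ri, ci = linear_sum_assignment(cost)
        new_sim = _fit_similarity(moving_features.points[ri],
                                  fixed_features.points[ci])
        delta = abs(
            np.arctan2(new_sim[1, 0], new_sim[0, 0])
            - np.arctan2(sim[1, 0], sim[0, 0])
        )
        sim = new_sim
        if delta < np.deg2rad(0.2):
            break
    scale = float(np.sqrt(max(np.linalg.det(sim[:2, :2]), 1e-18)))
    rotation = float(np.arctan2(sim[1, 0], sim[0, 0]))
    translation = sim[:2, 2].copy()

    best = GlobalTransform(
        rotation_rad=rotation,
        scale=scale,
        translation=translation,
        matrix=sim.copy(),
    )
    if not refine_anisotropic:
        return best

    center = dst.mean(axis=0)
    best_score = None
    for sy in aniso_grid:
        for sx in aniso_grid:
            m = _aniso_matrix(sx, sy, center) @ sim
            cand = GlobalTransform(
                rotation_rad=rotation,
                scale=scale,
                translation=translation,
                sx=sx,
                sy=sy,
                matrix=m,
            )
            warped = apply_global_transform(moving, cand, fixed.shape)
            score = hog_l2(warped, fixed, config)
            # prefer scales nearest unity on ties
            key = (score, abs(sx - 1) + abs(sy - 1))
            if best_score is None or key < best_score:
                best_score = key
                best = cand
    return best


# ---------------------------------------------------------------------------
# HOG features
# ---------------------------------------------------------------------------

def cell_histograms(image: np.ndarray, config: HOGConfig) -> np.ndarray:
    """Per-cell orientation histograms (no block normalization).

    Gradients are binned into unsigned orientation bins with linear
    interpolation between neighboring bins; pixels below the intensity
    threshold contribute nothing.
    """
    image = np.asarray(image, dtype=np.float64)
    c = config.cell_size_px
    nb = config.n_orientations
    h, w = image.shape
    ncy, ncx = h // c, w // c
    if ncy < 1 or ncx < 1:
        raise ValueError("image smaller than one HOG cell")
    image = image[: ncy * c, : ncx * c]

    gy, gx = np.gradient(image)
    mag = np.hypot(gy, gx)
    mag[image < config.intensity_threshold] = 0.0
    ang = np.arctan2(gy, gx) % np.pi

    pos = ang / (np.pi / nb)
    b0 = np.floor(pos).astype(np.intp) % nb
    frac = pos - np.floor(pos)
    b1 = (b0 + 1) % nb

    cy = np.repeat(np.arange(ncy, dtype=np.intp), c)[:, None]
    cx = np.repeat(np.arange(ncx, dtype=np.intp), c)[None, :]
    cell_idx = cy * ncx + cx
    flat0 = (cell_idx * nb + b0).ravel()
    flat1 = (cell_idx * nb + b1).ravel()
    hist = np.bincount(flat0, weights=(mag * (1.0 - frac)).ravel(),
                       minlength=ncy * ncx * nb)
    hist += np.bincount(flat1, weights=(mag * frac).ravel(),
                        minlength=ncy * ncx * nb)
    return hist.reshape(ncy, ncx, nb)


def block_normalize(cells: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    """L2-normalize 2x2 cell blocks; returns ``(nby, nbx, 4 * n_bins)``."""
    ncy, ncx, nb = cells.shape
    if ncy < 2 or ncx < 2:
        raise ValueError("image smaller than one 2x2-cell HOG block")
    blocks = np.concatenate(
        [
            cells[:-1, :-1],
            cells[:-1, 1:],
            cells[1:, :-1],
            cells[1:, 1:],
        ],
        axis=2,
    )
    norm = np.sqrt(np.sum(blocks**2, axis=2, keepdims=True) + eps**2)
    return blocks / norm


def hog_features(image: np.ndarray, config: HOGConfig | None = None) -> np.ndarray:
    """Block-wise normalized HOG feature array of an image in [0, 1]."""
    config = config or HOGConfig()
    return block_normalize(cell_histograms(image, config), config.block_norm_eps)


def block_mask(mask: np.ndarray, config: HOGConfig) -> np.ndarray:
    """Boolean array over HOG blocks fully covered by a pixel mask."""
    c = config.cell_size_px
    m = np.asarray(mask, dtype=bool)
    ncy, ncx = m.shape[0] // c, m.shape[1] // c
    cells = m[: ncy * c, : ncx * c].reshape(ncy, c, ncx, c).all(axis=(1, 3))
    return cells[:-1, :-1] & cells[:-1, 1:] & cells[1:, :-1] & cells[1:, 1:]


def hog_l2(
    a: np.ndarray,
    b: np.ndarray,
    config: HOGConfig | None = None,
    mask: np.ndarray | None = None,
) -> float:
    """Scalar difference score: summed squared HOG feature difference.

    Symmetric and non-negative; zero for identical images. With ``mask``,
    the sum runs over the blocks fully inside the masked region
    (half-slice matching), which avoids spurious gradients at the mask
    boundary.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    config = config or HOGConfig()
    fa = hog_features(a, config)
    fb = hog_features(b, config)
    diff = np.sum((fa - fb) ** 2, axis=2)
    if mask is not None:
        diff = diff * block_mask(mask, config)
    return float(np.sum(diff))
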