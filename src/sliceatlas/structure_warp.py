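"""Thin-plate-spline correction of a segmented hollow structure.

A heavily squeezed aqueduct can be smaller than the registration grid
cell, so the MRF stage cannot reshape it. Instead, point correspondence
is built directly on the structure outlines — split each closed contour
at its highest and lowest points, sample the two halves uniformly by arc
length — and an exact thin-plate-spline warp carries the experimental
outline onto its atlas counterpart. Grid points ringing the structures
are added as identity anchors so the correction stays local.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.interpolate import RBFInterpolator
from skimage import measure

from .mrf import WarpField

__all__ = [
    "ContourCorrespondence",
    "TPSTransform",
    "contour_correspondence",
    "fit_tps",
    "warp_with_tps",
    "identity_anchors",
]


@dataclass
class ContourCorrespondence:
    u: np.ndarray  # experimental contour points, (2*n_per_half, 2)
    v: np.ndarray  # atlas contour points, same shape, paired by order
    anchors_exp: tuple[np.ndarray, np.ndarray]  # (top, bottom)
    anchors_atlas: tuple[np.ndarray, np.ndarray]
    n_per_half: int

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "u_y": self.u[:, 0],
                "u_x": self.u[:, 1],
                "v_y": self.v[:, 0],
                "v_x": self.v[:, 1],
            }
        ).to_csv(path, index=False)


@dataclass
class TPSTransform:
    """Exact thin-plate interpolant (r^2 log r kernel + affine part)."""

    source: np.ndarray
    target: np.ndarray
    _rbf: RBFInterpolator

    def __call__(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return self._rbf(pts)


def _closed_contour(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask, dtype=float)
    if mask.max() <= 0:
        raise ValueError("empty structure mask")
    contours = measure.find_contours(mask, 0.5)
    if not contours:
        raise ValueError("structure mask has no contour")
    contour = max(contours, key=len)
    if np.allclose(contour[0], contour[-1]):
        contour = contour[:-1]
    # fix traversal orientation (counter-clockwise in image coordinates)
    x, y = contour[:, 1], contour[:, 0]
    area = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    if area < 0:
        contour = contour[::-1]
    return contour


def _anchor_indices(contour: np.ndarray) -> tuple[int, int]:
    """Highest and lowest contour points; ties resolved toward the
    contour centroid in the horizontal direction."""
    rows, cols = contour[:, 0], contour[:, 1]
    cx = float(cols.mean())

    def pick(extreme_row: float) -> int:
        cand = np.flatnonzero(np.abs(rows - extreme_row) < 0.5)
        return int(cand[np.argmin(np.abs(cols[cand] - cx))])

    top = pick(rows.min())
    bottom = pick(rows.max())
    if top == bottom:
        raise ValueError("degenerate structure: top and bottom anchors coincide")
    return top, bottom


def _sample_half(points: np.ndarray, n: int) -> np.ndarray:
    """n interior points at uniform arc-length fractions (anchors excluded)."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] <= 0:
        raise ValueError("zero-length contour half")
    fr = (np.arange(1, n + 1)) / (n + 1)
    t = fr * s[-1]
    rows = np.interp(t, s, points[:, 0])
    cols = np.interp(t, s, points[:, 1])
    return np.column_stack([rows, cols])


def _split_and_sample(mask: np.ndarray, n_per_half: int):
    contour = _closed_contour(mask)
    top, bottom = _anchor_indices(contour)
    rolled = np.roll(contour, -top, axis=0)
    bottom_r = (bottom - top) % len(contour)
    half1 = rolled[: bottom_r + 1]
    half2 = np.vstack([rolled[bottom_r:], rolled[:1]])
    pts = np.vstack(
        [_sample_half(half1, n_per_half), _sample_half(half2, n_per_half)]
    )
    return pts, (contour[top], contour[bottom])


def contour_correspondence(
    mask_exp: np.ndarray, mask_atlas: np.ndarray, n_per_half: int = 8
) -> ContourCorrespondence:
    """Ordered point pairs along two structure outlines.

    Both contours are traversed with the same orientation starting at
    their top anchor, split at the bottom anchor, and each half sampled
    uniformly by arc length; pairing is by order.
    """
    u, anchors_e = _split_and_sample(mask_exp, n_per_half)
    v, anchors_a = _split_and_sample(mask_atlas, n_per_half)
    return ContourCorrespondence(
        u=u, v=v, anchors_exp=anchors_e, anchors_atlas=anchors_a,
        n_per_half=n_per_half,
    )


def fit_tps(
    source_points: np.ndarray,
    target_points: np.ndarray,
    extra_fixed_points: np.ndarray | None = None,
) -> TPSTransform:
    """Exact TPS through all source -> target pairs.

    ``extra_fixed_points`` map to themselves, pinning the far field so
    the correction does not leak across the slice.
    """
    src = np.asarray(source_points, dtype=float)
    tgt = np.asarray(target_points, dtype=float)
    if src.shape != tgt.shape or src.ndim != 2 or src.shape[1] != 2:
        raise ValueError("source and target must be matching (n, 2) arrays")
    if extra_fixed_points is not None and len(extra_fixed_points):
        extra = np.asarray(extra_fixed_points, dtype=float)
        src = np.vstack([src, extra])
        tgt = np.vstack([tgt, extra])
    if len(src) < 3:
        raise ValueError("need at least 3 landmarks")
    span = np.ptp(src, axis=0)
    if np.min(span) < 1e-9:
        raise ValueError("degenerate (collinear) landmark configuration")
    try:
        rbf = RBFInterpolator(
            src, tgt, kernel="thin_plate_spline", degree=1, smoothing=0.0
        )
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise ValueError(f"degenerate landmark configuration: {exc}") from exc
    return TPSTransform(source=src, target=tgt, _rbf=rbf)


def identity_anchors(
    grid_positions: np.ndarray,
    structure_union_mask: np.ndarray,
    spacing_px: int = 16,
    ring_cells: int = 3,
) -> np.ndarray:
    """Grid nodes within a ``ring_cells``-cell band outside the structures."""
    mask = np.asarray(structure_union_mask, dtype=bool)
    if not mask.any():
        return np.asarray(grid_positions, dtype=float)
    dist = ndimage.distance_transform_edt(~mask)
    pos = np.asarray(grid_positions)
    h, w = mask.shape
    keep = []
    for py, px in pos:
        y, x = int(np.clip(py, 0, h - 1)), int(np.clip(px, 0, w - 1))
        if 0 < dist[y, x] <= ring_cells * spacing_px:
            keep.append((py, px))
    return np.asarray(keep, dtype=float).reshape(-1, 2)


def warp_with_tps(obj, tps: TPSTransform):
    """Compose the TPS with a registration output.

    * For a :class:`WarpField` ``D`` (backward map ``T(x) = x + D(x)``),
      returns the field of the composition ``x -> tps(x + D(x))``.
    * For an image, treats the TPS as the backward map and resamples:
      ``out(x) = image(tps(x))``.
    """
    if isinstance(obj, WarpField):
        h, w = obj.shape
        yy, xx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        pts = np.column_stack(
            [(yy + obj.dy).ravel(), (xx + obj.dx).ravel()]
        )
        mapped = tps(pts)
        dy = mapped[:, 0].reshape(h, w) - yy
        dx = mapped[:, 1].reshape(h, w) - xx
        return WarpField(dy=dy, dx=dx, level_info=list(obj.level_info))
    image = np.asarray(obj, dtype=float)
    h, w = image.shape
    yy, xx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    pts = np.column_stack([yy.ravel().astype(float), xx.ravel().astype(float)])
    mapped = tps(pts)
    return ndimage.map_coordinates(
        image, [mapped[:, 0].reshape(h, w), mapped[:, 1].reshape(h, w)],
        order=1, mode="constant", cval=0.0,
    )
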