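"""Sectioning-angle estimation and slice-to-plane mapping.

Each selected experimental slice is scored against every coronal plane of
the (rotated) atlas with the HOG-L2 metric after global pre-alignment.
A dynamic program then finds the monotone slice-to-plane assignment of
minimum total score subject to a physical spacing constraint: the atlas
index step between consecutive matches must agree with the known slice
spacing within a relative tolerance ``theta``.

The sectioning-angle difference about each axis is found without an
exhaustive 2D search: matching the two half-slices (upper/lower for the
left-right axis, left/right for the superior-inferior axis) separately
yields an average matched-index difference ``D`` whose sign says which
way the atlas is tilted relative to the stack. The atlas is re-rotated
in 1-degree steps until ``D`` changes sign, and the flip-adjacent angle
with the smaller ``|D|`` wins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import downscale_local_mean

from .core_data import (
    ReslicedAtlas,
    Rotation,
    SliceStack,
    Volume,
    half_masks,
    rotate_and_reslice,
)
from .similarity import (
    HOGConfig,
    apply_global_transform,
    contour_features,
    global_align,
    hog_l2,
    rough_mask,
)

__all__ = [
    "CostMatrix",
    "SliceMapping",
    "DPConfig",
    "NoAdmissibleMappingError",
    "build_cost_matrix",
    "dp_map",
    "half_index_difference",
    "estimate_angles",
    "interpolate_mapping",
]

log = logging.getLogger(__name__)

#: finite stand-in cost for pairs whose pre-alignment is degenerate
UNMATCHABLE_COST = 1e6

#: rows where a half-mask holds less than this foreground fraction of the
#: slice are excluded from the half-index difference
MIN_HALF_FOREGROUND = 0.05


@dataclass(frozen=True)
class DPConfig:
    """Knobs of the mapping DP and the angle search."""

    theta: float = 0.5
    angle_step_deg: float = 1.0
    max_angle_deg: float = 12.0
    search_downsample: int = 2

    def __post_init__(self) -> None:
        if not 0.0 < self.theta < 1.0:
            raise ValueError("theta must lie in (0, 1)")
        if self.max_angle_deg > 20:
            raise ValueError("max_angle_deg must be <= 20")
        if self.search_downsample < 1:
            raise ValueError("search_downsample must be >= 1")


@dataclass
class CostMatrix:
    """``|A| x M`` HOG-L2 scores between selected slices and atlas planes."""

    rho: np.ndarray
    mask_kind: str = "full"

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho, dtype=np.float64)
        if self.rho.ndim != 2:
            raise ValueError("cost matrix must be 2D")
        if not np.all(np.isfinite(self.rho)) or self.rho.min() < 0:
            raise ValueError("cost matrix entries must be finite and >= 0")


@dataclass
class SliceMapping:
    """Result of the localization stage."""

    rotation: Rotation
    selected_map: np.ndarray  # plane index per selected slice
    full_map: np.ndarray  # real-valued plane index per slice
    total_cost: float
    row_min_cost: np.ndarray = field(default=None)  # per-slice quality flag


class NoAdmissibleMappingError(RuntimeError):
    """Raised when the spacing constraint admits no monotone mapping."""


# ---------------------------------------------------------------------------
# cost matrices
# ---------------------------------------------------------------------------

def _pair_costs(
    stack: SliceStack,
    atlas: ReslicedAtlas,
    masks: list[np.ndarray | None],
    config: HOGConfig,
    *,
    refine_anisotropic: bool = False,
    n_contour: int = 64,
    align_per_pair: bool = True,
    ref_planes=None,
    plane_band=None,
) -> list[np.ndarray]:
    """HOG-L2 cost matrices for several half-masks in one alignment pass.

    With ``align_per_pair`` (the final-mapping mode), pre-alignment
    (contour extraction, Shape Context matching, similarity fit) is done
    once per (slice, plane) pair; each requested mask then contributes
    one masked score matrix. Without it (the angle-search mode), every
    slice is aligned once per reslice to an area-matched reference plane
    — all planes share one coordinate frame, so a single transform per
    slice suffices — and its features are scored against every plane's
    precomputed features, which is roughly 30x cheaper and avoids
    per-pair scale noise.
    """
    if len(atlas) == 0:
        raise ValueError("empty resliced atlas")
    if not stack.selected:
        raise ValueError("selected subset A is empty")

    def norm(im: np.ndarray) -> np.ndarray:
        mx = float(im.max())
        return im / mx if mx > 0 else im

    planes = [norm(p) for p in atlas.slices]
    slices = [norm(stack.images[i]) for i in stack.selected]

    # physical admissibility: the slice pixel size is known, so the
    # moving->fixed similarity scale must sit near this value, and a
    # slice can only match a plane of comparable tissue area. Without
    # this gate, contour alignment happily shrinks a slice onto a tiny
    # near-empty border plane where the HOG score degenerates to ~0.
    expected_scale = stack.pixel_size_um / atlas.spacing_um
    plane_areas = [rough_mask(p, config.intensity_threshold).sum() for p in planes]
    slice_areas = [rough_mask(s, config.intensity_threshold).sum() for s in slices]

    plane_feats = []
    for p in planes:
        m = rough_mask(p, config.intensity_threshold)
        try:
            plane_feats.append(contour_features(m, n_contour))
        except ValueError:
            plane_feats.append(None)
    slice_feats = []
    for s in slices:
        m = rough_mask(s, config.intensity_threshold)
        try:
            slice_feats.append(contour_features(m, n_contour))
        except ValueError:
            slice_feats.append(None)

    from .similarity import block_mask, hog_features

    plane_hog = [
        hog_features(p, config) if pf is not None else None
        for p, pf in zip(planes, plane_feats)
    ]
    bmasks = [
        block_mask(m, config) if m is not None else None for m in masks
    ]

    def masked_cost(slice_hog, j):
        diff = np.sum((slice_hog - plane_hog[j]) ** 2, axis=2)
        return [
            float(np.sum(diff * bm)) if bm is not None else float(np.sum(diff))
            for bm in bmasks
        ]

    rhos = [np.empty((len(slices), len(planes))) for _ in masks]
    for i, (s, sf) in enumerate(zip(slices, slice_feats)):
        exp_area = slice_areas[i] * expected_scale**2
        admissible = [
            j
            for j, pf in enumerate(plane_feats)
            if pf is not None and exp_area / 3 <= plane_areas[j] <= exp_area * 3
            and (plane_band is None
                 or plane_band[i][0] <= j <= plane_band[i][1])
        ]
        for r in rhos:
            r[i, :] = UNMATCHABLE_COST
        if sf is None or not admissible:
            continue

        if not align_per_pair:
            # one alignment into the shared atlas frame, against either a
            # caller-provided reference plane or the admissible plane of
            # most similar tissue area
            if ref_planes is not None:
                j_ref = min(
                    admissible, key=lambda j: abs(j - int(ref_planes[i]))
                )
            else:
                j_ref = min(
                    admissible, key=lambda j: abs(plane_areas[j] - exp_area)
                )
            try:
                gt = global_align(
                    s, None, planes[j_ref], None, config,
                    moving_features=sf, fixed_features=plane_feats[j_ref],
                    refine_anisotropic=refine_anisotropic,
                    refine_iters=1,  # slices are near-upright here
                )
                if not 0.7 <= gt.scale / expected_scale <= 1.4:
                    raise ValueError("similarity scale outside physical range")
                warped = apply_global_transform(s, gt, planes[j_ref].shape)
            except ValueError:
                continue
            s_hog = hog_features(warped, config)
            for j in admissible:
                vals = masked_cost(s_hog, j)
                for r, v in zip(rhos, vals):
                    r[i, j] = v
            continue

        for j in admissible:
            try:
                gt = global_align(
                    s, None, planes[j], None, config,
                    moving_features=sf, fixed_features=plane_feats[j],
                    refine_anisotropic=refine_anisotropic,
                )
                if not 0.7 <= gt.scale / expected_scale <= 1.4:
                    raise ValueError("similarity scale outside physical range")
                warped = apply_global_transform(s, gt, planes[j].shape)
            except ValueError:
                continue
            vals = masked_cost(hog_features(warped, config), j)
            for r, v in zip(rhos, vals):
                r[i, j] = v
    return rhos


def build_cost_matrix(
    stack: SliceStack,
    atlas: ReslicedAtlas,
    mask_kind: str = "full",
    config: HOGConfig | None = None,
    *,
    refine_anisotropic: bool = False,
    theta: float = 0.5,
    band_halfwidth: int = 8,
) -> CostMatrix:
    """Score every selected slice against every atlas plane.

    ``mask_kind`` restricts the comparison to half of each image:
    ``upper``/``lower`` (vertical split) or ``left``/``right``
    (horizontal split); ``full`` uses the whole images.

    Each slice is first located with cheap shared-frame costs and a DP
    pass; full per-pair alignment (optionally with the anisotropic
    rescale search) is then spent only on the plausible band of
    ``band_halfwidth`` planes around that location, with the bootstrap
    scores standing elsewhere.
    """
    config = config or HOGConfig()
    if mask_kind == "full":
        mask = None
    else:
        shape = atlas.slices[0].shape
        if mask_kind in ("upper", "lower"):
            first, second = half_masks(shape, "vertical")
        elif mask_kind in ("left", "right"):
            first, second = half_masks(shape, "horizontal")
        else:
            raise ValueError(f"unknown mask_kind {mask_kind!r}")
        mask = first if mask_kind in ("upper", "left") else second

    (rho_boot,) = _pair_costs(stack, atlas, [mask], config, align_per_pair=False)
    try:
        boot_map, _ = dp_map(
            rho_boot, stack.selected, stack.spacing_um, atlas.spacing_um, theta
        )
    except NoAdmissibleMappingError:
        boot_map = np.asarray(rho_boot).argmin(axis=1)
    (rho_band,) = _pair_costs(
        stack, atlas, [mask], config,
        refine_anisotropic=refine_anisotropic,
        plane_band=[(int(j) - band_halfwidth, int(j) + band_halfwidth)
                    for j in boot_map],
    )
    rho = np.asarray(rho_boot).copy()
    band_ok = np.asarray(rho_band) < UNMATCHABLE_COST
    rho[band_ok] = np.asarray(rho_band)[band_ok]
    return CostMatrix(rho=rho, mask_kind=mask_kind)


# ---------------------------------------------------------------------------
# dynamic program
# ---------------------------------------------------------------------------

def dp_map(
    costs,
    A,
    s_E: float,
    s_A: float,
    theta: float,
) -> tuple[np.ndarray, float]:
    """Minimum-cost monotone slice-to-plane mapping under spacing bounds.

    Solves ``C(i, j) = min_k C(i-1, k) + rho[i, j]`` over predecessors
    ``k`` whose index step satisfies
    ``|s_A (j - k) / (s_E (A_i - A_{i-1})) - 1| < theta``; the first
    selected slice may match any plane. Ties among predecessors go to the
    ``k`` nearest the spacing-ideal position, final-plane ties to the
    smallest plane index.

    Returns ``(selected_map, total_cost)``.
    """
    rho = costs.rho if isinstance(costs, CostMatrix) else np.asarray(costs, float)
    A = np.asarray(A)
    n, m = rho.shape
    if n < 2:
        raise ValueError("need at least two selected slices")
    if len(A) != n:
        raise ValueError("A length does not match cost matrix rows")

    C = np.full((n, m), np.inf)
    back = np.full((n, m), -1, dtype=int)
    C[0] = rho[0]
    for i in range(1, n):
        delta = s_E * (A[i] - A[i - 1]) / s_A  # ideal index step
        lo = delta * (1.0 - theta)
        hi = delta * (1.0 + theta)
        for j in range(m):
            # admissible predecessors: lo < j - k < hi (strict)
            k_min = int(np.floor(j - hi)) + 1
            k_max = int(np.ceil(j - lo)) - 1
            k_min = max(k_min, 0)
            k_max = min(k_max, m - 1)
            if k_max < k_min:
                continue
            ks = np.arange(k_min, k_max + 1)
            ks = ks[(j - ks > lo) & (j - ks < hi)]
            if ks.size == 0:
                continue
            vals = C[i - 1, ks]
            best = vals.min()
            if not np.isfinite(best):
                continue
            cand = ks[vals == best]
            ideal = j - delta
            k_star = int(cand[np.argmin(np.abs(cand - ideal))])
            C[i, j] = best + rho[i, j]
            back[i, j] = k_star
        if not np.any(np.isfinite(C[i])):
            raise NoAdmissibleMappingError(
                f"no admissible transition from selected slice {i - 1} to {i} "
                f"(ideal plane step {delta:.2f}, theta={theta})"
            )

    j_star = int(np.flatnonzero(C[-1] == C[-1].min())[0])
    total = float(C[-1, j_star])
    mapping = np.empty(n, dtype=int)
    mapping[-1] = j_star
    for i in range(n - 1, 0, -1):
        mapping[i - 1] = back[i, mapping[i]]
    return mapping, total


def interpolate_mapping(selected_map, A, N: int) -> np.ndarray:
    """Real-valued matched plane index for every slice, by piecewise-linear
    interpolation over the selected subset (end segments extrapolate)."""
    A = np.asarray(A, dtype=float)
    y = np.asarray(selected_map, dtype=float)
    if len(A) != len(y):
        raise ValueError("A and selected_map must have equal length")
    t = np.arange(N, dtype=float)
    if len(A) == 1:
        return np.full(N, y[0])
    out = np.interp(t, A, y)
    first_slope = (y[1] - y[0]) / (A[1] - A[0])
    last_slope = (y[-1] - y[-2]) / (A[-1] - A[-2])
    out[t < A[0]] = y[0] + first_slope * (t[t < A[0]] - A[0])
    out[t > A[-1]] = y[-1] + last_slope * (t[t > A[-1]] - A[-1])
    return out


# ---------------------------------------------------------------------------
# half-index difference and angle search
# ---------------------------------------------------------------------------

def half_index_difference(
    stack: SliceStack,
    atlas: ReslicedAtlas,
    split_axis: str,
    config: DPConfig | None = None,
    hog: HOGConfig | None = None,
) -> float:
    """Mean matched-index difference between the two half-slice mappings.

    For a vertical split the value is mean(upper - lower); for a
    horizontal split mean(left - right). Rows where either half carries
    less than 5% foreground in the experimental slice are excluded.
    """
    config = config or DPConfig()
    hog = hog or HOGConfig()
    shape = atlas.slices[0].shape
    first, second = half_masks(shape, split_axis)

    # bootstrap: align each slice to an area-matched plane, locate it
    # with the full-mask DP, then re-align to the located plane — the
    # reference alignment error is shared across all planes, so an
    # off-target reference would masquerade as a tilt in the half costs
    (rho_boot,) = _pair_costs(stack, atlas, [None], hog, align_per_pair=False)
    boot_map, _ = dp_map(
        rho_boot, stack.selected, stack.spacing_um, atlas.spacing_um, config.theta
    )
    rho_first, rho_second = _pair_costs(
        stack, atlas, [first, second], hog,
        align_per_pair=False, ref_planes=boot_map,
    )

    map_first, _ = dp_map(
        rho_first, stack.selected, stack.spacing_um, atlas.spacing_um, config.theta
    )
    map_second, _ = dp_map(
        rho_second, stack.selected, stack.spacing_um, atlas.spacing_um, config.theta
    )

    keep = []
    for row, idx in enumerate(stack.selected):
        m = rough_mask(stack.images[idx] / max(stack.images[idx].max(), 1e-12),
                       hog.intensity_threshold)
        sf, ss = half_masks(m.shape, split_axis)
        area = max(m.sum(), 1)
        if (m & sf).sum() / area >= MIN_HALF_FOREGROUND and \
           (m & ss).sum() / area >= MIN_HALF_FOREGROUND:
            keep.append(row)
    if not keep:
        keep = list(range(len(stack.selected)))
    diff = map_first[keep].astype(float) - map_second[keep].astype(float)
    return float(diff.mean())


def _downsample_for_search(stack: SliceStack, volume: Volume, factor: int):
    """Isotropic resolution reduction for the angle search.

    All three volume axes shrink together (the reslicing geometry
    assumes isotropic voxels), so the atlas voxel size grows by the
    factor while the physical slice spacing is untouched.
    """
    if factor == 1:
        return stack, volume
    images = [downscale_local_mean(im, (factor, factor)) for im in stack.images]
    small_stack = SliceStack(
        images=images,
        spacing_um=stack.spacing_um,
        pixel_size_um=stack.pixel_size_um * factor,
        selected=stack.selected,
    )
    data = downscale_local_mean(volume.data, (factor, factor, factor))
    small_volume = Volume(
        data=data, voxel_size_um=volume.voxel_size_um * factor
    )
    return small_stack, small_volume


def _search_axis(
    stack: SliceStack,
    volume: Volume,
    split_axis: str,
    make_rotation,
    config: DPConfig,
    hog: HOGConfig,
    trace: list | None = None,
    start_deg: float = 0.0,
) -> float:
    """1-degree sign-flip search for one angle, the other held fixed."""

    def measure(angle: float) -> float:
        atlas = rotate_and_reslice(volume, make_rotation(angle))
        d = half_index_difference(stack, atlas, split_axis, config, hog)
        if trace is not None:
            trace.append({"split": split_axis, "angle_deg": angle, "D": d})
        log.info("angle search %s: angle=%+.1f deg, D=%+.3f", split_axis, angle, d)
        return d

    step = config.angle_step_deg
    angle = start_deg
    d = measure(angle)
    if d == 0.0:
        return angle
    # under our axis conventions the first (upper/left) half maps to
    # *smaller* plane indices than the second half while the atlas is
    # under-rotated, so a negative D calls for a more positive angle
    direction = -1.0 if d > 0 else 1.0
    prev_angle, prev_d = angle, d
    while abs(angle) < config.max_angle_deg:
        angle = prev_angle + direction * step
        d = measure(angle)
        if d == 0.0:
            return angle
        if np.sign(d) != np.sign(prev_d):
            return angle if abs(d) < abs(prev_d) else prev_angle
        prev_angle, prev_d = angle, d
    raise RuntimeError(
        f"half-index difference did not change sign within "
        f"+/-{config.max_angle_deg} deg about the {split_axis} split"
    )


def estimate_angles(
    stack: SliceStack,
    volume: Volume,
    config: DPConfig | None = None,
    hog: HOGConfig | None = None,
    trace: list | None = None,
) -> Rotation:
    """Estimate the sectioning-angle pair by the sign-flip half-index search.

    ``beta`` (about the left-right axis, upper/lower halves) is estimated
    first since it tends to be the larger tilt; ``alpha`` follows with
    left/right halves and ``beta`` held at its estimate. The search runs
    on images downsampled by ``config.search_downsample`` with the HOG
    cell shrunk proportionally so the descriptor keeps its physical scale.
    """
    config = config or DPConfig()
    hog = hog or HOGConfig()
    ds = config.search_downsample
    small_stack, small_volume = _downsample_for_search(stack, volume, ds)
    search_hog = HOGConfig(
        cell_size_px=max(4, round(hog.cell_size_px / ds)),
        n_orientations=hog.n_orientations,
        intensity_threshold=hog.intensity_threshold,
    )

    # alternate the two 1D searches: the half-index statistic for one
    # axis is measured with the other axis held fixed, so a wrong first
    # guess of alpha biases beta (and vice versa); warm-started rounds
    # converge in one or two extra passes
    alpha, beta = 0.0, 0.0
    for _ in range(3):
        new_beta = _search_axis(
            small_stack, small_volume, "vertical",
            lambda b: Rotation(alpha_deg=alpha, beta_deg=b),
            config, search_hog, trace, start_deg=beta,
        )
        new_alpha = _search_axis(
            small_stack, small_volume, "horizontal",
            lambda a: Rotation(alpha_deg=a, beta_deg=new_beta),
            config, search_hog, trace, start_deg=alpha,
        )
        if new_alpha == alpha and new_beta == beta:
            break
        alpha, beta = new_alpha, new_beta
    return Rotation(alpha_deg=alpha, beta_deg=beta)
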