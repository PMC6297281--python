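"""Multilevel discrete-MRF nonrigid 2D registration with tissue coherency.

A uniform control grid (16 px spacing at every level's resolution) is
laid over the target slice; each node takes a discrete label encoding an
integer displacement. Nodes are classed by the atlas annotation:

* **coherent** nodes sit in tissue; displacing two coherent nodes that
  are connected through tissue alone stretches or compresses it, so such
  node pairs carry *tension edges* with a squared-displacement-difference
  pairwise cost (a spring energy),
* **free** nodes sit in hollow space (ventricles, background) but still
  move tissue through their bilinear influence; they carry no tension
  and are minimized independently,
* **fixed** nodes influence no tissue and do not move.

The solve runs at three resolutions (4x, 2x, 1x downsampling). Unlike a
conventional coarse-to-fine scheme, displacements are *carried*: each
node's label set at level ``t+1`` is its inherited displacement (the
bilinearly interpolated motion from level ``t``, doubled with the
resolution) plus a fresh offset from the integer grid ``[-8, 8]^2``.
Because the pairwise cost is evaluated on the *cumulative*
displacements, a stretch introduced at a coarse level keeps costing
spring energy at finer levels instead of being silently absorbed.

Unary data terms compare HOG features (cell 4) of the target patch
around a node with the source patch translated by the candidate
cumulative displacement; nodes that influence the tissue contour use the
symmetric difference of warped tissue masks instead, and optional
structure landmark pairs add a Euclidean distance term. All terms are
min-max normalized to [0, 1] per level before being combined with
weights ``(c_a, c_b, c_d, c_p) = (3, 1, 1, 5)``.

Coherent nodes are solved with sequential tree-reweighted message
passing (quadratic-pairwise messages computed exactly with a 1D
lower-envelope distance transform), followed by ICM polishing seeded
from the better of the decoded and the zero-displacement labeling, which
guarantees the returned energy never exceeds the zero labeling's.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.draw import line as draw_line
from skimage.transform import rescale

from .similarity import HOGConfig, block_normalize, cell_histograms

__all__ = [
    "MRFConfig",
    "ControlGrid",
    "LevelProblem",
    "WarpField",
    "theta_grid",
    "build_label_set",
    "classify_nodes",
    "tension_edges",
    "solve_level",
    "register_pair",
    "apply_warp",
    "dense_field_from_nodes",
]

log = logging.getLogger(__name__)

COHERENT, FREE, FIXED, CONTOUR = 0, 1, 2, 3


@dataclass(frozen=True)
class MRFConfig:
    grid_spacing_px: int = 16
    max_disp_px: int = 8  # half the grid spacing
    hog: HOGConfig = field(
        default_factory=lambda: HOGConfig(cell_size_px=4, intensity_threshold=0.02)
    )
    c_atlas: float = 3.0
    c_prev: float = 1.0
    c_struct: float = 1.0
    c_pair: float = 5.0
    level_downsamples: tuple[int, ...] = (4, 2, 1)
    max_sweeps: int = 50
    energy_tol: float = 1e-6


def theta_grid(max_disp_px: int = 8) -> np.ndarray:
    """The per-level fresh displacement offsets: integer grid [-m, m]^2.

    With the default half-spacing bound this is 17 x 17 = 289 labels.
    """
    r = np.arange(-max_disp_px, max_disp_px + 1)
    ty, tx = np.meshgrid(r, r, indexing="ij")
    return np.column_stack([ty.ravel(), tx.ravel()])


# ---------------------------------------------------------------------------
# control grid
# ---------------------------------------------------------------------------

@dataclass
class ControlGrid:
    """Uniform node lattice over one level's image."""

    shape: tuple[int, int]  # level image shape
    spacing: int
    positions: np.ndarray  # (n_nodes, 2) as (row, col), scan order
    grid_shape: tuple[int, int]  # (ny, nx)

    @classmethod
    def cover(cls, shape, spacing: int = 16) -> "ControlGrid":
        h, w = shape
        ny = int(np.ceil((h - 1) / spacing)) + 1
        nx = int(np.ceil((w - 1) / spacing)) + 1
        ys = np.arange(ny) * spacing
        xs = np.arange(nx) * spacing
        yy, xx = np.meshgrid(ys, xs, indexing="ij")
        return cls(
            shape=(h, w),
            spacing=spacing,
            positions=np.column_stack([yy.ravel(), xx.ravel()]),
            grid_shape=(ny, nx),
        )

    def neighbor_pairs(self) -> list[tuple[int, int]]:
        ny, nx = self.grid_shape
        pairs = []
        for iy in range(ny):
            for ix in range(nx):
                p = iy * nx + ix
                if ix + 1 < nx:
                    pairs.append((p, p + 1))
                if iy + 1 < ny:
                    pairs.append((p, p + nx))
        return pairs


def classify_nodes(
    grid: ControlGrid, r_c: np.ndarray, r_e: np.ndarray
) -> np.ndarray:
    """Class per node: coherent in tissue, free in hollow space with tissue
    influence, fixed otherwise."""
    r_c = np.asarray(r_c, dtype=bool)
    r_e = np.asarray(r_e, dtype=bool)
    if np.any(r_c & r_e):
        raise ValueError("coherent and empty-space masks overlap")
    h, w = grid.shape
    s = grid.spacing
    classes = np.full(len(grid.positions), FIXED, dtype=int)
    for i, (py, px) in enumerate(grid.positions):
        y = int(np.clip(py, 0, h - 1))
        x = int(np.clip(px, 0, w - 1))
        if r_c[y, x]:
            classes[i] = COHERENT
        elif r_e[y, x]:
            # influence support: one cell each side (bilinear tent)
            y0, y1 = max(0, py - s), min(h, py + s + 1)
            x0, x1 = max(0, px - s), min(w, px + s + 1)
            if y1 > y0 and x1 > x0 and r_c[y0:y1, x0:x1].any():
                classes[i] = FREE
    return classes


def tension_edges(
    grid: ControlGrid, r_c: np.ndarray, classes: np.ndarray
) -> list[tuple[int, int]]:
    """4-neighbor node pairs whose connecting segment crosses only tissue."""
    r_c = np.asarray(r_c, dtype=bool)
    h, w = grid.shape
    edges = []
    for p, q in grid.neighbor_pairs():
        if classes[p] != COHERENT or classes[q] != COHERENT:
            continue
        py, px = grid.positions[p]
        qy, qx = grid.positions[q]
        py, px = int(np.clip(py, 0, h - 1)), int(np.clip(px, 0, w - 1))
        qy, qx = int(np.clip(qy, 0, h - 1)), int(np.clip(qx, 0, w - 1))
        rr, cc = draw_line(py, px, qy, qx)
        if r_c[rr, cc].all():
            edges.append((p, q))
    return edges


def build_label_set(
    grid: ControlGrid,
    prev_grid: ControlGrid | None,
    prev_cum_disp: np.ndarray | None,
    max_disp_px: int = 8,
) -> tuple[np.ndarray, np.ndarray]:
    """Carried base displacements and per-node candidate displacement sets.

    Returns ``(dbar, offsets)`` where ``dbar`` is ``(n_nodes, 2)`` integer
    base displacements (doubled and bilinearly interpolated from the
    previous level; zero at the first level) and ``offsets`` the shared
    fresh-offset grid. A node's candidate cumulative displacements are
    ``dbar[p] + offsets``.
    """
    offsets = theta_grid(max_disp_px)
    n = len(grid.positions)
    if prev_grid is None or prev_cum_disp is None:
        return np.zeros((n, 2), dtype=int), offsets
    ny, nx = prev_grid.grid_shape
    prev_field = prev_cum_disp.reshape(ny, nx, 2).astype(float)
    ys = np.arange(ny) * prev_grid.spacing
    xs = np.arange(nx) * prev_grid.spacing
    # this level's image has twice the resolution of the previous one
    qy = np.clip(grid.positions[:, 0] / 2.0, ys[0], ys[-1])
    qx = np.clip(grid.positions[:, 1] / 2.0, xs[0], xs[-1])
    dbar = np.empty((n, 2))
    for c in range(2):
        interp = ndimage.map_coordinates(
            prev_field[:, :, c],
            np.vstack(
                [qy / prev_grid.spacing, qx / prev_grid.spacing]
            ),
            order=1,
            mode="nearest",
        )
        dbar[:, c] = 2.0 * interp
    return np.rint(dbar).astype(int), offsets


# ---------------------------------------------------------------------------
# unary terms
# ---------------------------------------------------------------------------

class _PatchHOGScorer:
    """HOG-L2 cost of translating source patches against target patches.

    The source image's cell histograms and block features are precomputed
    densely for every cell-grid phase, so the cost of one (node, label)
    pair reduces to cropping a block window and a squared difference.
    """

    def __init__(self, target: np.ndarray, source: np.ndarray, spacing: int,
                 hog: HOGConfig, pad: int):
        self.hog = hog
        self.spacing = spacing
        self.pad = pad
        self.cell = hog.cell_size_px
        self.target = np.pad(target, pad)
        self.source = np.pad(source, pad)
        self.n_cells = (2 * spacing) // self.cell  # cells per patch side
        self._source_blocks = {}

    def _blocks_for_phase(self, oy: int, ox: int) -> np.ndarray:
        key = (oy, ox)
        if key not in self._source_blocks:
            img = self.source[oy:, ox:]
            cells = cell_histograms(img, self.hog)
            self._source_blocks[key] = block_normalize(
                cells, self.hog.block_norm_eps
            )
        return self._source_blocks[key]

    def target_patch_features(self, pos: np.ndarray) -> np.ndarray:
        s = self.spacing
        r0 = int(pos[0]) - s + self.pad
        c0 = int(pos[1]) - s + self.pad
        patch = self.target[r0 : r0 + 2 * s, c0 : c0 + 2 * s]
        return block_normalize(cell_histograms(patch, self.hog),
                               self.hog.block_norm_eps)

    def cost(self, pos: np.ndarray, disp: np.ndarray,
             target_feats: np.ndarray) -> float:
        s, c = self.spacing, self.cell
        r0 = int(pos[0]) + int(disp[0]) - s + self.pad
        c0 = int(pos[1]) + int(disp[1]) - s + self.pad
        nb = self.n_cells - 1
        if r0 < 0 or c0 < 0 or \
           r0 + 2 * s > self.source.shape[0] or c0 + 2 * s > self.source.shape[1]:
            return float(np.sum(target_feats**2))  # fully outside padding
        blocks = self._blocks_for_phase(r0 % c, c0 % c)
        sy, sx = r0 // c, c0 // c
        if sy + nb > blocks.shape[0] or sx + nb > blocks.shape[1]:
            return float(np.sum(target_feats**2))
        win = blocks[sy : sy + nb, sx : sx + nb]
        return float(np.sum((win - target_feats) ** 2))


def _hog_unary(
    scorer: _PatchHOGScorer,
    grid: ControlGrid,
    dbar: np.ndarray,
    offsets: np.ndarray,
    nodes: np.ndarray,
) -> np.ndarray:
    """(n_nodes, n_labels) translation-approximation HOG unary (Eq-style)."""
    n, L = len(grid.positions), len(offsets)
    out = np.zeros((n, L))
    for p in np.flatnonzero(nodes):
        tf = scorer.target_patch_features(grid.positions[p])
        for li, th in enumerate(offsets):
            out[p, li] = scorer.cost(grid.positions[p], dbar[p] + th, tf)
    return out


def _tent_weights(coords: np.ndarray, center: np.ndarray, spacing: int) -> np.ndarray:
    wy = np.maximum(0.0, 1.0 - np.abs(coords[:, 0] - center[0]) / spacing)
    wx = np.maximum(0.0, 1.0 - np.abs(coords[:, 1] - center[1]) / spacing)
    return wy * wx


def _contour_unary(
    m_target: np.ndarray,
    m_source: np.ndarray,
    grid: ControlGrid,
    dbar: np.ndarray,
    offsets: np.ndarray,
    nodes: np.ndarray,
) -> np.ndarray:
    """Symmetric-difference unary: the source tissue mask patch is truly
    warped (bilinear + 0.5 threshold) by the candidate node motion."""
    s = grid.spacing
    # border nodes can overhang the image by up to spacing-1 px
    pad = 2 * s + int(np.abs(dbar).max(initial=0)) + int(np.abs(offsets).max()) + 2
    mt = np.pad(m_target.astype(float), pad)
    ms = np.pad(m_source.astype(float), pad)
    n, L = len(grid.positions), len(offsets)
    out = np.zeros((n, L))
    yy, xx = np.meshgrid(np.arange(2 * s), np.arange(2 * s), indexing="ij")
    tent = (
        np.maximum(0.0, 1.0 - np.abs(yy - s) / s)
        * np.maximum(0.0, 1.0 - np.abs(xx - s) / s)
    )
    for p in np.flatnonzero(nodes):
        py, px = grid.positions[p]
        r0, c0 = py - s + pad, px - s + pad
        t_patch = mt[r0 : r0 + 2 * s, c0 : c0 + 2 * s]
        for li, th in enumerate(offsets):
            d = dbar[p] + th
            src_r = yy + r0 + tent * d[0]
            src_c = xx + c0 + tent * d[1]
            warped = ndimage.map_coordinates(
                ms, [src_r, src_c], order=1, mode="constant", cval=0.0
            )
            out[p, li] = float(np.abs((warped > 0.5) - t_patch).sum())
    return out


def _structure_unary(
    u_points: np.ndarray,
    v_points: np.ndarray,
    grid: ControlGrid,
    dbar: np.ndarray,
    offsets: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Euclidean-distance unary between warped experimental structure
    contour points and their atlas correspondents; applies to nodes whose
    influence covers at least one point."""
    n, L = len(grid.positions), len(offsets)
    out = np.zeros((n, L))
    applies = np.zeros(n, dtype=bool)
    if u_points is None or len(u_points) == 0:
        return out, applies
    u = np.asarray(u_points, dtype=float)
    v = np.asarray(v_points, dtype=float)
    for p in range(n):
        w = _tent_weights(u, grid.positions[p].astype(float), grid.spacing)
        sel = w > 0
        if not sel.any():
            continue
        applies[p] = True
        uw, vw, ws = u[sel], v[sel], w[sel]
        for li, th in enumerate(offsets):
            d = (dbar[p] + th).astype(float)
            moved = uw + ws[:, None] * d
            out[p, li] = float(np.linalg.norm(moved - vw, axis=1).sum())
    return out, applies


def _minmax_normalize(values: np.ndarray, mask: np.ndarray | None = None):
    """Min-max to [0, 1] over the applicable entries; constant -> zeros."""
    if mask is not None and not mask.any():
        return np.zeros_like(values)
    sel = values[mask] if mask is not None else values
    lo, hi = float(sel.min()), float(sel.max())
    if hi - lo < 1e-12:
        return np.zeros_like(values)
    out = (values - lo) / (hi - lo)
    if mask is not None:
        out[~mask] = 0.0
    return out


# ---------------------------------------------------------------------------
# level solve
# ---------------------------------------------------------------------------

@dataclass
class LevelProblem:
    """One level's discrete optimization, decoupled from image handling.

    ``unary`` holds the coefficient-weighted, normalized unary of every
    node; ``disp`` the candidate cumulative displacement per node and
    label; ``edges`` the tension edges; the pairwise cost of an edge is
    ``pair_scale * ||d_p - d_q||^2 + pair_offset`` (the affine form a
    min-max normalized, ``c_p``-weighted spring term takes).
    """

    unary: list[np.ndarray]  # per node: (L_p,)
    disp: list[np.ndarray]  # per node: (L_p, 2)
    classes: np.ndarray
    edges: list[tuple[int, int]]
    pair_scale: float
    pair_offset: float = 0.0
    zero_label: np.ndarray | None = None  # per-node index of the zero offset
    grid_labels: bool = False  # labels are dbar + full integer grid
    grid_side: int = 17

    def energy(self, labels: np.ndarray) -> float:
        e = sum(float(self.unary[p][labels[p]]) for p in range(len(self.unary)))
        for p, q in self.edges:
            dp = self.disp[p][labels[p]].astype(float)
            dq = self.disp[q][labels[q]].astype(float)
            e += self.pair_scale * float(np.sum((dp - dq) ** 2)) + self.pair_offset
        return e


def _dt1d(values: np.ndarray, src: np.ndarray, tgt: np.ndarray, a: float):
    """out[j] = min_i values[i] + a * (tgt[j] - src[i])^2 (lower envelope)."""
    n = len(src)
    v_idx = np.empty(n, dtype=int)
    z = np.empty(n + 1)
    v_idx[0] = 0
    z[0], z[1] = -np.inf, np.inf
    k = 0
    for i in range(1, n):
        while True:
            j = v_idx[k]
            denom = 2.0 * a * (src[i] - src[j])
            if denom == 0:
                if values[i] < values[j]:
                    if k == 0:
                        v_idx[0] = i
                        z[1] = np.inf
                        break
                    k -= 1
                    continue
                s = np.inf
            else:
                s = (
                    (values[i] - values[j]) / denom
                    + (src[i] + src[j]) / 2.0
                )
            if s <= z[k]:
                k -= 1
                continue
            k += 1
            v_idx[k] = i
            z[k], z[k + 1] = s, np.inf
            break
    out = np.empty(len(tgt))
    k = 0
    for j, x in enumerate(tgt):
        while z[k + 1] < x:
            k += 1
        i = v_idx[k]
        out[j] = values[i] + a * (x - src[i]) ** 2
    return out


def _message_grid(vec, dbar_p, dbar_q, side, a):
    """min_{l_p} vec(l_p) + a ||(dbar_p + th) - (dbar_q + th')||^2 via two
    separable 1D distance transforms on the offset grid."""
    m = (side - 1) // 2
    axis = np.arange(-m, m + 1, dtype=float)
    v = vec.reshape(side, side)
    tmp = np.empty((side, side))
    src_x = axis + dbar_p[1]
    tgt_x = axis + dbar_q[1]
    for r in range(side):
        tmp[r] = _dt1d(v[r], src_x, tgt_x, a)
    out = np.empty((side, side))
    src_y = axis + dbar_p[0]
    tgt_y = axis + dbar_q[0]
    for ccol in range(side):
        out[:, ccol] = _dt1d(tmp[:, ccol], src_y, tgt_y, a)
    return out.ravel()


def _message_dense(vec, disp_p, disp_q, a):
    d2 = np.sum(
        (disp_p[:, None, :].astype(float) - disp_q[None, :, :].astype(float)) ** 2,
        axis=2,
    )
    return np.min(vec[:, None] + a * d2, axis=0)


def solve_level(problem: LevelProblem, *, max_sweeps: int = 50,
                energy_tol: float = 1e-6) -> tuple[np.ndarray, dict]:
    """Label every node of one level.

    Free and fixed nodes are minimized independently; coherent nodes are
    solved jointly over the tension edges with sequential tree-reweighted
    message passing plus ICM polishing. The returned labeling's energy is
    guaranteed not to exceed the zero-offset labeling's.
    """
    n = len(problem.unary)
    labels = np.zeros(n, dtype=int)
    zero = (
        problem.zero_label
        if problem.zero_label is not None
        else np.array(
            [len(problem.disp[p]) // 2 for p in range(n)], dtype=int
        )
    )

    for p in range(n):
        cls = problem.classes[p]
        if cls == FIXED:
            labels[p] = zero[p]
        elif cls in (FREE, CONTOUR):
            labels[p] = int(np.argmin(problem.unary[p]))

    coherent = np.flatnonzero(problem.classes == COHERENT)
    in_edges = {p: [] for p in coherent}
    adj = {p: [] for p in coherent}
    for p, q in problem.edges:
        adj[p].append(q)
        adj[q].append(p)
    # isolated coherent nodes: independent
    for p in coherent:
        if not adj[p]:
            labels[p] = int(np.argmin(problem.unary[p]))
    linked = [p for p in coherent if adj[p]]

    info = {"sweeps": 0, "converged": True}
    if linked:
        labels = _trws(problem, labels, linked, adj, max_sweeps, energy_tol, info)

    labels = _icm(problem, labels, linked, adj)
    zero_energy = problem.energy(zero)
    if problem.energy(labels) > zero_energy:
        # fall back to the zero labeling and polish from there
        labels = _icm(problem, zero.copy(), linked, adj)
    info["energy"] = problem.energy(labels)
    info["zero_energy"] = zero_energy
    return labels, info


def _pair_message(problem: LevelProblem, vec, p, q):
    if problem.grid_labels:
        dbar_p = problem.disp[p][0] + (problem.grid_side - 1) // 2
        # recover dbar: first label is dbar + (-m, -m)
        m = (problem.grid_side - 1) // 2
        dp0 = problem.disp[p][0] + m
        dq0 = problem.disp[q][0] + m
        return _message_grid(vec, dp0, dq0, problem.grid_side, problem.pair_scale)
    return _message_dense(vec, problem.disp[p], problem.disp[q], problem.pair_scale)


def _trws(problem, labels, linked, adj, max_sweeps, energy_tol, info):
    order = {p: i for i, p in enumerate(linked)}
    msgs = {}
    for p in linked:
        for q in adj[p]:
            msgs[(q, p)] = np.zeros(len(problem.unary[p]))
    gamma = {
        p: 1.0
        / max(
            sum(1 for q in adj[p] if order.get(q, -1) > order[p]),
            sum(1 for q in adj[p] if order.get(q, -1) < order[p]),
            1,
        )
        for p in linked
    }

    best_labels = labels.copy()
    best_energy = np.inf
    stall = 0
    for sweep in range(max_sweeps):
        for seq in (linked, linked[::-1]):
            forward = seq is linked
            for p in seq:
                that = problem.unary[p] + sum(msgs[(q, p)] for q in adj[p])
                for q in adj[p]:
                    later = order.get(q, -1) > order[p]
                    if later != forward:
                        continue
                    vec = gamma[p] * that - msgs[(q, p)]
                    msg = _pair_message(problem, vec, p, q)
                    msgs[(p, q)] = msg - msg.min()
        cand = labels.copy()
        for p in linked:
            belief = problem.unary[p] + sum(msgs[(q, p)] for q in adj[p])
            cand[p] = int(np.argmin(belief))
        e = problem.energy(cand)
        if e < best_energy - energy_tol:
            best_energy = e
            best_labels = cand.copy()
            stall = 0
        else:
            stall += 1
        info["sweeps"] = sweep + 1
        if stall >= 2:
            break
    else:
        info["converged"] = False
        log.warning("TRW-S hit the sweep cap; returning best labeling found")
    return best_labels


def _icm(problem, labels, linked, adj, max_iters: int = 10):
    labels = labels.copy()
    for _ in range(max_iters):
        changed = False
        for p in linked:
            cost = problem.unary[p].copy()
            for q in adj[p]:
                dq = problem.disp[q][labels[q]].astype(float)
                d2 = np.sum((problem.disp[p].astype(float) - dq) ** 2, axis=1)
                cost = cost + problem.pair_scale * d2
            new = int(np.argmin(cost))
            if new != labels[p]:
                labels[p] = new
                changed = True
        if not changed:
            break
    return labels


# ---------------------------------------------------------------------------
# dense fields
# ---------------------------------------------------------------------------

@dataclass
class WarpField:
    """Dense backward displacement: target pixel x samples source x + D(x)."""

    dy: np.ndarray
    dx: np.ndarray
    level_info: list = field(default_factory=list)

    @property
    def shape(self) -> tuple[int, int]:
        return self.dy.shape

    def magnitude(self) -> np.ndarray:
        return np.hypot(self.dy, self.dx)


def dense_field_from_nodes(
    grid: ControlGrid, node_disp: np.ndarray, shape
) -> tuple[np.ndarray, np.ndarray]:
    """Bilinear interpolation of node displacements to a dense field."""
    ny, nx = grid.grid_shape
    s = grid.spacing
    dyn = node_disp[:, 0].reshape(ny, nx).astype(float)
    dxn = node_disp[:, 1].reshape(ny, nx).astype(float)
    h, w = shape
    yy, xx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    coords = np.vstack(
        [np.clip(yy.ravel() / s, 0, ny - 1), np.clip(xx.ravel() / s, 0, nx - 1)]
    )
    dy = ndimage.map_coordinates(dyn, coords, order=1, mode="nearest").reshape(h, w)
    dx = ndimage.map_coordinates(dxn, coords, order=1, mode="nearest").reshape(h, w)
    return dy, dx


def invert_warp(warp: WarpField, n_iters: int = 20, damping: float = 0.5) -> WarpField:
    """Damped fixed-point inverse of a backward field.

    Solves ``D_inv(x) = -D(x + D_inv(x))``; the under-relaxation keeps
    the iteration stable where the map's Jacobian strays from identity
    (e.g. under a strong local thin-plate correction)."""
    h, w = warp.shape
    yy, xx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    dyi = -warp.dy.copy()
    dxi = -warp.dx.copy()
    for _ in range(n_iters):
        sy = yy + dyi
        sx = xx + dxi
        ty = -ndimage.map_coordinates(warp.dy, [sy, sx], order=1, mode="nearest")
        tx = -ndimage.map_coordinates(warp.dx, [sy, sx], order=1, mode="nearest")
        dyi = (1 - damping) * dyi + damping * ty
        dxi = (1 - damping) * dxi + damping * tx
    return WarpField(dy=dyi, dx=dxi)


def apply_warp(image: np.ndarray, warp: WarpField) -> np.ndarray:
    """Backward-mapped bilinear resampling: out(x) = image(x + D(x))."""
    if not warp.dy.any() and not warp.dx.any():
        return image.copy()
    h, w = warp.shape
    yy, xx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    out = ndimage.map_coordinates(
        np.asarray(image, dtype=float),
        [yy + warp.dy, xx + warp.dx],
        order=1,
        mode="constant",
        cval=0.0,
    )
    return out


# ---------------------------------------------------------------------------
# full registration of one slice
# ---------------------------------------------------------------------------

def _resize_level(image: np.ndarray, factor: int, *, binary=False) -> np.ndarray:
    if factor == 1:
        return np.asarray(image, dtype=float if not binary else bool).copy()
    if binary:
        out = rescale(
            np.asarray(image, dtype=float), 1.0 / factor, order=0,
            anti_aliasing=False, preserve_range=True,
        )
        return out > 0.5
    return rescale(
        np.asarray(image, dtype=float), 1.0 / factor,
        anti_aliasing=True, preserve_range=True,
    )


def _contour_pixels(mask: np.ndarray) -> np.ndarray:
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        return np.zeros_like(m)
    return m & ~ndimage.binary_erosion(m)


def register_pair(
    g: np.ndarray,
    f: np.ndarray,
    r_c: np.ndarray,
    r_e: np.ndarray,
    m_g: np.ndarray | None = None,
    m_f: np.ndarray | None = None,
    prev_warped: np.ndarray | None = None,
    structure_points: tuple[np.ndarray, np.ndarray] | None = None,
    config: MRFConfig | None = None,
) -> WarpField:
    """Nonrigid registration of target slice ``g`` to source plane ``f``.

    ``g`` must already be globally pre-aligned to ``f``. ``r_c``/``r_e``
    are the tissue and hollow-space masks from the annotation plane;
    ``m_g``/``m_f`` optional tissue masks enabling the contour unary;
    ``prev_warped`` the previous slice resampled through its own final
    warp (drives the slice-consistency term); ``structure_points`` a pair
    ``(u, v)`` of corresponding structure contour points in full-res
    (row, col) coordinates.

    Returns the dense backward :class:`WarpField` with per-level energy
    diagnostics attached.
    """
    config = config or MRFConfig()
    g = np.asarray(g, dtype=float)
    f = np.asarray(f, dtype=float)
    gmax = max(float(g.max()), 1e-12)
    fmax = max(float(f.max()), 1e-12)
    g, f = g / gmax, f / fmax

    c_atlas, c_prev = config.c_atlas, config.c_prev
    if prev_warped is None:
        # first slice of a stack: fold the consistency weight into the
        # atlas term so total unary weight is unchanged
        c_atlas, c_prev = c_atlas + c_prev, 0.0
    else:
        prev_warped = np.asarray(prev_warped, dtype=float)
        prev_warped = prev_warped / max(float(prev_warped.max()), 1e-12)

    spacing = config.grid_spacing_px
    prev_grid: ControlGrid | None = None
    prev_cum: np.ndarray | None = None
    level_info = []

    for factor in config.level_downsamples:
        g_t = _resize_level(g, factor)
        f_t = _resize_level(f, factor)
        rc_t = _resize_level(r_c, factor, binary=True)
        re_t = _resize_level(r_e, factor, binary=True) & ~rc_t
        grid = ControlGrid.cover(g_t.shape, spacing)
        dbar, offsets = build_label_set(
            grid, prev_grid, prev_cum, config.max_disp_px
        )
        classes = classify_nodes(grid, rc_t, re_t)

        mg_t = _resize_level(m_g, factor, binary=True) if m_g is not None else None
        mf_t = _resize_level(m_f, factor, binary=True) if m_f is not None else None
        if mg_t is not None and mf_t is not None:
            c_e = _contour_pixels(mg_t)
            s = spacing
            for p in range(len(grid.positions)):
                if classes[p] == FIXED:
                    continue
                py, px = grid.positions[p]
                y0, y1 = max(0, py - s), min(g_t.shape[0], py + s + 1)
                x0, x1 = max(0, px - s), min(g_t.shape[1], px + s + 1)
                if y1 > y0 and x1 > x0 and c_e[y0:y1, x0:x1].any():
                    classes[p] = CONTOUR

        edges = tension_edges(grid, rc_t, classes)

        # 2x spacing: one for the patch half-width, one for grid nodes
        # overhanging the image border
        pad = (
            2 * spacing
            + config.max_disp_px
            + int(np.abs(dbar).max(initial=0))
            + config.hog.cell_size_px
            + 2
        )
        hog_nodes = classes != FIXED
        if mg_t is not None and mf_t is not None:
            hog_nodes = hog_nodes & (classes != CONTOUR)
        scorer = _PatchHOGScorer(g_t, f_t, spacing, config.hog, pad)
        v_atlas = _hog_unary(scorer, grid, dbar, offsets, hog_nodes)
        applies_atlas = hog_nodes.copy()

        if mg_t is not None and mf_t is not None:
            contour_nodes = classes == CONTOUR
            v_contour = _contour_unary(mg_t, mf_t, grid, dbar, offsets,
                                       contour_nodes)
            v_atlas = v_atlas + v_contour
            applies_atlas = applies_atlas | contour_nodes

        if c_prev > 0:
            p_t = _resize_level(prev_warped, factor)
            scorer_prev = _PatchHOGScorer(g_t, p_t, spacing, config.hog, pad)
            v_prev = _hog_unary(scorer_prev, grid, dbar, offsets,
                                classes != FIXED)
        else:
            v_prev = np.zeros_like(v_atlas)

        if structure_points is not None:
            u_pts = np.asarray(structure_points[0], dtype=float) / factor
            v_pts = np.asarray(structure_points[1], dtype=float) / factor
            v_struct, applies_struct = _structure_unary(
                u_pts, v_pts, grid, dbar, offsets
            )
        else:
            v_struct = np.zeros_like(v_atlas)
            applies_struct = np.zeros(len(grid.positions), dtype=bool)

        mask_rows = np.broadcast_to(
            applies_atlas[:, None], v_atlas.shape
        )
        unary = (
            c_atlas * _minmax_normalize(v_atlas, mask_rows)
            + c_prev * _minmax_normalize(
                v_prev, np.broadcast_to((classes != FIXED)[:, None], v_prev.shape)
            )
            + config.c_struct * _minmax_normalize(
                v_struct, np.broadcast_to(applies_struct[:, None], v_struct.shape)
            )
        )

        # pairwise normalization: joint min-max over all edge/label pairs,
        # computed in closed form from the offset-grid extremes
        mn, mx = _pairwise_extremes(dbar, edges, config.max_disp_px)
        if mx - mn < 1e-12:
            pair_scale, pair_offset = 0.0, 0.0
        else:
            pair_scale = config.c_pair / (mx - mn)
            pair_offset = -config.c_pair * mn / (mx - mn)

        disp = [dbar[p] + offsets for p in range(len(grid.positions))]
        zero_idx = len(offsets) // 2
        problem = LevelProblem(
            unary=[unary[p] for p in range(len(grid.positions))],
            disp=disp,
            classes=classes,
            edges=edges,
            pair_scale=pair_scale,
            pair_offset=pair_offset,
            zero_label=np.full(len(grid.positions), zero_idx, dtype=int),
            grid_labels=True,
            grid_side=2 * config.max_disp_px + 1,
        )
        labels, info = solve_level(
            problem, max_sweeps=config.max_sweeps, energy_tol=config.energy_tol
        )
        cum = np.array([disp[p][labels[p]] for p in range(len(labels))])
        # fixed nodes stay put entirely
        cum[classes == FIXED] = 0
        info.update({"factor": factor, "n_nodes": len(labels),
                     "n_edges": len(edges)})
        level_info.append(info)
        prev_grid, prev_cum = grid, cum

    dy, dx = dense_field_from_nodes(prev_grid, prev_cum, g.shape)
    return WarpField(dy=dy, dx=dx, level_info=level_info)


def _pairwise_extremes(dbar, edges, m):
    """Closed-form min/max of ||d_p - d_q||^2 over the offset grid."""
    if not edges:
        return 0.0, 0.0
    mn, mx = np.inf, -np.inf
    for p, q in edges:
        delta = dbar[p].astype(float) - dbar[q].astype(float)
        e_mn = e_mx = 0.0
        for comp in delta:
            lo, hi = comp - 2 * m, comp + 2 * m
            e_mx += max(lo**2, hi**2)
            if lo <= 0 <= hi:
                e_mn += 0.0
            else:
                e_mn += min(lo**2, hi**2)
        mn, mx = min(mn, e_mn), max(mx, e_mx)
    return mn, mx
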