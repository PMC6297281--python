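import itertools

import numpy as np
import pytest
from scipy import ndimage

from sliceatlas.mrf import (
    COHERENT,
    CONTOUR,
    FIXED,
    FREE,
    ControlGrid,
    LevelProblem,
    MRFConfig,
    WarpField,
    apply_warp,
    build_label_set,
    classify_nodes,
    dense_field_from_nodes,
    invert_warp,
    register_pair,
    solve_level,
    tension_edges,
    theta_grid,
)
from sliceatlas.phantom import DeformParams, _random_nonrigid


def _grid_2x2():
    g = ControlGrid.cover((17, 17), 16)
    assert g.grid_shape == (2, 2)
    return g


class TestLabelSets:
    def test_theta_grid_cardinality_is_17x17(self):
        offsets = theta_grid(8)
        assert len(offsets) == 289
        assert offsets.min() == -8 and offsets.max() == 8

    def test_first_level_base_displacements_are_zero(self):
        grid = _grid_2x2()
        dbar, offsets = build_label_set(grid, None, None, 8)
        assert np.all(dbar == 0)
        assert len(offsets) == 289

    def test_carried_motion_doubles_with_resolution(self):
        coarse = ControlGrid.cover((17, 17), 16)
        motion = np.zeros((4, 2), dtype=int)
        motion[:, 0] = 4  # every coarse node moved (4, 0)
        fine = ControlGrid.cover((33, 33), 16)
        dbar, _ = build_label_set(fine, coarse, motion, 8)
        assert np.all(dbar[:, 0] == 8)
        assert np.all(dbar[:, 1] == 0)


class TestNodeClasses:
    def test_classification_cases(self):
        r_c = np.zeros((33, 33), bool)
        r_c[:, :20] = True  # tissue on the left
        r_e = ~r_c
        grid = ControlGrid.cover((33, 33), 16)
        classes = classify_nodes(grid, r_c, r_e)
        # node at col 0/16 in tissue; col 32 in empty space with support
        # reaching tissue pixels at col < 20 -> free
        by_pos = {tuple(p): c for p, c in zip(map(tuple, grid.positions), classes)}
        assert by_pos[(16, 0)] == COHERENT
        assert by_pos[(16, 16)] == COHERENT
        assert by_pos[(16, 32)] == FREE

    def test_isolated_background_node_is_fixed(self):
        r_c = np.zeros((65, 65), bool)
        r_c[:20, :20] = True
        r_e = ~r_c
        grid = ControlGrid.cover((65, 65), 16)
        classes = classify_nodes(grid, r_c, r_e)
        by_pos = {tuple(p): c for p, c in zip(map(tuple, grid.positions), classes)}
        assert by_pos[(64, 64)] == FIXED

    def test_overlapping_masks_rejected(self):
        ones = np.ones((33, 33), bool)
        with pytest.raises(ValueError, match="overlap"):
            classify_nodes(_grid_2x2(), ones, ones)


class TestTensionEdges:
    def test_edge_present_in_solid_tissue(self):
        r_c = np.ones((17, 17), bool)
        grid = _grid_2x2()
        classes = classify_nodes(grid, r_c, ~r_c)
        edges = tension_edges(grid, r_c, classes)
        assert len(edges) == 4  # full 2x2 lattice

    def test_hollow_crossing_removes_edge(self):
        r_c = np.ones((17, 17), bool)
        r_c[:, 8] = False  # vertical cavity between left and right nodes
        r_e = ~r_c
        grid = _grid_2x2()
        classes = classify_nodes(grid, r_c, r_e)
        edges = tension_edges(grid, r_c, classes)
        ny, nx = grid.grid_shape
        horizontal = [(p, q) for p, q in edges if q == p + 1]
        assert not horizontal
        vertical = [(p, q) for p, q in edges if q == p + nx]
        assert len(vertical) == 2

    def test_free_coherent_pairs_carry_no_edge(self):
        r_c = np.zeros((17, 33), bool)
        r_c[:, :10] = True
        grid = ControlGrid.cover((17, 33), 16)
        classes = classify_nodes(grid, r_c, ~r_c)
        edges = tension_edges(grid, r_c, classes)
        for p, q in edges:
            assert classes[p] == COHERENT and classes[q] == COHERENT


def _random_problem(rng, n_labels=5, edges=((0, 1), (1, 2))):
    n_nodes = max(max(e) for e in edges) + 1
    disp = []
    unary = []
    for _ in range(n_nodes):
        d = rng.integers(-4, 5, (n_labels, 2))
        disp.append(d)
        unary.append(rng.uniform(0, 1, n_labels))
    return LevelProblem(
        unary=unary,
        disp=disp,
        classes=np.full(n_nodes, COHERENT),
        edges=list(edges),
        pair_scale=float(rng.uniform(0.01, 0.3)),
        zero_label=np.zeros(n_nodes, dtype=int),
    )


class TestSolveLevel:
    @pytest.mark.parametrize("trial", range(12))
    def test_oracle_equivalence_tiny_instances(self, trial):
        """Chain and 2x2-cycle instances with <= 9 labels match
        exhaustive search."""
        rng = np.random.default_rng(trial)
        edges = [(0, 1), (1, 2)] if trial % 2 else \
            [(0, 1), (2, 3), (0, 2), (1, 3)]
        problem = _random_problem(rng, n_labels=int(rng.integers(3, 10)),
                                  edges=edges)
        labels, info = solve_level(problem)
        n = len(problem.unary)
        best = min(
            problem.energy(np.array(combo))
            for combo in itertools.product(range(len(problem.disp[0])), repeat=n)
        )
        assert info["energy"] == pytest.approx(best, abs=1e-9)

    def test_zero_energy_never_exceeded(self):
        rng = np.random.default_rng(99)
        problem = _random_problem(rng)
        labels, info = solve_level(problem)
        assert info["energy"] <= info["zero_energy"] + 1e-12

    def test_free_nodes_minimize_unary_alone(self):
        rng = np.random.default_rng(3)
        problem = _random_problem(rng)
        problem.classes[:] = FREE
        problem.edges = []
        labels, _ = solve_level(problem)
        for p in range(3):
            assert labels[p] == int(np.argmin(problem.unary[p]))

    def test_rigid_shift_has_zero_tension(self):
        rng = np.random.default_rng(4)
        problem = _random_problem(rng)
        disp = np.array([[3, -2]] * 5)
        problem.disp = [disp.copy() for _ in range(3)]
        e = problem.energy(np.array([0, 2, 4]))
        assert e == pytest.approx(
            sum(problem.unary[p][l] for p, l in zip(range(3), [0, 2, 4]))
        )


class TestTensionCarrying:
    def test_resetting_carried_displacements_changes_the_argmin(self):
        """Two coherent nodes; node q inherited a +6 px stretch from the
        coarser level. With cumulative displacements the spring still
        charges for that stretch and pulls q back; resetting the carried
        motion (the conventional multilevel scheme) hides the stretch
        and the flat unary keeps q in place."""
        offsets = theta_grid(2)  # 5x5 labels for speed
        dbar_q = np.array([0, 6])
        disp_p = [np.array([0, 0]) + offsets]
        disp_q_cum = dbar_q + offsets
        disp_q_reset = offsets.copy()
        zero_idx = len(offsets) // 2
        flat = np.zeros(len(offsets))

        def solve(disp_q):
            problem = LevelProblem(
                unary=[flat.copy(), flat.copy()],
                disp=[disp_p[0], disp_q],
                classes=np.array([COHERENT, COHERENT]),
                edges=[(0, 1)],
                pair_scale=0.05,
                zero_label=np.array([zero_idx, zero_idx]),
            )
            labels, _ = solve_level(problem)
            return labels

        labels_cum = solve(disp_q_cum)
        labels_reset = solve(disp_q_reset)
        d_cum = disp_q_cum[labels_cum[1]]
        d_reset = disp_q_reset[labels_reset[1]]
        # cumulative scheme pulls the stretched node back toward p
        assert abs(int(d_cum[1]) - int(disp_p[0][labels_cum[0]][1])) < 6
        # reset scheme sees no stretch at all: displacement difference 0
        assert int(d_reset[1]) == int(disp_p[0][labels_reset[0]][1])
        assert not np.array_equal(labels_cum, labels_reset)


class TestWarps:
    def test_identity_warp_is_bit_exact_for_integer_data(self):
        img = np.arange(64, dtype=np.int64).reshape(8, 8)
        w = WarpField(dy=np.zeros((8, 8)), dx=np.zeros((8, 8)))
        out = apply_warp(img, w)
        np.testing.assert_array_equal(out, img)

    def test_constant_shift_translates(self):
        img = np.zeros((16, 16))
        img[8, 8] = 1.0
        w = WarpField(dy=np.zeros((16, 16)), dx=np.full((16, 16), 3.0))
        out = apply_warp(img, w)
        assert out[8, 5] == pytest.approx(1.0)

    def test_warp_then_inverse_recovers_smooth_image(self, mid_plane):
        plane, _, _ = mid_plane
        plane = ndimage.gaussian_filter(plane, 2.0)
        dy, dx = _random_nonrigid(
            np.random.default_rng(0), plane.shape,
            DeformParams(max_nonrigid_px=5.0, nonrigid_grid_px=48),
        )
        w = WarpField(dy=dy, dx=dx)
        winv = invert_warp(w)
        out = apply_warp(apply_warp(plane, w), winv)
        interior = np.zeros(plane.shape, bool)
        interior[12:-12, 12:-12] = True
        rms = np.sqrt(np.mean((out - plane)[interior] ** 2)) / plane.max()
        assert rms < 0.02

    def test_dense_field_is_identity_for_zero_nodes(self):
        grid = ControlGrid.cover((33, 33), 16)
        dy, dx = dense_field_from_nodes(grid, np.zeros((9, 2)), (33, 33))
        assert not dy.any() and not dx.any()


class TestRegisterPair:
    def test_identity_pair_gives_near_zero_warp(self, mid_plane):
        plane, r_c, r_e = mid_plane
        w = register_pair(plane, plane, r_c, r_e, config=MRFConfig())
        assert float(w.magnitude().mean()) < 1.0

    def test_known_warp_recovered(self, mid_plane):
        plane, r_c, r_e = mid_plane
        dy, dx = _random_nonrigid(
            np.random.default_rng(1), plane.shape, DeformParams()
        )
        yy, xx = np.mgrid[0 : plane.shape[0], 0 : plane.shape[1]]
        g = ndimage.map_coordinates(plane, [yy + dy, xx + dx], order=1)
        w = register_pair(g, plane, r_c, r_e, config=MRFConfig())
        mask = plane > 0.05
        rms = np.sqrt(np.mean((w.dy - dy)[mask] ** 2 + (w.dx - dx)[mask] ** 2))
        assert rms < 2.0

    def test_energy_never_exceeds_zero_labeling(self, mid_plane):
        plane, r_c, r_e = mid_plane
        dy, dx = _random_nonrigid(
            np.random.default_rng(2), plane.shape, DeformParams()
        )
        yy, xx = np.mgrid[0 : plane.shape[0], 0 : plane.shape[1]]
        g = ndimage.map_coordinates(plane, [yy + dy, xx + dx], order=1)
        w = register_pair(g, plane, r_c, r_e, config=MRFConfig())
        for info in w.level_info:
            assert info["energy"] <= info["zero_energy"] + 1e-9

    def test_default_coefficients(self):
        cfg = MRFConfig()
        assert (cfg.c_atlas, cfg.c_prev, cfg.c_struct, cfg.c_pair) == (3, 1, 1, 5)
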