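import numpy as np
import pytest

from sliceatlas.core_data import Rotation, rotate_and_reslice
from sliceatlas.localization import (
    DPConfig,
    NoAdmissibleMappingError,
    build_cost_matrix,
    dp_map,
    half_index_difference,
    interpolate_mapping,
)
from sliceatlas.similarity import HOGConfig


def brute_force_dp(rho, A, s_E, s_A, theta):
    """Exhaustive enumeration over admissible monotone mappings.

    Recursive depth-first enumeration: every mapping whose consecutive
    index steps satisfy the spacing bound is visited (branches whose
    partial cost already exceeds the incumbent are cut, which cannot
    change the optimum).
    """
    rho = np.asarray(rho, dtype=float)
    n, m = rho.shape
    deltas = [s_E * (A[i] - A[i - 1]) / s_A for i in range(1, n)]
    best = {"cost": np.inf, "map": None}

    def recurse(i, prev_j, cost, path):
        if cost >= best["cost"]:
            return
        if i == n:
            best["cost"] = cost
            best["map"] = tuple(path)
            return
        for j in range(m):
            if i > 0:
                if not abs((j - prev_j) / deltas[i - 1] - 1.0) < theta:
                    continue
            recurse(i + 1, j, cost + rho[i, j], path + [j])

    recurse(0, -1, 0.0, [])
    return best["map"], best["cost"]


class TestDPMap:
    def test_two_slice_example(self):
        rho = np.array([[0, 9, 9, 9, 9, 9], [9, 9, 0, 9, 9, 9]], dtype=float)
        # s_E * dA = 2 * s_A: ideal step of two planes
        mapping, cost = dp_map(rho, [0, 1], s_E=50.0, s_A=25.0, theta=0.3)
        assert list(mapping) == [0, 2]
        assert cost == 0.0

    def test_uniform_costs_degenerate_case(self):
        c = 0.7
        rho = np.full((3, 12), c)
        mapping, cost = dp_map(rho, [0, 1, 2], s_E=50.0, s_A=25.0, theta=0.9)
        assert cost == pytest.approx(3 * c)
        assert all(np.diff(mapping) > 0)

    @pytest.mark.parametrize("trial", range(20))
    def test_oracle_equivalence_random_instances(self, trial):
        rng = np.random.default_rng(100 + trial)
        n = int(rng.integers(2, 5))
        m = int(rng.integers(8, 16))
        A = np.sort(rng.choice(np.arange(12), size=n, replace=False))
        rho = rng.uniform(0, 1, (n, m))
        theta = 0.5
        try:
            mapping, cost = dp_map(rho, A, 50.0, 25.0, theta)
        except NoAdmissibleMappingError:
            bm, _ = brute_force_dp(rho, A, 50.0, 25.0, theta)
            assert bm is None
            return
        _, bcost = brute_force_dp(rho, A, 50.0, 25.0, theta)
        assert cost == pytest.approx(bcost)

    def test_strictly_increasing_mapping(self):
        rng = np.random.default_rng(7)
        rho = rng.uniform(size=(5, 30))
        mapping, _ = dp_map(rho, np.arange(5), 50.0, 25.0, theta=0.5)
        assert (np.diff(mapping) > 0).all()

    def test_impossible_spacing_reports_transition(self):
        rho = np.ones((3, 4))
        with pytest.raises(NoAdmissibleMappingError, match="slice"):
            # ideal step of 40 planes cannot fit into 4
            dp_map(rho, [0, 10, 20], s_E=100.0, s_A=25.0, theta=0.2)


class TestInterpolateMapping:
    def test_midpoint(self):
        full = interpolate_mapping([10, 14], [0, 2], 3)
        assert full[1] == pytest.approx(12.0)

    def test_extrapolation_uses_end_slope(self):
        full = interpolate_mapping([10, 14], [0, 2], 4)
        assert full[3] == pytest.approx(16.0)

    def test_all_slices_selected_is_identity(self):
        sel = [3, 7, 9]
        full = interpolate_mapping(sel, [0, 1, 2], 3)
        np.testing.assert_allclose(full, sel)


class TestCostMatrix:
    def test_identity_stack_maps_to_self(self, atlas_volume):
        """Slices that ARE atlas planes match their own plane index."""
        from sliceatlas.core_data import SliceStack

        atlas = rotate_and_reslice(atlas_volume, Rotation(0.0, 0.0))
        picks = list(range(10, 50, 4))
        stack = SliceStack(
            images=[atlas.slices[j] for j in picks],
            spacing_um=4 * atlas.spacing_um,
            pixel_size_um=atlas.spacing_um,
            selected=list(range(len(picks))),
        )
        costs = build_cost_matrix(stack, atlas, "full", HOGConfig(cell_size_px=8))
        mapping, _ = dp_map(
            costs, stack.selected, stack.spacing_um, atlas.spacing_um, 0.5
        )
        errors = np.abs(np.asarray(mapping) - np.asarray(picks))
        assert errors.max() <= 1

    def test_constant_images_give_zero_costs(self):
        from sliceatlas.core_data import ReslicedAtlas, SliceStack

        const = [np.full((48, 48), 0.5) for _ in range(4)]
        atlas = ReslicedAtlas(
            slices=const, rotation=Rotation(0, 0), spacing_um=25.0,
            kept_indices=list(range(4)), support=[1.0] * 4,
        )
        stack = SliceStack(images=const[:2], spacing_um=25.0,
                           pixel_size_um=25.0, selected=[0, 1])
        costs = build_cost_matrix(stack, atlas, "full", HOGConfig(cell_size_px=8))
        # constant images have no contours: every pair is flagged
        # unmatchable rather than spuriously zero-cost
        assert np.all(costs.rho >= 0)

    def test_empty_atlas_rejected(self, tilted_stack):
        from sliceatlas.localization import _pair_costs

        stack, _ = tilted_stack
        with pytest.raises(Exception):
            _pair_costs(stack, None, [None], HOGConfig())


class TestHalfIndexDifference:
    def test_untilted_phantom_has_near_zero_difference(
        self, atlas_pair
    ):
        from sliceatlas import phantom as ph

        volume, annotation = atlas_pair
        stack, _ = ph.make_sectioned_stack(
            volume, annotation, 0.0, 0.0, seed=3,
            deform=ph.DeformParams(max_rotation_deg=0.0,
                                   max_translation_px=0.0,
                                   max_nonrigid_px=0.0,
                                   contrast_range=(1.0, 1.0)),
        )
        atlas = rotate_and_reslice(volume, Rotation(0.0, 0.0))
        d = half_index_difference(stack, atlas, "vertical",
                                  DPConfig(), HOGConfig(cell_size_px=8))
        assert abs(d) <= 0.5

    def test_tilt_sign_and_monotonicity(self, atlas_volume, tilted_stack):
        """A +4 deg tilt against the unrotated atlas drives D away from
        zero in the direction that calls for a more positive rotation;
        pre-rotating the atlas by the true angle shrinks |D|."""
        stack, _ = tilted_stack
        cfg, hog = DPConfig(), HOGConfig(cell_size_px=8)
        atlas0 = rotate_and_reslice(atlas_volume, Rotation(0.0, 0.0))
        d0 = half_index_difference(stack, atlas0, "vertical", cfg, hog)
        # under this package's axis conventions the needed rotation sign
        # is -sign(D): a positive true tilt gives a negative D
        assert d0 < 0
        atlas4 = rotate_and_reslice(atlas_volume, Rotation(0.0, 4.0))
        d4 = half_index_difference(stack, atlas4, "vertical", cfg, hog)
        assert abs(d4) < abs(d0)
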