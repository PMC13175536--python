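import math

import numpy as np
import pytest

from clonekit.distances import pairwise_matrix
from clonekit.mll import assign_mlls_table
from clonekit.spatial import (
    EMPTY,
    OccupancyGrid,
    build_grid,
    cohesion_index,
    iji_index,
    permutation_null,
)

from conftest import make_table


def brute_cohesion(cells, mll, z):
    """Independent implementation of the cohesion formula by explicit
    component enumeration (flood fill)."""
    mask = cells == mll
    seen = np.zeros_like(mask)
    comps = []
    for x in range(mask.shape[0]):
        for y in range(mask.shape[1]):
            if mask[x, y] and not seen[x, y]:
                stack, comp = [(x, y)], []
                seen[x, y] = True
                while stack:
                    cx, cy = stack.pop()
                    comp.append((cx, cy))
                    for dx, dy in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                        nx, ny = cx + dx, cy + dy
                        if (
                            0 <= nx < mask.shape[0]
                            and 0 <= ny < mask.shape[1]
                            and mask[nx, ny]
                            and not seen[nx, ny]
                        ):
                            seen[nx, ny] = True
                            stack.append((nx, ny))
                comps.append(comp)
    num = den = 0.0
    for comp in comps:
        a = len(comp)
        p = 0
        s = set(comp)
        for cx, cy in comp:
            for dx, dy in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                if (cx + dx, cy + dy) not in s:
                    p += 1
        num += p
        den += p * math.sqrt(a)
    if z <= 1:
        return 0.0
    return (1 - num / den) / (1 - 1 / math.sqrt(z)) * 100


class TestBuildGrid:
    def test_single_stem(self):
        from clonekit.mll import MLLPartition

        t = make_table([[(10, 10)]], coords=[(2, 3)])
        part = MLLPartition(
            labels=np.array([0]), threshold=0, ids=t.sample_id, patch_id=t.patch_id
        )
        g = build_grid(part, t, "A")
        assert g.cells.shape == (1, 1) and g.cells[0, 0] == 0

    def test_full_patch_occupied(self):
        coords = [(x, y) for x in range(1, 6) for y in range(1, 11)]
        rows = [[(10, 10)]] * 50
        t = make_table(rows, coords=coords)
        part = assign_mlls_table(t, pairwise_matrix(t, "stepwise"), 0)
        g = build_grid(part, t, "A")
        assert (g.cells >= 0).sum() == 50

    def test_grid_round_trips_simulated_coordinates(self, field_sim, field_partition):
        table, _, _ = field_sim
        _, _, part = field_partition
        patch = table.patches()[0]
        g = build_grid(part, table, patch)
        n_patch = int((table.patch_id == patch).sum())
        assert (g.cells >= 0).sum() == n_patch


class TestCohesion:
    def test_single_cell_is_zero(self):
        cells = np.full((5, 10), EMPTY)
        cells[2, 2] = 1
        assert cohesion_index(OccupancyGrid("p", cells), 1) == 0.0

    def test_full_grid_is_hundred(self):
        cells = np.zeros((5, 10), dtype=int)
        assert cohesion_index(OccupancyGrid("p", cells), 0) == pytest.approx(100.0)

    def test_two_by_two_block_hand_value(self):
        cells = np.full((5, 10), EMPTY)
        cells[1:3, 1:3] = 4
        val = cohesion_index(OccupancyGrid("p", cells), 4)
        expect = (1 - 8 / 16) / (1 - 1 / math.sqrt(50)) * 100
        assert val == pytest.approx(expect, abs=1e-9)

    def test_scattered_singletons_zero(self):
        cells = np.full((5, 10), EMPTY)
        cells[0, 0] = cells[2, 4] = cells[4, 9] = 3
        assert cohesion_index(OccupancyGrid("p", cells), 3) == 0.0

    def test_translation_and_rotation_invariance(self):
        rng = np.random.default_rng(0)
        cells = np.full((6, 8), EMPTY)
        pts = rng.choice(24, size=8, replace=False)
        cells[pts // 6 + 1, pts % 6 + 1] = 1
        g = OccupancyGrid("p", cells)
        shifted = OccupancyGrid("p", np.roll(cells, (0, 0), axis=(0, 1)))
        rotated = OccupancyGrid("p", np.rot90(cells).copy())
        assert cohesion_index(g, 1) == pytest.approx(cohesion_index(shifted, 1))
        assert cohesion_index(g, 1) == pytest.approx(cohesion_index(rotated, 1))

    def test_matches_brute_force_on_enumerated_grids(self):
        rng = np.random.default_rng(7)
        for _ in range(40):
            cells = np.full((3, 3), EMPTY)
            k = rng.integers(1, 9)
            idx = rng.choice(9, size=k, replace=False)
            cells[idx // 3, idx % 3] = 1
            g = OccupancyGrid("p", cells)
            assert cohesion_index(g, 1) == pytest.approx(
                brute_cohesion(cells, 1, g.n_in_grid), abs=1e-9
            )

    def test_adjacency_increases_cohesion(self):
        # two diagonal ramets moved to be 4-adjacent never lose cohesion
        diag = np.full((3, 3), EMPTY)
        diag[0, 0] = diag[1, 1] = 1
        adj = np.full((3, 3), EMPTY)
        adj[0, 0] = adj[0, 1] = 1
        c_diag = cohesion_index(OccupancyGrid("p", diag), 1)
        c_adj = cohesion_index(OccupancyGrid("p", adj), 1)
        assert c_adj >= c_diag
        assert c_diag == 0.0


class TestIji:
    def test_two_classes_undefined(self):
        cells = np.full((5, 10), EMPTY)
        cells[0, :] = 1
        assert math.isnan(iji_index(OccupancyGrid("p", cells), 1))

    def test_single_neighbour_class_zero(self):
        cells = np.array([[1, 2, 3], [2, 2, 3], [3, 3, 3]])
        # focal 1 touches only class 2 (m = 3 classes present)
        assert iji_index(OccupancyGrid("p", cells), 1) == pytest.approx(0.0)

    def test_equal_edges_to_all_other_classes_is_hundred(self):
        cells = np.array([[2, 1, 3], [2, 1, 3], [2, 1, 3]])
        # focal column shares 3 edges with class 2 and 3 with class 3; m = 3
        assert iji_index(OccupancyGrid("p", cells), 1) == pytest.approx(100.0)

    def test_empty_counts_as_class(self):
        cells = np.full((3, 3), EMPTY)
        cells[1, 1] = 1
        cells[0, 1] = 2
        # classes {EMPTY, 1, 2} -> m = 3; focal edges: 1 to class 2, 3 to EMPTY
        val = iji_index(OccupancyGrid("p", cells), 1)
        p = np.array([1 / 4, 3 / 4])
        expect = -(p * np.log(p)).sum() / math.log(2) * 100
        assert val == pytest.approx(expect)

    def test_rotation_invariance(self):
        cells = np.array([[1, 2, 3], [2, 1, 3], [3, 3, EMPTY]])
        a = iji_index(OccupancyGrid("p", cells), 1)
        b = iji_index(OccupancyGrid("p", np.rot90(cells).copy()), 1)
        assert a == pytest.approx(b)


class TestPermutationNull:
    def test_single_mll_degenerate(self):
        cells = np.zeros((2, 3), dtype=int)
        rep = permutation_null(OccupancyGrid("p", cells), n_perm=25, seed=0)
        assert np.allclose(rep.null_cohesion, rep.observed_cohesion[0])

    def test_singleton_mll_cohesion_always_zero(self):
        cells = np.full((4, 4), EMPTY)
        cells[0, 0] = 0
        cells[1, 1] = 1
        cells[2, 2] = 1
        rep = permutation_null(OccupancyGrid("p", cells), n_perm=50, seed=1)
        i = list(rep.mll_ids).index(0)
        assert rep.observed_cohesion[i] == 0.0
        assert np.all(rep.null_cohesion[:, i] == 0.0)

    def test_frequencies_preserved_and_seed_reproducible(self):
        rng = np.random.default_rng(3)
        cells = np.full((5, 8), EMPTY)
        occ = rng.choice(40, size=25, replace=False)
        cells[occ // 8, occ % 8] = rng.integers(0, 5, size=25)
        g = OccupancyGrid("p", cells)
        a = permutation_null(g, n_perm=30, seed=9)
        b = permutation_null(g, n_perm=30, seed=9)
        assert np.array_equal(a.null_cohesion, b.null_cohesion)
        assert np.array_equal(a.ramet_counts, b.ramet_counts)

    def test_quantiles_well_formed(self, field_sim, field_partition):
        table, _, _ = field_sim
        _, _, part = field_partition
        g = build_grid(part, table, table.patches()[0])
        rep = permutation_null(g, n_perm=40, seed=2)
        q = rep.quantiles()
        for v in q.values():
            assert 0 <= v["cohesion_quantile"] <= 1
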