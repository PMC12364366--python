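"""Chemotaxis, excluded-volume movement and recruitment."""

import numpy as np
import pytest

from mff.cells import CellAgent
from mff.motility import (ChemotaxisParams, OccupancyGrid, border_mask,
                          chemotaxis_probabilities, crown_annulus,
                          move_cell, place_recruit,
                          recruit_probability_fibro,
                          recruit_probability_macrophage)
from mff.kinetics import hill


class TestChemotaxisProbabilities:
    def test_uniform_field_gives_zero(self):
        probs = chemotaxis_probabilities(np.full((5, 5), 3.0), (2, 2),
                                         ChemotaxisParams(k=0.5))
        assert np.all(probs == 0.0)

    def test_single_up_gradient_neighbor(self):
        grid = np.zeros((5, 5))
        grid[1, 2] = 1.0  # one unit above the cell at (2, 2)
        probs = chemotaxis_probabilities(grid, (2, 2),
                                         ChemotaxisParams(k=0.02))
        assert probs.sum() == pytest.approx(0.02)
        assert probs.max() == pytest.approx(0.02)

    def test_normalization_when_sum_exceeds_one(self):
        grid = np.zeros((5, 5))
        grid[1, 2] = 1.0
        grid[3, 2] = 1.0
        probs = chemotaxis_probabilities(grid, (2, 2),
                                         ChemotaxisParams(k=2.0))
        assert probs.sum() == pytest.approx(1.0)
        assert sorted(probs[probs > 0]) == pytest.approx([0.5, 0.5])

    def test_down_gradient_never_positive(self, rng):
        grid = rng.random((7, 7)) * 10
        probs = chemotaxis_probabilities(grid, (3, 3),
                                         ChemotaxisParams(k=0.5))
        here = grid[3, 3]
        from mff.fields import NEIGHBOR_OFFSETS
        for j, (dr, dc) in enumerate(NEIGHBOR_OFFSETS):
            if grid[3 + dr, 3 + dc] <= here:
                assert probs[j] == 0.0

    def test_negative_k_rejected(self):
        with pytest.raises(ValueError):
            ChemotaxisParams(k=-1.0)


class TestMoveCell:
    def _make(self, n=5, pos=(2, 2)):
        occ = OccupancyGrid(n)
        cell = CellAgent(7, "macrophage", "M0", pos)
        occ.place(7, pos)
        return cell, occ

    def test_fully_surrounded_cell_never_moves(self, rng):
        cell, occ = self._make()
        for i, (dr, dc) in enumerate([(-1, -1), (-1, 0), (-1, 1), (0, -1),
                                      (0, 1), (1, -1), (1, 0), (1, 1)]):
            occ.place(100 + i, (2 + dr, 2 + dc))
        grid = np.zeros((5, 5))
        grid[1, 2] = 100.0
        for _ in range(50):
            pos, by_chemo = move_cell(cell, grid, occ,
                                      ChemotaxisParams(k=2.0), rng)
            assert pos == (2, 2) and not by_chemo

    def test_zero_k_is_pure_random_walk(self, rng):
        # ensemble mean displacement of a single free walker ~ 0
        disp = []
        for _ in range(500):
            cell, occ = self._make(n=9, pos=(4, 4))
            grid = np.zeros((9, 9))
            for _ in range(10):
                move_cell(cell, grid, occ, ChemotaxisParams(k=0.0), rng)
            disp.append((cell.position[0] - 4, cell.position[1] - 4))
        disp = np.array(disp, dtype=float)
        assert abs(disp.mean(axis=0)).max() < 0.3
        assert not np.any(disp.std(axis=0) == 0)  # it does move

    def test_chemotactic_frequency_matches_probability(self, rng):
        # strong single gradient: observed chemotactic-move frequency
        # within 3 sigma of the computed probability
        grid = np.zeros((5, 5))
        grid[1, 2] = 1.0
        cp = ChemotaxisParams(k=0.3)
        p = chemotaxis_probabilities(grid, (2, 2), cp).sum()
        n_trials, hits = 10_000, 0
        for _ in range(n_trials):
            cell, occ = self._make()
            _, by_chemo = move_cell(cell, grid, occ, cp, rng)
            hits += by_chemo
        se = np.sqrt(p * (1 - p) / n_trials)
        assert abs(hits / n_trials - p) < 3 * se + 1e-9

    def test_inconsistent_occupancy_raises(self, rng):
        cell, occ = self._make()
        occ.grid[2, 2] = -1  # corrupt
        with pytest.raises(ValueError):
            move_cell(cell, np.zeros((5, 5)), occ,
                      ChemotaxisParams(k=0.0), rng)


class TestRecruitProbabilities:
    def test_zero_mediators_zero_probability(self, params):
        assert recruit_probability_macrophage(0.0, 0.0, params) == 0.0
        assert recruit_probability_fibro(0.0, 0.0, params) == 0.0

    def test_fibro_pim_term_matches_table_arithmetic(self, params):
        # local PIM = 30, a = 0.5, k = 30 -> 225/255
        p = recruit_probability_fibro(30.0, 0.0, params)
        assert p == pytest.approx(225 / 255)

    def test_macrophage_total_pim_monotone(self, params):
        ps = [recruit_probability_macrophage(t, 0.0, params)
              for t in (0, 10, 100, 1000, 10000)]
        assert all(b >= a for a, b in zip(ps, ps[1:]))

    def test_complementary_combination(self, params):
        # p = 1 - (1 - h_pim)(1 - h_aim)
        h_p = hill(30.0, a=params.patho_pim_recruit_scale_f, n=2,
                   k=params.recruitment_ff_term)
        h_a = hill(5.0, a=params.aim_recruit_scale_f, n=2,
                   k=params.recruitment_ff_term)
        p = recruit_probability_fibro(30.0, 5.0, params)
        assert p == pytest.approx(1 - (1 - h_p) * (1 - h_a))

    def test_biomaterial_mode_adds_fixed_term(self, params):
        params.recruitment_mm_term = 3.0
        base = recruit_probability_macrophage(0.0, 0.0, params,
                                              "biomaterial", 0.0)
        assert base == 0.0
        # total frozen PIM 20 * 196 saturates the Hill term
        p = recruit_probability_macrophage(0.0, 0.0, params,
                                           "biomaterial", 20.0 * 196)
        assert p == pytest.approx(1.0, abs=1e-4)

    def test_probability_bounded(self, params, rng):
        for _ in range(200):
            p = recruit_probability_fibro(
                rng.exponential(50), rng.exponential(50), params,
                "biomaterial", rng.exponential(50))
            assert 0.0 <= p <= 1.0

    def test_negative_inputs_rejected(self, params):
        with pytest.raises(ValueError):
            recruit_probability_macrophage(-1.0, 0.0, params)


class TestPlacement:
    def test_border_mode_only_boundary_pixels(self, rng):
        occ = OccupancyGrid(40)
        for _ in range(100):
            r, c = place_recruit("border", occ, rng)
            assert r in (0, 39) or c in (0, 39)

    def test_crown_mode_annulus_distance(self, rng):
        occ = OccupancyGrid(40)
        for _ in range(100):
            r, c = place_recruit("crown", occ, rng, stimulus_extent=14)
            cheb = max(abs(r - 19.5), abs(c - 19.5))
            assert 8.0 <= cheb <= 10.0

    def test_uniform_mode_any_empty_pixel(self, rng):
        occ = OccupancyGrid(6)
        seen = {place_recruit("uniform", occ, rng) for _ in range(300)}
        assert len(seen) > 20

    def test_full_region_returns_none(self, rng):
        occ = OccupancyGrid(6)
        occ.grid[:] = 1  # everything occupied
        assert place_recruit("border", occ, rng) is None

    def test_unknown_mode_raises(self, rng):
        with pytest.raises(ValueError):
            place_recruit("ring", OccupancyGrid(6), rng)

    def test_masks_disjoint_regions(self):
        b = border_mask(40)
        cr = crown_annulus(40, 14, margin=1.0, width=2.0)
        assert b.sum() == 4 * 40 - 4
        assert not (b & cr).any()
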