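"""Post-processing: area counting, secretion summaries, ANOVA, power law."""

import numpy as np
import pandas as pd
import pytest

from mff.analysis import (CountingGeometry, anova_bonferroni,
                          count_cells_in_areas, fit_power_law,
                          secretion_summary)
from mff.cells import F0, F1, M0, M1
from mff.engine import TRACE_COLUMNS, init_state, _Rngs
from mff.params import ScenarioConfig


def _state_with_cells(pixels_phen):
    """Minimal simulation state with cells at given (pixel, phen code)."""
    cfg = ScenarioConfig(n_resident_m0=0, duration_h=1.0)
    st = init_state(cfg, _Rngs(0))
    st.xs = np.array([p[0][0] for p in pixels_phen], dtype=np.int64)
    st.ys = np.array([p[0][1] for p in pixels_phen], dtype=np.int64)
    st.phen = np.array([p[1] for p in pixels_phen], dtype=np.int8)
    st.species = np.where(st.phen >= F0, 1, 0).astype(np.int8)
    st.occ = np.full((40, 40), -1, dtype=np.int64)
    st.rebuild_occupancy()
    return st


class TestCountingGeometry:
    def test_twelve_disjoint_areas_off_implant(self):
        geo = CountingGeometry(grid_n=40, implant_extent=14)
        assert len(geo.areas) == 12
        seen = np.zeros((40, 40), dtype=int)
        for _rank, _side, rs, cs in geo.areas:
            seen[rs, cs] += 1
        assert seen.max() == 1           # no overlap
        assert seen.sum() == 12 * 9      # twelve 3x3 squares
        assert not (seen.astype(bool) & geo.implant_mask).any()

    def test_one_cell_per_area_counts_four_per_rank(self):
        geo = CountingGeometry(grid_n=40, implant_extent=14)
        cells = []
        for _rank, _side, rs, cs in geo.areas:
            cells.append(((rs.start, cs.start), M1))
        df = count_cells_in_areas(_state_with_cells(cells), geo)
        assert (df["macrophages"] == 4).all()
        assert (df["fibroblasts"] == 0).all()

    def test_macrophage_count_pools_all_states_fibro_split(self):
        geo = CountingGeometry(grid_n=40, implant_extent=14)
        rank1 = [a for a in geo.areas if a[0] == 1][0]
        rs, cs = rank1[2], rank1[3]
        cells = [((rs.start, cs.start), M0),
                 ((rs.start, cs.start + 1), M1),
                 ((rs.start + 1, cs.start), F1),
                 ((rs.start + 1, cs.start + 1), F0)]
        df = count_cells_in_areas(_state_with_cells(cells), geo)
        assert df.loc[1, "macrophages"] == 2
        assert df.loc[1, "fibroblasts"] == 1
        assert df.loc[1, "fibrocytes"] == 1
        pooled = count_cells_in_areas(_state_with_cells(cells), geo,
                                      pool_f0=True)
        assert pooled.loc[1, "fibroblasts"] == 2

    def test_cell_on_implant_counted_nowhere(self):
        geo = CountingGeometry(grid_n=40, implant_extent=14)
        df = count_cells_in_areas(_state_with_cells([((19, 19), M1)]), geo)
        assert df.to_numpy().sum() == 0

    def test_grid_mismatch_raises(self):
        geo = CountingGeometry(grid_n=60, implant_extent=14)
        with pytest.raises(ValueError):
            count_cells_in_areas(_state_with_cells([((1, 1), M0)]), geo)

    def test_areas_outside_grid_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            CountingGeometry(grid_n=20, implant_extent=10)


def _trace_with_constant_rate(rate, steps):
    data = pd.DataFrame(0.0, index=range(steps), columns=TRACE_COLUMNS)
    data["step"] = np.arange(1, steps + 1)
    data["cum_pim"] = rate * np.arange(1, steps + 1)
    data["cum_aim"] = 2 * rate * np.arange(1, steps + 1)
    return data


class TestSecretionSummary:
    def test_zero_traces(self):
        df = secretion_summary({"control": [_trace_with_constant_rate(0, 10)]})
        assert df.loc["control", "pim"] == 0.0
        assert df.loc["control", "aim"] == 0.0

    def test_constant_rate_arithmetic_series(self):
        # cumulative r*t averaged over t = 1..T gives r*(T+1)/2
        r, T = 0.5, 40
        df = secretion_summary({"c": [_trace_with_constant_rate(r, T)]})
        assert df.loc["c", "pim"] == pytest.approx(r * (T + 1) / 2)
        assert df.loc["c", "aim"] == pytest.approx(2 * r * (T + 1) / 2)

    def test_runs_averaged_before_time_average(self):
        df = secretion_summary({"c": [_trace_with_constant_rate(1, 10),
                                      _trace_with_constant_rate(3, 10)]})
        assert df.loc["c", "pim"] == pytest.approx(2 * 11 / 2)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            secretion_summary({})
        with pytest.raises(ValueError):
            secretion_summary({"c": []})


def _anova_oracle(groups):
    """Textbook one-way ANOVA from sums of squares."""
    all_x = np.concatenate(groups)
    grand = all_x.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = all_x.size - len(groups)
    return (ss_between / df_b) / (ss_within / df_w)


class TestAnovaBonferroni:
    def test_identical_groups(self):
        g = [np.array([1.0, 2.0, 3.0])] * 3
        f, p, pairwise = anova_bonferroni(g)
        assert f == 0.0 and p == 1.0

    def test_matches_textbook_oracle_on_random_data(self, rng):
        for _ in range(100):
            k = rng.integers(2, 5)
            groups = [rng.normal(rng.normal(0, 2), 1.0,
                                 size=rng.integers(3, 12))
                      for _ in range(k)]
            f, p, _ = anova_bonferroni(groups)
            assert f == pytest.approx(_anova_oracle(groups), abs=1e-8,
                                      rel=1e-8)

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm
        from statsmodels.formula.api import ols
        groups = [rng.normal(m, 1.0, size=10) for m in (0.0, 1.0, 3.0)]
        f, p, _ = anova_bonferroni(groups)
        df = pd.DataFrame({
            "y": np.concatenate(groups),
            "g": np.repeat(["a", "b", "c"], 10)})
        table = sm.stats.anova_lm(ols("y ~ C(g)", df).fit())
        assert f == pytest.approx(float(table["F"].iloc[0]), rel=1e-10)
        assert p == pytest.approx(float(table["PR(>F)"].iloc[0]), rel=1e-8)

    def test_two_groups_single_comparison_unadjusted(self, rng):
        from scipy import stats
        a, b = rng.normal(0, 1, 10), rng.normal(1, 1, 10)
        _, _, pairwise = anova_bonferroni([a, b])
        assert pairwise[(0, 1)] == pytest.approx(
            stats.ttest_ind(a, b).pvalue)

    def test_bonferroni_capped_at_one(self, rng):
        groups = [rng.normal(0, 1, 10) for _ in range(4)]
        _, _, pairwise = anova_bonferroni(groups)
        assert len(pairwise) == 6
        assert all(0 <= v <= 1 for v in pairwise.values())

    def test_undersized_group_rejected(self):
        with pytest.raises(ValueError):
            anova_bonferroni([[1.0], [1.0, 2.0]])
        with pytest.raises(ValueError):
            anova_bonferroni([[1.0, 2.0]])


class TestPowerLawFit:
    def test_exact_power_law_recovered(self):
        k = np.array([0.02, 0.5, 1.0, 2.0])
        fit = fit_power_law(k, 1000.0 * k ** 0.25)
        assert fit.A == pytest.approx(1000.0, rel=1e-6)
        assert fit.m == pytest.approx(0.25, abs=1e-6)

    def test_constant_nc_gives_zero_exponent(self):
        fit = fit_power_law([0.1, 0.5, 1.0], [42.0, 42.0, 42.0])
        assert fit.m == pytest.approx(0.0, abs=1e-12)

    def test_zero_k_points_excluded(self):
        k = [0.0, 0.02, 0.5, 1.0, 2.0]
        nc = [999.0] + list(1000.0 * np.array(k[1:]) ** 0.25)
        fit = fit_power_law(k, nc)
        assert fit.n_excluded == 1
        assert fit.m == pytest.approx(0.25, abs=1e-6)

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError):
            fit_power_law([0.0, 0.5], [1.0, 2.0])

    def test_standard_errors_reported(self, rng):
        k = np.array([0.02, 0.1, 0.5, 1.0, 2.0])
        nc = 500.0 * k ** 0.3 * np.exp(rng.normal(0, 0.05, k.size))
        fit = fit_power_law(k, nc)
        assert fit.m_se > 0 and fit.A_se > 0
        assert fit.m == pytest.approx(0.3, abs=5 * fit.m_se)
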