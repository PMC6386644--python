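import itertools

import numpy as np
import pytest
from scipy import stats as sps

from archflow.cohort import PRINTED_MEANS, cohort_fixture
from archflow.stats import (
    DegenerateInputError,
    cohort_report,
    column_mean,
    conservation_residual,
    pearson_with_p,
    percent_change,
)


class TestColumnMean:
    @pytest.mark.parametrize("values,decimals,expected", [
        ([0.19, 0.12, 0.12, 0.41], 2, 0.21),   # LCCA pre-op flows
        ([6.31, 5.98, 4.74, 3.69], 2, 5.18),   # AAo pre-op flows
        ([5.26, 5.01, 3.85, 2.26], 2, 4.10),   # DAo pre-op: 4.095 rounds up
        ([89.3, 27.0, 33.8, 29.3], 1, 44.9),   # LCCA pre velocities: 44.85 up
        ([0.75, 0.82, 1.95, 2.90], 2, 1.61),   # LSA areas: 1.605 rounds up
        ([66, 56, 65, 55], 0, 61),             # diastolic post: 60.5 rounds up
    ])
    def test_decimal_half_away_from_zero(self, values, decimals, expected):
        """Exact decimal ties round away from zero, unlike binary floats."""
        assert column_mean(values, decimals) == expected

    def test_identity(self):
        assert column_mean([3.3] * 4, 2) == 3.3

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            column_mean([], 2)


class TestPercentChange:
    @pytest.mark.parametrize("pre,post,expected", [
        (44.9, 72.6, 62),    # LCCA max velocity
        (4.10, 3.29, -20),   # DAo flow
        (5.18, 4.60, -11),   # AAo flow
        (3.16, 3.19, 1),     # BCT area
        (0.94, 1.02, 9),     # LCCA area
        (2.0, 2.0, 0),
    ])
    def test_headline_changes(self, pre, post, expected):
        assert percent_change(pre, post) == expected

    def test_zero_baseline_rejected(self):
        with pytest.raises(ZeroDivisionError):
            percent_change(0.0, 1.0)


class TestConservation:
    def test_patient2_pre_residual(self, cohort):
        assert conservation_residual(cohort[1], "pre") == pytest.approx(0.01)

    def test_patient1_post_residual(self, cohort):
        assert conservation_residual(cohort[0], "post") == pytest.approx(0.00)

    def test_all_rows_conserve_to_print_precision(self, cohort):
        for rec in cohort:
            for phase in ("pre", "post"):
                assert conservation_residual(rec, phase) <= 0.02


class TestPearson:
    def test_perfect_linearity(self):
        res = pearson_with_p([1, 2, 3, 4], [2, 4, 6, 8])
        assert res.r == pytest.approx(1.0)
        assert res.p < 1e-12

    def test_r095_n4_sits_at_the_5pct_boundary(self):
        """t = 0.95 sqrt(2/(1-0.9025)) = 4.303 is the 5% critical value, 2 df."""
        x = np.array([1.0, 2.0, 3.0, 4.0])
        z = np.array([1.0, -1.0, -1.0, 1.0])  # orthogonal to x - mean(x)
        r = 0.95
        xs = (x - x.mean()) / np.std(x)
        zs = (z - z.mean()) / np.std(z)
        y = r * xs + np.sqrt(1 - r**2) * zs
        res = pearson_with_p(list(x), list(y))
        assert res.r == pytest.approx(0.95, abs=1e-12)
        assert res.p == pytest.approx(0.05, abs=0.001)

    def test_matches_scipy(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            x = rng.normal(size=6)
            y = rng.normal(size=6)
            mine = pearson_with_p(list(x), list(y))
            ref = sps.pearsonr(x, y)
            assert mine.r == pytest.approx(ref.statistic, rel=1e-12)
            assert mine.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_rank_agreement_with_permutation_p(self):
        """t-based and exact permutation p-values order datasets identically."""
        rng = np.random.default_rng(7)
        t_ps, perm_ps = [], []
        for _ in range(6):
            x = rng.normal(size=4)
            y = rng.normal(size=4)
            r_obs = abs(pearson_with_p(list(x), list(y)).r)
            perms = [
                abs(pearson_with_p(list(x), [y[i] for i in perm]).r)
                for perm in itertools.permutations(range(4))
            ]
            perm_ps.append(sum(rp >= r_obs - 1e-12 for rp in perms) / len(perms))
            t_ps.append(pearson_with_p(list(x), list(y)).p)
        rho = sps.spearmanr(t_ps, perm_ps).statistic
        assert rho > 0.9

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DegenerateInputError):
            pearson_with_p([1.0, 1.0, 1.0, 1.0], [1, 2, 3, 4])
        with pytest.raises(DegenerateInputError):
            pearson_with_p([1.0, 2.0], [1.0, 2.0])


class TestCohortReport:
    def test_headline_columns(self, cohort):
        s = cohort_report(cohort)
        assert s.columns["flow.pre.LCCA"].mean == 0.21
        assert s.columns["flow.post.LCCA"].mean == 0.61
        assert s.columns["velocity.pre.LCCA"].mean == 44.9
        assert s.columns["velocity.post.LCCA"].mean == 72.6
        assert s.columns["flow.pre.AAo"].mean == 5.18
        assert s.columns["flow.pre.AAo"].low == 3.69
        assert s.columns["flow.pre.AAo"].high == 6.31

    def test_means_lie_within_ranges(self, cohort):
        for key, col in cohort_report(cohort).columns.items():
            assert col.low <= col.mean <= col.high, key

    def test_known_print_discrepancies_flagged(self, cohort):
        s = cohort_report(cohort)
        assert set(s.discrepancies) == {
            "flow.pre.BCT",      # 0.625 printed as 0.62
            "flow.pre.LSA",      # 0.255 printed as 0.25
            "area.pre.BCT",      # 3.165 printed as 3.16
            "velocity.post.BCT", # column mean 44.4 printed as 44.5
        }
        for key in s.discrepancies:
            assert s.columns[key].matches_printed is False

    def test_percent_changes(self, cohort):
        s = cohort_report(cohort)
        assert s.percent_changes["velocity.LCCA"] == 62
        assert s.percent_changes["flow.AAo"] == -11
        assert s.percent_changes["flow.DAo"] == -20
        assert s.percent_changes["area.BCT"] == 1
        assert s.percent_changes["area.LCCA"] == 9
        # the published +294% for LCCA flow is not derivable from the table;
        # the ratio of printed column means gives +190%
        assert s.percent_changes["flow.LCCA"] == 190

    def test_residuals_included(self, cohort):
        s = cohort_report(cohort)
        assert len(s.conservation_residuals) == 8
        assert max(s.conservation_residuals.values()) <= 0.02


def test_fixture_cells_match_print(cohort):
    assert len(cohort) == 4
    rec1, rec2, rec3, rec4 = cohort
    assert rec1.flow_pre["AAo"] == 6.31
    assert rec3.pressure_pre["systolic"] == 117
    assert [(g.proximal_mm, g.distal_mm, g.length_mm) for g in rec4.graft] == [
        (42, 42, 200), (46, 46, 200), (46, 46, 150)
    ]
    assert rec1.velocity_post["LCCA"] == 134.9
    assert rec2.area_pre["LCCA"] == 0.67
    for name, value in PRINTED_MEANS["flow_pre"].items():
        assert value > 0
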