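"""Summary statistics: oracles, conventions, invariances."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nbdgkin import (
    CellGeometry,
    CellTrace,
    background_subtract,
    coefficient_of_variation,
    normalize_by_size,
    pearson_r,
    percent_of_baseline,
    steady_state_mean,
    welch_t,
)
from nbdgkin.stats import summary_table

GEOM = CellGeometry(1.0, 3.0)


def _trace(cell_id, values, times=None):
    times = np.arange(len(values)) * 20.0 if times is None else np.asarray(times)
    return CellTrace(cell_id, times, np.asarray(values, float), GEOM)


class TestBackgroundSubtract:
    def test_identical_background_gives_zero(self):
        corr, neg = background_subtract([10, 20], [10, 20])
        np.testing.assert_array_equal(corr, [0, 0])
        assert not neg

    def test_zero_background_identity(self):
        corr, neg = background_subtract([100, 200], [0, 0])
        np.testing.assert_array_equal(corr, [100, 200])
        assert not neg

    def test_negative_values_kept_and_flagged(self):
        corr, neg = background_subtract([5, 5], [10, 10])
        np.testing.assert_array_equal(corr, [-5, -5])
        assert neg

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            background_subtract([1, 2, 3], [1, 2])


class TestNormalizeBySize:
    def test_division(self):
        assert normalize_by_size(1000.0, 100) == 10.0
        assert normalize_by_size(0.0, 37) == 0.0

    def test_homogeneity(self):
        assert normalize_by_size(2 * 1000.0, 2 * 100) == normalize_by_size(1000.0, 100)

    def test_nonpositive_size_rejected(self):
        with pytest.raises(ValueError):
            normalize_by_size(10.0, 0)


class TestCV:
    def test_constant_vector_zero(self):
        assert coefficient_of_variation([3.0, 3.0, 3.0]) == 0.0

    def test_hand_computed_example(self):
        # sample SD 1 (n-1 denominator), mean 2 -> 50%
        assert coefficient_of_variation([1, 2, 3]) == pytest.approx(50.0)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(c=st.floats(0.1, 100))
    def test_scale_invariance(self, c):
        base = np.array([1.0, 2.5, 4.0, 8.0])
        assert coefficient_of_variation(c * base) == pytest.approx(
            coefficient_of_variation(base), rel=1e-9
        )

    def test_matches_formula_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            x = rng.uniform(1, 10, size=rng.integers(2, 50))
            mean = x.sum() / x.size
            sd = math.sqrt(((x - mean) ** 2).sum() / (x.size - 1))
            assert coefficient_of_variation(x) == pytest.approx(
                100 * sd / mean, abs=1e-12 * 100
            )


class TestPearson:
    def test_perfect_correlations(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson_r(x, x)[0] == pytest.approx(1.0)
        assert pearson_r(x, -2 * x)[0] == pytest.approx(-1.0)

    def test_matches_covariance_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(3, 60))
            x, y = rng.standard_normal(n), rng.standard_normal(n)
            xc, yc = x - x.mean(), y - y.mean()
            r_oracle = (xc * yc).sum() / math.sqrt((xc**2).sum() * (yc**2).sum())
            assert pearson_r(x, y)[0] == pytest.approx(r_oracle, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1, 1, 1], [1, 2, 3])


class TestWelch:
    def test_identical_samples(self):
        t, _, p = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_antisymmetry(self):
        x, y = [1.0, 2.0, 4.0], [3.0, 5.0, 6.0, 7.0]
        t1, df1, p1 = welch_t(x, y)
        t2, df2, p2 = welch_t(y, x)
        assert t1 == pytest.approx(-t2)
        assert df1 == pytest.approx(df2)
        assert p1 == pytest.approx(p2)

    def test_matches_formula_oracle(self):
        """Hand-computed Welch statistic with Satterthwaite df."""
        x = np.array([27.5, 21.0, 19.0, 23.6, 17.0, 17.9, 16.9, 20.1])
        y = np.array([27.1, 22.0, 20.8, 23.4, 23.4, 23.5, 25.8, 22.0, 24.8])
        vx, vy = x.var(ddof=1) / x.size, y.var(ddof=1) / y.size
        t_oracle = (x.mean() - y.mean()) / math.sqrt(vx + vy)
        df_oracle = (vx + vy) ** 2 / (
            vx**2 / (x.size - 1) + vy**2 / (y.size - 1)
        )
        t, df, _ = welch_t(x, y)
        assert t == pytest.approx(t_oracle, abs=1e-12)
        assert df == pytest.approx(df_oracle, abs=1e-9)


class TestPercentOfBaseline:
    @pytest.mark.parametrize(
        "baseline,new,expected",
        [(740.0, 1072.0, 145), (1072.0, 1714.0, 160), (500.0, 500.0, 100)],
    )
    def test_reported_condition_ratios(self, baseline, new, expected):
        assert round(percent_of_baseline(baseline, new)) == expected

    def test_multiplicativity(self):
        a, b, c = 740.0, 1072.0, 1714.0
        chained = percent_of_baseline(a, b) * percent_of_baseline(b, c) / 100.0
        assert chained == pytest.approx(percent_of_baseline(a, c), rel=1e-12)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError):
            percent_of_baseline(0.0, 10.0)


class TestSteadyStateMean:
    def test_identical_traces(self):
        traces = [_trace(f"c{i}", np.full(50, 7.0)) for i in range(3)]
        mean, sem, n = steady_state_mean(traces, t_query=900.0)
        assert (mean, sem, n) == (7.0, 0.0, 3)

    def test_two_cell_hand_computation(self):
        traces = [_trace("a", np.full(50, 1.0)), _trace("b", np.full(50, 3.0))]
        mean, sem, n = steady_state_mean(traces, t_query=900.0)
        assert mean == 2.0
        assert sem == pytest.approx(1.0)
        assert n == 2

    def test_query_outside_acquisition_rejected(self):
        traces = [_trace("a", np.full(10, 1.0))]  # ends at t = 180 s
        with pytest.raises(ValueError):
            steady_state_mean(traces, t_query=900.0)

    def test_reordering_invariance(self):
        rng = np.random.default_rng(6)
        traces = [_trace(f"c{i}", rng.uniform(0, 10, 50)) for i in range(8)]
        assert steady_state_mean(traces) == steady_state_mean(traces[::-1])


def test_summary_table_contents():
    rng = np.random.default_rng(1)
    traces = [_trace(f"c{i}", rng.uniform(5, 10, 50)) for i in range(6)]
    lp = rng.standard_normal((6, 2))
    tab = summary_table(traces, log_params=lp, condition="optimal")
    row = tab.iloc[0]
    assert row["n_cells"] == 6
    assert row["cv_percent"] >= 0
    assert -1 <= row["pearson_r_logu_logd"] <= 1
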