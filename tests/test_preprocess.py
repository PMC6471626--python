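import numpy as np
import pytest
from statsmodels.tsa.stattools import adfuller

from grangernet import TimeSeriesTable, adf_screen, adf_test, drop_missing, filter_abundance
from .conftest import ar1


def make_table(rows, classes=None, ids=None):
    values = np.asarray(rows, dtype=float)
    n = values.shape[0]
    ids = ids or [f"v{i}" for i in range(n)]
    classes = classes or ["OTU"] * n
    return TimeSeriesTable(values, ids, classes, [str(t) for t in range(values.shape[1])])


class TestFilterAbundance:
    def test_abundant_otu_kept(self):
        t = make_table([[2.0] * 10])
        out, rep = filter_abundance(t)
        assert out.var_ids == ["v0"] and rep.removed == []

    def test_low_mean_and_zero_inflated_removed(self):
        # mean 0.4 < 1 AND zero fraction 0.6 > 0.5
        t = make_table([[0, 0, 0, 0, 0, 0, 1, 1, 1, 1]])
        out, rep = filter_abundance(t, combine="and")
        assert out.n_vars == 0
        assert rep.removed_ids == ["v0"]

    def test_combine_or_vs_and(self):
        # mean 0.4 >= 0.3, zero fraction 0.6 > 0.5: fails only the zero test
        t = make_table([[0, 0, 0, 0, 0, 0, 1, 1, 1, 1]])
        kept_and, _ = filter_abundance(t, mean_thresh=0.3, combine="and")
        kept_or, rep = filter_abundance(t, mean_thresh=0.3, combine="or")
        assert kept_and.n_vars == 1
        assert kept_or.n_vars == 0
        assert rep.removed == [("v0", "high_zero_fraction")]

    def test_environmental_exempt(self):
        t = make_table([[0.0] * 10], classes=["environmental"])
        out, _ = filter_abundance(t)
        assert out.n_vars == 1

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        t = make_table(rng.poisson(0.7, size=(6, 20)))
        once, _ = filter_abundance(t)
        twice, rep = filter_abundance(once)
        assert twice.var_ids == once.var_ids and rep.removed == []

    def test_order_invariance(self):
        rng = np.random.default_rng(1)
        vals = rng.poisson(0.7, size=(6, 20)).astype(float)
        t = make_table(vals)
        perm = [3, 0, 5, 1, 4, 2]
        t_perm = make_table(vals[perm], ids=[f"v{i}" for i in perm])
        _, rep = filter_abundance(t)
        _, rep_perm = filter_abundance(t_perm)
        assert set(rep.removed_ids) == set(rep_perm.removed_ids)

    def test_errors(self):
        with pytest.raises(ValueError, match="empty"):
            filter_abundance(make_table(np.zeros((0, 5))))
        with pytest.raises(ValueError, match="zero_frac"):
            filter_abundance(make_table([[1.0] * 10]), zero_frac_thresh=1.5)


class TestDropMissing:
    def test_no_missing_identity(self):
        t = make_table(np.arange(20.0).reshape(2, 10))
        out, rep = drop_missing(t)
        np.testing.assert_array_equal(out.values, t.values)
        assert rep.dropped_time_labels == []

    def test_single_missing_point(self):
        vals = np.ones((3, 12))
        vals[1, 3] = np.nan
        out, rep = drop_missing(make_table(vals))
        assert out.T == 11
        assert rep.dropped_time_labels == ["3"]
        assert not out.has_missing

    def test_count_equals_distinct_affected_columns(self):
        vals = np.ones((4, 15))
        # 6 missing cells over 4 distinct time points
        for i, j in [(0, 2), (1, 2), (2, 5), (3, 9), (0, 9), (1, 13)]:
            vals[i, j] = np.nan
        out, _ = drop_missing(make_table(vals))
        assert out.T == 15 - 4

    def test_min_T_enforced(self):
        vals = np.ones((2, 12))
        vals[0, :5] = np.nan
        with pytest.raises(ValueError, match="complete time points"):
            drop_missing(make_table(vals), min_T=10)

    def test_temporal_order_preserved(self):
        vals = np.arange(12.0)[None, :].copy()
        vals[0, 4] = np.nan
        out, _ = drop_missing(make_table(vals))
        assert list(out.values[0]) == [0, 1, 2, 3, 5, 6, 7, 8, 9, 10, 11]


def df_tstat_oracle(y: np.ndarray, k: int) -> float:
    """Dickey-Fuller t-statistic by explicit OLS of the auxiliary regression.

    delta y_t = a + rho*y_{t-1} + sum_{i=1..k} phi_i * delta y_{t-i} + e_t;
    returns t(rho). Independent of the statsmodels implementation.
    """
    dy = np.diff(y)
    rows = []
    for t in range(k, len(dy)):
        rows.append([1.0, y[t]] + [dy[t - i] for i in range(1, k + 1)])
    X = np.asarray(rows)
    target = dy[k:]
    beta = np.linalg.solve(X.T @ X, X.T @ target)
    resid = target - X @ beta
    s2 = resid @ resid / (len(target) - X.shape[1])
    cov = s2 * np.linalg.inv(X.T @ X)
    return beta[1] / np.sqrt(cov[1, 1])


class TestADF:
    def test_random_walk_nonstationary(self):
        rng = np.random.default_rng(1)
        walk = np.cumsum(rng.normal(size=200))
        assert adf_test(walk).verdict == "nonstationary"

    def test_white_noise_stationary(self):
        rng = np.random.default_rng(12)
        assert adf_test(rng.normal(size=200)).verdict == "stationary"

    @pytest.mark.parametrize("k", [0, 1, 3])
    def test_statistic_matches_df_regression_oracle(self, k):
        rng = np.random.default_rng(7)
        y = np.cumsum(rng.normal(size=150))
        stat, *_ = adfuller(y, maxlag=k, regression="c", autolag=None)
        res = adf_test(y, max_lags=k)
        oracle = df_tstat_oracle(y, k)
        assert abs(stat - oracle) < 1e-8
        assert abs(res.adf_statistic - oracle) < 1e-8

    def test_constant_series_flagged_with_warning(self):
        t = make_table([np.ones(30), ar1(0.2, 30, 3)])
        with pytest.warns(UserWarning, match="constant"):
            out, results = adf_screen(t)
        assert results[0].verdict == "nonstationary"
        assert out.var_ids == ["v1"]

    def test_ar_series_retained_with_high_power(self):
        hits = sum(
            adf_test(ar1(0.3, 500, seed)).verdict == "stationary" for seed in range(100)
        )
        assert hits > 95

    def test_screen_removes_only_nonstationary(self):
        rng = np.random.default_rng(21)
        walk = np.cumsum(rng.normal(size=200))
        t = make_table([ar1(0.3, 200, 1), walk, ar1(0.1, 200, 2)])
        out, results = adf_screen(t)
        assert out.var_ids == ["v0", "v2"]
        assert [r.verdict for r in results] == ["stationary", "nonstationary", "stationary"]
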