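"""Empirical CDFs, percentiles, centile tables, fits, quantile regression."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from conftest import discretized_gaussian_pmf, group_dist
from vitalcentiles.ages import enumerate_age_groups
from vitalcentiles.centiles import (
    PERCENTILE_LEVELS,
    CentileTable,
    build_centile_table,
    empirical_cdf,
    fit_discrepancy,
    fit_lms_fixed_power,
    fit_parametric,
    percentile_from_cdf,
    pinball_loss,
    quantile_regression_centile,
    smooth_centiles_over_age,
)
from vitalcentiles.distributions import (
    DegenerateDistributionError,
    ValueHistogram,
    pmf_mean_sd,
)

COARSE = [g for g in enumerate_age_groups() if g.kind == "coarse"]


def _pmf_on(support_values, weights):
    pmf = np.zeros(299)
    pmf[np.asarray(support_values) - 1] = weights
    return pmf / pmf.sum()


@st.composite
def random_pmfs(draw):
    seed = draw(st.integers(min_value=0, max_value=10_000))
    rng = np.random.default_rng(seed)
    k = rng.integers(1, 20)
    support = np.sort(rng.choice(np.arange(1, 300), size=k, replace=False))
    return _pmf_on(support, rng.dirichlet(np.ones(k)))


class TestEmpiricalCDF:
    def test_point_mass(self):
        cdf = empirical_cdf(group_dist(_pmf_on([100], [1.0])))
        assert cdf.support.tolist() == [100.0]
        assert cdf.cumulative.tolist() == [1.0]

    def test_three_bin_example(self):
        cdf = empirical_cdf(group_dist(_pmf_on([1, 2, 3], [0.2, 0.3, 0.5])))
        np.testing.assert_allclose(cdf.cumulative, [0.2, 0.5, 1.0])

    @given(random_pmfs())
    def test_matches_bruteforce_prefix_sums(self, pmf):
        cdf = empirical_cdf(group_dist(pmf))
        expected = []
        total = 0.0
        for p in pmf:
            if p > 0:
                total += p
                expected.append(total)
        np.testing.assert_allclose(cdf.cumulative, expected, atol=1e-12)


class TestPercentileFromCDF:
    def test_uniform_median(self):
        cdf = empirical_cdf(group_dist(_pmf_on(range(1, 101), np.ones(100))))
        assert percentile_from_cdf(cdf, 50) == pytest.approx(50.0, abs=1e-9)

    def test_point_mass_every_level(self):
        cdf = empirical_cdf(group_dist(_pmf_on([80], [1.0])))
        assert all(percentile_from_cdf(cdf, p) == 80.0 for p in PERCENTILE_LEVELS)

    def test_discretized_gaussian_95th_matches_closed_form(self):
        cdf = empirical_cdf(group_dist(discretized_gaussian_pmf(100, 10)))
        target = 100 + stats.norm.ppf(0.95) * 10  # 116.449
        assert percentile_from_cdf(cdf, 95) == pytest.approx(target, abs=0.5)

    @pytest.mark.parametrize("level", [0, 100, -3])
    def test_out_of_range_level_rejected(self, level):
        cdf = empirical_cdf(group_dist(_pmf_on([80], [1.0])))
        with pytest.raises(ValueError):
            percentile_from_cdf(cdf, level)

    @given(random_pmfs(), st.integers(min_value=1, max_value=99))
    def test_quantile_bracketing_property(self, pmf, level):
        cdf = empirical_cdf(group_dist(pmf))
        x = percentile_from_cdf(cdf, level)
        q = level / 100.0
        below = cdf.cumulative[cdf.support < x]
        at_or_above = cdf.cumulative[cdf.support >= x]
        if below.size:
            assert below[-1] <= q + 1e-12
        if at_or_above.size:
            assert at_or_above[0] >= q - 1e-12


class TestCentileTable:
    def test_point_mass_row_is_constant_with_99_levels(self):
        table = build_centile_table([group_dist(_pmf_on([80], [1.0]))])
        assert table.data.shape == (1, 99)
        assert (table.data.iloc[0] == 80.0).all()

    def test_rows_ordered_by_age_and_monotone_in_level(self):
        dists = [
            group_dist(discretized_gaussian_pmf(100 + 5 * i, 10), age_group=g.label)
            for i, g in enumerate(COARSE)
        ]
        table = build_centile_table(dists[::-1])  # shuffled input order
        assert list(table.data.index) == [g.label for g in COARSE]
        values = table.data.to_numpy()
        assert (np.diff(values, axis=1) >= 0).all()
        # generator has an age-increasing median: p50 column non-decreasing
        assert (np.diff(values[:, 49]) >= 0).all()


class TestCentileSmoothing:
    def _table(self, row_values):
        data = pd.DataFrame(
            {f"p{p}": row_values + 0.1 * p for p in PERCENTILE_LEVELS},
            index=[g.label for g in COARSE],
        )
        return CentileTable(variable="HR", data=data)

    def test_constant_over_age_unchanged(self):
        table = self._table(np.full(13, 50.0))
        out = smooth_centiles_over_age(table, span=0.5)
        np.testing.assert_allclose(out.data.to_numpy(), table.data.to_numpy(), atol=1e-6)
        assert out.smoothed

    def test_rows_remain_monotone_after_smoothing(self):
        rng = np.random.default_rng(5)
        table = self._table(100 + rng.normal(0, 3, 13))
        out = smooth_centiles_over_age(table, span=0.4)
        assert (np.diff(out.data.to_numpy(), axis=1) >= -1e-12).all()

    def test_outlier_row_pulled_toward_trend(self):
        x = np.log([g.midpoint_days for g in COARSE])
        trend = 100 + 10 * (x - x[0]) / (x[-1] - x[0])
        bumped = trend.copy()
        bumped[6] += 8.0
        out = smooth_centiles_over_age(self._table(bumped), span=0.5)
        dev_after = abs(out.data.iloc[6, 49] - (trend[6] + 0.1 * 50))
        assert dev_after < 8.0

    def test_fewer_than_three_rows_is_identity_with_warning(self, caplog):
        data = pd.DataFrame(
            {f"p{p}": [100.0 + p] for p in PERCENTILE_LEVELS}, index=["0-3 months"]
        )
        table = CentileTable(variable="HR", data=data)
        with caplog.at_level("WARNING"):
            out = smooth_centiles_over_age(table)
        np.testing.assert_array_equal(out.data.to_numpy(), data.to_numpy())
        assert any("3" in rec.message for rec in caplog.records)


class TestParametricFits:
    def test_gaussian_recovery(self, gaussian_group):
        fit = fit_parametric(gaussian_group, "gaussian")
        assert fit.parameters["mean"] == pytest.approx(120.0, abs=0.1)
        assert fit.parameters["sd"] == pytest.approx(10.0, abs=0.1)

    def test_logistic_location_matches_center(self, gaussian_group):
        fit = fit_parametric(gaussian_group, "logistic")
        assert fit.parameters["location"] == pytest.approx(120.0, abs=0.2)
        assert fit.parameters["scale"] > 0

    def test_lms_with_unit_power_is_affine_normal(self, gaussian_group):
        fit = fit_lms_fixed_power(gaussian_group, L=1.0)
        mean, _ = pmf_mean_sd(gaussian_group.pmf)
        assert fit.parameters["M"] == pytest.approx(mean, rel=0.01)

    def test_lms_parameter_recovery(self, rng):
        L, M, S = 0.5, 100.0, 0.1
        z = rng.standard_normal(400_000)
        x = M * (1 + L * S * z) ** (1 / L)
        x = np.clip(np.round(x), 1, 299).astype(int)
        d = group_dist(ValueHistogram.from_values("MBP", x).pmf, variable="MBP")
        fit = fit_parametric(d, "lms")
        assert fit.parameters["L"] == pytest.approx(L, rel=0.05)
        assert fit.parameters["M"] == pytest.approx(M, rel=0.05)
        assert fit.parameters["S"] == pytest.approx(S, rel=0.05)

    def test_point_mass_is_degenerate(self):
        with pytest.raises(DegenerateDistributionError):
            fit_parametric(group_dist(_pmf_on([100], [1.0])), "gaussian")


class TestFitDiscrepancy:
    def test_identical_cdfs_have_zero_discrepancy(self, gaussian_group):
        fit = fit_parametric(gaussian_group, "gaussian")
        cdf = empirical_cdf(gaussian_group)
        d = fit_discrepancy(cdf, fit)
        assert 0 <= d < 0.05  # same family, so near-zero

    def test_near_point_mass_vs_gaussian_fit(self):
        pmf = _pmf_on([99, 100, 101], [0.01, 0.98, 0.01])
        d = group_dist(pmf)
        fit = fit_parametric(d, "gaussian")
        assert fit.discrepancy > 0.4

    def test_gaussian_fit_worse_on_leptokurtic_data(
        self, gaussian_group, leptokurtic_group
    ):
        meso = fit_parametric(gaussian_group, "gaussian").discrepancy
        lepto = fit_parametric(leptokurtic_group, "gaussian").discrepancy
        assert lepto > meso


class TestQuantileRegression:
    def test_constant_data_yields_flat_curve(self):
        ages = np.arange(10.0)
        values = np.full(10, 100.0)
        for p in (0.1, 0.5, 0.9):
            qc = quantile_regression_centile(ages, values, p)
            np.testing.assert_allclose(qc.fitted, 100.0, atol=1e-8)

    @pytest.mark.parametrize("level", [0.1, 0.25, 0.5, 0.75, 0.9])
    def test_tiny_dataset_matches_bruteforce_search(self, level):
        ages = np.array([1.0, 2, 3, 5, 8, 13, 21, 30])
        values = np.array([3.0, 7, 2, 9, 11, 4, 15, 13])
        qc = quantile_regression_centile(ages, values, level)
        loss = pinball_loss(values - qc.predict(ages), level)
        best = np.inf
        for i in range(len(ages)):
            for j in range(len(ages)):
                if ages[i] == ages[j]:
                    continue
                slope = (values[j] - values[i]) / (ages[j] - ages[i])
                intercept = values[i] - slope * ages[i]
                cand = pinball_loss(values - (intercept + slope * ages), level)
                best = min(best, cand)
        assert loss == pytest.approx(best, abs=1e-9)

    def test_median_slope_recovery(self, rng):
        n = 10_000
        ages = rng.uniform(0, 5000, n)
        values = 100 + 0.01 * ages + rng.normal(0, 5, n)
        qc = quantile_regression_centile(ages, values, 0.5)
        assert qc.coefficients[1] == pytest.approx(0.01, rel=0.1)

    def test_agrees_with_statsmodels_quantreg(self, rng):
        import statsmodels.api as sm

        n = 2_000
        ages = rng.uniform(0, 1000, n)
        values = 50 + 0.05 * ages + rng.normal(0, 3, n)
        level = 0.75
        qc = quantile_regression_centile(ages, values, level)
        X = sm.add_constant(ages)
        ref = sm.QuantReg(values, X).fit(q=level)
        ours = pinball_loss(values - qc.predict(ages), level)
        theirs = pinball_loss(values - ref.predict(X), level)
        assert ours <= theirs + 1e-6

    def test_per_group_covariate_matches_sample_quantiles(self, rng):
        ages = np.repeat([10.0, 20.0, 30.0], 100)
        values = rng.normal(100, 10, 300)
        qc = quantile_regression_centile(ages, values, 0.25, covariate="per_group")
        for a, f in zip(qc.ages, qc.fitted):
            assert f == np.quantile(values[ages == a], 0.25)

    def test_degenerate_design_rejected(self):
        with pytest.raises(ValueError):
            quantile_regression_centile(
                np.array([5.0, 5.0]), np.array([1.0, 2.0]), 0.5
            )
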