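import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rmcorr import (
    ConfigurationError,
    ConsistencyError,
    DataInsufficiencyError,
    DegenerateDesignError,
    PairedRepeatedData,
    approx_df,
    error_df,
    fit_rmcorr,
    pearson_baselines,
    predicted_lines,
)

from conftest import FIXTURE_DF, FIXTURE_P, FIXTURE_R, FIXTURE_SLOPE, random_unbalanced_dataset


def parallel_lines_data(n=4, k=5, slope=1.0):
    parts, xs, ys = [], [], []
    for j in range(n):
        x = np.arange(k, dtype=float)
        parts += [f"s{j}"] * k
        xs.append(x)
        ys.append(10.0 * j + slope * x)
    return PairedRepeatedData(parts, np.concatenate(ys), np.concatenate(xs))


class TestFit:
    def test_perfect_parallel_fit(self):
        res = fit_rmcorr(parallel_lines_data(slope=1.0))
        assert res.r_rm == 1.0
        assert res.slope == pytest.approx(1.0)
        assert res.p_value < 1e-12
        assert res.table.ss_error == 0.0

    def test_constant_response_gives_zero(self):
        parts = ["a"] * 4 + ["b"] * 4
        y = [3.0] * 4 + [7.0] * 4
        x = list(range(4)) * 2
        res = fit_rmcorr(PairedRepeatedData(parts, y, x))
        assert res.r_rm == 0.0
        assert res.slope == 0.0
        assert res.f_ratio == 0.0
        assert res.p_value == 1.0

    def test_fixture_matches_frozen_oracle_values(self, fixed_dataset):
        res = fit_rmcorr(fixed_dataset)
        assert res.r_rm == pytest.approx(FIXTURE_R, rel=1e-12)
        assert res.p_value == pytest.approx(FIXTURE_P, rel=1e-10)
        assert res.slope == pytest.approx(FIXTURE_SLOPE, rel=1e-12)
        assert res.df_error == FIXTURE_DF

    def test_fixture_cross_checked_against_pingouin(self, fixed_dataset):
        pg = pytest.importorskip("pingouin")
        out = pg.rm_corr(
            data=fixed_dataset.to_dataframe(),
            x="measure2", y="measure1", subject="participant",
        )
        res = fit_rmcorr(fixed_dataset)
        assert res.r_rm == pytest.approx(float(out["r"].iloc[0]), rel=1e-9)
        assert res.p_value == pytest.approx(float(out["pval"].iloc[0]), rel=1e-6)
        assert res.df_error == int(out["dof"].iloc[0])

    def test_dummy_coded_regression_oracle(self, fixed_dataset):
        d = fixed_dataset
        design = np.column_stack(
            [np.equal.outer(d.codes, np.arange(d.N)).astype(float), d.measure2]
        )
        beta, _, _, _ = np.linalg.lstsq(design, d.measure1, rcond=None)
        resid = d.measure1 - design @ beta
        res = fit_rmcorr(d)
        assert res.slope == pytest.approx(beta[-1], rel=1e-12)
        assert res.table.ss_error == pytest.approx(resid @ resid, rel=1e-12)

    def test_statsmodels_ancova_cross_check(self, fixed_dataset):
        smf = pytest.importorskip("statsmodels.formula.api")
        sm_api = pytest.importorskip("statsmodels.api")
        df = fixed_dataset.to_dataframe()
        model = smf.ols("measure1 ~ C(participant) + measure2", data=df).fit()
        anova = sm_api.stats.anova_lm(model, typ=1)
        res = fit_rmcorr(fixed_dataset)
        assert res.table.ss_measure == pytest.approx(anova.loc["measure2", "sum_sq"], rel=1e-10)
        assert res.table.ss_error == pytest.approx(anova.loc["Residual", "sum_sq"], rel=1e-10)
        assert res.f_ratio == pytest.approx(anova.loc["measure2", "F"], rel=1e-10)

    def test_separated_within_and_between_patterns(self, rng):
        # Strong within-slope but participant means arranged with no
        # between-participant trend: rmcorr is large while the
        # averaged-data Pearson correlation stays near zero.
        n, k = 10, 5
        parts, xs, ys = [], [], []
        means = rng.permutation(n).astype(float)  # scrambled: no trend
        for j in range(n):
            x = np.arange(k, dtype=float)
            parts += [f"s{j}"] * k
            xs.append(x + rng.normal(0, 0.1, k))
            ys.append(3.0 * means[j] + x + rng.normal(0, 0.3, k))
        data = PairedRepeatedData(parts, np.concatenate(ys), np.concatenate(xs))
        res = fit_rmcorr(data)
        base = pearson_baselines(data)
        assert res.r_rm > 0.9
        assert abs(base.averaged.r) < 0.5
        assert res.r_rm > abs(base.averaged.r)

    def test_swapping_measures_preserves_estimates(self, rng):
        for _ in range(10):
            d = random_unbalanced_dataset(rng)
            swapped = PairedRepeatedData(d.participants, d.measure2, d.measure1)
            a, b = fit_rmcorr(d), fit_rmcorr(swapped)
            assert a.r_rm == pytest.approx(b.r_rm, abs=1e-12)
            assert a.p_value == pytest.approx(b.p_value, rel=1e-9)
            assert a.ci[0] == pytest.approx(b.ci[0], abs=1e-10)

    def test_degenerate_design_rejected(self):
        parts = ["a", "a", "b", "b"]
        with pytest.raises(DegenerateDesignError):
            fit_rmcorr(PairedRepeatedData(parts, [1.0, 2, 3, 4], [5.0, 5, 7, 7]))

    def test_single_constant_covariate_participant_is_kept(self):
        parts = ["a"] * 3 + ["b"] * 3
        x = [2.0, 2.0, 2.0, 0.0, 1.0, 2.0]
        y = [1.0, 2.0, 3.0, 0.0, 1.1, 2.2]
        res = fit_rmcorr(PairedRepeatedData(parts, y, x))
        assert res.n_participants == 2
        assert math.isfinite(res.r_rm)

    def test_minimal_design_fits_with_single_error_df(self):
        # N = 2, k = 2 is the smallest admissible design: df_error = 1,
        # so the fit succeeds but no analytic interval is available.
        parts = ["a", "a", "b", "b"]
        with pytest.warns(UserWarning, match="df_error < 2"):
            res = fit_rmcorr(PairedRepeatedData(parts, [1.0, 2, 3, 4], [1.0, 2, 3, 4.5]))
        assert res.df_error == 1
        assert res.ci == (-1.0, 1.0)


class TestAncovaTable:
    def test_additivity_and_nonnegativity(self, rng):
        for _ in range(20):
            t = fit_rmcorr(random_unbalanced_dataset(rng)).table
            assert min(t.ss_participants, t.ss_measure, t.ss_error, t.ss_total) >= 0
            assert t.ss_participants + t.ss_measure + t.ss_error == pytest.approx(
                t.ss_total, rel=1e-9
            )
            assert t.df_participants + t.df_measure + t.df_error == t.df_total

    def test_text_rendering_has_all_rows(self, fixed_dataset):
        text = fit_rmcorr(fixed_dataset).table.to_text()
        for row in ("Participants", "Measure", "Error", "Total"):
            assert row in text

    def test_csv_round_trip(self, fixed_dataset, tmp_path):
        table = fit_rmcorr(fixed_dataset).table
        out = tmp_path / "table.csv"
        table.to_csv(out)
        frame = pd.read_csv(out, index_col="Source")
        assert frame.loc["Error", "SS"] == pytest.approx(table.ss_error)


class TestDegreesOfFreedom:
    @pytest.mark.parametrize("n,k,expected", [(11, 4, 32), (72, 2, 71), (2, 2, 1)])
    def test_error_df_worked_examples(self, n, k, expected):
        assert error_df(n, k) == expected

    def test_error_df_equals_l_minus_n_minus_1_unbalanced(self, rng):
        for _ in range(20):
            d = random_unbalanced_dataset(rng)
            assert error_df(d.N, d.k) == d.L - d.N - 1

    def test_error_df_rejects_degenerate(self):
        with pytest.raises(DataInsufficiencyError):
            error_df(2, 1.5)  # N(k-1)-1 = 0
        with pytest.raises(DataInsufficiencyError):
            error_df(1, 4)

    @pytest.mark.parametrize("n,k,expected", [(100, 2, 98), (11, 4, 27)])
    def test_approx_df_values(self, n, k, expected):
        assert approx_df(n, k) == expected

    def test_approx_converges_to_exact(self):
        ratios = [approx_df(n, 3) / error_df(n, 3) for n in (10, 100, 1000, 10000)]
        assert ratios == sorted(ratios)
        assert ratios[-1] == pytest.approx(1.0, abs=1e-3)


class TestPredictedLines:
    def test_lines_share_slope_and_zero_residual_sums(self, fixed_dataset):
        res = fit_rmcorr(fixed_dataset)
        lines = predicted_lines(res, fixed_dataset)
        slopes = [
            (ln.y_hat[-1] - ln.y_hat[0]) / (ln.x[-1] - ln.x[0]) for ln in lines
        ]
        assert max(slopes) - min(slopes) < 1e-12
        for ln in lines:
            rows = fixed_dataset.participant_rows(ln.participant)
            fitted = res.intercepts[ln.participant] + res.slope * fixed_dataset.measure2[rows]
            assert np.sum(fixed_dataset.measure1[rows] - fitted) == pytest.approx(0, abs=1e-9)

    def test_zero_slope_gives_horizontal_lines(self):
        parts = ["a"] * 4 + ["b"] * 4
        y = [3.0] * 4 + [7.0] * 4
        x = list(range(4)) * 2
        data = PairedRepeatedData(parts, y, x)
        res = fit_rmcorr(data)
        for ln in predicted_lines(res, data):
            assert np.ptp(ln.y_hat) == 0.0

    def test_mismatched_data_rejected(self, fixed_dataset, rng):
        res = fit_rmcorr(fixed_dataset)
        other = random_unbalanced_dataset(rng)
        with pytest.raises(ConsistencyError):
            predicted_lines(res, other)


class TestPearsonBaselines:
    def test_collinear_means_give_unit_averaged_r(self):
        # Participant means on one line; within-pattern sloping the other way.
        parts, xs, ys = [], [], []
        for j in range(4):
            parts += [f"s{j}"] * 3
            x = np.array([-1.0, 0.0, 1.0]) + j
            xs.append(x)
            ys.append(2.0 * j - (x - j))  # means on y=2x, within slope -1
        data = PairedRepeatedData(parts, np.concatenate(ys), np.concatenate(xs))
        base = pearson_baselines(data)
        assert base.averaged.r == pytest.approx(1.0)
        assert fit_rmcorr(data).r_rm == -1.0

    def test_degrees_of_freedom_of_baselines(self):
        parts = [f"s{j}" for j in range(11) for _ in range(4)]
        rng = np.random.default_rng(0)
        data = PairedRepeatedData(parts, rng.normal(size=44), rng.normal(size=44))
        base = pearson_baselines(data)
        assert base.averaged.df == 9
        assert base.pooled.df == 42

    def test_per_occasion_correlations(self):
        rng = np.random.default_rng(1)
        parts = [f"s{j}" for j in range(6) for _ in range(3)]
        trial = [t for _ in range(6) for t in ("t1", "t2", "t3")]
        data = PairedRepeatedData(parts, rng.normal(size=18), rng.normal(size=18))
        base = pearson_baselines(data, trial=trial)
        assert len(base.per_occasion) == 3
        for _, corr in base.per_occasion:
            assert corr.df == 4

    def test_matches_scipy_directly(self, fixed_dataset):
        base = pearson_baselines(fixed_dataset)
        means = fixed_dataset.to_dataframe().groupby("participant").mean()
        r, p = stats.pearsonr(means["measure2"], means["measure1"])
        assert base.averaged.r == pytest.approx(r)
        assert base.averaged.p_value == pytest.approx(p)

    def test_too_few_participants(self):
        parts = ["a", "a", "b", "b", "b"]
        data = PairedRepeatedData(parts, [1.0, 2, 3, 4, 5], [5.0, 4, 3, 2, 1])
        with pytest.raises(DataInsufficiencyError):
            pearson_baselines(data)

    def test_trial_length_mismatch(self, fixed_dataset):
        with pytest.raises(ConfigurationError):
            pearson_baselines(fixed_dataset, trial=["t1", "t2"])
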