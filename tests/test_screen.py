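import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import instdiffs as idf
from instdiffs.screen import TIER_NS, TIER_P05, TIER_TUKEY


class TestTukeyThreshold:
    @pytest.mark.parametrize(
        "n_tests,expected", [(406, 0.0025), (30, 0.0091), (1, 0.05)]
    )
    def test_known_values(self, n_tests, expected):
        assert round(idf.tukey_threshold(n_tests), 4) == expected

    def test_invalid_count(self):
        with pytest.raises(ValueError):
            idf.tukey_threshold(0)


class TestCriticalR:
    def test_published_two_decimal_value(self):
        assert round(idf.critical_r(29, 0.05), 2) == 0.37

    def test_unrounded_inversion_of_t_quantile(self):
        t = stats.t.ppf(0.975, 27)
        assert idf.critical_r(29, 0.05) == pytest.approx(t / np.sqrt(t**2 + 27))
        assert round(idf.critical_r(29, 0.05), 3) == 0.367

    def test_strictly_decreasing_in_n(self):
        values = [idf.critical_r(n, 0.05) for n in range(5, 100, 7)]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_critical_r_gives_50_percent_power_not_80(self):
        # detecting rho equal to the critical r has ~50% power; 80%
        # power at alpha=0.05, n=29 needs a substantially larger rho
        r_crit = idf.critical_r(29, 0.05)
        assert idf.screen.correlation_power(r_crit, 29) == pytest.approx(0.5, abs=0.05)
        assert idf.screen.correlation_power(0.50, 29) == pytest.approx(0.8, abs=0.05)


class TestCorrelationScreen:
    def test_perfect_correlation_reaches_tukey_tier(self):
        x = np.arange(10.0)
        rng = np.random.default_rng(0)
        values = pd.DataFrame(
            {"x": x, "y": 2 * x, "z": rng.standard_normal(10)}
        )
        screen = idf.correlation_screen(values)
        assert screen.r.loc["x", "y"] == pytest.approx(1.0)
        assert screen.tier.loc["x", "y"] == TIER_TUKEY

    def test_symmetry_and_unit_diagonal(self, noise_matrix):
        screen = idf.correlation_screen(noise_matrix(20, 8, 1))
        assert np.allclose(screen.r, screen.r.T)
        assert np.allclose(screen.p, screen.p.T)
        assert np.allclose(np.diag(screen.r), 1.0)

    def test_effective_tests_use_rank_bound_when_auto(self, noise_matrix):
        screen = idf.correlation_screen(noise_matrix(29, 50, 2))
        assert screen.n_pairs == 1225
        assert screen.effective_tests == 406
        assert screen.tukey_alpha == pytest.approx(0.0025, abs=5e-5)

    def test_tier_counts_sum_and_ordering(self, noise_matrix):
        screen = idf.correlation_screen(noise_matrix(29, 30, 3))
        counts = screen.tier_counts()
        assert sum(counts.values()) == screen.n_pairs
        assert screen.n_significant(TIER_TUKEY) <= screen.n_significant(TIER_P05)

    def test_p05_tier_agrees_with_critical_r(self, noise_matrix):
        screen = idf.correlation_screen(noise_matrix(25, 12, 4))
        r_crit = idf.critical_r(25, 0.05)
        iu = np.triu_indices(12, k=1)
        sig = np.abs(screen.r.to_numpy()[iu]) > r_crit
        tiers = screen.tier.to_numpy()[iu]
        assert np.array_equal(sig, tiers != TIER_NS)

    def test_constant_column_rejected(self):
        values = pd.DataFrame({"a": [1.0] * 6, "b": np.arange(6.0)})
        with pytest.raises(ValueError, match="constant"):
            idf.correlation_screen(values)

    def test_long_format_export(self, noise_matrix):
        screen = idf.correlation_screen(noise_matrix(10, 5, 5))
        long = screen.to_long()
        assert len(long) == 10
        assert set(long.columns) == {"measure_a", "measure_b", "r", "p", "tier"}


class TestGroupCompare:
    def test_identical_groups_give_t_zero_p_one(self):
        block = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        values = pd.concat([block, block], ignore_index=True)
        comp = idf.group_compare(idf.SchoolMeasureMatrix(values), [True] * 3 + [False] * 3)
        assert np.allclose(comp.table["t"], 0.0)
        assert np.allclose(comp.table["p"], 1.0)

    def test_welch_statistics_match_scipy_oracle(self, noise_matrix):
        matrix = noise_matrix(20, 6, 6)
        flag = np.arange(20) < 8
        comp = idf.group_compare(matrix, flag)
        for m in matrix.measure_names:
            ref = stats.ttest_ind(
                matrix.values.loc[flag, m], matrix.values.loc[~flag, m], equal_var=False
            )
            assert comp.table.loc[m, "t"] == pytest.approx(ref.statistic)
            assert comp.table.loc[m, "p"] == pytest.approx(ref.pvalue)

    def test_divisor_parameter_controls_family_threshold(self, noise_matrix):
        matrix = noise_matrix(12, 49, 7)
        flag = np.arange(12) < 6
        default = idf.group_compare(matrix, flag)
        adjusted = idf.group_compare(matrix, flag, tukey_divisor=48)
        assert default.tukey_alpha == pytest.approx(0.05 / np.sqrt(49))
        assert adjusted.tukey_alpha == pytest.approx(0.0072, abs=1e-4)

    def test_tiny_group_rejected(self, noise_matrix):
        with pytest.raises(ValueError):
            idf.group_compare(noise_matrix(5, 3, 8), [True] + [False] * 4)


class TestPartialCorrelation:
    def test_no_controls_reduces_to_pearson(self, noise_matrix):
        matrix = noise_matrix(25, 5, 9)
        pc = idf.partial_correlation(matrix, "m00", "m01")
        r = matrix.values["m00"].corr(matrix.values["m01"])
        assert pc.r_p == pytest.approx(r)
        assert pc.df == 23

    @given(seed=st.integers(0, 1000))
    def test_single_control_matches_closed_form(self, seed):
        rng = np.random.default_rng(seed)
        values = pd.DataFrame(
            rng.standard_normal((20, 3)) + 0.5 * rng.standard_normal((20, 1)),
            columns=["x", "y", "z"],
        )
        pc = idf.partial_correlation(idf.SchoolMeasureMatrix(values), "x", "y", ["z"])
        c = values.corr()
        expected = (c.loc["x", "y"] - c.loc["x", "z"] * c.loc["y", "z"]) / np.sqrt(
            (1 - c.loc["x", "z"] ** 2) * (1 - c.loc["y", "z"] ** 2)
        )
        assert pc.r_p == pytest.approx(expected, abs=1e-10)
        assert pc.df == 20 - 3

    def test_matches_pingouin(self, noise_matrix):
        pingouin = pytest.importorskip("pingouin")
        matrix = noise_matrix(30, 6, 10)
        pc = idf.partial_correlation(matrix, "m00", "m01", ["m02", "m03"])
        ref = pingouin.partial_corr(
            data=matrix.values, x="m00", y="m01", covar=["m02", "m03"]
        )
        assert pc.r_p == pytest.approx(float(ref["r"].iloc[0]), abs=1e-8)
        assert pc.p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-8)

    def test_control_duplicating_x_rejected(self, noise_matrix):
        with pytest.raises(ValueError, match="controls"):
            idf.partial_correlation(noise_matrix(10, 4, 11), "m00", "m01", ["m00"])

    def test_collinear_controls_rejected(self):
        rng = np.random.default_rng(12)
        v = pd.DataFrame(rng.standard_normal((15, 3)), columns=["x", "y", "z1"])
        v["z2"] = 2 * v["z1"]
        with pytest.raises(ValueError, match="collinear"):
            idf.partial_correlation(
                idf.SchoolMeasureMatrix(v), "x", "y", ["z1", "z2"]
            )


class TestLinearFit:
    def test_noiseless_line_recovered_exactly(self):
        x = np.linspace(0, 10, 12)
        values = pd.DataFrame({"x": x, "y": 3 + 2 * x})
        intercept, slope, predict = idf.linear_fit(
            idf.SchoolMeasureMatrix(values), y="y", x="x"
        )
        assert intercept == pytest.approx(3.0)
        assert slope == pytest.approx(2.0)
        assert predict(600) == pytest.approx(3 + 2 * 600)

    def test_zero_variance_predictor_rejected(self):
        values = pd.DataFrame({"x": [1.0] * 5, "y": np.arange(5.0)})
        with pytest.raises(ValueError, match="zero variance"):
            idf.linear_fit(idf.SchoolMeasureMatrix(values), y="y", x="x")


class TestNullCalibration:
    def test_type_one_rate_near_nominal(self):
        out = idf.null_calibration(29, 50, reps=200, seed=123)
        assert out["prop_p05"] == pytest.approx(0.050, abs=0.005)
        # the Tukey tier proportion should sit near its own alpha
        assert out["prop_tukey"] == pytest.approx(0.0025, abs=0.002)

    def test_single_rep_reproducible(self):
        a = idf.null_calibration(15, 10, reps=1, seed=5)
        b = idf.null_calibration(15, 10, reps=1, seed=5)
        assert a.equals(b)
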