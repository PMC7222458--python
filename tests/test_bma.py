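import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from itertools import combinations
from scipy import integrate

import instdiffs as idf
from instdiffs.bma import (
    bf_to_pip,
    evidence_tier,
    log_marginal_likelihood,
    pip_to_bf,
    small_model_fit,
)


def brute_force_bma(y, X, g):
    """Naive model-by-model enumeration used as an independent oracle."""
    names = list(X.columns)
    lmls = {}
    for size in range(len(names) + 1):
        for sub in combinations(names, size):
            block = X.loc[:, list(sub)] if sub else None
            lmls[sub] = log_marginal_likelihood(y, block, g)
    mx = max(lmls.values())
    weights = {s: np.exp(v - mx) for s, v in lmls.items()}
    total = sum(weights.values())
    post = {s: w / total for s, w in weights.items()}
    pip = {c: sum(p for s, p in post.items() if c in s) for c in names}
    return post, pip


class TestLogMarginalLikelihood:
    def test_null_model_scores_zero(self):
        y = np.arange(10.0)
        assert log_marginal_likelihood(y, None, g=10.0) == 0.0

    def test_uncorrelated_predictor_pays_pure_penalty(self):
        # x exactly orthogonal to y in-sample: R^2 = 0, so the log BF
        # reduces to -(k/2) ln(1+g)
        rng = np.random.default_rng(1)
        y = rng.standard_normal(30)
        x = rng.standard_normal(30)
        yc = (y - y.mean()) / y.std(ddof=1)
        x = x - x @ yc / (yc @ yc) * yc  # orthogonalize against y
        g = 30.0
        got = log_marginal_likelihood(y, pd.DataFrame({"x": x}), g)
        assert got == pytest.approx(-0.5 * np.log1p(g), abs=1e-10)

    def test_matches_numerical_integration_of_g_prior(self):
        # 2D quadrature over (slope, residual variance) with the flat
        # intercept integrated analytically; n=8 toy data
        rng = np.random.default_rng(7)
        n, g = 8, 8.0
        x = rng.standard_normal(n)
        y = 0.9 * x + rng.standard_normal(n) * 0.7
        xc, yc = x - x.mean(), y - y.mean()
        sxx = float(xc @ xc)

        def like_given_b(b, v):
            ss = float((yc - b * xc) @ (yc - b * xc))
            return (2 * np.pi * v / n) ** 0.5 * (2 * np.pi * v) ** (-n / 2) * np.exp(
                -ss / (2 * v)
            )

        def m1_integrand(b, v):
            prior_b = (2 * np.pi * g * v / sxx) ** -0.5 * np.exp(
                -(b**2) * sxx / (2 * g * v)
            )
            return like_given_b(b, v) * prior_b / v  # Jeffreys 1/v

        def m0_integrand(v):
            return like_given_b(0.0, v) / v

        m1, _ = integrate.dblquad(
            m1_integrand, 1e-6, 400.0, lambda v: -30, lambda v: 30,
            epsabs=0, epsrel=1e-11,
        )
        m0, _ = integrate.quad(
            m0_integrand, 1e-6, 400.0, epsabs=0, epsrel=1e-11, limit=400
        )
        expected = np.log(m1 / m0)
        got = log_marginal_likelihood(y, pd.DataFrame({"x": x}), g)
        assert got == pytest.approx(expected, abs=1e-6)

    def test_singular_design_rejected(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(20)
        X = pd.DataFrame({"a": x, "b": 2 * x})
        with pytest.raises(ValueError, match="singular"):
            log_marginal_likelihood(rng.standard_normal(20), X, g=20.0)


class TestEnumerateBMA:
    def test_matches_brute_force_oracle(self, noise_matrix):
        matrix = noise_matrix(25, 6, 17)
        X = matrix.values.iloc[:, :5]
        y = matrix.values.iloc[:, 5]
        g = 25.0
        fit = idf.enumerate_bma(y, X, g=g)
        post, pip = brute_force_bma(y, X, g)
        assert len(fit.model_posteriors) == 2**5
        assert sum(fit.model_posteriors.values()) == pytest.approx(1.0, abs=1e-10)
        for sub, prob in post.items():
            assert fit.model_posteriors[sub] == pytest.approx(prob, abs=1e-10)
        for c in X.columns:
            assert fit.pip[c] == pytest.approx(pip[c], abs=1e-10)

    def test_recovers_true_predictor_among_noise(self):
        rng = np.random.default_rng(11)
        n = 200
        x1 = rng.standard_normal(n)
        X = pd.DataFrame(
            np.column_stack([x1, rng.standard_normal((n, 4))]),
            columns=["x1", "n1", "n2", "n3", "n4"],
        )
        y = 0.8 * x1 + rng.standard_normal(n) * 0.6
        fit = idf.enumerate_bma(y, X)
        assert fit.pip["x1"] > 0.99
        assert (fit.pip[["n1", "n2", "n3", "n4"]] < 0.5).all()

    def test_orthogonal_candidate_dilutes_others_exactly(self):
        # appending a candidate exactly orthogonal (in-sample) to y and
        # to the others multiplies every containing model's weight by
        # (1+g)^{-1/2}, leaving other PIPs unchanged
        rng = np.random.default_rng(23)
        n = 40
        X = pd.DataFrame(rng.standard_normal((n, 2)), columns=["a", "b"])
        y = pd.Series(0.5 * X["a"] + rng.standard_normal(n), name="y")
        basis = np.column_stack(
            [np.ones(n), X.to_numpy(), np.asarray(y)]
        )
        z = rng.standard_normal(n)
        z = z - basis @ np.linalg.lstsq(basis, z, rcond=None)[0]
        g = float(n)
        base = idf.enumerate_bma(y, X, g=g)
        ext = idf.enumerate_bma(y, X.assign(z=z), g=g)
        for c in ["a", "b"]:
            assert ext.pip[c] == pytest.approx(base.pip[c], abs=1e-10)
        f = (1 + g) ** -0.5
        assert ext.pip["z"] == pytest.approx(f / (1 + f), abs=1e-10)

    def test_enumeration_guard(self, noise_matrix):
        matrix = noise_matrix(30, 22, 19)
        with pytest.raises(ValueError, match="rotation_select"):
            idf.enumerate_bma(
                matrix.values.iloc[:, 0], matrix.values.iloc[:, 1:], g=30.0
            )


class TestPipBfMapping:
    @pytest.mark.parametrize("pip,bf", [(0.75, 3.0), (0.5, 1.0)])
    def test_known_equivalences(self, pip, bf):
        assert pip_to_bf(pip) == pytest.approx(bf)

    def test_91_percent_is_about_bf_10(self):
        assert pip_to_bf(0.91) == pytest.approx(10.1, abs=0.02)

    def test_pip_one_is_infinite_strongest_tier(self):
        assert np.isinf(pip_to_bf(1.0))
        assert evidence_tier(pip_to_bf(1.0)) == "strong100"

    @given(st.floats(0.001, 0.999))
    def test_round_trip_identity(self, pip):
        assert bf_to_pip(pip_to_bf(pip)) == pytest.approx(pip, abs=1e-12)

    @pytest.mark.parametrize(
        "bf,tier",
        [
            (0.05, "null_strong"),
            (0.2, "null_moderate"),
            (1.0, "inconclusive"),
            (5.0, "moderate"),
            (15.0, "strong10"),
            (50.0, "strong30"),
            (500.0, "strong100"),
        ],
    )
    def test_tier_boundaries(self, bf, tier):
        assert evidence_tier(bf) == tier


class TestRotationSelect:
    def test_small_candidate_set_equals_one_shot_enumeration(self, noise_matrix):
        matrix = noise_matrix(30, 8, 29)
        y = matrix.values.iloc[:, 0]
        X = matrix.values.iloc[:, 1:]
        rot = idf.rotation_select(y, X)
        full = idf.enumerate_bma(y, X)
        pd.testing.assert_series_equal(rot.pip, full.pip)

    def test_true_predictor_last_in_proximity_survives(self):
        rng = np.random.default_rng(7)
        n = 100
        X = pd.DataFrame(
            rng.standard_normal((n, 12)), columns=[f"c{i:02d}" for i in range(12)]
        )
        y = 0.7 * X["c00"] + rng.standard_normal(n) * np.sqrt(1 - 0.49)
        order = [f"c{i:02d}" for i in range(1, 12)] + ["c00"]  # true one last
        rot = idf.rotation_select(y, X.loc[:, order])
        full = idf.enumerate_bma(y, X.loc[:, order])
        assert abs(rot.pip["c00"] - full.pip["c00"]) < 0.02
        assert rot.bf["c00"] > 100

    def test_false_inclusion_rate_on_noise_below_one_per_response(self):
        rng = np.random.default_rng(123)
        counts = []
        for _ in range(200):
            X = pd.DataFrame(
                rng.standard_normal((29, 12)), columns=[f"c{i}" for i in range(12)]
            )
            y = rng.standard_normal(29)
            fit = idf.rotation_select(y, X)
            counts.append(int((fit.bf >= 3).sum()))
        assert np.mean(counts) < 1.0

    def test_tiny_candidate_set_deferred_to_small_model(self, noise_matrix):
        matrix = noise_matrix(20, 4, 31)
        with pytest.raises(ValueError, match="small_model_fit"):
            idf.rotation_select(matrix.values.iloc[:, 0], matrix.values.iloc[:, 1:])


class TestSmallModelFit:
    def test_zero_candidates_gives_empty_inclusion(self):
        fit = small_model_fit(np.arange(10.0), pd.DataFrame(index=range(10)))
        assert fit.included == []

    def test_single_strong_predictor_power(self):
        rng = np.random.default_rng(41)
        hits = 0
        for _ in range(60):
            x = rng.standard_normal(29)
            y = 0.9 * x + rng.standard_normal(29) * np.sqrt(1 - 0.81)
            fit = small_model_fit(y, pd.DataFrame({"x": x}))
            hits += "x" in fit.included
        assert hits / 60 > 0.95

    def test_duplicate_candidate_columns_rejected(self):
        rng = np.random.default_rng(43)
        x = rng.standard_normal(20)
        X = pd.DataFrame({"a": x, "b": x})
        with pytest.raises(ValueError, match="collinear"):
            small_model_fit(rng.standard_normal(20), X)

    def test_more_than_three_candidates_rejected(self, noise_matrix):
        matrix = noise_matrix(20, 5, 47)
        with pytest.raises(ValueError, match="at most 3"):
            small_model_fit(matrix.values.iloc[:, 0], matrix.values.iloc[:, 1:])


class TestParameterRecovery:
    def test_conditional_betas_close_to_generating_paths(self):
        spec = idf.SyntheticSpec(
            nodes=[("a", 1), ("b", 2), ("c", 3), ("y", 4)],
            edges=[("a", "y", 0.5), ("b", "y", -0.6)],
            n_units=200,
            seed=54,
        )
        matrix = idf.generate_from_dag(spec)
        fit = idf.enumerate_bma(
            matrix.values["y"], matrix.values[["a", "b", "c"]]
        )
        assert fit.beta_conditional["a"] == pytest.approx(0.5, abs=0.1)
        assert fit.beta_conditional["b"] == pytest.approx(-0.6, abs=0.1)
        assert fit.pip["c"] < 0.5
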