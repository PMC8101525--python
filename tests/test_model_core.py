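import math

import numpy as np
import pytest
from scipy import integrate, stats

from curefrail import (
    CureModelParams,
    Dataset,
    cure_probability,
    latency_density,
    latency_survival,
    log_likelihood,
    population_survival,
    weibull_cumhaz,
)
from curefrail.model_core import read_dataset_csv


class TestWeibullCumhaz:
    @pytest.mark.parametrize("t,shape,scale,expected", [
        (0.0, 1.01, 2.2, 0.0),
        (1.0, 0.7, 3.3, 3.3),
        (1.0, 2.5, 0.4, 0.4),
        (2.0, 2.0, 0.5, 2.0),
    ])
    def test_values(self, t, shape, scale, expected):
        assert weibull_cumhaz(t, shape, scale) == pytest.approx(expected)

    def test_nondecreasing_in_t(self):
        t = np.linspace(0, 50, 200)
        h = weibull_cumhaz(t, 0.8, 0.3)
        assert np.all(np.diff(h) >= 0)

    @pytest.mark.parametrize("t,shape,scale", [(-1, 1, 1), (1, 0, 1), (1, 1, -2)])
    def test_domain_errors(self, t, shape, scale):
        with pytest.raises(ValueError):
            weibull_cumhaz(t, shape, scale)


class TestCureProbability:
    def test_zero_linear_predictor_is_half(self):
        assert float(cure_probability([0.0, 0.0], 0.0, [1.2, -3.0])) == pytest.approx(0.5)

    def test_logistic_of_log3(self):
        assert float(cure_probability([1.0], 0.0, [math.log(3)])) == pytest.approx(0.75)

    def test_large_intercept_saturates(self):
        assert float(cure_probability([0.0], 30.0, [1.0])) == pytest.approx(1.0, abs=1e-9)

    def test_strictly_increasing_in_intercept(self):
        vals = [float(cure_probability([0.3], b0, [0.5])) for b0 in (-1, 0, 1, 2)]
        assert np.all(np.diff(vals) > 0)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            cure_probability([1.0, 2.0], 0.0, [1.0])


def _quadrature_uncured_survival(t, eta, params):
    """Independent oracle: integrate the conditional Weibull-PH survival
    against the Gamma(theta, theta) frailty density."""
    h = params.scale * t ** params.shape

    def integrand(w):
        return math.exp(-w * h * math.exp(eta)) * stats.gamma.pdf(
            w, a=params.theta, scale=1.0 / params.theta)

    val, err = integrate.quad(integrand, 0, np.inf, limit=200)
    return val


class TestLatencySurvival:
    def test_survival_at_origin_is_one(self):
        p = CureModelParams(b0=0, b=[], beta=[0.7], shape=1.3, scale=0.2, theta=0.8)
        assert latency_survival(0.0, [1.0], p) == pytest.approx(1.0)

    def test_matches_frailty_quadrature(self):
        p = CureModelParams(b0=0, b=[], beta=[1.0], shape=1.0, scale=0.1, theta=2.0)
        expected = _quadrature_uncured_survival(5.0, 0.0, p)
        assert latency_survival(5.0, [0.0], p) == pytest.approx(expected, abs=1e-8)

    def test_no_frailty_limit(self):
        p = CureModelParams(b0=0, b=[], beta=[0.0], shape=1.0, scale=0.1, theta=1e6)
        assert latency_survival(5.0, [0.0], p) == pytest.approx(math.exp(-0.5), abs=1e-4)

    def test_nonincreasing_in_t(self):
        p = CureModelParams(b0=0, b=[], beta=[0.4], shape=0.7, scale=0.3, theta=1.5)
        t = np.linspace(0, 80, 300)
        s = latency_survival(t, [1.0], p)
        assert np.all(np.diff(s) <= 0)


class TestLatencyDensity:
    def test_requires_positive_t(self):
        p = CureModelParams(b0=0, b=[], beta=[], shape=1.0, scale=0.5, theta=1.0)
        with pytest.raises(ValueError):
            latency_density(0.0, [], p)

    def test_matches_numeric_derivative_of_survival(self):
        p = CureModelParams(b0=0, b=[], beta=[0.3], shape=1.4, scale=0.08, theta=3.0)
        eps = 1e-6
        num = (latency_survival(3 - eps, [1.0], p)
               - latency_survival(3 + eps, [1.0], p)) / (2 * eps)
        assert latency_density(3.0, [1.0], p) == pytest.approx(num, abs=1e-6)

    @pytest.mark.parametrize("shape,scale,theta,eta", [
        (0.8, 0.3, 0.7, 0.4), (1.5, 0.05, 2.5, -0.6), (1.0, 0.2, 10.0, 0.0),
    ])
    def test_integrates_to_one(self, shape, scale, theta, eta):
        p = CureModelParams(b0=0, b=[], beta=[eta], shape=shape, scale=scale,
                            theta=theta)
        val, _ = integrate.quad(lambda t: latency_density(t, [1.0], p),
                                0, np.inf, limit=300)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_exponential_limit(self):
        p = CureModelParams(b0=0, b=[], beta=[], shape=1.0, scale=0.3, theta=1e7)
        t = np.array([0.5, 2.0, 7.0])
        assert latency_density(t, [], p) == pytest.approx(
            0.3 * np.exp(-0.3 * t), abs=1e-5)


class TestPopulationSurvival:
    def test_starts_at_one_and_plateaus_at_cure_probability(self):
        p = CureModelParams(b0=-0.5, b=[0.8], beta=[0.2], shape=1.1, scale=0.2,
                            theta=2.0)
        pi = float(cure_probability([1.0], p.b0, p.b))
        assert population_survival(0.0, [1.0], [1.0], p) == pytest.approx(1.0)
        assert population_survival(1e9, [1.0], [1.0], p) == pytest.approx(pi, abs=1e-4)

    def test_mixture_arithmetic(self):
        # pi = 0.3 and S_u(t*) = 0.5 must combine to 0.65
        p = CureModelParams(b0=math.log(0.3 / 0.7), b=[], beta=[], shape=1.0,
                            scale=1.0, theta=1e8)
        # pick t* so that H0(t*) = log 2 under the near-exponential latency
        t_star = math.log(2.0)
        assert population_survival(t_star, [], [], p) == pytest.approx(0.65, abs=1e-6)

    def test_bounded_by_cure_probability_and_one(self):
        p = CureModelParams(b0=0.2, b=[-0.4], beta=[0.5], shape=0.9, scale=0.15,
                            theta=1.2)
        pi = float(cure_probability([1.0], p.b0, p.b))
        for t in np.linspace(0, 500, 50):
            s = population_survival(t, [1.0], [1.0], p)
            assert pi - 1e-12 <= s <= 1.0 + 1e-12


class TestLogLikelihood:
    def test_hand_computed_toy(self, toy_dataset, toy_params):
        # independent hand computation with the exact frailty formulas
        th = toy_params.theta
        f1 = 0.5 * (1 + 0.5 / th) ** (-th - 1)       # h0(1)=0.5, H0(1)=0.5
        s2 = (1 + 1.0 / th) ** (-th)                 # H0(2)=1
        expected = math.log(0.5 * f1) + math.log(0.5 + 0.5 * s2)
        assert log_likelihood(toy_dataset, toy_params) == pytest.approx(
            expected, abs=1e-6)

    def test_additivity_under_duplication(self, toy_dataset, toy_params):
        doubled = Dataset(
            np.concatenate([toy_dataset.time] * 2),
            np.concatenate([toy_dataset.event] * 2),
            np.vstack([toy_dataset.covariates] * 2),
            covariate_names=[],
        )
        assert log_likelihood(doubled, toy_params) == pytest.approx(
            2 * log_likelihood(toy_dataset, toy_params))

    def test_permutation_invariance(self, registry_cohort):
        data = registry_cohort(n=200, seed=11)
        perm = np.random.default_rng(0).permutation(data.n)
        shuffled = data.subset(perm)
        p = CureModelParams(b0=-0.8, b=np.log([1.5, 3.0, 0.4]),
                            beta=[-0.35, -0.98, 0.4], shape=0.83, scale=0.22,
                            theta=2.0)
        assert log_likelihood(shuffled, p) == pytest.approx(
            log_likelihood(data, p), rel=1e-12)

    def test_event_at_time_zero_rejected(self):
        with pytest.raises(ValueError, match="time 0"):
            Dataset([0.0, 2.0], [1, 0], np.empty((2, 0)), covariate_names=[])

    def test_dimension_mismatch(self, toy_dataset):
        p = CureModelParams(b0=0.0, b=[1.0], beta=[], shape=1.0, scale=1.0,
                            theta=1.0)
        with pytest.raises(ValueError):
            log_likelihood(toy_dataset, p)


class TestCsvRoundTrip:
    def test_dummy_coding_and_references(self, tmp_path):
        import pandas as pd

        df = pd.DataFrame({
            "time": [1.0, 2.0, 3.0, 4.0],
            "event": [1, 0, 1, 0],
            "treated": ["yes", "no", "no", "yes"],
            "age": [60.0, 71.0, 55.0, 62.0],
        })
        path = tmp_path / "cohort.csv"
        df.to_csv(path, index=False)
        data = read_dataset_csv(path, reference_levels={"treated": "no"})
        assert data.covariate_names == ["treated:yes", "age"]
        assert data.reference_levels["treated"] == "no"
        np.testing.assert_allclose(
            data.covariates[:, 0], [1.0, 0.0, 0.0, 1.0])

    def test_missing_values_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("time,event,x\n1.0,1,0.5\n2.0,0,\n")
        with pytest.raises(ValueError, match="missing"):
            read_dataset_csv(path)

    def test_missing_required_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("time,x\n1.0,0.5\n")
        with pytest.raises(ValueError, match="event"):
            read_dataset_csv(path)
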