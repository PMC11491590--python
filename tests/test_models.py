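import numpy as np
import pytest
from scipy.optimize import minimize_scalar
from scipy.stats import multivariate_normal

from caratlas.graph import ValidationError, build_graph, leroux_precision
from caratlas.models import (
    IncidenceData,
    ModelParams,
    PriorConfig,
    SurvivalData,
    car_logprior,
    excess_hazard_loglik,
    hyper_logprior,
    incidence_loglik,
    log_posterior,
)


def inc(y, E, ids=None):
    y, E = np.atleast_1d(np.asarray(y, float)), np.atleast_1d(np.asarray(E, float))
    if ids is None:
        # match the conftest path-graph ids for small sizes
        ids = tuple("ABCDEFGH"[: y.size])
    return IncidenceData(area_ids=tuple(ids), observed=y, expected=E)


class TestIncidenceLoglik:
    @pytest.mark.parametrize("y,expected_ll", [
        (0.0, -1.0),                       # Poisson(1) at 0
        (2.0, -1.0 - np.log(2.0)),         # 2*log1*... = -1.6931471805599454
    ])
    def test_single_area_values(self, y, expected_ll):
        data = inc([y], [1.0])
        assert incidence_loglik(data, 0.0, np.zeros(1)) == pytest.approx(expected_ll)

    def test_additive_over_areas(self):
        one = incidence_loglik(inc([3], [2.0]), 0.1, np.array([0.2]))
        two = incidence_loglik(inc([3, 3], [2.0, 2.0]), 0.1, np.array([0.2, 0.2]))
        assert two == pytest.approx(2 * one)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            incidence_loglik(inc([1], [1.0]), 0.0, np.zeros(2))

    def test_mle_of_mu_is_log_ratio_of_totals(self):
        data = inc([4, 7, 2], [3.0, 5.0, 1.5])
        res = minimize_scalar(
            lambda m: -incidence_loglik(data, m, np.zeros(3)),
            bounds=(-3, 3), method="bounded",
        )
        expected = np.log(13.0 / 9.5)
        assert res.x == pytest.approx(expected, abs=1e-5)


class TestExcessHazardLoglik:
    def surv(self, d, e, t):
        d = np.atleast_2d(np.asarray(d, float))
        ids = tuple(f"a{k}" for k in range(d.shape[0]))
        return SurvivalData(area_ids=ids, deaths=d,
                            expected_deaths=np.atleast_2d(np.asarray(e, float)),
                            person_time=np.atleast_2d(np.asarray(t, float)))

    def test_mean_one_no_deaths(self):
        data = self.surv([[0]], [[0.5]], [[1.0]])
        ll = excess_hazard_loglik(data, np.array([0.5]), np.zeros(1))
        assert ll == pytest.approx(-1.0)

    def test_mean_one_single_death(self):
        data = self.surv([[1]], [[0.0]], [[2.0]])
        ll = excess_hazard_loglik(data, np.array([0.5]), np.zeros(1))
        assert ll == pytest.approx(-1.0)

    def test_large_negative_s_reduces_to_background(self):
        data = self.surv([[3, 1]], [[2.0, 1.5]], [[1.0, 1.0]])
        ll = excess_hazard_loglik(data, np.array([0.5, 0.5]), np.array([-40.0]))
        background = (3 * np.log(2.0) - 2.0 - np.log(6.0)
                      + 1 * np.log(1.5) - 1.5)
        assert ll == pytest.approx(background, rel=1e-6)

    def test_zero_mean_with_deaths_flags_minus_inf(self):
        data = self.surv([[2]], [[0.0]], [[1.0]])
        ll = excess_hazard_loglik(data, np.array([1e-300]), np.array([-720.0]))
        assert ll == -np.inf


class TestLogPosterior:
    def test_iid_prior_at_zero(self, path_graph):
        S = np.zeros(3)
        sigma2 = 0.7
        lp = car_logprior(S, path_graph, 0.0, sigma2)
        assert lp == pytest.approx(-1.5 * np.log(2 * np.pi * sigma2))

    def test_decomposes_into_components(self, path_graph):
        data = inc([2, 5, 1], [1.5, 3.0, 0.8])
        params = ModelParams(S=np.array([0.1, -0.2, 0.3]), rho=0.4,
                             sigma2=0.5, mu=0.2)
        priors = PriorConfig()
        total = log_posterior(params, data, path_graph, priors)
        parts = (incidence_loglik(data, params.mu, params.S)
                 + car_logprior(params.S, path_graph, params.rho, params.sigma2)
                 + hyper_logprior(params, priors))
        assert total == pytest.approx(parts)

    def test_car_prior_matches_dense_mvn(self, path_graph):
        # brute-force oracle: dense covariance multivariate normal
        S = np.array([0.3, -0.1, 0.25])
        rho, sigma2 = 0.6, 0.4
        Q = leroux_precision(path_graph, rho, sigma2).toarray()
        oracle = multivariate_normal(mean=np.zeros(3),
                                     cov=np.linalg.inv(Q)).logpdf(S)
        assert car_logprior(S, path_graph, rho, sigma2) == pytest.approx(oracle)

    def test_continuity_near_domain_interior(self, path_graph):
        data = inc([2, 5, 1], [1.5, 3.0, 0.8])
        base = ModelParams(S=np.zeros(3), rho=0.5, sigma2=0.2, mu=0.0)
        lp0 = log_posterior(base, data, path_graph)
        eps = 1e-6
        bumped = ModelParams(S=np.zeros(3) + eps, rho=0.5 + eps,
                             sigma2=0.2 + eps, mu=eps)
        assert abs(log_posterior(bumped, data, path_graph) - lp0) < 1e-3

    def test_graph_data_mismatch_rejected(self):
        g = build_graph([], ["X"])
        data = inc([1], [1.0])
        with pytest.raises(ValidationError):
            log_posterior(ModelParams(S=np.zeros(1), rho=0.1, sigma2=1.0),
                          data, g)


class TestDataValidation:
    def test_nonpositive_expected_rejected(self):
        with pytest.raises(ValidationError):
            inc([1], [0.0])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            inc([-1], [1.0])

    def test_nonpositive_person_time_rejected(self):
        with pytest.raises(ValidationError):
            SurvivalData(area_ids=("a",), deaths=np.zeros((1, 1)),
                         expected_deaths=np.zeros((1, 1)),
                         person_time=np.zeros((1, 1)))
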