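import numpy as np
import pytest
from scipy import stats
from scipy.special import expit

from apomap.data import PanelData
from apomap.graph import path_graph
from apomap.model import (HyperPriors, ModelConfig, ModelParams,
                          apply_constraints, initial_params, linear_predictor,
                          log_likelihood, log_posterior, log_prior)
from apomap.simulate import GeneratorConfig, generate_dataset, generate_lattice


def _blank_panel(N, J, K, n=10):
    return PanelData(Y=np.zeros((N, J, K), dtype=int),
                     n=np.full((N, J), n, dtype=int),
                     observed_mask=np.ones((N, J, K), dtype=bool),
                     area_ids=tuple(f"a{i}" for i in range(N)),
                     periods=tuple(range(J)),
                     outcomes=tuple(f"o{k}" for k in range(K)))


def _zero_params(N, J, K):
    return ModelParams(alpha=np.zeros(K), gamma_s=np.ones(K),
                       gamma_t=np.ones(K), u_s=np.zeros(N),
                       u_sk=np.zeros((N, K)), u_t=np.zeros(J),
                       u_tk=np.zeros((J, K)), nu=np.zeros((N, J)))


def _random_constrained(N, J, K, graph, rng, config=None):
    lg_s = rng.normal(0, 0.3, K)
    lg_t = rng.normal(0, 0.3, K)
    p = ModelParams(
        alpha=rng.normal(-3, 0.5, K),
        gamma_s=np.exp(lg_s - lg_s.mean()), gamma_t=np.exp(lg_t - lg_t.mean()),
        u_s=rng.normal(0, 0.4, N), u_sk=rng.normal(0, 0.3, (N, K)),
        u_t=rng.normal(0, 0.2, J), u_tk=rng.normal(0, 0.2, (J, K)),
        nu=rng.normal(0, 0.1, (N, J)),
        tau_us=rng.uniform(0.5, 4), tau_usk=rng.uniform(0.5, 4, K),
        tau_ut=rng.uniform(0.5, 4), tau_utk=rng.uniform(0.5, 4, K),
        tau_nu=rng.uniform(0.5, 4))
    return apply_constraints(p, graph, config)


class TestLinearPredictor:
    def test_all_zero_gives_even_odds(self):
        data = _blank_panel(2, 2, 2)
        p = _zero_params(2, 2, 2)
        assert linear_predictor(p, data, 0, 0, 0) == 0.0
        assert expit(0.0) == 0.5

    def test_intercept_only(self):
        data = _blank_panel(2, 2, 2)
        p = _zero_params(2, 2, 2)
        p.alpha[:] = -3.0
        eta = linear_predictor(p, data, 1, 0, 1)
        assert eta == -3.0
        assert expit(eta) == pytest.approx(1 / (1 + np.e ** 3), rel=1e-12)
        assert expit(eta) == pytest.approx(0.0474, abs=5e-4)

    def test_scaled_shared_spatial_term(self):
        data = _blank_panel(3, 2, 2)
        p = _zero_params(3, 2, 2)
        p.gamma_s[:] = 2.0
        p.u_s[1] = 0.5
        assert linear_predictor(p, data, 1, 0, 0) == pytest.approx(1.0)

    def test_index_bounds(self):
        data = _blank_panel(2, 2, 2)
        with pytest.raises(IndexError):
            linear_predictor(_zero_params(2, 2, 2), data, 5, 0, 0)


class TestLogLikelihood:
    def test_single_bernoulli_cell(self):
        data = _blank_panel(1, 2, 1, n=1)
        data.observed_mask[:] = False
        data.observed_mask[0, 0, 0] = True        # one cell: Y=0, n=1
        ll = log_likelihood(_zero_params(1, 2, 1), data)
        assert ll == pytest.approx(np.log(0.5), abs=1e-12)

    def test_binomial_pmf_oracle(self):
        data = _blank_panel(1, 2, 1, n=10)
        data.Y[0, 0, 0] = 2
        data.observed_mask[:] = False
        data.observed_mask[0, 0, 0] = True
        ll = log_likelihood(_zero_params(1, 2, 1), data)
        assert ll == pytest.approx(np.log(45) - 10 * np.log(2), abs=1e-10)
        assert ll == pytest.approx(stats.binom.logpmf(2, 10, 0.5), abs=1e-10)

    def test_masking_removes_exactly_one_term(self, rng):
        cfg = GeneratorConfig(n_rows=3, n_cols=3)
        data, graph, truth = generate_dataset(cfg, seed=8)
        full = log_likelihood(truth.params, data)
        masked = log_likelihood(truth.params, data.mask_cells([(2, 1, 3)]))
        eta = linear_predictor(truth.params, data, 2, 1, 3)
        cell = stats.binom.logpmf(data.Y[2, 1, 3], data.n[2, 1],
                                  expit(eta))
        assert full - masked == pytest.approx(cell, abs=1e-8)


class TestLogPrior:
    def test_zero_fields_leave_only_hyperprior_terms(self):
        g = path_graph(3)
        p = _zero_params(3, 2, 2)
        h = HyperPriors()
        lp = log_prior(p, g, h)
        # independent term-by-term oracle at the zero/initial state
        expected = 0.0
        rank_s = 2
        for tau in [1.0] + [1.0] * 2:          # u_s and two u_sk blocks
            expected += 0.5 * rank_s * (np.log(tau) - np.log(2 * np.pi))
        for tau in [1.0] * 3:                  # u_t, u_tk x2 (rank J-1=1)
            expected += 0.5 * 1 * (np.log(tau) - np.log(2 * np.pi))
        expected += 0.5 * (3 * 2 - 1) * (np.log(1.0) - np.log(2 * np.pi))  # nu
        expected += stats.norm.logpdf(np.zeros(2), scale=h.alpha_sd).sum()
        expected += stats.norm.logpdf(np.log(np.ones(4)),
                                      scale=h.log_gamma_sd).sum()
        # 7 precisions: u_s, two u_sk, u_t, two u_tk, nu
        expected += stats.gamma.logpdf(np.ones(7), h.precision_shape,
                                       scale=1 / h.precision_rate).sum()
        assert lp == pytest.approx(expected, abs=1e-8)

    def test_doubling_field_quadruples_penalty(self):
        g = generate_lattice(2, 3)
        rng = np.random.default_rng(0)
        p = _random_constrained(6, 3, 2, g, rng)
        lp1 = log_prior(p, g, HyperPriors())
        pen1 = -0.5 * p.tau_us * float(
            np.sum((p.u_s[[e[0] for e in g.edges]]
                    - p.u_s[[e[1] for e in g.edges]]) ** 2))
        p2 = p.copy()
        p2.u_s = 2 * p.u_s
        lp2 = log_prior(p2, g, HyperPriors())
        assert lp2 - lp1 == pytest.approx(4 * pen1 - pen1, abs=1e-8)

    def test_path_graph_term_by_term_oracle(self):
        """Hand-set state on a 3-area path: every prior term summed
        independently with scipy densities."""
        g = path_graph(3)
        K, J = 2, 3
        p = ModelParams(
            alpha=np.array([-2.0, -3.0]),
            gamma_s=np.array([2.0, 0.5]), gamma_t=np.array([1.25, 0.8]),
            u_s=np.array([0.2, -0.3, 0.1]),
            u_sk=np.array([[0.1, -0.05], [0.0, 0.1], [-0.1, -0.05]]),
            u_t=np.array([0.15, -0.3, 0.15]),
            u_tk=np.array([[0.05, 0.0], [0.0, 0.05], [-0.05, -0.05]]),
            nu=np.full((3, 3), 0.0) + np.array([[0.02, -0.01, -0.01],
                                                [0.0, 0.01, -0.01],
                                                [0.0, 0.0, 0.0]]),
            tau_us=2.0, tau_usk=np.array([3.0, 1.5]),
            tau_ut=4.0, tau_utk=np.array([2.5, 2.0]), tau_nu=5.0,
            beta_s=np.array([0.3]), beta_st=np.array([-0.2]))
        p.nu -= p.nu.mean()
        h = HyperPriors()
        lp = log_prior(p, g, h)

        def icar_term(u, tau, edges, rank):
            q = sum((u[a] - u[b]) ** 2 for a, b in edges)
            return 0.5 * rank * (np.log(tau) - np.log(2 * np.pi)) \
                - 0.5 * tau * q

        edges_s = [(0, 1), (1, 2)]
        edges_t = [(0, 1), (1, 2)]
        expected = icar_term(p.u_s, p.tau_us, edges_s, 2)
        for k in range(K):
            expected += icar_term(p.u_sk[:, k], p.tau_usk[k], edges_s, 2)
        expected += icar_term(p.u_t, p.tau_ut, edges_t, 2)
        for k in range(K):
            expected += icar_term(p.u_tk[:, k], p.tau_utk[k], edges_t, 2)
        expected += 0.5 * (9 - 1) * (np.log(p.tau_nu) - np.log(2 * np.pi)) \
            - 0.5 * p.tau_nu * np.sum(p.nu ** 2)
        expected += stats.norm.logpdf(p.alpha, scale=h.alpha_sd).sum()
        expected += stats.norm.logpdf(p.beta_s, scale=h.beta_sd).sum()
        expected += stats.norm.logpdf(p.beta_st, scale=h.beta_sd).sum()
        expected += stats.norm.logpdf(np.log(p.gamma_s),
                                      scale=h.log_gamma_sd).sum()
        expected += stats.norm.logpdf(np.log(p.gamma_t),
                                      scale=h.log_gamma_sd).sum()
        taus = [p.tau_us, p.tau_ut, p.tau_nu, *p.tau_usk, *p.tau_utk]
        expected += stats.gamma.logpdf(taus, h.precision_shape,
                                       scale=1 / h.precision_rate).sum()
        assert lp == pytest.approx(expected, abs=1e-8)


class TestLogPosterior:
    def test_composition_and_brute_force_oracle(self):
        """Tiny 3-area x 2-period x 2-outcome instance vs an independent
        cell-by-cell + term-by-term summation."""
        g = path_graph(3)
        rng = np.random.default_rng(12)
        p = _random_constrained(3, 2, 2, g, rng)
        data = _blank_panel(3, 2, 2, n=50)
        data.Y[:] = rng.integers(0, 20, (3, 2, 2))
        h = HyperPriors()
        lp = log_posterior(p, data, g, h)
        # oracle: scipy binom per cell + log_prior (itself oracle-checked)
        brute_ll = 0.0
        for i in range(3):
            for j in range(2):
                for k in range(2):
                    eta = linear_predictor(p, data, i, j, k)
                    brute_ll += stats.binom.logpmf(
                        data.Y[i, j, k], data.n[i, j], expit(eta))
        assert lp == pytest.approx(brute_ll + log_prior(p, g, h), abs=1e-8)

    def test_likelihood_dominates_for_outlying_count(self):
        g = path_graph(3)
        rng = np.random.default_rng(3)
        p = _random_constrained(3, 2, 2, g, rng)
        data = _blank_panel(3, 2, 2, n=100)
        data.Y[:] = 5
        base = log_posterior(data=data, params=p, graph=g,
                             hyper=HyperPriors())
        data.Y[0, 0, 0] = 95           # far from n*pi
        worse = log_posterior(data=data, params=p, graph=g,
                              hyper=HyperPriors())
        assert worse < base


class TestApplyConstraints:
    def test_idempotent(self, rng):
        g = generate_lattice(3, 3)
        p = _random_constrained(9, 4, 4, g, np.random.default_rng(5))
        q = apply_constraints(p, g)
        assert np.allclose(q.u_s, p.u_s, atol=1e-12)
        assert np.allclose(q.alpha, p.alpha, atol=1e-12)
        assert np.allclose(q.gamma_t, p.gamma_t, atol=1e-12)

    def test_gamma_product_one_rule(self):
        g = generate_lattice(2, 2)
        p = _zero_params(4, 3, 4)
        p.gamma_t = np.array([2.0, 2.0, 0.5, 0.5])    # geometric mean 1
        q = apply_constraints(p, g)
        assert np.allclose(q.gamma_t, p.gamma_t)
        p.gamma_t = np.array([2.0, 2.0, 2.0, 2.0])
        q = apply_constraints(p, g)
        assert np.allclose(q.gamma_t, 1.0)

    def test_likelihood_invariance_on_random_params(self):
        cfg = GeneratorConfig(n_rows=3, n_cols=4)
        data, graph, _ = generate_dataset(cfg, seed=21)
        for s in range(5):
            rng = np.random.default_rng(100 + s)
            p = _random_constrained(12, 4, 4, graph, rng)
            p.u_s = p.u_s + rng.normal(0, 0.5)
            p.u_sk = p.u_sk + rng.normal(0, 0.5, 4)[None, :]
            p.gamma_t = p.gamma_t * rng.uniform(0.5, 2)
            p.nu = p.nu + 0.2
            before = log_likelihood(p, data)
            after = log_likelihood(apply_constraints(p, graph), data)
            assert after == pytest.approx(before, abs=1e-8)
            apply_constraints(p, graph).validate_constraints(graph)

    def test_literal_spatial_mode_sums_to_zero(self):
        cfg = ModelConfig(literal_spatial_constraint=True)
        g = generate_lattice(2, 2)
        p = _zero_params(4, 3, 4)
        p.gamma_s = np.array([0.5, 0.2, -0.1, 0.8])
        p.u_s = np.array([0.3, -0.1, -0.1, -0.1])
        q = apply_constraints(p, g, cfg)
        assert q.gamma_s.sum() == pytest.approx(0.0, abs=1e-12)
        q.validate_constraints(g, cfg)


def test_initial_params_match_empirical_logit(small_panel):
    data, graph, _ = small_panel
    p = initial_params(data)
    assert np.allclose(p.alpha, data.pooled_logit())
    assert np.all(p.u_s == 0) and np.all(p.gamma_s == 1)
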