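import numpy as np
import pytest
from scipy import stats
from scipy.special import psi

from apomap.data import PanelData
from apomap.graph import icar_quadform
from apomap.mcmc import ChainConfig, SharedComponentModel, run_chains
from apomap.model import HyperPriors, ModelConfig


def _flat_panel(N_rows, N_cols, J, K, n, p, seed):
    rng = np.random.default_rng(seed)
    from apomap.simulate import generate_lattice
    graph = generate_lattice(N_rows, N_cols)
    N = graph.n_areas
    nn = np.full((N, J), n, dtype=int)
    Y = rng.binomial(n, p, (N, J, K))
    data = PanelData(Y=Y, n=nn, observed_mask=np.ones((N, J, K), bool),
                     area_ids=graph.area_ids, periods=tuple(range(J)),
                     outcomes=tuple(f"o{k}" for k in range(K)))
    return data, graph


class TestChainConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            ChainConfig(n_iterations=100, burn_in=100)
        with pytest.raises(ValueError):
            ChainConfig(thin=0)
        with pytest.raises(ValueError):
            ChainConfig(fixed_blocks=("bogus",))

    def test_retained_count(self):
        c = ChainConfig(n_iterations=8000, burn_in=2000, thin=10)
        assert c.n_retained == 600


class TestDeterminism:
    def test_identical_seeds_give_identical_draws(self, small_panel):
        data, graph, _ = small_panel
        cfg = ChainConfig(n_chains=2, n_iterations=400, burn_in=100, thin=2,
                          seeds=(7, 7))
        s = run_chains(data, graph, config=cfg)
        for name in ("alpha", "u_s", "tau_us", "gamma_t", "nu"):
            assert np.array_equal(s.get(name)[0], s.get(name)[1])

    def test_rerun_bit_identical(self, small_panel):
        data, graph, _ = small_panel
        cfg = ChainConfig(n_chains=1, n_iterations=300, burn_in=100, thin=1,
                          base_seed=3)
        s1 = run_chains(data, graph, config=cfg)
        s2 = run_chains(data, graph, config=cfg)
        for name, arr in s1.draws.items():
            assert np.array_equal(arr, s2.draws[name]), name


class TestDegenerateConjugateOracle:
    def test_alpha_matches_beta_binomial_logit_mean(self):
        """With every random effect held at zero the model is a single
        binomial proportion on the logit scale; under an (effectively) flat
        prior the posterior of logit(pi) has mean psi(Y) - psi(n - Y)."""
        data, graph = _flat_panel(2, 2, 2, 1, n=500, p=0.05, seed=9)
        cfg = ChainConfig(
            n_chains=2, n_iterations=4000, burn_in=500, thin=1, base_seed=1,
            fixed_blocks=("u_s", "u_sk", "u_t", "u_tk", "nu",
                          "gamma_s", "gamma_t", "precisions"))
        s = run_chains(data, graph, config=cfg)
        draws = s.stacked("alpha")[:, 0]
        y_tot, n_tot = data.Y.sum(), data.n.sum()
        analytic = psi(y_tot) - psi(n_tot - y_tot)
        # 3 Monte-Carlo SEs with an effective-sample-size correction
        ess = max(50.0, _ess(draws))
        mc_se = draws.std(ddof=1) / np.sqrt(ess)
        assert abs(draws.mean() - analytic) < 3 * mc_se

    def test_fixed_blocks_stay_at_initial_values(self, small_panel):
        data, graph, _ = small_panel
        cfg = ChainConfig(n_chains=1, n_iterations=200, burn_in=50, thin=1,
                          base_seed=2,
                          fixed_blocks=("u_s", "gamma_s", "gamma_t"))
        s = run_chains(data, graph, config=cfg)
        assert np.all(s.get("u_s") == 0)
        assert np.all(s.get("gamma_s") == 1)


def _ess(x):
    """Crude autocorrelation-based effective sample size."""
    x = x - x.mean()
    n = len(x)
    acf = np.correlate(x, x, "full")[n - 1:] / (np.arange(n, 0, -1) * x.var())
    s = 0.0
    for r in acf[1:]:
        if r < 0.05:
            break
        s += r
    return n / (1 + 2 * s)


class TestPrecisionGibbs:
    def test_full_conditional_matches_analytic_gamma(self, small_panel):
        """Holding the fields fixed, repeated precision draws follow the
        conjugate Gamma(a + rank/2, b + quadform/2) full conditional."""
        data, graph, truth = small_panel
        cfg = ChainConfig(
            n_chains=1, n_iterations=5100, burn_in=100, thin=1, base_seed=8,
            fixed_blocks=("alpha", "beta_s", "beta_st", "gamma_s", "gamma_t",
                          "u_s", "u_sk", "u_t", "u_tk", "nu"))
        s = run_chains(data, graph, config=cfg)
        draws = s.get("tau_us")[0]
        h = HyperPriors()
        # fields are frozen at zero under fixed_blocks, so quadform = 0
        shape = h.precision_shape + 0.5 * graph.rank
        rate = h.precision_rate
        ks = stats.kstest(draws, stats.gamma(shape, scale=1 / rate).cdf)
        assert len(draws) == 5000
        assert ks.pvalue > 0.01

    def test_full_conditional_with_nonzero_field(self, small_panel):
        """Same check at a non-trivial quadratic form: freeze the fields at
        the simulating truth and drive the Gibbs step directly."""
        from apomap.mcmc import _ChainState
        data, graph, truth = small_panel
        h = HyperPriors()
        state = _ChainState(data, graph, h, ModelConfig(),
                            ChainConfig(n_iterations=10, burn_in=1), seed=4)
        state.params.u_s = truth.params.u_s.copy()
        draws = np.empty(5000)
        for t in range(5000):
            state.update_precisions()
            draws[t] = state.params.tau_us
        q = float(icar_quadform(truth.params.u_s, graph))
        shape = h.precision_shape + 0.5 * graph.rank
        rate = h.precision_rate + 0.5 * q
        ks = stats.kstest(draws, stats.gamma(shape, scale=1 / rate).cdf)
        assert ks.pvalue > 0.01


class TestRetainedDraws:
    def test_every_draw_satisfies_constraints(self, fitted):
        data, graph, truth, samples = fitted
        mc = ModelConfig()
        for chain in range(samples.n_chains):
            for d in range(0, samples.n_draws, 37):
                samples.params_at(chain, d).validate_constraints(graph, mc)

    def test_draw_count_contract(self, fitted):
        _, _, _, samples = fitted
        assert samples.n_draws == samples.config.n_retained

    def test_log_posterior_trace_recorded(self, fitted):
        _, _, _, samples = fitted
        lp = samples.get("log_posterior")
        assert lp.shape == (2, samples.n_draws)
        assert np.all(np.isfinite(lp))

    def test_acceptance_rates_reasonable(self, fitted):
        _, _, _, samples = fitted
        for name, rate in samples.acceptance.items():
            assert 0.05 <= rate <= 0.95, name


class TestEstimatorInterface:
    def test_fit_predict_shapes(self, small_panel):
        data, graph, _ = small_panel
        m = SharedComponentModel(n_chains=1, n_iterations=600, burn_in=200,
                                 thin=2, random_state=0)
        assert m.fit(data, graph) is m
        pi = m.predict_pi()
        assert pi.shape == data.shape
        assert np.all((pi > 0) & (pi < 1))
        rate = m.predict_rate(scale=1000.0)
        assert np.allclose(rate, 1000 * pi)

    def test_get_set_params_round_trip(self):
        m = SharedComponentModel(n_iterations=1234)
        params = m.get_params()
        assert params["n_iterations"] == 1234
        m.set_params(thin=3)
        assert m.thin == 3
        with pytest.raises(ValueError):
            m.set_params(bogus=1)

    def test_unfitted_predict_raises(self):
        with pytest.raises(AttributeError, match="not fitted"):
            SharedComponentModel().predict_pi()
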