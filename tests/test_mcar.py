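import numpy as np
import pytest
from scipy.special import gammaln
from scipy.stats import poisson

from comap.mcar import (
    ChainOutput,
    MCARModelSpec,
    MCMCControl,
    PosteriorState,
    correlation_matrix,
    fit_mcmc,
    initial_states,
    leroux_logdet,
    leroux_precision,
    log_posterior,
)
from comap.synthetic import make_ground_truth, simulate_counts

LOG2PI = np.log(2 * np.pi)


def flat_loop_log_posterior(state, spec, Y, E, graph):
    """Independent scalar-loop oracle for the unnormalised log posterior."""
    J = len(state.beta)
    n = graph.n_areas
    phi = state.phi()
    lp = 0.0
    for i in range(n):
        for j in range(J):
            if E[i, j] == 0 and Y[i, j] == 0:
                continue
            mu = E[i, j] * np.exp(state.beta[j] + phi[i, j])
            lp += Y[i, j] * np.log(mu) - mu - gammaln(Y[i, j] + 1)
    rho = state.rho_per_latent(J)
    for l in range(J):
        Q = leroux_precision(graph, rho[l])
        ul = state.u[:, l]
        quad = 0.0
        for i in range(n):
            for k in range(n):
                quad += ul[i] * Q[i, k] * ul[k]
        sign, logdet = np.linalg.slogdet(Q)
        lp += 0.5 * logdet - 0.5 * quad - 0.5 * n * LOG2PI
    prec = spec.intercept_prior_precision
    for j in range(J):
        lp += 0.5 * np.log(prec) - 0.5 * LOG2PI - 0.5 * prec * state.beta[j] ** 2
        lp += -np.log(spec.prior_sd_upper)
    return lp


@pytest.fixture
def state3(path3, rng):
    spec = MCARModelSpec(variant="M1")
    return PosteriorState(
        beta=np.array([0.1, -0.2, 0.05]),
        u=rng.normal(size=(3, 3)),
        sigma_sd=np.array([0.3, 0.5, 0.2]),
        sigma_corr=np.array([0.4, 0.3, 0.5]),
        rho=np.array([0.2, 0.5, 0.8]),
    ), spec


class TestLerouxPrecision:
    def test_rho_zero_identity(self, graph4):
        assert np.allclose(leroux_precision(graph4, 0.0), np.eye(4))

    def test_two_area_hand_matrix(self, pair2):
        assert np.allclose(leroux_precision(pair2, 0.9),
                           [[1.0, -0.9], [-0.9, 1.0]])

    def test_positive_definite_across_rho(self, lattice98):
        for rho in (0.0, 0.3, 0.67, 0.99):
            Q = leroux_precision(lattice98, rho)
            assert np.linalg.eigvalsh(Q).min() > 0

    def test_invalid_rho_rejected(self, graph4):
        for rho in (-0.01, 1.0):
            with pytest.raises(ValueError, match="rho"):
                leroux_precision(graph4, rho)

    def test_logdet_matches_eigen_oracle(self, lattice98, graph4):
        for graph in (lattice98, graph4):
            for rho in (0.0, 0.25, 0.67, 0.95):
                _, oracle = np.linalg.slogdet(leroux_precision(graph, rho))
                assert abs(leroux_logdet(graph, rho) - oracle) < 1e-8


class TestLogPosterior:
    def test_matches_flat_loop_oracle(self, path3, state3, rng):
        state, spec = state3
        E = rng.uniform(5, 50, size=(3, 3))
        Y = rng.poisson(E).astype(float)
        got = log_posterior(state, spec, Y, E, path3)
        want = flat_loop_log_posterior(state, spec, Y, E, path3)
        assert abs(got - want) < 1e-10

    def test_matches_oracle_shared_rho(self, path3, rng):
        spec = MCARModelSpec(variant="M2")
        state = PosteriorState(
            beta=np.zeros(3), u=rng.normal(size=(3, 3)),
            sigma_sd=np.full(3, 0.4), sigma_corr=np.array([0.47, 0.42, 0.65]),
            rho=np.array(0.67),
        )
        E = np.full((3, 3), 20.0)
        Y = rng.poisson(E).astype(float)
        got = log_posterior(state, spec, Y, E, path3)
        want = flat_loop_log_posterior(state, spec, Y, E, path3)
        assert abs(got - want) < 1e-10

    def test_zero_field_closed_form(self, path3):
        # u = 0: the CAR quadratic vanishes, leaving only logdet terms, the
        # Poisson likelihood at mu = E exp(beta) and the prior terms
        spec = MCARModelSpec(variant="M2")
        state = PosteriorState(
            beta=np.zeros(3), u=np.zeros((3, 3)), sigma_sd=np.full(3, 0.5),
            sigma_corr=np.array([0.1, 0.1, 0.1]), rho=np.array(0.5),
        )
        E = np.full((3, 3), 10.0)
        Y = np.full((3, 3), 10.0)
        want = (
            float(np.sum(poisson.logpmf(Y, E)))
            + 3 * (0.5 * leroux_logdet(path3, 0.5) - 0.5 * 3 * LOG2PI)
            + 3 * (0.5 * np.log(0.1) - 0.5 * LOG2PI)
            - 3 * np.log(10.0)
        )
        assert abs(log_posterior(state, spec, Y, E, path3) - want) < 1e-10

    def test_outside_support_is_minus_inf(self, path3):
        E = np.full((3, 3), 10.0)
        Y = np.full((3, 3), 10.0)
        spec = MCARModelSpec(variant="M2")
        base = dict(beta=np.zeros(3), u=np.zeros((3, 3)),
                    sigma_sd=np.full(3, 0.5),
                    sigma_corr=np.array([0.1, 0.1, 0.1]), rho=np.array(0.5))
        bad = [
            {**base, "sigma_corr": np.array([1.01, 0.1, 0.1])},
            {**base, "sigma_sd": np.array([0.5, 0.5, 11.0])},
            {**base, "rho": np.array(1.0)},
            {**base, "rho": np.array(-0.2)},
            {**base, "sigma_corr": np.array([0.9, 0.9, -0.9])},  # not PD
        ]
        for kw in bad:
            assert log_posterior(PosteriorState(**kw), spec, Y, E, path3) == -np.inf

    def test_e_zero_y_positive_rejected(self, path3, state3):
        state, spec = state3
        E = np.full((3, 3), 10.0)
        Y = np.full((3, 3), 1.0)
        E[0, 0] = 0.0
        with pytest.raises(ValueError, match="undefined"):
            log_posterior(state, spec, Y, E, path3)


class TestInitialStates:
    def test_first_chain_is_null_state(self, graph4):
        spec = MCARModelSpec(variant="M2")
        Y = np.full((4, 3), 30.0)
        E = np.full((4, 3), 20.0)
        st = initial_states(spec, Y, E, 1, seed=0)[0]
        assert np.allclose(st.beta, np.log(30.0 / 20.0))
        assert np.all(st.u == 0)
        assert np.all(st.sigma_sd == 0.5)
        assert st.rho.ndim == 0

    def test_later_chains_jittered_and_valid(self, graph4):
        Y = np.full((4, 3), 30.0)
        E = np.full((4, 3), 20.0)
        for variant in ("M1", "M2", "M3"):
            spec = MCARModelSpec(variant=variant)
            states = initial_states(spec, Y, E, 3, seed=1)
            for c, st in enumerate(states):
                assert st.is_valid(spec)
                if c > 0:
                    assert not np.allclose(st.beta, states[0].beta)
                    assert not np.all(st.u == 0)

    def test_m3_has_zero_correlations(self, graph4):
        spec = MCARModelSpec(variant="M3")
        Y = np.full((4, 3), 30.0)
        E = np.full((4, 3), 20.0)
        for st in initial_states(spec, Y, E, 2, seed=0):
            assert np.all(st.sigma_corr == 0)
            assert st.rho.shape == (3,)


class TestFitMCMC:
    def test_reruns_bit_identical(self, graph4, rng):
        truth = make_ground_truth(graph4, seed=0)
        E = np.full((4, 3), 50.0)
        Y = simulate_counts(truth, E, seed=1).astype(float)
        control = MCMCControl(n_chains=2, iterations=400, burn_in=200, thin=2, seed=9)
        a = fit_mcmc(MCARModelSpec(variant="M2"), Y, E, graph4, control)
        b = fit_mcmc(MCARModelSpec(variant="M2"), Y, E, graph4, control)
        for f in ("beta", "u", "sigma_sd", "sigma_corr", "rho", "phi", "mu"):
            assert np.array_equal(getattr(a, f), getattr(b, f))

    def test_retained_draw_count(self, graph4):
        truth = make_ground_truth(graph4, seed=0)
        E = np.full((4, 3), 50.0)
        Y = simulate_counts(truth, E, seed=1).astype(float)
        control = MCMCControl(n_chains=2, iterations=350, burn_in=100, thin=7, seed=0)
        out = fit_mcmc(MCARModelSpec(variant="M2"), Y, E, graph4, control)
        assert out.n_draws == 2 * ((350 - 100) // 7)
        assert set(np.unique(out.chain_id)) == {0, 1}

    def test_degree_zero_graph_rejected(self):
        from comap.geography import build_adjacency

        with pytest.warns(UserWarning):
            g = build_adjacency([("a", "b")], ["a", "b", "isl"])
        Y = np.ones((3, 3))
        E = np.ones((3, 3))
        with pytest.raises(ValueError, match="degree-0"):
            fit_mcmc(MCARModelSpec(), Y, E, g, MCMCControl(
                n_chains=1, iterations=20, burn_in=10, thin=1, seed=0))

    def test_draws_stay_inside_prior_support(self, graph4):
        truth = make_ground_truth(graph4, seed=0)
        E = np.full((4, 3), 50.0)
        Y = simulate_counts(truth, E, seed=2).astype(float)
        spec = MCARModelSpec(variant="M1", prior_sd_upper=2.0)
        out = fit_mcmc(spec, Y, E, graph4, MCMCControl(
            n_chains=2, iterations=600, burn_in=100, thin=1, seed=3))
        assert np.all(out.sigma_sd > 0) and np.all(out.sigma_sd < 2.0)
        assert np.all(out.sigma_corr > 0) and np.all(out.sigma_corr < 1)
        assert np.all(out.rho > 0) and np.all(out.rho < 1)
        for s in range(0, out.n_draws, 100):
            R = correlation_matrix(out.sigma_corr[s], 3)
            assert np.linalg.eigvalsh(R).min() > 0

    def test_y_equals_e_concentrates_sir_near_one(self, lattice98):
        # large counts with Y = E: fitted SIRs should concentrate near 1
        Y = np.full((98, 3), 500.0)
        E = np.full((98, 3), 500.0)
        out = fit_mcmc(MCARModelSpec(variant="M2"), Y, E, lattice98, MCMCControl(
            n_chains=1, iterations=3_000, burn_in=1_500, thin=5, seed=4))
        sir = out.mu.mean(axis=0) / E
        assert sir.min() > 0.95 and sir.max() < 1.05

    def test_acceptance_rates_in_healthy_band(self, lattice98):
        truth = make_ground_truth(lattice98, seed=0)
        E = np.full((98, 3), 200.0)
        Y = simulate_counts(truth, E, seed=5).astype(float)
        out = fit_mcmc(MCARModelSpec(variant="M2"), Y, E, lattice98, MCMCControl(
            n_chains=1, iterations=4_000, burn_in=2_000, thin=5, seed=6))
        rates = out.meta["chains"][0]["acceptance_rates"]
        for name, r in rates.items():
            assert 0.1 < r < 0.6, f"{name} acceptance {r}"


class TestM3Equivalence:
    def test_joint_equals_univariate_draw_for_draw(self, graph4):
        truth = make_ground_truth(graph4, variant="M3", seed=0)
        E = np.full((4, 3), 50.0)
        Y = simulate_counts(truth, E, seed=7).astype(float)
        control = MCMCControl(n_chains=2, iterations=500, burn_in=200, thin=3, seed=11)
        joint = fit_mcmc(MCARModelSpec(variant="M3"), Y, E, graph4, control)
        for j in range(3):
            uni = fit_mcmc(
                MCARModelSpec(variant="M3", n_diseases=1),
                Y[:, [j]], E[:, [j]], graph4, control, disease_labels=[j],
            )
            assert np.array_equal(joint.beta[:, j], uni.beta[:, 0])
            assert np.array_equal(joint.u[:, :, j], uni.u[:, :, 0])
            assert np.array_equal(joint.sigma_sd[:, j], uni.sigma_sd[:, 0])
            assert np.array_equal(joint.rho[:, j], uni.rho[:, 0])
            assert np.array_equal(joint.phi[:, :, j], uni.phi[:, :, 0])


class TestAgainstClosedForms:
    def test_single_dimension_posterior_matches_quadrature(self, pair2):
        # one disease, latent field and hyperparameters frozen at the null
        # initial state: the intercept's 1-D posterior is available by
        # quadrature of the same unnormalised density
        spec = MCARModelSpec(n_diseases=1)
        Y = np.full((2, 1), 12.0)
        E = np.full((2, 1), 10.0)
        control = MCMCControl(
            n_chains=1, iterations=22_000, burn_in=2_000, thin=5, seed=21,
            update={"u": False, "sd": False, "corr": False, "rho": False},
        )
        out = fit_mcmc(spec, Y, E, pair2, control)
        # quadrature oracle over beta with everything else at the init state
        st = initial_states(spec, Y, E, 1, seed=21)[0]
        grid = np.linspace(-1.5, 2.0, 4_001)
        lp = np.array([
            log_posterior(
                PosteriorState(np.array([b]), st.u, st.sigma_sd,
                               st.sigma_corr, st.rho), spec, Y, E, pair2)
            for b in grid
        ])
        w = np.exp(lp - lp.max())
        mean_oracle = np.sum(grid * w) / np.sum(w)
        assert abs(out.beta[:, 0].mean() - mean_oracle) < 0.02

    def test_gaussian_field_conditional_matches_closed_form(self, graph4):
        # gaussian likelihood with beta, sd, rho frozen: u | y is Gaussian
        # with precision Q(rho) + (sd^2/tau^2) I and mean solving the normal
        # equations; the sampler must reproduce mean and variances
        spec = MCARModelSpec(n_diseases=1, likelihood="gaussian", gaussian_tau=1.0)
        y = np.array([[1.2], [-0.4], [0.7], [2.0]])
        E = np.ones((4, 1))
        control = MCMCControl(
            n_chains=1, iterations=42_000, burn_in=2_000, thin=4, seed=13,
            update={"beta": False, "sd": False, "corr": False, "rho": False},
        )
        out = fit_mcmc(spec, y, E, graph4, control)
        st = initial_states(spec, y, E, 1, seed=13)[0]  # beta = mean(y), sd 0.5
        sd, tau, rho = st.sigma_sd[0], 1.0, 0.5
        Q = leroux_precision(graph4, rho)
        Lam = Q + (sd ** 2 / tau ** 2) * np.eye(4)
        m = np.linalg.solve(Lam, (sd / tau ** 2) * (y[:, 0] - st.beta[0]))
        cov = np.linalg.inv(Lam)
        u_draws = out.u[:, :, 0]
        assert np.abs(u_draws.mean(axis=0) - m).max() < 0.05
        assert np.abs(u_draws.var(axis=0) / np.diag(cov) - 1).max() < 0.15


class TestChainOutput:
    def test_state_round_trips_into_log_posterior(self, graph4):
        truth = make_ground_truth(graph4, seed=0)
        E = np.full((4, 3), 50.0)
        Y = simulate_counts(truth, E, seed=8).astype(float)
        spec = MCARModelSpec(variant="M2")
        out = fit_mcmc(spec, Y, E, graph4, MCMCControl(
            n_chains=1, iterations=200, burn_in=100, thin=10, seed=1))
        st = out.state(0)
        assert np.isfinite(log_posterior(st, spec, Y, E, graph4))
        assert np.allclose(st.phi(), out.phi[0], atol=1e-12)

    def test_deviance_matches_mu(self, graph4):
        truth = make_ground_truth(graph4, seed=0)
        E = np.full((4, 3), 50.0)
        Y = simulate_counts(truth, E, seed=8).astype(float)
        out = fit_mcmc(MCARModelSpec(variant="M2"), Y, E, graph4, MCMCControl(
            n_chains=1, iterations=200, burn_in=100, thin=10, seed=1))
        for s in range(out.n_draws):
            dev = -2 * np.sum(Y * np.log(out.mu[s]) - out.mu[s] - gammaln(Y + 1))
            assert abs(out.deviance[s] - dev) < 1e-8


class TestSpecValidation:
    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="variant"):
            MCARModelSpec(variant="M9")

    def test_bad_control_rejected(self):
        with pytest.raises(ValueError, match="burn_in"):
            MCMCControl(iterations=100, burn_in=100)
        with pytest.raises(ValueError, match="thin"):
            MCMCControl(iterations=100, burn_in=10, thin=0)

    def test_shape_mismatch_rejected(self, graph4):
        with pytest.raises(ValueError, match="shape"):
            fit_mcmc(MCARModelSpec(), np.ones((4, 3)), np.ones((3, 3)), graph4,
                     MCMCControl(n_chains=1, iterations=20, burn_in=10, thin=1))
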