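"""BYM sampler internals: densities, full-conditional steps, diagnostics, DIC."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from walkbym import (
    BYMSpec,
    ChainSettings,
    autocorrelation,
    build_grid_lattice,
    dic,
    gelman_rubin,
    icar_log_density,
    log_likelihood,
    run_chains,
)
from walkbym.bym import (
    BYMData,
    SamplerState,
    build_design,
    gibbs_step_precisions,
    gibbs_step_s,
    gibbs_step_u,
)


class TestLogLikelihood:
    def test_saturated_at_offset(self):
        o = np.array([3.0, 7.0, 1.0])
        got = log_likelihood(o, o, np.zeros(3))
        want = stats.poisson.logpmf(o, o).sum()
        assert got == pytest.approx(want)

    def test_single_area_hand_value(self):
        # o=2, e=1, linpred=ln2: 2 ln 2 - 2 - ln 2! = -1.30685...
        got = log_likelihood([2.0], [1.0], [np.log(2.0)])
        assert got == pytest.approx(float(stats.poisson.logpmf(2, 2.0)))
        assert got == pytest.approx(-1.3068528194400546)

    def test_matches_poisson_pmf_oracle_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            n = rng.integers(1, 8)
            o = rng.poisson(5.0, n).astype(float)
            e = rng.gamma(2.0, 3.0, n)
            lp = rng.normal(0.0, 0.5, n)
            want = stats.poisson.logpmf(o, e * np.exp(lp)).sum()
            assert log_likelihood(o, e, lp) == pytest.approx(want)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            log_likelihood([-1.0], [1.0], [0.0])
        with pytest.raises(ValueError):
            log_likelihood([1.0], [0.0], [0.0])


class TestIcarLogDensity:
    def test_constant_field_is_zero(self, lattice33_rook):
        assert icar_log_density(np.full(9, 2.5), 3.0, lattice33_rook) == 0.0

    def test_two_area_single_pair(self):
        g = build_grid_lattice(1, 2, "rook")
        assert icar_log_density([1.0, -1.0], 1.0, g) == pytest.approx(-2.0)

    def test_equals_laplacian_quadratic_form(self, path4):
        rng = np.random.default_rng(1)
        L = path4.laplacian()
        for _ in range(5):
            s = rng.normal(size=4)
            tau = float(rng.gamma(2.0))
            assert icar_log_density(s, tau, path4) == pytest.approx(
                -tau / 2.0 * s @ L @ s)

    def test_nonpositive_tau_rejected(self, path4):
        with pytest.raises(ValueError):
            icar_log_density(np.zeros(4), 0.0, path4)


def make_data(graph, o=None, e=None, X=None, names=()):
    n = graph.n_areas
    o = np.full(n, 5.0) if o is None else np.asarray(o, dtype=float)
    e = np.full(n, 5.0) if e is None else np.asarray(e, dtype=float)
    X = np.zeros((n, 0)) if X is None else X
    return BYMData(o, e, X, list(names), graph)


def make_state(data, **kw):
    base = dict(alpha=0.0, beta=np.zeros(data.p), s=np.zeros(data.n),
                u=np.zeros(data.n), tau_s=1.0, tau_u=1.0,
                scale_s=np.full(data.n, 0.5), scale_u=np.full(data.n, 0.5),
                scale_alpha=0.1, scale_beta=np.full(data.p, 0.1))
    base.update(kw)
    return SamplerState(**base)


class TestGibbsStepS:
    def test_flat_likelihood_single_site_conditional(self, path4):
        """With the Poisson contribution removed, the stationary law of s_1
        (others frozen) is N(neighbour mean, sigma_s^2 / k_1)."""
        data = make_data(path4, o=np.zeros(4), e=np.full(4, 1e-300))
        tau_s = 2.0
        scales = np.zeros(4)
        scales[1] = 2.4 / np.sqrt(tau_s * 2)
        state = make_state(data, s=np.array([0.5, 0.0, -0.3, 0.0]),
                           tau_s=tau_s, scale_s=scales)
        rng = np.random.default_rng(12)
        draws = np.empty(20_000)
        for i in range(draws.size):
            gibbs_step_s(state, data, rng, recenter=False)
            draws[i] = state.s[1]
        cond_mean = (0.5 - 0.3) / 2.0
        cond_var = 1.0 / (tau_s * 2.0)
        # generous MC tolerances: RW draws are autocorrelated
        assert abs(draws.mean() - cond_mean) < 0.04
        assert abs(draws.var() / cond_var - 1.0) < 0.15
        assert np.all(state.s[[0, 2, 3]] == [0.5, -0.3, 0.0])

    def test_recentring_enforces_antisymmetry_on_two_areas(self):
        g = build_grid_lattice(1, 2, "rook")
        data = make_data(g, o=[4.0, 6.0], e=[5.0, 5.0])
        state = make_state(data, s=np.array([0.2, -0.2]))
        rng = np.random.default_rng(3)
        for _ in range(200):
            gibbs_step_s(state, data, rng)
            assert state.s[0] == pytest.approx(-state.s[1], abs=1e-12)

    def test_recentring_leaves_linear_predictor_invariant(self, lattice33_rook):
        data = make_data(lattice33_rook)
        state = make_state(data, s=np.arange(9, dtype=float) / 10.0)
        rng = np.random.default_rng(5)
        scales = np.zeros(9)  # proposals frozen: only the recentring acts
        state.scale_s = scales
        before = state.linpred(data).copy()
        gibbs_step_s(state, data, rng)
        assert np.allclose(state.linpred(data), before, atol=1e-12)
        assert abs(state.s.mean()) < 1e-12

    def test_isolated_area_refused(self):
        from walkbym import AdjacencyGraph
        g = AdjacencyGraph(("a", "b", "c"),
                           (frozenset({1}), frozenset({0}), frozenset()))
        with pytest.raises(ValueError, match="exclusion filter"):
            make_data(g)


class TestGibbsStepU:
    def test_huge_precision_pins_u_at_zero(self, lattice33_rook):
        data = make_data(lattice33_rook)
        state = make_state(data, tau_u=1e12)
        rng = np.random.default_rng(7)
        for _ in range(100):
            gibbs_step_u(state, data, rng)
        assert np.all(state.u == 0.0)

    def test_targets_normal_prior_when_likelihood_flat(self, lattice33_rook):
        data = make_data(lattice33_rook, o=np.zeros(9), e=np.full(9, 1e-300))
        state = make_state(data, tau_u=4.0, scale_u=np.full(9, 1.2))
        rng = np.random.default_rng(8)
        draws = []
        for _ in range(4000):
            gibbs_step_u(state, data, rng)
            draws.append(state.u.copy())
        draws = np.array(draws)[500:]
        assert abs(draws.mean()) < 0.03
        assert abs(draws.var() - 0.25) < 0.04


class TestGibbsPrecisions:
    def test_zero_field_conditional_is_rank_shifted_prior(self, path4):
        data = make_data(path4)
        spec = BYMSpec(precision_prior=(0.5, 0.2))
        state = make_state(data)
        rng = np.random.default_rng(9)
        draws = np.empty(5000)
        for i in range(draws.size):
            state.s[:] = 0.0
            gibbs_step_precisions(state, data, spec, rng)
            draws[i] = state.tau_s
        shape = 0.5 + (4 - 1) / 2.0
        want_mean = shape / 0.2
        se = np.sqrt(shape) / 0.2 / np.sqrt(draws.size)
        assert abs(draws.mean() - want_mean) < 4 * se

    def test_known_pairwise_sum_conditional_mean(self, path4):
        data = make_data(path4)
        s = np.array([0.4, -0.1, 0.2, -0.5])
        pair = ((0.4 + 0.1) ** 2 + (-0.1 - 0.2) ** 2 + (0.2 + 0.5) ** 2)
        spec = BYMSpec(precision_prior=(1.0, 0.5))
        state = make_state(data, s=s)
        rng = np.random.default_rng(10)
        draws = np.empty(5000)
        for i in range(draws.size):
            state.s = s.copy()
            gibbs_step_precisions(state, data, spec, rng)
            draws[i] = state.tau_s
        want = (1.0 + 3 / 2.0) / (0.5 + pair / 2.0)
        assert abs(draws.mean() - want) / want < 0.05

    def test_tau_u_recovery_coverage(self):
        """Pure-noise data o ~ Poisson(e exp(u)), u ~ N(0, 0.3^2): the 95% CrI
        for sigma_u^2 covers the generating value in most replicates."""
        g = build_grid_lattice(6, 10, "queen")
        sigma_u = 0.3
        hits = 0
        reps = 20
        for rep in range(reps):
            rng = np.random.default_rng(200 + rep)
            e = np.full(g.n_areas, 100.0)
            u = rng.normal(0.0, sigma_u, g.n_areas)
            o = rng.poisson(e * np.exp(u)).astype(float)
            table = pd.DataFrame({"area_id": g.area_ids, "o": o, "e_unadj": e})
            post = run_chains(BYMSpec(fixed_tau_s=1e8), table, g,
                              settings=ChainSettings(2, 250, 4, 300, seed=rep))
            lo, hi = post.credible_interval("sigma2_u")
            hits += lo <= sigma_u**2 <= hi
        assert hits >= 16


class TestFixedEffects:
    def test_intercept_only_posterior_mean(self, lattice33_rook):
        rng = np.random.default_rng(13)
        e = np.full(9, 100.0)
        o = rng.poisson(1.3 * e).astype(float)
        table = pd.DataFrame({"area_id": lattice33_rook.area_ids, "o": o, "e_unadj": e})
        post = run_chains(BYMSpec(fixed_tau_s=1e8, fixed_tau_u=1e8), table,
                          lattice33_rook, settings=ChainSettings(2, 400, 4, 400, seed=1))
        want = np.log(o.sum() / e.sum())
        assert abs(post.pooled("alpha").mean() - want) < 0.02

    def test_binary_covariate_recovers_standardized_ratio(self, lattice33_rook):
        e = np.full(9, 100.0)
        walk = np.array(["high"] * 4 + ["low"] * 5, dtype=object)
        o = np.where(walk == "high", 200.0, 100.0)
        table = pd.DataFrame({"area_id": lattice33_rook.area_ids, "o": o,
                              "e_unadj": e, "walkability": walk,
                              "disadvantage": "Q2"})
        spec = BYMSpec(covariates=("walkability",), fixed_tau_s=1e8, fixed_tau_u=1e8)
        post = run_chains(spec, table, lattice33_rook,
                          settings=ChainSettings(2, 400, 4, 500, seed=2))
        beta = post.pooled("beta")[:, post.coef_names.index("walkability=high")]
        ratio = (o[walk == "high"].sum() / e[walk == "high"].sum()) / (
            o[walk == "low"].sum() / e[walk == "low"].sum())
        assert np.exp(np.median(beta)) == pytest.approx(ratio, abs=0.2)


class TestRunChains:
    def test_identical_seed_identical_draws(self, lattice33_rook):
        rng = np.random.default_rng(3)
        e = np.full(9, 50.0)
        o = rng.poisson(e).astype(float)
        table = pd.DataFrame({"area_id": lattice33_rook.area_ids, "o": o, "e_unadj": e})
        settings = ChainSettings(2, 50, 2, 100, seed=42)
        a = run_chains(BYMSpec(), table, lattice33_rook, settings=settings)
        b = run_chains(BYMSpec(), table, lattice33_rook, settings=settings)
        assert np.array_equal(a.s, b.s)
        assert np.array_equal(a.alpha, b.alpha)
        assert a.dic == b.dic

    def test_component_means_of_kept_s_draws_are_zero(self, lattice33_rook):
        rng = np.random.default_rng(4)
        e = np.full(9, 80.0)
        o = rng.poisson(e * np.exp(rng.normal(0, 0.3, 9))).astype(float)
        table = pd.DataFrame({"area_id": lattice33_rook.area_ids, "o": o, "e_unadj": e})
        post = run_chains(BYMSpec(), table, lattice33_rook,
                          settings=ChainSettings(2, 100, 2, 200, seed=5))
        assert np.max(np.abs(post.pooled("s").mean(axis=1))) < 1e-10

    def test_adaptation_reaches_target_acceptance_band(self, small_scenario):
        from walkbym import analysis_subset, expected_counts, fit_logistic, generate_cohort
        cohort, truth = generate_cohort(small_scenario)
        subset, y = analysis_subset(cohort, "overweight")
        null = fit_logistic(subset, y, None)
        table, g = expected_counts(null, null, subset, y, small_scenario.graph,
                                   truth[["area_id", "walkability", "disadvantage"]])
        post = run_chains(BYMSpec(), table, g,
                          settings=ChainSettings(2, 200, 5, 600, seed=6))
        for block, rate in post.acceptance.items():
            assert 0.2 <= rate <= 0.6, (block, rate)

    def test_misaligned_table_rejected(self, lattice33_rook):
        table = pd.DataFrame({"area_id": list(lattice33_rook.area_ids)[::-1],
                              "o": 1.0, "e_unadj": 1.0})
        with pytest.raises(ValueError, match="match graph"):
            run_chains(BYMSpec(), table, lattice33_rook)


class TestDesignMatrix:
    def test_main_effects_and_interaction_dimensions(self):
        table = pd.DataFrame({
            "walkability": ["low", "high", "medium-high", "low-medium"],
            "disadvantage": ["Q1-most", "Q2", "Q4", "Q5-least"],
        })
        X, names = build_design(table, BYMSpec(covariates=("walkability", "disadvantage")))
        assert X.shape == (4, 7)
        Xi, names_i = build_design(
            table, BYMSpec(covariates=("walkability", "disadvantage"), interaction=True))
        assert Xi.shape == (4, 7 + 12)
        assert names_i[-1] == "walkability=high:disadvantage=Q5-least"

    def test_interaction_requires_main_effects(self):
        with pytest.raises(ValueError, match="main-effect"):
            BYMSpec(covariates=("walkability",), interaction=True)


class TestGelmanRubin:
    def test_identical_chains_report_one(self):
        c = np.tile(np.arange(20.0), (2, 1))
        assert gelman_rubin(c) == 1.0

    def test_hand_computation_on_separated_chains(self):
        chains = np.array([[1.0, 2, 3, 4], [101.0, 102, 103, 104]])
        W = np.mean([np.var(c, ddof=1) for c in chains])
        B = 4 * np.var([2.5, 102.5], ddof=1)
        want = np.sqrt(((4 - 1) / 4 * W + B / 4) / W)
        assert gelman_rubin(chains) == pytest.approx(want)
        assert gelman_rubin(chains) > 10

    def test_converges_to_one_with_length(self):
        rng = np.random.default_rng(11)
        short = rng.normal(size=(2, 100))
        long = rng.normal(size=(2, 1000))
        assert gelman_rubin(long) < 1.05
        assert gelman_rubin(long) <= gelman_rubin(short) + 0.05

    def test_degenerate_within_variance(self):
        chains = np.array([[1.0] * 10, [2.0] * 10])
        assert gelman_rubin(chains) == float("inf")


class TestAutocorrelation:
    def test_constant_series_flagged(self):
        acf = autocorrelation(np.ones(100), 5)
        assert np.all(np.isnan(acf))

    def test_alternating_series(self):
        x = np.tile([1.0, -1.0], 500)
        # biased estimator: (n-1)/n at lag 1 for a perfectly alternating series
        assert autocorrelation(x, 1)[0] == pytest.approx(-0.999, abs=1e-9)

    def test_ar1_process(self):
        rng = np.random.default_rng(15)
        n, rho = 10_000, 0.8
        x = np.empty(n)
        x[0] = rng.normal()
        for t in range(1, n):
            x[t] = rho * x[t - 1] + rng.normal() * np.sqrt(1 - rho**2)
        assert abs(autocorrelation(x, 1)[0] - rho) < 0.05


class TestDic:
    def test_degenerate_posterior(self):
        lp = np.tile(np.array([0.1, -0.2, 0.3]), (5, 1))
        o = np.array([4.0, 5.0, 6.0])
        e = np.array([5.0, 5.0, 5.0])
        d, p_d = dic(lp, o, e)
        assert p_d == pytest.approx(0.0, abs=1e-10)
        assert d == pytest.approx(-2 * log_likelihood(o, e, lp[0]))

    def test_two_draw_hand_computation(self):
        o, e = np.array([3.0]), np.array([2.0])
        lp = np.array([[0.0], [0.5]])
        d1 = -2 * stats.poisson.logpmf(3, 2.0 * np.exp(0.0))
        d2 = -2 * stats.poisson.logpmf(3, 2.0 * np.exp(0.5))
        d_bar = (d1 + d2) / 2
        d_hat = -2 * stats.poisson.logpmf(3, 2.0 * np.exp(0.25))
        want_pd = d_bar - d_hat
        got_dic, got_pd = dic(lp, o, e)
        assert got_pd == pytest.approx(float(want_pd))
        assert got_dic == pytest.approx(float(d_bar + want_pd))
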