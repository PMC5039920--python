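import warnings

import numpy as np
import pytest

from chipseg.hmm_engine import (
    HIGH,
    LOW,
    HMMParams,
    baum_welch,
    discretize,
    fit_baseline_from_controls,
    forward_backward,
    identify_state_roles,
    n_free_parameters,
    viterbi,
)
from chipseg.io_binning import CountMatrix, WindowGrid
from chipseg.simulator import SimConfig, default_truth_params, simulate
from chipseg.zinm_model import ZINMParams, fit_zinb, zinm_params_from_means
from oracles import brute_force_posteriors, brute_force_viterbi


def _random_params(rng, r=1):
    nu = rng.dirichlet(np.ones(3))
    Q = rng.dirichlet(np.ones(3), size=3)
    pi, alpha = rng.uniform(0.05, 0.3), rng.uniform(1.0, 4.0)
    emissions = [
        zinm_params_from_means(pi, alpha, rng.uniform(0.5, 20.0, size=r))
        for _ in range(3)
    ]
    return HMMParams(nu=nu, Q=Q, emissions=emissions)


def _counts_from_chips(chips, n_controls=1, control=None):
    chips = np.atleast_2d(chips)
    n = chips.shape[0]
    grid = WindowGrid(300, {"chr1": 300 * n})
    ctl = control if control is not None else np.ones((n, n_controls), dtype=int)
    counts = np.hstack([ctl, chips])
    roles = ["control"] * ctl.shape[1] + ["chip"] * chips.shape[1]
    return CountMatrix(grid=grid, counts=counts, roles=roles)


class TestForwardBackward:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_path_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        params = _random_params(rng)
        Y = rng.integers(0, 15, size=(3, 1))
        gamma, _, ll = forward_backward(Y, params)
        post, total = brute_force_posteriors(Y, params)
        np.testing.assert_allclose(gamma, post, atol=1e-12)
        assert ll == pytest.approx(total, abs=1e-10)

    def test_absorbing_chain_stays_in_start_state(self, toy_hmm_params):
        params = HMMParams(
            nu=np.array([1.0, 0.0, 0.0]),
            Q=np.eye(3),
            emissions=toy_hmm_params.emissions,
        )
        Y = np.array([[0], [5], [2], [9]])
        gamma, _, _ = forward_backward(Y, params)
        np.testing.assert_allclose(gamma[:, 0], 1.0)

    def test_identical_emissions_give_chain_marginals(self):
        rng = np.random.default_rng(1)
        nu = np.array([0.5, 0.3, 0.2])
        Q = rng.dirichlet(np.ones(3), size=3)
        em = zinm_params_from_means(0.1, 2.0, [4.0])
        params = HMMParams(nu=nu, Q=Q, emissions=[em, em, em])
        Y = rng.integers(0, 10, size=(6, 1))
        gamma, _, _ = forward_backward(Y, params)
        marg = nu.copy()
        for t in range(6):
            np.testing.assert_allclose(gamma[t], marg, atol=1e-12)
            marg = marg @ Q

    def test_posterior_rows_normalized(self):
        rng = np.random.default_rng(2)
        params = _random_params(rng, r=2)
        Y = rng.integers(0, 30, size=(500, 2))
        gamma, _, _ = forward_backward(Y, params)
        np.testing.assert_allclose(gamma.sum(axis=1), 1.0, atol=1e-9)

    def test_blocks_are_independent_chains(self):
        rng = np.random.default_rng(3)
        params = _random_params(rng)
        Y = rng.integers(0, 10, size=(8, 1))
        blocks = [slice(0, 5), slice(5, 8)]
        _, _, ll = forward_backward(Y, params, blocks)
        _, _, ll_a = forward_backward(Y[:5], params)
        _, _, ll_b = forward_backward(Y[5:], params)
        assert ll == pytest.approx(ll_a + ll_b, abs=1e-10)


class TestViterbi:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_argmax(self, seed):
        rng = np.random.default_rng(100 + seed)
        params = _random_params(rng)
        Y = rng.integers(0, 15, size=(8, 1))
        path = viterbi(Y, params)
        winners, best = brute_force_viterbi(Y, params)
        assert any(np.array_equal(path, w) for w in winners)
        # generic parameters: the optimum is unique
        if len(winners) == 1:
            np.testing.assert_array_equal(path, winners[0])

    def test_absorbing_start_at_high(self, toy_hmm_params):
        params = HMMParams(
            nu=np.array([0.0, 0.0, 1.0]),
            Q=np.eye(3),
            emissions=toy_hmm_params.emissions,
        )
        Y = np.array([[0], [5], [2]])
        np.testing.assert_array_equal(viterbi(Y, params), [2, 2, 2])

    def test_ties_resolve_to_lowest_state_index(self):
        em = zinm_params_from_means(0.0, 2.0, [4.0])
        params = HMMParams(
            nu=np.full(3, 1 / 3),
            Q=np.full((3, 3), 1 / 3),
            emissions=[em, em, em],
        )
        Y = np.array([[1], [2], [3], [1]])
        np.testing.assert_array_equal(viterbi(Y, params), np.zeros(4))


class TestBaseline:
    def test_single_column_equals_fit_zinb(self, small_sim):
        ctl = small_sim.counts.control_counts
        pi, alpha = fit_baseline_from_controls(ctl)
        res = fit_zinb(ctl[:, 0])
        assert pi == pytest.approx(res.params.pi)
        assert alpha == pytest.approx(res.params.alpha)

    def test_recovery_from_simulated_controls(self):
        rng = np.random.default_rng(4)
        n = 100_000
        pi_true, alpha_true, mean = 0.25, 3.0, 4.0
        lam = rng.gamma(alpha_true, 1.0, size=n)
        k = rng.poisson(lam * mean / alpha_true)
        k[rng.random(n) < pi_true] = 0
        pi, alpha = fit_baseline_from_controls(k[:, None])
        assert pi == pytest.approx(pi_true, rel=0.05)
        assert alpha == pytest.approx(alpha_true, rel=0.05)

    def test_pooling_two_identical_columns(self):
        # duplicated columns double the depth but leave pi and the
        # gamma-shape of the pooled baseline unchanged
        rng = np.random.default_rng(5)
        n = 100_000
        pi_true, alpha_true = 0.2, 3.0
        lam = rng.gamma(alpha_true, 1.0, size=n)
        keep = rng.random(n) >= pi_true
        k1 = np.where(keep, rng.poisson(lam * 4.0 / alpha_true), 0)
        k2 = np.where(keep, rng.poisson(lam * 4.0 / alpha_true), 0)
        pi, alpha = fit_baseline_from_controls(np.stack([k1, k2], axis=1))
        assert pi == pytest.approx(pi_true, rel=0.05)
        assert alpha == pytest.approx(alpha_true, rel=0.10)

    def test_all_zero_controls_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_baseline_from_controls(np.zeros((100, 1), dtype=int))


class TestBaumWelch:
    def test_loglik_trace_nondecreasing_over_seeds(self):
        for seed in range(50):
            config = SimConfig(
                chrom_windows={"chr1": 300},
                hmm=default_truth_params(r=1, state_means=(1.5, 5.0, 15.0)),
                seed=seed,
            )
            sim = simulate(config)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = baum_welch(sim.counts, pi=0.1, alpha=3.0, max_iter=25)
            trace = np.array(fit.loglik_trace)
            assert np.all(np.diff(trace) >= -1e-6)

    def test_infinite_tol_stops_after_one_iteration(self, small_sim):
        fit = baum_welch(small_sim.counts, pi=0.1, alpha=3.0, tol=np.inf)
        assert fit.n_iter == 1
        assert fit.posteriors.shape == (small_sim.counts.n, 3)

    def test_initialized_at_truth_is_near_fixed_point(self, small_sim):
        truth = small_sim.config.hmm
        fit = baum_welch(
            small_sim.counts, pi=truth.pi, alpha=truth.alpha,
            init=truth, max_iter=2,
        )
        ll = np.array(fit.loglik_trace[:2])
        assert abs(ll[1] - ll[0]) <= 1e-3 * abs(ll[0])

    def test_parameter_recovery_medium_sim(self):
        config = SimConfig(chrom_windows={"chr1": 8000}, seed=17)
        sim = simulate(config)
        fit = baum_welch(sim.counts, pi=0.1, alpha=3.0)
        order = fit.state_order
        raw_of_role = np.empty(3, dtype=int)
        raw_of_role[order] = np.arange(3)
        Q_hat = fit.params.Q[np.ix_(raw_of_role, raw_of_role)]
        assert np.abs(Q_hat - config.hmm.Q).max() < 0.05
        for role in range(3):
            means = fit.params.emissions[raw_of_role[role]].means()
            np.testing.assert_allclose(
                means, config.hmm.emissions[role].means(), rtol=0.10
            )


class TestRolesAndDiscretize:
    def test_roles_sorted_by_mean_total(self):
        pi, alpha = 0.1, 2.0
        emissions = [
            zinm_params_from_means(pi, alpha, [4.0]),
            zinm_params_from_means(pi, alpha, [20.0]),
            zinm_params_from_means(pi, alpha, [1.0]),
        ]
        params = HMMParams(
            nu=np.full(3, 1 / 3), Q=np.full((3, 3), 1 / 3), emissions=emissions
        )
        np.testing.assert_array_equal(identify_state_roles(params), [1, 2, 0])

    def test_tied_means_warn(self):
        em = zinm_params_from_means(0.1, 2.0, [4.0])
        params = HMMParams(
            nu=np.full(3, 1 / 3), Q=np.full((3, 3), 1 / 3), emissions=[em] * 3
        )
        with pytest.warns(UserWarning, match="tied"):
            identify_state_roles(params)

    def test_label_switching_invariance(self, small_sim):
        pi, alpha = fit_baseline_from_controls(small_sim.counts.control_counts)
        fit = baum_welch(small_sim.counts, pi=pi, alpha=alpha)
        perm = np.array([2, 0, 1])
        init = HMMParams(
            nu=fit.params.nu[perm],
            Q=fit.params.Q[np.ix_(perm, perm)],
            emissions=[fit.params.emissions[s] for s in perm],
        )
        refit = baum_welch(small_sim.counts, pi=pi, alpha=alpha, init=init)
        np.testing.assert_array_equal(fit.role_path, refit.role_path)

    def test_recovers_generating_states(self, small_sim):
        profile = discretize(small_sim.counts)
        accuracy = (profile.states == small_sim.states).mean()
        assert accuracy >= 0.95

    def test_null_chips_yield_almost_no_targets(self):
        # ChIP columns drawn from the baseline at every window
        config = SimConfig(
            chrom_windows={"chr1": 3000},
            hmm=default_truth_params(state_means=(4.0, 4.001, 4.002)),
            seed=23,
        )
        sim = simulate(config)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            profile = discretize(sim.counts)
        assert profile.targets.mean() <= 0.01

    def test_all_zero_windows_never_targets(self, small_sim):
        profile = discretize(small_sim.counts)
        all_zero = small_sim.counts.counts.sum(axis=1) == 0
        assert not np.any(profile.targets & all_zero)

    def test_requires_control_and_chip(self, small_sim):
        cm = small_sim.counts
        chips_only = CountMatrix(
            grid=cm.grid, counts=cm.chip_counts, roles=["chip", "chip"]
        )
        with pytest.raises(ValueError, match="control"):
            discretize(chips_only)

    def test_deterministic_given_inputs(self, small_sim):
        a = discretize(small_sim.counts)
        b = discretize(small_sim.counts)
        np.testing.assert_array_equal(a.states, b.states)
        np.testing.assert_allclose(a.confidence, b.confidence, rtol=0, atol=0)


class TestParameterCount:
    @pytest.mark.parametrize("r", [1, 2, 5])
    def test_free_scalars_total_3r_plus_9(self, r):
        params = default_truth_params(r=r)
        # 2 free in nu, 6 free in Q, alpha, and r free emission
        # probabilities per state (pi is pinned, not estimated)
        by_construction = (
            (params.nu.size - 1)
            + params.Q.size - params.Q.shape[0]
            + 1
            + sum(em.p.size - 1 for em in params.emissions)
        )
        assert n_free_parameters(params) == by_construction == 3 * r + 9
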