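import numpy as np
import pytest

from oracles import (
    counts_from_assignment,
    enumerate_posterior,
    gd_posterior_mean_numeric,
    log_joint,
)

import zinlda
from zinlda.lda import LDAHyper, expand_reads, fit_lda
from zinlda.sampler import (
    ChainState,
    ZinHyper,
    conditional_delta,
    conditional_z,
    estimate_beta_draw,
    estimate_theta_draw,
    finalize,
    gibbs_sweep,
    init_from_lda,
    run_chain,
)
from zinlda.types import Cohort, Fit, PosteriorDraws


def make_state(counts, z, K, delta=None):
    cohort = Cohort(np.asarray(counts), [f"s{d}" for d in range(len(counts))], [f"t{i}" for i in range(len(counts[0]))])
    rs, rt = expand_reads(cohort)
    state = ChainState.from_assignments(rs, rt, np.asarray(z, dtype=np.int32), cohort.n_samples, cohort.n_taxa, K)
    if delta is not None:
        state.delta = np.asarray(delta, dtype=np.int8)
    return cohort, state


class TestHyper:
    def test_alpha_default(self):
        assert ZinHyper(K=5, pi=0.4, a=0.05, b=10.0).alpha == pytest.approx(10.0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(K=0, pi=0.4, a=1.0, b=1.0),
            dict(K=2, pi=1.5, a=1.0, b=1.0),
            dict(K=2, pi=0.4, a=-1.0, b=1.0),
            dict(K=2, pi=0.4, a=1.0, b=1.0, alpha=0.0),
        ],
    )
    def test_validation(self, kwargs):
        with pytest.raises(ValueError):
            ZinHyper(**kwargs)


class TestInitFromLDA:
    def test_concentrated_beta_assigns_all_reads(self, tiny_cohort):
        beta = np.array([[1e-12, 0.5, 0.5], [1.0, 0.5, 0.5]])
        beta = beta / beta.sum(axis=1, keepdims=True)
        fit = Fit(beta=beta, theta=np.full((2, 2), 0.5))
        hyper = ZinHyper(K=2, pi=0.4, a=0.5, b=2.0, alpha=1.0)
        state = init_from_lda(tiny_cohort, fit, hyper, rng=0)
        # taxon 0 has essentially all its column mass in community 1
        assert state.n[1, 0] == 2 and state.n[0, 0] == 0
        assert np.all(state.delta == 0)
        state.check_consistency()

    def test_uniform_beta_splits_reads(self):
        rng = np.random.default_rng(1)
        counts = np.full((20, 4), 25)
        cohort = Cohort(counts, [f"s{d}" for d in range(20)], list("abcd"))
        fit = Fit(beta=np.full((4, 4), 0.25), theta=np.full((20, 4), 0.25))
        hyper = ZinHyper(K=4, pi=0.2, a=0.5, b=2.0, alpha=1.0)
        state = init_from_lda(cohort, fit, hyper, rng)
        fracs = state.n_total / state.n_total.sum()
        assert np.allclose(fracs, 0.25, atol=3 * np.sqrt(0.25 * 0.75 / 2000))

    def test_k_mismatch_rejected(self, tiny_cohort):
        fit = Fit(beta=np.full((3, 3), 1 / 3), theta=np.ones((2, 3)) / 3)
        with pytest.raises(ValueError):
            init_from_lda(tiny_cohort, fit, ZinHyper(K=2, pi=0.4, a=0.5, b=2.0), rng=0)


class TestConditionalZ:
    def test_single_community(self):
        cohort, state = make_state([[2, 1, 0]], [0, 0, 0], K=1)
        state.n[0, 0] -= 1
        state.n_total[0] -= 1
        state.m[0, 0] -= 1
        probs = conditional_z(0, 0, state, ZinHyper(K=1, pi=0.4, a=0.5, b=2.0, alpha=1.0))
        np.testing.assert_allclose(probs, [1.0])

    def test_excluded_community_gets_zero(self):
        cohort, state = make_state([[2, 1, 1]], [0, 0, 0, 0], K=2, delta=[[0, 0, 0], [1, 0, 0]])
        state.n[0, 0] -= 1
        state.n_total[0] -= 1
        state.m[0, 0] -= 1
        probs = conditional_z(0, 0, state, ZinHyper(K=2, pi=0.4, a=0.5, b=2.0, alpha=1.0))
        assert probs[1] == 0.0 and probs[0] == 1.0

    @pytest.mark.parametrize(
        "delta, z",
        [
            ([[0, 0, 0], [0, 0, 0]], [0, 1, 1, 0]),
            ([[0, 1, 0], [0, 0, 0]], [0, 1, 1, 0]),
            ([[0, 0, 0], [0, 1, 0]], [0, 0, 0, 0]),
            ([[1, 0, 0], [0, 0, 0]], [1, 0, 1, 0]),
        ],
    )
    def test_matches_exact_joint_ratio(self, delta, z):
        # ratio of closed-form joint probabilities P(z, delta, w) with the
        # resampled read placed in each community
        alpha, pi, a, b = 1.0, 0.3, 0.5, 2.0
        K = 2
        counts = [[1, 2, 0], [0, 0, 1]]
        cohort, state = make_state(counts, z, K, delta=delta)
        rs, rt = expand_reads(cohort)
        dmat = np.asarray(delta)[:, :2]
        r = 1  # read of taxon 1 in sample 0
        assert rt[r] == 1 and rs[r] == 0
        expect = np.zeros(K)
        for j in range(K):
            z_try = np.array(z)
            z_try[r] = j
            n, m = counts_from_assignment(z_try, rs, rt, 2, 3, K)
            lp = log_joint(n, m, dmat, alpha, pi, a, b)
            expect[j] = 0.0 if lp == -np.inf else np.exp(lp)
        assert expect.sum() > 0  # every case is a reachable chain state
        expect /= expect.sum()

        jo = z[r]
        state.n[jo, rt[r]] -= 1
        state.n_total[jo] -= 1
        state.m[rs[r], jo] -= 1
        probs = conditional_z(int(rt[r]), int(rs[r]), state, ZinHyper(K=K, pi=pi, a=a, b=b, alpha=alpha))
        np.testing.assert_allclose(probs, expect, atol=1e-10)


class TestConditionalDelta:
    def test_zero_when_counts_positive(self):
        _, state = make_state([[5, 1, 0]], [0] * 6, K=1)
        assert conditional_delta(0, 0, state, ZinHyper(K=1, pi=0.4, a=0.05, b=10.0)) == 0.0

    def test_zero_when_pi_zero(self):
        _, state = make_state([[0, 1, 1]], [0, 0], K=1)
        assert conditional_delta(0, 0, state, ZinHyper(K=1, pi=0.0, a=0.05, b=10.0)) == 0.0

    def test_no_trailing_counts_gives_pi(self):
        # with n_j^(i)=0 and no trailing counts the Beta ratio is 1, so the
        # conditional equals the prior pi
        _, state = make_state([[1, 1, 0, 0]], [0, 0], K=1)
        p = conditional_delta(2, 0, state, ZinHyper(K=1, pi=0.4, a=0.05, b=10.0))
        assert p == pytest.approx(0.4, abs=1e-12)

    def test_trailing_counts_raise_probability(self):
        # trailing reads shrink B(a, b+S)/B(a, b) below 1, pushing the
        # posterior toward the structural zero
        _, state = make_state([[0, 0, 5, 5]], [0] * 10, K=1)
        p = conditional_delta(0, 0, state, ZinHyper(K=1, pi=0.4, a=0.5, b=2.0))
        assert p > 0.4

    def test_last_taxon_never_inflated(self):
        _, state = make_state([[1, 1, 0]], [0, 0], K=1)
        assert conditional_delta(2, 0, state, ZinHyper(K=1, pi=0.9, a=0.5, b=2.0)) == 0.0


class TestEstimators:
    def test_theta_hand_counts(self):
        _, state = make_state([[3, 1]], [0, 0, 0, 1], K=2)
        theta = estimate_theta_draw(state, ZinHyper(K=2, pi=0.0, a=1.0, b=1.0, alpha=1.0))
        np.testing.assert_allclose(theta, [[4 / 6, 2 / 6]])

    def test_theta_prior_dominance(self):
        _, state = make_state([[3, 1]], [0, 0, 0, 1], K=2)
        theta = estimate_theta_draw(state, ZinHyper(K=2, pi=0.0, a=1.0, b=1.0, alpha=1e7))
        np.testing.assert_allclose(theta, 0.5, atol=1e-6)

    def test_beta_hand_counts_full_support(self):
        # V=3, counts (2,1,0), a=b=1: E[Q1]=3/5, E[Q2]=2/3 ->
        # beta = (3/5, 2/3*2/5, 1/3*2/5)
        _, state = make_state([[2, 1, 0]], [0, 0, 0], K=1)
        beta = estimate_beta_draw(state, ZinHyper(K=1, pi=0.0, a=1.0, b=1.0))
        np.testing.assert_allclose(beta[0], [3 / 5, 4 / 15, 2 / 15], rtol=1e-12)
        assert beta.sum() == pytest.approx(1.0, abs=1e-12)

    def test_beta_matches_numeric_integration(self):
        counts = np.array([3, 0, 2, 1, 0])
        _, state = make_state([list(counts)], [0] * counts.sum(), K=1)
        for a, b in [(0.5, 2.0), (1.0, 1.0), (0.05, 10.0)]:
            beta = estimate_beta_draw(state, ZinHyper(K=1, pi=0.0, a=a, b=b))
            oracle = gd_posterior_mean_numeric(counts, a, b)
            np.testing.assert_allclose(beta[0], oracle, atol=1e-6)

    def test_beta_off_support_exactly_zero(self):
        _, state = make_state([[2, 0, 1]], [0, 0, 0], K=1, delta=[[0, 1, 0]])
        beta = estimate_beta_draw(state, ZinHyper(K=1, pi=0.5, a=0.5, b=2.0))
        assert beta[0, 1] == 0.0
        assert beta.sum() == pytest.approx(1.0, abs=1e-12)

    def test_single_support_taxon_gets_everything(self):
        _, state = make_state([[0, 0, 4]], [0] * 4, K=1, delta=[[1, 1, 0]])
        beta = estimate_beta_draw(state, ZinHyper(K=1, pi=0.5, a=0.5, b=2.0))
        np.testing.assert_array_equal(beta[0], [0.0, 0.0, 1.0])


class TestSweepAndChain:
    def test_sweep_preserves_depths_and_consistency(self, tiny_cohort, rng):
        hyper = ZinHyper(K=2, pi=0.3, a=0.5, b=2.0, alpha=1.0)
        rs, rt = expand_reads(tiny_cohort)
        state = ChainState.from_assignments(rs, rt, rng.integers(0, 2, rs.size).astype(np.int32), 2, 3, 2)
        depths = state.m.sum(axis=1).copy()
        for _ in range(10):
            gibbs_sweep(state, hyper, rng)
            assert np.array_equal(state.m.sum(axis=1), depths)
        state.check_consistency()

    def test_pi_zero_never_sets_delta(self, tiny_cohort, rng):
        hyper = ZinHyper(K=2, pi=0.0, a=0.5, b=2.0, alpha=1.0)
        rs, rt = expand_reads(tiny_cohort)
        state = ChainState.from_assignments(rs, rt, rng.integers(0, 2, rs.size).astype(np.int32), 2, 3, 2)
        for _ in range(20):
            gibbs_sweep(state, hyper, rng)
            assert not state.delta.any()

    def test_two_engines_same_invariants(self, tiny_cohort):
        hyper = ZinHyper(K=2, pi=0.3, a=0.5, b=2.0, alpha=1.0)
        for engine in ["numba", "python"]:
            draws = run_chain(tiny_cohort, hyper, n_iter=30, burn_in=10, rng=4, engine=engine)
            np.testing.assert_allclose(draws.beta.sum(axis=2), 1.0, atol=1e-9)
            np.testing.assert_allclose(draws.theta.sum(axis=2), 1.0, atol=1e-9)
            assert set(np.unique(draws.delta)) <= {0, 1}

    def test_determinism_same_seed_same_fit(self, tiny_cohort):
        hyper = ZinHyper(K=2, pi=0.3, a=0.5, b=2.0, alpha=1.0)
        fits = []
        for _ in range(2):
            draws = run_chain(tiny_cohort, hyper, n_iter=60, burn_in=30, rng=7)
            fits.append(finalize(draws))
        np.testing.assert_array_equal(fits[0].beta, fits[1].beta)
        np.testing.assert_array_equal(fits[0].pi_hat, fits[1].pi_hat)

    def test_single_retained_draw(self, tiny_cohort):
        hyper = ZinHyper(K=2, pi=0.3, a=0.5, b=2.0, alpha=1.0)
        draws = run_chain(tiny_cohort, hyper, n_iter=11, burn_in=10, rng=0)
        assert draws.n_draws == 1

    def test_chain_matches_enumerated_posterior_small(self, tiny_cohort):
        # reduced-sweep version of the exactness gate (the full check lives
        # in the acceptance tests)
        K, alpha, pi, a, b = 2, 1.0, 0.4, 0.5, 2.0
        rs, rt = expand_reads(tiny_cohort)
        exact = enumerate_posterior(rs, rt, 2, 3, K, alpha, pi, a, b)
        draws = run_chain(
            tiny_cohort, ZinHyper(K=K, pi=pi, a=a, b=b, alpha=alpha), n_iter=20_000, burn_in=0, rng=5, record_z=True
        )
        from collections import Counter

        from oracles import total_variation

        freq = Counter(
            (tuple(int(x) for x in zrow), tuple(int(x) for x in drow[:, :2].ravel()))
            for zrow, drow in zip(draws.meta["z_draws"], draws.delta)
        )
        assert total_variation(exact, freq, draws.n_draws) < 0.05


class TestFinalize:
    def _draws(self, delta_seq, beta_seq, theta_seq):
        return PosteriorDraws(
            beta=np.asarray(beta_seq, dtype=float),
            theta=np.asarray(theta_seq, dtype=float),
            delta=np.asarray(delta_seq, dtype=np.int8),
        )

    def test_unanimous_delta_zeroes_beta(self):
        draws = self._draws(
            delta_seq=[[[1, 0, 0]], [[1, 0, 0]]],
            beta_seq=[[[0.0, 0.5, 0.5]], [[0.0, 0.25, 0.75]]],
            theta_seq=[[[1.0]], [[1.0]]],
        )
        fit = finalize(draws)
        assert fit.pi_hat[0, 0] == 1.0 and fit.beta[0, 0] == 0.0
        assert fit.beta[0].sum() == pytest.approx(1.0, abs=1e-12)

    def test_tie_at_half_is_zeroed(self):
        draws = self._draws(
            delta_seq=[[[1, 0, 0]], [[0, 0, 0]]],
            beta_seq=[[[0.0, 0.5, 0.5]], [[0.2, 0.4, 0.4]]],
            theta_seq=[[[1.0]], [[1.0]]],
        )
        fit = finalize(draws)
        assert fit.pi_hat[0, 0] == 0.5
        assert fit.delta_hat[0, 0] == 1 and fit.beta[0, 0] == 0.0

    def test_single_draw_reproduced(self):
        beta = np.array([[[0.0, 0.6, 0.4]]])
        draws = self._draws([[[1, 0, 0]]], beta, [[[1.0]]])
        fit = finalize(draws)
        np.testing.assert_allclose(fit.beta, beta[0], atol=1e-12)

    def test_fully_zeroed_community_errors(self):
        draws = self._draws(
            delta_seq=[[[1, 1, 1]]],
            beta_seq=[[[0.0, 0.0, 0.0]]],
            theta_seq=[[[1.0]]],
        )
        with pytest.raises(ValueError):
            finalize(draws)

    def test_renormalization_within_tolerance(self, small_fitted_cohort):
        fit = small_fitted_cohort["zin_fit"]
        np.testing.assert_allclose(fit.beta.sum(axis=1), 1.0, atol=1e-12)
        assert np.array_equal(fit.beta == 0.0, fit.delta_hat == 1)
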