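"""Exact math of the absorbing-state diffusion: schedules, transitions,
posterior (against brute-force Bayes enumeration) and the ELBO."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import abdiff as ab
from abdiff.diffusion_core import (
    MASK_INDEX,
    VOCAB_SIZE,
    NoisedState,
    _categorical_kl,
)
from abdiff.denoiser import OracleDenoiser

PREFIX = np.zeros(64, dtype=np.int64)  # conditioning payload, never noised


def toy_x0(tokens):
    return NoisedState(tokens=np.asarray(tokens, dtype=np.int64), t=0, cdr_prefix=PREFIX)


class TestSchedule:
    def test_default_T512_endpoints(self):
        s = ab.make_schedule(512)
        assert s.beta.shape == (512,)
        assert s.alpha_bar(512) == 0.0
        assert s.alpha_bar(0) == 1.0

    def test_degenerate_T1(self):
        s = ab.make_schedule(1)
        assert s.beta[0] == pytest.approx(1.0)
        assert s.alpha_bar(1) == 0.0

    @pytest.mark.parametrize("T", [1, 7, 512])
    def test_linear_marginal_closed_form(self, T):
        """beta_t = 1/(T-t+1) telescopes to alpha_bar(t) = (T-t)/T."""
        s = ab.make_schedule(T)
        for t in range(1, T + 1):
            assert s.alpha_bar(t) == pytest.approx((T - t) / T, abs=1e-12)
            assert s.beta[t - 1] == pytest.approx(1.0 / (T - t + 1), abs=1e-12)

    @pytest.mark.parametrize("kind", ["linear-marginal", "cosine", "spindle"])
    def test_recurrence_and_monotonicity(self, kind):
        s = ab.make_schedule(64, kind)
        prev = 1.0
        for t in range(1, 65):
            expected = prev * (1.0 - s.beta[t - 1])
            assert s.alpha_bar(t) == pytest.approx(expected, abs=1e-12)
            assert s.alpha_bar(t) <= prev + 1e-12
            prev = s.alpha_bar(t)
        assert s.alpha_bar(64) == 0.0

    def test_unknown_kind(self):
        with pytest.raises(ValueError, match="kind"):
            ab.make_schedule(8, "quadratic")


class TestTransitionMatrices:
    def test_rows_stochastic_and_absorbing(self):
        s = ab.make_schedule(16)
        for t in (1, 8, 16):
            Q = ab.transition_matrix(s, t).Q
            np.testing.assert_allclose(Q.sum(axis=1), 1.0, atol=1e-12)
            assert (Q >= 0).all()
            assert Q[MASK_INDEX, MASK_INDEX] == 1.0
            assert Q[MASK_INDEX].sum() == 1.0

    def test_beta_one_maps_everything_to_mask(self):
        s = ab.make_schedule(4)
        Q = ab.transition_matrix(s, 4).Q  # beta_T = 1
        np.testing.assert_allclose(Q[:, MASK_INDEX], 1.0)

    def test_off_diagonal_structure(self):
        s = ab.make_schedule(8)
        Q = ab.transition_matrix(s, 3).Q
        off = Q.copy()
        np.fill_diagonal(off, 0.0)
        off[:, MASK_INDEX] = 0.0
        assert np.abs(off).max() == 0.0

    @pytest.mark.parametrize("kind", ["linear-marginal", "cosine"])
    def test_cumulative_matches_explicit_product(self, kind):
        """Closed-form Q_bar_t vs the explicit product Q_1 ... Q_t."""
        s = ab.make_schedule(12, kind)
        product = np.eye(VOCAB_SIZE)
        for t in range(1, 13):
            product = product @ ab.transition_matrix(s, t).Q
            closed = ab.cumulative_transition(s, t).Q
            assert np.abs(closed - product).max() < 1e-10
            np.testing.assert_allclose(closed.sum(axis=1), 1.0, atol=1e-12)

    def test_cumulative_t1_is_q1(self):
        s = ab.make_schedule(6)
        np.testing.assert_allclose(
            ab.cumulative_transition(s, 1).Q, ab.transition_matrix(s, 1).Q
        )

    def test_t_out_of_range(self):
        s = ab.make_schedule(6)
        for t in (0, 7):
            with pytest.raises(ValueError):
                ab.transition_matrix(s, t)
            with pytest.raises(ValueError):
                ab.cumulative_transition(s, t)


class TestForwardSample:
    def test_t0_identity(self):
        s = ab.make_schedule(8)
        x0 = toy_x0(np.arange(10))
        out = ab.forward_sample(x0, 0, s, seed=0)
        np.testing.assert_array_equal(out.tokens, x0.tokens)

    def test_tT_fully_masked(self):
        s = ab.make_schedule(8)
        x0 = toy_x0(np.arange(20) % 20)
        out = ab.forward_sample(x0, 8, s, seed=1)
        assert (out.tokens == MASK_INDEX).all()

    def test_prefix_bitwise_invariant(self):
        s = ab.make_schedule(8)
        x0 = toy_x0(np.arange(20) % 20)
        for t in range(9):
            out = ab.forward_sample(x0, t, s, seed=t)
            assert out.cdr_prefix is x0.cdr_prefix

    def test_rejects_masked_input(self):
        s = ab.make_schedule(8)
        bad = NoisedState(np.array([MASK_INDEX, 0]), t=0, cdr_prefix=PREFIX)
        with pytest.raises(ValueError, match="MASK"):
            ab.forward_sample(bad, 1, s)

    def test_mask_fraction_matches_linear_marginal(self):
        """Empirical mask fraction over 10000 draws within 3 sigma of t/T."""
        T = 16
        s = ab.make_schedule(T)
        x0 = toy_x0(np.arange(149) % 20)
        for t in (4, 8, 12):
            rng = np.random.default_rng(t)
            n = 10_000 // 149 + 1
            count = total = 0
            for _ in range(n):
                out = ab.forward_sample(x0, t, s, seed=rng)
                count += int((out.tokens == MASK_INDEX).sum())
                total += 149
            p = t / T
            sigma = np.sqrt(p * (1 - p) / total)
            assert abs(count / total - p) <= 3 * sigma

    def test_marginal_matches_cumulative_transition(self):
        """Iterated single-step masking agrees in distribution with Q_bar."""
        T = 3
        s = ab.make_schedule(T)
        n = 100_000
        rng = np.random.default_rng(9)
        token = 5
        state = np.full(n, token)
        for t in range(1, T + 1):
            mask = rng.random(n) < s.beta[t - 1]
            state = np.where(mask & (state != MASK_INDEX), MASK_INDEX, state)
        # after T steps everything should be masked (alpha_bar(T)=0);
        # compare at t=2 instead for a nondegenerate check
        state = np.full(n, token)
        for t in (1, 2):
            mask = rng.random(n) < s.beta[t - 1]
            state = np.where(mask & (state != MASK_INDEX), MASK_INDEX, state)
        empirical = (state == token).mean()
        expected = ab.cumulative_transition(s, 2).Q[token, token]
        sigma = np.sqrt(expected * (1 - expected) / n)
        assert abs(empirical - expected) <= 4 * sigma

    def test_freeze_columns_exempt(self):
        s = ab.make_schedule(8)
        x0 = toy_x0(np.arange(20) % 20)
        freeze = np.zeros(20, dtype=bool)
        freeze[:5] = True
        out = ab.forward_sample(x0, 8, s, seed=0, freeze_columns=freeze)
        np.testing.assert_array_equal(out.tokens[:5], x0.tokens[:5])
        assert (out.tokens[5:] == MASK_INDEX).all()


def brute_force_posterior(s, t, xt_token, x0_dist):
    """Bayes enumeration: q(x_{t-1}|x_t, x0 ~ x0_dist) via explicit matrices."""
    Qt = ab.transition_matrix(s, t).Q
    Qbar_prev = (
        np.eye(VOCAB_SIZE) if t == 1 else ab.cumulative_transition(s, t - 1).Q
    )
    Qbar_t = ab.cumulative_transition(s, t).Q
    post = np.zeros(VOCAB_SIZE)
    for x0 in range(VOCAB_SIZE):
        w = x0_dist[x0]
        if w == 0:
            continue
        denom = Qbar_t[x0, xt_token]
        if denom == 0:
            continue
        for prev in range(VOCAB_SIZE):
            post[prev] += w * Qt[prev, xt_token] * Qbar_prev[x0, prev] / denom
    return post / post.sum()


class TestPosterior:
    def test_unmasked_positions_are_point_masses(self):
        s = ab.make_schedule(8)
        xt = NoisedState(np.array([3, MASK_INDEX, 7]), t=4, cdr_prefix=PREFIX)
        probs = np.full((3, VOCAB_SIZE), 1.0 / VOCAB_SIZE)
        post = ab.posterior_params(xt, probs, s)
        np.testing.assert_allclose(post[0], np.eye(VOCAB_SIZE)[3])
        np.testing.assert_allclose(post[2], np.eye(VOCAB_SIZE)[7])
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-12)

    @pytest.mark.parametrize("t", [1, 2, 3])
    def test_matches_brute_force_enumeration(self, t):
        """K=4 support (3 residues + mask), T=3, length-2: exact Bayes."""
        s = ab.make_schedule(3)
        rng = np.random.default_rng(t)
        # x0 distribution supported on tokens {0, 1, 2}
        x0_dist = np.zeros(VOCAB_SIZE)
        x0_dist[:3] = rng.dirichlet(np.ones(3))
        for xt_token in (0, MASK_INDEX):
            if xt_token != MASK_INDEX and s.alpha_bar(t) == 0.0:
                continue  # an unmasked x_t at full noise has probability zero
            xt = NoisedState(
                np.array([xt_token, MASK_INDEX]), t=t, cdr_prefix=PREFIX
            )
            probs = np.stack([x0_dist, x0_dist])
            post = ab.posterior_params(xt, probs, s)
            expected = brute_force_posterior(s, t, xt_token, x0_dist)
            np.testing.assert_allclose(post[0], expected, atol=1e-12)

    def test_one_hot_t1_reveals_x0(self):
        """At t=1 a masked position returns x0 with the analytic weight 1."""
        s = ab.make_schedule(4)
        xt = NoisedState(np.array([MASK_INDEX]), t=1, cdr_prefix=PREFIX)
        onehot = np.zeros((1, VOCAB_SIZE))
        onehot[0, 9] = 1.0
        post = ab.posterior_params(xt, onehot, s)
        # reveal weight (alpha_bar_0 - alpha_bar_1)/(1 - alpha_bar_1) = 1
        assert post[0, 9] == pytest.approx(1.0)
        assert post[0, MASK_INDEX] == pytest.approx(0.0)

    def test_rejects_non_stochastic(self):
        s = ab.make_schedule(4)
        xt = NoisedState(np.array([MASK_INDEX]), t=2, cdr_prefix=PREFIX)
        with pytest.raises(ValueError, match="sum to 1"):
            ab.posterior_params(xt, np.full((1, VOCAB_SIZE), 0.5), s)

    @given(t=st.integers(1, 8), seed=st.integers(0, 50))
    def test_rows_are_probability_vectors(self, t, seed):
        s = ab.make_schedule(8)
        rng = np.random.default_rng(seed)
        tokens = rng.integers(0, 20, size=6)
        tokens[rng.random(6) < 0.5] = MASK_INDEX
        xt = NoisedState(tokens, t=t, cdr_prefix=PREFIX)
        probs = rng.dirichlet(np.ones(VOCAB_SIZE), size=6)
        post = ab.posterior_params(xt, probs, s)
        assert (post >= -1e-15).all()
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-9)

    def test_ancestral_sampling_with_oracle_reconstructs_x0(self):
        """Posterior chained from t=T with one-hot x0 probs recovers x0."""
        T = 12
        s = ab.make_schedule(T)
        rng = np.random.default_rng(3)
        x0 = rng.integers(0, 20, size=30)
        onehot = np.eye(VOCAB_SIZE)[x0]
        tokens = np.full(30, MASK_INDEX)
        for t in range(T, 0, -1):
            xt = NoisedState(tokens, t=t, cdr_prefix=PREFIX)
            post = ab.posterior_params(xt, onehot, s)
            cdf = np.cumsum(post, axis=1)
            u = rng.random((30, 1))
            tokens = (u > cdf).sum(axis=1)
        np.testing.assert_array_equal(tokens, x0)


def enumerate_elbo(x0_token, schedule, denoiser_probs):
    """Exhaustive ELBO for a length-1 sequence by summing over all (t, x_t).

    denoiser_probs: (VOCAB_SIZE,) model x0 distribution, input-independent.
    """
    T = schedule.T
    total = 0.0
    for t in range(1, T + 1):
        ab_t = schedule.alpha_bar(t)
        # x_t = x0 with prob alpha_bar_t: both posteriors are the same point
        # mass, zero contribution. x_t = MASK with prob 1 - alpha_bar_t:
        p_masked = 1.0 - ab_t
        xt = NoisedState(np.array([MASK_INDEX]), t=t, cdr_prefix=PREFIX)
        onehot = np.zeros((1, VOCAB_SIZE))
        onehot[0, x0_token] = 1.0
        model = denoiser_probs[None, :]
        if t == 1:
            p_post = ab.posterior_params(xt, model, schedule)
            total += p_masked * np.log(p_post[0, x0_token])
        else:
            q_post = ab.posterior_params(xt, onehot, schedule)
            p_post = ab.posterior_params(xt, model, schedule)
            total -= p_masked * float(_categorical_kl(q_post, np.maximum(p_post, 1e-300))[0])
    return total


class TestElbo:
    def test_oracle_denoiser_gives_zero(self, heavy_repertoire):
        """Per-step KLs vanish when the model always outputs the truth."""
        chain = heavy_repertoire[0]
        tokens = ab.VOCAB.encode(chain.sequence)
        prefix = ab.VOCAB.encode(ab.extract_cdr_prefix(chain))
        oracle = OracleDenoiser(tokens)
        s = ab.make_schedule(8)
        val = ab.elbo(tokens, oracle.as_denoise_fn(), s, prefix, n_samples=24, seed=0)
        assert abs(val) < 1e-9

    def test_uniform_denoiser_matches_enumeration(self):
        """Length-1, T=2, 3-residue support: MC estimate vs exhaustive sum."""
        s = ab.make_schedule(2)
        uniform = np.zeros(VOCAB_SIZE)
        uniform[:3] = 1.0 / 3.0

        def denoise_fn(state, t):
            return uniform[None, :]

        x0 = np.array([1])
        exact = enumerate_elbo(1, s, uniform)
        assert exact == pytest.approx(np.log(1.0 / 3.0), abs=1e-12)
        est = ab.elbo(x0, denoise_fn, s, PREFIX, n_samples=20_000, seed=4)
        # per-draw sd ~ 0.78, so 3 sigma at n=20000 is ~0.017
        assert est == pytest.approx(exact, abs=0.03)

    def test_elbo_nonpositive_for_random_denoisers(self):
        s = ab.make_schedule(6)
        rng = np.random.default_rng(8)
        x0 = rng.integers(0, 20, size=12)
        for trial in range(3):
            dist = rng.dirichlet(np.ones(21), size=12)
            probs = np.zeros((12, VOCAB_SIZE))
            probs[:, :21] = dist

            def denoise_fn(state, t, probs=probs):
                return probs

            val = ab.elbo(x0, denoise_fn, s, PREFIX, n_samples=20, seed=trial)
            assert val <= 1e-12

    def test_rejects_bad_denoiser(self):
        s = ab.make_schedule(4)

        def bad_fn(state, t):
            return np.full((3, VOCAB_SIZE), 0.9)

        with pytest.raises(ValueError, match="stochastic"):
            ab.elbo(np.array([1, 2, 3]), bad_fn, s, PREFIX, n_samples=2, seed=0)
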