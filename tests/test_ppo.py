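"""Policy network, sampling, surrogate objective, advantages, training loop."""

import numpy as np
import pytest

from stairgait.ppo import (
    Adam,
    BernoulliPolicy,
    MLP,
    PPOConfig,
    RolloutBatch,
    ValueNet,
    clipped_objective,
    compute_advantages,
    ppo_update,
    prob_ratio,
    train,
)


class BanditEnv:
    """One-state two-action sanity environment: reward 1 for action bit 1."""

    observation_size = 3
    n_muscles = 1

    def __init__(self, episode_len=16):
        self._t = 0
        self._len = episode_len

    def reset(self, seed=None):
        self._t = 0
        return np.zeros(3), {}

    def step(self, action):
        self._t += 1
        return np.zeros(3), float(action[0]), False, self._t >= self._len, {}


class TestPolicyForward:
    def test_zero_parameters_give_half(self):
        policy = BernoulliPolicy(4, 3, hidden=(8,))
        for p in policy.net.params:
            p[...] = 0.0
        probs = policy.probs(np.ones(4))
        assert np.allclose(probs, 0.5)

    def test_deterministic_for_identical_observations(self, rng):
        policy = BernoulliPolicy(6, 2, hidden=(16,), rng=rng)
        obs = rng.normal(size=6)
        assert np.array_equal(policy.probs(obs), policy.probs(obs.copy()))

    def test_hand_computed_single_unit_network(self):
        # 1 input -> 1 tanh hidden -> 1 sigmoid output, all weights set by hand
        policy = BernoulliPolicy(1, 1, hidden=(1,))
        policy.net.W[0][...] = 2.0
        policy.net.b[0][...] = -1.0
        policy.net.W[1][...] = 3.0
        policy.net.b[1][...] = 0.5
        x = 0.7
        h = np.tanh(2.0 * x - 1.0)
        expect = 1.0 / (1.0 + np.exp(-(3.0 * h + 0.5)))
        assert policy.probs(np.array([x]))[0] == pytest.approx(expect, abs=1e-12)

    def test_dimension_mismatch_rejected(self):
        policy = BernoulliPolicy(4, 2, hidden=(8,))
        with pytest.raises(ValueError):
            policy.probs(np.ones(5))


class TestSampling:
    def test_reproducible_given_seed(self):
        policy = BernoulliPolicy(3, 5, hidden=(8,))
        obs = np.ones(3)
        a1, l1 = policy.act(obs, np.random.default_rng(42))
        a2, l2 = policy.act(obs, np.random.default_rng(42))
        assert np.array_equal(a1, a2)
        assert l1 == l2

    def test_empirical_mean_matches_probability(self, rng):
        policy = BernoulliPolicy(2, 1, hidden=(4,))
        # force p = 0.3 via the output bias
        for p in policy.net.params:
            p[...] = 0.0
        policy.net.b[-1][...] = np.log(0.3 / 0.7)
        draws = np.array([policy.act(np.zeros(2), rng)[0][0] for _ in range(100_000)])
        assert draws.mean() == pytest.approx(0.3, abs=0.005)

    def test_log_prob_matches_bernoulli_product(self, rng):
        policy = BernoulliPolicy(4, 6, hidden=(8,), rng=rng)
        obs = rng.normal(size=4)
        a, logp = policy.act(obs, rng)
        p = policy.probs(obs)
        direct = np.prod(np.where(a > 0.5, p, 1 - p))
        assert np.exp(logp) == pytest.approx(direct, rel=1e-12)


class TestSurrogate:
    def test_ratio_identities(self):
        assert prob_ratio(-1.5, -1.5) == pytest.approx(1.0)
        assert prob_ratio(-1.0 + np.log(2), -1.0) == pytest.approx(2.0)

    def test_ratio_equals_explicit_bernoulli_ratio(self, rng):
        p_new = rng.uniform(0.1, 0.9, size=8)
        p_old = rng.uniform(0.1, 0.9, size=8)
        a = (rng.random(8) < 0.5).astype(float)
        lp_new = np.sum(a * np.log(p_new) + (1 - a) * np.log(1 - p_new))
        lp_old = np.sum(a * np.log(p_old) + (1 - a) * np.log(1 - p_old))
        explicit = np.prod(np.where(a > 0, p_new, 1 - p_new)) / \
            np.prod(np.where(a > 0, p_old, 1 - p_old))
        assert prob_ratio(lp_new, lp_old) == pytest.approx(explicit, rel=1e-12)

    def test_unit_ratios_give_mean_advantage(self, rng):
        adv = rng.normal(size=50)
        assert clipped_objective(np.ones(50), adv, 0.2) == pytest.approx(adv.mean())

    def test_positive_advantage_clip(self):
        assert clipped_objective([1.5], [1.0], 0.2) == pytest.approx(1.2)

    def test_negative_advantage_clip(self):
        # min(0.5 * -1, 0.8 * -1) = -0.8
        assert clipped_objective([0.5], [-1.0], 0.2) == pytest.approx(-0.8)

    def test_clipped_never_exceeds_unclipped_for_positive_advantage(self, rng):
        r = rng.uniform(0.0, 2.5, 100)
        A = rng.uniform(0.0, 2.0, 100)
        clipped = np.minimum(r * A, np.clip(r, 0.8, 1.2) * A)
        assert np.all(clipped <= r * A + 1e-12)
        assert clipped_objective(r, A, 0.2) <= float(np.mean(r * A)) + 1e-12


class TestAdvantages:
    def test_all_zero(self):
        adv, ret = compute_advantages(np.zeros(5), np.zeros(5), 0.99, 0.95)
        assert np.allclose(adv, 0.0)
        assert np.allclose(ret, 0.0)

    def test_single_step_td(self):
        adv, _ = compute_advantages([2.0], [0.5], 1.0, 0.95, last_value=0.25)
        assert adv[0] == pytest.approx(2.0 + 0.25 - 0.5)

    def test_lambda_one_equals_discounted_return_minus_value(self, rng):
        r = rng.normal(size=7)
        v = rng.normal(size=7)
        gamma = 0.9
        adv, ret = compute_advantages(r, v, gamma, 1.0, last_value=0.0)
        # brute-force discounted sums
        for t in range(7):
            G = sum(gamma ** (k - t) * r[k] for k in range(t, 7))
            assert adv[t] == pytest.approx(G - v[t], abs=1e-12)
            assert ret[t] == pytest.approx(G, abs=1e-12)

    def test_three_step_hand_example_vs_brute_force(self):
        r = [1.0, 0.0, 2.0]
        v = [0.5, 0.2, 0.1]
        gamma, lam = 0.9, 0.8
        adv, _ = compute_advantages(r, v, gamma, lam, last_value=0.3)
        deltas = [1.0 + 0.9 * 0.2 - 0.5, 0.0 + 0.9 * 0.1 - 0.2, 2.0 + 0.9 * 0.3 - 0.1]
        g = gamma * lam
        expect = [deltas[0] + g * deltas[1] + g**2 * deltas[2],
                  deltas[1] + g * deltas[2],
                  deltas[2]]
        assert np.allclose(adv, expect, atol=1e-12)

    def test_no_bootstrap_across_episode_ends(self):
        r = [1.0, 1.0]
        v = [0.0, 0.0]
        adv, _ = compute_advantages(r, v, 0.9, 0.9, last_value=5.0,
                                    dones=[True, True])
        assert np.allclose(adv, [1.0, 1.0])


class TestGradientIdentity:
    def test_surrogate_at_old_params_equals_mean_advantage(self, rng):
        """Evaluating the clipped objective at theta = theta_old yields the
        mean advantage exactly (all ratios are 1)."""
        policy = BernoulliPolicy(4, 3, hidden=(8,), rng=rng)
        obs = rng.normal(size=(20, 4))
        actions = (rng.random((20, 3)) < 0.5).astype(float)
        logp_old = policy.log_prob(obs, actions)
        ratios = prob_ratio(policy.log_prob(obs, actions), logp_old)
        adv = rng.normal(size=20)
        assert clipped_objective(ratios, adv, 0.2) == pytest.approx(adv.mean(), rel=1e-12)

    def test_mlp_gradient_matches_finite_differences(self, rng):
        net = MLP((3, 5, 2), rng)
        x = rng.normal(size=(4, 3))
        target = rng.normal(size=(4, 2))

        def loss():
            return float(np.sum((net.forward(x) - target) ** 2))

        out = net.forward(x)
        grads = net.backward(2.0 * (out - target))
        eps = 1e-6
        for gi, p in enumerate(net.params):
            flat = p.ravel()
            for k in (0, flat.size // 2, flat.size - 1):
                old = flat[k]
                flat[k] = old + eps
                up = loss()
                flat[k] = old - eps
                dn = loss()
                flat[k] = old
                assert grads[gi].ravel()[k] == pytest.approx((up - dn) / (2 * eps), abs=1e-4)


class TestTrainingLoop:
    def test_zero_learning_rate_freezes_parameters(self):
        env = BanditEnv()
        cfg = PPOConfig(hidden=(8,), rollout_length=32, total_iterations=3,
                        minibatch_size=32, learning_rate=0.0, value_lr=0.0, seed=0)
        res = train(env, cfg)
        fresh = BernoulliPolicy(3, 1, hidden=(8,), rng=np.random.default_rng(0))
        for a, b in zip(res.policy.net.params, fresh.net.params):
            assert np.array_equal(a, b)

    def test_same_seed_identical_learning_curves(self):
        cfg = PPOConfig(hidden=(8,), rollout_length=64, total_iterations=5,
                        minibatch_size=64, learning_rate=0.01, seed=3)
        r1 = train(BanditEnv(), cfg)
        r2 = train(BanditEnv(), cfg)
        assert r1.mean_rewards == r2.mean_rewards

    def test_bandit_learns_rewarded_action(self):
        env = BanditEnv()
        cfg = PPOConfig(hidden=(8,), rollout_length=64, total_iterations=200,
                        minibatch_size=64, learning_rate=0.01, value_lr=0.01, seed=0)
        res = train(env, cfg)
        assert res.policy.probs(np.zeros(3))[0] > 0.9

    def test_metrics_and_checkpoints_persisted(self, tmp_path):
        env = BanditEnv()
        cfg = PPOConfig(hidden=(8,), rollout_length=32, total_iterations=7,
                        minibatch_size=32, learning_rate=0.01, seed=0,
                        metrics_every=5)
        res = train(env, cfg, out_dir=tmp_path)
        assert (tmp_path / "metrics.csv").exists()
        lines = (tmp_path / "metrics.csv").read_text().splitlines()
        assert len(lines) == 8  # header + 7 iterations
        assert res.checkpoints, "no improvement checkpoint written"
        assert res.checkpoints[0].exists()

    def test_nan_rewards_abort_with_diagnostics(self):
        class NaNEnv(BanditEnv):
            def step(self, action):
                obs, r, term, trunc, info = super().step(action)
                return obs, float("nan"), term, trunc, info

        cfg = PPOConfig(hidden=(8,), rollout_length=16, total_iterations=3,
                        minibatch_size=16, learning_rate=0.01, seed=0)
        res = train(NaNEnv(), cfg)
        assert res.aborted
        assert "non-finite" in res.abort_reason or "NaN" in res.abort_reason


class TestBatchInvariants:
    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            RolloutBatch(np.zeros((3, 2)), np.zeros((2, 1)), np.zeros(3),
                         np.zeros(3), np.zeros(3), np.zeros(3))

    def test_nonfinite_advantages_rejected(self):
        with pytest.raises(ValueError, match="advantages"):
            RolloutBatch(np.zeros((2, 2)), np.zeros((2, 1)), np.zeros(2),
                         np.zeros(2), np.array([1.0, np.inf]), np.zeros(2))
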