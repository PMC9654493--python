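"""Binary muscle-excitation policy and proximal policy optimization.

The policy is a multilayer perceptron with tanh hidden activations whose
final linear layer parameterises independent Bernoulli distributions, one
per muscle (a sigmoid maps each output to an excitation probability; a tanh
output head cannot represent probabilities, so the squashing nonlinearity is
reserved for the hidden layers).  Actions are sampled during training and
thresholded at 0.5 for evaluation.

The update maximises the clipped surrogate

    L(theta) = E_t[ min( r_t A_t, clip(r_t, 1 - eps, 1 + eps) A_t ) ],

with r_t the probability ratio between the new and the collecting policy,
and A_t generalized advantage estimates from a separately trained value
network of the same trunk architecture.  All gradients are computed in
closed form (the networks are small enough that hand-written
backpropagation in numpy is both transparent and fast), and optimised with
Adam.  Every source of randomness flows from a single seeded generator, so
training is exactly reproducible.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "MLP",
    "BernoulliPolicy",
    "ValueNet",
    "PPOConfig",
    "RolloutBatch",
    "prob_ratio",
    "clipped_objective",
    "compute_advantages",
    "collect_rollout",
    "ppo_update",
    "train",
    "TrainResult",
]


class Adam:
    """Adam optimiser over a list of parameter arrays."""

    def __init__(self, params, lr=3e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class MLP:
    """Fully connected net, tanh hidden layers, linear output.

    ``forward`` caches activations; ``backward(dout)`` returns parameter
    gradients (averaging/batching is the caller's responsibility: ``dout``
    is d(loss)/d(output) per sample).
    """

    def __init__(self, sizes, rng: np.random.Generator):
        self.sizes = tuple(sizes)
        self.W = []
        self.b = []
        for n_in, n_out in zip(sizes[:-1], sizes[1:]):
            # orthogonal-ish scaled Gaussian init
            self.W.append(rng.normal(0.0, math.sqrt(1.0 / n_in), size=(n_in, n_out)))
            self.b.append(np.zeros(n_out))
        self._cache = None

    @property
    def params(self):
        return self.W + self.b

    def set_params(self, params):
        n = len(self.W)
        for i in range(n):
            self.W[i][...] = params[i]
            self.b[i][...] = params[n + i]

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        hs = [x]
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            z = hs[-1] @ W + b
            hs.append(np.tanh(z) if i < len(self.W) - 1 else z)
        self._cache = hs
        return hs[-1]

    def backward(self, dout: np.ndarray):
        hs = self._cache
        grads_W = [None] * len(self.W)
        grads_b = [None] * len(self.b)
        delta = np.atleast_2d(dout)
        for i in reversed(range(len(self.W))):
            grads_W[i] = hs[i].T @ delta
            grads_b[i] = delta.sum(axis=0)
            if i > 0:
                delta = (delta @ self.W[i].T) * (1.0 - hs[i] ** 2)
        return grads_W + grads_b


def _sigmoid(z):
    return 0.5 * (1.0 + np.tanh(0.5 * z))


class BernoulliPolicy:
    """MLP policy emitting independent per-muscle excitation probabilities."""

    def __init__(self, obs_size: int, n_actions: int, hidden=(312, 312),
                 rng: np.random.Generator = None, logit_bias_init: float = 0.0):
        rng = rng or np.random.default_rng(0)
        self.net = MLP((obs_size,) + tuple(hidden) + (n_actions,), rng)
        # a negative head bias starts the policy at sparse muscle firing
        self.net.b[-1][:] = logit_bias_init
        self.n_actions = n_actions

    def probs(self, obs: np.ndarray) -> np.ndarray:
        """Excitation probabilities in (0, 1), clipped away from 0/1."""
        p = _sigmoid(self.net.forward(obs))
        out = np.clip(p, 1e-7, 1.0 - 1e-7)
        return out[0] if np.asarray(obs).ndim == 1 else out

    def act(self, obs: np.ndarray, rng: np.random.Generator):
        """Sample a binary action; returns (action, joint log-probability)."""
        p = self.probs(obs)
        a = (rng.random(p.shape) < p).astype(float)
        logp = float(np.sum(a * np.log(p) + (1 - a) * np.log1p(-p)))
        return a, logp

    def mode(self, obs: np.ndarray) -> np.ndarray:
        """Deterministic evaluation action: probabilities thresholded at 0.5."""
        return (self.probs(obs) >= 0.5).astype(float)

    def log_prob(self, obs: np.ndarray, actions: np.ndarray) -> np.ndarray:
        p = self.probs(np.atleast_2d(obs))
        a = np.atleast_2d(actions)
        return np.sum(a * np.log(p) + (1 - a) * np.log1p(-p), axis=1)


class ValueNet:
    """State-value approximator with the same trunk sizes as the policy."""

    def __init__(self, obs_size: int, hidden=(312, 312), rng=None):
        rng = rng or np.random.default_rng(1)
        self.net = MLP((obs_size,) + tuple(hidden) + (1,), rng)

    def value(self, obs: np.ndarray) -> np.ndarray:
        return self.net.forward(np.atleast_2d(obs))[:, 0]


@dataclass
class PPOConfig:
    """Hyperparameters of the clipped-surrogate update and training loop."""

    clip_epsilon: float = 0.2
    gamma: float = 0.99
    gae_lambda: float = 0.95
    learning_rate: float = 3e-4
    epochs_per_update: int = 4
    minibatch_size: int = 256
    rollout_length: int = 2048
    total_iterations: int = 50
    hidden: tuple = (312, 312)
    normalize_advantages: bool = True
    entropy_coef: float = 0.0
    value_lr: float = 1e-3
    lr_decay_to: float = 1.0  # final lr as a fraction of the initial (linear)
    logit_bias_init: float = 0.0
    seed: int = 0
    metrics_every: int = 5  # iterations between metric-file flushes

    def __post_init__(self) -> None:
        if not (0.0 < self.clip_epsilon < 1.0):
            raise ValueError("clip_epsilon must lie in (0, 1)")
        if not (0.0 < self.gamma <= 1.0) or not (0.0 <= self.gae_lambda <= 1.0):
            raise ValueError("invalid gamma or gae_lambda")


@dataclass
class RolloutBatch:
    """Time-aligned transitions collected under one policy."""

    states: np.ndarray
    actions: np.ndarray
    rewards: np.ndarray
    log_probs: np.ndarray
    advantages: np.ndarray
    returns: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.states)
        for name in ("actions", "rewards", "log_probs", "advantages", "returns"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length mismatch")
        if not np.all(np.isfinite(self.advantages)):
            raise ValueError("non-finite advantages")


def prob_ratio(new_logp, old_logp):
    """Probability ratio r_t = exp(log pi_new - log pi_old)."""
    return np.exp(np.asarray(new_logp, dtype=float) - np.asarray(old_logp, dtype=float))


def clipped_objective(ratios, advantages, clip_epsilon: float) -> float:
    """Mean clipped surrogate: E[min(r A, clip(r, 1-eps, 1+eps) A)]."""
    r = np.asarray(ratios, dtype=float)
    A = np.asarray(advantages, dtype=float)
    if r.shape != A.shape:
        raise ValueError("ratios and advantages must have equal length")
    clipped = np.clip(r, 1.0 - clip_epsilon, 1.0 + clip_epsilon)
    return float(np.mean(np.minimum(r * A, clipped * A)))


def compute_advantages(rewards, values, gamma: float, lam: float,
                       last_value: float = 0.0, dones=None):
    """Generalized advantage estimation; returns (advantages, returns).

    ``values`` are V(s_t) for each collected state; ``last_value`` is the
    bootstrap V(s_T) after the final transition.  ``dones`` marks episode
    ends (no bootstrap across them).  With lam = 1 the advantages reduce to
    discounted-return-minus-value.
    """
    r = np.asarray(rewards, dtype=float)
    v = np.asarray(values, dtype=float)
    n = len(r)
    d = np.zeros(n, dtype=bool) if dones is None else np.asarray(dones, dtype=bool)
    adv = np.zeros(n)
    gae = 0.0
    for t in reversed(range(n)):
        v_next = last_value if t == n - 1 else v[t + 1]
        nonterm = 0.0 if d[t] else 1.0
        delta = r[t] + gamma * v_next * nonterm - v[t]
        gae = delta + gamma * lam * nonterm * gae
        adv[t] = gae
    return adv, adv + v


def collect_rollout(env, policy: BernoulliPolicy, value_net: ValueNet,
                    config: PPOConfig, rng: np.random.Generator) -> RolloutBatch:
    """Collect ``rollout_length`` steps, resetting the env at episode ends."""
    obs, _ = env.reset(seed=int(rng.integers(2**31 - 1)))
    S, A, R, L, D = [], [], [], [], []
    for _ in range(config.rollout_length):
        a, logp = policy.act(obs, rng)
        nxt, rew, term, trunc, _info = env.step(a)
        S.append(obs)
        A.append(a)
        R.append(rew)
        L.append(logp)
        D.append(term or trunc)
        obs = nxt
        if term or trunc:
            obs, _ = env.reset(seed=int(rng.integers(2**31 - 1)))
    S = np.array(S)
    values = value_net.value(S)
    last_v = 0.0 if D[-1] else float(value_net.value(obs[None])[0])
    adv, ret = compute_advantages(R, values, config.gamma, config.gae_lambda,
                                  last_value=last_v, dones=D)
    return RolloutBatch(S, np.array(A), np.array(R), np.array(L), adv, ret)


def ppo_update(policy: BernoulliPolicy, value_net: ValueNet, batch: RolloutBatch,
               config: PPOConfig, rng: np.random.Generator,
               pol_opt: Adam = None, val_opt: Adam = None) -> dict:
    """One PPO update: several epochs of minibatch clipped-surrogate ascent.

    Returns diagnostics (mean surrogate, value loss, clip fraction).  NaN in
    either loss raises ``FloatingPointError`` so the caller can abort while
    retaining the previous parameters.
    """
    pol_opt = pol_opt or Adam(policy.net.params, lr=config.learning_rate)
    val_opt = val_opt or Adam(value_net.net.params, lr=config.value_lr)
    n = len(batch.states)
    adv = batch.advantages
    if config.normalize_advantages and n > 1 and adv.std() > 1e-12:
        adv = (adv - adv.mean()) / adv.std()
    eps = config.clip_epsilon
    stats = {"surrogate": 0.0, "value_loss": 0.0, "clip_fraction": 0.0}
    count = 0
    for _epoch in range(config.epochs_per_update):
        order = rng.permutation(n)
        for start in range(0, n, config.minibatch_size):
            idx = order[start : start + config.minibatch_size]
            S = batch.states[idx]
            a = batch.actions[idx]
            A_mb = adv[idx]
            old = batch.log_probs[idx]

            logits = policy.net.forward(S)
            p = np.clip(_sigmoid(logits), 1e-7, 1.0 - 1e-7)
            logp = np.sum(a * np.log(p) + (1 - a) * np.log1p(-p), axis=1)
            r = np.exp(logp - old)
            clipped = np.clip(r, 1.0 - eps, 1.0 + eps)
            surr = np.minimum(r * A_mb, clipped * A_mb)
            if not np.all(np.isfinite(surr)):
                raise FloatingPointError("NaN/inf in PPO surrogate")
            # gradient flows only where the unclipped branch attains the min
            unclipped_active = r * A_mb <= clipped * A_mb
            g_logp = np.where(unclipped_active, r * A_mb, 0.0) / len(idx)
            dlogits = -g_logp[:, None] * (a - p)  # minimise the negative surrogate
            if config.entropy_coef > 0.0:
                dH = p * (1 - p) * np.log((1 - p) / p)
                dlogits -= config.entropy_coef * dH / len(idx)
            grads = policy.net.backward(dlogits)
            pol_opt.step(policy.net.params, grads)

            v = value_net.net.forward(S)[:, 0]
            err = v - batch.returns[idx]
            if not np.all(np.isfinite(err)):
                raise FloatingPointError("NaN/inf in value loss")
            vgrads = value_net.net.backward((2.0 * err / len(idx))[:, None])
            val_opt.step(value_net.net.params, vgrads)

            stats["surrogate"] += float(np.mean(surr))
            stats["value_loss"] += float(np.mean(err**2))
            stats["clip_fraction"] += float(np.mean(~unclipped_active))
            count += 1
    for k in stats:
        stats[k] /= max(count, 1)
    return stats


@dataclass
class TrainResult:
    """Learning curve and final networks of one training run."""

    mean_rewards: list          # mean per-step reward per iteration
    policy: BernoulliPolicy
    value_net: ValueNet
    best_iteration: int
    aborted: bool = False
    abort_reason: str = ""
    checkpoints: list = field(default_factory=list)


def train(env, config: PPOConfig, policy: BernoulliPolicy = None,
          value_net: ValueNet = None, out_dir=None, callback=None) -> TrainResult:
    """Run the full PPO training loop.

    Alternates rollout collection and clipped-surrogate/value updates for
    ``total_iterations`` iterations, recording the mean per-step reward each
    iteration.  Metrics are flushed to ``out_dir/metrics.csv`` every
    ``metrics_every`` iterations and a checkpoint is saved whenever the mean
    reward improves.  Fully reproducible from ``config.seed``.  A NaN loss
    aborts with the last checkpoint retained.
    """
    rng = np.random.default_rng(config.seed)
    obs_size = env.observation_size
    if policy is None:
        policy = BernoulliPolicy(obs_size, env.n_muscles, config.hidden, rng,
                                 logit_bias_init=config.logit_bias_init)
    if value_net is None:
        value_net = ValueNet(obs_size, config.hidden, rng)
    pol_opt = Adam(policy.net.params, lr=config.learning_rate)
    val_opt = Adam(value_net.net.params, lr=config.value_lr)

    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    curve = []
    metrics_rows = []
    best = -np.inf
    best_iter = -1
    result = TrainResult(curve, policy, value_net, best_iter)
    for it in range(config.total_iterations):
        if config.lr_decay_to < 1.0 and config.total_iterations > 1:
            frac = it / (config.total_iterations - 1)
            scale = 1.0 + (config.lr_decay_to - 1.0) * frac
            pol_opt.lr = config.learning_rate * scale
            val_opt.lr = config.value_lr * scale
        try:
            batch = collect_rollout(env, policy, value_net, config, rng)
            mean_r = float(np.mean(batch.rewards))
            curve.append(mean_r)
            stats = ppo_update(policy, value_net, batch, config, rng, pol_opt, val_opt)
        except (FloatingPointError, ValueError) as exc:
            result.aborted = True
            result.abort_reason = str(exc)
            break
        metrics_rows.append({"iteration": it, "mean_reward": mean_r, **stats})
        if mean_r > best:
            best, best_iter = mean_r, it
            result.best_iteration = it
            if out_dir is not None:
                _save_checkpoint(out_dir / f"checkpoint_{it:04d}.npz", policy, value_net)
                result.checkpoints.append(out_dir / f"checkpoint_{it:04d}.npz")
        if out_dir is not None and (it + 1) % config.metrics_every == 0:
            _write_metrics(out_dir / "metrics.csv", metrics_rows)
        if callback is not None:
            callback(it, mean_r, policy)
    if out_dir is not None and metrics_rows:
        _write_metrics(out_dir / "metrics.csv", metrics_rows)
    return result


def _save_checkpoint(path, policy: BernoulliPolicy, value_net: ValueNet) -> None:
    arrays = {}
    for i, p in enumerate(policy.net.params):
        arrays[f"policy_{i}"] = p
    for i, p in enumerate(value_net.net.params):
        arrays[f"value_{i}"] = p
    np.savez(path, **arrays)


def load_checkpoint(path, policy: BernoulliPolicy, value_net: ValueNet = None) -> None:
    data = np.load(path)
    policy.net.set_params([data[f"policy_{i}"] for i in range(len(policy.net.params))])
    if value_net is not None:
        value_net.net.set_params([data[f"value_{i}"] for i in range(len(value_net.net.params))])


def _write_metrics(path, rows) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
        writer.writeheader()
        writer.writerows(rows)
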