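"""Adaptive random search (ARS) policy training.

ARS is a derivative-free evolution-strategy: each update samples
antithetic Gaussian perturbations of the flat parameter vector,
evaluates both signed perturbations as full episodes, keeps the top-b
directions by their better return, and steps along the
reward-difference-weighted average of the kept directions,

    theta' = theta + alpha / (b sigma_R) sum_b (r+ - r-) delta,

with sigma_R the standard deviation of the 2b kept returns.  The
default variant is V2-t: online observation whitening plus top-b
elites.  Because only parameter values move, the wiring of the policy
network (its edge set and synapse signs) is never altered by training.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

from .snn import SNNPolicy, rollout

__all__ = [
    "ARSConfig",
    "TrainingTrace",
    "RunningStat",
    "perturb",
    "ars_update",
    "train",
    "evaluate",
]


@dataclass
class ARSConfig:
    """Hyper-parameters and evaluation protocol of one training run.

    ``total_steps`` counts every environment step of every perturbed
    rollout (both members of each antithetic pair).  Evaluation runs
    every ``eval_every`` steps as the mean return of ``eval_episodes``
    noise-free episodes.
    """

    n_directions: int = 16
    top_b: int = 8
    step_size: float = 0.02
    noise_scale: float = 0.03
    reward_std_norm: bool = True
    obs_norm: bool = True
    total_steps: int = 300_000
    eval_every: int = 10_000
    eval_episodes: int = 10
    max_episode_steps: int = 1_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.top_b <= self.n_directions:
            raise ValueError("need 1 <= top_b <= n_directions")
        if self.step_size <= 0 or self.noise_scale <= 0:
            raise ValueError("step size and noise scale must be positive")


@dataclass
class TrainingTrace:
    """Evaluation points (env_steps, mean, std) and the best parameters."""

    eval_points: list[tuple[int, float, float]] = field(default_factory=list)
    best_params: np.ndarray | None = None
    best_return: float = -np.inf

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["steps", "mean_return", "std_return"])
            w.writerows(self.eval_points)


class RunningStat:
    """Welford online mean/variance used for observation whitening."""

    def __init__(self, dim: int):
        self.n = 0
        self.mean = np.zeros(dim)
        self._m2 = np.zeros(dim)

    def update(self, x: np.ndarray) -> None:
        self.n += 1
        delta = x - self.mean
        self.mean += delta / self.n
        self._m2 += delta * (x - self.mean)

    @property
    def std(self) -> np.ndarray:
        if self.n < 2:
            return np.ones_like(self.mean)
        return np.sqrt(np.maximum(self._m2 / self.n, 1e-8))

    def normalize(self, x: np.ndarray) -> np.ndarray:
        if self.n < 2:
            return x
        return (x - self.mean) / self.std


def perturb(
    theta: np.ndarray, nu: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Antithetic pair theta +/- nu*delta with standard-normal delta."""
    if nu <= 0:
        raise ValueError("noise scale must be positive")
    delta = rng.standard_normal(theta.shape)
    return theta + nu * delta, theta - nu * delta, delta


def ars_update(
    theta: np.ndarray,
    direction_results: list[tuple[np.ndarray, float, float]],
    cfg: ARSConfig,
) -> np.ndarray:
    """One ARS parameter update from evaluated antithetic directions.

    ``direction_results`` holds (delta, r_plus, r_minus) triples; the
    top_b directions by max(r_plus, r_minus) are kept.
    """
    if not direction_results:
        raise ValueError("no direction results")
    ranked = sorted(
        direction_results, key=lambda t: max(t[1], t[2]), reverse=True
    )[: cfg.top_b]
    rewards = np.array([[r_p, r_m] for _, r_p, r_m in ranked])
    sigma_r = rewards.std()
    if not cfg.reward_std_norm or sigma_r < 1e-12:
        sigma_r = 1.0
    step = np.zeros_like(theta)
    for delta, r_p, r_m in ranked:
        step += (r_p - r_m) * delta
    return theta + cfg.step_size / (len(ranked) * sigma_r) * step


def evaluate(
    policy: SNNPolicy,
    env,
    episodes: int = 10,
    max_steps: int = 1000,
    seeds: list[int] | None = None,
    obs_transform=None,
) -> tuple[float, float]:
    """Mean and std of the return over noise-free episodes."""
    seeds = seeds if seeds is not None else list(range(episodes))
    returns = [
        rollout(policy, env, max_steps, env_seed=s, obs_transform=obs_transform)[0]
        for s in seeds[:episodes]
    ]
    return float(np.mean(returns)), float(np.std(returns))


def train(policy: SNNPolicy, env, cfg: ARSConfig) -> TrainingTrace:
    """ARS training loop under the step-budget evaluation protocol.

    Repeats perturb -> rollout pair -> update until ``total_steps``
    environment steps are consumed, evaluating every ``eval_every``
    steps; fully reproducible from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    theta = policy.get_params()
    stat = RunningStat(policy.io.obs_dim) if cfg.obs_norm else None

    def train_filter(obs):
        if stat is None:
            return obs
        stat.update(obs)
        return stat.normalize(obs)

    def eval_filter(obs):
        return obs if stat is None else stat.normalize(obs)

    trace = TrainingTrace()
    steps_done = 0
    next_eval = cfg.eval_every
    update_idx = 0
    cost_per_update = 2 * cfg.n_directions  # at least one step per rollout
    if cfg.total_steps < cost_per_update:
        raise ValueError("step budget smaller than a single update")

    def run_eval() -> None:
        policy.set_params(theta)
        mean, std = evaluate(
            policy,
            env,
            episodes=cfg.eval_episodes,
            max_steps=cfg.max_episode_steps,
            seeds=list(range(cfg.eval_episodes)),
            obs_transform=eval_filter,
        )
        trace.eval_points.append((steps_done, mean, std))
        if mean > trace.best_return:
            trace.best_return = mean
            trace.best_params = theta.copy()

    while steps_done < cfg.total_steps:
        results = []
        for _ in range(cfg.n_directions):
            t_plus, t_minus, delta = perturb(theta, cfg.noise_scale, rng)
            policy.set_params(t_plus)
            r_plus, n_plus = rollout(
                policy, env, cfg.max_episode_steps,
                env_seed=int(rng.integers(2**31)), obs_transform=train_filter,
            )
            policy.set_params(t_minus)
            r_minus, n_minus = rollout(
                policy, env, cfg.max_episode_steps,
                env_seed=int(rng.integers(2**31)), obs_transform=train_filter,
            )
            results.append((delta, r_plus, r_minus))
            steps_done += n_plus + n_minus
        theta = ars_update(theta, results, cfg)
        update_idx += 1
        while steps_done >= next_eval and next_eval <= cfg.total_steps:
            run_eval()
            next_eval += cfg.eval_every
    policy.set_params(theta)
    if trace.best_params is None:
        run_eval()
    return trace
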