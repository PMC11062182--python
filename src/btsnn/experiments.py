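"""Reduced-scale topology-vs-random training experiments.

A desk-scale analogue of full physics-simulator benchmarks: train the
same spiking policy architecture on the toy mountain-car task once per
seed for a planted brain-like topology and once for its matched
uniform-random baseline, recording the initial-policy evaluation and
the best evaluation reached.  Per-seed improvement (best > initial) is
the robust summary at small step budgets, where absolute scores are
dominated by how quickly the search trims wasted action cost.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ars import ARSConfig, evaluate, train
from .envs import toy_mountain_car
from .snn import SNNPolicy
from .synthetic import synthetic_connectome, two_module_spec
from .topology import BTNetwork, build_bt_network, matched_random_network

__all__ = [
    "ExperimentResult",
    "planted_toy_network",
    "train_improvement_experiment",
    "matched_pair_experiment",
]


@dataclass
class ExperimentResult:
    """Per-seed initial and best evaluation returns for one topology."""

    name: str
    initial: list[float] = field(default_factory=list)
    best: list[float] = field(default_factory=list)

    @property
    def n_improved(self) -> int:
        return sum(b > i for i, b in zip(self.initial, self.best))

    @property
    def n_seeds(self) -> int:
        return len(self.initial)


def planted_toy_network(seed: int = 3) -> BTNetwork:
    """10-node network from the large module of a planted two-module
    connectome; covers input, hidden, and output roles."""
    spec = two_module_spec(sizes=(10, 5), p_within=0.8, p_between=0.05, seed=seed)
    c, truth = synthetic_connectome(spec)
    nodes = [r for r in c.region_ids if truth[r] == 0]
    return build_bt_network(c, nodes, seed=0)


def train_improvement_experiment(
    net: BTNetwork,
    seeds: range | list[int],
    total_steps: int = 20_000,
    eval_every: int = 5_000,
    max_episode_steps: int = 500,
    n_directions: int = 8,
    top_b: int = 4,
    name: str | None = None,
) -> ExperimentResult:
    """Train ``net`` on toy mountain-car once per seed.

    Records the noise-free evaluation of the freshly initialized policy
    and the best evaluation over training; deterministic per seed.
    """
    result = ExperimentResult(name=name or net.name)
    for seed in seeds:
        env = toy_mountain_car()
        policy = SNNPolicy.from_network(net, env.obs_dim, env.act_dim, seed=seed)
        init_mean, _ = evaluate(
            policy, env, episodes=1, max_steps=max_episode_steps
        )
        cfg = ARSConfig(
            n_directions=n_directions,
            top_b=top_b,
            total_steps=total_steps,
            eval_every=eval_every,
            eval_episodes=1,
            max_episode_steps=max_episode_steps,
            seed=seed,
        )
        trace = train(policy, env, cfg)
        result.initial.append(init_mean)
        result.best.append(trace.best_return)
    return result


def matched_pair_experiment(
    seeds: range | list[int],
    net: BTNetwork | None = None,
    rand_seed: int = 0,
    **kwargs,
) -> tuple[ExperimentResult, ExperimentResult]:
    """Planted topology vs matched random baseline, same protocol."""
    net = net or planted_toy_network()
    rnd = matched_random_network(net, seed=rand_seed)
    return (
        train_improvement_experiment(net, seeds, name=net.name, **kwargs),
        train_improvement_experiment(rnd, seeds, name=rnd.name, **kwargs),
    )
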