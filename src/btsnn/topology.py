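"""Biologically-constrained subnetwork selection and network construction.

Link communities are filtered by node-count band, community
connectedness band, and functional coverage (the cluster must contain
sensation, motor, and other regions so it can serve as input, output,
and hidden layers of a policy network).  A selected cluster's node set
plus the original *directed* connectome entries among those nodes forms
a BTNetwork: roles follow the functional groups and each synapse gets
an excitatory or inhibitory sign, with a fixed excitatory fraction
(default 70%, the cortical ratio).  Matched uniform-random baselines
with identical node/synapse/role/sign counts provide the null topology.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .connectome import GROUPS, Connectome, WeightedGraph
from .linkclust import LinkPartition, community_connectedness

__all__ = [
    "SelectionConstraints",
    "BTNetwork",
    "select_candidates",
    "build_bt_network",
    "network_sparsity",
    "generate_net_rand",
    "matched_random_network",
    "threshold_connections",
]

ROLE_OF_GROUP = {"sensation": "input", "motor": "output", "other": "hidden"}


@dataclass
class SelectionConstraints:
    """Bands a link community must satisfy to become a policy topology."""

    size_band: tuple[int, int] = (30, 60)
    connectedness_band: tuple[float, float] = (10.0, 40.0)
    required_groups: frozenset[str] = frozenset(GROUPS)

    def __post_init__(self) -> None:
        if self.size_band[0] > self.size_band[1]:
            raise ValueError("empty size band")
        if self.connectedness_band[0] > self.connectedness_band[1]:
            raise ValueError("empty connectedness band")
        if not set(self.required_groups) <= set(GROUPS):
            raise ValueError("unknown functional group in required_groups")


@dataclass
class BTNetwork:
    """Role-annotated signed directed network wiring a spiking policy.

    ``nodes`` is ordered; ``roles[node]`` in {input, hidden, output};
    ``synapses`` is a list of ``(source, target, strength, sign)`` with
    strength > 0 and sign in {excitatory, inhibitory}.
    """

    nodes: list[str]
    roles: dict[str, str]
    synapses: list[tuple[str, str, float, str]]
    name: str = "NET"

    def __post_init__(self) -> None:
        for s, t, w, sign in self.synapses:
            if w <= 0:
                raise ValueError(f"non-positive synapse strength {s}->{t}")
            if sign not in ("excitatory", "inhibitory"):
                raise ValueError(f"bad sign {sign!r}")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_synapses(self) -> int:
        return len(self.synapses)

    @property
    def n_excitatory(self) -> int:
        return sum(1 for *_, sign in self.synapses if sign == "excitatory")

    def nodes_with_role(self, role: str) -> list[str]:
        return [n for n in self.nodes if self.roles[n] == role]

    def role_counts(self) -> dict[str, int]:
        counts = {"input": 0, "hidden": 0, "output": 0}
        for n in self.nodes:
            counts[self.roles[n]] += 1
        return counts

    def edge_set(self) -> set[tuple[str, str]]:
        return {(s, t) for s, t, *_ in self.synapses}

    def to_csv(self, edge_path, node_path) -> None:
        pd.DataFrame(
            self.synapses, columns=["source", "target", "strength", "sign"]
        ).to_csv(edge_path, index=False, float_format="%.17g")
        pd.DataFrame(
            {"region": self.nodes, "role": [self.roles[n] for n in self.nodes]}
        ).to_csv(node_path, index=False)

    @classmethod
    def from_csv(cls, edge_path, node_path, name: str = "NET") -> "BTNetwork":
        edges = pd.read_csv(edge_path, float_precision="round_trip")
        nodes = pd.read_csv(node_path)
        return cls(
            nodes=[str(n) for n in nodes["region"]],
            roles=dict(zip(nodes["region"].astype(str), nodes["role"])),
            synapses=[
                (str(r.source), str(r.target), float(r.strength), str(r.sign))
                for r in edges.itertuples()
            ],
            name=name,
        )


def select_candidates(
    p: LinkPartition,
    c: Connectome,
    g: WeightedGraph,
    k: SelectionConstraints | None = None,
) -> list[int]:
    """Cluster indices passing size, connectedness, and coverage filters.

    A cluster qualifies when its incident-node count lies in
    ``size_band``, its community connectedness C_i lies in
    ``connectedness_band``, and its node set covers every required
    functional group.  The result is sorted by C_i (ascending).
    """
    k = k or SelectionConstraints()
    out = []
    for i, nodes in enumerate(p.node_sets()):
        if not k.size_band[0] <= len(nodes) <= k.size_band[1]:
            continue
        ci = community_connectedness(p, i, g)
        if not k.connectedness_band[0] <= ci <= k.connectedness_band[1]:
            continue
        present = {c.groups[n] for n in nodes}
        if not set(k.required_groups) <= present:
            continue
        out.append((ci, i))
    return [i for _, i in sorted(out)]


def _assign_signs(
    m: int,
    exc_ratio: float,
    rng: np.random.Generator,
    strengths: list[float] | None = None,
    assignment: str = "random",
) -> list[str]:
    """Exactly round(exc_ratio * m) excitatory labels over m synapses."""
    n_exc = round(exc_ratio * m)
    if assignment == "random":
        exc_idx = set(rng.choice(m, size=n_exc, replace=False).tolist())
    elif assignment == "strength":
        order = np.argsort(np.argsort([-s for s in strengths], kind="stable"))
        exc_idx = {i for i in range(m) if order[i] < n_exc}
    else:
        raise ValueError(f"unknown sign assignment rule {assignment!r}")
    return ["excitatory" if i in exc_idx else "inhibitory" for i in range(m)]


def build_bt_network(
    c: Connectome,
    cluster_nodes,
    exc_ratio: float = 0.7,
    seed: int = 0,
    assignment: str = "random",
    name: str | None = None,
) -> BTNetwork:
    """Wire the directed subnetwork induced by ``cluster_nodes``.

    Roles map from functional groups (sensation -> input, motor ->
    output, other -> hidden).  Exactly ``round(exc_ratio * m)`` synapses
    are labeled excitatory, chosen uniformly at random under ``seed``
    (or strongest-first with ``assignment='strength'``).
    """
    nodes = sorted(cluster_nodes, key=c.index_of)
    unknown = set(nodes) - set(c.region_ids)
    if unknown:
        raise ValueError(f"unknown regions {sorted(unknown)}")
    if not 0.0 <= exc_ratio <= 1.0:
        raise ValueError("exc_ratio must lie in [0, 1]")
    w = c.subgraph_weights(nodes)
    edges = [
        (nodes[i], nodes[j], float(w[i, j]))
        for i in range(len(nodes))
        for j in range(len(nodes))
        if i != j and w[i, j] > 0
    ]
    if not edges:
        raise ValueError("cluster has no internal directed connections")
    rng = np.random.default_rng(seed)
    signs = _assign_signs(
        len(edges), exc_ratio, rng, [e[2] for e in edges], assignment
    )
    return BTNetwork(
        nodes=nodes,
        roles={n: ROLE_OF_GROUP[c.groups[n]] for n in nodes},
        synapses=[(s, t, wgt, sg) for (s, t, wgt), sg in zip(edges, signs)],
        name=name or f"NET-{len(nodes)}",
    )


def network_sparsity(b: BTNetwork) -> float:
    """1 − m / (n(n−1)): fraction of absent ordered node pairs."""
    n, m = b.n_nodes, b.n_synapses
    if n < 2:
        raise ValueError("sparsity undefined for fewer than 2 nodes")
    return 1.0 - m / (n * (n - 1))


def generate_net_rand(
    n_nodes: int,
    n_synapses: int,
    role_counts: dict[str, int],
    exc_ratio: float = 0.7,
    seed: int = 0,
    strength_pool: list[float] | None = None,
    name: str = "NET-Rand",
) -> BTNetwork:
    """Uniform random simple digraph matched to a reference topology.

    Exactly ``n_synapses`` directed edges drawn uniformly from the
    n(n−1) ordered pairs; role labels honor ``role_counts``; sign
    counts follow the same round(exc_ratio * m) rule as
    :func:`build_bt_network`.  Strengths are resampled with replacement
    from ``strength_pool`` (constant 1.0 when none given).
    """
    if sum(role_counts.values()) != n_nodes:
        raise ValueError("role counts do not sum to node count")
    max_edges = n_nodes * (n_nodes - 1)
    if n_synapses > max_edges:
        raise ValueError(f"cannot place {n_synapses} edges among {max_edges} pairs")
    rng = np.random.default_rng(seed)
    nodes = [f"R{i:03d}" for i in range(n_nodes)]
    roles: dict[str, str] = {}
    i = 0
    for role in ("input", "hidden", "output"):
        for _ in range(role_counts.get(role, 0)):
            roles[nodes[i]] = role
            i += 1
    pair_idx = rng.choice(max_edges, size=n_synapses, replace=False)
    edges = []
    for p in sorted(pair_idx.tolist()):
        s, t = divmod(p, n_nodes - 1)
        t = t if t < s else t + 1
        edges.append((nodes[s], nodes[t]))
    if strength_pool:
        strengths = rng.choice(strength_pool, size=n_synapses, replace=True)
    else:
        strengths = np.ones(n_synapses)
    signs = _assign_signs(n_synapses, exc_ratio, rng, list(strengths))
    return BTNetwork(
        nodes=nodes,
        roles=roles,
        synapses=[
            (s, t, float(w), sg)
            for (s, t), w, sg in zip(edges, strengths, signs)
        ],
        name=name,
    )


def matched_random_network(ref: BTNetwork, seed: int = 0) -> BTNetwork:
    """NET-Rand baseline matched to ``ref``'s node, synapse, role and
    excitatory counts, with strengths resampled from ``ref``."""
    exc_ratio = ref.n_excitatory / ref.n_synapses
    return generate_net_rand(
        ref.n_nodes,
        ref.n_synapses,
        ref.role_counts(),
        exc_ratio=exc_ratio,
        seed=seed,
        strength_pool=[w for *_, w, _ in ref.synapses],
        name=f"{ref.name}-Rand",
    )


def threshold_connections(b: BTNetwork, min_strength: float) -> BTNetwork:
    """Drop synapses weaker than ``min_strength``; nodes are retained."""
    if min_strength < 0:
        raise ValueError("threshold must be non-negative")
    return BTNetwork(
        nodes=list(b.nodes),
        roles=dict(b.roles),
        synapses=[syn for syn in b.synapses if syn[2] >= min_strength],
        name=b.name,
    )
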