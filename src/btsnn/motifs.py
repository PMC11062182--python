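"""Directed 3-node motif census and random-null significance.

Every weakly-connected unordered node triple of a simple digraph falls
into exactly one of the 13 connected triad isomorphism classes
(numbered 1-13; the canonical adjacency matrices ship in
``data/triad_motifs.json``).  Motif class frequencies are compared to a
uniform G(n, m) null ensemble: per class, a one-sided add-one P-value
P = (1 + #{null frequency >= observed}) / (ensemble size + 1), and the
"credible frequency" = frequency x (1 - P), which discounts classes a
size-matched random digraph reproduces equally often.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import networkx as nx
import numpy as np

__all__ = [
    "MOTIF_ADJACENCY",
    "N_MOTIF_CLASSES",
    "MotifCensus",
    "motif_census",
    "null_ensemble",
    "motif_significance",
    "plot_motif_distribution",
]

N_MOTIF_CLASSES = 13


def _load_motif_dictionary() -> dict[int, np.ndarray]:
    raw = json.loads(
        resources.files("btsnn.data").joinpath("triad_motifs.json").read_text()
    )
    return {int(k): np.array(v, dtype=int) for k, v in raw.items()}


MOTIF_ADJACENCY = _load_motif_dictionary()


def _triad_code_map() -> dict[str, int]:
    """Triad-census code (e.g. '030T') -> motif id, derived from the
    shipped canonical matrices so numbering cannot drift."""
    code_of: dict[str, int] = {}
    for motif_id, adj in MOTIF_ADJACENCY.items():
        g = nx.from_numpy_array(adj, create_using=nx.DiGraph)
        code = nx.triads.triad_type(g)
        if code in code_of:
            raise RuntimeError(f"duplicate triad class in motif dictionary: {code}")
        code_of[code] = motif_id
    if len(code_of) != N_MOTIF_CLASSES:
        raise RuntimeError("motif dictionary does not cover 13 classes")
    return code_of

_CODE_TO_MOTIF = _triad_code_map()


@dataclass
class MotifCensus:
    """Counts, frequencies and (optionally) null statistics per class.

    Arrays are length 13; index ``i`` is motif class ``i + 1``.
    """

    counts: np.ndarray
    total_triples: int
    frequencies: np.ndarray = field(init=False)
    p_values: np.ndarray | None = None
    credible: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (N_MOTIF_CLASSES,):
            raise ValueError("census needs one count per motif class")
        if self.counts.sum() != self.total_triples:
            raise ValueError("counts do not sum to the connected-triple total")
        if self.total_triples > 0:
            self.frequencies = self.counts / self.total_triples
        else:
            self.frequencies = np.zeros(N_MOTIF_CLASSES)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "motif_id": np.arange(1, N_MOTIF_CLASSES + 1),
                "count": self.counts,
                "frequency": self.frequencies,
                "p_value": self.p_values,
                "credible_frequency": self.credible,
            }
        )


def _as_digraph(edges) -> nx.DiGraph:
    if isinstance(edges, nx.DiGraph):
        g = edges
    elif hasattr(edges, "edge_set"):  # BTNetwork
        g = nx.DiGraph()
        g.add_nodes_from(edges.nodes)
        g.add_edges_from(edges.edge_set())
    else:
        g = nx.DiGraph()
        g.add_edges_from(edges)
    if any(u == v for u, v in g.edges):
        raise ValueError("self-loops are not allowed in the motif census")
    return g


def motif_census(edges) -> MotifCensus:
    """Classify every connected node triple into its motif class.

    ``edges`` may be an iterable of directed pairs, a networkx DiGraph,
    or a BTNetwork (signs and strengths ignored).  Graphs with fewer
    than 3 nodes yield an all-zero census.
    """
    g = _as_digraph(edges)
    counts = np.zeros(N_MOTIF_CLASSES, dtype=int)
    if g.number_of_nodes() >= 3:
        census = nx.triadic_census(g)
        for code, motif_id in _CODE_TO_MOTIF.items():
            counts[motif_id - 1] = census[code]
    return MotifCensus(counts=counts, total_triples=int(counts.sum()))


def null_ensemble(
    n: int, m: int, size: int = 1000, seed: int = 0
) -> list[list[tuple[int, int]]]:
    """``size`` uniform simple digraphs with exactly n nodes, m edges."""
    max_edges = n * (n - 1)
    if m > max_edges:
        raise ValueError(f"cannot place {m} edges among {max_edges} ordered pairs")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(size):
        pair_idx = rng.choice(max_edges, size=m, replace=False)
        edges = []
        for p in pair_idx.tolist():
            s, t = divmod(p, n - 1)
            t = t if t < s else t + 1
            edges.append((s, t))
        out.append(edges)
    return out


def motif_significance(
    observed: MotifCensus, ensemble_censuses: list[MotifCensus]
) -> MotifCensus:
    """Attach one-sided add-one P-values and credible frequencies.

    Per class, P = (1 + #{null frequency >= observed frequency}) /
    (ensemble size + 1); credible = observed frequency x (1 - P).
    Add-one smoothing keeps P > 0 so credible < frequency strictly.
    """
    if not ensemble_censuses:
        raise ValueError("empty null ensemble")
    null_freq = np.stack([c.frequencies for c in ensemble_censuses])
    n_null = len(ensemble_censuses)
    exceed = (null_freq >= observed.frequencies[None, :]).sum(axis=0)
    p = (1.0 + exceed) / (n_null + 1.0)
    return MotifCensus(
        counts=observed.counts,
        total_triples=observed.total_triples,
        p_values=p,
        credible=observed.frequencies * (1.0 - p),
    )


def plot_motif_distribution(census: MotifCensus, ax=None, label: str | None = None):
    """Bar plot of credible frequency (or plain frequency) per class."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    y = census.credible if census.credible is not None else census.frequencies
    ax.bar(np.arange(1, N_MOTIF_CLASSES + 1), y, label=label)
    ax.set_xlabel("motif class")
    ax.set_ylabel(
        "credible frequency" if census.credible is not None else "frequency"
    )
    ax.set_xticks(np.arange(1, N_MOTIF_CLASSES + 1))
    if label:
        ax.legend(frameon=False)
    return ax
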