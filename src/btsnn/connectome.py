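"""Region-level connectome containers and I/O.

A mesoscale connectome is a square non-negative matrix of projection
strengths between brain regions, together with an annotation table that
assigns each region an acronym, a long name, and a functional group
(``sensation``, ``motor`` or ``other``).  The directed matrix is kept for
synapse wiring and motif analysis; link clustering operates on an
undirected, symmetrized view of it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GROUPS",
    "Connectome",
    "WeightedGraph",
    "load_connectome",
    "write_connectome",
    "symmetrize",
    "group_counts",
]

log = logging.getLogger(__name__)

GROUPS = ("sensation", "motor", "other")


@dataclass
class Connectome:
    """Weighted directed region graph with functional annotations.

    Parameters
    ----------
    region_ids : list of str
        Ordered region identifiers (acronyms).  Row/column ``i`` of
        ``weights`` refers to ``region_ids[i]``.
    weights : ndarray of shape (n, n)
        ``weights[s, t]`` is the connection strength from source region
        ``s`` to target region ``t``.  Non-negative, zero diagonal.
    groups : dict
        Region id -> functional group in :data:`GROUPS`.
    names : dict, optional
        Region id -> long descriptive name.
    """

    region_ids: list[str]
    weights: np.ndarray
    groups: dict[str, str]
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        n = len(self.region_ids)
        if self.weights.shape != (n, n):
            raise ValueError(
                f"weight matrix shape {self.weights.shape} does not match "
                f"{n} regions"
            )
        if len(set(self.region_ids)) != n:
            raise ValueError("duplicate region identifiers")
        if np.any(self.weights < 0):
            raise ValueError("negative weight in connectivity matrix")
        if np.any(np.diag(self.weights) != 0):
            warnings.warn("self-loops on the diagonal dropped", stacklevel=2)
            np.fill_diagonal(self.weights, 0.0)
        missing = set(self.region_ids) - set(self.groups)
        if missing:
            raise ValueError(f"regions without a functional group: {sorted(missing)[:5]}")
        bad = {g for g in self.groups.values() if g not in GROUPS}
        if bad:
            raise ValueError(f"unknown group label(s): {sorted(bad)}")

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    @property
    def n_connections(self) -> int:
        """Number of strictly positive off-diagonal directed entries."""
        return int(np.count_nonzero(self.weights))

    def index_of(self, region: str) -> int:
        return self.region_ids.index(region)

    def subgraph_weights(self, regions: list[str]) -> np.ndarray:
        idx = [self.index_of(r) for r in regions]
        return self.weights[np.ix_(idx, idx)]


@dataclass
class WeightedGraph:
    """Undirected weighted graph used by link clustering.

    ``edge_weights`` maps sorted node pairs ``(u, v)`` (``u < v``) to a
    strictly positive strength.  ``M`` is the edge count and
    ``avg_degree`` the whole-network average degree ``2M / |nodes|``.
    """

    nodes: list[str]
    edge_weights: dict[tuple[str, str], float]

    def __post_init__(self) -> None:
        for (u, v), w in self.edge_weights.items():
            if u == v:
                raise ValueError(f"self-pair {u!r} in edge set")
            if w <= 0:
                raise ValueError(f"non-positive weight on edge ({u}, {v})")

    @property
    def M(self) -> int:
        return len(self.edge_weights)

    @property
    def avg_degree(self) -> float:
        return 2.0 * self.M / len(self.nodes)

    def weight(self, u: str, v: str) -> float:
        return self.edge_weights.get((u, v) if u < v else (v, u), 0.0)

    def neighbors(self, u: str) -> list[str]:
        out = []
        for a, b in self.edge_weights:
            if a == u:
                out.append(b)
            elif b == u:
                out.append(a)
        return out

    def links(self) -> list[tuple[str, str]]:
        """Edges as sorted tuples, in deterministic lexicographic order."""
        return sorted(self.edge_weights)


def load_connectome(matrix_path, annotation_path) -> Connectome:
    """Read a delimited connectivity matrix plus its annotation table.

    The matrix file carries region acronyms in the first row and first
    column; the annotation file has columns ``acronym,name,group``.
    Acronyms are matched case-sensitively.  Negative entries are
    rejected; diagonal entries are dropped with a warning.
    """
    mat = pd.read_csv(matrix_path, index_col=0, sep=None, engine="python")
    mat.columns = [str(c) for c in mat.columns]
    mat.index = [str(i) for i in mat.index]
    if mat.shape[0] != mat.shape[1]:
        raise ValueError(f"non-square matrix: {mat.shape}")
    if list(mat.index) != list(mat.columns):
        raise ValueError("row labels do not match column labels")

    ann = pd.read_csv(annotation_path, sep=None, engine="python")
    required = {"acronym", "group"}
    if not required.issubset(ann.columns):
        raise ValueError(f"annotation table needs columns {sorted(required)}")
    ann["acronym"] = ann["acronym"].astype(str)
    if set(ann["acronym"]) != set(mat.index):
        raise ValueError("region labels differ between matrix and annotations")

    groups = dict(zip(ann["acronym"], ann["group"]))
    names = (
        dict(zip(ann["acronym"], ann["name"].astype(str)))
        if "name" in ann.columns
        else {}
    )
    c = Connectome(
        region_ids=list(mat.index),
        weights=mat.to_numpy(dtype=float),
        groups=groups,
        names=names,
    )
    log.info(
        "loaded connectome: %d regions, %d nonzero directed connections",
        c.n_regions,
        c.n_connections,
    )
    return c


def write_connectome(c: Connectome, matrix_path, annotation_path) -> None:
    """Write ``c`` in the same CSV dialect :func:`load_connectome` reads."""
    pd.DataFrame(c.weights, index=c.region_ids, columns=c.region_ids).to_csv(
        matrix_path, float_format="%.17g"
    )
    pd.DataFrame(
        {
            "acronym": c.region_ids,
            "name": [c.names.get(r, r) for r in c.region_ids],
            "group": [c.groups[r] for r in c.region_ids],
        }
    ).to_csv(annotation_path, index=False)


def symmetrize(c: Connectome, mode: str = "max") -> WeightedGraph:
    """Collapse the directed matrix to one strength per unordered pair.

    ``mode`` combines the two directed entries: ``max`` (default,
    preserves the stronger projection), ``sum``, or ``mean`` (of the two
    directed entries).  Pairs whose combined weight is zero are omitted.
    """
    w = c.weights
    if mode == "max":
        s = np.maximum(w, w.T)
    elif mode == "sum":
        s = w + w.T
    elif mode == "mean":
        s = (w + w.T) / 2.0
    else:
        raise ValueError(f"unknown symmetrization mode {mode!r}")
    edges: dict[tuple[str, str], float] = {}
    iu, ju = np.triu_indices_from(s, k=1)
    for i, j in zip(iu, ju):
        if s[i, j] > 0:
            u, v = c.region_ids[i], c.region_ids[j]
            edges[(u, v) if u < v else (v, u)] = float(s[i, j])
    return WeightedGraph(nodes=list(c.region_ids), edge_weights=edges)


def group_counts(c: Connectome) -> dict[str, int]:
    """Number of regions per functional group (all groups always keyed)."""
    counts = {g: 0 for g in GROUPS}
    for r in c.region_ids:
        counts[c.groups[r]] += 1
    return counts
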