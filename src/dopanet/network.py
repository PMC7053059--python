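"""Set-pair interactome enrichment against randomized-network nulls.

Two disease-module statistics are supported for a pair of disjoint gene
sets on an interactome:

``ppi_count``
    the number of interactions spanning the two sets — undirected edges
    with one endpoint in each set, or directed edges with a chosen set
    upstream;
``lcc_size``
    the node count of the largest connected component of the subgraph
    induced by the union of the two sets (all edges treated as undirected
    for connectivity).

Each observed statistic is compared with an ensemble of randomized
networks — degree-preserving double-edge swaps or uniform node-label
permutation — yielding a z-score and an add-one empirical p-value
p = (1 + #{null >= observed}) / (1 + n_random), which is never zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

import networkx as nx
import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .io_model import Edge, Interactome, normalize_symbols

__all__ = [
    "NetworkTestResult",
    "count_cross_interactions",
    "lcc_size",
    "randomize_network",
    "network_enrichment_test",
]

DIRECTIONS = ("undirected", "set_a_upstream", "set_a_downstream")
STATISTICS = ("ppi_count", "lcc_size")
METHODS = ("degree_preserving_rewire", "node_label_shuffle")

#: z reported when the null ensemble has zero spread.
Z_UNDEFINED = float("nan")


@dataclass
class NetworkTestResult:
    statistic_name: str
    direction: str
    observed: int
    null_values: list[int]
    z: float
    p_empirical: float
    method: str = "degree_preserving_rewire"
    n_random: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_random = len(self.null_values)

    def to_dict(self) -> dict:
        return {
            "statistic_name": self.statistic_name,
            "direction": self.direction,
            "observed": int(self.observed),
            "z": None if np.isnan(self.z) else float(self.z),
            "p_empirical": float(self.p_empirical),
            "method": self.method,
            "n_random": self.n_random,
            "null_values": [int(v) for v in self.null_values],
        }


# ---------------------------------------------------------------------------
# Array-backed view of an Interactome (single source of truth for statistics)
# ---------------------------------------------------------------------------


class _IndexedGraph:
    """Edge arrays over integer node ids, multiplicities collapsed per pair.

    ``und_u/und_v``: unique undirected non-self pairs (u < v);
    ``dir_u/dir_v``: unique directed non-self pairs (source, target);
    ``all_u/all_v``: unique pairs of either kind, undirected view, used for
    connectivity.
    """

    def __init__(self, g: Interactome):
        self.node_list = sorted(g.nodes)
        self.index = {n: i for i, n in enumerate(self.node_list)}
        self.n = len(self.node_list)
        und, drc, allp = set(), set(), set()
        for e in g.edges:
            if e.source == e.target:
                continue  # self-loops never enter pair statistics
            u, v = self.index[e.source], self.index[e.target]
            if e.directed:
                drc.add((u, v))
            else:
                und.add((min(u, v), max(u, v)))
            allp.add((min(u, v), max(u, v)))
        self.und_u, self.und_v = _pair_arrays(und)
        self.dir_u, self.dir_v = _pair_arrays(drc)
        self.all_u, self.all_v = _pair_arrays(allp)

    def masks(self, set_a: Iterable[str], set_b: Iterable[str]) -> tuple[np.ndarray, np.ndarray]:
        ma = np.zeros(self.n, dtype=bool)
        mb = np.zeros(self.n, dtype=bool)
        for g in set_a:
            i = self.index.get(g)
            if i is not None:
                ma[i] = True
        for g in set_b:
            i = self.index.get(g)
            if i is not None:
                mb[i] = True
        return ma, mb

    def cross_count(self, ma: np.ndarray, mb: np.ndarray, direction: str) -> int:
        if direction == "undirected":
            hits = (ma[self.und_u] & mb[self.und_v]) | (mb[self.und_u] & ma[self.und_v])
        elif direction == "set_a_upstream":
            hits = ma[self.dir_u] & mb[self.dir_v]
        elif direction == "set_a_downstream":
            hits = mb[self.dir_u] & ma[self.dir_v]
        else:
            raise ValueError(f"direction must be one of {DIRECTIONS}")
        return int(np.count_nonzero(hits))

    def lcc(self, member: np.ndarray) -> int:
        """LCC node count of the subgraph induced by the membership mask."""
        n_members = int(np.count_nonzero(member))
        if n_members == 0:
            return 0
        keep = member[self.all_u] & member[self.all_v]
        if not np.any(keep):
            return 1
        u = self.all_u[keep]
        v = self.all_v[keep]
        # compress member node ids to 0..n_members-1
        ids = np.flatnonzero(member)
        remap = np.full(self.n, -1, dtype=np.int64)
        remap[ids] = np.arange(n_members)
        adj = coo_matrix(
            (np.ones(u.size), (remap[u], remap[v])), shape=(n_members, n_members)
        )
        n_comp, labels = connected_components(adj, directed=False)
        return int(np.bincount(labels).max())


def _pair_arrays(pairs: set[tuple[int, int]]) -> tuple[np.ndarray, np.ndarray]:
    if not pairs:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    arr = np.array(sorted(pairs), dtype=np.int64)
    return arr[:, 0], arr[:, 1]


# ---------------------------------------------------------------------------
# Public statistics
# ---------------------------------------------------------------------------


def _check_disjoint(set_a: frozenset[str], set_b: frozenset[str]) -> None:
    shared = set_a & set_b
    if shared:
        raise ValueError(f"gene sets must be disjoint; shared genes: {sorted(shared)}")


def count_cross_interactions(
    g: Interactome | _IndexedGraph,
    set_a: Iterable[str],
    set_b: Iterable[str],
    direction: str = "undirected",
) -> int:
    """Number of interactions between two disjoint gene sets.

    ``undirected`` counts undirected edges with one endpoint in each set;
    ``set_a_upstream`` counts directed edges source in A, target in B;
    ``set_a_downstream`` the reverse. Multiple interaction types between
    the same pair count once, and self-loops never count.
    """
    sa, sb = normalize_symbols(set_a), normalize_symbols(set_b)
    _check_disjoint(sa, sb)
    ig = g if isinstance(g, _IndexedGraph) else _IndexedGraph(g)
    ma, mb = ig.masks(sa, sb)
    return ig.cross_count(ma, mb, direction)


def lcc_size(
    g: Interactome | _IndexedGraph, set_a: Iterable[str], set_b: Iterable[str] = ()
) -> int:
    """Largest-connected-component size of the subgraph induced by A ∪ B."""
    sa, sb = normalize_symbols(set_a), normalize_symbols(set_b)
    ig = g if isinstance(g, _IndexedGraph) else _IndexedGraph(g)
    ma, mb = ig.masks(sa, sb)
    return ig.lcc(ma | mb)


# ---------------------------------------------------------------------------
# Randomization
# ---------------------------------------------------------------------------


def randomize_network(
    g: Interactome,
    method: str = "degree_preserving_rewire",
    n_swaps_per_edge: int = 10,
    seed: Optional[int] = None,
) -> Interactome:
    """Return a randomized copy of the graph.

    ``degree_preserving_rewire`` performs double-edge swaps separately on
    the undirected and directed edge sets, preserving every node's degree
    (in/out degrees for directed edges) and introducing no duplicate edges
    or self-loops; edge type labels are reassigned by shuffling the
    original type multiset. ``node_label_shuffle`` permutes node labels
    uniformly, leaving the topology untouched.

    If no legal swap exists the input is returned unchanged with a warning.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")
    rng = np.random.default_rng(seed)
    if method == "node_label_shuffle":
        labels = sorted(g.nodes)
        permuted = list(rng.permutation(labels))
        mapping = dict(zip(labels, permuted))
        edges = [
            Edge(mapping[e.source], mapping[e.target], e.type, e.directed)
            for e in g.edges
        ]
        return Interactome(nodes=set(mapping.values()), edges=edges)

    und = [(e.source, e.target) for e in g.edges if not e.directed and e.source != e.target]
    drc = [(e.source, e.target) for e in g.edges if e.directed and e.source != e.target]
    loops = [e for e in g.edges if e.source == e.target]
    new_und, new_drc = und, drc
    try:
        if len(und) >= 2:
            G = nx.Graph()
            G.add_nodes_from(g.nodes)
            G.add_edges_from(und)
            nswap = n_swaps_per_edge * G.number_of_edges()
            nx.double_edge_swap(
                G, nswap=nswap, max_tries=100 * nswap, seed=int(rng.integers(2**31))
            )
            new_und = list(G.edges())
        if len(drc) >= 3:
            D = nx.DiGraph()
            D.add_nodes_from(g.nodes)
            D.add_edges_from(drc)
            nswap = n_swaps_per_edge * D.number_of_edges()
            nx.directed_edge_swap(
                D, nswap=nswap, max_tries=100 * nswap, seed=int(rng.integers(2**31))
            )
            new_drc = list(D.edges())
    except nx.NetworkXError as err:
        warnings.warn(f"rewiring not possible ({err}); returning the input graph")
        return Interactome(nodes=set(g.nodes), edges=list(g.edges))

    und_types = [e.type for e in g.edges if not e.directed and e.source != e.target]
    drc_types = [e.type for e in g.edges if e.directed and e.source != e.target]
    rng.shuffle(und_types)
    rng.shuffle(drc_types)
    edges = [Edge(s, t, ty, False) for (s, t), ty in zip(new_und, und_types)]
    edges += [Edge(s, t, ty, True) for (s, t), ty in zip(new_drc, drc_types)]
    edges += loops
    return Interactome(nodes=set(g.nodes), edges=edges)


# ---------------------------------------------------------------------------
# Enrichment test
# ---------------------------------------------------------------------------


def network_enrichment_test(
    g: Interactome,
    set_a: Iterable[str],
    set_b: Iterable[str],
    statistic: str = "ppi_count",
    direction: str = "undirected",
    n_random: int = 1000,
    method: str = "degree_preserving_rewire",
    n_swaps_per_edge: int = 10,
    seed: Optional[int] = None,
) -> NetworkTestResult:
    """Compare an observed set-pair statistic with a randomized-network null.

    The observed value comes from the real graph; ``n_random`` independent
    randomizations provide the null ensemble. The empirical p uses the
    add-one estimator and z = (observed − mean(null)) / sd(null) (NaN when
    the null has zero spread).
    """
    if statistic not in STATISTICS:
        raise ValueError(f"statistic must be one of {STATISTICS}")
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")
    sa, sb = normalize_symbols(set_a), normalize_symbols(set_b)
    if statistic == "ppi_count":
        _check_disjoint(sa, sb)

    ig = _IndexedGraph(g)
    ma, mb = ig.masks(sa, sb)

    def stat(ma_: np.ndarray, mb_: np.ndarray) -> int:
        if statistic == "ppi_count":
            return ig.cross_count(ma_, mb_, direction)
        return ig.lcc(ma_ | mb_)

    observed = stat(ma, mb)
    rng = np.random.default_rng(seed)
    null_values = np.empty(n_random, dtype=np.int64)
    if method == "node_label_shuffle":
        # Permuting node labels and keeping the sets fixed is equivalent to
        # permuting the membership masks on the fixed topology.
        for i in range(n_random):
            perm = rng.permutation(ig.n)
            null_values[i] = stat(ma[perm], mb[perm])
    else:
        for i in range(n_random):
            rg = randomize_network(
                g,
                method="degree_preserving_rewire",
                n_swaps_per_edge=n_swaps_per_edge,
                seed=int(rng.integers(2**31)),
            )
            rig = _IndexedGraph(rg)
            rma, rmb = rig.masks(sa, sb)
            if statistic == "ppi_count":
                null_values[i] = rig.cross_count(rma, rmb, direction)
            else:
                null_values[i] = rig.lcc(rma | rmb)

    mean = float(null_values.mean()) if n_random else float("nan")
    sd = float(null_values.std(ddof=1)) if n_random > 1 else 0.0
    z = (observed - mean) / sd if sd > 0 else Z_UNDEFINED
    p = (1 + int(np.count_nonzero(null_values >= observed))) / (1 + n_random)
    return NetworkTestResult(
        statistic_name=statistic,
        direction=direction,
        observed=observed,
        null_values=[int(v) for v in null_values],
        z=z,
        p_empirical=p,
        method=method,
    )
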