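"""Binary undirected networks and their degree-distribution / integration metrics.

The central object is :class:`Network`, an immutable simple graph on labeled
nodes ``0..N-1`` (no self-loops, no parallel edges), isomorphic to a binary
symmetric adjacency matrix.  The metrics implemented here are the ones used
to characterize functional brain networks built from ROI correlation
matrices:

* the normalized degree distribution ``P(k)`` and its Shannon entropy
  ``S = -sum_k P(k) ln P(k)`` (natural-log units, so a regular graph has
  ``S = 0`` and broader degree distributions have larger ``S``),
* population variance and Pearson kurtosis (``m4 / m2**2``) of the degree
  multiset,
* mean geodesic distance ``D`` (hop counts; ``+inf`` when any pair is
  unreachable),
* clustering coefficient ``C`` (mean of local clustering, nodes of degree
  < 2 contributing 0),
* global efficiency ``E_g`` (mean reciprocal geodesic distance, ``1/inf = 0``),
* local efficiency ``E_l`` (global-efficiency-style average computed inside
  each node's neighbor-induced subgraph).

Shortest paths are breadth-first searches on the adjacency matrix via
``scipy.sparse.csgraph``; triangles come from the third power of the
adjacency matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path

__all__ = [
    "Network",
    "DegreeDistribution",
    "MetricSet",
    "degree_distribution",
    "shannon_entropy",
    "degree_moments",
    "moments_of_degrees",
    "mean_geodesic_distance",
    "clustering_coefficient",
    "global_efficiency",
    "local_efficiency",
    "compute_metric_set",
    "network_to_edgelist_text",
    "network_from_edgelist_text",
    "network_to_graphml",
]

Edge = Tuple[int, int]


def _normalize_edge(i: int, j: int) -> Edge:
    return (i, j) if i < j else (j, i)


@dataclass(frozen=True)
class Network:
    """Simple undirected graph on nodes ``0..n_nodes-1``.

    ``edges`` is a frozenset of ordered pairs ``(i, j)`` with ``i < j``.
    Construction validates the simple-graph invariants once; instances are
    immutable afterwards.
    """

    n_nodes: int
    edges: frozenset

    def __post_init__(self) -> None:
        if self.n_nodes < 1:
            raise ValueError("a network needs at least one node")
        for (i, j) in self.edges:
            if i == j:
                raise ValueError(f"self-loop on node {i}")
            if not (0 <= i < j < self.n_nodes):
                raise ValueError(f"edge ({i}, {j}) out of range or unordered")

    @classmethod
    def from_edges(cls, n_nodes: int, edges: Iterable[Tuple[int, int]]) -> "Network":
        """Build a network, normalizing pair order and dropping duplicates."""
        normalized = frozenset(_normalize_edge(i, j) for i, j in edges)
        return cls(n_nodes=n_nodes, edges=normalized)

    @classmethod
    def from_adjacency(cls, a: np.ndarray) -> "Network":
        a = np.asarray(a)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency matrix must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency matrix must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency matrix must have zero diagonal")
        ii, jj = np.nonzero(np.triu(a, 1))
        return cls(n_nodes=a.shape[0], edges=frozenset(zip(ii.tolist(), jj.tolist())))

    # -- basic views ---------------------------------------------------------

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency_matrix(self) -> np.ndarray:
        a = np.zeros((self.n_nodes, self.n_nodes), dtype=np.int8)
        if self.edges:
            idx = np.array(sorted(self.edges))
            a[idx[:, 0], idx[:, 1]] = 1
            a[idx[:, 1], idx[:, 0]] = 1
        return a

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=np.int64)
        for i, j in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg

    def neighbors(self, node: int) -> List[int]:
        return [j if i == node else i for i, j in self.edges if node in (i, j)]

    def adjacency_sets(self) -> List[set]:
        adj: List[set] = [set() for _ in range(self.n_nodes)]
        for i, j in self.edges:
            adj[i].add(j)
            adj[j].add(i)
        return adj

    def is_connected(self) -> bool:
        if self.n_nodes == 1:
            return True
        n_comp, _ = connected_components(
            csr_matrix(self.adjacency_matrix()), directed=False
        )
        return n_comp == 1

    def relabeled(self, permutation: Iterable[int]) -> "Network":
        """Return the isomorphic network with node ``i`` renamed ``perm[i]``."""
        perm = list(permutation)
        if sorted(perm) != list(range(self.n_nodes)):
            raise ValueError("permutation must be a bijection on node labels")
        return Network.from_edges(
            self.n_nodes, ((perm[i], perm[j]) for i, j in self.edges)
        )


@dataclass(frozen=True)
class DegreeDistribution:
    """Normalized histogram ``P(k)`` of node degrees."""

    probabilities: Dict[int, float]

    def __post_init__(self) -> None:
        total = sum(self.probabilities.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"probabilities sum to {total!r}, not 1")
        for k, p in self.probabilities.items():
            if k < 0 or not (0.0 < p <= 1.0):
                raise ValueError(f"invalid entry P({k}) = {p}")


@dataclass(frozen=True)
class MetricSet:
    """All per-network summary metrics, as produced by :func:`compute_metric_set`.

    ``degree_kurtosis`` is ``None`` for regular graphs (zero degree variance),
    where the Pearson kurtosis ``m4/m2**2`` is undefined.
    """

    entropy_nats: float
    mean_geodesic: float
    clustering: float
    global_efficiency: float
    local_efficiency: float
    degree_variance: float
    degree_kurtosis: Optional[float]
    mean_degree: float

    def as_dict(self) -> Dict[str, Optional[float]]:
        return {
            "entropy": self.entropy_nats,
            "geodesic": self.mean_geodesic,
            "clustering": self.clustering,
            "global_efficiency": self.global_efficiency,
            "local_efficiency": self.local_efficiency,
            "degree_variance": self.degree_variance,
            "degree_kurtosis": self.degree_kurtosis,
            "mean_degree": self.mean_degree,
        }


METRIC_NAMES = (
    "entropy",
    "geodesic",
    "clustering",
    "global_efficiency",
    "local_efficiency",
    "degree_variance",
    "degree_kurtosis",
    "mean_degree",
)


# -- degree distribution and moments ----------------------------------------


def degree_distribution(net: Network) -> DegreeDistribution:
    """Normalized histogram of node degrees (exact integer counts over N)."""
    deg = net.degrees()
    counts = np.bincount(deg)
    n = net.n_nodes
    probs = {int(k): c / n for k, c in enumerate(counts) if c > 0}
    return DegreeDistribution(probabilities=probs)


def shannon_entropy(dist: DegreeDistribution) -> float:
    """Shannon entropy ``-sum_k P(k) ln P(k)`` in nats; 0 for regular graphs."""
    return float(-sum(p * math.log(p) for p in dist.probabilities.values()))


def moments_of_degrees(degrees: Iterable[int]) -> Tuple[float, Optional[float]]:
    """Population variance ``m2`` and Pearson kurtosis ``m4/m2**2`` of a
    degree multiset; kurtosis is ``None`` when the variance is zero."""
    deg = np.asarray(list(degrees), dtype=float)
    centered = deg - deg.mean()
    m2 = float(np.mean(centered**2))
    if m2 == 0.0:
        return 0.0, None
    m4 = float(np.mean(centered**4))
    return m2, m4 / m2**2


def degree_moments(net: Network) -> Tuple[float, Optional[float]]:
    """Population variance and Pearson kurtosis of a network's degrees.

    Kurtosis is returned as ``None`` for regular graphs (zero variance),
    where the ratio is undefined.
    """
    if net.n_nodes < 2:
        raise ValueError("degree moments need at least two nodes")
    return moments_of_degrees(net.degrees())


# -- distance-based metrics --------------------------------------------------


def _distance_matrix(a: np.ndarray) -> np.ndarray:
    """All-pairs hop counts by BFS; ``inf`` marks unreachable pairs."""
    return shortest_path(csr_matrix(a), method="D", unweighted=True, directed=False)


def mean_geodesic_distance(net: Network) -> float:
    """Mean hop count over ordered node pairs; ``+inf`` if any pair is unreachable."""
    if net.n_nodes < 2:
        raise ValueError("mean geodesic distance needs at least two nodes")
    d = _distance_matrix(net.adjacency_matrix())
    off = ~np.eye(net.n_nodes, dtype=bool)
    if np.isinf(d[off]).any():
        return math.inf
    return float(d[off].mean())


def global_efficiency(net: Network) -> float:
    """Mean reciprocal geodesic distance over ordered pairs (``1/inf = 0``)."""
    if net.n_nodes < 2:
        raise ValueError("global efficiency needs at least two nodes")
    d = _distance_matrix(net.adjacency_matrix())
    off = ~np.eye(net.n_nodes, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isinf(d[off]), 0.0, 1.0 / d[off])
    return float(inv.mean())


def clustering_coefficient(net: Network) -> float:
    """Mean local clustering ``2 t_i / (k_i (k_i - 1))``; degree-<2 nodes give 0."""
    a = net.adjacency_matrix().astype(np.int64)
    deg = a.sum(axis=1)
    triangles = np.diag(a @ a @ a) / 2.0
    denom = deg * (deg - 1)
    local = np.zeros(net.n_nodes)
    ok = denom > 0
    local[ok] = 2.0 * triangles[ok] / denom[ok]
    return float(local.mean())


def _efficiency_sum(a_sub: np.ndarray) -> float:
    """Sum of reciprocal distances over ordered pairs of a subgraph, / n(n-1)."""
    n = a_sub.shape[0]
    if n < 2:
        return 0.0
    d = _distance_matrix(a_sub)
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isinf(d[off]), 0.0, 1.0 / d[off])
    return float(inv.sum()) / (n * (n - 1))


def local_efficiency(net: Network) -> float:
    """Average, over all nodes, of the efficiency of the neighbor-induced subgraph.

    Distances are measured *within* each induced subgraph; nodes with fewer
    than two neighbors contribute 0 to the average.
    """
    a = net.adjacency_matrix()
    total = 0.0
    for i in range(net.n_nodes):
        nbrs = np.nonzero(a[i])[0]
        if nbrs.size < 2:
            continue
        total += _efficiency_sum(a[np.ix_(nbrs, nbrs)])
    return total / net.n_nodes


def efficiency_pair(net: Network) -> Tuple[float, float]:
    """(global, local) efficiency only — the pair the small-world-vs-null
    criterion needs; cheaper than a full metric set on ensemble members."""
    a = net.adjacency_matrix()
    d = _distance_matrix(a)
    off = ~np.eye(net.n_nodes, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isinf(d[off]), 0.0, 1.0 / d[off])
    e_g = float(inv.mean())
    total = 0.0
    for i in range(net.n_nodes):
        nbrs = np.nonzero(a[i])[0]
        if nbrs.size >= 2:
            total += _efficiency_sum(a[np.ix_(nbrs, nbrs)])
    return e_g, total / net.n_nodes


def compute_metric_set(net: Network) -> MetricSet:
    """Compute every metric in one pass (shares the BFS distance matrix)."""
    if net.n_nodes < 2:
        raise ValueError("metric set needs at least two nodes")
    a = net.adjacency_matrix()
    d = _distance_matrix(a)
    off = ~np.eye(net.n_nodes, dtype=bool)
    dvals = d[off]
    mean_d = math.inf if np.isinf(dvals).any() else float(dvals.mean())
    with np.errstate(divide="ignore"):
        inv = np.where(np.isinf(dvals), 0.0, 1.0 / dvals)
    e_g = float(inv.mean())
    variance, kurtosis = degree_moments(net)
    deg = net.degrees()
    return MetricSet(
        entropy_nats=shannon_entropy(degree_distribution(net)),
        mean_geodesic=mean_d,
        clustering=clustering_coefficient(net),
        global_efficiency=e_g,
        local_efficiency=local_efficiency(net),
        degree_variance=variance,
        degree_kurtosis=kurtosis,
        mean_degree=float(deg.mean()),
    )


# -- serialization -----------------------------------------------------------


def network_to_edgelist_text(net: Network) -> str:
    """Plain-text edge list: header ``# n_nodes=N`` then one ``i<TAB>j`` per line."""
    lines = [f"# n_nodes={net.n_nodes}"]
    lines.extend(f"{i}\t{j}" for i, j in sorted(net.edges))
    return "\n".join(lines) + "\n"


def network_from_edgelist_text(text: str) -> Network:
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    if not lines or not lines[0].startswith("# n_nodes="):
        raise ValueError("edge-list text must start with a '# n_nodes=N' header")
    n_nodes = int(lines[0].split("=", 1)[1])
    edges = []
    for ln in lines[1:]:
        i_str, j_str = ln.split("\t")
        edges.append((int(i_str), int(j_str)))
    return Network.from_edges(n_nodes, edges)


def network_to_graphml(net: Network, path: str) -> None:
    """Write GraphML via networkx for interoperability with graph tools."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(net.n_nodes))
    g.add_edges_from(net.edges)
    nx.write_graphml(g, path)
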