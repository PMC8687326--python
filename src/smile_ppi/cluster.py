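"""Module detection backends: cohesiveness-greedy growth and Markov clustering.

Both backends are scikit-learn style estimators whose ``fit`` takes a
:class:`networkx.Graph` (nodes are protein ids, edges optionally carry a
``score`` weight) and exposes the detected clusters as ``clusters_``.

The greedy backend grows possibly-overlapping clusters from high-degree seeds,
supervised by the cohesiveness fitness

    f(V) = w_in(V) / (w_in(V) + w_bound(V) + p * |V|)

where ``w_in`` sums the weights of edges inside V, ``w_bound`` the weights of
edges with exactly one endpoint in V, and ``p`` penalises each member for the
uncertainty of untested interactions.  Markov clustering (MCL) alternates
expansion (matrix powers) and inflation (element-wise powers with column
re-normalisation) of a column-stochastic flow matrix until attractors emerge;
it yields a non-overlapping clustering of all non-isolated nodes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import networkx as nx
import numpy as np
from sklearn.base import BaseEstimator

__all__ = [
    "Cluster",
    "cohesiveness",
    "GreedyCohesiveClusterer",
    "MarkovClusterer",
    "greedy_grow",
    "mcl",
    "filter_by_size",
]

# Gains below this are treated as ties/no-improvement so float noise cannot
# break the strict-increase guarantee of the greedy growth loop.
_EPS = 1e-12


@dataclass(frozen=True)
class Cluster:
    """A candidate module: a protein set plus the network it came from."""

    members: frozenset[str]
    source: str = "global"

    def __len__(self) -> int:
        return len(self.members)


def _edge_weight(data: dict, weighted: bool) -> float:
    return float(data.get("score", 1.0)) if weighted else 1.0


def cohesiveness(
    members: Iterable[str],
    network: nx.Graph,
    penalty: float = 2.0,
    weighted: bool = True,
) -> float:
    """Cohesiveness f(V) of a protein set within a network.

    Uses edge ``score`` attributes as weights when *weighted* (missing scores
    count as 1), plain edge counts otherwise.  Empty clusters are undefined;
    a fully isolated set with zero penalty returns 0.
    """
    members = set(members)
    if not members:
        raise ValueError("cohesiveness is undefined for an empty cluster")
    if penalty < 0:
        raise ValueError("penalty must be >= 0")
    missing = members - set(network.nodes)
    if missing:
        raise ValueError(f"cluster members not in network: {sorted(missing)}")
    w_in = w_bound = 0.0
    for node in members:
        for neigh, data in network[node].items():
            w = _edge_weight(data, weighted)
            if neigh in members:
                w_in += w / 2.0  # internal edges visited from both endpoints
            else:
                w_bound += w
    denominator = w_in + w_bound + penalty * len(members)
    return w_in / denominator if denominator > 0 else 0.0


def overlap_coefficient(a: frozenset, b: frozenset) -> float:
    """Squared-intersection overlap |A∩B|² / (|A|·|B|) used for cluster merging."""
    inter = len(a & b)
    return (inter * inter) / (len(a) * len(b)) if inter else 0.0


class GreedyCohesiveClusterer(BaseEstimator):
    """Seeded greedy growth of cohesive, possibly overlapping clusters.

    Parameters
    ----------
    penalty : float, default 2.0
        Per-member penalty term ``p`` of the cohesiveness fitness, modelling
        undiscovered interactions.
    min_size : int, default 3
        Internal minimum cluster size; smaller growths are discarded.  The
        separate "size larger than ten" module filter is applied downstream
        via :func:`filter_by_size`.
    density_min : float, default 0.5
        Minimum internal edge density ``w_in / C(|V|, 2)``; sparser growths
        are discarded.
    merge_overlap : float, default 0.8
        Clusters whose pairwise overlap score reaches this value are merged
        (connected-component closure) before filtering.
    weighted : bool, default True
        Use edge ``score`` attributes as weights; otherwise count edges.

    Attributes
    ----------
    clusters_ : list of Cluster
        Detected clusters, deterministically ordered by member sets.
    growth_traces_ : list of list of float
        Cohesiveness after each accepted step of every seed growth (strictly
        increasing by construction; exposed for auditing).
    """

    def __init__(
        self,
        penalty: float = 2.0,
        min_size: int = 3,
        density_min: float = 0.5,
        merge_overlap: float = 0.8,
        weighted: bool = True,
        source: str = "global",
    ):
        self.penalty = penalty
        self.min_size = min_size
        self.density_min = density_min
        self.merge_overlap = merge_overlap
        self.weighted = weighted
        self.source = source

    # -- growth internals ---------------------------------------------------

    def _weights_to(self, network: nx.Graph, node: str, members: set[str]) -> tuple[float, float]:
        """(weight into members, total weighted degree) of *node*."""
        inside = total = 0.0
        for neigh, data in network[node].items():
            w = _edge_weight(data, self.weighted)
            total += w
            if neigh in members:
                inside += w
        return inside, total

    def _grow(self, network: nx.Graph, seed: str) -> tuple[frozenset[str], float, list[float]]:
        members = {seed}
        w_in = 0.0
        _, w_bound = self._weights_to(network, seed, members)
        p = self.penalty

        def fitness(win: float, wbound: float, size: int) -> float:
            den = win + wbound + p * size
            return win / den if den > 0 else 0.0

        current = fitness(w_in, w_bound, 1)
        trace = [current]
        while True:
            best: tuple[float, int, str] | None = None  # (f, action, node)
            boundary = {
                neigh for node in members for neigh in network[node] if neigh not in members
            }
            for node in boundary:
                inside, total = self._weights_to(network, node, members)
                f = fitness(w_in + inside, w_bound - inside + (total - inside), len(members) + 1)
                cand = (f, 0, node)
                if f > current + _EPS and (best is None or _better(cand, best)):
                    best = cand
            if len(members) > 1:
                for node in members:
                    inside, total = self._weights_to(network, node, members)
                    f = fitness(
                        w_in - inside, w_bound + inside - (total - inside), len(members) - 1
                    )
                    cand = (f, 1, node)
                    if f > current + _EPS and (best is None or _better(cand, best)):
                        best = cand
            if best is None:
                break
            f, action, node = best
            inside, total = self._weights_to(network, node, members)
            if action == 0:
                members.add(node)
                w_in += inside
                w_bound += (total - inside) - inside
            else:
                members.remove(node)
                w_in -= inside
                w_bound += inside - (total - inside)
            current = f
            trace.append(current)
        return frozenset(members), w_in, trace

    def fit(self, X: nx.Graph, y=None) -> "GreedyCohesiveClusterer":
        """Detect clusters in the graph *X*."""
        if X is None or X.number_of_nodes() == 0:
            self.clusters_, self.growth_traces_ = [], []
            self.n_clusters_ = 0
            return self
        # Seeds: every not-yet-claimed node with at least one edge, visited in
        # (weighted degree desc, id asc) order for determinism.
        def wdeg(node: str) -> float:
            return sum(_edge_weight(d, self.weighted) for d in X[node].values())

        order = sorted((n for n in X.nodes if X.degree(n) > 0), key=lambda n: (-wdeg(n), n))
        claimed: set[str] = set()
        grown: list[tuple[frozenset[str], float]] = []
        self.growth_traces_ = []
        for seed in order:
            if seed in claimed:
                continue
            members, w_in, trace = self._grow(X, seed)
            claimed |= members
            grown.append((members, w_in))
            self.growth_traces_.append(trace)
        merged = self._merge_overlapping([m for m, _ in grown])
        kept = []
        for members in merged:
            if len(members) < self.min_size:
                continue
            w_in = sum(
                _edge_weight(d, self.weighted)
                for u, v, d in X.subgraph(members).edges(data=True)
            )
            possible = len(members) * (len(members) - 1) / 2.0
            if possible > 0 and w_in / possible < self.density_min:
                continue
            kept.append(members)
        self.clusters_ = [
            Cluster(m, self.source) for m in sorted(kept, key=lambda s: sorted(s))
        ]
        self.n_clusters_ = len(self.clusters_)
        return self

    def _merge_overlapping(self, clusters: list[frozenset[str]]) -> list[frozenset[str]]:
        if not clusters:
            return []
        graph = nx.Graph()
        graph.add_nodes_from(range(len(clusters)))
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                if overlap_coefficient(clusters[i], clusters[j]) >= self.merge_overlap:
                    graph.add_edge(i, j)
        return [
            frozenset().union(*(clusters[i] for i in component))
            for component in nx.connected_components(graph)
        ]


def _better(candidate: tuple[float, int, str], incumbent: tuple[float, int, str]) -> bool:
    """Tie-break equal-gain steps: higher fitness, then smallest protein id."""
    f_c, _, node_c = candidate
    f_i, _, node_i = incumbent
    if f_c > f_i + _EPS:
        return True
    if f_i > f_c + _EPS:
        return False
    return node_c < node_i


class MarkovClusterer(BaseEstimator):
    """Markov clustering (MCL) on the weighted adjacency matrix.

    Simulates flow through the network: expansion (matrix power) spreads flow
    along paths, inflation (element-wise power with column re-normalisation)
    strengthens strong flows and prunes weak ones, until the flow matrix is
    stable and attractor rows define the clusters.  The result is a partition
    of the non-isolated nodes; flow cannot cross between components.

    Attributes
    ----------
    clusters_ : list of Cluster
    n_iter_ : int
        Iterations run before convergence (or ``max_iterations``).
    converged_ : bool
    """

    def __init__(
        self,
        inflation: float = 2.0,
        expansion: int = 2,
        prune_threshold: float = 1e-5,
        max_iterations: int = 100,
        convergence_tol: float = 1e-6,
        weighted: bool = True,
        self_loop_weight: float = 1.0,
        source: str = "global",
    ):
        self.inflation = inflation
        self.expansion = expansion
        self.prune_threshold = prune_threshold
        self.max_iterations = max_iterations
        self.convergence_tol = convergence_tol
        self.weighted = weighted
        self.self_loop_weight = self_loop_weight
        self.source = source

    def _validate(self):
        if self.inflation <= 1:
            raise ValueError("inflation must be > 1")
        if self.expansion < 2:
            raise ValueError("expansion must be >= 2")
        if self.prune_threshold <= 0 or self.max_iterations < 1 or self.convergence_tol <= 0:
            raise ValueError("prune_threshold, max_iterations, convergence_tol must be positive")

    def _iterates(self, matrix: np.ndarray) -> Iterator[np.ndarray]:
        """Yield the column-stochastic flow matrix after every iteration."""
        m = _normalise_columns(matrix)
        for _ in range(self.max_iterations):
            m = np.linalg.matrix_power(m, self.expansion)
            m = np.power(m, self.inflation)
            m = _normalise_columns(m)
            m[m < self.prune_threshold] = 0.0
            m = _normalise_columns(m)
            yield m

    def fit(self, X: nx.Graph, y=None) -> "MarkovClusterer":
        """Cluster the non-isolated nodes of the graph *X*."""
        self._validate()
        nodes = sorted(n for n in X.nodes if X.degree(n) > 0)
        if not nodes:
            self.clusters_, self.n_iter_, self.converged_ = [], 0, True
            return self
        index = {n: i for i, n in enumerate(nodes)}
        matrix = np.zeros((len(nodes), len(nodes)))
        for u, v, data in X.subgraph(nodes).edges(data=True):
            w = _edge_weight(data, self.weighted)
            matrix[index[u], index[v]] = matrix[index[v], index[u]] = w
        np.fill_diagonal(matrix, self.self_loop_weight)

        previous = _normalise_columns(matrix)
        self.converged_ = False
        self.n_iter_ = 0
        for current in self._iterates(matrix):
            self.n_iter_ += 1
            if np.max(np.abs(current - previous)) < self.convergence_tol:
                self.converged_ = True
                previous = current
                break
            previous = current
        if not self.converged_:
            warnings.warn(
                f"MCL did not converge in {self.max_iterations} iterations; "
                "interpreting the current flow matrix",
                stacklevel=2,
            )
        self.clusters_ = self._read_clusters(previous, nodes)
        self.n_clusters_ = len(self.clusters_)
        return self

    def _read_clusters(self, matrix: np.ndarray, nodes: list[str]) -> list[Cluster]:
        attractors = np.where(np.diag(matrix) > self.prune_threshold)[0]
        raw: list[set[int]] = []
        for row in attractors:
            raw.append(set(np.where(matrix[row] > self.prune_threshold)[0]))
        # Attractor systems sharing nodes describe the same cluster: merge.
        graph = nx.Graph()
        graph.add_nodes_from(range(len(raw)))
        for i in range(len(raw)):
            for j in range(i + 1, len(raw)):
                if raw[i] & raw[j]:
                    graph.add_edge(i, j)
        merged = [
            set().union(*(raw[i] for i in component))
            for component in nx.connected_components(graph)
        ]
        covered = set().union(*merged) if merged else set()
        # Nodes starved of all flow (fully pruned columns) attach nowhere;
        # give each its own singleton so the covered set stays a partition.
        for i in range(len(nodes)):
            if i not in covered:
                merged.append({i})
        clusters = [frozenset(nodes[i] for i in c) for c in merged]
        return [Cluster(c, self.source) for c in sorted(clusters, key=lambda s: sorted(s))]


def _normalise_columns(matrix: np.ndarray) -> np.ndarray:
    sums = matrix.sum(axis=0)
    sums[sums == 0.0] = 1.0
    return matrix / sums


def greedy_grow(network: nx.Graph, **params) -> list[Cluster]:
    """Functional wrapper over :class:`GreedyCohesiveClusterer`."""
    return GreedyCohesiveClusterer(**params).fit(network).clusters_


def mcl(network: nx.Graph, **params) -> list[Cluster]:
    """Functional wrapper over :class:`MarkovClusterer`."""
    return MarkovClusterer(**params).fit(network).clusters_


def filter_by_size(clusters: Sequence[Cluster], min_size: int = 11) -> list[Cluster]:
    """Keep clusters with at least *min_size* members.

    The default keeps clusters strictly larger than ten proteins, the cut at
    which small clusters stop being treated as modules.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    return [c for c in clusters if len(c.members) >= min_size]
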