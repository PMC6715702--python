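"""Markov clustering (MCL) of weighted undirected graphs, from scratch.

The algorithm simulates flow on the graph: the weighted adjacency matrix
(with self-loops) is column-normalized into a stochastic matrix, then
alternately *expanded* (matrix power, spreading flow) and *inflated*
(entry-wise power followed by column renormalization, sharpening flow)
until the matrix stops changing. At convergence the matrix is close to a
doubly idempotent limit whose non-zero structure encodes the clustering:
rows with mass on their own diagonal are attractors, attractors connected
through non-zero entries form attractor systems, and every column's mass
points at the system(s) it belongs to.

Granularity is controlled by the inflation exponent (higher -> finer).
Clusters smaller than a minimum size are reported as unclustered rather
than discarded silently.

``naive_mcl_oracle`` is a deliberately literal re-implementation without
pruning, kept as an independent correctness oracle for the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np

from .errors import ClusteringError
from .network import CorrelationNetwork

__all__ = ["MclParams", "ClusterPartition", "mcl_cluster", "naive_mcl_oracle"]

# entries below this are treated as structural zeros when reading clusters
# out of the converged matrix (safe: converged mass is either ~0 or >= the
# inverse cluster size, and the pruning default sits well below it)
_ATTRACTOR_EPS = 1e-5


@dataclass(frozen=True)
class MclParams:
    """Tuning knobs of the Markov clustering iteration."""

    inflation: float = 2.2
    expansion: int = 2
    prune_threshold: float = 1e-6
    max_iterations: int = 200
    convergence_tol: float = 1e-8
    min_cluster_size: int = 3
    self_loop_weight: object = "max_incident"  # or a positive float

    def __post_init__(self) -> None:
        if not self.inflation > 1:
            raise ClusteringError(f"inflation must be > 1, got {self.inflation}")
        if not (isinstance(self.expansion, int) and self.expansion >= 2):
            raise ClusteringError(f"expansion must be an integer >= 2, got {self.expansion}")
        if self.prune_threshold < 0:
            raise ClusteringError("prune_threshold must be >= 0")
        if self.max_iterations < 1:
            raise ClusteringError("max_iterations must be >= 1")
        if self.min_cluster_size < 1:
            raise ClusteringError("min_cluster_size must be >= 1")
        if not isinstance(self.self_loop_weight, str):
            if not float(self.self_loop_weight) > 0:
                raise ClusteringError("self_loop_weight must be > 0")
        elif self.self_loop_weight != "max_incident":
            raise ClusteringError(
                f"unknown self_loop_weight rule {self.self_loop_weight!r}"
            )


@dataclass
class ClusterPartition:
    """Disjoint clusters (size >= min_cluster_size) plus an unclustered set.

    Clusters are ordered by descending size with ties broken by smallest
    member ID, so the partition is deterministic and label-stable.
    """

    clusters: list[frozenset[str]]
    unclustered: frozenset[str]
    converged: bool = True
    n_iterations: int = 0
    params: Optional[MclParams] = None

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for c in self.clusters:
            if seen & c:
                raise ClusteringError(f"overlapping clusters: {sorted(seen & c)}")
            seen |= c
        if seen & self.unclustered:
            raise ClusteringError(
                f"nodes both clustered and unclustered: {sorted(seen & self.unclustered)}"
            )

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def n_clustered(self) -> int:
        return sum(len(c) for c in self.clusters)

    def labels(self) -> dict[str, str]:
        """Map every node to 'cluster_<k>' (1-based) or 'unclustered'."""
        out = {}
        for k, cluster in enumerate(self.clusters, start=1):
            for node in cluster:
                out[node] = f"cluster_{k}"
        for node in self.unclustered:
            out[node] = "unclustered"
        return out

    def membership(self) -> dict[str, int]:
        """Integer labels for partition-comparison metrics; unclustered
        nodes become singletons with unique negative labels."""
        out = {}
        for k, cluster in enumerate(self.clusters, start=1):
            for node in cluster:
                out[node] = k
        for i, node in enumerate(sorted(self.unclustered), start=1):
            out[node] = -i
        return out

    # ----------------------------------------------------------------- I/O
    def to_tsv(self, path) -> None:
        labels = self.labels()
        with open(path, "w") as fh:
            fh.write("scan_id\tcluster_label\n")
            for node in sorted(labels):
                fh.write(f"{node}\t{labels[node]}\n")

    @classmethod
    def from_tsv(cls, path, min_cluster_size: int = 3) -> "ClusterPartition":
        groups: dict[str, set[str]] = {}
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("scan_id"):
                raise ClusteringError(f"{path}: expected partition header")
            for line in fh:
                node, label = line.rstrip("\n").split("\t")
                groups.setdefault(label, set()).add(node)
        unclustered = frozenset(groups.pop("unclustered", set()))
        clusters = _order_clusters(groups.values())
        return cls(clusters=clusters, unclustered=unclustered)

    def summary_rows(self) -> list[dict]:
        rows = []
        for k, cluster in enumerate(self.clusters, start=1):
            rows.append(
                {
                    "cluster_label": f"cluster_{k}",
                    "size": len(cluster),
                    "members": ",".join(sorted(cluster)),
                }
            )
        if self.unclustered:
            rows.append(
                {
                    "cluster_label": "unclustered",
                    "size": len(self.unclustered),
                    "members": ",".join(sorted(self.unclustered)),
                }
            )
        return rows


def _order_clusters(groups: Iterable[Iterable[str]]) -> list[frozenset[str]]:
    return sorted(
        (frozenset(g) for g in groups),
        key=lambda c: (-len(c), min(c)),
    )


def _build_stochastic(
    net: CorrelationNetwork, params: MclParams
) -> tuple[np.ndarray, list[str]]:
    nodes = sorted(net.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    adj = np.zeros((n, n), dtype=float)
    for a, b, w in net.edges:
        if w <= 0:
            raise ClusteringError(f"non-positive edge weight {w} on ({a},{b})")
        adj[index[a], index[b]] = w
        adj[index[b], index[a]] = w
    if params.self_loop_weight == "max_incident":
        loops = adj.max(axis=0)
        loops[loops == 0] = 1.0  # isolated nodes keep a unit loop
    else:
        loops = np.full(n, float(params.self_loop_weight))
    adj[np.diag_indices(n)] = loops
    return adj / adj.sum(axis=0), nodes


def _mcl_iterate(
    matrix: np.ndarray, params: MclParams, prune: bool
) -> tuple[np.ndarray, bool, int]:
    m = matrix
    for iteration in range(1, params.max_iterations + 1):
        expanded = np.linalg.matrix_power(m, params.expansion)
        inflated = np.power(expanded, params.inflation)
        inflated /= inflated.sum(axis=0)
        if prune and params.prune_threshold > 0:
            inflated[inflated < params.prune_threshold] = 0.0
            colsums = inflated.sum(axis=0)
            # a fully pruned column would lose its node; restore its argmax
            dead = colsums == 0
            if dead.any():
                tops = expanded[:, dead].argmax(axis=0)
                inflated[tops, np.flatnonzero(dead)] = 1.0
                colsums = inflated.sum(axis=0)
            inflated /= colsums
        if np.max(np.abs(inflated - m)) < params.convergence_tol:
            return inflated, True, iteration
        m = inflated
    return m, False, params.max_iterations


def _read_partition(
    matrix: np.ndarray,
    nodes: list[str],
    params: MclParams,
    graph_excluded: Iterable[str],
    converged: bool,
    n_iterations: int,
) -> ClusterPartition:
    n = len(nodes)
    support = matrix > _ATTRACTOR_EPS
    attractors = np.flatnonzero(support.diagonal())
    # attractor systems: connected components among attractor rows/columns
    parent = {int(i): int(i) for i in attractors}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in attractors:
        for j in attractors:
            if support[i, j] or support[j, i]:
                ri, rj = find(int(i)), find(int(j))
                if ri != rj:
                    parent[rj] = ri
    systems: dict[int, set[int]] = {}
    for i in attractors:
        systems.setdefault(find(int(i)), set()).add(int(i))

    # each column joins the system(s) of the attractor rows feeding it
    raw_clusters: dict[int, set[int]] = {root: set(members) for root, members in systems.items()}
    for j in range(n):
        roots = {find(int(i)) for i in attractors if support[i, j]}
        if not roots:
            # numerically starved column: follow its heaviest row instead
            top = int(matrix[:, j].argmax())
            roots = {find(top)} if top in parent else set()
        for root in roots:
            raw_clusters[root].add(j)

    # overlap resolution: larger cluster wins, ties to smallest member ID
    order = sorted(
        raw_clusters.values(),
        key=lambda c: (-len(c), min(nodes[i] for i in c)),
    )
    assigned: set[int] = set()
    groups: list[set[str]] = []
    for cluster in order:
        fresh = cluster - assigned
        if fresh:
            groups.append({nodes[i] for i in fresh})
            assigned |= fresh
    leftovers = {nodes[i] for i in range(n) if i not in assigned}

    kept = [g for g in groups if len(g) >= params.min_cluster_size]
    small = [g for g in groups if len(g) < params.min_cluster_size]
    unclustered = set(leftovers) | {x for g in small for x in g} | set(graph_excluded)
    return ClusterPartition(
        clusters=_order_clusters(kept),
        unclustered=frozenset(unclustered),
        converged=converged,
        n_iterations=n_iterations,
        params=params,
    )


def mcl_cluster(
    net: CorrelationNetwork, params: MclParams | None = None
) -> ClusterPartition:
    """Cluster a correlation network by Markov clustering.

    Self-loops are added per ``params.self_loop_weight`` (default: each
    node's maximum incident edge weight), the adjacency is column-
    normalized, and the expand/inflate/prune loop runs until the matrix is
    stable in max-norm. Clusters below ``min_cluster_size`` and the
    network's excluded scans land in the unclustered set.
    """
    params = params or MclParams()
    if not net.nodes:
        return ClusterPartition(
            clusters=[],
            unclustered=frozenset(net.excluded_nodes),
            converged=True,
            n_iterations=0,
            params=params,
        )
    stochastic, nodes = _build_stochastic(net, params)
    final, converged, iterations = _mcl_iterate(stochastic, params, prune=True)
    if not converged:
        warnings.warn(
            f"MCL did not converge within {params.max_iterations} iterations; "
            "returning the partition of the final matrix",
            stacklevel=2,
        )
    return _read_partition(
        final, nodes, params, net.excluded_nodes, converged, iterations
    )


def naive_mcl_oracle(
    net: CorrelationNetwork, params: MclParams | None = None
) -> ClusterPartition:
    """Literal dense MCL without pruning; test oracle for small graphs only."""
    params = params or MclParams()
    if net.nodes and len(net.nodes) > 50:
        raise ClusteringError(
            f"oracle limited to 50 nodes, got {len(net.nodes)}"
        )
    if not net.nodes:
        return ClusterPartition(
            clusters=[],
            unclustered=frozenset(net.excluded_nodes),
            converged=True,
            n_iterations=0,
            params=params,
        )
    stochastic, nodes = _build_stochastic(net, params)
    m = stochastic
    converged = False
    iterations = params.max_iterations
    for iteration in range(1, params.max_iterations + 1):
        nxt = np.linalg.matrix_power(m, params.expansion)
        nxt = np.power(nxt, params.inflation)
        nxt = nxt / nxt.sum(axis=0)
        if np.max(np.abs(nxt - m)) < params.convergence_tol:
            converged, iterations = True, iteration
            m = nxt
            break
        m = nxt
    return _read_partition(
        m, nodes, params, net.excluded_nodes, converged, iterations
    )
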