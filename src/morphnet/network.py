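"""Scan-to-scan Pearson correlation network construction.

Each scan's centered parameter profile is correlated with every other
scan's; pairs above a correlation threshold become weighted edges of an
undirected graph. Scans without any retained edge are reported separately
so node bookkeeping stays exact. A threshold sweep supports the
"maximum nodes, minimum edges" threshold choice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .errors import NetworkError
from .preprocess import MorphometricMatrix

__all__ = [
    "CorrelationNetwork",
    "pearson_matrix",
    "threshold_graph",
    "threshold_scan",
    "suggest_threshold",
]


@dataclass
class CorrelationNetwork:
    """Thresholded Pearson graph over scans.

    nodes: scan IDs with at least one retained edge; edges carry the raw r
    as weight; excluded_nodes had no correlation above the threshold (they
    are absent from the graph but tracked for bookkeeping).
    """

    nodes: list[str]
    edges: list[tuple[str, str, float]]
    threshold: float
    excluded_nodes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for a, b, w in self.edges:
            if a == b:
                raise NetworkError(f"self-edge on {a!r}")
            if not (w > self.threshold):
                raise NetworkError(
                    f"edge ({a},{b}) weight {w} not above threshold {self.threshold}"
                )

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph(threshold=self.threshold)
        g.add_nodes_from(self.nodes)
        g.add_weighted_edges_from(self.edges)
        return g

    # ----------------------------------------------------------------- I/O
    def to_edgelist_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# threshold={self.threshold!r}\n")
            fh.write(f"# excluded={','.join(self.excluded_nodes)}\n")
            fh.write("scan_a\tscan_b\tr\n")
            for a, b, w in self.edges:
                fh.write(f"{a}\t{b}\t{w!r}\n")

    @classmethod
    def from_edgelist_tsv(cls, path) -> "CorrelationNetwork":
        threshold = 0.0
        excluded: list[str] = []
        edges: list[tuple[str, str, float]] = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("# threshold="):
                    threshold = float(line.split("=", 1)[1])
                elif line.startswith("# excluded="):
                    raw = line.split("=", 1)[1]
                    excluded = [s for s in raw.split(",") if s]
                elif line.startswith("#") or line.startswith("scan_a\t") or not line:
                    continue
                else:
                    a, b, w = line.split("\t")
                    edges.append((a, b, float(w)))
        nodes = sorted({n for a, b, _ in edges for n in (a, b)})
        return cls(nodes=nodes, edges=edges, threshold=threshold,
                   excluded_nodes=excluded)

    def to_graphml(self, path) -> None:
        nx.write_graphml(self.to_networkx(), path)

    @classmethod
    def from_graphml(cls, path, threshold: float | None = None) -> "CorrelationNetwork":
        g = nx.read_graphml(path)
        t = float(g.graph.get("threshold", 0.0) if threshold is None else threshold)
        edges = [(a, b, float(d["weight"])) for a, b, d in g.edges(data=True)]
        nodes = sorted(n for n in g.nodes if g.degree(n) > 0)
        excluded = sorted(n for n in g.nodes if g.degree(n) == 0)
        return cls(nodes=nodes, edges=edges, threshold=t, excluded_nodes=excluded)


def pearson_matrix(matrix: MorphometricMatrix) -> tuple[np.ndarray, list[str]]:
    """All-pairs Pearson correlation between scan profiles.

    Returns ``(corr, scan_ids)`` where ``corr[i, j]`` is the correlation of
    scans i and j across the parameter axis. Scans with a constant profile
    have undefined correlations and are excluded with a warning before
    computing the grid.
    """
    if len(matrix.parameter_names) < 3:
        raise NetworkError(
            f"need >= 3 parameters per scan, got {len(matrix.parameter_names)}"
        )
    values = matrix.values
    keep = np.ptp(values, axis=1) > 0
    constant = [sid for sid, k in zip(matrix.scan_ids, keep) if not k]
    if constant:
        warnings.warn(
            f"excluding {len(constant)} scan(s) with constant profiles: {constant}",
            stacklevel=2,
        )
    scan_ids = [sid for sid, k in zip(matrix.scan_ids, keep) if k]
    sub = values[keep]
    if len(scan_ids) == 0:
        return np.empty((0, 0)), []
    corr = np.corrcoef(sub)
    corr = np.atleast_2d(corr)
    np.fill_diagonal(corr, 1.0)
    return corr, scan_ids


def threshold_graph(
    corr: np.ndarray, scan_ids: list[str], threshold: float
) -> CorrelationNetwork:
    """Keep scan pairs with r strictly above the threshold.

    Scans left without any edge are listed in ``excluded_nodes``.
    """
    if not (0 <= threshold < 1):
        raise NetworkError(f"threshold must be in [0, 1), got {threshold}")
    corr = np.asarray(corr, dtype=float)
    n = len(scan_ids)
    edges: list[tuple[str, str, float]] = []
    connected = np.zeros(n, dtype=bool)
    iu, ju = np.triu_indices(n, k=1)
    above = corr[iu, ju] > threshold
    for i, j in zip(iu[above], ju[above]):
        edges.append((scan_ids[i], scan_ids[j], float(corr[i, j])))
        connected[i] = connected[j] = True
    nodes = [sid for sid, c in zip(scan_ids, connected) if c]
    excluded = [sid for sid, c in zip(scan_ids, connected) if not c]
    return CorrelationNetwork(
        nodes=nodes, edges=edges, threshold=threshold, excluded_nodes=excluded
    )


def threshold_scan(corr: np.ndarray, thresholds) -> pd.DataFrame:
    """Diagnostic sweep: node and edge counts at each candidate threshold."""
    thresholds = list(thresholds)
    if thresholds != sorted(thresholds):
        raise NetworkError("thresholds must be sorted ascending")
    corr = np.asarray(corr, dtype=float)
    n = corr.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    weights = corr[iu, ju]
    rows = []
    for t in thresholds:
        above = weights > t
        n_edges = int(above.sum())
        touched = np.zeros(n, dtype=bool)
        touched[iu[above]] = True
        touched[ju[above]] = True
        rows.append({"threshold": t, "n_nodes": int(touched.sum()), "n_edges": n_edges})
    return pd.DataFrame(rows, columns=["threshold", "n_nodes", "n_edges"])


def suggest_threshold(scan_table: pd.DataFrame, node_fraction: float = 0.95) -> float:
    """Largest threshold keeping at least ``node_fraction`` of the maximum
    node count — a reproducible stand-in for the informal "maximum nodes
    with minimum edges" criterion; the final choice rests with the user."""
    if scan_table.empty:
        raise NetworkError("empty threshold scan")
    max_nodes = scan_table["n_nodes"].max()
    ok = scan_table[scan_table["n_nodes"] >= node_fraction * max_nodes]
    return float(ok["threshold"].max())
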