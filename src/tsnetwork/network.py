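"""Coexpression network construction and Markov clustering.

Edges connect gene pairs whose Pearson correlation across the chosen sample
set reaches a threshold (default 0.80, signed).  Modules are found with a
from-scratch Markov Cluster (MCL) implementation: alternating expansion
(matrix power), inflation (elementwise power + column renormalization) and
pruning on a column-stochastic flow matrix until the attractor structure
stabilizes.
"""

from __future__ import annotations

import logging
from collections.abc import Callable, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EXPORT_FORMATS = ("edgelist", "graphml")


def pearson_matrix(
    expression: pd.DataFrame,
    samples: Sequence[str] | None = None,
    log_transform: bool = False,
) -> pd.DataFrame:
    """Gene-by-gene Pearson correlation over the given sample columns.

    Genes with zero variance across the subset are dropped with a warning.
    ``log_transform`` correlates natural-log values instead (requires strictly
    positive expression), appropriate when co-regulation acts multiplicatively.
    """
    sub = expression if samples is None else expression.loc[:, list(samples)]
    if sub.shape[1] < 3:
        raise ValueError(
            f"need at least 3 samples for correlation, got {sub.shape[1]}"
        )
    values = sub.to_numpy(dtype=float)
    if log_transform:
        if (values <= 0).any():
            raise ValueError("log_transform requires strictly positive expression")
        values = np.log(values)
    keep = values.std(axis=1) > 0
    if not keep.all():
        dropped = sub.index[~keep].tolist()
        logger.warning(
            "dropping %d zero-variance gene(s) from correlation: %s",
            len(dropped), dropped[:10],
        )
        values = values[keep]
    genes = sub.index[keep]
    corr = np.clip(np.corrcoef(values), -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=genes, columns=genes)


def build_network(corr: pd.DataFrame, threshold: float = 0.80) -> nx.Graph:
    """Threshold a correlation matrix into an undirected weighted graph.

    Edges keep pairs with signed r >= threshold; no self-edges; isolated
    genes remain as nodes.
    """
    if not corr.index.equals(corr.columns):
        raise ValueError("correlation matrix must have matching row/column ids")
    graph = nx.Graph(threshold=float(threshold))
    genes = corr.index.tolist()
    graph.add_nodes_from(genes)
    values = corr.to_numpy()
    rows, cols = np.triu_indices(len(genes), k=1)
    hit = values[rows, cols] >= threshold
    graph.add_weighted_edges_from(
        (genes[i], genes[j], float(values[i, j]))
        for i, j in zip(rows[hit], cols[hit])
    )
    return graph


@dataclass
class ClusterAssignment:
    """A partition of network nodes into clusters.

    Cluster ids are contiguous from 1 and ordered by decreasing size
    (ties by first member in node order).
    """

    labels: dict[str, int]
    converged: bool = True
    n_iter: int = 0
    sizes: dict[int, int] = field(init=False)

    def __post_init__(self) -> None:
        sizes: dict[int, int] = {}
        for cid in self.labels.values():
            sizes[cid] = sizes.get(cid, 0) + 1
        self.sizes = dict(sorted(sizes.items()))

    def clusters(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {cid: [] for cid in self.sizes}
        for node, cid in self.labels.items():
            out[cid].append(node)
        return out

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"gene_id": list(self.labels), "cluster": list(self.labels.values())}
        )
        return df.sort_values(["cluster", "gene_id"]).reset_index(drop=True)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def mcl_cluster(
    network: nx.Graph,
    inflation: float = 2.0,
    expansion: int = 2,
    self_loop_weight: float | str = "max",
    prune_below: float = 1e-5,
    max_iter: int = 100,
    tol: float = 1e-6,
    on_iteration: Callable[[int, np.ndarray], None] | None = None,
) -> ClusterAssignment:
    """Partition a weighted graph with the Markov Cluster algorithm.

    Self-loops are added with weight equal to each column's maximum edge
    weight (``"max"``, the default; isolated nodes get 1) before column
    normalization.  Iteration alternates expansion (matrix power
    ``expansion``), inflation (elementwise power ``inflation`` followed by
    column renormalization) and pruning of entries below ``prune_below``,
    stopping when the largest entry change falls below ``tol``.  Clusters are
    the connected components of the converged flow matrix's support.

    ``on_iteration(iteration, matrix)`` is called with each iterate, mainly
    for invariant checking.
    """
    if network.number_of_nodes() == 0:
        raise ValueError("MCL needs a network with at least one node")
    if inflation <= 1.0:
        raise ValueError(f"inflation must exceed 1, got {inflation}")
    if expansion < 2:
        raise ValueError(f"expansion must be >= 2, got {expansion}")

    nodes = list(network.nodes)
    adj = nx.to_numpy_array(network, nodelist=nodes, weight="weight")
    np.fill_diagonal(adj, 0.0)
    if self_loop_weight == "max":
        loops = adj.max(axis=0)
        loops[loops == 0] = 1.0  # isolated nodes
    else:
        loops = np.full(len(nodes), float(self_loop_weight))
        if (loops <= 0).any():
            raise ValueError("numeric self_loop_weight must be positive")
    np.fill_diagonal(adj, loops)

    matrix = adj / adj.sum(axis=0)
    converged = False
    iteration = 0
    for iteration in range(1, max_iter + 1):
        new = np.linalg.matrix_power(matrix, expansion)
        np.power(new, inflation, out=new)
        new /= new.sum(axis=0)
        new[new < prune_below] = 0.0
        colsum = new.sum(axis=0)
        dead = colsum == 0  # cannot happen while prune_below << 1/n; guard anyway
        if dead.any():
            idx = np.flatnonzero(dead)
            new[idx, idx] = 1.0
            colsum = new.sum(axis=0)
        new /= colsum
        if on_iteration is not None:
            on_iteration(iteration, new)
        delta = np.abs(new - matrix).max()
        matrix = new
        if delta < tol:
            converged = True
            break
    if not converged:
        logger.warning(
            "MCL did not converge within %d iterations; clustering the final "
            "iterate", max_iter,
        )

    # Support graph: node j flows to attractor rows i with positive mass;
    # merging along nonzero entries joins overlapping attractor systems.
    uf = _UnionFind(len(nodes))
    rows, cols = np.nonzero(matrix)
    for i, j in zip(rows, cols):
        uf.union(i, j)

    roots: dict[int, list[int]] = {}
    for idx in range(len(nodes)):
        roots.setdefault(uf.find(idx), []).append(idx)
    ordered = sorted(roots.values(), key=lambda members: (-len(members), members[0]))
    labels = {
        nodes[idx]: cid
        for cid, members in enumerate(ordered, start=1)
        for idx in members
    }
    labels = {node: labels[node] for node in nodes}
    return ClusterAssignment(labels=labels, converged=converged, n_iter=iteration)


def export_network(
    network: nx.Graph,
    assignment: ClusterAssignment | None,
    path: str | Path,
    fmt: str = "edgelist",
) -> Path:
    """Write the network as an edge-list TSV or GraphML file.

    GraphML carries the cluster id as a node attribute; the edge list has
    columns gene_a, gene_b, r.
    """
    path = Path(path)
    if fmt == "edgelist":
        rows = sorted(
            (min(str(a), str(b)), max(str(a), str(b)), data["weight"])
            for a, b, data in network.edges(data=True)
        )
        df = pd.DataFrame(rows, columns=["gene_a", "gene_b", "r"])
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")
        return path
    if fmt == "graphml":
        graph = network.copy()
        if assignment is not None:
            nx.set_node_attributes(graph, assignment.labels, name="cluster")
        nx.write_graphml(graph, path)
        return path
    raise ValueError(
        f"unknown export format {fmt!r}; supported: {', '.join(EXPORT_FORMATS)}"
    )


def read_edgelist(path: str | Path) -> nx.Graph:
    """Read an edge-list TSV written by :func:`export_network`."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    graph = nx.Graph()
    graph.add_weighted_edges_from(
        (a, b, float(r)) for a, b, r in df.itertuples(index=False)
    )
    return graph


def read_graphml(path: str | Path) -> nx.Graph:
    """Read a GraphML network written by :func:`export_network`."""
    return nx.read_graphml(path)
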