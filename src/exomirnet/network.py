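"""PPI graph construction, Markov Clustering, topology scores and hub selection.

The candidate-DEG interaction network is an undirected weighted graph (a
networkx ``Graph``). It is clustered with Markov Clustering (MCL): random
walks on the graph are simulated by alternating *expansion* (matrix
squaring of the column-stochastic transition matrix) and *inflation*
(element-wise powering followed by column renormalization); inflation
strength controls cluster granularity and defaults to 3 here. Clusters are
read off the attractor structure of the converged matrix.

Hub genes are the union of pathway-enriched genes and the core PPI module
(the largest MCL cluster by default); the regulatory network is the directed
bipartite graph from screened miRNAs to hub genes supported by retained
target predictions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .target_screen import TargetPrediction

__all__ = [
    "ClusterAssignment",
    "TopologyScores",
    "BipartiteNetwork",
    "build_graph",
    "mcl_cluster",
    "topology_scores",
    "select_hubs",
    "build_bipartite",
    "write_graphml",
    "write_sif",
]


@dataclass
class ClusterAssignment:
    """Node -> cluster id partition; ids dense from 1, largest cluster first."""

    cluster_of: dict[str, int]
    converged: bool = True

    def clusters(self) -> list[set[str]]:
        out: dict[int, set[str]] = {}
        for node, cid in self.cluster_of.items():
            out.setdefault(cid, set()).add(node)
        return [out[cid] for cid in sorted(out)]

    def largest(self) -> set[str]:
        return self.clusters()[0]


@dataclass
class TopologyScores:
    """Per-node degree and neighborhood connectivity (mean neighbor degree)."""

    degree: dict[str, int]
    neighborhood_connectivity: dict[str, float]


@dataclass
class BipartiteNetwork:
    """Directed miRNA -> hub-gene edges, each backed by a prediction."""

    edges: list[TargetPrediction]
    mirnas: set[str] = field(default_factory=set)
    genes: set[str] = field(default_factory=set)
    degree: dict[str, int] = field(default_factory=dict)
    neighborhood_connectivity: dict[str, float] = field(default_factory=dict)


def build_graph(
    edges: Iterable[tuple[str, str, float]],
    node_whitelist: Iterable[str] | None = None,
    min_weight: float = 0.0,
) -> nx.Graph:
    """Undirected weighted graph restricted to whitelisted nodes.

    Isolated whitelist nodes are retained so downstream topology scores
    cover every candidate gene.
    """
    g = nx.Graph()
    whitelist = None if node_whitelist is None else set(node_whitelist)
    if whitelist is not None:
        g.add_nodes_from(sorted(whitelist))
    for a, b, w in edges:
        if a == b:
            raise ValueError(f"self-loop edge {a!r}")
        if w <= 0:
            raise ValueError(f"non-positive weight on edge {a}-{b}")
        if w < min_weight:
            continue
        if whitelist is not None and (a not in whitelist or b not in whitelist):
            continue
        g.add_edge(a, b, weight=w)
    return g


def mcl_cluster(
    g: nx.Graph,
    inflation: float = 3.0,
    expansion: int = 2,
    prune_below: float = 1e-5,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> ClusterAssignment:
    """Markov Clustering of an undirected weighted graph.

    The transition matrix gets a self-loop per node (weight = the node's
    maximum incident edge weight, at least 1) and is column-normalized.
    Each iteration raises the matrix to the ``expansion`` power, inflates
    entries element-wise to the ``inflation`` power with column
    renormalization, prunes entries below ``prune_below`` and renormalizes,
    until the largest column change falls under ``tol``. Clusters are the
    connected components of the nonzero attractor structure: rows with
    positive diagonal mass are attractors, and nodes supported by a common
    attractor row belong to one cluster (overlaps merged). Non-convergence
    returns the current partition flagged, not an exception.
    """
    nodes = sorted(g.nodes)
    if not nodes:
        raise ValueError("empty graph")
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    M = np.zeros((n, n))
    for a, b, data in g.edges(data=True):
        w = data.get("weight", 1.0)
        M[idx[a], idx[b]] = w
        M[idx[b], idx[a]] = w
    loop = np.maximum(M.max(axis=0), 1.0)
    M[np.diag_indices(n)] = loop
    M /= M.sum(axis=0, keepdims=True)

    converged = False
    for _ in range(max_iter):
        prev = M
        M = np.linalg.matrix_power(M, expansion)
        M = np.power(M, inflation)
        M /= M.sum(axis=0, keepdims=True)
        M[M < prune_below] = 0.0
        colsum = M.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        M /= colsum
        if np.abs(M - prev).max() < tol:
            converged = True
            break
    if not converged:
        warnings.warn("MCL did not converge within max_iter", stacklevel=2)

    # attractors are rows with diagonal support; cluster nodes sharing a row
    attractors = np.flatnonzero(np.diag(M) > 0)
    comp = nx.Graph()
    comp.add_nodes_from(range(n))
    for a in attractors:
        members = np.flatnonzero(M[a, :] > 0)
        for m in members:
            comp.add_edge(a, m)
    components = sorted(
        (sorted(c) for c in nx.connected_components(comp)),
        key=lambda c: (-len(c), c),
    )
    cluster_of = {
        nodes[i]: cid for cid, members in enumerate(components, start=1) for i in members
    }
    return ClusterAssignment(cluster_of=cluster_of, converged=converged)


def topology_scores(g: nx.Graph) -> TopologyScores:
    """Unweighted degree and neighborhood connectivity per node.

    Neighborhood connectivity of v is the mean degree of v's neighbors;
    isolated nodes score (0, 0) by convention.
    """
    deg = dict(g.degree())
    nc = {
        v: (float(np.mean([deg[u] for u in g.neighbors(v)])) if deg[v] > 0 else 0.0)
        for v in g.nodes
    }
    return TopologyScores(degree=deg, neighborhood_connectivity=nc)


def select_hubs(
    enriched_pathway_genes: Iterable[str],
    core_cluster_genes: Iterable[str],
) -> set[str]:
    """Hub genes = pathway-enriched genes UNION core-module genes."""
    pathway = set(enriched_pathway_genes)
    core = set(core_cluster_genes)
    if not pathway and not core:
        raise ValueError("both hub sources are empty")
    return pathway | core


def write_graphml(g: nx.Graph, path, scores: TopologyScores | None = None) -> None:
    """GraphML export with degree/neighborhood-connectivity node attributes."""
    out = g.copy()
    if scores is not None:
        nx.set_node_attributes(out, scores.degree, "degree")
        nx.set_node_attributes(out, scores.neighborhood_connectivity,
                               "neighborhood_connectivity")
    nx.write_graphml(out, path)


def write_sif(g: nx.Graph, path, relation: str = "pp") -> None:
    """Simple interaction format: one 'a <relation> b' line per edge."""
    with open(path, "w", encoding="utf-8") as fh:
        for a, b in sorted(map(lambda e: tuple(sorted(e)), g.edges())):
            fh.write(f"{a}\t{relation}\t{b}\n")
        for v in sorted(g.nodes):
            if g.degree[v] == 0:
                fh.write(f"{v}\n")


def build_bipartite(
    hubs: Iterable[str],
    predictions: Sequence[TargetPrediction],
) -> BipartiteNetwork:
    """Directed miRNA -> gene network over retained predictions into hubs.

    Topology scores are computed on the undirected view of the bipartite
    graph; hub genes untouched by any prediction still appear as nodes.
    """
    hubset = set(hubs)
    edges = sorted(
        (p for p in predictions if p.gene_id in hubset),
        key=lambda p: (p.mirna_id, p.gene_id),
    )
    g = nx.Graph()
    g.add_nodes_from(sorted(hubset))
    for p in edges:
        g.add_edge(p.mirna_id, p.gene_id)
    scores = topology_scores(g)
    return BipartiteNetwork(
        edges=edges,
        mirnas={p.mirna_id for p in edges},
        genes=hubset,
        degree=scores.degree,
        neighborhood_connectivity=scores.neighborhood_connectivity,
    )
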