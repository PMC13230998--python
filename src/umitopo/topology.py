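"""Betti numbers of thresholded abstraction graphs viewed as 1-complexes.

A PAGA abstraction graph thresholded at connectivity tau is a simple
undirected graph.  Its zeroth Betti number beta0 counts connected components
(disjoint manifold pieces) and its first Betti number beta1 = E - V + beta0
counts independent loops.  Tree-like skeletons (constrained, lineage-like
transitions) have beta1 = 0; spurious hubs created by shallowly observed
cells inflate beta1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .workflow import AbstractionGraph

__all__ = ["TopologySummary", "threshold_abstraction", "betti_numbers"]


@dataclass(frozen=True)
class TopologySummary:
    """(V, E, beta0, beta1) of a thresholded abstraction graph."""

    n_nodes: int
    n_edges: int
    beta0: int
    beta1: int
    threshold: float

    def __post_init__(self) -> None:
        if self.beta1 != self.n_edges - self.n_nodes + self.beta0:
            raise ValueError("beta1 must satisfy the Euler relation E - V + beta0")

    def to_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "beta0": self.beta0,
            "beta1": self.beta1,
            "threshold": self.threshold,
        }


def threshold_abstraction(graph: AbstractionGraph, tau: float = 0.05) -> sp.csr_matrix:
    """Keep edges with connectivity >= tau (inclusive); all nodes are retained.

    Returns a symmetric binary adjacency matrix whose shape preserves isolated
    nodes, so beta0 still reflects the cluster count.
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    conn = graph.connectivity
    adj = (conn >= tau) & (conn > 0)
    return sp.csr_matrix(adj.astype(np.int8))


def betti_numbers(adjacency: sp.spmatrix, threshold: float = np.nan) -> TopologySummary:
    """beta0 (components) and beta1 (independent loops) of a simple graph.

    ``adjacency`` must be symmetric with an empty diagonal; edge weights are
    ignored.  beta1 follows the Euler relation for 1-complexes:
    beta1 = E - V + beta0.
    """
    adj = sp.csr_matrix(adjacency)
    if adj.shape[0] != adj.shape[1]:
        raise ValueError("adjacency must be square")
    if adj.diagonal().any():
        raise ValueError("self-loops are not allowed")
    if (adj != adj.T).nnz:
        raise ValueError("adjacency must be symmetric")
    n_nodes = adj.shape[0]
    n_edges = int(adj.nnz // 2)
    beta0 = int(connected_components(adj, directed=False)[0]) if n_nodes else 0
    beta1 = n_edges - n_nodes + beta0
    return TopologySummary(
        n_nodes=n_nodes,
        n_edges=n_edges,
        beta0=beta0,
        beta1=beta1,
        threshold=float(threshold),
    )
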