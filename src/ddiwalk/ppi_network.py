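"""Propagation substrate: confidence filtering and the walk matrix.

The protein-protein interaction network is filtered to the top confidence
quantile (the scores' only role), binarized, and turned into a
column-stochastic transition matrix W = A D^-1 over the surviving nodes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .errors import ValidationError
from .io_formats import PPIEdgeList

COLUMN_SUM_TOL = 1e-12


@dataclass
class TransitionMatrix:
    """Column-stochastic sparse walk matrix over PPI nodes.

    Every column sums to 1; isolated nodes are absent by construction. The
    node index is the sorted node-id order, exposed via ``index_of``.
    """

    node_ids: list[str]
    M: sp.csr_matrix

    def __post_init__(self):
        n = len(self.node_ids)
        if self.M.shape != (n, n):
            raise ValidationError("transition matrix shape mismatch")
        colsums = np.asarray(self.M.sum(axis=0)).ravel()
        if np.max(np.abs(colsums - 1.0)) > COLUMN_SUM_TOL:
            raise ValidationError("transition matrix columns must sum to 1")
        self._index = {nid: i for i, nid in enumerate(self.node_ids)}

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def index_of(self, node_id: str) -> int:
        return self._index[node_id]

    def contains(self, node_id: str) -> bool:
        return node_id in self._index


def filter_top_confidence(edges: PPIEdgeList, keep_fraction: float) -> PPIEdgeList:
    """Retain edges at or above the empirical top-``keep_fraction`` score cutoff.

    The cutoff is the k-th largest score with k = ceil(keep_fraction * n); all
    ties at the cutoff are retained, so the kept count is at least k.
    """
    if not 0.0 < keep_fraction <= 1.0:
        raise ValidationError(f"keep_fraction must be in (0, 1], got {keep_fraction}")
    if not edges.edges:
        raise ValidationError("cannot filter an empty edge list")
    scores = np.array([s for _, _, s in edges.edges], dtype=float)
    k = math.ceil(keep_fraction * len(scores))
    cutoff = np.sort(scores)[::-1][k - 1]
    kept = [(u, v, s) for u, v, s in edges.edges if s >= cutoff]
    return PPIEdgeList(edges=kept)


def build_transition_matrix(
    edges: PPIEdgeList, weighted: bool = False
) -> TransitionMatrix:
    """Column-normalized adjacency of the (filtered) undirected network.

    Adjacency is binary by default — confidence has already done its job in
    the quantile filter; ``weighted=True`` keeps scores as edge weights for
    sensitivity analysis. Nodes appear only if they touch a retained edge, so
    no column is zero.
    """
    if not edges.edges:
        raise ValidationError("cannot build a transition matrix from no edges")
    node_ids = sorted(edges.nodes)
    index = {nid: i for i, nid in enumerate(node_ids)}
    n = len(node_ids)
    rows, cols, vals = [], [], []
    for u, v, s in edges.edges:
        i, j = index[u], index[v]
        w = float(s) if weighted else 1.0
        rows += [i, j]
        cols += [j, i]
        vals += [w, w]
    A = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsc()
    # collapse any duplicate entries, then column-normalize
    A.sum_duplicates()
    colsums = np.asarray(A.sum(axis=0)).ravel()
    M = (A @ sp.diags(1.0 / colsums)).tocsr()
    return TransitionMatrix(node_ids=node_ids, M=M)
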