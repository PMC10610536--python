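"""Random walk with restart (RWR) over the PPI transition matrix.

The walker starts from a uniform distribution over a drug's network-present
CTET proteins and at each step either follows the column-stochastic walk
matrix W or restarts, with probability r, from the seed distribution:

    p(t+1) = (1 - r) * W @ p(t) + r * p(0)

W = A D^-1 for the symmetric adjacency A is exactly the transpose of the
row-normalized adjacency, so this update is the standard normalized-adjacency
restart walk and conserves total probability mass at every step. The unique
fixed point p* = r * (I - (1-r) W)^-1 @ p(0) measures network proximity of
every protein to the seed set; the iteration contracts toward it in L1 at
rate at most (1 - r).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ConvergenceError, SeedError
from .ppi_network import TransitionMatrix

logger = logging.getLogger(__name__)

DEFAULT_RESTART = 0.5
DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITER = 100


@dataclass(frozen=True)
class SeedSet:
    """A drug's seed proteins (its CTET set), possibly partially off-network."""

    proteins: frozenset[str]

    def present(self, M: TransitionMatrix) -> list[str]:
        return sorted(p for p in self.proteins if M.contains(p))


@dataclass
class PropagationVector:
    """A probability vector over network nodes, with convergence metadata."""

    node_ids: list[str]
    p: np.ndarray
    r: float
    iterations: int
    residual: float

    def value(self, node_id: str) -> float:
        return float(self.p[self.node_ids.index(node_id)])


def initial_vector(seeds: SeedSet, M: TransitionMatrix) -> np.ndarray:
    """Uniform seed distribution 1/|present seeds| over network-present seeds.

    Seeds absent from the filtered network are dropped with a warning; only a
    fully absent seed set is an error (the drug cannot be propagated at all).
    """
    present = seeds.present(M)
    if not present:
        missing = sorted(seeds.proteins)
        raise SeedError(f"no seed protein present in the network: {missing}")
    if len(present) < len(seeds.proteins):
        absent = sorted(seeds.proteins - set(present))
        logger.warning("%d seed protein(s) absent from network: %s", len(absent), absent)
    p0 = np.zeros(M.n_nodes)
    for prot in present:
        p0[M.index_of(prot)] = 1.0 / len(present)
    return p0


def rwr(
    p0: np.ndarray,
    M: TransitionMatrix,
    r: float = DEFAULT_RESTART,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> PropagationVector:
    """Iterate the restart walk to its stationary distribution.

    Terminates when the L1 change between iterates drops below ``tol``.
    Geometric contraction at rate (1-r) makes max_iter=100 generous for any
    r >= 0.1.
    """
    if not 0.0 < r < 1.0:
        raise ValueError(f"restart probability must be in (0, 1), got {r}")
    p = np.asarray(p0, dtype=float)
    W = M.M
    residual = np.inf
    for it in range(1, max_iter + 1):
        p_next = (1.0 - r) * (W @ p) + r * p0
        residual = float(np.abs(p_next - p).sum())
        p = p_next
        if residual < tol:
            return PropagationVector(
                node_ids=list(M.node_ids), p=p, r=r, iterations=it, residual=residual
            )
    raise ConvergenceError(residual=residual, max_iter=max_iter)


def rwr_dense_solve(p0: np.ndarray, M: TransitionMatrix, r: float) -> np.ndarray:
    """Closed-form stationary distribution via a dense linear solve.

    Solves (I - (1-r) W) p = r p0. Serves as an independent oracle for the
    iterative path on small networks; never used in production (dense).
    """
    W = M.M.toarray()
    n = W.shape[0]
    return np.linalg.solve(np.eye(n) - (1.0 - r) * W, r * np.asarray(p0, float))
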