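"""Protein similarity profiles (PSP) from propagation, plus the non-walk baseline.

The association score of ordered drug pair (A, B) is the mean stationary
probability, under the restart walk seeded at A's CTET proteins, over B's
network-present CTET proteins. Stacking these scores for one seeding drug
against every drug in the universe gives that drug's PSP row. The profile is
directional — seeding from A and scoring B is not the same as the reverse —
so the matrix is left asymmetric.

The baseline profile skips the network entirely: each drug becomes a binary
indicator vector over the protein universe (CTET membership) and pairs are
scored with the Tanimoto coefficient. It sees only directly shared proteins,
whereas the walk also credits indirect proximity through the network.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np

from .chem_similarity import tanimoto
from .errors import SeedError, UndefinedScoreError
from .io_formats import DrugRecord, ProfileMatrix
from .ppi_network import TransitionMatrix
from .propagation import (
    DEFAULT_MAX_ITER,
    DEFAULT_RESTART,
    DEFAULT_TOL,
    PropagationVector,
    SeedSet,
    initial_vector,
    rwr,
)

logger = logging.getLogger(__name__)


def association_score(p: PropagationVector, target_ctet: SeedSet) -> float:
    """Mean propagated probability over the target drug's network-present CTET."""
    index = {nid: i for i, nid in enumerate(p.node_ids)}
    present = [prot for prot in sorted(target_ctet.proteins) if prot in index]
    if not present:
        raise UndefinedScoreError(
            f"target CTET set absent from network: {sorted(target_ctet.proteins)}"
        )
    return float(np.mean([p.p[index[prot]] for prot in present]))


def build_psp(
    drugs: Sequence[DrugRecord],
    M: TransitionMatrix,
    r: float = DEFAULT_RESTART,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> ProfileMatrix:
    """Propagate every drug's CTET seeds and score against every drug's CTET.

    Row i holds the association scores from drug i's walk to each drug j's
    CTET set (including j = i, computed like any other entry). CTET proteins
    missing from the filtered network are excluded from both seeding and
    target averaging; per-drug coverage is logged. Drugs whose CTET sets are
    entirely off-network are reported together as a seed error.
    """
    target_indices: list[np.ndarray] = []
    failures: list[str] = []
    for d in drugs:
        present = [prot for prot in sorted(d.ctet_ids) if M.contains(prot)]
        if not present:
            failures.append(d.drug_id)
            target_indices.append(np.empty(0, dtype=int))
            continue
        coverage = len(present) / len(d.ctet_ids)
        if coverage < 1.0:
            logger.info(
                "drug %s: %d/%d CTET proteins on network (coverage %.2f)",
                d.drug_id,
                len(present),
                len(d.ctet_ids),
                coverage,
            )
        target_indices.append(np.array([M.index_of(p) for p in present], dtype=int))
    if failures:
        raise SeedError(f"drugs with no network-present CTET protein: {failures}")

    n = len(drugs)
    values = np.zeros((n, n))
    for i, d in enumerate(drugs):
        p0 = initial_vector(SeedSet(frozenset(d.ctet_ids)), M)
        prop = rwr(p0, M, r=r, tol=tol, max_iter=max_iter)
        for j in range(n):
            values[i, j] = float(prop.p[target_indices[j]].mean())
    ids = [d.drug_id for d in drugs]
    return ProfileMatrix(row_ids=ids, col_ids=list(ids), values=values)


def build_psp_baseline(
    drugs: Sequence[DrugRecord], protein_universe: Sequence[str]
) -> ProfileMatrix:
    """Tanimoto of CTET indicator vectors — the network-free baseline profile."""
    universe = list(protein_universe)
    index = {p: i for i, p in enumerate(universe)}
    missing = {p for d in drugs for p in d.ctet_ids if p not in index}
    if missing:
        raise UndefinedScoreError(
            f"CTET protein(s) outside the given universe: {sorted(missing)[:10]}"
        )
    indicators = np.zeros((len(drugs), len(universe)), dtype=np.uint8)
    for i, d in enumerate(drugs):
        for prot in d.ctet_ids:
            indicators[i, index[prot]] = 1
    n = len(drugs)
    values = np.zeros((n, n))
    for i in range(n):
        values[i, i] = tanimoto(indicators[i], indicators[i])
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = tanimoto(indicators[i], indicators[j])
    ids = [d.drug_id for d in drugs]
    return ProfileMatrix(row_ids=ids, col_ids=list(ids), values=values)
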