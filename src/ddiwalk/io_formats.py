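"""Readers and writers for every on-disk artifact.

All tables are tab-separated UTF-8 with a header row. This matches the export
conventions of STRING-style edge lists and keeps every artifact diff-friendly.
Protein lists inside a single drug-table column are '|'-delimited.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

CTET_DELIMITER = "|"
ABSTAIN_LITERAL = "none"


@dataclass(frozen=True)
class DrugRecord:
    """One drug: identifier, SMILES, and its CTET protein identifiers.

    CTET proteins are the carriers, transporters, enzymes and targets that
    bind or process the drug — its protein-level footprint. A record lacking
    either a SMILES string or a CTET set is kept on load but flagged so that
    modeling can exclude it.
    """

    drug_id: str
    smiles: str
    ctet_ids: frozenset[str]

    @property
    def includable(self) -> bool:
        """True when the drug carries both a structure and a CTET set."""
        return bool(self.smiles) and bool(self.ctet_ids)


@dataclass(frozen=True)
class DDIPair:
    """An ORDERED drug pair with a directional interaction-type label.

    Interaction types are directional sentences ("Drug A may increase the
    effect of Drug B"), so (a, b) and (b, a) are distinct pairs.
    """

    drug_a: str
    drug_b: str
    ddi_type: int

    def __post_init__(self):
        if self.drug_a == self.drug_b:
            raise ValidationError(f"self-pair not allowed: {self.drug_a!r}")


@dataclass
class PPIEdgeList:
    """Undirected scored protein-protein edges, canonicalized.

    Edges are stored with node ids in sorted order per edge; duplicates have
    been collapsed (max score kept) and self-edges removed.
    """

    edges: list[tuple[str, str, float]]

    @property
    def nodes(self) -> set[str]:
        out: set[str] = set()
        for u, v, _ in self.edges:
            out.add(u)
            out.add(v)
        return out

    def __len__(self) -> int:
        return len(self.edges)


@dataclass(frozen=True)
class PredictionResult:
    """Prediction for one ordered drug pair.

    ``predicted_type`` is None when the model abstains: the winning class
    probability fell below the decision threshold.
    """

    drug_a: str
    drug_b: str
    predicted_type: int | None
    confidence: float


@dataclass
class ProfileMatrix:
    """A drugs x drugs numeric profile (SSP or PSP).

    Rows are the profiled drugs, columns span the drug universe. Structure
    similarity profiles (SSP) are symmetric with values in [0, 1]; protein
    similarity profiles (PSP) from network propagation are generally
    asymmetric because propagation is seeded from the row drug.
    """

    row_ids: list[str]
    col_ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValidationError(
                f"profile shape {self.values.shape} does not match "
                f"{len(self.row_ids)} rows x {len(self.col_ids)} cols"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("profile matrix contains non-finite values")

    def row(self, drug_id: str) -> np.ndarray:
        return self.values[self.row_ids.index(drug_id)]


def _read_table(path: str | Path, columns: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    return df


def load_drugs(path: str | Path) -> list[DrugRecord]:
    """Load a drug table (drug_id, smiles, ctet_ids).

    Rows with an empty SMILES or an empty CTET list are returned but their
    ``includable`` flag is False — they carry too little information to model.
    Duplicate drug ids are an error naming the offending lines.
    """
    df = _read_table(path, ["drug_id", "smiles", "ctet_ids"])
    dup = df[df.duplicated("drug_id", keep=False)]
    if not dup.empty:
        lines = {}
        for idx, row in dup.iterrows():
            lines.setdefault(row["drug_id"], []).append(idx + 2)  # +2: header + 1-based
        msg = "; ".join(
            f"drug_id {did!r} on lines {sorted(ls)}" for did, ls in sorted(lines.items())
        )
        raise ParseError(f"{path}: duplicate drug ids: {msg}")
    records = []
    for _, row in df.iterrows():
        ctet = frozenset(t for t in row["ctet_ids"].split(CTET_DELIMITER) if t)
        records.append(DrugRecord(row["drug_id"], row["smiles"].strip(), ctet))
    n_excluded = sum(not r.includable for r in records)
    if n_excluded:
        logger.warning(
            "%d of %d drugs lack SMILES or CTET proteins and are excluded from modeling",
            n_excluded,
            len(records),
        )
    return records


def write_drugs(records: Iterable[DrugRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "drug_id": [r.drug_id for r in records],
            "smiles": [r.smiles for r in records],
            "ctet_ids": [CTET_DELIMITER.join(sorted(r.ctet_ids)) for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def load_ppi(path: str | Path, id_map_path: str | Path | None = None) -> PPIEdgeList:
    """Load a STRING-like edge list (protein1, protein2, combined_score).

    When an id map is given, node identifiers are remapped and edges touching
    unmappable nodes are dropped (count logged). Duplicate undirected edges
    collapse keeping the maximum score; self-edges are dropped.
    """
    df = _read_table(path, ["protein1", "protein2", "combined_score"])
    scores = pd.to_numeric(df["combined_score"], errors="coerce")
    bad = scores.isna() | ~np.isfinite(scores) | (scores < 0)
    if bad.any():
        line = int(bad.idxmax()) + 2
        raise ParseError(
            f"{path}: non-numeric or negative score on line {line}: "
            f"{df['combined_score'].iloc[int(bad.idxmax())]!r}"
        )

    id_map: Mapping[str, str] | None = None
    if id_map_path is not None:
        mdf = pd.read_csv(id_map_path, sep="\t", dtype=str, keep_default_na=False)
        if mdf.shape[1] < 2:
            raise ParseError(f"{id_map_path}: id map needs 2 columns")
        id_map = dict(zip(mdf.iloc[:, 0], mdf.iloc[:, 1]))

    best: dict[tuple[str, str], float] = {}
    n_self = 0
    n_unmapped = 0
    for u, v, s in zip(df["protein1"], df["protein2"], scores):
        if id_map is not None:
            if u not in id_map or v not in id_map:
                n_unmapped += 1
                continue
            u, v = id_map[u], id_map[v]
        if u == v:
            n_self += 1
            continue
        key = (u, v) if u <= v else (v, u)
        s = float(s)
        if key not in best or s > best[key]:
            best[key] = s
    if n_self:
        logger.warning("dropped %d self-edge(s)", n_self)
    if n_unmapped:
        logger.warning("dropped %d edge(s) touching unmappable node(s)", n_unmapped)
    edges = [(u, v, s) for (u, v), s in sorted(best.items())]
    return PPIEdgeList(edges=edges)


def write_ppi(ppi: PPIEdgeList, path: str | Path) -> None:
    df = pd.DataFrame(ppi.edges, columns=["protein1", "protein2", "combined_score"])
    df.to_csv(path, sep="\t", index=False)


def load_ddi_pairs(path: str | Path, n_types: int) -> list[DDIPair]:
    """Load ordered labeled drug pairs; labels validated against 1..n_types."""
    df = _read_table(path, ["drug_a", "drug_b", "ddi_type"])
    pairs = []
    for idx, row in df.iterrows():
        line = idx + 2
        try:
            t = int(row["ddi_type"])
        except ValueError:
            raise ParseError(f"{path}: non-integer ddi_type on line {line}") from None
        if not 1 <= t <= n_types:
            raise ValidationError(
                f"{path}: ddi_type {t} outside 1..{n_types} on line {line}"
            )
        if row["drug_a"] == row["drug_b"]:
            raise ValidationError(f"{path}: self-pair {row['drug_a']!r} on line {line}")
        pairs.append(DDIPair(row["drug_a"], row["drug_b"], t))
    return pairs


def write_ddi_pairs(pairs: Iterable[DDIPair], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "drug_a": [p.drug_a for p in pairs],
            "drug_b": [p.drug_b for p in pairs],
            "ddi_type": [p.ddi_type for p in pairs],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_predictions(results: Sequence[PredictionResult], path: str | Path) -> None:
    """Write a prediction report (pair, type or "none", full-precision confidence)."""
    rows = [
        (
            r.drug_a,
            r.drug_b,
            ABSTAIN_LITERAL if r.predicted_type is None else str(r.predicted_type),
            repr(float(r.confidence)),
        )
        for r in results
    ]
    df = pd.DataFrame(rows, columns=["drug_a", "drug_b", "predicted_type", "confidence"])
    df.to_csv(path, sep="\t", index=False)


def load_predictions(path: str | Path) -> list[PredictionResult]:
    df = _read_table(path, ["drug_a", "drug_b", "predicted_type", "confidence"])
    out = []
    for idx, row in df.iterrows():
        raw = row["predicted_type"]
        if raw == ABSTAIN_LITERAL:
            ptype: int | None = None
        else:
            try:
                ptype = int(raw)
            except ValueError:
                raise ParseError(
                    f"{path}: bad predicted_type {raw!r} on line {idx + 2}"
                ) from None
        conf = float(row["confidence"])
        if not (math.isfinite(conf) and 0.0 <= conf <= 1.0):
            raise ParseError(f"{path}: confidence out of [0,1] on line {idx + 2}")
        out.append(PredictionResult(row["drug_a"], row["drug_b"], ptype, conf))
    return out


def write_profile(profile: ProfileMatrix, path: str | Path) -> None:
    """Serialize a profile matrix with row/column drug-id headers."""
    df = pd.DataFrame(profile.values, index=profile.row_ids, columns=profile.col_ids)
    df.to_csv(path, sep="\t", index_label="drug_id", float_format="%.12g")


def load_profile(path: str | Path) -> ProfileMatrix:
    df = pd.read_csv(path, sep="\t", index_col="drug_id")
    return ProfileMatrix(
        row_ids=[str(i) for i in df.index],
        col_ids=[str(c) for c in df.columns],
        values=df.to_numpy(dtype=float),
    )
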