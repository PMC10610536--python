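"""Structure similarity profiles (SSP) from SMILES.

Each drug's SMILES is canonicalized, hashed into a binary topological
path-based fingerprint (RDKit, 2048 bits by default), and compared against
every other drug with the Tanimoto coefficient |a AND b| / |a OR b|. The SSP
of a drug is its row of pairwise similarities over the full drug universe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator

from .errors import ChemistryError, ValidationError
from .io_formats import DrugRecord, ProfileMatrix

RDLogger.DisableLog("rdApp.*")  # parse failures are raised, not printed

logger = logging.getLogger(__name__)

DEFAULT_N_BITS = 2048


@dataclass
class FingerprintMatrix:
    """Binary fingerprints, one row per drug, row order matches drug_ids."""

    drug_ids: list[str]
    bits: np.ndarray  # (n_drugs, n_bits) uint8 in {0, 1}

    def __post_init__(self):
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if self.bits.ndim != 2 or self.bits.shape[0] != len(self.drug_ids):
            raise ValidationError("fingerprint matrix shape mismatch")
        if not np.isin(self.bits, (0, 1)).all():
            raise ValidationError("fingerprint entries must be binary")


def fingerprint(smiles: str, n_bits: int = DEFAULT_N_BITS) -> np.ndarray:
    """Hashed topological path fingerprint of one molecule as a 0/1 vector.

    The SMILES is parsed and implicitly canonicalized by the toolkit, so any
    spelling of the same molecule yields the same bits.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ChemistryError(f"unparseable SMILES: {smiles!r}")
    gen = rdFingerprintGenerator.GetRDKitFPGenerator(fpSize=n_bits)
    fp = gen.GetFingerprint(mol)
    arr = np.zeros(n_bits, dtype=np.uint8)
    for bit in fp.GetOnBits():
        arr[bit] = 1
    return arr


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto coefficient of two equal-length binary vectors.

    Defined as 0.0 when both vectors are all-zero (no shared substructure
    evidence rather than an indeterminate 0/0).
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValidationError(f"length mismatch: {a.shape} vs {b.shape}")
    inter = int(np.count_nonzero(np.logical_and(a, b)))
    union = int(np.count_nonzero(np.logical_or(a, b)))
    return inter / union if union else 0.0


def build_fingerprints(
    drugs: Sequence[DrugRecord], n_bits: int = DEFAULT_N_BITS
) -> FingerprintMatrix:
    """Fingerprint every drug; aggregate all chemistry failures into one error."""
    rows = []
    failures = []
    for d in drugs:
        try:
            rows.append(fingerprint(d.smiles, n_bits))
        except ChemistryError:
            failures.append(d.drug_id)
    if failures:
        raise ChemistryError(f"unparseable SMILES for drugs: {failures}")
    return FingerprintMatrix(
        drug_ids=[d.drug_id for d in drugs],
        bits=np.vstack(rows) if rows else np.zeros((0, n_bits), np.uint8),
    )


def ssp_from_fingerprints(fps: FingerprintMatrix) -> ProfileMatrix:
    """All-pairs Tanimoto matrix computed vectorized from a bit matrix."""
    bits = fps.bits.astype(np.int32)
    inter = bits @ bits.T
    ones = bits.sum(axis=1)
    union = ones[:, None] + ones[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    return ProfileMatrix(
        row_ids=list(fps.drug_ids), col_ids=list(fps.drug_ids), values=sim
    )


def build_ssp(drugs: Sequence[DrugRecord], n_bits: int = DEFAULT_N_BITS) -> ProfileMatrix:
    """Structure similarity profile matrix over the drug universe.

    Square, symmetric, unit diagonal for any drug with at least one on-bit.
    """
    return ssp_from_fingerprints(build_fingerprints(drugs, n_bits))


def write_fingerprints(fps: FingerprintMatrix, path: str | Path) -> None:
    """Cache fingerprints as TSV: drug_id + hex-packed bits."""
    n_bits = fps.bits.shape[1]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("drug_id\tn_bits\thex_bits\n")
        for did, row in zip(fps.drug_ids, fps.bits):
            packed = np.packbits(row).tobytes().hex()
            fh.write(f"{did}\t{n_bits}\t{packed}\n")


def load_fingerprints(path: str | Path) -> FingerprintMatrix:
    drug_ids: list[str] = []
    rows: list[np.ndarray] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("drug_id"):
            raise ChemistryError(f"{path}: not a fingerprint cache")
        for line in fh:
            did, n_bits_s, hex_bits = line.rstrip("\n").split("\t")
            n_bits = int(n_bits_s)
            unpacked = np.unpackbits(np.frombuffer(bytes.fromhex(hex_bits), np.uint8))
            drug_ids.append(did)
            rows.append(unpacked[:n_bits])
    bits = np.vstack(rows) if rows else np.zeros((0, 0), np.uint8)
    return FingerprintMatrix(drug_ids=drug_ids, bits=bits)
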