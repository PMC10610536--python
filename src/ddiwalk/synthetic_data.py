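"""Synthetic drugs, PPI network, CTET assignments and planted DDI labels.

The generator emulates the statistical structure the predictor exploits,
with no external database: a scale-free (preferential-attachment) protein
network organized into modules with dense intra- and sparse inter-module
edges; drugs anchored to a home module, their CTET sets drawn from it; and
chemical structures derived from a per-module template so that structural
similarity mirrors module membership. The planted label of an ordered pair
(A, B) is a deterministic function of (home(A), home(B)), so both the
structure channel (SSP) and the network channel (PSP) carry the label
signal and a perfect model exists. Setting ``structure_noise=0.5`` severs
the structure channel (templates are forgotten bit-by-bit), leaving labels
recoverable only through the network — the variant used to show the walk's
advantage over direct CTET overlap.

Every random draw flows from the single config seed through named child
generators, so identical configs produce byte-identical files.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .errors import ValidationError
from . import io_formats
from .chem_similarity import FingerprintMatrix, write_fingerprints
from .io_formats import DDIPair, DrugRecord, PPIEdgeList

SMILES_ALPHABET = ("C", "N", "O", "S")  # chain-safe atoms (valence >= 2)

LABEL_RULE_COMMUNITY_PAIR = "community_pair"


@dataclass
class SyntheticConfig:
    """Knobs of the generator; defaults give a comfortably learnable benchmark."""

    n_drugs: int = 120
    n_proteins: int = 300
    attachment_m: int = 3          # preferential-attachment edges per new node
    n_communities: int = 3
    ctet_per_drug: tuple[int, int] = (2, 5)
    n_types: int = 9
    structure_noise: float = 0.05  # per-position template corruption probability
    inter_community_fraction: float = 0.05  # cross-module edges per intra edge
    label_rule: str = LABEL_RULE_COMMUNITY_PAIR
    structure_mode: str = "smiles"  # "smiles" | "fingerprint"
    template_length: int = 30       # SMILES chain length (smiles mode)
    n_bits: int = 256               # fingerprint length (fingerprint mode)
    n_pairs: int | None = None      # subsample of ordered pairs; None = all
    seed: int = 0

    def __post_init__(self):
        if min(self.n_drugs, self.n_proteins, self.n_communities, self.n_types) <= 0:
            raise ValidationError("counts must be positive")
        if self.label_rule != LABEL_RULE_COMMUNITY_PAIR:
            raise ValidationError(f"unknown label rule: {self.label_rule!r}")
        if self.n_types > self.n_communities**2:
            raise ValidationError(
                f"{self.n_types} types exceed the {self.n_communities**2} "
                "distinguishable ordered community pairs"
            )
        if not 0.0 <= self.structure_noise <= 1.0:
            raise ValidationError("structure_noise must be a probability")
        if self.structure_mode not in ("smiles", "fingerprint"):
            raise ValidationError(f"unknown structure_mode: {self.structure_mode!r}")
        lo, hi = self.ctet_per_drug
        if not 1 <= lo <= hi:
            raise ValidationError("ctet_per_drug must be a positive (low, high) range")


@dataclass
class SyntheticDataset:
    """Paths of the emitted TSV artifacts (io_formats dialects)."""

    drugs_path: Path
    ppi_path: Path
    ddi_path: Path
    fingerprints_path: Path | None = None
    home_community: dict[str, int] = field(default_factory=dict)


def _rngs(seed: int, names: list[str]) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(ss) for name, ss in zip(names, children)}


def _protein_id(i: int) -> str:
    return f"P{i:05d}"


def _community_blocks(n_proteins: int, c: int) -> list[list[str]]:
    sizes = [n_proteins // c + (1 if i < n_proteins % c else 0) for i in range(c)]
    blocks, start = [], 0
    for size in sizes:
        blocks.append([_protein_id(i) for i in range(start, start + size)])
        start += size
    return blocks


def _build_network(cfg: SyntheticConfig, rng: np.random.Generator) -> PPIEdgeList:
    blocks = _community_blocks(cfg.n_proteins, cfg.n_communities)
    edges: list[tuple[str, str]] = []
    for block in blocks:
        m = min(cfg.attachment_m, len(block) - 1)
        g = nx.barabasi_albert_graph(len(block), m, seed=int(rng.integers(2**31)))
        edges.extend((block[u], block[v]) for u, v in g.edges())
    n_inter = int(np.ceil(cfg.inter_community_fraction * len(edges)))
    seen = {tuple(sorted(e)) for e in edges}
    while n_inter > 0:
        ci, cj = rng.choice(cfg.n_communities, size=2, replace=False)
        u = blocks[ci][int(rng.integers(len(blocks[ci])))]
        v = blocks[cj][int(rng.integers(len(blocks[cj])))]
        key = tuple(sorted((u, v)))
        if key not in seen:
            seen.add(key)
            edges.append((u, v))
            n_inter -= 1
    scored = [
        (u, v, float(np.round(rng.uniform(100.0, 1000.0), 3))) for u, v in edges
    ]
    scored = [(u, v, s) if u <= v else (v, u, s) for u, v, s in scored]
    return PPIEdgeList(edges=sorted(scored))


def _make_drugs(
    cfg: SyntheticConfig,
    blocks: list[list[str]],
    rng: np.random.Generator,
) -> tuple[list[DrugRecord], dict[str, int], np.ndarray | None]:
    lo, hi = cfg.ctet_per_drug
    if cfg.structure_mode == "smiles":
        templates = [
            rng.choice(len(SMILES_ALPHABET), size=cfg.template_length)
            for _ in range(cfg.n_communities)
        ]
    else:
        templates = [
            rng.integers(0, 2, size=cfg.n_bits).astype(np.uint8)
            for _ in range(cfg.n_communities)
        ]
    drugs: list[DrugRecord] = []
    home: dict[str, int] = {}
    fp_rows: list[np.ndarray] = []
    for i in range(cfg.n_drugs):
        drug_id = f"D{i:04d}"
        community = i % cfg.n_communities
        home[drug_id] = community
        block = blocks[community]
        size = int(rng.integers(lo, hi + 1))
        ctet = frozenset(
            rng.choice(block, size=min(size, len(block)), replace=False).tolist()
        )
        if cfg.structure_mode == "smiles":
            letters = templates[community].copy()
            corrupt = rng.random(cfg.template_length) < cfg.structure_noise
            letters[corrupt] = rng.choice(len(SMILES_ALPHABET), size=int(corrupt.sum()))
            smiles = "".join(SMILES_ALPHABET[k] for k in letters)
        else:
            bits = templates[community].copy()
            flips = rng.random(cfg.n_bits) < cfg.structure_noise
            bits[flips] ^= 1
            fp_rows.append(bits)
            smiles = "C"  # structural information lives in the fingerprint file
        drugs.append(DrugRecord(drug_id, smiles, ctet))
    fps = np.vstack(fp_rows) if fp_rows else None
    return drugs, home, fps


def planted_label(home_a: int, home_b: int, n_communities: int, n_types: int) -> int:
    """Deterministic type for an ordered community pair, folded into 1..n_types."""
    return (home_a * n_communities + home_b) % n_types + 1


def _make_pairs(
    cfg: SyntheticConfig, home: dict[str, int], rng: np.random.Generator
) -> list[DDIPair]:
    drug_ids = sorted(home)
    all_pairs = [
        (a, b) for a, b in itertools.permutations(drug_ids, 2)
    ]
    if cfg.n_pairs is not None and cfg.n_pairs < len(all_pairs):
        chosen = rng.choice(len(all_pairs), size=cfg.n_pairs, replace=False)
        all_pairs = [all_pairs[i] for i in sorted(chosen)]
    return [
        DDIPair(a, b, planted_label(home[a], home[b], cfg.n_communities, cfg.n_types))
        for a, b in all_pairs
    ]


def generate(config: SyntheticConfig, out_dir: str | Path) -> SyntheticDataset:
    """Emit drugs.tsv, ppi.tsv and ddi.tsv (plus fingerprints.tsv when asked).

    Output is byte-identical for identical configs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rngs = _rngs(config.seed, ["network", "drugs", "pairs"])
    blocks = _community_blocks(config.n_proteins, config.n_communities)
    ppi = _build_network(config, rngs["network"])
    drugs, home, fps = _make_drugs(config, blocks, rngs["drugs"])
    pairs = _make_pairs(config, home, rngs["pairs"])

    dataset = SyntheticDataset(
        drugs_path=out_dir / "drugs.tsv",
        ppi_path=out_dir / "ppi.tsv",
        ddi_path=out_dir / "ddi.tsv",
        home_community=home,
    )
    io_formats.write_drugs(drugs, dataset.drugs_path)
    io_formats.write_ppi(ppi, dataset.ppi_path)
    io_formats.write_ddi_pairs(pairs, dataset.ddi_path)
    if fps is not None:
        dataset.fingerprints_path = out_dir / "fingerprints.tsv"
        write_fingerprints(
            FingerprintMatrix(drug_ids=[d.drug_id for d in drugs], bits=fps),
            dataset.fingerprints_path,
        )
    return dataset


def planted_indirect_fixture(out_dir: str | Path) -> SyntheticDataset:
    """Fixed micro-fixture isolating the walk's indirect-signal advantage.

    Drugs DA and DB have disjoint CTET sets ({u} and {v}) bridged by an
    intermediate protein x, so direct CTET overlap is zero but a two-step
    network path exists. Control drugs DC and DD sit on mutually unreachable
    components. A propagation-based profile separates (DA, DB) from
    (DC, DD); the Tanimoto-on-CTET baseline scores both pairs 0.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    edges = [
        ("u", "x", 900.0),
        ("v", "x", 900.0),
        ("w", "y", 900.0),
        ("q", "z", 900.0),
    ]
    drugs = [
        DrugRecord("DA", "CC", frozenset({"u"})),
        DrugRecord("DB", "CCC", frozenset({"v"})),
        DrugRecord("DC", "CCO", frozenset({"w"})),
        DrugRecord("DD", "CCN", frozenset({"z"})),
    ]
    pairs = [DDIPair("DA", "DB", 1), DDIPair("DC", "DD", 2)]
    dataset = SyntheticDataset(
        drugs_path=out_dir / "drugs.tsv",
        ppi_path=out_dir / "ppi.tsv",
        ddi_path=out_dir / "ddi.tsv",
    )
    io_formats.write_drugs(drugs, dataset.drugs_path)
    io_formats.write_ppi(
        PPIEdgeList(edges=sorted((u, v, s) if u <= v else (v, u, s) for u, v, s in edges)),
        dataset.ppi_path,
    )
    io_formats.write_ddi_pairs(pairs, dataset.ddi_path)
    return dataset
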