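"""End-to-end orchestration: files in, trained model and evaluation out.

Chains the whole workflow — load tables, filter the PPI network, build the
structure (SSP) and propagation (PSP) profiles, reduce with PCA, assemble
ordered-pair features, train the thresholded classifier on a stratified
7:3 split and score the held-out pairs. The CLI subcommands are thin
wrappers over these functions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import chem_similarity, drug_profiles, evaluation, feature_model, io_formats
from .errors import ValidationError
from .feature_model import ModelConfig, ReducedProfiles, TrainedModel
from .io_formats import DDIPair, DrugRecord, PredictionResult, ProfileMatrix
from .ppi_network import build_transition_matrix, filter_top_confidence

logger = logging.getLogger(__name__)

PSP_MODE_RWR = "rwr"
PSP_MODE_BASELINE = "baseline"


@dataclass
class PipelineConfig:
    """Workflow-level knobs around the classifier's own ModelConfig."""

    keep_fraction: float = 0.2        # PPI top-confidence quantile
    restart_probability: float = 0.5  # RWR restart parameter r
    d_ssp: int = feature_model.DEFAULT_D_SSP
    d_psp: int = feature_model.DEFAULT_D_PSP
    train_fraction: float = 0.7
    psp_mode: str = PSP_MODE_RWR
    model: ModelConfig = field(default_factory=ModelConfig)

    def __post_init__(self):
        if self.psp_mode not in (PSP_MODE_RWR, PSP_MODE_BASELINE):
            raise ValidationError(f"unknown psp_mode: {self.psp_mode!r}")


@dataclass
class PipelineResult:
    drugs: list[DrugRecord]
    ssp: ProfileMatrix
    psp: ProfileMatrix
    reduced: ReducedProfiles
    model: TrainedModel
    report: evaluation.EvalReport
    test_pairs: list[DDIPair]
    predictions: list[PredictionResult]


def build_profiles(
    drugs_path: str | Path,
    ppi_path: str | Path,
    config: PipelineConfig,
    id_map_path: str | Path | None = None,
    fingerprints_path: str | Path | None = None,
) -> tuple[list[DrugRecord], ProfileMatrix, ProfileMatrix]:
    """Load inputs and build both drug-level profiles.

    Drugs lacking SMILES/CTET data, and drugs whose CTET proteins all fall
    off the filtered network, are dropped here (counts logged) — they cannot
    be modeled.
    """
    all_drugs = io_formats.load_drugs(drugs_path)
    drugs = [d for d in all_drugs if d.includable]
    if len(drugs) < len(all_drugs):
        logger.info("excluded %d drug(s) lacking SMILES or CTET", len(all_drugs) - len(drugs))

    ppi = io_formats.load_ppi(ppi_path, id_map_path)
    filtered = filter_top_confidence(ppi, config.keep_fraction)
    M = build_transition_matrix(filtered)

    on_network = [d for d in drugs if any(M.contains(p) for p in d.ctet_ids)]
    if len(on_network) < len(drugs):
        logger.info(
            "excluded %d drug(s) with no CTET protein on the filtered network",
            len(drugs) - len(on_network),
        )
    drugs = on_network
    if len(drugs) < 2:
        raise ValidationError("fewer than 2 modelable drugs after filtering")

    if fingerprints_path is not None:
        fps = chem_similarity.load_fingerprints(fingerprints_path)
        keep = {d.drug_id for d in drugs}
        idx = [i for i, did in enumerate(fps.drug_ids) if did in keep]
        fps = chem_similarity.FingerprintMatrix(
            drug_ids=[fps.drug_ids[i] for i in idx], bits=fps.bits[idx]
        )
        order = {d.drug_id: i for i, d in enumerate(drugs)}
        perm = sorted(range(len(fps.drug_ids)), key=lambda i: order[fps.drug_ids[i]])
        fps = chem_similarity.FingerprintMatrix(
            drug_ids=[fps.drug_ids[i] for i in perm], bits=fps.bits[perm]
        )
        ssp = chem_similarity.ssp_from_fingerprints(fps)
    else:
        ssp = chem_similarity.build_ssp(drugs)

    if config.psp_mode == PSP_MODE_RWR:
        psp = drug_profiles.build_psp(drugs, M, r=config.restart_probability)
    else:
        universe = sorted({p for d in drugs for p in d.ctet_ids})
        psp = drug_profiles.build_psp_baseline(drugs, universe)
    return drugs, ssp, psp


def run_pipeline(
    drugs_path: str | Path,
    ppi_path: str | Path,
    ddi_path: str | Path,
    config: PipelineConfig,
    id_map_path: str | Path | None = None,
    fingerprints_path: str | Path | None = None,
    predictions_path: str | Path | None = None,
) -> PipelineResult:
    """Full workflow on one dataset; returns the held-out evaluation."""
    drugs, ssp, psp = build_profiles(
        drugs_path, ppi_path, config, id_map_path, fingerprints_path
    )
    modelable = {d.drug_id for d in drugs}
    pairs = io_formats.load_ddi_pairs(ddi_path, n_types=config.model.n_types)
    pairs = [p for p in pairs if p.drug_a in modelable and p.drug_b in modelable]
    if not pairs:
        raise ValidationError("no labeled pairs cover the modelable drugs")

    d_ssp = min(config.d_ssp, len(drugs))
    d_psp = min(config.d_psp, len(drugs))
    reduced = feature_model.fit_reduce(ssp, psp, d_ssp=d_ssp, d_psp=d_psp)

    train_pairs, test_pairs = evaluation.stratified_split(
        pairs, train_fraction=config.train_fraction, seed=config.model.seed
    )
    model = feature_model.train(train_pairs, reduced, config.model)
    predictions = feature_model.predict_batch(model, test_pairs, reduced)
    report = evaluation.compute_metrics(
        [p.ddi_type for p in test_pairs], predictions, config.model.n_types
    )
    if predictions_path is not None:
        io_formats.write_predictions(predictions, predictions_path)
    return PipelineResult(
        drugs=drugs,
        ssp=ssp,
        psp=psp,
        reduced=reduced,
        model=model,
        report=report,
        test_pairs=test_pairs,
        predictions=predictions,
    )
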