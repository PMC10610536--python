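"""PCA reduction, ordered-pair feature assembly, and the thresholded classifier.

The two drug-level profiles (SSP over structures, PSP over propagated CTET
proteins) are reduced with PCA fitted once on the full profile matrices —
drugs are rows, so the pair-level train/test split does not touch the
profile fit. An ordered pair (A, B) becomes the concatenation
[ssp_A, psp_A, ssp_B, psp_B]; with the default 200 SSP and 300 PSP
components the input is 1000-dimensional. Ordered concatenation is used
because interaction types are directional sentences.

The classifier is a feed-forward softmax network — four 1024-node rectifier
(ReLU) hidden layers with dropout 0.3, trained with mini-batch Adam
(batch 128, learning rate 1e-3, 100 epochs by default). Implemented directly
on NumPy: forward/backward passes, inverted dropout, and the Adam update are
a few dozen lines, and full control of the RNG gives bit-reproducible
training for a fixed seed. A pair is assigned the argmax interaction type
only when its winning probability reaches the decision threshold tau
(default 0.47); otherwise the model abstains ("no interaction asserted").
"""

from __future__ import annotations

import io
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.decomposition import PCA

from .errors import ValidationError
from .io_formats import DDIPair, DrugRecord, PredictionResult, ProfileMatrix

logger = logging.getLogger(__name__)

DEFAULT_D_SSP = 200
DEFAULT_D_PSP = 300
DEFAULT_THRESHOLD = 0.47


@dataclass
class ModelConfig:
    """Hyperparameters of the pair classifier (defaults: the reference setup)."""

    hidden_layers: int = 4
    hidden_nodes: int = 1024
    batch_size: int = 128
    learning_rate: float = 0.001
    epochs: int = 100
    dropout: float = 0.3
    decision_threshold: float = DEFAULT_THRESHOLD
    n_types: int = 80
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.decision_threshold < 1.0:
            raise ValidationError("decision_threshold must be in (0, 1)")
        if min(self.hidden_layers, self.hidden_nodes, self.batch_size, self.epochs,
               self.n_types) <= 0:
            raise ValidationError("model size parameters must be positive")
        if self.learning_rate < 0 or not 0.0 <= self.dropout < 1.0:
            raise ValidationError("learning_rate must be >= 0 and dropout in [0, 1)")


@dataclass
class ReducedProfiles:
    """Per-drug PCA coordinates plus the fitted transforms for reuse."""

    drug_ids: list[str]
    ssp_components: np.ndarray  # (n_drugs, d_ssp)
    psp_components: np.ndarray  # (n_drugs, d_psp)
    ssp_basis: np.ndarray       # (d_ssp, n_features)
    psp_basis: np.ndarray
    ssp_mean: np.ndarray
    psp_mean: np.ndarray

    def __post_init__(self):
        self._index = {d: i for i, d in enumerate(self.drug_ids)}

    @property
    def d_ssp(self) -> int:
        return self.ssp_components.shape[1]

    @property
    def d_psp(self) -> int:
        return self.psp_components.shape[1]

    def row(self, drug_id: str) -> tuple[np.ndarray, np.ndarray]:
        i = self._index[drug_id]
        return self.ssp_components[i], self.psp_components[i]


def _fit_pca(X: np.ndarray, d: int, label: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic PCA: centered SVD projection with a fixed sign convention.

    Each component's largest-magnitude loading is made positive so repeated
    fits (and fits of duplicated rows) are identical.
    """
    rank = int(np.linalg.matrix_rank(X - X.mean(axis=0)))
    if d > min(X.shape):
        raise ValidationError(
            f"{label}: {d} components exceed matrix dimensions {X.shape}"
        )
    if d > rank:
        warnings.warn(
            f"{label}: requested {d} components but matrix rank is {rank}; reduced",
            stacklevel=3,
        )
        d = max(rank, 1)
    pca = PCA(n_components=d, svd_solver="full")
    scores = pca.fit_transform(X)
    basis = pca.components_
    flip = np.sign(basis[np.arange(d), np.argmax(np.abs(basis), axis=1)])
    flip[flip == 0] = 1.0
    return scores * flip, basis * flip[:, None], pca.mean_


def fit_reduce(
    ssp: ProfileMatrix,
    psp: ProfileMatrix,
    d_ssp: int = DEFAULT_D_SSP,
    d_psp: int = DEFAULT_D_PSP,
) -> ReducedProfiles:
    """Fit PCA on both profile matrices and return per-drug coordinates."""
    if ssp.row_ids != psp.row_ids:
        raise ValidationError("SSP and PSP must cover the same drug universe, in order")
    s_scores, s_basis, s_mean = _fit_pca(ssp.values, d_ssp, "SSP")
    p_scores, p_basis, p_mean = _fit_pca(psp.values, d_psp, "PSP")
    return ReducedProfiles(
        drug_ids=list(ssp.row_ids),
        ssp_components=s_scores,
        psp_components=p_scores,
        ssp_basis=s_basis,
        psp_basis=p_basis,
        ssp_mean=s_mean,
        psp_mean=p_mean,
    )


def pair_features(pair: DDIPair | tuple[str, str], reduced: ReducedProfiles) -> np.ndarray:
    """Ordered concatenation [ssp_A, psp_A, ssp_B, psp_B] for one drug pair."""
    a, b = (pair.drug_a, pair.drug_b) if isinstance(pair, DDIPair) else pair
    try:
        ssp_a, psp_a = reduced.row(a)
        ssp_b, psp_b = reduced.row(b)
    except KeyError as exc:
        raise ValidationError(f"unknown drug id in pair: {exc.args[0]!r}") from None
    return np.concatenate([ssp_a, psp_a, ssp_b, psp_b])


# --------------------------------------------------------------------------
# the softmax MLP


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


@dataclass
class TrainedModel:
    """Weights of the softmax MLP plus its training configuration and loss curve."""

    config: ModelConfig
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    loss_trajectory: list[float] = field(default_factory=list)

    @property
    def input_dim(self) -> int:
        return self.weights[0].shape[0]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Class probabilities (inference mode: dropout off)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.input_dim:
            raise ValidationError(
                f"feature dimension {X.shape[1]} != model input {self.input_dim}"
            )
        h = X
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            h = _relu(h @ W + b)
        return _softmax(h @ self.weights[-1] + self.biases[-1])


def _init_layers(rng: np.random.Generator, dims: list[int]) -> tuple[list, list]:
    weights, biases = [], []
    for fan_in, fan_out in zip(dims[:-1], dims[1:]):
        weights.append(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return weights, biases


def train(
    pairs: Sequence[DDIPair],
    reduced: ReducedProfiles,
    config: ModelConfig,
) -> TrainedModel:
    """Train the softmax MLP on labeled ordered pairs.

    Mini-batch Adam with He-initialized weights and inverted dropout after
    each hidden activation. All randomness (init, shuffling, dropout masks)
    flows from config.seed, so two runs with the same config are identical.
    The recorded loss trajectory is the full-data cross-entropy evaluated in
    inference mode after each epoch.
    """
    if not pairs:
        raise ValidationError("no training pairs")
    labels = np.array([p.ddi_type - 1 for p in pairs], dtype=int)
    present = np.unique(labels)
    if present.size < 2:
        raise ValidationError("need at least 2 classes to train")
    empty = sorted(set(range(config.n_types)) - set(present.tolist()))
    if empty:
        logger.warning(
            "%d of %d interaction types have no training examples (kept in output layer)",
            len(empty),
            config.n_types,
        )
    X = np.vstack([pair_features(p, reduced) for p in pairs])
    n, d = X.shape
    T = config.n_types

    rng = np.random.default_rng(config.seed)
    dims = [d] + [config.hidden_nodes] * config.hidden_layers + [T]
    weights, biases = _init_layers(rng, dims)
    mw = [np.zeros_like(W) for W in weights]
    vw = [np.zeros_like(W) for W in weights]
    mb = [np.zeros_like(b) for b in biases]
    vb = [np.zeros_like(b) for b in biases]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    keep = 1.0 - config.dropout
    step = 0
    model = TrainedModel(config=config, weights=weights, biases=biases)

    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = X[idx], labels[idx]
            m = len(idx)
            # forward with inverted dropout on hidden activations
            acts = [xb]
            masks = []
            h = xb
            for W, b in zip(weights[:-1], biases[:-1]):
                h = _relu(h @ W + b)
                if config.dropout > 0:
                    mask = (rng.random(h.shape) < keep) / keep
                    h = h * mask
                    masks.append(mask)
                else:
                    masks.append(None)
                acts.append(h)
            probs = _softmax(h @ weights[-1] + biases[-1])
            # backward
            delta = probs
            delta[np.arange(m), yb] -= 1.0
            delta /= m
            grads_w = [None] * len(weights)
            grads_b = [None] * len(biases)
            for li in range(len(weights) - 1, -1, -1):
                grads_w[li] = acts[li].T @ delta
                grads_b[li] = delta.sum(axis=0)
                if li > 0:
                    delta = delta @ weights[li].T
                    if masks[li - 1] is not None:
                        delta = delta * masks[li - 1]
                    delta = delta * (acts[li] > 0)
            # Adam update
            step += 1
            corr1 = 1.0 - beta1**step
            corr2 = 1.0 - beta2**step
            for li in range(len(weights)):
                mw[li] = beta1 * mw[li] + (1 - beta1) * grads_w[li]
                vw[li] = beta2 * vw[li] + (1 - beta2) * grads_w[li] ** 2
                weights[li] -= config.learning_rate * (mw[li] / corr1) / (
                    np.sqrt(vw[li] / corr2) + eps
                )
                mb[li] = beta1 * mb[li] + (1 - beta1) * grads_b[li]
                vb[li] = beta2 * vb[li] + (1 - beta2) * grads_b[li] ** 2
                biases[li] -= config.learning_rate * (mb[li] / corr1) / (
                    np.sqrt(vb[li] / corr2) + eps
                )
        probs_all = model.predict_proba(X)
        ll = -np.log(np.maximum(probs_all[np.arange(n), labels], 1e-300))
        model.loss_trajectory.append(float(ll.mean()))
    return model


def predict(
    model: TrainedModel,
    pair: DDIPair | tuple[str, str],
    reduced: ReducedProfiles,
    threshold: float | None = None,
) -> PredictionResult:
    """Assign the argmax interaction type, abstaining below the threshold.

    Argmax ties break toward the lowest type index. The confidence (winning
    probability) is reported whether or not the model abstains.
    """
    tau = model.config.decision_threshold if threshold is None else threshold
    a, b = (pair.drug_a, pair.drug_b) if isinstance(pair, DDIPair) else pair
    probs = model.predict_proba(pair_features((a, b), reduced))[0]
    best = int(np.argmax(probs))
    conf = float(probs[best])
    return PredictionResult(
        drug_a=a,
        drug_b=b,
        predicted_type=best + 1 if conf >= tau else None,
        confidence=conf,
    )


def predict_batch(
    model: TrainedModel,
    pairs: Sequence[DDIPair | tuple[str, str]],
    reduced: ReducedProfiles,
    threshold: float | None = None,
) -> list[PredictionResult]:
    tau = model.config.decision_threshold if threshold is None else threshold
    ab = [
        (p.drug_a, p.drug_b) if isinstance(p, DDIPair) else tuple(p) for p in pairs
    ]
    if not ab:
        return []
    X = np.vstack([pair_features(p, reduced) for p in ab])
    probs = model.predict_proba(X)
    best = np.argmax(probs, axis=1)
    out = []
    for (a, b), k, row in zip(ab, best, probs):
        conf = float(row[k])
        out.append(
            PredictionResult(a, b, int(k) + 1 if conf >= tau else None, conf)
        )
    return out


# --------------------------------------------------------------------------
# checkpointing


def save_checkpoint(
    model: TrainedModel, reduced: ReducedProfiles, path: str | Path
) -> None:
    """Single-archive checkpoint: weights, config, PCA bases and coordinates."""
    arrays: dict[str, np.ndarray] = {}
    for i, (W, b) in enumerate(zip(model.weights, model.biases)):
        arrays[f"W{i}"] = W
        arrays[f"b{i}"] = b
    arrays["ssp_components"] = reduced.ssp_components
    arrays["psp_components"] = reduced.psp_components
    arrays["ssp_basis"] = reduced.ssp_basis
    arrays["psp_basis"] = reduced.psp_basis
    arrays["ssp_mean"] = reduced.ssp_mean
    arrays["psp_mean"] = reduced.psp_mean
    meta = {
        "config": asdict(model.config),
        "drug_ids": reduced.drug_ids,
        "n_layers": len(model.weights),
        "loss_trajectory": model.loss_trajectory,
    }
    arrays["meta_json"] = np.frombuffer(
        json.dumps(meta).encode("utf-8"), dtype=np.uint8
    )
    np.savez_compressed(path, **arrays)


def load_checkpoint(path: str | Path) -> tuple[TrainedModel, ReducedProfiles]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta_json"]).decode("utf-8"))
        n_layers = meta["n_layers"]
        model = TrainedModel(
            config=ModelConfig(**meta["config"]),
            weights=[data[f"W{i}"] for i in range(n_layers)],
            biases=[data[f"b{i}"] for i in range(n_layers)],
            loss_trajectory=list(meta["loss_trajectory"]),
        )
        reduced = ReducedProfiles(
            drug_ids=list(meta["drug_ids"]),
            ssp_components=data["ssp_components"],
            psp_components=data["psp_components"],
            ssp_basis=data["ssp_basis"],
            psp_basis=data["psp_basis"],
            ssp_mean=data["ssp_mean"],
            psp_mean=data["psp_mean"],
        )
    return model, reduced
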