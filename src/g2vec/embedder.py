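"""The modified CBOW model producing distributed gene representations.

A path is encoded as a multi-hot gene vector of length N.  The model is
a linear projection W (N x M, no bias, no activation) followed by a
single sigmoid output unit predicting whether the path came from the
poor-prognosis network.  It is trained with binary cross-entropy and
Adam, with early stopping on validation loss.  The trained rows of W
are the gene representations; a gene that appears in no training path
receives zero gradient throughout and so keeps its random initial row
exactly — the central "untrained" cluster.

The model is small enough (N*M + M + 1 parameters) that the forward and
backward passes are plain numpy matrix products; training a corpus of a
few thousand paths takes seconds on one CPU.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .walker import PathCorpus, encode_corpus

logger = logging.getLogger(__name__)


class DegenerateLabelsError(ValueError):
    """Raised when the corpus contains only one path label."""


@dataclass
class ModelConfig:
    projection_size: int = 128  # M
    learning_rate: float = 0.005
    max_epochs: int = 30
    early_stopping_patience: int = 3
    batch_size: int = 64
    init_scale: float = 0.01
    seed: int = 0


@dataclass
class EmbeddingMatrix:
    """N x M trained input-to-projection weights, one row per gene."""

    weights: np.ndarray
    gene_index: dict[str, int]
    trained_mask: np.ndarray  # True where the gene occurred in >= 1 training path

    @property
    def n_genes(self) -> int:
        return self.weights.shape[0]

    @property
    def projection_size(self) -> int:
        return self.weights.shape[1]

    def vector(self, gene: str) -> np.ndarray:
        return self.weights[self.gene_index[gene]]


@dataclass
class ModelState:
    W: np.ndarray  # N x M input-to-projection
    V: np.ndarray  # M projection-to-output
    b: float  # output bias
    config: ModelConfig
    # Adam moments
    mW: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    vW: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    mV: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    vV: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    mb: float = 0.0
    vb: float = 0.0
    t: int = 0

    def __post_init__(self) -> None:
        if self.mW is None:
            self.mW = np.zeros_like(self.W)
            self.vW = np.zeros_like(self.W)
            self.mV = np.zeros_like(self.V)
            self.vV = np.zeros_like(self.V)


def init_model(n_genes: int, config: ModelConfig) -> ModelState:
    """Zero-mean Gaussian initialization at scale ``init_scale``, seeded."""
    if n_genes < 1:
        raise ValueError("need at least one gene")
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    W = rng.normal(0.0, config.init_scale, size=(n_genes, config.projection_size))
    V = rng.normal(0.0, config.init_scale, size=config.projection_size)
    return ModelState(W=W, V=V, b=0.0, config=config)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _forward(state: ModelState, X: np.ndarray) -> np.ndarray:
    return _sigmoid(X @ state.W @ state.V + state.b)


def _bce(p: np.ndarray, y: np.ndarray) -> float:
    eps = 1e-12
    p = np.clip(p, eps, 1.0 - eps)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


_BETA1, _BETA2, _ADAM_EPS = 0.9, 0.999, 1e-8


def _adam_step(state: ModelState, gW: np.ndarray, gV: np.ndarray, gb: float) -> None:
    cfg = state.config
    state.t += 1
    c1 = 1.0 - _BETA1 ** state.t
    c2 = 1.0 - _BETA2 ** state.t

    state.mW = _BETA1 * state.mW + (1.0 - _BETA1) * gW
    state.vW = _BETA2 * state.vW + (1.0 - _BETA2) * gW * gW
    state.W -= cfg.learning_rate * (state.mW / c1) / (np.sqrt(state.vW / c2) + _ADAM_EPS)

    state.mV = _BETA1 * state.mV + (1.0 - _BETA1) * gV
    state.vV = _BETA2 * state.vV + (1.0 - _BETA2) * gV * gV
    state.V -= cfg.learning_rate * (state.mV / c1) / (np.sqrt(state.vV / c2) + _ADAM_EPS)

    state.mb = _BETA1 * state.mb + (1.0 - _BETA1) * gb
    state.vb = _BETA2 * state.vb + (1.0 - _BETA2) * gb * gb
    state.b -= cfg.learning_rate * (state.mb / c1) / (np.sqrt(state.vb / c2) + _ADAM_EPS)


def fit_path_classifier(
    corpus: PathCorpus, config: ModelConfig
) -> tuple[ModelState, np.ndarray, list[dict]]:
    """Train the path-origin classifier; return state, trained mask and log.

    Stops at ``max_epochs`` or when validation loss fails to improve for
    ``early_stopping_patience`` consecutive epochs, restoring the
    weights of the best validation epoch.
    """
    gene_index = corpus.gene_index
    n_genes = len(gene_index)
    X_train, y_train = encode_corpus(corpus.train, gene_index)
    X_val, y_val = encode_corpus(corpus.validation, gene_index)
    for name, y in (("train", y_train), ("validation", y_val)):
        if len(np.unique(y)) < 2:
            raise DegenerateLabelsError(f"{name} corpus has a single path label")

    state = init_model(n_genes, config)
    init_W = state.W.copy()
    trained_mask = X_train.any(axis=0)

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n = len(y_train)
    best_val = np.inf
    best_W, best_V, best_b = state.W.copy(), state.V.copy(), state.b
    patience_left = config.early_stopping_patience
    log: list[dict] = []
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            Xb, yb = X_train[idx], y_train[idx]
            h = Xb @ state.W
            p = _sigmoid(h @ state.V + state.b)
            # BCE + sigmoid: dL/dlogit = (p - y) / batch
            delta = (p - yb) / len(yb)
            gV = h.T @ delta
            gb = float(delta.sum())
            gW = Xb.T @ np.outer(delta, state.V)
            _adam_step(state, gW, gV, gb)
        train_loss = _bce(_forward(state, X_train), y_train)
        val_loss = _bce(_forward(state, X_val), y_val)
        log.append({"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss})
        if val_loss < best_val:
            best_val = val_loss
            best_W, best_V, best_b = state.W.copy(), state.V.copy(), state.b
            patience_left = config.early_stopping_patience
        else:
            patience_left -= 1
            if patience_left == 0:
                logger.info("early stopping at epoch %d (best val %.4f)", epoch, best_val)
                break
    state.W, state.V, state.b = best_W, best_V, best_b

    # genes outside every training path receive zero gradient; their Adam
    # moments stay zero, so the rows must still equal the initialization
    assert np.array_equal(state.W[~trained_mask], init_W[~trained_mask])
    return state, trained_mask, log


def train_cbow(
    corpus: PathCorpus, config: ModelConfig
) -> tuple[EmbeddingMatrix, list[dict]]:
    """Train the modified CBOW and extract gene representations (rows of W)."""
    state, trained_mask, log = fit_path_classifier(corpus, config)
    emb = EmbeddingMatrix(
        weights=state.W, gene_index=dict(corpus.gene_index), trained_mask=trained_mask
    )
    return emb, log


def predict_path_origin(state: ModelState, encoded: np.ndarray) -> float:
    """Probability that an encoded path came from the poor network."""
    encoded = np.asarray(encoded, dtype=float)
    if encoded.shape != (state.W.shape[0],):
        raise ValueError(
            f"encoded path has shape {encoded.shape}, expected ({state.W.shape[0]},)"
        )
    return float(_forward(state, encoded[None, :])[0])


def write_embeddings(path: str, emb: EmbeddingMatrix) -> None:
    """TSV: gene id, trained flag, M weight columns."""
    genes = sorted(emb.gene_index, key=emb.gene_index.get)
    with open(path, "w") as fh:
        cols = "\t".join(f"w{j}" for j in range(emb.projection_size))
        fh.write(f"gene\ttrained\t{cols}\n")
        for g in genes:
            row = emb.weights[emb.gene_index[g]]
            flag = int(bool(emb.trained_mask[emb.gene_index[g]]))
            fh.write(f"{g}\t{flag}\t" + "\t".join(f"{v:.8g}" for v in row) + "\n")


def read_embeddings(path: str) -> EmbeddingMatrix:
    genes: list[str] = []
    flags: list[bool] = []
    rows: list[list[float]] = []
    with open(path) as fh:
        next(fh)  # header
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            genes.append(parts[0])
            flags.append(parts[1] == "1")
            rows.append([float(v) for v in parts[2:]])
    return EmbeddingMatrix(
        weights=np.array(rows),
        gene_index={g: i for i, g in enumerate(genes)},
        trained_mask=np.array(flags),
    )


def write_training_log(path: str, log: list[dict]) -> None:
    with open(path, "w") as fh:
        for rec in log:
            fh.write(json.dumps(rec) + "\n")
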