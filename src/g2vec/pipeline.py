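"""End-to-end biomarker selection on one training cohort.

Runs the full chain — group correlation networks, constrained random
walks, path-origin model training, K-means L-group detection, gene
scoring — and returns the selected panel together with every
intermediate artifact.  Cross-validation repeats this chain per fold on
training samples only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import corrnet, embedder, scorer, walker
from .datagen import GOOD, POOR, ExpressionDataset
from .embedder import EmbeddingMatrix, ModelConfig
from .scorer import BiomarkerSet
from .walker import PathCorpus, WalkConfig

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    threshold: float = corrnet.DEFAULT_THRESHOLD
    walk: WalkConfig = field(default_factory=WalkConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    k_clusters: int = 3
    per_group: int = 50


@dataclass
class SelectionResult:
    markers: BiomarkerSet
    diff_freq_markers: BiomarkerSet
    score_table: pd.DataFrame
    embeddings: EmbeddingMatrix
    corpus: PathCorpus
    frequencies: dict[str, tuple[int, int]]
    good_network: corrnet.CorrelationNetwork
    poor_network: corrnet.CorrelationNetwork
    training_log: list[dict]


def _derive_seeds(seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n)
    return [int(s % (2**31)) for s in state]


def select_markers(
    data: ExpressionDataset,
    reference_edges: list[tuple[str, str]],
    config: PipelineConfig,
    seed: int = 0,
) -> SelectionResult:
    """Select biomarkers from a (training) cohort.

    Only the samples in ``data`` enter correlation, walking, training
    and scoring, so callers can guarantee no leakage by passing the
    training portion of a fold.
    """
    walk_seed, model_seed, kmeans_seed = _derive_seeds(seed, 3)

    good_net = corrnet.build_correlation_network(
        data, GOOD, reference_edges, config.threshold
    )
    poor_net = corrnet.build_correlation_network(
        data, POOR, reference_edges, config.threshold
    )

    walk_cfg = WalkConfig(
        max_path_length=config.walk.max_path_length,
        walks_per_node=config.walk.walks_per_node,
        train_fraction=config.walk.train_fraction,
        seed=walk_seed,
    )
    corpus = walker.generate_corpus(good_net, poor_net, walk_cfg, data.gene_ids)
    freqs = walker.path_frequencies(corpus)

    model_cfg = ModelConfig(
        projection_size=config.model.projection_size,
        learning_rate=config.model.learning_rate,
        max_epochs=config.model.max_epochs,
        early_stopping_patience=config.model.early_stopping_patience,
        batch_size=config.model.batch_size,
        init_scale=config.model.init_scale,
        seed=model_seed,
    )
    emb, log = embedder.train_cbow(corpus, model_cfg)

    clusters = scorer.cluster_embeddings(emb, config.k_clusters, kmeans_seed)
    cluster_labels = scorer.assign_lgroups(clusters, emb, freqs)
    cluster_of = {
        g: cluster_labels[int(clusters[emb.gene_index[g]])] for g in data.gene_ids
    }

    labels = data.label_array
    d_scores = {g: scorer.d_score(emb.vector(g)) for g in data.gene_ids}
    t_scores = {
        g: scorer.t_score(data.matrix[i], labels)
        for i, g in enumerate(data.gene_ids)
        if cluster_of[g] != scorer.INITIAL
    }
    table = scorer.combine_scores(d_scores, t_scores, cluster_of)
    markers = scorer.select_biomarkers(table, config.per_group)
    diff_freq = scorer.diff_freq_select(freqs, config.per_group)
    return SelectionResult(
        markers=markers,
        diff_freq_markers=diff_freq,
        score_table=table,
        embeddings=emb,
        corpus=corpus,
        frequencies=freqs,
        good_network=good_net,
        poor_network=poor_net,
        training_log=log,
    )
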