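"""Constrained random walks and the labeled path corpus.

Walks obey three constraints: a node is never revisited, the next node
is drawn among unvisited neighbors with probability proportional to
edge weight, and the walk stops at a dead end or at a maximum number of
nodes (default 80).  Ten walks depart from every node of each
prognosis network; a path sequence generated under both labels is
removed from both, and the survivors are split 80/20 into training and
validation corpora.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .corrnet import CorrelationNetwork
from .datagen import GOOD, POOR, InvalidInputError

logger = logging.getLogger(__name__)


class EmptyNetworkError(ValueError):
    pass


@dataclass
class WalkConfig:
    max_path_length: int = 80  # counted in nodes
    walks_per_node: int = 10
    train_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_path_length < 1:
            raise InvalidInputError("max_path_length must be >= 1")
        if self.walks_per_node < 1:
            raise InvalidInputError("walks_per_node must be >= 1")
        if not 0.0 < self.train_fraction < 1.0:
            raise InvalidInputError("train_fraction must lie in (0, 1)")


@dataclass(frozen=True)
class Path:
    genes: tuple[str, ...]
    label: str  # good | poor


@dataclass
class PathCorpus:
    train: list[Path]
    validation: list[Path]
    gene_index: dict[str, int]

    @property
    def all_paths(self) -> list[Path]:
        return self.train + self.validation


def random_walk(
    network: CorrelationNetwork,
    start: str,
    config: WalkConfig,
    rng: np.random.Generator,
) -> Path:
    """One weight-proportional, non-revisiting walk from ``start``."""
    if start not in set(network.nodes):
        raise InvalidInputError(f"start node {start!r} not in network")
    path = [start]
    visited = {start}
    while len(path) < config.max_path_length:
        options = [(g, w) for g, w in network.neighbors(path[-1]) if g not in visited]
        if not options:
            break  # dead end
        weights = np.array([w for _, w in options], dtype=float)
        total = weights.sum()
        if total <= 0.0:
            break
        idx = int(rng.choice(len(options), p=weights / total))
        nxt = options[idx][0]
        path.append(nxt)
        visited.add(nxt)
    return Path(genes=tuple(path), label=network.group)


def _walk_network(
    network: CorrelationNetwork, config: WalkConfig, rng: np.random.Generator
) -> list[Path]:
    paths = []
    for node in network.nodes:
        for _ in range(config.walks_per_node):
            paths.append(random_walk(network, node, config, rng))
    return paths


def deduplicate(paths: list[Path]) -> list[Path]:
    """Drop every path whose ordered gene sequence occurs under both labels.

    Duplicates within one label are kept; only cross-label redundancy is
    removed, and it is removed from both sides.
    """
    labels_of: dict[tuple[str, ...], set[str]] = {}
    for p in paths:
        labels_of.setdefault(p.genes, set()).add(p.label)
    kept = [p for p in paths if len(labels_of[p.genes]) == 1]
    n_removed = len(paths) - len(kept)
    if n_removed:
        logger.info("removed %d cross-label redundant paths", n_removed)
    return kept


def _stratified_split(
    paths: list[Path], train_fraction: float, rng: np.random.Generator
) -> tuple[list[Path], list[Path]]:
    train: list[Path] = []
    val: list[Path] = []
    for label in (GOOD, POOR):
        group = [p for p in paths if p.label == label]
        order = rng.permutation(len(group))
        n_train = int(round(train_fraction * len(group)))
        chosen = set(order[:n_train].tolist())
        for i, p in enumerate(group):
            (train if i in chosen else val).append(p)
    return train, val


def generate_corpus(
    good_net: CorrelationNetwork,
    poor_net: CorrelationNetwork,
    config: WalkConfig,
    gene_ids: list[str],
) -> PathCorpus:
    """Walk both networks, deduplicate across labels, split train/validation.

    ``gene_ids`` is the full gene list of the expression dataset; the
    corpus ``gene_index`` covers all of it, including never-walked genes.
    """
    for net in (good_net, poor_net):
        if not net.nodes:
            raise EmptyNetworkError(f"{net.group} network has no nodes")
    ss = np.random.SeedSequence(config.seed)
    rng_good, rng_poor, rng_split = (np.random.default_rng(c) for c in ss.spawn(3))
    paths = _walk_network(good_net, config, rng_good)
    paths += _walk_network(poor_net, config, rng_poor)
    logger.info("collected %d walks before deduplication", len(paths))
    paths = deduplicate(paths)
    logger.info("corpus size after deduplication: %d paths", len(paths))
    train, val = _stratified_split(paths, config.train_fraction, rng_split)
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    return PathCorpus(train=train, validation=val, gene_index=gene_index)


def encode(path: Path, gene_index: dict[str, int]) -> np.ndarray:
    """Multi-hot vector over the gene index: 1 where the gene is on the path."""
    vec = np.zeros(len(gene_index), dtype=float)
    for g in path.genes:
        if g not in gene_index:
            raise KeyError(f"gene {g!r} missing from gene index")
        vec[gene_index[g]] = 1.0
    return vec


def encode_corpus(paths: list[Path], gene_index: dict[str, int]) -> tuple[np.ndarray, np.ndarray]:
    """Stack multi-hot encodings; labels are 1 for poor, 0 for good."""
    X = np.zeros((len(paths), len(gene_index)), dtype=float)
    y = np.zeros(len(paths), dtype=float)
    for i, p in enumerate(paths):
        for g in p.genes:
            X[i, gene_index[g]] = 1.0
        y[i] = 1.0 if p.label == POOR else 0.0
    return X, y


def path_frequencies(corpus: PathCorpus) -> dict[str, tuple[int, int]]:
    """Per gene: number of (good, poor) paths containing it, over the whole corpus."""
    good_counts: Counter[str] = Counter()
    poor_counts: Counter[str] = Counter()
    for p in corpus.all_paths:
        target = good_counts if p.label == GOOD else poor_counts
        for g in set(p.genes):
            target[g] += 1
    return {
        g: (good_counts.get(g, 0), poor_counts.get(g, 0))
        for g in corpus.gene_index
    }


def write_corpus(path: str, corpus: PathCorpus) -> None:
    """One path per line: split, label, comma-separated gene ids (tab-separated)."""
    with open(path, "w") as fh:
        for split, paths in (("train", corpus.train), ("validation", corpus.validation)):
            for p in paths:
                fh.write(f"{split}\t{p.label}\t{','.join(p.genes)}\n")


def read_corpus(path: str, gene_ids: list[str]) -> PathCorpus:
    train: list[Path] = []
    val: list[Path] = []
    with open(path) as fh:
        for line in fh:
            split, label, genes = line.rstrip("\n").split("\t")
            p = Path(genes=tuple(genes.split(",")), label=label)
            (train if split == "train" else val).append(p)
    return PathCorpus(train=train, validation=val,
                      gene_index={g: i for i, g in enumerate(gene_ids)})
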