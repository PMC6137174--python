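"""Prognosis-group correlation networks.

A reference gene-interaction network is re-weighted per prognosis group:
each edge gets the absolute Pearson correlation of its endpoint genes'
expression over that group's samples, and edges below a threshold
(default 0.5) are discarded.  Nodes are every measured gene incident to
a reference edge; a node may end up with no retained edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .datagen import ExpressionDataset, InvalidInputError

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.5


class InsufficientDataError(ValueError):
    """Raised when a group has too few samples for a correlation."""


@dataclass
class CorrelationNetwork:
    """Weighted undirected graph for one prognosis group.

    ``edges`` maps an unordered gene pair (stored sorted) to its |PCC|
    weight; ``nodes`` includes genes whose every edge fell below the
    threshold, so walks can still depart from them.
    """

    group: str
    nodes: list[str]
    edges: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._adj: dict[str, list[tuple[str, float]]] | None = None

    def neighbors(self, gene: str) -> list[tuple[str, float]]:
        if self._adj is None:
            adj: dict[str, list[tuple[str, float]]] = {g: [] for g in self.nodes}
            for (a, b), w in self.edges.items():
                adj[a].append((b, w))
                adj[b].append((a, w))
            for g in adj:
                adj[g].sort()
            self._adj = adj
        return self._adj[gene]

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def pearson_weight(x: np.ndarray, y: np.ndarray) -> float:
    """|Pearson r| of two equal-length vectors; 0 if either is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InvalidInputError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.ndim != 1 or len(x) < 3:
        raise InvalidInputError("need 1-D vectors of length >= 3")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt((xc * xc).sum())
    sy = np.sqrt((yc * yc).sum())
    if sx == 0.0 or sy == 0.0:
        return 0.0
    return float(abs((xc * yc).sum() / (sx * sy)))


def build_correlation_network(
    data: ExpressionDataset,
    group: str,
    reference_edges: list[tuple[str, str]],
    threshold: float = DEFAULT_THRESHOLD,
) -> CorrelationNetwork:
    """Weight reference edges by |PCC| over one group's samples and threshold.

    Edges with weight strictly below ``threshold`` are removed (a weight
    exactly equal to the threshold is retained).  Reference edges
    touching genes absent from the expression matrix are dropped with a
    logged count.
    """
    if not reference_edges:
        raise InvalidInputError("reference edge list is empty")
    cols = data.group_columns(group)
    if cols.shape[1] < 3:
        raise InsufficientDataError(
            f"group {group!r} has {cols.shape[1]} samples; need >= 3"
        )
    gene_pos = {g: i for i, g in enumerate(data.gene_ids)}

    # standardize rows once; per-edge |PCC| is then a dot product
    centered = cols - cols.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered * centered).sum(axis=1))
    safe = norms.copy()
    safe[safe == 0.0] = 1.0
    standardized = centered / safe[:, None]

    measured_nodes: set[str] = set()
    edges: dict[tuple[str, str], float] = {}
    n_unmeasured = 0
    for a, b in reference_edges:
        ia = gene_pos.get(a)
        ib = gene_pos.get(b)
        if ia is None or ib is None:
            n_unmeasured += 1
            continue
        measured_nodes.add(a)
        measured_nodes.add(b)
        if norms[ia] == 0.0 or norms[ib] == 0.0:
            continue  # constant gene: weight 0, below any positive threshold
        w = float(abs(standardized[ia] @ standardized[ib]))
        if w >= threshold:
            key = (a, b) if a <= b else (b, a)
            edges[key] = min(w, 1.0)
    if n_unmeasured:
        logger.info(
            "dropped %d reference edges touching unmeasured genes", n_unmeasured
        )
    logger.info(
        "%s network: %d nodes, %d edges retained at threshold %.2f",
        group, len(measured_nodes), len(edges), threshold,
    )
    return CorrelationNetwork(group=group, nodes=sorted(measured_nodes), edges=edges)


def write_correlation_network(path: str, net: CorrelationNetwork) -> None:
    """Three-column weighted edge list, weights to 6 decimal places."""
    with open(path, "w") as fh:
        for (a, b), w in sorted(net.edges.items()):
            fh.write(f"{a}\t{b}\t{w:.6f}\n")
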