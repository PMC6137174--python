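"""Gene scoring and biomarker panel selection.

Gene vectors are clustered with K-means (K=3) into the central cluster
of untrained initial vectors and two "L-groups" that separate from it.
Each L-group is tied to the good or poor prognosis class by the path
frequencies of its member genes.  A gene score is the mean of two
min-max normalized components: the d-score (Euclidean distance of the
gene vector from the origin, the center of the initial vectors) and the
t-score (absolute Welch t-statistic of the gene's expression between
good and poor samples).  The 50 highest-scoring genes of each L-group
form the biomarker panel.  A frequency-difference baseline (Diff-Freq)
is included for comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .datagen import GOOD, POOR, ExpressionDataset, InvalidInputError
from .embedder import EmbeddingMatrix

logger = logging.getLogger(__name__)

INITIAL = "initial"
NONE = "none"


class InsufficientDataError(ValueError):
    pass


class SelectionError(ValueError):
    pass


@dataclass
class BiomarkerSet:
    good_markers: list[str]
    poor_markers: list[str]

    @property
    def combined(self) -> list[str]:
        return self.good_markers + self.poor_markers


def cluster_embeddings(
    emb: EmbeddingMatrix, k: int = 3, seed: int = 0
) -> np.ndarray:
    """K-means partition of the N gene vectors; deterministic given seed."""
    n = emb.n_genes
    if n < k:
        raise InvalidInputError(f"{n} genes cannot form {k} clusters")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    return km.fit_predict(emb.weights)


def assign_lgroups(
    clusters: np.ndarray,
    emb: EmbeddingMatrix,
    freqs: dict[str, tuple[int, int]],
) -> dict[int, str]:
    """Map the three cluster ids to {initial, good, poor}.

    The initial cluster holds the most untrained genes (ties go to the
    centroid nearest the origin).  The remaining two are labeled by the
    majority dominant-frequency label of their members; a gene whose
    good and poor path counts tie abstains.  If both clusters vote the
    same way, the one with the stronger majority keeps that label.
    """
    ids = sorted(set(int(c) for c in clusters))
    if len(ids) != 3:
        raise InvalidInputError(f"expected 3 clusters, got {len(ids)}")
    if not emb.trained_mask.any():
        raise SelectionError("all genes are untrained; no signal to assign L-groups")

    untrained_counts = {
        c: int((~emb.trained_mask[clusters == c]).sum()) for c in ids
    }
    top = max(untrained_counts.values())
    tied = [c for c in ids if untrained_counts[c] == top]
    if len(tied) == 1:
        initial_cluster = tied[0]
    else:  # tie: centroid nearest the zero vector
        norms = {
            c: float(np.linalg.norm(emb.weights[clusters == c].mean(axis=0)))
            for c in tied
        }
        initial_cluster = min(tied, key=lambda c: (norms[c], c))

    genes = sorted(emb.gene_index, key=emb.gene_index.get)
    rest = [c for c in ids if c != initial_cluster]
    votes: dict[int, dict[str, int]] = {c: {GOOD: 0, POOR: 0} for c in rest}
    for g in genes:
        c = int(clusters[emb.gene_index[g]])
        if c == initial_cluster:
            continue
        good_n, poor_n = freqs.get(g, (0, 0))
        if good_n > poor_n:
            votes[c][GOOD] += 1
        elif poor_n > good_n:
            votes[c][POOR] += 1
        # tie: abstain

    def majority(c: int) -> str | None:
        v = votes[c]
        if v[GOOD] > v[POOR]:
            return GOOD
        if v[POOR] > v[GOOD]:
            return POOR
        return None

    def proportion(c: int, label: str) -> float:
        total = votes[c][GOOD] + votes[c][POOR]
        return votes[c][label] / total if total else 0.0

    a, b = rest
    lab_a, lab_b = majority(a), majority(b)
    if lab_a is not None and lab_a == lab_b:
        # both vote the same label: stronger proportion wins it
        winner = a if proportion(a, lab_a) >= proportion(b, lab_b) else b
        loser = b if winner == a else a
        assignment = {winner: lab_a, loser: (POOR if lab_a == GOOD else GOOD)}
    else:
        assignment = {}
        if lab_a is not None:
            assignment[a] = lab_a
        if lab_b is not None:
            assignment[b] = lab_b
        if a not in assignment and b in assignment:
            assignment[a] = POOR if assignment[b] == GOOD else GOOD
        elif b not in assignment and a in assignment:
            assignment[b] = POOR if assignment[a] == GOOD else GOOD
        elif not assignment:  # both abstain entirely: deterministic fallback
            assignment = {min(a, b): GOOD, max(a, b): POOR}
    assignment[initial_cluster] = INITIAL
    return assignment


def d_score(vector: np.ndarray) -> float:
    """Euclidean distance from the origin (center of the initial vectors)."""
    return float(np.linalg.norm(np.asarray(vector, dtype=float)))


def t_score(expression: np.ndarray, labels: np.ndarray) -> float:
    """|Welch t| comparing a gene's expression between good and poor samples."""
    expression = np.asarray(expression, dtype=float)
    labels = np.asarray(labels)
    good = expression[labels == GOOD]
    poor = expression[labels == POOR]
    if len(good) < 2 or len(poor) < 2:
        raise InsufficientDataError(
            f"need >= 2 samples per class, got {len(good)} good / {len(poor)} poor"
        )
    t, _ = stats.ttest_ind(good, poor, equal_var=False)
    if np.isnan(t):  # zero variance in both groups
        return 0.0 if good.mean() == poor.mean() else float("inf")
    return float(abs(t))


def _min_max(values: np.ndarray) -> np.ndarray:
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.zeros_like(values)  # degenerate: all equal -> all zeros
    return (values - lo) / (hi - lo)


def combine_scores(
    d_scores: dict[str, float],
    t_scores: dict[str, float],
    cluster_of: dict[str, str],
) -> pd.DataFrame:
    """Build the per-gene score table.

    ``cluster_of`` maps each gene to {initial, good, poor}.  Min-max
    normalization runs over the scored set — the union of the two
    L-groups; initial-cluster genes get zero scores and are never
    selected.
    """
    genes = sorted(cluster_of)
    scored = [g for g in genes if cluster_of[g] != INITIAL]
    if not scored:
        raise SelectionError("no genes outside the initial cluster")
    d = np.array([d_scores[g] for g in scored])
    t = np.array([t_scores[g] for g in scored])
    d_norm = dict(zip(scored, _min_max(d)))
    t_norm = dict(zip(scored, _min_max(t)))

    rows = []
    for g in genes:
        lg = cluster_of[g]
        if lg == INITIAL:
            rows.append((g, INITIAL, NONE, d_scores.get(g, 0.0), t_scores.get(g, 0.0),
                         0.0, 0.0, 0.0))
        else:
            dn, tn = d_norm[g], t_norm[g]
            rows.append((g, "L1" if lg == GOOD else "L2", lg,
                         d_scores[g], t_scores[g], dn, tn, (dn + tn) / 2.0))
    return pd.DataFrame(
        rows,
        columns=["gene", "cluster", "lgroup", "d_score", "t_score",
                 "d_norm", "t_norm", "gene_score"],
    ).set_index("gene")


def select_biomarkers(table: pd.DataFrame, per_group: int = 50) -> BiomarkerSet:
    """Top ``per_group`` genes per L-group by gene score.

    Ties break by higher t-score, then lexicographic gene id.  An
    L-group smaller than ``per_group`` contributes all its members with
    a logged warning.
    """
    panels: dict[str, list[str]] = {}
    for label in (GOOD, POOR):
        members = table[table["lgroup"] == label]
        if members.empty:
            raise SelectionError(f"the {label} L-group is empty")
        # mergesort is stable; pre-sorting by gene id gives the final tie level
        ordered = members.sort_index().sort_values(
            by=["gene_score", "t_score"], ascending=[False, False], kind="mergesort"
        )
        if len(ordered) < per_group:
            logger.warning(
                "%s L-group has only %d genes (< %d requested)",
                label, len(ordered), per_group,
            )
        panels[label] = list(ordered.index[:per_group])
    return BiomarkerSet(good_markers=panels[GOOD], poor_markers=panels[POOR])


def diff_freq_select(
    freqs: dict[str, tuple[int, int]], per_group: int = 50
) -> BiomarkerSet:
    """Baseline: select by path-occurrence frequency difference.

    The good panel takes the genes with the largest positive
    good-minus-poor count differences, the poor panel the most negative;
    ties break by gene id, and the panels stay disjoint.
    """
    if not freqs:
        raise InvalidInputError("frequency table is empty")
    diffs = {g: c[0] - c[1] for g, c in freqs.items()}
    if len(set(diffs.values())) == 1:
        logger.warning("all frequency differences equal; panels follow tie-break order")
    by_desc = sorted(diffs, key=lambda g: (-diffs[g], g))
    good_panel = by_desc[:per_group]
    taken = set(good_panel)
    by_asc = sorted(diffs, key=lambda g: (diffs[g], g))
    poor_panel = [g for g in by_asc if g not in taken][:per_group]
    return BiomarkerSet(good_markers=good_panel, poor_markers=poor_panel)


def write_score_table(path: str, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", float_format="%.6g")


def write_biomarkers(path: str, markers: BiomarkerSet) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tpanel\n")
        for g in markers.good_markers:
            fh.write(f"{g}\tgood\n")
        for g in markers.poor_markers:
            fh.write(f"{g}\tpoor\n")
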