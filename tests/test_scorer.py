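import math

import numpy as np
import pandas as pd
import pytest

from g2vec.datagen import GOOD, POOR, InvalidInputError
from g2vec.embedder import EmbeddingMatrix
from g2vec.scorer import (
    INITIAL,
    InsufficientDataError,
    SelectionError,
    assign_lgroups,
    cluster_embeddings,
    combine_scores,
    d_score,
    diff_freq_select,
    select_biomarkers,
    t_score,
)


def _embedding(weights, trained=None):
    weights = np.asarray(weights, dtype=float)
    n = weights.shape[0]
    if trained is None:
        trained = np.ones(n, dtype=bool)
    return EmbeddingMatrix(
        weights=weights,
        gene_index={f"g{i}": i for i in range(n)},
        trained_mask=np.asarray(trained, dtype=bool),
    )


class TestClusterEmbeddings:
    def test_recovers_separated_blobs(self):
        rng = np.random.default_rng(0)
        blobs = np.vstack([
            rng.normal(0, 0.05, size=(30, 4)),
            rng.normal(0, 0.05, size=(30, 4)) + [10, 0, 0, 0],
            rng.normal(0, 0.05, size=(30, 4)) + [0, 10, 0, 0],
        ])
        clusters = cluster_embeddings(_embedding(blobs), 3, seed=1)
        for block in (clusters[:30], clusters[30:60], clusters[60:]):
            assert len(set(block)) == 1
        assert len({clusters[0], clusters[30], clusters[60]}) == 3

    def test_deterministic(self):
        rng = np.random.default_rng(2)
        emb = _embedding(rng.normal(size=(50, 8)))
        a = cluster_embeddings(emb, 3, seed=9)
        b = cluster_embeddings(emb, 3, seed=9)
        assert np.array_equal(a, b)

    def test_k_exceeding_n_rejected(self):
        with pytest.raises(InvalidInputError):
            cluster_embeddings(_embedding(np.zeros((2, 3))), 3, seed=0)


class TestAssignLgroups:
    def _setup(self):
        # 9 genes: g0-2 untrained near origin, g3-5 good-heavy, g6-8 poor-heavy
        weights = np.vstack([
            np.full((3, 2), 0.01),
            np.full((3, 2), 5.0),
            np.full((3, 2), -5.0),
        ])
        trained = [False] * 3 + [True] * 6
        clusters = np.array([0, 0, 0, 1, 1, 1, 2, 2, 2])
        emb = _embedding(weights, trained)
        freqs = {f"g{i}": (0, 0) for i in range(3)}
        freqs.update({f"g{i}": (10, 2) for i in range(3, 6)})
        freqs.update({f"g{i}": (1, 8) for i in range(6, 9)})
        return clusters, emb, freqs

    def test_majority_vote(self):
        clusters, emb, freqs = self._setup()
        labels = assign_lgroups(clusters, emb, freqs)
        assert labels == {0: INITIAL, 1: GOOD, 2: POOR}

    def test_abstention_does_not_block_decision(self):
        clusters, emb, freqs = self._setup()
        freqs["g3"] = (5, 5)  # tie: abstains, remaining majority decides
        labels = assign_lgroups(clusters, emb, freqs)
        assert labels[1] == GOOD and labels[2] == POOR

    def test_same_vote_resolved_by_proportion(self):
        clusters, emb, freqs = self._setup()
        # cluster 2 also leans good, but weakly (2 good vs 1 poor voters)
        freqs.update({"g6": (9, 1), "g7": (6, 2), "g8": (1, 7)})
        labels = assign_lgroups(clusters, emb, freqs)
        assert labels[1] == GOOD and labels[2] == POOR

    def test_all_untrained_rejected(self):
        clusters, emb, freqs = self._setup()
        emb.trained_mask[:] = False
        with pytest.raises(SelectionError):
            assign_lgroups(clusters, emb, freqs)


class TestScores:
    @pytest.mark.parametrize(
        "vec,expected",
        [
            (np.zeros(4), 0.0),
            (np.array([3.0, 4.0]), 5.0),
            (np.ones(128), math.sqrt(128)),
        ],
    )
    def test_d_score(self, vec, expected):
        assert d_score(vec) == pytest.approx(expected)

    def test_t_score_symmetric_groups(self):
        expr = np.array([1.0, 2, 3, 1, 2, 3])
        labels = np.array([GOOD] * 3 + [POOR] * 3)
        assert t_score(expr, labels) == pytest.approx(0.0)

    def test_t_score_known_value(self):
        # good=[1,2,3], poor=[4,5,6]: Welch t = -3 / sqrt(2/3)
        expr = np.array([1.0, 2, 3, 4, 5, 6])
        labels = np.array([GOOD] * 3 + [POOR] * 3)
        assert t_score(expr, labels) == pytest.approx(3.0 / math.sqrt(2.0 / 3.0))

    def test_t_score_matches_brute_force_welch(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            n1, n2 = int(rng.integers(2, 30)), int(rng.integers(2, 30))
            a, b = rng.normal(size=n1), rng.normal(2, 1.5, size=n2)
            expr = np.concatenate([a, b])
            labels = np.array([GOOD] * n1 + [POOR] * n2)
            # Welch statistic from first principles
            se = math.sqrt(a.var(ddof=1) / n1 + b.var(ddof=1) / n2)
            expected = abs((a.mean() - b.mean()) / se)
            assert t_score(expr, labels) == pytest.approx(expected, abs=1e-10)

    def test_t_score_label_swap_invariant(self):
        expr = np.array([1.0, 5, 2, 8, 3, 9])
        labels = np.array([GOOD, POOR] * 3)
        swapped = np.where(labels == GOOD, POOR, GOOD)
        assert t_score(expr, labels) == pytest.approx(t_score(expr, swapped))

    def test_t_score_small_class_rejected(self):
        expr = np.array([1.0, 2, 3])
        labels = np.array([GOOD, POOR, POOR])
        with pytest.raises(InsufficientDataError):
            t_score(expr, labels)


class TestCombineScores:
    def test_min_max_normalization(self):
        cluster_of = {"g0": GOOD, "g1": GOOD, "g2": POOR, "gI": INITIAL}
        d = {"g0": 2.0, "g1": 4.0, "g2": 6.0, "gI": 0.1}
        t = {"g0": 1.0, "g1": 1.0, "g2": 3.0}
        table = combine_scores(d, t, cluster_of)
        assert table.loc["g0", "d_norm"] == pytest.approx(0.0)
        assert table.loc["g1", "d_norm"] == pytest.approx(0.5)
        assert table.loc["g2", "d_norm"] == pytest.approx(1.0)
        # gene score is the mean of the two normalized components
        assert table.loc["g2", "gene_score"] == pytest.approx(1.0)
        assert table.loc["g1", "gene_score"] == pytest.approx(0.25)
        # initial-cluster genes get no L-group and zero scores
        assert table.loc["gI", "lgroup"] == "none"
        assert table.loc["gI", "gene_score"] == 0.0

    def test_extremes_attained(self, selection):
        scored = selection.score_table.query("lgroup != 'none'")
        for col in ("d_norm", "t_norm"):
            assert scored[col].min() == 0.0 and scored[col].max() == 1.0

    def test_degenerate_all_equal_component(self):
        cluster_of = {"g0": GOOD, "g1": POOR}
        table = combine_scores({"g0": 3.0, "g1": 3.0}, {"g0": 1.0, "g1": 2.0},
                               cluster_of)
        assert (table["d_norm"] == 0.0).all()

    def test_no_scored_genes_rejected(self):
        with pytest.raises(SelectionError):
            combine_scores({"g0": 1.0}, {}, {"g0": INITIAL})


def _score_table(rows):
    return pd.DataFrame(
        rows,
        columns=["gene", "cluster", "lgroup", "d_score", "t_score",
                 "d_norm", "t_norm", "gene_score"],
    ).set_index("gene")


class TestSelectBiomarkers:
    def test_top_per_group(self):
        rows = [(f"a{i}", "L1", GOOD, 1, i, 0, 0, i / 10) for i in range(5)]
        rows += [(f"b{i}", "L2", POOR, 1, i, 0, 0, i / 10) for i in range(5)]
        out = select_biomarkers(_score_table(rows), per_group=2)
        assert out.good_markers == ["a4", "a3"]
        assert out.poor_markers == ["b4", "b3"]
        assert len(out.combined) == 4

    def test_tie_breaks_by_t_score_then_gene_id(self):
        rows = [
            ("aZ", "L1", GOOD, 1, 2.0, 0, 0, 0.5),
            ("aA", "L1", GOOD, 1, 2.0, 0, 0, 0.5),
            ("aB", "L1", GOOD, 1, 9.0, 0, 0, 0.5),
            ("b0", "L2", POOR, 1, 1.0, 0, 0, 0.5),
        ]
        out = select_biomarkers(_score_table(rows), per_group=2)
        assert out.good_markers == ["aB", "aA"]

    def test_small_group_returns_all_members(self, caplog):
        rows = [("a0", "L1", GOOD, 1, 1, 0, 0, 0.5),
                ("b0", "L2", POOR, 1, 1, 0, 0, 0.5)]
        out = select_biomarkers(_score_table(rows), per_group=50)
        assert out.good_markers == ["a0"] and out.poor_markers == ["b0"]

    def test_empty_lgroup_rejected(self):
        rows = [("a0", "L1", GOOD, 1, 1, 0, 0, 0.5)]
        with pytest.raises(SelectionError, match="poor"):
            select_biomarkers(_score_table(rows), per_group=1)

    def test_input_order_invariance(self):
        rows = [(f"g{i}", "L1", GOOD, 1, i % 3, 0, 0, (i % 5) / 5) for i in range(20)]
        rows += [(f"h{i}", "L2", POOR, 1, i % 3, 0, 0, (i % 5) / 5) for i in range(20)]
        t1 = _score_table(rows)
        t2 = _score_table(rows[::-1])
        out1 = select_biomarkers(t1, per_group=5)
        out2 = select_biomarkers(t2, per_group=5)
        assert out1.good_markers == out2.good_markers
        assert out1.poor_markers == out2.poor_markers


class TestDiffFreq:
    def test_sign_partition(self):
        freqs = {"A": (5, 0), "B": (0, 5), "C": (2, 2)}
        out = diff_freq_select(freqs, per_group=1)
        assert out.good_markers == ["A"] and out.poor_markers == ["B"]

    def test_degenerate_equal_counts_fill_by_gene_id(self, caplog):
        freqs = {g: (3, 3) for g in ("c", "a", "b", "d")}
        out = diff_freq_select(freqs, per_group=2)
        assert out.good_markers == ["a", "b"]
        assert out.poor_markers == ["c", "d"]
        assert not set(out.good_markers) & set(out.poor_markers)

    def test_panels_disjoint_when_genes_scarce(self):
        freqs = {f"g{i}": (i, 0) for i in range(4)}
        out = diff_freq_select(freqs, per_group=50)
        assert not set(out.good_markers) & set(out.poor_markers)
        assert len(out.combined) == 4

    def test_empty_rejected(self):
        with pytest.raises(InvalidInputError):
            diff_freq_select({}, per_group=5)
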