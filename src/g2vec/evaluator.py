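"""Cross-validated outcome prediction with the selected biomarkers.

For each stratified fold, biomarker selection runs on training samples
only; a random forest is then trained on the training samples'
expression restricted to the fold's markers and scored on the held-out
samples by AUC-ROC.  A small-training-sample experiment draws 10, 20 or
30 samples per prognosis group as training and evaluates on the rest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .datagen import GOOD, POOR, ExpressionDataset
from .pipeline import PipelineConfig, select_markers
from .scorer import BiomarkerSet

logger = logging.getLogger(__name__)

RF_N_ESTIMATORS = 500


class FoldConstructionError(ValueError):
    pass


@dataclass
class EvaluationResult:
    fold_aucs: list[float]
    fold_markers: list[BiomarkerSet]
    config: dict = field(default_factory=dict)

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_aucs))

    def to_json(self) -> str:
        return json.dumps(
            {
                "fold_aucs": self.fold_aucs,
                "mean_auc": self.mean_auc,
                "config": self.config,
            },
            indent=2,
        )


def _derive_seeds(seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n)
    return [int(s % (2**31)) for s in state]


def _fit_and_score(
    train_data: ExpressionDataset,
    test_data: ExpressionDataset,
    markers: list[str],
    rf_seed: int,
) -> float:
    gene_pos = {g: i for i, g in enumerate(train_data.gene_ids)}
    rows = [gene_pos[g] for g in markers]
    X_train = train_data.matrix[rows].T
    X_test = test_data.matrix[rows].T
    y_train = (train_data.label_array == POOR).astype(int)
    y_test = (test_data.label_array == POOR).astype(int)
    rf = RandomForestClassifier(n_estimators=RF_N_ESTIMATORS, random_state=rf_seed)
    rf.fit(X_train, y_train)
    scores = rf.predict_proba(X_test)[:, list(rf.classes_).index(1)]
    return float(roc_auc_score(y_test, scores))


def cross_validate(
    data: ExpressionDataset,
    reference_edges: list[tuple[str, str]],
    config: PipelineConfig | None = None,
    n_folds: int = 10,
    seed: int = 0,
) -> EvaluationResult:
    """Stratified n-fold evaluation with per-fold biomarker selection.

    The entire selection pipeline (correlation networks, walks, model
    training, scoring) sees only each fold's training samples.
    """
    config = config or PipelineConfig()
    labels = data.label_array
    for cls in (GOOD, POOR):
        n_cls = int((labels == cls).sum())
        if n_cls < n_folds:
            raise FoldConstructionError(
                f"class {cls!r} has {n_cls} samples; need >= {n_folds} for "
                f"{n_folds}-fold stratified CV"
            )
    seeds = _derive_seeds(seed, 1 + 2 * n_folds)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seeds[0])
    samples = np.array(data.sample_ids)

    fold_aucs: list[float] = []
    fold_markers: list[BiomarkerSet] = []
    for fold, (train_idx, test_idx) in enumerate(skf.split(samples, labels)):
        train_data = data.subset_samples(list(samples[train_idx]))
        test_data = data.subset_samples(list(samples[test_idx]))
        result = select_markers(
            train_data, reference_edges, config, seed=seeds[1 + 2 * fold]
        )
        auc = _fit_and_score(
            train_data, test_data, result.markers.combined, seeds[2 + 2 * fold]
        )
        logger.info("fold %d: %d markers, AUC %.3f",
                    fold, len(result.markers.combined), auc)
        fold_aucs.append(auc)
        fold_markers.append(result.markers)
    return EvaluationResult(
        fold_aucs=fold_aucs,
        fold_markers=fold_markers,
        config={
            "n_folds": n_folds,
            "seed": seed,
            "rf_n_estimators": RF_N_ESTIMATORS,
            "per_group": config.per_group,
            "threshold": config.threshold,
            "max_path_length": config.walk.max_path_length,
            "walks_per_node": config.walk.walks_per_node,
            "train_fraction": config.walk.train_fraction,
            "projection_size": config.model.projection_size,
            "learning_rate": config.model.learning_rate,
            "max_epochs": config.model.max_epochs,
        },
    )


def small_sample_experiment(
    data: ExpressionDataset,
    reference_edges: list[tuple[str, str]],
    n_per_group: int,
    config: PipelineConfig | None = None,
    n_repeats: int = 10,
    seed: int = 0,
) -> dict:
    """Repeatedly train on ``n_per_group`` samples per class, test on the rest."""
    config = config or PipelineConfig()
    good = data.group_samples(GOOD)
    poor = data.group_samples(POOR)
    if n_per_group >= len(good) or n_per_group >= len(poor):
        raise FoldConstructionError(
            f"n_per_group={n_per_group} leaves no test samples "
            f"({len(good)} good, {len(poor)} poor)"
        )
    seeds = _derive_seeds(seed, 3 * n_repeats)
    rng = np.random.default_rng(np.random.SeedSequence([seed, n_per_group]))
    aucs: list[float] = []
    train_sets: list[list[str]] = []
    for rep in range(n_repeats):
        tr_good = list(rng.choice(good, size=n_per_group, replace=False))
        tr_poor = list(rng.choice(poor, size=n_per_group, replace=False))
        train_ids = tr_good + tr_poor
        test_ids = [s for s in data.sample_ids if s not in set(train_ids)]
        train_data = data.subset_samples(train_ids)
        test_data = data.subset_samples(test_ids)
        result = select_markers(
            train_data, reference_edges, config, seed=seeds[3 * rep]
        )
        auc = _fit_and_score(
            train_data, test_data, result.markers.combined, seeds[3 * rep + 1]
        )
        logger.info("n=%d repeat %d: AUC %.3f", n_per_group, rep, auc)
        aucs.append(auc)
        train_sets.append(sorted(train_ids))
    return {
        "n_per_group": n_per_group,
        "n_training_samples": 2 * n_per_group,
        "repeat_aucs": aucs,
        "mean_auc": float(np.mean(aucs)),
        "repeat_train_ids": train_sets,
    }
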