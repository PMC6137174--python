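"""Expression/clinical input handling and synthetic cohort simulation.

Real inputs are a genes-by-samples log-scale expression matrix, binary
good/poor prognosis labels (or survival records from which labels are
derived by a time criterion), and an undirected gene-interaction edge
list.  The simulator produces cohorts with the same shape: a sparse
random gene network containing planted co-expression modules, two
patient groups whose expression differs on the planted genes, and
survival records consistent with the labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GOOD = "good"
POOR = "poor"
EXCLUDED = "excluded"


class InvalidInputError(ValueError):
    """Raised when an input value violates a stated precondition."""


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is infeasible."""


@dataclass
class ExpressionDataset:
    """Gene-by-sample expression with per-sample prognosis labels.

    ``matrix`` holds log-scale expression, one row per entry of
    ``gene_ids`` and one column per entry of ``sample_ids``.  ``labels``
    maps each sample id to ``"good"`` or ``"poor"``.
    """

    gene_ids: list[str]
    matrix: np.ndarray
    sample_ids: list[str]
    labels: dict[str, str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise InvalidInputError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise InvalidInputError("duplicate gene identifiers")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise InvalidInputError("duplicate sample identifiers")
        missing = [s for s in self.sample_ids if s not in self.labels]
        if missing:
            raise InvalidInputError(f"samples without labels: {missing[:5]}")
        if np.isnan(self.matrix).any():
            raise InvalidInputError("expression matrix contains missing values")

    def group_samples(self, group: str) -> list[str]:
        return [s for s in self.sample_ids if self.labels[s] == group]

    def group_columns(self, group: str) -> np.ndarray:
        idx = [i for i, s in enumerate(self.sample_ids) if self.labels[s] == group]
        return self.matrix[:, idx]

    def subset_samples(self, keep: list[str]) -> "ExpressionDataset":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in keep]
        return ExpressionDataset(
            gene_ids=list(self.gene_ids),
            matrix=self.matrix[:, idx].copy(),
            sample_ids=list(keep),
            labels={s: self.labels[s] for s in keep},
        )

    @property
    def label_array(self) -> np.ndarray:
        return np.array([self.labels[s] for s in self.sample_ids])


@dataclass(frozen=True)
class SurvivalRecord:
    sample_id: str
    time: float  # days
    event: bool  # death observed

    def __post_init__(self) -> None:
        if self.time < 0:
            raise InvalidInputError(
                f"negative survival time for sample {self.sample_id}: {self.time}"
            )


@dataclass
class SyntheticCohortConfig:
    """Parameters of a simulated two-group cohort with planted modules.

    Each planted module is a near-clique in the simulated network whose
    member genes are co-expressed (pairwise correlation about
    ``within_module_corr``) in exactly one prognosis group, and whose
    mean expression differs between groups by ``planted_effect``.
    """

    n_genes: int = 500
    n_samples_per_group: int = 60
    n_network_edges: int = 2000
    planted_module_sizes: list[int] = field(default_factory=lambda: [20, 20])
    planted_effect: float = 1.0
    within_module_corr: float = 0.9
    noise_sd: float = 0.5
    seed: int = 0
    baseline_mean: float = 8.0
    survival_criterion_days: float = 730.0

    def validate(self) -> None:
        if self.n_genes <= 0 or self.n_samples_per_group <= 0:
            raise ConfigurationError("n_genes and n_samples_per_group must be positive")
        if any(m <= 0 for m in self.planted_module_sizes):
            raise ConfigurationError("module sizes must be positive")
        if sum(self.planted_module_sizes) > self.n_genes:
            raise ConfigurationError(
                f"planted modules need {sum(self.planted_module_sizes)} genes "
                f"but only {self.n_genes} exist"
            )
        max_edges = self.n_genes * (self.n_genes - 1) // 2
        if self.n_network_edges > max_edges:
            raise ConfigurationError(
                f"{self.n_network_edges} edges exceed the {max_edges} possible"
            )
        clique_edges = sum(m * (m - 1) // 2 for m in self.planted_module_sizes)
        if self.n_network_edges < clique_edges:
            raise ConfigurationError(
                f"n_network_edges={self.n_network_edges} cannot cover the "
                f"{clique_edges} planted-module clique edges"
            )
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        if not 0 <= self.within_module_corr < 1:
            raise ConfigurationError("within_module_corr must lie in [0, 1)")


def preprocess_expression(raw_matrix: np.ndarray) -> np.ndarray:
    """log2(x + 1) transform of a non-negative raw count/abundance matrix."""
    raw = np.asarray(raw_matrix, dtype=float)
    if (raw < 0).any():
        i, j = np.argwhere(raw < 0)[0]
        raise InvalidInputError(
            f"negative expression value {raw[i, j]} at row {i}, column {j}"
        )
    return np.log2(raw + 1.0)


def label_patients(
    records: list[SurvivalRecord], criterion: float
) -> dict[str, str]:
    """Assign good/poor/excluded by a survival-time criterion.

    Good: survived past the criterion with no death event.  Poor: death
    recorded within the criterion.  Everything else (censored before the
    criterion, or death after it) is excluded from the labeled cohort.
    """
    if criterion <= 0:
        raise InvalidInputError(f"criterion must be positive, got {criterion}")
    out: dict[str, str] = {}
    for rec in records:
        if rec.time < 0:
            raise InvalidInputError(f"negative time for {rec.sample_id}")
        if rec.time > criterion and not rec.event:
            out[rec.sample_id] = GOOD
        elif rec.event and rec.time <= criterion:
            out[rec.sample_id] = POOR
        else:
            out[rec.sample_id] = EXCLUDED
    return out


def _simulate_network(
    cfg: SyntheticCohortConfig, gene_ids: list[str], modules: list[list[int]],
    rng: np.random.Generator,
) -> list[tuple[str, str]]:
    """Planted-module cliques plus random background edges."""
    edges: set[tuple[int, int]] = set()
    for module in modules:
        for a_pos in range(len(module)):
            for b_pos in range(a_pos + 1, len(module)):
                a, b = module[a_pos], module[b_pos]
                edges.add((min(a, b), max(a, b)))
    n_extra = cfg.n_network_edges - len(edges)
    while n_extra > 0:
        a = int(rng.integers(0, cfg.n_genes))
        b = int(rng.integers(0, cfg.n_genes))
        if a == b:
            continue
        e = (min(a, b), max(a, b))
        if e in edges:
            continue
        edges.add(e)
        n_extra -= 1
    ordered = sorted(edges)
    return [(gene_ids[a], gene_ids[b]) for a, b in ordered]


def simulate_cohort(
    config: SyntheticCohortConfig,
) -> tuple[ExpressionDataset, list[SurvivalRecord], list[tuple[str, str]], list[str]]:
    """Simulate (expression dataset, survival records, network edges, planted genes).

    Module k is co-expressed (latent-factor correlation) in the good
    group for even k and in the poor group for odd k; its genes are
    up-shifted by ``planted_effect`` in that same group relative to the
    other.  Non-planted genes are i.i.d. Gaussian noise in both groups.
    All randomness derives from ``config.seed`` via named substreams, so
    identical seeds give identical cohorts.
    """
    cfg = config
    cfg.validate()
    ss = np.random.SeedSequence(cfg.seed)
    rng_net, rng_expr, rng_surv = (
        np.random.default_rng(child) for child in ss.spawn(3)
    )

    width = len(str(cfg.n_genes - 1))
    gene_ids = [f"G{i:0{width}d}" for i in range(cfg.n_genes)]
    n = cfg.n_samples_per_group
    sample_ids = [f"S{g}{i:03d}" for g in ("G", "P") for i in range(n)]
    labels = {s: (GOOD if s.startswith("SG") else POOR) for s in sample_ids}

    modules: list[list[int]] = []
    start = 0
    for size in cfg.planted_module_sizes:
        modules.append(list(range(start, start + size)))
        start += size
    planted = [gene_ids[i] for mod in modules for i in mod]

    edge_list = _simulate_network(cfg, gene_ids, modules, rng_net)

    # background: independent noise everywhere
    X = rng_expr.normal(cfg.baseline_mean, cfg.noise_sd, size=(cfg.n_genes, 2 * n))
    good_cols = np.arange(n)
    poor_cols = np.arange(n, 2 * n)
    rho = cfg.within_module_corr
    for k, module in enumerate(modules):
        corr_cols = good_cols if k % 2 == 0 else poor_cols
        # shared latent factor induces pairwise correlation ~ rho
        z = rng_expr.normal(0.0, 1.0, size=len(corr_cols))
        for g in module:
            eps = rng_expr.normal(0.0, 1.0, size=len(corr_cols))
            X[g, corr_cols] = cfg.baseline_mean + cfg.noise_sd * (
                np.sqrt(rho) * z + np.sqrt(1.0 - rho) * eps
            )
        X[np.ix_(module, corr_cols)] += cfg.planted_effect
    X = np.clip(X, 0.0, None)  # log-scale expression stays non-negative

    crit = cfg.survival_criterion_days
    records = []
    for s in sample_ids:
        if labels[s] == GOOD:
            t = float(rng_surv.uniform(crit + 1.0, 2.0 * crit))
            records.append(SurvivalRecord(s, t, False))
        else:
            t = float(rng_surv.uniform(30.0, crit))
            records.append(SurvivalRecord(s, t, True))

    data = ExpressionDataset(gene_ids, X, sample_ids, labels)
    return data, records, edge_list, planted


# ---------------------------------------------------------------------------
# File interfaces

def read_expression(path: str) -> tuple[list[str], np.ndarray, list[str]]:
    """Read a TSV matrix: first column gene id, header row sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return list(df.index.astype(str)), df.to_numpy(dtype=float), list(
        df.columns.astype(str)
    )


def write_expression(
    path: str, gene_ids: list[str], matrix: np.ndarray, sample_ids: list[str]
) -> None:
    df = pd.DataFrame(matrix, index=gene_ids, columns=sample_ids)
    df.index.name = "gene"
    df.to_csv(path, sep="\t", float_format="%.6g")


def read_clinical(path: str) -> list[SurvivalRecord]:
    """Read TSV with columns sample_id, time_days, event (0/1)."""
    df = pd.read_csv(path, sep="\t")
    return [
        SurvivalRecord(str(r.sample_id), float(r.time_days), bool(int(r.event)))
        for r in df.itertuples(index=False)
    ]


def write_clinical(path: str, records: list[SurvivalRecord]) -> None:
    df = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "time_days": [r.time for r in records],
            "event": [int(r.event) for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_labels(path: str) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["sample_id"].astype(str), df["label"].astype(str)))


def write_labels(path: str, labels: dict[str, str]) -> None:
    df = pd.DataFrame(sorted(labels.items()), columns=["sample_id", "label"])
    df.to_csv(path, sep="\t", index=False)


def read_network(path: str) -> list[tuple[str, str]]:
    """Read a two-column edge list; reversed/duplicate edges collapse."""
    seen: set[tuple[str, str]] = set()
    edges: list[tuple[str, str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise InvalidInputError(f"malformed network line: {line!r}")
            a, b = parts[0], parts[1]
            if a == b:
                continue  # self-loops carry no walk information
            key = (a, b) if a <= b else (b, a)
            if key in seen:
                continue
            seen.add(key)
            edges.append(key)
    return edges


def write_network(path: str, edges: list[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for a, b in edges:
            fh.write(f"{a}\t{b}\n")
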