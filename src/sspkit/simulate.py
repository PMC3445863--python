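"""Synthetic cohorts with the statistical structure the pipeline assumes:
subtype centroids, Gaussian expression noise, a two-site additive gene-wise
batch effect, subtype-conditional clinical covariates and subtype-dependent
exponential survival with uniform administrative censoring.

All outputs are pure functions of (config, seed): each generator draws from
its own named child stream of the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core import (
    CLINICAL_FEATURES,
    SUBTYPES,
    BatchDesign,
    CentroidSet,
    ClinicalRecord,
    ExpressionMatrix,
    SurvivalRecord,
    ValidationError,
)

BATCH_1 = "batch1"
BATCH_2 = "batch2"

# Default P(category | subtype) tables, taken from the observed cross-tabs of
# a 117-sample two-signature-consistent cohort (order: level -> per-subtype
# probability, subtype order LumA, LumB, Normal, Her2E, Basal).
DEFAULT_CLINICAL_CONDITIONALS: dict[str, dict[str, tuple[float, ...]]] = {
    "er": {
        "positive": (35 / 35, 15 / 16, 2 / 6, 3 / 21, 0 / 39),
        "negative": (0 / 35, 1 / 16, 4 / 6, 18 / 21, 39 / 39),
    },
    "her2": {
        "over-expressed": (2 / 35, 5 / 16, 2 / 6, 18 / 21, 2 / 39),
        "not": (33 / 35, 11 / 16, 4 / 6, 3 / 21, 37 / 39),
    },
    "grade": {
        "I": (17 / 35, 0 / 16, 1 / 6, 0 / 21, 0 / 39),
        "II": (16 / 35, 4 / 16, 2 / 6, 4 / 21, 2 / 39),
        "III": (2 / 35, 12 / 16, 3 / 6, 17 / 21, 37 / 39),
    },
    "nodal": {
        "positive": (16 / 35, 9 / 16, 5 / 6, 14 / 21, 10 / 39),
        "negative": (19 / 35, 7 / 16, 1 / 6, 7 / 21, 29 / 39),
    },
    "lvi": {
        "positive": (14 / 35, 11 / 16, 4 / 6, 13 / 21, 11 / 39),
        "negative": (21 / 35, 5 / 16, 2 / 6, 8 / 21, 28 / 39),
    },
}

#: Monthly event rates chosen to mirror the qualitative prognosis ordering
#: (LumA best; LumB/Her2E worst; Basal between). Config-exposed defaults.
DEFAULT_HAZARDS: dict[str, float] = {
    "LumA": 0.004,
    "LumB": 0.015,
    "Normal": 0.006,
    "Her2E": 0.015,
    "Basal": 0.008,
}

_STREAMS = {"centroids": 0, "cohort": 1, "clinical": 2, "survival": 3}


@dataclass
class SimulationConfig:
    n_genes: int = 50
    subtype_sizes: tuple[int, int, int, int, int] = (40, 40, 40, 40, 40)
    tau: float = 1.0
    sigma: float = 0.5
    batch_beta: float = 0.0
    batch_fraction: float = 0.5
    clinical_conditionals: Mapping[str, Mapping[str, Sequence[float]]] = field(
        default_factory=lambda: DEFAULT_CLINICAL_CONDITIONALS
    )
    hazards: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_HAZARDS))
    censor_time_max: float = 62.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValidationError("n_genes must be >= 1")
        if len(self.subtype_sizes) != 5 or any(s < 0 for s in self.subtype_sizes):
            raise ValidationError("subtype_sizes must be 5 non-negative integers")
        if sum(self.subtype_sizes) < 1:
            raise ValidationError("subtype_sizes must sum to >= 1")
        for name in ("tau", "sigma", "batch_beta"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not 0.0 <= self.batch_fraction <= 1.0:
            raise ValidationError("batch_fraction must be in [0, 1]")
        if self.censor_time_max <= 0:
            raise ValidationError("censor_time_max must be positive")
        for feature, table in self.clinical_conditionals.items():
            if feature not in CLINICAL_FEATURES:
                raise ValidationError(f"unknown clinical feature {feature!r}")
            probs = np.array([list(v) for v in table.values()], dtype=float)
            if probs.shape[1] != 5 or (probs < 0).any():
                raise ValidationError(
                    f"{feature}: conditional table needs 5 non-negative entries per level"
                )
            sums = probs.sum(axis=0)
            if np.abs(sums - 1.0).max() > 1e-9:
                raise ValidationError(f"{feature}: conditional columns must sum to 1")
        for subtype in SUBTYPES:
            if subtype not in self.hazards:
                raise ValidationError(f"hazard missing for subtype {subtype}")
            if self.hazards[subtype] <= 0:
                raise ValidationError(f"hazard for {subtype} must be > 0")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), _STREAMS[stream]])


def simulate_centroids(config: SimulationConfig) -> CentroidSet:
    """Independent Normal(0, tau^2) centroid entries, 5 x n_genes."""
    rng = config.rng("centroids")
    values = rng.normal(0.0, config.tau, size=(config.n_genes, len(SUBTYPES)))
    genes = [f"G{i:04d}" for i in range(config.n_genes)]
    return CentroidSet("simulated", genes, values)


def simulate_cohort(
    config: SimulationConfig, centroids: CentroidSet
) -> tuple[ExpressionMatrix, dict[str, str], BatchDesign]:
    """Draw samples around their subtype centroid, then shift batch 2.

    The batch-2 shift is one Normal(0, batch_beta^2) vector per gene shared by
    every batch-2 sample (systemic bias, not sample noise). Sample order is
    shuffled so batches are not confounded with subtype blocks.
    """
    if centroids.values.shape[0] != config.n_genes:
        raise ValidationError("centroid panel does not match config.n_genes")
    rng = config.rng("cohort")
    n = int(sum(config.subtype_sizes))
    labels_idx = np.repeat(np.arange(5), config.subtype_sizes)
    rng.shuffle(labels_idx)
    sample_ids = [f"S{i:04d}" for i in range(n)]
    X = centroids.values.T[labels_idx] + rng.normal(0.0, config.sigma, size=(n, config.n_genes))
    n2 = int(round(config.batch_fraction * n))
    batch2 = np.zeros(n, dtype=bool)
    if n2 > 0:
        batch2[rng.choice(n, size=n2, replace=False)] = True
    delta = rng.normal(0.0, config.batch_beta, size=config.n_genes)
    X[batch2] += delta
    truth = {sid: SUBTYPES[k] for sid, k in zip(sample_ids, labels_idx)}
    design = BatchDesign(
        {sid: (BATCH_2 if b2 else BATCH_1) for sid, b2 in zip(sample_ids, batch2)}
    )
    matrix = ExpressionMatrix(list(centroids.gene_ids), sample_ids, X.T)
    return matrix, truth, design


def simulate_clinical(
    truth: Mapping[str, str], config: SimulationConfig
) -> list[ClinicalRecord]:
    """Draw each clinical feature independently from P(category | subtype)."""
    rng = config.rng("clinical")
    records = []
    for sample_id, subtype in truth.items():
        k = SUBTYPES.index(subtype)
        kwargs = {}
        for feature, table in config.clinical_conditionals.items():
            levels = list(table)
            probs = np.array([table[lvl][k] for lvl in levels], dtype=float)
            kwargs[feature] = levels[rng.choice(len(levels), p=probs / probs.sum())]
        records.append(ClinicalRecord(sample_id=sample_id, **kwargs))
    return records


def simulate_survival(
    truth: Mapping[str, str], config: SimulationConfig
) -> list[SurvivalRecord]:
    """Exponential event times per subtype hazard, uniform censoring."""
    rng = config.rng("survival")
    records = []
    for sample_id, subtype in truth.items():
        rate = config.hazards[subtype]
        event_time = rng.exponential(1.0 / rate)
        censor_time = rng.uniform(0.0, config.censor_time_max)
        observed = min(event_time, censor_time)
        records.append(SurvivalRecord(sample_id, observed, int(event_time <= censor_time)))
    return records


def simulate_all(config: SimulationConfig):
    """Centroids, cohort, truth, batches, clinical and survival in one call."""
    centroids = simulate_centroids(config)
    matrix, truth, design = simulate_cohort(config, centroids)
    clinical = simulate_clinical(truth, config)
    survival = simulate_survival(truth, config)
    return centroids, matrix, truth, design, clinical, survival
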