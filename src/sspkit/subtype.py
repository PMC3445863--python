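"""Probe collapsing, centroid construction, and Spearman nearest-centroid
single-sample prediction.

A sample is assigned to the subtype whose centroid maximizes the Spearman
rank correlation over the shared gene panel; if all five correlations fall
below the threshold (default 0.1) the sample is Unclassified. Exact ties at
the maximum resolve deterministically in the fixed label order and set the
tie flag.
"""

from __future__ import annotations

import logging
from collections import OrderedDict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    SUBTYPES,
    UNCLASSIFIED,
    CentroidSet,
    ExpressionMatrix,
    GeneSignature,
    SubtypeCall,
    ValidationError,
)

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.1
DEFAULT_MIN_GENES = 10


def collapse_probes(matrix: ExpressionMatrix, probe_map: Mapping[str, str]) -> ExpressionMatrix:
    """Average multi-probe genes into one row per mapped gene symbol.

    Probes absent from the map are dropped (count logged). Missing values are
    averaged over the non-missing probes per sample; a gene with no observed
    probe for some sample is an error.
    """
    groups: "OrderedDict[str, list[int]]" = OrderedDict()
    dropped = 0
    for i, probe in enumerate(matrix.gene_ids):
        gene = probe_map.get(probe)
        if gene is None:
            dropped += 1
            continue
        groups.setdefault(gene, []).append(i)
    if not groups:
        raise ValidationError("no probes left after applying the probe map")
    if dropped:
        logger.info("collapse_probes: dropped %d unmapped probes", dropped)
    out = np.empty((len(groups), matrix.n_samples))
    for k, (gene, rows) in enumerate(groups.items()):
        block = matrix.values[rows, :]
        with np.errstate(invalid="ignore"):
            means = np.nanmean(block, axis=0)
        if np.isnan(means).any():
            bad = [matrix.sample_ids[j] for j in np.where(np.isnan(means))[0]]
            raise ValidationError(
                f"gene {gene!r}: all probes missing for sample(s) {bad[:5]}"
            )
        out[k] = means
    return ExpressionMatrix(list(groups), list(matrix.sample_ids), out)


def compute_centroids(
    training: ExpressionMatrix,
    labels: Mapping[str, str],
    signature: GeneSignature,
) -> CentroidSet:
    """Per-subtype mean expression over the signature genes present in training."""
    unknown = sorted({v for v in labels.values()} - set(SUBTYPES))
    if unknown:
        raise ValidationError(f"unknown subtype label(s) in training labels: {unknown}")
    missing = [s for s in training.sample_ids if s not in labels]
    if missing:
        raise ValidationError(f"training samples without a label: {missing[:10]}")
    train_genes = set(training.gene_ids)
    panel = [g for g in signature.gene_symbols if g in train_genes]
    if not panel:
        raise ValidationError("no signature genes present in the training matrix")
    if len(panel) < len(signature.gene_symbols):
        logger.info(
            "compute_centroids: %d/%d signature genes present in training",
            len(panel),
            len(signature.gene_symbols),
        )
    sub = training.subset_genes(panel)
    sample_labels = np.array([labels[s] for s in sub.sample_ids])
    values = np.empty((len(panel), len(SUBTYPES)))
    for k, subtype in enumerate(SUBTYPES):
        mask = sample_labels == subtype
        if not mask.any():
            raise ValidationError(f"subtype {subtype!r} has no training samples")
        values[:, k] = sub.values[:, mask].mean(axis=1)
    return CentroidSet(signature.name, panel, values)


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (average ranks for ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValidationError("spearman_rho needs vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("spearman_rho undefined for a constant vector")
    return float(stats.spearmanr(x, y).statistic)


def classify_sample(
    sample: Sequence[float],
    centroids: CentroidSet,
    threshold: float = DEFAULT_THRESHOLD,
    sample_id: str = "sample",
) -> SubtypeCall:
    """Nearest-centroid call for one sample aligned to the centroid panel.

    A constant centroid contributes correlation 0.0 (no association) rather
    than an error, so fully degenerate centroid sets still produce a
    deterministic, tie-flagged result.
    """
    x = np.asarray(sample, dtype=float)
    if x.shape != (len(centroids.gene_ids),):
        raise ValidationError(
            f"{sample_id}: sample has {x.shape} values for a "
            f"{len(centroids.gene_ids)}-gene centroid panel"
        )
    if np.ptp(x) == 0:
        raise ValidationError(f"{sample_id}: constant expression vector")
    rhos = []
    for k in range(len(SUBTYPES)):
        c = centroids.values[:, k]
        rhos.append(0.0 if np.ptp(c) == 0 else spearman_rho(x, c))
    rhos_t = tuple(rhos)
    rmax = max(rhos_t)
    tie = rhos_t.count(rmax) > 1
    if rmax < threshold:
        label = UNCLASSIFIED
    else:
        label = SUBTYPES[rhos_t.index(rmax)]  # first argmax in fixed order
    return SubtypeCall(sample_id, label, rhos_t, threshold=threshold, tie_flag=tie)


def _align(matrix: ExpressionMatrix, centroids: CentroidSet, min_genes: int):
    matrix_genes = set(matrix.gene_ids)
    shared = [g for g in centroids.gene_ids if g in matrix_genes]
    if len(shared) < min_genes:
        raise ValidationError(
            f"only {len(shared)} genes shared with the centroid panel "
            f"(floor {min_genes})"
        )
    if len(shared) < len(centroids.gene_ids):
        logger.info(
            "classify: %d/%d centroid genes present in matrix",
            len(shared),
            len(centroids.gene_ids),
        )
    sub = matrix.subset_genes(shared)
    idx = [centroids.gene_ids.index(g) for g in shared]
    trimmed = CentroidSet(centroids.signature_name, shared, centroids.values[idx, :])
    return sub, trimmed


def classify_cohort(
    matrix: ExpressionMatrix,
    centroids: CentroidSet,
    threshold: float = DEFAULT_THRESHOLD,
    min_genes: int = DEFAULT_MIN_GENES,
) -> tuple[list[SubtypeCall], pd.Series]:
    """Call every sample; also return the 6-category distribution table."""
    if matrix.n_samples == 0:
        raise ValidationError("empty cohort")
    sub, trimmed = _align(matrix, centroids, min_genes)
    calls = []
    for j, sid in enumerate(sub.sample_ids):
        try:
            calls.append(classify_sample(sub.values[:, j], trimmed, threshold, sample_id=sid))
        except ValidationError as exc:
            raise ValidationError(f"classification failed for sample {sid!r}: {exc}") from exc
    return calls, call_distribution(calls)


def call_distribution(calls: Sequence[SubtypeCall]) -> pd.Series:
    """Counts over the 6 categories in fixed order, summing to len(calls)."""
    counts = pd.Series(0, index=list(SUBTYPES) + [UNCLASSIFIED], dtype=int)
    for c in calls:
        counts[c.label] += 1
    return counts
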