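"""Core domain types shared by every stage of the pipeline.

The data model is deliberately small: an expression matrix (genes as rows,
samples as columns, log2 units), a gene signature with an optional
probe-to-gene map, a five-subtype centroid set, per-sample subtype calls,
and flat clinical/survival/batch records.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Fixed subtype label order used everywhere (centroid columns, tie-breaking,
#: distribution tables, report rows).
SUBTYPES: tuple[str, ...] = ("LumA", "LumB", "Normal", "Her2E", "Basal")
UNCLASSIFIED = "Unclassified"
CALL_CATEGORIES: tuple[str, ...] = SUBTYPES + (UNCLASSIFIED,)

#: Missing-value token for categorical clinical fields.
NA_TOKEN = "NA"

ER_LEVELS = ("positive", "negative")
HER2_LEVELS = ("over-expressed", "not")
GRADE_LEVELS = ("I", "II", "III")
NODAL_LEVELS = ("positive", "negative")
LVI_LEVELS = ("positive", "negative")

CLINICAL_FEATURES: dict[str, tuple[str, ...]] = {
    "er": ER_LEVELS,
    "her2": HER2_LEVELS,
    "grade": GRADE_LEVELS,
    "nodal": NODAL_LEVELS,
    "lvi": LVI_LEVELS,
}


class ValidationError(ValueError):
    """A domain invariant was violated."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: dict[str, int] = {}
    dups = []
    for x in ids:
        if x in seen:
            dups.append(x)
        seen[x] = 1
    if dups:
        raise ValidationError(f"duplicate {what} identifiers: {sorted(set(dups))}")


@dataclass
class ExpressionMatrix:
    """Log2-scale genes x samples grid with unique identifiers on both axes.

    ``allow_missing`` may only be set before probe collapsing; all downstream
    operations require finite values.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    allow_missing: bool = False

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-D array")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"shape mismatch: values {self.values.shape} vs "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(self.gene_ids) == 0 or len(self.sample_ids) == 0:
            raise ValidationError("matrix needs at least 1 gene and 1 sample")
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if np.isinf(self.values).any():
            raise ValidationError("infinite expression values are not allowed")
        if not self.allow_missing and np.isnan(self.values).any():
            raise ValidationError(
                "missing expression values only permitted with allow_missing=True"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, allow_missing: bool = False) -> "ExpressionMatrix":
        return cls(
            gene_ids=list(frame.index.astype(str)),
            sample_ids=list(frame.columns.astype(str)),
            values=frame.to_numpy(dtype=float),
            allow_missing=allow_missing,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in idx]
        if missing:
            raise ValidationError(f"genes absent from matrix: {missing[:10]}")
        rows = [idx[g] for g in genes]
        return ExpressionMatrix(
            list(genes), list(self.sample_ids), self.values[rows, :],
            allow_missing=self.allow_missing,
        )

    def sample(self, sample_id: str) -> np.ndarray:
        try:
            j = self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample {sample_id!r}") from None
        return self.values[:, j]


@dataclass
class GeneSignature:
    """A named intrinsic gene panel, optionally with a many-to-one probe map."""

    name: str
    gene_symbols: list[str]
    probe_map: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if not self.gene_symbols:
            raise ValidationError("signature gene list must be non-empty")
        _check_unique(self.gene_symbols, "gene symbol")
        if self.probe_map is not None:
            for probe, gene in self.probe_map.items():
                if not isinstance(gene, str) or not gene:
                    raise ValidationError(f"probe {probe!r} maps to invalid gene {gene!r}")


@dataclass
class CentroidSet:
    """Per-subtype mean expression vectors over one signature's gene panel.

    ``values`` is genes x 5, columns in :data:`SUBTYPES` order.
    """

    signature_name: str
    gene_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(SUBTYPES)):
            raise ValidationError(
                f"centroid matrix must be {len(self.gene_ids)} genes x 5 subtypes, "
                f"got {self.values.shape}"
            )
        _check_unique(self.gene_ids, "gene")
        if not np.isfinite(self.values).all():
            raise ValidationError("centroid values must all be finite")

    @property
    def subtype_labels(self) -> tuple[str, ...]:
        return SUBTYPES

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=list(SUBTYPES))

    def centroid(self, label: str) -> np.ndarray:
        return self.values[:, SUBTYPES.index(label)]


@dataclass
class BatchDesign:
    """sample_id -> batch label."""

    assignments: dict[str, str]

    def __post_init__(self) -> None:
        self.assignments = {str(k): str(v) for k, v in self.assignments.items()}

    @property
    def batches(self) -> list[str]:
        return sorted(set(self.assignments.values()))

    def labels_for(self, sample_ids: Sequence[str]) -> list[str]:
        missing = [s for s in sample_ids if s not in self.assignments]
        if missing:
            raise ValidationError(f"samples without a batch label: {missing[:10]}")
        return [self.assignments[s] for s in sample_ids]

    def require_two_batches(self) -> tuple[str, str]:
        b = self.batches
        if len(b) != 2:
            raise ValidationError(f"exactly 2 batches required, got {b}")
        return b[0], b[1]


@dataclass
class SubtypeCall:
    """Assigned label plus the five centroid correlations behind it."""

    sample_id: str
    label: str
    correlations: tuple[float, float, float, float, float]
    threshold: float = 0.1
    tie_flag: bool = False

    def __post_init__(self) -> None:
        if self.label not in CALL_CATEGORIES:
            raise ValidationError(f"unknown call label {self.label!r}")
        if len(self.correlations) != len(SUBTYPES):
            raise ValidationError("exactly 5 correlations required")
        rmax = max(self.correlations)
        if self.label == UNCLASSIFIED:
            if rmax >= self.threshold:
                raise ValidationError(
                    f"{self.sample_id}: Unclassified but max rho {rmax:.4f} >= "
                    f"threshold {self.threshold}"
                )
        else:
            if self.correlations[SUBTYPES.index(self.label)] != rmax:
                raise ValidationError(
                    f"{self.sample_id}: label {self.label} is not an argmax correlation"
                )


@dataclass
class ClinicalRecord:
    sample_id: str
    er: str = NA_TOKEN
    her2: str = NA_TOKEN
    grade: str = NA_TOKEN
    nodal: str = NA_TOKEN
    lvi: str = NA_TOKEN

    def __post_init__(self) -> None:
        for feature, levels in CLINICAL_FEATURES.items():
            value = getattr(self, feature)
            if value != NA_TOKEN and value not in levels:
                raise ValidationError(
                    f"{self.sample_id}: {feature}={value!r} not in "
                    f"{levels + (NA_TOKEN,)}"
                )


@dataclass
class SurvivalRecord:
    sample_id: str
    time: float
    event: int

    def __post_init__(self) -> None:
        self.time = float(self.time)
        self.event = int(self.event)
        if self.time < 0:
            raise ValidationError(f"{self.sample_id}: negative survival time {self.time}")
        if self.event not in (0, 1):
            raise ValidationError(f"{self.sample_id}: event must be 0 or 1, got {self.event}")
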