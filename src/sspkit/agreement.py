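"""Pairwise agreement between call sets: contingency tables, unweighted
Cohen's kappa with a large-sample (delta-method) standard error, and
consistent-sample extraction."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import CALL_CATEGORIES, SUBTYPES, UNCLASSIFIED, SubtypeCall, ValidationError

Z_95 = 1.96


@dataclass
class AgreementResult:
    table: pd.DataFrame
    kappa: float
    se: float
    ci_low: float
    ci_high: float
    n: int

    @property
    def categories(self) -> list[str]:
        return list(self.table.index)

    def to_dict(self) -> dict:
        return {
            "categories": self.categories,
            "table": self.table.to_numpy().tolist(),
            "kappa": self.kappa,
            "se": self.se,
            "ci": [self.ci_low, self.ci_high],
            "n": self.n,
        }


def _call_map(calls: Sequence[SubtypeCall], name: str) -> dict[str, str]:
    out = {c.sample_id: c.label for c in calls}
    if len(out) != len(calls):
        raise ValidationError(f"duplicate sample ids in call set {name}")
    return out


def crosstab(
    a: Sequence[SubtypeCall],
    b: Sequence[SubtypeCall],
    unclassified: str = "category",
) -> pd.DataFrame:
    """K x K contingency table of two call sets over identical samples.

    ``unclassified='category'`` keeps Unclassified as a sixth level;
    ``'drop'`` excludes samples Unclassified by either caller (K = 5).
    """
    map_a, map_b = _call_map(a, "a"), _call_map(b, "b")
    if set(map_a) != set(map_b):
        diff = sorted(set(map_a) ^ set(map_b))
        raise ValidationError(f"call sets cover different samples: {diff[:10]}")
    if unclassified == "category":
        cats = list(CALL_CATEGORIES)
        pairs = [(map_a[s], map_b[s]) for s in map_a]
    elif unclassified == "drop":
        cats = list(SUBTYPES)
        pairs = [
            (map_a[s], map_b[s])
            for s in map_a
            if map_a[s] != UNCLASSIFIED and map_b[s] != UNCLASSIFIED
        ]
    else:
        raise ValueError(f"unclassified must be 'category' or 'drop', got {unclassified!r}")
    table = pd.DataFrame(0, index=cats, columns=cats, dtype=int)
    for la, lb in pairs:
        table.loc[la, lb] += 1
    return table


def cohen_kappa(table: pd.DataFrame | np.ndarray) -> AgreementResult:
    """Unweighted kappa with Fleiss-Cohen-Everitt large-sample SE and 95% CI.

    The CI is kappa +/- 1.96 se, not truncated to [-1, 1].
    """
    if isinstance(table, pd.DataFrame):
        frame = table
    else:
        arr = np.asarray(table)
        frame = pd.DataFrame(arr, index=[str(i) for i in range(arr.shape[0])],
                             columns=[str(i) for i in range(arr.shape[1])])
    counts = frame.to_numpy(dtype=float)
    if counts.shape[0] != counts.shape[1]:
        raise ValidationError("kappa requires a square table")
    if (counts < 0).any():
        raise ValidationError("negative cell counts")
    n = counts.sum()
    if n < 2:
        raise ValidationError("kappa requires at least 2 rated samples")
    p = counts / n
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    po = float(np.trace(p))
    pe = float(row @ col)
    if pe == 1.0:
        raise ValidationError("kappa undefined: both raters constant and identical (pe = 1)")
    kappa = (po - pe) / (1.0 - pe)

    # Fleiss, Cohen & Everitt (1969) asymptotic variance of unweighted kappa
    diag = np.diag(p)
    a = float(np.sum(diag * (1.0 - (row + col) * (1.0 - kappa)) ** 2))
    off = p * (col[:, None] + row[None, :]) ** 2
    np.fill_diagonal(off, 0.0)
    b = (1.0 - kappa) ** 2 * float(off.sum())
    c = (kappa - pe * (1.0 - kappa)) ** 2
    var = (a + b - c) / (n * (1.0 - pe) ** 2)
    se = float(np.sqrt(max(var, 0.0)))
    return AgreementResult(
        table=frame,
        kappa=float(kappa),
        se=se,
        ci_low=float(kappa - Z_95 * se),
        ci_high=float(kappa + Z_95 * se),
        n=int(round(n)),
    )


def agreement(
    a: Sequence[SubtypeCall],
    b: Sequence[SubtypeCall],
    unclassified: str = "category",
) -> AgreementResult:
    """Convenience: crosstab then kappa."""
    return cohen_kappa(crosstab(a, b, unclassified=unclassified))


def consistent_samples(a: Sequence[SubtypeCall], b: Sequence[SubtypeCall]) -> list[str]:
    """Samples given the same non-Unclassified label by both call sets."""
    map_a, map_b = _call_map(a, "a"), _call_map(b, "b")
    if set(map_a) != set(map_b):
        diff = sorted(set(map_a) ^ set(map_b))
        raise ValidationError(f"call sets cover different samples: {diff[:10]}")
    return [
        c.sample_id
        for c in a
        if c.label != UNCLASSIFIED and map_b[c.sample_id] == c.label
    ]


def multi_way_consistent(call_sets: Sequence[Sequence[SubtypeCall]]) -> list[str]:
    """Samples consistently labelled (non-Unclassified) across all call sets."""
    if len(call_sets) < 2:
        raise ValidationError("need at least 2 call sets")
    keep = set(consistent_samples(call_sets[0], call_sets[1]))
    for i in range(len(call_sets)):
        for j in range(i + 1, len(call_sets)):
            keep &= set(consistent_samples(call_sets[i], call_sets[j]))
    order = [c.sample_id for c in call_sets[0]]
    return [s for s in order if s in keep]
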