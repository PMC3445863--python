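from __future__ import annotations

import numpy as np
import pytest

from sspkit.core import SUBTYPES, UNCLASSIFIED, ExpressionMatrix, SubtypeCall


def make_call(sample_id: str, label: str, threshold: float = 0.1) -> SubtypeCall:
    """Fabricate a call whose correlations are consistent with ``label``."""
    if label == UNCLASSIFIED:
        rhos = (0.05, 0.04, 0.03, 0.02, 0.01)
    else:
        rhos = tuple(0.9 if s == label else 0.0 for s in SUBTYPES)
    return SubtypeCall(sample_id, label, rhos, threshold=threshold)


def make_calls(labels: list[str], prefix: str = "S") -> list[SubtypeCall]:
    return [make_call(f"{prefix}{i}", lab) for i, lab in enumerate(labels)]


def random_matrix(
    n_genes: int, n_samples: int, seed: int = 0, scale: float = 1.0
) -> ExpressionMatrix:
    rng = np.random.default_rng(seed)
    return ExpressionMatrix(
        [f"G{i}" for i in range(n_genes)],
        [f"S{j}" for j in range(n_samples)],
        rng.normal(0, scale, size=(n_genes, n_samples)),
    )


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    return ExpressionMatrix(
        ["GA", "GB", "GC"],
        ["S1", "S2"],
        np.array([[1.0, 2.0], [3.0, 4.5], [5.25, 6.125]]),
    )
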