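"""Cohort pooling, quantile normalization and gene-wise centring."""

from __future__ import annotations

import numpy as np

from .core import BatchDesign, ExpressionMatrix, ValidationError


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the shared empirical distribution.

    The reference distribution is the across-sample mean of sorted columns;
    each column's values are replaced by the reference values at their ranks.
    Ties within a column all receive the mean of the reference values at the
    tied ranks, so with ties the output multisets can differ between columns.
    """
    if matrix.n_samples < 2:
        raise ValidationError("quantile normalization needs at least 2 samples")
    if np.isnan(matrix.values).any():
        raise ValidationError("quantile normalization requires complete values")
    vals = matrix.values
    reference = np.sort(vals, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    for j in range(vals.shape[1]):
        col = vals[:, j]
        order = np.argsort(col, kind="stable")
        sorted_col = col[order]
        assigned = reference.copy()
        # average the reference over each run of tied values
        start = 0
        for i in range(1, len(sorted_col) + 1):
            if i == len(sorted_col) or sorted_col[i] != sorted_col[start]:
                if i - start > 1:
                    assigned[start:i] = reference[start:i].mean()
                start = i
        out[order, j] = assigned
    return ExpressionMatrix(list(matrix.gene_ids), list(matrix.sample_ids), out)


def mean_center_genes(matrix: ExpressionMatrix, method: str = "mean") -> ExpressionMatrix:
    """Subtract each gene's across-sample mean (or median) from its row."""
    if np.isnan(matrix.values).any():
        raise ValidationError("centring requires complete values")
    if method == "mean":
        center = matrix.values.mean(axis=1, keepdims=True)
    elif method == "median":
        center = np.median(matrix.values, axis=1, keepdims=True)
    else:
        raise ValueError(f"unknown centring method {method!r}; use 'mean' or 'median'")
    return ExpressionMatrix(
        list(matrix.gene_ids), list(matrix.sample_ids), matrix.values - center
    )


def pool_cohorts(
    a: ExpressionMatrix,
    b: ExpressionMatrix,
    label_a: str = "a",
    label_b: str = "b",
    normalize: bool = True,
) -> tuple[ExpressionMatrix, BatchDesign]:
    """Concatenate two cohorts on their shared genes and quantile-normalize.

    Gene order follows cohort ``a`` filtered to the intersection. The returned
    batch design maps every pooled sample to its source cohort.
    """
    if label_a == label_b:
        raise ValidationError("cohort labels must differ")
    collisions = set(a.sample_ids) & set(b.sample_ids)
    if collisions:
        raise ValidationError(f"colliding sample identifiers: {sorted(collisions)[:10]}")
    b_genes = set(b.gene_ids)
    shared = [g for g in a.gene_ids if g in b_genes]
    if not shared:
        raise ValidationError("cohorts share no genes")
    a_sub = a.subset_genes(shared)
    b_sub = b.subset_genes(shared)
    pooled = ExpressionMatrix(
        shared,
        list(a.sample_ids) + list(b.sample_ids),
        np.hstack([a_sub.values, b_sub.values]),
    )
    if normalize:
        pooled = quantile_normalize(pooled)
    design = BatchDesign(
        {**{s: label_a for s in a.sample_ids}, **{s: label_b for s in b.sample_ids}}
    )
    return pooled, design
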