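"""Distance-weighted discrimination between two batches.

The separating direction w and intercept b minimize

    sum_i 1/r_i + C * sum_i xi_i
    s.t.  r_i = y_i (w . x_i + b) + xi_i,  r_i > 0,  xi_i >= 0,  ||w||_2 <= 1

with y_i = +/-1 encoding the batch. Eliminating the slacks analytically gives
the equivalent smooth convex problem

    minimize  sum_i phi(m_i)   over ||w|| <= 1,  m_i = y_i (w . x_i + b)

    phi(m) = 1/m              if m >= 1/sqrt(C)
             2*sqrt(C) - C*m  otherwise

(for m below the 1/sqrt(C) knee the optimal slack is 1/sqrt(C) - m), which is
solved with a constrained quasi-Newton method. Batch adjustment translates
each batch along w so both batch mean projections hit zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import NonlinearConstraint, minimize

from .core import BatchDesign, ExpressionMatrix, ValidationError


class SolverError(RuntimeError):
    """Optimizer failed to converge; carries the solver status message."""


@dataclass
class DWDModel:
    """Fitted DWD direction over a gene panel plus per-batch mean projections.

    ``direction`` is unit-norm; ``scale`` is the norm of the raw solution
    vector (the optimum can sit strictly inside the unit ball when the
    batches overlap), so the solved w is ``scale * direction``.
    """

    gene_ids: list[str]
    direction: np.ndarray  # unit norm
    intercept: float
    cost: float
    batch_offsets: dict[str, float]  # batch label -> mean projection on direction
    scale: float = 1.0

    def __post_init__(self) -> None:
        self.direction = np.asarray(self.direction, dtype=float)
        norm = float(np.linalg.norm(self.direction))
        if abs(norm - 1.0) > 1e-8:
            raise ValidationError(f"direction norm {norm} not 1 within 1e-8")
        if len(self.batch_offsets) != 2:
            raise ValidationError("exactly 2 batch offsets required")
        if self.cost <= 0:
            raise ValidationError("cost must be positive")


def _design(matrix: ExpressionMatrix, batches: BatchDesign):
    lab_lo, lab_hi = batches.require_two_batches()
    labels = np.array(batches.labels_for(matrix.sample_ids))
    y = np.where(labels == lab_hi, 1.0, -1.0)
    for lab in (lab_lo, lab_hi):
        if (labels == lab).sum() < 2:
            raise ValidationError(f"batch {lab!r} has fewer than 2 samples")
    X = matrix.values.T  # samples x genes
    if np.isnan(X).any():
        raise ValidationError("DWD requires complete values")
    return X, y, labels, (lab_lo, lab_hi)


def auto_cost(matrix: ExpressionMatrix, batches: BatchDesign) -> float:
    """Scale-free penalty: 100 over the squared median cross-batch distance."""
    X, y, _, _ = _design(matrix, batches)
    A, B = X[y < 0], X[y > 0]
    d = np.linalg.norm(A[:, None, :] - B[None, :, :], axis=2).ravel()
    med = float(np.median(d))
    if med == 0.0:
        raise ValidationError("all cross-batch distances are zero; cost undefined")
    return 100.0 / med**2


def _objective(X: np.ndarray, y: np.ndarray, C: float):
    knee = 1.0 / np.sqrt(C)

    def fun(z):
        w, b = z[:-1], z[-1]
        m = y * (X @ w + b)
        lo = m < knee
        val = np.where(lo, 2.0 * np.sqrt(C) - C * m, 1.0 / np.where(lo, 1.0, m)).sum()
        dphi = np.where(lo, -C, -1.0 / np.where(lo, 1.0, m) ** 2)
        g = np.empty_like(z)
        g[:-1] = X.T @ (dphi * y)
        g[-1] = float(np.dot(dphi, y))
        return float(val), g

    return fun


def fit_dwd(
    matrix: ExpressionMatrix, batches: BatchDesign, cost: float | str = "auto"
) -> DWDModel:
    """Fit the DWD direction between the two batches of ``matrix``.

    Orientation convention: the second batch label in sorted order is encoded
    +1 and ends up with the larger (non-negative after overall centring) mean
    projection on the returned direction.
    """
    X, y, labels, (lab_lo, lab_hi) = _design(matrix, batches)
    C = auto_cost(matrix, batches) if cost == "auto" else float(cost)
    if C <= 0:
        raise ValidationError("cost must be positive")

    mu_hi = X[y > 0].mean(axis=0)
    mu_lo = X[y < 0].mean(axis=0)
    gap = mu_hi - mu_lo
    norm = np.linalg.norm(gap)
    p = X.shape[1]
    w0 = gap / norm if norm > 0 else np.ones(p) / np.sqrt(p)
    z0 = np.append(w0, -float(w0 @ (mu_hi + mu_lo)) / 2.0)

    fun = _objective(X, y, C)

    def feasible(z):
        z = np.asarray(z, dtype=float).copy()
        norm = np.linalg.norm(z[:-1])
        if norm > 1.0:
            z[:-1] /= norm
        return z

    def value(z):
        return fun(z)[0]

    def solve_slsqp(z_start):
        return minimize(
            fun,
            z_start,
            jac=True,
            method="SLSQP",
            constraints=[
                {
                    "type": "ineq",
                    "fun": lambda z: 1.0 - float(z[:-1] @ z[:-1]),
                    "jac": lambda z: np.append(-2.0 * z[:-1], 0.0),
                }
            ],
            options={"maxiter": 2000, "ftol": 1e-14},
        )

    def solve_tc(z_start):
        con = NonlinearConstraint(
            lambda z: float(z[:-1] @ z[:-1]),
            -np.inf,
            1.0,
            jac=lambda z: np.append(2.0 * z[:-1], 0.0).reshape(1, -1),
        )
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", message="delta_grad == 0.0")
            return minimize(
                fun,
                z_start,
                jac=True,
                method="trust-constr",
                constraints=[con],
                options={"maxiter": 3000, "gtol": 1e-10, "xtol": 1e-13},
            )

    # convex problem: multi-start SLSQP plus a trust-constr polish guards
    # against line-search stalls at the piecewise-curvature knee
    shrunk = z0.copy()
    shrunk[:-1] *= 0.1
    candidates = []
    for start in (z0, shrunk):
        res = solve_slsqp(start)
        candidates.append(feasible(res.x))
    best_z = min(candidates, key=value)
    for polish in (solve_slsqp, solve_tc):
        res = polish(best_z)
        z = feasible(res.x)
        if value(z) < value(best_z):
            best_z = z
    if not np.isfinite(value(best_z)):
        raise SolverError("DWD solver failed to produce a finite objective")
    w_raw, b = best_z[:-1], float(best_z[-1])
    wnorm = float(np.linalg.norm(w_raw))
    if wnorm == 0:
        raise SolverError("DWD solver returned a zero direction")
    w = w_raw / wnorm
    # orient so the +1 (second sorted) batch has the larger mean projection
    if float((mu_hi - mu_lo) @ w) < 0:
        w, b = -w, -b
    offsets = {
        lab_lo: float(X[labels == lab_lo].mean(axis=0) @ w),
        lab_hi: float(X[labels == lab_hi].mean(axis=0) @ w),
    }
    return DWDModel(list(matrix.gene_ids), w, b, C, offsets, scale=wnorm)


def dwd_objective(model: DWDModel, matrix: ExpressionMatrix, batches: BatchDesign) -> float:
    """Evaluate the slack-eliminated DWD objective at the fitted model."""
    X, y, _, _ = _design(matrix, batches)
    fun = _objective(X, y, model.cost)
    val, _ = fun(np.append(model.scale * model.direction, model.intercept))
    return val


def dwd_adjust(
    matrix: ExpressionMatrix,
    model: DWDModel,
    batches: BatchDesign,
    reference: str | None = None,
) -> ExpressionMatrix:
    """Translate each batch along the DWD direction.

    By default both batch mean projections are moved to 0 (symmetric). With
    ``reference`` set, the other batch is moved onto the reference batch's
    mean projection and the reference batch is left untouched.
    """
    if list(model.gene_ids) != list(matrix.gene_ids):
        raise ValidationError("gene panel mismatch between model and matrix")
    labels = np.array(batches.labels_for(matrix.sample_ids))
    for lab in set(labels):
        if lab not in model.batch_offsets:
            raise ValidationError(f"batch {lab!r} unknown to the model")
    if reference is not None and reference not in model.batch_offsets:
        raise ValidationError(f"reference batch {reference!r} unknown to the model")
    w = model.direction
    X = matrix.values.T.copy()
    proj = {lab: float(X[labels == lab].mean(axis=0) @ w) for lab in set(labels)}
    target = 0.0 if reference is None else proj.get(reference, model.batch_offsets[reference])
    for lab, off in proj.items():
        X[labels == lab] -= (off - target) * w
    return ExpressionMatrix(list(matrix.gene_ids), list(matrix.sample_ids), X.T)
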