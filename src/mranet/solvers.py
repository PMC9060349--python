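"""Local response matrices from global responses.

Modular response analysis relates the observed global responses R to the
local (direct) interaction strengths r through r R = -P, where P is the
diagonal matrix of perturbation sensitivities and the diagonal of r is
normalized to -1. Two solvers are provided:

``solve_local_inverse``
    The closed form r = -[diag(R^-1)]^-1 R^-1, a single full inversion.

``solve_local_blockwise``
    For every module i, the homogeneous relations over k != i

        R[i, k] = sum_{j != i} r[i, j] R[j, k]

    form an (n-1)-dimensional linear system in the unknown row
    {r[i, j] : j != i}. The n systems are independent, are each solved by
    LU factorization with partial pivoting, and can be dispatched to
    parallel workers. Results are assembled in fixed row order, so the
    output is bit-identical for any worker count.

Both solvers force the diagonal of r to exactly -1 afterwards: it is a
definition, not an estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from joblib import Parallel, delayed

from .errors import IllConditionedError, InputError, SingularSubsystemError
from .matrices import GlobalResponseMatrix, LocalResponseMatrix

__all__ = [
    "SensitivityDiagonal",
    "SolverDiagnostics",
    "solve_local_inverse",
    "solve_local_blockwise",
    "recover_sensitivities",
]

#: Default cap on the 1-norm condition estimate of R (refuse above it).
DEFAULT_CONDITION_CAP = 1e12


@dataclass
class SensitivityDiagonal:
    """Diagonal entries P[i, i] of the sensitivity matrix in r R = -P.

    Each entry is the product of the parameter sensitivity dx_i/dp_i at the
    basal state and the relative parameter change dp_i / x_i; only the
    product is identifiable.
    """

    values: np.ndarray
    module_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise InputError("sensitivities must form a vector")
        if not self.module_ids:
            self.module_ids = [f"M{i}" for i in range(self.values.size)]

    def as_matrix(self) -> np.ndarray:
        return np.diag(self.values)


@dataclass
class SolverDiagnostics:
    """Numerical diagnostics of a blockwise solve."""

    condition_estimate: float
    pivot_warnings: int
    per_subsystem_residuals: np.ndarray

    def __post_init__(self) -> None:
        self.per_subsystem_residuals = np.asarray(self.per_subsystem_residuals, dtype=float)
        if np.any(self.per_subsystem_residuals < 0):
            raise InputError("residuals must be non-negative")

    def report(self) -> str:
        lines = [
            f"condition_estimate\t{self.condition_estimate:.6e}",
            f"pivot_warnings\t{self.pivot_warnings}",
            f"max_subsystem_residual\t{self.per_subsystem_residuals.max():.6e}",
        ]
        return "\n".join(lines) + "\n"


def _condition_estimate(values: np.ndarray) -> float:
    try:
        return float(np.linalg.cond(values, 1))
    except np.linalg.LinAlgError:
        return float("inf")


def _apply_ridge(values: np.ndarray, ridge: float) -> np.ndarray:
    if ridge < 0:
        raise InputError("ridge must be non-negative")
    if ridge == 0.0:
        return values
    return values + ridge * np.eye(values.shape[0])


def solve_local_inverse(
    R: GlobalResponseMatrix,
    condition_cap: float = DEFAULT_CONDITION_CAP,
    ridge: float = 0.0,
) -> LocalResponseMatrix:
    """Closed-form local response, r = -[diag(R^-1)]^-1 R^-1.

    Refuses ill-conditioned inputs (1-norm condition estimate above
    ``condition_cap``) instead of silently regularizing; ``ridge`` adds an
    optional diagonal term for exploratory use only.
    """
    values = _apply_ridge(R.values, ridge)
    cond = _condition_estimate(values)
    if not np.isfinite(cond) or cond > condition_cap:
        raise IllConditionedError(cond, condition_cap)
    rinv = np.linalg.inv(values)
    diag = np.diag(rinv)
    if np.any(diag == 0.0):
        raise SingularSubsystemError(int(np.argmax(diag == 0.0)))
    r = -rinv / diag[:, None]
    np.fill_diagonal(r, -1.0)
    return LocalResponseMatrix(r, list(R.module_ids))


def _solve_row(values: np.ndarray, i: int) -> tuple[np.ndarray, float, bool]:
    """Solve the (n-1)-dimensional homogeneous system for row i."""
    n = values.shape[0]
    idx = np.delete(np.arange(n), i)
    # unknowns u_j = r[i, j], equations over k != i: sum_j u_j R[j, k] = R[i, k]
    system = values[np.ix_(idx, idx)].T
    rhs = values[i, idx]
    try:
        lu, piv = scipy.linalg.lu_factor(system)
    except (scipy.linalg.LinAlgError, ValueError) as exc:  # pragma: no cover - rare path
        raise SingularSubsystemError(i) from exc
    udiag = np.abs(np.diag(lu))
    if udiag.min() == 0.0:
        raise SingularSubsystemError(i)
    pivot_warning = bool(udiag.min() < 1e-12 * udiag.max())
    row = scipy.linalg.lu_solve((lu, piv), rhs)
    if not np.all(np.isfinite(row)):
        raise SingularSubsystemError(i)
    residual = float(np.max(np.abs(system @ row - rhs))) if n > 1 else 0.0
    return row, residual, pivot_warning


def solve_local_blockwise(
    R: GlobalResponseMatrix,
    workers: int = 1,
) -> tuple[LocalResponseMatrix, SolverDiagnostics]:
    """Blockwise local response via n independent LU-factorized systems.

    Raises :class:`SingularSubsystemError` identifying the offending row if
    any subsystem is singular. The result does not depend on ``workers``.
    """
    if workers < 1:
        raise InputError("workers must be a positive count")
    values = R.values
    n = values.shape[0]
    if n < 2:
        raise InputError("at least two modules are required")

    if workers == 1:
        solved = [_solve_row(values, i) for i in range(n)]
    else:
        # LAPACK releases the GIL, so threads give real parallelism without
        # copying R; rows are reduced in fixed order (determinism contract).
        solved = Parallel(n_jobs=workers, prefer="threads")(
            delayed(_solve_row)(values, i) for i in range(n)
        )

    r = np.empty((n, n), dtype=float)
    residuals = np.empty(n, dtype=float)
    warnings = 0
    for i, (row, residual, pivot_warning) in enumerate(solved):
        idx = np.delete(np.arange(n), i)
        r[i, idx] = row
        residuals[i] = residual
        warnings += pivot_warning
    np.fill_diagonal(r, -1.0)
    diagnostics = SolverDiagnostics(
        condition_estimate=_condition_estimate(values),
        pivot_warnings=warnings,
        per_subsystem_residuals=residuals,
    )
    return LocalResponseMatrix(r, list(R.module_ids)), diagnostics


def recover_sensitivities(
    r: LocalResponseMatrix, R: GlobalResponseMatrix
) -> SensitivityDiagonal:
    """Sensitivity diagonal P from a solved r and the observed R.

    From the self-perturbation relation with r[i, i] = -1,

        R[i, i] = sum_{j != i} r[i, j] R[j, i] + P[i, i],

    so P[i, i] = R[i, i] - sum_{j != i} r[i, j] R[j, i] = -(r R)[i, i],
    consistent with r R = -P.
    """
    if r.values.shape != R.values.shape:
        raise InputError("shape mismatch between r and R")
    if r.module_ids != R.module_ids:
        raise InputError("module identifiers of r and R must match")
    p = -np.einsum("ij,ji->i", r.values, R.values)
    return SensitivityDiagonal(p, list(r.module_ids))
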