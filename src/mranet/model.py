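"""Model/results interface for modular response analysis.

`ModularResponseAnalysis` is constructed from perturbation data (or a
precomputed global response matrix) and `fit()` returns an `MRAResults`
holding the local response matrix, the sensitivity diagonal, solver
diagnostics, the CLR-pruned scores, and edge selection/evaluation helpers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import clr as _clr
from .dataset import PerturbationDataset
from .errors import InputError
from .evaluate import ConfusionTable, ReferenceNetwork, confusion
from .matrices import GlobalResponseMatrix, LocalResponseMatrix, SignedScoreMatrix
from .response import global_response
from .solvers import (
    DEFAULT_CONDITION_CAP,
    SensitivityDiagonal,
    SolverDiagnostics,
    recover_sensitivities,
    solve_local_blockwise,
    solve_local_inverse,
)

__all__ = ["ModularResponseAnalysis", "MRAResults"]


class ModularResponseAnalysis:
    """Modular response analysis of a systematic perturbation experiment.

    Parameters
    ----------
    data : PerturbationDataset, optional
        Basal and single-perturbation steady-state activities.
    response : GlobalResponseMatrix, optional
        A precomputed global response matrix, as an alternative entry
        point; exactly one of ``data`` and ``response`` must be given.

    Examples
    --------
    >>> model = ModularResponseAnalysis.from_dataframe(frame)   # doctest: +SKIP
    >>> results = model.fit(method="blockwise", workers=4)      # doctest: +SKIP
    >>> print(results.summary())                                # doctest: +SKIP
    """

    def __init__(
        self,
        data: PerturbationDataset | None = None,
        response: GlobalResponseMatrix | None = None,
    ):
        if (data is None) == (response is None):
            raise InputError("provide exactly one of data and response")
        self.data = data
        self._response = response

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        basal_label: str = "basal",
        value_scale: str = "positive_abundance",
    ) -> "ModularResponseAnalysis":
        """Build the model from a wide modules-by-conditions table."""
        return cls(PerturbationDataset.from_dataframe(frame, basal_label, value_scale))

    @property
    def global_response(self) -> GlobalResponseMatrix:
        if self._response is None:
            self._response = global_response(self.data)
        return self._response

    @property
    def module_ids(self) -> list[str]:
        return list(self.global_response.module_ids)

    def fit(
        self,
        method: str = "blockwise",
        workers: int = 1,
        condition_cap: float = DEFAULT_CONDITION_CAP,
        ridge: float = 0.0,
    ) -> "MRAResults":
        """Solve for the local response matrix.

        ``method`` is ``"blockwise"`` (n independent LU-factorized systems,
        parallelizable over ``workers``) or ``"inverse"`` (the closed-form
        full inversion, subject to ``condition_cap``).
        """
        R = self.global_response
        if method == "blockwise":
            r, diagnostics = solve_local_blockwise(R, workers=workers)
        elif method == "inverse":
            r = solve_local_inverse(R, condition_cap=condition_cap, ridge=ridge)
            diagnostics = None
        else:
            raise InputError(f"unknown method {method!r}")
        sensitivities = recover_sensitivities(r, R)
        return MRAResults(self, r, sensitivities, diagnostics, method)


class MRAResults:
    """Fitted local response matrix with diagnostics and pruning helpers."""

    def __init__(
        self,
        model: ModularResponseAnalysis,
        local_response: LocalResponseMatrix,
        sensitivities: SensitivityDiagonal,
        diagnostics: SolverDiagnostics | None,
        method: str,
    ):
        self.model = model
        self.local_response = local_response
        self.sensitivities = sensitivities
        self.diagnostics = diagnostics
        self.method = method

    @property
    def global_response(self) -> GlobalResponseMatrix:
        return self.model.global_response

    def clr_scores(self, clamp: bool = False) -> SignedScoreMatrix:
        """Signed CLR z-scores of the fitted local response matrix."""
        return _clr.clr_transform(self.local_response, clamp=clamp)

    def _score_matrix(self, use_clr: bool) -> np.ndarray:
        values = (self.clr_scores().values if use_clr else self.local_response.values).copy()
        np.fill_diagonal(values, 0.0)
        return values

    def select_edges(
        self,
        fraction: float | None = None,
        tau: float | None = None,
        use_clr: bool = True,
    ) -> _clr.EdgeSet:
        """Symmetrize scores and select edges by top fraction or by an
        absolute threshold (exactly one of the two)."""
        if (fraction is None) == (tau is None):
            raise InputError("provide exactly one of fraction and tau")
        values = self._score_matrix(use_clr)
        ids = list(self.local_response.module_ids)
        if tau is not None:
            return _clr.threshold_absolute(values, tau, ids)
        edges = _clr.symmetrize_scores(values, ids)
        return _clr.select_top_fraction(edges, fraction)

    def evaluate(
        self,
        ref: ReferenceNetwork,
        fraction: float = 0.10,
        use_clr: bool = True,
    ) -> ConfusionTable:
        """Confusion table of a top-fraction selection against a reference."""
        return confusion(self.select_edges(fraction=fraction, use_clr=use_clr), ref)

    def max_interactions(self, k: int = 10, use_clr: bool = False) -> pd.DataFrame:
        """The k strongest inferred directed interactions."""
        values = self._score_matrix(use_clr)
        ids = self.local_response.module_ids
        flat = np.argsort(-np.abs(values), axis=None)[:k]
        rows, cols = np.unravel_index(flat, values.shape)
        return pd.DataFrame(
            {
                "source": [ids[j] for j in cols],
                "target": [ids[i] for i in rows],
                "strength": values[rows, cols],
            }
        )

    def summary(self) -> str:
        """Human-readable fit summary."""
        r = self.local_response.values
        off = r[~np.eye(r.shape[0], dtype=bool)]
        p = self.sensitivities.values
        lines = [
            "Modular Response Analysis Results",
            "=" * 45,
            f"{'modules':<30}{r.shape[0]:>15}",
            f"{'solver':<30}{self.method:>15}",
            f"{'off-diagonal |r| median':<30}{np.median(np.abs(off)):>15.4g}",
            f"{'off-diagonal |r| max':<30}{np.max(np.abs(off)):>15.4g}",
            f"{'sensitivity |P| min':<30}{np.min(np.abs(p)):>15.4g}",
            f"{'sensitivity |P| max':<30}{np.max(np.abs(p)):>15.4g}",
        ]
        if self.diagnostics is not None:
            lines += [
                f"{'condition estimate (1-norm)':<30}{self.diagnostics.condition_estimate:>15.4g}",
                f"{'pivot warnings':<30}{self.diagnostics.pivot_warnings:>15}",
                f"{'max subsystem residual':<30}{self.diagnostics.per_subsystem_residuals.max():>15.4g}",
            ]
        lines.append("=" * 45)
        return "\n".join(lines)
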