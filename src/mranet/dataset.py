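"""Systematic single-module perturbation datasets.

A dataset is the raw material of modular response analysis: the activity of
every module (gene) at the unperturbed steady state, plus one steady-state
activity vector per elementary perturbation, where each perturbation
targets exactly one module. Activities are positive abundances (counts,
normalized expression) or signed consensus z-scores, which changes the
formula used to build the global response matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError

POSITIVE_ABUNDANCE = "positive_abundance"
SIGNED_ZSCORE = "signed_zscore"
VALUE_SCALES = (POSITIVE_ABUNDANCE, SIGNED_ZSCORE)


@dataclass
class PerturbationDataset:
    """Basal and single-perturbation steady-state activities.

    Parameters
    ----------
    module_ids : list of str
        Ordered identifiers of the n modules.
    basal : (n,) array
        Activity of every module in the unperturbed condition, x(p0).
    perturbed : (n, n) array
        Column k holds the steady-state activity vector under the
        elementary perturbation of module k, x(p0 + dp_k).
    value_scale : str
        ``positive_abundance`` (nonnegative expression levels) or
        ``signed_zscore`` (level-5 style consensus signatures).
    """

    module_ids: list[str]
    basal: np.ndarray
    perturbed: np.ndarray
    value_scale: str = POSITIVE_ABUNDANCE

    def __post_init__(self) -> None:
        self.module_ids = [str(m) for m in self.module_ids]
        if len(set(self.module_ids)) != len(self.module_ids):
            raise InputError("module identifiers must be unique")
        self.basal = np.asarray(self.basal, dtype=float)
        self.perturbed = np.asarray(self.perturbed, dtype=float)
        n = len(self.module_ids)
        if self.basal.shape != (n,):
            raise InputError(f"basal vector has shape {self.basal.shape}, expected ({n},)")
        if self.perturbed.shape != (n, n):
            raise InputError(
                f"perturbed matrix has shape {self.perturbed.shape}, expected ({n}, {n}); "
                "exactly one perturbation column per module is required"
            )
        if self.value_scale not in VALUE_SCALES:
            raise InputError(f"unknown value scale {self.value_scale!r}")
        if not (np.all(np.isfinite(self.basal)) and np.all(np.isfinite(self.perturbed))):
            raise InputError("activities must be finite")
        if self.value_scale == POSITIVE_ABUNDANCE and (
            np.any(self.basal < 0) or np.any(self.perturbed < 0)
        ):
            raise InputError("negative activity on the positive-abundance scale")

    @property
    def n(self) -> int:
        return len(self.module_ids)

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        basal_label: str = "basal",
        value_scale: str = POSITIVE_ABUNDANCE,
    ) -> "PerturbationDataset":
        """Build a dataset from a wide table.

        Rows are modules; one column (``basal_label``) is the unperturbed
        condition and every other column is named after the module whose
        perturbation it measures.
        """
        if basal_label not in frame.columns:
            raise InputError(f"basal column {basal_label!r} not found")
        module_ids = [str(m) for m in frame.index]
        others = [c for c in frame.columns if c != basal_label]
        missing = set(module_ids) - set(map(str, others))
        extra = set(map(str, others)) - set(module_ids)
        if missing or extra:
            raise InputError(
                "perturbation columns must map one-to-one onto module ids; "
                f"missing {sorted(missing)}, unknown {sorted(extra)}"
            )
        basal = frame[basal_label].to_numpy(dtype=float)
        perturbed = frame[module_ids].to_numpy(dtype=float)
        return cls(module_ids, basal, perturbed, value_scale)

    @classmethod
    def from_long(
        cls,
        frame: pd.DataFrame,
        basal_label: str = "basal",
        value_scale: str = POSITIVE_ABUNDANCE,
    ) -> "PerturbationDataset":
        """Build a dataset from a long table with columns
        (module, perturbation, value)."""
        required = {"module", "perturbation", "value"}
        if not required.issubset(frame.columns):
            raise InputError(f"long format requires columns {sorted(required)}")
        wide = frame.pivot_table(
            index="module", columns="perturbation", values="value", aggfunc="mean"
        )
        if wide.isna().any().any():
            raise InputError("long-format table has missing (module, perturbation) cells")
        # preserve first-appearance module order rather than pivot's sorting
        order = list(dict.fromkeys(frame["module"].astype(str)))
        wide = wide.loc[order]
        return cls.from_dataframe(wide, basal_label=basal_label, value_scale=value_scale)

    def to_frame(self, basal_label: str = "basal") -> pd.DataFrame:
        data = np.column_stack([self.basal, self.perturbed])
        return pd.DataFrame(data, index=self.module_ids, columns=[basal_label] + self.module_ids)

    def expression_panel(self, include_basal: bool = True) -> pd.DataFrame:
        """Modules-by-conditions matrix used as the sample set of the
        mutual-information baselines."""
        return self.to_frame() if include_basal else self.to_frame().drop(columns="basal")


def average_datasets(batch: list[PerturbationDataset]) -> PerturbationDataset:
    """Average raw activities across replicate datasets.

    This is the alternative to averaging per-replicate response matrices
    (see :func:`mranet.response.average_response_matrices`, the default
    replicate convention).
    """
    if not batch:
        raise InputError("empty replicate list")
    first = batch[0]
    for other in batch[1:]:
        if other.module_ids != first.module_ids:
            raise InputError("replicate datasets have mismatched module identifiers")
        if other.value_scale != first.value_scale:
            raise InputError("replicate datasets have mismatched value scales")
    basal = np.mean([d.basal for d in batch], axis=0)
    perturbed = np.mean([d.perturbed for d in batch], axis=0)
    return PerturbationDataset(first.module_ids, basal, perturbed, first.value_scale)
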