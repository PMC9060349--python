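"""Global response matrices from perturbation data.

The global response R[i, k] quantifies the relative steady-state change of
module i when module k is perturbed. On positive abundances it is computed
with the symmetric relative difference

    R[i, k] = 2 (x_i' - x_i) / (x_i' + x_i),

which is bounded in [-2, 2] and more stable than dx/x. On signed z-score
scales the denominator uses absolute values, |x_i'| + |x_i|, to avoid
divisions by values near zero with opposed signs. In both variants a 0/0
cell means "no observable change" and is defined as 0.
"""

from __future__ import annotations

import numpy as np

from .dataset import POSITIVE_ABUNDANCE, SIGNED_ZSCORE, PerturbationDataset
from .errors import InputError
from .matrices import GlobalResponseMatrix

__all__ = [
    "build_global_response",
    "build_global_response_signed_scale",
    "average_response_matrices",
]


def _relative_difference(basal: np.ndarray, perturbed: np.ndarray, signed: bool) -> np.ndarray:
    base = basal[:, None]
    num = 2.0 * (perturbed - base)
    denom = np.abs(perturbed) + np.abs(base) if signed else perturbed + base
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.where(denom == 0.0, 0.0, num / np.where(denom == 0.0, 1.0, denom))
    return values


def build_global_response(data: PerturbationDataset) -> GlobalResponseMatrix:
    """Relative-difference global response for positive abundances."""
    if data.value_scale != POSITIVE_ABUNDANCE:
        raise InputError(
            "build_global_response requires positive-abundance data; "
            "use build_global_response_signed_scale for signed z-scores"
        )
    values = _relative_difference(data.basal, data.perturbed, signed=False)
    return GlobalResponseMatrix(values, list(data.module_ids))


def build_global_response_signed_scale(data: PerturbationDataset) -> GlobalResponseMatrix:
    """Absolute-value-denominator variant for signed z-score data
    (consensus gene signatures)."""
    if data.value_scale != SIGNED_ZSCORE:
        raise InputError("build_global_response_signed_scale requires signed z-score data")
    values = _relative_difference(data.basal, data.perturbed, signed=True)
    return GlobalResponseMatrix(values, list(data.module_ids))


def global_response(data: PerturbationDataset) -> GlobalResponseMatrix:
    """Dispatch on the dataset's value scale."""
    if data.value_scale == POSITIVE_ABUNDANCE:
        return build_global_response(data)
    return build_global_response_signed_scale(data)


def average_response_matrices(batch: list[GlobalResponseMatrix]) -> GlobalResponseMatrix:
    """Entrywise mean of per-replicate (per-plate) response matrices.

    Averaging R matrices, rather than raw expression, is the default
    replicate convention; :func:`mranet.dataset.average_datasets` provides
    the raw-averaging alternative.
    """
    if not batch:
        raise InputError("empty batch of response matrices")
    first = batch[0]
    for other in batch[1:]:
        if other.module_ids != first.module_ids:
            raise InputError("response matrices have mismatched module identifiers")
    values = np.mean([m.values for m in batch], axis=0)
    return GlobalResponseMatrix(values, list(first.module_ids))
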