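"""Labeled square matrices exchanged between the inference steps.

All network-scale quantities (global response R, local response r, signed
CLR scores Z, mutual-information matrices) are square matrices indexed by
the same ordered list of module identifiers on both axes. A thin wrapper
keeps the identifiers attached to the numbers without imposing pandas on
the numerical code paths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = [
    "LabeledMatrix",
    "GlobalResponseMatrix",
    "LocalResponseMatrix",
    "SignedScoreMatrix",
]


@dataclass
class LabeledMatrix:
    """A square real matrix with module identifiers on both axes."""

    values: np.ndarray
    module_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise InputError(f"expected a square matrix, got shape {self.values.shape}")
        if not self.module_ids:
            self.module_ids = [f"M{i}" for i in range(self.values.shape[0])]
        self.module_ids = [str(m) for m in self.module_ids]
        if len(self.module_ids) != self.values.shape[0]:
            raise InputError(
                f"{len(self.module_ids)} module ids for a "
                f"{self.values.shape[0]}x{self.values.shape[1]} matrix"
            )
        if len(set(self.module_ids)) != len(self.module_ids):
            raise InputError("module identifiers must be unique")
        if not np.all(np.isfinite(self.values)):
            raise InputError("matrix entries must be finite")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.module_ids, columns=self.module_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "LabeledMatrix":
        if list(frame.index) != list(frame.columns):
            raise InputError("row and column identifiers must match")
        return cls(frame.to_numpy(dtype=float), list(frame.index))

    def same_modules(self, other: "LabeledMatrix") -> bool:
        return self.module_ids == other.module_ids


@dataclass
class GlobalResponseMatrix(LabeledMatrix):
    """Relative global responses R; R[i, k] is the effect on module i of
    perturbing module k."""


@dataclass
class LocalResponseMatrix(LabeledMatrix):
    """Direct interaction strengths r with the diagonal normalized to -1."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if not np.all(np.diag(self.values) == -1.0):
            raise InputError("the diagonal of a local response matrix must be exactly -1")


@dataclass
class SignedScoreMatrix(LabeledMatrix):
    """Sign-preserving CLR scores Z = sign(r) * sqrt(z_row^2 + z_col^2)."""
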