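"""CLR-style pruning of the local response matrix and edge selection.

The local response matrix of a large system is dense; interaction strengths
must be brought to a comparable scale before thresholding. The heuristic
adapted here from the CLR algorithm z-scores every entry against its row
and its column background,

    z_row(i, j) = (r[i, j] - mean(row i)) / sd(row i)
    z_col(i, j) = (r[i, j] - mean(col j)) / sd(col j)
    w(i, j)     = sqrt(z_row^2 + z_col^2)
    Z[i, j]     = sign(r[i, j]) * w(i, j)

without the max{0, .} clamp of the mutual-information CLR (available behind
``clamp=True``). Edge selection then symmetrizes by the dominant direction
and keeps the top fraction of unordered pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .errors import InputError
from .matrices import LabeledMatrix, LocalResponseMatrix, SignedScoreMatrix

__all__ = [
    "Edge",
    "EdgeSet",
    "clr_transform",
    "threshold_absolute",
    "symmetrize_scores",
    "select_top_fraction",
]


class Edge(NamedTuple):
    module_a: str
    module_b: str
    score: float
    sign: int = 0


@dataclass
class EdgeSet:
    """Undirected scored pairs over a module universe.

    ``edges`` holds (a, b, score, sign) with a < b in identifier order; the
    universe is the full set of n(n-1)/2 unordered pairs over
    ``module_ids`` (self-pairs excluded by construction).
    """

    edges: list[Edge]
    module_ids: list[str]
    shortfall: bool = False
    directed: bool = field(default=False)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        known = set(self.module_ids)
        for e in self.edges:
            if e.module_a == e.module_b:
                raise InputError(f"self-edge on {e.module_a!r}")
            if e.module_a > e.module_b:
                raise InputError("edges must be stored with module_a < module_b")
            if e.module_a not in known or e.module_b not in known:
                raise InputError(f"edge ({e.module_a}, {e.module_b}) outside the module universe")
            if (e.module_a, e.module_b) in seen:
                raise InputError(f"duplicate pair ({e.module_a}, {e.module_b})")
            if not math.isfinite(e.score):
                raise InputError("edge scores must be finite")
            seen.add((e.module_a, e.module_b))

    def __len__(self) -> int:
        return len(self.edges)

    def __iter__(self):
        return iter(self.edges)

    @property
    def universe_size(self) -> int:
        n = len(self.module_ids)
        return n * (n - 1) // 2

    def pairs(self) -> set[tuple[str, str]]:
        return {(e.module_a, e.module_b) for e in self.edges}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.edges, columns=["module_a", "module_b", "score", "sign"])


def clr_transform(r: LocalResponseMatrix, clamp: bool = False) -> SignedScoreMatrix:
    """Signed row/column z-score transform of the local response matrix.

    Row and column statistics run over all n entries (the -1 diagonal
    included, matching the printed definition); standard deviations use the
    n-1 denominator. A zero-variance row or column contributes z = 0.
    ``clamp=True`` floors each z at 0 before combining, as in the
    mutual-information CLR.
    """
    values = r.values
    n = values.shape[0]
    if n < 2:
        raise InputError("CLR transform needs at least two modules")
    row_mean = values.mean(axis=1, keepdims=True)
    row_sd = values.std(axis=1, ddof=1, keepdims=True)
    col_mean = values.mean(axis=0, keepdims=True)
    col_sd = values.std(axis=0, ddof=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        z_row = np.where(row_sd == 0.0, 0.0, (values - row_mean) / np.where(row_sd == 0, 1, row_sd))
        z_col = np.where(col_sd == 0.0, 0.0, (values - col_mean) / np.where(col_sd == 0, 1, col_sd))
    if clamp:
        z_row = np.maximum(z_row, 0.0)
        z_col = np.maximum(z_col, 0.0)
    w = np.sqrt(z_row**2 + z_col**2)
    return SignedScoreMatrix(np.sign(values) * w, list(r.module_ids))


def symmetrize_scores(M: LabeledMatrix | np.ndarray, module_ids: list[str] | None = None) -> EdgeSet:
    """Collapse a directed score matrix to unordered pairs.

    The pair (i, j), i < j, receives max{|M[i, j]|, |M[j, i]|}; the sign is
    taken from the dominant direction's entry. The diagonal is discarded;
    the output enumerates all n(n-1)/2 pairs.
    """
    if isinstance(M, LabeledMatrix):
        values, ids = M.values, list(M.module_ids)
    else:
        values = np.asarray(M, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise InputError("symmetrize_scores requires a square matrix")
        ids = [str(m) for m in module_ids] if module_ids else [f"M{i}" for i in range(values.shape[0])]
    n = values.shape[0]
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            fwd, bwd = values[i, j], values[j, i]
            dominant = fwd if abs(fwd) >= abs(bwd) else bwd
            a, b = sorted((ids[i], ids[j]))
            edges.append(Edge(a, b, float(max(abs(fwd), abs(bwd))), int(np.sign(dominant))))
    return EdgeSet(edges, ids)


def threshold_absolute(
    M: LabeledMatrix | np.ndarray,
    tau: float,
    module_ids: list[str] | None = None,
) -> EdgeSet:
    """Zero entries with |value| < tau, then symmetrize into an edge set."""
    if tau < 0:
        raise InputError("tau must be non-negative")
    if isinstance(M, LabeledMatrix):
        values, ids = M.values.copy(), list(M.module_ids)
    else:
        values = np.array(M, dtype=float)
        ids = [str(m) for m in module_ids] if module_ids else None
    values[np.abs(values) < tau] = 0.0
    return symmetrize_scores(values, ids)


def select_top_fraction(edges: EdgeSet, fraction: float) -> EdgeSet:
    """Keep the ceil(fraction * n(n-1)/2) highest-scoring pairs.

    Selection ranks nonzero scores only, with a deterministic tie-break
    (score descending, then identifier pair); if fewer nonzero scores exist
    than requested, all of them are returned and ``shortfall`` is set.
    """
    if not (0.0 < fraction <= 1.0):
        raise InputError("fraction must lie in (0, 1]")
    requested = math.ceil(fraction * edges.universe_size)
    candidates = [e for e in edges if e.score != 0.0]
    candidates.sort(key=lambda e: (-e.score, e.module_a, e.module_b))
    shortfall = len(candidates) < requested
    return EdgeSet(candidates[:requested], list(edges.module_ids), shortfall=shortfall)
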