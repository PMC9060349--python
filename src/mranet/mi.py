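"""Mutual-information baseline algorithms: relevance networks, CLR, MRNET,
and ARACNE.

Expression is discretized per gene, entropies are plug-in (maximum
likelihood) estimates with natural logarithms, and

    MI[i, j] = H(X_i) + H(X_j) - H(X_i, X_j).

CLR z-scores each MI against its row background (clamped at zero) and
combines the two directions as a root-sum-of-squares. MRNET runs a
maximum-relevance-minimum-redundancy forward selection per target gene.
ARACNE applies the data-processing inequality: in every triplet of nonzero
MIs, the strictly weakest edge is an indirect-interaction candidate and is
removed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InputError
from .matrices import LabeledMatrix

__all__ = [
    "BinnedExpression",
    "MIMatrix",
    "discretize",
    "mi_matrix",
    "clr_mi",
    "mrnet",
    "aracne",
]

EQUAL_FREQUENCY = "equal_frequency"
EQUAL_WIDTH = "equal_width"


@dataclass
class BinnedExpression:
    """Per-gene discretized expression; labels are integers in 1..n_bins."""

    labels: np.ndarray  # (n_genes, n_samples) int
    n_bins: int
    method: str
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.ndim != 2:
            raise InputError("binned expression must be genes x samples")
        if self.labels.min() < 1 or self.labels.max() > self.n_bins:
            raise InputError("bin labels must lie in 1..n_bins")


@dataclass
class MIMatrix:
    """Symmetric pairwise MI with per-gene entropies on the diagonal."""

    values: np.ndarray
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def n(self) -> int:
        return self.values.shape[0]


def _bin_one(x: np.ndarray, n_bins: int, method: str) -> np.ndarray:
    if method == EQUAL_FREQUENCY:
        edges = np.unique(np.quantile(x, np.linspace(0, 1, n_bins + 1))[1:-1])
    elif method == EQUAL_WIDTH:
        edges = np.unique(np.linspace(x.min(), x.max(), n_bins + 1)[1:-1])
    else:
        raise InputError(f"unknown discretization method {method!r}")
    return np.searchsorted(edges, x, side="right").astype(np.int64) + 1


def discretize(
    expr: np.ndarray | LabeledMatrix,
    n_bins: int | None = None,
    method: str = EQUAL_FREQUENCY,
    gene_ids: list[str] | None = None,
) -> BinnedExpression:
    """Independent per-gene binning of a genes-by-samples matrix.

    ``n_bins`` defaults to ceil(sqrt(m)) for m samples. A constant gene
    occupies a single bin (zero entropy), which equal-frequency binning
    handles by merging duplicate quantile edges.
    """
    if isinstance(expr, LabeledMatrix):
        gene_ids = list(expr.module_ids)
        expr = expr.values
    expr = np.asarray(expr, dtype=float)
    if expr.ndim != 2:
        raise InputError("expression must be a genes x samples matrix")
    n, m = expr.shape
    if m < 2:
        raise InputError("at least two samples are required")
    if n_bins is None:
        n_bins = math.ceil(math.sqrt(m))
    if n_bins < 2:
        raise InputError("n_bins must be at least 2")
    labels = np.vstack([_bin_one(expr[g], n_bins, method) for g in range(n)])
    ids = [str(g) for g in gene_ids] if gene_ids else [f"G{i}" for i in range(n)]
    return BinnedExpression(labels, n_bins, method, ids)


def _entropy_from_counts(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum())


def mi_matrix(binned: BinnedExpression) -> MIMatrix:
    """Plug-in pairwise MI; diagonal holds the marginal entropies H(X_i)."""
    labels = binned.labels
    n, m = labels.shape
    b = binned.n_bins
    marginals = np.array(
        [_entropy_from_counts(np.bincount(labels[i], minlength=b + 1)) for i in range(n)]
    )
    values = np.zeros((n, n), dtype=float)
    np.fill_diagonal(values, marginals)
    for i in range(n):
        base = labels[i] * (b + 1)
        for j in range(i + 1, n):
            joint = np.bincount(base + labels[j], minlength=(b + 1) ** 2)
            h_ij = _entropy_from_counts(joint)
            mi = max(marginals[i] + marginals[j] - h_ij, 0.0)
            values[i, j] = values[j, i] = mi
    return MIMatrix(values, list(binned.gene_ids))


def clr_mi(MI: MIMatrix) -> LabeledMatrix:
    """CLR normalization of an MI matrix.

    Per gene i, z_i(i, j) = max{0, (MI[i, j] - mean_i) / sd_i} with the row
    statistics over the off-diagonal entries (self-information excluded);
    the pair score is sqrt(z_i^2 + z_j^2).
    """
    values = MI.values
    n = values.shape[0]
    if n < 2:
        raise InputError("CLR needs at least two genes")
    off = values.copy()
    np.fill_diagonal(off, np.nan)
    mean = np.nanmean(off, axis=1)
    sd = np.nanstd(off, axis=1, ddof=1) if n > 2 else np.zeros(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd[:, None] == 0.0, 0.0, (values - mean[:, None]) / np.where(sd[:, None] == 0, 1, sd[:, None]))
    z = np.maximum(z, 0.0)
    scores = np.sqrt(z**2 + z.T**2)
    np.fill_diagonal(scores, 0.0)
    return LabeledMatrix(scores, list(MI.gene_ids))


def mrnet(MI: MIMatrix) -> LabeledMatrix:
    """Maximum-relevance-minimum-redundancy forward selection per target.

    For target i the first partner is argmax_j MI[i, j] with score
    MI[i, j]; each further candidate j is scored by
    MI[i, j] - mean_{k selected} MI[j, k], the best candidate is added with
    its score, and selection stops when the best score is <= 0. The
    directed score matrix is symmetrized by max.
    """
    values = MI.values
    n = values.shape[0]
    scores = np.zeros((n, n), dtype=float)
    order = np.arange(n)
    for i in range(n):
        relevance = values[i].copy()
        relevance[i] = -np.inf
        remaining = [j for j in order if j != i]
        selected: list[int] = []
        while remaining:
            if not selected:
                mrmr = [relevance[j] for j in remaining]
            else:
                mrmr = [relevance[j] - values[j, selected].mean() for j in remaining]
            best = int(np.argmax(mrmr))
            if mrmr[best] <= 0.0:
                break
            j = remaining.pop(best)
            scores[i, j] = max(mrmr[best], 0.0)
            selected.append(j)
    sym = np.maximum(scores, scores.T)
    return LabeledMatrix(sym, list(MI.gene_ids))


def aracne(MI: MIMatrix, tau: float = 0.0, eps: float = 0.0) -> LabeledMatrix:
    """Relevance network with data-processing-inequality pruning.

    Entries below ``tau`` are zeroed; then, for every triplet (i, j, k)
    whose three MIs are all nonzero, the edge (i, j) is removed when it is
    the strictly weakest, MI[i, j] < min{MI[i, k], MI[k, j]} - eps (strict
    at eps = 0, so exact three-way ties survive). All removal decisions are
    taken on the original matrix and applied at once, making the result
    order-independent. Surviving entries keep their MI values.
    """
    if tau < 0 or eps < 0:
        raise InputError("tau and eps must be non-negative")
    values = MI.values.copy()
    np.fill_diagonal(values, 0.0)
    values[values < tau] = 0.0
    nonzero = values > 0.0
    remove = np.zeros_like(nonzero)
    n = values.shape[0]
    for k in range(n):
        vk = values[:, k]
        ok = nonzero[:, k]
        # floor of the two edges through k, for every pair (i, j)
        floor = np.minimum.outer(vk, vk)
        triplet = np.logical_and.outer(ok, ok) & nonzero
        weakest = (values < floor) & (values <= floor - eps)
        remove |= triplet & weakest
    remove[np.arange(n), np.arange(n)] = False
    pruned = values.copy()
    pruned[remove | remove.T] = 0.0
    return LabeledMatrix(pruned, list(MI.gene_ids))
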