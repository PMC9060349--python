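"""Benchmarking inferred edge sets against a reference network.

Evaluation is undirected over the n(n-1)/2 unordered module pairs, because
curated references (STRING-style) and MI-based inferences carry neither
direction nor sign. Each selected edge set yields a confusion table, the
standard derived metrics, and an upper-tail hypergeometric p-value for the
significance of the overlap with the reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .clr import EdgeSet, select_top_fraction, symmetrize_scores
from .dataset import PerturbationDataset
from .errors import InputError
from .mi import aracne, clr_mi, discretize, mi_matrix, mrnet
from .response import global_response
from .solvers import solve_local_blockwise
from . import clr as _clr

__all__ = [
    "ReferenceNetwork",
    "ConfusionTable",
    "filter_reference",
    "confusion",
    "hypergeometric_pvalue",
    "compare_algorithms",
    "DEFAULT_FRACTIONS",
]

#: Uniform cross-algorithm selection levels.
DEFAULT_FRACTIONS = (0.05, 0.10, 0.20, 0.30, 0.40)


@dataclass
class ReferenceNetwork:
    """Unordered reference pairs with confidence scores in [0, 1]."""

    edges: dict[tuple[str, str], float]
    module_ids: list[str]

    def __post_init__(self) -> None:
        known = set(self.module_ids)
        normalized: dict[tuple[str, str], float] = {}
        for (a, b), score in self.edges.items():
            a, b = str(a), str(b)
            if a == b:
                raise InputError(f"self-pair on {a!r} in reference")
            if a not in known or b not in known:
                raise InputError(f"reference pair ({a}, {b}) outside the module universe")
            if not (0.0 <= score <= 1.0):
                raise InputError(f"reference score {score} outside [0, 1]")
            key = (a, b) if a < b else (b, a)
            normalized[key] = max(score, normalized.get(key, 0.0))
        self.edges = normalized

    @property
    def universe_size(self) -> int:
        n = len(self.module_ids)
        return n * (n - 1) // 2

    def pairs(self) -> set[tuple[str, str]]:
        return set(self.edges)

    def __len__(self) -> int:
        return len(self.edges)


@dataclass
class ConfusionTable:
    """Confusion counts over the pair universe plus derived metrics.

    All numbers are coupled: with a fixed reference and a fixed number of
    selected pairs, TP determines every other entry.
    """

    TP: int
    FP: int
    TN: int
    FN: int
    universe: int
    specificity: float
    accuracy: float
    precision: float
    recall: float
    pvalue: float

    def to_dict(self) -> dict:
        return dict(
            TP=self.TP, FP=self.FP, TN=self.TN, FN=self.FN, universe=self.universe,
            specificity=self.specificity, accuracy=self.accuracy,
            precision=self.precision, recall=self.recall, pvalue=self.pvalue,
        )


def filter_reference(ref: ReferenceNetwork, min_score: float) -> ReferenceNetwork:
    """Keep reference pairs with confidence strictly greater than
    ``min_score`` (the > 0, > 0.5, > 0.8 regimes)."""
    if not (0.0 <= min_score < 1.0):
        raise InputError("min_score must lie in [0, 1)")
    kept = {pair: s for pair, s in ref.edges.items() if s > min_score}
    return ReferenceNetwork(kept, list(ref.module_ids))


def hypergeometric_pvalue(overlap: int, selected: int, ref_size: int, universe: int) -> float:
    """Upper-tail P(X >= overlap), X ~ Hypergeometric(universe, ref_size,
    selected); the enrichment convention, observed overlap included."""
    if min(overlap, selected, ref_size, universe) < 0:
        raise InputError("counts must be non-negative")
    if selected > universe or ref_size > universe:
        raise InputError("selected and ref_size cannot exceed the universe")
    if overlap > min(selected, ref_size):
        raise InputError("overlap cannot exceed min(selected, ref_size)")
    return float(scipy.stats.hypergeom.sf(overlap - 1, universe, ref_size, selected))


def confusion(selected: EdgeSet, ref: ReferenceNetwork) -> ConfusionTable:
    """Confusion table of a selected edge set against the reference."""
    if sorted(selected.module_ids) != sorted(ref.module_ids):
        raise InputError("selected edges and reference cover different module universes")
    universe = ref.universe_size
    # zero-score pairs in a full symmetrized enumeration are not inferences
    sel = {(e.module_a, e.module_b) for e in selected if e.score != 0.0}
    refp = ref.pairs()
    tp = len(sel & refp)
    fp = len(sel - refp)
    fn = len(refp - sel)
    tn = universe - tp - fp - fn
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    specificity = tn / (tn + fp) if tn + fp else 0.0
    accuracy = (tp + tn) / universe if universe else 0.0
    pvalue = hypergeometric_pvalue(tp, len(sel), len(refp), universe) if universe else 1.0
    return ConfusionTable(tp, fp, tn, fn, universe, specificity, accuracy, precision, recall, pvalue)


def _algorithm_scores(
    dataset: PerturbationDataset,
    workers: int = 1,
    n_bins: int | None = None,
    aracne_tau: float = 0.0,
    aracne_eps: float = 0.0,
) -> dict[str, EdgeSet]:
    """Run every algorithm on the dataset and symmetrize to edge sets."""
    R = global_response(dataset)
    r, _ = solve_local_blockwise(R, workers=workers)
    mra_scores = r.values.copy()
    np.fill_diagonal(mra_scores, 0.0)  # the -1 diagonal is a normalization, not an inference
    z = _clr.clr_transform(r)
    z_scores = z.values.copy()
    np.fill_diagonal(z_scores, 0.0)

    panel = dataset.expression_panel()
    binned = discretize(panel.to_numpy(), n_bins=n_bins, gene_ids=list(panel.index))
    mi = mi_matrix(binned)
    ids = list(dataset.module_ids)
    return {
        "MRA": symmetrize_scores(mra_scores, ids),
        "MRA+CLR": symmetrize_scores(z_scores, ids),
        "CLR": symmetrize_scores(clr_mi(mi)),
        "MRNET": symmetrize_scores(mrnet(mi)),
        "ARACNE": symmetrize_scores(aracne(mi, tau=aracne_tau, eps=aracne_eps)),
    }


def compare_algorithms(
    dataset: PerturbationDataset,
    ref: ReferenceNetwork,
    fractions: tuple[float, ...] = DEFAULT_FRACTIONS,
    workers: int = 1,
    n_bins: int | None = None,
    aracne_tau: float = 0.0,
    aracne_eps: float = 0.0,
) -> pd.DataFrame:
    """Uniform top-fraction comparison of all algorithms on one dataset.

    Returns one row per (algorithm, fraction) with the confusion counts and
    derived metrics; an algorithm that cannot supply the requested number
    of nonzero scores at some fraction is flagged as skipped there (its
    counts are reported as missing).
    """
    scores = _algorithm_scores(
        dataset, workers=workers, n_bins=n_bins, aracne_tau=aracne_tau, aracne_eps=aracne_eps
    )
    rows = []
    for name, edge_set in scores.items():
        for fraction in fractions:
            selected = select_top_fraction(edge_set, fraction)
            row: dict = {"algorithm": name, "fraction": fraction, "skipped": selected.shortfall}
            if selected.shortfall:
                rows.append(row)
                continue
            row.update(confusion(selected, ref).to_dict())
            rows.append(row)
    return pd.DataFrame(rows)
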