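"""TSV input/output.

All files are tab-separated UTF-8 text with "." as the decimal mark:
labeled matrices (identifier column plus header row), edge lists
(module_a, module_b, score, sign), STRING-style reference lists
(node1, node2, score; a 0-1000 combined-score scale is auto-detected and
rescaled to [0, 1]), and plain-text diagnostics/provenance reports.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .clr import Edge, EdgeSet
from .errors import ParseError
from .evaluate import ReferenceNetwork

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_edge_list",
    "write_edge_list",
    "read_reference",
    "write_provenance",
]


def read_matrix(path: str | Path | _io.StringIO) -> pd.DataFrame:
    """Read a labeled matrix: first column identifiers, header row labels.

    Rejects ragged rows, duplicated identifiers, non-numeric cells and
    missing headers, reporting the 1-based offending line where possible.
    """
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0, header=0, dtype=str)
    except pd.errors.ParserError as exc:
        raise ParseError(f"malformed TSV: {exc}") from exc
    except pd.errors.EmptyDataError as exc:
        raise ParseError("empty file") from exc
    if frame.index.isna().any() or any(str(c).startswith("Unnamed") for c in frame.columns):
        raise ParseError("ragged or incomplete rows detected", line=1)
    if all(_is_number(c) for c in frame.columns):
        raise ParseError("header row appears to be numeric data; missing header?", line=1)
    dup = frame.index.duplicated()
    if dup.any():
        pos = int(np.argmax(dup))
        raise ParseError(f"duplicate identifier {frame.index[pos]!r}", line=pos + 2)
    frame.index = frame.index.map(str)
    frame.columns = frame.columns.map(str)
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & frame.notna()
    if bad.any().any():
        row = int(np.argmax(bad.any(axis=1).to_numpy()))
        col = bad.iloc[row].idxmax()
        raise ParseError(f"non-numeric cell {frame.iloc[row][col]!r} in column {col!r}", line=row + 2)
    if numeric.isna().any().any():
        row = int(np.argmax(numeric.isna().any(axis=1).to_numpy()))
        raise ParseError("missing value", line=row + 2)
    return numeric


def _is_number(token: str) -> bool:
    try:
        float(token)
    except (TypeError, ValueError):
        return False
    return True


def write_matrix(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index_label="id")


def write_edge_list(edges: EdgeSet, path: str | Path) -> None:
    edges.to_frame().to_csv(path, sep="\t", index=False)


def read_edge_list(path: str | Path, module_ids: list[str] | None = None) -> EdgeSet:
    frame = pd.read_csv(path, sep="\t", dtype={"module_a": str, "module_b": str})
    required = {"module_a", "module_b", "score"}
    if not required.issubset(frame.columns):
        raise ParseError(f"edge list requires columns {sorted(required)}", line=1)
    if "sign" not in frame.columns:
        frame["sign"] = 0
    edges = [
        Edge(*sorted((row.module_a, row.module_b)), float(row.score), int(row.sign))
        for row in frame.itertuples()
    ]
    if module_ids is None:
        module_ids = sorted({e.module_a for e in edges} | {e.module_b for e in edges})
    return EdgeSet(edges, list(module_ids))


def read_reference(
    path: str | Path | _io.StringIO,
    module_ids: list[str] | None = None,
    log=None,
) -> ReferenceNetwork:
    """Read a three-column (node1, node2, score) reference edge list.

    Scores on a STRING-style 0-1000 integer scale are detected (any score
    above 1) and divided by 1000; the rescaling is reported through ``log``.
    """
    frame = pd.read_csv(path, sep="\t")
    if frame.shape[1] < 3:
        raise ParseError("reference list requires three columns: node1, node2, score", line=1)
    node1, node2, score = frame.columns[:3]
    scores = pd.to_numeric(frame[score], errors="coerce")
    if scores.isna().any():
        row = int(np.argmax(scores.isna().to_numpy()))
        raise ParseError("non-numeric reference score", line=row + 2)
    values = scores.to_numpy(dtype=float)
    if values.max() > 1.0:
        values = values / 1000.0
        if log is not None:
            log("reference scores detected on a 0-1000 scale; rescaled to [0, 1]")
    pairs: dict[tuple[str, str], float] = {}
    for (a, b), s in zip(
        frame[[node1, node2]].astype(str).itertuples(index=False, name=None), values
    ):
        key = (a, b) if a < b else (b, a)
        pairs[key] = max(s, pairs.get(key, 0.0))
    if module_ids is None:
        module_ids = sorted({m for pair in pairs for m in pair})
    return ReferenceNetwork(pairs, list(module_ids))


def write_provenance(path: str | Path, version: str, seed: int | None, config: dict) -> None:
    """Plain-text provenance header: version, seed, configuration."""
    lines = [f"mranet_version\t{version}"]
    if seed is not None:
        lines.append(f"seed\t{seed}")
    for key in sorted(config):
        lines.append(f"{key}\t{config[key]}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
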