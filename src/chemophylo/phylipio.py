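"""PHYLIP square distance-matrix files.

Two dialects: the strict classic layout (labels padded to 10
characters) and a relaxed one (whitespace-delimited labels of any
length, the dialect actually written by default).  Reading accepts both.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from skbio import DistanceMatrix


def write_phylip_matrix(dm: DistanceMatrix, path: str | Path, strict_labels: bool = False) -> None:
    lines = [f"    {dm.shape[0]}"]
    for label, row in zip(dm.ids, dm.data):
        if strict_labels:
            name = f"{label[:10]:<10}"
        else:
            name = f"{label}  "
        lines.append(name + "  ".join(f"{v:.6f}" for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_phylip_matrix(path: str | Path, atol: float = 1e-6) -> DistanceMatrix:
    """Read a square PHYLIP distance matrix; asymmetry beyond ``atol`` is an error."""
    text = Path(path).read_text().split("\n")
    header = text[0].split()
    if not header:
        raise ValueError(f"{path}: missing taxon-count header")
    n = int(header[0])
    labels: list[str] = []
    rows: list[list[float]] = []
    tokens: list[str] = []
    for line in text[1:]:
        tokens.extend(line.split())
    idx = 0
    for _ in range(n):
        if idx >= len(tokens):
            raise ValueError(f"{path}: truncated matrix (expected {n} rows)")
        labels.append(tokens[idx])
        idx += 1
        row = [float(t) for t in tokens[idx: idx + n]]
        if len(row) != n:
            raise ValueError(f"{path}: non-square matrix row for {labels[-1]}")
        rows.append(row)
        idx += n
    D = np.asarray(rows, dtype=float)
    if np.max(np.abs(D - D.T)) > atol:
        raise ValueError(f"{path}: matrix is asymmetric beyond {atol}")
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(D, ids=labels)
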