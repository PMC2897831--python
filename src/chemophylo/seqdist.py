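"""Sequence-space distances for the receptor set.

The multiple sequence alignment is an input (typically the 7-TM domain,
optionally restricted to a binding-site column set such as the
30-residue or 44-residue selections from the literature, supplied as a
column list).  Built-in distances are the uncorrected p-distance and its
Poisson correction; the exact-reproduction route for ML protein
distances (PHYLIP Protdist, JTT) is to import the precomputed matrix via
:func:`read_phylip_matrix`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import AlignIO
from skbio import DistanceMatrix

from .phylipio import read_phylip_matrix, write_phylip_matrix  # noqa: F401  (re-export)

logger = logging.getLogger(__name__)


@dataclass
class Alignment:
    sequence_ids: list[str]
    rows: list[str]  # equal-length aligned strings, gap '-'

    def __post_init__(self) -> None:
        if len(self.sequence_ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"ragged alignment rows (lengths {sorted(lengths)})")
        if len(set(self.sequence_ids)) != len(self.sequence_ids):
            dupes = sorted({i for i in self.sequence_ids if self.sequence_ids.count(i) > 1})
            raise ValueError(f"duplicate sequence id(s): {', '.join(dupes)}")

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def __len__(self) -> int:
        return len(self.rows)


def read_alignment(path: str | Path, format: str = "fasta") -> Alignment:
    """Read a FASTA or (interleaved/sequential) PHYLIP alignment."""
    if format not in {"fasta", "phylip"}:
        raise ValueError(f"unsupported alignment format {format!r}")
    if format == "phylip":
        try:
            aln = AlignIO.read(str(path), "phylip-relaxed")
        except ValueError:
            aln = AlignIO.read(str(path), "phylip")
    else:
        aln = AlignIO.read(str(path), "fasta")
    return Alignment(
        sequence_ids=[rec.id for rec in aln],
        rows=[str(rec.seq).upper() for rec in aln],
    )


def select_columns(aln: Alignment, columns: list[int]) -> Alignment:
    """Restrict the alignment to 1-based column indices, order preserved."""
    for c in columns:
        if not 1 <= c <= aln.length:
            raise ValueError(f"column index {c} outside alignment length {aln.length}")
    return Alignment(
        sequence_ids=list(aln.sequence_ids),
        rows=["".join(row[c - 1] for c in columns) for row in aln.rows],
    )


def pairwise_distance(
    aln: Alignment, model: str = "p", max_distance: float = 10.0
) -> DistanceMatrix:
    """Pairwise p- or Poisson-corrected distances with pairwise gap deletion.

    For each pair only the columns where neither sequence has a gap are
    compared; ``p`` is the mismatch fraction and ``poisson`` is
    ``−ln(1 − p)``.  A saturated pair (p = 1) under the Poisson model is
    set to ``max_distance`` with a warning.
    """
    if model not in {"p", "poisson"}:
        raise ValueError(f"unknown distance model {model!r}")
    if len(aln) < 2:
        raise ValueError("need at least two sequences")
    arr = np.array([list(r) for r in aln.rows])
    gaps = arr == "-"
    n = len(aln)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~gaps[i] & ~gaps[j]
            m = int(ok.sum())
            if m == 0:
                raise ValueError(
                    f"no comparable columns between {aln.sequence_ids[i]} "
                    f"and {aln.sequence_ids[j]}"
                )
            p = float((arr[i, ok] != arr[j, ok]).sum()) / m
            if model == "p":
                d = p
            elif p >= 1.0:
                logger.warning(
                    "saturated pair (%s, %s): Poisson distance capped at %g",
                    aln.sequence_ids[i], aln.sequence_ids[j], max_distance,
                )
                d = max_distance
            else:
                d = -np.log(1.0 - p)
            D[i, j] = D[j, i] = d
    return DistanceMatrix(D, ids=aln.sequence_ids)
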