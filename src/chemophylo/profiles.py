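"""Substructure-frequency profiles and the ligand-space distance matrix.

The frequent patterns of all classes are merged (duplicates removed,
fragments under 50 Da discarded) and, for every class, the relative
frequency of every merged pattern is computed from a persistent
occurrence lookup table — including in classes where the pattern was not
itself frequent.  Each target's column is its substructure profile;
targets are compared by the Pearson correlation of their profiles, and
1 − r, min-max rescaled over the off-diagonal, is the ligand-space
distance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .chem_io import MoleculeGraph, TargetClass
from .mining import MiningResult, Substructure, contains_subgraph, occurrence_by_lattice

logger = logging.getLogger(__name__)


@dataclass
class FrequencyMatrix:
    """Relative frequencies of merged substructures per target class."""

    df: pd.DataFrame  # rows = canonical codes, columns = target ids

    @property
    def substructure_codes(self) -> list[str]:
        return list(self.df.index)

    @property
    def target_ids(self) -> list[str]:
        return list(self.df.columns)

    @property
    def F(self) -> np.ndarray:
        return self.df.to_numpy()

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index_label="canonical_code")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FrequencyMatrix":
        return cls(df=pd.read_csv(path, sep="\t", index_col="canonical_code"))


def occurrence_table(
    molecules: list[MoleculeGraph],
    codes: list[str],
    graphs: dict[str, Substructure] | None = None,
) -> dict[str, set[str]]:
    """Map each canonical code to the set of molecule ids containing it.

    This lookup table is computed once over *all* molecules and reused by
    profiling and by every leave-one-out round (no re-mining per orphan).
    Structurally identical molecules share one containment test each.
    """
    from collections import Counter

    from .canon import canonical_code
    from .mining import _to_networkx

    graphs = graphs or {}
    # group molecules by whole-graph canonical code: duplicates are common in
    # both screening extracts and scaffold-decorated synthetic sets
    groups: dict[str, list[str]] = {}
    rep: dict[str, MoleculeGraph] = {}
    for m in molecules:
        key = canonical_code(list(m.atoms), list(m.bonds))
        groups.setdefault(key, []).append(m.mol_id)
        rep.setdefault(key, m)

    rep_nx = {k: _to_networkx(m) for k, m in rep.items()}
    rep_atoms = {k: Counter(m.atoms) for k, m in rep.items()}
    rep_bonds = {k: Counter(lab for _, _, lab in m.bonds) for k, m in rep.items()}

    table: dict[str, set[str]] = {}
    for code in codes:
        sub = graphs.get(code) or Substructure.from_code(code)
        sub_atoms = Counter(sub.atoms)
        sub_bonds = Counter(lab for _, _, lab in sub.bonds)
        sub_nx = _to_networkx(sub)
        hits: set[str] = set()
        for key, members in groups.items():
            if any(rep_atoms[key][a] < c for a, c in sub_atoms.items()):
                continue
            if any(rep_bonds[key][b] < c for b, c in sub_bonds.items()):
                continue
            matcher = nx.algorithms.isomorphism.GraphMatcher(
                rep_nx[key],
                sub_nx,
                node_match=_element_match,
                edge_match=_order_match,
            )
            if matcher.subgraph_is_monomorphic():
                hits.update(members)
        table[code] = hits
    return table


def _element_match(a: dict, b: dict) -> bool:
    return a["element"] == b["element"]


def _order_match(a: dict, b: dict) -> bool:
    return a["order"] == b["order"]


def merge_and_profile(
    results: list[MiningResult],
    classes: list[TargetClass],
    molecules: list[MoleculeGraph],
    mw_min: float = 50.0,
    occurrence: dict[str, set[str]] | None = None,
) -> tuple[FrequencyMatrix, dict[str, set[str]]]:
    """Merge mined pattern sets and compute the frequency matrix.

    Returns the matrix together with the occurrence table it was built
    from so downstream stages can reuse the lookups.
    """
    by_target = {c.target_id: c for c in classes}
    missing = [r.target_id for r in results if r.target_id not in by_target]
    if missing:
        raise ValueError(f"mining results without a matching class: {missing}")

    graphs: dict[str, Substructure] = {}
    for res in results:
        graphs.update(res.graphs)
    merged = sorted(
        {
            code
            for res in results
            for code in res.substructures
            if (graphs.get(code) or Substructure.from_code(code)).mw >= mw_min
        }
    )
    if not merged:
        raise ValueError("no substructures survive the molecular-weight filter")
    if occurrence is None:
        if all(code in graphs for res in results for code in res.substructures):
            # mined union is downward-closed: one lattice pass beats
            # per-pair isomorphism tests by an order of magnitude
            occurrence = occurrence_by_lattice(molecules, graphs)
        else:
            occurrence = occurrence_table(molecules, merged, graphs)
    target_ids = sorted(r.target_id for r in results)
    F = np.zeros((len(merged), len(target_ids)))
    for cj, tid in enumerate(target_ids):
        members = set(by_target[tid].mol_ids)
        size = len(members)
        for ri, code in enumerate(merged):
            F[ri, cj] = len(occurrence[code] & members) / size
    fm = FrequencyMatrix(df=pd.DataFrame(F, index=merged, columns=target_ids))
    return fm, occurrence


def minmax_offdiagonal(D: np.ndarray) -> np.ndarray:
    """Linearly rescale the off-diagonal entries to [0, 1], diagonal to 0."""
    D = np.asarray(D, dtype=float).copy()
    n = D.shape[0]
    mask = ~np.eye(n, dtype=bool)
    off = D[mask]
    lo, hi = off.min(), off.max()
    if hi == lo:
        warnings.warn("all off-diagonal distances equal; normalized matrix is all zeros")
        D[mask] = 0.0
    else:
        D[mask] = (off - lo) / (hi - lo)
    np.fill_diagonal(D, 0.0)
    return D


def pearson_distance(F: FrequencyMatrix) -> DistanceMatrix:
    """Pearson-correlation distance between target profiles.

    d_raw(i, j) = 1 − r(i, j) over the merged substructure rows, then
    min-max normalized over the off-diagonal so the closest observed pair
    maps to 0 and the farthest to 1.
    """
    X = F.F
    if X.shape[1] < 2:
        raise ValueError("need at least two targets")
    sd = X.std(axis=0)
    flat = [t for t, s in zip(F.target_ids, sd) if s == 0]
    if flat:
        raise ValueError(
            f"constant substructure profile (zero variance) for target(s): {', '.join(flat)}"
        )
    r = np.corrcoef(X, rowvar=False)
    d_raw = 1.0 - r
    # numerical guard: force exact symmetry/diagonal before rescaling
    d_raw = (d_raw + d_raw.T) / 2.0
    np.fill_diagonal(d_raw, 0.0)
    D = minmax_offdiagonal(d_raw)
    return DistanceMatrix(D, ids=F.target_ids)
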