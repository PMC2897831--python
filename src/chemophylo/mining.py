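"""Frequent connected-subgraph mining over a ligand class.

The miner finds every connected labeled subgraph occurring in at least a
minimum fraction of a class's molecules (support counted once per
molecule, not per embedding).  The search is level-wise a-priori: single
atoms seed the search and every stored pattern is extended edge-by-edge,
so no extension of an infrequent pattern is ever generated.  Patterns are
deduplicated by canonical code; support is counted through embedding
lists that are extended along with the patterns, which makes the output
independent of the input molecule order (the bond-count sort the search
applies is a memory optimisation only).

An exhaustive enumeration oracle (`enumerate_all_subgraphs`) provides an
independent route to the same answer on small molecules and backs the
correctness tests.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from functools import cached_property

import networkx as nx
from rdkit import Chem
from sklearn.base import BaseEstimator, TransformerMixin

from .canon import canonical_code, decode_code
from .chem_io import MoleculeGraph

logger = logging.getLogger(__name__)

_BOND_ORDER = {"single": 1.0, "double": 2.0, "triple": 3.0, "aromatic": 1.5}

_PT = Chem.GetPeriodicTable()


@dataclass(frozen=True)
class Substructure:
    """A connected labeled subgraph identified by its canonical code."""

    atoms: tuple[str, ...]
    bonds: tuple[tuple[int, int, str], ...]

    @cached_property
    def canonical_code(self) -> str:
        return canonical_code(self.atoms, self.bonds)

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    @cached_property
    def mw(self) -> float:
        return substructure_mw(self)

    @classmethod
    def from_code(cls, code: str) -> "Substructure":
        atoms, bonds = decode_code(code)
        return cls(atoms=tuple(atoms), bonds=tuple(bonds))


@dataclass
class MiningResult:
    """Frequent substructures of one target class."""

    target_id: str
    substructures: dict[str, int]  # canonical code -> per-molecule support
    min_support_abs: int
    n_molecules: int
    capped: bool = False
    graphs: dict[str, Substructure] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.substructures)


def absolute_support(fraction: float, n: int) -> int:
    """ceil(fraction*n) with a guard against binary-float overshoot."""
    return max(1, math.ceil(fraction * n - 1e-9))


def substructure_mw(sub: Substructure | MoleculeGraph) -> float:
    """Molecular weight of a fragment, hydrogen-completed.

    Implicit hydrogens per atom = standard valence minus the sum of
    explicit bond orders (aromatic counts 1.5, fractional totals are
    floored), clamped at zero.  A lone O therefore weighs as water, a
    C–C fragment as ethane.
    """
    orders = [0.0] * len(sub.atoms)
    for i, j, lab in sub.bonds:
        orders[i] += _BOND_ORDER[lab]
        orders[j] += _BOND_ORDER[lab]
    mass = 0.0
    h_mass = _PT.GetAtomicWeight("H")
    for symbol, used in zip(sub.atoms, orders):
        try:
            w = _PT.GetAtomicWeight(symbol)
        except Exception as exc:
            raise ValueError(f"unknown element {symbol!r}") from exc
        if w == 0.0 and symbol != "*":
            raise ValueError(f"unknown element {symbol!r}")
        valence = _PT.GetDefaultValence(symbol)
        n_h = max(0, math.floor(valence - used + 1e-9)) if valence > 0 else 0
        mass += w + n_h * h_mass
    return mass


def _to_networkx(g: Substructure | MoleculeGraph) -> nx.Graph:
    G = nx.Graph()
    for idx, symbol in enumerate(g.atoms):
        G.add_node(idx, element=symbol)
    for i, j, lab in g.bonds:
        G.add_edge(i, j, order=lab)
    return G


def _label_counts(g: Substructure | MoleculeGraph) -> tuple[Counter, Counter]:
    return Counter(g.atoms), Counter(lab for _, _, lab in g.bonds)


def contains_subgraph(mol: MoleculeGraph, sub: Substructure) -> bool:
    """Label-preserving subgraph (monomorphism) containment test.

    Counts per molecule: any number of embeddings is one hit.
    """
    mol_atoms, mol_bonds = _label_counts(mol)
    sub_atoms, sub_bonds = _label_counts(sub)
    if any(mol_atoms[a] < c for a, c in sub_atoms.items()):
        return False
    if any(mol_bonds[b] < c for b, c in sub_bonds.items()):
        return False
    matcher = nx.algorithms.isomorphism.GraphMatcher(
        _to_networkx(mol),
        _to_networkx(sub),
        node_match=lambda a, b: a["element"] == b["element"],
        edge_match=lambda a, b: a["order"] == b["order"],
    )
    return matcher.subgraph_is_monomorphic()


class FrequentSubgraphMiner(BaseEstimator, TransformerMixin):
    """Frequent connected-subgraph miner (a-priori, canonical-code dedup).

    Parameters
    ----------
    min_support_fraction : float, default 0.30
        Minimum fraction of the fitted molecules a pattern must occur in;
        the absolute threshold is ``ceil(fraction * n_molecules)``.
    max_bonds : int or None
        Optional hard cap on pattern size, mainly for bounded test runs.

    Attributes
    ----------
    substructures_ : dict[str, Substructure]
        Canonical code -> pattern graph for every frequent pattern
        (single atoms included; downstream stages apply the 50 Da filter).
    supports_ : dict[str, int]
        Canonical code -> number of molecules containing the pattern.
    min_support_abs_ : int
    n_molecules_ : int
    """

    def __init__(self, min_support_fraction: float = 0.30, max_bonds: int | None = None):
        self.min_support_fraction = min_support_fraction
        self.max_bonds = max_bonds

    def fit(self, X: list[MoleculeGraph], y=None) -> "FrequentSubgraphMiner":
        if not X:
            raise ValueError("cannot mine an empty molecule list")
        if not 0 < self.min_support_fraction <= 1:
            raise ValueError("min_support_fraction must be in (0, 1]")
        n = len(X)
        minsup = absolute_support(self.min_support_fraction, n)
        # ascending bond-count order: prunes large rare patterns early.
        # Semantics are order-independent; this is the memory optimisation.
        molecules = sorted(X, key=lambda m: m.n_bonds)
        adj: list[list[list[tuple[int, str]]]] = []
        for m in molecules:
            a: list[list[tuple[int, str]]] = [[] for _ in m.atoms]
            for i, j, lab in m.bonds:
                a[i].append((j, lab))
                a[j].append((i, lab))
            adj.append(a)

        # level 0: single atoms, all embeddings
        frontier: dict[str, tuple[Substructure, list[tuple[int, tuple[int, ...]]]]] = {}
        for mi, m in enumerate(molecules):
            for vi, symbol in enumerate(m.atoms):
                code = f"{symbol}()"
                if code not in frontier:
                    frontier[code] = (Substructure(atoms=(symbol,), bonds=()), [])
                frontier[code][1].append((mi, (vi,)))
        frontier = {
            c: pe for c, pe in frontier.items()
            if len({mi for mi, _ in pe[1]}) >= minsup
        }

        substructures: dict[str, Substructure] = {}
        supports: dict[str, int] = {}
        for code, (pat, emb) in frontier.items():
            substructures[code] = pat
            supports[code] = len({mi for mi, _ in emb})

        while frontier:
            next_frontier: dict[str, tuple[Substructure, list[tuple[int, tuple[int, ...]]]]] = {}
            for code, (pat, embeddings) in frontier.items():
                if self.max_bonds is not None and pat.n_bonds >= self.max_bonds:
                    continue
                existing = set()
                for i, j, lab in pat.bonds:
                    existing.add((i, j))
                # collect distinct one-edge extension descriptors over embeddings
                descriptors: set[tuple] = set()
                for mi, mapping in embeddings:
                    pos = {v: k for k, v in enumerate(mapping)}
                    for k, v in enumerate(mapping):
                        for u, lab in adj[mi][v]:
                            if u in pos:
                                k2 = pos[u]
                                e = (min(k, k2), max(k, k2))
                                if e not in existing:
                                    descriptors.add(("close", e[0], e[1], lab))
                            else:
                                descriptors.add(("grow", k, molecules[mi].atoms[u], lab))
                for desc in descriptors:
                    child, child_code = self._apply_descriptor(pat, desc)
                    if child_code in next_frontier or child_code in substructures:
                        continue
                    child_emb = self._extend_embeddings(
                        desc, embeddings, molecules, adj
                    )
                    support = len({mi for mi, _ in child_emb})
                    if support < minsup:
                        continue
                    next_frontier[child_code] = (child, child_emb)
                    substructures[child_code] = child
                    supports[child_code] = support
            frontier = next_frontier

        self.substructures_ = substructures
        self.supports_ = supports
        self.min_support_abs_ = minsup
        self.n_molecules_ = n
        return self

    @staticmethod
    def _apply_descriptor(pat: Substructure, desc: tuple) -> tuple[Substructure, str]:
        if desc[0] == "close":
            _, i, j, lab = desc
            child = Substructure(atoms=pat.atoms, bonds=pat.bonds + ((i, j, lab),))
        else:
            _, k, symbol, lab = desc
            new_idx = len(pat.atoms)
            child = Substructure(
                atoms=pat.atoms + (symbol,), bonds=pat.bonds + ((k, new_idx, lab),)
            )
        return child, child.canonical_code

    @staticmethod
    def _extend_embeddings(desc, embeddings, molecules, adj):
        out = set()
        if desc[0] == "close":
            _, i, j, lab = desc
            for mi, mapping in embeddings:
                for u, bond_lab in adj[mi][mapping[i]]:
                    if u == mapping[j] and bond_lab == lab:
                        out.add((mi, mapping))
                        break
        else:
            _, k, symbol, lab = desc
            for mi, mapping in embeddings:
                mapped = set(mapping)
                for u, bond_lab in adj[mi][mapping[k]]:
                    if bond_lab == lab and u not in mapped and molecules[mi].atoms[u] == symbol:
                        out.add((mi, mapping + (u,)))
        return sorted(out)

    def transform(self, X: list[MoleculeGraph]):
        """Binary presence matrix (molecules x frequent patterns).

        Columns follow sorted canonical-code order.
        """
        import numpy as np

        codes = sorted(self.substructures_)
        M = np.zeros((len(X), len(codes)), dtype=float)
        for r, mol in enumerate(X):
            for c, code in enumerate(codes):
                if contains_subgraph(mol, self.substructures_[code]):
                    M[r, c] = 1.0
        return M


def mine_frequent(
    molecules: list[MoleculeGraph],
    min_support_fraction: float = 0.30,
    target_id: str = "",
) -> MiningResult:
    """Mine one class; thin wrapper over :class:`FrequentSubgraphMiner`."""
    miner = FrequentSubgraphMiner(min_support_fraction=min_support_fraction).fit(molecules)
    return MiningResult(
        target_id=target_id,
        substructures=dict(miner.supports_),
        min_support_abs=miner.min_support_abs_,
        n_molecules=miner.n_molecules_,
        graphs=dict(miner.substructures_),
    )


def enumerate_all_subgraphs(
    mol: MoleculeGraph, max_bonds: int, max_atoms_guard: int = 14
) -> set[str]:
    """Exhaustive oracle: every connected subgraph up to ``max_bonds``.

    Brute-force state expansion over (vertex set, edge set) pairs with no
    a-priori reasoning; intended for small molecules only (the guard
    rejects inputs above ``max_atoms_guard`` heavy atoms).
    """
    if mol.n_atoms > max_atoms_guard:
        raise ValueError(
            f"molecule has {mol.n_atoms} atoms, oracle guard is {max_atoms_guard}"
        )
    bonds = list(mol.bonds)
    adj: dict[int, list[tuple[int, int]]] = {i: [] for i in range(mol.n_atoms)}
    for bi, (i, j, _lab) in enumerate(bonds):
        adj[i].append((j, bi))
        adj[j].append((i, bi))

    codes: set[str] = set()
    seen_states: set[tuple[frozenset, frozenset]] = set()
    stack: list[tuple[frozenset, frozenset]] = []
    for v in range(mol.n_atoms):
        state = (frozenset([v]), frozenset())
        stack.append(state)
        seen_states.add(state)
        codes.add(f"{mol.atoms[v]}()")
    while stack:
        verts, edges = stack.pop()
        if len(edges) >= max_bonds:
            continue
        for v in verts:
            for u, bi in adj[v]:
                if bi in edges:
                    continue
                if u in verts:
                    new_state = (verts, edges | {bi})
                else:
                    new_state = (verts | {u}, edges | {bi})
                if new_state in seen_states:
                    continue
                seen_states.add(new_state)
                stack.append(new_state)
                vlist = sorted(new_state[0])
                vmap = {v2: k for k, v2 in enumerate(vlist)}
                sub = Substructure(
                    atoms=tuple(mol.atoms[v2] for v2 in vlist),
                    bonds=tuple(
                        (vmap[bonds[b][0]], vmap[bonds[b][1]], bonds[b][2])
                        for b in sorted(new_state[1])
                    ),
                )
                codes.add(sub.canonical_code)
    return codes


def occurrence_by_lattice(
    molecules: list[MoleculeGraph], graphs: dict[str, Substructure]
) -> dict[str, set[str]]:
    """Occurrence sets for a *downward-closed* pattern collection.

    One embedding-extension pass over all molecules, walking only the
    given pattern lattice: every pattern's embeddings are grown from a
    one-bond-smaller parent, which must also be in ``graphs`` (true for
    any union of per-class frequent sets, with or without the dominance
    cap, by a-priori closure).  Far faster than per-pair isomorphism
    tests; results are identical to :func:`contains_subgraph`.
    """
    by_level: dict[int, set[str]] = {}
    for code, g in graphs.items():
        by_level.setdefault(g.n_bonds, set()).add(code)
    adj: list[list[list[tuple[int, str]]]] = []
    for m in molecules:
        a: list[list[tuple[int, str]]] = [[] for _ in m.atoms]
        for i, j, lab in m.bonds:
            a[i].append((j, lab))
            a[j].append((i, lab))
        adj.append(a)

    table: dict[str, set[str]] = {code: set() for code in graphs}
    frontier: dict[str, tuple[Substructure, list[tuple[int, tuple[int, ...]]]]] = {}
    for code in by_level.get(0, ()):
        pat = graphs[code]
        emb = [
            (mi, (vi,))
            for mi, m in enumerate(molecules)
            for vi, symbol in enumerate(m.atoms)
            if symbol == pat.atoms[0]
        ]
        frontier[code] = (pat, emb)
        table[code] = {molecules[mi].mol_id for mi, _ in emb}

    level = 0
    max_level = max(by_level) if by_level else 0
    while level < max_level:
        level += 1
        wanted = by_level.get(level, set())
        next_frontier: dict[str, tuple[Substructure, list[tuple[int, tuple[int, ...]]]]] = {}
        for _code, (pat, embeddings) in frontier.items():
            existing = {(i, j) for i, j, _lab in pat.bonds}
            descriptors: set[tuple] = set()
            for mi, mapping in embeddings:
                pos = {v: k for k, v in enumerate(mapping)}
                for k, v in enumerate(mapping):
                    for u, lab in adj[mi][v]:
                        if u in pos:
                            k2 = pos[u]
                            e = (min(k, k2), max(k, k2))
                            if e not in existing:
                                descriptors.add(("close", e[0], e[1], lab))
                        else:
                            descriptors.add(("grow", k, molecules[mi].atoms[u], lab))
            for desc in descriptors:
                child, child_code = FrequentSubgraphMiner._apply_descriptor(pat, desc)
                if child_code not in wanted or child_code in next_frontier:
                    continue
                child_emb = FrequentSubgraphMiner._extend_embeddings(
                    desc, embeddings, molecules, adj
                )
                next_frontier[child_code] = (child, child_emb)
                table[child_code] = {molecules[mi].mol_id for mi, _ in child_emb}
        frontier = next_frontier
    return table


def apply_dominance_cap(
    results: list[MiningResult],
    abs_cap: int = 1_000_000,
    ratio_cap: float = 1000.0,
) -> list[MiningResult]:
    """Stop any single class from dominating the merged substructure set.

    A class whose pattern count exceeds ``abs_cap``, or exceeds
    ``ratio_cap`` times the median count of the *other* classes, keeps
    only the patterns that also occur in at least one other class.
    """
    import statistics

    if len(results) < 2:
        raise ValueError("dominance cap needs at least two classes")
    capped_results = []
    for idx, res in enumerate(results):
        other_counts = [len(r) for k, r in enumerate(results) if k != idx]
        median_other = statistics.median(other_counts)
        if len(res) > abs_cap or (median_other > 0 and len(res) > ratio_cap * median_other):
            shared = set()
            for k, r in enumerate(results):
                if k != idx:
                    shared.update(r.substructures)
            kept = {c: s for c, s in res.substructures.items() if c in shared}
            if not kept:
                logger.warning(
                    "dominance cap left class %s with zero substructures", res.target_id
                )
            logger.info(
                "dominance cap: class %s reduced from %d to %d substructures",
                res.target_id, len(res), len(kept),
            )
            capped_results.append(
                MiningResult(
                    target_id=res.target_id,
                    substructures=kept,
                    min_support_abs=res.min_support_abs,
                    n_molecules=res.n_molecules,
                    capped=True,
                    graphs={c: g for c, g in res.graphs.items() if c in kept},
                )
            )
        else:
            capped_results.append(res)
    return capped_results
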