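"""Canonical codes for small labeled molecular graphs.

A substructure is a connected undirected graph with atom labels (element
symbols) and bond labels (``single``/``double``/``triple``/``aromatic``).
Two substructures are the same pattern iff they are isomorphic as labeled
graphs, so every pattern needs an order-independent string key.

The code produced here is a minimal connected-construction code: vertices
are emitted one at a time, each (after the first) attached to previously
emitted vertices, and the lexicographically smallest token sequence over
all valid emission orders is the canonical code.  A Weisfeiler-Lehman
color refinement restricts the starting vertices and prunes the
backtracking, which keeps the search fast for molecule-sized graphs
(automorphism-bounded branching in practice).

The code string is self-describing and can be decoded back into
``(atoms, bonds)`` with :func:`decode_code`.
"""

from __future__ import annotations

import re
from typing import Sequence

Bond = tuple[int, int, str]

BOND_CHARS = {"single": "s", "double": "d", "triple": "t", "aromatic": "a"}
CHAR_BONDS = {v: k for k, v in BOND_CHARS.items()}

_TOKEN_RE = re.compile(r"^([A-Za-z*][a-z]?)\(([^)]*)\)$")
_EDGE_RE = re.compile(r"^(\d+)([sdta])$")


def _adjacency(n: int, bonds: Sequence[Bond]) -> list[list[tuple[int, str]]]:
    adj: list[list[tuple[int, str]]] = [[] for _ in range(n)]
    for i, j, lab in bonds:
        if i == j:
            raise ValueError(f"self-loop on atom {i}")
        adj[i].append((j, lab))
        adj[j].append((i, lab))
    return adj


def _refine_colors(atoms: Sequence[str], adj: list[list[tuple[int, str]]]) -> list[int]:
    """Iterated 1-WL color refinement; returns isomorphism-invariant ranks."""
    sigs: list = [(a,) for a in atoms]
    ranks = _rank(sigs)
    while True:
        new_sigs = [
            (ranks[v], tuple(sorted((lab, ranks[u]) for u, lab in adj[v])))
            for v in range(len(atoms))
        ]
        new_ranks = _rank(new_sigs)
        if new_ranks == ranks:
            return ranks
        ranks = new_ranks


def _rank(sigs: list) -> list[int]:
    order = {s: i for i, s in enumerate(sorted(set(sigs)))}
    return [order[s] for s in sigs]


def canonical_code(atoms: Sequence[str], bonds: Sequence[Bond]) -> str:
    """Return the canonical string code of a connected labeled graph.

    Invariant under any permutation of the vertex numbering; raises
    ``ValueError`` for disconnected or empty graphs.
    """
    n = len(atoms)
    if n == 0:
        raise ValueError("empty graph has no canonical code")
    adj = _adjacency(n, bonds)
    if n == 1:
        return f"{atoms[0]}()"
    colors = _refine_colors(atoms, adj)

    # start from every vertex achieving the minimal (label, color) key
    start_key = min((atoms[v], colors[v]) for v in range(n))
    starts = [v for v in range(n) if (atoms[v], colors[v]) == start_key]

    best: list | None = None

    def extend(pos: dict[int, int], tokens: list, tight: bool) -> None:
        """DFS over emission orders; only minimal-token candidates are expanded.

        ``tight`` is True while the current token prefix equals the best-known
        prefix, which is the only case where position-wise pruning is sound.
        """
        nonlocal best
        k = len(tokens)
        if k == n:
            if best is None or tokens < best:
                best = list(tokens)
            return
        cand = {}
        for v in range(n):
            if v in pos:
                continue
            back = tuple(sorted((pos[u], lab) for u, lab in adj[v] if u in pos))
            if back:
                cand[v] = (back, atoms[v], colors[v])
        if not cand:
            raise ValueError("graph is not connected")
        tok_min = min(cand.values())
        child_tight = tight
        if best is not None and tight:
            if tok_min > best[k]:
                return
            if tok_min < best[k]:
                child_tight = False
        for v, tok in cand.items():
            if tok != tok_min:
                continue
            pos[v] = k
            tokens.append(tok)
            extend(pos, tokens, child_tight)
            tokens.pop()
            del pos[v]

    for s in starts:
        first = ((), atoms[s], colors[s])
        tight = best is not None and first == best[0]
        extend({s: 0}, [first], tight)
    assert best is not None
    return "|".join(
        f"{label}({','.join(f'{p}{BOND_CHARS[lab]}' for p, lab in back)})"
        for back, label, _color in best
    )


def decode_code(code: str) -> tuple[list[str], list[Bond]]:
    """Inverse of :func:`canonical_code`: rebuild ``(atoms, bonds)``."""
    atoms: list[str] = []
    bonds: list[Bond] = []
    for k, token in enumerate(code.split("|")):
        m = _TOKEN_RE.match(token)
        if not m:
            raise ValueError(f"malformed code token {token!r}")
        atoms.append(m.group(1))
        if m.group(2):
            for edge in m.group(2).split(","):
                em = _EDGE_RE.match(edge)
                if not em:
                    raise ValueError(f"malformed edge {edge!r} in token {token!r}")
                p = int(em.group(1))
                if p >= k:
                    raise ValueError(f"forward edge reference in token {token!r}")
                bonds.append((p, k, CHAR_BONDS[em.group(2)]))
    return atoms, bonds
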