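"""Shared fixtures: tiny molecules, random labeled graphs, random additive
trees, and the planted-family benchmark dataset (built once per session)."""

from __future__ import annotations

import numpy as np
import pytest
from skbio import DistanceMatrix, TreeNode

import chemophylo as cp
from chemophylo.chem_io import ActivityRecord, MoleculeGraph, molecule_from_smiles


@pytest.fixture
def smi():
    """SMILES -> MoleculeGraph helper."""

    def _make(smiles: str, mol_id: str | None = None) -> MoleculeGraph:
        g = molecule_from_smiles(smiles, mol_id or smiles)
        assert g is not None, f"fixture SMILES failed to parse: {smiles}"
        return g

    return _make


def random_molecule(rng: np.random.Generator, mol_id: str, max_atoms: int = 10) -> MoleculeGraph:
    """Random connected labeled graph (not necessarily valid chemistry).

    A random spanning tree plus at most one extra edge, atom labels from
    {C, N, O}, bond labels from {single, double, aromatic}; the miner and
    its oracle operate on labeled graphs, so chemical validity is not
    required.
    """
    n = int(rng.integers(4, max_atoms + 1))
    atoms = tuple(rng.choice(["C", "C", "C", "N", "O"]) for _ in range(n))
    bond_labels = ["single", "single", "double", "aromatic"]
    bonds = []
    for v in range(1, n):
        u = int(rng.integers(v))
        bonds.append((u, v, bond_labels[int(rng.integers(len(bond_labels)))]))
    if n >= 4 and rng.random() < 0.5:
        existing = {(i, j) for i, j, _ in bonds}
        for _ in range(4):
            i, j = sorted(rng.choice(n, size=2, replace=False).tolist())
            if (i, j) not in existing:
                bonds.append((i, j, bond_labels[int(rng.integers(len(bond_labels)))]))
                break
    return MoleculeGraph(mol_id=mol_id, atoms=atoms, bonds=tuple(sorted(bonds)), mw=0.0)


def random_additive_tree(
    rng: np.random.Generator, n: int
) -> tuple[TreeNode, DistanceMatrix]:
    """Random unrooted binary tree with positive lengths and its path metric."""
    leaves = [TreeNode(name=f"L{i}") for i in range(n)]
    pool = list(leaves)
    while len(pool) > 3:
        idx = sorted(rng.choice(len(pool), size=2, replace=False).tolist(), reverse=True)
        b, a = pool.pop(idx[0]), pool.pop(idx[1])
        a.length = float(rng.uniform(0.1, 2.0))
        b.length = float(rng.uniform(0.1, 2.0))
        pool.append(TreeNode(children=[a, b]))
    for node in pool:
        node.length = float(rng.uniform(0.1, 2.0))
    tree = TreeNode(children=pool)
    td = tree.tip_tip_distances()
    ids = [f"L{i}" for i in range(n)]
    D = np.array([[td[a, b] if a != b else 0.0 for b in ids] for a in ids])
    return tree, DistanceMatrix(D, ids=ids)


def bipartitions(tree: TreeNode) -> set[frozenset]:
    """Non-trivial bipartitions of an (un)rooted tree, reference-leaf normalized."""
    tips = sorted(t.name for t in tree.tips())
    ref, full = tips[0], frozenset(tips)
    out = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = full - side
        if 1 < len(side) < len(full) - 1:
            out.add(side)
    return out


@pytest.fixture(scope="session")
def benchmark():
    """Planted 4x4x30 benchmark taken through mining, profiling and distances."""
    spec = cp.SyntheticSpec(seed=7)
    molecules, activity = cp.generate_ligands(spec)
    records = [
        ActivityRecord(r.mol_id, r.target_id, r.activity_type, r.activity_value_uM)
        for r in activity.itertuples(index=False)
    ]
    classes = cp.build_classes(records, molecules)
    by_id = {m.mol_id: m for m in molecules}
    results = [
        cp.mine_frequent([by_id[m] for m in c.mol_ids], 0.30, target_id=c.target_id)
        for c in classes
    ]
    results = cp.apply_dominance_cap(results)
    F, occurrence = cp.merge_and_profile(results, classes, molecules)
    Dlig = cp.pearson_distance(F)
    alignment = cp.generate_alignment(spec)
    Dseq = cp.pairwise_distance(alignment, model="poisson")
    return {
        "spec": spec,
        "molecules": molecules,
        "classes": classes,
        "results": results,
        "F": F,
        "occurrence": occurrence,
        "Dlig": Dlig,
        "Dseq": Dseq,
        "alignment": alignment,
        "truth": cp.planted_truth(spec),
    }
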