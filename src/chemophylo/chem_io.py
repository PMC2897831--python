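"""Ligand structures, activity tables and per-target ligand classes.

Molecules are held as plain labeled graphs: atom nodes carry element
symbols, bonds carry one of four order labels with a dedicated
``aromatic`` type, hydrogens are implicit.  Charges, isotopes and
stereochemistry are deliberately dropped — the substructure miner works
on element/bond labels only.  Multi-fragment inputs (salts) keep the
largest fragment so every molecule is a connected graph.

Dataset assembly applies the standard potency filters: a ligand is
active below 10 µM (Ki/IC50/EC) or when the source reports an affinity
without a value, molecular weight must lie in [50, 700] Da, and a target
needs at least 20 surviving ligands to form a class.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")

_BOND_LABELS = {
    Chem.BondType.SINGLE: "single",
    Chem.BondType.DOUBLE: "double",
    Chem.BondType.TRIPLE: "triple",
    Chem.BondType.AROMATIC: "aromatic",
}

ACTIVITY_COLUMNS = ("mol_id", "target_id", "activity_type", "activity_value_uM")


@dataclass(frozen=True)
class MoleculeGraph:
    """Connected labeled graph of one ligand (implicit hydrogens)."""

    mol_id: str
    atoms: tuple[str, ...]
    bonds: tuple[tuple[int, int, str], ...]
    mw: float

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)


@dataclass(frozen=True)
class ActivityRecord:
    mol_id: str
    target_id: str
    activity_type: str
    activity_value_uM: float | None  # None = source-declared active

    def __post_init__(self) -> None:
        if self.activity_value_uM is not None and not self.activity_value_uM > 0:
            raise ValueError(
                f"activity value must be positive, got {self.activity_value_uM}"
            )


@dataclass
class TargetClass:
    target_id: str
    mol_ids: tuple[str, ...]  # ordered, unique

    def __len__(self) -> int:
        return len(self.mol_ids)


def molecule_from_rdkit(mol: Chem.Mol, mol_id: str) -> MoleculeGraph:
    """Convert an RDKit molecule, keeping only its largest fragment."""
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) > 1:
        mol = max(frags, key=lambda f: f.GetNumAtoms())
    atoms = tuple(a.GetSymbol() for a in mol.GetAtoms())
    bonds = []
    for b in mol.GetBonds():
        label = _BOND_LABELS.get(b.GetBondType(), "single")
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        bonds.append((min(i, j), max(i, j), label))
    return MoleculeGraph(
        mol_id=mol_id, atoms=atoms, bonds=tuple(sorted(bonds)), mw=Descriptors.MolWt(mol)
    )


def molecule_from_smiles(smiles: str, mol_id: str) -> MoleculeGraph | None:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    return molecule_from_rdkit(mol, mol_id)


def parse_molecules(path: str | Path, format: str = "smiles") -> list[MoleculeGraph]:
    """Read ligands from a SMILES (.smi) or SDF file.

    Invalid records are skipped with a warning; an unreadable file or a
    file with zero valid records is a fatal error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    molecules: list[MoleculeGraph] = []
    n_skipped = 0
    if format == "smiles":
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            mol_id = parts[1] if len(parts) > 1 else str(lineno)
            g = molecule_from_smiles(parts[0], mol_id)
            if g is None:
                n_skipped += 1
                logger.warning("skipping unparsable SMILES at line %d: %s", lineno, parts[0])
                continue
            molecules.append(g)
    elif format == "sdf":
        supplier = Chem.SDMolSupplier(str(path), sanitize=True)
        for idx, mol in enumerate(supplier):
            if mol is None:
                n_skipped += 1
                logger.warning("skipping unparsable SDF record %d", idx)
                continue
            name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
            molecules.append(molecule_from_rdkit(mol, name.strip() or str(idx)))
    else:
        raise ValueError(f"unsupported format {format!r} (use 'smiles' or 'sdf')")
    if not molecules:
        raise ValueError(f"no valid molecule records in {path}")
    if n_skipped:
        logger.warning("%d invalid records skipped in %s", n_skipped, path)
    return molecules


def load_activity_table(path: str | Path) -> list[ActivityRecord]:
    """Read a CSV/TSV activity table; no filtering is applied here.

    A blank ``activity_value_uM`` means the source database reports the
    compound as active without a numeric affinity.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    missing = [c for c in ACTIVITY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"activity table {path} is missing column(s): {', '.join(missing)}")
    records = []
    for row in df.itertuples(index=False):
        raw = getattr(row, "activity_value_uM")
        value = None
        if raw is not None and not (isinstance(raw, float) and math.isnan(raw)):
            raw = str(raw).strip()
            if raw:
                value = float(raw)
        records.append(
            ActivityRecord(
                mol_id=str(row.mol_id),
                target_id=str(row.target_id),
                activity_type=str(row.activity_type),
                activity_value_uM=value,
            )
        )
    return records


def build_classes(
    records: list[ActivityRecord],
    molecules: list[MoleculeGraph],
    mw_min: float = 50.0,
    mw_max: float = 700.0,
    activity_max: float = 10.0,
    min_class_size: int = 20,
) -> list[TargetClass]:
    """Assemble per-target ligand classes after the dataset filters.

    Keeps records whose activity is strictly below ``activity_max`` µM or
    whose value is absent; keeps molecules with ``mw_min ≤ mw ≤ mw_max``;
    deduplicates ligands per target and drops targets with fewer than
    ``min_class_size`` ligands.  Classes come back sorted by target id.
    """
    by_id = {m.mol_id: m for m in molecules}
    n_inactive = n_unresolved = n_mw = 0
    members: dict[str, list[str]] = {}
    seen: set[tuple[str, str]] = set()
    for rec in records:
        if rec.activity_value_uM is not None and rec.activity_value_uM >= activity_max:
            n_inactive += 1
            continue
        mol = by_id.get(rec.mol_id)
        if mol is None:
            n_unresolved += 1
            logger.warning("dropping record for unresolvable molecule %r", rec.mol_id)
            continue
        if not (mw_min <= mol.mw <= mw_max):
            n_mw += 1
            continue
        key = (rec.target_id, rec.mol_id)
        if key in seen:
            continue
        seen.add(key)
        members.setdefault(rec.target_id, []).append(rec.mol_id)

    classes = [
        TargetClass(target_id=t, mol_ids=tuple(ids))
        for t, ids in sorted(members.items())
        if len(ids) >= min_class_size
    ]
    n_small = len(members) - len(classes)
    logger.info(
        "build_classes: %d classes kept; dropped %d inactive records, %d unresolved, "
        "%d outside MW window, %d undersized targets",
        len(classes), n_inactive, n_unresolved, n_mw, n_small,
    )
    if not classes:
        raise ValueError(
            "all target classes dropped "
            f"(inactive records: {n_inactive}, unresolved molecules: {n_unresolved}, "
            f"outside MW [{mw_min},{mw_max}]: {n_mw}, undersized targets: {n_small})"
        )
    return classes
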