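"""Molecule and property-table input.

Molecules are held as hydrogen-suppressed labelled graphs: the vertices are
heavy atoms (element, formal charge, aromatic flag) and the edges carry a
bond order (1, 2, 3 or aromatic).  RDKit does the actual SMILES/SDF parsing
and aromaticity perception; this module only reshapes its output into the
small immutable container the descriptor code walks.

Property tables are CSV/TSV files with a SMILES column and a numeric value
column.  Endpoints tabulated only as inequalities ("> cutoff") cannot be
used in regression, so records with a non-exact qualifier are dropped, and
an optional decimal-log transform puts concentration-like values on the
log scale the models operate on.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

logger = logging.getLogger("sigqsar")

RDLogger.DisableLog("rdApp.warning")

#: bond orders carried on graph edges
BOND_SINGLE = 1
BOND_DOUBLE = 2
BOND_TRIPLE = 3
BOND_AROMATIC = "ar"

_RDKIT_BOND = {
    Chem.BondType.SINGLE: BOND_SINGLE,
    Chem.BondType.DOUBLE: BOND_DOUBLE,
    Chem.BondType.TRIPLE: BOND_TRIPLE,
    Chem.BondType.AROMATIC: BOND_AROMATIC,
}
_TO_RDKIT_BOND = {
    BOND_SINGLE: Chem.BondType.SINGLE,
    BOND_DOUBLE: Chem.BondType.DOUBLE,
    BOND_TRIPLE: Chem.BondType.TRIPLE,
    BOND_AROMATIC: Chem.BondType.AROMATIC,
}


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed."""


@dataclass(frozen=True)
class Atom:
    """One heavy atom: element symbol, formal charge and aromatic flag."""

    symbol: str
    charge: int = 0
    aromatic: bool = False


@dataclass(frozen=True)
class MolecularGraph:
    """Hydrogen-suppressed molecular graph.

    Atom indices are 0-based and contiguous; bonds are stored once per
    unordered atom pair as ``(i, j, order)`` with ``i < j``.
    """

    atoms: tuple[Atom, ...]
    bonds: frozenset[tuple[int, int, int | str]]
    source: str = ""

    def __post_init__(self) -> None:
        n = len(self.atoms)
        seen_pairs = set()
        for i, j, order in self.bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise ValueError(f"invalid bond endpoints ({i}, {j}) for {n} atoms")
            if i > j:
                raise ValueError("bonds must be stored with i < j")
            if (i, j) in seen_pairs:
                raise ValueError(f"duplicate bond between atoms {i} and {j}")
            if order not in (BOND_SINGLE, BOND_DOUBLE, BOND_TRIPLE, BOND_AROMATIC):
                raise ValueError(f"unknown bond order {order!r}")
            seen_pairs.add((i, j))
        for atom in self.atoms:
            if atom.symbol == "H":
                raise ValueError("explicit hydrogen vertices are not allowed")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def neighbors(self) -> list[list[tuple[int, int | str]]]:
        """Adjacency list: for each atom, ``(neighbor index, bond order)``."""
        adj: list[list[tuple[int, int | str]]] = [[] for _ in self.atoms]
        for i, j, order in self.bonds:
            adj[i].append((j, order))
            adj[j].append((i, order))
        return adj

    def permuted(self, order: Sequence[int]) -> "MolecularGraph":
        """Relabel atoms so that new index ``k`` holds old atom ``order[k]``."""
        if sorted(order) != list(range(self.n_atoms)):
            raise ValueError("order must be a permutation of atom indices")
        inverse = [0] * self.n_atoms
        for new, old in enumerate(order):
            inverse[old] = new
        atoms = tuple(self.atoms[old] for old in order)
        bonds = frozenset(
            (min(inverse[i], inverse[j]), max(inverse[i], inverse[j]), o)
            for i, j, o in self.bonds
        )
        return MolecularGraph(atoms=atoms, bonds=bonds, source=self.source)

    def to_rdkit(self) -> Chem.Mol:
        """Rebuild an RDKit molecule (used for SMILES/SDF export)."""
        em = Chem.RWMol()
        for atom in self.atoms:
            a = Chem.Atom(atom.symbol)
            a.SetFormalCharge(atom.charge)
            a.SetIsAromatic(atom.aromatic)
            em.AddAtom(a)
        for i, j, order in self.bonds:
            em.AddBond(i, j, _TO_RDKIT_BOND[order])
        mol = em.GetMol()
        Chem.SanitizeMol(mol)
        return mol

    def to_smiles(self) -> str:
        return Chem.MolToSmiles(self.to_rdkit())


class Qualifier(Enum):
    """Relation between the tabulated number and the true endpoint value."""

    EXACT = "="
    GREATER = ">"
    LESS = "<"


_QUALIFIER_ALIASES = {
    "=": Qualifier.EXACT,
    "": Qualifier.EXACT,
    ">": Qualifier.GREATER,
    ">=": Qualifier.GREATER,
    "<": Qualifier.LESS,
    "<=": Qualifier.LESS,
}


@dataclass(frozen=True)
class PropertyRecord:
    """One modelling record: a molecule with a continuous endpoint value."""

    molecule: MolecularGraph
    value: float
    qualifier: Qualifier = Qualifier.EXACT
    identifier: str = ""


@dataclass
class LoadReport:
    """Row accounting from :func:`load_dataset`."""

    n_rows: int = 0
    dropped_inequality: int = 0
    dropped_bad_smiles: int = 0
    dropped_nonpositive: int = 0

    @property
    def dropped(self) -> int:
        return self.dropped_inequality + self.dropped_bad_smiles + self.dropped_nonpositive


def mol_to_graph(mol: Chem.Mol, source: str = "") -> MolecularGraph:
    """Convert a sanitized RDKit molecule to a :class:`MolecularGraph`."""
    mol = Chem.RemoveHs(mol)
    atoms = tuple(
        Atom(a.GetSymbol(), a.GetFormalCharge(), a.GetIsAromatic())
        for a in mol.GetAtoms()
    )
    bonds = set()
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        order = _RDKIT_BOND.get(b.GetBondType())
        if order is None:
            raise SmilesParseError(f"unsupported bond type {b.GetBondType()} in {source!r}")
        bonds.add((min(i, j), max(i, j), order))
    return MolecularGraph(atoms=atoms, bonds=frozenset(bonds), source=source)


def parse_smiles(smiles: str) -> MolecularGraph:
    """Parse a SMILES string into a hydrogen-suppressed molecular graph.

    Aromaticity is perceived during sanitization, so two spellings of the
    same molecule (e.g. kekulized vs. aromatic benzene) give isomorphic
    graphs.

    Raises
    ------
    SmilesParseError
        If the SMILES cannot be parsed.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"invalid SMILES: {smiles!r}")
    return mol_to_graph(mol, source=smiles)


def _split_qualifier(raw: str) -> tuple[Qualifier, str]:
    raw = raw.strip()
    for prefix in (">=", "<=", ">", "<", "="):
        if raw.startswith(prefix):
            return _QUALIFIER_ALIASES[prefix], raw[len(prefix):].strip()
    return Qualifier.EXACT, raw


def load_dataset(
    path,
    *,
    smiles_column: str = "smiles",
    value_column: str = "value",
    qualifier_column: str | None = None,
    id_column: str | None = None,
    log_transform: bool = False,
    sep: str | None = None,
) -> tuple[list[PropertyRecord], LoadReport]:
    """Load a SMILES + endpoint table and apply the cleaning rules.

    Rows whose value carries an inequality qualifier — either in a dedicated
    qualifier column or as a ``<``/``>`` prefix on the value itself — are
    dropped: a "larger than cutoff" entry has no usable regression target.
    With ``log_transform`` the surviving values are replaced by their
    decimal logarithm (non-positive raw values are then rejected).

    Returns the surviving records together with a :class:`LoadReport`
    counting each class of dropped row.
    """
    path = str(path)
    if path.lower().endswith(".sdf"):
        return _load_sdf(path, value_column, log_transform)
    if sep is None:
        sep = "\t" if path.lower().endswith((".tsv", ".tab")) else ","
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    for col in (smiles_column, value_column):
        if col not in frame.columns:
            raise ValueError(f"column {col!r} not found in {path}")

    records: list[PropertyRecord] = []
    report = LoadReport(n_rows=len(frame))
    for pos, row in enumerate(frame.itertuples(index=False)):
        row = dict(zip(frame.columns, row))
        qualifier = Qualifier.EXACT
        if qualifier_column is not None:
            token = str(row.get(qualifier_column, "")).strip()
            if token not in _QUALIFIER_ALIASES:
                raise ValueError(f"unknown qualifier {token!r} on row {pos}")
            qualifier = _QUALIFIER_ALIASES[token]
        prefix_qualifier, value_text = _split_qualifier(str(row[value_column]))
        if qualifier is Qualifier.EXACT:
            qualifier = prefix_qualifier
        if qualifier is not Qualifier.EXACT:
            report.dropped_inequality += 1
            continue
        raw = float(value_text)
        if log_transform:
            if raw <= 0:
                logger.warning("row %d: non-positive value %g under log transform", pos, raw)
                report.dropped_nonpositive += 1
                continue
            value = math.log10(raw)
        else:
            value = raw
        if not math.isfinite(value):
            report.dropped_nonpositive += 1
            continue
        try:
            graph = parse_smiles(str(row[smiles_column]))
        except SmilesParseError:
            logger.warning("row %d: unparseable SMILES %r", pos, row[smiles_column])
            report.dropped_bad_smiles += 1
            continue
        identifier = str(row[id_column]) if id_column else f"row{pos}"
        records.append(PropertyRecord(graph, value, Qualifier.EXACT, identifier))
    logger.info(
        "loaded %d records from %s (%d rows dropped)", len(records), path, report.dropped
    )
    return records, report


def _load_sdf(path: str, value_tag: str, log_transform: bool) -> tuple[list[PropertyRecord], LoadReport]:
    records: list[PropertyRecord] = []
    report = LoadReport()
    for pos, mol in enumerate(Chem.SDMolSupplier(path)):
        report.n_rows += 1
        if mol is None:
            report.dropped_bad_smiles += 1
            continue
        if not mol.HasProp(value_tag):
            raise ValueError(f"SDF record {pos} lacks property tag {value_tag!r}")
        qualifier, value_text = _split_qualifier(mol.GetProp(value_tag))
        if qualifier is not Qualifier.EXACT:
            report.dropped_inequality += 1
            continue
        raw = float(value_text)
        if log_transform:
            if raw <= 0:
                report.dropped_nonpositive += 1
                continue
            raw = math.log10(raw)
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"mol{pos}"
        records.append(PropertyRecord(mol_to_graph(mol), raw, Qualifier.EXACT, name))
    return records, report
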