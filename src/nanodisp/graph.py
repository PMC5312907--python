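"""Hydrogen-depleted molecular graphs with Kekulé bond orders.

All topological descriptors in this package are defined on the
hydrogen-depleted graph: vertices are heavy atoms (each carrying its
implicit-hydrogen count, atomic mass and valence-electron count), edges carry
integer bond orders 1/2/3, and aromatic rings are stored in a fixed Kekulé
assignment.  SMILES parsing and Kekulization are delegated to RDKit, which is
deterministic for a given input string.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from typing import Iterable, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path

__all__ = ["Atom", "MolecularGraph"]

# masses/valence electrons for atoms built without RDKit (synthetic graphs)
_ELEMENTS = {
    "C": (6, 12.011, 4),
    "N": (7, 14.007, 5),
    "O": (8, 15.999, 6),
    "S": (16, 32.06, 6),
    "Cl": (17, 35.45, 7),
    "F": (9, 18.998, 7),
    "H": (1, 1.008, 1),
}


@dataclass(frozen=True)
class Atom:
    """A heavy atom: element, attached hydrogens, mass, valence electrons."""

    symbol: str
    n_h: int
    mass: float
    valence_electrons: int
    atomic_number: int

    @classmethod
    def of(cls, symbol: str, n_h: int = 0) -> "Atom":
        z, mass, zv = _ELEMENTS[symbol]
        return cls(symbol, n_h, mass, zv, z)


class MolecularGraph:
    """Connected labelled graph of heavy atoms with integer bond orders."""

    def __init__(self, atoms: Sequence[Atom], bonds: Iterable[tuple[int, int, int]]):
        atoms = tuple(atoms)
        bond_list = []
        seen = set()
        n = len(atoms)
        for i, j, order in bonds:
            if i == j:
                raise ValueError(f"self-loop on atom {i}")
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i},{j}) out of range for {n} atoms")
            if order not in (1, 2, 3):
                raise ValueError(f"bond order must be 1, 2 or 3, got {order}")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"duplicate bond {key}")
            seen.add(key)
            bond_list.append((key[0], key[1], int(order)))
        self.atoms = atoms
        self.bonds = tuple(sorted(bond_list))
        adj = np.zeros((n, n), dtype=np.int64)
        for i, j, _ in self.bonds:
            adj[i, j] = adj[j, i] = 1
        self.adjacency = adj
        if n > 1:
            n_comp, _ = connected_components(csr_matrix(adj), directed=False)
            if n_comp != 1:
                raise ValueError("molecular graph must be connected")
        self._order = {(i, j): o for i, j, o in self.bonds}

    # -- basic accessors ---------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @cached_property
    def degrees(self) -> np.ndarray:
        """Heavy-atom degrees (number of heavy neighbours)."""
        return self.adjacency.sum(axis=1)

    @cached_property
    def distances(self) -> np.ndarray:
        """Topological distances: shortest-path edge counts between heavy atoms."""
        d = shortest_path(csr_matrix(self.adjacency), method="BF", unweighted=True)
        return d.astype(np.int64)

    def bond_order(self, i: int, j: int) -> int:
        return self._order[(min(i, j), max(i, j))]

    def neighbors(self, i: int) -> np.ndarray:
        return np.flatnonzero(self.adjacency[i])

    # -- construction ------------------------------------------------------

    @classmethod
    def from_smiles(cls, smiles: str) -> "MolecularGraph":
        """Parse a neutral organic SMILES into a Kekulized H-depleted graph.

        Aromatic systems are Kekulized to an explicit alternating 1/2 bond
        order pattern (RDKit's deterministic assignment).

        Raises
        ------
        ValueError
            On unparseable SMILES, disconnected structures, or net charge.
        """
        from rdkit import Chem

        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ValueError(f"unparseable SMILES: {smiles!r}")
        if len(Chem.GetMolFrags(mol)) != 1:
            raise ValueError(f"disconnected structure: {smiles!r}")
        if Chem.GetFormalCharge(mol) != 0:
            raise ValueError(f"structure carries net charge: {smiles!r}")
        Chem.Kekulize(mol, clearAromaticFlags=True)
        pt = Chem.GetPeriodicTable()
        atoms = [
            Atom(
                symbol=a.GetSymbol(),
                n_h=a.GetTotalNumHs(),
                mass=pt.GetAtomicWeight(a.GetAtomicNum()),
                valence_electrons=pt.GetNOuterElecs(a.GetAtomicNum()),
                atomic_number=a.GetAtomicNum(),
            )
            for a in mol.GetAtoms()
        ]
        bonds = [
            (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), int(round(b.GetBondTypeAsDouble())))
            for b in mol.GetBonds()
        ]
        return cls(atoms, bonds)

    def with_explicit_hydrogens(self) -> "MolecularGraph":
        """Expanded graph where implicit hydrogens become explicit vertices."""
        atoms = list(self.atoms)
        bonds = list(self.bonds)
        for i, a in enumerate(self.atoms):
            for _ in range(a.n_h):
                atoms.append(Atom.of("H", 0))
                bonds.append((i, len(atoms) - 1, 1))
            # parent atom keeps its identity but no implicit H in the new graph
            atoms[i] = Atom(a.symbol, 0, a.mass, a.valence_electrons, a.atomic_number)
        return MolecularGraph(atoms, bonds)

    def __repr__(self) -> str:
        return f"MolecularGraph({self.n_atoms} atoms, {len(self.bonds)} bonds)"
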