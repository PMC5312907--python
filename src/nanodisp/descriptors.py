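"""Topological descriptors on hydrogen-depleted molecular graphs.

The descriptor families implemented here are the ones entering the packaged
dispersibility models:

``SRW09``
    self-returning walk count of order 9 — the trace of the 9th power of the
    adjacency matrix.  Zero for any graph without odd rings; nonzero values
    probe the surroundings of odd-membered (here five-membered) rings.
``Ram``
    ramification (branching) index — sum over heavy atoms of
    ``max(0, degree - 2)``.
``X0Av``
    average zeroth-order valence connectivity index — mean over heavy atoms
    of ``1/sqrt(delta_v)`` with Kier–Hall valence degrees.
``piPC05``
    multiple path count of order 5 — sum over simple 5-edge paths of the
    product of (Kekulé) bond orders along the path.
``ATS6m``
    Broto–Moreau autocorrelation at topological lag 6, atomic-mass weighted.
    Several dialects exist in the wild; all are implemented and a calibration
    report tabulates them against a supplied reference column.

The quantum-chemical ``DipoleZ`` column is always consumed as supplied input;
this package never computes it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .corpus import DescriptorMatrix, SolventRecord
from .graph import MolecularGraph

__all__ = [
    "srw_count",
    "ram_index",
    "valence_degree",
    "chi0v_average",
    "multiple_path_count",
    "ats_autocorrelation",
    "ats_dialect_report",
    "build_descriptor_matrix",
    "verify_against_reference",
    "DiscrepancyReport",
    "COMPUTED_DESCRIPTORS",
    "KNOWN_DISCREPANT_CELLS",
]

CARBON_MASS = 12.011

ATS_DIALECTS = ("raw-sum", "log1p", "include-H")
ATS_WEIGHTS = ("mass", "scaled-mass")

#: Cells of the packaged reference matrix known not to be reproducible from
#: the packaged structures under the canonical definitions above, measured by
#: re-computation over all 29 structures (see docs/methods.md).  The pattern
#: is coherent: reference rows 3 and 4 are transposed relative to the
#: compound table; rows 2, 5, 10 and 14 correspond to different structures
#: than the named compounds (e.g. the row-5 values match plain
#: 2-pyrrolidinone rather than its N-methyl derivative, and row 14
#: duplicates row 28 verbatim); row 16's X0Av is off by 0.015; and no ATS
#: dialect explains the reference ATS6m column (nonzero entries occur below
#: the lag-6 diameter).  All other cells of SRW09, piPC05, Ram and X0Av
#: reproduce exactly (counts) or to 0.002 (X0Av).
KNOWN_DISCREPANT_CELLS: dict[str, object] = {
    "SRW09": (5, 10),
    "piPC05": (2, 3, 4, 5, 10),
    "Ram": (2, 3, 4, 5, 10, 14),
    "X0Av": (2, 3, 4, 5, 10, 14, 16),
    "ATS6m": "all-nonzero",  # dialect unresolved; see ats_dialect_report
}


def srw_count(g: MolecularGraph, k: int) -> int:
    """Self-returning walk count of order ``k``: ``trace(A^k)``.

    Counts closed walks of length ``k`` in the hydrogen-depleted graph.  For
    odd ``k`` this is zero unless the graph contains an odd ring.
    """
    if k < 1:
        raise ValueError(f"walk order must be >= 1, got {k}")
    power = np.linalg.matrix_power(g.adjacency, k)
    return int(np.trace(power))


def ram_index(g: MolecularGraph) -> int:
    """Ramification (branching) index: sum of ``max(0, degree - 2)``."""
    return int(np.maximum(g.degrees - 2, 0).sum())


def valence_degree(g: MolecularGraph, atom_index: int) -> float:
    """Kier–Hall valence degree of one heavy atom.

    ``delta_v = Zv - h`` for second-row atoms and
    ``(Zv - h) / (Z - Zv - 1)`` for higher rows, with ``Zv`` the
    valence-electron count, ``h`` the attached-hydrogen count and ``Z`` the
    atomic number.
    """
    a = g.atoms[atom_index]
    raw = a.valence_electrons - a.n_h
    if raw <= 0:
        raise ValueError(
            f"atom {atom_index} ({a.symbol}, {a.n_h} H) has non-positive "
            f"valence degree {raw}"
        )
    if a.atomic_number <= 10:
        return float(raw)
    return raw / (a.atomic_number - a.valence_electrons - 1)


def chi0v_average(g: MolecularGraph) -> float:
    """Average zeroth-order valence connectivity index (X0Av).

    ``(sum_i delta_v(i)^(-1/2)) / n_heavy``.
    """
    deltas = np.array([valence_degree(g, i) for i in range(g.n_atoms)])
    return float(np.sum(deltas ** -0.5) / g.n_atoms)


def multiple_path_count(g: MolecularGraph, k: int) -> float:
    """Bond-order weighted count of simple paths of exactly ``k`` edges.

    Each undirected path is counted once; its weight is the product of the
    bond orders along it (Kekulé orders, so aromatic rings contribute
    alternating 1/2 factors).  Integer-valued whenever all orders are.
    """
    if k < 1:
        raise ValueError(f"path order must be >= 1, got {k}")
    total = 0.0
    visited = np.zeros(g.n_atoms, dtype=bool)

    def extend(last: int, start: int, length: int, weight: float) -> None:
        nonlocal total
        if length == k:
            if last > start:  # count each undirected path once
                total += weight
            return
        for nxt in g.neighbors(last):
            if not visited[nxt]:
                visited[nxt] = True
                extend(nxt, start, length + 1, weight * g.bond_order(last, nxt))
                visited[nxt] = False

    for start in range(g.n_atoms):
        visited[start] = True
        extend(start, start, 0, 1.0)
        visited[start] = False
    return total


def _ats_weights(g: MolecularGraph, weight: str) -> np.ndarray:
    if weight not in ATS_WEIGHTS:
        raise ValueError(f"unknown weight scheme {weight!r}; choose from {ATS_WEIGHTS}")
    masses = np.array([a.mass for a in g.atoms])
    return masses / CARBON_MASS if weight == "scaled-mass" else masses


def ats_autocorrelation(
    g: MolecularGraph, k: int, weight: str = "mass", dialect: str = "raw-sum"
) -> float:
    """Broto–Moreau autocorrelation at topological lag ``k``.

    ``raw-sum`` is the canonical definition: the sum of ``w_i * w_j`` over
    unordered heavy-atom pairs at shortest-path distance ``k``; it is exactly
    zero when the graph diameter is below ``k``.  ``log1p`` applies
    ``log(1 + raw)``.  ``include-H`` evaluates the raw sum on the graph with
    explicit hydrogen vertices.  Weights are atomic masses, optionally scaled
    by the carbon mass (``scaled-mass``).
    """
    if k < 1:
        raise ValueError(f"lag must be >= 1, got {k}")
    if dialect not in ATS_DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {ATS_DIALECTS}")
    if dialect == "include-H":
        g = g.with_explicit_hydrogens()
    w = _ats_weights(g, weight)
    d = g.distances
    iu, ju = np.triu_indices(g.n_atoms, 1)
    raw = float(np.sum(w[iu] * w[ju] * (d[iu, ju] == k)))
    if dialect == "log1p":
        return float(np.log1p(raw))
    return raw


def ats_dialect_report(
    graphs: Mapping[int, MolecularGraph],
    reference: pd.Series,
    k: int = 6,
) -> pd.DataFrame:
    """Calibration table of every ATS dialect/weight against a reference column.

    One row per compound; one column per (dialect, weight) pair with the
    computed value, plus ``abs_diff_*`` columns against ``reference``.  No
    dialect is asserted to match — the table is diagnostic output.
    """
    rows = {}
    for ident, g in graphs.items():
        row = {}
        for dialect in ATS_DIALECTS:
            for weight in ATS_WEIGHTS:
                row[f"{dialect}/{weight}"] = ats_autocorrelation(g, k, weight, dialect)
        rows[ident] = row
    table = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    table["reference"] = reference.reindex(table.index)
    for col in [c for c in table.columns if c != "reference"]:
        table[f"abs_diff[{col}]"] = (table[col] - table["reference"]).abs()
    return table


#: descriptor name -> callable computing it from a MolecularGraph
COMPUTED_DESCRIPTORS = {
    "SRW09": lambda g: srw_count(g, 9),
    "piPC05": lambda g: multiple_path_count(g, 5),
    "Ram": ram_index,
    "X0Av": chi0v_average,
    "ATS6m": lambda g: ats_autocorrelation(g, 6, "mass", "raw-sum"),
}


def build_descriptor_matrix(
    records: Sequence[SolventRecord],
    supplied: Mapping[str, Mapping[int, float]] | pd.DataFrame | None = None,
    descriptors: Sequence[str] = tuple(COMPUTED_DESCRIPTORS),
) -> DescriptorMatrix:
    """Compute descriptors from structures and merge supplied columns.

    Parameters
    ----------
    records : sequence of SolventRecord
        Must carry SMILES for every compound.
    supplied : mapping column-name -> {id: value}, or DataFrame indexed by id
        Externally computed columns (e.g. ``DipoleZ``); must cover every
        record id.
    descriptors : names from :data:`COMPUTED_DESCRIPTORS`

    Raises
    ------
    ValueError
        If a supplied column misses a compound id (the id is named), or a
        record lacks a structure.
    """
    ids = [r.id for r in records]
    if supplied is None:
        supplied = {}
    if isinstance(supplied, pd.DataFrame):
        supplied = {c: supplied[c].to_dict() for c in supplied.columns}

    data: dict[str, list[float]] = {}
    provenance: dict[str, str] = {}
    graphs = {}
    for r in records:
        if not r.smiles:
            raise ValueError(f"record id={r.id} ({r.name}) has no structure")
        graphs[r.id] = MolecularGraph.from_smiles(r.smiles)
    for name in descriptors:
        if name not in COMPUTED_DESCRIPTORS:
            raise ValueError(f"unknown computed descriptor {name!r}")
        data[name] = [COMPUTED_DESCRIPTORS[name](graphs[i]) for i in ids]
        provenance[name] = "computed"
    for name, column in supplied.items():
        missing = [i for i in ids if i not in column]
        if missing:
            raise ValueError(f"supplied column {name!r} missing id(s): {missing}")
        data[name] = [float(column[i]) for i in ids]
        provenance[name] = "supplied"
    df = pd.DataFrame(data, index=pd.Index(ids, name="id"))
    return DescriptorMatrix(df, provenance)


@dataclass
class DiscrepancyReport:
    """Cell-level comparison of a computed matrix against a reference."""

    table: pd.DataFrame  # columns: column, id, computed, reference, abs_diff, flagged, known
    skipped: list[str] = field(default_factory=list)

    @property
    def unexpected(self) -> pd.DataFrame:
        """Flagged cells that are not on the known-discrepancy list."""
        return self.table[self.table.flagged & ~self.table.known]

    def __str__(self) -> str:
        n_flag = int(self.table.flagged.sum())
        n_known = int((self.table.flagged & self.table.known).sum())
        lines = [
            f"{len(self.table)} cells compared; {n_flag} above tolerance "
            f"({n_known} on the known-discrepancy list)"
        ]
        if self.skipped:
            lines.append(f"skipped (absent from reference): {', '.join(self.skipped)}")
        if len(self.unexpected):
            lines.append("UNEXPECTED discrepancies:")
            lines.append(self.unexpected.to_string(index=False))
        return "\n".join(lines)


def verify_against_reference(
    computed: DescriptorMatrix,
    reference: DescriptorMatrix,
    tolerances: Mapping[str, float],
    known: Mapping[str, object] | None = None,
) -> DiscrepancyReport:
    """Compare computed descriptor columns to a reference matrix cell by cell.

    Columns absent from the reference are skipped with a notice.  Cells whose
    absolute difference exceeds the column tolerance are flagged; flagged
    cells on the ``known`` discrepancy list (per-column id tuples, or the
    string ``"all-nonzero"``) are reported separately from unexpected ones.

    Raises
    ------
    ValueError
        If the compound id sets differ (shape mismatch).
    """
    if list(computed.compound_ids) != list(reference.compound_ids):
        raise ValueError(
            f"compound id mismatch: {len(computed)} computed vs "
            f"{len(reference)} reference rows"
        )
    if known is None:
        known = KNOWN_DISCREPANT_CELLS
    rows = []
    skipped = []
    for col in computed.columns:
        if col not in reference.columns:
            skipped.append(col)
            continue
        tol = tolerances.get(col, 0.0)
        kn = known.get(col, ())
        for ident in computed.compound_ids:
            c = float(computed[col].loc[ident])
            r = float(reference[col].loc[ident])
            diff = abs(c - r)
            flagged = diff > tol
            if kn == "all-nonzero":
                is_known = r != 0 or c != 0
            else:
                is_known = ident in kn
            rows.append(
                dict(column=col, id=ident, computed=c, reference=r,
                     abs_diff=diff, flagged=flagged, known=bool(is_known))
            )
    return DiscrepancyReport(pd.DataFrame(rows), skipped)
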