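"""The packaged study data: 29 organic solvents with SWCNT dispersibility endpoints.

The dataset couples each solvent to the maximum stable single-walled
carbon-nanotube concentration ``C`` (mg/mL) it supports.  The modelled
endpoint is ``LogC = log10(C in mg/mL)``; the packaged table also carries the
originally reported calculated column (``logc_cal``), which is stored for
comparison purposes only and never used as ground truth.  Seven compounds
(ids 2, 5, 12, 19, 20, 21, 25) form the external test set; the remaining 22
are the training set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from importlib import resources
from typing import IO, Iterable, Sequence

import numpy as np
import pandas as pd

#: ids of the external test-set compounds (the remaining 22 are training).
TEST_IDS: tuple[int, ...] = (2, 5, 12, 19, 20, 21, 25)

#: number of solvents in the packaged study table.
N_SOLVENTS = 29

#: descriptor columns of the packaged matrix, in their canonical order.
DESCRIPTOR_COLUMNS = ("SRW09", "DipoleZ", "piPC05", "Ram", "X0Av", "ATS6m")

#: columns that are integer-valued counts by definition.
_INTEGER_COLUMNS = ("SRW09", "Ram")

#: columns that cannot be negative.
_NONNEGATIVE_COLUMNS = ("SRW09", "piPC05", "Ram")


@dataclass(frozen=True)
class SolventRecord:
    """One solvent of the study set.

    Attributes
    ----------
    id : int
        Row number, 1-29, unique.
    name : str
        Compound name.
    conc : float
        Maximum dispersed SWCNT concentration, mg/mL, strictly positive.
    log_conc : float
        log10 of ``conc`` (the regression endpoint).
    split : str
        ``"train"`` or ``"test"``.
    smiles : str or None
        Structure encoding, when available.
    log_conc_calc : float or None
        The originally reported calculated LogC.  Kept for side-by-side
        comparison; never used as a response.
    """

    id: int
    name: str
    conc: float
    log_conc: float
    split: str
    smiles: str | None = None
    log_conc_calc: float | None = None


def to_log_endpoint(conc: float) -> float:
    """Convert a dispersibility ``C`` in mg/mL to the modelled LogC endpoint.

    ``LogC = log10(C)`` with ``C`` in mg/mL; this reproduces every reported
    LogC(exp) value of the packaged table to 0.001.

    Raises
    ------
    ValueError
        If ``conc`` is not strictly positive.
    """
    if not conc > 0:
        raise ValueError(f"concentration must be positive, got {conc!r}")
    return math.log10(conc)


def load_solvent_table(
    source: str | IO[str], strict: bool = True, logc_tol: float = 0.05
) -> list[SolventRecord]:
    """Read a solvent table (CSV with header) into :class:`SolventRecord` rows.

    Expected columns: ``id, name, conc_mg_ml, split`` and optionally
    ``logc_exp``, ``logc_cal``, ``smiles``.  When ``logc_exp`` is absent it is
    recomputed with :func:`to_log_endpoint`.

    A supplied ``logc_exp`` is authoritative but is cross-checked against
    ``log10(conc)`` to within ``logc_tol``; the default 0.05 accommodates
    concentrations reported to one significant figure (in the packaged table
    row 13 pairs C = 0.03 with LogC = −1.553, i.e. an unrounded C ≈ 0.028),
    while all other packaged rows agree to 0.001.

    Parameters
    ----------
    source : path or text stream
    strict : bool
        Require exactly 29 rows (the packaged study size).
    logc_tol : float
        Maximum tolerated |logc_exp − log10(conc)|.

    Raises
    ------
    ValueError
        On an empty table, duplicate ids, a non-positive concentration (the
        offending row is identified), or a row-count mismatch in strict mode.
    """
    try:
        df = pd.read_csv(source, comment="#")
    except pd.errors.EmptyDataError:
        raise ValueError("no rows") from None
    if df.empty:
        raise ValueError("no rows")
    required = {"id", "name", "conc_mg_ml", "split"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing column(s): {sorted(missing)}")
    dup = df["id"][df["id"].duplicated()].tolist()
    if dup:
        raise ValueError(f"duplicate id(s): {sorted(set(dup))}")
    if strict and len(df) != N_SOLVENTS:
        raise ValueError(f"expected {N_SOLVENTS} rows, got {len(df)}")

    records: list[SolventRecord] = []
    for row in df.itertuples(index=False):
        conc = float(row.conc_mg_ml)
        if conc <= 0:
            raise ValueError(f"row id={row.id}: non-positive concentration {conc}")
        log_conc = (
            float(row.logc_exp) if hasattr(row, "logc_exp") else to_log_endpoint(conc)
        )
        if abs(log_conc - to_log_endpoint(conc)) > logc_tol:
            raise ValueError(
                f"row id={row.id}: logc_exp {log_conc} inconsistent with "
                f"log10({conc}) = {to_log_endpoint(conc):.4f}"
            )
        records.append(
            SolventRecord(
                id=int(row.id),
                name=str(row.name),
                conc=conc,
                log_conc=log_conc,
                split=str(row.split),
                smiles=str(row.smiles) if hasattr(row, "smiles") else None,
                log_conc_calc=float(row.logc_cal) if hasattr(row, "logc_cal") else None,
            )
        )
    return records


def write_solvent_table(records: Iterable[SolventRecord], target: str | IO[str]) -> None:
    """Write records back to the CSV layout read by :func:`load_solvent_table`."""
    rows = list(records)
    df = pd.DataFrame(
        {
            "id": [r.id for r in rows],
            "name": [r.name for r in rows],
            "conc_mg_ml": [r.conc for r in rows],
            "logc_exp": [r.log_conc for r in rows],
            "logc_cal": [r.log_conc_calc for r in rows],
            "split": [r.split for r in rows],
        }
    )
    df.to_csv(target, index=False)


def split_dataset(
    records: Sequence[SolventRecord],
) -> tuple[list[SolventRecord], list[SolventRecord]]:
    """Partition records into (train, test) by their split flag, preserving order.

    Raises
    ------
    ValueError
        If any record carries a flag other than ``"train"``/``"test"``.
    """
    train, test = [], []
    for r in records:
        if r.split == "train":
            train.append(r)
        elif r.split == "test":
            test.append(r)
        else:
            raise ValueError(f"record id={r.id} ({r.name}): unknown split flag {r.split!r}")
    return train, test


class DescriptorMatrix:
    """Named descriptor columns over an ordered set of compounds.

    A thin, validated wrapper around a :class:`pandas.DataFrame` indexed by
    compound id, with a per-column provenance tag (``"computed"`` from
    structure, or ``"supplied"`` e.g. the quantum-chemical DipoleZ column,
    which this package never computes).
    """

    def __init__(self, data: pd.DataFrame, provenance: dict[str, str]):
        if data.isna().any().any():
            bad = data.columns[data.isna().any()].tolist()
            raise ValueError(f"missing entries in column(s): {bad}")
        unknown = set(provenance) - set(data.columns)
        if unknown:
            raise ValueError(f"provenance for unknown column(s): {sorted(unknown)}")
        for col in data.columns:
            provenance.setdefault(col, "supplied")
            if provenance[col] not in ("computed", "supplied"):
                raise ValueError(f"bad provenance tag for {col}: {provenance[col]!r}")
        for col in _NONNEGATIVE_COLUMNS:
            if col in data.columns and (data[col] < 0).any():
                raise ValueError(f"negative values in count column {col}")
        for col in _INTEGER_COLUMNS:
            if col in data.columns and not np.allclose(
                data[col], np.round(data[col]), atol=1e-9
            ):
                raise ValueError(f"non-integer values in count column {col}")
        self.data = data.copy()
        self.data.index = self.data.index.astype(int)
        self.provenance = dict(provenance)

    @property
    def compound_ids(self) -> list[int]:
        return list(self.data.index)

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    def __len__(self) -> int:  # number of compounds
        return len(self.data)

    def __getitem__(self, column: str) -> pd.Series:
        return self.data[column]

    def subset(self, ids: Sequence[int]) -> "DescriptorMatrix":
        """Row-subset by compound ids, keeping order of ``ids``."""
        missing = [i for i in ids if i not in self.data.index]
        if missing:
            raise KeyError(f"compound id(s) not in matrix: {missing}")
        return DescriptorMatrix(self.data.loc[list(ids)], dict(self.provenance))

    def to_csv(self, target: str | IO[str]) -> None:
        """Write as CSV with a leading provenance comment line."""
        prov = ",".join(f"{c}={self.provenance[c]}" for c in self.data.columns)
        header = f"# provenance: {prov}\n"
        if hasattr(target, "write"):
            target.write(header)
            self.data.to_csv(target, index_label="id")
        else:
            with open(target, "w", encoding="utf-8") as fh:
                fh.write(header)
                self.data.to_csv(fh, index_label="id")

    @classmethod
    def read_csv(cls, source: str | IO[str]) -> "DescriptorMatrix":
        """Read the CSV layout written by :meth:`to_csv`."""
        if hasattr(source, "read"):
            text = source.read()
        else:
            with open(source, encoding="utf-8") as fh:
                text = fh.read()
        lines = text.splitlines(keepends=True)
        provenance: dict[str, str] = {}
        body_start = 0
        for i, line in enumerate(lines):
            if line.startswith("#"):
                if "provenance:" in line:
                    spec = line.split("provenance:", 1)[1].strip()
                    for item in spec.split(","):
                        if "=" in item:
                            k, v = item.split("=", 1)
                            provenance[k.strip()] = v.strip()
                body_start = i + 1
            else:
                break
        import io as _io

        df = pd.read_csv(_io.StringIO("".join(lines[body_start:])), index_col="id")
        return cls(df, provenance)


def _data_file(name: str):
    return resources.files("nanodisp").joinpath("data").joinpath(name)


def load_packaged_smiles() -> dict[int, str]:
    """Structure encodings of the 29 solvents, keyed by compound id."""
    out: dict[int, str] = {}
    for line in _data_file("solvents.smi").read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        ident, smi = line.split(None, 1)
        out[int(ident)] = smi.strip()
    return out


def load_packaged_solvents(with_smiles: bool = True) -> list[SolventRecord]:
    """The packaged 29-solvent table, optionally joined with structures."""
    with _data_file("solvents.csv").open("r", encoding="utf-8") as fh:
        records = load_solvent_table(fh, strict=True)
    if with_smiles:
        smiles = load_packaged_smiles()
        records = [replace(r, smiles=smiles.get(r.id)) for r in records]
    return records


def load_sdf_structures(path: str) -> dict[int, str]:
    """Alternative structure input: an SDF file mapped to record ids.

    Each molecule must carry an integer id in an ``id`` property or, failing
    that, in its title line.  Returns id -> canonical SMILES, suitable for
    attaching to :class:`SolventRecord` rows.
    """
    from rdkit import Chem

    out: dict[int, str] = {}
    for k, mol in enumerate(Chem.SDMolSupplier(str(path))):
        if mol is None:
            raise ValueError(f"unparseable molecule at SDF position {k}")
        if mol.HasProp("id"):
            ident = int(mol.GetProp("id"))
        elif mol.GetProp("_Name").strip():
            ident = int(mol.GetProp("_Name").strip())
        else:
            raise ValueError(f"molecule at SDF position {k} carries no id")
        if ident in out:
            raise ValueError(f"duplicate id {ident} in SDF")
        out[ident] = Chem.MolToSmiles(mol)
    return out


def load_packaged_descriptor_matrix() -> DescriptorMatrix:
    """The packaged 29x6 descriptor matrix (all columns provenance='supplied')."""
    with _data_file("descriptors.csv").open("r", encoding="utf-8") as fh:
        return DescriptorMatrix.read_csv(fh)


def study_frame() -> pd.DataFrame:
    """Joined modelling frame: descriptors + LogC + split flag, indexed by id.

    Convenience entry point used by the Model constructors, the CLI and the
    reproduction report.
    """
    records = load_packaged_solvents(with_smiles=False)
    matrix = load_packaged_descriptor_matrix()
    df = matrix.data.copy()
    df["LogC"] = pd.Series({r.id: r.log_conc for r in records})
    df["split"] = pd.Series({r.id: r.split for r in records})
    return df
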