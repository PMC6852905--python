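"""Reading and writing QM9-style extended-XYZ files.

File layout::

    <n_atoms>
    <property line: whitespace-separated values, order given by a schema>
    <element  x  y  z  [extra per-atom columns, passed through]>
    ... (n_atoms rows)

The property line is schema-driven: a schema is an ordered tuple of field
names.  ``id`` is parsed as a string, ``multiplicity`` as an integer, every
other field as a float.  Orbital energies (``homo``/``lumo``) are stored in
Hartree on disk and converted to eV in :class:`~chemdiv.core.PropertyRecord`.
Both the plain ``1.23E-4`` and the QM9 ``1.23*^-4`` exponent dialects are
accepted; plain notation is emitted.
"""
from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .constants import ATOMIC_NUMBER, HARTREE_TO_EV
from .core import Dataset, Entry, Molecule, PropertyRecord

#: QM9-style schema: id tag then U0, HOMO, LUMO, zpve (all Hartree) and
#: spin multiplicity.
QM9_SCHEMA: tuple[str, ...] = ("id", "U0", "homo", "lumo", "zpve", "multiplicity")
#: PC9-style schema: electronic (SCF) energy, no zpve.
PC9_SCHEMA: tuple[str, ...] = ("id", "E", "homo", "lumo", "multiplicity")

_KNOWN_FIELDS = {"id", "U0", "E", "zpve", "homo", "lumo", "multiplicity"}


class XYZFormatError(ValueError):
    """Raised for a malformed extended-XYZ file; the message names the file."""


def _parse_float(token: str) -> float:
    # QM9 files in the wild write scientific notation as 1.23*^-4
    return float(token.replace("*^", "e"))


@dataclass
class XYZRecord:
    """One parsed extended-XYZ file before conversion to domain objects."""

    n_atoms: int
    properties: dict[str, object]
    elements: tuple[str, ...]
    coords: np.ndarray
    atom_extras: list[list[str]]

    def to_entry(self) -> Entry:
        props = self.properties
        mult = int(props.get("multiplicity", 1))
        mol = Molecule(
            elements=self.elements,
            coords=self.coords,
            multiplicity=mult,
            source_id=str(props.get("id", "")),
        )
        U0 = props.get("U0")
        zpve = props.get("zpve")
        E = props.get("E")
        if E is None and U0 is not None and zpve is not None:
            E = float(U0) - float(zpve)
        homo = props.get("homo")
        lumo = props.get("lumo")
        extras = {
            k: float(v)
            for k, v in props.items()
            if k not in _KNOWN_FIELDS and isinstance(v, float)
        }
        rec = PropertyRecord(
            E=None if E is None else float(E),
            U0=None if U0 is None else float(U0),
            zpve=None if zpve is None else float(zpve),
            homo=None if homo is None else float(homo) * HARTREE_TO_EV,
            lumo=None if lumo is None else float(lumo) * HARTREE_TO_EV,
            multiplicity=mult,
            extras=extras,
        )
        return Entry(mol, rec)


def parse_xyz(text: str, schema: Sequence[str] = QM9_SCHEMA, name: str = "<string>") -> XYZRecord:
    lines = [ln for ln in text.splitlines() if ln.strip() != ""]
    if not lines:
        raise XYZFormatError(f"{name}: empty file")
    try:
        n_atoms = int(lines[0].split()[0])
    except (ValueError, IndexError) as exc:
        raise XYZFormatError(f"{name}: malformed atom count line {lines[0]!r}") from exc
    if n_atoms < 1:
        raise XYZFormatError(f"{name}: atom count must be positive")
    if len(lines) < 2 + n_atoms:
        raise XYZFormatError(
            f"{name}: declares {n_atoms} atoms but only {max(len(lines) - 2, 0)} atom rows present"
        )
    tokens = lines[1].split()
    props: dict[str, object] = {}
    for i, field in enumerate(schema):
        if i >= len(tokens):
            raise XYZFormatError(
                f"{name}: property line has {len(tokens)} fields, schema expects {len(schema)}"
            )
        tok = tokens[i]
        if field == "id":
            props[field] = tok
        elif field == "multiplicity":
            props[field] = int(round(_parse_float(tok)))
        else:
            try:
                props[field] = _parse_float(tok)
            except ValueError as exc:
                raise XYZFormatError(
                    f"{name}: non-numeric value {tok!r} for property {field!r}"
                ) from exc
    elements: list[str] = []
    coords = np.empty((n_atoms, 3), dtype=float)
    atom_extras: list[list[str]] = []
    for row, ln in enumerate(lines[2 : 2 + n_atoms]):
        parts = ln.split()
        if len(parts) < 4:
            raise XYZFormatError(f"{name}: atom row {row} too short: {ln!r}")
        sym = parts[0]
        if sym not in ATOMIC_NUMBER:
            raise XYZFormatError(f"{name}: unknown element {sym!r} in atom row {row}")
        try:
            coords[row] = [_parse_float(p) for p in parts[1:4]]
        except ValueError as exc:
            raise XYZFormatError(f"{name}: non-numeric coordinate in atom row {row}") from exc
        elements.append(sym)
        atom_extras.append(parts[4:])
    if not np.all(np.isfinite(coords)):
        raise XYZFormatError(f"{name}: non-finite coordinate")
    return XYZRecord(n_atoms, props, tuple(elements), coords, atom_extras)


def read_dataset(path: str | Path, schema: Sequence[str] = QM9_SCHEMA) -> Dataset:
    """Read every ``*.xyz`` file under *path* (sorted by filename).

    Sorting makes the dataset identity independent of directory listing
    order.  A malformed file raises :class:`XYZFormatError` naming it.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    files = sorted(path.glob("*.xyz"))
    if not files:
        warnings.warn(f"no .xyz files found under {path}", stacklevel=2)
        return Dataset()
    entries = []
    for f in files:
        rec = parse_xyz(f.read_text(), schema=schema, name=f.name)
        entries.append(rec.to_entry())
    return Dataset(entries)


def _format_float(x: float) -> str:
    return f"{x: .10f}".strip()


def format_entry(entry: Entry, schema: Sequence[str] = QM9_SCHEMA) -> str:
    """Serialize one entry to extended-XYZ text under the given schema."""
    mol, p = entry.molecule, entry.properties
    fields = []
    for field in schema:
        if field == "id":
            fields.append(mol.source_id or "mol")
        elif field == "multiplicity":
            fields.append(str(int(p.multiplicity)))
        elif field in ("homo", "lumo"):
            v = getattr(p, field)
            if v is None:
                raise ValueError(f"entry missing property {field!r} required by schema")
            fields.append(_format_float(v / HARTREE_TO_EV))
        else:
            v = getattr(p, field, None)
            if v is None:
                v = p.extras.get(field)
            if v is None:
                raise ValueError(f"entry missing property {field!r} required by schema")
            fields.append(_format_float(float(v)))
    lines = [str(mol.n_atoms), "\t".join(fields)]
    for sym, (x, y, z) in zip(mol.elements, mol.coords):
        lines.append(f"{sym}\t{x: .10f}\t{y: .10f}\t{z: .10f}")
    return "\n".join(lines) + "\n"


_SAFE_NAME = re.compile(r"[^A-Za-z0-9_.-]+")


def write_dataset(dataset: Dataset, path: str | Path, schema: Sequence[str] = QM9_SCHEMA) -> list[Path]:
    """Write one XYZ file per entry into directory *path*; returns the paths."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    written = []
    for i, entry in enumerate(dataset):
        stem = _SAFE_NAME.sub("_", entry.molecule.source_id) or f"mol_{i:06d}"
        f = path / f"{stem}.xyz"
        f.write_text(format_entry(entry, schema=schema))
        written.append(f)
    return written


def write_report(report: pd.DataFrame, path: str | Path, format: str = "csv") -> Path:
    """Write a tabular report as CSV or JSON with deterministic bytes."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "csv":
        path.write_text(report.to_csv(index=False, lineterminator="\n"))
    elif format == "json":
        payload = report.to_dict(orient="records")
        path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=float) + "\n")
    else:
        raise ValueError(f"unknown report format {format!r}; use 'csv' or 'json'")
    return path
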