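"""Core in-memory containers: molecules, property records, datasets.

A :class:`Dataset` is an ordered list of :class:`Entry` objects, each pairing
a 3D :class:`Molecule` with its :class:`PropertyRecord`.  Everything
downstream (curation, descriptors, models, diversity profiling) consumes
these containers.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .constants import ATOMIC_NUMBER


@dataclass
class Molecule:
    """A molecular geometry: element symbols plus Cartesian coordinates [Angstrom]."""

    elements: tuple[str, ...]
    coords: np.ndarray  # shape (n_atoms, 3), Angstrom
    charge: int = 0
    multiplicity: int = 1
    source_id: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if len(self.elements) == 0:
            raise ValueError("molecule must contain at least one atom")
        if self.coords.shape != (len(self.elements), 3):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match "
                f"{len(self.elements)} atoms"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if self.multiplicity < 1:
            raise ValueError("multiplicity must be >= 1")
        unknown = [e for e in self.elements if e not in ATOMIC_NUMBER]
        if unknown:
            raise ValueError(f"unknown element symbol(s): {sorted(set(unknown))}")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def atomic_numbers(self) -> np.ndarray:
        return np.array([ATOMIC_NUMBER[e] for e in self.elements], dtype=int)

    @property
    def n_heavy_atoms(self) -> int:
        return sum(1 for e in self.elements if e != "H")

    def composition(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for e in self.elements:
            out[e] = out.get(e, 0) + 1
        return out


@dataclass
class PropertyRecord:
    """Per-molecule scalar properties.

    Energies (``U0``, ``E``, ``zpve``, ``nre``) are in Hartree; orbital
    energies (``homo``, ``lumo``) are in eV.  Missing values are ``None``.
    """

    E: float | None = None
    U0: float | None = None
    zpve: float | None = None
    homo: float | None = None
    lumo: float | None = None
    nre: float | None = None
    multiplicity: int = 1
    extras: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.U0 is not None and self.zpve is not None and self.E is not None:
            if not math.isclose(self.E, self.U0 - self.zpve, abs_tol=1e-9):
                raise ValueError("inconsistent record: E != U0 - zpve")


@dataclass
class Entry:
    molecule: Molecule
    properties: PropertyRecord
    #: canonical graph identifier, filled in by the curation module
    identifier: str | None = None

    def with_properties(self, **changes) -> "Entry":
        return Entry(self.molecule, replace(self.properties, **changes), self.identifier)


class Dataset:
    """An ordered collection of molecule entries with vectorized accessors."""

    def __init__(self, entries: Iterable[Entry] = ()):
        self.entries: list[Entry] = list(entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[Entry]:
        return iter(self.entries)

    def __getitem__(self, idx):
        if isinstance(idx, (int, np.integer)):
            return self.entries[idx]
        if isinstance(idx, slice):
            return Dataset(self.entries[idx])
        return Dataset([self.entries[i] for i in np.asarray(idx).tolist()])

    def molecules(self) -> list[Molecule]:
        return [e.molecule for e in self.entries]

    def property_array(self, name: str) -> np.ndarray:
        """Stack one property across entries (NaN where missing)."""
        vals = []
        for e in self.entries:
            v = getattr(e.properties, name)
            vals.append(np.nan if v is None else float(v))
        return np.array(vals, dtype=float)

    def source_ids(self) -> list[str]:
        return [e.molecule.source_id for e in self.entries]

    def identifiers(self) -> list[str | None]:
        return [e.identifier for e in self.entries]

    def max_atoms(self) -> int:
        return max((e.molecule.n_atoms for e in self.entries), default=0)

    def to_frame(self) -> pd.DataFrame:
        """Tabular summary of the dataset (one row per entry)."""
        rows = []
        for e in self.entries:
            p = e.properties
            rows.append(
                {
                    "source_id": e.molecule.source_id,
                    "identifier": e.identifier,
                    "n_atoms": e.molecule.n_atoms,
                    "n_heavy": e.molecule.n_heavy_atoms,
                    "multiplicity": e.molecule.multiplicity,
                    "E": p.E,
                    "U0": p.U0,
                    "zpve": p.zpve,
                    "homo": p.homo,
                    "lumo": p.lumo,
                    "nre": p.nre,
                }
            )
        return pd.DataFrame(rows)
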