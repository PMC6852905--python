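"""Energy bookkeeping: SCF energy from U0, atomization energies, nuclear repulsion.

All inputs are Hartree unless stated; atomization energies are returned in
kcal/mol because that is the scale on which energy-model errors are reported.
"""
from __future__ import annotations

from typing import Mapping

import numpy as np

from .constants import ANGSTROM_TO_BOHR, HARTREE_TO_KCALMOL
from .core import Dataset, Molecule

#: element -> free-atom reference energy [Hartree], keyed by level-of-theory label
AtomRefTable = Mapping[str, float]


def scf_from_u0(U0: float, zpve: float | None) -> float:
    """Electronic (SCF) energy: E = U0 - zpve.

    U0 includes the zero-point vibrational energy; datasets computed without
    frequency analysis report E directly, so a missing zpve is an error that
    points the caller at the E field instead.
    """
    if zpve is None:
        raise ValueError("zpve missing: use the dataset's E (SCF) energy directly")
    if not (np.isfinite(U0) and np.isfinite(zpve)):
        raise ValueError("U0 and zpve must be finite")
    return U0 - zpve


def atomization_energy(E: float, composition: Mapping[str, int], ref_table: AtomRefTable) -> float:
    """Total energy minus the summed free-atom reference energies, in kcal/mol."""
    missing = [el for el in composition if el not in ref_table]
    if missing:
        raise KeyError(f"atom reference table missing element(s): {sorted(missing)}")
    ref_sum = sum(ref_table[el] * n for el, n in composition.items())
    return (E - ref_sum) * HARTREE_TO_KCALMOL


def atomization_energies(dataset: Dataset, ref_table: AtomRefTable, property: str = "E") -> np.ndarray:
    """Vectorized atomization energy [kcal/mol] for every entry of a dataset."""
    out = np.empty(len(dataset))
    for i, entry in enumerate(dataset):
        E = getattr(entry.properties, property)
        if E is None:
            raise ValueError(f"entry {entry.molecule.source_id!r} missing property {property!r}")
        out[i] = atomization_energy(E, entry.molecule.composition(), ref_table)
    return out


def nuclear_repulsion_energy(molecule: Molecule) -> float:
    """NRE = sum_{I<J} Z_I Z_J / |R_I - R_J| in Hartree (distances in Bohr)."""
    Z = molecule.atomic_numbers.astype(float)
    R = molecule.coords * ANGSTROM_TO_BOHR
    n = len(Z)
    if n == 1:
        return 0.0
    diff = R[:, None, :] - R[None, :, :]
    dist = np.sqrt((diff**2).sum(-1))
    iu = np.triu_indices(n, k=1)
    d = dist[iu]
    if np.any(d <= 0.0):
        raise ValueError("coincident atoms: NRE undefined")
    return float(((Z[:, None] * Z[None, :])[iu] / d).sum())


def attach_nre(dataset: Dataset) -> Dataset:
    """Return a dataset copy with the nre property computed for every entry."""
    return Dataset(
        e.with_properties(nre=nuclear_repulsion_energy(e.molecule)) for e in dataset
    )
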