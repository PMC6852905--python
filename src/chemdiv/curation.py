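"""Dataset curation: graph perception, canonical identity, constraints, overlap.

Molecular graphs are perceived from 3D geometry with a covalent-radius
distance criterion, after which bond orders and aromaticity are assigned by
valence rules.  Canonical identity is the standard InChI, optionally with
the enantiomeric sublayers (/t, /m, /s) stripped so that mirror-image
geometries of one constitution compare equal.  The overlap split mirrors the
common/exclusive partition used when two datasets covering the same chemical
constraints are compared.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import rdDetermineBonds

from .constants import (
    BOND_PERCEPTION_TOLERANCE,
    COVALENT_RADIUS,
    HARTREE_TO_KCALMOL,
    QM9_ELEMENTS,
    QM9_MAX_HEAVY_ATOMS,
)
from .core import Dataset, Entry, Molecule

logger = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.warning")


class GraphPerceptionError(ValueError):
    """Geometry could not be turned into a chemically sensible graph."""


@dataclass
class MolGraph:
    """A perceived molecular graph backed by an RDKit molecule."""

    elements: tuple[str, ...]
    bonds: list[tuple[int, int, float]]  # (i, j, order); 1.5 marks aromatic
    aromatic: np.ndarray  # per-atom flags
    rings: list[tuple[int, ...]]
    rdmol: Chem.Mol = field(repr=False, default=None)

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def bond_set(self) -> set[tuple[int, int]]:
        return {(min(i, j), max(i, j)) for i, j, _ in self.bonds}


def perceive_connectivity(molecule: Molecule, tolerance: float = BOND_PERCEPTION_TOLERANCE) -> list[tuple[int, int]]:
    """Bonded atom pairs: d(i,j) < r_cov(i) + r_cov(j) + tolerance."""
    coords = molecule.coords
    n = molecule.n_atoms
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff**2).sum(-1))
    iu = np.triu_indices(n, k=1)
    if n > 1 and dist[iu].min() < 0.3:
        raise GraphPerceptionError(
            f"{molecule.source_id!r}: atoms closer than 0.3 A, geometry not sensible"
        )
    radii = np.array([COVALENT_RADIUS.get(e, 0.0) for e in molecule.elements])
    cutoff = radii[:, None] + radii[None, :] + tolerance
    pairs = [(int(i), int(j)) for i, j in zip(*iu) if dist[i, j] < cutoff[i, j]]
    return pairs


def perceive_graph(molecule: Molecule, tolerance: float = BOND_PERCEPTION_TOLERANCE) -> MolGraph:
    """Perceive bonds from geometry, then assign orders and aromaticity.

    Bond orders are completed by valence rules (via RDKit's 3D bond-order
    determination on the perceived connectivity).  Molecules for which no
    valence assignment exists raise :class:`GraphPerceptionError`; callers
    curating whole datasets catch this and exclude the molecule with a log
    entry rather than aborting.
    """
    pairs = perceive_connectivity(molecule, tolerance)
    rw = Chem.RWMol()
    for e in molecule.elements:
        rw.AddAtom(Chem.Atom(e))
    for i, j in pairs:
        rw.AddBond(i, j, Chem.BondType.SINGLE)
    conf = Chem.Conformer(molecule.n_atoms)
    for i, p in enumerate(molecule.coords):
        conf.SetAtomPosition(i, [float(p[0]), float(p[1]), float(p[2])])
    rw.AddConformer(conf)
    mol = rw.GetMol()
    try:
        rdDetermineBonds.DetermineBondOrders(mol, charge=molecule.charge)
    except Exception:
        # Open-shell or artefact geometries: keep the perceived connectivity
        # with single bonds and explicit hydrogen counts.  InChI identity is
        # connectivity-based, so this still yields a usable identifier.
        mol = rw.GetMol()
        for atom in mol.GetAtoms():
            atom.SetNoImplicit(True)
        try:
            Chem.SanitizeMol(
                mol,
                Chem.SanitizeFlags.SANITIZE_ALL
                ^ Chem.SanitizeFlags.SANITIZE_PROPERTIES,
            )
        except Exception as exc:  # pragma: no cover - truly degenerate input
            raise GraphPerceptionError(
                f"{molecule.source_id!r}: no valence assignment found"
            ) from exc
    try:
        Chem.AssignStereochemistryFrom3D(mol)
    except Exception:
        pass  # stereo perception is best-effort; identity falls back to constitution
    bonds = []
    for b in mol.GetBonds():
        order = 1.5 if b.GetIsAromatic() else float(b.GetBondTypeAsDouble())
        bonds.append((b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order))
    aromatic = np.array([a.GetIsAromatic() for a in mol.GetAtoms()], dtype=bool)
    rings = [tuple(r) for r in mol.GetRingInfo().AtomRings()]
    return MolGraph(
        elements=molecule.elements,
        bonds=bonds,
        aromatic=aromatic,
        rings=rings,
        rdmol=mol,
    )


_STEREO_LAYER = re.compile(r"/[tms][^/]*")


def strip_enantiomeric_layers(inchi: str) -> str:
    """Remove the /t, /m and /s stereo sublayers from an InChI string."""
    return _STEREO_LAYER.sub("", inchi)


def canonical_identifier(graph: MolGraph, drop_enantiomeric_layer: bool = True) -> str:
    """Standard InChI of a perceived graph, optionally stereo-stripped."""
    inchi = Chem.MolToInchi(graph.rdmol, treatWarningAsError=False)
    if not inchi:
        raise GraphPerceptionError("InChI generation failed")
    if drop_enantiomeric_layer:
        inchi = strip_enantiomeric_layers(inchi)
    return inchi


def compute_identifiers(dataset: Dataset, drop_enantiomeric_layer: bool = True) -> tuple[Dataset, list[Entry]]:
    """Attach canonical identifiers; unperceivable molecules are excluded and returned."""
    kept, flagged = [], []
    for entry in dataset:
        try:
            graph = perceive_graph(entry.molecule)
            ident = canonical_identifier(graph, drop_enantiomeric_layer)
        except GraphPerceptionError as exc:
            logger.warning("excluding %s: %s", entry.molecule.source_id, exc)
            flagged.append(entry)
            continue
        kept.append(Entry(entry.molecule, entry.properties, identifier=ident))
    return Dataset(kept), flagged


def apply_qm9_constraints(
    dataset: Dataset,
    elements: frozenset[str] = QM9_ELEMENTS,
    max_heavy_atoms: int = QM9_MAX_HEAVY_ATOMS,
) -> tuple[Dataset, list[tuple[Entry, str]]]:
    """Keep molecules with <= 9 heavy atoms drawn from {H,C,N,O,F}.

    Returns (kept, rejected) where each rejection carries the violated rule.
    The operation is idempotent: re-applying it to ``kept`` changes nothing.
    """
    kept, rejected = [], []
    for entry in dataset:
        mol = entry.molecule
        bad_elements = sorted(set(mol.elements) - elements)
        if bad_elements:
            rejected.append((entry, f"element: {','.join(bad_elements)} not allowed"))
        elif mol.n_heavy_atoms > max_heavy_atoms:
            rejected.append(
                (entry, f"size: {mol.n_heavy_atoms} heavy atoms > {max_heavy_atoms}")
            )
        else:
            kept.append(entry)
    return Dataset(kept), rejected


def deduplicate(dataset: Dataset) -> Dataset:
    """One representative per identifier: lowest total energy, ties by source_id."""
    groups: dict[str, list[Entry]] = {}
    order: list[str] = []
    for entry in dataset:
        if entry.identifier is None:
            raise ValueError("identifiers must be computed before deduplication")
        if entry.identifier not in groups:
            order.append(entry.identifier)
        groups.setdefault(entry.identifier, []).append(entry)
    survivors = []
    for ident in order:
        group = sorted(
            groups[ident],
            key=lambda e: (
                np.inf if e.properties.E is None else e.properties.E,
                e.molecule.source_id,
            ),
        )
        survivors.append(group[0])
    return Dataset(survivors)


@dataclass
class OverlapPartition:
    """Common/exclusive index partition of two identifier-annotated datasets."""

    common_A: list[int]
    exclusive_A: list[int]
    common_B: list[int]
    exclusive_B: list[int]
    matched_pairs: list[tuple[str, str]]

    def swap(self) -> "OverlapPartition":
        return OverlapPartition(
            self.common_B, self.exclusive_B, self.common_A, self.exclusive_A,
            [(b, a) for a, b in self.matched_pairs],
        )


def split_overlap(dataset_A: Dataset, dataset_B: Dataset) -> OverlapPartition:
    """Partition both datasets by identifier equality."""
    ids_A = dataset_A.identifiers()
    ids_B = dataset_B.identifiers()
    if any(i is None for i in ids_A) or any(i is None for i in ids_B):
        raise ValueError("identifiers must be computed on both datasets")
    set_A, set_B = set(ids_A), set(ids_B)
    shared = set_A & set_B
    common_A = [i for i, ident in enumerate(ids_A) if ident in shared]
    exclusive_A = [i for i, ident in enumerate(ids_A) if ident not in shared]
    common_B = [i for i, ident in enumerate(ids_B) if ident in shared]
    exclusive_B = [i for i, ident in enumerate(ids_B) if ident not in shared]
    first_B = {}
    for i, ident in enumerate(ids_B):
        first_B.setdefault(ident, i)
    matched = [
        (dataset_A[i].molecule.source_id, dataset_B[first_B[ids_A[i]]].molecule.source_id)
        for i in common_A
    ]
    return OverlapPartition(common_A, exclusive_A, common_B, exclusive_B, matched)


def conformer_discrepancy(
    partition: OverlapPartition,
    dataset_A: Dataset,
    dataset_B: Dataset,
    nre_flag_threshold: float = 10_000.0,
) -> pd.DataFrame:
    """Per matched pair: energy and NRE deltas (B - A) in kcal/mol.

    Identifier matching can pair different tautomeric or conformational
    forms; a large |dNRE| (default flag threshold 10,000 kcal/mol) marks
    such geometry mismatches.
    """
    from .energetics import nuclear_repulsion_energy

    id_to_B = {}
    for i, ident in enumerate(dataset_B.identifiers()):
        id_to_B.setdefault(ident, i)
    rows = []
    for i in partition.common_A:
        a = dataset_A[i]
        j = id_to_B.get(a.identifier)
        if j is None:
            raise KeyError(f"identifier {a.identifier!r} not found in dataset B")
        b = dataset_B[j]
        nre_a = a.properties.nre
        nre_b = b.properties.nre
        if nre_a is None:
            nre_a = nuclear_repulsion_energy(a.molecule)
        if nre_b is None:
            nre_b = nuclear_repulsion_energy(b.molecule)
        dE = None
        if a.properties.E is not None and b.properties.E is not None:
            dE = (b.properties.E - a.properties.E) * HARTREE_TO_KCALMOL
        dNRE = (nre_b - nre_a) * HARTREE_TO_KCALMOL
        rows.append(
            {
                "id_A": a.molecule.source_id,
                "id_B": b.molecule.source_id,
                "delta_E_kcalmol": dE,
                "delta_NRE_kcalmol": dNRE,
                "nre_flagged": abs(dNRE) > nre_flag_threshold,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["id_A", "id_B", "delta_E_kcalmol", "delta_NRE_kcalmol", "nre_flagged"],
    )
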