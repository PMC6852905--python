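"""Synthetic paired molecule datasets with known statistical structure.

The generator draws molecules from a pool of small-fragment templates
(alkanes, alcohols, ethers, amines, alkynes, nitriles, peroxides, acids,
fluorides, aromatics...), each carrying a fixed idealized 3D geometry, and
labels every instance with an additive ground-truth energy:

    E = sum(atom terms) + sum(bond terms) + multiplicity penalty + noise

so that every downstream stage — curation, descriptors, regression models,
generalization analysis, diversity profiling, SOM affinity — can be tested
against a known truth without downloading any quantum-chemistry data.

Two sets generated with nested functional-group coverage emulate the
situation where one dataset spans broader chemistry than the other; an
affine "level-of-theory" shift between paired sets emulates energies
computed with two different basis sets.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .core import Dataset, Entry, Molecule, PropertyRecord

# ---------------------------------------------------------------------------
# Template catalogue
# ---------------------------------------------------------------------------

#: name -> (SMILES, coarse coverage labels).  Labels drive the
#: ``group_coverage`` filter; they are deliberately coarser than the
#: SMARTS-level functional-group census in :mod:`chemdiv.chemspace`.
TEMPLATE_CATALOGUE: dict[str, tuple[str, frozenset[str]]] = {
    "methane": ("C", frozenset({"alkane"})),
    "ethane": ("CC", frozenset({"alkane"})),
    "propane": ("CCC", frozenset({"alkane"})),
    "butane": ("CCCC", frozenset({"alkane"})),
    "isobutane": ("CC(C)C", frozenset({"alkane"})),
    "cyclopropane": ("C1CC1", frozenset({"alkane", "ring"})),
    "water": ("O", frozenset({"alcohol"})),
    "methanol": ("CO", frozenset({"alcohol"})),
    "ethanol": ("CCO", frozenset({"alcohol"})),
    "isopropanol": ("CC(O)C", frozenset({"alcohol", "secondary_alcohol"})),
    "dimethyl_ether": ("COC", frozenset({"ether"})),
    "methoxyethane": ("CCOC", frozenset({"ether"})),
    "oxirane": ("C1CO1", frozenset({"ether", "ring", "heterocycle"})),
    "methylamine": ("CN", frozenset({"amine"})),
    "dimethylamine": ("CNC", frozenset({"amine"})),
    "trimethylamine": ("CN(C)C", frozenset({"amine", "tertiary_amine"})),
    "acetonitrile": ("CC#N", frozenset({"nitrile"})),
    "propionitrile": ("CCC#N", frozenset({"nitrile"})),
    "propyne": ("CC#C", frozenset({"alkyne"})),
    "but_2_yne": ("CC#CC", frozenset({"alkyne"})),
    "hydrogen_peroxide": ("OO", frozenset({"peroxide"})),
    "methyl_hydroperoxide": ("COO", frozenset({"peroxide", "hydroperoxide"})),
    "dimethyl_peroxide": ("COOC", frozenset({"peroxide"})),
    "formic_acid": ("OC=O", frozenset({"carboxylic_acid"})),
    "acetic_acid": ("CC(=O)O", frozenset({"carboxylic_acid"})),
    "fluoromethane": ("CF", frozenset({"fluoride"})),
    "fluoroethane": ("CCF", frozenset({"fluoride"})),
    "benzene": ("c1ccccc1", frozenset({"aromatic", "ring"})),
    "toluene": ("Cc1ccccc1", frozenset({"aromatic", "ring"})),
    "fluorobenzene": ("Fc1ccccc1", frozenset({"aromatic", "ring", "fluoride"})),
    "phenol": ("Oc1ccccc1", frozenset({"aromatic", "ring", "alcohol"})),
}


@dataclass(frozen=True)
class Template:
    name: str
    elements: tuple[str, ...]
    coords: np.ndarray
    bonds: tuple[tuple[int, int, float], ...]  # (i, j, order); 1.5 aromatic
    groups: frozenset[str]

    @property
    def n_heavy(self) -> int:
        return sum(1 for e in self.elements if e != "H")


@lru_cache(maxsize=None)
def get_template(name: str) -> Template:
    """Build a template's idealized geometry (deterministic per name).

    Geometries come from distance-geometry embedding followed by a force
    field relaxation with a name-derived fixed seed, giving standard bond
    lengths and angles without any conformer search.
    """
    smiles, groups = TEMPLATE_CATALOGUE[name]
    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    params = AllChem.ETKDGv3()
    params.randomSeed = zlib.crc32(name.encode()) % (2**31 - 1)
    if AllChem.EmbedMolecule(mol, params) != 0:
        raise RuntimeError(f"embedding failed for template {name}")
    AllChem.MMFFOptimizeMolecule(mol)
    conf = mol.GetConformer()
    coords = np.array(
        [[conf.GetAtomPosition(i).x, conf.GetAtomPosition(i).y, conf.GetAtomPosition(i).z]
         for i in range(mol.GetNumAtoms())]
    )
    bonds = tuple(
        (
            b.GetBeginAtomIdx(),
            b.GetEndAtomIdx(),
            1.5 if b.GetIsAromatic() else float(b.GetBondTypeAsDouble()),
        )
        for b in mol.GetBonds()
    )
    elements = tuple(a.GetSymbol() for a in mol.GetAtoms())
    return Template(name, elements, coords, bonds, groups)


# ---------------------------------------------------------------------------
# Specifications
# ---------------------------------------------------------------------------


@dataclass
class GeneratorSpec:
    """What to generate: pool, constraints, coverage, overlap, jitter, seed."""

    n_molecules: int = 500
    template_pool: tuple[str, ...] = tuple(TEMPLATE_CATALOGUE)
    element_whitelist: frozenset[str] = frozenset({"H", "C", "N", "O", "F"})
    max_heavy_atoms: int = 9
    group_coverage: frozenset[str] | None = None  # None = everything
    overlap_fraction: float = 0.0
    coordinate_jitter_sd: float = 0.02  # Angstrom
    #: fraction of molecules flagged with spin multiplicity 2 or 3 (flags
    #: alter only the energy penalty and metadata, never the geometry)
    multiplet_fraction: float = 0.054
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction must lie in [0, 1]")
        if self.max_heavy_atoms < 1:
            raise ValueError("max_heavy_atoms must be >= 1")

    def feasible_templates(self) -> list[Template]:
        feasible, reasons = [], []
        for name in self.template_pool:
            t = get_template(name)
            if not set(t.elements) <= self.element_whitelist:
                reasons.append(f"{name}: element outside whitelist")
            elif t.n_heavy > self.max_heavy_atoms:
                reasons.append(f"{name}: {t.n_heavy} heavy atoms > {self.max_heavy_atoms}")
            elif self.group_coverage is not None and not t.groups <= self.group_coverage:
                reasons.append(f"{name}: groups {sorted(t.groups)} outside coverage")
            else:
                feasible.append(t)
        if not feasible:
            raise ValueError(
                "no feasible templates; violated constraints: " + "; ".join(reasons)
            )
        return feasible


def _default_bond_terms() -> dict[tuple[str, str, float], float]:
    # Mean bond enthalpies (kJ/mol) converted to Hartree, sign-flipped so a
    # bound molecule sits below its free atoms.
    kj = {
        ("C", "C", 1.0): 347, ("C", "C", 1.5): 505, ("C", "C", 2.0): 611,
        ("C", "C", 3.0): 839, ("C", "H", 1.0): 413, ("C", "N", 1.0): 305,
        ("C", "N", 1.5): 450, ("C", "N", 2.0): 615, ("C", "N", 3.0): 891,
        ("C", "O", 1.0): 358, ("C", "O", 2.0): 745, ("C", "F", 1.0): 485,
        ("H", "N", 1.0): 391, ("H", "O", 1.0): 467, ("N", "N", 1.0): 160,
        ("N", "N", 2.0): 418, ("N", "N", 3.0): 945, ("N", "O", 1.0): 201,
        ("N", "O", 2.0): 607, ("O", "O", 1.0): 146, ("F", "H", 1.0): 565,
    }
    return {k: -v / 2625.4996 for k, v in kj.items()}


@dataclass
class EnergyModelSpec:
    """Additive ground-truth energy model standing in for quantum targets."""

    atom_terms: dict[str, float] = field(
        default_factory=lambda: {"H": -0.5, "C": -37.8, "N": -54.6, "O": -75.0, "F": -99.7}
    )
    bond_terms: dict[tuple[str, str, float], float] = field(default_factory=_default_bond_terms)
    noise_sd: float = 1e-3  # Hartree, ~0.6 kcal/mol, a DFT-protocol-scale scatter
    #: HOMO/LUMO [eV] as linear functions of elemental composition:
    #: intercept + sum(coef[el] * count), plus Gaussian noise
    homo_rule: dict[str, float] = field(
        default_factory=lambda: {"const": -7.0, "C": 0.10, "N": 0.25, "O": -0.20, "F": -0.35}
    )
    lumo_rule: dict[str, float] = field(
        default_factory=lambda: {"const": 1.5, "C": -0.12, "N": -0.20, "O": -0.15, "F": -0.10}
    )
    orbital_noise_sd: float = 0.05  # eV
    #: destabilization added for open-shell species (multiplicity > 1);
    #: ~50 kcal/mol so unmodelled multiplets become genuine outliers
    multiplicity_penalty: float = 0.08  # Hartree
    #: deterministic zpve proxy per atom [Hartree], so U0 = E + zpve paths run
    zpve_per_atom: float = 0.004

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def bond_term(self, el_i: str, el_j: str, order: float) -> float:
        key = (min(el_i, el_j), max(el_i, el_j), float(order))
        if key not in self.bond_terms:
            raise KeyError(f"no bond term for {key}")
        return self.bond_terms[key]

    def template_energy(self, template: Template) -> float:
        """Noiseless closed-shell energy of a template (atom + bond terms)."""
        e = sum(self.atom_terms[el] for el in template.elements)
        for i, j, order in template.bonds:
            e += self.bond_term(template.elements[i], template.elements[j], order)
        return e

    def template_atomization(self, template: Template) -> float:
        """Noiseless atomization part: the bond-term sum [Hartree]."""
        return self.template_energy(template) - sum(
            self.atom_terms[el] for el in template.elements
        )

    def orbital(self, rule: dict[str, float], composition: dict[str, int]) -> float:
        return rule.get("const", 0.0) + sum(
            rule.get(el, 0.0) * n for el, n in composition.items()
        )


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def _make_entry(
    template: Template,
    energy_spec: EnergyModelSpec,
    rng: np.random.Generator,
    jitter_sd: float,
    multiplet_fraction: float,
    source_id: str,
) -> Entry:
    coords = template.coords + rng.normal(0.0, jitter_sd, size=template.coords.shape)
    multiplicity = 1
    if multiplet_fraction > 0 and rng.random() < multiplet_fraction:
        multiplicity = 2 if rng.random() < 5.0 / 6.0 else 3
    E = energy_spec.template_energy(template)
    if multiplicity > 1:
        E += energy_spec.multiplicity_penalty
    if energy_spec.noise_sd > 0:
        E += rng.normal(0.0, energy_spec.noise_sd)
    comp: dict[str, int] = {}
    for el in template.elements:
        comp[el] = comp.get(el, 0) + 1
    homo = energy_spec.orbital(energy_spec.homo_rule, comp)
    lumo = energy_spec.orbital(energy_spec.lumo_rule, comp)
    if energy_spec.orbital_noise_sd > 0:
        homo += rng.normal(0.0, energy_spec.orbital_noise_sd)
        lumo += rng.normal(0.0, energy_spec.orbital_noise_sd)
    zpve = energy_spec.zpve_per_atom * len(template.elements)
    mol = Molecule(
        elements=template.elements,
        coords=coords,
        multiplicity=multiplicity,
        source_id=source_id,
    )
    rec = PropertyRecord(
        E=E, U0=E + zpve, zpve=zpve, homo=homo, lumo=lumo,
        multiplicity=multiplicity,
        extras={"template_atomization": energy_spec.template_atomization(template)},
    )
    return Entry(mol, rec)


def generate_dataset(
    gen_spec: GeneratorSpec,
    energy_spec: EnergyModelSpec | None = None,
    prefix: str = "syn",
) -> Dataset:
    """Draw ``n_molecules`` template instances with jitter, energies and flags."""
    energy_spec = energy_spec or EnergyModelSpec()
    rng = np.random.default_rng(gen_spec.seed)
    templates = gen_spec.feasible_templates()
    entries = []
    for i in range(gen_spec.n_molecules):
        t = templates[int(rng.integers(len(templates)))]
        entries.append(
            _make_entry(
                t, energy_spec, rng, gen_spec.coordinate_jitter_sd,
                gen_spec.multiplet_fraction, f"{prefix}_{i:05d}_{t.name}",
            )
        )
    return Dataset(entries)


@dataclass
class PairPartition:
    """Ground-truth shared/exclusive indices of a generated dataset pair."""

    shared_A: list[int]
    exclusive_A: list[int]
    shared_B: list[int]
    exclusive_B: list[int]


def generate_pair(
    spec_A: GeneratorSpec,
    spec_B: GeneratorSpec,
    energy_spec: EnergyModelSpec | None = None,
) -> tuple[Dataset, Dataset, PairPartition]:
    """Two overlapping datasets with a known shared/exclusive partition.

    ``spec_A.overlap_fraction`` controls the shared count: that fraction of
    the smaller set consists of instances generated once (from templates in
    both coverages) and copied verbatim into both datasets.  Exclusive
    molecules are drawn from each side's coverage, preferring templates
    outside the partner's coverage when any exist, so that the exclusive
    parts genuinely probe unshared chemistry.
    """
    energy_spec = energy_spec or EnergyModelSpec()
    rng = np.random.default_rng(spec_A.seed)
    templates_A = spec_A.feasible_templates()
    templates_B = spec_B.feasible_templates()
    names_A = {t.name for t in templates_A}
    names_B = {t.name for t in templates_B}
    shared_pool = [t for t in templates_A if t.name in names_B]
    excl_pool_A = [t for t in templates_A if t.name not in names_B] or templates_A
    excl_pool_B = [t for t in templates_B if t.name not in names_A] or templates_B

    n_shared = int(round(spec_A.overlap_fraction * min(spec_A.n_molecules, spec_B.n_molecules)))
    if n_shared > 0 and not shared_pool:
        raise ValueError("overlap requested but the coverages share no template")

    shared_entries = [
        _make_entry(
            shared_pool[int(rng.integers(len(shared_pool)))], energy_spec, rng,
            spec_A.coordinate_jitter_sd, spec_A.multiplet_fraction, f"shared_{i:05d}",
        )
        for i in range(n_shared)
    ]

    def _exclusives(pool, n, spec, prefix):
        return [
            _make_entry(
                pool[int(rng.integers(len(pool)))], energy_spec, rng,
                spec.coordinate_jitter_sd, spec.multiplet_fraction, f"{prefix}_{i:05d}",
            )
            for i in range(n)
        ]

    excl_A = _exclusives(excl_pool_A, spec_A.n_molecules - n_shared, spec_A, "exclA")
    excl_B = _exclusives(excl_pool_B, spec_B.n_molecules - n_shared, spec_B, "exclB")

    ds_A = Dataset(shared_entries + excl_A)
    ds_B = Dataset([Entry(e.molecule, e.properties, e.identifier) for e in shared_entries] + excl_B)
    part = PairPartition(
        shared_A=list(range(n_shared)),
        exclusive_A=list(range(n_shared, len(ds_A))),
        shared_B=list(range(n_shared)),
        exclusive_B=list(range(n_shared, len(ds_B))),
    )
    return ds_A, ds_B, part


def apply_theory_shift(
    dataset: Dataset,
    a: float = 1.0,
    b: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> Dataset:
    """Affine "level-of-theory" shift of the energies: E' = a*E + b + eps.

    Emulates the systematic offset between two basis sets; geometries,
    identifiers and every other property are untouched.
    """
    rng = np.random.default_rng(seed)
    out = []
    for entry in dataset:
        E = entry.properties.E
        if E is None:
            raise ValueError("dataset entries must carry an energy E")
        E2 = a * E + b + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
        zpve = entry.properties.zpve
        out.append(
            entry.with_properties(E=E2, U0=None if zpve is None else E2 + zpve)
        )
    return Dataset(out)


def atom_ref_table(energy_spec: EnergyModelSpec) -> dict[str, float]:
    """Free-atom reference energies consistent with the generator's truth."""
    return dict(energy_spec.atom_terms)
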