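"""Chemical-diversity profiling: bond lengths, functional groups, scaffolds.

Three complementary views of what chemistry a dataset actually contains:

* density estimates of bond lengths per element pair (perceived bonds only),
* a functional-group census from a curated SMARTS pattern set,
* first-layer (Murcko-style) scaffolds with the acyclic fraction and the
  cumulative scaffold-frequency curve.

Functional-group detection is pattern-based; absolute counts are therefore
detector-dependent and comparisons should be made within one detector.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold
from scipy.stats import gaussian_kde

from .constants import ANGSTROM_TO_PM
from .core import Dataset
from .curation import GraphPerceptionError, MolGraph, perceive_graph

#: the element pairs profiled in the bond-length analysis
DEFAULT_BOND_PAIRS = (
    ("C", "C"), ("C", "H"), ("C", "N"), ("C", "O"), ("C", "F"),
    ("N", "N"), ("N", "H"), ("O", "N"), ("O", "H"),
)


# ---------------------------------------------------------------------------
# Bond-length densities
# ---------------------------------------------------------------------------


@dataclass
class BondLengthDensity:
    """Sampled bond lengths [pm] for one element pair with a KDE on a fixed grid."""

    pair: tuple[str, str]
    lengths_pm: np.ndarray
    grid_pm: np.ndarray
    density: np.ndarray  # per-pm density; integrates to 1 when non-empty

    @property
    def empty(self) -> bool:
        return len(self.lengths_pm) == 0


def collect_bond_lengths(
    dataset: Dataset, pair: tuple[str, str], graphs: list[MolGraph] | None = None
) -> np.ndarray:
    """Lengths [pm] of perceived bonds between the two elements (either order)."""
    want = frozenset(pair) if pair[0] != pair[1] else frozenset({pair[0]})
    out = []
    for k, entry in enumerate(dataset):
        graph = graphs[k] if graphs is not None else perceive_graph(entry.molecule)
        if graph is None:
            continue
        coords = entry.molecule.coords
        for i, j, _ in graph.bonds:
            if frozenset({graph.elements[i], graph.elements[j]}) == want:
                out.append(np.linalg.norm(coords[i] - coords[j]) * ANGSTROM_TO_PM)
    return np.array(out)


def bond_length_profile(
    dataset: Dataset,
    pair_list: tuple[tuple[str, str], ...] = DEFAULT_BOND_PAIRS,
    grid_pm: np.ndarray | None = None,
) -> list[BondLengthDensity]:
    """Gaussian KDE (Scott's rule) of bond lengths per pair on a shared grid.

    The grid is fixed (default 50-200 pm) so that profiles from different
    datasets overlay directly.  Pairs with no occurrences come back empty.
    """
    if grid_pm is None:
        grid_pm = np.linspace(50.0, 200.0, 601)
    graphs: list[MolGraph | None] = []
    for entry in dataset:
        try:
            graphs.append(perceive_graph(entry.molecule))
        except GraphPerceptionError:
            graphs.append(None)
    profiles = []
    for pair in pair_list:
        lengths = collect_bond_lengths(dataset, pair, graphs=graphs)
        if len(lengths) == 0:
            density = np.zeros_like(grid_pm)
        elif np.std(lengths) < 0.5:
            # (near-)degenerate sample: a narrow Gaussian at the mean, since
            # the KDE bandwidth collapses below the grid resolution
            sd = 0.5
            density = np.exp(-((grid_pm - lengths.mean()) ** 2) / (2 * sd**2)) / (
                sd * np.sqrt(2 * np.pi)
            )
        else:
            density = gaussian_kde(lengths, bw_method="scott")(grid_pm)
        profiles.append(BondLengthDensity(pair, lengths, grid_pm, density))
    return profiles


# ---------------------------------------------------------------------------
# Functional groups
# ---------------------------------------------------------------------------


def load_group_patterns() -> dict[str, Chem.Mol]:
    """The bundled (label -> SMARTS) pattern set, compiled."""
    raw = json.loads(
        resources.files("chemdiv").joinpath("data/functional_groups.json").read_text()
    )
    patterns = {}
    for label, smarts in raw.items():
        patt = Chem.MolFromSmarts(smarts)
        if patt is None:
            raise ValueError(f"invalid SMARTS for group {label!r}: {smarts}")
        patterns[label] = patt
    return patterns


_PATTERN_CACHE: dict[str, Chem.Mol] | None = None


def detect_functional_groups(graph: MolGraph, patterns: dict[str, Chem.Mol] | None = None) -> set[str]:
    """Labels of every bundled pattern the perceived graph matches."""
    global _PATTERN_CACHE
    if patterns is None:
        if _PATTERN_CACHE is None:
            _PATTERN_CACHE = load_group_patterns()
        patterns = _PATTERN_CACHE
    mol = graph.rdmol
    return {label for label, patt in patterns.items() if mol.HasSubstructMatch(patt)}


@dataclass
class FunctionalGroupTable:
    """Per-molecule group labels plus the dataset-level census."""

    per_molecule: list[set[str]]

    def counts(self) -> pd.DataFrame:
        tally: dict[str, int] = {}
        for groups in self.per_molecule:
            for g in groups:
                tally[g] = tally.get(g, 0) + 1
        rows = [{"group": g, "n_molecules": n} for g, n in sorted(tally.items())]
        return pd.DataFrame(rows, columns=["group", "n_molecules"])

    @property
    def groups_per_molecule(self) -> float:
        if not self.per_molecule:
            return 0.0
        return float(np.mean([len(g) for g in self.per_molecule]))

    @property
    def n_distinct_groups(self) -> int:
        return len(set().union(*self.per_molecule)) if self.per_molecule else 0


def functional_group_table(dataset: Dataset) -> FunctionalGroupTable:
    patterns = load_group_patterns()
    per_mol = []
    for entry in dataset:
        try:
            graph = perceive_graph(entry.molecule)
            per_mol.append(detect_functional_groups(graph, patterns))
        except GraphPerceptionError:
            per_mol.append(set())
    return FunctionalGroupTable(per_mol)


# ---------------------------------------------------------------------------
# Scaffolds
# ---------------------------------------------------------------------------


@dataclass
class ScaffoldSummary:
    """First-layer scaffold keys, acyclic fraction, frequency structure."""

    per_molecule: list[str | None]  # canonical scaffold SMILES; None = acyclic

    @property
    def n_molecules(self) -> int:
        return len(self.per_molecule)

    @property
    def acyclic_fraction(self) -> float:
        if not self.per_molecule:
            return 0.0
        return sum(1 for s in self.per_molecule if s is None) / len(self.per_molecule)

    def frequency_table(self) -> pd.DataFrame:
        tally: dict[str, int] = {}
        for s in self.per_molecule:
            if s is not None:
                tally[s] = tally.get(s, 0) + 1
        rows = [
            {"scaffold": s, "n_molecules": n}
            for s, n in sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))
        ]
        return pd.DataFrame(rows, columns=["scaffold", "n_molecules"])

    def cumulative_frequency(self, acyclic: str = "exclude") -> np.ndarray:
        """Cumulative molecule fraction vs scaffold rank.

        ``acyclic`` selects the limit convention: ``exclude`` (cyclic
        molecules only), ``one`` (all acyclic molecules count as a single
        extra scaffold, the upper limit) or ``singletons`` (every acyclic
        molecule is its own scaffold, the lower limit).
        """
        counts = sorted(
            (n for s, n in self._tally().items()), reverse=True
        )
        n_acyclic = sum(1 for s in self.per_molecule if s is None)
        if acyclic == "one" and n_acyclic:
            counts.append(n_acyclic)
            counts.sort(reverse=True)
        elif acyclic == "singletons":
            counts.extend([1] * n_acyclic)
            counts.sort(reverse=True)
        elif acyclic not in ("exclude", "one", "singletons"):
            raise ValueError(f"unknown acyclic convention {acyclic!r}")
        total = sum(counts)
        if total == 0:
            return np.array([])
        return np.cumsum(counts) / total

    def _tally(self) -> dict[str, int]:
        tally: dict[str, int] = {}
        for s in self.per_molecule:
            if s is not None:
                tally[s] = tally.get(s, 0) + 1
        return tally


def scaffold_key(graph: MolGraph) -> str | None:
    """Canonical first-layer scaffold of a perceived graph (None if acyclic)."""
    mol = Chem.RemoveHs(graph.rdmol)
    if mol.GetRingInfo().NumRings() == 0:
        return None
    core = MurckoScaffold.GetScaffoldForMol(mol)
    if core is None or core.GetNumAtoms() == 0:
        return None
    return Chem.MolToSmiles(core)


def scaffold_summary(dataset: Dataset) -> ScaffoldSummary:
    per_mol = []
    for entry in dataset:
        try:
            graph = perceive_graph(entry.molecule)
            per_mol.append(scaffold_key(graph))
        except GraphPerceptionError:
            per_mol.append(None)
    return ScaffoldSummary(per_mol)
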