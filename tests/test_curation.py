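import numpy as np
import pytest

from chemdiv.core import Dataset, Entry, Molecule, PropertyRecord
from chemdiv.curation import (
    GraphPerceptionError,
    apply_qm9_constraints,
    canonical_identifier,
    compute_identifiers,
    conformer_discrepancy,
    deduplicate,
    perceive_connectivity,
    perceive_graph,
    split_overlap,
    strip_enantiomeric_layers,
)
from conftest import entry_from_template, random_rotation, template_molecule


def _mol(elements, coords, source_id="m"):
    return Molecule(tuple(elements), np.array(coords, dtype=float), source_id=source_id)


class TestBondPerception:
    def test_h2_single_bond(self):
        m = _mol(["H", "H"], [[0, 0, 0], [0, 0, 0.74]])
        assert perceive_connectivity(m) == [(0, 1)]

    def test_distant_atoms_unbonded(self):
        m = _mol(["C", "C"], [[0, 0, 0], [0, 0, 5.0]])
        assert perceive_connectivity(m) == []

    def test_water_two_oh_bonds(self):
        g = perceive_graph(template_molecule("water"))
        assert len(g.bonds) == 2
        for i, j, _ in g.bonds:
            assert {g.elements[i], g.elements[j]} == {"O", "H"}

    def test_too_close_atoms_rejected(self):
        m = _mol(["C", "C"], [[0, 0, 0], [0, 0, 0.1]])
        with pytest.raises(GraphPerceptionError):
            perceive_connectivity(m)

    def test_aromatic_ring_perceived(self):
        g = perceive_graph(template_molecule("benzene"))
        assert g.aromatic.sum() == 6
        assert len(g.rings) == 1


class TestIdentifiers:
    def test_conformers_share_identifier(self, rng):
        base = template_molecule("ethanol")
        jittered = Molecule(
            base.elements, base.coords + rng.normal(0, 0.03, base.coords.shape),
            source_id="jit",
        )
        assert canonical_identifier(perceive_graph(base)) == canonical_identifier(
            perceive_graph(jittered)
        )

    def test_constitutional_isomers_differ(self):
        i1 = canonical_identifier(perceive_graph(template_molecule("ethanol")))
        i2 = canonical_identifier(perceive_graph(template_molecule("dimethyl_ether")))
        assert i1 != i2

    def test_enantiomers_collapse_only_with_flag(self):
        from rdkit import Chem
        from rdkit.Chem import AllChem

        m = Chem.AddHs(Chem.MolFromSmiles("NC(O)F"))
        ps = AllChem.ETKDGv3()
        ps.randomSeed = 11
        AllChem.EmbedMolecule(m, ps)
        AllChem.MMFFOptimizeMolecule(m)
        conf = m.GetConformer()
        xyz = np.array([list(conf.GetAtomPosition(i)) for i in range(m.GetNumAtoms())])
        elems = tuple(a.GetSymbol() for a in m.GetAtoms())
        mol_r = Molecule(elems, xyz, source_id="R")
        mol_s = Molecule(elems, xyz * np.array([1.0, 1.0, -1.0]), source_id="S")
        with_stereo = [
            canonical_identifier(perceive_graph(x), drop_enantiomeric_layer=False)
            for x in (mol_r, mol_s)
        ]
        stripped = [
            canonical_identifier(perceive_graph(x), drop_enantiomeric_layer=True)
            for x in (mol_r, mol_s)
        ]
        assert with_stereo[0] != with_stereo[1]
        assert stripped[0] == stripped[1]

    def test_strip_removes_t_m_s_layers(self):
        inchi = "InChI=1S/CH4FNO/c2-1(3)4/h1,4H,3H2/t1-/m1/s1"
        assert strip_enantiomeric_layers(inchi) == "InChI=1S/CH4FNO/c2-1(3)4/h1,4H,3H2"

    def test_identifier_invariant_under_rotation_and_permutation(self, rng):
        base = template_molecule("isopropanol")
        ref = canonical_identifier(perceive_graph(base))
        R = random_rotation(rng)
        perm = rng.permutation(base.n_atoms)
        transformed = Molecule(
            tuple(base.elements[i] for i in perm),
            base.coords[perm] @ R.T + np.array([1.0, -2.0, 0.5]),
            source_id="t",
        )
        assert canonical_identifier(perceive_graph(transformed)) == ref


class TestConstraints:
    def test_oversized_rejected(self):
        decane = _mol(
            ["C"] * 10, [[1.54 * i, 0.3 * (i % 2), 0] for i in range(10)], "decane"
        )
        kept, rejected = apply_qm9_constraints(
            Dataset([Entry(decane, PropertyRecord())])
        )
        assert len(kept) == 0
        assert "size" in rejected[0][1]

    def test_foreign_element_rejected(self):
        m = _mol(["S", "H", "H"], [[0, 0, 0], [0, 0, 1.34], [1.3, 0, -0.3]], "h2s")
        kept, rejected = apply_qm9_constraints(Dataset([Entry(m, PropertyRecord())]))
        assert len(kept) == 0
        assert "element" in rejected[0][1]

    def test_benzene_kept_and_idempotent(self):
        ds = Dataset([entry_from_template("benzene")])
        kept, _ = apply_qm9_constraints(ds)
        assert len(kept) == 1
        kept2, rejected2 = apply_qm9_constraints(kept)
        assert len(kept2) == 1 and not rejected2


class TestDeduplication:
    def test_lowest_energy_survives(self):
        entries = [
            entry_from_template("methane", E=-1.0, source_id="a"),
            entry_from_template("methane", E=-1.2, source_id="b"),
            entry_from_template("methane", E=-1.1, source_id="c"),
        ]
        ds, _ = compute_identifiers(Dataset(entries))
        out = deduplicate(ds)
        assert len(out) == 1
        assert out[0].properties.E == pytest.approx(-1.2)

    def test_unique_set_unchanged(self):
        ds, _ = compute_identifiers(
            Dataset([entry_from_template(n) for n in ("methane", "water", "benzene")])
        )
        assert len(deduplicate(ds)) == 3


class TestOverlap:
    def _ids(self, names, tag):
        ds, _ = compute_identifiers(
            Dataset([entry_from_template(n, source_id=f"{tag}_{n}") for n in names])
        )
        return ds

    def test_identical_sets_have_no_exclusives(self):
        a = self._ids(["methane", "water"], "a")
        part = split_overlap(a, a)
        assert part.exclusive_A == [] and part.exclusive_B == []
        assert len(part.common_A) == 2

    def test_disjoint_sets_have_no_common(self):
        part = split_overlap(self._ids(["methane"], "a"), self._ids(["water"], "b"))
        assert part.common_A == [] and part.common_B == []

    def test_constructed_partial_overlap(self):
        names_a = ["methane", "water", "ethanol", "benzene", "propane",
                   "butane", "methanol", "toluene", "oxirane", "phenol"]
        names_b = ["methane", "water", "ethanol", "benzene", "acetonitrile",
                   "propyne", "formic_acid", "fluoromethane", "dimethylamine",
                   "hydrogen_peroxide"]
        part = split_overlap(self._ids(names_a, "a"), self._ids(names_b, "b"))
        assert len(part.common_A) == 4
        assert len(part.exclusive_A) == 6
        assert len(part.matched_pairs) == 4

    def test_swap_symmetry(self):
        a = self._ids(["methane", "water", "ethanol"], "a")
        b = self._ids(["water", "benzene"], "b")
        part = split_overlap(a, b)
        swapped = split_overlap(b, a)
        assert sorted(swapped.common_A) == sorted(part.common_B)
        assert sorted(swapped.exclusive_A) == sorted(part.exclusive_B)


class TestConformerDiscrepancy:
    def test_identical_geometries_zero_delta(self):
        a, _ = compute_identifiers(Dataset([entry_from_template("water", E=-76.0)]))
        table = conformer_discrepancy(split_overlap(a, a), a, a)
        assert table["delta_NRE_kcalmol"].iloc[0] == pytest.approx(0.0, abs=1e-9)
        assert not table["nre_flagged"].any()

    def test_stretched_geometry_matches_direct_nre_recomputation(self):
        from chemdiv.constants import HARTREE_TO_KCALMOL
        from chemdiv.energetics import nuclear_repulsion_energy

        base = template_molecule("water", "w")
        stretched_coords = base.coords.copy()
        stretched_coords[1] += (stretched_coords[1] - stretched_coords[0]) * 0.2
        stretched = Molecule(base.elements, stretched_coords, source_id="w2")
        a, _ = compute_identifiers(Dataset([Entry(base, PropertyRecord(E=-76.0))]))
        b, _ = compute_identifiers(Dataset([Entry(stretched, PropertyRecord(E=-76.0))]))
        table = conformer_discrepancy(split_overlap(a, b), a, b)
        expected = (
            nuclear_repulsion_energy(stretched) - nuclear_repulsion_energy(base)
        ) * HARTREE_TO_KCALMOL
        assert table["delta_NRE_kcalmol"].iloc[0] == pytest.approx(expected, abs=1e-9)
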