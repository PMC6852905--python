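"""Physical constants and element data shared across the package.

Unit conventions: coordinates are stored in Angstrom everywhere; energies are
stored in Hartree and converted at the edges (kcal/mol for energy reports,
eV for orbital energies, pm for bond-length profiles).
"""

# CODATA-2018 conversion factors
HARTREE_TO_KCALMOL = 627.5094740631
HARTREE_TO_EV = 27.211386245988
ANGSTROM_TO_BOHR = 1.8897259886
ANGSTROM_TO_PM = 100.0

#: Atomic numbers for the QM9 element set (plus a few common rejects so the
#: constraint filter can name them).
ATOMIC_NUMBER = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "Ne": 10, "Na": 11, "Mg": 12, "Al": 13, "Si": 14, "P": 15,
    "S": 16, "Cl": 17, "Ar": 18, "K": 19, "Ca": 20, "Br": 35, "I": 53,
}

#: Single-bond covalent radii in Angstrom (Cordero et al. consensus values
#: for the light elements; sp3 carbon).
COVALENT_RADIUS = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57,
    "S": 1.05, "Cl": 1.02, "P": 1.07, "Si": 1.11, "B": 0.84, "Br": 1.20,
}

#: Tolerance added to the summed covalent radii when perceiving bonds from
#: 3D geometry [Angstrom].
BOND_PERCEPTION_TOLERANCE = 0.45

#: QM9 dataset constraints: element whitelist and heavy-atom cap.
QM9_ELEMENTS = frozenset({"H", "C", "N", "O", "F"})
QM9_MAX_HEAVY_ATOMS = 9
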