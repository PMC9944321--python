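"""Versioned neutron constants used for SLD arithmetic.

Bound coherent scattering lengths follow the standard neutron data tables
(Sears compilation), except that the values for protium and deuterium are
pinned to the conventional round figures b_c(1H) = -3.742 fm and
b_c(2H/D) = +6.675 fm used throughout the contrast calculations here.

Displaced atomic volumes are the Fraser-MacRae-Suzuki set commonly used for
solvent-excluded-volume corrections in solution-scattering codes; a hydrogen
attached to a heavy atom adds V_H to the displaced group volume.
"""

from __future__ import annotations

TABLE_VERSION = "2024.1"

FM_TO_ANGSTROM = 1.0e-5  # 1 fm = 1e-5 Angstrom
AVOGADRO = 6.02214076e23

# bound coherent scattering length, fm
B_COHERENT_FM: dict[str, float] = {
    "H": -3.742,
    "D": 6.675,
    "C": 6.6460,
    "N": 9.36,
    "O": 5.803,
    "S": 2.847,
    "P": 5.13,
    "NA": 3.63,
    "CL": 9.5770,
    "K": 3.67,
    "CA": 4.70,
    "MG": 5.375,
    "AL": 3.449,
    "CU": 7.718,
    "FE": 9.45,
    "ZN": 5.680,
    "SE": 7.970,
    "MN": -3.73,
    "F": 5.654,
    "SI": 4.1491,
    "B": 5.30,
}

# atomic mass, g/mol
ATOMIC_MASS: dict[str, float] = {
    "H": 1.008,
    "D": 2.0141,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "NA": 22.990,
    "CL": 35.45,
    "K": 39.098,
    "CA": 40.078,
    "MG": 24.305,
    "AL": 26.982,
    "CU": 63.546,
    "FE": 55.845,
    "ZN": 65.38,
    "SE": 78.971,
    "MN": 54.938,
    "F": 18.998,
    "SI": 28.085,
    "B": 10.81,
}

# displaced atomic volume, Angstrom^3 (Fraser-MacRae-Suzuki)
DISPLACED_VOLUME: dict[str, float] = {
    "H": 5.15,
    "D": 5.15,
    "C": 16.44,
    "N": 2.49,
    "O": 9.13,
    "S": 19.86,
    "P": 5.73,
    "FE": 7.99,
    "CU": 8.78,
    "ZN": 9.85,
    "CA": 31.89,
    "MG": 21.69,
    "NA": 49.0,
    "CL": 28.81,
    "SE": 28.73,
}

# solvent reference densities at 25 C, g/cm^3
DENSITY_H2O = 0.9970
DENSITY_D2O = 1.1044

# Implicit hydrogen templates for the standard amino acids:
# residue -> heavy-atom name -> (bound H count, of which exchangeable).
# Backbone amide NH is exchangeable; side-chain H on N/O/S are exchangeable.
_BACKBONE = {"N": (1, 1), "CA": (1, 0), "C": (0, 0), "O": (0, 0), "OXT": (0, 0)}

RESIDUE_H_TEMPLATES: dict[str, dict[str, tuple[int, int]]] = {
    "ALA": {**_BACKBONE, "CB": (3, 0)},
    "ARG": {**_BACKBONE, "CB": (2, 0), "CG": (2, 0), "CD": (2, 0), "NE": (1, 1),
            "CZ": (0, 0), "NH1": (2, 2), "NH2": (2, 2)},
    "ASN": {**_BACKBONE, "CB": (2, 0), "CG": (0, 0), "OD1": (0, 0), "ND2": (2, 2)},
    "ASP": {**_BACKBONE, "CB": (2, 0), "CG": (0, 0), "OD1": (0, 0), "OD2": (0, 0)},
    "CYS": {**_BACKBONE, "CB": (2, 0), "SG": (1, 1)},
    "GLN": {**_BACKBONE, "CB": (2, 0), "CG": (2, 0), "CD": (0, 0), "OE1": (0, 0),
            "NE2": (2, 2)},
    "GLU": {**_BACKBONE, "CB": (2, 0), "CG": (2, 0), "CD": (0, 0), "OE1": (0, 0),
            "OE2": (0, 0)},
    "GLY": {**_BACKBONE, "CA": (2, 0)},
    "HIS": {**_BACKBONE, "CB": (2, 0), "CG": (0, 0), "ND1": (1, 1), "CD2": (1, 0),
            "CE1": (1, 0), "NE2": (0, 0)},
    "ILE": {**_BACKBONE, "CB": (1, 0), "CG1": (2, 0), "CG2": (3, 0), "CD1": (3, 0)},
    "LEU": {**_BACKBONE, "CB": (2, 0), "CG": (1, 0), "CD1": (3, 0), "CD2": (3, 0)},
    "LYS": {**_BACKBONE, "CB": (2, 0), "CG": (2, 0), "CD": (2, 0), "CE": (2, 0),
            "NZ": (3, 3)},
    "MET": {**_BACKBONE, "CB": (2, 0), "CG": (2, 0), "SD": (0, 0), "CE": (3, 0)},
    "PHE": {**_BACKBONE, "CB": (2, 0), "CG": (0, 0), "CD1": (1, 0), "CD2": (1, 0),
            "CE1": (1, 0), "CE2": (1, 0), "CZ": (1, 0)},
    "PRO": {**_BACKBONE, "N": (0, 0), "CB": (2, 0), "CG": (2, 0), "CD": (2, 0)},
    "SER": {**_BACKBONE, "CB": (2, 0), "OG": (1, 1)},
    "THR": {**_BACKBONE, "CB": (1, 0), "OG1": (1, 1), "CG2": (3, 0)},
    "TRP": {**_BACKBONE, "CB": (2, 0), "CG": (0, 0), "CD1": (1, 0), "CD2": (0, 0),
            "NE1": (1, 1), "CE2": (0, 0), "CE3": (1, 0), "CZ2": (1, 0),
            "CZ3": (1, 0), "CH2": (1, 0)},
    "TYR": {**_BACKBONE, "CB": (2, 0), "CG": (0, 0), "CD1": (1, 0), "CD2": (1, 0),
            "CE1": (1, 0), "CE2": (1, 0), "CZ": (0, 0), "OH": (1, 1)},
    "VAL": {**_BACKBONE, "CB": (1, 0), "CG1": (3, 0), "CG2": (3, 0)},
    "HOH": {"O": (2, 2)},
}


def b_coherent(element: str) -> float:
    """Bound coherent scattering length in fm; KeyError-safe wrapper."""
    try:
        return B_COHERENT_FM[element.upper()]
    except KeyError:
        raise KeyError(f"no coherent scattering length for element {element!r}") from None


def atomic_mass(element: str) -> float:
    try:
        return ATOMIC_MASS[element.upper()]
    except KeyError:
        raise KeyError(f"no atomic mass for element {element!r}") from None


def displaced_volume(element: str) -> float:
    try:
        return DISPLACED_VOLUME[element.upper()]
    except KeyError:
        raise KeyError(f"no displaced volume for atom group {element!r}") from None
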