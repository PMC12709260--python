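"""Physicochemical reference tables.

Single home for every per-residue and per-element constant used across the
package: Kyte–Doolittle hydropathies, integer side-chain charges at neutral
pH, average and monoisotopic free-amino-acid masses, residue elemental
compositions, Cromer–Mann X-ray form-factor coefficients, excluded-solvent
volumes, and Bondi van der Waals radii.
"""

from __future__ import annotations

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Kyte & Doolittle hydropathy scale (dimensionless).
KYTE_DOOLITTLE: dict[str, float] = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}

# Integer side-chain charge at neutral pH (His handled separately: 0 when
# modelled neutral, +1 otherwise).
SIDECHAIN_CHARGE: dict[str, int] = {
    "D": -1, "E": -1, "K": +1, "R": +1,
}

WATER_AVERAGE = 18.01528  # Da
WATER_MONO = 18.010565    # Da

# Free amino-acid masses (Da). Residue-in-chain mass = free mass - water.
RESIDUE_MASS_AVERAGE: dict[str, float] = {
    "G": 75.0669, "A": 89.0935, "S": 105.0930, "P": 115.1310, "V": 117.1469,
    "T": 119.1197, "C": 121.1590, "L": 131.1736, "I": 131.1736,
    "N": 132.1184, "D": 133.1032, "Q": 146.1451, "K": 146.1882,
    "E": 147.1293, "M": 149.2124, "H": 155.1552, "F": 165.1900,
    "R": 174.2017, "Y": 181.1894, "W": 204.2262,
}

RESIDUE_MASS_MONO: dict[str, float] = {
    "G": 75.032028, "A": 89.047678, "S": 105.042593, "P": 115.063329,
    "V": 117.078979, "T": 119.058243, "C": 121.019749, "L": 131.094629,
    "I": 131.094629, "N": 132.053492, "D": 133.037508, "Q": 146.069142,
    "K": 146.105528, "E": 147.053158, "M": 149.051049, "H": 155.069477,
    "F": 165.078979, "R": 174.111676, "Y": 181.073893, "W": 204.089878,
}

# Elemental composition of the residue *in chain* (peptide-bonded, neutral
# side chain): counts of C, H, N, O, S.
RESIDUE_FORMULA: dict[str, dict[str, int]] = {
    "G": {"C": 2, "H": 3, "N": 1, "O": 1, "S": 0},
    "A": {"C": 3, "H": 5, "N": 1, "O": 1, "S": 0},
    "S": {"C": 3, "H": 5, "N": 1, "O": 2, "S": 0},
    "P": {"C": 5, "H": 7, "N": 1, "O": 1, "S": 0},
    "V": {"C": 5, "H": 9, "N": 1, "O": 1, "S": 0},
    "T": {"C": 4, "H": 7, "N": 1, "O": 2, "S": 0},
    "C": {"C": 3, "H": 5, "N": 1, "O": 1, "S": 1},
    "L": {"C": 6, "H": 11, "N": 1, "O": 1, "S": 0},
    "I": {"C": 6, "H": 11, "N": 1, "O": 1, "S": 0},
    "N": {"C": 4, "H": 6, "N": 2, "O": 2, "S": 0},
    "D": {"C": 4, "H": 5, "N": 1, "O": 3, "S": 0},
    "Q": {"C": 5, "H": 8, "N": 2, "O": 2, "S": 0},
    "K": {"C": 6, "H": 12, "N": 2, "O": 1, "S": 0},
    "E": {"C": 5, "H": 7, "N": 1, "O": 3, "S": 0},
    "M": {"C": 5, "H": 9, "N": 1, "O": 1, "S": 1},
    "H": {"C": 6, "H": 7, "N": 3, "O": 1, "S": 0},
    "F": {"C": 9, "H": 9, "N": 1, "O": 1, "S": 0},
    "R": {"C": 6, "H": 12, "N": 4, "O": 1, "S": 0},
    "Y": {"C": 9, "H": 9, "N": 1, "O": 2, "S": 0},
    "W": {"C": 11, "H": 10, "N": 2, "O": 1, "S": 0},
}

ELEMENT_ELECTRONS: dict[str, int] = {"H": 1, "C": 6, "N": 7, "O": 8, "S": 16}

ELEMENT_MASS: dict[str, float] = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
}

# Cromer-Mann 4-Gaussian coefficients (International Tables Vol. C):
# f(q) = sum_i a_i exp(-b_i (q/4pi)^2) + c, with f(0) ~ Z.
CROMER_MANN: dict[str, dict[str, tuple]] = {
    "H": {"a": (0.489918, 0.262003, 0.196767, 0.049879),
          "b": (20.6593, 7.74039, 49.5519, 2.20159), "c": 0.001305},
    "C": {"a": (2.31000, 1.02000, 1.58860, 0.865000),
          "b": (20.8439, 10.2075, 0.568700, 51.6512), "c": 0.215600},
    "N": {"a": (12.2126, 3.13220, 2.01250, 1.16630),
          "b": (0.005700, 9.89330, 28.9975, 0.582600), "c": -11.529},
    "O": {"a": (3.04850, 2.28680, 1.54630, 0.867000),
          "b": (13.2771, 5.70110, 0.323900, 32.9089), "c": 0.250800},
    "S": {"a": (6.90530, 5.20340, 1.43790, 1.58630),
          "b": (1.46790, 22.2151, 0.253600, 56.1720), "c": 0.866900},
}

# Per-atom excluded-solvent (dummy-atom) volumes, A^3 (Fraser et al. set,
# as used by CRYSOL-style forward models).
EXCLUDED_VOLUME: dict[str, float] = {
    "H": 5.15, "C": 16.44, "N": 2.49, "O": 9.13, "S": 19.86,
}

SOLVENT_DENSITY = 0.334  # bulk water electron density, e/A^3

# Bondi van der Waals radii, Angstrom.
VDW_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
}

# Default 35-residue AICD segment (APP C-terminus preceded by a Gly-Ala-Met
# expression scar); configurable everywhere it is used.
AICD_SEQUENCE = "GAMDAAVTPEERHLSKMQQNGYENPTYKFFEQMQN"


def residue_electrons(code: str) -> int:
    """Total electron count of a neutral in-chain residue."""
    f = RESIDUE_FORMULA[code]
    return sum(ELEMENT_ELECTRONS[el] * n for el, n in f.items())
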