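"""Small element/residue lookup tables used across the package.

Atomic masses are standard atomic weights (g/mol); van der Waals radii are the
Bondi set commonly used for solvent-mask construction; formal charges per
residue type follow the usual pH-7 convention for the titratable side chains.
"""

from __future__ import annotations

# standard atomic weights, g/mol
ATOMIC_MASS: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "NA": 22.990,
    "MG": 24.305,
    "P": 30.974,
    "S": 32.06,
    "CL": 35.45,
    "K": 39.098,
    "CA": 40.078,
    "FE": 55.845,
    "ZN": 65.38,
    "SE": 78.971,
}

# Bondi van der Waals radii, Angstrom
VDW_RADIUS: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "NA": 2.27,
    "MG": 1.73,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "K": 2.75,
    "CA": 2.31,
    "FE": 2.00,
    "ZN": 1.39,
    "SE": 1.90,
}

# formal side-chain charge at neutral pH per residue type
RESIDUE_CHARGE: dict[str, int] = {
    "ASP": -1,
    "GLU": -1,
    "LYS": +1,
    "ARG": +1,
    "HIS": 0,
}

# volume of one water molecule at 1 g/cm^3, Angstrom^3
WATER_VOLUME_A3 = 29.9

# partial specific volume of protein, ml/g
PROTEIN_SPECIFIC_VOLUME = 0.74

# 1 Da * 1 ml/g expressed in Angstrom^3 (1e24 / N_A)
DA_ML_PER_G_TO_A3 = 1.6605


def element_mass(symbol: str) -> float:
    """Atomic mass in g/mol; raises KeyError with the supported list."""
    key = symbol.strip().upper()
    try:
        return ATOMIC_MASS[key]
    except KeyError:
        raise KeyError(
            f"unknown element {symbol!r}; supported: {sorted(ATOMIC_MASS)}"
        ) from None


def vdw_radius(symbol: str) -> float:
    key = symbol.strip().upper()
    try:
        return VDW_RADIUS[key]
    except KeyError:
        raise KeyError(
            f"no van der Waals radius for {symbol!r}; supported: {sorted(VDW_RADIUS)}"
        ) from None
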