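"""Physical constants, unit conversions and element data.

Everything inside the package works in Hartree atomic units (bohr for
length, hartree for energy, electron masses for mass).  Conversions to the
conventional I/O units (angstrom, amu, kJ/mol, cm^-1, kelvin) happen only at
the boundaries, through the constants defined here.
"""

# length
BOHR_PER_ANGSTROM = 1.8897261254578281
ANGSTROM_PER_BOHR = 1.0 / BOHR_PER_ANGSTROM

# mass
ME_PER_AMU = 1822.888486209

# energy
KJMOL_PER_HARTREE = 2625.49964
BOLTZMANN_HARTREE_PER_K = 3.166811563e-6

# sqrt(eigenvalue in hartree/(m_e bohr^2)) -> wavenumber in cm^-1
# (hartree expressed in cm^-1, i.e. E_h / (h c))
WAVENUMBER_PER_SQRT_HARTREE = 219474.6313632

# atomic numbers for the elements handled by the package
ATOMIC_NUMBER = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "Ne": 10, "Na": 11, "Mg": 12, "Al": 13, "Si": 14, "P": 15,
    "S": 16, "Cl": 17, "Ar": 18, "K": 19, "Ca": 20, "Br": 35, "I": 53,
}

# standard atomic weights (amu), most-abundant-isotope-dominated values
ATOMIC_MASS_AMU = {
    "H": 1.008, "He": 4.0026, "Li": 6.94, "Be": 9.0122, "B": 10.81,
    "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998, "Ne": 20.180,
    "Na": 22.990, "Mg": 24.305, "Al": 26.982, "Si": 28.085, "P": 30.974,
    "S": 32.06, "Cl": 35.45, "Ar": 39.948, "K": 39.098, "Ca": 40.078,
    "Br": 79.904, "I": 126.904,
}

# covalent radii (angstrom), used for bond detection with a 1.2 tolerance
COVALENT_RADIUS_ANGSTROM = {
    "H": 0.31, "He": 0.28, "Li": 1.28, "Be": 0.96, "B": 0.84, "C": 0.76,
    "N": 0.71, "O": 0.66, "F": 0.57, "Ne": 0.58, "Na": 1.66, "Mg": 1.41,
    "Al": 1.21, "Si": 1.11, "P": 1.07, "S": 1.05, "Cl": 1.02, "Ar": 1.06,
    "K": 2.03, "Ca": 1.76, "Br": 1.20, "I": 1.39,
}


class UnknownElementError(KeyError):
    """Raised when an element symbol has no tabulated mass/radius/number."""


def atomic_number(symbol: str) -> int:
    try:
        return ATOMIC_NUMBER[symbol]
    except KeyError:
        raise UnknownElementError(f"unknown element symbol: {symbol!r}") from None


def atomic_mass_me(symbol: str) -> float:
    """Default isotope-averaged mass in electron masses."""
    try:
        return ATOMIC_MASS_AMU[symbol] * ME_PER_AMU
    except KeyError:
        raise UnknownElementError(f"unknown element symbol: {symbol!r}") from None


def covalent_radius_bohr(symbol: str) -> float:
    try:
        return COVALENT_RADIUS_ANGSTROM[symbol] * BOHR_PER_ANGSTROM
    except KeyError:
        raise UnknownElementError(f"unknown element symbol: {symbol!r}") from None
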