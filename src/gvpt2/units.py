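"""Physical constants and unit conversions (CODATA 2018).

Internal conventions: atomic units throughout (hartree, bohr, electron
masses) with angles in radians.  Wavenumber output uses the hartree ->
cm^-1 factor below; all spectroscopic quantities are reported in cm^-1.
"""

# CODATA 2018
HARTREE_TO_CM = 219474.6313632  # E_h -> cm^-1 (2 R_inf in cm^-1)
AMU_TO_ME = 1822.888486209  # unified atomic mass unit -> electron masses
BOHR_TO_ANGSTROM = 0.529177210903
ANGSTROM_TO_BOHR = 1.0 / BOHR_TO_ANGSTROM

#: default finite-difference step along mass-weighted normal coordinates,
#: in amu^1/2 * bohr (converted to atomic units where used)
DEFAULT_DELTA_Q = 0.02

# Atomic masses of the most abundant isotope (amu).  Vibrational analyses
# conventionally use single-isotope masses, not standard atomic weights.
ISOTOPE_MASSES = {
    "H": 1.00782503207,
    "D": 2.01410177785,
    "He": 4.00260325415,
    "Li": 7.01600455,
    "B": 11.0093054,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "F": 18.99840322,
    "Ne": 19.9924401754,
    "Na": 22.9897692809,
    "Mg": 23.985041700,
    "Al": 26.98153863,
    "Si": 27.9769265325,
    "P": 30.97376163,
    "S": 31.97207100,
    "Cl": 34.96885268,
    "Ar": 39.9623831225,
    "K": 38.96370668,
    "Ca": 39.96259098,
    "Br": 78.9183371,
    "I": 126.904473,
}

# Covalent radii in Angstrom (Cordero et al. 2008), used only for the
# bond-detection heuristic in topology perception.
COVALENT_RADII_A = {
    "H": 0.31,
    "D": 0.31,
    "He": 0.28,
    "Li": 1.28,
    "B": 0.84,
    "C": 0.76,
    "N": 0.71,
    "O": 0.66,
    "F": 0.57,
    "Ne": 0.58,
    "Na": 1.66,
    "Mg": 1.41,
    "Al": 1.21,
    "Si": 1.11,
    "P": 1.07,
    "S": 1.05,
    "Cl": 1.02,
    "Ar": 1.06,
    "K": 2.03,
    "Ca": 1.76,
    "Br": 1.20,
    "I": 1.39,
}


def covalent_radius_bohr(symbol: str) -> float:
    try:
        return COVALENT_RADII_A[symbol] * ANGSTROM_TO_BOHR
    except KeyError:  # pragma: no cover - exotic elements
        raise KeyError(f"no covalent radius tabulated for element {symbol!r}")


def isotope_mass(symbol: str) -> float:
    try:
        return ISOTOPE_MASSES[symbol]
    except KeyError:  # pragma: no cover
        raise KeyError(f"no isotope mass tabulated for element {symbol!r}")
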