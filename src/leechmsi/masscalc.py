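"""Molecular-formula and peptide m/z computation for MALDI / ToF-SIMS ion assignments.

Covers the adduct species the pipeline annotates: protonated and deprotonated
ions, lithiated neutral lipids (lithiation aids MALDI detection of
endocannabinoids such as 2-AG and AEA), in-source dehydration fragments like
the cholesterol [M+H-H2O]+ ion, and preformed cations such as phosphocholine.

Masses are computed from an embedded atomic-mass table (CODATA-2018 electron
mass; IUPAC/AME-2020 isotope masses, stored to 6 decimals), never per-residue
constants: peptide residue masses are derived from elemental composition at
import time.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = [
    "MolecularFormula",
    "AdductSpec",
    "FormulaError",
    "parse_formula",
    "formula_mass",
    "adduct_mz",
    "peptide_mz",
    "ELECTRON_MASS",
    "PROTON_MASS",
]

# Most-abundant-isotope masses (Da), 6 decimals. 2H is the deuterium tag used
# for the internal standards (AEAd8, 2-AGd8); Li is 7Li (92.4% abundant).
MONOISOTOPIC = {
    "C": 12.000000,
    "H": 1.007825,
    "2H": 2.014102,
    "N": 14.003074,
    "O": 15.994915,
    "P": 30.973762,
    "S": 31.972071,
    "Li": 7.016003,
    "Na": 22.989770,
    "K": 38.963707,
}

# IUPAC 2021 standard atomic weights (Da).
AVERAGE = {
    "C": 12.011000,
    "H": 1.008000,
    "2H": 2.014102,
    "N": 14.007000,
    "O": 15.999000,
    "P": 30.973762,
    "S": 32.060000,
    "Li": 6.940000,
    "Na": 22.989769,
    "K": 39.098300,
}

ELECTRON_MASS = 0.000549  # CODATA 2018, Da
PROTON_MASS = MONOISOTOPIC["H"] - ELECTRON_MASS

#: element-count composition, e.g. {"C": 23, "H": 38, "O": 4}
MolecularFormula = dict


class FormulaError(ValueError):
    """Raised for malformed molecular formulas, with the offending position."""


_TOKEN = re.compile(r"\[(\d+)([A-Z][a-z]?)\](\d*)|([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> MolecularFormula:
    """Parse ``"C23H38O4"`` or isotope-tagged ``"C22H29[2H]8NO2"`` into counts.

    Order-insensitive; repeated elements accumulate. Unknown element symbols,
    zero counts and stray characters raise :class:`FormulaError` naming the
    position of the problem.
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError("empty formula")
    text = text.strip()
    counts: MolecularFormula = {}
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None:
            raise FormulaError(f"unparseable formula at position {pos}: {text[pos:]!r}")
        if m.group(2) is not None:  # isotope tag, e.g. [2H]8
            symbol = m.group(1) + m.group(2)
            digits = m.group(3)
        else:
            symbol = m.group(4)
            digits = m.group(5)
        if symbol not in MONOISOTOPIC:
            raise FormulaError(f"unknown element {symbol!r} at position {m.start()}")
        n = int(digits) if digits else 1
        if n <= 0:
            raise FormulaError(f"count must be positive for {symbol!r} at position {m.start()}")
        counts[symbol] = counts.get(symbol, 0) + n
        pos = m.end()
    return counts


def formula_mass(formula: MolecularFormula | str, mode: str = "monoisotopic") -> float:
    """Neutral mass of a formula in Da (``monoisotopic`` or ``average``)."""
    if isinstance(formula, str):
        formula = parse_formula(formula)
    table = {"monoisotopic": MONOISOTOPIC, "average": AVERAGE}.get(mode)
    if table is None:
        raise ValueError(f"unknown mass mode {mode!r}")
    for el, n in formula.items():
        if el not in table:
            raise FormulaError(f"unknown element {el!r}")
        if not isinstance(n, int) or n <= 0:
            raise FormulaError(f"count for {el!r} must be a positive integer")
    return sum(table[el] * n for el, n in formula.items())


_WATER = {"H": 2, "O": 1}

# adduct kind -> (element deltas, charge)
_ADDUCTS = {
    "M+H": ({"H": +1}, +1),
    "M-H": ({"H": -1}, -1),
    "M+Li": ({"Li": +1}, +1),
    "M+Na": ({"Na": +1}, +1),
    "M+K": ({"K": +1}, +1),
    "M+H-H2O": ({"H": -1, "O": -1}, +1),
    "preformed_cation": ({}, +1),
}


@dataclass(frozen=True)
class AdductSpec:
    """Ion species formed from a neutral molecule.

    ``kind`` is one of ``M+H``, ``M-H``, ``M+Li``, ``M+Na``, ``M+K``,
    ``M+H-H2O`` or ``preformed_cation`` (the formula already describes the
    cation's atoms, e.g. phosphocholine C5H15NO4P+). ``electron_correction``
    subtracts/adds the electron mass so the result is an ion m/z rather than a
    neutral-atom sum; it is on by default.
    """

    kind: str = "M+H"
    electron_correction: bool = True

    def __post_init__(self):
        if self.kind not in _ADDUCTS:
            raise ValueError(f"unknown adduct kind {self.kind!r}; known: {sorted(_ADDUCTS)}")

    @property
    def charge(self) -> int:
        return _ADDUCTS[self.kind][1]


def adduct_mz(
    formula: MolecularFormula | str,
    adduct: AdductSpec | str = "M+H",
    mode: str = "monoisotopic",
) -> float:
    """m/z of an adduct ion of ``formula``.

    m/z = (neutral mass + adduct atom deltas - charge * electron mass) / |charge|
    with the electron term dropped when ``electron_correction`` is off.
    """
    if isinstance(adduct, str):
        adduct = AdductSpec(kind=adduct)
    if isinstance(formula, str):
        formula = parse_formula(formula)
    deltas, charge = _ADDUCTS[adduct.kind]
    table = {"monoisotopic": MONOISOTOPIC, "average": AVERAGE}[
        mode if mode in ("monoisotopic", "average") else "monoisotopic"
    ]
    if mode not in ("monoisotopic", "average"):
        raise ValueError(f"unknown mass mode {mode!r}")
    mass = formula_mass(formula, mode)
    mass += sum(table[el] * n for el, n in deltas.items())
    if adduct.electron_correction:
        mass -= charge * ELECTRON_MASS
    return mass / abs(charge)


# Elemental composition of the 20 standard amino-acid residues (peptide-bonded,
# i.e. the free amino acid minus one water). Masses are derived from these at
# call time, never stored as per-residue constants.
RESIDUE_FORMULAS = {
    "G": {"C": 2, "H": 3, "N": 1, "O": 1},
    "A": {"C": 3, "H": 5, "N": 1, "O": 1},
    "S": {"C": 3, "H": 5, "N": 1, "O": 2},
    "P": {"C": 5, "H": 7, "N": 1, "O": 1},
    "V": {"C": 5, "H": 9, "N": 1, "O": 1},
    "T": {"C": 4, "H": 7, "N": 1, "O": 2},
    "C": {"C": 3, "H": 5, "N": 1, "O": 1, "S": 1},
    "L": {"C": 6, "H": 11, "N": 1, "O": 1},
    "I": {"C": 6, "H": 11, "N": 1, "O": 1},
    "N": {"C": 4, "H": 6, "N": 2, "O": 2},
    "D": {"C": 4, "H": 5, "N": 1, "O": 3},
    "Q": {"C": 5, "H": 8, "N": 2, "O": 2},
    "K": {"C": 6, "H": 12, "N": 2, "O": 1},
    "E": {"C": 5, "H": 7, "N": 1, "O": 3},
    "M": {"C": 5, "H": 9, "N": 1, "O": 1, "S": 1},
    "H": {"C": 6, "H": 7, "N": 3, "O": 1},
    "F": {"C": 9, "H": 9, "N": 1, "O": 1},
    "R": {"C": 6, "H": 12, "N": 4, "O": 1},
    "Y": {"C": 9, "H": 9, "N": 1, "O": 2},
    "W": {"C": 11, "H": 10, "N": 2, "O": 1},
}


def peptide_formula(sequence: str) -> MolecularFormula:
    """Elemental composition of a free-termini peptide (residues + H2O)."""
    if not sequence:
        raise ValueError("empty peptide sequence")
    counts: MolecularFormula = dict(_WATER)
    for i, aa in enumerate(sequence):
        comp = RESIDUE_FORMULAS.get(aa)
        if comp is None:
            raise ValueError(f"unknown residue {aa!r} at position {i}")
        for el, n in comp.items():
            counts[el] = counts.get(el, 0) + n
    return counts


def peptide_mz(
    sequence: str,
    adduct: AdductSpec | str = "M+H",
    mode: str = "monoisotopic",
) -> float:
    """m/z of an adduct ion of a free-termini peptide given in one-letter code."""
    return adduct_mz(peptide_formula(sequence), adduct, mode)
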