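"""Exact-mass arithmetic for small-molecule LC-MS.

Monoisotopic masses from elemental formulas, adduct m/z for singly charged
ions, ppm errors, and the CO2 neutral-loss shift that links a decarboxylase
substrate to its biogenic-amine product.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = [
    "MONOISOTOPIC_MASS",
    "PROTON_MASS",
    "CO2_MASS",
    "IonSpec",
    "ION_POSITIVE",
    "ION_NEGATIVE",
    "FormulaError",
    "parse_formula",
    "formula_mass",
    "ion_mz",
    "neutral_mass",
    "ppm_error",
    "decarboxylation_mz",
]

# IUPAC monoisotopic element masses, fixed at 5 decimals for reproducibility.
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.000000,
    "H": 1.007825,
    "N": 14.003074,
    "O": 15.994915,
    "S": 31.972071,
}

# Proton shift for [M+H]+ / [M-H]-; the electron mass (~0.5 mDa) is ignored,
# which is below every tolerance used in this package.
PROTON_MASS = 1.007276


class FormulaError(ValueError):
    """Raised for unparseable formulas or unsupported element symbols."""


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-notation elemental formula into element counts.

    Parameters
    ----------
    formula:
        A string such as ``"C5H9NO4"``. Only C, H, N, O and S are supported;
        any other symbol raises :class:`FormulaError` naming the token.

    Returns
    -------
    dict mapping element symbol to a positive integer count.
    """
    if not isinstance(formula, str) or not formula.strip():
        raise FormulaError(f"empty or non-string formula: {formula!r}")
    counts: dict[str, int] = {}
    pos = 0
    text = formula.strip()
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None or m.start() != pos or not m.group(1):
            raise FormulaError(
                f"cannot parse formula {formula!r} at {text[pos:]!r}"
            )
        symbol, digits = m.group(1), m.group(2)
        if symbol not in MONOISOTOPIC_MASS:
            raise FormulaError(
                f"unsupported element {symbol!r} in formula {formula!r}"
            )
        n = int(digits) if digits else 1
        if n <= 0:
            raise FormulaError(f"zero count for {symbol!r} in {formula!r}")
        counts[symbol] = counts.get(symbol, 0) + n
        pos = m.end()
    if not counts:
        raise FormulaError(f"formula {formula!r} contains no elements")
    return counts


def formula_mass(formula: str) -> float:
    """Monoisotopic mass (Da) of a Hill-notation formula."""
    counts = parse_formula(formula)
    return sum(MONOISOTOPIC_MASS[el] * n for el, n in counts.items())


# Neutral loss of one CO2 during decarboxylation.
CO2_MASS = formula_mass("CO2")  # 43.98983 Da


@dataclass(frozen=True)
class IonSpec:
    """A singly charged adduct: [M+H]+ in positive mode, [M-H]- in negative.

    ``shift`` is the signed m/z offset added to the neutral monoisotopic
    mass; it is fixed by the adduct.
    """

    name: str
    polarity: str
    shift: float

    def __post_init__(self) -> None:
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"unknown polarity {self.polarity!r}")
        if (self.polarity == "positive") != (self.shift > 0):
            raise ValueError("adduct shift sign inconsistent with polarity")


ION_POSITIVE = IonSpec("[M+H]+", "positive", +PROTON_MASS)
ION_NEGATIVE = IonSpec("[M-H]-", "negative", -PROTON_MASS)

IONS_BY_POLARITY = {"positive": ION_POSITIVE, "negative": ION_NEGATIVE}


def ion_mz(neutral: float, ion: IonSpec) -> float:
    """m/z of the singly charged adduct of a neutral mass."""
    if neutral <= 0:
        raise ValueError(f"neutral mass must be positive, got {neutral}")
    return neutral + ion.shift


def neutral_mass(mz: float, ion: IonSpec) -> float:
    """Invert :func:`ion_mz`: the neutral mass behind an observed m/z."""
    return mz - ion.shift


def ppm_error(observed: float, expected: float) -> float:
    """Signed relative m/z deviation in parts per million."""
    if expected <= 0:
        raise ValueError(f"expected m/z must be positive, got {expected}")
    return 1e6 * (observed - expected) / expected


def decarboxylation_mz(substrate_ion_mz: float) -> float:
    """Expected product ion m/z after loss of CO2 from the substrate ion.

    Valid for both polarities with same-adduct pairing, because the adduct
    shift cancels in the difference.
    """
    product = substrate_ion_mz - CO2_MASS
    if product <= 0:
        raise ValueError(
            f"substrate ion m/z {substrate_ion_mz} does not exceed the CO2 mass"
        )
    return product
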