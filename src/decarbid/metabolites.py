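"""Reference small-molecule data: proteinogenic amino acids and the
group II decarboxylase substrate/product map.

Retention times are for the amide-HILIC separation emulated by the
simulator; they are package conventions (minutes), not measured values.
"""

from __future__ import annotations

from .masscalc import CO2_MASS, formula_mass

# name -> Hill formula for the 20 proteinogenic amino acids (free acids).
AMINO_ACID_FORMULAS: dict[str, str] = {
    "glycine": "C2H5NO2",
    "alanine": "C3H7NO2",
    "serine": "C3H7NO3",
    "proline": "C5H9NO2",
    "valine": "C5H11NO2",
    "threonine": "C4H9NO3",
    "cysteine": "C3H7NO2S",
    "leucine": "C6H13NO2",
    "isoleucine": "C6H13NO2",
    "asparagine": "C4H8N2O3",
    "aspartic acid": "C4H7NO4",
    "glutamine": "C5H10N2O3",
    "lysine": "C6H14N2O2",
    "glutamic acid": "C5H9NO4",
    "methionine": "C5H11NO2S",
    "histidine": "C6H9N3O2",
    "phenylalanine": "C9H11NO2",
    "arginine": "C6H14N4O2",
    "tyrosine": "C9H11NO3",
    "tryptophan": "C11H12N2O2",
}

# Cystine appears in the MRM panel in place of cysteine.
EXTRA_FORMULAS: dict[str, str] = {
    "cystine": "C6H12N2O4S2",
    "cysteine sulfinic acid": "C3H7NO4S",
    "gaba": "C4H9NO2",
    "histamine": "C5H9N3",
    "hypotaurine": "C2H7NO2S",
    "tryptamine": "C10H12N2",
    "phenethylamine": "C8H11N",
    "tyramine": "C8H11NO",
}

FORMULAS: dict[str, str] = {**AMINO_ACID_FORMULAS, **EXTRA_FORMULAS}

# Known substrate -> product pairs of the human group II amino acid
# decarboxylases; every pair differs by exactly one CO2.
# (enzyme, substrate name, product name)
KNOWN_DECARBOXYLATION_PAIRS: list[tuple[str, str, str]] = [
    ("GAD", "glutamic acid", "gaba"),
    ("HDC", "histidine", "histamine"),
    ("CSAD", "cysteine sulfinic acid", "hypotaurine"),
    ("AADC", "tryptophan", "tryptamine"),
    ("AADC", "phenylalanine", "phenethylamine"),
    ("AADC", "tyrosine", "tyramine"),
]

# Nominal HILIC retention times (min) used by the simulator; polar amino
# acids elute late on amide HILIC, amines earlier.
RETENTION_TIMES: dict[str, float] = {
    "glycine": 5.6,
    "alanine": 5.1,
    "serine": 5.9,
    "proline": 4.6,
    "valine": 4.2,
    "threonine": 5.3,
    "cysteine": 5.0,
    "leucine": 3.6,
    "isoleucine": 3.8,
    "asparagine": 6.0,
    "aspartic acid": 6.6,
    "glutamine": 5.7,
    "lysine": 6.9,
    "glutamic acid": 6.3,
    "methionine": 4.0,
    "histidine": 6.5,
    "phenylalanine": 3.3,
    "arginine": 6.8,
    "tyrosine": 4.4,
    "tryptophan": 3.1,
    "cystine": 6.2,
    "cysteine sulfinic acid": 6.1,
    "gaba": 4.8,
    "histamine": 5.4,
    "hypotaurine": 5.2,
    "tryptamine": 2.6,
    "phenethylamine": 2.4,
    "tyramine": 3.0,
}

# Fragment lists (m/z, relative intensity) for the metabolites whose MS2
# identity matters to the workflow; values are package conventions modelled
# on typical immonium/neutral-loss fragments of protonated amino acids.
MS2_FRAGMENTS: dict[str, list[tuple[float, float]]] = {
    "glutamic acid": [(84.0444, 1.00), (102.0550, 0.45), (130.0499, 0.30), (56.0495, 0.15)],
    "gaba": [(87.0441, 1.00), (69.0335, 0.60), (86.0600, 0.25), (45.0335, 0.10)],
    "histidine": [(110.0713, 1.00), (95.0604, 0.35), (83.0604, 0.20)],
    "histamine": [(95.0604, 1.00), (68.0495, 0.40)],
    "tryptophan": [(146.0600, 1.00), (188.0706, 0.55), (118.0651, 0.30)],
    "tryptamine": [(144.0808, 1.00), (117.0573, 0.35)],
    "phenylalanine": [(120.0808, 1.00), (103.0542, 0.50), (77.0386, 0.20)],
    "phenethylamine": [(105.0699, 1.00), (79.0542, 0.30)],
    "tyrosine": [(136.0757, 1.00), (119.0491, 0.45), (91.0542, 0.25)],
    "tyramine": [(121.0648, 1.00), (93.0699, 0.35)],
    "cysteine sulfinic acid": [(88.0215, 1.00), (70.0287, 0.40)],
    "hypotaurine": [(92.0170, 1.00), (74.0064, 0.30)],
}


def verify_decarboxylation_pairs(tolerance_da: float = 1e-4) -> None:
    """Assert every known pair differs by one CO2 within ``tolerance_da``."""
    for enzyme, substrate, product in KNOWN_DECARBOXYLATION_PAIRS:
        delta = formula_mass(FORMULAS[substrate]) - formula_mass(FORMULAS[product])
        if abs(delta - CO2_MASS) > tolerance_da:
            raise AssertionError(
                f"{enzyme}: {substrate} -> {product} mass delta {delta:.5f} "
                f"is not a CO2 loss"
            )
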