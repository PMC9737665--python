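"""Identification of substrate/product candidates.

Three confirmation layers, mirroring the untargeted workflow: (1) pairing
of depleted with accumulated candidates through the CO2 neutral-loss mass
shift; (2) formula/adduct annotation against a metabolite library (with
optional retention-time gating); (3) MS2 spectral matching by greedy
cosine similarity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import metabolites as _metab
from .differential import CandidateCall
from .masscalc import (
    CO2_MASS,
    IONS_BY_POLARITY,
    IonSpec,
    decarboxylation_mz,
    formula_mass,
    ion_mz,
    ppm_error,
)
from .runs import MS2Spectrum
from .synthetic_data import MetaboliteRecord

__all__ = [
    "SubstrateProductPair",
    "Annotation",
    "pair_decarboxylation",
    "annotate_feature",
    "cosine_score",
    "identify_ms2",
    "label_known_pairs",
]


@dataclass
class SubstrateProductPair:
    """A depleted/accumulated candidate pair consistent with CO2 loss."""

    substrate: CandidateCall
    product: CandidateCall
    observed_delta: float  # Da
    ppm_error: float  # vs the CO2-shifted substrate ion m/z
    polarity: str
    substrate_name: str | None = None
    product_name: str | None = None
    enzyme: str | None = None
    ms2_score: float | None = None


@dataclass
class Annotation:
    """A library identity assigned to an observed ion."""

    name: str
    formula: str
    adduct: str
    theoretical_mz: float
    ppm_error: float
    rt_error: float | None = None
    ms2_score: float | None = None


def pair_decarboxylation(
    depleted: list[CandidateCall],
    accumulated: list[CandidateCall],
    ppm_tol: float = 10.0,
) -> list[SubstrateProductPair]:
    """All same-polarity (depleted, accumulated) pairs whose m/z difference
    matches a CO2 loss within ``ppm_tol``, sorted by absolute ppm error.

    Same-adduct pairing makes the test polarity-safe: the adduct shift
    cancels in the difference, so the expected product ion m/z is simply
    the substrate ion m/z minus the CO2 mass.
    """
    pairs = []
    for d in depleted:
        if d.mz <= CO2_MASS:
            continue
        expected = decarboxylation_mz(d.mz)
        for a in accumulated:
            if a.polarity != d.polarity:
                continue
            err = ppm_error(a.mz, expected)
            if abs(err) <= ppm_tol:
                pairs.append(
                    SubstrateProductPair(
                        d, a, d.mz - a.mz, err, d.polarity
                    )
                )
    pairs.sort(key=lambda p: abs(p.ppm_error))
    return pairs


def annotate_feature(
    mz: float,
    polarity: str,
    library: list[MetaboliteRecord],
    adducts: list[IonSpec] | None = None,
    ppm_tol: float = 5.0,
    rt: float | None = None,
    rt_tol: float = 0.5,
) -> list[Annotation]:
    """Library identities compatible with an observed ion.

    Every (metabolite, adduct) combination within ``ppm_tol`` is returned,
    sorted by absolute ppm error. When both the observed RT and a library
    RT are available, matches outside ``rt_tol`` minutes are rejected.
    """
    if adducts is None:
        adducts = [IONS_BY_POLARITY[polarity]]
    out = []
    for record in library:
        for ion in adducts:
            if ion.polarity != polarity:
                continue
            theory = ion_mz(formula_mass(record.formula), ion)
            err = ppm_error(mz, theory)
            if abs(err) > ppm_tol:
                continue
            rt_err = None
            if rt is not None and record.retention_time is not None:
                rt_err = rt - record.retention_time
                if abs(rt_err) > rt_tol:
                    continue
            out.append(
                Annotation(record.name, record.formula, ion.name, theory, err, rt_err)
            )
    out.sort(key=lambda a: abs(a.ppm_error))
    return out


def cosine_score(
    a: MS2Spectrum,
    b: MS2Spectrum,
    frag_tol: float = 0.02,
    intensity_power: float = 1.0,
) -> float:
    """Greedy cosine similarity between two fragmentation spectra.

    Candidate fragment pairs within ``frag_tol`` are accepted in descending
    order of intensity product, each fragment used at most once; the score
    is the dot product of matched intensities normalized by both spectra's
    full intensity norms, so it lies in [0, 1] and equals 1 only for
    proportional spectra. ``intensity_power`` < 1 (for example 0.5) damps
    dominant fragments; the default applies no weighting.
    """
    if a.polarity != b.polarity:
        raise ValueError("spectra must share polarity")
    if len(a.mz) == 0 or len(b.mz) == 0:
        return 0.0
    ia = np.power(a.intensity, intensity_power)
    ib = np.power(b.intensity, intensity_power)
    norm = np.linalg.norm(ia) * np.linalg.norm(ib)
    if norm == 0:
        return 0.0
    candidates = [
        (float(ia[i] * ib[j]), i, j)
        for i in range(len(a.mz))
        for j in range(len(b.mz))
        if abs(a.mz[i] - b.mz[j]) <= frag_tol
    ]
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    dot = 0.0
    for product, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        dot += product
    return float(dot / norm)


def identify_ms2(
    query: MS2Spectrum,
    library: list[MetaboliteRecord],
    min_score: float = 0.7,
    precursor_ppm_tol: float = 5.0,
    frag_tol: float = 0.02,
) -> Annotation | None:
    """Best-scoring library identity for a fragmentation spectrum.

    Library entries must match the query precursor within the annotation
    ppm tolerance; among entries with cosine score >= ``min_score`` the
    highest score wins, ties broken by smaller precursor ppm error.
    """
    ion = IONS_BY_POLARITY[query.polarity]
    best: tuple[float, float, Annotation] | None = None
    for record in library:
        if not record.ms2_fragments:
            continue
        theory = ion_mz(formula_mass(record.formula), ion)
        prec_err = ppm_error(query.precursor_mz, theory)
        if abs(prec_err) > precursor_ppm_tol:
            continue
        ref = MS2Spectrum(
            theory,
            query.polarity,
            np.array([m for m, _ in record.ms2_fragments]),
            np.array([r for _, r in record.ms2_fragments]),
            name=record.name,
        )
        score = cosine_score(query, ref, frag_tol)
        if score < min_score:
            continue
        key = (score, -abs(prec_err))
        if best is None or key > (best[0], -abs(best[1])):
            best = (
                score,
                prec_err,
                Annotation(
                    record.name, record.formula, ion.name, theory, prec_err,
                    ms2_score=score,
                ),
            )
    return best[2] if best else None


def label_known_pairs(
    pairs: list[SubstrateProductPair],
    library: list[MetaboliteRecord],
    ppm_tol: float = 5.0,
) -> list[SubstrateProductPair]:
    """Attach library names and, where applicable, the known decarboxylase.

    Both ends of each pair are annotated against the library; when the
    named substrate/product combination appears in the group II
    decarboxylase map, the enzyme name is recorded too.
    """
    enzyme_by_pair = {
        (sub, prod): enz for enz, sub, prod in _metab.KNOWN_DECARBOXYLATION_PAIRS
    }
    for pair in pairs:
        subs = annotate_feature(
            pair.substrate.mz, pair.polarity, library, ppm_tol=ppm_tol
        )
        prods = annotate_feature(
            pair.product.mz, pair.polarity, library, ppm_tol=ppm_tol
        )
        if subs:
            pair.substrate_name = subs[0].name
        if prods:
            pair.product_name = prods[0].name
        if pair.substrate_name and pair.product_name:
            pair.enzyme = enzyme_by_pair.get((pair.substrate_name, pair.product_name))
    return pairs
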