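"""CO2-loss pairing, library annotation and MS2 cosine matching."""

import itertools

import numpy as np
import pytest

from decarbid.annotation import (
    annotate_feature,
    cosine_score,
    identify_ms2,
    label_known_pairs,
    pair_decarboxylation,
)
from decarbid.differential import CandidateCall
from decarbid.masscalc import CO2_MASS, ION_POSITIVE, formula_mass, ion_mz
from decarbid.runs import MS2Spectrum
from decarbid.synthetic_data import MetaboliteRecord, build_library


def call(mz, direction, polarity="positive", rt=3.0):
    fold = 10.0 if direction == "depleted" else 10.0
    ratio = fold if direction == "depleted" else 1.0 / fold
    return CandidateCall(0, mz, rt, polarity, direction, fold, ratio, 1)


class TestPairDecarboxylation:
    def test_observed_glutamate_gaba_ions_pair_within_tolerance(self):
        # instrument-observed values: 148.0600 depleted, 104.0703 accumulated
        depleted = [call(148.0600, "depleted")]
        accumulated = [
            call(104.0703, "accumulated"),
            call(104.12, "accumulated"),  # decoy ~0.05 Da off
            call(104.02, "accumulated"),  # decoy ~0.05 Da off
        ]
        pairs = pair_decarboxylation(depleted, accumulated, ppm_tol=10.0)
        assert len(pairs) == 1
        p = pairs[0]
        assert p.product.mz == 104.0703
        assert p.observed_delta == pytest.approx(CO2_MASS, abs=0.001)
        assert abs(p.ppm_error) < 2.0

    def test_polarity_mismatch_never_pairs(self):
        depleted = [call(148.0600, "depleted", polarity="positive")]
        accumulated = [call(104.0703, "accumulated", polarity="negative")]
        assert pair_decarboxylation(depleted, accumulated) == []

    def test_pairs_sorted_by_absolute_ppm_error(self):
        expected = 148.0600 - CO2_MASS
        depleted = [call(148.0600, "depleted")]
        accumulated = [
            call(expected * (1 + 6e-6), "accumulated"),
            call(expected * (1 - 2e-6), "accumulated"),
        ]
        pairs = pair_decarboxylation(depleted, accumulated, ppm_tol=10.0)
        assert len(pairs) == 2
        assert abs(pairs[0].ppm_error) < abs(pairs[1].ppm_error)
        assert pairs[0].ppm_error == pytest.approx(-2.0, abs=0.1)

    def test_substrate_below_co2_mass_is_skipped(self):
        assert pair_decarboxylation([call(40.0, "depleted")], [call(30.0, "accumulated")]) == []


class TestAnnotateFeature:
    def test_observed_positive_glutamate_ion_annotates(self):
        lib = build_library(0, seed=0)
        anns = annotate_feature(148.0600, "positive", lib)
        assert anns and anns[0].name == "glutamic acid"
        assert anns[0].adduct == "[M+H]+"
        assert abs(anns[0].ppm_error) < 5.0

    def test_observed_negative_glutamate_ion_annotates(self):
        lib = build_library(0, seed=0)
        anns = annotate_feature(146.0461, "negative", lib)
        assert anns and anns[0].name == "glutamic acid"
        assert anns[0].adduct == "[M-H]-"
        assert abs(anns[0].ppm_error) < 5.0

    def test_unmatched_mz_returns_empty(self):
        lib = build_library(0, seed=0)
        assert annotate_feature(500.0, "positive", lib) == []

    def test_rt_gate_rejects_distant_candidates(self):
        lib = build_library(0, seed=0)
        glu_rt = next(r.retention_time for r in lib if r.name == "glutamic acid")
        assert annotate_feature(148.0600, "positive", lib, rt=glu_rt + 0.1)
        assert annotate_feature(148.0600, "positive", lib, rt=glu_rt + 2.0) == []

    def test_isobaric_leucine_isoleucine_both_reported(self):
        lib = build_library(0, seed=0)
        mz = ion_mz(formula_mass("C6H13NO2"), ION_POSITIVE)
        names = {a.name for a in annotate_feature(mz, "positive", lib)}
        assert names == {"leucine", "isoleucine"}


def spec(mzs, ints, precursor=200.0, polarity="positive", name=""):
    return MS2Spectrum(precursor, polarity, np.array(mzs, float), np.array(ints, float), name=name)


class TestCosineScore:
    def test_identical_spectrum_scores_one(self):
        s = spec([56.05, 84.04, 130.05], [1.0, 0.8, 0.3])
        assert cosine_score(s, s) == pytest.approx(1.0)

    def test_proportional_spectra_score_one(self):
        a = spec([56.05, 84.04], [1.0, 0.5])
        b = spec([56.05, 84.04], [200.0, 100.0])
        assert cosine_score(a, b) == pytest.approx(1.0)

    def test_disjoint_spectra_score_zero(self):
        a = spec([56.05, 84.04], [1.0, 0.5])
        b = spec([120.0, 150.0], [1.0, 0.5])
        assert cosine_score(a, b) == 0.0

    def test_symmetry(self):
        rng = np.random.default_rng(4)
        a = spec(np.sort(rng.uniform(50, 190, 5)), rng.uniform(0.1, 1, 5))
        b = spec(np.sort(rng.uniform(50, 190, 5)), rng.uniform(0.1, 1, 5))
        assert cosine_score(a, b) == pytest.approx(cosine_score(b, a), abs=1e-12)

    def test_polarity_mismatch_is_an_error(self):
        a = spec([56.05], [1.0], polarity="positive")
        b = spec([56.05], [1.0], polarity="negative")
        with pytest.raises(ValueError):
            cosine_score(a, b)

    def test_empty_spectrum_scores_zero(self):
        a = spec([56.05], [1.0])
        b = spec([], [])
        assert cosine_score(a, b) == 0.0


def brute_force_cosine(a, b, frag_tol=0.02):
    """Oracle: maximum matched dot product over all one-to-one matchings."""
    na, nb = len(a.mz), len(b.mz)
    pairs = [
        (i, j)
        for i in range(na)
        for j in range(nb)
        if abs(a.mz[i] - b.mz[j]) <= frag_tol
    ]
    best = 0.0
    for r in range(min(na, nb) + 1):
        for combo in itertools.combinations(pairs, r):
            ia = [i for i, _ in combo]
            jb = [j for _, j in combo]
            if len(set(ia)) != r or len(set(jb)) != r:
                continue
            dot = sum(a.intensity[i] * b.intensity[j] for i, j in combo)
            best = max(best, dot)
    norm = np.linalg.norm(a.intensity) * np.linalg.norm(b.intensity)
    return best / norm if norm else 0.0


class TestCosineOracles:
    def test_greedy_equals_exhaustive_on_separated_instances(self):
        """With fragments separated by > 2x tolerance inside each spectrum,
        the greedy matching attains the exhaustive maximum."""
        rng = np.random.default_rng(23)
        for _ in range(100):
            na, nb = int(rng.integers(1, 7)), int(rng.integers(1, 7))
            mz_a = np.sort(rng.choice(np.arange(50.0, 200.0, 0.06), na, replace=False))
            # half of b's fragments sit on a's grid (shifted < tol), rest random
            mz_b = []
            for _ in range(nb):
                if rng.random() < 0.5 and na:
                    mz_b.append(float(rng.choice(mz_a)) + rng.uniform(-0.015, 0.015))
                else:
                    mz_b.append(float(rng.uniform(50, 200)))
            a = spec(mz_a, rng.uniform(0.05, 1.0, na))
            b = spec(np.sort(mz_b), rng.uniform(0.05, 1.0, nb))
            assert cosine_score(a, b) == pytest.approx(brute_force_cosine(a, b), abs=1e-9)

    def test_cross_check_against_matchms(self):
        from matchms import Spectrum
        from matchms.similarity import CosineGreedy

        rng = np.random.default_rng(31)
        sim = CosineGreedy(tolerance=0.02)
        for _ in range(20):
            na, nb = int(rng.integers(2, 7)), int(rng.integers(2, 7))
            mz_a = np.sort(rng.choice(np.arange(50.0, 200.0, 0.06), na, replace=False))
            mz_b = np.sort(rng.choice(np.arange(50.0, 200.0, 0.06), nb, replace=False))
            ia, ib = rng.uniform(0.05, 1.0, na), rng.uniform(0.05, 1.0, nb)
            ours = cosine_score(spec(mz_a, ia), spec(mz_b, ib))
            theirs = sim.pair(
                Spectrum(mz=mz_a, intensities=ia, metadata={}),
                Spectrum(mz=mz_b, intensities=ib, metadata={}),
            )
            assert ours == pytest.approx(float(theirs["score"]), abs=1e-9)


class TestIdentifyMs2:
    def _library(self):
        return [
            MetaboliteRecord(
                "glutamic acid", "C5H9NO4", 6.3, 20000.0,
                ms2_fragments=[(130.0499, 1.0), (84.0444, 0.9), (102.0550, 0.4)],
            ),
            MetaboliteRecord(
                "gaba", "C4H9NO2", 4.8, 15000.0,
                ms2_fragments=[(87.0441, 1.0), (69.0335, 0.6), (45.0335, 0.2)],
            ),
        ]

    def _query(self, record, polarity="positive"):
        theory = ion_mz(formula_mass(record.formula), ION_POSITIVE)
        mzs = np.array([m for m, _ in record.ms2_fragments])
        ints = np.array([r for _, r in record.ms2_fragments]) * 1000.0
        return MS2Spectrum(theory, polarity, mzs, ints)

    def test_round_trip_identification(self):
        lib = self._library()
        for rec in lib:
            ann = identify_ms2(self._query(rec), lib)
            assert ann is not None
            assert ann.name == rec.name
            assert ann.ms2_score == pytest.approx(1.0)

    def test_unattainable_min_score_returns_none(self):
        lib = self._library()
        assert identify_ms2(self._query(lib[0]), lib, min_score=1.01) is None

    def test_precursor_gate_rejects_wrong_mass(self):
        lib = self._library()
        q = self._query(lib[0])
        shifted = MS2Spectrum(q.precursor_mz + 1.5, q.polarity, q.mz, q.intensity)
        assert identify_ms2(shifted, lib) is None


def test_label_known_pairs_attaches_names_and_enzyme():
    lib = build_library(0, seed=0) + [
        MetaboliteRecord("gaba", "C4H9NO2", 4.8, 15000.0)
    ]
    glu_mz = ion_mz(formula_mass("C5H9NO4"), ION_POSITIVE)
    gaba_mz = ion_mz(formula_mass("C4H9NO2"), ION_POSITIVE)
    pairs = pair_decarboxylation(
        [call(glu_mz, "depleted")], [call(gaba_mz, "accumulated")]
    )
    assert len(pairs) == 1
    label_known_pairs(pairs, lib)
    assert pairs[0].substrate_name == "glutamic acid"
    assert pairs[0].product_name == "gaba"
    assert pairs[0].enzyme == "GAD"
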