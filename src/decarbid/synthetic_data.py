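"""Seeded simulator for decarboxylase substrate-identification experiments.

Generates vector-control and enzyme-group LC-MS runs with the statistical
structure the analysis assumes: a metabolite pool (the 20 proteinogenic
amino acids plus an arbitrary number of background tissue metabolites),
Gaussian elution peaks on a regular scan grid, per-point m/z jitter,
additive baseline noise, replicate-level multiplicative noise, substrate
depletion and product accumulation in the enzyme arm, and matching MS2
spectra and MRM traces.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from . import metabolites as _metab
from .masscalc import (
    CO2_MASS,
    IONS_BY_POLARITY,
    formula_mass,
    ion_mz,
    ppm_error,
)
from .runs import CentroidSpectrum, MRMTrace, MS2Spectrum, Run

__all__ = [
    "MetaboliteRecord",
    "EnzymeEffect",
    "RunSpec",
    "ExperimentBundle",
    "build_library",
    "simulate_run",
    "simulate_experiment",
    "simulate_targeted_experiment",
    "gad65_effect",
    "aadc_effects",
]


@dataclass
class MetaboliteRecord:
    """A library entry: identity, chromatography and MS behaviour."""

    name: str
    formula: str
    retention_time: float  # minutes
    base_intensity: float  # apex height in counts at unit concentration
    ms2_fragments: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.base_intensity <= 0:
            raise ValueError("base_intensity must be positive")
        precursor = formula_mass(self.formula) + 1.01
        for mz, rel in self.ms2_fragments:
            if mz >= precursor + 0.01:
                raise ValueError(
                    f"{self.name}: fragment {mz} above precursor {precursor}"
                )
            if not 0 <= rel <= 1:
                raise ValueError("fragment relative intensity outside [0, 1]")

    @property
    def neutral_mass(self) -> float:
        return formula_mass(self.formula)


@dataclass
class EnzymeEffect:
    """One substrate -> product conversion applied to the enzyme group.

    The substrate is scaled by ``1/depletion_factor`` in the enzyme arm and
    the product, absent from the vector arm, appears at
    ``accumulation_intensity`` counts. When ``decarboxylation`` is true the
    substrate/product formulas must differ by exactly one CO2.
    """

    substrate: str
    depletion_factor: float
    product: str
    product_formula: str
    accumulation_intensity: float
    product_rt: float | None = None
    decarboxylation: bool = True

    def __post_init__(self) -> None:
        if self.depletion_factor < 1:
            raise ValueError("depletion_factor must be >= 1")


@dataclass
class RunSpec:
    """Acquisition and noise model for one simulated injection series."""

    polarity: str = "positive"
    duration_min: float = 8.0
    scan_interval_s: float = 1.0
    peak_sigma_min: float = 0.05
    mz_jitter_ppm: float = 3.0
    replicate_sigma: float = 0.1  # lognormal sigma on peak height
    baseline_peaks_per_scan: float = 2.0
    baseline_intensity_scale: float = 60.0  # mean of exponential draw
    baseline_mz_range: tuple[float, float] = (60.0, 600.0)
    centroid_merge_da: float = 0.004  # instrument centroid resolution
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scan_interval_s <= 0 or self.duration_min <= 0:
            raise ValueError("scan interval and duration must be positive")
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"unknown polarity {self.polarity!r}")

    @property
    def scan_times(self) -> np.ndarray:
        n = int(round(self.duration_min * 60.0 / self.scan_interval_s)) + 1
        return np.arange(n) * self.scan_interval_s / 60.0


def _known_pair_ion_mzs() -> dict[str, np.ndarray]:
    """All substrate/product ion m/z of the known decarboxylase pairs."""
    out: dict[str, list[float]] = {"positive": [], "negative": []}
    names = set()
    for _, sub, prod in _metab.KNOWN_DECARBOXYLATION_PAIRS:
        names.update((sub, prod))
    for name in names:
        mass = formula_mass(_metab.FORMULAS[name])
        for pol, ion in IONS_BY_POLARITY.items():
            out[pol].append(ion_mz(mass, ion))
    return {pol: np.array(v) for pol, v in out.items()}


def _random_fragments(rng: np.random.Generator, neutral: float) -> list[tuple[float, float]]:
    n = int(rng.integers(3, 9))
    hi = max(31.0, neutral - 2.0)
    mzs = np.sort(rng.uniform(30.0, hi, n))
    rels = rng.uniform(0.05, 1.0, n)
    rels /= rels.max()
    return [(float(m), float(r)) for m, r in zip(mzs, rels)]


def build_library(
    n_background: int,
    seed: int,
    rt_range: tuple[float, float] = (0.8, 7.2),
    amino_acid_intensity: float = 20000.0,
    background_intensity_range: tuple[float, float] = (800.0, 50000.0),
    exclude_near_known: bool = True,
    exclusion_ppm: float = 25.0,
) -> list[MetaboliteRecord]:
    """The 20 proteinogenic amino acids plus random background metabolites.

    Background entries get random CHNOS formulas, retention times and base
    intensities. With ``exclude_near_known`` (default) no background ion in
    either polarity falls within ``exclusion_ppm`` of a known decarboxylase
    substrate or product ion, so simulated pairings are unambiguous.
    """
    if n_background < 0:
        raise ValueError("n_background must be >= 0")
    rng = np.random.default_rng(seed)
    records: list[MetaboliteRecord] = []
    for name, formula in _metab.AMINO_ACID_FORMULAS.items():
        frags = _metab.MS2_FRAGMENTS.get(name) or _random_fragments(
            rng, formula_mass(formula)
        )
        records.append(
            MetaboliteRecord(
                name,
                formula,
                _metab.RETENTION_TIMES[name],
                amino_acid_intensity,
                list(frags),
            )
        )
    known = _known_pair_ion_mzs()
    lo_i, hi_i = np.log(background_intensity_range)
    made = 0
    while made < n_background:
        c = int(rng.integers(2, 21))
        h = int(rng.integers(3, 2 * c + 3))
        n = int(rng.integers(0, 5))
        o = int(rng.integers(0, 9))
        s = int(rng.integers(0, 10) == 0)
        formula = f"C{c}H{h}" + (f"N{n}" if n else "") + (f"O{o}" if o else "") + (
            "S" if s else ""
        )
        mass = formula_mass(formula)
        if not 60.0 <= mass <= 550.0:
            continue
        if exclude_near_known:
            clash = False
            for pol, ion in IONS_BY_POLARITY.items():
                mz = ion_mz(mass, ion)
                dev = 1e6 * np.abs(mz - known[pol]) / known[pol]
                if np.any(dev <= exclusion_ppm):
                    clash = True
                    break
            if clash:
                continue
        rt = float(rng.uniform(*rt_range))
        height = float(np.exp(rng.uniform(lo_i, hi_i)))
        records.append(
            MetaboliteRecord(
                f"bg_{made:04d}", formula, rt, height, _random_fragments(rng, mass)
            )
        )
        made += 1
    return records


def simulate_run(
    library: list[MetaboliteRecord],
    concentrations: dict[str, float] | None,
    spec: RunSpec,
    run_id: str = "run",
) -> Run:
    """One centroided run: Gaussian elution profiles plus baseline noise.

    Each metabolite with a positive scale contributes apex height
    ``base_intensity * scale`` at its retention time; points below one count
    or beyond four peak sigmas are dropped. Per-point m/z jitter is Gaussian
    with the RunSpec's ppm sigma; baseline noise peaks are Poisson per scan
    with exponential intensities.
    """
    if not library:
        raise ValueError("empty metabolite library")
    rng = np.random.default_rng(spec.seed)
    ion = IONS_BY_POLARITY[spec.polarity]
    times = spec.scan_times
    sigma = spec.peak_sigma_min
    scan_parts: list[np.ndarray] = []
    mz_parts: list[np.ndarray] = []
    int_parts: list[np.ndarray] = []

    for record in library:
        scale = 1.0 if concentrations is None else concentrations.get(record.name, 0.0)
        if scale < 0:
            raise ValueError(f"negative concentration scale for {record.name}")
        if scale == 0.0:
            continue
        height = record.base_intensity * scale
        mz0 = ion_mz(record.neutral_mass, ion)
        lo = np.searchsorted(times, record.retention_time - 4 * sigma)
        hi = np.searchsorted(times, record.retention_time + 4 * sigma, side="right")
        t = times[lo:hi]
        inten = height * np.exp(-0.5 * ((t - record.retention_time) / sigma) ** 2)
        keep = inten >= 1.0
        idxs = np.nonzero(keep)[0] + lo
        inten = inten[keep]
        if spec.mz_jitter_ppm > 0:
            mzs = mz0 * (1.0 + 1e-6 * spec.mz_jitter_ppm * rng.standard_normal(len(inten)))
        else:
            mzs = np.full(len(inten), mz0)
        scan_parts.append(idxs)
        mz_parts.append(mzs)
        int_parts.append(inten)

    if spec.baseline_peaks_per_scan > 0:
        counts = rng.poisson(spec.baseline_peaks_per_scan, len(times))
        total = int(counts.sum())
        scan_parts.append(np.repeat(np.arange(len(times)), counts))
        mz_parts.append(rng.uniform(*spec.baseline_mz_range, total))
        int_parts.append(rng.exponential(spec.baseline_intensity_scale, total))

    if scan_parts:
        all_scan = np.concatenate(scan_parts)
        all_mz = np.concatenate(mz_parts)
        all_int = np.concatenate(int_parts)
    else:
        all_scan = np.empty(0, dtype=int)
        all_mz = all_int = np.empty(0)
    order = np.lexsort((all_mz, all_scan))
    all_scan, all_mz, all_int = all_scan[order], all_mz[order], all_int[order]
    bounds = np.searchsorted(all_scan, np.arange(len(times) + 1))

    scans = []
    for i, rt in enumerate(times):
        mz = all_mz[bounds[i]: bounds[i + 1]]
        inten = all_int[bounds[i]: bounds[i + 1]]
        if len(mz) > 1:
            # centroids closer than the instrument can resolve merge into
            # one peak (intensity-weighted m/z, summed intensity)
            new_cluster = np.diff(mz) >= spec.centroid_merge_da
            starts = np.r_[0, np.nonzero(new_cluster)[0] + 1]
            inten_sum = np.add.reduceat(inten, starts)
            mz = np.add.reduceat(mz * inten, starts) / inten_sum
            inten = inten_sum
        scans.append(CentroidSpectrum(float(rt), spec.polarity, mz, inten))
    return Run(run_id, spec.polarity, scans, metadata={"seed": spec.seed})


@dataclass
class ExperimentBundle:
    """The full simulated output of one two-arm enzymatic experiment."""

    vector_runs: list[Run]
    enzyme_runs: list[Run]
    ms2_spectra: list[MS2Spectrum]
    mrm_traces: list[MRMTrace]
    library: list[MetaboliteRecord]
    effects: list[EnzymeEffect]
    spec: RunSpec

    @property
    def runs(self) -> dict[str, Run]:
        return {r.run_id: r for r in self.vector_runs + self.enzyme_runs}

    @property
    def groups(self) -> dict[str, str]:
        labels = {r.run_id: "vector" for r in self.vector_runs}
        labels.update({r.run_id: "enzyme" for r in self.enzyme_runs})
        return labels


def _validate_effect(effect: EnzymeEffect, by_name: dict[str, MetaboliteRecord]) -> None:
    if effect.substrate not in by_name:
        raise ValueError(f"substrate {effect.substrate!r} absent from library")
    if effect.decarboxylation:
        delta = (
            by_name[effect.substrate].neutral_mass
            - formula_mass(effect.product_formula)
        )
        if abs(delta - CO2_MASS) > 1e-3:
            raise ValueError(
                f"{effect.substrate} -> {effect.product}: mass delta "
                f"{delta:.5f} Da is not a CO2 loss"
            )


def _replicate_scales(
    rng: np.random.Generator, names: list[str], sigma: float
) -> dict[str, float]:
    if sigma <= 0:
        return {n: 1.0 for n in names}
    draws = rng.lognormal(0.0, sigma, len(names))
    return dict(zip(names, draws.tolist()))


def simulate_experiment(
    library: list[MetaboliteRecord],
    effects: EnzymeEffect | list[EnzymeEffect],
    n_replicates: int,
    spec: RunSpec,
    mrm_transitions: list | None = None,
) -> ExperimentBundle:
    """Simulate the two-arm design: vector-control vs enzyme reactions.

    Vector runs use unit concentration scales; enzyme runs divide each
    substrate's scale by its depletion factor and add the product at its
    accumulation intensity. Replicate-level lognormal noise multiplies every
    metabolite's height independently per run. MS2 spectra are emitted for
    each substrate and product; MRM traces are emitted for the targeted
    amino acid panel analytes present in the library.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if isinstance(effects, EnzymeEffect):
        effects = [effects]
    by_name = {r.name: r for r in library}
    for effect in effects:
        _validate_effect(effect, by_name)

    rng = np.random.default_rng(spec.seed)
    # Enzyme-arm library gains the products (vector scale 0).
    products: list[MetaboliteRecord] = []
    for effect in effects:
        rt = effect.product_rt
        if rt is None:
            rt = _metab.RETENTION_TIMES.get(
                effect.product, by_name[effect.substrate].retention_time - 0.5
            )
        frags = _metab.MS2_FRAGMENTS.get(effect.product) or _random_fragments(
            rng, formula_mass(effect.product_formula)
        )
        products.append(
            MetaboliteRecord(
                effect.product,
                effect.product_formula,
                rt,
                effect.accumulation_intensity,
                list(frags),
            )
        )
    full_library = library + [p for p in products if p.name not in by_name]
    names = [r.name for r in full_library]

    vector_runs, enzyme_runs = [], []
    for group, run_list in (("vector", vector_runs), ("enzyme", enzyme_runs)):
        for rep in range(n_replicates):
            scales = _replicate_scales(rng, names, spec.replicate_sigma)
            for product in products:
                scales[product.name] = 0.0
            if group == "enzyme":
                for effect, product in zip(effects, products):
                    scales[effect.substrate] /= effect.depletion_factor
                    noise = (
                        rng.lognormal(0.0, spec.replicate_sigma)
                        if spec.replicate_sigma > 0
                        else 1.0
                    )
                    scales[product.name] = noise
            child = int(rng.integers(0, 2**31 - 1))
            run_spec = dataclasses.replace(spec, seed=child)
            run_list.append(
                simulate_run(
                    full_library, scales, run_spec, run_id=f"{group}_{rep + 1}"
                )
            )

    ion = IONS_BY_POLARITY[spec.polarity]
    ms2 = []
    for effect, product in zip(effects, products):
        for record in (by_name[effect.substrate], product):
            frag_mz = np.array([m for m, _ in record.ms2_fragments])
            frag_int = np.array([r for _, r in record.ms2_fragments]) * 1000.0
            if spec.mz_jitter_ppm > 0:
                frag_mz = frag_mz * (
                    1.0 + 1e-6 * spec.mz_jitter_ppm * rng.standard_normal(len(frag_mz))
                )
            ms2.append(
                MS2Spectrum(
                    ion_mz(record.neutral_mass, ion),
                    spec.polarity,
                    frag_mz,
                    frag_int,
                    name=record.name,
                )
            )

    if mrm_transitions is None:
        from .targeted_panel import load_transitions

        mrm_transitions = load_transitions()
    traces: list[MRMTrace] = []
    effect_map = {e.substrate: e for e in effects}
    for run_list, group in ((vector_runs, "vector"), (enzyme_runs, "enzyme")):
        for run in run_list:
            for tr in mrm_transitions:
                record = by_name.get(tr.analyte)
                if record is None:
                    continue
                scale = 1.0
                if group == "enzyme" and tr.analyte in effect_map:
                    scale = 1.0 / effect_map[tr.analyte].depletion_factor
                noise = (
                    rng.lognormal(0.0, spec.replicate_sigma)
                    if spec.replicate_sigma > 0
                    else 1.0
                )
                t = spec.scan_times
                y = (
                    record.base_intensity
                    * scale
                    * noise
                    * np.exp(
                        -0.5
                        * ((t - record.retention_time) / spec.peak_sigma_min) ** 2
                    )
                )
                traces.append(
                    MRMTrace(
                        tr.analyte, tr.q1, tr.q3, tr.polarity, t, y, run.run_id, group
                    )
                )
    return ExperimentBundle(
        vector_runs, enzyme_runs, ms2, traces, full_library, effects, spec
    )


def simulate_targeted_experiment(
    effects: EnzymeEffect | list[EnzymeEffect],
    n_replicates: int = 3,
    spec: RunSpec | None = None,
) -> list[MRMTrace]:
    """MRM traces for the uniform amino-acid-mixture experiment.

    Emulates the simple-system assay: every panel amino acid at the same
    concentration, with the enzyme arm depleting its substrates.
    """
    spec = spec or RunSpec()
    library = build_library(0, seed=spec.seed)
    bundle = simulate_experiment(library, effects, n_replicates, spec)
    return bundle.mrm_traces


def gad65_effect(
    depletion_factor: float = 10.0, accumulation_intensity: float = 15000.0
) -> EnzymeEffect:
    """Glutamate decarboxylase: glutamate -> GABA."""
    return EnzymeEffect(
        "glutamic acid",
        depletion_factor,
        "gaba",
        _metab.FORMULAS["gaba"],
        accumulation_intensity,
        product_rt=_metab.RETENTION_TIMES["gaba"],
    )


def aadc_effects() -> list[EnzymeEffect]:
    """Aromatic amino acid decarboxylase: Phe/Trp depleted more strongly
    than Tyr, each paired with its biogenic amine."""
    return [
        EnzymeEffect(
            "phenylalanine", 8.0, "phenethylamine",
            _metab.FORMULAS["phenethylamine"], 12000.0,
            product_rt=_metab.RETENTION_TIMES["phenethylamine"],
        ),
        EnzymeEffect(
            "tryptophan", 8.0, "tryptamine",
            _metab.FORMULAS["tryptamine"], 12000.0,
            product_rt=_metab.RETENTION_TIMES["tryptamine"],
        ),
        EnzymeEffect(
            "tyrosine", 3.0, "tyramine",
            _metab.FORMULAS["tyramine"], 6000.0,
            product_rt=_metab.RETENTION_TIMES["tyramine"],
        ),
    ]
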