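# Methods

This document records the model behind each stage, the fixed parameter
values, what the simulator does and does not reproduce, and the numerical
choices that affect results.

## Mass arithmetic (`masscalc`)

Monoisotopic element masses (C 12.0, H 1.007825, N 14.003074,
O 15.994915, S 31.972071) are summed over parsed elemental formulas.
Adducts are [M+H]+ and [M−H]− with a proton mass of 1.007276 Da; the CO2
neutral-loss shift is the formula mass of CO2, 43.98983 Da. ppm error is
`1e6 * (observed − expected) / expected`. These five elements cover every
metabolite the package models; other elements raise `FormulaError` rather
than silently mis-summing.

## Simulator (`synthetic_data`)

One simulated injection is a regular scan grid (default 8 min at 1-s
intervals, 481 scans). Each library metabolite contributes a Gaussian
elution peak (σ = 0.05 min) in its adduct's m/z channel; points below one
count or beyond ±4σ are dropped. Per-point m/z jitter is Gaussian with
σ = 3 ppm; per-replicate peak heights are scaled by a lognormal factor
(σ = 0.1); the baseline adds Poisson(2) random centroids per scan with
exponentially distributed intensities (mean 60, below the 100-count
detection floor). Centroids closer than 0.004 Da within one scan are
merged intensity-weighted, emulating instrument centroiding — without
this, co-eluting isobars (leucine/isoleucine) would emit two separate
centroids at the same m/z, which no centroided file would contain.

The library holds the 20 proteinogenic amino acids (apex 20 000 counts)
plus `n_background` random CHNOS metabolites (mass 60–550, RT uniform in
0.8–7.2 min, heights log-uniform 800–50 000). Background ions falling
within 25 ppm of a known substrate/product ion are excluded so that
ground truth stays unambiguous — a deliberate simplification, not a claim
about real tissue extracts.

Enzyme effects scale the substrate by `1/depletion_factor` in the enzyme
arm and add the product (absent from the vector arm) at a fixed apex
intensity; substrate and product formulas must differ by exactly one CO2.
Presets: GAD65 (glutamate 10×, GABA at 15 000) and AADC (Phe and Trp 8×,
Tyr 3×, each with its amine). All randomness flows from one seed through
per-run child seeds, so every bundle is bit-reproducible.

**Scope.** The simulator does not model isotope patterns, in-source
fragmentation, ion suppression, RT drift between runs, peak tailing, or
detector saturation. Conclusions drawn from it are therefore about the
*analysis logic* (thresholds, pairing, ranking), not about instrument
physics.

## Feature extraction (`feature_extraction`)

1. **Noise floor.** Centroids below 100 counts are discarded.
2. **EIC building.** All remaining points are visited in descending
   intensity. Each unassigned point seeds a chromatogram; scans are
   walked outward from the seed and in each scan the nearest unassigned
   point within `max(0.002 Da, 20 ppm)` of the running intensity-weighted
   m/z center is appended. Every visited point is consumed once. A
   chromatogram survives with ≥ 5 points and a maximum ≥ 200 counts.
3. **Smoothing.** Savitzky–Golay, window 7, order 2, clamped at zero.
   This reproduces quadratics exactly, so Gaussian apexes are barely
   biased while high-frequency noise is attenuated.
4. **Peak resolving.** The EIC is split at interior local intensity
   minima (plateau minima resolve to their first index). A segment
   becomes a feature if its apex exceeds the 0.85 intensity quantile of
   the whole EIC, the apex-to-edge ratio is ≥ 1.7 (edge = the larger of
   the two per-side minima), and it spans ≥ 5 points.

**Area convention.** Area is the trapezoidal integral of the smoothed
intensity over RT in minutes. A valley point belongs to the left
feature's scan span, but it is the *integration boundary of both*
neighbouring peaks: the right-hand segment integrates from the valley
point itself. This conserves the total EIC area exactly and splits two
equal overlapping Gaussians symmetrically; assigning the valley→next
trapezoid wholly to one side biases both areas by ~2% at 2σ peak
separation, which is why the convention matters at the calibration
tolerance.

Calibration (noiseless simulation, all 20 amino acids including the
isobaric leucine/isoleucine pair 0.2 min apart): 100% recall with areas
within 2% of the analytic `height · σ · √(2π)`.

## Alignment (`alignment`)

Runs are merged sequentially into a consensus table. Features match
consensus rows within `max(0.002 Da, 20 ppm)` m/z and 0.2 min RT; among
in-tolerance options the assignment minimizes the summed normalized score
`dmz/mz_tol + drt/rt_tol` over a one-to-one matching (solved with
`scipy.optimize.linear_sum_assignment`; a large constant for the
"new row" option makes match count take precedence over score). The test
suite verifies this against exhaustive enumeration on random instances.
Consensus m/z and RT are the means over member features.

**Gap filling.** For a missing cell, the most intense in-tolerance point
per scan within RT ± 0.2 min is collected; from the local apex the
window extends outward while intensity does not rise more than 2-fold
point-to-point (intensity tolerance 1.0), and at least one point is
required. A single-point fill integrates over one median scan interval.
Detected cells are never modified. Gap filling runs on *noise-filtered*
scans (same 100-count floor as extraction) so filled and detected values
share the same floor.

**Duplicate filtering.** Rows within both tolerances of each other are
collapsed; the greater total intensity wins, ties resolve to the lower
m/z. The result contains no in-tolerance pair (idempotent).

## Differential analysis (`differential`)

Per row, the group summary (mean by default; median available) is
computed over gap-filled intensities, and the ratio is
`(vector + p) / (enzyme + p)` with pseudocount `p` = half the smallest
nonzero intensity in the table. Rows are ranked by ascending ratio
(rank 1 = strongest accumulation). Calls use an inclusive 2-fold
threshold in both directions. An optional label-permutation p-value (with
the +1 correction) is provided but is not part of the core calling.

The pseudocount shrinks extreme ratios toward 1: a true 10× depletion
prints slightly below 10 when the enzyme-arm mean is small. This is the
standard bias/variance trade of pseudocounted ratios and is left visible
rather than corrected.

## Annotation (`annotation`)

- **Pairing.** Depleted and accumulated candidates of the same polarity
  pair when the accumulated m/z sits within 10 ppm of
  `substrate m/z − 43.98983`. Because both ions carry the same adduct,
  the adduct shift cancels in the difference, making the test
  polarity-safe.
- **Library annotation.** Every (metabolite, adduct) combination within
  5 ppm is returned, sorted by |ppm error|, with optional RT gating at
  ± 0.5 min.
- **MS2 matching.** Greedy cosine: candidate fragment pairs within
  0.02 Da are accepted in descending intensity-product order, each
  fragment used at most once; the matched dot product is normalized by
  both spectra's full norms, so the score lies in [0, 1] and reaches 1
  only for proportional spectra. Identification requires a 5-ppm
  precursor match and a score ≥ 0.7. The greedy matching equals the
  exhaustive-enumeration optimum whenever each fragment has at most one
  in-tolerance partner (fragments separated by more than twice the
  tolerance), which holds for the sparse amino-acid spectra modeled
  here; the test suite verifies both this and agreement with an
  independent implementation.

## Targeted panel (`targeted_panel`)

The built-in table lists 19 amino acid MRM transitions (no glycine;
cystine rather than cysteine; leucine and isoleucine share
Q1 132.1 / Q3 86.0 and are distinguished chromatographically). Q1 values
are validated against the formula-derived nominal [M+H]+ (monoisotopic
mass + 1.007276, rounded to one decimal); deviations above 0.25 warn but
never fail, because printed instrument tables round inconsistently.

Traces are integrated over the library RT ± 0.5 min after subtracting a
straight-line baseline between the window endpoints, clamped at zero —
this makes the area invariant under any constant offset and zero for a
flat trace. Group comparison reuses the untargeted ratio/pseudocount
logic; analytes at or above the 2-fold threshold are flagged depleted.

## Pipeline and reproducibility (`pipeline`)

`PipelineConfig` carries every parameter and serializes to YAML; its
SHA-256 hash is echoed in each report. Child seeds are derived as
`(seed · 1000003 + k) mod (2³¹ − 1)`, so each polarity and replicate gets
an independent, reproducible stream. Reports write the ranked table, the
feature table, the panel table (CSV, `%.6g`), a plain-text summary, and
the config echo; re-running the same config yields byte-identical files.

## Limitations

- Single adduct per polarity; no isotopologue or multi-charge handling.
- Sequential join alignment is order-dependent in principle; with the
  default tolerances and well-separated simulated features the result is
  order-stable, but heavily overlapping real data could differ.
- The untargeted branch currently starts from the simulator; reading
  external mzML runs is supported at the container level
  (`decarbid.runs.read_mzml`) but not yet wired into the pipeline entry
  points.
- The null-specificity guarantee (no calls on vector-vs-vector data) is
  demonstrated under the simulator's noise model, not against real blank
  injections.
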