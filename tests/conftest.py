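"""Shared fixtures: noiseless acquisition specs and small seeded experiments."""

from __future__ import annotations

import dataclasses

import pytest

from decarbid.synthetic_data import RunSpec, build_library, gad65_effect, simulate_experiment


@pytest.fixture
def noiseless_spec() -> RunSpec:
    """An acquisition with no jitter, no baseline and no replicate noise."""
    return RunSpec(
        mz_jitter_ppm=0.0,
        replicate_sigma=0.0,
        baseline_peaks_per_scan=0.0,
        seed=0,
    )


@pytest.fixture(scope="session")
def small_gad65_bundle():
    """A compact seeded GAD65 experiment (20 AAs + 40 background, 3 reps)."""
    library = build_library(40, seed=11)
    spec = RunSpec(seed=11)
    return simulate_experiment(library, gad65_effect(), 3, spec)


def make_noiseless_bundle(effect=None, n_background=0, seed=0, **spec_kwargs):
    library = build_library(n_background, seed=seed)
    spec = RunSpec(
        mz_jitter_ppm=0.0,
        replicate_sigma=0.0,
        baseline_peaks_per_scan=0.0,
        seed=seed,
        **spec_kwargs,
    )
    effects = [effect] if effect is not None else [gad65_effect()]
    return simulate_experiment(library, effects, 3, spec)


@pytest.fixture
def noiseless_gad65_bundle():
    return make_noiseless_bundle()
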