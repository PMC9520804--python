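"""Shared fixtures: small deterministic nuclei and the full two-phase cohort."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest

from telo3d.simulate import (
    IntensityMixture,
    SynthNucleusConfig,
    packaged_cohort_config,
)


def single_component_mixture(intensity: float) -> IntensityMixture:
    """Degenerate mixture: every telomere has exactly this intensity."""
    return IntensityMixture(
        weights=(1.0, 0.0, 0.0),
        log_means=(float(np.log(intensity)),) * 3,
        log_sds=(0.0, 0.0, 0.0),
    )


def clean_nucleus_config(**overrides) -> SynthNucleusConfig:
    """Noiseless single-population nucleus used for exactness tests."""
    base = dict(
        semi_axes=(4000.0, 3500.0, 2500.0),
        n_telomeres=(10, 0.0),
        n_aggregates=(0.0, 0.0),
        intensity_mixture=single_component_mixture(1000.0),
        noise_sd=0.0,
        background_level=20.0,
    )
    base.update(overrides)
    return SynthNucleusConfig(**base)


@pytest.fixture(scope="session")
def paper_cohorts() -> pd.DataFrame:
    """Both packaged phase cohorts (18 patients x 30 nuclei each), fully
    simulated and quantified in memory at their canonical seeds.

    Computed once per session; this is the most expensive fixture and backs
    the cohort-recovery and phase-discrimination checks.
    """
    from telo3d.pipeline import run_cohort

    tables = [
        run_cohort(packaged_cohort_config(phase), compute_radial=False)
        for phase in ("chronic", "accelerated_blast")
    ]
    return pd.concat(tables, ignore_index=True)


@pytest.fixture()
def tiny_cohort_config():
    """A 2-patient x 2-nucleus chronic cohort for plumbing tests."""
    cfg = packaged_cohort_config("chronic")
    return dataclasses.replace(cfg, n_patients=2, n_nuclei_per_sample=2, rng_seed=7)
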