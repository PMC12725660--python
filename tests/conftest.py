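"""Shared fixtures: reference simulations and (expensive) fitted cohorts."""

from __future__ import annotations

import warnings
from dataclasses import replace

import pytest

from glucostore.cohort import (
    CohortSpec,
    REFERENCE_CD,
    generate_cohort,
    study_cohort_spec,
)
from glucostore.estimation import FitConfig, fit_mouse
from glucostore.model import ModelParameters

PARAMS = ("k1", "k2", "k3", "k4", "k5", "k6", "k7", "k8", "G0", "I0")


def params_from_row(row) -> ModelParameters:
    return ModelParameters.from_dict({k: float(row[k]) for k in PARAMS})


@pytest.fixture(scope="session")
def reference_params() -> ModelParameters:
    return REFERENCE_CD


@pytest.fixture(scope="session")
def cd_clamp_traj(reference_params):
    """Closed-loop clamp of the reference chow-fed mouse, slow priming."""
    from glucostore.protocols import InfusionProtocol, run_clamp

    protocol = InfusionProtocol(mode="clamp", body_weight=27.0, initial_rate=0.15)
    return run_clamp(reference_params, protocol)


@pytest.fixture(scope="session")
def noisefree_cd_dataset():
    """Two noise-free chow-fed mice with exact (unrounded) doses."""
    full = study_cohort_spec(seed=101)
    spec = CohortSpec(
        groups=(replace(full.groups[0], n=2),),
        glucose_cv=0.0, insulin_cv=0.0, seed=101, dose_round_mg=0.0,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_cohort(spec)


@pytest.fixture(scope="session")
def noisefree_cd_fit(noisefree_cd_dataset):
    """Full global+local fit of the first noise-free chow-fed mouse."""
    rec = noisefree_cd_dataset.records[0]
    cfg = FitConfig(seed=42, population_size=32, generations=30)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_mouse(rec, cfg)
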