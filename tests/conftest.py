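"""Shared fixtures: small synthetic cohorts and random masked subgrids."""

from __future__ import annotations

import numpy as np
import pytest

from bladder_radiomics import SyntheticParams, default_specs, generate_cohort
from bladder_radiomics.pipeline import (
    CohortSource,
    StudyConfig,
    extract_cohort_features,
    run_training,
)


def random_masked_subgrid(rng: np.random.Generator, max_shape=(6, 6, 3), n_levels=8):
    """A random discretized subgrid with a random (non-empty) mask."""
    shape = tuple(int(rng.integers(2, m + 1)) for m in max_shape)
    levels = rng.integers(1, n_levels + 1, size=shape)
    mask = rng.random(shape) < rng.uniform(0.3, 0.95)
    if not mask.any():
        mask.flat[int(rng.integers(mask.size))] = True
    return levels, mask


@pytest.fixture(scope="session")
def strong_cohort():
    """A cohort with the default (clearly discriminative) texture effect."""
    params = SyntheticParams(n_patients=24, prevalence=0.5, effect_size=1.0, seed=7)
    records, table = generate_cohort(params)
    return params, records, table


@pytest.fixture(scope="session")
def strong_features(strong_cohort):
    _, records, _ = strong_cohort
    return extract_cohort_features(records, default_specs())


@pytest.fixture(scope="session")
def trained_study():
    """A full training run at the study's cohort geometry (40 = 21 + 19)."""
    config = StudyConfig(
        training=CohortSource(
            synthetic=SyntheticParams(
                n_patients=40, prevalence=0.525, effect_size=1.0, seed=11
            )
        ),
        validation=CohortSource(
            synthetic=SyntheticParams(
                n_patients=44, prevalence=0.636, effect_size=1.0, seed=12
            )
        ),
    )
    return config, run_training(config)
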