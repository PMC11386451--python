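"""Shared fixtures: small, fully in-memory synthetic cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from bpsubtype.synthetic_cohort import GeneratorConfig, generate_cohort


def tiny_config(**overrides) -> GeneratorConfig:
    """A fast cohort for unit tests: 40 train / 20 test patients, 6 patches."""
    defaults = dict(
        n_train_patients=40,
        n_test_patients=20,
        msi_fraction_train=0.30,
        msi_fraction_test=0.30,
        patches_per_patient=6,
        seed=0,
    )
    defaults.update(overrides)
    return GeneratorConfig(**defaults)


@pytest.fixture(scope="session")
def tiny_cohort():
    """(patients, patches, images) for a small rendered cohort."""
    return generate_cohort(tiny_config())


@pytest.fixture(scope="session")
def tiny_records():
    """(patients, patches) without any image rendering — covariates only."""
    patients, patches, _ = generate_cohort(tiny_config(), render=False)
    return patients, patches


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
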