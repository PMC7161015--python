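"""Shared fixtures: small synthetic cohorts reused across test modules."""

import dataclasses

import numpy as np
import pytest

from jawtmd import (
    CohortSpec,
    GroupProfile,
    default_profiles,
    extract_all,
    generate_cohort,
    study_profiles,
)


def noise_free(profiles):
    """Strip sensor noise and between-subject variation from profiles."""
    return {
        g: dataclasses.replace(p, sensor_noise_sd=0.0, between_subject_sd=0.0)
        for g, p in profiles.items()
    }


@pytest.fixture(scope="session")
def clean_profile():
    """One deterministic noise-free profile with round target features."""
    return GroupProfile(
        group_label="CG",
        opening_amplitude=40.0,
        opening_deviation=2.0,
        lateral_amplitude_left=10.0,
        lateral_amplitude_right=12.0,
        protrusion_amplitude=8.0,
        vertical_lateral_coupling=2.0,
        sagittal_coupling=1.5,
        between_subject_sd=0.0,
        sensor_noise_sd=0.0,
    )


@pytest.fixture(scope="session")
def separated_cohort():
    """40-subject cohort (20/10/10), group means 5 between-subject SDs apart."""
    spec = CohortSpec(n_per_group=(20, 10, 10), seed=20260924)
    sessions, labels, truth = generate_cohort(spec, study_profiles(separation=5.0))
    return sessions, labels, truth


@pytest.fixture(scope="session")
def separated_table(separated_cohort):
    sessions, _, _ = separated_cohort
    return extract_all(sessions)


@pytest.fixture(scope="session")
def noise_free_cohort():
    """Tiny noise-free cohort whose extracted features equal the truth table."""
    spec = CohortSpec(n_per_group=(2, 2, 2), seed=7)
    return generate_cohort(spec, noise_free(default_profiles()))
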