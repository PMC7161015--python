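"""Generator correctness: determinism, cohort layout, feature recovery."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from jawtmd import (
    CohortSpec,
    GroupProfile,
    extract_all,
    generate_cohort,
    generate_trajectory,
    movement_features,
    preprocess_session,
    truth_features,
)
from jawtmd.features import FEATURE_NAMES

from conftest import noise_free
from jawtmd.synthetic import default_profiles, study_profiles


def extract_one(profile, movement, seed=0, **pp_kwargs):
    session = generate_trajectory(profile, movement, np.random.default_rng(seed))
    segs = preprocess_session(session, **pp_kwargs)
    return pd.DataFrame([movement_features(s) for s in segs]).mean()


class TestGenerateTrajectory:
    def test_noise_free_opening_recovers_amplitude(self, clean_profile):
        profile = dataclasses.replace(
            clean_profile, opening_deviation=0.0, sagittal_coupling=0.0
        )
        feats = extract_one(profile, "OC", filter_enabled=False)
        assert feats["OCY"] == pytest.approx(40.0, abs=1e-6)
        assert feats["ODX"] == pytest.approx(0.0, abs=1e-6)
        assert feats["CDX"] == pytest.approx(0.0, abs=1e-6)

    def test_opening_deviation_doubles_into_ocx(self, clean_profile):
        # brute-force maximum of the generated deviation curve is the
        # profile's deviation amplitude, counted once per phase
        feats = extract_one(clean_profile, "OC", filter_enabled=False)
        assert feats["ODX"] == pytest.approx(2.0, abs=1e-9)
        assert feats["CDX"] == pytest.approx(2.0, abs=1e-9)
        assert feats["OCX"] == pytest.approx(4.0, abs=1e-9)

    def test_deviation_maximum_at_half_opening(self, clean_profile):
        feats = extract_one(clean_profile, "OC", filter_enabled=False)
        assert feats["ODY"] == pytest.approx(feats["OCY"] / 2, abs=1e-9)

    def test_same_rng_state_is_bit_identical(self, clean_profile):
        profile = dataclasses.replace(clean_profile, sensor_noise_sd=0.3)
        a = generate_trajectory(profile, "OC", np.random.default_rng(42))
        b = generate_trajectory(profile, "OC", np.random.default_rng(42))
        np.testing.assert_array_equal(a.primary.positions, b.primary.positions)
        np.testing.assert_array_equal(
            a.head_reference.positions, b.head_reference.positions
        )

    def test_unknown_movement_rejected(self, clean_profile):
        with pytest.raises(ValueError, match="unknown movement"):
            generate_trajectory(clean_profile, "XX", np.random.default_rng(0))

    def test_low_frame_rate_rejected(self, clean_profile):
        with pytest.raises(ValueError, match="frame_rate"):
            generate_trajectory(
                clean_profile, "OC", np.random.default_rng(0), frame_rate=12.0
            )


class TestProfileValidation:
    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValueError, match="opening_amplitude"):
            GroupProfile(group_label="CG", opening_amplitude=-1.0)

    def test_noise_inside_passband_rejected(self):
        with pytest.raises(ValueError, match="sensor_noise_freq"):
            GroupProfile(group_label="CG", sensor_noise_freq=5.0)

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError, match="group label"):
            GroupProfile(group_label="XX")


class TestGenerateCohort:
    def test_study_layout_counts(self):
        spec = CohortSpec(n_per_group=(20, 10, 10), seed=1)
        sessions, labels, truth = generate_cohort(
            spec, noise_free(default_profiles())
        )
        assert len(labels) == 40
        assert len(sessions) == 160
        assert len(truth) == 40
        assert labels.value_counts().to_dict() == {"CG": 20, "MG": 10, "AG": 10}

    def test_minimal_cohort(self):
        spec = CohortSpec(n_per_group=(1, 0, 0), seed=1)
        sessions, labels, _ = generate_cohort(spec, noise_free(default_profiles()))
        assert len(labels) == 1
        assert len(sessions) == 4
        assert set(labels) == {"CG"}

    def test_seed_isolation(self):
        profiles = default_profiles(sensor_noise_sd=0.2)
        a, _, _ = generate_cohort(CohortSpec(n_per_group=(1, 1, 1), seed=5), profiles)
        b, _, _ = generate_cohort(CohortSpec(n_per_group=(1, 1, 1), seed=6), profiles)
        assert len(a) == len(b)
        assert a[0].primary.positions.shape == b[0].primary.positions.shape
        assert not np.array_equal(a[0].primary.positions, b[0].primary.positions)

    def test_cohort_deterministic_under_seed(self):
        spec = CohortSpec(n_per_group=(2, 1, 1), seed=9)
        profiles = default_profiles(sensor_noise_sd=0.2)
        a, _, ta = generate_cohort(spec, profiles)
        b, _, tb = generate_cohort(spec, profiles)
        pd.testing.assert_frame_equal(ta, tb)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.primary.positions, sb.primary.positions)

    def test_missing_profile_rejected(self):
        profiles = {"CG": default_profiles()["CG"]}
        with pytest.raises(ValueError, match="missing profile"):
            generate_cohort(CohortSpec(n_per_group=(1, 1, 0), seed=0), profiles)


class TestFeatureRecovery:
    def test_noise_free_cohort_matches_truth_exactly(self, noise_free_cohort):
        sessions, _, truth = noise_free_cohort
        table = extract_all(sessions, filter_enabled=False)
        err = (table[list(FEATURE_NAMES)] - truth[list(FEATURE_NAMES)]).abs()
        assert err.max().max() < 1e-6

    def test_full_pipeline_recovery_with_band_pass(self, noise_free_cohort):
        # the 0.01 Hz high-pass side sags a finite record's baseline by a few
        # tenths of a mm; rebased features stay within 0.75 mm of truth
        sessions, _, truth = noise_free_cohort
        table = extract_all(sessions)
        err = (table[list(FEATURE_NAMES)] - truth[list(FEATURE_NAMES)]).abs()
        assert err.max().max() < 0.75

    def test_out_of_band_noise_filtered_out(self, clean_profile):
        profile = dataclasses.replace(
            clean_profile, sensor_noise_sd=0.5, sensor_noise_freq=25.0
        )
        targets = truth_features(profile)
        for movement, amplitude_feature in [
            ("OC", "OCY"), ("LL", "LLX"), ("LR", "LRX"), ("P", "PZ"),
        ]:
            feats = extract_one(profile, movement, seed=13)
            assert feats[amplitude_feature] == pytest.approx(
                targets[amplitude_feature], abs=0.5
            )

    def test_truth_table_mirrors_profile_targets(self):
        profiles = noise_free(study_profiles(separation=2.0))
        _, _, truth = generate_cohort(
            CohortSpec(n_per_group=(1, 1, 1), seed=0), profiles
        )
        for group, profile in profiles.items():
            row = truth[truth["group"] == group].iloc[0]
            for name, value in truth_features(profile).items():
                assert row[name] == pytest.approx(value, abs=1e-12)
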