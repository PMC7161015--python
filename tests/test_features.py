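"""Feature definitions against brute-force maxima over constructed curves."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from jawtmd import Movement, Segment, aggregate, extract_all, movement_features
from jawtmd.features import FEATURE_NAMES

FS = 100.0


def oc_segment(x, y, z, split=None):
    pos = np.column_stack([x, y, z])
    pos = pos - pos[0]
    if split is None:
        split = int(np.argmin(pos[:, 1]))
    return Segment(Movement.OC, pos, FS, phase_split_index=split)


def simple_segment(movement, x, y, z):
    pos = np.column_stack([x, y, z])
    return Segment(movement, pos - pos[0], FS)


class TestOpenClose:
    def test_axis_pure_opening(self):
        # y: 0 -> -40 -> 0, x and z silent
        n = 201
        y = -40.0 * np.sin(np.pi * np.arange(n) / (n - 1))
        seg = oc_segment(np.zeros(n), y, np.zeros(n))
        f = movement_features(seg)
        assert f["OCY"] == pytest.approx(40.0)
        for name in ("ODX", "CDX", "OCX", "OCZ", "ODY", "CDY"):
            assert f[name] == pytest.approx(0.0, abs=1e-12)

    def test_parametric_curve_against_brute_force(self):
        # open phase: x = 2 sin(pi p), y = -40 p for p 0..1; symmetric close
        p = np.linspace(0.0, 1.0, 2001)
        x_open, y_open = 2.0 * np.sin(np.pi * p), -40.0 * p
        x = np.concatenate([x_open, x_open[::-1][1:]])
        y = np.concatenate([y_open, y_open[::-1][1:]])
        seg = oc_segment(x, y, np.zeros_like(x))
        f = movement_features(seg)
        # brute-force maxima over the dense grid
        split = seg.phase_split_index
        assert f["ODX"] == pytest.approx(np.abs(x[: split + 1]).max(), abs=1e-12)
        assert f["ODX"] == pytest.approx(2.0, abs=1e-6)
        assert f["CDX"] == pytest.approx(2.0, abs=1e-6)
        assert f["OCX"] == pytest.approx(4.0, abs=1e-6)
        assert f["ODY"] == pytest.approx(20.0, abs=1e-2)
        assert f["CDY"] == pytest.approx(20.0, abs=1e-2)
        assert f["OCY"] == pytest.approx(40.0, abs=1e-9)

    def test_close_deviation_measured_from_split(self):
        # open path straight down at x=0; close path returns shifted in x
        y = np.concatenate([np.linspace(0, -30, 100), np.linspace(-30, 0, 100)[1:]])
        x = np.concatenate([np.zeros(100), 3 * np.sin(np.pi * np.linspace(0, 1, 100))[1:]])
        seg = oc_segment(x, y, np.zeros_like(x))
        f = movement_features(seg)
        assert f["ODX"] == pytest.approx(0.0, abs=1e-12)
        assert f["CDX"] == pytest.approx(3.0, abs=1e-3)

    def test_chord_reference_ignores_straight_drift(self):
        # a perfectly straight but slanted opening has zero chord deviation
        n = 101
        y = np.linspace(0.0, -40.0, n)
        x = np.linspace(0.0, 5.0, n)  # linear drift
        x_full = np.concatenate([x, x[::-1][1:]])
        y_full = np.concatenate([y, y[::-1][1:]])
        seg = oc_segment(x_full, y_full, np.zeros_like(x_full))
        start_axis = movement_features(seg, deviation_reference="start_axis")
        chord = movement_features(seg, deviation_reference="chord")
        assert start_axis["ODX"] == pytest.approx(5.0, abs=1e-9)
        assert chord["ODX"] == pytest.approx(0.0, abs=1e-9)


class TestLateralAndProtrusion:
    def test_protrusion_worked_example(self):
        # z goes 0 -> 8 and back; x peaks 1.5 where z = 5, y peaks 2 where z = 3
        z_out = np.linspace(0.0, 8.0, 801)
        z = np.concatenate([z_out, z_out[::-1][1:]])
        x = 1.5 * np.exp(-(((z_out - 5.0) / 0.8) ** 2))
        y = 2.0 * np.exp(-(((z_out - 3.0) / 0.8) ** 2))
        x = np.concatenate([x, np.zeros(800)])
        y = np.concatenate([y, np.zeros(800)])
        f = movement_features(simple_segment(Movement.P, x, y, z))
        assert f["PZ"] == pytest.approx(8.0)
        assert f["PX"] == pytest.approx(1.5, abs=1e-5)
        assert f["PY"] == pytest.approx(2.0, abs=1e-5)
        assert f["PDX"] == pytest.approx(5.0, abs=1e-2)
        assert f["PDZ"] == pytest.approx(3.0, abs=1e-2)

    def test_lateral_left_right_directionality(self):
        n = 201
        out = np.sin(np.pi * np.arange(n) / (n - 1))
        f_ll = movement_features(
            simple_segment(Movement.LL, 10 * out, 2 * out, np.zeros(n))
        )
        assert f_ll["LLX"] == pytest.approx(10.0)
        assert f_ll["LLY"] == pytest.approx(2.0)
        f_lr = movement_features(
            simple_segment(Movement.LR, -12 * out, 2 * out, np.zeros(n))
        )
        assert f_lr["LRX"] == pytest.approx(12.0)

    def test_mirror_symmetry_swaps_lateralities(self):
        n = 201
        out = np.sin(np.pi * np.arange(n) / (n - 1))
        ll = simple_segment(Movement.LL, 10 * out, 2 * out, out)
        # reflecting x turns a leftward excursion into a rightward one
        lr = simple_segment(Movement.LR, -10 * out, 2 * out, out)
        f_ll, f_lr = movement_features(ll), movement_features(lr)
        assert f_ll["LLX"] == pytest.approx(f_lr["LRX"])
        assert f_ll["LLY"] == pytest.approx(f_lr["LRY"])
        assert f_ll["LLZ"] == pytest.approx(f_lr["LRZ"])

    def test_degenerate_segment_rejected(self):
        seg = simple_segment(Movement.LL, np.zeros(2), np.zeros(2), np.zeros(2))
        with pytest.raises(ValueError, match="degenerate segment"):
            movement_features(seg)


class TestInvariants:
    @given(
        scale=st.floats(0.1, 10.0),
        shift=st.tuples(
            st.floats(-50, 50), st.floats(-50, 50), st.floats(-50, 50)
        ),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_scaling_and_translation(self, scale, shift):
        """Features scale linearly with the motion and ignore constant offsets."""
        rng = np.random.default_rng(7)
        n = 301
        p = np.linspace(0.0, 2.0, n)  # out-and-back progress
        x = 3 * np.sin(np.pi * p) + 0.3 * rng.normal(size=n).cumsum() / 50
        y = -35 * np.sin(np.pi * p / 2) ** 2
        z = 2 * np.sin(np.pi * p)
        base = oc_segment(x, y, z)
        f0 = movement_features(base)
        pos = base.positions * scale + np.asarray(shift)
        pos = pos - pos[0]  # segments arrive rebased by construction
        scaled = Segment(Movement.OC, pos, FS, phase_split_index=base.phase_split_index)
        f1 = movement_features(scaled)
        for name, value in f0.items():
            assert f1[name] == pytest.approx(scale * value, rel=1e-9, abs=1e-9)

    def test_ocx_identity_on_every_extraction(self, separated_table):
        assert np.allclose(
            separated_table["OCX"],
            separated_table["ODX"] + separated_table["CDX"],
            atol=1e-9,
        )


class TestAggregate:
    def test_mean_of_two(self):
        reps = [full_rep(OCY=40.0), full_rep(OCY=42.0)]
        assert aggregate(reps)["OCY"] == pytest.approx(41.0)

    def test_single_repetition_identity(self):
        rep = full_rep(OCY=38.5, PDZ=2.5)
        assert aggregate([rep]) == pytest.approx(rep)

    def test_mean_preserves_ocx_identity(self):
        reps = [
            full_rep(ODX=1.0, CDX=2.0, OCX=3.0),
            full_rep(ODX=2.0, CDX=2.0, OCX=4.0),
            full_rep(ODX=3.0, CDX=2.0, OCX=5.0),
        ]
        out = aggregate(reps)
        assert out["OCX"] == pytest.approx(4.0)
        assert out["OCX"] == pytest.approx(out["ODX"] + out["CDX"], abs=1e-12)

    def test_max_reducer(self):
        reps = [full_rep(OCY=40.0), full_rep(OCY=42.0)]
        assert aggregate(reps, reducer="max")["OCY"] == pytest.approx(42.0)

    def test_missing_movement_listed(self):
        reps = [full_rep()]
        incomplete = [{k: v for k, v in reps[0].items() if not k.startswith("P")}]
        with pytest.raises(ValueError, match="missing movement.*P"):
            aggregate(incomplete)


def full_rep(**overrides):
    rep = {name: 1.0 for name in FEATURE_NAMES}
    rep["OCX"] = rep["ODX"] + rep["CDX"]
    rep.update(overrides)
    return rep


class TestExtractAll:
    def test_missing_task_names_subject(self, noise_free_cohort):
        sessions, _, _ = noise_free_cohort
        partial = [
            s for s in sessions
            if not (s.subject_id == "CG01" and s.movement is Movement.P)
        ]
        with pytest.raises(ValueError, match="subject CG01: missing movement P"):
            extract_all(partial)

    def test_table_shape_and_order(self, separated_table):
        assert separated_table.shape == (40, 19)
        assert list(separated_table.columns) == ["group", *FEATURE_NAMES]
        assert (separated_table[list(FEATURE_NAMES)] >= 0).all().all()
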