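"""Synthetic jaw-movement cohorts with known kinematic signatures.

The study population this emulates (40 subjects: 20 controls, 10 myopathy,
10 arthropathy; four tasks, six repetitions each, 100 Hz) is private, so the
generator produces trajectories whose extracted features follow configurable
group-specific targets — every downstream stage can then be tested against
analytic ground truth.

Kinematic template
------------------
Each repetition is an out-and-back path of duration ``cycle_duration``; with
task progress ``p`` running 0→1 (out) and 1→2 (back):

* primary axis displacement  ``A · sin²(πp/2)``  — smooth, zero velocity at
  the endpoints, extremum ``A`` at mid-task, and exactly ``A/2`` at the
  deviation maxima below;
* deviation/coupling axes    ``D · sin(πp)``     — maximal ``|D|`` at
  p = 0.5 and 1.5.

This makes every feature analytically predictable: OCY = A, ODX = CDX = D,
OCX = 2D, ODY = CDY = A/2, PDX = PDZ = PZ/2, and range-type z features equal
twice the coupling amplitude. Repetitions are separated by 0.5 s of
stationary rest so segmentation sees realistic input. Sensor noise is a
random-phase sinusoid at ``sensor_noise_freq`` (above the 8 Hz band-pass
cut-off) with standard deviation ``sensor_noise_sd``; an optional constant
head offset (plus linear drift) is added to both markers so head
compensation is exercised.

The default group presets are **illustrative** plausible clinic-scale values;
no group-level feature means were ever published for the real cohort.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES
from .trajectory import GROUPS, MarkerTrajectory, Movement, RecordingSession

__all__ = [
    "GroupProfile",
    "CohortSpec",
    "default_profiles",
    "study_profiles",
    "truth_features",
    "draw_subject_profile",
    "generate_trajectory",
    "generate_cohort",
]

#: stationary rest inserted before, between and after repetitions (s)
REST_S = 0.5
#: band-pass upper cut-off the noise must sit above (Hz)
_BAND_UPPER_HZ = 8.0


@dataclass(frozen=True)
class GroupProfile:
    """Target kinematics of one diagnostic group (all lengths in mm).

    The amplitude fields are the group means of the corresponding features;
    ``between_subject_sd`` is the SD of the truncated-Gaussian perturbation
    applied per subject to every amplitude field.
    """

    group_label: str
    opening_amplitude: float = 45.0  # target OCY
    opening_deviation: float = 1.0  # target ODX = CDX (OCX = 2x this)
    lateral_amplitude_left: float = 10.0  # target LLX
    lateral_amplitude_right: float = 10.0  # target LRX
    protrusion_amplitude: float = 8.0  # target PZ
    vertical_lateral_coupling: float = 2.0  # target LLY = LRY
    sagittal_coupling: float = 1.5  # targets OCZ/LLZ/LRZ (= 2x) and PX/PY
    between_subject_sd: float = 1.0
    cycle_duration: float = 2.0  # s
    sensor_noise_sd: float = 0.0  # mm
    sensor_noise_freq: float = 25.0  # Hz

    def __post_init__(self) -> None:
        if self.group_label not in GROUPS:
            raise ValueError(f"unknown group label: {self.group_label!r}")
        for name in (
            "opening_amplitude", "opening_deviation", "lateral_amplitude_left",
            "lateral_amplitude_right", "protrusion_amplitude",
            "vertical_lateral_coupling", "sagittal_coupling",
            "between_subject_sd", "sensor_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.cycle_duration <= 0:
            raise ValueError("cycle_duration must be > 0")
        if self.sensor_noise_freq <= _BAND_UPPER_HZ:
            raise ValueError(
                "sensor_noise_freq must exceed the band-pass upper cut-off "
                f"({_BAND_UPPER_HZ} Hz)"
            )


@dataclass(frozen=True)
class CohortSpec:
    """Cohort layout: group sizes, repetitions per task, frame rate, seed."""

    n_per_group: tuple[int, int, int] = (20, 10, 10)  # (CG, MG, AG)
    repetitions_per_task: int = 6
    frame_rate: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.n_per_group) or sum(self.n_per_group) < 1:
            raise ValueError("group counts must be >= 0 with at least one subject")
        if self.repetitions_per_task < 1:
            raise ValueError("repetitions_per_task must be >= 1")
        if self.frame_rate <= 2 * _BAND_UPPER_HZ:
            raise ValueError(
                f"frame_rate must exceed twice the band-pass upper cut-off "
                f"({2 * _BAND_UPPER_HZ} Hz)"
            )


# illustrative presets: controls with full range of motion; myopathy with
# restricted opening; arthropathy with marked opening deviation and
# left/right asymmetry. NOT published values.
_PRESETS = dict(
    CG=dict(opening_amplitude=45.0, opening_deviation=1.0,
            lateral_amplitude_left=10.0, lateral_amplitude_right=10.0,
            protrusion_amplitude=8.0, vertical_lateral_coupling=2.0,
            sagittal_coupling=1.5),
    MG=dict(opening_amplitude=32.0, opening_deviation=2.5,
            lateral_amplitude_left=8.0, lateral_amplitude_right=8.0,
            protrusion_amplitude=6.0, vertical_lateral_coupling=2.5,
            sagittal_coupling=2.0),
    AG=dict(opening_amplitude=38.0, opening_deviation=5.0,
            lateral_amplitude_left=6.0, lateral_amplitude_right=11.0,
            protrusion_amplitude=5.0, vertical_lateral_coupling=3.5,
            sagittal_coupling=2.5),
)


def default_profiles(
    between_subject_sd: float = 1.0, sensor_noise_sd: float = 0.15
) -> dict[str, GroupProfile]:
    """Illustrative per-group presets (clinic-plausible, not published values)."""
    return {
        g: GroupProfile(
            group_label=g,
            between_subject_sd=between_subject_sd,
            sensor_noise_sd=sensor_noise_sd,
            **_PRESETS[g],
        )
        for g in GROUPS
    }


def study_profiles(
    separation: float = 5.0,
    between_subject_sd: float = 1.0,
    sensor_noise_sd: float = 0.15,
) -> dict[str, GroupProfile]:
    """Profiles whose amplitude means differ by ``separation`` between-subject SDs.

    Built from a common baseline with per-group offsets of
    ``separation * between_subject_sd`` on the opening, deviation, lateral and
    protrusion amplitudes: ``separation=0`` yields three identical groups
    (chance-level classification), large values yield near-separable cohorts.
    """
    delta = separation * between_subject_sd
    base = dict(
        opening_amplitude=40.0, opening_deviation=2.0,
        lateral_amplitude_left=9.0, lateral_amplitude_right=9.0,
        protrusion_amplitude=7.0, vertical_lateral_coupling=2.0,
        sagittal_coupling=1.5,
    )
    # myopathy restricts range of motion across tasks; arthropathy shows
    # marked opening deviation, left/right asymmetry and irregular vertical
    # coupling — so each group pair differs on several feature families
    offsets = {
        "CG": {},
        "MG": {
            "opening_amplitude": -delta,
            "lateral_amplitude_left": -delta,
            "lateral_amplitude_right": -delta,
            "protrusion_amplitude": -delta,
        },
        "AG": {
            "opening_deviation": delta,
            "lateral_amplitude_right": delta,
            "vertical_lateral_coupling": delta,
        },
    }
    out = {}
    for g in GROUPS:
        params = dict(base)
        for key, off in offsets[g].items():
            params[key] = max(0.0, params[key] + off)
        out[g] = GroupProfile(
            group_label=g,
            between_subject_sd=between_subject_sd,
            sensor_noise_sd=sensor_noise_sd,
            **params,
        )
    return out


def truth_features(profile: GroupProfile) -> dict[str, float]:
    """Analytic feature values the extraction pipeline recovers (noise-free)."""
    a = profile.opening_amplitude
    d = profile.opening_deviation
    s = profile.sagittal_coupling
    v = profile.vertical_lateral_coupling
    p = profile.protrusion_amplitude
    return {
        "OCX": 2 * d, "OCY": a, "OCZ": 2 * s,
        "ODX": d, "ODY": a / 2 if d > 0 else 0.0,
        "CDX": d, "CDY": a / 2 if d > 0 else 0.0,
        "LLX": profile.lateral_amplitude_left, "LLY": v, "LLZ": 2 * s,
        "LRX": profile.lateral_amplitude_right, "LRY": v, "LRZ": 2 * s,
        "PX": s, "PY": s, "PZ": p,
        "PDX": p / 2 if s > 0 else 0.0, "PDZ": p / 2 if s > 0 else 0.0,
    }


def draw_subject_profile(
    profile: GroupProfile, rng: np.random.Generator
) -> GroupProfile:
    """Perturb each amplitude by N(0, between_subject_sd), truncated at 0.

    The four primary task amplitudes (opening, both lateralities, protrusion)
    are floored at 0.5 mm instead: a live subject's active range of motion is
    strictly positive, and a task with no primary excursion at all has no
    repetitions to segment. The opening deviation and sagittal coupling are
    floored at 0.3 mm: the *position* of their maxima defines ODY/CDY and
    PDX/PDZ, which degenerate to noise when the underlying excursion
    vanishes — and no real incisor path is perfectly planar. Returns a
    subject-level profile with ``between_subject_sd`` reset to 0; its
    :func:`truth_features` are the subject's ground-truth feature vector.
    """
    sd = profile.between_subject_sd
    floors = {
        "opening_amplitude": 0.5, "opening_deviation": 0.3,
        "lateral_amplitude_left": 0.5, "lateral_amplitude_right": 0.5,
        "protrusion_amplitude": 0.5, "vertical_lateral_coupling": 0.0,
        "sagittal_coupling": 0.3,
    }
    # draw in fixed field order for reproducibility
    updates = {
        name: max(floor, getattr(profile, name) + rng.normal(0.0, sd)) if sd > 0
        else getattr(profile, name)
        for name, floor in floors.items()
    }
    return dataclasses.replace(profile, between_subject_sd=0.0, **updates)


def _cycle_displacements(profile: GroupProfile, movement: Movement, p: np.ndarray):
    """(x, y, z) displacement of one cycle given task progress p in [0, 2]."""
    out = np.sin(np.pi * p / 2.0) ** 2
    dev = np.sin(np.pi * p)
    x = np.zeros_like(p)
    y = np.zeros_like(p)
    z = np.zeros_like(p)
    if movement is Movement.OC:
        y = -profile.opening_amplitude * out
        x = profile.opening_deviation * dev
        z = profile.sagittal_coupling * dev
    elif movement is Movement.LL:
        x = profile.lateral_amplitude_left * out
        y = profile.vertical_lateral_coupling * dev
        z = profile.sagittal_coupling * dev
    elif movement is Movement.LR:
        x = -profile.lateral_amplitude_right * out
        y = profile.vertical_lateral_coupling * dev
        z = profile.sagittal_coupling * dev
    elif movement is Movement.P:
        z = profile.protrusion_amplitude * out
        x = profile.sagittal_coupling * dev
        y = profile.sagittal_coupling * dev
    return x, y, z


def generate_trajectory(
    profile: GroupProfile,
    movement: Movement | str,
    rng: np.random.Generator,
    repetitions: int = 6,
    frame_rate: float = 100.0,
    subject_id: str = "S000",
    head_offset: np.ndarray | None = None,
    head_drift: np.ndarray | None = None,
) -> RecordingSession:
    """Simulate one recording session: rest–cycle–rest … with noise and offset.

    The primary marker carries the task displacement plus sensor noise plus
    the head offset (and optional linear drift, mm/s); the head marker carries
    the offset/drift alone, so head compensation recovers the displacement.
    """
    movement = Movement.coerce(movement)
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    if frame_rate <= 2 * _BAND_UPPER_HZ:
        raise ValueError(
            f"frame_rate must exceed {2 * _BAND_UPPER_HZ} Hz for the band-pass"
        )

    fs = frame_rate
    n_rest = int(round(REST_S * fs))
    n_cycle = int(round(profile.cycle_duration * fs))
    pieces = [np.zeros((n_rest, 3))]
    p = np.arange(n_cycle + 1) * (2.0 / n_cycle)  # progress 0..2 inclusive
    cycle = np.column_stack(_cycle_displacements(profile, movement, p))
    for _ in range(repetitions):
        pieces.append(cycle)
        pieces.append(np.zeros((n_rest, 3)))
    disp = np.vstack(pieces)
    n = disp.shape[0]
    t = np.arange(n) / fs

    if profile.sensor_noise_sd > 0:
        # narrow-band jitter at the sensor frequency, random phase per axis;
        # amplitude sqrt(2)*sd gives the requested standard deviation
        phases = rng.uniform(0.0, 2.0 * np.pi, size=3)
        noise = (
            np.sqrt(2.0) * profile.sensor_noise_sd
            * np.sin(2.0 * np.pi * profile.sensor_noise_freq * t[:, None] + phases)
        )
        disp = disp + noise

    offset = np.zeros((n, 3))
    if head_offset is not None:
        offset += np.asarray(head_offset, dtype=float)
    if head_drift is not None:
        offset += t[:, None] * np.asarray(head_drift, dtype=float)

    primary = MarkerTrajectory("primary", fs, disp + offset)
    head = MarkerTrajectory("head", fs, offset)
    return RecordingSession(
        subject_id=subject_id,
        movement=movement,
        primary=primary,
        head_reference=head,
        group_label=profile.group_label,
    )


def generate_cohort(
    spec: CohortSpec, profiles: dict[str, GroupProfile]
) -> tuple[list[RecordingSession], pd.Series, pd.DataFrame]:
    """Generate a full cohort: sessions, labels, and ground-truth features.

    Returns ``(sessions, labels, truth_table)``: one session per subject x
    movement (4 per subject), a label Series indexed by subject_id in fixed
    subject order, and the analytic noise-free feature table per subject.
    """
    missing = [g for g, n in zip(GROUPS, spec.n_per_group) if n > 0 and g not in profiles]
    if missing:
        raise ValueError(f"missing profile for group(s): {', '.join(missing)}")

    sessions: list[RecordingSession] = []
    labels: dict[str, str] = {}
    truth_rows: list[dict[str, float]] = []
    subject_index = 0
    for group, n in zip(GROUPS, spec.n_per_group):
        for i in range(n):
            subject_id = f"{group}{i + 1:02d}"
            rng = np.random.default_rng(
                np.random.SeedSequence([int(spec.seed), subject_index])
            )
            subj_profile = draw_subject_profile(profiles[group], rng)
            head_offset = rng.uniform(-30.0, 30.0, size=3)
            for movement in Movement:
                sessions.append(
                    generate_trajectory(
                        subj_profile,
                        movement,
                        rng,
                        repetitions=spec.repetitions_per_task,
                        frame_rate=spec.frame_rate,
                        subject_id=subject_id,
                        head_offset=head_offset,
                    )
                )
            labels[subject_id] = group
            truth_rows.append({"group": group, **truth_features(subj_profile)})
            subject_index += 1

    index = pd.Index(list(labels), name="subject_id")
    truth = pd.DataFrame(truth_rows, index=index).loc[:, ["group", *FEATURE_NAMES]]
    return sessions, pd.Series(labels, name="group"), truth
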