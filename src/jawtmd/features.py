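"""The 18 biomechanical jaw-movement features.

All features are maximum displacements in millimetres, measured per repetition
segment and averaged over the six repetitions of each task:

========  =============================================================
feature   meaning
========  =============================================================
OCY       maximum mouth opening (vertical, y)
ODX/CDX   maximum lateral (x) deviation of the opening / closing path
ODY/CDY   vertical distance from the phase start to where ODX / CDX occurs
OCX       ODX + CDX
OCZ       anteroposterior (z) extent of the opening/closing path
LLX/LRX   maximum lateral excursion to the left / right
LLY/LRY   maximum vertical displacement during the lateral excursions
LLZ/LRZ   anteroposterior extent of the lateral excursions
PZ        maximum protrusion (anterior, z)
PX/PY     maximum lateral / vertical displacement during protrusion
PDX/PDZ   protrusive (z) distance from the start to where PX / PY occurs
========  =============================================================

Deviations are measured relative to the phase's starting position
(``deviation_reference="start_axis"``: a vertical reference line through the
phase start) or, optionally, relative to the straight chord between the phase
endpoints (``"chord"``).
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .preprocess import Segment, preprocess_session
from .trajectory import GROUPS, Movement, RecordingSession

__all__ = [
    "FEATURE_NAMES",
    "MOVEMENT_FEATURES",
    "movement_features",
    "aggregate",
    "extract_all",
    "validate_feature_table",
]

#: canonical feature order (open/close, lateral left, lateral right, protrusion)
FEATURE_NAMES = (
    "OCX", "OCY", "OCZ", "ODX", "ODY", "CDX", "CDY",
    "LLX", "LLY", "LLZ",
    "LRX", "LRY", "LRZ",
    "PX", "PY", "PZ", "PDX", "PDZ",
)

#: which features each movement contributes
MOVEMENT_FEATURES: Mapping[Movement, tuple[str, ...]] = {
    Movement.OC: ("OCX", "OCY", "OCZ", "ODX", "ODY", "CDX", "CDY"),
    Movement.LL: ("LLX", "LLY", "LLZ"),
    Movement.LR: ("LRX", "LRY", "LRZ"),
    Movement.P: ("PX", "PY", "PZ", "PDX", "PDZ"),
}


def _phase_deviation(x: np.ndarray, reference: str) -> np.ndarray:
    """Signed x-deviation of one phase from its reference line.

    ``start_axis``: deviation from a vertical line through the phase start.
    ``chord``: deviation from the straight line joining the phase endpoints,
    parameterised by sample index.
    """
    if reference == "start_axis":
        return x - x[0]
    if reference == "chord":
        return x - np.linspace(x[0], x[-1], len(x))
    raise ValueError(f"unknown deviation_reference: {reference!r}")


def movement_features(
    segment: Segment, deviation_reference: str = "start_axis"
) -> dict[str, float]:
    """Compute the features contributed by one repetition segment.

    The segment must be rebased at the origin; OC segments must carry the
    open/close phase split. Returns only the features of the segment's
    movement (e.g. 7 values for OC).
    """
    if segment.n_frames < 3:
        raise ValueError(
            f"degenerate segment: {segment.n_frames} frames (need >= 3)"
        )
    x, y, z = (segment.positions[:, i] for i in range(3))
    out: dict[str, float] = {}

    if segment.movement is Movement.OC:
        k = segment.phase_split_index
        dev_open = _phase_deviation(x[: k + 1], deviation_reference)
        i_od = int(np.argmax(np.abs(dev_open)))
        odx = float(np.abs(dev_open[i_od]))
        ody = float(np.abs(y[i_od] - y[0]))
        dev_close = _phase_deviation(x[k:], deviation_reference)
        i_cd = int(np.argmax(np.abs(dev_close)))
        cdx = float(np.abs(dev_close[i_cd]))
        cdy = float(np.abs(y[k + i_cd] - y[k]))
        out.update(
            ODX=odx, ODY=ody, CDX=cdx, CDY=cdy,
            OCX=odx + cdx,
            OCY=float(np.max(np.abs(y))),
            OCZ=float(z.max() - z.min()),
        )
    elif segment.movement is Movement.LL:
        out.update(
            LLX=float(x.max()),
            LLY=float(np.max(np.abs(y))),
            LLZ=float(z.max() - z.min()),
        )
    elif segment.movement is Movement.LR:
        out.update(
            LRX=float((-x).max()),
            LRY=float(np.max(np.abs(y))),
            LRZ=float(z.max() - z.min()),
        )
    elif segment.movement is Movement.P:
        i_px = int(np.argmax(np.abs(x)))
        i_py = int(np.argmax(np.abs(y)))
        out.update(
            PX=float(np.abs(x[i_px])),
            PY=float(np.abs(y[i_py])),
            PZ=float(z.max()),
            PDX=float(np.abs(z[i_px])),
            PDZ=float(np.abs(z[i_py])),
        )
    else:  # pragma: no cover - Movement.coerce guards this
        raise ValueError(f"unknown movement: {segment.movement}")
    return out


def aggregate(
    per_repetition: Iterable[Mapping[str, float]], reducer: str = "mean"
) -> dict[str, float]:
    """Reduce per-repetition feature sets to one 18-feature vector.

    Each input mapping holds the features of one repetition of one movement;
    across the inputs every one of the 18 features must appear at least once
    (i.e. all four movements are represented). The reducer is the per-feature
    mean over repetitions (the feature averages stabilise at six repetitions)
    or, optionally, the max. OCX is recomputed from the reduced ODX and CDX so
    the identity OCX = ODX + CDX survives aggregation exactly.
    """
    if reducer not in ("mean", "max"):
        raise ValueError(f"unknown reducer: {reducer!r}")
    values: dict[str, list[float]] = defaultdict(list)
    for rep in per_repetition:
        for name, val in rep.items():
            values[name].append(float(val))
    missing_feats = [f for f in FEATURE_NAMES if f not in values]
    if missing_feats:
        absent = sorted(
            {m.value for m, feats in MOVEMENT_FEATURES.items()
             if any(f in missing_feats for f in feats)}
        )
        raise ValueError(f"missing movement(s): {', '.join(absent)}")
    reduce = np.mean if reducer == "mean" else np.max
    vec = {name: float(reduce(values[name])) for name in FEATURE_NAMES}
    vec["OCX"] = vec["ODX"] + vec["CDX"]
    return vec


def validate_feature_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate and canonicalise a per-subject feature table.

    Requires a ``group`` column with labels in {CG, MG, AG} and exactly the
    18 feature columns; returns a copy with columns in canonical order.
    """
    missing = [f for f in FEATURE_NAMES if f not in table.columns]
    if missing:
        raise ValueError(f"missing feature column: {', '.join(missing)}")
    dup = table.columns[table.columns.duplicated()].tolist()
    if dup:
        raise ValueError(f"duplicated column: {', '.join(map(str, dup))}")
    if "group" not in table.columns:
        raise ValueError("missing 'group' column")
    bad = set(table["group"]) - set(GROUPS)
    if bad:
        raise ValueError(f"unknown group label: {', '.join(map(str, sorted(bad)))}")
    vals = table.loc[:, list(FEATURE_NAMES)].to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("feature table contains non-finite values")
    if (vals < 0).any():
        raise ValueError("feature table contains negative values")
    return table.loc[:, ["group", *FEATURE_NAMES]].copy()


def extract_all(
    sessions: Iterable[RecordingSession],
    expected_reps: int = 6,
    low_hz: float = 0.01,
    high_hz: float = 8.0,
    poles: int = 4,
    deviation_reference: str = "start_axis",
    reducer: str = "mean",
    filter_enabled: bool = True,
    compensate_first: bool = True,
) -> pd.DataFrame:
    """Extract the 18-feature table for a cohort of sessions.

    Every subject must contribute all four movements. Returns a DataFrame
    indexed by subject_id with a ``group`` column (empty string when sessions
    carry no label) and the 18 features in canonical order.
    """
    by_subject: dict[str, list[RecordingSession]] = defaultdict(list)
    order: list[str] = []
    for s in sessions:
        if s.subject_id not in by_subject:
            order.append(s.subject_id)
        by_subject[s.subject_id].append(s)

    rows = []
    for subject_id in order:
        subj_sessions = by_subject[subject_id]
        have = {s.movement for s in subj_sessions}
        absent = [m.value for m in Movement if m not in have]
        if absent:
            raise ValueError(
                f"subject {subject_id}: missing movement {', '.join(absent)}"
            )
        reps: list[dict[str, float]] = []
        for s in subj_sessions:
            try:
                segments = preprocess_session(
                    s,
                    low_hz=low_hz,
                    high_hz=high_hz,
                    poles=poles,
                    expected=expected_reps,
                    filter_enabled=filter_enabled,
                    compensate_first=compensate_first,
                )
            except ValueError as err:
                raise type(err)(f"subject {subject_id} ({s.movement.value}): {err}")
            reps.extend(
                movement_features(seg, deviation_reference) for seg in segments
            )
        vec = aggregate(reps, reducer=reducer)
        groups = {s.group_label for s in subj_sessions if s.group_label}
        if len(groups) > 1:
            raise ValueError(f"subject {subject_id}: conflicting group labels")
        rows.append({"group": groups.pop() if groups else "", **vec})

    table = pd.DataFrame(rows, index=pd.Index(order, name="subject_id"))
    return table.loc[:, ["group", *FEATURE_NAMES]]
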