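"""CSV I/O for marker trajectories, session manifests and feature tables.

Trajectory files use a fixed dialect::

    # frame_rate_hz: 100
    # units: mm
    time_s,primary_x,primary_y,primary_z,head_x,head_y,head_z
    0.00,1.203,-0.004,0.881,5.0,5.0,5.0
    ...

A cohort is described by a manifest CSV with columns
``subject_id,group,movement,file`` (``file`` relative to the manifest's
directory). Feature tables are plain CSV with ``subject_id,group`` plus the
18 feature columns, normalised to canonical order on read and write.

Binary motion-capture formats (C3D/TRC) are a documented extension point,
not parsed here.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES, validate_feature_table
from .trajectory import MarkerTrajectory, Movement, RecordingSession

__all__ = [
    "read_session",
    "write_session",
    "read_manifest",
    "write_manifest",
    "read_feature_table",
    "write_feature_table",
]

_TRAJ_COLUMNS = (
    "time_s",
    "primary_x", "primary_y", "primary_z",
    "head_x", "head_y", "head_z",
)


def write_session(session: RecordingSession, path: str | Path) -> None:
    """Write one session in the trajectory CSV dialect."""
    path = Path(path)
    t = session.primary.times()
    data = np.column_stack(
        [t, session.primary.positions, session.head_reference.positions]
    )
    with path.open("w", newline="") as fh:
        fh.write(f"# frame_rate_hz: {session.primary.frame_rate:g}\n")
        fh.write("# units: mm\n")
        fh.write(",".join(_TRAJ_COLUMNS) + "\n")
        np.savetxt(fh, data, delimiter=",", fmt="%.9f")


def read_session(
    trajectory_file: str | Path, manifest_row: Mapping[str, str]
) -> RecordingSession:
    """Read one session from a trajectory CSV and its manifest row.

    The manifest row supplies ``subject_id``, ``movement`` and optionally
    ``group``; the frame rate comes from the file header. Malformed headers,
    non-monotone time, or any missing coordinate raise ``ValueError`` naming
    the offending row/column.
    """
    path = Path(trajectory_file)
    if not path.exists():
        raise FileNotFoundError(f"trajectory file not found: {path}")
    with path.open() as fh:
        text = fh.read()

    frame_rate = None
    lines = text.splitlines()
    body_start = 0
    for i, line in enumerate(lines):
        if not line.startswith("#"):
            body_start = i
            break
        key, _, value = line.lstrip("# ").partition(":")
        if key.strip() == "frame_rate_hz":
            try:
                frame_rate = float(value)
            except ValueError:
                raise ValueError(f"{path}: malformed frame_rate_hz header: {line!r}")
    if frame_rate is None or frame_rate <= 0:
        raise ValueError(f"{path}: missing or invalid '# frame_rate_hz:' header")

    df = pd.read_csv(_io.StringIO("\n".join(lines[body_start:])))
    missing_cols = [c for c in _TRAJ_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing column(s): {', '.join(missing_cols)}")
    for col in _TRAJ_COLUMNS:
        nan_rows = df.index[df[col].isna()]
        if len(nan_rows):
            raise ValueError(
                f"{path}: missing value in column '{col}' at data row {nan_rows[0]}"
            )
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) >= 2 and not np.all(np.diff(t) > 0):
        raise ValueError(f"{path}: time_s column is not strictly increasing")

    primary = MarkerTrajectory(
        "primary", frame_rate, df[["primary_x", "primary_y", "primary_z"]].to_numpy(float)
    )
    head = MarkerTrajectory(
        "head", frame_rate, df[["head_x", "head_y", "head_z"]].to_numpy(float)
    )
    group = manifest_row.get("group") or None
    return RecordingSession(
        subject_id=str(manifest_row["subject_id"]),
        movement=Movement.coerce(manifest_row["movement"]),
        primary=primary,
        head_reference=head,
        group_label=group,
    )


def write_manifest(rows: Iterable[Mapping[str, str]], path: str | Path) -> None:
    pd.DataFrame(list(rows), columns=["subject_id", "group", "movement", "file"]).to_csv(
        path, index=False
    )


def read_manifest(path: str | Path) -> list[RecordingSession]:
    """Read every session listed in a manifest CSV (paths relative to it)."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str).fillna("")
    required = {"subject_id", "group", "movement", "file"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: manifest missing column(s): {', '.join(sorted(missing))}")
    return [
        read_session(path.parent / row["file"], row) for _, row in df.iterrows()
    ]


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a feature table CSV in canonical column order."""
    out = table.loc[:, ["group", *FEATURE_NAMES]].copy()
    out.index.name = "subject_id"
    out.to_csv(path, float_format="%.9f")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a per-subject feature table CSV.

    The header must contain each of the 18 feature names exactly once and a
    ``group`` column; output columns are normalised to canonical order.
    """
    df = pd.read_csv(path, index_col="subject_id")
    return validate_feature_table(df)
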