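"""Core containers for jaw motion-capture recordings.

Coordinate convention (used throughout the package):

* ``x`` — subject's left (+) lateral axis,
* ``y`` — superior (+) vertical axis; mouth opening moves toward −y,
* ``z`` — anterior (+) axis; protrusion moves toward +z.

The frontal view is the x–y plane (opening/closing and lateral excursions),
the sagittal view the y–z plane (protrusion). All positions are millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "Movement",
    "MarkerTrajectory",
    "RecordingSession",
    "GROUPS",
    "CLASS_ORDER",
]

#: Valid diagnostic group labels: control, myopathy, arthropathy.
GROUPS = ("CG", "MG", "AG")

#: Fixed class order used for every confusion matrix in the package.
CLASS_ORDER = ("AG", "MG", "CG")


class Movement(str, Enum):
    """The four jaw tasks recorded per subject."""

    OC = "OC"  #: mouth opening/closing (elevation/depression)
    LL = "LL"  #: lateral excursion to the subject's left
    LR = "LR"  #: lateral excursion to the subject's right
    P = "P"  #: protrusion/retraction

    @classmethod
    def coerce(cls, value: "Movement | str") -> "Movement":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).upper())
        except ValueError:
            raise ValueError(
                f"unknown movement type: {value!r} (expected one of "
                f"{[m.value for m in cls]})"
            ) from None

    #: signed unit direction of the task's primary axis (progress is positive
    #: along this direction): OC opens toward −y, LL toward +x, LR toward −x,
    #: P toward +z.
    @property
    def primary_axis(self) -> int:
        return {"OC": 1, "LL": 0, "LR": 0, "P": 2}[self.value]

    @property
    def primary_sign(self) -> float:
        return {"OC": -1.0, "LL": 1.0, "LR": -1.0, "P": 1.0}[self.value]


@dataclass
class MarkerTrajectory:
    """Time series of 3D positions (mm) of one marker at a fixed frame rate."""

    marker_id: str
    frame_rate: float
    positions: np.ndarray  # shape (n_frames, 3), mm

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError(
                f"positions must have shape (n, 3), got {self.positions.shape}"
            )
        if self.n_frames < 2:
            raise ValueError("a trajectory needs at least 2 frames")
        if not self.frame_rate > 0:
            raise ValueError(f"frame_rate must be positive, got {self.frame_rate}")
        if not np.all(np.isfinite(self.positions)):
            bad = np.argwhere(~np.isfinite(self.positions))[0]
            raise ValueError(
                f"non-finite coordinate at frame {bad[0]}, axis {'xyz'[bad[1]]}"
            )

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return (self.n_frames - 1) / self.frame_rate

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate

    def with_positions(self, positions: np.ndarray) -> "MarkerTrajectory":
        return MarkerTrajectory(self.marker_id, self.frame_rate, positions)


@dataclass
class RecordingSession:
    """One subject performing one jaw task.

    Holds the mandible (primary) marker trajectory and the forehead
    head-reference trajectory used to subtract rigid head translation.
    """

    subject_id: str
    movement: Movement
    primary: MarkerTrajectory
    head_reference: MarkerTrajectory
    group_label: str | None = field(default=None)

    def __post_init__(self) -> None:
        self.movement = Movement.coerce(self.movement)
        if self.group_label is not None and self.group_label not in GROUPS:
            raise ValueError(
                f"unknown group label: {self.group_label!r} (expected one of {GROUPS})"
            )
        if self.primary.frame_rate != self.head_reference.frame_rate:
            raise ValueError("primary and head markers must share a frame rate")
        if self.primary.n_frames != self.head_reference.n_frames:
            raise ValueError(
                "frame count mismatch between primary "
                f"({self.primary.n_frames}) and head ({self.head_reference.n_frames}) markers"
            )
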