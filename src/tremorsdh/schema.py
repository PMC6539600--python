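"""Channel schema and core containers for leap-motion hand captures.

A capture is a fixed-rate stream of 40-scalar samples: position and velocity
triplets (x, y, z) for the five fingertips and the palm centre — 36 channels —
plus the four components of the hand-rotation quaternion. Positions are in mm,
velocities in mm/s, in the sensor's coordinate frame with x the lateral axis
(the direction of the push task). One sample is one row of the recording's
DataFrame; the schema fixes the channel names and their canonical order.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

PARTS: tuple[str, ...] = ("thumb", "index", "middle", "ring", "little", "palm")
AXES: tuple[str, ...] = ("x", "y", "z")
HANDS: tuple[str, ...] = ("left", "right")

POSITION_CHANNELS: tuple[str, ...] = tuple(
    f"{part}_pos_{axis}" for part in PARTS for axis in AXES
)
VELOCITY_CHANNELS: tuple[str, ...] = tuple(
    f"{part}_vel_{axis}" for part in PARTS for axis in AXES
)
QUATERNION_CHANNELS: tuple[str, ...] = tuple(
    f"hand_rot_{axis}" for axis in ("x", "y", "z", "w")
)

#: Canonical order of the 40 capture channels.
CHANNELS: tuple[str, ...] = POSITION_CHANNELS + VELOCITY_CHANNELS + QUATERNION_CHANNELS

#: Palm-centre x position — the single channel the final pipeline analyses.
PALM_X: str = "palm_pos_x"


def palm_position_channels(axes: str | Sequence[str] = "xyz") -> list[str]:
    """Channel names for the palm-centre position coordinates.

    ``axes`` may be a string like ``"x"`` or ``"xyz"`` or a sequence of axis
    letters; channels are returned in the requested order.
    """
    bad = [a for a in axes if a not in AXES]
    if bad:
        raise KeyError(f"unknown axes {bad!r}; expected letters from {AXES}")
    return [f"palm_pos_{a}" for a in axes]


@dataclasses.dataclass
class Recording:
    """One hand's capture: metadata plus the 40-channel sample matrix.

    ``data`` holds one row per sample in the :data:`CHANNELS` order; columns
    are reordered by name on construction so channel identity never depends
    on column position.
    """

    patient_id: str
    hand: str
    tremor_level: int
    sample_rate: float
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.hand not in HANDS:
            raise ValueError(f"hand must be one of {HANDS}, got {self.hand!r}")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if int(self.tremor_level) != self.tremor_level or self.tremor_level < 0:
            raise ValueError("tremor_level must be a non-negative integer")
        self.tremor_level = int(self.tremor_level)
        if len(self.data) == 0:
            raise ValueError("empty recording: at least one sample required")
        missing = [c for c in CHANNELS if c not in self.data.columns]
        extra = [c for c in self.data.columns if c not in CHANNELS]
        if missing or extra:
            raise ValueError(
                f"bad channel set: missing {missing!r}, unexpected {extra!r}"
            )
        self.data = self.data[list(CHANNELS)].astype(float)
        if not np.isfinite(self.data.to_numpy()).all():
            raise ValueError("recording contains non-finite values")

    @property
    def n_samples(self) -> int:
        return len(self.data)

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sample_rate

    @property
    def recording_id(self) -> str:
        return f"{self.patient_id}:{self.hand}"

    def sample(self, i: int) -> pd.Series:
        """The i-th 40-scalar sample as a named Series."""
        return self.data.iloc[i]


@dataclasses.dataclass
class ManifestEntry:
    """One cohort-manifest row: one hand of one patient."""

    patient_id: str
    gender: str
    hand: str
    tremor_level: int
    path: Path | None = None


@dataclasses.dataclass
class CohortManifest:
    """Cohort bookkeeping: one entry per (patient, hand).

    Entries may reference capture files on disk or act as pure metadata
    (``path`` is None). Tremor levels above the retained range are allowed to
    exist here — they are flagged and removed by
    :func:`tremorsdh.io.apply_exclusions`, never silently kept.
    """

    entries: list[ManifestEntry]

    def __post_init__(self) -> None:
        keys = [(e.patient_id, e.hand) for e in self.entries]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise ValueError(f"duplicate (patient, hand) entries: {dupes!r}")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[ManifestEntry]:
        return iter(self.entries)

    def level_counts(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for e in self.entries:
            counts[e.tremor_level] = counts.get(e.tremor_level, 0) + 1
        return dict(sorted(counts.items()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": [e.patient_id for e in self.entries],
                "gender": [e.gender for e in self.entries],
                "hand": [e.hand for e in self.entries],
                "tremor_level": [e.tremor_level for e in self.entries],
                "file": ["" if e.path is None else str(e.path) for e in self.entries],
            }
        )
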