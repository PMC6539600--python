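"""Synthetic tremor cohort generator.

Emulates the clinical acquisition protocol: a seated subject holds the hand
still in front of the depth sensor for 10 s, then pushes a virtual ball
~100 mm along the lateral (x) axis over the remaining 5 s of a 15 s capture
at 40 samples/s. An action tremor is modelled as an additive sinusoid in the
4–6 Hz band on the palm x coordinate, with amplitude set by severity level
(0 normal, 1 slight, 2 mild) and Gaussian sensor noise on every position
channel. Finger channels follow the palm rigidly at fixed offsets; velocity
channels are forward differences times the sample rate; the hand-rotation
quaternion is held at identity.

The generator is deterministic given (level, hand, config, seed) and its
default cohort composition reproduces the clinic cohort table: 22/14/3
recordings at levels 0/1/2 across 20 patients' hands (39 retained, plus one
level-3 right hand flagged for exclusion).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as lmc_io
from .schema import AXES, HANDS, PARTS, CohortManifest, ManifestEntry, Recording

#: Fixed rigid-hand offsets (mm) of each part from the palm centre, (x, y, z).
_PART_OFFSETS: dict[str, tuple[float, float, float]] = {
    "thumb": (-35.0, 5.0, -20.0),
    "index": (-15.0, 10.0, -45.0),
    "middle": (0.0, 12.0, -50.0),
    "ring": (15.0, 10.0, -45.0),
    "little": (30.0, 6.0, -35.0),
    "palm": (0.0, 0.0, 0.0),
}

#: Rest position of the palm centre above the sensor (mm).
_PALM_REST = {"x": 0.0, "y": 200.0, "z": 0.0}


@dataclasses.dataclass
class TremorModelConfig:
    """Parameters of the synthetic acquisition and tremor model.

    Amplitudes must be strictly increasing with level; defaults put levels
    0 and 1 close enough to overlap slightly while level 2 is well
    separated, mirroring the clinical difficulty ordering (the slight
    tremor of level 1 is near the normal micro-movement of level 0).
    """

    sample_rate: float = 40.0          # samples/s
    duration: float = 15.0             # s
    hold_duration: float = 10.0        # s of initial still posture
    tremor_freq_range: tuple[float, float] = (4.0, 6.0)  # Hz, uniform draw
    level_amplitudes: Mapping[int, float] = dataclasses.field(
        default_factory=lambda: {0: 0.2, 1: 1.5, 2: 4.0}  # mm
    )
    task_excursion: float = 100.0      # mm travelled by the push
    noise_sd: float = 0.05             # mm sensor noise, per position channel

    def __post_init__(self) -> None:
        n = self.sample_rate * self.duration
        if abs(n - round(n)) > 1e-9:
            raise ValueError("sample_rate x duration must be an integer")
        if not 0 <= self.hold_duration < self.duration:
            raise ValueError("hold_duration must lie within the test duration")
        levels = sorted(self.level_amplitudes)
        amps = [self.level_amplitudes[k] for k in levels]
        if any(b <= a for a, b in zip(amps, amps[1:])):
            raise ValueError("level amplitudes must be strictly increasing")
        if self.tremor_freq_range[1] >= self.sample_rate / 2:
            raise ValueError("tremor band must lie below the Nyquist frequency")
        if self.tremor_freq_range[0] > self.tremor_freq_range[1]:
            raise ValueError("tremor_freq_range must be (low, high)")

    @property
    def n_samples(self) -> int:
        return round(self.sample_rate * self.duration)


def task_trajectory(cfg: TremorModelConfig, hand: str) -> np.ndarray:
    """Noiseless palm-x task trajectory: hold plateau then a smooth ramp.

    The ramp is a C1 smoothstep from 0 to ±task_excursion (positive for the
    right hand, negative for the left — the target appears on that side).
    """
    t = np.arange(cfg.n_samples) / cfg.sample_rate
    sign = 1.0 if hand == "right" else -1.0
    u = np.clip((t - cfg.hold_duration) / (cfg.duration - cfg.hold_duration), 0.0, 1.0)
    return sign * cfg.task_excursion * (3.0 * u**2 - 2.0 * u**3)


def simulate_recording(
    level: int,
    hand: str = "right",
    cfg: TremorModelConfig | None = None,
    seed: int = 0,
    patient_id: str | None = None,
) -> Recording:
    """Simulate one hand's capture at the given tremor level.

    palm-x = task trajectory + A_level * sin(2 pi f t + phi) + noise, with f
    uniform over the tremor band and phi uniform over the circle, drawn once
    per recording. All 39 remaining channels are filled consistently (rigid
    finger offsets sharing the same tremor, forward-difference velocities,
    identity quaternion). Deterministic given (level, hand, cfg, seed).
    """
    cfg = cfg or TremorModelConfig()
    if level not in cfg.level_amplitudes:
        raise ValueError(
            f"level must be one of {sorted(cfg.level_amplitudes)}, got {level!r}"
        )
    if hand not in HANDS:
        raise ValueError(f"hand must be one of {HANDS}, got {hand!r}")
    rng = np.random.default_rng(seed)
    n = cfg.n_samples
    t = np.arange(n) / cfg.sample_rate

    freq = rng.uniform(*cfg.tremor_freq_range)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    tremor = cfg.level_amplitudes[level] * np.sin(2.0 * np.pi * freq * t + phase)

    base = {
        "x": task_trajectory(cfg, hand) + tremor + _PALM_REST["x"],
        "y": np.full(n, _PALM_REST["y"]),
        "z": np.full(n, _PALM_REST["z"]),
    }

    columns: dict[str, np.ndarray] = {}
    for part in PARTS:
        off = _PART_OFFSETS[part]
        for axis, offset in zip(AXES, off):
            pos = base[axis] + offset
            if cfg.noise_sd > 0:
                pos = pos + rng.normal(0.0, cfg.noise_sd, size=n)
            vel = np.empty(n)
            vel[0] = 0.0
            vel[1:] = np.diff(pos) * cfg.sample_rate
            columns[f"{part}_pos_{axis}"] = pos
            columns[f"{part}_vel_{axis}"] = vel
    for axis, value in zip(("x", "y", "z", "w"), (0.0, 0.0, 0.0, 1.0)):
        columns[f"hand_rot_{axis}"] = np.full(n, value)

    return Recording(
        patient_id=patient_id or f"SIM{seed:08d}",
        hand=hand,
        tremor_level=level,
        sample_rate=cfg.sample_rate,
        data=pd.DataFrame(columns),
    )


def table1_composition(include_outlier: bool = True) -> list[dict]:
    """The clinic cohort composition: per-hand tremor levels by gender.

    Returns one dict per (patient, hand) with keys patient_id, gender, hand,
    tremor_level. 20 patients (9 female, 11 male), both hands each; levels
    0/1/2 appear on 22/14/3 hands and one male right hand carries level 3
    (included only when ``include_outlier``). Per-patient pairing of right
    and left levels is not part of the published margins and is fixed here
    deterministically.
    """
    female_right = [0] * 7 + [1] * 2
    female_left = [0] * 6 + [1] * 3
    male_right = [0] * 5 + [1] * 4 + [2] * 1 + [3] * 1
    male_left = [0] * 4 + [1] * 5 + [2] * 2
    rows: list[dict] = []
    for i, (r, l) in enumerate(zip(female_right, female_left)):
        pid = f"P{i + 1:02d}"
        rows.append(dict(patient_id=pid, gender="F", hand="right", tremor_level=r))
        rows.append(dict(patient_id=pid, gender="F", hand="left", tremor_level=l))
    for i, (r, l) in enumerate(zip(male_right, male_left)):
        pid = f"P{i + 10:02d}"
        rows.append(dict(patient_id=pid, gender="M", hand="right", tremor_level=r))
        rows.append(dict(patient_id=pid, gender="M", hand="left", tremor_level=l))
    if not include_outlier:
        rows = [r for r in rows if r["tremor_level"] <= 2]
    return rows


def table1_manifest(include_outlier: bool = True) -> CohortManifest:
    """Metadata-only manifest of the clinic cohort composition."""
    return CohortManifest(
        entries=[ManifestEntry(path=None, **row) for row in table1_composition(include_outlier)]
    )


def _recording_seed(master_seed: int, index: int) -> int:
    """Stable per-recording seed derived from the master seed."""
    ss = np.random.SeedSequence([int(master_seed), int(index)])
    return int(ss.generate_state(1)[0] % (2**31))


def simulate_cohort(
    cfg: TremorModelConfig | None = None,
    composition: Sequence[Mapping] | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> tuple[CohortManifest, list[Recording]]:
    """Simulate a whole cohort from a composition table.

    ``composition`` rows need keys (patient_id, gender, hand, tremor_level);
    the default is the clinic cohort after exclusion — 39 recordings. Each
    recording gets its own seed derived reproducibly from ``seed``. When
    ``out_dir`` is given, capture CSVs and a ``manifest.csv`` (recording the
    master seed in a sidecar) are written there.
    """
    cfg = cfg or TremorModelConfig()
    if composition is None:
        composition = table1_composition(include_outlier=False)
    recordings: list[Recording] = []
    entries: list[ManifestEntry] = []
    for idx, row in enumerate(composition):
        rec = simulate_recording(
            level=int(row["tremor_level"]),
            hand=str(row["hand"]),
            cfg=cfg,
            seed=_recording_seed(seed, idx),
            patient_id=str(row["patient_id"]),
        )
        path = None
        if out_dir is not None:
            path = Path(out_dir) / f"{rec.patient_id}_{rec.hand}.csv"
            lmc_io.write_recording(rec, path)
        recordings.append(rec)
        entries.append(
            ManifestEntry(
                patient_id=rec.patient_id,
                gender=str(row.get("gender", "U")),
                hand=rec.hand,
                tremor_level=rec.tremor_level,
                path=path,
            )
        )
    manifest = CohortManifest(entries=entries)
    if out_dir is not None:
        lmc_io.write_manifest(manifest, Path(out_dir) / "manifest.csv")
        import json

        meta = {"master_seed": int(seed), "n_recordings": len(recordings)}
        (Path(out_dir) / "cohort_meta.json").write_text(json.dumps(meta, indent=2))
    return manifest, recordings


def expand_composition(counts: Mapping[int, int]) -> list[dict]:
    """Build a composition from per-level recording counts.

    Counts are split across hands as evenly as possible (right gets the
    extra one when odd); useful for custom cohorts like ``{0: 10, 1: 10,
    2: 10}``.
    """
    rows: list[dict] = []
    pid = 0
    for level in sorted(counts):
        c = counts[level]
        if c < 0:
            raise ValueError("counts must be non-negative")
        for j in range(c):
            pid += 1
            rows.append(
                dict(
                    patient_id=f"S{pid:03d}",
                    gender="U",
                    hand="right" if j % 2 == 0 else "left",
                    tremor_level=level,
                )
            )
    return rows
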