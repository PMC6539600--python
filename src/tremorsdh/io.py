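"""Reading and writing capture files and cohort manifests.

Capture files are plain CSV with one header row naming the 40 channels of
:data:`tremorsdh.schema.CHANNELS`; recording-level metadata (patient, hand,
tremor level) lives in the cohort manifest, not in the capture file. Channels
are always mapped by name, never by column position.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .schema import CHANNELS, CohortManifest, ManifestEntry, Recording

logger = logging.getLogger(__name__)

MANIFEST_COLUMNS = ("patient_id", "gender", "hand", "tremor_level", "file")

#: Decimal places used when writing capture CSVs; fixed so that
#: write -> read -> write round-trips bit-identically.
CAPTURE_DECIMALS = 6


class SchemaError(ValueError):
    """A capture or manifest file does not match the expected channel schema."""


class CaptureParseError(ValueError):
    """A capture file contains a cell that cannot be parsed as a number."""


def read_recording(
    path: str | Path,
    schema: Sequence[str] = CHANNELS,
    *,
    patient_id: str = "unknown",
    hand: str = "right",
    tremor_level: int = 0,
    sample_rate: float = 40.0,
) -> Recording:
    """Read one capture CSV into a :class:`Recording`.

    The file must carry exactly the channels of ``schema`` (any column
    order); missing or extra channels raise :class:`SchemaError` naming the
    offending channels, and a non-numeric cell raises
    :class:`CaptureParseError` with its row index. Metadata is supplied by
    the caller (normally from the manifest).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"empty recording: {path}") from None
    if len(df) == 0:
        raise SchemaError(f"empty recording: {path}")
    missing = [c for c in schema if c not in df.columns]
    extra = [c for c in df.columns if c not in schema]
    if missing or extra:
        raise SchemaError(
            f"{path}: channel schema mismatch — missing {missing!r}, "
            f"unexpected {extra!r}"
        )
    for col in schema:
        if not pd.api.types.is_numeric_dtype(df[col]):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad_rows = df.index[coerced.isna() & df[col].notna()].tolist()
            raise CaptureParseError(
                f"{path}: non-numeric value in channel {col!r} at row(s) "
                f"{bad_rows[:5]!r}"
            )
    rec = Recording(
        patient_id=patient_id,
        hand=hand,
        tremor_level=tremor_level,
        sample_rate=sample_rate,
        data=df,
    )
    logger.info("read %s: %d samples, %d channels", path, rec.n_samples, len(schema))
    return rec


def write_recording(rec: Recording, path: str | Path) -> Path:
    """Write a recording's sample matrix as a capture CSV (fixed precision)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rec.data.to_csv(path, index=False, float_format=f"%.{CAPTURE_DECIMALS}f")
    logger.info("wrote %s: %d samples", path, rec.n_samples)
    return path


def extract_channel(rec: Recording, channel: str | Sequence[str]) -> np.ndarray:
    """Project one channel (1-D array) or an ordered channel set (2-D array).

    A pure projection: never modifies the stored samples. For a name set the
    columns appear in the requested order, one per name.
    """
    names = [channel] if isinstance(channel, str) else list(channel)
    unknown = [c for c in names if c not in CHANNELS]
    if unknown:
        raise KeyError(f"unknown channel(s) {unknown!r}")
    values = rec.data[names].to_numpy(copy=True)
    return values[:, 0] if isinstance(channel, str) else values


def apply_exclusions(manifest: CohortManifest, max_level: int = 2) -> CohortManifest:
    """Drop manifest entries whose tremor level exceeds the retained range.

    Levels above ``max_level`` (clinic scale entries beyond mild) are treated
    as outliers and removed; the number of removals is logged. Idempotent.
    An empty result is allowed but warned about.
    """
    kept = [e for e in manifest.entries if e.tremor_level <= max_level]
    removed = len(manifest.entries) - len(kept)
    logger.info(
        "exclusions: removed %d of %d entries (level > %d), %d retained",
        removed, len(manifest.entries), max_level, len(kept),
    )
    if not kept:
        warnings.warn("exclusions removed every manifest entry", stacklevel=2)
    return CohortManifest(entries=kept)


def write_manifest(manifest: CohortManifest, path: str | Path) -> Path:
    """Write a cohort manifest CSV; file paths are stored relative to it."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = manifest.to_frame()
    rel = []
    for e in manifest.entries:
        if e.path is None:
            rel.append("")
        else:
            p = Path(e.path)
            try:
                rel.append(str(p.relative_to(path.parent)))
            except ValueError:
                rel.append(str(p))
    df["file"] = rel
    df.to_csv(path, index=False)
    logger.info("wrote manifest %s: %d entries", path, len(manifest))
    return path


def read_manifest(path: str | Path) -> CohortManifest:
    """Read a cohort manifest CSV; relative file paths resolve against it."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"patient_id": str, "gender": str, "hand": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: manifest missing columns {missing!r}")
    entries = []
    for row in df.itertuples(index=False):
        file_field = "" if pd.isna(row.file) else str(row.file)
        entries.append(
            ManifestEntry(
                patient_id=str(row.patient_id),
                gender=str(row.gender),
                hand=str(row.hand),
                tremor_level=int(row.tremor_level),
                path=(path.parent / file_field) if file_field else None,
            )
        )
    manifest = CohortManifest(entries=entries)
    logger.info("read manifest %s: %d entries", path, len(manifest))
    return manifest


def load_recordings(
    manifest: CohortManifest, sample_rate: float = 40.0
) -> list[Recording]:
    """Load every manifest entry that references a capture file."""
    recs = []
    for e in manifest.entries:
        if e.path is None:
            continue
        recs.append(
            read_recording(
                e.path,
                patient_id=e.patient_id,
                hand=e.hand,
                tremor_level=e.tremor_level,
                sample_rate=sample_rate,
            )
        )
    logger.info("loaded %d recordings", len(recs))
    return recs
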