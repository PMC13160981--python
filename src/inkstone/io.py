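"""Readers and writers for every file the pipeline touches.

All on-disk formats are UTF-8, tab-separated tables with a header row.  The
pen-sample dialect is ``t_ms  x  y  pressure  trial_id``: one row per pen
sample at the tablet's sampling rate, timestamps in milliseconds since
session start, coordinates and pressure in device-native units (pressure 0 =
pen in air).  The delimiter and column names can be overridden through a
:class:`Dialect` for streams exported by other acquisition front-ends.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Dialect",
    "FormatError",
    "ValidationError",
    "PEN_SAMPLE_COLUMNS",
    "EVENT_COLUMNS",
    "SELF_REPORT_CORRECT",
    "SELF_REPORT_AMNESIA",
    "SELF_REPORT_DONT_KNOW",
    "read_pen_samples",
    "write_pen_samples",
    "read_events",
    "write_events",
    "check_event_coverage",
    "read_decomposition",
    "write_decomposition",
    "read_lexical_norms",
    "write_lexical_norms",
    "read_metrics",
    "write_metrics",
    "LEXICAL_PREDICTORS",
]


class FormatError(ValueError):
    """A file does not have the expected layout (missing/renamed columns)."""


class ValidationError(ValueError):
    """A file parses but violates a typed invariant (e.g. time not monotonic)."""


PEN_SAMPLE_COLUMNS = ["t_ms", "x", "y", "pressure", "trial_id"]

EVENT_COLUMNS = [
    "trial_id",
    "participant_id",
    "item_number",
    "target_char",
    "audio_onset_ms",
    "audio_offset_ms",
    "space_press_ms",
    "self_report",
]

# Self-report key codes from the dictation task keypad.
SELF_REPORT_CORRECT = 0
SELF_REPORT_AMNESIA = 1
SELF_REPORT_DONT_KNOW = 2

#: The 14 lexical predictors attached to each target character.
LEXICAL_PREDICTORS = [
    "phonogram",
    "phonetic_radical_order",
    "regularity",
    "homophone_density",
    "n_meanings",
    "imageability",
    "concreteness",
    "frequency",
    "age_of_acquisition",
    "n_strokes",
    "n_radicals",
    "left_right",
    "top_down",
    "word_familiarity",
]


@dataclass(frozen=True)
class Dialect:
    """On-disk dialect for pen-sample streams."""

    sep: str = "\t"
    encoding: str = "utf-8"
    #: mapping from on-disk column name -> canonical name, for foreign exports
    column_map: dict = field(default_factory=dict)

    def normalize(self, df: pd.DataFrame) -> pd.DataFrame:
        if self.column_map:
            df = df.rename(columns=self.column_map)
        return df


DEFAULT_DIALECT = Dialect()


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{what} file is missing column(s): {', '.join(missing)}")


def read_pen_samples(path: str | Path, dialect: Dialect = DEFAULT_DIALECT) -> pd.DataFrame:
    """Read a pen-sample stream, validating per-trial time monotonicity.

    Returns the samples in file order with canonical columns
    ``t_ms x y pressure trial_id``.  Raises :class:`FormatError` if a required
    column is absent and :class:`ValidationError` (naming the offending 0-based
    data row) if timestamps are not strictly increasing within a trial, a
    pressure is negative, or a trial id is < 1.
    """
    df = pd.read_csv(path, sep=dialect.sep, encoding=dialect.encoding)
    df = dialect.normalize(df)
    _require_columns(df, PEN_SAMPLE_COLUMNS, "pen sample")
    df = df[PEN_SAMPLE_COLUMNS].copy()
    validate_pen_samples(df)
    return df


def validate_pen_samples(df: pd.DataFrame) -> None:
    """Check the pen-sample invariants on an in-memory stream."""
    if (df["pressure"] < 0).any():
        row = int(np.flatnonzero(df["pressure"].to_numpy() < 0)[0])
        raise ValidationError(f"negative pressure at row {row}")
    if (df["trial_id"] < 1).any():
        row = int(np.flatnonzero(df["trial_id"].to_numpy() < 1)[0])
        raise ValidationError(f"trial_id < 1 at row {row}")
    t = df["t_ms"].to_numpy()
    trial = df["trial_id"].to_numpy()
    same_trial = trial[1:] == trial[:-1]
    bad = same_trial & (np.diff(t) <= 0)
    if bad.any():
        row = int(np.flatnonzero(bad)[0]) + 1
        raise ValidationError(f"non-monotonic timestamp within trial at row {row}")


def write_pen_samples(
    df: pd.DataFrame, path: str | Path, dialect: Dialect = DEFAULT_DIALECT
) -> None:
    df[PEN_SAMPLE_COLUMNS].to_csv(path, sep=dialect.sep, encoding=dialect.encoding, index=False)


def read_events(path: str | Path, dialect: Dialect = DEFAULT_DIALECT) -> pd.DataFrame:
    """Read per-trial event logs (one row per trial).

    Validates that self-report codes are in {0, 1, 2} and that the spacebar
    press follows the audio offset on every trial.
    """
    df = pd.read_csv(path, sep=dialect.sep, encoding=dialect.encoding)
    df = dialect.normalize(df)
    _require_columns(df, EVENT_COLUMNS, "events")
    df = df[EVENT_COLUMNS].copy()
    validate_events(df)
    return df


def validate_events(df: pd.DataFrame) -> None:
    bad_report = ~df["self_report"].isin(
        [SELF_REPORT_CORRECT, SELF_REPORT_AMNESIA, SELF_REPORT_DONT_KNOW]
    )
    if bad_report.any():
        val = df.loc[bad_report, "self_report"].iloc[0]
        raise ValidationError(f"self_report code {val!r} outside {{0, 1, 2}}")
    if df["trial_id"].duplicated().any():
        dup = int(df.loc[df["trial_id"].duplicated(), "trial_id"].iloc[0])
        raise ValidationError(f"duplicate event row for trial {dup}")
    bad_order = df["audio_offset_ms"] >= df["space_press_ms"]
    if bad_order.any():
        tid = int(df.loc[bad_order, "trial_id"].iloc[0])
        raise ValidationError(f"audio offset at/after spacebar press on trial {tid}")


def write_events(df: pd.DataFrame, path: str | Path, dialect: Dialect = DEFAULT_DIALECT) -> None:
    df[EVENT_COLUMNS].to_csv(path, sep=dialect.sep, encoding=dialect.encoding, index=False)


def check_event_coverage(samples: pd.DataFrame, events: pd.DataFrame) -> list[int]:
    """Return trial ids present in the sample stream but missing an event row.

    Emits a warning listing the orphans (they carry ink nobody timed the
    audio for, so no character latency can be computed).
    """
    sample_trials = set(np.unique(samples["trial_id"].to_numpy()))
    event_trials = set(events["trial_id"].to_numpy())
    orphans = sorted(int(t) for t in sample_trials - event_trials)
    if orphans:
        warnings.warn(f"trials without event rows: {orphans}", stacklevel=2)
    return orphans


def read_decomposition(path: str | Path, dialect: Dialect = DEFAULT_DIALECT) -> pd.DataFrame:
    """Read the character decomposition table.

    Columns: ``character``, ``radical_stroke_counts`` (comma-separated
    positive integers, in writing order), ``total_strokes``.  The parsed
    ``radical_stroke_counts`` column holds tuples of ints.  Rows whose counts
    do not sum to ``total_strokes`` raise :class:`ValidationError` naming the
    character.
    """
    df = pd.read_csv(path, sep=dialect.sep, encoding=dialect.encoding, dtype={"character": str})
    df = dialect.normalize(df)
    _require_columns(df, ["character", "radical_stroke_counts", "total_strokes"], "decomposition")
    counts = [
        tuple(int(c) for c in str(s).split(",")) for s in df["radical_stroke_counts"]
    ]
    df = df[["character", "total_strokes"]].copy()
    df["radical_stroke_counts"] = counts
    validate_decomposition(df)
    return df[["character", "radical_stroke_counts", "total_strokes"]]


def validate_decomposition(df: pd.DataFrame) -> None:
    for _, row in df.iterrows():
        counts = row["radical_stroke_counts"]
        if any(c < 1 for c in counts):
            raise ValidationError(
                f"character {row['character']!r}: radical stroke count < 1"
            )
        if sum(counts) != row["total_strokes"]:
            raise ValidationError(
                f"character {row['character']!r}: radical stroke counts "
                f"{list(counts)} sum to {sum(counts)}, not total_strokes="
                f"{row['total_strokes']}"
            )


def write_decomposition(
    df: pd.DataFrame, path: str | Path, dialect: Dialect = DEFAULT_DIALECT
) -> None:
    out = df.copy()
    out["radical_stroke_counts"] = [
        ",".join(str(c) for c in counts) for counts in out["radical_stroke_counts"]
    ]
    out[["character", "radical_stroke_counts", "total_strokes"]].to_csv(
        path, sep=dialect.sep, encoding=dialect.encoding, index=False
    )


def read_lexical_norms(path: str | Path, dialect: Dialect = DEFAULT_DIALECT) -> pd.DataFrame:
    """Read the per-character lexical norms table (14 predictors).

    Binary predictors (phonogram, phonetic radical order, left-right,
    top-down) are sum-coded ±0.5 and validated as such.
    """
    df = pd.read_csv(path, sep=dialect.sep, encoding=dialect.encoding, dtype={"character": str})
    df = dialect.normalize(df)
    _require_columns(df, ["character"] + LEXICAL_PREDICTORS, "lexical norms")
    df = df[["character"] + LEXICAL_PREDICTORS].copy()
    validate_lexical_norms(df)
    return df


def validate_lexical_norms(df: pd.DataFrame) -> None:
    for col in ["phonogram", "phonetic_radical_order", "left_right", "top_down"]:
        vals = df[col].to_numpy(dtype=float)
        if not np.all(np.isin(vals, [-0.5, 0.5])):
            raise ValidationError(f"{col} must be sum-coded -0.5/+0.5")
    for col in ["n_strokes", "n_radicals"]:
        if (df[col] < 1).any():
            raise ValidationError(f"{col} must be >= 1")


def write_lexical_norms(
    df: pd.DataFrame, path: str | Path, dialect: Dialect = DEFAULT_DIALECT
) -> None:
    df[["character"] + LEXICAL_PREDICTORS].to_csv(
        path, sep=dialect.sep, encoding=dialect.encoding, index=False
    )


def read_metrics(path: str | Path, dialect: Dialect = DEFAULT_DIALECT) -> pd.DataFrame:
    """Read a long-format metric table produced by :func:`write_metrics`."""
    df = pd.read_csv(
        path, sep=dialect.sep, encoding=dialect.encoding, dtype={"target_char": str, "flags": str}
    )
    df["flags"] = df["flags"].fillna("")
    return df


def write_metrics(df: pd.DataFrame, path: str | Path, dialect: Dialect = DEFAULT_DIALECT) -> None:
    df.to_csv(path, sep=dialect.sep, encoding=dialect.encoding, index=False)


def with_dialect(sep: str | None = None, **column_map: str) -> Dialect:
    """Convenience constructor: ``with_dialect(sep=',', time='t_ms')``."""
    d = DEFAULT_DIALECT
    if sep is not None:
        d = replace(d, sep=sep)
    if column_map:
        d = replace(d, column_map={v: k for k, v in column_map.items()})
    return d
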