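"""Stroke detection and radical grouping for single-trial pen streams.

A stroke is a maximal run of consecutive samples with pressure > 0; the
zero-pressure (pen-in-air) samples between runs separate strokes and are kept
only for rendering.  Strokes are grouped into radicals by consuming the
decomposition table's ordered per-radical stroke counts in writing order —
there is no geometric radical discovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Stroke", "SegmentTree", "path_length", "detect_strokes", "group_radicals"]


def path_length(points: np.ndarray) -> float:
    """Trajectory length of an ordered (n, 2) coordinate array.

    Sum of Euclidean distances between successive points; a single point has
    length 0.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    if len(pts) < 2:
        return 0.0
    return float(np.hypot(*np.diff(pts, axis=0).T).sum())


@dataclass
class Stroke:
    """One maximal pressure-positive run of pen samples."""

    index: int  # 1-based order within the trial
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    pressure: np.ndarray
    sample_range: tuple[int, int]  # [start, stop) indices into the trial stream

    @property
    def onset_t(self) -> float:
        return float(self.t[0])

    @property
    def offset_t(self) -> float:
        return float(self.t[-1])

    @property
    def duration(self) -> float:
        return self.offset_t - self.onset_t

    @property
    def start_xy(self) -> tuple[float, float]:
        return float(self.x[0]), float(self.y[0])

    @property
    def end_xy(self) -> tuple[float, float]:
        return float(self.x[-1]), float(self.y[-1])

    @property
    def length(self) -> float:
        return path_length(np.column_stack([self.x, self.y]))

    @property
    def mean_pressure(self) -> float:
        return float(np.mean(self.pressure))

    @property
    def n_samples(self) -> int:
        return len(self.t)


@dataclass
class SegmentTree:
    """trial → radicals → strokes hierarchy for one trial.

    ``radical_spans`` holds, per radical in writing order, the [start, stop)
    range of stroke indices (0-based into ``strokes``); it is ``None`` when no
    decomposition was available or the stroke count did not match, in which
    case ``flags`` records why and radical-level metrics are skipped.
    """

    trial_id: int
    strokes: list[Stroke]
    radical_spans: list[tuple[int, int]] | None = None
    flags: list[str] = field(default_factory=list)
    hover: pd.DataFrame | None = None  # zero-pressure samples, rendering only

    @property
    def n_strokes(self) -> int:
        return len(self.strokes)

    @property
    def n_radicals(self) -> int:
        return len(self.radical_spans) if self.radical_spans is not None else 0

    def radical_strokes(self, k: int) -> list[Stroke]:
        """Strokes of radical ``k`` (0-based)."""
        if self.radical_spans is None:
            raise ValueError("no radical grouping on this tree")
        start, stop = self.radical_spans[k]
        return self.strokes[start:stop]

    def to_index_ranges(self) -> dict:
        """JSON-able sidecar: sample-index ranges per radical and stroke."""
        strokes = [
            {"stroke": s.index, "samples": list(s.sample_range)} for s in self.strokes
        ]
        radicals = None
        if self.radical_spans is not None:
            radicals = [
                {"radical": k + 1, "strokes": [start + 1, stop]}
                for k, (start, stop) in enumerate(self.radical_spans)
            ]
        return {
            "trial_id": int(self.trial_id),
            "strokes": strokes,
            "radicals": radicals,
            "flags": list(self.flags),
        }


def detect_strokes(trial: pd.DataFrame, min_stroke_samples: int = 1) -> list[Stroke]:
    """Segment one trial's time-sorted sample stream into strokes.

    Strokes are maximal runs of consecutive samples with pressure > 0.  Runs
    shorter than ``min_stroke_samples`` are discarded (default 1: no
    de-noising).  An all-hover or empty stream yields an empty list.
    """
    t = trial["t_ms"].to_numpy(dtype=float)
    x = trial["x"].to_numpy(dtype=float)
    y = trial["y"].to_numpy(dtype=float)
    p = trial["pressure"].to_numpy(dtype=float)
    ink = p > 0
    if not ink.any():
        return []
    # run starts: ink sample whose predecessor is hover (or stream start)
    starts = np.flatnonzero(ink & ~np.concatenate([[False], ink[:-1]]))
    stops = np.flatnonzero(ink & ~np.concatenate([ink[1:], [False]])) + 1
    strokes: list[Stroke] = []
    for a, b in zip(starts, stops):
        if b - a < min_stroke_samples:
            continue
        strokes.append(
            Stroke(
                index=len(strokes) + 1,
                t=t[a:b],
                x=x[a:b],
                y=y[a:b],
                pressure=p[a:b],
                sample_range=(int(a), int(b)),
            )
        )
    return strokes


def group_radicals(
    strokes: list[Stroke],
    entry: pd.Series | dict | None,
    trial_id: int = 0,
    hover: pd.DataFrame | None = None,
) -> SegmentTree:
    """Group detected strokes into radicals using a decomposition entry.

    Radical ``k`` receives the next ``radical_stroke_counts[k]`` strokes in
    writing order.  If the stroke count does not match the entry's total (or
    no entry is given) the tree is flagged and carries no radical level.
    """
    tree = SegmentTree(trial_id=trial_id, strokes=strokes, hover=hover)
    if not strokes:
        # nothing was written; the metric layer flags the trial as no_ink
        return tree
    if entry is None:
        tree.flags.append("no_decomposition")
        return tree
    counts = tuple(entry["radical_stroke_counts"])
    if sum(counts) != len(strokes):
        tree.flags.append("decomposition_mismatch")
        return tree
    spans = []
    pos = 0
    for c in counts:
        spans.append((pos, pos + c))
        pos += c
    tree.radical_spans = spans
    return tree
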