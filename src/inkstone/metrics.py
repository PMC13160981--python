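"""Character-, radical-, and stroke-level handwriting metrics.

For every trial the pipeline reports, per unit:

====================  =========================================================
latency_ms            character: audio offset → first pen-down;
                      radical/stroke: previous unit's offset → this unit's
                      onset (undefined for the first unit, which has no
                      predecessor — its preparation is covered by the
                      character latency)
duration_ms           first to last non-zero-pressure sample of the unit
length                sum of Euclidean distances between successive ink
                      samples, summed over the unit's strokes
pressure              mean pen pressure over the unit's ink samples (hover
                      samples excluded)
distance              straight-line gap from the previous unit's last ink
                      point to this unit's first (radical/stroke only)
====================  =========================================================

Times are in milliseconds; lengths, distances, and pressure stay in
device-native units.  Two equivalent code paths exist: a readable per-trial
path built on :class:`~inkstone.segmentation.SegmentTree` (``trial_metrics``)
and a vectorized batch path over a whole experiment (``extract_metrics``);
the test suite holds them to exact agreement.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .segmentation import SegmentTree, detect_strokes, group_radicals

__all__ = [
    "METRIC_COLUMNS",
    "character_metrics",
    "radical_metrics",
    "stroke_metrics",
    "trial_metrics",
    "extract_metrics",
    "extract_trees",
    "write_segment_sidecar",
]

METRIC_COLUMNS = [
    "trial_id",
    "participant_id",
    "item_number",
    "target_char",
    "level",
    "unit_index",
    "latency_ms",
    "duration_ms",
    "length",
    "pressure",
    "distance",
    "flags",
]


def character_metrics(tree: SegmentTree, audio_offset_ms: float) -> dict:
    """Whole-character metrics for one trial.

    Latency runs from the dictation prompt's audio offset to the first
    pen-down; duration from the first pen-down to the last inked sample.
    A trial with no ink yields missing metrics and the ``no_ink`` flag.
    """
    if not tree.strokes:
        return {
            "level": "character",
            "unit_index": 1,
            "latency_ms": math.nan,
            "duration_ms": math.nan,
            "length": math.nan,
            "pressure": math.nan,
            "distance": math.nan,
            "flags": ";".join(tree.flags + ["no_ink"]),
        }
    first, last = tree.strokes[0], tree.strokes[-1]
    pressures = np.concatenate([s.pressure for s in tree.strokes])
    return {
        "level": "character",
        "unit_index": 1,
        "latency_ms": first.onset_t - audio_offset_ms,
        "duration_ms": last.offset_t - first.onset_t,
        "length": float(sum(s.length for s in tree.strokes)),
        "pressure": float(pressures.mean()),
        "distance": math.nan,
        "flags": ";".join(tree.flags),
    }


def radical_metrics(tree: SegmentTree) -> list[dict]:
    """Per-radical metrics; empty when the tree carries no radical grouping.

    A radical's onset/offset are those of its first/last stroke.  Latency and
    distance are inter-radical intervals and are therefore absent for
    radical 1.
    """
    if tree.radical_spans is None:
        return []
    records = []
    prev_offset = math.nan
    prev_end = (math.nan, math.nan)
    for k in range(tree.n_radicals):
        strokes = tree.radical_strokes(k)
        first, last = strokes[0], strokes[-1]
        pressures = np.concatenate([s.pressure for s in strokes])
        latency = first.onset_t - prev_offset if k > 0 else math.nan
        if k > 0:
            distance = math.hypot(
                first.start_xy[0] - prev_end[0], first.start_xy[1] - prev_end[1]
            )
        else:
            distance = math.nan
        records.append(
            {
                "level": "radical",
                "unit_index": k + 1,
                "latency_ms": latency,
                "duration_ms": last.offset_t - first.onset_t,
                "length": float(sum(s.length for s in strokes)),
                "pressure": float(pressures.mean()),
                "distance": distance,
                "flags": "",
            }
        )
        prev_offset = last.offset_t
        prev_end = last.end_xy
    return records


def stroke_metrics(tree: SegmentTree) -> list[dict]:
    """Per-stroke metrics; latency/distance are absent for stroke 1."""
    records = []
    for i, s in enumerate(tree.strokes):
        if i > 0:
            prev = tree.strokes[i - 1]
            latency = s.onset_t - prev.offset_t
            distance = math.hypot(
                s.start_xy[0] - prev.end_xy[0], s.start_xy[1] - prev.end_xy[1]
            )
        else:
            latency = math.nan
            distance = math.nan
        records.append(
            {
                "level": "stroke",
                "unit_index": i + 1,
                "latency_ms": latency,
                "duration_ms": s.duration,
                "length": s.length,
                "pressure": s.mean_pressure,
                "distance": distance,
                "flags": "",
            }
        )
    return records


def trial_metrics(tree: SegmentTree, event: pd.Series | dict) -> pd.DataFrame:
    """Long-format metric table (character + radical + stroke rows) for one trial."""
    rows = [character_metrics(tree, event["audio_offset_ms"])]
    rows += radical_metrics(tree)
    rows += stroke_metrics(tree)
    df = pd.DataFrame(rows)
    df.insert(0, "trial_id", tree.trial_id)
    df.insert(1, "participant_id", event["participant_id"])
    df.insert(2, "item_number", event["item_number"])
    df.insert(3, "target_char", event["target_char"])
    return df[METRIC_COLUMNS]


def extract_trees(
    samples: pd.DataFrame,
    events: pd.DataFrame,
    decomposition: pd.DataFrame | None = None,
    min_stroke_samples: int = 1,
) -> dict[int, SegmentTree]:
    """Build a :class:`SegmentTree` per trial (per-trial reference path)."""
    decomp = _decomposition_index(decomposition)
    events = events.set_index("trial_id", drop=False)
    trees: dict[int, SegmentTree] = {}
    for trial_id, trial in samples.groupby("trial_id", sort=False):
        strokes = detect_strokes(trial, min_stroke_samples=min_stroke_samples)
        char = (
            events.loc[trial_id, "target_char"] if trial_id in events.index else None
        )
        entry = decomp.get(char) if char is not None else None
        tree = group_radicals(strokes, entry, trial_id=int(trial_id),
                              hover=trial[trial["pressure"] <= 0])
        trees[int(trial_id)] = tree
    return trees


def _decomposition_index(decomposition: pd.DataFrame | None) -> dict:
    if decomposition is None:
        return {}
    return {
        row["character"]: {"radical_stroke_counts": tuple(row["radical_stroke_counts"])}
        for _, row in decomposition.iterrows()
    }


def write_segment_sidecar(trees: dict[int, SegmentTree], path: str | Path) -> None:
    """Write the trial → radical → stroke sample-index ranges as JSON."""
    payload = [trees[k].to_index_ranges() for k in sorted(trees)]
    Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


# ---------------------------------------------------------------------------
# vectorized batch path


def extract_metrics(
    samples: pd.DataFrame,
    events: pd.DataFrame,
    decomposition: pd.DataFrame | None = None,
    min_stroke_samples: int = 1,
) -> pd.DataFrame:
    """Compute the full long-format metric table for a whole experiment.

    Vectorized equivalent of running :func:`trial_metrics` over every trial;
    suitable for hundreds of thousands of samples.  Trials listed in
    ``events`` but absent from the stream (or with no ink) are reported as
    character rows flagged ``no_ink``; trials whose detected stroke count
    disagrees with the decomposition are flagged ``decomposition_mismatch``
    and carry no radical rows.
    """
    strokes = _stroke_table(samples, min_stroke_samples)
    ev = events[
        ["trial_id", "participant_id", "item_number", "target_char", "audio_offset_ms"]
    ].copy()

    char_rows = _character_rows(strokes, ev)
    stroke_rows = _stroke_rows(strokes, ev)
    radical_rows, trial_flags = _radical_rows(strokes, ev, decomposition)

    if trial_flags:
        flag_map = pd.Series(trial_flags)
        extra = char_rows["trial_id"].map(flag_map).fillna("")
        char_rows["flags"] = np.where(
            char_rows["flags"] == "", extra, char_rows["flags"] + ";" + extra
        )
        char_rows["flags"] = char_rows["flags"].str.strip(";")

    frames = [f for f in (char_rows, radical_rows, stroke_rows) if len(f)]
    out = pd.concat(frames, ignore_index=True) if frames else char_rows
    order = pd.CategoricalDtype(["character", "radical", "stroke"], ordered=True)
    out["level"] = out["level"].astype(order)
    out = out.sort_values(["trial_id", "level", "unit_index"], kind="stable")
    out["level"] = out["level"].astype(str)
    return out.reset_index(drop=True)[METRIC_COLUMNS]


def _stroke_table(samples: pd.DataFrame, min_stroke_samples: int) -> pd.DataFrame:
    """Per-stroke summary table from the raw stream, via run-length encoding."""
    trial = samples["trial_id"].to_numpy()
    t = samples["t_ms"].to_numpy(dtype=float)
    x = samples["x"].to_numpy(dtype=float)
    y = samples["y"].to_numpy(dtype=float)
    p = samples["pressure"].to_numpy(dtype=float)

    ink = p > 0
    if not ink.any():
        return pd.DataFrame(
            columns=["trial_id", "onset", "offset", "sx", "sy", "ex", "ey",
                     "length", "psum", "n"]
        ).astype({"trial_id": np.int64})

    prev_ink = np.concatenate([[False], ink[:-1]])
    new_trial = np.concatenate([[True], trial[1:] != trial[:-1]])
    start_flag = ink & (~prev_ink | new_trial)

    ti, xi, yi, pi = t[ink], x[ink], y[ink], p[ink]
    trial_i = trial[ink]
    sflag = start_flag[ink]
    sid = np.cumsum(sflag) - 1
    n_strokes = int(sid[-1]) + 1

    firsts = np.flatnonzero(sflag)
    lasts = np.concatenate([firsts[1:] - 1, [len(ti) - 1]])

    d = np.hypot(np.diff(xi), np.diff(yi))
    same = sid[1:] == sid[:-1]
    length = np.bincount(sid[1:][same], weights=d[same], minlength=n_strokes)
    psum = np.bincount(sid, weights=pi, minlength=n_strokes)
    n = np.bincount(sid, minlength=n_strokes)

    st = pd.DataFrame(
        {
            "trial_id": trial_i[firsts],
            "onset": ti[firsts],
            "offset": ti[lasts],
            "sx": xi[firsts],
            "sy": yi[firsts],
            "ex": xi[lasts],
            "ey": yi[lasts],
            "length": length,
            "psum": psum,
            "n": n,
        }
    )
    if min_stroke_samples > 1:
        st = st[st["n"] >= min_stroke_samples].reset_index(drop=True)
    return st


def _stroke_rows(st: pd.DataFrame, ev: pd.DataFrame) -> pd.DataFrame:
    if st.empty:
        return pd.DataFrame(columns=METRIC_COLUMNS)
    g = st.groupby("trial_id", sort=False)
    out = pd.DataFrame(
        {
            "trial_id": st["trial_id"],
            "level": "stroke",
            "unit_index": g.cumcount() + 1,
            "latency_ms": st["onset"] - g["offset"].shift(1),
            "duration_ms": st["offset"] - st["onset"],
            "length": st["length"],
            "pressure": st["psum"] / st["n"],
            "distance": np.hypot(
                st["sx"] - g["ex"].shift(1), st["sy"] - g["ey"].shift(1)
            ),
            "flags": "",
        }
    )
    return out.merge(ev.drop(columns=["audio_offset_ms"]), on="trial_id")[METRIC_COLUMNS]


def _character_rows(st: pd.DataFrame, ev: pd.DataFrame) -> pd.DataFrame:
    if st.empty:
        agg = pd.DataFrame(
            {
                "trial_id": pd.Series(dtype=np.int64),
                "onset": pd.Series(dtype=float),
                "offset": pd.Series(dtype=float),
                "length": pd.Series(dtype=float),
                "psum": pd.Series(dtype=float),
                "n": pd.Series(dtype=float),
            }
        )
    else:
        agg = st.groupby("trial_id", sort=False).agg(
            onset=("onset", "first"),
            offset=("offset", "last"),
            length=("length", "sum"),
            psum=("psum", "sum"),
            n=("n", "sum"),
        ).reset_index()
    merged = ev.merge(agg, on="trial_id", how="left")
    no_ink = merged["onset"].isna()
    out = pd.DataFrame(
        {
            "trial_id": merged["trial_id"],
            "participant_id": merged["participant_id"],
            "item_number": merged["item_number"],
            "target_char": merged["target_char"],
            "level": "character",
            "unit_index": 1,
            "latency_ms": merged["onset"] - merged["audio_offset_ms"],
            "duration_ms": merged["offset"] - merged["onset"],
            "length": merged["length"],
            "pressure": merged["psum"] / merged["n"],
            "distance": np.nan,
            "flags": np.where(no_ink, "no_ink", ""),
        }
    )
    return out[METRIC_COLUMNS]


def _radical_rows(
    st: pd.DataFrame, ev: pd.DataFrame, decomposition: pd.DataFrame | None
) -> tuple[pd.DataFrame, dict[int, str]]:
    """Assign strokes to radicals per trial and aggregate.

    Returns the radical-level rows and a per-trial flag map for trials where
    grouping failed (missing decomposition entry or stroke-count mismatch).
    """
    empty = pd.DataFrame(columns=METRIC_COLUMNS)
    if st.empty:
        return empty, {}
    counts_by_char = (
        {}
        if decomposition is None
        else {
            row["character"]: np.asarray(row["radical_stroke_counts"], dtype=int)
            for _, row in decomposition.iterrows()
        }
    )
    char_by_trial = dict(zip(ev["trial_id"], ev["target_char"]))

    trial_ids, trial_starts = np.unique(st["trial_id"].to_numpy(), return_index=True)
    order = np.argsort(trial_starts)
    trial_ids, trial_starts = trial_ids[order], trial_starts[order]
    boundaries = np.concatenate([trial_starts, [len(st)]])

    radical_idx = np.full(len(st), -1, dtype=int)
    flags: dict[int, str] = {}
    for tid, a, b in zip(trial_ids, boundaries[:-1], boundaries[1:]):
        counts = counts_by_char.get(char_by_trial.get(tid))
        if counts is None:
            flags[int(tid)] = "no_decomposition"
            continue
        if counts.sum() != b - a:
            flags[int(tid)] = "decomposition_mismatch"
            continue
        radical_idx[a:b] = np.repeat(np.arange(len(counts)), counts)

    grouped = st[radical_idx >= 0].copy()
    if grouped.empty:
        return empty, flags
    grouped["radical"] = radical_idx[radical_idx >= 0] + 1
    rad = grouped.groupby(["trial_id", "radical"], sort=False).agg(
        onset=("onset", "first"),
        offset=("offset", "last"),
        sx=("sx", "first"),
        sy=("sy", "first"),
        ex=("ex", "last"),
        ey=("ey", "last"),
        length=("length", "sum"),
        psum=("psum", "sum"),
        n=("n", "sum"),
    ).reset_index()
    g = rad.groupby("trial_id", sort=False)
    out = pd.DataFrame(
        {
            "trial_id": rad["trial_id"],
            "level": "radical",
            "unit_index": rad["radical"],
            "latency_ms": rad["onset"] - g["offset"].shift(1),
            "duration_ms": rad["offset"] - rad["onset"],
            "length": rad["length"],
            "pressure": rad["psum"] / rad["n"],
            "distance": np.hypot(
                rad["sx"] - g["ex"].shift(1), rad["sy"] - g["ey"].shift(1)
            ),
            "flags": "",
        }
    )
    out = out.merge(ev.drop(columns=["audio_offset_ms"]), on="trial_id")
    return out[METRIC_COLUMNS], flags
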