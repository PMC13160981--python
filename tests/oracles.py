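"""Independent brute-force oracles for the test suite.

Everything here is deliberately written as plain Python loops, independent of
the package's implementation (which is vectorized and shares no code with
these), so agreement is a meaningful check.
"""

from __future__ import annotations

import math


def brute_stroke_runs(pressures) -> list[tuple[int, int]]:
    """Maximal runs of consecutive pressure>0 samples as [start, stop) pairs."""
    runs = []
    start = None
    for i, p in enumerate(pressures):
        if p > 0 and start is None:
            start = i
        elif p <= 0 and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(pressures)))
    return runs


def brute_path_length(xs, ys) -> float:
    total = 0.0
    for i in range(1, len(xs)):
        total += math.hypot(xs[i] - xs[i - 1], ys[i] - ys[i - 1])
    return total


def brute_trial_metrics(t, x, y, p, audio_offset, counts=None) -> dict:
    """All unit-level metrics of one trial, by direct enumeration.

    Returns ``{"character": dict, "strokes": [dict...], "radicals": [dict...]
    or None}``; latency/distance of a first unit are None.
    """
    runs = brute_stroke_runs(p)
    if not runs:
        return {"character": None, "strokes": [], "radicals": None}

    strokes = []
    for a, b in runs:
        strokes.append(
            {
                "onset": t[a],
                "offset": t[b - 1],
                "duration": t[b - 1] - t[a],
                "length": brute_path_length(x[a:b], y[a:b]),
                "pressure": sum(p[a:b]) / (b - a),
                "start": (x[a], y[a]),
                "end": (x[b - 1], y[b - 1]),
                "n": b - a,
            }
        )
    for i, s in enumerate(strokes):
        if i == 0:
            s["latency"] = None
            s["distance"] = None
        else:
            prev = strokes[i - 1]
            s["latency"] = s["onset"] - prev["offset"]
            s["distance"] = math.hypot(
                s["start"][0] - prev["end"][0], s["start"][1] - prev["end"][1]
            )

    all_p = []
    for a, b in runs:
        all_p.extend(p[a:b])
    character = {
        "latency": strokes[0]["onset"] - audio_offset,
        "duration": strokes[-1]["offset"] - strokes[0]["onset"],
        "length": sum(s["length"] for s in strokes),
        "pressure": sum(all_p) / len(all_p),
    }

    radicals = None
    if counts is not None and sum(counts) == len(strokes):
        radicals = []
        pos = 0
        for k, c in enumerate(counts):
            members = strokes[pos : pos + c]
            pos += c
            member_p = []
            for s in members:
                member_p.append((s["pressure"], s["n"]))
            total_n = sum(n for _, n in member_p)
            rad = {
                "onset": members[0]["onset"],
                "offset": members[-1]["offset"],
                "duration": members[-1]["offset"] - members[0]["onset"],
                "length": sum(s["length"] for s in members),
                "pressure": sum(pm * n for pm, n in member_p) / total_n,
                "start": members[0]["start"],
                "end": members[-1]["end"],
            }
            if k == 0:
                rad["latency"] = None
                rad["distance"] = None
            else:
                prev = radicals[k - 1]
                rad["latency"] = rad["onset"] - prev["offset"]
                rad["distance"] = math.hypot(
                    rad["start"][0] - prev["end"][0], rad["start"][1] - prev["end"][1]
                )
            radicals.append(rad)
    return {"character": character, "strokes": strokes, "radicals": radicals}


def brute_bh_stepup(p_values, q=0.05) -> list[bool]:
    """Benjamini–Hochberg step-up by literal definition.

    Reject H_(1..k*) where k* = max{k : p_(k) <= k q / m}.
    """
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    k_star = 0
    for rank, idx in enumerate(order, start=1):
        if p_values[idx] <= rank * q / m:
            k_star = rank
    flags = [False] * m
    for rank, idx in enumerate(order, start=1):
        if rank <= k_star:
            flags[idx] = True
    return flags


def brute_vif_two_predictors(r: float) -> float:
    """Closed form for a two-predictor system with correlation r."""
    return 1.0 / (1.0 - r * r)
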