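"""Synthetic handwriting-to-dictation experiments with known ground truth.

The generator emulates the four input files the pipeline consumes — a
pen-sample stream, per-trial event logs, a character decomposition table,
and a lexical-norms table — for a configurable experiment of
``n_participants × n_items`` dictation trials sampled at 200 Hz (5 ms).

Trials follow the task timeline: cue, 500 ms blank, a spoken prompt, then
the participant writes the target character inside their grid cell, stroke by
stroke, with zero-pressure hover samples recorded while the pen is in the
air.  Latencies and durations are log-normal (positive and right-skewed,
matching the mean ≪ max pattern of real pen data); item-level outcome means
are linear functions of the *z-scored* lexical predictors (the designed
effect vectors ``beta_*``) plus item and participant random intercepts; the
probability of a character-amnesia response follows a logistic model on the
same predictors.  Ink geometry is schematic polylines — metrics depend only
on coordinates and timestamps, never on legibility.

Every dataset ships with its :class:`GroundTruth` so recovery can be checked
end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    LEXICAL_PREDICTORS,
    SELF_REPORT_AMNESIA,
    SELF_REPORT_CORRECT,
    SELF_REPORT_DONT_KNOW,
    write_decomposition,
    write_events,
    write_lexical_norms,
    write_pen_samples,
)

__all__ = ["SimulationConfig", "GroundTruth", "SimulatedExperiment",
           "simulate_norms", "simulate_decomposition", "simulate_trial",
           "simulate_dataset", "write_dataset"]


@dataclass
class SimulationConfig:
    """All knobs of the synthetic experiment.

    Times are milliseconds, geometry is in abstract device units (one grid
    cell is ``cell_size`` units wide).  The latency/duration location-scale
    pairs parameterize log-normal distributions by their *mean and SD on the
    ms scale*; defaults reproduce the scale of real single-character
    dictation data (character latency ≈ 1030 ms, stroke latency ≈ 113 ms,
    stroke duration ≈ 148 ms, pressure ≈ 12 500 device units).
    """

    seed: int = 0
    n_participants: int = 42
    n_items: int = 1200

    sampling_interval_ms: int = 5  # 200 Hz

    # trial timeline
    cue_blank_ms: int = 500
    prompt_duration_ms: int = 1500
    post_write_ms: int = 500
    inter_trial_ms: int = 500

    # character-level writing latency (log-normal trial noise, ms)
    char_latency_mean: float = 1030.0
    char_latency_sd: float = 300.0
    # inter-stroke gaps within a radical / between radicals
    stroke_gap_mean: float = 100.0
    stroke_gap_sd: float = 25.0
    radical_gap_mean: float = 150.0
    radical_gap_sd: float = 45.0
    # per-stroke ink duration
    stroke_duration_mean: float = 148.0
    stroke_duration_sd: float = 28.0

    # pen pressure (device units, truncated normal per sample)
    pressure_mean: float = 12500.0
    pressure_sd: float = 1000.0
    participant_pressure_sd: float = 400.0

    # ink geometry (device units)
    cell_size: float = 40.0
    cell_pitch: float = 50.0
    grid_cols: int = 8
    grid_rows: int = 5
    stroke_length_mean: float = 5.1
    stroke_length_sd: float = 1.2
    stroke_jump_mean: float = 2.3
    stroke_jump_sd: float = 0.6
    radical_jump_mean: float = 3.8
    radical_jump_sd: float = 1.2
    polyline_points: tuple[int, int] = (2, 6)

    # random-effect and residual structure (ms)
    participant_latency_sd: float = 100.0
    participant_duration_sd: float = 120.0
    item_latency_sd: float = 250.0
    item_duration_sd: float = 150.0
    residual_duration_sd: float = 120.0

    # designed effects on z-scored lexical predictors (ms per SD / logits)
    beta_latency: dict = field(
        default_factory=lambda: {"frequency": -180.0, "age_of_acquisition": 120.0,
                                 "n_strokes": 60.0}
    )
    beta_duration: dict = field(default_factory=dict)
    beta_amnesia: dict = field(
        default_factory=lambda: {"frequency": -0.8, "age_of_acquisition": 0.6}
    )
    amnesia_intercept: float = -3.0
    amnesia_latency_factor: float = 1.6  # amnesia attempts start later
    p_dont_know: float = 0.01
    p_revised: float = 0.027

    # rater behaviour
    n_raters: int = 3
    p_rater_self_disagree: float = 0.0238  # majority code contradicts self-report
    p_rater_dissent: float = 0.12  # one of the raters deviates from the majority

    def validate(self) -> None:
        for name in ("char_latency_sd", "stroke_gap_sd", "radical_gap_sd",
                     "stroke_duration_sd", "pressure_sd", "item_latency_sd",
                     "item_duration_sd", "residual_duration_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.sampling_interval_ms <= 0:
            raise ValueError("sampling_interval_ms must be > 0")
        for name in ("p_dont_know", "p_revised", "p_rater_self_disagree",
                     "p_rater_dissent"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be a probability")


@dataclass
class GroundTruth:
    """Designed and realized truth stored alongside every generated dataset."""

    beta_latency: pd.Series
    beta_duration: pd.Series
    beta_amnesia: pd.Series
    items: pd.DataFrame  # character, eta_latency, eta_duration, p_amnesia, ...
    trials: pd.DataFrame  # realized per-trial truth


@dataclass
class SimulatedExperiment:
    config: SimulationConfig
    samples: pd.DataFrame
    events: pd.DataFrame
    decomposition: pd.DataFrame
    norms: pd.DataFrame
    raters: pd.DataFrame
    truth: GroundTruth


def _lognormal(rng: np.random.Generator, mean, sd, size=None):
    """Log-normal draws parameterized by their mean and SD on the data scale.

    ``mean``/``sd`` may be scalars or arrays (with matching ``size``); an SD
    of zero degenerates to the constant mean.
    """
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    if np.all(sd == 0):
        shape = size if size is not None else np.broadcast(mean, sd).shape
        return np.broadcast_to(mean, shape).copy() if shape else float(mean)
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    sigma = np.sqrt(sigma2)
    if size is None and mu.shape == ():
        return float(rng.lognormal(float(mu), float(sigma)))
    return np.exp(rng.normal(mu, sigma, size))


def simulate_norms(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Lexical-norms table with realistic marginals for ``n_items`` characters.

    Characters are consecutive CJK codepoints; binary predictors are
    sum-coded ±0.5.
    """
    n = config.n_items
    chars = [chr(0x4E00 + i) for i in range(n)]
    n_strokes = np.clip(np.round(rng.normal(9.72, 2.96, n)), 5, 21).astype(int)
    n_radicals = np.clip(
        np.round(rng.normal(2.95, 1.04, n)), 1, np.minimum(7, n_strokes)
    ).astype(int)
    norms = pd.DataFrame(
        {
            "character": chars,
            "phonogram": np.where(rng.random(n) < 0.75, 0.5, -0.5),
            "phonetic_radical_order": np.where(rng.random(n) < 0.18, 0.5, -0.5),
            "regularity": rng.normal(0.0, 0.85, n),
            "homophone_density": np.clip(rng.normal(0.9, 0.35, n), 0.0, None),
            "n_meanings": 1 + rng.poisson(2.2, n),
            "imageability": rng.normal(0.0, 0.6, n),
            "concreteness": rng.normal(0.0, 0.69, n),
            "frequency": np.clip(rng.normal(3.44, 0.68, n), 1.58, 5.0),
            "age_of_acquisition": np.clip(rng.normal(8.5, 1.63, n), 6.5, 15.0),
            "n_strokes": n_strokes,
            "n_radicals": n_radicals,
            "left_right": np.where(rng.random(n) < 0.58, 0.5, -0.5),
            "top_down": np.where(rng.random(n) < 0.73, 0.5, -0.5),
            "word_familiarity": rng.normal(0.33, 0.33, n),
        }
    )
    return norms[["character"] + LEXICAL_PREDICTORS]


def simulate_decomposition(
    norms: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Random ordered split of each character's strokes into its radicals."""
    rows = []
    for _, r in norms.iterrows():
        total, k = int(r["n_strokes"]), int(r["n_radicals"])
        if k == 1:
            counts = (total,)
        else:
            cuts = np.sort(rng.choice(np.arange(1, total), size=k - 1, replace=False))
            counts = tuple(np.diff(np.concatenate([[0], cuts, [total]])).tolist())
        rows.append(
            {"character": r["character"], "radical_stroke_counts": counts,
             "total_strokes": total}
        )
    return pd.DataFrame(rows)


def _zscore_cols(norms: pd.DataFrame) -> pd.DataFrame:
    z = {}
    for c in LEXICAL_PREDICTORS:
        x = norms[c].to_numpy(dtype=float)
        z[c] = (x - x.mean()) / x.std()
    return pd.DataFrame(z, index=norms.index)


def _eta(z: pd.DataFrame, beta: dict) -> np.ndarray:
    eta = np.zeros(len(z))
    for name, b in beta.items():
        if name not in z.columns:
            raise ValueError(f"unknown predictor {name!r} in effect vector")
        eta += b * z[name].to_numpy()
    return eta


def _polyline(rng, start, length, k_range):
    """Random k-vertex polyline of given arc length starting at ``start``."""
    k = int(rng.integers(k_range[0], k_range[1] + 1))
    angles = rng.uniform(0, 2 * math.pi) + np.concatenate(
        [[0.0], np.cumsum(rng.normal(0.0, 0.8, k - 2))]
    ) if k > 2 else np.array([rng.uniform(0, 2 * math.pi)])
    seg = rng.uniform(0.5, 1.5, k - 1)
    seg *= length / seg.sum()
    dx = np.concatenate([[start[0]], seg * np.cos(angles)])
    dy = np.concatenate([[start[1]], seg * np.sin(angles)])
    return np.cumsum(dx), np.cumsum(dy)


def _sample_polyline(vx, vy, n_samples):
    """n_samples points at equal arc-length spacing along the polyline."""
    seg = np.hypot(np.diff(vx), np.diff(vy))
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    if n_samples == 1 or cum[-1] == 0:
        return np.full(n_samples, vx[0]), np.full(n_samples, vy[0])
    s = np.linspace(0.0, cum[-1], n_samples)
    return np.interp(s, cum, vx), np.interp(s, cum, vy)


def _reflect(v: float, lo: float, hi: float) -> float:
    """Fold a coordinate back into [lo, hi]."""
    span = hi - lo
    if span <= 0:
        return lo
    v = (v - lo) % (2 * span)
    return lo + (v if v <= span else 2 * span - v)


def _grid_round(x: float, step: int) -> int:
    return int(round(x / step)) * step


def _trial_arrays(
    counts: tuple,
    config: SimulationConfig,
    rng: np.random.Generator,
    t0: int,
    latency_ms: float | None,
    duration_shift_ms: float,
    pressure_offset: float,
    cell: tuple[float, float],
    n_strokes: int | None,
):
    """Core trial generator; returns raw sample arrays and realized timings."""
    step = config.sampling_interval_ms
    n_s = int(n_strokes) if n_strokes is not None else int(sum(counts))
    if n_s < 1:
        raise ValueError("a trial needs at least one stroke")

    audio_onset = t0 + config.cue_blank_ms
    audio_offset = audio_onset + config.prompt_duration_ms

    if latency_ms is None:
        latency_ms = float(_lognormal(rng, config.char_latency_mean,
                                      config.char_latency_sd))
    latency = max(2 * step, _grid_round(latency_ms, step))

    # radical boundaries: gap before stroke i (i >= 1) is a radical gap when
    # stroke i starts a new radical
    boundary = np.zeros(n_s, dtype=bool)
    pos = 0
    for c in counts:
        pos += c
        if pos < n_s:
            boundary[pos] = True
    if n_s > 1:
        gap_mean = np.where(boundary[1:], config.radical_gap_mean,
                            config.stroke_gap_mean)
        gap_sd = np.where(boundary[1:], config.radical_gap_sd, config.stroke_gap_sd)
        raw = _lognormal(rng, gap_mean, gap_sd, n_s - 1)
        gaps = np.maximum(2 * step, (np.round(raw / step) * step).astype(int))
        jump_mean = np.where(boundary[1:], config.radical_jump_mean,
                             config.stroke_jump_mean)
        jump_sd = np.where(boundary[1:], config.radical_jump_sd,
                           config.stroke_jump_sd)
        jumps = _lognormal(rng, jump_mean, jump_sd, n_s - 1)
    else:
        gaps = np.zeros(0, dtype=int)
        jumps = np.zeros(0)

    durs = _lognormal(rng, config.stroke_duration_mean, config.stroke_duration_sd, n_s)
    durs = durs + duration_shift_ms / n_s
    durs = np.maximum(step, (np.round(durs / step) * step).astype(int))

    lengths = _lognormal(rng, config.stroke_length_mean, config.stroke_length_sd, n_s)

    half = config.cell_size / 2.0
    lo_x, hi_x = cell[0] - half, cell[0] + half
    lo_y, hi_y = cell[1] - half, cell[1] + half
    hover_start = (cell[0] + rng.normal(0, 2.0), cell[1] + rng.normal(0, 2.0))

    t_parts, x_parts, y_parts, p_parts = [], [], [], []
    onset = audio_offset + latency
    prev_end = hover_start
    prev_offset = audio_offset  # hover starts at the prompt's end
    first_onset, last_offset = onset, onset

    for i in range(n_s):
        if i == 0:
            start = (
                _reflect(hover_start[0] + rng.normal(0, 1.0), lo_x, hi_x),
                _reflect(hover_start[1] + rng.normal(0, 1.0), lo_y, hi_y),
            )
        else:
            jm = float(jumps[i - 1])
            ang = rng.uniform(0, 2 * math.pi)
            start = (
                _reflect(prev_end[0] + jm * math.cos(ang), lo_x, hi_x),
                _reflect(prev_end[1] + jm * math.sin(ang), lo_y, hi_y),
            )
        # hover from the previous pen-up (or the audio offset) to this onset
        n_hover = (onset - prev_offset) // step - 1 if i > 0 else (onset - prev_offset) // step
        if n_hover > 0:
            ht = prev_offset + (0 if i == 0 else step) + step * np.arange(n_hover)
            frac = np.linspace(0.0, 1.0, n_hover + 2)[1:-1] if i > 0 else \
                np.linspace(0.0, 1.0, n_hover + 1)[:-1]
            t_parts.append(ht)
            x_parts.append(prev_end[0] + frac * (start[0] - prev_end[0]))
            y_parts.append(prev_end[1] + frac * (start[1] - prev_end[1]))
            p_parts.append(np.zeros(n_hover))

        n_samp = durs[i] // step + 1
        vx, vy = _polyline(rng, start, float(lengths[i]), config.polyline_points)
        sx, sy = _sample_polyline(vx, vy, n_samp)
        st = onset + step * np.arange(n_samp)
        press = np.maximum(
            1.0,
            np.round(rng.normal(config.pressure_mean + pressure_offset,
                                config.pressure_sd, n_samp)),
        )
        t_parts.append(st)
        x_parts.append(sx)
        y_parts.append(sy)
        p_parts.append(press)

        last_offset = onset + durs[i]
        prev_end = (float(sx[-1]), float(sy[-1]))
        prev_offset = last_offset
        if i < n_s - 1:
            onset = last_offset + gaps[i]

    arrays = (
        np.concatenate(t_parts).astype(np.int64),
        np.concatenate(x_parts),
        np.concatenate(y_parts),
        np.concatenate(p_parts).astype(np.int64),
    )
    timing = {
        "audio_onset": int(audio_onset),
        "audio_offset": int(audio_offset),
        "latency": int(latency),
        "first_onset": int(first_onset),
        "last_offset": int(last_offset),
        "n_strokes": n_s,
    }
    return arrays, timing


def simulate_trial(
    item: dict,
    config: SimulationConfig,
    seed: int | np.random.Generator = 0,
    t0: int = 0,
    trial_id: int = 1,
    participant_id: int = 1,
    latency_ms: float | None = None,
    duration_shift_ms: float = 0.0,
    pressure_offset: float = 0.0,
    cell: tuple[float, float] = (0.0, 0.0),
    n_strokes: int | None = None,
) -> tuple[pd.DataFrame, dict, dict]:
    """Generate one trial's pen-sample stream, event row, and realized truth.

    ``item`` needs ``character`` and ``radical_stroke_counts``; gaps between
    strokes are realized as zero-pressure hover samples, timestamps sit on
    the configured sampling grid, and the number of maximal pressure-positive
    runs equals the requested stroke count by construction.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    config.validate()
    (t, x, y, p), timing = _trial_arrays(
        tuple(item["radical_stroke_counts"]), config, rng, t0, latency_ms,
        duration_shift_ms, pressure_offset, cell, n_strokes,
    )
    samples = pd.DataFrame(
        {"t_ms": t, "x": x, "y": y, "pressure": p, "trial_id": np.int64(trial_id)}
    )
    space_press = timing["last_offset"] + config.post_write_ms
    event = {
        "trial_id": trial_id,
        "participant_id": participant_id,
        "item_number": item.get("item_number", 0),
        "target_char": item["character"],
        "audio_onset_ms": timing["audio_onset"],
        "audio_offset_ms": timing["audio_offset"],
        "space_press_ms": space_press,
        "self_report": SELF_REPORT_CORRECT,
    }
    truth = {
        "trial_id": trial_id,
        "true_latency_ms": timing["latency"],
        "true_duration_ms": timing["last_offset"] - timing["first_onset"],
        "n_strokes_written": timing["n_strokes"],
        "t_end": space_press + config.inter_trial_ms,
    }
    return samples, event, truth


def simulate_dataset(config: SimulationConfig) -> SimulatedExperiment:
    """Generate the complete file set for one synthetic experiment.

    Each participant writes every item once, in a random order, on successive
    grid cells.  Response categories (correct / amnesia / don't know),
    revision flags, rater codes, latencies, and durations all follow the
    configured generative model; the returned :class:`GroundTruth` records
    both the designed effect vectors and the realized per-trial values.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    norms = simulate_norms(config, rng)
    decomposition = simulate_decomposition(norms, rng)
    z = _zscore_cols(norms)

    eta_lat = _eta(z, config.beta_latency) + rng.normal(0, config.item_latency_sd,
                                                        config.n_items)
    eta_dur = _eta(z, config.beta_duration) + rng.normal(0, config.item_duration_sd,
                                                         config.n_items)
    p_amnesia = 1.0 / (1.0 + np.exp(-(config.amnesia_intercept
                                      + _eta(z, config.beta_amnesia))))

    items = decomposition.merge(norms[["character"]], on="character")
    items["item_number"] = np.arange(1, config.n_items + 1)
    item_truth = pd.DataFrame(
        {
            "character": norms["character"],
            "item_number": items["item_number"],
            "eta_latency": eta_lat,
            "eta_duration": eta_dur,
            "p_amnesia": p_amnesia,
        }
    )

    u_lat = rng.normal(0, config.participant_latency_sd, config.n_participants)
    u_dur = rng.normal(0, config.participant_duration_sd, config.n_participants)
    u_press = rng.normal(0, config.participant_pressure_sd, config.n_participants)

    t_parts, x_parts, y_parts, p_parts, id_parts = [], [], [], [], []
    event_rows, truth_rows, rater_rows = [], [], []
    trial_id = 0
    step = config.sampling_interval_ms
    cells_per_sheet = config.grid_cols * config.grid_rows
    item_records = items.to_dict("records")

    for p in range(config.n_participants):
        order = rng.permutation(config.n_items)
        t_cursor = 0
        for slot, idx in enumerate(order):
            item = item_records[idx]
            trial_id += 1
            cell_slot = slot % cells_per_sheet
            cell = (
                (cell_slot % config.grid_cols) * config.cell_pitch,
                (cell_slot // config.grid_cols) * config.cell_pitch,
            )

            u = rng.random()
            if u < config.p_dont_know:
                category, report = "dont_know", SELF_REPORT_DONT_KNOW
            elif u < config.p_dont_know + (1 - config.p_dont_know) * p_amnesia[idx]:
                category, report = "amnesia", SELF_REPORT_AMNESIA
            else:
                category, report = "correct", SELF_REPORT_CORRECT

            base_lat = float(
                _lognormal(rng, config.char_latency_mean, config.char_latency_sd)
            )
            latency = base_lat + eta_lat[idx] + u_lat[p]
            n_strokes = None
            if category == "amnesia":
                latency *= config.amnesia_latency_factor
                n_strokes = max(2, item["total_strokes"] + int(rng.integers(-2, 3)))
            elif category == "dont_know":
                latency *= config.amnesia_latency_factor
                n_strokes = 1  # the circle drawn to signal "don't know"
            dur_shift = (
                eta_dur[idx]
                + u_dur[p]
                + float(rng.normal(0, config.residual_duration_sd))
            )

            (ts, xs, ys, ps), timing = _trial_arrays(
                tuple(item["radical_stroke_counts"]),
                config,
                rng,
                t_cursor,
                max(2 * step, latency),
                dur_shift,
                float(u_press[p]),
                cell,
                n_strokes,
            )
            t_parts.append(ts)
            x_parts.append(xs)
            y_parts.append(ys)
            p_parts.append(ps)
            id_parts.append(np.full(len(ts), trial_id, dtype=np.int64))

            space_press = timing["last_offset"] + config.post_write_ms
            event = {
                "trial_id": trial_id,
                "participant_id": p + 1,
                "item_number": item["item_number"],
                "target_char": item["character"],
                "audio_onset_ms": timing["audio_onset"],
                "audio_offset_ms": timing["audio_offset"],
                "space_press_ms": space_press,
                "self_report": report,
            }
            revised = category == "correct" and rng.random() < config.p_revised
            truth = {
                "trial_id": trial_id,
                "participant_id": p + 1,
                "item_number": item["item_number"],
                "target_char": item["character"],
                "category": category,
                "revised": revised,
                "true_latency_ms": timing["latency"],
                "true_duration_ms": timing["last_offset"] - timing["first_onset"],
                "n_strokes_written": timing["n_strokes"],
            }
            t_cursor = space_press + config.inter_trial_ms

            # rater codes: the majority tracks the self-report except for a
            # configured share of genuine disagreements; one rater may dissent
            base_correct = category == "correct"
            majority_correct = base_correct
            if rng.random() < config.p_rater_self_disagree:
                majority_correct = not majority_correct
            codes = np.full(config.n_raters, "correct" if majority_correct else "incorrect",
                            dtype=object)
            if config.n_raters >= 3 and rng.random() < config.p_rater_dissent:
                flip = rng.integers(config.n_raters)
                codes[flip] = "incorrect" if majority_correct else "correct"
            for r_i, code in enumerate(codes):
                rater_rows.append(
                    {"trial_id": trial_id, "rater_id": r_i + 1, "code": code,
                     "revised": int(revised)}
                )

            event_rows.append(event)
            truth_rows.append(truth)

    samples = pd.DataFrame(
        {
            "t_ms": np.concatenate(t_parts),
            "x": np.concatenate(x_parts),
            "y": np.concatenate(y_parts),
            "pressure": np.concatenate(p_parts),
            "trial_id": np.concatenate(id_parts),
        }
    )
    events = pd.DataFrame(event_rows)
    raters = pd.DataFrame(rater_rows)
    trials = pd.DataFrame(truth_rows)

    truth = GroundTruth(
        beta_latency=pd.Series(config.beta_latency, dtype=float),
        beta_duration=pd.Series(config.beta_duration, dtype=float),
        beta_amnesia=pd.Series(config.beta_amnesia, dtype=float),
        items=item_truth,
        trials=trials,
    )
    return SimulatedExperiment(
        config=config,
        samples=samples,
        events=events,
        decomposition=decomposition,
        norms=norms,
        raters=raters,
        truth=truth,
    )


def write_dataset(exp: SimulatedExperiment, outdir: str | Path) -> dict[str, Path]:
    """Write the four input files plus rater codes and ground-truth tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "samples": outdir / "pen_samples.tsv",
        "events": outdir / "events.tsv",
        "decomposition": outdir / "decomposition.tsv",
        "norms": outdir / "lexical_norms.tsv",
        "raters": outdir / "raters.tsv",
        "truth_items": outdir / "ground_truth_items.tsv",
        "truth_trials": outdir / "ground_truth_trials.tsv",
        "config": outdir / "config.yaml",
    }
    write_pen_samples(exp.samples, paths["samples"])
    write_events(exp.events, paths["events"])
    write_decomposition(exp.decomposition, paths["decomposition"])
    write_lexical_norms(exp.norms, paths["norms"])
    exp.raters.to_csv(paths["raters"], sep="\t", index=False)
    exp.truth.items.to_csv(paths["truth_items"], sep="\t", index=False)
    exp.truth.trials.to_csv(paths["truth_trials"], sep="\t", index=False)
    import yaml

    cfg = asdict(exp.config)
    cfg["polyline_points"] = list(cfg["polyline_points"])
    paths["config"].write_text(yaml.safe_dump(cfg, sort_keys=False), encoding="utf-8")
    return paths
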