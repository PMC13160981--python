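"""Response coding and trial-/metric-level exclusion rules.

The dictation task yields two sources of trial classification: the
participant's self-report key press (correct / character amnesia / don't
know) and human raters who inspect each penscript and mark it correct or
incorrect, plus whether it was revised (false start, crossed-out radical,
...).  Analyses of latency, duration, and pressure keep only trials the
raters marked correct and unrevised; "don't know" trials (the participant
drew a circle) never enter metric analyses.

Metric-level exclusions then trim implausible intervals.  The defaults are
the conventional thresholds for single-character dictation: character
latencies longer than 10 s and durations outside 1–10 s are removed, and at
the radical and stroke level latencies and durations longer than 2 s are
removed.  Removal is per metric — a discarded latency does not discard the
same unit's duration — which is why latency and duration exclusion rates can
differ within a level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import SELF_REPORT_AMNESIA, SELF_REPORT_CORRECT, SELF_REPORT_DONT_KNOW

__all__ = [
    "CodingResult",
    "ExclusionRules",
    "code_responses",
    "filter_analysis_trials",
    "apply_metric_exclusions",
    "SELF_REPORT_LABELS",
]

SELF_REPORT_LABELS = {
    SELF_REPORT_CORRECT: "correct",
    SELF_REPORT_AMNESIA: "amnesia",
    SELF_REPORT_DONT_KNOW: "dont_know",
}


@dataclass
class CodingResult:
    """Outcome of reconciling self-reports with rater codes."""

    codes: pd.DataFrame  # trial_id, rater_code, revised, self_report, consistent
    consistency_rate: float  # fraction of coded trials where the two agree
    uncoded_trials: list[int]  # trials with no rater code, excluded from the rate


def code_responses(events: pd.DataFrame, raters: pd.DataFrame) -> CodingResult:
    """Majority-code each penscript and measure self-report consistency.

    ``raters`` holds one row per (trial, rater): columns ``trial_id``,
    ``rater_id``, ``code`` ("correct"/"incorrect"), ``revised`` (0/1).  With
    several raters the majority wins; even ties break toward "incorrect"
    (and toward revised), the conservative direction since such trials are
    then excluded.  A trial is *consistent* when a "correct" self-report
    coincides with a "correct" rater code and a non-correct self-report
    (amnesia or don't know) with an "incorrect" one.
    """
    bad = ~raters["code"].isin(["correct", "incorrect"])
    if bad.any():
        raise ValueError(f"unknown rater code {raters.loc[bad, 'code'].iloc[0]!r}")
    by_trial = raters.groupby("trial_id").agg(
        n=("code", "size"),
        n_correct=("code", lambda c: (c == "correct").sum()),
        n_revised=("revised", "sum"),
    )
    # strict majority required for "correct"; ties are conservative
    by_trial["rater_code"] = np.where(
        by_trial["n_correct"] * 2 > by_trial["n"], "correct", "incorrect"
    )
    by_trial["revised"] = by_trial["n_revised"] * 2 >= by_trial["n"]

    codes = events[["trial_id", "self_report"]].merge(
        by_trial[["rater_code", "revised"]], on="trial_id", how="left"
    )
    uncoded = codes.loc[codes["rater_code"].isna(), "trial_id"].astype(int).tolist()
    coded = codes.dropna(subset=["rater_code"]).copy()
    coded["self_report"] = coded["self_report"].map(SELF_REPORT_LABELS)
    coded["revised"] = coded["revised"].astype(bool)
    coded["consistent"] = (coded["self_report"] == "correct") == (
        coded["rater_code"] == "correct"
    )
    rate = float(coded["consistent"].mean()) if len(coded) else float("nan")
    return CodingResult(
        codes=coded.reset_index(drop=True),
        consistency_rate=rate,
        uncoded_trials=uncoded,
    )


def filter_analysis_trials(codes: pd.DataFrame) -> pd.Index:
    """Trial ids retained for latency/duration/pressure analyses.

    Keeps trials the raters coded correct and unrevised; incorrect and
    revised penscripts (and with them all amnesia/don't-know trials, which
    raters necessarily code incorrect) are dropped.
    """
    keep = (codes["rater_code"] == "correct") & (~codes["revised"].astype(bool))
    return pd.Index(codes.loc[keep, "trial_id"])


@dataclass(frozen=True)
class ExclusionRules:
    """Metric-level exclusion thresholds, in milliseconds.

    ``None`` disables a bound.  Bounds are strict: a value is removed only
    when it exceeds (or, for the duration minimum, falls short of) the
    threshold, so a latency of exactly 10 000 ms survives a 10 s cap.
    """

    char_latency_max: float | None = 10_000.0
    char_duration_min: float | None = 1_000.0
    char_duration_max: float | None = 10_000.0
    sub_latency_max: float | None = 2_000.0  # radical and stroke levels
    sub_duration_max: float | None = 2_000.0

    def bounds(self, level: str, metric: str) -> tuple[float | None, float | None]:
        """(lower, upper) bound for one level × metric cell."""
        if level == "character":
            if metric == "latency_ms":
                return None, self.char_latency_max
            return self.char_duration_min, self.char_duration_max
        if level in ("radical", "stroke"):
            if metric == "latency_ms":
                return None, self.sub_latency_max
            return None, self.sub_duration_max
        raise ValueError(f"unknown unit level {level!r}")


def apply_metric_exclusions(
    metrics: pd.DataFrame, rules: ExclusionRules = ExclusionRules()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply latency/duration exclusion rules per level, per metric.

    Out-of-bounds values are blanked to NaN (the unit's other metrics are
    untouched).  Returns the filtered table and an exclusion report with one
    row per level × metric: ``n_before`` (non-missing values), ``n_removed``,
    ``percent_removed``, and the rule applied.  Idempotent by construction.
    """
    levels = set(metrics["level"].unique())
    unknown = levels - {"character", "radical", "stroke"}
    if unknown:
        raise ValueError(f"unknown unit level(s) {sorted(unknown)!r}")

    out = metrics.copy()
    report_rows = []
    for level in ["character", "radical", "stroke"]:
        if level not in levels:
            continue
        at_level = out["level"] == level
        for metric in ["latency_ms", "duration_ms"]:
            lo, hi = ExclusionRules.bounds(rules, level, metric)
            values = out.loc[at_level, metric]
            n_before = int(values.notna().sum())
            bad = pd.Series(False, index=values.index)
            rule_parts = []
            if lo is not None:
                bad |= values < lo
                rule_parts.append(f"< {lo:g} ms")
            if hi is not None:
                bad |= values > hi
                rule_parts.append(f"> {hi:g} ms")
            n_removed = int(bad.sum())
            out.loc[values.index[bad], metric] = np.nan
            report_rows.append(
                {
                    "level": level,
                    "metric": metric,
                    "rule": "removed if " + " or ".join(rule_parts),
                    "n_before": n_before,
                    "n_removed": n_removed,
                    "percent_removed": 100.0 * n_removed / n_before if n_before else 0.0,
                }
            )
    return out, pd.DataFrame(report_rows)
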