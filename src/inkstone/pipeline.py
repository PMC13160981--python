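"""End-to-end convenience layer: extract → code → filter → aggregate.

These helpers wire the modules together the way the CLI and the test-bench
use them, so a whole experiment can be analyzed in a few calls:

>>> exp = simulate_dataset(SimulationConfig(seed=1, n_participants=4, n_items=30))
>>> res = analyze_experiment(exp.samples, exp.events, exp.decomposition,
...                          raters=exp.raters)
>>> res.items.head()
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io import SELF_REPORT_AMNESIA, SELF_REPORT_DONT_KNOW
from .metrics import extract_metrics
from .qc import (
    CodingResult,
    ExclusionRules,
    apply_metric_exclusions,
    code_responses,
    filter_analysis_trials,
)
from .stats import aggregate_items

__all__ = ["PipelineResult", "analyze_experiment", "trial_character_table",
           "amnesia_trial_table", "self_report_codes"]


@dataclass
class PipelineResult:
    metrics: pd.DataFrame  # raw long-format metric table
    filtered: pd.DataFrame  # after metric-level exclusions
    exclusion_report: pd.DataFrame
    coding: CodingResult
    retained_trials: pd.Index
    items: pd.DataFrame  # one row per character


def self_report_codes(events: pd.DataFrame) -> pd.DataFrame:
    """Fallback coding when no rater table exists: trust the self-reports.

    Correct self-reports count as rater-correct and unrevised; everything
    else as incorrect.  Useful for smoke tests and datasets without manual
    checking, not a substitute for real rater codes.
    """
    raters = pd.DataFrame(
        {
            "trial_id": events["trial_id"],
            "rater_id": 1,
            "code": events["self_report"].map(
                lambda r: "correct" if r == 0 else "incorrect"
            ),
            "revised": 0,
        }
    )
    return raters


def analyze_experiment(
    samples: pd.DataFrame,
    events: pd.DataFrame,
    decomposition: pd.DataFrame | None = None,
    raters: pd.DataFrame | None = None,
    rules: ExclusionRules = ExclusionRules(),
    min_stroke_samples: int = 1,
    amnesia_denominator: str = "non_dont_know",
) -> PipelineResult:
    """Run extraction, response coding, exclusions, and item aggregation."""
    metrics = extract_metrics(
        samples, events, decomposition, min_stroke_samples=min_stroke_samples
    )
    if raters is None:
        raters = self_report_codes(events)
    coding = code_responses(events, raters)
    retained = filter_analysis_trials(coding.codes)
    filtered, report = apply_metric_exclusions(metrics, rules)
    items = aggregate_items(
        filtered, events, retained_trials=retained,
        amnesia_denominator=amnesia_denominator,
    )
    return PipelineResult(
        metrics=metrics,
        filtered=filtered,
        exclusion_report=report,
        coding=coding,
        retained_trials=retained,
        items=items,
    )


def trial_character_table(
    filtered_metrics: pd.DataFrame,
    retained_trials: pd.Index | None = None,
) -> pd.DataFrame:
    """Per-trial character-level measures, for split-half reliability."""
    char = filtered_metrics[filtered_metrics["level"] == "character"]
    if retained_trials is not None:
        char = char[char["trial_id"].isin(retained_trials)]
    return char[
        ["trial_id", "participant_id", "target_char", "latency_ms", "duration_ms"]
    ].rename(columns={"latency_ms": "char_latency", "duration_ms": "char_duration"})


def amnesia_trial_table(
    events: pd.DataFrame, denominator: str = "non_dont_know"
) -> pd.DataFrame:
    """Per-trial amnesia indicators (for split-half reliability of the rate)."""
    ev = events
    if denominator == "non_dont_know":
        ev = ev[ev["self_report"] != SELF_REPORT_DONT_KNOW]
    elif denominator != "all":
        raise ValueError("denominator must be 'non_dont_know' or 'all'")
    return pd.DataFrame(
        {
            "trial_id": ev["trial_id"],
            "participant_id": ev["participant_id"],
            "target_char": ev["target_char"],
            "amnesia": (ev["self_report"] == SELF_REPORT_AMNESIA).astype(float),
        }
    )
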