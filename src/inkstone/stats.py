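"""Item-level aggregation and the statistical battery.

Analyses are *item-level*: trials are collapsed to one row per target
character by averaging across participants, after the QC exclusions.
Radical- and stroke-level metrics are first averaged within a trial (across
that trial's units, skipping the first unit's undefined latency/distance) so
the character remains the unit of analysis at every orthographic level.

The battery covers:

* split-half reliability of item-level measures (random participant halves,
  Pearson r across items, Spearman–Brown prophecy correction),
* inter-rater ICC (two-way random effects, absolute agreement, single rater),
* a phi/Pearson correlation matrix with significance stars,
* stepwise variance-inflation-factor screening of the lexical predictors,
* ordinary least squares regressions of each handwriting measure on the 14
  z-scored lexical predictors with Benjamini–Hochberg FDR control, and
* cross-level contrast models with Level × predictor interaction terms.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .io import LEXICAL_PREDICTORS

__all__ = [
    "ITEM_MEASURES",
    "BINARY_PREDICTORS",
    "DEFAULT_COVARIATES",
    "ReliabilityResult",
    "CollinearityReport",
    "RegressionResult",
    "aggregate_items",
    "spearman_brown",
    "split_half_reliability",
    "icc_agreement",
    "correlation_matrix",
    "vif_screen",
    "fdr_adjust",
    "fit_item_regression",
    "fit_level_contrast",
    "zscore",
]

BINARY_PREDICTORS = ["phonogram", "phonetic_radical_order", "left_right", "top_down"]

#: Item-level handwriting measures produced by :func:`aggregate_items`.
ITEM_MEASURES = [
    "amnesia_rate",
    "char_latency",
    "char_duration",
    "char_length",
    "char_pressure",
    "radical_latency",
    "radical_duration",
    "radical_length",
    "radical_pressure",
    "radical_distance",
    "stroke_latency",
    "stroke_duration",
    "stroke_length",
    "stroke_pressure",
    "stroke_distance",
]

#: Handwriting covariates entered alongside the lexical predictors for some
#: outcomes, to account for mechanical confounds (e.g. a character's duration
#: partly reflects how much ink it takes and how long the pen travels between
#: strokes).  Covariates are exempt from the FDR family.
DEFAULT_COVARIATES: dict[str, list[str]] = {
    "char_duration": ["char_length", "stroke_distance", "stroke_latency"],
    "radical_latency": ["radical_distance"],
    "radical_duration": ["radical_length", "stroke_latency"],
    "stroke_latency": ["stroke_distance"],
}

_METRIC_MAP = {
    "latency_ms": "latency",
    "duration_ms": "duration",
    "length": "length",
    "pressure": "pressure",
    "distance": "distance",
}


def zscore(x: pd.Series | np.ndarray) -> np.ndarray:
    """Standardize to mean 0, SD 1 (population SD, NaN-aware)."""
    x = np.asarray(x, dtype=float)
    mu = np.nanmean(x)
    sd = np.nanstd(x)
    if sd == 0:
        raise ValueError("cannot z-score a constant column")
    return (x - mu) / sd


# ---------------------------------------------------------------------------
# aggregation


def aggregate_items(
    metrics: pd.DataFrame,
    events: pd.DataFrame,
    retained_trials: pd.Index | None = None,
    amnesia_denominator: str = "non_dont_know",
) -> pd.DataFrame:
    """Collapse trial-level metrics to one row per target character.

    ``metrics`` is the long table from :func:`~inkstone.metrics.extract_metrics`
    (after :func:`~inkstone.qc.apply_metric_exclusions`); ``retained_trials``
    is the rater-approved trial set from
    :func:`~inkstone.qc.filter_analysis_trials` (``None`` keeps all trials).

    Radical/stroke metrics are averaged within each trial across units, then
    across participants; character metrics directly across participants.
    The amnesia rate is the proportion of "character amnesia" self-reports
    per item, computed from *all* trials (amnesia trials carry no valid
    handwriting to time, so they can never survive the metric filters); the
    denominator excludes "don't know" trials by default
    (``amnesia_denominator="all"`` keeps them).
    """
    from .io import SELF_REPORT_AMNESIA, SELF_REPORT_DONT_KNOW

    m = metrics
    if retained_trials is not None:
        m = m[m["trial_id"].isin(retained_trials)]

    # within-trial average across units (no-op for the character level)
    per_trial = (
        m.groupby(["target_char", "trial_id", "level"], sort=False)[
            ["latency_ms", "duration_ms", "length", "pressure", "distance"]
        ]
        .mean()
        .reset_index()
    )
    per_item = (
        per_trial.groupby(["target_char", "level"], sort=False)
        .agg(
            latency_ms=("latency_ms", "mean"),
            duration_ms=("duration_ms", "mean"),
            length=("length", "mean"),
            pressure=("pressure", "mean"),
            distance=("distance", "mean"),
            n_trials=("trial_id", "size"),
        )
        .reset_index()
    )
    prefix = {"character": "char", "radical": "radical", "stroke": "stroke"}
    wide = per_item.pivot(index="target_char", columns="level")
    cols = {}
    for level in ["character", "radical", "stroke"]:
        for metric, short in _METRIC_MAP.items():
            if level == "character" and short == "distance":
                continue
            key = (metric, level)
            if key in wide.columns:
                cols[f"{prefix[level]}_{short}"] = wide[key]
    out = pd.DataFrame(cols)
    out["n_trials"] = wide[("n_trials", "character")] if ("n_trials", "character") in wide.columns else np.nan
    # every item with an event row appears, even if all its trials were excluded
    out = out.reindex(pd.Index(events["target_char"].unique()))

    # amnesia rate from self-reports, before metric exclusions
    ev = events.copy()
    if amnesia_denominator == "non_dont_know":
        ev = ev[ev["self_report"] != SELF_REPORT_DONT_KNOW]
    elif amnesia_denominator != "all":
        raise ValueError("amnesia_denominator must be 'non_dont_know' or 'all'")
    rate = (
        ev.assign(amnesia=ev["self_report"] == SELF_REPORT_AMNESIA)
        .groupby("target_char")["amnesia"]
        .mean()
    )
    out.insert(0, "amnesia_rate", rate)
    out.index.name = "character"

    missing = out[[c for c in out.columns if c != "n_trials"]].isna()
    if missing.any().any():
        n = int(missing.any(axis=1).sum())
        warnings.warn(f"{n} item(s) have at least one missing aggregated cell",
                      stacklevel=2)
    return out.reset_index()


# ---------------------------------------------------------------------------
# reliability


def spearman_brown(r_half: float) -> float:
    """Spearman–Brown prophecy correction for a half-test correlation.

    ``2 r / (1 + r)``: the predicted reliability of the full-length test from
    the correlation between two random halves.  Monotone on (−1, 1] and fixes
    0 and 1.
    """
    if not -1 < r_half <= 1:
        raise ValueError("r_half must lie in (-1, 1]")
    return 2.0 * r_half / (1.0 + r_half)


@dataclass
class ReliabilityResult:
    measure: str
    r_half: float
    r_corrected: float
    n_items: int
    half_a: list
    half_b: list


def split_half_reliability(
    trial_table: pd.DataFrame,
    measure: str,
    seed: int | np.random.Generator = 0,
    amnesia: bool = False,
) -> ReliabilityResult:
    """Split-half reliability of an item-level measure.

    Participants are randomly divided into two equal halves (with an odd
    count one participant is dropped at random and logged); the item-level
    measure is computed separately per half and correlated across items, then
    Spearman–Brown corrected.  ``trial_table`` needs columns
    ``participant_id``, ``target_char`` and ``measure`` (a per-trial value;
    with ``amnesia=True`` the measure is treated as a binary indicator and
    the item value is a proportion, which is the same arithmetic).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    participants = np.unique(trial_table["participant_id"].to_numpy())
    if len(participants) < 2:
        raise ValueError("need at least two participants")
    perm = rng.permutation(participants)
    if len(perm) % 2:
        dropped = perm[-1]
        warnings.warn(f"odd participant count: dropping participant {dropped}",
                      stacklevel=2)
        perm = perm[:-1]
    half = len(perm) // 2
    half_a, half_b = perm[:half], perm[half:]

    def item_means(ids: np.ndarray) -> pd.Series:
        sub = trial_table[trial_table["participant_id"].isin(ids)]
        return sub.groupby("target_char")[measure].mean()

    a, b = item_means(half_a), item_means(half_b)
    joined = pd.concat([a.rename("a"), b.rename("b")], axis=1)
    n_total = len(joined)
    joined = joined.dropna()
    if len(joined) < max(3, n_total / 2):
        raise ValueError(
            f"measure {measure!r} missing for too many items "
            f"({n_total - len(joined)} of {n_total})"
        )
    r_half = float(scipy.stats.pearsonr(joined["a"], joined["b"])[0])
    return ReliabilityResult(
        measure=measure,
        r_half=r_half,
        r_corrected=spearman_brown(r_half),
        n_items=len(joined),
        half_a=sorted(half_a.tolist()),
        half_b=sorted(half_b.tolist()),
    )


def icc_agreement(ratings: pd.DataFrame) -> tuple[float, tuple[float, float]]:
    """Inter-rater ICC for an items × raters table of codes.

    Uses the two-way random-effects, absolute-agreement, single-rater model
    (ICC(2,1)): every penscript is coded by the same number of interchangeable
    raters drawn from a larger pool.  Returns the ICC and its 95% F-based
    confidence interval.  Constant ratings leave the variance decomposition
    degenerate and raise.
    """
    if ratings.shape[1] < 2:
        raise ValueError("need at least two raters")
    values = ratings.to_numpy(dtype=float)
    if np.allclose(values, values.flat[0]):
        raise ValueError("ICC undefined for constant ratings")
    long = ratings.reset_index(drop=True).reset_index(names="item").melt(
        id_vars="item", var_name="rater", value_name="score"
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = pg.intraclass_corr(
            data=long, targets="item", raters="rater", ratings="score"
        ).set_index("Type")
    # the two-way random, absolute agreement, single-rater row (naming varies
    # across pingouin versions)
    key = "ICC2" if "ICC2" in table.index else "ICC(A,1)"
    row = table.loc[key]
    ci = row["CI95%"] if "CI95%" in row.index else row["CI95"]
    return float(row["ICC"]), (float(ci[0]), float(ci[1]))


# ---------------------------------------------------------------------------
# correlations and collinearity


def correlation_matrix(
    df: pd.DataFrame, columns: list[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pairwise correlation matrix with significance stars.

    Pearson r throughout; for a pair of binary (sum-coded) variables this
    equals the phi coefficient.  Returns (r, p, stars) frames; zero-variance
    columns yield NaN entries and a warning.  Stars: * p<.05, ** p<.01,
    *** p<.001.
    """
    cols = columns or [c for c in df.columns if pd.api.types.is_numeric_dtype(df[c])]
    k = len(cols)
    r = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((k, k)), index=cols, columns=cols)
    for i in range(k):
        for j in range(i + 1, k):
            pair = df[[cols[i], cols[j]]].dropna()
            xi, xj = pair[cols[i]], pair[cols[j]]
            if xi.nunique() < 2 or xj.nunique() < 2:
                warnings.warn(f"zero variance in pair ({cols[i]}, {cols[j]})",
                              stacklevel=2)
                rij, pij = np.nan, np.nan
            else:
                rij, pij = scipy.stats.pearsonr(xi, xj)
            r.iloc[i, j] = r.iloc[j, i] = rij
            p.iloc[i, j] = p.iloc[j, i] = pij
    stars = p.map(
        lambda v: "***" if v < 0.001 else "**" if v < 0.01 else "*" if v < 0.05 else ""
    )
    np.fill_diagonal(stars.values, "")
    return r, p, stars


@dataclass
class CollinearityReport:
    threshold: float
    steps: list[pd.DataFrame]  # VIF table per elimination step
    dropped: list[str]
    retained: list[str]

    @property
    def final_vif(self) -> pd.Series:
        return self.steps[-1].set_index("predictor")["vif"]


def _vifs(X: pd.DataFrame) -> pd.Series:
    """VIF_j = 1 / (1 - R²_j) regressing predictor j on the others + intercept."""
    out = {}
    for col in X.columns:
        others = sm.add_constant(X.drop(columns=[col]))
        r2 = sm.OLS(X[col], others).fit().rsquared
        out[col] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


def vif_screen(X: pd.DataFrame, threshold: float = 5.0) -> CollinearityReport:
    """Stepwise variance-inflation-factor screening.

    Iteratively drops the predictor with the highest VIF while any VIF is at
    or above ``threshold``; ties (including perfect collinearity, VIF = ∞)
    break toward the alphabetically last name, with a warning for perfect
    collinearity.  Records the VIF table at every step.
    """
    if X.shape[1] < 2:
        raise ValueError("need at least two predictors")
    if X.shape[0] <= X.shape[1]:
        raise ValueError("need more observations than predictors")
    X = X.astype(float)
    steps, dropped = [], []
    while True:
        vifs = _vifs(X)
        steps.append(
            pd.DataFrame({"predictor": vifs.index, "vif": vifs.to_numpy()})
        )
        worst = vifs[vifs == vifs.max()]
        if vifs.max() < threshold:
            break
        victim = sorted(worst.index)[-1]
        if math.isinf(vifs.max()):
            warnings.warn(
                f"perfect collinearity: dropping {victim!r}", stacklevel=2
            )
        dropped.append(victim)
        X = X.drop(columns=[victim])
        if X.shape[1] < 2:
            break
    return CollinearityReport(
        threshold=threshold,
        steps=steps,
        dropped=dropped,
        retained=list(X.columns),
    )


def fdr_adjust(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up over one family of p values.

    Returns (significance flags, adjusted p values) at level ``q``.
    """
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p values must lie in [0, 1]")
    flags, p_adj = multipletests(p, alpha=q, method="fdr_bh")[:2]
    return flags, p_adj


# ---------------------------------------------------------------------------
# regression battery


@dataclass
class RegressionResult:
    outcome: str
    terms: pd.DataFrame  # term, beta, t, p, p_fdr, significant, in_fdr_family
    r_squared: float
    n: int
    covariates: list[str] = field(default_factory=list)

    def coef(self, term: str) -> float:
        return float(self.terms.set_index("term").loc[term, "beta"])


def _fit_ols(y: pd.Series, X: pd.DataFrame, family: list[str]) -> tuple[pd.DataFrame, float, int]:
    if len(y) <= X.shape[1] + 1:
        raise ValueError("not enough items for the number of model terms")
    model = sm.OLS(y, sm.add_constant(X)).fit()
    terms = pd.DataFrame(
        {
            "term": model.params.index,
            "beta": model.params.to_numpy(),
            "t": model.tvalues.to_numpy(),
            "p": model.pvalues.to_numpy(),
        }
    )
    terms["in_fdr_family"] = terms["term"].isin(family)
    terms["p_fdr"] = np.nan
    terms["significant"] = False
    fam = terms["in_fdr_family"]
    if fam.any():
        flags, p_adj = fdr_adjust(terms.loc[fam, "p"].to_numpy())
        terms.loc[fam, "p_fdr"] = p_adj
        terms.loc[fam, "significant"] = flags
    return terms, float(model.rsquared), int(model.nobs)


def fit_item_regression(
    items: pd.DataFrame,
    norms: pd.DataFrame,
    outcome: str,
    covariates: list[str] | None = None,
    predictors: list[str] | None = None,
) -> RegressionResult:
    """OLS of one item-level handwriting measure on the lexical predictors.

    All predictors (and any handwriting covariates, taken from
    :data:`DEFAULT_COVARIATES` when ``covariates`` is None) are z-transformed
    over the analysis sample before entry.  FDR flags are computed over the
    lexical-predictor family only; the intercept and covariates are exempt.
    """
    predictors = predictors if predictors is not None else list(LEXICAL_PREDICTORS)
    if covariates is None:
        covariates = DEFAULT_COVARIATES.get(outcome, [])
    data = items.merge(norms, on="character", how="inner")
    use = data[[outcome] + predictors + covariates].dropna()
    X = pd.DataFrame({c: zscore(use[c]) for c in predictors + covariates},
                     index=use.index)
    terms, r2, n = _fit_ols(use[outcome], X, family=predictors)
    return RegressionResult(outcome=outcome, terms=terms, r_squared=r2, n=n,
                            covariates=covariates)


def fit_level_contrast(
    items: pd.DataFrame,
    norms: pd.DataFrame,
    measure: str,
    pair: tuple[str, str],
    include_length: bool | None = None,
) -> RegressionResult:
    """Cross-level contrast model for one unit-level pair.

    Stacks the two levels' item means of ``measure`` ("latency" or
    "duration") in long format, codes Level as ±0.5 (+0.5 for the coarser of
    the pair, given the character ⊃ radical ⊃ stroke ordering), and fits OLS
    with the 14 lexical main effects, the Level term, and Level × predictor
    interactions.  Duration models additionally enter the per-level ink
    Length and its Level interaction (``include_length`` overrides).  The FDR
    family covers the lexical main effects and all Level × interactions;
    Level itself and the Length covariate are exempt.

    Items missing the measure at either level are dropped from the pair.
    """
    hierarchy = ["character", "radical", "stroke"]
    coarse, fine = sorted(pair, key=hierarchy.index)
    if include_length is None:
        include_length = measure == "duration"
    prefix = {"character": "char", "radical": "radical", "stroke": "stroke"}

    frames = []
    for level, code in [(coarse, +0.5), (fine, -0.5)]:
        cols = {"character": items["character"],
                "y": items[f"{prefix[level]}_{measure}"],
                "level_code": code}
        if include_length:
            cols["length"] = items[f"{prefix[level]}_length"]
        frames.append(pd.DataFrame(cols))
    long = pd.concat(frames, ignore_index=True)
    n_levels = long.dropna(subset=["y"]).groupby("character")["level_code"].nunique()
    complete = n_levels[n_levels == 2].index
    dropped = n_levels.index.difference(complete)
    if len(dropped):
        warnings.warn(
            f"{len(dropped)} item(s) missing {measure} at one level of "
            f"{coarse}-vs-{fine}; dropped", stacklevel=2,
        )
    long = long[long["character"].isin(complete)].dropna(subset=["y"])
    long = long.merge(norms, on="character", how="inner")

    predictors = list(LEXICAL_PREDICTORS)
    X = pd.DataFrame({c: zscore(long[c]) for c in predictors}, index=long.index)
    X["Level"] = long["level_code"].to_numpy()
    family = list(predictors)
    if include_length:
        X["Length"] = zscore(long["length"])
    for c in predictors + (["Length"] if include_length else []):
        X[f"Level:{c}"] = X["Level"] * X[c]
        family.append(f"Level:{c}")
    terms, r2, n = _fit_ols(long["y"].astype(float), X, family=family)
    return RegressionResult(
        outcome=f"{measure}[{coarse} vs {fine}]",
        terms=terms,
        r_squared=r2,
        n=n,
        covariates=["Level"] + (["Length"] if include_length else []),
    )
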