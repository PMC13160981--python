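import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from inkstone.io import LEXICAL_PREDICTORS
from inkstone.simulate import SimulationConfig, simulate_norms
from inkstone.stats import (
    aggregate_items,
    correlation_matrix,
    fdr_adjust,
    fit_item_regression,
    fit_level_contrast,
    icc_agreement,
    spearman_brown,
    split_half_reliability,
    vif_screen,
    zscore,
)

from conftest import make_event
from oracles import brute_bh_stepup


class TestSpearmanBrown:
    @pytest.mark.parametrize(
        "r, expected", [(0.9, 2 * 0.9 / 1.9), (0.0, 0.0), (1.0, 1.0), (0.5, 2 / 3)]
    )
    def test_closed_form(self, r, expected):
        assert spearman_brown(r) == pytest.approx(expected)

    def test_monotone_and_fixed_points(self):
        grid = np.linspace(-0.99, 1.0, 400)
        vals = [spearman_brown(r) for r in grid]
        assert np.all(np.diff(vals) > 0)

    def test_undefined_at_minus_one(self):
        with pytest.raises(ValueError):
            spearman_brown(-1.0)


class TestFdrAdjust:
    def test_examples(self):
        flags, _ = fdr_adjust([0.001, 0.02, 0.04])
        assert flags.tolist() == [True, True, True]
        flags, _ = fdr_adjust([0.9, 0.95])
        assert flags.tolist() == [False, False]
        assert fdr_adjust([0.01])[0].tolist() == [True]
        assert fdr_adjust([0.06])[0].tolist() == [False]

    @settings(max_examples=200, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_matches_brute_force_stepup(self, ps):
        flags, _ = fdr_adjust(ps)
        assert flags.tolist() == brute_bh_stepup(ps)

    def test_nested_between_bonferroni_and_raw(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            ps = rng.random(12) ** 2
            flags, _ = fdr_adjust(ps)
            bonf = ps <= 0.05 / len(ps)
            raw = ps <= 0.05
            assert (flags | raw).tolist() == raw.tolist()  # subset of raw
            assert (flags & bonf).tolist() == bonf.tolist()  # superset of Bonferroni

    def test_rejects_invalid_p(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.5])


class TestVifScreen:
    def test_orthogonal_predictors_all_retained(self):
        rng = np.random.default_rng(0)
        q, _ = np.linalg.qr(rng.normal(size=(60, 3)))
        X = pd.DataFrame(q, columns=["a", "b", "c"])
        report = vif_screen(X)
        assert report.retained == ["a", "b", "c"]
        assert np.allclose(report.final_vif.to_numpy(), 1.0, atol=0.01)

    def test_two_correlated_predictors_closed_form(self):
        # correlation 0.9 -> VIF = 1/(1-0.81) ~ 5.26 >= 5 -> one dropped
        rng = np.random.default_rng(1)
        n = 100_000
        x = rng.normal(size=n)
        y = 0.9 * x + np.sqrt(1 - 0.81) * rng.normal(size=n)
        X = pd.DataFrame({"a": x, "b": y})
        r = np.corrcoef(x, y)[0, 1]
        report = vif_screen(X)
        expected = 1.0 / (1.0 - r**2)
        assert report.steps[0]["vif"].iloc[0] == pytest.approx(expected, abs=1e-6)
        assert len(report.dropped) == 1

    def test_exact_copy_dropped_with_warning(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=50)
        X = pd.DataFrame({"x1": x, "x2": x.copy(), "z": rng.normal(size=50)})
        with pytest.warns(UserWarning, match="perfect collinearity"):
            report = vif_screen(X)
        assert "x2" in report.dropped
        assert "z" in report.retained

    def test_order_independence_for_orthogonal(self):
        rng = np.random.default_rng(3)
        q, _ = np.linalg.qr(rng.normal(size=(40, 4)))
        X = pd.DataFrame(q, columns=list("abcd"))
        r1 = vif_screen(X)
        r2 = vif_screen(X[list("dcba")])
        assert set(r1.retained) == set(r2.retained)


class TestCorrelationMatrix:
    def test_self_correlation_and_phi(self):
        # phi from a 2x2 table (10,0;0,10) is 1; (25,25;25,25) is 0
        a = np.repeat([0.5, -0.5], 10)
        perfect = pd.DataFrame({"u": a, "v": a})
        r, _, _ = correlation_matrix(perfect)
        assert r.loc["u", "u"] == 1.0
        assert r.loc["u", "v"] == pytest.approx(1.0)

        u = np.repeat([0.5, -0.5], 50)
        v = np.tile(np.repeat([0.5, -0.5], 25), 2)
        balanced = pd.DataFrame({"u": u, "v": v})
        r, _, _ = correlation_matrix(balanced)
        assert r.loc["u", "v"] == pytest.approx(0.0, abs=1e-12)

    def test_stars_track_p_values(self):
        rng = np.random.default_rng(7)
        n = 200
        x = rng.normal(size=n)
        df = pd.DataFrame({"x": x, "strong": x + 0.1 * rng.normal(size=n),
                           "noise": rng.normal(size=n)})
        _, p, stars = correlation_matrix(df)
        assert stars.loc["x", "strong"] == "***"
        assert (p.loc["x", "noise"] < 0.05) == (stars.loc["x", "noise"] != "")

    def test_zero_variance_column_warns(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]})
        with pytest.warns(UserWarning, match="zero variance"):
            r, _, _ = correlation_matrix(df)
        assert np.isnan(r.loc["a", "b"])


class TestIcc:
    def test_perfect_agreement(self):
        items = np.repeat(np.arange(1, 21), 1)
        ratings = pd.DataFrame({"r1": items, "r2": items, "r3": items})
        icc, _ = icc_agreement(ratings)
        assert icc == pytest.approx(1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(11)
        ratings = pd.DataFrame(rng.random((500, 3)), columns=["r1", "r2", "r3"])
        icc, _ = icc_agreement(ratings)
        assert abs(icc) < 0.1

    def test_designed_variance_ratio(self):
        # between-item variance 4x error variance -> ICC = 4/5 = 0.8
        rng = np.random.default_rng(13)
        n_items, n_raters = 600, 3
        item_effect = rng.normal(0, 2.0, n_items)
        data = item_effect[:, None] + rng.normal(0, 1.0, (n_items, n_raters))
        icc, (lo, hi) = icc_agreement(pd.DataFrame(data, columns=["a", "b", "c"]))
        assert icc == pytest.approx(0.8, abs=0.05)
        assert lo <= icc <= hi

    def test_constant_ratings_undefined(self):
        ratings = pd.DataFrame({"r1": [1, 1, 1], "r2": [1, 1, 1]})
        with pytest.raises(ValueError, match="constant"):
            icc_agreement(ratings)


def trial_table(rng, n_participants, n_items, sigma_item, sigma_e, measure="y"):
    item_effect = rng.normal(0, sigma_item, n_items)
    rows = []
    for p in range(n_participants):
        for i in range(n_items):
            rows.append(
                {
                    "participant_id": p + 1,
                    "target_char": chr(0x4E00 + i),
                    measure: 100 + item_effect[i] + rng.normal(0, sigma_e),
                }
            )
    return pd.DataFrame(rows)


class TestSplitHalf:
    def test_identical_halves_give_unity(self):
        rng = np.random.default_rng(0)
        t = trial_table(rng, 1, 50, sigma_item=10, sigma_e=0)
        # duplicate the single participant so both halves are exact copies
        t2 = t.copy()
        t2["participant_id"] = 2
        res = split_half_reliability(pd.concat([t, t2]), "y", seed=1)
        assert res.r_half == pytest.approx(1.0)
        assert res.r_corrected == pytest.approx(1.0)

    def test_matches_closed_form_reliability(self):
        # the prophecy-corrected r estimates the full-sample reliability
        # sigma_item^2 / (sigma_item^2 + sigma_e^2 / n_total):
        # r_half = a/(a+b) with a = sigma_item^2, b = sigma_e^2/n_half, and
        # 2r/(1+r) = a/(a+b/2)
        rng = np.random.default_rng(21)
        sigma_item, sigma_e, n_half = 30.0, 60.0, 10
        theory = sigma_item**2 / (sigma_item**2 + sigma_e**2 / (2 * n_half))
        vals = []
        for rep in range(60):
            t = trial_table(rng, 2 * n_half, 150, sigma_item, sigma_e)
            res = split_half_reliability(t, "y", seed=rng)
            vals.append(res.r_corrected)
        mc_se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert np.mean(vals) == pytest.approx(theory, abs=3 * mc_se + 0.01)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(22)
        t = trial_table(rng, 10, 1200, sigma_item=0.0, sigma_e=50.0)
        res = split_half_reliability(t, "y", seed=3)
        assert abs(res.r_corrected) < 0.1

    def test_odd_participant_dropped_with_warning(self):
        rng = np.random.default_rng(23)
        t = trial_table(rng, 5, 30, 10, 5)
        with pytest.warns(UserWarning, match="odd participant count"):
            res = split_half_reliability(t, "y", seed=0)
        assert len(res.half_a) == len(res.half_b) == 2

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(24)
        t = trial_table(rng, 8, 60, 10, 20)
        r1 = split_half_reliability(t, "y", seed=7)
        r2 = split_half_reliability(t, "y", seed=7)
        assert r1.r_half == r2.r_half and r1.half_a == r2.half_a


class TestAggregateItems:
    def metrics_for(self, rows):
        base = {
            "participant_id": 1,
            "item_number": 1,
            "target_char": "稻",
            "length": np.nan,
            "pressure": np.nan,
            "distance": np.nan,
            "flags": "",
        }
        return pd.DataFrame([{**base, **r} for r in rows])

    def test_units_average_within_trial_then_across(self):
        metrics = self.metrics_for(
            [
                {"trial_id": 1, "level": "character", "unit_index": 1,
                 "latency_ms": 900.0, "duration_ms": 2000.0},
                {"trial_id": 1, "level": "radical", "unit_index": 1,
                 "latency_ms": np.nan, "duration_ms": 450.0},
                {"trial_id": 1, "level": "radical", "unit_index": 2,
                 "latency_ms": 100.0, "duration_ms": 350.0},
                {"trial_id": 2, "level": "character", "unit_index": 1,
                 "latency_ms": 1100.0, "duration_ms": 2200.0},
                {"trial_id": 2, "level": "radical", "unit_index": 1,
                 "latency_ms": np.nan, "duration_ms": 300.0},
                {"trial_id": 2, "level": "radical", "unit_index": 2,
                 "latency_ms": 200.0, "duration_ms": 500.0},
            ]
        )
        events = pd.concat(
            [make_event(trial_id=1), make_event(trial_id=2, participant_id=2)],
            ignore_index=True,
        )
        items = aggregate_items(metrics, events)
        row = items.set_index("character").loc["稻"]
        assert row["char_latency"] == pytest.approx(1000.0)  # (900+1100)/2
        assert row["radical_latency"] == pytest.approx(150.0)  # (100+200)/2
        assert row["radical_duration"] == pytest.approx((400 + 400) / 2)
        assert row["amnesia_rate"] == 0.0

    def test_amnesia_rate_counts_self_reports(self):
        events = pd.concat(
            [make_event(trial_id=i + 1, participant_id=i + 1, self_report=r)
             for i, r in enumerate([1, 0, 0, 2, 0, 0, 1])],
            ignore_index=True,
        )
        metrics = self.metrics_for(
            [{"trial_id": 2, "level": "character", "unit_index": 1,
              "latency_ms": 1000.0, "duration_ms": 2000.0}]
        )
        items = aggregate_items(metrics, events)
        # 2 amnesia of 6 non-don't-know trials
        assert items.loc[0, "amnesia_rate"] == pytest.approx(2 / 6)
        items_all = aggregate_items(metrics, events, amnesia_denominator="all")
        assert items_all.loc[0, "amnesia_rate"] == pytest.approx(2 / 7)

    def test_retained_trials_respected_and_participant_relabeling(self):
        metrics = self.metrics_for(
            [
                {"trial_id": 1, "level": "character", "unit_index": 1,
                 "latency_ms": 900.0, "duration_ms": 2000.0},
                {"trial_id": 2, "level": "character", "unit_index": 1,
                 "latency_ms": 1100.0, "duration_ms": 2200.0},
                {"trial_id": 3, "level": "character", "unit_index": 1,
                 "latency_ms": 5000.0, "duration_ms": 9000.0},
            ]
        )
        events = pd.concat(
            [make_event(trial_id=i, participant_id=i) for i in (1, 2, 3)],
            ignore_index=True,
        )
        items = aggregate_items(metrics, events, retained_trials=pd.Index([1, 2]))
        assert items.loc[0, "char_latency"] == pytest.approx(1000.0)
        # relabeling participants must not change item means
        relabeled = events.copy()
        relabeled["participant_id"] = relabeled["participant_id"].map({1: 9, 2: 4, 3: 7})
        m2 = metrics.copy()
        m2["participant_id"] = m2["trial_id"].map({1: 9, 2: 4, 3: 7})
        items2 = aggregate_items(m2, relabeled, retained_trials=pd.Index([1, 2]))
        assert items2.loc[0, "char_latency"] == items.loc[0, "char_latency"]


def make_norms(n_items=400, seed=0):
    cfg = SimulationConfig(seed=seed, n_items=n_items)
    return simulate_norms(cfg, np.random.default_rng(seed))


class TestItemRegression:
    def test_zero_noise_recovery(self):
        norms = make_norms(300)
        items = pd.DataFrame({"character": norms["character"]})
        items["char_latency"] = 1000 + 2.0 * zscore(norms["frequency"])
        res = fit_item_regression(items, norms, "char_latency", covariates=[])
        assert res.coef("frequency") == pytest.approx(2.0, abs=1e-8)
        others = res.terms.set_index("term")["beta"].drop(["const", "frequency"])
        assert np.allclose(others.to_numpy(), 0.0, atol=1e-8)
        assert res.r_squared == pytest.approx(1.0)

    def test_outcome_equal_to_covariate_gives_r2_one(self):
        norms = make_norms(200, seed=3)
        rng = np.random.default_rng(3)
        items = pd.DataFrame({"character": norms["character"]})
        items["stroke_distance"] = rng.normal(size=len(norms))
        items["char_duration"] = items["stroke_distance"] * 3.0
        items["char_length"] = rng.normal(size=len(norms))
        items["stroke_latency"] = rng.normal(size=len(norms))
        res = fit_item_regression(items, norms, "char_duration")
        assert res.covariates == ["char_length", "stroke_distance", "stroke_latency"]
        assert res.r_squared == pytest.approx(1.0)

    def test_fdr_family_excludes_intercept_and_covariates(self):
        norms = make_norms(250, seed=4)
        rng = np.random.default_rng(4)
        items = pd.DataFrame({"character": norms["character"]})
        items["stroke_distance"] = rng.normal(size=len(norms))
        items["stroke_latency"] = (
            500 + 50 * items["stroke_distance"] + rng.normal(0, 5, len(norms))
        )
        res = fit_item_regression(items, norms, "stroke_latency")
        fam = res.terms.set_index("term")["in_fdr_family"]
        assert not fam["const"] and not fam["stroke_distance"]
        assert fam[LEXICAL_PREDICTORS].all()


class TestLevelContrast:
    def test_pure_level_shift_recovered(self):
        norms = make_norms(150, seed=5)
        rng = np.random.default_rng(5)
        base = 500 + 20 * zscore(norms["frequency"])
        items = pd.DataFrame({"character": norms["character"]})
        items["char_latency"] = base + 400  # character slower by a pure shift
        items["radical_latency"] = base
        res = fit_level_contrast(items, norms, "latency", ("character", "radical"))
        assert res.coef("Level") == pytest.approx(400.0, abs=1e-8)
        inter = res.terms[res.terms["term"].str.startswith("Level:")]["beta"]
        assert np.allclose(inter, 0.0, atol=1e-8)

    def test_interaction_recovers_cascaded_attenuation(self):
        # effect b at the coarse level, b/2 at the fine level -> Level:freq = b/2
        norms = make_norms(400, seed=6)
        rng = np.random.default_rng(6)
        b = 60.0
        zf = zscore(norms["frequency"])
        items = pd.DataFrame({"character": norms["character"]})
        noise = rng.normal(0, 1.0, len(norms))
        items["char_latency"] = 1000 + b * zf + noise
        items["stroke_latency"] = 120 + (b / 2) * zf + rng.normal(0, 1.0, len(norms))
        res = fit_level_contrast(items, norms, "latency", ("character", "stroke"))
        assert res.coef("Level:frequency") == pytest.approx(b / 2, abs=1.0)
        assert res.coef("Level:frequency") > 0

    def test_identical_levels_give_zero_level_effect(self):
        norms = make_norms(120, seed=7)
        rng = np.random.default_rng(7)
        y = 300 + rng.normal(0, 10, len(norms))
        items = pd.DataFrame({"character": norms["character"]})
        items["radical_latency"] = y
        items["stroke_latency"] = y
        res = fit_level_contrast(items, norms, "latency", ("radical", "stroke"))
        assert res.coef("Level") == pytest.approx(0.0, abs=1e-9)

    def test_duration_models_include_length_interaction(self):
        norms = make_norms(150, seed=8)
        rng = np.random.default_rng(8)
        items = pd.DataFrame({"character": norms["character"]})
        items["char_duration"] = rng.normal(2200, 100, len(norms))
        items["stroke_duration"] = rng.normal(148, 10, len(norms))
        items["char_length"] = rng.normal(40, 5, len(norms))
        items["stroke_length"] = rng.normal(5, 1, len(norms))
        res = fit_level_contrast(items, norms, "duration", ("character", "stroke"))
        terms = set(res.terms["term"])
        assert {"Length", "Level:Length"} <= terms
        fam = res.terms.set_index("term")["in_fdr_family"]
        assert not fam["Length"] and not fam["Level"]
        assert fam["Level:Length"]

    def test_item_missing_one_level_dropped(self):
        norms = make_norms(80, seed=9)
        rng = np.random.default_rng(9)
        items = pd.DataFrame({"character": norms["character"]})
        items["char_latency"] = rng.normal(1000, 50, len(norms))
        items["radical_latency"] = rng.normal(150, 10, len(norms))
        items.loc[0, "radical_latency"] = np.nan
        with pytest.warns(UserWarning, match="missing latency at one level"):
            res = fit_level_contrast(items, norms, "latency", ("character", "radical"))
        assert res.n == 2 * (len(norms) - 1)
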