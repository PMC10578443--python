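"""Split plans, metrics, nested CV, attribution, curves, reports."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from e4wild import (
    FEATURE_NAMES,
    TrainingSet,
    binary_metrics,
    compare_personal_vs_temporal,
    downsample_other_participants,
    fit_inverse_power_law,
    fit_model,
    make_split_plan,
    oversample_positives,
    permutation_importance_report,
    roc_threshold_sweep,
    run_nested_cv,
    run_temporal_per_participant,
    simulate_lab_session,
    standardize,
    tree_path_attribution,
)
from e4wild.reports import acceptability_report, rest_vs_exposure_report

from conftest import SMALL_GRID


def fake_table(n_participants=4, rows_per=30, days=10, seed=0):
    """Synthetic feature-table skeleton with random feature values."""
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_participants):
        for i in range(rows_per):
            rows.append({
                "participant": f"P{p:02d}", "session": f"P{p:02d}_s0",
                "label": "event" if rng.random() < 0.4 else "nonevent",
                "day_index": int(i * days / rows_per),
                "start": 0.0, "end": 300.0,
                **{f: rng.normal() for f in FEATURE_NAMES},
            })
    return pd.DataFrame(rows)


class TestSplitPlans:
    def test_random_plan_covers_every_row_once(self):
        t = fake_table()
        plan = make_split_plan(t, "random", seed=0, outer_k=10)
        plan.check_disjoint()
        seen = np.concatenate([f.test for f in plan.folds])
        assert sorted(seen) == list(range(len(t)))

    def test_participant_plan_has_one_fold_per_participant(self):
        t = fake_table(n_participants=8)
        plan = make_split_plan(t, "participant", seed=0)
        assert len(plan.folds) == 8
        for f in plan.folds:
            te = set(t.loc[f.test, "participant"])
            assert len(te) == 1
            assert te.isdisjoint(set(t.loc[f.train, "participant"]))

    def test_participant_plan_needs_three(self):
        with pytest.raises(ValueError):
            make_split_plan(fake_table(n_participants=2), "participant")

    def test_temporal_day_arithmetic(self):
        """40 observation days split as train 0-29, val 30-34, test 35-39."""
        t = fake_table(n_participants=1, rows_per=40, days=40)
        plan = make_split_plan(t, "temporal", seed=0)
        f = plan.folds[0]
        assert t.loc[f.train, "day_index"].max() == 29
        assert sorted(t.loc[f.validation, "day_index"].unique()) == [30, 31, 32, 33, 34]
        assert sorted(t.loc[f.test, "day_index"].unique()) == [35, 36, 37, 38, 39]

    def test_temporal_ordering_invariant(self, temporal_table):
        plan = make_split_plan(temporal_table, "temporal", seed=0)
        f = plan.folds[0]
        for p, g in temporal_table.groupby("participant"):
            tr = temporal_table.loc[f.train]
            va = temporal_table.loc[f.validation]
            te = temporal_table.loc[f.test]
            tr_d = tr[tr["participant"] == p]["day_index"]
            va_d = va[va["participant"] == p]["day_index"]
            te_d = te[te["participant"] == p]["day_index"]
            if len(va_d) and len(tr_d):
                assert tr_d.max() < va_d.min()
            if len(te_d) and len(va_d):
                assert va_d.min() <= te_d.min()

    def test_personalized_skips_short_participants(self):
        t = pd.concat([fake_table(1, 40, days=20, seed=0),
                       fake_table(1, 6, days=3, seed=1).assign(participant="PX")],
                      ignore_index=True)
        plan = make_split_plan(t, "personalized", seed=0, min_days_personal=8)
        assert [f.test_participant for f in plan.folds] == ["P00"]


class TestMetrics:
    def test_identities_and_conventions(self):
        y = np.array([1, 1, 0, 0, 1, 0])
        yhat = np.array([1, 0, 0, 1, 1, 0])
        m = binary_metrics(y, yhat, scores=yhat.astype(float))
        assert m["accuracy"] == pytest.approx(4 / 6)
        p, r = m["precision"], m["recall"]
        assert m["f1"] == pytest.approx(2 * p * r / (p + r))

    def test_no_positive_predictions_gives_zero_precision(self):
        m = binary_metrics([1, 0, 1], [0, 0, 0])
        assert m["precision"] == 0 and m["f1"] == 0

    def test_auc_equals_concordance_on_toy_set(self):
        """Trapezoid AUC equals the brute-force pairwise concordance
        probability over all positive-negative pairs."""
        y = np.array([0, 0, 0, 1, 1, 1])
        s = np.array([0.1, 0.4, 0.35, 0.8, 0.3, 0.9])
        res = roc_threshold_sweep(s, y)
        pairs, conc = 0, 0.0
        for sp in s[y == 1]:
            for sn in s[y == 0]:
                pairs += 1
                conc += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
        assert res["auc"] == pytest.approx(conc / pairs)

    def test_perfect_separation(self):
        y = np.array([0, 0, 1, 1])
        res = roc_threshold_sweep(np.array([0.1, 0.2, 0.8, 0.9]), y)
        assert res["auc"] == 1.0
        assert res["operating_points"][0.9]["fpr"] == 0.0

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 50)
        y[:2] = [0, 1]
        s = rng.random(50)
        a = roc_threshold_sweep(s, y)["auc"]
        b = roc_threshold_sweep(np.exp(5 * s), y)["auc"]
        assert a == pytest.approx(b)

    def test_single_class_is_error(self):
        with pytest.raises(ValueError):
            roc_threshold_sweep(np.array([0.1, 0.9]), np.array([1, 1]))


class TestNestedCV:
    def test_strong_effect_beats_baseline(self, effect_table):
        plan = make_split_plan(effect_table, "random", seed=0, outer_k=5)
        res = run_nested_cv(effect_table, plan, grid=SMALL_GRID, seed=0,
                            inner_k=3)
        assert res.mean("accuracy") > res.baseline_accuracy + 0.1
        assert res.mean("roc_auc") > 0.8

    def test_participant_weights_sum_to_one(self, effect_table):
        plan = make_split_plan(effect_table, "participant", seed=0)
        res = run_nested_cv(effect_table, plan, grid=SMALL_GRID, seed=0)
        w = res.per_fold["n_test"] / res.per_fold["n_test"].sum()
        assert w.sum() == pytest.approx(1.0)

    def test_temporal_repetitions_recorded(self, temporal_table):
        plan = make_split_plan(temporal_table, "temporal", seed=0,
                               n_repetitions=3)
        res = run_nested_cv(temporal_table, plan, grid=SMALL_GRID, seed=0)
        assert len(res.per_fold) == 3
        assert res.summary.loc["accuracy", "se"] >= 0


class TestPersonalVsTemporal:
    def test_identical_arms_give_zero_increase(self):
        a = pd.DataFrame({"participant": ["P0"] * 3, "rep": range(3),
                          "accuracy": [0.8, 0.7, 0.9]})
        out = compare_personal_vs_temporal(a, a.copy(), metrics=("accuracy",))
        assert out["mean_increase"].iloc[0] == 0
        assert out["p_value"].iloc[0] == 1.0

    def test_constant_shift_recovered(self):
        a = pd.DataFrame({"participant": ["P0"] * 4, "rep": range(4),
                          "accuracy": [0.6, 0.7, 0.65, 0.72]})
        b = a.copy()
        b["accuracy"] += 0.05
        out = compare_personal_vs_temporal(a, b, metrics=("accuracy",))
        assert out["mean_increase"].iloc[0] == pytest.approx(0.05)

    def test_t_statistic_matches_closed_form(self):
        rng = np.random.default_rng(1)
        diffs = 0.05 + 0.02 * rng.normal(size=10)
        a = pd.DataFrame({"participant": ["P0"] * 10, "rep": range(10),
                          "accuracy": 0.7 * np.ones(10)})
        b = a.copy()
        b["accuracy"] = a["accuracy"] + diffs
        out = compare_personal_vs_temporal(a, b, metrics=("accuracy",))
        from scipy import stats
        t = diffs.mean() / (diffs.std(ddof=1) / np.sqrt(10))
        p = 2 * stats.t.sf(abs(t), df=9)
        assert out["p_value"].iloc[0] == pytest.approx(p)

    def test_unequal_reps_error(self):
        a = pd.DataFrame({"participant": ["P0"] * 3, "rep": range(3),
                          "accuracy": [0.8] * 3})
        b = a.iloc[:2]
        with pytest.raises(ValueError):
            compare_personal_vs_temporal(a, b, metrics=("accuracy",))

    def test_end_to_end_comparison_runs(self, temporal_table):
        plan = make_split_plan(temporal_table, "personalized", seed=0,
                               n_repetitions=2)
        pers = run_nested_cv(temporal_table, plan, grid=SMALL_GRID, seed=0)
        temp = run_temporal_per_participant(temporal_table, grid=SMALL_GRID,
                                            seed=0, n_repetitions=2)
        out = compare_personal_vs_temporal(pers.per_fold, temp)
        assert set(out["metric"]) == {"accuracy", "f1", "precision",
                                      "recall", "roc_auc"}


class TestDownsampling:
    def test_two_equal_participants_unchanged(self):
        t = fake_table(n_participants=2, rows_per=20)
        out = downsample_other_participants(t, "P00", seed=0)
        assert len(out) == len(t)

    def test_others_matched_to_target_total(self):
        t = fake_table(n_participants=5, rows_per=40)
        target = t[t["participant"] == "P00"].sample(10, random_state=0)
        t2 = pd.concat([target, t[t["participant"] != "P00"]])
        out = downsample_other_participants(t2, "P00", seed=0)
        assert len(out[out["participant"] != "P00"]) == 10

    def test_label_proportions_preserved(self):
        t = fake_table(n_participants=3, rows_per=60, seed=3)
        target = t[t["participant"] == "P00"].iloc[:30]
        t2 = pd.concat([target, t[t["participant"] != "P00"]])
        out = downsample_other_participants(t2, "P00", seed=0)
        for p in ("P01", "P02"):
            src = t2[t2["participant"] == p]
            kept = out[out["participant"] == p]
            expect = len(kept) * (src["label"] == "event").mean()
            got = (kept["label"] == "event").sum()
            assert abs(got - expect) <= 1


class TestImportance:
    def test_single_signal_feature_ranked_first(self):
        """When only one feature carries label signal it tops the ranking."""
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(200, 10))
            y = (X[:, 3] > 0).astype(int)
            ts = TrainingSet(X, y, np.zeros(200))
            m = fit_model("rf", ts, {"n_estimators": 40}, seed=seed)
            rep = tree_path_attribution(m, X)
            if rep.ranking()["feature"].iloc[0] == "x3":
                wins += 1
        assert wins >= 9

    def test_unused_feature_has_zero_attribution(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(100, 4))
        X[:, 2] = 0.0  # constant: never split on
        y = (X[:, 0] > 0).astype(int)
        ts = TrainingSet(X, y, np.zeros(100))
        m = fit_model("rf", ts, {"n_estimators": 20}, seed=0)
        rep = tree_path_attribution(m, X)
        assert np.abs(rep.attributions[:, 2]).max() == 0.0

    def test_ranking_covers_all_features(self, effect_table):
        std, _ = standardize(effect_table)
        X = std[FEATURE_NAMES].to_numpy()
        y = (std["label"] == "event").astype(int).to_numpy()
        ts = oversample_positives(
            TrainingSet(X, y, std["participant"].to_numpy()), seed=0)
        m = fit_model("merf", ts, {"n_estimators": 30, "max_iter": 2}, seed=0)
        rep = tree_path_attribution(m, X, FEATURE_NAMES)
        assert len(rep.ranking()) == 66
        assert len(rep.top(20)) == 20

    def test_non_tree_model_instructs_fallback(self):
        ts = TrainingSet(np.zeros((10, 2)), [0, 1] * 5, np.zeros(10))
        m = fit_model("lr", ts, seed=0)
        with pytest.raises(TypeError, match="permutation"):
            tree_path_attribution(m, ts.X)
        rep = permutation_importance_report(m, ts.X, ts.y)
        assert len(rep) == 2


class TestLearningCurve:
    def test_noiseless_parameters_recovered(self):
        n = np.array([50, 100, 200, 400, 800, 1600], dtype=float)
        a, b, c = 0.9, 0.5, 0.5
        fit = fit_inverse_power_law(n, a - b * n ** (-c))
        assert fit.a == pytest.approx(a, abs=1e-3)
        assert fit.b == pytest.approx(b, abs=1e-3)
        assert fit.c == pytest.approx(c, abs=1e-3)

    def test_constant_metric_flagged_degenerate(self):
        n = np.array([50.0, 100.0, 200.0, 400.0])
        fit = fit_inverse_power_law(n, np.full(4, 0.75))
        assert fit.degenerate or abs(fit.predict(n).std()) < 1e-6

    def test_extrapolation_flags_unreachable_target(self):
        n = np.array([50, 100, 200, 400], dtype=float)
        fit = fit_inverse_power_law(n, 0.8 - 0.5 * n ** (-0.5))
        n_needed, flagged = fit.n_for_target(0.95)
        assert flagged and np.isinf(n_needed)
        n_needed, flagged = fit.n_for_target(0.75)
        assert not flagged and np.isfinite(n_needed)

    def test_noisy_recovery_of_asymptote(self):
        rng = np.random.default_rng(0)
        recovered = []
        n = np.repeat([50, 100, 200, 400, 800, 1600], 10).astype(float)
        for _ in range(10):
            perf = 0.9 - 0.5 * n ** (-0.5) + rng.normal(0, 0.02, n.size)
            recovered.append(fit_inverse_power_law(n, np.clip(perf, 0, 1)).a)
        assert np.abs(np.array(recovered) - 0.9).max() < 0.03


class TestReports:
    def test_rest_vs_exposure_effect_visible(self):
        from e4wild import EffectSpec
        eff = EffectSpec(eda_phasic_gain=3.0)
        labs = {f"P{i}": {"rest": simulate_lab_session("rest", eff, seed=i),
                          "exposure": simulate_lab_session("exposure", eff,
                                                           seed=i)}
                for i in range(5)}
        out = rest_vs_exposure_report(labs, ["eda.scr_count", "eda.phasic_rms"])
        s = out["summary"]
        med = s.set_index(["feature", "condition"])["median"]
        assert med["eda.scr_count", "exposure"] > med["eda.scr_count", "rest"]

    def test_missing_condition_excluded(self):
        labs = {"P0": {"rest": simulate_lab_session("rest", seed=0)},
                "P1": {"rest": simulate_lab_session("rest", seed=1),
                       "exposure": simulate_lab_session("exposure", seed=1)}}
        out = rest_vs_exposure_report(labs, ["eda.mean"])
        assert set(out["values"]["participant"]) == {"P1"}

    def test_identical_segments_zero_difference(self):
        s = simulate_lab_session("rest", seed=3)
        labs = {"P0": {"rest": s, "exposure": s}}
        out = rest_vs_exposure_report(labs, ["eda.mean", "hr.mean"])
        v = out["values"].pivot_table(index="feature", columns="condition",
                                      values="value")
        assert (v["rest"] == v["exposure"]).all()

    def test_acceptability_spearman_properties(self):
        from e4wild import reference_cohort
        ref = reference_cohort()
        meta = pd.DataFrame({"age": [11, 12, 10, 11, 14, 15, 16, 13]},
                            index=ref.index)
        rep = acceptability_report(ref, meta)
        assert rep.totals["total_days"] == 270
        rho = rep.rho
        # symmetric with unit diagonal
        assert np.allclose(rho.values, rho.values.T)
        assert np.allclose(np.diag(rho.values), 1.0)
        # monotone pair: hours vs hours^2 would be rho=1; check via transform
        x = ref["n_hours"]
        assert spearmanr(x, x ** 2).statistic == pytest.approx(1.0)

    def test_few_participants_suppress_correlations(self):
        from e4wild import reference_cohort
        rep = acceptability_report(reference_cohort().iloc[:2])
        assert rep.rho is None
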