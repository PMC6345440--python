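"""Deep stroma score: cutpoints, Cox fits, score construction, comparators."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from deepstroma import (CLASS_CODES, CohortConfig, DeepStromaScorer,
                        ScoreModel, build_score_model, caf_score,
                        compare_scores, compute_score, dichotomize,
                        generate_cohort, multivariable_cox, per_stage_models,
                        published_score_model, univariable_hr, youden_cutoff)
from deepstroma.cohort import ACTIVATION_COLUMNS
from deepstroma.score import ScoreModelError

from conftest import brute_force_youden


class TestYoudenCutoff:
    def test_perfect_separation(self):
        tau = youden_cutoff([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert tau == pytest.approx(0.5)

    def test_tie_broken_toward_smaller_cutoff(self):
        # J ties at 1.5 and 3.5 (J = 0.5), both equidistant from median 2.5
        tau = youden_cutoff([1, 2, 3, 4], [0, 1, 0, 1])
        assert tau == pytest.approx(1.5)

    def test_single_label_class_rejected(self):
        with pytest.raises(ValueError, match="both label classes"):
            youden_cutoff([1, 2, 3], [1, 1, 1])

    def test_constant_values_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            youden_cutoff([2, 2, 2, 2], [0, 1, 0, 1])

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            n = rng.integers(4, 40)
            v = np.round(rng.normal(size=n), 2)
            y = rng.integers(0, 2, size=n)
            if y.min() == y.max() or np.unique(v).size < 2:
                continue
            assert youden_cutoff(v, y) == pytest.approx(brute_force_youden(v, y))

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(st.lists(st.integers(0, 9), min_size=4, max_size=12),
           st.lists(st.integers(0, 1), min_size=4, max_size=12))
    def test_no_candidate_beats_the_returned_cutoff(self, vals, labels):
        n = min(len(vals), len(labels))
        v = np.asarray(vals[:n], float)
        y = np.asarray(labels[:n], int)
        if y.min() == y.max() or np.unique(v).size < 2:
            return
        tau = youden_cutoff(v, y)

        def J(t):
            sens = ((v > t) & (y == 1)).sum() / (y == 1).sum()
            spec = ((v <= t) & (y == 0)).sum() / (y == 0).sum()
            return sens + spec - 1

        uniq = np.unique(v)
        assert all(J(c) <= J(tau) + 1e-12 for c in (uniq[:-1] + uniq[1:]) / 2)


class TestUnivariableHR:
    def test_planted_doubling_recovered(self):
        cfg = CohortConfig(n_patients=2000, beta={"STR": np.log(2.0)},
                           baseline_hazard=0.03, censoring_horizon=300, seed=21)
        c = generate_cohort(cfg)
        hr = univariable_hr(c["a_STR"], c["time_OS"], c["event_OS"])
        assert 1.6 <= hr <= 2.5

    def test_null_covariate_near_one(self):
        cfg = CohortConfig(n_patients=2000, baseline_hazard=0.03,
                           censoring_horizon=300, seed=22)
        c = generate_cohort(cfg)
        hr = univariable_hr(c["a_MUC"], c["time_OS"], c["event_OS"])
        assert 0.8 <= hr <= 1.25

    def test_zero_events_rejected(self):
        with pytest.raises(ValueError, match="events"):
            univariable_hr([0.1, 0.2, 0.3], [1, 2, 3], [0, 0, 0])

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="non-identifiable"):
            univariable_hr([0.5] * 20, np.arange(1, 21), [1] * 20)

    def test_agrees_with_independent_cox_implementation(self):
        """lifelines-based fit vs scikit-survival on the same data."""
        from sksurv.linear_model import CoxPHSurvivalAnalysis
        cfg = CohortConfig(n_patients=400, beta={"DEB": 1.0},
                           baseline_hazard=0.03, censoring_horizon=200, seed=30)
        c = generate_cohort(cfg)
        hr = univariable_hr(c["a_DEB"], c["time_OS"], c["event_OS"])
        yy = np.array(list(zip(c["event_OS"].astype(bool), c["time_OS"])),
                      dtype=[("e", bool), ("t", float)])
        est = CoxPHSurvivalAnalysis().fit(c[["a_DEB"]].to_numpy(), yy)
        assert hr == pytest.approx(float(np.exp(est.coef_[0])), rel=1e-3)


class TestScoreModel:
    def test_published_worked_example(self):
        """Debris + lymphocytes + stroma above cutoff reproduces the
        published training-cohort median score exactly."""
        sm = published_score_model()
        a = np.array(sm.cutoff) * 0.5
        for code in ("DEB", "LYM", "STR"):
            a[CLASS_CODES.index(code)] = sm.cutoff[CLASS_CODES.index(code)] + 0.01
        assert compute_score(sm, a) == pytest.approx(8.347, abs=1e-9)

    def test_published_selection_is_five_classes(self):
        sm = published_score_model()
        assert sm.selected == ("ADI", "DEB", "LYM", "MUS", "STR")

    def test_all_selected_above_gives_full_sum(self):
        sm = published_score_model()
        a = np.array(sm.cutoff) + 0.001
        assert compute_score(sm, a) == pytest.approx(13.258, abs=1e-9)

    def test_all_below_gives_zero(self):
        sm = published_score_model()
        assert compute_score(sm, np.zeros(9)) == 0.0

    def test_score_ignores_unselected_classes(self):
        sm = published_score_model()
        a = np.zeros(9)
        for code in ("BACK", "MUC", "NORM", "TUM"):  # HR < 1 classes
            a[CLASS_CODES.index(code)] = 1.0
        assert compute_score(sm, a) == 0.0

    def test_score_monotone_in_selected_activations(self):
        sm = published_score_model()
        rng = np.random.default_rng(3)
        a = rng.uniform(0, 0.05, 9)
        base = compute_score(sm, a)
        for code in sm.selected:
            bumped = a.copy()
            bumped[CLASS_CODES.index(code)] = 1.0
            assert compute_score(sm, bumped) >= base

    def test_json_round_trip_reproduces_scores(self, tmp_path):
        sm = published_score_model()
        path = tmp_path / "score.json"
        sm.to_json(path)
        back = ScoreModel.from_json(path)
        rng = np.random.default_rng(8)
        a = rng.dirichlet(np.ones(9), size=50)
        np.testing.assert_array_equal(back.score(a), sm.score(a))
        np.testing.assert_array_equal(back.dichotomize(back.score(a)),
                                      sm.dichotomize(sm.score(a)))

    def test_no_positive_hr_rejected(self):
        with pytest.raises(ScoreModelError, match="no class with HR > 1"):
            ScoreModel(hr=tuple([0.5] * 9), cutoff=tuple([0.1] * 9), median=0.0)


class TestDichotomize:
    def test_scores_equal_to_median_are_low(self):
        sm = published_score_model()
        labels = dichotomize(sm, np.full(5, sm.median))
        assert np.all(labels == 0)

    def test_frozen_median_on_validation_cohort(self):
        sm = published_score_model()
        assert list(dichotomize(sm, [0.0, 8.346, 8.348, 13.258])) == [0, 0, 1, 1]


def _planted_cohort(n=1000, seed=40, **beta):
    cfg = CohortConfig(n_patients=n, beta=beta, baseline_hazard=0.03,
                       censoring_horizon=300, seed=seed)
    return generate_cohort(cfg)


class TestBuildScore:
    def test_planted_classes_selected(self):
        c = _planted_cohort(n=1500, seed=41, DEB=np.log(6), MUS=np.log(4),
                            MUC=np.log(0.2), TUM=np.log(0.3))
        sm = build_score_model(c)
        assert {"DEB", "MUS"} <= set(sm.selected)
        assert "MUC" not in sm.selected and "TUM" not in sm.selected

    def test_deterministic(self):
        c = _planted_cohort(n=400, seed=42, DEB=np.log(3))
        a = build_score_model(c)
        b = build_score_model(c.copy())
        assert a.to_json() == b.to_json()

    def test_protective_only_cohort_rejected(self):
        """Max-pooled activations need not sum to 1, so a cohort where
        every class is protective (all HRs < 1) is constructible; the
        builder must refuse it."""
        rng = np.random.default_rng(43)
        n = 600
        acts = rng.uniform(0, 1, size=(n, 9))
        lam = 0.2 * np.exp(-4.0 * acts.mean(axis=1))
        t_event = rng.exponential(1 / lam)
        t_cens = rng.uniform(0, 40, n)
        df = pd.DataFrame({c: acts[:, i] for i, c in enumerate(ACTIVATION_COLUMNS)})
        df["time_OS"] = np.minimum(t_event, t_cens)
        df["event_OS"] = (t_event <= t_cens).astype(int)
        with pytest.raises(ScoreModelError, match="no class with HR > 1"):
            build_score_model(df)

    def test_training_split_roughly_balanced(self):
        c = _planted_cohort(n=1000, seed=44, DEB=np.log(5), STR=np.log(2))
        sm = build_score_model(c)
        scores = sm.score(c[list(ACTIVATION_COLUMNS)].to_numpy())
        frac_high = sm.dichotomize(scores).mean()
        assert abs(frac_high - 0.5) <= 0.15

    def test_missing_endpoint_rows_excluded(self):
        c = _planted_cohort(n=300, seed=45, DEB=np.log(4))
        c.loc[:24, "time_OS"] = np.nan
        sm_dropped = build_score_model(c)
        sm_clean = build_score_model(c.iloc[25:])
        assert sm_dropped.to_json() == sm_clean.to_json()

    def test_sklearn_estimator_interface(self):
        c = _planted_cohort(n=500, seed=46, DEB=np.log(5))
        scorer = DeepStromaScorer().fit(c)
        assert scorer.median_ == scorer.model_.median
        scores = scorer.transform(c)
        labels = scorer.predict(c)
        np.testing.assert_array_equal(labels, scorer.model_.dichotomize(scores))
        params = scorer.get_params()
        assert params == {"endpoint": "OS"}


class TestMultivariableCox:
    def test_planted_group_effect_recovered(self):
        cfg = CohortConfig(n_patients=1000, baseline_hazard=0.03,
                           censoring_horizon=300, seed=50)
        c = generate_cohort(cfg)
        rng = np.random.default_rng(51)
        group = rng.integers(0, 2, len(c))
        # regenerate event times with a doubled hazard in the group
        lam = 0.03 * np.exp(np.log(2.0) * group)
        t_event = rng.exponential(1 / lam)
        t_cens = rng.uniform(0, 300, len(c))
        c["time_OS"] = np.minimum(t_event, t_cens)
        c["event_OS"] = (t_event <= t_cens).astype(int)
        res = multivariable_cox(c, group, "OS")
        assert 1.6 <= res["group"].hr <= 2.5
        assert res["group"].ci_low > 1.0

    def test_random_group_ci_covers_one(self):
        """Null coverage: ~95% CIs should cover 1 in >= 90% of replicates."""
        covered = 0
        reps = 40
        for i in range(reps):
            cfg = CohortConfig(n_patients=300, baseline_hazard=0.03,
                               censoring_horizon=300, seed=600 + i)
            c = generate_cohort(cfg)
            group = np.random.default_rng(900 + i).integers(0, 2, len(c))
            res = multivariable_cox(c, group, "OS")
            if res["group"].ci_low <= 1.0 <= res["group"].ci_high:
                covered += 1
        assert covered / reps >= 0.90

    def test_zero_events_rejected(self):
        c = _planted_cohort(n=100, seed=52)
        c["event_OS"] = 0
        with pytest.raises(ValueError, match="events"):
            multivariable_cox(c, np.zeros(len(c)), "OS")

    def test_ci_brackets_hr(self):
        c = _planted_cohort(n=500, seed=53, DEB=np.log(3))
        sm = build_score_model(c)
        labels = sm.dichotomize(sm.score(c[list(ACTIVATION_COLUMNS)].to_numpy()))
        res = multivariable_cox(c, labels, "OS")
        for r in res.values():
            assert r.ci_low <= r.hr <= r.ci_high


class TestPerStage:
    def _cohort_with_stage_effect(self, seed=60, n=2400):
        cfg = CohortConfig(n_patients=n, baseline_hazard=0.03,
                           censoring_horizon=300, seed=seed)
        c = generate_cohort(cfg)
        rng = np.random.default_rng(seed + 1)
        group = rng.integers(0, 2, len(c))
        # group triples hazard, but only within stage 4
        lam = 0.03 * np.exp(np.log(3.0) * group * (c["stage"] == 4))
        t_event = rng.exponential(1 / lam)
        t_cens = rng.uniform(0, 300, len(c))
        c["time_OS"] = np.minimum(t_event, t_cens)
        c["event_OS"] = (t_event <= t_cens).astype(int)
        return c, group

    def test_stage_specific_effect_localized(self):
        c, group = self._cohort_with_stage_effect()
        res = per_stage_models(c, group, "OS")
        assert res[4]["group"].ci_low > 1.0
        assert res[1]["group"].ci_low <= 1.0 <= res[1]["group"].ci_high

    def test_missing_stage_reported_not_raised(self):
        c, group = self._cohort_with_stage_effect(seed=61, n=600)
        keep = c["stage"] != 1
        res = per_stage_models(c[keep].reset_index(drop=True), group[keep], "OS")
        assert res[1] == "insufficient events"

    def test_pooled_effect_within_per_stage_hull(self):
        """Homogeneous group effect: the pooled log-HR lies inside the
        range of the per-stage log-HRs."""
        cfg = CohortConfig(n_patients=3000, baseline_hazard=0.03,
                           censoring_horizon=300, seed=62)
        c = generate_cohort(cfg)
        rng = np.random.default_rng(63)
        group = rng.integers(0, 2, len(c))
        lam = 0.03 * np.exp(np.log(2.0) * group)
        t_event = rng.exponential(1 / lam)
        t_cens = rng.uniform(0, 300, len(c))
        c["time_OS"] = np.minimum(t_event, t_cens)
        c["event_OS"] = (t_event <= t_cens).astype(int)
        pooled = np.log(multivariable_cox(c, group, "OS")["group"].hr)
        per = [np.log(r["group"].hr)
               for r in per_stage_models(c, group, "OS").values()
               if not isinstance(r, str)]
        assert min(per) <= pooled <= max(per)


class TestComparators:
    def test_caf_score_is_mean_over_signature(self):
        expr = pd.DataFrame({"P1": [2.0, 4.0, 99.0], "P2": [1.0, 3.0, 99.0]},
                            index=["FAP", "PDGFRB", "OTHER"])
        s = caf_score(expr, ["FAP", "PDGFRB"])
        assert s["P1"] == pytest.approx(3.0)
        assert s["P2"] == pytest.approx(2.0)

    def test_caf_score_order_invariant_and_missing_logged(self):
        expr = pd.DataFrame({"P1": [2.0, 4.0]}, index=["FAP", "PDGFRB"])
        a = caf_score(expr, ["FAP", "PDGFRB", "NOTAGENE"])
        b = caf_score(expr, ["PDGFRB", "FAP"])
        assert a["P1"] == b["P1"] == pytest.approx(3.0)

    def test_caf_empty_intersection_rejected(self):
        expr = pd.DataFrame({"P1": [1.0]}, index=["GENE"])
        with pytest.raises(ValueError, match="no signature gene"):
            caf_score(expr, ["OTHER"])

    def test_planted_str_caf_correlation_recovered(self):
        """CAF score built as STR activation + noise at planted rho ~ 0.3
        comes back in a band around it."""
        c = _planted_cohort(n=500, seed=70, DEB=np.log(4))
        rng = np.random.default_rng(71)
        x = c["a_STR"].to_numpy()
        rho = 0.3
        noise = rng.normal(0, 1, len(c))
        z = (x - x.mean()) / x.std()
        c["caf_score"] = rho * z + np.sqrt(1 - rho**2) * noise
        rep = compare_scores(c, build_score_model(c))
        r = rep["correlations"]["str_activation_vs_caf"]["r"]
        assert 0.15 <= r <= 0.45

    def test_absent_comparator_skipped(self):
        c = _planted_cohort(n=500, seed=72, DEB=np.log(4))
        rep = compare_scores(c, build_score_model(c))
        assert "deep_stroma" in rep["models"]
        assert "caf" not in rep["models"]

    def test_identical_scores_correlate_perfectly(self):
        c = _planted_cohort(n=400, seed=73, DEB=np.log(4))
        sm = build_score_model(c)
        c["caf_score"] = sm.score(c[list(ACTIVATION_COLUMNS)].to_numpy())
        rep = compare_scores(c, sm)
        assert rep["correlations"]["deep_stroma_vs_caf"]["r"] == pytest.approx(1.0)
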