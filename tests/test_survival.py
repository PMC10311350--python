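"""Survival stack: concordance, RSF, folds, importance, stratification, tests."""

import numpy as np
import pandas as pd
import pytest

from conftest import harrell_c_oracle

from spatprot.datamodel import ClinicalTable
from spatprot.survival import (
    CVScheme,
    SELECTION_BIAS_CAVEAT,
    cohort_feature_tests,
    cross_validate,
    fit_rsf,
    harrell_c,
    kaplan_meier,
    logrank_test,
    make_folds,
    patient_risk,
    permutation_importance,
    stratify_patients,
)


def toy_clinical(n_patients=20, samples_per_patient=2, n_coverslips=4, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_patients):
        t = rng.exponential(100.0)
        e = int(rng.random() > 0.3)
        for s in range(samples_per_patient):
            rows.append(
                {
                    "patient_id": f"P{p:02d}",
                    "sample_id": f"P{p:02d}_S{s}",
                    "coverslip_id": f"CS{p % n_coverslips}",
                    "time": t,
                    "event": e,
                }
            )
    return ClinicalTable(pd.DataFrame(rows))


class TestHarrellC:
    def test_perfect_and_reversed(self):
        assert harrell_c([1, 2, 3], [1, 1, 1], [3, 2, 1]) == 1.0
        assert harrell_c([1, 2, 3], [1, 1, 1], [1, 2, 3]) == 0.0

    def test_censored_example(self):
        # pairs (1,2) and (1,3) comparable and concordant; (2,3) not comparable
        assert harrell_c([2, 4, 6], [1, 0, 1], [5, 1, 1]) == 1.0

    def test_risk_ties_half_credit(self):
        assert harrell_c([1, 2], [1, 1], [1, 1]) == 0.5

    def test_no_comparable_pairs_rejected(self):
        with pytest.raises(ValueError):
            harrell_c([1, 2], [0, 0], [1, 2])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 50
        t = rng.integers(1, 20, n).astype(float)  # many time ties
        e = rng.integers(0, 2, n)
        r = rng.integers(0, 5, n).astype(float)  # many risk ties
        if not ((e == 1) & (t < t.max())).any():
            e[np.argmin(t)] = 1
        assert harrell_c(t, e, r) == harrell_c_oracle(t, e, r)

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        st.lists(
            st.tuples(
                st.integers(1, 8), st.integers(0, 1), st.integers(0, 4)
            ),
            min_size=3,
            max_size=25,
        )
    )
    @settings(max_examples=80, derandomize=True, deadline=None)
    def test_oracle_equality_property(self, rows):
        t = np.array([r[0] for r in rows], dtype=float)
        e = np.array([r[1] for r in rows])
        r_ = np.array([r[2] for r in rows], dtype=float)
        comparable = ((t[:, None] < t[None, :]) & (e[:, None] == 1)).any()
        if not comparable:
            with pytest.raises(ValueError):
                harrell_c(t, e, r_)
        else:
            assert harrell_c(t, e, r_) == harrell_c_oracle(t, e, r_)

    def test_complement_under_risk_negation(self, rng):
        t = rng.exponential(10, 30)
        e = rng.integers(0, 2, 30)
        e[np.argmin(t)] = 1
        r = rng.normal(0, 1, 30)  # continuous: no ties
        assert harrell_c(t, e, r) + harrell_c(t, e, -r) == pytest.approx(1.0)


class TestRSF:
    def _planted(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 2, n).astype(float)
        X = pd.DataFrame(
            {"signal": x, "noise": rng.normal(0, 1, n)},
            index=[f"s{i}" for i in range(n)],
        )
        lam = 0.01 * 4.0**x  # hazard ratio 4 between levels
        times = rng.exponential(1.0 / lam)
        out = pd.DataFrame({"time": times, "event": 1}, index=X.index)
        return X, out

    def test_planted_signal_out_of_sample(self):
        X, out = self._planted()
        model = fit_rsf(X.iloc[:100], out.iloc[:100], {"n_estimators": 100}, seed=0)
        risks = model.predict_risk(X.iloc[100:])
        c = harrell_c(out["time"].iloc[100:], out["event"].iloc[100:], risks)
        assert c > 0.6

    def test_deterministic_given_seed(self):
        X, out = self._planted(n=80)
        r1 = fit_rsf(X, out, {"n_estimators": 50}, seed=4).predict_risk(X)
        r2 = fit_rsf(X, out, {"n_estimators": 50}, seed=4).predict_risk(X)
        np.testing.assert_array_equal(r1, r2)

    def test_all_censored_rejected(self):
        X, out = self._planted(n=30)
        out["event"] = 0
        with pytest.raises(ValueError):
            fit_rsf(X, out, {"n_estimators": 10}, seed=0)


class TestFolds:
    def test_patients_never_span_folds(self):
        clinical = toy_clinical()
        folds = make_folds(clinical, CVScheme("patient_kfold", 10, seed=1))
        s2p = clinical.sample_to_patient()
        assert len(folds) == 10
        for train, test in folds:
            assert not ({s2p[s] for s in train} & {s2p[s] for s in test})

    def test_folds_partition_samples(self):
        clinical = toy_clinical()
        folds = make_folds(clinical, CVScheme("patient_kfold", 5, seed=1))
        all_test = [s for _, test in folds for s in test]
        assert sorted(all_test) == sorted(clinical.data["sample_id"])

    def test_one_fold_per_coverslip(self):
        clinical = toy_clinical(n_coverslips=7)
        folds = make_folds(clinical, CVScheme("leave_one_coverslip_out"))
        assert len(folds) == 7
        s2c = clinical.sample_to_coverslip()
        for _, test in folds:
            assert len({s2c[s] for s in test}) == 1

    def test_deterministic_given_seed(self):
        clinical = toy_clinical()
        a = make_folds(clinical, CVScheme("patient_kfold", 5, seed=9))
        b = make_folds(clinical, CVScheme("patient_kfold", 5, seed=9))
        assert a == b

    def test_too_few_patients_rejected(self):
        clinical = toy_clinical(n_patients=5)
        with pytest.raises(ValueError):
            make_folds(clinical, CVScheme("patient_kfold", 10))


class TestCrossValidate:
    def _planted_cohort(self, n_patients=60, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, n_patients)
        rows, feats = [], {}
        for p in range(n_patients):
            pid = f"P{p:02d}"
            sid = f"{pid}_S0"
            rows.append(
                {"patient_id": pid, "sample_id": sid, "coverslip_id": f"CS{p % 4}"}
            )
            feats[sid] = {"signal": x[p], "noise": rng.normal()}
        lam = 0.01 * np.exp(1.5 * x)
        clin = pd.DataFrame(rows)
        times = rng.exponential(1.0 / lam)
        clin["time"] = times[np.arange(n_patients)]
        clin["event"] = 1
        return pd.DataFrame(feats).T, ClinicalTable(clin)

    def test_planted_signal_beats_chance(self):
        X, clinical = self._planted_cohort()
        cv = cross_validate(
            X, clinical, CVScheme("patient_kfold", 5), {"n_estimators": 50},
            n_repeats=3, seed=0,
        )
        assert cv.mean > 0.6

    def test_null_features_near_half(self):
        rng = np.random.default_rng(3)
        X, clinical = self._planted_cohort(seed=1)
        X[:] = rng.normal(size=X.shape)  # destroy the signal
        cv = cross_validate(
            X, clinical, CVScheme("patient_kfold", 5), {"n_estimators": 50},
            n_repeats=5, seed=0,
        )
        lo, hi = cv.ci95()
        assert lo < 0.58 and hi > 0.42

    def test_patient_level_option_runs(self):
        X, clinical = self._planted_cohort(n_patients=30)
        cv = cross_validate(
            X, clinical, CVScheme("patient_kfold", 3), {"n_estimators": 30},
            n_repeats=1, seed=0, level="patient",
        )
        assert 0.0 <= cv.mean <= 1.0


class TestPermutationImportance:
    def test_constant_feature_zero_and_planted_first(self):
        rng = np.random.default_rng(0)
        n = 120
        x = rng.integers(0, 2, n).astype(float)
        X = pd.DataFrame(
            {"signal": x, "noise": rng.normal(0, 1, n), "const": np.ones(n)},
            index=[f"s{i}" for i in range(n)],
        )
        out = pd.DataFrame(
            {"time": rng.exponential(1.0 / (0.01 * 6.0**x)), "event": 1}, index=X.index
        )
        model = fit_rsf(X, out, {"n_estimators": 100}, seed=0)
        imp = permutation_importance(model, X, out, n_perm=10, seed=0)
        assert imp.loc[imp["feature"] == "const", "delta_c"].iloc[0] == 0.0
        assert imp.iloc[0]["feature"] == "signal"

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
        out = pd.DataFrame({"time": rng.exponential(10, 40), "event": 1}, index=X.index)
        model = fit_rsf(X, out, {"n_estimators": 20}, seed=0)
        i1 = permutation_importance(model, X, out, n_perm=5, seed=2)
        i2 = permutation_importance(model, X, out, n_perm=5, seed=2)
        pd.testing.assert_frame_equal(i1, i2)


class TestPatientRisk:
    def test_mean_and_single(self):
        risks = pd.Series({"s0": 0.2, "s1": 0.4, "s2": 0.9})
        mapping = {"s0": "P0", "s1": "P0", "s2": "P1"}
        out = patient_risk(risks, mapping)
        assert out["P0"] == pytest.approx(0.3)
        assert out["P1"] == 0.9

    def test_unmapped_sample_rejected(self):
        with pytest.raises(ValueError):
            patient_risk(pd.Series({"s0": 1.0}), {})

    def test_matches_bruteforce(self, rng):
        risks = pd.Series(rng.random(20), index=[f"s{i}" for i in range(20)])
        mapping = {f"s{i}": f"P{i % 5}" for i in range(20)}
        out = patient_risk(risks, mapping)
        for p in set(mapping.values()):
            expected = np.mean([risks[s] for s, q in mapping.items() if q == p])
            assert out[p] == pytest.approx(expected)


class TestKaplanMeier:
    def test_all_censored_flat(self):
        km = kaplan_meier([5, 10, 15], [0, 0, 0])
        assert (km["survival"] == 1.0).all()

    def test_two_event_steps(self):
        km = kaplan_meier([1, 2], [1, 1])
        lookup = dict(zip(km["time"], km["survival"]))
        assert lookup[0.0] == 1.0
        assert lookup[1.0] == 0.5
        assert lookup[2.0] == 0.0

    def test_no_censoring_equals_empirical(self, rng):
        t = rng.exponential(10, 40)
        km = kaplan_meier(t, np.ones(40))
        emp = [(t > u).mean() for u in km["time"]]
        np.testing.assert_allclose(km["survival"], emp, atol=1e-12)

    def test_monotone_nonincreasing(self, rng):
        t = rng.exponential(10, 30)
        e = rng.integers(0, 2, 30)
        km = kaplan_meier(t, e)
        assert (np.diff(km["survival"]) <= 1e-12).all()


class TestLogrank:
    def test_identical_groups_null(self):
        res = logrank_test([1, 2, 3], [1, 1, 1], [1, 2, 3], [1, 1, 1])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_matches_lifelines(self, rng):
        from lifelines.statistics import logrank_test as llr

        for _ in range(5):
            ta, tb = rng.exponential(10, 25), rng.exponential(5, 20)
            ea, eb = rng.integers(0, 2, 25), rng.integers(0, 2, 20)
            if ea.sum() == 0 or eb.sum() == 0:
                continue
            mine = logrank_test(ta, ea, tb, eb)
            ref = llr(ta, tb, event_observed_A=ea, event_observed_B=eb)
            assert mine.statistic == pytest.approx(ref.test_statistic, abs=1e-9)
            assert mine.p_value == pytest.approx(ref.p_value, abs=1e-9)

    def test_strong_separation_significant(self, rng):
        hits = 0
        for s in range(20):
            r = np.random.default_rng(s)
            res = logrank_test(
                r.exponential(100, 100), np.ones(100),
                r.exponential(20, 100), np.ones(100),
            )
            hits += res.p_value < 0.01
        assert hits >= 19

    def test_no_event_group_flagged(self):
        res = logrank_test([1, 2], [1, 1], [3, 4], [0, 0])
        assert res.warning is not None
        assert np.isfinite(res.statistic)


class TestStratification:
    def test_four_patient_example(self):
        risks = pd.Series({"P0": 1.0, "P1": 2.0, "P2": 9.0, "P3": 10.0})
        out = pd.DataFrame(
            {"time": [100.0, 120.0, 5.0, 4.0], "event": [1, 1, 1, 1]},
            index=risks.index,
        )
        split = stratify_patients(risks, out, min_fraction=0.0)
        assert 2.0 < split.threshold < 9.0
        assert split.labels.tolist() == ["low", "low", "high", "high"]
        assert split.caveat == SELECTION_BIAS_CAVEAT

    def test_equal_risks_rejected(self):
        risks = pd.Series({"P0": 1.0, "P1": 1.0, "P2": 1.0})
        out = pd.DataFrame({"time": [1.0, 2.0, 3.0], "event": [1, 1, 1]}, index=risks.index)
        with pytest.raises(ValueError):
            stratify_patients(risks, out)

    def test_min_cohort_size_respected(self, rng):
        n = 30
        risks = pd.Series(rng.normal(0, 1, n), index=[f"P{i:02d}" for i in range(n)])
        out = pd.DataFrame(
            {"time": rng.exponential(10, n), "event": 1}, index=risks.index
        )
        split = stratify_patients(risks, out, min_fraction=0.2)
        assert (split.labels == "high").sum() >= 6
        assert (split.labels == "low").sum() >= 6


class TestCohortTests:
    def test_exact_small_sample_p(self):
        feats = pd.DataFrame({"f": [1.0, 2.0, 3.0, 4.0]}, index=list("abcd"))
        labels = pd.Series(["lo", "lo", "hi", "hi"], index=list("abcd"))
        out = cohort_feature_tests(feats, labels)
        assert out.loc[0, "U"] == 0.0
        assert out.loc[0, "p_raw"] == pytest.approx(1.0 / 3.0)

    def test_bonferroni_arithmetic(self):
        rng = np.random.default_rng(0)
        feats = pd.DataFrame(rng.normal(size=(10, 5)), columns=list("abcde"))
        labels = pd.Series(["x"] * 5 + ["y"] * 5, index=feats.index)
        out = cohort_feature_tests(feats, labels)
        np.testing.assert_allclose(
            out["p_bonferroni"], np.minimum(1.0, out["p_raw"] * 5)
        )

    def test_constant_feature_p_one(self):
        feats = pd.DataFrame({"f": [1.0] * 6, "g": [1, 2, 3, 4, 5, 6.0]})
        labels = pd.Series(["x"] * 3 + ["y"] * 3, index=feats.index)
        out = cohort_feature_tests(feats, labels)
        assert out.set_index("feature").loc["f", "p_raw"] == 1.0

    def test_identical_groups_large_p(self, rng):
        vals = rng.normal(size=10)
        feats = pd.DataFrame({"f": np.concatenate([vals, vals])})
        labels = pd.Series(["x"] * 10 + ["y"] * 10, index=feats.index)
        out = cohort_feature_tests(feats, labels)
        assert out.loc[0, "p_raw"] > 0.9
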