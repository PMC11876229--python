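"""Metric suite: oracle cross-checks and protocol invariants."""

import numpy as np
import pandas as pd
import pytest

from mammojig.evaluation import (MetricError, compare_auc_ttest, evaluate_run,
                                 grouped_kfold, mean_roc_curve, roc_auc,
                                 subgroup_report, youden_cutoff)


from oracles import brute_force_auc, exhaustive_youden


class TestRocAuc:
    def test_perfect_and_reversed_ranking(self):
        labels = [0, 0, 1, 1]
        assert roc_auc([0.1, 0.2, 0.8, 0.9], labels)[1] == 1.0
        assert roc_auc([0.9, 0.8, 0.2, 0.1], labels)[1] == 0.0

    def test_hand_example(self):
        # pairs (pos, neg): (.35,.1)+, (.35,.4)-, (.8,.1)+, (.8,.4)+ -> 3/4
        _, auc = roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert auc == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(MetricError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(4, 201))
            scores = np.round(rng.random(n), 2)  # rounded -> ties occur
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            _, auc = roc_auc(scores, labels)
            assert auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)


class TestYouden:
    def test_perfectly_separable(self):
        _, j, sens, spec = youden_cutoff([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert j == 1.0 and sens == 1.0 and spec == 1.0

    def test_uninformative_scores(self):
        cutoff, j, _, _ = youden_cutoff([0.5] * 6, [0, 1, 0, 1, 0, 1])
        assert j == 0.0
        assert cutoff == 0.5  # smallest candidate on ties

    def test_hand_example(self):
        cutoff, j, sens, spec = youden_cutoff([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert cutoff == pytest.approx(0.35)
        assert j == pytest.approx(0.5)
        assert sens == 1.0 and spec == 0.5

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = int(rng.integers(4, 120))
            scores = np.round(rng.random(n), 2)
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            got = youden_cutoff(scores, labels)
            want = exhaustive_youden(scores, labels)
            assert got[0] == pytest.approx(want[0])
            assert got[1] == pytest.approx(want[1])

    def test_operating_point_lies_on_roc(self):
        rng = np.random.default_rng(2)
        scores = rng.random(60)
        labels = rng.integers(0, 2, 60)
        labels[:2] = [0, 1]
        (fpr, tpr), _ = roc_auc(scores, labels)
        _, _, sens, spec = youden_cutoff(scores, labels)
        on_curve = np.any(np.isclose(fpr, 1 - spec) & np.isclose(tpr, sens))
        assert on_curve


class TestSubgroups:
    @pytest.fixture()
    def toy_table(self):
        return pd.DataFrame({
            "score": [0.9, 0.2, 0.8, 0.3, 0.7, 0.4, 0.1, 0.6],
            "label": [1, 0, 1, 0, 1, 0, 0, 0],
            "finding": ["mass", "mass", "calcification", "calcification",
                        "distortion", "distortion", "normal", "normal"],
            "density": ["DB", "DB", "Not-DB", "Not-DB", "DB", "DB", "DB", "Not-DB"],
        })

    def test_subgroup_aucs_match_brute_force(self, toy_table):
        rep = subgroup_report(toy_table, cutoff=0.5)
        for finding in ("mass", "calcification", "distortion"):
            sub = toy_table[toy_table.finding == finding]
            assert rep["per_finding_auc"][finding] == pytest.approx(
                brute_force_auc(sub.score, sub.label))
        for density in ("DB", "Not-DB"):
            sub = toy_table[toy_table.density == density]
            assert rep["per_density_auc"][density] == pytest.approx(
                brute_force_auc(sub.score, sub.label))

    def test_normal_tnr(self, toy_table):
        rep = subgroup_report(toy_table, cutoff=0.5)
        # normal scores 0.1 and 0.6: one below cutoff
        assert rep["normal_tnr"] == pytest.approx(0.5)
        all_low = toy_table.copy()
        all_low.loc[all_low.finding == "normal", "score"] = 0.0
        assert subgroup_report(all_low, 0.5)["normal_tnr"] == 1.0

    def test_single_class_subgroup_is_nan_not_error(self, toy_table):
        crippled = toy_table.copy()
        crippled.loc[crippled.finding == "mass", "label"] = 0
        rep = subgroup_report(crippled, 0.5)
        assert np.isnan(rep["per_finding_auc"]["mass"])


class TestMeanRoc:
    def test_single_trial_identity(self):
        fpr = np.array([0.0, 0.5, 1.0])
        tpr = np.array([0.0, 0.8, 1.0])
        grid, mean_tpr, (lo, hi) = mean_roc_curve([(fpr, tpr)])
        np.testing.assert_allclose(mean_tpr, np.interp(grid, fpr, tpr))
        np.testing.assert_allclose(lo, hi)

    def test_two_identical_trials_zero_envelope(self):
        curve = (np.array([0.0, 0.3, 1.0]), np.array([0.0, 0.9, 1.0]))
        _, _, (lo, hi) = mean_roc_curve([curve, curve])
        np.testing.assert_allclose(lo, hi)

    def test_two_hand_drawn_curves(self):
        a = (np.array([0.0, 0.5, 1.0]), np.array([0.0, 0.6, 1.0]))
        b = (np.array([0.0, 0.5, 1.0]), np.array([0.0, 1.0, 1.0]))
        grid, mean_tpr, _ = mean_roc_curve([a, b])
        # at fpr=0.5: (0.6 + 1.0)/2 = 0.8 ; at fpr=0.25: (0.3 + 0.5)/2 = 0.4
        assert mean_tpr[50] == pytest.approx(0.8)
        assert mean_tpr[25] == pytest.approx(0.4)
        assert np.all(np.diff(mean_tpr) >= -1e-12)

    def test_empty_rejected(self):
        with pytest.raises(MetricError):
            mean_roc_curve([])


class TestGroupedKFold:
    def test_equal_folds_for_ten_patients(self):
        plan = grouped_kfold([f"P{i}" for i in range(10)], k=5, trials=3, seed=0)
        for trial in range(3):
            sizes = [len(plan.patients_in_fold(trial, f)) for f in range(5)]
            assert sizes == [2] * 5

    def test_patient_never_spans_folds(self):
        patients = [f"P{i}" for i in range(23)]
        image_patients = patients * 3  # several images per patient
        plan = grouped_kfold(image_patients, k=5, trials=4, seed=1)
        for trial in range(4):
            folds = [plan.fold_of(trial, p) for p in patients]
            assert all(0 <= f < 5 for f in folds)
            # conservation: union of folds = all patients, pairwise disjoint
            union = set().union(*(plan.patients_in_fold(trial, f) for f in range(5)))
            assert union == set(patients)
            sizes = [len(plan.patients_in_fold(trial, f)) for f in range(5)]
            assert sum(sizes) == len(patients)
            assert max(sizes) - min(sizes) <= 1

    def test_deterministic(self):
        ids = [f"P{i}" for i in range(17)]
        a = grouped_kfold(ids, seed=5)
        b = grouped_kfold(ids, seed=5)
        assert a.assignment == b.assignment

    def test_too_few_patients(self):
        with pytest.raises(ValueError):
            grouped_kfold(["A", "B"], k=5)


class TestAucTTest:
    def test_identical_vectors(self):
        t, p = compare_auc_ttest([0.9, 0.8, 0.85], [0.9, 0.8, 0.85])
        assert t == 0.0 and p == 1.0

    def test_constant_shift_with_jitter_significant(self):
        rng = np.random.default_rng(3)
        base = 0.85 + rng.normal(0, 1e-4, 10)
        t, p = compare_auc_ttest(base + 0.01, base)
        assert p < 0.05 and t > 0

    def test_matches_closed_form(self):
        a = np.array([0.91, 0.92, 0.90, 0.93, 0.94, 0.92, 0.91, 0.93, 0.92, 0.90])
        b = np.array([0.90, 0.91, 0.90, 0.91, 0.92, 0.91, 0.90, 0.92, 0.91, 0.89])
        d = a - b
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        t, p = compare_auc_ttest(a, b)
        assert t == pytest.approx(t_hand)
        assert 0 <= p <= 1

    def test_zero_variance_nonzero_mean(self):
        t, p = compare_auc_ttest([0.9, 0.9], [0.8, 0.8])
        assert p == 0.0 and np.isinf(t)


class TestEvaluateRun:
    def test_full_report_structure(self):
        rng = np.random.default_rng(4)
        rows = []
        for trial in range(3):
            for i in range(80):
                label = int(rng.random() < 0.5)
                rows.append({
                    "trial": trial, "score": np.clip(label * 0.4 + rng.random() * 0.6, 0, 1),
                    "label": label,
                    "finding": rng.choice(["mass", "calcification", "normal"]),
                    "density": rng.choice(["DB", "Not-DB"]),
                })
        rows = pd.DataFrame(rows)
        rows.loc[rows.finding == "normal", "label"] = 0
        report = evaluate_run(rows)
        assert 0.5 < report.auc <= 1.0
        assert 0 <= report.sensitivity <= 1 and 0 <= report.specificity <= 1
        lo, hi = report.ci95["auc"]
        assert lo <= report.auc <= hi
        assert len(report.trial_aucs) == 3
        grid, tpr = report.mean_roc
        assert len(grid) == 101 and np.all(np.diff(tpr) >= -1e-12)
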