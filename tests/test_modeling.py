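import numpy as np
import pandas as pd
import pytest

import saddlefit as sf
from saddlefit.features import FEATURE_NAMES
from saddlefit.modeling import (ClassifierSpec, cv_misclassification,
                                forward_sfs, losocv_evaluate,
                                single_feature_accuracy_ranking,
                                tune_hyperparameters)


def blobs(n_per_class=40, spread=0.2, centers=(0.0, 5.0, 10.0), seed=0,
          n_features=2):
    rng = np.random.default_rng(seed)
    X, y = [], []
    for c, mu in enumerate(centers, start=1):
        X.append(rng.normal(mu, spread, size=(n_per_class, n_features)))
        y.extend([c] * n_per_class)
    return pd.DataFrame(np.vstack(X),
                        columns=[f"f{i}" for i in range(n_features)]), np.array(y)


class TestCvMisclassification:
    def test_separable_blobs_have_zero_rate(self):
        X, y = blobs()
        rate = cv_misclassification(X, y, ClassifierSpec("knn",
                                    {"n_neighbors": 1}), folds=5, seed=0)
        assert rate == 0.0

    def test_permuted_labels_sit_at_chance(self):
        """With labels shuffled, three balanced classes give ~2/3
        misclassification; the mean over 20 seeds stays within 5 binomial
        standard errors of the null."""
        X, _ = blobs(n_per_class=200, seed=1)
        n = len(X)
        rates = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            y_perm = rng.permutation(np.repeat([1, 2, 3], 200))
            rates.append(cv_misclassification(
                X, y_perm, ClassifierSpec("knn"), folds=5, seed=seed))
        se = np.sqrt((2 / 3) * (1 / 3) / (n * 20))
        assert abs(np.mean(rates) - 2 / 3) < 5 * se

    def test_rate_matches_hand_tally_per_fold(self):
        """The reported rate equals an independent per-fold error count
        using the returned fold assignment."""
        X, y = blobs(n_per_class=10, spread=3.0, centers=(0.0, 2.0, 4.0),
                     seed=2)
        spec = ClassifierSpec("knn", {"n_neighbors": 3})
        rate, folds = cv_misclassification(X, y, spec, folds=5, seed=0,
                                           return_folds=True)
        errors = 0
        Xa = X.to_numpy()
        for k in range(5):
            te = folds == k
            clf = spec.build()
            clf.fit(Xa[~te], y[~te])
            errors += int(np.sum(clf.predict(Xa[te]) != y[te]))
        assert rate == errors / len(y)

    def test_class_smaller_than_folds_raises(self):
        X, y = blobs(n_per_class=3)
        with pytest.raises(ValueError, match="stratified"):
            cv_misclassification(X, y, ClassifierSpec("knn"), folds=5)


class TestForwardSFS:
    def test_informative_feature_found_first_then_stops(self):
        """One feature separates the classes, nine are pure noise: the
        informative one is picked first (verified against an exhaustive
        single-feature scan) and the search stops by tolerance."""
        rng = np.random.default_rng(0)
        n = 150
        y = np.repeat([1, 2, 3], n // 3)
        X = pd.DataFrame(rng.normal(size=(n, 10)),
                         columns=[f"f{i}" for i in range(10)])
        X["f3"] = y * 2.0 + rng.normal(0, 0.1, n)
        spec = ClassifierSpec("knn")
        res = forward_sfs(X, y, spec, folds=5, tol=1e-4, seed=0)
        scan = [cv_misclassification(X[[c]], y, spec, folds=5, seed=0)
                for c in X.columns]
        assert res.selected[0] == X.columns[int(np.argmin(scan))] == "f3"
        assert res.stop_reason == "tolerance"
        assert len(res.selected) <= 3

    def test_duplicate_features_select_exactly_one(self):
        rng = np.random.default_rng(1)
        base = np.repeat([1, 2, 3], 30) + rng.normal(0, 0.05, 90)
        X = pd.DataFrame({f"copy{i}": base for i in range(4)})
        y = np.repeat([1, 2, 3], 30)
        res = forward_sfs(X, y, ClassifierSpec("knn"), seed=0)
        assert len(res.selected) == 1

    def test_every_step_matches_exhaustive_scan(self):
        """Step-wise oracle: each greedy pick equals the argmin of an
        independently recomputed scan over that step's candidates."""
        rng = np.random.default_rng(2)
        n = 120
        y = np.repeat([1, 2, 3], n // 3)
        X = pd.DataFrame({
            "a": y + rng.normal(0, 0.8, n),
            "b": rng.normal(size=n),
            "c": (y == 2) + rng.normal(0, 0.4, n),
            "d": rng.normal(size=n),
            "e": y + rng.normal(0, 2.0, n),
        })
        spec = ClassifierSpec("knn")
        res = forward_sfs(X, y, spec, folds=5, tol=1e-4, seed=0)
        selected = []
        remaining = list(X.columns)
        for pick in res.selected:
            rates = [cv_misclassification(X[selected + [c]], y, spec,
                                          folds=5, seed=0)
                     for c in remaining]
            assert pick == remaining[int(np.argmin(rates))]
            selected.append(pick)
            remaining.remove(pick)

    def test_trace_is_non_increasing_and_selection_unique(self,
                                                          small_cohort_table):
        data = sf.LabeledDataset.from_feature_table(
            sf.normalize_columns(small_cohort_table))
        res = forward_sfs(data.X, data.y, ClassifierSpec("knn"), seed=0,
                          max_features=6)
        assert len(set(res.selected)) == len(res.selected)
        assert all(a >= b - 1e-12 for a, b in zip(res.trace, res.trace[1:]))


class TestTuneHyperparameters:
    def fixture_xy(self):
        # tight blobs: small k clearly optimal, large k catastrophic
        rng = np.random.default_rng(3)
        centers = np.arange(30.0)
        y = np.array([c % 3 + 1 for c in range(30) for _ in range(3)])
        X = pd.DataFrame({
            "f0": np.repeat(centers, 3) + rng.normal(0, 0.03, 90)})
        return X, y

    def test_knn_matches_exhaustive_grid_oracle(self):
        """On interleaved tight clusters the exhaustive grid says k=1 wins;
        the sequential optimizer must land in the same small-k basin."""
        X, y = self.fixture_xy()
        grid = {}
        for k in range(1, 51):
            for metric in ("euclidean", "cityblock"):
                spec = ClassifierSpec("knn", {"n_neighbors": k,
                                              "metric": metric})
                grid[(k, metric)] = cv_misclassification(X, y, spec,
                                                         folds=5, seed=42)
        best_k = min(grid, key=grid.get)[0]
        assert best_k == 1
        res = tune_hyperparameters(X, y, "knn", budget=30, seed=42, folds=5)
        assert res.spec.params["n_neighbors"] <= 2
        assert res.score <= min(grid.values()) + 0.02

    def test_same_seed_same_result(self):
        X, y = self.fixture_xy()
        a = tune_hyperparameters(X, y, "dt", budget=8, seed=5)
        b = tune_hyperparameters(X, y, "dt", budget=8, seed=5)
        assert a.spec == b.spec and a.score == b.score

    def test_budget_too_small_raises(self):
        X, y = self.fixture_xy()
        with pytest.raises(ValueError):
            tune_hyperparameters(X, y, "knn", budget=3)

    def test_single_class_raises(self):
        X, _ = self.fixture_xy()
        with pytest.raises(ValueError):
            tune_hyperparameters(X, np.ones(len(X)), "knn", budget=6)


def cohort_table(n_subjects=4, n_cycles=6, seed=0, **cfg_kwargs):
    cfg = sf.SimulationConfig(n_cycles=n_cycles, seed=seed, **cfg_kwargs)
    cycles = []
    for rec in sf.generate_cohort(n_subjects, cfg):
        cs, _ = sf.segment_recording(rec)
        cycles.extend(cs)
    return sf.build_feature_table(cycles)


class TestLosocv:
    def test_noiseless_separable_cohort_is_perfect(self):
        """Identical riders, zero noise and fixed saddle fractions: the
        classes are exactly separable and KNN scores 100%."""
        cfg = sf.SimulationConfig(
            n_cycles=5, cadence_jitter_sd=0.0, sagittal_noise_sd=0.0,
            sagittal_cycle_sd=0.0, offplane_cycle_sd=0.0,
            offplane_sd_base=0.0, offplane_sd_slope=0.0, rank_noise_sd=0.0)
        cycles = []
        for sid in (1, 2, 3):
            prof = sf.AnthropometricProfile(880, 560, 530, 80, sid)
            for level in (sf.SaddleLevel.low(),
                          sf.SaddleLevel.moderate(fraction=1.0),
                          sf.SaddleLevel.high()):
                rig = sf.RigGeometry(
                    saddle_height=level.gth_fraction * 880)
                rec = sf.simulate_recording(prof, rig, level, cfg)
                cs, _ = sf.segment_recording(rec)
                cycles.extend(cs)
        table = sf.build_feature_table(cycles)
        report = losocv_evaluate(table, [ClassifierSpec("knn")],
                                 leakage_mode="paper", seed=0)
        assert report.models["knn"]["average"] == pytest.approx(100.0)

    def test_permuted_labels_hit_chance_level(self):
        """Shuffling labels within subjects pushes LOSOCV accuracy to the
        1/3 chance level (mean over 20 seeds)."""
        table = cohort_table(n_subjects=4, n_cycles=6)
        accs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            y_perm = table.y.copy()
            for s in np.unique(table.subjects):
                m = table.subjects == s
                y_perm[m] = rng.permutation(y_perm[m])
            shuffled = sf.FeatureTable(X=table.X, y=y_perm,
                                       subjects=table.subjects)
            rep = losocv_evaluate(shuffled, [ClassifierSpec("knn")],
                                  leakage_mode="paper", seed=seed)
            accs.append(rep.models["knn"]["average"])
        assert abs(np.mean(accs) - 100 / 3) < 5.0

    def test_two_subject_fixture_matches_manual_tally(self):
        """Hand-checkable 2-subject dataset without SMOTE or normalization
        surprises: the report equals a manual fit-and-count."""
        X = pd.DataFrame(0.5, index=range(12), columns=FEATURE_NAMES)
        rng = np.random.default_rng(0)
        labels = np.array([1, 1, 2, 2, 3, 3] * 2)
        X["theta_knee_Mean"] = labels * 10.0 + rng.normal(0, 0.1, 12)
        subjects = np.array([1] * 6 + [2] * 6)
        table = sf.FeatureTable(X=X, y=labels, subjects=subjects)
        spec = ClassifierSpec("knn", {"n_neighbors": 1})
        report = losocv_evaluate(table, [spec],
                                 feature_subset=["theta_knee_Mean"],
                                 leakage_mode="strict", seed=0, smote=False)
        # manual: train on the other subject, predict with 1-NN
        expected = []
        for s in (1, 2):
            tr = subjects != s
            scale = np.abs(X.loc[tr, "theta_knee_Mean"]).max()
            xtr = (X.loc[tr, "theta_knee_Mean"] / scale).to_numpy()
            xte = (X.loc[~tr, "theta_knee_Mean"] / scale).to_numpy()
            pred = [labels[tr][np.argmin(np.abs(xtr - v))] for v in xte]
            expected.append(np.mean(pred == labels[~tr]))
        assert report.models["knn"]["average"] == pytest.approx(
            100.0 * np.mean(expected))

    def test_average_invariant_to_subject_relabeling(self):
        table = cohort_table(n_subjects=4, n_cycles=5)
        rep1 = losocv_evaluate(table, [ClassifierSpec("knn")], seed=0)
        remap = {1: 40, 2: 17, 3: 99, 4: 5}
        table2 = sf.FeatureTable(
            X=table.X, y=table.y,
            subjects=np.array([remap[s] for s in table.subjects]))
        rep2 = losocv_evaluate(table2, [ClassifierSpec("knn")], seed=0)
        assert rep1.models["knn"]["average"] == pytest.approx(
            rep2.models["knn"]["average"])

    def test_unknown_leakage_mode_rejected(self, small_cohort_table):
        with pytest.raises(ValueError):
            losocv_evaluate(small_cohort_table, [ClassifierSpec("knn")],
                            leakage_mode="loose")


class TestSingleFeatureRanking:
    def test_label_copy_scores_perfectly(self):
        rng = np.random.default_rng(0)
        y = np.repeat([1, 2, 3], 30)
        X = pd.DataFrame({"oracle": y.astype(float),
                          "noise": rng.normal(size=90)})
        ranking = single_feature_accuracy_ranking(X, y,
                                                  ClassifierSpec("knn"))
        assert ranking[0][0] == "oracle"
        assert ranking[0][1] == pytest.approx(100.0)
        assert ranking[1][1] < 55.0      # noise near the 33% chance level

    def test_sorted_descending_with_name_tiebreak(self):
        y = np.repeat([1, 2, 3], 20)
        X = pd.DataFrame({"b": y.astype(float), "a": y.astype(float)})
        ranking = single_feature_accuracy_ranking(X, y, ClassifierSpec("knn"))
        assert [r[0] for r in ranking] == ["a", "b"]


class TestModelResultsFrontEnd:
    def test_fit_returns_results_with_summary(self, small_cohort_table):
        res = sf.SaddleHeightModel(small_cohort_table).fit(
            models=("knn",), max_features=4, seed=0)
        text = res.summary()
        assert "LOSOCV" in text and "knn" in text
        assert res.selection.selected
        frame = res.report.summary_frame()
        assert set(frame.columns) == {"low_acc_pct", "moderate_acc_pct",
                                      "high_acc_pct", "average_acc_pct"}

    def test_normalized_table_rejected(self, small_cohort_table):
        with pytest.raises(ValueError):
            sf.SaddleHeightModel(sf.normalize_columns(small_cohort_table))
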