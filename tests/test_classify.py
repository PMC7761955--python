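import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.svm import SVC

from metabopanel import (
    CohortSpec,
    clinical_marker_roc,
    evaluate,
    evaluate_scores,
    exhaustive_panel_search,
    generate_cohort,
    hybrid_model,
    optimal_cutoff,
    roc_curve,
    train_svm,
)
from metabopanel.classify import ClassifierError

from conftest import make_meta


def auc_oracle(scores, labels):
    """Normalized Mann-Whitney U with midrank ties counting 1/2."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    pos, neg = scores[y == 1], scores[y == 0]
    gt = (pos[:, None] > neg[None, :]).sum()
    eq = (pos[:, None] == neg[None, :]).sum()
    return (gt + 0.5 * eq) / (len(pos) * len(neg))


def blobs(n=40, gap=4.0, seed=0, p=2):
    rng = np.random.default_rng(seed)
    y = np.r_[np.zeros(n // 2), np.ones(n // 2)].astype(int)
    X = rng.normal(size=(n, p)) + gap * y[:, None]
    return X, y


class TestRocCurve:
    def test_perfect_ranking(self):
        roc = roc_curve([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert roc.auc == 1.0

    def test_three_of_four_concordant_pairs(self):
        roc = roc_curve([0.9, 0.7, 0.8, 0.6], [1, 1, 0, 0])
        assert roc.auc == pytest.approx(0.75)

    def test_auc_equals_mann_whitney_u(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            n = rng.integers(6, 30)
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                continue
            # coarse grid forces ties
            s = rng.integers(0, 5, n) / 4.0
            assert roc_curve(s, y).auc == pytest.approx(auc_oracle(s, y), abs=1e-12)

    def test_sensitivity_nonincreasing_in_threshold(self):
        rng = np.random.default_rng(2)
        s, y = rng.random(50), rng.integers(0, 2, 50)
        roc = roc_curve(s, y)
        # thresholds descending -> sensitivity nondecreasing along the array
        assert (np.diff(roc.sensitivity) >= -1e-12).all()

    def test_single_class_errors(self):
        with pytest.raises(ClassifierError):
            roc_curve([0.1, 0.9], [1, 1])


class TestOptimalCutoff:
    def scan_oracle(self, scores, y):
        best = None
        for thr in np.unique(scores):
            sens = np.mean(np.asarray(scores)[np.asarray(y) == 1] >= thr)
            spec = np.mean(np.asarray(scores)[np.asarray(y) == 0] < thr)
            key = (sens + spec - 1, spec, thr)
            if best is None or key > best:
                best = key
        return best[2]

    def test_hand_example(self):
        scores = [0.9, 0.8, 0.7, 0.6, 0.75, 0.3, 0.2, 0.1]
        y = [1, 1, 1, 1, 0, 0, 0, 0]
        roc = roc_curve(scores, y)
        cut = optimal_cutoff(roc)
        assert cut == pytest.approx(0.6)
        rep = evaluate_scores(scores, y, cut)
        assert rep.sensitivity == 1.0 and rep.specificity == 0.75

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = rng.integers(8, 40)
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                continue
            s = np.round(rng.random(n), 2)
            if len(np.unique(s)) < 2:
                continue
            assert optimal_cutoff(roc_curve(s, y)) == self.scan_oracle(s, y)

    def test_separated_scores_cutoff_at_smallest_positive(self):
        scores = [0.9, 0.8, 0.2, 0.1]
        y = [1, 1, 0, 0]
        assert optimal_cutoff(roc_curve(scores, y)) == 0.8

    def test_degenerate_scores_error(self):
        with pytest.raises(ClassifierError):
            optimal_cutoff(roc_curve([0.5, 0.5, 0.5], [1, 0, 1]))


class TestTrainSvm:
    def test_separable_blobs_perfect_training_accuracy(self):
        X, y = blobs()
        model = train_svm(X, y, gamma=0.1, cost=100.0, seed=1000)
        model.probability_cutoff = 0.5
        assert (model.predict(X) == y).mean() == 1.0

    def test_same_seed_identical_probabilities(self):
        X, y = blobs(seed=4, gap=1.0)
        m1 = train_svm(X, y, seed=520)
        m2 = train_svm(X, y, seed=520)
        np.testing.assert_array_equal(m1.scores(X), m2.scores(X))

    def test_single_class_rejected(self):
        X, _ = blobs()
        with pytest.raises(ClassifierError):
            train_svm(X, np.ones(len(X), dtype=int))

    def test_frozen_scaler_used_at_evaluation(self):
        X, y = blobs(seed=5)
        model = train_svm(X, y, seed=1)
        model.set_cutoff_from(X, y)
        shifted = X + 100.0     # same data in a shifted frame
        rep_orig = evaluate(model, X, y, cohort="discovery")
        rep_shift = evaluate(model, shifted, y, cohort="discovery")
        # the frozen scaler centers at training means, so a shift degrades
        # scores instead of being silently re-normalized away
        assert rep_orig.auc >= rep_shift.auc


class TestPanelSearch:
    def cv_auc_oracle(self, X, y, cols, folds, gamma, cost, seed):
        """Independent CV-AUC: same documented fold rule (global shuffled
        order, within-class rank mod folds), own scaling and SVM calls."""
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(y))
        fold_of = np.empty(len(y), dtype=int)
        for cls in np.unique(y.astype(float)):
            members = order[y[order].astype(float) == cls]
            fold_of[members] = np.arange(len(members)) % folds
        Xs = X[:, list(cols)]
        aucs = []
        for k in range(folds):
            tr, te = fold_of != k, fold_of == k
            mu = Xs[tr].mean(0)
            div = np.sqrt(Xs[tr].std(0, ddof=1))
            Ztr, Zte = (Xs[tr] - mu) / div, (Xs[te] - mu) / div
            s = SVC(kernel="rbf", gamma=gamma, C=cost).fit(Ztr, y[tr]).decision_function(Zte)
            if len(np.unique(y[te])) == 2:
                aucs.append(roc_auc_score(y[te], s))
        return float(np.mean(aucs))

    def enumerate_oracle(self, candidates, X, y, max_size, folds, gamma, cost, seed):
        best = (-np.inf, None)
        for size in range(1, max_size + 1):
            for cols in itertools.combinations(range(len(candidates)), size):
                score = self.cv_auc_oracle(X, y, cols, folds, gamma, cost, seed)
                if score > best[0]:
                    best = (score, cols)
        return [candidates[c] for c in best[1]], best[0]

    def test_xor_pair_found_by_enumeration(self):
        # only features 0 and 1 jointly separate the classes
        rng = np.random.default_rng(6)
        n = 60
        a = rng.integers(0, 2, n)
        b = rng.integers(0, 2, n)
        y = (a ^ b).astype(int)
        X = np.c_[
            a + rng.normal(0, 0.1, n),
            b + rng.normal(0, 0.1, n),
            rng.normal(size=(n, 2)),
        ]
        cands = ["f1", "f2", "f3", "f4"]
        res = exhaustive_panel_search(
            cands, X, y, max_panel_size=2, folds=5, gamma=1.0, cost=10.0,
            seed=3, budget=100,
        )
        oracle_panel, _ = self.enumerate_oracle(cands, X, y, 2, 5, 1.0, 10.0, 3)
        assert sorted(res.panel) == ["f1", "f2"] == sorted(oracle_panel)
        assert res.method == "exhaustive"

    def test_agrees_with_full_enumeration_8_candidates(self):
        rng = np.random.default_rng(7)
        X, y = blobs(n=30, gap=1.0, seed=7, p=8)
        X[:, 3] += 1.5 * y      # make one feature clearly best
        cands = [f"c{i}" for i in range(8)]
        res = exhaustive_panel_search(
            cands, X, y, max_panel_size=3, folds=5, gamma=0.1, cost=10.0,
            seed=11, budget=1000,
        )
        oracle_panel, oracle_score = self.enumerate_oracle(
            cands, X, y, 3, 5, 0.1, 10.0, 11
        )
        assert res.n_evaluated == 92
        assert res.panel == oracle_panel
        assert res.cv_auc == pytest.approx(oracle_score, abs=1e-12)

    def test_single_candidate_returned(self):
        X, y = blobs(n=20, seed=8, p=1)
        res = exhaustive_panel_search(["only"], X, y, folds=5, seed=0)
        assert res.panel == ["only"]

    def test_budget_overflow_triggers_reported_greedy(self):
        X, y = blobs(n=30, gap=2.0, seed=9, p=6)
        res = exhaustive_panel_search(
            [f"c{i}" for i in range(6)], X, y, max_panel_size=3, folds=5,
            seed=0, budget=5,
        )
        assert res.method == "greedy_forward"
        assert res.used_fallback
        assert 1 <= len(res.panel) <= 3

    def test_empty_candidates_error(self):
        with pytest.raises(ClassifierError):
            exhaustive_panel_search([], np.zeros((4, 0)), np.array([0, 1, 0, 1]))


class TestEvaluate:
    def test_discovery_self_consistency(self):
        X, y = blobs(seed=10, gap=2.0)
        model = train_svm(X, y, seed=3)
        cut = model.set_cutoff_from(X, y)
        rep = evaluate(model, X, y, cohort="discovery")
        roc = roc_curve(model.scores(X), y)
        idx = int(np.where(roc.thresholds == cut)[0][0])
        assert rep.sensitivity == pytest.approx(roc.sensitivity[idx])
        assert rep.specificity == pytest.approx(roc.specificity[idx])
        assert rep.tp + rep.fp + rep.tn + rep.fn == rep.n

    def test_iid_validation_auc_close_to_discovery(self):
        rng = np.random.default_rng(12)
        def draw(n):
            y = np.r_[np.zeros(n // 2), np.ones(n // 2)].astype(int)
            X = rng.normal(size=(n, 3)) + 2.5 * y[:, None]
            return X, y
        X_d, y_d = draw(80)
        X_v, y_v = draw(200)
        model = train_svm(X_d, y_d, cost=10.0, seed=7)
        model.set_cutoff_from(X_d, y_d)
        rep_d = evaluate(model, X_d, y_d, cohort="discovery")
        rep_v = evaluate(model, X_v, y_v, cohort="validation")
        assert abs(rep_v.auc - rep_d.auc) <= 0.05

    def test_subset_filter_no_match_errors(self):
        X, y = blobs(seed=13)
        ids = [f"s{i}" for i in range(len(y))]
        meta = make_meta(ids, groups=["normal"] * 20 + ["malignant"] * 20)
        model = train_svm(X, y, seed=3)
        model.set_cutoff_from(X, y)
        with pytest.raises(ClassifierError, match="no samples"):
            evaluate(
                model, X, y, meta=meta, sample_ids=ids,
                subset_filter=lambda row: row["stage"] == "IV",
            )


class TestMarkerAndHybrid:
    def marker_meta(self, values, groups):
        ids = [f"s{i}" for i in range(len(values))]
        return ids, make_meta(ids, groups=groups, ca125=values)

    def test_marker_identical_to_class_auc_one(self):
        groups = ["normal"] * 5 + ["malignant"] * 5
        ids, meta = self.marker_meta([0.0] * 5 + [1.0] * 5, groups)
        y = np.r_[np.zeros(5), np.ones(5)].astype(int)
        res = clinical_marker_roc(meta, y, "ca125", ids)
        assert res.roc.auc == 1.0

    def test_fixed_cutoff_35_matches_hand_tally(self):
        # ten controls below/above 35 and ten cases: count directly
        vals = [5, 10, 20, 30, 34, 36, 40, 8, 12, 33,      # controls: 2 >= 35
                40, 100, 30, 36, 500, 20, 37, 90, 34, 70]  # cases: 7 >= 35
        groups = ["normal"] * 10 + ["malignant"] * 10
        ids, meta = self.marker_meta([float(v) for v in vals], groups)
        y = np.r_[np.zeros(10), np.ones(10)].astype(int)
        res = clinical_marker_roc(meta, y, "ca125", ids, fixed_cutoff=35.0)
        assert res.at_fixed.sensitivity == pytest.approx(7 / 10)
        assert res.at_fixed.specificity == pytest.approx(8 / 10)

    def test_class_independent_marker_auc_near_half(self):
        rng = np.random.default_rng(14)
        n = 500
        groups = ["normal"] * (n // 2) + ["malignant"] * (n // 2)
        ids, meta = self.marker_meta(rng.lognormal(3, 1, n), groups)
        y = np.r_[np.zeros(n // 2), np.ones(n // 2)].astype(int)
        res = clinical_marker_roc(meta, y, "ca125", ids)
        assert abs(res.roc.auc - 0.5) < 0.08

    def test_dominant_marker_gives_hybrid_auc_one(self):
        spec = CohortSpec(
            n_features=40, n_differential=0, seed=15,
            group_sizes={"normal": 10, "malignant": 10},
            missing_baseline=0.0,
        )
        table, meta, _ = generate_cohort(spec)
        import pandas as pd

        log_table = type(table)(
            pd.DataFrame(np.log2(table.values), index=table.labels,
                         columns=table.sample_ids),
            table.features.copy(),
        )
        ids = list(meta.non_qc_ids)
        y = (meta.table.loc[ids, "group"] == "malignant").astype(int)
        # overwrite the marker with a perfectly separating value
        meta.table.loc[ids, "ca125"] = np.where(y == 1, 1000.0, 5.0)
        panel = list(table.labels[:2])
        model, kept, n_excl = hybrid_model(
            log_table, meta, panel, "ca125", ids, y, gamma=0.1, cost=10.0, seed=1
        )
        assert n_excl == 0
        X, _, _ = __import__("metabopanel").assemble_matrix(
            log_table, meta, panel, kept, marker="ca125"
        )
        scores = model.scores(X.to_numpy())
        assert roc_curve(scores, y.loc[kept].to_numpy()).auc == 1.0

    def test_constant_marker_surfaces_scaling_error(self):
        spec = CohortSpec(
            n_features=10, n_differential=0, seed=16,
            group_sizes={"normal": 6, "malignant": 6}, missing_baseline=0.0,
        )
        table, meta, _ = generate_cohort(spec)
        ids = list(meta.non_qc_ids)
        y = (meta.table.loc[ids, "group"] == "malignant").astype(int)
        meta.table.loc[ids, "ca125"] = 42.0
        with pytest.raises(Exception, match="constant|scal"):
            hybrid_model(table, meta, list(table.labels[:2]), "ca125", ids, y)
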