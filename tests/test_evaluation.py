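import dataclasses

import numpy as np
import pytest

from pina import synth
from pina.evaluation import (
    BASE_METHODS,
    EnsembleConfig,
    ScoreMatrix,
    auc,
    ensemble_score,
    kfold_split,
    precision_recall_f1,
    run_cv,
    select_threshold,
)


def brute_force_auc(scores, labels):
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestAUC:
    def test_perfect_separation(self):
        assert auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties_is_half(self):
        assert auc([0.5] * 10, [1, 0] * 5) == 0.5

    def test_matches_pairwise_count_with_ties(self, rng):
        scores = rng.integers(0, 20, size=200).astype(float)  # heavy ties
        labels = rng.random(200) < 0.3
        if labels.all() or not labels.any():
            labels[0], labels[1] = True, False
        assert auc(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels), abs=1e-12
        )

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.random(80)
        labels = rng.random(80) < 0.4
        labels[0], labels[1] = True, False
        a1 = auc(scores, labels)
        assert auc(np.exp(3 * scores) + 7, labels) == pytest.approx(a1, abs=1e-12)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            auc([0.1, 0.2], [1, 1])


class TestPrecisionRecallF1:
    def test_perfect_prediction(self):
        assert precision_recall_f1([0.9, 0.8, 0.1], [1, 1, 0], 0.5) == (1.0, 1.0, 1.0)

    def test_hand_counted_halves(self):
        # 2 predicted, 1 true positive of 2 actual positives
        p, r, f1 = precision_recall_f1([0.9, 0.8, 0.1], [1, 0, 1], 0.5)
        assert (p, r, f1) == (0.5, 0.5, 0.5)

    def test_threshold_above_max_flags_empty_predictions(self, caplog):
        with caplog.at_level("WARNING", logger="pina"):
            p, r, f1 = precision_recall_f1([0.3, 0.2], [1, 0], 0.9)
        assert (p, r, f1) == (0.0, 0.0, 0.0) and "no predictions" in caplog.text


class TestSelectThreshold:
    def test_single_top_positive(self):
        scores, labels = [0.9, 0.5, 0.1], [1, 0, 0]
        t = select_threshold(scores, labels)
        assert t == 0.9
        assert precision_recall_f1(scores, labels, t)[2] == 1.0

    def test_matches_exhaustive_grid_search(self, rng):
        scores = rng.random(60)
        labels = rng.random(60) < 0.3
        labels[0] = True
        best = max(
            np.unique(scores),
            key=lambda t: (precision_recall_f1(scores, labels, t)[2], -t),
        )
        assert select_threshold(scores, labels) == pytest.approx(float(best))

    def test_all_positive_selects_min_score(self):
        assert select_threshold([0.4, 0.2, 0.9], [1, 1, 1]) == 0.2


class TestKFold:
    POS = [(f"c{i}", "d") for i in range(10)]

    def test_even_fold_sizes(self):
        folds = kfold_split(self.POS, 5, seed=1)
        sizes = np.bincount(list(folds.values()))
        assert list(sizes) == [2, 2, 2, 2, 2]

    def test_deterministic(self):
        assert kfold_split(self.POS, 5, 42) == kfold_split(self.POS, 5, 42)

    def test_partitions_positives(self):
        folds = kfold_split(self.POS, 3, 0)
        assert set(folds) == set(self.POS)

    def test_bad_k_rejected(self):
        with pytest.raises(ValueError):
            kfold_split(self.POS, 1, 0)
        with pytest.raises(ValueError):
            kfold_split(self.POS, 11, 0)


class TestEnsembleScore:
    def test_unanimous_methods_pass_through(self):
        cfg = EnsembleConfig({"a": 0.8, "b": 0.7, "c": 0.9})
        assert ensemble_score({"a": 0.4, "b": 0.4, "c": 0.4}, cfg) == pytest.approx(0.4)

    def test_degenerate_weights_select_one_method(self):
        cfg = EnsembleConfig({"a": 1.0, "b": 0.0, "c": 0.0})
        assert ensemble_score({"a": 0.3, "b": 0.9, "c": 0.9}, cfg) == pytest.approx(0.3)

    def test_hand_computed_normalised_sum(self):
        w = {"a": 0.85, "b": 0.81, "c": 0.86}
        s = {"a": 0.8, "b": 0.2, "c": 0.5}
        expected = (0.85 * 0.8 + 0.81 * 0.2 + 0.86 * 0.5) / (0.85 + 0.81 + 0.86)
        assert ensemble_score(s, EnsembleConfig(w)) == pytest.approx(expected)

    def test_raw_mode_skips_normalisation(self):
        cfg = EnsembleConfig({"a": 2.0}, normalize=False)
        assert ensemble_score({"a": 0.5}, cfg) == pytest.approx(1.0)

    def test_missing_method_errors(self):
        with pytest.raises(KeyError):
            ensemble_score({"a": 0.5}, EnsembleConfig({"b": 1.0}))

    def test_normalised_scores_stay_in_unit_interval(self, rng):
        for _ in range(20):
            w = {m: float(x) for m, x in zip("abc", rng.random(3) + 0.01)}
            s = {m: float(x) for m, x in zip("abc", rng.random(3))}
            assert 0.0 <= ensemble_score(s, EnsembleConfig(w)) <= 1.0


class TestRunCV:
    def test_folds_partition_positives(self, tiny_bundle):
        bundle, _ = tiny_bundle
        report = run_cv(bundle, k=5, seed=7)
        assert set(report.fold_of_positive) == set(bundle.associations.positives())
        sizes = np.bincount(list(report.fold_of_positive.values()), minlength=5)
        assert sizes.max() - sizes.min() <= 1

    def test_planted_structure_fully_recovered(self, tiny_bundle):
        bundle, _ = tiny_bundle
        report = run_cv(bundle, k=5, seed=7)
        for m in (*BASE_METHODS, "PINA"):
            assert report.per_method[m]["auc"] == 1.0

    def test_metrics_within_unit_interval(self, tiny_bundle):
        bundle, _ = tiny_bundle
        report = run_cv(bundle, k=5, seed=7)
        for v in report.per_method.values():
            for key in ("auc", "precision", "recall", "f1"):
                assert 0.0 <= v[key] <= 1.0

    def test_too_many_folds_rejected(self, tiny_bundle):
        bundle, _ = tiny_bundle
        with pytest.raises(ValueError):
            run_cv(bundle, k=10 ** 4, seed=0)


class TestScoreMatrix:
    def test_frame_round_trip(self, rng):
        sm = ScoreMatrix(["c1", "c2"], ["d1"], rng.random((2, 1)), "PIPP")
        back = ScoreMatrix.from_frame(sm.to_frame(), "PIPP")
        assert back.compounds == sm.compounds
        assert np.allclose(back.values, sm.values)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            ScoreMatrix(["c"], ["d"], np.array([[np.nan]]))
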