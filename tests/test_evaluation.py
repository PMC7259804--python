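import numpy as np
import pytest

from circda import pipeline as pipeline_mod
from circda.evaluation import (
    confusion_metrics,
    cross_validate,
    curve_metrics,
    f1_from_rates,
    independent_validation,
    kfold_split,
)
from circda.model import (
    build_training_set,
    sample_negatives,
    train_classifier,
)
from circda.pipeline import PipelineConfig, build_similarities


def bruteforce_auc(labels, scores):
    """Exhaustive pair-counting: P(pos outranks neg), ties half-credit."""
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestKFold:
    def test_balanced_fold_sizes(self):
        labels = np.concatenate([np.ones(612), np.zeros(612)])
        folds = kfold_split(labels, k=5, seed=0)
        for _, test in folds:
            per_class = np.bincount(labels[test].astype(int))
            assert all(size in (122, 123) for size in per_class)

    def test_every_sample_in_exactly_one_test_fold(self):
        labels = np.array([0, 1] * 10)
        folds = kfold_split(labels, k=5, seed=1)
        seen = np.concatenate([test for _, test in folds])
        assert sorted(seen) == list(range(20))

    def test_train_test_disjoint_union_is_everything(self):
        labels = np.array([0, 1] * 10)
        for train, test in kfold_split(labels, k=5, seed=1):
            assert not set(train) & set(test)
            assert sorted(np.concatenate([train, test])) == list(range(20))

    def test_too_few_samples_per_class_rejected(self):
        with pytest.raises(ValueError, match="per class"):
            kfold_split(np.array([0, 0, 0, 1, 1]), k=3)


class TestConfusionMetrics:
    def test_hand_computed_counts(self):
        # TP=3, FP=1, TN=4, FN=2
        labels = [1, 1, 1, 1, 1, 0, 0, 0, 0, 0]
        preds = [1, 1, 1, 0, 0, 1, 0, 0, 0, 0]
        m = confusion_metrics(labels, preds)
        assert (m["tp"], m["fp"], m["tn"], m["fn"]) == (3, 1, 4, 2)
        assert m["accuracy"] == pytest.approx(0.7)
        assert m["sensitivity"] == pytest.approx(0.6)
        assert m["precision"] == pytest.approx(0.75)
        assert m["f1"] == pytest.approx(2 * 0.6 * 0.75 / 1.35)

    def test_perfect_prediction_all_ones(self):
        m = confusion_metrics([0, 1, 1], [0, 1, 1])
        assert m["accuracy"] == m["sensitivity"] == m["precision"] == m["f1"] == 1.0

    def test_zero_denominator_flagged_not_raised(self):
        m = confusion_metrics([0, 0], [0, 0])
        assert m["sensitivity"] == 0.0
        assert "sensitivity" in m["undefined"]

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 2, 30)
        preds = rng.integers(0, 2, 30)
        perm = rng.permutation(30)
        assert confusion_metrics(labels, preds) == confusion_metrics(
            labels[perm], preds[perm]
        )

    def test_published_fold_arithmetic(self):
        # sensitivity 88.62%, precision 80.74% combine to F1 84.50%
        assert f1_from_rates(0.8862, 0.8074) * 100 == pytest.approx(84.50, abs=0.011)


class TestCurveMetrics:
    def test_perfect_and_reversed_rankings(self):
        labels = [0, 0, 1, 1]
        auc, aupr = curve_metrics(labels, [0.1, 0.2, 0.8, 0.9])
        assert auc == 1.0 and aupr == pytest.approx(1.0)
        auc_rev, _ = curve_metrics(labels, [0.9, 0.8, 0.2, 0.1])
        assert auc_rev == 0.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            curve_metrics([1, 1, 1], [0.1, 0.2, 0.3])

    def test_auc_matches_pair_counting_oracle_with_ties(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            labels = rng.integers(0, 2, 30)
            if labels.min() == labels.max():
                continue
            scores = rng.integers(0, 5, 30).astype(float)  # many ties
            auc, _ = curve_metrics(labels, scores)
            assert auc == pytest.approx(bruteforce_auc(labels, scores))


class TestCrossValidate:
    def test_report_shape_and_reproducibility(self, small_bundle):
        bundle, _, _ = small_bundle
        config = PipelineConfig(seed=3)
        report_a = cross_validate(bundle, config)
        report_b = cross_validate(bundle, config)
        assert len(report_a.folds) == 5
        assert (report_a.folds[["accuracy", "auc"]].to_numpy()
                == report_b.folds[["accuracy", "auc"]].to_numpy()).all()

    def test_planted_signal_recovered(self, small_bundle):
        bundle, _, _ = small_bundle
        report = cross_validate(bundle, PipelineConfig(seed=0))
        assert report.mean["auc"] > 0.9

    def test_fold_safe_never_sees_test_positives(self, small_bundle, monkeypatch):
        """Instrumentation: every fold-safe kernel rebuild must receive an
        association matrix with all test-fold positive cells zeroed."""
        bundle, _, _ = small_bundle
        acd = bundle.associations
        config = PipelineConfig(seed=11, fold_safe=True)

        positives = acd.positive_pairs()
        negatives = sample_negatives(acd, count=len(positives), seed=11)
        pairs = list(positives) + list(negatives)
        labels = np.concatenate(
            [np.ones(len(positives)), np.zeros(len(negatives))]
        )
        expected_folds = kfold_split(labels, k=5, seed=11)

        seen: list[np.ndarray] = []
        original = pipeline_mod.build_similarities

        def recording(bundle_, config_, acd_values=None, seq_sim=None):
            if acd_values is not None:
                seen.append(np.array(acd_values))
            return original(bundle_, config_, acd_values=acd_values, seq_sim=seq_sim)

        monkeypatch.setattr(pipeline_mod, "build_similarities", recording)
        cross_validate(bundle, config)
        assert len(seen) == 5
        for masked, (_, test_idx) in zip(seen, expected_folds):
            for t in test_idx:
                if labels[t] == 1:
                    i, j = pairs[t]
                    assert masked[i, j] == 0


class TestIndependentValidation:
    @pytest.fixture
    def fitted(self, small_bundle):
        bundle, _, _ = small_bundle
        s_c, s_d = build_similarities(bundle)
        acd = bundle.associations
        training = build_training_set(acd, s_c, s_d, seed=0)
        model = train_classifier(training.X, training.labels,
                                 n=acd.index.n, m=acd.index.m)
        return model, acd, s_c, s_d

    def test_external_subset_of_training_is_error(self, fitted):
        model, acd, s_c, s_d = fitted
        known = [
            (acd.index.circrna_ids[i], acd.index.disease_names[j])
            for i, j in acd.positive_pairs()[:4]
        ]
        with pytest.raises(ValueError, match="empty independent test set"):
            independent_validation(model, acd, known, s_c, s_d)

    def test_accuracy_is_fraction_scored_positive(self, fitted):
        model, acd, s_c, s_d = fitted
        unknown = acd.unknown_pairs()[:8]
        external = [
            (acd.index.circrna_ids[i], acd.index.disease_names[j])
            for i, j in unknown
        ]
        accuracy, report = independent_validation(model, acd, external, s_c, s_d)
        assert report["n_test"] == 8
        assert accuracy == pytest.approx(report["n_scored_positive"] / 8)

    def test_unmapped_names_reported_not_dropped_silently(self, fitted):
        model, acd, s_c, s_d = fitted
        i, j = acd.unknown_pairs()[0]
        external = [
            (acd.index.circrna_ids[i], acd.index.disease_names[j]),
            ("not_a_circ", "not a disease"),
        ]
        _, report = independent_validation(model, acd, external, s_c, s_d)
        assert report["n_unmapped"] == 1
        assert ("not_a_circ", "not a disease") in report["unmapped"]
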