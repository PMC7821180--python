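import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from snfnn import (
    CvConfig,
    FusionConfig,
    MetricsReport,
    ModelConfig,
    PipelineConfig,
    auc_curves,
    compare_reports,
    confusion_metrics,
    fuse_dataset,
    rank_novel_candidates,
    run_cross_validation,
    train_model,
)
from snfnn.evaluation import _feature_network
from snfnn.features import build_features, sample_balanced_pairs


def brute_force_auc_roc(labels, scores):
    """Pairwise concordance: P(pos outscores neg), ties counted half."""
    pos = [s for l, s in zip(labels, scores) if l == 1]
    neg = [s for l, s in zip(labels, scores) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def brute_force_auc_pr(labels, scores):
    """Step-wise sum of precision x recall increments, descending by score."""
    order = np.argsort(-np.asarray(scores), kind="stable")
    labels = np.asarray(labels)[order]
    scores = np.asarray(scores)[order]
    n_pos = labels.sum()
    area = 0.0
    tp = fp = 0
    prev_recall = 0.0
    i = 0
    while i < len(labels):
        j = i
        while j < len(labels) and scores[j] == scores[i]:  # threshold groups ties
            tp += labels[j]
            fp += 1 - labels[j]
            j += 1
        recall = tp / n_pos
        precision = tp / (tp + fp)
        area += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return area


class TestConfusionMetrics:
    def test_perfect_classifier(self):
        report = confusion_metrics(tp=50, tn=50, fp=0, fn=0)
        for name in ("accuracy", "specificity", "precision", "recall", "f1", "mcc"):
            assert report.metric(name) == 1.0

    def test_uninformative_classifier(self):
        report = confusion_metrics(tp=25, tn=25, fp=25, fn=25)
        assert report.mcc == 0.0
        assert report.accuracy == 0.5

    def test_hand_computed_confusion_table(self):
        report = confusion_metrics(tp=40, tn=45, fp=5, fn=10)
        assert report.accuracy == pytest.approx(0.85)
        assert report.specificity == pytest.approx(0.9)
        assert report.precision == pytest.approx(40 / 45)
        assert report.recall == pytest.approx(0.8)
        assert report.f1 == pytest.approx(2 * (40 / 45) * 0.8 / ((40 / 45) + 0.8))
        assert report.mcc == pytest.approx(0.70353, abs=1e-5)

    @given(
        tp=st.integers(0, 50), tn=st.integers(0, 50),
        fp=st.integers(0, 50), fn=st.integers(0, 50),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_sklearn_on_random_tables(self, tp, tn, fp, fn):
        if tp + tn + fp + fn == 0:
            return
        from sklearn.metrics import (
            accuracy_score,
            f1_score,
            matthews_corrcoef,
            precision_score,
            recall_score,
        )

        y_true = [1] * tp + [0] * tn + [0] * fp + [1] * fn
        y_pred = [1] * tp + [0] * tn + [1] * fp + [0] * fn
        report = confusion_metrics(tp, tn, fp, fn)
        assert report.accuracy == pytest.approx(accuracy_score(y_true, y_pred))
        if not report.degenerate:
            assert report.precision == pytest.approx(
                precision_score(y_true, y_pred), abs=1e-12
            )
            assert report.recall == pytest.approx(recall_score(y_true, y_pred), abs=1e-12)
            assert report.f1 == pytest.approx(f1_score(y_true, y_pred), abs=1e-12)
            assert report.mcc == pytest.approx(
                matthews_corrcoef(y_true, y_pred), abs=1e-12
            )

    def test_zero_denominator_flagged_not_raised(self):
        report = confusion_metrics(tp=0, tn=10, fp=0, fn=5)
        assert report.precision == 0.0
        assert "precision" in report.degenerate

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics(-1, 1, 1, 1)


class TestAucCurves:
    def test_perfect_scores(self):
        labels = np.array([0, 1, 0, 1])
        roc, pr = auc_curves(labels, labels.astype(float))
        assert roc == 1.0 and pr == 1.0

    def test_constant_scores_give_half_roc(self):
        labels = np.array([0, 1, 0, 1, 1])
        roc, _ = auc_curves(labels, np.full(5, 0.4))
        assert roc == pytest.approx(0.5)

    @given(seed=st.integers(0, 300))
    @settings(max_examples=40, deadline=None)
    def test_matches_brute_force_oracles(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 30))
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        scores = np.round(rng.random(n), 2)  # coarse grid forces score ties
        roc, pr = auc_curves(labels, scores)
        assert roc == pytest.approx(brute_force_auc_roc(labels, scores), abs=1e-12)
        assert pr == pytest.approx(brute_force_auc_pr(labels, scores), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_curves(np.ones(4), np.random.rand(4))


@pytest.fixture(scope="module")
def small_cv_result(small_dataset_module):
    config = PipelineConfig(
        fusion=FusionConfig(K=10, T=10),
        model=ModelConfig(
            n_hidden_layers=1, n_neurons=16, dropout_rate=0.0,
            batch_size=32, epochs=25, seed=0,
        ),
        cv=CvConfig(n_folds=4, n_repeats=2, base_seed=0),
    )
    return run_cross_validation(small_dataset_module, config), config


@pytest.fixture(scope="module")
def small_dataset_module():
    from snfnn import SyntheticConfig, generate_dataset

    dataset, _ = generate_dataset(
        SyntheticConfig(
            m=36, n=30, n_blocks=3, p_in=0.5, p_out=0.02,
            sim_signal=0.8, sim_noise_sd=0.05, seed=7,
        )
    )
    return dataset


class TestCrossValidation:
    def test_folds_cover_each_repeat_once(self, small_cv_result):
        result, config = small_cv_result
        assert len(result.folds) == config.cv.n_folds * config.cv.n_repeats
        assert len(result.histories) == len(result.folds)

    def test_fold_sizes_balanced_within_classes(self, small_dataset_module):
        from sklearn.model_selection import StratifiedKFold

        pairs = sample_balanced_pairs(small_dataset_module.interactions, seed=0)
        labels = np.array([p[2] for p in pairs])
        splitter = StratifiedKFold(n_splits=4, shuffle=True, random_state=0)
        seen = []
        for _, test_idx in splitter.split(np.zeros(len(labels)), labels):
            seen.append(test_idx)
            counts = np.bincount(labels[test_idx], minlength=2)
            assert abs(counts[0] - counts[1]) <= 1
        flat = np.concatenate(seen)
        assert len(flat) == len(labels)
        assert len(np.unique(flat)) == len(labels)  # disjoint partition

    def test_planted_structure_recovered(self, small_cv_result):
        result, _ = small_cv_result
        assert result.aggregate.auc_roc > 0.8
        assert result.aggregate.scope == "aggregate"
        assert set(result.aggregate.std) >= {"auc_roc", "auc_pr"}

    def test_aggregate_is_mean_of_folds(self, small_cv_result):
        result, _ = small_cv_result
        assert result.aggregate.auc_roc == pytest.approx(
            np.mean([f.auc_roc for f in result.folds])
        )

    def test_too_many_folds_rejected(self, small_dataset_module):
        config = PipelineConfig(cv=CvConfig(n_folds=10_000, n_repeats=1))
        with pytest.raises(ValueError):
            run_cross_validation(small_dataset_module, config)


@pytest.fixture(scope="module")
def trained_ranker(small_dataset_module):
    config = PipelineConfig(
        fusion=FusionConfig(K=10, T=10),
        model=ModelConfig(
            n_hidden_layers=1, n_neurons=16, dropout_rate=0.0,
            batch_size=32, epochs=25, seed=0,
        ),
    )
    fd, fs, _ = fuse_dataset(small_dataset_module, config)
    fd = _feature_network(fd, True)
    fs = _feature_network(fs, True)
    pairs = sample_balanced_pairs(small_dataset_module.interactions, seed=0)
    table = build_features(fd, fs, pairs)
    model, _ = train_model(table, config.model)
    return model, fd, fs


class TestRankNovelCandidates:
    def test_empty_candidates_empty_output(self, trained_ranker, small_dataset_module):
        model, fd, fs = trained_ranker
        ranked, per_drug = rank_novel_candidates(
            model, fd, fs, small_dataset_module.interactions, []
        )
        assert len(ranked) == 0 and len(per_drug) == 0

    def test_sorted_and_counts_consistent(self, trained_ranker, small_dataset_module):
        model, fd, fs = trained_ranker
        y = small_dataset_module.interactions
        zero_r, zero_c = np.nonzero(y.values == 0)
        candidates = [
            (y.drug_ids[r], y.disease_ids[c]) for r, c in zip(zero_r[:200], zero_c[:200])
        ]
        ranked, per_drug = rank_novel_candidates(model, fd, fs, y, candidates)
        assert (np.diff(ranked["score"].to_numpy()) <= 0).all()
        assert per_drug.sum() == ranked["predicted"].sum()
        assert (ranked["predicted"] == (ranked["score"] > 0.5)).all()

    def test_known_positive_candidate_rejected(self, trained_ranker, small_dataset_module):
        model, fd, fs = trained_ranker
        y = small_dataset_module.interactions
        r, c = np.argwhere(y.values == 1)[0]
        with pytest.raises(ValueError):
            rank_novel_candidates(
                model, fd, fs, y, [(y.drug_ids[r], y.disease_ids[c])]
            )


class TestCompareReports:
    @staticmethod
    def report(**kwargs):
        base = dict(
            tp=1, tn=1, fp=1, fn=1, accuracy=0.5, specificity=0.5,
            precision=0.5, recall=0.5, f1=0.5, mcc=0.0,
        )
        return MetricsReport(**(base | kwargs))

    def test_percentage_point_difference(self):
        a = self.report(auc_pr=0.856)
        b = self.report(auc_pr=0.301)
        assert compare_reports(a, b, "auc_pr") == 55.5

    def test_identical_reports_differ_by_zero(self):
        a = self.report(auc_roc=0.9)
        assert compare_reports(a, a, "auc_roc") == 0.0

    def test_unknown_metric_rejected(self):
        a = self.report(auc_roc=0.9)
        with pytest.raises(KeyError):
            compare_reports(a, a, "lift")

    def test_missing_metric_rejected(self):
        a = self.report()  # no AUCs recorded
        with pytest.raises(KeyError):
            compare_reports(a, a, "auc_roc")


def test_strict_no_leakage_mode_runs_and_differs(small_dataset_module):
    """Masking held-out positives out of the GIP/fusion stages changes the
    features, so the leak-free estimate differs from the default protocol."""
    base = PipelineConfig(
        fusion=FusionConfig(K=10, T=5),
        model=ModelConfig(
            n_hidden_layers=1, n_neurons=8, dropout_rate=0.0,
            batch_size=32, epochs=5, seed=0,
        ),
        cv=CvConfig(n_folds=3, n_repeats=1, base_seed=0),
    )
    import dataclasses

    default = run_cross_validation(small_dataset_module, base)
    strict = run_cross_validation(
        small_dataset_module, dataclasses.replace(base, strict_no_leakage=True)
    )
    assert strict.selection_reports is None  # per-fold selection, no global report
    assert len(strict.folds) == len(default.folds)
    assert strict.aggregate.auc_roc != default.aggregate.auc_roc
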