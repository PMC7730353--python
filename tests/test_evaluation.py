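import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from epshar import (
    PipelineConfig,
    confusion,
    feature_sweep,
    fit_pipeline,
    kfold_cv,
    metrics,
    split_train_test,
)
from epshar.evaluation import ConfusionMatrix, DEFAULT_SWEEP_COUNTS
from epshar.io_signals import LabeledDataset, SignalWindow
from epshar.synthetic import default_spec, generate

random_confusions = st.builds(
    lambda seed, k: ConfusionMatrix(
        counts=np.random.default_rng(seed).integers(0, 20, size=(k, k)) + np.eye(k, dtype=int),
        class_names=[str(i) for i in range(k)],
    ),
    seed=st.integers(0, 2**16),
    k=st.integers(2, 6),
)


class TestConfusion:
    def test_direct_count(self):
        c = confusion([0, 0, 1, 1], [0, 1, 1, 1], 2)
        np.testing.assert_array_equal(c.counts, [[1, 1], [0, 2]])

    def test_perfect_predictions_are_diagonal(self):
        y = [0, 1, 2, 2, 1]
        c = confusion(y, y, 3)
        np.testing.assert_array_equal(c.counts, np.diag([1, 2, 2]))

    def test_class_permutation_equivariance(self, rng):
        t = rng.integers(0, 3, 30)
        p = rng.integers(0, 3, 30)
        perm = np.array([2, 0, 1])
        c1 = confusion(t, p, 3)
        c2 = confusion(perm[t], perm[p], 3)
        np.testing.assert_array_equal(c1.counts, c2.counts[np.ix_(perm, perm)])

    def test_contract_errors(self):
        with pytest.raises(ValueError, match="length mismatch"):
            confusion([0], [0, 1], 2)
        with pytest.raises(ValueError, match="outside"):
            confusion([0, 2], [0, 1], 2)


class TestMetrics:
    def test_hand_computed_two_class_example(self):
        # class 0: Tp=8, Fp=2, Fn=1, Tn=9
        c = ConfusionMatrix(counts=np.array([[8, 1], [2, 9]]), class_names=["0", "1"])
        rep = metrics(c, averaging="macro")
        cls0 = rep.per_class[0]
        assert cls0["precision"] == pytest.approx(0.8000, abs=1e-4)
        assert cls0["recall"] == pytest.approx(0.8889, abs=1e-4)
        assert cls0["f1"] == pytest.approx(0.8421, abs=1e-4)
        assert rep.accuracy == pytest.approx(0.85, abs=1e-9)

    def test_diagonal_confusion_is_perfect(self):
        c = ConfusionMatrix(counts=np.diag([3, 4, 5]), class_names=list("abc"))
        rep = metrics(c)
        assert rep.accuracy == rep.precision == rep.recall == rep.f1 == 1.0

    @settings(max_examples=60, deadline=None)
    @given(random_confusions)
    def test_micro_identity_and_count_consistency(self, conf):
        rep = metrics(conf, averaging="micro")
        assert rep.micro["precision"] == pytest.approx(rep.accuracy, abs=1e-12)
        assert rep.micro["recall"] == pytest.approx(rep.accuracy, abs=1e-12)
        pc = conf.per_class_counts()
        for i in range(len(conf.class_names)):
            assert pc["tp"][i] + pc["fp"][i] + pc["fn"][i] + pc["tn"][i] == conf.total

    def test_zero_division_maps_to_zero(self):
        c = ConfusionMatrix(counts=np.array([[0, 2], [0, 3]]), class_names=["0", "1"])
        rep = metrics(c)
        assert rep.per_class[0]["precision"] == 0.0
        assert rep.per_class[0]["f1"] == 0.0

    def test_macro_invariant_under_relabeling(self, rng):
        t = rng.integers(0, 3, 60)
        p = rng.integers(0, 3, 60)
        perm = np.array([1, 2, 0])
        r1 = metrics(confusion(t, p, 3))
        r2 = metrics(confusion(perm[t], perm[p], 3))
        assert r1.precision == pytest.approx(r2.precision)
        assert r1.recall == pytest.approx(r2.recall)
        assert r1.accuracy == pytest.approx(r2.accuracy)

    def test_empty_confusion_rejected(self):
        c = ConfusionMatrix(counts=np.zeros((2, 2), dtype=int), class_names=["0", "1"])
        with pytest.raises(ValueError, match="empty"):
            metrics(c)


class TestSplitTrainTest:
    def test_even_split_counts(self, headline_dataset):
        tr, te = split_train_test(headline_dataset, 0.5, stratified=True, seed=0)
        for c in range(5):
            assert (tr.labels == c).sum() == 100
            assert (te.labels == c).sum() == 100

    def test_fraction_rounding_per_class(self):
        # Table-1-like uneven class sizes
        sizes = [19, 18, 19, 17, 30]
        windows = []
        r = np.random.default_rng(0)
        for c, n in enumerate(sizes):
            for _ in range(n):
                windows.append(
                    SignalWindow(values=r.normal(size=(2, 16)), sample_rate=50.0, label=c)
                )
        ds = LabeledDataset(windows=windows, class_names=[str(i) for i in range(5)])
        tr, _ = split_train_test(ds, 0.7, stratified=True, seed=1)
        for c, n in enumerate(sizes):
            assert (tr.labels == c).sum() == int(np.floor(0.7 * n + 0.5))

    def test_disjoint_exhaustive_and_deterministic(self, small_dataset):
        tr1, te1 = split_train_test(small_dataset, 0.6, seed=9)
        tr2, te2 = split_train_test(small_dataset, 0.6, seed=9)
        assert len(tr1) + len(te1) == len(small_dataset)
        assert tr1.labels.tolist() == tr2.labels.tolist()
        for a, b in zip(tr1.windows, tr2.windows):
            np.testing.assert_array_equal(a.values, b.values)

    def test_bad_fraction_and_tiny_class(self, small_dataset):
        with pytest.raises(ValueError, match="train_fraction"):
            split_train_test(small_dataset, 1.5)
        w = SignalWindow(values=np.zeros((1, 4)), sample_rate=50.0, label=0)
        w2 = SignalWindow(values=np.ones((1, 4)), sample_rate=50.0, label=1)
        w3 = SignalWindow(values=np.ones((1, 4)), sample_rate=50.0, label=1)
        ds = LabeledDataset(windows=[w, w2, w3], class_names=["a", "b"])
        with pytest.raises(ValueError, match="stratified"):
            split_train_test(ds, 0.5)


class TestKfoldCv:
    def test_fold_partition_and_sizes(self, small_dataset):
        result = kfold_cv(small_dataset, 3, seed=2)
        assert len(result.fold_reports) == 3
        totals = [r.confusion.total for r in result.fold_reports]
        assert sum(totals) == len(small_dataset)
        assert max(totals) - min(totals) <= small_dataset.n_classes
        # equal folds: mean accuracy equals pooled accuracy
        pooled = np.trace(result.mean_report.confusion.counts) / len(small_dataset)
        assert result.mean_report.accuracy == pytest.approx(pooled, abs=1e-12)

    def test_single_split_mode_uses_one_fold(self, small_dataset):
        result = kfold_cv(small_dataset, 3, seed=2, mode="single-split")
        assert len(result.fold_reports) == 1
        # last fold held out; round-robin dealing makes it the smallest
        total = result.fold_reports[0].confusion.total
        assert abs(total - len(small_dataset) // 3) <= small_dataset.n_classes

    def test_equal_class_sizes_give_equal_folds(self):
        """99 windows in 3 balanced classes split 33/33/33."""
        ds = generate(default_spec(n_classes=3, n_per_class=33, samples=16, seed=5))
        result = kfold_cv(ds, 3, seed=5)
        assert [r.confusion.total for r in result.fold_reports] == [33, 33, 33]

    def test_no_leakage_from_test_fold(self, small_dataset):
        """Corrupting the labels of one fold's windows must not change the
        LDA projection fitted when that fold is held out."""
        from epshar.evaluation import _stratified_folds
        from epshar.eps import eps_feature_matrix
        from epshar.lda import fit_lda

        rng = np.random.default_rng(2)
        folds = _stratified_folds(small_dataset.labels, 3, rng)
        train_idx = sorted(np.concatenate([folds[1], folds[2]]).tolist())
        train = small_dataset.subset(train_idx)
        X, y = eps_feature_matrix(train)
        reference = fit_lda(X, y).projection
        corrupted = small_dataset.subset(range(len(small_dataset)))
        for i in folds[0]:
            corrupted.windows[i] = SignalWindow(
                values=corrupted.windows[i].values,
                sample_rate=50.0,
                label=(corrupted.windows[i].label + 1) % 3,
            )
        X2, y2 = eps_feature_matrix(corrupted.subset(train_idx))
        np.testing.assert_allclose(fit_lda(X2, y2).projection, reference, atol=1e-12)

    def test_class_smaller_than_k_rejected(self, small_dataset):
        with pytest.raises(ValueError, match=">= k"):
            kfold_cv(small_dataset, 21)


@pytest.fixture(scope="module")
def split():
    ds = generate(default_spec(n_classes=4, n_per_class=40, samples=64, seed=3))
    return split_train_test(ds, 0.5, seed=3)


class TestFeatureSweep:

    def test_default_counts_table_shape(self, split):
        tr, te = split
        result = feature_sweep(tr, te, seed=3)
        assert [r["n_features"] for r in result.rows] == list(DEFAULT_SWEEP_COUNTS)
        for r in result.rows:
            for m in ("accuracy", "precision", "recall", "f1"):
                assert 0.0 <= r[m] <= 100.0

    def test_single_all_row(self, split):
        tr, te = split
        result = feature_sweep(tr, te, counts=["all"], seed=3)
        assert len(result.rows) == 1

    def test_few_features_beat_all_with_nuisance_dimensions(self, split):
        tr, te = split
        result = feature_sweep(tr, te, counts=[5, "all"], seed=3)
        assert result.rows[0]["accuracy"] >= result.rows[1]["accuracy"]

    def test_invalid_counts(self, split):
        tr, te = split
        with pytest.raises(ValueError, match="non-empty"):
            feature_sweep(tr, te, counts=[])
        with pytest.raises(ValueError, match="increasing"):
            feature_sweep(tr, te, counts=[10, 5])
        with pytest.raises(ValueError, match="last"):
            feature_sweep(tr, te, counts=["all", 5])
        with pytest.raises(ValueError, match="n_features"):
            feature_sweep(tr, te, counts=[10**6])

    def test_csv_formatting(self, split, tmp_path):
        tr, te = split
        result = feature_sweep(tr, te, counts=[5, "all"], seed=3)
        p = tmp_path / "sweep.csv"
        result.to_csv(p, comment="seed=3")
        lines = p.read_text().splitlines()
        assert lines[0].startswith("#")
        assert lines[1] == "n_features,accuracy,precision,recall,f1"
        assert lines[-1].startswith("all,")


def test_pipeline_accuracy_on_small_synthetic(small_dataset):
    tr, te = split_train_test(small_dataset, 0.5, seed=7)
    fitted = fit_pipeline(tr, PipelineConfig(n_features=2), seed=7)
    from epshar import evaluate_pipeline

    rep = evaluate_pipeline(fitted, te)
    assert rep.accuracy >= 0.9
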