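import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from neoseg.classify import (
    ClassWeights,
    KnnModel,
    class_weights,
    corrected_posteriors,
    knn_posteriors,
    neighbor_class_counts,
    segment_subject,
    train_model,
)
from neoseg.features import FEATURE_COLUMNS
from neoseg.imaging import TissueLabel, majority_label
from neoseg.preprocess import ScalingParams
from neoseg.register import AffineTransform


def _model(X, y, k, codes=None):
    cols = FEATURE_COLUMNS[: X.shape[1]]
    scaling = ScalingParams(
        mean=pd.Series(np.zeros(X.shape[1]), index=cols),
        std=pd.Series(np.ones(X.shape[1]), index=cols),
    )
    if codes is None:
        codes = np.unique(y)
    return KnnModel(features=X, labels=y, k=k, scaling=scaling, class_codes=np.asarray(codes))


def oracle_posteriors(X_train, y_train, k, X_query, codes):
    """Independent oracle: full distance matrix, stable (distance, index)
    sort, count labels of the first k rows."""
    out = np.zeros((len(X_query), len(codes)))
    idx = np.arange(len(X_train))
    for r, q in enumerate(X_query):
        d2 = ((X_train - q) ** 2).sum(axis=1)
        order = np.lexsort((idx, d2))[:k]
        for lab in y_train[order]:
            out[r, list(codes).index(lab)] += 1
    return out / k


class TestKnnPosteriors:
    @pytest.mark.parametrize("trial", range(5))
    def test_matches_brute_force_oracle_exactly(self, trial):
        rng = np.random.default_rng(100 + trial)
        n_train = rng.integers(60, 500)
        n_query = rng.integers(20, 200)
        k = int(rng.integers(1, min(60, n_train)))
        codes = [0, 1, 3, 5, 8]
        X = rng.normal(size=(n_train, 5))
        y = rng.choice(codes, size=n_train).astype(np.int16)
        q = rng.normal(size=(n_query, 5))
        model = _model(X, y, k, codes)
        got = knn_posteriors(model, q)
        want = oracle_posteriors(X, y, k, q, codes)
        np.testing.assert_array_equal(got, want)

    def test_crafted_distance_ties_follow_smallest_index_rule(self):
        # 4 training points all at distance 1 from the query, k=2:
        # the two smallest-index rows must win.
        X = np.array([[1.0, 0], [0, 1.0], [-1.0, 0], [0, -1.0]])
        y = np.array([1, 2, 3, 4], dtype=np.int16)
        model = _model(X, y, k=2, codes=[1, 2, 3, 4])
        post = knn_posteriors(model, np.array([[0.0, 0.0]]))
        np.testing.assert_allclose(post[0], [0.5, 0.5, 0.0, 0.0])
        want = oracle_posteriors(X, y, 2, np.array([[0.0, 0.0]]), [1, 2, 3, 4])
        np.testing.assert_array_equal(post, want)

    def test_single_class_training_gives_certainty(self, rng):
        X = rng.normal(size=(30, 5))
        y = np.full(30, TissueLabel.UWM, dtype=np.int16)
        model = _model(X, y, k=10, codes=TissueLabel.codes())
        post = knn_posteriors(model, rng.normal(size=(5, 5)))
        assert (post[:, TissueLabel.UWM] == 1.0).all()

    def test_k_exact_duplicates_dominate(self, rng):
        q = np.array([[0.5, -0.5, 1.0, 0.0, 2.0]])
        X = np.vstack([np.repeat(q, 5, axis=0), rng.normal(loc=10, size=(20, 5))])
        y = np.array([TissueLabel.CSF] * 5 + [TissueLabel.UWM] * 20, dtype=np.int16)
        model = _model(X, y, k=5, codes=TissueLabel.codes())
        post = knn_posteriors(model, q)
        assert post[0, TissueLabel.CSF] == 1.0

    def test_posteriors_are_multiples_of_one_over_k(self, rng):
        X = rng.normal(size=(100, 5))
        y = rng.choice([1, 3, 5], size=100).astype(np.int16)
        model = _model(X, y, k=7, codes=[1, 3, 5])
        post = knn_posteriors(model, rng.normal(size=(40, 5)))
        np.testing.assert_allclose(post * 7, np.round(post * 7), atol=1e-12)
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-12)

    def test_unstandardized_query_detected(self, rng):
        X = rng.normal(size=(50, 5))
        y = np.ones(50, dtype=np.int16)
        model = _model(X, y, k=5, codes=[1])
        with pytest.raises(ValueError, match="unstandardized"):
            knn_posteriors(model, rng.normal(loc=5e3, size=(3, 5)))

    def test_k_larger_than_training_rejected(self, rng):
        with pytest.raises(ValueError, match="k="):
            _model(rng.normal(size=(5, 5)), np.ones(5, dtype=np.int16), k=6, codes=[1])


class TestClassWeights:
    def test_equal_counts_give_unit_weights(self):
        w = class_weights([1] * 10 + [2] * 10, exponent=4.0)
        assert w.weights[1] == pytest.approx(1.0)
        assert w.weights[2] == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # Num = {A:100, B:4}, exponent 2: w_A = 25^(-1/2) = 0.2, w_B = 1
        labels = [0] * 100 + [1] * 4
        w = class_weights(labels, exponent=2.0)
        assert w.weights[0] == pytest.approx(0.2)
        assert w.weights[1] == pytest.approx(1.0)

    def test_rarest_class_has_weight_exactly_one(self, rng):
        labels = rng.choice([1, 2, 3], size=200, p=[0.7, 0.2, 0.1])
        w = class_weights(labels, exponent=3.0)
        counts = {c: (labels == c).sum() for c in (1, 2, 3)}
        rarest = min(counts, key=counts.get)
        assert w.weights[rarest] == pytest.approx(1.0)
        assert all(0 < v <= 1 for v in w.weights.values())

    def test_weights_monotone_in_exponent_toward_one(self):
        labels = [0] * 80 + [1] * 5
        exponents = [2.0, 5.0, 10.0, 30.0, 75.0]
        ws = [class_weights(labels, e).weights[0] for e in exponents]
        assert all(b > a for a, b in zip(ws, ws[1:]))
        assert ws[-1] > 0.95  # approaching 1 at exponent 75

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        counts=st.lists(st.integers(min_value=1, max_value=500), min_size=1, max_size=6),
        e1=st.floats(min_value=1.01, max_value=60.0),
        delta=st.floats(min_value=0.1, max_value=30.0),
    )
    def test_weight_properties_hold_for_arbitrary_multisets(self, counts, e1, delta):
        """All weights lie in (0, 1], the rarest class gets exactly 1, and
        every weight moves toward 1 as the exponent increases."""
        labels = np.repeat(np.arange(len(counts)), counts)
        wa = class_weights(labels, e1)
        wb = class_weights(labels, e1 + delta)
        rare = counts.index(min(counts))
        assert wa.weights[rare] == pytest.approx(1.0)
        for c in wa.weights:
            assert 0.0 < wa.weights[c] <= 1.0 + 1e-12
            assert wb.weights[c] >= wa.weights[c] - 1e-12

    def test_exponent_at_most_one_rejected(self):
        with pytest.raises(ValueError, match="exponent"):
            class_weights([1, 2], exponent=1.0)

    def test_empty_multiset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            class_weights([], exponent=2.0)


class TestCorrectedPosteriors:
    def test_uniform_weights_are_identity(self):
        raw = np.array([0.2, 0.5, 0.3])
        w = ClassWeights(weights={0: 1.0, 1: 1.0, 2: 1.0}, exponent=2.0, neighborhood_size=10)
        np.testing.assert_allclose(corrected_posteriors(raw, w, [0, 1, 2]), raw)

    def test_hand_computed_renormalization_flips_argmax(self):
        raw = np.array([0.6, 0.4])
        w = ClassWeights(weights={0: 0.5, 1: 1.0}, exponent=2.0, neighborhood_size=10)
        out = corrected_posteriors(raw, w, [0, 1])
        np.testing.assert_allclose(out, [0.3 / 0.7, 0.4 / 0.7], atol=1e-12)
        assert out.argmax() == 1  # rare class wins after weighting

    def test_one_hot_unchanged_and_zeros_preserved(self):
        raw = np.array([0.0, 1.0, 0.0])
        w = ClassWeights(weights={0: 0.3, 1: 0.7, 2: 0.9}, exponent=2.0, neighborhood_size=5)
        out = corrected_posteriors(raw, w, [0, 1, 2])
        np.testing.assert_allclose(out, raw)

    def test_all_zero_products_returns_raw_with_warning(self):
        raw = np.array([1.0, 0.0])
        w = ClassWeights(weights={1: 1.0}, exponent=2.0, neighborhood_size=5)  # class 0 absent
        with pytest.warns(UserWarning, match="zero"):
            out = corrected_posteriors(raw, w, [0, 1])
        np.testing.assert_allclose(out, raw)


class TestSegmentSubject:
    def test_clean_subject_self_training_recovers_labels(self, clean_subject):
        from neoseg.features import extract_features

        tab = extract_features(
            clean_subject.t1, clean_subject.t2, clean_subject.mask,
            AffineTransform.identity(), labels=clean_subject.labels,
        )
        model = train_model(tab, k=5)
        probmaps = segment_subject(
            model, clean_subject.t1, clean_subject.t2, clean_subject.mask,
            AffineTransform.identity(),
        )
        probmaps.validate()
        pred = majority_label(probmaps)
        agree = (pred.data[clean_subject.mask] == clean_subject.labels.data[clean_subject.mask]).mean()
        assert agree > 0.999

    def test_empty_mask_gives_all_background(self, clean_subject, rng):
        X = rng.normal(size=(30, 5))
        y = np.full(30, TissueLabel.UWM, dtype=np.int16)
        model = _model(X, y, k=5, codes=TissueLabel.codes())
        probmaps = segment_subject(
            model, clean_subject.t1, clean_subject.t2,
            np.zeros(clean_subject.mask.shape, bool), AffineTransform.identity(),
        )
        assert probmaps.probs.max() == 0
        assert (majority_label(probmaps).data == TissueLabel.BG).all()

    def test_atlas_space_classification_close_to_native(self, clean_subject):
        from neoseg.features import extract_features

        tab = extract_features(
            clean_subject.t1, clean_subject.t2, clean_subject.mask,
            AffineTransform.identity(), labels=clean_subject.labels,
        )
        model = train_model(tab, k=5)
        native = segment_subject(
            model, clean_subject.t1, clean_subject.t2, clean_subject.mask,
            AffineTransform.identity(),
        )
        atlas = segment_subject(
            model, clean_subject.t1, clean_subject.t2, clean_subject.mask,
            AffineTransform.identity(), classify_space="atlas",
            atlas_geometry=clean_subject.t2,
        )
        a = majority_label(native).data[clean_subject.mask]
        b = majority_label(atlas).data[clean_subject.mask]
        assert (a == b).mean() > 0.98  # differ only by interpolation at boundaries


def test_model_save_load_roundtrip(tmp_path, rng):
    X = rng.normal(size=(40, 5))
    y = rng.choice([0, 3, 5], size=40).astype(np.int16)
    model = _model(X, y, k=7, codes=TissueLabel.codes())
    model.save(tmp_path)
    back = KnnModel.load(tmp_path)
    np.testing.assert_array_equal(back.features, model.features)
    np.testing.assert_array_equal(back.labels, model.labels)
    assert back.k == model.k
    q = rng.normal(size=(10, 5))
    np.testing.assert_array_equal(knn_posteriors(back, q), knn_posteriors(model, q))
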