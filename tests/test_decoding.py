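"""Target schemes, stratified splits, the SVM protocol, and its null."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegwm.decoding import (
    GROUPINGS,
    DecodingError,
    confusion_grouping_check,
    fit_eval_svm,
    make_targets,
    permutation_chance,
    repeated_accuracy,
    split_80_10_10,
)


def _design_meta(n_participants=18):
    rows = [
        {"participant": f"P{p:02d}", "modality": m, "segment": s}
        for p in range(1, n_participants + 1)
        for m in ("visual", "audiovisual")
        for s in range(1, 7)
    ]
    return pd.DataFrame(rows)


class TestTargets:
    def test_four_class_numbering(self):
        meta = pd.DataFrame(
            {
                "participant": ["P01"] * 4,
                "modality": ["visual", "visual", "audiovisual", "audiovisual"],
                "segment": [2, 5, 1, 6],
            }
        )
        assert make_targets(meta, "four_class").tolist() == [1, 2, 3, 4]

    def test_binary_schemes(self):
        meta = pd.DataFrame(
            {"participant": ["P01"] * 2, "modality": ["audiovisual"] * 2,
             "segment": [5, 2]}
        )
        assert make_targets(meta, "load").tolist() == ["high", "low"]
        assert make_targets(meta, "modality").tolist() == ["audiovisual"] * 2

    def test_full_design_is_balanced(self):
        y = make_targets(_design_meta(), "four_class")
        assert len(y) == 216
        _, counts = np.unique(y, return_counts=True)
        assert counts.tolist() == [54, 54, 54, 54]

    def test_bad_segment_and_scheme_rejected(self):
        meta = pd.DataFrame(
            {"participant": ["P01"], "modality": ["visual"], "segment": [7]}
        )
        with pytest.raises(DecodingError):
            make_targets(meta, "load")
        with pytest.raises(DecodingError):
            make_targets(_design_meta(), "not_a_scheme")


class TestSplit:
    def test_sizes_on_full_design(self):
        y = make_targets(_design_meta(), "four_class")
        train, cv, test = split_80_10_10(y, seed=0)
        assert (len(train), len(cv), len(test)) == (172, 22, 22)

    def test_disjoint_exhaustive_stratified(self):
        y = make_targets(_design_meta(), "four_class")
        train, cv, test = split_80_10_10(y, seed=3)
        all_idx = np.concatenate([train, cv, test])
        assert sorted(all_idx) == list(range(216))
        for fold in (cv, test):
            _, counts = np.unique(y[fold], return_counts=True)
            assert counts.max() - counts.min() <= 1

    def test_deterministic_given_seed(self):
        y = make_targets(_design_meta(), "four_class")
        a = split_80_10_10(y, seed=11)
        b = split_80_10_10(y, seed=11)
        for fa, fb in zip(a, b):
            assert np.array_equal(fa, fb)
        assert not np.array_equal(split_80_10_10(y, seed=12)[2], a[2])

    def test_small_or_degenerate_inputs_rejected(self):
        with pytest.raises(DecodingError):
            split_80_10_10(np.array([1, 2] * 3), seed=0)
        with pytest.raises(DecodingError):
            split_80_10_10(np.array([1] * 20 + [2] * 2), seed=0)


class TestSvm:
    def test_separable_classes_reach_perfect_accuracy(self, rng):
        X = np.vstack([rng.normal(c * 20, 0.5, (20, 6)) for c in range(4)])
        y = np.repeat([1, 2, 3, 4], 20)
        idx = rng.permutation(80)
        res = fit_eval_svm(
            X[idx[:60]], y[idx[:60]], X[idx[60:70]], y[idx[60:70]],
            X[idx[70:]], y[idx[70:]],
        )
        assert res.test_accuracy == 1.0
        assert res.cv_accuracy == 1.0

    def test_confusion_rows_sum_to_class_counts(self, rng):
        X = rng.standard_normal((60, 5))
        y = np.repeat([1, 2, 3], 20)
        res = fit_eval_svm(X[:40], y[:40], X[40:50], y[40:50], X[50:], y[50:])
        counts = [np.sum(y[50:] == l) for l in res.labels]
        assert res.confusion.sum(axis=1).tolist() == counts

    def test_single_class_train_rejected(self, rng):
        X = rng.standard_normal((10, 3))
        y = np.ones(10)
        with pytest.raises(DecodingError):
            fit_eval_svm(X, y, X, y, X, y)


@pytest.fixture(scope="module")
def features_targets():
    rng = np.random.default_rng(5)
    meta = _design_meta(6)  # 72 rows
    y = make_targets(meta, "four_class")
    X = rng.standard_normal((72, 8)) + 3.0 * y[:, None]
    return X, y


class TestRepeatedProtocol:
    def test_distribution_shape_and_determinism(self, features_targets):
        X, y = features_targets
        a = repeated_accuracy(X, y, reps=6, seed=2)
        b = repeated_accuracy(X, y, reps=6, seed=2)
        assert len(a.accuracies) == 6
        assert np.all((a.accuracies >= 0) & (a.accuracies <= 1))
        assert np.array_equal(a.accuracies, b.accuracies)
        assert a.confusions.shape == (6, 4, 4)

    def test_informative_features_beat_matched_null(self, features_targets):
        X, y = features_targets
        actual = repeated_accuracy(X, y, reps=10, seed=7)
        null = permutation_chance(X, y, reps=10, seed=7)
        assert actual.mean > null.mean + 0.3

    def test_null_concentrates_at_one_over_k(self):
        rng = np.random.default_rng(8)
        meta = _design_meta(6)
        X = rng.standard_normal((72, 8))  # no signal at all
        for scheme, expected in (("four_class", 0.25), ("modality", 0.5)):
            y = make_targets(meta, scheme)
            null = permutation_chance(X, y, reps=30, seed=1)
            se = null.sd / np.sqrt(30)
            assert abs(null.mean - expected) < max(3 * se, 0.08)


class TestGrouping:
    def test_perfect_and_swapped_confusions(self):
        perfect = np.eye(4) * 10
        assert confusion_grouping_check(perfect, GROUPINGS["modality"]) == 1.0
        swapped = np.zeros((4, 4))
        swapped[0, 1] = swapped[1, 0] = swapped[2, 3] = swapped[3, 2] = 10
        assert confusion_grouping_check(swapped, GROUPINGS["modality"]) == 1.0
        assert confusion_grouping_check(swapped, GROUPINGS["load"]) == 0.0

    def test_uniform_confusion_gives_half(self):
        uniform = np.full((4, 4), 5.0)
        assert confusion_grouping_check(uniform, GROUPINGS["load"]) == 0.5

    def test_invalid_grouping_rejected(self):
        with pytest.raises(DecodingError):
            confusion_grouping_check(np.eye(4), {1: "a", 2: "b"})

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.integers(min_value=0, max_value=20), min_size=16, max_size=16
        ).filter(lambda v: sum(v) > 0)
    )
    def test_collapsing_never_decreases_accuracy(self, cells):
        cm = np.array(cells, dtype=float).reshape(4, 4)
        four = np.trace(cm) / cm.sum()
        for grouping in GROUPINGS.values():
            assert confusion_grouping_check(cm, grouping) >= four - 1e-12
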