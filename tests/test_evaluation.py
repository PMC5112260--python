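"""Split protocols, downsampling ensembles, combination rule, metrics."""

import numpy as np
import pytest
from sklearn.base import BaseEstimator, ClassifierMixin

from conftest import exact_signed_rank_p
from pilvq.evaluation import (
    DownsampledEnsembleClassifier,
    combine_two_classifiers,
    compare_models,
    confusion_rates,
    macro_mae,
    make_splits,
    relative_median_reduction,
)
from pilvq.gmlvq import GMLVQClassifier


def imaging_cohort_labels():
    return np.array(["patient"] * 9 + ["control"] * 25)


def full_cohort_labels():
    y = np.array(["patient"] * 13 + ["control"] * 47)
    img = np.zeros(60, dtype=bool)
    img[:9] = True       # 9 imaging patients
    img[13:38] = True    # 25 imaging controls
    return y, img


class TestSplits:
    def test_imaging_protocol_test_arithmetic(self):
        plan = make_splits(imaging_cohort_labels(), protocol="M-PD",
                           n_splits=10, seed=0)
        y = imaging_cohort_labels()
        for tr, te in plan.splits:
            assert np.sum(y[tr] == "patient") == 6
            assert np.sum(y[tr] == "control") == 17
            assert np.sum(y[te] == "patient") == 3
            assert np.sum(y[te] == "control") == 8
            assert np.intersect1d(tr, te).size == 0

    def test_full_protocol_sizes(self):
        y, img = full_cohort_labels()
        plan = make_splits(y, protocol="M-CD", has_imaging=img,
                           n_splits=10, seed=0)
        for tr, te in plan.splits:
            assert tr.size == 42 and te.size == 18

    def test_imaging_balance_preserved(self):
        y, img = full_cohort_labels()
        plan = make_splits(y, protocol="M-CD", has_imaging=img,
                           n_splits=10, seed=1)
        for tr, _ in plan.splits:
            pat_tr = tr[y[tr] == "patient"]
            # 9 of 13 patients, 9 with imaging: proportional draw = 6 imaged
            assert np.sum(img[pat_tr]) == 6

    def test_determinism(self):
        y = imaging_cohort_labels()
        p1 = make_splits(y, protocol="M-PD", n_splits=5, seed=3)
        p2 = make_splits(y, protocol="M-PD", n_splits=5, seed=3)
        for (a, b), (c, d) in zip(p1.splits, p2.splits):
            assert np.array_equal(a, c) and np.array_equal(b, d)

    def test_insufficient_cohort_rejected(self):
        y = np.array(["patient"] * 5 + ["control"] * 25)
        with pytest.raises(ValueError, match="insufficient"):
            make_splits(y, protocol="M-PD")


class _FixedLabel(BaseEstimator, ClassifierMixin):
    """Stub member predicting a constant label (for vote mechanics)."""

    def __init__(self, label="patient", conf=0.1):
        self.label = label
        self.conf = conf

    def fit(self, X, y):
        self.classes_ = np.unique(y)
        self.lambda_ = np.eye(X.shape[1]) / X.shape[1]
        return self

    def predict(self, X):
        return np.full(len(np.atleast_2d(X)), self.label, dtype=object)

    def class_winner_distance(self, X, label, lam_override=None):
        return np.full(len(np.atleast_2d(X)), self.conf)


def stub_ensemble(votes, confs=None):
    ens = DownsampledEnsembleClassifier()
    ens.classes_ = np.array(["control", "patient"], dtype=object)
    ens.minority_label_ = "patient"
    ens.members_ = [
        _FixedLabel(v, c).fit(np.zeros((2, 2)), np.array(["control", "patient"]))
        for v, c in zip(votes, confs or [0.1] * len(votes))
    ]
    return ens


class TestEnsemble:
    def test_members_see_balanced_subsets(self, rng):
        X = rng.normal(size=(23, 3))
        y = np.array(["patient"] * 6 + ["control"] * 17)
        X[np.array(y) == "patient"] += 3
        ens = DownsampledEnsembleClassifier(
            GMLVQClassifier(epochs=10), n_downsamples=8, random_state=0
        ).fit(X, y)
        for idx in ens.member_indices_:
            assert idx.size == 12
            assert np.sum(np.asarray(y)[idx] == "patient") == 6

    def test_single_downsample_is_one_classifier(self, rng):
        X = rng.normal(size=(10, 2))
        y = np.array(["patient"] * 4 + ["control"] * 6)
        ens = DownsampledEnsembleClassifier(
            GMLVQClassifier(epochs=10), n_downsamples=1, random_state=0
        ).fit(X, y)
        assert len(ens.members_) == 1
        assert (ens.predict(X) == ens.members_[0].predict(X)).all()

    def test_equal_class_sizes_unanimous_members(self, rng):
        X = np.vstack([rng.normal(0, 0.3, (5, 2)), rng.normal(5, 0.3, (5, 2))])
        y = np.array(["patient"] * 5 + ["control"] * 5)
        ens = DownsampledEnsembleClassifier(
            GMLVQClassifier(epochs=30), n_downsamples=4, random_state=0
        ).fit(X, y)
        for idx in ens.member_indices_:
            assert np.array_equal(idx, np.arange(10))
        votes = np.array([m.predict(X) for m in ens.members_])
        assert (votes == votes[0]).all()

    def test_majority_vote(self):
        ens = stub_ensemble(["patient"] * 60 + ["control"] * 40)
        assert ens.predict(np.zeros((1, 2)))[0] == "patient"

    def test_tie_goes_to_patient(self):
        ens = stub_ensemble(["patient"] * 50 + ["control"] * 50)
        assert ens.predict(np.zeros((1, 2)))[0] == "patient"

    def test_unanimous(self):
        ens = stub_ensemble(["control"] * 10)
        assert ens.predict(np.zeros((1, 2)))[0] == "control"


class TestCombination:
    def test_agreement_passes_through(self):
        c1 = stub_ensemble(["patient"] * 3)
        c2 = stub_ensemble(["patient"] * 3)
        assert combine_two_classifiers(c1, c2, np.zeros((1, 2)))[0] == "patient"

    def test_disagreement_resolved_by_confidence(self):
        c1 = stub_ensemble(["patient"] * 3, confs=[0.2] * 3)
        c2 = stub_ensemble(["control"] * 3, confs=[0.5] * 3)
        assert combine_two_classifiers(c1, c2, np.zeros((1, 2)))[0] == "patient"
        c3 = stub_ensemble(["control"] * 3, confs=[0.05] * 3)
        assert combine_two_classifiers(c1, c3, np.zeros((1, 2)))[0] == "control"

    def test_exact_confidence_tie_keeps_first(self):
        c1 = stub_ensemble(["control"] * 3, confs=[0.3] * 3)
        c2 = stub_ensemble(["patient"] * 3, confs=[0.3] * 3)
        assert combine_two_classifiers(c1, c2, np.zeros((1, 2)))[0] == "control"


class TestMetrics:
    def test_confusion_rates_hand(self):
        r = confusion_rates(tp=3, tn=5, fp=0, fn=1)
        assert r["TPR"] == pytest.approx(0.75)
        assert r["FPR"] == 0.0 and r["TNR"] == 1.0
        assert r["TPR"] + r["FNR"] == 1.0
        assert r["TNR"] + r["FPR"] == 1.0

    def test_confusion_empty_class_rejected(self):
        with pytest.raises(ValueError):
            confusion_rates(tp=0, tn=3, fp=1, fn=0)

    def test_macro_mae_hand(self):
        y = np.array(["a"] * 4 + ["b"] * 2)
        p = np.array(["a", "a", "b", "b", "b", "a"])
        assert macro_mae(y, p) == pytest.approx(0.5)

    def test_macro_mae_extremes(self):
        y = np.array([0, 0, 1, 1])
        assert macro_mae(y, y) == 0.0
        assert macro_mae(y, 1 - y) == 1.0

    def test_macro_mae_duplication_invariance(self, rng):
        y = np.array([0] * 6 + [1] * 3)
        p = rng.integers(0, 2, 9)
        dup = np.concatenate([y, y[y == 0]])
        pdup = np.concatenate([p, p[y == 0]])
        assert macro_mae(dup, pdup) == pytest.approx(macro_mae(y, p))

    def test_relative_reduction_printed_values(self):
        assert relative_median_reduction(0.3942, 0.2381) == pytest.approx(
            39.6, abs=0.05
        )
        assert relative_median_reduction(0.3942, 0.3413) == pytest.approx(
            13.4, abs=0.05
        )
        assert relative_median_reduction(0.5, 0.5) == 0.0

    def test_relative_reduction_bad_baseline(self):
        with pytest.raises(ValueError):
            relative_median_reduction(0.0, 0.1)


class TestModelComparison:
    def test_identical_samples_p_one(self):
        a = np.linspace(0.1, 0.5, 50)
        assert compare_models(a, a) == 1.0

    def test_large_shift_significant(self, rng):
        a = rng.normal(0.4, 0.05, 50)
        assert compare_models(a, a - 0.3) < 0.01

    def test_symmetry(self, rng):
        a = rng.normal(0.4, 0.05, 50)
        b = a + rng.normal(0, 0.02, 50)
        assert compare_models(a, b) == pytest.approx(compare_models(b, a))

    def test_matches_exact_signed_rank_oracle(self, rng):
        a = rng.normal(0.0, 1.0, 10)
        b = a + rng.normal(0.5, 0.7, 10)
        d = a - b
        p_two = compare_models(a, b)
        p_gr = exact_signed_rank_p(d, "greater")
        p_ls = exact_signed_rank_p(d, "less")
        assert p_two == pytest.approx(min(1.0, 2 * min(p_gr, p_ls)), abs=1e-6)


class TestLeakage:
    def test_member_training_confined_to_split_train_side(self):
        y, img = full_cohort_labels()
        plan = make_splits(y, protocol="M-CD", has_imaging=img,
                           n_splits=4, seed=0)
        rng = np.random.default_rng(0)
        X = rng.normal(size=(60, 4))
        for tr, te in plan.splits:
            ens = DownsampledEnsembleClassifier(
                GMLVQClassifier(epochs=5), n_downsamples=3, random_state=1
            ).fit(X[tr], y[tr])
            for idx in ens.member_indices_:
                # member rows index into the training side only
                assert idx.max() < tr.size
                global_rows = tr[idx]
                assert np.intersect1d(global_rows, te).size == 0
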