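"""Split protocols, imbalance ensembles, classifier combination, metrics.

The evaluation design follows a small-cohort, imbalanced two-class study:

* repeated stratified train/test splits with fixed per-class training
  counts (and, for the cognitive-data protocol, preserved balance of
  subjects with and without imaging),
* per split, an ensemble of ``N_d`` classifiers each trained on the full
  minority-class training portion plus an equally sized random
  downsample of the majority class, combined by majority vote,
* the macroaveraged mean absolute error (MMAE) as the imbalance-robust
  headline metric — for binary labels, the mean of the two per-class
  error rates (1 - balanced accuracy),
* paired Wilcoxon signed-rank comparison of MMAE distributions of two
  models over identical splits.

Two ensembles trained with different privileged-information families can
be merged per test point: agreement wins outright, disagreement is
resolved toward the ensemble whose voting members are, on average, closer
to their winning prototype under eigenvalue-normalized metric tensors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import wilcoxon
from sklearn.base import BaseEstimator, ClassifierMixin, clone

from .gmlvq import normalize_metric_tensor

__all__ = [
    "SplitPlan",
    "make_splits",
    "DownsampledEnsembleClassifier",
    "train_balanced_ensemble",
    "ensemble_predict",
    "combine_two_classifiers",
    "confusion_rates",
    "macro_mae",
    "relative_median_reduction",
    "compare_models",
    "summarize_mmae",
    "PROTOCOL_TRAIN_COUNTS",
]

# (patients, controls) in the training side, per protocol
PROTOCOL_TRAIN_COUNTS = {"M-PD": (6, 17), "M-CD": (9, 33)}


@dataclass
class SplitPlan:
    protocol: str
    seed: int
    splits: list[tuple[np.ndarray, np.ndarray]]  # (train_idx, test_idx)

    @property
    def n_splits(self) -> int:
        return len(self.splits)


def _largest_remainder(counts: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation of ``total`` proportional to ``counts``."""
    if counts.sum() == 0:
        return np.zeros_like(counts)
    quota = counts * total / counts.sum()
    alloc = np.floor(quota).astype(int)
    rem = total - alloc.sum()
    order = np.argsort(-(quota - alloc))
    for k in order[:rem]:
        alloc[k] += 1
    return np.minimum(alloc, counts)


def make_splits(
    labels,
    protocol: str = "M-CD",
    has_imaging=None,
    n_splits: int = 50,
    seed: int = 0,
    train_counts: tuple[int, int] | None = None,
    patient_label: str = "patient",
) -> SplitPlan:
    """Repeated stratified splits with fixed per-class training counts.

    ``protocol`` selects the default counts: "M-PD" trains on 6 patients
    + 17 controls (imaging cohort), "M-CD" on 9 + 33 (full cohort).  When
    ``has_imaging`` is given (M-CD case), training subjects within each
    class are drawn proportionally from the with- and without-imaging
    subgroups so both sides of every split keep the modality balance.
    """
    y = np.asarray(labels)
    if protocol not in PROTOCOL_TRAIN_COUNTS and train_counts is None:
        raise ValueError(f"unknown protocol {protocol!r} and no train_counts given")
    n_p_train, n_c_train = train_counts or PROTOCOL_TRAIN_COUNTS[protocol]
    is_patient = y == patient_label
    pat_idx = np.flatnonzero(is_patient)
    ctl_idx = np.flatnonzero(~is_patient)
    if pat_idx.size <= n_p_train or ctl_idx.size <= n_c_train:
        raise ValueError(
            f"insufficient subjects for protocol {protocol}: have "
            f"{pat_idx.size} patients / {ctl_idx.size} controls, need more than "
            f"{n_p_train} / {n_c_train}"
        )
    img = None if has_imaging is None else np.asarray(has_imaging, dtype=bool)
    rng = np.random.default_rng(seed)
    splits = []
    for _ in range(n_splits):
        train = []
        for idx, n_train in ((pat_idx, n_p_train), (ctl_idx, n_c_train)):
            if img is None:
                train.extend(rng.choice(idx, size=n_train, replace=False))
            else:
                cells = [idx[img[idx]], idx[~img[idx]]]
                sizes = np.array([c.size for c in cells])
                alloc = _largest_remainder(sizes, n_train)
                # top up if a cell is exhausted
                short = n_train - alloc.sum()
                for k in range(len(cells)):
                    add = min(short, sizes[k] - alloc[k])
                    alloc[k] += add
                    short -= add
                for cell, take in zip(cells, alloc):
                    if take:
                        train.extend(rng.choice(cell, size=int(take), replace=False))
        train = np.sort(np.array(train, dtype=int))
        test = np.setdiff1d(np.arange(y.size), train)
        splits.append((train, test))
    return SplitPlan(protocol=protocol, seed=seed, splits=splits)


class DownsampledEnsembleClassifier(BaseEstimator, ClassifierMixin):
    """Majority-vote ensemble over repeated majority-class downsampling.

    Each of ``n_downsamples`` members is a clone of ``base_estimator``
    trained on every minority-class training point plus an equal-size
    random draw (without replacement) of majority-class points.  Voting
    ties go to the minority (patient) class.

    Fitted attributes: ``members_``, ``member_indices_`` (rows of X used
    by each member), ``member_train_errors_`` (balanced training error of
    each member on its own subset), ``minority_label_``.
    """

    def __init__(self, base_estimator=None, n_downsamples: int = 100,
                 random_state: int | None = None):
        self.base_estimator = base_estimator
        self.n_downsamples = n_downsamples
        self.random_state = random_state

    def fit(self, X, y, X_privileged=None, privileged_rows=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes, counts = np.unique(y, return_counts=True)
        if classes.size != 2:
            raise ValueError("ensemble expects exactly 2 classes")
        if self.n_downsamples < 1:
            raise ValueError("n_downsamples must be >= 1")
        order = np.argsort(counts, kind="stable")
        minority, majority = classes[order[0]], classes[order[1]]
        self.minority_label_ = minority
        self.majority_label_ = majority
        min_idx = np.flatnonzero(y == minority)
        maj_idx = np.flatnonzero(y == majority)

        priv_map = {}
        if X_privileged is not None:
            Xp = np.asarray(X_privileged, dtype=float)
            rows = (np.arange(X.shape[0]) if privileged_rows is None
                    else np.asarray(privileged_rows, dtype=int))
            priv_map = {int(r): k for k, r in enumerate(rows)}

        ss = np.random.SeedSequence(self.random_state)
        child_seeds = ss.generate_state(self.n_downsamples)
        rng = np.random.default_rng(ss.spawn(1)[0])
        self.members_ = []
        self.member_indices_ = []
        self.member_train_errors_ = []
        template = self.base_estimator
        if template is None:
            from .gmlvq import GMLVQClassifier
            template = GMLVQClassifier()
        for k in range(self.n_downsamples):
            draw = rng.choice(maj_idx, size=min_idx.size, replace=False)
            idx = np.sort(np.concatenate([min_idx, draw]))
            member = clone(template)
            if hasattr(member, "random_state"):
                member.set_params(random_state=int(child_seeds[k] % (2**31)))
            fit_kwargs = {}
            if priv_map:
                local = [(pos, priv_map[int(r)]) for pos, r in enumerate(idx)
                         if int(r) in priv_map]
                if local:
                    pos_arr = np.array([p for p, _ in local], dtype=int)
                    src_arr = np.array([s for _, s in local], dtype=int)
                    fit_kwargs = dict(X_privileged=Xp[src_arr],
                                      privileged_rows=pos_arr)
            member.fit(X[idx], y[idx], **fit_kwargs)
            self.members_.append(member)
            self.member_indices_.append(idx)
            self.member_train_errors_.append(
                macro_mae(y[idx], member.predict(X[idx]))
            )
        self.classes_ = classes
        return self

    def _member_votes(self, X):
        return np.array([m.predict(X) for m in self.members_])

    def predict(self, X):
        votes = self._member_votes(X)
        n = votes.shape[1]
        out = np.empty(n, dtype=self.classes_.dtype)
        for i in range(n):
            vals, cnts = np.unique(votes[:, i], return_counts=True)
            top = cnts.max()
            winners = vals[cnts == top]
            if winners.size > 1:
                out[i] = self.minority_label_  # tie policy: favour patients
            else:
                out[i] = winners[0]
        return out

    def vote_and_confidence(self, X):
        """Majority label plus mean normalized winner distance of its voters.

        The confidence distance of a sample is averaged over the members
        that voted for the winning label, each measured to its closest
        prototype of that label under the member's eigenvalue-normalized
        metric tensor (so distances are comparable across classifiers).
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        votes = self._member_votes(X)
        labels = self.predict(X)
        norm_lams = [normalize_metric_tensor(m.lambda_) for m in self.members_]
        dists = np.empty((len(self.members_), X.shape[0]))
        for k, m in enumerate(self.members_):
            per_class = {c: m.class_winner_distance(X, c, lam_override=norm_lams[k])
                         for c in self.classes_}
            for i in range(X.shape[0]):
                dists[k, i] = per_class[votes[k, i]][i]
        conf = np.empty(X.shape[0])
        for i in range(X.shape[0]):
            mask = votes[:, i] == labels[i]
            conf[i] = dists[mask, i].mean() if mask.any() else np.inf
        return labels, conf


def train_balanced_ensemble(X, y, base_estimator, n_downsamples: int = 100,
                            seed: int | None = None, **fit_kwargs
                            ) -> DownsampledEnsembleClassifier:
    ens = DownsampledEnsembleClassifier(
        base_estimator=base_estimator, n_downsamples=n_downsamples,
        random_state=seed,
    )
    return ens.fit(X, y, **fit_kwargs)


def ensemble_predict(ens: DownsampledEnsembleClassifier, X):
    return ens.predict(np.atleast_2d(X))


def combine_two_classifiers(c1, c2, X):
    """Merge two ensemble predictions per test point.

    Agreement passes through; on disagreement the label whose claiming
    ensemble reports the smaller mean normalized winner distance wins;
    exact ties go to the first classifier's label.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    l1, d1 = c1.vote_and_confidence(X)
    l2, d2 = c2.vote_and_confidence(X)
    out = l1.copy()
    for i in range(X.shape[0]):
        if l1[i] == l2[i]:
            out[i] = l1[i]
        else:
            out[i] = l1[i] if d1[i] <= d2[i] else l2[i]
    return out


def confusion_rates(tp: int, tn: int, fp: int, fn: int) -> dict:
    """TPR/TNR/FPR/FNR from confusion counts; complements are exact."""
    for name, v in (("tp", tp), ("tn", tn), ("fp", fp), ("fn", fn)):
        if v < 0:
            raise ValueError(f"negative count {name}={v}")
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("undefined rate: an actual class is empty")
    tpr = tp / (tp + fn)
    tnr = tn / (tn + fp)
    return {"TPR": tpr, "TNR": tnr, "FPR": 1.0 - tnr, "FNR": 1.0 - tpr}


def macro_mae(y_true, y_pred) -> float:
    """Macroaveraged mean absolute error over ordinal class labels.

    Classes are encoded 1..C in sorted label order; the per-class mean
    absolute label error is averaged over classes, making the metric
    invariant to class imbalance.  For binary labels this equals the mean
    of the two per-class error rates (1 - balanced accuracy).
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("label arrays must have equal length")
    classes = np.unique(np.concatenate([y_true, y_pred]))
    code = {c: k + 1 for k, c in enumerate(classes)}
    t = np.array([code[c] for c in y_true])
    p = np.array([code[c] for c in y_pred])
    true_classes = np.unique(t)
    per_class = []
    for c in true_classes:
        mask = t == c
        per_class.append(np.abs(t[mask] - p[mask]).mean())
    return float(np.mean(per_class))


def relative_median_reduction(baseline_median: float, model_median: float) -> float:
    """Percentage reduction of a model's median metric vs. a baseline."""
    if baseline_median <= 0:
        raise ValueError("baseline median must be positive")
    return 100.0 * (baseline_median - model_median) / baseline_median


def compare_models(mmae_a, mmae_b) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value over identical splits."""
    a = np.asarray(mmae_a, dtype=float)
    b = np.asarray(mmae_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    diffs = a - b
    if np.all(diffs == 0):
        return 1.0
    return float(wilcoxon(a, b, alternative="two-sided").pvalue)


def summarize_mmae(values) -> dict:
    """Table-style summary: mean, sd, median, 25/75 percentiles."""
    v = np.asarray(values, dtype=float)
    return {
        "mean": float(v.mean()),
        "std": float(v.std(ddof=1)) if v.size > 1 else 0.0,
        "median": float(np.median(v)),
        "q25": float(np.percentile(v, 25)),
        "q75": float(np.percentile(v, 75)),
    }


@dataclass
class EvaluationReport:
    """Per-split evaluation results of one experiment.

    ``confusions`` holds dicts with keys tp/tn/fp/fn per split;
    ``member_lambdas``/``member_errors`` keep, per split, the metric
    tensors and balanced training errors of all ensemble members (the raw
    material for relevance analysis); ``importance`` optionally maps
    (family, session) to per-split edge-importance matrices.
    """

    model_name: str
    mmae: np.ndarray
    confusions: list[dict]
    member_lambdas: list[list[np.ndarray]] = field(default_factory=list)
    member_errors: list[list[float]] = field(default_factory=list)
    importance: dict = field(default_factory=dict)

    @property
    def summary(self) -> dict:
        return summarize_mmae(self.mmae)

    @property
    def overall_rates(self) -> dict:
        tot = {k: sum(c[k] for c in self.confusions) for k in ("tp", "tn", "fp", "fn")}
        return confusion_rates(tot["tp"], tot["tn"], tot["fp"], tot["fn"])

    def split_frame(self):
        import pandas as pd

        rows = []
        for i, (mmae, conf) in enumerate(zip(self.mmae, self.confusions)):
            rows.append({"split": i, "mmae": mmae, **conf})
        return pd.DataFrame(rows)
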