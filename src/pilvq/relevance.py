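"""Post-hoc interpretation of learned metric tensors and importance matrices.

Many members of a downsampling ensemble are trained on very small data
sets and some fail outright, so interpretation starts with a reliability
filter: a data split is retained only if the error of its ``N_b``-th best
ensemble member is at most ``E_max``; all members of retained splits are
pooled.  On the pooled matrices:

* diagonal relevance histogram — how often each feature's diagonal
  metric element exceeds the 90th percentile of *all* pooled diagonal
  elements (a frequency-of-dominance reading of feature relevance),
* off-diagonal interplay — two one-sided signed-rank tests per feature
  pair for a positive / negative median interplay term,
* between-class correlation screen on raw scores — per-feature one-sided
  rank-sum tests patients vs. controls, combined pairwise into
  positive / negative / insignificant between-class correlation verdicts,
* pre/post edge-importance shift — per-edge one-sided signed-rank tests
  on paired pre- vs. post-session importance values.

No multiple-testing correction is applied by default (``adjust="none"``);
Benjamini-Hochberg is available via ``adjust="bh"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import mannwhitneyu, wilcoxon

__all__ = [
    "RelevanceSelection",
    "select_reliable_members",
    "diagonal_relevance_histogram",
    "offdiagonal_sign_tests",
    "between_class_correlation_screen",
    "edge_importance_shift",
]


@dataclass
class RelevanceSelection:
    n_b: int
    e_max: float
    retained_split_ids: list[int]
    matrices: list[np.ndarray]  # pooled members of retained splits


def _safe_wilcoxon_onesided(x: np.ndarray, alternative: str) -> float:
    x = np.asarray(x, dtype=float)
    if np.all(x == 0):
        return 1.0
    try:
        return float(wilcoxon(x, alternative=alternative).pvalue)
    except ValueError:
        return 1.0


def _bh_adjust(pvals: np.ndarray) -> np.ndarray:
    p = np.asarray(pvals, dtype=float)
    order = np.argsort(p)
    ranked = p[order] * p.size / (np.arange(p.size) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.clip(ranked, 0, 1)
    return out


def select_reliable_members(split_results, n_b: int = 15, e_max: float = 0.25
                            ) -> RelevanceSelection:
    """Keep splits whose N_b-th best member error is within E_max.

    ``split_results`` is a sequence of (matrices, errors) pairs per split,
    where ``matrices`` are the member metric (or importance) matrices and
    ``errors`` the matching per-member errors in [0, 1].
    """
    retained_ids: list[int] = []
    pooled: list[np.ndarray] = []
    for sid, (matrices, errors) in enumerate(split_results):
        errors = np.asarray(errors, dtype=float)
        if n_b > errors.size:
            raise ValueError(
                f"N_b={n_b} exceeds ensemble size {errors.size} in split {sid}"
            )
        if np.any((errors < 0) | (errors > 1)):
            raise ValueError("member errors must lie in [0, 1]")
        nb_best = np.sort(errors)[n_b - 1]
        if nb_best <= e_max:
            retained_ids.append(sid)
            pooled.extend(np.asarray(m, dtype=float) for m in matrices)
    if not retained_ids:
        warnings.warn("no split passed the reliability filter; empty selection")
    return RelevanceSelection(
        n_b=n_b, e_max=e_max, retained_split_ids=retained_ids, matrices=pooled
    )


def diagonal_relevance_histogram(selection: RelevanceSelection) -> np.ndarray:
    """Count, per feature, diagonal elements above the pooled 90th percentile.

    All diagonal elements of all retained matrices form the reference
    pool; only values *strictly* greater than its 90th percentile count.
    """
    if not selection.matrices:
        raise ValueError("empty selection")
    diags = np.array([np.diag(m) for m in selection.matrices])
    pooled = diags.ravel()
    threshold = np.percentile(pooled, 90)
    # values strictly above the percentile count; ties *at* the percentile
    # count only when the percentile sits above the pooled minimum, so a
    # dominant feature saturating the top decile is not discarded while a
    # flat pool counts nothing.
    qualify = diags > threshold
    if threshold > pooled.min():
        qualify |= diags == threshold
    return qualify.sum(axis=0)


def offdiagonal_sign_tests(selection: RelevanceSelection, alpha: float = 0.05,
                           adjust: str = "none"):
    """Per feature pair, one-sided signed-rank tests of median interplay.

    Returns a dict (i, j) -> {"p_positive", "p_negative", "verdict"} with
    verdict in {"positive", "negative", "none"} at level ``alpha``.
    """
    if len(selection.matrices) < 6:
        raise ValueError("need at least 6 pooled matrices for sign tests")
    mats = np.array(selection.matrices)
    m = mats.shape[1]
    pairs = [(i, j) for i in range(m) for j in range(i + 1, m)]
    p_pos = np.array([
        _safe_wilcoxon_onesided(mats[:, i, j], "greater") for i, j in pairs
    ])
    p_neg = np.array([
        _safe_wilcoxon_onesided(mats[:, i, j], "less") for i, j in pairs
    ])
    if adjust == "bh":
        p_pos = _bh_adjust(p_pos)
        p_neg = _bh_adjust(p_neg)
    elif adjust != "none":
        raise ValueError("adjust must be 'none' or 'bh'")
    out = {}
    for k, (i, j) in enumerate(pairs):
        if p_pos[k] < alpha and p_pos[k] <= p_neg[k]:
            verdict = "positive"
        elif p_neg[k] < alpha:
            verdict = "negative"
        else:
            verdict = "none"
        out[(i, j)] = {
            "p_positive": float(p_pos[k]),
            "p_negative": float(p_neg[k]),
            "verdict": verdict,
        }
    return out


def between_class_correlation_screen(scores, labels, alpha: float = 0.05,
                                     patient_label: str = "patient"):
    """Pairwise between-class correlation verdicts from per-feature shifts.

    For each feature, one-sided rank-sum tests decide whether patients
    score significantly higher or lower than controls.  A feature pair is
    "positive" when both features shift significantly in the same
    direction, "negative" for significant opposite shifts, otherwise
    "insignificant".
    """
    X = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    pat = X[y == patient_label]
    ctl = X[y != patient_label]
    if pat.shape[0] < 3 or ctl.shape[0] < 3:
        raise ValueError("need at least 3 subjects per class")
    m = X.shape[1]
    direction = np.zeros(m, dtype=int)
    for f in range(m):
        p_greater = mannwhitneyu(pat[:, f], ctl[:, f], alternative="greater").pvalue
        p_less = mannwhitneyu(pat[:, f], ctl[:, f], alternative="less").pvalue
        if p_greater < alpha:
            direction[f] = 1
        elif p_less < alpha:
            direction[f] = -1
    out = {}
    for i in range(m):
        for j in range(i + 1, m):
            if direction[i] == 0 or direction[j] == 0:
                out[(i, j)] = "insignificant"
            elif direction[i] == direction[j]:
                out[(i, j)] = "positive"
            else:
                out[(i, j)] = "negative"
    return out, direction


def edge_importance_shift(pre_matrices, post_matrices, alpha: float = 0.05):
    """Per-edge pre-to-post shift verdicts from paired importance matrices.

    ``pre_matrices`` and ``post_matrices`` must be paired (same split /
    member, same node set).  For each edge (i, j), one-sided signed-rank
    tests on the paired post - pre differences yield a verdict in
    {"increased", "reduced", "none"}.
    """
    pre = np.array([np.asarray(m, dtype=float) for m in pre_matrices])
    post = np.array([np.asarray(m, dtype=float) for m in post_matrices])
    if pre.shape != post.shape:
        raise ValueError(
            f"mismatched matrix collections: pre {pre.shape} vs post {post.shape}"
        )
    if pre.ndim != 3 or pre.shape[1] != pre.shape[2]:
        raise ValueError("importance matrices must be square and stacked")
    k = pre.shape[1]
    out = {}
    for i in range(k):
        for j in range(i + 1, k):
            diffs = post[:, i, j] - pre[:, i, j]
            p_up = _safe_wilcoxon_onesided(diffs, "greater")
            p_down = _safe_wilcoxon_onesided(diffs, "less")
            if p_up < alpha and p_up <= p_down:
                verdict = "increased"
            elif p_down < alpha:
                verdict = "reduced"
            else:
                verdict = "none"
            out[(i, j)] = {
                "p_increased": float(p_up),
                "p_reduced": float(p_down),
                "verdict": verdict,
            }
    return out
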