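"""Presence/absence classification metrics and the continuous Boyce index.

Conventions fixed package-wide:

* a score **equal to** the threshold counts as a predicted presence;
* threshold candidates are the observed unique score values, and ties in
  the maximal TSS are broken by the smallest such value;
* AUC is the Mann-Whitney pair-ranking probability (ties count 1/2),
  identical to the trapezoidal ROC area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata, spearmanr

__all__ = [
    "ConfusionCounts",
    "EvaluationScores",
    "confusion",
    "tss_kappa",
    "auc",
    "max_tss_threshold",
    "boyce",
    "score_predictions",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be nonnegative")
        if self.tp + self.fp + self.tn + self.fn == 0:
            raise ValueError("empty confusion table")


@dataclass
class EvaluationScores:
    sensitivity: float
    specificity: float
    tss: float
    kappa: float
    auc: float
    threshold: float
    boyce: float | None = None

    def to_dict(self) -> dict:
        d = {
            "sensitivity": float(self.sensitivity),
            "specificity": float(self.specificity),
            "tss": float(self.tss),
            "kappa": float(self.kappa),
            "auc": float(self.auc),
            "threshold": float(self.threshold),
        }
        if self.boyce is not None:
            d["boyce"] = float(self.boyce)
        return d


def _validate(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    return scores, labels.astype(int)


def confusion(scores, labels, threshold: float) -> ConfusionCounts:
    """Counts under the >=-threshold convention."""
    scores, labels = _validate(scores, labels)
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)),
        fp=int(np.sum(pred & ~pos)),
        tn=int(np.sum(~pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


def tss_kappa(counts: ConfusionCounts) -> tuple[float, float, float, float]:
    """(sensitivity, specificity, TSS, Kappa) from a confusion table."""
    npos = counts.tp + counts.fn
    nneg = counts.tn + counts.fp
    if npos == 0 or nneg == 0:
        raise ValueError("both classes must be present")
    sens = counts.tp / npos
    spec = counts.tn / nneg
    tss = sens + spec - 1.0
    n = npos + nneg
    p_o = (counts.tp + counts.tn) / n
    pred_pos = counts.tp + counts.fp
    pred_neg = counts.tn + counts.fn
    p_e = (pred_pos * npos + pred_neg * nneg) / n**2
    kappa = 0.0 if p_e == 1.0 else (p_o - p_e) / (1.0 - p_e)
    return sens, spec, tss, kappa


def auc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) AUC; ties count one half."""
    scores, labels = _validate(scores, labels)
    pos = labels == 1
    n1 = int(pos.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def max_tss_threshold(scores, labels) -> tuple[float, float]:
    """Threshold (from the observed score values) maximising TSS.

    Vectorised sweep over unique scores; ties in the maximum resolve to the
    smallest optimal threshold, so duplicating existing scores never
    changes the answer.
    """
    scores, labels = _validate(scores, labels)
    pos = labels == 1
    n1 = int(pos.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    order = np.argsort(scores, kind="mergesort")
    s_sorted = scores[order]
    pos_sorted = pos[order]
    uniq, first_idx = np.unique(s_sorted, return_index=True)
    # counts of scores strictly below each candidate threshold
    pos_below = np.concatenate([[0], np.cumsum(pos_sorted)])[first_idx]
    neg_below = first_idx - pos_below
    # integer numerator of TSS = sens + spec - 1 over the common denominator
    # n1*n0, so ties are exact and the smallest optimal threshold wins
    numer = n0 * (n1 - pos_below) + n1 * neg_below - n1 * n0
    best = int(np.argmax(numer))  # first occurrence = smallest threshold
    return float(uniq[best]), float(numer[best] / (n1 * n0))


def boyce(
    suitability_background,
    suitability_at_presences,
    n_windows: int = 101,
    window_width: float | None = None,
) -> float:
    """Continuous Boyce index.

    Overlapping windows span the observed suitability range; each window's
    predicted-to-expected ratio ``P/E`` compares the fraction of presences
    with the fraction of background cells inside the window.  The index is
    the Spearman rank correlation of P/E against the window midpoint
    (windows with E = 0 are skipped).  +1 means suitability ranks presence
    frequency perfectly; 0 means no better than random.
    """
    bg = np.asarray(suitability_background, dtype=float)
    pr = np.asarray(suitability_at_presences, dtype=float)
    bg = bg[np.isfinite(bg)]
    if len(bg) == 0 or len(pr) == 0:
        raise ValueError("background and presence suitabilities required")
    lo, hi = bg.min(), bg.max()
    if hi <= lo:
        raise ValueError("degenerate suitability range")
    if window_width is None:
        window_width = (hi - lo) / 10.0
    mids = np.linspace(lo + window_width / 2.0, hi - window_width / 2.0, n_windows)
    ratios, centers = [], []
    for m in mids:
        in_w_bg = (bg >= m - window_width / 2.0) & (bg <= m + window_width / 2.0)
        e = in_w_bg.mean()
        if e == 0:
            continue
        in_w_pr = (pr >= m - window_width / 2.0) & (pr <= m + window_width / 2.0)
        ratios.append(in_w_pr.mean() / e)
        centers.append(m)
    if len(ratios) < 2:
        raise ValueError("fewer than 2 usable windows")
    rho = spearmanr(ratios, centers).statistic
    return float(rho)


def score_predictions(scores, labels, boyce_background=None) -> EvaluationScores:
    """Full evaluation at the max-TSS threshold (the package's default gate)."""
    threshold, tss_val = max_tss_threshold(scores, labels)
    sens, spec, tss_chk, kappa = tss_kappa(confusion(scores, labels, threshold))
    assert abs(tss_chk - tss_val) < 1e-12
    b = None
    if boyce_background is not None:
        scores_arr, labels_arr = _validate(scores, labels)
        b = boyce(boyce_background, scores_arr[labels_arr == 1])
    return EvaluationScores(
        sensitivity=sens,
        specificity=spec,
        tss=tss_val,
        kappa=kappa,
        auc=auc(scores, labels),
        threshold=threshold,
        boyce=b,
    )
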