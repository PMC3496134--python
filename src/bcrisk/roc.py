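"""ROC/AUC model discrimination with DeLong inference.

The AUC is the Mann-Whitney probability that a random case outscores a
random control (ties count one half), computed from midranks. Variance and
the paired test for two correlated AUCs use DeLong's structural components
(placement values), which handle the heavy ties of discrete genetic
scores. Operating points maximise Youden's J; cross-validated AUC pools
held-out scores over stratified folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .datatypes import StudyDataset

__all__ = [
    "RocResult",
    "auc_mann_whitney",
    "roc_analysis",
    "delong_paired_test",
    "youden_operating_point",
    "roc_curve_points",
    "cv_auc",
]


def _split(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if labels.dtype.kind in "OU":
        labels = labels == "case"
    labels = labels.astype(bool)
    if not labels.any() or labels.all():
        raise ValueError("both classes must be present")
    return scores[labels], scores[~labels]


def _placements(cases: np.ndarray, controls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong placement values via midranks of the pooled sample."""
    m, n = len(cases), len(controls)
    pooled = np.concatenate([cases, controls])
    ranks = stats.rankdata(pooled)  # midranks
    rank_cases = stats.rankdata(cases)
    rank_controls = stats.rankdata(controls)
    v10 = (ranks[:m] - rank_cases) / n          # P(case_i > control) + ties/2
    v01 = 1.0 - (ranks[m:] - rank_controls) / m
    return v10, v01


def auc_mann_whitney(scores: Sequence[float], labels: Sequence) -> tuple[float, float]:
    """(AUC, DeLong variance) of a score against binary labels."""
    cases, controls = _split(np.asarray(scores), np.asarray(labels))
    v10, v01 = _placements(cases, controls)
    auc = float(v10.mean())
    m, n = len(cases), len(controls)
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return auc, float(s10 / m + s01 / n)


@dataclass
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    cutoff: float
    sensitivity: float
    specificity: float
    n_cases: int
    n_controls: int


def roc_analysis(scores: Sequence[float], labels: Sequence) -> RocResult:
    """AUC with a Wald 95% CI (truncated to [0,1]) and the Youden point."""
    cases, controls = _split(np.asarray(scores), np.asarray(labels))
    auc, var = auc_mann_whitney(scores, labels)
    se = np.sqrt(var)
    cutoff, sens, spec = youden_operating_point(scores, labels)
    return RocResult(
        auc=auc,
        ci_low=float(max(0.0, auc - 1.96 * se)),
        ci_high=float(min(1.0, auc + 1.96 * se)),
        cutoff=cutoff,
        sensitivity=sens,
        specificity=spec,
        n_cases=len(cases),
        n_controls=len(controls),
    )


def delong_paired_test(
    scores_a: Sequence[float], scores_b: Sequence[float], labels: Sequence
) -> tuple[float, float, float]:
    """DeLong's test for two correlated AUCs on the same subjects.

    Returns (auc_a, auc_b, two-sided p). A zero-variance difference (for
    example, b a monotone transform of a) yields p = 1 with a warning.
    """
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    if sa.shape != sb.shape:
        raise ValueError("paired scores must have equal length")
    ca, qa = _split(sa, np.asarray(labels))
    cb, qb = _split(sb, np.asarray(labels))
    v10a, v01a = _placements(ca, qa)
    v10b, v01b = _placements(cb, qb)
    auc_a, auc_b = float(v10a.mean()), float(v10b.mean())
    m, n = len(ca), len(qa)
    s10 = np.cov(np.vstack([v10a, v10b])) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01a, v01b])) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var_diff <= 0:
        if auc_a != auc_b:
            warnings.warn("zero DeLong variance for a non-zero AUC difference")
        else:
            warnings.warn("zero variance of the AUC difference; returning p = 1")
        return auc_a, auc_b, 1.0
    z = (auc_a - auc_b) / np.sqrt(var_diff)
    return auc_a, auc_b, float(2 * stats.norm.sf(abs(z)))


def youden_operating_point(
    scores: Sequence[float], labels: Sequence
) -> tuple[float, float, float]:
    """Cutoff maximising Youden's J = sensitivity + specificity - 1.

    A subject is called positive when score >= cutoff; ties on J are
    broken toward higher specificity.
    """
    cases, controls = _split(np.asarray(scores), np.asarray(labels))
    candidates = np.unique(np.concatenate([cases, controls]))
    best = None
    for c in candidates:
        sens = float((cases >= c).mean())
        spec = float((controls < c).mean())
        j = sens + spec - 1
        if best is None or j > best[0] + 1e-12 or (
            abs(j - best[0]) <= 1e-12 and spec > best[3]
        ):
            best = (j, float(c), sens, spec)
    return best[1], best[2], best[3]


def roc_curve_points(scores: Sequence[float], labels: Sequence) -> pd.DataFrame:
    """(1 - specificity, sensitivity) at every distinct cutoff, for plotting."""
    cases, controls = _split(np.asarray(scores), np.asarray(labels))
    cuts = np.concatenate([[-np.inf], np.unique(np.concatenate([cases, controls])), [np.inf]])
    rows = [
        {"cutoff": c, "fpr": float((controls >= c).mean()), "tpr": float((cases >= c).mean())}
        for c in cuts
    ]
    return pd.DataFrame(rows)


def cv_auc(
    dataset: StudyDataset,
    model_builder: Callable[[StudyDataset], Callable[[StudyDataset], np.ndarray]],
    k: int = 10,
    seed: int = 0,
) -> float:
    """Stratified k-fold cross-validated AUC on pooled held-out scores.

    ``model_builder`` receives the training fold (a StudyDataset) and must
    return a scorer mapping a dataset to per-subject scores. Folds missing
    a class are refolded with a new seed (at most 10 attempts).
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    y = (dataset.subjects["status"] == "case").to_numpy()
    idx = np.arange(len(y))
    for attempt in range(10):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed + attempt)
        folds = list(skf.split(idx, y))
        if all(y[tr].any() and (~y[tr]).any() and y[te].any() and (~y[te]).any()
               for tr, te in folds):
            break
    else:
        raise RuntimeError("could not stratify folds with both classes present")
    held_scores = np.empty(len(y))
    for train_idx, test_idx in folds:
        train = StudyDataset(
            dataset.panel, dataset.subjects.iloc[train_idx].reset_index(drop=True)
        )
        test = StudyDataset(
            dataset.panel, dataset.subjects.iloc[test_idx].reset_index(drop=True)
        )
        scorer = model_builder(train)
        held_scores[test_idx] = np.asarray(scorer(test), dtype=float)
    ok = ~np.isnan(held_scores)
    auc, _ = auc_mann_whitney(held_scores[ok], y[ok])
    return auc
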