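"""Two-loop (double) cross-validation for the PLS-DA/TP classifier.

An outer loop holds out 20% of the samples at a time (5 folds, every
sample out exactly once) to measure honest classification performance.
Within each outer-retained 80%, an inner loop (4 folds, 25% out at a
time) selects the only free hyperparameter of the chain — the number of
PLS components A — by held-out misclassification of the TP-score sign.
The outer held-out predictions are pooled into a single correct
classification rate.

Fold assignment is stratified by group by default so balanced designs
(e.g. 10 + 10 per series) survive the splitting.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .matrix import NormalizedMatrix
from .tp import ModelError, fit_tp_model


@dataclass
class CVPlan:
    """Design of the two cross-validation loops."""

    outer_folds: int = 5
    inner_folds: int = 4
    a_grid: Sequence[int] = (1, 2, 3, 4, 5)
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("fold counts must be >= 2")
        if not self.a_grid or min(self.a_grid) < 1:
            raise ValueError("a_grid must contain positive component counts")


@dataclass
class CVReport:
    """Outcome of one double cross-validation run."""

    chosen_a_per_fold: List[int]
    outer_scores: List[float]  # per-fold correct fraction
    pooled_ccr: float  # percent, from pooled held-out predictions
    chosen_a_final: int
    predictions: np.ndarray = field(default=None, repr=False)  # pooled, sample order
    seed_used: int = 0


def _fold_assignment(
    y: np.ndarray, k: int, rng: np.random.Generator, stratified: bool
) -> np.ndarray:
    """Fold index per sample; folds are disjoint and cover all samples."""
    n = y.size
    fold = np.empty(n, dtype=int)
    if stratified:
        for cls in np.unique(y):
            idx = np.flatnonzero(y == cls)
            idx = rng.permutation(idx)
            fold[idx] = np.arange(idx.size) % k
    else:
        fold[:] = rng.permutation(np.arange(n) % k)
    return fold


def _fit_predict(
    xtr: np.ndarray, ytr: np.ndarray, xte: np.ndarray, a: int
) -> np.ndarray:
    """Fit TP model with <= a components (backing off on rank deficiency)."""
    a_cap = min(a, xtr.shape[0] - 1, xtr.shape[1])
    for a_try in range(a_cap, 0, -1):
        try:
            tp = fit_tp_model(xtr, ytr, n_components=a_try)
        except ModelError:
            continue
        return tp.predict_group(xte)
    # no fittable model (e.g. constant matrix): predict the majority class
    maj = 1 if ytr.mean() > 0.5 else 0
    return np.full(xte.shape[0], maj, dtype=int)


def _folds_ok(y: np.ndarray, fold: np.ndarray, k: int) -> bool:
    for f in range(k):
        tr = y[fold != f]
        if tr.size == 0 or np.unique(tr).size < 2:
            return False
    return True


def double_cv(x, y=None, plan: Optional[CVPlan] = None) -> CVReport:
    """Run the nested cross-validation and pool held-out predictions.

    ``x`` is a :class:`NormalizedMatrix` (labels from metadata) or an
    (n_samples, p) array with explicit binary ``y``.  Returns the chosen
    component count per outer fold, per-fold correct fractions, the pooled
    CCR (percent over all held-out predictions) and the final component
    count (mode over folds, ties to the smaller value).
    """
    plan = plan or CVPlan()
    if isinstance(x, NormalizedMatrix):
        xmat = x.values.T
        yvec = x.y() if y is None else np.asarray(y, dtype=float)
    else:
        xmat = np.asarray(x, dtype=float)
        yvec = np.asarray(y, dtype=float)
    n = yvec.size
    if np.unique(yvec).size < 2:
        raise ModelError("both groups must be present")
    for g in np.unique(yvec):
        if plan.stratified and (yvec == g).sum() < plan.outer_folds:
            raise ModelError(
                f"group {g} has fewer samples than outer_folds={plan.outer_folds}"
            )

    seed_used = plan.seed
    for attempt in range(10):
        seed_used = plan.seed + attempt
        rng = np.random.default_rng(seed_used)
        outer = _fold_assignment(yvec, plan.outer_folds, rng, plan.stratified)
        if not _folds_ok(yvec, outer, plan.outer_folds):
            continue
        inner_assignments = []
        ok = True
        for f in range(plan.outer_folds):
            tr_idx = np.flatnonzero(outer != f)
            inner = _fold_assignment(
                yvec[tr_idx], plan.inner_folds, rng, plan.stratified
            )
            if not _folds_ok(yvec[tr_idx], inner, plan.inner_folds):
                ok = False
                break
            inner_assignments.append((tr_idx, inner))
        if ok:
            break
    else:
        raise ModelError("could not build folds with both classes after 10 reshuffles")

    chosen_a: List[int] = []
    outer_scores: List[float] = []
    pooled_pred = np.full(n, -1, dtype=int)
    for f in range(plan.outer_folds):
        tr_idx, inner = inner_assignments[f]
        te_idx = np.flatnonzero(outer == f)
        xtr_all, ytr_all = xmat[tr_idx], yvec[tr_idx]

        errors = {}
        for a in plan.a_grid:
            miss = 0
            for g in range(plan.inner_folds):
                itr = tr_idx[inner != g]
                ite = tr_idx[inner == g]
                pred = _fit_predict(xmat[itr], yvec[itr], xmat[ite], a)
                miss += int((pred != yvec[ite]).sum())
            errors[a] = miss
        best_a = min(errors, key=lambda a: (errors[a], a))
        chosen_a.append(best_a)

        pred = _fit_predict(xtr_all, ytr_all, xmat[te_idx], best_a)
        pooled_pred[te_idx] = pred
        outer_scores.append(float((pred == yvec[te_idx]).mean()))

    pooled_ccr = 100.0 * float((pooled_pred == yvec).mean())
    counts = Counter(chosen_a)
    top = max(counts.values())
    chosen_final = min(a for a, c in counts.items() if c == top)
    return CVReport(
        chosen_a_per_fold=chosen_a,
        outer_scores=outer_scores,
        pooled_ccr=pooled_ccr,
        chosen_a_final=chosen_final,
        predictions=pooled_pred,
        seed_used=seed_used,
    )
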