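"""Discriminating-variable (DIVA) test: per-variable correct classification
rates and the selectivity-ratio significance limit.

The DIVA test asks, for every variable (protein) separately: how well does
a one-variable threshold classifier separate the two groups on held-out
samples?  The answer is a correct classification rate (CCR) calibrated so
that a variable carrying no class information scores ~50% and a variable
that separates the groups completely scores 100%.

Operationalization (the published account states only the endpoints): over
``n_splits`` seeded stratified Monte-Carlo splits, ~25% of samples are
held out; on the training part the threshold maximizing balanced accuracy
(in either direction) is chosen among midpoints of consecutive distinct
sorted values plus the two extremes, ties resolved toward the lower
threshold; the held-out part is scored with balanced accuracy under the
fixed convention "value > threshold predicts persistence".  The mean
held-out balanced accuracy m over splits gives CCR = 100 * max(m, 1 - m),
so the direction of separation is irrelevant and chance maps to ~50.

Given per-protein CCRs and signed selectivity ratios, a CCR objective
(e.g. 90%) converts into a symmetric SR limit: the smallest |SR| among
proteins reaching the objective.  Proteins with |SR| at or above the limit
are flagged significant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .matrix import NormalizedMatrix


@dataclass
class DivaResult:
    """Per-protein CCRs plus the SR significance limit for one objective."""

    ccr: np.ndarray  # percent, in [50, 100]
    sr: np.ndarray  # signed selectivity ratios, aligned
    sr_limit: float  # +inf when no protein reaches the objective
    significant: np.ndarray  # bool, |SR| >= sr_limit
    objective_ccr: float
    n_splits: int
    seed: int
    protein_ids: Optional[List[str]] = None


def _stratified_holdout(
    y: np.ndarray, rng: np.random.Generator, fraction: float
) -> Tuple[np.ndarray, np.ndarray]:
    """Indices (train, test) with ~`fraction` of each class held out (>= 1)."""
    test: List[int] = []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        k = max(1, int(round(fraction * idx.size)))
        k = min(k, idx.size - 1)  # keep at least one training sample per class
        test.extend(rng.choice(idx, size=k, replace=False))
    test_idx = np.sort(np.array(test, dtype=int))
    train_idx = np.setdiff1d(np.arange(y.size), test_idx)
    return train_idx, test_idx


def _train_thresholds(values: np.ndarray, y01: np.ndarray) -> np.ndarray:
    """Best threshold per column by direction-free balanced accuracy.

    ``values``: (n_train, p); returns (p,) thresholds under the convention
    "value > threshold predicts class 1".  Candidate cuts are midpoints
    between consecutive *distinct* sorted training values plus the two
    extremes; ties go to the lower threshold.
    """
    n, p = values.shape
    order = np.argsort(values, axis=0, kind="stable")
    vs = np.take_along_axis(values, order, axis=0)
    ys = np.take_along_axis(np.broadcast_to(y01[:, None], (n, p)), order, axis=0)

    n1 = float(y01.sum())
    n0 = float(n - n1)
    # cum1[k] = class-1 samples among the k lowest values (predicted 0 at cut k)
    cum1 = np.vstack([np.zeros(p), np.cumsum(ys, axis=0)])
    ks = np.arange(n + 1, dtype=float)[:, None]
    cum0 = ks - cum1
    ba = 0.5 * (cum0 / n0 + (n1 - cum1) / n1)  # (n+1, p)
    score = np.maximum(ba, 1.0 - ba)

    # interior cut k is valid only between distinct values
    valid = np.ones((n + 1, p), dtype=bool)
    if n > 1:
        valid[1:n] = vs[1:] > vs[:-1]
    score = np.where(valid, score, -np.inf)

    best = np.argmax(score, axis=0)  # first (lowest-threshold) argmax
    thr = np.empty(p)
    for j in range(p):
        k = best[j]
        if k == 0:
            thr[j] = -np.inf
        elif k == n:
            thr[j] = np.inf
        else:
            thr[j] = 0.5 * (vs[k - 1, j] + vs[k, j])
    return thr


def matrix_ccr(
    x: np.ndarray,
    y,
    n_splits: int = 200,
    seed: int = 0,
    holdout_fraction: float = 0.25,
) -> np.ndarray:
    """CCR (percent) for every column of an (n_samples, p) matrix at once."""
    xmat = np.asarray(x, dtype=float)
    y01 = np.asarray(y, dtype=float)
    if np.unique(y01).size < 2:
        raise ValueError("both groups must be present")
    if n_splits < 1:
        raise ValueError("n_splits must be >= 1")
    rng = np.random.default_rng(seed)
    p = xmat.shape[1]
    acc = np.zeros(p)
    for _ in range(n_splits):
        tr, te = _stratified_holdout(y01, rng, holdout_fraction)
        thr = _train_thresholds(xmat[tr], y01[tr])
        pred1 = xmat[te] > thr[None, :]  # (n_te, p)
        yte = y01[te]
        m1 = yte == 1
        ba = 0.5 * (pred1[m1].mean(axis=0) + (~pred1[~m1]).mean(axis=0))
        acc += ba
    m = acc / n_splits
    return 100.0 * np.maximum(m, 1.0 - m)


def variable_ccr(
    values: Sequence[float],
    y,
    n_splits: int = 200,
    seed: int = 0,
    holdout_fraction: float = 0.25,
) -> float:
    """CCR of a single variable; see module docstring for the procedure."""
    v = np.asarray(values, dtype=float)[:, None]
    return float(matrix_ccr(v, y, n_splits=n_splits, seed=seed,
                            holdout_fraction=holdout_fraction)[0])


def sr_limit_for_ccr(
    sr: Sequence[float], ccr: Sequence[float], objective: float
) -> Tuple[float, np.ndarray]:
    """SR significance limit for a CCR objective.

    The limit is the smallest |SR| among proteins whose CCR reaches the
    objective; with no qualifying protein the limit is +inf and nothing is
    significant.  Significance is then |SR| >= limit for every protein.
    """
    sr_arr = np.asarray(sr, dtype=float)
    ccr_arr = np.asarray(ccr, dtype=float)
    if sr_arr.shape != ccr_arr.shape:
        raise ValueError("sr and ccr must be aligned")
    qualifying = np.abs(sr_arr[ccr_arr >= objective])
    limit = float(qualifying.min()) if qualifying.size else np.inf
    significant = np.abs(sr_arr) >= limit
    return limit, significant


def marker_screen(
    offset_counts,
    tp_model,
    objective: float = 90.0,
    n_splits: int = 200,
    seed: int = 0,
) -> DivaResult:
    """Full marker screen: SR from the multivariate model, CCR on counts.

    Selectivity ratios come from a TP model fitted to the *normalized*
    matrix (the multivariate view), while each protein's CCR is evaluated
    on the *offset counts* — the detection scale on which single-variable
    thresholds are interpretable ("<= 1" means "not detected").  Per-sample
    normalization factors would otherwise inject depth noise into an
    essentially binary presence pattern and blur the per-variable test.

    ``offset_counts`` is a :class:`SpectralCountMatrix` with the +1 offset
    applied; ``tp_model`` a :class:`~spcregress.tp.TPModel` over the same
    proteins in the same order.
    """
    from .matrix import SpectralCountMatrix

    if not isinstance(offset_counts, SpectralCountMatrix):
        raise TypeError("offset_counts must be a SpectralCountMatrix")
    if not offset_counts.offset_applied:
        raise ValueError("apply add_offset before screening")
    if list(tp_model.protein_ids) != list(offset_counts.protein_ids):
        raise ValueError("TP model and count matrix list different proteins")
    ccr = matrix_ccr(
        offset_counts.counts.T.astype(float),
        offset_counts.y(),
        n_splits=n_splits,
        seed=seed,
    )
    limit, significant = sr_limit_for_ccr(tp_model.selectivity_ratio, ccr, objective)
    return DivaResult(
        ccr=ccr,
        sr=np.asarray(tp_model.selectivity_ratio, dtype=float),
        sr_limit=limit,
        significant=significant,
        objective_ccr=objective,
        n_splits=n_splits,
        seed=seed,
        protein_ids=list(offset_counts.protein_ids),
    )


def diva_test(
    x,
    y=None,
    sr: Optional[Sequence[float]] = None,
    objective: float = 90.0,
    n_splits: int = 200,
    seed: int = 0,
) -> DivaResult:
    """Run the DIVA test on a full matrix and derive the SR limit.

    ``x`` may be a :class:`NormalizedMatrix` (labels taken from metadata)
    or an (n_samples, p) array with explicit ``y``.  ``sr`` are the signed
    selectivity ratios from a fitted TP model on the same proteins.
    """
    if isinstance(x, NormalizedMatrix):
        xmat = x.values.T
        yvec = x.y() if y is None else np.asarray(y, dtype=float)
        prot = list(x.protein_ids)
    else:
        xmat = np.asarray(x, dtype=float)
        yvec = np.asarray(y, dtype=float)
        prot = None
    ccr = matrix_ccr(xmat, yvec, n_splits=n_splits, seed=seed)
    if sr is None:
        sr = np.full(ccr.shape, np.nan)
    sr_arr = np.asarray(sr, dtype=float)
    limit, significant = sr_limit_for_ccr(sr_arr, ccr, objective)
    return DivaResult(
        ccr=ccr,
        sr=sr_arr,
        sr_limit=limit,
        significant=significant,
        objective_ccr=objective,
        n_splits=n_splits,
        seed=seed,
        protein_ids=prot,
    )
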