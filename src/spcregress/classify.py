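"""Single- and two-marker classification on spectral counts.

These are the downstream, clinically readable classifiers built after the
multivariate screen has nominated candidate proteins:

* :func:`roc_threshold` — an ROC-derived decision stump (one protein, one
  cutoff) maximizing Youden's J.  On offset counts the natural cutoff for
  a presence/absence marker is "<= 1 versus > 1", i.e. detected or not.
* :func:`fit_two_node_tree` — a CART-style depth-2 tree by exhaustive
  Gini impurity search, with a competitor ranking of all proteins at the
  root.
* :func:`logistic_rank` — per-protein single-variable binary logistic
  fits ranked by likelihood-ratio statistic, with explicit detection of
  complete separation (where the maximum-likelihood slope diverges).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Literal, Optional, Sequence, Tuple

import numpy as np

from .matrix import NormalizedMatrix, SpectralCountMatrix

Direction = Literal["gt_is_regression", "gt_is_persistence"]


@dataclass
class ClassifierRule:
    """A decision stump: one protein, one threshold, one direction."""

    accession: str
    threshold: float
    direction: Direction
    source: Literal["roc", "tree_root", "tree_child"] = "roc"
    youden_j: float = np.nan
    uninformative: bool = False

    def predict(self, values: np.ndarray) -> np.ndarray:
        """0 = regression, 1 = persistence per sample."""
        gt = np.asarray(values, dtype=float) > self.threshold
        if self.direction == "gt_is_persistence":
            return gt.astype(int)
        return (~gt).astype(int)


@dataclass
class TreeModel:
    """A depth-<=2 classification tree (root stump plus optional child).

    ``child_branch`` names the root *side* the child refines: samples with
    value > root.threshold go to the "gt" branch, the rest to "le".
    ``competitor_ranking`` orders all proteins by their best achievable
    root impurity decrease.
    """

    root: Optional[ClassifierRule]
    child: Optional[ClassifierRule] = None
    child_branch: Optional[Literal["gt", "le"]] = None
    competitor_ranking: List[Tuple[str, float]] = None
    degenerate: bool = False

    def predict(self, value_of: Dict[str, np.ndarray]) -> np.ndarray:
        if self.root is None:
            raise ValueError("degenerate tree has no splits")
        root_vals = value_of[self.root.accession]
        pred = self.root.predict(root_vals)
        if self.child is not None:
            on_branch = (
                root_vals > self.root.threshold
                if self.child_branch == "gt"
                else root_vals <= self.root.threshold
            )
            child_pred = self.child.predict(value_of[self.child.accession])
            pred = np.where(on_branch, child_pred, pred)
        return pred


def _candidate_thresholds(values: np.ndarray) -> np.ndarray:
    """Midpoints of consecutive distinct sorted values plus both extremes."""
    vs = np.unique(values)
    mids = (vs[:-1] + vs[1:]) / 2.0 if vs.size > 1 else np.empty(0)
    return np.concatenate([[vs[0] - 1.0], mids, [vs[-1] + 1.0]])


def roc_threshold(values: Sequence[float], y, accession: str = "") -> ClassifierRule:
    """ROC-derived stump maximizing Youden's J (sensitivity + specificity - 1).

    Ties in J go to the lower threshold.  The direction makes regression
    the predicted class on the side with the higher regression rate.  A
    variable with J = 0 (e.g. constant) yields an ``uninformative`` rule.
    """
    v = np.asarray(values, dtype=float)
    yv = np.asarray(y, dtype=float)
    if np.unique(yv).size < 2:
        raise ValueError("both groups must be present")
    n1 = yv.sum()
    n0 = yv.size - n1

    best = None  # (j, threshold, direction)
    for thr in _candidate_thresholds(v):
        gt = v > thr
        # rate of each class on the high side
        p1_hi = (gt & (yv == 1)).sum() / n1  # persistence sensitivity if gt->1
        p0_hi = (gt & (yv == 0)).sum() / n0
        j_gt1 = p1_hi - p0_hi  # J for gt_is_persistence
        if j_gt1 >= 0:
            j, direction = j_gt1, "gt_is_persistence"
        else:
            j, direction = -j_gt1, "gt_is_regression"
        if best is None or j > best[0] + 1e-12:
            best = (j, thr, direction)
    j, thr, direction = best
    return ClassifierRule(
        accession=accession,
        threshold=float(thr),
        direction=direction,
        source="roc",
        youden_j=float(j),
        uninformative=bool(j <= 1e-12),
    )


def _values_by_accession(matrix) -> Tuple[Dict[str, np.ndarray], List[str]]:
    if isinstance(matrix, SpectralCountMatrix):
        vals = matrix.counts.astype(float)
        prot, samp = matrix.protein_ids, matrix.sample_ids
    elif isinstance(matrix, NormalizedMatrix):
        vals = matrix.values
        prot, samp = matrix.protein_ids, matrix.sample_ids
    else:
        raise TypeError("matrix must be SpectralCountMatrix or NormalizedMatrix")
    return {a: vals[i] for i, a in enumerate(prot)}, list(samp)


def apply_rules(rules, matrix, y=None):
    """Apply a stump or tree to a matrix; return predictions and confusion.

    ``rules`` is a :class:`ClassifierRule` or :class:`TreeModel`.  Returns
    ``(predictions, summary)`` where predictions are 0/1 per sample in
    matrix order and ``summary`` holds the 2x2 confusion table plus
    per-group and (when split labels exist) per-split correct counts.
    """
    value_of, sample_ids = _values_by_accession(matrix)
    needed = [rules.accession] if isinstance(rules, ClassifierRule) else [
        r.accession for r in (rules.root, rules.child) if r is not None
    ]
    for acc in needed:
        if acc not in value_of:
            raise KeyError(f"accession {acc!r} not present in matrix")

    if isinstance(rules, ClassifierRule):
        pred = rules.predict(value_of[rules.accession])
    else:
        pred = rules.predict(value_of)

    if y is None:
        yv = np.array(
            [1.0 if matrix.group_of[s] == "persistence" else 0.0 for s in sample_ids]
        )
    else:
        yv = np.asarray(y, dtype=float)

    confusion = {
        "tn": int(((pred == 0) & (yv == 0)).sum()),  # regression called regression
        "fp": int(((pred == 1) & (yv == 0)).sum()),
        "fn": int(((pred == 0) & (yv == 1)).sum()),
        "tp": int(((pred == 1) & (yv == 1)).sum()),
    }
    summary = {
        "confusion": confusion,
        "n_correct": confusion["tn"] + confusion["tp"],
        "n_samples": int(yv.size),
        "correct_by_group": {
            "regression": confusion["tn"],
            "persistence": confusion["tp"],
        },
    }
    split_of = getattr(matrix, "split_of", None)
    if split_of:
        per_split: Dict[str, Dict[str, int]] = {}
        for j, s in enumerate(sample_ids):
            sp = split_of.get(s)
            if sp is None:
                continue
            d = per_split.setdefault(sp, {"correct": 0, "total": 0})
            d["total"] += 1
            d["correct"] += int(pred[j] == yv[j])
        summary["by_split"] = per_split
    return pred, summary


def _gini(y: np.ndarray) -> float:
    if y.size == 0:
        return 0.0
    p = y.mean()
    return 2.0 * p * (1.0 - p)


def _best_split_for_values(v: np.ndarray, y: np.ndarray) -> Tuple[float, float]:
    """(impurity decrease, threshold) of the best binary split on one protein."""
    n = y.size
    parent = _gini(y)
    best_dec, best_thr = 0.0, None
    for thr in _candidate_thresholds(v):
        gt = v > thr
        n_gt = int(gt.sum())
        if n_gt == 0 or n_gt == n:
            continue
        dec = parent - (n_gt / n) * _gini(y[gt]) - ((n - n_gt) / n) * _gini(y[~gt])
        if dec > best_dec + 1e-12 or (
            abs(dec - best_dec) <= 1e-12 and best_thr is not None and thr < best_thr
        ):
            best_dec, best_thr = dec, thr
    if best_thr is None:
        best_thr = np.nan
    return best_dec, float(best_thr)


def _stump_from_split(acc: str, v: np.ndarray, y: np.ndarray, thr: float, source):
    gt = v > thr
    # each side predicts its majority class; ties favour regression (0)
    gt_cls = 1 if y[gt].mean() > 0.5 else 0
    direction = "gt_is_persistence" if gt_cls == 1 else "gt_is_regression"
    return ClassifierRule(accession=acc, threshold=thr, direction=direction, source=source)


def fit_two_node_tree(matrix, y=None) -> TreeModel:
    """Exhaustive-search CART-style tree of depth <= 2 with Gini impurity.

    The root is the (protein, threshold) pair with maximal impurity
    decrease; ties break to the lexicographically lower accession, then
    the lower threshold.  A child stump is fitted on the more impure root
    branch only if it further reduces impurity.  All proteins are ranked
    by their best root impurity decrease as competitors.
    """
    value_of, sample_ids = _values_by_accession(matrix)
    if y is None:
        yv = np.array(
            [1.0 if matrix.group_of[s] == "persistence" else 0.0 for s in sample_ids]
        )
    else:
        yv = np.asarray(y, dtype=float)
    if len(value_of) < 1:
        raise ValueError("empty matrix")
    if np.unique(yv).size < 2:
        return TreeModel(root=None, competitor_ranking=[], degenerate=True)

    results = {}
    for acc in value_of:
        results[acc] = _best_split_for_values(value_of[acc], yv)
    ranking = sorted(results.items(), key=lambda kv: (-kv[1][0], kv[0]))
    competitor_ranking = [(acc, dec) for acc, (dec, _) in ranking]

    root_acc, (root_dec, root_thr) = ranking[0]
    if root_dec <= 1e-12 or np.isnan(root_thr):
        return TreeModel(root=None, competitor_ranking=competitor_ranking, degenerate=True)
    root_vals = value_of[root_acc]
    root = _stump_from_split(root_acc, root_vals, yv, root_thr, "tree_root")

    # refine the more impure branch, if any impurity remains
    gt = root_vals > root_thr
    branches = [("gt", gt), ("le", ~gt)]
    branches.sort(key=lambda b: -(b[1].sum() / yv.size) * _gini(yv[b[1]]))
    child = None
    child_branch = None
    name, mask = branches[0]
    if _gini(yv[mask]) > 1e-12:
        sub_results = {
            acc: _best_split_for_values(value_of[acc][mask], yv[mask])
            for acc in value_of
        }
        sub_rank = sorted(sub_results.items(), key=lambda kv: (-kv[1][0], kv[0]))
        c_acc, (c_dec, c_thr) = sub_rank[0]
        if c_dec > 1e-12 and not np.isnan(c_thr):
            child = _stump_from_split(
                c_acc, value_of[c_acc][mask], yv[mask], c_thr, "tree_child"
            )
            child_branch = name
    return TreeModel(
        root=root,
        child=child,
        child_branch=child_branch,
        competitor_ranking=competitor_ranking,
    )


@dataclass
class LogisticRankEntry:
    accession: str
    lr_stat: float  # likelihood-ratio statistic vs intercept-only
    separated: bool  # complete separation: ML slope diverges
    converged: bool = True


def _complete_separation(v: np.ndarray, y: np.ndarray) -> bool:
    v0, v1 = v[y == 0], v[y == 1]
    return v0.max() < v1.min() or v1.max() < v0.min()


def logistic_rank(matrix, y=None, max_iter: int = 25) -> List[LogisticRankEntry]:
    """Rank proteins by single-variable logistic-regression discrimination.

    Each protein gets a one-variable binary logistic fit (intercept +
    slope); proteins are ordered by the likelihood-ratio statistic against
    the intercept-only model.  Completely separating proteins — where the
    likelihood is monotone and the slope estimate diverges — are flagged
    and placed at the top (infinite LR statistic); constant proteins score
    zero.  Degeneracies never raise.
    """
    import statsmodels.api as sm

    value_of, sample_ids = _values_by_accession(matrix)
    if y is None:
        yv = np.array(
            [1.0 if matrix.group_of[s] == "persistence" else 0.0 for s in sample_ids]
        )
    else:
        yv = np.asarray(y, dtype=float)
    if np.unique(yv).size < 2:
        raise ValueError("both groups must be present")

    entries: List[LogisticRankEntry] = []
    for acc, v in value_of.items():
        if np.ptp(v) == 0:
            entries.append(LogisticRankEntry(acc, 0.0, separated=False))
            continue
        if _complete_separation(v, yv):
            entries.append(LogisticRankEntry(acc, np.inf, separated=True))
            continue
        design = sm.add_constant(v)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                fit = sm.Logit(yv, design).fit(disp=0, maxiter=max_iter)
                lr = float(2.0 * (fit.llf - fit.llnull))
                entries.append(
                    LogisticRankEntry(acc, max(lr, 0.0), separated=False,
                                      converged=bool(fit.mle_retvals.get("converged", True)))
                )
            except Exception:
                entries.append(LogisticRankEntry(acc, 0.0, separated=False, converged=False))
    entries.sort(key=lambda e: (-e.lr_stat, e.accession))
    return entries
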