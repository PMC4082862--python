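"""PLS-DA with a target-projection component and selectivity ratios.

Discriminant analysis is run as PLS1 regression of a binary response
(regression = 0, persistence = 1) on the mean-centered protein matrix.
However many latent components A are fitted, the whole model can be
collapsed onto a single *target-projection* (TP) component: the unit
vector w_TP along the regression coefficient vector b.  Each sample gets
one TP score t_TP = X_c w_TP, and each protein a TP loading
p_TP = X_cᵀ t_TP / (t_TPᵀ t_TP).

The *selectivity ratio* of a protein is the variance of its centered
column explained by the TP component divided by the residual variance,
signed by the TP loading.  Proteins with large |SR| drive the group
separation; the ratio is the basis of the DIVA significance limit
downstream.

Scores are oriented so that persistence samples have positive mean score,
making signs comparable across runs and datasets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np

from .matrix import NormalizedMatrix

_NORM_TOL = 1e-12


class ModelError(ValueError):
    """Raised for degenerate model inputs (single group, zero signal...)."""


@dataclass
class PLSState:
    """Internal state of a fitted PLS1 model (NIPALS, X-only deflation).

    Matrices are stored column-per-component: ``weights`` W, ``scores`` T,
    ``loadings`` P, and the inner y-loadings ``q``.  ``coef`` is the
    A-component regression coefficient vector b = W (PᵀW)⁻¹ q.
    """

    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray  # (p, A)
    scores: np.ndarray  # (n, A)
    loadings: np.ndarray  # (p, A)
    q: np.ndarray  # (A,)
    coef: np.ndarray  # (p,)
    n_components: int
    scale: Optional[np.ndarray] = None  # per-column std when autoscaled


@dataclass
class TPModel:
    """A PLS-DA model reduced to its single target-projection component."""

    n_components: int
    weight_tp: np.ndarray  # (p,), unit norm
    scores_tp: np.ndarray  # (n,)
    loadings_tp: np.ndarray  # (p,)
    selectivity_ratio: np.ndarray  # (p,), signed; +/-inf where residual = 0
    explained_var: np.ndarray  # (p,)
    residual_var: np.ndarray  # (p,)
    infinite_sr: np.ndarray  # (p,) bool, flags the zero-residual sentinel
    protein_ids: List[str]
    sample_ids: List[str]
    y_coding: Dict[str, int]
    x_mean: np.ndarray
    scale: Optional[np.ndarray] = None

    def project(self, x_new: np.ndarray) -> np.ndarray:
        """TP scores for new samples (rows), centered with the training means."""
        xc = np.asarray(x_new, dtype=float) - self.x_mean
        if self.scale is not None:
            xc = xc / self.scale
        return xc @ self.weight_tp

    def predict_group(self, x_new: np.ndarray) -> np.ndarray:
        """Class by TP-score sign: positive -> persistence (1), else regression (0)."""
        return (self.project(x_new) > 0).astype(int)


def _as_xy(x, y):
    if isinstance(x, NormalizedMatrix):
        xmat = x.values.T  # samples x proteins
        yvec = x.y() if y is None else np.asarray(y, dtype=float)
        prot, samp = list(x.protein_ids), list(x.sample_ids)
    else:
        xmat = np.asarray(x, dtype=float)
        yvec = np.asarray(y, dtype=float)
        prot = [f"v{i}" for i in range(xmat.shape[1])]
        samp = [f"s{i}" for i in range(xmat.shape[0])]
    return xmat, yvec, prot, samp


def fit_plsda(
    x,
    y=None,
    n_components: int = 2,
    *,
    autoscale: bool = False,
) -> PLSState:
    """Fit PLS1 of a centered binary response on the centered protein matrix.

    Parameters
    ----------
    x
        :class:`NormalizedMatrix` (proteins x samples; transposed
        internally) or a plain ``(n_samples, n_proteins)`` array.
    y
        Binary labels (0 = regression, 1 = persistence); taken from the
        matrix metadata when omitted.
    n_components
        Number of latent components A, ``1 <= A <= min(n-1, p)``.
    autoscale
        Divide columns by their standard deviation after centering.
        Off by default: spectral counts share a common scale.
    """
    xmat, yvec, _, _ = _as_xy(x, y)
    n, p = xmat.shape
    if yvec.shape[0] != n:
        raise ModelError(f"y length {yvec.shape[0]} != {n} samples")
    classes = np.unique(yvec)
    if classes.size < 2:
        raise ModelError("both groups must be present to fit PLS-DA")
    a_max = min(n - 1, p)
    if not (1 <= n_components <= a_max):
        raise ModelError(f"n_components must be in [1, {a_max}], got {n_components}")

    x_mean = xmat.mean(axis=0)
    xc = xmat - x_mean
    scale = None
    if autoscale:
        scale = xc.std(axis=0, ddof=1)
        scale[scale < _NORM_TOL] = 1.0
        xc = xc / scale
    y_mean = float(yvec.mean())
    yc = yvec - y_mean

    W = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    P = np.zeros((p, n_components))
    q = np.zeros(n_components)
    xa = xc.copy()
    for a in range(n_components):
        w = xa.T @ yc
        nw = np.linalg.norm(w)
        if nw < _NORM_TOL:
            raise ModelError(
                f"no residual covariance with y at component {a + 1}; "
                f"reduce n_components"
            )
        w /= nw
        t = xa @ w
        tt = float(t @ t)
        if tt < _NORM_TOL:
            raise ModelError(f"degenerate score vector at component {a + 1}")
        pvec = xa.T @ t / tt
        q[a] = float(yc @ t / tt)
        xa = xa - np.outer(t, pvec)
        W[:, a], T[:, a], P[:, a] = w, t, pvec

    coef = W @ np.linalg.solve(P.T @ W, q)
    return PLSState(
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W,
        scores=T,
        loadings=P,
        q=q,
        coef=coef,
        n_components=n_components,
        scale=scale,
    )


def target_projection(pls: PLSState, x, y=None) -> TPModel:
    """Collapse a fitted PLS model onto its target-projection component.

    The TP weight is the normalized coefficient vector; scores, loadings
    and selectivity ratios follow.  Orientation is fixed so the mean TP
    score of persistence samples exceeds that of regression samples.
    """
    xmat, yvec, prot, samp = _as_xy(x, y)
    bnorm = np.linalg.norm(pls.coef)
    if bnorm < _NORM_TOL:
        raise ModelError("zero coefficient vector: no discriminative signal")
    w_tp = pls.coef / bnorm
    xc = xmat - pls.x_mean
    if pls.scale is not None:
        xc = xc / pls.scale
    t_tp = xc @ w_tp
    tt = float(t_tp @ t_tp)
    if tt < _NORM_TOL:
        raise ModelError("degenerate TP scores")
    p_tp = xc.T @ t_tp / tt

    # orient: persistence (y=1) mean score positive
    mask1 = yvec == 1
    if mask1.any() and (~mask1).any():
        if t_tp[mask1].mean() < t_tp[~mask1].mean():
            w_tp, t_tp, p_tp = -w_tp, -t_tp, -p_tp

    explained = (p_tp**2) * tt
    residual = ((xc - np.outer(t_tp, p_tp)) ** 2).sum(axis=0)
    infinite = residual <= _NORM_TOL * np.maximum(explained, 1.0)
    magnitude = np.where(infinite, np.inf, explained / np.where(residual > 0, residual, 1.0))
    sr = magnitude * np.where(np.signbit(p_tp), -1.0, 1.0)

    return TPModel(
        n_components=pls.n_components,
        weight_tp=w_tp,
        scores_tp=t_tp,
        loadings_tp=p_tp,
        selectivity_ratio=sr,
        explained_var=explained,
        residual_var=residual,
        infinite_sr=infinite,
        protein_ids=prot,
        sample_ids=samp,
        y_coding={"regression": 0, "persistence": 1},
        x_mean=pls.x_mean,
        scale=pls.scale,
    )


def fit_tp_model(x, y=None, n_components: int = 2, **kw) -> TPModel:
    """Convenience: :func:`fit_plsda` followed by :func:`target_projection`."""
    return target_projection(fit_plsda(x, y, n_components, **kw), x, y)


def selectivity_ratio(tp: TPModel, x=None) -> np.ndarray:
    """Signed per-protein selectivity ratios of a fitted TP model.

    Provided for symmetry with the fitting API; the ratios are computed at
    fit time from the same matrix, so this accessor simply validates the
    optional matrix dimensions and returns them.
    """
    if x is not None:
        xmat, _, _, _ = _as_xy(x, None)
        if xmat.shape[1] != tp.weight_tp.shape[0]:
            raise ModelError(
                f"matrix has {xmat.shape[1]} proteins, model has {tp.weight_tp.shape[0]}"
            )
    return tp.selectivity_ratio


def score_sign_match(tp: TPModel, y=None) -> float:
    """Fraction of samples whose oriented TP-score sign matches their group.

    Persistence samples should score positive, regression samples negative
    (or zero).  This is the quantity summarized as "discrimination" in a
    TP score plot.
    """
    if y is None:
        raise ModelError("labels required")
    yvec = np.asarray(y, dtype=float)
    pred = (tp.scores_tp > 0).astype(float)
    return float((pred == yvec).mean())
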