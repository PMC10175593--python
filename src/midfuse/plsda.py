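"""PLS2 regression (NIPALS) and its discriminant-analysis wrapper.

PLS-DA regresses an indicator-coded class matrix Y on the measured
variables X through a small number of latent variables chosen to
maximize X-Y covariance. The class of a new sample is the argmax of its
predicted indicator columns. Variable Importance in Projection (VIP)
summarizes each variable's contribution to the latent structure and is
normalized so that the mean squared VIP equals 1; VIP > 1 flags
influential variables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .data_model import DataError
from .preprocessing import CenteringModel, apply_pretreatment, fit_pretreatment

logger = logging.getLogger(__name__)

def encode_classes(labels) -> tuple[np.ndarray, tuple[str, ...]]:
    """Indicator-code class labels: one {0,1} column per class.

    Class order is first-appearance order; rows sum to 1. Two classes
    still get two columns so VIP treats both symmetrically.
    """
    labels = list(labels)
    classes: list[str] = []
    for lab in labels:
        if lab not in classes:
            classes.append(lab)
    if len(classes) < 2:
        raise DataError("need at least 2 classes to encode")
    index = {c: j for j, c in enumerate(classes)}
    Y = np.zeros((len(labels), len(classes)))
    for i, lab in enumerate(labels):
        Y[i, index[lab]] = 1.0
    return Y, tuple(classes)


def decode_classes(Y: np.ndarray, classes) -> list:
    """Inverse of :func:`encode_classes` on exact indicator rows."""
    return [classes[j] for j in np.argmax(np.asarray(Y), axis=1)]


@dataclass
class PLSModel:
    """Fitted NIPALS PLS2 discriminant model.

    Attributes
    ----------
    W, P : ndarray (p, A)
        X-weights (unit norm per column) and X-loadings.
    Q : ndarray (m, A)
        Y-loadings per component.
    T : ndarray (n, A)
        X-scores on the training set (mutually orthogonal columns).
    B : ndarray (p, m)
        Regression coefficients on centered data, W (PᵀW)⁻¹ Qᵀ.
    explained_x, explained_y : ndarray (A,)
        Per-component fractions of the centered X / Y sum of squares.
    """

    n_lv: int
    W: np.ndarray
    P: np.ndarray
    Q: np.ndarray
    T: np.ndarray
    B: np.ndarray
    explained_x: np.ndarray
    explained_y: np.ndarray
    x_pretreatment: CenteringModel | None
    y_means: np.ndarray
    classes: tuple[str, ...]
    ssy_components: np.ndarray = field(default=None)  # (tᵀt)·‖q‖² per component

    @property
    def n_vars(self) -> int:
        return self.B.shape[0]

    def coefficients_for(self, n_lv: int) -> np.ndarray:
        """Regression coefficients using only the first ``n_lv`` components."""
        if not 1 <= n_lv <= self.n_lv:
            raise DataError(f"n_lv must be in [1, {self.n_lv}]")
        W, P, Q = self.W[:, :n_lv], self.P[:, :n_lv], self.Q[:, :n_lv]
        return W @ np.linalg.solve(P.T @ W, Q.T)

    def predict_scores(self, X: np.ndarray, n_lv: int | None = None) -> np.ndarray:
        """Continuous predicted indicator values for each class."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_vars:
            raise DataError(f"expected {self.n_vars} columns, got {X.shape[1]}")
        Xc = apply_pretreatment(self.x_pretreatment, X)
        B = self.B if n_lv is None else self.coefficients_for(n_lv)
        return Xc @ B + self.y_means

    def predict(self, X: np.ndarray, n_lv: int | None = None) -> list[str]:
        """Hard class assignment = argmax of predicted indicators.

        Ties go to the first class in coding order (logged).
        """
        scores = self.predict_scores(X, n_lv=n_lv)
        out = []
        for row in scores:
            best = np.flatnonzero(row == row.max())
            if best.size > 1:
                logger.info("tie between classes %s; taking first",
                            [self.classes[j] for j in best])
            out.append(self.classes[best[0]])
        return out


def _nipals(Xc: np.ndarray, Yc: np.ndarray, n_lv: int):
    """NIPALS extraction with X-deflation only; Y is left intact."""
    n, p = Xc.shape
    m = Yc.shape[1]
    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    Q = np.zeros((m, n_lv))
    T = np.zeros((n, n_lv))
    ssx0 = float(np.sum(Xc**2))
    ssy0 = float(np.sum(Yc**2))
    if ssx0 <= 0:
        raise DataError("X has zero variance after centering")
    X = Xc.copy()
    explained_x = np.zeros(n_lv)
    ssy_comp = np.zeros(n_lv)
    for a in range(n_lv):
        if np.sum(X**2) <= 1e-14 * ssx0:
            raise DataError(
                f"X residual exhausted before component {a + 1}; reduce n_lv"
            )
        # the NIPALS inner loop is power iteration on XᵀY YᵀX; its fixed
        # point is the leading left singular vector of XᵀY, computed
        # here directly (converged solution, deterministic sign)
        C = X.T @ Yc
        U, sv, _ = np.linalg.svd(C, full_matrices=False)
        if sv[0] <= 1e-14 * max(1.0, np.linalg.norm(X)):
            raise DataError(f"degenerate weight vector at component {a + 1}")
        w = U[:, 0]
        # sign convention: score correlates positively with the starting
        # Y column NIPALS would use (the one of maximal variance)
        u0 = Yc[:, int(np.argmax(Yc.var(axis=0)))]
        t = X @ w
        if t @ u0 < 0:
            w = -w
            t = -t
        q = Yc.T @ t / (t @ t)
        tt = float(t @ t)
        pvec = X.T @ t / tt
        X -= np.outer(t, pvec)
        W[:, a], P[:, a], Q[:, a], T[:, a] = w, pvec, q, t
        explained_x[a] = tt * float(pvec @ pvec) / ssx0
        ssy_comp[a] = tt * float(q @ q)
    explained_y = ssy_comp / ssy0 if ssy0 > 0 else np.zeros(n_lv)
    return W, P, Q, T, explained_x, explained_y, ssy_comp


def fit_plsda(
    X: np.ndarray,
    labels,
    n_lv: int,
    *,
    pretreatment: str = "center",
) -> PLSModel:
    """Fit a PLS-DA model with ``n_lv`` latent variables.

    X is pretreated per ``pretreatment`` (default mean centering); the
    indicator matrix Y is mean-centered internally.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if not 1 <= n_lv <= min(n - 1, p):
        raise DataError(f"n_lv={n_lv} outside [1, min(n-1, p)={min(n - 1, p)}]")
    Y, classes = encode_classes(labels)
    xpre = fit_pretreatment(X, pretreatment)
    Xc = apply_pretreatment(xpre, X)
    y_means = Y.mean(axis=0)
    Yc = Y - y_means
    W, P, Q, T, ex, ey, ssy = _nipals(Xc, Yc, n_lv)
    B = W @ np.linalg.solve(P.T @ W, Q.T)
    return PLSModel(
        n_lv=n_lv, W=W, P=P, Q=Q, T=T, B=B,
        explained_x=ex, explained_y=ey,
        x_pretreatment=xpre, y_means=y_means, classes=classes,
        ssy_components=ssy,
    )


def predict_plsda(model: PLSModel, X: np.ndarray) -> tuple[list[str], np.ndarray]:
    """Predicted class per row plus continuous per-class scores."""
    scores = model.predict_scores(X)
    return model.predict(X), scores


@dataclass(frozen=True)
class VipResult:
    """Per-variable VIP scores with the applied selection threshold."""

    scores: np.ndarray
    threshold: float
    selected: tuple[int, ...]


def compute_vip(model: PLSModel, threshold: float = 1.0) -> VipResult:
    """Variable Importance in Projection for a fitted model.

    VIP_j = sqrt( p * sum_a SSY_a (w_ja / ||w_a||)^2 / sum_a SSY_a )
    with SSY_a = (t_a' t_a) ||q_a||^2, the Y sum of squares captured by
    component a (multi-response form). Satisfies sum_j VIP_j^2 = p.
    """
    p = model.W.shape[0]
    ssy = model.ssy_components
    total = float(ssy.sum())
    if total <= 0:
        raise DataError("model explains none of Y; VIP undefined")
    wnorm = model.W / np.linalg.norm(model.W, axis=0, keepdims=True)
    vip = np.sqrt(p * (wnorm**2 @ ssy) / total)
    selected = tuple(int(j) for j in np.flatnonzero(vip > threshold))
    return VipResult(scores=vip, threshold=threshold, selected=selected)


def select_n_lv(
    X: np.ndarray,
    labels,
    max_lv: int,
    *,
    pretreatment: str = "center",
) -> tuple[int, np.ndarray]:
    """Choose the latent-variable count by leave-one-out accuracy.

    Returns the smallest A achieving the maximum LOOCV accuracy
    (parsimony tie-break) together with the per-A accuracy curve.
    One model with ``max_lv`` components is fitted per left-out sample;
    truncated coefficient matrices give the predictions at every A.
    """
    X = np.asarray(X, dtype=float)
    labels = list(labels)
    n, p = X.shape
    if max_lv < 1:
        raise DataError("max_lv must be >= 1")
    cap = min(n - 2, p)
    if max_lv > cap:
        logger.warning("max_lv=%d capped at %d", max_lv, cap)
        max_lv = cap
    _, classes = encode_classes(labels)
    correct = np.zeros(max_lv)
    for i in range(n):
        keep = np.arange(n) != i
        model = fit_plsda(X[keep], [labels[j] for j in range(n) if keep[j]],
                          max_lv, pretreatment=pretreatment)
        for a in range(1, max_lv + 1):
            pred = model.predict(X[i: i + 1], n_lv=a)[0]
            if pred == labels[i]:
                correct[a - 1] += 1
    curve = correct / n
    best = float(curve.max())
    chosen = int(np.flatnonzero(curve == best)[0]) + 1
    return chosen, curve
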