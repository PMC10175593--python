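"""PCA-DA: linear discriminant analysis on principal-component scores.

The classifier projects the centered data onto its leading principal
components and applies Gaussian linear discriminant functions with a
pooled within-class covariance on that score space. Unlike PLS-DA with
an indicator threshold, every sample receives a class (no unclassified
outcome).

Univariate Wilks' lambda (within-group sum of squares over total sum of
squares; smaller = more discriminating) drives backward stepwise
variable elimination: the variable with the largest lambda is removed
while the cross-validated accuracy of the refit model does not drop.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .data_model import DataError
from .preprocessing import CenteringModel, apply_pretreatment, fit_pretreatment

logger = logging.getLogger(__name__)

DEFAULT_MAX_PC = 10


def wilks_lambda(values: np.ndarray, groups) -> float:
    """Univariate Wilks' lambda = SSW / SST for one variable.

    SSW is the within-group sum of squared deviations from the group
    means; SST the total sum of squared deviations from the grand mean.
    Always in [0, 1]; invariant to affine rescaling of the variable.
    """
    values = np.asarray(values, dtype=float).ravel()
    groups = np.asarray(groups)
    if values.shape[0] != groups.shape[0]:
        raise DataError("values and groups must have equal length")
    uniq = np.unique(groups)
    if uniq.size < 2:
        raise DataError("need at least 2 groups")
    sst = float(np.sum((values - values.mean()) ** 2))
    if sst <= 0:
        raise DataError("zero total variance; Wilks' lambda undefined")
    ssw = 0.0
    for g in uniq:
        v = values[groups == g]
        ssw += float(np.sum((v - v.mean()) ** 2))
    return ssw / sst


@dataclass
class DAModel:
    """PCA loadings plus linear discriminant functions on the scores."""

    n_pc: int
    loadings: np.ndarray            # (p, n_pc), orthonormal columns
    x_pretreatment: CenteringModel | None
    class_means: np.ndarray         # (g, n_pc) score-space centroids
    pooled_cov: np.ndarray          # (n_pc, n_pc)
    priors: np.ndarray              # (g,)
    classes: tuple[str, ...]
    accuracy_curve: np.ndarray | None = field(default=None)

    @property
    def n_vars(self) -> int:
        return self.loadings.shape[0]

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_vars:
            raise DataError(f"expected {self.n_vars} columns, got {X.shape[1]}")
        return apply_pretreatment(self.x_pretreatment, X) @ self.loadings

    def discriminant_scores(self, X: np.ndarray) -> np.ndarray:
        """delta_k(s) = s' S^-1 mu_k - mu_k' S^-1 mu_k / 2 + ln pi_k."""
        S = self.transform(X)
        inv_mu = np.linalg.solve(self.pooled_cov, self.class_means.T)  # (A, g)
        lin = S @ inv_mu
        const = -0.5 * np.einsum("ka,ak->k", self.class_means, inv_mu) + np.log(self.priors)
        return lin + const

    def predict(self, X: np.ndarray) -> list[str]:
        scores = self.discriminant_scores(X)
        out = []
        for row in scores:
            best = np.flatnonzero(row == row.max())
            if best.size > 1:
                logger.info("discriminant tie between %s; taking first",
                            [self.classes[j] for j in best])
            out.append(self.classes[best[0]])
        return out


def _class_order(labels) -> tuple[str, ...]:
    order: list[str] = []
    for lab in labels:
        if lab not in order:
            order.append(lab)
    return tuple(order)


def _lda_on_scores(S: np.ndarray, labels, classes) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Class centroids, pooled within-class covariance and priors."""
    labels = np.asarray(labels)
    n, A = S.shape
    g = len(classes)
    means = np.zeros((g, A))
    pooled = np.zeros((A, A))
    priors = np.zeros(g)
    for k, c in enumerate(classes):
        Sk = S[labels == c]
        if Sk.shape[0] == 0:
            raise DataError(f"class {c!r} absent from training data")
        means[k] = Sk.mean(axis=0)
        D = Sk - means[k]
        pooled += D.T @ D
        priors[k] = Sk.shape[0] / n
    dof = n - g
    if dof <= 0:
        raise DataError("need more samples than classes for pooled covariance")
    pooled /= dof
    # reject a numerically singular pooled scatter
    sign, logdet = np.linalg.slogdet(pooled)
    if sign <= 0 or not np.isfinite(logdet):
        raise DataError("singular pooled within-class scatter; reduce n_pc")
    return means, pooled, priors


def fit_pcada(
    X: np.ndarray,
    labels,
    n_pc: int | str = "auto",
    *,
    pretreatment: str = "center",
    max_pc: int = DEFAULT_MAX_PC,
) -> DAModel:
    """Fit PCA followed by LDA on the leading ``n_pc`` scores.

    ``n_pc="auto"`` picks the component count maximizing leave-one-out
    accuracy (smallest count on ties) up to ``max_pc`` and the
    admissible cap min(n - g - 1, rank(X)).
    """
    X = np.asarray(X, dtype=float)
    labels = list(labels)
    n, p = X.shape
    classes = _class_order(labels)
    g = len(classes)
    if g < 2:
        raise DataError("need at least 2 classes")

    xpre = fit_pretreatment(X, pretreatment)
    Xc = apply_pretreatment(xpre, X)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-10)) if s.size else 0
    cap = min(n - g - 1, rank)
    if cap < 1:
        raise DataError("not enough samples/rank for any principal component")

    curve = None
    if n_pc == "auto":
        cap = min(cap, max_pc)
        curve = _loocv_pc_curve(X, labels, classes, cap, pretreatment)
        n_pc = int(np.flatnonzero(curve == curve.max())[0]) + 1
    else:
        n_pc = int(n_pc)
        if not 1 <= n_pc <= cap:
            raise DataError(f"n_pc={n_pc} outside [1, {cap}] "
                            "(cap = min(n - g - 1, rank))")

    V = Vt[:n_pc].T
    S = Xc @ V
    means, pooled, priors = _lda_on_scores(S, labels, classes)
    return DAModel(
        n_pc=n_pc, loadings=V, x_pretreatment=xpre,
        class_means=means, pooled_cov=pooled, priors=priors,
        classes=classes, accuracy_curve=curve,
    )


def _loocv_pc_curve(X, labels, classes, max_pc, pretreatment) -> np.ndarray:
    """Leave-one-out accuracy for each candidate component count.

    One SVD per fold; LDA statistics for dimension k are the leading
    k x k submatrices of the full-score statistics, so every k shares
    the fold's decomposition.
    """
    n = X.shape[0]
    labels_arr = np.asarray(labels)
    correct = np.zeros(max_pc)
    for i in range(n):
        keep = np.arange(n) != i
        Xtr, ytr = X[keep], labels_arr[keep]
        xpre = fit_pretreatment(Xtr, pretreatment)
        Xc = apply_pretreatment(xpre, Xtr)
        _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        rank = int(np.sum(s > s[0] * 1e-10)) if s.size else 0
        kmax = min(max_pc, rank, Xtr.shape[0] - len(classes) - 1)
        if kmax < 1:
            continue
        V = Vt[:kmax].T
        Str = Xc @ V
        ste = (apply_pretreatment(xpre, X[i: i + 1]) @ V).ravel()
        try:
            means, pooled, priors = _lda_on_scores(Str, ytr, classes)
        except DataError:
            continue
        for k in range(1, kmax + 1):
            try:
                inv_mu = np.linalg.solve(pooled[:k, :k], means[:, :k].T)
            except np.linalg.LinAlgError:
                continue
            delta = ste[:k] @ inv_mu - 0.5 * np.einsum(
                "ka,ak->k", means[:, :k], inv_mu) + np.log(priors)
            if classes[int(np.argmax(delta))] == labels_arr[i]:
                correct[k - 1] += 1
    return correct / n


def predict_pcada(model: DAModel, X: np.ndarray) -> tuple[list[str], np.ndarray]:
    """Predicted class per row plus per-class discriminant scores."""
    return model.predict(X), model.discriminant_scores(X)


@dataclass(frozen=True)
class StepwiseConfig:
    """Settings for backward Wilks'-lambda elimination."""

    n_pc: int | str = "auto"
    max_pc: int = DEFAULT_MAX_PC
    pretreatment: str = "center"
    min_vars: int = 1


@dataclass
class LambdaTable:
    """Stepwise elimination record.

    ``lambdas`` holds the univariate Wilks' lambda of every variable on
    the full starting set; ``eliminated`` the committed removal order;
    ``accuracy_trace`` the LOOCV accuracy of the model before any
    removal and after each committed one.
    """

    var_names: tuple[str, ...]
    lambdas: np.ndarray
    eliminated: tuple[int, ...]
    accuracy_trace: tuple[float, ...]
    selected: tuple[int, ...]


def _loocv_accuracy(X, labels, cfg: StepwiseConfig) -> float:
    """LOOCV accuracy of PCA-DA under the config's component rule."""
    labels = list(labels)
    n = X.shape[0]
    if cfg.n_pc == "auto":
        # the auto search already computes the per-fold-refit accuracy curve
        model = fit_pcada(X, labels, "auto", pretreatment=cfg.pretreatment,
                          max_pc=cfg.max_pc)
        return float(model.accuracy_curve.max())
    n_pc = int(cfg.n_pc)
    good = 0
    for i in range(n):
        keep = np.arange(n) != i
        try:
            m = fit_pcada(X[keep], [labels[j] for j in range(n) if keep[j]],
                          min(n_pc, X.shape[1]), pretreatment=cfg.pretreatment,
                          max_pc=cfg.max_pc)
        except DataError:
            continue
        if m.predict(X[i: i + 1])[0] == labels[i]:
            good += 1
    return good / n


def stepwise_eliminate(
    X: np.ndarray,
    labels,
    config: StepwiseConfig | None = None,
    var_names=None,
) -> tuple[LambdaTable, tuple[int, ...]]:
    """Backward elimination by largest univariate Wilks' lambda.

    At each step the variable with the largest lambda among the
    remaining set is tentatively removed and the PCA-DA model refit;
    the removal is committed while the leave-one-out accuracy does not
    fall below the best seen so far, otherwise it is undone and the
    loop stops. Never returns an empty set.
    """
    cfg = config or StepwiseConfig()
    X = np.asarray(X, dtype=float)
    labels = list(labels)
    n, p = X.shape
    if p < 2:
        raise DataError("stepwise elimination needs at least 2 variables")
    names = tuple(var_names) if var_names is not None else tuple(str(j) for j in range(p))

    full_lambdas = np.array([wilks_lambda(X[:, j], labels) for j in range(p)])
    remaining = list(range(p))
    eliminated: list[int] = []
    best = _loocv_accuracy(X, labels, cfg)
    trace = [best]
    while len(remaining) > max(cfg.min_vars, 1):
        lams = np.array([wilks_lambda(X[:, j], labels) for j in remaining])
        candidate = remaining[int(np.argmax(lams))]
        trial = [j for j in remaining if j != candidate]
        acc = _loocv_accuracy(X[:, trial], labels, cfg)
        if acc < best:
            break
        best = max(best, acc)
        remaining = trial
        eliminated.append(candidate)
        trace.append(acc)
    table = LambdaTable(
        var_names=names,
        lambdas=full_lambdas,
        eliminated=tuple(eliminated),
        accuracy_trace=tuple(trace),
        selected=tuple(remaining),
    )
    return table, tuple(remaining)
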