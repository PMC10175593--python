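"""Competitive Adaptive Reweighted Sampling (CARS) for NIR wavelengths.

CARS runs N Monte-Carlo iterations. Each iteration fits a PLS model on
a random calibration subset of the samples restricted to the currently
retained wavelengths, ranks wavelengths by the magnitude of their
regression coefficients, keeps the top fraction prescribed by an
exponentially decreasing function (EDF, from 100% of the wavelengths
down to 2), and then resamples that retained set in proportion to the
coefficient weights (adaptive reweighted sampling, ARS). The subset
whose K-fold RMSECV over all samples is smallest wins.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .data_model import DataError
from .plsda import _nipals, encode_classes
from .preprocessing import apply_pretreatment, fit_pretreatment

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CarsConfig:
    """Monte-Carlo sampling settings.

    ``n_runs`` Monte-Carlo iterations; ``cv_folds``-fold RMSECV;
    ``calib_ratio`` of the samples drawn (without replacement) per run;
    inner PLS component count capped at ``max_lv`` and chosen once on
    the full data by RMSECV before the competition starts.
    """

    n_runs: int = 100
    cv_folds: int = 10
    calib_ratio: float = 0.8
    max_lv: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_runs < 2:
            raise DataError("n_runs must be >= 2")
        if not 0 < self.calib_ratio <= 1:
            raise DataError("calib_ratio must be in (0, 1]")
        if self.cv_folds < 2:
            raise DataError("cv_folds must be >= 2")


@dataclass
class CarsTrace:
    """Per-run record of one CARS competition."""

    ratios: np.ndarray                       # EDF retention ratio r_i
    retained_sets: list[np.ndarray]          # indices retained after run i
    rmsecv: np.ndarray                       # K-fold RMSECV after run i
    best_run: int                            # argmin RMSECV (0-based, first on ties)
    selected: tuple[int, ...]                # winning wavelength indices
    selected_names: tuple[str, ...]
    n_lv: int                                # inner PLS component count used

    @property
    def n_retained(self) -> np.ndarray:
        return np.array([s.size for s in self.retained_sets])


def edf_ratio(i: int, n_runs: int, p: int) -> float:
    """Fraction of wavelengths force-retained at run ``i`` (1-based).

    r_i = a e^(-k i) with a and k fixed so r_1 = 1 and r_N = 2/p: the
    first run keeps every wavelength, the last keeps two.
    """
    if p < 2:
        raise DataError("need at least 2 variables for the EDF schedule")
    if not 1 <= i <= n_runs:
        raise DataError(f"run index {i} outside [1, {n_runs}]")
    a = (p / 2) ** (1 / (n_runs - 1))
    k = math.log(p / 2) / (n_runs - 1)
    return a * math.exp(-k * i)


def _fit_pls_B(Xc: np.ndarray, Yc: np.ndarray, n_lv: int) -> np.ndarray:
    """Centered-data PLS regression coefficients (p x m).

    Falls back to fewer components if the X residual is exhausted
    (rank-deficient subsets drawn during the competition).
    """
    for a in range(n_lv, 0, -1):
        try:
            W, P, Q, _, _, _, _ = _nipals(Xc, Yc, a)
        except DataError:
            if a == 1:
                raise
            continue
        return W @ np.linalg.solve(P.T @ W, Q.T)
    raise DataError("PLS fit failed")


def _max_components(n: int, p: int, cap: int) -> int:
    return max(1, min(cap, n - 2, p))


def rmsecv(
    X: np.ndarray,
    Y: np.ndarray,
    n_lv: int,
    folds: int,
    seed: int | np.random.Generator = 0,
) -> float:
    """K-fold root mean squared error of cross-validation of a PLS model.

    Folds come from a seeded shuffle; centering of X and Y is refit on
    each training fold. For a multi-column Y the error is pooled over
    all response entries.
    """
    X = np.asarray(X, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] != X.shape[0]:
        Y = Y.T
    n = X.shape[0]
    if folds > n:
        raise DataError(f"folds={folds} exceeds n={n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    order = rng.permutation(n)
    assignments = np.empty(n, dtype=int)
    assignments[order] = np.arange(n) % folds
    sq_sum = 0.0
    for f in range(folds):
        test = assignments == f
        train = ~test
        if train.sum() < 2:
            raise DataError("fold leaves fewer than 2 training samples")
        xpre = fit_pretreatment(X[train], "center")
        Xc = apply_pretreatment(xpre, X[train])
        ym = Y[train].mean(axis=0)
        a = _max_components(train.sum(), X.shape[1], n_lv)
        B = _fit_pls_B(Xc, Y[train] - ym, a)
        pred = apply_pretreatment(xpre, X[test]) @ B + ym
        sq_sum += float(np.sum((pred - Y[test]) ** 2))
    return math.sqrt(sq_sum / Y.size)


def _choose_inner_lv(X, Y, cfg: CarsConfig, rng) -> int:
    """Pick the inner PLS component count once, by full-data RMSECV."""
    cap = _max_components(X.shape[0], X.shape[1], cfg.max_lv)
    errors = []
    for a in range(1, cap + 1):
        errors.append(rmsecv(X, Y, a, cfg.cv_folds,
                             np.random.default_rng(rng.integers(2**31))))
    return int(np.argmin(errors)) + 1


def cars_select(
    X: np.ndarray,
    labels,
    config: CarsConfig | None = None,
    var_names=None,
) -> CarsTrace:
    """Run the CARS competition and return its trace.

    ``labels`` are class tags; the regression response is their
    indicator coding, and a wavelength's weight is the row norm of its
    coefficients. The winning subset minimizes K-fold RMSECV computed
    on all samples restricted to the run's retained set (earliest run
    on ties).
    """
    cfg = config or CarsConfig()
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if p < 2:
        raise DataError("CARS needs at least 2 wavelengths")
    names = tuple(var_names) if var_names is not None else tuple(str(j) for j in range(p))
    Y, _ = encode_classes(labels)
    rng = np.random.default_rng(cfg.seed)
    n_lv = _choose_inner_lv(X, Y, cfg, rng)
    n_calib = max(2, math.ceil(cfg.calib_ratio * n))

    retained = np.arange(p)
    ratios = np.empty(cfg.n_runs)
    retained_sets: list[np.ndarray] = []
    errors = np.full(cfg.n_runs, np.inf)
    n_done = 0
    for i in range(1, cfg.n_runs + 1):
        r_i = edf_ratio(i, cfg.n_runs, p)
        ratios[i - 1] = r_i
        calib = rng.choice(n, size=n_calib, replace=False)
        Xi = X[np.ix_(calib, retained)]
        xpre = fit_pretreatment(Xi, "center")
        ym = Y[calib].mean(axis=0)
        a = _max_components(n_calib, retained.size, n_lv)
        try:
            B = _fit_pls_B(apply_pretreatment(xpre, Xi), Y[calib] - ym, a)
        except DataError:
            warnings.warn(f"PLS fit failed at run {i}; trace truncated", UserWarning)
            break
        weights = np.linalg.norm(np.atleast_2d(B), axis=1)
        total = weights.sum()
        if total <= 0:
            warnings.warn(f"all-zero coefficients at run {i}; trace truncated", UserWarning)
            break
        weights = weights / total
        n_keep = min(retained.size, max(2, round(r_i * p)))
        # forced retention: top-weight wavelengths survive outright
        top = np.argsort(weights)[::-1][:n_keep]
        forced = retained[top]
        fw = weights[top]
        # adaptive reweighted sampling among the survivors: p draws with
        # replacement, so low-weight wavelengths fade out gradually
        draws = rng.choice(forced, size=p, replace=True, p=fw / fw.sum())
        new_retained = np.unique(draws)
        if new_retained.size < 1:
            warnings.warn(f"retained set collapsed at run {i}; trace truncated", UserWarning)
            break
        retained = new_retained
        retained_sets.append(retained.copy())
        errors[i - 1] = rmsecv(X[:, retained], Y, n_lv, cfg.cv_folds,
                               np.random.default_rng(rng.integers(2**31)))
        n_done = i
    if n_done == 0:
        raise DataError("CARS produced no completed runs")
    ratios = ratios[:n_done]
    errors = errors[:n_done]
    best = int(np.argmin(errors))
    selected = tuple(int(j) for j in retained_sets[best])
    return CarsTrace(
        ratios=ratios,
        retained_sets=retained_sets,
        rmsecv=errors,
        best_run=best,
        selected=selected,
        selected_names=tuple(names[j] for j in selected),
        n_lv=n_lv,
    )
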