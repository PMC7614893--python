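"""Elastic-net penalized logistic regression with cross-validated tuning.

Fits minimize the penalized average negative log-likelihood

    (1/n) sum_i log(1 + exp(-s_i * eta_i))  +  lambda * [ alpha * ||b||_1
                                                + (1 - alpha)/2 * ||b||_2^2 ]

with an unpenalized intercept, over columns standardized internally to
zero mean and unit variance; reported coefficients are transformed back
to the original column scale.  ``alpha`` is the elastic-net mixing
parameter (1 = lasso).  The solver is the standard iteratively
reweighted least squares outer loop with cyclic coordinate descent on
the weighted working response, warm-started along a descending lambda
path, which yields exact zeros and makes the full-shrinkage limit exact:
at ``lambda >= lambda_max`` every coefficient is identically zero and
the intercept equals the log-odds of ``mean(y)``.

Tuning (`tune_lambda`) selects lambda on a log-spaced path from
``lambda_max`` downward by minimizing mean inner-CV binomial deviance
(the "min" rule; a one-standard-error rule is available), with folds
stratified by outcome.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .data_model import ValidationError

__all__ = [
    "PenalizedFit",
    "fit_penalized_logistic",
    "fit_path",
    "lambda_max",
    "lambda_grid",
    "tune_lambda",
    "tune_penalty",
    "binomial_deviance",
]

_P_CLIP = 1e-9
_W_FLOOR = 1e-9


@dataclass(frozen=True)
class PenalizedFit:
    """One penalized logistic fit, reported on the original column scale."""

    intercept: float
    coef: np.ndarray
    lambda_: float
    alpha: float

    @property
    def nonzero(self) -> np.ndarray:
        """Selection indicator: exact non-zeros of the standardized fit."""
        return self.coef != 0.0

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return self.intercept + np.asarray(X, dtype=float) @ self.coef

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.decision_function(X)))


def _validate_xy(X, y) -> tuple[np.ndarray, np.ndarray]:
    X = np.ascontiguousarray(np.asarray(X, dtype=np.float64))
    y = np.asarray(y, dtype=np.float64).ravel()
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValidationError("X and y are misaligned")
    if not np.all(np.isfinite(X)):
        raise ValidationError("X contains non-finite values")
    classes = np.unique(y)
    if not np.isin(classes, (0.0, 1.0)).all():
        raise ValidationError("y must be binary 0/1")
    if classes.size < 2:
        raise ValidationError("degenerate outcome: y has a single class")
    return X, y


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    free = sd > 0  # constant columns carry no information; coef pinned at 0
    sd_safe = np.where(free, sd, 1.0)
    return (X - mean) / sd_safe, mean, sd_safe, free


def lambda_max(X, y, alpha: float = 1.0) -> float:
    """Smallest lambda at which the lasso/elastic-net solution is all-zero."""
    if not 0 < alpha <= 1:
        raise ValidationError("alpha must be in (0, 1]")
    X, y = _validate_xy(X, y)
    Xs, _, _, free = _standardize(X)
    n = len(y)
    score = np.abs(Xs[:, free].T @ (y - y.mean())) / n
    return float(score.max() / alpha) if score.size else 0.0


def lambda_grid(
    lmax: float, n_lambdas: int = 20, min_ratio: float = 1e-3
) -> np.ndarray:
    """Log-spaced descending path from lambda_max."""
    return np.geomspace(lmax, lmax * min_ratio, n_lambdas)


def _path_std(
    Xs: np.ndarray,
    y: np.ndarray,
    lambdas: Sequence[float],
    alpha: float,
    free: np.ndarray,
    tol: float = 1e-7,
    max_outer: int = 100,
    max_sweeps: int = 200,
    dev_stop_ratio: float = 0.999,
) -> list[tuple[float, np.ndarray]]:
    """Warm-started IRLS/CD path on standardized columns.

    Following common practice for regularization paths, a multi-lambda
    path stops early once the fit explains ``dev_stop_ratio`` of the
    null deviance (the remaining, effectively unpenalized tail is a
    quasi-separated regime whose optimum diverges); the last computed
    solution is carried forward for the remaining lambdas.  Single-
    lambda requests are always solved at their lambda.
    """
    n, p = Xs.shape
    ybar = y.mean()
    b0 = float(np.log(ybar / (1.0 - ybar)))
    beta = np.zeros(p)
    eta = np.full(n, b0)
    free_idx = np.flatnonzero(free)
    null_dev = binomial_deviance(y, np.full(n, ybar))
    out = []
    for i_lam, lam in enumerate(lambdas):
        l1 = lam * alpha
        l2 = lam * (1.0 - alpha)
        for _ in range(max_outer):
            pr = 1.0 / (1.0 + np.exp(-eta))
            np.clip(pr, _P_CLIP, 1.0 - _P_CLIP, out=pr)
            w = np.maximum(pr * (1.0 - pr), _W_FLOOR)
            r = (y - pr) / w  # working residual: z - eta
            WX = np.multiply(Xs, w[:, None], order="F")
            d = np.einsum("ij,ij->j", WX, Xs) / n
            wsum = w.sum()
            b0_prev, beta_prev = b0, beta.copy()

            def _sweep(idx) -> float:
                nonlocal b0, r
                delta_max = 0.0
                d0 = float(w @ r) / wsum
                if d0 != 0.0:
                    b0 += d0
                    r -= d0
                    delta_max = abs(d0)
                for j in idx:
                    bj = beta[j]
                    rho = float(WX[:, j] @ r) / n + d[j] * bj
                    if rho > l1:
                        bj_new = (rho - l1) / (d[j] + l2)
                    elif rho < -l1:
                        bj_new = (rho + l1) / (d[j] + l2)
                    else:
                        bj_new = 0.0
                    step = bj_new - bj
                    if step != 0.0:
                        r -= Xs[:, j] * step
                        beta[j] = bj_new
                        delta_max = max(delta_max, abs(step))
                return delta_max

            sweeps = 0
            while sweeps < max_sweeps:
                delta_max = _sweep(free_idx)  # full sweep (KKT over all)
                sweeps += 1
                if delta_max < tol:
                    break
                active = free_idx[beta[free_idx] != 0.0]
                while sweeps < max_sweeps:  # iterate the active set only
                    sweeps += 1
                    if _sweep(active) < tol:
                        break
            eta = b0 + Xs @ beta
            if max(abs(b0 - b0_prev), float(np.abs(beta - beta_prev).max())) < tol:
                break
        out.append((b0, beta.copy()))
        if len(lambdas) > 1 and i_lam < len(lambdas) - 1:
            dev = binomial_deviance(y, 1.0 / (1.0 + np.exp(-eta)))
            saturated = 1.0 - dev / null_dev > dev_stop_ratio
            stalled = i_lam > 0 and (prev_dev - dev) < 1e-5 * null_dev
            if saturated or stalled:
                out.extend((b0, beta.copy()) for _ in lambdas[i_lam + 1 :])
                break
            prev_dev = dev
    return out


def fit_path(
    X,
    y,
    lambdas: Sequence[float],
    alpha: float = 1.0,
    tol: float = 1e-7,
) -> list[PenalizedFit]:
    """Fit the full descending-lambda path (standardizing internally)."""
    if not 0 <= alpha <= 1:
        raise ValidationError("alpha must be in [0, 1]")
    X, y = _validate_xy(X, y)
    lambdas = np.asarray(lambdas, dtype=float)
    if np.any(lambdas < 0):
        raise ValidationError("lambda must be >= 0")
    if np.any(np.diff(lambdas) > 0):
        raise ValidationError("lambda path must be non-increasing")
    Xs, mean, sd, free = _standardize(X)
    Xs = np.asfortranarray(Xs)  # contiguous columns for the CD sweeps
    fits = []
    for lam, (b0_std, beta_std) in zip(
        lambdas, _path_std(Xs, y, lambdas, alpha, free, tol=tol)
    ):
        coef = beta_std / sd
        intercept = b0_std - float(mean @ coef)
        fits.append(
            PenalizedFit(intercept=intercept, coef=coef, lambda_=float(lam), alpha=alpha)
        )
    return fits


def fit_penalized_logistic(
    X, y, alpha: float = 1.0, lam: float = 0.0, tol: float = 1e-9
) -> PenalizedFit:
    """Single penalized fit at (alpha, lambda).

    ``lam = 0`` gives the unpenalized maximum-likelihood fit (assuming it
    exists; separation makes the unpenalized optimum diverge).
    """
    return fit_path(X, y, [lam], alpha=alpha, tol=tol)[-1]


def binomial_deviance(y: np.ndarray, probs: np.ndarray) -> float:
    """Mean binomial deviance, -2 * mean log-likelihood."""
    p = np.clip(np.asarray(probs, dtype=float), _P_CLIP, 1.0 - _P_CLIP)
    y = np.asarray(y, dtype=float)
    return float(-2.0 * np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def _stratified_folds(y: np.ndarray, n_folds: int, seed: int):
    """Stratified fold index pairs; refolds to fewer folds when a class is
    too small, errors when stratification is impossible."""
    counts = np.bincount(y.astype(int), minlength=2)
    min_class = int(counts.min())
    if min_class < 2:
        raise ValidationError(
            f"cannot stratify: minority class has {min_class} sample(s)"
        )
    folds = min(n_folds, min_class)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros_like(y), y))


def _cv_deviance(
    X: np.ndarray,
    y: np.ndarray,
    lambdas: np.ndarray,
    alpha: float,
    splits,
    tol: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean and SE (over folds) of validation deviance along the path."""
    devs = np.empty((len(splits), len(lambdas)))
    for k, (tr, va) in enumerate(splits):
        fits = fit_path(X[tr], y[tr], lambdas, alpha=alpha, tol=tol)
        for i, fit in enumerate(fits):
            devs[k, i] = binomial_deviance(y[va], fit.predict_proba(X[va]))
    mean = devs.mean(axis=0)
    se = devs.std(axis=0, ddof=1) / np.sqrt(len(splits))
    return mean, se


def tune_lambda(
    X,
    y,
    alpha: float = 1.0,
    inner_folds: int = 10,
    seed: int = 0,
    rule: str = "min",
    n_lambdas: int = 20,
    lambda_min_ratio: float = 1e-3,
    tol: float = 1e-6,
) -> float:
    """Select lambda by stratified inner cross-validation.

    ``rule="min"`` takes the deviance-minimizing lambda; ``rule="1se"``
    the largest lambda within one standard error of the minimum.
    Deterministic given ``seed``.
    """
    lam, _alpha = tune_penalty(
        X,
        y,
        alphas=(alpha,),
        inner_folds=inner_folds,
        seed=seed,
        rule=rule,
        n_lambdas=n_lambdas,
        lambda_min_ratio=lambda_min_ratio,
        tol=tol,
    )
    return lam


def tune_penalty(
    X,
    y,
    alphas: Sequence[float] = (1.0,),
    inner_folds: int = 10,
    seed: int = 0,
    rule: str = "min",
    n_lambdas: int = 20,
    lambda_min_ratio: float = 1e-3,
    tol: float = 1e-6,
) -> tuple[float, float]:
    """Jointly select (lambda, alpha) by inner-CV mean binomial deviance."""
    if rule not in ("min", "1se"):
        raise ValidationError(f"unknown lambda rule {rule!r}")
    X, y = _validate_xy(X, y)
    splits = _stratified_folds(y, inner_folds, seed)
    best: Optional[tuple[float, float, float]] = None  # (dev, lam, alpha)
    for alpha in alphas:
        lambdas = lambda_grid(lambda_max(X, y, alpha), n_lambdas, lambda_min_ratio)
        mean, se = _cv_deviance(X, y, lambdas, alpha, splits, tol)
        i_min = int(np.argmin(mean))
        if rule == "1se":
            threshold = mean[i_min] + se[i_min]
            i_sel = int(np.flatnonzero(mean <= threshold)[0])  # largest lambda
        else:
            i_sel = i_min
        cand = (float(mean[i_sel]), float(lambdas[i_sel]), float(alpha))
        if best is None or cand[0] < best[0]:
            best = cand
    assert best is not None
    return best[1], best[2]
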