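"""Stability selection by repeated cross-validated penalized logistic fits.

The model-building procedure: repeat an outcome-stratified K-fold split R
times (default 300 x 10 = 3000 models).  Within each split, every fold in
turn is held out; the penalty weight (and, for the elastic net, the
mixing parameter) is tuned by inner cross-validation on the remaining
K-1 folds, a penalized logistic model is fitted there, its non-zero
coefficient set is logged, and predicted probabilities are produced for
the held-out fold.  Per-sample out-of-fold probabilities are averaged
over the R replications and summarized by ROC AUC (Mann-Whitney
concordance).  Predictors are ranked by selection frequency — the
fraction of the R*K models with a non-zero coefficient — and those
selected in strictly more than half of the models are taken forward to
univariate logistic odds ratios; a random forest over the chosen set
serves as a check for interactions and non-linearity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import rankdata
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.model_selection import KFold, StratifiedKFold

from .data_model import ValidationError
from .penalized import (
    fit_path,
    lambda_grid,
    lambda_max,
    tune_penalty,
)

__all__ = [
    "StabilityConfig",
    "SelectionResult",
    "ORResult",
    "RFCheckResult",
    "StabilitySelector",
    "repeated_cv",
    "compute_auc",
    "choose_predictors",
    "univariate_or",
    "rf_check",
]

_WALD_Z = 1.96  # 95% Wald interval multiplier
_SEPARATION_SE = 50.0  # Wald SE beyond which the estimate is treated as divergent

DEFAULT_ALPHA_GRID = (0.1, 0.3, 0.5, 0.7, 0.9, 1.0)


@dataclass(frozen=True)
class StabilityConfig:
    """Settings of the repeated-CV selection procedure.

    ``n_repeats * n_folds`` is the total number of fitted models (the
    reference analysis uses 300 x 10 = 3000).  ``selection_threshold`` is
    the strict selection-frequency cut-off (default one half).
    """

    n_repeats: int = 300
    n_folds: int = 10
    penalty: str = "lasso"  # "lasso" | "elastic_net"
    alpha_grid: tuple[float, ...] = DEFAULT_ALPHA_GRID
    inner_folds: int = 10
    selection_threshold: float = 0.5
    seed: int = 0
    lambda_rule: str = "min"  # "min" | "1se"
    n_lambdas: int = 20
    lambda_min_ratio: float = 1e-3
    stratified: bool = True
    tol: float = 1e-6  # convergence of the logged per-fold fits
    tune_tol: float = 1e-4  # convergence of inner-CV path fits (deviance only)

    def __post_init__(self):
        if self.n_repeats < 1 or self.n_folds < 2 or self.inner_folds < 2:
            raise ValidationError("need n_repeats >= 1 and folds >= 2")
        if self.penalty not in ("lasso", "elastic_net"):
            raise ValidationError(f"unknown penalty {self.penalty!r}")
        if not 0 < self.selection_threshold < 1:
            raise ValidationError("selection_threshold must lie in (0, 1)")
        if not all(0 < a <= 1 for a in self.alpha_grid):
            raise ValidationError("alpha grid values must lie in (0, 1]")

    @property
    def n_models(self) -> int:
        return self.n_repeats * self.n_folds


@dataclass
class SelectionResult:
    """Output of :func:`repeated_cv`.

    ``frequencies`` are exact rationals ``selection count / (R*K)``;
    ``per_model_log`` has one row per fitted model and reconstructs them.
    """

    frequencies: pd.Series
    selection_counts: pd.Series
    averaged_oof_probs: np.ndarray
    auc: float
    chosen: list[str]
    per_model_log: pd.DataFrame
    config: StabilityConfig


@dataclass(frozen=True)
class ORResult:
    """Univariate logistic odds ratio with a 95% Wald interval."""

    predictor: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    n_used: int
    separated: bool = False


@dataclass
class RFCheckResult:
    oof_auc: float
    importance: dict[str, float]


def compute_auc(scores, labels) -> float:
    """ROC AUC as the Mann-Whitney concordance P(case > control) + P(tie)/2.

    Computed from midranks, hence exactly the all-pairs concordance count
    (ties credited one half) divided by ``n_case * n_control``.
    """
    s = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(labels).ravel().astype(int)
    if s.shape != y.shape:
        raise ValidationError("scores and labels are misaligned")
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValidationError("AUC needs both classes present")
    ranks = rankdata(s)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def choose_predictors(result: SelectionResult, threshold: Optional[float] = None) -> list[str]:
    """Predictors selected in strictly more than ``threshold`` of the models,
    sorted by descending frequency (ties broken by name)."""
    if threshold is None:
        threshold = result.config.selection_threshold
    freq = result.frequencies
    picked = freq[freq > threshold]
    return sorted(picked.index, key=lambda name: (-picked[name], name))


def _column_names(X) -> list[str]:
    if isinstance(X, pd.DataFrame):
        return [str(c) for c in X.columns]
    return [f"x{j}" for j in range(np.asarray(X).shape[1])]


def _outer_splitter(stratified: bool, n_folds: int, seed: int):
    if stratified:
        return StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return KFold(n_splits=n_folds, shuffle=True, random_state=seed)


def repeated_cv(X, y, config: StabilityConfig) -> SelectionResult:
    """Run the full repeated cross-validated selection procedure.

    Deterministic given ``config.seed``: all fold draws and inner-CV
    seeds derive from it.  Errors in inner fits propagate annotated with
    their (replicate, fold) context.
    """
    names = _column_names(X)
    Xa = np.asarray(X, dtype=float)
    ya = np.asarray(y).ravel().astype(int)
    if Xa.shape[0] != ya.shape[0]:
        raise ValidationError("X and y are misaligned")
    n, p = Xa.shape

    alphas: Sequence[float] = (
        (1.0,) if config.penalty == "lasso" else config.alpha_grid
    )
    seed_rng = np.random.default_rng(config.seed)
    seeds = seed_rng.integers(0, 2**31 - 1, size=(config.n_repeats, config.n_folds + 1))

    counts = np.zeros(p, dtype=int)
    prob_sum = np.zeros(n)
    log_rows = []
    for r in range(config.n_repeats):
        splitter = _outer_splitter(
            config.stratified, config.n_folds, int(seeds[r, -1])
        )
        for k, (tr, va) in enumerate(splitter.split(Xa, ya)):
            try:
                lam, alpha = tune_penalty(
                    Xa[tr],
                    ya[tr],
                    alphas=alphas,
                    inner_folds=config.inner_folds,
                    seed=int(seeds[r, k]),
                    rule=config.lambda_rule,
                    n_lambdas=config.n_lambdas,
                    lambda_min_ratio=config.lambda_min_ratio,
                    tol=config.tune_tol,
                )
                grid = lambda_grid(
                    lambda_max(Xa[tr], ya[tr], alpha),
                    config.n_lambdas,
                    config.lambda_min_ratio,
                )
                path = grid[grid >= lam * (1.0 - 1e-12)]
                fit = fit_path(Xa[tr], ya[tr], path, alpha=alpha, tol=config.tol)[-1]
            except ValidationError as exc:
                raise ValidationError(
                    f"replicate {r}, fold {k}: {exc}"
                ) from exc
            nonzero = fit.nonzero
            counts += nonzero
            prob_sum[va] += fit.predict_proba(Xa[va])
            log_rows.append(
                {
                    "replicate": r,
                    "fold": k,
                    "lambda": fit.lambda_,
                    "alpha": alpha,
                    "n_selected": int(nonzero.sum()),
                    "selected": ";".join(
                        name for name, nz in zip(names, nonzero) if nz
                    ),
                }
            )

    index = pd.Index(names, name="predictor")
    frequencies = pd.Series(counts / config.n_models, index=index, name="frequency")
    selection_counts = pd.Series(counts, index=index, name="count")
    averaged = prob_sum / config.n_repeats
    result = SelectionResult(
        frequencies=frequencies,
        selection_counts=selection_counts,
        averaged_oof_probs=averaged,
        auc=compute_auc(averaged, ya),
        chosen=[],
        per_model_log=pd.DataFrame(log_rows),
        config=config,
    )
    result.chosen = choose_predictors(result)
    return result


def univariate_or(column, y, name: str = "predictor") -> ORResult:
    """Single-predictor logistic odds ratio with a 95% Wald interval.

    For a binary predictor this equals the 2x2 cross-product ratio.
    Complete or quasi-complete separation (divergent estimate) yields a
    flagged result with an unbounded interval instead of an exception.
    """
    x = np.asarray(column, dtype=float).ravel()
    yb = np.asarray(y).ravel().astype(float)
    if x.shape != yb.shape:
        raise ValidationError("column and y are misaligned")
    if np.all(x == x[0]):
        raise ValidationError("constant predictor has no odds ratio")
    design = sm.add_constant(x)
    separated = False
    try:
        with warnings.catch_warnings():
            # separation manifests as convergence/overflow warnings; we
            # detect and flag it from the estimates instead
            warnings.simplefilter("ignore")
            res = sm.Logit(yb, design).fit(disp=0, maxiter=200)
        b, se = float(res.params[1]), float(res.bse[1])
        if not (np.isfinite(b) and np.isfinite(se)) or se > _SEPARATION_SE:
            separated = True
    except Exception:
        separated = True
        b = np.nan
    if separated:
        direction = np.sign(np.corrcoef(x, yb)[0, 1]) if np.isnan(b) else np.sign(b)
        return ORResult(
            predictor=name,
            odds_ratio=float("inf") if direction >= 0 else 0.0,
            ci_low=0.0,
            ci_high=float("inf"),
            n_used=len(yb),
            separated=True,
        )
    return ORResult(
        predictor=name,
        odds_ratio=float(np.exp(b)),
        ci_low=float(np.exp(b - _WALD_Z * se)),
        ci_high=float(np.exp(b + _WALD_Z * se)),
        n_used=len(yb),
    )


def rf_check(
    X_chosen,
    y,
    n_folds: int = 10,
    seed: int = 0,
    n_trees: int = 500,
    stratified: bool = True,
) -> RFCheckResult:
    """Random-forest check for interactions/non-linearity among chosen
    predictors: out-of-fold AUC under the same K-fold scheme, plus
    permutation importances from a full-data fit."""
    names = _column_names(X_chosen)
    Xa = np.asarray(X_chosen, dtype=float)
    ya = np.asarray(y).ravel().astype(int)
    if Xa.shape[1] == 0:
        raise ValidationError("chosen predictor set is empty")
    seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=3)
    oof = np.zeros(len(ya))
    splitter = _outer_splitter(stratified, n_folds, int(seeds[0]))
    for tr, va in splitter.split(Xa, ya):
        clf = RandomForestClassifier(
            n_estimators=n_trees, max_features="sqrt", random_state=int(seeds[1])
        ).fit(Xa[tr], ya[tr])
        oof[va] = clf.predict_proba(Xa[va])[:, 1]
    full = RandomForestClassifier(
        n_estimators=n_trees, max_features="sqrt", random_state=int(seeds[1])
    ).fit(Xa, ya)
    imp = permutation_importance(
        full, Xa, ya, scoring="roc_auc", n_repeats=10, random_state=int(seeds[2])
    )
    return RFCheckResult(
        oof_auc=compute_auc(oof, ya),
        importance=dict(zip(names, imp.importances_mean.astype(float))),
    )


class StabilitySelector(BaseEstimator):
    """Scikit-learn style estimator wrapping :func:`repeated_cv`.

    ``fit`` exposes the stability-selection outputs as fitted attributes
    (``frequencies_``, ``auc_``, ``chosen_``, ``oof_probs_``, ...);
    ``transform`` reduces a matrix to the chosen predictors, so the
    selector composes with sklearn pipelines.
    """

    def __init__(
        self,
        n_repeats: int = 300,
        n_folds: int = 10,
        penalty: str = "lasso",
        alpha_grid: tuple[float, ...] = DEFAULT_ALPHA_GRID,
        inner_folds: int = 10,
        selection_threshold: float = 0.5,
        lambda_rule: str = "min",
        n_lambdas: int = 20,
        lambda_min_ratio: float = 1e-3,
        stratified: bool = True,
        tol: float = 1e-6,
        tune_tol: float = 1e-4,
        random_state: int = 0,
    ):
        self.n_repeats = n_repeats
        self.n_folds = n_folds
        self.penalty = penalty
        self.alpha_grid = alpha_grid
        self.inner_folds = inner_folds
        self.selection_threshold = selection_threshold
        self.lambda_rule = lambda_rule
        self.n_lambdas = n_lambdas
        self.lambda_min_ratio = lambda_min_ratio
        self.stratified = stratified
        self.tol = tol
        self.tune_tol = tune_tol
        self.random_state = random_state

    def _config(self) -> StabilityConfig:
        return StabilityConfig(
            n_repeats=self.n_repeats,
            n_folds=self.n_folds,
            penalty=self.penalty,
            alpha_grid=tuple(self.alpha_grid),
            inner_folds=self.inner_folds,
            selection_threshold=self.selection_threshold,
            seed=self.random_state,
            lambda_rule=self.lambda_rule,
            n_lambdas=self.n_lambdas,
            lambda_min_ratio=self.lambda_min_ratio,
            stratified=self.stratified,
            tol=self.tol,
            tune_tol=self.tune_tol,
        )

    def fit(self, X, y):
        result = repeated_cv(X, y, self._config())
        self.result_ = result
        self.feature_names_in_ = np.asarray(_column_names(X), dtype=object)
        self.n_features_in_ = len(self.feature_names_in_)
        self.frequencies_ = result.frequencies
        self.selection_counts_ = result.selection_counts
        self.oof_probs_ = result.averaged_oof_probs
        self.auc_ = result.auc
        self.chosen_ = result.chosen
        self.support_ = np.isin(self.feature_names_in_, result.chosen)
        return self

    def get_support(self) -> np.ndarray:
        return self.support_

    def transform(self, X):
        if isinstance(X, pd.DataFrame):
            return X.loc[:, [c for c in X.columns if c in self.chosen_]]
        return np.asarray(X)[:, self.support_]

    def fit_transform(self, X, y):
        return self.fit(X, y).transform(X)
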