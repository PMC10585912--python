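"""Conditional-model wrappers used by the plasmode generators.

Each wrapper holds one fitted conditional law — the distribution of a
single generated variable given its time-admissible predictors — and
knows how to (a) evaluate its mean / class probabilities on a partial
data frame and (b) draw new values from the law with a NumPy Generator.

Parametric laws store coefficient vectors aligned with the design built
by :func:`longplasmode.design.design_matrix`, so a generator set can also
be constructed directly from known coefficients (used for closed-form
oracles).  Random-forest laws wrap scikit-learn forests; regression
forests carry a pool of out-of-bag residuals that supplies the noise
when generating.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from .design import design_matrix
from .errors import DegenerateModelError, FittingError


def _categorical_draw(proba: np.ndarray, levels: Sequence, rng) -> np.ndarray:
    """One categorical draw per row from an (n, J) probability matrix."""
    cum = np.cumsum(proba, axis=1)
    # guard against rounding: force the last cumulative to 1
    cum[:, -1] = 1.0
    u = rng.random(len(proba))
    idx = (u[:, None] > cum).sum(axis=1)
    return np.asarray(levels)[idx]


@dataclass
class LinearCM:
    """Gaussian conditional: mean = X beta, noise ~ N(0, sd^2)."""

    cols: tuple
    beta: np.ndarray
    sd: float
    levels: Mapping = field(default_factory=dict)
    names: tuple = ()

    def _X(self, df):
        X, _ = design_matrix(df, self.cols, self.levels)
        return X

    def mean(self, df) -> np.ndarray:
        return self._X(df) @ self.beta

    def draw(self, df, rng) -> np.ndarray:
        mu = self.mean(df)
        return mu + rng.normal(0.0, self.sd, size=len(mu))


@dataclass
class LogisticCM:
    """Bernoulli conditional: P(1) = expit(X beta)."""

    cols: tuple
    beta: np.ndarray
    levels: Mapping = field(default_factory=dict)
    names: tuple = ()

    def _X(self, df):
        X, _ = design_matrix(df, self.cols, self.levels)
        return X

    def proba(self, df) -> np.ndarray:
        return expit(self._X(df) @ self.beta)

    def draw(self, df, rng) -> np.ndarray:
        p = self.proba(df)
        return (rng.random(len(p)) < p).astype(np.int64)


@dataclass
class MultinomialCM:
    """Categorical conditional via baseline-category logits.

    ``beta`` has shape (J-1, p); class probabilities are the softmax of
    (0, X beta_1, ..., X beta_{J-1}) over the frozen ``target_levels``
    (first level = reference).
    """

    cols: tuple
    beta: np.ndarray
    target_levels: tuple
    levels: Mapping = field(default_factory=dict)
    names: tuple = ()

    def proba(self, df) -> np.ndarray:
        X, _ = design_matrix(df, self.cols, self.levels)
        eta = X @ self.beta.T  # (n, J-1)
        eta = np.column_stack([np.zeros(len(X)), eta])
        eta -= eta.max(axis=1, keepdims=True)
        p = np.exp(eta)
        return p / p.sum(axis=1, keepdims=True)

    def draw(self, df, rng) -> np.ndarray:
        return _categorical_draw(self.proba(df), self.target_levels, rng)


@dataclass
class ConstantCM:
    """Degenerate conditional: the target was constant in the input."""

    value: float

    def draw(self, df, rng) -> np.ndarray:
        return np.full(len(df), self.value)

    def mean(self, df) -> np.ndarray:
        return np.full(len(df), float(self.value))


@dataclass
class RFRegressionCM:
    """Regression-forest conditional: prediction + out-of-bag residual.

    The generated law is the forest's point prediction plus one draw
    (uniform with replacement) from the stored pool of out-of-bag
    residuals, which makes the conditional noise distribution explicit
    and reusable by the counterfactual pass.
    """

    cols: tuple
    forest: RandomForestRegressor
    residual_pool: np.ndarray
    levels: Mapping = field(default_factory=dict)

    def mean(self, df) -> np.ndarray:
        X, _ = design_matrix(df, self.cols, self.levels, intercept=False)
        return self.forest.predict(X)

    def draw(self, df, rng) -> np.ndarray:
        mu = self.mean(df)
        res = rng.choice(self.residual_pool, size=len(mu), replace=True)
        return mu + res


@dataclass
class RFClassifierCM:
    """Classification-forest conditional: categorical draw from predicted
    class probabilities."""

    cols: tuple
    forest: RandomForestClassifier
    target_levels: tuple
    levels: Mapping = field(default_factory=dict)

    def proba(self, df) -> np.ndarray:
        X, _ = design_matrix(df, self.cols, self.levels, intercept=False)
        raw = self.forest.predict_proba(X)
        # align forest classes to the frozen level order, zero-filling
        # levels the forest never saw
        out = np.zeros((len(X), len(self.target_levels)))
        for j, cls in enumerate(self.forest.classes_):
            out[:, self.target_levels.index(cls)] = raw[:, j]
        return out

    def draw(self, df, rng) -> np.ndarray:
        drawn = _categorical_draw(self.proba(df), self.target_levels, rng)
        if np.issubdtype(np.asarray(self.target_levels).dtype, np.integer):
            return drawn.astype(np.int64)
        return drawn


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def fit_linear(df, target, cols, levels, name=None) -> tuple:
    """OLS fit; residual SD uses denominator n - p. Returns (model, log)."""
    X, names = design_matrix(df, cols, levels)
    y = df[target].to_numpy(dtype=float)
    res = sm.OLS(y, X).fit()
    sd = float(np.sqrt(res.ssr / res.df_resid)) if res.df_resid > 0 else 0.0
    log = {
        "variable": name or target,
        "family": "gaussian",
        "converged": True,
        "n": len(y),
        "p": X.shape[1],
        "residual_sd": sd,
        "sd_denominator": f"n - p = {int(res.df_resid)}",
    }
    return (
        LinearCM(cols=tuple(cols), beta=np.asarray(res.params), sd=sd,
                 levels=dict(levels), names=tuple(names)),
        log,
    )


def fit_logistic(df, target, cols, levels, name=None) -> tuple:
    """Logistic fit via statsmodels; separation/non-convergence raise."""
    X, names = design_matrix(df, cols, levels)
    y = df[target].to_numpy(dtype=float)
    uniq = np.unique(y)
    if len(uniq) < 2:
        raise DegenerateModelError(
            f"binary target {name or target!r} is single-valued ({uniq[0]})"
        )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=RuntimeWarning)
            res = sm.Logit(y, X).fit(disp=0, maxiter=100)
    except Exception as exc:  # PerfectSeparationError, LinAlgError, ...
        raise FittingError(
            f"logistic model for {name or target!r} failed to fit: {exc}"
        ) from exc
    if not res.mle_retvals.get("converged", False):
        raise FittingError(
            f"logistic model for {name or target!r} did not converge"
        )
    log = {
        "variable": name or target,
        "family": "binomial",
        "converged": True,
        "n": len(y),
        "p": X.shape[1],
    }
    return (
        LogisticCM(cols=tuple(cols), beta=np.asarray(res.params),
                   levels=dict(levels), names=tuple(names)),
        log,
    )


def fit_multinomial(df, target, cols, levels, target_levels, name=None) -> tuple:
    """Baseline-category multinomial logit via statsmodels MNLogit."""
    X, names = design_matrix(df, cols, levels)
    target_levels = list(target_levels)
    codes = pd.Categorical(
        df[target], categories=target_levels, ordered=False
    ).codes
    if (codes < 0).any():
        raise FittingError(
            f"multinomial target {name or target!r} has values outside its "
            f"frozen level set {target_levels}"
        )
    observed = np.unique(codes)
    if len(observed) < 2:
        raise DegenerateModelError(
            f"multinomial target {name or target!r} is single-valued"
        )
    try:
        res = sm.MNLogit(codes, X).fit(disp=0, maxiter=200, method="newton")
    except Exception as exc:
        raise FittingError(
            f"multinomial model for {name or target!r} failed to fit: {exc}"
        ) from exc
    if not res.mle_retvals.get("converged", False):
        raise FittingError(
            f"multinomial model for {name or target!r} did not converge"
        )
    # res.params has shape (p, J-1); our convention is (J-1, p).
    beta_fit = np.asarray(res.params).T
    # MNLogit drops unobserved categories: re-insert all-(-inf) rows would
    # be wrong; instead require all frozen levels observed at fit time.
    if len(observed) != len(target_levels):
        missing = [target_levels[c] for c in range(len(target_levels))
                   if c not in observed]
        raise DegenerateModelError(
            f"multinomial target {name or target!r}: levels {missing} "
            "unobserved in the fitting data"
        )
    log = {
        "variable": name or target,
        "family": "multinomial",
        "converged": True,
        "n": len(codes),
        "p": X.shape[1],
        "levels": target_levels,
    }
    return (
        MultinomialCM(cols=tuple(cols), beta=beta_fit,
                      target_levels=tuple(target_levels),
                      levels=dict(levels), names=tuple(names)),
        log,
    )


DEFAULT_RF_PARAMS = {
    "n_estimators": 500,
    "min_samples_leaf": 5,
}


def fit_rf_classifier(
    df, target, cols, levels, target_levels, rf_params=None, seed=None,
    name=None, allow_constant=False,
) -> tuple:
    """Classification forest (max_features = sqrt); constant targets raise
    unless *allow_constant*, in which case a degenerate law is stored."""
    X, _ = design_matrix(df, cols, levels, intercept=False)
    y = df[target].to_numpy()
    uniq = np.unique(y)
    if len(uniq) < 2:
        if not allow_constant:
            raise DegenerateModelError(
                f"forest target {name or target!r} is single-valued ({uniq[0]})"
            )
        return ConstantCM(value=uniq[0]), {
            "variable": name or target, "family": "constant", "n": len(y),
        }
    params = dict(DEFAULT_RF_PARAMS, max_features="sqrt")
    params.update(rf_params or {})
    forest = RandomForestClassifier(random_state=seed, **params)
    forest.fit(X, y)
    log = {
        "variable": name or target,
        "family": "classification-forest",
        "n": len(y),
        "n_estimators": forest.n_estimators,
        "max_features": params["max_features"],
        "min_samples_leaf": params["min_samples_leaf"],
    }
    return (
        RFClassifierCM(cols=tuple(cols), forest=forest,
                       target_levels=tuple(target_levels),
                       levels=dict(levels)),
        log,
    )


def fit_rf_regressor(
    df, target, cols, levels, rf_params=None, seed=None, name=None
) -> tuple:
    """Regression forest (max_features = 1/3) with an out-of-bag residual
    pool of length n; rows never out-of-bag fall back to the in-bag
    prediction (residual 0)."""
    X, _ = design_matrix(df, cols, levels, intercept=False)
    y = df[target].to_numpy(dtype=float)
    params = dict(DEFAULT_RF_PARAMS, max_features=1.0 / 3.0)
    params.update(rf_params or {})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # "some inputs do not have OOB scores"
        forest = RandomForestRegressor(
            random_state=seed, oob_score=True, bootstrap=True, **params
        )
        forest.fit(X, y)
        oob = forest.oob_prediction_
    oob = np.where(np.isnan(oob), forest.predict(X), oob)
    residuals = y - oob
    log = {
        "variable": name or target,
        "family": "regression-forest",
        "n": len(y),
        "n_estimators": forest.n_estimators,
        "max_features": params["max_features"],
        "min_samples_leaf": params["min_samples_leaf"],
        "residual_pool_mean": float(residuals.mean()),
        "residual_pool_sd": float(residuals.std(ddof=1)),
    }
    return (
        RFRegressionCM(cols=tuple(cols), forest=forest,
                       residual_pool=residuals, levels=dict(levels)),
        log,
    )
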