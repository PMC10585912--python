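"""Estimators of marginal-structural-model parameters.

Implements the compared estimators for the MSM
E[Y^a] = gamma_0 + gamma' d(a-bar), with d() the cumulative-exposure
dummy coding:

* ``estimate_iptw`` — stabilized inverse-probability-of-treatment
  weighting: weighted regression of Y on the dummies with weights
  sw_i = prod_t P(A_t = a_ti | A-bar_{t-1}) / P(A_t = a_ti | A-bar_{t-1},
  L-bar_t); heteroskedasticity-robust (HC0) standard errors.
* ``estimate_gcomp`` — sequential-regression g-computation (iterated
  conditional expectations evaluated at fixed regimes, averaged over the
  covariate distribution); SE = SD over nonparametric bootstrap
  resamples of subjects.
* ``estimate_tmle`` — the same recursion with, at each step, a targeted
  fluctuation Q* = Q + eps * H along the clever covariate
  H_t = I(A-bar_t = a-bar_t) / prod_{s<=t} g_s; SE from the empirical
  efficient influence curve.
* ``estimate_standard`` — ordinary regression of Y on the dummies with
  adjustment for baseline covariates only, or for baseline plus
  time-varying covariates (the two traditional comparators).

All working models default to main terms over the full time-admissible
history; ``WorkingModels`` can exclude covariates (to stage
misspecification experiments) or saturate the designs (for exact
small-sample identities with nonparametric standardization).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import CohortTable, RegimeCoding, VariableSpec, validate_cohort
from .design import design_matrix
from .errors import EstimationError, FittingError, PositivityError


# ---------------------------------------------------------------------------
# Configuration and result containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WorkingModels:
    """Working-model configuration for the estimators.

    q_exclude : covariate columns omitted from the outcome/sequential (Q)
        regressions — deliberate Q-misspecification.
    g_exclude : covariate columns omitted from the exposure (g) models —
        deliberate g-misspecification.
    saturated : build fully saturated designs (all interaction products)
        instead of main terms; intended for small discrete problems.
    """

    q_exclude: tuple = ()
    g_exclude: tuple = ()
    saturated: bool = False


@dataclass
class WeightVector:
    """Per-subject stabilized weights with their component probabilities."""

    sw: np.ndarray
    numerator_probs: np.ndarray  # (n, K), at the observed exposure value
    denominator_probs: np.ndarray
    diagnostics: dict = field(default_factory=dict)


@dataclass
class MSMEstimate:
    """MSM coefficient estimates with SEs and 95% CIs."""

    estimator: str
    names: list
    estimate: np.ndarray
    se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    se_method: str
    diagnostics: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimator": self.estimator,
                "coefficient": self.names,
                "estimate": self.estimate,
                "se": self.se,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )

    def as_dict(self) -> dict:
        return dict(zip(self.names, self.estimate))


def _as_cohort(data, spec: VariableSpec | None) -> CohortTable:
    if isinstance(data, CohortTable):
        return data
    if spec is None:
        raise EstimationError("a VariableSpec is required with raw tabular data")
    return validate_cohort(data, spec)


def _wald_ci(est, se):
    return est - 1.96 * se, est + 1.96 * se


def _observed_labels(df, spec, coding):
    A = df[list(spec.exposure_names)].to_numpy()
    labels = [coding.label(tuple(row)) for row in A]
    present = set(labels)
    missing = [lab for lab in coding.labels if lab not in present]
    if missing:
        raise EstimationError(
            f"exposure categories absent from the data: {missing}; the MSM "
            "design is rank deficient"
        )
    return labels


# ---------------------------------------------------------------------------
# Stabilized weights and IPTW
# ---------------------------------------------------------------------------


def _irls_logistic(X: np.ndarray, y: np.ndarray, max_iter: int = 60,
                   tol: float = 1e-10) -> np.ndarray:
    """Newton/IRLS logistic MLE on a prebuilt design (hot path: the
    exposure models are refitted once per bootstrap resample).  Raises
    on non-convergence or separation-driven divergence."""
    from scipy.special import expit as _expit

    if len(np.unique(y)) < 2:
        raise FittingError("exposure target is single-valued in this sample")
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        p = _expit(eta)
        W = p * (1.0 - p)
        grad = X.T @ (y - p)
        H = (X * W[:, None]).T @ X
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step, *_ = np.linalg.lstsq(H, grad, rcond=None)
        beta = beta + step
        if not np.isfinite(beta).all():
            raise FittingError("logistic exposure model diverged (separation?)")
        if np.max(np.abs(step)) < tol:
            return beta
    raise FittingError("logistic exposure model did not converge")


class _ExposureModelSet:
    """Per-wave logistic exposure models on precomputed designs.

    Numerator models condition on past exposure only; denominator models
    add the covariate history through the current wave.  Designs are
    built once; ``probs_at_observed`` can re-fit on a row subset
    (bootstrap) and returns probabilities aligned with that subset.
    """

    def __init__(self, cohort: CohortTable, working: WorkingModels):
        spec, df, levels = cohort.spec, cohort.df, cohort.levels
        self.K = spec.K
        self.a_obs, self.num_X, self.den_X = [], [], []
        for t in range(1, spec.K + 1):
            a_col = spec.exposure_names[t - 1]
            num_cols = spec.exposures_through(t - 1)
            den_cols = num_cols + [
                c for c in spec.covariates_through(t)
                if c not in working.g_exclude
            ]
            sat = working.saturated
            Xn, _ = design_matrix(df, num_cols, levels, saturated=sat)
            Xd, _ = design_matrix(df, den_cols, levels, saturated=sat)
            self.a_obs.append(df[a_col].to_numpy(dtype=float))
            self.num_X.append(Xn)
            self.den_X.append(Xd)

    def probs_at_observed(self, which: str, rows=None) -> np.ndarray:
        """(len(rows), K) fitted P(A_t = observed a_t | model), fitted
        and evaluated on *rows* (default: all subjects)."""
        from scipy.special import expit as _expit

        designs = self.num_X if which == "numerator" else self.den_X
        n = len(self.a_obs[0]) if rows is None else len(rows)
        out = np.empty((n, self.K))
        for t in range(self.K):
            X, a = designs[t], self.a_obs[t]
            if rows is not None:
                X, a = X[rows], a[rows]
            try:
                beta = _irls_logistic(X, a)
            except FittingError as exc:
                raise FittingError(
                    f"{which} exposure model for wave {t + 1}: {exc}"
                ) from exc
            p1 = _expit(X @ beta)
            out[:, t] = np.where(a == 1, p1, 1.0 - p1)
        return out


def compute_stabilized_weights(
    data,
    spec: VariableSpec | None = None,
    truncation: tuple | None = None,
    working: WorkingModels | None = None,
) -> WeightVector:
    """Stabilized IPT weights sw_i (product over waves of numerator /
    denominator probabilities at the observed exposure).

    ``truncation`` is an optional (low, high) percentile pair applied
    symmetrically to the weights after computation (e.g. (1, 99)) and
    recorded in the diagnostics.  Without truncation, a fitted
    probability of exactly 0 or 1 at an observed value raises
    :class:`PositivityError`.
    """
    cohort = _as_cohort(data, spec)
    working = working or WorkingModels()
    ems = _ExposureModelSet(cohort, working)
    num_p = ems.probs_at_observed("numerator")
    den_p = ems.probs_at_observed("denominator")
    if truncation is None and ((den_p <= 0).any() or (den_p >= 1).any()):
        raise PositivityError(
            "a fitted exposure probability of 0 or 1 was encountered at an "
            "observed value; consider weight truncation"
        )
    den_safe = np.clip(den_p, np.finfo(float).tiny, None)
    sw = np.prod(num_p / den_safe, axis=1)
    diagnostics = {
        "mean": float(sw.mean()),
        "min": float(sw.min()),
        "max": float(sw.max()),
        "truncation": None,
    }
    if truncation is not None:
        lo_pct, hi_pct = truncation
        lo, hi = np.percentile(sw, [lo_pct, hi_pct])
        sw = np.clip(sw, lo, hi)
        diagnostics["truncation"] = {
            "percentiles": (lo_pct, hi_pct),
            "bounds": (float(lo), float(hi)),
            "mean_after": float(sw.mean()),
        }
    return WeightVector(
        sw=sw, numerator_probs=num_p, denominator_probs=den_p,
        diagnostics=diagnostics,
    )


def estimate_iptw(
    data,
    spec: VariableSpec | None = None,
    coding: RegimeCoding | None = None,
    truncation: tuple | None = None,
    working: WorkingModels | None = None,
) -> MSMEstimate:
    """Stabilized-IPTW MSM fit: weighted least squares of Y on the
    cumulative-exposure dummies with HC0 (sandwich) standard errors,
    treating the weights as fixed."""
    cohort = _as_cohort(data, spec)
    spec = cohort.spec
    coding = coding or RegimeCoding.default_for(spec.K)
    labels = _observed_labels(cohort.df, spec, coding)
    wv = compute_stabilized_weights(cohort, truncation=truncation, working=working)
    X = coding.design_from_labels(labels)
    y = cohort.df[spec.outcome_name].to_numpy(dtype=float)
    res = sm.WLS(y, X, weights=wv.sw).fit(cov_type="HC0")
    est, se = np.asarray(res.params), np.asarray(res.bse)
    lo, hi = _wald_ci(est, se)
    return MSMEstimate(
        estimator="iptw",
        names=coding.coef_names(),
        estimate=est, se=se, ci_low=lo, ci_high=hi,
        se_method="robust",
        diagnostics={"weights": wv.diagnostics},
    )


# ---------------------------------------------------------------------------
# Sequential g-computation / TMLE engine
# ---------------------------------------------------------------------------


def _saturate(block: np.ndarray, names: list):
    cols = [block[:, j] for j in range(block.shape[1])]
    out_cols, out_names = list(cols), list(names)
    for r in range(2, len(cols) + 1):
        for combo in itertools.combinations(range(len(cols)), r):
            prod = cols[combo[0]].copy()
            for j in combo[1:]:
                prod = prod * cols[j]
            out_cols.append(prod)
            out_names.append(":".join(names[j] for j in combo))
    return np.column_stack(out_cols), out_names


class _SequentialEngine:
    """Shared iterated-regression recursion for g-computation and TMLE.

    Precomputes per-wave expanded covariate blocks once; each ``run``
    (optionally on a bootstrap index set) fits the step regressions by
    pseudo-inverse and walks the recursion for every regime.  With
    ``fluctuate=False`` this is exactly the g-computation algorithm;
    with ``fluctuate=True`` each Q_t is targeted before becoming the
    next step's regression target, and the empirical efficient
    influence curve is accumulated for the variance.
    """

    def __init__(self, cohort: CohortTable, coding: RegimeCoding,
                 working: WorkingModels):
        spec = cohort.spec
        self.spec, self.coding, self.working = spec, coding, working
        df = cohort.df
        self.y = df[spec.outcome_name].to_numpy(dtype=float)
        self.A = df[list(spec.exposure_names)].to_numpy(dtype=float)
        self.n = len(df)
        # expanded covariate block through wave t (columns cumulative)
        self.L_blocks, self.L_names = [], []
        for t in range(1, spec.K + 1):
            cols = [c for c in spec.covariate_names[t - 1]
                    if c not in working.q_exclude]
            X, names = design_matrix(df, cols, cohort.levels, intercept=False)
            self.L_blocks.append(X)
            self.L_names.append(names)
        self.regimes = sorted(coding.mapping.keys())
        self.rank_warnings = []

    def _step_design(self, t, rows, a_values=None):
        """Design for the step-t regression: A_1..A_t (observed, or fixed
        regime values) + L-bar_t expanded, optionally saturated, plus
        intercept."""
        if a_values is None:
            Ablock = self.A[rows, :t]
        else:
            Ablock = np.tile(np.asarray(a_values[:t], dtype=float),
                             (len(rows), 1))
        blocks = [Ablock] + [self.L_blocks[s][rows] for s in range(t)]
        base = np.column_stack(blocks) if blocks else np.empty((len(rows), 0))
        if self.working.saturated:
            names = [f"A{s + 1}" for s in range(t)] + [
                nm for s in range(t) for nm in self.L_names[s]
            ]
            base, _ = _saturate(base, names)
        return np.column_stack([np.ones(len(rows)), base])

    def run(self, rows=None, fluctuate=False, gprobs=None, eps_override=None):
        """One full pass; returns (gamma, info).

        rows : optional index array (bootstrap resample); default all.
        gprobs : fitted P(A_t = observed | history) aligned with *rows*,
            required when fluctuating (the clever-covariate denominators).
        eps_override : force every fluctuation coefficient to this value
            (diagnostic; 0 reproduces g-computation exactly).
        """
        spec, K = self.spec, self.spec.K
        rows = np.arange(self.n) if rows is None else np.asarray(rows)
        y = self.y[rows]
        A_obs = self.A[rows]

        # per-step observed designs and their pseudo-inverses (shared
        # across regimes; the step-K fit is also shared since its target
        # Y does not depend on the regime)
        X_obs = [self._step_design(t, rows) for t in range(1, K + 1)]
        pinvs = []
        for t, X in enumerate(X_obs, start=1):
            rank = np.linalg.matrix_rank(X)
            if rank < X.shape[1]:
                self.rank_warnings.append(
                    f"step-{t} design rank {rank} < {X.shape[1]}; "
                    "minimum-norm (pseudo-inverse) solution used"
                )
            pinvs.append(np.linalg.pinv(X))
        beta_K = pinvs[K - 1] @ y

        if fluctuate:
            if gprobs is None:
                raise EstimationError("fluctuation requires exposure probabilities")
            gp = gprobs  # caller supplies probabilities aligned with rows
            if len(gp) != len(rows):
                raise EstimationError(
                    "exposure probabilities are not aligned with the row subset"
                )
            if (gp <= 0).any():
                raise PositivityError(
                    "clever covariate denominator hit a zero exposure "
                    "probability; consider truncating the g probabilities"
                )
            Gcum = np.cumprod(gp, axis=1)  # (n, K)

        n_r = len(self.regimes)
        Q1 = np.empty((len(rows), n_r))
        psi = np.empty(n_r)
        ic = np.zeros((len(rows), n_r)) if fluctuate else None
        eps_log = {}
        for r_idx, regime in enumerate(self.regimes):
            target = y
            eps_list = []
            for t in range(K, 0, -1):
                beta = beta_K if t == K else pinvs[t - 1] @ target
                Q = self._step_design(t, rows, a_values=regime) @ beta
                if fluctuate:
                    follower = (A_obs[:, :t] == np.asarray(regime[:t])).all(axis=1)
                    H = follower / Gcum[:, t - 1]
                    h2 = float(H @ H)
                    if eps_override is not None:
                        eps = float(eps_override)
                    elif h2 > 0:
                        eps = float(H @ (target - Q)) / h2
                    else:
                        eps = 0.0
                    Qstar = Q + eps * H
                    ic[:, r_idx] += H * (target - Qstar)
                    eps_list.append(eps)
                else:
                    Qstar = Q
                target = Qstar
            Q1[:, r_idx] = target
            psi[r_idx] = target.mean()
            if fluctuate:
                ic[:, r_idx] += target - psi[r_idx]
                eps_log[str(tuple(regime))] = eps_list[::-1]

        gamma, C = self._msm_from_psi(psi)
        info = {"psi": psi, "Q1": Q1, "contrast": C}
        if fluctuate:
            info["ic_gamma"] = ic @ C.T
            info["epsilon"] = eps_log
        return gamma, info

    def _msm_from_psi(self, psi):
        """MSM coefficients from per-regime counterfactual means.

        Stacking the per-subject Q_1 values over regimes and regressing
        on the category dummies is a saturated one-way design, so the
        OLS solution equals pooled category means (each regime weighted
        equally); gamma is that closed form, expressed as a contrast
        matrix C with gamma = C psi (also used for the delta-method
        influence-curve variance).
        """
        labels = self.coding.labels
        by_cat = {lab: [] for lab in labels}
        for j, regime in enumerate(self.regimes):
            by_cat[self.coding.label(regime)].append(j)
        C = np.zeros((len(labels), len(self.regimes)))
        ref = labels[0]
        for j in by_cat[ref]:
            C[0, j] = 1.0 / len(by_cat[ref])
        for i, lab in enumerate(labels[1:], start=1):
            if not by_cat[lab]:
                raise EstimationError(
                    f"regime set covers no regime in category {lab!r}"
                )
            for j in by_cat[lab]:
                C[i, j] = 1.0 / len(by_cat[lab])
            C[i] -= C[0]
        return C @ psi, C


def estimate_gcomp(
    data,
    spec: VariableSpec | None = None,
    coding: RegimeCoding | None = None,
    n_boot: int = 50,
    seed=None,
    working: WorkingModels | None = None,
    ci_method: str = "normal",
) -> MSMEstimate:
    """Sequential-regression g-computation MSM fit.

    For each regime: fit E[Y | A-bar, L-bar], predict at A-bar = a-bar
    (Q_K); recursively regress Q_{t+1} on (A-bar_t, L-bar_t) and predict
    at a-bar_t down to t = 1; average Q_1.  MSM coefficients come from
    the stacked per-subject Q_1 values on the category dummies.  The SE
    is the SD over ``n_boot`` nonparametric bootstrap resamples of
    subjects (the whole pipeline refitted per resample); ``ci_method``
    "normal" gives estimate +/- 1.96 SE, "percentile" the 2.5th/97.5th
    bootstrap quantiles.
    """
    cohort = _as_cohort(data, spec)
    spec = cohort.spec
    coding = coding or RegimeCoding.default_for(spec.K)
    working = working or WorkingModels()
    engine = _SequentialEngine(cohort, coding, working)
    gamma, _ = engine.run()
    if n_boot < 2:
        raise EstimationError("n_boot must be >= 2 for a bootstrap SE")
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, len(gamma)))
    for b in range(n_boot):
        idx = rng.integers(0, cohort.n, size=cohort.n)
        boots[b], _ = engine.run(rows=idx)
    se = boots.std(axis=0, ddof=1)
    if ci_method == "percentile":
        lo, hi = np.percentile(boots, [2.5, 97.5], axis=0)
        se_method = "bootstrap-percentile"
    else:
        lo, hi = _wald_ci(gamma, se)
        se_method = "bootstrap-SD"
    return MSMEstimate(
        estimator="gcomp",
        names=coding.coef_names(),
        estimate=gamma, se=se, ci_low=lo, ci_high=hi,
        se_method=se_method,
        diagnostics={
            "n_boot": n_boot,
            "rank_warnings": engine.rank_warnings,
        },
    )


def _tmle_pass(engine, ems, rows, g_truncation, epsilon_override):
    gprobs = ems.probs_at_observed("denominator", rows=rows)
    if g_truncation is not None:
        gprobs = np.clip(gprobs, g_truncation, 1.0 - g_truncation)
    return engine.run(
        rows=rows, fluctuate=True, gprobs=gprobs,
        eps_override=epsilon_override,
    )


def estimate_tmle(
    data,
    spec: VariableSpec | None = None,
    coding: RegimeCoding | None = None,
    working: WorkingModels | None = None,
    g_truncation: float | None = None,
    epsilon_override: float | None = None,
    se_method: str = "influence-curve",
    n_boot: int = 50,
    seed=None,
) -> MSMEstimate:
    """Targeted maximum likelihood MSM fit (continuous outcome, linear
    fluctuation with offset).

    The g-computation recursion is augmented at each step with the
    clever-covariate update Q* = Q + eps H_t, where H_t is the indicator
    of following a-bar through wave t divided by the cumulative product
    of fitted exposure probabilities, and eps is the offset-regression
    coefficient of the current target on H_t.

    ``se_method`` is "influence-curve" (default: square root of
    Var(empirical efficient influence curve)/n) or "bootstrap-SD"
    (SD over ``n_boot`` nonparametric resamples of subjects with the
    whole pipeline — g models included — refitted per resample).  The
    influence-curve SE estimates the nonparametric efficiency bound and
    is conservative when a correctly specified parametric outcome model
    lets the estimator beat that bound; the bootstrap tracks the actual
    sampling variance.  ``g_truncation`` bounds the fitted exposure
    probabilities away from 0/1 (e.g. 0.01); ``epsilon_override``
    forces every fluctuation coefficient (0 reproduces g-computation
    exactly, a diagnostic identity).
    """
    cohort = _as_cohort(data, spec)
    spec = cohort.spec
    coding = coding or RegimeCoding.default_for(spec.K)
    working = working or WorkingModels()
    engine = _SequentialEngine(cohort, coding, working)
    ems = _ExposureModelSet(cohort, working)
    gamma, info = _tmle_pass(engine, ems, None, g_truncation, epsilon_override)
    if se_method == "influence-curve":
        ic = info["ic_gamma"]
        se = ic.std(axis=0, ddof=1) / np.sqrt(cohort.n)
        boot_count = None
    elif se_method == "bootstrap-SD":
        if n_boot < 2:
            raise EstimationError("n_boot must be >= 2 for a bootstrap SE")
        rng = np.random.default_rng(seed)
        boots, failed = [], 0
        for b in range(n_boot):
            idx = rng.integers(0, cohort.n, size=cohort.n)
            try:
                g_b, _ = _tmle_pass(
                    engine, ems, idx, g_truncation, epsilon_override
                )
            except (FittingError, PositivityError):
                failed += 1  # e.g. separation in a resampled g model
                continue
            boots.append(g_b)
        if len(boots) < max(2, int(0.8 * n_boot)):
            raise FittingError(
                f"TMLE bootstrap failed on {failed}/{n_boot} resamples; "
                "consider g_truncation"
            )
        se = np.stack(boots).std(axis=0, ddof=1)
        boot_count = len(boots)
    else:
        raise EstimationError(
            f"unknown se_method {se_method!r}; use 'influence-curve' or "
            "'bootstrap-SD'"
        )
    lo, hi = _wald_ci(gamma, se)
    return MSMEstimate(
        estimator="tmle",
        names=coding.coef_names(),
        estimate=gamma, se=se, ci_low=lo, ci_high=hi,
        se_method=se_method,
        diagnostics={
            "epsilon": info["epsilon"],
            "g_truncation": g_truncation,
            "n_boot": boot_count,
            "rank_warnings": engine.rank_warnings,
        },
    )


def estimate_standard(
    data,
    spec: VariableSpec | None = None,
    adjustment: str = "baseline",
    coding: RegimeCoding | None = None,
) -> MSMEstimate:
    """Standard regression comparator: OLS of Y on the cumulative-
    exposure dummies plus either the baseline covariates only
    (``adjustment="baseline"``) or baseline and time-varying covariates
    (``adjustment="baseline+timevarying"``), with model-based SEs."""
    cohort = _as_cohort(data, spec)
    spec = cohort.spec
    coding = coding or RegimeCoding.default_for(spec.K)
    if adjustment == "baseline":
        covars = list(spec.covariate_names[0])
        label = "std-baseline"
    elif adjustment == "baseline+timevarying":
        covars = spec.all_covariates()
        label = "std-tv"
    else:
        raise EstimationError(
            f"unknown adjustment {adjustment!r}; use 'baseline' or "
            "'baseline+timevarying'"
        )
    labels = _observed_labels(cohort.df, spec, coding)
    D = coding.design_from_labels(labels)
    Xc, _ = design_matrix(cohort.df, covars, cohort.levels, intercept=False)
    X = np.column_stack([D, Xc]) if Xc.shape[1] else D
    y = cohort.df[spec.outcome_name].to_numpy(dtype=float)
    res = sm.OLS(y, X).fit()
    k = len(coding.labels)
    est, se = np.asarray(res.params[:k]), np.asarray(res.bse[:k])
    lo, hi = _wald_ci(est, se)
    return MSMEstimate(
        estimator=label,
        names=coding.coef_names(),
        estimate=est, se=se, ci_low=lo, ci_high=hi,
        se_method="model-based",
        diagnostics={"adjustment": adjustment},
    )
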