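"""Parametric plasmode algorithm.

The joint law of a longitudinal cohort factorises over the time-ordering
as f(Y | A-bar, L-bar) * prod_t f(L_t | A-bar_{t-1}, L-bar_{t-1})
* f(A_t | A-bar_{t-1}, L-bar_t).  This module fits one parametric
regression per factor to the original cohort — logistic for each binary
exposure, linear / logistic / multinomial for each covariate according
to its distribution tag, linear with normal errors for the continuous
outcome — and generates plasmode replicates by resampling the wave-1
covariates with replacement and simulating A_1, L_2, A_2, ..., Y
sequentially from the fitted conditionals.  Because generation mirrors
the fitted law exactly (no probability truncation), the counterfactual
truth computed from the same generator set is coherent with the
replicates.
"""

from __future__ import annotations

import warnings

import numpy as np

from .cohort import CohortTable, VariableSpec, validate_cohort
from .conditionals import fit_linear, fit_logistic, fit_multinomial
from .errors import ConfigError, DegenerateModelError
from .generators import GeneratorSet, as_seed_sequence, resample_base


def _default_predictors(spec: VariableSpec):
    """Full time-admissible main-terms predictor set per generated variable."""
    preds = {}
    for t in range(1, spec.K + 1):
        preds[spec.exposure_names[t - 1]] = (
            spec.exposures_through(t - 1) + spec.covariates_through(t)
        )
        if t >= 2:
            for col in spec.covariate_names[t - 1]:
                preds[col] = (
                    spec.exposures_through(t - 1) + spec.covariates_through(t - 1)
                )
    preds[spec.outcome_name] = (
        spec.exposures_through(spec.K) + spec.covariates_through(spec.K)
    )
    return preds


def fit_parametric_generators(
    cohort: CohortTable,
    predictor_subsets: dict | None = None,
) -> GeneratorSet:
    """Fit the "true" parametric conditional models to *cohort*.

    Parameters
    ----------
    cohort : validated input cohort.
    predictor_subsets : optional map {generated column -> predictor list}.
        Each subset must be contained in the full time-admissible history
        for that variable (supports parsimonious models chosen on
        substantive grounds); unlisted variables use the full history
        with main terms only.

    Returns
    -------
    GeneratorSet with fitted coefficients, residual SDs (denominator
    n - p) and a fitting log recording convergence of every model.
    """
    spec, levels, df = cohort.spec, cohort.levels, cohort.df
    defaults = _default_predictors(spec)
    predictor_subsets = predictor_subsets or {}
    for target, subset in predictor_subsets.items():
        if target not in defaults:
            raise ConfigError(f"{target!r} is not a generated variable")
        extra = [c for c in subset if c not in defaults[target]]
        if extra:
            raise ConfigError(
                f"predictors {extra} for {target!r} are not in its "
                "time-admissible history"
            )

    models, logs = {}, []
    for target, default_cols in defaults.items():
        cols = list(predictor_subsets.get(target, default_cols))
        tag = spec.distributions[target]
        if tag == "gaussian":
            if np.ptp(df[target].to_numpy(dtype=float)) == 0:
                raise DegenerateModelError(
                    f"gaussian target {target!r} is constant"
                )
            cm, log = fit_linear(df, target, cols, levels)
        elif tag == "binomial":
            cm, log = fit_logistic(df, target, cols, levels)
        else:
            cm, log = fit_multinomial(
                df, target, cols, levels, target_levels=levels[target]
            )
        models[target] = cm
        logs.append(log)
    return GeneratorSet(
        spec=spec, levels=dict(levels), models=models,
        kind="parametric", fitting_log=logs,
    )


def generate_parametric(
    gen: GeneratorSet,
    cohort: CohortTable,
    m: int,
    J: int,
    seed,
) -> list:
    """Generate *J* parametric plasmode replicates of size *m*.

    Each replicate resamples m subjects' wave-1 covariates with
    replacement from *cohort* (all other columns discarded), then draws
    A_1 ~ Bernoulli(expit(x'beta)), each later covariate from its fitted
    law, and finally Y = x'beta + N(0, sigma^2).  Replicates use
    independent child streams of *seed*, so a fixed seed is
    bit-reproducible and replicate j does not depend on J.
    """
    gen.check_compatible(cohort.spec)
    spec = cohort.spec
    if m > cohort.n:
        warnings.warn(
            f"m = {m} exceeds the original n = {cohort.n}; the algorithm "
            "is intended for m < n", stacklevel=2,
        )
    keep = list(spec.covariate_names[0])
    out = []
    for child in as_seed_sequence(seed).spawn(J):
        rng = np.random.default_rng(child)
        base = resample_base(cohort.df, spec, m, rng, keep)
        frame = gen.sequential_generate(base, rng)
        out.append(validate_cohort(frame, spec, levels=cohort.levels))
    return out
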