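"""Nonparametric (random-forest) plasmode algorithm.

Same factorisation and sequential generation as the parametric
algorithm, but every conditional law is a random forest: classification
forests for binary/multinomial targets (new values are categorical draws
from the predicted class probabilities) and regression forests for
continuous targets (point prediction plus one draw from the pool of
out-of-bag residuals).  Forests for the exposure are fitted for waves
2..K; wave 1's exposure is by default retained from the resample
alongside the wave-1 covariates, or an extra A_1 forest (on wave-1
covariates) is fitted when retention is switched off.
"""

from __future__ import annotations

import warnings

import numpy as np

from .cohort import CohortTable
from .conditionals import fit_rf_classifier, fit_rf_regressor
from .errors import ConfigError
from .generators import GeneratorSet, as_seed_sequence, resample_base
from .parametric import _default_predictors


def fit_rf_generators(
    cohort: CohortTable,
    rf_params: dict | None = None,
    seed=None,
    fit_a1: bool = False,
    allow_constant: bool = False,
) -> GeneratorSet:
    """Fit random-forest conditional models to *cohort*.

    Parameters
    ----------
    cohort : validated input cohort.
    rf_params : forest hyperparameters applied to every forest
        (defaults: 500 trees, min leaf 5; variables-per-split sqrt(p)
        for classification, p/3 for regression).
    seed : seed for the forests' internal randomisation.
    fit_a1 : also fit a forest for the wave-1 exposure (needed when
        generation will not retain A_1 from the resample).
    allow_constant : store a degenerate law for single-valued
        categorical targets instead of raising.
    """
    spec, levels, df = cohort.spec, cohort.levels, cohort.df
    defaults = _default_predictors(spec)
    ss = np.random.SeedSequence(seed)

    targets = []
    for t in range(2, spec.K + 1):
        targets.extend(spec.covariate_names[t - 1])
        targets.append(spec.exposure_names[t - 1])
    if fit_a1:
        targets.insert(0, spec.exposure_names[0])
    targets.append(spec.outcome_name)

    models, logs = {}, []
    for target, child in zip(targets, ss.spawn(len(targets))):
        cols = defaults[target]
        tag = spec.distributions[target]
        forest_seed = int(child.generate_state(1)[0] % (2**31))
        if tag == "gaussian":
            cm, log = fit_rf_regressor(
                df, target, cols, levels, rf_params=rf_params, seed=forest_seed
            )
        else:
            cm, log = fit_rf_classifier(
                df, target, cols, levels, target_levels=levels[target],
                rf_params=rf_params, seed=forest_seed,
                allow_constant=allow_constant,
            )
        models[target] = cm
        logs.append(log)
    return GeneratorSet(
        spec=spec, levels=dict(levels), models=models,
        kind="nonparametric", fitting_log=logs,
    )


def generate_nonparametric(
    gen: GeneratorSet,
    cohort: CohortTable,
    m: int,
    J: int,
    seed,
    retain_A1: bool = True,
) -> list:
    """Generate *J* nonparametric plasmode replicates of size *m*.

    Each replicate resamples m subjects with replacement keeping the
    wave-1 covariates (and A_1 when *retain_A1*, the default), then
    sequentially draws L_2, A_2, ..., Y from the fitted forests.
    """
    gen.check_compatible(cohort.spec)
    spec = cohort.spec
    if m >= cohort.n:
        warnings.warn(
            f"m = {m} is not smaller than the original n = {cohort.n}; the "
            "algorithm samples m < n observations", stacklevel=2,
        )
    a1 = spec.exposure_names[0]
    if not retain_A1 and a1 not in gen.models:
        raise ConfigError(
            "retain_A1 is off but the generator set has no A_1 model; "
            "refit with fit_a1=True"
        )
    keep = list(spec.covariate_names[0]) + ([a1] if retain_A1 else [])
    from .cohort import validate_cohort

    out = []
    for child in as_seed_sequence(seed).spawn(J):
        rng = np.random.default_rng(child)
        base = resample_base(cohort.df, spec, m, rng, keep)
        frame = gen.sequential_generate(base, rng)
        out.append(validate_cohort(frame, spec, levels=cohort.levels))
    return out
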