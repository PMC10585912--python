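"""Counterfactual truth by deterministic-exposure Monte Carlo.

For every subject's observed wave-1 covariates and every exposure regime
a-bar, later covariates are simulated from the generator's "true"
confounder models with the exposures held fixed at the regime (never
drawn), and the counterfactual outcome Y^a is simulated from the "true"
outcome model.  The full regime set yields n x 2^K stacked rows; the
true marginal-structural-model parameters are the OLS coefficients of
Y^a on the cumulative-exposure dummies of this stacked dataset, i.e.
each category's truth is the unweighted pooled mean over the
(subject x regime) counterfactuals of the regimes in that category.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import CohortTable, RegimeCoding
from .errors import ConfigError, EstimationError
from .generators import GeneratorSet, as_seed_sequence


def enumerate_regimes(K: int) -> np.ndarray:
    """All 2^K binary exposure regimes, one per row, lexicographic order."""
    if K < 1:
        raise ConfigError(f"K must be a positive integer, got {K}")
    return np.array(list(itertools.product((0, 1), repeat=K)), dtype=np.int64)


def _check_regimes(regimes: np.ndarray, K: int) -> np.ndarray:
    regimes = np.asarray(regimes)
    if regimes.ndim != 2 or regimes.shape[1] != K:
        raise ConfigError(
            f"regime matrix has shape {regimes.shape}, expected (*, {K})"
        )
    if not np.isin(regimes, [0, 1]).all():
        raise ConfigError("regime entries must be binary")
    if len(np.unique(regimes, axis=0)) != len(regimes):
        raise ConfigError("regime rows must be unique")
    return regimes.astype(np.int64)


@dataclass
class CounterfactualTable:
    """Stacked regime dataset of counterfactual outcomes.

    ``df`` has one row per (replicate, subject, regime) carrying the
    subject index, the regime columns, the simulated covariates, the
    counterfactual outcome and the regime's category label.
    """

    df: pd.DataFrame
    K: int
    coding: RegimeCoding
    outcome_name: str
    n_input: int
    n_regimes: int
    replicates: int


def simulate_counterfactuals(
    gen: GeneratorSet,
    cohort: CohortTable,
    regimes: np.ndarray | None = None,
    replicates: int = 1,
    seed=None,
    coding: RegimeCoding | None = None,
) -> CounterfactualTable:
    """Simulate Y^a for every subject and regime.

    Parameters
    ----------
    gen : fitted generator set (parametric or random-forest).
    cohort : the original cohort supplying the wave-1 covariates
        (the truth pass uses all n subjects, not a resample).
    regimes : optional regime matrix (rows a-bar in {0,1}^K); default is
        the full 2^K set.
    replicates : number of complete passes; more passes shrink the
        Monte Carlo error of the truth.
    coding : regime-to-category coding (default: published five-category
        coding at K = 3, saturated otherwise).

    Returns
    -------
    CounterfactualTable with n x (#regimes) x replicates rows.
    """
    gen.check_compatible(cohort.spec)
    spec = cohort.spec
    K = spec.K
    regimes = (
        enumerate_regimes(K) if regimes is None else _check_regimes(regimes, K)
    )
    coding = coding or RegimeCoding.default_for(K)
    if replicates < 1:
        raise ConfigError("replicates must be >= 1")

    base_cols = list(spec.covariate_names[0])
    base = cohort.df[base_cols].reset_index(drop=True)
    n = len(base)
    chunks = []
    for r, child in enumerate(as_seed_sequence(seed).spawn(replicates)):
        rng = np.random.default_rng(child)
        for a in regimes:
            fixed = np.tile(a, (n, 1))
            frame = gen.sequential_generate(base, rng, fixed_exposures=fixed)
            frame.insert(0, "_subject", np.arange(n))
            frame.insert(0, "_replicate", r)
            frame["_category"] = coding.label(tuple(a))
            chunks.append(frame)
    df = pd.concat(chunks, ignore_index=True)
    return CounterfactualTable(
        df=df, K=K, coding=coding, outcome_name=spec.outcome_name,
        n_input=n, n_regimes=len(regimes), replicates=replicates,
    )


@dataclass
class TrueMSM:
    """True MSM parameters with their Monte Carlo uncertainty."""

    gamma: dict
    mc_se: dict
    coding: RegimeCoding
    n_input: int
    replicates: int

    def as_arrays(self):
        names = ["intercept"] + list(self.coding.labels[1:])
        return (
            names,
            np.array([self.gamma[k] for k in names]),
            np.array([self.mc_se[k] for k in names]),
        )


def true_msm_parameters(cf: CounterfactualTable) -> TrueMSM:
    """OLS of the counterfactual outcomes on the category dummies.

    On the saturated one-way design this reproduces pooled category
    means: the intercept is the never-exposed mean and each coefficient
    a category-vs-never mean difference.  Monte Carlo SEs come from
    between-replicate variation when replicates > 1, otherwise from
    subject-level cluster-robust variances (each subject contributes one
    row per regime).
    """
    coding = cf.coding
    present = set(cf.df["_category"])
    missing = [lab for lab in coding.labels if lab not in present]
    if missing:
        raise EstimationError(
            f"counterfactual table lacks categories {missing}; supply the "
            "full regime set to identify every MSM coefficient"
        )
    names = coding.coef_names()
    y = cf.df[cf.outcome_name].to_numpy(dtype=float)
    X = coding.design_from_labels(cf.df["_category"].tolist())

    if cf.replicates > 1:
        reps = cf.df["_replicate"].to_numpy()
        per_rep = []
        for r in range(cf.replicates):
            mask = reps == r
            beta, *_ = np.linalg.lstsq(X[mask], y[mask], rcond=None)
            per_rep.append(beta)
        per_rep = np.stack(per_rep)
        gamma = per_rep.mean(axis=0)
        mc_se = per_rep.std(axis=0, ddof=1) / np.sqrt(cf.replicates)
    else:
        groups = cf.df["_subject"].to_numpy()
        res = sm.OLS(y, X).fit(
            cov_type="cluster", cov_kwds={"groups": groups}
        )
        gamma = np.asarray(res.params)
        mc_se = np.asarray(res.bse)
    return TrueMSM(
        gamma=dict(zip(names, gamma)),
        mc_se=dict(zip(names, mc_se)),
        coding=coding,
        n_input=cf.n_input,
        replicates=cf.replicates,
    )
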