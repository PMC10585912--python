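"""Simulation-study orchestration and performance metrics.

``run_study`` generates J plasmode replicates from a fitted generator
set, runs a list of estimators on each, and collects every coefficient
estimate with its SE and 95% CI; failures are recorded and counted, not
silently dropped.  ``performance_metrics`` turns the estimate array and
a truth vector into the study's summary — per estimator and coefficient:
bias, SD of the estimates, RMSE and coverage of the 95% CIs, each with
its Monte Carlo standard error.  ``summarize_report`` renders the
metric blocks in the conventional layout (bias / SD / RMSE / coverage
by estimator and exposure category).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .cohort import CohortTable, RegimeCoding
from .counterfactual import TrueMSM
from .errors import ConfigError, EstimationError, LongPlasmodeError
from .generators import as_seed_sequence
from .estimators import (
    WorkingModels,
    estimate_gcomp,
    estimate_iptw,
    estimate_standard,
    estimate_tmle,
)
from .fixture import FixtureTruth
from .generators import GeneratorSet
from .nonparametric import generate_nonparametric
from .parametric import generate_parametric


@dataclass(frozen=True)
class EstimatorConfig:
    """One estimator to run per replicate.

    name : one of "iptw", "gcomp", "tmle", "std-baseline", "std-tv".
    label : output label (defaults to the name).
    kwargs : extra keyword arguments forwarded to the estimator (e.g.
        ``n_boot``, ``working``, ``truncation``).
    """

    name: str
    label: str | None = None
    kwargs: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.name not in _RUNNERS:
            raise ConfigError(
                f"unknown estimator {self.name!r}; choose from {sorted(_RUNNERS)}"
            )

    @property
    def out_label(self) -> str:
        return self.label or self.name


def _run_iptw(cohort, coding, seed, **kw):
    return estimate_iptw(cohort, coding=coding, **kw)


def _run_gcomp(cohort, coding, seed, **kw):
    kw.setdefault("n_boot", 50)
    return estimate_gcomp(cohort, coding=coding, seed=seed, **kw)


def _run_tmle(cohort, coding, seed, **kw):
    # simulation-study convention: bootstrap-SD(50) like g-computation;
    # the influence-curve SE targets the nonparametric bound and
    # overcovers when the parametric outcome model is correct
    kw.setdefault("se_method", "bootstrap-SD")
    kw.setdefault("n_boot", 50)
    return estimate_tmle(cohort, coding=coding, seed=seed, **kw)


def _run_std_baseline(cohort, coding, seed, **kw):
    return estimate_standard(cohort, coding=coding, adjustment="baseline", **kw)


def _run_std_tv(cohort, coding, seed, **kw):
    return estimate_standard(
        cohort, coding=coding, adjustment="baseline+timevarying", **kw
    )


_RUNNERS = {
    "iptw": _run_iptw,
    "gcomp": _run_gcomp,
    "tmle": _run_tmle,
    "std-baseline": _run_std_baseline,
    "std-tv": _run_std_tv,
}


@dataclass
class StudyResult:
    """Per-replicate estimates plus failure bookkeeping."""

    estimates: pd.DataFrame  # replicate, estimator, coefficient, estimate, se, ci
    failures: pd.DataFrame  # replicate, estimator, error
    J: int
    m: int
    scenario: str

    def failure_rate(self) -> pd.Series:
        if self.failures.empty:
            return pd.Series(dtype=float)
        return self.failures.groupby("estimator").size() / self.J


def _one_replicate(j, seed, gen, cohort, m, estimators, coding, scenario):
    children = as_seed_sequence(seed).spawn(len(estimators) + 1)
    if scenario == "parametric":
        table = generate_parametric(gen, cohort, m, 1, children[0])[0]
    else:
        table = generate_nonparametric(gen, cohort, m, 1, children[0])[0]
    rows, fails = [], []
    for cfg, child in zip(estimators, children[1:]):
        est_seed = int(child.generate_state(1)[0] % (2**31))
        try:
            est = _RUNNERS[cfg.name](table, coding, est_seed, **cfg.kwargs)
        except LongPlasmodeError as exc:
            fails.append({"replicate": j, "estimator": cfg.out_label,
                          "error": f"{type(exc).__name__}: {exc}"})
            continue
        for name, e, s, lo, hi in zip(
            est.names, est.estimate, est.se, est.ci_low, est.ci_high
        ):
            rows.append({
                "replicate": j, "estimator": cfg.out_label,
                "coefficient": name, "estimate": e, "se": s,
                "ci_low": lo, "ci_high": hi,
            })
    return rows, fails


def run_study(
    gen: GeneratorSet,
    cohort: CohortTable,
    estimators,
    m: int,
    J: int,
    seed,
    coding: RegimeCoding | None = None,
    n_jobs: int = 1,
) -> StudyResult:
    """Run the full simulation study.

    Each replicate gets an independent child seed stream spawned from
    *seed* before any work starts, so results are bit-identical for a
    fixed seed regardless of ``n_jobs``.  Estimator entries may be
    strings (default settings) or :class:`EstimatorConfig`.
    """
    gen.check_compatible(cohort.spec)
    if J < 1 or m < 2:
        raise ConfigError("J must be >= 1 and m >= 2")
    if not estimators:
        raise ConfigError("at least one estimator is required")
    estimators = [
        cfg if isinstance(cfg, EstimatorConfig) else EstimatorConfig(cfg)
        for cfg in estimators
    ]
    labels = [c.out_label for c in estimators]
    if len(set(labels)) != len(labels):
        raise ConfigError("estimator output labels must be unique")
    coding = coding or RegimeCoding.default_for(cohort.spec.K)
    scenario = gen.kind
    rep_seeds = np.random.SeedSequence(seed).spawn(J)

    if n_jobs == 1:
        results = [
            _one_replicate(j, s, gen, cohort, m, estimators, coding, scenario)
            for j, s in enumerate(rep_seeds)
        ]
    else:
        results = Parallel(n_jobs=n_jobs)(
            delayed(_one_replicate)(
                j, s, gen, cohort, m, estimators, coding, scenario
            )
            for j, s in enumerate(rep_seeds)
        )
    rows = [r for rws, _ in results for r in rws]
    fails = [f for _, fls in results for f in fls]
    est_df = pd.DataFrame(
        rows, columns=["replicate", "estimator", "coefficient", "estimate",
                       "se", "ci_low", "ci_high"],
    )
    fail_df = pd.DataFrame(fails, columns=["replicate", "estimator", "error"])
    return StudyResult(estimates=est_df, failures=fail_df, J=J, m=m,
                       scenario=scenario)


def _truth_to_dict(truth) -> dict:
    if isinstance(truth, (TrueMSM, FixtureTruth)):
        return dict(truth.gamma)
    return dict(truth)


def performance_metrics(
    estimates: pd.DataFrame | StudyResult,
    truth,
    scenario: str = "",
    truth_mc_se: dict | None = None,
) -> pd.DataFrame:
    """Bias, SD, RMSE and 95%-CI coverage with Monte Carlo SEs.

    bias = mean(estimate) - truth; SD = sample SD (ddof 1); RMSE =
    sqrt(mean((estimate - truth)^2)); coverage = fraction of CIs
    containing the truth.  Monte Carlo SEs: SD/sqrt(J) for bias,
    SD/sqrt(2(J-1)) for SD, sqrt(p(1-p)/J) for coverage.  *truth* may be
    a dict, a :class:`TrueMSM` or a :class:`FixtureTruth`; its own MC SE
    (when available) is carried into the ``truth_mc_se`` column so bias
    can be judged against the truth's uncertainty.
    """
    if isinstance(estimates, StudyResult):
        scenario = scenario or estimates.scenario
        estimates = estimates.estimates
    gamma = _truth_to_dict(truth)
    if truth_mc_se is None and isinstance(truth, (TrueMSM, FixtureTruth)):
        truth_mc_se = dict(truth.mc_se)
    truth_mc_se = truth_mc_se or {}
    rows = []
    for (estimator, coef), grp in estimates.groupby(
        ["estimator", "coefficient"], sort=False
    ):
        if coef not in gamma:
            raise EstimationError(
                f"no true value supplied for coefficient {coef!r}"
            )
        g = float(gamma[coef])
        vals = grp["estimate"].to_numpy(dtype=float)
        J = len(vals)
        if J < 2:
            raise EstimationError(
                f"need >= 2 successful replicates for {estimator}/{coef}, "
                f"got {J}"
            )
        bias = float(vals.mean() - g)
        sd = float(vals.std(ddof=1))
        rmse = float(np.sqrt(np.mean((vals - g) ** 2)))
        covered = (
            (grp["ci_low"].to_numpy() <= g) & (g <= grp["ci_high"].to_numpy())
        )
        cov = float(covered.mean())
        rows.append({
            "scenario": scenario,
            "estimator": estimator,
            "coefficient": coef,
            "truth": g,
            "bias": bias,
            "sd": sd,
            "rmse": rmse,
            "coverage": cov,
            "mc_se_bias": sd / np.sqrt(J),
            "mc_se_sd": sd / np.sqrt(2.0 * (J - 1)),
            "mc_se_coverage": float(np.sqrt(cov * (1.0 - cov) / J)),
            "truth_mc_se": float(truth_mc_se.get(coef, 0.0)),
            "n_reps": J,
        })
    return pd.DataFrame(rows)


_METRIC_BLOCKS = (
    ("bias", "Bias"),
    ("sd", "Standard deviation"),
    ("rmse", "RMSE"),
    ("coverage", "Coverage of the 95% confidence interval"),
)


def summarize_report(tables) -> str:
    """Human-readable report: one section per scenario, four metric
    blocks (bias / SD / RMSE / coverage), estimators as rows and
    exposure categories as columns."""
    if isinstance(tables, pd.DataFrame):
        tables = [tables]
    if not tables:
        raise ConfigError("at least one performance table is required")
    lines = []
    for table in tables:
        if table.empty:
            raise ConfigError("performance table is empty")
        scenario = table["scenario"].iloc[0] or "scenario"
        lines.append(f"=== {scenario} ===")
        coefs = [c for c in table["coefficient"].unique() if c != "intercept"]
        estimators = list(table["estimator"].unique())
        width = max(len(e) for e in estimators) + 2
        for key, title in _METRIC_BLOCKS:
            lines.append(title)
            header = " " * width + "".join(f"{c:>14}" for c in coefs)
            lines.append(header)
            for est in estimators:
                sub = table[table["estimator"] == est].set_index("coefficient")
                cells = []
                for c in coefs:
                    v = sub.loc[c, key]
                    cells.append(
                        f"{v:>13.0%} " if key == "coverage" else f"{v:>14.2f}"
                    )
                lines.append(f"{est:<{width}}" + "".join(cells))
            lines.append("")
    return "\n".join(lines)
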