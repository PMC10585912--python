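"""Synthetic input cohorts with fully known data-generating equations.

The motivating occupational-health cohort (psychosocial stressors at
work as a three-wave binary exposure, ambulatory blood pressure as the
continuous outcome) is private, so this module generates stand-in
"original" cohorts with the same structure: time-fixed baseline
covariates (age, gender, education), time-varying covariates (smoking,
body-mass-index category) with exposure-to-covariate feedback, and an
outcome on a blood-pressure-like scale.  Because every equation of a
:class:`FixtureDesign` is known, the fixture's own true MSM parameters
can be computed by Monte Carlo (:func:`true_fixture_msm`) independently
of the fitted-generator counterfactual machinery, which makes the
fixture the anchor for end-to-end parameter-recovery tests.

Equations are written as generalized linear predictors over earlier
columns in the time-ordering.  Term keys accept four forms: a plain
column name (``"age"``), a level indicator (``"bmi_1==2"``), a
threshold (``"age>50"``) and a two-column product (``"psw_3*smoking_3"``);
the latter two exist for the deliberately non-linear design variant
that stresses the nonparametric plasmode algorithm.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm
import yaml

from .cohort import CohortTable, RegimeCoding, VariableSpec, validate_cohort
from .errors import ConfigError


def _term_value(frame: pd.DataFrame, key: str) -> np.ndarray:
    if "*" in key:
        a, b = key.split("*")
        return frame[a].to_numpy(dtype=float) * frame[b].to_numpy(dtype=float)
    if "==" in key:
        col, v = key.split("==")
        return (frame[col].to_numpy(dtype=float) == float(v)).astype(float)
    if ">" in key:
        col, v = key.split(">")
        return (frame[col].to_numpy(dtype=float) > float(v)).astype(float)
    return frame[key].to_numpy(dtype=float)


def _linpred(frame: pd.DataFrame, intercept: float, terms: Mapping) -> np.ndarray:
    eta = np.full(len(frame), float(intercept))
    for key, coef in terms.items():
        eta += float(coef) * _term_value(frame, key)
    return eta


@dataclass(frozen=True)
class Equation:
    """One data-generating equation.

    dist : "gaussian" (linear, normal error ``sd``), "binomial"
        (logistic) or "multinomial" (baseline-category logits:
        ``intercept`` and ``terms`` are then tuples, one entry per
        non-reference level of ``levels``).
    """

    dist: str
    intercept: float | tuple
    terms: Mapping | tuple
    sd: float | None = None
    levels: tuple | None = None

    def __post_init__(self):
        if self.dist == "gaussian":
            if self.sd is None or self.sd <= 0:
                raise ConfigError("gaussian equation requires sd > 0")
        elif self.dist == "multinomial":
            if self.levels is None or len(self.levels) < 2:
                raise ConfigError("multinomial equation requires >= 2 levels")
            if len(self.intercept) != len(self.levels) - 1 or len(
                self.terms
            ) != len(self.levels) - 1:
                raise ConfigError(
                    "multinomial equation needs one intercept and term set "
                    "per non-reference level"
                )
        elif self.dist != "binomial":
            raise ConfigError(f"unknown equation distribution {self.dist!r}")

    def draw(self, frame: pd.DataFrame, rng: np.random.Generator) -> np.ndarray:
        if self.dist == "gaussian":
            mu = _linpred(frame, self.intercept, self.terms)
            return mu + rng.normal(0.0, self.sd, size=len(mu))
        if self.dist == "binomial":
            from scipy.special import expit

            p = expit(_linpred(frame, self.intercept, self.terms))
            return (rng.random(len(p)) < p).astype(np.int64)
        eta = np.column_stack(
            [np.zeros(len(frame))]
            + [_linpred(frame, b0, tr) for b0, tr in zip(self.intercept, self.terms)]
        )
        eta -= eta.max(axis=1, keepdims=True)
        p = np.exp(eta)
        p /= p.sum(axis=1, keepdims=True)
        cum = np.cumsum(p, axis=1)
        cum[:, -1] = 1.0
        idx = (rng.random(len(frame))[:, None] > cum).sum(axis=1)
        return np.asarray(self.levels, dtype=np.int64)[idx]


@dataclass
class FixtureDesign:
    """A complete synthetic cohort design.

    baseline : marginal laws for wave-1 covariates without an equation —
        ``("gaussian", mean, sd)``, ``("binomial", p)`` or
        ``("multinomial", levels, probs)``.
    equations : :class:`Equation` per generated column (remaining wave-1
        covariates conditional on earlier ones, every exposure, every
        later-wave covariate, and the outcome), predictors restricted to
        earlier columns in the time-ordering.
    """

    spec: VariableSpec
    baseline: dict
    equations: dict
    name: str = "custom"

    def __post_init__(self):
        spec = self.spec
        for col in spec.covariate_names[0]:
            if (col in self.baseline) == (col in self.equations):
                raise ConfigError(
                    f"wave-1 covariate {col!r} needs exactly one of a baseline "
                    "law or an equation"
                )
        needed = list(spec.exposure_names) + [
            c for wave in spec.covariate_names[1:] for c in wave
        ] + [spec.outcome_name]
        missing = [c for c in needed if c not in self.equations]
        if missing:
            raise ConfigError(f"equations missing for {missing}")
        for col, eq in self.equations.items():
            tag = spec.distributions.get(col)
            if tag is not None and tag != eq.dist:
                raise ConfigError(
                    f"equation for {col!r} is {eq.dist!r} but the spec tags "
                    f"it {tag!r}"
                )
        for col, law in self.baseline.items():
            kind = law[0]
            if kind not in ("gaussian", "binomial", "multinomial"):
                raise ConfigError(f"unknown baseline law {kind!r} for {col!r}")
            if kind == "gaussian" and law[2] <= 0:
                raise ConfigError(f"baseline sd for {col!r} must be > 0")
            if kind == "binomial" and not 0 < law[1] < 1:
                raise ConfigError(f"baseline p for {col!r} must be in (0,1)")
            if kind == "multinomial":
                probs = np.asarray(law[2], dtype=float)
                if len(law[1]) != len(probs) or not np.isclose(probs.sum(), 1.0):
                    raise ConfigError(
                        f"baseline probabilities for {col!r} must match the "
                        "levels and sum to 1"
                    )

    @property
    def K(self) -> int:
        return self.spec.K

    # -- serialisation ---------------------------------------------------
    def to_dict(self) -> dict:
        eqs = {}
        for col, eq in self.equations.items():
            d = {"dist": eq.dist, "intercept": eq.intercept,
                 "terms": eq.terms}
            if eq.sd is not None:
                d["sd"] = eq.sd
            if eq.levels is not None:
                d["levels"] = list(eq.levels)
            if eq.dist == "multinomial":
                d["intercept"] = list(eq.intercept)
                d["terms"] = [dict(t) for t in eq.terms]
            else:
                d["terms"] = dict(eq.terms)
            eqs[col] = d
        return {
            "name": self.name,
            "spec": self.spec.to_dict(),
            "baseline": {c: list(law) for c, law in self.baseline.items()},
            "equations": eqs,
        }

    @classmethod
    def from_dict(cls, cfg: Mapping) -> "FixtureDesign":
        eqs = {}
        for col, d in cfg["equations"].items():
            if d["dist"] == "multinomial":
                eq = Equation(
                    dist=d["dist"], intercept=tuple(d["intercept"]),
                    terms=tuple(dict(t) for t in d["terms"]),
                    levels=tuple(d["levels"]),
                )
            else:
                eq = Equation(
                    dist=d["dist"], intercept=float(d["intercept"]),
                    terms=dict(d["terms"]), sd=d.get("sd"),
                )
            eqs[col] = eq
        baseline = {c: tuple(law) for c, law in cfg["baseline"].items()}
        return cls(
            spec=VariableSpec.from_dict(cfg["spec"]),
            baseline=baseline, equations=eqs,
            name=cfg.get("name", "custom"),
        )

    @classmethod
    def from_yaml(cls, path) -> "FixtureDesign":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


def _draw_baseline(law, n, rng):
    kind = law[0]
    if kind == "gaussian":
        return rng.normal(law[1], law[2], size=n)
    if kind == "binomial":
        return (rng.random(n) < law[1]).astype(np.int64)
    levels, probs = law[1], np.asarray(law[2], dtype=float)
    cum = np.cumsum(probs)
    cum[-1] = 1.0
    idx = (rng.random(n)[:, None] > cum[None, :]).sum(axis=1)
    return np.asarray(levels, dtype=np.int64)[idx]


def _simulate(
    design: FixtureDesign,
    n: int,
    rng: np.random.Generator,
    fixed_exposures: np.ndarray | None = None,
    base: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Walk the time-ordering L_1, A_1, ..., L_K, A_K, Y once.

    With *fixed_exposures* set, exposures come from the regime matrix
    (counterfactual mode); *base* reuses previously drawn wave-1
    covariates so regimes share identical subjects.
    """
    spec = design.spec
    if base is not None:
        frame = base.copy()
    else:
        frame = pd.DataFrame(index=range(n))
        for col in spec.covariate_names[0]:
            if col in design.baseline:
                frame[col] = _draw_baseline(design.baseline[col], n, rng)
            else:
                frame[col] = design.equations[col].draw(frame, rng)
    for t in range(1, spec.K + 1):
        if t >= 2:
            for col in spec.covariate_names[t - 1]:
                frame[col] = design.equations[col].draw(frame, rng)
        a_col = spec.exposure_names[t - 1]
        if fixed_exposures is not None:
            frame[a_col] = fixed_exposures[:, t - 1].astype(np.int64)
        else:
            frame[a_col] = design.equations[a_col].draw(frame, rng)
    frame[spec.outcome_name] = design.equations[spec.outcome_name].draw(frame, rng)
    return frame


def generate_fixture(design: FixtureDesign, n: int, seed) -> CohortTable:
    """Draw a synthetic original cohort of size *n* from *design*."""
    if n < 2:
        raise ConfigError("n must be >= 2")
    rng = np.random.default_rng(seed)
    frame = _simulate(design, n, rng)
    frame.insert(0, design.spec.id_name, np.arange(1, n + 1))
    return validate_cohort(frame, design.spec)


@dataclass
class FixtureTruth:
    """True MSM parameters of a fixture design, by Monte Carlo."""

    gamma: dict
    mc_se: dict
    coding: RegimeCoding
    n_mc: int

    def as_arrays(self):
        names = ["intercept"] + list(self.coding.labels[1:])
        return (
            names,
            np.array([self.gamma[k] for k in names]),
            np.array([self.mc_se[k] for k in names]),
        )


def true_fixture_msm(
    design: FixtureDesign,
    n_mc: int,
    seed,
    coding: RegimeCoding | None = None,
) -> FixtureTruth:
    """Monte Carlo truth for the fixture's own equations.

    Draws ``n_mc`` wave-1 covariate sets, simulates the counterfactual
    outcome under every exposure regime (exposures deterministic,
    covariate feedback simulated from the design equations), and
    regresses the stacked Y^a on the cumulative-exposure dummies.
    Monte Carlo SEs are subject-level cluster-robust (each simulated
    subject contributes one row per regime).  This path is deliberately
    independent of the fitted-generator counterfactual module so the two
    can cross-check each other.
    """
    spec = design.spec
    coding = coding or RegimeCoding.default_for(spec.K)
    rng = np.random.default_rng(seed)
    base = pd.DataFrame(index=range(n_mc))
    for col in spec.covariate_names[0]:
        if col in design.baseline:
            base[col] = _draw_baseline(design.baseline[col], n_mc, rng)
        else:
            base[col] = design.equations[col].draw(base, rng)

    regimes = list(itertools.product((0, 1), repeat=spec.K))
    ys, labels, subjects = [], [], []
    for a in regimes:
        fixed = np.tile(np.asarray(a, dtype=np.int64), (n_mc, 1))
        frame = _simulate(design, n_mc, rng, fixed_exposures=fixed, base=base)
        ys.append(frame[spec.outcome_name].to_numpy(dtype=float))
        labels.extend([coding.label(a)] * n_mc)
        subjects.append(np.arange(n_mc))
    y = np.concatenate(ys)
    X = coding.design_from_labels(labels)
    groups = np.concatenate(subjects)
    res = sm.OLS(y, X).fit(cov_type="cluster", cov_kwds={"groups": groups})
    names = coding.coef_names()
    return FixtureTruth(
        gamma=dict(zip(names, np.asarray(res.params))),
        mc_se=dict(zip(names, np.asarray(res.bse))),
        coding=coding,
        n_mc=n_mc,
    )


# ---------------------------------------------------------------------------
# Bundled designs
# ---------------------------------------------------------------------------

_DEFAULT_SIGMA_Y = 10.0  # blood-pressure-like residual scale (mm Hg)


def default_spec() -> VariableSpec:
    return VariableSpec(
        id_name="id",
        outcome_name="abp",
        exposure_names=("psw_1", "psw_2", "psw_3"),
        covariate_names=(
            ("age", "gender", "education", "smoking_1", "bmi_1"),
            ("smoking_2", "bmi_2"),
            ("smoking_3", "bmi_3"),
        ),
        distributions={
            "age": "gaussian",
            "gender": "binomial",
            "education": "multinomial",
            "smoking_1": "binomial",
            "smoking_2": "binomial",
            "smoking_3": "binomial",
            "bmi_1": "multinomial",
            "bmi_2": "multinomial",
            "bmi_3": "multinomial",
            "psw_1": "binomial",
            "psw_2": "binomial",
            "psw_3": "binomial",
            "abp": "gaussian",
        },
    )


def default_design() -> FixtureDesign:
    """Three-wave design with moderate confounding and exposure-to-
    covariate feedback on a blood-pressure-like outcome scale.

    Direct exposure effects on the outcome are 0.5 / 0.8 / 1.0 mm Hg per
    wave; feedback (exposure raising next-wave smoking and body-mass
    category, both of which raise the outcome and future exposure) adds
    an indirect component, so true cumulative effects are of order
    0-3 mm Hg against a residual SD of 10 mm Hg.
    """
    spec = default_spec()
    eqs = {
        "smoking_1": Equation(
            "binomial", -1.41,
            {"age": 0.01, "gender": 0.2, "education==2": -0.3},
        ),
        "bmi_1": Equation(
            "multinomial",
            (-1.57, -2.60),
            (
                {"age": 0.02, "gender": 0.3},
                {"age": 0.01, "smoking_1": 0.3},
            ),
            levels=(0, 1, 2),
        ),
        "psw_1": Equation(
            "binomial", -1.23,
            {"age": 0.01, "gender": 0.15, "smoking_1": 0.7,
             "bmi_1==1": 0.2, "bmi_1==2": 0.1,
             "education==1": -0.15, "education==2": -0.3},
        ),
        "smoking_2": Equation(
            "binomial", -2.0,
            {"smoking_1": 2.0, "psw_1": 0.8, "age": 0.005},
        ),
        "bmi_2": Equation(
            "multinomial",
            (-1.2, -2.4),
            (
                {"bmi_1==1": 2.2, "bmi_1==2": 0.5, "psw_1": 0.4, "gender": 0.2},
                {"bmi_1==1": 0.8, "bmi_1==2": 2.8, "psw_1": 0.3, "age": 0.01},
            ),
            levels=(0, 1, 2),
        ),
        "psw_2": Equation(
            "binomial", -1.5,
            {"psw_1": 1.2, "age": 0.008, "gender": 0.15, "smoking_2": 0.7,
             "bmi_2==1": 0.2, "bmi_2==2": 0.15, "education==2": -0.2},
        ),
        "smoking_3": Equation(
            "binomial", -2.0,
            {"smoking_2": 2.0, "psw_2": 0.8, "age": 0.005},
        ),
        "bmi_3": Equation(
            "multinomial",
            (-1.2, -2.4),
            (
                {"bmi_2==1": 2.2, "bmi_2==2": 0.5, "psw_2": 0.4, "gender": 0.2},
                {"bmi_2==1": 0.8, "bmi_2==2": 2.8, "psw_2": 0.3, "age": 0.01},
            ),
            levels=(0, 1, 2),
        ),
        "psw_3": Equation(
            "binomial", -1.5,
            {"psw_2": 1.2, "psw_1": 0.4, "age": 0.008, "gender": 0.15,
             "smoking_3": 0.7, "bmi_3==1": 0.2, "bmi_3==2": 0.15,
             "education==2": -0.2},
        ),
        "abp": Equation(
            "gaussian", 110.0,
            {"age": 0.25, "gender": 3.0, "education==2": -1.0,
             "smoking_1": 1.5, "smoking_2": 1.5, "smoking_3": 4.0,
             "bmi_1==1": 0.5, "bmi_3==1": 2.0, "bmi_3==2": 1.0,
             "psw_1": 0.5, "psw_2": 0.8, "psw_3": 1.0},
            sd=_DEFAULT_SIGMA_Y,
        ),
    }
    baseline = {
        "age": ("gaussian", 41.0, 9.0),
        "gender": ("binomial", 0.41),
        "education": ("multinomial", (0, 1, 2), (0.30, 0.35, 0.35)),
    }
    return FixtureDesign(spec=spec, baseline=baseline, equations=eqs,
                         name="default")


def _strip_exposure_terms(eq: Equation, exposures) -> Equation:
    """Remove every term referencing an exposure column."""

    def references_exposure(key):
        tokens = re.split(r"\*|==|>", key)
        return any(tok in exposures for tok in tokens)

    def clean(terms):
        return {k: v for k, v in terms.items() if not references_exposure(k)}

    if eq.dist == "multinomial":
        return Equation(eq.dist, eq.intercept,
                        tuple(clean(t) for t in eq.terms),
                        levels=eq.levels)
    return Equation(eq.dist, eq.intercept, clean(eq.terms), sd=eq.sd)


def null_design() -> FixtureDesign:
    """Default structure but with every exposure effect removed: the
    exposure influences neither covariates nor outcome, so all true MSM
    contrasts are 0."""
    base = default_design()
    exposures = base.spec.exposure_names
    eqs = {
        col: (_strip_exposure_terms(eq, exposures)
              if col not in exposures else eq)
        for col, eq in base.equations.items()
    }
    return FixtureDesign(spec=base.spec, baseline=base.baseline,
                         equations=eqs, name="null")


def additive_design(theta: float = 1.0) -> FixtureDesign:
    """No exposure-to-covariate feedback and an outcome that is linear
    with coefficient *theta* on each exposure wave, so the true chronic
    effect is exactly 3 theta (closed form)."""
    base = default_design()
    exposures = base.spec.exposure_names
    eqs = {}
    for col, eq in base.equations.items():
        if col == base.spec.outcome_name:
            terms = dict(_strip_exposure_terms(eq, exposures).terms)
            for a in exposures:
                terms[a] = theta
            eqs[col] = Equation(eq.dist, eq.intercept, terms, sd=eq.sd)
        elif col in exposures:
            eqs[col] = eq
        else:
            eqs[col] = _strip_exposure_terms(eq, exposures)
    return FixtureDesign(spec=base.spec, baseline=base.baseline,
                         equations=eqs, name=f"additive(theta={theta})")


def nonlinear_design() -> FixtureDesign:
    """Default design plus non-linear features (an age threshold and
    exposure-by-smoking interactions) that a main-terms parametric
    generator cannot represent; used to stress the random-forest
    plasmode algorithm."""
    base = default_design()
    eqs = dict(base.equations)
    y = eqs["abp"]
    terms = dict(y.terms)
    terms.update({"age>50": 3.0, "psw_3*smoking_3": 2.5})
    eqs["abp"] = Equation(y.dist, y.intercept, terms, sd=y.sd)
    s3 = eqs["smoking_3"]
    terms3 = dict(s3.terms)
    terms3["psw_2*smoking_2"] = 0.8
    eqs["smoking_3"] = Equation(s3.dist, s3.intercept, terms3)
    return FixtureDesign(spec=base.spec, baseline=base.baseline,
                         equations=eqs, name="nonlinear")


BUNDLED_DESIGNS = {
    "default": default_design,
    "null": null_design,
    "nonlinear": nonlinear_design,
}
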