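"""Shared fixtures: small cohorts, fitted generators, discrete oracles."""

import numpy as np
import pandas as pd
import pytest

import longplasmode as lp
from longplasmode.fixture import Equation, FixtureDesign


@pytest.fixture(scope="session")
def default_design():
    return lp.default_design()


@pytest.fixture(scope="session")
def cohort_small(default_design):
    """A 600-subject synthetic original cohort (fast fitting)."""
    return lp.generate_fixture(default_design, 600, seed=7)


@pytest.fixture(scope="session")
def param_gen(cohort_small):
    return lp.fit_parametric_generators(cohort_small)


def binary_l_spec(K: int, outcome_dist: str = "gaussian") -> lp.VariableSpec:
    """Minimal K-wave spec: one binary covariate per wave."""
    return lp.VariableSpec(
        id_name="id",
        outcome_name="y",
        exposure_names=tuple(f"a{t}" for t in range(1, K + 1)),
        covariate_names=tuple((f"l{t}",) for t in range(1, K + 1)),
        distributions={
            "y": outcome_dist,
            **{f"a{t}": "binomial" for t in range(1, K + 1)},
            **{f"l{t}": "binomial" for t in range(1, K + 1)},
        },
    )


def binary_l_design(K: int) -> FixtureDesign:
    """Minimal K-wave design with feedback a_{t-1} -> l_t and a linear
    outcome; used where the full mixed-covariate design is overkill."""
    spec = binary_l_spec(K)
    eqs = {}
    for t in range(1, K + 1):
        terms_a = {f"l{t}": 0.8}
        if t > 1:
            terms_a[f"a{t - 1}"] = 0.9
        eqs[f"a{t}"] = Equation("binomial", -0.5, terms_a)
        if t > 1:
            eqs[f"l{t}"] = Equation(
                "binomial", -0.6, {f"l{t - 1}": 1.2, f"a{t - 1}": 0.7}
            )
    y_terms = {f"a{t}": 1.0 for t in range(1, K + 1)}
    y_terms.update({f"l{t}": 1.5 for t in range(1, K + 1)})
    eqs["y"] = Equation("gaussian", 10.0, y_terms, sd=3.0)
    return FixtureDesign(
        spec=spec, baseline={"l1": ("binomial", 0.4)}, equations=eqs,
        name=f"binary-l-K{K}",
    )


@pytest.fixture(scope="session")
def discrete_k1_cohort():
    """K=1, binary L, binary A, continuous Y — the saturated-model
    playground where all estimators collapse to standardization."""
    rng = np.random.default_rng(42)
    n = 400
    L = rng.integers(0, 2, n)
    pA = np.where(L == 1, 0.7, 0.3)
    A = (rng.random(n) < pA).astype(int)
    Y = 1.0 + 2.0 * A + 1.5 * L + 0.8 * A * L + rng.normal(0, 1, n)
    spec = binary_l_spec(1)
    df = pd.DataFrame({"id": np.arange(n), "l1": L, "a1": A, "y": Y})
    return lp.validate_cohort(df, spec)


def standardization_oracle(cohort):
    """Brute-force standardization on K=1 discrete data:
    sum_l E-hat(Y | A=a, L=l) P-hat(L=l), independent of the estimator
    implementations."""
    df = cohort.df
    psi = {}
    for a in (0, 1):
        tot = 0.0
        for l in sorted(df["l1"].unique()):
            cell = df[(df["a1"] == a) & (df["l1"] == l)]
            tot += cell["y"].mean() * (df["l1"] == l).mean()
        psi[a] = tot
    return psi
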