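"""Parametric plasmode: generator fitting and replicate generation."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import longplasmode as lp
from longplasmode.errors import (
    CompatibilityError,
    ConfigError,
    DegenerateModelError,
    FittingError,
)

from conftest import binary_l_spec


@pytest.fixture(scope="module")
def discrete_k1():
    """K=1, binary L and A with known cell proportions, continuous Y."""
    rng = np.random.default_rng(5)
    n = 500
    L = rng.integers(0, 2, n)
    A = (rng.random(n) < np.where(L == 1, 0.65, 0.25)).astype(int)
    Y = 2.0 + A + 0.5 * L + rng.normal(0, 1, n)
    df = pd.DataFrame({"id": range(n), "l1": L, "a1": A, "y": Y})
    return lp.validate_cohort(df, binary_l_spec(1))


class TestFitParametricGenerators:
    def test_saturated_logistic_reproduces_cell_proportions(self, discrete_k1):
        """With one binary covariate, the main-terms logistic for A_1 is
        saturated, so fitted P(A=1|L=l) equals the tabulated proportion."""
        gen = lp.fit_parametric_generators(discrete_k1)
        df = discrete_k1.df
        cm = gen.models["a1"]
        for l in (0, 1):
            fitted = expit(cm.beta[0] + cm.beta[1] * l)
            empirical = df.loc[df.l1 == l, "a1"].mean()
            assert fitted == pytest.approx(empirical, abs=1e-6)

    def test_residual_sd_uses_n_minus_p(self, discrete_k1):
        gen = lp.fit_parametric_generators(discrete_k1)
        df, cm = discrete_k1.df, gen.models["y"]
        X = np.column_stack([np.ones(len(df)), df.a1, df.l1])
        resid = df.y.to_numpy() - X @ cm.beta
        expected = np.sqrt((resid**2).sum() / (len(df) - 3))
        assert cm.sd == pytest.approx(expected, rel=1e-10)
        log = next(l for l in gen.fitting_log if l["variable"] == "y")
        assert "n - p" in log["sd_denominator"]

    def test_predictor_subset_respected(self, cohort_small):
        gen = lp.fit_parametric_generators(
            cohort_small, predictor_subsets={"psw_2": ["psw_1"]}
        )
        assert gen.models["psw_2"].cols == ("psw_1",)
        # subsets outside the admissible history are rejected
        with pytest.raises(ConfigError, match="time-admissible"):
            lp.fit_parametric_generators(
                cohort_small, predictor_subsets={"psw_1": ["psw_2"]}
            )

    def test_separation_raises_fitting_error(self):
        n = 60
        L = np.repeat([0, 1], n // 2)
        A = L.copy()  # perfectly separated
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"id": range(n), "l1": L, "a1": A,
                           "y": rng.normal(size=n)})
        cohort = lp.validate_cohort(df, binary_l_spec(1))
        with pytest.raises(FittingError):
            lp.fit_parametric_generators(cohort)

    def test_constant_gaussian_target_raises(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({
            "id": range(40),
            "l1": rng.integers(0, 2, 40),
            "a1": rng.integers(0, 2, 40),
            "y": np.ones(40),
        })
        cohort = lp.validate_cohort(df, binary_l_spec(1))
        with pytest.raises(DegenerateModelError):
            lp.fit_parametric_generators(cohort)

    def test_every_model_logged_as_converged(self, param_gen):
        assert len(param_gen.fitting_log) == len(param_gen.models)
        assert all(log.get("converged", True) for log in param_gen.fitting_log)


class TestGenerateParametric:
    def test_shapes_and_validation(self, param_gen, cohort_small):
        tables = lp.generate_parametric(param_gen, cohort_small, m=120, J=4,
                                        seed=2)
        assert len(tables) == 4
        for t in tables:
            assert t.n == 120
            assert isinstance(t, lp.CohortTable)  # re-validated on the way out
            assert list(t.df.columns) == cohort_small.spec.all_columns()

    def test_seeded_determinism_and_independent_replicates(
        self, param_gen, cohort_small
    ):
        t1 = lp.generate_parametric(param_gen, cohort_small, m=100, J=2, seed=8)
        t2 = lp.generate_parametric(param_gen, cohort_small, m=100, J=2, seed=8)
        pd.testing.assert_frame_equal(t1[0].df, t2[0].df)
        pd.testing.assert_frame_equal(t1[1].df, t2[1].df)
        assert not t1[0].df.equals(t1[1].df)

    def test_zero_coefficient_exposure_model_gives_half_prevalence(
        self, param_gen, cohort_small
    ):
        """Forcing every exposure-model coefficient to 0 makes each A_t
        a fair coin (expit(0) = 0.5) regardless of history."""
        import copy

        gen = copy.deepcopy(param_gen)
        for a in cohort_small.spec.exposure_names:
            gen.models[a].beta = np.zeros_like(gen.models[a].beta)
        tables = lp.generate_parametric(gen, cohort_small, m=500, J=4, seed=3)
        pooled = pd.concat([t.df for t in tables])
        for a in cohort_small.spec.exposure_names:
            prev = pooled[a].mean()
            se = np.sqrt(0.25 / len(pooled))
            assert abs(prev - 0.5) < 3 * se, a

    def test_l1_resampling_consistency(self, param_gen, cohort_small):
        """Pooled over replicates, the wave-1 covariates keep the input
        cohort's empirical distribution."""
        tables = lp.generate_parametric(param_gen, cohort_small, m=400, J=10,
                                        seed=4)
        pooled = pd.concat([t.df for t in tables])
        src = cohort_small.df
        m_tot = len(pooled)
        p = src["smoking_1"].mean()
        assert abs(pooled["smoking_1"].mean() - p) < 3 * np.sqrt(
            p * (1 - p) / m_tot
        )
        assert pooled["age"].mean() == pytest.approx(
            src["age"].mean(),
            abs=3 * src["age"].std() / np.sqrt(m_tot),
        )
        assert set(pooled["education"]) <= set(src["education"])

    def test_k1_joint_cells_match_resample_times_conditional(
        self, discrete_k1
    ):
        """Simulated (L1, A1) cell frequencies equal the empirical L1
        frequencies times the fitted conditional law, the factorized
        joint the generator is supposed to sample from."""
        gen = lp.fit_parametric_generators(discrete_k1)
        tables = lp.generate_parametric(gen, discrete_k1, m=500, J=40, seed=6)
        pooled = pd.concat([t.df for t in tables])
        df, cm = discrete_k1.df, gen.models["a1"]
        n_tot = len(pooled)
        for l in (0, 1):
            pl = (df.l1 == l).mean()
            pa1 = expit(cm.beta[0] + cm.beta[1] * l)
            for a in (0, 1):
                expected = pl * (pa1 if a == 1 else 1 - pa1)
                obs = ((pooled.l1 == l) & (pooled.a1 == a)).mean()
                mc_se = np.sqrt(expected * (1 - expected) / n_tot)
                assert abs(obs - expected) < 3 * mc_se, (l, a)

    def test_spec_mismatch_rejected(self, param_gen):
        other = lp.generate_fixture(lp.null_design(), 100, seed=1)
        other = lp.CohortTable(
            df=other.df.rename(columns={"abp": "bp"}),
            spec=other.spec, levels=other.levels,
        )
        rng_spec = binary_l_spec(1)
        df = pd.DataFrame({"id": range(10), "l1": [0, 1] * 5,
                           "a1": [0, 1] * 5, "y": np.arange(10.0)})
        mism = lp.validate_cohort(df, rng_spec)
        with pytest.raises(CompatibilityError):
            lp.generate_parametric(param_gen, mism, m=5, J=1, seed=0)

    def test_m_above_n_warns(self, param_gen, cohort_small):
        with pytest.warns(UserWarning, match="exceeds"):
            lp.generate_parametric(param_gen, cohort_small,
                                   m=cohort_small.n + 10, J=1, seed=0)
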