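"""MSM estimators: weights, IPTW, g-computation, TMLE, standard models."""

import numpy as np
import pandas as pd
import pytest

import longplasmode as lp
from longplasmode.errors import EstimationError, PositivityError
from longplasmode.estimators import _SequentialEngine

from conftest import binary_l_spec, standardization_oracle

SATURATED = lp.WorkingModels(saturated=True)


def tiny_discrete_cohort():
    """8 subjects with exact cell counts: P(A=1) = 0.5 marginally,
    P(A=1|L=1) = 0.75, P(A=1|L=0) = 0.25."""
    rows = []
    for l, a, k in [(1, 1, 3), (1, 0, 1), (0, 1, 1), (0, 0, 3)]:
        rows += [(l, a)] * k
    df = pd.DataFrame(rows, columns=["l1", "a1"])
    df["id"] = range(len(df))
    df["y"] = np.arange(len(df), dtype=float)
    return lp.validate_cohort(df, binary_l_spec(1))


class TestStabilizedWeights:
    def test_identical_numerator_denominator_gives_unit_weights(self):
        """Excluding every covariate from the denominator makes the two
        models identical, so each ratio (hence each weight) is 1."""
        cohort = tiny_discrete_cohort()
        wv = lp.compute_stabilized_weights(
            cohort, working=lp.WorkingModels(g_exclude=("l1",))
        )
        assert np.allclose(wv.sw, 1.0, atol=1e-8)

    def test_hand_computed_weight_on_exact_cells(self):
        """Subject with a=1, l=0: sw = P(A=1) / P(A=1|L=0) = 0.5/0.25 = 2."""
        cohort = tiny_discrete_cohort()
        wv = lp.compute_stabilized_weights(cohort)
        df = cohort.df
        sw = pd.Series(wv.sw, index=df.index)
        case = sw[(df.a1 == 1) & (df.l1 == 0)]
        assert np.allclose(case, 2.0, atol=1e-6)
        case2 = sw[(df.a1 == 1) & (df.l1 == 1)]  # 0.5 / 0.75
        assert np.allclose(case2, 2.0 / 3.0, atol=1e-6)

    def test_mean_weight_near_one_on_simulated_cohort(self, default_design):
        cohort = lp.generate_fixture(default_design, 3000, seed=31)
        wv = lp.compute_stabilized_weights(cohort)
        assert abs(wv.diagnostics["mean"] - 1.0) < 0.05

    def test_truncation_applied_and_logged(self, default_design):
        cohort = lp.generate_fixture(default_design, 800, seed=32)
        wv = lp.compute_stabilized_weights(cohort, truncation=(5, 95))
        trunc = wv.diagnostics["truncation"]
        assert trunc["percentiles"] == (5, 95)
        lo, hi = trunc["bounds"]
        assert wv.sw.min() >= lo - 1e-12 and wv.sw.max() <= hi + 1e-12


class TestIPTW:
    def test_unit_weights_reduce_to_ols(self):
        cohort = tiny_discrete_cohort()
        est = lp.estimate_iptw(
            cohort, working=lp.WorkingModels(g_exclude=("l1",))
        )
        df = cohort.df
        crude = (df.loc[df.a1 == 1, "y"].mean()
                 - df.loc[df.a1 == 0, "y"].mean())
        assert est.estimate[1] == pytest.approx(crude, abs=1e-8)

    def test_saturated_equals_standardization(self, discrete_k1_cohort):
        psi = standardization_oracle(discrete_k1_cohort)
        est = lp.estimate_iptw(discrete_k1_cohort, working=SATURATED)
        assert est.estimate[0] == pytest.approx(psi[0], abs=1e-8)
        assert est.estimate[1] == pytest.approx(psi[1] - psi[0], abs=1e-8)

    def test_missing_category_rejected(self):
        rng = np.random.default_rng(0)
        n = 40
        df = pd.DataFrame({
            "id": range(n),
            "l1": rng.integers(0, 2, n), "l2": rng.integers(0, 2, n),
            "l3": rng.integers(0, 2, n),
            # only never and chronic observed
            "a1": [0, 1] * (n // 2), "a2": [0, 1] * (n // 2),
            "a3": [0, 1] * (n // 2),
            "y": rng.normal(size=n),
        })
        cohort = lp.validate_cohort(df, binary_l_spec(3))
        with pytest.raises(EstimationError, match="absent"):
            lp.estimate_iptw(cohort)


class TestGComp:
    def test_k1_saturated_equals_standardization(self, discrete_k1_cohort):
        psi = standardization_oracle(discrete_k1_cohort)
        est = lp.estimate_gcomp(discrete_k1_cohort, working=SATURATED,
                                n_boot=10, seed=0)
        assert est.estimate[0] == pytest.approx(psi[0], abs=1e-8)
        assert est.estimate[1] == pytest.approx(psi[1] - psi[0], abs=1e-8)

    def test_null_outcome_near_zero(self, default_design):
        """Outcome independent of exposure in truth and fitted models."""
        cohort = lp.generate_fixture(lp.null_design(), 5000, seed=41)
        est = lp.estimate_gcomp(cohort, n_boot=20, seed=1)
        for lab, g, se in zip(est.names[1:], est.estimate[1:], est.se[1:]):
            assert abs(g) < 3.5 * se, lab

    def test_percentile_ci_option(self, discrete_k1_cohort):
        est = lp.estimate_gcomp(discrete_k1_cohort, n_boot=40, seed=2,
                                ci_method="percentile")
        assert est.se_method == "bootstrap-percentile"
        assert (est.ci_low <= est.estimate).all()
        assert (est.estimate <= est.ci_high).all()


class TestTMLE:
    def test_epsilon_zero_identity(self, param_gen, cohort_small):
        """Forcing every fluctuation coefficient to zero reproduces the
        g-computation point estimates exactly."""
        table = lp.generate_parametric(param_gen, cohort_small, m=300, J=1,
                                       seed=51)[0]
        gc = lp.estimate_gcomp(table, n_boot=2, seed=0)
        tm = lp.estimate_tmle(table, epsilon_override=0.0)
        np.testing.assert_allclose(tm.estimate, gc.estimate, rtol=0,
                                   atol=1e-12)

    def test_saturated_equals_standardization(self, discrete_k1_cohort):
        psi = standardization_oracle(discrete_k1_cohort)
        est = lp.estimate_tmle(discrete_k1_cohort, working=SATURATED)
        assert est.estimate[0] == pytest.approx(psi[0], abs=1e-8)
        assert est.estimate[1] == pytest.approx(psi[1] - psi[0], abs=1e-8)
        # with a saturated Q the score is already solved: eps ~ 0
        eps = [e for v in est.diagnostics["epsilon"].values() for e in v]
        assert max(abs(e) for e in eps) < 1e-8

    def test_zero_probability_raises_positivity_error(
        self, discrete_k1_cohort
    ):
        coding = lp.RegimeCoding.saturated(1)
        engine = _SequentialEngine(discrete_k1_cohort, coding,
                                   lp.WorkingModels())
        gprobs = np.zeros((discrete_k1_cohort.n, 1))
        with pytest.raises(PositivityError, match="truncat"):
            engine.run(fluctuate=True, gprobs=gprobs)

    def test_bootstrap_se_method(self, discrete_k1_cohort):
        est = lp.estimate_tmle(discrete_k1_cohort, se_method="bootstrap-SD",
                               n_boot=20, seed=3)
        assert est.se_method == "bootstrap-SD"
        assert (est.se > 0).all()


class TestStandard:
    def test_no_covariates_gives_crude_category_means(self):
        rng = np.random.default_rng(7)
        n = 200
        spec = lp.VariableSpec(
            id_name="id", outcome_name="y",
            exposure_names=("a1", "a2", "a3"),
            covariate_names=((), (), ()),
            distributions={"y": "gaussian", "a1": "binomial",
                           "a2": "binomial", "a3": "binomial"},
        )
        df = pd.DataFrame({
            "id": range(n),
            "a1": rng.integers(0, 2, n), "a2": rng.integers(0, 2, n),
            "a3": rng.integers(0, 2, n), "y": rng.normal(size=n),
        })
        cohort = lp.validate_cohort(df, spec)
        est = lp.estimate_standard(cohort, adjustment="baseline")
        labels = [
            lp.code_exposure_pattern(t).label
            for t in df[["a1", "a2", "a3"]].itertuples(index=False)
        ]
        means = df.assign(c=labels).groupby("c")["y"].mean()
        assert est.estimate[0] == pytest.approx(means["never"], abs=1e-8)
        for i, lab in enumerate(est.names[1:], start=1):
            assert est.estimate[i] == pytest.approx(
                means[lab] - means["never"], abs=1e-8
            ), lab

    def test_unknown_adjustment_rejected(self, discrete_k1_cohort):
        with pytest.raises(EstimationError, match="adjustment"):
            lp.estimate_standard(discrete_k1_cohort, adjustment="everything")


class TestSharedInvariants:
    @pytest.mark.parametrize("method", ["iptw", "gcomp", "tmle",
                                        "std-baseline", "std-tv"])
    def test_location_shift_moves_intercept_only(self, method, param_gen,
                                                 cohort_small):
        table = lp.generate_parametric(param_gen, cohort_small, m=250, J=1,
                                       seed=61)[0]
        shifted = lp.CohortTable(
            df=table.df.assign(abp=table.df["abp"] + 100.0),
            spec=table.spec, levels=table.levels,
        )

        def run(c):
            if method == "iptw":
                return lp.estimate_iptw(c)
            if method == "gcomp":
                return lp.estimate_gcomp(c, n_boot=2, seed=0)
            if method == "tmle":
                return lp.estimate_tmle(c)
            adj = ("baseline" if method == "std-baseline"
                   else "baseline+timevarying")
            return lp.estimate_standard(c, adjustment=adj)

        e0, e1 = run(table), run(shifted)
        if method.startswith("std"):
            # covariate-adjusted intercept is not gamma0; contrasts only
            np.testing.assert_allclose(e1.estimate[1:], e0.estimate[1:],
                                       atol=1e-7)
        else:
            assert e1.estimate[0] - e0.estimate[0] == pytest.approx(
                100.0, abs=1e-7
            )
            np.testing.assert_allclose(e1.estimate[1:], e0.estimate[1:],
                                       atol=1e-7)

    @pytest.mark.parametrize("method", ["iptw", "gcomp", "tmle"])
    def test_row_order_invariance(self, method, param_gen, cohort_small):
        table = lp.generate_parametric(param_gen, cohort_small, m=250, J=1,
                                       seed=62)[0]
        rng = np.random.default_rng(3)
        perm = rng.permutation(table.n)
        permuted = lp.CohortTable(
            df=table.df.iloc[perm].reset_index(drop=True),
            spec=table.spec, levels=table.levels,
        )

        def point(c):
            if method == "iptw":
                return lp.estimate_iptw(c).estimate
            if method == "gcomp":
                return lp.estimate_gcomp(c, n_boot=2, seed=0).estimate
            return lp.estimate_tmle(c).estimate

        np.testing.assert_allclose(point(permuted), point(table), atol=1e-7)
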