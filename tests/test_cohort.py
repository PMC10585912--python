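"""Schema validation and cumulative-exposure coding."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import longplasmode as lp
from longplasmode.errors import (
    DistributionError,
    MissingDataError,
    SchemaError,
    UnsupportedCodingError,
)

from conftest import binary_l_spec


def _k1_df(n=6):
    return pd.DataFrame({
        "id": range(n),
        "l1": [0, 1, 0, 1, 0, 1][:n],
        "a1": [0, 1, 1, 0, 0, 1][:n],
        "y": np.linspace(0.0, 1.0, n),
    })


class TestVariableSpec:
    def test_duplicate_role_rejected(self):
        with pytest.raises(SchemaError, match="more than one role"):
            lp.VariableSpec(
                id_name="id", outcome_name="y",
                exposure_names=("a1",), covariate_names=(("a1",),),
                distributions={"y": "gaussian", "a1": "binomial"},
            )

    def test_unknown_distribution_tag_rejected(self):
        with pytest.raises(DistributionError, match="poisson"):
            lp.VariableSpec(
                id_name="id", outcome_name="y",
                exposure_names=("a1",), covariate_names=(("l1",),),
                distributions={"y": "gaussian", "a1": "binomial",
                               "l1": "poisson"},
            )

    def test_exposure_must_be_binomial(self):
        with pytest.raises(DistributionError, match="binomial"):
            lp.VariableSpec(
                id_name="id", outcome_name="y",
                exposure_names=("a1",), covariate_names=(("l1",),),
                distributions={"y": "gaussian", "a1": "gaussian",
                               "l1": "binomial"},
            )

    def test_history_helpers(self):
        spec = binary_l_spec(3)
        assert spec.K == 3
        assert spec.covariates_through(2) == ["l1", "l2"]
        assert spec.exposures_through(2) == ["a1", "a2"]

    def test_yaml_round_trip(self, tmp_path):
        spec = binary_l_spec(2)
        path = tmp_path / "spec.yml"
        spec.to_yaml(path)
        assert lp.VariableSpec.from_yaml(path) == spec


class TestValidateCohort:
    def test_valid_table_accepted(self):
        cohort = lp.validate_cohort(_k1_df(), binary_l_spec(1))
        assert cohort.n == 6
        assert cohort.levels["a1"] == [0, 1]

    def test_missing_value_rejected(self):
        df = _k1_df()
        df.loc[2, "l1"] = np.nan
        with pytest.raises(MissingDataError, match="missing"):
            lp.validate_cohort(df, binary_l_spec(1))

    def test_nonbinary_exposure_rejected(self):
        df = _k1_df()
        df.loc[0, "a1"] = 2
        with pytest.raises(DistributionError, match="outside"):
            lp.validate_cohort(df, binary_l_spec(1))

    def test_missing_column_rejected(self):
        with pytest.raises(SchemaError, match="missing columns"):
            lp.validate_cohort(_k1_df().drop(columns=["l1"]), binary_l_spec(1))

    def test_constant_exposure_rejected(self):
        df = _k1_df()
        df["a1"] = 1
        with pytest.raises(DistributionError, match="constant"):
            lp.validate_cohort(df, binary_l_spec(1))

    def test_frozen_levels_reject_unknown(self):
        spec = lp.VariableSpec(
            id_name="id", outcome_name="y", exposure_names=("a1",),
            covariate_names=(("l1",),),
            distributions={"y": "gaussian", "a1": "binomial",
                           "l1": "multinomial"},
        )
        df = _k1_df()
        df["l1"] = [0, 1, 2, 0, 1, 2]
        cohort = lp.validate_cohort(df, spec)
        assert cohort.levels["l1"] == [0, 1, 2]
        df2 = df.copy()
        df2["l1"] = [0, 1, 3, 0, 1, 3]
        with pytest.raises(DistributionError, match="unknown levels"):
            lp.validate_cohort(df2, spec, levels=cohort.levels)
        # a replicate that dropped a level still validates against the
        # frozen set
        df3 = df.copy()
        df3["l1"] = [0, 1, 0, 1, 0, 1]
        assert lp.validate_cohort(df3, spec, levels=cohort.levels).n == 6


PUBLISHED_MAPPING = {
    (0, 0, 0): "never",
    (0, 1, 0): "intermittent",
    (1, 0, 1): "intermittent",
    (1, 0, 0): "cessation",
    (1, 1, 0): "cessation",
    (0, 1, 1): "onset",
    (0, 0, 1): "onset",
    (1, 1, 1): "chronic",
}


class TestExposureCoding:
    @pytest.mark.parametrize("pattern,label", PUBLISHED_MAPPING.items())
    def test_published_mapping(self, pattern, label):
        assert lp.code_exposure_pattern(pattern).label == label

    def test_total_on_all_patterns_with_right_multiplicities(self):
        counts = {}
        for p in itertools.product((0, 1), repeat=3):
            lab = lp.code_exposure_pattern(p).label
            counts[lab] = counts.get(lab, 0) + 1
        assert counts == {"never": 1, "intermittent": 2, "cessation": 2,
                          "onset": 2, "chronic": 1}

    def test_wrong_length_rejected(self):
        with pytest.raises(UnsupportedCodingError):
            lp.code_exposure_pattern((0, 1))

    def test_nonbinary_rejected(self):
        with pytest.raises(DistributionError):
            lp.code_exposure_pattern((0, 2, 1))

    @pytest.mark.parametrize("label,dummies", [
        ("never", (0, 0, 0, 0)),
        ("intermittent", (1, 0, 0, 0)),
        ("cessation", (0, 1, 0, 0)),
        ("onset", (0, 0, 1, 0)),
        ("chronic", (0, 0, 0, 1)),
    ])
    def test_category_dummies(self, label, dummies):
        pattern = next(p for p, lab in PUBLISHED_MAPPING.items()
                       if lab == label)
        cat = lp.code_exposure_pattern(pattern)
        assert lp.category_dummies(cat) == dummies
        # exactly zero or one dummy is set
        assert sum(cat.dummies) in (0, 1)


class TestRegimeCodingProperties:
    @given(st.integers(1, 5).flatmap(
        lambda k: st.tuples(*([st.sampled_from([0, 1])] * k))
    ))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_saturated_coding_is_total_and_consistent(self, regime):
        """Any binary regime of any supported length gets exactly one
        label, and its dummy row points back to that label."""
        coding = lp.RegimeCoding.saturated(len(regime))
        lab = coding.label(regime)
        d = coding.dummies(regime)
        assert d.sum() == (0 if lab == "never" else 1)
        if lab != "never":
            assert coding.labels[1:][int(np.argmax(d))] == lab

    @given(st.tuples(st.sampled_from([0, 1]), st.sampled_from([0, 1]),
                     st.sampled_from([0, 1])))
    @settings(max_examples=16, deadline=None, derandomize=True)
    def test_cumulative_coding_total_on_three_wave_patterns(self, pattern):
        cat = lp.code_exposure_pattern(pattern)
        assert cat.label in PUBLISHED_MAPPING.values()
        assert sum(cat.dummies) == (0 if cat.label == "never" else 1)


class TestRegimeCoding:
    def test_saturated_labels_and_reference(self):
        coding = lp.RegimeCoding.saturated(2)
        assert coding.labels[0] == "never"
        assert len(coding.labels) == 4
        assert coding.label((0, 0)) == "never"
        assert (coding.dummies((0, 0)) == 0).all()
        assert coding.dummies((1, 1)).sum() == 1

    def test_default_for_k3_is_cumulative(self):
        from longplasmode.cohort import CUMULATIVE_LABELS

        coding = lp.RegimeCoding.default_for(3)
        assert coding.labels == CUMULATIVE_LABELS
        assert coding.label((1, 0, 1)) == "intermittent"

    def test_design_from_labels(self):
        coding = lp.RegimeCoding.default_for(3)
        X = coding.design_from_labels(["never", "chronic"])
        assert X.shape == (2, 5)
        assert X[0].tolist() == [1, 0, 0, 0, 0]
        assert X[1].tolist() == [1, 0, 0, 0, 1]
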