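"""Longitudinal cohort schema, validation and cumulative-exposure coding.

The data model is a wide-format table with one row per subject, the
time-ordering (L_1, A_1, L_2, A_2, ..., L_K, A_K, Y): covariates L_t are
measured before the binary exposure A_t at each wave, and a single
continuous outcome Y closes the follow-up.  A :class:`VariableSpec` names
the columns and their roles; :func:`validate_cohort` enforces the schema
(complete data, binary exposures, frozen categorical level sets) and
returns a :class:`CohortTable` that downstream modules accept.

For the canonical three-wave design, an exposure history (a_1, a_2, a_3)
is summarised into five cumulative-exposure categories — never,
intermittent, cessation, onset, chronic — which form the dummy coding of
the marginal structural model E[Y^a] = γ0 + γ1·intermittent +
γ2·cessation + γ3·onset + γ4·chronic.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import (
    DistributionError,
    MissingDataError,
    SchemaError,
    UnsupportedCodingError,
)

ADMITTED_DISTRIBUTIONS = ("gaussian", "binomial", "multinomial")

#: Published mapping of the 8 three-wave exposure patterns to 5 categories.
CUMULATIVE_LABELS = ("never", "intermittent", "cessation", "onset", "chronic")
_K3_CATEGORY = {
    (0, 0, 0): "never",
    (0, 1, 0): "intermittent",
    (1, 0, 1): "intermittent",
    (1, 0, 0): "cessation",
    (1, 1, 0): "cessation",
    (0, 1, 1): "onset",
    (0, 0, 1): "onset",
    (1, 1, 1): "chronic",
}


@dataclass(frozen=True)
class VariableSpec:
    """Names, roles and distribution tags of a longitudinal cohort.

    Parameters
    ----------
    id_name : str
        Subject identifier column.
    outcome_name : str
        Final continuous outcome column (Y).
    exposure_names : sequence of str
        One binary exposure column per wave, A_1..A_K; K is their count.
    covariate_names : sequence of sequences of str
        Covariate columns per wave, L_1..L_K.  Wave 1 may include
        time-fixed covariates (e.g. gender, age, education).
    distributions : mapping str -> str
        Per-column tag: "gaussian", "binomial" or "multinomial".
    """

    id_name: str
    outcome_name: str
    exposure_names: tuple
    covariate_names: tuple
    distributions: Mapping[str, str]

    def __post_init__(self):
        object.__setattr__(self, "exposure_names", tuple(self.exposure_names))
        object.__setattr__(
            self, "covariate_names", tuple(tuple(w) for w in self.covariate_names)
        )
        object.__setattr__(self, "distributions", dict(self.distributions))
        if self.K < 1:
            raise SchemaError("at least one exposure wave is required")
        if len(self.covariate_names) != self.K:
            raise SchemaError(
                f"covariate_names has {len(self.covariate_names)} waves, "
                f"expected K={self.K}"
            )
        seen = {self.id_name, self.outcome_name}
        if len(seen) < 2:
            raise SchemaError("id and outcome columns must differ")
        for col in self.exposure_names + tuple(self.all_covariates()):
            if col in seen:
                raise SchemaError(f"column {col!r} appears in more than one role")
            seen.add(col)
        for col in (self.outcome_name, *self.exposure_names, *self.all_covariates()):
            tag = self.distributions.get(col)
            if tag not in ADMITTED_DISTRIBUTIONS:
                raise DistributionError(
                    f"column {col!r} has distribution tag {tag!r}; expected one of "
                    f"{ADMITTED_DISTRIBUTIONS}"
                )
        for col in self.exposure_names:
            if self.distributions[col] != "binomial":
                raise DistributionError(
                    f"exposure column {col!r} must be tagged 'binomial'"
                )

    @property
    def K(self) -> int:
        return len(self.exposure_names)

    def all_covariates(self) -> list:
        return [c for wave in self.covariate_names for c in wave]

    def covariates_through(self, t: int) -> list:
        """L_1..L_t flattened (time-admissible covariate history)."""
        return [c for wave in self.covariate_names[:t] for c in wave]

    def exposures_through(self, t: int) -> list:
        """A_1..A_t (exposure history)."""
        return list(self.exposure_names[:t])

    def all_columns(self) -> list:
        return (
            [self.id_name]
            + self.all_covariates()
            + list(self.exposure_names)
            + [self.outcome_name]
        )

    def multinomial_columns(self) -> list:
        return [c for c, d in self.distributions.items() if d == "multinomial"]

    # -- serialisation --------------------------------------------------
    @classmethod
    def from_yaml(cls, path) -> "VariableSpec":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        return cls.from_dict(cfg)

    @classmethod
    def from_dict(cls, cfg: Mapping) -> "VariableSpec":
        try:
            return cls(
                id_name=cfg["id"],
                outcome_name=cfg["outcome"],
                exposure_names=tuple(cfg["exposures"]),
                covariate_names=tuple(tuple(w) for w in cfg["covariates"]),
                distributions=dict(cfg["distributions"]),
            )
        except KeyError as exc:
            raise SchemaError(f"spec config missing key {exc}") from exc

    def to_dict(self) -> dict:
        return {
            "id": self.id_name,
            "outcome": self.outcome_name,
            "exposures": list(self.exposure_names),
            "covariates": [list(w) for w in self.covariate_names],
            "distributions": dict(self.distributions),
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class CohortTable:
    """A validated wide-format longitudinal cohort.

    Attributes
    ----------
    df : pandas.DataFrame
        The validated data, columns ordered id, L, A, Y.
    spec : VariableSpec
    levels : dict
        Frozen, ordered level set of every categorical (binomial or
        multinomial) column, fixed at validation time so that design
        matrices are reproducible across plasmode replicates even when a
        resampled subset drops a level.
    """

    df: pd.DataFrame
    spec: VariableSpec
    levels: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.df)

    def __len__(self) -> int:
        return self.n


def validate_cohort(
    table: pd.DataFrame, spec: VariableSpec, levels: Mapping | None = None
) -> CohortTable:
    """Validate a raw table against *spec* and return a :class:`CohortTable`.

    Missing data are rejected outright (excluded or imputed upstream);
    binomial columns must be {0,1}-valued; multinomial columns must show
    at least two levels unless *levels* supplies a frozen level set (used
    when validating generated replicates against the original cohort).
    """
    missing_cols = [c for c in spec.all_columns() if c not in table.columns]
    if missing_cols:
        raise SchemaError(f"table is missing columns {missing_cols}")
    df = table[spec.all_columns()].copy()
    if df.isna().any().any():
        bad = df.columns[df.isna().any()].tolist()
        raise MissingDataError(
            f"missing values in columns {bad}; missing data are not supported "
            "(exclude or impute before validation)"
        )
    if len(df) < 2:
        raise SchemaError("cohort must contain at least 2 subjects")

    for col in (*spec.exposure_names, *spec.all_covariates(), spec.outcome_name):
        tag = spec.distributions[col]
        vals = df[col].to_numpy()
        if tag == "binomial":
            uniq = np.unique(vals)
            if not np.isin(uniq, [0, 1]).all():
                raise DistributionError(
                    f"binomial column {col!r} contains values outside {{0,1}}: "
                    f"{sorted(set(uniq) - {0, 1})}"
                )
            df[col] = df[col].astype(np.int64)
        elif tag == "multinomial":
            uniq = sorted(pd.unique(df[col]))
            if levels is not None:
                known = list(levels[col])
                extra = [v for v in uniq if v not in known]
                if extra:
                    raise DistributionError(
                        f"multinomial column {col!r} contains unknown levels {extra}"
                    )
            elif len(uniq) < 2:
                raise DistributionError(
                    f"multinomial column {col!r} has fewer than 2 observed levels"
                )
        else:
            if not np.issubdtype(np.asarray(vals).dtype, np.number):
                raise DistributionError(f"gaussian column {col!r} is not numeric")
            df[col] = df[col].astype(float)

    for col in spec.exposure_names:
        if df[col].nunique() < 2:
            raise DistributionError(
                f"exposure column {col!r} is constant; downstream model fitting "
                "requires both exposure levels"
            )

    frozen = {}
    for col, tag in spec.distributions.items():
        if tag == "binomial":
            frozen[col] = [0, 1]
        elif tag == "multinomial":
            frozen[col] = (
                list(levels[col]) if levels is not None else sorted(pd.unique(df[col]))
            )
    return CohortTable(df=df.reset_index(drop=True), spec=spec, levels=frozen)


# ---------------------------------------------------------------------------
# Cumulative-exposure coding
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CumulativeCategory:
    """A cumulative-exposure category with its MSM dummy row.

    ``dummies`` is the 4-vector (intermittent, cessation, onset, chronic);
    the never-exposed reference is all zeros.
    """

    label: str
    dummies: tuple

    def __post_init__(self):
        if self.label not in CUMULATIVE_LABELS:
            raise UnsupportedCodingError(f"unknown category label {self.label!r}")


def code_exposure_pattern(a: Sequence[int]) -> CumulativeCategory:
    """Map a three-wave exposure history to its cumulative category.

    The published coding: never (0,0,0); intermittent (0,1,0), (1,0,1);
    cessation (1,0,0), (1,1,0); onset (0,1,1), (0,0,1); chronic (1,1,1).
    Defined only for K = 3; other K need a user-supplied regime map.
    """
    a = tuple(a)
    if len(a) != 3:
        raise UnsupportedCodingError(
            f"cumulative coding is defined for 3 waves, got {len(a)}"
        )
    if any(v not in (0, 1) for v in a):
        raise DistributionError(f"exposure pattern must be binary, got {a}")
    label = _K3_CATEGORY[a]
    idx = CUMULATIVE_LABELS.index(label)
    dummies = tuple(int(j == idx) for j in range(1, 5))
    return CumulativeCategory(label=label, dummies=dummies)


def category_dummies(c: CumulativeCategory) -> tuple:
    """Design row (intermittent, cessation, onset, chronic) for the MSM."""
    return c.dummies


class RegimeCoding:
    """Maps exposure regimes to MSM categories and dummy design rows.

    ``labels[0]`` is the reference category.  The default for K = 3 is the
    published five-level cumulative coding; for other K a saturated coding
    (one category per regime, reference = never exposed) is provided, and
    arbitrary user mappings are accepted via :meth:`from_mapping`.
    """

    def __init__(self, labels: Sequence[str], mapping: Mapping[tuple, str]):
        self.labels = tuple(labels)
        self.mapping = {tuple(k): v for k, v in mapping.items()}
        missing = set(self.mapping.values()) - set(self.labels)
        if missing:
            raise UnsupportedCodingError(f"mapping uses unknown labels {missing}")
        ks = {len(k) for k in self.mapping}
        if len(ks) != 1:
            raise UnsupportedCodingError("all regimes must have the same length")
        self.K = ks.pop()

    @classmethod
    def cumulative(cls) -> "RegimeCoding":
        return cls(CUMULATIVE_LABELS, _K3_CATEGORY)

    @classmethod
    def saturated(cls, K: int) -> "RegimeCoding":
        if K < 1:
            raise UnsupportedCodingError("K must be >= 1")
        regimes = list(itertools.product((0, 1), repeat=K))
        labels = ["never"] + [
            "a=" + "".join(map(str, r)) for r in regimes if any(r)
        ]
        mapping = {
            r: ("never" if not any(r) else "a=" + "".join(map(str, r)))
            for r in regimes
        }
        return cls(labels, mapping)

    @classmethod
    def from_mapping(cls, mapping: Mapping[tuple, str]) -> "RegimeCoding":
        labels = list(dict.fromkeys(mapping.values()))
        return cls(labels, mapping)

    @classmethod
    def default_for(cls, K: int) -> "RegimeCoding":
        return cls.cumulative() if K == 3 else cls.saturated(K)

    def label(self, a: Sequence[int]) -> str:
        a = tuple(int(v) for v in a)
        if len(a) != self.K:
            raise UnsupportedCodingError(
                f"regime has length {len(a)}, coding expects {self.K}"
            )
        try:
            return self.mapping[a]
        except KeyError:
            raise UnsupportedCodingError(f"regime {a} not covered by coding")

    def dummies(self, a: Sequence[int]) -> np.ndarray:
        lab = self.label(a)
        idx = self.labels.index(lab)
        return np.array([int(j == idx) for j in range(1, len(self.labels))])

    def label_dummies(self, lab: str) -> np.ndarray:
        idx = self.labels.index(lab)
        return np.array([int(j == idx) for j in range(1, len(self.labels))])

    def design_from_labels(self, labs: Sequence[str]) -> np.ndarray:
        """Intercept + dummy design matrix for a vector of category labels."""
        rows = np.stack([self.label_dummies(l) for l in labs])
        return np.column_stack([np.ones(len(rows)), rows])

    def coef_names(self) -> list:
        return ["intercept"] + list(self.labels[1:])
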