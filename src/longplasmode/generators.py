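"""Shared machinery for fitted plasmode generator sets.

A generator set holds one conditional model per generated variable and a
driver that walks the time-ordering L_1, A_1, L_2, A_2, ..., L_K, A_K, Y:
wave-1 covariates always come from the resampled (or supplied) base
frame; later waves are drawn sequentially from the fitted conditionals.
The same driver serves random plasmode generation (exposures drawn from
their models, or retained) and the counterfactual pass (exposures fixed
to a regime, never drawn).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import VariableSpec
from .errors import CompatibilityError, ConfigError


def as_seed_sequence(seed) -> np.random.SeedSequence:
    """Accept either entropy (int/sequence) or an existing SeedSequence."""
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


@dataclass
class GeneratorSet:
    """Fitted conditional models keyed by generated column name.

    ``models`` must contain an entry for every covariate of waves
    2..K and for the outcome; exposure entries are optional per wave
    (absent entries require the exposure to be retained or fixed).
    ``fitting_log`` records one dict per fitted model (family,
    convergence, residual SD / hyperparameters).
    """

    spec: VariableSpec
    levels: dict
    models: dict
    kind: str
    fitting_log: list = field(default_factory=list)

    def check_compatible(self, spec: VariableSpec) -> None:
        if spec.all_columns() != self.spec.all_columns() or (
            dict(spec.distributions) != dict(self.spec.distributions)
        ):
            raise CompatibilityError(
                "generator set and cohort were built from different variable specs"
            )

    def sequential_generate(
        self,
        base: pd.DataFrame,
        rng: np.random.Generator,
        fixed_exposures: np.ndarray | None = None,
    ) -> pd.DataFrame:
        """Complete *base* (holding wave-1 covariates, optionally some
        exposures) into a full table by sequential simulation.

        Parameters
        ----------
        base : frame with the wave-1 covariate columns; exposure columns
            already present (e.g. a retained A_1) are kept as-is.
        fixed_exposures : optional (len(base), K) 0/1 array; when given,
            exposures are set deterministically (counterfactual mode) and
            exposure models are not used.
        """
        spec = self.spec
        frame = base.copy()
        if fixed_exposures is not None:
            fixed_exposures = np.asarray(fixed_exposures)
            if fixed_exposures.shape != (len(frame), spec.K):
                raise ConfigError(
                    f"fixed_exposures has shape {fixed_exposures.shape}, "
                    f"expected {(len(frame), spec.K)}"
                )
        for t in range(1, spec.K + 1):
            if t >= 2:
                for col in spec.covariate_names[t - 1]:
                    frame[col] = self.models[col].draw(frame, rng)
            a_col = spec.exposure_names[t - 1]
            if fixed_exposures is not None:
                frame[a_col] = fixed_exposures[:, t - 1].astype(np.int64)
            elif a_col in frame.columns:
                pass  # retained from the resample
            else:
                if a_col not in self.models:
                    raise ConfigError(
                        f"no model for exposure {a_col!r} and no retained value; "
                        "fit an exposure model or retain it from the resample"
                    )
                frame[a_col] = self.models[a_col].draw(frame, rng)
        frame[spec.outcome_name] = self.models[spec.outcome_name].draw(frame, rng)
        return frame


def resample_base(
    cohort_df: pd.DataFrame,
    spec: VariableSpec,
    m: int,
    rng: np.random.Generator,
    keep: list,
) -> pd.DataFrame:
    """Sample *m* rows with replacement, keeping only the *keep* columns;
    subject ids are renumbered 1..m."""
    idx = rng.integers(0, len(cohort_df), size=m)
    base = cohort_df.iloc[idx][keep].reset_index(drop=True)
    base.insert(0, spec.id_name, np.arange(1, m + 1))
    return base
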