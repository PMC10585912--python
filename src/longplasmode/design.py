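"""Design-matrix construction with frozen categorical levels.

Multinomial predictors are expanded into indicator columns for every
non-reference level of the level set frozen at cohort validation, so the
same columns appear (possibly all-zero) in every replicate.
"""

from __future__ import annotations

import itertools
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


def design_matrix(
    df: pd.DataFrame,
    cols: Sequence[str],
    levels: Mapping[str, list] | None = None,
    saturated: bool = False,
    intercept: bool = True,
):
    """Build a numeric design matrix over *cols*.

    Parameters
    ----------
    df : DataFrame holding the predictor columns.
    cols : predictor column names, in order.
    levels : frozen level sets; a column with >2 levels listed here is
        dummy-expanded (reference = first level).  Binomial columns (levels
        [0, 1]) enter as-is.
    saturated : if True, append products over every subset of size >= 2 of
        the expanded columns (useful for fully saturated working models on
        small discrete problems).
    intercept : prepend a column of ones.

    Returns
    -------
    (X, names) : float ndarray of shape (n, p) and the column names.
    """
    levels = levels or {}
    blocks, names = [], []
    for col in cols:
        lv = levels.get(col)
        if lv is not None and len(lv) > 2:
            vals = df[col].to_numpy()
            for level in lv[1:]:
                blocks.append((vals == level).astype(float))
                names.append(f"{col}=={level}")
        else:
            blocks.append(df[col].to_numpy(dtype=float))
            names.append(col)
    if saturated and len(blocks) > 1:
        base = list(zip(names, blocks))
        for r in range(2, len(base) + 1):
            for combo in itertools.combinations(base, r):
                prod = combo[0][1].copy()
                for _, b in combo[1:]:
                    prod = prod * b
                blocks.append(prod)
                names.append(":".join(nm for nm, _ in combo))
    n = len(df)
    if intercept:
        blocks.insert(0, np.ones(n))
        names.insert(0, "intercept")
    X = np.column_stack(blocks) if blocks else np.empty((n, 0))
    return X, names
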