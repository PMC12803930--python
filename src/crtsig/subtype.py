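"""Chi-square association between a binary subtype label and response.

Subtype labels (e.g. CMS3 vs CMS4, iCMS2 vs iCMS3) are produced by external
classifiers and consumed here as plain annotations; the test is the ordinary
chi-square test of independence on the 2x2 contingency table, without
continuity correction by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError


@dataclass
class Chi2Result:
    statistic: float
    df: int
    p_value: float
    n: int
    expected: np.ndarray


def chi_square_2x2(table, continuity_correction: bool = False) -> Chi2Result:
    """Pearson chi-square on a 2x2 table of counts.

    X^2 = sum (O - E)^2 / E with expectations from the row/column margins,
    referred to chi-square with 1 df; Yates correction only when requested.
    A warning is emitted when any expected cell is below 5.
    """
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise DataError(f"expected a 2x2 table, got shape {arr.shape}")
    if (arr < 0).any():
        raise DataError("counts must be nonnegative")
    if arr.sum() <= 0:
        raise DataError("empty table")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise DataError("zero row or column margin")
    stat, p, df, expected = stats.chi2_contingency(arr, correction=continuity_correction)
    if (expected < 5).any():
        warnings.warn("expected cell count below 5; chi-square approximation is weak",
                      stacklevel=2)
    return Chi2Result(
        statistic=float(stat),
        df=int(df),
        p_value=float(p),
        n=int(arr.sum()),
        expected=expected,
    )


def association_table(
    annot: pd.DataFrame,
    subtype_col: str,
    response_col: str = "response",
    subtype_levels: tuple[str, str] | None = None,
    response_levels: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Build the 2x2 subtype x response table from a sample annotation.

    Samples outside the two named levels of either variable are excluded
    (mirroring the restriction to labeled, evaluable patients).
    """
    for col in (subtype_col, response_col):
        if col not in annot.columns:
            raise DataError(f"annotation lacks column {col!r}")
    sub = annot[[subtype_col, response_col]].dropna()
    if subtype_levels is None:
        levels = sorted(sub[subtype_col].unique())
        if len(levels) != 2:
            raise DataError(
                f"{subtype_col!r} has {len(levels)} levels; pass subtype_levels"
            )
        subtype_levels = tuple(levels)
    if response_levels is None:
        levels = sorted(sub[response_col].unique())
        if len(levels) != 2:
            raise DataError(
                f"{response_col!r} has {len(levels)} levels; pass response_levels"
            )
        response_levels = tuple(levels)
    sub = sub[
        sub[subtype_col].isin(subtype_levels) & sub[response_col].isin(response_levels)
    ]
    table = pd.crosstab(sub[subtype_col], sub[response_col])
    return table.reindex(index=list(subtype_levels), columns=list(response_levels), fill_value=0)
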