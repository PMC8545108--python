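"""Soil nutrient indices and linkage regressions.

The multinutrient cycling (MNC) index summarizes soil fertility as the mean
of Z-scored nutrient measurements (soil organic matter, total and alkaline
hydrolytic nitrogen, total and available phosphorus, total and available
potassium).  Ordinary least-squares regressions link per-sample substrate
quality (median dG_Cox) to soil properties and diversity, and a
site-combination scan checks how robust a regression's significance is to
which subset of sites is analyzed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

NUTRIENT_COLUMNS = (
    "som",
    "total_n",
    "alkaline_n",
    "total_p",
    "available_p",
    "total_k",
    "available_k",
)


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def mnc_index(nutrients: pd.DataFrame, columns: Sequence[str] = NUTRIENT_COLUMNS) -> pd.Series:
    """Multinutrient cycling index: mean of per-nutrient Z-scores.

    Z-scores use the sample standard deviation (n-1 denominator) across
    samples, so the index is invariant to each nutrient's units and averages
    to ~0 over the cohort.  A zero-variance nutrient is an error: its Z-score
    is undefined.
    """
    if len(nutrients) < 2:
        raise ValueError("MNC needs at least two samples")
    missing = [c for c in columns if c not in nutrients.columns]
    if missing:
        raise KeyError(f"missing nutrient column(s): {missing}")
    sub = nutrients[list(columns)].astype(float)
    if sub.isna().any().any():
        raise ValueError("missing nutrient values")
    sd = sub.std(axis=0, ddof=1)
    flat = sd[sd == 0]
    if len(flat):
        raise ValueError(f"zero-variance nutrient(s): {list(flat.index)}")
    z = (sub - sub.mean(axis=0)) / sd
    return z.mean(axis=1).rename("mnc")


def ols_fit(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Simple OLS of y on x with the two-sided slope t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be matching 1-d vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance")
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=len(x),
    )


def site_combination_scan(
    data: pd.DataFrame,
    site_col: str,
    x_col: str,
    y_col: str,
    k: int,
    alpha: float = 0.05,
) -> tuple[float, pd.DataFrame]:
    """Refit the x-y regression on every k-subset of sites.

    Returns the fraction of evaluated combinations significant at ``alpha``
    and the per-combination table.  Combinations with fewer than 3 samples
    are skipped with a warning.
    """
    sites = sorted(data[site_col].unique())
    if not 2 <= k <= len(sites):
        raise ValueError("k must be between 2 and the number of sites")
    rows = []
    for combo in combinations(sites, k):
        sub = data[data[site_col].isin(combo)]
        if len(sub) < 3:
            logger.warning("combination %s has n=%d < 3; skipped", combo, len(sub))
            continue
        try:
            fit = ols_fit(sub[x_col], sub[y_col])
        except ValueError as exc:
            logger.warning("combination %s skipped: %s", combo, exc)
            continue
        rows.append(
            {
                "sites": "+".join(map(str, combo)),
                "n": fit.n,
                "slope": fit.slope,
                "r_squared": fit.r_squared,
                "p_value": fit.p_value,
                "significant": fit.p_value < alpha,
            }
        )
    table = pd.DataFrame(
        rows, columns=["sites", "n", "slope", "r_squared", "p_value", "significant"]
    )
    if not len(table):
        raise ValueError("no evaluable site combination")
    return float(table["significant"].mean()), table
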