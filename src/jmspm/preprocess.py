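"""Metabolite-value preprocessing: half-minimum imputation and inverse-normal transform.

Raw LC/MS intensity values contain exact zeros where a compound fell below the
detection limit; the conventional remedy is to replace each zero by half of the
smallest positive intensity observed for that metabolite.  Intensities are then
mapped to normal scores by a rank-based inverse-normal transformation (INT)
before entering any longitudinal model, so that a one-unit change on the
transformed scale is comparable across metabolites.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["half_min_impute", "inverse_normal_transform", "preprocess_measurements"]


def half_min_impute(values) -> np.ndarray:
    """Replace zeros by half of the minimum positive value.

    Parameters
    ----------
    values : array-like of nonnegative reals
        Raw intensities; zeros denote below-detection measurements.

    Returns
    -------
    ndarray with every 0 replaced by ``min(positive values) / 2``; positive
    entries are unchanged.

    Raises
    ------
    ValueError
        If the input is empty, contains negative values, or has no strictly
        positive entry (nothing to halve).
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty value vector")
    if np.any(v < 0):
        raise ValueError("raw intensities must be nonnegative")
    pos = v[v > 0]
    if pos.size == 0:
        raise ValueError("all-zero vector: no positive minimum to halve")
    out = v.copy()
    out[out == 0] = pos.min() / 2.0
    return out


def inverse_normal_transform(values, offset: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse-normal transformation (Blom scores by default).

    Maps value ``i`` to ``Phi^{-1}((r_i - offset) / (n - 2*offset + 1))`` where
    ``r_i`` is the 1-based rank (ties receive average ranks).  With the default
    Blom offset 3/8 the denominator is ``n + 1/4``.  The map is strictly
    rank-preserving on distinct inputs and produces an approximately standard
    normal sample.

    Parameters
    ----------
    values : array-like, length >= 2
    offset : rankit offset in [0, 0.5]; 3/8 (Blom) by default.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("inverse-normal transform needs at least 2 values")
    ranks = stats.rankdata(v, method="average")
    p = (ranks - offset) / (v.size - 2.0 * offset + 1.0)
    return stats.norm.ppf(p)


def preprocess_measurements(
    df: pd.DataFrame,
    value_col: str = "value",
    impute: bool = True,
    transform: bool = True,
    offset: float = 3.0 / 8.0,
) -> pd.DataFrame:
    """Apply half-minimum imputation and/or INT to a long-format measurement table.

    The transformation is computed on the pooled analytic sample (all visits
    together), so repeated measurements of one subject are ranked against the
    full set of measurements.
    """
    out = df.copy()
    vals = out[value_col].to_numpy(dtype=float)
    if impute:
        vals = half_min_impute(vals)
    if transform:
        vals = inverse_normal_transform(vals, offset=offset)
    out[value_col] = vals
    return out
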