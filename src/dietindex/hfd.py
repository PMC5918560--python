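"""Healthy Food Diversity index.

The HFD-index combines dietary variety with the healthiness of what is
eaten: each subject's daily gram intakes are converted to shares
``s_i = g_i / sum(g)``, diversity is measured by the Berry/Simpson index
``BI = 1 - sum(s_i^2)``, and the subject's mean health value
``hv = sum(hv_i * s_i)`` (item health values in (0, 1]) weights it:

    HFD = hv * BI.

The score lies in [0, 1 - 1/n_items); it is 0 exactly for single-food
(or zero-intake) diets, and approaches its supremum for equal shares of
maximally healthy foods.  Intakes are deliberately not energy-adjusted.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def food_shares(intakes: pd.DataFrame) -> pd.DataFrame:
    """Per-item shares of total daily gram intake (rows on the simplex).

    Zero-intake subjects keep an all-zero row and are logged; their HFD
    is 0 by the single-food/zero-intake convention.
    """
    if (intakes.to_numpy() < 0).any():
        raise ValueError("intakes must be nonnegative")
    totals = intakes.sum(axis=1)
    n_zero = int((totals == 0).sum())
    if n_zero:
        logger.info("%d subjects with zero total intake (HFD will be 0)", n_zero)
    safe = totals.replace(0, np.nan)
    return intakes.div(safe, axis=0).fillna(0.0)


def berry_index(shares: pd.DataFrame | pd.Series) -> pd.Series | float:
    """Berry index ``1 - sum(s_i^2)`` (a Simpson-type diversity)."""
    if isinstance(shares, pd.Series):
        return float(1.0 - np.sum(shares.to_numpy() ** 2))
    bi = 1.0 - (shares.to_numpy() ** 2).sum(axis=1)
    # all-zero rows (zero intake) get BI 0, not 1
    bi = np.where(shares.sum(axis=1).to_numpy() == 0, 0.0, bi)
    return pd.Series(bi, index=shares.index, name="berry")


def hfd_score(shares: pd.DataFrame, health_values: pd.Series) -> pd.DataFrame:
    """Health value, Berry index, and HFD per subject.

    Raises if a consumed item has no health value, or a health value
    falls outside (0, 1].
    """
    consumed = shares.columns[shares.gt(0).any()]
    missing = consumed.difference(health_values.index)
    if len(missing):
        raise KeyError(f"missing health value for consumed item(s): {list(missing)}")
    hv_items = health_values.reindex(shares.columns).fillna(1.0)
    known = health_values.loc[health_values.index.intersection(shares.columns)]
    if ((known <= 0) | (known > 1)).any():
        raise ValueError("health values must lie in (0, 1]")
    hv = shares.to_numpy() @ hv_items.to_numpy(dtype=float)
    bi = berry_index(shares).to_numpy()
    return pd.DataFrame(
        {"health_value": hv, "berry": bi, "hfd": hv * bi}, index=shares.index
    )


def hfd_total(intakes: pd.DataFrame, composition: pd.DataFrame) -> pd.DataFrame:
    """Convenience pipeline: shares -> HFD using composition health values."""
    return hfd_score(food_shares(intakes), composition["health_value"])
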