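"""Relate growth-rate differences to competitive-ability differences.

One row per (species, soil, native-partner) comparison: the difference in
back-transformed, nodulation-adjusted single-grown mean growth rates
between introduced and native provenance, against the Monte-Carlo mean RCI
difference.  By default both columns are taken as magnitudes (absolute
values), since the sign conventions differ across soils.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import math

import numpy as np
import pandas as pd
from scipy import stats

from rcikit.design import INTRODUCED
from rcikit.errors import InvalidInputError
from rcikit.growth import GrowthFit
from rcikit.rci import RCIDiffSummary

__all__ = ["CorrelationResult", "build_comparison_table", "pearson_correlation"]

COMPARISON_COLUMNS = (
    "species",
    "soil_country",
    "native_partner",
    "growth_diff",
    "rci_diff",
)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    n: int


def build_comparison_table(
    fits: Mapping[tuple[str, str], GrowthFit],
    rci_diffs: Sequence[RCIDiffSummary],
    use_absolute: bool = True,
    log_scale: bool = False,
) -> pd.DataFrame:
    """One comparison row per RCI contrast.

    ``fits`` maps (species, soil_country) to the fit whose single-grown cell
    means supply the growth difference; ``log_scale`` keeps the difference
    on the log scale instead of back-transforming.
    """
    rows = []
    for d in rci_diffs:
        key = (d.species, d.soil_country)
        if key not in fits:
            raise InvalidInputError(f"no fit supplied for species x soil {key}")
        fit = fits[key]
        m_intro = fit.coef(INTRODUCED)
        m_native = fit.coef(d.native_partner)
        if log_scale:
            growth_diff = m_intro - m_native
        else:
            growth_diff = math.exp(m_intro) - math.exp(m_native)
        rci_diff = d.mean_diff
        if use_absolute:
            growth_diff, rci_diff = abs(growth_diff), abs(rci_diff)
        rows.append(
            {
                "species": d.species,
                "soil_country": d.soil_country,
                "native_partner": d.native_partner,
                "growth_diff": growth_diff,
                "rci_diff": rci_diff,
            }
        )
    return pd.DataFrame(rows, columns=list(COMPARISON_COLUMNS))


def pearson_correlation(x, y) -> CorrelationResult:
    """Pearson r with a two-sided t-test p-value on n - 2 degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidInputError("x and y must be equal-length vectors")
    n = len(x)
    if n < 3:
        raise InvalidInputError("need at least 3 points for a defined p-value")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise InvalidInputError("correlation undefined: a variable has zero variance")
    res = stats.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p_value=float(res.pvalue), n=n)
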