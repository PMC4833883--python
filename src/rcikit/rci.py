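"""Relative competition intensity with Monte-Carlo propagated uncertainty.

RCI for a focal provenance A grown with partner B is

    RCI_A(B) = (GR_A - GR_A(B)) / GR_A

where GR_A is the growth rate of A grown alone and GR_A(B) its growth rate
in competition.  Zero means no competitive effect, the supremum 1 complete
suppression, and negative values facilitation.

Uncertainty propagation: coefficient vectors are drawn from the
multivariate normal defined by a fit's coefficients and fixed-effects
variance-covariance matrix; each draw is back-transformed to the natural
scale by exponentiation before the RCI formula is applied.  Contrasts
between two indices from the same fit reuse the same coefficient draws
(common random numbers), so their per-draw difference has reduced
Monte-Carlo variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from rcikit.errors import InvalidInputError, NumericalError
from rcikit.growth import GrowthFit

__all__ = [
    "DEFAULT_DRAWS",
    "RCIDraws",
    "RCISummary",
    "RCIDiffSummary",
    "compute_rci",
    "simulate_fixed_effects",
    "rci_from_draws",
    "summarize_rci",
    "rci_difference",
]

DEFAULT_DRAWS = 100_000
_PSD_REPAIR_TOL = 1e-10


@dataclass(frozen=True)
class RCIDraws:
    """Monte-Carlo draws of one RCI index."""

    index_label: str
    values: np.ndarray
    S: int
    seed: int

    def __post_init__(self) -> None:
        if len(self.values) != self.S:
            raise InvalidInputError("draw vector length must equal S")


@dataclass(frozen=True)
class RCISummary:
    """Mean and equal-tailed 50%/95% intervals of an RCI draw distribution."""

    index_label: str
    mean: float
    ci50: tuple[float, float]
    ci95: tuple[float, float]


@dataclass(frozen=True)
class RCIDiffSummary:
    """Summary of a per-draw RCI contrast (introduced minus native).

    Positive means the native provenance was the stronger competitor;
    negative means the introduced provenance was.  ``significant`` is True
    iff the 95% interval excludes zero.
    """

    species: str
    soil_country: str
    native_partner: str
    mean_diff: float
    ci50: tuple[float, float]
    ci95: tuple[float, float]
    significant: bool


def compute_rci(gr_alone, gr_with):
    """(gr_alone - gr_with) / gr_alone, elementwise on arrays or scalars."""
    alone = np.asarray(gr_alone, dtype=float)
    with_ = np.asarray(gr_with, dtype=float)
    if np.any(alone <= 0):
        raise InvalidInputError("gr_alone must be strictly positive")
    if np.any(with_ < 0):
        raise InvalidInputError("gr_with must be nonnegative")
    out = (alone - with_) / alone
    return float(out) if out.ndim == 0 else out


def simulate_fixed_effects(fit: GrowthFit, S: int = DEFAULT_DRAWS, seed: int = 0) -> np.ndarray:
    """Draw S coefficient vectors from N(coefficients, vcov_fixed).

    The covariance matrix is symmetrized and eigenvalues within a relative
    tolerance of zero are clipped; a matrix indefinite beyond that raises
    :class:`NumericalError` reporting its smallest eigenvalue.
    """
    if S < 1:
        raise InvalidInputError("S must be >= 1")
    cov = 0.5 * (fit.vcov_fixed + fit.vcov_fixed.T)
    eigval, eigvec = np.linalg.eigh(cov)
    scale = max(eigval.max(), 1.0)
    if eigval.min() < -_PSD_REPAIR_TOL * scale:
        raise NumericalError(
            f"vcov_fixed is not positive semidefinite (smallest eigenvalue {eigval.min():.3e})"
        )
    root = eigvec * np.sqrt(np.clip(eigval, 0.0, None))
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((S, len(fit.coefficients)))
    return fit.coefficients + z @ root.T


def rci_from_draws(
    draws: np.ndarray,
    fit: GrowthFit,
    alone_cell: str,
    paired_cell: str,
    seed: int = 0,
) -> RCIDraws:
    """Per-draw RCI for one focal provenance.

    ``alone_cell`` names the focal provenance's single-grown cell and
    ``paired_cell`` its in-competition cell; both are exponentiated back to
    the natural growth-rate scale before the RCI formula.  The nodulation
    coefficient does not enter: cell means are already nodulation-adjusted.
    """
    i = fit.index(alone_cell)
    j = fit.index(paired_cell)
    gr_alone = np.exp(draws[:, i])
    gr_with = np.exp(draws[:, j])
    values = compute_rci(gr_alone, gr_with)
    return RCIDraws(index_label=paired_cell, values=values, S=len(values), seed=seed)


def summarize_rci(draws: RCIDraws) -> RCISummary:
    """Mean plus equal-tailed 50% and 95% quantile intervals."""
    v = draws.values
    if len(v) == 0:
        raise InvalidInputError("cannot summarize empty draws")
    q = np.quantile(v, [0.025, 0.25, 0.75, 0.975])
    return RCISummary(
        index_label=draws.index_label,
        mean=float(np.mean(v)),
        ci50=(float(q[1]), float(q[2])),
        ci95=(float(q[0]), float(q[3])),
    )


def rci_difference(
    draws_introduced: RCIDraws,
    draws_native: RCIDraws,
    species: str = "",
    soil_country: str = "",
    native_partner: str = "",
) -> RCIDiffSummary:
    """Per-draw contrast RCI_introduced(native) - RCI_native(introduced).

    Both draw vectors must have equal S and should come from the same
    underlying coefficient draws so the subtraction is paired.
    """
    if draws_introduced.S != draws_native.S:
        raise InvalidInputError(
            f"mismatched draw counts: {draws_introduced.S} vs {draws_native.S}"
        )
    diff = draws_introduced.values - draws_native.values
    q = np.quantile(diff, [0.025, 0.25, 0.75, 0.975])
    ci95 = (float(q[0]), float(q[3]))
    return RCIDiffSummary(
        species=species,
        soil_country=soil_country,
        native_partner=native_partner,
        mean_diff=float(np.mean(diff)),
        ci50=(float(q[1]), float(q[2])),
        ci95=ci95,
        significant=bool(ci95[0] > 0 or ci95[1] < 0),
    )


def summaries_to_frame(summaries: list[RCISummary]) -> pd.DataFrame:
    rows = [
        {
            "index_label": s.index_label,
            "mean": s.mean,
            "ci50_lower": s.ci50[0],
            "ci50_upper": s.ci50[1],
            "ci95_lower": s.ci95[0],
            "ci95_upper": s.ci95[1],
        }
        for s in summaries
    ]
    return pd.DataFrame(rows)


def diffs_to_frame(diffs: list[RCIDiffSummary]) -> pd.DataFrame:
    rows = [
        {
            "species": d.species,
            "soil_country": d.soil_country,
            "native_partner": d.native_partner,
            "mean_diff": d.mean_diff,
            "ci50_lower": d.ci50[0],
            "ci50_upper": d.ci50[1],
            "ci95_lower": d.ci95[0],
            "ci95_upper": d.ci95[1],
            "significant": d.significant,
        }
        for d in diffs
    ]
    return pd.DataFrame(rows)
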