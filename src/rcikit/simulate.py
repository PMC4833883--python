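"""Synthetic plant-level data with the statistical structure the analysis
assumes.

The generator is a log-normal growth model: for a plant in cell
(species, soil, provenance) with nodulation score ``nod``,

    log growth_rate = m + beta_nod * nod + b_site (+ b_pot) + eps

where ``m`` is the cell's true mean log growth rate at nodulation 0.  For
paired plants the competition effect is injected on the natural scale via
the RCI identity  GR_with = GR_alone * (1 - RCI), so the downstream
inference target is exact by construction.  Site effects are drawn once per
(soil_country, site); the optional pot effect defaults to zero.

The generator is a pure function of (design, params): identical seeds give
bit-identical tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from rcikit.design import PotSpec
from rcikit.errors import ConfigurationError, InvalidInputError
from rcikit.records import RECORD_COLUMNS, read_records, validate_records, write_records

__all__ = [
    "TrueParams",
    "default_true_params",
    "generate_dataset",
    "apply_mortality",
    "params_to_yaml",
    "params_from_yaml",
    "read_records",
    "write_records",
]

CellKey = tuple[str, str, str]  # (species, soil_country, provenance)
PairKey = tuple[str, str, str, str]  # (species, soil_country, focal, partner)


@dataclass(frozen=True)
class TrueParams:
    """Generative parameters for one synthetic experiment.

    ``single_cell_means_log`` maps (species, soil, provenance) to the true
    mean log growth rate (log g/day) of singly grown plants at nodulation 0.
    ``true_rci`` maps (species, soil, focal, partner) to the dimensionless
    competition intensity experienced by the focal provenance; values must
    stay below 1 so paired growth remains positive.
    """

    single_cell_means_log: Mapping[CellKey, float]
    true_rci: Mapping[PairKey, float]
    beta_nod: float = 0.0
    sigma_site: float = 0.0
    sigma_resid: float = 0.0
    sigma_pot: float = 0.0
    mortality_rate: float = 0.0
    growing_days: int = 90
    nodulation_probs: tuple[float, float, float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_site < 0 or self.sigma_resid < 0 or self.sigma_pot < 0:
            raise ConfigurationError("standard deviations must be nonnegative")
        if not 0 <= self.mortality_rate < 1:
            raise ConfigurationError("mortality_rate must lie in [0, 1)")
        if self.growing_days < 1:
            raise ConfigurationError("growing_days must be a positive integer")
        for key, value in self.true_rci.items():
            if value >= 1:
                raise ConfigurationError(
                    f"true_rci must be < 1 so paired growth stays positive; got {value} for {key}"
                )
        if self.nodulation_probs is not None:
            p = np.asarray(self.nodulation_probs, dtype=float)
            if p.shape != (4,) or (p < 0).any() or not math.isclose(p.sum(), 1.0, rel_tol=1e-9):
                raise ConfigurationError("nodulation_probs must be 4 probabilities summing to 1")


def default_true_params(seed: int = 0, **overrides) -> TrueParams:
    """A complete, deliberately asymmetric parameter set for the full design.

    Cell means sit around log(0.03 g/day) with deterministic provenance and
    soil offsets; every (introduced, native) pairing gets mildly asymmetric
    true RCI values.  Intended for demos, smoke tests and pipeline defaults.
    """
    from rcikit.design import NATIVE_PROVENANCES, SOIL_COUNTRIES, SPECIES

    base = math.log(0.03)
    sp_off = {"arvense": 0.00, "campestre": -0.15, "striatum": 0.10}
    soil_off = {"NZ": 0.05, "SP": 0.00, "UK": -0.05}
    prov_off = {"NZ": 0.20, "SP": 0.00, "UK": -0.10}
    means: dict[CellKey, float] = {}
    for sp in SPECIES:
        for soil in SOIL_COUNTRIES:
            # all provenances get a mean in every soil so that both design
            # readings (including strict-formula paired pots) are generable
            for prov in ("NZ", "SP", "UK"):
                means[(sp, soil, prov)] = base + sp_off[sp] + soil_off[soil] + prov_off[prov]
    rci: dict[PairKey, float] = {}
    for sp in SPECIES:
        for soil in SOIL_COUNTRIES:
            for native in NATIVE_PROVENANCES:
                rci[(sp, soil, "NZ", native)] = 0.30
                rci[(sp, soil, native, "NZ")] = 0.40
    defaults = dict(
        single_cell_means_log=means,
        true_rci=rci,
        beta_nod=0.08,
        sigma_site=0.10,
        sigma_resid=0.30,
        mortality_rate=0.11,
        growing_days=90,
        seed=seed,
    )
    defaults.update(overrides)
    return TrueParams(**defaults)


def _cell_mean(params: TrueParams, pot: PotSpec, focal: str, partner: str | None) -> float:
    key = (pot.species, pot.soil_country, focal)
    try:
        m_single = params.single_cell_means_log[key]
    except KeyError:
        raise ConfigurationError(
            f"no single-cell mean configured for cell {key}"
        ) from None
    if partner is None:
        return m_single
    pair = (pot.species, pot.soil_country, focal, partner)
    try:
        rci = params.true_rci[pair]
    except KeyError:
        raise ConfigurationError(f"no true RCI configured for paired cell {pair}") from None
    return m_single + math.log1p(-rci)


def generate_dataset(design: Sequence[PotSpec], params: TrueParams) -> pd.DataFrame:
    """Simulate one plant-record table for a pot design.

    Single pots yield one plant; paired pots yield two (each plant focal in
    turn, the other as partner).  Nodulation scores are uniform on {0..3}
    unless ``params.nodulation_probs`` is set.
    """
    rng = np.random.default_rng(params.seed)
    pots = sorted(design)  # deterministic order regardless of caller's order

    site_keys = sorted({(p.soil_country, p.soil_site) for p in pots})
    site_effects = dict(
        zip(site_keys, rng.normal(0.0, params.sigma_site, size=len(site_keys)))
    )
    nod_p = params.nodulation_probs
    rows: list[dict] = []
    for pot in pots:
        b_site = site_effects[(pot.soil_country, pot.soil_site)]
        b_pot = rng.normal(0.0, params.sigma_pot) if params.sigma_pot > 0 else 0.0
        if pot.treatment == "single":
            plants = [(1, pot.provenances[0], None)]
        else:
            a, b = pot.provenances
            plants = [(1, a, b), (2, b, a)]
        for slot, focal, partner in plants:
            nod = int(rng.choice(4, p=nod_p)) if nod_p is not None else int(rng.integers(0, 4))
            eps = rng.normal(0.0, params.sigma_resid)
            m = _cell_mean(params, pot, focal, partner)
            log_gr = m + params.beta_nod * nod + b_site + b_pot + eps
            biomass = math.exp(log_gr) * params.growing_days
            # store the quotient so the growth-rate identity is bit-exact
            gr = biomass / params.growing_days
            rows.append(
                {
                    "pot_id": pot.pot_id,
                    "soil_country": pot.soil_country,
                    "soil_site": pot.soil_site,
                    "species": pot.species,
                    "treatment": pot.treatment,
                    "replicate": pot.replicate,
                    "plant_slot": slot,
                    "focal_provenance": focal,
                    "partner_provenance": partner if partner is not None else np.nan,
                    "nodulation_score": nod,
                    "growing_days": params.growing_days,
                    "dry_biomass_g": biomass,
                    "growth_rate": gr,
                }
            )
    records = pd.DataFrame(rows, columns=list(RECORD_COLUMNS))
    validate_records(records)
    return records


def apply_mortality(
    records: pd.DataFrame, mortality_rate: float, seed: int
) -> pd.DataFrame:
    """Remove each plant independently with the given probability.

    Mirrors early random seedling mortality: thinning happens before any
    analysis and is independent of treatment.  Same seed, same thinning.
    """
    if not 0 <= mortality_rate < 1:
        raise InvalidInputError("mortality_rate must lie in [0, 1)")
    if mortality_rate == 0:
        return records.copy()
    rng = np.random.default_rng(seed)
    keep = rng.random(len(records)) >= mortality_rate
    return records.loc[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# parameter (de)serialisation — nested YAML keyed by cell


def params_to_yaml(params: TrueParams, path: str | Path) -> None:
    means: dict = {}
    for (sp, soil, prov), v in params.single_cell_means_log.items():
        means.setdefault(sp, {}).setdefault(soil, {})[prov] = float(v)
    rci: dict = {}
    for (sp, soil, focal, partner), v in params.true_rci.items():
        rci.setdefault(sp, {}).setdefault(soil, {})[f"{focal}({partner})"] = float(v)
    doc = {
        "single_cell_means_log": means,
        "true_rci": rci,
        "beta_nod": float(params.beta_nod),
        "sigma_site": float(params.sigma_site),
        "sigma_resid": float(params.sigma_resid),
        "sigma_pot": float(params.sigma_pot),
        "mortality_rate": float(params.mortality_rate),
        "growing_days": int(params.growing_days),
        "nodulation_probs": (
            [float(p) for p in params.nodulation_probs]
            if params.nodulation_probs is not None
            else None
        ),
        "seed": int(params.seed),
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def params_from_yaml(path: str | Path) -> TrueParams:
    doc = yaml.safe_load(Path(path).read_text())
    means: dict[CellKey, float] = {}
    for sp, soils in doc["single_cell_means_log"].items():
        for soil, provs in soils.items():
            for prov, v in provs.items():
                means[(sp, soil, prov)] = float(v)
    rci: dict[PairKey, float] = {}
    for sp, soils in doc.get("true_rci", {}).items():
        for soil, pairs in soils.items():
            for label, v in pairs.items():
                focal, partner = label.rstrip(")").split("(")
                rci[(sp, soil, focal, partner)] = float(v)
    nod = doc.get("nodulation_probs")
    return TrueParams(
        single_cell_means_log=means,
        true_rci=rci,
        beta_nod=float(doc.get("beta_nod", 0.0)),
        sigma_site=float(doc.get("sigma_site", 0.0)),
        sigma_resid=float(doc.get("sigma_resid", 0.0)),
        sigma_pot=float(doc.get("sigma_pot", 0.0)),
        mortality_rate=float(doc.get("mortality_rate", 0.0)),
        growing_days=int(doc.get("growing_days", 90)),
        nodulation_probs=tuple(nod) if nod is not None else None,
        seed=int(doc.get("seed", 0)),
    )


def with_seed(params: TrueParams, seed: int) -> TrueParams:
    """Copy of ``params`` with a different seed."""
    return replace(params, seed=seed)
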