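"""Factorial pot layouts for the two-glasshouse competition study.

The study crosses three clover species with seed provenances (NZ introduced;
SP and UK native) over soils from three countries, five collection sites per
country and two replicates.  Single-plant pots carry one plant grown alone;
paired pots always pit the introduced provenance against one native
provenance.

Two readings of the paired design are supported via :class:`DesignConfig`:

``strict_formula``
    Both native pairings in every soil country, fully crossed (the printed
    3 x 2 x 5 x 2 = 60 formula).
``harvest_consistent``
    Both pairings in NZ soil, but only the local native pairing in each
    native-range soil (NZxSP in SP soil, NZxUK in UK soil).  This is the
    default because it yields the twelve (species, soil, native-partner)
    comparison cells the downstream correlation uses.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from rcikit.errors import InvalidInputError

SOIL_COUNTRIES: tuple[str, ...] = ("NZ", "SP", "UK")
SPECIES: tuple[str, ...] = ("arvense", "campestre", "striatum")
INTRODUCED: str = "NZ"
NATIVE_PROVENANCES: tuple[str, ...] = ("SP", "UK")
PROVENANCES: tuple[str, ...] = ("NZ", "SP", "UK")

DESIGN_MODES: tuple[str, ...] = ("strict_formula", "harvest_consistent")

#: Column order of a design CSV (PlantRecord design fields, no measurements).
DESIGN_COLUMNS: tuple[str, ...] = (
    "pot_id",
    "soil_country",
    "soil_site",
    "species",
    "treatment",
    "provenance_1",
    "provenance_2",
    "replicate",
)


@dataclass(frozen=True, order=True)
class PotSpec:
    """One pot in the factorial layout.

    ``provenances`` holds one label for single pots and the ordered
    (introduced, native) pair for paired pots.
    """

    soil_country: str
    soil_site: int
    species: str
    treatment: str
    provenances: tuple[str, ...]
    replicate: int

    def __post_init__(self) -> None:
        if self.soil_country not in SOIL_COUNTRIES:
            raise InvalidInputError(f"unknown soil country {self.soil_country!r}")
        if self.species not in SPECIES:
            raise InvalidInputError(f"unknown species {self.species!r}")
        if self.treatment not in ("single", "paired"):
            raise InvalidInputError(f"unknown treatment {self.treatment!r}")
        if any(p not in PROVENANCES for p in self.provenances):
            raise InvalidInputError(f"unknown provenance in {self.provenances!r}")
        if self.treatment == "single" and len(self.provenances) != 1:
            raise InvalidInputError("single pots carry exactly one provenance")
        if self.treatment == "paired":
            if len(self.provenances) != 2:
                raise InvalidInputError("paired pots carry exactly two provenances")
            if INTRODUCED not in self.provenances:
                raise InvalidInputError("paired pots must include the introduced provenance")
            partner = [p for p in self.provenances if p != INTRODUCED]
            if len(partner) != 1 or partner[0] not in NATIVE_PROVENANCES:
                raise InvalidInputError(
                    "paired pots must pit the introduced provenance against one native provenance"
                )
        if not 1 <= self.soil_site:
            raise InvalidInputError("soil_site must be >= 1")
        if not 1 <= self.replicate:
            raise InvalidInputError("replicate must be >= 1")

    @property
    def pot_id(self) -> str:
        """Deterministic identifier derived from the factor tuple."""
        prov = "x".join(self.provenances)
        return (
            f"{self.soil_country}-s{self.soil_site}-{self.species}-"
            f"{self.treatment}-{prov}-r{self.replicate}"
        )


@dataclass(frozen=True)
class DesignConfig:
    """Configurable factor levels of the layout."""

    mode: str = "harvest_consistent"
    species: tuple[str, ...] = SPECIES
    sites_per_country: int = 5
    replicates: int = 2

    def __post_init__(self) -> None:
        if self.mode not in DESIGN_MODES:
            raise InvalidInputError(
                f"unknown design mode {self.mode!r}; expected one of {DESIGN_MODES}"
            )
        if self.sites_per_country < 1:
            raise InvalidInputError("sites_per_country must be >= 1")
        if self.replicates < 1:
            raise InvalidInputError("replicates must be >= 1")
        object.__setattr__(self, "species", tuple(self.species))


def single_provenances(soil_country: str) -> tuple[str, ...]:
    """Provenances grown singly in a given soil.

    All three provenances were grown in introduced-range (NZ) soil; each
    native-range soil hosted the introduced provenance plus its local native
    provenance only.
    """
    if soil_country == "NZ":
        return PROVENANCES
    if soil_country == "SP":
        return ("NZ", "SP")
    if soil_country == "UK":
        return ("NZ", "UK")
    raise InvalidInputError(f"unknown soil country {soil_country!r}")


def paired_pairings(soil_country: str, mode: str) -> tuple[tuple[str, str], ...]:
    """(introduced, native) pairings planted in a soil under a design mode."""
    if soil_country not in SOIL_COUNTRIES:
        raise InvalidInputError(f"unknown soil country {soil_country!r}")
    if mode not in DESIGN_MODES:
        raise InvalidInputError(f"unknown design mode {mode!r}")
    both = tuple((INTRODUCED, nat) for nat in NATIVE_PROVENANCES)
    if mode == "strict_formula" or soil_country == "NZ":
        return both
    local = soil_country  # native-range soils host their local pairing only
    return ((INTRODUCED, local),)


def build_single_design(
    soil_country: str, config: DesignConfig | None = None
) -> list[PotSpec]:
    """Full crossing of species x provenance x site x replicate for single pots."""
    config = config or DesignConfig()
    provs = single_provenances(soil_country)
    return [
        PotSpec(soil_country, site, sp, "single", (prov,), rep)
        for sp in config.species
        for prov in provs
        for site in range(1, config.sites_per_country + 1)
        for rep in range(1, config.replicates + 1)
    ]


def build_paired_design(
    soil_country: str, config: DesignConfig | None = None
) -> list[PotSpec]:
    """Paired pots for one soil, crossing species x pairing x site x replicate."""
    config = config or DesignConfig()
    pairings = paired_pairings(soil_country, config.mode)
    return [
        PotSpec(soil_country, site, sp, "paired", pairing, rep)
        for sp in config.species
        for pairing in pairings
        for site in range(1, config.sites_per_country + 1)
        for rep in range(1, config.replicates + 1)
    ]


def build_study_design(config: DesignConfig | None = None) -> list[PotSpec]:
    """Single and paired pots over all three soil countries."""
    config = config or DesignConfig()
    pots: list[PotSpec] = []
    for soil in SOIL_COUNTRIES:
        pots.extend(build_single_design(soil, config))
        pots.extend(build_paired_design(soil, config))
    return pots


def comparison_cells(config: DesignConfig | None = None) -> list[tuple[str, str, str]]:
    """Distinct (species, soil_country, native_partner) comparison cells.

    These are the rows of the growth-difference vs RCI-difference table;
    the default harvest-consistent design yields exactly twelve.
    """
    config = config or DesignConfig()
    cells = []
    for soil in SOIL_COUNTRIES:
        for sp in config.species:
            for _, native in paired_pairings(soil, config.mode):
                cells.append((sp, soil, native))
    return cells


def count_pots(design: Iterable[PotSpec]) -> pd.DataFrame:
    """Tabulate a design by (soil_country, treatment).

    Returns a tidy frame with columns soil_country, treatment, n_pots; the
    counts always sum to the design size.
    """
    rows = [(p.soil_country, p.treatment) for p in design]
    if not rows:
        return pd.DataFrame(columns=["soil_country", "treatment", "n_pots"])
    df = pd.DataFrame(rows, columns=["soil_country", "treatment"])
    out = (
        df.groupby(["soil_country", "treatment"], sort=True)
        .size()
        .rename("n_pots")
        .reset_index()
    )
    return out


def design_to_frame(design: Sequence[PotSpec]) -> pd.DataFrame:
    """Tidy one-row-per-pot frame with the fixed design columns."""
    rows = []
    for p in design:
        rows.append(
            {
                "pot_id": p.pot_id,
                "soil_country": p.soil_country,
                "soil_site": p.soil_site,
                "species": p.species,
                "treatment": p.treatment,
                "provenance_1": p.provenances[0],
                "provenance_2": p.provenances[1] if len(p.provenances) == 2 else "",
                "replicate": p.replicate,
            }
        )
    return pd.DataFrame(rows, columns=list(DESIGN_COLUMNS))


def write_design(design: Sequence[PotSpec], path: str | Path) -> None:
    design_to_frame(design).to_csv(path, index=False)


def read_design(path: str | Path) -> list[PotSpec]:
    """Read a design CSV back into validated :class:`PotSpec` objects."""
    df = pd.read_csv(path, dtype={"provenance_2": "string"})
    missing = set(DESIGN_COLUMNS) - set(df.columns)
    if missing:
        raise InvalidInputError(f"design file missing columns: {sorted(missing)}")
    pots = []
    for _, row in df.iterrows():
        p2 = row["provenance_2"]
        provs = (row["provenance_1"],) if pd.isna(p2) or p2 == "" else (row["provenance_1"], p2)
        pots.append(
            PotSpec(
                soil_country=row["soil_country"],
                soil_site=int(row["soil_site"]),
                species=row["species"],
                treatment=row["treatment"],
                provenances=tuple(provs),
                replicate=int(row["replicate"]),
            )
        )
    return pots


def with_mode(config: DesignConfig, mode: str) -> DesignConfig:
    """Copy of ``config`` with a different paired-design reading."""
    return replace(config, mode=mode)
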