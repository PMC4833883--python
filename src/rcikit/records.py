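"""Plant-level record table: schema, validation and CSV round-trip.

One row per harvested plant.  Growth rate is defined as dry biomass divided
by the number of glasshouse growing days, and the table is rejected if the
stored rate disagrees with that identity.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from rcikit.design import PROVENANCES, SOIL_COUNTRIES, SPECIES
from rcikit.errors import RecordValidationError

#: Fixed column order of a plant-record CSV.
RECORD_COLUMNS: tuple[str, ...] = (
    "pot_id",
    "soil_country",
    "soil_site",
    "species",
    "treatment",
    "replicate",
    "plant_slot",
    "focal_provenance",
    "partner_provenance",
    "nodulation_score",
    "growing_days",
    "dry_biomass_g",
    "growth_rate",
)

_REL_TOL = 1e-9


def validate_records(records: pd.DataFrame) -> None:
    """Raise :class:`RecordValidationError` on the first violated invariant.

    Error messages cite 1-based row numbers of the offending rows.
    """
    missing = set(RECORD_COLUMNS) - set(records.columns)
    if missing:
        raise RecordValidationError(f"missing columns: {sorted(missing)}")

    def bad_rows(mask: pd.Series) -> list[int]:
        return [int(i) + 1 for i in np.flatnonzero(mask.to_numpy())]

    checks: list[tuple[pd.Series, str]] = [
        (~records["soil_country"].isin(SOIL_COUNTRIES), "unknown soil_country"),
        (~records["species"].isin(SPECIES), "unknown species"),
        (~records["treatment"].isin(["single", "paired"]), "unknown treatment"),
        (~records["focal_provenance"].isin(PROVENANCES), "unknown focal_provenance"),
        (records["dry_biomass_g"] <= 0, "dry_biomass_g must be > 0"),
        (records["growing_days"] <= 0, "growing_days must be > 0"),
        (~records["nodulation_score"].isin([0, 1, 2, 3]), "nodulation_score outside 0-3"),
        (~records["plant_slot"].isin([1, 2]), "plant_slot must be 1 or 2"),
    ]
    partner = records["partner_provenance"]
    has_partner = partner.notna() & (partner != "")
    checks.append(
        ((records["treatment"] == "single") & has_partner, "single pot with a partner")
    )
    checks.append(
        ((records["treatment"] == "paired") & ~has_partner, "paired pot without a partner")
    )
    checks.append(
        (has_partner & ~partner.isin(list(PROVENANCES) + [np.nan]), "unknown partner_provenance")
    )
    expected = records["dry_biomass_g"] / records["growing_days"]
    mismatch = ~np.isclose(records["growth_rate"], expected, rtol=_REL_TOL, atol=0)
    checks.append((pd.Series(mismatch, index=records.index), "growth_rate != dry_biomass_g / growing_days"))

    for mask, message in checks:
        if mask.any():
            raise RecordValidationError(f"{message} (rows {bad_rows(mask)[:10]})")


def write_records(records: pd.DataFrame, path: str | Path) -> None:
    """Write a validated record table as tidy CSV (empty field = no partner)."""
    validate_records(records)
    out = records.loc[:, list(RECORD_COLUMNS)].copy()
    out["partner_provenance"] = out["partner_provenance"].fillna("")
    out.to_csv(path, index=False, float_format="%.17g")


def read_records(path: str | Path) -> pd.DataFrame:
    """Read a record CSV, recompute growth rates and validate all invariants."""
    try:
        df = pd.read_csv(
            path,
            dtype={
                "partner_provenance": "object",
                "soil_site": "int64",
                "replicate": "int64",
                "plant_slot": "int64",
                "nodulation_score": "int64",
                "growing_days": "int64",
            },
            float_precision="round_trip",
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise RecordValidationError(f"malformed record file {path}: {exc}") from exc
    missing = set(RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise RecordValidationError(f"missing columns: {sorted(missing)}")
    df["partner_provenance"] = df["partner_provenance"].where(
        df["partner_provenance"].notna() & (df["partner_provenance"] != ""), np.nan
    )
    validate_records(df)
    # growth_rate is derived; keep the identity exact after the round-trip
    df["growth_rate"] = df["dry_biomass_g"] / df["growing_days"]
    return df
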