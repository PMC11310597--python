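"""Packaged lookup tables: country regions, reporter occupations, outcomes.

These are editable conventions, not regulatory data: the reporting-region
grouping (Europe / North America / Asia / Oceania / South America / Africa)
is not a field of the source database, and the occupation and outcome code
maps follow the usual quarterly-file code books.
"""
from __future__ import annotations

from functools import lru_cache
from importlib import resources
from pathlib import Path

import pandas as pd

UNKNOWN = "unknown"

#: occp_cod -> reporter category
OCCUPATION_MAP = {
    "MD": "health_professional",
    "PH": "health_professional",
    "OT": "health_professional",
    "HP": "health_professional",
    "CN": "non_health_professional",
    "LW": "non_health_professional",
}

#: outc_cod -> outcome category
OUTCOME_MAP = {
    "DE": "death",
    "LT": "life_threatening",
    "HO": "hospitalization",
    "DS": "disability",
    "CA": "congenital_anomaly",
    "RI": "required_intervention",
    "OT": "other_serious",
}

OUTCOME_CATEGORIES = (
    "death",
    "life_threatening",
    "hospitalization",
    "disability",
    "congenital_anomaly",
    "required_intervention",
    "other_serious",
    UNKNOWN,
)

REGIONS = (
    "Europe",
    "North America",
    "Asia",
    "Oceania",
    "South America",
    "Africa",
    UNKNOWN,
)


def _data_path(name: str) -> Path:
    return Path(str(resources.files("pvsignal").joinpath("data", name)))


@lru_cache(maxsize=None)
def load_region_map(path: str | Path | None = None) -> dict[str, str]:
    """ISO-3166 alpha-2 country code -> reporting region.

    A custom two-column CSV (``country,region``) may be supplied to change
    the grouping without touching code.
    """
    src = Path(path) if path is not None else _data_path("country_regions.csv")
    table = pd.read_csv(src, dtype=str)
    return dict(zip(table["country"].str.upper(), table["region"]))


def region_for_country(code: str | None, region_map: dict[str, str] | None = None) -> str:
    if region_map is None:
        region_map = load_region_map()
    if not code:
        return UNKNOWN
    return region_map.get(str(code).strip().upper(), UNKNOWN)
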