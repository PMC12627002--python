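"""Province -> macro-region lookup (NBS four-region classification).

The standard National Bureau of Statistics grouping of mainland provinces
into East, Central, West and Northeast ships as an editable CSV
(``data/province_regions.csv``); analyses that need a different grouping
can pass their own file of the same two-column shape.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["REGIONS", "load_region_map", "map_provinces"]

REGIONS = ("East", "Central", "West", "Northeast")


def load_region_map(path=None) -> dict[str, str]:
    """Return {province: region}; ``path`` overrides the bundled lookup."""
    if path is None:
        src = resources.files("urrbmi_redist").joinpath("data/province_regions.csv")
        with resources.as_file(src) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    if not {"province", "region"} <= set(df.columns):
        raise ValueError("region lookup needs 'province' and 'region' columns")
    bad = set(df["region"]) - set(REGIONS)
    if bad:
        raise ValueError(f"unknown region labels in lookup: {sorted(bad)}")
    return dict(zip(df["province"], df["region"]))


def map_provinces(provinces: pd.Series, path=None) -> pd.Series:
    """Map a province column to region labels; unknown provinces become NaN."""
    lookup = load_region_map(path)
    return provinces.map(lookup)
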