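"""Land-use change and bleaching scenario construction.

Deforestation converts loggable capability classes (V–VII) inside
concessions to pine plantation and arable classes (I–IV) outside
concessions to monoculture; restoration returns pine plantations to native
forest.  Bleaching applies depth-stratified proportional reductions to the
predicted coral-cover map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ridge2reef.core_io.config import (
    BLEACHING_REDUCTIONS,
    DEFAULT_C_FACTORS,
    LAND_COVER_CODES,
)
from ridge2reef.core_io.grid import Grid

#: Land covers that can be cleared for plantations or monoculture.
CONVERTIBLE_COVERS = ("native_forest", "secondary_forest", "shrubland")


@dataclass
class ScenarioSpec:
    land_use: str = "current"
    bleaching: str = "none"
    #: depth band (min, max] in meters -> proportional cover reduction
    reductions: dict[tuple[float, float], float] = field(default_factory=dict)
    proportional: bool = True

    def __post_init__(self) -> None:
        if self.land_use not in ("current", "deforestation", "restoration"):
            raise ValueError(f"unknown land-use scenario {self.land_use!r}")
        if not self.reductions and self.bleaching in BLEACHING_REDUCTIONS:
            self.reductions = dict(BLEACHING_REDUCTIONS[self.bleaching])
        for band, r in self.reductions.items():
            if not 0 <= r <= 1:
                raise ValueError(f"reduction {r} for band {band} not in [0, 1]")
        bands = sorted(self.reductions)
        for (a, b), (c, d) in zip(bands, bands[1:]):
            if c < b:
                raise ValueError("depth bands overlap")


def c_factor_grid(
    land_use: Grid, c_factors: dict[str, float] | None = None
) -> Grid:
    """Cover-factor grid from land-cover class codes."""
    c_factors = c_factors or DEFAULT_C_FACTORS
    out = np.full(land_use.shape, np.nan)
    for name, code in LAND_COVER_CODES.items():
        if name in c_factors:
            out[land_use.values == code] = c_factors[name]
    unknown = np.isnan(out) & land_use.mask()
    if unknown.any():
        codes = np.unique(land_use.values[unknown])
        raise ValueError(f"unknown land-cover class codes {codes.tolist()}")
    return Grid(out, land_use.cell_size, land_use.origin, float("nan"), land_use.crs)


def apply_landuse_scenario(
    land_use: Grid,
    luc: Grid,
    concessions: Grid,
    scenario: str,
    c_factors: dict[str, float] | None = None,
) -> tuple[Grid, Grid, pd.DataFrame]:
    """Reclassify land use under a scenario and rebuild the C grid.

    Returns ``(new_land_use, new_c_grid, ledger)`` where the ledger records
    per-class area (ha) before and after.
    """
    codes = LAND_COVER_CODES
    lu = land_use.values.copy()
    luc_vals = luc.values
    if land_use.mask().any():
        bad = np.unique(luc_vals[land_use.mask() & ((luc_vals < 1) | (luc_vals > 8))])
        if bad.size:
            raise ValueError(f"LUC classes outside I–VIII: {bad.tolist()}")
    conc = concessions.values.astype(bool)
    before = lu.copy()

    if scenario == "deforestation":
        convertible = np.isin(
            lu, [codes[c] for c in CONVERTIBLE_COVERS]
        )
        loggable = np.isin(luc_vals, [5, 6, 7])
        arable = np.isin(luc_vals, [1, 2, 3, 4])
        lu[conc & loggable & convertible] = codes["pine_plantation"]
        lu[~conc & arable & convertible] = codes["monoculture"]
        # LUC VIII (conservation-only) never converts, by construction
    elif scenario == "restoration":
        lu[lu == codes["pine_plantation"]] = codes["native_forest"]
    elif scenario != "current":
        raise ValueError(f"unknown scenario {scenario!r}")

    new_lu = land_use.like(lu)
    new_c = c_factor_grid(new_lu, c_factors)
    area = land_use.cell_area_ha
    rows = []
    for name, code in codes.items():
        rows.append(
            {
                "class": name,
                "area_ha_before": float(np.sum(before == code)) * area,
                "area_ha_after": float(np.sum(lu == code)) * area,
            }
        )
    return new_lu, new_c, pd.DataFrame(rows)


def apply_bleaching(
    coral_map: Grid,
    depth: Grid,
    spec: ScenarioSpec | str,
) -> Grid:
    """Reduce predicted coral cover in each depth band by the configured
    proportion; cells outside all bands are unchanged."""
    if isinstance(spec, str):
        spec = ScenarioSpec(bleaching=spec)
    coral_map.require_aligned(depth, "coral and depth grids")
    out = coral_map.values.copy().astype(float)
    d = depth.values
    for (dmin, dmax), reduction in spec.reductions.items():
        band = np.isfinite(d) & (d >= dmin) & (d < dmax)
        if spec.proportional:
            out[band] = out[band] * (1.0 - reduction)
        else:
            out[band] = np.maximum(out[band] - 100.0 * reduction, 0.0)
    return coral_map.like(out)
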