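"""Tracing reef impacts back to source watersheds and priority land areas.

Watersheds are linked to a significant reef footprint when they jointly
contribute the bulk (> 90 %) of the dispersed sediment over that
footprint; within linked watersheds, the smallest set of cells carrying
more than 66 % of the export (or the cells with significantly changed
export) become priority land areas, buffered by 100 m for management.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import box
from shapely.ops import unary_union

from ridge2reef.core_io.grid import Grid
from ridge2reef.impact_assessment import SigDiffParams, sig_diff
from ridge2reef.sediment_export import WatershedSet


@dataclass
class LinkageResult:
    linked: list[int]
    fractions: dict[int, float]

    def frame(self) -> pd.DataFrame:
        rows = [
            {
                "watershed_id": wid,
                "contribution_fraction": frac,
                "linked": wid in self.linked,
            }
            for wid, frac in sorted(
                self.fractions.items(), key=lambda kv: -kv[1]
            )
        ]
        return pd.DataFrame(rows)


def link_watersheds(
    sig_reef_mask: Grid,
    plumes: dict[int, Grid],
    threshold: float = 0.90,
) -> LinkageResult:
    """Smallest set of watersheds whose cumulative share of dispersed
    sediment over the significant reef cells exceeds ``threshold``.

    Watersheds are ranked by their plume sum over the footprint; the linked
    set is the minimal prefix of that descending ranking.
    """
    mask = sig_reef_mask.values.astype(bool)
    contributions: dict[int, float] = {}
    for wid, plume in plumes.items():
        sig_reef_mask.require_aligned(plume, "mask and plume grids")
        contributions[wid] = float(np.nansum(plume.values[mask]))
    total = sum(contributions.values())
    if not mask.any():
        return LinkageResult([], {w: 0.0 for w in contributions})
    if total <= 0:
        raise ValueError("no dispersed sediment over the significant reef cells")
    fractions = {w: v / total for w, v in contributions.items()}
    ranked = sorted(fractions.items(), key=lambda kv: (-kv[1], kv[0]))
    linked: list[int] = []
    cum = 0.0
    for wid, frac in ranked:
        linked.append(wid)
        cum += frac
        if cum > threshold:
            break
    return LinkageResult(linked, fractions)


def priority_land_areas(
    export_current: Grid,
    watersheds: WatershedSet,
    linked: list[int],
    mode: str = "climate",
    frac: float = 0.66,
    export_scenario: Grid | None = None,
    sigdiff_params: SigDiffParams | None = None,
    flow_accum: Grid | None = None,
) -> Grid:
    """Priority land mask on the 30 m grid.

    ``climate`` mode selects, per linked watershed, the smallest cell set
    whose cumulative current-land-use export exceeds ``frac`` of the
    watershed total (ties broken by flow accumulation, then row-major
    order).  ``landuse`` mode flags cells of linked watersheds whose export
    change versus present is significant.
    """
    if not linked:
        raise ValueError("linked watershed set is empty")
    labels = watersheds.labels.values
    mask = np.zeros(labels.shape, dtype=np.int32)
    if mode == "climate":
        export = np.nan_to_num(export_current.values, nan=0.0)
        accum = (
            np.nan_to_num(flow_accum.values, nan=0.0)
            if flow_accum is not None
            else np.zeros_like(export)
        )
        for wid in linked:
            cells = np.argwhere(labels == wid)
            if not len(cells):
                continue
            vals = export[cells[:, 0], cells[:, 1]]
            total = vals.sum()
            if total <= 0:
                continue
            acc = accum[cells[:, 0], cells[:, 1]]
            rowmajor = cells[:, 0] * labels.shape[1] + cells[:, 1]
            order = np.lexsort((rowmajor, -acc, -vals))
            cum = np.cumsum(vals[order])
            # smallest prefix with cumulative export > frac of the total
            k = int(np.searchsorted(cum, frac * total, side="right")) + 1
            k = min(k, len(order))
            chosen = cells[order[:k]]
            mask[chosen[:, 0], chosen[:, 1]] = 1
    elif mode == "landuse":
        if export_scenario is None:
            raise ValueError("landuse mode needs the scenario export grid")
        _, sig, _ = sig_diff(
            export_scenario, export_current, sigdiff_params or SigDiffParams()
        )
        in_linked = np.isin(labels, list(linked))
        mask[(sig.values == 1) & in_linked] = 1
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return Grid(mask, watersheds.labels.cell_size, watersheds.labels.origin, 0,
                watersheds.labels.crs)


def buffer_priority(
    mask: Grid,
    distance: float = 100.0,
    land_mask: np.ndarray | None = None,
):
    """Dissolved polygons: union of priority cell squares dilated by
    ``distance`` meters (rounded corners), clipped to land."""
    cells = np.argwhere(mask.values.astype(bool))
    if not len(cells):
        return unary_union([])
    cs = mask.cell_size
    x0, y0 = mask.origin
    boxes = [
        box(x0 + c * cs, y0 - (r + 1) * cs, x0 + (c + 1) * cs, y0 - r * cs)
        for r, c in cells
    ]
    buffered = unary_union(boxes).buffer(distance)
    if land_mask is not None:
        land_cells = np.argwhere(np.asarray(land_mask, dtype=bool))
        land_poly = unary_union(
            [
                box(x0 + c * cs, y0 - (r + 1) * cs, x0 + (c + 1) * cs, y0 - r * cs)
                for r, c in land_cells
            ]
        )
        buffered = buffered.intersection(land_poly)
    return buffered
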