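"""Coastal sediment plume dispersal.

Each watershed's exported load spreads from its pour point over the marine
grid along least-accumulated-cost paths, with the per-cell unit cost a
weighted blend of normalized depth, distance to the stream mouth, and wind
exposure.  The dispersed surface decays as s_p·exp(−c²/D_c) and is clipped
to a fixed distance from the shoreline; plumes are summed into a TSS proxy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from ridge2reef.core_io.config import PlumeParams
from ridge2reef.core_io.grid import Grid
from ridge2reef.sediment_export import NEIGHBOR_OFFSETS, _STEP


@dataclass
class PlumeField:
    """Per-watershed dispersed sediment surfaces and their cellwise sum."""

    costs: dict[int, Grid]
    plumes: dict[int, Grid]
    tss: Grid
    s_p: dict[int, float] = field(default_factory=dict)

    def totals_frame(self) -> pd.DataFrame:
        rows = [
            {
                "watershed_id": wid,
                "load_t_yr": self.s_p.get(wid, 0.0),
                "plume_sum_t_yr": float(np.nansum(g.values)),
            }
            for wid, g in sorted(self.plumes.items())
        ]
        return pd.DataFrame(rows)


def _minmax(values: np.ndarray, mask: np.ndarray, name: str) -> np.ndarray:
    lo = np.nanmin(np.where(mask, values, np.nan))
    hi = np.nanmax(np.where(mask, values, np.nan))
    if not np.isfinite(lo) or not np.isfinite(hi) or hi - lo < 1e-12:
        warnings.warn(f"driver {name!r} is constant over the marine domain; "
                      "its cost contribution is zeroed", stacklevel=3)
        return np.zeros_like(values, dtype=float)
    return (values - lo) / (hi - lo)


def build_cost_surface(
    depth: Grid,
    dist_to_mouth: Grid,
    wind_exposure: Grid,
    params: PlumeParams,
) -> Grid:
    """Unit cost grid: weighted sum of min–max normalized drivers, floored
    at a small positive value so accumulated cost strictly increases."""
    depth.require_aligned(dist_to_mouth, "marine driver grids")
    depth.require_aligned(wind_exposure, "marine driver grids")
    mask = depth.mask()
    cost = (
        params.w_depth * _minmax(depth.values, mask, "depth")
        + params.w_dist * _minmax(dist_to_mouth.values, mask, "distance")
        + params.w_wind * _minmax(wind_exposure.values, mask, "wind exposure")
    )
    cost = np.maximum(cost, params.cost_floor)
    cost = np.where(mask, cost, np.nan)
    return depth.like(cost)


def accumulate_cost(unit_cost: Grid, pour_point: tuple[float, float]) -> Grid:
    """Minimal accumulated cost over 8-connected paths from the pour point.

    Edge cost = planimetric step length (m) × mean unit cost of the two
    cells.  Marine cells unreachable from the pour point get nodata.
    """
    values = unit_cost.values
    valid = unit_cost.mask()
    nrow, ncol = values.shape
    idx = -np.ones((nrow, ncol), dtype=np.int64)
    cells = np.argwhere(valid)
    idx[cells[:, 0], cells[:, 1]] = np.arange(len(cells))

    rows, cols, weights = [], [], []
    d = unit_cost.cell_size
    for k, (dr, dc) in enumerate(NEIGHBOR_OFFSETS):
        rr = cells[:, 0] + dr
        cc = cells[:, 1] + dc
        inb = (rr >= 0) & (rr < nrow) & (cc >= 0) & (cc < ncol)
        src_rc = cells[inb]
        rr, cc = rr[inb], cc[inb]
        keep = valid[rr, cc]
        src_rc, rr, cc = src_rc[keep], rr[keep], cc[keep]
        rows.append(idx[src_rc[:, 0], src_rc[:, 1]])
        cols.append(idx[rr, cc])
        weights.append(d * _STEP[k] * 0.5 * (values[src_rc[:, 0], src_rc[:, 1]] + values[rr, cc]))
    n = len(cells)
    graph = coo_matrix(
        (np.concatenate(weights), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsr()

    r0, c0 = unit_cost.rowcol(*pour_point)
    r0 = min(max(r0, 0), nrow - 1)
    c0 = min(max(c0, 0), ncol - 1)
    if idx[r0, c0] < 0:
        # pour point sits on the coastline: snap to the nearest marine cell
        dist2 = (cells[:, 0] - r0) ** 2 + (cells[:, 1] - c0) ** 2
        source = int(np.argmin(dist2))
    else:
        source = int(idx[r0, c0])
    dist = dijkstra(graph, directed=False, indices=source)
    out = np.full((nrow, ncol), np.nan)
    out[cells[:, 0], cells[:, 1]] = dist
    out[~np.isfinite(out)] = np.nan
    return unit_cost.like(out)


def calibrate_dc(
    cost: Grid,
    shoreline_dist: Grid,
    max_distance: float = 3000.0,
    band: float = 300.0,
) -> float:
    """Decay scale: square of the mean accumulated cost over marine cells in
    a ring around the cutoff distance from shore, so exp(−c²/D_c) ≈ 1/e at
    the cutoff."""
    ring = (
        np.isfinite(cost.values)
        & (shoreline_dist.values >= max_distance - band)
        & (shoreline_dist.values <= max_distance + band)
    )
    if not ring.any():
        # fall back to the largest finite cost observed
        ref = np.nanmax(cost.values)
    else:
        ref = float(np.nanmean(cost.values[ring]))
    if not np.isfinite(ref) or ref <= 0:
        raise ValueError("cannot calibrate decay scale: no finite costs")
    return float(ref * ref)


def disperse(
    s_p: float,
    cost: Grid,
    params: PlumeParams,
    shoreline_dist: Grid,
    d_c: float | None = None,
) -> Grid:
    """Dispersed sediment surface S = s_p·exp(−c²/D_c), zero beyond the
    shoreline cutoff distance."""
    if s_p < 0:
        raise ValueError("pour-point load must be nonnegative")
    if d_c is None:
        d_c = params.d_c
    if d_c is None:
        d_c = calibrate_dc(cost, shoreline_dist, params.max_distance)
    if d_c <= 0:
        raise ValueError("D_c must be > 0")
    c = cost.values
    with np.errstate(over="ignore"):
        s = s_p * np.exp(-(c * c) / d_c)
    s = np.where(np.isfinite(c), s, 0.0)
    s = np.where(
        np.nan_to_num(shoreline_dist.values, nan=np.inf) <= params.max_distance,
        s,
        0.0,
    )
    return cost.like(s)


def sum_plumes(plumes: dict[int, Grid]) -> Grid:
    """Cellwise sum of per-watershed plumes (the TSS proxy)."""
    if not plumes:
        raise ValueError("no plumes to sum")
    grids = list(plumes.values())
    first = grids[0]
    total = np.zeros(first.shape)
    for g in grids:
        first.require_aligned(g, "plume grids")
        total += np.nan_to_num(g.values, nan=0.0)
    return first.like(total)


def run_plume(
    loads: dict[int, float],
    pour_points: dict[int, tuple[float, float]],
    depth: Grid,
    shoreline_dist: Grid,
    wind_exposure: Grid,
    params: PlumeParams | None = None,
) -> PlumeField:
    """Disperse every watershed load and sum the plumes.

    Distance-to-mouth for the cost composite is computed per pour point as
    Euclidean distance on the marine grid.
    """
    params = params or PlumeParams()
    costs: dict[int, Grid] = {}
    plumes: dict[int, Grid] = {}
    xs = depth.x_centers()
    ys = depth.y_centers()
    xx, yy = np.meshgrid(xs, ys)
    for wid in sorted(pour_points):
        px, py = pour_points[wid]
        dist_mouth = depth.like(np.hypot(xx - px, yy - py))
        unit = build_cost_surface(depth, dist_mouth, wind_exposure, params)
        cost = accumulate_cost(unit, (px, py))
        costs[wid] = cost
        plumes[wid] = disperse(loads.get(wid, 0.0), cost, params, shoreline_dist)
    tss = sum_plumes(plumes)
    return PlumeField(costs=costs, plumes=plumes, tss=tss, s_p=dict(loads))
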