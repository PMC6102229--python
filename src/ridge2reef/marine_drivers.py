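"""Marine predictor grids from bathymetry and habitat-class maps.

Derives geography (depth, distance from shore), seafloor terrain (BPI at
two scales, slope, slope of slope, curvatures), exposure (aspect, circular
statistics, northness/eastness), and habitat-connectivity metrics
(contiguity, fractal dimension, proximity, Shannon diversity).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from ridge2reef.core_io.grid import Grid

CONTINUOUS_DRIVERS = (
    "depth", "dist_shore", "bpi_60", "bpi_240", "slope", "slope_of_slope",
    "curv_plan", "curv_prof", "northness", "eastness", "aspect_circ_sd",
    "contiguity", "fractal_dim", "proximity", "shannon",
)


@dataclass
class DriverStack:
    """Co-registered named marine predictor grids."""

    grids: dict[str, Grid]

    def __post_init__(self) -> None:
        names = list(self.grids)
        first = self.grids[names[0]]
        for name in names[1:]:
            first.require_aligned(self.grids[name], f"driver grids ({name})")

    def __getitem__(self, name: str) -> Grid:
        return self.grids[name]

    def names(self) -> list[str]:
        return list(self.grids)

    def manifest(self) -> pd.DataFrame:
        units = {
            "depth": "m", "dist_shore": "m", "bpi_60": "m", "bpi_240": "m",
            "slope": "deg", "slope_of_slope": "deg", "curv_plan": "1/m",
            "curv_prof": "1/m", "aspect": "deg", "northness": "-",
            "eastness": "-", "aspect_circ_sd": "rad", "contiguity": "-",
            "fractal_dim": "-", "proximity": "-", "shannon": "nats",
            "tss": "t/yr",
        }
        return pd.DataFrame(
            [{"name": n, "units": units.get(n, "-")} for n in self.grids]
        )


# ---------------------------------------------------------------------------
# Geography
# ---------------------------------------------------------------------------


def compute_geography(
    bathy: Grid,
    land_mask: np.ndarray,
    positive_down: bool = True,
) -> tuple[Grid, Grid]:
    """Depth (m, positive down, marine only) and Euclidean distance from the
    coastline (m, 0 on coastal/land cells)."""
    if positive_down is None:
        raise ValueError("depth sign convention must be declared")
    depth = bathy.values if positive_down else -bathy.values
    depth = np.where(land_mask, np.nan, depth)
    dist = ndimage.distance_transform_edt(
        ~np.asarray(land_mask, dtype=bool), sampling=bathy.cell_size
    )
    return bathy.like(depth), bathy.like(dist.astype(float))


# ---------------------------------------------------------------------------
# Terrain
# ---------------------------------------------------------------------------


def _disk_kernel(radius_cells: float) -> np.ndarray:
    r = int(np.floor(radius_cells))
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    return (yy**2 + xx**2 <= radius_cells**2 + 1e-9).astype(float)


def _nanmean_filter(values: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Mean over the kernel footprint ignoring NaNs (shrinking at edges)."""
    finite = np.isfinite(values)
    filled = np.where(finite, values, 0.0)
    total = ndimage.convolve(filled, kernel, mode="constant", cval=0.0)
    count = ndimage.convolve(finite.astype(float), kernel, mode="constant", cval=0.0)
    with np.errstate(invalid="ignore"):
        return np.where(count > 0, total / count, np.nan)


def compute_bpi(bathy_depth: Grid, radius: float) -> Grid:
    """Bathymetric position index: neighborhood-mean depth minus cell depth
    over a circular window of ``radius`` meters (positive = ridge/pinnacle).
    """
    if radius < bathy_depth.cell_size:
        raise ValueError("BPI radius must be at least one cell")
    kernel = _disk_kernel(radius / bathy_depth.cell_size)
    mean_depth = _nanmean_filter(bathy_depth.values, kernel)
    bpi = mean_depth - bathy_depth.values
    return bathy_depth.like(np.where(np.isfinite(bathy_depth.values), bpi, np.nan))


def _fill_nearest(values: np.ndarray) -> np.ndarray:
    """Replace NaN cells with the value of the nearest finite cell, so 3×3
    stencils stay defined along the land-sea boundary."""
    finite = np.isfinite(values)
    if finite.all():
        return values
    if not finite.any():
        return values
    idx = ndimage.distance_transform_edt(~finite, return_distances=False,
                                         return_indices=True)
    return values[tuple(idx)]


def _horn_gradient(values: np.ndarray, cell_size: float) -> tuple[np.ndarray, np.ndarray]:
    """Horn 3×3 gradient (dz/dx eastward, dz/dy northward) on an elevation
    surface laid out row-major from the north."""
    z = _fill_nearest(np.asarray(values, dtype=float))
    # replicate edges so border cells keep a defined gradient
    zp = np.pad(z, 1, mode="edge")
    a = zp[:-2, :-2]; b = zp[:-2, 1:-1]; c = zp[:-2, 2:]
    d = zp[1:-1, :-2]; f = zp[1:-1, 2:]
    g = zp[2:, :-2]; h = zp[2:, 1:-1]; i = zp[2:, 2:]
    dzdx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8.0 * cell_size)
    dzdy = ((a + 2 * b + c) - (g + 2 * h + i)) / (8.0 * cell_size)
    return dzdx, dzdy


def compute_slope(elevation: Grid) -> Grid:
    """Slope in degrees via the Horn 3×3 operator."""
    dzdx, dzdy = _horn_gradient(elevation.values, elevation.cell_size)
    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    return elevation.like(slope)


def compute_terrain(bathy_depth: Grid) -> tuple[Grid, Grid, Grid, Grid]:
    """Slope, slope-of-slope (both deg), and planar/profile curvature (1/m)
    of the seafloor."""
    elev = bathy_depth.like(-bathy_depth.values)  # work on elevation
    slope = compute_slope(elev)
    slope_of_slope = compute_slope(slope.like(slope.values))

    z = _fill_nearest(np.asarray(elev.values, dtype=float))
    cs = bathy_depth.cell_size
    zy, zx = np.gradient(z, cs)
    zy = -zy  # row axis runs southward
    zyy, zyx = np.gradient(zy, cs)
    zxy, zxx = np.gradient(zx, cs)
    zyy = -zyy
    zxy = -zxy
    g2 = zx**2 + zy**2
    with np.errstate(invalid="ignore", divide="ignore"):
        prof = (zxx * zx**2 + 2 * zxy * zx * zy + zyy * zy**2) / g2
        plan = (zxx * zy**2 - 2 * zxy * zx * zy + zyy * zx**2) / g2
    mean_curv = 0.5 * (zxx + zyy)
    flat = g2 < 1e-12
    prof = np.where(flat, mean_curv, prof)
    plan = np.where(flat, mean_curv, plan)
    valid = np.isfinite(bathy_depth.values)
    return (
        slope.like(np.where(valid, slope.values, np.nan)),
        slope_of_slope.like(np.where(valid, slope_of_slope.values, np.nan)),
        bathy_depth.like(np.where(valid, plan, np.nan)),
        bathy_depth.like(np.where(valid, prof, np.nan)),
    )


# ---------------------------------------------------------------------------
# Exposure
# ---------------------------------------------------------------------------


def compute_aspect(bathy_depth: Grid) -> Grid:
    """Steepest downslope direction of the seafloor, degrees clockwise from
    north; flat cells are nodata."""
    elev = -bathy_depth.values
    dzdx, dzdy = _horn_gradient(elev, bathy_depth.cell_size)
    flat = np.hypot(dzdx, dzdy) < 1e-9
    aspect = np.degrees(np.arctan2(-dzdx, -dzdy)) % 360.0
    aspect = np.where(flat | ~np.isfinite(bathy_depth.values), np.nan, aspect)
    return bathy_depth.like(aspect)


def compute_exposure(
    bathy_depth: Grid, window: int = 3
) -> tuple[Grid, Grid, Grid, Grid]:
    """Aspect plus windowed circular statistics.

    Returns (aspect, northness, eastness, circular SD).  Northness and
    eastness are cos/sin of the circular-mean aspect over the window; the
    circular SD is sqrt(−2·ln R̄) in radians.
    """
    if window % 2 != 1:
        raise ValueError("window must be odd")
    aspect = compute_aspect(bathy_depth)
    rad = np.radians(aspect.values)
    kernel = np.ones((window, window))
    sin_m = _nanmean_filter(np.sin(rad), kernel)
    cos_m = _nanmean_filter(np.cos(rad), kernel)
    rbar = np.hypot(sin_m, cos_m)
    mean_angle = np.arctan2(sin_m, cos_m)
    with np.errstate(invalid="ignore", divide="ignore"):
        circ_sd = np.sqrt(np.maximum(-2.0 * np.log(np.clip(rbar, 1e-12, 1.0)), 0.0))
    northness = np.cos(mean_angle)
    eastness = np.sin(mean_angle)
    valid = np.isfinite(bathy_depth.values)

    def _mask(arr: np.ndarray) -> Grid:
        return bathy_depth.like(np.where(valid, arr, np.nan))

    return aspect, _mask(northness), _mask(eastness), _mask(circ_sd)


def compute_wind_exposure(aspect: Grid, wind_from_deg: float = 135.0) -> Grid:
    """Angular exposure (deg, 0–180) of the seafloor aspect to the prevailing
    wind direction (default: southeast trades)."""
    diff = np.abs(((aspect.values - wind_from_deg + 180.0) % 360.0) - 180.0)
    exposure = 180.0 - diff
    exposure = np.where(np.isfinite(aspect.values), exposure, 90.0)
    return aspect.like(exposure)


# ---------------------------------------------------------------------------
# Habitat metrics
# ---------------------------------------------------------------------------

_CONTIG_KERNEL = np.array([[1.0, 2.0, 1.0], [2.0, 1.0, 2.0], [1.0, 2.0, 1.0]])
_CONTIG_MAX = float(_CONTIG_KERNEL.sum())  # 13


def _patches(habitat: Grid, connectivity: int = 1):
    """Yield (class_code, patch_label_array, n_patches) per habitat class."""
    values = habitat.values
    nodata = int(habitat.nodata) if not np.isnan(habitat.nodata) else None
    classes = np.unique(values)
    structure = ndimage.generate_binary_structure(2, connectivity)
    for cls in classes:
        if nodata is not None and cls == nodata:
            continue
        labeled, n = ndimage.label(values == cls, structure=structure)
        if n:
            yield int(cls), labeled, n


def compute_habitat_metrics(
    habitat: Grid,
    window: int = 5,
    search_radius: float = 600.0,
    connectivity: int = 1,
) -> tuple[Grid, Grid, Grid, Grid]:
    """Contiguity, fractal dimension, proximity, and Shannon diversity.

    Patch metrics (contiguity/fractal/proximity) are computed per
    4-connected same-class patch and rasterized back onto member cells;
    Shannon diversity (nats) uses class proportions in a moving window.
    """
    values = habitat.values
    if values.size == 0 or not np.isfinite(values.astype(float)).any():
        raise ValueError("empty habitat map")
    cs = habitat.cell_size
    contig = np.full(values.shape, np.nan)
    frac = np.full(values.shape, np.nan)
    prox = np.full(values.shape, np.nan)

    for cls, labeled, n in _patches(habitat, connectivity):
        inside = labeled > 0
        # per-pixel template sum restricted to same-patch neighbors
        same = ndimage.convolve(
            inside.astype(float), _CONTIG_KERNEL, mode="constant", cval=0.0
        )
        areas = ndimage.sum_labels(inside, labeled, index=np.arange(1, n + 1))
        boundaries: list[np.ndarray] = []
        for p in range(1, n + 1):
            patch = labeled == p
            # contiguity: mean template value over patch cells (center weight
            # 1 counts the cell itself), rescaled to [0, 1]
            mean_t = same[patch].mean()
            contig_val = (mean_t - 1.0) / (_CONTIG_MAX - 1.0)
            contig[patch] = min(max(contig_val, 0.0), 1.0)
            # perimeter: exposed cell edges, in meters
            padded = np.pad(patch, 1)
            perim_cells = (
                np.sum(padded[1:-1, 1:-1] & ~padded[:-2, 1:-1])
                + np.sum(padded[1:-1, 1:-1] & ~padded[2:, 1:-1])
                + np.sum(padded[1:-1, 1:-1] & ~padded[1:-1, :-2])
                + np.sum(padded[1:-1, 1:-1] & ~padded[1:-1, 2:])
            )
            perim_m = perim_cells * cs
            area_m2 = patch.sum() * cs * cs
            with np.errstate(divide="ignore", invalid="ignore"):
                f = 2.0 * np.log(0.25 * perim_m) / np.log(area_m2)
            frac[patch] = f
            # boundary pixels for proximity distances
            eroded = ndimage.binary_erosion(patch)
            boundary = np.argwhere(patch & ~eroded)
            boundaries.append(boundary)
        # proximity: sum area/dist^2 over same-class patches within radius
        for p in range(1, n + 1):
            patch = labeled == p
            total = 0.0
            for q in range(1, n + 1):
                if q == p:
                    continue
                bp, bq = boundaries[p - 1], boundaries[q - 1]
                d2 = (
                    (bp[:, None, 0] - bq[None, :, 0]) ** 2
                    + (bp[:, None, 1] - bq[None, :, 1]) ** 2
                ).min() * cs * cs
                dist = np.sqrt(d2)
                if 0 < dist <= search_radius:
                    total += (areas[q - 1] * cs * cs) / d2
            prox[patch] = total

    shannon = compute_shannon(habitat, window)
    return (
        habitat.like(contig),
        habitat.like(frac),
        habitat.like(prox),
        shannon,
    )


def compute_shannon(habitat: Grid, window: int = 5) -> Grid:
    """Shannon diversity (nats) of habitat-class proportions in a moving
    window, with shrunken windows at edges."""
    values = habitat.values
    kernel = np.ones((window, window))
    nodata = int(habitat.nodata) if not np.isnan(habitat.nodata) else None
    classes = [c for c in np.unique(values) if nodata is None or c != nodata]
    valid = np.ones(values.shape) if nodata is None else (values != nodata).astype(float)
    count = ndimage.convolve(valid, kernel, mode="constant", cval=0.0)
    h = np.zeros(values.shape)
    for cls in classes:
        k = ndimage.convolve((values == cls).astype(float), kernel,
                             mode="constant", cval=0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(count > 0, k / count, 0.0)
            h -= np.where(p > 0, p * np.log(p), 0.0)
    h = np.where(valid > 0, h, np.nan)
    return habitat.like(h)


# ---------------------------------------------------------------------------
# Stack assembly
# ---------------------------------------------------------------------------


def build_driver_stack(
    bathy: Grid,
    land_mask: np.ndarray,
    habitat: Grid | None = None,
    positive_down: bool = True,
    exposure_window: int = 3,
    shannon_window: int = 5,
    proximity_radius: float = 600.0,
) -> DriverStack:
    """Derive the full marine driver stack from bathymetry (and habitat)."""
    depth, dist_shore = compute_geography(bathy, land_mask, positive_down)
    grids: dict[str, Grid] = {"depth": depth, "dist_shore": dist_shore}
    grids["bpi_60"] = compute_bpi(depth, max(60.0, depth.cell_size))
    grids["bpi_240"] = compute_bpi(depth, 240.0)
    slope, sos, plan, prof = compute_terrain(depth)
    grids.update(slope=slope, slope_of_slope=sos, curv_plan=plan, curv_prof=prof)
    aspect, northness, eastness, circ_sd = compute_exposure(depth, exposure_window)
    grids.update(
        aspect=aspect, northness=northness, eastness=eastness,
        aspect_circ_sd=circ_sd,
    )
    if habitat is not None:
        contig, fracd, prox, shan = compute_habitat_metrics(
            habitat, window=shannon_window, search_radius=proximity_radius
        )
        grids.update(contiguity=contig, fractal_dim=fracd, proximity=prox,
                     shannon=shan)
    return DriverStack(grids)
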