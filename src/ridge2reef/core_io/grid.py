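"""Core raster and point-table data model.

A :class:`Grid` is a single-band georeferenced raster in a projected CRS
(coordinates in meters).  Indexing is row-major from the upper-left corner;
cell centers represent cell location.  Continuous grids use ``NaN`` as the
in-memory nodata value; class-code (integer) grids use the ``nodata``
sentinel directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd


class GridAlignmentError(ValueError):
    """Raised when an operation mixes grids on incompatible geometry."""


@dataclass
class Grid:
    """Single-band raster with square cells in projected meters.

    Parameters
    ----------
    values
        2-D array, row-major from the upper-left corner.
    cell_size
        Cell edge length in meters (> 0).
    origin
        ``(x, y)`` map coordinates of the *upper-left corner* of the
        upper-left cell.
    nodata
        Sentinel used on disk; ``NaN`` in memory for float grids.
    crs
        Opaque identifier carried through, never transformed.
    """

    values: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    nodata: float = float("nan")
    crs: str = "local-meters"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError(f"grid values must be 2-D, got {self.values.ndim}-D")
        if not self.cell_size > 0:
            raise ValueError(f"cell_size must be > 0, got {self.cell_size}")
        self.origin = (float(self.origin[0]), float(self.origin[1]))

    # -- geometry ----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def is_class_grid(self) -> bool:
        return np.issubdtype(self.values.dtype, np.integer)

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the outer grid edge."""
        nrow, ncol = self.shape
        x0, y0 = self.origin
        return (x0, y0 - nrow * self.cell_size, x0 + ncol * self.cell_size, y0)

    def x_centers(self) -> np.ndarray:
        x0 = self.origin[0]
        return x0 + (np.arange(self.shape[1]) + 0.5) * self.cell_size

    def y_centers(self) -> np.ndarray:
        y0 = self.origin[1]
        return y0 - (np.arange(self.shape[0]) + 0.5) * self.cell_size

    def rowcol(self, x: float, y: float) -> tuple[int, int]:
        """Cell indices containing map coordinates (x, y)."""
        col = int(np.floor((x - self.origin[0]) / self.cell_size))
        row = int(np.floor((self.origin[1] - y) / self.cell_size))
        return row, col

    def xy(self, row: int, col: int) -> tuple[float, float]:
        """Map coordinates of a cell center."""
        x = self.origin[0] + (col + 0.5) * self.cell_size
        y = self.origin[1] - (row + 0.5) * self.cell_size
        return x, y

    def contains(self, x: float, y: float) -> bool:
        xmin, ymin, xmax, ymax = self.extent
        return xmin <= x < xmax and ymin < y <= ymax

    # -- nodata ------------------------------------------------------------

    def mask(self) -> np.ndarray:
        """Boolean array: True where the cell holds valid data."""
        if self.is_class_grid:
            if np.isnan(self.nodata):
                return np.ones(self.shape, dtype=bool)
            return self.values != int(self.nodata)
        valid = np.isfinite(self.values)
        if not np.isnan(self.nodata):
            valid &= self.values != self.nodata
        return valid

    # -- construction helpers ---------------------------------------------

    def like(self, values: np.ndarray) -> "Grid":
        """New grid sharing this grid's geometry."""
        values = np.asarray(values)
        if values.shape != self.shape:
            raise GridAlignmentError(
                f"shape {values.shape} does not match grid {self.shape}"
            )
        return replace(self, values=values)

    def copy(self) -> "Grid":
        return replace(self, values=self.values.copy())

    def aligned_with(self, other: "Grid", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and abs(self.cell_size - other.cell_size) <= atol
            and abs(self.origin[0] - other.origin[0]) <= atol
            and abs(self.origin[1] - other.origin[1]) <= atol
        )

    def require_aligned(self, other: "Grid", what: str = "grids") -> None:
        if not self.aligned_with(other):
            raise GridAlignmentError(
                f"{what} are not aligned: "
                f"{self.shape}@{self.origin}/{self.cell_size} vs "
                f"{other.shape}@{other.origin}/{other.cell_size}"
            )

    @property
    def cell_area_ha(self) -> float:
        return self.cell_size * self.cell_size / 10_000.0


@dataclass
class PointTable:
    """Survey points: id, coordinates, and named real-valued attributes."""

    ids: np.ndarray
    x: np.ndarray
    y: np.ndarray
    attributes: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n = len(self.ids)
        if len(self.x) != n or len(self.y) != n:
            raise ValueError("ids, x, y must have the same length")
        if len(self.attributes) not in (0, n):
            raise ValueError("attribute table length mismatch")
        if self.attributes.columns.duplicated().any():
            raise ValueError("attribute names must be unique")

    def __len__(self) -> int:
        return len(self.ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PointTable":
        frame = frame.reset_index(drop=True)
        attrs = frame.drop(columns=["id", "x", "y"])
        return cls(frame["id"].to_numpy(), frame["x"].to_numpy(),
                   frame["y"].to_numpy(), attrs)

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"id": self.ids, "x": self.x, "y": self.y})
        return pd.concat([out, self.attributes.reset_index(drop=True)], axis=1)

    def subset(self, keep: np.ndarray) -> "PointTable":
        keep = np.asarray(keep)
        return PointTable(
            self.ids[keep], self.x[keep], self.y[keep],
            self.attributes.iloc[keep].reset_index(drop=True)
            if len(self.attributes) else self.attributes,
        )


def stack_attrs(points: PointTable, extra: Mapping[str, Iterable[float]]) -> PointTable:
    """Return a copy of ``points`` with additional attribute columns."""
    attrs = points.attributes.copy()
    for name, vals in extra.items():
        attrs[name] = np.asarray(list(vals), dtype=float)
    return PointTable(points.ids, points.x, points.y, attrs)
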