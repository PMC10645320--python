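"""Gridded raster layers and ESRI ASCII grid I/O.

A :class:`RasterLayer` is the universal spatial carrier of the package: a 2D
array plus a geotransform (top-left origin, square cell size in map units,
optional nodata sentinel, CRS tag). Grids are row-major and north-up: row 0
is the northern edge, and the y coordinate decreases with increasing row
index. Alignment between layers is checked with *exact* geotransform
equality — silent resampling corrupts barrier geometry, so any resampling
must be an explicit operation.

Files are read and written in the ESRI ASCII grid format (``.asc``), a plain
text format with a six-line header (``ncols``, ``nrows``, ``xllcorner``,
``yllcorner``, ``cellsize``, optional ``NODATA_value``) followed by rows of
values from north to south.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import AlignmentError, RasterFormatError

__all__ = ["RasterLayer", "read_ascii_grid", "write_ascii_grid", "require_aligned"]


@dataclass
class RasterLayer:
    """A rectangular grid with a geotransform.

    Parameters
    ----------
    values : ndarray, shape (nrows, ncols)
        Cell values. Integer dtypes are preserved through file round-trips.
    origin_x, origin_y : float
        Map coordinates of the *top-left corner* of the grid (not a cell
        center).
    cell_size : float
        Square cell edge length, in the map units of ``crs_tag`` (meters for
        projected frames).
    nodata : float or None
        Sentinel marking missing cells, or None when every cell is valid.
    crs_tag : str
        Free-form CRS label. ``"local-m"`` denotes a local projected frame
        in meters (the default for all synthetic grids).
    """

    values: np.ndarray
    origin_x: float = 0.0
    origin_y: float = 0.0
    cell_size: float = 200.0
    nodata: float | None = None
    crs_tag: str = "local-m"

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError(f"raster values must be 2D, got shape {self.values.shape}")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    # -- geometry -----------------------------------------------------------

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def geotransform(self) -> tuple[float, float, float, int, int]:
        return (self.origin_x, self.origin_y, self.cell_size, self.nrows, self.ncols)

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the outer grid boundary."""
        return (
            self.origin_x,
            self.origin_y - self.nrows * self.cell_size,
            self.origin_x + self.ncols * self.cell_size,
            self.origin_y,
        )

    def x_of(self, col):
        """x coordinate of cell centers in column ``col``."""
        return self.origin_x + (np.asarray(col) + 0.5) * self.cell_size

    def y_of(self, row):
        """y coordinate of cell centers in row ``row``."""
        return self.origin_y - (np.asarray(row) + 0.5) * self.cell_size

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid arrays (X, Y) of all cell-center coordinates."""
        xs = self.x_of(np.arange(self.ncols))
        ys = self.y_of(np.arange(self.nrows))
        return np.meshgrid(xs, ys)

    def index_of(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """(row, col) of the cell containing each point; may be out of range."""
        col = np.floor((np.asarray(x, dtype=float) - self.origin_x) / self.cell_size)
        row = np.floor((self.origin_y - np.asarray(y, dtype=float)) / self.cell_size)
        return row.astype(int), col.astype(int)

    def contains(self, x, y) -> np.ndarray:
        row, col = self.index_of(x, y)
        return (row >= 0) & (row < self.nrows) & (col >= 0) & (col < self.ncols)

    # -- values -------------------------------------------------------------

    @property
    def valid_mask(self) -> np.ndarray:
        """Boolean mask of non-nodata cells."""
        if self.nodata is None:
            return np.ones(self.shape, dtype=bool)
        if np.isnan(self.nodata):
            return ~np.isnan(self.values)
        return self.values != self.nodata

    def with_values(self, values: np.ndarray, nodata: float | None = None) -> "RasterLayer":
        """A new layer sharing this geotransform with different values."""
        out = replace(self, values=np.asarray(values))
        out.nodata = nodata
        return out

    def same_geometry(self, other: "RasterLayer") -> bool:
        return self.geotransform == other.geotransform

    def copy(self) -> "RasterLayer":
        return replace(self, values=self.values.copy())


def require_aligned(*layers: RasterLayer) -> None:
    """Raise :class:`AlignmentError` unless all layers share one geotransform."""
    first = layers[0]
    for other in layers[1:]:
        if not first.same_geometry(other):
            raise AlignmentError(
                "misaligned rasters: geotransform "
                f"{first.geotransform} vs {other.geotransform}"
            )


_HEADER_KEYS = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"}


def read_ascii_grid(path: str | Path, crs_tag: str = "local-m") -> RasterLayer:
    """Read an ESRI ASCII grid.

    Integer-looking grids (no ``.``, ``e`` or ``nan`` tokens) are returned
    with dtype int64 so that integer class rasters round-trip exactly;
    everything else is float64. Cells equal to ``NODATA_value`` are kept as
    the sentinel, not masked to NaN.
    """
    path = Path(path)
    header: dict[str, float] = {}
    data_lines: list[str] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            parts = stripped.split()
            key = parts[0].lower()
            if key in _HEADER_KEYS and len(parts) == 2 and not data_lines:
                try:
                    header[key] = float(parts[1])
                except ValueError as exc:
                    raise RasterFormatError(
                        f"{path}:{lineno}: bad header value {parts[1]!r}"
                    ) from exc
            else:
                data_lines.append(stripped)

    for required in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if required not in header:
            raise RasterFormatError(f"{path}: missing header field {required!r}")
    ncols = int(header["ncols"])
    nrows = int(header["nrows"])

    tokens = " ".join(data_lines).split()
    if len(tokens) != nrows * ncols:
        raise RasterFormatError(
            f"{path}: expected {nrows * ncols} values, found {len(tokens)}"
        )
    is_integer = not any(("." in t) or ("e" in t.lower()) or ("n" in t.lower()) for t in tokens)
    try:
        arr = np.array(tokens, dtype=np.int64 if is_integer else np.float64)
    except ValueError as exc:
        raise RasterFormatError(f"{path}: non-numeric cell value ({exc})") from exc
    values = arr.reshape(nrows, ncols)

    nodata = header.get("nodata_value")
    if nodata is not None and is_integer:
        nodata = int(nodata)
    return RasterLayer(
        values=values,
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"] + nrows * header["cellsize"],
        cell_size=header["cellsize"],
        nodata=nodata,
        crs_tag=crs_tag,
    )


def write_ascii_grid(layer: RasterLayer, path: str | Path) -> None:
    """Write a layer as an ESRI ASCII grid (text)."""
    path = Path(path)
    is_integer = np.issubdtype(layer.values.dtype, np.integer)
    lines = [
        f"ncols {layer.ncols}",
        f"nrows {layer.nrows}",
        f"xllcorner {layer.origin_x!r}",
        f"yllcorner {layer.origin_y - layer.nrows * layer.cell_size!r}",
        f"cellsize {layer.cell_size!r}",
    ]
    if layer.nodata is not None:
        nd = int(layer.nodata) if is_integer else layer.nodata
        lines.append(f"NODATA_value {nd}")
    if is_integer:
        rows = (" ".join(str(v) for v in row) for row in layer.values)
    else:
        rows = (" ".join(f"{v:.10g}" for v in row) for row in layer.values)
    lines.extend(rows)
    path.write_text("\n".join(lines) + "\n")
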