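"""Terrain covariates from bathymetry.

Rugosity is quantified with the vector ruggedness measure (VRM): per-cell
unit surface normals are computed from the depth surface, summed over a
square neighbourhood, and the shortfall of the resultant length from the
cell count measures how much the normals disagree.  VRM is 0 on a plane
(flat or uniformly tilted) and approaches 1 as orientations decorrelate.

Depth is stored positive-down (metres below the surface).  The sign
convention cancels out of VRM because flipping the surface flips every
normal's horizontal components coherently, leaving the resultant length
unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "BathymetryGrid",
    "CovariateStandardization",
    "vrm",
    "logit_rugosity",
    "standardize",
    "sample_raster_at_points",
    "read_ascii_grid",
    "write_ascii_grid",
]


@dataclass
class BathymetryGrid:
    """Regular raster of depths (metres, positive down).

    ``origin`` is the (x, y) of the *lower-left cell centre*; row 0 of
    ``values`` is the top (largest y) row, as in ESRI ASCII grids.
    """

    values: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    nodata_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("grid values must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.nodata_mask is None:
            self.nodata_mask = ~np.isfinite(self.values)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
            if self.nodata_mask.shape != self.values.shape:
                raise ValueError("nodata_mask shape mismatch")
        if not np.all(np.isfinite(self.values[~self.nodata_mask])):
            raise ValueError("non-finite depth outside the nodata mask")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def x_coords(self) -> np.ndarray:
        """x of each column's cell centre."""
        ncols = self.values.shape[1]
        return self.origin[0] + self.cell_size * np.arange(ncols)

    def y_coords(self) -> np.ndarray:
        """y of each row's cell centre (row 0 = top)."""
        nrows = self.values.shape[0]
        return self.origin[1] + self.cell_size * np.arange(nrows)[::-1]

    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) of the covered area (cell edges)."""
        h = self.cell_size / 2.0
        xs, ys = self.x_coords(), self.y_coords()
        return (xs[0] - h, xs[-1] + h, ys[-1] - h, ys[0] + h)


@dataclass
class CovariateStandardization:
    """Centre/scale parameters so prediction grids reuse the sample transform."""

    mean: float
    sd: float

    def apply(self, values: np.ndarray | float) -> np.ndarray | float:
        return (np.asarray(values, dtype=float) - self.mean) / self.sd

    def invert(self, values: np.ndarray | float) -> np.ndarray | float:
        return np.asarray(values, dtype=float) * self.sd + self.mean


def _horn_normals(values: np.ndarray, cell_size: float) -> np.ndarray:
    """Unit surface normals from Horn's 8-neighbour finite differences.

    Returns an (nrows, ncols, 3) array; border cells (no full 3x3 window)
    are NaN.  Row 0 is the top row, so the +y direction is towards
    decreasing row index.
    """
    z = values
    n = np.full(z.shape + (3,), np.nan)
    if z.shape[0] < 3 or z.shape[1] < 3:
        return n
    nw, no, ne = z[:-2, :-2], z[:-2, 1:-1], z[:-2, 2:]
    w, e = z[1:-1, :-2], z[1:-1, 2:]
    sw, so, se = z[2:, :-2], z[2:, 1:-1], z[2:, 2:]
    dzdx = ((ne + 2 * e + se) - (nw + 2 * w + sw)) / (8.0 * cell_size)
    # +y is up the map = decreasing row index
    dzdy = ((nw + 2 * no + ne) - (sw + 2 * so + se)) / (8.0 * cell_size)
    norm = np.sqrt(dzdx**2 + dzdy**2 + 1.0)
    n[1:-1, 1:-1, 0] = -dzdx / norm
    n[1:-1, 1:-1, 1] = -dzdy / norm
    n[1:-1, 1:-1, 2] = 1.0 / norm
    return n


def vrm(grid: BathymetryGrid, neighborhood_cells: int = 3) -> BathymetryGrid:
    """Vector ruggedness measure on a square ``neighborhood_cells`` window.

    VRM = 1 - |sum of unit normals| / N over the N = n^2 neighbourhood
    cells, with normals from Horn slope/aspect on each 3x3 window.  Cells
    whose neighbourhood (including the gradient stencil) touches nodata or
    the grid edge are nodata, mirroring the exclusion of unmapped survey
    area.  Returns a raster aligned with the input grid.
    """
    n = int(neighborhood_cells)
    if n < 3 or n % 2 == 0:
        raise ValueError("neighborhood_cells must be odd and >= 3")
    nr, nc = grid.shape
    if nr < n or nc < n:
        raise ValueError("grid smaller than the VRM neighbourhood")
    if nr < 3 or nc < 3:
        raise ValueError("VRM undefined on grids smaller than 3x3")
    if grid.nodata_mask.all():
        warnings.warn("all-nodata grid: VRM raster is empty", stacklevel=2)
        return BathymetryGrid(
            np.full(grid.shape, np.nan), grid.cell_size, grid.origin,
            nodata_mask=np.ones(grid.shape, dtype=bool),
        )

    z = np.where(grid.nodata_mask, np.nan, grid.values)
    normals = _horn_normals(z, grid.cell_size)  # NaN where stencil invalid

    half = n // 2
    out = np.full(grid.shape, np.nan)
    # sliding-window sums of the three normal components
    from numpy.lib.stride_tricks import sliding_window_view

    if nr >= n and nc >= n:
        win = sliding_window_view(normals, (n, n), axis=(0, 1))
        # win shape: (nr-n+1, nc-n+1, 3, n, n)
        sums = win.sum(axis=(-2, -1))
        resultant = np.sqrt((sums**2).sum(axis=-1))
        vals = 1.0 - resultant / float(n * n)
        out[half : nr - half, half : nc - half] = vals
    # guard tiny negatives from rounding
    with np.errstate(invalid="ignore"):
        out = np.where(np.isfinite(out), np.clip(out, 0.0, 1.0), np.nan)
    return BathymetryGrid(
        out, grid.cell_size, grid.origin, nodata_mask=~np.isfinite(out)
    )


def logit_rugosity(values: np.ndarray | float, epsilon: float = 1e-6) -> np.ndarray:
    """log(v / (1 - v)) after clipping v into [epsilon, 1 - epsilon].

    Raw VRM is right-skewed on reef (mostly near 0 with occasional large
    values); the logit spreads the low end and tames leverage from the
    upper tail before standardisation.
    """
    v = np.asarray(values, dtype=float)
    if np.any((v < 0) | (v > 1)):
        raise ValueError("rugosity values must lie in [0, 1]")
    v = np.clip(v, epsilon, 1.0 - epsilon)
    return np.log(v / (1.0 - v))


def standardize(values: np.ndarray) -> tuple[np.ndarray, CovariateStandardization]:
    """Centre by the sample mean and scale by the sample sd (ddof=1)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two values to standardize")
    mean = float(np.mean(v))
    sd = float(np.std(v, ddof=1))
    if sd == 0.0:
        raise ValueError("constant input: standard deviation is zero")
    return (v - mean) / sd, CovariateStandardization(mean, sd)


def sample_raster_at_points(
    raster: BathymetryGrid, points: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-cell lookup of raster values at (x, y) points.

    Returns ``(values, missing)`` where ``missing`` flags points landing on
    nodata cells (the caller drops those records).  Points outside the
    raster extent raise, naming the first offending point index.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    xmin, xmax, ymin, ymax = raster.extent()
    outside = (
        (pts[:, 0] < xmin) | (pts[:, 0] > xmax)
        | (pts[:, 1] < ymin) | (pts[:, 1] > ymax)
    )
    if outside.any():
        idx = int(np.argmax(outside))
        raise ValueError(
            f"point {idx} at ({pts[idx, 0]:.2f}, {pts[idx, 1]:.2f}) "
            "lies outside the raster extent"
        )
    nr = raster.shape[0]
    col = np.rint((pts[:, 0] - raster.origin[0]) / raster.cell_size).astype(int)
    row_from_bottom = np.rint(
        (pts[:, 1] - raster.origin[1]) / raster.cell_size
    ).astype(int)
    row = nr - 1 - row_from_bottom
    col = np.clip(col, 0, raster.shape[1] - 1)
    row = np.clip(row, 0, nr - 1)
    values = raster.values[row, col]
    missing = raster.nodata_mask[row, col]
    return values, missing


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O


def write_ascii_grid(grid: BathymetryGrid, path, nodata_value: float = -9999.0) -> None:
    nr, nc = grid.shape
    vals = np.where(grid.nodata_mask, nodata_value, grid.values)
    h = grid.cell_size / 2.0
    with open(path, "w") as fh:
        fh.write(f"ncols {nc}\n")
        fh.write(f"nrows {nr}\n")
        fh.write(f"xllcorner {grid.origin[0] - h:.6f}\n")
        fh.write(f"yllcorner {grid.origin[1] - h:.6f}\n")
        fh.write(f"cellsize {grid.cell_size:.6f}\n")
        fh.write(f"NODATA_value {nodata_value:g}\n")
        for row in vals:
            fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")


def read_ascii_grid(path) -> BathymetryGrid:
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner",
                       "cellsize", "nodata_value"} and len(parts) == 2:
                header[key] = float(parts[1])
            else:
                rows.append([float(p) for p in parts])
    for req in ("ncols", "nrows", "cellsize"):
        if req not in header:
            raise ValueError(f"ASCII grid missing header field {req!r}")
    values = np.asarray(rows, dtype=float)
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError("ASCII grid data does not match declared dimensions")
    cell = header["cellsize"]
    origin = (
        header.get("xllcorner", 0.0) + cell / 2.0,
        header.get("yllcorner", 0.0) + cell / 2.0,
    )
    nodata = header.get("nodata_value")
    mask = np.zeros(values.shape, dtype=bool)
    if nodata is not None:
        mask = np.isclose(values, nodata)
        values = np.where(mask, np.nan, values)
    return BathymetryGrid(values, cell, origin, nodata_mask=mask)
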