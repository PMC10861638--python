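"""Synthetic terrain: regular elevation grids with derived slope and aspect.

A :class:`TerrainModel` is a regular grid of elevations (metres) on a planar
easting/northing coordinate system, mirroring the 16 m digital elevation
models used to annotate cattle GPS fixes in hill-country studies.  Slope and
aspect are derived from the elevation grid with Horn's 3x3 finite-difference
method (the convention of common GIS surface toolboxes); edge cells use
clamped neighbourhoods.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = ["TerrainModel", "generate_terrain", "horn_slope_aspect"]

# Horn (1981) weights for d z / d x on a grid whose columns increase eastward.
_HORN_X = np.array([[-1.0, 0.0, 1.0], [-2.0, 0.0, 2.0], [-1.0, 0.0, 1.0]])


def horn_slope_aspect(elevation: np.ndarray, cell_size: float):
    """Slope (degrees) and aspect (degrees clockwise from north) per cell.

    Rows are treated as increasing northward, columns increasing eastward.
    Edge cells use clamped (nearest-replicated) neighbourhoods.
    """
    z = np.asarray(elevation, dtype=float)
    if z.ndim != 2:
        raise ValueError("elevation grid must be 2-D")
    dzdx = ndimage.convolve(z, _HORN_X[:, ::-1], mode="nearest") / (8.0 * cell_size)
    dzdy = ndimage.convolve(z, _HORN_X.T[::-1, :], mode="nearest") / (8.0 * cell_size)
    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    aspect = (np.degrees(np.arctan2(dzdx, dzdy)) + 180.0) % 360.0
    return slope, aspect


@dataclass
class TerrainModel:
    """Regular elevation grid with derived slope/aspect grids.

    Row 0 is the southernmost row; cell centres sit at
    ``origin + (index + 0.5) * cell_size``.
    """

    origin_easting: float
    origin_northing: float
    cell_size: float
    elevation: np.ndarray
    slope: np.ndarray = field(default=None, repr=False)
    aspect: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        self.elevation = np.asarray(self.elevation, dtype=float)
        if self.cell_size <= 0:
            raise ValueError("cell size must be positive")
        if not np.all(np.isfinite(self.elevation)):
            raise ValueError("elevation grid contains non-finite values")
        if self.slope is None or self.aspect is None:
            self.slope, self.aspect = horn_slope_aspect(self.elevation, self.cell_size)
        # cached Horn gradients, used by the walk simulator for uphill drift
        self._dzdx = ndimage.convolve(
            self.elevation, _HORN_X[:, ::-1], mode="nearest"
        ) / (8.0 * self.cell_size)
        self._dzdy = ndimage.convolve(
            self.elevation, _HORN_X.T[::-1, :], mode="nearest"
        ) / (8.0 * self.cell_size)

    @property
    def n_rows(self) -> int:
        return self.elevation.shape[0]

    @property
    def n_cols(self) -> int:
        return self.elevation.shape[1]

    @property
    def extent(self):
        """(east_min, east_max, north_min, north_max) of the covered area."""
        return (
            self.origin_easting,
            self.origin_easting + self.n_cols * self.cell_size,
            self.origin_northing,
            self.origin_northing + self.n_rows * self.cell_size,
        )

    # ------------------------------------------------------------------ sampling
    def _indices(self, easting, northing, tolerance_cells: float = 0.5):
        e = np.asarray(easting, dtype=float)
        n = np.asarray(northing, dtype=float)
        col = (e - self.origin_easting) / self.cell_size
        row = (n - self.origin_northing) / self.cell_size
        lo = -tolerance_cells
        if np.any(col < lo) or np.any(col > self.n_cols + tolerance_cells) or np.any(
            row < lo
        ) or np.any(row > self.n_rows + tolerance_cells):
            bad = np.flatnonzero(
                (col < lo)
                | (col > self.n_cols + tolerance_cells)
                | (row < lo)
                | (row > self.n_rows + tolerance_cells)
            )
            raise ValueError(
                f"{bad.size} fix(es) outside terrain extent beyond tolerance; "
                f"first offending index {bad[0]}"
            )
        return row, col

    def sample(self, easting, northing, grid: str = "elevation", method: str = "nearest"):
        """Sample a grid at planar coordinates.

        ``method='nearest'`` returns the value of the containing cell;
        ``'bilinear'`` interpolates between the four surrounding cell centres.
        Points up to half a cell outside the extent are clamped to the border.
        """
        values = getattr(self, grid)
        row, col = self._indices(easting, northing)
        if method == "nearest":
            r = np.clip(np.floor(row).astype(int), 0, self.n_rows - 1)
            c = np.clip(np.floor(col).astype(int), 0, self.n_cols - 1)
            return values[r, c]
        if method == "bilinear":
            # shift to cell-centre coordinates
            r = np.clip(row - 0.5, 0.0, self.n_rows - 1.0)
            c = np.clip(col - 0.5, 0.0, self.n_cols - 1.0)
            return ndimage.map_coordinates(values, [np.atleast_1d(r), np.atleast_1d(c)], order=1)
        raise ValueError(f"unknown sampling method {method!r}")

    def gradient_at(self, easting, northing):
        """(dz/dx, dz/dy) at the containing cell (nearest sampling)."""
        row, col = self._indices(easting, northing)
        r = np.clip(np.floor(row).astype(int), 0, self.n_rows - 1)
        c = np.clip(np.floor(col).astype(int), 0, self.n_cols - 1)
        return self._dzdx[r, c], self._dzdy[r, c]

    # ------------------------------------------------------------------ text I/O
    def to_text(self) -> str:
        """Serialize as the package's plain-text grid format."""
        buf = io.StringIO()
        buf.write(f"origin {self.origin_easting!r} {self.origin_northing!r}\n")
        buf.write(f"cell_size {self.cell_size!r}\n")
        buf.write(f"dims {self.n_rows} {self.n_cols}\n")
        np.savetxt(buf, self.elevation, fmt="%.6f")
        return buf.getvalue()

    @classmethod
    def from_text(cls, text: str) -> "TerrainModel":
        lines = text.splitlines()
        _, oe, on = lines[0].split()
        _, cs = lines[1].split()
        _, nr, nc = lines[2].split()
        grid = np.loadtxt(io.StringIO("\n".join(lines[3:])))
        grid = grid.reshape(int(nr), int(nc))
        return cls(float(oe), float(on), float(cs), grid)


def generate_terrain(
    seed,
    extent: float,
    cell_size: float = 16.0,
    relief_amplitude: float = 300.0,
    base_elevation: float = 400.0,
    smoothness: float = 6.0,
    origin_easting: float = 0.0,
    origin_northing: float = 0.0,
) -> TerrainModel:
    """Generate a smooth correlated random elevation field.

    White noise is smoothed with a Gaussian kernel (``smoothness`` in cells)
    and rescaled so the elevation spans ``relief_amplitude`` metres above
    ``base_elevation``; a zero amplitude yields a perfectly flat paddock.

    Parameters
    ----------
    seed : int or numpy.random.SeedSequence
        Source of randomness; identical seeds give bit-identical grids.
    extent : float
        Side length of the (square) covered area, metres; at least 4 cells.
    """
    if cell_size <= 0:
        raise ValueError("cell size must be positive")
    if relief_amplitude < 0:
        raise ValueError("relief amplitude must be non-negative")
    n = int(np.ceil(extent / cell_size))
    if n < 4:
        raise ValueError("extent must cover at least 4 cells per side")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((n, n))
    field_ = ndimage.gaussian_filter(noise, sigma=smoothness, mode="reflect")
    span = field_.max() - field_.min()
    if relief_amplitude == 0 or span == 0:
        z = np.full((n, n), base_elevation)
    else:
        z = base_elevation + (field_ - field_.min()) / span * relief_amplitude
    return TerrainModel(origin_easting, origin_northing, cell_size, z)
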