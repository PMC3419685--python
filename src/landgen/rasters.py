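"""Categorical land-cover rasters in the ESRI ASCII grid format.

The grid uses a lower-left origin with a cell-centre coordinate convention:
cell (row, col) of the in-memory array (row 0 = top row, as stored in the
file body) has centre x = xll + (col + 0.5) * cellsize and
y = yll + (nrows - row - 0.5) * cellsize.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: land-cover legend used throughout: code -> class name
DEFAULT_LEGEND = {
    1: "forest",
    2: "oil_palm",
    3: "pasture",
    4: "river",
    5: "residential",
    6: "other",
}

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "NODATA_value")


class RasterError(ValueError):
    pass


@dataclass
class LandscapeRaster:
    """Categorical class grid with georeferencing header and legend."""

    data: np.ndarray  # (nrows, ncols) int codes, row 0 = northernmost
    xllcorner: float
    yllcorner: float
    cellsize: float
    nodata: int = -9999
    legend: dict[int, str] = field(default_factory=lambda: dict(DEFAULT_LEGEND))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.int64)
        if self.data.ndim != 2:
            raise RasterError("raster body must be 2-D")
        if self.cellsize <= 0:
            raise RasterError("cellsize must be positive")

    @property
    def nrows(self) -> int:
        return self.data.shape[0]

    @property
    def ncols(self) -> int:
        return self.data.shape[1]

    @property
    def valid(self) -> np.ndarray:
        """Boolean mask of non-NODATA cells."""
        return self.data != self.nodata

    def code_of(self, name: str) -> int:
        for code, cls in self.legend.items():
            if cls == name:
                return code
        raise KeyError(f"class {name!r} not in legend {sorted(self.legend.values())}")

    def class_fractions(self) -> dict[str, float]:
        """Fraction of valid cells per legend class."""
        valid = self.data[self.valid]
        return {
            name: float((valid == code).sum()) / valid.size
            for code, name in self.legend.items()
        }

    # ---- coordinate conversions ------------------------------------------

    def rowcol_to_xy(self, row, col):
        x = self.xllcorner + (np.asarray(col) + 0.5) * self.cellsize
        y = self.yllcorner + (self.nrows - np.asarray(row) - 0.5) * self.cellsize
        return x, y

    def xy_to_rowcol(self, x, y):
        """Snap a point to its containing cell; raises if off-grid."""
        col = int(np.floor((x - self.xllcorner) / self.cellsize))
        row = int(self.nrows - 1 - np.floor((y - self.yllcorner) / self.cellsize))
        if not (0 <= row < self.nrows and 0 <= col < self.ncols):
            raise RasterError(f"point ({x}, {y}) falls outside the grid")
        return row, col

    # ---- I/O ---------------------------------------------------------------

    def write_ascii(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"ncols {self.ncols}\n")
            fh.write(f"nrows {self.nrows}\n")
            fh.write(f"xllcorner {self.xllcorner}\n")
            fh.write(f"yllcorner {self.yllcorner}\n")
            fh.write(f"cellsize {self.cellsize}\n")
            fh.write(f"NODATA_value {self.nodata}\n")
            for row in self.data:
                fh.write(" ".join(str(int(v)) for v in row) + "\n")


def read_ascii_grid(path, legend: dict[int, str] | None = None) -> LandscapeRaster:
    """Parse an ESRI ASCII grid of integer class codes.

    When a legend is supplied (or by default), any body code outside the
    legend and distinct from NODATA raises an error listing the offenders.
    Pass ``legend=None`` semantics via an explicit permissive legend if
    arbitrary codes must be accepted.
    """
    header: dict[str, float] = {}
    body_tokens: list[str] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0] in _HEADER_KEYS and len(parts) == 2 and parts[0] not in header:
                header[parts[0]] = float(parts[1])
            else:
                body_tokens.extend(parts)
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise RasterError(f"missing header keyword {key}")
    ncols = int(header["ncols"])
    nrows = int(header["nrows"])
    nodata = int(header.get("NODATA_value", -9999))
    if len(body_tokens) != ncols * nrows:
        raise RasterError(
            f"body has {len(body_tokens)} cells, header says {ncols}x{nrows}"
        )
    data = np.array(body_tokens, dtype=np.int64).reshape(nrows, ncols)
    legend = dict(DEFAULT_LEGEND) if legend is None else dict(legend)
    unknown = sorted(int(c) for c in set(np.unique(data)) - set(legend) - {nodata})
    if unknown:
        raise RasterError(f"unknown class codes in raster body: {unknown}")
    return LandscapeRaster(
        data=data,
        xllcorner=header["xllcorner"],
        yllcorner=header["yllcorner"],
        cellsize=header["cellsize"],
        nodata=nodata,
        legend=legend,
    )
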