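"""Goose-density raster: an ESRI ASCII grid with point lookup.

Values are nesting goose densities (geese/ha), a proxy for nest density.
Row 0 of ``values`` is the northernmost row, following the ESRI ASCII
convention. Lookup returns the value of the cell containing the point
(no interpolation): density is a survey-block quantity, not a smooth
field.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np


@dataclass
class DensityRaster:
    values: np.ndarray  # (n_rows, n_cols), row 0 = north
    xllcorner: float
    yllcorner: float
    cell_size: float
    nodata_value: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("raster grid must be a non-empty 2-D array")
        if self.cell_size <= 0:
            raise ValueError("cell size must be positive")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid."""
        return (
            self.xllcorner,
            self.yllcorner,
            self.xllcorner + self.n_cols * self.cell_size,
            self.yllcorner + self.n_rows * self.cell_size,
        )

    def value_at(self, x, y) -> np.ndarray:
        """Density at point(s); NaN outside the extent or on NODATA cells."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        col = np.floor((x - self.xllcorner) / self.cell_size).astype(int)
        row_s = np.floor((y - self.yllcorner) / self.cell_size).astype(int)
        row = self.n_rows - 1 - row_s
        inside = (col >= 0) & (col < self.n_cols) & (row >= 0) & (row < self.n_rows)
        out = np.full(x.shape, np.nan)
        r, c = row[inside], col[inside]
        vals = self.values[r, c]
        vals = np.where(vals == self.nodata_value, np.nan, vals)
        out[inside] = vals
        return out

    def to_ascii(self, path: str | Path) -> None:
        header = (
            f"ncols {self.n_cols}\n"
            f"nrows {self.n_rows}\n"
            f"xllcorner {float(self.xllcorner):.10g}\n"
            f"yllcorner {float(self.yllcorner):.10g}\n"
            f"cellsize {float(self.cell_size):.10g}\n"
            f"NODATA_value {float(self.nodata_value):.10g}\n"
        )
        body = "\n".join(
            " ".join(f"{float(v):.10g}" for v in row) for row in self.values
        )
        Path(path).write_text(header + body + "\n")

    @classmethod
    def from_ascii(cls, path: str | Path) -> "DensityRaster":
        lines = Path(path).read_text().splitlines()
        header: dict[str, float] = {}
        i = 0
        while i < len(lines) and lines[i].split()[0].lower() in (
            "ncols",
            "nrows",
            "xllcorner",
            "yllcorner",
            "cellsize",
            "nodata_value",
        ):
            key, val = lines[i].split()
            header[key.lower()] = float(val)
            i += 1
        required = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize"}
        missing = required - set(header)
        if missing:
            raise ValueError(f"ASCII grid header missing {sorted(missing)}")
        values = np.loadtxt(lines[i:], ndmin=2)
        if values.shape != (int(header["nrows"]), int(header["ncols"])):
            raise ValueError(
                f"grid body shape {values.shape} disagrees with header "
                f"({int(header['nrows'])}, {int(header['ncols'])})"
            )
        return cls(
            values=values,
            xllcorner=header["xllcorner"],
            yllcorner=header["yllcorner"],
            cell_size=header["cellsize"],
            nodata_value=header.get("nodata_value", -9999.0),
        )
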