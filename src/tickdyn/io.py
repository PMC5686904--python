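"""Plain-text raster I/O (ESRI ASCII grid).

Rasters in this package (land cover legends, prediction surfaces) are small
single-band grids; the ESRI ASCII grid format keeps them human-readable and
GDAL-compatible without a binary raster dependency.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

NODATA = -9999


@dataclass(frozen=True)
class GridMeta:
    """Geotransform metadata for a north-up raster.

    ``xllcorner``/``yllcorner`` locate the lower-left corner in projected
    metres; ``cellsize`` is the square pixel edge in metres.
    """

    xllcorner: float = 0.0
    yllcorner: float = 0.0
    cellsize: float = 500.0
    nodata: float = NODATA


def write_ascii_grid(path: str | Path, data: np.ndarray, meta: GridMeta = GridMeta(),
                     fmt: str = "%d") -> Path:
    """Write a 2-D array as an ESRI ASCII grid. Row 0 is the top (north) row."""
    data = np.asarray(data)
    if data.ndim != 2:
        raise ValueError(f"expected a 2-D raster, got shape {data.shape}")
    path = Path(path)
    header = (
        f"ncols {data.shape[1]}\n"
        f"nrows {data.shape[0]}\n"
        f"xllcorner {meta.xllcorner}\n"
        f"yllcorner {meta.yllcorner}\n"
        f"cellsize {meta.cellsize}\n"
        f"NODATA_value {meta.nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, data, fmt=fmt)
    return path


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, GridMeta]:
    """Read an ESRI ASCII grid; returns (array, metadata)."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, value = fh.readline().split()
            header[key.lower()] = float(value)
        data = np.loadtxt(fh)
    data = np.atleast_2d(data)
    expected = (int(header["nrows"]), int(header["ncols"]))
    if data.shape != expected:
        raise ValueError(f"{path}: header says {expected}, data is {data.shape}")
    meta = GridMeta(
        xllcorner=header.get("xllcorner", 0.0),
        yllcorner=header.get("yllcorner", 0.0),
        cellsize=header.get("cellsize", 500.0),
        nodata=header.get("nodata_value", NODATA),
    )
    return data, meta
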