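"""Plain-text raster I/O on the ESRI ASCII grid format.

All analysis layers live on a single common grid (row-major, origin at the
top-left corner, 0-based ``(row, col)`` addressing).  Rasters are exchanged
as ESRI ASCII grids (``.asc``) so that every artifact the pipeline writes is
human-readable text and round-trips bit-exactly for integer bands.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["GridMeta", "read_ascii_grid", "write_ascii_grid", "ensure_same_grid"]

_DEFAULT_NODATA = -9999


@dataclass(frozen=True)
class GridMeta:
    """Georeferencing header of an ASCII grid."""

    nrows: int
    ncols: int
    xllcorner: float = 0.0
    yllcorner: float = 0.0
    cellsize: float = 1.0
    nodata: float = _DEFAULT_NODATA

    def matches(self, other: "GridMeta") -> bool:
        return (
            self.nrows == other.nrows
            and self.ncols == other.ncols
            and np.isclose(self.xllcorner, other.xllcorner)
            and np.isclose(self.yllcorner, other.yllcorner)
            and np.isclose(self.cellsize, other.cellsize)
        )


def write_ascii_grid(
    array: np.ndarray,
    path: str | Path,
    *,
    cellsize: float = 1.0,
    xllcorner: float = 0.0,
    yllcorner: float = 0.0,
    nodata: float = _DEFAULT_NODATA,
) -> None:
    """Write a 2-D array as an ESRI ASCII grid.

    Integer arrays are written as integers (lossless round-trip); float
    arrays are written with ``repr``-level precision and NaN cells are
    encoded as the nodata value.
    """
    arr = np.asarray(array)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D raster, got shape {arr.shape}")
    path = Path(path)
    is_int = np.issubdtype(arr.dtype, np.integer) or arr.dtype == bool
    header = (
        f"ncols {arr.shape[1]}\n"
        f"nrows {arr.shape[0]}\n"
        f"xllcorner {xllcorner!r}\n"
        f"yllcorner {yllcorner!r}\n"
        f"cellsize {cellsize!r}\n"
        f"NODATA_value {int(nodata) if is_int else nodata!r}\n"
    )
    with path.open("w") as fh:
        fh.write(header)
        if is_int:
            np.savetxt(fh, arr.astype(np.int64), fmt="%d")
        else:
            body = np.where(np.isnan(arr.astype(float)), float(nodata), arr)
            np.savetxt(fh, body, fmt="%.17g")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, GridMeta]:
    """Read an ESRI ASCII grid.

    Returns an ``int64`` array when every value token is integral, else a
    ``float64`` array with nodata cells mapped to NaN.
    """
    path = Path(path)
    header: dict[str, float] = {}
    with path.open() as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            key, _, value = line.partition(" ")
            key = key.strip().lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"}:
                header[key] = float(value)
                pos = fh.tell()
            else:  # header may legally omit NODATA_value
                break
        fh.seek(pos)
        data = np.loadtxt(fh, ndmin=2)
    nodata = header.get("nodata_value", _DEFAULT_NODATA)
    meta = GridMeta(
        nrows=int(header["nrows"]),
        ncols=int(header["ncols"]),
        xllcorner=header.get("xllcorner", 0.0),
        yllcorner=header.get("yllcorner", 0.0),
        cellsize=header.get("cellsize", 1.0),
        nodata=nodata,
    )
    if data.shape != (meta.nrows, meta.ncols):
        raise ValueError(
            f"{path}: body shape {data.shape} does not match header "
            f"({meta.nrows}, {meta.ncols})"
        )
    if np.all(data == np.floor(data)):
        out = data.astype(np.int64)
        return out, meta
    data = data.astype(float)
    data[data == nodata] = np.nan
    return data, meta


def ensure_same_grid(*arrays: np.ndarray, names: list[str] | None = None) -> None:
    """Raise ``ValueError`` naming the offenders if raster shapes differ."""
    if not arrays:
        return
    shapes = [np.asarray(a).shape for a in arrays]
    ref = shapes[0]
    for i, shape in enumerate(shapes[1:], start=1):
        if shape != ref:
            a = names[0] if names else "raster 0"
            b = names[i] if names else f"raster {i}"
            raise ValueError(f"grid mismatch: {a} has shape {ref}, {b} has shape {shape}")
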