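"""Raster containers and dependency-light grid / census-table I/O.

Grids are plain 2-D numpy arrays with a shared boolean validity mask.
On disk they are ESRI ASCII grids (``.asc``), a text format every GIS
reads; census tables are CSV with columns ``unit_id,count,region,country``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CovariateStack",
    "ZoneMap",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_census_csv",
    "write_census_csv",
]

ASCII_NODATA = -9999.0


@dataclass
class CovariateStack:
    """Named, aligned 2-D covariate grids with a shared nodata mask.

    Parameters
    ----------
    names
        Covariate names, one per layer, in layer order.
    data
        Array of shape ``(n_covariates, rows, cols)``.
    mask
        Boolean ``(rows, cols)`` array, ``True`` where pixels are valid.
    kinds
        Optional map from covariate name to its generator kind tag
        (e.g. ``"binary-extent"``); used to pick the zonal summary
        statistic (mean vs. proportion).
    """

    names: list[str]
    data: np.ndarray
    mask: np.ndarray
    kinds: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("stack data must be (n_covariates, rows, cols)")
        if len(self.names) != self.data.shape[0]:
            raise ValueError("one name per layer required")
        if self.mask.shape != self.data.shape[1:]:
            raise ValueError("mask shape must match grid shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    def grid(self, name: str) -> np.ndarray:
        """Return the 2-D grid for one covariate."""
        return self.data[self.names.index(name)]

    def subset(self, names: list[str]) -> "CovariateStack":
        idx = [self.names.index(n) for n in names]
        return CovariateStack(
            names=list(names),
            data=self.data[idx],
            mask=self.mask,
            kinds={n: self.kinds[n] for n in names if n in self.kinds},
        )


@dataclass
class ZoneMap:
    """Integer admin-zone labels on the same grid as a CovariateStack.

    Label 0 marks nodata pixels; valid zones are labelled ``1..n_zones``.
    ``pixel_area`` is the area of one pixel in km².
    """

    labels: np.ndarray
    pixel_area: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.ndim != 2:
            raise ValueError("zone labels must be a 2-D grid")
        if self.pixel_area <= 0:
            raise ValueError("pixel_area must be positive")

    @property
    def zone_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    @property
    def mask(self) -> np.ndarray:
        return self.labels > 0

    def zone_areas_km2(self) -> pd.Series:
        """Area of each zone (valid pixels × pixel_area)."""
        ids, counts = np.unique(self.labels[self.labels > 0], return_counts=True)
        return pd.Series(counts * self.pixel_area, index=ids, name="area_km2")


def write_ascii_grid(path: str | os.PathLike, grid: np.ndarray,
                     nodata: float = ASCII_NODATA,
                     mask: np.ndarray | None = None,
                     cellsize: float = 1.0) -> None:
    """Write a 2-D array as an ESRI ASCII grid."""
    grid = np.asarray(grid, dtype=float)
    out = grid.copy()
    if mask is not None:
        out[~np.asarray(mask, bool)] = nodata
    rows, cols = out.shape
    header = (
        f"ncols {cols}\nnrows {rows}\nxllcorner 0.0\nyllcorner 0.0\n"
        f"cellsize {cellsize}\nNODATA_value {nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.10g")


def read_ascii_grid(path: str | os.PathLike) -> tuple[np.ndarray, np.ndarray]:
    """Read an ESRI ASCII grid.

    Returns
    -------
    grid, mask
        The data array (nodata pixels as NaN) and a boolean validity mask.
    """
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            key, _, val = line.partition(" ")
            key = key.strip().lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner",
                       "cellsize", "nodata_value"}:
                header[key] = float(val)
                pos = fh.tell()
            else:  # header may be shorter than six lines
                fh.seek(pos)
                break
        body = np.loadtxt(fh)
    body = np.atleast_2d(body)
    if "nrows" in header:
        body = body.reshape(int(header["nrows"]), int(header["ncols"]))
    nodata = header.get("nodata_value", ASCII_NODATA)
    mask = body != nodata
    grid = body.astype(float)
    grid[~mask] = np.nan
    return grid, mask


def write_census_csv(path: str | os.PathLike, census: pd.DataFrame) -> None:
    cols = [c for c in ("unit_id", "count", "region", "country")
            if c in census.columns]
    census.loc[:, cols].to_csv(path, index=False)


def read_census_csv(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "unit_id" not in df.columns or "count" not in df.columns:
        raise ValueError("census CSV needs unit_id and count columns")
    if (df["count"] < 0).any():
        raise ValueError("census counts must be non-negative")
    return df
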