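"""Habitat-productivity quantification from NDVI rasters.

The study area is tessellated into 3 x 3 km grid cells (roughly one
leopard home range each) grouped into named zones, and each scat location
gets a 2 km circular buffer; the mean NDVI inside each geometry is the
habitat-productivity measure.  Rasters are plain-text ESRI ASCII grids in
a projected metric CRS; the pixel-inclusion rule is pixel-centre-in-
geometry, which is deterministic and matches common zonal-statistics
defaults.  No reprojection is ever attempted: rasters and zones must share
their coordinate frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .stats import TestResult, one_way_anova, paired_t, tukey_hsd

__all__ = [
    "RasterGrid",
    "Zone",
    "ZonalStat",
    "read_ascii_grid",
    "write_ascii_grid",
    "make_grid",
    "make_buffer",
    "zonal_mean",
    "compare_zones_spatial",
    "compare_zones_temporal",
]


class RasterError(ValueError):
    pass


@dataclass
class RasterGrid:
    """North-up NDVI raster: origin is the lower-left corner in metres."""

    origin: tuple[float, float]
    cell_size: float
    values: np.ndarray  # (nrows, ncols), row 0 = northernmost
    year: int
    nodata: float = -9999.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.cell_size <= 0:
            raise RasterError("raster needs a 2-D value matrix and positive cell size")
        valid = self.values != self.nodata
        v = self.values[valid]
        if v.size and ((v < -1.0) | (v > 1.0)).any():
            raise RasterError("NDVI values must lie in [-1, 1] or equal nodata")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    def pixel_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinate vectors of column / row pixel centres."""
        x0, y0 = self.origin
        xs = x0 + (np.arange(self.ncols) + 0.5) * self.cell_size
        # row 0 is the top row
        ys = y0 + (self.nrows - np.arange(self.nrows) - 0.5) * self.cell_size
        return xs, ys


@dataclass(frozen=True)
class Zone:
    """A named geometry: an axis-aligned rectangle or a circle (metres)."""

    zone_id: str
    kind: str  # 'grid_cell' | 'sample_buffer' | 'named_zone'
    geometry: tuple  # ('rect', xmin, ymin, xmax, ymax) | ('circle', cx, cy, r)
    parent_zone: str | None = None
    partial: bool = False

    def __post_init__(self):
        if self.kind not in ("grid_cell", "sample_buffer", "named_zone"):
            raise RasterError(f"unknown zone kind {self.kind!r}")
        g = tuple(self.geometry)
        if g[0] == "rect":
            _, xmin, ymin, xmax, ymax = g
            if not (xmax > xmin and ymax > ymin):
                raise RasterError(f"zone {self.zone_id}: degenerate rectangle")
        elif g[0] == "circle":
            _, cx, cy, r = g
            if not r > 0:
                raise RasterError(f"zone {self.zone_id}: radius must be positive")
        else:
            raise RasterError(f"zone {self.zone_id}: unknown geometry {g[0]!r}")
        object.__setattr__(self, "geometry", g)

    @property
    def area_km2(self) -> float:
        g = self.geometry
        if g[0] == "rect":
            return (g[3] - g[1]) * (g[4] - g[2]) / 1e6
        return float(np.pi * g[3] ** 2 / 1e6)

    def contains(self, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
        """Boolean mask over the (ys, xs) pixel-centre mesh."""
        g = self.geometry
        X, Y = np.meshgrid(xs, ys)
        if g[0] == "rect":
            _, xmin, ymin, xmax, ymax = g
            return (X >= xmin) & (X < xmax) & (Y >= ymin) & (Y < ymax)
        _, cx, cy, r = g
        return (X - cx) ** 2 + (Y - cy) ** 2 <= r**2


@dataclass
class ZonalStat:
    zone_id: str
    year: int
    mean_ndvi: float
    n_pixels: int
    parent_zone: str | None = None

    @property
    def empty(self) -> bool:
        return self.n_pixels == 0


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O (text raster dialect)


def read_ascii_grid(path, year: int = 0) -> RasterGrid:
    """Read an ESRI ASCII grid (.asc).  Supports xllcorner/yllcorner headers."""
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"):
                header[key] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    for req in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if req not in header:
            raise RasterError(f"{path}: missing header field {req!r}")
    values = np.asarray([v for row in rows for v in row]).reshape(
        int(header["nrows"]), int(header["ncols"])
    )
    return RasterGrid(
        origin=(header["xllcorner"], header["yllcorner"]),
        cell_size=header["cellsize"],
        values=values,
        year=year,
        nodata=header.get("nodata_value", -9999.0),
    )


def write_ascii_grid(raster: RasterGrid, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"ncols {raster.ncols}\n")
        fh.write(f"nrows {raster.nrows}\n")
        fh.write(f"xllcorner {raster.origin[0]!r}\n")
        fh.write(f"yllcorner {raster.origin[1]!r}\n")
        fh.write(f"cellsize {raster.cell_size!r}\n")
        fh.write(f"NODATA_value {raster.nodata!r}\n")
        for row in raster.values:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# zone construction


def make_grid(extent, cell_km: float = 3.0, parent_zone: str | None = None) -> list[Zone]:
    """Tessellate a rectangular extent into square grid cells.

    ``extent`` is (xmin, ymin, xmax, ymax) in metres.  Cells are anchored at
    the extent origin; partial cells at the east/north edges are clipped to
    the extent, retained, and flagged ``partial``.
    """
    if cell_km <= 0:
        raise RasterError("cell size must be positive")
    xmin, ymin, xmax, ymax = map(float, extent)
    if not (xmax > xmin and ymax > ymin):
        raise RasterError("extent has non-positive area")
    size = cell_km * 1000.0
    ncx = int(np.ceil((xmax - xmin) / size - 1e-9))
    ncy = int(np.ceil((ymax - ymin) / size - 1e-9))
    cells = []
    for iy in range(ncy):
        for ix in range(ncx):
            x0 = xmin + ix * size
            y0 = ymin + iy * size
            x1 = min(x0 + size, xmax)
            y1 = min(y0 + size, ymax)
            partial = (x1 - x0 < size - 1e-9) or (y1 - y0 < size - 1e-9)
            prefix = f"{parent_zone}_" if parent_zone else ""
            cells.append(
                Zone(
                    zone_id=f"{prefix}cell_{ix}_{iy}",
                    kind="grid_cell",
                    geometry=("rect", x0, y0, x1, y1),
                    parent_zone=parent_zone,
                    partial=partial,
                )
            )
    return cells


def make_buffer(point, radius_m: float = 2000.0, zone_id: str | None = None,
                parent_zone: str | None = None) -> Zone:
    """Circular sample buffer around a scat location (default 2 km radius)."""
    x, y = map(float, point)
    return Zone(
        zone_id=zone_id or f"buffer_{x:.0f}_{y:.0f}",
        kind="sample_buffer",
        geometry=("circle", x, y, float(radius_m)),
        parent_zone=parent_zone,
    )


# ---------------------------------------------------------------------------
# zonal statistics


def zonal_mean(raster: RasterGrid, zone: Zone) -> ZonalStat:
    """Mean NDVI over pixels whose centre falls inside the zone geometry.

    Nodata pixels are excluded; a zone capturing no pixel centres is
    returned with n_pixels = 0 and NaN mean (flagged, never silent).
    """
    xs, ys = raster.pixel_centres()
    mask = zone.contains(xs, ys) & (raster.values != raster.nodata)
    n = int(mask.sum())
    if n:
        v = raster.values[mask]
        # shifted mean: exact for constant rasters, stabler in general
        mean = float(v[0] + (v - v[0]).mean())
    else:
        mean = float("nan")
    return ZonalStat(zone.zone_id, raster.year, mean, n, zone.parent_zone)


def compare_zones_spatial(stats: list[ZonalStat]) -> dict:
    """One-way ANOVA + Tukey-Kramer over per-cell means grouped by zone.

    ``stats`` are grid-cell means carrying ``parent_zone`` labels; cells
    with no pixels are dropped.  Returns the ANOVA result and the pairwise
    comparisons.
    """
    by_zone: dict[str, list[float]] = {}
    for st in stats:
        if st.empty:
            continue
        by_zone.setdefault(st.parent_zone or st.zone_id, []).append(st.mean_ndvi)
    if len(by_zone) < 2:
        raise RasterError("need >= 2 named zones with cells")
    labels = sorted(by_zone)
    groups = [by_zone[z] for z in labels]
    anova = one_way_anova(groups)
    pairwise = tukey_hsd(groups, labels=labels)
    return {"anova": anova, "pairwise": pairwise, "zones": labels}


def compare_zones_temporal(stats_a: list[ZonalStat], stats_b: list[ZonalStat]) -> dict[str, TestResult]:
    """Paired t test of per-cell means between two years, per named zone.

    Cells are matched by zone_id; unmatched ids are an error listing them.
    """
    a = {s.zone_id: s for s in stats_a}
    b = {s.zone_id: s for s in stats_b}
    unmatched = sorted(set(a) ^ set(b))
    if unmatched:
        raise RasterError(f"unmatched cell ids between years: {unmatched}")
    by_zone: dict[str, tuple[list[float], list[float]]] = {}
    for zid in sorted(a):
        if a[zid].empty or b[zid].empty:
            continue
        key = a[zid].parent_zone or "all"
        by_zone.setdefault(key, ([], []))
        by_zone[key][0].append(a[zid].mean_ndvi)
        by_zone[key][1].append(b[zid].mean_ndvi)
    return {zone: paired_t(x, y) for zone, (x, y) in by_zone.items()}
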