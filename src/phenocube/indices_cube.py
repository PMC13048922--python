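"""Reflectance cubes, mosaic quality filtering and vegetation-index matrices.

A :class:`ReflectanceCube` is the raw observable: a dated stack of 5-band
surface-reflectance grids with per-pixel validity and cloud masks.  This
module screens acquisition dates on cloud cover and data completeness,
evaluates the four vegetation indices (EVI, NBR, NDVI, NDWI) and reshapes
each index cube into the dates x pixels :class:`SpatioTemporalMatrix` that
the decomposition stage consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BANDS = ("BLUE", "GREEN", "RED", "NIR", "SWIR1")

#: bands required by each vegetation index
INDEX_BANDS = {
    "EVI": ("BLUE", "RED", "NIR"),
    "NBR": ("NIR", "SWIR1"),
    "NDVI": ("RED", "NIR"),
    "NDWI": ("GREEN", "NIR"),
}

INDEX_NAMES = tuple(INDEX_BANDS)


class DegenerateConfigError(ValueError):
    """A configuration that cannot yield a usable scene or filtering result."""


def as_day_array(dates) -> np.ndarray:
    """Coerce a sequence of dates to a numpy datetime64[D] array."""
    return np.asarray(dates, dtype="datetime64[D]")


@dataclass(frozen=True)
class GridGeoreference:
    """Minimal north-up affine georeference for a regular pixel grid.

    ``x_origin``/``y_origin`` locate the outer corner of pixel (0, 0)
    (top-left); ``pixel_size`` is the square pixel edge in metres.
    """

    x_origin: float = 0.0
    y_origin: float = 0.0
    pixel_size: float = 10.0
    crs: str = "EPSG:32753"

    def pixel_center(self, row, col):
        x = self.x_origin + (np.asarray(col) + 0.5) * self.pixel_size
        y = self.y_origin - (np.asarray(row) + 0.5) * self.pixel_size
        return x, y

    def pixel_of(self, x, y, shape):
        """Map coordinates to the enclosing pixel (row, col).

        Points exactly on a shared pixel edge/corner resolve to the smaller
        row, then smaller column.
        """
        n_rows, n_cols = shape
        c = (np.asarray(x, dtype=float) - self.x_origin) / self.pixel_size
        r = (self.y_origin - np.asarray(y, dtype=float)) / self.pixel_size
        col = np.floor(c).astype(int)
        row = np.floor(r).astype(int)
        # boundary tie-break: an integer offset belongs to the pixel above/left
        col = np.where((c == np.floor(c)) & (col > 0), col - 1, col)
        row = np.where((r == np.floor(r)) & (row > 0), row - 1, row)
        out = (row < 0) | (row >= n_rows) | (col < 0) | (col >= n_cols)
        if np.any(out):
            bad = np.argwhere(np.atleast_1d(out)).ravel()
            xs, ys = np.atleast_1d(x), np.atleast_1d(y)
            raise ValueError(
                "waypoint(s) outside raster extent: "
                + ", ".join(f"({xs[i]}, {ys[i]})" for i in bad[:5])
            )
        return row, col

    @property
    def pixel_area_km2(self) -> float:
        return (self.pixel_size / 1000.0) ** 2


@dataclass
class ReflectanceCube:
    """Dated stack of 5-band reflectance grids with validity/cloud masks.

    bands maps band name -> float array of shape (n_dates, rows, cols) with
    values in [0, 1] where valid.  ``valid_mask`` is False for nodata pixels
    (clouds included); ``cloud_mask`` flags the cloudy subset.
    """

    dates: np.ndarray
    bands: dict
    valid_mask: np.ndarray
    geo: GridGeoreference = field(default_factory=GridGeoreference)
    cloud_mask: np.ndarray | None = None

    def __post_init__(self):
        self.dates = as_day_array(self.dates)
        if self.dates.size == 0:
            raise DegenerateConfigError("cube has no acquisition dates")
        if np.any(np.diff(self.dates) <= np.timedelta64(0, "D")):
            raise ValueError("cube dates must be strictly increasing")
        shapes = {b: a.shape for b, a in self.bands.items()}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"band grids disagree in shape: {shapes}")
        shape = next(iter(shapes.values()))
        if shape[0] != self.dates.size:
            raise ValueError("band stacks and date list disagree in length")
        if self.valid_mask.shape != shape:
            raise ValueError("valid_mask shape does not match band grids")
        if self.cloud_mask is None:
            self.cloud_mask = np.zeros(shape, dtype=bool)
        for b, a in self.bands.items():
            vals = a[self.valid_mask]
            if vals.size and (vals.min() < 0 or vals.max() > 1):
                raise ValueError(f"band {b} has valid reflectance outside [0, 1]")

    @property
    def shape(self):
        """(rows, cols) of the pixel grid."""
        return next(iter(self.bands.values())).shape[1:]

    @property
    def n_dates(self) -> int:
        return self.dates.size

    def select_dates(self, keep_dates) -> "ReflectanceCube":
        """Subset the cube to the given dates (order preserved)."""
        keep = np.isin(self.dates, as_day_array(keep_dates))
        return ReflectanceCube(
            dates=self.dates[keep],
            bands={b: a[keep] for b, a in self.bands.items()},
            valid_mask=self.valid_mask[keep],
            cloud_mask=self.cloud_mask[keep],
            geo=self.geo,
        )


@dataclass(frozen=True)
class MosaicQuality:
    date: np.datetime64
    cloud_fraction: float
    valid_fraction: float

    def __post_init__(self):
        for name in ("cloud_fraction", "valid_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass(frozen=True)
class VegetationIndexSpec:
    """One of the four supported vegetation indices.

    The EVI constants default to the standard gain/aerosol/soil values
    G=2.5, C1=6, C2=7.5, L=1 and are only meaningful for EVI.
    """

    name: str
    G: float = 2.5
    C1: float = 6.0
    C2: float = 7.5
    L: float = 1.0

    def __post_init__(self):
        if self.name not in INDEX_BANDS:
            raise ValueError(f"unknown index {self.name!r}; expected one of {INDEX_NAMES}")


def assess_quality(cube: ReflectanceCube) -> list[MosaicQuality]:
    """Per-date cloud and valid-data fractions of a cube."""
    n_px = cube.shape[0] * cube.shape[1]
    out = []
    for i, d in enumerate(cube.dates):
        out.append(
            MosaicQuality(
                date=d,
                cloud_fraction=float(cube.cloud_mask[i].sum()) / n_px,
                valid_fraction=float(cube.valid_mask[i].sum()) / n_px,
            )
        )
    return out


def filter_mosaics(quality, cloud_max: float = 0.03, valid_min: float = 0.90) -> np.ndarray:
    """Dates passing the mosaic screen: cloud < cloud_max AND valid > valid_min.

    Both inequalities are strict, so a mosaic at exactly 3% cloud or exactly
    90% valid data is excluded.  Input order is preserved.
    """
    if not 0 <= cloud_max <= 1 or not 0 <= valid_min <= 1:
        raise ValueError("thresholds must lie in [0, 1]")
    kept = [q.date for q in quality
            if q.cloud_fraction < cloud_max and q.valid_fraction > valid_min]
    if not kept:
        raise DegenerateConfigError(
            "no mosaics pass the quality screen "
            f"(cloud < {cloud_max}, valid > {valid_min}); relax the thresholds"
        )
    return as_day_array(kept)


def compute_index(cube: ReflectanceCube, spec: VegetationIndexSpec) -> np.ndarray:
    """Evaluate one vegetation index over the cube.

    Returns a (n_dates, rows, cols) float array with NaN wherever the pixel
    is invalid or the index denominator vanishes.
    """
    for b in INDEX_BANDS[spec.name]:
        if b not in cube.bands:
            raise ValueError(f"index {spec.name} requires band {b}, absent from cube")
    g = {b: cube.bands[b] for b in BANDS if b in cube.bands}
    with np.errstate(divide="ignore", invalid="ignore"):
        if spec.name == "EVI":
            num = spec.G * (g["NIR"] - g["RED"])
            den = g["NIR"] + spec.C1 * g["RED"] - spec.C2 * g["BLUE"] + spec.L
        elif spec.name == "NBR":
            num = g["NIR"] - g["SWIR1"]
            den = g["NIR"] + g["SWIR1"]
        elif spec.name == "NDVI":
            num = g["NIR"] - g["RED"]
            den = g["NIR"] + g["RED"]
        else:  # NDWI
            num = g["GREEN"] - g["NIR"]
            den = g["GREEN"] + g["NIR"]
        vals = np.where(den == 0, np.nan, num / den)
    vals = np.where(cube.valid_mask, vals, np.nan)
    return vals


@dataclass
class SpatioTemporalMatrix:
    """One vegetation index as a dates x pixels matrix.

    Rows follow ``dates``; columns are pixels flattened row-major from the
    top-left, so column j maps to pixel (j // n_cols, j % n_cols).
    """

    values: np.ndarray
    dates: np.ndarray
    grid_shape: tuple
    index_name: str
    n_imputed: int = 0

    def __post_init__(self):
        self.dates = as_day_array(self.dates)
        n_rows, n_cols = self.grid_shape
        if self.values.shape != (self.dates.size, n_rows * n_cols):
            raise ValueError("matrix shape inconsistent with dates/grid")
        if np.isnan(self.values).any():
            raise ValueError("SpatioTemporalMatrix may not contain missing entries")

    @property
    def n_pixels(self) -> int:
        return self.values.shape[1]

    def pixel_of_column(self, j: int):
        return j // self.grid_shape[1], j % self.grid_shape[1]

    def to_grid(self, vector: np.ndarray) -> np.ndarray:
        """Unflatten a pixel-length vector back to the raster grid."""
        return np.asarray(vector).reshape(self.grid_shape)


def build_matrix(
    index_grids: np.ndarray,
    dates,
    retained_dates=None,
    impute_policy: str = "linear_time",
    index_name: str = "",
    grid_shape=None,
) -> SpatioTemporalMatrix:
    """Flatten index grids for the retained dates into a complete matrix.

    Residual missing entries (masked pixels on retained dates) are filled
    per ``impute_policy``; the default interpolates each pixel's time series
    linearly in acquisition time and extends the ends with the nearest
    observed value.  A pixel with no valid observation at all is an error.
    """
    dates = as_day_array(dates)
    index_grids = np.asarray(index_grids, dtype=float)
    if grid_shape is None:
        grid_shape = index_grids.shape[1:]
    if retained_dates is None:
        retained_dates = dates
    retained_dates = as_day_array(retained_dates)
    if retained_dates.size < 2:
        raise DegenerateConfigError("need at least 2 retained dates to build a matrix")
    keep = np.isin(dates, retained_dates)
    mat = index_grids[keep].reshape(retained_dates.size, -1)
    t = (retained_dates - retained_dates[0]).astype(float)

    missing = np.isnan(mat)
    n_imputed = int(missing.sum())
    if n_imputed:
        if impute_policy == "linear_time":
            dead = missing.all(axis=0)
            if dead.any():
                cols = np.flatnonzero(dead)[:10]
                px = [(int(j // grid_shape[1]), int(j % grid_shape[1])) for j in cols]
                raise ValueError(
                    f"{int(dead.sum())} pixel(s) have no valid observation on any "
                    f"retained date; first offenders (row, col): {px}"
                )
            for j in np.flatnonzero(missing.any(axis=0)):
                ok = ~missing[:, j]
                # np.interp clamps beyond the first/last sample -> nearest fill
                mat[missing[:, j], j] = np.interp(t[missing[:, j]], t[ok], mat[ok, j])
        elif impute_policy == "column_mean":
            mu = np.nanmean(mat, axis=0)
            if np.isnan(mu).any():
                raise ValueError("pixel(s) with no valid observation cannot be mean-filled")
            mat = np.where(missing, mu[None, :], mat)
        else:
            raise ValueError(f"unknown impute_policy {impute_policy!r}")

    return SpatioTemporalMatrix(
        values=mat,
        dates=retained_dates,
        grid_shape=tuple(grid_shape),
        index_name=index_name,
        n_imputed=n_imputed,
    )


def index_matrices(
    cube: ReflectanceCube,
    indices=INDEX_NAMES,
    cloud_max: float = 0.03,
    valid_min: float = 0.90,
    impute_policy: str = "linear_time",
) -> dict:
    """Convenience pipeline: QC screen the cube, then one matrix per index."""
    quality = assess_quality(cube)
    retained = filter_mosaics(quality, cloud_max=cloud_max, valid_min=valid_min)
    out = {}
    for name in indices:
        grids = compute_index(cube, VegetationIndexSpec(name))
        out[name] = build_matrix(
            grids, cube.dates, retained, impute_policy=impute_policy, index_name=name
        )
    return out
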