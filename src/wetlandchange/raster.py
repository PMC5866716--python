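"""Core raster containers and lightweight GeoTIFF / sidecar I/O.

All rasters in the package share a :class:`Grid`: a north-up regular grid
with square pixels, addressed row/col 0-based from the top-left corner.
World coordinates follow the usual GIS convention (x east, y north), so row
index increases as y decreases.

GeoTIFF files are written with :mod:`tifffile`, embedding the standard
``ModelPixelScaleTag`` / ``ModelTiepointTag`` georeferencing tags; legend,
nodata and band names travel in a small ``<file>.aux.json`` sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import tifffile

NODATA_LABEL = 255  # categorical rasters: uint8 with 255 reserved

# GeoTIFF tag codes
_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922


@dataclass(frozen=True)
class Grid:
    """Regular north-up raster grid with square pixels.

    Parameters
    ----------
    rows, cols
        Grid dimensions.
    pixel_size
        Ground length of a pixel side in metres (30 for Landsat).
    origin
        World (x, y) of the top-left *corner* of pixel (0, 0).
    """

    rows: int
    cols: int
    pixel_size: float = 30.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.rows <= 0 or self.cols <= 0:
            raise ValueError("grid must have positive dimensions")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.rows, self.cols)

    @property
    def pixel_area_ha(self) -> float:
        """Area of one pixel in hectares (0.09 ha for 30 m pixels)."""
        return self.pixel_size**2 / 10_000.0

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """World coordinates of every pixel center as (X, Y) 2-D arrays."""
        x0, y0 = self.origin
        xs = x0 + (np.arange(self.cols) + 0.5) * self.pixel_size
        ys = y0 - (np.arange(self.rows) + 0.5) * self.pixel_size
        return np.meshgrid(xs, ys)

    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid extent."""
        x0, y0 = self.origin
        return (x0, y0 - self.rows * self.pixel_size,
                x0 + self.cols * self.pixel_size, y0)

    def pixel_box(self, row: int, col: int) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of one pixel's footprint."""
        x0, y0 = self.origin
        xmin = x0 + col * self.pixel_size
        ymax = y0 - row * self.pixel_size
        return (xmin, ymax - self.pixel_size, xmin + self.pixel_size, ymax)


def _require_same_grid(a: Grid, b: Grid, what: str = "rasters") -> None:
    if a != b:
        raise ValueError(f"{what} are not on the same grid: {a} vs {b}")


@dataclass
class HabitatMap:
    """Categorical habitat raster with a legend.

    ``labels`` is a 2-D integer array; every value is either ``nodata`` or a
    key of ``legend``.
    """

    labels: np.ndarray
    legend: dict[int, str]
    grid: Grid
    nodata: int = NODATA_LABEL

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.shape != self.grid.shape:
            raise ValueError(
                f"label array shape {self.labels.shape} != grid shape {self.grid.shape}"
            )
        present = np.unique(self.labels)
        bad = [int(v) for v in present if v != self.nodata and int(v) not in self.legend]
        if bad:
            raise ValueError(f"labels {bad} missing from legend")

    @property
    def valid_mask(self) -> np.ndarray:
        return self.labels != self.nodata

    def class_counts(self) -> dict[int, int]:
        """Pixel count per legend class (zero for absent classes)."""
        out = {}
        for cid in self.legend:
            out[cid] = int(np.count_nonzero(self.labels == cid))
        return out


@dataclass
class SpectralCube:
    """Multi-season, multi-band reflectance/radiance stack on one grid.

    ``values`` has shape (n_seasons, n_bands, rows, cols).
    """

    values: np.ndarray
    band_roles: Sequence[str]
    season_tags: Sequence[str]
    grid: Grid
    nodata_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 4:
            raise ValueError("cube values must be 4-D (season, band, row, col)")
        ns, nb, r, c = self.values.shape
        if (r, c) != self.grid.shape:
            raise ValueError("cube spatial shape does not match grid")
        if ns != len(self.season_tags) or nb != len(self.band_roles):
            raise ValueError("season/band axis lengths do not match tags/roles")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.grid.shape, dtype=bool)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.nodata_mask.shape != self.grid.shape:
            raise ValueError("nodata mask shape does not match grid")

    def band(self, season: int | str, role: str) -> np.ndarray:
        """One band image by season index/tag and band role."""
        if isinstance(season, str):
            season = list(self.season_tags).index(season)
        try:
            b = list(self.band_roles).index(role)
        except ValueError:
            raise KeyError(f"band role {role!r} not in cube (has {list(self.band_roles)})")
        return self.values[season, b]


@dataclass
class FeatureStack:
    """Per-pixel feature vectors for classification.

    ``features`` has shape (n_features, rows, cols); ``feature_names`` are
    unique strings such as ``"spring_nir"`` or ``"autumn_ndwi"``.
    """

    features: np.ndarray
    feature_names: list[str]
    grid: Grid
    nodata_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        if self.features.ndim != 3:
            raise ValueError("features must be 3-D (feature, row, col)")
        if self.features.shape[1:] != self.grid.shape:
            raise ValueError("feature spatial shape does not match grid")
        if len(self.feature_names) != self.features.shape[0]:
            raise ValueError("feature_names length does not match feature axis")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.grid.shape, dtype=bool)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)

    @property
    def n_features(self) -> int:
        return self.features.shape[0]

    def as_table(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Flatten valid pixels to an (n, p) matrix.

        Returns ``(X, rows, cols)`` where ``X[k]`` is the feature vector of
        pixel ``(rows[k], cols[k])``.
        """
        valid = ~self.nodata_mask
        rr, cc = np.nonzero(valid)
        X = self.features[:, rr, cc].T
        return X, rr, cc

    def select(self, names: Sequence[str]) -> "FeatureStack":
        """Reorder/subset features by name (raises on unknown names)."""
        idx = []
        for n in names:
            try:
                idx.append(self.feature_names.index(n))
            except ValueError:
                raise KeyError(f"feature {n!r} not in stack")
        return FeatureStack(self.features[idx], list(names), self.grid,
                            self.nodata_mask)


# ---------------------------------------------------------------------------
# GeoTIFF + sidecar I/O


def _geo_extratags(grid: Grid):
    x0, y0 = grid.origin
    scale = (float(grid.pixel_size), float(grid.pixel_size), 0.0)
    tiepoint = (0.0, 0.0, 0.0, float(x0), float(y0), 0.0)
    return [
        (_MODEL_PIXEL_SCALE, "d", 3, scale, True),
        (_MODEL_TIEPOINT, "d", 6, tiepoint, True),
    ]


def _write_sidecar(path: Path, meta: Mapping) -> None:
    Path(str(path) + ".aux.json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def _read_sidecar(path: Path) -> dict:
    p = Path(str(path) + ".aux.json")
    return json.loads(p.read_text()) if p.exists() else {}


def _read_grid(path: Path, shape: tuple[int, int], meta: dict) -> Grid:
    scale = tie = None
    with tifffile.TiffFile(path) as tf:
        tags = tf.pages[0].tags
        if _MODEL_PIXEL_SCALE in tags and _MODEL_TIEPOINT in tags:
            scale = tuple(tags[_MODEL_PIXEL_SCALE].value)
            tie = tuple(tags[_MODEL_TIEPOINT].value)
    if scale is not None and tie is not None:
        px = float(scale[0])
        origin = (float(tie[3]), float(tie[4]))
    else:
        px = float(meta.get("pixel_size", 30.0))
        origin = tuple(meta.get("origin", (0.0, 0.0)))
    return Grid(shape[0], shape[1], px, origin)


def write_habitat_map(path: str | Path, hmap: HabitatMap) -> None:
    """Write a categorical map as single-band uint8 GeoTIFF (+ sidecar)."""
    path = Path(path)
    data = hmap.labels.astype(np.uint8)
    tifffile.imwrite(path, data, extratags=_geo_extratags(hmap.grid))
    _write_sidecar(path, {
        "kind": "habitat_map",
        "legend": {str(k): v for k, v in hmap.legend.items()},
        "nodata": int(hmap.nodata),
        "pixel_size": hmap.grid.pixel_size,
        "origin": list(hmap.grid.origin),
    })


def read_habitat_map(path: str | Path) -> HabitatMap:
    path = Path(path)
    data = tifffile.imread(path)
    meta = _read_sidecar(path)
    grid = _read_grid(path, data.shape, meta)
    legend = {int(k): v for k, v in meta.get("legend", {}).items()}
    return HabitatMap(data.astype(np.int64), legend, grid,
                      nodata=int(meta.get("nodata", NODATA_LABEL)))


def write_cube(path: str | Path, cube: SpectralCube) -> None:
    """Write a spectral cube as a (season·band, rows, cols) float32 GeoTIFF."""
    path = Path(path)
    ns, nb, r, c = cube.values.shape
    flat = cube.values.reshape(ns * nb, r, c).astype(np.float32)
    tifffile.imwrite(path, flat, extratags=_geo_extratags(cube.grid))
    _write_sidecar(path, {
        "kind": "spectral_cube",
        "band_roles": list(cube.band_roles),
        "season_tags": list(cube.season_tags),
        "pixel_size": cube.grid.pixel_size,
        "origin": list(cube.grid.origin),
    })


def read_cube(path: str | Path) -> SpectralCube:
    path = Path(path)
    flat = tifffile.imread(path).astype(np.float64)
    meta = _read_sidecar(path)
    roles = meta["band_roles"]
    seasons = meta["season_tags"]
    ns, nb = len(seasons), len(roles)
    grid = _read_grid(path, flat.shape[1:], meta)
    return SpectralCube(flat.reshape(ns, nb, *flat.shape[1:]), roles, seasons, grid)


def write_feature_stack(path: str | Path, stack: FeatureStack) -> None:
    path = Path(path)
    tifffile.imwrite(path, stack.features.astype(np.float32),
                     extratags=_geo_extratags(stack.grid))
    _write_sidecar(path, {
        "kind": "feature_stack",
        "feature_names": list(stack.feature_names),
        "pixel_size": stack.grid.pixel_size,
        "origin": list(stack.grid.origin),
    })
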