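"""Reference polygons and labelled pixel-sample extraction.

Reference areas are digitized polygons with a habitat-class label and a
role (``training`` or ``validation``) fixed at the polygon level, so that
pixels of one polygon can never leak across the train/validation split.

Pixel coverage is decided by the pixel-center rule, half-open on the max
edges: a pixel belongs to an axis-aligned polygon iff
``xmin <= xc < xmax`` and ``ymin < yc <= ymax`` for its center ``(xc, yc)``.
Adjacent polygons sharing an edge therefore never double-count a pixel.
Non-rectangular polygons use strict interior containment, which obeys the
same no-double-counting guarantee.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import shapely
from shapely.geometry import Polygon, box, mapping, shape

from .raster import FeatureStack, Grid, HabitatMap

ROLES = ("training", "validation")


@dataclass(frozen=True)
class ReferencePolygon:
    geometry: Polygon
    class_id: int
    role: str
    polygon_id: int
    class_name: str = ""

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")


@dataclass
class ReferenceAreas:
    """A set of labelled reference polygons partitioned into roles."""

    polygons: list[ReferencePolygon] = field(default_factory=list)

    def __iter__(self):
        return iter(self.polygons)

    def __len__(self) -> int:
        return len(self.polygons)

    def by_role(self, role: str) -> list[ReferencePolygon]:
        return [p for p in self.polygons if p.role == role]

    def counts(self) -> dict[tuple[int, str], int]:
        """Polygon counts keyed by (class_id, role)."""
        out: dict[tuple[int, str], int] = {}
        for p in self.polygons:
            key = (p.class_id, p.role)
            out[key] = out.get(key, 0) + 1
        return out

    def to_geojson(self, path: str | Path) -> None:
        features = []
        for p in self.polygons:
            features.append({
                "type": "Feature",
                "geometry": mapping(p.geometry),
                "properties": {
                    "polygon_id": p.polygon_id,
                    "class_id": p.class_id,
                    "class_name": p.class_name,
                    "role": p.role,
                },
            })
        Path(path).write_text(json.dumps(
            {"type": "FeatureCollection", "features": features}, indent=2))

    @classmethod
    def from_geojson(cls, path: str | Path) -> "ReferenceAreas":
        doc = json.loads(Path(path).read_text())
        polys = []
        for feat in doc["features"]:
            props = feat["properties"]
            polys.append(ReferencePolygon(
                geometry=shape(feat["geometry"]),
                class_id=int(props["class_id"]),
                role=props["role"],
                polygon_id=int(props.get("polygon_id", len(polys))),
                class_name=props.get("class_name", ""),
            ))
        return cls(polys)


@dataclass
class LabeledSamples:
    """Per-pixel feature vectors with class labels, roles and provenance."""

    X: np.ndarray            # (n, p) feature matrix
    y: np.ndarray            # (n,) class ids
    role: np.ndarray         # (n,) role strings
    rows: np.ndarray         # (n,) pixel row of each sample
    cols: np.ndarray         # (n,) pixel col of each sample
    polygon_ids: np.ndarray  # (n,) source polygon id
    feature_names: list[str]
    legend: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.y)
        if not (len(self.X) == n == len(self.role) == len(self.rows)
                == len(self.cols) == len(self.polygon_ids)):
            raise ValueError("sample arrays have inconsistent lengths")
        train = set(zip(self.rows[self.role == "training"].tolist(),
                        self.cols[self.role == "training"].tolist()))
        valid = set(zip(self.rows[self.role == "validation"].tolist(),
                        self.cols[self.role == "validation"].tolist()))
        if train & valid:
            raise ValueError("a pixel appears in both training and validation roles")

    def __len__(self) -> int:
        return len(self.y)

    def subset(self, role: str) -> "LabeledSamples":
        m = self.role == role
        return LabeledSamples(self.X[m], self.y[m], self.role[m], self.rows[m],
                              self.cols[m], self.polygon_ids[m],
                              self.feature_names, self.legend)

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame(self.X, columns=self.feature_names)
        df.insert(0, "polygon_id", self.polygon_ids)
        df.insert(0, "role", self.role)
        df.insert(0, "class_id", self.y)
        df.insert(0, "col", self.cols)
        df.insert(0, "row", self.rows)
        return df


def covered_pixels(geometry: Polygon, grid: Grid) -> tuple[np.ndarray, np.ndarray]:
    """Rows/cols of pixels whose center the polygon covers.

    Axis-aligned rectangles use the exact half-open rule; general polygons
    use strict interior containment of the center point.
    """
    xmin, ymin, xmax, ymax = geometry.bounds
    gx0, gy0 = grid.origin
    ps = grid.pixel_size
    # candidate window in pixel indices
    c0 = max(0, int(np.floor((xmin - gx0) / ps - 0.5)))
    c1 = min(grid.cols - 1, int(np.ceil((xmax - gx0) / ps)))
    r0 = max(0, int(np.floor((gy0 - ymax) / ps - 0.5)))
    r1 = min(grid.rows - 1, int(np.ceil((gy0 - ymin) / ps)))
    if c1 < c0 or r1 < r0:
        return np.array([], dtype=int), np.array([], dtype=int)
    cs = np.arange(c0, c1 + 1)
    rs = np.arange(r0, r1 + 1)
    xc = gx0 + (cs + 0.5) * ps
    yc = gy0 - (rs + 0.5) * ps
    XC, YC = np.meshgrid(xc, yc)
    is_rect = geometry.equals(box(*geometry.bounds))
    if is_rect:
        inside = (XC >= xmin) & (XC < xmax) & (YC > ymin) & (YC <= ymax)
    else:
        inside = shapely.contains_xy(geometry, XC.ravel(), YC.ravel()).reshape(XC.shape)
    rr, cc = np.nonzero(inside)
    return rs[rr], cs[cc]


def extract_samples(stack: FeatureStack, areas: ReferenceAreas) -> LabeledSamples:
    """Turn reference polygons plus a feature stack into labelled samples.

    One sample per non-nodata pixel whose center a polygon covers; label and
    role are inherited from the polygon. Overlapping polygons with the same
    class and role are deduplicated by pixel (first claim wins); overlaps
    that disagree on class or role are ambiguous and raise.
    """
    grid = stack.grid
    extent = box(*grid.bounds())
    owner: dict[tuple[int, int], tuple[int, str, int]] = {}
    order: list[tuple[int, int]] = []
    for poly in areas:
        if not poly.geometry.intersects(extent):
            raise ValueError(
                f"polygon {poly.polygon_id} lies wholly outside the raster extent")
        rr, cc = covered_pixels(poly.geometry, grid)
        keep = ~stack.nodata_mask[rr, cc]
        rr, cc = rr[keep], cc[keep]
        if len(rr) == 0:
            warnings.warn(
                f"polygon {poly.polygon_id} covers no valid pixel centers; skipped",
                stacklevel=2)
            continue
        for r, c in zip(rr.tolist(), cc.tolist()):
            prev = owner.get((r, c))
            if prev is None:
                owner[(r, c)] = (poly.class_id, poly.role, poly.polygon_id)
                order.append((r, c))
            elif prev[0] != poly.class_id or prev[1] != poly.role:
                raise ValueError(
                    f"pixel ({r}, {c}) claimed by polygons {prev[2]} and "
                    f"{poly.polygon_id} with conflicting class/role")
    if not order:
        raise ValueError("no polygon produced any samples")
    rows = np.array([r for r, _ in order])
    cols = np.array([c for _, c in order])
    y = np.array([owner[rc][0] for rc in order])
    role = np.array([owner[rc][1] for rc in order])
    pids = np.array([owner[rc][2] for rc in order])
    X = stack.features[:, rows, cols].T
    legend = {p.class_id: p.class_name for p in areas if p.class_name}
    return LabeledSamples(X, y, role, rows, cols, pids,
                          list(stack.feature_names), legend)
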