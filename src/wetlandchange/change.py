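"""Habitat-change quantification between two dates.

Per-class areas are pixel counts times the pixel area in hectares (0.09 ha
for 30 m pixels). The transition matrix cross-tabulates the two dates'
labels over pixels valid at both dates, on the union of both legends, so a
class present only at one date contributes an all-zero row or column.
Percent change per class is computed from the transition-matrix marginals
— column sum (area at the later date) against row sum (area at the earlier
date) — so nodata exclusion is identical at both dates; a class absent at
the earlier date has undefined percent change (NaN).

A published pair of ensemble transition matrices for a 984 ha coastal
wetland (2003 → 2016) ships as ``data/table3_transitions.csv`` and can be
loaded with :func:`load_published_transitions` for worked examples and
cross-checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .raster import HabitatMap, _require_same_grid


@dataclass
class TransitionMatrix:
    """Class-from x class-to area cross-tabulation in hectares."""

    areas: np.ndarray
    class_ids: list[int]
    class_names: dict[int, str]
    pixel_area: float
    date_from: str = ""
    date_to: str = ""

    def __post_init__(self) -> None:
        self.areas = np.asarray(self.areas, dtype=float)
        k = len(self.class_ids)
        if self.areas.shape != (k, k):
            raise ValueError("areas must be K x K")
        if (self.areas < 0).any():
            raise ValueError("areas must be non-negative")
        if self.pixel_area <= 0:
            raise ValueError("pixel_area must be positive")
        mult = self.areas / self.pixel_area
        if not np.allclose(self.areas, np.round(mult) * self.pixel_area,
                           atol=1e-9, rtol=0):
            raise ValueError("every area must be an integer multiple of pixel_area")

    @property
    def total_area(self) -> float:
        return float(self.areas.sum())

    def row_sums(self) -> dict[int, float]:
        """Per-class area at date_from."""
        return {c: float(s) for c, s in zip(self.class_ids, self.areas.sum(axis=1))}

    def col_sums(self) -> dict[int, float]:
        """Per-class area at date_to."""
        return {c: float(s) for c, s in zip(self.class_ids, self.areas.sum(axis=0))}

    def transpose(self) -> "TransitionMatrix":
        return TransitionMatrix(self.areas.T.copy(), list(self.class_ids),
                                dict(self.class_names), self.pixel_area,
                                self.date_to, self.date_from)

    def to_dataframe(self) -> pd.DataFrame:
        names = [self.class_names.get(c, str(c)) for c in self.class_ids]
        return pd.DataFrame(self.areas, index=names, columns=names)


def class_areas(hmap: HabitatMap, pixel_area: float | None = None) -> dict[int, float]:
    """Spatial extent (ha) of each legend class: pixel count x pixel area."""
    if pixel_area is None:
        pixel_area = hmap.grid.pixel_area_ha
    if pixel_area <= 0:
        raise ValueError("pixel_area must be positive")
    return {cid: cnt * pixel_area for cid, cnt in hmap.class_counts().items()}


def transition_matrix(map_from: HabitatMap, map_to: HabitatMap,
                      pixel_area: float | None = None,
                      date_from: str = "", date_to: str = "") -> TransitionMatrix:
    """Cross-tabulate two dates' habitat maps into an area matrix (ha)."""
    _require_same_grid(map_from.grid, map_to.grid, "maps")
    if pixel_area is None:
        pixel_area = map_from.grid.pixel_area_ha
    class_ids = sorted(set(map_from.legend) | set(map_to.legend))
    names = {**map_to.legend, **map_from.legend}
    index = {c: i for i, c in enumerate(class_ids)}
    k = len(class_ids)
    valid = map_from.valid_mask & map_to.valid_mask
    a = map_from.labels[valid]
    b = map_to.labels[valid]
    ai = np.vectorize(index.__getitem__)(a) if a.size else np.array([], dtype=int)
    bi = np.vectorize(index.__getitem__)(b) if b.size else np.array([], dtype=int)
    counts = np.bincount(ai * k + bi, minlength=k * k).reshape(k, k)
    return TransitionMatrix(counts * pixel_area, class_ids, names, pixel_area,
                            date_from, date_to)


def percent_change(tm: TransitionMatrix) -> dict[int, float]:
    """Signed percent change per class from the matrix marginals.

    ``100 * (colsum_c - rowsum_c) / rowsum_c``; negative means loss. A class
    with zero area at date_from (e.g. one that only appears at the later
    date) has undefined change and maps to NaN.
    """
    rows = tm.row_sums()
    cols = tm.col_sums()
    out = {}
    for c in tm.class_ids:
        if rows[c] == 0:
            out[c] = float("nan")
        else:
            out[c] = 100.0 * (cols[c] - rows[c]) / rows[c]
    return out


def change_summary(tm: TransitionMatrix) -> pd.DataFrame:
    """Tidy per-class change table: areas, signed %, magnitude and tag."""
    rows = tm.row_sums()
    cols = tm.col_sums()
    pct = percent_change(tm)
    recs = []
    for c in tm.class_ids:
        p = pct[c]
        tag = "undefined" if np.isnan(p) else ("gain" if p > 0 else
                                               "loss" if p < 0 else "stable")
        recs.append({
            "class_id": c,
            "class_name": tm.class_names.get(c, str(c)),
            f"area_ha_{tm.date_from or 'from'}": rows[c],
            f"area_ha_{tm.date_to or 'to'}": cols[c],
            "percent_change": p,
            "percent_magnitude": abs(p),
            "direction": tag,
        })
    return pd.DataFrame(recs)


_PUBLISHED_LEGEND = {
    1: "Sand dunes", 2: "Burned areas", 3: "Tidal areas", 4: "Forest",
    5: "Reedbed", 6: "Sea dunes", 7: "Grasslands", 8: "Salt marshes",
}


def load_published_transitions(path: str | Path | None = None,
                               ) -> dict[str, TransitionMatrix]:
    """Load the shipped published 2003→2016 transition matrices.

    Returns ``{"Ens_SV": ..., "Ens_WV": ...}`` with 0.09 ha pixels.
    """
    if path is None:
        src = resources.files("wetlandchange").joinpath(
            "data/table3_transitions.csv")
        df = pd.read_csv(src.open())
    else:
        df = pd.read_csv(path)
    name_to_id = {v: k for k, v in _PUBLISHED_LEGEND.items()}
    class_ids = sorted(_PUBLISHED_LEGEND)
    out = {}
    for ens, block in df.groupby("ensemble"):
        areas = np.zeros((len(class_ids), len(class_ids)))
        for _, row in block.iterrows():
            i = name_to_id[row["from_class"]] - 1
            for name, j in ((n, name_to_id[n] - 1) for n in name_to_id):
                areas[i, j] = float(row[name])
        out[ens] = TransitionMatrix(areas, class_ids, dict(_PUBLISHED_LEGEND),
                                    pixel_area=0.09, date_from="2003",
                                    date_to="2016")
    return out
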