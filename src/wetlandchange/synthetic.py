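"""Synthetic labelled wetland landscapes.

The generator produces everything the downstream pipeline consumes from a
real study site: a ground-truth habitat map with spatially coherent
patches, seasonal multispectral reflectance cubes with class-specific
spectral signatures plus Gaussian sensor noise, and stratified-random
reference polygons split into training/validation roles.

Patches come from per-class smoothed Gaussian random fields: each class
gets an independent standard-normal field smoothed at ``patch_scale``
pixels, and every pixel takes the class whose (bias-shifted) field value is
largest. The per-class biases are calibrated iteratively so realized class
shares track the requested ``target_proportions``. The whole construction
is a pure function of the configuration and seed.

The default eight-class signature set mimics a coastal Atlantic wetland
mosaic (sand dunes, tidal flats/lagoons, conifer forest, reed bed,
vegetated grey dunes, semi-natural grasslands, salt marshes, burned areas)
with seasonal phenology in the red/NIR bands; any two classes differ by at
least 0.1 reflectance in some season/band, i.e. five noise standard
deviations at the default ``noise_sd`` of 0.02.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .raster import Grid, HabitatMap, SpectralCube, NODATA_LABEL
from .sampling import ReferenceAreas, ReferencePolygon
from shapely.geometry import box

DEFAULT_BANDS = ("blue", "green", "red", "nir", "swir1", "swir2")
DEFAULT_SEASONS = ("spring", "autumn")

# Habitat legend used throughout the worked examples; ids are arbitrary but
# stable, names follow broad Annex-I-style habitat classes.
DEFAULT_LEGEND = {
    1: "Sand dunes",
    2: "Burned areas",
    3: "Tidal areas",
    4: "Forest",
    5: "Reedbed",
    6: "Sea dunes of Atlantic coast",
    7: "Natural and semi-natural grasslands",
    8: "Salt marshes and meadows",
}


@dataclass(frozen=True)
class ClassSignature:
    """Reference spectral signature of one habitat class.

    ``mean_reflectance`` is an (n_seasons, n_bands) array of surface
    reflectance in [0, 1]; ``noise_sd`` the per-band standard deviation of
    the additive Gaussian noise (shared across seasons).
    """

    class_id: int
    name: str
    mean_reflectance: tuple  # nested tuples, (n_seasons, n_bands)
    noise_sd: tuple          # (n_bands,)

    def means(self) -> np.ndarray:
        m = np.asarray(self.mean_reflectance, dtype=float)
        if m.ndim != 2:
            raise ValueError("mean_reflectance must be (n_seasons, n_bands)")
        if m.min() < 0 or m.max() > 1:
            raise ValueError("mean reflectance must lie in [0, 1]")
        return m

    def sds(self) -> np.ndarray:
        s = np.asarray(self.noise_sd, dtype=float)
        if (s < 0).any():
            raise ValueError("noise_sd must be non-negative")
        return s


def _sig(cid, name, spring, autumn, sd=0.02):
    nb = len(spring)
    return ClassSignature(cid, name, (tuple(spring), tuple(autumn)), (sd,) * nb)


def default_signatures(noise_sd: float = 0.02) -> list[ClassSignature]:
    """Eight-class coastal-wetland signature set (spring, autumn × 6 bands).

    Band order is blue, green, red, nir, swir1, swir2.
    """
    raw = [
        (1, "Sand dunes",
         (0.30, 0.35, 0.40, 0.45, 0.50, 0.45), (0.32, 0.37, 0.42, 0.47, 0.52, 0.47)),
        (2, "Burned areas",
         (0.05, 0.06, 0.07, 0.10, 0.20, 0.25), (0.05, 0.06, 0.08, 0.09, 0.22, 0.28)),
        (3, "Tidal areas",
         (0.08, 0.10, 0.06, 0.03, 0.02, 0.01), (0.09, 0.11, 0.07, 0.04, 0.02, 0.01)),
        (4, "Forest",
         (0.03, 0.06, 0.05, 0.35, 0.18, 0.09), (0.03, 0.06, 0.05, 0.33, 0.17, 0.09)),
        (5, "Reedbed",
         (0.04, 0.08, 0.07, 0.25, 0.15, 0.08), (0.05, 0.09, 0.12, 0.45, 0.28, 0.15)),
        (6, "Sea dunes of Atlantic coast",
         (0.12, 0.16, 0.18, 0.30, 0.32, 0.26), (0.13, 0.17, 0.20, 0.28, 0.34, 0.28)),
        (7, "Natural and semi-natural grasslands",
         (0.04, 0.09, 0.06, 0.50, 0.25, 0.12), (0.06, 0.10, 0.12, 0.30, 0.26, 0.16)),
        (8, "Salt marshes and meadows",
         (0.06, 0.09, 0.10, 0.20, 0.22, 0.14), (0.07, 0.10, 0.11, 0.18, 0.24, 0.16)),
    ]
    return [_sig(cid, name, sp, au, noise_sd) for cid, name, sp, au in raw]


@dataclass(frozen=True)
class SceneConfig:
    """Configuration of one synthetic scene (one acquisition year)."""

    rows: int = 120
    cols: int = 120
    pixel_size: float = 30.0
    bands: Sequence[str] = DEFAULT_BANDS
    season_tags: Sequence[str] = DEFAULT_SEASONS
    classes: Sequence[ClassSignature] = field(default_factory=default_signatures)
    target_proportions: Mapping[int, float] | None = None
    patch_scale: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rows * self.cols <= 0:
            raise ValueError("grid must be non-empty")
        if not self.classes:
            raise ValueError("class list must not be empty")
        if self.patch_scale < 1:
            raise ValueError("patch_scale must be >= 1 pixel")
        for sig in self.classes:
            m = sig.means()
            if m.shape != (len(self.season_tags), len(self.bands)):
                raise ValueError(
                    f"class {sig.class_id}: signature shape {m.shape} does not "
                    f"match {len(self.season_tags)} seasons x {len(self.bands)} bands")
        props = self.proportions()
        total = sum(props.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"target proportions sum to {total}, expected 1")

    def proportions(self) -> dict[int, float]:
        if self.target_proportions is None:
            k = len(self.classes)
            return {sig.class_id: 1.0 / k for sig in self.classes}
        return {int(c): float(p) for c, p in self.target_proportions.items()}

    @property
    def grid(self) -> Grid:
        return Grid(self.rows, self.cols, self.pixel_size)

    def legend(self) -> dict[int, str]:
        return {sig.class_id: sig.name for sig in self.classes}


@dataclass
class LabeledScene:
    """One date's ground truth, reflectance cube and reference polygons."""

    truth: HabitatMap
    cube: SpectralCube
    reference: ReferenceAreas
    date: str = ""


# ---------------------------------------------------------------------------
# label map generation


def _smooth_fields(shape, n, patch_scale, generator) -> np.ndarray:
    fields = np.empty((n, *shape))
    for i in range(n):
        f = gaussian_filter(generator.standard_normal(shape), sigma=patch_scale,
                            mode="wrap")
        sd = f.std()
        fields[i] = f / sd if sd > 0 else f
    return fields


def _labels_from_fields(fields: np.ndarray, class_ids: Sequence[int],
                        targets: np.ndarray, n_iter: int = 200,
                        lr: float = 2.5) -> np.ndarray:
    """Argmax over bias-shifted fields, biases calibrated to hit targets."""
    n, rows, cols = fields.shape
    npix = rows * cols
    biases = np.zeros(n)
    absent = targets <= 0
    biases[absent] = -np.inf
    active = ~absent
    for _ in range(n_iter):
        lab_idx = np.argmax(fields + biases[:, None, None], axis=0)
        realized = np.bincount(lab_idx.ravel(), minlength=n) / npix
        err = targets - realized
        if np.abs(err[active]).max() < 0.002:
            break
        biases[active] += lr * err[active]
    lab_idx = np.argmax(fields + biases[:, None, None], axis=0)
    ids = np.asarray(class_ids)
    return ids[lab_idx]


def generate_label_map(cfg: SceneConfig, *,
                       fields: np.ndarray | None = None) -> HabitatMap:
    """Generate a spatially coherent ground-truth habitat map.

    Deterministic in ``(cfg, cfg.seed)``; classes with a zero target
    proportion receive no pixels. Realized class shares land within a few
    percentage points of ``target_proportions`` (the calibration stops once
    every class is within 0.2 points, grid permitting).
    """
    props = cfg.proportions()
    class_ids = [sig.class_id for sig in cfg.classes]
    for cid in props:
        if cid not in set(class_ids):
            raise ValueError(f"target proportion given for unknown class {cid}")
    targets = np.array([props.get(cid, 0.0) for cid in class_ids])
    if len(class_ids) == 1:
        labels = np.full((cfg.rows, cfg.cols), class_ids[0])
        return HabitatMap(labels, cfg.legend(), cfg.grid)
    if fields is None:
        gen = np.random.default_rng(cfg.seed)
        fields = _smooth_fields((cfg.rows, cfg.cols), len(class_ids),
                                cfg.patch_scale, gen)
    labels = _labels_from_fields(fields, class_ids, targets)
    return HabitatMap(labels, cfg.legend(), cfg.grid)


def render_reflectance(truth: HabitatMap, cfg: SceneConfig, season: int,
                       seed: int) -> np.ndarray:
    """Render one season's reflectance bands from a truth map.

    Returns an (n_bands, rows, cols) array: per pixel the class mean for
    (season, band) plus Gaussian noise with that band's standard deviation,
    clipped to [0, 1]. Raises if the truth map contains a label with no
    signature, naming the label.
    """
    sig_by_id = {s.class_id: s for s in cfg.classes}
    present = [int(v) for v in np.unique(truth.labels) if v != truth.nodata]
    missing = [v for v in present if v not in sig_by_id]
    if missing:
        raise ValueError(f"no spectral signature for label(s) {missing}")
    nb = len(cfg.bands)
    max_id = max(sig_by_id) if sig_by_id else 0
    mean_lut = np.zeros((max_id + 1, nb))
    sd_lut = np.zeros((max_id + 1, nb))
    for cid, s in sig_by_id.items():
        mean_lut[cid] = s.means()[season]
        sd_lut[cid] = s.sds()
    rng = np.random.default_rng(seed)
    out = np.empty((nb, *truth.grid.shape))
    valid = truth.valid_mask
    safe_labels = np.where(valid, truth.labels, 0)
    for b in range(nb):
        noise = rng.standard_normal(truth.grid.shape) * sd_lut[safe_labels, b]
        img = np.clip(mean_lut[safe_labels, b] + noise, 0.0, 1.0)
        img[~valid] = 0.0
        out[b] = img
    return out


def render_cube(truth: HabitatMap, cfg: SceneConfig, seed: int) -> SpectralCube:
    """Render all seasons of a scene into a SpectralCube."""
    vals = np.stack([
        render_reflectance(truth, cfg, s, seed + 1000 * s)
        for s in range(len(cfg.season_tags))
    ])
    return SpectralCube(vals, list(cfg.bands), list(cfg.season_tags), truth.grid,
                        nodata_mask=~truth.valid_mask)


# ---------------------------------------------------------------------------
# stratified-random reference areas


def sample_reference_areas(truth: HabitatMap,
                           n_areas_per_class: Mapping[int, int | tuple[int, int]],
                           role_fractions: tuple[float, float] = (0.5, 0.5),
                           min_area: int = 2, max_area: int = 12,
                           seed: int = 0,
                           max_tries: int = 4000) -> ReferenceAreas:
    """Place homogeneous, non-overlapping rectangular reference areas.

    ``n_areas_per_class`` maps class_id to either a total count (split into
    roles by ``role_fractions``, training count rounded) or an explicit
    ``(n_training, n_validation)`` pair. Every polygon covers only pixels of
    its own class; placement is stratified-random rejection sampling, seeded
    and deterministic. When a class is too fragmented for the requested
    sizes the sampler falls back to single-pixel rectangles before giving up.
    """
    if min_area < 1 or max_area < min_area:
        raise ValueError("need 1 <= min_area <= max_area")
    rng = np.random.default_rng(seed)
    grid = truth.grid
    occupied = np.zeros(grid.shape, dtype=bool)
    polygons: list[ReferencePolygon] = []
    pid = 0
    for cid in sorted(n_areas_per_class):
        req = n_areas_per_class[cid]
        if isinstance(req, tuple):
            n_train, n_valid = int(req[0]), int(req[1])
        else:
            n_train = int(round(int(req) * role_fractions[0]
                                / (role_fractions[0] + role_fractions[1])))
            n_valid = int(req) - n_train
        total = n_train + n_valid
        if total == 0:
            continue
        class_mask = truth.labels == cid
        if not class_mask.any():
            raise ValueError(f"class {cid} has no pixels in the truth map")
        roles = ["training"] * n_train + ["validation"] * n_valid
        rng.shuffle(roles)
        for role in roles:
            rect = _place_rectangle(class_mask, occupied, rng, min_area,
                                    max_area, max_tries)
            if rect is None:
                raise RuntimeError(
                    f"could not place {total} homogeneous non-overlapping "
                    f"areas for class {cid} after {max_tries} tries")
            r0, c0, h, w = rect
            occupied[r0:r0 + h, c0:c0 + w] = True
            x0, y0 = grid.origin
            ps = grid.pixel_size
            geom = box(x0 + c0 * ps, y0 - (r0 + h) * ps,
                       x0 + (c0 + w) * ps, y0 - r0 * ps)
            polygons.append(ReferencePolygon(
                geometry=geom, class_id=cid, role=role, polygon_id=pid,
                class_name=truth.legend.get(cid, "")))
            pid += 1
    return ReferenceAreas(polygons)


def _place_rectangle(class_mask, occupied, rng, min_area, max_area, max_tries):
    rows, cols = class_mask.shape
    free = class_mask & ~occupied
    for attempt in range(max_tries):
        # late attempts shrink to single pixels for fragmented classes
        hi = max_area if attempt < max_tries // 2 else min(max_area, 2)
        lo = min_area if attempt < max_tries // 2 else 1
        w = int(rng.integers(1, int(np.sqrt(hi)) + 1))
        h_lo = max(1, -(-lo // w))
        h_hi = max(h_lo, hi // w)
        h = int(rng.integers(h_lo, h_hi + 1))
        if h * w < lo or h * w > hi:
            continue
        r0 = int(rng.integers(0, max(1, rows - h + 1)))
        c0 = int(rng.integers(0, max(1, cols - w + 1)))
        window = free[r0:r0 + h, c0:c0 + w]
        if window.shape == (h, w) and window.all():
            return r0, c0, h, w
    return None


# ---------------------------------------------------------------------------
# ready-made scenes

# Class-share targets shaped on the study-site marginals: date 1 has no
# burned areas; date 2 trades grassland/salt marsh for forest, reed bed and
# burn scars.
DATE1_PROPORTIONS = {1: 0.08, 2: 0.0, 3: 0.06, 4: 0.15,
                     5: 0.03, 6: 0.27, 7: 0.25, 8: 0.16}
DATE2_PROPORTIONS = {1: 0.06, 2: 0.03, 3: 0.06, 4: 0.20,
                     5: 0.03, 6: 0.31, 7: 0.18, 8: 0.13}


def build_scene(cfg: SceneConfig, *, n_areas_per_class=None,
                role_fractions=(0.5, 0.5), min_area=2, max_area=12,
                date: str = "", fields: np.ndarray | None = None) -> LabeledScene:
    """Generate truth, reflectance cube and reference areas for one date."""
    truth = generate_label_map(cfg, fields=fields)
    cube = render_cube(truth, cfg, seed=cfg.seed + 77)
    if n_areas_per_class is None:
        n_areas_per_class = {cid: 30 for cid, p in cfg.proportions().items()
                             if p > 0}
    reference = sample_reference_areas(
        truth, n_areas_per_class, role_fractions, min_area, max_area,
        seed=cfg.seed + 131)
    return LabeledScene(truth, cube, reference, date)


def two_date_scenario(seed: int, rows: int = 120, cols: int = 120,
                      noise_sd: float = 0.02, patch_scale: float = 6.0,
                      n_areas_per_class: int | Mapping | None = None,
                      min_area: int = 2, max_area: int = 9,
                      field_persistence: float = 0.9,
                      proportions_date1: Mapping[int, float] | None = None,
                      proportions_date2: Mapping[int, float] | None = None,
                      ) -> dict[str, LabeledScene]:
    """Two correlated acquisition dates over one evolving landscape.

    The second date reuses the first date's random fields with weight
    ``field_persistence`` (plus fresh innovation), so most of the landscape
    persists and change is concentrated along patch edges — the structure a
    real two-date change analysis sees.
    """
    sigs = default_signatures(noise_sd)
    p1 = dict(DATE1_PROPORTIONS if proportions_date1 is None else proportions_date1)
    p2 = dict(DATE2_PROPORTIONS if proportions_date2 is None else proportions_date2)
    base = dict(rows=rows, cols=cols, classes=sigs, patch_scale=patch_scale)
    cfg1 = SceneConfig(**base, target_proportions=p1, seed=seed)
    cfg2 = SceneConfig(**base, target_proportions=p2, seed=seed + 500_009)
    gen = np.random.default_rng(seed)
    n = len(sigs)
    fields1 = _smooth_fields((rows, cols), n, patch_scale, gen)
    innov = _smooth_fields((rows, cols), n, patch_scale, gen)
    a = field_persistence
    fields2 = a * fields1 + np.sqrt(1 - a * a) * innov

    def _counts(cfg):
        if n_areas_per_class is None:
            return None
        if isinstance(n_areas_per_class, int):
            return {cid: n_areas_per_class
                    for cid, p in cfg.proportions().items() if p > 0}
        return dict(n_areas_per_class)

    scene1 = build_scene(cfg1, n_areas_per_class=_counts(cfg1),
                         min_area=min_area, max_area=max_area, date="date1",
                         fields=fields1)
    scene2 = build_scene(cfg2, n_areas_per_class=_counts(cfg2),
                         min_area=min_area, max_area=max_area, date="date2",
                         fields=fields2)
    return {"date1": scene1, "date2": scene2}
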