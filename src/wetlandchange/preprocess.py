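"""Radiometric calibration, spectral indices and feature-stack assembly.

The classifier input for each year is one feature vector per pixel holding
every reflective band of every seasonal acquisition plus NDVI and NDWI per
season: with 2 seasons x 6 bands that is 2·(6+2) = 16 features. Seasonal
stacking captures vegetation phenology (e.g. reed beds green up late),
which is what separates spectrally similar wetland classes.

Indices follow the standard normalized-difference forms:
``NDVI = (nir - red)/(nir + red)`` and ``NDWI = (green - nir)/(green + nir)``
(the green/NIR open-water variant). Pixels with a zero denominator become
nodata rather than a fake 0 — an undefined ratio must not masquerade as a
valid index value.
"""

from __future__ import annotations

import numpy as np

from .raster import FeatureStack, SpectralCube


def dn_to_radiance(dn: np.ndarray, gain: float | np.ndarray,
                   offset: float | np.ndarray,
                   nodata_mask: np.ndarray | None = None) -> np.ndarray:
    """Linear sensor calibration: ``radiance = gain * DN + offset``.

    ``gain``/``offset`` may be scalars or per-band arrays broadcastable
    against ``dn``. Nodata pixels (where given) propagate as NaN.
    """
    dn = np.asarray(dn, dtype=np.float64)
    gain = np.asarray(gain, dtype=np.float64)
    offset = np.asarray(offset, dtype=np.float64)
    if not (np.isfinite(gain).all() and np.isfinite(offset).all()):
        raise ValueError("gain and offset must be finite")
    out = gain * dn + offset
    if nodata_mask is not None:
        out = np.where(nodata_mask, np.nan, out)
    return out


def _normalized_difference(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(a - b)/(a + b) with a mask of zero-denominator pixels."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"grid mismatch: {a.shape} vs {b.shape}")
    denom = a + b
    bad = denom == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        idx = np.where(bad, np.nan, (a - b) / np.where(bad, 1.0, denom))
    return idx, bad


def ndvi(red: np.ndarray, nir: np.ndarray) -> np.ndarray:
    """Normalized Difference Vegetation Index, (nir-red)/(nir+red).

    Zero-denominator pixels are NaN (treated as nodata downstream). Bounded
    in [-1, 1] for non-negative inputs.
    """
    idx, _ = _normalized_difference(np.asarray(nir), np.asarray(red))
    return idx


def ndwi(green: np.ndarray, nir: np.ndarray) -> np.ndarray:
    """Normalized Difference Water Index, (green-nir)/(green+nir)."""
    idx, _ = _normalized_difference(np.asarray(green), np.asarray(nir))
    return idx


def build_feature_stack(cube: SpectralCube) -> FeatureStack:
    """All seasonal bands plus per-season NDVI and NDWI, as one stack.

    Feature order: for each season in cube order, the bands in cube order,
    then ``<season>_ndvi`` and ``<season>_ndwi``. A pixel that is nodata in
    any layer (including undefined indices) is masked in the whole stack.
    """
    for role in ("green", "red", "nir"):
        if role not in cube.band_roles:
            raise ValueError(
                f"cube lacks band role {role!r} required for index computation")
    layers: list[np.ndarray] = []
    names: list[str] = []
    mask = cube.nodata_mask.copy()
    for s, tag in enumerate(cube.season_tags):
        for b, role in enumerate(cube.band_roles):
            layers.append(cube.values[s, b])
            names.append(f"{tag}_{role}")
        v = ndvi(cube.band(s, "red"), cube.band(s, "nir"))
        w = ndwi(cube.band(s, "green"), cube.band(s, "nir"))
        layers.append(v)
        names.append(f"{tag}_ndvi")
        layers.append(w)
        names.append(f"{tag}_ndwi")
        mask |= np.isnan(v) | np.isnan(w)
    feats = np.stack(layers)
    mask |= ~np.isfinite(feats).all(axis=0)
    return FeatureStack(feats, names, cube.grid, mask)
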