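"""Vegetation indices and the shared thresholding / morphology machinery.

Both detectors are built from the same primitives: a vegetation index image,
an automatic OTSU threshold, morphological mask refinement, and connected
component extraction.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure, morphology

from .errors import ConfigurationError, ContractError, DegenerateInputError

INDEX_NAMES = ("OSAVI", "GEMI", "NDVI", "NDVI_RE")

#: Number of uniform histogram bins used by the OTSU threshold search.
OTSU_BINS = 256


@dataclass
class IndexImage:
    values: np.ndarray
    index_name: str
    valid_mask: np.ndarray


@dataclass
class BinaryMask:
    values: np.ndarray
    provenance: list[str] = field(default_factory=list)


@dataclass
class PixelCluster:
    """One connected component: pixel coordinates, area and centroid."""

    pixels: np.ndarray  # (n, 2) array of (row, col)
    area: int
    centroid: tuple[float, float]  # (row, col)


def _safe_ratio(num: np.ndarray, den: np.ndarray, valid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ok = valid & (den != 0)
    out = np.zeros_like(num, dtype=np.float64)
    np.divide(num, den, out=out, where=ok)
    return out, ok


def compute_index(bands: dict[str, np.ndarray], index_name: str,
                  valid_mask: np.ndarray | None = None) -> IndexImage:
    """Compute a vegetation index from a (possibly masked) band stack.

    Supported indices:

    * ``OSAVI`` = 1.16 * (NIR - Red) / (NIR + Red + 0.16)
    * ``NDVI`` = (NIR - Red) / (NIR + Red)
    * ``NDVI_RE`` = (RE - Red) / (RE + Red)
    * ``GEMI`` = eta * (1 - 0.25 * eta) - (Red - 0.125) / (1 - Red), with
      eta = (2 * (NIR^2 - Red^2) + 1.5 * NIR + 0.5 * Red) / (NIR + Red + 0.5)

    Pixels with a zero denominator are marked invalid rather than raising.
    """
    if index_name not in INDEX_NAMES:
        raise ConfigurationError(f"unknown index {index_name!r}; expected one of {INDEX_NAMES}")
    red = np.asarray(bands["red"], dtype=np.float64)
    if valid_mask is None:
        valid_mask = np.ones(red.shape, dtype=bool)
    valid = valid_mask & np.isfinite(red)

    if index_name == "OSAVI":
        nir = np.asarray(bands["nir"], dtype=np.float64)
        valid &= np.isfinite(nir)
        values, ok = _safe_ratio(1.16 * (nir - red), nir + red + 0.16, valid)
    elif index_name == "NDVI":
        nir = np.asarray(bands["nir"], dtype=np.float64)
        valid &= np.isfinite(nir)
        values, ok = _safe_ratio(nir - red, nir + red, valid)
    elif index_name == "NDVI_RE":
        re = np.asarray(bands["red_edge"], dtype=np.float64)
        valid &= np.isfinite(re)
        values, ok = _safe_ratio(re - red, re + red, valid)
    else:  # GEMI
        nir = np.asarray(bands["nir"], dtype=np.float64)
        valid &= np.isfinite(nir)
        eta, ok = _safe_ratio(2.0 * (nir**2 - red**2) + 1.5 * nir + 0.5 * red,
                              nir + red + 0.5, valid)
        soil_term, ok2 = _safe_ratio(red - 0.125, 1.0 - red, valid)
        ok &= ok2
        values = eta * (1.0 - 0.25 * eta) - soil_term
    values = np.where(ok, values, 0.0)
    return IndexImage(values=values, index_name=index_name, valid_mask=ok)


def otsu_threshold(index: IndexImage | np.ndarray, valid_mask: np.ndarray | None = None,
                   bins: int = OTSU_BINS) -> float:
    """OTSU's automatic threshold over the valid pixels of an index image.

    Valid values are quantized into ``bins`` uniform bins over the observed
    [min, max] range; the returned threshold is the interior bin edge that
    minimises the within-class variance.  Ties resolve to the lowest edge, so
    the result is deterministic for a fixed input.
    """
    if isinstance(index, IndexImage):
        values = index.values[index.valid_mask]
    else:
        arr = np.asarray(index, dtype=np.float64)
        values = arr[valid_mask] if valid_mask is not None else arr.ravel()
    values = values[np.isfinite(values)]
    if values.size < 2 or np.unique(values).size < 2:
        raise DegenerateInputError("need at least two distinct valid values for OTSU")
    lo, hi = float(values.min()), float(values.max())
    counts, edges = np.histogram(values, bins=bins, range=(lo, hi))
    counts = counts.astype(np.float64)
    centers = 0.5 * (edges[:-1] + edges[1:])

    # Cumulative statistics for every split "class0 = bins < j".
    w0 = np.cumsum(counts)[:-1]
    w1 = counts.sum() - w0
    s0 = np.cumsum(counts * centers)[:-1]
    s1 = (counts * centers).sum() - s0
    sq = counts * centers**2
    q0 = np.cumsum(sq)[:-1]
    q1 = sq.sum() - q0

    with np.errstate(invalid="ignore", divide="ignore"):
        var0 = q0 / w0 - (s0 / w0) ** 2
        var1 = q1 / w1 - (s1 / w1) ** 2
    var0 = np.where(w0 > 0, var0, 0.0)
    var1 = np.where(w1 > 0, var1, 0.0)
    within = w0 * var0 + w1 * var1
    j = int(np.argmin(within))  # argmin takes the first (lowest) minimiser
    return float(edges[j + 1])


def _footprint(size: int = 3) -> np.ndarray:
    # 3x3 elliptical element == disk of radius (size - 1) // 2
    return morphology.disk((size - 1) // 2)


def refine_mask(mask: BinaryMask, open_then_close: bool = True, element_size: int = 3,
                iterations: int = 1) -> BinaryMask:
    """Morphological opening then closing to drop noise and fill holes."""
    values = mask.values.astype(bool)
    fp = _footprint(element_size)
    steps = list(mask.provenance)
    if open_then_close:
        for _ in range(iterations):
            values = morphology.opening(values, fp)
        steps.append(f"open({element_size})")
        for _ in range(iterations):
            values = morphology.closing(values, fp)
        steps.append(f"close({element_size})")
    else:
        for _ in range(iterations):
            values = morphology.closing(values, fp)
        steps.append(f"close({element_size})")
        for _ in range(iterations):
            values = morphology.opening(values, fp)
        steps.append(f"open({element_size})")
    return BinaryMask(values=values, provenance=steps)


def connected_components(mask: BinaryMask, min_area_px: int) -> list[PixelCluster]:
    """8-connected components with at least ``min_area_px`` pixels."""
    if min_area_px < 1:
        raise ContractError(f"min_area_px must be >= 1, got {min_area_px}")
    labels = measure.label(mask.values, connectivity=2)
    clusters: list[PixelCluster] = []
    for region in measure.regionprops(labels):
        if region.area < min_area_px:
            continue
        clusters.append(
            PixelCluster(
                pixels=region.coords.copy(),
                area=int(region.area),
                centroid=(float(region.centroid[0]), float(region.centroid[1])),
            )
        )
    return clusters
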