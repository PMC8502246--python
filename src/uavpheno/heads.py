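"""Head counting with circularity-based declustering of overlapping heads.

Head pixels are isolated in two steps: an OTSU threshold on GEMI removes the
soil background, and a fixed threshold on NDVI_RE (red-edge vs red) removes
green leaves, leaving head clusters.  Each cluster's contour circularity
(4*pi*A/P^2) is scored; Gaussian kernel density minima over the per-plot
circularity sample split clusters into single, double and triple heads, and
the plot total is n_single + 2*n_double + 3*n_triple.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure

from .errors import ContractError, DegenerateInputError
from .geometry import PlotImage
from .indices import BinaryMask, compute_index, connected_components, otsu_threshold, refine_mask

#: NDVI_RE below this value marks head (non-leaf) canopy pixels.
NDVI_RE_THRESHOLD = 0.3

#: Density grid for the circularity KDE.
KDE_GRID_POINTS = 512
KDE_GRID_RANGE = (0.0, 1.3)
KDE_BANDWIDTH_FLOOR = 0.015

#: Shrink factor on the Silverman rule-of-thumb bandwidth.  Plain Silverman
#: targets unimodal densities and oversmooths the (tri-modal) circularity
#: sample enough to erase the double/triple valley; half-Silverman keeps it.
KDE_BANDWIDTH_FACTOR = 0.5

#: Plots with fewer clusters than this skip the KDE (all classed single).
MIN_CLUSTERS_FOR_KDE = 4


@dataclass
class HeadDetectConfig:
    ndvi_re_threshold: float = NDVI_RE_THRESHOLD
    min_area_px: int = 10
    element_size: int = 3
    bandwidth_floor: float = KDE_BANDWIDTH_FLOOR
    min_class_separation: float = 0.15


@dataclass
class HeadCluster:
    contour: np.ndarray  # (n, 2) sub-pixel (row, col) ring
    area_px: float
    perimeter_px: float
    circularity: float
    multiplicity: int | None = None

    def __post_init__(self) -> None:
        if self.area_px <= 0 or self.perimeter_px <= 0:
            raise ContractError("cluster area and perimeter must be positive")


@dataclass
class HeadCount:
    plot_id: str
    capture_id: str
    n_single: int
    n_double: int
    n_triple: int
    thresholds: list[float]
    qc_flags: list[str] = field(default_factory=list)

    @property
    def n_heads(self) -> int:
        return self.n_single + 2 * self.n_double + 3 * self.n_triple


def head_mask(plot_image: PlotImage, ndvi_re_threshold: float = NDVI_RE_THRESHOLD,
              element_size: int = 3, min_class_separation: float = 0.15,
              ) -> tuple[BinaryMask, list[str]]:
    """Two-step background masking: GEMI OTSU (soil), then NDVI_RE (leaves)."""
    qc: list[str] = []
    gemi = compute_index(plot_image.bands, "GEMI", valid_mask=plot_image.valid_mask)
    try:
        t_soil = otsu_threshold(gemi)
    except DegenerateInputError:
        return (BinaryMask(values=np.zeros(plot_image.valid_mask.shape, dtype=bool),
                           provenance=["degenerate_gemi"]), ["degenerate_gemi_histogram"])
    canopy = gemi.valid_mask & (gemi.values > t_soil)
    if canopy.any() and (gemi.valid_mask & ~canopy).any():
        sep = float(gemi.values[canopy].mean() - gemi.values[gemi.valid_mask & ~canopy].mean())
        if sep < min_class_separation:
            return (BinaryMask(values=np.zeros_like(canopy), provenance=["no_canopy"]),
                    ["no_canopy_contrast"])
    ndvi_re = compute_index(plot_image.bands, "NDVI_RE", valid_mask=plot_image.valid_mask)
    heads = canopy & ndvi_re.valid_mask & (ndvi_re.values < ndvi_re_threshold)
    mask = refine_mask(
        BinaryMask(values=heads, provenance=[f"gemi>{t_soil:.4f}", f"ndvi_re<{ndvi_re_threshold}"]),
        element_size=element_size)
    return mask, qc


def _outer_contour(component: np.ndarray) -> np.ndarray:
    padded = np.pad(component.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        raise ContractError("component has no contour")
    ring = max(contours, key=lambda c: len(c))
    return ring - 1.0  # undo padding offset


def _ring_area_perimeter(ring: np.ndarray) -> tuple[float, float]:
    y, x = ring[:, 0], ring[:, 1]
    area = 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))
    perimeter = float(np.hypot(np.diff(x, append=x[0]), np.diff(y, append=y[0])).sum())
    return area, perimeter


def circularity(area: float, perimeter: float) -> float:
    """4*pi*A/P^2; 1 for a circle, pi/4 for a square, lower for merged blobs."""
    return 4.0 * np.pi * area / perimeter**2


def cluster_shapes(mask: BinaryMask, min_area_px: int = 10) -> list[HeadCluster]:
    """One contour-scored cluster per retained connected component."""
    clusters: list[HeadCluster] = []
    for comp in connected_components(mask, min_area_px):
        component = np.zeros(mask.values.shape, dtype=bool)
        component[comp.pixels[:, 0], comp.pixels[:, 1]] = True
        rmin, cmin = comp.pixels.min(axis=0)
        rmax, cmax = comp.pixels.max(axis=0)
        local = component[rmin:rmax + 1, cmin:cmax + 1]
        ring = _outer_contour(local)
        ring[:, 0] += rmin
        ring[:, 1] += cmin
        area, perimeter = _ring_area_perimeter(ring)
        if area <= 0 or perimeter <= 0:
            continue
        clusters.append(HeadCluster(contour=ring, area_px=area, perimeter_px=perimeter,
                                    circularity=circularity(area, perimeter)))
    return clusters


def silverman_bandwidth(values: np.ndarray, floor: float = KDE_BANDWIDTH_FLOOR,
                        factor: float = KDE_BANDWIDTH_FACTOR) -> float:
    """Scaled Silverman rule-of-thumb bandwidth with a hard floor.

    0.9 * min(sd, IQR/1.34) * n^(-1/5), shrunk by ``factor`` (see
    :data:`KDE_BANDWIDTH_FACTOR`) and clipped from below at ``floor``.
    """
    values = np.asarray(values, dtype=np.float64)
    n = values.size
    if n < 2:
        return floor
    sd = float(values.std(ddof=1))
    q75, q25 = np.percentile(values, [75, 25])
    iqr = float(q75 - q25)
    spread = min(s for s in (sd, iqr / 1.34) if s > 0) if (sd > 0 or iqr > 0) else 0.0
    if spread == 0:
        return floor
    return max(factor * 0.9 * spread * n ** (-0.2), floor)


def kde_density(values: np.ndarray, grid: np.ndarray, bandwidth: float) -> np.ndarray:
    """Mean of Gaussian kernels centred on each value, evaluated on ``grid``."""
    z = (grid[:, None] - values[None, :]) / bandwidth
    return np.exp(-0.5 * z**2).sum(axis=1) / (values.size * bandwidth * np.sqrt(2 * np.pi))


def kde_circularity_thresholds(circularities: list[float] | np.ndarray,
                               bandwidth: float | None = None,
                               bandwidth_floor: float = KDE_BANDWIDTH_FLOOR,
                               ) -> list[float]:
    """Circularity class boundaries from the local minima of a Gaussian KDE.

    At most the two lowest-density interior minima are kept (so at most three
    groups); an empty list means the density is unimodal and every cluster is
    a single head.  Returned thresholds are sorted descending.
    """
    values = np.asarray(circularities, dtype=np.float64)
    if values.size == 0:
        raise ContractError("need at least one circularity value")
    if values.size == 1 or np.ptp(values) == 0:
        return []
    if bandwidth is None:
        bandwidth = silverman_bandwidth(values, floor=bandwidth_floor)
    grid = np.linspace(*KDE_GRID_RANGE, KDE_GRID_POINTS)
    density = kde_density(values, grid, bandwidth)
    interior = (density[1:-1] < density[:-2]) & (density[1:-1] <= density[2:])
    idx = np.nonzero(interior)[0] + 1
    # Only minima strictly between data extremes can separate groups.
    idx = idx[(grid[idx] > values.min()) & (grid[idx] < values.max())]
    if idx.size == 0:
        return []
    order = idx[np.argsort(density[idx], kind="stable")][:2]
    return sorted((float(grid[i]) for i in order), reverse=True)


def classify_and_count(clusters: list[HeadCluster], thresholds: list[float],
                       plot_id: str = "", capture_id: str = "",
                       qc_flags: list[str] | None = None) -> HeadCount:
    """Assign single/double/triple classes by circularity interval.

    With thresholds t1 >= t2: circularity >= t1 is a single head, [t2, t1) a
    double, below t2 a triple.  One threshold gives single/double only; none
    means every cluster is a single head.  Multiplicity is capped at three.
    """
    if sorted(thresholds, reverse=True) != list(thresholds):
        raise ContractError("thresholds must be sorted descending")
    if len(thresholds) > 2:
        raise ContractError("at most two thresholds are supported")
    n = [0, 0, 0]
    for cluster in clusters:
        group = sum(cluster.circularity < t for t in thresholds)  # 0, 1 or 2
        cluster.multiplicity = group + 1
        n[group] += 1
    return HeadCount(plot_id=plot_id, capture_id=capture_id,
                     n_single=n[0], n_double=n[1], n_triple=n[2],
                     thresholds=list(thresholds), qc_flags=list(qc_flags or []))


def count_heads(plot_image: PlotImage, config: HeadDetectConfig | None = None) -> HeadCount:
    """Full head-count pipeline for one extracted plot image."""
    config = config or HeadDetectConfig()
    mask, qc = head_mask(plot_image, ndvi_re_threshold=config.ndvi_re_threshold,
                         element_size=config.element_size,
                         min_class_separation=config.min_class_separation)
    clusters = cluster_shapes(mask, min_area_px=config.min_area_px)
    if len(clusters) < MIN_CLUSTERS_FOR_KDE:
        thresholds: list[float] = []
        if clusters:
            qc = qc + ["too_few_clusters_for_kde"]
    else:
        thresholds = kde_circularity_thresholds(
            [c.circularity for c in clusters], bandwidth_floor=config.bandwidth_floor)
    return classify_and_count(clusters, thresholds, plot_id=plot_image.plot_id,
                              capture_id=plot_image.capture_id, qc_flags=qc)
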