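"""Plant stand counting from a nadir row/plot image.

Green pixels are separated from soil with an OTSU threshold on OSAVI, the
binary image is cleaned with morphological opening and closing, and the
surviving 8-connected pixel clusters are counted as plants.  The threshold
is recomputed per image, so lighting differences between captures need no
manual tuning.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError
from .geometry import PlotImage
from .indices import BinaryMask, compute_index, connected_components, otsu_threshold, refine_mask


@dataclass
class PlantCountConfig:
    min_area_px: int = 4
    element_size: int = 3
    # Minimum separation between class means (index units) for the OTSU split
    # to count as vegetation-vs-soil rather than noise within bare soil.
    min_class_separation: float = 0.15


@dataclass
class PlantCount:
    plot_id: str
    capture_id: str
    n_plants: int
    component_centroids: list[tuple[float, float]]
    qc_flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_plants != len(self.component_centroids):
            raise ValueError("n_plants must equal the number of centroids")


def count_plants(plot_image: PlotImage, config: PlantCountConfig | None = None) -> PlantCount:
    """Count plants in one extracted row/plot image.

    A degenerate histogram (bare soil) yields a zero count with a QC flag
    rather than an exception.
    """
    config = config or PlantCountConfig()
    qc: list[str] = []
    index = compute_index(plot_image.bands, "OSAVI", valid_mask=plot_image.valid_mask)
    try:
        threshold = otsu_threshold(index)
    except DegenerateInputError:
        return PlantCount(plot_image.plot_id, plot_image.capture_id, 0, [],
                          qc_flags=["degenerate_histogram"])
    binary = index.valid_mask & (index.values > threshold)
    if binary.any() and (~binary & index.valid_mask).any():
        sep = float(index.values[binary].mean() - index.values[index.valid_mask & ~binary].mean())
        if sep < config.min_class_separation:
            return PlantCount(plot_image.plot_id, plot_image.capture_id, 0, [],
                              qc_flags=["no_vegetation_contrast"])
    mask = refine_mask(BinaryMask(values=binary, provenance=[f"osavi>{threshold:.4f}"]),
                       element_size=config.element_size)
    clusters = connected_components(mask, config.min_area_px)
    n_raw = len(connected_components(mask, 1))
    if n_raw > len(clusters):
        qc.append("tiny_components_removed")
    centroids = [(c.centroid[1], c.centroid[0]) for c in clusters]  # (u, v)
    return PlantCount(plot_image.plot_id, plot_image.capture_id, len(clusters),
                      centroids, qc_flags=qc)
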