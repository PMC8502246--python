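"""Reverse calculation: world plot/row boundaries -> per-capture pixel polygons.

World-space boundaries are lifted to 3-D with a digital surface model, then
projected into each capture through its 3x4 projection matrix.  For every
plot the capture whose projected boundary sits closest to the image centre
(the nadir view) is retained and the plot sub-image extracted.

Pixel convention: u = column, v = row, 0-based, origin at the top-left pixel
centre.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import Polygon

from .errors import (
    BehindCameraError,
    ContractError,
    GeometryError,
    OutOfExtentError,
    PointAtInfinityError,
)
from .radiometry import BANDS, ReflectanceStack


@dataclass
class CameraSolution:
    """Calibrated exterior solution for one capture."""

    capture_id: str
    P: np.ndarray  # 3x4
    position: tuple[float, float, float]
    image_size: tuple[int, int]  # (rows, cols)

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=np.float64)
        if self.P.shape != (3, 4):
            raise ContractError(f"P must be 3x4, got {self.P.shape}")
        if np.linalg.matrix_rank(self.P) != 3:
            raise ContractError(f"P matrix for {self.capture_id} is rank deficient")


@dataclass
class DSMGrid:
    """Surface elevations on a north-up grid with a GDAL-style geotransform.

    ``geotransform`` = (x0, dx, 0, y0, 0, dy) maps (col, row) to world
    (X, Y) of the cell's upper-left corner; dy is negative for north-up.
    """

    elevations: np.ndarray
    geotransform: tuple[float, float, float, float, float, float]
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        gt = self.geotransform
        if gt[2] != 0 or gt[4] != 0:
            raise GeometryError("rotated geotransforms are not supported")
        if gt[1] == 0 or gt[5] == 0:
            raise GeometryError("geotransform is not invertible")

    def world_to_cell(self, x: float, y: float) -> tuple[int, int]:
        x0, dx, _, y0, _, dy = self.geotransform
        col = int(np.floor((x - x0) / dx))
        row = int(np.floor((y - y0) / dy))
        return row, col

    def sample(self, x: float, y: float) -> float:
        """Nearest-cell elevation at world (x, y)."""
        row, col = self.world_to_cell(x, y)
        rows, cols = self.elevations.shape
        if not (0 <= row < rows and 0 <= col < cols):
            raise OutOfExtentError(f"vertex ({x}, {y}) outside DSM extent")
        z = float(self.elevations[row, col])
        if z == self.nodata or not np.isfinite(z):
            raise OutOfExtentError(f"vertex ({x}, {y}) falls on a DSM nodata cell")
        return z


@dataclass
class WorldBoundary:
    """A closed world-space ring delimiting a plot or a buffered row."""

    plot_id: str
    kind: str  # "row" | "plot"
    vertices: list[tuple[float, float]]

    def __post_init__(self) -> None:
        if self.kind not in ("row", "plot"):
            raise ContractError(f"kind must be 'row' or 'plot', got {self.kind!r}")
        if len(self.vertices) < 3:
            raise GeometryError(f"boundary {self.plot_id} needs >= 3 ring vertices")
        ring = Polygon(self.vertices)
        if not ring.is_valid or ring.area <= 0:
            raise GeometryError(f"boundary {self.plot_id} ring is self-intersecting or degenerate")

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)


@dataclass
class PlotView:
    """One boundary projected into one capture."""

    plot_id: str
    capture_id: str
    pixel_polygon: list[tuple[float, float]]  # ordered (u, v)
    fully_contained: bool
    center_distance: float
    kind: str = "plot"


def buffer_row(line: list[tuple[float, float]], half_width_m: float = 0.10,
               plot_id: str = "", ) -> WorldBoundary:
    """Buffer a 2-point row line into its 4-vertex rectangular boundary."""
    if len(line) != 2:
        raise GeometryError("row line must have exactly 2 points")
    (x0, y0), (x1, y1) = line
    dx, dy = x1 - x0, y1 - y0
    length = float(np.hypot(dx, dy))
    if length == 0:
        raise GeometryError(f"row line for {plot_id!r} has zero length")
    # Unit normal (left of travel direction), scaled to the half width.
    nx, ny = -dy / length * half_width_m, dx / length * half_width_m
    ring = [(x0 - nx, y0 - ny), (x1 - nx, y1 - ny), (x1 + nx, y1 + ny), (x0 + nx, y0 + ny)]
    return WorldBoundary(plot_id=plot_id, kind="row", vertices=ring)


def lift_polygon(boundary: WorldBoundary, dsm: DSMGrid) -> list[tuple[float, float, float]]:
    """Attach a DSM elevation to every boundary vertex (nearest cell)."""
    return [(x, y, dsm.sample(x, y)) for x, y in boundary.vertices]


def project_point(P: np.ndarray, world: tuple[float, float, float]) -> tuple[float, float]:
    """Project homogeneous world (X, Y, Z, 1) to pixel (u, v) = (x/z, y/z)."""
    x, y, z = np.asarray(P, dtype=np.float64) @ np.array([*world, 1.0])
    if z == 0:
        raise PointAtInfinityError(f"point {world} projects to infinity")
    if z < 0:
        raise BehindCameraError(f"point {world} lies behind the camera")
    return float(x / z), float(y / z)


def project_boundary(boundary: WorldBoundary, dsm: DSMGrid, camera: CameraSolution) -> PlotView:
    """Lift a boundary through the DSM and project it into one capture."""
    world3 = lift_polygon(boundary, dsm)
    try:
        pixel = [project_point(camera.P, w) for w in world3]
    except (PointAtInfinityError, BehindCameraError):
        return PlotView(boundary.plot_id, camera.capture_id, [], False, float("inf"),
                        kind=boundary.kind)
    rows, cols = camera.image_size
    contained = all(0 <= u < cols and 0 <= v < rows for u, v in pixel)
    centroid = Polygon(pixel).centroid
    cu, cv = (cols - 1) / 2.0, (rows - 1) / 2.0
    dist = float(np.hypot(centroid.x - cu, centroid.y - cv))
    return PlotView(boundary.plot_id, camera.capture_id, pixel, contained, dist,
                    kind=boundary.kind)


def select_nadir(views: list[PlotView]) -> PlotView | None:
    """The fully contained view nearest the image centre, or None.

    Ties break on the lexicographically smallest capture id.
    """
    if not views:
        return None
    plot_ids = {v.plot_id for v in views}
    if len(plot_ids) > 1:
        raise ContractError(f"select_nadir received mixed plot_ids {plot_ids}")
    contained = [v for v in views if v.fully_contained]
    if not contained:
        return None
    return min(contained, key=lambda v: (v.center_distance, v.capture_id))


@dataclass
class PlotImage:
    """Bounding-box crop of an aligned stack masked to a pixel polygon."""

    plot_id: str
    capture_id: str
    bands: dict[str, np.ndarray]
    valid_mask: np.ndarray
    origin: tuple[int, int]  # (row, col) of crop origin in the full image
    kind: str = "plot"


def extract_plot_image(stack: ReflectanceStack, view: PlotView) -> PlotImage:
    """Crop all bands to the view polygon; pixels outside are invalid."""
    if not stack.aligned:
        raise ContractError("stack must be band-aligned before plot extraction")
    if not view.fully_contained:
        raise ContractError(f"view {view.plot_id}/{view.capture_id} is not fully contained")
    poly = Polygon(view.pixel_polygon)
    if poly.area <= 0:
        raise GeometryError(f"pixel polygon for {view.plot_id} has zero area")
    rows, cols = stack.shape
    us = [u for u, _ in view.pixel_polygon]
    vs = [v for _, v in view.pixel_polygon]
    c0 = max(int(np.floor(min(us))), 0)
    c1 = min(int(np.ceil(max(us))) + 1, cols)
    r0 = max(int(np.floor(min(vs))), 0)
    r1 = min(int(np.ceil(max(vs))) + 1, rows)
    if r1 <= r0 or c1 <= c0:
        raise GeometryError(f"empty extraction for {view.plot_id}")
    uu, vv = np.meshgrid(np.arange(c0, c1, dtype=float), np.arange(r0, r1, dtype=float))
    inside = shapely.contains_xy(poly, uu.ravel(), vv.ravel()).reshape(uu.shape)
    if not inside.any():
        raise GeometryError(f"no pixel centres inside polygon for {view.plot_id}")
    valid = inside
    if stack.valid_mask is not None:
        valid = valid & stack.valid_mask[r0:r1, c0:c1]
    bands = {b: stack.bands[b][r0:r1, c0:c1].copy() for b in BANDS}
    return PlotImage(plot_id=view.plot_id, capture_id=view.capture_id, bands=bands,
                     valid_mask=valid, origin=(r0, c0), kind=view.kind)
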