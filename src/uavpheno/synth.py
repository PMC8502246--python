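"""Synthetic flight generation with exact ground truth.

Renders a flat-terrain breeding trial (plot grid, row lines, plant and head
discs with class-specific reflectance spectra), synthesises per-capture raw
DN imagery by inverting the reflectance and radiance calibration models
(including a non-trivial vignette and per-band misregistration), and emits
the camera solutions, DSM, layout and reference-panel capture the pipeline
consumes — together with per-plot truth counts.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from skimage.draw import disk as draw_disk

from .errors import ConfigurationError, ContractError
from .geometry import CameraSolution, DSMGrid, WorldBoundary
from .indices import compute_index
from .radiometry import BANDS, CaptureMeta, radiance_to_dn

CLASSES = ("soil", "leaf", "red_head", "white_head", "green_head")

_CLASS_CODE = {name: i for i, name in enumerate(CLASSES)}


@dataclass
class ClassSpectra:
    """Per-class, per-band reflectance plus multiplicative noise level.

    The defaults are chosen so the detector thresholds separate the classes
    by construction: leaves sit above the red-edge/red threshold, red and
    white heads below it, and soil below vegetation in both OSAVI and GEMI.
    """

    reflectance: dict[str, dict[str, float]] = field(default_factory=lambda: {
        "soil": {"blue": 0.08, "green": 0.12, "red": 0.15, "red_edge": 0.17, "nir": 0.18},
        "leaf": {"blue": 0.04, "green": 0.08, "red": 0.05, "red_edge": 0.30, "nir": 0.50},
        "red_head": {"blue": 0.10, "green": 0.14, "red": 0.18, "red_edge": 0.21, "nir": 0.55},
        "white_head": {"blue": 0.28, "green": 0.30, "red": 0.30, "red_edge": 0.33, "nir": 0.90},
        "green_head": {"blue": 0.04, "green": 0.09, "red": 0.06, "red_edge": 0.28, "nir": 0.45},
    })
    noise_sd: float = 0.02

    def __post_init__(self) -> None:
        self.validate()

    def _index(self, cls: str, name: str) -> float:
        bands = {b: np.array([[v]]) for b, v in self.reflectance[cls].items()}
        return float(compute_index(bands, name).values[0, 0])

    def validate(self) -> None:
        for cls in CLASSES:
            if cls not in self.reflectance:
                raise ConfigurationError(f"missing spectra for class {cls}")
        if self._index("leaf", "NDVI_RE") <= 0.3:
            raise ConfigurationError("leaf NDVI_RE must exceed 0.3")
        for head in ("red_head", "white_head"):
            if self._index(head, "NDVI_RE") >= 0.3:
                raise ConfigurationError(f"{head} NDVI_RE must be below 0.3")
        for name in ("OSAVI", "GEMI"):
            soil = self._index("soil", name)
            for veg in ("leaf", "red_head", "white_head"):
                if self._index(veg, name) <= soil:
                    raise ConfigurationError(f"soil {name} must be below {veg}")

    def lut(self) -> np.ndarray:
        """(n_classes, n_bands) reflectance lookup table."""
        return np.array([[self.reflectance[c][b] for b in BANDS] for c in CLASSES])


@dataclass
class HeadsConfig:
    """Head-stage composition and geometry parameters (pixels at ground GSD)."""

    n_clusters_range: tuple[int, int] = (8, 36)
    double_frac_range: tuple[float, float] = (0.18, 0.30)
    triple_frac_range: tuple[float, float] = (0.12, 0.22)
    radius_px_range: tuple[float, float] = (5.5, 7.5)
    spacing_radii_range: tuple[float, float] = (1.1, 1.3)
    colours: tuple[str, ...] = ("red", "white")
    leaf_discs_per_row: int = 70


@dataclass
class RowLine:
    """A row centre line in world metres, stored unbuffered."""

    plot_id: str
    start: tuple[float, float]
    end: tuple[float, float]


@dataclass
class PlotTruth:
    plot_id: str
    n_plants: int = 0
    plants_per_row: tuple[int, ...] = ()
    n_single: int = 0
    n_double: int = 0
    n_triple: int = 0
    head_colour: str | None = None

    @property
    def n_heads(self) -> int:
        return self.n_single + 2 * self.n_double + 3 * self.n_triple


@dataclass
class SceneTruth:
    plots: list[PlotTruth]
    alignment_matrices: dict[str, np.ndarray]  # true per-band inverse maps
    reflectance_factors: dict[str, float]
    seed: int
    spectra: ClassSpectra
    flight_height_m: float
    gsd_m: float

    def plot(self, plot_id: str) -> PlotTruth:
        for p in self.plots:
            if p.plot_id == plot_id:
                return p
        raise KeyError(plot_id)


@dataclass
class Capture:
    capture_id: str
    dn: dict[str, np.ndarray]  # band -> uint16
    meta: dict[str, CaptureMeta]
    camera: CameraSolution


@dataclass
class PanelCapture:
    dn: dict[str, np.ndarray]
    meta: dict[str, CaptureMeta]
    panel_polygon: list[tuple[float, float]]
    known_reflectance: dict[str, float]


@dataclass
class FlightScene:
    captures: list[Capture]
    panel: PanelCapture
    dsm: DSMGrid
    plots: list[WorldBoundary]
    rows: list[RowLine]
    truth: SceneTruth
    # Renderer's world class raster (QA / oracle use): codes per CLASSES,
    # upper-left corner at (world_x0, world_y0), cell size world_gsd metres.
    world_classes: np.ndarray | None = None
    world_x0: float = 0.0
    world_y0: float = 0.0
    world_gsd: float = 0.0


# Trial geometry (metres), loosely matching a 4 m / 0.6 m row-spacing layout.
PLOT_PITCH_X = 4.8
PLOT_PITCH_Y = 2.4
PLOT_LEN_X = 4.4
PLOT_LEN_Y = 2.0
ROW_LENGTH = 4.0
ROW_OFFSET_Y = 0.3  # data rows sit at plot centre +/- this
GROUND_Z = 100.0


def _default_meta(band: str, capture_id: str, image_shape: tuple[int, int],
                  vignette: bool = True) -> CaptureMeta:
    rows, cols = image_shape
    coeffs = (2e-4, 1e-7, 0.0, 0.0, 0.0, 0.0) if vignette else (0.0,) * 6
    return CaptureMeta(
        a1=2.2, a2=1e-6, a3=1e-5, black_level=4800.0, exposure_s=0.004, gain=2.0,
        vignette_center=((cols - 1) / 2.0, (rows - 1) / 2.0),
        vignette_coeffs=coeffs, band_id=band, capture_id=capture_id, bit_depth=16,
    )


def _nadir_camera(capture_id: str, centre: tuple[float, float], height: float,
                  focal_px: float, image_shape: tuple[int, int]) -> CameraSolution:
    rows, cols = image_shape
    cx, cy = (cols - 1) / 2.0, (rows - 1) / 2.0
    K = np.array([[focal_px, 0.0, cx], [0.0, focal_px, cy], [0.0, 0.0, 1.0]])
    R = np.array([[1.0, 0.0, 0.0], [0.0, -1.0, 0.0], [0.0, 0.0, -1.0]])
    C = np.array([centre[0], centre[1], GROUND_Z + height])
    P = K @ np.hstack([R, (-R @ C)[:, None]])
    return CameraSolution(capture_id=capture_id, P=P, position=tuple(C),
                          image_size=image_shape)


def _rigid_warp(shift_xy: tuple[float, float], angle_deg: float, scale: float,
                centre: tuple[float, float]) -> np.ndarray:
    """Similarity matrix about ``centre`` mapping output to source coords."""
    t = np.deg2rad(angle_deg)
    c, s = np.cos(t) * scale, np.sin(t) * scale
    cx, cy = centre
    rot = np.array([[c, -s, cx - c * cx + s * cy + shift_xy[0]],
                    [s, c, cy - s * cx - c * cy + shift_xy[1]],
                    [0.0, 0.0, 1.0]])
    return rot


class _WorldRaster:
    """Class-code raster covering the trial at the ground sampling distance."""

    def __init__(self, x_min: float, y_max: float, width_m: float, height_m: float,
                 gsd: float):
        self.x0 = x_min
        self.y0 = y_max
        self.gsd = gsd
        self.classes = np.zeros((int(np.ceil(height_m / gsd)), int(np.ceil(width_m / gsd))),
                                dtype=np.uint8)

    def to_cell(self, x: float, y: float) -> tuple[float, float]:
        return (self.y0 - y) / self.gsd, (x - self.x0) / self.gsd

    def draw_disc(self, x: float, y: float, radius_m: float, cls: str) -> None:
        row, col = self.to_cell(x, y)
        rr, cc = draw_disk((row, col), radius_m / self.gsd, shape=self.classes.shape)
        self.classes[rr, cc] = _CLASS_CODE[cls]


def _place_plants(raster: _WorldRaster, cx: float, row_y: float, n: int,
                  rng: np.random.Generator, gsd: float) -> None:
    if n <= 0:
        return
    spacing = ROW_LENGTH / n
    radius = float(np.clip(0.28 * spacing, 1.5 * gsd, 3.0 * gsd))
    jitter_cap = max((spacing - 2 * radius - 3 * gsd) / 2.0, 0.0)
    for i in range(n):
        x = cx - ROW_LENGTH / 2 + (i + 0.5) * spacing
        x += rng.uniform(-1, 1) * min(jitter_cap, 1.5 * gsd)
        y = row_y + rng.uniform(-1, 1) * 2.0 * gsd
        raster.draw_disc(x, y, radius, "leaf")


def _place_head_clusters(raster: _WorldRaster, cx: float, cy: float,
                         n_single: int, n_double: int, n_triple: int,
                         colour: str, cfg: HeadsConfig, rng: np.random.Generator,
                         gsd: float) -> None:
    cls = f"{colour}_head"
    pitch_x, pitch_y = 46 * gsd, 30 * gsd
    nx = int((PLOT_LEN_X - 0.4) // pitch_x)
    ny = int((PLOT_LEN_Y - 0.2) // pitch_y)
    slots = [(cx + (i - (nx - 1) / 2) * pitch_x, cy + (j - (ny - 1) / 2) * pitch_y)
             for i in range(nx) for j in range(ny)]
    n_total = n_single + n_double + n_triple
    if n_total > len(slots):
        raise ConfigurationError(
            f"cannot place {n_total} clusters in {len(slots)} slots; reduce n_clusters")
    chosen = rng.permutation(len(slots))[:n_total]
    kinds = [1] * n_single + [2] * n_double + [3] * n_triple
    rng.shuffle(kinds)
    # One head size and overlap geometry per plot (a genotype property), so
    # the per-plot circularity sample forms tight single/double/triple modes.
    r = rng.uniform(*cfg.radius_px_range) * gsd
    spacing = rng.uniform(*cfg.spacing_radii_range) * r
    for slot_idx, k in zip(chosen, kinds):
        sx, sy = slots[slot_idx]
        angle = rng.uniform(-25, 25) * np.pi / 180.0
        dx, dy = np.cos(angle) * spacing, np.sin(angle) * spacing
        offsets = {1: [(0.0, 0.0)],
                   2: [(-dx / 2, -dy / 2), (dx / 2, dy / 2)],
                   3: [(-dx, -dy), (0.0, 0.0), (dx, dy)]}[k]
        for ox, oy in offsets:
            raster.draw_disc(sx + ox, sy + oy, r, cls)


def _place_leaves(raster: _WorldRaster, cx: float, row_y: float, n: int,
                  rng: np.random.Generator, gsd: float) -> None:
    for _ in range(n):
        x = cx + rng.uniform(-ROW_LENGTH / 2, ROW_LENGTH / 2)
        y = row_y + rng.normal(0.0, 0.10)
        raster.draw_disc(x, y, rng.uniform(3, 8) * gsd, "leaf")


def generate_flight(n_plot_rows: int, n_plot_cols: int,
                    plants_per_row_range: tuple[int, int] = (5, 30),
                    heads_config: HeadsConfig | None = None,
                    overlap_fraction: float = 0.0,
                    flight_height_m: float = 20.0,
                    seed: int = 0,
                    *,
                    image_shape: tuple[int, int] = (600, 800),
                    focal_px: float = 2000.0,
                    capture_strategy: str = "per_plot",
                    spectra: ClassSpectra | None = None,
                    misregistration: bool = True,
                    vignette: bool = True,
                    plants_per_plot_range: tuple[int, int] | None = None,
                    weeds_per_plot: int = 0,
                    panel_reflectance: float = 0.49,
                    camera_jitter_m: float = 0.2,
                    ) -> FlightScene:
    """Generate one complete synthetic flight with ground truth.

    ``heads_config=None`` renders the post-emergence (plant-count) stage;
    otherwise the heading stage is rendered with leaf canopy plus head
    clusters of known single/double/triple composition.  Deterministic for a
    fixed seed.
    """
    if n_plot_rows <= 0 or n_plot_cols <= 0:
        raise ContractError("plot grid dimensions must be positive")
    if not 0 <= overlap_fraction < 1:
        raise ContractError("overlap_fraction must be in [0, 1)")
    if capture_strategy not in ("per_plot", "grid"):
        raise ConfigurationError(f"unknown capture strategy {capture_strategy!r}")
    spectra = spectra or ClassSpectra()
    rng = np.random.default_rng(seed)
    rows_px, cols_px = image_shape
    gsd = flight_height_m / focal_px
    foot_x, foot_y = cols_px * gsd, rows_px * gsd

    # --- world layout -----------------------------------------------------
    x_extent = (n_plot_cols - 1) * PLOT_PITCH_X
    y_extent = (n_plot_rows - 1) * PLOT_PITCH_Y
    margin = max(foot_x, foot_y) / 2 + 1.0
    raster = _WorldRaster(-margin, y_extent + margin,
                          x_extent + 2 * margin, y_extent + 2 * margin, gsd)

    plots: list[WorldBoundary] = []
    row_lines: list[RowLine] = []
    truths: list[PlotTruth] = []
    centres: list[tuple[float, float]] = []

    for gr in range(n_plot_rows):
        for gc in range(n_plot_cols):
            plot_id = f"R{gr:02d}C{gc:02d}"
            cx, cy = gc * PLOT_PITCH_X, gr * PLOT_PITCH_Y
            centres.append((cx, cy))
            ring = [(cx - PLOT_LEN_X / 2, cy - PLOT_LEN_Y / 2),
                    (cx + PLOT_LEN_X / 2, cy - PLOT_LEN_Y / 2),
                    (cx + PLOT_LEN_X / 2, cy + PLOT_LEN_Y / 2),
                    (cx - PLOT_LEN_X / 2, cy + PLOT_LEN_Y / 2)]
            plots.append(WorldBoundary(plot_id=plot_id, kind="plot", vertices=ring))
            row_ys = (cy - ROW_OFFSET_Y, cy + ROW_OFFSET_Y)
            for y in row_ys:
                row_lines.append(RowLine(plot_id=plot_id,
                                         start=(cx - ROW_LENGTH / 2, y),
                                         end=(cx + ROW_LENGTH / 2, y)))
            truth = PlotTruth(plot_id=plot_id)
            if heads_config is None:
                if plants_per_plot_range is not None:
                    total = int(rng.integers(plants_per_plot_range[0],
                                             plants_per_plot_range[1] + 1))
                    per_row = (total // 2, total - total // 2)
                else:
                    per_row = tuple(int(rng.integers(plants_per_row_range[0],
                                                     plants_per_row_range[1] + 1))
                                    for _ in row_ys)
                for y, n in zip(row_ys, per_row):
                    _place_plants(raster, cx, y, n, rng, gsd)
                for _ in range(weeds_per_plot):
                    wx = cx + rng.uniform(-ROW_LENGTH / 2, ROW_LENGTH / 2)
                    raster.draw_disc(wx, cy, 2.5 * gsd, "leaf")  # between the rows
                truth.plants_per_row = per_row
                truth.n_plants = sum(per_row)
            else:
                for y in row_ys:
                    _place_leaves(raster, cx, y, heads_config.leaf_discs_per_row, rng, gsd)
                n_clusters = int(rng.integers(heads_config.n_clusters_range[0],
                                              heads_config.n_clusters_range[1] + 1))
                fd = rng.uniform(*heads_config.double_frac_range)
                ft = rng.uniform(*heads_config.triple_frac_range)
                n_double = int(round(fd * n_clusters))
                n_triple = int(round(ft * n_clusters))
                n_single = n_clusters - n_double - n_triple
                colour = str(rng.choice(heads_config.colours))
                _place_head_clusters(raster, cx, cy, n_single, n_double, n_triple,
                                     colour, heads_config, rng, gsd)
                truth.n_single, truth.n_double, truth.n_triple = n_single, n_double, n_triple
                truth.head_colour = colour
            truths.append(truth)

    # --- cameras ----------------------------------------------------------
    cam_centres: list[tuple[float, float]] = []
    if capture_strategy == "per_plot":
        j = camera_jitter_m
        for cx, cy in centres:
            cam_centres.append((cx + rng.uniform(-j, j), cy + rng.uniform(-j, j)))
    else:
        step_x = foot_x * (1 - overlap_fraction)
        step_y = foot_y * (1 - overlap_fraction)
        xs = np.arange(-PLOT_LEN_X / 2, x_extent + PLOT_LEN_X / 2 + step_x, step_x)
        ys = np.arange(-PLOT_LEN_Y / 2, y_extent + PLOT_LEN_Y / 2 + step_y, step_y)
        for y in ys:
            for x in xs:
                cam_centres.append((float(x), float(y)))

    # Per-band misregistration warps, constant across the flight (rigid lens
    # offsets); the true alignment matrix is the inverse of the injected warp.
    centre_px = ((cols_px - 1) / 2.0, (rows_px - 1) / 2.0)
    warps: dict[str, np.ndarray] = {"green": np.eye(3)}
    if misregistration:
        for band in BANDS:
            if band == "green":
                continue
            warps[band] = _rigid_warp(
                shift_xy=(float(rng.uniform(-4, 4)), float(rng.uniform(-4, 4))),
                angle_deg=float(rng.uniform(-0.4, 0.4)),
                scale=float(rng.uniform(0.998, 1.002)),
                centre=centre_px)
    else:
        for band in BANDS:
            warps[band] = np.eye(3)
    true_alignment = {b: np.linalg.inv(warps[b]) for b in BANDS if b != "green"}

    factors = {b: 0.005 for b in BANDS}
    lut = spectra.lut()

    uu, vv = np.meshgrid(np.arange(cols_px, dtype=np.float64),
                         np.arange(rows_px, dtype=np.float64))
    cxp, cyp = centre_px
    t_ground = flight_height_m  # camera height above the flat ground

    captures: list[Capture] = []
    for idx, (camx, camy) in enumerate(cam_centres):
        capture_id = f"IMG{idx:04d}"
        camera = _nadir_camera(capture_id, (camx, camy), flight_height_m,
                               focal_px, image_shape)
        dn: dict[str, np.ndarray] = {}
        meta: dict[str, CaptureMeta] = {}
        for bi, band in enumerate(BANDS):
            w = warps[band]
            up = w[0, 0] * uu + w[0, 1] * vv + w[0, 2]
            vp = w[1, 0] * uu + w[1, 1] * vv + w[1, 2]
            wx = camx + t_ground * (up - cxp) / focal_px
            wy = camy - t_ground * (vp - cyp) / focal_px
            rr = np.clip(((raster.y0 - wy) / gsd).astype(np.intp), 0,
                         raster.classes.shape[0] - 1)
            cc = np.clip(((wx - raster.x0) / gsd).astype(np.intp), 0,
                         raster.classes.shape[1] - 1)
            refl = lut[raster.classes[rr, cc], bi]
            if spectra.noise_sd > 0:
                refl = refl * rng.lognormal(-0.5 * spectra.noise_sd**2,
                                            spectra.noise_sd, refl.shape)
            m = _default_meta(band, capture_id, image_shape, vignette=vignette)
            dn[band] = radiance_to_dn(refl / factors[band], m)
            meta[band] = m
        captures.append(Capture(capture_id=capture_id, dn=dn, meta=meta, camera=camera))

    # --- reference panel capture -----------------------------------------
    panel_shape = (120, 160)
    panel_dn: dict[str, np.ndarray] = {}
    panel_meta: dict[str, CaptureMeta] = {}
    rho = {b: panel_reflectance for b in BANDS}
    for band in BANDS:
        m = _default_meta(band, "PANEL", panel_shape, vignette=vignette)
        refl = np.full(panel_shape, panel_reflectance)
        refl = refl * rng.lognormal(-0.5 * spectra.noise_sd**2, spectra.noise_sd,
                                    panel_shape)
        panel_dn[band] = radiance_to_dn(refl / factors[band], m)
        panel_meta[band] = m
    panel_poly = [(40.0, 30.0), (120.0, 30.0), (120.0, 90.0), (40.0, 90.0)]
    panel = PanelCapture(dn=panel_dn, meta=panel_meta, panel_polygon=panel_poly,
                         known_reflectance=rho)

    # --- DSM --------------------------------------------------------------
    dsm_margin = margin + 1.0
    dsm_cols = int(np.ceil((x_extent + 2 * dsm_margin)))
    dsm_rows = int(np.ceil((y_extent + 2 * dsm_margin)))
    dsm = DSMGrid(elevations=np.full((dsm_rows, dsm_cols), GROUND_Z, dtype=np.float32),
                  geotransform=(-dsm_margin, 1.0, 0.0, y_extent + dsm_margin, 0.0, -1.0))

    truth = SceneTruth(plots=truths, alignment_matrices=true_alignment,
                       reflectance_factors=factors, seed=seed, spectra=spectra,
                       flight_height_m=flight_height_m, gsd_m=gsd)
    return FlightScene(captures=captures, panel=panel, dsm=dsm, plots=plots,
                       rows=row_lines, truth=truth, world_classes=raster.classes,
                       world_x0=raster.x0, world_y0=raster.y0, world_gsd=gsd)


def render_degradation(captures: list[Capture], mode: str, magnitude: float,
                       seed: int = 0) -> list[Capture]:
    """Apply a named corruption to a list of captures; magnitude 0 is identity."""
    if magnitude < 0:
        raise ContractError("magnitude must be >= 0")
    if mode not in ("band_shift", "vignette", "exposure_jitter"):
        raise ConfigurationError(f"unknown degradation mode {mode!r}")
    if magnitude == 0:
        return captures
    rng = np.random.default_rng(seed)
    out: list[Capture] = []
    if mode == "band_shift":
        shift = (int(round(rng.uniform(0.5, 1.0) * magnitude * rng.choice([-1, 1]))),
                 int(round(rng.uniform(0.5, 1.0) * magnitude * rng.choice([-1, 1]))))
    for cap in captures:
        dn = {b: a.copy() for b, a in cap.dn.items()}
        meta = dict(cap.meta)
        if mode == "band_shift":
            for band in BANDS:
                if band == "green":
                    continue
                bl = int(round(meta[band].black_level))
                arr = np.full_like(dn[band], bl)
                src = dn[band]
                dy, dx = shift[1], shift[0]
                ys = slice(max(dy, 0), src.shape[0] + min(dy, 0))
                xs = slice(max(dx, 0), src.shape[1] + min(dx, 0))
                ys_src = slice(max(-dy, 0), src.shape[0] + min(-dy, 0))
                xs_src = slice(max(-dx, 0), src.shape[1] + min(-dx, 0))
                arr[ys, xs] = src[ys_src, xs_src]
                dn[band] = arr
        elif mode == "exposure_jitter":
            factor = float(rng.lognormal(0.0, magnitude))
            for band in BANDS:
                bl = meta[band].black_level
                scaled = bl + (dn[band].astype(np.float64) - bl) * factor
                dn[band] = np.clip(np.rint(scaled), 0, 2**16 - 1).astype(np.uint16)
        else:  # vignette
            for band in BANDS:
                m = meta[band]
                if any(k != 0 for k in m.vignette_coeffs):
                    raise ConfigurationError(
                        "vignette degradation requires captures generated without one")
                rows, cols = dn[band].shape
                cx, cy = m.vignette_center
                x = np.arange(cols) - cx
                y = np.arange(rows) - cy
                r = np.hypot(x[None, :], y[:, None])
                # Inverse of the model's V = 1/(1 + k1*r): calibration with the
                # updated coefficients removes the injected field exactly.
                bl = m.black_level
                scaled = bl + (dn[band].astype(np.float64) - bl) * (1.0 + magnitude * r)
                dn[band] = np.clip(np.rint(scaled), 0, 2**16 - 1).astype(np.uint16)
                meta[band] = replace(m, vignette_coeffs=(magnitude, 0, 0, 0, 0, 0))
        out.append(Capture(capture_id=cap.capture_id, dn=dn, meta=meta, camera=cap.camera))
    return out
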