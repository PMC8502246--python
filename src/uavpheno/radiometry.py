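"""Radiometric calibration: raw digital numbers -> radiance -> reflectance.

The sensor model converts a raw digital number (DN) image into spectral
radiance using per-capture metadata (radiometric coefficients, black level,
exposure, gain, and a radial vignette polynomial), and then into surface
reflectance using a factor derived from a calibrated reference panel of
known reflectance.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import Polygon

from .errors import (
    CalibrationError,
    ContractError,
    DegeneratePanelError,
    GeometryError,
    InvalidMetadataError,
)

BANDS = ("blue", "green", "red", "red_edge", "nir")

_VALID_BIT_DEPTHS = (8, 10, 12, 16)


@dataclass
class CaptureMeta:
    """Per-capture, per-band radiometric metadata.

    Parameters mirror the vendor calibration model: ``a1``–``a3`` are the
    radiometric coefficients, ``black_level`` is in raw DN counts,
    ``exposure_s`` is the exposure time in seconds, ``gain`` the sensor gain,
    and ``vignette_coeffs`` the six radial polynomial coefficients about
    ``vignette_center`` (pixel coordinates, x = column, y = row).
    """

    a1: float
    a2: float
    a3: float
    black_level: float
    exposure_s: float
    gain: float
    vignette_center: tuple[float, float]
    vignette_coeffs: tuple[float, ...]
    band_id: str
    capture_id: str
    bit_depth: int = 16
    # Whether the row-dependent exposure terms act on the flipped row axis.
    flip_row_axis: bool = False

    def __post_init__(self) -> None:
        if not np.isfinite([self.a1, self.a2, self.a3, self.black_level]).all():
            raise InvalidMetadataError(f"non-finite radiometric coefficients for {self.capture_id}")
        if not (np.isfinite(self.exposure_s) and self.exposure_s > 0):
            raise InvalidMetadataError(f"exposure_s must be > 0, got {self.exposure_s}")
        if not (np.isfinite(self.gain) and self.gain > 0):
            raise InvalidMetadataError(f"gain must be > 0, got {self.gain}")
        if self.bit_depth not in _VALID_BIT_DEPTHS:
            raise InvalidMetadataError(f"bit_depth must be one of {_VALID_BIT_DEPTHS}")
        if self.band_id not in BANDS:
            raise InvalidMetadataError(f"unknown band_id {self.band_id!r}")
        self.vignette_coeffs = tuple(float(k) for k in self.vignette_coeffs)
        if len(self.vignette_coeffs) != 6:
            raise InvalidMetadataError("vignette_coeffs must have exactly 6 entries")
        if not np.isfinite(self.vignette_coeffs).all():
            raise InvalidMetadataError("non-finite vignette coefficients")

    @property
    def dn_scale(self) -> float:
        return float(2**self.bit_depth)


@dataclass
class RadianceImage:
    """Spectral radiance (W/m2/sr/nm) for one band of one capture."""

    values: np.ndarray
    band_id: str
    capture_id: str


@dataclass
class PanelReference:
    """Known per-band panel reflectances and the panel pixel polygon."""

    known_reflectance: dict[str, float]
    panel_polygon: list[tuple[float, float]]

    def __post_init__(self) -> None:
        for band, rho in self.known_reflectance.items():
            if not 0.0 < rho < 1.0:
                raise InvalidMetadataError(f"panel reflectance for {band} must be in (0, 1), got {rho}")
        if len(self.panel_polygon) < 3:
            raise GeometryError("panel polygon needs at least 3 vertices")


@dataclass
class ReflectanceStack:
    """All five reflectance bands of one capture, optionally pixel-aligned."""

    bands: dict[str, np.ndarray]
    capture_id: str
    aligned: bool = False
    valid_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        missing = [b for b in BANDS if b not in self.bands]
        if missing:
            raise ContractError(f"missing bands {missing} in stack {self.capture_id}")
        shapes = {self.bands[b].shape for b in BANDS}
        if len(shapes) != 1:
            raise ContractError(f"band shapes differ in stack {self.capture_id}: {shapes}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.bands["green"].shape


def vignette_factor(meta: CaptureMeta, shape: tuple[int, int]) -> np.ndarray:
    """Evaluate the radial vignette correction V(x, y) on a pixel grid.

    V = 1 / (1 + sum_{i=1..6} k_i r^i), r the Euclidean pixel distance to the
    vignette centre.  V equals 1 at the centre and for all-zero coefficients.
    """
    rows, cols = shape
    if rows <= 0 or cols <= 0:
        raise ContractError(f"shape must be positive, got {shape}")
    cx, cy = meta.vignette_center
    x = np.arange(cols, dtype=np.float64)
    y = np.arange(rows, dtype=np.float64)
    r = np.hypot(x[None, :] - cx, y[:, None] - cy)
    poly = np.zeros_like(r)
    rp = np.ones_like(r)
    for k in meta.vignette_coeffs:
        rp = rp * r
        if k != 0.0:
            poly += k * rp
    v = 1.0 / (1.0 + poly)
    if not np.isfinite(v).all() or (v <= 0).any():
        raise InvalidMetadataError("vignette polynomial produced non-positive or non-finite values")
    return v


def _row_denominator(meta: CaptureMeta, rows: int) -> np.ndarray:
    y = np.arange(rows, dtype=np.float64)
    if meta.flip_row_axis:
        y = y[::-1].copy()
    return meta.exposure_s + meta.a2 * y - meta.a3 * meta.exposure_s * y


def dn_to_radiance(raw: np.ndarray, meta: CaptureMeta) -> RadianceImage:
    """Calibrate a raw DN image into spectral radiance.

    L = V(x, y) * (a1 / g) * (p - p_BL) / (t_e + a2*y - a3*t_e*y) with
    p = DN / 2^bit_depth and y the 0-based pixel row index.
    """
    raw = np.asarray(raw, dtype=np.float64)
    rows, _ = raw.shape
    denom = _row_denominator(meta, rows)
    bad = np.nonzero(denom <= 0)[0]
    if bad.size:
        raise CalibrationError(
            f"non-positive calibration denominator at row {int(bad[0])} for capture {meta.capture_id}"
        )
    p = raw / meta.dn_scale
    p_bl = meta.black_level / meta.dn_scale
    v = vignette_factor(meta, raw.shape)
    values = v * (meta.a1 / meta.gain) * (p - p_bl) / denom[:, None]
    return RadianceImage(values=values, band_id=meta.band_id, capture_id=meta.capture_id)


def panel_pixel_mask(polygon: list[tuple[float, float]], shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of pixels whose centres fall inside a pixel polygon."""
    poly = Polygon(polygon)
    if poly.area == 0:
        raise GeometryError("panel polygon has zero area")
    rows, cols = shape
    xs, ys = np.meshgrid(np.arange(cols, dtype=float), np.arange(rows, dtype=float))
    return shapely.contains_xy(poly, xs.ravel(), ys.ravel()).reshape(shape)


def panel_factor(panel_radiance: RadianceImage, ref: PanelReference) -> float:
    """Reflectance calibration factor F = rho / avg(L) over the panel area."""
    band = panel_radiance.band_id
    if band not in ref.known_reflectance:
        raise ContractError(f"no known panel reflectance for band {band}")
    mask = panel_pixel_mask(ref.panel_polygon, panel_radiance.values.shape)
    if not mask.any():
        raise GeometryError("panel polygon contains no pixel centres")
    mean_l = float(panel_radiance.values[mask].mean())
    if mean_l <= 0:
        raise DegeneratePanelError(f"mean panel radiance {mean_l} is not positive for band {band}")
    return ref.known_reflectance[band] / mean_l


def radiance_to_reflectance(rad: RadianceImage, factor: float) -> np.ndarray:
    """Scale radiance to surface reflectance; no clipping is applied.

    Emits a warning when more than 5% of pixels exceed 1 (specular pixels
    are retained for QA).
    """
    if not (np.isfinite(factor) and factor > 0):
        raise ContractError(f"reflectance factor must be positive, got {factor}")
    refl = rad.values * factor
    frac_over = float((refl > 1.0).mean())
    if frac_over > 0.05:
        warnings.warn(
            f"{frac_over:.1%} of pixels exceed reflectance 1.0 in {rad.capture_id}/{rad.band_id}",
            stacklevel=2,
        )
    return refl


def radiance_to_dn(radiance: np.ndarray, meta: CaptureMeta, quantize: bool = True) -> np.ndarray:
    """Invert the calibration model: radiance -> raw DN.

    Exact inverse of :func:`dn_to_radiance`; with ``quantize`` the result is
    rounded and clipped to the sensor's integer range.
    """
    radiance = np.asarray(radiance, dtype=np.float64)
    rows, _ = radiance.shape
    denom = _row_denominator(meta, rows)
    if (denom <= 0).any():
        raise CalibrationError(f"non-positive calibration denominator for capture {meta.capture_id}")
    v = vignette_factor(meta, radiance.shape)
    p = radiance * denom[:, None] * meta.gain / (meta.a1 * v) + meta.black_level / meta.dn_scale
    dn = p * meta.dn_scale
    if quantize:
        dn = np.clip(np.rint(dn), 0, meta.dn_scale - 1).astype(np.uint16 if meta.bit_depth > 8 else np.uint8)
    return dn
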