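"""Readers and writers for the interchange formats.

Rasters are single-band TIFFs (16-bit raw DN, float32 otherwise) with an
optional YAML sidecar carrying the geotransform; camera solutions travel as
CSV (one row per capture: id, the twelve P entries row-major, position and
image size); the plot/row layout is GeoJSON; capture metadata and pipeline
configuration are YAML.
"""
from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .alignment import BandHomography
from .errors import SchemaError
from .geometry import CameraSolution, DSMGrid, WorldBoundary
from .radiometry import BANDS, CaptureMeta
from .synth import Capture, FlightScene, PanelCapture, RowLine


# --- rasters --------------------------------------------------------------

def write_raster(path: str | Path, values: np.ndarray,
                 geotransform: tuple | None = None) -> None:
    path = Path(path)
    arr = values if values.dtype in (np.uint8, np.uint16) else values.astype(np.float32)
    tifffile.imwrite(path, arr, compression="zlib")
    if geotransform is not None:
        sidecar = path.with_suffix(path.suffix + ".meta.yaml")
        sidecar.write_text(yaml.safe_dump({"geotransform": list(geotransform)}))


def read_raster(path: str | Path) -> tuple[np.ndarray, tuple | None]:
    path = Path(path)
    values = tifffile.imread(path)
    sidecar = path.with_suffix(path.suffix + ".meta.yaml")
    gt = None
    if sidecar.exists():
        gt = tuple(yaml.safe_load(sidecar.read_text())["geotransform"])
    return values, gt


def write_dsm(path: str | Path, dsm: DSMGrid) -> None:
    write_raster(path, dsm.elevations, geotransform=dsm.geotransform)
    sidecar = Path(path).with_suffix(Path(path).suffix + ".meta.yaml")
    meta = yaml.safe_load(sidecar.read_text())
    meta["nodata"] = float(dsm.nodata)
    sidecar.write_text(yaml.safe_dump(meta))


def read_dsm(path: str | Path) -> DSMGrid:
    values, gt = read_raster(path)
    if gt is None:
        raise SchemaError(f"DSM {path} is missing its geotransform sidecar")
    sidecar = Path(path).with_suffix(Path(path).suffix + ".meta.yaml")
    nodata = yaml.safe_load(sidecar.read_text()).get("nodata", -9999.0)
    return DSMGrid(elevations=values, geotransform=gt, nodata=nodata)


# --- capture metadata -----------------------------------------------------

def _meta_to_dict(meta: CaptureMeta) -> dict:
    return {
        "a1": meta.a1, "a2": meta.a2, "a3": meta.a3,
        "black_level": meta.black_level, "exposure_s": meta.exposure_s,
        "gain": meta.gain, "vignette_center": list(meta.vignette_center),
        "vignette_coeffs": list(meta.vignette_coeffs), "band_id": meta.band_id,
        "capture_id": meta.capture_id, "bit_depth": meta.bit_depth,
        "flip_row_axis": meta.flip_row_axis,
    }


def _meta_from_dict(d: dict) -> CaptureMeta:
    return CaptureMeta(
        a1=d["a1"], a2=d["a2"], a3=d["a3"], black_level=d["black_level"],
        exposure_s=d["exposure_s"], gain=d["gain"],
        vignette_center=tuple(d["vignette_center"]),
        vignette_coeffs=tuple(d["vignette_coeffs"]), band_id=d["band_id"],
        capture_id=d["capture_id"], bit_depth=d.get("bit_depth", 16),
        flip_row_axis=d.get("flip_row_axis", False),
    )


def write_capture(directory: str | Path, capture: Capture) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for band in BANDS:
        write_raster(directory / f"{band}.tif", capture.dn[band])
    (directory / "meta.yaml").write_text(
        yaml.safe_dump({b: _meta_to_dict(capture.meta[b]) for b in BANDS}))


def read_capture_dn(directory: str | Path) -> tuple[dict[str, np.ndarray], dict[str, CaptureMeta]]:
    directory = Path(directory)
    meta_raw = yaml.safe_load((directory / "meta.yaml").read_text())
    dn = {b: read_raster(directory / f"{b}.tif")[0] for b in BANDS}
    meta = {b: _meta_from_dict(meta_raw[b]) for b in BANDS}
    return dn, meta


# --- camera solutions -----------------------------------------------------

_CAMERA_HEADER = (["capture_id"] + [f"p{i}{j}" for i in range(3) for j in range(4)]
                  + ["x", "y", "z", "rows", "cols"])


def write_cameras(path: str | Path, cameras: list[CameraSolution]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CAMERA_HEADER)
        for cam in cameras:
            writer.writerow([cam.capture_id, *(repr(float(v)) for v in cam.P.ravel()),
                             *(repr(float(v)) for v in cam.position),
                             cam.image_size[0], cam.image_size[1]])


def read_cameras(path: str | Path) -> list[CameraSolution]:
    cameras: list[CameraSolution] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if header != _CAMERA_HEADER:
            raise SchemaError(f"unexpected camera CSV header in {path}")
        for row in reader:
            p = np.array([float(v) for v in row[1:13]]).reshape(3, 4)
            cameras.append(CameraSolution(
                capture_id=row[0], P=p,
                position=(float(row[13]), float(row[14]), float(row[15])),
                image_size=(int(row[16]), int(row[17]))))
    return cameras


# --- layout ---------------------------------------------------------------

def write_layout(path: str | Path, plots: list[WorldBoundary], rows: list[RowLine]) -> None:
    features = []
    for plot in plots:
        ring = [list(v) for v in plot.vertices] + [list(plot.vertices[0])]
        features.append({
            "type": "Feature",
            "properties": {"plot_id": plot.plot_id, "kind": "plot"},
            "geometry": {"type": "Polygon", "coordinates": [ring]},
        })
    for row in rows:
        features.append({
            "type": "Feature",
            "properties": {"plot_id": row.plot_id, "kind": "row"},
            "geometry": {"type": "LineString",
                         "coordinates": [list(row.start), list(row.end)]},
        })
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": features}))


def read_layout(path: str | Path) -> tuple[list[WorldBoundary], list[RowLine]]:
    """Plots come back as rings, rows as unbuffered 2-point lines."""
    data = json.loads(Path(path).read_text())
    plots: list[WorldBoundary] = []
    rows: list[RowLine] = []
    for i, feature in enumerate(data.get("features", [])):
        props = feature.get("properties") or {}
        plot_id = props.get("plot_id")
        if plot_id is None:
            raise SchemaError(f"feature {i} is missing the plot_id property")
        geom = feature.get("geometry") or {}
        gtype = geom.get("type")
        if gtype == "Polygon":
            ring = [tuple(v) for v in geom["coordinates"][0]]
            if len(ring) > 1 and ring[0] == ring[-1]:
                ring = ring[:-1]
            plots.append(WorldBoundary(plot_id=plot_id, kind="plot", vertices=ring))
        elif gtype == "LineString":
            coords = geom["coordinates"]
            if len(coords) != 2:
                raise SchemaError(f"feature {i}: row lines must have exactly 2 points")
            rows.append(RowLine(plot_id=plot_id, start=tuple(coords[0]),
                                end=tuple(coords[1])))
        else:
            raise SchemaError(f"feature {i} has unsupported geometry type {gtype!r}")
    return plots, rows


# --- panel ----------------------------------------------------------------

def write_panel(directory: str | Path, panel: PanelCapture) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for band in BANDS:
        write_raster(directory / f"{band}.tif", panel.dn[band])
    (directory / "meta.yaml").write_text(
        yaml.safe_dump({b: _meta_to_dict(panel.meta[b]) for b in BANDS}))
    (directory / "panel.yaml").write_text(yaml.safe_dump({
        "known_reflectance": {b: float(v) for b, v in panel.known_reflectance.items()},
        "panel_polygon": [list(v) for v in panel.panel_polygon],
    }))


def read_panel(directory: str | Path) -> PanelCapture:
    directory = Path(directory)
    dn, meta = read_capture_dn(directory)
    info = yaml.safe_load((directory / "panel.yaml").read_text())
    return PanelCapture(dn=dn, meta=meta,
                        panel_polygon=[tuple(v) for v in info["panel_polygon"]],
                        known_reflectance=info["known_reflectance"])


# --- homographies ---------------------------------------------------------

def write_homography(path: str | Path, h: BandHomography) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["band", h.source_band, "converged", h.converged,
                         "correlation", repr(float(h.correlation))])
        for row in h.matrix:
            writer.writerow([repr(float(v)) for v in row])


def read_homography(path: str | Path) -> BandHomography:
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        head = next(reader)
        matrix = np.array([[float(v) for v in next(reader)] for _ in range(3)])
    return BandHomography(matrix=matrix, source_band=head[1],
                          converged=head[3] == "True", correlation=float(head[5]))


# --- whole flights --------------------------------------------------------

def write_flight(scene: FlightScene, directory: str | Path) -> Path:
    """Write every interface file for a synthetic flight; returns the root."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for capture in scene.captures:
        write_capture(directory / "captures" / capture.capture_id, capture)
    write_panel(directory / "panel", scene.panel)
    write_cameras(directory / "cameras.csv", [c.camera for c in scene.captures])
    write_dsm(directory / "dsm.tif", scene.dsm)
    write_layout(directory / "layout.geojson", scene.plots, scene.rows)
    truth = {
        "seed": scene.truth.seed,
        "plots": [{
            "plot_id": p.plot_id, "n_plants": p.n_plants,
            "plants_per_row": list(p.plants_per_row),
            "n_single": p.n_single, "n_double": p.n_double, "n_triple": p.n_triple,
            "n_heads": p.n_heads, "head_colour": p.head_colour,
        } for p in scene.truth.plots],
    }
    (directory / "truth.yaml").write_text(yaml.safe_dump(truth))
    return directory
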