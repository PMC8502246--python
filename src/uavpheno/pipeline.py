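"""End-to-end orchestration: calibrate, align, reverse-calculate, count.

The pipeline is lazy about raster data: capture geometry (projection, nadir
selection, coverage) is resolved first from the camera CSV alone, and only
the captures actually selected as a nadir view for some boundary are loaded,
calibrated and aligned.  Any per-plot stage failure is logged and flagged,
never fatal.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .alignment import BandHomography, align_capture, estimate_homography, median_homography
from .config import PipelineConfig
from .errors import UavPhenoError
from .geometry import (
    PlotView,
    WorldBoundary,
    buffer_row,
    extract_plot_image,
    project_boundary,
    select_nadir,
)
from .heads import HeadDetectConfig, count_heads
from .plants import PlantCount, PlantCountConfig, count_plants
from .radiometry import (
    BANDS,
    PanelReference,
    ReflectanceStack,
    dn_to_radiance,
    panel_factor,
    radiance_to_reflectance,
)

log = logging.getLogger("uavpheno")


@dataclass
class PipelineResult:
    plant_counts: pd.DataFrame | None
    head_counts: pd.DataFrame | None
    coverage: pd.DataFrame
    homographies: dict[str, BandHomography]
    reflectance_factors: dict[str, float]


def compute_panel_factors(panel_dir: str | Path) -> tuple[dict[str, float], PanelReference]:
    panel = io.read_panel(panel_dir)
    ref = PanelReference(known_reflectance=panel.known_reflectance,
                        panel_polygon=panel.panel_polygon)
    factors = {}
    for band in BANDS:
        rad = dn_to_radiance(panel.dn[band], panel.meta[band])
        factors[band] = panel_factor(rad, ref)
    return factors, ref


def calibrate_capture(capture_dir: str | Path, factors: dict[str, float],
                      capture_id: str) -> ReflectanceStack:
    dn, meta = io.read_capture_dn(capture_dir)
    bands = {}
    for band in BANDS:
        rad = dn_to_radiance(dn[band], meta[band])
        bands[band] = radiance_to_reflectance(rad, factors[band])
    return ReflectanceStack(bands=bands, capture_id=capture_id, aligned=False)


def estimate_flight_homographies(captures_dir: Path, capture_ids: list[str],
                                 factors: dict[str, float],
                                 n_samples: int = 5) -> dict[str, BandHomography]:
    """Median per-band transform over a spread of sampled captures."""
    if not capture_ids:
        return {b: BandHomography(np.eye(3), source_band=b) for b in BANDS if b != "green"}
    idx = np.unique(np.linspace(0, len(capture_ids) - 1,
                                min(n_samples, len(capture_ids))).astype(int))
    per_band: dict[str, list[BandHomography]] = {b: [] for b in BANDS if b != "green"}
    for i in idx:
        cid = capture_ids[i]
        stack = calibrate_capture(captures_dir / cid, factors, cid)
        for band in per_band:
            h = estimate_homography(stack.bands["green"], stack.bands[band],
                                    source_band=band)
            if h.converged:
                per_band[band].append(h)
            else:
                log.warning("alignment failed to converge for %s/%s", cid, band)
    out = {}
    for band, hs in per_band.items():
        if hs:
            out[band] = median_homography(hs)
        else:
            log.warning("no converged homography for band %s; using identity", band)
            out[band] = BandHomography(np.eye(3), source_band=band)
    return out


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "pipeline.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run(config, out_dir)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, out_dir: Path) -> PipelineResult:
    captures_dir = Path(config.captures_dir)
    cameras = io.read_cameras(config.cameras_csv)
    dsm = io.read_dsm(config.dsm_path)
    plots, rows = io.read_layout(config.layout_path)
    log.info("loaded %d cameras, %d plots, %d rows", len(cameras), len(plots), len(rows))

    # Plot polygons are always projected (they drive the coverage report);
    # head counting on them is gated on the configured stages further down.
    boundaries: list[WorldBoundary] = list(plots)
    if "plants" in config.stages:
        for i, line in enumerate(rows):
            b = buffer_row([line.start, line.end], half_width_m=config.row_buffer_m,
                           plot_id=line.plot_id)
            b.plot_id = line.plot_id
            boundaries.append(b)
    # Distinguish the (up to two) rows of one plot in the working tables.
    row_seq: dict[str, int] = {}
    keys = []
    for b in boundaries:
        if b.kind == "row":
            row_seq[b.plot_id] = row_seq.get(b.plot_id, -1) + 1
            keys.append((b.plot_id, f"row{row_seq[b.plot_id]}"))
        else:
            keys.append((b.plot_id, "plot"))

    # --- reverse calculation + nadir selection ---------------------------
    nadir: dict[tuple[str, str], PlotView | None] = {}
    full_views: dict[str, int] = {p.plot_id: 0 for p in plots}
    for key, boundary in zip(keys, boundaries):
        views = []
        for camera in cameras:
            try:
                views.append(project_boundary(boundary, dsm, camera))
            except UavPhenoError as exc:
                log.warning("projection failed for %s in %s: %s", key, camera.capture_id, exc)
        nadir[key] = select_nadir(views)
        if boundary.kind == "plot":
            full_views[boundary.plot_id] = sum(v.fully_contained for v in views)
    coverage = pd.DataFrame({
        "plot_id": list(full_views),
        "n_full_captures": [full_views[p] for p in full_views],
    }).sort_values("plot_id").reset_index(drop=True)
    coverage["fully_captured"] = coverage["n_full_captures"] > 0

    # --- calibration + alignment -----------------------------------------
    factors, _ = compute_panel_factors(config.panel_dir)
    log.info("panel factors: %s", {b: round(f, 6) for b, f in factors.items()})
    capture_ids = sorted({v.capture_id for v in nadir.values() if v is not None})
    homographies: dict[str, BandHomography] = {}
    if config.alignment_mode == "per_flight":
        homographies = estimate_flight_homographies(
            captures_dir, capture_ids, factors, n_samples=config.alignment_samples)
        for band, h in homographies.items():
            io.write_homography(out_dir / f"homography_{band}.csv", h)

    plant_cfg = PlantCountConfig(min_area_px=config.min_area_plants_px,
                                 element_size=config.element_size)
    head_cfg = HeadDetectConfig(ndvi_re_threshold=config.ndvi_re_threshold,
                                min_area_px=config.min_area_heads_px,
                                element_size=config.element_size,
                                bandwidth_floor=config.kde_bandwidth_floor)

    plant_rows: dict[str, dict] = {}
    head_rows: list[dict] = []
    stacks: dict[str, ReflectanceStack] = {}

    def aligned_stack(capture_id: str) -> ReflectanceStack:
        if capture_id not in stacks:
            if len(stacks) > 8:  # keep the working set bounded
                stacks.pop(next(iter(stacks)))
            stack = calibrate_capture(captures_dir / capture_id, factors, capture_id)
            h = homographies
            if config.alignment_mode == "per_capture":
                h = {band: estimate_homography(stack.bands["green"], stack.bands[band],
                                               source_band=band)
                     for band in BANDS if band != "green"}
            stacks[capture_id] = align_capture(stack, h)
        return stacks[capture_id]

    # Group work per capture so each capture is loaded once.
    order = sorted(nadir.items(), key=lambda kv: ("" if kv[1] is None else kv[1].capture_id))
    for (plot_id, part), view in order:
        if part == "plot":
            if "heads" not in config.stages:
                continue
            if view is None:
                head_rows.append({"plot_id": plot_id, "capture_id": "", "n_single": 0,
                                  "n_double": 0, "n_triple": 0, "n_heads": 0,
                                  "thresholds": "", "qc_flags": "not_fully_captured"})
                continue
            try:
                image = extract_plot_image(aligned_stack(view.capture_id), view)
                hc = count_heads(image, head_cfg)
                head_rows.append({
                    "plot_id": plot_id, "capture_id": view.capture_id,
                    "n_single": hc.n_single, "n_double": hc.n_double,
                    "n_triple": hc.n_triple, "n_heads": hc.n_heads,
                    "thresholds": ";".join(f"{t:.4f}" for t in hc.thresholds),
                    "qc_flags": ";".join(hc.qc_flags)})
            except UavPhenoError as exc:
                log.error("head stage failed for %s: %s", plot_id, exc)
                head_rows.append({"plot_id": plot_id, "capture_id": view.capture_id,
                                  "n_single": 0, "n_double": 0, "n_triple": 0,
                                  "n_heads": 0, "thresholds": "",
                                  "qc_flags": f"stage_error:{type(exc).__name__}"})
        else:
            if "plants" not in config.stages:
                continue
            entry = plant_rows.setdefault(
                plot_id, {"plot_id": plot_id, "capture_id": set(), "n_plants": 0,
                          "qc_flags": set(), "n_rows_counted": 0})
            if view is None:
                entry["qc_flags"].add("partial_capture")
                continue
            try:
                image = extract_plot_image(aligned_stack(view.capture_id), view)
                pc = count_plants(image, plant_cfg)
                entry["n_plants"] += pc.n_plants
                entry["capture_id"].add(view.capture_id)
                entry["qc_flags"].update(pc.qc_flags)
                entry["n_rows_counted"] += 1
            except UavPhenoError as exc:
                log.error("plant stage failed for %s/%s: %s", plot_id, part, exc)
                entry["qc_flags"].add(f"stage_error:{type(exc).__name__}")

    plant_df = None
    if "plants" in config.stages:
        plant_df = pd.DataFrame([
            {"plot_id": e["plot_id"], "capture_id": ";".join(sorted(e["capture_id"])),
             "n_plants": e["n_plants"], "n_rows_counted": e["n_rows_counted"],
             "qc_flags": ";".join(sorted(e["qc_flags"]))}
            for e in plant_rows.values()
        ]).sort_values("plot_id").reset_index(drop=True)
        plant_df.to_csv(out_dir / "plant_counts.csv", index=False)
    head_df = None
    if "heads" in config.stages:
        head_df = pd.DataFrame(head_rows).sort_values("plot_id").reset_index(drop=True)
        head_df.to_csv(out_dir / "head_counts.csv", index=False)
    coverage.to_csv(out_dir / "coverage.csv", index=False)
    return PipelineResult(plant_counts=plant_df, head_counts=head_df, coverage=coverage,
                          homographies=homographies, reflectance_factors=factors)
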