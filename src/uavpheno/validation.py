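"""End-to-end benchmark runs on synthetic flights with known truth.

Shared between the test suite and ``scripts/acceptance.py`` so both measure
the very same computation: generate a flight, write every interface file,
run the full pipeline from disk, and score estimated against true counts.
"""
from __future__ import annotations

import tempfile
from pathlib import Path

import numpy as np

from . import io
from .config import PipelineConfig
from .pipeline import run_pipeline
from .synth import HeadsConfig, generate_flight


def r_squared(truth, estimate) -> float:
    """1 - SS_res / SS_tot of the estimate against the 1:1 line."""
    y = np.asarray(truth, dtype=np.float64)
    yhat = np.asarray(estimate, dtype=np.float64)
    ss_tot = ((y - y.mean()) ** 2).sum()
    if ss_tot == 0:
        raise ValueError("truth has zero variance")
    return float(1.0 - ((y - yhat) ** 2).sum() / ss_tot)


def rmse(truth, estimate) -> float:
    y = np.asarray(truth, dtype=np.float64)
    yhat = np.asarray(estimate, dtype=np.float64)
    return float(np.sqrt(((y - yhat) ** 2).mean()))


def run_plant_benchmark(seed: int, n_plot_rows: int = 10, n_plot_cols: int = 12,
                        plants_per_plot_range: tuple[int, int] = (3, 100),
                        workdir: str | Path | None = None) -> dict:
    """Full-pipeline plant counting on a synthetic flight; returns metrics."""
    scene = generate_flight(n_plot_rows, n_plot_cols,
                            plants_per_plot_range=plants_per_plot_range, seed=seed)
    with tempfile.TemporaryDirectory(dir=workdir) as tmp:
        io.write_flight(scene, tmp)
        result = run_pipeline(PipelineConfig(stages=("plants",), seed=seed).resolve(tmp))
    est = dict(zip(result.plant_counts.plot_id, result.plant_counts.n_plants))
    truth = {p.plot_id: p.n_plants for p in scene.truth.plots}
    captured = [p for p in truth if p in est]
    y = [truth[p] for p in captured]
    yhat = [est[p] for p in captured]
    return {
        "n_plots": len(captured),
        "r2": r_squared(y, yhat),
        "rmse": rmse(y, yhat),
        "truth": y,
        "estimate": yhat,
        "coverage": result.coverage,
    }


def run_head_benchmark(seed: int, n_plot_rows: int = 10, n_plot_cols: int = 12,
                       heads_config: HeadsConfig | None = None,
                       workdir: str | Path | None = None) -> dict:
    """Full-pipeline head counting on a synthetic flight; returns metrics."""
    scene = generate_flight(n_plot_rows, n_plot_cols,
                            heads_config=heads_config or HeadsConfig(), seed=seed)
    with tempfile.TemporaryDirectory(dir=workdir) as tmp:
        io.write_flight(scene, tmp)
        result = run_pipeline(PipelineConfig(stages=("heads",), seed=seed).resolve(tmp))
    df = result.head_counts
    est = dict(zip(df.plot_id, df.n_heads))
    truth = {p.plot_id: p.n_heads for p in scene.truth.plots}
    captured = [p for p in truth if p in est]
    y = [truth[p] for p in captured]
    yhat = [est[p] for p in captured]
    identity_ok = bool((df.n_heads == df.n_single + 2 * df.n_double + 3 * df.n_triple).all())
    return {
        "n_plots": len(captured),
        "r2": r_squared(y, yhat),
        "rmse": rmse(y, yhat),
        "truth": y,
        "estimate": yhat,
        "count_identity_holds": identity_ok,
        "coverage": result.coverage,
    }
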