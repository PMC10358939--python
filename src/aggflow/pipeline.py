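"""End-to-end pipeline: phantom-or-load -> imaging -> porous -> flow -> metrics.

``run_pipeline`` executes the whole image-based modelling workflow for every
requested wall shear rate, writes all field and summary artifacts to disk
and records a machine-readable manifest (config echo, package versions,
seed, convergence reports) sufficient to reproduce the run.  One master
seed drives the phantom and calibration draws; the solver itself is
deterministic, so re-running an identical config is bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import RunConfig
from .flow import NonConvergenceError
from .imaging import read_stack
from .model import AggregateFlowModel
from .metrics import porosity_sweep
from .phantoms import (CalibrationSampleSet, make_calibration_samples,
                       make_phantom, write_phantom)
from .porous import CalibrationFit, fit_intensity_density

__all__ = ["run_pipeline", "run_sweep", "build_model", "PipelineError"]

log = logging.getLogger("aggflow")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _calibration_fit(config: RunConfig) -> CalibrationFit:
    cal = config.calibration
    spec = config.phantom
    if cal.mode == "explicit":
        return CalibrationFit(cal.slope, cal.intercept, 0.0, 2)
    if cal.mode == "true":
        return CalibrationFit(spec.slope, spec.intercept, 0.0, 2)
    if cal.mode == "csv":
        samples = CalibrationSampleSet.from_csv(cal.file)
        return fit_intensity_density(samples)
    samples = make_calibration_samples(spec.slope, spec.intercept, cal.n,
                                       cal.noise_sd, seed=config.seed + 1)
    return fit_intensity_density(samples)


def build_model(config: RunConfig, wall_shear_rate: float) -> AggregateFlowModel:
    """Assemble the flow model for one wall shear rate from a config."""
    fit = _calibration_fit(config)
    if config.input is not None:
        intensity = read_stack(config.input.intensity, config.input.spacing,
                               kind="intensity")
        masks = read_stack(config.input.masks, config.input.spacing, kind="mask")
        from .imaging import VoxelGrid
        H = config.phantom.height
        grid = VoxelGrid.for_channel(H, config.nz, config.phantom.lx,
                                     config.phantom.ly)
        return AggregateFlowModel.from_stacks(
            intensity, masks, grid, fit, config.physics, wall_shear_rate,
            config.smoothing_length, tuple(config.clamp), config.agonists,
            config.lateral)
    spec = dataclasses.replace(config.phantom, seed=config.seed)
    return AggregateFlowModel.from_phantom(
        spec, config.nz, config.physics, wall_shear_rate, fit,
        smoothing_length=config.smoothing_length, clamp=tuple(config.clamp),
        agonists=config.agonists, lateral=config.lateral)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage for every wall shear rate; returns the manifest."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "aggflow",
        "version": __version__,
        "numpy": np.__version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "runs": {},
    }

    t0 = time.perf_counter()
    spec = dataclasses.replace(config.phantom, seed=config.seed)
    if config.input is None:
        stage_dir = outdir / "phantom"
        try:
            write_phantom(spec, stage_dir)
        except Exception as exc:
            raise PipelineError(f"phantom stage failed: {exc}") from exc
        log.info("phantom stage done in %.2f s", time.perf_counter() - t0)

    frames = []
    for wsr in config.wall_shear_rates:
        run_dir = outdir / f"wsr_{wsr:g}"
        t1 = time.perf_counter()
        try:
            model = build_model(config, wsr)
        except Exception as exc:
            raise PipelineError(f"preprocessing stage failed at WSR {wsr:g}: {exc}"
                                ) from exc
        try:
            results = model.fit(config.solver)
        except NonConvergenceError as exc:
            raise PipelineError(f"solver stage failed at WSR {wsr:g}: {exc}") from exc
        paths = results.save(run_dir)
        frames.append(results.summary_frame())
        manifest["runs"][f"{wsr:g}"] = {
            "paths": paths,
            "convergence": {
                "steps": results.convergence.steps,
                "dt": results.convergence.dt,
                "final_residual": float(results.convergence.final_residual),
            },
            "diagnostics": {k: float(v) for k, v in results.diagnostics.items()},
        }
        log.info("WSR %g done in %.2f s (%d steps)", wsr,
                 time.perf_counter() - t1, results.convergence.steps)

    combined = pd.concat(frames, ignore_index=True)
    combined_path = outdir / "summary_by_wsr.csv"
    combined.to_csv(combined_path, index=False)
    manifest["summary_table"] = str(combined_path)
    (outdir / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
    return manifest


def run_sweep(config: RunConfig) -> pd.DataFrame:
    """Porosity sensitivity sweep on the configured phantom geometry.

    Each porosity specification (uniform value or ``(lo, hi)`` range mapped
    onto the intensity field) replaces the calibrated porosity while the
    geometry, boundary conditions and solver stay fixed.
    """
    from .porous import porosity_range_map

    base = {}

    def runner(spec_p, wsr):
        if wsr not in base:
            base[wsr] = build_model(config, wsr)
        model = base[wsr]
        if np.isscalar(spec_p):
            eps = float(spec_p)
        else:
            lo, hi = spec_p
            intensity = _phantom_intensity(config, model)
            eps = porosity_range_map(intensity, model.aggregate.occupied, (lo, hi))
        return model.with_porosity(eps).fit(config.solver).summary_stats

    specs = list(config.sweep.porosities) + [tuple(r) for r in config.sweep.ranges]
    table = porosity_sweep(runner, specs, config.sweep.wall_shear_rates)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    table.to_csv(outdir / "porosity_sweep.csv", index=False)
    return table


def _phantom_intensity(config: RunConfig, model: AggregateFlowModel) -> np.ndarray:
    """Noise-matched intensity lattice on the flow grid for range mapping."""
    from .imaging import resample_to_grid

    spec = dataclasses.replace(config.phantom, seed=config.seed)
    _, intensity, _ = make_phantom(spec)
    return resample_to_grid(intensity, model.aggregate.grid)
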