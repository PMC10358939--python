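"""Model/Results front end for aggregate flow simulations.

``AggregateFlowModel`` bundles everything that defines one steady-flow
problem — the porous aggregate on its grid, the fluid parameters and the
channel boundary conditions — and ``fit()`` runs the solver and returns an
``AggregateFlowResults`` carrying the velocity/pressure fields, the derived
hemodynamic lattices, per-region summary statistics, convergence and
conservation diagnostics, and a printable ``summary()`` table.

Construction helpers cover the two standard routes:

* ``from_phantom`` — generate a synthetic aggregate, reconstruct its
  geometry from the per-slice masks, calibrate the intensity-density map
  and build the permeability field (the full image-processing pipeline);
* ``from_stacks`` — the same starting from user-supplied intensity and
  mask stacks.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import cached_property

import numpy as np
import pandas as pd

from .flow import (BoundaryConditions, ConvergenceReport, FlowField,
                   PhysicalParams, SolverSettings, assemble_darcy_coefficient,
                   check_divergence, solve_steady)
from .imaging import (ImageStack, VoxelGrid, resample_to_grid, smooth_geometry,
                      stack_and_interpolate)
from .metrics import DEFAULT_AGONISTS, DerivedFieldSet, FlowSummary, summarize
from .phantoms import PhantomSpec, make_calibration_samples, make_phantom
from .porous import (AggregateField, CalibrationFit, DEFAULT_PHI_CLAMP,
                     fit_intensity_density)

__all__ = ["AggregateFlowModel", "AggregateFlowResults"]


class AggregateFlowModel:
    """Steady Navier-Stokes-Brinkman flow past one porous platelet aggregate.

    Parameters
    ----------
    aggregate : AggregateField
        Occupancy / porosity / permeability lattices on the flow grid.
    params : PhysicalParams
    bc : BoundaryConditions
    agonists : sequence of AgonistSpec for the Peclet classification.
    """

    def __init__(self, aggregate: AggregateField, params: PhysicalParams,
                 bc: BoundaryConditions, agonists=DEFAULT_AGONISTS):
        self.aggregate = aggregate
        self.params = params
        self.bc = bc
        self.agonists = tuple(agonists)

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_stacks(cls, intensity: ImageStack, masks: ImageStack,
                    grid: VoxelGrid, fit: CalibrationFit,
                    params: PhysicalParams | None = None,
                    wall_shear_rate: float = 1600.0,
                    smoothing_length: float = 0.0,
                    clamp=DEFAULT_PHI_CLAMP,
                    agonists=DEFAULT_AGONISTS,
                    lateral: str = "slip") -> "AggregateFlowModel":
        """Image-processing route: masks -> occupancy, intensity -> porosity."""
        params = params or PhysicalParams()
        occ_stack = stack_and_interpolate(masks, masks.spacing[2])
        if smoothing_length > 0:
            occ_stack = smooth_geometry(occ_stack, smoothing_length)
        occupancy = resample_to_grid(occ_stack, grid)
        intensity_lat = resample_to_grid(intensity, grid)
        agg = AggregateField.from_intensity(grid, occupancy, intensity_lat, fit,
                                            params.sphericity, params.d_p, clamp)
        H = grid.shape[2] * grid.h
        bc = BoundaryConditions(wall_shear_rate, H, lateral=lateral)
        return cls(agg, params, bc, agonists)

    @classmethod
    def from_phantom(cls, spec: PhantomSpec | None = None, nz: int = 32,
                     params: PhysicalParams | None = None,
                     wall_shear_rate: float = 1600.0,
                     calibration: CalibrationFit | str = "samples",
                     n_calibration: int = 30,
                     calibration_noise_sd: float = 0.02,
                     smoothing_length: float = 0.0,
                     clamp=DEFAULT_PHI_CLAMP,
                     agonists=DEFAULT_AGONISTS,
                     lateral: str = "slip") -> "AggregateFlowModel":
        """Full synthetic pipeline on a phantom aggregate.

        ``calibration="samples"`` regenerates seeded calibration pairs from
        the phantom's own affine law and fits them (the self-consistent
        default); ``"true"`` uses the phantom coefficients directly; an
        explicit ``CalibrationFit`` bypasses both.
        """
        spec = spec or PhantomSpec()
        params = params or PhysicalParams()
        grid = VoxelGrid.for_channel(spec.height, nz, spec.lx, spec.ly)
        _, intensity, masks = make_phantom(spec)
        if isinstance(calibration, CalibrationFit):
            fit = calibration
        elif calibration == "true":
            fit = CalibrationFit(spec.slope, spec.intercept, 0.0, 2)
        elif calibration == "samples":
            samples = make_calibration_samples(spec.slope, spec.intercept,
                                               n_calibration,
                                               calibration_noise_sd,
                                               seed=spec.seed + 1)
            fit = fit_intensity_density(samples)
        else:
            raise ValueError("calibration must be 'samples', 'true' or a CalibrationFit")
        return cls.from_stacks(intensity, masks, grid, fit, params,
                               wall_shear_rate, smoothing_length, clamp,
                               agonists, lateral)

    # -- solving -----------------------------------------------------------

    @property
    def sigma(self) -> np.ndarray:
        """Cell-centered Darcy coefficient lattice (g mm^-3 s^-1)."""
        return assemble_darcy_coefficient(self.aggregate, self.params)

    def fit(self, settings: SolverSettings | None = None) -> "AggregateFlowResults":
        """Run the pseudo-time march to steady state."""
        field, report = solve_steady(self.params, self.bc, self.sigma,
                                     self.aggregate.grid, settings)
        return AggregateFlowResults(self, field, report)

    solve = fit

    def with_porosity(self, eps) -> "AggregateFlowModel":
        """Same geometry and flow problem with a prescribed porosity
        (uniform value or lattice); used by sensitivity sweeps."""
        agg = AggregateField.from_porosity(self.aggregate.grid,
                                           self.aggregate.occupancy, eps,
                                           self.params.sphericity,
                                           self.params.d_p)
        return AggregateFlowModel(agg, self.params, self.bc, self.agonists)

    def with_wall_shear_rate(self, gamma_w: float) -> "AggregateFlowModel":
        bc = replace(self.bc, gamma_w=gamma_w)
        return AggregateFlowModel(self.aggregate, self.params, bc, self.agonists)


class AggregateFlowResults:
    """Converged flow solution plus derived fields and diagnostics."""

    def __init__(self, model: AggregateFlowModel, field: FlowField,
                 convergence: ConvergenceReport):
        self.model = model
        self.flow = field
        self.convergence = convergence

    @cached_property
    def derived(self) -> DerivedFieldSet:
        return DerivedFieldSet.compute(self.flow, self.model.sigma,
                                       self.model.params.mu,
                                       self.model.params.d_p,
                                       self.model.agonists)

    @cached_property
    def summary_stats(self) -> FlowSummary:
        return summarize(self.flow, self.model.aggregate, self.model.sigma,
                         self.model.params.d_p, self.model.bc.gamma_w,
                         self.model.agonists)

    @property
    def diagnostics(self) -> dict:
        return {
            "max_divergence": check_divergence(self.flow),
            "flux_mismatch": self.flow.flux_mismatch(),
            "steps": self.convergence.steps,
            "dt": self.convergence.dt,
            "final_residual": self.convergence.final_residual,
        }

    def summary_frame(self) -> pd.DataFrame:
        return self.summary_stats.to_frame()

    def summary(self) -> str:
        """Human-readable run report."""
        s = self.summary_stats
        d = self.diagnostics
        lines = [
            "Aggregate flow results",
            "=" * 58,
            f"wall shear rate          {s.wall_shear_rate:12.6g} 1/s",
            f"intrathrombus speed      {s.intra_speed_mean:12.4g} +/- {s.intra_speed_sd:.4g} mm/s",
            f"extra-thrombus speed     {s.extra_speed_mean:12.4g} +/- {s.extra_speed_sd:.4g} mm/s",
            f"kinetic force per voxel  {s.force_mean:12.4g} +/- {s.force_sd:.4g} N",
        ]
        for name in s.peclet_mean:
            lines.append(
                f"Peclet [{name:8s}]       {s.peclet_mean[name]:12.4g} +/- "
                f"{s.peclet_sd[name]:.4g}   advection-dominated "
                f"{s.advection_dominated_pct[name]:.2f}%")
        lines += [
            "-" * 58,
            f"cells: {s.n_intra} intrathrombus / {s.n_extra} extra-thrombus",
            f"converged in {d['steps']} steps (dt = {d['dt']:.3g} s, "
            f"residual {d['final_residual']:.2e})",
            f"max divergence {d['max_divergence']:.2e}, "
            f"flux mismatch {d['flux_mismatch']:.2e}",
        ]
        return "\n".join(lines)

    def save(self, outdir) -> dict:
        """Write VTK fields and the summary CSV; returns written paths."""
        from pathlib import Path

        from .vtkio import write_structured_points

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        grid = self.model.aggregate.grid
        der = self.derived
        agg = self.model.aggregate
        paths = {}
        for name, fields in {
            "occupancy": {"occupancy": agg.occupancy},
            "porosity": {"porosity": agg.eps},
            "permeability": {"permeability_mm2": agg.k},
            "velocity": {"speed_mm_per_s": self.flow.speed(),
                         "pressure_Pa": self.flow.p},
            "shear": {"shear_rate_1_per_s": der.shear_rate,
                      "shear_stress_Pa": der.shear_stress,
                      "elongation_rate_1_per_s": der.elongation},
            "transport": {"force_N": der.force,
                          **{f"peclet_{k}": v for k, v in der.peclet.items()}},
        }.items():
            path = outdir / f"{name}.vtk"
            write_structured_points(path, grid, fields)
            paths[name] = str(path)
        csv = outdir / "summary.csv"
        self.summary_frame().to_csv(csv, index=False)
        paths["summary"] = str(csv)
        hist = outdir / "convergence.csv"
        pd.DataFrame(self.convergence.residual_history,
                     columns=["step", "residual"]).to_csv(hist, index=False)
        paths["convergence"] = str(hist)
        # raw state for postprocessing without re-solving
        npz = outdir / "fields.npz"
        np.savez_compressed(
            npz, u=self.flow.u, v=self.flow.v, w=self.flow.w, p=self.flow.p,
            shape=np.array(grid.shape), h=grid.h, v_ref=self.flow.v_ref,
            occupancy=agg.occupancy, phi=agg.phi, eps=agg.eps, k=agg.k,
            sigma=self.model.sigma, d_p=self.model.params.d_p,
            gamma_w=self.model.bc.gamma_w)
        paths["fields"] = str(npz)
        return paths
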