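"""Derived hemodynamic fields and summary statistics.

From a converged flow field this module computes the strain-rate tensor
``D = (grad u + grad u^T) / 2``, the shear-rate magnitude
``gdot = sqrt(2 D:D)`` and shear stress ``sigma = mu * gdot``, the uniaxial
elongation rate ``edot = sqrt((du/dx)^2 + (dv/dy)^2 + (dw/dz)^2)`` relevant
to von Willebrand factor unfolding, the per-voxel Darcy (kinetic) force the
flow exerts on the porous matrix, and per-agonist Peclet fields
``Pe = |u| L / D_diff`` with the platelet diameter as characteristic length
L.  Cells with ``Pe > 1`` (strictly) are advection-dominated: the agonist is
washed over a platelet faster than it can diffuse across one.

Summary statistics follow the core-shell reading of the aggregate:
*intrathrombus* cells are those with occupancy >= 0.5, *extra-thrombus* is
the entire remaining fluid domain; Peclet statistics are taken inside the
aggregate only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .flow import FlowField

__all__ = [
    "AgonistSpec",
    "DEFAULT_AGONISTS",
    "DerivedFieldSet",
    "FlowSummary",
    "VWFThresholdMaps",
    "velocity_gradients",
    "strain_and_shear",
    "elongation_rate",
    "darcy_force",
    "peclet",
    "advection_dominated_fraction",
    "vwf_threshold_maps",
    "recovered_wall_shear",
    "summarize",
    "porosity_sweep",
]

#: shear rate above which VWF is expected to unfold (1/s); inclusive
VWF_SHEAR_THRESHOLD = 5000.0
#: elongation rate above which VWF is expected to unfold (1/s); inclusive
VWF_ELONGATION_THRESHOLD = 1000.0

# g mm / s^2 -> N
_FORCE_TO_N = 1e-6


@dataclass(frozen=True)
class AgonistSpec:
    """A soluble agonist with its free-flow diffusion coefficient (mm^2/s)."""

    name: str
    molecular_weight: float  # g/mol, informational
    d_diff: float

    def __post_init__(self):
        if self.d_diff <= 0:
            raise ValueError("diffusion coefficient must be positive")


#: calcium, ADP and coagulation Factor X, in order of decreasing diffusivity
DEFAULT_AGONISTS = (
    AgonistSpec("Ca2+", 40.08, 6.64e-4),
    AgonistSpec("ADP", 472.201, 2.57e-4),
    AgonistSpec("FactorX", 59000.0, 5e-5),
)


def velocity_gradients(fieldf: FlowField) -> np.ndarray:
    """All nine cell-centered velocity derivatives, shape (3, 3, nx, ny, nz).

    Diagonal entries come directly from the staggered face differences
    (exact at cell centers); off-diagonal entries use centered differences
    of the cell-centered components, one-sided at boundaries.
    """
    g = fieldf.grid
    if min(g.shape) < 2:
        raise ValueError("gradients need at least 2 cells along every axis")
    h = g.h
    uc, vc, wc = fieldf.cell_center_velocity()
    grad = np.empty((3, 3) + g.shape)
    for a, comp in enumerate((uc, vc, wc)):
        for b in range(3):
            grad[a, b] = np.gradient(comp, h, axis=b)
    grad[0, 0] = np.diff(fieldf.u, axis=0) / h
    grad[1, 1] = np.diff(fieldf.v, axis=1) / h
    grad[2, 2] = np.diff(fieldf.w, axis=2) / h
    return grad


def strain_and_shear(fieldf: FlowField, mu: float
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Strain-rate tensor D (s^-1), shear-rate magnitude and shear stress.

    Returns ``(D, gdot, stress)`` with ``D`` of shape (3, 3, nx, ny, nz),
    ``gdot = sqrt(2 D:D)`` and ``stress = mu * gdot`` (Pa in mm-g-s units).
    """
    grad = velocity_gradients(fieldf)
    D = 0.5 * (grad + np.swapaxes(grad, 0, 1))
    gdot = np.sqrt(2.0 * np.einsum("ab...,ab...->...", D, D))
    return D, gdot, mu * gdot


def elongation_rate(fieldf: FlowField) -> np.ndarray:
    """Uniaxial elongation rate: magnitude of the diagonal of D (s^-1)."""
    g = fieldf.grid
    if min(g.shape) < 2:
        raise ValueError("gradients need at least 2 cells along every axis")
    h = g.h
    dudx = np.diff(fieldf.u, axis=0) / h
    dvdy = np.diff(fieldf.v, axis=1) / h
    dwdz = np.diff(fieldf.w, axis=2) / h
    return np.sqrt(dudx ** 2 + dvdy ** 2 + dwdz ** 2)


def darcy_force(fieldf: FlowField, sigma: np.ndarray,
                cell_volume: float | None = None) -> np.ndarray:
    """Per-voxel kinetic (Darcy drag) force magnitude in N.

    ``f = sigma_D * |u| * V_cell`` per cell; exactly zero outside the
    aggregate because sigma_D is.  The force *density* is ``sigma_D |u|``.
    """
    V = fieldf.grid.cell_volume if cell_volume is None else cell_volume
    if V <= 0:
        raise ValueError("cell volume must be positive")
    return np.asarray(sigma) * fieldf.speed() * V * _FORCE_TO_N


def peclet(fieldf: FlowField, agonist: AgonistSpec, d_p: float) -> np.ndarray:
    """Local Peclet lattice Pe = |u| * D_p / D_diff (dimensionless)."""
    return fieldf.speed() * d_p / agonist.d_diff


def advection_dominated_fraction(pe: np.ndarray, occupied: np.ndarray) -> float:
    """Percentage of intrathrombus cells with Pe strictly above 1.

    Returns NaN for an empty aggregate (the fraction is undefined).
    """
    occupied = np.asarray(occupied, dtype=bool)
    n = occupied.sum()
    if n == 0:
        return float("nan")
    return 100.0 * float((np.asarray(pe)[occupied] > 1.0).sum()) / float(n)


@dataclass(frozen=True)
class VWFThresholdMaps:
    """Boolean exceedance maps for VWF unfolding (thresholds inclusive)."""

    shear: np.ndarray        # gdot >= 5000 1/s
    elongation: np.ndarray   # edot >= 1000 1/s
    shear_fraction: float    # % of all cells
    elongation_fraction: float


def vwf_threshold_maps(gdot: np.ndarray, edot: np.ndarray,
                       shear_threshold: float = VWF_SHEAR_THRESHOLD,
                       elongation_threshold: float = VWF_ELONGATION_THRESHOLD,
                       ) -> VWFThresholdMaps:
    shear = np.asarray(gdot) >= shear_threshold
    elong = np.asarray(edot) >= elongation_threshold
    return VWFThresholdMaps(shear, elong,
                            100.0 * float(shear.mean()),
                            100.0 * float(elong.mean()))


def recovered_wall_shear(fieldf: FlowField) -> float:
    """Wall shear rate recovered from the computed profile (1/s).

    Fits a quadratic through the three x,y-averaged streamwise velocities
    nearest each wall and evaluates its slope on the wall; exact for any
    quadratic profile, hence insensitive to the O(h^2) offset of the
    staggered wall treatment.  Returns the average of the two walls.
    """
    g = fieldf.grid
    if g.shape[2] < 3:
        raise ValueError("need at least 3 cells across the channel height")
    vc = 0.5 * (fieldf.v[:, :-1] + fieldf.v[:, 1:])
    prof = vc.mean(axis=(0, 1))
    z = g.cell_centers(2)
    H = g.shape[2] * g.h
    bot = np.polyfit(z[:3], prof[:3], 2)
    top = np.polyfit(H - z[-3:], prof[-3:], 2)
    return float(0.5 * (bot[1] + top[1]))


@dataclass(frozen=True)
class DerivedFieldSet:
    """All derived lattices for one converged run."""

    strain: np.ndarray                       # (3,3,...) s^-1
    shear_rate: np.ndarray                   # s^-1
    shear_stress: np.ndarray                 # Pa
    elongation: np.ndarray                   # s^-1
    force: np.ndarray                        # N per voxel
    peclet: dict = field(default_factory=dict)   # name -> lattice
    vwf: VWFThresholdMaps | None = None

    @classmethod
    def compute(cls, fieldf: FlowField, sigma: np.ndarray, mu: float,
                d_p: float, agonists=DEFAULT_AGONISTS) -> "DerivedFieldSet":
        D, gdot, stress = strain_and_shear(fieldf, mu)
        edot = elongation_rate(fieldf)
        force = darcy_force(fieldf, sigma)
        pe = {a.name: peclet(fieldf, a, d_p) for a in agonists}
        return cls(D, gdot, stress, edot, force, pe, vwf_threshold_maps(gdot, edot))


@dataclass(frozen=True)
class FlowSummary:
    """Table-style summary of one run (means +/- sd; percentages in [0,100])."""

    wall_shear_rate: float
    intra_speed_mean: float
    intra_speed_sd: float
    extra_speed_mean: float
    extra_speed_sd: float
    force_mean: float
    force_sd: float
    peclet_mean: dict
    peclet_sd: dict
    advection_dominated_pct: dict
    n_intra: int
    n_extra: int

    def to_frame(self) -> pd.DataFrame:
        row = {
            "wall_shear_rate_1_per_s": self.wall_shear_rate,
            "intrathrombus_speed_mm_per_s": self.intra_speed_mean,
            "intrathrombus_speed_sd": self.intra_speed_sd,
            "extrathrombus_speed_mm_per_s": self.extra_speed_mean,
            "extrathrombus_speed_sd": self.extra_speed_sd,
            "kinetic_force_N": self.force_mean,
            "kinetic_force_sd": self.force_sd,
        }
        for name in self.peclet_mean:
            row[f"peclet_{name}"] = self.peclet_mean[name]
            row[f"peclet_{name}_sd"] = self.peclet_sd[name]
            row[f"advection_dominated_pct_{name}"] = self.advection_dominated_pct[name]
        row["n_intrathrombus_cells"] = self.n_intra
        row["n_extrathrombus_cells"] = self.n_extra
        return pd.DataFrame([row])


def summarize(fieldf: FlowField, agg, sigma: np.ndarray, d_p: float,
              wall_shear_rate: float, agonists=DEFAULT_AGONISTS) -> FlowSummary:
    """Per-region statistics of one converged run.

    Intrathrombus cells are ``agg.occupied``; the extra-thrombus region is
    every other cell of the fluid domain.  Force and Peclet statistics are
    intrathrombus-only.  With no occupied cell the intrathrombus entries are
    NaN (reported as undefined, not an error).
    """
    occ = agg.occupied
    speed = fieldf.speed()
    intra = speed[occ]
    extra = speed[~occ]

    def _stats(x):
        if x.size == 0:
            return float("nan"), float("nan")
        return float(x.mean()), float(x.std())

    i_mean, i_sd = _stats(intra)
    e_mean, e_sd = _stats(extra)
    force = darcy_force(fieldf, sigma)
    f_mean, f_sd = _stats(force[occ])
    pe_mean, pe_sd, adv = {}, {}, {}
    for a in agonists:
        pe = peclet(fieldf, a, d_p)
        pe_mean[a.name], pe_sd[a.name] = _stats(pe[occ])
        adv[a.name] = advection_dominated_fraction(pe, occ)
    return FlowSummary(wall_shear_rate, i_mean, i_sd, e_mean, e_sd,
                       f_mean, f_sd, pe_mean, pe_sd, adv,
                       int(occ.sum()), int((~occ).sum()))


def porosity_sweep(runner, porosity_specs, wall_shear_rates) -> pd.DataFrame:
    """Cross product of porosity specifications and wall shear rates.

    ``runner(porosity_spec, wsr)`` must return a ``FlowSummary``;
    ``porosity_specs`` may mix uniform values (floats) and ``(lo, hi)``
    ranges.  Failed runs are recorded in the ``error`` column and the sweep
    continues.  Returns one tidy row per combination.
    """
    rows = []
    for spec in porosity_specs:
        label = (f"{spec:g}" if np.isscalar(spec)
                 else f"{spec[0]:g}-{spec[1]:g}")
        for wsr in wall_shear_rates:
            row = {"porosity": label, "wall_shear_rate": wsr, "error": ""}
            try:
                summary = runner(spec, wsr)
                row["intrathrombus_speed_mm_per_s"] = summary.intra_speed_mean
                for name, pct in summary.advection_dominated_pct.items():
                    row[f"advection_dominated_pct_{name}"] = pct
            except Exception as exc:  # keep sweeping, record the failure
                row["error"] = f"{type(exc).__name__}: {exc}"
            rows.append(row)
    return pd.DataFrame(rows)
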