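"""Porous-medium description of a platelet aggregate.

The fluorescence intensity recorded inside an aggregate is (affinely)
proportional to the local platelet volume fraction phi.  This module
calibrates that map by ordinary least squares on counted samples, converts
intensity to phi (with a configurable clamp, since an affine calibration can
leave [0, 1]), forms the porosity ``eps = 1 - phi`` and closes the problem
with the Kozeny-Carman permeability

    k = Phi_s**2 * eps**3 * D_p**2 / (150 * (1 - eps)**2)   [mm^2]

where ``Phi_s`` is the platelet sphericity and ``D_p`` the platelet
diameter.  The resulting Darcy coefficient ``mu / k`` enters the momentum
equation as a volumetric drag inside the aggregate and is exactly zero in
the free lumen.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .imaging import OCCUPANCY_THRESHOLD, VoxelGrid

__all__ = [
    "CalibrationFit",
    "AggregateField",
    "fit_intensity_density",
    "intensity_to_volume_fraction",
    "kozeny_carman",
    "porosity_range_map",
    "DEFAULT_PHI_CLAMP",
]

#: default clamp on the platelet volume fraction before Kozeny-Carman
DEFAULT_PHI_CLAMP = (0.05, 0.95)


@dataclass(frozen=True)
class CalibrationFit:
    """OLS line of counted volume fraction on fluorescence intensity."""

    slope: float        # fraction per a.u.
    intercept: float    # fraction
    resid_sd: float
    n: int

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("a calibration fit needs >= 2 samples")
        if not np.isfinite(self.slope):
            raise ValueError("slope must be finite")

    def __call__(self, intensity):
        return self.slope * np.asarray(intensity) + self.intercept

    def report(self) -> str:
        return (f"intensity-density calibration: slope = {self.slope:.6g} /a.u., "
                f"intercept = {self.intercept:.4g}, residual sd = {self.resid_sd:.3g}, "
                f"n = {self.n}")


def fit_intensity_density(samples) -> CalibrationFit:
    """Least-squares calibration of volume fraction against intensity."""
    i = np.asarray(samples.intensity, dtype=float)
    f = np.asarray(samples.fraction, dtype=float)
    if np.ptp(i) == 0:
        raise ValueError("degenerate design: all intensities identical")
    res = stats.linregress(i, f)
    resid = f - (res.slope * i + res.intercept)
    dof = max(i.size - 2, 1)
    return CalibrationFit(float(res.slope), float(res.intercept),
                          float(np.sqrt(resid @ resid / dof)), int(i.size))


def intensity_to_volume_fraction(intensity: np.ndarray, occupied: np.ndarray,
                                 fit: CalibrationFit,
                                 clamp: tuple[float, float] = DEFAULT_PHI_CLAMP,
                                 ) -> np.ndarray:
    """phi = slope * I + intercept inside the aggregate, clamped; 0 outside."""
    lo, hi = clamp
    if not (0.0 < lo < hi < 1.0):
        raise ValueError("clamp bounds must satisfy 0 < lo < hi < 1")
    phi = np.clip(fit(intensity), lo, hi)
    return np.where(occupied, phi, 0.0)


def kozeny_carman(eps: np.ndarray, sphericity: float = 0.71,
                  diameter: float = 2e-3, occupied: np.ndarray | None = None,
                  ) -> np.ndarray:
    """Permeability (mm^2) of a packed bed of platelets at porosity ``eps``.

    ``eps`` must lie strictly inside (0, 1) wherever ``occupied`` (clamping
    is the caller's job); non-occupied cells return 0.
    """
    eps = np.asarray(eps, dtype=float)
    if occupied is None:
        occupied = np.ones(eps.shape, dtype=bool)
    vals = eps[occupied]
    if vals.size and (vals.min() <= 0.0 or vals.max() >= 1.0):
        raise ValueError("porosity must lie strictly in (0, 1) where occupied; "
                         "clamp the volume fraction upstream")
    k = np.zeros_like(eps)
    e = eps[occupied]
    k[occupied] = sphericity ** 2 * e ** 3 * diameter ** 2 / (150.0 * (1.0 - e) ** 2)
    return k


def porosity_range_map(intensity: np.ndarray, occupied: np.ndarray,
                       eps_range: tuple[float, float]) -> np.ndarray:
    """Affine remap of intensity to a prescribed porosity range.

    Inside the aggregate the minimum intensity maps to ``eps_hi`` and the
    maximum to ``eps_lo`` (brighter means denser, hence less porous).  A
    degenerate range gives a uniform porosity, as does a constant intensity
    field (midpoint of the range).  Used for sensitivity sweeps over the
    porosity calibration.
    """
    eps_lo, eps_hi = eps_range
    if not (0.0 < eps_lo <= eps_hi < 1.0):
        raise ValueError("need 0 < eps_lo <= eps_hi < 1")
    occupied = np.asarray(occupied, dtype=bool)
    if not occupied.any():
        raise ValueError("empty aggregate: no occupied cells to map")
    eps = np.zeros(np.asarray(intensity).shape)
    vals = np.asarray(intensity, dtype=float)[occupied]
    lo, hi = vals.min(), vals.max()
    if eps_lo == eps_hi or lo == hi:
        eps[occupied] = 0.5 * (eps_lo + eps_hi)
    else:
        t = (np.asarray(intensity, dtype=float)[occupied] - lo) / (hi - lo)
        eps[occupied] = eps_hi + (eps_lo - eps_hi) * t
    return eps


@dataclass(frozen=True)
class AggregateField:
    """Co-registered occupancy / phi / porosity / permeability on a flow grid.

    ``occupied`` is the boolean intrathrombus classification
    (occupancy >= 0.5); ``eps + phi == 1`` exactly there, ``k > 0`` there and
    the Darcy coefficient ``mu / k`` is identically zero everywhere else.
    """

    grid: VoxelGrid
    occupancy: np.ndarray
    phi: np.ndarray
    eps: np.ndarray
    k: np.ndarray
    threshold: float = OCCUPANCY_THRESHOLD

    def __post_init__(self):
        shape = self.grid.shape
        for name in ("occupancy", "phi", "eps", "k"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != shape:
                raise ValueError(f"{name} lattice shape {arr.shape} != grid {shape}")
            object.__setattr__(self, name, arr)
        occ = self.occupied
        if not np.allclose(self.eps[occ] + self.phi[occ], 1.0, atol=1e-12):
            raise ValueError("eps + phi must equal 1 on occupied cells")
        if occ.any() and self.k[occ].min() <= 0:
            raise ValueError("permeability must be positive where occupied")

    @property
    def occupied(self) -> np.ndarray:
        return self.occupancy >= self.threshold

    def darcy_coefficient(self, mu: float) -> np.ndarray:
        """sigma_D = mu / k on occupied cells, 0 elsewhere (g mm^-3 s^-1)."""
        sigma = np.zeros(self.grid.shape)
        occ = self.occupied
        sigma[occ] = mu / self.k[occ]
        if not np.isfinite(sigma).all():
            raise ValueError("non-finite Darcy coefficient (bad permeability)")
        return sigma

    @classmethod
    def from_intensity(cls, grid: VoxelGrid, occupancy: np.ndarray,
                       intensity: np.ndarray, fit: CalibrationFit,
                       sphericity: float = 0.71, diameter: float = 2e-3,
                       clamp: tuple[float, float] = DEFAULT_PHI_CLAMP,
                       ) -> "AggregateField":
        """Standard route: calibrated intensity -> phi -> eps -> k."""
        occ = np.asarray(occupancy) >= OCCUPANCY_THRESHOLD
        phi = intensity_to_volume_fraction(intensity, occ, fit, clamp)
        eps = np.where(occ, 1.0 - phi, 0.0)
        k = kozeny_carman(eps, sphericity, diameter, occ)
        return cls(grid, np.asarray(occupancy, dtype=float), phi, eps, k)

    @classmethod
    def from_porosity(cls, grid: VoxelGrid, occupancy: np.ndarray,
                      eps: np.ndarray | float, sphericity: float = 0.71,
                      diameter: float = 2e-3) -> "AggregateField":
        """Prescribed-porosity route (uniform value or full lattice), used by
        the porosity sensitivity sweeps."""
        occ = np.asarray(occupancy) >= OCCUPANCY_THRESHOLD
        eps_lat = np.zeros(grid.shape)
        eps_lat[occ] = eps if np.isscalar(eps) else np.asarray(eps)[occ]
        phi = np.where(occ, 1.0 - eps_lat, 0.0)
        k = kozeny_carman(eps_lat, sphericity, diameter, occ)
        return cls(grid, np.asarray(occupancy, dtype=float), phi, eps_lat, k)
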