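"""Synthetic platelet aggregates, image stacks and calibration samples.

Real perfusion-chamber image data are not distributed with this package, so
every downstream stage is exercised on seeded phantoms that reproduce the
statistical structure the pipeline assumes:

* a wall-attached ellipsoidal-cap aggregate with a dense *core* and a looser
  *shell* (platelet volume fraction ``phi_core > phi_shell``), blended by a
  cubic smoothstep over a finite transition width;
* a fluorescence intensity that is an affine function of the local platelet
  volume fraction, ``phi = a * I + b``, plus additive Gaussian noise clipped
  at zero (fluorescence is recorded in arbitrary units);
* per-slice binary outline masks, the synthetic counterpart of the
  DIC-image segmentations.

One integer seed drives all stochastic draws; the occupancy geometry itself
is deterministic given the specification (noise touches the intensity only).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from .imaging import ImageStack, write_stack

__all__ = [
    "PhantomSpec",
    "CalibrationSampleSet",
    "make_phantom",
    "make_calibration_samples",
    "write_phantom",
    "DEFAULT_PHANTOM",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, microstructure and imaging parameters of a synthetic aggregate.

    Lengths in mm, volume fractions dimensionless.  The aggregate is half an
    ellipsoid with semi-axes ``(rx, ry, rz)`` attached to the bottom wall
    (z = 0) at footprint center ``(cx, cy)``; platelet volume fraction is
    ``phi_core`` for normalized radius below ``r_core`` and decays to
    ``phi_shell`` over ``transition_width``.  ``slope``/``intercept`` define
    the affine intensity map ``phi = slope * I + intercept`` (defaults from
    the 1600 1/s calibration: slope 0.0014, intercept 0.28).
    """

    height: float = 0.1            # channel height H
    lx: float = 0.1                # lateral extent
    ly: float = 0.2                # streamwise extent
    center: tuple[float, float] = (0.05, 0.08)
    semi_axes: tuple[float, float, float] = (0.035, 0.045, 0.03)
    phi_core: float = 0.75
    phi_shell: float = 0.35
    r_core: float = 0.5            # core radius as fraction of the cap radius
    transition_width: float = 0.008
    slope: float = 0.0014          # fraction per a.u.
    intercept: float = 0.28        # fraction
    noise_sd: float = 5.0          # intensity a.u.
    voxel: float = 1e-3            # isotropic voxel spacing (1 um)
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.phi_shell < self.phi_core < 1.0):
            raise ValueError("need 0 < phi_shell < phi_core < 1")
        if min(self.height, self.lx, self.ly, *self.semi_axes, self.voxel) <= 0:
            raise ValueError("all lengths must be positive")
        if self.transition_width < 0:
            raise ValueError("transition width must be non-negative")
        if not (0.0 < self.r_core < 1.0):
            raise ValueError("core radius fraction must lie in (0, 1)")
        if self.slope == 0:
            raise ValueError("intensity slope must be nonzero")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")
        cx, cy = self.center
        rx, ry, rz = self.semi_axes
        if (cx - rx < 0 or cx + rx > self.lx or cy - ry < 0 or cy + ry > self.ly
                or rz > self.height):
            raise ValueError(
                "aggregate exceeds the channel box: footprint "
                f"[{cx - rx:.4f}, {cx + rx:.4f}] x [{cy - ry:.4f}, {cy + ry:.4f}] mm, "
                f"height {rz:.4f} mm must fit in "
                f"[0, {self.lx}] x [0, {self.ly}] x [0, {self.height}] mm"
            )


DEFAULT_PHANTOM = PhantomSpec()


@dataclass(frozen=True)
class CalibrationSampleSet:
    """(intensity, counted platelet volume fraction) pairs.

    Emulates the manual platelet counting used to calibrate the
    intensity-to-density map; fractions lie in [0, 1].
    """

    intensity: np.ndarray
    fraction: np.ndarray
    region_size: float = 5e-3
    seed: int = 0

    def __post_init__(self):
        i = np.asarray(self.intensity, dtype=float)
        f = np.asarray(self.fraction, dtype=float)
        if i.ndim != 1 or i.shape != f.shape or i.size < 2:
            raise ValueError("need >= 2 matching (intensity, fraction) pairs")
        if f.min() < 0 or f.max() > 1:
            raise ValueError("fractions must lie in [0, 1]")
        object.__setattr__(self, "intensity", i)
        object.__setattr__(self, "fraction", f)

    def to_csv(self, path) -> None:
        np.savetxt(path, np.column_stack([self.intensity, self.fraction]),
                   delimiter=",", header="intensity,fraction", comments="")

    @classmethod
    def from_csv(cls, path) -> "CalibrationSampleSet":
        arr = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        return cls(arr[:, 0], arr[:, 1])


def _smoothstep(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def make_phantom(spec: PhantomSpec) -> tuple[ImageStack, ImageStack, ImageStack]:
    """Generate (true phi, intensity, per-slice masks) stacks for a phantom.

    Voxel centers sit at ``(i + 1/2) * voxel`` so a centered aggregate is
    exactly mirror-symmetric about the mid-x plane.  The intensity is the
    inverse affine map of phi plus seeded Gaussian noise, clipped at 0 and
    zero outside the aggregate; the mask stack is the z-slices of the
    occupancy.  Identical seeds give bit-identical output.
    """
    s = spec.voxel
    nx = int(round(spec.lx / s))
    ny = int(round(spec.ly / s))
    nz = int(round(spec.height / s))
    x = (np.arange(nx) + 0.5) * s
    y = (np.arange(ny) + 0.5) * s
    z = (np.arange(nz) + 0.5) * s
    cx, cy = spec.center
    rx, ry, rz = spec.semi_axes
    rho = np.sqrt(((x[:, None, None] - cx) / rx) ** 2
                  + ((y[None, :, None] - cy) / ry) ** 2
                  + (z[None, None, :] / rz) ** 2)
    occupied = rho <= 1.0

    width_norm = spec.transition_width / float(np.mean(spec.semi_axes))
    if width_norm == 0:
        blend = (rho > spec.r_core).astype(float)
    else:
        blend = _smoothstep((rho - spec.r_core) / width_norm)
    phi = np.where(occupied, spec.phi_core - (spec.phi_core - spec.phi_shell) * blend, 0.0)

    intensity = np.where(occupied, (phi - spec.intercept) / spec.slope, 0.0)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        intensity = intensity + np.where(
            occupied, rng.normal(0.0, spec.noise_sd, size=intensity.shape), 0.0)
    intensity = np.clip(intensity, 0.0, None)

    spacing = (s, s, s)
    origin = (0.5 * s, 0.5 * s, 0.5 * s)  # voxel centers at (i + 1/2) s
    phi_stack = ImageStack(phi, spacing, origin, kind="intensity")
    intensity_stack = ImageStack(intensity, spacing, origin, kind="intensity")
    mask_stack = ImageStack(occupied.astype(np.uint8), spacing, origin, kind="mask")
    return phi_stack, intensity_stack, mask_stack


def make_calibration_samples(slope: float, intercept: float, n: int,
                             noise_sd: float, seed: int,
                             intensity_range: tuple[float, float] = (0.0, 400.0),
                             ) -> CalibrationSampleSet:
    """Seeded (intensity, fraction) pairs on the line ``phi = a*I + b``.

    Intensities are uniform over ``intensity_range``; fractions get additive
    Gaussian noise of standard deviation ``noise_sd`` and are clipped to
    [0, 1].
    """
    if n < 2:
        raise ValueError("need at least two calibration samples")
    rng = np.random.default_rng(seed)
    intensity = rng.uniform(*intensity_range, size=n)
    fraction = slope * intensity + intercept
    if noise_sd > 0:
        fraction = fraction + rng.normal(0.0, noise_sd, size=n)
    fraction = np.clip(fraction, 0.0, 1.0)
    return CalibrationSampleSet(intensity, fraction, seed=seed)


def write_phantom(spec: PhantomSpec, outdir) -> dict:
    """Write intensity and mask TIFF stacks plus a YAML sidecar; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    phi, intensity, masks = make_phantom(spec)
    paths = {
        "intensity": outdir / "intensity.tif",
        "masks": outdir / "masks.tif",
        "sidecar": outdir / "phantom.yaml",
    }
    write_stack(intensity, paths["intensity"])
    write_stack(masks, paths["masks"])
    spec_dict = {k: (list(v) if isinstance(v, tuple) else v)
                 for k, v in asdict(spec).items()}
    sidecar = {"spacing_mm": list(intensity.spacing), "seed": spec.seed,
               "spec": spec_dict}
    paths["sidecar"].write_text(yaml.safe_dump(sidecar, sort_keys=False))
    return {k: str(v) for k, v in paths.items()}
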