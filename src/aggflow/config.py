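"""Validated run configuration (YAML-backed).

One structured-text file captures everything needed to reproduce a run:
phantom or input-stack description, grid resolution, physical parameters,
boundary conditions, calibration source, clamp bounds, solver settings,
agonist registry, sweep specification and the master seed.  Unknown keys
are rejected so a typo cannot silently fall back to a default.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields as dc_fields
from pathlib import Path

import yaml

from .flow import PhysicalParams, SolverSettings
from .metrics import AgonistSpec, DEFAULT_AGONISTS
from .phantoms import PhantomSpec
from .porous import DEFAULT_PHI_CLAMP

__all__ = ["RunConfig", "load_config"]


@dataclass(frozen=True)
class InputStacks:
    """Paths to user-supplied TIFF stacks instead of a phantom."""

    intensity: str
    masks: str
    spacing: tuple[float, float, float] = (1e-3, 1e-3, 1e-3)


@dataclass(frozen=True)
class CalibrationConfig:
    """Where the intensity-density calibration comes from.

    ``mode``: ``samples`` (generate seeded pairs from the phantom law and
    fit them), ``true`` (use the phantom coefficients directly),
    ``explicit`` (slope/intercept given here) or ``csv`` (fit pairs from
    ``file``).
    """

    mode: str = "samples"
    slope: float | None = None
    intercept: float | None = None
    file: str | None = None
    n: int = 30
    noise_sd: float = 0.02

    def __post_init__(self):
        if self.mode not in ("samples", "true", "explicit", "csv"):
            raise ValueError(f"unknown calibration mode '{self.mode}'")
        if self.mode == "explicit" and (self.slope is None or self.intercept is None):
            raise ValueError("explicit calibration needs slope and intercept")
        if self.mode == "csv" and not self.file:
            raise ValueError("csv calibration needs a file path")


@dataclass(frozen=True)
class SweepConfig:
    porosities: tuple = (0.5, 0.7, 0.9)
    ranges: tuple = ()
    wall_shear_rates: tuple = (1600.0,)


@dataclass(frozen=True)
class RunConfig:
    """Full description of one pipeline invocation."""

    output_dir: str = "runs/aggflow"
    seed: int = 0
    nz: int = 32
    wall_shear_rates: tuple = (800.0, 1600.0, 4000.0)
    lateral: str = "slip"
    smoothing_length: float = 0.0
    clamp: tuple = DEFAULT_PHI_CLAMP
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    input: InputStacks | None = None
    physics: PhysicalParams = field(default_factory=PhysicalParams)
    solver: SolverSettings = field(default_factory=SolverSettings)
    calibration: CalibrationConfig = field(default_factory=CalibrationConfig)
    agonists: tuple = DEFAULT_AGONISTS
    sweep: SweepConfig = field(default_factory=SweepConfig)

    def to_dict(self) -> dict:
        d = asdict(self)
        return _tuples_to_lists(d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw or {})
        kwargs = {}
        nested = {
            "phantom": PhantomSpec,
            "input": InputStacks,
            "physics": PhysicalParams,
            "solver": SolverSettings,
            "calibration": CalibrationConfig,
            "sweep": SweepConfig,
        }
        allowed = {f.name for f in dc_fields(cls)}
        unknown = set(raw) - allowed
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for name, sub_cls in nested.items():
            if name in raw and raw[name] is not None:
                kwargs[name] = _build(sub_cls, raw.pop(name), name)
            elif name in raw:
                raw.pop(name)
        if "agonists" in raw:
            kwargs["agonists"] = tuple(
                _build(AgonistSpec, a, "agonists") for a in raw.pop("agonists"))
        for key, val in raw.items():
            kwargs[key] = tuple(val) if isinstance(val, list) else val
        return cls(**kwargs)


def _build(sub_cls, raw, where):
    if not isinstance(raw, dict):
        raise ValueError(f"config section '{where}' must be a mapping")
    allowed = {f.name for f in dc_fields(sub_cls)}
    unknown = set(raw) - allowed
    if unknown:
        raise ValueError(f"unknown keys in '{where}': {sorted(unknown)}")
    kwargs = {k: (tuple(v) if isinstance(v, list) else v) for k, v in raw.items()}
    return sub_cls(**kwargs)


def _tuples_to_lists(obj):
    if isinstance(obj, dict):
        return {k: _tuples_to_lists(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_tuples_to_lists(v) for v in obj]
    return obj


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    return RunConfig.from_dict(raw)
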