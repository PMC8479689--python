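"""Configuration dataclasses and YAML loading.

All internal computation is in SI units; the YAML interface uses the
laboratory units of the underlying experiment (mW, μm, μm/s, pN, μN/m,
mPa·s) with the unit embedded in the key name.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Optional, Sequence

import yaml

from .errors import ConfigError

#: speed of light in vacuum, m/s
SPEED_OF_LIGHT = 2.99792458e8


def _require_finite(name: str, value: float) -> list[str]:
    if value is None or not math.isfinite(value):
        return [f"{name} must be finite, got {value!r}"]
    return []


@dataclass(frozen=True)
class OpticalConfig:
    """Laser/beam/medium parameters of the trap-force model.

    Defaults reflect a 1064-nm near-infrared tweezer with ~30 mW at the
    objective trapping red blood cells suspended in aqueous serum.  The
    beam waist, medium index and cell/medium index ratio are instrument
    and sample properties that must be configured per experiment; the
    defaults (3 μm waist, n_medium 1.334, index ratio 1.05) are
    representative values, not measured ones.
    """

    power: float = 30e-3            # W at the trap
    beam_waist: float = 3e-6        # m, minimum spot size w0
    wavelength: float = 1064e-9     # m, metadata only
    n_medium: float = 1.334         # refractive index of the suspending medium
    index_ratio: float = 1.05       # cell index / medium index (m); force vanishes at 1
    light_speed: float = SPEED_OF_LIGHT

    def __post_init__(self) -> None:
        problems = []
        for f in fields(self):
            problems += _require_finite(f.name, getattr(self, f.name))
        if not problems:
            if self.power <= 0:
                problems.append("power must be > 0")
            if self.beam_waist <= 0:
                problems.append("beam_waist must be > 0")
            if self.n_medium < 1:
                problems.append("n_medium must be >= 1")
            if self.index_ratio <= 0:
                problems.append("index_ratio must be > 0")
            if self.light_speed <= 0:
                problems.append("light_speed must be > 0")
        if problems:
            raise ConfigError("invalid OpticalConfig: " + "; ".join(problems))


@dataclass(frozen=True)
class CellOpticalGeometry:
    """Thin-cylinder cell geometry entering the trap-force model.

    The cell is a cylinder of radius ``radius`` and thickness
    ``thickness`` (thickness << radius) whose centre of mass sits
    ``trap_offset`` metres from the trap centre along the polarization
    (drag) axis.
    """

    radius: float                   # m
    thickness: float = 1.0e-6       # m
    trap_offset: float = 0.0        # m, >= 0

    def __post_init__(self) -> None:
        problems = []
        for f in fields(self):
            problems += _require_finite(f.name, getattr(self, f.name))
        if not problems:
            if self.radius <= 0:
                problems.append("radius must be > 0")
            if self.thickness <= 0:
                problems.append("thickness must be > 0")
            elif self.thickness >= self.radius:
                problems.append("thickness must be < radius (thin-cylinder model)")
            if self.trap_offset < 0:
                problems.append("trap_offset must be >= 0")
        if problems:
            raise ConfigError("invalid CellOpticalGeometry: " + "; ".join(problems))


@dataclass(frozen=True)
class FluidConfig:
    """Viscous medium for the stage-motion drag force.

    ``shape_factor`` multiplies the Stokes sphere drag 6πηrv to absorb
    disc geometry and wall proximity; default 1.0 (plain Stokes).
    """

    viscosity: float = 1.0e-3       # Pa·s (water/serum at room temperature)
    shape_factor: float = 1.0

    def __post_init__(self) -> None:
        problems = []
        for f in fields(self):
            problems += _require_finite(f.name, getattr(self, f.name))
        if not problems:
            if self.viscosity <= 0:
                problems.append("viscosity must be > 0")
            if self.shape_factor <= 0:
                problems.append("shape_factor must be > 0")
        if problems:
            raise ConfigError("invalid FluidConfig: " + "; ".join(problems))


@dataclass(frozen=True)
class StageMotion:
    """Constant-speed stage translation along the polarization axis."""

    speed: float                    # m/s, >= 0
    direction: int = 1              # sign along the polarization axis

    def __post_init__(self) -> None:
        problems = _require_finite("speed", self.speed)
        if not problems and self.speed < 0:
            problems.append("speed must be >= 0")
        if self.direction not in (-1, 1):
            problems.append("direction must be -1 or +1")
        if problems:
            raise ConfigError("invalid StageMotion: " + "; ".join(problems))


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of one synthetic cohort.

    Two modes share the class:

    * ``morphology`` — free-cell size survey; requires ``diameter_mean``
      and ``diameter_sd`` (μm).
    * ``elasticity`` — trap-and-stretch experiment; requires
      ``radius_mean``/``radius_range`` (μm), force and stiffness means,
      and a seven-entry subgroup drag-force target list (pN) from which
      stage speeds are back-solved.

    Dispersion parameters (coefficients of variation, compression sd,
    noise) are generator defaults, not measured quantities.
    """

    label: str                      # "HbAS" | "HbSS" | "SCT" | "SCA" (free text)
    mode: str                       # "morphology" | "elasticity"
    n_cells: int
    # morphology mode
    diameter_mean: Optional[float] = None      # μm
    diameter_sd: Optional[float] = None        # μm
    # elasticity mode
    radius_mean: Optional[float] = None        # μm, free r_max
    radius_range: Optional[tuple[float, float]] = None  # μm truncation bounds
    trap_compression_pct_mean: Optional[float] = None   # % reduction free->trapped
    trap_compression_pct_sd: Optional[float] = None
    trap_force_mean_pN: Optional[float] = None
    trap_force_cv: float = 0.25
    drag_force_mean_pN: Optional[float] = None
    subgroup_drag_targets_pN: Optional[tuple[float, ...]] = None
    subgroup_speeds_um_s: Optional[tuple[float, ...]] = None
    stiffness_mean: Optional[float] = None     # μN/m
    stiffness_cv: float = 0.25
    force_model: str = "statistical"           # "statistical" | "physical"
    # shared
    axis_ratio_mean: float = 1.05
    axis_ratio_sd: float = 0.03
    noise: float = 0.002            # multiplicative measurement-noise sd (fraction)
    seed: int = 0

    def __post_init__(self) -> None:
        problems = []
        if self.mode not in ("morphology", "elasticity"):
            problems.append(f"mode must be morphology|elasticity, got {self.mode!r}")
        if self.n_cells < 1:
            problems.append("n_cells must be >= 1")
        if self.noise < 0:
            problems.append("noise must be >= 0")
        if self.axis_ratio_mean < 1:
            problems.append("axis_ratio_mean must be >= 1")
        if self.axis_ratio_sd < 0:
            problems.append("axis_ratio_sd must be >= 0")
        if self.force_model not in ("statistical", "physical"):
            problems.append("force_model must be statistical|physical")
        if self.mode == "morphology":
            if self.diameter_mean is None or self.diameter_mean <= 0:
                problems.append("diameter_mean must be set and > 0")
            if self.diameter_sd is None or self.diameter_sd < 0:
                problems.append("diameter_sd must be set and >= 0")
        elif self.mode == "elasticity":
            if self.radius_mean is None or self.radius_mean <= 0:
                problems.append("radius_mean must be set and > 0")
            if self.radius_range is None:
                problems.append("radius_range must be set")
            elif not (self.radius_range[0] < self.radius_mean < self.radius_range[1]):
                problems.append("radius_range must bracket radius_mean")
            for name in ("trap_compression_pct_mean", "trap_force_mean_pN",
                         "drag_force_mean_pN", "stiffness_mean"):
                v = getattr(self, name)
                if v is None or v <= 0:
                    problems.append(f"{name} must be set and > 0")
            if self.trap_compression_pct_sd is None or self.trap_compression_pct_sd < 0:
                problems.append("trap_compression_pct_sd must be set and >= 0")
            if self.trap_force_cv < 0 or self.stiffness_cv < 0:
                problems.append("coefficients of variation must be >= 0")
            if self.n_cells % 7 != 0:
                problems.append("n_cells must be divisible into 7 subgroups")
            if (self.subgroup_drag_targets_pN is not None
                    and len(self.subgroup_drag_targets_pN) != 7):
                problems.append("subgroup_drag_targets_pN must have 7 entries")
            if (self.subgroup_speeds_um_s is not None
                    and len(self.subgroup_speeds_um_s) != 7):
                problems.append("subgroup_speeds_um_s must have 7 entries")
        if problems:
            raise ConfigError(
                f"invalid CohortConfig ({self.label!r}): " + "; ".join(problems))


@dataclass(frozen=True)
class RunConfig:
    """Top-level run configuration bundling all blocks."""

    optics: OpticalConfig = field(default_factory=OpticalConfig)
    fluid: FluidConfig = field(default_factory=FluidConfig)
    cohorts: tuple[CohortConfig, ...] = ()
    pixel_size_um: float = 0.05
    seed: int = 0


def _optics_from_block(block: dict) -> OpticalConfig:
    return OpticalConfig(
        power=block.get("power_mW", 30.0) * 1e-3,
        beam_waist=block.get("beam_waist_um", 3.0) * 1e-6,
        wavelength=block.get("wavelength_nm", 1064.0) * 1e-9,
        n_medium=block.get("n_medium", 1.334),
        index_ratio=block.get("index_ratio", 1.05),
    )


def _fluid_from_block(block: dict) -> FluidConfig:
    return FluidConfig(
        viscosity=block.get("viscosity_mPa_s", 1.0) * 1e-3,
        shape_factor=block.get("shape_factor", 1.0),
    )


def _cohort_from_block(block: dict) -> CohortConfig:
    kwargs = dict(block)
    if "radius_range" in kwargs:
        kwargs["radius_range"] = tuple(kwargs["radius_range"])
    for key in ("subgroup_drag_targets_pN", "subgroup_speeds_um_s"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    try:
        return CohortConfig(**kwargs)
    except TypeError as exc:  # unknown field name
        raise ConfigError(f"invalid cohort block: {exc}") from exc


def load_run_config(path) -> RunConfig:
    """Parse a YAML run configuration into a validated :class:`RunConfig`."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    io_block = doc.get("io", {})
    return RunConfig(
        optics=_optics_from_block(doc.get("optics", {})),
        fluid=_fluid_from_block(doc.get("fluid", {})),
        cohorts=tuple(_cohort_from_block(b) for b in doc.get("cohorts", [])),
        pixel_size_um=io_block.get("pixel_size_um", 0.05),
        seed=doc.get("seed", 0),
    )
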