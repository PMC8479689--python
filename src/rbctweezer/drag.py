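"""Stage-motion drag force on a trapped cell.

At constant stage speed the trapped cell sits in equilibrium: the viscous
drag is equal and opposite to the trap force, so drag is the calibrated
handle on the stretching force.  The model is Stokes sphere drag with a
dimensionless ``shape_factor`` absorbing disc geometry and wall proximity:

    F_drag = shape_factor · 6π η r v.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .config import FluidConfig, StageMotion
from .errors import DegenerateFitError, InvalidArgumentError


def drag_force(fluid: FluidConfig, cell_radius: float, motion: StageMotion) -> float:
    """Drag force magnitude (N) on a cell of ``cell_radius`` (m) at ``motion``.

    Linear in both speed and radius; zero at zero speed.
    """
    if not (math.isfinite(cell_radius) and cell_radius > 0):
        raise InvalidArgumentError(f"cell_radius must be > 0, got {cell_radius!r}")
    return fluid.shape_factor * 6.0 * math.pi * fluid.viscosity * cell_radius * motion.speed


@dataclass(frozen=True)
class CalibrationResult:
    shape_factor: float
    residuals: tuple[float, ...]    # target - fitted, N


def calibrate_shape_factor(
    target_forces: Sequence[float],
    speeds: Sequence[float],
    fluid: FluidConfig,
    cell_radius: float,
) -> CalibrationResult:
    """Least-squares scalar fit of the drag shape factor.

    Fits ``sf`` so that ``sf * 6π η r v_i`` matches ``target_forces[i]``
    (a through-origin linear regression); used to anchor the drag model
    to measured subgroup mean forces.
    """
    targets = np.asarray(target_forces, dtype=float)
    v = np.asarray(speeds, dtype=float)
    if targets.size == 0 or targets.shape != v.shape:
        raise InvalidArgumentError("target_forces and speeds must be equal-length, nonempty")
    if np.any(v < 0):
        raise InvalidArgumentError("speeds must be >= 0")
    if not (math.isfinite(cell_radius) and cell_radius > 0):
        raise InvalidArgumentError(f"cell_radius must be > 0, got {cell_radius!r}")
    base = 6.0 * math.pi * fluid.viscosity * cell_radius * v
    denom = float(np.dot(base, base))
    if denom == 0.0:
        raise DegenerateFitError("all speeds are zero; shape factor is unidentifiable")
    sf = float(np.dot(targets, base)) / denom
    residuals = tuple(float(r) for r in targets - sf * base)
    return CalibrationResult(shape_factor=sf, residuals=residuals)
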