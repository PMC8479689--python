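"""End-to-end recovery workflows.

These functions chain generator → (imaging) → metrics → statistics and
return the cohort-level quantities the pipeline is designed to estimate.
They are the single implementation used by the command-line
``reproduce`` command, the acceptance script and the test suite.
"""
from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np

from .cohort_stats import compare_cohorts, summarize_cohort
from .config import CohortConfig, FluidConfig, StageMotion
from .drag import drag_force
from .imaging import measure_image
from .metrics import evaluate_table, stiffness
from .synthetic import (GeneratedDataset, generate_elasticity_cohort,
                        generate_morphology_cohort)


def morphology_recovery(
    config: CohortConfig,
    seed: int,
    pixel_size_um: float = 0.05,
    image_size: int = 256,
) -> dict:
    """Render → segment → measure a morphology cohort.

    Returns the sample mean and SD (n−1) of the measured diameters
    2·r_equiv, the quantities the original size survey tabulates.
    """
    ds = generate_morphology_cohort(config, render_images=True,
                                    pixel_size_um=pixel_size_um,
                                    image_size=image_size, seed=seed)
    diameters = np.array([2.0 * measure_image(img).r_equiv for img in ds.images])
    return {
        "n": int(diameters.size),
        "mean_diameter_um": float(diameters.mean()),
        "sd_diameter_um": float(diameters.std(ddof=1)),
    }


def elasticity_recovery(
    config: CohortConfig,
    seed: int,
    fluid: FluidConfig = FluidConfig(),
    n_cells: Optional[int] = None,
) -> dict:
    """Generate an elasticity cohort and recompute its cohort means.

    The free radius and trap force are read from the records; the drag
    force is *recomputed* per cell from its recorded radius and subgroup
    stage speed through the drag model; the stiffness is recomputed per
    cell as ΔF/ΔR by the metrics module.  ``n_cells`` overrides the
    config's size (must stay divisible by 7).
    """
    if n_cells is not None and n_cells != config.n_cells:
        config = dataclasses.replace(config, n_cells=n_cells)
    ds = generate_elasticity_cohort(config, fluid=fluid, seed=seed)
    free_rmax = np.array([r.free.r_max for r in ds.records])
    trap = np.array([r.trap_force_pN for r in ds.records])
    drag_recomputed = np.array([
        drag_force(fluid, r.free.r_max * 1e-6,
                   StageMotion(speed=r.stage_speed_um_s * 1e-6)) * 1e12
        for r in ds.records])
    k = np.array([stiffness(r) for r in ds.records])
    return {
        "n": len(ds.records),
        "mean_free_rmax_um": float(free_rmax.mean()),
        "mean_trap_force_pN": float(trap.mean()),
        "mean_drag_force_pN": float(drag_recomputed.mean()),
        "mean_stiffness_uN_per_m": float(k.mean()),
        "dataset": ds,
    }


SIGNIFICANCE_METRICS = ("pct_dr_free", "pct_dr_stretch", "stiffness_uN_per_m")


def cohort_comparison(
    config_a: CohortConfig,
    config_b: CohortConfig,
    seed: int,
    fluid: FluidConfig = FluidConfig(),
    metrics: tuple[str, ...] = SIGNIFICANCE_METRICS,
) -> dict:
    """Generate both cohorts, evaluate per-cell metrics and compare them."""
    ds_a = generate_elasticity_cohort(config_a, fluid=fluid, seed=seed)
    ds_b = generate_elasticity_cohort(config_b, fluid=fluid, seed=seed + 1)
    table_a = evaluate_table(ds_a.records)
    table_b = evaluate_table(ds_b.records)
    reports = compare_cohorts(table_a, table_b, metrics)
    summaries = (
        [summarize_cohort(table_a[m], metric=f"{config_a.label}:{m}") for m in metrics]
        + [summarize_cohort(table_b[m], metric=f"{config_b.label}:{m}") for m in metrics]
    )
    return {"comparisons": reports, "summaries": summaries,
            "table_a": table_a, "table_b": table_b}
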