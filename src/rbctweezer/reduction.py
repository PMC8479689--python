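"""Sort-and-delete data reduction.

Before summarising or plotting, the analysis removes a stated number of
extreme cells per metric: sort the per-cell table by one metric, delete
``n_low`` cells from the minimum end and ``n_high`` from the maximum
end, and move on to the next step.  The built-in recipes encode the
exact deletion counts used for the published cohort figures; trimming is
deliberately this manual recipe, not a statistical outlier test.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import InsufficientDataError, InvalidArgumentError

#: recipe key -> metrics-table column
KEY_COLUMNS = {
    "trap_force": "trap_force_pN",
    "radius": "free_rmax_um",
    "pct_da": "pct_da_free",
    "axis_ratio": "axis_ratio",
    "stiffness": "stiffness_uN_per_m",
    "drag_force": "drag_force_pN",
    "delta_radius": "delta_radius_um",
}


@dataclass(frozen=True)
class TrimStep:
    """Remove ``n_low`` minima and ``n_high`` maxima after sorting by ``key``."""

    key: str
    n_low: int = 0
    n_high: int = 0

    def __post_init__(self) -> None:
        if self.key not in KEY_COLUMNS:
            raise InvalidArgumentError(
                f"unknown trim key {self.key!r}; valid: {sorted(KEY_COLUMNS)}")
        if self.n_low < 0 or self.n_high < 0:
            raise InvalidArgumentError("n_low and n_high must be >= 0")


@dataclass(frozen=True)
class TrimRecipe:
    name: str
    steps: tuple[TrimStep, ...]

    def __post_init__(self) -> None:
        if not self.steps:
            raise InvalidArgumentError(f"recipe {self.name!r} has no steps")

    @property
    def total_removed(self) -> int:
        return sum(s.n_low + s.n_high for s in self.steps)


@dataclass(frozen=True)
class TrimAudit:
    """Removed cell ids per step, in application order."""

    recipe: str
    removed: tuple[tuple[str, tuple[str, ...]], ...] = ()  # (key, cell_ids)

    @property
    def total_removed(self) -> int:
        return sum(len(ids) for _, ids in self.removed)


# Built-in recipes for the two published free-vs-trapped cohort figures.
# HbSS: 2 min + 1 max by trap force; 2 min + 2 max by radius;
#       1 min + 3 max by area percent difference  -> 11 removed, 38 of 49 left.
# HbAS: 2 min + 2 max by trap force; 1 min + 2 max by radius;
#       3 max by area percent difference          -> 10 removed, 39 of 49 left.
BUILTIN_RECIPES = {
    "hbss_fig6": TrimRecipe("hbss_fig6", (
        TrimStep("trap_force", n_low=2, n_high=1),
        TrimStep("radius", n_low=2, n_high=2),
        TrimStep("pct_da", n_low=1, n_high=3),
    )),
    "hbas_fig6": TrimRecipe("hbas_fig6", (
        TrimStep("trap_force", n_low=2, n_high=2),
        TrimStep("radius", n_low=1, n_high=2),
        TrimStep("pct_da", n_low=0, n_high=3),
    )),
}


def trim_extremes(table: pd.DataFrame, step: TrimStep) -> tuple[pd.DataFrame, tuple[str, ...]]:
    """Apply one trim step to a per-cell metrics table.

    Sorts ascending by the step's metric (ties broken by ``cell_id`` so
    the removal set is independent of input order), removes the stated
    counts from each end, and returns the survivors in their original
    order plus the removed cell ids.
    """
    if "cell_id" not in table.columns:
        raise InvalidArgumentError("table must have a cell_id column")
    column = KEY_COLUMNS[step.key]
    if column not in table.columns:
        raise InvalidArgumentError(f"table lacks column {column!r} for key {step.key!r}")
    n = len(table)
    if n <= step.n_low + step.n_high:
        raise InsufficientDataError(
            f"cannot remove {step.n_low}+{step.n_high} of {n} records")
    order = table.sort_values([column, "cell_id"], kind="mergesort")
    drop_labels = (list(order.index[: step.n_low])
                   + list(order.index[n - step.n_high:] if step.n_high else []))
    drop = pd.Index(drop_labels, dtype=table.index.dtype)
    removed_ids = tuple(sorted(table.loc[drop, "cell_id"].tolist()))
    kept = table.drop(index=drop)
    return kept, removed_ids


def apply_recipe(table: pd.DataFrame, recipe: TrimRecipe) -> tuple[pd.DataFrame, TrimAudit]:
    """Apply a recipe's steps sequentially; returns survivors + audit log."""
    current = table
    removed_log: list[tuple[str, tuple[str, ...]]] = []
    for i, step in enumerate(recipe.steps):
        try:
            current, removed = trim_extremes(current, step)
        except (InsufficientDataError, InvalidArgumentError) as exc:
            raise type(exc)(f"recipe {recipe.name!r} step {i} ({step.key}): {exc}") from exc
        removed_log.append((step.key, removed))
    return current, TrimAudit(recipe=recipe.name, removed=tuple(removed_log))
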