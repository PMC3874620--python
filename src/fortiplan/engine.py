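"""Fortification-level computation and the three-axis scenario grid.

Two fortification approaches are implemented:

* **Constant** — one year-round level sized so that a consumer's total
  daily intake reaches a recommendation I_r:

      f_c = max(0, (I_r - I_a) * 100 / F_i)        [ug per 100 g]

  with I_a the current vitamin D intake (diet + supplements, ug/day) and
  F_i the daily consumption of the carrier food (g/day).

* **Seasonally varying** — month-specific levels sized so the serum
  concentration reaches a target L_r given the monthly baseline L_a(m)
  and the intake-to-serum conversion factor c_f (nmol/L per ug/day):

      f_v(m) = max(0, (L_r - L_a(m)) * 100 / (c_f * F_i))

  Months whose baseline already exceeds the target are floored to level 0.

Because changing the added dose every month is impractical, monthly
seasonal levels are clustered into a zero-level *summer* block (the longest
circular run of zero-requirement months) and a single-level *winter* block.
The winter level defaults to the maximum monthly requirement in the block
— the only aggregate that never undershoots the serum target in any winter
month; a mean aggregate is available behind a flag.

The scenario grid spans the model's three axes — current vitamin D intake
percentile, carrier consumption percentile, and the target — for every
carrier, flagging combinations with zero carrier consumption (e.g. the 5th
percentile of juice drinkers) as infeasible rather than failing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .baseline import SerumTrajectory
from .parameters import (
    PERCENTILES,
    ConversionFactor,
    ParameterSet,
    TargetSpec,
    effective_carrier_intake,
    effective_vitd_intake,
)

__all__ = [
    "InfeasibleScenarioError",
    "FortificationPlan",
    "Scenario",
    "constant_fortification",
    "varying_fortification",
    "cluster_plan",
    "constant_plan",
    "seasonal_plan",
    "scenario_grid",
]


class InfeasibleScenarioError(ValueError):
    """The scenario's carrier consumption is zero; no fortification level exists."""


@dataclass(frozen=True)
class Scenario:
    """One cell of the three-axis model: intake percentile x carrier percentile x target."""

    vitd_intake_percentile: str
    carrier_percentile: str
    target: TargetSpec

    def __post_init__(self):
        for label, axis in (
            (self.vitd_intake_percentile, "vitd_intake_percentile"),
            (self.carrier_percentile, "carrier_percentile"),
        ):
            if label not in PERCENTILES:
                raise ValueError(f"{axis}: unknown percentile '{label}'")


@dataclass(frozen=True)
class FortificationPlan:
    """Monthly fortification levels (ug per 100 g) for one carrier.

    ``monthly_levels`` are the levels actually applied each month
    (January-first). In constant mode all twelve are equal. In seasonal
    mode, after clustering, summer months carry level 0 and every winter
    month carries the single ``winter_level``; the raw per-month
    requirements the clustering started from are kept in
    ``monthly_requirements``.
    """

    carrier: str
    mode: str  # "constant" | "seasonal"
    monthly_levels: tuple[float, ...]
    summer_months: frozenset[int] = frozenset()
    winter_months: frozenset[int] = frozenset()
    winter_level: float = 0.0
    monthly_requirements: tuple[float, ...] | None = None
    feasible: bool = True

    def __post_init__(self):
        levels = tuple(float(v) for v in self.monthly_levels)
        if len(levels) != 12:
            raise ValueError(f"expected 12 monthly levels, got {len(levels)}")
        if any(v < 0 for v in levels):
            raise ValueError("fortification levels must be >= 0")
        if self.mode not in ("constant", "seasonal"):
            raise ValueError(f"unknown mode '{self.mode}'")
        if self.mode == "constant" and len(set(levels)) > 1:
            raise ValueError("constant-mode plan must repeat a single level")
        for m in self.summer_months:
            if levels[m - 1] != 0.0:
                raise ValueError(f"summer-cluster month {m} has nonzero level")
        object.__setattr__(self, "monthly_levels", levels)

    def level(self, month: int) -> float:
        return self.monthly_levels[month - 1]


def constant_fortification(i_r: float, i_a: float, f_i: float) -> float:
    """Constant fortification level f_c (ug per 100 g), floored at zero.

    Raises :class:`InfeasibleScenarioError` when ``f_i`` is zero — pick a
    scenario with nonzero carrier consumption (the 5th percentile of juice
    consumers eats none).
    """
    if f_i <= 0:
        raise InfeasibleScenarioError(
            "carrier consumption F_i must be positive; use a scenario with "
            "nonzero consumption of the carrier"
        )
    return max(0.0, (i_r - i_a) * 100.0 / f_i)


def varying_fortification(
    l_r: float,
    trajectory: SerumTrajectory,
    c_f: ConversionFactor | float,
    f_i: float,
    floor: bool = True,
) -> np.ndarray:
    """Monthly seasonal fortification levels f_v (ug per 100 g), January-first.

    With ``floor=False`` the raw (possibly negative) requirements are
    returned; the default floors at zero, matching the convention that a
    baseline already above target needs no fortification.
    """
    cf = c_f.cf if isinstance(c_f, ConversionFactor) else float(c_f)
    if f_i <= 0:
        raise InfeasibleScenarioError(
            "carrier consumption F_i must be positive; use a scenario with "
            "nonzero consumption of the carrier"
        )
    if cf <= 0:
        raise ValueError(f"conversion factor must be positive, got {cf}")
    baseline = np.asarray(trajectory.values, dtype=float)
    levels = (l_r - baseline) * 100.0 / (cf * f_i)
    return np.maximum(levels, 0.0) if floor else levels


def _longest_circular_zero_run(levels: Sequence[float]) -> set[int]:
    """Months (1-based) of the longest circular run of zero levels.

    Ties go to the run starting at the earliest calendar month. Returns the
    empty set when no month is zero, all twelve when every month is.
    """
    zero = [lv == 0.0 for lv in levels]
    if all(zero):
        return set(range(1, 13))
    if not any(zero):
        return set()
    best_start, best_len = None, 0
    for start in range(12):
        if not zero[start]:
            continue
        length = 0
        while length < 12 and zero[(start + length) % 12]:
            length += 1
        if length > best_len:
            best_start, best_len = start, length
    return {(best_start + k) % 12 + 1 for k in range(best_len)}


def cluster_plan(
    monthly_levels: Sequence[float],
    carrier: str = "custom",
    aggregate: str = "max",
    feasible: bool = True,
) -> FortificationPlan:
    """Collapse 12 monthly requirements into a summer/winter two-cluster plan.

    The summer cluster is the longest circular run of consecutive
    zero-requirement months; all remaining months form the winter cluster
    and share one level: their maximum requirement (default, guarantees
    the target every winter month) or their mean (``aggregate="mean"``).
    """
    levels = [float(v) for v in monthly_levels]
    if len(levels) != 12:
        raise ValueError(f"expected 12 monthly levels, got {len(levels)}")
    if any(v < 0 for v in levels):
        raise ValueError("monthly levels must be >= 0")
    if aggregate not in ("max", "mean"):
        raise ValueError(f"unknown aggregate '{aggregate}'")
    summer = _longest_circular_zero_run(levels)
    winter = set(range(1, 13)) - summer
    if winter:
        winter_values = [levels[m - 1] for m in winter]
        winter_level = max(winter_values) if aggregate == "max" else float(
            np.mean(winter_values)
        )
    else:
        winter_level = 0.0
    clustered = tuple(
        0.0 if m in summer else winter_level for m in range(1, 13)
    )
    return FortificationPlan(
        carrier=carrier,
        mode="seasonal",
        monthly_levels=clustered,
        summer_months=frozenset(summer),
        winter_months=frozenset(winter),
        winter_level=winter_level,
        monthly_requirements=tuple(levels),
        feasible=feasible,
    )


def constant_plan(
    params: ParameterSet, carrier: str, scenario: Scenario
) -> FortificationPlan:
    """Constant-mode plan for one grid cell (target must be an intake target)."""
    if scenario.target.kind != "intake":
        raise ValueError("constant fortification requires an intake target")
    profile = params.carrier(carrier)
    f_i = effective_carrier_intake(profile, scenario.carrier_percentile)
    i_a = effective_vitd_intake(params.intake, scenario.vitd_intake_percentile)
    level = constant_fortification(scenario.target.value, i_a, f_i)
    return FortificationPlan(
        carrier=carrier,
        mode="constant",
        monthly_levels=(level,) * 12,
        winter_months=frozenset(range(1, 13)),
        winter_level=level,
        monthly_requirements=(level,) * 12,
    )


def seasonal_plan(
    params: ParameterSet,
    carrier: str,
    scenario: Scenario,
    trajectory: SerumTrajectory,
    cluster: bool = True,
    aggregate: str = "max",
) -> FortificationPlan:
    """Seasonal-mode plan for one grid cell (target must be a serum target)."""
    if scenario.target.kind != "serum":
        raise ValueError("seasonal fortification requires a serum target")
    profile = params.carrier(carrier)
    f_i = effective_carrier_intake(profile, scenario.carrier_percentile)
    levels = varying_fortification(
        scenario.target.value, trajectory, params.conversion, f_i
    )
    if cluster:
        return cluster_plan(levels, carrier=carrier, aggregate=aggregate)
    zero_months = frozenset(m for m in range(1, 13) if levels[m - 1] == 0.0)
    return FortificationPlan(
        carrier=carrier,
        mode="seasonal",
        monthly_levels=tuple(levels),
        summer_months=zero_months,
        winter_months=frozenset(range(1, 13)) - zero_months,
        winter_level=float(levels.max()),
        monthly_requirements=tuple(levels),
    )


def _infeasible_plan(carrier: str, mode: str) -> FortificationPlan:
    return FortificationPlan(
        carrier=carrier,
        mode=mode,
        monthly_levels=(0.0,) * 12,
        summer_months=frozenset(range(1, 13)) if mode == "seasonal" else frozenset(),
        feasible=False,
    )


def scenario_grid(
    params: ParameterSet,
    trajectory: SerumTrajectory,
    carriers: Iterable[str] | None = None,
    cluster: bool = True,
) -> pd.DataFrame:
    """Fortification plans for every carrier x scenario combination.

    Constant mode spans the intake targets, seasonal mode the serum targets;
    both span all 3 x 3 percentile combinations. Cells with zero carrier
    consumption are emitted with ``feasible=False`` and level NaN instead of
    raising. Constant cells occupy one row (``month="all"``); seasonal cells
    twelve rows.
    """
    carriers = list(carriers) if carriers is not None else sorted(params.carriers)
    intake_targets = [t for t in params.targets.values() if t.kind == "intake"]
    serum_targets = [t for t in params.targets.values() if t.kind == "serum"]
    rows = []

    def cell_rows(carrier, mode, target, vp, cp, plan):
        base = {
            "carrier": carrier,
            "mode": mode,
            "target_label": target.label,
            "vitd_percentile": vp,
            "carrier_percentile": cp,
            "feasible": plan is not None,
        }
        if mode == "constant":
            level = plan.monthly_levels[0] if plan is not None else np.nan
            rows.append({**base, "month": "all", "level_ug_per_100g": level})
        else:
            for m in range(1, 13):
                level = plan.level(m) if plan is not None else np.nan
                rows.append({**base, "month": m, "level_ug_per_100g": level})

    for carrier in carriers:
        for cp in PERCENTILES:
            f_i = effective_carrier_intake(params.carrier(carrier), cp)
            for vp in PERCENTILES:
                for target in intake_targets:
                    scen = Scenario(vp, cp, target)
                    plan = None if f_i <= 0 else constant_plan(params, carrier, scen)
                    cell_rows(carrier, "constant", target, vp, cp, plan)
                for target in serum_targets:
                    scen = Scenario(vp, cp, target)
                    plan = (
                        None
                        if f_i <= 0
                        else seasonal_plan(
                            params, carrier, scen, trajectory, cluster=cluster
                        )
                    )
                    cell_rows(carrier, "seasonal", target, vp, cp, plan)

    return pd.DataFrame(
        rows,
        columns=[
            "carrier",
            "mode",
            "target_label",
            "vitd_percentile",
            "carrier_percentile",
            "month",
            "level_ug_per_100g",
            "feasible",
        ],
    )
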