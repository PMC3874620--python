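"""Forward serum response, risk envelopes, UL flags and intake multipliers.

Given a fortification plan, the new monthly serum concentration is the
linear response

    L_n(m) = L_a(m) + c_f * F_i * level(m) / 100

and the total daily vitamin D intake is ``level(m) * F_i / 100 + I_a``.
Safety is assessed against two thresholds: the tolerable upper intake
level (100 ug/day by default) on intake, and the intoxication region
(serum above 500 nmol/L). Both comparisons are strict: sitting exactly at
a limit does not flag.

The risk envelope evaluates a plan that was sized for the *mean* consumer
on the extremes of the population: the upper envelope combines
95th-percentile carrier consumption with 95th-percentile vitamin D intake,
the lower envelope the 5th/5th combination. A 5th percentile that consumes
none of the carrier (juice) leaves the lower envelope exactly at baseline.

Intake multipliers compare the fortified-food vitamin D dose across
consumption percentiles; the fortification level cancels, so the ratios
reduce to consumption ratios. A zero denominator yields NaN (undefined),
not an exception.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .baseline import SerumTrajectory
from .engine import FortificationPlan
from .parameters import (
    CarrierProfile,
    ConversionFactor,
    ParameterSet,
    effective_carrier_intake,
    effective_vitd_intake,
)

__all__ = [
    "ResponseResult",
    "apply_fortification",
    "total_daily_intake",
    "risk_envelope",
    "intake_multipliers",
    "ul_flags",
]


@dataclass(frozen=True)
class ResponseResult:
    """Monthly serum and intake outcome of applying a plan to a baseline."""

    baseline: tuple[float, ...]  # nmol/L, January-first
    new_values: tuple[float, ...]  # nmol/L
    total_intake_by_month: tuple[float, ...]  # ug/day
    ul_flag_by_month: tuple[bool, ...]  # total intake strictly above the UL
    intox_flag_by_month: tuple[bool, ...]  # serum strictly above intoxication threshold
    region: str = "germany"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "month": range(1, 13),
                "baseline_nmol_L": self.baseline,
                "new_nmol_L": self.new_values,
                "total_intake_ug": self.total_intake_by_month,
                "ul_flag": self.ul_flag_by_month,
                "intox_flag": self.intox_flag_by_month,
            }
        )


def total_daily_intake(level: float, f_i: float, i_a: float) -> float:
    """Total daily vitamin D intake (ug): fortified-carrier dose plus current intake."""
    if level < 0 or f_i < 0 or i_a < 0:
        raise ValueError("level, F_i and I_a must all be non-negative")
    return level * f_i / 100.0 + i_a


def apply_fortification(
    trajectory: SerumTrajectory,
    plan: FortificationPlan,
    f_i: float,
    c_f: ConversionFactor | float,
    i_a: float = 0.0,
    ul_intake: float = 100.0,
    intox_threshold: float = 500.0,
) -> ResponseResult:
    """New monthly serum trajectory and total intakes under a fortification plan.

    ``f_i`` is the consumer's carrier consumption (g/day) — not necessarily
    the one the plan was sized with, which is exactly what risk analysis
    exploits. ``i_a`` (current vitamin D intake, ug/day) enters only the
    intake totals, not the serum response.
    """
    cf = c_f.cf if isinstance(c_f, ConversionFactor) else float(c_f)
    baseline = np.asarray(trajectory.values, dtype=float)
    levels = np.asarray(plan.monthly_levels, dtype=float)
    if baseline.shape != levels.shape:
        raise ValueError("plan and trajectory must cover the same 12 months")
    new_values = baseline + cf * f_i * levels / 100.0
    intakes = levels * f_i / 100.0 + i_a
    return ResponseResult(
        baseline=tuple(baseline),
        new_values=tuple(new_values),
        total_intake_by_month=tuple(intakes),
        ul_flag_by_month=tuple(bool(v) for v in intakes > ul_intake),
        intox_flag_by_month=tuple(bool(v) for v in new_values > intox_threshold),
        region=trajectory.region,
    )


def ul_flags(
    result: ResponseResult,
    ul_intake: float = 100.0,
    intox_threshold: float = 500.0,
) -> ResponseResult:
    """Re-evaluate the safety flags of a response under different thresholds."""
    if ul_intake <= 0 or intox_threshold <= 0:
        raise ValueError("thresholds must be positive")
    intakes = np.asarray(result.total_intake_by_month)
    new_values = np.asarray(result.new_values)
    return ResponseResult(
        baseline=result.baseline,
        new_values=result.new_values,
        total_intake_by_month=result.total_intake_by_month,
        ul_flag_by_month=tuple(bool(v) for v in intakes > ul_intake),
        intox_flag_by_month=tuple(bool(v) for v in new_values > intox_threshold),
        region=result.region,
    )


def risk_envelope(
    params: ParameterSet,
    trajectory: SerumTrajectory,
    plan: FortificationPlan,
) -> tuple[ResponseResult, ResponseResult]:
    """Upper (p95 consumption, p95 intake) and lower (p5/p5) responses to a plan.

    The plan is expected to have been sized for the mean-carrier scenario;
    the envelope then shows what the same product does to extreme
    consumers. Returns ``(upper, lower)``.
    """
    profile = params.carrier(plan.carrier)

    def respond(pct: str) -> ResponseResult:
        f_i = effective_carrier_intake(profile, pct)
        i_a = effective_vitd_intake(params.intake, pct)
        return apply_fortification(
            trajectory,
            plan,
            f_i=f_i,
            c_f=params.conversion,
            i_a=i_a,
            ul_intake=params.ul_intake,
            intox_threshold=params.intoxication_serum,
        )

    return respond("p95"), respond("p5")


def intake_multipliers(
    profile: CarrierProfile, gender: str | None = None
) -> dict[str, float]:
    """Ratios of fortified-food vitamin D intake across consumption percentiles.

    Because every percentile eats the same product, the fortification level
    cancels and each multiplier is a ratio of consumption quantities. With
    ``gender=None`` the scenario-selection convention supplies the
    quantities (max of genders for mean/p95, min for p5); passing ``"men"``
    or ``"women"`` uses that gender's column throughout. A zero denominator
    (e.g. the 5th percentile of juice consumers) yields ``nan``.
    """
    if gender is None:
        q = {p: effective_carrier_intake(profile, p) for p in ("p5", "mean", "p95")}
    else:
        q = {p: profile.grams(p, gender) for p in ("p5", "mean", "p95")}

    def ratio(num: float, den: float) -> float:
        return num / den if den > 0 else math.nan

    return {
        "mean_over_p5": ratio(q["mean"], q["p5"]),
        "p95_over_p5": ratio(q["p95"], q["p5"]),
        "p95_over_mean": ratio(q["p95"], q["mean"]),
    }
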