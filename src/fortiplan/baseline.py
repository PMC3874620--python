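"""Synthetic monthly baseline 25(OH)D trajectories.

The fortification formulas need the population's month-by-month baseline
serum 25(OH)D concentration L_a(m). The upstream bottom-up serum model
that produced those values for Germany publishes only the annual average
(45 nmol/L), so this module generates a synthetic stand-in: a
single-harmonic cosine seasonal cycle

    L_a(m) = annual_mean + region_offset
             - amplitude * cos(2*pi*(m - trough_month)/12)

whose 12-month mean is exactly ``annual_mean + region_offset`` and whose
minimum falls in ``trough_month``. The default amplitude of 17.2 nmol/L is
calibrated so that January (the trough) sits at 27.8 nmol/L, the value
implied by the published January bread example; any externally supplied
12-vector can be used instead via :meth:`SerumTrajectory` directly or
:meth:`SerumTrajectory.from_csv`.

An optional seeded Gaussian noise term (``noise_sd``, default 0) supports
robustness testing; the default trajectory is deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .parameters import BaselineConfig

__all__ = [
    "MONTHS",
    "SeasonalModel",
    "SerumTrajectory",
    "generate_trajectory",
    "calibrate_amplitude",
    "default_trajectory",
]

MONTHS = (
    "Jan", "Feb", "Mar", "Apr", "May", "Jun",
    "Jul", "Aug", "Sep", "Oct", "Nov", "Dec",
)


@dataclass(frozen=True)
class SeasonalModel:
    """Single-harmonic seasonal model of baseline serum 25(OH)D (nmol/L).

    Parameters
    ----------
    annual_mean
        Population annual average concentration, nmol/L.
    amplitude
        Half the peak-to-trough seasonal swing, nmol/L; must be >= 0.
    trough_month
        Calendar month (1 = January) at which the minimum is attained.
    region_offset
        Additive regional shift, nmol/L (default 0).
    noise_sd
        Standard deviation of optional Gaussian month-level noise, nmol/L.
    """

    annual_mean: float = 45.0
    amplitude: float = 17.2
    trough_month: int = 1
    region: str = "germany"
    region_offset: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValueError(f"amplitude must be >= 0, got {self.amplitude}")
        if not 1 <= self.trough_month <= 12:
            raise ValueError(f"trough_month must be in 1..12, got {self.trough_month}")
        if self.annual_mean + self.region_offset - self.amplitude <= 0:
            raise ValueError(
                "trajectory would reach non-positive serum values: "
                f"mean+offset-amplitude = "
                f"{self.annual_mean + self.region_offset - self.amplitude}"
            )
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")

    @classmethod
    def from_config(cls, config: BaselineConfig) -> "SeasonalModel":
        return cls(
            annual_mean=config.annual_mean,
            amplitude=config.amplitude,
            trough_month=config.trough_month,
            region=config.region,
            region_offset=config.region_offset,
            noise_sd=config.noise_sd,
        )


@dataclass(frozen=True)
class SerumTrajectory:
    """Twelve monthly baseline 25(OH)D values, January-first, nmol/L."""

    values: tuple[float, ...]
    region: str = "germany"

    def __post_init__(self):
        values = tuple(float(v) for v in self.values)
        if len(values) != 12:
            raise ValueError(f"expected 12 monthly values, got {len(values)}")
        if any(v <= 0 for v in values):
            raise ValueError("serum concentrations must be positive")
        object.__setattr__(self, "values", values)

    def value(self, month: int) -> float:
        """Baseline concentration for calendar ``month`` (1 = January)."""
        return self.values[month - 1]

    @property
    def annual_mean(self) -> float:
        return float(np.mean(self.values))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "month": range(1, 13),
                "region": self.region,
                "value_nmol_per_L": self.values,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SerumTrajectory":
        df = pd.read_csv(path).sort_values("month")
        region = str(df["region"].iloc[0]) if "region" in df else "unknown"
        return cls(values=tuple(df["value_nmol_per_L"]), region=region)


def generate_trajectory(
    model: SeasonalModel, rng: np.random.Generator | int | None = None
) -> SerumTrajectory:
    """Evaluate the seasonal model at the 12 calendar months.

    With ``noise_sd > 0`` a seeded ``rng`` (Generator or integer seed) adds
    independent Gaussian perturbations; values are clipped away from zero
    to keep concentrations physical.
    """
    months = np.arange(1, 13)
    values = (
        model.annual_mean
        + model.region_offset
        - model.amplitude * np.cos(2 * np.pi * (months - model.trough_month) / 12.0)
    )
    if model.noise_sd > 0:
        rng = np.random.default_rng(rng)
        values = values + rng.normal(0.0, model.noise_sd, size=12)
        values = np.maximum(values, 1e-6)
    return SerumTrajectory(values=tuple(values), region=model.region)


def calibrate_amplitude(
    annual_mean: float,
    anchor_month: int,
    anchor_value: float,
    trough_month: int = 1,
    region_offset: float = 0.0,
) -> float:
    """Amplitude that makes the cosine model hit ``anchor_value`` at ``anchor_month``.

    Inverts the model equation:
    ``amplitude = (annual_mean + region_offset - anchor_value) / cos(...)``.
    Raises if the anchor month sits at a zero of the cosine (a quarter
    period from the trough), where the amplitude is unidentifiable, or if
    the implied amplitude is negative (anchor on the wrong side of the mean).
    """
    c = math.cos(2 * math.pi * (anchor_month - trough_month) / 12.0)
    if abs(c) < 1e-12:
        raise ValueError(
            f"anchor month {anchor_month} is a quarter period from trough month "
            f"{trough_month}; amplitude is unidentifiable there"
        )
    amplitude = (annual_mean + region_offset - anchor_value) / c
    if amplitude < 0:
        raise ValueError(
            f"anchor value {anchor_value} at month {anchor_month} implies a negative "
            f"amplitude ({amplitude:.3f}) for trough month {trough_month}"
        )
    return amplitude


def default_trajectory() -> SerumTrajectory:
    """The deterministic default German baseline (mean 45, January 27.8 nmol/L)."""
    return generate_trajectory(SeasonalModel())
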