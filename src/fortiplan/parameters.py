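"""Model inputs: carrier consumption, vitamin D intake, targets, conversion factor.

All headline inputs of the fortification model live here as validated,
immutable records, loaded from a YAML document whose packaged default
(``data/table1_defaults.yaml``) holds the published German values: carrier
consumption percentiles from the National Nutritional Survey II, dietary
vitamin D intake means, intake recommendations (IOM 15 ug, DGE 20 ug,
UL 100 ug), serum targets (50 and 75 nmol/L) and the intake-to-serum
conversion factor of 2.32 nmol/L per ug/day.

Two selection conventions turn the gendered percentile tables into the
scalar scenario inputs the formulas consume:

* Carrier consumption (``effective_carrier_intake``): for the mean and the
  95th-percentile scenarios the *higher* of the two gender values is used
  — a conservative choice, since larger consumption means a lower
  fortification level suffices; for the 5th-percentile scenario the
  *lower* value is used. This reproduces the published choices including
  the milk exception (at the 5th percentile men drink less than women).
* Dietary intake (``effective_vitd_intake``): the unweighted mean of the
  men/women values at the scenario percentile, plus the mean supplement
  intake (0.3 ug/day by default, applied identically in every scenario).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "PERCENTILES",
    "GENDERS",
    "ParameterError",
    "CarrierProfile",
    "IntakeProfile",
    "TargetSpec",
    "ConversionFactor",
    "BaselineConfig",
    "ParameterSet",
    "load_parameters",
    "save_parameters",
    "default_parameters",
    "effective_carrier_intake",
    "effective_vitd_intake",
]

PERCENTILES = ("p5", "mean", "p95")
GENDERS = ("men", "women")


class ParameterError(ValueError):
    """Invalid or missing model input; the message names the offending field."""


def _validate_percentile_table(table: Mapping[str, Mapping[str, float]], owner: str):
    """Check a (percentile, gender) table: keys, non-negativity, p5 <= mean <= p95."""
    out: dict[str, dict[str, float]] = {}
    for pct in PERCENTILES:
        if pct not in table:
            raise ParameterError(f"{owner}: missing percentile '{pct}'")
        row = table[pct]
        out[pct] = {}
        for gender in GENDERS:
            if gender not in row:
                raise ParameterError(f"{owner}.{pct}: missing gender '{gender}'")
            value = float(row[gender])
            if value < 0:
                raise ParameterError(
                    f"{owner}.{pct}.{gender}: negative value {value!r}"
                )
            out[pct][gender] = value
    for gender in GENDERS:
        p5, mean, p95 = (out[p][gender] for p in PERCENTILES)
        if not (p5 <= mean <= p95):
            raise ParameterError(
                f"{owner}.{gender}: percentile ordering violated "
                f"(p5={p5}, mean={mean}, p95={p95})"
            )
    return out


@dataclass(frozen=True)
class CarrierProfile:
    """Daily consumption of a candidate carrier food, g/day by (percentile, gender)."""

    name: str
    consumption: Mapping[str, Mapping[str, float]]

    def __post_init__(self):
        table = _validate_percentile_table(self.consumption, f"carrier '{self.name}'")
        object.__setattr__(self, "consumption", table)

    def grams(self, percentile: str, gender: str) -> float:
        return self.consumption[percentile][gender]


@dataclass(frozen=True)
class IntakeProfile:
    """Daily vitamin D intake from natural food (ug/day) plus mean supplement intake."""

    dietary: Mapping[str, Mapping[str, float]]
    supplement_mean: float = 0.3

    def __post_init__(self):
        table = _validate_percentile_table(self.dietary, "intake.dietary")
        object.__setattr__(self, "dietary", table)
        if self.supplement_mean < 0:
            raise ParameterError(
                f"intake.supplement_mean: negative value {self.supplement_mean!r}"
            )


@dataclass(frozen=True)
class TargetSpec:
    """A fortification goal: a daily-intake recommendation or a serum concentration.

    ``kind`` is ``"intake"`` (value in ug/day, e.g. IOM 15) or ``"serum"``
    (value in nmol/L, e.g. 75).
    """

    kind: str
    value: float
    label: str = "custom"

    def __post_init__(self):
        if self.kind not in ("intake", "serum"):
            raise ParameterError(f"target '{self.label}': unknown kind {self.kind!r}")
        if self.value <= 0:
            raise ParameterError(
                f"target '{self.label}': value must be positive, got {self.value!r}"
            )


@dataclass(frozen=True)
class ConversionFactor:
    """Serum 25(OH)D rise (nmol/L) per 1 ug/day of vitamin D from fortified food."""

    cf: float = 2.32

    def __post_init__(self):
        if self.cf <= 0:
            raise ParameterError(f"conversion_factor: must be positive, got {self.cf!r}")


@dataclass(frozen=True)
class BaselineConfig:
    """Parameters of the synthetic baseline serum trajectory (see `baseline` module)."""

    annual_mean: float = 45.0
    amplitude: float = 17.2
    trough_month: int = 1
    region: str = "germany"
    region_offset: float = 0.0
    noise_sd: float = 0.0


@dataclass(frozen=True)
class ParameterSet:
    """The complete, validated input set of the fortification model."""

    carriers: Mapping[str, CarrierProfile]
    intake: IntakeProfile
    targets: Mapping[str, TargetSpec]
    conversion: ConversionFactor
    ul_intake: float = 100.0
    intoxication_serum: float = 500.0
    baseline: BaselineConfig = field(default_factory=BaselineConfig)

    def __post_init__(self):
        if self.ul_intake <= 0:
            raise ParameterError(f"limits.ul_intake: must be positive, got {self.ul_intake!r}")
        if self.intoxication_serum <= 0:
            raise ParameterError(
                f"limits.intoxication_serum: must be positive, got {self.intoxication_serum!r}"
            )
        for label, target in self.targets.items():
            if (
                target.kind == "intake"
                and label != "UL"
                and target.value > self.ul_intake
            ):
                raise ParameterError(
                    f"target '{label}': intake recommendation {target.value} ug exceeds "
                    f"the upper limit {self.ul_intake} ug"
                )

    def carrier(self, name: str) -> CarrierProfile:
        try:
            return self.carriers[name]
        except KeyError:
            raise ParameterError(
                f"unknown carrier '{name}' (have: {', '.join(sorted(self.carriers))})"
            ) from None

    def target(self, label: str) -> TargetSpec:
        try:
            return self.targets[label]
        except KeyError:
            raise ParameterError(
                f"unknown target '{label}' (have: {', '.join(sorted(self.targets))})"
            ) from None


def effective_carrier_intake(profile: CarrierProfile, scenario: str) -> float:
    """Scenario carrier consumption F_i (g/day) after the gender-selection rule.

    Mean and p95 scenarios take the maximum over genders (conservative:
    more consumption, lower fortification level); p5 takes the minimum.
    """
    if scenario not in PERCENTILES:
        raise ParameterError(
            f"unknown scenario '{scenario}' (expected one of {PERCENTILES})"
        )
    values = [profile.grams(scenario, g) for g in GENDERS]
    return min(values) if scenario == "p5" else max(values)


def effective_vitd_intake(profile: IntakeProfile, scenario: str) -> float:
    """Scenario vitamin D intake I_a (ug/day): gender-averaged diet + supplements."""
    if scenario not in PERCENTILES:
        raise ParameterError(
            f"unknown scenario '{scenario}' (expected one of {PERCENTILES})"
        )
    dietary = sum(profile.dietary[scenario][g] for g in GENDERS) / len(GENDERS)
    return dietary + profile.supplement_mean


# ---------------------------------------------------------------------------
# YAML (de)serialisation


def _build_parameter_set(doc: Mapping) -> ParameterSet:
    for key in ("carriers", "intake", "targets", "conversion_factor"):
        if key not in doc:
            raise ParameterError(f"config: missing key '{key}'")
    carriers = {
        name: CarrierProfile(name=name, consumption=table)
        for name, table in doc["carriers"].items()
    }
    intake_doc = doc["intake"]
    if "dietary" not in intake_doc:
        raise ParameterError("config: missing key 'intake.dietary'")
    intake = IntakeProfile(
        dietary=intake_doc["dietary"],
        supplement_mean=float(intake_doc.get("supplement_mean", 0.3)),
    )
    targets: dict[str, TargetSpec] = {}
    for label, value in doc["targets"].get("intake", {}).items():
        targets[label] = TargetSpec(kind="intake", value=float(value), label=label)
    for label, value in doc["targets"].get("serum", {}).items():
        targets[label] = TargetSpec(kind="serum", value=float(value), label=label)
    limits = doc.get("limits", {})
    baseline = BaselineConfig(**doc.get("baseline", {}))
    return ParameterSet(
        carriers=carriers,
        intake=intake,
        targets=targets,
        conversion=ConversionFactor(cf=float(doc["conversion_factor"])),
        ul_intake=float(limits.get("ul_intake", 100.0)),
        intoxication_serum=float(limits.get("intoxication_serum", 500.0)),
        baseline=baseline,
    )


def load_parameters(source: str | Path | Mapping | None = None) -> ParameterSet:
    """Load a :class:`ParameterSet` from a YAML file path, a mapping, or the defaults.

    With ``source=None`` the packaged default document (the published German
    inputs) is used.
    """
    if source is None:
        ref = importlib.resources.files("fortiplan.data") / "table1_defaults.yaml"
        doc = yaml.safe_load(ref.read_text())
    elif isinstance(source, Mapping):
        doc = source
    else:
        doc = yaml.safe_load(Path(source).read_text())
    if not isinstance(doc, Mapping):
        raise ParameterError("config: document is not a mapping")
    return _build_parameter_set(doc)


def _to_document(params: ParameterSet) -> dict:
    targets_intake = {
        label: t.value for label, t in params.targets.items() if t.kind == "intake"
    }
    targets_serum = {
        label: t.value for label, t in params.targets.items() if t.kind == "serum"
    }
    return {
        "carriers": {
            name: {p: dict(c.consumption[p]) for p in PERCENTILES}
            for name, c in params.carriers.items()
        },
        "intake": {
            "dietary": {p: dict(params.intake.dietary[p]) for p in PERCENTILES},
            "supplement_mean": params.intake.supplement_mean,
        },
        "targets": {"intake": targets_intake, "serum": targets_serum},
        "conversion_factor": params.conversion.cf,
        "limits": {
            "ul_intake": params.ul_intake,
            "intoxication_serum": params.intoxication_serum,
        },
        "baseline": {
            "annual_mean": params.baseline.annual_mean,
            "amplitude": params.baseline.amplitude,
            "trough_month": params.baseline.trough_month,
            "region": params.baseline.region,
            "region_offset": params.baseline.region_offset,
            "noise_sd": params.baseline.noise_sd,
        },
    }


def save_parameters(params: ParameterSet, path: str | Path) -> None:
    """Write a parameter set back to YAML; ``load_parameters`` round-trips it."""
    Path(path).write_text(yaml.safe_dump(_to_document(params), sort_keys=False))


def default_parameters() -> ParameterSet:
    """The packaged published defaults."""
    return load_parameters(None)
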