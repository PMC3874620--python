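"""End-to-end pipeline: parameters -> baseline -> plans -> response/risk.

``run_pipeline`` chains the stages and writes four artifacts to an output
directory:

* ``plans.csv``        — the full scenario grid of fortification plans
* ``trajectories.csv`` — baseline and fortified serum trajectories for the
                         mean-consumer scenario of every carrier and serum target
* ``risk.csv``         — upper/lower risk-envelope responses to the mean-sized
                         seasonal plans
* ``manifest.json``    — config checksum, package version, seed, timestamp,
                         list of emitted files

Outputs are deterministic for a given config and seed (the seed only
matters when baseline noise is enabled). Floats are serialised with six
significant digits; display rounding to one decimal belongs to the
human-readable report, not to these files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from .baseline import SeasonalModel, SerumTrajectory, generate_trajectory
from .engine import Scenario, scenario_grid, seasonal_plan
from .parameters import ParameterSet, load_parameters, _to_document
from .response import apply_fortification, risk_envelope
from .parameters import effective_carrier_intake, effective_vitd_intake

__all__ = ["RunManifest", "run_pipeline", "PipelineError"]

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.6g"


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class RunManifest:
    """Provenance record for one pipeline run."""

    config_sha256: str
    package_version: str
    seed: int | None
    timestamp: str
    files: tuple[str, ...]


def _config_checksum(params: ParameterSet) -> str:
    canonical = json.dumps(_to_document(params), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()


def _mean_scenario_frames(
    params: ParameterSet, trajectory: SerumTrajectory
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Trajectory and risk tables for mean-sized seasonal plans of every carrier."""
    serum_targets = [t for t in params.targets.values() if t.kind == "serum"]
    traj_rows, risk_rows = [], []
    for carrier in sorted(params.carriers):
        f_i_mean = effective_carrier_intake(params.carrier(carrier), "mean")
        i_a_mean = effective_vitd_intake(params.intake, "mean")
        for target in serum_targets:
            if f_i_mean <= 0:
                logger.info(
                    "skipping %s/%s: zero mean carrier consumption", carrier, target.label
                )
                continue
            scen = Scenario("mean", "mean", target)
            plan = seasonal_plan(params, carrier, scen, trajectory)
            logger.info(
                "carrier=%s target=%s winter level %.2f ug/100 g over %d months",
                carrier, target.label, plan.winter_level, len(plan.winter_months),
            )
            mean_resp = apply_fortification(
                trajectory, plan, f_i=f_i_mean, c_f=params.conversion, i_a=i_a_mean,
                ul_intake=params.ul_intake, intox_threshold=params.intoxication_serum,
            )
            frame = mean_resp.to_frame()
            frame.insert(0, "target_label", target.label)
            frame.insert(0, "carrier", carrier)
            traj_rows.append(frame)
            upper, lower = risk_envelope(params, trajectory, plan)
            for bound, resp in (("upper", upper), ("lower", lower)):
                rframe = resp.to_frame()
                rframe.insert(0, "bound", bound)
                rframe.insert(0, "target_label", target.label)
                rframe.insert(0, "carrier", carrier)
                risk_rows.append(rframe)
    empty_traj = pd.DataFrame(
        columns=["carrier", "target_label", "month", "baseline_nmol_L",
                 "new_nmol_L", "total_intake_ug", "ul_flag", "intox_flag"]
    )
    empty_risk = pd.DataFrame(columns=["carrier", "target_label", "bound", *empty_traj.columns[2:]])
    traj = pd.concat(traj_rows, ignore_index=True) if traj_rows else empty_traj
    risk = pd.concat(risk_rows, ignore_index=True) if risk_rows else empty_risk
    return traj, risk


def run_pipeline(
    config: str | Path | Mapping | None = None,
    outdir: str | Path = "results",
    seed: int | None = None,
) -> RunManifest:
    """Run the full model and write plans.csv, trajectories.csv, risk.csv, manifest.json."""
    try:
        params = load_parameters(config)
    except Exception as exc:
        raise PipelineError(f"parameters stage failed: {exc}") from exc

    try:
        model = SeasonalModel.from_config(params.baseline)
        trajectory = generate_trajectory(model, rng=seed)
    except Exception as exc:
        raise PipelineError(f"baseline stage failed: {exc}") from exc

    try:
        grid = scenario_grid(params, trajectory)
    except Exception as exc:
        raise PipelineError(f"fortification stage failed: {exc}") from exc

    try:
        traj_frame, risk_frame = _mean_scenario_frames(params, trajectory)
    except Exception as exc:
        raise PipelineError(f"response/risk stage failed: {exc}") from exc

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    grid.to_csv(outdir / "plans.csv", index=False, float_format=_FLOAT_FMT)
    traj_frame.to_csv(outdir / "trajectories.csv", index=False, float_format=_FLOAT_FMT)
    risk_frame.to_csv(outdir / "risk.csv", index=False, float_format=_FLOAT_FMT)

    manifest = RunManifest(
        config_sha256=_config_checksum(params),
        package_version=__version__,
        seed=seed,
        timestamp=datetime.now(timezone.utc).isoformat(),
        files=("plans.csv", "trajectories.csv", "risk.csv", "manifest.json"),
    )
    (outdir / "manifest.json").write_text(json.dumps(asdict(manifest), indent=2) + "\n")
    logger.info("pipeline complete: %d grid rows -> %s", len(grid), outdir)
    return manifest
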