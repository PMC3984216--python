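"""Output writing and run manifests.

File names are deterministic, numeric formatting is fixed at six
significant digits, and every output set is accompanied by a manifest
(config checksum, scenario, grid, seed, package version) sufficient to
reproduce the run exactly. Wall-clock timestamps are omitted by default
so that identical runs produce byte-identical output sets.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from .config import ScenarioConfig

__all__ = ["RunManifest", "config_checksum", "write_trajectory", "write_summary",
           "write_manifest", "write_outputs"]

_FLOAT_FORMAT = "%.6g"

_COLUMN_NOTES = (
    "# velodyn trajectory: one row per Euler step (year inclusive of both endpoints).\n"
    "# shares are fractions of commuters; cyclists/commuters are persons;\n"
    "# lv_vkt is km/yr; fatal/serious are annual counts (serious on the\n"
    "# underreporting-adjusted scale); injury_rate_per_1000 is (fatal+serious)\n"
    "# per 1000 cyclists; air_* are annual commuting-attributable counts;\n"
    "# ghg_total_t is CO2eq metric tons/yr; fuel_cost_nzd is $NZ/yr;\n"
    "# deaths_averted_pa is annual all-cause deaths averted by physical activity.\n"
)


def config_checksum(cfg: ScenarioConfig) -> str:
    payload = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=float)
    return hashlib.sha256(payload.encode()).hexdigest()


@dataclass
class RunManifest:
    config_checksum: str
    scenario: str
    start_year: float
    end_year: float
    dt: float
    seed: int | None
    package_version: str
    timestamp: str | None = None

    @classmethod
    def for_run(cls, cfg: ScenarioConfig, seed: int | None = None,
                include_timestamp: bool = False) -> "RunManifest":
        from . import __version__
        return cls(
            config_checksum=config_checksum(cfg),
            scenario=cfg.policy.scenario,
            start_year=cfg.grid.start_year,
            end_year=cfg.grid.end_year,
            dt=cfg.grid.dt,
            seed=seed,
            package_version=__version__,
            timestamp=datetime.now(timezone.utc).isoformat() if include_timestamp else None,
        )


def write_trajectory(traj: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_COLUMN_NOTES)
        traj.to_csv(fh, index=False, float_format=_FLOAT_FORMAT, lineterminator="\n")
    return path


def write_summary(summary: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("# velodyn summary: rows are outcome categories (count: cumulative\n"
                 "# scenario-minus-baseline, negative = saving; nzd_m: $NZ million),\n"
                 "# columns are scenarios.\n")
        summary.to_csv(fh, index=True, float_format=_FLOAT_FORMAT, lineterminator="\n")
    return path


def write_manifest(manifest: RunManifest, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = dataclasses.asdict(manifest)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path


def write_outputs(outdir, trajectories: dict, summary: pd.DataFrame | None,
                  manifest: RunManifest) -> list[Path]:
    """Write a full output set: per-scenario trajectory CSVs, an optional
    summary CSV and the run manifest. Returns the written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, traj in sorted(trajectories.items()):
        written.append(write_trajectory(traj, outdir / f"trajectory_{name}.csv"))
    if summary is not None:
        written.append(write_summary(summary, outdir / "summary.csv"))
    written.append(write_manifest(manifest, outdir / "manifest.json"))
    return written
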