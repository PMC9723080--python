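"""File formats and run provenance.

Longitudinal volumes have no standard interchange format, so cohorts travel
as plain CSV (one row per scan: subject_id, arm, time_months, volume_ml),
survival outcomes as (subject_id, event_time_months, event), and Levin
scores as (subject_id, time_weeks, enhancing_score, nonenhancing_score,
new_lesion_flag, disappearance_flag).  Volumes round-trip at full precision
(written with repr-level floating-point formatting).  Every CLI run also
writes a RunManifest JSON capturing the config, seed, package version, and
output paths, so any run can be reproduced byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence, Union

import pandas as pd
import yaml

from . import __version__
from .exceptions import SchemaError, ValidationError
from .levin import LevinEntry, LevinScoreSeries
from .simulate import SimulationConfig, SubjectRecord, VolumeTrajectory

COHORT_COLUMNS = ["subject_id", "arm", "time_months", "volume_ml"]
SURVIVAL_COLUMNS = ["subject_id", "event_time_months", "event"]
LEVIN_COLUMNS = ["subject_id", "time_weeks", "enhancing_score", "nonenhancing_score"]


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{what} file is missing required column {col!r}")


def write_cohort(records: Sequence[SubjectRecord], path: Union[str, Path]) -> Path:
    """One row per scan; float columns at full (round-trippable) precision."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(",".join(COHORT_COLUMNS) + "\n")
        for rec in records:
            for t, v in zip(rec.trajectory.times, rec.trajectory.volumes):
                fh.write(f"{rec.subject_id},{rec.arm},{float(t)!r},{float(v)!r}\n")
    return path


def read_cohort(path: Union[str, Path]) -> list[SubjectRecord]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, COHORT_COLUMNS, "cohort")
    records = []
    for sid, grp in df.groupby("subject_id", sort=False):
        arms = grp["arm"].unique()
        if len(arms) != 1:
            raise ValidationError(f"subject {sid!r} appears in multiple arms")
        times = grp["time_months"].to_numpy(dtype=float)
        if not (times[1:] > times[:-1]).all():
            raise ValidationError(
                f"subject {sid!r}: scan times must be strictly increasing"
            )
        traj = VolumeTrajectory(str(sid), times, grp["volume_ml"].to_numpy(dtype=float))
        records.append(SubjectRecord(trajectory=traj, arm=str(arms[0])))
    return records


def write_survival(records: Sequence[SubjectRecord], path: Union[str, Path]) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(",".join(SURVIVAL_COLUMNS) + "\n")
        for rec in records:
            if rec.survival is None:
                continue
            t, e = rec.survival
            fh.write(f"{rec.subject_id},{float(t)!r},{int(e)}\n")
    return path


def read_survival(path: Union[str, Path]) -> Dict[str, tuple[float, bool]]:
    df = pd.read_csv(path)
    _require_columns(df, SURVIVAL_COLUMNS, "survival")
    return {
        str(r.subject_id): (float(r.event_time_months), bool(r.event))
        for r in df.itertuples()
    }


def attach_survival(
    cohort: Sequence[SubjectRecord], survival: Dict[str, tuple[float, bool]]
) -> None:
    for rec in cohort:
        if rec.subject_id in survival:
            rec.survival = survival[rec.subject_id]


def read_levin_scores(path: Union[str, Path]) -> list[LevinScoreSeries]:
    df = pd.read_csv(path)
    _require_columns(df, LEVIN_COLUMNS, "Levin score")

    def _score(value) -> Optional[int]:
        return None if pd.isna(value) else int(value)

    series = []
    for sid, grp in df.groupby("subject_id", sort=False):
        entries = [
            LevinEntry(float(r.time_weeks), _score(r.enhancing_score),
                       _score(r.nonenhancing_score))
            for r in grp.itertuples()
        ]
        series.append(LevinScoreSeries(str(sid), entries))
    return series


def write_levin_scores(series: Sequence[LevinScoreSeries], path: Union[str, Path]) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in series:
        for e in s.entries:
            rows.append(
                {
                    "subject_id": s.subject_id,
                    "time_weeks": e.time,
                    "enhancing_score": e.enhancing,
                    "nonenhancing_score": e.nonenhancing,
                }
            )
    pd.DataFrame(rows, columns=LEVIN_COLUMNS).to_csv(path, index=False)
    return path


def load_config(path: Union[str, Path], **overrides) -> SimulationConfig:
    """SimulationConfig from a YAML mapping mirroring its field names."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise SchemaError("config file must be a YAML mapping")
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(raw) - known
    if unknown:
        raise SchemaError(f"unknown config field(s): {sorted(unknown)}")
    if "randomization_ratio" in raw:
        raw["randomization_ratio"] = tuple(raw["randomization_ratio"])
    raw.update(overrides)
    return SimulationConfig(**raw)


def dump_config(config: SimulationConfig, path: Union[str, Path]) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = dataclasses.asdict(config)
    data["randomization_ratio"] = list(data["randomization_ratio"])
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
    return path


@dataclass
class RunManifest:
    """Provenance of one CLI run: enough to reproduce every output byte."""

    command: str
    seed: Optional[int]
    config: Optional[dict]
    outputs: Dict[str, str] = field(default_factory=dict)
    package_version: str = __version__
    started_at: str = ""
    finished_at: str = ""

    def add_output(self, name: str, path: Union[str, Path]) -> None:
        self.outputs[name] = str(path)

    def write(self, path: Union[str, Path]) -> Path:
        path = Path(path)
        self.finished_at = time.strftime("%Y-%m-%dT%H:%M:%S")
        for name, out in self.outputs.items():
            if not Path(out).exists():
                raise ValidationError(f"manifest output {name!r} missing: {out}")
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)
            fh.write("\n")
        return path


def new_manifest(command: str, seed: Optional[int] = None,
                 config: Optional[SimulationConfig] = None) -> RunManifest:
    return RunManifest(
        command=command,
        seed=seed,
        config=None if config is None else dataclasses.asdict(config),
        started_at=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
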