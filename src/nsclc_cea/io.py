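"""CSV / YAML interchange for curves, schedules, traces and run configs.

Digitized KM curves travel as ``time_weeks,survival`` CSVs with an optional
``<stem>_at_risk.csv`` companion (``time_weeks,n_at_risk``).  All outputs
are plain text and deterministic for a given input and seed.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from .calibration import TransitionSchedule
from .cohort import CohortTrace
from .survival import DigitizedKM

__all__ = [
    "read_km",
    "write_km",
    "read_schedule",
    "write_schedule",
    "write_trace",
    "load_config",
    "dump_config",
    "write_provenance",
]


def _at_risk_path(path: Path) -> Path:
    return path.with_name(path.stem + "_at_risk.csv")


def write_km(km: DigitizedKM, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"time_weeks": km.times, "survival": km.survival}).to_csv(path, index=False)
    if km.at_risk is not None:
        pd.DataFrame(
            {"time_weeks": km.times, "n_at_risk": km.at_risk.astype(int)}
        ).to_csv(_at_risk_path(path), index=False)
    return path


def read_km(path: str | Path, endpoint: str) -> DigitizedKM:
    path = Path(path)
    df = pd.read_csv(path)
    at_risk = None
    companion = _at_risk_path(path)
    if companion.exists():
        ar = pd.read_csv(companion)
        merged = df.merge(ar, on="time_weeks", how="left")
        if merged["n_at_risk"].notna().all():
            at_risk = merged["n_at_risk"].to_numpy()
    return DigitizedKM(
        endpoint=endpoint,
        times=df["time_weeks"].to_numpy(),
        survival=df["survival"].to_numpy(),
        at_risk=at_risk,
    )


def write_schedule(schedule: TransitionSchedule, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    schedule.to_frame().to_csv(path, index=False)
    return path


def read_schedule(path: str | Path) -> TransitionSchedule:
    return TransitionSchedule.from_frame(pd.read_csv(path))


def write_trace(trace: CohortTrace, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    trace.to_frame().to_csv(path, index=False)
    return path


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def dump_config(config: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
    return path


def write_provenance(out_dir: str | Path, config: dict, seed: int) -> Path:
    """Record the config hash, seed and package version next to the outputs."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    blob = yaml.safe_dump(config, sort_keys=True).encode()
    record = {
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": seed,
        "package_version": __version__,
    }
    path = out_dir / "provenance.json"
    path.write_text(json.dumps(record, indent=2, sort_keys=True) + "\n")
    return path
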