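"""Trial-bundle disk format.

One directory per trial: ``emg.csv`` (time + 16 channels), ``force.csv``
(time + Fx,Fy,Fz,Mx,My,Mz per plate), ``kin.csv`` (time + CoM + joint
angles + malleoli trajectories), ``sensor.csv`` (time + 0/1 beam state),
``meta.json`` and optional ``truth.json``.  CSV dialect: comma-separated,
header row, UTF-8, '.' decimal; times in seconds.  Schemas are validated on
read; unknown extra columns are warned about and ignored.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError
from .types import JOINTS, MUSCLES, TrialGroundTruth, TrialMeta, TrialRecording

_FLOAT_FMT = "%.10g"

_KIN_REQUIRED = (["time", "com_x", "com_y", "com_z"] + JOINTS
                 + ["malleolus_support_x", "malleolus_support_y",
                    "malleolus_landing_x", "malleolus_landing_y"])
_FORCE_REQUIRED = ["time"] + [f"{q}_{p}" for p in ("L", "R")
                              for q in ("fx", "fy", "fz", "mx", "my", "mz")]


def write_trial_bundle(path: str | Path, trial: TrialRecording,
                       truth: TrialGroundTruth | None = None) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    trial.emg.to_csv(path / "emg.csv", index=False, float_format=_FLOAT_FMT)
    trial.force.to_csv(path / "force.csv", index=False, float_format=_FLOAT_FMT)
    trial.kin.to_csv(path / "kin.csv", index=False, float_format=_FLOAT_FMT)
    trial.sensor.to_csv(path / "sensor.csv", index=False, float_format=_FLOAT_FMT)
    with open(path / "meta.json", "w", encoding="utf-8") as fh:
        json.dump(dataclasses.asdict(trial.meta), fh, indent=1, sort_keys=True)
    if truth is not None:
        with open(path / "truth.json", "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(truth), fh, indent=1, sort_keys=True)
    return path


def _read_csv(path: Path, required: list[str]) -> pd.DataFrame:
    if not path.exists():
        raise DataError(f"missing stream file {path}")
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataError(f"{path.name}: missing required columns {missing}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        warnings.warn(f"{path.name}: ignoring unknown columns {extra}")
        df = df[required]
    if df["time"].size < 2 or not np.all(np.diff(df["time"].to_numpy()) > 0):
        raise DataError(f"{path.name}: time column must be strictly increasing")
    return df


def read_trial_bundle(path: str | Path) -> tuple[TrialRecording, TrialGroundTruth | None]:
    path = Path(path)
    meta_path = path / "meta.json"
    if not meta_path.exists():
        raise DataError(f"missing meta.json in {path}")
    with open(meta_path, "r", encoding="utf-8") as fh:
        raw = json.load(fh)
    try:
        raw["plate_centers"] = {k: tuple(v) for k, v in raw["plate_centers"].items()}
        meta = TrialMeta(**raw)
    except (KeyError, TypeError) as exc:
        raise DataError(f"meta.json in {path}: {exc}") from exc
    emg = _read_csv(path / "emg.csv", ["time"] + MUSCLES)
    force = _read_csv(path / "force.csv", _FORCE_REQUIRED)
    kin = _read_csv(path / "kin.csv", _KIN_REQUIRED)
    sensor = _read_csv(path / "sensor.csv", ["time", "beam"])
    truth = None
    if (path / "truth.json").exists():
        with open(path / "truth.json", "r", encoding="utf-8") as fh:
            truth = TrialGroundTruth(**json.load(fh))
    return TrialRecording(meta=meta, emg=emg, force=force, kin=kin,
                          sensor=sensor), truth


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Deterministic CSV output (fixed float format, no index)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path
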