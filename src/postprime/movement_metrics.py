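"""Preparatory and total CoM measures plus peak-to-peak joint excursions.

Intervals follow the event timeline: the preparatory interval is
[cop_on, step_on] (postural preparation between CoP onset and landing-limb
unloading) and the movement interval is [cop_on, reach_off] — preparation
through target contact; the endpoint is configurable since "duration of
movement" admits either target contact or trial end.
"""

from __future__ import annotations

import math
from typing import Mapping, Optional

import numpy as np

from .config import MovementParams
from .errors import DataError
from .types import EventSet, MovementMetrics, StepCharacteristics


def _window(time_s: np.ndarray, t0: float, t1: float) -> np.ndarray:
    sel = (time_s >= t0 - 1e-9) & (time_s <= t1 + 1e-9)
    return np.flatnonzero(sel)


def preparatory_com_metrics(
    time_s: np.ndarray,
    com_ap: np.ndarray,
    com_ml: np.ndarray,
    events: EventSet,
    min_samples: int = 3,
) -> tuple[float, float, float, float, list[str]]:
    """Peak |CoM acceleration| and excursion per axis on [cop_on, step_on].

    Excursion is max − min of position; acceleration is the peak magnitude
    of the second central difference of the (already smoothed) position.
    Returns (acc_ap, acc_ml, exc_ap, exc_ml, flags); metrics are NaN when
    the interval holds fewer than ``min_samples`` samples.
    """
    if events.cop_on is None:
        return (math.nan,) * 4 + (["no_cop_onset"],)
    if not events.cop_on < events.step_on:
        raise DataError("preparatory interval requires cop_on < step_on")
    idx = _window(time_s, events.cop_on, events.step_on)
    if idx.size < min_samples:
        return (math.nan,) * 4 + (["prep_interval_too_short"],)
    dt = float(np.median(np.diff(time_s)))
    out = []
    for x in (com_ap, com_ml):
        seg = np.asarray(x, dtype=float)[idx]
        acc = np.gradient(np.gradient(seg, dt), dt)
        out.append(float(np.max(np.abs(acc))))
    for x in (com_ap, com_ml):
        seg = np.asarray(x, dtype=float)[idx]
        out.append(float(seg.max() - seg.min()))
    return out[0], out[1], out[2], out[3], []


def total_com_excursion(
    time_s: np.ndarray,
    com_ap: np.ndarray,
    com_ml: np.ndarray,
    events: EventSet,
    movement_end: str = "reach_off",
) -> tuple[float, float]:
    """Peak-to-peak CoM excursion per axis over the movement interval."""
    start = events.cop_on if events.cop_on is not None else events.step_on
    end = events.reach_off if movement_end == "reach_off" else float(time_s[-1])
    idx = _window(time_s, start, end)
    if idx.size < 2:
        raise DataError("movement interval too short for an excursion")
    ap = np.asarray(com_ap, dtype=float)[idx]
    ml = np.asarray(com_ml, dtype=float)[idx]
    return float(ap.max() - ap.min()), float(ml.max() - ml.min())


def peak_joint_excursions(
    time_s: np.ndarray,
    joints: Mapping[str, np.ndarray],
    events: EventSet,
    movement_end: str = "reach_off",
) -> tuple[dict[str, float], list[str]]:
    """Per-joint peak-to-peak excursion (degrees) over the movement interval.

    Missing joints yield no entry and a QC flag rather than an error.
    """
    start = events.cop_on if events.cop_on is not None else events.step_on
    end = events.reach_off if movement_end == "reach_off" else float(time_s[-1])
    idx = _window(time_s, start, end)
    out: dict[str, float] = {}
    flags: list[str] = []
    for joint, trace in joints.items():
        x = np.asarray(trace, dtype=float)
        if x.size != time_s.size:
            flags.append(f"missing_joint:{joint}")
            continue
        seg = x[idx]
        out[joint] = float(seg.max() - seg.min())
    return out, flags


def compute_movement_metrics(
    time_s: np.ndarray,
    com_ap: np.ndarray,
    com_ml: np.ndarray,
    joints: Mapping[str, np.ndarray],
    events: EventSet,
    step: Optional[StepCharacteristics] = None,
    params: Optional[MovementParams] = None,
) -> MovementMetrics:
    params = params or MovementParams()
    acc_ap, acc_ml, exc_ap, exc_ml, flags = preparatory_com_metrics(
        time_s, com_ap, com_ml, events, params.min_prep_samples)
    tot_ap, tot_ml = total_com_excursion(time_s, com_ap, com_ml, events,
                                         params.movement_end)
    jexc, jflags = peak_joint_excursions(time_s, joints, events, params.movement_end)
    return MovementMetrics(
        prep_com_acc_ap=acc_ap, prep_com_acc_ml=acc_ml,
        prep_com_exc_ap=exc_ap, prep_com_exc_ml=exc_ml,
        total_com_exc_ap=tot_ap, total_com_exc_ml=tot_ml,
        joint_excursions_deg=jexc, step=step, flags=flags + jflags,
    )
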