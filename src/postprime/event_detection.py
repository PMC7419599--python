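"""Per-trial event timeline and step characteristics.

Events are reported on the force-plate clock (converted to seconds, snapped
to samples of their source stream); kinematic metrics interpolate to event
times.  Conventions used throughout the package: AP = +x toward the target,
ML = +y leftward, 0-based sample indexing, time zero at recording start.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .config import EventParams
from .errors import DataError, UnanalyzableTrialError
from .types import EventSet, StepCharacteristics, TrialRecording


def _first_sustained(mask: np.ndarray, n_sustain: int) -> Optional[int]:
    """Index of the first run of at least ``n_sustain`` consecutive True."""
    if n_sustain <= 1:
        idx = np.flatnonzero(mask)
        return int(idx[0]) if idx.size else None
    kernel = np.ones(n_sustain, dtype=int)
    runs = np.convolve(mask.astype(int), kernel, mode="valid")
    idx = np.flatnonzero(runs == n_sustain)
    return int(idx[0]) if idx.size else None


def detect_reach_events(time_s: np.ndarray, beam: np.ndarray) -> tuple[float, float]:
    """Reach onset/offset from the binary infrared-beam channel.

    Onset is the first rising edge (hand departs), offset the first edge
    after it (target contact).
    """
    beam = np.asarray(beam)
    values = set(np.unique(beam).tolist())
    if not values <= {0, 1}:
        raise DataError(f"sensor stream is not binary: values {sorted(values)}")
    d = np.diff(beam.astype(int))
    rising = np.flatnonzero(d == 1) + 1
    falling = np.flatnonzero(d == -1) + 1
    if falling.size and (not rising.size or falling[0] < rising[0]):
        raise DataError("target-contact edge precedes hand-departure edge")
    if not rising.size:
        raise UnanalyzableTrialError("no reach onset edge in sensor stream")
    on_idx = rising[0]
    later = falling[falling > on_idx]
    if not later.size:
        raise UnanalyzableTrialError("no target-contact edge after reach onset")
    return float(time_s[on_idx]), float(time_s[later[0]])


def net_cop(force: pd.DataFrame, plate_centers: dict[str, tuple[float, float]]) -> np.ndarray:
    """Net centre of pressure (N×2, AP/ML) from two-plate forces and moments.

    Per plate (surface moments about the plate centre): CoPx = cx − My/Fz,
    CoPy = cy + Mx/Fz; the net CoP is the vertical-load-weighted average.
    Samples where a plate is unloaded get zero weight.
    """
    out = np.empty((len(force), 2))
    num = np.zeros((len(force), 2))
    den = np.zeros(len(force))
    for suffix, (cx, cy) in plate_centers.items():
        fz = force[f"fz_{suffix}"].to_numpy()
        w = np.clip(fz, 0.0, None)
        safe = np.where(np.abs(fz) > 1e-9, fz, np.inf)
        copx = cx - force[f"my_{suffix}"].to_numpy() / safe
        copy_ = cy + force[f"mx_{suffix}"].to_numpy() / safe
        num[:, 0] += w * copx
        num[:, 1] += w * copy_
        den += w
    ok = den > 1e-9
    out[ok] = num[ok] / den[ok, None]
    if not ok.all():
        # carry last valid value through fully unloaded samples
        idx = np.where(ok, np.arange(len(force)), -1)
        np.maximum.accumulate(idx, out=idx)
        out[~ok] = out[np.clip(idx[~ok], 0, None)]
    return out


def detect_cop_onset(
    time_s: np.ndarray,
    cop_xy: np.ndarray,
    params: EventParams,
) -> tuple[Optional[float], str]:
    """Onset of the net-CoP shift preceding landing-limb unloading.

    Trigger: first excursion beyond baseline mean ± ``cop_k_sd`` SD sustained
    for ``cop_sustain_s`` on either axis (the axis that deviates first wins).
    With ``cop_refine="hinge"`` (default), the onset is refined by a
    least-squares one-changepoint ("hinge") fit of the deviation over a
    window around the trigger, which removes the threshold-crossing latency
    of the trigger; ``"threshold"`` reports the raw sustained crossing.
    Returns ``(None, "")`` when no deviation is found.
    """
    cop_xy = np.atleast_2d(np.asarray(cop_xy, dtype=float))
    if cop_xy.shape[0] == 2 and cop_xy.shape[1] != 2:
        cop_xy = cop_xy.T
    dt = float(np.median(np.diff(time_s)))
    b0, b1 = params.baseline_window
    if time_s[-1] < b1:
        raise DataError(f"stream ends at {time_s[-1]:.3f}s, before the "
                        f"baseline window [{b0}, {b1}]s")
    base = (time_s >= b0) & (time_s < b1)
    if base.sum() < 2:
        raise DataError("CoP baseline window contains fewer than 2 samples")
    n_sustain = max(1, int(round(params.cop_sustain_s / dt)))
    start = int(np.flatnonzero(base)[-1]) + 1
    # the axis whose sustained excursion triggers first wins
    best: tuple[int, int, str] | None = None
    for axis, label in ((0, "ap"), (1, "ml")):
        x = cop_xy[:, axis]
        mu = x[base].mean()
        sd = x[base].std(ddof=1)
        mask = np.abs(x - mu) > params.cop_k_sd * max(sd, 1e-12)
        mask[:start] = False
        idx = _first_sustained(mask, n_sustain)
        if idx is not None and (best is None or idx < best[0]):
            best = (idx, axis, label)
    if best is None:
        return None, ""
    idx, axis, label = best
    t_on = float(time_s[idx])
    if params.cop_refine == "hinge":
        x = cop_xy[:, axis]
        mu = x[base].mean()
        sign = float(np.sign(x[idx] - mu)) or 1.0
        s = (x - mu) * sign
        lo = max(start, idx - int(round(params.cop_refine_back_s / dt)))
        hi = min(len(s), idx + int(round(params.cop_refine_fwd_s / dt)) + 1)
        seg, tseg = s[lo:hi], time_s[lo:hi]
        best_sse, best_t0 = np.inf, t_on
        for c in range(0, idx - lo + 1):   # candidate changepoints up to trigger
            ramp = np.clip(tseg - tseg[c], 0.0, None)
            denom = float(ramp @ ramp)
            v = max(0.0, float(seg @ ramp) / denom) if denom > 0 else 0.0
            resid = seg - v * ramp
            sse = float(resid @ resid)
            if sse < best_sse:
                best_sse, best_t0 = sse, float(tseg[c])
        t_on = float(time_s[int(round((best_t0 - time_s[0]) / dt))])  # snap
    return t_on, label


def detect_step_events(
    time_s: np.ndarray,
    fz_landing: np.ndarray,
    body_weight_n: float,
    params: EventParams,
) -> tuple[float, float]:
    """Step onset (landing-limb unloading) and offset (landing contact).

    ``step_on``: vertical force of the landing limb first drops below
    ``unload_frac`` of its quiet-stance value; ``step_off``: first subsequent
    loading above ``load_frac_bw`` of body weight.  Both crossings must be
    sustained for ``step_sustain_s``.
    """
    fz = np.asarray(fz_landing, dtype=float)
    dt = float(np.median(np.diff(time_s)))
    b0, b1 = params.baseline_window
    base = (time_s >= b0) & (time_s < b1)
    quiet = fz[base].mean()
    if quiet < 0.05 * body_weight_n:
        raise UnanalyzableTrialError("landing limb not loaded during quiet stance")
    n_sustain = max(1, int(round(params.step_sustain_s / dt)))
    on_idx = _first_sustained(fz < params.unload_frac * quiet, n_sustain)
    if on_idx is None:
        raise UnanalyzableTrialError("landing limb never unloads")
    off_mask = fz > params.load_frac_bw * body_weight_n
    off_mask[: on_idx + 1] = False
    off_idx = _first_sustained(off_mask, n_sustain)
    if off_idx is None:
        raise UnanalyzableTrialError("no landing contact after step onset")
    return float(time_s[on_idx]), float(time_s[off_idx])


def compute_step_characteristics(
    kin: pd.DataFrame, events: EventSet
) -> StepCharacteristics:
    """Step length/width from malleoli positions at landing, plus step time.

    Length is the AP (+x) distance between support and landing malleoli and
    width the ML (+y) distance, both evaluated at ``step_off`` (foot flat at
    landing); the kinematic stream is interpolated to the event time.
    """
    needed = ["malleolus_support_x", "malleolus_support_y",
              "malleolus_landing_x", "malleolus_landing_y"]
    missing = [c for c in needed if c not in kin.columns]
    if missing:
        raise DataError(f"kin stream lacks malleoli channels: {missing}")
    t = kin["time"].to_numpy()
    if events.step_off > t[-1]:
        raise DataError("kinematic stream ends before step_off")
    at = {c: float(np.interp(events.step_off, t, kin[c].to_numpy())) for c in needed}
    return StepCharacteristics(
        step_length_m=abs(at["malleolus_landing_x"] - at["malleolus_support_x"]),
        step_width_m=abs(at["malleolus_landing_y"] - at["malleolus_support_y"]),
        step_time_s=events.step_off - events.step_on,
    )


def detect_events(trial: TrialRecording, params: Optional[EventParams] = None) -> EventSet:
    """Full per-trial timeline from the sensor and force-plate streams."""
    params = params or EventParams()
    t_sensor = trial.sensor["time"].to_numpy()
    reach_on, reach_off = detect_reach_events(t_sensor, trial.sensor["beam"].to_numpy())
    tf = trial.force["time"].to_numpy()
    weight = trial.meta.body_mass_kg * 9.81
    step_on, step_off = detect_step_events(tf, trial.force["fz_R"].to_numpy(),
                                           weight, params)
    cop = net_cop(trial.force, trial.meta.plate_centers)
    cop_on, axis = detect_cop_onset(tf, cop, params)
    flags = []
    if cop_on is None:
        flags.append("no_cop_onset")
    events = EventSet(reach_on=reach_on, reach_off=reach_off, cop_on=cop_on,
                      step_on=step_on, step_off=step_off, cop_axis=axis,
                      flags=flags)
    events.validate(duration_s=float(tf[-1]) + (tf[1] - tf[0]))
    return events
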