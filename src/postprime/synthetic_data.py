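"""Synthetic step-and-reach cohort generator with known ground truth.

Emulates the study's full channel inventory — 16-channel surface EMG at
2000 Hz, two tri-axial force plates (forces + moments) at 1000 Hz, CoM /
joint-angle kinematics at 100 Hz and a binary reach-beam channel — for a
2 × 10 participant cohort crossing four blocked surface conditions
(NL -> LP -> LL -> LB) with 3 trials per block and 8 s per trial.

Generative model
----------------
Every scalar quantity of a trial (event timings, step geometry, CoM
excursions, joint excursions, muscle-onset latencies, VAS scores) is drawn
from an :class:`~postprime.config.EffectSpec`:

    value = baseline + condition effect + group effect + interaction
            + participant random intercept + trial noise,

with VAS noise drawn once per condition block (scales are administered
before each block, so a block's three trials share its scores).  The drawn
scalars then parameterize fully deterministic channel constructions, so the
ground truth of every downstream metric is known exactly:

* Landing-limb (right-plate) vertical force declines linearly from its
  quiet-stance value to zero starting at ``cop_on``; because the net CoP of
  a two-plate stance is the load-weighted average of the foot positions,
  this single mechanism produces a mediolateral CoP shift toward the support
  limb that starts exactly at ``cop_on``, and a 5 %-of-quiet-load crossing
  exactly at ``step_on``.  Landing-zone reloading crosses 5 % of body weight
  exactly at ``step_off``.
* CoM travels a half-cosine of the configured preparatory excursion over
  [cop_on, step_on], holds briefly, then completes a quintic ramp to the
  configured total excursion; joint angles ramp monotonically by their
  configured peak-to-peak excursion over the movement interval.
* EMG bursts are activation envelopes (10 ms half-cosine rise) riding a
  deterministic ±1 square-wave carrier, so the rectified burst equals the
  envelope exactly; zero-mean Gaussian baseline noise is added on top.
  Ground-truth onset is the envelope ramp start.

Reproducibility: one master seed is expanded per participant / block / trial
through ``numpy.random.SeedSequence`` keys, so trials are independent yet
the whole cohort is bit-reproducible and insensitive to generation order.
"""

from __future__ import annotations

import math
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd

from .config import CohortSpec, EffectSpec
from .errors import ConfigError
from .types import JOINTS, MUSCLES, TrialGroundTruth, TrialMeta, TrialRecording

G = 9.81

#: global coordinates of the feet (AP = +x toward the target, ML = +y left)
SUPPORT_FOOT_XY = (0.0, 0.05)
LANDING_FOOT_XY = (0.0, -0.05)
PLATE_CENTERS = {"L": (0.0, 0.12), "R": (0.0, -0.12)}

JOINT_BASE_DEG = {"ankle": 10.0, "knee": 15.0, "hip": 20.0, "lumbar": 5.0,
                  "thorax": 10.0, "shoulder": 5.0, "elbow": 10.0}

#: muscle-onset latency model relative to reach onset (seconds).  Postural
#: muscles lead the reach; rectus abdominis and gastrocnemius lag it in the
#: OLDER group (delayed anticipatory adjustments).
_LATENCY_BASE = {
    "ES_L": -0.15, "ES_R": -0.15,
    "RA_L": -0.05, "RA_R": -0.05,
    "TA_L": -0.12, "TA_R": -0.12,
    "GAS_L": -0.04, "GAS_R": -0.04,
    "VL_L": 0.02, "VL_R": 0.02,
    "BF_L": 0.01, "BF_R": 0.01,
    "DELT_A_R": 0.00, "DELT_P_R": 0.02,
    "BIC_R": 0.01, "TRI_R": 0.03,
}
_LATENCY_OLDER_SHIFT = {"RA_L": 0.13, "RA_R": 0.13, "GAS_L": 0.14, "GAS_R": 0.14}


def default_effects() -> dict[str, EffectSpec]:
    """The study-design effect table (units in each metric's name).

    Condition effects mirror the direction of the reported findings: VAS
    fear ratings climb monotonically over the blocked conditions, step width
    and lumbar flexion increase while support-ankle flexion decreases under
    lubricated surfaces, and total ML CoM excursion grows in YOUNG
    participants under the most threatening (LB) condition — a group ×
    condition interaction.
    """
    E: dict[str, EffectSpec] = {}
    E["move_onset_s"] = EffectSpec(baseline=2.80, subject_sd=0.05, noise_sd=0.05)
    E["apa_duration_s"] = EffectSpec(baseline=0.55, subject_sd=0.03, noise_sd=0.02)
    E["reach_lag_s"] = EffectSpec(baseline=0.05, interaction={"OLDER:LB": -0.15},
                                  subject_sd=0.01, noise_sd=0.01)
    E["reach_duration_s"] = EffectSpec(baseline=0.90, subject_sd=0.05, noise_sd=0.03)
    E["step_length_m"] = EffectSpec(baseline=0.55, interaction={"OLDER:LB": -0.04},
                                    subject_sd=0.03, noise_sd=0.01)
    E["step_width_m"] = EffectSpec(baseline=0.10,
                                   condition={"LP": 0.01, "LL": 0.02, "LB": 0.03},
                                   subject_sd=0.015, noise_sd=0.005)
    E["step_time_s"] = EffectSpec(baseline=0.40, subject_sd=0.03, noise_sd=0.02)
    E["prep_com_exc_ap_m"] = EffectSpec(baseline=0.015,
                                        condition={"LP": 0.002, "LL": 0.004, "LB": 0.006},
                                        subject_sd=0.002, noise_sd=0.001)
    E["prep_com_exc_ml_m"] = EffectSpec(baseline=0.008,
                                        condition={"LP": 0.001, "LL": 0.002, "LB": 0.003},
                                        subject_sd=0.001, noise_sd=0.0005)
    E["total_com_exc_ap_m"] = EffectSpec(baseline=0.35, subject_sd=0.02, noise_sd=0.01)
    E["total_com_exc_ml_m"] = EffectSpec(baseline=0.06,
                                         interaction={"YOUNG:LL": 0.012, "YOUNG:LB": 0.030},
                                         subject_sd=0.008, noise_sd=0.004)
    E["vas_likely_mm"] = EffectSpec(baseline=5.0,
                                    condition={"LP": 15.0, "LL": 30.0, "LB": 45.0},
                                    subject_sd=6.0, noise_sd=4.0)
    E["vas_concern_mm"] = EffectSpec(baseline=8.0,
                                     condition={"LP": 15.0, "LL": 30.0, "LB": 45.0},
                                     subject_sd=6.0, noise_sd=4.0)
    exc = {"ankle": (25.0, {"LL": -2.5, "LB": -5.0}),
           "knee": (40.0, {}),
           "hip": (50.0, {"LL": 2.0, "LB": 4.0}),
           "lumbar": (20.0, {"LL": 4.0, "LB": 8.0}),
           "thorax": (15.0, {"LL": 1.5, "LB": 3.0}),
           "shoulder": (70.0, {}),
           "elbow": (30.0, {})}
    for joint, (base, cond) in exc.items():
        E[f"exc_{joint}_deg"] = EffectSpec(baseline=base, condition=cond,
                                           subject_sd=2.0, noise_sd=1.0)
    for m in MUSCLES:
        grp = {"OLDER": _LATENCY_OLDER_SHIFT.get(m, 0.0)}
        E[f"lat_{m}_s"] = EffectSpec(baseline=_LATENCY_BASE[m], group=grp,
                                     subject_sd=0.02, noise_sd=0.02)
        E[f"amp_{m}"] = EffectSpec(baseline=1.0)
    return E


def _effects(spec: CohortSpec) -> dict[str, EffectSpec]:
    eff = default_effects()
    eff.update(spec.effects)
    return eff


# ---------------------------------------------------------------------------
# primitive profiles


def _halfcos(t: np.ndarray, t0: float, width: float) -> np.ndarray:
    """0 before t0, smooth half-cosine rise to 1 over ``width``, 1 after."""
    u = np.clip((t - t0) / width, 0.0, 1.0)
    return 0.5 * (1.0 - np.cos(np.pi * u))


def _smoothstep(t: np.ndarray, t0: float, width: float) -> np.ndarray:
    """Quintic smoothstep (zero 1st/2nd derivatives at both ends)."""
    u = np.clip((t - t0) / width, 0.0, 1.0)
    return u ** 3 * (10.0 - 15.0 * u + 6.0 * u * u)


def _burst_envelope(t: np.ndarray, onset: float, duration: float,
                    rise_s: float = 0.010, fall_s: float = 0.050) -> np.ndarray:
    """Activation envelope: half-cosine rise at ``onset``, half-cosine decay
    ending at ``onset + duration``.  Ground-truth onset is the ramp start."""
    env = _halfcos(t, onset, rise_s)
    env = env * (1.0 - _halfcos(t, onset + duration - fall_s, fall_s))
    return env


# ---------------------------------------------------------------------------
# channel generators


def generate_emg_channel(
    duration_s: float,
    rate_hz: float,
    baseline_sd: float,
    bursts: Sequence[tuple[float, float, float]],
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    carrier_hz: float = 250.0,
    carrier_phase: float = 0.0,
) -> np.ndarray:
    """One raw surface-EMG channel: Gaussian baseline plus carrier bursts.

    ``bursts`` is a list of ``(onset_s, duration_s, amplitude)``; each burst
    adds ``amplitude * envelope(t) * carrier(t)`` where the carrier is a ±1
    square wave, so full-wave rectification recovers the envelope exactly.
    Overlapping bursts simply add.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    n = int(round(duration_s * rate_hz))
    t = np.arange(n) / rate_hz
    x = rng.normal(0.0, baseline_sd, n) if baseline_sd > 0 else np.zeros(n)
    if bursts:
        carrier = np.sign(np.sin(2.0 * np.pi * carrier_hz * t + carrier_phase))
        carrier[carrier == 0.0] = 1.0
        for onset, duration, amplitude in bursts:
            if amplitude < 0:
                raise ConfigError(f"burst amplitude must be >= 0, got {amplitude}")
            if not 0.0 <= onset <= duration_s:
                raise ConfigError(f"burst onset {onset}s outside [0, {duration_s}]")
            x = x + amplitude * _burst_envelope(t, onset, duration) * carrier
    return x


def _force_kin_streams(
    spec: CohortSpec,
    vals: dict[str, float],
    events: dict[str, float],
    body_mass_kg: float,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Force-plate and kinematic streams realizing the drawn trial scalars."""
    ns = spec.noise.noise_scale
    w = body_mass_kg * G
    cop_on, step_on = events["cop_on"], events["step_on"]
    step_off, reach_off = events["step_off"], events["reach_off"]
    apa = step_on - cop_on

    # --- force plates (landing limb on the right plate) ------------------
    tf = np.arange(int(round(spec.duration_s * spec.force_rate_hz))) / spec.force_rate_hz
    t_zero = cop_on + apa / 0.95          # linear decline crosses 5% at step_on
    fz_r = 0.5 * w * np.clip(1.0 - (tf - cop_on) / (t_zero - cop_on), 0.0, 1.0)
    reload_slope = 0.45 * w / 0.25
    reload_start = step_off - (0.05 * w) / reload_slope
    fz_r = fz_r + np.clip((tf - reload_start) * reload_slope, 0.0, 0.45 * w)
    fz_l = w - fz_r

    # per-plate CoP: under each foot; support-plate CoP drifts forward
    # during the reach (weight rolls onto the toes)
    sup, land = SUPPORT_FOOT_XY, LANDING_FOOT_XY
    land_final = (vals["step_length_m"], sup[1] - vals["step_width_m"])
    cl, cr = PLATE_CENTERS["L"], PLATE_CENTERS["R"]
    s_move = _smoothstep(tf, step_on, max(reach_off - 0.3 - step_on, 0.1))
    copx_l = sup[0] + 0.04 * s_move - cl[0]
    copy_l = np.full_like(tf, sup[1] - cl[1])
    s_land = _smoothstep(tf, reload_start, 0.1)
    copx_r = land[0] + (land_final[0] - land[0]) * s_land - cr[0]
    copy_r = land[1] + (land_final[1] - land[1]) * s_land - cr[1]

    def noisy(x, sd):
        return x + rng.normal(0.0, sd * ns, x.shape) if sd * ns > 0 else x.copy()

    f_sd, m_sd = spec.noise.force_sd_n, spec.noise.moment_sd_nm
    force = pd.DataFrame({"time": tf})
    for suffix, fz, cx, cy in (("L", fz_l, copx_l, copy_l), ("R", fz_r, copx_r, copy_r)):
        force[f"fx_{suffix}"] = noisy(np.zeros_like(tf), f_sd)
        force[f"fy_{suffix}"] = noisy(np.zeros_like(tf), f_sd)
        force[f"fz_{suffix}"] = noisy(fz, f_sd)
        force[f"mx_{suffix}"] = noisy(cy * fz, m_sd)
        force[f"my_{suffix}"] = noisy(-cx * fz, m_sd)
        force[f"mz_{suffix}"] = noisy(np.zeros_like(tf), m_sd)

    # --- kinematics -------------------------------------------------------
    tk = np.arange(int(round(spec.duration_s * spec.kin_rate_hz))) / spec.kin_rate_hz
    move_end = reach_off - 0.30
    com_start = min(step_on + 0.25, move_end - 0.10)
    kin = pd.DataFrame({"time": tk})
    for axis, prep_key, total_key in (
        ("x", "prep_com_exc_ap_m", "total_com_exc_ap_m"),
        ("y", "prep_com_exc_ml_m", "total_com_exc_ml_m"),
    ):
        prep, total = vals[prep_key], vals[total_key]
        pos = prep * _halfcos(tk, cop_on, apa)
        pos = pos + (total - prep) * _smoothstep(tk, com_start, move_end - com_start)
        kin[f"com_{axis}"] = noisy(pos, spec.noise.com_sd_m)
    kin["com_z"] = noisy(np.full_like(tk, 0.95), spec.noise.com_sd_m)

    j_start = cop_on + 0.05
    j_width = max(move_end - j_start, 0.1)
    for joint in JOINTS:
        ang = JOINT_BASE_DEG[joint] + vals[f"exc_{joint}_deg"] * _smoothstep(tk, j_start, j_width)
        kin[joint] = noisy(ang, spec.noise.joint_sd_deg)

    swing = _smoothstep(tk, step_on, min(0.15, 0.5 * (step_off - step_on)))
    kin["malleolus_support_x"] = noisy(np.full_like(tk, sup[0]), spec.noise.malleolus_sd_m)
    kin["malleolus_support_y"] = noisy(np.full_like(tk, sup[1]), spec.noise.malleolus_sd_m)
    kin["malleolus_landing_x"] = noisy(land[0] + (land_final[0] - land[0]) * swing,
                                       spec.noise.malleolus_sd_m)
    kin["malleolus_landing_y"] = noisy(land[1] + (land_final[1] - land[1]) * swing,
                                       spec.noise.malleolus_sd_m)
    return force, kin


def generate_force_and_kinematics(
    condition: str,
    group: str,
    spec: Optional[CohortSpec] = None,
    seed: int = 0,
    participant_index: int = 0,
    trial_index: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, TrialGroundTruth]:
    """Convenience: force + kinematic streams for one (condition, group) cell."""
    spec = spec or CohortSpec()
    if group not in spec.groups or condition not in spec.conditions:
        raise ConfigError(f"unknown group/condition: {group}/{condition}")
    rec, truth = generate_trial(spec, group, participant_index, condition,
                                trial_index, master_seed=seed)
    return rec.force, rec.kin, truth


# ---------------------------------------------------------------------------
# trial / cohort assembly


def _subject_intercepts(spec: CohortSpec, p_global: int) -> tuple[dict[str, float], float]:
    eff = _effects(spec)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1, p_global]))
    intercepts = {name: rng.normal(0.0, 1.0) * eff[name].subject_sd
                  for name in sorted(eff)}
    mass = float(np.clip(rng.normal(spec.body_mass_kg, spec.body_mass_sd_kg), 45.0, 110.0))
    return intercepts, mass


def _block_vas(spec: CohortSpec, p_global: int, c_idx: int, group: str,
               condition: str, intercepts: dict[str, float]) -> dict[str, float]:
    eff = _effects(spec)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 3, p_global, c_idx]))
    out = {}
    for name in ("vas_likely_mm", "vas_concern_mm"):
        e = eff[name]
        v = (e.mean(group, condition) + intercepts[name]
             + rng.normal(0.0, 1.0) * e.noise_sd * spec.noise.noise_scale)
        out[name] = float(np.clip(v, 0.0, 100.0))
    return out


def _draw_trial(spec: CohortSpec, group: str, condition: str,
                intercepts: dict[str, float],
                rng: np.random.Generator) -> tuple[dict[str, float], dict[str, float]]:
    """Draw all trial scalars and derive the event timeline (pre-snap)."""
    eff = _effects(spec)
    ns = spec.noise.noise_scale
    vals: dict[str, float] = {}
    for name in sorted(eff):
        if name.startswith("vas_"):
            continue  # block-level, drawn separately
        e = eff[name]
        vals[name] = (e.mean(group, condition) + intercepts[name]
                      + rng.normal(0.0, 1.0) * e.noise_sd * ns)

    # physical guards; generator trials are always analyzable by construction
    vals["apa_duration_s"] = max(vals["apa_duration_s"], 0.15)
    vals["step_time_s"] = max(vals["step_time_s"], 0.10)
    vals["reach_duration_s"] = max(vals["reach_duration_s"], 0.40)
    for key in ("prep_com_exc_ap_m", "prep_com_exc_ml_m"):
        vals[key] = max(vals[key], 1e-4)
    vals["total_com_exc_ap_m"] = max(vals["total_com_exc_ap_m"], vals["prep_com_exc_ap_m"])
    vals["total_com_exc_ml_m"] = max(vals["total_com_exc_ml_m"], vals["prep_com_exc_ml_m"])

    cop_on = float(np.clip(vals["move_onset_s"], 1.8, spec.duration_s - 3.0))
    step_on = cop_on + vals["apa_duration_s"]
    reach_on = step_on + vals["reach_lag_s"]
    reach_off = reach_on + vals["reach_duration_s"]
    step_off = step_on + min(vals["step_time_s"], reach_off - step_on - 0.05)
    vals["step_time_s"] = step_off - step_on
    # snap the beam edges to the sensor clock so the constructed edge *is*
    # the ground truth
    fs = spec.force_rate_hz
    reach_on = round(reach_on * fs) / fs
    reach_off = round(reach_off * fs) / fs
    events = {"cop_on": cop_on, "step_on": step_on, "step_off": step_off,
              "reach_on": reach_on, "reach_off": reach_off}
    vals["copon_latency_s"] = cop_on - reach_on
    vals["stepon_latency_s"] = step_on - reach_on
    vals["stepoff_latency_s"] = step_off - reach_on
    apa = vals["apa_duration_s"]
    vals["prep_com_acc_ap_mss"] = vals["prep_com_exc_ap_m"] / 2.0 * (math.pi / apa) ** 2
    vals["prep_com_acc_ml_mss"] = vals["prep_com_exc_ml_m"] / 2.0 * (math.pi / apa) ** 2
    return vals, events


def generate_trial(
    spec: CohortSpec,
    group: str,
    participant_index: int,
    condition: str,
    trial_index: int,
    master_seed: Optional[int] = None,
) -> tuple[TrialRecording, TrialGroundTruth]:
    """Generate one trial (all four streams) plus its ground truth."""
    if master_seed is not None:
        spec = spec.model_copy(update={"seed": master_seed})
    g_idx = list(spec.groups).index(group)
    c_idx = list(spec.conditions).index(condition)
    p_global = g_idx * spec.n_per_group + participant_index
    intercepts, mass = _subject_intercepts(spec, p_global)
    vas = _block_vas(spec, p_global, c_idx, group, condition, intercepts)
    rng = np.random.default_rng(
        np.random.SeedSequence([spec.seed, 2, p_global, c_idx, trial_index]))
    vals, events = _draw_trial(spec, group, condition, intercepts, rng)

    # EMG: one burst per muscle from its ground-truth onset to target contact
    n_emg = int(round(spec.duration_s * spec.emg_rate_hz))
    t_emg = np.arange(n_emg) / spec.emg_rate_hz
    emg = pd.DataFrame({"time": t_emg})
    onsets: dict[str, float] = {}
    base_sd = spec.noise.emg_baseline_sd
    noise_sd = base_sd * spec.noise.noise_scale
    for i, muscle in enumerate(MUSCLES):
        onset = events["reach_on"] + vals[f"lat_{muscle}_s"]
        onset = float(np.clip(onset, 1.0, spec.duration_s - 1.0))
        onsets[muscle] = onset
        emg[muscle] = generate_emg_channel(
            spec.duration_s, spec.emg_rate_hz, noise_sd,
            [(onset, events["reach_off"] - onset, vals[f"amp_{muscle}"])],
            rng=rng, carrier_hz=spec.carrier_hz,
            carrier_phase=2.0 * np.pi * i / len(MUSCLES),
        )

    force, kin = _force_kin_streams(spec, vals, events, mass, rng)

    tf = force["time"].to_numpy()
    beam = ((tf >= events["reach_on"] - 1e-9) & (tf < events["reach_off"] - 1e-9))
    sensor = pd.DataFrame({"time": tf, "beam": beam.astype(int)})

    participant = f"{group[0]}{participant_index + 1:02d}"
    meta = TrialMeta(
        participant=participant, group=group, condition=condition,
        trial_index=trial_index,
        vas_likely_mm=vas["vas_likely_mm"], vas_concern_mm=vas["vas_concern_mm"],
        body_mass_kg=mass,
        rates={"emg": spec.emg_rate_hz, "force": spec.force_rate_hz,
               "kin": spec.kin_rate_hz},
        plate_centers={k: tuple(v) for k, v in PLATE_CENTERS.items()},
    )
    truth = TrialGroundTruth(events=events, muscle_onsets=onsets, metrics=vals,
                             vas_likely_mm=vas["vas_likely_mm"],
                             vas_concern_mm=vas["vas_concern_mm"])
    return TrialRecording(meta=meta, emg=emg, force=force, kin=kin, sensor=sensor), truth


def generate_cohort(spec: CohortSpec) -> Iterator[tuple[TrialRecording, TrialGroundTruth]]:
    """Yield every trial of the cohort in participant-major blocked order.

    Trials stream lazily (a full default cohort is ~1 GB of channel data);
    wrap in ``list`` only for reduced designs.
    """
    for group in spec.groups:
        for p in range(spec.n_per_group):
            for condition in spec.conditions:
                for t in range(spec.trials_per_condition):
                    yield generate_trial(spec, group, p, condition, t)


def generate_metric_table(spec: CohortSpec) -> pd.DataFrame:
    """Ground-truth metric table in long format, without channel synthesis.

    Draws the identical per-trial scalars as :func:`generate_cohort` (same
    seed expansion) and returns them as rows
    ``participant, group, condition, trial, metric, value`` — the fast path
    for statistical calibration studies where the channel-level pipeline has
    already been validated separately.
    """
    rows = []
    for g_idx, group in enumerate(spec.groups):
        for p in range(spec.n_per_group):
            p_global = g_idx * spec.n_per_group + p
            intercepts, _ = _subject_intercepts(spec, p_global)
            participant = f"{group[0]}{p + 1:02d}"
            for c_idx, condition in enumerate(spec.conditions):
                vas = _block_vas(spec, p_global, c_idx, group, condition, intercepts)
                for t in range(spec.trials_per_condition):
                    rng = np.random.default_rng(
                        np.random.SeedSequence([spec.seed, 2, p_global, c_idx, t]))
                    vals, _ = _draw_trial(spec, group, condition, intercepts, rng)
                    vals = dict(vals)
                    vals.update(vas)
                    for metric, value in vals.items():
                        if metric.startswith("amp_"):
                            continue
                        rows.append((participant, group, condition, t, metric, value))
    return pd.DataFrame(rows, columns=["participant", "group", "condition",
                                       "trial", "metric", "value"])
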