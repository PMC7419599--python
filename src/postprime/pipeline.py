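"""Orchestration: simulate -> condition -> detect -> measure -> analyze.

Stages are pure functions over in-memory trials; ``run_pipeline`` streams a
synthetic cohort (or reads trial bundles from disk), processes one
participant at a time (EMG max-normalization spans a participant's trials
across all conditions, so the participant is the natural unit of work),
accumulates the long-format cohort metric table and runs the statistical
layer.  Per-trial failures are recorded as QC flags and skipped; the run
manifest records the config hash and analyzed/failed counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import numpy as np
import pandas as pd

from . import emg_metrics, event_detection, movement_metrics, signal_conditioning
from .config import PipelineConfig
from .errors import DataError, PostprimeError
from .io import read_trial_bundle, write_table, write_trial_bundle
from .synthetic_data import generate_cohort
from .types import (JOINTS, MUSCLES, EventSet, TrialGroundTruth, TrialRecording)

log = logging.getLogger("postprime")

POSTURAL_MUSCLES = ["ES_L", "ES_R", "RA_L", "RA_R", "TA_L", "TA_R", "GAS_L", "GAS_R"]


@dataclass
class TrialResult:
    trial_id: str
    participant: str
    group: str
    condition: str
    trial_index: int
    events: EventSet
    metrics: dict[str, float]
    onsets: dict[str, Optional[float]]
    latencies: dict[str, Optional[float]]
    cci: dict[tuple[str, str], float]
    flags: list[str] = field(default_factory=list)


@dataclass
class PipelineRun:
    metrics: pd.DataFrame
    anova: pd.DataFrame
    posthoc: pd.DataFrame
    qc: pd.DataFrame
    manifest: dict


def condition_trial(trial: TrialRecording, config: PipelineConfig
                    ) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Raw streams -> EMG envelopes (unnormalized) + smoothed kinematics."""
    rate_emg = trial.meta.rates["emg"]
    rate_kin = trial.meta.rates["kin"]
    envelopes = {m: signal_conditioning.condition_emg(
        trial.emg[m].to_numpy(), config.filters, rate_emg) for m in MUSCLES}
    kin = pd.DataFrame({"time": trial.kin["time"].to_numpy()})
    for col in ["com_x", "com_y", "com_z"] + JOINTS:
        kin[col] = signal_conditioning.condition_kinematics(
            trial.kin[col].to_numpy(), config.filters, rate_kin)
    for col in ["malleolus_support_x", "malleolus_support_y",
                "malleolus_landing_x", "malleolus_landing_y"]:
        kin[col] = signal_conditioning.condition_kinematics(
            trial.kin[col].to_numpy(), config.filters, rate_kin, remove_dc=False)
    return envelopes, kin


def _measure_trial(trial: TrialRecording, envelopes: dict[str, np.ndarray],
                   kin: pd.DataFrame, config: PipelineConfig) -> TrialResult:
    events = event_detection.detect_events(trial, config.events)
    step = event_detection.compute_step_characteristics(kin, events)
    t_kin = kin["time"].to_numpy()
    mm = movement_metrics.compute_movement_metrics(
        t_kin, kin["com_x"].to_numpy(), kin["com_y"].to_numpy(),
        {j: kin[j].to_numpy() for j in JOINTS}, events, step, config.movement)
    t_emg = trial.emg["time"].to_numpy()
    onsets, latencies, cci, eflags = emg_metrics.trial_emg_metrics(
        envelopes, t_emg, trial.meta.rates["emg"], events,
        config.onset, config.cci)

    metrics: dict[str, float] = {
        "vas_likely_mm": trial.meta.vas_likely_mm,
        "vas_concern_mm": trial.meta.vas_concern_mm,
        "stepon_latency_s": events.step_on - events.reach_on,
        "stepoff_latency_s": events.step_off - events.reach_on,
        "step_length_m": step.step_length_m,
        "step_width_m": step.step_width_m,
        "step_time_s": step.step_time_s,
        "prep_com_acc_ap_mss": mm.prep_com_acc_ap,
        "prep_com_acc_ml_mss": mm.prep_com_acc_ml,
        "prep_com_exc_ap_m": mm.prep_com_exc_ap,
        "prep_com_exc_ml_m": mm.prep_com_exc_ml,
        "total_com_exc_ap_m": mm.total_com_exc_ap,
        "total_com_exc_ml_m": mm.total_com_exc_ml,
    }
    if events.cop_on is not None:
        metrics["copon_latency_s"] = events.cop_on - events.reach_on
    for joint, v in mm.joint_excursions_deg.items():
        metrics[f"exc_{joint}_deg"] = v
    for muscle, lat in latencies.items():
        if lat is not None:
            metrics[f"lat_{muscle}_s"] = lat
    for phase in ("i", "ii", "iii", "iv"):
        vals = [v for (region, ph), v in cci.items() if ph == phase]
        if vals:
            metrics[f"cci_{phase}"] = float(np.mean(vals))

    meta = trial.meta
    return TrialResult(
        trial_id=meta.trial_id, participant=meta.participant, group=meta.group,
        condition=meta.condition, trial_index=meta.trial_index, events=events,
        metrics=metrics, onsets=onsets, latencies=latencies, cci=cci,
        flags=list(events.flags) + eflags + mm.flags)


def process_participant(
    trials: list[TrialRecording], config: PipelineConfig
) -> tuple[list[TrialResult], list[dict]]:
    """Condition, normalize across the participant's conditions, and measure."""
    conditioned: list[tuple[TrialRecording, dict[str, np.ndarray], pd.DataFrame]] = []
    failures: list[dict] = []
    for trial in trials:
        try:
            env, kin = condition_trial(trial, config)
            conditioned.append((trial, env, kin))
        except PostprimeError as exc:
            failures.append({"trial_id": trial.meta.trial_id,
                             "stage": "condition", "error": str(exc)})
    if conditioned:
        for muscle in MUSCLES:
            normed, _ = signal_conditioning.normalize_envelopes(
                [env[muscle] for _, env, _ in conditioned])
            for (_, env, _), e in zip(conditioned, normed):
                env[muscle] = e
    results: list[TrialResult] = []
    for trial, env, kin in conditioned:
        try:
            results.append(_measure_trial(trial, env, kin, config))
        except PostprimeError as exc:
            failures.append({"trial_id": trial.meta.trial_id,
                             "stage": "measure", "error": str(exc)})
    return results, failures


def results_to_long(results: Iterable[TrialResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        for metric, value in r.metrics.items():
            rows.append((r.participant, r.group, r.condition, r.trial_index,
                         metric, value))
    return pd.DataFrame(rows, columns=["participant", "group", "condition",
                                       "trial", "metric", "value"])


def _iter_participant_batches(
    trials: Iterator[tuple[TrialRecording, Optional[TrialGroundTruth]]]
) -> Iterator[list[TrialRecording]]:
    batch: list[TrialRecording] = []
    for trial, _ in trials:
        if batch and trial.meta.participant != batch[0].meta.participant:
            yield batch
            batch = []
        batch.append(trial)
    if batch:
        yield batch


def _read_cohort(input_dir: Path) -> Iterator[tuple[TrialRecording, None]]:
    dirs = sorted(p for p in Path(input_dir).iterdir() if p.is_dir())
    if not dirs:
        raise DataError(f"no trial bundles under {input_dir}")
    for d in dirs:
        try:
            trial, _ = read_trial_bundle(d)
        except Exception as exc:  # noqa: BLE001 - corrupt bundles must not kill the run
            yield _FailedTrial(d.name, str(exc)), None
            continue
        yield trial, None


class _FailedTrial:
    """Sentinel for a bundle that could not be read."""

    def __init__(self, trial_id: str, error: str) -> None:
        self.trial_id = trial_id
        self.error = error


def simulate_to_dir(config: PipelineConfig, out_dir: str | Path,
                    with_truth: bool = True) -> int:
    """Write the configured synthetic cohort as trial bundles; returns count."""
    out = Path(out_dir)
    n = 0
    for trial, truth in generate_cohort(config.cohort):
        write_trial_bundle(out / trial.meta.trial_id, trial,
                           truth if with_truth else None)
        n += 1
    return n


def run_pipeline(config: PipelineConfig, out_dir: Optional[str | Path] = None,
                 input_dir: Optional[str | Path] = None,
                 write_trial_outputs: bool = False) -> PipelineRun:
    """Full run; reads bundles from ``input_dir`` or simulates the cohort."""
    if input_dir is not None:
        source: Iterator = _read_cohort(Path(input_dir))
    else:
        source = generate_cohort(config.cohort)

    all_results: list[TrialResult] = []
    failures: list[dict] = []
    n_seen = 0

    def trial_stream():
        nonlocal n_seen
        for trial, truth in source:
            n_seen += 1
            if isinstance(trial, _FailedTrial):
                failures.append({"trial_id": trial.trial_id, "stage": "read",
                                 "error": trial.error})
                continue
            yield trial, truth

    for batch in _iter_participant_batches(trial_stream()):
        results, fails = process_participant(batch, config)
        all_results.extend(results)
        failures.extend(fails)
        for f in fails:
            log.warning("trial %s failed at %s: %s", f["trial_id"], f["stage"],
                        f["error"])

    metrics = results_to_long(all_results)
    from .stats_engine import analyze_cohort  # deferred: keeps stage imports light
    if metrics.empty:
        raise DataError("no analyzable trials")
    anova, posthoc = analyze_cohort(metrics, config.families, config.stats)

    qc_rows = [{"trial_id": r.trial_id, "stage": "ok",
                "flags": ";".join(r.flags)} for r in all_results]
    qc_rows += [{"trial_id": f["trial_id"], "stage": f["stage"],
                 "flags": f"error:{f['error']}"} for f in failures]
    qc = pd.DataFrame(qc_rows).sort_values("trial_id").reset_index(drop=True)

    manifest = {
        "config_sha256": hashlib.sha256(config.to_yaml().encode()).hexdigest(),
        "n_trials_seen": n_seen,
        "n_trials_analyzed": len(all_results),
        "n_trials_failed": len(failures),
        "stages": ["simulate" if input_dir is None else "read",
                   "condition", "events", "metrics", "analyze"],
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_table(metrics, out / "cohort_metrics.csv")
        write_table(anova, out / "anova_results.csv")
        write_table(posthoc, out / "posthoc_results.csv")
        write_table(qc, out / "qc.csv")
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        if write_trial_outputs:
            for r in all_results:
                tdir = out / "trials" / r.trial_id
                ev = [("reach_on", r.events.reach_on, "sensor"),
                      ("reach_off", r.events.reach_off, "sensor"),
                      ("cop_on", r.events.cop_on, "force"),
                      ("step_on", r.events.step_on, "force"),
                      ("step_off", r.events.step_off, "force")]
                write_table(pd.DataFrame(ev, columns=["event", "time_s",
                                                      "source_stream"]),
                            tdir / "events.csv")
                write_table(pd.DataFrame(
                    [(m, r.onsets[m], r.latencies[m]) for m in r.onsets],
                    columns=["muscle", "onset_s", "latency_s"]),
                    tdir / "emg_metrics.csv")
                write_table(pd.DataFrame(
                    [(region, phase, v) for (region, phase), v in r.cci.items()],
                    columns=["pair", "phase", "value"]), tdir / "cci.csv")
                write_table(pd.DataFrame(sorted(r.metrics.items()),
                                         columns=["metric", "value"]),
                            tdir / "metrics.csv")
    return PipelineRun(metrics=metrics, anova=anova, posthoc=posthoc, qc=qc,
                       manifest=manifest)
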