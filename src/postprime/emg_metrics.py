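"""Muscle onset detection and phase-windowed co-contraction indices.

Onset criterion: activity must exceed baseline mean + ``k_sd`` × baseline SD
and stay above that threshold for ``sustain_s`` (defaults 7 SD / 50 ms).
"7 SD of average baseline activity" is read as mean + 7·SD of the
conditioned envelope over the quiet-stance baseline window; the alternative
reading (7 × mean) is dimensionally inconsistent with an SD-based phrase.

The co-contraction index (CCI) of an agonist–antagonist pair over a window
is, per sample,

    CCI = min(a, b) / max(a, b) × (a + b)

averaged over the window (samples with max(a,b) = 0 contribute 0).  It is
symmetric in the pair, ranges over [0, 2] for envelopes normalized to
[0, 1], and is amplitude-weighted by design: doubling both envelopes
doubles the CCI.  The plain ratio mean[min/max] is available as
``method="ratio"``.  Four phases are evaluated: (i) early and (ii)
preparatory before reach onset — the preparatory pair — and (iii) movement
and (iv) termination after it — the compensatory pair.
"""

from __future__ import annotations

from typing import Mapping, Optional

import numpy as np

from .config import CciConfig, CciPhases, OnsetParams
from .errors import DataError, DegenerateBaselineError
from .types import EventSet

PHASE_TAGS = {"i": "preparatory", "ii": "preparatory",
              "iii": "compensatory", "iv": "compensatory"}


def detect_muscle_onset(
    envelope: np.ndarray,
    rate_hz: float,
    params: Optional[OnsetParams] = None,
) -> Optional[float]:
    """First sustained supra-threshold sample of a conditioned envelope.

    Returns the onset in seconds, or ``None`` when no sample exceeds
    baseline mean + ``k_sd`` × SD for every sample of the following
    ``sustain_s`` window (the window must fit inside the record).
    """
    params = params or OnsetParams()
    env = np.asarray(envelope, dtype=float)
    n = env.size
    b0, b1 = params.baseline_window
    i0, i1 = int(round(b0 * rate_hz)), int(round(b1 * rate_hz))
    if not 0 <= i0 < i1 <= n:
        raise DataError("onset baseline window outside the envelope")
    base = env[i0:i1]
    mu, sd = base.mean(), base.std(ddof=1)
    if sd == 0.0:
        if np.any(env != mu):
            raise DegenerateBaselineError(
                "baseline SD is zero but the envelope is not flat")
        return None
    thr = mu + params.k_sd * sd
    n_sustain = int(round(params.sustain_s * rate_hz)) + 1  # t .. t+sustain inclusive
    above = env > thr
    if n_sustain > n:
        return None
    ok = np.convolve(above.astype(int), np.ones(n_sustain, dtype=int),
                     mode="valid") == n_sustain
    idx = np.flatnonzero(ok)
    return float(idx[0] / rate_hz) if idx.size else None


def onsets_relative_to_reach(
    onsets_s: Mapping[str, Optional[float]], events: EventSet
) -> dict[str, Optional[float]]:
    """Signed latencies, onset − reach_on: negative = preparatory."""
    return {m: (None if t is None else t - events.reach_on)
            for m, t in onsets_s.items()}


def compute_cci(
    envelope_a: np.ndarray,
    envelope_b: np.ndarray,
    method: str = "weighted",
) -> float:
    """Co-contraction index over a pair of (windowed) envelopes."""
    a = np.asarray(envelope_a, dtype=float)
    b = np.asarray(envelope_b, dtype=float)
    if a.shape != b.shape:
        raise DataError(f"envelope length mismatch: {a.shape} vs {b.shape}")
    if a.size == 0:
        raise DataError("CCI window is empty")
    if (a < 0).any() or (b < 0).any():
        raise DataError("CCI expects non-negative envelopes")
    hi = np.maximum(a, b)
    lo = np.minimum(a, b)
    ratio = np.divide(lo, hi, out=np.zeros_like(hi), where=hi > 0)
    if method == "weighted":
        return float(np.mean(ratio * (a + b)))
    if method == "ratio":
        return float(np.mean(ratio))
    raise DataError(f"unknown CCI method {method!r}")


def cci_by_phase(
    envelope_a: np.ndarray,
    envelope_b: np.ndarray,
    time_s: np.ndarray,
    events: EventSet,
    phases: Optional[CciPhases] = None,
    method: str = "weighted",
) -> tuple[dict[str, float], list[str]]:
    """One CCI per phase i–iv, anchored to reach onset / target contact.

    A termination window overlapping the movement window is permitted
    (short reaches) but flagged.
    """
    phases = phases or CciPhases()
    windows = phases.windows(events.reach_on, events.reach_off)
    flags: list[str] = []
    if windows["iv"][0] < windows["iii"][1]:
        flags.append("termination_overlaps_movement")
    out: dict[str, float] = {}
    for name, (t0, t1) in windows.items():
        if t0 < time_s[0] - 1e-9 or t1 > time_s[-1] + 1e-9:
            raise DataError(f"CCI phase {name} window [{t0:.2f}, {t1:.2f}]s "
                            "falls outside the trial")
        sel = (time_s >= t0) & (time_s < t1)
        out[name] = compute_cci(envelope_a[sel], envelope_b[sel], method=method)
    return out, flags


def trial_emg_metrics(
    envelopes: Mapping[str, np.ndarray],
    time_s: np.ndarray,
    rate_hz: float,
    events: EventSet,
    onset_params: Optional[OnsetParams] = None,
    cci_config: Optional[CciConfig] = None,
) -> tuple[dict[str, Optional[float]], dict[str, Optional[float]], dict[tuple[str, str], float], list[str]]:
    """Onsets, reach-relative latencies and per-pair CCI for one trial.

    Muscles with no detected onset keep ``None`` (excluded, not imputed,
    from onset statistics downstream); implausibly early/late onsets are
    QC-flagged rather than visually inspected.
    """
    onset_params = onset_params or OnsetParams()
    cci_config = cci_config or CciConfig()
    onsets: dict[str, Optional[float]] = {}
    flags: list[str] = []
    for muscle, env in envelopes.items():
        onset = detect_muscle_onset(env, rate_hz, onset_params)
        onsets[muscle] = onset
        if onset is None:
            flags.append(f"no_onset:{muscle}")
        elif onset < events.reach_on - 1.0 or onset > events.reach_off:
            flags.append(f"implausible_onset:{muscle}")
    latencies = onsets_relative_to_reach(onsets, events)
    cci: dict[tuple[str, str], float] = {}
    for pair in cci_config.pairs:
        for name in (pair.agonist, pair.antagonist):
            if name not in envelopes:
                raise DataError(f"CCI pair references unknown channel {name!r}")
        values, pflags = cci_by_phase(
            envelopes[pair.agonist], envelopes[pair.antagonist], time_s,
            events, cci_config.phases, method=cci_config.method)
        flags.extend(f"{f}:{pair.region}" for f in pflags)
        for phase, v in values.items():
            cci[(pair.region, phase)] = v
    return onsets, latencies, cci, flags
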