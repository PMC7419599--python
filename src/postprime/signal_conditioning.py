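"""Preprocessing chains for kinematic and EMG streams.

Kinematics: 40-point Savitzky–Golay smoothing followed by removal of the
quiet-stance DC offset.  EMG: 60 Hz notch -> demean -> full-wave rectify ->
4th-order zero-lag Butterworth low-pass at 100 Hz, then per participant ×
muscle max-normalization across all conditions.

Conventions (documented because the originals leave them open):

* ``sg_window`` is a length in samples of the stream the filter is applied
  to; an even window is promoted to the next odd length, as required by the
  centred least-squares fit (40 -> 41).
* "zero-lag" is realized by forward–backward application of a half-order
  Butterworth design, so the *effective* order matches ``lp_order`` (a
  forward–backward pass of a 4th-order design would be effectively 8th).
* Edge handling: reflect padding for both the Savitzky–Golay fit and the
  forward–backward Butterworth pass.
* Small negative values produced by low-passing a rectified signal are
  clipped to zero: the output is an activation envelope.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import signal

from .config import FilterSpec
from .errors import ConfigError, DataError, DeadChannelError


def _odd_window(n: int) -> int:
    return n if n % 2 else n + 1


def condition_kinematics(
    x: np.ndarray,
    spec: FilterSpec,
    rate_hz: float,
    remove_dc: bool = True,
) -> np.ndarray:
    """Savitzky–Golay smoothing, then quiet-stance DC-offset removal.

    The DC offset is the mean of the first ``spec.dc_baseline_s`` seconds
    (quiet stance), not the whole-trial mean — the latter is contaminated by
    the movement itself.  ``remove_dc=False`` keeps absolute coordinates, as
    needed for marker positions such as the malleoli.
    """
    x = np.asarray(x, dtype=float)
    win = _odd_window(spec.sg_window)
    if x.size <= win:
        raise DataError(f"stream of {x.size} samples is shorter than the "
                        f"{win}-sample smoothing window")
    y = signal.savgol_filter(x, window_length=win, polyorder=spec.sg_polyorder,
                             mode="mirror")
    if remove_dc:
        n_base = max(1, int(round(spec.dc_baseline_s * rate_hz)))
        y = y - y[:n_base].mean()
    return y


def condition_emg(x: np.ndarray, spec: FilterSpec, rate_hz: float) -> np.ndarray:
    """Notch -> demean -> rectify -> zero-lag low-pass, in that order.

    Returns a non-negative activation envelope with no phase delay (the
    peak of an isolated burst is unshifted beyond one sample).
    """
    x = np.asarray(x, dtype=float)
    nyq = rate_hz / 2.0
    if spec.lp_cutoff_hz >= nyq:
        raise ConfigError(f"lp_cutoff_hz={spec.lp_cutoff_hz} must be below the "
                          f"Nyquist frequency {nyq} Hz")
    b, a = signal.iirnotch(spec.notch_hz, spec.notch_q, fs=rate_hz)
    y = signal.filtfilt(b, a, x)
    y = y - y.mean()
    y = np.abs(y)
    # forward–backward pass of a half-order design -> effective lp_order
    sos = signal.butter(spec.lp_order // 2, spec.lp_cutoff_hz, fs=rate_hz,
                        output="sos")
    y = signal.sosfiltfilt(sos, y)
    return np.clip(y, 0.0, None)


def normalize_envelopes(envelopes: Sequence[np.ndarray]) -> tuple[list[np.ndarray], float]:
    """Divide a participant × muscle group of envelopes by its global maximum.

    ``envelopes`` holds that muscle's conditioned envelope from every trial of
    every condition for one participant.  Returns the scaled envelopes (max
    over the whole group is exactly 1) and the maximum used.
    """
    if not envelopes:
        raise DataError("normalize_envelopes needs at least one trial")
    peak = max(float(np.max(e)) for e in envelopes)
    if peak <= 0.0:
        raise DeadChannelError("all-zero EMG channel: cannot max-normalize "
                               "(dead channel?)")
    return [np.asarray(e, dtype=float) / peak for e in envelopes], peak


def normalize_emg(
    grouped: Mapping[tuple[str, str], Sequence[np.ndarray]],
) -> dict[tuple[str, str], list[np.ndarray]]:
    """Max-normalize envelopes grouped by (participant, muscle).

    Each group is normalized to the maximum amplitude recorded across all of
    that participant's trials in all conditions, so values are in [0, 1] and
    the group-wide max is exactly 1.
    """
    return {key: normalize_envelopes(envs)[0] for key, envs in grouped.items()}
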