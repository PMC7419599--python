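"""Muscle onset detector (threshold-and-sustain) and co-contraction index."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from postprime import (CciPhases, EventSet, FilterSpec, OnsetParams,
                       cci_by_phase, compute_cci, condition_emg,
                       detect_muscle_onset, onsets_relative_to_reach)
from postprime.errors import DataError, DegenerateBaselineError
from postprime.signal_conditioning import normalize_envelopes
from postprime.synthetic_data import generate_emg_channel

FS = 2000.0


def brute_force_onset(env, rate, params: OnsetParams):
    """Exhaustive scan over all candidate onsets (test oracle)."""
    i0 = int(round(params.baseline_window[0] * rate))
    i1 = int(round(params.baseline_window[1] * rate))
    base = env[i0:i1]
    mu, sd = base.mean(), base.std(ddof=1)
    if sd == 0.0:
        return None
    thr = mu + params.k_sd * sd
    n = int(round(params.sustain_s * rate)) + 1
    for t in range(env.size - n + 1):
        if np.all(env[t: t + n] > thr):
            return t / rate
    return None


def _envelope(rng, n_bursts=1, amp=10.0, duration=0.2, sd=0.1):
    bursts = []
    for k in range(n_bursts):
        bursts.append((0.8 + 0.6 * k + rng.uniform(0, 0.2), duration, amp * sd))
    raw = generate_emg_channel(2.5, FS, sd, bursts, rng=rng)
    return condition_emg(raw, FilterSpec(), FS), bursts


class TestOnsetDetector:
    def test_burst_10sigma_found_within_10ms(self, rng):
        raw = generate_emg_channel(5.0, FS, 0.1, [(3.0, 0.2, 1.0)], rng=rng)
        env = condition_emg(raw, FilterSpec(), FS)
        onset = detect_muscle_onset(env, FS)
        assert onset is not None
        assert abs(onset - 3.0) <= 0.010

    def test_short_burst_fails_sustain(self, rng):
        """An 8-sigma burst lasting only 40 ms cannot satisfy 50 ms sustain."""
        raw = generate_emg_channel(3.0, FS, 0.1, [(2.0, 0.040, 0.8)], rng=rng)
        env = condition_emg(raw, FilterSpec(), FS)
        assert detect_muscle_onset(env, FS) is None

    def test_flat_envelope_has_no_onset(self):
        env = np.full(4000, 0.25)
        env[:1000] += np.sin(np.arange(1000)) * 1e-3  # non-degenerate baseline
        assert detect_muscle_onset(env, FS) is None

    def test_degenerate_baseline_rejected(self):
        env = np.zeros(4000)
        env[2000:] = 1.0
        with pytest.raises(DegenerateBaselineError):
            detect_muscle_onset(env, FS)

    def test_equals_brute_force_on_short_signals(self, rng):
        """Exhaustive-scan equivalence on 50 random short envelopes."""
        params = OnsetParams(baseline_window=(0.0, 0.5))
        for _ in range(50):
            env, _ = _envelope(rng, n_bursts=rng.integers(0, 3),
                               amp=rng.uniform(4, 12),
                               duration=rng.uniform(0.02, 0.3))
            assert detect_muscle_onset(env, FS, params) == brute_force_onset(
                env, FS, params)

    @given(st.floats(min_value=7.0, max_value=14.0))
    @settings(deadline=None, max_examples=20)
    def test_raising_threshold_never_advances_onset(self, k):
        rng = np.random.default_rng(42)
        env, _ = _envelope(rng)
        base = detect_muscle_onset(env, FS, OnsetParams(k_sd=7.0))
        higher = detect_muscle_onset(env, FS, OnsetParams(k_sd=k))
        if higher is not None:
            assert base is not None and higher >= base

    @given(st.floats(min_value=0.05, max_value=0.4))
    @settings(deadline=None, max_examples=20)
    def test_longer_sustain_never_creates_an_onset(self, sustain):
        rng = np.random.default_rng(43)
        env, _ = _envelope(rng, duration=0.12)
        short = detect_muscle_onset(env, FS, OnsetParams(sustain_s=0.05))
        longer = detect_muscle_onset(env, FS, OnsetParams(sustain_s=sustain))
        if short is None:
            assert longer is None


class TestLatencies:
    EV = EventSet(reach_on=3.0, reach_off=4.0, cop_on=2.6, step_on=2.9,
                  step_off=3.3)

    def test_signs(self):
        lat = onsets_relative_to_reach({"ES_L": 2.8, "GAS_R": 3.1, "RA_L": None},
                                       self.EV)
        assert lat["ES_L"] == pytest.approx(-0.2)
        assert lat["GAS_R"] == pytest.approx(0.1)
        assert lat["RA_L"] is None

    def test_older_gastrocnemius_follows_reach(self, default_cohort):
        """Sign structure of the cohort: GAS latency positive in OLDER,
        negative in YOUNG (delayed anticipatory adjustments with age)."""
        _, _, metrics = default_cohort
        gas = metrics[metrics.metric == "lat_GAS_L_s"]
        older = gas[gas.group == "OLDER"]["value"]
        young = gas[gas.group == "YOUNG"]["value"]
        assert (older > 0).mean() > 0.8
        assert (young < 0).mean() > 0.8


class TestCci:
    def test_silent_antagonist_gives_zero(self):
        assert compute_cci(np.array([0.4, 0.8]), np.zeros(2)) == 0.0

    def test_equal_half_activation_gives_one(self):
        a = np.full(100, 0.5)
        assert compute_cci(a, a) == pytest.approx(1.0)

    def test_hand_computed_example(self):
        a = np.array([0.2, 0.4])
        b = np.array([0.1, 0.4])
        # mean of [(0.1/0.2)*0.3, 1*0.8] = mean(0.15, 0.8)
        assert compute_cci(a, b) == pytest.approx(0.475)

    def test_symmetry_and_amplitude_weighting(self, rng):
        a, b = rng.random(200), rng.random(200)
        assert compute_cci(a, b) == pytest.approx(compute_cci(b, a))
        assert compute_cci(2 * a, 2 * b) == pytest.approx(2 * compute_cci(a, b))

    def test_ratio_method_is_scale_invariant(self, rng):
        a, b = rng.random(200) + 0.1, rng.random(200) + 0.1
        assert compute_cci(2 * a, 2 * b, method="ratio") == pytest.approx(
            compute_cci(a, b, method="ratio"))

    def test_length_mismatch_rejected(self):
        with pytest.raises(DataError, match="mismatch"):
            compute_cci(np.zeros(3), np.zeros(4))

    def test_range_bounds(self, rng):
        a, b = rng.random(500), rng.random(500)
        assert 0.0 <= compute_cci(a, b) <= 2.0


class TestCciPhases:
    EV = EventSet(reach_on=3.0, reach_off=4.2, cop_on=2.6, step_on=2.9,
                  step_off=3.3)

    def test_constant_equal_envelopes_equal_phases(self):
        t = np.arange(0, 8, 1 / FS)
        a = np.full_like(t, 0.4)
        values, flags = cci_by_phase(a, a, t, self.EV)
        assert len(set(round(v, 12) for v in values.values())) == 1
        assert not flags

    def test_coactivity_only_after_reach(self):
        t = np.arange(0, 8, 1 / FS)
        a = np.where(t >= 3.0, 0.5, 0.0)
        values, _ = cci_by_phase(a, a, t, self.EV)
        assert values["i"] == 0.0 and values["ii"] == 0.0
        assert values["iii"] > 0.5

    def test_overlapping_termination_flagged(self):
        ev = EventSet(reach_on=3.0, reach_off=3.3, cop_on=2.6, step_on=2.9,
                      step_off=3.2)
        t = np.arange(0, 8, 1 / FS)
        a = np.full_like(t, 0.2)
        _, flags = cci_by_phase(a, a, t, ev)
        assert "termination_overlaps_movement" in flags

    def test_configured_phase_ratio_recovered_without_noise(self):
        """Channel A at half of B's amplitude in phase ii (A peaks later) ->
        normalized CCI(ii) = 0.5/1 × (0.5 + 1) = 0.75, within 2%."""
        ev = self.EV
        dur = 8.0
        a_raw = generate_emg_channel(
            dur, FS, 0.0,
            [(ev.reach_on - 0.6, 0.7, 0.5), (ev.reach_on + 0.2, 0.5, 1.0)],
            seed=0)
        b_raw = generate_emg_channel(
            dur, FS, 0.0, [(ev.reach_on - 0.6, 1.4, 1.0)], seed=0)
        spec = FilterSpec()
        # normalize each muscle by its own maximum, as the pipeline does
        a_env = condition_emg(a_raw, spec, FS)
        b_env = condition_emg(b_raw, spec, FS)
        a_env, _ = normalize_envelopes([a_env])
        b_env, _ = normalize_envelopes([b_env])
        t = np.arange(int(dur * FS)) / FS
        values, _ = cci_by_phase(a_env[0], b_env[0], t, ev)
        assert values["ii"] == pytest.approx(0.75, rel=0.02)
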