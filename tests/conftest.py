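"""Shared fixtures: synthetic cohorts generated at test time.

The session-scoped default cohort (full 2×10 design, 240 trials, default
noise) is the workhorse for round-trip and end-to-end checks; smaller specs
serve the fast unit tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from postprime import CohortSpec, NoiseConfig, PipelineConfig
from postprime.pipeline import process_participant, results_to_long
from postprime.synthetic_data import generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Full default cohort processed end-to-end: (results, truths, metrics).

    ``results[i]`` is the pipeline's TrialResult for the trial whose ground
    truth is ``truths[i]``.
    """
    spec = CohortSpec(seed=11)
    cfg = PipelineConfig(cohort=spec)
    results, truths = [], []
    batch, batch_truths = [], []
    for rec, truth in generate_cohort(spec):
        if batch and rec.meta.participant != batch[0].meta.participant:
            res, fails = process_participant(batch, cfg)
            assert not fails, fails
            results.extend(res)
            truths.extend(batch_truths)
            batch, batch_truths = [], []
        batch.append(rec)
        batch_truths.append(truth)
    res, fails = process_participant(batch, cfg)
    assert not fails, fails
    results.extend(res)
    truths.extend(batch_truths)
    metrics = results_to_long(results)
    return results, truths, metrics


@pytest.fixture()
def small_spec():
    """2 participants/group × 4 conditions × 1 trial = 16 trials."""
    return CohortSpec(n_per_group=2, trials_per_condition=1, seed=5)


@pytest.fixture()
def zero_noise_spec():
    """Noise-free channels; between-participant heterogeneity retained."""
    return CohortSpec(seed=7, noise=NoiseConfig(noise_scale=0.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
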