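import numpy as np
import pandas as pd
import pytest

from oddball_erp import (
    DesignSpec,
    EpochSet,
    PreprocessConfig,
    SubjectSpec,
    generate_sequence,
    synthesize_recording,
)
from oddball_erp.templates import templates_for_age, uk_preset


@pytest.fixture
def default_design():
    return DesignSpec()


@pytest.fixture
def small_design():
    # scaled-down session that still exercises every pipeline stage
    return DesignSpec(n_trials_total=100, n_frequent=80, n_infrequent=10,
                      n_trial_unique=10)


@pytest.fixture
def uk_truth():
    return uk_preset()


def make_epochs(
    waveforms: np.ndarray,
    conditions,
    sample_rate_hz: float = 500.0,
    pre_ms: float = 200.0,
    post_ms: float = 800.0,
) -> EpochSet:
    """Build an EpochSet directly from per-epoch Fz waveforms (other
    channels copy Fz); waveforms are (n_epochs, n_times) matching the
    -200..800 ms grid."""
    waveforms = np.asarray(waveforms, float)
    n, n_t = waveforms.shape
    times = np.arange(-int(pre_ms * sample_rate_hz / 1000),
                      int(post_ms * sample_rate_hz / 1000) + 1) \
        * 1000.0 / sample_rate_hz
    assert n_t == len(times)
    data = np.repeat(waveforms[:, None, :], 8, axis=1)
    conditions = np.asarray(conditions, dtype=object)
    ordinals = np.zeros(n, dtype=int)
    for c in np.unique(conditions):
        idx = np.flatnonzero(conditions == c)
        ordinals[idx] = np.arange(len(idx))
    return EpochSet(data=data, times_ms=times, conditions=conditions,
                    ordinals=ordinals, sample_rate_hz=sample_rate_hz)


@pytest.fixture
def epoch_factory():
    return make_epochs


@pytest.fixture
def times_ms():
    return np.arange(-100, 401) * 2.0  # -200..800 ms at 500 Hz


def make_noise_free_subject(design, age="5m", seed=0, truth=None,
                            **spec_kw):
    truth = truth or uk_preset()
    n_by_cond = {"Frequent": design.n_frequent,
                 "Infrequent": design.n_infrequent,
                 "TrialUnique": design.n_trial_unique}
    tpls = templates_for_age(truth, age, n_by_cond,
                             sample_rate_hz=design.sample_rate_hz)
    kw = dict(noise_sd_uv=0.0, drift_amplitude_uv=0.0,
              artifact_epoch_fraction=0.0)
    kw.update(spec_kw)
    return SubjectSpec(subject_id="sub", cohort=truth.name, age_point=age,
                       state="awake", templates=tpls, seed=seed, **kw)


@pytest.fixture
def noise_free_recording(small_design):
    seq = generate_sequence(small_design, seed=11)
    spec = make_noise_free_subject(small_design, seed=12)
    return synthesize_recording(spec, seq)
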