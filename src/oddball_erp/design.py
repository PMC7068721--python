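"""Oddball stimulus-sequence design and generation.

The session design presents three auditory categories: a *Frequent*
standard tone (80% of trials), an *Infrequent* white-noise deviant (10%)
and *Trial Unique* novel sounds (10%), each novel sound occurring exactly
once.  Stimuli last 100 ms (5 ms ramps) and are separated by an
inter-stimulus interval jittered uniformly between 650 and 750 ms
(mean 700 ms).  Condition counts are exact, not probabilistic.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import StimulusSequence


class ConfigurationError(ValueError):
    """Raised when a design or subject specification is inconsistent."""


@dataclass(frozen=True)
class DesignSpec:
    """Parameters of one oddball session.

    Defaults encode the 1000-trial 800/100/100 design at 500 Hz.
    """

    n_trials_total: int = 1000
    n_frequent: int = 800
    n_infrequent: int = 100
    n_trial_unique: int = 100
    stim_duration_ms: float = 100.0
    ramp_ms: float = 5.0
    isi_mean_ms: float = 700.0
    isi_min_ms: float = 650.0
    isi_max_ms: float = 750.0
    sample_rate_hz: float = 500.0
    lead_in_s: float = 1.0

    def __post_init__(self) -> None:
        if self.n_frequent + self.n_infrequent + self.n_trial_unique \
                != self.n_trials_total:
            raise ConfigurationError(
                "condition counts "
                f"{self.n_frequent}+{self.n_infrequent}+{self.n_trial_unique}"
                f" do not sum to n_trials_total={self.n_trials_total}"
            )
        if not (self.isi_min_ms <= self.isi_mean_ms <= self.isi_max_ms):
            raise ConfigurationError("require isi_min <= isi_mean <= isi_max")
        if min(self.n_frequent, self.n_infrequent, self.n_trial_unique) < 0:
            raise ConfigurationError("condition counts must be non-negative")
        if self.sample_rate_hz <= 0:
            raise ConfigurationError("sample_rate_hz must be positive")


def sample_isis(design: DesignSpec, n: int,
                rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` inter-stimulus intervals (ms), uniform on
    [isi_min_ms, isi_max_ms]."""
    return rng.uniform(design.isi_min_ms, design.isi_max_ms, size=n)


def generate_sequence(design: DesignSpec, seed: int) -> StimulusSequence:
    """Generate one randomized session with exact per-condition counts.

    Trial order is an unconstrained uniform shuffle (no minimum spacing
    between oddballs is imposed).  Successive onsets are separated by
    ``stim_duration_ms`` plus a uniformly jittered ISI.  Trial Unique
    events carry unique ``stimulus_id`` values; Frequent/Infrequent
    events reuse a single identifier each.
    """
    rng = np.random.default_rng(seed)
    labels = np.array(
        ["Frequent"] * design.n_frequent
        + ["Infrequent"] * design.n_infrequent
        + ["TrialUnique"] * design.n_trial_unique,
        dtype=object,
    )
    rng.shuffle(labels)

    n = design.n_trials_total
    isis_ms = sample_isis(design, n, rng)
    # onset[i+1] = onset[i] + stimulus duration + ISI_i; last ISI is unused
    # for onsets but kept so each trial has an associated interval.
    gaps_s = (design.stim_duration_ms + isis_ms[:-1]) / 1000.0 if n > 1 \
        else np.empty(0)
    onsets_s = design.lead_in_s + np.concatenate(([0.0], np.cumsum(gaps_s)))

    stim_ids = np.empty(n, dtype=object)
    stim_ids[labels == "Frequent"] = "tone_500hz"
    stim_ids[labels == "Infrequent"] = "white_noise"
    tu_idx = np.flatnonzero(labels == "TrialUnique")
    for k, i in enumerate(tu_idx):
        stim_ids[i] = f"unique_{k:03d}"

    ordinals = np.zeros(n, dtype=int)
    for cond in np.unique(labels):
        idx = np.flatnonzero(labels == cond)
        ordinals[idx] = np.arange(len(idx))

    events = pd.DataFrame(
        {
            "onset_s": onsets_s,
            "onset_sample": np.round(
                onsets_s * design.sample_rate_hz).astype(int),
            "condition": labels,
            "stimulus_id": stim_ids,
            "ordinal": ordinals,
            "isi_ms": isis_ms,
        }
    )
    return StimulusSequence(events=events,
                            sample_rate_hz=design.sample_rate_hz)
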