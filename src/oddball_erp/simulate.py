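"""Forward simulation of continuous oddball EEG and of whole cohorts.

The continuous signal is built as: per-event Gaussian component bumps
(scaled by condition, habituation ordinal and a fixed per-channel gain)
+ white/pink instrument noise + a slow sinusoidal drift emulating sweat
artifact + optional high-amplitude artifact pulses injected into a random
fraction of epochs.  Everything is driven by a single seed per subject,
so the output is bit-reproducible.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CHANNELS, CONDITIONS, Recording, StimulusSequence
from .design import ConfigurationError, DesignSpec, generate_sequence
from .templates import (
    AGE_POINTS,
    CohortGroundTruth,
    SubjectSpec,
    _ANTHRO_MEASURES,
    templates_for_age,
)

# relative projection of the (frontal) components onto the montage;
# Fz carries the full amplitude since all analyses read Fz
CHANNEL_GAINS = np.array([1.0, 0.9, 0.9, 0.85, 0.95, 0.85, 0.8, 0.8])

EPOCH_PRE_S = 0.2
EPOCH_POST_S = 0.8

ARTIFACT_AMPLITUDE_UV = 400.0
ARTIFACT_WIDTH_S = 0.15


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f-shaped noise via spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = 1.0 / np.sqrt(freqs[nz])
    scale[0] = 0.0
    out = np.fft.irfft(spec * scale, n)
    sd = out.std()
    return out / sd if sd > 0 else out


def synthesize_recording(
    subject: SubjectSpec,
    sequence: StimulusSequence,
    duration_s: float | None = None,
) -> Recording:
    """Render one subject's continuous 8-channel session.

    ``duration_s`` defaults to one second past the end of the last epoch;
    a sequence extending beyond an explicitly requested duration is an
    error.  Epochs flagged for artifact injection receive a smooth
    high-amplitude pulse (peak-to-peak well above the 200 uV rejection
    threshold even after band-pass filtering) on one random channel; the
    injected event indices are recorded in ``Recording.meta``.
    """
    fs = sequence.sample_rate_hz
    events = sequence.events
    last_onset_s = float(events["onset_s"].iloc[-1]) if len(events) else 0.0
    needed_s = last_onset_s + EPOCH_POST_S + 1.0
    if duration_s is None:
        duration_s = needed_s
    elif duration_s < needed_s:
        raise ConfigurationError(
            f"sequence needs {needed_s:.1f}s but only "
            f"{duration_s:.1f}s requested"
        )
    n = int(round(duration_s * fs))
    rng = np.random.default_rng(subject.seed)

    sig = np.zeros((len(CHANNELS), n))

    # stimulus markers precede the true acoustic onset by the hardware
    # timing delay; neural responses are locked to the *sound*, so the
    # bumps go in delayed relative to the marker
    delay = int(round(subject.timing_delay_ms / 1000.0 * fs))

    # --- event-locked component bumps (vector per event, all channels) ---
    for tpl in subject.templates:
        half_ms = 5.0 * tpl.width_ms
        lo = int(np.floor((tpl.peak_latency_ms - half_ms) / 1000.0 * fs))
        hi = int(np.ceil((tpl.peak_latency_ms + half_ms) / 1000.0 * fs))
        rel = np.arange(lo, hi + 1)
        t_ms = rel * 1000.0 / fs
        z = (t_ms - tpl.peak_latency_ms) / tpl.width_ms
        bump = np.exp(-0.5 * z * z)
        for onset, cond, ordinal in zip(
            events["onset_sample"], events["condition"], events["ordinal"]
        ):
            a = tpl.amplitude(cond, int(ordinal))
            idx = onset + delay + rel
            m = (idx >= 0) & (idx < n)
            sig[:, idx[m]] += np.outer(CHANNEL_GAINS, a * bump[m])

    # --- noise: white + pink per channel ---
    if subject.noise_sd_uv > 0:
        pf = subject.pink_fraction
        for ch in range(len(CHANNELS)):
            w = rng.standard_normal(n)
            p = _pink_noise(n, rng)
            sig[ch] += subject.noise_sd_uv * (
                np.sqrt(1.0 - pf) * w + np.sqrt(pf) * p
            )

    # --- slow sinusoidal drift (sweat artifact), random phase/channel ---
    if subject.drift_amplitude_uv > 0:
        t = np.arange(n) / fs
        for ch in range(len(CHANNELS)):
            phase = rng.uniform(0, 2 * np.pi)
            sig[ch] += subject.drift_amplitude_uv * np.sin(
                2 * np.pi * t / subject.drift_period_s + phase
            )

    # --- artifact pulses in a random fraction of epochs ---
    n_art = int(round(subject.artifact_epoch_fraction * len(events)))
    art_events = np.sort(
        rng.choice(len(events), size=n_art, replace=False)
    ) if n_art else np.empty(0, dtype=int)
    pulse = ARTIFACT_AMPLITUDE_UV * np.hanning(
        max(int(ARTIFACT_WIDTH_S * fs), 3))
    for ev in art_events:
        onset = int(events["onset_sample"].iloc[ev])
        ch = int(rng.integers(len(CHANNELS)))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        # keep the pulse inside this trial's epoch window and clear of
        # the neighbouring trials' pre-stimulus windows
        start = onset + delay + int(rng.uniform(0.05, 0.35) * fs)
        stop = min(start + len(pulse), n)
        sig[ch, start:stop] += sign * pulse[: stop - start]

    return Recording(
        samples=sig,
        sample_rate_hz=fs,
        events=events[["onset_sample", "condition", "stimulus_id",
                       "ordinal"]].copy(),
        meta={
            "subject_id": subject.subject_id,
            "cohort": subject.cohort,
            "age_point": subject.age_point,
            "state": subject.state,
            "seed": subject.seed,
            "artifact_events": art_events.tolist(),
        },
    )


# ---------------------------------------------------------------------------
# cohort-level simulation


@dataclass
class SubjectRecordings:
    subject_id: str
    cohort: str
    recordings: dict[str, Recording]  # age point -> recording
    state: dict[str, str] = field(default_factory=dict)


@dataclass
class CohortDataset:
    """Recordings at both age points plus the ground-truth marker table."""

    subjects: list[SubjectRecordings]
    truth_table: pd.DataFrame


def _anthro_draw(truth: CohortGroundTruth, n: int,
                 rng: np.random.Generator) -> pd.DataFrame:
    cols = [f"{m}_{a}" for a in AGE_POINTS for m in _ANTHRO_MEASURES]
    mean = np.array([truth.anthro_mean.get(c, 0.0) for c in cols])
    k = len(cols)
    cov = np.full((k, k), truth.anthro_cross_corr)
    np.fill_diagonal(cov, 1.0)
    draws = rng.multivariate_normal(mean, cov, size=n)
    df = pd.DataFrame(draws, columns=cols)
    for m in _ANTHRO_MEASURES:
        df[f"d_{m}"] = df[f"{m}_5m"] - df[f"{m}_1m"]
    return df


def _subject_truth(truth: CohortGroundTruth, rng: np.random.Generator):
    """Per-subject window-mean targets (preset + between-subject noise)
    and the implied true delta-P3."""
    offsets = {
        (age, cond): rng.normal(0.0, truth.subject_sd_uv)
        for age in AGE_POINTS for cond in CONDITIONS
    }
    targets = {
        k: truth.p3_window_mean_uv[k] + offsets[k] for k in offsets
    }
    c1 = targets[("1m", "Infrequent")] - targets[("1m", "TrialUnique")]
    c5 = targets[("5m", "Infrequent")] - targets[("5m", "TrialUnique")]
    return targets, offsets, c1, c5


def simulate_marker_table(
    truth: CohortGroundTruth,
    n: int,
    seed: int,
    measurement_noise_sd: float = 1.0,
) -> pd.DataFrame:
    """Fast path: draw the marker table directly, without rendering EEG.

    Measured delta-P3 is the true per-subject delta plus independent
    measurement noise; the outcome composite is linearly coupled to the
    *true* delta.  Used for replicate studies (power, calibration) where
    full signal synthesis would be pointlessly expensive.
    """
    if n < 2:
        raise ConfigurationError("n must be >= 2")
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        _, _, c1, c5 = _subject_truth(truth, rng)
        d_true = c1 - c5
        rows.append({
            "subject_id": f"{truth.name}_{i:03d}",
            "cohort": truth.name,
            "contrast_1m_uv": c1,
            "contrast_5m_uv": c5,
            "true_delta_p3": d_true,
            "delta_p3": d_true + rng.normal(0.0, measurement_noise_sd),
            "outcome": truth.outcome_mean
            + truth.delta_p3_outcome_slope * d_true
            + rng.normal(0.0, truth.outcome_sd),
        })
    df = pd.DataFrame(rows)
    return pd.concat([df, _anthro_draw(truth, n, rng)], axis=1)


def generate_cohort(
    truth: CohortGroundTruth,
    n_per_cohort: int,
    seed: int,
    design: DesignSpec | None = None,
    noise_sd_uv: float = 5.0,
    drift_amplitude_uv: float = 20.0,
    artifact_epoch_fraction: float = 0.05,
    state_by_age: dict[str, str] | None = None,
) -> CohortDataset:
    """Render full recordings at both age points for ``n_per_cohort``
    subjects, plus a ground-truth table with the true per-subject
    delta-P3, anthropometric z-scores and the outcome composite.
    """
    if n_per_cohort < 2:
        raise ConfigurationError("n_per_cohort must be >= 2")
    design = design or DesignSpec()
    state_by_age = state_by_age or {"1m": "asleep", "5m": "awake"}
    rng = np.random.default_rng(seed)

    n_by_cond = {
        "Frequent": design.n_frequent,
        "Infrequent": design.n_infrequent,
        "TrialUnique": design.n_trial_unique,
    }

    subjects: list[SubjectRecordings] = []
    rows = []
    anthro = _anthro_draw(truth, n_per_cohort, rng)
    for i in range(n_per_cohort):
        sid = f"{truth.name}_{i:03d}"
        targets, offsets, c1, c5 = _subject_truth(truth, rng)
        d_true = c1 - c5
        recs: dict[str, Recording] = {}
        for age in AGE_POINTS:
            seq = generate_sequence(design,
                                    seed=int(rng.integers(2 ** 31)))
            tpls = templates_for_age(
                truth, age, n_by_cond,
                sample_rate_hz=design.sample_rate_hz,
                subject_offsets={
                    cond: offsets[(age, cond)] for cond in CONDITIONS
                },
            )
            spec = SubjectSpec(
                subject_id=sid, cohort=truth.name, age_point=age,
                state=state_by_age[age], templates=tpls,
                noise_sd_uv=noise_sd_uv,
                drift_amplitude_uv=drift_amplitude_uv,
                artifact_epoch_fraction=artifact_epoch_fraction,
                seed=int(rng.integers(2 ** 31)),
            )
            recs[age] = synthesize_recording(spec, seq)
        subjects.append(SubjectRecordings(
            subject_id=sid, cohort=truth.name, recordings=recs,
            state=dict(state_by_age)))
        rows.append({
            "subject_id": sid, "cohort": truth.name,
            "true_contrast_1m_uv": c1, "true_contrast_5m_uv": c5,
            "true_delta_p3": d_true,
            "outcome": truth.outcome_mean
            + truth.delta_p3_outcome_slope * d_true
            + rng.normal(0.0, truth.outcome_sd),
        })
    table = pd.concat(
        [pd.DataFrame(rows), anthro.reset_index(drop=True)], axis=1)
    return CohortDataset(subjects=subjects, truth_table=table)
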