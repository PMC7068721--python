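"""ERP component templates and cohort-level ground truth.

The simulator models each ERP component as a Gaussian bump added to the
continuous signal at every stimulus onset: peak latency and width (the
Gaussian standard deviation) are fixed per component and age point, the
peak amplitude depends on condition, and amplitudes decay multiplicatively
across the session (habituation) as ``a0 * (1 - rate)**k`` where ``k`` is
the within-condition trial ordinal.

Ground-truth P3 effects are specified on the *measured* scale — the
session-averaged mean amplitude inside the age-specific analysis window —
and the generator back-calculates the Gaussian peak amplitude that yields
exactly that window mean under the habituation schedule.  This makes
recovery tests exact: what the pipeline measures is, in expectation, the
number stored in the ground-truth table.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import CONDITIONS

AGE_POINTS = ("1m", "5m")


@dataclass
class ComponentTemplate:
    """One Gaussian ERP component.

    ``amplitude_by_condition`` holds signed peak amplitudes in microvolts
    (negative for negative-going components); ``width_ms`` is the Gaussian
    standard deviation.  ``habituation_rate`` maps condition to the
    per-trial multiplicative decay rate in [0, 1).
    """

    name: str
    polarity: str
    peak_latency_ms: float
    width_ms: float
    amplitude_by_condition: dict[str, float]
    habituation_rate: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.width_ms <= 0:
            raise ValueError("width_ms must be positive")
        if self.polarity not in ("+", "-"):
            raise ValueError("polarity must be '+' or '-'")
        for c, a in self.amplitude_by_condition.items():
            if not np.isfinite(a):
                raise ValueError(f"non-finite amplitude for {c}")
        for c, r in self.habituation_rate.items():
            if not (0.0 <= r < 1.0):
                raise ValueError(f"habituation_rate for {c} outside [0,1)")

    def rate(self, condition: str) -> float:
        return self.habituation_rate.get(condition, 0.0)

    def amplitude(self, condition: str, ordinal: int) -> float:
        """Signed peak amplitude of trial ``ordinal`` (0-based) of
        ``condition`` after habituation decay."""
        a0 = self.amplitude_by_condition[condition]
        return a0 * (1.0 - self.rate(condition)) ** ordinal

    def waveform(self, times_ms: np.ndarray, condition: str,
                 ordinal: int = 0) -> np.ndarray:
        """Evaluate the component on a time grid (ms, stimulus-locked)."""
        a = self.amplitude(condition, ordinal)
        z = (np.asarray(times_ms, float) - self.peak_latency_ms) / self.width_ms
        return a * np.exp(-0.5 * z * z)


@dataclass
class SubjectSpec:
    """Everything needed to synthesize one subject's session."""

    subject_id: str
    cohort: str
    age_point: str
    state: str  # "asleep" | "awake"
    templates: list[ComponentTemplate]
    noise_sd_uv: float = 5.0
    drift_amplitude_uv: float = 20.0
    drift_period_s: float = 30.0
    artifact_epoch_fraction: float = 0.05
    pink_fraction: float = 0.5
    timing_delay_ms: float = 32.0  # marker precedes the acoustic onset
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.artifact_epoch_fraction <= 1.0):
            raise ValueError("artifact_epoch_fraction outside [0,1]")
        if self.age_point not in AGE_POINTS:
            raise ValueError(f"unknown age point {self.age_point!r}")


# ---------------------------------------------------------------------------
# helpers relating peak amplitudes to measured window means


def session_mean_decay_factor(rate: float, n_trials: int) -> float:
    """Mean of ``(1-rate)**k`` over k = 0..n_trials-1 (closed form)."""
    if n_trials < 1:
        return 1.0  # condition absent from the design: nothing to average
    if rate == 0.0:
        return 1.0
    q = 1.0 - rate
    return (1.0 - q ** n_trials) / (n_trials * rate)


def window_mean_factor(peak_ms: float, width_ms: float,
                       t_start_ms: float, t_end_ms: float,
                       sample_rate_hz: float = 500.0) -> float:
    """Mean of a unit-peak Gaussian over the inclusive sample grid of an
    analysis window — the factor converting peak amplitude to window mean."""
    step = 1000.0 / sample_rate_hz
    t = np.arange(t_start_ms, t_end_ms + step / 2, step)
    z = (t - peak_ms) / width_ms
    return float(np.mean(np.exp(-0.5 * z * z)))


# ---------------------------------------------------------------------------
# cohort ground truth


@dataclass
class CohortGroundTruth:
    """True effect structure of a simulated cohort.

    ``p3_window_mean_uv`` maps (age_point, condition) to the session-
    averaged P3 mean amplitude (microvolts, measured scale) a noise-free
    subject would show; ``p3_habituation_rate`` maps the same keys to the
    per-trial decay rate.  ``subject_sd_uv`` is the between-subject SD
    added independently to each (age, condition) target, which is what
    makes the true per-subject delta-P3 vary and couple to outcome.
    The outcome composite is ``outcome_mean +
    delta_p3_outcome_slope * true_delta_p3 + N(0, outcome_sd)``.
    """

    name: str
    p3_window_mean_uv: dict[tuple[str, str], float]
    p3_habituation_rate: dict[tuple[str, str], float]
    delta_p3_outcome_slope: float = 2.2
    outcome_mean: float = 95.0
    outcome_sd: float = 12.0
    subject_sd_uv: float = 0.8
    anthro_mean: dict[str, float] = field(default_factory=dict)
    anthro_cross_corr: float = 0.45
    p3_peak_ms: dict[str, float] = field(
        default_factory=lambda: {"1m": 350.0, "5m": 300.0})
    p3_width_ms: dict[str, float] = field(
        default_factory=lambda: {"1m": 30.0, "5m": 30.0})

    def true_contrast(self, age: str) -> float:
        """Infrequent minus Trial Unique window-mean amplitude at ``age``."""
        return (self.p3_window_mean_uv[(age, "Infrequent")]
                - self.p3_window_mean_uv[(age, "TrialUnique")])

    @property
    def true_delta_p3(self) -> float:
        """Population delta-P3: 1-month contrast minus 5-month contrast."""
        return self.true_contrast("1m") - self.true_contrast("5m")


_ANTHRO_MEASURES = ("waz", "laz", "hcz", "wlz")


def _anthro_means(vals_1m, vals_5m) -> dict[str, float]:
    out = {}
    for m, v in zip(_ANTHRO_MEASURES, vals_1m):
        out[f"{m}_1m"] = v
    for m, v in zip(_ANTHRO_MEASURES, vals_5m):
        out[f"{m}_5m"] = v
    return out


def uk_preset() -> CohortGroundTruth:
    """High-income-cohort preset: developmental crossover of the P3.

    At 1 month the intensity-driven Infrequent (white noise) response
    dominates; by 5 months the novelty-driven Trial Unique response is
    largest, and within-session habituation to the Infrequent deviant
    strengthens.  True delta-P3 is +4 microvolts.
    """
    return CohortGroundTruth(
        name="UK",
        p3_window_mean_uv={
            ("1m", "Frequent"): 2.5, ("1m", "Infrequent"): 5.0,
            ("1m", "TrialUnique"): 3.0,
            ("5m", "Frequent"): 2.0, ("5m", "Infrequent"): 3.5,
            ("5m", "TrialUnique"): 5.5,
        },
        p3_habituation_rate={
            ("1m", "Frequent"): 0.02, ("1m", "Infrequent"): 0.004,
            ("1m", "TrialUnique"): 0.0,
            ("5m", "Frequent"): 0.02, ("5m", "Infrequent"): 0.02,
            ("5m", "TrialUnique"): 0.0,
        },
        anthro_mean=_anthro_means(
            (-0.066, -0.305, 0.698, 0.10), (-0.136, -0.030, 0.746, 0.147)),
    )


def gambia_preset() -> CohortGroundTruth:
    """Rural-LMIC-cohort preset: no developmental crossover.

    The Infrequent-minus-TrialUnique contrast is the same (+1.5 uV) at
    both age points, so the population delta-P3 is exactly zero, and the
    Infrequent habituation rate does not increase with age.
    """
    return CohortGroundTruth(
        name="Gambia",
        p3_window_mean_uv={
            ("1m", "Frequent"): 2.5, ("1m", "Infrequent"): 4.5,
            ("1m", "TrialUnique"): 3.0,
            ("5m", "Frequent"): 2.0, ("5m", "Infrequent"): 3.5,
            ("5m", "TrialUnique"): 2.0,
        },
        p3_habituation_rate={
            ("1m", "Frequent"): 0.02, ("1m", "Infrequent"): 0.004,
            ("1m", "TrialUnique"): 0.0,
            ("5m", "Frequent"): 0.02, ("5m", "Infrequent"): 0.004,
            ("5m", "TrialUnique"): 0.0,
        },
        anthro_mean=_anthro_means(
            (-0.603, -0.852, -0.285, 0.292), (-0.447, -0.492, -0.356, -0.104)),
    )


PRESETS = {"UK": uk_preset, "Gambia": gambia_preset}


# fixed (condition-independent) early/late components per age point;
# peak amplitudes in microvolts, widths are Gaussian SDs
_FIXED_COMPONENTS = {
    "1m": [("N1", "-", 100.0, 25.0, -4.0), ("Nc", "-", 650.0, 40.0, -3.0)],
    "5m": [("P1", "+", 70.0, 8.0, 2.0), ("N2", "-", 100.0, 8.0, -2.0),
           ("Nc", "-", 600.0, 40.0, -4.0)],
}

# analysis windows on which the P3 targets are defined (must agree with
# the component-quantification registry)
_P3_WINDOW = {"1m": (250.0, 450.0), "5m": (200.0, 400.0)}


def templates_for_age(
    truth: CohortGroundTruth,
    age: str,
    n_trials_by_condition: dict[str, int],
    sample_rate_hz: float = 500.0,
    subject_offsets: dict[str, float] | None = None,
    state_gain: float = 1.0,
) -> list[ComponentTemplate]:
    """Build the component set for one subject at one age point.

    The P3 peak amplitude per condition is calibrated so that the
    session-averaged window mean equals the ground-truth target (plus the
    per-subject offset), under the condition's habituation schedule and
    trial count.  ``state_gain`` scales all component amplitudes (used to
    emulate a global asleep/awake difference; 1.0 by default).
    """
    peak = truth.p3_peak_ms[age]
    width = truth.p3_width_ms[age]
    w0, w1 = _P3_WINDOW[age]
    c = window_mean_factor(peak, width, w0, w1, sample_rate_hz)

    offsets = subject_offsets or {}
    amps: dict[str, float] = {}
    rates: dict[str, float] = {}
    for cond in CONDITIONS:
        target = truth.p3_window_mean_uv[(age, cond)] + offsets.get(cond, 0.0)
        rate = truth.p3_habituation_rate[(age, cond)]
        g = session_mean_decay_factor(rate, n_trials_by_condition[cond])
        amps[cond] = state_gain * target / (g * c)
        rates[cond] = rate
    p3 = ComponentTemplate("P3", "+", peak, width, amps, rates)

    fixed = [
        ComponentTemplate(
            name, pol, lat, wid,
            {cond: state_gain * amp for cond in CONDITIONS},
        )
        for name, pol, lat, wid, amp in _FIXED_COMPONENTS[age]
    ]
    return fixed + [p3]
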