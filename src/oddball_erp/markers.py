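"""Derived markers: within-session habituation and the delta-P3.

The habituation score for a condition is the P3 mean amplitude of the
first half of that condition's kept epochs minus that of the second half
(split by presentation order); positive scores indicate a response
decrement over the session.

The delta-P3 is the developmental change of the novelty contrast:
(Infrequent - TrialUnique) P3 mean amplitude at 1 month minus the same
contrast at 5 months.  A positive delta indexes a shift from intensity-
driven (white-noise) to novelty-driven (trial-unique) responding.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .components import WindowSpec, mean_amplitude
from .containers import EpochSet


@dataclass
class HabituationScore:
    subject_id: str
    condition: str
    first_half_mean_uv: float
    second_half_mean_uv: float
    score_uv: float
    n_first: int
    n_second: int


def habituation_score(
    es: EpochSet, condition: str, w: WindowSpec,
    subject_id: str = "", channel: str = "Fz",
    split: str = "condition",
) -> HabituationScore:
    """First-half minus second-half window mean amplitude.

    Kept epochs of the condition are ordered by original presentation
    (their within-condition ordinal) and median-split; with an odd count
    the middle epoch joins the first half.  ``split="session"`` instead
    splits at the session midpoint of the condition's ordinal range.
    Requires at least 2 kept epochs.
    """
    idx = es.select(condition, "kept")
    if len(idx) < 2:
        raise ValueError(
            f"habituation score undefined: {len(idx)} kept epoch(s) of "
            f"{condition!r} (need >= 2)"
        )
    ch = es.channel_index(channel)
    if split == "condition":
        cut = (len(idx) + 1) // 2  # middle epoch -> first half
        first, second = idx[:cut], idx[cut:]
    elif split == "session":
        ords = es.ordinals[idx]
        mid = (ords.min() + ords.max()) / 2.0
        first = idx[ords <= mid]
        second = idx[ords > mid]
        if len(first) == 0 or len(second) == 0:
            raise ValueError("session-midpoint split left a half empty")
    else:
        raise ValueError(f"unknown split {split!r}")
    wave1 = es.data[first, ch, :].mean(axis=0)
    wave2 = es.data[second, ch, :].mean(axis=0)
    a1 = mean_amplitude(wave1, es.times_ms, w)
    a2 = mean_amplitude(wave2, es.times_ms, w)
    return HabituationScore(
        subject_id=subject_id, condition=condition,
        first_half_mean_uv=a1, second_half_mean_uv=a2,
        score_uv=a1 - a2, n_first=len(first), n_second=len(second),
    )


@dataclass
class DeltaP3:
    subject_id: str
    contrast_1m_uv: float
    contrast_5m_uv: float
    delta_uv: float


def delta_p3_single(
    infrequent_1m: float, trial_unique_1m: float,
    infrequent_5m: float, trial_unique_5m: float,
    subject_id: str = "",
) -> DeltaP3:
    """Delta-P3 from the four P3 mean amplitudes of one subject."""
    c1 = infrequent_1m - trial_unique_1m
    c5 = infrequent_5m - trial_unique_5m
    return DeltaP3(subject_id=subject_id, contrast_1m_uv=c1,
                   contrast_5m_uv=c5, delta_uv=c1 - c5)


def delta_p3(measures: pd.DataFrame) -> pd.DataFrame:
    """Per-subject delta-P3 from a tidy measures table.

    Expects columns subject_id, age_point, condition, component,
    mean_amp_uv.  Subjects missing any of the four required P3 cells
    (Infrequent/TrialUnique at both ages) are excluded; the returned
    frame notes them in ``attrs["excluded"]``.
    """
    p3 = measures[(measures["component"] == "P3")
                  & measures["condition"].isin(
                      ["Infrequent", "TrialUnique"])]
    rows, excluded = [], []
    for sid, grp in p3.groupby("subject_id"):
        cell = {(a, c): v for a, c, v in zip(
            grp["age_point"], grp["condition"], grp["mean_amp_uv"])}
        needed = [("1m", "Infrequent"), ("1m", "TrialUnique"),
                  ("5m", "Infrequent"), ("5m", "TrialUnique")]
        if any(k not in cell for k in needed):
            excluded.append(
                {"subject_id": sid,
                 "missing": [f"{a}/{c}" for a, c in needed
                             if (a, c) not in cell]})
            continue
        d = delta_p3_single(
            cell[("1m", "Infrequent")], cell[("1m", "TrialUnique")],
            cell[("5m", "Infrequent")], cell[("5m", "TrialUnique")],
            subject_id=str(sid))
        rows.append({
            "subject_id": str(sid),
            "contrast_1m_uv": d.contrast_1m_uv,
            "contrast_5m_uv": d.contrast_5m_uv,
            "delta_p3": d.delta_uv,
        })
    out = pd.DataFrame(rows,
                       columns=["subject_id", "contrast_1m_uv",
                                "contrast_5m_uv", "delta_p3"])
    out.attrs["excluded"] = excluded
    return out


def habituation_table(
    epoch_sets: dict[str, EpochSet], age_point: str, w: WindowSpec,
    channel: str = "Fz", split: str = "condition",
) -> pd.DataFrame:
    """Habituation scores for every subject x condition at one age."""
    rows = []
    for sid, es in epoch_sets.items():
        for cond in np.unique(es.conditions):
            try:
                h = habituation_score(es, str(cond), w, subject_id=sid,
                                      channel=channel, split=split)
            except ValueError:
                continue
            rows.append({
                "subject_id": sid, "age_point": age_point,
                "condition": str(cond),
                "first_half_uv": h.first_half_mean_uv,
                "second_half_uv": h.second_half_mean_uv,
                "habituation_uv": h.score_uv,
            })
    return pd.DataFrame(rows)


def build_marker_table(
    delta: pd.DataFrame, covariates: pd.DataFrame,
) -> pd.DataFrame:
    """Join delta-P3 scores with cohort covariates (z-scores, outcome)
    on subject_id."""
    return delta.merge(covariates, on="subject_id", how="inner",
                       suffixes=("", "_cov"))
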