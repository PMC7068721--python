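"""Core in-memory containers shared across the pipeline.

A :class:`Recording` is a continuous multichannel signal plus its stimulus
events; an :class:`EpochSet` is the stack of fixed-length stimulus-locked
segments cut from it, carrying per-epoch condition labels, within-condition
ordinals and validity bookkeeping.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Default 8-electrode frontocentral montage (left-mastoid referenced).
CHANNELS = ("Fz", "FC1", "FC2", "C1", "Cz", "C2", "CP1", "CP2")

CONDITIONS = ("Frequent", "Infrequent", "TrialUnique")


@dataclass
class StimulusSequence:
    """Ordered trial events of one oddball session.

    ``events`` columns: onset_s, onset_sample, condition, stimulus_id,
    ordinal (0-based index within its condition, in presentation order).
    """

    events: pd.DataFrame
    sample_rate_hz: float

    def __len__(self) -> int:
        return len(self.events)

    def counts(self) -> dict[str, int]:
        return self.events["condition"].value_counts().to_dict()


@dataclass
class Recording:
    """Continuous EEG: ``samples`` is (n_channels, n_times) in microvolts."""

    samples: np.ndarray
    sample_rate_hz: float
    events: pd.DataFrame  # onset_sample, condition, stimulus_id, ordinal
    channel_names: tuple[str, ...] = CHANNELS
    reference: str = "left mastoid"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (channels x time)")
        if self.samples.shape[0] != len(self.channel_names):
            raise ValueError(
                f"{self.samples.shape[0]} rows but "
                f"{len(self.channel_names)} channel names"
            )
        bad = self.events["onset_sample"].to_numpy()
        if len(bad) and (bad.min() < 0 or bad.max() >= self.n_times):
            raise ValueError("event onsets fall outside the recording")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_times(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_times / self.sample_rate_hz

    def channel_index(self, name: str) -> int:
        return self.channel_names.index(name)

    def copy(self) -> "Recording":
        return replace(
            self, samples=self.samples.copy(), events=self.events.copy(),
            meta=dict(self.meta),
        )


@dataclass
class EpochSet:
    """Stimulus-locked epochs: ``data`` is (n_epochs, n_channels, n_times).

    ``valid`` marks epochs that survived artifact screening;
    ``kept`` additionally marks epochs retained after trial equalization.
    ``reason`` is one of {"none", "ptp", "flatline"} per epoch.
    """

    data: np.ndarray
    times_ms: np.ndarray
    conditions: np.ndarray
    ordinals: np.ndarray
    sample_rate_hz: float
    channel_names: tuple[str, ...] = CHANNELS
    valid: np.ndarray = None
    reason: np.ndarray = None
    kept: np.ndarray = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.data)
        if self.valid is None:
            self.valid = np.ones(n, dtype=bool)
        if self.reason is None:
            self.reason = np.array(["none"] * n, dtype=object)
        if self.kept is None:
            self.kept = self.valid.copy()

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    def channel_index(self, name: str) -> int:
        return self.channel_names.index(name)

    def counts(self, which: str = "kept") -> dict[str, int]:
        """Per-condition epoch counts over ``kept``/``valid``/``all``."""
        if which == "all":
            mask = np.ones(len(self), dtype=bool)
        elif which in ("kept", "valid"):
            mask = getattr(self, which)
        else:
            raise ValueError(f"unknown selector {which!r}")
        out: dict[str, int] = {}
        for cond in np.unique(self.conditions):
            out[str(cond)] = int(np.sum(mask & (self.conditions == cond)))
        return out

    def select(self, condition: str, which: str = "kept") -> np.ndarray:
        """Indices of epochs of ``condition`` passing the selector,
        in presentation (ordinal) order."""
        if which == "all":
            mask = self.conditions == condition
        else:
            mask = getattr(self, which) & (self.conditions == condition)
        idx = np.flatnonzero(mask)
        return idx[np.argsort(self.ordinals[idx], kind="stable")]

    def copy(self) -> "EpochSet":
        return replace(
            self,
            data=self.data.copy(),
            times_ms=self.times_ms.copy(),
            conditions=self.conditions.copy(),
            ordinals=self.ordinals.copy(),
            valid=self.valid.copy(),
            reason=self.reason.copy(),
            kept=self.kept.copy(),
            meta=dict(self.meta),
        )
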