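"""Preprocessing: band-pass filtering, timing-offset correction, epoching,
artifact/flatline rejection, trial equalization and dataset inclusion.

The chain reproduces a fixed automated routine: 0.5-30 Hz zero-phase
Blackman-window FIR (order 5500), stimulus markers advanced by the
measured acoustic delay (32.0 ms by default), segmentation from 200 ms
pre- to 800 ms post-stimulus, per-epoch peak-to-peak rejection above
200 uV and flatline rejection below 0.1 uV, equalization of the three
conditions to the smallest valid count, and exclusion of datasets with
fewer than 15 trials per condition.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .containers import CONDITIONS, EpochSet, Recording

logger = logging.getLogger(__name__)


@dataclass
class PreprocessConfig:
    hp_hz: float = 0.5
    lp_hz: float = 30.0
    filter_order: int = 5500
    filter_window: str = "blackman"
    zero_phase: bool = True
    offset_ms: float = 32.0
    epoch_pre_ms: float = 200.0
    epoch_post_ms: float = 800.0
    reject_ptp_uv: float = 200.0
    flatline_ptp_uv: float = 0.1
    min_trials_per_condition: int = 15
    baseline_correct: bool = True
    reject_channels: tuple[str, ...] | None = None  # None = all channels
    equalize_seed: int = 0

    def validate(self, sample_rate_hz: float) -> None:
        if not (0 < self.hp_hz < self.lp_hz < sample_rate_hz / 2):
            raise ValueError("require 0 < hp < lp < Nyquist")
        if self.epoch_pre_ms < 0 or self.epoch_post_ms <= 0:
            raise ValueError("epoch window must span stimulus onset")
        if self.offset_ms < 0:
            raise ValueError("offset_ms must be >= 0")


def design_fir(cfg: PreprocessConfig, sample_rate_hz: float) -> np.ndarray:
    """Band-pass FIR taps (odd length = order + 1, linear phase)."""
    numtaps = cfg.filter_order + 1
    if numtaps % 2 == 0:
        numtaps += 1  # odd length keeps an integer group delay
    return sps.firwin(
        numtaps,
        [cfg.hp_hz, cfg.lp_hz],
        pass_zero=False,
        window=cfg.filter_window,
        fs=sample_rate_hz,
    )


def bandpass_filter(rec: Recording, cfg: PreprocessConfig) -> Recording:
    """Zero-phase band-pass filter each channel.

    The symmetric (linear-phase) kernel is applied by centred FFT
    convolution, which compensates the group delay exactly; the band-pass
    design itself removes DC.  Raises if the recording is shorter than
    the kernel.
    """
    cfg.validate(rec.sample_rate_hz)
    taps = design_fir(cfg, rec.sample_rate_hz)
    if rec.n_times < len(taps):
        raise ValueError(
            f"recording has {rec.n_times} samples but the filter kernel "
            f"needs at least {len(taps)}"
        )
    demeaned = rec.samples - rec.samples.mean(axis=1, keepdims=True)
    filtered = sps.fftconvolve(demeaned, taps[None, :], mode="same", axes=1)
    out = rec.copy()
    out.samples = filtered
    out.meta["filtered"] = {
        "hp_hz": cfg.hp_hz, "lp_hz": cfg.lp_hz, "numtaps": len(taps),
        "window": cfg.filter_window, "zero_phase": cfg.zero_phase,
    }
    return out


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def apply_timing_offset(rec: Recording, cfg: PreprocessConfig) -> Recording:
    """Advance stimulus markers to the true acoustic onset.

    The marker precedes the sound by ``offset_ms``; onsets therefore move
    *later* in the recording by ``round(offset_ms * fs / 1000)`` samples
    (half rounds away from zero).  Events shifted beyond the recording
    end are dropped with a warning.
    """
    cfg.validate(rec.sample_rate_hz)
    shift = _round_half_away(cfg.offset_ms * rec.sample_rate_hz / 1000.0)
    events = rec.events.copy()
    events["onset_sample"] = events["onset_sample"] + shift
    keep = events["onset_sample"] < rec.n_times
    n_drop = int((~keep).sum())
    if n_drop:
        logger.warning("timing offset dropped %d event(s) beyond the "
                       "recording end", n_drop)
    out = rec.copy()
    out.events = events[keep].reset_index(drop=True)
    out.meta["timing_offset_samples"] = shift
    out.meta["events_dropped_by_offset"] = n_drop
    return out


def epoch(rec: Recording, cfg: PreprocessConfig) -> EpochSet:
    """Cut fixed-length stimulus-locked epochs.

    Window is [-epoch_pre_ms, +epoch_post_ms] with inclusive endpoints
    (501 samples at the defaults).  Baseline correction subtracts the
    mean over [-epoch_pre_ms, 0] per channel.  Events too close to
    either edge are dropped and counted in ``meta``.
    """
    cfg.validate(rec.sample_rate_hz)
    fs = rec.sample_rate_hz
    n_pre = _round_half_away(cfg.epoch_pre_ms * fs / 1000.0)
    n_post = _round_half_away(cfg.epoch_post_ms * fs / 1000.0)
    n_len = n_pre + n_post + 1
    times_ms = np.arange(-n_pre, n_post + 1) * 1000.0 / fs

    data, conds, ords = [], [], []
    n_edge = 0
    for onset, cond, ordinal in zip(
        rec.events["onset_sample"], rec.events["condition"],
        rec.events["ordinal"],
    ):
        lo, hi = onset - n_pre, onset + n_post + 1
        if lo < 0 or hi > rec.n_times:
            n_edge += 1
            continue
        seg = rec.samples[:, lo:hi]
        if cfg.baseline_correct:
            base = seg[:, times_ms <= 0].mean(axis=1, keepdims=True)
            seg = seg - base
        data.append(seg)
        conds.append(cond)
        ords.append(int(ordinal))
    if n_edge:
        logger.info("epoching dropped %d event(s) at recording edges",
                    n_edge)
    arr = (np.stack(data) if data
           else np.empty((0, rec.n_channels, n_len)))
    return EpochSet(
        data=arr,
        times_ms=times_ms,
        conditions=np.array(conds, dtype=object),
        ordinals=np.array(ords, dtype=int),
        sample_rate_hz=fs,
        channel_names=rec.channel_names,
        meta={**rec.meta, "events_dropped_at_edge": n_edge,
              "baseline_corrected": cfg.baseline_correct},
    )


def reject_artifacts(es: EpochSet, cfg: PreprocessConfig) -> EpochSet:
    """Flag epochs whose peak-to-peak range breaks the thresholds.

    An epoch is invalid if ANY screened channel's max-minus-min exceeds
    ``reject_ptp_uv`` (reason "ptp") or falls below ``flatline_ptp_uv``
    (reason "flatline").  Screened channels default to all eight; set
    ``cfg.reject_channels`` to e.g. ("Fz",) for Fz-only screening.
    """
    out = es.copy()
    if len(es) == 0:
        return out
    if cfg.reject_channels is None:
        ch_idx = np.arange(len(es.channel_names))
    else:
        ch_idx = np.array([es.channel_index(c) for c in cfg.reject_channels])
    ptp = (es.data[:, ch_idx, :].max(axis=2)
           - es.data[:, ch_idx, :].min(axis=2))
    too_big = (ptp > cfg.reject_ptp_uv).any(axis=1)
    flat = (ptp < cfg.flatline_ptp_uv).any(axis=1)
    out.valid = ~(too_big | flat)
    reason = np.array(["none"] * len(es), dtype=object)
    reason[flat] = "flatline"
    reason[too_big] = "ptp"  # ptp wins if an epoch trips both
    out.reason = reason
    out.kept = out.valid.copy()
    out.meta["rejection"] = {
        "n_ptp": int(too_big.sum()),
        "n_flatline": int((flat & ~too_big).sum()),
        "valid_counts": out.counts("valid"),
    }
    return out


def equalize_trials(es: EpochSet, seed: int | None = None) -> EpochSet:
    """Down-sample the two larger conditions to the smallest valid count.

    Sampling is without replacement with a seeded generator; kept epochs
    retain their original ordinals (presentation order).  A condition
    with zero valid trials marks the dataset unusable.
    """
    out = es.copy()
    counts = {c: len(es.select(c, "valid")) for c in CONDITIONS
              if (es.conditions == c).any()}
    if not counts:
        out.meta["usable"] = False
        return out
    m = min(counts.values())
    if m == 0:
        out.meta["usable"] = False
        out.kept = np.zeros(len(es), dtype=bool)
        return out
    rng = np.random.default_rng(seed)
    kept = np.zeros(len(es), dtype=bool)
    for cond in counts:
        idx = es.select(cond, "valid")
        if len(idx) > m:
            idx = np.sort(rng.choice(idx, size=m, replace=False))
        kept[idx] = True
    out.kept = kept
    out.meta["usable"] = True
    out.meta["equalized_to"] = m
    out.meta["equalize_seed"] = seed
    return out


@dataclass
class InclusionDecision:
    included: bool
    counts: dict[str, int]
    threshold: int


def inclusion_filter(es: EpochSet, cfg: PreprocessConfig) -> InclusionDecision:
    """Keep the dataset only if every condition retains at least
    ``min_trials_per_condition`` equalized trials."""
    counts = es.counts("kept")
    present = all(c in counts for c in CONDITIONS)
    ok = present and all(
        counts.get(c, 0) >= cfg.min_trials_per_condition for c in CONDITIONS
    ) and es.meta.get("usable", True)
    decision = InclusionDecision(
        included=bool(ok), counts=counts,
        threshold=cfg.min_trials_per_condition)
    logger.info("inclusion: %s (counts=%s, threshold=%d)",
                "included" if ok else "excluded", counts,
                cfg.min_trials_per_condition)
    return decision


def preprocess_recording(
    rec: Recording, cfg: PreprocessConfig | None = None,
) -> tuple[EpochSet, InclusionDecision]:
    """Run the full chain: filter -> offset -> epoch -> reject ->
    equalize -> inclusion decision."""
    cfg = cfg or PreprocessConfig()
    filtered = bandpass_filter(rec, cfg)
    shifted = apply_timing_offset(filtered, cfg)
    es = epoch(shifted, cfg)
    es = reject_artifacts(es, cfg)
    es = equalize_trials(es, seed=cfg.equalize_seed)
    decision = inclusion_filter(es, cfg)
    return es, decision
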