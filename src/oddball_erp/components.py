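"""ERP component quantification at Fz.

Components are measured as mean amplitudes inside fixed, age-specific
windows (mean amplitude is preferred over peak amplitude in noisy infant
data).  Peak latencies are estimated with the leave-one-out jackknife:
n grand averages of size n-1 are formed, the peak latency of each is
taken, and test statistics computed on those n values are deflated
(t / (n-1), F / (n-1)^2) to undo the artificial reduction of error
variance that grand-averaging induces.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sst

from .containers import EpochSet


class WindowRegistryError(KeyError):
    """Component not defined at the requested age point."""


@dataclass(frozen=True)
class WindowSpec:
    component: str
    age_point: str
    t_start_ms: float
    t_end_ms: float
    polarity: str  # "+" or "-"

    def __post_init__(self) -> None:
        if not self.t_start_ms < self.t_end_ms:
            raise ValueError("t_start_ms must be < t_end_ms")
        if self.polarity not in ("+", "-"):
            raise ValueError("polarity must be '+' or '-'")


# age-specific analysis windows (ms post-stimulus)
WINDOWS: dict[tuple[str, str], WindowSpec] = {
    ("1m", "N1"): WindowSpec("N1", "1m", 50.0, 150.0, "-"),
    ("1m", "P3"): WindowSpec("P3", "1m", 250.0, 450.0, "+"),
    ("1m", "Nc"): WindowSpec("Nc", "1m", 550.0, 750.0, "-"),
    ("5m", "P1"): WindowSpec("P1", "5m", 60.0, 80.0, "+"),
    ("5m", "N2"): WindowSpec("N2", "5m", 90.0, 110.0, "-"),
    ("5m", "P3"): WindowSpec("P3", "5m", 200.0, 400.0, "+"),
    ("5m", "Nc"): WindowSpec("Nc", "5m", 500.0, 700.0, "-"),
}


def get_window(age_point: str, component: str) -> WindowSpec:
    try:
        return WINDOWS[(age_point, component)]
    except KeyError:
        raise WindowRegistryError(
            f"component {component!r} is not defined at age point "
            f"{age_point!r}; available: "
            f"{sorted(k for k in WINDOWS if k[0] == age_point)}"
        ) from None


def components_for_age(age_point: str) -> list[str]:
    return [c for (a, c) in WINDOWS if a == age_point]


# ---------------------------------------------------------------------------
# averaging and window measures


def condition_average(
    es: EpochSet, condition: str, channel: str = "Fz",
    which: str = "kept",
) -> tuple[np.ndarray, int]:
    """Pointwise mean waveform over the selected epochs of a condition
    at one electrode; returns (waveform, n)."""
    idx = es.select(condition, which)
    if len(idx) == 0:
        raise ValueError(f"no {which} epochs of condition {condition!r}")
    ch = es.channel_index(channel)
    return es.data[idx, ch, :].mean(axis=0), len(idx)


def _window_mask(times_ms: np.ndarray, w: WindowSpec) -> np.ndarray:
    mask = (times_ms >= w.t_start_ms) & (times_ms <= w.t_end_ms)
    if not mask.any():
        raise ValueError(
            f"window [{w.t_start_ms}, {w.t_end_ms}] ms lies outside the "
            f"epoch time axis [{times_ms[0]}, {times_ms[-1]}] ms"
        )
    if w.t_start_ms < times_ms[0] or w.t_end_ms > times_ms[-1]:
        raise ValueError("analysis window extends beyond the epoch")
    return mask


def mean_amplitude(waveform: np.ndarray, times_ms: np.ndarray,
                   w: WindowSpec) -> float:
    """Arithmetic mean over samples with t_start <= t <= t_end
    (inclusive endpoints)."""
    return float(np.mean(np.asarray(waveform)[_window_mask(times_ms, w)]))


def peak_latency(waveform: np.ndarray, times_ms: np.ndarray,
                 w: WindowSpec) -> float:
    """Latency (ms) of the window's extremum — maximum for positive
    components, minimum for negative.  Ties break to the earliest
    sample (argmax/argmin convention)."""
    mask = _window_mask(times_ms, w)
    seg = np.asarray(waveform)[mask]
    t = times_ms[mask]
    i = int(np.argmax(seg)) if w.polarity == "+" else int(np.argmin(seg))
    return float(t[i])


@dataclass
class ComponentMeasure:
    subject_id: str
    condition: str
    component: str
    mean_amplitude_uv: float
    peak_latency_ms: float
    n_epochs: int


def measure_components(
    es: EpochSet, age_point: str, subject_id: str = "",
    channel: str = "Fz",
) -> pd.DataFrame:
    """Tidy per-condition measures of every component defined at this
    age point (mean amplitude + subject-level diagnostic peak latency)."""
    rows = []
    for cond in np.unique(es.conditions):
        try:
            wave, n = condition_average(es, str(cond), channel)
        except ValueError:
            continue
        for comp in components_for_age(age_point):
            w = get_window(age_point, comp)
            rows.append({
                "subject_id": subject_id,
                "condition": str(cond),
                "component": comp,
                "age_point": age_point,
                "mean_amp_uv": mean_amplitude(wave, es.times_ms, w),
                "latency_ms": peak_latency(wave, es.times_ms, w),
                "n_epochs": n,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# jackknife latency inference


@dataclass
class JackknifeResult:
    """Leave-one-out latency test for one contrast or factorial design."""

    loo_latencies: dict[str, np.ndarray]  # cell label -> n latencies (ms)
    statistic_name: str  # "t" or "F"
    raw: float
    corrected: float
    p: float
    df: tuple
    n_subjects: int
    boundary_flagged: bool = False
    effects: pd.DataFrame | None = field(default=None, repr=False)


def loo_grand_average_latencies(
    waveforms: np.ndarray, times_ms: np.ndarray, w: WindowSpec,
) -> np.ndarray:
    """Peak latencies of the n leave-one-subject-out grand averages.

    ``waveforms`` is (n_subjects, n_times); subject i's entry is the
    average of all other subjects' waveforms.
    """
    waveforms = np.asarray(waveforms, float)
    n = waveforms.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects for leave-one-out")
    total = waveforms.sum(axis=0)
    lats = np.empty(n)
    for i in range(n):
        loo = (total - waveforms[i]) / (n - 1)
        lats[i] = peak_latency(loo, times_ms, w)
    return lats


def _boundary(lats: np.ndarray, w: WindowSpec, step_ms: float) -> bool:
    return bool(np.any(np.isclose(lats, w.t_start_ms))
                or np.any(np.isclose(lats, w.t_end_ms)))


def jackknife_latency_ttest(
    waves_a: np.ndarray, waves_b: np.ndarray,
    times_ms: np.ndarray, w: WindowSpec,
    correct: bool = True,
) -> JackknifeResult:
    """Paired latency contrast between two conditions via the jackknife.

    Leave-one-out latencies are computed per condition, a paired t is run
    across the n leave-one-out values, and the statistic is deflated by
    (n - 1); the p-value comes from the corrected statistic on df = n-1.
    """
    la = loo_grand_average_latencies(waves_a, times_ms, w)
    lb = loo_grand_average_latencies(waves_b, times_ms, w)
    n = len(la)
    if n < 3 or len(lb) != n:
        raise ValueError("need >= 3 paired subjects")
    diff = la - lb
    sd = diff.std(ddof=1)
    if sd == 0.0:
        raw = 0.0 if np.allclose(diff, 0.0) \
            else float(np.sign(diff.mean()) * np.inf)
    else:
        raw = float(diff.mean() / (sd / np.sqrt(n)))
    corr = raw / (n - 1) if correct else raw
    p = float(2 * sst.t.sf(abs(corr), n - 1)) if np.isfinite(corr) else 0.0
    step = float(np.median(np.diff(times_ms)))
    return JackknifeResult(
        loo_latencies={"a": la, "b": lb},
        statistic_name="t", raw=raw, corrected=corr, p=p,
        df=(n - 1,), n_subjects=n,
        boundary_flagged=_boundary(la, w, step) or _boundary(lb, w, step),
    )


def jackknife_latency_anova(
    waves_by_cell: dict[tuple, np.ndarray],
    times_ms: np.ndarray, w: WindowSpec,
    within: list[str],
    between: str | None = None,
    groups: np.ndarray | None = None,
    correct: bool = True,
) -> pd.DataFrame:
    """Repeated-measures ANOVA on leave-one-out latencies.

    ``waves_by_cell`` maps within-cell labels (tuples over ``within``
    factors) to (n_subjects, n_times) arrays; for a between factor the
    jackknife is performed within each group separately (grand averages
    never mix groups), then latencies are stacked.  Every F is deflated
    by (n - 1)^2 using the group-wise n for pure within effects and the
    total n otherwise; corrected p-values follow.
    """
    from .stats import mixed_rm_anova  # local import avoids a cycle

    cells = sorted(waves_by_cell)
    n = next(iter(waves_by_cell.values())).shape[0]
    rows = []
    for cell in cells:
        waves = np.asarray(waves_by_cell[cell], float)
        if waves.shape[0] != n:
            raise ValueError("all cells need the same subjects")
        if between is None:
            lats = loo_grand_average_latencies(waves, times_ms, w)
        else:
            lats = np.empty(n)
            for g in np.unique(groups):
                gi = np.flatnonzero(groups == g)
                lats[gi] = loo_grand_average_latencies(
                    waves[gi], times_ms, w)
        for i in range(n):
            row = {"subject": i, "latency": lats[i]}
            for f, lev in zip(within, cell):
                row[f] = lev
            if between is not None:
                row[between] = groups[i]
            rows.append(row)
    df = pd.DataFrame(rows)
    res = mixed_rm_anova(df, dv="latency", within=within,
                         between=between, subject="subject")
    out = res.to_frame()
    if correct:
        out["F_corrected"] = out["F"] / (n - 1) ** 2
        out["p_corrected"] = [
            float(sst.f.sf(fc, d1, d2))
            for fc, d1, d2 in zip(out["F_corrected"], out["df1"],
                                  out["df2"])
        ]
    return out
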