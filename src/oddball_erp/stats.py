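"""Statistical layer: mixed repeated-measures ANOVA, paired contrasts,
correlation comparison, hierarchical regression with R-squared change,
FDR correction, and the sleep/wake state check.

The mixed RM-ANOVA is the sphericity-assumed ("averaged univariate")
split-plot analysis, computed from a multivariate OLS fit of the
subject-by-cell response matrix on the between-subjects design, with
orthonormal within-subject contrasts.  For balanced within cells and
effect-coded groups this reproduces the classical Type-III split-plot
table (e.g. Condition tested on (N - g)(k - 1) error df), including with
unequal group sizes.  Greenhouse-Geisser correction is available but off
by default, matching the integer-df reporting convention.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sst
from statsmodels.stats.multitest import multipletests


@dataclass
class StatResult:
    effect: str
    statistic_name: str
    statistic: float
    df1: float
    df2: float | None
    p: float
    effect_size_name: str | None = None
    effect_size: float | None = None
    correction: str = "none"
    extra: dict = field(default_factory=dict)

    def as_row(self) -> dict:
        row = {
            "effect": self.effect, "stat": self.statistic_name,
            self.statistic_name: self.statistic,
            "df1": self.df1, "df2": self.df2, "p": self.p,
            "correction": self.correction,
        }
        if self.effect_size_name:
            row[self.effect_size_name] = self.effect_size
        return row


class AnovaResults:
    """Container for RM-ANOVA effects with a printable summary."""

    def __init__(self, results: list[StatResult], meta: dict | None = None):
        self.results = results
        self.meta = meta or {}

    def __iter__(self):
        return iter(self.results)

    def __getitem__(self, effect: str) -> StatResult:
        for r in self.results:
            if r.effect == effect:
                return r
        raise KeyError(effect)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"effect": r.effect, "df1": r.df1, "df2": r.df2,
             "F": r.statistic, "p": r.p, "partial_eta_sq": r.effect_size}
            for r in self.results
        ])

    def summary(self) -> str:
        lines = ["Repeated-measures mixed ANOVA",
                 "-" * 58,
                 f"{'effect':<28}{'F':>8}{'df':>10}{'p':>8}{'np2':>6}"]
        for r in self.results:
            df = f"{r.df1:g},{r.df2:g}"
            lines.append(
                f"{r.effect:<28}{r.statistic:>8.3f}{df:>10}"
                f"{r.p:>8.3f}{r.effect_size:>6.3f}")
        return "\n".join(lines)


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """k x (k-1) orthonormal basis of the space orthogonal to the mean."""
    basis = np.linalg.qr(
        np.column_stack([np.ones(k), np.eye(k)[:, : k - 1]])
    )[0]
    return basis[:, 1:]


def mixed_rm_anova(
    data: pd.DataFrame,
    dv: str,
    within: list[str] | str,
    subject: str,
    between: str | None = None,
    gg_correction: bool = False,
) -> AnovaResults:
    """Split-plot RM-ANOVA with up to two within factors and one
    optional between factor; reports F, df, p and partial eta squared
    for every main effect and interaction.

    Requires complete within cells per subject (one observation each);
    raises listing offending subjects otherwise.
    """
    if isinstance(within, str):
        within = [within]
    if not 1 <= len(within) <= 2:
        raise ValueError("one or two within factors supported")

    levels = [sorted(data[f].unique()) for f in within]
    wide = data.pivot_table(index=subject, columns=within, values=dv,
                            aggfunc="mean")
    full_cols = (pd.MultiIndex.from_product(levels, names=within)
                 if len(within) > 1 else pd.Index(levels[0],
                                                  name=within[0]))
    wide = wide.reindex(columns=full_cols)
    bad = wide.index[wide.isna().any(axis=1)].tolist()
    if bad:
        raise ValueError(
            f"incomplete within-subject cells for subjects: {bad}")
    Y = wide.to_numpy()
    n_subj = Y.shape[0]

    # between design (effect coding -> Type III hypotheses)
    if between is not None:
        grp = (data.groupby(subject)[between].first()
               .reindex(wide.index))
        glev = sorted(grp.unique())
        g = len(glev)
        X = np.ones((n_subj, g))
        for j, lev in enumerate(glev[:-1]):
            col = np.where(grp.to_numpy() == lev, 1.0, 0.0)
            col[grp.to_numpy() == glev[-1]] = -1.0
            X[:, j + 1] = col
    else:
        g = 1
        X = np.ones((n_subj, 1))

    XtX = X.T @ X
    XtX_inv = np.linalg.inv(XtX)
    B = XtX_inv @ X.T @ Y
    resid = Y - X @ B
    E = resid.T @ resid
    df_resid = n_subj - g

    ks = [len(lv) for lv in levels]
    Ks = [_orthonormal_contrasts(k) for k in ks]
    means = [np.ones((k, 1)) / np.sqrt(k) for k in ks]

    def kron(parts):
        m = parts[0]
        for p in parts[1:]:
            m = np.kron(m, p)
        return m

    L_int = np.zeros((1, X.shape[1]))
    L_int[0, 0] = 1.0
    L_grp = np.hstack([np.zeros((g - 1, 1)), np.eye(g - 1)]) if g > 1 \
        else None

    effects: list[tuple[str, np.ndarray, np.ndarray]] = []
    if between is not None:
        effects.append((between, L_grp, kron(means)))
    for i, f in enumerate(within):
        parts = [Ks[j] if j == i else means[j] for j in range(len(within))]
        effects.append((f, L_int, kron(parts)))
        if between is not None:
            effects.append((f"{f} * {between}", L_grp, kron(parts)))
    if len(within) == 2:
        M12 = kron(Ks)
        effects.append((" * ".join(within), L_int, M12))
        if between is not None:
            effects.append(
                (" * ".join(within) + f" * {between}", L_grp, M12))

    out: list[StatResult] = []
    # numerical floor for "no variance at all" (degenerate inputs)
    tol = 1e-10 * (float(np.abs(Y).max()) ** 2 * Y.size + 1.0)
    for name, L, M in effects:
        q = M.shape[1]
        LBM = L @ B @ M
        H = LBM.T @ np.linalg.inv(L @ XtX_inv @ L.T) @ LBM
        EM = M.T @ E @ M
        df1 = L.shape[0] * q
        df2 = df_resid * q
        ss_h, ss_e = float(np.trace(H)), float(np.trace(EM))
        eps = 1.0
        if gg_correction and q > 1:
            # Greenhouse-Geisser epsilon from the error SSCP
            S = EM / df_resid
            tr = np.trace(S)
            eps = tr ** 2 / (q * float(np.sum(S * S)))
            eps = min(max(eps, 1.0 / q), 1.0)
        if ss_e > tol:
            F = (ss_h / df1) / (ss_e / df2)
            p = float(sst.f.sf(F, df1 * eps, df2 * eps))
        elif ss_h > tol:
            F, p = np.inf, 0.0
        else:
            F, p = 0.0, 1.0
        np2 = ss_h / (ss_h + ss_e) if (ss_h + ss_e) > 0 else 0.0
        out.append(StatResult(
            effect=name, statistic_name="F", statistic=float(F),
            df1=df1, df2=df2, p=p,
            effect_size_name="partial_eta_sq", effect_size=float(np2),
            correction="greenhouse-geisser" if (gg_correction and q > 1)
            else "none",
            extra={"ss_hyp": ss_h, "ss_err": ss_e, "gg_epsilon": eps},
        ))
    return AnovaResults(out, meta={"n_subjects": n_subj,
                                   "between_levels": g})


def rm_anova(data: pd.DataFrame, dv: str, within, subject: str,
             between: str | None = None, **kw) -> AnovaResults:
    """Alias for :func:`mixed_rm_anova` (spec-facing name)."""
    return mixed_rm_anova(data, dv=dv, within=within, subject=subject,
                          between=between, **kw)


# ---------------------------------------------------------------------------


def paired_contrast(values_a, values_b) -> StatResult:
    """Paired t-test with Cohen's d = mean(diff) / SD(diff)."""
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need paired samples of equal length >= 2")
    diff = a - b
    sd = diff.std(ddof=1)
    n = a.size
    if sd == 0.0:
        if np.allclose(diff.mean(), 0.0):
            t, p, d = 0.0, 1.0, 0.0
        else:
            t = np.inf if diff.mean() > 0 else -np.inf
            p, d = 0.0, np.inf * np.sign(diff.mean())
            warnings.warn("zero variance of differences with nonzero "
                          "mean: infinite t", RuntimeWarning)
    else:
        t, p = sst.ttest_rel(a, b)
        d = diff.mean() / sd
    return StatResult(
        effect="paired contrast", statistic_name="t", statistic=float(t),
        df1=n - 1, df2=None, p=float(p),
        effect_size_name="cohen_d", effect_size=float(d),
    )


def fisher_z(r: float) -> float:
    return float(np.arctanh(r))


def correlate_and_compare(x, y, by_group) -> dict:
    """Pearson r per group plus the Fisher r-to-z comparison of the two
    group correlations.

    Returns ``{"groups": {label: StatResult}, "comparison": StatResult}``;
    the comparison reports the one-sided p (reporting convention of a
    magnitude comparison) with the two-sided value in ``extra``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    by_group = np.asarray(by_group)
    out: dict[str, StatResult] = {}
    zs, ns = {}, {}
    for gname in np.unique(by_group):
        m = by_group == gname
        if m.sum() < 4:
            raise ValueError(f"group {gname!r} has fewer than 4 pairs")
        if np.std(x[m]) == 0 or np.std(y[m]) == 0:
            warnings.warn(f"constant input in group {gname!r}: "
                          "correlation undefined", RuntimeWarning)
            out[str(gname)] = StatResult(
                effect=f"r[{gname}]", statistic_name="r",
                statistic=np.nan, df1=m.sum() - 2, df2=None, p=np.nan)
            continue
        r, p = sst.pearsonr(x[m], y[m])
        out[str(gname)] = StatResult(
            effect=f"r[{gname}]", statistic_name="r", statistic=float(r),
            df1=m.sum() - 2, df2=None, p=float(p),
            extra={"n": int(m.sum())})
        zs[str(gname)] = fisher_z(r)
        ns[str(gname)] = int(m.sum())
    comparison = None
    if len(zs) == 2:
        (g1, z1), (g2, z2) = zs.items()
        n1, n2 = ns[g1], ns[g2]
        se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
        z = (z1 - z2) / se
        comparison = StatResult(
            effect=f"r[{g1}] vs r[{g2}]", statistic_name="z",
            statistic=float(z), df1=np.inf, df2=None,
            p=float(sst.norm.sf(abs(z))),
            correction="one-sided",
            extra={"p_two_sided": float(2 * sst.norm.sf(abs(z)))},
        )
    return {"groups": out, "comparison": comparison}


# ---------------------------------------------------------------------------
# hierarchical regression (outcome-association models)

MODEL_CANDIDATES = {
    1: ["laz_5m", "waz_5m"],          # current size at 5 months
    2: ["d_hcz", "d_laz", "d_waz", "d_wlz"],  # growth 1 -> 5 months
}


@dataclass
class HierarchicalResult:
    model_id: int
    screening: pd.DataFrame
    selected_predictor: str
    rsq_null: float
    rsq_full: float
    rsq_change: float
    f_change: float
    p_change: float
    params: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    n: int

    def to_results(self) -> list[StatResult]:
        out = [StatResult(
            effect=f"Model {self.model_id}: {self.selected_predictor}",
            statistic_name="t",
            statistic=float(self.tvalues[self.selected_predictor]),
            df1=self.n - len(self.params), df2=None,
            p=float(self.pvalues[self.selected_predictor]),
            effect_size_name="r_sq", effect_size=self.rsq_null,
        ), StatResult(
            effect=f"Model {self.model_id}: delta_p3",
            statistic_name="t",
            statistic=float(self.tvalues["delta_p3"]),
            df1=self.n - len(self.params), df2=None,
            p=float(self.pvalues["delta_p3"]),
            effect_size_name="r_sq_change", effect_size=self.rsq_change,
        ), StatResult(
            effect=f"Model {self.model_id}: R2 change",
            statistic_name="F", statistic=self.f_change,
            df1=1, df2=self.n - len(self.params), p=self.p_change,
            effect_size_name="r_sq_change", effect_size=self.rsq_change,
        )]
        return out

    def summary(self) -> str:
        lines = [
            f"Hierarchical regression, Model {self.model_id} "
            f"(n = {self.n})",
            f"  screening winner: {self.selected_predictor}",
            f"  null model R^2      = {self.rsq_null:.4f}",
            f"  + delta_p3    R^2   = {self.rsq_full:.4f}",
            f"  R^2 change          = {self.rsq_change:.4f} "
            f"(F(1,{self.n - len(self.params)}) = {self.f_change:.3f}, "
            f"p = {self.p_change:.4g})",
            "  coefficients:",
        ]
        for name in self.params.index:
            lines.append(
                f"    {name:<12} b = {self.params[name]:>8.3f}  "
                f"t = {self.tvalues[name]:>7.3f}  "
                f"p = {self.pvalues[name]:.4g}")
        return "\n".join(lines)


def hierarchical_regression(
    table: pd.DataFrame,
    model_id: int,
    outcome: str = "outcome",
    marker: str = "delta_p3",
    candidates: list[str] | None = None,
) -> HierarchicalResult:
    """Two-step outcome regression with univariate predictor screening.

    Candidate anthropometric predictors are each fit alone against the
    outcome; the one with the lowest univariate p enters the null model
    (ties break alphabetically).  The marker (delta-P3) is then added and
    the R-squared change tested with the single-predictor F-test.
    Candidate pairs with |r| > 0.9 raise a collinearity warning.
    """
    if candidates is None:
        candidates = MODEL_CANDIDATES[model_id]
    df = table.dropna(subset=[outcome, marker] + candidates)
    n = len(df)

    for c1, c2 in combinations(candidates, 2):
        r = np.corrcoef(df[c1], df[c2])[0, 1]
        if abs(r) > 0.9:
            warnings.warn(
                f"candidate predictors {c1} and {c2} are collinear "
                f"(r = {r:.2f})", RuntimeWarning)

    rows = []
    for cand in sorted(candidates):
        fit = sm.OLS(df[outcome],
                     sm.add_constant(df[[cand]])).fit()
        rows.append({"predictor": cand, "t": float(fit.tvalues[cand]),
                     "p": float(fit.pvalues[cand]),
                     "r_sq": float(fit.rsquared)})
    screening = pd.DataFrame(rows)
    selected = screening.sort_values(
        ["p", "predictor"]).iloc[0]["predictor"]

    null_fit = sm.OLS(df[outcome],
                      sm.add_constant(df[[selected]])).fit()
    full_fit = sm.OLS(df[outcome],
                      sm.add_constant(df[[selected, marker]])).fit()
    rsq_change = full_fit.rsquared - null_fit.rsquared
    df2 = n - int(full_fit.df_model) - 1
    denom = (1.0 - full_fit.rsquared) / df2
    f_change = rsq_change / denom if denom > 0 else np.inf
    p_change = float(sst.f.sf(f_change, 1, df2))
    return HierarchicalResult(
        model_id=model_id, screening=screening,
        selected_predictor=str(selected),
        rsq_null=float(null_fit.rsquared),
        rsq_full=float(full_fit.rsquared),
        rsq_change=float(rsq_change),
        f_change=float(f_change), p_change=p_change,
        params=full_fit.params, tvalues=full_fit.tvalues,
        pvalues=full_fit.pvalues, n=n,
    )


def fdr_correct(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("p_values must be a non-empty 1-D sequence")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# sleep/wake state check


def match_by_trial_count(
    target_counts: dict[str, int],
    pool_counts: dict[str, int],
    tolerance: int = 5,
) -> tuple[dict[str, str], list[str]]:
    """Greedy matching of each target subject to an unused pool subject
    whose good-trial count is within ``tolerance``; nearest count wins.
    Returns (matches target->pool, unmatched targets)."""
    available = dict(pool_counts)
    matches: dict[str, str] = {}
    unmatched: list[str] = []
    for sid, cnt in target_counts.items():
        best, best_diff = None, None
        for pid, pcnt in available.items():
            diff = abs(pcnt - cnt)
            if diff <= tolerance and (best_diff is None or diff < best_diff):
                best, best_diff = pid, diff
        if best is None:
            unmatched.append(sid)
        else:
            matches[sid] = best
            del available[best]
    return matches, unmatched


def state_effect_check(
    data: pd.DataFrame,
    dv: str = "mean_amp_uv",
    tolerance: int = 5,
) -> dict:
    """Condition x State ANOVA on a trial-count-matched subset.

    ``data`` is long format with columns subject_id, state
    ("asleep"/"awake"), condition, ``dv`` and n_good_trials.  Every
    asleep subject is matched to an awake subject within ``tolerance``
    good trials; unmatched asleep subjects are excluded with a log entry.
    """
    counts = data.groupby("subject_id").agg(
        state=("state", "first"), n=("n_good_trials", "first"))
    asleep = counts[counts["state"] == "asleep"]["n"].to_dict()
    awake = counts[counts["state"] == "awake"]["n"].to_dict()
    matches, unmatched = match_by_trial_count(asleep, awake, tolerance)
    keep = set(matches) | set(matches.values())
    sub = data[data["subject_id"].isin(keep)]
    res = mixed_rm_anova(sub, dv=dv, within=["condition"],
                         subject="subject_id", between="state")
    return {"anova": res, "matches": matches, "unmatched": unmatched,
            "n_pairs": len(matches)}
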