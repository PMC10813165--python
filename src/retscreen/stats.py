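"""Longitudinal statistics for baseline-normalised retinal measures.

The analysis layer mirrors a standard preclinical pharmacology workflow:
per-subject normalisation to baseline, robust (ROUT-style) outlier
screening, classical two-way mixed-design (repeated-measures) ANOVA with
a between-subjects grouping factor and time as the within-subject
factor, Sidak-corrected pairwise group contrasts at each timepoint, and
mean +/- SEM group summaries.

The ANOVA uses the classical expected-mean-squares decomposition: the
group effect is tested against subjects-within-groups, time and the
group x time interaction against the subject x time residual.  With
complete within-subject data the cell frequencies are proportional, so
the weighted sums of squares are orthogonal and add to the total even
for unbalanced group sizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "MEASURE_COLUMNS",
    "ANOVAResult",
    "EffectRow",
    "OutlierReport",
    "normalize_to_baseline",
    "rout_outliers",
    "sidak_adjust",
    "mixed_anova",
    "mixed_anova_wide",
    "posthoc_by_time",
    "summarize_groups",
]

MEASURE_COLUMNS = ("subject_id", "genotype", "treatment", "time_min", "measure", "value")


@dataclass(frozen=True)
class EffectRow:
    ss: float
    df: int
    ms: float
    F: float
    p: float


@dataclass
class ANOVAResult:
    """Mixed-design ANOVA table with its two error strata.

    ``effects`` holds 'between', 'time' and 'interaction'; ``strata``
    holds 'subjects_within_groups' and 'residual'.  Construction checks
    that the component sums of squares add to the total and the degrees
    of freedom to N_obs - 1.
    """

    effects: dict[str, EffectRow]
    strata: dict[str, EffectRow]
    n_obs: int
    ss_total: float
    posthoc: pd.DataFrame | None = None
    gg_epsilon: float | None = None

    def __post_init__(self) -> None:
        parts = list(self.effects.values()) + list(self.strata.values())
        ss_sum = sum(e.ss for e in parts)
        scale = max(self.ss_total, 1.0)
        if abs(ss_sum - self.ss_total) > 1e-8 * scale:
            raise AssertionError(
                f"SS decomposition not additive: components {ss_sum} vs total {self.ss_total}"
            )
        if any(e.ss < -1e-12 for e in parts):
            raise AssertionError("negative sum of squares in decomposition")
        df_sum = sum(e.df for e in parts)
        if df_sum != self.n_obs - 1:
            raise AssertionError(f"df sum {df_sum} != N_obs - 1 = {self.n_obs - 1}")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, e in {**self.effects, **self.strata}.items():
            rows.append({"effect": name, "SS": e.ss, "df": e.df, "MS": e.ms, "F": e.F, "p": e.p})
        return pd.DataFrame(rows)


@dataclass
class OutlierReport:
    """Result of the robust (ROUT-style) outlier scan of one value vector."""

    flagged: list[int]
    q: float
    center: float
    rsdr: float
    p_values: np.ndarray

    @property
    def is_empty(self) -> bool:
        return len(self.flagged) == 0


def _check_measure_table(t: pd.DataFrame) -> None:
    missing = [c for c in MEASURE_COLUMNS if c not in t.columns]
    if missing:
        raise ValueError(f"measure table is missing columns {missing}")


def normalize_to_baseline(t: pd.DataFrame, baseline_time: float = 0.0) -> pd.DataFrame:
    """Express each subject's series as percent of its own baseline.

    value_norm = 100 * value(t) / value(baseline) per subject per
    measure; baseline rows become exactly 100.  Subjects lacking a
    usable (nonzero) baseline for a measure are dropped with a warning.
    """
    _check_measure_table(t)
    out = t.copy()
    dropped = []
    parts = []
    for (subj, meas), g in out.groupby(["subject_id", "measure"], sort=False):
        base = g.loc[g["time_min"] == baseline_time, "value"]
        if base.empty or base.isna().any() or float(base.iloc[0]) == 0.0:
            dropped.append((subj, meas))
            continue
        gg = g.copy()
        gg["value"] = 100.0 * gg["value"] / float(base.iloc[0])
        gg.loc[gg["time_min"] == baseline_time, "value"] = 100.0
        parts.append(gg)
    if dropped:
        warnings.warn(
            f"normalize_to_baseline: excluded {len(dropped)} subject/measure series "
            f"with missing or zero baseline: {dropped[:5]}{'...' if len(dropped) > 5 else ''}"
        )
    if not parts:
        raise ValueError("no subject had a usable baseline")
    return pd.concat(parts, ignore_index=True)


def rout_outliers(values, q: float = 0.01) -> OutlierReport:
    """Robust outlier detection on a single sample (ROUT reduced to a constant model).

    The robust centre is the median; the robust scale (RSDR) is the
    68.27th percentile of the absolute residuals with the small-sample
    correction n/(n-K), K=1.  Each point gets a two-tailed p-value from
    a t distribution on n-K df, and points are flagged by a
    Benjamini-Hochberg-style step-up at FDR level ``q``, restricted to
    residuals beyond 2 robust SDs.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 3:
        raise ValueError("rout_outliers needs a 1-D vector with n >= 3")
    if not (0.0 < q < 1.0):
        raise ValueError("Q must be in (0, 1)")
    n = v.size
    center = float(np.median(v))
    resid = np.abs(v - center)
    if np.allclose(resid, 0.0):
        return OutlierReport([], q, center, 0.0, np.ones(n))
    rsdr = float(np.percentile(resid, 68.27) * n / (n - 1))
    if rsdr == 0.0:
        # Majority of points identical: any deviation is infinitely unlikely.
        flagged = np.flatnonzero(resid > 0.0)
        p = np.where(resid > 0.0, 0.0, 1.0)
        return OutlierReport(flagged.tolist(), q, center, rsdr, p)
    tstat = resid / rsdr
    p = 2.0 * sps.t.sf(tstat, df=n - 1)
    candidates = resid >= 2.0 * rsdr
    order = np.argsort(p)
    passed = np.zeros(n, dtype=bool)
    thresh = q * (np.arange(1, n + 1)) / n
    below = p[order] <= thresh
    if below.any():
        k = int(np.max(np.flatnonzero(below)))
        passed[order[: k + 1]] = True
    flagged = np.flatnonzero(passed & candidates)
    return OutlierReport(flagged.tolist(), q, center, rsdr, p)


def sidak_adjust(p: float, m: int) -> float:
    """Sidak multiplicity adjustment  p_adj = 1 - (1 - p)^m,  clipped to [0, 1]."""
    if not (0.0 <= p <= 1.0):
        raise ValueError("p must be in [0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    return float(np.clip(-np.expm1(m * np.log1p(-p)) if p < 1.0 else 1.0, 0.0, 1.0))


def _f_test(ss_num: float, df_num: int, ss_den: float, df_den: int) -> tuple[float, float, float]:
    """(MS, F, p) testing ss_num/df_num against ss_den/df_den."""
    ms_num = ss_num / df_num if df_num > 0 else np.nan
    ms_den = ss_den / df_den if df_den > 0 else np.nan
    if not np.isfinite(ms_num) or not np.isfinite(ms_den):
        return ms_num, np.nan, np.nan
    if ms_num <= 0.0:
        return ms_num, 0.0, 1.0
    if ms_den <= 0.0:
        return ms_num, float("inf"), 0.0
    F = ms_num / ms_den
    return ms_num, F, float(sps.f.sf(F, df_num, df_den))


def mixed_anova_wide(
    values: np.ndarray,
    group_labels: Sequence,
    gg_correction: bool = False,
) -> ANOVAResult:
    """Two-way mixed ANOVA on a complete subjects x timepoints matrix.

    ``values`` has one row per subject and one column per within-subject
    level (time); ``group_labels`` assigns each subject to a between
    group.  Group sizes may differ but every subject must be complete.
    """
    y = np.asarray(values, dtype=float)
    if y.ndim != 2:
        raise ValueError("values must be a 2-D subjects x timepoints matrix")
    if np.isnan(y).any():
        raise ValueError("mixed_anova_wide requires complete data (no NaN)")
    n_subj, k = y.shape
    if k < 2:
        raise ValueError("need >= 2 within-subject levels")
    labels = np.asarray(group_labels)
    if labels.size != n_subj:
        raise ValueError("one group label per subject required")
    groups, gidx = np.unique(labels, return_inverse=True)
    g = groups.size
    if g < 2:
        raise ValueError("need >= 2 between-subject groups")
    n_per = np.bincount(gidx)
    if np.any(n_per < 2):
        small = groups[n_per < 2]
        raise ValueError(f"fewer than 2 subjects in group(s) {small.tolist()}")

    grand = y.mean()
    subj_means = y.mean(axis=1)
    time_means = y.mean(axis=0)
    group_means = np.array([subj_means[gidx == j].mean() for j in range(g)])
    # Cell means: group x time
    cell = np.vstack([y[gidx == j].mean(axis=0) for j in range(g)])

    ss_total = float(((y - grand) ** 2).sum())
    ss_between = float(k * (n_per * (group_means - grand) ** 2).sum())
    ss_subj = float(k * ((subj_means - group_means[gidx]) ** 2).sum())
    ss_time = float(n_subj * ((time_means - grand) ** 2).sum())
    inter_dev = cell - group_means[:, None] - time_means[None, :] + grand
    ss_inter = float((n_per[:, None] * inter_dev**2).sum())
    ss_resid = ss_total - ss_between - ss_subj - ss_time - ss_inter
    ss_resid = float(max(ss_resid, 0.0))

    df_between, df_subj = g - 1, n_subj - g
    df_time, df_inter = k - 1, (g - 1) * (k - 1)
    df_resid = (n_subj - g) * (k - 1)

    ms_b, F_b, p_b = _f_test(ss_between, df_between, ss_subj, df_subj)
    ms_t, F_t, p_t = _f_test(ss_time, df_time, ss_resid, df_resid)
    ms_i, F_i, p_i = _f_test(ss_inter, df_inter, ss_resid, df_resid)

    eps = None
    if gg_correction:
        eps = _gg_epsilon(y, gidx, g)
        if np.isfinite(F_t) and F_t > 0:
            p_t = float(sps.f.sf(F_t, df_time * eps, df_resid * eps))
        if np.isfinite(F_i) and F_i > 0:
            p_i = float(sps.f.sf(F_i, df_inter * eps, df_resid * eps))

    ms_subj = ss_subj / df_subj if df_subj else np.nan
    ms_res = ss_resid / df_resid if df_resid else np.nan
    return ANOVAResult(
        effects={
            "between": EffectRow(ss_between, df_between, ms_b, F_b, p_b),
            "time": EffectRow(ss_time, df_time, ms_t, F_t, p_t),
            "interaction": EffectRow(ss_inter, df_inter, ms_i, F_i, p_i),
        },
        strata={
            "subjects_within_groups": EffectRow(ss_subj, df_subj, ms_subj, np.nan, np.nan),
            "residual": EffectRow(ss_resid, df_resid, ms_res, np.nan, np.nan),
        },
        n_obs=n_subj * k,
        ss_total=ss_total,
        gg_epsilon=eps,
    )


def _gg_epsilon(y: np.ndarray, gidx: np.ndarray, g: int) -> float:
    """Greenhouse-Geisser epsilon from the pooled within-group covariance."""
    k = y.shape[1]
    cov = np.zeros((k, k))
    dof = 0
    for j in range(g):
        yj = y[gidx == j]
        cov += (yj.shape[0] - 1) * np.cov(yj, rowvar=False)
        dof += yj.shape[0] - 1
    cov /= max(dof, 1)
    mean_diag = np.trace(cov) / k
    mean_all = cov.mean()
    row_means = cov.mean(axis=1)
    num = (k * (mean_diag - mean_all)) ** 2
    den = (k - 1) * (np.sum(cov**2) - 2 * k * np.sum(row_means**2) + k**2 * mean_all**2)
    if den <= 0:
        return 1.0
    return float(np.clip(num / den, 1.0 / (k - 1), 1.0))


def _pivot_complete(
    t: pd.DataFrame,
    dv: str,
    between: str | Sequence[str],
    subject: str,
    within: str,
) -> tuple[np.ndarray, np.ndarray, list, np.ndarray]:
    sub = t[t["measure"] == dv] if "measure" in t.columns and dv in set(t["measure"]) else t
    if isinstance(between, str):
        between = [between]
    value_col = "value" if "value" in sub.columns else dv
    wide = sub.pivot_table(index=subject, columns=within, values=value_col, aggfunc="mean")
    labels = (
        sub.drop_duplicates(subject)
        .set_index(subject)[list(between)]
        .astype(str)
        .agg("_".join, axis=1)
        .reindex(wide.index)
    )
    incomplete = wide.isna().any(axis=1)
    if incomplete.any():
        warnings.warn(
            f"mixed_anova: listwise-deleted {int(incomplete.sum())} subject(s) with "
            f"missing timepoints: {wide.index[incomplete].tolist()}"
        )
        wide = wide[~incomplete]
        labels = labels[~incomplete]
    return wide.to_numpy(), labels.to_numpy(), list(wide.columns), wide.index.to_numpy()


def mixed_anova(
    t: pd.DataFrame,
    dv: str,
    between: str | Sequence[str] = ("genotype", "treatment"),
    subject: str = "subject_id",
    within: str = "time_min",
    gg_correction: bool = False,
) -> ANOVAResult:
    """Two-way repeated-measures ANOVA on a long-format measure table.

    ``dv`` selects the measure; ``between`` may name one column or
    several (combined into a single grouping factor); ``within`` is the
    repeated factor (time).  Subjects with missing timepoints are
    listwise-deleted with a warning.
    """
    y, labels, _, _ = _pivot_complete(t, dv, between, subject, within)
    return mixed_anova_wide(y, labels, gg_correction=gg_correction)


def posthoc_by_time(
    t: pd.DataFrame,
    dv: str,
    pairs: Sequence[tuple[str, str]] | None = None,
    between: str | Sequence[str] = ("genotype", "treatment"),
    subject: str = "subject_id",
    within: str = "time_min",
    m: int | None = None,
) -> pd.DataFrame:
    """Pairwise group contrasts at each timepoint with Sidak correction.

    Standard errors use the mixed-model estimate of the between-plus-
    within variance of a cell observation, (MS_subj + (k-1) MS_resid)/k,
    with Satterthwaite degrees of freedom.  The Sidak family size ``m``
    defaults to the number of comparisons computed in this call.
    """
    y, labels, times, _ = _pivot_complete(t, dv, between, subject, within)
    res = mixed_anova_wide(y, labels)
    groups = list(np.unique(labels))
    if pairs is None:
        # Default family: treatment contrast within each genotype when the
        # labels carry a genotype prefix, else all pairs.
        by_geno: dict[str, list[str]] = {}
        for gname in groups:
            by_geno.setdefault(gname.split("_")[0], []).append(gname)
        pairs = []
        for gs in by_geno.values():
            pairs.extend((a, b) for i, a in enumerate(gs) for b in gs[i + 1 :])
        if not pairs:
            pairs = [(a, b) for i, a in enumerate(groups) for b in groups[i + 1 :]]
    for a, b in pairs:
        if a not in groups or b not in groups:
            raise ValueError(f"undefined contrast {a} vs {b}; groups are {groups}")
    k = len(times)
    ms_subj = res.strata["subjects_within_groups"].ms
    ms_res = res.strata["residual"].ms
    df_subj = res.strata["subjects_within_groups"].df
    df_res = res.strata["residual"].df
    var_cell = (ms_subj + (k - 1) * ms_res) / k
    # Satterthwaite df of the combined variance estimate.
    a1, a2 = ms_subj / k, (k - 1) * ms_res / k
    df_sw = (a1 + a2) ** 2 / (a1**2 / df_subj + a2**2 / df_res) if var_cell > 0 else df_res
    records = []
    for ti, tval in enumerate(times):
        for a, b in pairs:
            ya = y[labels == a][:, ti]
            yb = y[labels == b][:, ti]
            diff = float(ya.mean() - yb.mean())
            se = float(np.sqrt(var_cell * (1.0 / ya.size + 1.0 / yb.size)))
            if se == 0.0:
                tstat, p_raw = np.inf if diff != 0 else 0.0, 0.0 if diff != 0 else 1.0
            else:
                tstat = diff / se
                p_raw = float(2.0 * sps.t.sf(abs(tstat), df_sw))
            records.append(
                {
                    "contrast": f"{a} vs {b}",
                    "time": tval,
                    "diff": diff,
                    "se": se,
                    "t": float(tstat),
                    "df": float(df_sw),
                    "raw_p": p_raw,
                }
            )
    out = pd.DataFrame(records)
    m_eff = m if m is not None else len(out)
    out["sidak_p"] = [sidak_adjust(p, m_eff) for p in out["raw_p"]]
    return out


def summarize_groups(
    t: pd.DataFrame,
    dv: str,
    by: Sequence[str] = ("genotype", "treatment", "time_min"),
) -> pd.DataFrame:
    """Mean, SD, SEM and n per group cell (SEM = SD / sqrt(n))."""
    _check_measure_table(t)
    sub = t[t["measure"] == dv]
    if sub.empty:
        raise ValueError(f"no rows for measure {dv!r}")
    agg = (
        sub.groupby(list(by))["value"]
        .agg(mean="mean", sd="std", n="count")
        .reset_index()
    )
    agg["sem"] = agg["sd"] / np.sqrt(agg["n"])
    agg["single_subject"] = agg["n"] < 2
    return agg
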