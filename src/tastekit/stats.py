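"""Repeated-measures ANOVA with Bonferroni and Dunnett post-tests.

Two designs are supported, matching how the figure-legend statistics were
run: one-way within-subject (each unit measured at every level of one
factor) and two-way mixed (a between-unit factor such as feeding state
crossed with a within-unit factor such as concentration). Units are groups
of flies for behavioral percentages and single flies for imaging.

Sums of squares are the classical balanced decomposition; sphericity is
assumed (matching the source analysis) and incomplete or unbalanced data
are rejected rather than silently accommodated. Percentages are analyzed
untransformed by default; pass ``transform="arcsine"`` for the
arcsine-square-root variance-stabilizing option.

Dunnett's many-to-one adjustment is computed by seeded Monte Carlo over the
max-|t| null of the correlated comparison statistics (correlation 1/2 from
the shared control); with the default 100,000 draws adjusted p-values carry
~±0.003 Monte-Carlo error near p=0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AnovaTable",
    "PostTestResult",
    "rm_anova",
    "oneway_rm_anova",
    "mixed_rm_anova",
    "bonferroni",
    "bonferroni_posttests",
    "dunnett",
    "power_audit",
]


@dataclass
class AnovaTable:
    """SS/df/MS/F/p per effect, plus bookkeeping for post-tests."""

    table: pd.DataFrame
    design: str
    n_units: int
    error_ms: float
    error_df: int
    subject_ms: float | None = None
    subject_df: int | None = None

    def effect(self, name: str) -> pd.Series:
        rows = self.table[self.table["effect"] == name]
        if len(rows) == 0:
            raise KeyError(f"no effect {name!r} in {list(self.table['effect'])}")
        return rows.iloc[0]

    def p(self, name: str) -> float:
        return float(self.effect(name)["p"])

    def F(self, name: str) -> float:
        return float(self.effect(name)["F"])


@dataclass
class PostTestResult:
    comparison: str
    mean_difference: float
    statistic: float
    df: float
    raw_p: float
    adjusted_p: float
    significant: bool


def _f_row(effect: str, ss: float, df: int, ms_error: float, df_error: int) -> dict:
    ms = ss / df if df > 0 else 0.0
    if ss <= 0 or df == 0:
        # all-identical responses: guard 0/0 as F=0, p=1
        return {"effect": effect, "ss": max(ss, 0.0), "df": df, "ms": ms, "F": 0.0, "p": 1.0}
    if ms_error == 0:
        return {"effect": effect, "ss": ss, "df": df, "ms": ms, "F": np.inf, "p": 0.0}
    F = ms / ms_error
    return {
        "effect": effect,
        "ss": ss,
        "df": df,
        "ms": ms,
        "F": F,
        "p": float(sps.f.sf(F, df, df_error)),
    }


def _apply_transform(y: np.ndarray, transform: str | None) -> np.ndarray:
    if transform is None:
        return y
    if transform == "arcsine":
        # for percentages in [0, 100]
        return np.arcsin(np.sqrt(np.clip(y / 100.0, 0.0, 1.0)))
    raise ValueError(f"unknown transform {transform!r}")


def oneway_rm_anova(data: np.ndarray, transform: str | None = None) -> AnovaTable:
    """One-way within-subject ANOVA on an ``(n_units, n_levels)`` matrix.

    Decomposition: SS_total = SS_subject + SS_within + SS_error with
    F_within = MS_within / MS_error on ((a-1), (n-1)(a-1)) df.
    """
    y = _apply_transform(np.asarray(data, dtype=np.float64), transform)
    if y.ndim != 2:
        raise ValueError("data must be 2-D (units x within levels)")
    n, a = y.shape
    if n < 2 or a < 2:
        raise ValueError(f"need >= 2 units and >= 2 within levels; got {n} x {a}")
    if not np.all(np.isfinite(y)):
        raise ValueError("incomplete data: RM ANOVA requires complete cases")

    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())
    ss_subject = float(a * ((y.mean(axis=1) - grand) ** 2).sum())
    ss_within = float(n * ((y.mean(axis=0) - grand) ** 2).sum())
    ss_error = ss_total - ss_subject - ss_within

    df_within = a - 1
    df_subject = n - 1
    df_error = (n - 1) * (a - 1)
    ms_error = ss_error / df_error

    rows = [
        _f_row("within", ss_within, df_within, ms_error, df_error),
        {
            "effect": "subject",
            "ss": ss_subject,
            "df": df_subject,
            "ms": ss_subject / df_subject,
            "F": np.nan,
            "p": np.nan,
        },
        {
            "effect": "error",
            "ss": ss_error,
            "df": df_error,
            "ms": ms_error,
            "F": np.nan,
            "p": np.nan,
        },
    ]
    return AnovaTable(
        table=pd.DataFrame(rows),
        design="oneway_rm",
        n_units=n,
        error_ms=ms_error,
        error_df=df_error,
    )


def mixed_rm_anova(data: dict[str, np.ndarray], transform: str | None = None) -> AnovaTable:
    """Two-way mixed ANOVA: between-unit factor (dict keys) × within-unit
    factor (columns of each ``(n_units, n_levels)`` matrix).

    Between effects are tested against subjects-within-groups; the within
    main effect and interaction against the within-subject error. Requires
    a balanced design (equal group sizes, complete levels).
    """
    if len(data) < 2:
        raise ValueError("need >= 2 between-factor levels")
    mats = {g: _apply_transform(np.asarray(m, dtype=np.float64), transform) for g, m in data.items()}
    shapes = {m.shape for m in mats.values()}
    if len(shapes) != 1:
        raise ValueError(f"unbalanced design: group data shapes {shapes}")
    n, a = shapes.pop()
    if n < 2 or a < 2:
        raise ValueError(f"need >= 2 units per group and >= 2 within levels; got {n} x {a}")
    for m in mats.values():
        if not np.all(np.isfinite(m)):
            raise ValueError("incomplete data: RM ANOVA requires complete cases")
    g = len(mats)
    groups = list(mats)
    y = np.stack([mats[k] for k in groups])  # (g, n, a)

    grand = y.mean()
    group_means = y.mean(axis=(1, 2))  # (g,)
    level_means = y.mean(axis=(0, 1))  # (a,)
    cell_means = y.mean(axis=1)  # (g, a)
    subj_means = y.mean(axis=2)  # (g, n)

    ss_total = float(((y - grand) ** 2).sum())
    ss_between = float(n * a * ((group_means - grand) ** 2).sum())
    ss_subj = float(a * ((subj_means - group_means[:, None]) ** 2).sum())
    ss_within = float(g * n * ((level_means - grand) ** 2).sum())
    ss_inter = float(
        n * ((cell_means - group_means[:, None] - level_means[None, :] + grand) ** 2).sum()
    )
    ss_error = ss_total - ss_between - ss_subj - ss_within - ss_inter

    df_between = g - 1
    df_subj = g * (n - 1)
    df_within = a - 1
    df_inter = (g - 1) * (a - 1)
    df_error = g * (n - 1) * (a - 1)
    ms_subj = ss_subj / df_subj
    ms_error = ss_error / df_error

    rows = [
        _f_row("between", ss_between, df_between, ms_subj, df_subj),
        {
            "effect": "subject(between)",
            "ss": ss_subj,
            "df": df_subj,
            "ms": ms_subj,
            "F": np.nan,
            "p": np.nan,
        },
        _f_row("within", ss_within, df_within, ms_error, df_error),
        _f_row("interaction", ss_inter, df_inter, ms_error, df_error),
        {
            "effect": "error",
            "ss": ss_error,
            "df": df_error,
            "ms": ms_error,
            "F": np.nan,
            "p": np.nan,
        },
    ]
    return AnovaTable(
        table=pd.DataFrame(rows),
        design="mixed_rm",
        n_units=g * n,
        error_ms=ms_error,
        error_df=df_error,
        subject_ms=ms_subj,
        subject_df=df_subj,
    )


def rm_anova(
    df: pd.DataFrame,
    dv: str,
    within: str,
    subject: str,
    between: str | None = None,
    transform: str | None = None,
) -> AnovaTable:
    """Long-format front end: pivots to complete matrices, then dispatches.

    Rejects incomplete (missing cells) or unbalanced (unequal group sizes)
    layouts.
    """
    wide = df.pivot_table(index=subject, columns=within, values=dv, aggfunc="mean")
    if wide.isna().any().any():
        missing = wide.isna().sum().sum()
        raise ValueError(f"incomplete design: {missing} missing unit x level cells")
    if between is None:
        return oneway_rm_anova(wide.to_numpy(), transform=transform)
    group_of = df.groupby(subject)[between].agg(lambda s: s.unique())
    if any(len(np.atleast_1d(v)) != 1 for v in group_of):
        raise ValueError("a unit maps to multiple between-factor levels")
    group_of = group_of.apply(lambda v: np.atleast_1d(v)[0])
    data = {
        str(level): wide.loc[group_of[group_of == level].index].to_numpy()
        for level in pd.unique(group_of)
    }
    sizes = {k: v.shape[0] for k, v in data.items()}
    if len(set(sizes.values())) != 1:
        raise ValueError(f"unbalanced design: group sizes {sizes}")
    return mixed_rm_anova(data, transform=transform)


# ---------------------------------------------------------------------------
# Post-tests
# ---------------------------------------------------------------------------


def bonferroni(raw_ps: Sequence[float], m: int | None = None) -> list[float]:
    """Bonferroni adjustment: min(1, m × p). ``m`` defaults to len(raw_ps)."""
    ps = list(raw_ps)
    m = len(ps) if m is None else m
    if m < len(ps):
        raise ValueError(f"family size m={m} smaller than {len(ps)} comparisons")
    return [min(1.0, m * float(p)) for p in ps]


def bonferroni_posttests(
    data: dict[str, np.ndarray],
    table: AnovaTable | None = None,
    alpha: float = 0.05,
    transform: str | None = None,
) -> list[PostTestResult]:
    """Between-group comparisons at each within level after a mixed ANOVA.

    Per-comparison t uses the pooled error MS (subjects-within-groups +
    within-subject error), with α split across all level × group-pair
    comparisons — the convention of the software the source analysis used.
    """
    if table is None:
        table = mixed_rm_anova(data, transform=transform)
    if table.design != "mixed_rm" or table.subject_ms is None:
        raise ValueError("bonferroni_posttests needs a mixed between x within table")
    mats = {g: _apply_transform(np.asarray(m, float), transform) for g, m in data.items()}
    groups = list(mats)
    n, a = mats[groups[0]].shape
    ss_pooled = table.subject_ms * table.subject_df + table.error_ms * table.error_df
    df_pooled = table.subject_df + table.error_df
    ms_pooled = ss_pooled / df_pooled

    comparisons: list[PostTestResult] = []
    raw = []
    labels = []
    diffs = []
    ts = []
    for level in range(a):
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                d = float(mats[groups[i]][:, level].mean() - mats[groups[j]][:, level].mean())
                se = np.sqrt(ms_pooled * 2.0 / n)
                t = d / se if se > 0 else 0.0
                p = float(2 * sps.t.sf(abs(t), df_pooled)) if se > 0 else 1.0
                labels.append(f"level[{level}]: {groups[i]} vs {groups[j]}")
                diffs.append(d)
                ts.append(t)
                raw.append(p)
    adjusted = bonferroni(raw)
    for label, d, t, p, ap in zip(labels, diffs, ts, raw, adjusted):
        comparisons.append(
            PostTestResult(
                comparison=label,
                mean_difference=d,
                statistic=t,
                df=df_pooled,
                raw_p=p,
                adjusted_p=ap,
                significant=ap < alpha,
            )
        )
    return comparisons


def _dunnett_null_max_abs_t(k: int, df: int, n_mc: int, rng: np.random.Generator) -> np.ndarray:
    """Monte-Carlo null of max_j |T_j| with T_j = (z_j − z_0)/(s√2),
    z iid standard normal, s² ~ χ²_df/df shared — the correlated
    many-to-one t family under sphericity."""
    z = rng.standard_normal((n_mc, k + 1))
    s = np.sqrt(rng.chisquare(df, size=n_mc) / df)
    t = (z[:, 1:] - z[:, [0]]) / (s[:, None] * np.sqrt(2.0))
    return np.abs(t).max(axis=1)


def dunnett(
    data: np.ndarray,
    control: int = 0,
    n_mc: int = 100_000,
    seed: int = 0,
    alpha: float = 0.05,
    labels: Sequence[str] | None = None,
) -> list[PostTestResult]:
    """Many-to-one comparisons vs a control level after one-way RM ANOVA.

    ``data`` is ``(n_units, n_levels)``; each non-control level mean is
    compared to the control mean with t = diff / sqrt(2·MS_error/n) on the
    RM error df, and the family-wise adjusted p is the Monte-Carlo
    probability that the null max-|t| exceeds the observed |t|.
    """
    y = np.asarray(data, dtype=np.float64)
    table = oneway_rm_anova(y)
    n, a = y.shape
    k = a - 1
    if k == 0:
        raise ValueError("no non-control levels to compare")
    if not 0 <= control < a:
        raise ValueError(f"control index {control} out of range for {a} levels")
    if labels is None:
        labels = [str(i) for i in range(a)]

    rng = np.random.default_rng(seed)
    null_max = _dunnett_null_max_abs_t(k, table.error_df, n_mc, rng)
    se = np.sqrt(2.0 * table.error_ms / n)
    out = []
    means = y.mean(axis=0)
    for lvl in range(a):
        if lvl == control:
            continue
        d = float(means[lvl] - means[control])
        t = d / se if se > 0 else 0.0
        raw = float(2 * sps.t.sf(abs(t), table.error_df)) if se > 0 else 1.0
        adj = float(np.mean(null_max >= abs(t))) if se > 0 else 1.0
        adj = max(adj, raw)  # adjusted p never below raw
        out.append(
            PostTestResult(
                comparison=f"{labels[lvl]} vs {labels[control]}",
                mean_difference=d,
                statistic=t,
                df=table.error_df,
                raw_p=raw,
                adjusted_p=min(adj, 1.0),
                significant=adj < alpha,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Simulation audit
# ---------------------------------------------------------------------------


def power_audit(
    params,
    effect: str = "interaction",
    states: Sequence[str] = ("fed", "starved_2d"),
    n_sims: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Rejection rate of a mixed RM-ANOVA effect over simulated PER
    experiments drawn from ``params`` (a ``BehaviorSimParams``).

    Each simulation generates group-level percent-PER summaries for the
    requested states across the dose series and tests ``effect`` at
    ``alpha``. With a zero-effect generator this audits the type-I error;
    with the default calibration it measures power for the state × dose
    interaction.
    """
    import dataclasses as dc

    from tastekit.behavior import summarize_groups
    from tastekit.synthetic import make_per_dataset

    if n_sims < 100:
        raise ValueError("n_sims must be >= 100 for a meaningful rate")
    rejections = 0
    for s in range(n_sims):
        sim_params = dc.replace(params, states=tuple(states), seed=0)
        ds = make_per_dataset(sim_params, seed=seed * 1_000_003 + s)
        groups = summarize_groups(ds)
        table = rm_anova(
            groups, dv="percent_per", within="dose", subject="group_id", between="state"
        )
        if table.p(effect) < alpha:
            rejections += 1
    return rejections / n_sims
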