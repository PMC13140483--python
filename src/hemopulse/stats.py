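"""Group-by-time statistical workflow.

A long-format study table (subject, group, time, outcome, value) feeds a
two-group by three-time mixed-design repeated-measures ANOVA: the
between-subject effect (group) is tested against subject-within-group
variation, the within-subject effects (time and group-by-time) against
the subject-by-time residual. Effect sizes are partial eta squared,
SS_effect / (SS_effect + SS_error-for-that-effect). Normality is gated by
Shapiro–Wilk per design cell with a natural-log rescue, post hoc pairwise
contrasts are Bonferroni-corrected within their declared family, and
baseline descriptives use Welch t tests and Pearson chi-squared.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    InsufficientDataError,
    IntegrityError,
    TransformError,
)

TIME_ORDER = ("baseline", "30", "60")

REQUIRED_COLUMNS = ("subject", "group", "time", "outcome", "value")


# ---------------------------------------------------------------------------
# study table handling
# ---------------------------------------------------------------------------

def validate_study_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check key uniqueness and single group membership; returns the table."""
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise IntegrityError(f"study table missing columns {missing}")
    dup = table.duplicated(subset=["subject", "time", "outcome"])
    if dup.any():
        raise IntegrityError(
            f"{int(dup.sum())} duplicate (subject, time, outcome) keys"
        )
    multi = table.groupby("subject")["group"].nunique()
    bad = multi[multi > 1]
    if len(bad):
        raise IntegrityError(
            f"subjects in more than one group: {list(bad.index)}"
        )
    return table


def complete_cases(table: pd.DataFrame, outcome: str) -> pd.DataFrame:
    """Wide (subjects x times) table for one outcome, complete cases only.

    Returned frame is indexed by subject with a ``group`` column followed
    by one column per time point in protocol order.
    """
    sub = table[(table["outcome"] == outcome) & table["value"].notna()]
    wide = sub.pivot(index="subject", columns="time", values="value")
    times = [t for t in TIME_ORDER if t in wide.columns]
    wide = wide[times].dropna()
    groups = sub.drop_duplicates("subject").set_index("subject")["group"]
    wide.insert(0, "group", groups.reindex(wide.index))
    return wide


# ---------------------------------------------------------------------------
# normality gate
# ---------------------------------------------------------------------------

@dataclass
class NormalityReport:
    transform_applied: str  # {"none", "log"}
    cell_p_before: dict
    cell_p_after: dict | None
    flagged_cells: list = field(default_factory=list)


def normality_gate(
    table: pd.DataFrame, outcome: str, alpha: float = 0.05
) -> tuple[pd.DataFrame, NormalityReport]:
    """Shapiro–Wilk on design-cell residuals; natural-log rescue on failure.

    The gate runs one Shapiro–Wilk test on the residuals pooled across
    (group, time) cells (each value centered on its cell mean), keeping
    the gate's false-transform rate at ``alpha`` rather than inflating it
    across six per-cell tests; per-cell p values are still reported as
    diagnostics. Cells that are too small (< 3) or constant leave their
    diagnostic undefined and are flagged. On rejection at ``alpha`` the
    outcome's values are replaced by their natural logarithms (erroring
    on non-positive values) and residuals re-tested.
    """
    def cell_pvalues(tab: pd.DataFrame) -> tuple[dict, list]:
        ps, flagged = {}, []
        resid = []
        sub = tab[tab["outcome"] == outcome]
        for (g, tm), grp in sub.groupby(["group", "time"]):
            v = grp["value"].dropna().to_numpy()
            if v.size < 3 or np.ptp(v) == 0:
                # test undefined for this cell: flag it and keep its
                # (information-free) residuals out of the pooled test
                flagged.append((g, tm))
                continue
            resid.append(v - v.mean())
            ps[(g, tm)] = float(sps.shapiro(v).pvalue)
        pooled = np.concatenate(resid) if resid else np.array([])
        if pooled.size < 3 or np.ptp(pooled) == 0:
            ps["pooled_residuals"] = np.nan
        else:
            ps["pooled_residuals"] = float(sps.shapiro(pooled).pvalue)
        return ps, flagged

    ps, flagged = cell_pvalues(table)
    pooled_p = ps.get("pooled_residuals", np.nan)
    if not np.isfinite(pooled_p) or pooled_p >= alpha:
        return table, NormalityReport("none", ps, None, flagged)

    mask = table["outcome"] == outcome
    vals = table.loc[mask, "value"]
    nonpos = table.loc[mask & (table["value"] <= 0)]
    if len(nonpos):
        raise TransformError(
            f"log transform of {outcome!r} undefined for "
            f"{len(nonpos)} non-positive rows: "
            f"{nonpos['subject'].tolist()[:10]}"
        )
    out = table.copy()
    out.loc[mask, "value"] = np.log(vals)
    ps_after, flagged_after = cell_pvalues(out)
    return out, NormalityReport("log", ps, ps_after,
                                sorted(set(flagged) | set(flagged_after)))


# ---------------------------------------------------------------------------
# mixed-design repeated-measures ANOVA
# ---------------------------------------------------------------------------

@dataclass
class EffectResult:
    ss: float
    df: int
    ms: float
    F: float
    p: float
    partial_eta_sq: float
    p_gg: float | None = None  # sphericity-corrected, within effects only


@dataclass
class AnovaResult:
    effects: dict  # {"group", "time", "group_x_time"} -> EffectResult
    ss_subject: float
    ss_residual: float
    df_subject: int
    df_residual: int
    gg_epsilon: float | None
    n_per_group: dict
    posthoc: list = field(default_factory=list)


def mixed_anova_arrays(groups: list[np.ndarray]) -> dict:
    """Sums-of-squares partition of a one-between, one-within design.

    ``groups`` holds one (n_g x p) array per group; every subject has all
    p repeated measurements. Returns the SS/df/F/p building blocks. The
    within-subject time factor is balanced across subjects, so the
    partition below is exact (SS components sum to SS_total) even with
    unequal group sizes; time and interaction means are weighted by group
    size.
    """
    p = groups[0].shape[1]
    k = len(groups)
    ns = np.array([g.shape[0] for g in groups])
    if np.any(ns < 2):
        raise InsufficientDataError(
            "each group needs at least 2 complete subjects"
        )
    big = np.vstack(groups)
    n_tot = big.shape[0]
    grand = big.mean()

    group_means = np.array([g.mean() for g in groups])
    time_means = big.mean(axis=0)  # weighted across all subjects
    cell_means = np.vstack([g.mean(axis=0) for g in groups])  # k x p

    ss_total = float(((big - grand) ** 2).sum())
    ss_group = float(p * (ns * (group_means - grand) ** 2).sum())
    ss_subj = float(
        p * sum(((g.mean(axis=1) - m) ** 2).sum()
                for g, m in zip(groups, group_means))
    )
    ss_time = float(n_tot * ((time_means - grand) ** 2).sum())
    inter = (
        cell_means
        - group_means[:, None]
        - time_means[None, :]
        + grand
    )
    ss_int = float((ns[:, None] * inter ** 2).sum())
    ss_resid = 0.0
    for gi, g in enumerate(groups):
        pred = (
            g.mean(axis=1)[:, None]
            + cell_means[gi][None, :]
            - group_means[gi]
        )
        ss_resid += float(((g - pred) ** 2).sum())

    df_group = k - 1
    df_subj = n_tot - k
    df_time = p - 1
    df_int = (k - 1) * (p - 1)
    df_resid = (n_tot - k) * (p - 1)
    return {
        "ss_total": ss_total,
        "ss_group": ss_group, "df_group": df_group,
        "ss_subject": ss_subj, "df_subject": df_subj,
        "ss_time": ss_time, "df_time": df_time,
        "ss_interaction": ss_int, "df_interaction": df_int,
        "ss_residual": ss_resid, "df_residual": df_resid,
        "n_per_group": ns, "p_levels": p,
    }


def _gg_epsilon(groups: list[np.ndarray]) -> float:
    """Greenhouse–Geisser epsilon from the pooled within-group covariance."""
    p = groups[0].shape[1]
    pooled = np.zeros((p, p))
    dof = 0
    for g in groups:
        c = g - g.mean(axis=0)
        pooled += c.T @ c
        dof += g.shape[0] - 1
    s = pooled / dof
    # double-center
    sc = s - s.mean(axis=0) - s.mean(axis=1)[:, None] + s.mean()
    num = np.trace(sc) ** 2
    den = (p - 1) * float((sc * sc).sum())
    if den <= 0:
        return 1.0
    return float(min(max(num / den, 1.0 / (p - 1)), 1.0))


def rm_anova_2x3(table: pd.DataFrame, outcome: str) -> AnovaResult:
    """Two-group by three-time mixed repeated-measures ANOVA.

    Complete cases only. Uncorrected degrees of freedom are reported as
    the primary result; the Greenhouse–Geisser-corrected p value rides
    along for the within-subject effects since a three-level within
    factor commonly violates sphericity.
    """
    wide = complete_cases(validate_study_table(table), outcome)
    if wide.shape[1] - 1 < 2:
        raise InsufficientDataError(f"outcome {outcome!r} has < 2 time points")
    labels = sorted(wide["group"].unique())
    groups = [
        wide[wide["group"] == lab].drop(columns="group").to_numpy()
        for lab in labels
    ]
    ss = mixed_anova_arrays(groups)
    eps = _gg_epsilon(groups)

    def effect(name_ss: str, name_df: str, err_ss: str, err_df: str,
               gg: bool) -> EffectResult:
        s, d = ss[name_ss], ss[name_df]
        se, de = ss[err_ss], ss[err_df]
        ms, mse = s / d, se / de
        F = ms / mse if mse > 0 else np.inf
        pval = float(sps.f.sf(F, d, de))
        eta = s / (s + se) if (s + se) > 0 else 0.0
        p_gg = None
        if gg:
            p_gg = float(sps.f.sf(F, d * eps, de * eps))
        return EffectResult(s, d, ms, F, pval, eta, p_gg)

    effects = {
        "group": effect("ss_group", "df_group", "ss_subject", "df_subject",
                        gg=False),
        "time": effect("ss_time", "df_time", "ss_residual", "df_residual",
                       gg=True),
        "group_x_time": effect("ss_interaction", "df_interaction",
                               "ss_residual", "df_residual", gg=True),
    }
    return AnovaResult(
        effects=effects,
        ss_subject=ss["ss_subject"],
        ss_residual=ss["ss_residual"],
        df_subject=ss["df_subject"],
        df_residual=ss["df_residual"],
        gg_epsilon=eps,
        n_per_group={lab: g.shape[0] for lab, g in zip(labels, groups)},
    )


# ---------------------------------------------------------------------------
# post hoc contrasts
# ---------------------------------------------------------------------------

@dataclass
class Contrast:
    family: str
    label: str
    mean_diff: float
    t: float | None
    p_raw: float | None
    p_adjusted: float | None
    flagged: str | None = None


def bonferroni_posthoc(
    table: pd.DataFrame, outcome: str, which: str
) -> list[Contrast]:
    """Bonferroni-corrected pairwise tests for one contrast family.

    ``time_within_group``: paired t over the three time pairs, separately
    per group (m = 3 within each group's family). ``group_within_time``:
    Welch t between groups at each time (m = 3). ``time_overall``: paired
    t over time pairs pooling groups (m = 3). Adjusted p is
    min(1, m * p_raw); zero-variance contrasts are flagged with p
    undefined.
    """
    wide = complete_cases(validate_study_table(table), outcome)
    times = [c for c in wide.columns if c != "group"]
    pairs = [(a, b) for i, a in enumerate(times) for b in times[i + 1:]]
    out: list[Contrast] = []

    def paired(sub: pd.DataFrame, family: str, prefix: str = "") -> None:
        m = len(pairs)
        for a, b in pairs:
            d = sub[b].to_numpy() - sub[a].to_numpy()
            label = f"{prefix}{a} vs {b}"
            if d.size < 2 or np.ptp(d) == 0:
                out.append(Contrast(family, label, float(np.mean(d)) if d.size
                                    else np.nan, None, None, None,
                                    flagged="zero_variance"))
                continue
            t, p = sps.ttest_rel(sub[b], sub[a])
            out.append(Contrast(family, label, float(np.mean(d)), float(t),
                                float(p), min(1.0, m * float(p))))

    if which == "time_within_group":
        for lab, sub in wide.groupby("group"):
            paired(sub, f"time_within_{lab}", prefix=f"{lab}: ")
    elif which == "time_overall":
        paired(wide, "time_overall")
    elif which == "group_within_time":
        labs = sorted(wide["group"].unique())
        if len(labs) != 2:
            raise InsufficientDataError("need exactly two groups")
        m = len(times)
        a_w = wide[wide["group"] == labs[0]]
        b_w = wide[wide["group"] == labs[1]]
        for tm in times:
            x, y = a_w[tm].to_numpy(), b_w[tm].to_numpy()
            label = f"{labs[0]} vs {labs[1]} @ {tm}"
            if np.ptp(x) == 0 and np.ptp(y) == 0:
                out.append(Contrast("group_within_time", label,
                                    float(np.mean(y) - np.mean(x)),
                                    None, None, None, flagged="zero_variance"))
                continue
            t, p = sps.ttest_ind(y, x, equal_var=False)
            out.append(Contrast("group_within_time", label,
                                float(np.mean(y) - np.mean(x)), float(t),
                                float(p), min(1.0, m * float(p))))
    else:
        raise InsufficientDataError(f"unknown contrast family {which!r}")
    return out


# ---------------------------------------------------------------------------
# baseline descriptives
# ---------------------------------------------------------------------------

def describe_groups(
    frame: pd.DataFrame,
    group_col: str = "group",
    categorical: tuple = (),
) -> pd.DataFrame:
    """Two-group baseline comparison table.

    Continuous variables: Welch (unequal-variance) independent t test.
    Categorical variables (named in ``categorical`` or non-numeric):
    Pearson chi-squared on the contingency table, without continuity
    correction. Undefined tests (a zero expected count) are flagged.
    """
    labs = sorted(frame[group_col].unique())
    if len(labs) != 2:
        raise InsufficientDataError("need exactly two groups")
    rows = []
    for col in frame.columns:
        if col == group_col:
            continue
        is_cat = col in categorical or not pd.api.types.is_numeric_dtype(
            frame[col]
        )
        if is_cat:
            ct = pd.crosstab(frame[group_col], frame[col]).to_numpy()
            if ct.size == 0 or (ct.sum(axis=0) == 0).any() or (
                ct.sum(axis=1) == 0
            ).any():
                rows.append((col, "chi2", np.nan, np.nan, "undefined"))
                continue
            res = sps.chi2_contingency(ct, correction=False)
            rows.append((col, "chi2", float(res.statistic),
                         float(res.pvalue), None))
        else:
            x = frame.loc[frame[group_col] == labs[0], col].dropna()
            y = frame.loc[frame[group_col] == labs[1], col].dropna()
            if np.ptp(x) == 0 and np.ptp(y) == 0 and x.mean() == y.mean():
                rows.append((col, "t", 0.0, 1.0, None))
                continue
            t, p = sps.ttest_ind(x, y, equal_var=False)
            rows.append((col, "t", float(t), float(p), None))
    return pd.DataFrame(
        rows, columns=["variable", "test", "statistic", "p", "flag"]
    )


def chi2_counts(table_2x2: np.ndarray) -> tuple[float, float]:
    """Pearson chi-squared (no continuity correction) on a count table."""
    res = sps.chi2_contingency(np.asarray(table_2x2), correction=False)
    return float(res.statistic), float(res.pvalue)
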