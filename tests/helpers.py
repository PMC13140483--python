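"""Independent oracles used by the test suite.

These deliberately re-derive results from first principles (explicit
loops over textbook definitions) and never call the package code paths
they are used to check.
"""

import numpy as np


def brute_force_mixed_anova(groups):
    """Textbook sums-of-squares for a one-between, one-within design.

    ``groups``: list of (n_g x p) arrays, every subject measured at all p
    levels. All means are computed with explicit Python loops over the
    definitions: between-subject variation is split into group and
    subject-within-group parts, within-subject variation into time,
    group-by-time and residual parts.
    """
    k = len(groups)
    p = groups[0].shape[1]
    ns = [g.shape[0] for g in groups]
    n_tot = sum(ns)

    grand = sum(float(g.sum()) for g in groups) / (n_tot * p)
    group_mean = [float(g.sum()) / (ns[i] * p) for i, g in enumerate(groups)]
    time_mean = [
        sum(float(g[:, s].sum()) for g in groups) / n_tot for s in range(p)
    ]
    cell_mean = [[float(g[:, s].mean()) for s in range(p)] for g in groups]

    ss_group = 0.0
    ss_subj = 0.0
    ss_time = 0.0
    ss_int = 0.0
    ss_resid = 0.0
    ss_total = 0.0
    for gi, g in enumerate(groups):
        ss_group += p * ns[gi] * (group_mean[gi] - grand) ** 2
        for i in range(ns[gi]):
            subj_mean = float(np.mean(g[i]))
            ss_subj += p * (subj_mean - group_mean[gi]) ** 2
            for s in range(p):
                resid = (
                    g[i, s] - subj_mean - cell_mean[gi][s] + group_mean[gi]
                )
                ss_resid += resid ** 2
                ss_total += (g[i, s] - grand) ** 2
        for s in range(p):
            ss_int += ns[gi] * (
                cell_mean[gi][s] - group_mean[gi] - time_mean[s] + grand
            ) ** 2
    for s in range(p):
        ss_time += n_tot * (time_mean[s] - grand) ** 2

    from scipy.stats import f as fdist

    df_group, df_subj = k - 1, n_tot - k
    df_time, df_int = p - 1, (k - 1) * (p - 1)
    df_resid = (n_tot - k) * (p - 1)

    def eff(ss, df, ss_err, df_err):
        F = (ss / df) / (ss_err / df_err)
        return {
            "F": F,
            "p": float(fdist.sf(F, df, df_err)),
            "partial_eta_sq": ss / (ss + ss_err),
        }

    return {
        "group": eff(ss_group, df_group, ss_subj, df_subj),
        "time": eff(ss_time, df_time, ss_resid, df_resid),
        "group_x_time": eff(ss_int, df_int, ss_resid, df_resid),
        "ss": {
            "total": ss_total, "group": ss_group, "subject": ss_subj,
            "time": ss_time, "interaction": ss_int, "residual": ss_resid,
        },
    }


def chi2_by_hand(table):
    """Pearson chi-squared from the definition, no continuity correction."""
    table = np.asarray(table, dtype=float)
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    total = table.sum()
    stat = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            e = row[i] * col[j] / total
            stat += (table[i, j] - e) ** 2 / e
    from scipy.stats import chi2

    dof = (table.shape[0] - 1) * (table.shape[1] - 1)
    return stat, float(chi2.sf(stat, dof))


def make_long_table(groups_dict, times=("baseline", "30", "60")):
    """Long-format study table from {group: (n x p) array}."""
    import pandas as pd

    rows = []
    for g, arr in groups_dict.items():
        for i, row in enumerate(arr):
            for t, v in zip(times, row):
                rows.append((f"{g}{i:03d}", g, t, "y", float(v)))
    return pd.DataFrame(
        rows, columns=["subject", "group", "time", "outcome", "value"]
    )
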