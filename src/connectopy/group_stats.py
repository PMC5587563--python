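"""Connectivity-strength group comparisons.

Within-subject connectivity strength distributions are summarised by
quartiles for each region-set (left intra-hemispheric, right
intra-hemispheric, interhemispheric).  Group comparisons use

* a max-statistic (t_max) permutation test across the family of nine
  quartile-by-region-set comparisons, which controls the family-wise
  error without a distributional assumption;
* two-sample Kolmogorov-Smirnov tests of group-averaged within-subject
  weight distributions;
* a two-way mixed ANOVA (between: group; within: region-set) of median
  connectivity strength, with partial eta squared per effect and Hedges' g
  for simple effects.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .connectome import Connectome, extract_hemisphere

__all__ = [
    "REGION_SETS",
    "region_set_weights",
    "strength_quartiles",
    "quartile_table",
    "two_sample_t",
    "tmax_permutation_test",
    "group_averaged_distribution",
    "ks_two_sample",
    "rm_anova_2xk",
    "hedges_g",
    "simple_effects",
]

REGION_SETS = ("left", "right", "interhemispheric")
QUARTILES = (0.25, 0.5, 0.75)


def region_set_weights(c: Connectome, region_set: str) -> np.ndarray:
    """Nonzero edge weights of one region-set of a subject's connectome."""
    if region_set in ("left", "right"):
        sub = extract_hemisphere(c, region_set).weights
        iu, ju = np.triu_indices(sub.shape[0], k=1)
        vals = sub[iu, ju]
    elif region_set == "interhemispheric":
        vals = extract_hemisphere(c, "interhemispheric").ravel()
    else:
        raise ValueError(f"unknown region set {region_set!r}")
    return vals[vals > 0]


def strength_quartiles(c: Connectome) -> pd.DataFrame:
    """Quartiles (q25, q50, q75) of nonzero weights per region-set.

    Linear-interpolation quantiles; empty region-sets yield NaN.
    """
    rows = []
    for rs in REGION_SETS:
        vals = region_set_weights(c, rs)
        if vals.size == 0:
            q = (np.nan, np.nan, np.nan)
        else:
            q = tuple(np.quantile(vals, QUARTILES))
        rows.append({"region_set": rs, "q25": q[0], "q50": q[1], "q75": q[2]})
    return pd.DataFrame(rows)


def quartile_table(cohort: list[Connectome]) -> pd.DataFrame:
    """One row per subject, columns ``<region_set>_q<level>`` (9 statistics)."""
    records = []
    for c in cohort:
        rec: dict[str, float | str] = {"subject_id": c.subject_id}
        q = strength_quartiles(c)
        for _, row in q.iterrows():
            for col in ("q25", "q50", "q75"):
                rec[f"{row['region_set']}_{col}"] = row[col]
        records.append(rec)
    return pd.DataFrame(records).set_index("subject_id")


def two_sample_t(x: np.ndarray, y: np.ndarray) -> float:
    """Independent-samples pooled-variance t statistic (x mean minus y mean)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = len(x), len(y)
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    return float((x.mean() - y.mean()) / np.sqrt(sp2 * (1 / nx + 1 / ny)))


def _t_for_assignments(values: np.ndarray, assign: np.ndarray, n1: int) -> np.ndarray:
    """Pooled t statistics for many group assignments at once.

    ``values``: (n_subjects, n_stats); ``assign``: (n_perm, n_subjects)
    boolean, True marking membership of the first group (size n1 each row).
    Returns (n_perm, n_stats).
    """
    n = values.shape[0]
    n2 = n - n1
    a = assign.astype(float)
    s1 = a @ values
    s1sq = a @ values**2
    tot = values.sum(axis=0)
    totsq = (values**2).sum(axis=0)
    m1 = s1 / n1
    m2 = (tot - s1) / n2
    ss1 = s1sq - n1 * m1**2
    ss2 = (totsq - s1sq) - n2 * m2**2
    sp2 = (ss1 + ss2) / (n - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    return t


def tmax_permutation_test(
    values: pd.DataFrame | np.ndarray,
    groups: np.ndarray,
    n_perm: int = 10_000,
    seed: int | None = None,
    exact: bool = False,
    control: str | None = None,
):
    """Max-statistic permutation test over a family of comparisons.

    For every permutation of the group labels, the maximum |t| over all
    statistics is recorded; the adjusted p-value of each statistic is the
    proportion of permutations (the identity included) whose max |t| is at
    least the observed |t|.  With ``exact=True`` all distinct label
    assignments are enumerated instead of sampled.

    Returns a DataFrame with observed t, raw and adjusted p per statistic.
    The t numerator is mean(first group) - mean(second group); the first
    group is ``control`` if given, else the alphabetically first label.
    """
    if isinstance(values, pd.DataFrame):
        names = list(values.columns)
        x = values.to_numpy(dtype=float)
    else:
        x = np.asarray(values, dtype=float)
        names = [f"stat_{i}" for i in range(x.shape[1])]
    groups = np.asarray(groups)
    levels = sorted(pd.unique(groups))
    if len(levels) != 2:
        raise ValueError("exactly two groups required")
    first = control if control is not None else levels[0]
    is_first = groups == first
    n, n1 = len(groups), int(is_first.sum())

    t_obs = _t_for_assignments(x, is_first[None, :], n1)[0]
    abs_obs = np.abs(t_obs)

    if exact:
        assign = np.zeros((comb(n, n1), n), dtype=bool)
        for r, idx in enumerate(combinations(range(n), n1)):
            assign[r, list(idx)] = True
    else:
        if n_perm < 1:
            raise ValueError("n_perm must be positive")
        rng = np.random.default_rng(seed)
        assign = np.zeros((n_perm, n), dtype=bool)
        for r in range(n_perm):
            assign[r, rng.permutation(n)[:n1]] = True
        assign[0] = is_first  # identity permutation always included

    t_perm = np.abs(_t_for_assignments(x, assign, n1))
    max_perm = np.nanmax(t_perm, axis=1)
    n_eff = assign.shape[0]
    p_adj = (max_perm[:, None] >= abs_obs[None, :] - 1e-12).sum(axis=0) / n_eff
    p_raw = (t_perm >= abs_obs[None, :] - 1e-12).sum(axis=0) / n_eff
    return pd.DataFrame(
        {"statistic": names, "t": t_obs, "p_raw": p_raw, "p_adjusted": p_adj}
    ).set_index("statistic")


def group_averaged_distribution(
    cohort: list[Connectome], groups: np.ndarray, region_set: str
) -> dict[str, np.ndarray]:
    """Edge-wise mean weight vectors per group for one region-set.

    For each group the subject matrices are averaged edge-wise and the
    region-set's edge values (including averaged zeros) are returned as a
    vector; these vectors are the inputs of the KS comparison.
    """
    groups = np.asarray(groups)
    out = {}
    for level in pd.unique(groups):
        members = [c for c, g in zip(cohort, groups) if g == level]
        mean_w = np.mean([c.weights for c in members], axis=0)
        mean_c = Connectome(
            weights=(mean_w + mean_w.T) / 2,
            parcellation=members[0].parcellation,
            subject_id=f"mean_{level}",
        )
        if region_set in ("left", "right"):
            sub = extract_hemisphere(mean_c, region_set).weights
            iu, ju = np.triu_indices(sub.shape[0], k=1)
            out[level] = sub[iu, ju]
        else:
            out[level] = extract_hemisphere(mean_c, "interhemispheric").ravel()
    return out


def ks_two_sample(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov statistic and asymptotic p-value."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    res = stats.ks_2samp(x, y, method="asymp")
    return float(res.statistic), float(res.pvalue)


def rm_anova_2xk(
    long_table: pd.DataFrame,
    dv: str = "value",
    subject: str = "subject_id",
    within: str = "region_set",
    between: str = "group",
) -> pd.DataFrame:
    """Two-way mixed ANOVA (between-subject group, within-subject factor).

    Implements the standard sums-of-squares decomposition for a balanced
    within-factor design (every subject measured at every within level).
    Returns one row per effect (group, within, interaction) with SS, df,
    F, p and partial eta squared, plus the two error strata.

    The full decomposition satisfies
    ``SS_total = SS_group + SS_subjects_within + SS_within + SS_interaction
    + SS_error_within``.
    """
    df = long_table[[subject, within, between, dv]].dropna().copy()
    wide = df.pivot_table(index=[subject, between], columns=within, values=dv)
    if wide.isna().any().any():
        raise ValueError("unbalanced design: every subject needs every within level")
    y = wide.to_numpy(dtype=float)
    grp = wide.index.get_level_values(between).to_numpy()
    levels = sorted(pd.unique(grp))
    if len(levels) != 2:
        raise ValueError("between factor must have exactly two levels")
    n_total, b = y.shape
    grand = y.mean()

    subj_means = y.mean(axis=1)
    within_means = y.mean(axis=0)

    ss_between_subj = b * np.sum((subj_means - grand) ** 2)
    ss_group = 0.0
    ss_inter = 0.0
    for g in levels:
        sel = grp == g
        ng = sel.sum()
        gmean = y[sel].mean()
        ss_group += b * ng * (gmean - grand) ** 2
        cell = y[sel].mean(axis=0)
        ss_inter += ng * np.sum((cell - gmean - within_means + grand) ** 2)
    ss_subj_within = ss_between_subj - ss_group
    ss_within_total = np.sum((y - subj_means[:, None]) ** 2)
    ss_within = n_total * np.sum((within_means - grand) ** 2)
    ss_err_within = ss_within_total - ss_within - ss_inter
    # guard against negative roundoff in the subtractive error terms
    tol = 1e-12 * max(np.sum((y - grand) ** 2), 1.0)
    ss_subj_within = max(ss_subj_within, 0.0)
    ss_err_within = max(ss_err_within, 0.0)
    if ss_inter < tol:
        ss_inter = max(ss_inter, 0.0)

    df_group, df_subj = 1, n_total - 2
    df_within, df_inter = b - 1, b - 1
    df_err = (b - 1) * (n_total - 2)

    def row(name, ss, dfe, ss_err, df_err_):
        ms, ms_err = ss / dfe, ss_err / df_err_
        if ms_err <= 0:
            f = 0.0 if ss <= tol else np.inf
        else:
            f = ms / ms_err
        p = stats.f.sf(f, dfe, df_err_)
        return {
            "effect": name, "SS": ss, "df1": dfe, "df2": df_err_,
            "F": f, "p": p, "partial_eta_sq": ss / (ss + ss_err),
        }

    out = [
        row("group", ss_group, df_group, ss_subj_within, df_subj),
        row("within", ss_within, df_within, ss_err_within, df_err),
        row("interaction", ss_inter, df_inter, ss_err_within, df_err),
    ]
    table = pd.DataFrame(out).set_index("effect")
    table.attrs["SS_subjects_within"] = float(ss_subj_within)
    table.attrs["SS_error_within"] = float(ss_err_within)
    table.attrs["SS_total"] = float(np.sum((y - grand) ** 2))
    return table


def hedges_g(x: np.ndarray, y: np.ndarray) -> float:
    """Bias-corrected standardised mean difference between two samples.

    ``g = J * (mean_x - mean_y) / s_pooled`` with the small-sample
    correction ``J = 1 - 3 / (4 (n_x + n_y - 2) - 1)``.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError("each sample needs at least two observations")
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    if sp2 == 0:
        raise ValueError("zero pooled variance")
    j = 1 - 3 / (4 * (nx + ny - 2) - 1)
    return float(j * (x.mean() - y.mean()) / np.sqrt(sp2))


def simple_effects(
    long_table: pd.DataFrame,
    dv: str = "value",
    subject: str = "subject_id",
    within: str = "region_set",
    between: str = "group",
    control: str | None = None,
) -> pd.DataFrame:
    """Per-within-level independent t-tests between groups, with Hedges' g."""
    df = long_table.dropna(subset=[dv])
    levels = sorted(pd.unique(df[between]))
    first = control if control is not None else levels[0]
    second = [g for g in levels if g != first][0]
    rows = []
    for lvl, sub in df.groupby(within, sort=False):
        x = sub.loc[sub[between] == first, dv].to_numpy()
        y = sub.loc[sub[between] == second, dv].to_numpy()
        t = two_sample_t(x, y)
        dof = len(x) + len(y) - 2
        rows.append(
            {
                within: lvl,
                "t": t,
                "df": dof,
                "p": 2 * stats.t.sf(abs(t), dof),
                "hedges_g": hedges_g(x, y),
            }
        )
    return pd.DataFrame(rows).set_index(within)
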