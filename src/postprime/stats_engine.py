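"""Two-way mixed repeated-measures ANOVA layer.

For every dependent variable (DV) the design is Condition (within-subject,
k levels) × AgeGroup (between-subject, g levels), with trials first averaged
to one value per participant × condition.  The classical univariate
decomposition is used:

    SS_total = SS_group + SS_subjects(group)            (between-subject)
             + SS_condition + SS_interaction + SS_error (within-subject)

    F_group = MS_group / MS_subjects(group)
    F_condition = MS_condition / MS_error
    F_interaction = MS_interaction / MS_error

Effect sizes are partial eta squared, η²p = F·df1 / (F·df1 + df2).
Sphericity of the within-subject covariance is tested with Mauchly's W
(pooled within-group covariance); when rejected at 0.05 the
Greenhouse–Geisser ε multiplies both degrees of freedom (never increasing
them, so the corrected p is never smaller than the uncorrected one).

Family-wise correction follows the published divided-alpha rule:
``alpha_adj = 0.05 / (#DVs × 2)``, two tests (condition main effect and the
interaction) per DV; a true sequential Holm procedure is available as
``stats.method = "holm_sequential"``.  Significant omnibus effects may be
followed by Bonferroni-adjusted pairwise comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import FamilySpec, StatsConfig
from .errors import DataError, DegenerateDataError, MissingCellError, PosthocRefusedError

DEFAULT_FAMILIES = [
    FamilySpec(name="vas", dvs=["vas_likely_mm", "vas_concern_mm"]),
    FamilySpec(name="step_prep", dvs=["copon_latency_s", "stepon_latency_s"]),
    FamilySpec(name="com_prep", dvs=["prep_com_acc_ap_mss", "prep_com_acc_ml_mss",
                                     "prep_com_exc_ap_m", "prep_com_exc_ml_m"]),
    FamilySpec(name="muscle_onsets", dvs=["lat_ES_L_s", "lat_ES_R_s", "lat_RA_L_s",
                                          "lat_RA_R_s", "lat_TA_L_s", "lat_TA_R_s",
                                          "lat_GAS_L_s", "lat_GAS_R_s"]),
    FamilySpec(name="cci_prep", dvs=["cci_i", "cci_ii"]),
    FamilySpec(name="step_comp", dvs=["stepoff_latency_s", "step_time_s",
                                      "step_length_m", "step_width_m"]),
    FamilySpec(name="com_comp", dvs=["total_com_exc_ap_m", "total_com_exc_ml_m"]),
    FamilySpec(name="cci_comp", dvs=["cci_iii", "cci_iv"]),
    FamilySpec(name="joint_exc", dvs=[f"exc_{j}_deg" for j in
                                      ("ankle", "knee", "hip", "lumbar",
                                       "thorax", "shoulder", "elbow")]),
]


def partial_eta_squared(F: float, df1: float, df2: float) -> float:
    """η²p = F·df1 / (F·df1 + df2)."""
    if F < 0 or df1 <= 0 or df2 <= 0:
        raise DataError("partial_eta_squared needs F >= 0 and positive dfs")
    return (F * df1) / (F * df1 + df2)


def holm_family_alpha(n_dvs: int) -> float:
    """Family-adjusted alpha: 0.05 / (#DVs × 2 tests per DV)."""
    if n_dvs < 1:
        raise DataError("family needs at least one DV")
    return 0.05 / (n_dvs * 2)


def holm_sequential(p_values: Sequence[float], alpha: float = 0.05) -> np.ndarray:
    """Sequential Holm step-down: True where the hypothesis is rejected."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p)
    reject = np.zeros(m, dtype=bool)
    for rank, idx in enumerate(order):
        if p[idx] <= alpha / (m - rank):
            reject[idx] = True
        else:
            break
    return reject


# ---------------------------------------------------------------------------
# sphericity


def _contrast_matrix(k: int) -> np.ndarray:
    """Orthonormal (k−1)×k contrast matrix (orthonormalized Helmert)."""
    c = np.zeros((k - 1, k))
    for i in range(k - 1):
        c[i, : i + 1] = 1.0
        c[i, i + 1] = -(i + 1)
        c[i] /= np.linalg.norm(c[i])
    return c


def _pooled_within_cov(scores: np.ndarray, groups: np.ndarray) -> tuple[np.ndarray, int]:
    """Pooled within-group covariance of condition scores; df = N − g."""
    k = scores.shape[1]
    s = np.zeros((k, k))
    df = 0
    for g in np.unique(groups):
        y = scores[groups == g]
        yc = y - y.mean(axis=0)
        s += yc.T @ yc
        df += y.shape[0] - 1
    if df < 1:
        raise DataError("need at least 2 participants in some group")
    return s / df, df


def gg_epsilon(scores: np.ndarray, groups: Optional[np.ndarray] = None) -> float:
    """Greenhouse–Geisser ε from the sample covariance of condition scores.

    ``scores`` is participants × conditions; with ``groups`` given the
    covariance is pooled within group.  ε lies in [1/(k−1), 1]; a singular
    covariance degrades to the lower bound.
    """
    y = np.asarray(scores, dtype=float)
    n, k = y.shape
    if groups is None:
        groups = np.zeros(n)
    s, _ = _pooled_within_cov(y, np.asarray(groups))
    # double-centre the covariance and apply the trace formula
    sc = s - s.mean(axis=0, keepdims=True) - s.mean(axis=1, keepdims=True) + s.mean()
    denom = (k - 1) * float(np.sum(sc * sc))
    if denom <= 0:
        return 1.0 / (k - 1)
    eps = float(np.trace(sc)) ** 2 / denom
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def mauchly_test(scores: np.ndarray, groups: Optional[np.ndarray] = None) -> tuple[float, float]:
    """Mauchly's sphericity test on pooled within-group condition scores.

    Returns (W, p).  A singular contrast covariance returns (0, 0):
    sphericity maximally violated.
    """
    y = np.asarray(scores, dtype=float)
    n, k = y.shape
    if groups is None:
        groups = np.zeros(n)
    s, ne = _pooled_within_cov(y, np.asarray(groups))
    c = _contrast_matrix(k)
    a = c @ s @ c.T
    d = k - 1
    tr = np.trace(a)
    if tr <= 0:
        return 0.0, 0.0
    det = float(np.linalg.det(a))
    if det <= 0:
        return 0.0, 0.0
    w = det / (tr / d) ** d
    f = 1.0 - (2.0 * d * d + d + 2.0) / (6.0 * d * ne)
    chi2 = -f * ne * np.log(w)
    dof = d * (d + 1) // 2 - 1
    p = float(sps.chi2.sf(chi2, dof))
    return float(w), p


# ---------------------------------------------------------------------------
# mixed ANOVA


@dataclass
class _Design:
    scores: np.ndarray         # N × k participant-by-condition means
    groups: np.ndarray         # N group labels
    conditions: list[str]
    participants: list[str]


def _pivot(df: pd.DataFrame, participant: str, group: str, condition: str,
           value: str) -> _Design:
    agg = (df.groupby([participant, group, condition], sort=False)[value]
             .mean().reset_index())
    wide = agg.pivot_table(index=[participant, group], columns=condition,
                           values=value, sort=False)
    if wide.isna().any().any():
        missing = [f"{p}/{c}" for (p, _), row in wide.iterrows()
                   for c, v in row.items() if pd.isna(v)]
        raise MissingCellError(f"missing participant×condition cells: {missing}")
    conditions = list(wide.columns)
    participants = [p for p, _ in wide.index]
    groups = np.asarray([g for _, g in wide.index])
    return _Design(wide.to_numpy(dtype=float), groups, conditions, participants)


def mixed_rm_anova(
    df: pd.DataFrame,
    dv: Optional[str] = None,
    participant: str = "participant",
    group: str = "group",
    condition: str = "condition",
    value: str = "value",
    gg: str = "auto",
) -> pd.DataFrame:
    """Condition × Group mixed repeated-measures ANOVA for one DV.

    ``df`` is long format with one or more rows (trials) per participant ×
    condition; trials are averaged first.  Returns one row per effect
    (condition, group, condition × group) with F, dfs, p, η²p and the
    Greenhouse–Geisser ε (recorded when applied to the within-subject
    effects; ``gg`` ∈ {"auto", "always", "never"}).

    The sums-of-squares decomposition is verified internally
    (SS components must add to SS_total to 1e-8 relative).
    """
    if dv is not None and "metric" in df.columns:
        df = df[df["metric"] == dv]
        if df.empty:
            raise DataError(f"no rows for DV {dv!r}")
    design = _pivot(df, participant, group, condition, value)
    y = design.scores
    n, k = y.shape
    glabels, gidx = np.unique(design.groups, return_inverse=True)
    g = glabels.size
    if k < 2 or g < 1:
        raise DataError("need >= 2 conditions")
    counts = np.bincount(gidx)
    if counts.min() < 2:
        raise DataError("each group needs >= 2 participants")

    grand = y.mean()
    subj_mean = y.mean(axis=1)
    cond_mean = y.mean(axis=0)
    group_mean = np.array([y[gidx == i].mean() for i in range(g)])
    cell_mean = np.vstack([y[gidx == i].mean(axis=0) for i in range(g)])

    ss_total = float(((y - grand) ** 2).sum())
    ss_between_subj = float(k * ((subj_mean - grand) ** 2).sum())
    ss_group = float(k * (counts * (group_mean - grand) ** 2).sum())
    ss_subj_within = ss_between_subj - ss_group
    ss_cond = float(n * ((cond_mean - grand) ** 2).sum())
    ss_cells = float((counts[:, None] * (cell_mean - grand) ** 2).sum())
    ss_inter = ss_cells - ss_group - ss_cond
    ss_within = ss_total - ss_between_subj
    ss_error = ss_within - ss_cond - ss_inter

    # internal consistency check of the decomposition
    recon = ss_group + ss_subj_within + ss_cond + ss_inter + ss_error
    if abs(recon - ss_total) > 1e-8 * max(ss_total, 1.0):
        raise DataError("sums-of-squares decomposition failed to close")
    ss_inter = max(ss_inter, 0.0)
    ss_error = max(ss_error, 0.0)

    df_group, df_subj = g - 1, n - g
    df_cond = k - 1
    df_inter = (g - 1) * (k - 1)
    df_error = (k - 1) * (n - g)

    def f_ratio(ss_eff, df_eff, ss_err, df_err):
        ms_err = ss_err / df_err
        ms_eff = ss_eff / df_eff if df_eff > 0 else 0.0
        if ms_err == 0.0:
            if ms_eff == 0.0:
                return 0.0
            raise DegenerateDataError("zero error variance with a nonzero effect")
        return ms_eff / ms_err

    eps = gg_epsilon(y, design.groups) if gg != "never" else 1.0
    if gg == "auto":
        _, p_mauchly = mauchly_test(y, design.groups)
        apply_gg = p_mauchly < 0.05
    else:
        apply_gg = gg == "always"

    rows = []
    spec = [
        ("group", ss_group, df_group, ss_subj_within, df_subj, False),
        ("condition", ss_cond, df_cond, ss_error, df_error, True),
        ("condition:group", ss_inter, df_inter, ss_error, df_error, True),
    ]
    for effect, ss_eff, df1, ss_err, df2, within in spec:
        if df1 <= 0:
            continue
        F = f_ratio(ss_eff, df1, ss_err, df2)
        d1, d2, used_eps = float(df1), float(df2), np.nan
        if within and apply_gg:
            d1, d2, used_eps = eps * df1, eps * df2, eps
        p = float(sps.f.sf(F, d1, d2)) if F > 0 else 1.0
        rows.append({
            "effect": effect, "F": F, "df1": d1, "df2": d2, "p": p,
            "eta_p2": partial_eta_squared(F, d1, d2) if F > 0 else 0.0,
            "gg_epsilon": used_eps,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# post hocs and family orchestration


def _paired_p(a: np.ndarray, b: np.ndarray) -> float:
    d = a - b
    if np.allclose(d, 0.0):
        return 1.0
    p = float(sps.ttest_rel(a, b).pvalue)
    return 1.0 if np.isnan(p) else p


def posthoc_pairwise(
    df: pd.DataFrame,
    omnibus_significant: bool,
    participant: str = "participant",
    group: str = "group",
    condition: str = "condition",
    value: str = "value",
    compare: str = "within_conditions",
) -> pd.DataFrame:
    """Bonferroni-adjusted pairwise comparisons following a significant omnibus.

    ``within_conditions``: paired t-tests across condition pairs, per group
    (C(k,2) comparisons each, the Bonferroni multiplier).  ``between_groups``:
    independent t-tests between the two groups at each condition (multiplier
    = number of conditions).  Raw p-values are multiplied by the family size
    and capped at 1.  Refused when the omnibus effect is not significant.
    """
    if not omnibus_significant:
        raise PosthocRefusedError(
            "post hoc comparisons require a significant omnibus effect")
    design = _pivot(df, participant, group, condition, value)
    y, conds = design.scores, design.conditions
    rows = []
    if compare == "within_conditions":
        pairs = list(combinations(range(len(conds)), 2))
        m = len(pairs)
        for glabel in np.unique(design.groups):
            sel = design.groups == glabel
            for i, j in pairs:
                p_raw = _paired_p(y[sel, i], y[sel, j])
                rows.append({"group": glabel, "level_a": conds[i],
                             "level_b": conds[j], "p_raw": p_raw,
                             "p_adj": min(1.0, p_raw * m), "n_comparisons": m})
    elif compare == "between_groups":
        glabels = np.unique(design.groups)
        if glabels.size != 2:
            raise DataError("between_groups post hoc needs exactly 2 groups")
        m = len(conds)
        for j, cond in enumerate(conds):
            a = y[design.groups == glabels[0], j]
            b = y[design.groups == glabels[1], j]
            p_raw = float(sps.ttest_ind(a, b).pvalue)
            if np.isnan(p_raw):
                p_raw = 1.0
            rows.append({"group": f"{glabels[0]} vs {glabels[1]}",
                         "level_a": cond, "level_b": cond, "p_raw": p_raw,
                         "p_adj": min(1.0, p_raw * m), "n_comparisons": m})
    else:
        raise DataError(f"unknown comparison mode {compare!r}")
    return pd.DataFrame(rows)


def _drop_incomplete_participants(sub: pd.DataFrame, dv: str) -> pd.DataFrame:
    """Exclude participants missing a condition cell for this DV (e.g. after
    a failed trial) so the rest of the cohort remains analyzable."""
    conditions = set(sub["condition"].unique())
    have = sub.groupby("participant")["condition"].agg(set)
    incomplete = have[have != conditions].index
    if len(incomplete):
        import logging
        logging.getLogger("postprime").warning(
            "dropping %d participant(s) with incomplete cells for %s: %s",
            len(incomplete), dv, list(incomplete))
        sub = sub[~sub["participant"].isin(incomplete)]
    return sub


def analyze_cohort(
    metrics: pd.DataFrame,
    families: Optional[Sequence[FamilySpec]] = None,
    config: Optional[StatsConfig] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full statistical layer on a long-format cohort metric table.

    For each family, every DV gets a mixed ANOVA; the family's divided
    alpha (or sequential Holm over the family's condition/interaction
    p-values) decides significance, and significant omnibus effects trigger
    Bonferroni post hocs (within-group across conditions for condition
    effects; additionally between groups for interactions).
    Returns (anova_table, posthoc_table).
    """
    families = list(families) if families is not None else DEFAULT_FAMILIES
    config = config or StatsConfig()
    present = set(metrics["metric"].unique())
    anova_rows: list[pd.DataFrame] = []
    posthoc_rows: list[pd.DataFrame] = []
    for family in families:
        dvs = [dv for dv in family.dvs if dv in present]
        if not dvs:
            continue
        alpha_adj = holm_family_alpha(len(dvs))
        per_dv: dict[str, pd.DataFrame] = {}
        for dv in dvs:
            sub = metrics[metrics["metric"] == dv].dropna(subset=["value"])
            sub = _drop_incomplete_participants(sub, dv)
            try:
                table = mixed_rm_anova(sub, gg=config.gg)
            except DataError as exc:
                import logging
                logging.getLogger("postprime").warning(
                    "skipping DV %s: %s", dv, exc)
                continue
            table.insert(0, "dv", dv)
            table.insert(0, "family", family.name)
            per_dv[dv] = table
        if config.method == "holm_sequential":
            fam_p = [(dv, i, row.p) for dv, t in per_dv.items()
                     for i, row in t.iterrows() if row.effect != "group"]
            reject = holm_sequential([p for _, _, p in fam_p], config.alpha)
            decisions = {(dv, i): bool(r) for (dv, i, _), r in zip(fam_p, reject)}
            for dv, t in per_dv.items():
                t["alpha_adj"] = alpha_adj
                t["significant"] = [decisions.get((dv, i), row.p < alpha_adj)
                                    for i, row in t.iterrows()]
        else:
            for t in per_dv.values():
                t["alpha_adj"] = alpha_adj
                t["significant"] = t["p"] < alpha_adj
        for dv, t in per_dv.items():
            anova_rows.append(t)
            sub = metrics[metrics["metric"] == dv].dropna(subset=["value"])
            for _, row in t.iterrows():
                if not row.significant:
                    continue
                if row.effect == "condition":
                    ph = posthoc_pairwise(sub, True, compare="within_conditions")
                elif row.effect == "condition:group":
                    ph = posthoc_pairwise(sub, True, compare="between_groups")
                else:
                    continue
                ph.insert(0, "effect", row.effect)
                ph.insert(0, "dv", dv)
                ph.insert(0, "family", family.name)
                posthoc_rows.append(ph)
    anova = (pd.concat(anova_rows, ignore_index=True) if anova_rows
             else pd.DataFrame())
    posthoc = (pd.concat(posthoc_rows, ignore_index=True) if posthoc_rows
               else pd.DataFrame())
    return anova, posthoc
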