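"""Normality-gated group comparisons with nonparametric post hocs.

The policy mirrors common practice in quantitative-morphology papers: each
group is checked for normality and lognormality (Shapiro-Wilk on raw and
log-transformed values at alpha = 0.05); if every group passes at least one
of the two, the parametric branch is used (Student's t test, or one-way ANOVA
with Tukey's HSD), otherwise the rank branch (Mann-Whitney U, or
Kruskal-Wallis with Dunn's tie-corrected post hoc and Holm adjustment).
Summaries follow the branch: mean +/- SEM parametric, median and IQR
nonparametric. The selected branch and the gate outcomes are recorded in the
result for auditability.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["TestPolicy", "GroupComparison", "compare_two", "compare_many", "dunn_posthoc"]

EXACT_U_MAX_N = 8


@dataclass
class TestPolicy:
    __test__ = False  # dataclass, not a pytest case

    alpha: float = 0.05
    force_branch: str | None = None      # None (gate decides) | "parametric" | "nonparametric"
    posthoc_adjust: str = "holm"         # "holm" | "bonferroni" | "none"
    use_continuity: bool = False         # continuity correction in asymptotic U

    def __post_init__(self):
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.force_branch not in (None, "parametric", "nonparametric"):
            raise ValueError("force_branch must be None, 'parametric' or 'nonparametric'")
        if self.posthoc_adjust not in ("holm", "bonferroni", "none"):
            raise ValueError("posthoc_adjust must be 'holm', 'bonferroni' or 'none'")


@dataclass
class GroupComparison:
    """Outcome of a two- or many-group comparison with full policy record."""

    group_labels: list
    n: list
    summaries: pd.DataFrame          # per-group median/IQR or mean/SEM
    test_name: str
    statistic: float
    p_value: float
    branch: str                      # "parametric" | "nonparametric"
    normality: pd.DataFrame          # per-group Shapiro p on raw and log scale
    posthoc: pd.DataFrame | None = None
    notes: list = field(default_factory=list)


def _shapiro_p(x):
    if len(x) < 3 or np.ptp(x) == 0:
        return np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(stats.shapiro(x).pvalue)


def _normality_gate(groups, labels, alpha):
    rows = []
    all_pass = True
    for lab, g in zip(labels, groups):
        raw_p = _shapiro_p(g)
        log_p = _shapiro_p(np.log(g)) if np.all(g > 0) else np.nan
        passed = (not np.isnan(raw_p) and raw_p > alpha) or (not np.isnan(log_p) and log_p > alpha)
        if np.isnan(raw_p) and np.isnan(log_p):
            passed = False
        all_pass &= passed
        rows.append({"group": lab, "shapiro_p_raw": raw_p, "shapiro_p_log": log_p, "passed": passed})
    return pd.DataFrame(rows), all_pass


def _summaries(groups, labels, branch):
    rows = []
    for lab, g in zip(labels, groups):
        if branch == "parametric":
            rows.append({"group": lab, "n": len(g), "mean": np.mean(g),
                         "sem": stats.sem(g) if len(g) > 1 else np.nan})
        else:
            q1, med, q3 = np.percentile(g, [25, 50, 75])
            rows.append({"group": lab, "n": len(g), "median": med, "iqr_low": q1, "iqr_high": q3})
    return pd.DataFrame(rows)


def _as_groups(groups, labels):
    gs = [np.asarray(g, dtype=float).ravel() for g in groups]
    if any(len(g) == 0 for g in gs):
        raise ValueError("empty group")
    if labels is None:
        labels = [f"group{i + 1}" for i in range(len(gs))]
    return gs, list(labels)


def compare_two(a, b, policy: TestPolicy | None = None, labels=None) -> GroupComparison:
    """Two-group comparison: normality-gated t test or Mann-Whitney U.

    The U branch uses the exact null distribution when ``min(n) <= 8`` and
    there are no ties, otherwise the tie-corrected normal approximation.
    Groups smaller than 3 cannot be gated and force the nonparametric branch
    with a note.
    """
    policy = policy or TestPolicy()
    (a, b), labels = _as_groups([a, b], labels or ["A", "B"])
    notes = []
    normality, all_pass = _normality_gate([a, b], labels, policy.alpha)
    if policy.force_branch:
        branch = policy.force_branch
        notes.append(f"branch forced to {branch}")
    elif min(len(a), len(b)) < 3:
        branch = "nonparametric"
        notes.append("group with n < 3: normality gate skipped, nonparametric branch forced")
    else:
        branch = "parametric" if all_pass else "nonparametric"

    if branch == "parametric":
        res = stats.ttest_ind(a, b)
        stat, p, test_name = float(res.statistic), float(res.pvalue), "Student t (unpaired, two-sided)"
        if np.isnan(stat):  # zero variance in both groups
            stat, p = 0.0, 1.0
    else:
        pooled = np.concatenate([a, b])
        has_ties = len(np.unique(pooled)) < len(pooled)
        if min(len(a), len(b)) <= EXACT_U_MAX_N and not has_ties:
            res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            test_name = "Mann-Whitney U (exact)"
        else:
            if has_ties and min(len(a), len(b)) <= EXACT_U_MAX_N:
                notes.append("ties present: exact U unavailable, tie-corrected normal approximation used")
            res = stats.mannwhitneyu(
                a, b, alternative="two-sided", method="asymptotic",
                use_continuity=policy.use_continuity,
            )
            test_name = "Mann-Whitney U (asymptotic, tie-corrected)"
        stat, p = float(res.statistic), float(min(res.pvalue, 1.0))

    return GroupComparison(
        group_labels=labels, n=[len(a), len(b)],
        summaries=_summaries([a, b], labels, branch),
        test_name=test_name, statistic=stat, p_value=p, branch=branch,
        normality=normality, posthoc=None, notes=notes,
    )


def _tie_term(pooled):
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts**3 - counts))


def dunn_posthoc(groups, labels, adjust="holm") -> pd.DataFrame:
    """Dunn's rank-based pairwise z tests after Kruskal-Wallis.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j))
    with T = sum(t^3 - t) over tie groups; two-sided normal p-values with the
    requested multiplicity adjustment over all pairs.
    """
    pooled = np.concatenate(groups)
    N = len(pooled)
    ranks = stats.rankdata(pooled)
    splits = np.cumsum([len(g) for g in groups])[:-1]
    group_ranks = np.split(ranks, splits)
    rbar = [r.mean() for r in group_ranks]
    tie = _tie_term(pooled) / (12.0 * (N - 1)) if N > 1 else 0.0
    var0 = N * (N + 1) / 12.0 - tie
    rows = []
    for i, j in itertools.combinations(range(len(groups)), 2):
        ni, nj = len(groups[i]), len(groups[j])
        se = np.sqrt(var0 * (1.0 / ni + 1.0 / nj))
        z = (rbar[i] - rbar[j]) / se if se > 0 else 0.0
        rows.append({"group_1": labels[i], "group_2": labels[j], "z": z,
                     "p_unadjusted": 2.0 * stats.norm.sf(abs(z))})
    df = pd.DataFrame(rows)
    if adjust == "none":
        df["p_adjusted"] = df["p_unadjusted"]
    else:
        df["p_adjusted"] = multipletests(df["p_unadjusted"], method=adjust)[1]
    df["adjustment"] = adjust
    return df


def compare_many(groups, policy: TestPolicy | None = None, labels=None) -> GroupComparison:
    """>= 3 group comparison: ANOVA + Tukey HSD or Kruskal-Wallis + Dunn."""
    policy = policy or TestPolicy()
    if len(groups) < 3:
        raise ValueError("compare_many needs >= 3 groups (use compare_two)")
    groups, labels = _as_groups(groups, labels)
    notes = []
    normality, all_pass = _normality_gate(groups, labels, policy.alpha)
    if policy.force_branch:
        branch = policy.force_branch
        notes.append(f"branch forced to {branch}")
    elif min(len(g) for g in groups) < 3:
        branch = "nonparametric"
        notes.append("group with n < 3: normality gate skipped, nonparametric branch forced")
    else:
        branch = "parametric" if all_pass else "nonparametric"

    pairs = list(itertools.combinations(range(len(groups)), 2))
    if branch == "parametric":
        res = stats.f_oneway(*groups)
        stat, p, test_name = float(res.statistic), float(res.pvalue), "one-way ANOVA"
        tk = stats.tukey_hsd(*groups)
        posthoc = pd.DataFrame(
            [{"group_1": labels[i], "group_2": labels[j],
              "statistic": float(tk.statistic[i, j]), "p_adjusted": float(tk.pvalue[i, j]),
              "adjustment": "tukey-hsd"} for i, j in pairs]
        )
    else:
        pooled = np.concatenate(groups)
        if np.ptp(pooled) == 0:  # fully constant data: H is 0 by definition
            stat, p = 0.0, 1.0
        else:
            res = stats.kruskal(*groups)
            stat, p = float(res.statistic), float(res.pvalue)
        test_name = "Kruskal-Wallis H"
        posthoc = dunn_posthoc(groups, labels, adjust=policy.posthoc_adjust)
        if np.ptp(pooled) == 0:
            posthoc["p_adjusted"] = 1.0
            posthoc["p_unadjusted"] = 1.0

    return GroupComparison(
        group_labels=labels, n=[len(g) for g in groups],
        summaries=_summaries(groups, labels, branch),
        test_name=test_name, statistic=stat, p_value=p, branch=branch,
        normality=normality, posthoc=posthoc, notes=notes,
    )
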