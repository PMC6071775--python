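"""Multi-group statistical battery for morphometric measurements.

The comparison family follows a normality gate: Shapiro-Wilk per group
at alpha = 0.05; if any group rejects normality the nonparametric
branch (Kruskal-Wallis omnibus + Dunn's pairwise z-tests, summaries as
median +- IQR/2) is used, otherwise one-way ANOVA + Tukey HSD
(summaries as mean +- SD). Dunn's pairwise p-values are adjusted for
multiplicity (Holm by default; Bonferroni or none selectable); the
adjustment method is recorded in every result because it is not
standardized across software.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

SHAPIRO_ALPHA = 0.05

STAR_LEVELS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


def significance_stars(p: float) -> str:
    """Map a p-value to the conventional star annotation (ns above 0.05)."""
    for level, stars in STAR_LEVELS:
        if p <= level:
            return stars
    return "ns"


@dataclass
class GroupComparison:
    """Result of a multi-group comparison with a post hoc matrix.

    ``posthoc`` is a symmetric DataFrame of pairwise adjusted p-values
    with 1.0 on the diagonal; ``summaries`` holds per-group location and
    spread in the family's convention.
    """

    group_names: list[str]
    n: dict[str, int]
    test_used: str  # "kruskal_dunn" | "anova_tukey"
    omnibus_p: float
    posthoc: pd.DataFrame
    summaries: dict[str, tuple[float, float]]
    adjustment: str = ""
    qc: dict = field(default_factory=dict)

    def pair_p(self, a: str, b: str) -> float:
        return float(self.posthoc.loc[a, b])

    def stars(self, a: str, b: str) -> str:
        return significance_stars(self.pair_p(a, b))


def _as_groups(groups: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    out = {str(k): np.asarray(v, dtype=float).ravel() for k, v in groups.items()}
    if any(v.size == 0 for v in out.values()):
        raise ValueError("empty group")
    return out


def median_iqr2(values) -> tuple[float, float]:
    """Median and half the interquartile range (linear-interp quartiles)."""
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("empty input")
    q1, med, q3 = np.percentile(v, [25, 50, 75])  # type-7 linear interpolation
    return float(med), float((q3 - q1) / 2.0)


def normality_gate(groups: dict[str, np.ndarray], alpha: float = SHAPIRO_ALPHA) -> str:
    """Choose the test family by per-group Shapiro-Wilk at ``alpha``."""
    groups = _as_groups(groups)
    for name, v in groups.items():
        if v.size < 3:
            raise ValueError(f"group {name!r} has n < 3; cannot test normality")
        if np.ptp(v) == 0:
            return "kruskal_dunn"  # degenerate: certainly not Gaussian
        if sps.shapiro(v).pvalue < alpha:
            return "kruskal_dunn"
    return "anova_tukey"


def kruskal_dunn(groups: dict[str, np.ndarray], adjustment: str = "holm") -> GroupComparison:
    """Kruskal-Wallis omnibus with Dunn's pairwise post hoc z-tests.

    Dunn's statistic compares mean pooled ranks with a tie-corrected
    variance; two-sided normal p-values are multiplicity-adjusted by
    ``adjustment`` ("holm", "bonferroni" or "none").
    """
    groups = _as_groups(groups)
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need >= 2 groups")
    pooled = np.concatenate([groups[g] for g in names])
    if np.ptp(pooled) == 0:
        # all observations identical everywhere: nothing to distinguish
        ph = pd.DataFrame(np.ones((len(names), len(names))), index=names, columns=names)
        return GroupComparison(
            names, {g: groups[g].size for g in names}, "kruskal_dunn", 1.0, ph,
            {g: median_iqr2(groups[g]) for g in names}, adjustment,
        )
    omnibus = sps.kruskal(*[groups[g] for g in names]).pvalue

    ranks = sps.rankdata(pooled)
    n_tot = pooled.size
    offsets = np.cumsum([0] + [groups[g].size for g in names])
    mean_rank = {
        g: ranks[offsets[i]: offsets[i + 1]].mean() for i, g in enumerate(names)
    }
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts))
    var_base = n_tot * (n_tot + 1) / 12.0 - tie_term / (12.0 * (n_tot - 1))

    pairs, raw = [], []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            se = np.sqrt(var_base * (1.0 / groups[a].size + 1.0 / groups[b].size))
            z = (mean_rank[a] - mean_rank[b]) / se if se > 0 else 0.0
            pairs.append((a, b))
            raw.append(2.0 * sps.norm.sf(abs(z)))
    if adjustment == "none":
        adj = np.asarray(raw)
    else:
        adj = multipletests(raw, method=adjustment)[1]
    ph = pd.DataFrame(np.ones((len(names), len(names))), index=names, columns=names)
    for (a, b), p in zip(pairs, adj):
        ph.loc[a, b] = ph.loc[b, a] = min(float(p), 1.0)
    qc = {g: {"bimodality_coefficient": bimodality_coefficient(groups[g])} for g in names}
    return GroupComparison(
        names, {g: groups[g].size for g in names}, "kruskal_dunn", float(omnibus),
        ph, {g: median_iqr2(groups[g]) for g in names}, adjustment, qc,
    )


def anova_tukey(groups: dict[str, np.ndarray]) -> GroupComparison:
    """One-way ANOVA omnibus with Tukey HSD pairwise adjusted p-values."""
    groups = _as_groups(groups)
    names = list(groups)
    if len(names) < 2 or any(groups[g].size < 2 for g in names):
        raise ValueError("need >= 2 groups with n >= 2 each")
    summaries = {
        g: (float(groups[g].mean()), float(groups[g].std(ddof=1))) for g in names
    }
    pooled = np.concatenate([groups[g] for g in names])
    ph = pd.DataFrame(np.ones((len(names), len(names))), index=names, columns=names)
    if np.ptp(pooled) == 0:
        return GroupComparison(
            names, {g: groups[g].size for g in names}, "anova_tukey", 1.0, ph,
            summaries, "tukey_hsd",
        )
    if all(np.ptp(groups[g]) == 0 for g in names):
        # between-group differences with zero within-group variance:
        # F is unbounded; report the limiting p
        omnibus = 0.0
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                p = 1.0 if summaries[names[i]][0] == summaries[names[j]][0] else 0.0
                ph.iloc[i, j] = ph.iloc[j, i] = p
        return GroupComparison(
            names, {g: groups[g].size for g in names}, "anova_tukey", omnibus,
            ph, summaries, "tukey_hsd",
        )
    omnibus = sps.f_oneway(*[groups[g] for g in names]).pvalue
    hsd = sps.tukey_hsd(*[groups[g] for g in names])
    for i in range(len(names)):
        for j in range(len(names)):
            if i != j:
                ph.iloc[i, j] = float(hsd.pvalue[i, j])
    return GroupComparison(
        names, {g: groups[g].size for g in names}, "anova_tukey", float(omnibus),
        ph, summaries, "tukey_hsd",
    )


def compare_groups(groups: dict[str, np.ndarray], adjustment: str = "holm") -> GroupComparison:
    """Normality-gated comparison: the full battery in one call."""
    family = normality_gate(groups)
    if family == "kruskal_dunn":
        return kruskal_dunn(groups, adjustment=adjustment)
    return anova_tukey(groups)


def bimodality_coefficient(values) -> float:
    """Sarle's bimodality coefficient, a descriptive multimodality cue.

    BC = (g1^2 + 1) / (g2 + 3(n-1)^2 / ((n-2)(n-3))) with sample
    skewness g1 and excess kurtosis g2; values above ~0.555 (the uniform
    distribution's BC) hint at bimodality. Reported as QC only — no
    inferential claim is attached.
    """
    v = np.asarray(values, dtype=float).ravel()
    n = v.size
    if n < 4 or np.ptp(v) == 0:
        return float("nan")
    g1 = sps.skew(v, bias=False)
    g2 = sps.kurtosis(v, bias=False)  # excess kurtosis
    return float((g1 ** 2 + 1.0) / (g2 + 3.0 * (n - 1) ** 2 / ((n - 2) * (n - 3))))


def comparison_to_dict(c: GroupComparison) -> dict:
    """JSON-serializable form of a GroupComparison."""
    return {
        "test_used": c.test_used,
        "adjustment": c.adjustment,
        "omnibus_p": c.omnibus_p,
        "n": c.n,
        "summaries": {g: list(s) for g, s in c.summaries.items()},
        "posthoc": {a: {b: float(c.posthoc.loc[a, b]) for b in c.group_names}
                    for a in c.group_names},
        "stars": {f"{a}|{b}": c.stars(a, b)
                  for i, a in enumerate(c.group_names)
                  for b in c.group_names[i + 1:]},
        "qc": c.qc,
    }
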