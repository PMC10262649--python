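"""Group-comparison harness for cohort analyses.

Two statistical schedules are provided, matching how Barnes-maze cohorts
are conventionally compared:

* **Per-day nonparametric comparisons** of strategy usage and network
  measures: Wilcoxon rank-sum for two groups, Kruskal–Wallis for three or
  more (with rank-sum post hoc gated on significance), all Bonferroni
  corrected within the family of days.  Effect size is ``r = |z| / sqrt(N)``.
* **Mixed-design two-way ANOVA** (between: group; within: day or hole) for
  conventional features and probe dwell profiles, with partial eta squared
  ``eta_p^2 = SS_effect / (SS_effect + SS_error)`` and Tukey's HSD post hoc
  gated on significance.  The ANOVA itself delegates to pingouin.

Rank-sum z uses the tie-corrected normal approximation with continuity
correction; p-values are exact (via the Mann–Whitney null distribution)
for small tie-free samples.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger("mazenet")

__all__ = [
    "ComparisonResult",
    "ranksum",
    "per_day_ranksum",
    "mixed_anova_eta",
]

ALPHA = 0.05            # significance level before Bonferroni correction
EXACT_MAX_N = 10        # exact rank-sum p for samples up to this size


@dataclass(frozen=True)
class ComparisonResult:
    test: str
    statistic: float
    p_raw: float
    p_adjusted: float
    effect_kind: str            # "r" | "eta_p_sq" | ""
    effect_size: float
    groups: Tuple[str, ...]
    stratum: str = ""           # e.g. "day 3", "hole +30"

    def significant(self, alpha: float = ALPHA) -> bool:
        return self.p_adjusted < alpha

    def as_dict(self) -> dict:
        return {
            "test": self.test, "statistic": self.statistic,
            "p_raw": self.p_raw, "p_adjusted": self.p_adjusted,
            "effect_kind": self.effect_kind, "effect_size": self.effect_size,
            "groups": "|".join(self.groups), "stratum": self.stratum,
        }


def _bonferroni(p: float, m: int) -> float:
    return min(1.0, p * m)


def ranksum(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float, float]:
    """Wilcoxon rank-sum comparison of two independent samples.

    Returns ``(z, p, r)`` where ``z`` is the tie-corrected,
    continuity-corrected normal deviate of the rank sum, ``p`` is two-sided
    (exact when both samples have at most 10 observations and no ties), and
    ``r = |z| / sqrt(n1 + n2)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    n = n1 + n2
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0

    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = np.sum(tie_counts ** 3 - tie_counts) / (n * (n - 1.0))
    var = n1 * n2 / 12.0 * (n + 1.0 - tie_term)
    if var <= 0:  # every observation identical
        return 0.0, 1.0, 0.0
    diff = u1 - mu
    z = (diff - 0.5 * np.sign(diff)) / math.sqrt(var) if diff != 0 else 0.0

    has_ties = np.any(tie_counts > 1)
    if max(n1, n2) <= EXACT_MAX_N and not has_ties:
        p = float(sps.mannwhitneyu(x, y, alternative="two-sided",
                                   method="exact").pvalue)
    else:
        p = float(2.0 * sps.norm.sf(abs(z)))
    return float(z), min(p, 1.0), abs(z) / math.sqrt(n)


def per_day_ranksum(data: pd.DataFrame, value: str = "value",
                    group: str = "group", day: str = "day",
                    alpha: float = ALPHA,
                    min_per_group: int = 2) -> List[ComparisonResult]:
    """Per-day nonparametric comparison of one measure between groups.

    ``data`` is tidy: one row per mouse per day with columns ``group``,
    ``day``, ``value``.  Two groups get a rank-sum per day; three or more
    get Kruskal–Wallis per day with pairwise rank-sum post hoc only where
    the Kruskal–Wallis survives correction.  Bonferroni families: the days
    for the primary tests; days x pairs for the post hoc.
    """
    groups = sorted(data[group].unique())
    days = sorted(data[day].unique())
    m_days = len(days)
    results: List[ComparisonResult] = []
    for d in days:
        sub = data[data[day] == d]
        samples = {g: sub.loc[sub[group] == g, value].dropna().to_numpy()
                   for g in groups}
        if any(len(s) < min_per_group for s in samples.values()):
            logger.warning("day %s skipped: a group has <%d observations",
                           d, min_per_group)
            continue
        if len(groups) == 2:
            z, p, r = ranksum(samples[groups[0]], samples[groups[1]])
            results.append(ComparisonResult(
                "wilcoxon_ranksum", z, p, _bonferroni(p, m_days),
                "r", r, tuple(groups), f"day {d}"))
        else:
            stat, p = sps.kruskal(*[samples[g] for g in groups])
            kw = ComparisonResult(
                "kruskal_wallis", float(stat), float(p),
                _bonferroni(float(p), m_days), "", float("nan"),
                tuple(groups), f"day {d}")
            results.append(kw)
            if kw.significant(alpha):
                pairs = [(a, b) for i, a in enumerate(groups)
                         for b in groups[i + 1:]]
                m_post = m_days * len(pairs)
                for a, b in pairs:
                    z, p2, r = ranksum(samples[a], samples[b])
                    results.append(ComparisonResult(
                        "wilcoxon_ranksum_posthoc", z, p2,
                        _bonferroni(p2, m_post), "r", r, (a, b), f"day {d}"))
    return results


def mixed_anova_eta(data: pd.DataFrame, dv: str = "value",
                    within: str = "day", subject: str = "mouse",
                    between: str = "group",
                    alpha: float = ALPHA) -> List[ComparisonResult]:
    """Mixed-design two-way ANOVA with eta_p^2 and gated Tukey HSD.

    Between-subject factor: ``between`` (group); within-subject factor:
    ``within`` (day or hole).  Returns one result per effect (between,
    within, interaction) plus Tukey HSD pairwise comparisons of the groups
    when the between main effect or the interaction is significant.
    """
    import pingouin as pg

    counts = data.groupby([subject])[within].nunique()
    if counts.nunique() != 1:
        bad = counts[counts != counts.mode().iloc[0]].index.tolist()
        raise ValueError(f"unbalanced within-factor levels for subjects {bad}")

    aov = pg.mixed_anova(data=data, dv=dv, within=within,
                         subject=subject, between=between)
    results: List[ComparisonResult] = []
    name_map = {between: "between", within: "within",
                "Interaction": "interaction"}
    for _, row in aov.iterrows():
        label = name_map.get(row["Source"], str(row["Source"]))
        results.append(ComparisonResult(
            f"mixed_anova_{label}", float(row["F"]), float(row["p_unc"]),
            float(row["p_unc"]), "eta_p_sq", float(row["np2"]),
            tuple(sorted(data[between].unique())), label))

    sig = {r.stratum: r.significant(alpha) for r in results}
    if sig.get("between") or sig.get("interaction"):
        tukey = pg.pairwise_tukey(data=data, dv=dv, between=between)
        for _, row in tukey.iterrows():
            results.append(ComparisonResult(
                "tukey_hsd", float(row["T"]), float(row["p_tukey"]),
                float(row["p_tukey"]), "", float("nan"),
                (str(row["A"]), str(row["B"])), "posthoc"))
    return results


def results_table(results: Sequence[ComparisonResult]) -> pd.DataFrame:
    """Flatten comparison results to a DataFrame for CSV export."""
    return pd.DataFrame([r.as_dict() for r in results])
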