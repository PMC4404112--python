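"""Cohort-level statistics: matched-pair construction, trajectory group
comparisons (one-way ANOVA with Student–Newman–Keuls post hoc,
Kruskal–Wallis, Holm–Šidák), the cytokine age×time linear model, and
univariate clinical-table tests (Fisher's exact, Wilcoxon two-sample).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

from .dataio import CytokinePanel, ClinicalCountTable, InsufficientDataError, SampleMeta

logger = logging.getLogger("traumadfr")

__all__ = [
    "MatchedPairSet", "PairwiseComparison", "GroupComparison", "GlmResult",
    "match_pairs", "anova_newman_keuls", "kruskal_wallis", "holm_sidak",
    "cytokine_glm", "contingency_stats", "wilcoxon_two_sample",
]


# ---------------------------------------------------------------------------
# Matched pairs


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    gender: str
    ais: tuple[int, ...]
    timepoints: frozenset
    survived_28d: bool


@dataclass(frozen=True)
class MatchedPairSet:
    pairs: tuple[tuple[str, str], ...]  # (aged patient_id, young patient_id)
    costs: tuple[float, ...]  # summed |ΔAIS| per pair
    unmatched_aged: tuple[str, ...]
    unmatched_young: tuple[str, ...]


def _patient_records(metadata: Sequence[SampleMeta], age_group: str
                     ) -> list[PatientRecord]:
    by_pid: dict[str, list[SampleMeta]] = {}
    for m in metadata:
        if m.age_group == age_group:
            by_pid.setdefault(m.patient_id, []).append(m)
    out = []
    for pid, ms in sorted(by_pid.items()):
        tps = frozenset(m.timepoint_days for m in ms if m.timepoint_days is not None)
        out.append(PatientRecord(pid, ms[0].gender or "", ms[0].ais, tps,
                                 bool(ms[0].survived_28d)))
    return out


def _ais_cost(a: tuple[int, ...], b: tuple[int, ...]) -> float:
    n = max(len(a), len(b))
    a = tuple(a) + (0,) * (n - len(a))
    b = tuple(b) + (0,) * (n - len(b))
    return float(sum(abs(x - y) for x, y in zip(a, b)))


def match_pairs(metadata: Sequence[SampleMeta]) -> MatchedPairSet:
    """Greedily pair aged with young patients under hard matching criteria.

    A candidate pair requires exact gender match, exact 28-day survival
    match, and identical sampled-timepoint sets; among candidates the summed
    per-region |ΔAIS| is minimized greedily (pairs taken in ascending cost,
    ties broken by ascending patient ids). Unmatched patients are listed.
    """
    aged = _patient_records(metadata, "aged")
    young = _patient_records(metadata, "young")
    candidates = []
    for a in aged:
        for y in young:
            if (a.gender == y.gender and a.survived_28d == y.survived_28d
                    and a.timepoints == y.timepoints):
                candidates.append((_ais_cost(a.ais, y.ais), a.patient_id, y.patient_id))
    candidates.sort()
    used_a: set[str] = set()
    used_y: set[str] = set()
    pairs, costs = [], []
    for cost, pid_a, pid_y in candidates:
        if pid_a in used_a or pid_y in used_y:
            continue
        used_a.add(pid_a)
        used_y.add(pid_y)
        pairs.append((pid_a, pid_y))
        costs.append(cost)
    logger.info("matched %d pairs (%d aged, %d young unmatched)",
                len(pairs), len(aged) - len(pairs), len(young) - len(pairs))
    return MatchedPairSet(
        tuple(pairs), tuple(costs),
        tuple(a.patient_id for a in aged if a.patient_id not in used_a),
        tuple(y.patient_id for y in young if y.patient_id not in used_y),
    )


# ---------------------------------------------------------------------------
# Group comparisons


@dataclass(frozen=True)
class PairwiseComparison:
    group_a: str
    group_b: str
    statistic: float  # q (SNK) or raw p (Holm–Šidák input)
    reject: bool
    adjusted_p: float | None = None


@dataclass(frozen=True)
class GroupComparison:
    groups: tuple[str, ...]
    omnibus_statistic: float
    omnibus_p: float
    method: str  # "newman-keuls" | "holm-sidak" | "kruskal-wallis"
    pairwise: tuple[PairwiseComparison, ...] = ()
    alpha: float = 0.05


def anova_newman_keuls(groups: Mapping[str, Sequence[float]],
                       alpha: float = 0.05) -> GroupComparison:
    """One-way ANOVA omnibus plus Student–Newman–Keuls pairwise comparisons.

    SNK tests each pair with the studentized-range statistic
    ``q = |x̄_a − x̄_b| / sqrt(MSW/2 · (1/n_a + 1/n_b))`` against the
    critical value for the number of ordered means the pair spans, stepping
    down from the widest range; a non-rejected stretch blocks every
    comparison nested inside it. At k=2 the decision coincides with the
    pooled two-sample t-test at the same alpha.
    """
    names = sorted(groups)
    data = [np.asarray(groups[g], dtype=float) for g in names]
    if len(names) < 2 or any(d.size < 2 for d in data):
        raise InsufficientDataError("SNK needs >=2 groups with >=2 observations each")
    f_stat, p_omni = stats.f_oneway(*data)
    n = np.array([d.size for d in data])
    df_within = int(n.sum() - len(data))
    msw = sum(((d - d.mean()) ** 2).sum() for d in data) / df_within
    if msw <= 0:
        # all observations identical within groups
        if all(np.allclose(d.mean(), data[0].mean()) for d in data):
            pw = tuple(PairwiseComparison(names[i], names[j], 0.0, False)
                       for i, j in itertools.combinations(range(len(names)), 2))
            return GroupComparison(tuple(names), 0.0, 1.0, "newman-keuls", pw, alpha)
        raise ValueError("degenerate within-group variance with unequal means")

    order = np.argsort([d.mean() for d in data])  # ascending means
    means = np.array([data[i].mean() for i in order])
    sizes = n[order]
    k = len(names)

    # blocked[i][j]: comparison of ordered means i<j suppressed by step-down rule
    results: dict[tuple[int, int], tuple[float, bool]] = {}
    blocked = np.zeros((k, k), dtype=bool)
    for span in range(k, 1, -1):  # widest ranges first
        for i in range(0, k - span + 1):
            j = i + span - 1
            q = (means[j] - means[i]) / np.sqrt(
                msw / 2 * (1 / sizes[i] + 1 / sizes[j]))
            q_crit = stats.studentized_range.ppf(1 - alpha, span, df_within)
            reject = bool(q > q_crit) and not blocked[i, j]
            results[(i, j)] = (float(q), reject)
            if not reject:  # block all nested comparisons
                for ii in range(i, j + 1):
                    for jj in range(ii + 1, j + 1):
                        blocked[ii, jj] = True
    pw = []
    for (i, j), (q, reject) in sorted(results.items()):
        a, b = names[order[i]], names[order[j]]
        pw.append(PairwiseComparison(*sorted((a, b)), statistic=q, reject=reject))
    return GroupComparison(tuple(names), float(f_stat), float(p_omni),
                           "newman-keuls", tuple(pw), alpha)


def kruskal_wallis(groups: Mapping[str, Sequence[float]]) -> GroupComparison:
    """Rank-based Kruskal–Wallis H with tie correction, chi-square reference."""
    names = sorted(groups)
    if len(names) < 2:
        raise InsufficientDataError("Kruskal-Wallis needs >=2 groups")
    data = [np.asarray(groups[g], dtype=float) for g in names]
    if all(np.array_equal(d, data[0]) for d in data):
        return GroupComparison(tuple(names), 0.0, 1.0, "kruskal-wallis")
    h, p = stats.kruskal(*data)
    return GroupComparison(tuple(names), float(h), float(p), "kruskal-wallis")


def holm_sidak(p_values: Sequence[float], alpha: float = 0.05
               ) -> tuple[np.ndarray, np.ndarray]:
    """Step-down Holm–Šidák: ``(reject_flags, adjusted_p)``.

    Sorted p_(j) is compared to 1 − (1−α)^(1/(m−j+1)); adjusted values are
    monotone non-decreasing in the sorted order and capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return np.zeros(0, dtype=bool), p.copy()
    reject, adj, *_ = multipletests(p, alpha=alpha, method="holm-sidak")
    return reject, adj


# ---------------------------------------------------------------------------
# Cytokine GLM


@dataclass(frozen=True)
class FactorEffect:
    name: str
    f_statistic: float
    p_value: float
    df: int


@dataclass(frozen=True)
class GlmResult:
    analyte: str
    effects: tuple[FactorEffect, ...]
    n_obs: int
    model: str

    def effect(self, name: str) -> FactorEffect:
        for e in self.effects:
            if e.name == name:
                return e
        raise KeyError(name)


def cytokine_glm(panel: CytokinePanel, analyte: str,
                 include_interaction: bool = False) -> GlmResult:
    """Two-factor linear model of log concentration on age group and time.

    Concentrations are log-transformed (half the smallest positive value is
    substituted for exact zeros); age group and timepoint enter as
    categorical factors; factor significance uses type-II F tests, which
    tolerate the unbalanced designs produced by dropout.
    """
    df = panel.to_frame()
    df = df[df["analyte"] == analyte].copy()
    if df.empty:
        raise InsufficientDataError(f"no observations for analyte {analyte!r}")
    if df["age_group"].nunique() < 2 or df["timepoint_hours"].nunique() < 2:
        raise InsufficientDataError("need >=2 age groups and >=2 timepoints")
    positive = df.loc[df["concentration"] > 0, "concentration"]
    if positive.empty:
        raise InsufficientDataError("all concentrations are zero")
    eps = positive.min() / 2
    df["log_conc"] = np.log(df["concentration"].clip(lower=eps))
    formula = "log_conc ~ C(age_group) + C(timepoint_hours)"
    if include_interaction:
        formula += " + C(age_group):C(timepoint_hours)"
    fit = ols(formula, data=df).fit()
    table = anova_lm(fit, typ=2)
    effects = []
    rename = {"C(age_group)": "age_group", "C(timepoint_hours)": "time",
              "C(age_group):C(timepoint_hours)": "age_group:time"}
    for term, row in table.iterrows():
        if term == "Residual":
            continue
        effects.append(FactorEffect(rename.get(term, term), float(row["F"]),
                                    float(row["PR(>F)"]), int(row["df"])))
    return GlmResult(analyte, tuple(effects), int(len(df)), formula)


# ---------------------------------------------------------------------------
# Clinical tables


@dataclass(frozen=True)
class ContingencyResult:
    row: str
    proportions: tuple[float, float]  # per group, as fractions
    percents: tuple[float, float]  # printed precision (one decimal)
    fisher_p: float
    odds_ratio: float


def contingency_stats(table: ClinicalCountTable, row: str,
                      percent_decimals: int = 1) -> ContingencyResult:
    """Per-group proportions plus Fisher's exact test of one category.

    The 2×2 is (row vs all-other-outcomes) × group, using the group totals as
    column sums; the exact p is the two-sided hypergeometric-enumeration
    value; the odds ratio applies the Haldane +0.5 correction when any cell
    is zero.
    """
    try:
        i = table.row_labels.index(row)
    except ValueError:
        raise KeyError(f"row {row!r} not in table") from None
    a, b = (int(x) for x in table.counts[i])
    ta, tb = table.group_totals
    props = (a / ta, b / tb)
    percents = tuple(round(100 * p, percent_decimals) for p in props)
    tab = np.array([[a, ta - a], [b, tb - b]])
    _, p = stats.fisher_exact(tab, alternative="two-sided")
    if np.any(tab == 0):
        tab = tab + 0.5
    odds = float(tab[0, 0] * tab[1, 1] / (tab[0, 1] * tab[1, 0]))
    return ContingencyResult(row, props, percents, float(p), odds)


@dataclass(frozen=True)
class RankSumResult:
    statistic: float  # rank sum W of the first sample
    p_value: float
    exact: bool
    alternative: str


def wilcoxon_two_sample(x: Sequence[float], y: Sequence[float],
                        alternative: str = "two-sided") -> RankSumResult:
    """Wilcoxon rank-sum test.

    Exact p by enumeration for combined n ≤ 12 (and no ties); normal
    approximation with tie and continuity correction otherwise. The reported
    statistic is the rank sum of ``x``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise InsufficientDataError("both samples need >=1 observation")
    combined = np.concatenate([x, y])
    has_ties = np.unique(combined).size < combined.size
    exact = (x.size + y.size) <= 12 and not has_ties
    method = "exact" if exact else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method,
                             use_continuity=True)
    w = float(res.statistic + x.size * (x.size + 1) / 2)  # U -> rank sum
    return RankSumResult(w, float(res.pvalue), exact, alternative)
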