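"""Diagnostic-validity statistics for the six torsobarographic indices.

Severity groups (Cobb < 10, 10-20, 20-40 deg) are compared per index with
the Kruskal-Wallis omnibus test (tie-corrected, chi-square reference),
Bonferroni-Holm adjusted across the six indices; indices whose adjusted
omnibus p falls below 0.05 get Dunn pairwise post hoc tests (Holm-adjusted
across the three pairs) with rank effect sizes ES = z / sqrt(N) for the
two compared groups; each index is also Spearman-correlated with the Cobb
angle.  The rank statistics are implemented directly (midranks throughout)
so they can be cross-checked against independent references.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2, norm, rankdata
from scipy.stats import t as t_dist

from .errors import UndefinedIndexError, ValidationError
from .indices import INDEX_NAMES, IndexSet

__all__ = [
    "SEVERITIES",
    "SubjectRecord",
    "GroupComparison",
    "CorrelationResult",
    "cluster_by_cobb",
    "kruskal_wallis",
    "dunn_posthoc",
    "holm_adjust",
    "effect_size",
    "spearman",
    "validity_analysis",
]

SEVERITIES = ("none", "mild", "moderate")


@dataclass
class SubjectRecord:
    id: str
    index_set: IndexSet
    cobb_angle_deg: float
    severity: str = ""

    def __post_init__(self) -> None:
        expected = cluster_by_cobb(self.cobb_angle_deg)
        if not self.severity:
            self.severity = expected
        elif self.severity != expected:
            raise ValidationError(
                f"severity {self.severity!r} inconsistent with Cobb "
                f"{self.cobb_angle_deg} deg (expected {expected!r})"
            )


@dataclass
class GroupComparison:
    index: str
    group_n: dict
    group_mean: dict
    group_sd: dict
    h_statistic: float
    p_raw: float
    p_adjusted: float
    pairwise: list = field(default_factory=list)  # (pair, z, p_raw, p_adj, es, es_cat)
    n_excluded: int = 0


@dataclass
class CorrelationResult:
    index: str
    rho: float
    p: float
    category: str
    n: int


def cluster_by_cobb(cobb: float) -> str:
    """Severity group from the Cobb angle: none (<10), mild [10, 20),
    moderate [20, 40).  Severe curves (>= 40 deg) are outside the studied
    range and rejected."""
    if cobb < 0:
        raise ValidationError(f"negative Cobb angle {cobb}")
    if cobb < 10:
        return "none"
    if cobb < 20:
        return "mild"
    if cobb < 40:
        return "moderate"
    raise ValidationError(f"Cobb angle {cobb} deg >= 40 (severe scoliosis not studied)")


def _pooled_ranks(groups):
    values = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    ranks = rankdata(values)  # midranks
    sizes = [len(g) for g in groups]
    edges = np.cumsum([0] + sizes)
    per_group = [ranks[edges[k] : edges[k + 1]] for k in range(len(groups))]
    return values, ranks, per_group


def _tie_term(values: np.ndarray) -> float:
    _, counts = np.unique(values, return_counts=True)
    return float((counts**3 - counts).sum())


def kruskal_wallis(groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValidationError("need >= 2 non-empty groups")
    n_total = sum(len(g) for g in groups)
    if n_total < 3:
        raise ValidationError("need >= 3 observations in total")
    values, _, per_group = _pooled_ranks(groups)
    if np.ptp(values) == 0:
        return 0.0, 1.0
    h = 12.0 / (n_total * (n_total + 1)) * sum(
        len(r) * (r.mean() - (n_total + 1) / 2.0) ** 2 for r in per_group
    )
    correction = 1.0 - _tie_term(values) / (n_total**3 - n_total)
    h /= correction
    p = float(chi2.sf(h, df=len(groups) - 1))
    return float(h), p


def dunn_posthoc(groups) -> list:
    """Dunn pairwise rank tests: list of ((a, b), z, p_raw) over group
    index pairs; z = (mean rank a - mean rank b) / SE with tie correction."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValidationError("need >= 2 non-empty groups")
    n_total = sum(len(g) for g in groups)
    values, _, per_group = _pooled_ranks(groups)
    tie = _tie_term(values)
    out = []
    for a, b in itertools.combinations(range(len(groups)), 2):
        var = (n_total * (n_total + 1) / 12.0 - tie / (12.0 * (n_total - 1))) * (
            1.0 / len(groups[a]) + 1.0 / len(groups[b])
        )
        if var <= 0:
            z = 0.0
        else:
            z = float((per_group[a].mean() - per_group[b].mean()) / math.sqrt(var))
        p = float(2 * norm.sf(abs(z)))
        out.append(((a, b), z, p))
    return out


def holm_adjust(pvals) -> np.ndarray:
    """Bonferroni-Holm step-down adjustment, returned in input order."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 0.0
    for k, idx in enumerate(order):
        running = max(running, (m - k) * p[idx])
        adjusted[idx] = min(running, 1.0)
    return adjusted


_ES_BANDS = ((0.5, "large"), (0.3, "medium"), (0.1, "small"))


def effect_size(z: float, n: int) -> tuple[float, str]:
    """Rank effect size ES = z / sqrt(N) with Cohen's categorization of
    |ES| (small [0.1, 0.3), medium [0.3, 0.5), large >= 0.5)."""
    if n < 1:
        raise ValidationError("sample count must be >= 1")
    es = z / math.sqrt(n)
    for cut, label in _ES_BANDS:
        if abs(es) >= cut:
            return es, label
    return es, "negligible"


_RHO_BANDS = ((0.8, "strong"), (0.6, "good"), (0.3, "moderate"))


def spearman(x, y) -> tuple[float, float, str]:
    """Spearman rank correlation with midrank ties, two-sided t-based p,
    and the clinical category of |rho| (poor < 0.3 <= moderate < 0.6 <=
    good < 0.8 <= strong)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValidationError("need two equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedIndexError("correlation undefined for a constant vector")
    rx, ry = rankdata(x), rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = len(x)
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        p = float(2 * t_dist.sf(abs(t), df=n - 2))
    category = "poor"
    for cut, label in _RHO_BANDS:
        if abs(rho) >= cut:
            category = label
            break
    return rho, p, category


def _index_values(records, name):
    """Values per severity group, skipping failed/undefined subjects."""
    per_group = {s: [] for s in SEVERITIES}
    excluded = 0
    cobbs, values = [], []
    for r in records:
        v = getattr(r.index_set, name)
        if v is None or not np.isfinite(v):
            excluded += 1
            continue
        per_group[r.severity].append(float(v))
        cobbs.append(r.cobb_angle_deg)
        values.append(float(v))
    return per_group, excluded, np.asarray(cobbs), np.asarray(values)


def validity_analysis(
    records, alpha: float = 0.05
) -> tuple[list, list]:
    """The full cascade over the six indices.

    Omnibus Kruskal-Wallis p-values are Holm-adjusted as a six-index family;
    Dunn post hoc tests (their own three-pair Holm family) are gated on an
    adjusted omnibus p < ``alpha``.  Invariant to subject ordering.
    """
    present = {s for r in records for s in [r.severity]}
    if len(present) < 2:
        raise ValidationError("need subjects from >= 2 severity groups")
    records = sorted(records, key=lambda r: str(r.id))

    comparisons = []
    raw_ps = []
    for name in INDEX_NAMES:
        per_group, excluded, _, _ = _index_values(records, name)
        groups = [per_group[s] for s in SEVERITIES if per_group[s]]
        h, p = kruskal_wallis(groups)
        comparisons.append(
            GroupComparison(
                index=name,
                group_n={s: len(per_group[s]) for s in SEVERITIES},
                group_mean={
                    s: float(np.mean(per_group[s])) if per_group[s] else math.nan
                    for s in SEVERITIES
                },
                group_sd={
                    s: float(np.std(per_group[s], ddof=1)) if len(per_group[s]) > 1 else math.nan
                    for s in SEVERITIES
                },
                h_statistic=h,
                p_raw=p,
                p_adjusted=math.nan,
                n_excluded=excluded,
            )
        )
        raw_ps.append(p)
    adjusted = holm_adjust(raw_ps)
    for comp, p_adj in zip(comparisons, adjusted):
        comp.p_adjusted = float(p_adj)
        if p_adj < alpha:
            per_group, _, _, _ = _index_values(records, comp.index)
            present_groups = [s for s in SEVERITIES if per_group[s]]
            groups = [per_group[s] for s in present_groups]
            pairs = dunn_posthoc(groups)
            pair_adj = holm_adjust([p for _, _, p in pairs])
            for ((a, b), z, p_raw), p_adjp in zip(pairs, pair_adj):
                n_pair = len(groups[a]) + len(groups[b])
                es, cat = effect_size(z, n_pair)
                comp.pairwise.append(
                    (
                        (present_groups[a], present_groups[b]),
                        z,
                        p_raw,
                        float(p_adjp),
                        es,
                        cat,
                    )
                )

    correlations = []
    for name in INDEX_NAMES:
        _, _, cobbs, values = _index_values(records, name)
        rho, p, cat = spearman(cobbs, values)
        correlations.append(
            CorrelationResult(index=name, rho=rho, p=p, category=cat, n=len(values))
        )
    return comparisons, correlations
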