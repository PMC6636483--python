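"""Group-comparison statistics for the study endpoints.

The pipeline mirrors standard practice for a three-arm animal study:

* **continuous endpoints** (morphometry, serum analytes) — Shapiro-Wilk
  normality per group; if all groups pass, one-way ANOVA with a
  Levene-gated choice of post hoc test: Tukey's HSD when variances are
  homogeneous (Levene p > alpha) and Dunnett's C when they are not.
  Dunnett's C is a decision-only procedure: each pair gets a critical
  difference ``q_bar * sqrt((s_i^2/n_i + s_j^2/n_j)/2)`` (studentized-range
  quantile at group df) and a significance flag, with no exact p-value.
* **ordinal or non-normal endpoints** (macroscopic grades) —
  Kruskal-Wallis with tie correction, followed by repeated Mann-Whitney U
  tests for each pair with Bonferroni-adjusted p-values.

Summaries follow the reporting convention of the endpoint's scale:
mean +/- SEM for continuous data, median (IQR, linear-interpolation
quantiles) for ordinal data.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "EndpointVector",
    "PairwiseComparison",
    "StatsReport",
    "InsufficientDataError",
    "DegenerateDataError",
    "choose_pipeline",
    "anova_tukey",
    "anova_dunnett_c",
    "kruskal_pairwise",
    "analyze_endpoint",
    "summarize",
    "sample_size_two_means",
]


class InsufficientDataError(ValueError):
    pass


class DegenerateDataError(ValueError):
    pass


@dataclass
class EndpointVector:
    """One endpoint's values, grouped by treatment arm."""

    name: str
    groups: dict[str, np.ndarray]
    scale: str  # "continuous" | "ordinal"

    def __post_init__(self):
        if self.scale not in ("continuous", "ordinal"):
            raise ValueError(f"scale must be 'continuous' or 'ordinal', got {self.scale!r}")
        self.groups = {k: np.asarray(v, dtype=float) for k, v in self.groups.items()}
        if len(self.groups) < 2:
            raise InsufficientDataError(f"{self.name}: need >= 2 groups")
        for g, v in self.groups.items():
            if v.size < 2:
                raise InsufficientDataError(f"{self.name}: group {g!r} has n={v.size} < 2")


@dataclass
class PairwiseComparison:
    group_a: str
    group_b: str
    estimate: float  # mean difference (a - b) or Mann-Whitney U
    p_raw: float | None
    p_adjusted: float | None
    significant: bool
    critical_difference: float | None = None  # Dunnett's C only

    def to_dict(self) -> dict:
        return {
            "group_a": self.group_a,
            "group_b": self.group_b,
            "estimate": float(self.estimate),
            "p_raw": None if self.p_raw is None else float(self.p_raw),
            "p_adjusted": None if self.p_adjusted is None else float(self.p_adjusted),
            "significant": bool(self.significant),
            "critical_difference": (
                None if self.critical_difference is None else float(self.critical_difference)
            ),
        }


@dataclass
class StatsReport:
    endpoint: str
    scale: str
    plan: str  # "anova_tukey" | "anova_dunnett_c" | "kruskal_pairwise"
    normality: dict[str, tuple[float, float]]  # group -> (W, p)
    levene_p: float | None
    omnibus_test: str
    omnibus_statistic: float
    omnibus_p: float
    pairwise: list[PairwiseComparison]
    summaries: dict[str, dict[str, float]]
    alpha: float = 0.05

    def to_dict(self) -> dict:
        return {
            "endpoint": self.endpoint,
            "scale": self.scale,
            "plan": self.plan,
            "normality": {g: {"W": w, "p": p} for g, (w, p) in self.normality.items()},
            "levene_p": self.levene_p,
            "omnibus": {
                "test": self.omnibus_test,
                "statistic": self.omnibus_statistic,
                "p": self.omnibus_p,
            },
            "pairwise": [c.to_dict() for c in self.pairwise],
            "summaries": self.summaries,
            "alpha": self.alpha,
        }


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------


def summarize(endpoint: EndpointVector) -> dict[str, dict[str, float]]:
    """Per-group summaries in the endpoint's reporting convention.

    Continuous: mean and SEM (sd/sqrt(n), ddof=1).  Ordinal: median and IQR
    (Q3 - Q1 with linear-interpolation quantiles).
    """
    out: dict[str, dict[str, float]] = {}
    for g, v in endpoint.groups.items():
        n = int(v.size)
        if endpoint.scale == "continuous":
            sd = float(np.std(v, ddof=1)) if n > 1 else 0.0
            out[g] = {"n": n, "mean": float(np.mean(v)), "sem": float(sd / np.sqrt(n))}
        else:
            q1, q2, q3 = np.percentile(v, [25, 50, 75])
            out[g] = {"n": n, "median": float(q2), "iqr": float(q3 - q1)}
    return out


# ---------------------------------------------------------------------------
# Gates
# ---------------------------------------------------------------------------


def _normality(endpoint: EndpointVector) -> dict[str, tuple[float, float]]:
    res = {}
    for g, v in endpoint.groups.items():
        if np.ptp(v) == 0:
            res[g] = (np.nan, 0.0)  # constant data: treat as non-normal
        else:
            w, p = sps.shapiro(v)
            res[g] = (float(w), float(p))
    return res


def _levene_p(endpoint: EndpointVector) -> float:
    # mean-centred Levene, the classic form used with ANOVA gating
    stat, p = sps.levene(*endpoint.groups.values(), center="mean")
    return float(p)


def choose_pipeline(endpoint: EndpointVector, alpha: float = 0.05) -> str:
    """Select the test plan for an endpoint.

    Ordinal or non-normal data go to Kruskal-Wallis with pairwise
    Mann-Whitney; normal continuous data go to one-way ANOVA with Tukey's
    HSD when Levene's test accepts variance homogeneity and Dunnett's C when
    it rejects.
    """
    if endpoint.scale == "ordinal":
        return "kruskal_pairwise"
    normality = _normality(endpoint)
    if any(p <= alpha for _, p in normality.values()):
        return "kruskal_pairwise"
    return "anova_tukey" if _levene_p(endpoint) > alpha else "anova_dunnett_c"


# ---------------------------------------------------------------------------
# Continuous pipelines
# ---------------------------------------------------------------------------


def _check_not_degenerate(endpoint: EndpointVector) -> None:
    if all(np.ptp(v) == 0 for v in endpoint.groups.values()):
        raise DegenerateDataError(
            f"{endpoint.name}: zero within-group variance in every group"
        )


def _anova(endpoint: EndpointVector) -> tuple[float, float]:
    f, p = sps.f_oneway(*endpoint.groups.values())
    return float(f), float(p)


def anova_tukey(endpoint: EndpointVector, alpha: float = 0.05) -> StatsReport:
    """One-way ANOVA with Tukey's HSD pairwise comparisons."""
    _check_not_degenerate(endpoint)
    names = list(endpoint.groups)
    f, p = _anova(endpoint)
    hsd = sps.tukey_hsd(*[endpoint.groups[g] for g in names])
    pairwise = []
    for i, j in combinations(range(len(names)), 2):
        p_adj = float(hsd.pvalue[i, j])
        pairwise.append(
            PairwiseComparison(
                group_a=names[i],
                group_b=names[j],
                estimate=float(np.mean(endpoint.groups[names[i]]) - np.mean(endpoint.groups[names[j]])),
                p_raw=p_adj,  # Tukey p is familywise by construction
                p_adjusted=p_adj,
                significant=p_adj < alpha,
            )
        )
    return StatsReport(
        endpoint=endpoint.name,
        scale=endpoint.scale,
        plan="anova_tukey",
        normality=_normality(endpoint),
        levene_p=_levene_p(endpoint),
        omnibus_test="one-way ANOVA",
        omnibus_statistic=f,
        omnibus_p=p,
        pairwise=pairwise,
        summaries=summarize(endpoint),
        alpha=alpha,
    )


@lru_cache(maxsize=256)
def _studentized_range_quantile(p: float, k: int, df: int) -> float:
    # numerically expensive (~0.1 s); the (p, k, df) space in a study is tiny
    return float(sps.studentized_range.ppf(p, k, df))


def anova_dunnett_c(endpoint: EndpointVector, alpha: float = 0.05) -> StatsReport:
    """One-way ANOVA with Dunnett's C pairwise comparisons.

    Dunnett's C handles heteroscedastic groups: for pair (i, j) the critical
    difference is ``q_bar * sqrt((s_i^2/n_i + s_j^2/n_j)/2)`` where q_bar
    averages the studentized-range quantiles at (k, n_i - 1) and
    (k, n_j - 1) degrees of freedom.  The procedure yields significance
    decisions only; no p-values are reported.
    """
    _check_not_degenerate(endpoint)
    names = list(endpoint.groups)
    k = len(names)
    f, p = _anova(endpoint)
    pairwise = []
    for i, j in combinations(range(k), 2):
        a, b = endpoint.groups[names[i]], endpoint.groups[names[j]]
        q_i = _studentized_range_quantile(1 - alpha, k, len(a) - 1)
        q_j = _studentized_range_quantile(1 - alpha, k, len(b) - 1)
        q_bar = 0.5 * (q_i + q_j)
        cd = q_bar * np.sqrt((np.var(a, ddof=1) / len(a) + np.var(b, ddof=1) / len(b)) / 2)
        diff = float(np.mean(a) - np.mean(b))
        pairwise.append(
            PairwiseComparison(
                group_a=names[i],
                group_b=names[j],
                estimate=diff,
                p_raw=None,
                p_adjusted=None,
                significant=abs(diff) > cd,
                critical_difference=float(cd),
            )
        )
    return StatsReport(
        endpoint=endpoint.name,
        scale=endpoint.scale,
        plan="anova_dunnett_c",
        normality=_normality(endpoint),
        levene_p=_levene_p(endpoint),
        omnibus_test="one-way ANOVA",
        omnibus_statistic=f,
        omnibus_p=p,
        pairwise=pairwise,
        summaries=summarize(endpoint),
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# Ordinal / non-normal pipeline
# ---------------------------------------------------------------------------


def _adjust(p_values: Sequence[float], method: str) -> list[float]:
    m = len(p_values)
    if method == "bonferroni":
        return [min(1.0, m * p) for p in p_values]
    if method == "holm":
        order = np.argsort(p_values)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * p_values[idx])
            adj[idx] = min(1.0, running)
        return adj.tolist()
    raise ValueError(f"unknown adjustment method: {method!r}")


def kruskal_pairwise(
    endpoint: EndpointVector,
    alpha: float = 0.05,
    adjust_method: str = "bonferroni",
) -> StatsReport:
    """Kruskal-Wallis omnibus with repeated pairwise Mann-Whitney tests.

    Mann-Whitney uses the exact null distribution when there are no ties and
    the normal approximation with tie correction otherwise; pairwise
    p-values are multiplied by the number of pairs (Bonferroni) by default.
    """
    values = list(endpoint.groups.values())
    if np.ptp(np.concatenate(values)) == 0:
        raise DegenerateDataError(f"{endpoint.name}: all values tied across all groups")
    h, p = sps.kruskal(*values)
    names = list(endpoint.groups)
    raw, pairs = [], []
    for i, j in combinations(range(len(names)), 2):
        a, b = endpoint.groups[names[i]], endpoint.groups[names[j]]
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="auto")
        raw.append(float(res.pvalue))
        pairs.append((names[i], names[j], float(res.statistic)))
    adjusted = _adjust(raw, adjust_method)
    pairwise = [
        PairwiseComparison(
            group_a=a,
            group_b=b,
            estimate=u,
            p_raw=pr,
            p_adjusted=pa,
            significant=pa < alpha,
        )
        for (a, b, u), pr, pa in zip(pairs, raw, adjusted)
    ]
    return StatsReport(
        endpoint=endpoint.name,
        scale=endpoint.scale,
        plan="kruskal_pairwise",
        normality=_normality(endpoint),
        levene_p=None,
        omnibus_test="Kruskal-Wallis",
        omnibus_statistic=float(h),
        omnibus_p=float(p),
        pairwise=pairwise,
        summaries=summarize(endpoint),
        alpha=alpha,
    )


def analyze_endpoint(
    endpoint: EndpointVector,
    alpha: float = 0.05,
    adjust_method: str = "bonferroni",
) -> StatsReport:
    """Run the full gated pipeline on one endpoint."""
    plan = choose_pipeline(endpoint, alpha=alpha)
    if plan == "anova_tukey":
        return anova_tukey(endpoint, alpha=alpha)
    if plan == "anova_dunnett_c":
        return anova_dunnett_c(endpoint, alpha=alpha)
    return kruskal_pairwise(endpoint, alpha=alpha, adjust_method=adjust_method)


def sample_size_two_means(
    delta: float,
    sd: float,
    alpha: float = 0.05,
    power: float = 0.90,
) -> int:
    """Per-group n for a two-sided two-sample comparison of means.

    Standard normal-approximation formula
    ``n = 2 * ((z_{1-alpha/2} + z_{power}) * sd / delta)**2``, rounded up.
    Provided as a planning helper only.
    """
    if delta <= 0 or sd <= 0:
        raise ValueError("delta and sd must be > 0")
    z_a = sps.norm.ppf(1 - alpha / 2)
    z_b = sps.norm.ppf(power)
    return int(np.ceil(2 * ((z_a + z_b) * sd / delta) ** 2))
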