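"""Enrichment tests on ancestry annotations.

Broad-scale ethnicity proportions are compared by one-sided Mann-Whitney U
(in-group stochastically greater than background), with an additional
in-group-median > 0 filter. Fine-scale community labels are tested by
upper-tail hypergeometric with Bonferroni correction over the community
universe and a fold-overrepresentation filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .simdata.annotate import AncestryAnnotation

__all__ = [
    "EthnicityTestResult",
    "CommunityTestResult",
    "test_ethnicities",
    "test_communities",
    "fold_overrepresentation",
    "mannwhitney_one_sided",
    "hypergeom_upper_tail",
]

logger = logging.getLogger(__name__)

# below this combined sample size (and with no ties) the exact Mann-Whitney
# null distribution is used instead of the tie-corrected normal approximation
EXACT_MW_MAX_N = 25


@dataclass(frozen=True)
class EthnicityTestResult:
    region: str
    p_value: float
    in_group_median: float
    passes: bool


@dataclass(frozen=True)
class CommunityTestResult:
    community: str
    p_raw: float
    p_adjusted: float
    fold: float | None
    passes: bool


def mannwhitney_one_sided(in_group: np.ndarray, background: np.ndarray) -> float:
    """One-sided Mann-Whitney U p-value (in-group greater).

    Exact when the combined sample is small and tie-free; otherwise the
    tie-corrected normal approximation with continuity correction.
    """
    x = np.asarray(in_group, dtype=float)
    y = np.asarray(background, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need >= 2 samples per side")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) < EXACT_MW_MAX_N and not has_ties) else "asymptotic"
    return float(
        stats.mannwhitneyu(x, y, alternative="greater", method=method).pvalue
    )


def hypergeom_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N population, K labeled, n drawn)."""
    if not (0 <= k <= n <= N and 0 <= K <= N):
        raise ValueError("invalid hypergeometric configuration")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def fold_overrepresentation(k: int, n: int, K: int, N: int) -> float | None:
    """In-group labeled rate over background labeled rate; None when the
    background rate is zero (undefined)."""
    if n <= 0 or N <= 0:
        raise ValueError("group sizes must be positive")
    if K == 0:
        return None
    return (k / n) / (K / N)


def _regions(annotations: dict[str, AncestryAnnotation]) -> list[str]:
    out: set[str] = set()
    for a in annotations.values():
        out.update(a.ethnicity)
    return sorted(out)


def test_ethnicities(
    in_group: dict[str, AncestryAnnotation],
    background: dict[str, AncestryAnnotation],
    alpha: float = 0.05,
    *,
    include_in_group_in_background: bool = False,
) -> list[EthnicityTestResult]:
    """Per-region one-sided Mann-Whitney U tests of ethnicity proportions.

    By default in-group samples are excluded from the background; set
    ``include_in_group_in_background`` to test against the pooled database
    convention. A region passes iff p < alpha AND in-group median > 0.
    """
    bg = dict(background)
    if include_in_group_in_background:
        bg.update(in_group)
    else:
        for sid in in_group:
            bg.pop(sid, None)
    results = []
    for region in _regions({**in_group, **bg}):
        x = np.array([a.ethnicity.get(region, 0.0) for a in in_group.values()])
        y = np.array([a.ethnicity.get(region, 0.0) for a in bg.values()])
        if not np.any(x) and not np.any(y):
            logger.info("region %s absent from all annotations; skipped", region)
            continue
        p = mannwhitney_one_sided(x, y)
        med = float(np.median(x))
        results.append(EthnicityTestResult(region, p, med, p < alpha and med > 0))
    return results


def test_communities(
    in_group: dict[str, AncestryAnnotation],
    background: dict[str, AncestryAnnotation],
    n_tested: int | None = None,
    alpha: float = 0.001,
    min_fold: float = 1.5,
    *,
    include_in_group_in_background: bool = False,
) -> list[CommunityTestResult]:
    """Per-community upper-tail hypergeometric tests with Bonferroni
    correction over ``n_tested`` communities (default: the number of
    communities present in the annotation universe).

    A community passes iff adjusted p < alpha AND fold > min_fold. A
    community with no background carriers has undefined fold and is reported
    but never passes.
    """
    bg = dict(background)
    if include_in_group_in_background:
        bg.update(in_group)
    else:
        for sid in in_group:
            bg.pop(sid, None)
    population = {**bg, **in_group}
    communities = sorted({c for a in population.values() for c in a.communities})
    if n_tested is None:
        n_tested = len(communities)
    if n_tested < 1:
        raise ValueError("n_tested must be >= 1")
    N, n = len(population), len(in_group)
    results = []
    for com in communities:
        K = sum(com in a.communities for a in population.values())
        k = sum(com in a.communities for a in in_group.values())
        p_raw = hypergeom_upper_tail(k, n, K, N)
        p_adj = min(1.0, p_raw * n_tested)
        fold = fold_overrepresentation(k, n, K, N)
        passes = fold is not None and p_adj < alpha and fold > min_fold
        results.append(CommunityTestResult(com, p_raw, p_adj, fold, passes))
    return results
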