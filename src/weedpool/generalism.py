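"""Habitat generalism: participation coefficient and rank-sum contrasts.

The participation coefficient summarizes how evenly a species' occurrences
spread across habitat modules:

    c = 1 - sum_h (n_h / n)^2

with n_h its occurrence count in habitat h and n = sum_h n_h. c = 0 for a
strict specialist (all occurrences in one habitat) and approaches
1 - 1/H for a perfect generalist over H habitats. This is the
Guimera–Amaral participation coefficient applied to occurrence counts
(equivalently the Simpson-diversity complement of the habitat profile);
alternative generalism measures can be plugged in via the ``formula``
argument.

Group contrasts (arable weeds vs other species, per habitat) use the
unpaired two-sample Wilcoxon rank-sum test, reported as the Mann–Whitney U
statistic of the first group.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats

from ._util import logger


@dataclass
class GeneralismScore:
    species_id: str
    counts: dict[str, int]  # habitat -> occurrence count n_h
    n: int
    c: float


@dataclass
class RankSumResult:
    W: float  # Mann–Whitney U of the first group
    n1: int
    n2: int
    p: float
    method: str  # "exact" | "normal_approx"


def participation_coefficient(counts: Sequence[int] | Mapping[str, int]) -> float:
    """c = 1 - sum (n_h/n)^2 over habitat occurrence counts.

    Invariant to habitat order and to scaling all counts by a constant;
    zero iff exactly one habitat is occupied. Raises on all-zero counts.
    """
    vals = np.asarray(
        list(counts.values()) if isinstance(counts, Mapping) else counts,
        dtype=float,
    )
    if np.any(vals < 0):
        raise ValueError("habitat counts must be non-negative")
    n = vals.sum()
    if n == 0:
        raise ValueError("participation coefficient undefined for zero occurrences")
    shares = vals / n
    return float(1.0 - np.sum(shares**2))


def score_species(
    habitat_counts: Mapping[str, Mapping[str, int]],
    formula: Callable[[Mapping[str, int]], float] = participation_coefficient,
) -> list[GeneralismScore]:
    """Participation scores for every species with >=1 labelled occurrence."""
    out = []
    for sp, counts in habitat_counts.items():
        n = sum(counts.values())
        if n == 0:
            continue
        out.append(GeneralismScore(sp, dict(counts), n, formula(counts)))
    return out


_EXACT_LIMIT = 12  # enumerate the null only for tiny tie-free samples


def rank_sum_test(group_a: Sequence[float], group_b: Sequence[float]) -> RankSumResult:
    """Two-sided unpaired Wilcoxon rank-sum (Mann–Whitney) test.

    Exact null distribution by enumeration when n1+n2 <= 12 and the pooled
    sample is tie-free; otherwise the normal approximation with midrank tie
    correction and continuity correction. W is the U statistic of the first
    group. Identical groups report p = 1 rather than erroring.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    tie_free = len(np.unique(pooled)) == pooled.size
    if np.ptp(pooled) == 0:
        # all values equal: no evidence of a difference
        u = a.size * b.size / 2.0
        return RankSumResult(u, a.size, b.size, 1.0, "normal_approx")
    if a.size + b.size <= _EXACT_LIMIT and tie_free:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        method = "exact"
    else:
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic",
            use_continuity=True,
        )
        method = "normal_approx"
    return RankSumResult(float(res.statistic), a.size, b.size,
                         float(res.pvalue), method)


def compare_groups_by_habitat(
    scores: Sequence[GeneralismScore],
    group_flag: Mapping[str, str],
    habitat: Mapping[str, str],
    min_group_size: int = 2,
) -> dict:
    """Per-habitat weed vs non-weed generalism contrasts.

    For each habitat stratum with at least ``min_group_size`` species per
    group: group sizes, median c, and the rank-sum test. Also returns the
    pooled contrast of each habitat's weeds against all other weeds (are
    this habitat's weeds more specialized than the rest?). Strata below the
    minimum are skipped with a warning.
    """
    by_habitat: dict[str, dict[str, list[float]]] = {}
    weed_c_by_habitat: dict[str, list[float]] = {}
    for s in scores:
        h = habitat.get(s.species_id)
        g = group_flag.get(s.species_id)
        if h is None or g is None or h == "unassigned":
            continue
        by_habitat.setdefault(h, {"weed": [], "non_weed": []})
        by_habitat[h].setdefault(g, []).append(s.c)
        if g == "weed":
            weed_c_by_habitat.setdefault(h, []).append(s.c)

    per_habitat = {}
    for h in sorted(by_habitat):
        weeds = by_habitat[h].get("weed", [])
        others = by_habitat[h].get("non_weed", [])
        if len(weeds) < min_group_size or len(others) < min_group_size:
            logger.warning("habitat %r skipped: stratum below %d species",
                           h, min_group_size)
            continue
        res = rank_sum_test(weeds, others)
        per_habitat[h] = {
            "n_weed": len(weeds),
            "n_non_weed": len(others),
            "median_weed": float(np.median(weeds)),
            "median_non_weed": float(np.median(others)),
            "W": res.W,
            "p": res.p,
            "method": res.method,
        }

    weed_contrasts = {}
    for h in sorted(weed_c_by_habitat):
        this = weed_c_by_habitat[h]
        rest = [c for h2, cs in weed_c_by_habitat.items() if h2 != h for c in cs]
        if len(this) < min_group_size or len(rest) < min_group_size:
            continue
        res = rank_sum_test(this, rest)
        weed_contrasts[h] = {
            "n_habitat": len(this),
            "n_other": len(rest),
            "median_habitat": float(np.median(this)),
            "median_other": float(np.median(rest)),
            "W": res.W,
            "p": res.p,
        }
    return {"per_habitat": per_habitat, "weed_vs_other_weeds": weed_contrasts}
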