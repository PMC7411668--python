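"""Observed-vs-expected habitat composition and contingency statistics.

A weed list's habitat composition is compared against a reference pool of
open-vegetation species: expected counts scale the reference habitat
proportions to the list's total, chi-square goodness-of-fit tests the
departure, and 2x2 contingency tests (optionally Yates-corrected) compare
category proportions between lists. Expected counts are rounded half-up
for display only; every test statistic is computed on unrounded expecteds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from ._util import percent, round_half_up


@dataclass
class ContingencyResult:
    chi2: float
    df: int
    p: float
    yates: bool = False


@dataclass
class HabitatCountTable:
    """One list's observed and expected counts against a reference pool."""

    habitats: list[str]
    reference: list[int]
    observed: list[int]
    expected_real: list[float]
    expected: list[int]  # rounded half-up, for display
    test: ContingencyResult

    def formatted(self) -> list[str]:
        """Rows in the conventional 'observed (expected)' display form."""
        return [f"{o} ({e})" for o, e in zip(self.observed, self.expected)]


def expected_counts_real(observed: Sequence[int], reference: Sequence[int]) -> np.ndarray:
    """Unrounded expecteds: list total allocated by reference proportions."""
    obs = np.asarray(observed, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if obs.shape != ref.shape or obs.size < 2:
        raise ValueError("observed and reference must have equal length >= 2")
    if obs.sum() <= 0:
        raise ValueError("observed total must be positive")
    if np.any(ref <= 0):
        raise ValueError("all reference counts must be positive")
    return obs.sum() * ref / ref.sum()


def expected_counts(observed: Sequence[int], reference: Sequence[int]) -> list[int]:
    """Expected counts E_h = round_half_up(N * r_h / sum r), N = sum O."""
    return [int(round_half_up(e)) for e in expected_counts_real(observed, reference)]


def chisq_gof(observed: Sequence[int], expected_real: Sequence[float]) -> ContingencyResult:
    """Chi-square goodness of fit on unrounded expecteds, df = H - 1."""
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected_real, dtype=float)
    if obs.shape != exp.shape:
        raise ValueError("observed and expected must have equal length")
    if np.any(exp <= 0):
        raise ValueError("expected counts must all be positive")
    chi2 = float(np.sum((obs - exp) ** 2 / exp))
    df = obs.size - 1
    p = float(stats.chi2.sf(chi2, df))
    return ContingencyResult(chi2=chi2, df=df, p=p)


def chisq_2x2(a: int, b: int, c: int, d: int, yates: bool = False) -> ContingencyResult:
    """Pearson chi-square for a 2x2 table [[a, b], [c, d]].

    With ``yates`` the continuity-corrected form
    N (|ad - bc| - N/2)^2 / ((a+b)(c+d)(a+c)(b+d)) is used (correction
    capped so over-correction cannot produce a spurious statistic).
    """
    cells = np.array([a, b, c, d], dtype=float)
    if np.any(cells < 0):
        raise ValueError("cell counts must be non-negative")
    n = cells.sum()
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("2x2 table has a zero margin")
    diff = abs(a * d - b * c)
    if yates:
        diff = max(diff - n / 2.0, 0.0)
    chi2 = float(n * diff**2 / (r1 * r2 * c1 * c2))
    p = float(stats.chi2.sf(chi2, 1))
    return ContingencyResult(chi2=chi2, df=1, p=p, yates=yates)


def proportion_comparison(
    k1: int, n1: int, k2: int, n2: int, yates: bool = True
) -> tuple[float, float, ContingencyResult]:
    """Two proportions to one decimal plus the 2x2 test between them."""
    for k, n in ((k1, n1), (k2, n2)):
        if n <= 0:
            raise ValueError("group size must be positive")
        if not 0 <= k <= n:
            raise ValueError("count must lie in [0, n]")
    pct1 = percent(k1, n1)
    pct2 = percent(k2, n2)
    res = chisq_2x2(k1, n1 - k1, k2, n2 - k2, yates=yates)
    return pct1, pct2, res


def habitat_count_table(
    habitats: Sequence[str], reference: Sequence[int], observed: Sequence[int]
) -> HabitatCountTable:
    """Observed(expected) table plus goodness-of-fit for one weed list."""
    exp_real = expected_counts_real(observed, reference)
    return HabitatCountTable(
        habitats=list(habitats),
        reference=[int(r) for r in reference],
        observed=[int(o) for o in observed],
        expected_real=list(map(float, exp_real)),
        expected=[int(round_half_up(e)) for e in exp_real],
        test=chisq_gof(observed, exp_real),
    )
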