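"""Adverse-event statistics for paired stimulation-tolerability studies.

Two study arms (active stimulation vs. a control such as photic stimulation)
are compared on nominally scaled adverse events with two-sided Fisher exact
tests on 2×2 incidence tables, and on paired NRS-11 pain ratings with the
Wilcoxon signed-rank test.  Incidences are additionally expressed as
percentages with the standard pharmacovigilance frequency categories
(very common > 1/10, common 1/100–1/10, uncommon 1/1000–1/100, rare below,
not observed at zero).

Conventions
-----------
* The two-sided Fisher p-value follows the point-probability criterion: the
  sum of hypergeometric probabilities, over all tables with the observed
  margins, of every table no more probable than the observed one (with a
  small relative slack for floating-point ties).  This is the convention of
  the major statistics packages' "Exact Sig. (2-tailed)".
* The Wilcoxon test drops zero differences, uses average ranks for ties, a
  tie-corrected variance and no continuity correction ("Asymp. Sig."
  convention); for small samples an exact sign-flip permutation p-value is
  also computed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, norm, rankdata

__all__ = [
    "DegenerateTestError",
    "ContingencyTable2x2",
    "PairedRatings",
    "TestResult",
    "fisher_exact_two_sided",
    "wilcoxon_signed_rank",
    "incidence_summary",
    "frequency_category",
    "compare_conditions",
]

#: relative slack when comparing hypergeometric point probabilities
_TIE_SLACK = 1e-7

#: sample sizes up to which the exact Wilcoxon permutation p is computed
_EXACT_WILCOXON_N = 12


class DegenerateTestError(ValueError):
    """The test statistic is undefined for this input (e.g. all paired
    differences are zero)."""


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Condition × event-present/absent counts for one adverse event.

    Rows are the two study arms; ``a``/``b`` are present/absent counts in the
    first arm, ``c``/``d`` in the second.
    """

    a: int
    b: int
    c: int
    d: int
    row_labels: Tuple[str, str] = ("rACS", "PS")
    event: str = ""
    phase: str = ""

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValueError(f"count {name} must be a non-negative integer")

    @property
    def row_sums(self) -> Tuple[int, int]:
        return (self.a + self.b, self.c + self.d)

    @property
    def event_total(self) -> int:
        return self.a + self.c

    def swapped_rows(self) -> "ContingencyTable2x2":
        return ContingencyTable2x2(self.c, self.d, self.a, self.b,
                                   self.row_labels[::-1], self.event,
                                   self.phase)


@dataclass(frozen=True)
class PairedRatings:
    """Per-subject paired NRS-11 ratings (integers 0–10), aligned by subject."""

    first: Tuple[int, ...]
    second: Tuple[int, ...]
    labels: Tuple[str, str] = ("rACS", "PS")

    def __post_init__(self) -> None:
        if len(self.first) != len(self.second) or len(self.first) == 0:
            raise ValueError("ratings must be non-empty and aligned by subject")
        for v in (*self.first, *self.second):
            if not 0 <= v <= 10:
                raise ValueError("NRS-11 ratings must be integers in [0, 10]")

    @property
    def differences(self) -> np.ndarray:
        return np.asarray(self.first, dtype=float) - np.asarray(
            self.second, dtype=float)


@dataclass(frozen=True)
class TestResult:
    """Outcome of one two-sided hypothesis test."""

    method: str
    p_value: float
    statistic: Optional[float] = None
    n: Optional[int] = None
    exact_p_value: Optional[float] = None
    sidedness: str = "two-sided"

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value must lie in [0, 1]")


def fisher_exact_two_sided(table: ContingencyTable2x2) -> TestResult:
    """Two-sided Fisher exact test by full hypergeometric enumeration.

    With margins fixed, every feasible first-cell value ``a'`` is enumerated;
    the p-value is the sum of point probabilities not exceeding that of the
    observed table (relative slack ``1e-7`` absorbs floating-point ties).
    Degenerate margins (the event absent, or universal, in both arms, or an
    empty arm) yield p = 1.
    """
    r1, r2 = table.row_sums
    n = r1 + r2
    c1 = table.event_total
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return TestResult("fisher-exact", 1.0, n=n)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, c1, r1)
    p_obs = pmf[table.a - lo]
    p = float(pmf[pmf <= p_obs * (1.0 + _TIE_SLACK)].sum())
    return TestResult("fisher-exact", min(p, 1.0), n=n)


def _signed_rank_exact_p(ranks: np.ndarray, w_obs: float) -> float:
    """Exact two-sided sign-flip p for the signed-rank statistic.

    Enumerates the distribution of W+ over all 2^n sign assignments with a
    subset-sum dynamic program over doubled (hence integral) ranks; the
    distribution is symmetric about n(n+1)/4, so the two-sided p is the
    probability of a deviation at least as large as observed.
    """
    doubled = np.rint(2 * ranks).astype(int)
    total = int(doubled.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = 0.5 * (dist + shifted)
    mean = total / 2.0
    dev = abs(2 * w_obs - mean)
    support = np.arange(total + 1)
    return float(dist[np.abs(support - mean) >= dev - 1e-9].sum())


def wilcoxon_signed_rank(ratings: PairedRatings) -> TestResult:
    """Wilcoxon signed-rank test on paired ratings.

    Zero differences are discarded; tied absolute differences receive average
    ranks; the asymptotic Z uses the tie-corrected variance without
    continuity correction, and the two-sided p comes from the normal
    distribution.  For ≤ 12 non-zero differences the exact permutation p
    (sign-flip enumeration) is returned alongside.

    Raises :class:`DegenerateTestError` when every difference is zero.
    """
    d = ratings.differences
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise DegenerateTestError("all paired differences are zero")
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mean = n * (n + 1) / 4.0
    # tie correction: subtract sum(t^3 - t)/48 over groups of tied |d|
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - float(
        ((tie_counts ** 3 - tie_counts) / 48.0).sum())
    if var <= 0:
        raise DegenerateTestError("zero variance (all differences tied at one"
                                  " magnitude and sign)")
    z = (w_plus - mean) / math.sqrt(var)
    p = float(2.0 * norm.sf(abs(z)))
    exact = _signed_rank_exact_p(ranks, w_plus) if n <= _EXACT_WILCOXON_N else None
    return TestResult("wilcoxon-signed-rank", min(p, 1.0), statistic=z, n=n,
                      exact_p_value=exact)


def frequency_category(k: int, n: int) -> str:
    """Pharmacovigilance frequency band of an incidence k out of n."""
    if n <= 0:
        raise ValueError("n must be > 0")
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    rate = k / n
    if rate == 0:
        return "not observed"
    if rate > 1 / 10:
        return "very common"
    if rate > 1 / 100:
        return "common"
    if rate > 1 / 1000:
        return "uncommon"
    return "rare"


def incidence_summary(
    counts: Iterable[Tuple[str, str, int, int]],
) -> pd.DataFrame:
    """Percentages and frequency categories for (event, phase, k, n) counts."""
    rows = []
    for event, phase, k, n in counts:
        if n <= 0:
            raise ValueError(f"group size must be > 0 for {event!r}/{phase!r}")
        rows.append({
            "event": event, "phase": phase, "k": int(k), "n": int(n),
            "percent": 100.0 * k / n,
            "category": frequency_category(k, n),
        })
    return pd.DataFrame(rows)


def compare_conditions(
    ae_tables: Sequence[ContingencyTable2x2],
    ratings: Optional[Dict[str, PairedRatings]] = None,
    bonferroni: bool = False,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Full between-condition results table (Fisher per event×phase, Wilcoxon
    per ratings comparison).

    Degenerate cells — an event observed in neither arm, or ratings with no
    non-zero differences — carry a NaN p-value and serialize as "–".  With
    ``bonferroni=True`` an adjusted significance flag over the family of
    non-degenerate tests is added (the uncorrected p-values themselves are
    always reported).
    """
    rows: List[dict] = []
    for t in ae_tables:
        n = sum(t.row_sums)
        degenerate = t.event_total == 0 or t.event_total == n
        if degenerate:
            p, note = math.nan, "degenerate (no discordant counts)"
        else:
            p, note = fisher_exact_two_sided(t).p_value, ""
        rows.append({
            "source": f"{t.row_labels[0]} vs. {t.row_labels[1]}",
            "event": t.event, "phase": t.phase,
            "test": "fisher-exact", "statistic": math.nan,
            "p_value": p, "note": note,
        })
    for label, pairs in (ratings or {}).items():
        try:
            res = wilcoxon_signed_rank(pairs)
            stat, p, note = res.statistic, res.p_value, ""
        except DegenerateTestError as exc:
            stat, p, note = math.nan, math.nan, str(exc)
        event, _, phase = label.partition("/")
        rows.append({
            "source": f"{pairs.labels[0]} vs. {pairs.labels[1]}",
            "event": event, "phase": phase or "",
            "test": "wilcoxon-signed-rank", "statistic": stat,
            "p_value": p, "note": note,
        })
    result = pd.DataFrame(rows)
    result["significant"] = result["p_value"] < alpha
    if bonferroni:
        m = int(result["p_value"].notna().sum())
        result["p_bonferroni"] = (result["p_value"] * m).clip(upper=1.0)
        result["significant_bonferroni"] = result["p_bonferroni"] < alpha
    return result
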