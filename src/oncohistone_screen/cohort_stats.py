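"""2x2 cohort contingency tables, exact Fisher probabilities and incidences.

The two-sided Fisher p-value is the sum of hypergeometric point probabilities
(margins fixed) over all tables whose point probability does not exceed that
of the observed table, with a multiplicative (1 + 1e-7) tolerance on the
comparison — the dominant convention for the two-sided exact test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable

import numpy as np
from scipy.stats import hypergeom

from .io_formats import CohortSample, Diagnosis, ValidationError

_REL_TOL = 1.0 + 1e-7


@dataclass(frozen=True)
class ContingencyTable:
    """Counts [[a, b], [c, d]]: rows = predicate-positive/negative samples,
    columns = group-positive/negative."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for cell in (self.a, self.b, self.c, self.d):
            if cell < 0:
                raise ValidationError(f"negative contingency cell in {self.cells()}")
        if self.total == 0:
            raise ValidationError("contingency table is empty")

    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def odds_ratio(self) -> float:
        """Sample (unconditional) odds ratio ad/bc; inf when bc = 0."""
        if self.b * self.c == 0:
            return float("inf") if self.a * self.d > 0 else float("nan")
        return (self.a * self.d) / (self.b * self.c)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n1: int
    n2: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValidationError(f"p_value={self.p_value} outside [0, 1]")


def build_contingency(
    samples: Iterable[CohortSample],
    row_predicate: Callable[[CohortSample], bool],
    col_predicate: Callable[[CohortSample], bool],
) -> ContingencyTable:
    """Cross-tabulate cohort samples by two predicates; remission samples are
    excluded (they duplicate their diagnosis sample)."""
    samples = [s for s in samples if s.diagnosis is not Diagnosis.REMISSION]
    if not samples:
        raise ValueError("build_contingency requires at least one non-remission sample")
    a = b = c = d = 0
    for s in samples:
        row, col = bool(row_predicate(s)), bool(col_predicate(s))
        if row and col:
            a += 1
        elif row:
            b += 1
        elif col:
            c += 1
        else:
            d += 1
    return ContingencyTable(a, b, c, d)


def fisher_exact_two_sided(table: ContingencyTable) -> TestResult:
    """Exact two-sided Fisher test on a 2x2 table with fixed margins.

    With row margin r1 = a + b and column margin c1 = a + c, the cell ``a``
    follows Hypergeometric(N, c1, r1); p is the total probability of all
    realizable tables at least as extreme (point probability <= observed, up
    to a 1e-7 relative tolerance).
    """
    a, b, c, d = table.cells()
    n = table.total
    r1 = a + b
    c1 = a + c
    support = np.arange(max(0, r1 + c1 - n), min(r1, c1) + 1)
    pmf = hypergeom.pmf(support, n, c1, r1)
    p_obs = hypergeom.pmf(a, n, c1, r1)
    p = float(pmf[pmf <= p_obs * _REL_TOL].sum())
    return TestResult(
        statistic=table.odds_ratio(),
        p_value=min(1.0, p),
        method="fisher-exact-two-sided",
        n1=r1,
        n2=n - r1,
    )


def incidence(
    samples: Iterable[CohortSample],
    subgroup_predicate: Callable[[CohortSample], bool],
    event_predicate: Callable[[CohortSample], bool],
) -> float:
    """Fraction of subgroup samples with the event; remission samples excluded."""
    subgroup = [
        s for s in samples
        if s.diagnosis is not Diagnosis.REMISSION and subgroup_predicate(s)
    ]
    if not subgroup:
        raise ValueError("incidence undefined on an empty subgroup")
    return sum(1 for s in subgroup if event_predicate(s)) / len(subgroup)
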