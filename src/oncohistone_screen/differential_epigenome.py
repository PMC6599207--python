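"""The bespoke differential layer: z-score statistic, triplicate t-test,
threshold calls, set overlap, Tukey box/notch statistics and mark/RNA
integration.

The z statistic is z = (Mutant - WT) / sqrt(Mutant + WT) for RNA (means are
non-negative RPKM) and z = (Mutant - WT) / sqrt(|Mutant| + |WT|) for ChIP net
signals, which may be negative after input subtraction. A gene is called
deregulated when |z| exceeds the threshold (strictly) and the unpaired
equal-variance t-test on the replicates is below the p threshold (strictly):
|z| > 1.5 and p < 0.05 by default, |z| > 0.8 in the expanded mode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from .cohort_stats import TestResult
from .io_formats import ValidationError

DEFAULT_Z_THRESH = 1.5
EXPANDED_Z_THRESH = 0.8
DEFAULT_P_THRESH = 0.05


@dataclass(slots=True)
class ExpressionRecord:
    """Replicate RPKM values of one gene in one condition."""

    gene_id: str
    condition: str
    replicate_values: list

    def __post_init__(self) -> None:
        self.replicate_values = [float(v) for v in self.replicate_values]
        if any(v < 0 for v in self.replicate_values):
            raise ValidationError(f"{self.gene_id}: negative RPKM")

    @property
    def mean_rpkm(self) -> float:
        return sum(self.replicate_values) / len(self.replicate_values)


@dataclass(slots=True)
class DifferentialResult:
    gene_id: str
    modality: str  # rna | chip_me3 | chip_ac
    mutant_mean: float
    wt_mean: float
    z: float
    p: Optional[float]
    call: str  # up | down | ns


@dataclass(frozen=True)
class BoxStats:
    """Tukey five-number box statistics with notches.

    Hinges are Tukey hinges (medians of the lower/upper halves, the sample
    median included in both halves when n is odd); whiskers reach the most
    extreme data point within hinge +/- 1.5*IQR; notches extend to
    median +/- 1.58*IQR/sqrt(n).
    """

    n: int
    median: float
    hinge_lo: float
    hinge_hi: float
    iqr: float
    whisker_lo: float
    whisker_hi: float
    notch_lo: float
    notch_hi: float


def zscore(mutant_mean: float, wt_mean: float, absolute_denominator: bool) -> float:
    """z = (M - W)/sqrt(|M| + |W|) in absolute mode (ChIP net signals), or
    (M - W)/sqrt(M + W) otherwise (RNA); 0 when the denominator is 0."""
    if not absolute_denominator and (mutant_mean < 0 or wt_mean < 0):
        raise ValueError("RNA-mode zscore requires non-negative means")
    denom = abs(mutant_mean) + abs(wt_mean) if absolute_denominator else mutant_mean + wt_mean
    if denom == 0:
        return 0.0
    return (mutant_mean - wt_mean) / math.sqrt(denom)


def ttest_two_sample(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-tailed unpaired equal-variance (Student) t-test.

    Degenerate rule when the pooled variance is zero: p = 1 if the means are
    equal, else p = 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("ttest_two_sample requires >= 2 values per group")
    n1, n2 = a.size, b.size
    df = n1 + n2 - 2
    pooled_var = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / df
    diff = a.mean() - b.mean()
    if pooled_var == 0.0:
        if diff == 0.0:
            stat, p = 0.0, 1.0
        else:
            stat, p = math.copysign(math.inf, diff), 0.0
    else:
        stat = diff / math.sqrt(pooled_var * (1.0 / n1 + 1.0 / n2))
        p = 2.0 * float(t_dist.sf(abs(stat), df))
    return TestResult(statistic=stat, p_value=min(1.0, p), method="student-t-two-tailed",
                      n1=n1, n2=n2)


def call_differential(
    expr: Iterable[tuple[ExpressionRecord, ExpressionRecord]],
    z_thresh: float = DEFAULT_Z_THRESH,
    p_thresh: float = DEFAULT_P_THRESH,
) -> list[DifferentialResult]:
    """Call per-gene deregulation from (mutant, WT) replicate-RPKM pairs.

    Replicates are averaged before the z-score; p comes from the t-test on
    the replicate values. call = up iff z > z_thresh and p < p_thresh (strict
    inequalities); down symmetrically; otherwise ns.
    """
    results = []
    for mutant, wt in expr:
        if mutant.gene_id != wt.gene_id:
            raise ValidationError(
                f"mismatched gene pair: {mutant.gene_id} vs {wt.gene_id}"
            )
        z = zscore(mutant.mean_rpkm, wt.mean_rpkm, absolute_denominator=False)
        p = ttest_two_sample(mutant.replicate_values, wt.replicate_values).p_value
        if z > z_thresh and p < p_thresh:
            call = "up"
        elif z < -z_thresh and p < p_thresh:
            call = "down"
        else:
            call = "ns"
        results.append(
            DifferentialResult(
                gene_id=mutant.gene_id, modality="rna",
                mutant_mean=mutant.mean_rpkm, wt_mean=wt.mean_rpkm,
                z=z, p=p, call=call,
            )
        )
    return results


def expression_pairs(
    table: pd.DataFrame, mutant_condition: str, wt_condition: str
) -> list[tuple[ExpressionRecord, ExpressionRecord]]:
    """Build (mutant, WT) ExpressionRecord pairs from a tidy RPKM table."""
    pairs = []
    for cond in (mutant_condition, wt_condition):
        if cond not in set(table["condition"]):
            raise ValidationError(f"condition '{cond}' absent from expression table")
    grouped = {
        (gene, cond): sub.sort_values("replicate")["rpkm"].tolist()
        for (gene, cond), sub in table.groupby(["gene_id", "condition"], sort=False)
    }
    genes_mut = {g for g, c in grouped if c == mutant_condition}
    genes_wt = {g for g, c in grouped if c == wt_condition}
    if genes_mut != genes_wt:
        raise ValidationError("mutant and WT gene sets differ in expression table")
    for gene in sorted(genes_mut):
        pairs.append(
            (
                ExpressionRecord(gene, mutant_condition, grouped[(gene, mutant_condition)]),
                ExpressionRecord(gene, wt_condition, grouped[(gene, wt_condition)]),
            )
        )
    return pairs


def chip_zscores(
    net_by_gene_mutant: Mapping[str, float], net_by_gene_wt: Mapping[str, float]
) -> dict[str, float]:
    """Per-gene ChIP z-scores (absolute-value denominator) from averaged net
    signals of a mutant and the WT condition."""
    if set(net_by_gene_mutant) != set(net_by_gene_wt):
        raise ValidationError("mutant and WT gene sets differ in ChIP signal")
    return {
        g: zscore(net_by_gene_mutant[g], net_by_gene_wt[g], absolute_denominator=True)
        for g in net_by_gene_mutant
    }


def overlap_sets(
    calls_a: Iterable[DifferentialResult],
    calls_b: Iterable[DifferentialResult],
    direction: str = "up",
) -> tuple[set, set, set]:
    """Partition genes with the given call into (only_a, shared, only_b)."""
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    a = {r.gene_id for r in calls_a if r.call == direction}
    b = {r.gene_id for r in calls_b if r.call == direction}
    return a - b, a & b, b - a


def _median(sorted_values: Sequence[float]) -> float:
    n = len(sorted_values)
    mid = n // 2
    if n % 2:
        return float(sorted_values[mid])
    return (sorted_values[mid - 1] + sorted_values[mid]) / 2.0


def box_stats(values: Sequence[float]) -> BoxStats:
    """Tukey box/notch statistics (hinges, 1.5*IQR whiskers, 1.58*IQR/sqrt(n)
    notches)."""
    values = sorted(float(v) for v in values)
    n = len(values)
    if n == 0:
        raise ValueError("box_stats requires at least one value")
    med = _median(values)
    half = (n + 1) // 2  # include the median in both halves when n is odd
    lo_half = values[:half]
    hi_half = values[n - half:]
    hinge_lo = _median(lo_half)
    hinge_hi = _median(hi_half)
    iqr = hinge_hi - hinge_lo
    lo_fence = hinge_lo - 1.5 * iqr
    hi_fence = hinge_hi + 1.5 * iqr
    inside = [v for v in values if lo_fence <= v <= hi_fence]
    # hinges are data values, so at least the central half is always inside
    whisker_lo, whisker_hi = inside[0], inside[-1]
    notch = 1.58 * iqr / math.sqrt(n)
    return BoxStats(
        n=n, median=med, hinge_lo=hinge_lo, hinge_hi=hinge_hi, iqr=iqr,
        whisker_lo=whisker_lo, whisker_hi=whisker_hi,
        notch_lo=med - notch, notch_hi=med + notch,
    )


@dataclass(frozen=True)
class PromoterShift:
    global_stats: BoxStats
    subset_stats: BoxStats
    subset_below_global_notch: bool


def promoter_set_shift(
    me3_z_by_gene: Mapping[str, float], gene_set: Iterable[str]
) -> PromoterShift:
    """Compare the distribution of promoter H3K27me3 z-scores over all genes
    against a gene subset, with a notch non-overlap read-out."""
    gene_set = set(gene_set)
    if not gene_set:
        raise ValueError("promoter_set_shift requires a non-empty gene set")
    missing = gene_set - set(me3_z_by_gene)
    if missing:
        raise ValidationError(f"gene_set contains unknown genes: {sorted(missing)[:5]}")
    global_stats = box_stats(list(me3_z_by_gene.values()))
    subset_stats = box_stats([me3_z_by_gene[g] for g in gene_set])
    return PromoterShift(
        global_stats=global_stats,
        subset_stats=subset_stats,
        subset_below_global_notch=subset_stats.median < global_stats.notch_lo,
    )


INTEGRATION_CATEGORIES = (
    "derepressed_activated", "me3_loss_only", "ac_gain_only", "unchanged", "other",
)


def integrate_marks(
    me3_z: Mapping[str, float],
    ac_z: Mapping[str, float],
    rna_z: Mapping[str, float],
    eps: float = 0.0,
) -> dict[str, str]:
    """Categorize genes by the sign pattern of H3K27me3, H3K27ac and RNA
    z-scores.

    derepressed_activated: me3 loss with ac gain and RNA up — the signature of
    a gene released from PRC2 repression. Categories are exhaustive and
    mutually exclusive.
    """
    universe = set(me3_z)
    if universe != set(ac_z) or universe != set(rna_z):
        raise ValidationError("integrate_marks requires one shared gene universe")
    out = {}
    for g in universe:
        m, a, r = me3_z[g], ac_z[g], rna_z[g]
        me3_loss, ac_gain, rna_up = m < -eps, a > eps, r > eps
        if abs(m) <= eps and abs(a) <= eps and abs(r) <= eps:
            out[g] = "unchanged"
        elif me3_loss and ac_gain and rna_up:
            out[g] = "derepressed_activated"
        elif me3_loss and not ac_gain:
            out[g] = "me3_loss_only"
        elif ac_gain and not me3_loss:
            out[g] = "ac_gain_only"
        else:
            out[g] = "other"
    return out
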