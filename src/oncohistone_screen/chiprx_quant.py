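"""Spike-in-normalized promoter ChIP quantification.

The chain is fixed: PCR-duplicate removal (identical coordinates) -> MAPQ
filter (quality must exceed 5) and 250-bp 3' extension -> 3-kb TSS-window
counting (>= 1 bp overlap) -> Rx normalization (reads per kb of window per
million *spike-in* reads) -> input subtraction (negatives preserved) ->
technical-replicate averaging. Normalizing to the spike-in library size
rather than the target library size is what lets a genuinely global loss of
signal survive normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .io_formats import PromoterWindow, ReadInterval, ValidationError

DEFAULT_MIN_MAPQ = 5  # strict: mapq must be > 5
DEFAULT_EXTENSION = 250  # bp appended at the 3' end


class NormalizationError(ValueError):
    """Rx normalization is impossible (no spike-in reads in the library)."""


@dataclass(slots=True)
class LibraryStats:
    """Read-accounting for one library; n_raw >= n_dedup >= n_pass_mq =
    n_target + n_spike."""

    library_id: str
    n_raw: int = 0
    n_dedup: int = 0
    n_pass_mq: int = 0
    n_target: int = 0
    n_spike: int = 0

    def validate(self) -> None:
        if not (self.n_raw >= self.n_dedup >= self.n_pass_mq):
            raise ValidationError(f"{self.library_id}: inconsistent read counts {self}")
        if self.n_pass_mq != self.n_target + self.n_spike:
            raise ValidationError(
                f"{self.library_id}: n_pass_mq != n_target + n_spike in {self}"
            )


@dataclass(slots=True)
class SignalRecord:
    """Per-gene promoter signal for one (mark, condition, replicate)."""

    gene_id: str
    mark: str
    condition: str
    replicate: str  # "rep1", ..., or "averaged"
    raw_count: float
    rx_signal: float  # reads per kb per million spike-in reads; >= 0
    net_signal: float  # rx_signal - input rx_signal; may be negative

    def __post_init__(self) -> None:
        if self.rx_signal < 0:
            raise ValidationError(f"{self.gene_id}: rx_signal must be >= 0")


# ---------------------------------------------------------------------------
# Stage 1: PCR-duplicate removal
# ---------------------------------------------------------------------------

def dedup_reads(
    reads: Iterable[ReadInterval],
    library_id: str = "",
    ignore_strand: bool = False,
) -> tuple[list[ReadInterval], LibraryStats]:
    """Discard reads with identical coordinates as PCR duplicates, keeping the
    first occurrence.

    The duplicate key is (chrom, start, end, strand) by default: for
    single-end data, identical coordinates on opposite strands are distinct
    molecules. ``ignore_strand`` drops strand from the key.
    """
    seen: set = set()
    kept: list[ReadInterval] = []
    n_raw = 0
    for r in reads:
        n_raw += 1
        key = (r.chrom, r.start, r.end) if ignore_strand else (r.chrom, r.start, r.end, r.strand)
        if key in seen:
            continue
        seen.add(key)
        kept.append(r)
    return kept, LibraryStats(library_id=library_id, n_raw=n_raw, n_dedup=len(kept))


# ---------------------------------------------------------------------------
# Stage 2: MAPQ filter + 3' extension
# ---------------------------------------------------------------------------

def filter_and_extend(
    reads: Iterable[ReadInterval],
    min_mq: int = DEFAULT_MIN_MAPQ,
    ext: int = DEFAULT_EXTENSION,
    mode: str = "extend",
) -> list[ReadInterval]:
    """Drop reads with MAPQ <= min_mq (strict: quality must exceed the bound),
    then stretch each survivor toward its 3' end.

    mode="extend" (default): a plus-strand read [s, e) becomes [s, e + ext);
    minus-strand [max(0, s - ext), e). mode="resize": the read is resized to
    ext bp total from its 5' end.
    """
    if mode not in ("extend", "resize"):
        raise ValueError(f"unknown extension mode {mode!r}")
    out = []
    for r in reads:
        if r.mapq <= min_mq:
            continue
        if mode == "extend":
            if r.strand == "+":
                new = replace(r, end=r.end + ext)
            else:
                new = replace(r, start=max(0, r.start - ext))
        else:
            if r.strand == "+":
                new = replace(r, end=r.start + ext)
            else:
                new = replace(r, start=max(0, r.end - ext))
        out.append(new)
    return out


# ---------------------------------------------------------------------------
# Stage 3: TSS-window counting
# ---------------------------------------------------------------------------

def window_counts(
    reads: Sequence[ReadInterval], promoters: Sequence[PromoterWindow]
) -> dict[str, int]:
    """Count reads overlapping each promoter window by >= 1 bp.

    A read may count toward several overlapping windows; half-open interval
    semantics, so a read ending exactly at the window start does not count.
    Only target-species reads should be passed here.
    """
    counts = {w.gene_id: 0 for w in promoters}
    if not reads or not promoters:
        return counts
    by_chrom: dict[str, list[ReadInterval]] = {}
    for r in reads:
        by_chrom.setdefault(r.chrom, []).append(r)
    arrays = {}
    for chrom, rs in by_chrom.items():
        starts = np.array([r.start for r in rs], dtype=np.int64)
        ends = np.array([r.end for r in rs], dtype=np.int64)
        order = np.argsort(starts, kind="stable")
        starts, ends = starts[order], ends[order]
        arrays[chrom] = (starts, ends, int((ends - starts).max()))
    for w in promoters:
        if w.chrom not in arrays:
            continue
        starts, ends, max_len = arrays[w.chrom]
        lo = np.searchsorted(starts, w.start - max_len, side="left")
        hi = np.searchsorted(starts, w.end, side="left")
        counts[w.gene_id] = int(np.count_nonzero(ends[lo:hi] > w.start))
    return counts


# ---------------------------------------------------------------------------
# Stage 4: Rx normalization
# ---------------------------------------------------------------------------

def rx_normalize(count: float, window_len: int, stats: LibraryStats) -> float:
    """Reads per kb of window per million spike-in reads:
    count * 1e9 / (window_len * n_spike)."""
    if stats.n_spike <= 0:
        raise NormalizationError(
            f"library {stats.library_id or '<unnamed>'}: no spike-in reads, cannot Rx-normalize"
        )
    if window_len <= 0:
        raise ValueError("window_len must be positive")
    return count * 1e9 / (window_len * stats.n_spike)


# ---------------------------------------------------------------------------
# Stage 5: input subtraction
# ---------------------------------------------------------------------------

def subtract_input(chip: SignalRecord, input_record: SignalRecord) -> float:
    """Net signal = ChIP rx_signal - input rx_signal; negatives are preserved
    (they motivate the absolute-value z-score denominator downstream)."""
    if chip.gene_id != input_record.gene_id:
        raise ValueError(
            f"gene mismatch: chip={chip.gene_id} input={input_record.gene_id}"
        )
    if chip.condition != input_record.condition:
        raise ValueError(
            f"condition mismatch: chip={chip.condition} input={input_record.condition}"
        )
    return chip.rx_signal - input_record.rx_signal


# ---------------------------------------------------------------------------
# Stage 6: replicate averaging
# ---------------------------------------------------------------------------

def average_replicates(records: Sequence[SignalRecord]) -> SignalRecord:
    """Arithmetic mean of the technical replicates of one (gene, mark,
    condition)."""
    if not records:
        raise ValueError("average_replicates requires at least one record")
    first = records[0]
    for r in records[1:]:
        if (r.gene_id, r.mark, r.condition) != (first.gene_id, first.mark, first.condition):
            raise ValueError("average_replicates: mixed gene/mark/condition")
    n = len(records)
    return SignalRecord(
        gene_id=first.gene_id,
        mark=first.mark,
        condition=first.condition,
        replicate="averaged",
        raw_count=sum(r.raw_count for r in records) / n,
        rx_signal=sum(r.rx_signal for r in records) / n,
        net_signal=sum(r.net_signal for r in records) / n,
    )


# ---------------------------------------------------------------------------
# Composed pipeline
# ---------------------------------------------------------------------------

def quantify_library(
    reads: Iterable[ReadInterval],
    promoters: Sequence[PromoterWindow],
    library_id: str = "",
    min_mq: int = DEFAULT_MIN_MAPQ,
    ext: int = DEFAULT_EXTENSION,
    extension_mode: str = "extend",
    dedup_ignore_strand: bool = False,
) -> tuple[dict[str, float], dict[str, int], LibraryStats]:
    """Run dedup -> MAPQ filter/extend -> count -> Rx for one library.

    Returns (rx_signal by gene, raw counts by gene, LibraryStats).
    """
    deduped, stats = dedup_reads(reads, library_id, ignore_strand=dedup_ignore_strand)
    filtered = filter_and_extend(deduped, min_mq=min_mq, ext=ext, mode=extension_mode)
    target = [r for r in filtered if r.species == "target"]
    spike = [r for r in filtered if r.species == "spikein"]
    stats.n_target = len(target)
    stats.n_spike = len(spike)
    stats.n_pass_mq = stats.n_target + stats.n_spike
    stats.validate()
    counts = window_counts(target, promoters)
    rx = {w.gene_id: rx_normalize(counts[w.gene_id], w.length, stats) for w in promoters}
    return rx, counts, stats


def quantify_libraries(
    libraries: Mapping[tuple, Iterable[ReadInterval]],
    promoters: Sequence[PromoterWindow],
    **kwargs,
) -> tuple[list[SignalRecord], dict[str, LibraryStats]]:
    """Quantify a mapping (condition, mark, replicate|"input") -> reads.

    For every (condition, mark), each ChIP replicate is Rx-normalized, the
    matching input library's rx signal is subtracted per gene, and the
    replicates are averaged. Returns per-replicate and averaged SignalRecords
    plus per-library stats.
    """
    rx_by_lib: dict[tuple, dict[str, float]] = {}
    counts_by_lib: dict[tuple, dict[str, int]] = {}
    all_stats: dict[str, LibraryStats] = {}
    for key, reads in libraries.items():
        lib_id = "_".join(str(k) for k in key)
        rx, counts, stats = quantify_library(reads, promoters, library_id=lib_id, **kwargs)
        rx_by_lib[key] = rx
        counts_by_lib[key] = counts
        all_stats[lib_id] = stats

    records: list[SignalRecord] = []
    pairs = sorted({(cond, mark) for cond, mark, _rep in rx_by_lib})
    for cond, mark in pairs:
        reps = sorted(rep for c, m, rep in rx_by_lib if (c, m) == (cond, mark) and rep != "input")
        input_rx = rx_by_lib.get((cond, mark, "input"))
        per_rep: list[SignalRecord] = []
        for rep in reps:
            rx = rx_by_lib[(cond, mark, rep)]
            counts = counts_by_lib[(cond, mark, rep)]
            for w in promoters:
                g = w.gene_id
                net = rx[g] - (input_rx[g] if input_rx is not None else 0.0)
                per_rep.append(
                    SignalRecord(
                        gene_id=g, mark=mark, condition=cond, replicate=rep,
                        raw_count=counts[g], rx_signal=rx[g], net_signal=net,
                    )
                )
        records.extend(per_rep)
        by_gene: dict[str, list[SignalRecord]] = {}
        for r in per_rep:
            by_gene.setdefault(r.gene_id, []).append(r)
        for g, rs in by_gene.items():
            records.append(average_replicates(rs))
    return records, all_stats


def averaged_net_by_gene(
    records: Iterable[SignalRecord], mark: str, condition: str
) -> dict[str, float]:
    """Convenience accessor: averaged net signal per gene for one
    (mark, condition)."""
    return {
        r.gene_id: r.net_signal
        for r in records
        if r.mark == mark and r.condition == condition and r.replicate == "averaged"
    }
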