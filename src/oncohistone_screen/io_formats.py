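"""Readers, writers and validated record types for every table the pipeline touches.

All genomic intervals are stored 0-based half-open. Variant positions are
1-based (VCF convention). Every writer prepends a ``#oncohistone-screen
v<version>`` comment line; every reader skips ``#`` comment lines.
"""

from __future__ import annotations

import dataclasses
import io
import os
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

import pandas as pd

from . import __version__

HEADER_COMMENT = f"#oncohistone-screen v{__version__}"

DEFAULT_SPIKEIN_PREFIX = "dmel_"


class FormatError(ValueError):
    """A file does not conform to the expected layout (bad column, bad field)."""


class ValidationError(ValueError):
    """A record violates a domain invariant (duplicate key, impossible counts)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

class Diagnosis(str, Enum):
    DE_NOVO_AML = "de_novo_aml"
    S_AML = "s_aml"
    REMISSION = "remission"
    OTHER = "other"


_DIAGNOSIS_ALIASES = {
    "de_novo_aml": Diagnosis.DE_NOVO_AML,
    "de_novo": Diagnosis.DE_NOVO_AML,
    "s_aml": Diagnosis.S_AML,
    "saml": Diagnosis.S_AML,
    "secondary_aml": Diagnosis.S_AML,
    "remission": Diagnosis.REMISSION,
}


def parse_diagnosis(text: str) -> Diagnosis:
    """Map a free-text diagnosis case-insensitively onto the enum.

    Strings naming a secondary AML ("AML secondary to myelofibrosis") map to
    s_aml; unknown strings map to ``other``.
    """
    key = str(text).strip().lower().replace("-", "_").replace(" ", "_")
    if key in _DIAGNOSIS_ALIASES:
        return _DIAGNOSIS_ALIASES[key]
    if "secondary" in key:
        return Diagnosis.S_AML
    return Diagnosis.OTHER


@dataclass(slots=True)
class CohortSample:
    """One patient sample: the unit of the cohort enrichment statistics."""

    sample_id: str
    diagnosis: Diagnosis
    cohort: str = ""
    h3_mutation: Optional[str] = None
    paired_with: Optional[str] = None
    k27_mutant: bool = False

    def __post_init__(self) -> None:
        if not isinstance(self.diagnosis, Diagnosis):
            self.diagnosis = parse_diagnosis(self.diagnosis)
        if self.h3_mutation is not None and not self.k27_mutant:
            self.k27_mutant = "K27" in self.h3_mutation
        if self.k27_mutant and not self.h3_mutation:
            raise ValidationError(
                f"sample {self.sample_id}: k27_mutant set without an h3_mutation"
            )


@dataclass(slots=True)
class VariantCall:
    """One variant observation with read support and caller provenance."""

    sample_id: str
    gene: str
    protein_change: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    alt_reads: Optional[int] = None
    depth: Optional[int] = None
    vaf: Optional[float] = None
    callers: frozenset = frozenset()
    assay: str = "targeted"

    def __post_init__(self) -> None:
        self.callers = frozenset(self.callers)
        if self.alt_reads is not None and self.depth is not None:
            if self.alt_reads > self.depth:
                raise ValidationError(
                    f"{self.key()}: alt_reads={self.alt_reads} exceeds depth={self.depth}"
                )
            recomputed = self.alt_reads / self.depth if self.depth else 0.0
            if self.vaf is not None and abs(self.vaf - recomputed) > 1e-9:
                # read counts are the record of truth
                self.vaf = recomputed
            elif self.vaf is None:
                self.vaf = recomputed
        if self.vaf is not None and not (0.0 <= self.vaf <= 1.0):
            raise ValidationError(f"{self.key()}: vaf={self.vaf} outside [0, 1]")
        if self.assay == "exome" and not self.callers:
            raise ValidationError(f"{self.key()}: exome call without caller labels")

    def key(self) -> tuple:
        return (self.sample_id, self.chrom, self.pos, self.ref, self.alt)

    def site(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(slots=True, frozen=True)
class ReadInterval:
    """One aligned read, 0-based half-open, tagged with its species of origin."""

    chrom: str
    start: int
    end: int
    strand: str
    mapq: int
    species: str = "target"  # "target" | "spikein"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError(f"read {self.chrom}:{self.start}-{self.end}: end <= start")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"read strand must be +/- not {self.strand!r}")


PROMOTER_HALF_WINDOW = 1500  # 3 kb bin centered on the TSS


@dataclass(slots=True, frozen=True)
class PromoterWindow:
    """A 3-kb promoter bin centered on a gene's transcription start site."""

    gene_id: str
    chrom: str
    tss: int  # 0-based
    strand: str
    start: int = dataclasses.field(default=-1)
    end: int = dataclasses.field(default=-1)

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < 0:
            object.__setattr__(self, "start", max(0, self.tss - PROMOTER_HALF_WINDOW))
            object.__setattr__(self, "end", self.tss + PROMOTER_HALF_WINDOW)
        if self.end <= self.start:
            raise ValidationError(f"promoter {self.gene_id}: empty window")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(slots=True)
class EngraftmentRecord:
    """Engraftment of one xenotransplanted mouse (percent human CD45+ cells)."""

    mouse_id: str
    group: str
    percent_engraftment: float
    cells_injected: Optional[int] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.percent_engraftment <= 100.0):
            raise ValidationError(
                f"mouse {self.mouse_id}: engraftment {self.percent_engraftment}% outside [0, 100]"
            )


# ---------------------------------------------------------------------------
# TSV helpers
# ---------------------------------------------------------------------------

def _read_tsv(path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    return df


def _write_tsv(df: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write(HEADER_COMMENT + "\n")
        df.to_csv(fh, sep="\t", index=False)


def _opt(text: str) -> Optional[str]:
    text = text.strip()
    return None if text in ("", "-", ".", "NA", "na") else text


# ---------------------------------------------------------------------------
# Sample sheets
# ---------------------------------------------------------------------------

def read_sample_sheet(path) -> list[CohortSample]:
    """Read a cohort sample sheet (TSV: sample_id, diagnosis, cohort,
    h3_mutation, paired_with)."""
    df = _read_tsv(path, ["sample_id", "diagnosis", "cohort", "h3_mutation", "paired_with"])
    samples: list[CohortSample] = []
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        sid = row.sample_id.strip()
        if sid in seen:
            raise ValidationError(f"{path}: duplicate sample_id '{sid}'")
        seen.add(sid)
        samples.append(
            CohortSample(
                sample_id=sid,
                diagnosis=parse_diagnosis(row.diagnosis),
                cohort=row.cohort.strip(),
                h3_mutation=_opt(row.h3_mutation),
                paired_with=_opt(row.paired_with),
            )
        )
    return samples


def write_sample_sheet(samples: Iterable[CohortSample], path) -> None:
    df = pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "diagnosis": s.diagnosis.value,
                "cohort": s.cohort,
                "h3_mutation": s.h3_mutation or "-",
                "paired_with": s.paired_with or "-",
            }
            for s in samples
        ],
        columns=["sample_id", "diagnosis", "cohort", "h3_mutation", "paired_with"],
    )
    _write_tsv(df, path)


# ---------------------------------------------------------------------------
# Variant tables (TSV or minimal VCF dialect)
# ---------------------------------------------------------------------------

_VARIANT_COLUMNS = [
    "sample_id", "gene", "protein_change", "chrom", "pos", "ref", "alt",
    "alt_reads", "depth", "vaf", "callers",
]


def _to_int(text: str, what: str, path) -> Optional[int]:
    text = text.strip()
    if text in ("", "-", "."):
        return None
    try:
        return int(text)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric {what} '{text}'") from exc


def _to_float(text: str, what: str, path) -> Optional[float]:
    text = text.strip()
    if text in ("", "-", "."):
        return None
    try:
        return float(text)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric {what} '{text}'") from exc


def _looks_like_vcf(path) -> bool:
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                return True
            if line.startswith("#CHROM"):
                return True
            if line.startswith("#"):
                continue
            return False
    return False


def read_variant_table(path, assay: str = "targeted") -> list[VariantCall]:
    """Read variant calls from a TSV or the minimal VCF dialect.

    The VCF dialect uses INFO keys ``AD=alt,ref`` (alternate count first),
    ``CALLERS=a,b``, and optionally ``SAMPLE=``, ``GENE=``, ``PCHANGE=``,
    ``VAF=``. VAF is recomputed from read counts whenever both are present.
    """
    if assay not in ("targeted", "exome"):
        raise ValueError(f"unknown assay '{assay}'")
    if _looks_like_vcf(path):
        return _read_variant_vcf(path, assay)
    df = _read_tsv(path, ["sample_id", "chrom", "pos", "ref", "alt"])
    calls = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        callers = _opt(d.get("callers", "")) or ""
        calls.append(
            VariantCall(
                sample_id=d["sample_id"].strip(),
                gene=d.get("gene", "").strip(),
                protein_change=d.get("protein_change", "").strip(),
                chrom=d["chrom"].strip(),
                pos=_to_int(d["pos"], "pos", path),
                ref=d["ref"].strip(),
                alt=d["alt"].strip(),
                alt_reads=_to_int(d.get("alt_reads", ""), "alt_reads", path),
                depth=_to_int(d.get("depth", ""), "depth", path),
                vaf=_to_float(d.get("vaf", ""), "vaf", path),
                callers=frozenset(c for c in callers.split(",") if c),
                assay=assay,
            )
        )
    return calls


def _read_variant_vcf(path, assay: str) -> list[VariantCall]:
    calls = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise FormatError(f"{path}:{lineno}: expected 8 VCF columns")
            chrom, pos, _id, ref, alt, _qual, _filt, info = fields[:8]
            kv = {}
            for item in info.split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    kv[k] = v
            alt_reads = depth = vaf = None
            if "AD" in kv:
                parts = kv["AD"].split(",")
                if len(parts) != 2:
                    raise FormatError(f"{path}:{lineno}: AD must be 'alt,ref'")
                alt_reads = _to_int(parts[0], "AD alt", path)
                ref_reads = _to_int(parts[1], "AD ref", path)
                depth = alt_reads + ref_reads
            if "VAF" in kv:
                vaf = _to_float(kv["VAF"], "VAF", path)
            callers = frozenset(
                c for c in kv.get("CALLERS", "").split(",") if c
            )
            calls.append(
                VariantCall(
                    sample_id=kv.get("SAMPLE", ""),
                    gene=kv.get("GENE", ""),
                    protein_change=kv.get("PCHANGE", ""),
                    chrom=chrom,
                    pos=_to_int(pos, "POS", path),
                    ref=ref,
                    alt=alt,
                    alt_reads=alt_reads,
                    depth=depth,
                    vaf=vaf,
                    callers=callers,
                    assay=assay,
                )
            )
    return calls


def write_variant_table(calls: Iterable[VariantCall], path) -> None:
    df = pd.DataFrame(
        [
            {
                "sample_id": c.sample_id,
                "gene": c.gene,
                "protein_change": c.protein_change,
                "chrom": c.chrom,
                "pos": c.pos,
                "ref": c.ref,
                "alt": c.alt,
                "alt_reads": "-" if c.alt_reads is None else c.alt_reads,
                "depth": "-" if c.depth is None else c.depth,
                "vaf": "-" if c.vaf is None else repr(c.vaf),
                "callers": ",".join(sorted(c.callers)) or "-",
            }
            for c in calls
        ],
        columns=_VARIANT_COLUMNS,
    )
    _write_tsv(df, path)


# ---------------------------------------------------------------------------
# BED reads
# ---------------------------------------------------------------------------

def read_bed_reads(path, spikein_chrom_prefix: str = DEFAULT_SPIKEIN_PREFIX) -> list[ReadInterval]:
    """Read aligned-read intervals from BED6; the score column carries MAPQ.

    Chromosomes whose name begins with ``spikein_chrom_prefix`` are tagged
    species="spikein"; everything else is "target".
    """
    reads = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise FormatError(f"{path}:{lineno}: expected 6 BED columns")
            chrom, start, end, _name, score, strand = fields[:6]
            start_i = _to_int(start, "start", path)
            end_i = _to_int(end, "end", path)
            if end_i <= start_i:
                raise FormatError(f"{path}:{lineno}: end <= start ({start_i}, {end_i})")
            if strand not in ("+", "-"):
                raise FormatError(f"{path}:{lineno}: strand must be +/- not {strand!r}")
            species = "spikein" if chrom.startswith(spikein_chrom_prefix) else "target"
            reads.append(
                ReadInterval(
                    chrom=chrom, start=start_i, end=end_i, strand=strand,
                    mapq=_to_int(score, "mapq", path), species=species,
                )
            )
    return reads


def write_bed_reads(reads: Iterable[ReadInterval], path) -> None:
    with open(path, "w") as fh:
        fh.write(HEADER_COMMENT + "\n")
        for i, r in enumerate(reads):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\tr{i}\t{r.mapq}\t{r.strand}\n")


# ---------------------------------------------------------------------------
# Promoter windows
# ---------------------------------------------------------------------------

def read_promoters(path) -> list[PromoterWindow]:
    """Read promoter windows from a TSV (gene_id, chrom, tss, strand) or from
    BED6 gene intervals.

    For BED gene input the strand-correct TSS is derived here: plus-strand
    TSS = start, minus-strand TSS = end. Windows are [tss-1500, tss+1500),
    clipped at 0.
    """
    with open(path) as fh:
        first = ""
        for line in fh:
            if not line.startswith("#"):
                first = line
                break
    if "gene_id" in first.split():
        df = _read_tsv(path, ["gene_id", "chrom", "tss", "strand"])
        raw = [
            (r.gene_id.strip(), r.chrom.strip(), _to_int(r.tss, "tss", path), r.strand.strip())
            for r in df.itertuples(index=False)
        ]
    else:
        raw = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#") or line.startswith("track"):
                    continue
                fields = line.split()
                if len(fields) < 6:
                    raise FormatError(f"{path}:{lineno}: expected 6 BED columns for genes")
                chrom, start, end, gene_id, _score, strand = fields[:6]
                start_i = _to_int(start, "start", path)
                end_i = _to_int(end, "end", path)
                tss = start_i if strand == "+" else end_i
                raw.append((gene_id, chrom, tss, strand))
    windows = []
    seen: set[str] = set()
    for gene_id, chrom, tss, strand in raw:
        if gene_id in seen:
            raise ValidationError(f"{path}: duplicate gene_id '{gene_id}'")
        seen.add(gene_id)
        if strand not in ("+", "-"):
            raise FormatError(f"{path}: gene {gene_id}: strand must be +/-")
        windows.append(PromoterWindow(gene_id=gene_id, chrom=chrom, tss=tss, strand=strand))
    return windows


def write_promoters(windows: Iterable[PromoterWindow], path) -> None:
    df = pd.DataFrame(
        [
            {"gene_id": w.gene_id, "chrom": w.chrom, "tss": w.tss, "strand": w.strand}
            for w in windows
        ],
        columns=["gene_id", "chrom", "tss", "strand"],
    )
    _write_tsv(df, path)


# ---------------------------------------------------------------------------
# Expression and engraftment tables
# ---------------------------------------------------------------------------

def read_expression_table(path) -> pd.DataFrame:
    """Read a tidy per-replicate RPKM table (gene_id, condition, replicate, rpkm)."""
    df = _read_tsv(path, ["gene_id", "condition", "replicate", "rpkm"])
    df["rpkm"] = df["rpkm"].astype(float)
    if (df["rpkm"] < 0).any():
        raise ValidationError(f"{path}: negative RPKM value")
    return df


def write_expression_table(df: pd.DataFrame, path) -> None:
    _write_tsv(df[["gene_id", "condition", "replicate", "rpkm"]], path)


def read_engraftment_table(path) -> list[EngraftmentRecord]:
    df = _read_tsv(path, ["mouse_id", "group", "percent_engraftment"])
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        records.append(
            EngraftmentRecord(
                mouse_id=d["mouse_id"].strip(),
                group=d["group"].strip(),
                percent_engraftment=_to_float(d["percent_engraftment"], "percent", path),
                cells_injected=_to_int(d.get("cells_injected", ""), "cells_injected", path),
            )
        )
    if not records:
        raise ValidationError(f"{path}: empty engraftment table")
    return records


def write_engraftment_table(records: Iterable[EngraftmentRecord], path) -> None:
    df = pd.DataFrame(
        [
            {
                "mouse_id": r.mouse_id,
                "group": r.group,
                "percent_engraftment": repr(r.percent_engraftment),
                "cells_injected": "-" if r.cells_injected is None else r.cells_injected,
            }
            for r in records
        ],
        columns=["mouse_id", "group", "percent_engraftment", "cells_injected"],
    )
    _write_tsv(df, path)
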