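"""Variant retention rules and VAF-based clonality classification.

Targeted (amplicon) calls are retained when VAF >= 10% with >= 20 alternate
reads; exome calls when >= 2 of 3 callers agree and the best-supported
observation reaches 20% VAF. Clonality is read off the allele frequencies: a
diagnosis variant re-detected in the paired remission sample marks a
pre-leukemic clone, and a diagnosis VAF near the heterozygous band marks the
major leukemic clone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional

from .io_formats import ValidationError, VariantCall


@dataclass
class ScreenConfig:
    targeted_min_vaf: float = 0.10
    targeted_min_alt: int = 20
    exome_min_callers: int = 2
    exome_min_support: float = 0.20
    blacklist: frozenset = frozenset()  # {(chrom, pos, ref, alt)}
    major_clone_min_vaf: float = 0.35
    detect_min_vaf: float = 0.10

    def __post_init__(self) -> None:
        self.blacklist = frozenset(self.blacklist)
        for name in ("targeted_min_vaf", "exome_min_support",
                     "major_clone_min_vaf", "detect_min_vaf"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")


class ClonalityStatus(str, Enum):
    PRE_LEUKEMIC = "pre_leukemic"
    LEUKEMIA_RESTRICTED = "leukemia_restricted"
    UNDETERMINED = "undetermined"


class CloneClass(str, Enum):
    MAJOR = "major"
    MINOR = "minor"


@dataclass(slots=True)
class ClonalityCall:
    variant: str
    status: ClonalityStatus
    clone_class: CloneClass
    dx_vaf: float
    remission_vaf: Optional[float] = None


def filter_targeted_variants(
    calls: Iterable[VariantCall], config: ScreenConfig = ScreenConfig()
) -> list[VariantCall]:
    """Retain targeted calls with VAF >= targeted_min_vaf, alt reads >=
    targeted_min_alt, and site not blacklisted. Order is preserved."""
    retained = []
    for call in calls:
        if call.assay != "targeted":
            raise ValueError(
                f"filter_targeted_variants applied to assay={call.assay!r} call"
            )
        if call.vaf is None or call.alt_reads is None:
            raise ValidationError(f"{call.key()}: targeted call lacks vaf or alt_reads")
        if (
            call.vaf >= config.targeted_min_vaf
            and call.alt_reads >= config.targeted_min_alt
            and call.site() not in config.blacklist
        ):
            retained.append(call)
    return retained


def consensus_exome_calls(
    calls_by_caller: Mapping[str, Iterable[VariantCall]],
    config: ScreenConfig = ScreenConfig(),
) -> list[VariantCall]:
    """Merge per-caller exome call lists into consensus calls.

    A variant (keyed by sample, chrom, pos, ref, alt) is emitted iff it was
    called by >= exome_min_callers callers and its maximum reported VAF is >=
    exome_min_support. The emitted record carries the union of caller labels
    and the read counts of the maximum-depth observation.
    """
    if not calls_by_caller:
        raise ValueError("consensus_exome_calls requires a non-empty caller mapping")
    if len(calls_by_caller) < config.exome_min_callers:
        raise ValueError(
            f"need >= {config.exome_min_callers} caller lists, got {len(calls_by_caller)}"
        )
    by_key: dict[tuple, list[tuple[str, VariantCall]]] = {}
    order: list[tuple] = []
    for caller, calls in calls_by_caller.items():
        for call in calls:
            key = call.key()
            if key not in by_key:
                by_key[key] = []
                order.append(key)
            by_key[key].append((caller, call))

    consensus = []
    for key in order:
        obs = by_key[key]
        callers = {caller for caller, _ in obs}
        if len(callers) < config.exome_min_callers:
            continue
        max_vaf = max((c.vaf for _, c in obs if c.vaf is not None), default=0.0)
        if max_vaf < config.exome_min_support:
            continue
        best = max(obs, key=lambda item: item[1].depth or 0)[1]
        consensus.append(
            VariantCall(
                sample_id=best.sample_id,
                gene=best.gene,
                protein_change=best.protein_change,
                chrom=best.chrom,
                pos=best.pos,
                ref=best.ref,
                alt=best.alt,
                alt_reads=best.alt_reads,
                depth=best.depth,
                vaf=best.vaf,
                callers=frozenset(callers) | best.callers,
                assay="exome",
            )
        )
    return consensus


def _variant_label(call: VariantCall) -> str:
    if call.gene and call.protein_change:
        return f"{call.gene} {call.protein_change}"
    return f"{call.chrom}:{call.pos}:{call.ref}>{call.alt}"


def classify_clonality(
    dx: Iterable[VariantCall],
    remission: Optional[Iterable[VariantCall]] = None,
    config: ScreenConfig = ScreenConfig(),
) -> list[ClonalityCall]:
    """Classify each diagnosis variant by clonality.

    pre_leukemic: a matching remission call exists with VAF >= detect_min_vaf
    (the mutation survived remission, so it arose in a pre-leukemic HSC);
    leukemia_restricted: a remission sample was screened and the variant was
    absent; undetermined: no remission sample. clone_class is major iff the
    diagnosis VAF >= major_clone_min_vaf.
    """
    dx = list(dx)
    if not dx:
        raise ValueError("classify_clonality requires at least one diagnosis variant")
    rem_by_site: dict[tuple, VariantCall] = {}
    if remission is not None:
        for call in remission:
            rem_by_site[call.site()] = call

    results = []
    for call in dx:
        dx_vaf = call.vaf or 0.0
        rem_vaf: Optional[float] = None
        if remission is None:
            status = ClonalityStatus.UNDETERMINED
        else:
            match = rem_by_site.get(call.site())
            if match is not None and (match.vaf or 0.0) >= config.detect_min_vaf:
                status = ClonalityStatus.PRE_LEUKEMIC
                rem_vaf = match.vaf
            else:
                status = ClonalityStatus.LEUKEMIA_RESTRICTED
        clone = (
            CloneClass.MAJOR if dx_vaf >= config.major_clone_min_vaf else CloneClass.MINOR
        )
        results.append(
            ClonalityCall(
                variant=_variant_label(call),
                status=status,
                clone_class=clone,
                dx_vaf=dx_vaf,
                remission_vaf=rem_vaf,
            )
        )
    return results
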