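"""Synthetic cohorts, ChIP-Rx read sets, expression tables and engraftment tables.

Every generator is a pure function of its :class:`SimulationConfig` (including
the seed) and also emits a planted-truth table, so downstream recovery,
calibration and invariance tests run without any external data.

The generated data emulate a two-cohort AML sample set with rare H3 mutants at
heterozygous-like allele frequencies, ChIP libraries carrying a fixed 2%
Drosophila spike-in, a global loss of promoter H3K27me3 in mutant conditions
with extra loss at planted upregulated genes, promoter H3K27ac gain at the
same planted genes, triplicate RNA RPKM with planted fold changes, and
two-group engraftment percentages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    CohortSample,
    Diagnosis,
    EngraftmentRecord,
    PromoterWindow,
    ReadInterval,
    VariantCall,
)


class ConfigError(ValueError):
    """A simulation configuration is internally inconsistent."""


KNOWN_CONDITIONS = ("WT", "K27M", "K27I")
MARKS = ("K27me3", "K27ac")

# sub-stream labels so each generator draws from an independent stream of the
# same seed
_STREAM_COHORT = 1
_STREAM_CHIP = 2
_STREAM_GENES = 3
_STREAM_EXPR = 4
_STREAM_ENGRAFT = 5
_STREAM_INTENSITY = 6


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults mirror the study design: 434 samples of which 7.6% are s-AML,
    seven H3-mutant samples (three of them s-AML) with true VAF uniform in
    [0.40, 0.55] at ~7000x targeted coverage, 2% spike-in chromatin, 50-bp
    single-end reads, two ChIP technical replicates, triplicate RNA, and a
    halving of promoter H3K27me3 in mutant conditions.
    """

    seed: int = 0
    # cohort / variants
    n_samples: int = 434
    saml_frac: float = 0.076
    n_h3_mutant: int = 7
    mutant_saml_frac: float = 3 / 7
    depth_mean: int = 7000
    # ChIP-Rx
    spike_frac: float = 0.02
    reads_per_library: int = 100_000
    me3_global_loss: float = 0.5
    ac_gain: float = 2.0
    planted_me3_factor: float = 0.5  # extra me3 loss at planted up-genes
    bg_frac: float = 0.30  # uniform-background fraction of each library
    n_chip_replicates: int = 2
    read_len: int = 50
    tss_spacing: int = 10_000
    intensity_sdlog: float = 0.5  # per-gene lognormal spread of ChIP intensity
    low_mapq_frac: float = 0.03
    spike_chrom: str = "dmel_2L"
    spike_chrom_len: int = 1_000_000
    target_chrom: str = "chr1"
    # expression
    n_genes: int = 200
    frac_up: float = 0.10
    expr_effect: float = 4.0
    expr_cv: float = 0.10
    n_replicates: int = 3
    rpkm_meanlog: float = math.log(30.0)
    rpkm_sdlog: float = 1.0
    # engraftment
    engraft_group_means: Mapping[str, float] = field(
        default_factory=lambda: {"WT": 0.6, "MUT": 30.0}
    )
    engraft_sd: float = 5.0
    n_mice_per_group: int = 6
    # replace all sampling with (rounded) expectations
    deterministic: bool = False

    def __post_init__(self) -> None:
        for name in ("saml_frac", "mutant_saml_frac", "spike_frac", "frac_up",
                     "expr_cv", "bg_frac", "low_mapq_frac"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if self.me3_global_loss <= 0:
            raise ConfigError("me3_global_loss must be positive")
        if self.n_h3_mutant > self.n_samples:
            raise ConfigError("n_h3_mutant exceeds n_samples")
        if self.expr_effect < 1.0:
            raise ConfigError("expr_effect must be >= 1")
        if self.spike_frac + self.bg_frac >= 1.0:
            raise ConfigError("spike_frac + bg_frac must leave room for signal reads")

    def rng(self, *stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), *stream])


# ---------------------------------------------------------------------------
# Gene universe and planted sets (shared across ChIP and RNA generators)
# ---------------------------------------------------------------------------

def gene_ids(config: SimulationConfig) -> list[str]:
    width = len(str(config.n_genes))
    return [f"G{i + 1:0{width}d}" for i in range(config.n_genes)]


def promoter_windows(config: SimulationConfig) -> list[PromoterWindow]:
    """One promoter per gene, TSSs evenly spaced along a synthetic chromosome."""
    return [
        PromoterWindow(
            gene_id=g,
            chrom=config.target_chrom,
            tss=config.tss_spacing * (i + 1),
            strand="+",
        )
        for i, g in enumerate(gene_ids(config))
    ]


def planted_gene_sets(config: SimulationConfig) -> tuple[set[str], set[str]]:
    """(up, down) planted gene sets; disjoint, chosen by the seed alone."""
    k = round(config.n_genes * config.frac_up)
    if 2 * k > config.n_genes:
        raise ConfigError("frac_up > 0.5: up and down sets must be disjoint")
    genes = gene_ids(config)
    perm = config.rng(_STREAM_GENES).permutation(config.n_genes)
    up = {genes[i] for i in perm[:k]}
    down = {genes[i] for i in perm[k:2 * k]}
    return up, down


# ---------------------------------------------------------------------------
# Cohort + variants
# ---------------------------------------------------------------------------

H3_MUTATION_POOL = [
    ("HIST1H3F", "K27I"),
    ("HIST1H3H", "K27M"),
    ("HIST1H3A", "Q69H"),
    ("H3F3A", "A26P"),
    ("H3F3A", "K27M"),
    ("H3F3C", "R2Q"),
    ("H3F3C", "R8H"),
]

TRUE_VAF_RANGE = (0.40, 0.55)


@dataclass
class CohortSim:
    samples: list[CohortSample]
    variants: list[VariantCall]
    truth: pd.DataFrame  # sample_id, gene, protein_change, true_vaf, is_saml


def simulate_cohort(config: SimulationConfig) -> CohortSim:
    """Simulate a two-cohort AML sample set with rare, high-VAF H3 mutants.

    Exactly ``round(n_samples * saml_frac)`` samples are labeled s-AML and
    ``round(n_h3_mutant * mutant_saml_frac)`` of the H3-mutant samples are
    assigned to the s-AML group. Alternate-read counts are Binomial(depth,
    true VAF) with true VAF uniform in [0.40, 0.55].
    """
    n_saml = round(config.n_samples * config.saml_frac)
    n_mut_saml = round(config.n_h3_mutant * config.mutant_saml_frac)
    if n_mut_saml > n_saml:
        raise ConfigError(
            f"{n_mut_saml} mutant s-AML samples requested but only {n_saml} s-AML samples"
        )
    if config.n_h3_mutant - n_mut_saml > config.n_samples - n_saml:
        raise ConfigError("more non-s-AML mutants than non-s-AML samples")

    rng = config.rng(_STREAM_COHORT)
    width = len(str(config.n_samples))
    ids = [f"S{i + 1:0{width}d}" for i in range(config.n_samples)]
    diagnoses = [Diagnosis.S_AML] * n_saml + [Diagnosis.DE_NOVO_AML] * (config.n_samples - n_saml)
    cohorts = ["Beirut" if i < round(config.n_samples * 122 / 434) else "Toronto"
               for i in range(config.n_samples)]

    saml_idx = [i for i, d in enumerate(diagnoses) if d is Diagnosis.S_AML]
    other_idx = [i for i, d in enumerate(diagnoses) if d is not Diagnosis.S_AML]
    if config.deterministic:
        mutant_idx = saml_idx[:n_mut_saml] + other_idx[: config.n_h3_mutant - n_mut_saml]
    else:
        mutant_idx = list(rng.choice(saml_idx, size=n_mut_saml, replace=False)) + list(
            rng.choice(other_idx, size=config.n_h3_mutant - n_mut_saml, replace=False)
        )

    mutations = {
        idx: H3_MUTATION_POOL[k % len(H3_MUTATION_POOL)]
        for k, idx in enumerate(mutant_idx)
    }
    samples = [
        CohortSample(
            sample_id=ids[i],
            diagnosis=diagnoses[i],
            cohort=cohorts[i],
            h3_mutation=f"{mutations[i][0]} {mutations[i][1]}" if i in mutations else None,
        )
        for i in range(config.n_samples)
    ]

    lo, hi = TRUE_VAF_RANGE
    variants: list[VariantCall] = []
    truth_rows = []
    for k, idx in enumerate(mutant_idx):
        gene, pchange = mutations[idx]
        if config.deterministic:
            true_vaf = (lo + hi) / 2
            depth = config.depth_mean
            alt = round(depth * true_vaf)
        else:
            true_vaf = float(rng.uniform(lo, hi))
            depth = max(1, int(rng.poisson(config.depth_mean)))
            alt = int(rng.binomial(depth, true_vaf))
        variants.append(
            VariantCall(
                sample_id=ids[idx],
                gene=gene,
                protein_change=pchange,
                chrom="chr6",
                pos=26_000_000 + 100 * k,
                ref="A",
                alt="T",
                alt_reads=alt,
                depth=depth,
                assay="targeted",
            )
        )
        truth_rows.append(
            {
                "sample_id": ids[idx],
                "gene": gene,
                "protein_change": pchange,
                "true_vaf": true_vaf,
                "is_saml": diagnoses[idx] is Diagnosis.S_AML,
            }
        )
    truth = pd.DataFrame(
        truth_rows, columns=["sample_id", "gene", "protein_change", "true_vaf", "is_saml"]
    )
    return CohortSim(samples=samples, variants=variants, truth=truth)


# ---------------------------------------------------------------------------
# ChIP-Rx read sets
# ---------------------------------------------------------------------------

@dataclass
class ChipRxSim:
    libraries: dict  # (condition, mark, replicate|"input") -> list[ReadInterval]
    promoters: list[PromoterWindow]
    truth: pd.DataFrame  # gene_id, planted, per-condition intensity factors


def _gene_intensity_weights(config: SimulationConfig, stream: int) -> np.ndarray:
    """Per-gene lognormal intensity weights, normalized to sum to 1; drawn from
    a stream shared by all libraries so a gene keeps its intensity across
    conditions and replicates."""
    rng = config.rng(_STREAM_INTENSITY, stream)
    if config.deterministic:
        w = np.ones(config.n_genes)
    else:
        w = rng.lognormal(mean=0.0, sigma=config.intensity_sdlog, size=config.n_genes)
    return w / w.sum()


def _condition_factors(
    config: SimulationConfig, mark: str, condition: str,
    up: set[str], down: set[str], genes: Sequence[str],
) -> np.ndarray:
    """Multiplicative per-gene intensity factor for one (condition, mark)."""
    if condition == "WT":
        return np.ones(len(genes))
    factors = np.ones(len(genes))
    for i, g in enumerate(genes):
        if mark == "K27me3":
            if g in up:
                # planted upregulated genes lose the repressive mark hardest
                factors[i] = config.me3_global_loss * config.planted_me3_factor
            elif g in down:
                # planted downregulated genes retain their H3K27me3
                factors[i] = 1.0
            else:
                factors[i] = config.me3_global_loss
        else:  # K27ac
            factors[i] = config.ac_gain if g in up else 1.0
    return factors


def _place_reads(
    rng: np.random.Generator, config: SimulationConfig, chrom: str,
    lo: int, hi: int, n: int, species: str,
) -> list[ReadInterval]:
    """n single-end reads of read_len bp with 5' starts uniform in [lo, hi)."""
    if n <= 0 or hi <= lo:
        return []
    if config.deterministic:
        starts = np.linspace(lo, hi - 1, n).astype(int)
        strands = ["+"] * n
        mapqs = np.full(n, 60)
    else:
        starts = rng.integers(lo, hi, size=n)
        strands = np.where(rng.random(n) < 0.5, "+", "-")
        mapqs = np.where(rng.random(n) < config.low_mapq_frac, 3, 60)
    L = config.read_len
    return [
        ReadInterval(chrom=chrom, start=int(s), end=int(s) + L,
                     strand=str(st), mapq=int(q), species=species)
        for s, st, q in zip(starts, strands, mapqs)
    ]


def _library_reads(
    config: SimulationConfig, condition: str, mark: str, rep: str,
    lam: Optional[np.ndarray], windows: Sequence[PromoterWindow], stream: Sequence[int],
) -> list[ReadInterval]:
    """One library: spike-in + uniform background + (for ChIP) promoter signal."""
    rng = config.rng(_STREAM_CHIP, *stream)
    genome_len = config.tss_spacing * (config.n_genes + 1) + 2 * config.read_len
    reads: list[ReadInterval] = []

    n_spike_exp = config.spike_frac * config.reads_per_library
    n_bg_exp = config.bg_frac * config.reads_per_library
    if config.deterministic:
        n_spike = round(n_spike_exp)
        n_bg = round(n_bg_exp)
    else:
        n_spike = int(rng.binomial(config.reads_per_library, config.spike_frac))
        n_bg = int(rng.poisson(n_bg_exp))
    reads += _place_reads(rng, config, config.spike_chrom, 0,
                          config.spike_chrom_len - config.read_len, n_spike, "spikein")
    reads += _place_reads(rng, config, config.target_chrom, 0,
                          genome_len - config.read_len, n_bg, "target")
    if lam is not None:
        if config.deterministic:
            counts = np.round(lam).astype(int)
        else:
            counts = rng.poisson(lam)
        for w, n in zip(windows, counts):
            reads += _place_reads(
                rng, config, w.chrom, w.start, w.end - config.read_len, int(n), "target"
            )
    return reads


def simulate_chiprx(
    config: SimulationConfig,
    conditions: Sequence[str] = ("WT", "K27M"),
    marks: Sequence[str] = MARKS,
) -> ChipRxSim:
    """Simulate ChIP-Rx libraries for WT and mutant conditions.

    Each library carries ``spike_frac * reads_per_library`` spike-in reads
    (condition-independent — the premise of Rx normalization), a uniform
    background, and, for ChIP (not input) libraries, promoter-window signal
    with per-gene Poisson intensity. Mutant H3K27me3 intensities are scaled by
    ``me3_global_loss`` (times ``planted_me3_factor`` at planted up-genes;
    planted down-genes retain their signal); mutant H3K27ac gains ``ac_gain``
    at planted up-genes. Two technical replicates plus one input per
    (condition, mark).
    """
    if "WT" not in conditions or len(conditions) < 2:
        raise ConfigError("conditions must include 'WT' and at least one mutant label")
    for c in conditions:
        if c not in KNOWN_CONDITIONS:
            raise ConfigError(f"unknown condition label '{c}' (known: {KNOWN_CONDITIONS})")
    for m in marks:
        if m not in MARKS:
            raise ConfigError(f"unknown mark '{m}' (known: {MARKS})")

    genes = gene_ids(config)
    windows = promoter_windows(config)
    up, down = planted_gene_sets(config)
    signal_budget = (1.0 - config.spike_frac - config.bg_frac) * config.reads_per_library

    libraries: dict = {}
    truth_rows = {g: {"gene_id": g,
                      "planted": "up" if g in up else ("down" if g in down else "none")}
                  for g in genes}
    for mi, mark in enumerate(marks):
        weights = _gene_intensity_weights(config, mi)
        base_lam = weights * signal_budget
        for ci, condition in enumerate(conditions):
            factors = _condition_factors(config, mark, condition, up, down, genes)
            lam = base_lam * factors
            for g, f in zip(genes, factors):
                truth_rows[g][f"{mark}_{condition}_factor"] = f
            for ri in range(config.n_chip_replicates):
                rep = f"rep{ri + 1}"
                libraries[(condition, mark, rep)] = _library_reads(
                    config, condition, mark, rep, lam, windows, (mi, ci, ri)
                )
            libraries[(condition, mark, "input")] = _library_reads(
                config, condition, mark, "input", None, windows, (mi, ci, 99)
            )
    truth = pd.DataFrame(list(truth_rows.values()))
    return ChipRxSim(libraries=libraries, promoters=windows, truth=truth)


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

@dataclass
class ExpressionSim:
    table: pd.DataFrame  # tidy: gene_id, condition, replicate, rpkm
    truth: pd.DataFrame  # gene_id, planted, true_fold


def simulate_expression(
    config: SimulationConfig, conditions: Sequence[str] = ("WT", "MUT")
) -> ExpressionSim:
    """Simulate per-replicate RPKM with planted up/down fold changes.

    Baselines are log-normal across genes; planted up-genes are multiplied by
    ``expr_effect`` in the mutant condition, the disjoint planted down set is
    divided by it; replicate noise is multiplicative Gaussian with CV
    ``expr_cv`` (floored at zero).
    """
    if len(conditions) != 2:
        raise ConfigError("simulate_expression expects exactly (WT, mutant) conditions")
    up, down = planted_gene_sets(config)  # raises if frac_up > 0.5
    genes = gene_ids(config)
    rng = config.rng(_STREAM_EXPR)
    if config.deterministic:
        baseline = np.full(config.n_genes, math.exp(config.rpkm_meanlog))
    else:
        baseline = rng.lognormal(config.rpkm_meanlog, config.rpkm_sdlog, config.n_genes)

    wt_cond, mut_cond = conditions
    fold = np.array(
        [config.expr_effect if g in up else (1.0 / config.expr_effect if g in down else 1.0)
         for g in genes]
    )
    rows = []
    for cond, means in ((wt_cond, baseline), (mut_cond, baseline * fold)):
        for r in range(config.n_replicates):
            if config.deterministic:
                values = means
            else:
                values = means * (1.0 + config.expr_cv * rng.standard_normal(config.n_genes))
                values = np.clip(values, 0.0, None)
            for g, v in zip(genes, values):
                rows.append({"gene_id": g, "condition": cond,
                             "replicate": f"rep{r + 1}", "rpkm": float(v)})
    table = pd.DataFrame(rows, columns=["gene_id", "condition", "replicate", "rpkm"])
    truth = pd.DataFrame(
        {
            "gene_id": genes,
            "planted": ["up" if g in up else ("down" if g in down else "none") for g in genes],
            "true_fold": fold,
        }
    )
    return ExpressionSim(table=table, truth=truth)


# ---------------------------------------------------------------------------
# Engraftment
# ---------------------------------------------------------------------------

@dataclass
class EngraftmentSim:
    records: list[EngraftmentRecord]
    truth: pd.DataFrame  # group, true_mean, sd


def simulate_engraftment(
    config: SimulationConfig, groups: Optional[Sequence[str]] = None
) -> EngraftmentSim:
    """Simulate per-mouse percent engraftment: Normal(group mean, engraft_sd)
    truncated to [0, 100]."""
    means = dict(config.engraft_group_means)
    if groups is None:
        groups = list(means)
    for g in groups:
        if g not in means:
            raise ConfigError(f"unknown engraftment group '{g}' (known: {sorted(means)})")
    rng = config.rng(_STREAM_ENGRAFT)
    records = []
    for g in groups:
        if config.deterministic:
            values = np.full(config.n_mice_per_group, means[g])
        else:
            values = means[g] + config.engraft_sd * rng.standard_normal(config.n_mice_per_group)
        values = np.clip(values, 0.0, 100.0)
        for i, v in enumerate(values):
            records.append(
                EngraftmentRecord(mouse_id=f"{g}_m{i + 1}", group=g, percent_engraftment=float(v))
            )
    truth = pd.DataFrame(
        {"group": list(groups), "true_mean": [means[g] for g in groups],
         "sd": [config.engraft_sd] * len(groups)}
    )
    return EngraftmentSim(records=records, truth=truth)
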