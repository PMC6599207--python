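# Methods

## Scope and data model

The package operates on five validated record families: cohort samples
(diagnosis class, H3 mutation annotation), variant calls (read support,
caller provenance, 1-based positions), aligned-read intervals (0-based
half-open, MAPQ, a target/spike-in species tag), 3-kb promoter windows
centered on the TSS, and per-gene signal/expression/engraftment records.
All external tables are TSV (or BED6, or a minimal VCF dialect with
`AD=alt,ref` and `CALLERS=` INFO keys); writers prepend a
`#oncohistone-screen v<version>` comment. Spike-in reads are identified by a
chromosome-name prefix (default `dmel_`), which keeps a single BED stream
per library; minus-strand gene TSSs are taken as the BED end coordinate.
When both read counts are present the VAF is recomputed as
alt_reads/depth and overrides any stated VAF column.

## Variant screening

Targeted retention: VAF ≥ 0.10 and ≥ 20 alternate reads, minus blacklisted
sites (the blacklist stands in for public-database SNP filtering and is
always supplied as a file, never fetched). Exome consensus: a variant keyed
by (sample, chrom, pos, ref, alt) is kept iff called by ≥ 2 callers and its
maximum reported VAF ≥ 0.20; the support rule is applied to the maximum
reported VAF (whether it should apply per caller is not decidable from the
protocol), and the emitted record carries the maximum-depth observation's
counts — a deterministic, auditable tie-break. Inputs are assumed
left-aligned/pre-normalized; no re-normalization is attempted.

Clonality: *pre-leukemic* requires re-detection in the paired remission
sample at VAF ≥ 0.10 (mirroring the targeted detection floor, since no
separate remission threshold is stated); *major clone* requires diagnosis
VAF ≥ 0.35 — observed mutant VAFs cluster at 42–99.9%, so the default sits
safely below the heterozygous band while excluding minor subclones. Both
thresholds are configurable and reported in output.

## Cohort statistics

The two-sided exact Fisher p sums hypergeometric point probabilities ≤ the
observed one, with a multiplicative 1+1e-7 tolerance on the comparison to
absorb floating-point ties; point probabilities come from
`scipy.stats.hypergeom`. The reported statistic is the sample odds ratio
ad/bc (descriptive only; ∞ when bc = 0). Remission samples are excluded from
tables and incidences — they duplicate a diagnosis sample. One- vs two-sided
is not stated upstream; the two-sided convention reproduces both published
p-values (0.011, 0.016) on the published tables and is the package default.

## ChIP-Rx quantification

Pipeline order is fixed: dedup → MAPQ filter + extension → window counting →
Rx normalization → input subtraction → replicate averaging.

- **Dedup** keys on (chrom, start, end, strand): for single-end data,
  identical coordinates on opposite strands are distinct molecules. An
  `ignore_strand` flag collapses them for users who read the duplicate rule
  as coordinates-only.
- **MAPQ filter** is strict (> 5), applied after dedup, matching the stated
  processing order.
- **Extension** appends 250 bp at the 3′ end of the 50-bp read (total
  300 bp), approximating the sonicated fragment; a `resize` mode (fragment
  = 250 bp total from the 5′ end) is exposed because the wording admits
  either reading.
- **Counting**: a read increments every window it overlaps by ≥ 1 bp
  (half-open semantics); windows are independent per-TSS quantities, so a
  read may count several times.
- **Rx**: rx = count·10⁹/(window_len·N_spike). No closed formula for the
  original "manual" normalization survives, so the package adopts the
  standard ChIP-Rx convention — RPKM with the spike-in library size as
  denominator — and records n_spike/n_target per library for audit. Its
  defining invariance (joint scaling of target and spike-in reads leaves the
  signal unchanged) is property-tested.
- **Input subtraction** keeps negative net signals (no flooring); this is
  why the downstream ChIP z-score uses absolute values in its denominator.
- Libraries with zero spike-in reads raise a normalization error naming the
  library rather than silently producing infinities.

## Differential layer

z = (M − W)/√(M + W) for RNA means (replicates averaged first, means are
non-negative) and z = (M − W)/√(|M| + |W|) for ChIP net signals; z = 0 when
the denominator is 0 (a gene silent in both conditions carries no signal
either way). Negative net signals are preserved, not clamped. Thresholds are
strict (z > 1.5, p < 0.05; expanded mode 0.8), and the t-test is the
equal-variance Student test with df = n₁+n₂−2; the zero-pooled-variance
degenerate case maps to p = 1 (equal means) or p = 0. No multiple-testing
correction is applied — the caller mirrors the raw-p thresholding design and
surfaces gene counts instead.

Box statistics use Tukey hinges (medians of the lower/upper halves, median
included in both when n is odd), 1.5·IQR whiskers clipped to data, and
notches at median ± 1.58·IQR/√n (≈ 95% CI of the median). The promoter-set
shift reports both box summaries plus a flag for the subset median falling
below the global notch interval. Mark integration is a pure sign test
(eps = 0 by default): me3 loss ∧ ac gain ∧ RNA up ⇒ "derepressed_activated",
with mutually exclusive, exhaustive fallback categories.

## Engraftment statistics

U is the midrank statistic for the second group (#{b > a} + ½·ties). The
two-sided p enumerates all C(n₁+n₂, n₂) label assignments and sums both
tails at the observed deviation; this rule reproduces the published
p = 4/924 ≈ 0.004 on the twelve published engraftment values. Enumeration is
used while C(n₁+n₂, n₂) ≤ 50,000 (every realistic mouse experiment); beyond
that the tie-corrected normal approximation is used and flagged in the
result. A mouse is engrafted iff its chimerism strictly exceeds 1%; group
means average over all mice, engrafted or not.

## Synthetic data

The generators are pure functions of a `SimulationConfig` (seed included)
and every generator also returns a planted-truth table. Defaults encode the
study design: 434 samples, 7.6% s-AML, seven H3 mutants (three s-AML), true
VAFs uniform in [0.40, 0.55] at ~7000× targeted depth with binomial read
sampling; 2% spike-in, 50-bp single-end reads, two ChIP technical
replicates, one input per (condition, mark); triplicate RNA with
multiplicative Gaussian replicate noise (CV 0.10) and planted 4-fold
up/down gene sets (10% each, disjoint, shared between the RNA and ChIP
generators); two engraftment arms at 0.6% and 30% mean chimerism with a
common 5% SD truncated to [0, 100] (a single-SD compromise between the
tight control arm and the dispersed mutant arm) and six mice per arm.

ChIP libraries compose three read classes: spike-in reads at a fixed
expected count per library (condition-independent — the premise that makes
Rx normalization informative), a uniform genomic background (30% of the
library, identical in ChIP and input libraries so input subtraction cancels
it in expectation), and per-gene promoter signal with lognormal intensity
weights (sdlog 0.5) held fixed across conditions and replicates. In mutant
conditions H3K27me3 intensities are multiplied by `me3_global_loss` (0.5),
with an extra `planted_me3_factor` (0.5) at planted up-genes and no loss at
planted down-genes — producing both the recoverable global loss and the
inverse me3/RNA relationship; H3K27ac gains `ac_gain` (2.0) at planted
up-genes. The gene universe is 200 promoters with TSSs every 10 kb on one
synthetic chromosome, and libraries hold 100,000 reads — a deliberately
scaled-down problem size that keeps full-pipeline property tests fast while
leaving per-gene counts (~hundreds) large enough for stable ratios. A
`deterministic` mode replaces all sampling with rounded expectations for
exact unit tests.

What the generator does **not** model: fragment-size distributions, GC and
mappability bias, diploid genotypes, peak shape, enhancer (non-promoter)
signal, and overdispersion beyond Poisson/lognormal. Passing recovery tests
therefore demonstrates that the analysis chain is correct and calibrated
under its own assumptions, not that it is robust to every artifact of real
sequencing data.

## Test design and problem sizes

Exact statistics are tested against independent brute-force oracles written
in the tests themselves (rational-arithmetic hypergeometric enumeration for
Fisher; pairwise-count permutation enumeration for Mann–Whitney; a
closed-form hinge-position implementation for box statistics), plus scipy
cross-checks where applicable. Recovery/calibration runs use 20 simulation
seeds for expression-level metrics and 5 seeds for the full read-level
ChIP-Rx chain; null calibration pools 4000 gene-level tests, giving a
binomial 95% band of ±1.0 percentage point around the nominal 5% rate.
Fisher-vs-oracle agreement is exhaustive on a small grid and sampled (200
seeded draws) for tables up to total 60; Mann–Whitney agreement is
exhaustive over all group sizes with n₁+n₂ ≤ 12.

## Known limitations

- The Rx formula is a declared convention, not a reconstruction of the
  original manual normalization; absolute signal levels are therefore not
  comparable to the original study, only their invariances and ratios.
- Variant matching assumes pre-normalized representations (no indel
  left-alignment).
- The engraftment generator's single SD cannot match both arms'
  dispersions simultaneously.
- The differential caller inherits the z statistic's scale covariance:
  weakly expressed genes cannot clear |z| > 1.5 even at large fold changes.
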