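# Methods

## The frequency model

`lohsim.model` treats the culture as a two-component mixture: a fraction
*f* of transiently hypermutable cells with per-copy reporter
inactivation frequency μ_h, and the remainder at μ. Both mechanisms of
recessive-mutant recovery in diploids are linear mixtures over that
composition:

* coincidence: `F_c(f) = f·μ_h² + (1−f)·μ²` — both homologs hit
  independently within the same cell;
* mutation–segregation: `F_s(f) = [f·μ_h + (1−f)·μ]·r` — one
  heterozygous hit, then an LOH event at per-cell frequency *r*
  homozygoses it.

These are the minimal forms consistent with independent per-copy hits
and a two-step segregation process; the package documents them as its
canonical model. Defaults: μ = 10⁻⁶, μ_h = 10⁻³, and two reference LOH
frequencies r = 3×10⁻⁶ (low-recombination regime) and r = 3×10⁻⁴ (the
same regime increased 100-fold, the elevated resting-phase value). With
these numbers the two mechanisms recover mutants in comparable
proportion at r = 3×10⁻⁴ and coincidence dominates at r = 3×10⁻⁶, and
the onset of a 1% hypermutable fraction raises diploid recovery four
orders of magnitude above the spontaneous double-hit rate of 10⁻¹².

`dominant_mechanism` labels a parameter point "coincidence",
"segregation" or "comparable" with a one-order-of-magnitude threshold,
matching how the regimes are usually discussed. The default fraction
grid is 41 log-spaced points on [10⁻⁴, 1]; the grid bounds are a display
choice, not a model assumption. Haploid curves: predicted =
`f·μ_h + (1−f)·μ`; observed = μ for f < 1 (hypermutable haploids die of
genome-wide load), flagged extinct at f = 1.

## The culture simulator

`lohsim.simulate` is cohort-based: cells are grouped by (subpopulation,
ploidy, reporter genotype, event provenance) with integer counts, and
genome-wide loads are carried as Poisson means. This makes 10⁶–10¹⁰-cell
cultures equally cheap; concrete genomes are materialised only for
archived resistant colonies. The hypermutable state is heritable within
one experiment — a fixed subpopulation set at t = 0; switching dynamics
are not modelled.

Phases:

* **Day 0.** A standing background of reporter mutants (per-copy
  frequency 10⁻⁶, the vector-level mutagenesis history) plus a weak
  leaky-expression pulse (2×10⁻⁶ per copy, roughly tripling the day-0
  mutant frequency over background).
* **Growth (day 0→1).** Eight synchronous doublings. Per division each
  reporter copy mutates with probability μ/8 (so the per-assay rate over
  the growth phase is μ), mitotic recombination converts +/m cells at
  r/8, and each cell gains heterozygous deaminations at its
  subpopulation's Poisson rate: 0.25 (normal) or 300 (hypermutable) per
  division. After growth a hypermutable diploid therefore carries ~2400
  heterozygous passenger SNVs — hundreds to thousands — while its
  meiotic haploid product (~1200 after segregation) exceeds the
  haploid-tolerance default of 1000 and is inviable, so recovered
  haploids descend from the normal fraction and carry few mutations.
* **Resting days (1→6).** No new SNVs. Heterozygous-reporter diploids
  convert to homozygous mutants with a daily LOH hazard; every diploid
  completes meiosis with a daily hazard (non-zero only on days 5–6,
  default 10⁻⁴/day), leaving one viable haploid descendant whose
  heterozygous load segregates. Cell count is conserved — no death is
  modelled in diploids.

**LOH hazard schedule.** The default is (3×10⁻⁴, 3×10⁻⁴, 9×10⁻³,
9×10⁻³, 3×10⁻²) for the five resting days. Under the cohort model the
expected day-6:day-1 resistant-frequency ratio is approximately
`1 + ΣH·(2fμ_h + 2μ)/(fμ_h² + r·het/2)`; the schedule was calibrated
against that closed form so the ratio sits near 10², the magnitude of
the observed rise over day 1. This is a documented default, not a fit to
any particular run.

**Plating.** Sampling is binomial in the population composition. A cell
scores resistant iff all reporter copies are inactivated and it can form
a colony; haploid colony formation uses the Poisson tail
`P(load ≤ tolerance)`. Frequencies are dilution-corrected:
`(resistant/plated_selective) / (viable/plated_permissive)`.

**Marker (recombination-assay) layout.** With `marker_assay=True` the
culture starts heterozygous CAN1/can1-G1018A with the phased ADE2-insert
and URA3 markers. LOH events are split across event classes: growth
phase {conversion 0.60, crossover 0.35, chromosome loss 0.05}, resting
phase {0.20, 0.75, 0.05} — resting-phase (meiotic-like) recombination is
taken to be crossover-rich, which is what makes the long-interval
crossover class prevail by day 6. Crossover breakpoints are uniform per
bp between CAN1 and CEN5, so interval classes are ordered by physical
length (84 kb URA3–CAN1 vs 36 kb CEN5–URA3). The split values are
round-number choices fixed once; only the direction (resting more
crossover-rich than growth) matters for the day-6 shift.

## Synthetic genomes

`lohsim.genomes` / `lohsim.synth` generate clone genomes against either
a user FASTA or a seeded random reference with yeast-like chromosome
counts and lengths (GC 0.38). Deamination spikes place heterozygous
C→T (or G→A, strand uniform) variants on actual C/G reference positions;
the motif is any cytosine — no context weighting is applied by default
since the deaminase context preference is left configurable. Each
heterozygous variant carries a parental haplotype (A or B, uniform),
which drives LOH semantics: `apply_loh_tract` homozygoses
retained-haplotype variants distal to the breakpoint and deletes the
rest, updating marker genotypes through the map phase (functional CAN1,
URA3 and the ADE2 insert in cis on haplotype A). The operation is
idempotent for a fixed breakpoint and haplotype.

Break-associated clusters (`apply_break_cluster`) model deamination of
resected single-stranded DNA at a double-strand break: homozygous
C→T-polarity variants distal, heterozygous reciprocal G→A variants
proximal, within a 10 kb resection window per side (an
order-of-magnitude choice), plus optional interspersed heterozygous
variants of random polarity from later single-strand exposure
("homo-heterozygous" clusters).

Marker coordinates default to ADE2-insert 22,500; CAN1 32,000; URA3
116,000; CEN5 152,000 on a 576,874 bp chromosome V, consistent with the
~80 kb URA3–CAN1 interval; all are configurable. Coordinates are
1-based inclusive (VCF convention); the left arm is every position below
the CEN5 start.

Clone VCFs are v4.2, one sample, GT 0/1 / 1/1 (haploid 1), with FS,
ORIGIN and HAP as INFO fields so a write→read round trip is lossless.

## The analysis pipeline

* **Filtering.** Variants overlapping the BED genome mask are dropped;
  the strand-bias filter retains FS ≤ 20 (boundary inclusive). A missing
  FS annotation retains the variant with a warning — filters should not
  silently drop unannotated synthetic data. The filter is idempotent and
  its two steps commute.
* **LOH calling.** Deaminases produce almost exclusively heterozygous
  SNVs in diploids, so one homozygous SNV on chromosome-V-left — outside
  a configurable shared-hotspot exclusion list (default empty) — is
  sufficient evidence of LOH. The original call partly relied on visual
  browser inspection; this codifies it as an explicit single-SNV rule.
* **Breakpoints.** Reported as the hom→het transition interval (most
  proximal homozygous variant of the distal run, nearest heterozygous
  variant proximal to it) with a midpoint convenience value — an
  interval, not a point, because the data only bracket the exchange.
  Whole-arm homozygosity yields no interval.
* **Reciprocal polarity.** True iff the majority deamination polarity
  (C→T vs G→A on the reference strand, ≥ 2/3 per side) differs across
  the breakpoint; sides without deamination-type variants make the call
  indeterminate. Interspersed random-polarity heterozygous variants
  dilute the majority, so detection is guaranteed only on the polarised
  resection signature itself.
* **Ploidy.** Haploid iff the genome-wide het fraction is below 0.05
  (tolerating residual false het calls), requiring ≥ 20 SNVs; mating-type
  genotyping is out of scope, so heterozygosity stands in for it.
* **Load statistics.** Kruskal–Wallis omnibus across day groups (scipy)
  followed by Dunn-type pairwise rank comparisons with tie correction
  and Bonferroni adjustment at α = 0.05. Dunn's procedure is implemented
  in-package (standard mean-rank z statistic) since no installed library
  provides it; the omnibus test and multiplicity adjustment use
  scipy/statsmodels.

## The event classifier

Phenotypes follow from the marker phase: Ade+ iff the ADE2 insert
survives on a retained homolog, Ura+ iff URA3 survives, canavanine
resistance iff no functional CAN1 remains. The decision tree — haploid →
HAPLOID; chrV monosomy → CHROMOSOME_LOSS; Ade−Ura− → CEN5–URA3
crossover; Ade−Ura+ → URA3–CAN1 crossover; Ade+Ura+ hom-G1018A → gene
conversion; Ade+Ura+ het-G1018A with a new CAN1 mutation → independent
point mutation — is reconstructed from the strain phase and is the
package's canonical mapping. A conversion tract homozygosing CAN1 but
sparing the flanking markers is phenotypically identical to gene
conversion and is deliberately lumped into that class. Distinguishing
chromosome loss from a CEN-proximal crossover requires the monosomy flag
from the genome record; marker phenotype alone cannot separate them.
Colony sampling defaults to 70 per culture with the number of cultures
an independent setting. Box-whisker summaries use Tukey quartiles
(linear interpolation) with the whisker at the smaller (larger) of the
data extreme and Q3 + 1.5·IQR (Q1 − 1.5·IQR), per the quoted plotting
convention.

## What the synthetic data does and does not show

The generator reproduces the *statistical structure* the analysis
assumes — zygosity geometry of LOH tracts, reciprocal cluster polarity,
load distributions, marker phase — not real sequencing data: there are
no read-level errors, no coverage variation, no alignment artifacts, no
real hotspot spectrum, and breakpoints are drawn uniformly rather than
from recombination hotspots. Passing the recovery suites therefore shows
the pipeline is correct on its own model of the data; performance on
real clone VCFs depends additionally on upstream calling quality, which
the FS/mask filters only partially emulate.

## Problem sizes and numerical choices

Test and acceptance runs use cohort simulations at 10⁶–10⁷ initial
cells (the cohort representation makes cost independent of census size),
20-seed pools for frequency ratios, 100 replicates for the rank-test
rejection rate, 200 clones for breakpoint recovery and 10⁴ toy variants
for filter conformance — sizes chosen as comfortable desk-scale defaults
with stable statistics. Random draws flow from a single seed through
named per-stage substreams (`seed`, crc32 of the stage name), so adding
a stage never perturbs earlier stages' draws. Degenerate inputs
(empty grids, empty groups, zero-viability platings, breakpoints off the
chromosome) raise `ValueError` rather than returning silently.

## Known limitations

* No nutrient/OD growth mechanics — the growth schedule is an input.
* No per-cell agent simulation; within-cohort load correlations beyond
  the Poisson means are not represented.
* Genome-wide (non-chrV) cluster calling reuses the arm machinery but
  its density threshold is configurable and unvalidated.
* The sequencing-scale results of a real experiment (clone counts per
  day, absolute frequencies) are reproduced qualitatively, not fitted.
* No indels/MNVs, no mitochondrial genome, no read-level simulation.
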