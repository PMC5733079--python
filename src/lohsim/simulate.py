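"""Stochastic forward simulator of a deaminase-expressing yeast culture.

The culture grows vigorously for one day (``doublings_growth`` synchronous
divisions) and then rests.  Mutations — reporter hits and genome-wide
heterozygous deaminations — are acquired only while cells divide; during
the stationary days no new SNVs appear, but heterozygous reporter cells are
converted to homozygous mutants by a daily loss-of-heterozygosity hazard
(return-to-growth recombination), and late in starvation a small hazard of
completed meiosis produces haploid clones.

Cells are tracked as cohorts (counts per subpopulation × genotype ×
provenance), not as agents, so population size is essentially free; genome
loads are carried as Poisson means and materialised into concrete
:class:`~lohsim.genomes.CloneGenome` records only for archived resistant
clones.

Two assay layouts are supported:

* the *mutagenesis* layout — both reporter copies start functional; the
  daily canavanine platings trace how the resistant frequency keeps rising
  after growth stops;
* the *marker* (recombination) layout — the culture starts heterozygous
  CAN1/can1-G1018A with phased Ade/Ura markers, and every resistant clone
  carries an event-class provenance (point mutation, gene conversion,
  interval crossover, chromosome loss, haploid) for downstream
  classification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import stage_rng
from .genomes import CloneGenome, MarkerMap
from .model import ModelParams

__all__ = [
    "SimConfig",
    "Cohort",
    "CultureState",
    "PlatingResult",
    "ArchiveRecord",
    "ExperimentResult",
    "simulate_growth_phase",
    "stationary_day_step",
    "plate_assay",
    "run_experiment",
    "materialize_clone",
    "record_load_summary",
]

RESISTANT_GENOTYPES = frozenset({"mm", "m", "hemi_m"})

#: event-class provenance labels used in the marker layout
_MARKER_EVENTS = ("point_mutation", "gene_conversion", "xo_ura3_can1", "xo_cen_ura3", "chrom_loss")


@dataclass
class SimConfig:
    """Study conditions of one starvation experiment.

    ``loh_hazard`` and ``meiosis_hazard`` are per-cell per-day probability
    schedules over the stationary days (day 1→2 … day 5→6); ``model``
    carries the reporter rates (``mu_base``, ``mu_hyper`` per copy per
    growth phase, ``r_loh`` for growth-phase recombination,
    ``haploid_tolerance`` as the viable genome-load ceiling).  Genome
    rates are expected heterozygous deaminations per cell per division.
    """

    n_initial: int = 10_000_000
    doublings_growth: int = 8
    days_stationary: int = 5
    ploidy: int = 2
    model: ModelParams = field(default_factory=ModelParams)
    hyper_fraction: float = 0.05
    genome_rate_base: float = 0.25
    genome_rate_hyper: float = 300.0
    loh_hazard: tuple[float, ...] = (3e-4, 3e-4, 9e-3, 9e-3, 3e-2)
    meiosis_hazard: tuple[float, ...] = (0.0, 0.0, 0.0, 1e-4, 1e-4)
    background_freq: float = 1e-6
    leak_reporter_prob: float = 2e-6
    marker_assay: bool = False
    marker_map: MarkerMap = field(default_factory=MarkerMap)
    growth_event_split: dict = field(
        default_factory=lambda: {"gene_conversion": 0.60, "crossover": 0.35, "chrom_loss": 0.05}
    )
    stationary_event_split: dict = field(
        default_factory=lambda: {"gene_conversion": 0.20, "crossover": 0.75, "chrom_loss": 0.05}
    )
    n_plated_selective: int = 1_000_000_000
    n_plated_permissive: int = 1_000
    archive_per_day: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.doublings_growth < 1:
            raise ValueError("doublings_growth must be >= 1")
        if self.ploidy not in (1, 2):
            raise ValueError("ploidy must be 1 or 2")
        if not (0.0 <= self.hyper_fraction <= 1.0):
            raise ValueError("hyper_fraction must be in [0, 1]")
        for name in ("loh_hazard", "meiosis_hazard"):
            sched = getattr(self, name)
            if len(sched) != self.days_stationary:
                raise ValueError(f"{name} schedule must have length days_stationary={self.days_stationary}")
            if any(not (0.0 <= h <= 1.0) for h in sched):
                raise ValueError(f"{name} values must be probabilities")
        for split in (self.growth_event_split, self.stationary_event_split):
            if abs(sum(split.values()) - 1.0) > 1e-9:
                raise ValueError("event splits must sum to 1")


@dataclass
class Cohort:
    """A group of identical cells: count plus Poisson genome-load means."""

    subpop: str  # normal | hyper
    ploidy: int
    genotype: str  # '++', '+m', 'mm', '+', 'm', 'hemi_m'
    tag: str | None = None  # provenance of the resistant state
    count: int = 0
    het_load: float = 0.0
    hom_load: float = 0.0

    @property
    def resistant(self) -> bool:
        return self.genotype in RESISTANT_GENOTYPES


@dataclass
class CultureState:
    day: int
    cohorts: list[Cohort]
    ploidy: int

    @property
    def total(self) -> int:
        return sum(c.count for c in self.cohorts)

    def prune(self) -> None:
        self.cohorts = [c for c in self.cohorts if c.count > 0]

    def mean_genome_load(self) -> float:
        """Population mean of the expected per-cell SNV count."""
        tot = self.total
        if tot == 0:
            return 0.0
        return sum(c.count * (c.het_load + c.hom_load) for c in self.cohorts) / tot


@dataclass(frozen=True)
class PlatingResult:
    day: int
    n_plated_selective: int
    n_resistant: int
    n_plated_permissive: int
    n_viable: int

    def __post_init__(self) -> None:
        if self.n_resistant > self.n_plated_selective:
            raise ValueError("resistant count cannot exceed plated count")
        if self.n_viable > self.n_plated_permissive:
            raise ValueError("viable count cannot exceed plated count")


@dataclass
class ArchiveRecord:
    """A sampled resistant colony, materialisable into a CloneGenome."""

    clone_id: str
    day: int
    subpop: str
    ploidy: int
    genotype: str
    tag: str | None
    n_het: int
    n_hom: int
    breakpoint: int | None = None

    @property
    def total_load(self) -> int:
        return self.n_het + self.n_hom


@dataclass
class ExperimentResult:
    config: SimConfig
    table: pd.DataFrame
    archive: list[ArchiveRecord]
    platings: list[PlatingResult]


def _viability(cohort: Cohort, tolerance: int) -> float:
    """Probability that a sampled cell of this cohort forms a colony.

    Diploids tolerate the load (lethal hits stay heterozygous); haploids
    survive only if their Poisson genome load is within tolerance.
    """
    if cohort.ploidy == 2:
        return 1.0
    lam = cohort.het_load + cohort.hom_load
    if lam == 0:
        return 1.0
    return float(stats.poisson.cdf(tolerance, lam))


def _initial_state(config: SimConfig, rng: np.random.Generator) -> CultureState:
    n_hyper = int(round(config.hyper_fraction * config.n_initial))
    n_normal = config.n_initial - n_hyper
    start_geno = "+m" if config.marker_assay else ("++" if config.ploidy == 2 else "+")
    cohorts: list[Cohort] = []
    for subpop, n in (("normal", n_normal), ("hyper", n_hyper)):
        if n == 0:
            continue
        base = Cohort(subpop=subpop, ploidy=config.ploidy, genotype=start_geno, count=n)
        cohorts.append(base)
        if not config.marker_assay:
            # standing background mutants (vector-level mutagenesis history)
            if config.ploidy == 1:
                k = int(rng.binomial(n, config.background_freq))
                if k:
                    base.count -= k
                    cohorts.append(replace(base, genotype="m", tag="background", count=k))
            else:
                k = int(rng.binomial(n, 2.0 * config.background_freq))
                if k:
                    base.count -= k
                    cohorts.append(replace(base, genotype="+m", tag=None, count=k))
        # leaky pre-induction expression: a weak mutagenic pulse at time 0
        p = config.leak_reporter_prob
        if p > 0:
            if base.genotype == "+":
                k = int(rng.binomial(base.count, p))
                if k:
                    base.count -= k
                    cohorts.append(replace(base, genotype="m", tag="leak", count=k))
            elif base.genotype == "++":
                k = int(rng.binomial(base.count, 2.0 * p))
                if k:
                    base.count -= k
                    cohorts.append(replace(base, genotype="+m", tag=None, count=k))
            elif base.genotype == "+m":
                k = int(rng.binomial(base.count, p))
                if k:
                    base.count -= k
                    cohorts.append(replace(base, genotype="mm", tag="point_mutation", count=k))
    state = CultureState(day=0, cohorts=cohorts, ploidy=config.ploidy)
    state.prune()
    return state


def _split_marker_events(
    k: int, split: dict, marker_map: MarkerMap, rng: np.random.Generator
) -> dict[str, int]:
    """Distribute ``k`` LOH events over marker-assay event classes.

    Crossover breakpoints are uniform per bp between CAN1 and CEN5, so the
    two interval classes receive weight proportional to physical length.
    """
    xo_total = split["crossover"]
    w_uc = xo_total * marker_map.interval_ura3_can1 / (marker_map.cen5 - marker_map.can1)
    w_cu = xo_total * marker_map.interval_cen_ura3 / (marker_map.cen5 - marker_map.can1)
    probs = np.array([split["gene_conversion"], w_uc, w_cu, split["chrom_loss"]])
    counts = rng.multinomial(k, probs / probs.sum())
    return dict(zip(("gene_conversion", "xo_ura3_can1", "xo_cen_ura3", "chrom_loss"), counts))


def _apply_loh_events(
    cohort: Cohort,
    k: int,
    config: SimConfig,
    rng: np.random.Generator,
    split: dict,
    out: list[Cohort],
    tag_plain: str,
) -> None:
    """Convert ``k`` heterozygous-reporter cells of ``cohort`` to resistant."""
    if k == 0:
        return
    cohort.count -= k
    if config.marker_assay:
        for event, n in _split_marker_events(k, split, config.marker_map, rng).items():
            if n == 0:
                continue
            geno = "hemi_m" if event == "chrom_loss" else "mm"
            out.append(replace(cohort, genotype=geno, tag=event, count=int(n)))
    else:
        out.append(replace(cohort, genotype="mm", tag=tag_plain, count=k))


def simulate_growth_phase(
    config: SimConfig,
    rng: np.random.Generator,
    state: CultureState | None = None,
) -> CultureState:
    """Run the day-0→1 vigorous-growth phase.

    Each synchronous division doubles every cohort, adds reporter hits at
    per-copy per-division rate ``mu/doublings`` (so the per-assay rate over
    the whole growth phase is ``mu``), applies growth-phase mitotic
    recombination at ``r_loh/doublings``, and accrues genome-wide
    heterozygous deaminations at the subpopulation's Poisson rate.
    """
    if state is None:
        state = _initial_state(config, rng)
    elif state.day != 0:
        raise ValueError("growth phase starts from the day-0 state")
    d = config.doublings_growth
    mu = {"normal": config.model.mu_base, "hyper": config.model.mu_hyper}
    g_rate = {"normal": config.genome_rate_base, "hyper": config.genome_rate_hyper}
    r_div = config.model.r_loh / d

    for _ in range(d):
        new: list[Cohort] = []
        for c in state.cohorts:
            c.count *= 2
            c.het_load += g_rate[c.subpop]
            q = mu[c.subpop] / d
            if c.genotype == "+":
                k = int(rng.binomial(c.count, q))
                if k:
                    c.count -= k
                    new.append(replace(c, genotype="m", tag="growth_mutation", count=k))
            elif c.genotype == "++":
                k_mm, k_het, _ = rng.multinomial(c.count, [q * q, 2.0 * q * (1.0 - q), (1.0 - q) ** 2])
                c.count -= int(k_het) + int(k_mm)
                if k_het:
                    new.append(replace(c, genotype="+m", tag=None, count=int(k_het)))
                if k_mm:
                    new.append(replace(c, genotype="mm", tag="coincidence", count=int(k_mm)))
            elif c.genotype == "+m":
                k_mut = int(rng.binomial(c.count, q))
                if k_mut:
                    c.count -= k_mut
                    tag = "point_mutation" if config.marker_assay else "coincidence"
                    new.append(replace(c, genotype="mm", tag=tag, count=k_mut))
                k_loh = int(rng.binomial(c.count, r_div))
                _apply_loh_events(c, k_loh, config, rng, config.growth_event_split, new, "loh_growth")
        state.cohorts.extend(new)
        state.prune()
    state.day = 1
    return state


def stationary_day_step(state: CultureState, config: SimConfig, rng: np.random.Generator) -> CultureState:
    """Advance the resting culture by one day.

    No new genome-wide SNVs are added.  Heterozygous-reporter diploids
    convert to homozygous mutants with the day's LOH hazard; every diploid
    completes meiosis with the day's meiosis hazard, yielding one viable
    haploid descendant whose heterozygous load segregates (half retained,
    now homozygous).  Total cell count is conserved.
    """
    if state.day < 1:
        raise ValueError("stationary steps start from the day-1 state; run the growth phase first")
    i = state.day - 1
    if i >= config.days_stationary:
        raise ValueError(f"no hazard scheduled beyond day {config.days_stationary + 1}")
    h_loh = config.loh_hazard[i]
    h_mei = config.meiosis_hazard[i]

    new: list[Cohort] = []
    for c in state.cohorts:
        if c.ploidy == 2 and c.genotype == "+m" and h_loh > 0:
            k = int(rng.binomial(c.count, h_loh))
            _apply_loh_events(c, k, config, rng, config.stationary_event_split, new, "loh")
        if c.ploidy == 2 and h_mei > 0 and c.count > 0:
            k = int(rng.binomial(c.count, h_mei))
            if k:
                c.count -= k
                hap = replace(
                    c,
                    ploidy=1,
                    count=k,
                    het_load=0.0,
                    hom_load=c.hom_load + c.het_load / 2.0,
                    tag="haploid" if config.marker_assay else "meiotic",
                )
                if c.genotype == "+m":
                    k_m = int(rng.binomial(k, 0.5))
                    if k_m:
                        new.append(replace(hap, genotype="m", count=k_m))
                    if k - k_m:
                        new.append(replace(hap, genotype="+", count=k - k_m))
                elif c.genotype in ("mm", "hemi_m"):
                    new.append(replace(hap, genotype="m"))
                else:  # '++'
                    new.append(replace(hap, genotype="+"))
    state.cohorts.extend(new)
    state.prune()
    state.day += 1
    return state


def plate_assay(
    state: CultureState,
    config: SimConfig,
    rng: np.random.Generator,
    n_selective: int | None = None,
    n_permissive: int | None = None,
) -> PlatingResult:
    """Plate samples on selective and permissive media.

    A sampled cell scores resistant iff every reporter copy is inactivated
    and the cell can form a colony (haploids die when their genome load
    exceeds the tolerance).  Sampling is binomial in the population
    composition.
    """
    total = state.total
    n_sel = min(config.n_plated_selective if n_selective is None else n_selective, total)
    n_perm = min(config.n_plated_permissive if n_permissive is None else n_permissive, total)
    if n_sel <= 0 or n_perm <= 0:
        raise ValueError("plated cell counts must be positive")
    tol = config.model.haploid_tolerance
    frac_res = sum(c.count * _viability(c, tol) for c in state.cohorts if c.resistant) / total
    frac_viable = sum(c.count * _viability(c, tol) for c in state.cohorts) / total
    return PlatingResult(
        day=state.day,
        n_plated_selective=n_sel,
        n_resistant=int(rng.binomial(n_sel, frac_res)),
        n_plated_permissive=n_perm,
        n_viable=int(rng.binomial(n_perm, min(frac_viable, 1.0))),
    )


def _sample_archive(
    state: CultureState, config: SimConfig, rng: np.random.Generator, n: int, prefix: str
) -> list[ArchiveRecord]:
    """Sample up to ``n`` resistant colonies from the current state."""
    tol = config.model.haploid_tolerance
    cands = [c for c in state.cohorts if c.resistant]
    weights = np.array([c.count * _viability(c, tol) for c in cands], dtype=float)
    if not cands or weights.sum() == 0:
        return []
    picks = rng.choice(len(cands), size=n, p=weights / weights.sum())
    mm = config.marker_map
    records = []
    for j, idx in enumerate(picks):
        c = cands[idx]
        bp = None
        if c.tag in ("loh", "loh_growth"):
            bp = int(rng.integers(mm.can1 + 1, mm.cen5))
        elif c.tag == "xo_ura3_can1":
            bp = int(rng.integers(mm.can1 + 1, mm.ura3))
        elif c.tag == "xo_cen_ura3":
            bp = int(rng.integers(mm.ura3 + 1, mm.cen5))
        records.append(
            ArchiveRecord(
                clone_id=f"{prefix}_d{state.day}_{j:03d}",
                day=state.day,
                subpop=c.subpop,
                ploidy=c.ploidy,
                genotype=c.genotype,
                tag=c.tag,
                n_het=int(rng.poisson(c.het_load)),
                n_hom=int(rng.poisson(c.hom_load)),
                breakpoint=bp,
            )
        )
    return records


def run_experiment(config: SimConfig) -> ExperimentResult:
    """Run the full plating experiment: day 0 through day ``1 + days_stationary``.

    Deterministic given ``config.seed``; all randomness flows through
    named substreams of that seed.
    """
    rng = stage_rng(config.seed, "culture")
    rng_plate = stage_rng(config.seed, "plating")
    rng_archive = stage_rng(config.seed, "archive")

    platings: list[PlatingResult] = []
    archive: list[ArchiveRecord] = []

    state = _initial_state(config, rng)
    platings.append(plate_assay(state, config, rng_plate))
    archive.extend(_sample_archive(state, config, rng_archive, config.archive_per_day, "clone"))

    state = simulate_growth_phase(config, rng, state)
    platings.append(plate_assay(state, config, rng_plate))
    archive.extend(_sample_archive(state, config, rng_archive, config.archive_per_day, "clone"))
    for _ in range(config.days_stationary):
        state = stationary_day_step(state, config, rng)
        platings.append(plate_assay(state, config, rng_plate))
        archive.extend(_sample_archive(state, config, rng_archive, config.archive_per_day, "clone"))

    rows = []
    for p in platings:
        freq = math.nan
        if p.n_viable > 0:
            freq = (p.n_resistant / p.n_plated_selective) / (p.n_viable / p.n_plated_permissive)
        rows.append(
            {
                "day": p.day,
                "n_plated_selective": p.n_plated_selective,
                "n_resistant": p.n_resistant,
                "n_plated_permissive": p.n_plated_permissive,
                "n_viable": p.n_viable,
                "frequency": freq,
            }
        )
    return ExperimentResult(config=config, table=pd.DataFrame(rows), archive=archive, platings=platings)


def record_load_summary(record: ArchiveRecord):
    """LoadSummary for an archived clone without genome materialisation."""
    from .pipeline import LoadSummary

    reporter = {"mm": "hom", "hemi_m": "hemizygous", "m": "hemizygous"}.get(record.genotype, "het")
    return LoadSummary(
        clone_id=record.clone_id,
        day=record.day,
        total=record.total_load,
        n_hom=record.n_hom if record.ploidy == 2 else record.total_load,
        n_het=record.n_het if record.ploidy == 2 else 0,
        n_transitions=record.total_load,
        reporter_state=reporter,
    )


def materialize_clone(
    record: ArchiveRecord,
    reference,
    config: SimConfig,
    rng: np.random.Generator,
) -> CloneGenome:
    """Build a concrete CloneGenome for an archived resistant colony.

    Genome-wide heterozygous deaminations are spiked at the recorded load;
    LOH clones then get their tract applied at the recorded breakpoint
    (haplotype B retained), marker-assay clones additionally carry the
    event's marker genotype, and meiotic haploids are reduced to one
    haplotype.
    """
    from . import synth

    mm = config.marker_map
    genome = CloneGenome(
        clone_id=record.clone_id,
        ploidy=2,
        marker_alleles=mm.heterozygous_alleles() if config.marker_assay else None,
        chrom_lengths=dict(reference.chrom_lengths),
    )
    if record.ploidy == 1:
        # haploid: all surviving variants are effectively homozygous
        genome = synth.spike_heterozygous_deaminations(genome, record.n_hom, reference, rng)
        genome.variants.append(
            _reporter_variant(reference, mm.chrom, mm.can1 + 500, "het", haplotype="B")
        )
        for v in genome.variants:
            v.genotype = "hom"
        genome.variants.sort(key=lambda v: v.sort_key())
        genome.ploidy = 1
        if genome.marker_alleles is not None:
            genome.marker_alleles = {
                locus: (mm.haplotype_allele("B", locus),) for locus in genome.marker_alleles
            }
        return genome

    genome = synth.spike_heterozygous_deaminations(genome, record.n_het, reference, rng)

    tag = record.tag
    if config.marker_assay and tag in _MARKER_EVENTS:
        if tag == "point_mutation":
            genome.marker_alleles["CAN1"] = ("can1-new", "can1-G1018A")
        elif tag == "gene_conversion":
            genome.marker_alleles["CAN1"] = ("can1-G1018A", "can1-G1018A")
        elif tag in ("xo_ura3_can1", "xo_cen_ura3"):
            genome = synth.apply_loh_tract(genome, mm.chrom, record.breakpoint, "B", marker_map=mm)
        elif tag == "chrom_loss":
            genome = synth.apply_chromosome_loss(genome, mm.chrom, "B", marker_map=mm)
    elif tag in ("loh", "loh_growth"):
        # heterozygous reporter hit homozygosed by recombination: must lie
        # distal of the exchange point
        hi = max(2, min(1500, record.breakpoint - mm.can1))
        pos = mm.can1 + int(rng.integers(1, hi))
        genome.variants.append(_reporter_variant(reference, mm.chrom, pos, "hom", haplotype="B"))
        genome.variants.sort(key=lambda v: v.sort_key())
        genome = synth.apply_loh_tract(genome, mm.chrom, record.breakpoint, "B", marker_map=mm)
    elif record.genotype == "mm":
        # coincidence: independent heteroallelic hits in the two homologs
        for hap, off in (("A", 200), ("B", 900)):
            genome.variants.append(
                _reporter_variant(reference, mm.chrom, mm.can1 + off, "het", haplotype=hap)
            )
        genome.variants.sort(key=lambda v: v.sort_key())
    return genome


def _reporter_variant(reference, chrom: str, pos: int, genotype: str, haplotype: str = "A"):
    from .genomes import Variant

    ref = reference.base(chrom, pos)
    # deamination-style change consistent with the reference base
    alt = {"C": "T", "G": "A", "A": "G", "T": "C"}[ref]
    return Variant(chrom=chrom, pos=pos, ref=ref, alt=alt, genotype=genotype,
                   fs=1.0, origin="transcription", haplotype=haplotype)
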