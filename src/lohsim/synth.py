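"""Generators for synthetic clone genomes.

These operations build, on top of a :class:`~lohsim.genomes.SyntheticReference`,
the variant structure that deaminase-exposed diploid clones show:

* genome-wide heterozygous C→T / G→A transitions (``spike_heterozygous_deaminations``),
* loss-of-heterozygosity tracts that homozygose everything distal to a
  recombination breakpoint (``apply_loh_tract``),
* break-associated mutation clusters in which resected single-stranded DNA
  is deaminated — homozygous C→T-polarity variants distal to the break and
  heterozygous variants of the reciprocal G→A polarity proximal to it
  (``apply_break_cluster``),
* whole-chromosome loss (``apply_chromosome_loss``),
* ready-made marker-assay clones for each selectable event class
  (``synthesize_event_clone``).
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np

from .genomes import CloneGenome, MarkerMap, SyntheticReference, Variant

__all__ = [
    "spike_heterozygous_deaminations",
    "apply_loh_tract",
    "apply_break_cluster",
    "apply_chromosome_loss",
    "make_haploid",
    "synthesize_event_clone",
]


def spike_heterozygous_deaminations(
    genome: CloneGenome,
    n: int,
    reference: SyntheticReference,
    rng: np.random.Generator,
    chrom: str | None = None,
    start: int = 1,
    end: int | None = None,
    fs_scale: float = 2.0,
    origin: str = "replication",
) -> CloneGenome:
    """Add ``n`` heterozygous deamination SNVs at reference C/G sites.

    Positions are sampled uniformly over available C/G sites (restricted to
    ``chrom``/``start``/``end`` when given); the mutated strand — and hence
    whether the call reads C→T or G→A — follows the reference base.  Each
    variant is assigned a parental haplotype uniformly at random and a
    small exponential FS score, well below the retention cutoff.

    Raises ``ValueError`` if ``n`` exceeds the available motif sites.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    out = genome.copy()
    if n == 0:
        return out
    chroms = [chrom] if chrom is not None else list(reference.chrom_lengths)
    # apportion n across chromosomes by C/G site counts
    weights = np.array([len(reference.cg_positions(c, start, end if c == chrom else None))
                        if chrom is not None else len(reference.cg_positions(c))
                        for c in chroms], dtype=float)
    if weights.sum() == 0:
        raise ValueError("no C/G sites available in the requested region")
    counts = rng.multinomial(n, weights / weights.sum()) if len(chroms) > 1 else np.array([n])
    occupied = {(v.chrom, v.pos) for v in out.variants}
    for c, k in zip(chroms, counts):
        if k == 0:
            continue
        exclude = {p for (vc, p) in occupied if vc == c}
        sites = reference.sample_deamination_sites(
            c, int(k), rng, start=start if chrom is not None else 1,
            end=end if chrom is not None else None, exclude=exclude,
        )
        for pos, ref, alt in sites:
            out.variants.append(
                Variant(
                    chrom=c,
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    genotype="het",
                    fs=float(rng.exponential(fs_scale)),
                    origin=origin,
                    haplotype="A" if rng.random() < 0.5 else "B",
                )
            )
    out.variants.sort(key=Variant.sort_key)
    return out


def apply_loh_tract(
    genome: CloneGenome,
    chrom: str,
    breakpoint_pos: int,
    retained_haplotype: str = "B",
    marker_map: MarkerMap | None = None,
    arm: str = "left",
) -> CloneGenome:
    """Homozygose every variant distal to ``breakpoint_pos``.

    On the left arm "distal" means positions below the breakpoint (toward
    the telomere).  Heterozygous variants on the retained haplotype become
    homozygous; those on the lost haplotype disappear.  When the clone
    carries marker alleles and the tract covers marker loci, their genotype
    is rewritten to the retained haplotype's alleles.  Idempotent for a
    fixed breakpoint and haplotype.
    """
    if retained_haplotype not in ("A", "B"):
        raise ValueError("retained_haplotype must be 'A' or 'B'")
    if chrom not in genome.chrom_lengths:
        raise ValueError(f"unknown chromosome {chrom!r}")
    if not (1 <= breakpoint_pos <= genome.chrom_lengths[chrom]):
        raise ValueError(
            f"breakpoint {breakpoint_pos} outside {chrom} (length {genome.chrom_lengths[chrom]})"
        )

    def distal(pos: int) -> bool:
        return pos < breakpoint_pos if arm == "left" else pos > breakpoint_pos

    out = genome.copy()
    kept: list[Variant] = []
    for v in out.variants:
        if v.chrom != chrom or not distal(v.pos) or v.genotype == "hom":
            kept.append(v)
        elif v.haplotype == retained_haplotype:
            kept.append(replace(v, genotype="hom"))
        # else: variant was on the lost haplotype — gone
    out.variants = sorted(kept, key=Variant.sort_key)

    if out.marker_alleles is not None and marker_map is not None and chrom == marker_map.chrom:
        alleles = dict(out.marker_alleles)
        for locus, pos in marker_map.locus_positions.items():
            if distal(pos):
                allele = marker_map.haplotype_allele(retained_haplotype, locus)
                alleles[locus] = (allele,) * len(alleles[locus])
        out.marker_alleles = alleles
    return out


def apply_break_cluster(
    genome: CloneGenome,
    chrom: str,
    break_pos: int,
    reference: SyntheticReference,
    rng: np.random.Generator,
    n_distal: int = 6,
    n_proximal: int = 4,
    n_het_extra: int = 3,
    window: int = 10_000,
    retained_haplotype: str = "B",
) -> CloneGenome:
    """Add a break-associated mutation cluster around ``break_pos``.

    Resection on the two sides of a double-strand break exposes opposite
    single strands, so the cluster is strand-coordinated with reciprocal
    polarity: the distal side gets ``n_distal`` homozygous C→T variants,
    the proximal side ``n_proximal`` heterozygous G→A variants, and
    ``n_het_extra`` further heterozygous variants of random polarity are
    interspersed across the window ("homo-heterozygous" cluster).  A
    window extending past a chromosome end is truncated with a warning.
    """
    length = genome.chrom_lengths[chrom]
    if not (1 <= break_pos <= length):
        raise ValueError(f"break position {break_pos} outside {chrom}")
    lo = break_pos - window
    hi = break_pos + window
    if lo < 1 or hi > length:
        warnings.warn(f"resection window around {chrom}:{break_pos} truncated at chromosome end")
        lo, hi = max(1, lo), min(length, hi)

    out = genome.copy()
    occupied = {v.pos for v in out.variants if v.chrom == chrom}

    def _sample_polarized(n: int, start: int, end: int, want_ref: str) -> list[tuple[int, str, str]]:
        sites = reference.cg_positions(chrom, start, end)
        seq = reference.sequences[chrom]
        sites = sites[seq[sites - 1] == want_ref.encode()]
        sites = sites[~np.isin(sites, list(occupied))] if occupied else sites
        if n > len(sites):
            raise ValueError(f"not enough {want_ref} sites in [{start},{end}] on {chrom}")
        chosen = rng.choice(sites, size=n, replace=False)
        occupied.update(int(p) for p in chosen)
        alt = "T" if want_ref == "C" else "A"
        return [(int(p), want_ref, alt) for p in np.sort(chosen)]

    for pos, ref, alt in _sample_polarized(n_distal, lo, break_pos - 1, "C"):
        out.variants.append(
            Variant(chrom, pos, ref, alt, genotype="hom", fs=float(rng.exponential(2.0)),
                    origin="break_distal", haplotype=retained_haplotype)
        )
    for pos, ref, alt in _sample_polarized(n_proximal, break_pos, hi, "G"):
        out.variants.append(
            Variant(chrom, pos, ref, alt, genotype="het", fs=float(rng.exponential(2.0)),
                    origin="break_proximal", haplotype=retained_haplotype)
        )
    for _ in range(n_het_extra):
        want = "C" if rng.random() < 0.5 else "G"
        (site,) = _sample_polarized(1, lo, hi, want)
        pos, ref, alt = site
        out.variants.append(
            Variant(chrom, pos, ref, alt, genotype="het", fs=float(rng.exponential(2.0)),
                    origin="hotspot", haplotype="A" if rng.random() < 0.5 else "B")
        )
    out.variants.sort(key=Variant.sort_key)
    return out


def apply_chromosome_loss(
    genome: CloneGenome,
    chrom: str,
    retained_haplotype: str = "B",
    marker_map: MarkerMap | None = None,
) -> CloneGenome:
    """Lose one homolog of ``chrom``: hets on the lost haplotype vanish,
    retained hets become hemizygous (reported hom); marker tuples shrink
    to length 1, flagging monosomy."""
    out = genome.copy()
    kept: list[Variant] = []
    for v in out.variants:
        if v.chrom != chrom or v.genotype == "hom":
            kept.append(v)
        elif v.haplotype == retained_haplotype:
            kept.append(replace(v, genotype="hom"))
    out.variants = sorted(kept, key=Variant.sort_key)
    if out.marker_alleles is not None and marker_map is not None and chrom == marker_map.chrom:
        out.marker_alleles = {
            locus: (marker_map.haplotype_allele(retained_haplotype, locus),)
            for locus in out.marker_alleles
        }
    return out


def make_haploid(
    genome: CloneGenome,
    rng: np.random.Generator,
    keep_haplotype: str | None = None,
    marker_map: MarkerMap | None = None,
) -> CloneGenome:
    """A meiotic haploid product: each het variant segregates with its
    haplotype; hom variants are retained.  With ``keep_haplotype=None``
    whole haplotypes are not tracked per chromosome — each chromosome
    independently keeps haplotype A or B."""
    out = genome.copy()
    keep: dict[str, str] = {}
    for c in out.chrom_lengths:
        keep[c] = keep_haplotype or ("A" if rng.random() < 0.5 else "B")
    variants = []
    for v in out.variants:
        if v.genotype == "hom" or v.haplotype == keep[v.chrom]:
            variants.append(replace(v, genotype="hom"))
    out.variants = sorted(variants, key=Variant.sort_key)
    out.ploidy = 1
    if out.marker_alleles is not None and marker_map is not None:
        hap = keep[marker_map.chrom]
        out.marker_alleles = {
            locus: (marker_map.haplotype_allele(hap, locus),) for locus in out.marker_alleles
        }
    return out


def synthesize_event_clone(
    event: str,
    marker_map: MarkerMap,
    rng: np.random.Generator,
    clone_id: str = "clone",
    breakpoint: int | None = None,
    chrom_lengths: dict[str, int] | None = None,
) -> CloneGenome:
    """A marker-assay clone embodying one selectable event class.

    ``event`` is one of ``point_mutation``, ``gene_conversion``,
    ``xo_ura3_can1``, ``xo_cen_ura3``, ``chrom_loss``, ``haploid``.
    Crossover breakpoints default to a uniform draw within the
    corresponding marker interval.
    """
    from .genomes import YEAST_CHROM_LENGTHS

    genome = CloneGenome(
        clone_id=clone_id,
        ploidy=2,
        marker_alleles=marker_map.heterozygous_alleles(),
        chrom_lengths=dict(YEAST_CHROM_LENGTHS) if chrom_lengths is None else dict(chrom_lengths),
    )
    mm = marker_map
    if event == "point_mutation":
        genome.marker_alleles["CAN1"] = ("can1-new", "can1-G1018A")
        return genome
    if event == "gene_conversion":
        genome.marker_alleles["CAN1"] = ("can1-G1018A", "can1-G1018A")
        return genome
    if event == "xo_ura3_can1":
        bp = breakpoint or int(rng.integers(mm.can1 + 1, mm.ura3))
        return apply_loh_tract(genome, mm.chrom, bp, "B", marker_map=mm)
    if event == "xo_cen_ura3":
        bp = breakpoint or int(rng.integers(mm.ura3 + 1, mm.cen5))
        return apply_loh_tract(genome, mm.chrom, bp, "B", marker_map=mm)
    if event == "chrom_loss":
        return apply_chromosome_loss(genome, mm.chrom, "B", marker_map=mm)
    if event == "haploid":
        return make_haploid(genome, rng, keep_haplotype="B", marker_map=mm)
    raise ValueError(f"unknown event class {event!r}")
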