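"""Clone-genome containers, the chromosome-V marker map, and synthetic references.

The unit of analysis is a :class:`CloneGenome`: the SNVs of one sequenced
(or simulated) diploid/haploid clone with per-site zygosity, plus the
genotype at the chromosome-V-left-arm selection markers.  A
:class:`MarkerMap` fixes the coordinates and parental phase of those
markers: the functional *CAN1*, *URA3* and the *ADE2* insert at *HXT13*
all lie in cis on haplotype A; haplotype B carries *can1-G1018A*, the
*ura3* deletion and plain *HXT13*.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

__all__ = [
    "Variant",
    "CloneGenome",
    "MarkerMap",
    "SyntheticReference",
    "YEAST_CHROM_LENGTHS",
    "DEAMINATION_PAIRS",
]

#: Approximate S288C nuclear chromosome lengths (bp).
YEAST_CHROM_LENGTHS: dict[str, int] = {
    "chrI": 230_218,
    "chrII": 813_184,
    "chrIII": 316_620,
    "chrIV": 1_531_933,
    "chrV": 576_874,
    "chrVI": 270_161,
    "chrVII": 1_090_940,
    "chrVIII": 562_643,
    "chrIX": 439_888,
    "chrX": 745_751,
    "chrXI": 666_816,
    "chrXII": 1_078_177,
    "chrXIII": 924_431,
    "chrXIV": 784_333,
    "chrXV": 1_091_291,
    "chrXVI": 948_066,
}

#: Cytosine-deamination transitions on the two reference strands.
DEAMINATION_PAIRS = (("C", "T"), ("G", "A"))


@dataclass
class Variant:
    """A single-nucleotide variant of one clone.

    ``haplotype`` records which parental homolog carries a heterozygous
    allele ('A' or 'B'); it drives LOH semantics and is irrelevant for
    homozygous sites.  ``fs`` is the Phred-scaled FisherStrand strand-bias
    score; ``origin`` tags the generating process (replication,
    transcription, break_distal, break_proximal, hotspot).
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    genotype: str = "het"  # het | hom
    fs: float | None = 0.0
    origin: str = "replication"
    haplotype: str = "A"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt must differ at {self.chrom}:{self.pos}")
        if self.genotype not in ("het", "hom"):
            raise ValueError(f"genotype must be het or hom, got {self.genotype!r}")

    @property
    def is_deamination(self) -> bool:
        return (self.ref, self.alt) in DEAMINATION_PAIRS

    @property
    def polarity(self) -> str | None:
        """'CT' or 'GA' on the reference strand, None for other changes."""
        if (self.ref, self.alt) == ("C", "T"):
            return "CT"
        if (self.ref, self.alt) == ("G", "A"):
            return "GA"
        return None

    def sort_key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)


@dataclass
class CloneGenome:
    """All retained SNVs of one clone plus its selection-marker genotype.

    ``marker_alleles`` maps each locus name ('HXT13', 'CAN1', 'URA3') to the
    tuple of alleles retained on the remaining homolog(s); a length-1 tuple
    on a diploid clone marks chromosome-V monosomy.  It is ``None`` for
    strains without the marker construct.
    """

    clone_id: str
    ploidy: int = 2
    variants: list[Variant] = field(default_factory=list)
    marker_alleles: dict[str, tuple[str, ...]] | None = None
    chrom_lengths: dict[str, int] = field(default_factory=lambda: dict(YEAST_CHROM_LENGTHS))

    def __post_init__(self) -> None:
        if self.ploidy not in (1, 2):
            raise ValueError(f"ploidy must be 1 or 2, got {self.ploidy}")
        self.variants.sort(key=Variant.sort_key)
        if self.ploidy == 1 and any(v.genotype == "het" for v in self.variants):
            raise ValueError("haploid clone cannot carry heterozygous variants")

    def on_chrom(self, chrom: str) -> list[Variant]:
        return [v for v in self.variants if v.chrom == chrom]

    @property
    def n_het(self) -> int:
        return sum(v.genotype == "het" for v in self.variants)

    @property
    def n_hom(self) -> int:
        return sum(v.genotype == "hom" for v in self.variants)

    def copy(self) -> "CloneGenome":
        return CloneGenome(
            clone_id=self.clone_id,
            ploidy=self.ploidy,
            variants=[replace(v) for v in self.variants],
            marker_alleles=None if self.marker_alleles is None else dict(self.marker_alleles),
            chrom_lengths=dict(self.chrom_lengths),
        )


# Alleles carried by each parental haplotype at the chrV-L marker loci.
_HAPLOTYPE_ALLELES: dict[str, dict[str, str]] = {
    "A": {"HXT13": "ADE2", "CAN1": "CAN1", "URA3": "URA3"},
    "B": {"HXT13": "HXT13", "CAN1": "can1-G1018A", "URA3": "ura3"},
}


@dataclass(frozen=True)
class MarkerMap:
    """Ordered chromosome-V left-arm marker loci with parental phase.

    Coordinates are 1-based; the left arm is everything below the CEN5
    start.  Default coordinates place the ADE2 insert (at HXT13), CAN1,
    URA3 and CEN5 so that URA3–CAN1 spans the long ~80 kb interval in
    which most selected crossovers fall.
    """

    chrom: str = "chrV"
    ade2_insert: int = 22_500
    can1: int = 32_000
    ura3: int = 116_000
    cen5: int = 152_000
    can1_mut_site: int = 1018  # offset of the G1018A site within CAN1

    def __post_init__(self) -> None:
        if not (0 < self.ade2_insert < self.can1 < self.ura3 < self.cen5):
            raise ValueError("marker order must be telomere < ADE2 insert < CAN1 < URA3 < CEN5")

    def is_left_arm(self, pos: int) -> bool:
        return pos < self.cen5

    @property
    def locus_positions(self) -> dict[str, int]:
        return {"HXT13": self.ade2_insert, "CAN1": self.can1, "URA3": self.ura3}

    def haplotype_allele(self, haplotype: str, locus: str) -> str:
        return _HAPLOTYPE_ALLELES[haplotype][locus]

    def heterozygous_alleles(self) -> dict[str, tuple[str, str]]:
        """Marker genotype of the unrecombined assay diploid (A allele first)."""
        return {
            locus: (_HAPLOTYPE_ALLELES["A"][locus], _HAPLOTYPE_ALLELES["B"][locus])
            for locus in ("HXT13", "CAN1", "URA3")
        }

    @property
    def interval_ura3_can1(self) -> int:
        return self.ura3 - self.can1

    @property
    def interval_cen_ura3(self) -> int:
        return self.cen5 - self.ura3

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "chrom": self.chrom,
                    "ade2_insert": self.ade2_insert,
                    "can1": self.can1,
                    "ura3": self.ura3,
                    "cen5": self.cen5,
                    "can1_mut_site": self.can1_mut_site,
                },
                fh,
            )

    @classmethod
    def from_yaml(cls, path) -> "MarkerMap":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


_BASES = np.frombuffer(b"ACGT", dtype="S1")


class SyntheticReference:
    """A reference genome backing synthetic variant placement.

    Either a seeded random genome with yeast-like chromosome sizes (the
    default) or a user FASTA.  Only base identity is used: deamination
    variants are placed on C (C→T) or G (G→A) reference positions.
    """

    def __init__(self, sequences: dict[str, np.ndarray]):
        #: per-chromosome arrays of b'A'/b'C'/b'G'/b'T'
        self.sequences = sequences
        self.chrom_lengths = {c: int(len(s)) for c, s in sequences.items()}

    @classmethod
    def yeast_like(
        cls,
        seed: int = 0,
        chrom_lengths: dict[str, int] | None = None,
        gc: float = 0.38,
    ) -> "SyntheticReference":
        """Seeded random genome with yeast-like chromosomes and GC content."""
        lengths = dict(YEAST_CHROM_LENGTHS) if chrom_lengths is None else dict(chrom_lengths)
        rng = np.random.default_rng(seed)
        p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        seqs = {c: _BASES[rng.choice(4, size=n, p=p)] for c, n in lengths.items()}
        return cls(seqs)

    @classmethod
    def from_fasta(cls, path) -> "SyntheticReference":
        from pyfaidx import Fasta

        fa = Fasta(str(path))
        seqs = {
            name: np.frombuffer(str(fa[name][:]).upper().encode(), dtype="S1").copy()
            for name in fa.keys()
        }
        return cls(seqs)

    def base(self, chrom: str, pos: int) -> str:
        return self.sequences[chrom][pos - 1].decode()

    def cg_positions(self, chrom: str, start: int = 1, end: int | None = None) -> np.ndarray:
        """1-based positions of C or G bases within [start, end]."""
        seq = self.sequences[chrom]
        end = len(seq) if end is None else min(end, len(seq))
        window = seq[start - 1 : end]
        idx = np.flatnonzero((window == b"C") | (window == b"G"))
        return idx + start

    def sample_deamination_sites(
        self,
        chrom: str,
        n: int,
        rng: np.random.Generator,
        start: int = 1,
        end: int | None = None,
        exclude: set[int] | None = None,
    ) -> list[tuple[int, str, str]]:
        """Sample ``n`` distinct C/G positions, returning (pos, ref, alt)."""
        sites = self.cg_positions(chrom, start, end)
        if exclude:
            sites = sites[~np.isin(sites, list(exclude))]
        if n > len(sites):
            raise ValueError(
                f"requested {n} deamination sites on {chrom}[{start}:{end}] but only {len(sites)} C/G positions available"
            )
        chosen = np.sort(rng.choice(sites, size=n, replace=False))
        out = []
        for pos in chosen:
            ref = self.base(chrom, int(pos))
            alt = "T" if ref == "C" else "A"
            out.append((int(pos), ref, alt))
        return out

    def to_fasta(self, path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for chrom, seq in self.sequences.items():
                fh.write(f">{chrom}\n")
                s = seq.tobytes().decode()
                for i in range(0, len(s), width):
                    fh.write(s[i : i + width] + "\n")
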