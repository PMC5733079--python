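"""Reading and writing clone genomes as VCF, plus BED masks and metadata tables.

Clone VCFs are v4.2, one sample per file, diploid genotypes ``0/1`` / ``1/1``
and haploid ``1``; the FisherStrand score travels in ``INFO/FS``, the
generating process in ``INFO/ORIGIN`` and the parental haplotype of
heterozygous calls in ``INFO/HAP`` so that a write→read round trip is
lossless.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import pysam

from .genomes import CloneGenome, Variant

__all__ = ["write_clone_vcf", "read_clone_vcf", "read_bed_mask", "read_clone_metadata", "VcfParseError"]


class VcfParseError(ValueError):
    """Raised when a clone VCF cannot be parsed; carries file and line context."""


def _header_for(clone: CloneGenome) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line('##fileformat=VCFv4.2')
    for chrom, length in clone.chrom_lengths.items():
        header.contigs.add(chrom, length=length)
    header.add_line('##INFO=<ID=FS,Number=1,Type=Float,Description="Phred-scaled FisherStrand strand-bias score">')
    header.add_line('##INFO=<ID=ORIGIN,Number=1,Type=String,Description="Generating process tag">')
    header.add_line('##INFO=<ID=HAP,Number=1,Type=String,Description="Parental haplotype of a heterozygous allele">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line(f'##lohsim_ploidy={clone.ploidy}')
    header.add_sample(clone.clone_id)
    return header


def write_clone_vcf(clone: CloneGenome, path) -> None:
    """Serialise a clone to an uncompressed VCF file."""
    path = str(path)
    header = _header_for(clone)
    with pysam.VariantFile(path, "w", header=header) as vcf:
        for v in clone.variants:
            rec = vcf.new_record(
                contig=v.chrom,
                start=v.pos - 1,
                stop=v.pos,
                alleles=(v.ref, v.alt),
            )
            if v.fs is not None:
                rec.info["FS"] = float(v.fs)
            rec.info["ORIGIN"] = v.origin
            rec.info["HAP"] = v.haplotype
            sample = rec.samples[clone.clone_id]
            if clone.ploidy == 1:
                sample["GT"] = (1,)
            else:
                sample["GT"] = (1, 1) if v.genotype == "hom" else (0, 1)
            vcf.write(rec)


def read_clone_vcf(path) -> CloneGenome:
    """Parse a clone VCF back into a :class:`CloneGenome`.

    Raises :class:`VcfParseError` (with file/line context where available)
    on malformed input or unsorted records.
    """
    path = str(path)
    try:
        vcf = pysam.VariantFile(path)
    except (ValueError, OSError) as exc:
        raise VcfParseError(f"{path}: cannot parse VCF header: {exc}") from exc

    ploidy = 2
    for line in str(vcf.header).splitlines():
        if line.startswith("##lohsim_ploidy="):
            ploidy = int(line.split("=", 1)[1])
    samples = list(vcf.header.samples)
    clone_id = samples[0] if samples else Path(path).stem
    chrom_lengths = {c: vcf.header.contigs[c].length for c in vcf.header.contigs}

    n_header = sum(1 for line in str(vcf.header).splitlines() if line.startswith("#"))
    variants: list[Variant] = []
    last: tuple[str, int] | None = None
    seen_chroms: list[str] = []
    try:
        for i, rec in enumerate(vcf.fetch() if vcf.index is not None else vcf):
            lineno = n_header + i + 1
            if rec.alts is None or len(rec.alts) != 1:
                raise VcfParseError(f"{path}:{lineno}: expected exactly one ALT allele")
            gt = rec.samples[clone_id]["GT"] if samples else (1, 1)
            if ploidy == 1 or gt == (1,):
                genotype = "hom"
            elif None in gt:
                raise VcfParseError(f"{path}:{lineno}: missing genotype")
            else:
                genotype = "hom" if all(a == 1 for a in gt) else "het"
            if rec.chrom == (last[0] if last else None) and rec.pos < last[1]:
                raise VcfParseError(f"{path}:{lineno}: records not sorted by position")
            if rec.chrom != (last[0] if last else None):
                if rec.chrom in seen_chroms:
                    raise VcfParseError(f"{path}:{lineno}: records not grouped by chromosome")
                seen_chroms.append(rec.chrom)
            last = (rec.chrom, rec.pos)
            fs = rec.info.get("FS")
            variants.append(
                Variant(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=rec.alts[0],
                    genotype=genotype,
                    fs=None if fs is None else float(fs),
                    origin=str(rec.info.get("ORIGIN", "replication")),
                    haplotype=str(rec.info.get("HAP", "A")),
                )
            )
    except VcfParseError:
        raise
    except (ValueError, OSError) as exc:
        raise VcfParseError(f"{path}: malformed VCF body: {exc}") from exc
    finally:
        vcf.close()

    return CloneGenome(
        clone_id=clone_id,
        ploidy=ploidy,
        variants=variants,
        chrom_lengths={c: n for c, n in chrom_lengths.items() if n is not None},
    )


def read_bed_mask(path) -> list[tuple[str, int, int]]:
    """Read a BED genome mask as (chrom, start, end) with BED half-open
    0-based coordinates."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", usecols=[0, 1, 2],
                     names=["chrom", "start", "end"], dtype={"chrom": str})
    return [(r.chrom, int(r.start), int(r.end)) for r in df.itertuples()]


def read_clone_metadata(path) -> pd.DataFrame:
    """Clone metadata table: clone_id, day, selection (TSV)."""
    df = pd.read_csv(path, sep="\t")
    required = {"clone_id", "day"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"clone metadata missing columns: {sorted(missing)}")
    return df
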