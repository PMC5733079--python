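"""Chromosome-V marker assay: phenotypes, event classes, proportions, frequencies.

The assay diploid is heterozygous for three phased markers on the left arm
of chromosome V — an ADE2 insert at HXT13, the functional CAN1 (opposite
the resident can1-G1018A allele) and URA3 — with the functional alleles in
cis.  A canavanine-resistant clone's Ade/Ura phenotype and CAN1 genotype
identify which genetic event removed the functional CAN1 copy: an
independent point mutation, gene conversion, a crossover in one of the two
marker intervals, whole-chromosome loss, or completed meiosis (haploid).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .genomes import CloneGenome, MarkerMap
from .simulate import PlatingResult

__all__ = [
    "ClonePhenotype",
    "EventClass",
    "ClassificationError",
    "phenotype_from_genotype",
    "classify_event",
    "class_proportions",
    "plating_frequency",
    "summarize_frequencies",
    "fold_change",
    "orders_of_magnitude",
]


class EventClass(str, Enum):
    CAN1_POINT_MUTATION = "CAN1_POINT_MUTATION"
    CAN1_GENE_CONVERSION = "CAN1_GENE_CONVERSION"
    CROSSOVER_URA3_CAN1 = "CROSSOVER_URA3_CAN1"
    CROSSOVER_CEN_URA3 = "CROSSOVER_CEN_URA3"
    CHROMOSOME_LOSS = "CHROMOSOME_LOSS"
    HAPLOID = "HAPLOID"


class ClassificationError(ValueError):
    """An internally inconsistent marker phenotype."""


@dataclass(frozen=True)
class ClonePhenotype:
    can_resistant: bool
    ade_plus: bool
    ura_plus: bool
    can1_g1018a_state: str  # het | hom | absent
    new_can1_mutation: bool
    ploidy: int
    chrV_monosomy: bool


def phenotype_from_genotype(clone: CloneGenome, marker_map: MarkerMap) -> ClonePhenotype:
    """Derive plate phenotypes from the clone's marker genotype.

    Ade+ iff the ADE2 insert survives on at least one retained homolog,
    Ura+ iff a functional URA3 survives, canavanine resistance iff no
    functional CAN1 copy remains.
    """
    if clone.marker_alleles is None:
        raise ValueError(f"clone {clone.clone_id} carries no marker genotype (phase missing)")
    alleles = clone.marker_alleles
    for locus in ("HXT13", "CAN1", "URA3"):
        if locus not in alleles:
            raise ValueError(f"clone {clone.clone_id}: marker {locus} missing")
    can1 = alleles["CAN1"]
    n_g1018a = sum(a == "can1-G1018A" for a in can1)
    if n_g1018a == len(can1):
        g_state = "hom"  # covers the hemizygous single-allele case too
    elif n_g1018a >= 1:
        g_state = "het"
    else:
        g_state = "absent"
    return ClonePhenotype(
        can_resistant=not any(a == "CAN1" for a in can1),
        ade_plus=any(a == "ADE2" for a in alleles["HXT13"]),
        ura_plus=any(a == "URA3" for a in alleles["URA3"]),
        can1_g1018a_state=g_state,
        new_can1_mutation=any(a == "can1-new" for a in can1),
        ploidy=clone.ploidy,
        chrV_monosomy=clone.ploidy == 2 and len(can1) == 1,
    )


def classify_event(ph: ClonePhenotype) -> EventClass:
    """Map a resistant clone's phenotype to its generating event class.

    Decision tree: haploid → HAPLOID; chrV monosomy → CHROMOSOME_LOSS;
    Ade− Ura− → crossover in CEN5–URA3; Ade− Ura+ → crossover in
    URA3–CAN1; Ade+ Ura+ with homozygous G1018A → gene conversion (this
    class also absorbs crossovers between the ADE2 insert and CAN1, which
    are phenotypically indistinguishable); Ade+ Ura+ with heterozygous
    G1018A and a new CAN1 mutation → independent point mutation.
    """
    if not ph.can_resistant:
        raise ClassificationError("event classification applies to canavanine-resistant clones only")
    if ph.can1_g1018a_state == "hom" and ph.new_can1_mutation:
        raise ClassificationError("homozygous G1018A cannot co-occur with a new CAN1 mutation")
    if ph.ploidy == 1:
        return EventClass.HAPLOID
    if ph.chrV_monosomy:
        return EventClass.CHROMOSOME_LOSS
    if not ph.ade_plus and not ph.ura_plus:
        return EventClass.CROSSOVER_CEN_URA3
    if not ph.ade_plus and ph.ura_plus:
        return EventClass.CROSSOVER_URA3_CAN1
    if ph.ade_plus and ph.ura_plus:
        if ph.can1_g1018a_state == "hom":
            return EventClass.CAN1_GENE_CONVERSION
        if ph.can1_g1018a_state == "het" and ph.new_can1_mutation:
            return EventClass.CAN1_POINT_MUTATION
    raise ClassificationError(f"no event class matches phenotype {ph}")


def class_proportions(
    classes_per_culture: list[list[EventClass]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pooled event-class proportions over all tested colonies.

    Colonies from all cultures are pooled; per-class Wilson binomial
    confidence intervals at level ``1 - alpha``.
    """
    if not classes_per_culture:
        raise ValueError("need at least one culture")
    pooled = [c for culture in classes_per_culture for c in culture]
    if not pooled:
        raise ValueError("zero colonies tested")
    n = len(pooled)
    rows = []
    for cls in EventClass:
        k = sum(c == cls for c in pooled)
        lo, hi = proportion_confint(k, n, alpha=alpha, method="wilson")
        rows.append({"event": cls.value, "count": k, "n": n,
                     "proportion": k / n, "ci_low": float(lo), "ci_high": float(hi)})
    return pd.DataFrame(rows)


def plating_frequency(p: PlatingResult) -> float:
    """Dilution-corrected resistant frequency from one day's plating."""
    if p.n_plated_selective <= 0 or p.n_plated_permissive <= 0:
        raise ValueError("plated cell counts must be positive")
    if p.n_viable == 0:
        raise ValueError("no viable colonies; frequency undefined")
    return (p.n_resistant / p.n_plated_selective) / (p.n_viable / p.n_plated_permissive)


def summarize_frequencies(values) -> dict[str, float]:
    """Tukey box-and-whisker summary of a set of frequencies.

    Quartiles by linear interpolation; the upper whisker is the smaller of
    the maximum and Q3 + 1.5·IQR, the lower whisker the larger of the
    minimum and Q1 − 1.5·IQR.
    """
    x = np.asarray(list(values), dtype=float)
    if x.size == 0:
        raise ValueError("no values to summarise")
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    iqr = q3 - q1
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "iqr": float(iqr),
        "whisker_low": float(max(x.min(), q1 - 1.5 * iqr)),
        "whisker_high": float(min(x.max(), q3 + 1.5 * iqr)),
        "n": int(x.size),
    }


def fold_change(a: float, b: float) -> float:
    """How many times larger ``a`` is than ``b``."""
    if b <= 0:
        raise ValueError("reference frequency must be positive")
    return a / b


def orders_of_magnitude(a: float, b: float) -> float:
    """log10 of the ratio a/b — the order-of-magnitude gap between two frequencies."""
    if a <= 0 or b <= 0:
        raise ValueError("frequencies must be positive")
    return float(np.log10(a / b))
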