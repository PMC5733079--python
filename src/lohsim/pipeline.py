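"""Clone-genome analysis: filtering, zygosity, LOH calls, breakpoints, loads.

The core biological rule: deaminases produce almost exclusively
*heterozygous* SNVs in a diploid, so any homozygous SNV on the left arm of
chromosome V (where the selected reporter sits) — outside known shared
mutational hotspots — is evidence of a loss-of-heterozygosity event, even a
single one.  The hom/het transition along the arm brackets the
recombination breakpoint.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genomes import CloneGenome, MarkerMap, Variant

__all__ = [
    "ZygosityProfile",
    "ClusterCall",
    "LoadSummary",
    "filter_variants",
    "zygosity_profile",
    "call_loh",
    "estimate_breakpoint",
    "detect_reciprocal_polarity",
    "infer_ploidy",
    "load_summary",
    "compare_loads_across_days",
    "DEFAULT_FS_MAX",
]

#: Strand-bias retention cutoff: calls with FS above this are artifacts.
DEFAULT_FS_MAX = 20.0


@dataclass
class ZygosityProfile:
    """Ordered per-position zygosity along one chromosome."""

    chrom: str
    positions: np.ndarray
    zygosity: np.ndarray  # 'het' | 'hom'
    variants: list[Variant] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=int)
        self.zygosity = np.asarray(self.zygosity, dtype=object)
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")


@dataclass
class ClusterCall:
    """A contiguous run of SNVs interpreted as an LOH / break cluster."""

    chrom: str
    start: int
    end: int
    n_hom: int
    n_het: int
    distal_hom_proximal_het: bool = False
    reciprocal_polarity: bool | None = None
    breakpoint_interval: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("cluster start must not exceed end")
        if self.n_hom + self.n_het < 1:
            raise ValueError("cluster must contain at least one variant")

    @property
    def breakpoint_midpoint(self) -> float | None:
        if self.breakpoint_interval is None:
            return None
        lo, hi = self.breakpoint_interval
        return (lo + hi) / 2.0


@dataclass
class LoadSummary:
    clone_id: str
    day: int
    total: int
    n_hom: int
    n_het: int
    n_transitions: int
    reporter_state: str = "het"  # het | hom | hemizygous

    def __post_init__(self) -> None:
        if self.n_hom + self.n_het != self.total:
            raise ValueError("n_hom + n_het must equal total")


def filter_variants(
    variants: list[Variant],
    mask: list[tuple[str, int, int]] | None = None,
    fs_max: float = DEFAULT_FS_MAX,
) -> list[Variant]:
    """Post-filter a sorted variant list.

    Drops variants overlapping any mask interval (BED, 0-based half-open)
    and variants with FS strictly above ``fs_max`` (the boundary value is
    retained).  A missing FS annotation retains the variant with a warning.
    Order is preserved; the filter is idempotent and the two steps commute.
    """
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end in mask or []:
        if end > start:
            trees.setdefault(chrom, IntervalTree()).addi(start, end)

    kept: list[Variant] = []
    for v in variants:
        tree = trees.get(v.chrom)
        if tree is not None and tree.overlaps(v.pos - 1, v.pos):
            continue
        if v.fs is None:
            warnings.warn(f"variant {v.chrom}:{v.pos} has no FS annotation; retained")
        elif v.fs > fs_max:
            continue
        kept.append(v)
    return kept


def zygosity_profile(clone: CloneGenome, chrom: str) -> ZygosityProfile:
    """Ordered zygosity sequence of one chromosome of a clone."""
    if chrom not in clone.chrom_lengths:
        raise ValueError(f"unknown chromosome {chrom!r}")
    variants = clone.on_chrom(chrom)
    return ZygosityProfile(
        chrom=chrom,
        positions=np.array([v.pos for v in variants], dtype=int),
        zygosity=np.array([v.genotype for v in variants], dtype=object),
        variants=variants,
    )


def _left_arm_variants(clone: CloneGenome, marker_map: MarkerMap) -> list[Variant]:
    return [v for v in clone.on_chrom(marker_map.chrom) if marker_map.is_left_arm(v.pos)]


def call_loh(
    clone: CloneGenome,
    marker_map: MarkerMap,
    shared_hotspots: frozenset[int] = frozenset(),
) -> tuple[bool, ClusterCall | None]:
    """Call LOH on the reporter arm of a clone.

    Positive iff at least one homozygous SNV lies on chromosome-V-left
    (positions below CEN5), excluding configured shared hotspot positions
    where independent biallelic deamination is plausible.  A single
    homozygous SNV suffices.  Returns the arm-level cluster call when
    positive.
    """
    arm = _left_arm_variants(clone, marker_map)
    homs = [v for v in arm if v.genotype == "hom" and v.pos not in shared_hotspots]
    if not homs:
        return False, None
    hets = [v for v in arm if v.genotype == "het"]
    start = min(v.pos for v in homs)
    end = max(v.pos for v in homs)
    hets_in_span = [v for v in hets if start <= v.pos <= end]
    interval = estimate_breakpoint(zygosity_profile(clone, marker_map.chrom), marker_map)
    max_hom = max(v.pos for v in homs)
    distal_hom_proximal_het = any(v.pos > max_hom for v in hets)
    call = ClusterCall(
        chrom=marker_map.chrom,
        start=start,
        end=end,
        n_hom=len(homs),
        n_het=len(hets_in_span),
        distal_hom_proximal_het=distal_hom_proximal_het,
        breakpoint_interval=interval,
    )
    return True, call


def estimate_breakpoint(
    profile: ZygosityProfile,
    marker_map: MarkerMap,
) -> tuple[int, int] | None:
    """Bracket the LOH breakpoint by the hom→het transition on chrV-L.

    The interval runs from the most centromere-proximal homozygous variant
    of the distal homozygous run to the nearest heterozygous variant
    proximal to it.  Returns ``None`` when there is no transition (no LOH,
    or LOH covering the whole arm with no proximal het left).
    """
    on_arm = profile.positions < marker_map.cen5
    pos = profile.positions[on_arm]
    zyg = profile.zygosity[on_arm]
    hom_pos = pos[zyg == "hom"]
    het_pos = pos[zyg == "het"]
    if hom_pos.size == 0:
        return None
    lo = int(hom_pos.max())
    proximal_hets = het_pos[het_pos > lo]
    if proximal_hets.size == 0:
        return None  # whole-arm homozygosity
    return lo, int(proximal_hets.min())


def detect_reciprocal_polarity(
    variants: list[Variant],
    breakpoint: int,
    min_majority: float = 2.0 / 3.0,
) -> bool | None:
    """Do the two sides of a break show reciprocal deamination polarity?

    Considers only C→T / G→A calls.  Each side's polarity must reach the
    ``min_majority`` excess; sides with no deamination variants make the
    call indeterminate (``None``).  True iff the majorities differ —
    the signature of deamination of the two opposite resected strands.
    """
    def majority(side: list[Variant]) -> str | None:
        pols = [v.polarity for v in side if v.polarity is not None]
        if not pols:
            return None
        ct = pols.count("CT") / len(pols)
        if ct >= min_majority:
            return "CT"
        if 1.0 - ct >= min_majority:
            return "GA"
        return "mixed"

    distal = majority([v for v in variants if v.pos < breakpoint])
    proximal = majority([v for v in variants if v.pos >= breakpoint])
    if distal is None or proximal is None:
        return None
    if "mixed" in (distal, proximal):
        return False
    return distal != proximal


def infer_ploidy(
    clone: CloneGenome,
    het_fraction_min: float = 0.05,
    min_snvs: int = 20,
) -> int | None:
    """Infer clone ploidy from its genome-wide heterozygosity.

    A true haploid cannot carry heterozygous calls, so a het fraction
    below ``het_fraction_min`` (tolerating residual false het calls) marks
    a haploid.  Clones with fewer than ``min_snvs`` SNVs are indeterminate
    (returns ``None`` with a warning).
    """
    total = len(clone.variants)
    if total < min_snvs:
        warnings.warn(f"clone {clone.clone_id}: only {total} SNVs; ploidy indeterminate")
        return None
    het_fraction = clone.n_het / total
    return 1 if het_fraction < het_fraction_min else 2


def load_summary(clone: CloneGenome, day: int, marker_map: MarkerMap | None = None) -> LoadSummary:
    """Per-clone mutation-load and zygosity summary."""
    transitions = sum(
        (v.ref, v.alt) in (("C", "T"), ("G", "A"), ("T", "C"), ("A", "G")) for v in clone.variants
    )
    reporter_state = "het"
    if clone.marker_alleles is not None:
        can1 = clone.marker_alleles.get("CAN1", ())
        if len(can1) == 1:
            reporter_state = "hemizygous"
        elif len(set(can1)) == 1:
            reporter_state = "hom"
    elif clone.ploidy == 1:
        reporter_state = "hemizygous"
    return LoadSummary(
        clone_id=clone.clone_id,
        day=day,
        total=len(clone.variants),
        n_hom=clone.n_hom,
        n_het=clone.n_het,
        n_transitions=transitions,
        reporter_state=reporter_state,
    )


def _dunn_pairwise(groups: dict[int, np.ndarray]) -> pd.DataFrame:
    """Dunn's rank-based pairwise comparisons after an omnibus rank test.

    Standard z statistic on mean ranks of the pooled sample with tie
    correction; two-sided normal p-values, Bonferroni-adjusted.
    """
    days = sorted(groups)
    pooled = np.concatenate([groups[d] for d in days])
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    offsets = np.cumsum([0] + [len(groups[d]) for d in days])
    mean_ranks = {
        d: ranks[offsets[i]: offsets[i + 1]].mean() for i, d in enumerate(days)
    }
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n - 1))
    var_base = n * (n + 1) / 12.0 - tie_term

    rows = []
    for a, b in itertools.combinations(days, 2):
        na, nb = len(groups[a]), len(groups[b])
        se = np.sqrt(var_base * (1.0 / na + 1.0 / nb))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"day_a": a, "day_b": b, "z": z, "p_raw": p})
    df = pd.DataFrame(rows)
    df["p_adj"] = multipletests(df["p_raw"], method="bonferroni")[1]
    return df


def compare_loads_across_days(
    summaries: list[LoadSummary],
    alpha: float = 0.05,
) -> dict:
    """Are resistant-clone mutation loads day-independent?

    Kruskal–Wallis omnibus test across day groups followed by Dunn-type
    pairwise comparisons with Bonferroni adjustment.  Requires at least
    two day groups with n ≥ 3 each.  Returns the omnibus statistic and
    p-value, the pairwise table, per-day medians (effect direction) and
    accept/reject decisions at ``alpha``.
    """
    groups: dict[int, np.ndarray] = {}
    for day in sorted({s.day for s in summaries}):
        loads = np.array([s.total for s in summaries if s.day == day], dtype=float)
        if loads.size == 0:
            raise ValueError(f"empty group for day {day}")
        groups[day] = loads
    if len(groups) < 2:
        raise ValueError("need at least two day groups")
    for day, loads in groups.items():
        if loads.size < 3:
            raise ValueError(f"day {day} group has n={loads.size} < 3")

    h, p = stats.kruskal(*groups.values())
    pairwise = _dunn_pairwise(groups)
    pairwise["significant"] = pairwise["p_adj"] < alpha
    medians = {d: float(np.median(g)) for d, g in groups.items()}
    return {
        "statistic": float(h),
        "p_value": float(p),
        "reject": bool(p < alpha),
        "alpha": alpha,
        "n_per_day": {d: int(g.size) for d, g in groups.items()},
        "median_per_day": medians,
        "pairwise": pairwise,
    }


def summaries_to_frame(summaries: list[LoadSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "clone_id": [s.clone_id for s in summaries],
            "day": [s.day for s in summaries],
            "total": [s.total for s in summaries],
            "n_hom": [s.n_hom for s in summaries],
            "n_het": [s.n_het for s in summaries],
            "n_transitions": [s.n_transitions for s in summaries],
            "reporter_state": [s.reporter_state for s in summaries],
        }
    )
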