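"""Deterministic model of recessive mutant recovery in haploids and diploids.

A transiently hypermutable subpopulation (fraction ``f``) mutates a reporter
gene at rate ``mu_hyper`` per copy, the rest of the culture at ``mu_base``.
In a diploid a recessive resistant mutant can be recovered two ways:

* **coincidence** — both homologs mutate independently, at frequency
  ``f·mu_hyper² + (1−f)·mu_base²``;
* **mutation–segregation** — one heterozygous hit followed by a loss of
  heterozygosity (LOH) event at frequency ``r_loh``, giving
  ``[f·mu_hyper + (1−f)·mu_base]·r_loh``.

In a haploid a single hit suffices, so the *predicted* frequency is the
linear mixture ``f·mu_hyper + (1−f)·mu_base``; the *observed* frequency
stays at ``mu_base`` because hypermutable haploids exceed the tolerable
genome-wide mutation load and die.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ModelParams",
    "MechanismCurve",
    "HaploidFrequencies",
    "coincidence_frequency",
    "segregation_frequency",
    "haploid_frequencies",
    "dominant_mechanism",
    "mechanism_curve_table",
    "default_fraction_grid",
    "DEFAULT_R_VALUES",
]

#: LOH frequencies for the two mutation-segregation curves: the low-
#: recombination regime and the same regime increased 100-fold.
DEFAULT_R_VALUES: tuple[float, float] = (3e-6, 3e-4)


@dataclass(frozen=True)
class ModelParams:
    """Per-cell per-assay rates governing reporter inactivation.

    Parameters
    ----------
    mu_base:
        Reporter inactivation frequency per gene copy in ordinary cells.
    mu_hyper:
        The same frequency in transiently hypermutable cells.
    r_loh:
        Per-cell frequency of an LOH event that homozygoses a
        heterozygous reporter mutation.
    haploid_tolerance:
        Maximum genome-wide mutation count compatible with haploid
        viability; hypermutable haploids typically exceed it.
    """

    mu_base: float = 1e-6
    mu_hyper: float = 1e-3
    r_loh: float = 3e-4
    haploid_tolerance: int = 1000

    def __post_init__(self) -> None:
        if not (0.0 < self.mu_base <= self.mu_hyper < 1.0):
            raise ValueError(
                f"need 0 < mu_base <= mu_hyper < 1, got mu_base={self.mu_base}, mu_hyper={self.mu_hyper}"
            )
        if not (0.0 <= self.r_loh < 1.0):
            raise ValueError(f"need 0 <= r_loh < 1, got {self.r_loh}")
        if self.haploid_tolerance <= 0:
            raise ValueError(f"haploid_tolerance must be positive, got {self.haploid_tolerance}")


@dataclass
class MechanismCurve:
    """One recovered-mutant frequency curve over a grid of hypermutable fractions."""

    fractions: np.ndarray
    frequencies: np.ndarray
    mechanism: str  # haploid-predicted | haploid-observed | diploid-coincidence | diploid-segregation
    r_used: float | None = None

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.fractions.shape != self.frequencies.shape:
            raise ValueError("fractions and frequencies must have the same length")
        finite = self.frequencies[np.isfinite(self.frequencies)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("frequencies must lie in [0, 1]")


@dataclass(frozen=True)
class HaploidFrequencies:
    predicted: float
    observed: float
    extinct: bool = False


def _check_fraction(f: float) -> float:
    f = float(f)
    if not (0.0 <= f <= 1.0):
        raise ValueError(f"hypermutable fraction must be in [0, 1], got {f}")
    return f


def coincidence_frequency(params: ModelParams, f: float) -> float:
    """Frequency of diploid mutants arising by independent hits in both homologs."""
    f = _check_fraction(f)
    return f * params.mu_hyper**2 + (1.0 - f) * params.mu_base**2


def segregation_frequency(params: ModelParams, f: float) -> float:
    """Frequency of diploid mutants arising by one heterozygous hit plus LOH."""
    f = _check_fraction(f)
    return (f * params.mu_hyper + (1.0 - f) * params.mu_base) * params.r_loh


def haploid_frequencies(params: ModelParams, f: float) -> HaploidFrequencies:
    """Predicted vs observed haploid mutant frequency.

    The prediction is the linear mixture of the two subpopulation rates.
    Observed recovery stays at ``mu_base`` because hypermutable haploids
    die of their genome-wide load; at ``f = 1`` the population is extinct
    and the observed frequency is undefined (NaN, ``extinct=True``).
    """
    f = _check_fraction(f)
    predicted = f * params.mu_hyper + (1.0 - f) * params.mu_base
    if f == 1.0:
        return HaploidFrequencies(predicted=predicted, observed=math.nan, extinct=True)
    return HaploidFrequencies(predicted=predicted, observed=params.mu_base, extinct=False)


def dominant_mechanism(params: ModelParams, f: float, threshold: float = 10.0) -> tuple[str, float]:
    """Which diploid mechanism dominates at fraction ``f``.

    Returns ``(label, ratio)`` with ``ratio = coincidence / segregation``.
    The label is ``"coincidence"`` above ``threshold``, ``"segregation"``
    below ``1/threshold`` and ``"comparable"`` in between; with ``r_loh = 0``
    the ratio is infinite and coincidence trivially dominates.
    """
    f = _check_fraction(f)
    if f == 0.0:
        raise ValueError("dominant_mechanism requires f > 0")
    if threshold <= 1.0:
        raise ValueError("threshold must exceed 1")
    coin = coincidence_frequency(params, f)
    seg = segregation_frequency(params, f)
    if seg == 0.0:
        return "coincidence", math.inf
    ratio = coin / seg
    if ratio > threshold:
        return "coincidence", ratio
    if ratio < 1.0 / threshold:
        return "segregation", ratio
    return "comparable", ratio


def default_fraction_grid(n: int = 41, lo: float = 1e-4, hi: float = 1.0) -> np.ndarray:
    """Log-spaced grid of hypermutable fractions used for curve tables."""
    if not (0.0 < lo < hi <= 1.0):
        raise ValueError("need 0 < lo < hi <= 1")
    return np.logspace(math.log10(lo), math.log10(hi), n)


def mechanism_curve_table(
    params: ModelParams,
    f_grid: Sequence[float] | None = None,
    r_values: Sequence[float] = DEFAULT_R_VALUES,
) -> list[MechanismCurve]:
    """All mechanism curves over a fraction grid.

    Emits haploid-predicted, haploid-observed, diploid-coincidence, and one
    diploid-segregation curve per LOH frequency in ``r_values``.
    """
    grid = np.asarray(default_fraction_grid() if f_grid is None else f_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("fraction grid is empty")
    if np.any(np.diff(grid) < 0):
        raise ValueError("fraction grid must be sorted ascending")
    if grid.min() < 0 or grid.max() > 1:
        raise ValueError("fractions must lie in [0, 1]")

    hap = [haploid_frequencies(params, f) for f in grid]
    curves = [
        MechanismCurve(grid, np.array([h.predicted for h in hap]), "haploid-predicted"),
        MechanismCurve(grid, np.array([h.observed for h in hap]), "haploid-observed"),
        MechanismCurve(grid, np.array([coincidence_frequency(params, f) for f in grid]), "diploid-coincidence"),
    ]
    for r in r_values:
        p = ModelParams(params.mu_base, params.mu_hyper, float(r), params.haploid_tolerance)
        curves.append(
            MechanismCurve(
                grid,
                np.array([segregation_frequency(p, f) for f in grid]),
                "diploid-segregation",
                r_used=float(r),
            )
        )
    return curves


def curves_to_frame(curves: Sequence[MechanismCurve]):
    """Tidy (mechanism, r, f, frequency) table for the curve set."""
    import pandas as pd

    rows = []
    for c in curves:
        for f, y in zip(c.fractions, c.frequencies):
            rows.append({"mechanism": c.mechanism, "r": c.r_used, "f": f, "frequency": y})
    return pd.DataFrame(rows)
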