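"""Luria-Delbrueck fluctuation-assay mutation-rate estimation.

Parallel cultures grown from small inocula are plated on selective medium
(here the canavanine-resistance paradigm); the wildly fluctuating mutant
colony counts reflect when mutations arose during growth.  Three steps
turn counts into a rate:

1. plating bookkeeping — scale the counted colonies back to mutant cells
   per culture, r, using plated volume, dilution and concentration;
2. Lea-Coulson correction — invert the implicit median relation
   ``r = M (1.24 + ln M)`` to convert the observed mutant count r into
   the number of independent mutation events M (each event's progeny all
   score as mutants);
3. rate — divide M by the total number of cells in the culture.

Per-culture rates are summarized by the cohort median with a 95%
confidence interval from exact binomial order statistics.  The classical
method-of-the-median variant (one correction applied to the median r) is
available via ``mode="median-r"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import binom

from .errors import ComputationError, ValidationError

__all__ = [
    "FluctuationCulture",
    "MutationRateEstimate",
    "mutants_per_culture",
    "lea_coulson_forward",
    "solve_lea_coulson",
    "mutation_rate",
    "median_confidence_interval",
    "summarize_rates",
    "estimate_rates",
    "read_culture_table",
    "write_culture_table",
]

#: the Lea-Coulson median constant in r = M (1.24 + ln M)
LEA_COULSON_CONSTANT = 1.24

CULTURE_COLUMNS = [
    "culture",
    "culture_volume_ml",
    "concentration_factor",
    "mutant_colonies",
    "plated_volume_ml",
    "dilution_factor",
    "total_cells",
]


@dataclass
class FluctuationCulture:
    """Plating bookkeeping for one independent culture."""

    culture_id: str
    culture_volume: float  # mL of resuspended culture
    concentration_factor: float  # >= 1, cells concentrated before plating
    mutant_colonies: int  # colonies counted on the selective plate
    plated_volume: float  # mL spread on the selective plate
    dilution_factor: float  # >= 1, dilution of the plated aliquot
    total_cells: float  # viable cells in the initial culture

    def __post_init__(self) -> None:
        if self.culture_volume <= 0 or self.plated_volume <= 0:
            raise ValidationError(f"culture {self.culture_id!r}: volumes must be > 0")
        if self.concentration_factor < 1 or self.dilution_factor < 1:
            raise ValidationError(
                f"culture {self.culture_id!r}: concentration and dilution factors "
                "must be >= 1"
            )
        if self.mutant_colonies < 0 or self.mutant_colonies != int(self.mutant_colonies):
            raise ValidationError(
                f"culture {self.culture_id!r}: mutant_colonies must be a "
                "non-negative integer"
            )
        if self.total_cells <= 0:
            raise ValidationError(f"culture {self.culture_id!r}: total_cells must be > 0")


@dataclass
class MutationRateEstimate:
    """Per-culture values and the cohort summary."""

    per_culture: pd.DataFrame  # culture, r, M, rate, zero_count flag
    median_rate: float
    ci_low: float
    ci_high: float
    n_cultures: int
    confidence: float = 0.95


def mutants_per_culture(culture: FluctuationCulture) -> float:
    """Mutant cells per culture, r, from the plating bookkeeping:

    ``r = culture_vol * (conc_factor * colonies / plated_vol * dilution)``.
    """
    return culture.culture_volume * (
        culture.concentration_factor
        * culture.mutant_colonies
        / culture.plated_volume
        * culture.dilution_factor
    )


def lea_coulson_forward(M: float) -> float:
    """Median mutant count r = M (1.24 + ln M); r = 0 at M = 0 by the limit."""
    if M < 0:
        raise ValidationError(f"M must be >= 0, got {M}")
    if M == 0:
        return 0.0
    return M * (LEA_COULSON_CONSTANT + math.log(M))


def solve_lea_coulson(r: float, tolerance: float = 1e-10) -> float:
    """Invert ``r = M (1.24 + ln M)`` for the number of mutation events M.

    The forward map is strictly increasing for M > exp(-1.24) and crosses
    0 there, so for r > 0 the root above exp(-1.24) is unique; it is
    bracketed and found with Brent's method to ``|forward(M) - r| <=
    tolerance``.  r = 0 maps to M = 0.
    """
    if r < 0:
        raise ValidationError(f"r must be >= 0, got {r}")
    if r == 0:
        return 0.0
    lo = math.exp(-LEA_COULSON_CONSTANT)  # forward(lo) = 0 < r
    hi = max(r, 10.0)
    for _ in range(200):
        if lea_coulson_forward(hi) >= r:
            break
        hi *= 10.0
    else:
        raise ComputationError(f"could not bracket the Lea-Coulson root for r={r}")
    M = brentq(lambda m: lea_coulson_forward(m) - r, lo, hi, xtol=1e-15, rtol=1e-14)
    if abs(lea_coulson_forward(M) - r) > max(tolerance, tolerance * abs(r)):
        raise ComputationError(f"Lea-Coulson inversion did not converge for r={r}")
    return float(M)


def mutation_rate(M: float, total_cells: float) -> float:
    """Mutation rate per cell per culture growth: M / total_cells."""
    if total_cells <= 0:
        raise ValidationError(f"total_cells must be > 0, got {total_cells}")
    if M < 0:
        raise ValidationError(f"M must be >= 0, got {M}")
    return M / total_cells


def median_confidence_interval(
    values: Sequence[float], confidence: float = 0.95
) -> tuple[float, float, float, tuple[int, int]]:
    """Sample median with an exact order-statistic confidence interval.

    Picks the tightest pair of order statistics (x_(l), x_(u)), 1-based,
    whose exact coverage ``P(l <= B <= u - 1)`` for B ~ Binomial(n, 1/2)
    reaches ``confidence``; ties broken by symmetry.  For small n no pair
    reaches the nominal level and the full range (l, u) = (1, n) is
    returned (its actual coverage is 1 - 2^(1-n)).
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n < 2:
        raise ComputationError("need at least 2 values for a median CI")
    med = float(np.median(x))
    best: tuple[int, int] | None = None
    for width in range(1, n):
        candidates = []
        for l in range(1, n - width + 1):
            u = l + width
            cover = binom.cdf(u - 1, n, 0.5) - binom.cdf(l - 1, n, 0.5)
            if cover >= confidence:
                candidates.append((abs((l - 1) - (n - u)), l, u))
        if candidates:
            _, l, u = min(candidates)
            best = (l, u)
            break
    if best is None:
        best = (1, n)
    l, u = best
    return med, float(x[l - 1]), float(x[u - 1]), (l, u)


def summarize_rates(
    rates: Sequence[float], confidence: float = 0.95
) -> tuple[float, float, float]:
    """Cohort median rate and its exact-binomial confidence interval."""
    med, lo, hi, _ = median_confidence_interval(rates, confidence)
    return med, lo, hi


def estimate_rates(
    cultures: Sequence[FluctuationCulture],
    mode: str = "per-culture",
    confidence: float = 0.95,
) -> MutationRateEstimate:
    """Full estimate for a cohort of parallel cultures.

    mode="per-culture" (default): the Lea-Coulson correction is applied
    to each culture's r and the cohort is summarized by the median of the
    per-culture rates.  mode="median-r": the classical method of the
    median — one correction applied to the median r, divided by the
    median cell count; per-culture columns are still reported and the CI
    is carried over from the per-culture rates.
    """
    if mode not in ("per-culture", "median-r"):
        raise ValidationError(f"unknown mode {mode!r}")
    if len(cultures) < 2:
        raise ComputationError("need at least 2 cultures")
    rows = []
    for c in cultures:
        r = mutants_per_culture(c)
        M = solve_lea_coulson(r)
        rows.append(
            {
                "culture": c.culture_id,
                "r": r,
                "M": M,
                "rate": mutation_rate(M, c.total_cells),
                "zero_count": c.mutant_colonies == 0,
            }
        )
    per_culture = pd.DataFrame(rows)
    med, lo, hi, _ = median_confidence_interval(
        per_culture["rate"].to_numpy(), confidence
    )
    if mode == "median-r":
        r_med = float(np.median(per_culture["r"]))
        cells_med = float(np.median([c.total_cells for c in cultures]))
        med = mutation_rate(solve_lea_coulson(r_med), cells_med)
    return MutationRateEstimate(per_culture, med, lo, hi, len(cultures), confidence)


def read_culture_table(path: str | Path) -> list[FluctuationCulture]:
    """Read the culture TSV dialect (one row per independent culture)."""
    df = pd.read_csv(path, sep="\t", dtype={"culture": str})
    missing = [c for c in CULTURE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    return [
        FluctuationCulture(
            culture_id=str(r["culture"]),
            culture_volume=float(r["culture_volume_ml"]),
            concentration_factor=float(r["concentration_factor"]),
            mutant_colonies=int(r["mutant_colonies"]),
            plated_volume=float(r["plated_volume_ml"]),
            dilution_factor=float(r["dilution_factor"]),
            total_cells=float(r["total_cells"]),
        )
        for _, r in df.iterrows()
    ]


def write_culture_table(cultures: Sequence[FluctuationCulture], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "culture": c.culture_id,
                "culture_volume_ml": c.culture_volume,
                "concentration_factor": c.concentration_factor,
                "mutant_colonies": c.mutant_colonies,
                "plated_volume_ml": c.plated_volume,
                "dilution_factor": c.dilution_factor,
                "total_cells": c.total_cells,
            }
            for c in cultures
        ]
    ).to_csv(path, sep="\t", index=False, float_format="%.12g")
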