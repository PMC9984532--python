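"""Synthetic datasets with the statistical structure the analysis assumes.

Three generators, each returning ground truth alongside the data so every
pipeline stage can be tested by parameter recovery:

* colony screens — plates under the multiplicative fitness model
  (base size x query fitness x gene fitness x interaction x smooth
  spatial surface x lognormal noise), laid out in the screening
  geometry: 2x2 technical-replicate blocks, the queries of one gene
  adjacent, a 4-deep dummy border;
* fluctuation cohorts — mutation events arise per growth generation as a
  Poisson process over the cells dividing in that generation and each
  mutant clone expands by deterministic doubling to the end of growth
  (no death, no differential mutant fitness — exactly the assumptions of
  the Lea-Coulson estimator), then the plated aliquot is binomially
  subsampled per the plating bookkeeping;
* growth curves — logistic trajectories sampled at a fixed interval with
  additive Gaussian read noise floored at 0.

All draws for one dataset flow from a single generator seeded with one
integer, so identical seeds give byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .fluctuation import FluctuationCulture
from .growth import GrowthCurve
from .plates import ColonyPlate, PlateLayout, PlateStage, Role
from .spatial import CorrectionSurface

__all__ = [
    "ScreenTruth",
    "PlatingSpec",
    "generate_screen",
    "generate_fluctuation",
    "generate_growth",
]

#: arbitrary base colony size in quantification units
BASE_COLONY_SIZE = 300.0


@dataclass
class ScreenTruth:
    """Ground truth behind one generated screen."""

    query_fitness: dict[str, float]
    gene_fitness: dict[str, float]
    interaction: dict[tuple[str, str], float]  # 1 = no interaction
    spatial: dict[str, CorrectionSurface]
    noise_sigma: float
    seed: int
    base_size: float = BASE_COLONY_SIZE


@dataclass
class PlatingSpec:
    """How a culture is plated; defaults plate the entire culture."""

    culture_volume_ml: float = 1.0
    concentration_factor: float = 1.0
    plated_volume_ml: float = 1.0
    dilution_factor: float = 1.0

    @property
    def plated_fraction(self) -> float:
        f = self.plated_volume_ml / (
            self.culture_volume_ml * self.concentration_factor * self.dilution_factor
        )
        if not (0 < f <= 1):
            raise ValidationError(f"plating spec implies plated fraction {f}")
        return f


def _smooth_effects(n: int, gradient: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth positive effects with geometric mean 1 (one sinusoidal mode)."""
    phase = rng.uniform(0, 2 * np.pi)
    amp = gradient * rng.uniform(0.5, 1.0)
    logs = amp * np.sin(2 * np.pi * np.arange(n) / n + phase)
    logs -= logs.mean()
    return np.exp(logs)


def _block_shape(replicates: int) -> tuple[int, int]:
    """Most-square factorization of the replicate count (2x2 for R = 4)."""
    best = (1, replicates)
    for rows in range(1, int(math.isqrt(replicates)) + 1):
        if replicates % rows == 0:
            best = (rows, replicates // rows)
    return best


def generate_screen(
    n_genes: int,
    queries: Sequence[str] = ("wt", "query"),
    replicates: int = 4,
    *,
    interactions: Mapping[tuple[str, str], float] | None = None,
    query_fitness: Mapping[str, float] | None = None,
    gene_fitness: Mapping[str, float] | None = None,
    noise_sigma: float = 0.1,
    spatial_gradient: float = 0.2,
    n_rows: int = 32,
    n_cols: int = 48,
    border_width: int = 4,
    base_size: float = BASE_COLONY_SIZE,
    max_plates: int | None = None,
    seed: int = 0,
) -> tuple[list[ColonyPlate], PlateLayout, ScreenTruth]:
    """Generate raw plates, a layout and the ground truth for one screen.

    Colony size at an experimental position is
    ``base * query_fitness * gene_fitness * interaction * spatial(row, col)
    * exp(N(0, sigma^2))``; border dummies follow the same model at
    fitness 1; inner positions left over after tiling are empty (size 0).
    ``interactions`` maps (query, gene) pairs to a true fitness ratio
    (1 = none).  Gene names are ``g0001`` ...; unspecified single-mutant
    fitness defaults to 1.
    """
    if n_genes < 1 or replicates < 1 or len(queries) < 1:
        raise ValidationError("need n_genes >= 1, replicates >= 1, >= 1 query")
    if len(set(queries)) != len(queries):
        raise ValidationError("query names must be unique")
    rng = np.random.default_rng(seed)
    genes = [f"g{i + 1:04d}" for i in range(n_genes)]
    qf = {q: float((query_fitness or {}).get(q, 1.0)) for q in queries}
    gf = {g: float((gene_fitness or {}).get(g, 1.0)) for g in genes}
    inter = {(q, g): float(v) for (q, g), v in (interactions or {}).items()}
    unknown = [k for k in inter if k[0] not in qf or k[1] not in gf]
    if unknown:
        raise ValidationError(f"interactions reference unknown crosses: {unknown}")

    br, bc = _block_shape(replicates)
    tile_rows, tile_cols = br, bc * len(queries)  # queries side by side
    inner_rows = n_rows - 2 * border_width
    inner_cols = n_cols - 2 * border_width
    if inner_rows < tile_rows or inner_cols < tile_cols:
        raise ValidationError(
            f"gene tile {tile_rows}x{tile_cols} does not fit the "
            f"{inner_rows}x{inner_cols} experimental grid"
        )
    tiles_per_band = inner_cols // tile_cols
    bands_per_plate = inner_rows // tile_rows
    genes_per_plate = tiles_per_band * bands_per_plate
    n_plates = -(-n_genes // genes_per_plate)
    if max_plates is not None and n_plates > max_plates:
        raise ValidationError(
            f"{n_genes} genes x {len(queries)} queries x {replicates} replicates "
            f"need {n_plates} plates (capacity {genes_per_plate} genes/plate), "
            f"but max_plates={max_plates}"
        )

    plates: list[ColonyPlate] = []
    layout_rows: list[dict] = []
    spatial: dict[str, CorrectionSurface] = {}
    gene_iter = iter(genes)
    done = False
    for p in range(n_plates):
        plate_id = f"p{p + 1:02d}"
        row_eff = _smooth_effects(n_rows, spatial_gradient, rng)
        col_eff = _smooth_effects(n_cols, spatial_gradient, rng)
        spatial[plate_id] = CorrectionSurface(plate_id, row_eff, col_eff)
        surface = row_eff[:, None] * col_eff[None, :]
        noise = np.exp(rng.normal(0.0, noise_sigma, size=(n_rows, n_cols)))
        sizes = np.zeros((n_rows, n_cols))
        occupied = np.zeros((n_rows, n_cols), dtype=bool)

        for band in range(bands_per_plate):
            for t in range(tiles_per_band):
                gene = next(gene_iter, None)
                if gene is None:
                    done = True
                    break
                r0 = border_width + band * tile_rows
                c0 = border_width + t * tile_cols
                for qi, q in enumerate(queries):
                    mean = base_size * qf[q] * gf[gene] * inter.get((q, gene), 1.0)
                    for rep in range(replicates):
                        dr, dc = rep // bc, rep % bc
                        rr, cc = r0 + dr, c0 + qi * bc + dc
                        sizes[rr, cc] = mean * surface[rr, cc] * noise[rr, cc]
                        occupied[rr, cc] = True
                        layout_rows.append(
                            {
                                "plate": plate_id,
                                "row": rr + 1,
                                "col": cc + 1,
                                "query": q,
                                "gene": gene,
                                "replicate": rep + 1,
                                "role": Role.EXPERIMENT.value,
                            }
                        )
            if done:
                break
        # dummy border at fitness 1, same surface and noise model
        for rr in range(n_rows):
            for cc in range(n_cols):
                on_border = (
                    rr < border_width
                    or rr >= n_rows - border_width
                    or cc < border_width
                    or cc >= n_cols - border_width
                )
                if on_border:
                    sizes[rr, cc] = base_size * surface[rr, cc] * noise[rr, cc]
                    layout_rows.append(
                        {
                            "plate": plate_id,
                            "row": rr + 1,
                            "col": cc + 1,
                            "query": None,
                            "gene": None,
                            "replicate": 0,
                            "role": Role.BORDER_DUMMY.value,
                        }
                    )
                elif not occupied[rr, cc]:
                    layout_rows.append(
                        {
                            "plate": plate_id,
                            "row": rr + 1,
                            "col": cc + 1,
                            "query": None,
                            "gene": None,
                            "replicate": 0,
                            "role": Role.EMPTY.value,
                        }
                    )
        plates.append(ColonyPlate(plate_id, sizes, PlateStage.RAW))
    layout = PlateLayout(
        pd.DataFrame(layout_rows),
        n_rows=n_rows,
        n_cols=n_cols,
        replicates=replicates,
        border_width=border_width,
    )
    truth = ScreenTruth(qf, gf, inter, spatial, noise_sigma, seed, base_size)
    return plates, layout, truth


def generate_fluctuation(
    mu: float,
    n0: float = 1e3,
    n_final: float = 1e8,
    n_cultures: int = 14,
    plating: PlatingSpec | None = None,
    seed: int = 0,
) -> tuple[list[FluctuationCulture], dict]:
    """Simulate a cohort of parallel cultures under the jackpot model.

    Growth proceeds by generations from ``n0`` to ``n_final`` (a final
    partial generation covers non-power-of-two ratios).  In each
    generation the number of new mutation events is Poisson with mean
    ``mu x (cells produced)``, and every mutant clone thereafter grows
    deterministically with the culture, giving the characteristic
    heavy-tailed ("jackpot") mutant-count distribution.  The plated
    aliquot receives a Binomial(r, plated fraction) subsample of mutants.

    Returns the culture records and a truth dict with the true rate and
    per-culture event/mutant counts.
    """
    if not (0 <= mu <= 1e-3):
        raise ValidationError(f"mu must be in [0, 1e-3], got {mu}")
    if n_final <= n0 or n0 < 1:
        raise ValidationError("need n_final > n0 >= 1")
    if n_cultures < 1:
        raise ValidationError("need at least 1 culture")
    plating = plating or PlatingSpec()
    frac = plating.plated_fraction
    rng = np.random.default_rng(seed)
    g_full = int(math.floor(math.log2(n_final / n0)))
    cultures = []
    truth_rows = []
    for i in range(n_cultures):
        pop = float(n0)
        mutants = 0.0
        events = 0
        for _ in range(g_full):
            m = rng.poisson(mu * pop)  # one event per newly made cell
            events += int(m)
            mutants = mutants * 2.0 + m  # existing clones double, new clones size 1
            pop *= 2.0
        if pop < n_final:  # partial last generation
            factor = n_final / pop
            m = rng.poisson(mu * pop * (factor - 1.0))
            events += int(m)
            mutants = mutants * factor + m
            pop = float(n_final)
        r_true = int(round(mutants))
        colonies = int(rng.binomial(r_true, frac)) if r_true > 0 else 0
        cultures.append(
            FluctuationCulture(
                culture_id=f"c{i + 1:02d}",
                culture_volume=plating.culture_volume_ml,
                concentration_factor=plating.concentration_factor,
                mutant_colonies=colonies,
                plated_volume=plating.plated_volume_ml,
                dilution_factor=plating.dilution_factor,
                total_cells=pop,
            )
        )
        truth_rows.append(
            {"culture": f"c{i + 1:02d}", "events": events, "mutant_cells": r_true}
        )
    truth = {
        "mu": mu,
        "n0": n0,
        "n_final": n_final,
        "seed": seed,
        "per_culture": pd.DataFrame(truth_rows),
    }
    return cultures, truth


def generate_growth(
    inoculum: float = 0.05,
    rate: float = 0.7,
    capacity: float = 1.0,
    duration: float = 20.0,
    interval: float = 1.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
    sample_id: str = "sim",
) -> GrowthCurve:
    """Logistic OD600 trajectory sampled at a fixed interval.

    ``od(t) = K / (1 + (K / x0 - 1) exp(-rate * t))`` plus additive
    Gaussian noise, floored at 0.  With ``capacity >> inoculum`` the
    early phase is exponential at ``rate`` per hour.
    """
    if not (0 < inoculum < capacity):
        raise ValidationError("need 0 < inoculum < capacity")
    if rate < 0 or duration <= 0 or interval <= 0 or noise_sigma < 0:
        raise ValidationError("invalid growth-curve parameters")
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, duration + interval / 2, interval)
    if rate == 0:
        od = np.full(times.shape, inoculum)
    else:
        od = capacity / (1.0 + (capacity / inoculum - 1.0) * np.exp(-rate * times))
    if noise_sigma > 0:
        od = od + rng.normal(0.0, noise_sigma, size=od.shape)
    od = np.maximum(od, 0.0)
    return GrowthCurve(sample_id, times, od)
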