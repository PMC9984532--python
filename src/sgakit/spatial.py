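"""Per-plate spatial correction and median normalization.

Colony arrays show smooth multiplicative gradients (nutrient access,
pinning pressure, incubator position).  Each plate is processed in three
steps:

1. mask — empty positions and the dummy border are set to missing so only
   experimental crosses enter any statistic;
2. correct — a multiplicative row x column surface is fitted by median
   polish on log sizes and divided out;
3. normalize — every surviving value is divided by the plate median, so
   plates are comparable on a common scale with median 1.

Median polish is used because it is deterministic, robust to the sick
colonies the screen is designed to find, and exact on separable
multiplicative gradients.  Effects are gauge-fixed to geometric mean 1, so
the overall plate level stays in the data and correction commutes with
global rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ComputationError, ValidationError
from .plates import ColonyPlate, PlateLayout, PlateStage, Role, ScreenConfig

__all__ = [
    "CorrectionSurface",
    "mask_non_experimental",
    "median_polish",
    "correct_spatial",
    "normalize_to_plate_median",
    "write_surface_table",
]


@dataclass
class CorrectionSurface:
    """Fitted multiplicative plate surface.

    ``row_effects`` and ``col_effects`` are strictly positive with
    geometric mean 1 over the rows/columns that carried data (others are
    neutral at 1), so the surface is identifiable and dividing by it does
    not change the overall plate level.
    """

    plate_id: str
    row_effects: np.ndarray
    col_effects: np.ndarray
    residual_surface: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.row_effects = np.asarray(self.row_effects, float)
        self.col_effects = np.asarray(self.col_effects, float)
        if (self.row_effects <= 0).any() or (self.col_effects <= 0).any():
            raise ValidationError(f"plate {self.plate_id!r}: non-positive effects")

    def grid(self, n_rows: int | None = None, n_cols: int | None = None) -> np.ndarray:
        surface = self.row_effects[:, None] * self.col_effects[None, :]
        if self.residual_surface is not None:
            surface = surface * self.residual_surface
        return surface


def mask_non_experimental(plate: ColonyPlate, layout: PlateLayout) -> ColonyPlate:
    """Set every non-experimental position (border dummy, empty) to missing.

    Experimental values, including those already missing, are untouched.
    The plate stays at its current stage (masking is not a correction).
    """
    if (plate.n_rows, plate.n_cols) != (layout.n_rows, layout.n_cols):
        raise ValidationError(
            f"plate {plate.plate_id!r} is {plate.n_rows}x{plate.n_cols} but layout "
            f"declares {layout.n_rows}x{layout.n_cols}"
        )
    roles = layout.role_grid(plate.plate_id)
    sizes = plate.sizes.copy()
    sizes[roles != Role.EXPERIMENT.value] = np.nan
    return ColonyPlate(plate.plate_id, sizes, plate.stage)


def _nanmedian_rows(a: np.ndarray, axis: int) -> np.ndarray:
    """nanmedian along ``axis`` returning 0 for all-missing slices, silently."""
    count = np.sum(np.isfinite(a), axis=axis)
    out = np.zeros(a.shape[1 - axis])
    ok = count > 0
    if ok.any():
        sub = np.compress(ok, a, axis=1 - axis)
        med = np.nanmedian(sub, axis=axis)
        out[ok] = med
    return out


def median_polish(
    values: np.ndarray, max_iter: int = 50, tol: float = 1e-10
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Additive median polish of a grid with missing values.

    Iterates row-median and column-median sweeps until the largest sweep
    update falls below ``tol`` or ``max_iter`` iterations.  Returns
    ``(row_effects, col_effects, residuals)`` with effects centred to mean
    0 over the rows/columns that carry data; the grand level remains in
    the residuals.  Missing entries stay missing.
    """
    r = np.array(values, dtype=float)
    n_rows, n_cols = r.shape
    row_eff = np.zeros(n_rows)
    col_eff = np.zeros(n_cols)
    for _ in range(max_iter):
        rm = _nanmedian_rows(r, axis=1)
        row_eff += rm
        r -= rm[:, None]
        cm = _nanmedian_rows(r, axis=0)
        col_eff += cm
        r -= cm[None, :]
        if max(np.abs(rm).max(initial=0.0), np.abs(cm).max(initial=0.0)) < tol:
            break
    # gauge: centre effects over rows/cols with data; the removed means are
    # grand level and belong to the plate, so fold them back into residuals
    has_row = np.isfinite(values).any(axis=1)
    has_col = np.isfinite(values).any(axis=0)
    row_shift = row_eff[has_row].mean() if has_row.any() else 0.0
    col_shift = col_eff[has_col].mean() if has_col.any() else 0.0
    row_eff[has_row] -= row_shift
    row_eff[~has_row] = 0.0
    col_eff[has_col] -= col_shift
    col_eff[~has_col] = 0.0
    residuals = values - row_eff[:, None] - col_eff[None, :]
    return row_eff, col_eff, residuals


def _moving_median_surface(residuals: np.ndarray, window: int) -> np.ndarray:
    """Moving-median smooth of log residuals; 1 (in linear space) off-grid."""
    n_rows, n_cols = residuals.shape
    half = window // 2
    out = np.zeros_like(residuals)
    for i in range(n_rows):
        for j in range(n_cols):
            patch = residuals[
                max(0, i - half) : i + half + 1, max(0, j - half) : j + half + 1
            ]
            if np.isfinite(patch).any():
                out[i, j] = np.nanmedian(patch)
    return out


def correct_spatial(
    plate: ColonyPlate,
    layout: PlateLayout,
    config: ScreenConfig | None = None,
    *,
    max_iter: int = 50,
    tol: float = 1e-10,
    fit_residual_surface: bool = False,
    residual_window: int = 7,
    min_present_fraction: float = 0.5,
) -> tuple[ColonyPlate, CorrectionSurface]:
    """Fit and divide out the multiplicative spatial surface of one plate.

    The surface is fitted by median polish on log-transformed sizes over
    the experimental grid only; zero sizes take no part in the fit but are
    preserved (0 divided by a positive surface is 0).  Optionally a second
    pass smooths the polish residuals with a moving median to capture
    non-separable gradients (off by default).

    Raises :class:`ComputationError` when fewer than
    ``min_present_fraction`` of experimental positions are present — such
    plates should be skipped.
    """
    config = config or ScreenConfig()
    masked = mask_non_experimental(plate, layout)
    roles = layout.role_grid(plate.plate_id)
    n_exp = int((roles == Role.EXPERIMENT.value).sum())
    if n_exp == 0:
        raise ComputationError(
            f"plate {plate.plate_id!r}: layout defines no experimental positions"
        )
    present = masked.present_mask
    if present.sum() < min_present_fraction * n_exp:
        raise ComputationError(
            f"plate {plate.plate_id!r}: only {int(present.sum())}/{n_exp} "
            "experimental positions present; skip this plate"
        )
    with np.errstate(divide="ignore"):
        logs = np.log(masked.sizes)
    logs[~np.isfinite(logs)] = np.nan  # zeros and missing excluded from the fit
    row_log, col_log, resid = median_polish(logs, max_iter=max_iter, tol=tol)
    residual_surface = None
    if fit_residual_surface:
        residual_surface = np.exp(_moving_median_surface(resid, residual_window))
    surface = CorrectionSurface(
        plate.plate_id, np.exp(row_log), np.exp(col_log), residual_surface
    )
    corrected = masked.sizes / surface.grid()
    return masked.advanced(corrected, PlateStage.CORRECTED), surface


def normalize_to_plate_median(plate: ColonyPlate) -> ColonyPlate:
    """Divide every present value by the plate median of present values.

    The resulting plate has median 1 (midpoint convention for even
    counts).  The plate must be at the corrected stage and carry at least
    one present value.
    """
    present = plate.sizes[plate.present_mask]
    if present.size == 0:
        raise ComputationError(f"plate {plate.plate_id!r}: no present values")
    med = float(np.median(present))
    if med <= 0:
        raise ComputationError(
            f"plate {plate.plate_id!r}: non-positive plate median {med}"
        )
    return plate.advanced(plate.sizes / med, PlateStage.NORMALIZED)


def prepare_plates(
    plates, layout: PlateLayout, config: ScreenConfig | None = None, **correct_kwargs
) -> tuple[list[ColonyPlate], list[CorrectionSurface]]:
    """Mask, spatially correct and median-normalize every plate.

    Convenience wrapper running the full per-plate stage; returns the
    normalized plates plus the fitted surfaces for diagnostics.
    """
    normalized, surfaces = [], []
    for p in plates:
        corrected, surface = correct_spatial(p, layout, config, **correct_kwargs)
        normalized.append(normalize_to_plate_median(corrected))
        surfaces.append(surface)
    return normalized, surfaces


def write_surface_table(surface: CorrectionSurface, path: str | Path) -> None:
    """Export a fitted surface as TSV (plate, row, col, effect) diagnostics."""
    grid = surface.grid()
    rows, cols = np.meshgrid(
        np.arange(1, grid.shape[0] + 1), np.arange(1, grid.shape[1] + 1), indexing="ij"
    )
    pd.DataFrame(
        {
            "plate": surface.plate_id,
            "row": rows.ravel(),
            "col": cols.ravel(),
            "effect": grid.ravel(),
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.12g")
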