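"""Plate-grid data model and the tab-separated dialects around it.

The screening pipeline consumes colony-size tables in the dialect emitted
by colony-grid quantification tools (one row per position: plate, row,
col, size) together with a layout table mapping each position to a cross
(query allele x array gene), a technical-replicate index and a role.

Conventions
-----------
* Coordinates are 1-based: row 1..n_rows (default 32), col 1..n_cols
  (default 48), matching colony-quantification output.
* Missing measurements are serialized as ``NA``.  A colony size of 0 is a
  legal measurement (a dead or unpinned cross) and is distinct from
  missing.
* Plates default to the 1536-position format (32 x 48); any rectangular
  format is accepted when declared.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "PlateStage",
    "Role",
    "ColonyPlate",
    "PlateLayout",
    "ScreenConfig",
    "read_plate_table",
    "write_plate_table",
    "read_layout",
    "write_layout",
    "read_results_table",
    "write_results_table",
]

#: significant digits used when rendering numeric fields to TSV
_FLOAT_FMT = "%.12g"

LAYOUT_COLUMNS = ["plate", "row", "col", "query", "gene", "replicate", "role"]
RESULT_COLUMNS = [
    "query",
    "gene",
    "n_replicates_used",
    "mean_fitness",
    "wt_mean_fitness",
    "fitness_ratio",
    "t_stat",
    "p_raw",
    "p_adj",
    "hit",
]


class PlateStage(enum.Enum):
    """Processing stage of a plate; transitions only move forward."""

    RAW = "raw"
    CORRECTED = "corrected"
    NORMALIZED = "normalized"


_STAGE_ORDER = {PlateStage.RAW: 0, PlateStage.CORRECTED: 1, PlateStage.NORMALIZED: 2}


class Role(str, enum.Enum):
    """What a plate position carries."""

    EXPERIMENT = "experiment"
    BORDER_DUMMY = "border_dummy"
    EMPTY = "empty"


@dataclass
class ColonyPlate:
    """One plate's grid of colony sizes.

    ``sizes`` is a float array of shape ``(n_rows, n_cols)``; ``NaN``
    encodes a missing measurement.  Present values must be >= 0.
    """

    plate_id: str
    sizes: np.ndarray
    stage: PlateStage = PlateStage.RAW

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes, dtype=float)
        if self.sizes.ndim != 2:
            raise ValidationError(
                f"plate {self.plate_id!r}: sizes must be 2-D, got {self.sizes.ndim}-D"
            )
        present = self.sizes[np.isfinite(self.sizes)]
        if present.size and (present < 0).any():
            raise ValidationError(f"plate {self.plate_id!r}: negative colony size")

    @property
    def n_rows(self) -> int:
        return self.sizes.shape[0]

    @property
    def n_cols(self) -> int:
        return self.sizes.shape[1]

    @property
    def present_mask(self) -> np.ndarray:
        return np.isfinite(self.sizes)

    @property
    def n_present(self) -> int:
        return int(self.present_mask.sum())

    def advanced(self, sizes: np.ndarray, stage: PlateStage) -> "ColonyPlate":
        """Return a new plate at ``stage``, enforcing forward-only transitions."""
        if _STAGE_ORDER[stage] <= _STAGE_ORDER[self.stage]:
            raise ValidationError(
                f"plate {self.plate_id!r}: illegal stage transition "
                f"{self.stage.value} -> {stage.value}"
            )
        return ColonyPlate(self.plate_id, np.asarray(sizes, float), stage)

    def copy(self) -> "ColonyPlate":
        return ColonyPlate(self.plate_id, self.sizes.copy(), self.stage)


@dataclass
class PlateLayout:
    """Position -> cross mapping for one or more plates.

    Backed by a DataFrame with columns ``plate, row, col, query, gene,
    replicate, role``.  Non-experimental positions carry missing query and
    gene.  The default geometry is the screening format: four technical
    replicates per cross in a 2x2 block, queries of one gene adjacent, and
    a 4-deep border of dummy strains on every plate edge.
    """

    table: pd.DataFrame
    n_rows: int = 32
    n_cols: int = 48
    replicates: int = 4
    border_width: int = 4

    def __post_init__(self) -> None:
        missing = [c for c in LAYOUT_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValidationError(f"layout missing columns: {missing}")
        self.table = self.table.reset_index(drop=True)

    @property
    def plate_ids(self) -> list[str]:
        return sorted(self.table["plate"].unique())

    def for_plate(self, plate_id: str) -> pd.DataFrame:
        return self.table[self.table["plate"] == plate_id]

    def role_grid(self, plate_id: str) -> np.ndarray:
        """Dense grid of role strings for one plate; absent positions 'empty'."""
        grid = np.full((self.n_rows, self.n_cols), Role.EMPTY.value, dtype=object)
        sub = self.for_plate(plate_id)
        grid[sub["row"].to_numpy() - 1, sub["col"].to_numpy() - 1] = sub[
            "role"
        ].to_numpy()
        return grid

    def validate(self) -> None:
        """Check the geometric invariants; raise listing every violation."""
        problems: list[str] = []
        t = self.table
        bad_coord = t[
            (t["row"] < 1)
            | (t["row"] > self.n_rows)
            | (t["col"] < 1)
            | (t["col"] > self.n_cols)
        ]
        for _, r in bad_coord.iterrows():
            problems.append(
                f"plate {r['plate']} position ({r['row']},{r['col']}) out of range"
            )
        dup = t.duplicated(subset=["plate", "row", "col"], keep=False)
        if dup.any():
            first = t[dup].iloc[0]
            problems.append(
                f"duplicate position plate {first['plate']} "
                f"({first['row']},{first['col']})"
            )
        b = self.border_width
        on_border = (
            (t["row"] <= b)
            | (t["row"] > self.n_rows - b)
            | (t["col"] <= b)
            | (t["col"] > self.n_cols - b)
        )
        bad_border = t[on_border & (t["role"] != Role.BORDER_DUMMY.value)]
        for _, r in bad_border.iterrows():
            problems.append(
                f"plate {r['plate']} border position ({r['row']},{r['col']}) "
                f"has role {r['role']!r}, expected border_dummy"
            )
        exp = t[t["role"] == Role.EXPERIMENT.value]
        no_ids = exp[exp["query"].isna() | exp["gene"].isna()]
        for _, r in no_ids.iterrows():
            problems.append(
                f"plate {r['plate']} experiment position ({r['row']},{r['col']}) "
                "lacks query or gene"
            )
        for (plate, query, gene), grp in exp.groupby(["plate", "query", "gene"]):
            if len(grp) != self.replicates:
                problems.append(
                    f"plate {plate} cross ({query},{gene}) has {len(grp)} replicates,"
                    f" expected {self.replicates}"
                )
                continue
            h = grp["row"].max() - grp["row"].min() + 1
            w = grp["col"].max() - grp["col"].min() + 1
            if h * w != self.replicates:
                problems.append(
                    f"plate {plate} cross ({query},{gene}) replicates are not a"
                    f" contiguous rectangular block ({h}x{w} bounding box)"
                )
        if problems:
            raise ValidationError("layout validation failed:\n  " + "\n  ".join(problems))


@dataclass
class ScreenConfig:
    """Thresholds of the interaction-scoring stage.

    fitness_ratio_threshold
        Call a synthetic-sick hit only below this query/wild-type fitness
        ratio (strict), default 0.8.
    alpha
        Significance level on the multiplicity-adjusted p-value (strict),
        default 0.05.
    variance_exclusion_threshold
        A replicate is dropped when its leave-one-out share of the sum of
        squared deviations exceeds this fraction, default 0.9.
    min_replicates_for_test
        Minimum surviving replicates per side for a t-test, default 3.
    border_width
        Depth of the dummy border masked on every plate edge, default 4.
    """

    fitness_ratio_threshold: float = 0.8
    alpha: float = 0.05
    variance_exclusion_threshold: float = 0.9
    min_replicates_for_test: int = 3
    border_width: int = 4
    use_adjusted_p: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.fitness_ratio_threshold <= 1):
            raise ValidationError("fitness_ratio_threshold must be in (0, 1]")
        if not (0 < self.alpha < 1):
            raise ValidationError("alpha must be in (0, 1)")
        if not (0 < self.variance_exclusion_threshold < 1):
            raise ValidationError("variance_exclusion_threshold must be in (0, 1)")
        if self.min_replicates_for_test < 2:
            raise ValidationError("min_replicates_for_test must be >= 2")
        if self.border_width < 0:
            raise ValidationError("border_width must be >= 0")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_plate_table(
    path: str | Path, n_rows: int = 32, n_cols: int = 48
) -> list[ColonyPlate]:
    """Read a colony-size TSV into one raw ColonyPlate per plate id.

    The file must have header columns ``plate, row, col, size``.  Positions
    absent from the file, and positions whose size field is non-numeric,
    become missing.  Duplicate positions and out-of-range coordinates are
    errors naming the offending position.
    """
    df = pd.read_csv(path, sep="\t", dtype={"plate": str})
    required = ["plate", "row", "col", "size"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    df["size"] = pd.to_numeric(df["size"], errors="coerce")
    bad = df[
        (df["row"] < 1) | (df["row"] > n_rows) | (df["col"] < 1) | (df["col"] > n_cols)
    ]
    if len(bad):
        r = bad.iloc[0]
        raise ValidationError(
            f"{path}: position ({int(r['row'])},{int(r['col'])}) on plate "
            f"{r['plate']} outside declared {n_rows}x{n_cols} format"
        )
    dup = df.duplicated(subset=["plate", "row", "col"], keep=False)
    if dup.any():
        r = df[dup].iloc[0]
        raise ValidationError(
            f"{path}: duplicate entry for plate {r['plate']} position "
            f"({int(r['row'])},{int(r['col'])})"
        )
    plates = []
    for plate_id, sub in df.groupby("plate", sort=True):
        sizes = np.full((n_rows, n_cols), np.nan)
        sizes[sub["row"].to_numpy() - 1, sub["col"].to_numpy() - 1] = sub[
            "size"
        ].to_numpy()
        plates.append(ColonyPlate(str(plate_id), sizes, PlateStage.RAW))
    return plates


def write_plate_table(plates: Iterable[ColonyPlate], path: str | Path) -> None:
    """Write plates to the ``plate, row, col, size`` TSV dialect.

    All positions are written, missing sizes as ``NA``, so a read-back
    reproduces the plates exactly.
    """
    frames = []
    for p in plates:
        rows, cols = np.meshgrid(
            np.arange(1, p.n_rows + 1), np.arange(1, p.n_cols + 1), indexing="ij"
        )
        frames.append(
            pd.DataFrame(
                {
                    "plate": p.plate_id,
                    "row": rows.ravel(),
                    "col": cols.ravel(),
                    "size": p.sizes.ravel(),
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out.to_csv(path, sep="\t", index=False, na_rep="NA", float_format=_FLOAT_FMT)


def read_layout(
    path: str | Path,
    n_rows: int = 32,
    n_cols: int = 48,
    replicates: int = 4,
    border_width: int = 4,
    validate: bool = True,
) -> PlateLayout:
    """Read and (by default) validate a layout TSV.

    Columns: ``plate, row, col, query, gene, replicate, role``.  Query and
    gene are missing (``NA``) on non-experimental positions.
    """
    df = pd.read_csv(path, sep="\t", dtype={"plate": str, "query": str, "gene": str})
    layout = PlateLayout(
        df,
        n_rows=n_rows,
        n_cols=n_cols,
        replicates=replicates,
        border_width=border_width,
    )
    if validate:
        layout.validate()
    return layout


def write_layout(layout: PlateLayout, path: str | Path) -> None:
    layout.table[LAYOUT_COLUMNS].to_csv(path, sep="\t", index=False, na_rep="NA")


def write_results_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a scored interaction table as TSV.

    One row per (query, gene); numeric fields rendered with 12 significant
    digits; missing values (including p-values and hit flags of untestable
    crosses) rendered as ``NA``.
    """
    missing = [c for c in RESULT_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"results table missing columns {missing}")
    out = table[RESULT_COLUMNS].copy()
    out["hit"] = out["hit"].replace({"untestable": np.nan})
    out.to_csv(path, sep="\t", index=False, na_rep="NA", float_format=_FLOAT_FMT)


def read_results_table(path: str | Path) -> pd.DataFrame:
    """Read back a results TSV written by :func:`write_results_table`."""
    df = pd.read_csv(path, sep="\t", dtype={"query": str, "gene": str, "hit": str})
    df.loc[df["p_adj"].isna() & df["hit"].isna(), "hit"] = "untestable"
    return df
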