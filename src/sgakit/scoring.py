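"""Double-mutant fitness and synthetic-sick interaction calling.

The screen scores each cross (query allele x array-gene deletion) under a
multiplicative null: absent genetic interaction, double-mutant colony
size is the product of the single-mutant effects, so after per-plate
normalization and division by the per-query median the expected fitness
of every cross is 1.  A synthetic-sick interaction shows up as a
query/wild-type fitness ratio below the threshold, supported by a Welch
t-test across technical replicates with Benjamini-Hochberg adjustment
across the gene family of each query.

Replicate exclusion
-------------------
A single aberrant replicate (pinning failure, contaminant) can dominate a
4-replicate cross.  A replicate is excluded when its leave-one-out share
of the total sum of squared deviations, ``1 - SS_without_i / SS``,
exceeds the configured threshold (default 0.9).  The leave-one-out form
makes the threshold operative at n = 4: the naive share
``(x_i - mean)^2 / SS`` cannot exceed 0.75 when the other three
replicates tie.  At most one replicate is excluded per cross, in a
single pass.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ComputationError, ValidationError
from .plates import ColonyPlate, PlateLayout, PlateStage, Role, ScreenConfig

__all__ = [
    "compute_fitness",
    "exclude_dominant_replicates",
    "test_interaction",
    "adjust_bh",
    "summarize_replicates",
    "call_hits",
    "score_screen",
]


def compute_fitness(
    plates: Sequence[ColonyPlate], layout: PlateLayout
) -> pd.DataFrame:
    """Per-replicate double-mutant fitness from normalized plates.

    Each normalized colony size is divided by the median of normalized
    sizes of its query across all genes and plates, giving fitness 1 for
    a typical cross of that query.  Returns a long table with columns
    ``plate, query, gene, replicate, fitness`` (missing sizes give
    missing fitness).
    """
    records = []
    by_id = {}
    for p in plates:
        if p.stage is not PlateStage.NORMALIZED:
            raise ValidationError(
                f"plate {p.plate_id!r} is at stage {p.stage.value}, expected normalized"
            )
        by_id[p.plate_id] = p
    for plate_id, sub in layout.table.groupby("plate"):
        if plate_id not in by_id:
            raise ValidationError(f"layout references unknown plate {plate_id!r}")
        p = by_id[plate_id]
        exp = sub[sub["role"] == Role.EXPERIMENT.value]
        sizes = p.sizes[exp["row"].to_numpy() - 1, exp["col"].to_numpy() - 1]
        records.append(
            pd.DataFrame(
                {
                    "plate": plate_id,
                    "query": exp["query"].to_numpy(),
                    "gene": exp["gene"].to_numpy(),
                    "replicate": exp["replicate"].to_numpy(),
                    "fitness": sizes,
                }
            )
        )
    table = pd.concat(records, ignore_index=True)
    for query, grp in table.groupby("query"):
        vals = grp["fitness"].dropna()
        if vals.empty:
            raise ComputationError(f"query {query!r} has no present measurements")
        table.loc[grp.index, "fitness"] = grp["fitness"] / float(vals.median())
    return table


def exclude_dominant_replicates(
    values: Sequence[float], threshold: float = 0.9
) -> tuple[list[int], list[int]]:
    """Indices kept/excluded under the leave-one-out variance-share rule.

    A replicate is excluded iff ``1 - SS_without_i / SS`` exceeds
    ``threshold``, where SS is the sum of squared deviations from the
    mean.  Applied in a single pass; if several replicates exceed the
    threshold only the largest share is excluded; zero total variance
    excludes nothing.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ComputationError("need at least 2 values for replicate exclusion")
    if not np.isfinite(x).all():
        raise ValidationError("replicate exclusion requires finite values")
    ss = float(np.sum((x - x.mean()) ** 2))
    idx = list(range(x.size))
    if ss == 0.0:
        return idx, []
    shares = np.empty(x.size)
    for i in idx:
        rest = np.delete(x, i)
        shares[i] = 1.0 - float(np.sum((rest - rest.mean()) ** 2)) / ss
    worst = int(np.argmax(shares))
    if shares[worst] > threshold:
        return [i for i in idx if i != worst], [worst]
    return idx, []


def test_interaction(
    query_fitness: Sequence[float],
    wt_fitness: Sequence[float],
    config: ScreenConfig | None = None,
) -> tuple[float, float, int]:
    """Welch t-test of query vs wild-type fitness replicates.

    Replicate exclusion is applied to each side independently first.
    Returns ``(t_stat, p_raw, n_used)`` with ``n_used`` the surviving
    query-side replicates; an untestable comparison (either side below
    ``min_replicates_for_test``) returns NaN statistics.  When both sides
    have zero within-group variance, p is 1 for equal means and 0
    otherwise.
    """
    config = config or ScreenConfig()
    q = np.asarray(query_fitness, float)
    w = np.asarray(wt_fitness, float)
    q = q[np.isfinite(q)]
    w = w[np.isfinite(w)]
    if q.size == 0 or w.size == 0:
        raise ComputationError("empty fitness vector")
    if q.size >= 2:
        kept, _ = exclude_dominant_replicates(q, config.variance_exclusion_threshold)
        q = q[kept]
    if w.size >= 2:
        kept, _ = exclude_dominant_replicates(w, config.variance_exclusion_threshold)
        w = w[kept]
    n_used = int(q.size)
    if min(q.size, w.size) < config.min_replicates_for_test:
        return float("nan"), float("nan"), n_used
    if q.var(ddof=1) == 0.0 and w.var(ddof=1) == 0.0:
        if q.mean() == w.mean():
            return 0.0, 1.0, n_used
        return float(np.sign(q.mean() - w.mean()) * np.inf), 0.0, n_used
    t, p = stats.ttest_ind(q, w, equal_var=False)
    return float(t), float(p), n_used


def adjust_bh(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; missing entries pass through.

    The family size m counts non-missing entries only.
    """
    p = np.asarray(p_values, dtype=float)
    finite = np.isfinite(p)
    if ((p[finite] < 0) | (p[finite] > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    if finite.any():
        out[finite] = multipletests(p[finite], method="fdr_bh")[1]
    return out


def summarize_replicates(
    fitness: Sequence[float], config: ScreenConfig | None = None
) -> float:
    """Arithmetic mean of replicates surviving the exclusion rule.

    Missing values are dropped first; an all-missing cross yields NaN.
    """
    config = config or ScreenConfig()
    x = np.asarray(fitness, float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        return float("nan")
    if x.size >= 2:
        kept, _ = exclude_dominant_replicates(x, config.variance_exclusion_threshold)
        x = x[kept]
    return float(x.mean())


def call_hits(table: pd.DataFrame, config: ScreenConfig | None = None) -> pd.DataFrame:
    """Flag synthetic-sick hits on a scored table.

    hit = "yes" iff fitness_ratio < threshold (strict) and the relevant
    p-value (adjusted by default) < alpha (strict); untestable rows keep
    hit = "untestable".
    """
    config = config or ScreenConfig()
    out = table.copy()
    p_col = "p_adj" if config.use_adjusted_p else "p_raw"
    testable = out[p_col].notna()
    is_hit = (
        testable
        & (out["fitness_ratio"] < config.fitness_ratio_threshold)
        & (out[p_col] < config.alpha)
    )
    out["hit"] = np.where(testable, np.where(is_hit, "yes", "no"), "untestable")
    return out


def score_screen(
    plates: Sequence[ColonyPlate],
    layout: PlateLayout,
    config: ScreenConfig | None = None,
    wt_query: str = "wt",
) -> pd.DataFrame:
    """Score a full screen from normalized plates to hit calls.

    For every non-control query and every gene: replicate fitness values
    on both sides pass the exclusion rule, the query/wild-type ratio of
    replicate means is formed, a two-sided Welch t-test compares the
    sides, and p-values are BH-adjusted per query across all its genes.
    """
    config = config or ScreenConfig()
    fitness = compute_fitness(plates, layout)
    queries = [q for q in fitness["query"].unique() if q != wt_query]
    if wt_query not in set(fitness["query"]):
        raise ValidationError(f"control query {wt_query!r} absent from layout")
    wt_by_gene = {
        g: grp["fitness"].to_numpy()
        for g, grp in fitness[fitness["query"] == wt_query].groupby("gene")
    }
    rows = []
    for query in queries:
        sub = fitness[fitness["query"] == query]
        for gene, grp in sub.groupby("gene"):
            qv = grp["fitness"].to_numpy()
            wv = wt_by_gene.get(gene, np.array([]))
            qv = qv[np.isfinite(qv)]
            wv = wv[np.isfinite(wv)]
            if qv.size == 0 or wv.size == 0:
                rows.append((query, gene, 0, np.nan, np.nan, np.nan, np.nan, np.nan))
                continue
            t, p, n_used = test_interaction(qv, wv, config)
            mean_q = summarize_replicates(qv, config)
            mean_w = summarize_replicates(wv, config)
            ratio = mean_q / mean_w if mean_w else np.nan
            rows.append((query, gene, n_used, mean_q, mean_w, ratio, t, p))
    table = pd.DataFrame(
        rows,
        columns=[
            "query",
            "gene",
            "n_replicates_used",
            "mean_fitness",
            "wt_mean_fitness",
            "fitness_ratio",
            "t_stat",
            "p_raw",
        ],
    )
    table["p_adj"] = np.nan
    for query in queries:
        mask = table["query"] == query
        table.loc[mask, "p_adj"] = adjust_bh(table.loc[mask, "p_raw"].to_numpy())
    return call_hits(table, config)
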