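"""Post-scoring set operations on hit lists.

Covers the three standard follow-ups to a multi-query screen: exclusive
Venn-region counts across queries, exclusion of hits that are genetically
linked to the query locus (linked genes co-segregate with the query
marker during meiosis and produce spurious sickness), and hypergeometric
gene-set enrichment of a hit list against user-supplied flattened sets.
"""

from __future__ import annotations

from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import hypergeom

from .errors import ComputationError, ValidationError

__all__ = [
    "hit_sets_from_results",
    "intersect_hits",
    "linkage_filter",
    "hypergeometric_enrichment",
    "read_gene_coordinates",
    "read_gene_sets",
]


def hit_sets_from_results(results: pd.DataFrame) -> dict[str, set[str]]:
    """Extract query -> {genes with hit == "yes"} from a scored table."""
    hits = results[results["hit"] == "yes"]
    sets: dict[str, set[str]] = {q: set() for q in results["query"].unique()}
    for q, grp in hits.groupby("query"):
        sets[q] = set(grp["gene"])
    return sets


def intersect_hits(hit_sets: Mapping[str, Iterable[str]]) -> pd.DataFrame:
    """Exclusive Venn-region counts for k >= 2 hit sets.

    Returns one row per non-empty membership pattern (all 2^k - 1
    regions), columns ``region`` (query names joined by "&"), ``queries``
    (the membership tuple) and ``count``.  Counts are exclusive and sum to
    the cardinality of the union.
    """
    names = list(hit_sets)
    if len(names) < 2:
        raise ValidationError("need at least 2 hit sets for a Venn intersection")
    sets = {n: set(hit_sets[n]) for n in names}
    rows = []
    for k in range(1, len(names) + 1):
        for members in combinations(names, k):
            inside = set.intersection(*(sets[n] for n in members))
            outside = set.union(
                *(sets[n] for n in names if n not in members), set()
            )
            rows.append(
                {
                    "region": "&".join(members),
                    "queries": members,
                    "count": len(inside - outside),
                }
            )
    return pd.DataFrame(rows)


def linkage_filter(
    hits: Iterable[str],
    locus: tuple[str, int],
    annotation: pd.DataFrame,
    window: int = 75_000,
) -> tuple[set[str], set[str]]:
    """Split hits into (kept, excluded) by genetic linkage to a locus.

    A gene is excluded iff it lies on the locus chromosome and the
    distance from the locus position to its nearest gene boundary is
    strictly less than ``window`` base pairs (a gene spanning the locus
    has distance 0).  ``annotation`` needs columns ``gene, chrom, start,
    end``; every hit must be annotated.
    """
    hits = set(hits)
    ann = annotation.set_index("gene")
    unknown = hits - set(ann.index)
    if unknown:
        raise ValidationError(f"unannotated hit genes: {sorted(unknown)}")
    chrom, pos = locus
    kept, excluded = set(), set()
    for gene in hits:
        rec = ann.loc[gene]
        if rec["chrom"] != chrom:
            kept.add(gene)
            continue
        start, end = int(rec["start"]), int(rec["end"])
        if start <= pos <= end:
            dist = 0
        else:
            dist = min(abs(start - pos), abs(end - pos))
        (excluded if dist < window else kept).add(gene)
    return kept, excluded


def hypergeometric_enrichment(
    hits: Iterable[str],
    universe: Iterable[str],
    gene_sets: Mapping[str, Iterable[str]],
    descriptions: Mapping[str, str] | None = None,
    top_n: int | None = 10,
) -> pd.DataFrame:
    """Over-representation of each gene set in a hit list.

    For a set with K members in the universe of size N, and a hit list of
    size n overlapping it in k genes, p = P(X >= k) for X hypergeometric.
    Gene sets are intersected with the universe before testing.  Returns
    a table sorted ascending by p, trimmed to ``top_n`` (None for all),
    with a BH-adjusted column for convenience (the primary ranking is the
    raw p, as is conventional for enrichment reporting).
    """
    hits = set(hits)
    universe = set(universe)
    if not universe or not hits:
        raise ComputationError("empty universe or hit list")
    if not hits <= universe:
        raise ValidationError(
            f"hits outside the universe: {sorted(hits - universe)[:5]}"
        )
    N, n = len(universe), len(hits)
    rows = []
    for term, members in gene_sets.items():
        members = set(members) & universe
        if not members:
            continue
        K = len(members)
        k = len(members & hits)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "term": term,
                "description": (descriptions or {}).get(term, ""),
                "overlap": k,
                "term_size": K,
                "p": min(p, 1.0),
            }
        )
    table = pd.DataFrame(
        rows, columns=["term", "description", "overlap", "term_size", "p"]
    )
    table = table.sort_values(["p", "term"], kind="mergesort").reset_index(drop=True)
    if len(table):
        from .scoring import adjust_bh

        table["p_adj"] = adjust_bh(table["p"].to_numpy())
    else:
        table["p_adj"] = []
    if top_n is not None:
        table = table.head(top_n)
    return table


def read_gene_coordinates(path: str | Path) -> pd.DataFrame:
    """Read a gene-coordinate TSV (gene, chrom, start, end)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "chrom": str})
    missing = [c for c in ("gene", "chrom", "start", "end") if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    if ((df["start"] > df["end"]) | (df["start"] < 1)).any():
        raise ValidationError(f"{path}: invalid coordinates (need 1 <= start <= end)")
    return df


def read_gene_sets(
    path: str | Path, descriptions_path: str | Path | None = None
) -> tuple[dict[str, set[str]], dict[str, str]]:
    """Read a two-column (term, gene) TSV, plus optional term descriptions."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"term", "gene"} <= set(df.columns):
        raise ValidationError(f"{path}: need columns term, gene")
    sets = {t: set(g["gene"]) for t, g in df.groupby("term")}
    desc: dict[str, str] = {}
    if descriptions_path is not None:
        dd = pd.read_csv(descriptions_path, sep="\t", dtype=str)
        if not {"term", "description"} <= set(dd.columns):
            raise ValidationError(
                f"{descriptions_path}: need columns term, description"
            )
        desc = dict(zip(dd["term"], dd["description"]))
    return sets, desc
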