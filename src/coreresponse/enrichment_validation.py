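"""Enrichment of the core gene set in external lists, and cohort grouping.

Validation machinery: the core gene set is tested for over-representation in
external gene lists (transgenic validation models, disease DE signatures)
with the one-tailed exact Fisher test against a declared, restricted gene
universe (here: genes carrying at least one ontology term). Expression
cohorts are stratified by a driver gene ("CDX2-like"): counts are RPKM
normalised, samples ranked by driver expression, and the upper / lower
quantile groups of equal size ceil(N x fraction) are formed (quartiles or
deciles), their separation confirmed with a two-sided rank-sum test. A
generic term-enrichment test (one Fisher test per term, BH adjusted) covers
ontology-style analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .deg_core import CoreGeneSet, DETable, direction_map

__all__ = [
    "GeneUniverse", "EnrichmentResult", "CohortGroups",
    "fisher_core_enrichment", "term_enrichment", "rpkm",
    "quantile_groups", "disease_overlap_report",
]


@dataclass
class GeneUniverse:
    """The background gene set every enrichment test is restricted to."""

    gene_ids: set[str]
    provenance: str = ""

    def __post_init__(self) -> None:
        self.gene_ids = set(self.gene_ids)
        if not self.gene_ids:
            raise ValueError("gene universe must be non-empty")

    @classmethod
    def from_term_map(cls, term_map: pd.DataFrame) -> "GeneUniverse":
        """Genes confidently associated with >= 1 ontology term."""
        return cls(set(term_map["gene_id"]), provenance="term_map>=1")

    def __len__(self) -> int:
        return len(self.gene_ids)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.gene_ids


@dataclass
class EnrichmentResult:
    """One 2x2 over-representation test against the universe.

    k = overlap, m = tested list size in universe, n = core size in
    universe, N = universe size; p is the one-tailed (greater) Fisher exact
    p, the upper hypergeometric tail from k.
    """

    list_id: str
    k: int
    m: int
    n: int
    N: int
    odds_ratio: float
    p: float
    p_adj: float = float("nan")
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.m, self.n) and
                max(self.m, self.n) <= self.N):
            raise ValueError(
                f"inconsistent contingency k={self.k} m={self.m} "
                f"n={self.n} N={self.N}")


@dataclass
class CohortGroups:
    """Upper and lower driver-expression quantile groups of a cohort."""

    driver_gene: str
    high_samples: list[str]
    low_samples: list[str]
    group_size_rule: float
    wilcoxon_p: float

    def __post_init__(self) -> None:
        if set(self.high_samples) & set(self.low_samples):
            raise ValueError("cohort groups overlap")
        if len(self.high_samples) != len(self.low_samples):
            raise ValueError("cohort groups differ in size")


def _fisher_greater(k: int, m: int, n: int, N: int) -> float:
    """One-tailed (over-representation) exact p for the 2x2 table
    [[k, n-k], [m-k, N-n-m+k]]: the hypergeometric tail P(X >= k)."""
    table = [[k, n - k], [m - k, N - n - m + k]]
    return float(stats.fisher_exact(table, alternative="greater")[1])


def _haldane_or(a: float, b: float, c: float, d: float) -> float:
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def fisher_core_enrichment(core: CoreGeneSet | set[str], gene_list: set[str],
                           universe: GeneUniverse,
                           list_id: str = "list") -> EnrichmentResult:
    """One-tailed Fisher over-representation of the core in a gene list.

    Core and list are intersected with the universe before testing. The
    result is flagged degenerate when the core or the list fills the whole
    universe (the tail is then certainty, p = 1).
    """
    core_ids = core.gene_ids if isinstance(core, CoreGeneSet) else set(core)
    n_set = core_ids & universe.gene_ids
    m_set = set(gene_list) & universe.gene_ids
    if len(universe) < len(gene_list):
        raise ValueError(
            f"universe ({len(universe)}) smaller than tested list "
            f"({len(gene_list)}); wrong universe?")
    k, m, n, N = len(n_set & m_set), len(m_set), len(n_set), len(universe)
    p = _fisher_greater(k, m, n, N)
    odds = _haldane_or(k, n - k, m - k, N - n - m + k)
    return EnrichmentResult(list_id=list_id, k=k, m=m, n=n, N=N,
                            odds_ratio=odds, p=p,
                            degenerate=(n == N or m == N))


def term_enrichment(gene_set: set[str], term_map: pd.DataFrame,
                    universe: GeneUniverse) -> pd.DataFrame:
    """Per-term one-tailed Fisher enrichment of *gene_set*, BH adjusted.

    *term_map* has columns gene_id, term_id and is restricted to the
    universe first. Returns one row per term: list_id (the term), k, m, n,
    N, odds_ratio, p, p_adj; empty frame for an empty gene set.
    """
    restricted = term_map[term_map["gene_id"].isin(universe.gene_ids)]
    gene_set = set(gene_set) & universe.gene_ids
    columns = ["list_id", "k", "m", "n", "N", "odds_ratio", "p", "p_adj"]
    if not gene_set:
        return pd.DataFrame(columns=columns)
    results = []
    for term, sub in restricted.groupby("term_id", sort=True):
        r = fisher_core_enrichment(gene_set, set(sub["gene_id"]), universe,
                                   list_id=str(term))
        results.append(r)
    df = pd.DataFrame([
        {"list_id": r.list_id, "k": r.k, "m": r.m, "n": r.n, "N": r.N,
         "odds_ratio": r.odds_ratio, "p": r.p} for r in results])
    df["p_adj"] = multipletests(df["p"], method="fdr_bh")[1]
    return df[columns]


def rpkm(counts: pd.DataFrame, gene_lengths_bp: pd.Series,
         library_sizes: pd.Series | None = None) -> pd.DataFrame:
    """Reads per kilobase of gene length per million mapped reads.

    ``value = count x 10^9 / (length_bp x library_size)``; library sizes
    default to column sums of the count matrix.
    """
    lengths = gene_lengths_bp.reindex(counts.index)
    if lengths.isna().any():
        raise ValueError("gene_lengths_bp missing for some genes")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    if (library_sizes == 0).any():
        bad = list(library_sizes.index[library_sizes == 0])
        raise ValueError(f"zero library size for sample(s) {bad[:5]}")
    return (counts * 1e9).div(lengths, axis=0).div(library_sizes, axis=1)


def quantile_groups(expr: pd.DataFrame, driver_gene: str,
                    fraction: float = 0.25) -> CohortGroups:
    """Split a cohort into upper and lower driver-expression quantiles.

    Group size is ceil(N x fraction) so the groups stay comparable
    (quartiles: fraction 0.25; deciles: 0.10). Samples are ranked by the
    driver's normalised expression, ties broken by sample id for
    determinism. A two-sided rank-sum test on driver expression between the
    groups is reported as confirmation of separation.
    """
    if driver_gene not in expr.index:
        raise KeyError(f"driver gene {driver_gene!r} not in matrix")
    n_samples = expr.shape[1]
    size = math.ceil(n_samples * fraction)
    if 2 * size > n_samples:
        raise ValueError(
            f"groups of {size} overlap in a cohort of {n_samples} samples")
    driver = expr.loc[driver_gene]
    order = sorted(expr.columns, key=lambda s: (driver[s], str(s)))
    low = order[:size]
    high = order[-size:]
    with np.errstate(all="ignore"):
        stat = stats.mannwhitneyu(driver[high], driver[low],
                                  alternative="two-sided")
    return CohortGroups(driver_gene=driver_gene, high_samples=high,
                        low_samples=low, group_size_rule=fraction,
                        wilcoxon_p=float(stat.pvalue))


def disease_overlap_report(core: CoreGeneSet, de_lists: Sequence[DETable],
                           universe: GeneUniverse,
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Core enrichment in each disease / validation DE list, plus the
    core-ordered direction map.

    Each table must already be filtered to its significant genes and
    oriented factor-high vs factor-low. Returns (enrichment table with BH
    adjustment across lists, gene x dataset direction matrix in the core's
    canonical order).
    """
    results = []
    for t in de_lists:
        r = fisher_core_enrichment(core, t.gene_ids, universe,
                                   list_id=t.condition)
        results.append(r)
    table = pd.DataFrame([
        {"list_id": r.list_id, "k": r.k, "m": r.m, "n": r.n, "N": r.N,
         "odds_ratio": r.odds_ratio, "p": r.p} for r in results])
    if len(table):
        table["p_adj"] = multipletests(table["p"], method="fdr_bh")[1]
    else:
        table["p_adj"] = []
    directions = direction_map(core, de_lists)
    return table, directions
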