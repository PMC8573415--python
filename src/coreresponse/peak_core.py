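"""Core chromatin regions shared across ChIP-seq peak sets, with annotation.

A core region is a maximal genomic segment simultaneously covered by a peak
in every input collection, kept when it is at least ``min_overlap_bp`` long
(default 10 bp, the n-way overlap rule). Peaks are merged within each
collection first so fragmented calls cannot split a core region; the
region's extent is the common-coverage intersection, with the contributing
peaks recorded per collection.

Each core region is then assigned exactly one genomic category against the
annotation: coding_promoter > coding_gene > noncoding_promoter >
noncoding_gene > intergenic, where a promoter is the 2-kb segment upstream
of the canonical TSS (strand-aware, clipped at chromosome bounds). Nearest
genes on both sides are recorded for intergenic regions, and intergenic
regions are optionally flagged for >= 1 bp overlap with a super-enhancer
catalogue (dbSUPER-style BED).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import GenomeAnnotation, PeakCollection

logger = logging.getLogger(__name__)

__all__ = [
    "CoreRegionSet", "CATEGORIES", "core_regions", "merge_intervals",
    "promoters", "annotate_regions", "super_enhancer_overlap",
    "link_promoter_peaks_to_core_genes",
]

CATEGORIES = ["coding_promoter", "coding_gene", "noncoding_promoter",
              "noncoding_gene", "intergenic"]


@dataclass
class CoreRegionSet:
    """The n-way intersection product.

    ``df`` columns: chrom, start, end, region_id, union_start, union_end
    (extent of the contributing peaks, the auxiliary extent), one
    ``peaks_<label>`` column per input collection (comma-joined contributing
    peak names), and after annotation: category, genes, promoter_genes,
    upstream_gene, downstream_gene, super_enhancer.
    """

    df: pd.DataFrame
    n_conditions: int
    labels: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.df)

    @property
    def annotated(self) -> bool:
        return "category" in self.df.columns

    def category_counts(self) -> pd.Series:
        """Counts per category; always sums to the number of core regions."""
        if not self.annotated:
            raise ValueError("regions not annotated yet")
        counts = self.df["category"].value_counts()
        return counts.reindex(CATEGORIES, fill_value=0)

    def super_enhancer_fraction(self) -> float:
        """Fraction of intergenic regions overlapping a super-enhancer."""
        inter = self.df[self.df["category"] == "intergenic"]
        if len(inter) == 0:
            return float("nan")
        return float(inter["super_enhancer"].mean())


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping or bookended intervals per chromosome."""
    rows = []
    for chrom, sub in df.groupby("chrom", sort=True):
        sub = sub.sort_values(["start", "end"])
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        cur_s, cur_e = int(starts[0]), int(ends[0])
        for s, e in zip(starts[1:], ends[1:]):
            if s <= cur_e:                      # overlap or bookend: fuse
                cur_e = max(cur_e, int(e))
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = int(s), int(e)
        rows.append((chrom, cur_s, cur_e))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _index_peaks(collection: PeakCollection
                 ) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Per-chromosome (starts, ends, names) sorted by start, for fast
    overlap queries."""
    out = {}
    for chrom, sub in collection.df.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        out[chrom] = (sub["start"].to_numpy(), sub["end"].to_numpy(),
                      sub["name"].to_numpy())
    return out


def core_regions(collections: Sequence[PeakCollection],
                 min_overlap_bp: int = 10) -> CoreRegionSet:
    """Intersect >= 2 peak collections into the shared core.

    Sweep-line over merged per-collection intervals: a core region is a
    maximal run of bases covered in all collections, retained when its
    length reaches ``min_overlap_bp``. The union extent of the contributing
    peaks is kept as an auxiliary pair of columns.
    """
    if len(collections) < 2:
        raise ValueError("core_regions needs at least 2 collections")
    labels = tuple(c.label for c in collections)
    if len(set(labels)) != len(labels):
        raise ValueError("collections must carry distinct labels")
    n = len(collections)
    empty_cols = [c.label for c in collections if len(c) == 0]
    if empty_cols:
        logger.warning("empty peak collection(s) %s: core is empty",
                       empty_cols)
        return CoreRegionSet(df=_empty_core_frame(labels), n_conditions=n,
                             labels=labels)
    merged = [merge_intervals(c.df) for c in collections]
    indices = [_index_peaks(c) for c in collections]
    chroms = set(merged[0]["chrom"])
    for m in merged[1:]:
        chroms &= set(m["chrom"])
    rows = []
    for chrom in sorted(chroms):
        events: list[tuple[int, int]] = []
        for m in merged:
            sub = m[m["chrom"] == chrom]
            for s, e in zip(sub["start"], sub["end"]):
                events.append((int(s), +1))
                events.append((int(e), -1))
        events.sort()
        coverage = 0
        run_start = None
        segments: list[tuple[int, int]] = []
        for pos, delta in events:
            prev = coverage
            coverage += delta
            if prev < n <= coverage:
                run_start = pos
            elif prev >= n > coverage:
                segments.append((run_start, pos))
                run_start = None
        for s, e in segments:
            if e - s >= min_overlap_bp:
                union_s, union_e = s, e
                row = {"chrom": chrom, "start": s, "end": e}
                for label, index in zip(labels, indices):
                    starts, ends, names = index[chrom]
                    hi = int(np.searchsorted(starts, e, side="left"))
                    mask = ends[:hi] > s
                    row[f"peaks_{label}"] = ",".join(names[:hi][mask])
                    if mask.any():
                        union_s = min(union_s, int(starts[:hi][mask].min()))
                        union_e = max(union_e, int(ends[:hi][mask].max()))
                row["union_start"], row["union_end"] = union_s, union_e
                rows.append(row)
    df = (pd.DataFrame(rows) if rows else _empty_core_frame(labels))
    if rows:
        df = df.sort_values(["chrom", "start"]).reset_index(drop=True)
    df["region_id"] = [f"core_{i}" for i in range(len(df))]
    return CoreRegionSet(df=df, n_conditions=n, labels=labels)


def _empty_core_frame(labels: Sequence[str]) -> pd.DataFrame:
    cols = (["chrom", "start", "end", "union_start", "union_end"]
            + [f"peaks_{l}" for l in labels] + ["region_id"])
    return pd.DataFrame(columns=cols)


def promoters(annotation: GenomeAnnotation,
              promoter_length_bp: int = 2000) -> pd.DataFrame:
    """Strand-aware promoter intervals: the segment immediately upstream of
    each gene's canonical TSS, clipped at chromosome bounds.

    + strand gene [s, e) -> promoter [s - L, s); - strand -> [e, e + L).
    Genes whose promoter is fully clipped away yield no row.
    """
    rows = []
    for g in annotation.genes:
        if g.strand == "+":
            start, end = g.start - promoter_length_bp, g.start
        else:
            start, end = g.end, g.end + promoter_length_bp
        start = max(0, start)
        limit = annotation.chrom_lengths.get(g.chrom)
        if limit is not None:
            end = min(end, limit)
        if start < end:
            rows.append((g.chrom, start, end, g.gene_id, g.biotype, g.strand))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "gene_id", "biotype",
                       "strand"])


def _overlap_ids(features: pd.DataFrame, chrom: str, start: int,
                 end: int) -> pd.DataFrame:
    sub = features[features["chrom"] == chrom]
    return sub[(sub["start"] < end) & (sub["end"] > start)]


def annotate_regions(core: CoreRegionSet, annotation: GenomeAnnotation,
                     promoter_length_bp: int = 2000) -> CoreRegionSet:
    """Assign each core region exactly one category by fixed precedence.

    Precedence: coding_promoter > coding_gene > noncoding_promoter >
    noncoding_gene > intergenic (promoters first: promoter peaks are the
    gene-linked class). All overlapping gene and promoter ids are recorded so
    alternative precedences stay recomputable; nearest genes on both sides
    are recorded for intergenic regions.
    """
    genes = annotation.to_frame()
    proms = promoters(annotation, promoter_length_bp)
    categories, gene_lists, prom_lists = [], [], []
    upstream, downstream = [], []
    for row in core.df.itertuples(index=False):
        g_hit = _overlap_ids(genes, row.chrom, row.start, row.end)
        p_hit = _overlap_ids(proms, row.chrom, row.start, row.end)
        coding_gene = g_hit[g_hit["biotype"] == "protein_coding"]
        noncoding_gene = g_hit[g_hit["biotype"] == "non_coding"]
        coding_prom = p_hit[p_hit["biotype"] == "protein_coding"]
        noncoding_prom = p_hit[p_hit["biotype"] == "non_coding"]
        if len(coding_prom):
            cat = "coding_promoter"
        elif len(coding_gene):
            cat = "coding_gene"
        elif len(noncoding_prom):
            cat = "noncoding_promoter"
        elif len(noncoding_gene):
            cat = "noncoding_gene"
        else:
            cat = "intergenic"
        categories.append(cat)
        gene_lists.append(",".join(g_hit["gene_id"]))
        prom_lists.append(",".join(p_hit["gene_id"]))
        if cat == "intergenic":
            chrom_genes = genes[genes["chrom"] == row.chrom]
            left = chrom_genes[chrom_genes["end"] <= row.start]
            right = chrom_genes[chrom_genes["start"] >= row.end]
            upstream.append(
                left.loc[left["end"].idxmax(), "gene_id"] if len(left) else "")
            downstream.append(
                right.loc[right["start"].idxmin(), "gene_id"]
                if len(right) else "")
        else:
            upstream.append("")
            downstream.append("")
    df = core.df.copy()
    df["category"] = categories
    df["genes"] = gene_lists
    df["promoter_genes"] = prom_lists
    df["upstream_gene"] = upstream
    df["downstream_gene"] = downstream
    return CoreRegionSet(df=df, n_conditions=core.n_conditions,
                         labels=core.labels)


def super_enhancer_overlap(core: CoreRegionSet,
                           se: PeakCollection) -> CoreRegionSet:
    """Flag intergenic core regions overlapping (>= 1 bp) a super-enhancer."""
    if not core.annotated:
        raise ValueError("annotate regions before the super-enhancer overlap")
    flags = []
    for row in core.df.itertuples(index=False):
        if row.category != "intergenic":
            flags.append(pd.NA)
            continue
        hit = _overlap_ids(se.df, row.chrom, row.start, row.end)
        flags.append(bool(len(hit)))
    df = core.df.copy()
    df["super_enhancer"] = pd.array(flags, dtype="boolean")
    return CoreRegionSet(df=df, n_conditions=core.n_conditions,
                         labels=core.labels)


def link_promoter_peaks_to_core_genes(core: CoreRegionSet,
                                      core_gene_ids: set[str]) -> list[str]:
    """Genes whose promoter hosts >= 1 core region and that belong to the
    DEG core (both cores built on the same annotation frame)."""
    if not core.annotated:
        raise ValueError("annotate regions before linking to the gene core")
    promoter_rows = core.df[core.df["category"].str.endswith("_promoter")]
    hosts: set[str] = set()
    for entry in promoter_rows["promoter_genes"]:
        hosts.update(g for g in entry.split(",") if g)
    return sorted(hosts & core_gene_ids)
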