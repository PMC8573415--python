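"""Cross-condition core of differentially expressed genes.

Each condition contributes a DE table (gene, log2 fold-change, adjusted p).
Replicate-based tables come from an upstream count-model test and are
filtered at |log2FC| > 2 and adjusted p < 0.05 (strict inequalities, both
configurable). Replicate-free comparisons are handled by the delta method:
the per-gene difference of log2-transformed, library-size-normalised
expression between experiment and control, thresholded at |delta| > 2, with
no p-value; two replicate-free datasets are combined by sign-consistent
consensus. The core set is the intersection of the filtered gene sets across
all conditions; membership does not require the direction of change to agree
across conditions, and the gene x condition sign matrix (orientation
normalised so every column reads factor-expressing vs non-expressing) is the
correlation-map payload. An orthology projection maps the core into a second
species, accepting pairs with high annotation confidence or sufficient
sequence homology.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DETable", "CoreGeneSet", "OrthologyMap",
    "delta_de", "delta_consensus", "filter_de", "build_core",
    "map_orthologues", "direction_map", "plot_direction_map",
]

ORIENTATIONS = {"factor_high_vs_low", "factor_low_vs_high"}


@dataclass
class DETable:
    """Per-condition differential-expression records.

    ``df`` columns: gene_id, log2fc, padj (NaN allowed only for tables from
    the replicate-free delta method). ``orientation`` declares which way the
    comparison ran so downstream signs can be normalised to the
    factor-expressing vs non-expressing convention.
    """

    condition: str
    df: pd.DataFrame
    orientation: str = "factor_high_vs_low"
    from_delta: bool = False

    def __post_init__(self) -> None:
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"bad orientation {self.orientation!r}")
        missing = {"gene_id", "log2fc", "padj"} - set(self.df.columns)
        if missing:
            raise ValueError(f"DETable missing column(s) {sorted(missing)}")
        if self.df["gene_id"].duplicated().any():
            dupes = self.df.loc[self.df["gene_id"].duplicated(), "gene_id"]
            raise ValueError(
                f"condition {self.condition!r}: duplicate gene_id(s) "
                f"{sorted(set(dupes))[:5]}")
        padj = self.df["padj"].dropna()
        if ((padj < 0) | (padj > 1)).any():
            raise ValueError(f"condition {self.condition!r}: padj outside [0,1]")
        self.df = self.df.reset_index(drop=True)

    @property
    def gene_ids(self) -> set[str]:
        return set(self.df["gene_id"])

    def oriented_sign(self) -> pd.Series:
        """Sign of log2fc, flipped for factor_low_vs_high tables."""
        sign = np.sign(self.df["log2fc"]).astype(int)
        if self.orientation == "factor_low_vs_high":
            sign = -sign
        return pd.Series(sign.to_numpy(), index=self.df["gene_id"].to_numpy())


@dataclass
class OrthologyMap:
    """Cross-species gene pairs with annotation confidence and % homology."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = ({"source_id", "target_id", "confidence", "homology_pct"}
                   - set(self.df.columns))
        if missing:
            raise ValueError(f"OrthologyMap missing column(s) {sorted(missing)}")
        h = self.df["homology_pct"]
        if ((h < 0) | (h > 100)).any():
            raise ValueError("homology_pct outside [0, 100]")


@dataclass
class CoreGeneSet:
    """The intersected core with its gene x condition direction matrix.

    ``direction_matrix``: rows = core genes in canonical order, columns =
    conditions, entries +1 / -1 (never 0 for member genes: every member
    passed the fold-change threshold in every condition).
    """

    direction_matrix: pd.DataFrame
    n_conditions: int = 0

    def __post_init__(self) -> None:
        if self.n_conditions == 0:
            self.n_conditions = self.direction_matrix.shape[1]

    @property
    def gene_ids(self) -> set[str]:
        return set(self.direction_matrix.index)

    @property
    def order(self) -> list[str]:
        """Canonical gene order used by every downstream correlation map."""
        return list(self.direction_matrix.index)

    def __len__(self) -> int:
        return len(self.direction_matrix)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def delta_de(expr_control: pd.Series, expr_experiment: pd.Series,
             delta_threshold: float = 2.0, condition: str = "delta",
             orientation: str = "factor_high_vs_low") -> DETable:
    """Replicate-free DE: per-gene delta of log2 expression values.

    Both vectors must be on the log2 scale over the same gene universe.
    Returns the full table with ``log2fc`` = experiment - control, ``padj``
    NaN (no replicates, no p-value), and a boolean ``flagged`` column for
    genes with |delta| strictly greater than the threshold.
    """
    ctrl_genes, expt_genes = set(expr_control.index), set(expr_experiment.index)
    if ctrl_genes != expt_genes:
        diff = len(ctrl_genes ^ expt_genes)
        raise ValueError(
            f"control and experiment gene universes differ by {diff} genes")
    delta = (expr_experiment - expr_control).reindex(expr_control.index)
    df = pd.DataFrame({
        "gene_id": delta.index,
        "log2fc": delta.to_numpy(dtype=float),
        "padj": np.nan,
    })
    df["flagged"] = df["log2fc"].abs() > delta_threshold
    return DETable(condition=condition, df=df, orientation=orientation,
                   from_delta=True)


def delta_consensus(de_a: DETable, de_b: DETable,
                    condition: str | None = None) -> DETable:
    """Combine two replicate-free delta tables: keep genes flagged in both
    with agreeing sign; log2fc is the mean of the two deltas."""
    for t in (de_a, de_b):
        if not t.from_delta or "flagged" not in t.df.columns:
            raise ValueError("delta_consensus expects tables from delta_de")
    if de_a.orientation != de_b.orientation:
        raise ValueError("delta tables must share an orientation")
    a = de_a.df[de_a.df["flagged"]].set_index("gene_id")["log2fc"]
    b = de_b.df[de_b.df["flagged"]].set_index("gene_id")["log2fc"]
    common = a.index.intersection(b.index)
    agree = common[np.sign(a[common]).to_numpy()
                   == np.sign(b[common]).to_numpy()]
    df = pd.DataFrame({
        "gene_id": agree,
        "log2fc": (a[agree].to_numpy() + b[agree].to_numpy()) / 2.0,
        "padj": np.nan,
    })
    df["flagged"] = True
    return DETable(
        condition=condition or f"{de_a.condition}+{de_b.condition}",
        df=df, orientation=de_a.orientation, from_delta=True)


def filter_de(table: DETable, lfc_threshold: float = 2.0,
              padj_threshold: float = 0.05) -> DETable:
    """Keep records with |log2fc| > lfc_threshold and padj < padj_threshold.

    Strict inequalities on both sides. Tables from the delta machinery carry
    no p-values, so only the fold-change condition applies to them; in
    replicate-based tables a missing padj fails the filter.
    """
    df = table.df
    keep = df["log2fc"].abs() > lfc_threshold
    if table.from_delta:
        if "flagged" in df.columns:
            keep &= df["flagged"]
    else:
        keep &= df["padj"] < padj_threshold      # NaN compares False
    out = df.loc[keep].reset_index(drop=True)
    return replace(table, df=out)


def build_core(filtered: Sequence[DETable]) -> CoreGeneSet:
    """Intersect filtered DE tables into the core gene set.

    Core genes are those present in every table after filtering. Signs are
    orientation-normalised per table; a gene whose direction differs between
    conditions stays in the core (context-dependent response), its row simply
    mixes +1 and -1. Rows are ordered by gene_id for a stable canonical
    order.
    """
    if len(filtered) < 2:
        raise ValueError("build_core needs at least 2 DE tables")
    conditions = [t.condition for t in filtered]
    if len(set(conditions)) != len(conditions):
        raise ValueError("DE tables must have distinct condition labels")
    core_ids = set.intersection(*(t.gene_ids for t in filtered))
    order = sorted(core_ids)
    matrix = pd.DataFrame(index=pd.Index(order, name="gene_id"), dtype=int)
    for t in filtered:
        matrix[t.condition] = t.oriented_sign().reindex(order).astype(int)
    return CoreGeneSet(direction_matrix=matrix, n_conditions=len(filtered))


def map_orthologues(core: CoreGeneSet, orthology: OrthologyMap,
                    min_confidence: float = 1,
                    min_homology_pct: float = 30.0) -> CoreGeneSet:
    """Project the core into the target species.

    A pair qualifies if confidence >= min_confidence OR homology_pct >=
    min_homology_pct (a disjunction: high-confidence annotation or enough
    sequence homology). Genes with no qualifying pair are dropped;
    one-to-many mappings expand to one row per target, directions inherited.
    If several source genes map to one target, the first source in core order
    wins.
    """
    pairs = orthology.df
    ok = ((pairs["confidence"] >= min_confidence)
          | (pairs["homology_pct"] >= min_homology_pct))
    qualifying = pairs.loc[ok, ["source_id", "target_id"]]
    by_source: dict[str, list[str]] = {}
    for source, target in qualifying.itertuples(index=False):
        by_source.setdefault(source, []).append(target)
    rows, index, seen_targets = [], [], set()
    for gene in core.order:
        for target in by_source.get(gene, []):
            if target in seen_targets:
                continue
            seen_targets.add(target)
            index.append(target)
            rows.append(core.direction_matrix.loc[gene])
    matrix = pd.DataFrame(rows, index=pd.Index(index, name="gene_id"),
                          columns=core.direction_matrix.columns, dtype=int)
    return CoreGeneSet(direction_matrix=matrix,
                       n_conditions=core.n_conditions)


def direction_map(core: CoreGeneSet,
                  extra_tables: Iterable[DETable] = ()) -> pd.DataFrame:
    """Gene x dataset sign matrix over the core, in the core's canonical
    order so maps stay comparable across figures.

    Columns of the core's own conditions come first; each extra (filtered,
    oriented) table adds a column with +1 / -1 for its significant genes and
    0 where a core gene is not significant in that dataset.
    """
    out = core.direction_matrix.copy()
    for t in extra_tables:
        sign = t.oriented_sign()
        out[t.condition] = (sign.reindex(out.index).fillna(0).astype(int))
    return out


def plot_direction_map(matrix: pd.DataFrame, path: str | None = None,
                       ax=None):
    """Render a direction matrix as a heatmap (up = yellow, down = blue)."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    if ax is None:
        _fig, ax = plt.subplots(
            figsize=(1 + 0.4 * matrix.shape[1],
                     max(2.0, 0.08 * matrix.shape[0])))
    cmap = ListedColormap(["#2166ac", "#f7f7f7", "#ffd92f"])
    ax.imshow(matrix.to_numpy(), aspect="auto", cmap=cmap, vmin=-1, vmax=1,
              interpolation="nearest")
    ax.set_xticks(range(matrix.shape[1]))
    ax.set_xticklabels(matrix.columns, rotation=90, fontsize=7)
    ax.set_yticks([])
    ax.set_ylabel(f"{matrix.shape[0]} core genes")
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight", dpi=150)
        plt.close(ax.figure)
    return ax
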