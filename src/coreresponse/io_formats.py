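"""Readers and writers for every external representation the pipeline touches.

Coordinate convention: everything in memory is 0-based half-open (BED-native).
The GTF reader/writer pair is the only place a +/-1 shift happens: GTF is
1-based closed on disk, so ``start`` loses 1 on read and gains it back on
write. Chromosome names are taken verbatim; an explicit rename map in
:class:`~coreresponse.config.PipelineConfig` is the only sanctioned renaming.

Formats handled: GTF (gene features), BED3-6 and narrowPeak, FASTA, JASPAR
position frequency matrices, and tab-separated gene tables (DE results, gene
lists, orthology pairs, term maps, count matrices).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pyfaidx

from .motif_analysis import PWMModel

logger = logging.getLogger(__name__)

__all__ = [
    "GeneRecord", "GenomeAnnotation", "PeakCollection",
    "read_annotation", "write_annotation",
    "read_intervals", "write_intervals",
    "read_fasta", "write_fasta",
    "read_pfm", "read_pfm_library", "write_pfm", "read_motif_classes",
    "read_gene_table", "SchemaError",
]

VALID_STRANDS = {"+", "-"}
BIOTYPES = {"protein_coding", "non_coding"}


class SchemaError(ValueError):
    """A delimited table does not match its declared schema."""


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneRecord:
    """One gene: 0-based half-open span on a named chromosome."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} >= end {self.end}")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        if self.biotype not in BIOTYPES:
            raise ValueError(
                f"gene {self.gene_id}: bad biotype {self.biotype!r}")

    @property
    def tss(self) -> int:
        """Canonical transcription start: 5' end of the gene span."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class GenomeAnnotation:
    """Gene records plus (optionally) the companion chromosome lengths."""

    genes: list[GeneRecord]
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate gene_id(s) in annotation: {dupes[:5]}")
        if self.chrom_lengths:
            for g in self.genes:
                if g.chrom not in self.chrom_lengths:
                    raise ValueError(
                        f"gene {g.gene_id} on unknown chromosome {g.chrom}")
                if g.end > self.chrom_lengths[g.chrom]:
                    raise ValueError(
                        f"gene {g.gene_id} extends past end of {g.chrom}")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def get(self, gene_id: str) -> GeneRecord:
        try:
            return self._index[gene_id]
        except AttributeError:
            self._index = {g.gene_id: g for g in self.genes}
            return self._index[gene_id]

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(g.gene_id, g.chrom, g.start, g.end, g.strand, g.biotype)
             for g in self.genes],
            columns=["gene_id", "chrom", "start", "end", "strand", "biotype"],
        )

    def validate_against_sequence(self, genome: Mapping[str, str]) -> None:
        """Check every gene's chromosome exists and contains its span."""
        for g in self.genes:
            if g.chrom not in genome:
                raise ValueError(
                    f"gene {g.gene_id}: chromosome {g.chrom} absent from sequence")
            if g.end > len(genome[g.chrom]):
                raise ValueError(
                    f"gene {g.gene_id}: span exceeds {g.chrom} length")


_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def read_annotation(path: str | Path,
                    coding_biotypes: Sequence[str] = ("protein_coding",),
                    chrom_rename: Mapping[str, str] | None = None,
                    ) -> GenomeAnnotation:
    """Read gene features from a GTF file into a :class:`GenomeAnnotation`.

    GTF's 1-based closed coordinates become 0-based half-open. The
    ``gene_biotype`` (or ``gene_type``) attribute is collapsed to
    ``protein_coding`` / ``non_coding`` via *coding_biotypes*; a missing
    biotype attribute counts as non-coding.
    """
    chrom_rename = chrom_rename or {}
    coding = set(coding_biotypes)
    genes: list[GeneRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(
                    f"{path}: line {lineno}: expected 9 tab-separated GTF "
                    f"fields, got {len(fields)}")
            chrom, _source, feature, start, end, _score, strand, _frame, attrs \
                = fields
            if feature != "gene":
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno}: non-numeric coordinates") from None
            attr = dict(_GTF_ATTR.findall(attrs))
            gene_id = attr.get("gene_id")
            if gene_id is None:
                raise ValueError(
                    f"{path}: line {lineno}: gene feature without gene_id")
            if gene_id in seen:
                raise ValueError(
                    f"{path}: line {lineno}: duplicate gene_id {gene_id!r}")
            seen.add(gene_id)
            raw_biotype = attr.get("gene_biotype", attr.get("gene_type", ""))
            biotype = "protein_coding" if raw_biotype in coding else "non_coding"
            genes.append(GeneRecord(
                gene_id=gene_id,
                chrom=chrom_rename.get(chrom, chrom),
                start=start_i - 1,          # the one and only -1 shift
                end=end_i,
                strand=strand,
                biotype=biotype,
            ))
    if not genes:
        logger.warning("annotation %s contains no gene features", path)
    return GenomeAnnotation(genes)


def write_annotation(annotation: GenomeAnnotation, path: str | Path,
                     source: str = "coreresponse") -> None:
    """Write gene features as GTF (back to 1-based closed coordinates)."""
    with open(path, "w") as fh:
        for g in annotation.genes:
            raw_biotype = ("protein_coding" if g.biotype == "protein_coding"
                           else "misc_RNA")
            attrs = f'gene_id "{g.gene_id}"; gene_biotype "{raw_biotype}";'
            fh.write("\t".join([
                g.chrom, source, "gene", str(g.start + 1), str(g.end),
                ".", g.strand, ".", attrs,
            ]) + "\n")


# ---------------------------------------------------------------------------
# intervals
# ---------------------------------------------------------------------------

@dataclass
class PeakCollection:
    """A labelled, sorted set of genomic intervals for one condition.

    ``df`` columns: chrom, start, end, name, and when the input provided
    them, score and summit (narrowPeak peak-offset).
    """

    label: str
    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["chrom", "start", "end", "name"]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise ValueError(f"PeakCollection missing columns {missing}")
        bad = self.df["start"] >= self.df["end"]
        if bad.any():
            idx = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"collection {self.label!r}: interval {idx} has start >= end")
        self.df = (self.df.sort_values(["chrom", "start", "end"],
                                       kind="mergesort")
                   .reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.df)


def read_intervals(path: str | Path, label: str | None = None,
                   ) -> PeakCollection:
    """Read BED3-6 or narrowPeak. Coordinates kept 0-based half-open."""
    path = Path(path)
    label = label if label is not None else path.stem
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#",
                     dtype={0: str})
    if df.shape[1] < 3:
        raise ValueError(f"{path}: need >= 3 columns, got {df.shape[1]}")
    ncol = df.shape[1]
    out = pd.DataFrame({
        "chrom": df[0].astype(str),
        "start": pd.to_numeric(df[1], errors="raise").astype(np.int64),
        "end": pd.to_numeric(df[2], errors="raise").astype(np.int64),
    })
    out["name"] = (df[3].astype(str) if ncol > 3
                   else [f"{label}_{i}" for i in range(len(df))])
    if ncol > 4:
        out["score"] = pd.to_numeric(df[4], errors="coerce")
    if ncol > 5:
        out["strand"] = df[5].astype(str)
    if ncol >= 10:          # narrowPeak: signal, p, q, summit offset
        out["signal"] = pd.to_numeric(df[6], errors="coerce")
        out["summit"] = pd.to_numeric(df[9], errors="raise").astype(np.int64)
    return PeakCollection(label=label, df=out)


def write_intervals(collection: PeakCollection, path: str | Path) -> None:
    cols = ["chrom", "start", "end", "name"]
    df = collection.df
    if "score" in df.columns:
        cols.append("score")
        if "strand" in df.columns:
            cols.append("strand")
    df.to_csv(path, sep="\t", header=False, index=False, columns=cols)


# ---------------------------------------------------------------------------
# sequence
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA file into a name -> uppercase sequence dict (pyfaidx)."""
    with pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True,
                       rebuild=True) as fa:
        return {name: str(fa[name][:]) for name in fa.keys()}


def write_fasta(sequences: Mapping[str, str], path: str | Path,
                width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# JASPAR position frequency matrices
# ---------------------------------------------------------------------------

def _parse_pfm_block(header: str, rows: list[str], origin: str,
                     pseudocount: float) -> PWMModel:
    parts = header[1:].split(None, 1)
    motif_id = parts[0] if parts else "motif"
    name = parts[1].strip() if len(parts) > 1 else motif_id
    if len(rows) != 4:
        raise ValueError(
            f"{origin}: motif {motif_id}: expected 4 base rows, got {len(rows)}")
    counts: dict[str, list[float]] = {}
    for row in rows:
        m = re.match(r"^\s*([ACGT])\s*\[?\s*([-\d.eE+\s]*?)\s*\]?\s*$", row)
        if not m:
            raise ValueError(f"{origin}: motif {motif_id}: bad row {row!r}")
        base, values = m.group(1), m.group(2).split()
        try:
            counts[base] = [float(v) for v in values]
        except ValueError:
            raise ValueError(
                f"{origin}: motif {motif_id}: non-numeric count in row "
                f"{base}") from None
    if set(counts) != {"A", "C", "G", "T"}:
        raise ValueError(
            f"{origin}: motif {motif_id}: rows must be labelled A,C,G,T")
    lengths = {len(v) for v in counts.values()}
    if len(lengths) != 1:
        raise ValueError(f"{origin}: motif {motif_id}: ragged rows")
    matrix = np.array([counts[b] for b in "ACGT"], dtype=float)
    if (matrix < 0).any():
        raise ValueError(f"{origin}: motif {motif_id}: negative counts")
    if matrix.shape[1] < 4:
        raise ValueError(
            f"{origin}: motif {motif_id}: length {matrix.shape[1]} < 4")
    return PWMModel(motif_id=motif_id, name=name, counts=matrix,
                    pseudocount=pseudocount)


def read_pfm_library(path: str | Path,
                     pseudocount: float = 1.0) -> list[PWMModel]:
    """Read one or more JASPAR-format PFMs from a file."""
    models: list[PWMModel] = []
    header: str | None = None
    rows: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                if header is not None:
                    models.append(
                        _parse_pfm_block(header, rows, str(path), pseudocount))
                header, rows = line, []
            else:
                if header is None:
                    raise ValueError(f"{path}: matrix row before '>' header")
                rows.append(line)
    if header is not None:
        models.append(_parse_pfm_block(header, rows, str(path), pseudocount))
    if not models:
        raise ValueError(f"{path}: no motifs found")
    return models


def read_pfm(path: str | Path, pseudocount: float = 1.0) -> PWMModel:
    """Read a single JASPAR-format PFM (error if the file holds several)."""
    models = read_pfm_library(path, pseudocount=pseudocount)
    if len(models) != 1:
        raise ValueError(f"{path}: expected one motif, found {len(models)}")
    return models[0]


def write_pfm(models: PWMModel | Sequence[PWMModel],
              path: str | Path) -> None:
    """Write one or more PWMModels back to JASPAR PFM text."""
    if isinstance(models, PWMModel):
        models = [models]
    with open(path, "w") as fh:
        for m in models:
            fh.write(f">{m.motif_id} {m.name}\n")
            for base, row in zip("ACGT", m.counts):
                cells = " ".join(format(v, "g") for v in row)
                fh.write(f"{base}  [ {cells} ]\n")


def read_motif_classes(path: str | Path) -> pd.DataFrame:
    """Read a motif -> class/family classification table (TSV).

    Columns: motif_id, class, family (TFclass-style subdivisions).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"motif_id", "class", "family"} - set(df.columns)
    if missing:
        raise SchemaError(
            f"{path}: motif class table missing column(s) {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# gene tables
# ---------------------------------------------------------------------------

_SCHEMAS: dict[str, list[str]] = {
    "de": ["gene_id", "log2fc", "padj"],
    "genelist": ["gene_id"],
    "orthology": ["source_id", "target_id", "confidence", "homology_pct"],
    "term_map": ["gene_id", "term_id"],
    "counts": ["gene_id", "length"],
}


def read_gene_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read a tab-separated gene table against a declared schema.

    Schemas: ``de`` (gene_id, log2fc, padj), ``genelist`` (gene_id),
    ``orthology`` (source_id, target_id, confidence, homology_pct),
    ``term_map`` (gene_id, term_id), ``counts`` (gene_id, length, then one
    integer column per sample).

    The reader validates types only; threshold filtering happens downstream.
    """
    if schema not in _SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; "
                         f"expected one of {sorted(_SCHEMAS)}")
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _SCHEMAS[schema] if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: schema {schema!r} missing required column(s) {missing}")
    if schema == "de":
        df["log2fc"] = pd.to_numeric(df["log2fc"], errors="raise")
        df["padj"] = pd.to_numeric(df["padj"], errors="coerce")
        bad = df["padj"].dropna()
        if ((bad < 0) | (bad > 1)).any():
            raise ValueError(f"{path}: padj outside [0, 1]")
    elif schema == "orthology":
        df["confidence"] = pd.to_numeric(df["confidence"], errors="raise")
        df["homology_pct"] = pd.to_numeric(df["homology_pct"], errors="raise")
        if ((df["homology_pct"] < 0) | (df["homology_pct"] > 100)).any():
            raise ValueError(f"{path}: homology_pct outside [0, 100]")
    elif schema == "counts":
        sample_cols = [c for c in df.columns if c not in ("gene_id", "length")]
        if not sample_cols:
            raise SchemaError(f"{path}: counts table has no sample columns")
        for c in sample_cols:
            df[c] = pd.to_numeric(df[c], errors="raise")
            if (df[c] < 0).any():
                raise ValueError(f"{path}: negative count in column {c!r}")
        if (pd.to_numeric(df["length"]) <= 0).any():
            raise ValueError(f"{path}: non-positive gene length")
    return df
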