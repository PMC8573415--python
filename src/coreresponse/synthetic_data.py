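"""Self-contained synthetic inputs with planted, known-truth signal.

Every downstream stage of the pipeline can be exercised without any
download: this module fabricates a small genome with a gene annotation,
negative-binomial count matrices in which a chosen core of genes is shifted
by a known log2 effect in every condition (with per-condition direction
signs, some deliberately inconsistent, emulating a context-dependent
response), per-condition peak sets guaranteed to share a planted set of core
regions carrying an exact CDX-type consensus site (with co-factor consensus
sites written into the +/- 50 bp flanks of a chosen fraction of them), and
an expression cohort whose designated driver gene follows a per-sample
gradient with a set of positively / negatively linked genes.

Replicate-based DE testing itself is upstream of the pipeline (a count-model
tool's output is consumed, not produced); for synthetic runs this module
emits those DE tables with a Wald test that uses the generator's own true
dispersion, standing in for the upstream tool's output schema.

All generators are deterministic under a fixed seed. A pipeline run uses one
seed forked per stage by fixed labels (:func:`stage_rng`), so stage-level
reproducibility survives re-ordering of the stages.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .deg_core import DETable
from .io_formats import GeneRecord, GenomeAnnotation, PeakCollection
from .motif_analysis import BASES, PWMModel

__all__ = [
    "SyntheticTruth", "stage_rng", "make_genome", "make_counts",
    "de_tables_from_counts", "make_peaks", "make_cohort",
    "cohort_de_table", "make_pwm_library", "consensus_string",
    "make_orthology", "make_term_map", "make_super_enhancers",
]


def stage_rng(seed: int, label: str) -> np.random.Generator:
    """Fork one run-level seed into an independent per-stage generator.

    The label is hashed into the seed sequence, so adding or re-ordering
    stages never perturbs another stage's stream.
    """
    digest = hashlib.sha256(label.encode()).digest()
    label_key = int.from_bytes(digest[:4], "big")
    return np.random.default_rng(np.random.SeedSequence([seed, label_key]))


@dataclass
class SyntheticTruth:
    """Everything that was planted, for downstream truth comparisons."""

    planted_core_genes: dict[str, dict[str, int]] = field(default_factory=dict)
    planted_core_regions: list[tuple[str, int, int]] = field(
        default_factory=list)
    planted_motif_positions: list[tuple[int, int, str]] = field(
        default_factory=list)     # (region index, offset in region, strand)
    planted_cofactor_regions: list[int] = field(default_factory=list)
    planted_cofactor_rate: float = 0.0
    planted_promoter_genes: list[str] = field(default_factory=list)
    driver_gene: str = ""
    linked_genes: dict[str, int] = field(default_factory=dict)
    cohort_gradient: pd.Series | None = None

    def condition_signs(self, condition: str) -> dict[str, int]:
        return {g: signs[condition]
                for g, signs in self.planted_core_genes.items()}


# ---------------------------------------------------------------------------
# genome and annotation
# ---------------------------------------------------------------------------

def make_genome(n_chrom: int = 3, chrom_len: int = 300_000, gc: float = 0.42,
                seed: int = 0, n_genes: int = 60, gene_len_range:
                tuple[int, int] = (1_000, 3_000), coding_fraction: float = 0.8,
                promoter_length_bp: int = 2_000,
                ) -> tuple[dict[str, str], GenomeAnnotation]:
    """Generate i.i.d. sequence at a stated GC and a non-overlapping gene set.

    Genes are laid out with a clear promoter-sized gap on both sides,
    alternating chromosomes, ~50 % per strand, biotype protein_coding at
    *coding_fraction*. Raises if the requested genes do not fit.
    """
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be in [0, 1]")
    if chrom_len < 10 * promoter_length_bp:
        raise ValueError(
            f"chrom_len must be >= 10 x promoter length "
            f"({10 * promoter_length_bp})")
    rng = stage_rng(seed, "genome")
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    genome = {
        f"chr{i + 1}": "".join(
            np.array(list(BASES))[rng.choice(4, size=chrom_len, p=probs)])
        for i in range(n_chrom)
    }
    # greedy layout: gene + promoter-sized spacer on each side
    spacer = promoter_length_bp + 500
    slots: list[tuple[str, int, int]] = []
    max_gene_len = gene_len_range[1]
    for chrom in genome:
        pos = spacer
        while pos + max_gene_len + spacer <= chrom_len:
            slots.append((chrom, pos, pos + max_gene_len))
            pos += max_gene_len + 2 * spacer
    if len(slots) < n_genes:
        raise ValueError(
            f"cannot place {n_genes} genes in {n_chrom} x {chrom_len} bp; "
            f"only {len(slots)} slots — use longer chromosomes")
    chosen = sorted(rng.choice(len(slots), size=n_genes, replace=False))
    genes = []
    for i, slot_idx in enumerate(chosen):
        chrom, lo, hi = slots[slot_idx]
        length = int(rng.integers(gene_len_range[0], gene_len_range[1] + 1))
        start = lo + int(rng.integers(0, hi - lo - length + 1))
        genes.append(GeneRecord(
            gene_id=f"gene_{i:04d}", chrom=chrom, start=start,
            end=start + length,
            strand="+" if rng.random() < 0.5 else "-",
            biotype=("protein_coding" if rng.random() < coding_fraction
                     else "non_coding")))
    annotation = GenomeAnnotation(
        genes=genes, chrom_lengths={c: len(s) for c, s in genome.items()})
    annotation.validate_against_sequence(genome)
    return genome, annotation


# ---------------------------------------------------------------------------
# count matrices with a planted DEG core
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: np.ndarray,
             dispersion: float, size: tuple[int, ...]) -> np.ndarray:
    """Negative binomial with Var = mu + dispersion * mu^2."""
    if dispersion <= 0:
        return rng.poisson(mean, size=size)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


def make_counts(annotation: GenomeAnnotation, n_conditions: int = 3,
                n_reps: int = 3, n_core_genes: int = 50,
                nb_dispersion: float = 0.02, effect_log2fc: float = 3.0,
                seed: int = 0, sign_flip_rate: float = 0.3,
                n_total_genes: int | None = None,
                truth: SyntheticTruth | None = None,
                ) -> tuple[dict[str, dict[str, pd.DataFrame]], SyntheticTruth]:
    """Negative-binomial counts for control and factor-perturbed samples.

    The planted core genes are shifted by +/- *effect_log2fc* in every
    condition's perturbed group, each gene carrying a base direction that
    flips per condition with probability *sign_flip_rate* (context-dependent
    response). Planted genes receive robustly expressed base means so the
    planted effect is recoverable, per the generator's contract; background
    genes get log-normal means. ``n_reps=1`` is supported to exercise the
    replicate-free delta machinery downstream.

    Returns ``({condition: {"control": genes x reps, "treatment": ...}},
    truth)``. The gene universe is padded with independent background genes up to
    *n_total_genes* in total (ids ``bg_*``).
    """
    if effect_log2fc < 0:
        raise ValueError("effect_log2fc must be >= 0")
    rng = stage_rng(seed, "counts")
    gene_ids = list(annotation.gene_ids)
    if n_total_genes is not None:
        extra = max(0, n_total_genes - len(gene_ids))
        gene_ids = gene_ids + [f"bg_{i:05d}" for i in range(extra)]
    if n_core_genes > len(gene_ids):
        raise ValueError("more planted core genes than genes available")
    planted_ids = list(rng.choice(annotation.gene_ids,
                                  size=n_core_genes, replace=False))
    conditions = [f"cond_{c + 1}" for c in range(n_conditions)]
    base_sign = {g: int(rng.choice([-1, 1])) for g in planted_ids}
    signs = {
        g: {c: (-base_sign[g] if rng.random() < sign_flip_rate
                else base_sign[g]) for c in conditions}
        for g in planted_ids
    }
    base_mean = pd.Series(
        np.maximum(rng.lognormal(mean=5.0, sigma=1.0, size=len(gene_ids)),
                   10.0),
        index=gene_ids)
    # planted genes sit in the well-expressed range: the effect must be
    # recoverable above the fold-change threshold at realistic noise
    base_mean[planted_ids] = rng.uniform(200.0, 1000.0, size=len(planted_ids))
    datasets: dict[str, dict[str, pd.DataFrame]] = {}
    for cond in conditions:
        mu_ctrl = base_mean.to_numpy()
        shift = np.ones(len(gene_ids))
        for g in planted_ids:
            shift[gene_ids.index(g)] = 2.0 ** (signs[g][cond] * effect_log2fc)
        mu_trt = mu_ctrl * shift
        ctrl = _nb_draw(rng, mu_ctrl[:, None], nb_dispersion,
                        (len(gene_ids), n_reps))
        trt = _nb_draw(rng, mu_trt[:, None], nb_dispersion,
                       (len(gene_ids), n_reps))
        datasets[cond] = {
            "control": pd.DataFrame(
                ctrl, index=gene_ids,
                columns=[f"{cond}_ctrl_{r}" for r in range(n_reps)]),
            "treatment": pd.DataFrame(
                trt, index=gene_ids,
                columns=[f"{cond}_trt_{r}" for r in range(n_reps)]),
        }
    out_truth = truth if truth is not None else SyntheticTruth()
    out_truth.planted_core_genes = signs
    return datasets, out_truth


def de_tables_from_counts(datasets: Mapping[str, Mapping[str, pd.DataFrame]],
                          nb_dispersion: float = 0.02,
                          flip_orientation: Sequence[str] = (),
                          ) -> list[DETable]:
    """Stand-in for the upstream replicate-based DE tool on synthetic counts.

    Wald test on the log2 ratio of group means, with the standard error
    derived from the generator's true negative-binomial dispersion
    (Var = mu + dispersion mu^2), Benjamini-Hochberg adjusted per condition.
    Conditions named in *flip_orientation* are emitted the other way around
    (control vs treatment) with orientation ``factor_low_vs_high``, to
    exercise downstream orientation normalisation.
    """
    from statsmodels.stats.multitest import multipletests

    tables = []
    for cond, groups in datasets.items():
        ctrl, trt = groups["control"], groups["treatment"]
        flipped = cond in flip_orientation
        a, b = (trt, ctrl) if flipped else (ctrl, trt)
        mean_a = a.mean(axis=1).to_numpy() + 0.5
        mean_b = b.mean(axis=1).to_numpy() + 0.5
        lfc = np.log2(mean_b / mean_a)
        ln2sq = math.log(2.0) ** 2
        var = ((1.0 / mean_a + nb_dispersion) / a.shape[1]
               + (1.0 / mean_b + nb_dispersion) / b.shape[1]) / ln2sq
        from scipy import stats as sstats
        z = lfc / np.sqrt(var)
        p = 2.0 * sstats.norm.sf(np.abs(z))
        padj = multipletests(p, method="fdr_bh")[1]
        tables.append(DETable(
            condition=cond,
            df=pd.DataFrame({"gene_id": ctrl.index, "log2fc": lfc,
                             "padj": padj}),
            orientation=("factor_low_vs_high" if flipped
                         else "factor_high_vs_low")))
    return tables


# ---------------------------------------------------------------------------
# peak sets with planted core regions and motifs
# ---------------------------------------------------------------------------

def consensus_string(pwm: PWMModel) -> str:
    """The matrix's single best-scoring sequence (column-wise argmax)."""
    return "".join(BASES[i] for i in pwm.counts.argmax(axis=0))


def _splice(seq: str, pos: int, insert: str) -> str:
    return seq[:pos] + insert + seq[pos + len(insert):]


def make_peaks(annotation: GenomeAnnotation, genome: dict[str, str],
               cdx_pwm: PWMModel, n_conditions: int = 3,
               n_core_regions: int = 60, region_len_bp: int = 20,
               peak_len_bp: int = 300, n_private_peaks: int = 100,
               jitter_bp: int = 40, planted_cofactor_rate: float = 0.5,
               cofactor_pwm: PWMModel | None = None, flank_bp: int = 50,
               min_overlap_bp: int = 10, seed: int = 0,
               promoter_gene_ids: Sequence[str] = (),
               promoter_length_bp: int = 2_000,
               truth: SyntheticTruth | None = None,
               ) -> tuple[dict[str, str], list[PeakCollection],
                          SyntheticTruth]:
    """Per-condition peak sets sharing a planted set of core regions.

    Every planted region is covered by one peak per condition whose borders
    jitter by up to *jitter_bp* while always containing the planted region,
    so the n-way intersection is guaranteed. The exact CDX consensus string
    is spliced into the genome at the centre of each planted region, and the
    co-factor consensus into the +/- *flank_bp* vicinity of that site for a
    *planted_cofactor_rate* fraction of regions. Private peaks are placed so
    they never co-occur across conditions (rejection sampling), hence the
    recovered core equals the planted set.

    The first *len(promoter_gene_ids)* planted regions are centred in the
    promoters of those genes (to link the region core with the gene core);
    the rest land in clear genomic space. Returns the edited genome, one
    collection per condition, and the truth.
    """
    if region_len_bp < min_overlap_bp:
        raise ValueError("planted regions must satisfy the overlap rule")
    if region_len_bp + 2 * jitter_bp > peak_len_bp:
        raise ValueError("peak_len_bp too small for region + jitter")
    rng = stage_rng(seed, "peaks")
    genome = dict(genome)
    chroms = list(genome)
    chrom_len = {c: len(genome[c]) for c in chroms}
    margin = peak_len_bp + jitter_bp + flank_bp

    # --- anchor the planted regions -------------------------------------
    anchors: list[tuple[str, int]] = []     # (chrom, region start)
    occupied: list[tuple[str, int, int]] = []

    def _clear(chrom: str, start: int, end: int) -> bool:
        return all(not (chrom == oc and start < oe and end > os_)
                   for oc, os_, oe in occupied)

    for gid in promoter_gene_ids:
        g = annotation.get(gid)
        centre = (g.start - promoter_length_bp // 2 if g.strand == "+"
                  else g.end + promoter_length_bp // 2)
        start = int(np.clip(centre - region_len_bp // 2, margin,
                            chrom_len[g.chrom] - margin - region_len_bp))
        if not _clear(g.chrom, start - margin, start + region_len_bp + margin):
            raise ValueError(f"promoter region for {gid} collides; "
                             f"use fewer promoter-linked regions")
        anchors.append((g.chrom, start))
        occupied.append((g.chrom, start - margin,
                         start + region_len_bp + margin))
    attempts = 0
    while len(anchors) < n_core_regions:
        attempts += 1
        if attempts > 200 * n_core_regions:
            raise ValueError("cannot place planted regions; genome too small")
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(margin,
                                 chrom_len[chrom] - margin - region_len_bp))
        if _clear(chrom, start - margin, start + region_len_bp + margin):
            anchors.append((chrom, start))
            occupied.append((chrom, start - margin,
                             start + region_len_bp + margin))

    # --- splice motifs into the genome ----------------------------------
    cdx_site = consensus_string(cdx_pwm)
    motif_positions: list[tuple[int, int, str]] = []
    cofactor_regions: list[int] = []
    n_cof = int(round(planted_cofactor_rate * n_core_regions))
    cof_choice = set(rng.choice(n_core_regions, size=n_cof, replace=False)
                     ) if n_cof else set()
    for idx, (chrom, start) in enumerate(anchors):
        site_pos = start + (region_len_bp - len(cdx_site)) // 2
        genome[chrom] = _splice(genome[chrom], site_pos, cdx_site)
        motif_positions.append((idx, site_pos - start, "+"))
        if idx in cof_choice:
            if cofactor_pwm is None:
                raise ValueError("planted_cofactor_rate > 0 needs a "
                                 "cofactor_pwm")
            cof_site = consensus_string(cofactor_pwm)
            gap = int(rng.integers(5, flank_bp - len(cof_site)))
            side = 1 if rng.random() < 0.5 else -1
            pos = (site_pos + len(cdx_site) + gap if side > 0
                   else site_pos - gap - len(cof_site))
            genome[chrom] = _splice(genome[chrom], pos, cof_site)
            cofactor_regions.append(idx)

    # --- per-condition peaks over the planted regions --------------------
    base_pad = (peak_len_bp - region_len_bp) // 2
    collections = []
    all_private: list[tuple[str, int, int]] = []
    for c in range(n_conditions):
        label = f"cond_{c + 1}"
        rows = []
        for idx, (chrom, start) in enumerate(anchors):
            end = start + region_len_bp
            if jitter_bp > 0:
                pad_l = base_pad + int(rng.integers(-jitter_bp, jitter_bp + 1))
                pad_r = base_pad + int(rng.integers(-jitter_bp, jitter_bp + 1))
            else:
                pad_l = pad_r = base_pad
            ps, pe = max(0, start - max(0, pad_l)), end + max(0, pad_r)
            assert ps <= start and pe >= end, "generator bug: jitter broke " \
                "the guaranteed overlap"
            rows.append((chrom, ps, pe, f"{label}_core_{idx}"))
        placed = 0
        tries = 0
        while placed < n_private_peaks:
            tries += 1
            if tries > 500 * max(1, n_private_peaks):
                raise ValueError("cannot place private peaks; genome too "
                                 "crowded")
            chrom = chroms[int(rng.integers(len(chroms)))]
            s = int(rng.integers(0, chrom_len[chrom] - peak_len_bp))
            e = s + peak_len_bp
            if not _clear(chrom, s, e):
                continue
            if any(chrom == pc and s < pe_ and e > ps_
                   for pc, ps_, pe_ in all_private):
                continue
            rows.append((chrom, s, e, f"{label}_private_{placed}"))
            all_private.append((chrom, s, e))
            placed += 1
        collections.append(PeakCollection(
            label=label,
            df=pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])))

    out_truth = truth if truth is not None else SyntheticTruth()
    out_truth.planted_core_regions = [
        (chrom, start, start + region_len_bp) for chrom, start in anchors]
    out_truth.planted_motif_positions = motif_positions
    out_truth.planted_cofactor_regions = sorted(cofactor_regions)
    out_truth.planted_cofactor_rate = planted_cofactor_rate
    out_truth.planted_promoter_genes = list(promoter_gene_ids)
    for chrom, start, end in out_truth.planted_core_regions:
        assert 0 <= start < end <= chrom_len[chrom]
    return genome, collections, out_truth


# ---------------------------------------------------------------------------
# cohorts with a driver-expression gradient
# ---------------------------------------------------------------------------

def make_cohort(annotation: GenomeAnnotation, n_samples: int = 100,
                gradient_strength: float = 2.0, n_linked_genes: int = 30,
                seed: int = 0, nb_dispersion: float = 0.05,
                driver_gene: str | None = None,
                linked_gene_ids: Sequence[str] = (),
                coupling: float = 0.8,
                truth: SyntheticTruth | None = None,
                ) -> tuple[pd.DataFrame, pd.Series, SyntheticTruth]:
    """An expression cohort whose driver gene follows a per-sample gradient.

    The driver's log2 mean moves with a latent uniform(-1, 1) per-sample
    gradient scaled by *gradient_strength* (log2 units across the gradient);
    each linked gene follows the same gradient with a recorded +/- sign at
    *coupling* times that strength; all other genes are independent of the
    gradient. Returns (counts genes x samples, gene lengths in bp, truth).
    """
    if n_samples < 8:
        raise ValueError("need at least 8 samples")
    rng = stage_rng(seed, "cohort")
    gene_ids = list(annotation.gene_ids)
    driver = driver_gene or gene_ids[0]
    if driver not in gene_ids:
        raise KeyError(f"driver gene {driver!r} not in annotation")
    linked = list(linked_gene_ids) if linked_gene_ids else []
    pool = [g for g in gene_ids if g != driver and g not in linked]
    need = n_linked_genes - len(linked)
    if need > 0:
        if need > len(pool):
            raise ValueError("not enough genes for the requested linkage")
        linked += list(rng.choice(pool, size=need, replace=False))
    samples = [f"sample_{i:03d}" for i in range(n_samples)]
    gradient = pd.Series(rng.uniform(-1.0, 1.0, size=n_samples),
                         index=samples)
    base_log2 = pd.Series(
        rng.uniform(5.0, 9.0, size=len(gene_ids)), index=gene_ids)
    signs = {g: int(rng.choice([-1, 1])) for g in linked}
    log2_mu = pd.DataFrame(
        np.tile(base_log2.to_numpy()[:, None], (1, n_samples)),
        index=gene_ids, columns=samples)
    log2_mu.loc[driver] += gradient_strength * gradient.to_numpy()
    for g in linked:
        log2_mu.loc[g] += (signs[g] * coupling * gradient_strength
                           * gradient.to_numpy())
    mu = 2.0 ** log2_mu.to_numpy()
    counts = pd.DataFrame(
        _nb_draw(rng, mu, nb_dispersion, mu.shape),
        index=gene_ids, columns=samples)
    lengths = pd.Series(rng.integers(500, 5_001, size=len(gene_ids)),
                        index=gene_ids, dtype=float)
    out_truth = truth if truth is not None else SyntheticTruth()
    out_truth.driver_gene = driver
    out_truth.linked_genes = signs
    out_truth.cohort_gradient = gradient
    return counts, lengths, out_truth


def cohort_de_table(counts: pd.DataFrame, high_samples: Sequence[str],
                    low_samples: Sequence[str], condition: str,
                    nb_dispersion: float = 0.05) -> DETable:
    """Stand-in upstream DE between cohort groups (high vs low driver).

    Same Wald-with-true-dispersion statistic as
    :func:`de_tables_from_counts`, oriented factor-high vs factor-low.
    """
    datasets = {condition: {
        "control": counts[list(low_samples)],
        "treatment": counts[list(high_samples)],
    }}
    return de_tables_from_counts(datasets, nb_dispersion=nb_dispersion)[0]


# ---------------------------------------------------------------------------
# motif library
# ---------------------------------------------------------------------------

# ---------------------------------------------------------------------------
# side tables: orthology, ontology terms, super-enhancers
# ---------------------------------------------------------------------------

def make_orthology(gene_ids: Sequence[str], seed: int = 0,
                   high_conf_rate: float = 0.7,
                   homology_only_rate: float = 0.15,
                   duplicate_rate: float = 0.1,
                   target_prefix: str = "HS_") -> pd.DataFrame:
    """A cross-species orthology table over the given source genes.

    Per gene: with *high_conf_rate* a confidence-1 pair (any homology); else
    with *homology_only_rate* / (1 - high_conf_rate) a low-confidence pair
    with >= 30 % homology (qualifies by homology alone); otherwise a
    low-confidence, low-homology pair that a confidence-1-or->=30 % filter
    drops. A *duplicate_rate* fraction of genes get a second target
    (one-to-many). Columns: source_id, target_id, confidence, homology_pct.
    """
    rng = stage_rng(seed, "orthology")
    rows = []
    for g in gene_ids:
        u = rng.random()
        if u < high_conf_rate:
            conf, hom = 1, float(rng.uniform(10, 95))
        elif u < high_conf_rate + homology_only_rate:
            conf, hom = 0, float(rng.uniform(30, 95))
        else:
            conf, hom = 0, float(rng.uniform(0, 29.9))
        rows.append((g, f"{target_prefix}{g}", conf, round(hom, 1)))
        if rng.random() < duplicate_rate:
            rows.append((g, f"{target_prefix}{g}_b", conf,
                         round(float(rng.uniform(10, 95)), 1)))
    return pd.DataFrame(
        rows, columns=["source_id", "target_id", "confidence",
                       "homology_pct"])


def make_term_map(gene_ids: Sequence[str], n_terms: int = 20, seed: int = 0,
                  annotated_fraction: float = 0.9,
                  max_terms_per_gene: int = 3) -> pd.DataFrame:
    """Gene -> ontology-term pairs; a fraction of genes carries no term (and
    so falls outside a universe defined by term membership)."""
    rng = stage_rng(seed, "terms")
    rows = []
    for g in gene_ids:
        if rng.random() >= annotated_fraction:
            continue
        k = int(rng.integers(1, max_terms_per_gene + 1))
        for t in rng.choice(n_terms, size=min(k, n_terms), replace=False):
            rows.append((g, f"TERM:{int(t):04d}"))
    return pd.DataFrame(rows, columns=["gene_id", "term_id"])


def make_super_enhancers(genome: Mapping[str, str], n_domains: int = 30,
                         length_bp: int = 3_000,
                         seed: int = 0) -> PeakCollection:
    """Random super-enhancer-style domains over the genome (dbSUPER-like)."""
    rng = stage_rng(seed, "super_enhancers")
    chroms = list(genome)
    rows = []
    for i in range(n_domains):
        chrom = chroms[int(rng.integers(len(chroms)))]
        limit = len(genome[chrom]) - length_bp
        if limit <= 0:
            raise ValueError("chromosomes shorter than a super-enhancer")
        s = int(rng.integers(0, limit))
        rows.append((chrom, s, s + length_bp, f"SE_{i}"))
    return PeakCollection(label="super_enhancers", df=pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name"]))


_FAMILIES = [("Homeodomain", "HOX-related"), ("Homeodomain", "NK-related"),
             ("Zinc finger", "GATA-type"), ("Zinc finger", "C2H2"),
             ("bHLH", "E-box binders"), ("bZIP", "CREB-related"),
             ("Forkhead", "FOX"), ("Nuclear receptor", "Steroid h")]


def make_pwm_library(n_motifs: int = 10, length: int = 8, seed: int = 0,
                     sharpness: float = 20.0,
                     pseudocount: float = 1.0) -> list[PWMModel]:
    """Random sharp position frequency matrices with class/family labels.

    Each column is a Dirichlet draw concentrated on one base (*sharpness*
    pseudo-observations on the preferred base, 1 elsewhere, scaled to 100
    counts), giving well-determined consensus strings that the planting
    machinery can splice into sequence. Families cycle through a fixed
    TFclass-style list.
    """
    rng = stage_rng(seed, "pwm_library")
    library = []
    for i in range(n_motifs):
        counts = np.empty((4, length))
        for j in range(length):
            alpha = np.ones(4)
            alpha[int(rng.integers(4))] = sharpness
            counts[:, j] = np.round(rng.dirichlet(alpha) * 100)
        tf_class, family = _FAMILIES[i % len(_FAMILIES)]
        library.append(PWMModel(
            motif_id=f"SYN{i:03d}.1", name=f"synthetic_tf_{i}",
            counts=counts, pseudocount=pseudocount,
            tf_class=tf_class, family=family))
    return library
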