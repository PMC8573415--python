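"""End-to-end run of the core-response analysis on synthetic data.

One call wires every stage together on generated inputs with planted truth:
genome and annotation, counts with a planted DEG core, DE filtering and core
construction with its orthology projection, peak sets with planted shared
regions, the region core with genomic categories and super-enhancer overlap,
CDX-type site scanning with flank co-motif enrichment against a matched
random background, term enrichment, and cohort stratification with
validation enrichment. The returned :class:`PipelineResult` keeps the
intermediate objects plus a flat numeric summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .config import PipelineConfig
from . import deg_core, enrichment_validation, motif_analysis, peak_core
from . import synthetic_data
from .synthetic_data import SyntheticTruth


def region_sequences(genome: Mapping[str, str],
                     regions: pd.DataFrame) -> dict[str, str]:
    """Extract the sequence of each region (region_id -> sequence)."""
    return {row.region_id: genome[row.chrom][row.start:row.end]
            for row in regions.itertuples(index=False)}


@dataclass
class PipelineResult:
    truth: SyntheticTruth
    core: deg_core.CoreGeneSet
    core_orthologues: deg_core.CoreGeneSet
    region_core: peak_core.CoreRegionSet
    promoter_core_genes: list[str]
    cdx_hits: list
    enrichment: pd.DataFrame
    term_table: pd.DataFrame
    groups: enrichment_validation.CohortGroups
    cohort_table: pd.DataFrame
    direction: pd.DataFrame
    summary: dict = field(default_factory=dict)


def run_synthetic_pipeline(seed: int = 0,
                           config: PipelineConfig | None = None,
                           n_core_genes: int = 20,
                           n_total_genes: int = 2_000,
                           n_core_regions: int = 60,
                           n_samples: int = 100,
                           cofactor_rate: float = 0.5,
                           library_size: int = 8) -> PipelineResult:
    """Generate a full synthetic study and run every stage of the analysis.

    Defaults are desk-scale study conditions: 3 conditions x 3 replicates
    with 20 planted core genes among ~2,000, 60 planted shared regions among
    3 x ~160 peaks on a ~1 Mb genome, a co-factor planted in half of the
    CDX-site flanks, and a 100-sample cohort with a driver-expression
    gradient touching part of the gene core.
    """
    cfg = config or PipelineConfig()
    from . import load_cdx_pwm
    cdx = load_cdx_pwm(pseudocount=cfg.pwm_pseudocount)
    library = synthetic_data.make_pwm_library(
        n_motifs=library_size, seed=seed, pseudocount=cfg.pwm_pseudocount)
    cofactor = library[0]

    # ---- genes: counts -> DE tables -> core -> orthologues -------------
    genome, annotation = synthetic_data.make_genome(seed=seed)
    datasets, truth = synthetic_data.make_counts(
        annotation, n_core_genes=n_core_genes,
        n_total_genes=n_total_genes, seed=seed)
    conditions = list(datasets)
    tables = synthetic_data.de_tables_from_counts(
        datasets, flip_orientation=(conditions[-1],))
    filtered = [deg_core.filter_de(t, cfg.lfc_threshold, cfg.padj_threshold)
                for t in tables]
    core = deg_core.build_core(filtered)
    orthology = deg_core.OrthologyMap(
        synthetic_data.make_orthology(
            sorted(set().union(*(t.gene_ids for t in tables))), seed=seed))
    core_orth = deg_core.map_orthologues(
        core, orthology, cfg.orthology_min_confidence,
        cfg.orthology_min_homology_pct)

    # ---- regions: peaks -> core -> categories -> super-enhancers -------
    planted_genes = sorted(truth.planted_core_genes)
    promoter_gene_ids = planted_genes[:5]
    genome, collections, truth = synthetic_data.make_peaks(
        annotation, genome, cdx, n_core_regions=n_core_regions,
        planted_cofactor_rate=cofactor_rate, cofactor_pwm=cofactor,
        flank_bp=cfg.flank_bp, min_overlap_bp=cfg.min_overlap_bp,
        seed=seed, promoter_gene_ids=promoter_gene_ids,
        promoter_length_bp=cfg.promoter_length_bp, truth=truth)
    region_core = peak_core.core_regions(collections, cfg.min_overlap_bp)
    region_core = peak_core.annotate_regions(
        region_core, annotation, cfg.promoter_length_bp)
    se = synthetic_data.make_super_enhancers(genome, seed=seed)
    region_core = peak_core.super_enhancer_overlap(region_core, se)
    promoter_core_genes = peak_core.link_promoter_peaks_to_core_genes(
        region_core, core.gene_ids)

    # ---- motifs: CDX sites -> flank windows -> co-motif enrichment -----
    seqs = region_sequences(genome, region_core.df)
    bg_freqs = motif_analysis.estimate_background(seqs)
    cdx_hits = motif_analysis.scan(cdx.with_background(bg_freqs), seqs,
                                   cfg.pwm_relative_score_min)
    windows = motif_analysis.flank_windows(cdx_hits, seqs, cdx.length,
                                           cfg.flank_bp)
    background = motif_analysis.random_background(
        genome, windows, seed=synthetic_data.stage_rng(seed, "background"))
    enrichment = motif_analysis.motif_enrichment(
        library, windows, background, cfg.pwm_relative_score_min)

    # ---- validation: terms, cohort grouping, core enrichment ----------
    all_genes = annotation.gene_ids + [g for g in datasets[conditions[0]]
                                       ["control"].index
                                       if g not in set(annotation.gene_ids)]
    term_map = synthetic_data.make_term_map(all_genes, seed=seed)
    universe = enrichment_validation.GeneUniverse.from_term_map(term_map)
    term_table = enrichment_validation.term_enrichment(
        core.gene_ids, term_map, universe)

    linked_core = planted_genes[:15]
    driver = next(g for g in annotation.gene_ids if g not in planted_genes)
    counts, lengths, truth = synthetic_data.make_cohort(
        annotation, n_samples=n_samples, seed=seed, driver_gene=driver,
        linked_gene_ids=linked_core, truth=truth)
    expr = enrichment_validation.rpkm(counts, lengths)
    groups = enrichment_validation.quantile_groups(
        expr, driver, cfg.quantile_fraction)
    cohort_de = synthetic_data.cohort_de_table(
        counts, groups.high_samples, groups.low_samples, "cohort")
    cohort_filtered = deg_core.filter_de(cohort_de, 0.5, cfg.padj_threshold)
    cohort_universe = enrichment_validation.GeneUniverse(
        set(counts.index), provenance="cohort genes")
    cohort_table, direction = enrichment_validation.disease_overlap_report(
        core, [cohort_filtered], cohort_universe)

    recovered = core.gene_ids
    planted = set(truth.planted_core_genes)
    planted_regions_found = sum(
        any(row.chrom == c and row.start <= s and row.end >= e
            for row in region_core.df.itertuples(index=False))
        for c, s, e in truth.planted_core_regions)
    counts_by_cat = region_core.category_counts()
    summary = {
        "n_core_genes": len(core),
        "deg_core_recovery": (len(recovered & planted) / len(planted)
                              if planted else float("nan")),
        "deg_core_false_positives": len(recovered - planted),
        "n_core_orthologues": len(core_orth),
        "n_core_regions": len(region_core),
        "planted_region_recovery": (
            planted_regions_found / len(truth.planted_core_regions)
            if truth.planted_core_regions else float("nan")),
        "category_counts": counts_by_cat.to_dict(),
        "category_sum_equals_core": int(counts_by_cat.sum())
        == len(region_core),
        "super_enhancer_fraction": region_core.super_enhancer_fraction(),
        "n_promoter_core_genes": len(promoter_core_genes),
        "n_cdx_sites": len(cdx_hits),
        "regions_with_cdx_site": len({h.region_id for h in cdx_hits}),
        "cofactor_enrichment_p": float(
            enrichment.set_index("motif_id").loc[cofactor.motif_id, "p"]),
        "cohort_wilcoxon_p": groups.wilcoxon_p,
        "cohort_enrichment_p": float(cohort_table["p"].iloc[0]),
        "cohort_overlap_k": int(cohort_table["k"].iloc[0]),
    }
    return PipelineResult(
        truth=truth, core=core, core_orthologues=core_orth,
        region_core=region_core, promoter_core_genes=promoter_core_genes,
        cdx_hits=cdx_hits, enrichment=enrichment, term_table=term_table,
        groups=groups, cohort_table=cohort_table, direction=direction,
        summary=summary)
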