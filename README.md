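# coreresponse

Tools for asking whether a transcription factor exerts a *core* of common
molecular activities across the different contexts in which it acts — the
kind of question raised by CDX2, a homeoprotein that drives trophectoderm
formation, posterior body elongation and intestinal specification during
development and is deregulated in digestive cancers and leukemia.

Given per-condition differential-expression tables, per-condition ChIP-seq
peak sets, a genome with its annotation, a JASPAR-style motif library and
external gene lists / expression cohorts, the package builds and validates
two cores:

- **a core gene set** — the intersection of the genes passing
  |log2FC| > 2 and adjusted p < 0.05 in *every* condition, with a
  gene × condition direction matrix (membership does not require the
  direction to agree across conditions: a context-dependent response is
  part of the signal) and an orthology projection into a second species
  (pairs accepted on annotation confidence 1 *or* ≥ 30 % sequence
  homology);
- **a core region set** — the maximal genomic segments covered by a peak in
  every ChIP-seq collection, kept at ≥ 10 bp, each assigned exactly one
  genomic category (coding/non-coding gene or 2-kb promoter, else
  intergenic) with super-enhancer overlap flagged for intergenic regions.

Around these it implements the downstream statistics:

- **CDX-type site scanning** — position frequency matrices become log-odds
  PWMs (pseudocount 1, estimated background frequencies); both strands are
  scanned and positions with relative score
  `(s − s_min)/(s_max − s_min) ≥ 0.8` are called sites. The packaged
  CDX-type matrix has the published consensus T/C-A-T-A-A-A-T/G (YATAAAK).
- **co-motif enrichment** — ±50 bp windows around called CDX-type sites are
  tested per library motif with ZOOPS counting (a window counts once if it
  has ≥ 1 hit) against a background of equally many, length-matched
  sequences drawn uniformly from the genome; one-tailed Fisher exact p,
  BH-adjusted, plus a within-family Bonferroni p.
- **validation enrichment** — one-tailed Fisher over-representation of the
  core in external gene lists against a restricted universe (genes carrying
  ≥ 1 ontology term), `p = P(X ≥ k)` for the hypergeometric overlap
  `(k, m, n, N)`; generic per-term enrichment with BH adjustment.
- **cohort stratification** — RPKM normalisation
  (`count · 10⁹ / (length_bp · library_size)`), samples ranked by a driver
  gene ("CDX2-like"), upper/lower quantile groups of size
  `ceil(N × fraction)` (quartiles or deciles; 436 samples → deciles of 44,
  151 samples → quartiles of 38), separation confirmed by a two-sided
  rank-sum test.

A first-class `synthetic_data` module generates every input with planted,
known truth (genome, annotation, negative-binomial counts with a planted
signed DEG core, peak sets with guaranteed shared regions carrying exact
CDX consensus sites and planted co-factor sites in their flanks, orthology
and term tables, cohorts with a driver-expression gradient), so the whole
pipeline runs and is tested without any download.

## Worked example

Run the full synthetic study end to end:

```sh
coreresponse run --seed 1
```

```json
{
  "n_core_genes": 20,
  "deg_core_recovery": 1.0,
  "deg_core_false_positives": 0,
  "n_core_orthologues": 20,
  "n_core_regions": 60,
  "planted_region_recovery": 1.0,
  "category_counts": {
    "coding_promoter": 8,
    "coding_gene": 7,
    "noncoding_promoter": 1,
    "noncoding_gene": 1,
    "intergenic": 43
  },
  "category_sum_equals_core": true,
  "super_enhancer_fraction": 0.09302325581395349,
  "n_promoter_core_genes": 6,
  "n_cdx_sites": 277,
  "regions_with_cdx_site": 60,
  "cofactor_enrichment_p": 0.00029746184876230876,
  "cohort_wilcoxon_p": 1.4156562248495537e-09,
  "cohort_enrichment_p": 0.00025213074122292845,
  "cohort_overlap_k": 17
}
```

Reading this: all 20 planted core genes were recovered with no false
positive, and all 20 survived the orthology projection. The 60 region core
equals the planted shared regions; the five category counts
(8+7+1+1+43) sum to 60 — the partition identity. Every core region carries
at least one called CDX-type site (277 sites in total; the planted
consensus plus chance matches of the 7-bp motif). The co-factor planted in
half of the site flanks is enriched against the matched random background
(p ≈ 3·10⁻⁴), the cohort's driver-based decile/quartile grouping separates
driver expression (rank-sum p ≈ 10⁻⁹), and 17 of the 20 core genes overlap
the cohort's DE list (Fisher p ≈ 2.5·10⁻⁴).

The same stages are available as a library
(`coreresponse.deg_core.build_core`, `coreresponse.peak_core.core_regions`,
`coreresponse.motif_analysis.motif_enrichment`, …) and as file-based CLI
subcommands (`simulate`, `io validate`, `deg-core`, `peak-core`, `motifs`,
`validate`).

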