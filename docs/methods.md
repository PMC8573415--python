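# Methods

## The question and the two cores

The package operationalises "does a transcription factor exert a common
core of activities across its contexts?" as two intersection constructions
plus the statistics needed to validate them.

**Gene core.** Each condition contributes a differential-expression table
(gene, log2 fold-change, adjusted p). Replicate-based tables are produced
upstream by a count-model tool and consumed as-is: the package deliberately
does not re-implement negative-binomial DE testing. Records pass the filter
when |log2FC| > `lfc_threshold` *and* padj < `padj_threshold`; both
inequalities are strict, so boundary values (log2FC exactly 2, padj exactly
0.05) are excluded. The core is the plain set intersection of the filtered
gene sets. Membership does **not** require the direction of change to agree
across conditions; the direction matrix (+1/−1 per gene and condition)
carries that information instead, after orientation normalisation: a table
declared `factor_low_vs_high` has its signs negated so every column reads
factor-expressing vs non-expressing. Every correlation-map rendering uses
the core's canonical (sorted) gene order so maps stay comparable.

**Replicate-free conditions.** When a condition has no replicates there is
no p-value; differential expression is then the per-gene delta of log2
expression values between experiment and control, thresholded at
`delta_threshold` (strict). The package computes the delta on
log2-transformed, library-size-normalised expression, so a threshold of 2
means a 4-fold change — commensurate with the |log2FC| > 2 filter used for
replicate-based tables. The source analyses state only "gene expression
values"; this is one defensible reading, flagged here rather than asserted.
Two replicate-free datasets are combined by *sign-consistent consensus*:
genes passing the delta threshold in both with the same sign, the combined
effect being the mean delta. A gene moving oppositely in two nominally
replicate datasets is not a reproducible change, hence the sign
requirement (the consensus operation is the only place sign agreement is
demanded).

**Orthology projection.** A cross-species pair qualifies if annotation
confidence ≥ `orthology_min_confidence` (default 1, "high") **or** sequence
homology ≥ `orthology_min_homology_pct` (default 30 %) — a disjunction, so
a confidence-1 pair with 10 % homology qualifies. One-to-many mappings
expand to one row per target with directions inherited; if two source genes
reach the same target, the first in canonical order wins (documented
tie-break; collisions are rare in practice and deterministic here).

**Region core.** Peaks are merged within each collection first
(overlapping or bookended intervals fuse) so fragmented peak calls cannot
split a shared region. A core region is then a maximal genomic segment
simultaneously covered in *every* collection — the common-coverage
intersection, computed by a sweep-line over interval endpoints — kept when
its length ≥ `min_overlap_bp` (default 10 bp). The intersection extent is
the primary coordinate set; the union extent of the contributing peaks is
emitted as auxiliary columns, since from the construction alone one cannot
tell which extent a downstream consumer wants. Contributing peak names per
collection are recorded.

**Annotation categories.** Promoters are the `promoter_length_bp` (default
2000 bp) segment immediately upstream of the canonical TSS, strand-aware
and clipped at chromosome bounds; the gene span itself is the annotation's
gene feature (isoforms are not modelled). Each core region gets exactly one
category by fixed precedence: coding_promoter > coding_gene >
noncoding_promoter > noncoding_gene > intergenic. Promoters rank first
because promoter peaks are the gene-linked class of interest; since all
overlapping gene and promoter ids are also recorded per region, any
alternative precedence is recomputable from the output. The category counts
always sum to the core size — a structural identity asserted on every run.
Intergenic regions additionally record the nearest gene on each side, and
are flagged when they overlap a super-enhancer interval by ≥ 1 bp (the
overlap criterion is not specified by the upstream catalogue; 1 bp is the
permissive choice and is configurable at the BED level).

## Motif machinery

A position frequency matrix with pseudocount `pwm_pseudocount` (default
1.0 per cell) and background frequencies `b` gives column probabilities
`p_ij` and log-odds `log2(p_ij / b_i)`. Background frequencies are
estimated from the scanned sequence set with a floor of 0.01 per base
(renormalised); uniform background is the fallback. A site call at offset
`o` and strand `s` requires relative score
`(score − s_min)/(s_max − s_min) ≥ pwm_relative_score_min` (default 0.8),
where `s_max`/`s_min` are the column-wise max/min sums — the standard
fraction-of-maximum calling rule when no p-value calibration is wanted.
Both strands are scanned by scoring with the reverse-complemented matrix,
so offsets always refer to the forward strand; windows containing N score
−∞. The scanner is exact: it must (and in tests does) agree position-for-
position with naive per-offset rescoring, with no pruning heuristics.

**Co-motif enrichment** replaces an external known-motif tool with an
implemented, oracle-verifiable statistic. Foreground = the ±`flank_bp`
(default 50 bp) windows around called CDX-type sites, clipped at region
bounds. Background = the same number of sequences with the identical
length multiset, drawn uniformly over all valid start positions of the
genome (chromosomes weighted by valid-start counts; > 50 % N sequences are
redrawn, bounded retries). Counting is ZOOPS — a window contributes once if
it has ≥ 1 hit on either strand — so overlapping-hit merging decisions
cannot affect the statistic. The 2×2 table (windows with/without hit,
foreground vs background) is tested one-tailed (foreground greater) with
the Fisher exact test; the odds ratio gets a Haldane +0.5 correction when
any cell is zero; BH adjustment runs across the library, and a family-level
p (min member p × family size, capped at 1) summarises TFclass-style
families. Raw p drives reporting counts, with adjusted p alongside.

**IUPAC consensus** of a matrix: per column, the IUPAC code of the bases
with post-pseudocount frequency ≥ 0.25. The packaged CDX-type matrix is a
*synthetic* frequency matrix constructed so this consensus is YATAAAK
(T/C-A-T-A-A-A-T/G), the published CDX-binding consensus; the curated
database entry itself is not redistributed.

## Validation statistics

Core-in-list enrichment is the over-representation tail of the
hypergeometric distribution, P(X ≥ k) for overlap k between an m-gene list
and an n-gene core in an N-gene universe, both sets intersected with the
universe first. The universe is restricted — by default the genes carrying
≥ 1 ontology term — because an inflated universe inflates significance;
degenerate cases (core or list filling the universe) are flagged. Per-term
enrichment applies the same test per term with BH adjustment.

Cohorts are normalised to RPKM (`count × 10⁹ / (length_bp × library)`,
library sizes defaulting to column sums), ranked by the driver gene, and
split into upper/lower groups of `ceil(N × fraction)` samples
(`quantile_fraction`, default 0.25; deciles use 0.10). Ties in driver
expression break by sample id so grouping is deterministic and invariant
to column order. The reported two-sided rank-sum p on driver expression
between the groups is a *grouping confirmation* (the groups were selected
on that variable, so it is biased by construction and should not be read
as an independent test). Group DE between high and low samples is again
consumed from upstream; the package then reports per-list Fisher
enrichment and the core-ordered direction column.

## What the synthetic generator emulates — and what it does not

`synthetic_data` reproduces the *statistical structure* of the real
inputs: multiple conditions sharing a planted signed gene core among
background genes, peak sets guaranteed to share planted regions, exact
consensus motifs (CDX-type in regions, co-factors in flanks), orthology
and ontology side tables, and cohorts with a driver gradient. Defaults,
chosen once as realistic desk-scale bulk RNA-seq / ChIP-seq conditions:

- counts: negative binomial with Var = μ + φμ², dispersion φ = 0.02
  (well-replicated bulk data), background means log-normal (median ≈ 150,
  floor 10), planted genes uniform 200–1000 so the planted |log2FC| = 3
  effect is recoverable above the threshold of 2 (a generator contract:
  planted signal must be above the calling threshold to be recoverable at
  all); per-condition signs flip with probability 0.3 to emulate the
  context-dependent direction changes seen in real cores.
- DE tables for synthetic runs come from a Wald test on the log2 ratio of
  group means whose standard error uses the generator's *own true*
  dispersion, BH-adjusted. This is a stand-in for the upstream count-model
  tool's output schema, not a general DE method: with estimated rather
  than known dispersion its error control would be optimistic at 3
  replicates.
- peaks: planted regions of 20 bp inside ~300 bp peaks with border jitter
  up to 40 bp constructed to always contain the planted region (the
  guaranteed ≥ 10 bp three-way overlap is asserted, not hoped for);
  private peaks are rejection-sampled so they never co-occur across
  conditions, making the planted set the exact expected core. Planted
  motifs are written as exact consensus strings, not PWM samples, so the
  scanner is guaranteed to call them at the 0.8 relative-score default.
- cohorts: a latent uniform(−1, 1) per-sample gradient moves the driver's
  log2 mean by `gradient_strength` (default 2 log2 units across the
  gradient) and each linked gene by ±0.8 of that; all other genes are
  independent.
- one run-level seed is forked per stage through a label hash
  (`stage_rng`), so adding or re-ordering stages never perturbs another
  stage's stream.

Passing tests on these inputs show the *machinery* is correct (exact
oracle agreement, exact planted recovery, calibrated type-I error). They
do not show that real data meet the assumptions: real ChIP-seq peaks have
correlated positions and fragment-pileup shapes, real dispersions are
gene-dependent, real motif instances are degenerate PWM samples rather
than consensus strings, and real orthology is far messier than the
generated table. Scale is also reduced (tens of genes and regions per
study, ~1 Mb genomes) to keep the default test run fast; sizes are
parameters, not limits.

## Numerical and degenerate-input choices

- Thresholds strict (`>`, `<`) everywhere; orthology homology uses ≥ 30.
- Fully degenerate PWM (max score = min score): relative score defined
  as 1.0 for valid windows.
- Fisher p from scipy's exact implementation; tests pin it to an
  independent integer tail-sum oracle within 1e-10.
- Haldane +0.5 on all cells only when some cell is zero, for odds ratios.
- Group size `ceil(N × fraction)`; this reproduces the reference sizes
  44 of 436 (deciles) and 38 of 151 (quartiles). A "quartiles n = 35 of
  272" grouping reported for one public cohort is arithmetically
  inconsistent with any simple rule and is not modelled; the fraction is
  freely configurable instead.
- The GTF reader is the only ±1 coordinate shift in the package;
  everything internal is 0-based half-open. Chromosome names are never
  silently normalised; a rename map in the config is the explicit hook.
- Empty inputs: empty annotation and empty peak collections warn and
  propagate empty results; empty gene sets give empty enrichment tables;
  mismatched gene universes and overlapping cohort groups raise.

## Known limitations

- No PWM p-value calibration (dynamic programming over the score
  distribution); the relative-score rule is the calling criterion.
- DE testing, peak calling and read processing are out of scope by
  design; their outputs are inputs here.
- The enrichment unit is the window/region (ZOOPS), not total site
  counts; with very long windows the two diverge.
- Survival analysis and database-specific term-enrichment variants
  (EASE-style corrections) are not implemented; the generic Fisher/BH
  path stands in.
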