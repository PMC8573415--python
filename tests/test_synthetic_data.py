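"""Determinism, planted-signal calibration and truth containment of the
synthetic generators."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from coreresponse import deg_core as dc
from coreresponse import synthetic_data as sd
from coreresponse.synthetic_data import stage_rng


class TestStageRng:
    def test_same_label_reproduces_the_stream(self):
        a = stage_rng(7, "peaks").integers(0, 10**9, size=5)
        b = stage_rng(7, "peaks").integers(0, 10**9, size=5)
        assert (a == b).all()

    def test_labels_fork_independent_streams(self):
        a = stage_rng(7, "peaks").integers(0, 10**9, size=5)
        b = stage_rng(7, "counts").integers(0, 10**9, size=5)
        assert not (a == b).all()


class TestMakeGenome:
    def test_deterministic_under_fixed_seed(self):
        g1, a1 = sd.make_genome(seed=3, n_chrom=1, chrom_len=60_000,
                                n_genes=3)
        g2, a2 = sd.make_genome(seed=3, n_chrom=1, chrom_len=60_000,
                                n_genes=3)
        assert g1 == g2 and a1.genes == a2.genes
        g3, _ = sd.make_genome(seed=4, n_chrom=1, chrom_len=60_000,
                               n_genes=3)
        assert g3 != g1

    def test_gc_one_gives_only_g_and_c(self):
        g, _ = sd.make_genome(seed=0, n_chrom=1, chrom_len=20_000, gc=1.0,
                              n_genes=2)
        assert set(g["chr1"]) <= {"G", "C"}

    def test_gc_fraction_concentrates_at_requested_value(self):
        # binomial concentration: sd of the GC fraction at 1 Mb ~ 0.0005
        g, _ = sd.make_genome(seed=1, n_chrom=1, chrom_len=1_000_000,
                              gc=0.4, n_genes=10)
        seq = g["chr1"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert 0.39 < gc < 0.41

    def test_genes_do_not_overlap_and_fit_chromosomes(self):
        _, ann = sd.make_genome(seed=2, n_genes=40)
        by_chrom = {}
        for g in ann.genes:
            by_chrom.setdefault(g.chrom, []).append((g.start, g.end))
        for spans in by_chrom.values():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 <= s2

    def test_unplaceable_request_suggests_longer_chromosomes(self):
        with pytest.raises(ValueError, match="longer chromosomes"):
            sd.make_genome(seed=0, n_chrom=1, chrom_len=25_000, n_genes=500)


@pytest.fixture(scope="module")
def annotation():
    return sd.make_genome(seed=0)[1]


@pytest.fixture(scope="module")
def base():
    from coreresponse import load_cdx_pwm
    genome, ann = sd.make_genome(seed=6)
    return genome, ann, load_cdx_pwm()


class TestMakeCounts:
    def test_deterministic_under_fixed_seed(self, annotation):
        d1, _ = sd.make_counts(annotation, seed=5)
        d2, _ = sd.make_counts(annotation, seed=5)
        for cond in d1:
            pd.testing.assert_frame_equal(d1[cond]["control"],
                                          d2[cond]["control"])

    def test_zero_effect_plants_no_differential_signal(self, annotation):
        datasets, _ = sd.make_counts(annotation, effect_log2fc=0.0, seed=1)
        tables = sd.de_tables_from_counts(datasets)
        filtered = [dc.filter_de(t) for t in tables]
        assert len(dc.build_core(filtered)) == 0

    def test_planted_mean_ratio_matches_effect(self, annotation):
        # sample-mean oracle: effect 3 with sign +1 means ~8x the control
        datasets, truth = sd.make_counts(
            annotation, n_core_genes=10, n_reps=3000, effect_log2fc=3.0,
            sign_flip_rate=0.0, seed=2)
        cond = next(iter(datasets))
        ctrl = datasets[cond]["control"].mean(axis=1)
        trt = datasets[cond]["treatment"].mean(axis=1)
        for gene, signs in truth.planted_core_genes.items():
            ratio = trt[gene] / ctrl[gene]
            expect = 8.0 if signs[cond] == 1 else 0.125
            assert ratio == pytest.approx(expect, rel=0.1)

    def test_single_replicate_supported(self, annotation):
        datasets, _ = sd.make_counts(annotation, n_reps=1, seed=3)
        cond = next(iter(datasets))
        assert datasets[cond]["control"].shape[1] == 1

    def test_truth_signs_recovered_through_the_pipeline(self, annotation):
        datasets, truth = sd.make_counts(annotation, n_core_genes=15,
                                         n_total_genes=500, seed=4)
        conds = list(datasets)
        tables = sd.de_tables_from_counts(datasets,
                                          flip_orientation=(conds[-1],))
        core = dc.build_core([dc.filter_de(t) for t in tables])
        assert core.gene_ids == set(truth.planted_core_genes)
        for gene, signs in truth.planted_core_genes.items():
            for cond in conds:
                assert core.direction_matrix.loc[gene, cond] == signs[cond]


class TestMakePeaks:
    def test_zero_jitter_no_private_gives_identical_collections(self, base):
        genome, ann, cdx = base
        _, colls, _ = sd.make_peaks(ann, genome, cdx, n_core_regions=10,
                                    n_private_peaks=0, jitter_bp=0,
                                    planted_cofactor_rate=0.0, seed=1)
        ref = colls[0].df[["chrom", "start", "end"]]
        for coll in colls[1:]:
            pd.testing.assert_frame_equal(
                coll.df[["chrom", "start", "end"]], ref)

    def test_planted_regions_are_contained_in_every_condition(self, base):
        genome, ann, cdx = base
        _, colls, truth = sd.make_peaks(ann, genome, cdx, n_core_regions=15,
                                        planted_cofactor_rate=0.0, seed=2)
        for chrom, s, e in truth.planted_core_regions:
            for coll in colls:
                sub = coll.df[(coll.df["chrom"] == chrom)
                              & (coll.df["start"] <= s)
                              & (coll.df["end"] >= e)]
                assert len(sub) >= 1

    def test_cdx_consensus_written_at_recorded_positions(self, base):
        genome, ann, cdx = base
        edited, _, truth = sd.make_peaks(ann, genome, cdx, n_core_regions=8,
                                         planted_cofactor_rate=0.0, seed=3)
        site = sd.consensus_string(cdx)
        for idx, offset, strand in truth.planted_motif_positions:
            chrom, start, _ = truth.planted_core_regions[idx]
            assert edited[chrom][start + offset:
                                 start + offset + len(site)] == site

    def test_zero_cofactor_rate_leaves_flanks_at_background_frequency(
            self, base):
        genome, ann, cdx = base
        library = sd.make_pwm_library(seed=0)
        cof = sd.consensus_string(library[0])
        edited, _, truth = sd.make_peaks(ann, genome, cdx,
                                         n_core_regions=40,
                                         planted_cofactor_rate=0.0, seed=4)
        count = 0
        window = 0
        for idx, offset, _ in truth.planted_motif_positions:
            chrom, start, _ = truth.planted_core_regions[idx]
            site = start + offset
            flank = edited[chrom][max(0, site - 50):site + 7 + 50]
            count += flank.count(cof)
            window += len(flank)
        # expected-occurrence oracle: ~window x p(string) on both strands
        p_string = (0.29 ** cof.count("A") * 0.29 ** cof.count("T")
                    * 0.21 ** cof.count("C") * 0.21 ** cof.count("G"))
        expected = 2 * window * p_string
        bound = expected + 3 * np.sqrt(max(expected, 1.0))
        assert count <= bound

    def test_cofactor_rate_half_plants_half_the_regions(self, base):
        genome, ann, cdx = base
        library = sd.make_pwm_library(seed=0)
        _, _, truth = sd.make_peaks(ann, genome, cdx, n_core_regions=20,
                                    planted_cofactor_rate=0.5,
                                    cofactor_pwm=library[0], seed=5)
        assert len(truth.planted_cofactor_regions) == 10


class TestMakeCohort:
    def test_deterministic_under_fixed_seed(self, annotation):
        c1, l1, _ = sd.make_cohort(annotation, seed=8)
        c2, l2, _ = sd.make_cohort(annotation, seed=8)
        pd.testing.assert_frame_equal(c1, c2)
        pd.testing.assert_series_equal(l1, l2)

    def test_zero_gradient_driver_independent_of_gradient(self, annotation):
        # driver expression between the latent-gradient extremes should be
        # indistinguishable in >= 90 % of runs when nothing was planted
        nonsig = 0
        runs = 100
        for seed in range(runs):
            counts, _, truth = sd.make_cohort(
                annotation, n_samples=40, gradient_strength=0.0,
                n_linked_genes=0, seed=seed)
            order = truth.cohort_gradient.sort_values().index
            low, high = order[:10], order[-10:]
            driver = counts.loc[truth.driver_gene]
            p = stats.mannwhitneyu(driver[high], driver[low],
                                   alternative="two-sided").pvalue
            if p >= 0.05:
                nonsig += 1
        assert nonsig >= 0.9 * runs

    def test_strong_gradient_separates_driver(self, annotation):
        from coreresponse.enrichment_validation import quantile_groups, rpkm
        counts, lengths, truth = sd.make_cohort(
            annotation, n_samples=60, gradient_strength=2.0, seed=9)
        groups = quantile_groups(rpkm(counts, lengths), truth.driver_gene,
                                 0.25)
        assert groups.wilcoxon_p < 0.01

    def test_linked_genes_follow_recorded_signs(self, annotation):
        counts, _, truth = sd.make_cohort(
            annotation, n_samples=200, gradient_strength=3.0,
            n_linked_genes=10, seed=10)
        log_expr = np.log2(counts + 1.0)
        driver = log_expr.loc[truth.driver_gene]
        for gene, sign in truth.linked_genes.items():
            r = stats.pearsonr(driver, log_expr.loc[gene]).statistic
            assert np.sign(r) == sign and abs(r) > 0.3

    def test_too_few_samples_rejected(self, annotation):
        with pytest.raises(ValueError, match="at least 8"):
            sd.make_cohort(annotation, n_samples=4)
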