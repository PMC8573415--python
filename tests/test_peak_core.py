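"""Region-core intersection, promoter geometry and genomic categorisation."""

import numpy as np
import pandas as pd
import pytest

from coreresponse import peak_core as pc
from coreresponse.io_formats import (GeneRecord, GenomeAnnotation,
                                     PeakCollection)
from tests.conftest import per_base_core_oracle, random_collection


def collection(label, intervals):
    return PeakCollection(label=label, df=pd.DataFrame(
        [(c, s, e, f"{label}_{i}") for i, (c, s, e) in enumerate(intervals)],
        columns=["chrom", "start", "end", "name"]))


class TestCoreRegions:
    def test_identical_collections_yield_the_merged_peaks(self):
        iv = [("chr1", 100, 300), ("chr1", 250, 500), ("chr1", 900, 1000)]
        colls = [collection(f"c{i}", iv) for i in range(3)]
        core = pc.core_regions(colls, 10)
        got = list(zip(core.df["chrom"], core.df["start"], core.df["end"]))
        assert got == [("chr1", 100, 500), ("chr1", 900, 1000)]

    def test_common_segment_below_min_overlap_excluded(self):
        colls = [collection("a", [("chr1", 0, 100)]),
                 collection("b", [("chr1", 95, 200)]),
                 collection("c", [("chr1", 90, 200)])]
        # three-way common segment is [95, 100): 5 bp < 10 bp
        assert len(pc.core_regions(colls, 10)) == 0
        assert len(pc.core_regions(colls, 5)) == 1

    def test_matches_per_base_coverage_oracle_over_seeds(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            colls = [random_collection(rng, f"c{i}", n_peaks=200,
                                       genome_len=100_000)
                     for i in range(3)]
            core = pc.core_regions(colls, 10)
            got = list(zip(core.df["chrom"], core.df["start"],
                           core.df["end"]))
            assert got == per_base_core_oracle(colls, 100_000, 10)

    def test_contributing_peaks_recorded_per_collection(self):
        colls = [collection("a", [("chr1", 0, 100)]),
                 collection("b", [("chr1", 50, 150)]),
                 collection("c", [("chr1", 40, 160)])]
        core = pc.core_regions(colls, 10)
        row = core.df.iloc[0]
        assert (row["peaks_a"], row["peaks_b"]) == ("a_0", "b_0")
        assert (row["union_start"], row["union_end"]) == (0, 160)

    def test_empty_collection_gives_empty_core_with_warning(self, caplog):
        colls = [collection("a", [("chr1", 0, 100)]),
                 PeakCollection("b", pd.DataFrame(
                     columns=["chrom", "start", "end", "name"]))]
        with caplog.at_level("WARNING"):
            core = pc.core_regions(colls, 10)
        assert len(core) == 0
        assert any("empty" in r.message for r in caplog.records)

    def test_idempotent_on_own_output(self, rng):
        colls = [random_collection(rng, f"c{i}", n_peaks=150)
                 for i in range(3)]
        core = pc.core_regions(colls, 10)
        as_coll = [PeakCollection(f"core{i}", core.df.assign(
            name=core.df["region_id"])[["chrom", "start", "end", "name"]])
            for i in range(2)]
        again = pc.core_regions(as_coll, 10)
        assert (list(zip(again.df["chrom"], again.df["start"],
                         again.df["end"]))
                == list(zip(core.df["chrom"], core.df["start"],
                            core.df["end"])))

    def test_adding_a_collection_never_grows_the_core(self, rng):
        colls = [random_collection(rng, f"c{i}", n_peaks=200)
                 for i in range(4)]
        small = pc.core_regions(colls[:3], 10)
        large = pc.core_regions(colls, 10)
        small_set = set(zip(small.df["chrom"], small.df["start"],
                            small.df["end"]))
        # every 4-way region is contained in some 3-way region
        for chrom, s, e in zip(large.df["chrom"], large.df["start"],
                               large.df["end"]):
            assert any(c == chrom and cs <= s and ce >= e
                       for c, cs, ce in small_set)

    def test_order_invariant(self, rng):
        colls = [random_collection(rng, f"c{i}", n_peaks=150)
                 for i in range(3)]
        a = pc.core_regions(colls, 10)
        b = pc.core_regions(colls[::-1], 10)
        assert (a.df[["chrom", "start", "end"]]
                .equals(b.df[["chrom", "start", "end"]]))


class TestPromoters:
    def test_plus_strand_upstream_segment(self, small_annotation):
        proms = pc.promoters(small_annotation, 2000).set_index("gene_id")
        assert (proms.loc["gA", "start"], proms.loc["gA", "end"]) \
            == (3000, 5000)

    def test_minus_strand_downstream_of_end(self):
        ann = GenomeAnnotation(
            [GeneRecord("g", "chr1", 1000, 2000, "-", "protein_coding")])
        proms = pc.promoters(ann, 2000)
        assert (proms.iloc[0]["start"], proms.iloc[0]["end"]) == (2000, 4000)

    def test_truncated_at_chromosome_start(self):
        ann = GenomeAnnotation(
            [GeneRecord("g", "chr1", 500, 900, "+", "protein_coding")])
        proms = pc.promoters(ann, 2000)
        assert (proms.iloc[0]["start"], proms.iloc[0]["end"]) == (0, 500)

    def test_truncated_at_chromosome_end(self):
        ann = GenomeAnnotation(
            [GeneRecord("g", "chr1", 100, 1000, "-", "protein_coding")],
            chrom_lengths={"chr1": 1500})
        proms = pc.promoters(ann, 2000)
        assert (proms.iloc[0]["start"], proms.iloc[0]["end"]) == (1000, 1500)


def _annotate(core_intervals, annotation, promoter_length=2000):
    core = pc.core_regions(
        [collection("a", core_intervals), collection("b", core_intervals)],
        min_overlap_bp=1)
    return pc.annotate_regions(core, annotation, promoter_length)


class TestAnnotateRegions:
    def test_region_in_coding_gene_body(self, small_annotation):
        out = _annotate([("chr1", 6000, 6100)], small_annotation)
        assert out.df["category"].tolist() == ["coding_gene"]

    def test_region_overlapping_nothing_is_intergenic(self, small_annotation):
        out = _annotate([("chr1", 25000, 25100)], small_annotation)
        assert out.df["category"].tolist() == ["intergenic"]

    def test_promoter_takes_precedence_over_gene_body(self, small_annotation):
        # spans the gA promoter/gene boundary: promoter wins
        out = _annotate([("chr1", 4900, 5100)], small_annotation)
        assert out.df["category"].tolist() == ["coding_promoter"]

    def test_intergenic_records_flanking_genes(self, small_annotation):
        out = _annotate([("chr1", 9000, 9100)], small_annotation)
        row = out.df.iloc[0]
        assert row["upstream_gene"] == "gA"
        assert row["downstream_gene"] == "gB"

    def test_random_regions_match_precedence_oracle(self, rng,
                                                    small_annotation):
        intervals = [("chr" + str(rng.integers(1, 3)),) + tuple(sorted(
            rng.integers(0, 24_000, size=2))) for _ in range(1000)]
        intervals = [(c, s, e if e > s else s + 1)
                     for c, s, e in intervals]
        out = _annotate(intervals, small_annotation)
        proms = pc.promoters(small_annotation, 2000)
        genes = small_annotation.to_frame()

        def overlap(df, c, s, e):
            hit = df[(df["chrom"] == c) & (df["start"] < e)
                     & (df["end"] > s)]
            return hit

        for row in out.df.itertuples(index=False):
            g = overlap(genes, row.chrom, row.start, row.end)
            p = overlap(proms, row.chrom, row.start, row.end)
            if len(p[p["biotype"] == "protein_coding"]):
                expect = "coding_promoter"
            elif len(g[g["biotype"] == "protein_coding"]):
                expect = "coding_gene"
            elif len(p):
                expect = "noncoding_promoter"
            elif len(g):
                expect = "noncoding_gene"
            else:
                expect = "intergenic"
            assert row.category == expect

    def test_category_counts_partition_the_core(self, rng, small_annotation):
        intervals = sorted({("chr1", int(s), int(s) + 200)
                            for s in rng.integers(0, 28_000, size=300)})
        out = _annotate(intervals, small_annotation)
        assert out.category_counts().sum() == len(out)


class TestSuperEnhancers:
    def _core(self, small_annotation):
        return _annotate([("chr1", 9000, 9100), ("chr1", 25000, 25100),
                          ("chr1", 6000, 6100)], small_annotation)

    def test_empty_catalogue_flags_nothing(self, small_annotation):
        core = self._core(small_annotation)
        se = collection("se", [("chr2", 0, 10)])
        out = pc.super_enhancer_overlap(core, se)
        inter = out.df[out.df["category"] == "intergenic"]
        assert not inter["super_enhancer"].any()

    def test_exact_interval_match_is_flagged(self, small_annotation):
        core = self._core(small_annotation)
        se = collection("se", [("chr1", 9000, 9100)])
        out = pc.super_enhancer_overlap(core, se)
        flagged = out.df[(out.df["category"] == "intergenic")
                         & out.df["super_enhancer"].fillna(False)]
        assert list(flagged["start"]) == [9000]

    def test_flags_match_any_overlap_oracle(self, rng, small_annotation):
        intervals = sorted({("chr1", int(s), int(s) + 150)
                            for s in rng.integers(0, 28_000, size=100)})
        core = _annotate(intervals, small_annotation)
        se_iv = [("chr1", int(s), int(s) + 400)
                 for s in rng.integers(0, 28_000, size=20)]
        out = pc.super_enhancer_overlap(core, collection("se", se_iv))
        for row in out.df.itertuples(index=False):
            if row.category != "intergenic":
                assert row.super_enhancer is pd.NA
            else:
                expect = any(s < row.end and e > row.start
                             for _, s, e in se_iv)
                assert bool(row.super_enhancer) == expect

    def test_fraction_reported_over_intergenic_only(self, small_annotation):
        core = self._core(small_annotation)
        se = collection("se", [("chr1", 9000, 9100)])
        out = pc.super_enhancer_overlap(core, se)
        assert out.super_enhancer_fraction() == pytest.approx(0.5)


class TestPromoterCoreLink:
    def test_disjoint_gene_sets_give_empty_link(self, small_annotation):
        core = _annotate([("chr1", 4900, 5100)], small_annotation)  # gA prom
        assert pc.link_promoter_peaks_to_core_genes(core, {"gB"}) == []

    def test_all_gene_core_returns_all_promoter_hosts(self, small_annotation):
        core = _annotate([("chr1", 4900, 5100), ("chr1", 14500, 14600)],
                         small_annotation)
        all_genes = set(small_annotation.gene_ids)
        assert pc.link_promoter_peaks_to_core_genes(core, all_genes) \
            == ["gA", "gB"]

    def test_recovers_exactly_the_planted_promoter_genes(self):
        from coreresponse import synthetic_data as sd
        from coreresponse import load_cdx_pwm
        genome, ann = sd.make_genome(seed=5)
        datasets, truth = sd.make_counts(ann, n_core_genes=10, seed=5)
        planted = sorted(truth.planted_core_genes)[:5]
        genome, colls, truth = sd.make_peaks(
            ann, genome, load_cdx_pwm(), n_core_regions=20,
            planted_cofactor_rate=0.0, seed=5, promoter_gene_ids=planted,
            truth=truth)
        core = pc.core_regions(colls, 10)
        core = pc.annotate_regions(core, ann, 2000)
        linked = pc.link_promoter_peaks_to_core_genes(
            core, set(truth.planted_core_genes))
        assert set(planted) <= set(linked)
        # any extra links must be planted genes whose promoter was hit by
        # chance by another planted region
        assert set(linked) <= set(truth.planted_core_genes)
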