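"""Peak-to-gene assignment, ranked lists, GSEA, annotation, recovery."""

import numpy as np
import pandas as pd
import pytest

from regland.diffacc import DifferentialRecord
from regland.genelink import (
    GeneModel,
    assign_peaks,
    annotate_locations,
    collapse_probes,
    enhancer_recovery,
    gsea,
    load_gene_models,
    ranked_list,
)
from regland.intervals import GenomicInterval


def rec(region, lfc, p=0.01, padj=None):
    return DifferentialRecord(region, 100.0, lfc, p, padj if padj is not None else p)


@pytest.fixture
def toy_genes():
    # gene A: + strand, TSS 10_000, two exons with one intron [10_500, 12_000)
    # gene B: - strand, TSS 24_999 (end-1), one intron [21_000, 24_000)
    a = GeneModel("geneA", "chr1", 10_000, 13_000, "+",
                  exons=((10_000, 10_500), (12_000, 13_000)))
    b = GeneModel("geneB", "chr1", 20_000, 25_000, "-",
                  exons=((20_000, 21_000), (24_000, 25_000)))
    return [a, b]


class TestGeneModel:
    def test_tss_is_strand_aware(self, toy_genes):
        assert toy_genes[0].tss == 10_000
        assert toy_genes[1].tss == 24_999

    def test_introns_derived_from_exons(self, toy_genes):
        assert toy_genes[0].introns == [(10_500, 12_000)]
        assert toy_genes[1].introns == [(21_000, 24_000)]

    def test_upstream_window_excludes_gene_body(self, toy_genes):
        assert toy_genes[0].upstream_window(5000) == (5_000, 10_000)
        assert toy_genes[1].upstream_window(5000) == (25_000, 30_000)

    def test_gff3_round_trip(self, tmp_path):
        gff = tmp_path / "g.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr1\tsrc\tgene\t1001\t4000\t.\t+\t.\tID=g1\n"
            "chr1\tsrc\texon\t1001\t1500\t.\t+\t.\tID=g1.e1;Parent=g1\n"
            "chr1\tsrc\texon\t3501\t4000\t.\t+\t.\tID=g1.e2;Parent=g1\n"
        )
        genes = load_gene_models(gff)
        assert genes[0].gene_id == "g1"
        assert (genes[0].start, genes[0].end) == (1000, 4000)
        assert genes[0].introns == [(1500, 3500)]


class TestAssignPeaks:
    def test_peak_3kb_upstream_links(self, toy_genes):
        peaks = [(rec("p1", 1.0), GenomicInterval("chr1", 6_900, 7_100, name="p1"))]
        links = assign_peaks(peaks, toy_genes)
        assert [l.gene_id for l in links] == ["geneA"]

    def test_peak_6kb_upstream_does_not_link(self, toy_genes):
        peaks = [(rec("p1", 1.0), GenomicInterval("chr1", 3_900, 4_000, name="p1"))]
        assert assign_peaks(peaks, toy_genes) == []

    def test_intronic_peak_can_link_to_two_genes(self):
        # peak inside geneA's intron and 4 kb upstream of neighbour geneB
        a = GeneModel("geneA", "chr1", 10_000, 20_000, "+",
                      exons=((10_000, 10_500), (19_000, 20_000)))
        b = GeneModel("geneB", "chr1", 19_500, 30_000, "-",
                      exons=((19_500, 30_000),))  # TSS 29_999... use + neighbour instead
        b = GeneModel("geneB", "chr1", 16_000, 30_000, "+", exons=((16_000, 30_000),))
        peak = (rec("p", 2.0), GenomicInterval("chr1", 12_000, 12_200, name="p"))
        links = assign_peaks([peak], [a, b])
        assert sorted(l.gene_id for l in links) == ["geneA", "geneB"]

    def test_most_significant_peak_retained_per_gene(self, toy_genes):
        peaks = [
            (rec("weak", 3.0, p=0.5, padj=0.5), GenomicInterval("chr1", 7_000, 7_100, name="weak")),
            (rec("strong", 1.0, p=1e-6, padj=1e-5), GenomicInterval("chr1", 8_000, 8_100, name="strong")),
        ]
        links = assign_peaks(peaks, toy_genes)
        assert len(links) == 1 and links[0].record.region == "strong"

    def test_nearest_tss_assigns_every_peak(self, toy_genes, rng):
        peaks = [
            (rec(f"p{i}", float(rng.normal())), GenomicInterval("chr1", int(s), int(s) + 100, name=f"p{i}"))
            for i, s in enumerate(rng.integers(0, 40_000, 30))
        ]
        links = assign_peaks(peaks, toy_genes, mode="nearest_tss")
        linked_regions = {l.record.region for l in links}
        # every gene's retained peak exists, and every peak was considered
        assert linked_regions <= {p.name for _, p in peaks}
        assert {l.gene_id for l in links} <= {"geneA", "geneB"}


class TestRankedList:
    def test_openers_on_top(self):
        links = assign_peaks(
            [
                (rec("up", 2.0), GenomicInterval("chr1", 6_900, 7_000, name="up")),
                (rec("down", -2.0), GenomicInterval("chr1", 25_500, 25_600, name="down")),
            ],
            [
                GeneModel("geneA", "chr1", 10_000, 13_000, "+", exons=((10_000, 13_000),)),
                GeneModel("geneB", "chr1", 20_000, 25_000, "-", exons=((20_000, 25_000),)),
            ],
        )
        ranked = ranked_list(links)
        assert list(ranked.index) == ["geneA", "geneB"]
        assert ranked.iloc[0] == 2.0

    def test_ties_lexicographic(self):
        links = assign_peaks(
            [(rec("p", 1.0), GenomicInterval("chr1", 6_900, 7_000, name="p"))],
            [GeneModel("zzz", "chr1", 10_000, 11_000, "+", exons=((10_000, 11_000),)),
             GeneModel("aaa", "chr1", 10_000, 11_000, "+", exons=((10_000, 11_000),))],
        )
        ranked = ranked_list(links)
        assert list(ranked.index) == ["aaa", "zzz"]


class TestGSEA:
    def make_ranked(self, scores):
        return pd.Series(scores, index=[f"g{i + 1}" for i in range(len(scores))])

    def test_perfectly_concentrated_set_reaches_one(self):
        ranked = self.make_ranked([5, 4, 3, 2, 1, 0.5, 0.4, 0.3, 0.2, 0.1])
        res = gsea(ranked, {"g1", "g2", "g3", "g4", "g5"}, weight=0, n_perm=100, seed=0)
        assert res.es == pytest.approx(1.0)

    def test_hand_computed_weighted_es(self):
        ranked = self.make_ranked([5, 4, 3, 2, 1])
        res = gsea(ranked, {"g1", "g3"}, weight=1, n_perm=100, seed=0)
        assert res.es == pytest.approx(2 / 3, abs=1e-4)
        assert set(res.leading_edge) == {"g1", "g3"}

    def test_weight_zero_matches_brute_force_ks(self, rng):
        for _ in range(30):
            n = int(rng.integers(8, 50))
            scores = np.sort(rng.normal(size=n))[::-1]
            ranked = pd.Series(scores, index=[f"g{i}" for i in range(n)])
            k = int(rng.integers(1, n - 1))
            members = set(rng.choice(ranked.index, size=k, replace=False))
            res = gsea(ranked, members, weight=0, n_perm=100, seed=1)
            run, best = 0.0, 0.0
            for g in ranked.index:
                run += 1 / k if g in members else -1 / (n - k)
                if abs(run) > abs(best):
                    best = run
            assert res.es == pytest.approx(best, abs=1e-9)

    def test_disjoint_set_rejected(self):
        ranked = self.make_ranked([3, 2, 1])
        with pytest.raises(ValueError, match="disjoint"):
            gsea(ranked, {"absent"}, n_perm=100)

    def test_null_pvalues_approximately_uniform(self):
        """Permutation p-values under a random gene set are uniform (KS)."""
        from scipy import stats

        r = np.random.default_rng(42)
        ranked = pd.Series(np.sort(r.normal(0, 1, 100))[::-1],
                           index=[f"g{i}" for i in range(100)])
        ps = [
            gsea(ranked, set(r.choice(ranked.index, 10, replace=False)),
                 weight=1, n_perm=200, seed=t).p
            for t in range(300)
        ]
        assert stats.kstest(ps, "uniform").statistic < 0.08


class TestEnhancerRecovery:
    def test_enhancers_equal_to_top_regions(self):
        regions = [GenomicInterval("chr1", i * 1000, i * 1000 + 100, name=f"r{i}") for i in range(10)]
        sets = {"top3": [GenomicInterval("chr1", i * 1000, i * 1000 + 100) for i in range(3)]}
        curves = enhancer_recovery(regions, sets)
        assert curves["top3"][2] == 3
        assert curves["top3"][-1] == 3

    def test_disjoint_enhancers_flat_zero(self):
        regions = [GenomicInterval("chr1", 0, 100, name="r")]
        sets = {"off": [GenomicInterval("chr2", 0, 100)]}
        assert enhancer_recovery(regions, sets)["off"].tolist() == [0]

    def test_each_enhancer_counted_once(self):
        regions = [GenomicInterval("chr1", 0, 100, name="a"), GenomicInterval("chr1", 50, 150, name="b")]
        sets = {"one": [GenomicInterval("chr1", 40, 60)]}
        assert enhancer_recovery(regions, sets)["one"].tolist() == [1, 1]

    def test_empty_set_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="empty"):
            curves = enhancer_recovery([GenomicInterval("chr1", 0, 10, name="r")], {"e": []})
        assert curves == {}

    def test_random_recovery_tracks_hypergeometric_mean(self):
        """With enhancers placed uniformly, recovery at half the ranking is
        near half the recoverable enhancers (null behaviour)."""
        r = np.random.default_rng(0)
        regions = [GenomicInterval("chr1", i * 500, i * 500 + 200, name=f"r{i}")
                   for i in r.permutation(200)]
        enhancers = [GenomicInterval("chr1", int(s) * 500 + 50, int(s) * 500 + 150)
                     for s in r.choice(200, size=50, replace=False)]
        curve = enhancer_recovery(regions, {"e": enhancers})["e"]
        assert curve[-1] == 50
        assert abs(curve[99] - 25) < 12  # ~3 sd of hypergeometric


class TestAnnotate:
    def test_categories_and_precedence(self, toy_genes):
        peaks = [
            GenomicInterval("chr1", 9_400, 9_600),    # promoter of geneA
            GenomicInterval("chr1", 10_100, 10_200),  # exon 1 of geneA
            GenomicInterval("chr1", 11_000, 11_100),  # intron of geneA
            GenomicInterval("chr1", 50_000, 50_100),  # desert
        ]
        counts = annotate_locations(peaks, toy_genes, promoter_bp=1000)
        assert counts["promoter"] == 1
        assert counts["exon"] == 1
        assert counts["intron"] == 1
        assert counts["distal_intergenic"] == 1

    def test_counts_partition_peak_set(self, toy_genes, rng):
        peaks = [GenomicInterval("chr1", int(s), int(s) + 100) for s in rng.integers(0, 60_000, 100)]
        counts = annotate_locations(peaks, toy_genes)
        assert counts.sum() == 100

    def test_promoter_beats_exon_of_other_gene(self):
        g1 = GeneModel("g1", "chr1", 10_000, 12_000, "+", exons=((10_000, 12_000),))
        g2 = GeneModel("g2", "chr1", 8_000, 9_900, "+", exons=((8_000, 9_900),))
        # peak in g1's promoter window and inside g2's exon: promoter wins
        counts = annotate_locations([GenomicInterval("chr1", 9_500, 9_700)], [g1, g2], 1000)
        assert counts["promoter"] == 1


class TestCollapseProbes:
    def test_most_significant_probe_kept(self):
        table = pd.DataFrame(
            {
                "gene": ["a", "a", "b"],
                "logFC": [1.0, 2.0, -1.0],
                "p": [0.01, 0.001, 0.5],
                "padj": [0.05, 0.004, 0.6],
            }
        )
        out = collapse_probes(table)
        assert out.loc["a", "logFC"] == 2.0
        assert len(out) == 2

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            collapse_probes(pd.DataFrame({"gene": ["a"]}))
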