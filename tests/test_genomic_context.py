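import numpy as np
import pytest

from srnaclassify.clustering import Cluster
from srnaclassify.genomic_context import (
    assign_context,
    cis_nat_srna_fraction,
    context_summary,
    genome_coverage,
    mask_genic_by_transposon,
    overlap_enrichment_test,
    predict_cis_nats,
)
from srnaclassify.io_model import AnnotationTrack

from conftest import make_read


def span_cluster(start, end, scaffold="s1"):
    return Cluster(scaffold, start, end, [make_read(scaffold=scaffold, start=start, length=21)])


def track(cls, *ivs):
    return AnnotationTrack(cls, [(iv[0], iv[1], iv[2], iv[3] if len(iv) > 3 else "+", "x") for iv in ivs])


class TestTransposonMasking:
    def test_one_nt_overlap_removes_exon(self):
        tracks = {
            "exon": track("exon", ("s1", 100, 200)),
            "transposon_known": track("transposon_known", ("s1", 199, 300)),
        }
        masked = mask_genic_by_transposon(tracks)
        assert len(masked["exon"]) == 0

    def test_abutting_exon_retained(self):
        tracks = {
            "exon": track("exon", ("s1", 100, 200)),
            "transposon_known": track("transposon_known", ("s1", 200, 300)),
        }
        assert len(mask_genic_by_transposon(tracks)["exon"]) == 1

    def test_no_transposons_leaves_tracks_unchanged(self):
        tracks = {"exon": track("exon", ("s1", 100, 200))}
        assert mask_genic_by_transposon(tracks)["exon"] is tracks["exon"]

    def test_transposon_tracks_themselves_untouched(self):
        tracks = {
            "intron": track("intron", ("s1", 150, 250)),
            "transposon_unknown": track("transposon_unknown", ("s1", 100, 200)),
        }
        masked = mask_genic_by_transposon(tracks)
        assert len(masked["intron"]) == 0
        assert len(masked["transposon_unknown"]) == 1


class TestAssignContext:
    def test_60_percent_exon_overlap_assigned(self):
        tracks = {"exon": track("exon", ("s1", 100, 160))}
        a = assign_context(span_cluster(100, 200), tracks)
        assert a.element_classes == ["exon"]
        assert a.overlap_fractions["exon"] == pytest.approx(0.60)

    def test_exactly_half_overlap_is_intergenic(self):
        tracks = {"exon": track("exon", ("s1", 100, 150))}
        a = assign_context(span_cluster(100, 200), tracks, min_fraction=0.51)
        assert a.is_intergenic and a.primary == "intergenic"

    def test_51_percent_overlap_assigned(self):
        tracks = {"exon": track("exon", ("s1", 100, 151))}
        a = assign_context(span_cluster(100, 200), tracks, min_fraction=0.51)
        assert a.element_classes == ["exon"]

    def test_multi_assignment_when_elements_overlap(self):
        tracks = {
            "exon": track("exon", ("s1", 100, 160)),
            "transposon_known": track("transposon_known", ("s1", 140, 200)),
        }
        a = assign_context(span_cluster(100, 200), tracks)
        assert set(a.element_classes) == {"exon", "transposon_known"}
        assert a.primary == "exon"  # single-label precedence

    def test_class_union_counts_once(self):
        # two overlapping exon intervals only cover 60 bp of the cluster
        tracks = {"exon": track("exon", ("s1", 100, 150), ("s1", 120, 160))}
        a = assign_context(span_cluster(100, 200), tracks)
        assert a.overlap_fractions["exon"] == pytest.approx(0.60)

    def test_zero_min_fraction_degenerates_to_any_overlap(self):
        tracks = {"exon": track("exon", ("s1", 199, 300))}
        a = assign_context(span_cluster(100, 200), tracks, min_fraction=0.0)
        assert a.element_classes == ["exon"]

    def test_summary_rows_can_exceed_100_percent(self):
        tracks = {
            "exon": track("exon", ("s1", 100, 200)),
            "transposon_known": track("transposon_known", ("s1", 100, 200)),
        }
        assignments = [assign_context(span_cluster(100, 200), tracks)]
        summary = context_summary({"endo_siRNA": assignments})
        assert summary.loc["endo_siRNA"].sum() == pytest.approx(200.0)


class TestGenomeCoverage:
    def test_single_interval_percentage(self):
        cov = genome_coverage({"exon": track("exon", ("s1", 0, 100))}, {"s1": 1000})
        assert cov.loc["exon", "genome_pct"] == pytest.approx(10.0)

    def test_union_semantics_for_overlapping_intervals(self):
        cov = genome_coverage(
            {"exon": track("exon", ("s1", 0, 100), ("s1", 50, 150))}, {"s1": 1000}
        )
        assert cov.loc["exon", "genome_pct"] == pytest.approx(15.0)

    def test_empty_track_is_zero(self):
        cov = genome_coverage({"exon": AnnotationTrack("exon", [])}, {"s1": 1000})
        assert cov.loc["exon", "genome_pct"] == 0.0

    def test_interval_beyond_scaffold_end_rejected(self):
        with pytest.raises(ValueError):
            genome_coverage({"exon": track("exon", ("s1", 900, 1100))}, {"s1": 1000})


class TestEnrichmentTest:
    glens = {"s1": 100_000}

    def test_reference_equal_to_clusters_hits_floor(self):
        clusters = [span_cluster(s, s + 150) for s in range(1000, 20000, 2000)]
        ref = track("exon", *[("s1", c.start, c.end) for c in clusters])
        observed, p = overlap_enrichment_test(clusters, ref, self.glens, 1000, 0)
        assert observed == len(clusters)
        assert p <= 2 / 1001

    def test_empty_reference_gives_p_one(self):
        clusters = [span_cluster(1000, 1150)]
        observed, p = overlap_enrichment_test(
            clusters, AnnotationTrack("exon", []), self.glens, 1000, 0
        )
        assert observed == 0 and p == 1.0

    def test_planted_correlated_layout_is_significant(self, ):
        rng = np.random.default_rng(11)
        anchors = rng.integers(0, 95_000, 25)
        clusters = [span_cluster(int(a), int(a) + 200) for a in anchors]
        ref = track("exon", *[("s1", int(a) - 50, int(a) + 100) for a in anchors if a > 50])
        _, p = overlap_enrichment_test(clusters, ref, self.glens, 1000, 1)
        assert p <= 0.01

    def test_cluster_longer_than_scaffold_skipped_with_warning(self):
        clusters = [span_cluster(0, 150), span_cluster(0, 600)]
        with pytest.warns(UserWarning, match="longer than scaffold"):
            observed, _ = overlap_enrichment_test(
                clusters, track("exon", ("s1", 0, 100)), {"s1": 500}, 100, 0
            )
        assert observed == 1


class TestCisNat:
    def test_one_nt_opposite_strand_overlap_links_both(self):
        gm = AnnotationTrack(
            "gene_model",
            [("s1", 100, 200, "+", "g1"), ("s1", 199, 300, "-", "g2")],
        )
        assert predict_cis_nats(gm) == {"g1", "g2"}

    def test_same_strand_overlap_is_not_cis_nat(self):
        gm = AnnotationTrack(
            "gene_model",
            [("s1", 100, 200, "+", "g1"), ("s1", 150, 250, "+", "g2")],
        )
        assert predict_cis_nats(gm) == set()

    def test_half_open_abutment_is_not_overlap(self):
        gm = AnnotationTrack(
            "gene_model",
            [("s1", 100, 200, "+", "g1"), ("s1", 200, 300, "-", "g2")],
        )
        assert predict_cis_nats(gm) == set()

    def test_relation_is_symmetric(self):
        gm = AnnotationTrack(
            "gene_model",
            [
                ("s1", 100, 300, "+", "g1"),
                ("s1", 250, 500, "-", "g2"),
                ("s1", 450, 700, "+", "g3"),
                ("s2", 0, 100, "+", "lonely"),
            ],
        )
        cis = predict_cis_nats(gm)
        assert cis == {"g1", "g2", "g3"}

    def test_gene_fraction_matches_hand_arithmetic(self):
        genes = [("s1", i * 1000, i * 1000 + 400, "+", f"g{i}") for i in range(10)]
        # overlap the first two pairs antisense
        genes[1] = ("s1", 300, 900, "-", "g1")
        genes[3] = ("s1", 2300, 2900, "-", "g3")
        gm = AnnotationTrack("gene_model", genes)
        frac_genes, _ = cis_nat_srna_fraction([], gm)
        assert frac_genes == pytest.approx(0.4)

    def test_all_endo_clusters_planted_in_cis_nat_overlaps(self):
        gm = AnnotationTrack(
            "gene_model",
            [("s1", 0, 1000, "+", "a"), ("s1", 800, 1800, "-", "b")],
        )
        clusters = [span_cluster(850, 950)]
        _, frac = cis_nat_srna_fraction(clusters, gm)
        assert frac == 1.0

    def test_no_cis_nats_gives_zero_fractions(self):
        gm = AnnotationTrack("gene_model", [("s1", 0, 1000, "+", "a")])
        assert cis_nat_srna_fraction([span_cluster(100, 200)], gm) == (0.0, 0.0)
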