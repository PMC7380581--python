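import pytest

from magprov.io import Feature, HitRecord
from magprov.provenance import (
    OperonRegion,
    build_report,
    filter_hits,
    neighborhood_discordance,
    scan_flanks,
)
from magprov.synthetic import make_genome, plant_operon


def hit(pident=50.0, qcov=0.9, evalue=1e-20, query="g1"):
    return HitRecord(query, "subj", pident, 300, qcov, evalue, 100.0)


class TestFilterHits:
    def test_integron_screen_boundaries_inclusive(self):
        h = hit(pident=30.0, qcov=0.75)
        assert filter_hits([h], 30.0, 0.75, None, inclusive=True) == [h]

    def test_transposon_screen_identity_strict(self):
        assert filter_hits([hit(pident=30.0)], 30.0, 0.75, 1e-5, inclusive=False) == []
        assert filter_hits([hit(pident=30.1)], 30.0, 0.75, 1e-5, inclusive=False) != []

    def test_transposon_screen_evalue_strict(self):
        assert filter_hits([hit(evalue=1e-5)], 30.0, 0.75, 1e-5, inclusive=False) == []
        assert filter_hits([hit(evalue=9e-6)], 30.0, 0.75, 1e-5, inclusive=False) != []

    def test_order_preserved(self):
        hits = [hit(query=f"g{i}") for i in range(5)]
        assert [h.query_id for h in filter_hits(hits, 30, 0.5)] == [
            f"g{i}" for i in range(5)
        ]

    def test_negative_thresholds_rejected(self):
        with pytest.raises(ValueError):
            filter_hits([], -1, 0.5)


def region(start=20_000, end=26_000, members=(), flank=10_000):
    return OperonRegion("b", "c1", start, end, list(members), flank)


class TestScanFlanks:
    def test_trna_upstream_within_flank(self):
        trna = Feature("c1", 18_000, 18_075, "+", "tRNA", feature_id="t1")
        found = scan_flanks(region(), [trna], contig_length=60_000)
        assert [h.kind for h in found] == ["tRNA"]

    def test_clean_flanks_empty(self):
        far = Feature("c1", 40_000, 40_075, "+", "tRNA")
        assert scan_flanks(region(), [far], contig_length=60_000) == []

    def test_transposase_hit_inside_operon_excluded(self):
        tnp = Feature("c1", 22_000, 23_000, "-", "CDS", feature_id="tnp1")
        found = scan_flanks(
            region(), [tnp], transposon_hits=[hit(query="tnp1")],
            contig_length=60_000,
        )
        assert found == []

    def test_transposase_hit_in_flank_passes_screen(self):
        tnp = Feature("c1", 28_000, 29_000, "-", "CDS", feature_id="tnp1")
        found = scan_flanks(
            region(), [tnp], transposon_hits=[hit(query="tnp1")],
            contig_length=60_000,
        )
        assert [h.kind for h in found] == ["transposon"]

    def test_repeat_feature_detected(self):
        rep = Feature("c1", 27_000, 27_400, None, "repeat_region", feature_id="r1")
        found = scan_flanks(region(), [rep], contig_length=60_000)
        assert [h.kind for h in found] == ["repeat"]

    def test_flank_truncated_at_contig_edge(self):
        r = region(start=2_000, end=8_000)
        assert r.flank_windows(20_000) == [(0, 2_000), (8_000, 18_000)]


def cds(start, taxon, contig="c1"):
    return Feature(contig, start, start + 900, "+", "CDS", best_hit_taxon=taxon)


class TestNeighborhoodDiscordance:
    def test_fully_discordant_neighborhood(self):
        members = [cds(20_000 + i * 1000, "Methanogens") for i in range(4)]
        flanks = [cds(15_000 + i * 1000, "Archaeoglobaceae") for i in range(4)]
        r = region(members=members)
        assert neighborhood_discordance(r, members + flanks, 60_000) == 1.0

    def test_concordant_neighborhood(self):
        members = [cds(20_000 + i * 1000, "X") for i in range(3)]
        flanks = [cds(15_000 + i * 1000, "X") for i in range(3)]
        assert neighborhood_discordance(region(members=members), members + flanks, 60_000) == 0.0

    def test_counting(self):
        members = [cds(20_000, "X")]
        flanks = [cds(10_000 + i * 900, "Y" if i < 4 else "X") for i in range(10)]
        r = region(members=members)
        assert neighborhood_discordance(r, members + flanks, 60_000) == pytest.approx(0.4)

    def test_undefined_below_three_labelled_flank_genes(self):
        members = [cds(20_000, "X")]
        flanks = [cds(15_000, "Y"), cds(17_000, "Y")]
        assert neighborhood_discordance(region(members=members), members + flanks, 60_000) is None


class TestBuildReport:
    def test_native_operon_clean_flanks_vertical(self):
        genome = make_genome(0.45, 120_000, 1, seed=21)
        planted, truth = plant_operon(genome, 0.45, 6000, "native", False, seed=22)
        r = truth.planted_regions[0][0]
        report = build_report(r, planted, truth.features)
        assert report.verdict == "vertical_consistent"

    def test_alien_operon_with_hallmarks_multiple_evidence_lines(self):
        genome = make_genome(0.40, 120_000, 1, seed=23)
        planted, truth = plant_operon(genome, 0.50, 6000, "alien", True, seed=24)
        r = truth.planted_regions[0][0]
        report = build_report(
            r, planted, truth.features, transposon_hits=truth.transposon_hits
        )
        assert report.verdict == "hgt_suspected"
        assert sum(1 for e in report.evidence if e["triggered"]) >= 2

    def test_partial_data_yields_indeterminate(self):
        genome = make_genome(0.45, 120_000, 1, seed=25)
        planted, truth = plant_operon(genome, 0.45, 6000, "native", False, seed=26)
        r = truth.planted_regions[0][0]
        # strip every taxon label: discordance undefined, nothing triggered
        stripped = []
        for f in truth.features:
            stripped.append(
                Feature(f.contig_id, f.start, f.end, f.strand, f.feature_type,
                        f.gene_label, f.ko_id, None, None, f.feature_id)
            )
        bare = OperonRegion(r.bin_id, r.contig_id, r.start, r.end,
                            [f for f in stripped if r.start <= f.start and f.end <= r.end
                             and f.feature_type == "CDS"],
                            r.flank_bp, r.name)
        report = build_report(bare, planted, stripped)
        assert report.verdict == "indeterminate"

    def test_report_deterministic(self):
        genome = make_genome(0.40, 120_000, 1, seed=27)
        planted, truth = plant_operon(genome, 0.50, 6000, "alien", True, seed=28)
        r = truth.planted_regions[0][0]
        d1 = build_report(r, planted, truth.features,
                          transposon_hits=truth.transposon_hits).to_dict()
        d2 = build_report(r, planted, truth.features,
                          transposon_hits=truth.transposon_hits).to_dict()
        assert d1 == d2

    def test_every_evidence_line_carries_thresholds(self):
        genome = make_genome(0.45, 120_000, 1, seed=29)
        planted, truth = plant_operon(genome, 0.45, 6000, "native", False, seed=30)
        report = build_report(truth.planted_regions[0][0], planted, truth.features)
        assert all("threshold" in e for e in report.evidence)
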