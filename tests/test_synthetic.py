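import numpy as np
import pytest

from magprov.composition import genome_profile, score_region
from magprov.phylo import placement_congruence, rf_distance
from magprov.provenance import scan_flanks
from magprov.synthetic import (
    make_genome,
    make_proteome_pair,
    make_tree_set,
    plant_operon,
)


class TestMakeGenome:
    def test_gc_converges_to_target(self):
        for length in (120_000, 300_000):
            genome = make_genome(0.455, length, 1, seed=1)
            assert genome_profile(genome).gc == pytest.approx(0.455, abs=0.01)

    def test_seed_determinism_byte_identical(self):
        g1 = make_genome(0.45, 50_000, 3, seed=9)
        g2 = make_genome(0.45, 50_000, 3, seed=9)
        assert [c.residues for c in g1.contigs] == [c.residues for c in g2.contigs]

    def test_different_seeds_differ(self):
        g1 = make_genome(0.45, 20_000, 1, seed=1)
        g2 = make_genome(0.45, 20_000, 1, seed=2)
        assert g1.contigs[0].residues != g2.contigs[0].residues

    def test_contig_count_and_total_length(self):
        genome = make_genome(0.455, 400_000, 45, seed=3)
        assert len(genome.contigs) == 45
        assert genome.total_length == 400_000

    def test_infeasible_gc_rejected(self):
        with pytest.raises(ValueError):
            make_genome(1.2, 10_000, 1, seed=0)


class TestPlantOperon:
    def test_native_requires_matching_gc(self):
        genome = make_genome(0.45, 60_000, 1, seed=4)
        with pytest.raises(ValueError, match="donor_gc"):
            plant_operon(genome, 0.50, 5000, "native")

    def test_planted_locus_recorded_and_sequence_inserted(self):
        genome = make_genome(0.45, 60_000, 1, seed=5)
        planted, truth = plant_operon(genome, 0.55, 5000, "alien", seed=6)
        region, provenance, donor_gc = truth.planted_regions[0]
        assert provenance == "alien" and donor_gc == 0.55
        assert planted.total_length == genome.total_length + 5000

    def test_hallmarks_recovered_by_scan(self):
        genome = make_genome(0.45, 80_000, 1, seed=7)
        planted, truth = plant_operon(genome, 0.45, 5000, "native", True, seed=8)
        region = truth.planted_regions[0][0]
        found = scan_flanks(
            region, truth.features, None, truth.transposon_hits,
            contig_length=len(planted.contigs[0]),
        )
        assert {h.kind for h in found} >= {"tRNA", "transposon"}

    def test_operon_longer_than_contig_rejected(self):
        genome = make_genome(0.45, 20_000, 1, seed=9)
        with pytest.raises(ValueError, match="longer"):
            plant_operon(genome, 0.45, 30_000, "native")

    def test_native_operon_composition_is_host_like(self):
        # single fixed seed; the replicate study lives in the acceptance suite
        genome = make_genome(0.45, 120_000, 1, seed=10)
        planted, truth = plant_operon(genome, 0.45, 6000, "native", seed=11)
        region = truth.planted_regions[0][0]
        seq = planted.contig(region.contig_id).residues[region.start : region.end]
        assert abs(score_region(seq, planted).gc_delta) < 0.03


class TestMakeTreeSet:
    def test_vertical_tree_identical_to_species(self):
        species, vertical, _, _ = make_tree_set(10, 3, seed=0)
        assert rf_distance(vertical, species) == 0

    def test_congruence_labels_by_construction(self):
        species, vertical, hgt, focal = make_tree_set(12, 3, seed=1)
        assert placement_congruence(vertical, species, focal) == "congruent"
        assert placement_congruence(hgt, species, focal) == "incongruent"

    def test_seed_determinism(self):
        t1 = make_tree_set(10, 2, seed=5)
        t2 = make_tree_set(10, 2, seed=5)
        assert t1[0].to_newick() == t2[0].to_newick()
        assert t1[2].to_newick() == t2[2].to_newick()

    def test_bad_clade_size_rejected(self):
        with pytest.raises(ValueError):
            make_tree_set(8, 6, seed=0)
        with pytest.raises(ValueError):
            make_tree_set(8, 1, seed=0)

    def test_many_seeds_always_incongruent(self):
        for seed in range(10):
            species, vertical, hgt, focal = make_tree_set(10, 3, seed=seed)
            assert placement_congruence(hgt, species, focal) == "incongruent"
            assert placement_congruence(vertical, species, focal) == "congruent"


class TestMakeProteomePair:
    def test_full_sharing_full_identity(self):
        from magprov.delineation import aai_between

        pa, pb, _ = make_proteome_pair(10, 1.0, 100.0, seed=2)
        result = aai_between(pa, pb)
        assert result.mean_identity == pytest.approx(100.0)
        assert result.n_orthologs == 10

    def test_seed_determinism_byte_identical(self):
        pa1, pb1, _ = make_proteome_pair(8, 0.5, 70.0, seed=3)
        pa2, pb2, _ = make_proteome_pair(8, 0.5, 70.0, seed=3)
        assert [r.residues for r in pa1] == [r.residues for r in pa2]
        assert [r.residues for r in pb1] == [r.residues for r in pb2]

    def test_truth_bookkeeping(self):
        _, _, truth = make_proteome_pair(50, 0.72, 63.0, seed=4)
        n_genes, n_shared, identity = truth.proteome_truth
        assert n_genes == 50 and n_shared == 36 and identity == 63.0

    def test_infeasible_parameters_rejected(self):
        with pytest.raises(ValueError):
            make_proteome_pair(10, 0.0, 60.0)
        with pytest.raises(ValueError):
            make_proteome_pair(10, 0.5, 10.0)
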