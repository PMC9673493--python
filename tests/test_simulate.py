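import numpy as np
import pytest

from magcurate._align import edlib_identity
from magcurate.quality import rna_complete
from magcurate.simulate import (
    mutate_genome,
    random_genome,
    simulate_annotations,
    simulate_gene_families,
    simulate_genomes,
    simulate_graph,
)


def test_same_seed_gives_identical_communities():
    a = simulate_genomes(2, 2, 5000, seed=4)
    b = simulate_genomes(2, 2, 5000, seed=4)
    assert [(r.id, r.sequence) for r in a[0]] == [(r.id, r.sequence) for r in b[0]]
    assert a[1].abundances == b[1].abundances


def test_single_strain_is_the_ancestor():
    genomes, truth = simulate_genomes(2, 1, 5000, seed=3)
    for g in genomes:
        assert g.sequence == truth.ancestors[truth.species_of(g.id)]


def test_incompatible_ani_thresholds_rejected():
    with pytest.raises(ValueError):
        simulate_genomes(2, 2, 5000, intra_species_ani=96.0, inter_species_ani_max=97.0)


def test_strain_pair_identity_matches_target(small_community):
    """Strains of one species diverge ~2x the per-strain rate: for a 99.3
    target (r = 0.007 per strain) the expected pairwise identity is
    100 * (1 - (2r(1-r) + 2/3 r^2)) ~ 98.61, since independently mutated
    strains differ unless both hit the same site with the same base."""
    genomes, truth = small_community
    by_id = {g.id: g for g in genomes}
    r = 0.007
    expected = 100.0 * (1.0 - (2 * r * (1 - r) + (2 / 3) * r * r))
    for species, members in truth.species_partition.items():
        a, b = (by_id[m].sequence for m in members)
        ident = edlib_identity(a, b, mode="NW")
        assert ident == pytest.approx(expected, abs=0.3)
        # and each strain sits within 0.3 points of the ancestor target
        anc = truth.ancestors[species]
        for m in members:
            assert edlib_identity(by_id[m].sequence, anc) == pytest.approx(99.3, abs=0.3)


def test_realized_identity_monotone_in_rate():
    base = random_genome(20_000, seed=9)
    idents = [
        edlib_identity(mutate_genome(base, rate, 0.0, seed=5), base)
        for rate in (0.005, 0.02, 0.05)
    ]
    assert idents[0] > idents[1] > idents[2]


def test_abundances_sum_to_one(small_community):
    _, truth = small_community
    assert np.isclose(sum(truth.abundances.values()), 1.0)
    covered = sorted(g for members in truth.species_partition.values() for g in members)
    assert covered == sorted(g[0] for g in truth.genomes)


class TestGraphSimulation:
    def test_circular_genome_is_one_self_linked_segment(self, small_community):
        genomes, truth = small_community
        plan = {genomes[0].id: "circular"}
        graph, planned = simulate_graph(genomes[:1], truth, plan, seed=0)
        assert len(graph.segments) == 1
        (link,) = graph.links
        assert link.from_id == link.to_id and link.from_orient == link.to_orient

    def test_tangled_species_shares_a_segment_and_cycles(self, small_community):
        genomes, truth = small_community
        members = truth.species_partition["sp01"]
        plan = {m: "tangled" for m in members}
        graph, planned = simulate_graph(
            [g for g in genomes if g.id in members], truth, plan, seed=0
        )
        (comp,) = planned
        assert comp.topology == "tangled" and len(comp.segment_ids) > 1
        assert any(s.endswith(".shared") for s in comp.segment_ids)
        # more links than a tree could carry -> the component has a cycle
        assert len(graph.links) > len(graph.segments) - 1

    def test_tangled_single_strain_rejected(self):
        genomes, truth = simulate_genomes(1, 1, 5000, seed=2)
        with pytest.raises(ValueError, match="tangled"):
            simulate_graph(genomes, truth, {genomes[0].id: "tangled"}, seed=0)

    def test_linear_genome_is_an_open_path(self, small_community):
        genomes, truth = small_community
        plan = {genomes[0].id: "linear"}
        graph, planned = simulate_graph(genomes[:1], truth, plan, seed=1)
        assert len(graph.links) == len(graph.segments) - 1

    def test_depth_proportional_to_abundance(self, small_community):
        genomes, truth = small_community
        gid = genomes[0].id
        graph, _ = simulate_graph(genomes[:1], truth, {gid: "circular"}, depth_scale=300, seed=0)
        assert graph.segments[gid].depth == pytest.approx(truth.abundances[gid] * 300)


class TestAnnotationSimulation:
    GENOME = None

    @pytest.fixture()
    def genome(self, small_community):
        return small_community[0][0]

    def test_intact_operons_pass_rna_completeness(self, genome):
        feats = simulate_annotations(genome, n_operons=2, n_trnas=50, seed=5)
        ok, detail = rna_complete(feats)
        assert ok and detail["operon_count"] == 2 and detail["trna_count"] == 50

    def test_broken_operon_fails_operon_criterion(self, genome):
        feats = simulate_annotations(genome, n_operons=1, n_trnas=50, operon_intact=False, seed=5)
        ok, detail = rna_complete(feats)
        assert not ok and detail["operon_count"] == 0

    def test_seventeen_trnas_fail_boundary(self, genome):
        feats = simulate_annotations(genome, n_operons=1, n_trnas=17, seed=5)
        ok, detail = rna_complete(feats)
        assert not ok and detail["trna_count"] == 17 and detail["operon_ok"]

    def test_operon_overflow_rejected(self, small_community):
        genomes, _ = small_community
        short = genomes[0]
        with pytest.raises(ValueError):
            simulate_annotations(short, n_operons=6, n_trnas=0, seed=1)


class TestGeneFamilies:
    def test_family_counts_and_truth_structure(self):
        genes, flags, truth = simulate_gene_families(10, 5, seed=7)
        assert len(genes) == 50 and len(truth) == 10
        assert all(len(fam) == 5 for fam in truth)
        assert set(flags) == {g.id for g in genes}

    def test_partial_fraction_count(self):
        genes, flags, _ = simulate_gene_families(10, 5, partial_fraction=0.2, seed=7)
        assert sum(1 for f in flags.values() if f != "00") == 10

    def test_single_member_families_are_singletons(self):
        _, _, truth = simulate_gene_families(4, 1, seed=7)
        assert all(len(fam) == 1 for fam in truth)

    def test_ambiguous_identity_rejected(self):
        with pytest.raises(ValueError):
            simulate_gene_families(2, 2, within_family_identity=95.0)

    def test_member_lengths_within_ten_percent(self):
        genes, _, _ = simulate_gene_families(5, 4, base_length_bp=600, seed=1)
        for g in genes:
            assert 0.9 * 600 <= len(g.sequence) <= 1.1 * 600 + 1
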