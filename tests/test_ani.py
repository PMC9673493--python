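import itertools

import numpy as np
import pytest

from magcurate.ani import (
    AniEstimate,
    DistanceMatrix,
    build_distance_matrix,
    cluster_complete_linkage,
    dereplicate,
    estimate_ani,
    pairwise_estimates,
    select_representative,
)
from magcurate.io import GenomeMetadata, SequenceRecord
from magcurate.simulate import mutate_genome, random_genome, simulate_genomes


def naive_complete_linkage(ids, dmat, stop):
    """Direct agglomerative reference: recompute every inter-cluster maximum
    from scratch each round, merge the closest pair while strictly below the
    stop distance, ties by smallest label pair."""
    pos = {g: i for i, g in enumerate(ids)}
    clusters = [frozenset([g]) for g in ids]
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(clusters, 2):
            d = max(dmat[pos[x], pos[y]] for x in a for y in b)
            key = (d, tuple(sorted((min(a), min(b)))))
            if best is None or key < best[0]:
                best = (key, a, b)
        (d, _), a, b = best
        if d >= stop:
            break
        clusters.remove(a)
        clusters.remove(b)
        clusters.append(a | b)
    return {frozenset(c) for c in clusters}


def truth_fragment_identity(query, reference, fragment_length=3000):
    """Exact identity oracle for substitution-only mutants: coordinates are
    preserved, so per-fragment identity is the position-wise match fraction."""
    n = len(query) // fragment_length
    idents = []
    for i in range(n):
        q = query[i * fragment_length : (i + 1) * fragment_length]
        r = reference[i * fragment_length : (i + 1) * fragment_length]
        idents.append(100.0 * sum(a == b for a, b in zip(q, r)) / fragment_length)
    return float(np.mean(idents))


class TestEstimator:
    def test_genome_vs_itself_is_100(self):
        g = SequenceRecord("g", random_genome(9000, seed=1))
        est = estimate_ani(g, g)
        assert est.ani == 100.0
        assert est.fragments_mapped == est.fragments_total == 3

    @pytest.mark.parametrize("rate", [0.005, 0.02, 0.05])
    def test_matches_exact_identity_on_substitution_mutants(self, rate):
        base = random_genome(30_000, seed=13)
        mutant = mutate_genome(base, rate, 0.0, seed=17)
        est = estimate_ani(SequenceRecord("m", mutant), SequenceRecord("b", base))
        assert est.fragments_mapped == est.fragments_total
        assert est.ani == pytest.approx(truth_fragment_identity(mutant, base), abs=0.3)

    def test_unrelated_genomes_undefined(self):
        a = SequenceRecord("a", random_genome(20_000, seed=1))
        b = SequenceRecord("b", random_genome(20_000, seed=2))
        est = estimate_ani(a, b)
        assert est.ani is None and est.fragments_mapped == 0

    def test_reverse_complement_recovered(self):
        seq = random_genome(9000, seed=5)
        rc = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        est = estimate_ani(SequenceRecord("q", rc), SequenceRecord("r", seq))
        assert est.ani == pytest.approx(100.0, abs=0.01)

    def test_short_query_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            estimate_ani(SequenceRecord("q", "ACGT"), SequenceRecord("r", "ACGT" * 1000))

    def test_non_dna_rejected(self):
        with pytest.raises(ValueError):
            estimate_ani(
                SequenceRecord("q", "QQ" * 2000), SequenceRecord("r", "ACGT" * 1000)
            )

    def test_inconsistent_estimate_rejected(self):
        with pytest.raises(ValueError):
            AniEstimate("a", "b", None, 4, 2)


class TestDistanceMatrix:
    def test_min_symmetrization(self):
        ests = [AniEstimate("a", "b", 99.5, 10, 10), AniEstimate("b", "a", 99.1, 10, 10)]
        m = build_distance_matrix(["a", "b"], ests)
        assert m.value("a", "b") == pytest.approx(0.009)

    def test_one_sided_estimate_used(self):
        ests = [AniEstimate("a", "b", 98.0, 10, 9)]
        m = build_distance_matrix(["a", "b"], ests)
        assert m.value("a", "b") == pytest.approx(0.02)

    def test_missing_pair_gets_unit_distance(self):
        m = build_distance_matrix(["a", "b"], [])
        assert m.value("a", "b") == 1.0

    def test_identity_100_gives_zero_distance(self):
        ests = [AniEstimate("a", "b", 100.0, 10, 10), AniEstimate("b", "a", 100.0, 10, 10)]
        assert build_distance_matrix(["a", "b"], ests).value("a", "b") == 0.0

    def test_unknown_genome_rejected(self):
        with pytest.raises(ValueError, match="zzz"):
            build_distance_matrix(["a"], [AniEstimate("a", "zzz", 99.0, 1, 1)])

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0.0, 0.1], [0.2, 0.0]]))


class TestCompleteLinkage:
    MATRIX = DistanceMatrix(
        ["A", "B", "C"],
        np.array([[0.0, 0.005, 0.04], [0.005, 0.0, 0.04], [0.04, 0.04, 0.0]]),
    )

    def test_three_genome_example_strain_stop(self):
        parts = {frozenset(c.members) for c in cluster_complete_linkage(self.MATRIX, 0.01).clusters}
        assert parts == {frozenset({"A", "B"}), frozenset({"C"})}

    def test_three_genome_example_species_stop(self):
        parts = {frozenset(c.members) for c in cluster_complete_linkage(self.MATRIX, 0.05).clusters}
        assert parts == {frozenset({"A", "B", "C"})}

    def test_singleton_input(self):
        m = DistanceMatrix(["x"], np.zeros((1, 1)))
        cs = cluster_complete_linkage(m, 0.05)
        assert [c.members for c in cs.clusters] == [("x",)]

    def test_pair_exactly_at_stop_not_merged(self):
        m = DistanceMatrix(["a", "b"], np.array([[0.0, 0.01], [0.01, 0.0]]))
        assert len(cluster_complete_linkage(m, 0.01).clusters) == 2

    @pytest.mark.parametrize("trial", range(40))
    def test_matches_naive_oracle_on_random_matrices(self, trial):
        rng = np.random.default_rng(1000 + trial)
        n = int(rng.integers(2, 13))
        ids = [f"g{i:02d}" for i in range(n)]
        d = np.triu(rng.uniform(0, 0.08, size=(n, n)), 1)
        d = d + d.T
        stop = float(rng.uniform(0.005, 0.06))
        ours = {frozenset(c.members) for c in cluster_complete_linkage(DistanceMatrix(ids, d), stop).clusters}
        assert ours == naive_complete_linkage(ids, d, stop)

    def test_result_invariant_to_id_order(self):
        rng = np.random.default_rng(7)
        n = 8
        ids = [f"g{i}" for i in range(n)]
        d = np.triu(rng.uniform(0, 0.08, size=(n, n)), 1)
        d = d + d.T
        base = {
            frozenset(c.members)
            for c in cluster_complete_linkage(DistanceMatrix(ids, d), 0.03).clusters
        }
        order = rng.permutation(n)
        ids2 = [ids[i] for i in order]
        d2 = d[np.ix_(order, order)]
        perm = {
            frozenset(c.members)
            for c in cluster_complete_linkage(DistanceMatrix(ids2, d2), 0.03).clusters
        }
        assert perm == base


class TestRepresentativeSelection:
    @staticmethod
    def md(gid, circular, completeness, contamination, size=2_000_000):
        return GenomeMetadata(gid, circular, size, 1 if circular else 3, completeness, contamination)

    def test_circular_beats_higher_score(self):
        meta = {"A": self.md("A", True, 80, 0), "B": self.md("B", False, 95, 0)}
        assert select_representative(["A", "B"], meta) == "A"

    def test_checkm_score_breaks_circular_tie(self):
        meta = {"A": self.md("A", True, 80, 0), "B": self.md("B", True, 90, 0)}
        assert select_representative(["A", "B"], meta) == "B"

    def test_assembly_size_breaks_score_tie(self):
        meta = {
            "A": self.md("A", True, 90, 0, size=2_400_000),
            "B": self.md("B", True, 90, 0, size=2_600_000),
        }
        assert select_representative(["A", "B"], meta) == "B"

    def test_missing_metadata_rejected(self):
        with pytest.raises(ValueError, match="B"):
            select_representative(["A", "B"], {"A": self.md("A", True, 90, 0)})


@pytest.fixture(scope="module")
def community(small_community_indels):
    genomes, truth = small_community_indels
    meta = {
        g.id: GenomeMetadata(g.id, False, len(g.sequence), 2, 80.0 + i, 1.0)
        for i, g in enumerate(genomes)
    }
    ests = pairwise_estimates(genomes)
    distances = build_distance_matrix([g.id for g in genomes], ests)
    return genomes, truth, meta, distances


class TestDereplication:
    def test_species_stop_recovers_species_partition(self, community):
        genomes, truth, meta, distances = community
        clusters, reps = dereplicate(genomes, meta, 0.05, distances=distances)
        got = {frozenset(c.members) for c in clusters.clusters}
        want = {frozenset(m) for m in truth.species_partition.values()}
        assert got == want and len(reps) == 3

    def test_strain_stop_keeps_every_strain(self, community):
        genomes, truth, meta, distances = community
        clusters, reps = dereplicate(genomes, meta, 0.01, distances=distances)
        assert {frozenset(c.members) for c in clusters.clusters} == {
            frozenset([g.id]) for g in genomes
        }
        assert len(reps) == 6

    def test_single_genome_dereplicates_to_itself(self):
        g = SequenceRecord("solo", random_genome(6000, seed=3))
        meta = {"solo": GenomeMetadata("solo", True, 6000, 1, 95.0, 0.5)}
        clusters, reps = dereplicate([g], meta, 0.05)
        assert [r.id for r in reps] == ["solo"]

    def test_idempotent_on_representatives(self, community):
        genomes, _truth, meta, distances = community
        _, reps = dereplicate(genomes, meta, 0.05, distances=distances)
        again_clusters, again = dereplicate(reps, meta, 0.05)
        assert [r.id for r in again] == [r.id for r in reps]

    def test_representative_set_invariant_to_input_order(self, community):
        genomes, _truth, meta, distances = community
        _, reps = dereplicate(genomes, meta, 0.05, distances=distances)
        _, reps2 = dereplicate(list(reversed(genomes)), meta, 0.05)
        assert {r.id for r in reps2} == {r.id for r in reps}

    def test_representatives_mutually_below_strain_identity(self, community):
        """At stop 0.01 every retained pair has symmetrized ANI <= 99."""
        genomes, _truth, meta, distances = community
        clusters, reps = dereplicate(genomes, meta, 0.01, distances=distances)
        ids = [r.id for r in reps]
        pos = {g: i for i, g in enumerate(distances.ids)}
        for a, b in itertools.combinations(ids, 2):
            identity = 100.0 - 100.0 * distances.d[pos[a], pos[b]]
            assert identity <= 99.0
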