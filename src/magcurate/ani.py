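"""Fragment-based ANI estimation and ANI dereplication.

The estimator follows the FastANI recipe: the query genome is cut into
non-overlapping fragments (default 3 kb), each fragment is located in the
reference by the diagonal with the most shared k-mers (k = 16, both strands),
scored by edit alignment of the fragment against that reference window, and
counted as mapped when its identity reaches the reporting floor (80%).  ANI
is the mean identity over mapped fragments; it is directional and undefined
when nothing maps.

Dereplication converts symmetrized identities into distances d = (100 -
identity)/100, clusters them by complete-linkage agglomeration with a stop
distance (0.01 for strains, 0.05 for species), and keeps one representative
per cluster: circular beats noncircular, then larger CheckM score
(completeness - 5 x contamination), then larger assembly, then smaller id.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from ._align import check_dna, edlib_identity, revcomp
from .io import GenomeMetadata, SequenceRecord
from .quality import checkm_score

_WINDOW_PAD = 64
_MIN_VOTES = 2
_DIAG_BIN = 64


@dataclass(frozen=True)
class AniEstimate:
    query_id: str
    reference_id: str
    ani: float | None
    fragments_total: int
    fragments_mapped: int

    def __post_init__(self) -> None:
        if self.fragments_mapped > self.fragments_total:
            raise ValueError("more fragments mapped than exist")
        if (self.ani is None) != (self.fragments_mapped == 0):
            raise ValueError("ani must be undefined exactly when nothing maps")


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if self.d.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("distance matrix has a nonzero diagonal")

    def value(self, a: str, b: str) -> float:
        return float(self.d[self.ids.index(a), self.ids.index(b)])


@dataclass
class Cluster:
    members: tuple[str, ...]
    representative: str | None = None


@dataclass
class ClusterSet:
    clusters: list[Cluster]
    stop_distance: float

    def partition(self) -> list[set[str]]:
        return [set(c.members) for c in self.clusters]

    def representatives(self) -> list[str]:
        reps = []
        for c in self.clusters:
            if c.representative is None:
                raise ValueError("cluster has no representative selected")
            reps.append(c.representative)
        return reps


class ReferenceIndex:
    """Forward k-mer position index of one reference genome."""

    def __init__(self, sequence: str, k: int = 16):
        check_dna(sequence, "reference")
        self.sequence = sequence
        self.k = k
        index: dict[str, list[int]] = {}
        for i in range(len(sequence) - k + 1):
            index.setdefault(sequence[i : i + k], []).append(i)
        self.index = index

    def locate(self, fragment: str) -> tuple[int, int] | None:
        """Best (diagonal, votes) over both fragment orientations.

        The diagonal of a shared k-mer is reference position minus fragment
        position; hits are pooled in bins so small indel drift still votes
        together.  Negative votes encode the reverse strand via the caller.
        """
        best: tuple[int, int, str] | None = None
        for strand, frag in (("+", fragment), ("-", revcomp(fragment))):
            votes: dict[int, int] = {}
            anchors: dict[int, int] = {}
            for i in range(len(frag) - self.k + 1):
                for pos in self.index.get(frag[i : i + self.k], ()):
                    b = (pos - i) // _DIAG_BIN
                    votes[b] = votes.get(b, 0) + 1
                    if b not in anchors:
                        anchors[b] = pos - i
            if votes:
                b = min(votes, key=lambda key: (-votes[key], key))
                cand = (anchors[b], votes[b], strand)
                if best is None or cand[1] > best[1]:
                    best = cand
            if best is not None and best[1] >= len(frag) // (2 * self.k):
                break  # forward strand already convincing; skip revcomp scan
        if best is None or best[1] < _MIN_VOTES:
            return None
        diagonal, _votes, strand = best
        return diagonal, (1 if strand == "+" else -1)


def estimate_ani(
    query: SequenceRecord,
    reference: SequenceRecord | ReferenceIndex,
    fragment_length: int = 3000,
    k: int = 16,
    min_fragment_identity: float = 80.0,
) -> AniEstimate:
    """Directional fragment-based ANI of ``query`` against ``reference``."""
    check_dna(query.sequence, f"query {query.id!r}")
    if len(query.sequence) < fragment_length:
        raise ValueError(
            f"query {query.id!r} ({len(query.sequence)} bp) is shorter than one "
            f"fragment ({fragment_length} bp)"
        )
    if isinstance(reference, ReferenceIndex):
        ref_id = getattr(reference, "id", "reference")
        index = reference
    else:
        ref_id = reference.id
        index = ReferenceIndex(reference.sequence, k)
        index.id = ref_id

    n_fragments = len(query.sequence) // fragment_length
    identities: list[float] = []
    ref_seq = index.sequence
    for i in range(n_fragments):
        fragment = query.sequence[i * fragment_length : (i + 1) * fragment_length]
        located = index.locate(fragment)
        if located is None:
            continue
        diagonal, strand = located
        if strand < 0:
            fragment = revcomp(fragment)
        lo = max(0, diagonal - _WINDOW_PAD)
        hi = min(len(ref_seq), diagonal + fragment_length + _WINDOW_PAD)
        identity = edlib_identity(fragment, ref_seq[lo:hi], mode="HW")
        if identity is not None and identity >= min_fragment_identity:
            identities.append(identity)
    ani = float(np.mean(identities)) if identities else None
    return AniEstimate(query.id, ref_id, ani, n_fragments, len(identities))


def build_distance_matrix(
    genome_ids: list[str], estimates: list[AniEstimate]
) -> DistanceMatrix:
    """Symmetrize directional ANI estimates into clustering distances.

    Identity of a pair is the minimum of the two directional ANIs when both
    are defined (conservative), the defined one otherwise; pairs with no
    defined estimate sit at distance 1.0 (below the ~80% detectability
    floor).  d = (100 - identity)/100.
    """
    known = set(genome_ids)
    lookup: dict[tuple[str, str], float | None] = {}
    for est in estimates:
        for gid in (est.query_id, est.reference_id):
            if gid not in known:
                raise ValueError(f"estimate names unknown genome {gid!r}")
        lookup[(est.query_id, est.reference_id)] = est.ani

    n = len(genome_ids)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        a, b = genome_ids[i], genome_ids[j]
        anis = [
            v for v in (lookup.get((a, b)), lookup.get((b, a))) if v is not None
        ]
        identity = min(anis) if anis else None
        dist = 1.0 if identity is None else (100.0 - identity) / 100.0
        d[i, j] = d[j, i] = dist
    return DistanceMatrix(list(genome_ids), d)


def cluster_complete_linkage(matrix: DistanceMatrix, stop_distance: float) -> ClusterSet:
    """Agglomerate while the closest pair of clusters is strictly below the
    stop distance; inter-cluster distance is the maximum member distance.

    Tie-breaking is deterministic: among equally close pairs, the pair whose
    (label, label) key is lexicographically smallest merges first, a cluster's
    label being its smallest member id.  A pair at exactly the stop distance
    (e.g. 99.0% ANI at stop 0.01) is NOT merged, so retained representatives
    may share up to and including the threshold identity.
    """
    if not 0.0 < stop_distance <= 1.0:
        raise ValueError("stop_distance must lie in (0, 1]")
    ids = matrix.ids
    clusters: dict[str, set[str]] = {gid: {gid} for gid in ids}
    # current complete-linkage distances between cluster labels
    dist: dict[tuple[str, str], float] = {}
    pos = {gid: i for i, gid in enumerate(ids)}
    for a, b in itertools.combinations(sorted(ids), 2):
        dist[(a, b)] = float(matrix.d[pos[a], pos[b]])

    while len(clusters) > 1:
        (a, b), dmin = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        if dmin >= stop_distance:
            break
        merged_label = min(a, b)
        merged = clusters.pop(a) | clusters.pop(b)
        clusters[merged_label] = merged
        new_dist: dict[tuple[str, str], float] = {}
        for (x, y), v in dist.items():
            if a in (x, y) or b in (x, y):
                continue
            new_dist[(x, y)] = v
        for label in clusters:
            if label == merged_label:
                continue
            da = dist[tuple(sorted((label, a)))]
            db = dist[tuple(sorted((label, b)))]
            new_dist[tuple(sorted((label, merged_label)))] = max(da, db)
        dist = new_dist

    out = [Cluster(tuple(sorted(members))) for members in clusters.values()]
    out.sort(key=lambda c: c.members[0])
    return ClusterSet(out, stop_distance)


def select_representative(
    member_ids: list[str] | tuple[str, ...], metadata: dict[str, GenomeMetadata]
) -> str:
    """Circular beats noncircular; then larger CheckM score; then larger
    assembly; then smaller genome id."""
    missing = [m for m in member_ids if m not in metadata]
    if missing:
        raise ValueError(f"metadata missing for genomes {missing}")
    ranked = sorted(
        member_ids,
        key=lambda g: (
            not metadata[g].is_circular,
            -checkm_score(metadata[g].completeness, metadata[g].contamination),
            -metadata[g].assembly_size,
            g,
        ),
    )
    return ranked[0]


def pairwise_estimates(
    genomes: list[SequenceRecord], **ani_kwargs
) -> list[AniEstimate]:
    """Directional ANI for all ordered pairs, reusing one index per reference."""
    k = ani_kwargs.get("k", 16)
    indexes: dict[str, ReferenceIndex] = {}
    for g in genomes:
        idx = ReferenceIndex(g.sequence, k)
        idx.id = g.id
        indexes[g.id] = idx
    estimates = []
    for q, r in itertools.permutations(genomes, 2):
        estimates.append(estimate_ani(q, indexes[r.id], **ani_kwargs))
    return estimates


def symmetrized_ani(a: SequenceRecord, b: SequenceRecord, **ani_kwargs) -> float | None:
    anis = [
        est.ani
        for est in (estimate_ani(a, b, **ani_kwargs), estimate_ani(b, a, **ani_kwargs))
        if est.ani is not None
    ]
    return min(anis) if anis else None


def dereplicate(
    genomes: list[SequenceRecord],
    metadata: dict[str, GenomeMetadata],
    stop_distance: float,
    distances: DistanceMatrix | None = None,
    **ani_kwargs,
) -> tuple[ClusterSet, list[SequenceRecord]]:
    """Full dereplication: pairwise ANI, distances, complete-linkage clusters,
    one representative per cluster; non-representatives are dropped as
    redundant.  A precomputed ``distances`` matrix skips the ANI stage."""
    by_id = {g.id: g for g in genomes}
    if len(by_id) != len(genomes):
        raise ValueError("duplicate genome ids")
    if distances is None:
        estimates = pairwise_estimates(genomes, **ani_kwargs)
        distances = build_distance_matrix([g.id for g in genomes], estimates)
    clusters = cluster_complete_linkage(distances, stop_distance)
    for cluster in clusters.clusters:
        cluster.representative = select_representative(cluster.members, metadata)
    nonredundant = [by_id[r] for r in sorted(clusters.representatives())]
    return clusters, nonredundant
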