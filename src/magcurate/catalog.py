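"""Nonredundant gene catalogs: greedy clustering and catalog comparison.

Clustering follows the CD-HIT-EST greedy rule at the catalog criteria
(identity > 95%, overlap > 90% of the shorter gene): genes are visited
longest first, compared against existing representatives that share at least
one exact word (default 10-mer), and join the FIRST representative whose
best local alignment clears both the identity and the shorter-sequence
coverage thresholds; otherwise they found a new cluster.  Identity counts
gap columns in the denominator.

Catalog comparison marks a gene as shared when ANY gene of the other catalog
aligns at >=95% identity over >=90% of the shorter sequence (inclusive, per
the confident-overlap definition).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._align import best_local_alignment, check_dna, local_aligner
from .io import SequenceRecord


@dataclass
class GeneCluster:
    representative_id: str
    member_ids: list[str] = field(default_factory=list)


@dataclass
class CatalogComparison:
    shared_a: int
    unique_a: int
    shared_b: int
    unique_b: int
    pairs: list[tuple[str, str, float, float]] = field(default_factory=list)


def _words(seq: str, word_size: int) -> set[str]:
    return {seq[i : i + word_size] for i in range(len(seq) - word_size + 1)}


def _meets(
    a: str,
    b: str,
    aligner,
    min_identity: float,
    min_coverage_of_shorter: float,
) -> tuple[float, float] | None:
    """(identity_fraction, coverage_of_shorter) when the pair clears both
    thresholds, else None."""
    result = best_local_alignment(a, b, aligner)
    if result is None:
        return None
    identity, _columns, span_a, span_b = result
    shorter = min(len(a), len(b))
    span_on_shorter = span_a if len(a) <= len(b) else span_b
    coverage = span_on_shorter / shorter
    if identity / 100.0 >= min_identity and coverage >= min_coverage_of_shorter:
        return identity / 100.0, coverage
    return None


def greedy_cluster_genes(
    genes: list[SequenceRecord],
    min_identity: float = 0.95,
    min_coverage_of_shorter: float = 0.90,
    word_size: int = 10,
    join_best: bool = False,
    use_prefilter: bool = True,
) -> list[GeneCluster]:
    """Greedy incremental clustering, longest gene first.

    ``join_best=True`` switches from CD-HIT's join-first semantics to joining
    the representative with the highest identity (sensitivity analysis).
    ``use_prefilter=False`` disables the shared-word screen (the all-pairs
    reference used to validate it).
    """
    if not genes:
        return []
    for g in genes:
        check_dna(g.sequence, f"gene {g.id!r}")
    aligner = local_aligner()
    ordered = sorted(genes, key=lambda g: (-len(g.sequence), g.id))

    clusters: list[GeneCluster] = []
    rep_seqs: list[str] = []
    rep_words: list[set[str]] = []
    for gene in ordered:
        words = _words(gene.sequence, word_size) if use_prefilter else None
        best: tuple[float, int] | None = None  # (identity, cluster index)
        joined = False
        for ci, cluster in enumerate(clusters):
            if use_prefilter and not (words & rep_words[ci]):
                continue
            hit = _meets(gene.sequence, rep_seqs[ci], aligner, min_identity, min_coverage_of_shorter)
            if hit is None:
                continue
            if not join_best:
                cluster.member_ids.append(gene.id)
                joined = True
                break
            if best is None or hit[0] > best[0]:
                best = (hit[0], ci)
        if join_best and best is not None:
            clusters[best[1]].member_ids.append(gene.id)
            joined = True
        if not joined:
            clusters.append(GeneCluster(gene.id, [gene.id]))
            rep_seqs.append(gene.sequence)
            rep_words.append(_words(gene.sequence, word_size) if use_prefilter else set())
    return clusters


def structure_completeness_ratio(partial_flags: dict[str, str]) -> float:
    """Fraction of genes with both ORF edges present (partial flags "00")."""
    if not partial_flags:
        raise ValueError("no genes given")
    bad = {g: f for g, f in partial_flags.items() if f is None}
    if bad:
        raise ValueError(f"genes missing partial flags: {sorted(bad)}")
    complete = sum(1 for f in partial_flags.values() if f == "00")
    return complete / len(partial_flags)


def compare_catalogs(
    catalog_a: list[SequenceRecord],
    catalog_b: list[SequenceRecord],
    min_identity: float = 0.95,
    min_coverage_of_shorter: float = 0.90,
    word_size: int = 10,
) -> CatalogComparison:
    """Shared/unique gene counts between two catalogs under the
    confident-overlap criteria (both thresholds inclusive)."""
    aligner = local_aligner()
    words_b = [_words(g.sequence, word_size) for g in catalog_b]
    words_a = [_words(g.sequence, word_size) for g in catalog_a]

    pairs: list[tuple[str, str, float, float]] = []

    def shared_count(
        catalog_x, words_x, catalog_y, words_y, record_pairs: bool
    ) -> int:
        n_shared = 0
        for gx, wx in zip(catalog_x, words_x):
            for gy, wy in zip(catalog_y, words_y):
                if not (wx & wy):
                    continue
                hit = _meets(gx.sequence, gy.sequence, aligner, min_identity, min_coverage_of_shorter)
                if hit is not None:
                    n_shared += 1
                    if record_pairs:
                        pairs.append((gx.id, gy.id, hit[0], hit[1]))
                    break
        return n_shared

    shared_a = shared_count(catalog_a, words_a, catalog_b, words_b, True)
    shared_b = shared_count(catalog_b, words_b, catalog_a, words_a, False)
    return CatalogComparison(
        shared_a=shared_a,
        unique_a=len(catalog_a) - shared_a,
        shared_b=shared_b,
        unique_b=len(catalog_b) - shared_b,
        pairs=pairs,
    )
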