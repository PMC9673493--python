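"""Novel strain/species/genus calls.

Genome-level novelty compares a query against a reference genome set by
symmetrized fragment ANI: a match requires ANI strictly above 99% (strain
level) or 95% (species level); anything else is novel at that level.
16S-level novelty uses the best local-alignment identity of a query 16S gene
against a reference 16S set: identity below 97% suggests a novel species,
below 95% a novel genus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from ._align import best_local_alignment, local_aligner
from .ani import ReferenceIndex, estimate_ani
from .io import SequenceRecord

logger = logging.getLogger("magcurate")

_MIN_16S_COLUMNS = 100


@dataclass(frozen=True)
class NoveltyCall:
    genome_id: str
    best_reference_id: str | None
    best_ani: float | None
    novel_strain: bool
    novel_species: bool

    def __post_init__(self) -> None:
        if self.novel_species and not self.novel_strain:
            raise ValueError("a novel species is necessarily a novel strain")


@dataclass(frozen=True)
class SixteenSNoveltyCall:
    genome_id: str
    best_identity: float | None
    call: str  # known_species | novel_species | novel_genus


def genome_novelty(
    query_genomes: list[SequenceRecord],
    reference_genomes: list[SequenceRecord],
    strain_threshold: float = 99.0,
    species_threshold: float = 95.0,
    **ani_kwargs,
) -> list[NoveltyCall]:
    """Best symmetrized ANI against any reference; matched only when ANI is
    strictly above the threshold."""
    if not reference_genomes:
        logger.warning("genome_novelty: empty reference set; all queries called novel")
    k = ani_kwargs.get("k", 16)
    ref_indexes = {}
    for ref in reference_genomes:
        idx = ReferenceIndex(ref.sequence, k)
        idx.id = ref.id
        ref_indexes[ref.id] = idx

    calls = []
    for query in query_genomes:
        qidx = ReferenceIndex(query.sequence, k)
        qidx.id = query.id
        best_ani, best_ref = None, None
        for ref in reference_genomes:
            fwd = estimate_ani(query, ref_indexes[ref.id], **ani_kwargs).ani
            rev = estimate_ani(ref, qidx, **ani_kwargs).ani
            anis = [v for v in (fwd, rev) if v is not None]
            ani = min(anis) if anis else None
            if ani is not None and (best_ani is None or ani > best_ani):
                best_ani, best_ref = ani, ref.id
        matched_strain = best_ani is not None and best_ani > strain_threshold
        matched_species = best_ani is not None and best_ani > species_threshold
        calls.append(
            NoveltyCall(
                genome_id=query.id,
                best_reference_id=best_ref,
                best_ani=best_ani,
                novel_strain=not matched_strain,
                novel_species=not matched_species,
            )
        )
    return calls


def best_16s_identity(
    query_16s: SequenceRecord,
    reference_16s_set: list[SequenceRecord],
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -2.0,
    gap_extend: float = -1.0,
) -> float | None:
    """Best local-alignment identity of a 16S gene against a reference set;
    undefined when no alignment reaches 100 columns."""
    if not query_16s.sequence:
        raise ValueError("empty 16S query")
    aligner = local_aligner(match, mismatch, gap_open, gap_extend)
    best = None
    for ref in reference_16s_set:
        result = best_local_alignment(query_16s.sequence, ref.sequence, aligner)
        if result is None:
            continue
        identity, columns, _sa, _sb = result
        if columns < _MIN_16S_COLUMNS:
            continue
        if best is None or identity > best:
            best = identity
    return best


def taxon_novelty_16s(best_identity: float | None) -> str:
    """identity < 95 (or undefined) -> novel_genus; < 97 -> novel_species;
    >= 97 -> known_species."""
    if best_identity is None or best_identity < 95.0:
        return "novel_genus"
    if best_identity < 97.0:
        return "novel_species"
    return "known_species"


def call_16s_novelty(
    query_16s: SequenceRecord, reference_16s_set: list[SequenceRecord], **kwargs
) -> SixteenSNoveltyCall:
    identity = best_16s_identity(query_16s, reference_16s_set, **kwargs)
    return SixteenSNoveltyCall(query_16s.id, identity, taxon_novelty_16s(identity))
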