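"""MIMAG-style quality ranking and the RNA-completeness criterion.

Quality ranks come from CheckM completeness/contamination alone:
near complete (>=90% completeness, <5% contamination), high quality (>=70%,
<10%), medium quality (>=50%, <10%), else fail.  The contamination cutoffs
are strict by default and configurable to inclusive.

RNA completeness asks for at least one full-length rRNA operon — colocated,
co-oriented full-length 5S, 16S and 23S genes — and at least 18 full-length
tRNA gene copies (alternatively 18 distinct isotypes, the MIMAG reading).
"""

from __future__ import annotations

from dataclasses import dataclass

from .io import FeatureAnnotation, GenomeMetadata, RRNA_TYPES

RANKS = ("near_complete", "high_quality", "medium_quality", "fail")

_RANK_RULES = (
    ("near_complete", 90.0, 5.0),
    ("high_quality", 70.0, 10.0),
    ("medium_quality", 50.0, 10.0),
)


@dataclass(frozen=True)
class QualityRank:
    genome_id: str
    score: float
    rank: str


@dataclass(frozen=True)
class OperonCall:
    contig_id: str
    strand: str
    member_features: tuple[FeatureAnnotation, ...]

    @property
    def span_bp(self) -> int:
        return max(f.end for f in self.member_features) - min(
            f.start for f in self.member_features
        ) + 1


def checkm_score(completeness: float, contamination: float) -> float:
    """completeness - 5 x contamination."""
    if not 0.0 <= completeness <= 100.0:
        raise ValueError("completeness must lie in [0, 100]")
    if contamination < 0.0:
        raise ValueError("contamination must be non-negative")
    return completeness - 5.0 * contamination


def quality_rank(
    metadata: GenomeMetadata, contamination_inclusive: bool = False
) -> QualityRank:
    """First matching rank in decreasing order of stringency, else fail."""
    comp, cont = metadata.completeness, metadata.contamination
    rank = "fail"
    for name, min_comp, max_cont in _RANK_RULES:
        cont_ok = cont <= max_cont if contamination_inclusive else cont < max_cont
        if comp >= min_comp and cont_ok:
            rank = name
            break
    return QualityRank(metadata.genome_id, checkm_score(comp, cont), rank)


def find_rrna_operons(
    annotations: list[FeatureAnnotation], max_gap_bp: int = 5000
) -> list[OperonCall]:
    """Chain same-contig same-strand rRNA genes with gaps <= ``max_gap_bp``;
    a chain is an operon iff it holds a full-length copy of all of 5S, 16S
    and 23S."""
    groups: dict[tuple[str, str], list[FeatureAnnotation]] = {}
    for f in annotations:
        if f.feature_type in RRNA_TYPES:
            groups.setdefault((f.contig_id, f.strand), []).append(f)

    operons: list[OperonCall] = []
    for (contig, strand), feats in sorted(groups.items()):
        feats.sort(key=lambda f: (f.start, f.end))
        chain: list[FeatureAnnotation] = []
        for f in feats + [None]:
            if f is not None and (not chain or f.start - chain[-1].end - 1 <= max_gap_bp):
                chain.append(f)
                continue
            if chain:
                full_types = {m.feature_type for m in chain if m.full_length}
                if full_types >= set(RRNA_TYPES):
                    operons.append(OperonCall(contig, strand, tuple(chain)))
            chain = [f] if f is not None else []
    return operons


def rna_complete(
    annotations: list[FeatureAnnotation],
    min_trna: int = 18,
    trna_mode: str = "copies",
    max_gap_bp: int = 5000,
) -> tuple[bool, dict]:
    """RNA-complete iff >=1 full-length rRNA operon and >= ``min_trna``
    full-length tRNAs (total copies, or distinct isotypes)."""
    if trna_mode not in ("copies", "distinct_isotypes"):
        raise ValueError(f"unknown trna_mode {trna_mode!r}")
    operons = find_rrna_operons(annotations, max_gap_bp)
    full_trnas = [
        f for f in annotations if f.feature_type == "tRNA" and f.full_length
    ]
    if trna_mode == "copies":
        trna_count = len(full_trnas)
    else:
        trna_count = len({f.isotype for f in full_trnas if f.isotype is not None})
    operon_ok = len(operons) >= 1
    trna_ok = trna_count >= min_trna
    detail = {
        "operon_count": len(operons),
        "trna_count": trna_count,
        "trna_mode": trna_mode,
        "operon_ok": operon_ok,
        "trna_ok": trna_ok,
    }
    return operon_ok and trna_ok, detail
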