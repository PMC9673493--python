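"""Shared alignment primitives.

Edit-distance alignments (global and infix) go through edlib; score-based
local alignments through Bio.Align.PairwiseAligner.  Identity is always
matches / alignment columns, gap columns included.
"""

from __future__ import annotations

import re

import edlib
from Bio import Align

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")

DNA_ALPHABET = set("ACGTN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def check_dna(seq: str, label: str = "sequence") -> None:
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise ValueError(f"{label} contains non-DNA characters {sorted(bad)}")


def edlib_identity(query: str, target: str, mode: str = "NW") -> float | None:
    """Percent identity of the best edit alignment of query against target.

    ``mode="NW"`` is global; ``mode="HW"`` aligns the whole query inside the
    target (infix).  Returns None when edlib reports no alignment.
    """
    res = edlib.align(query, target, task="path", mode=mode)
    if res["editDistance"] < 0 or not res.get("cigar"):
        return None
    columns = sum(int(n) for n, _op in _CIGAR_RE.findall(res["cigar"]))
    if columns == 0:
        return None
    matches = columns - res["editDistance"]
    return 100.0 * matches / columns


def local_aligner(
    match: float = 1.0, mismatch: float = -1.0, gap_open: float = -2.0, gap_extend: float = -1.0
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def best_local_alignment(
    a: str, b: str, aligner: Align.PairwiseAligner
) -> tuple[float, int, int, int] | None:
    """Best-scoring local alignment of ``a`` vs ``b``.

    Returns (identity_percent, alignment_columns, span_on_a, span_on_b), or
    None when no positive-scoring alignment exists.
    """
    if aligner.score(a, b) <= 0:
        return None
    aln = aligner.align(a, b)[0]
    counts = aln.counts()
    columns = (
        counts.identities
        + counts.mismatches
        + counts.internal_insertions
        + counts.internal_deletions
    )
    if columns == 0:
        return None
    identity = 100.0 * counts.identities / columns
    blocks_a, blocks_b = aln.aligned
    span_a = int(blocks_a[-1][1] - blocks_a[0][0])
    span_b = int(blocks_b[-1][1] - blocks_b[0][0])
    return identity, columns, span_a, span_b
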