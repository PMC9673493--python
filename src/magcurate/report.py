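"""Run-statistics aggregation and composition summaries.

Counts are summed as exact integers; N50 is only ever computed from pooled
per-read lengths (it is not additive across groups), and reported
percentages use round-half-up, matching how the ratios in the source tables
were printed.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import pandas as pd


@dataclass(frozen=True)
class RunStats:
    label: str
    n_reads: int
    n_bases: int
    n50_bp: int | None = None
    median_q: float | None = None

    def __post_init__(self) -> None:
        if self.n_reads < 0 or self.n_bases < 0:
            raise ValueError("negative counts")
        if self.n_reads > 0 and self.n_bases < self.n_reads:
            raise ValueError("fewer bases than reads")


def n50(lengths: Sequence[int]) -> int:
    """Smallest length whose descending cumulative sum first reaches half the
    total."""
    if not lengths:
        raise ValueError("n50 of no lengths")
    ordered = sorted(lengths, reverse=True)
    total = sum(ordered)
    running = 0
    for length in ordered:
        running += length
        if 2 * running >= total:
            return length
    raise AssertionError("unreachable")


def aggregate_run_stats(
    per_group_stats: Sequence[RunStats],
    read_lengths: Sequence[int] | None = None,
    read_qualities: Sequence[float] | None = None,
    label: str = "All",
) -> RunStats:
    """Exact totals row; N50/median quality only from pooled per-read values."""
    if not per_group_stats:
        raise ValueError("no groups to aggregate")
    total_reads = sum(s.n_reads for s in per_group_stats)
    total_bases = sum(s.n_bases for s in per_group_stats)
    pooled_n50 = n50(read_lengths) if read_lengths else None
    median_q = float(pd.Series(read_qualities).median()) if read_qualities else None
    return RunStats(label, total_reads, total_bases, pooled_n50, median_q)


def percent_round(numerator: float, denominator: float, decimals: int = 0) -> float:
    """Round-half-up percentage at the stated precision."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    quantum = Decimal(1).scaleb(-decimals)
    value = Decimal(100) * Decimal(str(numerator)) / Decimal(str(denominator))
    return float(value.quantize(quantum, rounding=ROUND_HALF_UP))


def composition_summary(classification_labels: Iterable[str]) -> pd.DataFrame:
    """(label, count, percent-to-1-decimal) sorted by descending count."""
    labels = list(classification_labels)
    if not labels:
        raise ValueError("no classification labels")
    counts = pd.Series(labels).value_counts()
    total = int(counts.sum())
    df = pd.DataFrame(
        {
            "label": counts.index,
            "count": counts.to_numpy(),
            "percent": [percent_round(c, total, 1) for c in counts],
        }
    )
    return df.sort_values(["count", "label"], ascending=[False, True], ignore_index=True)
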