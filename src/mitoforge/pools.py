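"""Quality-stratified read pools and library coverage arithmetic.

Recruited pairs are filtered at per-base quality thresholds (QV >= 20,
25, 30 by default; a read passes only when *every* base meets the
threshold). Each threshold yields two pools: PE-only (pairs in which
both mates passed) and PE+SE (the same pairs plus the surviving mate of
each broken pair), six pools in total with the default thresholds.
Assembling every pool independently at every k is what gives the
multi-k sweep its redundancy.

Coverage of a pool is the shotgun estimate C = (N * L * 2) / G for N
pairs of length-L reads plus (N_se * L) / G for singles, with G the
assumed mitogenome size (default 16,500 bp), reported rounded half-up
to the nearest integer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Iterable, Sequence

from .seqcore import QualityRead, ReadPair

DEFAULT_THRESHOLDS = (20, 25, 30)
DEFAULT_GENOME_SIZE = 16_500


class PoolMode(str, Enum):
    PE_ONLY = "PE"
    PE_PLUS_SE = "PE+SE"


class PairFilterResult(str, Enum):
    BOTH_PASS = "BOTH_PASS"
    FIRST_ONLY = "FIRST_ONLY"
    SECOND_ONLY = "SECOND_ONLY"
    NONE = "NONE"


def filter_pair(pair: ReadPair, qv_threshold: int) -> PairFilterResult:
    """Classify a pair by which mates have all bases at Phred >= threshold."""
    p1 = pair.first.min_qual >= qv_threshold if len(pair.first) else True
    p2 = pair.second.min_qual >= qv_threshold if len(pair.second) else True
    if p1 and p2:
        return PairFilterResult.BOTH_PASS
    if p1:
        return PairFilterResult.FIRST_ONLY
    if p2:
        return PairFilterResult.SECOND_ONLY
    return PairFilterResult.NONE


@dataclass
class ReadPool:
    """Reads surviving one (threshold, mode) cell of the pool grid."""

    qv_threshold: int
    mode: PoolMode
    pairs: list[ReadPair] = field(default_factory=list)
    singles: list[QualityRead] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.mode is PoolMode.PE_ONLY and self.singles:
            raise ValueError("PE_ONLY pool cannot contain single-end reads")

    @property
    def label(self) -> str:
        return f"QV{self.qv_threshold}_{self.mode.value}"

    def all_reads(self) -> list[QualityRead]:
        reads = [r for pair in self.pairs for r in pair.reads()]
        reads.extend(self.singles)
        return reads

    @property
    def n_reads(self) -> int:
        return 2 * len(self.pairs) + len(self.singles)


def build_pools(
    pairs: Sequence[ReadPair],
    thresholds: Iterable[int] = DEFAULT_THRESHOLDS,
    ) -> list[ReadPool]:
    """Build the PE-only and PE+SE pools for each quality threshold.

    Returns ``2 * len(thresholds)`` pools; for each threshold the
    PE-only pool holds exactly the pairs of the PE+SE pool, and singles
    (the surviving mate of a broken pair) appear only in PE+SE.
    """
    thresholds = list(thresholds)
    if not thresholds:
        raise ValueError("at least one quality threshold is required")
    pools: list[ReadPool] = []
    for t in thresholds:
        kept_pairs: list[ReadPair] = []
        singles: list[QualityRead] = []
        for pair in pairs:
            verdict = filter_pair(pair, t)
            if verdict is PairFilterResult.BOTH_PASS:
                kept_pairs.append(pair)
            elif verdict is PairFilterResult.FIRST_ONLY:
                singles.append(pair.first)
            elif verdict is PairFilterResult.SECOND_ONLY:
                singles.append(pair.second)
        pools.append(ReadPool(qv_threshold=t, mode=PoolMode.PE_ONLY, pairs=list(kept_pairs)))
        pools.append(
            ReadPool(
                qv_threshold=t,
                mode=PoolMode.PE_PLUS_SE,
                pairs=list(kept_pairs),
                singles=singles,
            )
        )
    return pools


def _round_half_up(value: Decimal) -> int:
    return int(value.quantize(Decimal("1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class PoolStats:
    """Library statistics for one pool: base counts and estimated coverage."""

    n_pairs: int
    n_singles: int
    read_length: int
    genome_size_assumed: int
    total_bases: int
    coverage: int


def estimate_coverage(
    n_pairs: int,
    n_singles: int,
    read_length: int = 90,
    genome_size: int = DEFAULT_GENOME_SIZE,
) -> PoolStats:
    """Closed-form coverage for fixed-length reads: (N*L*2 + N_se*L) / G."""
    if read_length <= 0:
        raise ValueError("read_length must be > 0")
    if genome_size <= 0:
        raise ValueError("genome_size must be > 0")
    total_bases = n_pairs * read_length * 2 + n_singles * read_length
    coverage = _round_half_up(Decimal(total_bases) / Decimal(genome_size))
    return PoolStats(
        n_pairs=n_pairs,
        n_singles=n_singles,
        read_length=read_length,
        genome_size_assumed=genome_size,
        total_bases=total_bases,
        coverage=coverage,
    )


def pool_stats(pool: ReadPool, genome_size: int = DEFAULT_GENOME_SIZE) -> PoolStats:
    """Statistics of an in-memory pool, summing actual base counts.

    Supports variable read lengths; the coverage figure is
    round-half-up(total_bases / G) as in :func:`estimate_coverage`.
    """
    if genome_size <= 0:
        raise ValueError("genome_size must be > 0")
    total_bases = sum(len(r) for r in pool.all_reads())
    lengths = {len(r) for r in pool.all_reads()}
    read_length = lengths.pop() if len(lengths) == 1 else 0  # 0 marks mixed lengths
    coverage = _round_half_up(Decimal(total_bases) / Decimal(genome_size))
    return PoolStats(
        n_pairs=len(pool.pairs),
        n_singles=len(pool.singles),
        read_length=read_length,
        genome_size_assumed=genome_size,
        total_bases=total_bases,
        coverage=coverage,
    )
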