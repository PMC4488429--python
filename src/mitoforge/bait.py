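"""Reference-assisted recruitment of putatively mitochondrial read pairs.

A whole-genome shotgun library from a vertebrate contains mitochondrial
reads at a tiny fraction (on the order of 0.04% of reads for a ~16.5 kb
organelle in a ~3 Gb genome). Before assembly those reads are "baited"
out using a related species' mitogenome as the reference. Here the
recruitment screen is an exact canonical-seed containment test: the
circular reference is decomposed into all length-``seed_k`` substrings
(both strands, wrapping the linearization origin), stored in canonical
form (lexicographic min of a seed and its reverse complement), and a
pair is kept when at least one mate carries ``min_hits`` seeds found in
the index. Both mates of a selected pair are kept — single-mate rescue —
so that pairing information survives into the read pools.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable

from .seqcore import ReadPair, clean_sequence, revcomp


class BaitParameterError(ValueError):
    pass


def canonical_kmer(kmer: str) -> str:
    """Lexicographic minimum of a k-mer and its reverse complement."""
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


@dataclass(frozen=True)
class ReferenceIndex:
    """Canonical seed k-mers of a circular reference genome.

    Seeds containing N are skipped. ``seed_k`` must be odd so no seed is
    its own reverse complement (which would make canonical counting
    double-book strand hits).
    """

    seed_k: int
    seeds: frozenset[str]
    ref_length: int


def build_reference_index(reference: str, seed_k: int = 31) -> ReferenceIndex:
    """Index every canonical seed of the circular ``reference``.

    The reference is treated as circular: seeds spanning the
    linearization point are included by scanning the sequence extended
    with its own first ``seed_k - 1`` bases.
    """
    if seed_k < 11 or seed_k % 2 == 0:
        raise BaitParameterError(f"seed_k must be odd and >= 11, got {seed_k}")
    ref = clean_sequence(reference)
    if len(ref) <= seed_k:
        raise BaitParameterError(
            f"reference length {len(ref)} must exceed seed_k {seed_k}"
        )
    extended = ref + ref[: seed_k - 1]
    rc_extended = revcomp(extended)
    n = len(extended)
    seeds = set()
    for i in range(len(ref)):
        fwd = extended[i : i + seed_k]
        if "N" in fwd:
            continue
        rev = rc_extended[n - i - seed_k : n - i]
        seeds.add(fwd if fwd <= rev else rev)
    return ReferenceIndex(seed_k=seed_k, seeds=frozenset(seeds), ref_length=len(ref))


def count_seed_hits(seq: str, index: ReferenceIndex) -> int:
    """Number of positions in ``seq`` whose canonical seed is in the index.

    Reads shorter than ``seed_k`` contribute no hits (rescue via the mate
    is still possible). Seeds containing N never match.
    """
    k = index.seed_k
    if len(seq) < k:
        return 0
    rc = revcomp(seq)
    n = len(seq)
    seeds = index.seeds
    hits = 0
    for i in range(n - k + 1):
        fwd = seq[i : i + k]
        if "N" in fwd:
            continue
        rev = rc[n - i - k : n - i]
        if (fwd if fwd <= rev else rev) in seeds:
            hits += 1
    return hits


@dataclass(frozen=True)
class BaitReport:
    total_pairs: int
    baited_pairs: int
    pairs_hit_by_one_mate: int
    pairs_hit_by_both: int
    alignment_rate: float

    def __post_init__(self) -> None:
        assert self.baited_pairs == self.pairs_hit_by_one_mate + self.pairs_hit_by_both

    def as_dict(self) -> dict:
        return {
            "total_pairs": self.total_pairs,
            "baited_pairs": self.baited_pairs,
            "pairs_hit_by_one_mate": self.pairs_hit_by_one_mate,
            "pairs_hit_by_both": self.pairs_hit_by_both,
            "alignment_rate": self.alignment_rate,
        }


def alignment_rate(mapped_reads: int, total_reads: int) -> float:
    """Percentage of reads recruited, rounded half-up to 2 decimals.

    E.g. 222,251 recruited of 574,495,990 total reads → 0.04.
    """
    if total_reads <= 0:
        raise BaitParameterError("total_reads must be > 0")
    if mapped_reads > total_reads:
        raise BaitParameterError("mapped_reads cannot exceed total_reads")
    pct = Decimal(mapped_reads) * 100 / Decimal(total_reads)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def bait_pairs(
    pairs: Iterable[ReadPair], index: ReferenceIndex, min_hits: int = 1
) -> tuple[list[ReadPair], BaitReport]:
    """Select pairs in which at least one mate carries ``min_hits`` reference seeds.

    Both mates of a selected pair are emitted even when only one mate
    hit the index (pair rescue). An empty stream yields an empty
    selection with a zeroed report.
    """
    if min_hits < 1:
        raise BaitParameterError(f"min_hits must be >= 1, got {min_hits}")
    selected: list[ReadPair] = []
    total = 0
    one_mate = 0
    both = 0
    mapped_reads = 0
    for pair in pairs:
        total += 1
        hit1 = count_seed_hits(pair.first.seq, index) >= min_hits
        hit2 = count_seed_hits(pair.second.seq, index) >= min_hits
        mapped_reads += int(hit1) + int(hit2)
        if hit1 and hit2:
            both += 1
            selected.append(pair)
        elif hit1 or hit2:
            one_mate += 1
            selected.append(pair)
    rate = alignment_rate(mapped_reads, 2 * total) if total else 0.0
    report = BaitReport(
        total_pairs=total,
        baited_pairs=len(selected),
        pairs_hit_by_one_mate=one_mate,
        pairs_hit_by_both=both,
        alignment_rate=rate,
    )
    return selected, report
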