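"""Synthetic paired-end sequencing of a circular mitogenome, with ground truth.

Emulates the study design the pipeline targets: a ~16.5 kb circular
genome shotgun-sequenced as 2×90 bp read pairs from ~500 bp fragments,
mixed into a large excess-free but configurable fraction of
non-mitochondrial ("decoy") pairs standing in for the nuclear
background. Fragments wrap the circular origin, so the linearization
junction is covered and end-overlap circularization is testable.

The error model is substitution-only (Illumina-like). Per-base Phred
scores follow a tiered profile: each read draws a quality tier whose
floor straddles the 20/25/30 pool thresholds, and erroneous bases
always receive low scores (Phred 2–19), so the all-bases QV filters
partition reads the way real quality stratification does.

Everything is reproducible from the config seed; the returned
:class:`GroundTruth` records each pair's origin, position, strand and
planted errors, so any emitted read can be reconstructed exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .finish import canonicalize
from .seqcore import QualityRead, ReadPair, revcomp

_BASES = np.array(list("ACGT"))
_BASE_TO_IDX = {b: i for i, b in enumerate("ACGT")}


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class QualityProfile:
    """Phred-score model: read-level quality tiers plus an error-base range.

    ``tiers`` maps a quality floor to its probability; a read in tier
    (floor, p) draws correct-base scores uniformly in [floor, 40].
    Erroneous bases draw from ``error_qual`` regardless of tier, so a
    read containing an error fails every all-bases QV >= 20 filter.
    """

    tiers: tuple[tuple[int, float], ...] = ((30, 0.35), (25, 0.30), (20, 0.25), (10, 0.10))
    max_qual: int = 40
    error_qual: tuple[int, int] = (2, 19)

    def __post_init__(self) -> None:
        if abs(sum(p for _, p in self.tiers) - 1.0) > 1e-9:
            raise SimulationError("tier probabilities must sum to 1")


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of one simulated library."""

    genome_length: int = 16_563
    gc_fraction: float = 0.44
    n_pairs: int = 37_500
    read_length: int = 90
    insert_mean: float = 500.0
    insert_sd: float = 50.0
    substitution_error_rate: float = 0.01
    quality_profile: QualityProfile = field(default_factory=QualityProfile)
    decoy_fraction: float = 0.2
    decoy_gc_fraction: float = 0.40
    decoy_length: int = 50_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("gc_fraction", "substitution_error_rate", "decoy_fraction",
                     "decoy_gc_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"{name} must be in [0, 1], got {v}")
        if self.genome_length <= 0 or self.n_pairs < 0 or self.read_length <= 0:
            raise SimulationError("sizes and counts must be positive")
        if 2 * self.read_length > self.insert_mean + 3 * self.insert_sd:
            raise SimulationError(
                "insert size distribution cannot accommodate two reads: "
                f"need 2*{self.read_length} <= {self.insert_mean} + 3*{self.insert_sd}"
            )


@dataclass(frozen=True)
class PairTruth:
    origin: str  # "genome" or "decoy"
    start: int  # fragment start on the source (0-based)
    insert: int
    strand: str  # "+" fragment read as-is, "-" reverse-complemented
    errors_r1: tuple[tuple[int, str], ...]  # (position in read, substituted base)
    errors_r2: tuple[tuple[int, str], ...]


@dataclass
class GroundTruth:
    genome: str
    decoy_genome: str
    pairs: list[PairTruth]

    @property
    def n_genome_pairs(self) -> int:
        return sum(1 for p in self.pairs if p.origin == "genome")

    @property
    def n_planted_errors(self) -> int:
        return sum(len(p.errors_r1) + len(p.errors_r2) for p in self.pairs)


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=length, p=p)])


def _has_repeated_window(seq: str, window: int, circular: bool) -> bool:
    text = seq + seq[: window - 1] if circular else seq
    n_windows = len(text) - window + 1
    seen = set()
    for i in range(n_windows):
        w = text[i : i + window]
        if w in seen:
            return True
        seen.add(w)
    return False


def simulate_genome(
    length: int = 16_563,
    gc_fraction: float = 0.44,
    seed: int = 0,
    repeat_free_window: int = 100,
    max_retries: int = 20,
) -> str:
    """I.i.d. random circular genome with no exact repeated 100-mer.

    The repeat-free constraint (checked across the circular wrap) keeps
    the genome assemblable into a single unitig at every k the sweep
    uses. Deterministic for a fixed seed.
    """
    if length <= 0:
        raise SimulationError("length must be positive")
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        seq = _random_sequence(rng, length, gc_fraction)
        if length <= repeat_free_window or not _has_repeated_window(
            seq, repeat_free_window, circular=True
        ):
            return seq
    raise SimulationError(
        f"could not draw a repeat-free genome in {max_retries} attempts"
    )


def _canonical_kmer_set(seq: str, k: int, circular: bool) -> set[str]:
    text = seq + seq[: k - 1] if circular else seq
    rc = revcomp(text)
    n = len(text)
    out = set()
    for i in range(n - k + 1):
        f = text[i : i + k]
        r = rc[n - i - k : n - i]
        out.add(f if f <= r else r)
    return out


def _simulate_decoy(rng: np.random.Generator, genome: str, config: SimConfig) -> str:
    """Linear background sequence sharing no canonical 31-mer with the target."""
    target = _canonical_kmer_set(genome, 31, circular=True)
    for _ in range(20):
        decoy = _random_sequence(rng, config.decoy_length, config.decoy_gc_fraction)
        if not (_canonical_kmer_set(decoy, 31, circular=False) & target):
            return decoy
    raise SimulationError("could not draw a decoy sharing no 31-mer with the target")


def _apply_errors_and_quals(
    read_seq: str,
    rng: np.random.Generator,
    rate: float,
    tier_floor: int,
    profile: QualityProfile,
) -> tuple[str, tuple[int, ...], tuple[tuple[int, str], ...]]:
    n = len(read_seq)
    quals = rng.integers(tier_floor, profile.max_qual + 1, size=n)
    if rate <= 0:
        return read_seq, tuple(int(q) for q in quals), ()
    err_mask = rng.random(n) < rate
    errors: list[tuple[int, str]] = []
    if err_mask.any():
        seq_list = list(read_seq)
        lo, hi = profile.error_qual
        for pos in np.flatnonzero(err_mask):
            pos = int(pos)
            orig = seq_list[pos]
            choices = [b for b in "ACGT" if b != orig]
            new = choices[int(rng.integers(0, 3))]
            seq_list[pos] = new
            quals[pos] = int(rng.integers(lo, hi + 1))
            errors.append((pos, new))
        read_seq = "".join(seq_list)
    return read_seq, tuple(int(q) for q in quals), tuple(errors)


def simulate_pairs(
    genome: str, config: SimConfig
) -> tuple[list[QualityRead], list[QualityRead], GroundTruth]:
    """Draw ``config.n_pairs`` read pairs from the genome and decoy background.

    Fragment starts are uniform on the circle (wrapping allowed);
    insert sizes are truncated-normal; mates read inward from the
    fragment ends with R2 reverse-complemented. Decoy pairs are drawn
    from an independent linear sequence. Fully reproducible by seed.
    """
    if len(genome) != config.genome_length:
        raise SimulationError(
            f"genome length {len(genome)} != config.genome_length {config.genome_length}"
        )
    rng = np.random.default_rng(config.seed)
    L = config.read_length
    n_total = config.n_pairs
    n_decoy = int(round(config.decoy_fraction * n_total))
    decoy = _simulate_decoy(rng, genome, config) if n_decoy else ""

    # which pair indices are decoys (uniform placement, reproducible)
    decoy_idx = set(rng.choice(n_total, size=n_decoy, replace=False).tolist()) if n_decoy else set()

    inserts = np.clip(
        np.rint(rng.normal(config.insert_mean, config.insert_sd, size=n_total)),
        L,
        None,
    ).astype(int)
    strands = rng.random(n_total) < 0.5
    tier_floors, tier_probs = zip(*config.quality_profile.tiers)
    tiers = rng.choice(len(tier_floors), size=2 * n_total, p=np.array(tier_probs))

    doubled = genome + genome
    r1_reads: list[QualityRead] = []
    r2_reads: list[QualityRead] = []
    truths: list[PairTruth] = []
    for i in range(n_total):
        insert = int(inserts[i])
        if i in decoy_idx:
            origin = "decoy"
            insert = min(insert, len(decoy))
            start = int(rng.integers(0, len(decoy) - insert + 1))
            frag = decoy[start : start + insert]
        else:
            origin = "genome"
            insert = min(insert, len(genome))
            start = int(rng.integers(0, len(genome)))
            frag = doubled[start : start + insert]  # wraps the circular origin
        strand = "-" if strands[i] else "+"
        if strand == "-":
            frag = revcomp(frag)
        r1_raw = frag[:L]
        r2_raw = revcomp(frag[-L:])
        seq1, quals1, errs1 = _apply_errors_and_quals(
            r1_raw, rng, config.substitution_error_rate,
            tier_floors[tiers[2 * i]], config.quality_profile,
        )
        seq2, quals2, errs2 = _apply_errors_and_quals(
            r2_raw, rng, config.substitution_error_rate,
            tier_floors[tiers[2 * i + 1]], config.quality_profile,
        )
        name = f"sim_{i:07d}"
        r1_reads.append(QualityRead(id=f"{name}/1", seq=seq1, quals=quals1, mate=1))
        r2_reads.append(QualityRead(id=f"{name}/2", seq=seq2, quals=quals2, mate=2))
        truths.append(
            PairTruth(
                origin=origin, start=start, insert=insert, strand=strand,
                errors_r1=errs1, errors_r2=errs2,
            )
        )
    truth = GroundTruth(genome=genome, decoy_genome=decoy, pairs=truths)
    return r1_reads, r2_reads, truth


def simulate_library(config: SimConfig) -> tuple[list[ReadPair], GroundTruth]:
    """Convenience wrapper: genome + pairs in one call, as ReadPair objects."""
    genome = simulate_genome(config.genome_length, config.gc_fraction, config.seed)
    r1, r2, truth = simulate_pairs(genome, config)
    pairs = [ReadPair(first=a, second=b) for a, b in zip(r1, r2)]
    return pairs, truth


@dataclass(frozen=True)
class RecoveryResult:
    status: str  # EXACT | ROTATION_RC_EXACT | MISMATCHES | FAIL
    mismatches: int | None = None
    detail: str = ""


def recovery_check(
    selected: str, truth: GroundTruth, max_length_diff: int = 100
) -> RecoveryResult:
    """Compare an assembled circular sequence against the planted genome.

    EXACT: verbatim identity. ROTATION_RC_EXACT: identical after
    rotation/strand normalization (canonical forms equal). MISMATCHES:
    canonical forms align with a small edit distance. FAIL: lengths
    differ by more than ``max_length_diff`` or the sequences are
    unrelated.
    """
    import edlib

    if not selected or not truth.genome:
        raise ValueError("both sequences must be nonempty")
    if selected == truth.genome:
        return RecoveryResult(status="EXACT")
    canon_sel, _ = canonicalize(selected)
    canon_truth, _ = canonicalize(truth.genome)
    if canon_sel == canon_truth:
        return RecoveryResult(status="ROTATION_RC_EXACT")
    if abs(len(selected) - len(truth.genome)) > max_length_diff:
        return RecoveryResult(
            status="FAIL",
            detail=f"length {len(selected)} vs {len(truth.genome)}",
        )
    # rotation-tolerant distance: best hit of the candidate in the doubled truth
    aln = edlib.align(canon_sel, canon_truth + canon_truth, mode="HW", task="distance")
    dist = aln["editDistance"]
    if dist < 0 or dist > max(10, len(canon_truth) // 10):
        return RecoveryResult(status="FAIL", detail=f"edit distance {dist}")
    return RecoveryResult(status="MISMATCHES", mismatches=dist)
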