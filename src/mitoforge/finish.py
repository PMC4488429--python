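"""Finishing: circularize contigs, canonicalize, cluster, pick the consensus.

A circular molecule sequenced and assembled as a linear contig carries
the same sequence at both ends (for a unitig assembler, exactly the
k-1 terminal bases). Finishing proceeds as:

1. detect the end overlap and trim it once (circularization);
2. keep candidates whose circular length falls in the expected
   mitogenome window (16,500–16,700 bp by default, bounds inclusive);
3. reduce every candidate to a canonical form — the lexicographically
   least string over all rotations of the sequence and all rotations
   of its reverse complement — so candidates from different assembly
   jobs are comparable regardless of start point and strand;
4. cluster candidates by exact canonical-string identity, recording
   how many members arose from forward vs reverse strand contigs;
5. the representative of the largest cluster is the consensus genome.
   A tie for largest is a hard error: the pipeline refuses to pick
   silently.

FORWARD/REVERSE strand form is defined relative to the canonical
string, not to the biological heavy strand.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

from .assemble import Contig
from .seqcore import revcomp

DEFAULT_MIN_OVERLAP = 20
DEFAULT_SIZE_WINDOW = (16_500, 16_700)


class NoCandidateError(RuntimeError):
    """The sweep produced no size-window circular candidate."""


class AmbiguousConsensusError(RuntimeError):
    """Two or more clusters tie for largest; carries their representatives."""

    def __init__(self, representatives: list[str]):
        super().__init__(
            f"{len(representatives)} clusters tie for largest; refusing to pick"
        )
        self.representatives = representatives


class StrandForm(str, Enum):
    FORWARD = "FORWARD"
    REVERSE = "REVERSE"


def least_rotation_index(s: str) -> int:
    """Start index of the lexicographically least rotation (Booth, O(n))."""
    if not s:
        return 0
    ss = s + s
    n = len(ss)
    fail = [-1] * n
    k = 0
    for j in range(1, n):
        cj = ss[j]
        i = fail[j - k - 1]
        while i != -1 and cj != ss[k + i + 1]:
            if cj < ss[k + i + 1]:
                k = j - i - 1
            i = fail[i]
        if cj != ss[k + i + 1]:
            if cj < ss[k]:
                k = j
            fail[j - k] = -1
        else:
            fail[j - k] = i + 1
    return k


def canonicalize(circular_seq: str) -> tuple[str, StrandForm]:
    """Canonical form of a circular sequence, strand/rotation independent.

    Returns the least string among all rotations of ``circular_seq``
    and of its reverse complement, and which strand it came from (ties
    between strands resolve to FORWARD).
    """
    if not circular_seq:
        raise ValueError("cannot canonicalize an empty sequence")
    i = least_rotation_index(circular_seq)
    fwd = circular_seq[i:] + circular_seq[:i]
    rc = revcomp(circular_seq)
    j = least_rotation_index(rc)
    rev = rc[j:] + rc[:j]
    if fwd <= rev:
        return fwd, StrandForm.FORWARD
    return rev, StrandForm.REVERSE


def find_end_overlap(
    contig: str,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_mismatch_rate: float = 0.0,
) -> int | None:
    """Longest m >= min_overlap with the contig's prefix matching its suffix.

    Exact by default; with ``max_mismatch_rate`` > 0 a Hamming mismatch
    fraction up to the rate is tolerated. Returns None when no length
    qualifies (in particular for contigs shorter than 2*min_overlap).
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    n = len(contig)
    if n < 2 * min_overlap:
        return None
    for m in range(n // 2, min_overlap - 1, -1):
        if max_mismatch_rate <= 0:
            if contig[:m] == contig[n - m :]:
                return m
        else:
            budget = int(max_mismatch_rate * m)
            mism = 0
            for a, b in zip(contig[:m], contig[n - m :]):
                if a != b:
                    mism += 1
                    if mism > budget:
                        break
            if mism <= budget:
                return m
    return None


def circularize(
    contig: str,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_mismatch_rate: float = 0.0,
) -> str | None:
    """Merge the terminal repeat: drop the last m bases on an m-base overlap."""
    m = find_end_overlap(contig, min_overlap, max_mismatch_rate)
    if m is None:
        return None
    return contig[:-m]


@dataclass(frozen=True)
class CircularCandidate:
    """A circularized, canonicalized candidate genome with provenance."""

    canonical_seq: str
    source_k: int
    source_pool: str
    observed_strand_form: StrandForm

    @property
    def length(self) -> int:
        return len(self.canonical_seq)


def circularize_contigs(
    contigs: Iterable[Contig],
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_mismatch_rate: float = 0.0,
) -> list[CircularCandidate]:
    """Circularize and canonicalize every contig with a detectable end overlap."""
    candidates = []
    for contig in contigs:
        circ = circularize(contig.seq, min_overlap, max_mismatch_rate)
        if circ is None:
            continue
        canonical, strand = canonicalize(circ)
        candidates.append(
            CircularCandidate(
                canonical_seq=canonical,
                source_k=contig.k,
                source_pool=contig.pool_label,
                observed_strand_form=strand,
            )
        )
    return candidates


def size_filter(
    candidates: Sequence[CircularCandidate],
    lo: int = DEFAULT_SIZE_WINDOW[0],
    hi: int = DEFAULT_SIZE_WINDOW[1],
) -> list[CircularCandidate]:
    """Keep candidates with lo <= length <= hi (both bounds inclusive)."""
    if lo > hi:
        raise ValueError(f"size window lower bound {lo} exceeds upper bound {hi}")
    return [c for c in candidates if lo <= c.length <= hi]


@dataclass(frozen=True)
class CandidateCluster:
    representative: str
    members: tuple[CircularCandidate, ...]

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def n_forward(self) -> int:
        return sum(1 for m in self.members if m.observed_strand_form is StrandForm.FORWARD)

    @property
    def n_reverse(self) -> int:
        return sum(1 for m in self.members if m.observed_strand_form is StrandForm.REVERSE)


def cluster_candidates(
    candidates: Sequence[CircularCandidate],
) -> list[CandidateCluster]:
    """Equivalence classes of exact canonical-sequence identity.

    Sorted by size descending, ties by representative lexicographic.
    """
    groups: dict[str, list[CircularCandidate]] = defaultdict(list)
    for cand in candidates:
        groups[cand.canonical_seq].append(cand)
    clusters = [
        CandidateCluster(representative=seq, members=tuple(members))
        for seq, members in groups.items()
    ]
    clusters.sort(key=lambda c: (-c.size, c.representative))
    return clusters


def select_consensus(
    clusters: Sequence[CandidateCluster],
) -> tuple[CircularCandidate, dict]:
    """Representative of the largest cluster, plus a selection report.

    Raises :class:`NoCandidateError` on an empty cluster list and
    :class:`AmbiguousConsensusError` on a tie for largest.
    """
    if not clusters:
        raise NoCandidateError("no circular candidate in the size window")
    top = clusters[0]
    rivals = [c for c in clusters if c.size == top.size]
    if len(rivals) > 1:
        raise AmbiguousConsensusError([c.representative for c in rivals])
    winner = top.members[0]
    report = {
        "n_clusters": len(clusters),
        "cluster_sizes": [c.size for c in clusters],
        "winner_length": len(top.representative),
        "winner_size": top.size,
        "winner_n_forward": top.n_forward,
        "winner_n_reverse": top.n_reverse,
        "winner_ks": sorted({m.source_k for m in top.members}),
        "winner_pools": sorted({m.source_pool for m in top.members}),
    }
    return winner, report


def rotate_like(seq: str, reference: str, probe_length: int = 200) -> str:
    """Rotate/strand-flip a circular ``seq`` to start where ``reference`` starts.

    Locates the reference's leading ``probe_length`` bases in the doubled
    sequence (both strands) by best edit-distance match and rotates the
    better strand there. Used only for presentation; clustering and
    consensus operate on canonical forms.
    """
    import edlib

    probe = reference[: min(probe_length, len(reference))]
    best = None
    for strand_seq in (seq, revcomp(seq)):
        doubled = strand_seq + strand_seq
        aln = edlib.align(probe, doubled, mode="HW", task="locations")
        if aln["locations"]:
            start = aln["locations"][0][0] % len(strand_seq)
            key = (aln["editDistance"], strand_seq is not seq)
            if best is None or key < best[0]:
                best = (key, strand_seq, start)
    if best is None:
        return seq
    _, strand_seq, start = best
    return strand_seq[start:] + strand_seq[:start]
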