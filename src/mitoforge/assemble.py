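"""De novo assembly: canonical k-mer de Bruijn graphs and unitig contigs.

Each (read pool, k) combination is assembled independently — with the
default six pools and k in {61, 63, ..., 89} that is the 90-job
multi-k sweep. Small k tolerates low coverage and sequencing error;
large k resolves repeats; assembling every combination and voting on
the resulting circular candidates (see :mod:`mitoforge.finish`) is the
core of the method.

The assembler is deliberately minimal, which a ~16.5 kb haploid circle
at hundreds-fold coverage permits:

* k-mers are counted canonically (lexicographic min of k-mer and
  reverse complement; k odd so no k-mer is its own complement);
* k-mers below a coverage floor ``min_count`` are dropped (kills most
  sequencing-error k-mers);
* contigs are maximal non-branching paths (unitigs);
* short error structures — tips, isolated fragments and simple
  bubbles — are removed iteratively (see :func:`_clean_graph`);
* no paired-end scaffolding, no gap filling.

A clean circular genome assembles into a single unitig whose two ends
repeat the same k-1 bases — the signature the finishing stage uses to
circularize.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from .pools import ReadPool
from .seqcore import revcomp

logger = logging.getLogger(__name__)

DEFAULT_K_VALUES = tuple(range(61, 90, 2))
DEFAULT_MIN_COUNT = 3
_BASES = "ACGT"


class AssemblyParameterError(ValueError):
    pass


@dataclass
class DeBruijnGraph:
    """Canonical k-mer spectrum of a read set after the ``min_count`` floor."""

    k: int
    counts: dict[str, int]
    min_count: int

    def __contains__(self, kmer: str) -> bool:
        rc = revcomp(kmer)
        return (kmer if kmer <= rc else rc) in self.counts

    @property
    def n_kmers(self) -> int:
        return len(self.counts)


def count_canonical_kmers(sequences: Iterable[str], k: int) -> dict[str, int]:
    """Count canonical k-mers across sequences; k-mers containing N are skipped.

    A sequence and its reverse complement produce identical counts.
    """
    counts: dict[str, int] = {}
    for seq in sequences:
        n = len(seq)
        if n < k:
            continue
        rc = revcomp(seq)
        if "N" in seq:
            for i in range(n - k + 1):
                fwd = seq[i : i + k]
                if "N" in fwd:
                    continue
                rev = rc[n - i - k : n - i]
                km = fwd if fwd <= rev else rev
                counts[km] = counts.get(km, 0) + 1
        else:
            for i in range(n - k + 1):
                fwd = seq[i : i + k]
                rev = rc[n - i - k : n - i]
                km = fwd if fwd <= rev else rev
                counts[km] = counts.get(km, 0) + 1
    return counts


def build_graph(
    reads: Iterable[str], k: int, min_count: int = DEFAULT_MIN_COUNT
) -> DeBruijnGraph:
    """Build the de Bruijn graph of a read set at word size ``k``.

    ``reads`` may be raw strings or objects with a ``seq`` attribute.
    Reads shorter than k contribute nothing. Raises for even k, k < 11,
    or k not smaller than the longest read.
    """
    if k % 2 == 0:
        raise AssemblyParameterError(f"k must be odd, got {k}")
    if k < 11:
        raise AssemblyParameterError(f"k must be >= 11, got {k}")
    if min_count < 1:
        raise AssemblyParameterError(f"min_count must be >= 1, got {min_count}")
    seqs = [getattr(r, "seq", r) for r in reads]
    if seqs and k > max(len(s) for s in seqs):
        raise AssemblyParameterError(
            f"k={k} exceeds the longest read ({max(len(s) for s in seqs)} bp)"
        )
    counts = count_canonical_kmers(seqs, k)
    if min_count > 1:
        counts = {km: c for km, c in counts.items() if c >= min_count}
    return DeBruijnGraph(k=k, counts=counts, min_count=min_count)


def _canon(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def _successors(kmer: str, counts: dict[str, int]) -> list[str]:
    suffix = kmer[1:]
    return [suffix + b for b in _BASES if _canon(suffix + b) in counts]


def _predecessors(kmer: str, counts: dict[str, int]) -> list[str]:
    prefix = kmer[:-1]
    return [b + prefix for b in _BASES if _canon(b + prefix) in counts]


def _walk_unitigs(counts: dict[str, int], k: int) -> list[tuple[str, list[str]]]:
    """Maximal non-branching paths over the oriented k-mer graph.

    Returns (sequence, oriented k-mer list) per unitig. Start k-mers are
    taken in lexicographic canonical order so output is deterministic.
    A full cycle (clean circular genome) is emitted as a linear walk of
    all its k-mers, so its string carries the k-1 terminal repeat.
    """
    visited: set[str] = set()
    unitigs: list[tuple[str, list[str]]] = []
    for start in sorted(counts):
        if start in visited:
            continue
        path = [start]
        visited.add(start)
        # extend right
        circular = False
        cur = start
        while True:
            succs = _successors(cur, counts)
            if len(succs) != 1:
                break
            nxt = succs[0]
            if len(_predecessors(nxt, counts)) != 1:
                break
            if nxt == start:
                circular = True
                break
            if _canon(nxt) in visited:
                break
            path.append(nxt)
            visited.add(_canon(nxt))
            cur = nxt
        if not circular:
            # extend left
            cur = start
            left: list[str] = []
            while True:
                preds = _predecessors(cur, counts)
                if len(preds) != 1:
                    break
                prv = preds[0]
                if len(_successors(prv, counts)) != 1:
                    break
                if _canon(prv) in visited:
                    break
                left.append(prv)
                visited.add(_canon(prv))
                cur = prv
            path = left[::-1] + path
        # spelling n k-mers gives n + k - 1 bases; for a full cycle the last
        # k-1 bases already repeat the first k-1 (the circularization signal)
        seq = path[0] + "".join(km[-1] for km in path[1:])
        unitigs.append((seq, path))
    return unitigs


def _clean_graph(counts: dict[str, int], k: int, max_rounds: int = 5) -> dict[str, int]:
    """Iteratively remove error structures from the graph.

    Three rules, all restricted to paths shorter than 2k bases (a single
    substitution error perturbs at most k consecutive k-mers, i.e. a
    path of at most 2k-1 bases):

    * tips — short paths dangling off one junction with a dead end;
    * short isolated paths — dead at both ends;
    * simple bubbles — of two (or more) short parallel paths joining
      the same pair of junction k-mers, only the highest-coverage
      branch is kept (ties by lexicographic sequence).
    """
    counts = dict(counts)
    for _ in range(max_rounds):
        unitigs = _walk_unitigs(counts, k)
        doomed: list[list[str]] = []
        bubble_groups: dict[tuple[str, str], list[tuple[float, str, list[str]]]] = {}
        for seq, path in unitigs:
            if len(seq) >= 2 * k:
                continue
            preds = _predecessors(path[0], counts)
            succs = _successors(path[-1], counts)
            if not preds or not succs:
                doomed.append(path)  # tip or isolated fragment
            elif len(preds) == 1 and len(succs) == 1:
                key = min(
                    (preds[0], succs[0]),
                    (revcomp(succs[0]), revcomp(preds[0])),  # opposite walk orientation
                )
                cov = sum(counts[_canon(km)] for km in path) / len(path)
                bubble_groups.setdefault(key, []).append((cov, seq, path))
        for group in bubble_groups.values():
            if len(group) >= 2:
                group.sort(key=lambda t: (-t[0], t[1]))
                doomed.extend(path for _, _, path in group[1:])
        if not doomed:
            break
        for path in doomed:
            for km in path:
                counts.pop(_canon(km), None)
    return counts


@dataclass(frozen=True)
class Contig:
    """A linear assembly product tagged with its (k, pool) provenance."""

    seq: str
    k: int
    pool_label: str
    mean_kmer_coverage: float


def assemble_contigs(graph: DeBruijnGraph, pool_label: str = "") -> list[Contig]:
    """Emit unitigs of the graph after tip clipping.

    Output order is deterministic: lexicographic by canonical sequence
    (min of the unitig and its reverse complement).
    """
    if not graph.counts:
        return []
    counts = _clean_graph(graph.counts, graph.k)
    unitigs = _walk_unitigs(counts, graph.k)
    contigs = []
    for seq, path in unitigs:
        cov = sum(counts[_canon(km)] for km in path) / len(path)
        contigs.append(
            Contig(seq=seq, k=graph.k, pool_label=pool_label, mean_kmer_coverage=cov)
        )
    contigs.sort(key=lambda c: min(c.seq, revcomp(c.seq)))
    return contigs


def multi_k_assemble(
    pools: Sequence[ReadPool],
    k_values: Sequence[int] = DEFAULT_K_VALUES,
    min_count: int = DEFAULT_MIN_COUNT,
) -> tuple[list[Contig], list[dict]]:
    """Assemble every (pool, k) combination independently.

    Returns all contigs (with provenance) and a per-job log. A failing
    job is recorded and skipped; the sweep continues.
    """
    contigs: list[Contig] = []
    jobs: list[dict] = []
    for pool in pools:
        reads = [r.seq for r in pool.all_reads()]
        for k in k_values:
            job = {"pool": pool.label, "k": k, "n_reads": len(reads)}
            try:
                graph = build_graph(reads, k=k, min_count=min_count)
                out = assemble_contigs(graph, pool_label=pool.label)
                job.update(status="ok", n_kmers=graph.n_kmers, n_contigs=len(out))
                contigs.extend(out)
            except Exception as exc:  # single-job failure is not fatal
                job.update(status="error", error=str(exc))
                logger.warning("assembly job pool=%s k=%d failed: %s", pool.label, k, exc)
            jobs.append(job)
    return contigs, jobs
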