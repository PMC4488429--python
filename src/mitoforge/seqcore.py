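"""Sequence and read data model plus FASTA/FASTQ input-output.

Coordinates throughout the package follow the GenBank convention:
1-based, inclusive on both ends. Sequences are uppercase strings over
``{A, C, G, T, N}``; any other symbol (including IUPAC ambiguity codes
other than N) is rejected so that downstream k-mer arithmetic stays
well defined.

Qualities are Phred scores in ``[0, 60]``, serialized as Phred+33
(ASCII ``!`` .. ``]``). Phred+64 input is not auto-detected; callers
that know their data is Phred+64 pass ``offset=64`` to :func:`read_fastq`
and it is converted on ingest.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGTN")
MAX_PHRED = 60

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class SequenceError(ValueError):
    """Invalid sequence content (bad alphabet, empty where forbidden)."""


class FastqParseError(ValueError):
    """Malformed FASTQ record; the message names the 1-based record index."""


class FastaParseError(ValueError):
    """Malformed or empty FASTA input."""


def clean_sequence(raw: str) -> str:
    """Uppercase ``raw`` and validate it against the {A,C,G,T,N} alphabet."""
    seq = raw.upper()
    if not set(seq) <= VALID_BASES:
        bad = sorted(set(seq) - VALID_BASES)
        raise SequenceError(f"invalid sequence characters: {bad}")
    return seq


def revcomp(seq: str) -> str:
    """Reverse complement; N maps to N. Involution: revcomp(revcomp(s)) == s."""
    cleaned = clean_sequence(seq)
    return cleaned.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class QualityRead:
    """A sequenced read with one Phred score per base.

    ``mate`` is 1 or 2 for a member of a pair, or ``None`` for an
    unpaired (single-end) read.
    """

    id: str
    seq: str
    quals: tuple[int, ...]
    mate: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", clean_sequence(self.seq))
        object.__setattr__(self, "quals", tuple(self.quals))
        if len(self.quals) != len(self.seq):
            raise SequenceError(
                f"read {self.id!r}: {len(self.quals)} quality values for "
                f"{len(self.seq)} bases"
            )
        if self.quals and not all(0 <= q <= MAX_PHRED for q in self.quals):
            raise SequenceError(f"read {self.id!r}: Phred values outside [0, {MAX_PHRED}]")
        if self.mate not in (None, 1, 2):
            raise SequenceError(f"read {self.id!r}: mate must be 1, 2 or None")

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def min_qual(self) -> int:
        return min(self.quals) if self.quals else 0


def read_id_stem(read_id: str) -> str:
    """Strip mate decorations: trailing ``/1``/``/2`` and space-delimited tokens."""
    stem = read_id.split()[0] if read_id.split() else read_id
    if stem.endswith("/1") or stem.endswith("/2"):
        stem = stem[:-2]
    return stem


@dataclass(frozen=True)
class ReadPair:
    """Mates of one sequenced fragment, record-synchronized across R1/R2."""

    first: QualityRead
    second: QualityRead

    def __post_init__(self) -> None:
        if read_id_stem(self.first.id) != read_id_stem(self.second.id):
            raise SequenceError(
                f"mate id stems differ: {self.first.id!r} vs {self.second.id!r}"
            )

    @property
    def id_stem(self) -> str:
        return read_id_stem(self.first.id)

    def reads(self) -> tuple[QualityRead, QualityRead]:
        return (self.first, self.second)


def _open_text(path: str | Path, mode: str = "rt") -> io.TextIOBase:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)  # type: ignore[return-value]
    return open(path, mode)


def read_fastq(path: str | Path, offset: int = 33) -> list[QualityRead]:
    """Parse a 4-line-record FASTQ file (optionally gzipped).

    Qualities are decoded as ``ord(char) - offset`` (Phred+33 default).
    Malformed records raise :class:`FastqParseError` naming the 1-based
    record index.
    """
    reads: list[QualityRead] = []
    with _open_text(path) as handle:
        lines = [line.rstrip("\n") for line in handle]
    # strip stray trailing blank lines, but never a record's own empty
    # quality line (a zero-length read is legal)
    while lines and lines[-1] == "" and len(lines) % 4 != 0:
        lines.pop()
    if len(lines) % 4 != 0:
        raise FastqParseError(
            f"record {len(lines) // 4 + 1}: truncated record "
            f"({len(lines) % 4} of 4 lines)"
        )
    for idx in range(0, len(lines), 4):
        rec = idx // 4 + 1
        header, seq, plus, qual = lines[idx : idx + 4]
        if not header.startswith("@"):
            raise FastqParseError(f"record {rec}: header does not start with '@'")
        if not plus.startswith("+"):
            raise FastqParseError(f"record {rec}: separator line does not start with '+'")
        if len(seq) != len(qual):
            raise FastqParseError(
                f"record {rec}: sequence length {len(seq)} != quality length {len(qual)}"
            )
        name = header[1:]
        mate: int | None = None
        stem = name.split()[0] if name.split() else name
        if stem.endswith("/1"):
            mate = 1
        elif stem.endswith("/2"):
            mate = 2
        try:
            quals = tuple(ord(c) - offset for c in qual)
            reads.append(QualityRead(id=name, seq=seq, quals=quals, mate=mate))
        except SequenceError as exc:
            raise FastqParseError(f"record {rec}: {exc}") from exc
    return reads


def write_fastq(reads: Iterable[QualityRead], path: str | Path) -> None:
    """Write reads as Phred+33 FASTQ. Inverse of :func:`read_fastq`."""
    with _open_text(path, "wt") as handle:
        for read in reads:
            qual = "".join(chr(q + 33) for q in read.quals)
            handle.write(f"@{read.id}\n{read.seq}\n+\n{qual}\n")


def iter_fastq_pairs(
    r1_path: str | Path, r2_path: str | Path, offset: int = 33
) -> Iterator[ReadPair]:
    """Yield record-synchronized pairs from R1/R2 files, verifying id stems."""
    r1 = read_fastq(r1_path, offset=offset)
    r2 = read_fastq(r2_path, offset=offset)
    if len(r1) != len(r2):
        raise FastqParseError(
            f"R1 has {len(r1)} records but R2 has {len(r2)}; files must be synchronized"
        )
    for a, b in zip(r1, r2):
        yield ReadPair(first=a, second=b)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an ordered header→sequence mapping (wrapped lines joined)."""
    with _open_text(path) as handle:
        records = {rec.id: clean_sequence(str(rec.seq)) for rec in SeqIO.parse(handle, "fasta")}
    if not records:
        raise FastaParseError(f"no FASTA records in {path}")
    return records


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    """Write an ordered name→sequence mapping as FASTA (60-column wrap)."""
    with _open_text(path, "wt") as handle:
        SeqIO.write(
            (SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()),
            handle,
            "fasta",
        )
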