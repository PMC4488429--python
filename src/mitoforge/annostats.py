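"""Feature-table arithmetic and composition statistics on a circular genome.

Coordinates are 1-based and inclusive on both ends (GenBank
convention): a feature spanning positions ``start..end`` has length
``end - start + 1``. The intergenic spacer between consecutive
features a, b is ``b.start - a.end - 1``; a negative value means the
genes overlap by that many bases. On a circular genome the gap from
the last feature back to the first wraps the origin:
``(genome_length - a.end) + (b.start - 1)``. Spacing ignores strand —
adjacency is positional, and annotated mitochondrial gene tables mix
heavy- and light-strand genes freely.

Composition statistics count bases on the presented strand; CpG is the
number of ``CG`` dinucleotides counted linearly (no origin wrap).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Sequence

from .seqcore import clean_sequence, revcomp

FEATURE_TYPES = ("PCG", "tRNA", "rRNA", "control", "other")


class FeatureError(ValueError):
    pass


@dataclass(frozen=True)
class FeatureRecord:
    """One annotated gene/region: 1-based inclusive coordinates, H or L strand."""

    name: str
    start: int
    end: int
    strand: str  # "H" (heavy) or "L" (light)
    ftype: str = "other"

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise FeatureError(
                f"{self.name}: need 1 <= start <= end, got {self.start}..{self.end}"
            )
        if self.strand not in ("H", "L"):
            raise FeatureError(f"{self.name}: strand must be 'H' or 'L'")
        if self.ftype not in FEATURE_TYPES:
            raise FeatureError(f"{self.name}: unknown feature type {self.ftype!r}")


def feature_length(f: FeatureRecord) -> int:
    """Length in bp of a 1-based inclusive span: end - start + 1."""
    return f.end - f.start + 1


def intergenic_spacer(a: FeatureRecord, b: FeatureRecord) -> int:
    """Bases separating a from the following feature b; negative = overlap."""
    if a.start > b.start:
        raise FeatureError(f"{a.name} does not precede {b.name} in genome order")
    return b.start - a.end - 1


def circular_gap(a: FeatureRecord, b: FeatureRecord, genome_length: int) -> int:
    """Gap from the last feature across the origin to the first feature."""
    if a.end > genome_length or b.end > genome_length:
        raise FeatureError("feature coordinates exceed genome length")
    return (genome_length - a.end) + (b.start - 1)


@dataclass
class FeatureTable:
    """Features of one circular (or linear) genome, sorted by start."""

    genome_length: int
    records: list[FeatureRecord]
    circular: bool = True

    def __post_init__(self) -> None:
        self.records = sorted(self.records, key=lambda r: (r.start, r.end))
        names = [r.name for r in self.records]
        if len(set(names)) != len(names):
            raise FeatureError("feature names must be unique")
        for r in self.records:
            if r.end > self.genome_length:
                raise FeatureError(
                    f"{r.name}: end {r.end} exceeds genome length {self.genome_length}"
                )

    def __iter__(self):
        return iter(self.records)

    def get(self, name: str) -> FeatureRecord:
        for r in self.records:
            if r.name == name:
                return r
        raise KeyError(name)


def spacer_table(table: FeatureTable) -> list[tuple[str, int]]:
    """Per-feature spacer to the next feature; the last entry wraps the origin.

    Returns ``(feature name, spacer)`` for every record. For a circular
    genome the final record's spacer is the wrap gap back to the first
    record (e.g. the control region separating tRNA-Pro from tRNA-Phe).
    """
    recs = table.records
    out: list[tuple[str, int]] = []
    for a, b in zip(recs, recs[1:]):
        out.append((a.name, intergenic_spacer(a, b)))
    if recs and table.circular:
        out.append((recs[-1].name, circular_gap(recs[-1], recs[0], table.genome_length)))
    return out


@dataclass(frozen=True)
class CompositionStats:
    counts: dict[str, int]
    percents: dict[str, float]
    gc_percent: float
    cpg_count: int
    length: int


def _pct(n: int, total: int) -> float:
    return float(
        (Decimal(n) * 100 / Decimal(total)).quantize(
            Decimal("0.01"), rounding=ROUND_HALF_UP
        )
    )


def composition(seq: str) -> CompositionStats:
    """Base counts, percentages (2 dp), G+C% and linear CpG count."""
    seq = clean_sequence(seq)
    if not seq:
        raise FeatureError("cannot compute composition of an empty sequence")
    counts = {b: seq.count(b) for b in "ACGTN"}
    total = len(seq)
    percents = {b: _pct(c, total) for b, c in counts.items()}
    gc = _pct(counts["G"] + counts["C"], total)
    return CompositionStats(
        counts=counts,
        percents=percents,
        gc_percent=gc,
        cpg_count=seq.count("CG"),
        length=total,
    )


def gc_percent_from_counts(a: int, c: int, g: int, t: int, n: int = 0) -> float:
    """G+C percentage (2 dp, half-up) straight from published base counts."""
    total = a + c + g + t + n
    if total <= 0:
        raise FeatureError("base counts sum to zero")
    return _pct(g + c, total)


def extract_feature_seq(genome: str, f: FeatureRecord) -> str:
    """Feature sequence in reading orientation (reverse-complemented for L)."""
    sub = genome[f.start - 1 : f.end]
    return revcomp(sub) if f.strand == "L" else sub


def terminal_codons(genome: str, f: FeatureRecord) -> tuple[str, str]:
    """Initiation codon and termination codon (or incomplete-stop remainder).

    For a protein-coding gene whose length is not a multiple of 3 the
    transcript ends in a partial codon completed by polyadenylation;
    the remainder is rendered with an em-dash placeholder, e.g. ``T—``
    for a single trailing T.
    """
    if f.ftype != "PCG":
        raise FeatureError(f"{f.name}: terminal codons only defined for PCG features")
    seq = extract_feature_seq(clean_sequence(genome), f)
    if len(seq) < 3:
        raise FeatureError(f"{f.name}: feature shorter than one codon")
    start_codon = seq[:3]
    remainder = len(seq) % 3
    if remainder == 0:
        stop = seq[-3:]
    else:
        stop = seq[-remainder:] + "—"
    return start_codon, stop


# ---------------------------------------------------------------------------
# Feature-table I/O: TSV (name/start/end/strand/type columns) and GFF3.

KM023192_LENGTH = 16_563


def load_km023192_features() -> FeatureTable:
    """Published gene coordinates of the M. cyclopis mitogenome (KM023192).

    16,563 bp circular genome: 13 protein-coding genes, 2 rRNAs,
    22 tRNAs; the control region is the tRNA-Pro→tRNA-Phe wrap gap.
    """
    from importlib.resources import files

    path = files("mitoforge.data").joinpath("macaca_cyclopis_km023192_features.tsv")
    records = []
    reader = csv.DictReader(path.read_text().splitlines(), delimiter="\t")
    for row in reader:
        records.append(
            FeatureRecord(
                name=row["name"],
                start=int(row["start"]),
                end=int(row["end"]),
                strand=row["strand"],
                ftype=row.get("type", "other") or "other",
            )
        )
    return FeatureTable(genome_length=KM023192_LENGTH, records=records, circular=True)

def read_feature_tsv(path: str | Path, genome_length: int, circular: bool = True) -> FeatureTable:
    records = []
    with open(path) as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        for row in reader:
            records.append(
                FeatureRecord(
                    name=row["name"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    strand=row["strand"],
                    ftype=row.get("type", "other") or "other",
                )
            )
    return FeatureTable(genome_length=genome_length, records=records, circular=circular)


def write_feature_tsv(table: FeatureTable, path: str | Path) -> None:
    spacers = dict(spacer_table(table))
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t")
        writer.writerow(["name", "start", "end", "strand", "type", "length", "spacer"])
        for r in table.records:
            writer.writerow(
                [r.name, r.start, r.end, r.strand, r.ftype,
                 feature_length(r), spacers.get(r.name, "")]
            )


_GFF_TYPE = {"PCG": "gene", "tRNA": "tRNA", "rRNA": "rRNA",
             "control": "D_loop", "other": "region"}
_GFF_TYPE_BACK = {"gene": "PCG", "CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA",
                  "D_loop": "control"}


def write_gff3(table: FeatureTable, path: str | Path, seqid: str = "genome") -> None:
    """Minimal GFF3 (1-based inclusive, like the internal model)."""
    with open(path, "w") as handle:
        handle.write("##gff-version 3\n")
        handle.write(f"##sequence-region {seqid} 1 {table.genome_length}\n")
        for r in table.records:
            strand = "+" if r.strand == "H" else "-"
            handle.write(
                f"{seqid}\tmitoforge\t{_GFF_TYPE[r.ftype]}\t{r.start}\t{r.end}"
                f"\t.\t{strand}\t.\tID={r.name};Name={r.name}\n"
            )


def read_gff3(path: str | Path, genome_length: int, circular: bool = True) -> FeatureTable:
    records = []
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FeatureError(f"GFF3 line has {len(cols)} columns, expected 9")
            attrs = dict(
                kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
            )
            name = attrs.get("Name") or attrs.get("ID") or f"feature_{len(records) + 1}"
            records.append(
                FeatureRecord(
                    name=name,
                    start=int(cols[3]),
                    end=int(cols[4]),
                    strand="H" if cols[6] != "-" else "L",
                    ftype=_GFF_TYPE_BACK.get(cols[2], "other"),
                )
            )
    return FeatureTable(genome_length=genome_length, records=records, circular=circular)
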