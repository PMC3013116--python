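"""Readers and writers for the formats the pipeline touches.

Sequence formats (FASTA, FASTQ, GFF3) go through Biopython; the tabular
report dialects (difference tables, region BED, annotation TSV) are defined
here.  All coordinates are 0-based half-open in memory and 1-based inclusive
in every written report.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO

VALID_BASES = frozenset("ACGTN")

__all__ = [
    "ReferenceGenome",
    "Read",
    "ReadSet",
    "GeneFeature",
    "FormatError",
    "read_fasta",
    "read_reads",
    "read_features",
    "write_fasta",
    "write_fastq",
    "write_difference_table",
    "read_difference_table",
    "write_regions_bed",
]


class FormatError(ValueError):
    """A file violates the expectations of its declared format."""


@dataclass(frozen=True)
class ReferenceGenome:
    """A named sequence over {A,C,G,T,N}: the mediator coordinate system."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        bad = _first_invalid(self.sequence)
        if bad is not None:
            raise FormatError(
                f"record {self.name!r}: invalid character {self.sequence[bad]!r} "
                f"at position {bad + 1}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Read:
    """One unpaired sequencing read; quality is Phred scores or None."""

    id: str
    sequence: str
    quality: Optional[tuple[int, ...]] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"read {self.id!r}: empty sequence")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise FormatError(
                f"read {self.id!r}: quality length {len(self.quality)} != "
                f"sequence length {len(self.sequence)}"
            )


@dataclass
class ReadSet:
    """A collection of reads plus length statistics used downstream."""

    reads: list[Read] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self):
        return iter(self.reads)

    @property
    def total_bases(self) -> int:
        return sum(len(r.sequence) for r in self.reads)

    @property
    def length_counts(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for r in self.reads:
            counts[len(r.sequence)] = counts.get(len(r.sequence), 0) + 1
        return counts

    @property
    def modal_length(self) -> Optional[int]:
        counts = self.length_counts
        if not counts:
            return None
        # most frequent length; ties broken toward the shorter read
        return min(counts, key=lambda n: (-counts[n], n))


@dataclass(frozen=True)
class GeneFeature:
    """A (CDS-like) feature on the mediator, 0-based half-open interval."""

    locus_tag: str
    description: str
    start: int
    end: int
    strand: str
    partial: bool = False

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise FormatError(
                f"feature {self.locus_tag!r}: end {self.end} <= start {self.start}"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(f"feature {self.locus_tag!r}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


def _first_invalid(seq: str) -> Optional[int]:
    for i, c in enumerate(seq):
        if c not in VALID_BASES:
            return i
    return None


def _normalize_sequence(raw: str, name: str) -> str:
    seq = str(raw).upper().replace("U", "T")
    bad = _first_invalid(seq)
    if bad is not None:
        raise FormatError(
            f"record {name!r}: invalid character {seq[bad]!r} at position {bad + 1}"
        )
    return seq


def read_fasta(path: str | Path) -> list[ReferenceGenome]:
    """Load all records of a FASTA file as reference genomes.

    Sequences are uppercased and U is mapped to T; any character outside
    {A,C,G,T,N} raises :class:`FormatError`, as do empty files and
    duplicate record names.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    seen: set[str] = set()
    genomes = []
    for rec in records:
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate record name {rec.id!r}")
        seen.add(rec.id)
        genomes.append(ReferenceGenome(rec.id, _normalize_sequence(str(rec.seq), rec.id)))
    return genomes


def read_reads(path: str | Path, format: str = "fastq") -> ReadSet:
    """Load unpaired reads from FASTQ (Phred+33) or FASTA."""
    if format not in ("fastq", "fasta"):
        raise ValueError(f"unsupported read format {format!r}")
    reads: list[Read] = []
    try:
        for rec in SeqIO.parse(str(path), format):
            seq = _normalize_sequence(str(rec.seq), rec.id)
            qual = None
            if format == "fastq":
                scores = rec.letter_annotations.get("phred_quality")
                if scores is None or len(scores) != len(seq):
                    raise FormatError(f"read {rec.id!r}: quality/sequence length mismatch")
                qual = tuple(scores)
            reads.append(Read(rec.id, seq, qual))
    except FormatError:
        raise
    except ValueError as exc:  # malformed FASTQ reported by the parser
        raise FormatError(f"{path}: {exc}") from exc
    return ReadSet(reads)


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq(readset: ReadSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in readset:
            qual = r.quality if r.quality is not None else (30,) * len(r.sequence)
            qstr = "".join(chr(q + 33) for q in qual)
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{qstr}\n")


_GFF_ATTR = re.compile(r"(\w+)=([^;]*)")


def read_features(
    path: str | Path,
    dialect: str = "gff3",
    genome: Optional[ReferenceGenome] = None,
) -> list[GeneFeature]:
    """Load gene features from GFF3 or a simple 5-column TSV.

    File coordinates are 1-based inclusive (GFF3 convention) and converted
    to 0-based half-open on load.  The TSV dialect is
    ``locus<TAB>description<TAB>start<TAB>end<TAB>strand``.
    """
    feats: list[GeneFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if dialect == "gff3":
                parts = line.split("\t")
                if len(parts) < 9:
                    raise FormatError(f"{path}:{lineno}: expected 9 GFF3 columns")
                start1, end1, strand = int(parts[3]), int(parts[4]), parts[6]
                attrs = dict(_GFF_ATTR.findall(parts[8]))
                locus = attrs.get("locus_tag") or attrs.get("ID") or f"feature_{lineno}"
                desc = attrs.get("product") or attrs.get("Name") or ""
                partial = attrs.get("partial", "").lower() in ("true", "1", "yes")
            elif dialect == "tsv":
                parts = line.split("\t")
                if len(parts) < 5:
                    raise FormatError(f"{path}:{lineno}: expected 5 TSV columns")
                locus, desc = parts[0], parts[1]
                start1, end1, strand = int(parts[2]), int(parts[3]), parts[4]
                partial = len(parts) > 5 and parts[5].lower() in ("true", "1", "yes")
            else:
                raise ValueError(f"unknown feature dialect {dialect!r}")
            if end1 < start1:
                raise FormatError(f"{path}:{lineno}: end {end1} < start {start1}")
            feats.append(GeneFeature(locus, desc, start1 - 1, end1, strand, partial))
    if genome is not None:
        for f in feats:
            if f.end > genome.length:
                raise FormatError(
                    f"feature {f.locus_tag!r} extends past genome end "
                    f"({f.end} > {genome.length})"
                )
    feats.sort(key=lambda f: (f.start, f.end, f.locus_tag))
    return feats


DIFFERENCE_COLUMNS = [
    "position",
    "type",
    "ref_allele",
    "alt_allele",
    "coverage",
    "alt_fraction",
    "pass_mode",
]


def write_difference_table(table, path: str | Path) -> None:
    """Write a difference table as TSV; positions are 1-based inclusive."""
    from .pileup import DifferenceTable  # local import to avoid a cycle

    assert isinstance(table, DifferenceTable)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(DIFFERENCE_COLUMNS)
        for call in table.calls:
            w.writerow(
                [
                    call.ref_pos + 1,
                    call.type,
                    call.ref_allele or ".",
                    call.alt_allele or ".",
                    call.coverage,
                    f"{call.alt_fraction:.4f}",
                    call.pass_mode,
                ]
            )


def read_difference_table(path: str | Path, isolate_label: str = "", genome_name: str = ""):
    """Read back a TSV written by :func:`write_difference_table`."""
    from .pileup import DifferenceTable, VariantCall

    calls = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != DIFFERENCE_COLUMNS:
            raise FormatError(f"{path}: unexpected header {header!r}")
        for row in reader:
            pos1, vtype, ref_a, alt_a, cov, frac, mode = row
            calls.append(
                VariantCall(
                    ref_pos=int(pos1) - 1,
                    type=vtype,
                    ref_allele="" if ref_a == "." else ref_a,
                    alt_allele="" if alt_a == "." else alt_a,
                    coverage=int(cov),
                    alt_fraction=float(frac),
                    pass_mode=mode,
                )
            )
    return DifferenceTable(isolate_label=isolate_label, genome_name=genome_name, calls=calls)


def write_regions_bed(regions: Sequence, genome_name: str, path: str | Path) -> None:
    """Write labeled regions as BED (0-based half-open, as BED requires)."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{genome_name}\t{r.start}\t{r.end}\t{r.label}\n")


def read_regions_bed(path: str | Path):
    """Read a BED written by :func:`write_regions_bed`."""
    from .regions import GenomicRegion

    regions = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            _, start, end, label = line.rstrip("\n").split("\t")[:4]
            regions.append(GenomicRegion(int(start), int(end), label))
    return regions


ALIGNMENT_COLUMNS = ["read_id", "strand", "ref_start", "cigar", "read_sequence"]


def write_alignments_tsv(alignments: Sequence, path: str | Path) -> None:
    """Serialize alignments (extended CIGAR over =XID) to TSV."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(ALIGNMENT_COLUMNS)
        for a in alignments:
            cigar = "".join(f"{n}{op}" for op, n in a.ops)
            w.writerow([a.read_id, a.strand, a.ref_start, cigar, a.read_sequence])


def read_alignments_tsv(path: str | Path) -> list:
    """Read back a TSV written by :func:`write_alignments_tsv`."""
    from .align import Alignment

    out = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != ALIGNMENT_COLUMNS:
            raise FormatError(f"{path}: unexpected header {header!r}")
        for read_id, strand, ref_start, cigar, seq in reader:
            ops: list[tuple[str, int]] = []
            num = ""
            for c in cigar:
                if c.isdigit():
                    num += c
                else:
                    ops.append((c, int(num)))
                    num = ""
            ref_span = sum(n for op, n in ops if op in "=XD")
            start = int(ref_start)
            out.append(
                Alignment(
                    read_id=read_id,
                    ref_start=start,
                    ref_end=start + ref_span,
                    strand=strand,
                    ops=tuple(ops),
                    read_sequence=seq,
                    n_mismatches=sum(n for op, n in ops if op == "X"),
                    n_gap_columns=sum(n for op, n in ops if op in "ID"),
                )
            )
    return out


def write_sam(
    alignments: Sequence,
    unaligned_ids: Sequence[str],
    genome,
    readset: "ReadSet",
    path: str | Path,
) -> None:
    """Minimal SAM export; unmapped reads carry flag 4."""
    by_id = {r.id: r for r in readset}
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        fh.write(f"@SQ\tSN:{genome.name}\tLN:{genome.length}\n")
        for a in alignments:
            flag = 16 if a.strand == "-" else 0
            runs: list[list] = []
            for op, n in a.ops:
                sam_op = "M" if op in "=X" else op
                if runs and runs[-1][0] == sam_op:
                    runs[-1][1] += n
                else:
                    runs.append([sam_op, n])
            cigar = "".join(f"{n}{op}" for op, n in runs)
            nm = a.n_mismatches + a.n_gap_columns
            fh.write(
                f"{a.read_id}\t{flag}\t{genome.name}\t{a.ref_start + 1}\t255\t"
                f"{cigar}\t*\t0\t0\t{a.read_sequence}\t*\tNM:i:{nm}\n"
            )
        for rid in unaligned_ids:
            seq = by_id[rid].sequence if rid in by_id else "*"
            fh.write(f"{rid}\t4\t*\t0\t0\t*\t*\t0\t0\t{seq}\t*\n")
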