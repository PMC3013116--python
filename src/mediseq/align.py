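"""Seed-and-extend placement of short reads on the mediator genome.

The contract mirrors a short-word blastn run: exact seed words of
``word_size`` bases nominate candidate loci on either strand, each
candidate is scored by a unit-cost edit distance (mismatches plus gap
columns count equally as "alignment errors"), and a read is reported at
its best locus only if the alignment stays within ``max_errors`` and
spans at least ``min_align_len`` columns.  Reads whose two best loci are
indistinguishable (equal errors and equal aligned length) are discarded
as ambiguous rather than placed arbitrarily.

The banded extension itself is delegated to edlib (Myers bit-vector edit
distance); seeding, candidate clustering, tie-breaking, strand handling
and the error budget are defined here.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import edlib
import numpy as np

from .io import Read, ReadSet, ReferenceGenome

logger = logging.getLogger(__name__)

__all__ = [
    "AlignerParams",
    "Alignment",
    "SeedIndex",
    "AlignmentStats",
    "build_seed_index",
    "align_read",
    "align_readset",
    "default_min_align_len",
    "reverse_complement",
    "parse_blast_tabular",
]

_COMP = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def default_min_align_len(modal_read_length: int) -> int:
    """Minimum reported alignment span: ceil(0.8 x modal read length).

    For 33 bp reads this gives 27 columns; the threshold scales with read
    length instead of being a fixed lookup, and can be overridden in
    :class:`AlignerParams`.
    """
    return math.ceil(0.8 * modal_read_length)


@dataclass(frozen=True)
class AlignerParams:
    word_size: int = 11
    max_errors: int = 6
    min_align_len: int = 27
    both_strands: bool = True

    def __post_init__(self) -> None:
        if self.word_size < 4:
            raise ValueError("word_size must be >= 4")
        if self.min_align_len < self.word_size:
            raise ValueError("min_align_len must be >= word_size")
        if self.max_errors < 0:
            raise ValueError("max_errors must be >= 0")


@dataclass(frozen=True)
class Alignment:
    """Placement of one read on the reference.

    ``ops`` is an extended-CIGAR list of ``(op, length)`` with op in
    ``=XID`` (``I``: base present in the read but not the reference;
    ``D``: reference base skipped by the read).  ``read_sequence`` is the
    read oriented to the reference strand, so pileup construction never
    needs to know the original strand.
    """

    read_id: str
    ref_start: int
    ref_end: int
    strand: str
    ops: tuple[tuple[str, int], ...]
    read_sequence: str
    n_mismatches: int
    n_gap_columns: int

    @property
    def n_errors(self) -> int:
        return self.n_mismatches + self.n_gap_columns

    @property
    def aligned_len(self) -> int:
        return sum(n for _, n in self.ops)

    def iter_columns(self, ref: str):
        """Yield (ref_pos|None, ref_base|None, read_base|None) per column."""
        rpos, qpos = self.ref_start, 0
        for op, n in self.ops:
            for _ in range(n):
                if op in "=X":
                    yield rpos, ref[rpos], self.read_sequence[qpos]
                    rpos += 1
                    qpos += 1
                elif op == "D":
                    yield rpos, ref[rpos], None
                    rpos += 1
                else:  # I
                    yield None, None, self.read_sequence[qpos]
                    qpos += 1


class SeedIndex:
    """Exact-match lookup from every word of the forward reference strand."""

    def __init__(self, ref: ReferenceGenome, word_size: int):
        if word_size > ref.length:
            raise ValueError(
                f"word_size {word_size} exceeds reference length {ref.length}"
            )
        self.word_size = word_size
        self.ref_name = ref.name
        seq = ref.sequence
        table: dict[str, list[int]] = {}
        w = word_size
        for p in range(ref.length - w + 1):
            word = seq[p : p + w]
            if "N" in word:
                continue
            table.setdefault(word, []).append(p)
        self._table = {k: np.asarray(v, dtype=np.int64) for k, v in table.items()}

    def lookup(self, word: str) -> np.ndarray:
        return self._table.get(word, _EMPTY)

    def __contains__(self, word: str) -> bool:
        return word in self._table

    def __len__(self) -> int:
        return len(self._table)


_EMPTY = np.empty(0, dtype=np.int64)


def build_seed_index(ref: ReferenceGenome, word_size: int = 11) -> SeedIndex:
    return SeedIndex(ref, word_size)


def _cigar_pairs(cigar: str) -> list[tuple[str, int]]:
    pairs: list[tuple[str, int]] = []
    num = ""
    for c in cigar:
        if c.isdigit():
            num += c
        else:
            pairs.append((c, int(num)))
            num = ""
    return pairs


@dataclass
class _Candidate:
    errors: int
    aligned_len: int
    ref_start: int
    strand: str
    ops: tuple[tuple[str, int], ...]
    oriented_seq: str
    n_mismatches: int
    n_gap_columns: int

    @property
    def sort_key(self):
        # fewer errors, then longer span, then leftmost, then + strand
        return (self.errors, -self.aligned_len, self.ref_start, self.strand)


def _candidate_from_hamming(
    oriented: str, diag: int, strand: str, ref_arr: np.ndarray, read_arr: np.ndarray
) -> Optional[_Candidate]:
    L = len(oriented)
    if diag < 0 or diag + L > len(ref_arr):
        return None
    mism = int(np.count_nonzero(ref_arr[diag : diag + L] != read_arr))
    window = ref_arr[diag : diag + L]
    ops: list[tuple[str, int]] = []
    if mism == 0:
        ops = [("=", L)]
    else:
        diff = window != read_arr
        run_start = 0
        for i in range(L):
            if diff[i]:
                if i > run_start:
                    ops.append(("=", i - run_start))
                if ops and ops[-1][0] == "X":
                    ops[-1] = ("X", ops[-1][1] + 1)
                else:
                    ops.append(("X", 1))
                run_start = i + 1
        if run_start < L:
            ops.append(("=", L - run_start))
    return _Candidate(mism, L, diag, strand, tuple(ops), oriented, mism, 0)


def _candidate_from_edlib(
    oriented: str,
    window_start: int,
    window: str,
    strand: str,
) -> Optional[_Candidate]:
    res = edlib.align(oriented, window, mode="HW", task="locations")
    dist = res["editDistance"]
    if dist < 0:
        return None
    # leftmost optimal location; re-align globally to that slice for the path
    loc = min(res["locations"], key=lambda se: (se[0] if se[0] else 0, se[1]))
    s = loc[0] or 0
    e = loc[1]
    sub = window[s : e + 1]
    path = edlib.align(oriented, sub, mode="NW", task="path")
    ops = tuple(_cigar_pairs(path["cigar"]))
    n_mm = sum(n for op, n in ops if op == "X")
    n_gap = sum(n for op, n in ops if op in "ID")
    return _Candidate(
        n_mm + n_gap,
        sum(n for _, n in ops),
        window_start + s,
        strand,
        ops,
        oriented,
        n_mm,
        n_gap,
    )


def _collect_diagonals(
    oriented: str, index: SeedIndex, step: int = 1
) -> set[int]:
    w = index.word_size
    diags: set[int] = set()
    for q in range(0, len(oriented) - w + 1, step):
        word = oriented[q : q + w]
        if "N" in word:
            continue
        for p in index.lookup(word):
            diags.add(int(p) - q)
    return diags


def _cluster(diags: Iterable[int], gap: int) -> list[list[int]]:
    out: list[list[int]] = []
    for d in sorted(diags):
        if out and d - out[-1][-1] <= gap:
            out[-1].append(d)
        else:
            out.append([d])
    return out


def align_read(
    read: Read,
    index: SeedIndex,
    ref: ReferenceGenome,
    params: AlignerParams,
    _ref_arr: Optional[np.ndarray] = None,
) -> Optional[Alignment]:
    """Place one read at its best location, or return None if unalignable.

    Unalignable covers three outcomes: no seed word matched, no candidate
    satisfied the error/length thresholds, or the two best candidates at
    distinct loci were indistinguishable (ambiguous placement).
    """
    if len(read.sequence) < index.word_size:
        return None
    ref_seq = ref.sequence
    if _ref_arr is None:
        _ref_arr = np.frombuffer(ref_seq.encode(), dtype=np.uint8)

    orientations = [(read.sequence, "+")]
    if params.both_strands:
        orientations.append((reverse_complement(read.sequence), "-"))

    candidates: list[_Candidate] = []
    gapped_clusters: list[tuple[str, str, int, str]] = []  # oriented, strand, wstart, window
    for oriented, strand in orientations:
        diags = _collect_diagonals(oriented, index)
        if not diags:
            continue
        read_arr = np.frombuffer(oriented.encode(), dtype=np.uint8)
        L = len(oriented)
        for cluster in _cluster(diags, params.max_errors):
            best_ham: Optional[_Candidate] = None
            for d in cluster:
                cand = _candidate_from_hamming(oriented, d, strand, _ref_arr, read_arr)
                if cand is not None and (best_ham is None or cand.sort_key < best_ham.sort_key):
                    best_ham = cand
            # An ungapped candidate with <=1 mismatch cannot be beaten by a
            # gapped alignment in the same neighbourhood (0 errors would be
            # an exact diagonal of its own), so skip the gapped extension.
            if best_ham is not None and best_ham.errors <= 1:
                candidates.append(best_ham)
                continue
            pad = params.max_errors + 1
            wstart = max(0, cluster[0] - pad)
            wend = min(len(ref_seq), cluster[-1] + L + pad)
            gapped_clusters.append((oriented, strand, wstart, ref_seq[wstart:wend]))

    for oriented, strand, wstart, window in gapped_clusters:
        cand = _candidate_from_edlib(oriented, wstart, window, strand)
        if cand is not None:
            candidates.append(cand)

    viable = [
        c
        for c in candidates
        if c.errors <= params.max_errors and c.aligned_len >= params.min_align_len
    ]

    if not viable:
        # clipped fallback: try progressively shorter read prefixes/suffixes
        # (local-alignment behaviour at e.g. deletion junctions)
        viable = _clipped_candidates(gapped_clusters, candidates, params)
        if not viable:
            return None

    viable.sort(key=lambda c: c.sort_key)
    best = viable[0]
    for other in viable[1:]:
        if other.ref_start == best.ref_start and other.strand == best.strand:
            continue
        if other.errors == best.errors and other.aligned_len == best.aligned_len:
            return None  # ambiguous between distinct loci
        break

    ref_span = sum(n for op, n in best.ops if op in "=XD")
    return Alignment(
        read_id=read.id,
        ref_start=best.ref_start,
        ref_end=best.ref_start + ref_span,
        strand=best.strand,
        ops=best.ops,
        read_sequence=best.oriented_seq,
        n_mismatches=best.n_mismatches,
        n_gap_columns=best.n_gap_columns,
    )


def _clipped_candidates(
    gapped_clusters: list[tuple[str, str, int, str]],
    full_candidates: list[_Candidate],
    params: AlignerParams,
) -> list[_Candidate]:
    """Clip read ends down to min_align_len looking for an in-budget hit."""
    out: list[_Candidate] = []
    for oriented, strand, wstart, window in gapped_clusters:
        L = len(oriented)
        for L2 in range(L - 1, params.min_align_len - 1, -1):
            found = None
            for clipped in (oriented[:L2], oriented[L - L2 :]):
                cand = _candidate_from_edlib(clipped, wstart, window, strand)
                if cand is not None and cand.errors <= params.max_errors:
                    if found is None or cand.sort_key < found.sort_key:
                        found = cand
            if found is not None:
                out.append(found)
                break
    return out


@dataclass
class AlignmentStats:
    n_reads: int = 0
    n_aligned: int = 0
    n_unaligned: int = 0
    n_with_errors: int = 0  # aligned with >= 1 error

    @property
    def fraction_with_errors(self) -> float:
        return self.n_with_errors / self.n_aligned if self.n_aligned else 0.0


def align_readset(
    reads: ReadSet,
    ref: ReferenceGenome,
    params: AlignerParams,
    index: Optional[SeedIndex] = None,
) -> tuple[list[Alignment], list[str], AlignmentStats]:
    """Align every read; returns (alignments, unaligned read ids, stats)."""
    if len(reads) == 0:
        raise ValueError("cannot align an empty read set")
    if index is None:
        index = build_seed_index(ref, params.word_size)
    ref_arr = np.frombuffer(ref.sequence.encode(), dtype=np.uint8)
    alignments: list[Alignment] = []
    unaligned: list[str] = []
    stats = AlignmentStats(n_reads=len(reads))
    for read in reads:
        aln = align_read(read, index, ref, params, _ref_arr=ref_arr)
        if aln is None:
            unaligned.append(read.id)
            stats.n_unaligned += 1
        else:
            alignments.append(aln)
            stats.n_aligned += 1
            if aln.n_errors >= 1:
                stats.n_with_errors += 1
    logger.info(
        "aligned %d/%d reads (%.1f%% with >=1 error), %d unaligned",
        stats.n_aligned,
        stats.n_reads,
        100.0 * stats.fraction_with_errors,
        stats.n_unaligned,
    )
    return alignments, unaligned, stats


def parse_blast_tabular(
    path: str,
    reads: ReadSet,
    ref: ReferenceGenome,
    params: AlignerParams,
) -> list[Alignment]:
    """Import externally produced alignments in BLAST tabular (outfmt 6).

    The 12-column dialect carries no per-column gap layout, so only
    ungapped rows can be reconstructed into full alignments; gapped rows
    are skipped with a warning (imported alignments therefore support SNV
    calling only).
    """
    by_id = {r.id: r for r in reads}
    out: list[Alignment] = []
    n_gapped = 0
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            qseqid, sseqid = f[0], f[1]
            length, mismatch, gapopen = int(f[3]), int(f[4]), int(f[5])
            qstart, qend, sstart, send = int(f[6]), int(f[7]), int(f[8]), int(f[9])
            if sseqid != ref.name or qseqid not in by_id:
                continue
            if gapopen > 0:
                n_gapped += 1
                continue
            read = by_id[qseqid]
            if sstart <= send:
                strand, ref_start = "+", sstart - 1
                oriented = read.sequence
                seg = oriented[qstart - 1 : qend]
            else:
                strand, ref_start = "-", send - 1
                oriented = reverse_complement(read.sequence)
                L = len(oriented)
                seg = oriented[L - qend : L - qstart + 1]
            if mismatch > params.max_errors or length < params.min_align_len:
                continue
            ref_seg = ref.sequence[ref_start : ref_start + len(seg)]
            ops: list[tuple[str, int]] = []
            for rb, qb in zip(ref_seg, seg):
                op = "=" if rb == qb else "X"
                if ops and ops[-1][0] == op:
                    ops[-1] = (op, ops[-1][1] + 1)
                else:
                    ops.append((op, 1))
            out.append(
                Alignment(
                    read_id=qseqid,
                    ref_start=ref_start,
                    ref_end=ref_start + len(seg),
                    strand=strand,
                    ops=tuple(ops),
                    read_sequence=seg,
                    n_mismatches=mismatch,
                    n_gap_columns=0,
                )
            )
    if n_gapped:
        logger.warning(
            "skipped %d gapped BLAST rows: tabular input supports SNV calling only",
            n_gapped,
        )
    return out
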