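"""Pileup construction and consensus difference calling.

A genomic position is called as differing from the mediator when the most
frequent non-reference event among the overlapping reads exceeds the
caller's fraction threshold (strictly) at sufficient coverage — the
"consistently different" rule.  A strict genome-wide pass (default:
fraction > 0.60 at coverage >= 5) is complemented by a relaxed pass
(fraction > 0.50 at coverage >= 2) restricted to flagged hyper-mutated
regions, where depressed coverage would otherwise silence real
differences.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

from .align import Alignment
from .io import ReferenceGenome

logger = logging.getLogger(__name__)

__all__ = [
    "PileupColumn",
    "CallerParams",
    "VariantCall",
    "DifferenceTable",
    "Pileup",
    "build_pileup",
    "call_differences",
    "merge_passes",
    "left_align_indel",
]

SNV, INS, DEL = "SNV", "INS", "DEL"


@dataclass(frozen=True)
class PileupColumn:
    """Per-position tally of read evidence projected on the reference."""

    ref_pos: int
    ref_base: str
    base_counts: dict[str, int]
    del_count: int
    ins_events: dict[str, int]
    coverage: int  # reads overlapping this position, gap columns included


@dataclass(frozen=True)
class CallerParams:
    min_coverage: int = 5
    min_alt_fraction: float = 0.60  # exclusive: a call needs fraction > this
    relaxed_min_coverage: int = 2
    relaxed_min_alt_fraction: float = 0.50

    def __post_init__(self) -> None:
        for f in (self.min_alt_fraction, self.relaxed_min_alt_fraction):
            if not 0.0 < f < 1.0:
                raise ValueError("alt fractions must lie strictly in (0, 1)")
        if self.relaxed_min_coverage > self.min_coverage:
            raise ValueError("relaxed coverage threshold exceeds the strict one")
        if self.relaxed_min_alt_fraction > self.min_alt_fraction:
            raise ValueError("relaxed fraction threshold exceeds the strict one")

    def thresholds(self, mode: str) -> tuple[int, float]:
        if mode == "strict":
            return self.min_coverage, self.min_alt_fraction
        if mode == "relaxed":
            return self.relaxed_min_coverage, self.relaxed_min_alt_fraction
        raise ValueError(f"unknown calling mode {mode!r}")


@dataclass(frozen=True)
class VariantCall:
    ref_pos: int  # 0-based; for INS, the base after which insertion occurs
    type: str  # SNV | INS | DEL
    ref_allele: str  # empty for INS
    alt_allele: str  # empty for DEL
    coverage: int
    alt_fraction: float
    pass_mode: str = "strict"

    def __post_init__(self) -> None:
        if self.type == SNV and (len(self.ref_allele) != 1 or self.ref_allele == self.alt_allele):
            raise ValueError("SNV must substitute a single differing base")
        if self.type == INS and (self.ref_allele != "" or not self.alt_allele):
            raise ValueError("INS must have empty ref allele and non-empty alt")
        if self.type == DEL and (self.alt_allele != "" or not self.ref_allele):
            raise ValueError("DEL must have empty alt allele and non-empty ref")


@dataclass
class DifferenceTable:
    """Ordered set of calls for one isolate against one mediator genome."""

    isolate_label: str
    genome_name: str
    calls: list[VariantCall] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sort()
        seen = set()
        for c in self.calls:
            k = (c.ref_pos, c.type)
            if k in seen:
                raise ValueError(f"duplicate call at position {c.ref_pos} type {c.type}")
            seen.add(k)

    def sort(self) -> None:
        self.calls.sort(key=lambda c: (c.ref_pos, c.type, c.alt_allele))

    def __len__(self) -> int:
        return len(self.calls)

    def __iter__(self):
        return iter(self.calls)


class Pileup:
    """Columnar pileup over one reference sequence.

    Dense numpy tracks hold overlap coverage and deletion counts; the
    (sparse) mismatch and insertion evidence lives in per-position
    dictionaries.  ``depth`` excludes deletion gap columns and is the
    track used for coverage statistics; ``coverage`` (the calling
    denominator) counts every read overlapping the position.
    """

    def __init__(self, ref: ReferenceGenome):
        self.ref = ref
        L = ref.length
        self.overlap = np.zeros(L, dtype=np.int32)
        self.del_count = np.zeros(L, dtype=np.int32)
        self.mismatches: dict[int, Counter] = defaultdict(Counter)
        self.ins_events: dict[int, Counter] = defaultdict(Counter)
        self.n_alignments = 0

    @property
    def depth(self) -> np.ndarray:
        """Reads contributing an aligned base (non-gap column) per position."""
        return self.overlap - self.del_count

    def add(self, aln: Alignment) -> None:
        if aln.ref_start < 0 or aln.ref_end > self.ref.length:
            raise ValueError(
                f"alignment of {aln.read_id!r} [{aln.ref_start},{aln.ref_end}) "
                f"outside genome bounds"
            )
        self.overlap[aln.ref_start : aln.ref_end] += 1
        rpos, qpos = aln.ref_start, 0
        seq = aln.read_sequence
        for op, n in aln.ops:
            if op == "=":
                rpos += n
                qpos += n
            elif op == "X":
                for i in range(n):
                    self.mismatches[rpos + i][seq[qpos + i]] += 1
                rpos += n
                qpos += n
            elif op == "D":
                self.del_count[rpos : rpos + n] += 1
                rpos += n
            else:  # I — anchored to the preceding reference position
                anchor = rpos - 1
                if anchor >= aln.ref_start:
                    self.ins_events[anchor][seq[qpos : qpos + n]] += 1
                qpos += n
        self.n_alignments += 1

    def candidate_positions(self) -> list[int]:
        pos = set(self.mismatches) | set(self.ins_events)
        pos.update(np.nonzero(self.del_count)[0].tolist())
        return sorted(pos)

    def column(self, pos: int) -> PileupColumn:
        ref_base = self.ref.sequence[pos]
        cov = int(self.overlap[pos])
        dels = int(self.del_count[pos])
        alts = dict(self.mismatches.get(pos, {}))
        ref_count = cov - dels - sum(alts.values())
        counts = dict(alts)
        if ref_count > 0:
            counts[ref_base] = counts.get(ref_base, 0) + ref_count
        return PileupColumn(
            ref_pos=pos,
            ref_base=ref_base,
            base_counts=counts,
            del_count=dels,
            ins_events=dict(self.ins_events.get(pos, {})),
            coverage=cov,
        )

    def columns(self) -> Iterable[PileupColumn]:
        for pos in np.nonzero(self.overlap)[0]:
            yield self.column(int(pos))


def build_pileup(alignments: Iterable[Alignment], ref: ReferenceGenome) -> Pileup:
    pile = Pileup(ref)
    for aln in alignments:
        pile.add(aln)
    return pile


def left_align_indel(ref_seq: str, pos: int, allele: str, vtype: str) -> tuple[int, str]:
    """Canonicalize an indel by shifting it left through repeated sequence.

    For INS, ``pos`` is the anchor (base after which the allele is
    inserted); for DEL, ``pos`` is the first deleted base.  Returns the
    left-most equivalent representation so that reads placing an
    ambiguous gap differently still produce one consensus event.
    """
    allele = str(allele)
    if vtype == INS:
        while pos >= 0 and allele and ref_seq[pos] == allele[-1]:
            allele = ref_seq[pos] + allele[:-1]
            pos -= 1
    elif vtype == DEL:
        while pos > 0 and allele and ref_seq[pos - 1] == allele[-1]:
            allele = ref_seq[pos - 1] + allele[:-1]
            pos -= 1
    return pos, allele


def _best_event(col: PileupColumn) -> Optional[tuple[str, str, int]]:
    """Most frequent non-reference event at a column, or None on a tie.

    Returns (type, allele, count).  Ties between two distinct top events
    yield no call: a genuinely mixed column cannot be 'consistent'.
    """
    events: list[tuple[str, str, int]] = []
    for base, cnt in col.base_counts.items():
        if base != col.ref_base and cnt > 0:
            events.append((SNV, base, cnt))
    if col.del_count > 0:
        events.append((DEL, col.ref_base, col.del_count))
    for seq, cnt in col.ins_events.items():
        events.append((INS, seq, cnt))
    if not events:
        return None
    events.sort(key=lambda e: (-e[2], e[0], e[1]))
    if len(events) > 1 and events[0][2] == events[1][2]:
        return None
    return events[0]


def call_differences(
    pileup: Pileup,
    params: CallerParams,
    mode: str = "strict",
    regions: Optional[Sequence] = None,
    isolate_label: str = "",
) -> DifferenceTable:
    """Call consensus differences from a pileup.

    In relaxed mode ``regions`` is required and calling is confined to
    those intervals.  Adjacent single-base deletion calls supported by
    the same gap run merge into one multi-base DEL; insertion runs are
    already keyed by their full inserted sequence, and adjacent insertion
    anchors merge likewise.  Indels are left-aligned before reporting.
    """
    if mode == "relaxed" and regions is None:
        raise ValueError("relaxed calling requires the flagged regions")
    min_cov, min_frac = params.thresholds(mode)

    def in_regions(pos: int) -> bool:
        if regions is None:
            return True
        return any(r.start <= pos < r.end for r in regions)

    raw: list[VariantCall] = []
    n_inspected = 0
    for pos in pileup.candidate_positions():
        if pileup.ref.sequence[pos] == "N":
            continue  # reference N positions are never callable
        if regions is not None and not in_regions(pos):
            continue
        col = pileup.column(pos)
        n_inspected += 1
        if col.coverage < min_cov:
            continue
        ev = _best_event(col)
        if ev is None:
            continue
        vtype, allele, count = ev
        frac = count / col.coverage
        if not frac > min_frac:
            continue
        if vtype == SNV:
            raw.append(VariantCall(pos, SNV, col.ref_base, allele, col.coverage, frac, mode))
        elif vtype == DEL:
            raw.append(VariantCall(pos, DEL, col.ref_base, "", col.coverage, frac, mode))
        else:
            raw.append(VariantCall(pos, INS, "", allele, col.coverage, frac, mode))

    merged = _merge_adjacent_indels(raw, pileup.ref.sequence)
    table = DifferenceTable(isolate_label=isolate_label, genome_name=pileup.ref.name, calls=merged)
    logger.info(
        "%s pass (%s): %d candidate columns inspected, %d calls",
        mode,
        isolate_label or "unlabeled",
        n_inspected,
        len(table),
    )
    return table


def _indel_span(c: VariantCall) -> tuple[int, int]:
    """Reference footprint of an indel call (zero-width boundary for INS)."""
    if c.type == INS:
        return c.ref_pos + 1, c.ref_pos + 1
    return c.ref_pos, c.ref_pos + len(c.ref_allele)


def _reconstruct_group(group: list[VariantCall], ref_seq: str) -> Optional[VariantCall]:
    """Collapse nearby indel calls into one canonical event, if possible.

    Aligners can place the same physical indel differently from read to
    read (e.g. a 2 bp insertion split around a homopolymer run), leaving
    several near-adjacent single-base calls.  Rebuilding the implied
    alternate sequence over the group's window and stripping the common
    context recovers the single underlying event; a group that does not
    reduce to a pure insertion or deletion is left as-is.
    """
    spans = [_indel_span(c) for c in group]
    wstart = min(s for s, _ in spans)
    wend = max(e for _, e in spans)
    ins_after = {c.ref_pos: c.alt_allele for c in group if c.type == INS}
    deleted = set()
    for c in group:
        if c.type == DEL:
            deleted.update(range(c.ref_pos, c.ref_pos + len(c.ref_allele)))
    alt_parts: list[str] = []
    if wstart - 1 in ins_after:
        alt_parts.append(ins_after[wstart - 1])
    for pos in range(wstart, wend):
        if pos not in deleted:
            alt_parts.append(ref_seq[pos])
        if pos in ins_after:
            alt_parts.append(ins_after[pos])
    alt = "".join(alt_parts)
    refseg = ref_seq[wstart:wend]
    # canonicalize: strip shared suffix, then shared prefix
    while refseg and alt and refseg[-1] == alt[-1]:
        refseg, alt = refseg[:-1], alt[:-1]
    offset = 0
    while offset < len(refseg) and offset < len(alt) and refseg[offset] == alt[offset]:
        offset += 1
    refseg, alt = refseg[offset:], alt[offset:]
    cov = min(c.coverage for c in group)
    frac = min(c.alt_fraction for c in group)
    mode = group[0].pass_mode
    if refseg and not alt:
        return VariantCall(wstart + offset, DEL, refseg, "", cov, frac, mode)
    if alt and not refseg:
        return VariantCall(wstart + offset - 1, INS, "", alt, cov, frac, mode)
    return None


def _merge_adjacent_indels(calls: list[VariantCall], ref_seq: str) -> list[VariantCall]:
    """Merge near-adjacent single-base indel calls into multi-base events.

    Indel calls whose reference footprints lie within 2 bp of each other
    are grouped and re-canonicalized together; everything is left-aligned
    before reporting.
    """
    out: list[VariantCall] = [c for c in calls if c.type == SNV]
    indels = sorted(
        (c for c in calls if c.type != SNV), key=lambda c: (_indel_span(c), c.type)
    )
    groups: list[list[VariantCall]] = []
    for c in indels:
        if groups and _indel_span(c)[0] - _indel_span(groups[-1][-1])[1] <= 2:
            groups[-1].append(c)
        else:
            groups.append([c])
    merged: list[VariantCall] = []
    for group in groups:
        collapsed = _reconstruct_group(group, ref_seq) if len(group) > 1 else group[0]
        merged.extend(group if collapsed is None else [collapsed])
    for c in merged:
        if c.type == DEL:
            pos, allele = left_align_indel(ref_seq, c.ref_pos, c.ref_allele, DEL)
            out.append(replace(c, ref_pos=pos, ref_allele=allele))
        else:
            pos, allele = left_align_indel(ref_seq, c.ref_pos, c.alt_allele, INS)
            out.append(replace(c, ref_pos=pos, alt_allele=allele))
    # normalization may collide two representations; keep the better-supported
    dedup: dict[tuple[int, str], VariantCall] = {}
    for c in out:
        k = (c.ref_pos, c.type)
        if k not in dedup or c.coverage > dedup[k].coverage:
            dedup[k] = c
    return list(dedup.values())


def merge_passes(
    strict_table: DifferenceTable,
    relaxed_table: DifferenceTable,
    regions: Sequence,
) -> DifferenceTable:
    """Union of the two passes; the strict call wins where both fire."""
    for c in relaxed_table:
        if not any(r.start <= c.ref_pos < r.end for r in regions):
            raise ValueError(
                f"relaxed call at position {c.ref_pos} lies outside the flagged regions"
            )
    by_key: dict[tuple[int, str], VariantCall] = {}
    for c in relaxed_table:
        by_key[(c.ref_pos, c.type)] = c
    for c in strict_table:
        by_key[(c.ref_pos, c.type)] = c
    return DifferenceTable(
        isolate_label=strict_table.isolate_label,
        genome_name=strict_table.genome_name,
        calls=list(by_key.values()),
    )
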