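"""Subtracting the wild-type difference table from the mutant's.

Differences shared by both isolates reflect the evolutionary distance
between the sequenced strain and the mediator and are discarded; the
remainder — differences unique to the mutant — are the candidate
causative mutations.  Matching is allele-level: two isolates mutated
independently at the same position do not cancel out.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from .pileup import DifferenceTable, VariantCall
from .regions import GenomicRegion

logger = logging.getLogger(__name__)

__all__ = ["match_key", "subtract", "compare_uncovered", "SubtractionResult"]


def match_key(call: VariantCall) -> tuple[int, str, str]:
    """Identity of a mutation for cross-isolate matching.

    Coverage, fraction and pass mode are evidence, not identity, and are
    excluded: a strict call in one isolate matches a relaxed call of the
    same allele in the other.
    """
    return (call.ref_pos, call.type, call.alt_allele)


@dataclass
class SubtractionResult:
    common: DifferenceTable
    unique_to_mutant: DifferenceTable
    unique_to_wt: DifferenceTable


def subtract(mutant: DifferenceTable, wt: DifferenceTable) -> SubtractionResult:
    """Partition the union of two difference tables by shared identity.

    Returns (common, unique_to_mutant, unique_to_wt); the common table
    carries the mutant's records for matched keys.  The cardinality
    identities |mutant| = |common| + |unique_to_mutant| and
    |wt| = |common| + |unique_to_wt| always hold and are asserted.
    """
    if mutant.genome_name != wt.genome_name:
        raise ValueError(
            f"difference tables target different genomes: "
            f"{mutant.genome_name!r} vs {wt.genome_name!r}"
        )
    wt_keys = {match_key(c) for c in wt}
    mut_keys = {match_key(c) for c in mutant}
    common = [c for c in mutant if match_key(c) in wt_keys]
    unique_mut = [c for c in mutant if match_key(c) not in wt_keys]
    unique_wt = [c for c in wt if match_key(c) not in mut_keys]
    res = SubtractionResult(
        common=DifferenceTable(mutant.isolate_label, mutant.genome_name, common),
        unique_to_mutant=DifferenceTable(mutant.isolate_label, mutant.genome_name, unique_mut),
        unique_to_wt=DifferenceTable(wt.isolate_label, wt.genome_name, unique_wt),
    )
    assert len(mutant) == len(res.common) + len(res.unique_to_mutant)
    assert len(wt) == len(res.common) + len(res.unique_to_wt)
    logger.info(
        "subtraction: %d mutant calls, %d wt calls -> %d common, "
        "%d unique to mutant, %d unique to wt",
        len(mutant),
        len(wt),
        len(res.common),
        len(res.unique_to_mutant),
        len(res.unique_to_wt),
    )
    return res


def compare_uncovered(
    mutant_regions: Sequence[GenomicRegion],
    wt_regions: Sequence[GenomicRegion],
    min_len: int = 50,
) -> list[GenomicRegion]:
    """Uncovered intervals present in the mutant but covered in the WT.

    Candidate mutant-specific large deletions: maximal sub-intervals of
    the mutant's zero-coverage runs that no WT zero-coverage run
    overlaps, filtered to ``min_len`` (shorter slivers are read-edge
    fuzz, not deletions).
    """
    wt_sorted = sorted((r.start, r.end) for r in wt_regions)
    out: list[GenomicRegion] = []
    for region in sorted(mutant_regions, key=lambda r: r.start):
        cursor = region.start
        for ws, we in wt_sorted:
            if we <= cursor:
                continue
            if ws >= region.end:
                break
            if ws > cursor:
                _maybe_add(out, cursor, ws, min_len)
            cursor = max(cursor, we)
            if cursor >= region.end:
                break
        if cursor < region.end:
            _maybe_add(out, cursor, region.end, min_len)
    return out


def _maybe_add(out: list[GenomicRegion], start: int, end: int, min_len: int) -> None:
    if end - start >= min_len:
        out.append(
            GenomicRegion(start, end, "uncovered", evidence="unique to mutant")
        )
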