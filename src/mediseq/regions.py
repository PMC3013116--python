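"""Coverage track, uncovered runs, hyper-mutated regions, insertion bound.

Zero-coverage runs mark sequence absent (or unalignably diverged) in the
sequenced isolate; windows that combine depressed coverage (below mean
minus one standard deviation by default) with a cluster of called
differences mark hyper-mutated cassettes that deserve a relaxed
re-calling pass.  The total length of unaligned reads divided by mean
depth bounds how much inserted sequence the mediator cannot show.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "CoverageTrack",
    "GenomicRegion",
    "RegionParams",
    "coverage_profile",
    "find_uncovered_runs",
    "find_hypermutated",
    "estimate_max_insertion",
]


@dataclass(frozen=True)
class GenomicRegion:
    start: int  # 0-based half-open
    end: int
    label: str  # "uncovered" | "hypermutated"
    evidence: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty region [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class RegionParams:
    sd_factor: float = 1.0
    window: int = 500
    min_cluster: int = 5
    min_uncovered_len: int = 1
    exclude_zeros: bool = False  # drop zero-depth positions from mean/SD

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ValueError("window must be positive")
        if self.min_cluster < 1:
            raise ValueError("min_cluster must be >= 1")


@dataclass
class CoverageTrack:
    depths: np.ndarray  # aligned-base depth per reference position
    mean: float
    sd: float
    fraction_uncovered: float

    @property
    def genome_length(self) -> int:
        return len(self.depths)


def coverage_profile(
    pileup, genome_length: Optional[int] = None, exclude_zeros: bool = False
) -> CoverageTrack:
    """Summarize aligned-base depth over the whole genome.

    Positions untouched by any alignment have depth 0.  Mean and SD are
    computed over all genome positions including zeros (the convention
    under which "one SD below the average" is well defined); pass
    ``exclude_zeros=True`` for the covered-only convention.
    """
    depths = np.asarray(pileup.depth, dtype=np.int64)
    if genome_length is not None and genome_length != len(depths):
        raise ValueError("genome_length disagrees with the pileup's reference")
    pool = depths[depths > 0] if exclude_zeros else depths
    mean = float(pool.mean()) if pool.size else 0.0
    sd = float(pool.std()) if pool.size else 0.0
    frac_uncov = float(np.count_nonzero(depths == 0)) / len(depths) if len(depths) else 1.0
    return CoverageTrack(depths=depths, mean=mean, sd=sd, fraction_uncovered=frac_uncov)


def find_uncovered_runs(
    track: CoverageTrack, min_uncovered_len: int = 1
) -> tuple[list[GenomicRegion], int, float]:
    """Maximal zero-depth runs of at least ``min_uncovered_len`` bases.

    Returns (regions, total uncovered bases, percent of genome to the
    nearest whole percent).  The total counts every zero-depth base,
    regardless of the run-length filter applied to the region list.
    """
    zero = track.depths == 0
    total = int(np.count_nonzero(zero))
    percent = round(100.0 * total / track.genome_length) if track.genome_length else 0.0
    regions: list[GenomicRegion] = []
    if total:
        padded = np.concatenate(([False], zero, [False]))
        edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
        for s, e in zip(edges[::2], edges[1::2]):
            if e - s >= min_uncovered_len:
                regions.append(GenomicRegion(int(s), int(e), "uncovered", f"run of {e - s} bp"))
    return regions, total, float(percent)


def find_hypermutated(
    track: CoverageTrack,
    diff_table,
    params: RegionParams = RegionParams(),
) -> list[GenomicRegion]:
    """Sliding-window scan for low-coverage mutation clusters.

    A window (length ``window``, step ``window // 2``) qualifies when its
    mean depth falls below ``track.mean - sd_factor * track.sd`` AND it
    holds at least ``min_cluster`` called differences — both signals are
    required.  Overlapping qualifying windows merge into one region.
    """
    L = track.genome_length
    w = min(params.window, L)
    step = max(1, w // 2)
    cutoff = track.mean - params.sd_factor * track.sd
    csum = np.concatenate(([0], np.cumsum(track.depths)))
    call_pos = np.asarray(sorted(c.ref_pos for c in diff_table), dtype=np.int64)
    hits: list[tuple[int, int]] = []
    for start in range(0, max(1, L - w + 1), step):
        end = min(L, start + w)
        mean_depth = (csum[end] - csum[start]) / (end - start)
        if mean_depth >= cutoff:
            continue
        n_calls = int(np.searchsorted(call_pos, end) - np.searchsorted(call_pos, start))
        if n_calls >= params.min_cluster:
            hits.append((start, end))
    merged: list[list[int]] = []
    for s, e in hits:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [
        GenomicRegion(s, e, "hypermutated", f"window scan, cutoff {cutoff:.1f}x")
        for s, e in merged
    ]


def union_regions(*region_lists: Sequence[GenomicRegion], label: str = "hypermutated") -> list[GenomicRegion]:
    """Union several region lists into disjoint, sorted, merged intervals."""
    intervals = sorted((r.start, r.end) for rl in region_lists for r in rl)
    merged: list[list[int]] = []
    for s, e in intervals:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [GenomicRegion(s, e, label, "union of per-isolate scans") for s, e in merged]


def estimate_max_insertion(unaligned_reads, track: CoverageTrack) -> int:
    """Upper bound on total inserted sequence absent from the mediator.

    Reads from inserted material cannot align, so summing unaligned read
    lengths and dividing by the mean depth bounds the inserted bases;
    the bound is floored to whole bases.
    """
    if track.mean <= 0:
        raise ValueError("mean depth must be positive to bound insertions")
    total = sum(len(r.sequence) for r in unaligned_reads)
    return math.floor(total / track.mean)
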