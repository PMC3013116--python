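"""End-to-end orchestration: align, call, subtract, annotate.

``run_full`` executes the whole mediator-based resequencing workflow for
one wild-type / mutant isolate pair: both read sets are aligned to the
mediator, per-isolate difference tables are called with the strict
consensus rule, hyper-mutated regions flagged on the wild-type coverage
track trigger a relaxed re-call in both isolates, the wild-type table is
subtracted from the mutant's, uncovered-region sets are compared for
mutant-specific large deletions, and the mutant-unique calls are
annotated against the supplied gene features.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Optional

import yaml

from . import annotate as ann
from . import io
from .align import AlignerParams, align_readset, build_seed_index, default_min_align_len
from .compare import compare_uncovered, subtract
from .pileup import CallerParams, DifferenceTable, build_pileup, call_differences, merge_passes
from .regions import (
    RegionParams,
    coverage_profile,
    estimate_max_insertion,
    find_hypermutated,
    find_uncovered_runs,
    union_regions,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "IsolateResult", "PipelineResult", "run_isolate", "run_full"]


@dataclass
class PipelineConfig:
    """Flat key-value configuration covering every tunable of the pipeline."""

    reference: str = ""
    reference_name: Optional[str] = None  # pick one record of a multi-FASTA
    wt_reads: str = ""
    mutant_reads: str = ""
    features: Optional[str] = None
    features_dialect: str = "gff3"
    reads_format: str = "fastq"
    outdir: str = "mediseq_out"
    # aligner
    word_size: int = 11
    max_errors: int = 6
    min_align_len: Optional[int] = None  # None -> ceil(0.8 x modal read length)
    both_strands: bool = True
    # caller
    min_coverage: int = 5
    min_alt_fraction: float = 0.60
    relaxed_min_coverage: int = 2
    relaxed_min_alt_fraction: float = 0.50
    # regions
    sd_factor: float = 1.0
    window: int = 500
    min_cluster: int = 5
    min_uncovered_len: int = 1
    min_unique_deletion_len: int = 50
    exclude_zeros: bool = False
    write_sam: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def aligner_params(self, modal_read_len: int) -> AlignerParams:
        mal = (
            self.min_align_len
            if self.min_align_len is not None
            else default_min_align_len(modal_read_len)
        )
        return AlignerParams(
            word_size=self.word_size,
            max_errors=self.max_errors,
            min_align_len=mal,
            both_strands=self.both_strands,
        )

    def caller_params(self) -> CallerParams:
        return CallerParams(
            min_coverage=self.min_coverage,
            min_alt_fraction=self.min_alt_fraction,
            relaxed_min_coverage=self.relaxed_min_coverage,
            relaxed_min_alt_fraction=self.relaxed_min_alt_fraction,
        )

    def region_params(self) -> RegionParams:
        return RegionParams(
            sd_factor=self.sd_factor,
            window=self.window,
            min_cluster=self.min_cluster,
            min_uncovered_len=self.min_uncovered_len,
            exclude_zeros=self.exclude_zeros,
        )


@dataclass
class IsolateResult:
    label: str
    alignments: list
    unaligned_ids: list[str]
    stats: object
    pileup: object
    track: object
    strict_table: DifferenceTable
    merged_table: DifferenceTable
    uncovered: list
    max_insertion_bound: int


@dataclass
class PipelineResult:
    wt: IsolateResult
    mutant: IsolateResult
    hypermutated: list
    common: DifferenceTable
    unique_to_mutant: DifferenceTable
    unique_to_wt: DifferenceTable
    mutant_only_uncovered: list
    annotations: list = field(default_factory=list)
    summary: dict = field(default_factory=dict)


def run_isolate(label, reads, genome, aligner_params, caller_params, region_params, index=None):
    """Align one isolate's reads and produce its strict-pass state."""
    alignments, unaligned, stats = align_readset(reads, genome, aligner_params, index=index)
    pileup = build_pileup(alignments, genome)
    track = coverage_profile(pileup, exclude_zeros=region_params.exclude_zeros)
    strict = call_differences(pileup, caller_params, mode="strict", isolate_label=label)
    uncovered, _, _ = find_uncovered_runs(track, region_params.min_uncovered_len)
    unaligned_set = set(unaligned)
    bound = (
        estimate_max_insertion([r for r in reads if r.id in unaligned_set], track)
        if track.mean > 0
        else 0
    )
    return IsolateResult(
        label=label,
        alignments=alignments,
        unaligned_ids=unaligned,
        stats=stats,
        pileup=pileup,
        track=track,
        strict_table=strict,
        merged_table=strict,
        uncovered=uncovered,
        max_insertion_bound=bound,
    )


def run_full(config: PipelineConfig, write_outputs: bool = True) -> PipelineResult:
    if not config.reference:
        raise ValueError("config.reference is required")
    genomes = io.read_fasta(config.reference)
    if config.reference_name:
        matches = [g for g in genomes if g.name == config.reference_name]
        if not matches:
            raise ValueError(f"no record named {config.reference_name!r} in reference")
        genome = matches[0]
    else:
        genome = genomes[0]

    wt_reads = io.read_reads(config.wt_reads, config.reads_format)
    mut_reads = io.read_reads(config.mutant_reads, config.reads_format)
    features = (
        io.read_features(config.features, config.features_dialect, genome)
        if config.features
        else []
    )
    result = _run_core(genome, wt_reads, mut_reads, features, config)
    if write_outputs:
        _write_bundle(result, genome, wt_reads, mut_reads, config)
    return result


def _run_core(genome, wt_reads, mut_reads, features, config: PipelineConfig) -> PipelineResult:
    caller = config.caller_params()
    rparams = config.region_params()
    index = build_seed_index(genome, config.word_size)

    wt = run_isolate(
        "wt", wt_reads, genome,
        config.aligner_params(wt_reads.modal_length or 33), caller, rparams, index,
    )
    mut = run_isolate(
        "mutant", mut_reads, genome,
        config.aligner_params(mut_reads.modal_length or 33), caller, rparams, index,
    )

    # hyper-mutated regions are flagged on either isolate's coverage track
    # (an under-aligning isolate sees the dip more clearly than its deeper
    # partner) and the union drives the relaxed re-call of both isolates
    hyper = union_regions(
        find_hypermutated(wt.track, wt.strict_table, rparams),
        find_hypermutated(mut.track, mut.strict_table, rparams),
    )
    for iso in (wt, mut):
        if hyper:
            relaxed = call_differences(
                iso.pileup, caller, mode="relaxed", regions=hyper, isolate_label=iso.label
            )
            iso.merged_table = merge_passes(iso.strict_table, relaxed, hyper)
        else:
            iso.merged_table = iso.strict_table

    res = subtract(mut.merged_table, wt.merged_table)
    mut_only_uncov = compare_uncovered(
        mut.uncovered, wt.uncovered, config.min_unique_deletion_len
    )
    annotations = ann.annotate_table(res.unique_to_mutant, features, genome) if features else []

    summary = {
        "genome": genome.name,
        "genome_length": genome.length,
        "wt_reads": wt.stats.n_reads,
        "wt_aligned": wt.stats.n_aligned,
        "wt_fraction_with_errors": round(wt.stats.fraction_with_errors, 4),
        "mutant_reads": mut.stats.n_reads,
        "mutant_aligned": mut.stats.n_aligned,
        "mutant_fraction_with_errors": round(mut.stats.fraction_with_errors, 4),
        "wt_mean_coverage": round(wt.track.mean, 2),
        "mutant_mean_coverage": round(mut.track.mean, 2),
        "wt_calls": len(wt.merged_table),
        "mutant_calls": len(mut.merged_table),
        "common": len(res.common),
        "unique_to_mutant": len(res.unique_to_mutant),
        "unique_to_wt": len(res.unique_to_wt),
        "hypermutated_regions": len(hyper),
        "mutant_only_uncovered_regions": len(mut_only_uncov),
        "wt_max_insertion_bound": wt.max_insertion_bound,
        "mutant_max_insertion_bound": mut.max_insertion_bound,
    }
    logger.info("pipeline summary: %s", summary)
    return PipelineResult(
        wt=wt,
        mutant=mut,
        hypermutated=hyper,
        common=res.common,
        unique_to_mutant=res.unique_to_mutant,
        unique_to_wt=res.unique_to_wt,
        mutant_only_uncovered=mut_only_uncov,
        annotations=annotations,
        summary=summary,
    )


def _write_bundle(result: PipelineResult, genome, wt_reads, mut_reads, config: PipelineConfig):
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        def _w(name, fn, *args):
            p = outdir / name
            fn(*args, p)
            written.append(p)

        _w("wt_differences.tsv", io.write_difference_table, result.wt.merged_table)
        _w("mutant_differences.tsv", io.write_difference_table, result.mutant.merged_table)
        _w("common.tsv", io.write_difference_table, result.common)
        _w("unique_to_mutant.tsv", io.write_difference_table, result.unique_to_mutant)
        _w("unique_to_wt.tsv", io.write_difference_table, result.unique_to_wt)
        _w("wt_uncovered.bed", io.write_regions_bed, result.wt.uncovered, genome.name)
        _w("mutant_uncovered.bed", io.write_regions_bed, result.mutant.uncovered, genome.name)
        _w("hypermutated.bed", io.write_regions_bed, result.hypermutated, genome.name)
        _w(
            "mutant_only_uncovered.bed",
            io.write_regions_bed,
            result.mutant_only_uncovered,
            genome.name,
        )
        if result.annotations:
            _w("unique_to_mutant_annotated.tsv", ann.write_annotation_table, result.annotations)
        if config.write_sam:
            _w("wt.sam", io.write_sam, result.wt.alignments, result.wt.unaligned_ids, genome, wt_reads)
            _w(
                "mutant.sam",
                io.write_sam,
                result.mutant.alignments,
                result.mutant.unaligned_ids,
                genome,
                mut_reads,
            )
        p = outdir / "summary.json"
        with open(p, "w") as fh:
            json.dump(result.summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
        written.append(p)
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise
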