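"""Synthetic mediator / wild-type / mutant genomes and read sets.

The generator emulates the study design this pipeline targets: a
sequenced "mediator" genome of a related strain; a wild-type isolate at
roughly 0.75% substitution divergence from it; a mutant isolate carrying
a handful of additional point mutations and a small insertion on top of
the wild type; optionally shared large deletions and locally
hyper-diverged cassettes; and uniform unpaired short reads (33 bp by
default) with a low per-base substitution error rate.  Every planted
event is recorded in a truth set, in mediator coordinates, so pipeline
output can be checked exactly.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .io import GeneFeature, Read, ReadSet, ReferenceGenome, write_fasta
from .pileup import DEL, INS, SNV, left_align_indel

__all__ = [
    "PlantedEvent",
    "TruthSet",
    "ScenarioConfig",
    "Scenario",
    "generate_mediator",
    "derive_genome",
    "simulate_reads",
    "build_scenario",
    "default_scenario_config",
    "paper_scale_config",
    "plant_repeat_deletion",
    "write_fasta_scenario",
    "toy_gene_grid",
    "write_gene_grid_gff3",
    "write_truth_tsv",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = {b: i for i, b in enumerate("ACGT")}


@dataclass(frozen=True)
class PlantedEvent:
    """One planted difference, in parent (mediator) coordinates.

    For SNV: ref/alt single bases at ``pos``.  For INS: ``alt`` inserted
    between ``pos`` and ``pos+1`` (anchor convention shared with the
    caller).  For DEL: ``ref`` spans the deleted bases starting at
    ``pos``.
    """

    pos: int
    type: str
    ref: str
    alt: str
    label: str  # "shared" | "unique"

    def span(self) -> tuple[int, int]:
        if self.type == DEL:
            return self.pos, self.pos + len(self.ref)
        if self.type == INS:
            return self.pos, self.pos + 2  # anchor and the next base
        return self.pos, self.pos + 1


@dataclass
class TruthSet:
    events: list[PlantedEvent] = field(default_factory=list)
    cassettes: list[tuple[int, int, float]] = field(default_factory=list)
    large_deletions: list[tuple[int, int]] = field(default_factory=list)

    def by_label(self, label: str) -> list[PlantedEvent]:
        return [e for e in self.events if e.label == label]

    def expected_call_keys(self, ref_sequence: str, label: Optional[str] = None) -> set:
        """Match keys (pos, type, alt) the caller should report, indels
        left-aligned to the same canonical form the caller uses."""
        keys = set()
        for e in self.events:
            if label is not None and e.label != label:
                continue
            if e.type == SNV:
                keys.add((e.pos, SNV, e.alt))
            elif e.type == INS:
                pos, allele = left_align_indel(ref_sequence, e.pos, e.alt, INS)
                keys.add((pos, INS, allele))
            else:
                pos, allele = left_align_indel(ref_sequence, e.pos, e.ref, DEL)
                keys.add((pos, DEL, ""))
        return keys


def generate_mediator(
    length: int, gc_fraction: float = 0.5, seed: int = 42, name: str = "mediator"
) -> ReferenceGenome:
    """I.i.d. random genome at the requested GC content."""
    if length < 1000:
        raise ValueError("mediator length must be >= 1000")
    if not 0.0 < gc_fraction < 1.0:
        raise ValueError("gc_fraction must lie strictly in (0, 1)")
    rng = np.random.default_rng(seed)
    at = (1.0 - gc_fraction) / 2.0
    gc = gc_fraction / 2.0
    codes = rng.choice(4, size=length, p=[at, gc, gc, at])
    seq = _BASES[codes].tobytes().decode()
    return ReferenceGenome(name, seq)


def _sample_positions(
    rng: np.random.Generator,
    length: int,
    n: int,
    occupied: set[int],
    margin: int,
    width: int = 1,
) -> list[int]:
    """Draw n event start positions avoiding occupied bases and genome ends.

    The margin keeps events away from coverage ramp-down at the genome
    ends, where read sampling alone cannot reach calling depth.
    """
    out: list[int] = []
    lo, hi = margin, length - margin - width
    if hi <= lo:
        raise ValueError("genome too short for the requested margin")
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 100 * n + 1000:
            raise RuntimeError("could not place events without overlap")
        p = int(rng.integers(lo, hi))
        if any(q in occupied for q in range(p - 1, p + width + 1)):
            continue
        out.append(p)
        occupied.update(range(p, p + width))
    return out


def _plan_substitutions(
    rng, seq: str, n: int, occupied: set[int], label: str, margin: int
) -> list[PlantedEvent]:
    events = []
    for p in _sample_positions(rng, len(seq), n, occupied, margin):
        ref = seq[p]
        alt = "ACGT"[(_CODE[ref] + 1 + int(rng.integers(3))) % 4]
        events.append(PlantedEvent(p, SNV, ref, alt, label))
    return events


def _plan_small_indels(
    rng, seq: str, n: int, occupied: set[int], label: str, margin: int, lengths=(1, 2, 3)
) -> list[PlantedEvent]:
    events = []
    for i in range(n):
        k = int(rng.choice(lengths))
        if i % 2 == 0:  # insertion
            p = _sample_positions(rng, len(seq), 1, occupied, margin, width=2)[0]
            ins = "".join("ACGT"[int(b)] for b in rng.integers(0, 4, k))
            events.append(PlantedEvent(p, INS, "", ins, label))
        else:  # deletion
            p = _sample_positions(rng, len(seq), 1, occupied, margin, width=k)[0]
            events.append(PlantedEvent(p, DEL, seq[p : p + k], "", label))
    return events


def _plan_cassette(
    rng, seq: str, interval: tuple[int, int], divergence: float, occupied: set[int], label: str
) -> list[PlantedEvent]:
    s, e = interval
    events = []
    for p in range(s, e):
        if p in occupied:
            continue
        if rng.random() < divergence:
            ref = seq[p]
            alt = "ACGT"[(_CODE[ref] + 1 + int(rng.integers(3))) % 4]
            events.append(PlantedEvent(p, SNV, ref, alt, label))
            occupied.add(p)
    return events


def _apply_events(seq: str, events: Sequence[PlantedEvent]) -> str:
    """Apply events (mediator coordinates) right-to-left to keep offsets valid."""
    s = list(seq)
    for e in sorted(events, key=lambda e: -e.pos):
        if e.type == SNV:
            assert s[e.pos] == e.ref
            s[e.pos] = e.alt
        elif e.type == INS:
            s[e.pos + 1 : e.pos + 1] = list(e.alt)
        else:
            assert "".join(s[e.pos : e.pos + len(e.ref)]) == e.ref
            del s[e.pos : e.pos + len(e.ref)]
    return "".join(s)


def derive_genome(
    parent: ReferenceGenome,
    n_subs: int = 0,
    n_small_indels: int = 0,
    deletions: Sequence[tuple[int, int]] = (),
    cassettes: Sequence[tuple[tuple[int, int], float]] = (),
    seed: int = 0,
    name: str = "derived",
    label: str = "shared",
    margin: int = 100,
) -> tuple[ReferenceGenome, TruthSet]:
    """Derive a child genome from ``parent`` with planted, recorded events."""
    rng = np.random.default_rng(seed)
    occupied: set[int] = set()
    truth = TruthSet()
    for (s, e) in deletions:
        if not 0 <= s < e <= parent.length:
            raise ValueError(f"deletion interval [{s}, {e}) out of bounds")
        occupied.update(range(max(0, s - 1), min(parent.length, e + 1)))
        truth.events.append(PlantedEvent(s, DEL, parent.sequence[s:e], "", label))
        truth.large_deletions.append((s, e))
    for interval, div in cassettes:
        truth.events.extend(
            _plan_cassette(rng, parent.sequence, interval, div, occupied, label)
        )
        truth.cassettes.append((interval[0], interval[1], div))
    truth.events.extend(
        _plan_substitutions(rng, parent.sequence, n_subs, occupied, label, margin)
    )
    truth.events.extend(
        _plan_small_indels(rng, parent.sequence, n_small_indels, occupied, label, margin)
    )
    truth.events.sort(key=lambda e: e.pos)
    return ReferenceGenome(name, _apply_events(parent.sequence, truth.events)), truth


def simulate_reads(
    genome: ReferenceGenome,
    read_len: int = 33,
    mean_coverage: float = 50.0,
    error_rate: float = 0.002,
    seed: int = 0,
    id_prefix: str = "read",
) -> ReadSet:
    """Uniform unpaired reads with i.i.d. substitution errors.

    Read count is round(mean_coverage * genome_length / read_len); start
    positions and strands are uniform; qualities are omitted (emitted as
    constant Q30 when written to FASTQ).
    """
    if mean_coverage <= 0:
        raise ValueError("mean_coverage must be positive")
    if read_len > genome.length:
        raise ValueError("read_len exceeds genome length")
    rng = np.random.default_rng(seed)
    n = int(round(mean_coverage * genome.length / read_len))
    arr = np.frombuffer(genome.sequence.encode(), dtype=np.uint8)
    code = np.zeros(256, dtype=np.uint8)
    for b, i in _CODE.items():
        code[ord(b)] = i
    genome_codes = code[arr]
    starts = rng.integers(0, genome.length - read_len + 1, size=n)
    mat = genome_codes[starts[:, None] + np.arange(read_len)[None, :]].copy()
    err = rng.random((n, read_len)) < error_rate
    if err.any():
        shift = rng.integers(1, 4, size=int(err.sum()))
        mat[err] = (mat[err] + shift) % 4
    rev = rng.random(n) < 0.5
    mat[rev] = (3 - mat[rev])[:, ::-1]  # reverse complement in code space
    letters = _BASES[mat]
    reads = [
        Read(f"{id_prefix}_{i:07d}", letters[i].tobytes().decode())
        for i in range(n)
    ]
    return ReadSet(reads)


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions for a full two-isolate synthetic experiment."""

    genome_length: int = 100_000
    gc_fraction: float = 0.5
    shared_subs: int = 750  # ~0.75% divergence between WT and mediator
    shared_deletions: tuple[tuple[int, int], ...] = ()
    shared_cassettes: tuple[tuple[tuple[int, int], float], ...] = ()
    unique_subs: int = 19
    unique_insertions: tuple[str, ...] = ("GT",)  # one 2 bp insertion
    unique_deletions: tuple[tuple[int, int], ...] = ()
    read_len: int = 33
    mean_coverage: float = 50.0
    error_rate: float = 0.002
    margin: int = 100


def default_scenario_config() -> ScenarioConfig:
    return ScenarioConfig()


def paper_scale_config() -> ScenarioConfig:
    """Full-genome-scale preset (slow; not used by the test suite)."""
    return ScenarioConfig(
        genome_length=3_782_950,
        shared_subs=28_379,
        unique_subs=19,
        unique_insertions=("GT",),
        mean_coverage=51.0,
    )


@dataclass
class Scenario:
    config: ScenarioConfig
    mediator: ReferenceGenome
    wt_genome: ReferenceGenome
    mutant_genome: ReferenceGenome
    truth: TruthSet
    wt_reads: ReadSet
    mutant_reads: ReadSet


def build_scenario(config: ScenarioConfig = ScenarioConfig(), seed: int = 42) -> Scenario:
    """Generate the whole two-isolate experiment deterministically.

    Shared events are applied to both the WT and the mutant genome;
    unique events only to the mutant, so the expected pipeline outcome
    is exactly the unique slice of the truth set.  Sub-seeds are derived
    from ``seed`` for each stochastic stage.
    """
    rng = np.random.default_rng(seed)
    sub = [int(s) for s in rng.integers(0, 2**31 - 1, size=5)]
    mediator = generate_mediator(config.genome_length, config.gc_fraction, seed=sub[0])

    occupied: set[int] = set()
    truth = TruthSet()
    srng = np.random.default_rng(sub[1])
    for (s, e) in config.shared_deletions:
        occupied.update(range(max(0, s - 1), min(mediator.length, e + 1)))
        truth.events.append(PlantedEvent(s, DEL, mediator.sequence[s:e], "", "shared"))
        truth.large_deletions.append((s, e))
    for interval, div in config.shared_cassettes:
        truth.events.extend(
            _plan_cassette(srng, mediator.sequence, interval, div, occupied, "shared")
        )
        truth.cassettes.append((interval[0], interval[1], div))
    truth.events.extend(
        _plan_substitutions(
            srng, mediator.sequence, config.shared_subs, occupied, "shared", config.margin
        )
    )

    urng = np.random.default_rng(sub[2])
    for (s, e) in config.unique_deletions:
        occupied.update(range(max(0, s - 1), min(mediator.length, e + 1)))
        truth.events.append(PlantedEvent(s, DEL, mediator.sequence[s:e], "", "unique"))
        truth.large_deletions.append((s, e))
    truth.events.extend(
        _plan_substitutions(
            urng, mediator.sequence, config.unique_subs, occupied, "unique", config.margin
        )
    )
    for ins_seq in config.unique_insertions:
        p = _sample_positions(urng, mediator.length, 1, occupied, config.margin, width=2)[0]
        truth.events.append(PlantedEvent(p, INS, "", ins_seq, "unique"))

    truth.events.sort(key=lambda e: e.pos)
    shared = truth.by_label("shared")
    wt_genome = ReferenceGenome("wt", _apply_events(mediator.sequence, shared))
    mutant_genome = ReferenceGenome("mutant", _apply_events(mediator.sequence, truth.events))

    wt_reads = simulate_reads(
        wt_genome, config.read_len, config.mean_coverage, config.error_rate,
        seed=sub[3], id_prefix="wt",
    )
    mutant_reads = simulate_reads(
        mutant_genome, config.read_len, config.mean_coverage, config.error_rate,
        seed=sub[4], id_prefix="mut",
    )
    return Scenario(config, mediator, wt_genome, mutant_genome, truth, wt_reads, mutant_reads)


def plant_repeat_deletion(
    sequence: str, pos: int, del_len: int = 42, repeat_len: int = 10
) -> tuple[str, tuple[int, int]]:
    """Engineer a deletion site flanked by a direct repeat.

    Rewrites ``sequence`` so that the ``repeat_len`` bases ending at
    ``pos`` recur as the last ``repeat_len`` bases of the deletion
    interval [pos, pos+del_len) — the geometry that recombination
    between the repeat pair would excise.  Returns the modified parent
    sequence and the deletion interval.
    """
    if repeat_len > del_len:
        raise ValueError("repeat cannot be longer than the deletion")
    if pos - repeat_len < 0 or pos + del_len > len(sequence):
        raise ValueError("not enough flank for the requested geometry")
    repeat = sequence[pos - repeat_len : pos]
    modified = (
        sequence[: pos + del_len - repeat_len] + repeat + sequence[pos + del_len :]
    )
    # break any accidental extension so the repeat length is exactly as asked
    left, right = pos - repeat_len - 1, pos + del_len - repeat_len - 1
    if left >= 0 and modified[left] == modified[right]:
        swap = {"A": "C", "C": "G", "G": "T", "T": "A"}[modified[right]]
        modified = modified[:right] + swap + modified[right + 1 :]
    return modified, (pos, pos + del_len)


def toy_gene_grid(
    genome: ReferenceGenome, gene_len: int = 900, spacing: int = 300
) -> list[GeneFeature]:
    """Regular grid of CDS features with alternating strands."""
    if gene_len % 3 != 0:
        raise ValueError("gene_len must be a multiple of 3")
    feats = []
    i = 0
    start = spacing
    while start + gene_len <= genome.length - spacing:
        strand = "+" if i % 2 == 0 else "-"
        feats.append(
            GeneFeature(f"tg{i:04d}", f"toy gene {i}", start, start + gene_len, strand)
        )
        start += gene_len + spacing
        i += 1
    return feats


def write_gene_grid_gff3(features: Sequence[GeneFeature], genome_name: str, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            fh.write(
                f"{genome_name}\tmediseq\tCDS\t{f.start + 1}\t{f.end}\t.\t{f.strand}\t0\t"
                f"locus_tag={f.locus_tag};product={f.description}\n"
            )


def write_fasta_scenario(scenario: Scenario, outdir) -> dict:
    """Write a scenario to disk: mediator FASTA, per-isolate FASTQ,
    truth TSV, and a toy gene grid GFF3.  Returns the path map."""
    from pathlib import Path

    from .io import write_fastq

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "reference": out / "mediator.fasta",
        "wt_reads": out / "wt_reads.fastq",
        "mutant_reads": out / "mutant_reads.fastq",
        "truth": out / "truth.tsv",
        "features": out / "features.gff3",
    }
    write_fasta([(scenario.mediator.name, scenario.mediator.sequence)], paths["reference"])
    write_fastq(scenario.wt_reads, paths["wt_reads"])
    write_fastq(scenario.mutant_reads, paths["mutant_reads"])
    write_truth_tsv(scenario.truth, paths["truth"])
    feats = toy_gene_grid(scenario.mediator)
    write_gene_grid_gff3(feats, scenario.mediator.name, paths["features"])
    return {k: str(v) for k, v in paths.items()}


def write_truth_tsv(truth: TruthSet, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["position", "type", "ref", "alt", "label"])
        for e in truth.events:
            w.writerow([e.pos + 1, e.type, e.ref or ".", e.alt or ".", e.label])
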