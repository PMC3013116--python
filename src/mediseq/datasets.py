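"""Published worked-example inputs from the Bdellovibrio host-independence study.

The original application of mediator-based resequencing compared
*Bdellovibrio bacteriovorus* 109J (wild type and a host-independent, HI,
mutant) against the HD100 mediator genome.  No raw sequencing data is
publicly deposited, but the study's printed summary numbers, its table
of HI-unique mutations, and its survey of the *hit* locus in 54 HI
isolates are usable as worked-example inputs for the arithmetic and
annotation machinery in this package.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "HD100_GENOME_LENGTH",
    "HD100_UNCOVERED_BASES",
    "HI_TOTAL_DIFFERENCES",
    "WT_TOTAL_DIFFERENCES",
    "SHARED_DIFFERENCES",
    "CodonChange",
    "hi_codon_changes",
    "hit_locus_survey",
    "summarize_survey",
]

# Genome-scale summary of the 109J-vs-HD100 comparison.
HD100_GENOME_LENGTH = 3_782_950
HD100_UNCOVERED_BASES = 150_223
HI_TOTAL_DIFFERENCES = 28_386  # HI mutant vs mediator
WT_TOTAL_DIFFERENCES = 28_379  # wild type vs mediator
SHARED_DIFFERENCES = 28_367  # identical in both isolates


@dataclass(frozen=True)
class CodonChange:
    """One HI-unique coding substitution: position (1-based on HD100),
    locus tag, WT and mutant codons, and the published amino acids."""

    position: int
    locus: str
    wt_codon: str
    mut_codon: str
    wt_aa: str
    mut_aa: str


def hi_codon_changes() -> list[CodonChange]:
    """The coding single-base substitutions unique to the HI isolate.

    Mutant codons are given uppercase; the original report lowercases the
    substituted base (see :func:`mediseq.annotate.mark_mutated_bases`).
    Intergenic changes and the 2 bp frameshift insertion at the *hit*
    locus (position 96981, Bd0108) are not codon-level and are omitted.
    """
    return [
        CodonChange(752169, "Bd0802", "ATC", "ATT", "I", "I"),
        CodonChange(807701, "Bd0859", "GGG", "TGG", "G", "W"),
        CodonChange(1262908, "Bd1335", "GGG", "AGG", "G", "R"),
        CodonChange(1322643, "Bd1395", "CGC", "TGC", "R", "C"),
        CodonChange(2110823, "Bd2212", "TCT", "TTT", "S", "F"),
        CodonChange(2117292, "Bd2221", "GGA", "GAG", "G", "E"),
        CodonChange(2309751, "Bd2403", "GGG", "GAG", "G", "E"),
        CodonChange(2309974, "", "ACG", "CCG", "T", "P"),
        CodonChange(2746436, "Bd2838", "TAT", "TGT", "Y", "C"),
        CodonChange(2876741, "Bd2981", "AAG", "AGG", "K", "R"),
        CodonChange(2891582, "Bd2994", "CAT", "CAA", "H", "Q"),
        CodonChange(3373629, "Bd3464", "GAC", "AAC", "D", "N"),
        CodonChange(3621096, "Bd3749", "ATG", "ATT", "M", "I"),
        CodonChange(3781899, "Bd3912", "TCC", "TAC", "S", "Y"),
    ]


def hit_locus_survey() -> dict[str, int]:
    """*hit* locus ORF4 status across the 54 surveyed HI isolates."""
    return {
        "frameshift": 19,
        "deletion_42bp": 25,
        "stop_codon": 3,
        "point_mutation": 1,
        "no_hit_mutation": 6,
    }


def summarize_survey(counts: dict[str, int]) -> dict[str, float]:
    """Percentages (nearest whole percent) of isolate classes in a survey."""
    total = sum(counts.values())
    if total == 0:
        raise ValueError("empty survey")
    with_hit = total - counts.get("no_hit_mutation", 0)
    out = {k: round(100.0 * v / total) for k, v in counts.items()}
    out["any_hit_mutation"] = round(100.0 * with_hit / total)
    out["total"] = total
    return out
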