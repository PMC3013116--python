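"""Gene-context and codon-level annotation of called variants.

SNVs inside a CDS are classified synonymous / non-synonymous / nonsense
by substituting the called base into the codon read in the feature's
frame (bacterial genetic code, translation table 11); indels whose
length is not a multiple of three are frameshifts.  Deletion breakpoints
are additionally screened for flanking direct repeats, the signature of
recombination-mediated loss.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Optional, Sequence

from Bio.Seq import Seq

from .align import reverse_complement
from .io import GeneFeature, ReferenceGenome
from .pileup import DEL, INS, SNV, VariantCall

__all__ = [
    "VariantAnnotation",
    "classify_codon_change",
    "annotate_variant",
    "annotate_table",
    "find_flanking_direct_repeat",
    "write_annotation_table",
    "mark_mutated_bases",
]

EFFECTS = ("synonymous", "nonsynonymous", "nonsense", "frameshift", "inframe_indel", "intergenic")


@dataclass(frozen=True)
class VariantAnnotation:
    variant: VariantCall
    locus_tag: str  # "intergenic" when no feature overlaps
    description: str = ""
    wt_codon: Optional[str] = None
    mut_codon: Optional[str] = None
    wt_aa: Optional[str] = None
    mut_aa: Optional[str] = None
    effect: str = "intergenic"


def _translate_codon(codon: str) -> str:
    return str(Seq(codon).translate(table=11))


def classify_codon_change(wt_codon: str, mut_codon: str) -> tuple[str, str, str]:
    """Amino-acid consequence of replacing one codon with another.

    Internal codons only: alternative start codons get no special
    treatment.  Returns (wt_aa, mut_aa, effect) with effect one of
    synonymous / nonsynonymous / nonsense.
    """
    for codon in (wt_codon, mut_codon):
        if len(codon) != 3 or any(b not in "ACGT" for b in codon.upper()):
            raise ValueError(f"not a valid codon: {codon!r}")
    wt_aa = _translate_codon(wt_codon.upper())
    mut_aa = _translate_codon(mut_codon.upper())
    if wt_aa == mut_aa:
        effect = "synonymous"
    elif mut_aa == "*" and wt_aa != "*":
        effect = "nonsense"
    else:
        effect = "nonsynonymous"
    return wt_aa, mut_aa, effect


def _codon_for(feature: GeneFeature, ref: ReferenceGenome, pos: int, alt: str) -> tuple[str, str]:
    """Extract (wt_codon, mut_codon) for an SNV at ``pos`` inside ``feature``."""
    if feature.strand == "+":
        offset = pos - feature.start
        ci = offset // 3
        codon_start = feature.start + 3 * ci
        wt = ref.sequence[codon_start : codon_start + 3]
        within = offset % 3
        mut_base = alt
    else:
        gene = reverse_complement(ref.sequence[feature.start : feature.end])
        offset = (feature.end - 1) - pos
        ci = offset // 3
        wt = gene[3 * ci : 3 * ci + 3]
        within = offset % 3
        mut_base = reverse_complement(alt)
    mut = wt[:within] + mut_base + wt[within + 1 :]
    return wt, mut


def annotate_variant(
    variant: VariantCall,
    features: Sequence[GeneFeature],
    ref: ReferenceGenome,
) -> list[VariantAnnotation]:
    """Annotate one variant against the feature set.

    Returns one annotation per overlapping feature, or a single
    intergenic record when none overlaps.  A CDS of length not divisible
    by three (and not flagged partial) is an annotation error.
    """
    overlapping = [f for f in features if f.contains(variant.ref_pos)]
    if not overlapping:
        return [VariantAnnotation(variant=variant, locus_tag="intergenic", effect="intergenic")]
    out: list[VariantAnnotation] = []
    for feat in overlapping:
        if feat.length % 3 != 0 and not feat.partial:
            raise ValueError(
                f"CDS {feat.locus_tag!r} length {feat.length} is not a multiple of 3"
            )
        if variant.type == SNV:
            wt, mut = _codon_for(feat, ref, variant.ref_pos, variant.alt_allele)
            wt_aa, mut_aa, effect = classify_codon_change(wt, mut)
            out.append(
                VariantAnnotation(
                    variant=variant,
                    locus_tag=feat.locus_tag,
                    description=feat.description,
                    wt_codon=wt,
                    mut_codon=mut,
                    wt_aa=wt_aa,
                    mut_aa=mut_aa,
                    effect=effect,
                )
            )
        else:
            indel_len = len(variant.alt_allele) if variant.type == INS else len(variant.ref_allele)
            effect = "frameshift" if indel_len % 3 != 0 else "inframe_indel"
            out.append(
                VariantAnnotation(
                    variant=variant,
                    locus_tag=feat.locus_tag,
                    description=feat.description,
                    effect=effect,
                )
            )
    return out


def annotate_table(table, features: Sequence[GeneFeature], ref: ReferenceGenome) -> list[VariantAnnotation]:
    out: list[VariantAnnotation] = []
    for call in table:
        out.extend(annotate_variant(call, features, ref))
    return out


def find_flanking_direct_repeat(
    ref: ReferenceGenome,
    deletion_interval: tuple[int, int],
    min_repeat: int = 4,
    max_repeat: int = 50,
) -> Optional[tuple[int, str]]:
    """Longest direct repeat flanking a deletion, or None.

    Reports the largest k in [min_repeat, max_repeat] for which the k
    bases immediately preceding the deletion start equal the k bases
    ending at the deletion end — the geometry left by recombination
    between a repeat pair that excises the intervening segment.
    """
    s, e = deletion_interval
    if not (0 <= s < e <= ref.length):
        raise ValueError(f"deletion interval [{s}, {e}) outside genome bounds")
    seq = ref.sequence
    for k in range(min(max_repeat, s), min_repeat - 1, -1):
        if seq[s - k : s] == seq[e - k : e]:
            return k, seq[s - k : s]
    return None


def mark_mutated_bases(wt_codon: str, mut_codon: str) -> str:
    """Lowercase the substituted bases of the mutant codon for reports."""
    return "".join(
        m.lower() if m != w else m for w, m in zip(wt_codon.upper(), mut_codon.upper())
    )


ANNOTATION_COLUMNS = [
    "position",
    "type",
    "locus",
    "description",
    "wt_codon",
    "mut_codon",
    "wt_aa",
    "mut_aa",
    "effect",
]


def write_annotation_table(annotations: Sequence[VariantAnnotation], path) -> None:
    """Annotated TSV; positions 1-based, mutated codon bases lowercased."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(ANNOTATION_COLUMNS)
        for a in annotations:
            mut = (
                mark_mutated_bases(a.wt_codon, a.mut_codon)
                if a.wt_codon and a.mut_codon
                else "."
            )
            w.writerow(
                [
                    a.variant.ref_pos + 1,
                    a.variant.type,
                    a.locus_tag,
                    a.description or ".",
                    a.wt_codon or ".",
                    mut,
                    a.wt_aa or ".",
                    a.mut_aa or ".",
                    a.effect,
                ]
            )
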