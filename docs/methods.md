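# Methods

This note documents the model, the parameters that matter, the numerical
choices, and what the synthetic experiments do and do not demonstrate.

## The comparison model

Two isolates of the same unsequenced strain — a wild type (WT) and a mutant —
are each compared against a *mediator*: the sequenced genome of a related
strain that serves as a shared coordinate system. Per isolate, the pipeline
produces a difference table `D_iso = {(pos, type, alt)}` of positions where
the isolate's reads consistently disagree with the mediator. The quantity of
interest is the set difference

```
unique_to_mutant = D_mut \ D_wt        (matched on (pos, type, alt))
```

Matching is allele-level by design: two isolates independently mutated at the
same position must not cancel out. Evidence fields (coverage, fraction, pass
mode) are excluded from the match key, so a strict call in one isolate
subtracts against a relaxed call of the same allele in the other. The
partition identities `|D_mut| = |common| + |unique_to_mutant|` and
`|D_wt| = |common| + |unique_to_wt|` are asserted on every run.

The approach assumes clonal haploid isolates, a mediator close enough that
most reads align (the original application had ~0.75% substitution divergence
and >90% of reads aligning), and coverage deep enough (tens of reads) that a
consensus threshold separates real differences from sequencing error.

## Read alignment

Seed-and-extend with the contract of a short-word blastn run:

| parameter | default | meaning |
|---|---|---|
| `word_size` | 11 bp | exact seed length; every read offset is seeded |
| `max_errors` | 6 | mismatches + gap columns, combined |
| `min_align_len` | ⌈0.8 × modal read length⌉ | minimum reported span (27 for 33 bp reads) |
| `both_strands` | true | seed the reverse complement too |

Candidate diagonals from seed hits are clustered (within `max_errors`) and
scored. An ungapped candidate with ≤ 1 mismatch is accepted without gapped
extension: a gapped alternative in the same neighbourhood would need 0 errors,
i.e. an exact diagonal of its own, which would have been seeded separately
(any placement with *e* errors of a read of length *L* contains an exact run
of ≥ ⌈(L − e)/(e + 1)⌉ bases, so placements with few errors are always
seeded at these read lengths). Otherwise the cluster window is aligned with
edlib (Myers bit-vector unit-cost edit distance, infix mode); the chosen
location is re-aligned globally to extract the column path. Candidates are
ranked by (errors, −aligned span, reference start, strand); a read whose two
best candidates at distinct loci tie on both errors and span is discarded as
ambiguous rather than placed arbitrarily — repeat-ambiguous reads would
otherwise manufacture phantom variants. If no full-length candidate fits the
error budget, progressively shorter read prefixes/suffixes (down to
`min_align_len`) are tried, which reproduces local-alignment behaviour at
deletion junctions.

The minimum-length rule is a single formula rather than the original two-point
lookup (27 for 33 bp, 30 for 38 bp reads); it reproduces 27 exactly and gives
31 instead of 30 for 38 bp reads, and can be overridden in the configuration.
The E-value of the original blastn invocation is not modelled — at these read
lengths the error cap and length floor subsume its filtering role. Known
limitation, shared with the seeded original: a read whose best placement
contains no exact `word_size` run can be missed; the brute-force-oracle test
generates reads long enough (≥ 44 bp at ≤ 3 planted errors) that this cannot
occur, so oracle disagreement would indicate a real defect.

## Pileup and consensus calling

Each alignment is projected onto the mediator. `coverage` at a position counts
every overlapping read (deletion gaps included); `depth` counts aligned bases
only and is the track used for coverage statistics, so the depth track sums
exactly to the aligned non-gap columns. Insertions anchor to the preceding
reference position and are keyed by the full inserted sequence; a called
insertion takes its anchor column's coverage.

A call requires the single most frequent non-reference event to exceed the
mode's fraction threshold *strictly* (0.60 is not > 0.60) at sufficient
coverage — strict: > 0.60 at ≥ 5 reads genome-wide; relaxed: > 0.50 at ≥ 2
reads, confined to flagged regions. The denominator is the full column
coverage, including reference-supporting reads and minor alts — the most
conservative reading of "consistently different". Ties between two top events
yield no call (a genuinely mixed column cannot be consistent in a clonal
isolate). The relaxed thresholds themselves are this package's choice: the
original study states only that thresholds were relaxed in flagged regions.
Positions whose reference base is N are never callable.

**Indel canonicalization.** The extension kernel may represent one physical
indel differently from read to read: a 2 bp insertion next to a homopolymer
run can be emitted either as one 2-base gap or split into two single-base
gaps two columns apart, at equal cost. Per-column calls are therefore
post-processed: indel calls whose reference footprints lie within 2 bp are
grouped, the implied alternate sequence of the group's window is rebuilt, the
shared flanking context is stripped, and a group reducing to a pure insertion
or deletion becomes one event (a group that does not reduce — e.g. two
genuinely independent indels — is kept as separate calls). All indels are then
left-aligned to their leftmost equivalent representation, the same
canonical form used when comparing against a truth set. The merged event
carries the minimum coverage and fraction of its parts (conservative).

## Coverage regions

Mean and SD of depth include zero-depth positions — otherwise "one standard
deviation below the average" is ill-defined on a genome with uncovered runs;
`exclude_zeros` switches to the covered-only convention. Uncovered regions are
maximal zero-depth runs; the reported genome-wide uncovered percentage is
rounded to the nearest whole percent. Hyper-mutated regions are 500 bp windows
at 250 bp step where mean depth < (mean − 1 SD) **and** ≥ 5 called differences
fall in the window; both signals are required, overlapping qualifying windows
merge. Window, step and cluster size are this package's defaults (the original
study gives none); they flag a gene-sized cassette at ≥ a few percent local
divergence under ~50× coverage, and all three are exposed in the
configuration. The pipeline scans *both* isolates' coverage tracks and takes
the union of the flagged regions: the original report scanned the deeper
wild-type data, but an under-aligning isolate sees its own coverage dip far
more reliably than its partner does, and a shared hyper-diverged region
depresses both. Because the flagging constants are not recoverable from the
original report, its intermediate count of 23,502 pre-relaxation mutations is
not reproducible and is not targeted.

The maximal-insertion bound is Σ(unaligned read lengths) / mean depth, floored
— an upper bound on mutant sequence absent from the mediator, since reads from
inserted material cannot align.

## Effect annotation

CDS features come from GFF3 or a simple TSV (1-based inclusive on file,
converted internally). SNVs are substituted into the codon read in the
feature's frame; minus-strand features are reverse-complemented before codon
extraction; the bacterial genetic code (translation table 11) is used with no
special-casing of internal start codons. Indels are frameshift iff length ∤ 3.
Overlapping features produce one annotation each; a CDS whose length is not a
multiple of three must be flagged partial or is rejected. Reports lowercase
the substituted base(s) of the mutant codon. A deletion's flanks are screened
for the longest direct repeat `k ∈ [4, 50]` with
`ref[s−k:s] == ref[e−k:e]` — the geometry left when recombination between a
repeat pair excises the intervening segment.

## Synthetic data: what it shows and what it does not

The generator's defaults are the study conditions scaled to desk size: 100 kb
i.i.d. mediator at 50% GC, 750 shared substitutions (~0.75% divergence), 19
mutant-unique substitutions plus one 2 bp insertion, uniform unpaired 33 bp
reads at 50× with 0.2% i.i.d. substitution error, constant Q30 qualities.
Planted events are non-overlapping and keep 100 bp from the genome ends,
where uniform read sampling cannot reach calling depth. A full-genome-scale
preset (3,782,950 bp, 28,379 shared) exists but is not exercised by the test
suite. The hyper-mutated-rescue scenario adds a 1 kb cassette at 8% local
divergence and sequences the mutant with 26 bp reads against the WT's 33 bp,
emulating the original asymmetric design (33 vs 38 bp) in which the shorter
reads aligned poorly in diverged regions; at symmetric read lengths and 50×,
an 8% cassette still aligns well enough that the strict pass misses nothing
and the relaxed pass has nothing to add.

The generator draws read positions uniformly and errors i.i.d.; it does not
model coverage bias, indel sequencing errors, quality-score structure, or
paired ends. Passing the recovery property therefore shows the *logic* of the
pipeline is correct under the stated noise model, not that the thresholds are
optimal for any particular instrument.

## Problem sizes and determinism

The test suite runs the default 100 kb scenario once (≈1 minute), the 50 kb
cassette scenario, a 200-instance aligner-oracle sweep, and unit tests on
1–20 kb fixtures. All randomness flows through seeded numpy generators;
identical configuration and seeds give byte-identical output bundles.
`scripts/acceptance.py` derives per-stage sub-seeds from its `--seed`
argument and recomputes every reported quantity at run time.
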