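"""Pileup construction and the consensus calling rule."""

import pytest

from mediseq.align import Alignment
from mediseq.io import ReferenceGenome
from mediseq.pileup import (
    CallerParams,
    DifferenceTable,
    VariantCall,
    build_pileup,
    call_differences,
    left_align_indel,
    merge_passes,
)
from mediseq.regions import GenomicRegion


REF = ReferenceGenome("g", "ACGTACGTTTGACCATGGTACCAGTACGCTAGCTAGGATCCAAGCTTGCA" * 2)


def _aln(start, seq, ops, rid="r"):
    return Alignment(
        rid,
        start,
        start + sum(n for op, n in ops if op in "=XD"),
        "+",
        tuple(ops),
        seq,
        sum(n for op, n in ops if op == "X"),
        sum(n for op, n in ops if op in "ID"),
    )


def _exact(start, length, rid="r"):
    return _aln(start, REF.sequence[start : start + length], [("=", length)], rid)


def _with_snv(start, length, at, alt, rid="r"):
    """Exact read with one substitution at reference position ``at``."""
    seq = list(REF.sequence[start : start + length])
    off = at - start
    seq[off] = alt
    ops = []
    if off > 0:
        ops.append(("=", off))
    ops.append(("X", 1))
    if off < length - 1:
        ops.append(("=", length - off - 1))
    return _aln(start, "".join(seq), ops, rid)


class TestBuildPileup:
    def test_single_exact_read(self):
        pile = build_pileup([_exact(10, 33)], REF)
        col = pile.column(20)
        assert col.coverage == 1
        assert col.base_counts == {REF.sequence[20]: 1}
        assert int(pile.overlap.sum()) == 33

    def test_mismatch_counted_alongside_reference(self):
        alt = "C" if REF.sequence[20] != "C" else "G"
        pile = build_pileup([_exact(10, 33, "a"), _with_snv(10, 33, 20, alt, "b")], REF)
        col = pile.column(20)
        assert col.coverage == 2
        assert col.base_counts == {REF.sequence[20]: 1, alt: 1}

    def test_deletion_column_counts_gap(self):
        ops = [("=", 10), ("D", 1), ("=", 10)]
        seq = REF.sequence[10:20] + REF.sequence[21:31]
        pile = build_pileup([_aln(10, seq, ops)], REF)
        col = pile.column(20)
        assert col.del_count == 1 and col.coverage == 1
        # depth excludes the gap column; overlap includes it
        assert pile.depth[20] == 0 and pile.overlap[20] == 1

    def test_insertion_keyed_to_preceding_position(self):
        ops = [("=", 10), ("I", 2), ("=", 10)]
        seq = REF.sequence[10:20] + "GT" + REF.sequence[20:30]
        pile = build_pileup([_aln(10, seq, ops)], REF)
        assert pile.column(19).ins_events == {"GT": 1}

    def test_out_of_bounds_alignment_rejected(self):
        with pytest.raises(ValueError):
            build_pileup([_aln(95, "A" * 10, [("=", 10)])], REF)


class TestCallingRule:
    def _pileup_with_counts(self, n_ref, n_alt, at=20, alt=None):
        if alt is None:
            alt = "C" if REF.sequence[at] != "C" else "G"
        alns = [_exact(10, 33, f"ref{i}") for i in range(n_ref)]
        alns += [_with_snv(10, 33, at, alt, f"alt{i}") for i in range(n_alt)]
        return build_pileup(alns, REF), alt

    def test_seventy_percent_at_coverage_ten_is_called(self):
        pile, alt = self._pileup_with_counts(3, 7)
        table = call_differences(pile, CallerParams())
        (call,) = table.calls
        assert (call.ref_pos, call.alt_allele, call.coverage) == (20, alt, 10)
        assert call.alt_fraction == pytest.approx(0.7)

    def test_coverage_below_five_not_called(self):
        pile, _ = self._pileup_with_counts(0, 4)
        assert len(call_differences(pile, CallerParams())) == 0

    def test_exactly_sixty_percent_not_called(self):
        # the rule is strict: fraction must exceed, not reach, the threshold
        pile, _ = self._pileup_with_counts(4, 6)
        assert len(call_differences(pile, CallerParams())) == 0

    def test_tied_alternative_events_yield_no_call(self):
        a1 = "C" if REF.sequence[20] != "C" else "G"
        a2 = "T" if REF.sequence[20] != "T" else "A"
        alns = [_with_snv(10, 33, 20, a1, f"x{i}") for i in range(5)]
        alns += [_with_snv(10, 33, 20, a2, f"y{i}") for i in range(5)]
        assert len(call_differences(build_pileup(alns, REF), CallerParams())) == 0

    def test_two_base_insertion_called_as_single_event(self):
        ops = [("=", 10), ("I", 2), ("=", 10)]
        seq = REF.sequence[10:20] + "GT" + REF.sequence[20:30]
        alns = [_aln(10, seq, ops, f"i{i}") for i in range(8)]
        table = call_differences(build_pileup(alns, REF), CallerParams())
        (call,) = table.calls
        assert call.type == "INS" and call.alt_allele in ("GT", "TG")
        assert len(call.alt_allele) == 2

    def test_multi_base_deletion_merged(self):
        ops = [("=", 10), ("D", 3), ("=", 10)]
        seq = REF.sequence[10:20] + REF.sequence[23:33]
        alns = [_aln(10, seq, ops, f"d{i}") for i in range(8)]
        table = call_differences(build_pileup(alns, REF), CallerParams())
        (call,) = table.calls
        assert call.type == "DEL" and len(call.ref_allele) == 3

    def test_determinism(self):
        pile, _ = self._pileup_with_counts(3, 7)
        t1 = call_differences(pile, CallerParams())
        t2 = call_differences(pile, CallerParams())
        assert t1.calls == t2.calls

    def test_no_call_ever_violates_thresholds(self, mini_pipeline):
        params = CallerParams()
        for label in ("wt", "mutant"):
            for call in mini_pipeline[label]["table"]:
                assert call.coverage >= params.min_coverage
                assert call.alt_fraction > params.min_alt_fraction


class TestSequencingErrorRobustness:
    def test_no_spurious_calls_from_error_only_columns(self):
        """>=1e5 column observations at 0.2% error: zero consensus calls.

        At coverage ~50 a spurious call needs >60% of reads to share one
        wrong base — a binomial tail far below 1e-6 per column.
        """
        from mediseq.align import AlignerParams, align_readset
        from mediseq.simulate import generate_mediator, simulate_reads

        genome = generate_mediator(2000, seed=77)
        reads = simulate_reads(genome, read_len=33, mean_coverage=50, error_rate=0.002, seed=78)
        alns, _, _ = align_readset(reads, genome, AlignerParams())
        pile = build_pileup(alns, genome)
        assert int(pile.overlap.sum()) >= 90_000
        assert len(call_differences(pile, CallerParams())) == 0


class TestMergePasses:
    def _call(self, pos, mode="strict", alt="T"):
        ref = REF.sequence[pos]
        alt = alt if alt != ref else "A"
        cov = 10 if mode == "strict" else 3
        return VariantCall(pos, "SNV", ref, alt, cov, 0.9, mode)

    def test_disjoint_tables_concatenate(self):
        regions = [GenomicRegion(0, 100, "hypermutated")]
        strict = DifferenceTable("m", "g", [self._call(10)])
        relaxed = DifferenceTable("m", "g", [self._call(20, "relaxed")])
        merged = merge_passes(strict, relaxed, regions)
        assert len(merged) == 2
        assert {c.pass_mode for c in merged} == {"strict", "relaxed"}

    def test_strict_wins_on_same_position(self):
        regions = [GenomicRegion(0, 100, "hypermutated")]
        strict = DifferenceTable("m", "g", [self._call(10)])
        relaxed = DifferenceTable("m", "g", [self._call(10, "relaxed")])
        merged = merge_passes(strict, relaxed, regions)
        (call,) = merged.calls
        assert call.pass_mode == "strict" and call.coverage == 10

    def test_relaxed_call_outside_regions_rejected(self):
        regions = [GenomicRegion(0, 5, "hypermutated")]
        strict = DifferenceTable("m", "g", [])
        relaxed = DifferenceTable("m", "g", [self._call(10, "relaxed")])
        with pytest.raises(ValueError, match="outside"):
            merge_passes(strict, relaxed, regions)


@pytest.mark.parametrize(
    "ref_seq,pos,allele,vtype,expected",
    [
        ("AACCC", 2, "C", "INS", (1, "C")),  # inserting C after a C run: shifts left
        ("AATTT", 4, "T", "DEL", (2, "T")),  # deleting one T of a run: leftmost T
        ("ACGTA", 2, "T", "INS", (2, "T")),  # no repeat context: unchanged
    ],
)
def test_left_align_indel(ref_seq, pos, allele, vtype, expected):
    assert left_align_indel(ref_seq, pos, allele, vtype) == expected
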