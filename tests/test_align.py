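"""Seed indexing, read placement, and oracle equivalence of the aligner."""

import numpy as np
import pytest

from conftest import semiglobal_min_errors
from mediseq.align import (
    AlignerParams,
    align_read,
    align_readset,
    build_seed_index,
    default_min_align_len,
    parse_blast_tabular,
    reverse_complement,
)
from mediseq.io import Read, ReadSet, ReferenceGenome
from mediseq.simulate import generate_mediator


def _params(**kw):
    base = dict(word_size=11, max_errors=6, min_align_len=27)
    base.update(kw)
    return AlignerParams(**base)


class TestSeedIndex:
    def test_repeated_word_maps_to_all_starts(self):
        idx = build_seed_index(ReferenceGenome("g", "ACGTACGT"), word_size=4)
        assert sorted(idx.lookup("ACGT").tolist()) == [0, 4]

    def test_reference_shorter_than_word_rejected(self):
        with pytest.raises(ValueError):
            build_seed_index(ReferenceGenome("g", "ACG"), word_size=4)

    def test_words_containing_n_excluded(self):
        idx = build_seed_index(ReferenceGenome("g", "ANGT"), word_size=2)
        assert "AN" not in idx and "NG" not in idx and "GT" in idx


@pytest.fixture(scope="module")
def ref():
    return generate_mediator(3000, seed=11, name="ref")


@pytest.fixture(scope="module")
def index(ref):
    return build_seed_index(ref, 11)


class TestAlignRead:
    def test_exact_substring_plus_strand(self, ref, index):
        read = Read("r", ref.sequence[100:133])
        aln = align_read(read, index, ref, _params())
        assert aln is not None
        assert (aln.ref_start, aln.ref_end, aln.strand, aln.n_errors) == (100, 133, "+", 0)

    def test_reverse_complement_minus_strand(self, ref, index):
        read = Read("r", reverse_complement(ref.sequence[100:133]))
        aln = align_read(read, index, ref, _params())
        assert aln is not None
        assert (aln.ref_start, aln.ref_end, aln.strand, aln.n_errors) == (100, 133, "-", 0)

    def test_error_cap_rejects_seven_mismatches(self, ref, index):
        seq = list(ref.sequence[200:233])
        # mutate 7 spread positions, keeping an exact seed word at the start
        for i in range(12, 33, 3):
            seq[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[i]]
        aln = align_read(Read("r", "".join(seq)), index, ref, _params())
        assert aln is None or aln.n_errors <= 6  # clipped hit may survive
        full = align_read(Read("r", "".join(seq)), index, ref, _params(min_align_len=33))
        assert full is None

    def test_single_base_insertion_costs_one_gap_column(self, ref, index):
        seq = ref.sequence[300:316] + "A" + ref.sequence[316:332]
        aln = align_read(Read("r", seq), index, ref, _params())
        assert aln is not None
        assert (aln.n_mismatches, aln.n_gap_columns) == (0, 1)
        assert aln.ref_start == 300

    def test_reported_alignments_respect_thresholds(self, ref, index):
        rng = np.random.default_rng(5)
        params = _params()
        for _ in range(100):
            start = int(rng.integers(0, ref.length - 33))
            seq = list(ref.sequence[start : start + 33])
            for pos in rng.choice(33, size=int(rng.integers(0, 8)), replace=False):
                seq[pos] = "ACGT"[int(rng.integers(4))]
            aln = align_read(Read("r", "".join(seq)), index, ref, params)
            if aln is not None:
                assert aln.n_errors <= params.max_errors
                assert aln.aligned_len >= params.min_align_len


class TestOracleEquivalence:
    def test_error_counts_match_brute_force(self):
        """Reported error counts equal the exhaustive semi-global minimum.

        Reads are long enough (>= 44 bp) relative to the 11 bp word that
        any placement within the planted error budget necessarily
        contains an exact seed, so a seeding miss cannot explain a
        disagreement.
        """
        rng = np.random.default_rng(42)
        n_reported = 0
        for trial in range(60):
            ref = generate_mediator(int(rng.integers(1000, 2000)), seed=int(rng.integers(2**31)), name="r")
            index = build_seed_index(ref, 11)
            L = int(rng.integers(44, 51))
            start = int(rng.integers(0, ref.length - L))
            seq = list(ref.sequence[start : start + L])
            for _ in range(int(rng.integers(0, 4))):  # up to 3 planted errors
                kind = rng.choice(["sub", "ins", "del"])
                pos = int(rng.integers(1, len(seq) - 1))
                if kind == "sub":
                    seq[pos] = "ACGT"[int(rng.integers(4))]
                elif kind == "ins":
                    seq.insert(pos, "ACGT"[int(rng.integers(4))])
                else:
                    del seq[pos]
            read_seq = "".join(seq)
            if rng.random() < 0.5:
                read_seq = reverse_complement(read_seq)
            params = AlignerParams(word_size=11, max_errors=6, min_align_len=len(read_seq))
            aln = align_read(Read("t", read_seq), index, ref, params)
            if aln is None:
                continue  # ambiguous placements are discarded by policy
            n_reported += 1
            assert aln.n_errors == semiglobal_min_errors(read_seq, ref.sequence), trial
        assert n_reported >= 55  # nearly every instance should be placeable

    def test_reverse_complement_invariance(self):
        rng = np.random.default_rng(7)
        ref = generate_mediator(2000, seed=3, name="r")
        index = build_seed_index(ref, 11)
        params = _params()
        for _ in range(50):
            start = int(rng.integers(0, ref.length - 33))
            seq = list(ref.sequence[start : start + 33])
            for pos in rng.choice(33, size=int(rng.integers(0, 3)), replace=False):
                seq[pos] = "ACGT"[int(rng.integers(4))]
            fwd = align_read(Read("f", "".join(seq)), index, ref, params)
            rev = align_read(Read("f", reverse_complement("".join(seq))), index, ref, params)
            if fwd is None:
                assert rev is None
            else:
                assert rev is not None
                assert (rev.ref_start, rev.ref_end) == (fwd.ref_start, fwd.ref_end)
                assert {rev.strand, fwd.strand} == {"+", "-"} or rev.strand == fwd.strand


class TestAlignReadset:
    def test_exact_reads_all_align_without_errors(self):
        ref = generate_mediator(2000, seed=9, name="r")
        reads = ReadSet([Read(f"r{i}", ref.sequence[i * 50 : i * 50 + 33]) for i in range(20)])
        alns, unaligned, stats = align_readset(reads, ref, _params())
        assert unaligned == [] and stats.n_with_errors == 0

    def test_foreign_reads_mostly_unaligned(self):
        ref = generate_mediator(2000, seed=9, name="r")
        foreign = generate_mediator(2000, seed=1234, name="x")
        reads = ReadSet([Read(f"f{i}", foreign.sequence[i * 40 : i * 40 + 33]) for i in range(40)])
        alns, unaligned, stats = align_readset(reads, ref, _params())
        assert stats.n_unaligned >= 38  # unrelated sequence should not place

    def test_duplicate_read_ids_placed_independently(self):
        ref = generate_mediator(2000, seed=9, name="r")
        reads = ReadSet([Read("dup", ref.sequence[0:33]), Read("dup", ref.sequence[500:533])])
        alns, _, _ = align_readset(reads, ref, _params())
        assert [a.read_id for a in alns] == ["dup", "dup"]
        assert {a.ref_start for a in alns} == {0, 500}

    def test_empty_readset_rejected(self):
        ref = generate_mediator(2000, seed=9, name="r")
        with pytest.raises(ValueError):
            align_readset(ReadSet([]), ref, _params())


def test_default_min_align_len_rule():
    assert default_min_align_len(33) == 27
    assert default_min_align_len(38) == 31


def test_blast_tabular_import(tmp_path):
    ref = generate_mediator(2000, seed=9, name="ref")
    read_seq = ref.sequence[100:133]
    reads = ReadSet([Read("q1", read_seq), Read("q2", reverse_complement(read_seq))])
    p = tmp_path / "hits.tsv"
    rows = [
        # qseqid sseqid pident length mismatch gapopen qstart qend sstart send evalue bits
        "q1\tref\t100.00\t33\t0\t0\t1\t33\t101\t133\t1e-10\t60",
        "q2\tref\t100.00\t33\t0\t0\t1\t33\t133\t101\t1e-10\t60",
        "q1\tref\t95.00\t33\t1\t1\t1\t33\t501\t534\t1e-5\t40",  # gapped: skipped
    ]
    p.write_text("\n".join(rows) + "\n")
    alns = parse_blast_tabular(p, reads, ref, _params())
    assert len(alns) == 2
    for a in alns:
        assert (a.ref_start, a.ref_end, a.n_errors) == (100, 133, 0)
    assert {a.strand for a in alns} == {"+", "-"}
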