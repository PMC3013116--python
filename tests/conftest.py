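"""Shared fixtures and the independent brute-force alignment oracle."""

from __future__ import annotations

import numpy as np
import pytest

from mediseq.align import reverse_complement
from mediseq.io import ReferenceGenome


def semiglobal_min_errors(read: str, ref: str) -> int:
    """Exhaustive minimum alignment errors of ``read`` anywhere on ``ref``.

    Plain dynamic programming over every placement and both strands:
    unit cost for mismatches and single-base gaps, free shifts of the
    read along the reference (semi-global).  Written independently of
    the production aligner so it can serve as its oracle.
    """
    best = min(_semiglobal_one_strand(read, ref), _semiglobal_one_strand(reverse_complement(read), ref))
    return best


def _semiglobal_one_strand(read: str, ref: str) -> int:
    m, n = len(read), len(ref)
    ref_arr = np.frombuffer(ref.encode(), dtype=np.uint8)
    read_arr = np.frombuffer(read.encode(), dtype=np.uint8)
    prev = np.zeros(n + 1, dtype=np.int64)  # D[0][j] = 0: free start anywhere
    js = np.arange(n + 1, dtype=np.int64)
    for i in range(1, m + 1):
        mismatch = (ref_arr != read_arr[i - 1]).astype(np.int64)
        diag = prev[:-1] + mismatch
        up = prev[1:] + 1
        m_row = np.minimum(diag, up)
        # cur[j] = min(m_row[j-1], cur[j-1] + 1) via the subtract-index trick
        a = np.minimum.accumulate(np.concatenate(([np.int64(i)], m_row - js[1:])))
        prev = a + js
    return int(prev.min())


@pytest.fixture(scope="session")
def mini_scenario():
    """A 20 kb two-isolate experiment, shared across tests (read-only)."""
    from mediseq.simulate import ScenarioConfig, build_scenario

    cfg = ScenarioConfig(genome_length=20_000, shared_subs=150, unique_subs=5)
    return build_scenario(cfg, seed=1)


@pytest.fixture(scope="session")
def mini_pipeline(mini_scenario):
    """The mini scenario pushed through align → call → subtract."""
    from mediseq.align import AlignerParams, align_readset
    from mediseq.compare import subtract
    from mediseq.pileup import CallerParams, build_pileup, call_differences

    sc = mini_scenario
    params = AlignerParams()
    cp = CallerParams()
    out = {}
    for label, reads in (("wt", sc.wt_reads), ("mutant", sc.mutant_reads)):
        alns, unaligned, stats = align_readset(reads, sc.mediator, params)
        pile = build_pileup(alns, sc.mediator)
        out[label] = {
            "alignments": alns,
            "unaligned": unaligned,
            "stats": stats,
            "pileup": pile,
            "table": call_differences(pile, cp, isolate_label=label),
        }
    out["subtraction"] = subtract(out["mutant"]["table"], out["wt"]["table"])
    return out


@pytest.fixture
def toy_genome():
    return ReferenceGenome("toy", "ACGTACGTTTGACCATGGTACCAGTACGCTAGCTAGGATCCAAGCTTGCA" * 4)
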