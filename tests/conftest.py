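"""Shared fixtures: toy alignments in all three formats, small simulated
genome pairs, and the random segment-instance generator used by the
property suites."""

from __future__ import annotations

import numpy as np
import pytest

from syntopy.model import (
    AlignmentSegment,
    AssemblyInfo,
    FORWARD,
    RankedAlignment,
    REVERSE,
)

# ---------------------------------------------------------------------------
# one toy alignment set expressed in PAF, chain and BLAST tabular form:
#   aln 1: q1[100,200) -> t1[500,610) forward, blocks 50+50, 10 bp target gap
#   aln 2: q2[0,100)   -> t2[300,400) reverse, one block
# (mismatch-free, because the chain format cannot carry substitutions)

TOY_PAF = (
    "q1\t1000\t100\t200\t+\tt1\t2000\t500\t610\t100\t110\t60\tcg:Z:50M10D50M\n"
    "q2\t500\t0\t100\t-\tt2\t1000\t300\t400\t100\t100\t60\tcg:Z:100M\n"
)

TOY_CHAIN = (
    "chain 100 t1 2000 + 500 610 q1 1000 + 100 200 1\n"
    "50 10 0\n"
    "50\n"
    "\n"
    "chain 100 t2 1000 + 300 400 q2 500 - 400 500 2\n"
    "100\n"
    "\n"
)

_BTOP_GAP10 = "50" + "-A" * 10 + "50"
TOY_BLAST = (
    f"q1\tt1\t100.00\t110\t0\t1\t101\t200\t501\t610\t0.0\t200\t{_BTOP_GAP10}\n"
    f"q2\tt2\t100.00\t100\t0\t0\t1\t100\t400\t301\t0.0\t190\t100\n"
)


@pytest.fixture
def toy_formats():
    return {"paf": TOY_PAF, "chain": TOY_CHAIN, "blast": TOY_BLAST}


@pytest.fixture
def toy_ranked():
    """Two ranked alignments with full statistics, for writer tests."""
    fwd = AlignmentSegment.build(
        "q1", "t1", FORWARD, [(0, 500, 100)], q_assembly="A", t_assembly="B"
    )
    rev = AlignmentSegment.build(
        "q2",
        "t2",
        REVERSE,
        [(10, 300, 40), (60, 200, 50)],
        mismatches=3,
        q_assembly="A",
        t_assembly="B",
    )
    return [RankedAlignment(fwd, 3), RankedAlignment(rev, 2)]


@pytest.fixture
def toy_infos():
    q = AssemblyInfo.from_lengths("A", {"q1": 1000, "q2": 800})
    t = AssemblyInfo.from_lengths("B", {"t1": 2000, "t2": 900})
    return q, t


# ---------------------------------------------------------------------------
# random segment instances for the oracle / conservation / exclusivity suites
#
# Instances are constrained so that segment-level ranking is unambiguous and
# survives splitting: coordinates on a 100-bp grid (every split piece is
# >= 100 bp, so proportional mismatch apportioning moves identity by < 1
# point), per-segment identities spaced 5 points apart, and no pair
# satisfying the merge-adjacency predicate (abutting collinear neighbours),
# which would blend statistics before ranking.


def _mergeable(a: AlignmentSegment, b: AlignmentSegment) -> bool:
    for x, y in ((a, b), (b, a)):
        if (
            x.query.seq_id == y.query.seq_id
            and x.target.seq_id == y.target.seq_id
            and x.orientation == y.orientation
            and y.query.start == x.query.end
        ):
            if x.orientation == FORWARD and y.target.start == x.target.end:
                return True
            if x.orientation == REVERSE and x.target.start == y.target.end:
                return True
    return False


def random_instance(rng: np.random.Generator, n_max: int = 10) -> list[AlignmentSegment]:
    while True:
        n = int(rng.integers(1, n_max + 1))
        segs: list[AlignmentSegment] = []
        for i in range(n):
            q_seq = f"q{int(rng.integers(1, 3))}"
            t_seq = f"t{int(rng.integers(1, 3))}"
            length = int(rng.integers(1, 5)) * 100
            q_start = int(rng.integers(0, 20)) * 100
            t_start = int(rng.integers(0, 20)) * 100
            orient = FORWARD if rng.random() < 0.7 else REVERSE
            mism = length * 5 * i // 100  # identity = 100 - 5 i, exactly
            segs.append(
                AlignmentSegment.build(
                    q_seq,
                    t_seq,
                    orient,
                    [(q_start, t_start, length)],
                    mismatches=mism,
                )
            )
        if not any(
            _mergeable(a, b)
            for k, a in enumerate(segs)
            for b in segs[k + 1 :]
        ):
            return segs


def base_pairs_of(segments) -> set[tuple[str, int, str, int]]:
    """Every aligned (query base, target base) pair of a segment list."""
    out: set[tuple[str, int, str, int]] = set()
    for s in segments:
        q_seq, t_seq = s.query.seq_id, s.target.seq_id
        for qp, tp in s.iter_base_pairs():
            out.add((q_seq, qp, t_seq, tp))
    return out


@pytest.fixture
def instance_rng():
    return np.random.default_rng(20240917)
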