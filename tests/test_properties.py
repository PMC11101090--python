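"""Cross-cutting invariants on random alignment instances.

The random instances come from ``conftest.random_instance``; the heavyweight
500-instance oracle comparison lives in the acceptance suite, while these
tests exercise the same invariants on a smaller corpus plus
hypothesis-driven segment shapes.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import base_pairs_of, random_instance
from syntopy.model import AlignmentSegment, FORWARD, ProcessingParams, REVERSE
from syntopy.pipeline import (
    process,
    split_at_overlaps,
    split_on_gaps,
)

CLOSE = ProcessingParams.same_or_close()


@st.composite
def gapped_segments(draw):
    """Multi-block segments with random gaps on both sides."""
    orientation = draw(st.sampled_from([FORWARD, REVERSE]))
    n_blocks = draw(st.integers(1, 5))
    q = draw(st.integers(0, 100))
    t = draw(st.integers(0, 100))
    blocks = []
    lengths = []
    for _ in range(n_blocks):
        length = draw(st.integers(1, 120))
        blocks.append((q, t, length))
        lengths.append(length)
        q += length + draw(st.integers(0, 80))
        t += length + draw(st.integers(0, 80))
    if orientation == REVERSE:
        # rebuild with descending targets, query order preserved
        t_sizes = [(b[2], b[1]) for b in blocks]
        total_span = blocks[-1][1] + blocks[-1][2]
        blocks = [
            (b[0], total_span - (b[1] + b[2]), b[2]) for b in blocks
        ]
    aligned = sum(lengths)
    mism = draw(st.integers(0, aligned // 2))
    return AlignmentSegment.build("q1", "t1", orientation, blocks, mismatches=mism)


@settings(max_examples=80, deadline=None, derandomize=True)
@given(seg=gapped_segments())
def test_gap_split_conserves_matches_and_geometry(seg):
    kids = split_on_gaps(seg, CLOSE)
    assert sum(k.matches for k in kids) == seg.matches
    assert sum(k.mismatches for k in kids) == seg.mismatches
    assert [b for k in kids for b in k.blocks] == list(seg.blocks)
    for k in kids:
        k.validate()
        # no retained junction reaches the effective threshold of its parent
    if len(kids) > 1:
        thr = CLOSE.split_threshold(seg.length)
        for k in kids:
            for q_gap, t_gap in k.junction_gaps():
                assert max(q_gap, t_gap) < thr


def test_overlap_split_changes_no_aligned_base(instance_rng):
    for _ in range(40):
        segs = random_instance(instance_rng)
        out = split_at_overlaps(segs)
        assert base_pairs_of(out) == base_pairs_of(segs)
        for s in out:
            s.validate()


def test_overlap_split_yields_identical_or_disjoint_ranges(instance_rng):
    for _ in range(40):
        out = split_at_overlaps(random_instance(instance_rng))
        for axis in ("query", "target"):
            ranges = sorted(
                (getattr(s, axis).seq_id, getattr(s, axis).start, getattr(s, axis).end)
                for s in out
            )
            for (s1, a1, b1), (s2, a2, b2) in zip(ranges, ranges[1:]):
                if s1 == s2 and a2 < b1:  # overlapping on the axis
                    assert (a1, b1) == (a2, b2)


def test_reciprocity3_set_is_exclusive_on_both_axes(instance_rng):
    for _ in range(40):
        ranked = process(random_instance(instance_rng))
        best = [ra.segment for ra in ranked if ra.reciprocity == 3]
        for axis in ("query", "target"):
            ivs = sorted(
                (getattr(s, axis).seq_id, getattr(s, axis).start, getattr(s, axis).end)
                for s in best
            )
            for (s1, a1, b1), (s2, a2, _) in zip(ivs, ivs[1:]):
                assert not (s1 == s2 and a2 < b1), f"{axis} overlap in best set"


def test_process_permutation_invariance_on_random_instances(instance_rng):
    for _ in range(10):
        segs = random_instance(instance_rng, n_max=6)
        reference = None
        for _ in range(3):
            order = instance_rng.permutation(len(segs))
            out = process([segs[i] for i in order])
            digest = tuple(
                (ra.reciprocity, ra.segment.query, ra.segment.target, ra.segment.blocks)
                for ra in out
            )
            if reference is None:
                reference = digest
            assert digest == reference


def test_pipeline_never_loses_query_best_coverage(instance_rng):
    """Every query base covered by some alignment keeps a placement in the
    union of reciprocity classes (nothing silently vanishes except
    best-on-neither duplicates, which by definition have both their query
    and target bases covered by better placements)."""
    for _ in range(20):
        segs = random_instance(instance_rng)
        ranked = process(segs)
        covered_in = set()
        for s in segs:
            covered_in.update(
                (s.query.seq_id, p) for p in range(s.query.start, s.query.end)
            )
        covered_best = set()
        for ra in ranked:
            if ra.reciprocity in (1, 3):
                s = ra.segment
                covered_best.update(
                    (s.query.seq_id, p) for p in range(s.query.start, s.query.end)
                )
        # query-best coverage = all query bases (scan 1 always has a winner)
        assert covered_best == covered_in
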