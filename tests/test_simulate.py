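"""Synthetic genome-pair generator and truth fragmentation."""

import pytest

from syntopy.io._util import segment_sans_source
from syntopy.model import FORWARD, REVERSE, ValidationError
from syntopy.pipeline import process
from syntopy.render import SyntenyScene, render_dotplot
from syntopy.model import RankedAlignment
from syntopy.simulate import (
    RearrangementEvent,
    RearrangementPlan,
    fragment_alignments,
    recovered_fraction,
    simulate_pair,
)


def small_plan(seed=0, events=(), snp=0.0, indel=0.0, n=2, length=5000):
    return RearrangementPlan(
        seed=seed,
        n_chromosomes=n,
        chromosome_length=length,
        snp_rate=snp,
        indel_rate=indel,
        events=tuple(events),
    )


class TestSimulatePair:
    def test_identity_plan_gives_one_segment_per_chromosome(self):
        pair = simulate_pair(small_plan())
        assert len(pair.truth) == 2
        for seg in pair.truth:
            assert seg.orientation == FORWARD
            assert seg.query.length == 5000
            assert seg.mismatches == 0
        assert pair.query_seqs == pair.target_seqs

    def test_inversion_plants_one_reverse_segment_of_exact_size(self):
        pair = simulate_pair(
            small_plan(events=[RearrangementEvent("inversion", "chr1", 1000, 2000)])
        )
        rev = [s for s in pair.truth if s.orientation == REVERSE]
        assert len(rev) == 1
        assert rev[0].query.length == 1000
        assert (rev[0].query.start, rev[0].query.end) == (1000, 2000)

    def test_inverted_sequence_is_reverse_complemented(self):
        pair = simulate_pair(
            small_plan(events=[RearrangementEvent("inversion", "chr1", 1000, 2000)])
        )
        region = pair.query_seqs["chr1"][1000:2000]
        rc = region.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        assert pair.target_seqs["chr1"][1000:2000] == rc

    def test_duplication_adds_one_extra_non_primary_segment(self):
        pair = simulate_pair(
            small_plan(events=[RearrangementEvent("duplication", "chr1", 1000, 1500)])
        )
        assert len(pair.truth) == len(pair.truth_primary) + 1
        extra = [s for s in pair.truth if s not in pair.truth_primary]
        assert extra[0].query.start == 1000
        assert len(pair.target_seqs["chr1"]) == 5500

    def test_translocation_moves_sequence_across_chromosomes(self):
        pair = simulate_pair(
            small_plan(
                events=[
                    RearrangementEvent(
                        "translocation", "chr1", 1000, 2000, dest_chrom="chr2"
                    )
                ]
            )
        )
        moved = [s for s in pair.truth if s.target.seq_id != s.query.seq_id]
        assert len(moved) == 1
        assert moved[0].query.seq_id == "chr1" and moved[0].target.seq_id == "chr2"
        assert len(pair.target_seqs["chr1"]) == 4000
        assert len(pair.target_seqs["chr2"]) == 6000

    def test_scramble_tiles_render_in_a_single_dotplot_cell(self):
        pair = simulate_pair(
            small_plan(
                events=[RearrangementEvent("scramble", "chr1", n_tiles=20)],
                length=20000,
            )
        )
        scr = [s for s in pair.truth if s.query.seq_id == "chr1"]
        assert len(scr) == 20
        scene = SyntenyScene(
            alignments=tuple(RankedAlignment(s, 3) for s in pair.truth),
            q_info=pair.q_info,
            t_info=pair.t_info,
        )
        svg = render_dotplot(scene)
        assert svg.count('class="aln') == len(pair.truth)
        # all scrambled tiles stay on the chr1/chr1 cell
        assert all(s.target.seq_id == "chr1" for s in scr)

    def test_snp_rate_produces_mismatches_and_truth_counts_match(self):
        pair = simulate_pair(small_plan(snp=0.01))
        for seg in pair.truth:
            q = pair.query_seqs[seg.query.seq_id]
            t = pair.target_seqs[seg.target.seq_id]
            observed = sum(
                1 for qp, tp in seg.iter_base_pairs() if q[qp] != t[tp]
            )
            assert observed == seg.mismatches
            assert seg.mismatches > 0

    def test_indels_split_blocks_and_sequences_stay_consistent(self):
        pair = simulate_pair(small_plan(indel=0.002))
        multi = [s for s in pair.truth if len(s.blocks) > 1]
        assert multi
        for seg in pair.truth:
            seg.validate()
            q = pair.query_seqs[seg.query.seq_id]
            t = pair.target_seqs[seg.target.seq_id]
            comp = str.maketrans("ACGT", "TGCA")
            for qp, tp in seg.iter_base_pairs():
                expect = q[qp] if seg.orientation == FORWARD else q[qp].translate(comp)
                assert t[tp] == expect

    def test_deterministic_from_seed(self):
        a = simulate_pair(small_plan(seed=7, snp=0.01, indel=0.001))
        b = simulate_pair(small_plan(seed=7, snp=0.01, indel=0.001))
        assert a.query_seqs == b.query_seqs
        assert a.target_seqs == b.target_seqs
        assert a.truth == b.truth

    def test_truth_tiles_each_unrearranged_region_exactly_once(self):
        pair = simulate_pair(
            small_plan(events=[RearrangementEvent("inversion", "chr1", 1000, 2000)])
        )
        for chrom in ("chr1", "chr2"):
            covered = sorted(
                (s.query.start, s.query.end)
                for s in pair.truth_primary
                if s.query.seq_id == chrom
            )
            cursor = 0
            for start, end in covered:
                assert start == cursor
                cursor = end
            assert cursor == 5000

    def test_overlapping_events_rejected(self):
        with pytest.raises(ValidationError):
            simulate_pair(
                small_plan(
                    events=[
                        RearrangementEvent("inversion", "chr1", 1000, 2000),
                        RearrangementEvent("deletion", "chr1", 1500, 2500),
                    ]
                )
            )


class TestFragmentAlignments:
    def test_no_cuts_no_injections_is_a_permutation_of_truth(self):
        pair = simulate_pair(small_plan(snp=0.005))
        raw = fragment_alignments(pair.truth, seed=3)
        norm = lambda lst: sorted(map(segment_sans_source, lst), key=str)
        assert norm(raw) == norm(pair.truth)

    def test_duplicate_fraction_injects_contained_segments(self):
        pair = simulate_pair(small_plan())
        raw = fragment_alignments(
            pair.truth, seed=3, n_cuts=10, duplicate_fraction=0.5
        )
        contained = [
            b
            for b in raw
            for a in raw
            if a is not b
            and a.query.contains(b.query)
            and a.target.contains(b.target)
        ]
        assert contained

    def test_overlap_fraction_injects_overlapping_segments(self):
        pair = simulate_pair(small_plan())
        raw = fragment_alignments(
            pair.truth, seed=3, n_cuts=10, overlap_fraction=0.5
        )
        partial = [
            (a, b)
            for a in raw
            for b in raw
            if a is not b
            and a.query.overlaps(b.query)
            and not (a.query == b.query)
        ]
        assert partial

    def test_deterministic_from_seed(self):
        pair = simulate_pair(small_plan(snp=0.005))
        raw1 = fragment_alignments(pair.truth, seed=5, n_cuts=20, overlap_fraction=0.2)
        raw2 = fragment_alignments(pair.truth, seed=5, n_cuts=20, overlap_fraction=0.2)
        assert raw1 == raw2

    def test_pipeline_recovers_fragmented_truth(self):
        pair = simulate_pair(small_plan(snp=0.005, indel=0.0005))
        raw = fragment_alignments(
            pair.truth, seed=11, n_cuts=30, overlap_fraction=0.2,
            duplicate_fraction=0.2,
        )
        ranked = process(raw, pair.q_info, pair.t_info)
        best = [ra.segment for ra in ranked if ra.reciprocity == 3]
        assert recovered_fraction(best, pair.truth_primary) >= 0.95
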