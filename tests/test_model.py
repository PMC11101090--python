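"""Core model: coordinate conventions, projection, identity."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from syntopy.model import (
    AlignmentBlock,
    AlignmentSegment,
    AssemblyInfo,
    FORWARD,
    InvalidSegmentError,
    NoOverlapError,
    ProcessingParams,
    REVERSE,
    SeqRange,
    ValidationError,
    percent_identity,
    project,
)


class TestSeqRange:
    def test_half_open_length(self):
        assert SeqRange("s", 3, 10).length == 7

    @pytest.mark.parametrize("start,end", [(-1, 5), (5, 5), (7, 3)])
    def test_invalid_ranges_rejected(self, start, end):
        with pytest.raises(ValidationError):
            SeqRange("s", start, end)


class TestProject:
    def test_forward_offset_identity(self):
        seg = AlignmentSegment.build("q", "t", FORWARD, [(0, 500, 100)])
        assert project(seg, SeqRange("q", 10, 20)) == SeqRange("t", 510, 520)

    def test_reverse_mirror_symmetry(self):
        seg = AlignmentSegment.build("q", "t", REVERSE, [(0, 500, 100)])
        assert project(seg, SeqRange("q", 0, 10)) == SeqRange("t", 590, 600)

    def test_projection_spanning_target_gap_includes_gap_bases(self):
        # blocks q[0,50)->t[500,550) and q[50,100)->t[580,630): 30 bp target gap
        seg = AlignmentSegment.build(
            "q", "t", FORWARD, [(0, 500, 50), (50, 580, 50)]
        )
        out = project(seg, SeqRange("q", 40, 60))
        # q40..50 -> t540..550, q50..60 -> t580..590; envelope spans the gap
        assert out == SeqRange("t", 540, 590)
        assert out.length == 20 + 30

    def test_disjoint_interval_raises(self):
        seg = AlignmentSegment.build("q", "t", FORWARD, [(0, 500, 100)])
        with pytest.raises(NoOverlapError):
            project(seg, SeqRange("q", 200, 300))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        t0=st.integers(0, 1000),
        length=st.integers(2, 500),
        lo=st.integers(0, 498),
        span=st.integers(1, 100),
        reverse=st.booleans(),
    )
    def test_projection_length_bounded_and_round_trip(
        self, t0, length, lo, span, reverse
    ):
        """Projecting a sub-interval of a single block is exact, and
        projecting the projection back recovers the original interval."""
        lo = lo % length
        hi = min(length, lo + span)
        if hi <= lo:
            hi = lo + 1
        orientation = REVERSE if reverse else FORWARD
        seg = AlignmentSegment.build("q", "t", orientation, [(0, t0, length)])
        fwd = project(seg, SeqRange("q", lo, hi))
        assert fwd.length == hi - lo
        # mirror segment: swap roles of query and target
        if reverse:
            back = AlignmentSegment.build(
                "t", "q", REVERSE, [(t0, 0, length)]
            )
        else:
            back = AlignmentSegment.build("t", "q", FORWARD, [(t0, 0, length)])
        restored = project(back, fwd)
        assert (restored.start, restored.end) == (lo, hi)


class TestPercentIdentity:
    @pytest.mark.parametrize(
        "matches,mismatches,gap_bases,expected",
        [(100, 0, 0, 100.0), (90, 10, 0, 90.0), (90, 5, 5, 90.0)],
    )
    def test_identity_formula(self, matches, mismatches, gap_bases, expected):
        seg = AlignmentSegment.build(
            "q",
            "t",
            FORWARD,
            [(0, 0, matches + mismatches)],
            matches=matches,
            mismatches=mismatches,
            gap_bases=gap_bases,
            gap_count=1 if gap_bases else 0,
        )
        assert percent_identity(seg) == pytest.approx(expected)

    def test_zero_denominator_rejected(self):
        seg = AlignmentSegment.build("q", "t", FORWARD, [(0, 0, 10)])
        object.__setattr__(seg, "matches", 0)
        object.__setattr__(seg, "mismatches", 0)
        with pytest.raises(InvalidSegmentError):
            percent_identity(seg)


class TestSegmentInvariants:
    def test_envelope_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            AlignmentSegment(
                query=SeqRange("q", 0, 50),  # wrong: blocks span [0,100)
                target=SeqRange("t", 0, 100),
                orientation=FORWARD,
                blocks=(AlignmentBlock(0, 0, 100),),
                matches=100,
            ).validate()

    def test_out_of_order_blocks_rejected(self):
        with pytest.raises(ValidationError):
            AlignmentSegment.build(
                "q", "t", FORWARD, [(50, 50, 20), (0, 0, 20)]
            )

    def test_gff3_coordinate_round_trip_is_lossless(self):
        """0-based half-open <-> 1-based closed conversion round-trips for
        any range of length >= 1."""
        for start, end in [(0, 1), (0, 100), (17, 18), (5, 250)]:
            disp = (start + 1, end)  # display convention
            back = (disp[0] - 1, disp[1])
            assert back == (start, end)
            assert disp[1] - disp[0] + 1 == end - start


class TestProcessingParams:
    def test_mode_defaults(self):
        close = ProcessingParams.same_or_close()
        far = ProcessingParams.distant()
        assert close.gap_split_bp == 50 and far.gap_split_bp == 50_000
        assert close.merge_max_gap == 50 and far.merge_max_gap == 50_000
        assert close.gap_split_frac == far.gap_split_frac == 0.05

    def test_effective_threshold_takes_the_binding_criterion(self):
        far = ProcessingParams.distant()
        assert far.split_threshold(10_000) == 500  # 5% binds before 50 kb
        close = ProcessingParams.same_or_close()
        assert close.split_threshold(10_000) == 50  # absolute binds

    def test_invalid_params_rejected(self):
        with pytest.raises(ValidationError):
            ProcessingParams(gap_split_bp=0)
        with pytest.raises(ValidationError):
            ProcessingParams(gap_split_frac=1.5)


class TestAssemblyInfo:
    def test_duplicate_sequence_ids_rejected(self):
        with pytest.raises(ValidationError):
            AssemblyInfo(
                assembly_id="x",
                sequences=[("s1", 10, "chromosome"), ("s1", 20, "chromosome")],
            )

    def test_lookup(self):
        info = AssemblyInfo.from_lengths("x", {"s1": 10, "s2": 20})
        assert info.length_of("s2") == 20
        assert info.total_length() == 30
        with pytest.raises(ValidationError):
            info.length_of("nope")
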