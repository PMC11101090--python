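"""SVG rendering contracts: connector counts, colors, slopes, flips."""

import xml.etree.ElementTree as ET

import pytest

from syntopy.model import (
    AlignmentSegment,
    AssemblyInfo,
    FORWARD,
    RankedAlignment,
    REVERSE,
    SeqRange,
    ValidationError,
)
from syntopy.render import (
    SyntenyScene,
    render_dotplot,
    render_ideogram,
    segment_info,
)

SVG_NS = "{http://www.w3.org/2000/svg}"


def elements(svg: str, cls: str):
    root = ET.fromstring(svg)
    return [
        el
        for el in root.iter()
        if cls in el.attrib.get("class", "").split()
    ]


def scene(alns, **kw):
    q_info = AssemblyInfo.from_lengths("Q", {"q1": 1000, "q2": 800})
    t_info = AssemblyInfo.from_lengths("T", {"t1": 1200, "t2": 900})
    return SyntenyScene(alignments=tuple(alns), q_info=q_info, t_info=t_info, **kw)


def fwd(reciprocity=3, q="q1", t="t1", start=0, length=100, t_start=0):
    return RankedAlignment(
        AlignmentSegment.build(q, t, FORWARD, [(start, t_start, length)]),
        reciprocity,
    )


def rev(reciprocity=3, q="q1", t="t1", start=0, length=100, t_start=0):
    return RankedAlignment(
        AlignmentSegment.build(q, t, REVERSE, [(start, t_start, length)]),
        reciprocity,
    )


class TestIdeogram:
    def test_one_connector_per_visible_alignment(self):
        svg = render_ideogram(scene([fwd(), fwd(q="q2", t="t2", start=100)]))
        assert len(elements(svg, "connector")) == 2

    def test_default_filter_hides_non_best(self):
        svg = render_ideogram(scene([fwd(reciprocity=2)]))
        assert len(elements(svg, "connector")) == 0
        assert elements(svg, "caption")  # explanatory caption present

    def test_include_non_best_shows_them(self):
        svg = render_ideogram(scene([fwd(reciprocity=2)], include_non_best=True))
        assert len(elements(svg, "connector")) == 1

    def test_min_length_filter(self):
        svg = render_ideogram(scene([fwd(length=100)], min_segment_length=101))
        assert len(elements(svg, "connector")) == 0

    def test_orientation_filter(self):
        both = [fwd(), rev(q="q2", t="t2")]
        svg = render_ideogram(scene(both, orientation="reverse_only"))
        assert len(elements(svg, "connector")) == 1

    def test_double_flip_restores_bytes(self):
        sc = scene([fwd(), rev(q="q2", t="t2")])
        once = render_ideogram(sc.with_flip("t1"))
        twice = render_ideogram(sc.with_flip("t1").with_flip("t1"))
        assert twice == render_ideogram(sc)
        assert once != twice

    def test_rendering_is_pure(self):
        sc = scene([fwd(), rev(q="q2", t="t2", start=50)])
        assert render_ideogram(sc) == render_ideogram(sc)

    def test_gene_glyphs_and_labels(self):
        from syntopy.io.gff3 import GeneFeature

        genes = (
            GeneFeature("t1", SeqRange("t1", 100, 300), "+", "amy1"),
        )
        svg = render_ideogram(scene([fwd()], genes=genes))
        assert len(elements(svg, "gene")) == 1
        assert "amy1" in svg

    def test_invalid_viewport_rejected(self):
        with pytest.raises(ValidationError):
            scene(
                [fwd()],
                viewport=(SeqRange("q1", 0, 5000), SeqRange("t1", 0, 100)),
            )

    def test_viewport_drops_outside_alignments(self):
        alns = [fwd(start=0, t_start=0), fwd(start=500, t_start=500, length=200)]
        sc = scene(
            alns,
            viewport=(SeqRange("q1", 450, 800), SeqRange("t1", 450, 800)),
        )
        assert len(elements(render_ideogram(sc), "connector")) == 1


class TestDotplot:
    def test_forward_green_positive_slope(self):
        svg = render_dotplot(scene([fwd()]))
        (line,) = elements(svg, "fwd")
        assert line.attrib["stroke"] == "green"
        dx = float(line.attrib["x2"]) - float(line.attrib["x1"])
        dy = float(line.attrib["y2"]) - float(line.attrib["y1"])
        assert dx > 0 and dy < 0  # SVG y grows downward: up-slope on screen

    def test_reverse_purple_negative_slope(self):
        svg = render_dotplot(scene([rev()]))
        (line,) = elements(svg, "rev")
        assert line.attrib["stroke"] == "purple"
        dx = float(line.attrib["x2"]) - float(line.attrib["x1"])
        dy = float(line.attrib["y2"]) - float(line.attrib["y1"])
        assert dx > 0 and dy > 0

    def test_non_best_always_drawn(self):
        svg = render_dotplot(scene([fwd(reciprocity=1)], include_non_best=False))
        assert len(elements(svg, "aln")) == 1

    def test_line_count_matches_post_filter_segments(self):
        alns = [fwd(), rev(q="q2", t="t2"), fwd(q="q2", t="t1", start=300, length=30)]
        svg = render_dotplot(scene(alns, min_segment_length=50))
        assert len(elements(svg, "aln")) == 2  # the 30 bp segment filtered


class TestSegmentInfo:
    def test_one_based_display_coordinates(self):
        rec = segment_info(fwd(start=0, length=100))
        assert (rec["query_start"], rec["query_end"]) == (1, 100)

    def test_orientation_and_reciprocity_reported(self):
        rec = segment_info(rev(reciprocity=2))
        assert rec["orientation"] == "reverse"
        assert rec["reciprocity"] == 2

    def test_identity_consistent_with_segment(self):
        ra = fwd()
        assert segment_info(ra)["percent_identity"] == pytest.approx(
            ra.segment.percent_identity
        )
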