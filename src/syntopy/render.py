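"""Static SVG rendering: synteny ideogram and dotplot.

The ideogram stacks the two assemblies as horizontal chromosome rows (query
on top) and links aligned regions with ribbon connectors, colored by target
chromosome.  The default view shows only reciprocal-best alignments; size
and orientation filters and per-chromosome flipping mirror the interactive
viewer semantics.  The dotplot draws forward alignments as positive-slope
green lines and reverse alignments as negative-slope purple lines, and
always shows both best-placed and non-best placed alignments.

Rendering is pure: the same scene always yields byte-identical SVG.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

from .io._util import natural_key
from .model import (
    AssemblyInfo,
    FORWARD,
    RankedAlignment,
    REVERSE,
    SeqRange,
    ValidationError,
)
from .io.gff3 import GeneFeature

logger = logging.getLogger(__name__)

__all__ = ["SyntenyScene", "render_ideogram", "render_dotplot", "segment_info"]

#: fixed categorical palette, keyed by target chromosome order
PALETTE = [
    "#4477aa", "#ee6677", "#228833", "#ccbb44", "#66ccee", "#aa3377",
    "#bbbbbb", "#e69f00", "#56b4e9", "#009e73", "#d55e00", "#cc79a7",
]

FORWARD_COLOR = "green"
REVERSE_COLOR = "purple"

ORIENTATION_FILTERS = ("all", "forward_only", "reverse_only")


@dataclass(frozen=True)
class SyntenyScene:
    """A filtered, oriented view of a ranked alignment set."""

    alignments: tuple[RankedAlignment, ...]
    q_info: AssemblyInfo
    t_info: AssemblyInfo
    min_segment_length: int = 0
    orientation: str = "all"
    include_non_best: bool = False
    flipped_sequences: frozenset[str] = frozenset()
    viewport: tuple[SeqRange, SeqRange] | None = None
    genes: tuple[GeneFeature, ...] = ()

    def __post_init__(self) -> None:
        if self.orientation not in ORIENTATION_FILTERS:
            raise ValidationError(f"bad orientation filter {self.orientation!r}")
        object.__setattr__(self, "alignments", tuple(self.alignments))
        object.__setattr__(self, "genes", tuple(self.genes))
        object.__setattr__(
            self, "flipped_sequences", frozenset(self.flipped_sequences)
        )
        if self.viewport is not None:
            qv, tv = self.viewport
            for rng, info in ((qv, self.q_info), (tv, self.t_info)):
                if rng.seq_id not in info or rng.end > info.length_of(rng.seq_id):
                    raise ValidationError(
                        f"viewport range {rng.seq_id}:{rng.start}-{rng.end} "
                        f"invalid for assembly {info.assembly_id}"
                    )

    def with_flip(self, seq_id: str) -> "SyntenyScene":
        """Toggle the flip state of one chromosome."""
        flipped = set(self.flipped_sequences)
        flipped.symmetric_difference_update({seq_id})
        return replace(self, flipped_sequences=frozenset(flipped))

    def visible(self, include_all_reciprocities: bool = False) -> list[RankedAlignment]:
        out = []
        for ra in self.alignments:
            if (
                not include_all_reciprocities
                and not self.include_non_best
                and ra.reciprocity != 3
            ):
                continue
            seg = ra.segment
            if seg.length < self.min_segment_length:
                continue
            if self.orientation == "forward_only" and seg.orientation != FORWARD:
                continue
            if self.orientation == "reverse_only" and seg.orientation != REVERSE:
                continue
            if self.viewport is not None:
                qv, tv = self.viewport
                if not (seg.query.overlaps(qv) and seg.target.overlaps(tv)):
                    continue
            out.append(ra)
        return out


class _Row:
    """Horizontal layout of one assembly's chromosomes."""

    def __init__(
        self,
        info: AssemblyInfo,
        flipped: frozenset[str],
        x0: float,
        width: float,
        gap: float = 8.0,
        restrict: SeqRange | None = None,
    ):
        if restrict is not None:
            seq_ids = [restrict.seq_id]
            lengths = {restrict.seq_id: restrict.length}
            self.starts = {restrict.seq_id: restrict.start}
        else:
            seq_ids = sorted(info.seq_ids(), key=natural_key)
            lengths = {sid: info.length_of(sid) for sid in seq_ids}
            self.starts = {sid: 0 for sid in seq_ids}
        total = sum(lengths.values())
        avail = width - gap * max(0, len(seq_ids) - 1)
        self.scale = avail / max(total, 1)
        self.offsets: dict[str, float] = {}
        self.lengths = lengths
        self.flipped = flipped
        x = x0
        for sid in seq_ids:
            self.offsets[sid] = x
            x += lengths[sid] * self.scale + gap

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self.offsets

    def x(self, seq_id: str, pos: int) -> float:
        rel = min(max(pos - self.starts[seq_id], 0), self.lengths[seq_id])
        if seq_id in self.flipped:
            rel = self.lengths[seq_id] - rel
        return self.offsets[seq_id] + rel * self.scale

    def span(self, seq_id: str) -> tuple[float, float]:
        return (
            self.offsets[seq_id],
            self.offsets[seq_id] + self.lengths[seq_id] * self.scale,
        )


def _f(v: float) -> str:
    return f"{v:.2f}"


def _svg_open(width: int, height: int) -> list[str]:
    return [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{width}" height="{height}" '
        f'viewBox="0 0 {width} {height}">',
    ]


def _chrom_row_svg(
    parts: list[str], row: _Row, y: float, h: float, label_above: bool
) -> None:
    for sid in row.offsets:
        x0, x1 = row.span(sid)
        parts.append(
            f'<rect class="chrom" x="{_f(x0)}" y="{_f(y)}" '
            f'width="{_f(x1 - x0)}" height="{_f(h)}" rx="4" '
            f'fill="#dddddd" stroke="#555555"/>'
        )
        ly = y - 6 if label_above else y + h + 14
        flip_mark = " (flipped)" if sid in row.flipped else ""
        parts.append(
            f'<text class="seq-label" x="{_f(x0)}" y="{_f(ly)}" '
            f'font-size="11" font-family="sans-serif">{sid}{flip_mark}</text>'
        )
        # simple ruler: tick at both ends with base-pair labels
        start = row.starts[sid]
        end = start + row.lengths[sid]
        ry = y + h + 3 if label_above else y - 3
        for pos, anchor in ((start, "start"), (end, "end")):
            tx = row.x(sid, pos)
            parts.append(
                f'<line class="tick" x1="{_f(tx)}" y1="{_f(y)}" '
                f'x2="{_f(tx)}" y2="{_f(ry)}" stroke="#999999"/>'
            )


def render_ideogram(scene: SyntenyScene) -> str:
    """Render the two-row chromosome ideogram with alignment connectors."""
    width, height = 1000, 420
    margin = 50.0
    q_y, t_y, chrom_h = 80.0, 300.0, 16.0
    qv, tv = (scene.viewport if scene.viewport is not None else (None, None))
    q_row = _Row(scene.q_info, scene.flipped_sequences, margin, width - 2 * margin,
                 restrict=qv)
    t_row = _Row(scene.t_info, scene.flipped_sequences, margin, width - 2 * margin,
                 restrict=tv)
    t_order = sorted(scene.t_info.seq_ids(), key=natural_key)
    color_of = {sid: PALETTE[i % len(PALETTE)] for i, sid in enumerate(t_order)}

    parts = _svg_open(width, height)
    parts.append(
        f'<text class="title" x="{_f(margin)}" y="24" font-size="14" '
        f'font-family="sans-serif">{scene.q_info.assembly_id} (top) vs '
        f"{scene.t_info.assembly_id} (bottom)</text>"
    )
    _chrom_row_svg(parts, q_row, q_y, chrom_h, label_above=True)
    _chrom_row_svg(parts, t_row, t_y, chrom_h, label_above=False)

    visible = [
        ra
        for ra in scene.visible()
        if ra.segment.query.seq_id in q_row and ra.segment.target.seq_id in t_row
    ]
    if not visible:
        logger.warning("ideogram: no alignments pass the current filters")
        parts.append(
            f'<text class="caption" x="{_f(width / 2)}" y="{_f(height / 2)}" '
            f'text-anchor="middle" font-size="13" font-family="sans-serif">'
            f"no alignments pass the current filters</text>"
        )
    for ra in visible:
        seg = ra.segment
        qx1 = q_row.x(seg.query.seq_id, seg.query.start)
        qx2 = q_row.x(seg.query.seq_id, seg.query.end)
        if seg.orientation == FORWARD:
            tx1 = t_row.x(seg.target.seq_id, seg.target.start)
            tx2 = t_row.x(seg.target.seq_id, seg.target.end)
        else:
            tx1 = t_row.x(seg.target.seq_id, seg.target.end)
            tx2 = t_row.x(seg.target.seq_id, seg.target.start)
        color = color_of[seg.target.seq_id]
        parts.append(
            f'<polygon class="connector" fill="{color}" fill-opacity="0.55" '
            f'stroke="{color}" stroke-width="0.5" points="'
            f"{_f(qx1)},{_f(q_y + chrom_h)} {_f(qx2)},{_f(q_y + chrom_h)} "
            f'{_f(tx2)},{_f(t_y)} {_f(tx1)},{_f(t_y)}"/>'
        )
    for gene in scene.genes:
        row = q_row if gene.seq_id in q_row else (t_row if gene.seq_id in t_row else None)
        if row is None:
            continue
        y = q_y if row is q_row else t_y
        gx1 = row.x(gene.seq_id, gene.range.start)
        gx2 = row.x(gene.seq_id, gene.range.end)
        x_lo, x_hi = min(gx1, gx2), max(gx1, gx2)
        parts.append(
            f'<rect class="gene" x="{_f(x_lo)}" y="{_f(y - 5)}" '
            f'width="{_f(max(x_hi - x_lo, 1.0))}" height="4" fill="#b22222"/>'
        )
        parts.append(
            f'<text class="gene-label" x="{_f(x_lo)}" y="{_f(y - 8)}" '
            f'font-size="9" font-family="sans-serif">{gene.gene_name}</text>'
        )
    parts.append("</svg>")
    return "\n".join(parts) + "\n"


def render_dotplot(scene: SyntenyScene) -> str:
    """Render the dotplot: target on X, query on Y.

    Always includes both best-placed and non-best placed alignments; size and
    orientation filters still apply.
    """
    width, height = 820, 820
    margin = 70.0
    plot_w = width - margin - 30
    plot_h = height - margin - 30
    qv, tv = (scene.viewport if scene.viewport is not None else (None, None))
    x_row = _Row(scene.t_info, frozenset(), margin, plot_w, restrict=tv)
    y_row = _Row(scene.q_info, frozenset(), 30.0, plot_h, restrict=qv)

    def y_of(seq_id: str, pos: int) -> float:
        # query coordinate ascends upward: invert the row coordinate
        return height - margin - (y_row.x(seq_id, pos) - 30.0)

    parts = _svg_open(width, height)
    parts.append(
        f'<text class="title" x="{_f(margin)}" y="20" font-size="14" '
        f'font-family="sans-serif">{scene.t_info.assembly_id} (x) vs '
        f"{scene.q_info.assembly_id} (y)</text>"
    )
    # grid of chromosome-pair cells
    for t_sid in x_row.offsets:
        x0, x1 = x_row.span(t_sid)
        for q_sid in y_row.offsets:
            yy0 = y_of(q_sid, y_row.starts[q_sid])
            yy1 = y_of(q_sid, y_row.starts[q_sid] + y_row.lengths[q_sid])
            parts.append(
                f'<rect class="cell" x="{_f(x0)}" y="{_f(min(yy0, yy1))}" '
                f'width="{_f(x1 - x0)}" height="{_f(abs(yy0 - yy1))}" '
                f'fill="none" stroke="#cccccc" stroke-width="0.5"/>'
            )
        parts.append(
            f'<text class="x-label" x="{_f(x0)}" y="{_f(height - margin + 16)}" '
            f'font-size="10" font-family="sans-serif">{t_sid}</text>'
        )
    for q_sid in y_row.offsets:
        ly = y_of(q_sid, y_row.starts[q_sid])
        parts.append(
            f'<text class="y-label" x="8" y="{_f(ly)}" font-size="10" '
            f'font-family="sans-serif">{q_sid}</text>'
        )

    visible = [
        ra
        for ra in scene.visible(include_all_reciprocities=True)
        if ra.segment.query.seq_id in y_row and ra.segment.target.seq_id in x_row
    ]
    if not visible:
        logger.warning("dotplot: no alignments pass the current filters")
        parts.append(
            f'<text class="caption" x="{_f(width / 2)}" y="{_f(height / 2)}" '
            f'text-anchor="middle" font-size="13" font-family="sans-serif">'
            f"no alignments pass the current filters</text>"
        )
    for ra in visible:
        seg = ra.segment
        x1 = x_row.x(seg.target.seq_id, seg.target.start)
        x2 = x_row.x(seg.target.seq_id, seg.target.end)
        if seg.orientation == FORWARD:
            y1 = y_of(seg.query.seq_id, seg.query.start)
            y2 = y_of(seg.query.seq_id, seg.query.end)
            cls, color = "aln fwd", FORWARD_COLOR
        else:
            y1 = y_of(seg.query.seq_id, seg.query.end)
            y2 = y_of(seg.query.seq_id, seg.query.start)
            cls, color = "aln rev", REVERSE_COLOR
        parts.append(
            f'<line class="{cls}" x1="{_f(x1)}" y1="{_f(y1)}" '
            f'x2="{_f(x2)}" y2="{_f(y2)}" stroke="{color}" stroke-width="1.5"/>'
        )
    parts.append("</svg>")
    return "\n".join(parts) + "\n"


def segment_info(ranked: RankedAlignment) -> dict:
    """Info-panel record: accessions, 1-based display coordinates, identity,
    gaps, mismatches, alignment length, reciprocity."""
    seg = ranked.segment
    return {
        "query_assembly": seg.query.assembly_id,
        "query_accession": seg.query.seq_id,
        "query_start": seg.query.start + 1,
        "query_end": seg.query.end,
        "target_assembly": seg.target.assembly_id,
        "target_accession": seg.target.seq_id,
        "target_start": seg.target.start + 1,
        "target_end": seg.target.end,
        "orientation": seg.orientation,
        "percent_identity": round(seg.percent_identity, 4),
        "gap_count": seg.gap_count,
        "mismatches": seg.mismatches,
        "alignment_length": seg.length,
        "reciprocity": ranked.reciprocity,
    }
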