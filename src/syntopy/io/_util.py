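"""Shared helpers for the format readers."""

from __future__ import annotations

import io
import re
from typing import IO, Iterable

from ..model import AlignmentBlock, AlignmentSegment, FORWARD, REVERSE

_NAT_SPLIT = re.compile(r"(\d+)")


def natural_key(name: str) -> tuple:
    """Sort key treating digit runs numerically (chr2 before chr10)."""
    return tuple(
        int(tok) if tok.isdigit() else tok for tok in _NAT_SPLIT.split(name)
    )


def ensure_text_stream(source) -> IO[str]:
    """Accept a path, str-path or open text handle and return a text handle."""
    if hasattr(source, "read"):
        return source
    return open(source, "r", encoding="utf-8")


def lines_of(source) -> Iterable[tuple[int, str]]:
    stream = ensure_text_stream(source)
    for i, line in enumerate(stream, start=1):
        yield i, line.rstrip("\n")


def synthesize_blocks(
    q_start: int,
    q_end: int,
    t_start: int,
    t_end: int,
    orientation: str,
    aligned: int,
) -> list[AlignmentBlock]:
    """Low-resolution block structure when no per-column alignment is given.

    ``aligned`` bases are split into at most two blocks anchored at the range
    ends so the block envelope matches the reported spans exactly; any span
    difference becomes a single internal gap.  Exact gap positions are
    unknowable without a CIGAR/BTOP, so downstream gap splitting degrades to
    whole-segment granularity for such segments.
    """
    q_span = q_end - q_start
    t_span = t_end - t_start
    aligned = min(aligned, q_span, t_span)
    if aligned <= 0:
        raise ValueError("alignment with no aligned bases")
    if q_span == t_span == aligned:
        if orientation == FORWARD:
            return [AlignmentBlock(q_start, t_start, aligned)]
        return [AlignmentBlock(q_start, t_start, aligned)]
    a = max(1, aligned // 2)
    b = aligned - a
    if b == 0:  # aligned == 1; single block anchored left
        a_blocks = [AlignmentBlock(q_start, t_end - 1 if orientation == REVERSE else t_start, 1)]
        return a_blocks
    if orientation == FORWARD:
        return [
            AlignmentBlock(q_start, t_start, a),
            AlignmentBlock(q_end - b, t_end - b, b),
        ]
    # reverse: first query block pairs with the high end of the target
    return [
        AlignmentBlock(q_start, t_end - a, a),
        AlignmentBlock(q_end - b, t_start, b),
    ]


def segment_sans_source(seg: AlignmentSegment) -> AlignmentSegment:
    from dataclasses import replace

    return replace(seg, source_id="")
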