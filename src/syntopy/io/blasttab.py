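"""BLAST tabular (outfmt 6) reader.

Standard 12 columns ``qseqid sseqid pident length mismatch gapopen qstart
qend sstart send evalue bitscore`` with an optional 13th BTOP column.  BLAST
coordinates are 1-based inclusive; ``sstart > send`` encodes a reverse-
orientation hit.  With BTOP the exact block structure is reconstructed;
without it a low-resolution block layout is synthesized from the spans.
"""

from __future__ import annotations

import re

from ..model import (
    AlignmentBlock,
    AlignmentSegment,
    FORWARD,
    ParseError,
    REVERSE,
)
from ._util import lines_of, synthesize_blocks

_BTOP_TOKEN = re.compile(r"(\d+)|([A-Za-z-]{2})")


def _decode_btop(
    btop: str, q0: int, sstart: int, send: int, line_no: int
):
    """Walk a BTOP string into blocks.

    Returns (blocks in ascending query order, matches, mismatches,
    gap_count, gap_bases).
    """
    reverse = sstart > send
    step = -1 if reverse else 1
    q = q0  # 0-based, ascending
    t = sstart - 1  # 0-based cursor, walks in subject direction
    blocks: list[AlignmentBlock] = []
    matches = mismatches = gap_count = gap_bases = 0
    in_gap = None  # 'q' or 't' while extending a gap run

    def emit(run: int) -> None:
        nonlocal q, t
        if run <= 0:
            return
        if reverse:
            blocks.append(AlignmentBlock(q, t - run + 1, run))
            t -= run
        else:
            blocks.append(AlignmentBlock(q, t, run))
            t += run
        q += run

    consumed = 0
    for m in _BTOP_TOKEN.finditer(btop):
        consumed += m.end() - m.start()
        if m.group(1):
            run = int(m.group(1))
            emit(run)
            matches += run
            in_gap = None
            continue
        a, b = m.group(2)
        if a == "-" and b == "-":
            raise ParseError(f"line {line_no}: bad BTOP pair '--'")
        if a == "-":  # gap in query: subject-only column
            t += step
            gap_bases += 1
            if in_gap != "q":
                gap_count += 1
            in_gap = "q"
        elif b == "-":  # gap in subject: query-only column
            q += 1
            gap_bases += 1
            if in_gap != "t":
                gap_count += 1
            in_gap = "t"
        else:  # mismatched aligned column
            emit(1)
            mismatches += 1
            in_gap = None
    if consumed != len(btop):
        raise ParseError(f"line {line_no}: malformed BTOP {btop!r}")
    # coalesce abutting blocks produced by mismatch columns
    merged: list[AlignmentBlock] = []
    for blk in blocks:
        if merged:
            prev = merged[-1]
            contiguous_t = (
                blk.t_start == prev.t_end
                if not reverse
                else blk.t_end == prev.t_start
            )
            if blk.q_start == prev.q_end and contiguous_t:
                merged[-1] = AlignmentBlock(
                    prev.q_start,
                    min(prev.t_start, blk.t_start),
                    prev.length + blk.length,
                )
                continue
        merged.append(blk)
    return merged, matches, mismatches, gap_count, gap_bases


def read_blast_tab(
    source, q_assembly: str = "query", t_assembly: str = "target"
) -> list[AlignmentSegment]:
    """Read BLAST outfmt-6 rows (optionally with BTOP) into segments."""
    segments: list[AlignmentSegment] = []
    for line_no, line in lines_of(source):
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) == 1:
            fields = line.split()
        if len(fields) < 12:
            raise ParseError(
                f"line {line_no}: outfmt 6 needs >= 12 columns, got {len(fields)}"
            )
        try:
            q_name, s_name = fields[0], fields[1]
            aln_len = int(fields[3])
            mismatch = int(fields[4])
            gapopen = int(fields[5])
            qstart, qend = int(fields[6]), int(fields[7])
            sstart, send = int(fields[8]), int(fields[9])
        except ValueError as exc:
            raise ParseError(f"line {line_no}: {exc}") from None
        if qstart > qend:
            raise ParseError(f"line {line_no}: query coordinates must ascend")
        q0, q1 = qstart - 1, qend
        reverse = sstart > send
        t0, t1 = (send - 1, sstart) if reverse else (sstart - 1, send)
        orientation = REVERSE if reverse else FORWARD
        btop = fields[12] if len(fields) > 12 and fields[12] else None
        if btop:
            blocks, matches, mismatches, gap_count, gap_bases = _decode_btop(
                btop, q0, sstart, send, line_no
            )
            seg = AlignmentSegment.build(
                q_name,
                s_name,
                orientation,
                blocks,
                matches=matches,
                mismatches=mismatches,
                gap_count=gap_count,
                gap_bases=gap_bases,
                q_assembly=q_assembly,
                t_assembly=t_assembly,
                source_id=f"blast:{line_no}",
            )
        else:
            q_span, t_span = q1 - q0, t1 - t0
            gap_bases = (aln_len - q_span) + (aln_len - t_span)
            matches = aln_len - mismatch - gap_bases
            aligned = matches + mismatch
            blocks = synthesize_blocks(q0, q1, t0, t1, orientation, aligned)
            seg = AlignmentSegment.build(
                q_name,
                s_name,
                orientation,
                blocks,
                matches=matches,
                mismatches=mismatch,
                gap_count=gapopen,
                gap_bases=gap_bases,
                q_assembly=q_assembly,
                t_assembly=t_assembly,
                source_id=f"blast:{line_no}",
            )
        segments.append(seg)
    return segments
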