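"""PAF reader (minimap2 dialect).

With a ``cg:Z`` CIGAR tag the block structure, mismatch and gap statistics
are exact; without it a low-resolution one/two-block segment is synthesized
from the line's spans and match count, and a warning is logged once per
stream.
"""

from __future__ import annotations

import logging
import re
from typing import IO

from ..model import (
    AlignmentBlock,
    AlignmentSegment,
    AssemblyInfo,
    FORWARD,
    ParseError,
    REVERSE,
)
from ._util import lines_of, synthesize_blocks

logger = logging.getLogger(__name__)

_CIGAR_OP = re.compile(r"(\d+)([MIDNSHP=X])")


def _decode_cigar(
    cigar: str,
    q_start: int,
    q_end: int,
    t_start: int,
    strand: str,
    n_match_col: int,
    line_no: int,
):
    """Walk a cg:Z CIGAR into blocks; returns (blocks, matches, mismatches)."""
    blocks: list[AlignmentBlock] = []
    has_eq = "=" in cigar or "X" in cigar
    matches = 0
    mismatches = 0
    t = t_start
    # on the minus strand the CIGAR walks the reverse-complemented query:
    # target ascends from t_start while forward-strand query descends from q_end
    q = q_start if strand == "+" else q_end
    consumed = 0
    for m in _CIGAR_OP.finditer(cigar):
        n, op = int(m.group(1)), m.group(2)
        consumed += m.end() - m.start()
        if op in "M=X":
            if strand == "+":
                blocks.append(AlignmentBlock(q, t, n))
                q += n
            else:
                blocks.append(AlignmentBlock(q - n, t, n))
                q -= n
            t += n
            if op == "X":
                mismatches += n
            else:
                matches += n  # 'M' runs resolved against column 10 below
        elif op == "I":  # extra query bases
            q = q + n if strand == "+" else q - n
        elif op in "DN":  # extra target bases
            t += n
        else:
            raise ParseError(f"line {line_no}: unsupported CIGAR op {op!r}")
    if consumed != len(cigar):
        raise ParseError(f"line {line_no}: malformed CIGAR {cigar!r}")
    if not has_eq:
        # M-only CIGAR: apportion column-10 matches over the aligned bases
        aligned = matches
        matches = min(n_match_col, aligned)
        mismatches = aligned - matches
    if strand == "-":
        blocks.reverse()  # restore ascending query order
    # coalesce abutting runs (e.g. "=" directly followed by "X") into
    # maximal ungapped blocks
    merged: list[AlignmentBlock] = []
    for blk in blocks:
        if merged:
            prev = merged[-1]
            contiguous_t = (
                blk.t_start == prev.t_end
                if strand == "+"
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
    return merged, matches, mismatches


def read_paf_with_info(
    source, q_assembly: str = "query", t_assembly: str = "target"
) -> tuple[list[AlignmentSegment], AssemblyInfo, AssemblyInfo]:
    """Read PAF; also collect sequence lengths into AssemblyInfo objects."""
    segments: list[AlignmentSegment] = []
    q_lengths: dict[str, int] = {}
    t_lengths: dict[str, int] = {}
    warned_low_res = False
    for line_no, line in lines_of(source):
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 12:
            raise ParseError(f"line {line_no}: PAF needs >= 12 columns, got {len(fields)}")
        try:
            q_name = fields[0]
            q_len = int(fields[1])
            q_start, q_end = int(fields[2]), int(fields[3])
            strand = fields[4]
            t_name = fields[5]
            t_len = int(fields[6])
            t_start, t_end = int(fields[7]), int(fields[8])
            n_match = int(fields[9])
        except ValueError as exc:
            raise ParseError(f"line {line_no}: {exc}") from None
        if strand not in "+-":
            raise ParseError(f"line {line_no}: bad strand {strand!r}")
        q_lengths[q_name] = q_len
        t_lengths[t_name] = t_len
        cigar = None
        for tag in fields[12:]:
            if tag.startswith("cg:Z:"):
                cigar = tag[5:]
                break
        orientation = FORWARD if strand == "+" else REVERSE
        if cigar:
            blocks, matches, mismatches = _decode_cigar(
                cigar, q_start, q_end, t_start, strand, n_match, line_no
            )
        else:
            if not warned_low_res:
                logger.warning(
                    "PAF lines without cg:Z CIGAR: block structure is "
                    "low-resolution; gap splitting degrades to whole segments"
                )
                warned_low_res = True
            aligned = min(q_end - q_start, t_end - t_start)
            blocks = synthesize_blocks(
                q_start, q_end, t_start, t_end, orientation, aligned
            )
            matches = min(n_match, aligned)
            mismatches = aligned - matches
        try:
            seg = AlignmentSegment.build(
                q_name,
                t_name,
                orientation,
                blocks,
                matches=matches,
                mismatches=mismatches,
                q_assembly=q_assembly,
                t_assembly=t_assembly,
                source_id=f"paf:{line_no}",
            )
        except Exception as exc:
            raise ParseError(f"line {line_no}: {exc}") from None
        segments.append(seg)
    q_info = AssemblyInfo.from_lengths(q_assembly, q_lengths)
    t_info = AssemblyInfo.from_lengths(t_assembly, t_lengths)
    return segments, q_info, t_info


def read_paf(source) -> list[AlignmentSegment]:
    """Read a PAF stream or path into alignment segments."""
    return read_paf_with_info(source)[0]


def write_paf(
    segments: list[AlignmentSegment],
    stream,
    q_info: AssemblyInfo,
    t_info: AssemblyInfo,
) -> None:
    """Write segments as PAF lines with a cg:Z CIGAR built from the blocks.

    Aligned runs are emitted as ``M`` operations (mismatch positions within
    blocks are not tracked); the match count goes in column 10, so the round
    trip preserves blocks and match/mismatch totals.
    """
    for seg in segments:
        strand = "+" if seg.orientation == FORWARD else "-"
        ops: list[str] = []
        blocks = seg.blocks if strand == "+" else tuple(reversed(seg.blocks))
        gaps = seg.junction_gaps()
        gaps = gaps if strand == "+" else list(reversed(gaps))
        for i, b in enumerate(blocks):
            if i > 0:
                q_gap, t_gap = gaps[i - 1]
                if q_gap:
                    ops.append(f"{q_gap}I")
                if t_gap:
                    ops.append(f"{t_gap}D")
            ops.append(f"{b.length}M")
        aln_cols = seg.aligned_length + seg.gap_bases
        stream.write(
            "\t".join(
                str(x)
                for x in (
                    seg.query.seq_id,
                    q_info.length_of(seg.query.seq_id),
                    seg.query.start,
                    seg.query.end,
                    strand,
                    seg.target.seq_id,
                    t_info.length_of(seg.target.seq_id),
                    seg.target.start,
                    seg.target.end,
                    seg.matches,
                    aln_cols,
                    255,
                    "cg:Z:" + "".join(ops),
                )
            )
            + "\n"
        )
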