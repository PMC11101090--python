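"""UCSC chain reader.

A chain header is::

    chain score tName tSize tStrand tStart tEnd qName qSize qStrand qStart qEnd id

followed by ``size dt dq`` lines (the last line is a bare ``size``).  The
target strand is always ``+``; reverse-strand query coordinates are counted
from the sequence end and are normalized here to forward coordinates.
"""

from __future__ import annotations

from ..model import (
    AlignmentBlock,
    AlignmentSegment,
    AssemblyInfo,
    FORWARD,
    ParseError,
    REVERSE,
)
from ._util import lines_of


def read_chain_with_info(
    source, q_assembly: str = "query", t_assembly: str = "target"
) -> tuple[list[AlignmentSegment], AssemblyInfo, AssemblyInfo]:
    segments: list[AlignmentSegment] = []
    q_lengths: dict[str, int] = {}
    t_lengths: dict[str, int] = {}

    header = None
    blocks_raw: list[tuple[int, int, int]] = []

    def flush(line_no: int) -> None:
        nonlocal header, blocks_raw
        if header is None:
            return
        (
            t_name,
            t_size,
            t_start,
            t_end,
            q_name,
            q_size,
            q_strand,
            q_start,
            q_end,
            chain_id,
        ) = header
        sizes = sum(s for s, _, _ in blocks_raw)
        dt = sum(d for _, d, _ in blocks_raw)
        dq = sum(d for _, _, d in blocks_raw)
        if t_start + sizes + dt != t_end or q_start + sizes + dq != q_end:
            raise ParseError(
                f"chain {chain_id}: block sums do not match header coordinates"
            )
        blocks: list[AlignmentBlock] = []
        t_cur, q_cur = t_start, q_start
        for size, d_t, d_q in blocks_raw:
            if q_strand == "+":
                blocks.append(AlignmentBlock(q_cur, t_cur, size))
            else:
                # reverse-strand coords count from the sequence end
                blocks.append(AlignmentBlock(q_size - (q_cur + size), t_cur, size))
            t_cur += size + d_t
            q_cur += size + d_q
        orientation = FORWARD
        if q_strand == "-":
            blocks.reverse()  # ascending query order; target now descends
            orientation = REVERSE
        q_lengths[q_name] = q_size
        t_lengths[t_name] = t_size
        # chains carry no substitution information: matches = aligned bases
        segments.append(
            AlignmentSegment.build(
                q_name,
                t_name,
                orientation,
                blocks,
                q_assembly=q_assembly,
                t_assembly=t_assembly,
                source_id=f"chain:{chain_id}",
            )
        )
        header = None
        blocks_raw = []

    for line_no, line in lines_of(source):
        line = line.strip()
        if not line or line.startswith("#"):
            flush(line_no)
            continue
        if line.startswith("chain"):
            flush(line_no)
            f = line.split()
            if len(f) != 13:
                raise ParseError(f"line {line_no}: chain header needs 13 fields")
            if f[4] != "+":
                raise ParseError(
                    f"line {line_no}: chain target strand must be '+', got {f[4]!r}"
                )
            if f[9] not in "+-":
                raise ParseError(f"line {line_no}: bad query strand {f[9]!r}")
            try:
                header = (
                    f[2],
                    int(f[3]),
                    int(f[5]),
                    int(f[6]),
                    f[7],
                    int(f[8]),
                    f[9],
                    int(f[10]),
                    int(f[11]),
                    f[12],
                )
            except ValueError as exc:
                raise ParseError(f"line {line_no}: {exc}") from None
            continue
        if header is None:
            raise ParseError(f"line {line_no}: alignment data outside a chain")
        try:
            parts = [int(x) for x in line.split()]
        except ValueError as exc:
            raise ParseError(f"line {line_no}: {exc}") from None
        if len(parts) == 1:
            blocks_raw.append((parts[0], 0, 0))
        elif len(parts) == 3:
            blocks_raw.append((parts[0], parts[1], parts[2]))
        else:
            raise ParseError(f"line {line_no}: expected 'size dt dq' or 'size'")
    flush(-1)
    q_info = AssemblyInfo.from_lengths(q_assembly, q_lengths)
    t_info = AssemblyInfo.from_lengths(t_assembly, t_lengths)
    return segments, q_info, t_info


def read_chain(source) -> list[AlignmentSegment]:
    """Read a UCSC chain stream or path into alignment segments."""
    return read_chain_with_info(source)[0]
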