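"""Human-readable table export (TSV / XLSX) of ranked alignments."""

from __future__ import annotations

import pandas as pd

from ..model import (
    AlignmentSegment,
    FORWARD,
    RankedAlignment,
    REVERSE,
    SeqRange,
)
from ._util import synthesize_blocks

#: column order; coordinates are displayed 1-based inclusive
COLUMNS = [
    "query_assembly",
    "query_seq",
    "query_start",
    "query_end",
    "target_assembly",
    "target_seq",
    "target_start",
    "target_end",
    "orientation",
    "percent_identity",
    "matches",
    "mismatches",
    "gap_count",
    "gap_bases",
    "length",
    "reciprocity",
]


def _to_frame(ranked) -> pd.DataFrame:
    rows = []
    for ra in ranked:
        s = ra.segment
        rows.append(
            {
                "query_assembly": s.query.assembly_id,
                "query_seq": s.query.seq_id,
                "query_start": s.query.start + 1,
                "query_end": s.query.end,
                "target_assembly": s.target.assembly_id,
                "target_seq": s.target.seq_id,
                "target_start": s.target.start + 1,
                "target_end": s.target.end,
                "orientation": s.orientation,
                "percent_identity": round(s.percent_identity, 4),
                "matches": s.matches,
                "mismatches": s.mismatches,
                "gap_count": s.gap_count,
                "gap_bases": s.gap_bases,
                "length": s.length,
                "reciprocity": ra.reciprocity,
            }
        )
    return pd.DataFrame(rows, columns=COLUMNS)


def write_table(ranked, path_or_stream, format: str = "tsv") -> None:
    """Write one row per alignment; TSV and XLSX are cell-identical."""
    df = _to_frame(ranked)
    if format == "tsv":
        df.to_csv(path_or_stream, sep="\t", index=False)
    elif format == "xlsx":
        df.to_excel(path_or_stream, index=False)
    else:
        raise ValueError(f"unsupported table format {format!r}; use tsv or xlsx")


def read_table_tsv(path_or_stream) -> list[RankedAlignment]:
    """Read a TSV written by :func:`write_table`.

    The table does not carry block structure, so segments are rebuilt with a
    low-resolution block layout consistent with the row's spans and counts.
    """
    df = pd.read_csv(path_or_stream, sep="\t")
    out: list[RankedAlignment] = []
    for row in df.itertuples(index=False):
        q0, q1 = int(row.query_start) - 1, int(row.query_end)
        t0, t1 = int(row.target_start) - 1, int(row.target_end)
        aligned = int(row.matches) + int(row.mismatches)
        blocks = synthesize_blocks(q0, q1, t0, t1, row.orientation, aligned)
        seg = AlignmentSegment.build(
            str(row.query_seq),
            str(row.target_seq),
            row.orientation,
            blocks,
            matches=int(row.matches),
            mismatches=int(row.mismatches),
            gap_count=int(row.gap_count),
            gap_bases=int(row.gap_bases),
            q_assembly="" if pd.isna(row.query_assembly) else str(row.query_assembly),
            t_assembly="" if pd.isna(row.target_assembly) else str(row.target_assembly),
        )
        out.append(RankedAlignment(segment=seg, reciprocity=int(row.reciprocity)))
    return out
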