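"""Alignment coverage statistics on the target assembly.

Coverage is computed on the union of **ungapped alignment blocks**, never on
segment envelopes, so internal gaps do not inflate the numbers.  Genome
coverage is the covered fraction of the whole target assembly; CDS coverage
is the covered fraction of the union of CDS intervals (isoforms pooled so
shared exonic bases are not double-counted).
"""

from __future__ import annotations

from collections import defaultdict
from typing import IO, Iterable, Sequence

from .io.gff3 import GeneFeature
from .model import (
    AssemblyInfo,
    RankedAlignment,
    SyntopyError,
    ValidationError,
)

__all__ = [
    "genome_coverage",
    "cds_coverage",
    "coverage_report",
    "merge_intervals",
]


class UndefinedCoverageError(SyntopyError):
    """Coverage denominator is empty (e.g. no CDS intervals)."""


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals as a sorted, disjoint list."""
    merged: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            if end > merged[-1][1]:
                merged[-1] = (merged[-1][0], end)
        else:
            merged.append((start, end))
    return merged


def _intersect_length(
    a: Sequence[tuple[int, int]], b: Sequence[tuple[int, int]]
) -> int:
    """Total overlap of two sorted disjoint interval lists."""
    total = 0
    i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if lo < hi:
            total += hi - lo
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return total


def _target_block_union(
    ranked: Iterable[RankedAlignment],
    t_info: AssemblyInfo | None,
    reciprocity_filter: Iterable[int] | None,
) -> dict[str, list[tuple[int, int]]]:
    wanted = set(reciprocity_filter) if reciprocity_filter is not None else None
    per_seq: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for ra in ranked:
        if wanted is not None and ra.reciprocity not in wanted:
            continue
        seg = ra.segment
        if t_info is not None and seg.target.seq_id not in t_info:
            raise ValidationError(
                f"alignment references unknown target sequence {seg.target.seq_id!r}"
            )
        for b in seg.blocks:
            per_seq[seg.target.seq_id].append((b.t_start, b.t_end))
    return {sid: merge_intervals(iv) for sid, iv in per_seq.items()}


def genome_coverage(
    ranked: Iterable[RankedAlignment],
    t_info: AssemblyInfo,
    reciprocity_filter: Iterable[int] | None = None,
) -> float:
    """Percent of target genome nucleotides covered by ungapped blocks.

    ``reciprocity_filter``: e.g. ``{3}`` for the reciprocal-best set only;
    None counts every alignment.
    """
    union = _target_block_union(ranked, t_info, reciprocity_filter)
    covered = sum(
        sum(e - s for s, e in iv) for iv in union.values()
    )
    total = t_info.total_length()
    if total <= 0:
        raise UndefinedCoverageError("target assembly has zero length")
    return 100.0 * covered / total


def cds_coverage(
    ranked: Iterable[RankedAlignment],
    genes: Sequence[GeneFeature],
    t_info: AssemblyInfo | None = None,
    reciprocity_filter: Iterable[int] | None = None,
) -> float:
    """Percent of CDS nucleotides (union over isoforms) covered by blocks."""
    cds_by_seq: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for g in genes:
        for r in g.cds_ranges:
            cds_by_seq[r.seq_id].append((r.start, r.end))
    cds_union = {sid: merge_intervals(iv) for sid, iv in cds_by_seq.items()}
    denom = sum(sum(e - s for s, e in iv) for iv in cds_union.values())
    if denom == 0:
        raise UndefinedCoverageError("no CDS intervals: coverage undefined")
    blocks = _target_block_union(ranked, t_info, reciprocity_filter)
    num = sum(
        _intersect_length(blocks.get(sid, []), iv) for sid, iv in cds_union.items()
    )
    return 100.0 * num / denom


def coverage_report(
    ranked: Sequence[RankedAlignment],
    t_info: AssemblyInfo,
    stream: IO[str],
    genes: Sequence[GeneFeature] | None = None,
    mash_distance: float | None = None,
    q_assembly: str = "",
    t_assembly: str = "",
) -> None:
    """TSV coverage report: one row per reciprocity filter."""
    stream.write(
        "query_assembly\ttarget_assembly\tmash_distance\treciprocity_filter\t"
        "genome_coverage_pct\tcds_coverage_pct\n"
    )
    for label, flt in (("all", None), ("best_placed", {3})):
        g_cov = genome_coverage(ranked, t_info, flt)
        if genes:
            c_cov = f"{cds_coverage(ranked, genes, t_info, flt):.4f}"
        else:
            c_cov = "NA"
        d = f"{mash_distance:.4f}" if mash_distance is not None else "NA"
        stream.write(
            f"{q_assembly}\t{t_assembly}\t{d}\t{label}\t{g_cov:.4f}\t{c_cov}\n"
        )
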