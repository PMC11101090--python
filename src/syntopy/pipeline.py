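"""Second-phase alignment processing: merge, split, rank, reciprocity.

The pipeline turns raw assembly-assembly alignments (from any aligner) into
ranked reciprocal-best / non-best sets:

1. ``merge_adjacent``  — stitch collinear neighbours with small gaps and no
   conflicting alignment in between;
2. ``split_on_gaps``   — break alignments at large internal gaps
   (>= min(absolute threshold, 5% of the alignment length));
3. ``split_at_overlaps`` — cut alignments wherever they intersect other
   alignments, so overlapping ranges become range-identical;
4. ``drop_contained``  — remove duplicates fully contained in higher-ranked
   alignments;
5. ``rank_sort``       — order by assembly level (chromosome placements
   first), identity, length;
6. ``assign_reciprocity`` — two scans (query ranges, then target ranges)
   classify alignments as reciprocal best (3) or one-sided best (1: query
   side, 2: target side); best-on-neither alignments are discarded;
7. ``remerge``         — stitch adjacent alignments back together within
   each reciprocity class.

Statistics of merged alignments are summed, never recomputed from sequence
(phase two has no sequence access); statistics of split alignments are
apportioned proportionally to aligned length, conserving matched-base totals
exactly.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from collections import defaultdict
from dataclasses import replace
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .model import (
    AlignmentBlock,
    AlignmentSegment,
    AssemblyInfo,
    CHROMOSOME,
    FORWARD,
    ProcessingParams,
    RankedAlignment,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "merge_adjacent",
    "split_on_gaps",
    "split_at_overlaps",
    "drop_contained",
    "rank_sort",
    "assign_reciprocity",
    "remerge",
    "process",
    "cut_at_query",
    "rank_key",
]


# ---------------------------------------------------------------------------
# cutting machinery


def _make_children(
    seg: AlignmentSegment, groups: Sequence[Sequence[AlignmentBlock]]
) -> list[AlignmentSegment]:
    """Build child segments from block groups, apportioning statistics.

    Mismatches are distributed proportionally to aligned length with
    cumulative rounding so totals are conserved exactly; gap statistics are
    recomputed from the junctions each child retains.
    """
    groups = [g for g in groups if g]
    if len(groups) == 1:
        blocks = tuple(groups[0])
        if blocks == seg.blocks:
            return [seg]
    aligned_total = seg.matches + seg.mismatches
    children: list[AlignmentSegment] = []
    acc_aligned = 0
    acc_mm = 0
    for g in groups:
        a = sum(b.length for b in g)
        acc_aligned += a
        target_mm = round(seg.mismatches * acc_aligned / aligned_total)
        mm_i = min(max(target_mm - acc_mm, 0), a)
        acc_mm += mm_i
        children.append(
            AlignmentSegment.build(
                seg.query.seq_id,
                seg.target.seq_id,
                seg.orientation,
                g,
                mismatches=mm_i,
                q_assembly=seg.query.assembly_id,
                t_assembly=seg.target.assembly_id,
                source_id=seg.source_id,
            )
        )
    # clamp slack (pathological rounding): push any remainder onto the last child
    deficit = seg.mismatches - acc_mm
    if deficit:
        last = children[-1]
        mm = last.mismatches + deficit
        children[-1] = replace(last, mismatches=mm, matches=last.aligned_length - mm)
    return children


def _split_blocks_at_query(
    blocks: Sequence[AlignmentBlock], orientation: str, pos: int
) -> tuple[list[AlignmentBlock], list[AlignmentBlock]]:
    left: list[AlignmentBlock] = []
    right: list[AlignmentBlock] = []
    for b in blocks:
        if b.q_end <= pos:
            left.append(b)
        elif b.q_start >= pos:
            right.append(b)
        else:
            l1 = pos - b.q_start
            if orientation == FORWARD:
                left.append(AlignmentBlock(b.q_start, b.t_start, l1))
                right.append(AlignmentBlock(pos, b.t_start + l1, b.length - l1))
            else:
                left.append(AlignmentBlock(b.q_start, b.t_start + b.length - l1, l1))
                right.append(AlignmentBlock(pos, b.t_start, b.length - l1))
    return left, right


def cut_at_query(
    seg: AlignmentSegment, positions: Iterable[int]
) -> list[AlignmentSegment]:
    """Cut a segment at query positions (those strictly inside its span)."""
    cuts = sorted(
        {p for p in positions if seg.query.start < p < seg.query.end}
    )
    if not cuts:
        return [seg]
    groups: list[list[AlignmentBlock]] = []
    remaining = list(seg.blocks)
    for pos in cuts:
        left, remaining = _split_blocks_at_query(remaining, seg.orientation, pos)
        groups.append(left)
    groups.append(remaining)
    return _make_children(seg, groups)


def _query_cut_for_target(seg: AlignmentSegment, p: int) -> int:
    """Query position c such that query < c exactly maps to the target side
    of ``p`` that precedes it in query order."""
    if seg.orientation == FORWARD:
        for b in seg.blocks:
            if p <= b.t_start:
                return b.q_start
            if p < b.t_end:
                return b.q_start + (p - b.t_start)
        return seg.query.end
    for b in seg.blocks:  # query order; target descends
        if p >= b.t_end:
            return b.q_start
        if p > b.t_start:
            return b.q_start + (b.t_end - p)
    return seg.query.end


def cut_at_target(
    seg: AlignmentSegment, positions: Iterable[int]
) -> list[AlignmentSegment]:
    """Cut a segment at target positions (those strictly inside its span)."""
    qcuts = [
        _query_cut_for_target(seg, p)
        for p in positions
        if seg.target.start < p < seg.target.end
    ]
    return cut_at_query(seg, qcuts)


# ---------------------------------------------------------------------------
# stage 1/7: merging


def _canonical(segments: Iterable[AlignmentSegment]) -> list[AlignmentSegment]:
    return sorted(
        segments,
        key=lambda s: (
            s.query.seq_id,
            s.query.start,
            s.query.end,
            s.target.seq_id,
            s.target.start,
            s.target.end,
            s.orientation,
            -s.matches,
        ),
    )


def _try_merge(
    a: AlignmentSegment,
    b: AlignmentSegment,
    all_segments: Sequence[AlignmentSegment],
    max_gap: int,
) -> AlignmentSegment | None:
    """Merge b onto a (a earlier on the query) if the adjacency rule allows."""
    if (
        a.query.seq_id != b.query.seq_id
        or a.target.seq_id != b.target.seq_id
        or a.orientation != b.orientation
        or a.query.assembly_id != b.query.assembly_id
        or a.target.assembly_id != b.target.assembly_id
    ):
        return None
    q_gap = b.query.start - a.query.end
    if q_gap < 0 or q_gap > max_gap:
        return None
    if a.orientation == FORWARD:
        t_gap = b.target.start - a.target.end
        t_lo, t_hi = a.target.end, b.target.start
    else:
        t_gap = a.target.start - b.target.end
        t_lo, t_hi = b.target.end, a.target.start
    if t_gap < 0 or t_gap > max_gap:
        return None
    # conflict check: no third alignment touches either intervening interval
    for other in all_segments:
        if other is a or other is b:
            continue
        if (
            q_gap > 0
            and other.query.seq_id == a.query.seq_id
            and other.query.start < b.query.start
            and other.query.end > a.query.end
        ):
            return None
        if (
            t_gap > 0
            and other.target.seq_id == a.target.seq_id
            and other.target.start < t_hi
            and other.target.end > t_lo
        ):
            return None
    return AlignmentSegment.build(
        a.query.seq_id,
        a.target.seq_id,
        a.orientation,
        a.blocks + b.blocks,
        matches=a.matches + b.matches,
        mismatches=a.mismatches + b.mismatches,
        gap_count=a.gap_count + b.gap_count + (q_gap > 0) + (t_gap > 0),
        gap_bases=a.gap_bases + b.gap_bases + q_gap + t_gap,
        q_assembly=a.query.assembly_id,
        t_assembly=a.target.assembly_id,
        source_id=a.source_id,
    )


def merge_adjacent(
    segments: Iterable[AlignmentSegment], params: ProcessingParams | None = None
) -> list[AlignmentSegment]:
    """Merge collinear adjacent alignments with no conflicting alignments.

    Two alignments merge iff they share the sequence pair and orientation,
    are collinear (query order matches target order under the orientation),
    both intervening gaps are <= ``merge_max_gap``, and no third alignment
    overlaps either intervening interval.  Applied transitively to fixpoint.
    """
    params = params or ProcessingParams.same_or_close()
    segs = _canonical(segments)
    changed = True
    while changed:
        changed = False
        groups: dict[tuple, list[int]] = defaultdict(list)
        for i, s in enumerate(segs):
            groups[(s.query.seq_id, s.target.seq_id, s.orientation)].append(i)
        merged_away: set[int] = set()
        replacements: dict[int, AlignmentSegment] = {}
        for idxs in groups.values():
            idxs.sort(key=lambda i: segs[i].query.start)
            j = 0
            while j < len(idxs) - 1:
                ia, ib = idxs[j], idxs[j + 1]
                if ia in merged_away or ib in merged_away:
                    j += 1
                    continue
                a = replacements.get(ia, segs[ia])
                b = replacements.get(ib, segs[ib])
                m = _try_merge(a, b, segs, params.merge_max_gap)
                if m is not None:
                    replacements[ia] = m
                    merged_away.add(ib)
                    changed = True
                    idxs.pop(j + 1)
                else:
                    j += 1
        if changed:
            segs = _canonical(
                replacements.get(i, s)
                for i, s in enumerate(segs)
                if i not in merged_away
            )
    return segs


# ---------------------------------------------------------------------------
# stage 2: gap splitting


def split_on_gaps(
    seg: AlignmentSegment, params: ProcessingParams
) -> list[AlignmentSegment]:
    """Split an alignment at junctions whose gap reaches the threshold.

    The gap at a junction is max(query-side, target-side); the threshold is
    min(absolute bp threshold, fractional threshold x pre-split alignment
    length).  Matched-base totals are conserved across the children.
    """
    threshold = params.split_threshold(seg.length)
    groups: list[list[AlignmentBlock]] = [[seg.blocks[0]]]
    for (q_gap, t_gap), blk in zip(seg.junction_gaps(), seg.blocks[1:]):
        if max(q_gap, t_gap) >= threshold:
            groups.append([blk])
        else:
            groups[-1].append(blk)
    return _make_children(seg, groups)


# ---------------------------------------------------------------------------
# stage 3: overlap splitting


def split_at_overlaps(
    segments: Iterable[AlignmentSegment],
) -> list[AlignmentSegment]:
    """Cut alignments at the boundaries of alignments overlapping them.

    Iterates to fixpoint so that afterwards, on either axis, any two
    alignments are range-identical or range-disjoint.  Cut points falling
    between blocks split at the junction; points inside a block bisect it.
    """
    segs = _canonical(segments)
    changed = True
    while changed:
        changed = False
        q_points: dict[str, list[int]] = defaultdict(list)
        t_points: dict[str, list[int]] = defaultdict(list)
        for s in segs:
            q_points[s.query.seq_id].extend((s.query.start, s.query.end))
            t_points[s.target.seq_id].extend((s.target.start, s.target.end))
        for k in q_points:
            q_points[k] = sorted(set(q_points[k]))
        for k in t_points:
            t_points[k] = sorted(set(t_points[k]))

        out: list[AlignmentSegment] = []
        for s in segs:
            qp = q_points[s.query.seq_id]
            tp = t_points[s.target.seq_id]
            q_cuts = qp[
                bisect_right(qp, s.query.start) : bisect_left(qp, s.query.end)
            ]
            t_cuts = tp[
                bisect_right(tp, s.target.start) : bisect_left(tp, s.target.end)
            ]
            pieces = [s]
            if q_cuts or t_cuts:
                all_q = list(q_cuts) + [
                    _query_cut_for_target(s, p) for p in t_cuts
                ]
                pieces = cut_at_query(s, all_q)
                if len(pieces) > 1:
                    changed = True
            out.extend(pieces)
        segs = out
    return _canonical(segs)


# ---------------------------------------------------------------------------
# stage 4/5: ranking and containment


def rank_key(
    seg: AlignmentSegment,
    q_info: AssemblyInfo | None = None,
    t_info: AssemblyInfo | None = None,
) -> tuple:
    """Sort key: chromosome placements first, then identity, then length,
    then coordinates as a deterministic tie-break.  Lower sorts first."""
    q_chrom = 1 if q_info is None else int(q_info.role_of(seg.query.seq_id) == CHROMOSOME)
    t_chrom = 1 if t_info is None else int(t_info.role_of(seg.target.seq_id) == CHROMOSOME)
    return (
        -(q_chrom + t_chrom),
        -seg.percent_identity,
        -seg.length,
        seg.query.seq_id,
        seg.query.start,
        seg.target.seq_id,
        seg.target.start,
    )


def rank_sort(
    segments: Iterable[AlignmentSegment],
    q_info: AssemblyInfo | None = None,
    t_info: AssemblyInfo | None = None,
) -> list[AlignmentSegment]:
    """Order alignments best-first by the ranking key."""
    return sorted(segments, key=lambda s: rank_key(s, q_info, t_info))


def drop_contained(
    segments: Iterable[AlignmentSegment],
    q_info: AssemblyInfo | None = None,
    t_info: AssemblyInfo | None = None,
) -> list[AlignmentSegment]:
    """Drop alignments contained on both axes within one higher-ranked
    alignment of the same orientation; exact duplicates keep the first
    representative in rank order."""
    ranked = rank_sort(segments, q_info, t_info)
    keys = [rank_key(s, q_info, t_info) for s in ranked]
    kept: list[AlignmentSegment] = []
    kept_keys: list[tuple] = []
    for s, k in zip(ranked, keys):
        dropped = False
        for a, ka in zip(kept, kept_keys):
            if (
                a.orientation == s.orientation
                and a.query.contains(s.query)
                and a.target.contains(s.target)
            ):
                identical = a.query == s.query and a.target == s.target
                if ka < k or identical:
                    dropped = True
                    break
        if not dropped:
            kept.append(s)
            kept_keys.append(k)
    return _canonical(kept)


# ---------------------------------------------------------------------------
# stage 6: reciprocity scans


def assign_reciprocity(
    sorted_segments: Sequence[AlignmentSegment],
    q_info: AssemblyInfo | None = None,
    t_info: AssemblyInfo | None = None,
    stats: dict | None = None,
) -> list[RankedAlignment]:
    """Two scans over rank-ordered alignments.

    Scan 1 marks an alignment query-best iff no higher-ranked alignment
    overlaps it on the query; scan 2 does the same on the target.
    reciprocity = 3 (best on both), 1 (query side only), 2 (target side
    only); alignments best on neither are discarded (count logged).
    """
    q_seen: dict[str, IntervalTree] = defaultdict(IntervalTree)
    t_seen: dict[str, IntervalTree] = defaultdict(IntervalTree)
    out: list[RankedAlignment] = []
    discarded = 0
    for seg in sorted_segments:
        q_best = not q_seen[seg.query.seq_id].overlaps(
            seg.query.start, seg.query.end
        )
        t_best = not t_seen[seg.target.seq_id].overlaps(
            seg.target.start, seg.target.end
        )
        q_seen[seg.query.seq_id].addi(seg.query.start, seg.query.end)
        t_seen[seg.target.seq_id].addi(seg.target.start, seg.target.end)
        if q_best and t_best:
            rec = 3
        elif q_best:
            rec = 1
        elif t_best:
            rec = 2
        else:
            discarded += 1
            continue
        out.append(
            RankedAlignment(
                segment=seg, reciprocity=rec, rank_key=rank_key(seg, q_info, t_info)
            )
        )
    if discarded:
        logger.info("reciprocity scans discarded %d best-on-neither segment(s)", discarded)
    if stats is not None:
        stats["discarded_non_best"] = discarded
    return out


# ---------------------------------------------------------------------------
# stage 7: per-reciprocity re-merge


def remerge(
    ranked: Iterable[RankedAlignment],
    params: ProcessingParams | None = None,
    q_info: AssemblyInfo | None = None,
    t_info: AssemblyInfo | None = None,
) -> list[RankedAlignment]:
    """Merge adjacent alignments again, independently per reciprocity class."""
    params = params or ProcessingParams.same_or_close()
    by_class: dict[int, list[AlignmentSegment]] = defaultdict(list)
    for ra in ranked:
        by_class[ra.reciprocity].append(ra.segment)
    out: list[RankedAlignment] = []
    for rec in sorted(by_class, reverse=True):
        for seg in merge_adjacent(by_class[rec], params):
            out.append(
                RankedAlignment(
                    segment=seg, reciprocity=rec, rank_key=rank_key(seg, q_info, t_info)
                )
            )
    return out


# ---------------------------------------------------------------------------
# the full pipeline


def _validate_inputs(
    segments: Sequence[AlignmentSegment],
    q_info: AssemblyInfo,
    t_info: AssemblyInfo,
) -> None:
    unknown: list[str] = []
    for s in segments:
        if s.query.seq_id not in q_info:
            unknown.append(f"query {s.query.seq_id!r}")
        elif s.query.end > q_info.length_of(s.query.seq_id):
            unknown.append(f"query {s.query.seq_id!r} (range past end)")
        if s.target.seq_id not in t_info:
            unknown.append(f"target {s.target.seq_id!r}")
        elif s.target.end > t_info.length_of(s.target.seq_id):
            unknown.append(f"target {s.target.seq_id!r} (range past end)")
    if unknown:
        uniq = sorted(set(unknown))
        raise ValidationError(
            "alignments reference unknown or overflowed sequences: "
            + ", ".join(uniq)
        )


def process(
    raw: Iterable[AlignmentSegment],
    q_info: AssemblyInfo | None = None,
    t_info: AssemblyInfo | None = None,
    params: ProcessingParams | None = None,
    stats: dict | None = None,
) -> list[RankedAlignment]:
    """Run the full second-phase pipeline; deterministic for any input order."""
    params = params or ProcessingParams.same_or_close()
    if stats is None:
        stats = {}
    segs = _canonical(raw)
    if q_info is not None and t_info is not None:
        _validate_inputs(segs, q_info, t_info)
    stats["input"] = len(segs)
    segs = merge_adjacent(segs, params)
    stats["after_merge"] = len(segs)
    segs = [child for s in segs for child in split_on_gaps(s, params)]
    stats["after_gap_split"] = len(segs)
    segs = split_at_overlaps(segs)
    stats["after_overlap_split"] = len(segs)
    segs = drop_contained(segs, q_info, t_info)
    stats["after_drop_contained"] = len(segs)
    ordered = rank_sort(segs, q_info, t_info)
    ranked = assign_reciprocity(ordered, q_info, t_info, stats=stats)
    stats["after_reciprocity"] = len(ranked)
    ranked = remerge(ranked, params, q_info, t_info)
    stats["output"] = len(ranked)
    for stage in (
        "input",
        "after_merge",
        "after_gap_split",
        "after_overlap_split",
        "after_drop_contained",
        "after_reciprocity",
        "output",
    ):
        logger.info("%-20s %d segments", stage, stats[stage])
    return sorted(
        ranked,
        key=lambda ra: (
            -ra.reciprocity,
            ra.segment.query.seq_id,
            ra.segment.query.start,
            ra.segment.target.seq_id,
            ra.segment.target.start,
        ),
    )
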