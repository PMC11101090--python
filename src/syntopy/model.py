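"""Core data model for pairwise whole-genome alignment processing.

Coordinate convention
---------------------
All coordinates are 0-based, half-open, and expressed on the forward strand
of both sequences.  Strandedness lives in a segment-level ``orientation``
flag.  For a reverse-orientation segment the target range is still stored in
forward coordinates; the block list is ordered by ascending query position,
which for reverse segments means descending target position.  Formats that
count reverse-strand coordinates from the sequence end (UCSC chain) or use
1-based closed coordinates (BLAST tabular, GFF3) are normalized at the I/O
boundary only.

Percent identity uses the alignment-column denominator::

    identity = 100 * matches / (matches + mismatches + gap_bases)

i.e. gapped columns count against identity.  This is the convention used
everywhere identity is reported (info panel, GFF3 score, ranking).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Literal, Sequence

__all__ = [
    "FORWARD",
    "REVERSE",
    "CHROMOSOME",
    "UNPLACED",
    "SeqRange",
    "AlignmentBlock",
    "AlignmentSegment",
    "RankedAlignment",
    "AssemblyInfo",
    "ProcessingParams",
    "SyntopyError",
    "ParseError",
    "ValidationError",
    "NoOverlapError",
    "InvalidSegmentError",
    "project",
    "percent_identity",
]

FORWARD: Literal["forward"] = "forward"
REVERSE: Literal["reverse"] = "reverse"

CHROMOSOME = "chromosome"
UNPLACED = "unplaced_scaffold"


class SyntopyError(Exception):
    """Base class for all package errors."""


class ParseError(SyntopyError):
    """Malformed input; carries a line number or record id when known."""


class ValidationError(SyntopyError):
    """Input violates a model invariant (bad range, unknown sequence...)."""


class NoOverlapError(SyntopyError):
    """Projection requested for an interval disjoint from the alignment."""


class InvalidSegmentError(SyntopyError):
    """Segment statistics are degenerate (e.g. zero-length alignment)."""


@dataclass(frozen=True, order=True)
class SeqRange:
    """Half-open interval ``[start, end)`` on a named sequence."""

    seq_id: str
    start: int
    end: int
    assembly_id: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid range [{self.start}, {self.end}) on {self.seq_id!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "SeqRange") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "SeqRange") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class AlignmentBlock:
    """Ungapped run of aligned bases; the unit of coverage statistics.

    ``q_start`` and ``t_start`` are absolute forward-strand offsets.  Within
    a forward segment query and target advance together; within a reverse
    segment query position ``q_start + i`` pairs with target position
    ``t_start + length - 1 - i``.
    """

    q_start: int
    t_start: int
    length: int

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValidationError(f"block length must be positive, got {self.length}")

    @property
    def q_end(self) -> int:
        return self.q_start + self.length

    @property
    def t_end(self) -> int:
        return self.t_start + self.length


@dataclass(frozen=True)
class AlignmentSegment:
    """One pairwise alignment between a query range and a target range."""

    query: SeqRange
    target: SeqRange
    orientation: str
    blocks: tuple[AlignmentBlock, ...]
    matches: int
    mismatches: int = 0
    gap_count: int = 0
    gap_bases: int = 0
    source_id: str = ""

    # -- construction -----------------------------------------------------

    @classmethod
    def build(
        cls,
        q_seq: str,
        t_seq: str,
        orientation: str,
        blocks: Iterable[AlignmentBlock | tuple[int, int, int]],
        matches: int | None = None,
        mismatches: int = 0,
        gap_count: int | None = None,
        gap_bases: int | None = None,
        q_assembly: str = "",
        t_assembly: str = "",
        source_id: str = "",
    ) -> "AlignmentSegment":
        """Build a segment from blocks, deriving envelopes and defaults.

        ``matches`` defaults to aligned length minus ``mismatches``; gap
        statistics default to what the junctions between blocks imply.
        """
        blk = tuple(
            b if isinstance(b, AlignmentBlock) else AlignmentBlock(*b) for b in blocks
        )
        if not blk:
            raise InvalidSegmentError("segment needs at least one block")
        if orientation not in (FORWARD, REVERSE):
            raise ValidationError(f"bad orientation {orientation!r}")
        q_range = SeqRange(q_seq, blk[0].q_start, blk[-1].q_end, q_assembly)
        if orientation == FORWARD:
            t_range = SeqRange(t_seq, blk[0].t_start, blk[-1].t_end, t_assembly)
        else:
            t_range = SeqRange(t_seq, blk[-1].t_start, blk[0].t_end, t_assembly)
        aligned = sum(b.length for b in blk)
        if matches is None:
            matches = aligned - mismatches
        seg = cls(
            query=q_range,
            target=t_range,
            orientation=orientation,
            blocks=blk,
            matches=matches,
            mismatches=mismatches,
            gap_count=0,
            gap_bases=0,
            source_id=source_id,
        )
        gaps = seg.junction_gaps()
        if gap_count is None:
            gap_count = sum((qg > 0) + (tg > 0) for qg, tg in gaps)
        if gap_bases is None:
            gap_bases = sum(qg + tg for qg, tg in gaps)
        seg = replace(seg, gap_count=gap_count, gap_bases=gap_bases)
        seg.validate()
        return seg

    # -- derived quantities ----------------------------------------------

    @property
    def length(self) -> int:
        """Alignment length as reported to users: the query span."""
        return self.query.length

    @property
    def aligned_length(self) -> int:
        return self.matches + self.mismatches

    @property
    def percent_identity(self) -> float:
        denom = self.matches + self.mismatches + self.gap_bases
        if denom <= 0:
            raise InvalidSegmentError("zero-length alignment has no identity")
        return 100.0 * self.matches / denom

    def junction_gaps(self) -> list[tuple[int, int]]:
        """(query-side, target-side) unaligned bases between consecutive blocks."""
        out: list[tuple[int, int]] = []
        for a, b in zip(self.blocks, self.blocks[1:]):
            q_gap = b.q_start - a.q_end
            if self.orientation == FORWARD:
                t_gap = b.t_start - a.t_end
            else:
                t_gap = a.t_start - b.t_end
            out.append((q_gap, t_gap))
        return out

    def validate(self) -> None:
        """Check structural invariants; raise :class:`ValidationError`."""
        blk = self.blocks
        if not blk:
            raise ValidationError("segment has no blocks")
        if self.query.start != blk[0].q_start or self.query.end != blk[-1].q_end:
            raise ValidationError("query range does not match block envelope")
        if self.orientation == FORWARD:
            t_lo, t_hi = blk[0].t_start, blk[-1].t_end
        else:
            t_lo, t_hi = blk[-1].t_start, blk[0].t_end
        if self.target.start != t_lo or self.target.end != t_hi:
            raise ValidationError("target range does not match block envelope")
        for q_gap, t_gap in self.junction_gaps():
            if q_gap < 0 or t_gap < 0:
                raise ValidationError("blocks overlap or are out of order")
        if self.matches + self.mismatches != sum(b.length for b in blk):
            raise ValidationError("matches + mismatches != aligned block length")
        if min(self.matches, self.mismatches, self.gap_count, self.gap_bases) < 0:
            raise ValidationError("negative alignment statistic")

    # -- coordinate mapping ----------------------------------------------

    def block_target_interval(self, block: AlignmentBlock) -> tuple[int, int]:
        return block.t_start, block.t_end

    def q_to_t(self, q_pos: int) -> int | None:
        """Target position aligned to query position, or None if in a gap."""
        for b in self.blocks:
            if b.q_start <= q_pos < b.q_end:
                off = q_pos - b.q_start
                if self.orientation == FORWARD:
                    return b.t_start + off
                return b.t_start + b.length - 1 - off
        return None

    def iter_base_pairs(self) -> Iterator[tuple[int, int]]:
        """Yield (query position, target position) for every aligned base."""
        for b in self.blocks:
            if self.orientation == FORWARD:
                for i in range(b.length):
                    yield b.q_start + i, b.t_start + i
            else:
                for i in range(b.length):
                    yield b.q_start + i, b.t_start + b.length - 1 - i


def project(segment: AlignmentSegment, q_interval: SeqRange) -> SeqRange:
    """Project a query interval through a segment onto the target.

    Returns the envelope of target positions aligned to ``q_interval``;
    target-side gap bases spanned by the projected interval are included.
    Reverse-orientation results are in forward target coordinates.
    """
    if q_interval.seq_id != segment.query.seq_id or not q_interval.overlaps(
        segment.query
    ):
        raise NoOverlapError(
            f"interval {q_interval.seq_id}:[{q_interval.start},{q_interval.end}) "
            f"does not overlap alignment query range"
        )
    t_lo: int | None = None
    t_hi: int | None = None
    for b in segment.blocks:
        lo = max(b.q_start, q_interval.start)
        hi = min(b.q_end, q_interval.end)
        if lo >= hi:
            continue
        if segment.orientation == FORWARD:
            blo = b.t_start + (lo - b.q_start)
            bhi = b.t_start + (hi - b.q_start)
        else:
            bhi = b.t_start + b.length - (lo - b.q_start)
            blo = b.t_start + b.length - (hi - b.q_start)
        t_lo = blo if t_lo is None else min(t_lo, blo)
        t_hi = bhi if t_hi is None else max(t_hi, bhi)
    if t_lo is None:
        # interval overlaps the query span but falls wholly in a query gap
        raise NoOverlapError("interval lies entirely within an alignment gap")
    return SeqRange(
        segment.target.seq_id, t_lo, t_hi, segment.target.assembly_id
    )


def percent_identity(segment: AlignmentSegment) -> float:
    """Percent identity = 100 * matches / (matches + mismatches + gap_bases)."""
    return segment.percent_identity


@dataclass(frozen=True)
class RankedAlignment:
    """An alignment plus its placement rank and reciprocity code.

    reciprocity 3 = reciprocal best (best placement on both assemblies,
    the "first pass" set); 1 = best on the query side only; 2 = best on the
    target side only (the "second pass" sets).
    """

    segment: AlignmentSegment
    reciprocity: int
    rank_key: tuple = ()

    def __post_init__(self) -> None:
        if self.reciprocity not in (1, 2, 3):
            raise ValidationError(f"bad reciprocity {self.reciprocity}")


@dataclass
class AssemblyInfo:
    """Sequence catalogue of one assembly: ids, lengths, chromosome roles."""

    assembly_id: str
    name: str = ""
    sequences: list[tuple[str, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._index: dict[str, tuple[int, str]] = {}
        for seq_id, length, role in self.sequences:
            if seq_id in self._index:
                raise ValidationError(f"duplicate sequence id {seq_id!r}")
            if role not in (CHROMOSOME, UNPLACED):
                raise ValidationError(f"bad role {role!r} for {seq_id!r}")
            self._index[seq_id] = (int(length), role)

    @classmethod
    def from_lengths(
        cls,
        assembly_id: str,
        lengths: dict[str, int],
        roles: dict[str, str] | None = None,
        name: str = "",
    ) -> "AssemblyInfo":
        roles = roles or {}
        seqs = [
            (sid, int(ln), roles.get(sid, CHROMOSOME)) for sid, ln in lengths.items()
        ]
        return cls(assembly_id=assembly_id, name=name, sequences=seqs)

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._index

    def seq_ids(self) -> list[str]:
        return [s for s, _, _ in self.sequences]

    def length_of(self, seq_id: str) -> int:
        try:
            return self._index[seq_id][0]
        except KeyError:
            raise ValidationError(f"unknown sequence {seq_id!r}") from None

    def role_of(self, seq_id: str) -> str:
        try:
            return self._index[seq_id][1]
        except KeyError:
            raise ValidationError(f"unknown sequence {seq_id!r}") from None

    def total_length(self) -> int:
        return sum(ln for _, ln, _ in self.sequences)


SAME_OR_CLOSE = "same_or_close"
DISTANT = "distant"

#: gap-split absolute thresholds by species proximity mode (bases)
_GAP_SPLIT_BP = {SAME_OR_CLOSE: 50, DISTANT: 50_000}


@dataclass(frozen=True)
class ProcessingParams:
    """Second-phase thresholds.

    ``gap_split_bp``: absolute gap threshold — 50 bp for the same or closer
    species, 50 kb for more distant species.  ``gap_split_frac``: fractional
    threshold, 5% of the alignment length.  The effective split threshold at
    a junction is ``min(gap_split_bp, gap_split_frac * alignment_length)``.
    ``merge_max_gap`` defaults to ``gap_split_bp`` so that merging and
    splitting are mutually consistent.
    """

    species_mode: str = SAME_OR_CLOSE
    gap_split_bp: int = 50
    gap_split_frac: float = 0.05
    merge_max_gap: int | None = None

    def __post_init__(self) -> None:
        if self.species_mode not in (SAME_OR_CLOSE, DISTANT):
            raise ValidationError(f"bad species mode {self.species_mode!r}")
        if self.gap_split_bp <= 0:
            raise ValidationError("gap_split_bp must be positive")
        if not (0.0 < self.gap_split_frac < 1.0):
            raise ValidationError("gap_split_frac must be in (0, 1)")
        if self.merge_max_gap is None:
            object.__setattr__(self, "merge_max_gap", self.gap_split_bp)

    @classmethod
    def for_mode(cls, species_mode: str, **overrides) -> "ProcessingParams":
        if species_mode not in _GAP_SPLIT_BP:
            raise ValidationError(f"bad species mode {species_mode!r}")
        kw = dict(species_mode=species_mode, gap_split_bp=_GAP_SPLIT_BP[species_mode])
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def same_or_close(cls, **overrides) -> "ProcessingParams":
        return cls.for_mode(SAME_OR_CLOSE, **overrides)

    @classmethod
    def distant(cls, **overrides) -> "ProcessingParams":
        return cls.for_mode(DISTANT, **overrides)

    def split_threshold(self, alignment_length: int) -> float:
        """Effective gap-split threshold for an alignment of this length."""
        return min(self.gap_split_bp, self.gap_split_frac * alignment_length)
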