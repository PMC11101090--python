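"""Simulated genome pairs with planted rearrangements and ground truth.

The generator copies a random query genome into a target genome through a
set of planned structural events (inversion, translocation, duplication,
within-chromosome scramble, deletion) plus point mutations and small indels,
and records the exact orthologous mapping as ground-truth alignment
segments.  ``fragment_alignments`` then degrades the truth into the kind of
raw, redundant, shuffled segment soup an aligner produces, which the
second-phase pipeline must clean up.

Base composition is uniform and event placement is user-specified; repeats,
GC structure and realistic molecular evolution are deliberately out of
scope — the second phase never reads sequence, only segment geometry.
Everything is reproducible from the plan seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import IO, Sequence

import numpy as np

from .model import (
    AlignmentBlock,
    AlignmentSegment,
    AssemblyInfo,
    FORWARD,
    REVERSE,
    ValidationError,
)
from .pipeline import cut_at_query

__all__ = [
    "RearrangementEvent",
    "RearrangementPlan",
    "SimulatedPair",
    "simulate_pair",
    "fragment_alignments",
    "standard_plan",
    "recovered_fraction",
    "write_plan",
]

QUERY_ASSEMBLY = "simQ"
TARGET_ASSEMBLY = "simT"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGT", b"TGCA"):
    _COMP[_a] = _b

EVENT_KINDS = ("inversion", "translocation", "duplication", "scramble", "deletion")


@dataclass(frozen=True)
class RearrangementEvent:
    kind: str
    chrom: str
    start: int = 0
    end: int = 0
    dest_chrom: str | None = None  # translocation only
    n_tiles: int = 20  # scramble only


@dataclass(frozen=True)
class RearrangementPlan:
    seed: int = 0
    n_chromosomes: int = 5
    chromosome_length: int = 1_000_000
    snp_rate: float = 0.002
    indel_rate: float = 0.0001
    events: tuple[RearrangementEvent, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "events", tuple(self.events))

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    def validate(self) -> None:
        if not (0.0 <= self.snp_rate < 1.0 and 0.0 <= self.indel_rate < 1.0):
            raise ValidationError("mutation rates must lie in [0, 1)")
        names = set(self.chrom_names())
        claimed: dict[str, list[tuple[int, int]]] = {n: [] for n in names}
        for ev in self.events:
            if ev.kind not in EVENT_KINDS:
                raise ValidationError(f"unknown event kind {ev.kind!r}")
            if ev.chrom not in names:
                raise ValidationError(f"event on unknown chromosome {ev.chrom!r}")
            if ev.kind == "scramble":
                lo, hi = 0, self.chromosome_length
                if not (2 <= ev.n_tiles <= self.chromosome_length):
                    raise ValidationError("scramble needs 2 <= n_tiles <= length")
            else:
                lo, hi = ev.start, ev.end
                if not (0 <= lo < hi <= self.chromosome_length):
                    raise ValidationError(
                        f"{ev.kind} bounds [{lo}, {hi}) outside chromosome"
                    )
            if ev.kind == "translocation":
                if ev.dest_chrom not in names or ev.dest_chrom == ev.chrom:
                    raise ValidationError("translocation needs a distinct dest_chrom")
            for s, e in claimed[ev.chrom]:
                if lo < e and s < hi:
                    raise ValidationError(
                        f"events overlap on {ev.chrom}: [{s},{e}) vs [{lo},{hi})"
                    )
            claimed[ev.chrom].append((lo, hi))


def standard_plan(seed: int = 0) -> RearrangementPlan:
    """The reference study conditions: 5 chromosomes of 1 Mb with one
    inversion, one translocation, one duplication, and one chromosome
    scrambled into 20 tiles."""
    return RearrangementPlan(
        seed=seed,
        n_chromosomes=5,
        chromosome_length=1_000_000,
        events=(
            RearrangementEvent("inversion", "chr1", 300_000, 400_000),
            RearrangementEvent("translocation", "chr2", 500_000, 600_000, dest_chrom="chr3"),
            RearrangementEvent("duplication", "chr4", 200_000, 250_000),
            RearrangementEvent("scramble", "chr5", n_tiles=20),
        ),
    )


@dataclass
class SimulatedPair:
    query_seqs: dict[str, str]
    target_seqs: dict[str, str]
    q_info: AssemblyInfo
    t_info: AssemblyInfo
    truth: list[AlignmentSegment]
    events: tuple[RearrangementEvent, ...]

    @property
    def truth_primary(self) -> list[AlignmentSegment]:
        """Truth segments excluding the extra copies planted by duplications."""
        return [s for s in self.truth if not s.source_id.startswith("dup")]


@dataclass
class _Tile:
    chrom: str  # source (query) chromosome
    start: int
    end: int
    inverted: bool = False
    is_dup: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start


def _plan_tiles(plan: RearrangementPlan, rng: np.random.Generator) -> dict[str, list[_Tile]]:
    """Target chromosome -> ordered source tiles after all planned events."""
    by_chrom: dict[str, list[RearrangementEvent]] = {
        c: [] for c in plan.chrom_names()
    }
    for ev in plan.events:
        by_chrom[ev.chrom].append(ev)

    tiles: dict[str, list[_Tile]] = {}
    appended: dict[str, list[_Tile]] = {c: [] for c in plan.chrom_names()}
    for chrom in plan.chrom_names():
        events = sorted(
            (e for e in by_chrom[chrom] if e.kind != "scramble"),
            key=lambda e: e.start,
        )
        cuts = sorted({p for e in events for p in (e.start, e.end)})
        bounds = [0] + cuts + [plan.chromosome_length]
        row: list[_Tile] = []
        for s, e in zip(bounds, bounds[1:]):
            if s >= e:
                continue
            tile = _Tile(chrom, s, e)
            ev = next((x for x in events if x.start == s and x.end == e), None)
            if ev is None:
                row.append(tile)
            elif ev.kind == "inversion":
                row.append(replace(tile, inverted=True))
            elif ev.kind == "deletion":
                pass
            elif ev.kind == "duplication":
                row.append(tile)
                appended[chrom].append(replace(tile, is_dup=True))
            elif ev.kind == "translocation":
                appended[ev.dest_chrom].append(tile)
        tiles[chrom] = row
    for chrom in plan.chrom_names():
        tiles[chrom].extend(appended[chrom])
        scr = next((e for e in by_chrom[chrom] if e.kind == "scramble"), None)
        if scr is not None:
            tiles[chrom] = _scramble(tiles[chrom], scr.n_tiles, rng)
    return tiles


def _scramble(row: Sequence[_Tile], n_tiles: int, rng: np.random.Generator) -> list[_Tile]:
    """Split a chromosome's tiles into ~n_tiles pieces and shuffle their order."""
    total = sum(t.length for t in row)
    piece = max(1, total // n_tiles)
    out: list[_Tile] = []
    for t in row:
        s = t.start
        while t.end - s > piece * 2 - 1:
            out.append(replace(t, start=s, end=s + piece))
            s += piece
        out.append(replace(t, start=s))
    order = rng.permutation(len(out))
    return [out[i] for i in order]


def _tile_indels(
    m: int, indel_rate: float, rng: np.random.Generator
) -> list[tuple[int, int, bool]]:
    """Sampled indels as (query offset, size, is_insertion); non-overlapping."""
    k = rng.binomial(m, indel_rate)
    if k == 0 or m < 4:
        return []
    positions = np.unique(rng.integers(1, m - 1, size=k))
    out: list[tuple[int, int, bool]] = []
    cursor = 0
    for pos in positions:
        pos = int(pos)
        if pos <= cursor:
            continue
        size = int(min(1 + rng.geometric(0.5), 40))
        is_ins = bool(rng.random() < 0.5)
        if not is_ins:
            size = min(size, m - 1 - pos)
            if size <= 0:
                continue
            cursor = pos + size
        else:
            cursor = pos
        out.append((pos, size, is_ins))
    return out


def simulate_pair(plan: RearrangementPlan) -> SimulatedPair:
    """Simulate a (query, target) genome pair with ground-truth alignments."""
    plan.validate()
    rng = np.random.default_rng(plan.seed)
    L = plan.chromosome_length
    query_arr = {
        c: _BASES[rng.integers(0, 4, size=L)] for c in plan.chrom_names()
    }
    tiles = _plan_tiles(plan, rng)

    truth: list[AlignmentSegment] = []
    target_arr: dict[str, np.ndarray] = {}
    for chrom in plan.chrom_names():
        parts: list[np.ndarray] = []
        t_cursor = 0
        for idx, tile in enumerate(tiles[chrom]):
            m = tile.length
            indels = _tile_indels(m, plan.indel_rate, rng)
            # local blocks (q_off, t_off, len) on the un-inverted tile
            blocks_local: list[tuple[int, int, int]] = []
            inserts: list[tuple[int, int]] = []  # (t_off, size)
            q = t = 0
            for pos, size, is_ins in indels:
                blocks_local.append((q, t, pos - q))
                t += pos - q
                if is_ins:
                    inserts.append((t, size))
                    t += size
                    q = pos
                else:
                    q = pos + size
            blocks_local.append((q, t, m - q))
            t_len = t + (m - q)

            # build the tile's target sequence (forward sense first)
            seq = np.empty(t_len, dtype=np.uint8)
            src = query_arr[tile.chrom]
            mism = 0
            for q_off, t_off, blen in blocks_local:
                chunk = src[tile.start + q_off : tile.start + q_off + blen].copy()
                n_snp = rng.binomial(blen, plan.snp_rate)
                if n_snp:
                    sites = rng.choice(blen, size=n_snp, replace=False)
                    shift = rng.integers(1, 4, size=n_snp)
                    idx_b = np.searchsorted(_BASES, chunk[sites])
                    chunk[sites] = _BASES[(idx_b + shift) % 4]
                    mism += int(n_snp)
                seq[t_off : t_off + blen] = chunk
            for t_off, size in inserts:
                seq[t_off : t_off + size] = _BASES[rng.integers(0, 4, size=size)]
            if tile.inverted:
                seq = _COMP[seq][::-1]

            # absolute blocks, query-ascending
            abs_blocks = []
            for q_off, t_off, blen in blocks_local:
                if tile.inverted:
                    t_start = t_cursor + (t_len - (t_off + blen))
                else:
                    t_start = t_cursor + t_off
                abs_blocks.append(
                    AlignmentBlock(tile.start + q_off, t_start, blen)
                )
            tag = "dup" if tile.is_dup else "truth"
            truth.append(
                AlignmentSegment.build(
                    tile.chrom,
                    chrom,
                    REVERSE if tile.inverted else FORWARD,
                    abs_blocks,
                    mismatches=mism,
                    q_assembly=QUERY_ASSEMBLY,
                    t_assembly=TARGET_ASSEMBLY,
                    source_id=f"{tag}:{chrom}:{idx}",
                )
            )
            parts.append(seq)
            t_cursor += t_len
        target_arr[chrom] = (
            np.concatenate(parts) if parts else np.empty(0, dtype=np.uint8)
        )

    query_seqs = {c: a.tobytes().decode("ascii") for c, a in query_arr.items()}
    target_seqs = {c: a.tobytes().decode("ascii") for c, a in target_arr.items()}
    q_info = AssemblyInfo.from_lengths(
        QUERY_ASSEMBLY, {c: len(s) for c, s in query_seqs.items()}
    )
    t_info = AssemblyInfo.from_lengths(
        TARGET_ASSEMBLY, {c: len(s) for c, s in target_seqs.items()}
    )
    return SimulatedPair(
        query_seqs=query_seqs,
        target_seqs=target_seqs,
        q_info=q_info,
        t_info=t_info,
        truth=truth,
        events=plan.events,
    )


def fragment_alignments(
    truth: Sequence[AlignmentSegment],
    seed: int = 0,
    n_cuts: int = 0,
    overlap_fraction: float = 0.0,
    duplicate_fraction: float = 0.0,
) -> list[AlignmentSegment]:
    """Degrade ground truth into raw aligner-like input.

    Cuts truth segments at ``n_cuts`` random positions, injects redundant
    pieces overlapping existing ones (``overlap_fraction`` of the piece
    count) and contained duplicates (``duplicate_fraction``), and shuffles
    the output order.  All injected pieces are consistent with the truth
    mapping, so the pipeline can reconstruct the truth coverage.
    """
    if not truth:
        raise ValidationError("cannot fragment an empty truth set")
    rng = np.random.default_rng(seed)
    items: list[tuple[AlignmentSegment, int]] = [
        (seg, i) for i, seg in enumerate(truth)
    ]
    for _ in range(n_cuts):
        weights = np.array([it[0].length for it in items], dtype=float)
        j = int(rng.choice(len(items), p=weights / weights.sum()))
        seg, parent = items[j]
        if seg.length < 2:
            continue
        pos = int(rng.integers(seg.query.start + 1, seg.query.end))
        pieces = cut_at_query(seg, [pos])
        items[j : j + 1] = [(p, parent) for p in pieces]

    n_overlap = round(overlap_fraction * len(items))
    n_dup = round(duplicate_fraction * len(items))
    extras: list[tuple[AlignmentSegment, int]] = []
    for _ in range(n_overlap):
        seg, parent = items[int(rng.integers(len(items)))]
        par = truth[parent]
        if par.length < 8 or seg.length < 4:
            continue
        # a redundant window of the parent overlapping the chosen piece
        lo = max(par.query.start, seg.query.start - seg.length)
        a = int(rng.integers(lo, seg.query.end - 1))
        b = int(rng.integers(max(a + 2, seg.query.start + 1), par.query.end + 1))
        window = [
            p
            for p in cut_at_query(par, [a, b])
            if p.query.start >= a and p.query.end <= b
        ]
        extras.extend((p, parent) for p in window)
    for _ in range(n_dup):
        seg, parent = items[int(rng.integers(len(items)))]
        if seg.length < 4:
            continue
        a = int(rng.integers(seg.query.start, seg.query.end - 2))
        b = int(rng.integers(a + 1, seg.query.end))
        if a == seg.query.start and b == seg.query.end:
            b -= 1
        contained = [
            p
            for p in cut_at_query(seg, [a, b])
            if p.query.start >= a and p.query.end <= b
        ]
        extras.extend((p, parent) for p in contained)

    items.extend(extras)
    order = rng.permutation(len(items))
    return [items[i][0] for i in order]


def recovered_fraction(
    result_segments: Sequence[AlignmentSegment],
    truth_primary: Sequence[AlignmentSegment],
) -> float:
    """Fraction of primary truth aligned bases reproduced with the correct
    base-level mapping by ``result_segments``."""
    index: dict[tuple, list[tuple[int, int, int]]] = {}
    total = 0
    for seg in truth_primary:
        key = (seg.query.seq_id, seg.target.seq_id, seg.orientation)
        for b in seg.blocks:
            total += b.length
            index.setdefault(key, []).append((b.q_start, b.q_end, b.t_start))
    for lst in index.values():
        lst.sort()
    recovered = 0
    for seg in result_segments:
        key = (seg.query.seq_id, seg.target.seq_id, seg.orientation)
        candidates = index.get(key, [])
        for b in seg.blocks:
            import bisect

            i = bisect.bisect_right(candidates, (b.q_start, float("inf"), 0)) - 1
            if i < 0:
                continue
            qs, qe, ts = candidates[i]
            if not (qs <= b.q_start and b.q_end <= qe):
                continue
            if seg.orientation == FORWARD:
                ok = b.t_start - b.q_start == ts - qs
            else:
                # anti-diagonal: q_start + t_end is constant within a block
                ok = b.q_start + b.t_end == qs + (ts + (qe - qs))
            if ok:
                recovered += b.length
    return recovered / total if total else 0.0


def write_plan(plan: RearrangementPlan, stream: IO[str]) -> None:
    """Write the plan as a plain-text key-value file."""
    stream.write(f"seed = {plan.seed}\n")
    stream.write(f"n_chromosomes = {plan.n_chromosomes}\n")
    stream.write(f"chromosome_length = {plan.chromosome_length}\n")
    stream.write(f"snp_rate = {plan.snp_rate}\n")
    stream.write(f"indel_rate = {plan.indel_rate}\n")
    for ev in plan.events:
        extra = ""
        if ev.kind == "translocation":
            extra = f" dest={ev.dest_chrom}"
        if ev.kind == "scramble":
            extra = f" n_tiles={ev.n_tiles}"
        stream.write(
            f"event = {ev.kind} {ev.chrom} {ev.start} {ev.end}{extra}\n"
        )
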