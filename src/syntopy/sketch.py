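"""MinHash genome sketching, Mash distance, and aligner recommendation.

The distance between two assemblies drives the choice of aligner and
parameters for the (external) alignment phase:

* same species, or Mash distance < 0.05  -> BLAST megablast, word_size 28
* 0.05 <= d < 0.1 (cross-species)        -> BLAST megablast, word_size 16
* 0.1 <= d <= 0.3                        -> LASTZ (make_lastz_chains);
  the most distant pairs may need the HoxD55 substitution matrix
* d > 0.3                                -> alignment likely uninformative

WindowMasker masking aggressiveness (``t_thres_pct``) follows the same
split: 99.5 for same-species BLAST, 98.5 for cross-species BLAST, 97.5 for
LASTZ pairs.  Boundaries are left-closed: d = 0.05 gives word_size 16 and
d = 0.1 gives LASTZ; the "likely uninformative" advisory applies strictly
above 0.3.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .model import SyntopyError

__all__ = [
    "Sketch",
    "AlignerRecommendation",
    "sketch",
    "mash_distance",
    "recommend_aligner",
    "format_recommendation",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: the exemplar megablast command; word_size is substituted per distance
BLAST_COMMAND_TEMPLATE = (
    "blastn -evalue 0.0001 -gapextend 1 -gapopen 2 -max_target_seqs 250 "
    "-soft_masking true -task megablast -window_size 150 -word_size {word_size}"
)


class EmptySketchError(SyntopyError):
    """No k-mers available (sequence shorter than k or all ambiguous)."""


def _hash_kmer(kmer: bytes, seed: int) -> int:
    digest = hashlib.blake2b(
        kmer, digest_size=8, key=seed.to_bytes(8, "little")
    ).digest()
    return int.from_bytes(digest, "little")


@dataclass(frozen=True)
class Sketch:
    """Bottom-s MinHash sketch of canonical k-mer hashes."""

    k: int
    s: int
    hashes: tuple[int, ...]  # sorted ascending, at most s entries

    def __post_init__(self) -> None:
        if len(self.hashes) > self.s:
            raise SyntopyError("sketch holds more than s hashes")
        if list(self.hashes) != sorted(set(self.hashes)):
            raise SyntopyError("sketch hashes must be sorted and unique")


def sketch(
    sequences: Mapping[str, str] | Iterable[str] | str,
    k: int = 21,
    s: int = 1000,
    seed: int = 42,
) -> Sketch:
    """Bottom-s sketch of the canonical k-mers of one assembly.

    Canonical k-mer = lexicographic min of a k-mer and its reverse
    complement, so a sequence and its reverse complement sketch
    identically.  k-mers containing non-ACGT characters are skipped.
    """
    if isinstance(sequences, str):
        seqs = [sequences]
    elif isinstance(sequences, Mapping):
        seqs = list(sequences.values())
    else:
        seqs = list(sequences)
    hashes: set[int] = set()
    for seq in seqs:
        seq = seq.upper()
        rc = seq.translate(_COMPLEMENT)[::-1]
        n = len(seq)
        for i in range(n - k + 1):
            fwd = seq[i : i + k]
            if not fwd.isalpha() or any(c not in "ACGT" for c in fwd):
                continue
            rev = rc[n - k - i : n - i]
            canon = fwd if fwd <= rev else rev
            hashes.add(_hash_kmer(canon.encode(), seed))
    if not hashes:
        raise EmptySketchError(f"no valid {k}-mers in input sequences")
    return Sketch(k=k, s=s, hashes=tuple(sorted(hashes)[:s]))


def mash_distance(a: Sketch, b: Sketch) -> float:
    """Mash distance d = -(1/k) * ln(2j / (1 + j)).

    j is the Jaccard index estimated on the merged bottom-s sketch (the s
    smallest hashes of the union).  d = 0 when the sketches agree (j = 1);
    d saturates to 1.0 when they share nothing (j = 0).
    """
    if a.k != b.k:
        raise SyntopyError(f"mismatched k-mer sizes {a.k} != {b.k}")
    s = min(a.s, b.s)
    set_a, set_b = set(a.hashes), set(b.hashes)
    merged = sorted(set_a | set_b)[:s]
    shared = sum(1 for h in merged if h in set_a and h in set_b)
    if not merged:
        raise EmptySketchError("cannot compare empty sketches")
    j = shared / len(merged)
    if j == 0.0:
        return 1.0
    if j == 1.0:
        return 0.0
    return -math.log(2.0 * j / (1.0 + j)) / a.k


@dataclass(frozen=True)
class AlignerRecommendation:
    """Aligner and parameter choice for one assembly pair."""

    aligner: str  # "BLAST", "LASTZ" or "none"
    mash_distance: float
    word_size: int | None = None
    t_thres_pct: float | None = None
    matrix_note: str | None = None
    advisory: str | None = None


def recommend_aligner(d: float, same_species: bool = False) -> AlignerRecommendation:
    """Map a Mash distance (plus same-species flag) to aligner parameters."""
    if d < 0:
        raise SyntopyError(f"Mash distance must be non-negative, got {d}")
    if same_species or d < 0.05:
        return AlignerRecommendation(
            aligner="BLAST",
            mash_distance=d,
            word_size=28,
            t_thres_pct=99.5 if same_species else 98.5,
        )
    if d < 0.1:
        return AlignerRecommendation(
            aligner="BLAST", mash_distance=d, word_size=16, t_thres_pct=98.5
        )
    if d <= 0.3:
        return AlignerRecommendation(
            aligner="LASTZ",
            mash_distance=d,
            t_thres_pct=97.5,
            matrix_note="HoxD55" if d > 0.2 else None,
        )
    return AlignerRecommendation(
        aligner="none",
        mash_distance=d,
        advisory=(
            "Mash distance > 0.3: whole-genome alignment is likely "
            "uninformative (sparse, short segments); consider protein or "
            "orthology-based comparison instead"
        ),
    )


def format_recommendation(rec: AlignerRecommendation) -> str:
    """Human-readable recommendation, including the exemplar BLAST command."""
    lines = [f"mash_distance\t{rec.mash_distance:.4f}", f"aligner\t{rec.aligner}"]
    if rec.t_thres_pct is not None:
        lines.append(f"windowmasker_t_thres_pct\t{rec.t_thres_pct}")
    if rec.aligner == "BLAST":
        lines.append(f"word_size\t{rec.word_size}")
        lines.append(
            "command\t" + BLAST_COMMAND_TEMPLATE.format(word_size=rec.word_size)
        )
    if rec.aligner == "LASTZ":
        lines.append("command\tmake_lastz_chains (default parameters)")
        if rec.matrix_note:
            lines.append(f"matrix_note\tconsider BLASTZ_Q={rec.matrix_note}")
    if rec.advisory:
        lines.append(f"advisory\t{rec.advisory}")
    return "\n".join(lines)
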