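"""FASTA and sequence-report ingestion of assembly metadata.

A sequence report is a TSV with header ``seq_id  length  role`` where role is
``chromosome`` or ``unplaced_scaffold``.  When only FASTA is available every
sequence is treated as a chromosome and a warning is logged, since the
ranking stage needs roles but plain FASTA does not carry them.
"""

from __future__ import annotations

import logging
from typing import IO

from Bio import SeqIO

from ..model import AssemblyInfo, CHROMOSOME, UNPLACED, ParseError, ValidationError
from ._util import ensure_text_stream

logger = logging.getLogger(__name__)


def read_fasta(source, assembly_id: str = "assembly"):
    """Read FASTA; returns (AssemblyInfo, dict of seq_id -> sequence string)."""
    stream = ensure_text_stream(source)
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(stream, "fasta"):
        if rec.id in seqs:
            raise ValidationError(f"duplicate sequence id {rec.id!r} in FASTA")
        seqs[rec.id] = str(rec.seq).upper()
    logger.warning(
        "no sequence report for %s: treating all %d sequence(s) as chromosomes",
        assembly_id,
        len(seqs),
    )
    info = AssemblyInfo.from_lengths(
        assembly_id, {sid: len(s) for sid, s in seqs.items()}
    )
    return info, seqs


def write_fasta(seqs: dict[str, str], stream: IO[str], width: int = 80) -> None:
    for sid, seq in seqs.items():
        stream.write(f">{sid}\n")
        for i in range(0, len(seq), width):
            stream.write(seq[i : i + width] + "\n")


def read_seq_report(source, assembly_id: str = "assembly") -> AssemblyInfo:
    """Read a ``seq_id length role`` TSV into an AssemblyInfo."""
    stream = ensure_text_stream(source)
    rows: list[tuple[str, int, str]] = []
    for line_no, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        if line_no == 1 and f[0].lower() in ("seq_id", "seqid", "sequence"):
            continue
        if len(f) < 2:
            raise ParseError(f"line {line_no}: need at least seq_id and length")
        role = f[2] if len(f) > 2 and f[2] else CHROMOSOME
        if role not in (CHROMOSOME, UNPLACED):
            raise ParseError(f"line {line_no}: unknown role {role!r}")
        try:
            rows.append((f[0], int(f[1]), role))
        except ValueError:
            raise ParseError(f"line {line_no}: bad length {f[1]!r}") from None
    return AssemblyInfo(assembly_id=assembly_id, sequences=rows)


def write_seq_report(info: AssemblyInfo, stream: IO[str]) -> None:
    stream.write("seq_id\tlength\trole\n")
    for sid, length, role in info.sequences:
        stream.write(f"{sid}\t{length}\t{role}\n")
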