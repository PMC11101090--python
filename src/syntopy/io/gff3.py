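"""GFF3 export/import of processed alignments and gene annotation reading.

Alignment features are anchored on the **target** assembly, one ``match``
feature per segment, 1-based closed coordinates, with the query placement in
the standard ``Target`` attribute.  A ``blocks`` attribute (comma-separated
``qstart:tstart:length`` absolute 0-based triples) makes the round trip
lossless, including the ungapped block structure used by coverage.
"""

from __future__ import annotations

import logging
import urllib.parse
from dataclasses import dataclass, field
from typing import IO, Iterable

from ..model import (
    AlignmentBlock,
    AlignmentSegment,
    FORWARD,
    ParseError,
    RankedAlignment,
    REVERSE,
    SeqRange,
)
from ._util import ensure_text_stream, natural_key

logger = logging.getLogger(__name__)

_SOURCE = "syntopy"


@dataclass
class GeneFeature:
    """A gene with its CDS intervals (all isoforms pooled)."""

    seq_id: str
    range: SeqRange
    strand: str
    gene_name: str
    cds_ranges: list[SeqRange] = field(default_factory=list)


def _esc(value: str) -> str:
    return urllib.parse.quote(str(value), safe="")


def write_gff3(ranked: Iterable[RankedAlignment], stream: IO[str]) -> None:
    """Write ranked alignments as GFF3 match features on the target assembly."""
    items = sorted(
        ranked,
        key=lambda r: (
            natural_key(r.segment.target.seq_id),
            r.segment.target.start,
            -r.reciprocity,
            r.segment.query.seq_id,
            r.segment.query.start,
        ),
    )
    stream.write("##gff-version 3\n")
    for n, ra in enumerate(items, start=1):
        seg = ra.segment
        strand = "+" if seg.orientation == FORWARD else "-"
        blocks = ",".join(
            f"{b.q_start}:{b.t_start}:{b.length}" for b in seg.blocks
        )
        attrs = [
            f"ID=match{n}",
            "Target={} {} {} {}".format(
                _esc(seg.query.seq_id), seg.query.start + 1, seg.query.end, strand
            ),
            f"reciprocity={ra.reciprocity}",
            f"percent_identity={seg.percent_identity:.4f}",
            f"matches={seg.matches}",
            f"mismatches={seg.mismatches}",
            f"gap_count={seg.gap_count}",
            f"gap_bases={seg.gap_bases}",
            f"blocks={blocks}",
        ]
        if seg.query.assembly_id:
            attrs.append(f"query_assembly={_esc(seg.query.assembly_id)}")
        if seg.target.assembly_id:
            attrs.append(f"target_assembly={_esc(seg.target.assembly_id)}")
        stream.write(
            "\t".join(
                [
                    seg.target.seq_id,
                    _SOURCE,
                    "match",
                    str(seg.target.start + 1),
                    str(seg.target.end),
                    f"{seg.percent_identity:.2f}",
                    strand,
                    ".",
                    ";".join(attrs),
                ]
            )
            + "\n"
        )


def _parse_attrs(text: str, line_no: int) -> dict[str, str]:
    out: dict[str, str] = {}
    for item in text.rstrip(";").split(";"):
        if not item:
            continue
        if "=" not in item:
            raise ParseError(f"line {line_no}: bad attribute {item!r}")
        k, v = item.split("=", 1)
        out[k.strip()] = urllib.parse.unquote(v.strip())
    return out


def read_gff3_alignments(source) -> list[RankedAlignment]:
    """Read back alignments written by :func:`write_gff3`."""
    out: list[RankedAlignment] = []
    stream = ensure_text_stream(source)
    for line_no, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) != 9:
            raise ParseError(f"line {line_no}: GFF3 needs 9 columns")
        if f[2] != "match":
            continue
        attrs = _parse_attrs(f[8], line_no)
        if "Target" not in attrs:
            raise ParseError(f"line {line_no}: match feature without Target")
        tgt = attrs["Target"].split()
        if len(tgt) != 4:
            raise ParseError(f"line {line_no}: bad Target attribute")
        q_seq = urllib.parse.unquote(tgt[0])
        strand = tgt[3]
        orientation = FORWARD if strand == "+" else REVERSE
        try:
            blocks = [
                AlignmentBlock(*(int(x) for x in triple.split(":")))
                for triple in attrs["blocks"].split(",")
            ]
            seg = AlignmentSegment.build(
                q_seq,
                f[0],
                orientation,
                blocks,
                matches=int(attrs["matches"]),
                mismatches=int(attrs["mismatches"]),
                gap_count=int(attrs["gap_count"]),
                gap_bases=int(attrs["gap_bases"]),
                q_assembly=attrs.get("query_assembly", ""),
                t_assembly=attrs.get("target_assembly", ""),
                source_id=attrs.get("ID", ""),
            )
            reciprocity = int(attrs.get("reciprocity", 3))
        except (KeyError, ValueError) as exc:
            raise ParseError(f"line {line_no}: {exc}") from None
        out.append(RankedAlignment(segment=seg, reciprocity=reciprocity))
    return out


def read_gff3_genes(source) -> list[GeneFeature]:
    """Read gene features (with CDS children) from a GFF3 annotation.

    CDS rows are attached to their gene ancestor through any number of
    intermediate transcript features; CDS pooling across isoforms is left to
    the caller (coverage unions intervals anyway).  CDS rows whose parent
    chain does not reach a gene are skipped with a warning.
    """
    import gffutils

    stream = ensure_text_stream(source)
    data = stream.read()
    db = gffutils.create_db(
        data,
        dbfn=":memory:",
        from_string=True,
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: dict[str, GeneFeature] = {}
    for g in db.features_of_type("gene"):
        name = g.attributes.get("Name", g.attributes.get("ID", [g.id]))[0]
        genes[g.id] = GeneFeature(
            seq_id=g.seqid,
            range=SeqRange(g.seqid, g.start - 1, g.end),
            strand=g.strand,
            gene_name=name,
        )
    orphans = 0
    for cds in db.features_of_type("CDS"):
        ancestors = [a.id for a in db.parents(cds) if a.featuretype == "gene"]
        if not ancestors:
            orphans += 1
            continue
        genes[ancestors[0]].cds_ranges.append(
            SeqRange(cds.seqid, cds.start - 1, cds.end)
        )
    if orphans:
        logger.warning("%d CDS feature(s) without a gene ancestor skipped", orphans)
    return list(genes.values())
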