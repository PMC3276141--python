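"""Readers and writers for the standard formats the pipeline touches.

Internal coordinates are 0-based half-open everywhere in the package; the
conversion to GFF3's 1-based closed convention happens only here, so there
is a single place for off-by-one mistakes to live (and be tested).
"""

from __future__ import annotations

import logging
import urllib.parse
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .seqcore import Sequence

log = logging.getLogger(__name__)

_GFF3_ESCAPE = ";=&,%\t\n"


@dataclass(frozen=True)
class AnnotationRecord:
    """One GFF3 feature line; interval is 1-based closed as in the file."""

    seq_id: str
    source: str
    type: str
    start: int  # 1-based
    end: int  # closed
    score: float | None
    strand: str
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"inverted interval {self.start}..{self.end}")
        if self.strand not in "+-.":
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def interval0(self) -> tuple[int, int]:
        """The feature interval as 0-based half-open."""
        return self.start - 1, self.end


def read_fasta(path: str | Path) -> list[Sequence]:
    """Read a (multi-record) FASTA file; residues case-folded to upper.

    Raises on duplicate ids or empty records; an empty file yields an
    empty list with a warning.
    """
    seqs: list[Sequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id) :].strip()
        seqs.append(Sequence(rec.id, str(rec.seq).upper(), desc))
    if not seqs:
        log.warning("no records in FASTA file %s", path)
    return seqs


def write_fasta(seqs: list[Sequence], path: str | Path, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description=s.description)
        for s in seqs
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def _esc(value: str) -> str:
    return urllib.parse.quote(str(value), safe=" :/().|'\"@^*[]{}!+-_")


def _unesc(value: str) -> str:
    return urllib.parse.unquote(value)


def write_gff3(records: list[AnnotationRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in records:
            score = "." if r.score is None else f"{r.score:g}"
            attrs = ";".join(f"{_esc(k)}={_esc(v)}" for k, v in r.attributes.items())
            fh.write(
                f"{r.seq_id}\t{r.source}\t{r.type}\t{r.start}\t{r.end}\t"
                f"{score}\t{r.strand}\t.\t{attrs or '.'}\n"
            )


def read_gff3(path: str | Path) -> list[AnnotationRecord]:
    records: list[AnnotationRecord] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            seq_id, source, ftype, start, end, score, strand, _, attr_s = fields
            attrs: dict[str, str] = {}
            if attr_s != ".":
                for pair in attr_s.split(";"):
                    if not pair:
                        continue
                    k, _, v = pair.partition("=")
                    attrs[_unesc(k)] = _unesc(v)
            records.append(
                AnnotationRecord(
                    seq_id,
                    source,
                    ftype,
                    int(start),
                    int(end),
                    None if score == "." else float(score),
                    strand,
                    attrs,
                )
            )
    return records


def element_records(elements, source: str = "mulescan") -> list[AnnotationRecord]:
    """Convert screened elements to GFF3 records (1-based closed here)."""
    records = []
    for e in elements:
        attrs = {
            "ID": f"{e.seq_id}_{e.start}_{e.end}",
            "class": e.structural_class.value if e.structural_class else "unclassified",
            "left_tir_identity": f"{e.left_tir.identity_pct:.1f}",
            "terminal_motifs": str(bool(e.terminal_motifs_ok)),
        }
        if e.right_tir is not None:
            attrs["right_tir_identity"] = f"{e.right_tir.identity_pct:.1f}"
        if e.tir_pair_identity_pct is not None:
            attrs["tir_pair_identity"] = f"{e.tir_pair_identity_pct:.1f}"
        if e.tsd is not None:
            attrs["tsd_present"] = (
                "indeterminate" if e.tsd.present is None else str(e.tsd.present)
            )
            if e.tsd.left_copy:
                attrs["tsd_sequence"] = e.tsd.left_copy
        records.append(
            AnnotationRecord(
                e.seq_id,
                source,
                "terminal_inverted_repeat_element",
                e.start + 1,
                e.end,
                None,
                "+",
                attrs,
            )
        )
    return records


def write_bed(
    intervals: list[tuple[str, int, int, str]], path: str | Path
) -> None:
    """Write (seq_id, start0, end0, name) tuples as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for seq_id, start, end, name in intervals:
            if start > end:
                raise ValueError(f"inverted interval {start}..{end}")
            fh.write(f"{seq_id}\t{start}\t{end}\t{name}\n")
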