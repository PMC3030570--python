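"""Stranded genomic intervals and light-weight FASTA/GFF3 I/O.

All in-memory coordinates are 0-based half-open on the forward strand;
GFF3 output converts to the format's 1-based inclusive convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded, 0-based half-open interval on a named sequence."""

    sequence_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.sequence_id == other.sequence_id
            and self.start <= other.start
            and other.end <= self.end
        )

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.sequence_id == other.sequence_id
            and self.start < other.end
            and other.start < self.end
        )

    def intersection_length(self, other: "GenomicInterval") -> int:
        if not self.overlaps(other):
            return 0
        return min(self.end, other.end) - max(self.start, other.start)

    def extract(self, sequences: Mapping[str, str]) -> str:
        """Strand-aware sequence slice (reverse-complemented for '-')."""
        seg = sequences[self.sequence_id][self.start : self.end]
        if self.strand == "-":
            seg = str(Seq(seg).reverse_complement())
        return seg


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


@dataclass
class Gff3Feature:
    interval: GenomicInterval
    feature_type: str
    attributes: dict[str, str]
    source: str = "fbxscape"
    score: str = "."
    phase: str = "."


def write_gff3(features: Iterable[Gff3Feature], path: str | Path) -> None:
    """Write features converting internal 0-based half-open to 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for feat in features:
            iv = feat.interval
            attrs = ";".join(f"{k}={v}" for k, v in feat.attributes.items())
            fh.write(
                "\t".join(
                    [
                        iv.sequence_id,
                        feat.source,
                        feat.feature_type,
                        str(iv.start + 1),
                        str(iv.end),
                        feat.score,
                        iv.strand,
                        feat.phase,
                        attrs,
                    ]
                )
                + "\n"
            )


def read_gff3(path: str | Path) -> list[Gff3Feature]:
    features = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            seqid, source, ftype, start, end, score, strand, phase, attrs = (
                line.rstrip("\n").split("\t")
            )
            attributes = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            features.append(
                Gff3Feature(
                    interval=GenomicInterval(seqid, int(start) - 1, int(end), strand),
                    feature_type=ftype,
                    attributes=attributes,
                    source=source,
                    score=score,
                    phase=phase,
                )
            )
    return features
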