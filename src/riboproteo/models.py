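"""Transcript models, coordinate maps and genome/annotation I/O.

Internal coordinates are 0-based half-open throughout; GFF3 input/output
converts from/to the 1-based inclusive convention and all user-facing
reports are 1-based.  Transcript coordinates run 5'->3' in transcription
direction, so position 0 of a minus-strand transcript is its rightmost
genomic base.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from intervaltree import IntervalTree

__all__ = [
    "TranscriptModel",
    "TranscriptIndex",
    "read_genome_fasta",
    "write_genome_fasta",
    "read_gff3",
    "write_gff3",
    "revcomp",
]


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass
class TranscriptModel:
    """One transcript with its exon structure and CDS.

    ``exons`` are genomic 0-based half-open intervals sorted by genomic
    start and must not overlap.  ``cds_start``/``cds_end`` are the genomic
    bounds of the CDS (half-open), irrespective of strand.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start: int
    cds_end: int
    _starts: list[int] = field(init=False, repr=False)
    _cum: list[int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for {self.transcript_id}")
        exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if e1 > s2:
                raise ValueError(f"overlapping exons in {self.transcript_id}")
        if any(e <= s for s, e in exons):
            raise ValueError(f"empty exon in {self.transcript_id}")
        self.exons = exons
        self._starts = [s for s, _ in exons]
        cum, total = [], 0
        for s, e in exons:
            cum.append(total)
            total += e - s
        self._cum = cum

    # -- basic geometry ----------------------------------------------------
    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def tx_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def cds_length(self) -> int:
        n = 0
        for s, e in self.exons:
            n += max(0, min(e, self.cds_end) - max(s, self.cds_start))
        return n

    # -- coordinate maps ---------------------------------------------------
    def _plus_index(self, pos: int) -> int | None:
        """Offset of *pos* along the concatenated exons, left to right."""
        i = bisect.bisect_right(self._starts, pos) - 1
        if i < 0:
            return None
        s, e = self.exons[i]
        if pos >= e:
            return None
        return self._cum[i] + (pos - s)

    def g2t(self, pos: int) -> int | None:
        """Genomic position -> transcript coordinate, or None if intronic/outside."""
        idx = self._plus_index(pos)
        if idx is None:
            return None
        return idx if self.strand == "+" else self.tx_length - 1 - idx

    def t2g(self, t: int) -> int:
        """Transcript coordinate -> genomic position."""
        if not 0 <= t < self.tx_length:
            raise IndexError(f"transcript coordinate {t} outside {self.transcript_id}")
        idx = t if self.strand == "+" else self.tx_length - 1 - t
        i = bisect.bisect_right(self._cum, idx) - 1
        s, _ = self.exons[i]
        return s + (idx - self._cum[i])

    @property
    def cds_start_tx(self) -> int:
        """Transcript coordinate of the first CDS nucleotide."""
        g = self.cds_start if self.strand == "+" else self.cds_end - 1
        t = self.g2t(g)
        if t is None:
            raise ValueError(f"CDS start of {self.transcript_id} not exonic")
        return t

    @property
    def cds_end_tx(self) -> int:
        """Transcript coordinate one past the last CDS nucleotide."""
        g = self.cds_end - 1 if self.strand == "+" else self.cds_start
        t = self.g2t(g)
        if t is None:
            raise ValueError(f"CDS end of {self.transcript_id} not exonic")
        return t + 1

    @property
    def tis_genomic(self) -> int:
        """Genomic position of the first nucleotide of the annotated start codon."""
        return self.t2g(self.cds_start_tx)

    def tx_positions(self):
        """Genomic positions in transcript (5'->3') order."""
        for t in range(self.tx_length):
            yield self.t2g(t)

    def sequence(self, genome: dict[str, str]) -> str:
        """Spliced transcript sequence, 5'->3'."""
        chrom = genome[self.chrom]
        seq = "".join(chrom[s:e] for s, e in self.exons)
        return seq if self.strand == "+" else revcomp(seq)

    def contains(self, pos: int) -> bool:
        return self._plus_index(pos) is not None


class TranscriptIndex:
    """Interval lookup of transcripts per (chrom, strand)."""

    def __init__(self, models: list[TranscriptModel]):
        self.models = list(models)
        self._trees: dict[tuple[str, str], IntervalTree] = {}
        for m in self.models:
            tree = self._trees.setdefault((m.chrom, m.strand), IntervalTree())
            tree[m.start:m.end] = m

    def overlapping(self, chrom: str, strand: str, pos: int) -> list[TranscriptModel]:
        tree = self._trees.get((chrom, strand))
        if tree is None:
            return []
        hits = [iv.data for iv in tree[pos] if iv.data.contains(pos)]
        return sorted(hits, key=lambda m: m.transcript_id)

    def near(self, chrom: str, strand: str, pos: int, slack: int = 2) -> list[TranscriptModel]:
        tree = self._trees.get((chrom, strand))
        if tree is None:
            return []
        hits = {iv.data.transcript_id: iv.data for iv in tree[pos - slack:pos + slack + 1]}
        return [hits[k] for k in sorted(hits)]


# -- FASTA ----------------------------------------------------------------

def read_genome_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_genome_fasta(genome: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in genome:
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# -- GFF3 -----------------------------------------------------------------

def read_gff3(path: str | Path) -> list[TranscriptModel]:
    """Parse a GFF3 file into transcript models (gene/mRNA/exon/CDS features)."""
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    models = []
    for mrna in db.features_of_type(("mRNA", "transcript")):
        exons = sorted((f.start - 1, f.end) for f in db.children(mrna, featuretype="exon"))
        cds = [(f.start - 1, f.end) for f in db.children(mrna, featuretype="CDS")]
        if not exons or not cds:
            continue
        parent = mrna.attributes.get("Parent", [mrna.id])
        models.append(
            TranscriptModel(
                gene_id=parent[0],
                transcript_id=mrna.id,
                chrom=mrna.seqid,
                strand=mrna.strand,
                exons=exons,
                cds_start=min(s for s, _ in cds),
                cds_end=max(e for _, e in cds),
            )
        )
    models.sort(key=lambda m: (m.chrom, m.start, m.transcript_id))
    return models


def write_gff3(models: list[TranscriptModel], path: str | Path) -> None:
    """Write transcript models as GFF3 (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in sorted(models, key=lambda m: (m.chrom, m.start, m.transcript_id)):
            attrs_gene = f"ID={m.gene_id}"
            fh.write(
                f"{m.chrom}\triboproteo\tgene\t{m.start + 1}\t{m.end}\t.\t{m.strand}\t.\t{attrs_gene}\n"
            )
            fh.write(
                f"{m.chrom}\triboproteo\tmRNA\t{m.start + 1}\t{m.end}\t.\t{m.strand}\t.\t"
                f"ID={m.transcript_id};Parent={m.gene_id}\n"
            )
            for i, (s, e) in enumerate(m.exons, 1):
                fh.write(
                    f"{m.chrom}\triboproteo\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t"
                    f"ID={m.transcript_id}.exon{i};Parent={m.transcript_id}\n"
                )
            for s, e in m.exons:
                cs, ce = max(s, m.cds_start), min(e, m.cds_end)
                if cs < ce:
                    # phase computed in transcript order below
                    fh.write(
                        f"{m.chrom}\triboproteo\tCDS\t{cs + 1}\t{ce}\t.\t{m.strand}\t0\t"
                        f"ID={m.transcript_id}.cds;Parent={m.transcript_id}\n"
                    )
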