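"""Ribosome footprint P-site assignment and positional count tracks.

Footprints of 26-34 nt are assigned a P-site by a length-dependent offset
from the read 5' end (+12 for 26-30 nt, +13 for 31-33 nt, +14 for 34 nt),
applied in transcription direction.  Reads outside the accepted length
range are rejected (a counted, normal outcome).  Positional scores are the
number of P-site-assigned reads per genomic position, kept strand-aware.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .models import TranscriptIndex, TranscriptModel

__all__ = [
    "AlignedRead",
    "PSiteTrack",
    "MIN_LENGTH",
    "MAX_LENGTH",
    "psite_offset",
    "assign_psite",
    "build_track",
    "metagene_density",
    "read_alignments_tsv",
    "write_alignments_tsv",
    "read_alignments_sam",
    "write_alignments_sam",
    "write_bedgraph",
]

MIN_LENGTH = 26
MAX_LENGTH = 34


@dataclass(frozen=True)
class AlignedRead:
    """One aligned footprint: 5'-end genomic coordinate (0-based), strand, length.

    For minus-strand reads ``five_prime`` is the rightmost genomic
    coordinate covered by the read.
    """

    chrom: str
    five_prime: int
    strand: str
    length: int


def psite_offset(length: int) -> int | None:
    """Offset from the 5' end to the P-site; None for rejected lengths."""
    if 26 <= length <= 30:
        return 12
    if 31 <= length <= 33:
        return 13
    if length == 34:
        return 14
    return None


def assign_psite(read: AlignedRead, index: TranscriptIndex | None = None) -> int | None:
    """Genomic P-site of a read, or None if its length is rejected.

    With a transcript index the offset is applied in transcript space
    (junction-safe); a read whose 5' end falls outside any transcript, or
    whose offset runs off the transcript, falls back to genomic arithmetic.
    """
    off = psite_offset(read.length)
    if off is None:
        return None
    if index is not None:
        for model in index.overlapping(read.chrom, read.strand, read.five_prime):
            t = model.g2t(read.five_prime)
            if t is not None and t + off < model.tx_length:
                return model.t2g(t + off)
    if read.strand == "+":
        return read.five_prime + off
    return read.five_prime - off


class PSiteTrack:
    """Strand-aware sparse P-site count track for one treatment."""

    def __init__(self, treatment: str):
        self.treatment = treatment
        self.counts: dict[tuple[str, str], Counter] = {}
        self.n_accepted = 0
        self.n_rejected = 0

    def add(self, chrom: str, strand: str, pos: int, n: int = 1) -> None:
        self.counts.setdefault((chrom, strand), Counter())[pos] += n
        self.n_accepted += n

    def get(self, chrom: str, strand: str, pos: int) -> int:
        return self.counts.get((chrom, strand), Counter()).get(pos, 0)

    def window_sum(self, chrom: str, strand: str, positions) -> int:
        c = self.counts.get((chrom, strand))
        if not c:
            return 0
        return sum(c.get(p, 0) for p in positions)

    def total(self) -> int:
        return sum(sum(c.values()) for c in self.counts.values())

    def transcript_total(self, model: TranscriptModel) -> int:
        """Total P-site count on the exonic positions of a transcript."""
        c = self.counts.get((model.chrom, model.strand))
        if not c:
            return 0
        n = 0
        for pos, cnt in c.items():
            if model.contains(pos):
                n += cnt
        return n


def build_track(
    reads,
    treatment: str,
    index: TranscriptIndex | None = None,
    chrom_sizes: dict[str, int] | None = None,
) -> PSiteTrack:
    """Accumulate P-sites of *reads* into a positional count track.

    Raises on a read whose chromosome is absent from *chrom_sizes* (when
    provided); rejected-length reads are tallied, not errors.
    """
    track = PSiteTrack(treatment)
    for read in reads:
        if chrom_sizes is not None and read.chrom not in chrom_sizes:
            raise ValueError(f"read on unknown chromosome: {read!r}")
        pos = assign_psite(read, index)
        if pos is None:
            track.n_rejected += 1
            continue
        track.add(read.chrom, read.strand, pos)
    return track


def metagene_density(
    track: PSiteTrack,
    models: list[TranscriptModel],
    flank: int = 20,
    min_rpfs: int = 20,
    codon_bins: bool = False,
):
    """Per-gene normalized footprint density around/over the CDS.

    Counts at each transcript position in [CDS start - flank, CDS end +
    flank) are divided by the mean count over that window; genes with fewer
    than *min_rpfs* P-sites on the transcript are excluded, as are genes
    with a zero window mean.  The aggregate profile is the mean over
    included genes at positions aligned on the CDS start (index 0 = first
    CDS nucleotide; negative indices = leader).  ``codon_bins`` averages
    the normalized values in-frame over codons.
    """
    profiles: dict[str, np.ndarray] = {}
    offsets: dict[str, int] = {}
    excluded: dict[str, str] = {}
    for m in models:
        total = track.transcript_total(m)
        if total < min_rpfs:
            excluded[m.transcript_id] = f"only {total} RPFs"
            continue
        lo = max(0, m.cds_start_tx - flank)
        hi = min(m.tx_length, m.cds_end_tx + flank)
        counts = np.array(
            [track.get(m.chrom, m.strand, m.t2g(t)) for t in range(lo, hi)], dtype=float
        )
        mean = counts.mean()
        if mean == 0:
            excluded[m.transcript_id] = "zero coverage in window"
            continue
        norm = counts / mean
        if codon_bins:
            cs = m.cds_start_tx - lo
            n_codons = (m.cds_end_tx - m.cds_start_tx) // 3
            norm = np.array(
                [norm[cs + 3 * c: cs + 3 * c + 3].mean() for c in range(n_codons)]
            )
            offsets[m.transcript_id] = 0
        else:
            offsets[m.transcript_id] = m.cds_start_tx - lo
        profiles[m.transcript_id] = norm

    # aggregate aligned on the CDS start
    agg: dict[int, list[float]] = {}
    for tid, vec in profiles.items():
        for i, v in enumerate(vec):
            agg.setdefault(i - offsets[tid], []).append(v)
    aggregate = pd.DataFrame(
        {
            "position": sorted(agg),
            "density": [float(np.mean(agg[k])) for k in sorted(agg)],
            "n_genes": [len(agg[k]) for k in sorted(agg)],
        }
    )
    return profiles, aggregate, excluded


# -- I/O ------------------------------------------------------------------

def read_alignments_tsv(path: str | Path) -> list[AlignedRead]:
    """Read the 4-column alignment dialect: chrom, 0-based 5'-end, strand, length."""
    df = pd.read_csv(
        path, sep="\t", names=["chrom", "five_prime", "strand", "length"], comment="#"
    )
    return [
        AlignedRead(r.chrom, int(r.five_prime), r.strand, int(r.length))
        for r in df.itertuples()
    ]


def write_alignments_tsv(reads, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# chrom\tfive_prime0\tstrand\tlength\n")
        for r in reads:
            fh.write(f"{r.chrom}\t{r.five_prime}\t{r.strand}\t{r.length}\n")


def read_alignments_sam(path: str | Path) -> list[AlignedRead]:
    reads = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                continue
            length = rec.query_length or rec.infer_query_length() or 0
            if rec.is_reverse:
                reads.append(
                    AlignedRead(rec.reference_name, rec.reference_end - 1, "-", length)
                )
            else:
                reads.append(
                    AlignedRead(rec.reference_name, rec.reference_start, "+", length)
                )
    return reads


def write_alignments_sam(
    reads, chrom_sizes: dict[str, int], path: str | Path
) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": n} for c, n in chrom_sizes.items()],
    }
    refs = {c: i for i, c in enumerate(chrom_sizes)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for i, r in enumerate(reads):
            a = pysam.AlignedSegment()
            a.query_name = f"read{i}"
            a.reference_id = refs[r.chrom]
            a.reference_start = r.five_prime if r.strand == "+" else r.five_prime - r.length + 1
            a.flag = 16 if r.strand == "-" else 0
            a.mapping_quality = 255
            a.cigarstring = f"{r.length}M"
            a.query_sequence = "N" * r.length
            out.write(a)


def write_bedgraph(track: PSiteTrack, path: str | Path, strand: str) -> None:
    with open(path, "w") as fh:
        for (chrom, s), counts in sorted(track.counts.items()):
            if s != strand:
                continue
            for pos in sorted(counts):
                fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{counts[pos]}\n")
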