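"""Translation initiation site calling from paired LTM/CHX P-site tracks.

A candidate TIS is an LTM P-site peak that (i) holds the maximal LTM count
within a 7-nt window (3 nt either side), (ii) lies within +-1 nt of the
first nucleotide of an AUG or near-cognate start codon, and (iii) passes a
category-specific minimum LTM count and a minimum difference of
transcript-normalized scores R_LTM - R_CHX, where R = (X/N) x 10 with X the
summed P-site count over the +-1 nt codon window and N the total P-site
count on the transcript for that treatment.  Annotated starts (dbTIS)
failing these criteria are rescued when their CDS shows elongating (CHX)
ribosome occupancy.

Category thresholds default to the established settings: annotated starts
5 counts / 0.01, leader and intergenic TIS 10 / 0.05, CDS-internal TIS
15 / 0.15.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .footprints import PSiteTrack
from .models import TranscriptIndex, TranscriptModel, revcomp

__all__ = [
    "START_CODONS",
    "NEAR_COGNATES",
    "TISThresholds",
    "CalledTIS",
    "normalized_score",
    "find_peaks",
    "categorize",
    "call_tis",
    "write_tis_tsv",
    "read_tis_tsv",
]

#: AUG plus its nine single-nucleotide neighbours, decoded with initiator Met.
NEAR_COGNATES = frozenset(
    {"CTG", "GTG", "TTG", "AAG", "ACG", "AGG", "ATA", "ATC", "ATT"}
)
START_CODONS = frozenset({"ATG"}) | NEAR_COGNATES

CATEGORIES = (
    "dbTIS",
    "leader5",
    "leader3",
    "cds_dTIS_inframe",
    "cds_other_frame",
    "intergenic",
)


@dataclass
class TISThresholds:
    """Per-category (minimum LTM count, minimum R_LTM - R_CHX) thresholds."""

    min_count: dict[str, int] = field(
        default_factory=lambda: {
            "dbTIS": 5,
            "leader5": 10,
            "leader3": 10,
            "intergenic": 10,
            "cds_dTIS_inframe": 15,
            "cds_other_frame": 15,
        }
    )
    min_rdiff: dict[str, float] = field(
        default_factory=lambda: {
            "dbTIS": 0.01,
            "leader5": 0.05,
            "leader3": 0.05,
            "intergenic": 0.05,
            "cds_dTIS_inframe": 0.15,
            "cds_other_frame": 0.15,
        }
    )
    #: CHX P-sites required over the CDS for dbTIS rescue.
    rescue_min_chx: int = 10
    #: Half-width of the pseudo-transcript used to normalize intergenic peaks.
    intergenic_flank: int = 500


@dataclass
class CalledTIS:
    gene: str
    transcript: str
    chrom: str
    strand: str
    position: int  # genomic first nt of the start codon, 0-based
    codon: str
    category: str
    ltm_count: int
    r_ltm: float
    r_chx: float
    rdiff: float
    status: str  # called | rescued_dbTIS


def normalized_score(x: int, n: int) -> float:
    """R = (X/N) x 10; undefined for a transcript without reads (n <= 0)."""
    if n <= 0:
        raise ValueError("normalized score undefined for a transcript with no reads")
    return (x / n) * 10.0


def _codon_at(
    chrom_seq: str,
    strand: str,
    first_nt: int,
    model: TranscriptModel | None = None,
    tx_seq: str | None = None,
) -> str | None:
    """Codon whose first nucleotide (transcription direction) is *first_nt*.

    Read in transcript space when a model covering the position is given
    (junction-safe), genomically otherwise.
    """
    if model is not None and tx_seq is not None:
        t = model.g2t(first_nt)
        if t is not None and t + 3 <= model.tx_length:
            return tx_seq[t:t + 3]
    if strand == "+":
        if first_nt < 0 or first_nt + 3 > len(chrom_seq):
            return None
        return chrom_seq[first_nt:first_nt + 3]
    if first_nt - 2 < 0 or first_nt + 1 > len(chrom_seq):
        return None
    return revcomp(chrom_seq[first_nt - 2:first_nt + 1])


def _downstream(strand: str, pos: int, step: int) -> int:
    """Move *step* nt in transcription direction."""
    return pos + step if strand == "+" else pos - step


@dataclass
class Candidate:
    chrom: str
    strand: str
    peak_pos: int
    peak_count: int
    anchor: int  # genomic first nt of the start codon
    codon: str


def find_peaks(
    ltm: PSiteTrack,
    index: TranscriptIndex,
    genome: dict[str, str],
    tx_seqs: dict[str, str] | None = None,
) -> list[Candidate]:
    """LTM peaks anchored to (near-)cognate start codons.

    A peak must carry the maximal LTM count within its 7-nt window and sit
    within +-1 nt of the codon first nucleotide.  Anchoring prefers a zero
    offset, then an ATG anchor over a near-cognate, then the most 5'
    position; the same order breaks equal-count ties between peaks fewer
    than 4 nt apart.
    """
    if tx_seqs is None:
        tx_seqs = {}
    candidates: dict[tuple[str, str, int], Candidate] = {}
    for (chrom, strand), counts in sorted(ltm.counts.items()):
        seq = genome[chrom]
        for p in sorted(counts):
            c_p = counts[p]
            if c_p <= 0:
                continue
            if any(counts.get(q, 0) > c_p for q in range(p - 3, p + 4)):
                continue  # not the window maximum
            anchor, codon = _anchor_peak(seq, chrom, strand, p, index, tx_seqs)
            if anchor is None:
                continue
            key = (chrom, strand, anchor)
            prev = candidates.get(key)
            if prev is None or c_p > prev.peak_count:
                candidates[key] = Candidate(chrom, strand, p, c_p, anchor, codon)

    return _resolve_ties(ltm, list(candidates.values()))


def _anchor_peak(seq, chrom, strand, p, index, tx_seqs):
    """Best codon anchor for a peak at p, or (None, None)."""
    models = index.overlapping(chrom, strand, p)
    model = models[0] if models else None
    tseq = None
    if model is not None:
        tseq = tx_seqs.get(model.transcript_id)
        if tseq is None:
            tseq = model.sequence({chrom: seq})
            tx_seqs[model.transcript_id] = tseq
    options = []
    for delta in (0, -1, 1):  # offset of the peak from the codon first nt
        c = _downstream(strand, p, -delta)
        codon = _codon_at(seq, strand, c, model, tseq)
        if codon in START_CODONS:
            five_rank = c if strand == "+" else -c
            options.append((abs(delta), 0 if codon == "ATG" else 1, five_rank, c, codon))
    if not options:
        return None, None
    options.sort()
    _, _, _, c, codon = options[0]
    return c, codon


def _resolve_ties(ltm: PSiteTrack, cands: list[Candidate]) -> list[Candidate]:
    """Keep at most one candidate per 7-nt window per strand."""
    out = []
    by_key: dict[tuple[str, str], list[Candidate]] = {}
    for c in cands:
        by_key.setdefault((c.chrom, c.strand), []).append(c)
    for (chrom, strand), group in sorted(by_key.items()):
        group.sort(key=lambda c: c.anchor)
        keep = set(range(len(group)))
        for i in range(len(group)):
            if i not in keep:
                continue
            for j in range(i + 1, len(group)):
                if j not in keep:
                    continue
                a, b = group[i], group[j]
                if b.anchor - a.anchor > 3:
                    break
                loser = _tie_loser(a, b, strand)
                keep.discard(i if loser is a else j)
        out.extend(group[i] for i in sorted(keep))
    return out


def _tie_loser(a: Candidate, b: Candidate, strand: str) -> Candidate:
    """Of two competing candidates within a 7-nt window, the one to drop."""
    if a.peak_count != b.peak_count:
        return a if a.peak_count < b.peak_count else b
    a_atg, b_atg = a.codon == "ATG", b.codon == "ATG"
    if a_atg != b_atg:
        return b if a_atg else a
    # most 5' wins
    if strand == "+":
        return b if a.anchor < b.anchor else a
    return b if a.anchor > b.anchor else a


def categorize(anchor: int, model: TranscriptModel) -> str | None:
    """Category of a codon-anchored position with respect to one transcript."""
    t = model.g2t(anchor)
    if t is None:
        return None
    cs, ce = model.cds_start_tx, model.cds_end_tx
    if t == cs:
        return "dbTIS"
    if t < cs:
        return "leader5"
    if t >= ce:
        return "leader3"
    return "cds_dTIS_inframe" if (t - cs) % 3 == 0 else "cds_other_frame"


def _window_positions(model: TranscriptModel | None, chrom: str, strand: str, anchor: int):
    """Genomic positions of the +-1 nt window around the codon first nt."""
    if model is not None:
        t = model.g2t(anchor)
        if t is not None:
            return [
                model.t2g(u) for u in (t - 1, t, t + 1) if 0 <= u < model.tx_length
            ]
    return [anchor - 1, anchor, anchor + 1]


def call_tis(
    ltm: PSiteTrack,
    chx: PSiteTrack,
    models: list[TranscriptModel],
    genome: dict[str, str],
    thresholds: TISThresholds | None = None,
) -> list[CalledTIS]:
    """Apply the peak, codon, count and R-difference criteria; rescue dbTIS."""
    if thresholds is None:
        thresholds = TISThresholds()
    index = TranscriptIndex(models)
    tx_seqs: dict[str, str] = {}
    n_ltm: dict[str, int] = {}
    n_chx: dict[str, int] = {}

    def totals(model: TranscriptModel) -> tuple[int, int]:
        tid = model.transcript_id
        if tid not in n_ltm:
            n_ltm[tid] = ltm.transcript_total(model)
            n_chx[tid] = chx.transcript_total(model)
        return n_ltm[tid], n_chx[tid]

    def scores(x_ltm: int, x_chx: int, nl: int, nc: int) -> tuple[float, float]:
        r_l = normalized_score(x_ltm, nl) if nl > 0 else 0.0
        r_c = normalized_score(x_chx, nc) if nc > 0 else 0.0
        return r_l, r_c

    called: dict[tuple[str, int, str], CalledTIS] = {}

    for cand in find_peaks(ltm, index, genome, tx_seqs):
        contexts = index.overlapping(cand.chrom, cand.strand, cand.anchor)
        records = []
        for model in contexts:
            cat = categorize(cand.anchor, model)
            if cat is None:
                continue
            win = _window_positions(model, cand.chrom, cand.strand, cand.anchor)
            x_l = ltm.window_sum(cand.chrom, cand.strand, win)
            x_c = chx.window_sum(cand.chrom, cand.strand, win)
            nl, nc = totals(model)
            r_l, r_c = scores(x_l, x_c, nl, nc)
            records.append(
                CalledTIS(
                    model.gene_id, model.transcript_id, cand.chrom, cand.strand,
                    cand.anchor, cand.codon, cat, x_l, r_l, r_c, r_l - r_c, "called",
                )
            )
        if not records:
            flank = thresholds.intergenic_flank
            win = [cand.anchor - 1, cand.anchor, cand.anchor + 1]
            x_l = ltm.window_sum(cand.chrom, cand.strand, win)
            x_c = chx.window_sum(cand.chrom, cand.strand, win)
            pseudo = range(cand.anchor - flank, cand.anchor + flank + 1)
            nl = ltm.window_sum(cand.chrom, cand.strand, pseudo)
            nc = chx.window_sum(cand.chrom, cand.strand, pseudo)
            r_l, r_c = scores(x_l, x_c, nl, nc)
            records.append(
                CalledTIS(
                    f"intergenic:{cand.chrom}:{cand.anchor}", "-", cand.chrom,
                    cand.strand, cand.anchor, cand.codon, "intergenic",
                    x_l, r_l, r_c, r_l - r_c, "called",
                )
            )
        # dbTIS context takes precedence; otherwise keep the max-rdiff context
        db = [r for r in records if r.category == "dbTIS"]
        pool = db if db else records
        best = max(pool, key=lambda r: (r.rdiff, r.transcript))
        if best.ltm_count >= thresholds.min_count[best.category] and (
            best.rdiff >= thresholds.min_rdiff[best.category]
        ):
            key = (best.chrom, best.position, best.strand)
            prev = called.get(key)
            if prev is None or best.rdiff > prev.rdiff:
                called[key] = best

    # dbTIS rescue by elongating (CHX) occupancy over the CDS
    rescued: dict[tuple[str, int, str], CalledTIS] = {}
    for model in models:
        anchor = model.tis_genomic
        key = (model.chrom, anchor, model.strand)
        if key in called and called[key].category == "dbTIS":
            continue
        chx_cds = chx.window_sum(
            model.chrom, model.strand,
            (model.t2g(t) for t in range(model.cds_start_tx, model.cds_end_tx)),
        )
        if chx_cds < thresholds.rescue_min_chx:
            continue
        win = _window_positions(model, model.chrom, model.strand, anchor)
        x_l = ltm.window_sum(model.chrom, model.strand, win)
        x_c = chx.window_sum(model.chrom, model.strand, win)
        nl, nc = totals(model)
        r_l, r_c = scores(x_l, x_c, nl, nc)
        codon = _codon_at(
            genome[model.chrom], model.strand, anchor, model,
            tx_seqs.get(model.transcript_id) or model.sequence(genome),
        )
        rec = CalledTIS(
            model.gene_id, model.transcript_id, model.chrom, model.strand,
            anchor, codon or "NNN", "dbTIS", x_l, r_l, r_c, r_l - r_c,
            "rescued_dbTIS",
        )
        prev = rescued.get(key)
        if prev is None or rec.rdiff > prev.rdiff:
            rescued[key] = rec
    for key, rec in rescued.items():
        if key not in called:
            called[key] = rec

    # per-gene deduplication: one record per (gene, position), max rdiff kept
    best_by_gene: dict[tuple[str, int], CalledTIS] = {}
    for rec in called.values():
        key = (rec.gene, rec.position)
        prev = best_by_gene.get(key)
        if prev is None or rec.rdiff > prev.rdiff:
            best_by_gene[key] = rec
    out = sorted(
        best_by_gene.values(), key=lambda r: (r.chrom, r.position, r.strand, r.gene)
    )
    return out


# -- I/O ------------------------------------------------------------------

def write_tis_tsv(called: list[CalledTIS], path: str | Path) -> None:
    """Write called TIS as TSV with 1-based codon positions."""
    rows = [
        {
            "gene": r.gene,
            "transcript": r.transcript,
            "chrom": r.chrom,
            "strand": r.strand,
            "position": r.position + 1,
            "codon": r.codon,
            "category": r.category,
            "ltm_count": r.ltm_count,
            "r_ltm": round(r.r_ltm, 6),
            "r_chx": round(r.r_chx, 6),
            "rdiff": round(r.rdiff, 6),
            "status": r.status,
        }
        for r in called
    ]
    pd.DataFrame(
        rows,
        columns=[
            "gene", "transcript", "chrom", "strand", "position", "codon",
            "category", "ltm_count", "r_ltm", "r_chx", "rdiff", "status",
        ],
    ).to_csv(path, sep="\t", index=False)


def read_tis_tsv(path: str | Path) -> list[CalledTIS]:
    df = pd.read_csv(path, sep="\t")
    return [
        CalledTIS(
            r.gene, r.transcript, r.chrom, r.strand, int(r.position) - 1, r.codon,
            r.category, int(r.ltm_count), float(r.r_ltm), float(r.r_chx),
            float(r.rdiff), r.status,
        )
        for r in df.itertuples()
    ]
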