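"""Proteoform search database construction from called TIS.

Each called, unannotated TIS is translated in silico into a proteoform
sequence (initiator tRNA decodes AUG and near-cognate starts alike as Met)
and appended to the annotated proteome with a systematic, self-describing
accession ``GENE|TIS:<chrom>:<pos>:<codon>|<relation>``.  In-frame TIS
downstream of an annotated start yield N-terminally truncated proteoforms
that are exact suffixes of their parent protein apart from residue 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio.Seq import Seq

from .models import TranscriptModel, revcomp
from .tis_caller import CalledTIS

__all__ = [
    "Proteoform",
    "translate_from_tis",
    "translate_cds",
    "build_database",
    "write_fasta",
    "read_fasta",
]

STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class Proteoform:
    accession: str
    gene: str
    transcript: str
    sequence: str
    start_codon: str
    relation: str  # annotated | truncated_dTIS | extended | leader_ORF | intergenic_ORF
    parent_offset: int  # 0-based residue offset into the parent for truncations, else -1
    no_stop: bool = False
    chrom: str = ""
    position: int = -1  # genomic first nt of the start codon, 0-based


def translate_cds(nt_seq: str) -> str:
    """Plain codon-table translation up to (excluding) the first stop."""
    trimmed = nt_seq[: len(nt_seq) - len(nt_seq) % 3]
    aa = str(Seq(trimmed).translate())
    stop = aa.find("*")
    return aa if stop < 0 else aa[:stop]


def translate_from_tis(tx_seq: str, tis: int) -> tuple[str, bool]:
    """Translate from a TIS (transcript coordinate of the codon first nt).

    Residue 1 is always Met regardless of the start codon.  Returns the
    amino-acid sequence and a flag set when no in-frame stop was reached
    before the transcript end.
    """
    if tis < 0 or tis + 3 > len(tx_seq):
        raise ValueError(f"TIS at {tis} outside transcript of length {len(tx_seq)}")
    body = tx_seq[tis + 3:]
    body = body[: len(body) - len(body) % 3]
    aa = str(Seq(body).translate())
    stop = aa.find("*")
    if stop < 0:
        return "M" + aa, True
    return "M" + aa[:stop], False


def _proteoform_for_tis(
    tis: CalledTIS, model: TranscriptModel, genome: dict[str, str],
    tx_seq: str,
) -> Proteoform | None:
    t = model.g2t(tis.position)
    if t is None:
        raise ValueError(
            f"TIS at {tis.chrom}:{tis.position + 1} not exonic in {model.transcript_id}"
        )
    cs = model.cds_start_tx
    if tis.category == "cds_dTIS_inframe":
        relation = "truncated_dTIS"
        parent_offset = (t - cs) // 3
    elif tis.category == "leader5":
        in_frame = (cs - t) % 3 == 0
        run = translate_cds(tx_seq[t + 3:])
        reaches_cds = 3 * len(run) + 3 > cs - t
        relation = "extended" if in_frame and reaches_cds else "leader_ORF"
        parent_offset = -1
    elif tis.category == "leader3":
        relation = "leader_ORF"
        parent_offset = -1
    else:
        return None
    seq, no_stop = translate_from_tis(tx_seq, t)
    return Proteoform(
        accession="",
        gene=tis.gene,
        transcript=model.transcript_id,
        sequence=seq,
        start_codon=tis.codon,
        relation=relation,
        parent_offset=parent_offset,
        no_stop=no_stop,
        chrom=tis.chrom,
        position=tis.position,
    )


def _intergenic_proteoform(
    tis: CalledTIS, genome: dict[str, str], max_nt: int = 3000
) -> Proteoform:
    seq = genome[tis.chrom]
    if tis.strand == "+":
        window = seq[tis.position: tis.position + max_nt]
    else:
        window = revcomp(seq[max(0, tis.position - max_nt + 1): tis.position + 1])
    aa, no_stop = translate_from_tis(window, 0)
    return Proteoform(
        accession="", gene=tis.gene, transcript="-", sequence=aa,
        start_codon=tis.codon, relation="intergenic_ORF", parent_offset=-1,
        no_stop=no_stop, chrom=tis.chrom, position=tis.position,
    )


def build_database(
    proteome: dict[str, str],
    called: list[CalledTIS],
    models: list[TranscriptModel],
    genome: dict[str, str],
    min_length: int = 7,
) -> tuple[list[Proteoform], pd.DataFrame]:
    """Annotated entries first, then unique alternative proteoforms.

    Exact duplicate sequences are collapsed onto the first accession; the
    mapping table records every entry's genomic origin and cross-references
    collapsed duplicates.  Out-of-frame CDS-internal TIS are reported by the
    caller but are not translated here.
    """
    by_tid = {m.transcript_id: m for m in models}
    entries: list[Proteoform] = []
    for acc in proteome:
        entries.append(
            Proteoform(acc, acc.split(".")[0], acc, proteome[acc], "ATG",
                       "annotated", -1)
        )
    seen: dict[str, str] = {p.sequence: p.accession for p in entries}
    rows = [
        {
            "accession": p.accession, "gene": p.gene, "transcript": p.transcript,
            "chrom": p.chrom, "position": p.position + 1 if p.position >= 0 else "",
            "codon": p.start_codon, "relation": p.relation,
            "parent_offset": p.parent_offset, "no_stop": p.no_stop,
            "duplicate_of": "",
        }
        for p in entries
    ]
    tx_seq_cache: dict[str, str] = {}
    for tis in called:
        if tis.category in ("dbTIS", "cds_other_frame"):
            continue
        if tis.category == "intergenic":
            pf = _intergenic_proteoform(tis, genome)
        else:
            model = by_tid.get(tis.transcript)
            if model is None:
                raise ValueError(f"called TIS references unknown transcript {tis.transcript}")
            tseq = tx_seq_cache.setdefault(tis.transcript, model.sequence(genome))
            pf = _proteoform_for_tis(tis, model, genome, tseq)
        if pf is None or len(pf.sequence) < min_length:
            continue
        pf.accession = f"{pf.gene}|TIS:{pf.chrom}:{pf.position + 1}:{pf.start_codon}|{pf.relation}"
        dup = seen.get(pf.sequence, "")
        row = {
            "accession": pf.accession, "gene": pf.gene, "transcript": pf.transcript,
            "chrom": pf.chrom, "position": pf.position + 1, "codon": pf.start_codon,
            "relation": pf.relation, "parent_offset": pf.parent_offset,
            "no_stop": pf.no_stop, "duplicate_of": dup,
        }
        rows.append(row)
        if not dup:
            seen[pf.sequence] = pf.accession
            entries.append(pf)
    mapping = pd.DataFrame(rows)
    return entries, mapping


def write_fasta(entries: list[Proteoform], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for p in entries:
            fh.write(f">{p.accession}\n")
            for i in range(0, len(p.sequence), width):
                fh.write(p.sequence[i:i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = ""
            elif name is not None:
                seqs[name] += line
    return seqs
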