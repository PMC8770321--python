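"""Filtering, collapsing and classification of N-terminal peptide evidence.

Protein N-termini observed by positional (N-terminomics) proteomics are
filtered on PSM q-value, collapsed per (protein, start) to the longest
peptide variant across enzymes and missed cleavages, checked against the
co-translational enzymatic rules of initiator-Met excision (NME, by Met
aminopeptidases) and N-terminal acetylation (NTA, by the NatA/NatB/NatC-E-F
N-acetyltransferase classes), and assigned an origin: annotated start
(dbTIS), downstream in-frame TIS (dTIS), transit-peptide neo-terminus
(cTP/mTP), ambiguous dual dTIS/cTP, or internal proteolytic neo-terminus.

NME exposes residue 2 only when it is small (A, C, G, P, S, T, V by MetAP
specificity); a retained initiator Met is therefore only NME-consistent in
strict mode when residue 2 is *not* small.  NatA acetylates small exposed
residues, NatB Met-acidic/amide (MD/ME/MN/MQ) termini, NatC/E/F Met-bulky
termini, and Pro N-termini are refractory to acetylation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "NME_SMALL",
    "NATA_RESIDUES",
    "NATB_SECOND",
    "NATCEF_SECOND",
    "NtPSM",
    "NTermRecord",
    "filter_psms",
    "collapse",
    "nme_compliant",
    "nat_class",
    "classify_origin",
    "read_psm_tsv",
    "write_nterm_tsv",
]

#: MetAP cleavage requires a small penultimate residue.
NME_SMALL = frozenset("ACGPSTV")
#: NatA substrates: small residues exposed after iMet removal.
NATA_RESIDUES = frozenset("ASTVGC")
#: NatB substrates: retained Met followed by Asp/Glu/Asn/Gln.
NATB_SECOND = frozenset("DENQ")
#: NatC/E/F substrates: retained Met followed by a bulky/basic residue.
NATCEF_SECOND = frozenset("LIFWYKHRM")

MODIFICATIONS = {"light_acetyl", "free_heavy", "unmodified"}


@dataclass
class NtPSM:
    peptide: str
    protein: str
    start: int  # 1-based position in the protein; iMet = 1
    modification: str  # light_acetyl (in vivo NTA) | free_heavy | unmodified
    enzyme: str = "trypsin"
    q_value: float = 0.0
    intensity_light: float = float("nan")
    intensity_heavy: float = float("nan")

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if not 0.0 <= self.q_value <= 1.0:
            raise ValueError(f"q-value outside [0,1]: {self.q_value}")


@dataclass
class NTermRecord:
    protein: str
    start: int
    peptide: str  # longest (representative) peptide
    psm_count_total: int
    psm_count_nta: int
    psm_count_free: int
    low_evidence: bool = False
    nme_compliant: bool | None = None
    nat_class: str = "none"
    origin: str = "internal_neo"
    supporting_tis: str = ""
    supporting_cleavage: str = ""
    nta_conflict: bool = False

    @property
    def has_nta(self) -> bool:
        """NTA status requires at least one in vivo (light) acetyl PSM."""
        return self.psm_count_nta >= 1


def filter_psms(
    psms: list[NtPSM], q_max: float = 0.01
) -> tuple[list[NtPSM], int]:
    """Keep PSMs at or below the q-value cutoff; return (kept, n_rejected)."""
    kept = [p for p in psms if p.q_value <= q_max]
    return kept, len(psms) - len(kept)


def collapse(psms: list[NtPSM], min_psm: int = 2) -> list[NTermRecord]:
    """Collapse PSMs sharing (protein, start) onto the longest peptide.

    N-termini supported by fewer than *min_psm* PSMs are kept but flagged
    low-evidence.  Peptides at one start must agree where they overlap;
    conflicting residues raise with the offending records named.
    """
    groups: dict[tuple[str, int], list[NtPSM]] = {}
    for p in psms:
        groups.setdefault((p.protein, p.start), []).append(p)
    records = []
    for (protein, start), group in sorted(groups.items()):
        longest = max(group, key=lambda p: len(p.peptide))
        for p in group:
            if longest.peptide[: len(p.peptide)] != p.peptide:
                raise ValueError(
                    f"conflicting peptides at {protein} start {start}: "
                    f"{p.peptide!r} vs {longest.peptide!r}"
                )
        nta = sum(1 for p in group if p.modification == "light_acetyl")
        records.append(
            NTermRecord(
                protein=protein,
                start=start,
                peptide=longest.peptide,
                psm_count_total=len(group),
                psm_count_nta=nta,
                psm_count_free=len(group) - nta,
                low_evidence=len(group) < min_psm,
            )
        )
    return records


def nme_compliant(
    start: int, parent: str, strict: bool = True,
    small: frozenset = NME_SMALL,
) -> bool | None:
    """Is an N-terminus at iMet (start 1) or iMet+1 (start 2) NME-consistent?

    *parent* is the proteoform sequence beginning at its initiator Met.
    Start 2 is compliant when the exposed residue is small; start 1 is
    compliant in strict mode only when residue 2 is not small (MetAPs would
    have removed the iMet otherwise) and always in lenient mode.  Other
    starts are not TIS-indicative: returns None.
    """
    if start == 2:
        return len(parent) > 1 and parent[1] in small
    if start == 1:
        if not strict:
            return True
        return len(parent) > 1 and parent[1] not in small
    return None


def nat_class(residues: str, imet_retained: bool) -> str:
    """NAT class of a mature N-terminus given its first residue(s).

    *residues* begins at the mature (observed) N-terminus.
    """
    if not residues:
        return "none"
    first = residues[0]
    if imet_retained:
        if first != "M" or len(residues) < 2:
            return "none"
        second = residues[1]
        if second in NATB_SECOND:
            return "NatB"
        if second in NATCEF_SECOND:
            return "NatCEF"
        return "none"
    if first == "P":
        return "refractory"
    if first in NATA_RESIDUES:
        return "NatA"
    return "none"


@dataclass
class OriginContext:
    """Everything needed to place one observed N-terminus.

    ``annotated_length``: length of the annotated (parent) protein, 0 if the
    accession is not an annotated entry.  ``dtis_starts``: 1-based iMet
    positions, in parent coordinates, of called in-frame dTIS for this
    protein.  ``cleavage``: transit-peptide matches as (prediction, P1')
    pairs from the cleavage annotator.
    """

    parent: str = ""
    annotated: bool = True
    dtis_starts: frozenset[int] = frozenset()
    cleavage: tuple[tuple[str, int], ...] = ()
    window: int = 5


def classify_origin(
    record: NTermRecord, ctx: OriginContext, strict_nme: bool = True
) -> NTermRecord:
    """Assign exactly one origin label to a collapsed N-terminus.

    Precedence: annotated start (1/2) -> dbTIS; then a called dTIS match at
    its iMet or iMet+1, demanding NME compliance (near-cognate starts
    exposing bulky residues are demoted to neo-termini); transit-peptide
    window matches give cTP_neo/mTP_neo, and a simultaneous dTIS and cTP
    match the ambiguous dual label.  Everything else is an internal
    neo-terminus.
    """
    start = record.start
    # dbTIS precedence: start 1/2 of an annotated protein
    if ctx.annotated and start in (1, 2):
        record.origin = "dbTIS"
        record.nme_compliant = nme_compliant(start, ctx.parent, strict_nme)
        record.nat_class = nat_class(ctx.parent[start - 1:], imet_retained=start == 1)
        _flag_nta_conflict(record)
        return record

    dtis_hit = None
    for imet in sorted(ctx.dtis_starts):
        if start in (imet, imet + 1):
            sub = ctx.parent[imet - 1:]
            ok = nme_compliant(start - imet + 1, sub, strict_nme)
            if ok:
                dtis_hit = (imet, sub)
                break
    cleav_hit = None
    for pred, p1p in ctx.cleavage:
        if abs(start - p1p) <= ctx.window:
            cleav_hit = (pred, p1p)
            break

    if dtis_hit and cleav_hit and cleav_hit[0] == "cTP":
        imet, sub = dtis_hit
        record.origin = "dual_dTIS_cTP"
        record.nme_compliant = True
        record.nat_class = nat_class(
            ctx.parent[start - 1:], imet_retained=start == imet
        )
        record.supporting_tis = f"iMet{imet}"
        record.supporting_cleavage = f"{cleav_hit[0]}:P1'={cleav_hit[1]}"
    elif dtis_hit:
        imet, sub = dtis_hit
        record.origin = "dTIS"
        record.nme_compliant = True
        record.nat_class = nat_class(
            ctx.parent[start - 1:], imet_retained=start == imet
        )
        record.supporting_tis = f"iMet{imet}"
    elif cleav_hit:
        record.origin = "cTP_neo" if cleav_hit[0] == "cTP" else "mTP_neo"
        record.nme_compliant = None
        record.nat_class = nat_class(ctx.parent[start - 1:], imet_retained=False)
        record.supporting_cleavage = f"{cleav_hit[0]}:P1'={cleav_hit[1]}"
    else:
        record.origin = "internal_neo"
        record.nme_compliant = None
        record.nat_class = nat_class(ctx.parent[start - 1:], imet_retained=False)
    _flag_nta_conflict(record)
    return record


def _flag_nta_conflict(record: NTermRecord) -> None:
    """Acetylation observed on a NAT-refractory N-terminus is flagged, not rejected."""
    record.nta_conflict = record.nat_class == "refractory" and record.has_nta


# -- I/O ------------------------------------------------------------------

PSM_COLUMNS = [
    "peptide", "protein", "start", "modification", "enzyme", "q_value",
    "intensity_light", "intensity_heavy",
]


def read_psm_tsv(path: str | Path) -> list[NtPSM]:
    df = pd.read_csv(path, sep="\t")
    return [
        NtPSM(
            r.peptide, r.protein, int(r.start), r.modification, r.enzyme,
            float(r.q_value), float(r.intensity_light), float(r.intensity_heavy),
        )
        for r in df.itertuples()
    ]


def write_nterm_tsv(records: list[NTermRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "protein": r.protein,
                "start": r.start,
                "peptide": r.peptide,
                "psm_total": r.psm_count_total,
                "psm_nta": r.psm_count_nta,
                "psm_free": r.psm_count_free,
                "low_evidence": r.low_evidence,
                "nme_compliant": r.nme_compliant,
                "nat_class": r.nat_class,
                "origin": r.origin,
                "supporting_tis": r.supporting_tis,
                "supporting_cleavage": r.supporting_cleavage,
                "nta_conflict": r.nta_conflict,
            }
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)
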