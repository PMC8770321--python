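"""Transit-peptide cleavage matching, representative selection and motifs.

Observed neo-N-termini are matched to predicted N-terminal sorting-signal
cleavage sites when their start lies in the P5-P5' region around the
predicted P1' (deviation |start - P1'| <= 5 by default; an exclusive
"< window" reading is available).  Because stromal aminopeptidases further
trim the primary processed terminus, starts clustering within five residues
are merged and the most upstream N-terminus represents the primary cleavage
event; representatives feed a P5..P1/P1'..P5' residue-frequency matrix of
the cleavage motif.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CleavagePrediction",
    "NeoTerminusMatch",
    "MotifMatrix",
    "match_cleavage",
    "cluster_starts",
    "select_representative",
    "motif_matrix",
    "flag_mito_nta",
    "read_targetp_tsv",
    "read_localization_tsv",
]

PREDICTIONS = ("cTP", "mTP", "SP", "luTP", "noTP")
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
MOTIF_POSITIONS = ["P5", "P4", "P3", "P2", "P1", "P1'", "P2'", "P3'", "P4'", "P5'"]


@dataclass(frozen=True)
class CleavagePrediction:
    protein: str
    prediction: str  # cTP | mTP | SP | luTP | noTP
    site: int  # presequence length = P1 position (1-based); 0 for noTP

    def __post_init__(self) -> None:
        if self.prediction not in PREDICTIONS:
            raise ValueError(f"unknown prediction {self.prediction!r}")
        if self.prediction != "noTP" and self.site < 1:
            raise ValueError(f"positive prediction needs site >= 1: {self!r}")

    @property
    def p1_prime(self) -> int:
        return self.site + 1


@dataclass
class NeoTerminusMatch:
    protein: str
    start: int  # 1-based mature N-terminus position
    prediction: str
    p1_prime: int
    deviation: int  # start - P1' (negative = upstream of P1')
    is_representative: bool = False


def match_cleavage(
    start: int,
    prediction: CleavagePrediction,
    window: int = 5,
    inclusive: bool = True,
) -> NeoTerminusMatch | None:
    """Match an observed start to a predicted cleavage P1' within the window."""
    if prediction.prediction == "noTP":
        return None
    dev = start - prediction.p1_prime
    hit = abs(dev) <= window if inclusive else abs(dev) < window
    if not hit:
        return None
    return NeoTerminusMatch(
        prediction.protein, start, prediction.prediction, prediction.p1_prime, dev
    )


def cluster_starts(starts: list[int], gap: int = 5) -> list[list[int]]:
    """Transitive linkage of starts no more than *gap* residues apart."""
    clusters: list[list[int]] = []
    for s in sorted(starts):
        if clusters and s - clusters[-1][-1] <= gap:
            clusters[-1].append(s)
        else:
            clusters.append([s])
    return clusters


def select_representative(
    matches: list[NeoTerminusMatch],
    localization: dict[str, str],
    compartment: str = "chloroplast",
    gap: int = 5,
) -> tuple[list[NeoTerminusMatch], list[str]]:
    """Most-upstream start per within-gap cluster, per protein.

    Only proteins whose consensus subcellular localization equals
    *compartment* are considered; proteins absent from the localization
    table are excluded and reported.
    """
    excluded: list[str] = []
    by_protein: dict[str, list[NeoTerminusMatch]] = {}
    for m in matches:
        loc = localization.get(m.protein)
        if loc is None:
            if m.protein not in excluded:
                excluded.append(m.protein)
            continue
        if loc != compartment:
            continue
        by_protein.setdefault(m.protein, []).append(m)
    reps: list[NeoTerminusMatch] = []
    for protein in sorted(by_protein):
        group = by_protein[protein]
        by_start = {m.start: m for m in group}
        for cluster in cluster_starts([m.start for m in group], gap=gap):
            rep = by_start[min(cluster)]
            rep.is_representative = True
            reps.append(rep)
    return reps, excluded


@dataclass
class MotifMatrix:
    """P5..P5' residue frequencies around representative cleavage sites."""

    frequencies: pd.DataFrame  # index: residues (+ gap), columns: MOTIF_POSITIONS
    n_sites: int

    def enrichment(self, background: dict[str, float]) -> pd.DataFrame:
        """log2 frequency over a supplied background residue distribution."""
        bg = pd.Series({aa: background.get(aa, np.nan) for aa in AMINO_ACIDS})
        freq = self.frequencies.loc[list(AMINO_ACIDS)]
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.log2(freq.div(bg, axis=0))


def motif_matrix(
    representatives: list[NeoTerminusMatch],
    sequences: dict[str, str],
) -> MotifMatrix:
    """Frequency matrix over the 10 residues flanking each representative start.

    The mature N-terminus (start, 1-based) occupies P1'; sites closer than
    five residues to the protein start are padded with a gap symbol.
    """
    rows = list(AMINO_ACIDS) + [GAP]
    counts = pd.DataFrame(0.0, index=rows, columns=MOTIF_POSITIONS)
    n = 0
    for m in representatives:
        seq = sequences.get(m.protein)
        if seq is None:
            continue
        n += 1
        for k, pos_name in enumerate(MOTIF_POSITIONS):
            idx = m.start - 6 + k  # 0-based residue index; P5 = start-5 (1-based)
            if 0 <= idx < len(seq) and seq[idx] in counts.index:
                counts.loc[seq[idx], pos_name] += 1
            else:
                counts.loc[GAP, pos_name] += 1
    if n > 0:
        counts /= n
    return MotifMatrix(frequencies=counts, n_sites=n)


def flag_mito_nta(
    matches: list[NeoTerminusMatch], nta_by_start: dict[tuple[str, int], bool]
) -> list[NeoTerminusMatch]:
    """Mitochondrial cleavage matches observed N-terminally acetylated.

    No NTA machinery is known in mitochondria, so these likely reflect
    mispredicted or ambiguous targeting peptides and are surfaced for review.
    """
    return [
        m
        for m in matches
        if m.prediction == "mTP" and nta_by_start.get((m.protein, m.start), False)
    ]


# -- I/O ------------------------------------------------------------------

def read_targetp_tsv(path: str | Path) -> list[CleavagePrediction]:
    """TargetP-style table: protein, prediction, cleavage site (presequence length)."""
    df = pd.read_csv(path, sep="\t")
    return [
        CleavagePrediction(r.protein, r.prediction, int(r.site)) for r in df.itertuples()
    ]


def read_localization_tsv(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["protein"], df["localization"]))
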