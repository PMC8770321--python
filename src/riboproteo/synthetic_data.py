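"""Synthetic riboproteogenomics data with planted ground truth.

Generates a toy genome and annotation, LTM/CHX footprint alignments, an
N-terminal PSM table with light/heavy acetyl intensity pairs, and transit-
peptide prediction and localization tables, all derived from one seeded
configuration so that every downstream stage can be tested against known
truth.  The generator emulates the structures the real libraries show:
initiating-ribosome (LTM) peaks at start codons with optional +-1 nt
jitter, elongating (CHX) coverage with triplet periodicity and 5'->3'
exponential decay, leaky-scanning downstream initiation, upstream ORFs,
NME/NAT-rule-obeying N-terminal peptides with class-specific acetylation
degrees, ragged aminopeptidase-trimmed stromal neo-termini downstream of
planted transit-peptide cleavage sites (carrying a (V/I)-X-(A/C)|A motif),
and log-normal MS1 intensity noise.

Simulation is transcript-space first: genes are built as 5' leader + CDS +
3' leader, optionally interrupted by a GT..AG intron, then projected
through the exon map onto the genome (half the genes on the minus strand),
so junction-spanning arithmetic is exercised throughout.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .footprints import AlignedRead, psite_offset
from .models import TranscriptModel, revcomp
from .nterm_classifier import NME_SMALL, nat_class
from .proteoform_db import translate_cds
from .tis_caller import NEAR_COGNATES

__all__ = [
    "SimConfig",
    "GroundTruth",
    "PlantedTIS",
    "PlantedCleavage",
    "PlantedNTerm",
    "simulate_genome",
    "simulate_footprints",
    "simulate_psm_table",
    "simulate_intensity_pair",
    "write_outputs",
]

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: sense codons per residue (no stops)
CODONS_BY_AA: dict[str, list[str]] = {}
_BASES = "TCAG"
_TABLE = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
for _i, _aa in enumerate(_TABLE):
    if _aa == "*":
        continue
    _codon = _BASES[_i // 16] + _BASES[_i // 4 % 4] + _BASES[_i % 4]
    CODONS_BY_AA.setdefault(_aa, []).append(_codon)

AA_BY_CODON = {c: aa for aa, cs in CODONS_BY_AA.items() for c in cs}

DEFAULT_READ_LENGTHS = {
    26: 0.05, 27: 0.08, 28: 0.25, 29: 0.20, 30: 0.15,
    31: 0.12, 32: 0.08, 33: 0.05, 34: 0.02,
}

#: planted per-class co-translational NTA degrees (percent); high for NatA/NatB
#: substrates, low for NatC/E/F-type Met-bulky termini, absent on Pro.
DEFAULT_NTA_BY_CLASS = {
    "NatA": 85.0, "NatB": 95.0, "NatCEF": 10.0, "refractory": 0.0, "none": 5.0,
}
#: planted residue-specific post-translational (stromal) degrees.
DEFAULT_STROMAL_NTA = {"A": 34.9, "S": 36.3, "V": 60.3, "T": 45.0}


@dataclass
class SimConfig:
    seed: int = 0
    n_genes: int = 20
    gene_length_range: tuple[int, int] = (180, 540)  # CDS nt, rounded to codons
    utr5_length_range: tuple[int, int] = (60, 180)
    utr3_length_range: tuple[int, int] = (40, 120)
    intron_genes_fraction: float = 0.3
    dtis_fraction: float = 0.5
    leaky_fraction: float = 0.3
    uorf_fraction: float = 0.2
    ltm_reads_per_tis: float = 100.0
    chx_reads_per_gene: float = 200.0
    chx_decay: float = 0.004  # per-nt 5'->3' exponential decay constant
    periodicity_weight: float = 0.85  # fraction of CHX P-sites on frame 0
    read_length_distribution: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_READ_LENGTHS)
    )
    ltm_jitter: float = 0.2  # fraction of LTM P-sites offset by +-1 nt
    noise_fraction: float = 0.05  # off-target reads per treatment
    enzyme_set: tuple[str, ...] = ("trypsin", "gluc")
    nta_degree_by_class: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_NTA_BY_CLASS)
    )
    stromal_nta_degree_by_residue: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STROMAL_NTA)
    )
    trimming_range: tuple[int, int] = (0, 3)  # aminopeptidase ragging, residues
    intensity_noise_cv: float = 0.10
    psms_per_enzyme: tuple[int, int] = (2, 5)
    decoy_fraction: float = 0.1
    ctp_fraction: float = 0.3
    mtp_fraction: float = 0.1
    dual_fraction: float = 0.5  # of cTP+dTIS genes, share with coinciding sites
    internal_neo_fraction: float = 0.1
    intergenic_spacer_range: tuple[int, int] = (200, 400)

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        for name in (
            "intron_genes_fraction", "dtis_fraction", "leaky_fraction",
            "uorf_fraction", "ltm_jitter", "noise_fraction", "decoy_fraction",
            "ctp_fraction", "mtp_fraction", "dual_fraction",
            "internal_neo_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        for name in ("gene_length_range", "utr5_length_range", "utr3_length_range"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"degenerate {name}: ({lo}, {hi})")
        if self.gene_length_range[0] < 150:
            raise ValueError("CDS length must allow planted features (>= 150 nt)")
        if self.utr5_length_range[0] < 40:
            raise ValueError("5' leader must be >= 40 nt for P-site offsets")
        if any(not 26 <= k <= 34 for k in self.read_length_distribution):
            raise ValueError("read lengths restricted to 26-34 nt")
        if abs(sum(self.read_length_distribution.values()) - 1.0) > 1e-6:
            raise ValueError("read length distribution must sum to 1")


@dataclass
class PlantedTIS:
    gene: str
    transcript: str
    tx_pos: int
    genomic_pos: int
    codon: str
    category: str  # dbTIS | cds_dTIS_inframe | leader5


@dataclass
class PlantedCleavage:
    protein: str
    prediction: str  # cTP | mTP
    p1_prime: int  # 1-based first mature residue
    trims: list[int]  # realized aminopeptidase offsets (0 = primary site)


@dataclass
class PlantedNTerm:
    protein: str
    start: int  # 1-based in the annotated protein
    origin: str  # dbTIS | dTIS | cTP_neo | mTP_neo | dual_dTIS_cTP | internal_neo
    nat_class: str
    degree: float  # planted percent NTA
    imet_retained: bool


@dataclass
class GroundTruth:
    tis: list[PlantedTIS]
    proteoforms: dict[str, str]  # annotated protein per transcript accession
    dtis_proteoforms: dict[str, str]  # truncated proteoform per parent accession
    dtis_imet: dict[str, int]  # parent accession -> 1-based dTIS iMet residue
    cleavages: list[PlantedCleavage]
    ntermini: list[PlantedNTerm]
    localization: dict[str, str]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "tis": [asdict(t) for t in self.tis],
            "proteoforms": self.proteoforms,
            "dtis_proteoforms": self.dtis_proteoforms,
            "dtis_imet": self.dtis_imet,
            "cleavages": [asdict(c) for c in self.cleavages],
            "ntermini": [asdict(n) for n in self.ntermini],
            "localization": self.localization,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def _choose_codon(rng: np.random.Generator, aa: str) -> str:
    options = CODONS_BY_AA[aa]
    return options[rng.integers(len(options))]


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def simulate_genome(
    config: SimConfig,
) -> tuple[dict[str, str], list[TranscriptModel], GroundTruth]:
    """Build the toy genome, annotation and full planted ground truth."""
    config.validate()
    rng = np.random.default_rng([config.seed, 11])
    chrom_parts: list[str] = []
    models: list[TranscriptModel] = []
    truth = GroundTruth([], {}, {}, {}, [], [], {})
    offset = 0
    chrom = "chr1"

    for i in range(config.n_genes):
        gene_id = f"SYNG{i + 1:04d}"
        tid = f"{gene_id}.1"
        strand = "+" if i % 2 == 0 else "-"
        n_cod = int(rng.integers(*[x // 3 for x in config.gene_length_range])) + 1
        utr5 = int(rng.integers(*config.utr5_length_range))
        utr3 = int(rng.integers(*config.utr3_length_range))

        residues = ["M"] + list(rng.choice(list(AA_ALPHABET), size=n_cod - 1))

        # ---- plant a downstream in-frame TIS -----------------------------
        has_dtis = rng.random() < config.dtis_fraction and n_cod >= 40
        k = 0
        dtis_codon = ""
        if has_dtis:
            k = int(rng.integers(9, n_cod - 25))  # 1-based residue index of dTIS iMet
            if rng.random() < 0.7:
                dtis_codon = "ATG"
            else:
                dtis_codon = sorted(NEAR_COGNATES)[rng.integers(len(NEAR_COGNATES))]
            residues[k - 1] = AA_BY_CODON[dtis_codon]
            # the residue after the dTIS iMet decides the mature N-terminus;
            # near-cognate starts are always given an NME-permissive residue
            u = rng.random()
            small = sorted(NME_SMALL - {"P"})
            if dtis_codon != "ATG" or u < 0.55:
                residues[k] = small[rng.integers(len(small))]
            elif u < 0.75:
                residues[k] = "DENQ"[rng.integers(4)]
            else:
                residues[k] = "LIFWYKHR"[rng.integers(8)]

        # ---- plant a transit peptide and its cleavage site ---------------
        r = rng.random()
        target = "cTP" if r < config.ctp_fraction else (
            "mTP" if r < config.ctp_fraction + config.mtp_fraction else "none"
        )
        c = 0
        dual = False
        if target != "none":
            dual = (
                target == "cTP" and has_dtis and rng.random() < config.dual_fraction
            )
            if dual:
                c = k + 1
                residues[c - 1] = "A"  # exposed/processed residue; P1 stays the iMet
            else:
                hi = max(37, min(60, n_cod - 25))
                options = [
                    x for x in range(36, hi)
                    if not has_dtis or abs(x - k) > 10
                ]
                if not options:
                    target = "none"
                else:
                    c = int(options[rng.integers(len(options))])
                    # plant the (V/I)-X-(A/C)|A processing-peptidase motif
                    residues[c - 4] = "VI"[rng.integers(2)]
                    residues[c - 2] = "AC"[rng.integers(2)]
                    residues[c - 1] = "A"

        # ---- internal proteolytic neo-terminus ---------------------------
        m_int = 0
        if rng.random() < config.internal_neo_fraction:
            cand = int(rng.integers(n_cod // 2, n_cod - 12))
            if (not has_dtis or abs(cand - k) > 10) and (c == 0 or abs(cand - c) > 10):
                m_int = cand

        # ---- assemble the CDS --------------------------------------------
        codons = [_choose_codon(rng, aa) for aa in residues]
        codons[0] = "ATG"
        if has_dtis:
            codons[k - 1] = dtis_codon
        stop = ["TAA", "TAG", "TGA"][rng.integers(3)]
        cds = "".join(codons) + stop
        cds_nt = len(cds)

        # ---- 5' leader, optional uORF, 3' leader --------------------------
        leader5 = _random_seq(rng, utr5)
        uorf_pos = -1
        if rng.random() < config.uorf_fraction and utr5 >= 60:
            n_uorf_cod = int(rng.integers(7, 10))
            uorf_pos = int(rng.integers(20, utr5 - 3 * (n_uorf_cod + 1) - 3))
            uorf_res = rng.choice(list(AA_ALPHABET), size=n_uorf_cod - 1)
            uorf_seq = "ATG" + "".join(_choose_codon(rng, aa) for aa in uorf_res) + "TAA"
            leader5 = (
                leader5[:uorf_pos] + uorf_seq + leader5[uorf_pos + len(uorf_seq):]
            )
        leader3 = _random_seq(rng, utr3)
        tx = leader5 + cds + leader3

        # ---- optional intron, sense-space exons ---------------------------
        sense_exons = [(0, len(tx))]
        gene_sense = tx
        if rng.random() < config.intron_genes_fraction:
            cut = utr5 + int(rng.integers(30, cds_nt - 30))
            ilen = int(rng.integers(60, 120))
            intron = "GT" + _random_seq(rng, ilen - 4) + "AG"
            gene_sense = tx[:cut] + intron + tx[cut:]
            sense_exons = [(0, cut), (cut + ilen, len(gene_sense))]
        cds_sense = (utr5, len(gene_sense) - utr3)  # includes the intron if inside

        # ---- genomic placement --------------------------------------------
        spacer = _random_seq(rng, int(rng.integers(*config.intergenic_spacer_range)))
        chrom_parts.append(spacer)
        offset += len(spacer)
        gene_start = offset
        L = len(gene_sense)
        if strand == "+":
            chrom_parts.append(gene_sense)
            exons = [(gene_start + s, gene_start + e) for s, e in sense_exons]
            cds_g = (gene_start + cds_sense[0], gene_start + cds_sense[1])
        else:
            chrom_parts.append(revcomp(gene_sense))
            exons = [(gene_start + L - e, gene_start + L - s) for s, e in sense_exons]
            cds_g = (gene_start + L - cds_sense[1], gene_start + L - cds_sense[0])
        offset += L
        model = TranscriptModel(gene_id, tid, chrom, strand, exons, *cds_g)
        models.append(model)

        # ---- record ground truth ------------------------------------------
        parent = translate_cds(cds)
        truth.proteoforms[tid] = parent
        truth.localization[tid] = {
            "cTP": "chloroplast", "mTP": "mitochondrion", "none": "cytosol"
        }[target]

        def tis_entry(tx_pos: int, codon: str, category: str) -> PlantedTIS:
            return PlantedTIS(
                gene_id, tid, tx_pos, model.t2g(tx_pos), codon, category
            )

        truth.tis.append(tis_entry(utr5, "ATG", "dbTIS"))
        if uorf_pos >= 0:
            truth.tis.append(tis_entry(uorf_pos, "ATG", "leader5"))
        if has_dtis:
            truth.tis.append(
                tis_entry(utr5 + 3 * (k - 1), dtis_codon, "cds_dTIS_inframe")
            )
            truth.dtis_proteoforms[tid] = "M" + parent[k:]
            truth.dtis_imet[tid] = k

        def plant_nterm(start: int, origin: str, retained: bool, degree=None):
            cls = nat_class(parent[start - 1:], imet_retained=retained)
            if degree is None:
                degree = config.nta_degree_by_class.get(cls, 0.0)
            truth.ntermini.append(
                PlantedNTerm(tid, start, origin, cls, float(degree), retained)
            )

        # annotated N-terminus after NME
        if len(parent) > 1 and parent[1] in NME_SMALL:
            plant_nterm(2, "dbTIS", retained=False)
        else:
            plant_nterm(1, "dbTIS", retained=True)
        # dTIS-derived mature N-terminus
        if has_dtis and not dual:
            if parent[k] in NME_SMALL:
                plant_nterm(k + 1, "dTIS", retained=False)
            else:
                plant_nterm(k, "dTIS", retained=True)
        # transit-peptide neo-termini with ragged trimming
        if target != "none":
            trims = [0]
            if target == "cTP":
                lo, hi = config.trimming_range
                extra = sorted(
                    set(int(t) for t in rng.integers(lo, hi + 1, size=2) if t > 0)
                )
                trims += [t for t in extra if c + t <= len(parent)]
            truth.cleavages.append(PlantedCleavage(tid, target, c, trims))
            for t in trims:
                start = c + t
                res = parent[start - 1]
                if target == "mTP":
                    deg = 0.0
                else:
                    deg = config.stromal_nta_degree_by_residue.get(res, 15.0)
                origin = "dual_dTIS_cTP" if (dual and t == 0) else f"{target}_neo"
                if dual and t == 0:
                    cls = nat_class(parent[start - 1:], imet_retained=False)
                    deg = config.nta_degree_by_class.get(cls, 0.0)
                truth.ntermini.append(
                    PlantedNTerm(
                        tid, start, origin,
                        nat_class(parent[start - 1:], imet_retained=False),
                        float(deg), False,
                    )
                )
        if m_int > 0:
            plant_nterm(m_int, "internal_neo", retained=False, degree=0.0)

    chrom_parts.append(_random_seq(rng, 300))
    genome = {chrom: "".join(chrom_parts)}
    return genome, models, truth


# -- footprints ------------------------------------------------------------

def _draw_length(rng: np.random.Generator, config: SimConfig) -> int:
    lengths = sorted(config.read_length_distribution)
    probs = np.array([config.read_length_distribution[k] for k in lengths])
    return int(rng.choice(lengths, p=probs / probs.sum()))


def _emit_read(
    rng, config, model: TranscriptModel, psite_tx: int, jitter: bool
) -> AlignedRead | None:
    if jitter and rng.random() < config.ltm_jitter:
        psite_tx += int(rng.choice([-1, 1]))
    length = _draw_length(rng, config)
    five_tx = psite_tx - psite_offset(length)
    if not 0 <= five_tx < model.tx_length:
        return None
    return AlignedRead(model.chrom, model.t2g(five_tx), model.strand, length)


def simulate_footprints(
    genome: dict[str, str],
    models: list[TranscriptModel],
    truth: GroundTruth,
    config: SimConfig,
) -> tuple[list[AlignedRead], list[AlignedRead]]:
    """LTM reads at planted TIS (leaky scanning splits dbTIS/dTIS initiation
    events) and CHX reads over CDSs with triplet periodicity and decay."""
    config.validate()
    rng = np.random.default_rng([config.seed, 17])
    by_tid = {m.transcript_id: m for m in models}
    tis_by_tid: dict[str, dict[str, PlantedTIS]] = {}
    for t in truth.tis:
        tis_by_tid.setdefault(t.transcript, {})[t.category] = t

    ltm: list[AlignedRead] = []
    chx: list[AlignedRead] = []
    for tid, planted in tis_by_tid.items():
        model = by_tid[tid]
        db = planted["dbTIS"]
        dtis = planted.get("cds_dTIS_inframe")
        n_events = rng.poisson(config.ltm_reads_per_tis)
        for _ in range(n_events):
            site = db
            if dtis is not None and rng.random() < config.leaky_fraction:
                site = dtis
            read = _emit_read(rng, config, model, site.tx_pos, jitter=True)
            if read:
                ltm.append(read)
        uorf = planted.get("leader5")
        if uorf is not None:
            for _ in range(rng.poisson(config.ltm_reads_per_tis)):
                read = _emit_read(rng, config, model, uorf.tx_pos, jitter=True)
                if read:
                    ltm.append(read)

        # CHX: elongating coverage over the CDS
        cs = model.cds_start_tx
        n_codons = (model.cds_end_tx - cs) // 3
        weights = np.exp(-config.chx_decay * 3.0 * np.arange(n_codons))
        weights /= weights.sum()
        for _ in range(rng.poisson(config.chx_reads_per_gene)):
            j = int(rng.choice(n_codons, p=weights))
            frame = 0 if rng.random() < config.periodicity_weight else int(
                rng.choice([1, 2])
            )
            read = _emit_read(rng, config, model, cs + 3 * j + frame, jitter=False)
            if read:
                chx.append(read)

    # off-target noise reads, uniform over the genome
    chrom = next(iter(genome))
    glen = len(genome[chrom])
    for pool in (ltm, chx):
        n_noise = int(round(config.noise_fraction * len(pool)))
        for _ in range(n_noise):
            length = _draw_length(rng, config)
            strand = "+" if rng.random() < 0.5 else "-"
            pos = int(rng.integers(40, glen - 40))
            pool.append(AlignedRead(chrom, pos, strand, length))
    return ltm, chx


# -- PSM / proteomics tables ----------------------------------------------

_ENZYME_SITES = {"trypsin": "KR", "gluc": "ED"}


def simulate_intensity_pair(
    rng: np.random.Generator, degree_percent: float, cv: float
) -> tuple[float, float]:
    """One light/heavy precursor intensity pair at a planted NTA degree.

    The light fraction L/(L+H) has expectation ~ degree with multiplicative
    log-normal noise of the given coefficient of variation on each channel;
    degrees of exactly 0 or 100 give an exactly-zero channel.
    """
    p = degree_percent / 100.0
    total = float(rng.lognormal(np.log(1e6), 0.5))
    light = total * p * float(np.exp(rng.normal(0.0, cv))) if p > 0 else 0.0
    heavy = total * (1 - p) * float(np.exp(rng.normal(0.0, cv))) if p < 1 else 0.0
    return light, heavy


def _nterm_peptide(seq: str, start: int, enzyme: str, min_len: int = 7) -> str:
    """N-terminal peptide from *start* (1-based) to the first enzymatic
    cleavage site giving at least *min_len* residues."""
    sites = _ENZYME_SITES[enzyme]
    s0 = start - 1
    for i in range(s0 + min_len - 1, len(seq)):
        if seq[i] in sites:
            return seq[s0:i + 1]
    return seq[s0:s0 + 20]


def simulate_psm_table(
    truth: GroundTruth, config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """PSM table with intensity pairs, TargetP-style table, localization table.

    Each planted N-terminus yields PSMs per enzyme; a PSM is in vivo (light)
    acetylated with probability equal to the planted degree, in vitro heavy-
    acetylated otherwise, and carries a light/heavy precursor intensity pair
    whose light fraction has expectation equal to the planted degree with
    the configured coefficient of variation.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 29])
    rows = []
    for nt in truth.ntermini:
        parent = truth.proteoforms[nt.protein]
        p = nt.degree / 100.0
        # observed peptide starts at nt.start; retained-Met termini read M
        seq_from = parent[nt.start - 1:]
        if nt.imet_retained:
            seq_from = "M" + seq_from[1:]
        for enzyme in config.enzyme_set:
            pep = _nterm_peptide("X" * (nt.start - 1) + seq_from, nt.start, enzyme)
            n_psm = int(rng.integers(*config.psms_per_enzyme))
            for _ in range(n_psm):
                light, heavy = simulate_intensity_pair(
                    rng, nt.degree, config.intensity_noise_cv
                )
                mod = "light_acetyl" if rng.random() < p else "free_heavy"
                rows.append(
                    {
                        "peptide": pep,
                        "protein": nt.protein,
                        "start": nt.start,
                        "modification": mod,
                        "enzyme": enzyme,
                        "q_value": float(rng.uniform(1e-4, 9e-3)),
                        "intensity_light": light,
                        "intensity_heavy": heavy,
                    }
                )
    n_decoys = int(round(config.decoy_fraction * len(rows)))
    for i in range(n_decoys):
        pep = "".join(rng.choice(list(AA_ALPHABET), size=10))
        rows.append(
            {
                "peptide": pep,
                "protein": f"DECOY{i + 1:04d}",
                "start": 1,
                "modification": "free_heavy",
                "enzyme": config.enzyme_set[0],
                "q_value": float(rng.uniform(0.02, 0.5)),
                "intensity_light": 0.0,
                "intensity_heavy": float(rng.lognormal(np.log(1e4), 0.5)),
            }
        )
    psms = pd.DataFrame(rows)

    targetp = pd.DataFrame(
        [
            {"protein": c.protein, "prediction": c.prediction, "site": c.p1_prime - 1}
            for c in truth.cleavages
        ]
        + [
            {"protein": tid, "prediction": "noTP", "site": 0}
            for tid in truth.proteoforms
            if tid not in {c.protein for c in truth.cleavages}
        ]
    )
    loc = pd.DataFrame(
        [
            {"protein": tid, "localization": truth.localization[tid]}
            for tid in truth.proteoforms
        ]
    )
    return psms, targetp, loc


# -- convenience writer ----------------------------------------------------

def write_outputs(
    outdir: str | Path,
    genome: dict[str, str],
    models: list[TranscriptModel],
    truth: GroundTruth,
    ltm: list[AlignedRead],
    chx: list[AlignedRead],
    psms: pd.DataFrame,
    targetp: pd.DataFrame,
    loc: pd.DataFrame,
    sam: bool = False,
) -> dict[str, Path]:
    from .footprints import write_alignments_sam, write_alignments_tsv
    from .models import write_genome_fasta, write_gff3

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "gff": outdir / "annotation.gff3",
        "ltm": outdir / "ltm.alignments.tsv",
        "chx": outdir / "chx.alignments.tsv",
        "psms": outdir / "psms.tsv",
        "targetp": outdir / "targetp.tsv",
        "localization": outdir / "localization.tsv",
        "truth": outdir / "ground_truth.json",
    }
    write_genome_fasta(genome, paths["genome"])
    write_gff3(models, paths["gff"])
    write_alignments_tsv(ltm, paths["ltm"])
    write_alignments_tsv(chx, paths["chx"])
    if sam:
        sizes = {c: len(s) for c, s in genome.items()}
        write_alignments_sam(ltm, sizes, outdir / "ltm.sam")
        write_alignments_sam(chx, sizes, outdir / "chx.sam")
    psms.to_csv(paths["psms"], sep="\t", index=False)
    targetp.to_csv(paths["targetp"], sep="\t", index=False)
    loc.to_csv(paths["localization"], sep="\t", index=False)
    truth.to_json(paths["truth"])
    return paths
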