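"""End-to-end orchestration: footprints -> TIS calling -> proteoform
database -> N-terminus classification -> NTA quantification -> cleavage
annotation, with a serializable configuration and a JSON run report."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import (
    cleavage_annotator as cleav,
    footprints as fp,
    nta_quant,
    nterm_classifier as ntc,
    proteoform_db as pdb,
    tis_caller as tc,
)
from .models import read_genome_fasta, read_gff3

log = logging.getLogger("riboproteo")

__all__ = ["RunConfig", "run_all"]


@dataclass
class RunConfig:
    genome: str = ""
    gff: str = ""
    ltm: str = ""
    chx: str = ""
    psms: str = ""
    targetp: str = ""
    localization: str = ""
    outdir: str = "riboproteo_out"
    alignment_format: str = "tsv"  # tsv | sam
    thresholds: tc.TISThresholds = field(default_factory=tc.TISThresholds)
    q_max: float = 0.01
    min_psm: int = 2
    strict_nme: bool = True
    cleavage_window: int = 5
    cleavage_inclusive: bool = True
    compartment: str = "chloroplast"
    nta_method: str = "sum"
    min_class_n: int = 5
    metagene_flank: int = 20
    metagene_min_rpfs: int = 20
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        thr = raw.pop("thresholds", None)
        cfg = cls(**raw)
        if thr:
            cfg.thresholds = tc.TISThresholds(**thr)
        return cfg


def _read_alignments(path: str, fmt: str):
    if fmt == "sam":
        return fp.read_alignments_sam(path)
    return fp.read_alignments_tsv(path)


def run_all(config: RunConfig) -> dict:
    """Execute every stage; write stage outputs and return the run report."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": config.to_dict(), "stages": {}}

    # ---- stage: footprints ------------------------------------------------
    try:
        genome = read_genome_fasta(config.genome)
        models = read_gff3(config.gff)
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"[inputs] failed to parse genome/annotation: {exc}") from exc
    index_models = models
    from .models import TranscriptIndex

    index = TranscriptIndex(index_models)
    sizes = {c: len(s) for c, s in genome.items()}
    try:
        ltm_reads = _read_alignments(config.ltm, config.alignment_format)
        chx_reads = _read_alignments(config.chx, config.alignment_format)
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"[footprints] failed to read alignments: {exc}") from exc
    ltm = fp.build_track(ltm_reads, "LTM", index, sizes)
    chx = fp.build_track(chx_reads, "CHX", index, sizes)
    for strand in "+-":
        fp.write_bedgraph(ltm, out / f"ltm.{'plus' if strand == '+' else 'minus'}.bedgraph", strand)
        fp.write_bedgraph(chx, out / f"chx.{'plus' if strand == '+' else 'minus'}.bedgraph", strand)
    _, aggregate, excluded = fp.metagene_density(
        chx, models, config.metagene_flank, config.metagene_min_rpfs
    )
    aggregate.to_csv(out / "metagene.chx.tsv", sep="\t", index=False)
    report["stages"]["footprints"] = {
        "ltm_accepted": ltm.n_accepted,
        "ltm_rejected": ltm.n_rejected,
        "chx_accepted": chx.n_accepted,
        "chx_rejected": chx.n_rejected,
        "metagene_excluded_genes": len(excluded),
    }

    # ---- stage: TIS calling ----------------------------------------------
    called = tc.call_tis(ltm, chx, models, genome, config.thresholds)
    tc.write_tis_tsv(called, out / "called_tis.tsv")
    tallies: dict[str, int] = {}
    for r in called:
        tallies[r.category] = tallies.get(r.category, 0) + 1
    report["stages"]["tis_caller"] = {
        "n_called": len(called),
        "by_category": tallies,
        "n_rescued": sum(1 for r in called if r.status == "rescued_dbTIS"),
    }

    # ---- stage: proteoform database ---------------------------------------
    proteome = {}
    for m in models:
        seq = m.sequence(genome)
        proteome[m.transcript_id] = pdb.translate_cds(
            seq[m.cds_start_tx: m.cds_end_tx]
        )
    entries, mapping = pdb.build_database(proteome, called, models, genome)
    pdb.write_fasta(entries, out / "proteoforms.fa")
    mapping.to_csv(out / "proteoform_mapping.tsv", sep="\t", index=False)
    report["stages"]["proteoform_db"] = {
        "n_annotated": len(proteome),
        "n_entries": len(entries),
        "n_alternative": len(entries) - len(proteome),
    }

    # ---- stage: N-terminus classification ---------------------------------
    dtis_starts: dict[str, set[int]] = {}
    for r in mapping.itertuples():
        if r.relation == "truncated_dTIS":
            dtis_starts.setdefault(r.transcript, set()).add(int(r.parent_offset) + 1)
    predictions = (
        cleav.read_targetp_tsv(config.targetp) if config.targetp else []
    )
    preds_by_protein: dict[str, list[cleav.CleavagePrediction]] = {}
    for p in predictions:
        preds_by_protein.setdefault(p.protein, []).append(p)

    records: list[ntc.NTermRecord] = []
    n_psms_in = n_psms_kept = 0
    if config.psms:
        psms = ntc.read_psm_tsv(config.psms)
        n_psms_in = len(psms)
        kept, _ = ntc.filter_psms(psms, config.q_max)
        n_psms_kept = len(kept)
        records = ntc.collapse(kept, config.min_psm)
        for rec in records:
            parent = proteome.get(rec.protein, "")
            cleavage = tuple(
                (p.prediction, p.p1_prime)
                for p in preds_by_protein.get(rec.protein, [])
                if p.prediction != "noTP"
            )
            ctx = ntc.OriginContext(
                parent=parent,
                annotated=rec.protein in proteome,
                dtis_starts=frozenset(dtis_starts.get(rec.protein, set())),
                cleavage=cleavage,
                window=config.cleavage_window,
            )
            ntc.classify_origin(rec, ctx, config.strict_nme)
        ntc.write_nterm_tsv(records, out / "ntermini.tsv")
    origin_tally: dict[str, int] = {}
    for rec in records:
        origin_tally[rec.origin] = origin_tally.get(rec.origin, 0) + 1
    report["stages"]["nterm_classifier"] = {
        "psms_in": n_psms_in,
        "psms_kept": n_psms_kept,
        "n_ntermini": len(records),
        "by_origin": origin_tally,
        "records": [
            {"protein": r.protein, "start": r.start, "origin": r.origin,
             "nat_class": r.nat_class}
            for r in records
        ],
    }

    # ---- stage: NTA quantification -----------------------------------------
    degrees: list[nta_quant.NTADegree] = []
    if config.psms:
        pairs = pd.read_csv(config.psms, sep="\t")
        pairs = pairs[pairs["q_value"] <= config.q_max]
        degrees, skipped = nta_quant.aggregate_degrees(pairs, config.nta_method)
        pd.DataFrame(
            [
                {"protein": d.protein, "start": d.start, "light": d.light,
                 "heavy": d.heavy, "degree": d.degree, "n_pairs": d.n_pairs,
                 "spread": d.spread}
                for d in degrees
            ]
        ).to_csv(out / "nta_degrees.tsv", sep="\t", index=False)
        labels = {
            (r.protein, r.start): (r.origin, r.nat_class) for r in records
        }
        summary = nta_quant.class_summary(degrees, labels, config.min_class_n)
        summary.to_csv(out / "nta_class_summary.tsv", sep="\t", index=False)
        report["stages"]["nta_quant"] = {
            "n_degrees": len(degrees),
            "n_skipped": len(skipped),
        }
    else:
        report["stages"]["nta_quant"] = {"n_degrees": 0, "n_skipped": 0}

    # ---- stage: cleavage annotation ----------------------------------------
    matches: list[cleav.NeoTerminusMatch] = []
    for rec in records:
        for p in preds_by_protein.get(rec.protein, []):
            m = cleav.match_cleavage(
                rec.start, p, config.cleavage_window, config.cleavage_inclusive
            )
            if m is not None:
                matches.append(m)
    localization = (
        cleav.read_localization_tsv(config.localization)
        if config.localization
        else {}
    )
    reps, excluded_prots = cleav.select_representative(
        matches, localization, config.compartment
    )
    motif = cleav.motif_matrix(reps, proteome)
    nta_by_start = {(r.protein, r.start): r.has_nta for r in records}
    mito_flags = cleav.flag_mito_nta(matches, nta_by_start)
    pd.DataFrame(
        [
            {"protein": m.protein, "start": m.start, "prediction": m.prediction,
             "p1_prime": m.p1_prime, "deviation": m.deviation,
             "is_representative": m.is_representative}
            for m in matches
        ]
    ).to_csv(out / "cleavage_matches.tsv", sep="\t", index=False)
    motif.frequencies.to_csv(out / "cleavage_motif.tsv", sep="\t")
    report["stages"]["cleavage_annotator"] = {
        "n_matches": len(matches),
        "n_representatives": len(reps),
        "n_excluded_no_localization": len(excluded_prots),
        "n_mito_nta_flags": len(mito_flags),
    }

    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report
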